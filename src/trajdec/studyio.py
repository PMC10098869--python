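"""On-disk persistence for studies and fitted decoders.

A study is written as a directory tree: a JSON manifest, per-block flat
binary recordings (``.npy``) with JSON sidecars (rate, channel labels, trial
boundaries), kinematics as tidy CSV (trial, t, p_hor, v_hor, p_ver, v_ver)
and the lead field in an HDF5 container with named datasets.  Fitted decoder
models are stored in HDF5 with their matrices and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import rewpls, srukf
from .containers import Kinematics, LeadField, Recording
from .scenarios import DecoderModel
from .synthgen import StudyDesign, SyntheticStudy

__all__ = ["save_study", "load_study", "save_model", "load_model"]


def _block_name(key) -> str:
    p, s, b = key
    return f"p{p:02d}_s{s}_b{b}"


def _write_recording(path: Path, rec: Recording) -> None:
    np.save(path.with_suffix(".npy"), rec.data)
    sidecar = {
        "fs": rec.fs,
        "ch_names": list(rec.ch_names),
        "trials": [list(t) for t in rec.trials],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def _read_recording(path: Path) -> Recording:
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.load(path.with_suffix(".npy"))
    return Recording(
        data=data, fs=meta["fs"], ch_names=tuple(meta["ch_names"]),
        trials=tuple(tuple(t) for t in meta["trials"]),
    )


def _write_kinematics(path: Path, kin: Kinematics) -> None:
    rows = []
    for trial_idx, (a, b) in enumerate(kin.trials):
        for t in range(a, b):
            rows.append(
                (trial_idx, t / kin.fs, kin.pos[0, t], kin.vel[0, t],
                 kin.pos[1, t], kin.vel[1, t])
            )
    pd.DataFrame(
        rows, columns=["trial", "t", "p_hor", "v_hor", "p_ver", "v_ver"]
    ).to_csv(path, index=False)


def _read_kinematics(path: Path, fs: float) -> Kinematics:
    df = pd.read_csv(path)
    pos = np.vstack([df["p_hor"].to_numpy(), df["p_ver"].to_numpy()])
    vel = np.vstack([df["v_hor"].to_numpy(), df["v_ver"].to_numpy()])
    trials = []
    for _, sub in df.groupby("trial", sort=True):
        trials.append((int(sub.index.min()), int(sub.index.max()) + 1))
    return Kinematics(pos=pos, vel=vel, fs=fs, trials=tuple(trials))


def save_study(study: SyntheticStudy, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    (out / "blocks").mkdir(parents=True, exist_ok=True)
    manifest = {
        "design": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in study.design.__dict__.items()},
        "coupling_mode": study.coupling_mode,
        "snr_db": study.snr_db,
        "seed": study.seed,
        "blocks": [list(k) for k in study.block_keys()],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for key in study.block_keys():
        stem = out / "blocks" / _block_name(key)
        _write_recording(stem, study.recordings[key])
        _write_kinematics(stem.with_name(stem.name + "_kin.csv"), study.kinematics[key])
    for p, rec in study.noise_blocks.items():
        _write_recording(out / "blocks" / f"p{p:02d}_noise", rec)
    with h5py.File(out / "leadfield.h5", "w") as f:
        lf = study.leadfield
        f.create_dataset("gain", data=lf.gain)
        f.create_dataset("positions", data=lf.source_positions)
        f.create_dataset("electrodes", data=lf.electrode_positions)
        f.create_dataset("roi_map", data=np.asarray(lf.roi_map, dtype="S"))
        grp = f.create_group("coupling")
        for (p, s), b in study.coupling.items():
            grp.create_dataset(f"p{p:02d}_s{s}", data=b)
        f.create_dataset("coupled_components", data=study.coupled_components)
    return out


def load_study(in_dir: str | Path) -> SyntheticStudy:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    raw_design = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in manifest["design"].items()
    }
    design = StudyDesign(**raw_design)
    with h5py.File(src / "leadfield.h5", "r") as f:
        leadfield = LeadField(
            gain=f["gain"][()],
            source_positions=f["positions"][()],
            orientations=np.eye(3),
            roi_map=np.asarray([x.decode() for x in f["roi_map"][()]]),
            electrode_positions=f["electrodes"][()],
        )
        coupling = {}
        for name, dset in f["coupling"].items():
            p, s = int(name[1:3]), int(name[5:])
            coupling[(p, s)] = dset[()]
        coupled_components = f["coupled_components"][()]
    recordings, kinematics = {}, {}
    for key_list in manifest["blocks"]:
        key = (int(key_list[0]), int(key_list[1]), str(key_list[2]))
        stem = src / "blocks" / _block_name(key)
        recordings[key] = _read_recording(stem)
        kinematics[key] = _read_kinematics(
            stem.with_name(stem.name + "_kin.csv"), design.fs
        )
    noise_blocks = {
        p: _read_recording(src / "blocks" / f"p{p:02d}_noise")
        for p in range(design.n_participants)
    }
    return SyntheticStudy(
        design=design, leadfield=leadfield, recordings=recordings,
        kinematics=kinematics, noise_blocks=noise_blocks, coupling=coupling,
        coupled_components=coupled_components,
        coupling_mode=manifest["coupling_mode"], snr_db=manifest["snr_db"],
        seed=manifest["seed"],
    )


def save_model(model: DecoderModel, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["name"] = model.name
        f.attrs["n_components"] = model.n_components
        f.attrs["lam"] = model.pls.lam
        f.attrs["training_blocks"] = json.dumps([list(k) for k in model.training_blocks])
        pls = f.create_group("pls")
        for key in ("weights", "loadings", "y_loadings", "coef", "mean_y", "mean_z"):
            pls.create_dataset(key, data=getattr(model.pls, key))
        ukf = f.create_group("ukf")
        for key in ("f_tr", "f_offset", "q_pr", "h_obs", "h_offset", "r_m",
                    "init_state", "init_cov"):
            ukf.create_dataset(key, data=getattr(model.ukf, key))
        for key in ("alpha_s", "beta_s", "kappa_s"):
            ukf.attrs[key] = getattr(model.ukf, key)
        st = f.create_group("state")
        for key in ("cyy", "cyz", "sum_y", "sum_z"):
            st.create_dataset(key, data=getattr(model.state, key))
        st.attrs["weight"] = model.state.weight
        st.attrs["lam"] = model.state.lam
        st.attrs["n_batches"] = model.state.n_batches
    return path


def load_model(path: str | Path) -> DecoderModel:
    with h5py.File(path, "r") as f:
        pls = rewpls.PLSModel(
            weights=f["pls/weights"][()],
            loadings=f["pls/loadings"][()],
            y_loadings=f["pls/y_loadings"][()],
            coef=f["pls/coef"][()],
            mean_y=f["pls/mean_y"][()],
            mean_z=f["pls/mean_z"][()],
            n_components=int(f.attrs["n_components"]),
            lam=float(f.attrs["lam"]),
        )
        ukf = srukf.UKFModel(
            f_tr=f["ukf/f_tr"][()], f_offset=f["ukf/f_offset"][()],
            q_pr=f["ukf/q_pr"][()], h_obs=f["ukf/h_obs"][()],
            h_offset=f["ukf/h_offset"][()], r_m=f["ukf/r_m"][()],
            init_state=f["ukf/init_state"][()], init_cov=f["ukf/init_cov"][()],
            alpha_s=float(f["ukf"].attrs["alpha_s"]),
            beta_s=float(f["ukf"].attrs["beta_s"]),
            kappa_s=float(f["ukf"].attrs["kappa_s"]),
        )
        state = rewpls.CovarianceState(
            cyy=f["state/cyy"][()], cyz=f["state/cyz"][()],
            sum_y=f["state/sum_y"][()], sum_z=f["state/sum_z"][()],
            weight=float(f["state"].attrs["weight"]),
            lam=float(f["state"].attrs["lam"]),
            n_batches=int(f["state"].attrs["n_batches"]),
        )
        training = tuple(
            tuple(k) for k in json.loads(f.attrs["training_blocks"])
        )
        return DecoderModel(
            name=str(f.attrs["name"]), pls=pls, ukf=ukf, state=state,
            n_components=int(f.attrs["n_components"]),
            training_blocks=training,
        )
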