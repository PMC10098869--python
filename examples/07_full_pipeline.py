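"""End-to-end orchestrated run: simulate, decode, evaluate, persist.

Runs the whole analysis from a single configuration mapping and prints what
lands in the results directory.  A rerun with the same configuration is
bit-identical.
"""

import json
import tempfile
from pathlib import Path

import pandas as pd

from trajdec import workbench

config = dict(
    study=dict(n_participants=3, n_sessions=2, n_trials_per_block=4,
               trial_duration_s=5.0, n_channels=12, n_locations=84),
    coupling_mode="shared",
    snr_db=10.0,
    seed=42,
    spaces=["sensor"],
    decoder=dict(a_max=6, n_folds=4),
    evaluation=dict(n_repeats=3, chance_models=["Gen"], chance_eval_samples=100),
)

with tempfile.TemporaryDirectory() as tmp:
    out = workbench.run_pipeline(config, Path(tmp) / "run")
    print("results written:", sorted(p.name for p in out.iterdir()))
    metrics = pd.read_csv(out / "metrics.csv")
    summary = (
        metrics[metrics["kinematic"].isin(["v_hor", "v_ver"])]
        .assign(abs_r=lambda t: t["r"].abs())
        .groupby("strategy")["abs_r"].median().round(3)
    )
    print("\nmedian velocity |r| by strategy (shared coupling):")
    print(summary.to_string())
    chance = json.loads((out / "chance.json").read_text())
    print("\ngroup chance level (Gen, sensor):",
          {k: round(v, 3) for k, v in chance["group"]["sensor"]["Gen"].items()})
    manifest = json.loads((out / "manifest.json").read_text())
    print(f"\nconfig digest {manifest['config_digest']} — rerunning with the same"
          " configuration reproduces every CSV byte-for-byte")
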