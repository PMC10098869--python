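"""Signal conditioning chain and lag embedding.

The chain reproduces the standard low-frequency trajectory-decoding recipe:
high-pass at 0.18 Hz, downsample to 100 Hz, common average reference, low-pass
at 3 Hz, downsample to 20 Hz, then expansion of each feature with its lags from
-6 to 0 samples (-300 to 0 ms at 20 Hz).

Filters are zero-phase 4th-order Butterworth applied forward-backward, so the
sample-wise pairing between features and kinematics survives every stage;
resampling is polyphase with integer rate ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal

from .containers import Kinematics, LaggedFeatures, Recording

__all__ = [
    "PreprocessConfig",
    "filter_chain",
    "common_average_reference",
    "lag_expand",
    "resample_kinematics",
    "lag_times_ms",
    "DEFAULT_LAGS",
]

#: Default lag offsets in samples at the decoding rate (0 .. -6).
DEFAULT_LAGS: tuple[int, ...] = tuple(range(0, -7, -1))


@dataclass
class PreprocessConfig:
    hp_hz: float = 0.18
    hp_order: int = 4
    lp_hz: float = 3.0
    lp_order: int = 4
    mid_fs: float = 100.0
    out_fs: float = 20.0
    lags: tuple[int, ...] = DEFAULT_LAGS


def _rescale_trials(
    trials: Sequence[tuple[int, int]], fs_in: float, fs_out: float, n_out: int
) -> tuple[tuple[int, int], ...]:
    ratio = fs_out / fs_in
    out = []
    for start, stop in trials:
        a = int(round(start * ratio))
        b = min(int(round(stop * ratio)), n_out)
        if b > a:
            out.append((a, b))
    return tuple(out)


def _resample(data: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)


def filter_chain(recording: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Apply the conditioning chain; output is at ``cfg.out_fs`` (default 20 Hz).

    Stages, in order: zero-phase high-pass -> resample to ``mid_fs`` ->
    zero-phase low-pass -> resample to ``out_fs``.  Trial boundaries are
    rescaled to the output rate.
    """
    cfg = cfg or PreprocessConfig()
    fs = recording.fs
    for cutoff, rate in ((cfg.hp_hz, fs), (cfg.lp_hz, cfg.mid_fs)):
        if cutoff >= rate / 2.0:
            raise ValueError(f"cutoff {cutoff} Hz >= Nyquist at {rate} Hz")
    if cfg.out_fs > cfg.mid_fs or cfg.mid_fs > fs:
        raise ValueError("rates must decrease along the chain")

    x = np.asarray(recording.data, dtype=float)
    sos_hp = signal.butter(cfg.hp_order, cfg.hp_hz, btype="highpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos_hp, x, axis=1)
    x = _resample(x, fs, cfg.mid_fs)
    sos_lp = signal.butter(cfg.lp_order, cfg.lp_hz, btype="lowpass", fs=cfg.mid_fs, output="sos")
    x = signal.sosfiltfilt(sos_lp, x, axis=1)
    x = _resample(x, cfg.mid_fs, cfg.out_fs)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite values after filtering")
    trials = _rescale_trials(recording.trials, fs, cfg.out_fs, x.shape[1])
    return Recording(data=x, fs=cfg.out_fs, ch_names=recording.ch_names, trials=trials)


def common_average_reference(recording: Recording) -> Recording:
    """Subtract the instantaneous mean across channels from every channel."""
    if recording.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    x = np.asarray(recording.data, dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    return recording.copy_with(data=x)


def resample_kinematics(kin: Kinematics, out_fs: float) -> Kinematics:
    """Decimate band-limited kinematics to ``out_fs`` by exact sub-sampling.

    The snake trajectory is band-limited well below the target Nyquist rate, so
    plain decimation is alias-free and keeps samples exactly on the output
    grid of the resampled recordings.
    """
    ratio = kin.fs / out_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError("kinematics rate must be an integer multiple of out_fs")
    pos = kin.pos[:, ::factor]
    vel = kin.vel[:, ::factor]
    trials = _rescale_trials(kin.trials, kin.fs, out_fs, pos.shape[1])
    return Kinematics(pos=pos, vel=vel, fs=out_fs, trials=trials)


def lag_times_ms(lags: Sequence[int] = DEFAULT_LAGS, fs: float = 20.0) -> tuple[float, ...]:
    """Lag offsets expressed in milliseconds at rate ``fs``."""
    return tuple(1000.0 * lag / fs for lag in lags)


def lag_expand(
    features: np.ndarray,
    trials: Sequence[tuple[int, int]] | None = None,
    lags: Sequence[int] = DEFAULT_LAGS,
    feature_labels: Sequence[str] | None = None,
) -> LaggedFeatures:
    """Expand each feature row with its (non-positive) lags.

    The embedding is per trial: the first ``L - 1`` samples of every trial are
    dropped rather than padded, so no sample mixes data across a trial boundary
    and no fabricated values enter the features.  ``kept_columns`` records which
    original columns survived, so paired targets can be subset identically.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n_feat, n_samples = features.shape
    lags = tuple(int(l) for l in lags)
    if any(l > 0 for l in lags):
        raise ValueError("lags must be non-positive (anti-causal offsets are not allowed)")
    if len(set(lags)) != len(lags):
        raise ValueError("duplicate lag offsets")
    max_back = -min(lags)
    if max_back >= n_samples:
        raise ValueError("largest lag magnitude must be smaller than the series length")
    if trials is None:
        trials = [(0, n_samples)]
    if feature_labels is None:
        feature_labels = tuple(f"f{i}" for i in range(n_feat))

    kept: list[np.ndarray] = []
    out_trials: list[tuple[int, int]] = []
    pos = 0
    for start, stop in trials:
        if stop - start <= max_back:
            raise ValueError(f"trial ({start}, {stop}) shorter than the lag window")
        cols = np.arange(start + max_back, stop)
        kept.append(cols)
        out_trials.append((pos, pos + cols.size))
        pos += cols.size
    kept_columns = np.concatenate(kept)

    blocks = [features[:, kept_columns + lag] for lag in lags]
    data = np.vstack(blocks)
    return LaggedFeatures(
        data=data,
        lags=lags,
        feature_labels=tuple(feature_labels),
        trials=tuple(out_trials),
        kept_columns=kept_columns,
    )
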