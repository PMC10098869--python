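"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Multichannel time series are ``(channels, samples)`` arrays; a column is one
  time step.
* Trial boundaries are 0-based, half-open ``(start, stop)`` sample intervals.
* Kinematics rows are ordered ``(p_hor, v_hor, p_ver, v_ver)``; the extended
  kinematics append distance ``d`` and speed ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: Canonical kinematic channel names (linear kinematics).
KINEMATIC_NAMES = ("p_hor", "v_hor", "p_ver", "v_ver")

#: Extended kinematics: linear kinematics plus distance and speed.
EXTENDED_KINEMATIC_NAMES = KINEMATIC_NAMES + ("d", "s")

#: Region-of-interest base names, one hemisphere.  Anatomical regions around the
#: central/medial wall that carry movement-related low-frequency activity:
#: cuneus, paracentral lobule, and split superior frontal, pre/postcentral,
#: superior parietal, precuneus and occipital gyri.
ROI_BASE_NAMES = (
    "CU", "PCL",
    "aSFG", "pSFG",
    "mPreCG", "lPreCG",
    "mPoCG", "lPoCG",
    "aSPL", "pSPL",
    "aPCU", "pPCU",
    "sOG", "iOG",
)

#: The 28 ROI labels (14 per hemisphere).
ROI_LABELS = tuple(f"{hemi}_{name}" for hemi in ("L", "R") for name in ROI_BASE_NAMES)


def _check_trials(trials: Sequence[tuple[int, int]], n_samples: int) -> tuple[tuple[int, int], ...]:
    out = []
    prev = 0
    for start, stop in trials:
        start, stop = int(start), int(stop)
        if not (0 <= start < stop <= n_samples):
            raise ValueError(f"trial ({start}, {stop}) outside [0, {n_samples})")
        if start < prev:
            raise ValueError("trials must be sorted and non-overlapping")
        prev = stop
        out.append((start, stop))
    return tuple(out)


@dataclass
class Recording:
    """A multichannel recording with sampling rate and trial structure."""

    data: np.ndarray            # (P, T)
    fs: float
    ch_names: tuple[str, ...]
    trials: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError("channel labels do not match data rows")
        self.ch_names = tuple(self.ch_names)
        self.trials = _check_trials(self.trials, self.data.shape[1])

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class Kinematics:
    """2-D target kinematics: horizontal/vertical position and velocity.

    ``pos`` and ``vel`` are ``(2, T)`` arrays with rows (horizontal, vertical)
    in screen units and screen units/s.
    """

    pos: np.ndarray
    vel: np.ndarray
    fs: float
    trials: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)
        if self.pos.shape != self.vel.shape or self.pos.ndim != 2 or self.pos.shape[0] != 2:
            raise ValueError("pos and vel must both be (2, T)")
        if not self.trials:
            self.trials = ((0, self.pos.shape[1]),)
        self.trials = _check_trials(self.trials, self.pos.shape[1])

    @property
    def n_samples(self) -> int:
        return self.pos.shape[1]

    def as_matrix(self) -> np.ndarray:
        """Return the (4, T) linear-kinematics matrix (p_hor, v_hor, p_ver, v_ver)."""
        return np.vstack([self.pos[0], self.vel[0], self.pos[1], self.vel[1]])


@dataclass
class LeadField:
    """Sensor gain model: unit source amplitude -> sensor potentials.

    ``gain`` is ``(P, Q)`` with ``Q = 3 * n_locations`` (three free orientation
    components per source location, ordered x, y, z per location).
    """

    gain: np.ndarray                 # (P, Q)
    source_positions: np.ndarray     # (n_locations, 3)
    orientations: np.ndarray         # (3, 3) canonical axes (rows)
    roi_map: np.ndarray              # (n_locations,) of str labels
    electrode_positions: np.ndarray  # (P, 3)

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.source_positions = np.asarray(self.source_positions, dtype=float)
        self.roi_map = np.asarray(self.roi_map)
        q = self.gain.shape[1]
        if q % 3 != 0:
            raise ValueError("gain must have a multiple of 3 columns")
        if q // 3 != self.source_positions.shape[0] or q // 3 != self.roi_map.shape[0]:
            raise ValueError("source positions / roi_map inconsistent with gain")
        if np.any(np.all(self.gain == 0.0, axis=0)):
            raise ValueError("gain has an all-zero column")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_locations(self) -> int:
        return self.gain.shape[1] // 3

    @property
    def n_components(self) -> int:
        return self.gain.shape[1]

    def roi_locations(self, label: str) -> np.ndarray:
        """Indices of source locations belonging to ROI ``label``."""
        return np.flatnonzero(self.roi_map == label)


@dataclass
class LaggedFeatures:
    """Lag-embedded feature matrix paired sample-wise with its targets.

    ``data`` has ``L * F`` rows; column ``t`` stacks the feature vectors at the
    kept sample and its ``L - 1`` preceding samples (lag blocks ordered as in
    ``lags``).  ``kept_columns`` indexes the original columns that survived the
    per-trial edge trimming so that targets can be subset identically.
    """

    data: np.ndarray
    lags: tuple[int, ...]
    feature_labels: tuple[str, ...]
    trials: tuple[tuple[int, int], ...]
    kept_columns: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.lags) * len(self.feature_labels):
            raise ValueError("row count must equal n_lags * n_features")
        self.trials = _check_trials(self.trials, self.data.shape[1])

    @property
    def n_lags(self) -> int:
        return len(self.lags)
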