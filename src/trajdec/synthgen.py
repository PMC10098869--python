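"""Synthetic multi-participant pursuit-tracking studies with known ground truth.

The generator emulates the structure of a three-session pursuit-tracking
experiment: per participant and session, blocks of continuous 2-D target
("snake") kinematics paired with multichannel EEG-like recordings.  Sensor data
follow the linear generative model ``X = G J + n``: a dipole-like gain matrix
``G`` mixes cortical source activity ``J`` into the sensors, where sources
inside designated coupling ROIs carry a linear function of the (lagged) target
kinematics and all remaining sources carry 1/f background noise; white sensor
noise is added at a configurable SNR.

Because the coupling matrices are stored alongside the data, every downstream
stage (inverse modeling, decoding, transfer scenarios, pattern recovery) can be
validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .containers import (
    Kinematics,
    LeadField,
    Recording,
    ROI_BASE_NAMES,
    ROI_LABELS,
)

__all__ = [
    "StudyDesign",
    "SyntheticStudy",
    "gen_leadfield",
    "gen_snake",
    "gen_study",
]

COUPLING_MODES = ("shared", "participant_specific", "session_drift")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

_GOLDEN = math.pi * (3.0 - math.sqrt(5.0))


def _fibonacci_sphere(n: int, phase: float = 0.0) -> np.ndarray:
    """n approximately evenly distributed points on the unit sphere."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = _GOLDEN * i + phase
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n points on the upper unit hemisphere (electrode montage stand-in)."""
    i = np.arange(n)
    z = 1.0 - (i + 0.5) / n  # z in (0, 1)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = _GOLDEN * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def gen_leadfield(
    n_channels: int = 32,
    n_locations: int = 500,
    seed: int = 0,
    source_radius: float = 0.85,
) -> LeadField:
    """Generate a dipole-like lead field on a unit sphere.

    Electrodes sit on the upper surface of a unit sphere; source locations are
    spread over a concentric sphere of radius ``source_radius`` (< 1).  Each
    location carries three orthogonal orientation components (x, y, z).  The
    gain of component ``o`` of source ``j`` at electrode ``i`` is
    ``o . d_ij / ||r_i - s_j||**2`` with ``d_ij`` the unit vector from source to
    electrode — a qualitatively EEG-like smooth distance falloff without a
    boundary-element model.

    ROI labels partition the locations into the 28 canonical regions by nearest
    angular patch center; every ROI is guaranteed at least one location.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if n_locations < len(ROI_LABELS):
        raise ValueError(
            f"n_locations must be >= {len(ROI_LABELS)} (one per ROI), got {n_locations}"
        )
    rng = np.random.default_rng(seed)
    electrodes = _fibonacci_hemisphere(n_channels)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    sources = _fibonacci_sphere(n_locations, phase=phase) * source_radius

    # gain: (P, n_loc, 3) -> (P, 3*n_loc)
    diff = electrodes[:, None, :] - sources[None, :, :]          # (P, n_loc, 3)
    dist = np.linalg.norm(diff, axis=2)                          # (P, n_loc)
    gain3 = diff / dist[:, :, None] ** 3                         # unit_vec / dist^2
    gain = gain3.reshape(n_channels, 3 * n_locations)

    # ROI assignment: nearest of 28 evenly spread patch centers.
    centers = _fibonacci_sphere(len(ROI_LABELS), phase=phase)
    cos = (sources / source_radius) @ centers.T
    assign = np.argmax(cos, axis=1)
    # guarantee non-empty ROIs: move the globally closest free source into any
    # empty patch
    for k in range(len(ROI_LABELS)):
        if not np.any(assign == k):
            counts = np.bincount(assign, minlength=len(ROI_LABELS))
            movable = counts[assign] > 1
            cand = np.flatnonzero(movable)
            assign[cand[np.argmax(cos[cand, k])]] = k
    roi_map = np.asarray([ROI_LABELS[k] for k in assign])

    return LeadField(
        gain=gain,
        source_positions=sources,
        orientations=np.eye(3),
        roi_map=roi_map,
        electrode_positions=electrodes,
    )


# ---------------------------------------------------------------------------
# snake kinematics
# ---------------------------------------------------------------------------


def gen_snake(
    duration_s: float,
    fs: float,
    band_hz: tuple[float, float] = (0.1, 1.5),
    seed: int = 0,
    n_components: int = 24,
    amplitude: float = 1.0,
) -> Kinematics:
    """Band-limited random 2-D target trajectory with analytic velocity.

    Each position dimension is a sum of ``n_components`` random-phase sinusoids
    with frequencies drawn uniformly in ``band_hz``; the velocity is the exact
    analytic derivative sampled at ``fs``.  Positions are scaled so that each
    dimension has standard deviation ``amplitude``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    f_lo, f_hi = band_hz
    if not (0.0 < f_lo < f_hi):
        raise ValueError("band_hz must satisfy 0 < f_lo < f_hi")
    if f_hi >= fs / 2.0:
        raise ValueError("band upper edge must be below Nyquist")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    pos = np.empty((2, n))
    vel = np.empty((2, n))
    for dim in range(2):
        freqs = rng.uniform(f_lo, f_hi, n_components)
        phases = rng.uniform(0.0, 2.0 * math.pi, n_components)
        amps = rng.uniform(0.5, 1.0, n_components)
        arg = 2.0 * math.pi * freqs[:, None] * t[None, :] + phases[:, None]
        p = (amps[:, None] * np.sin(arg)).sum(axis=0)
        v = (amps[:, None] * (2.0 * math.pi * freqs[:, None]) * np.cos(arg)).sum(axis=0)
        # analytic RMS of the sinusoid sum: sqrt(sum a_k^2 / 2)
        scale = amplitude / math.sqrt(float(np.sum(amps**2)) / 2.0)
        pos[dim] = p * scale
        vel[dim] = v * scale
    return Kinematics(pos=pos, vel=vel, fs=fs, trials=((0, n),))


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------


@dataclass
class StudyDesign:
    """Sizes, rates and coupling geometry of a synthetic study.

    Defaults are a desk-scale study: 8 participants, 3 sessions of 3 blocks
    (0%, 50%, 100% feedback), 6 contiguous 20-s trials per block, 32 channels
    at 200 Hz over 500 source locations.  The full-size configuration used by
    the original experiment (10 participants, 60 channels, 5000 locations) is
    reachable through these fields.
    """

    n_participants: int = 8
    n_sessions: int = 3
    blocks: tuple[str, ...] = ("0", "50", "100")
    n_trials_per_block: int = 6
    trial_duration_s: float = 20.0
    fs: float = 200.0
    n_channels: int = 32
    n_locations: int = 500
    band_hz: tuple[float, float] = (0.1, 1.5)
    #: ROI base names whose sources carry kinematic information.
    coupling_rois: tuple[str, ...] = ("PCL", "aPCU", "pPCU", "CU")
    #: Lags (in samples at ``fs``) of the kinematics feeding the sources.
    coupling_lags: tuple[int, ...] = (0, -10, -20)
    #: RMS of 1/f background source activity relative to coupled sources.
    background_rms: float = 0.5
    #: Rotation (degrees per session) of the coupling in kinematic space for
    #: ``session_drift`` mode.
    session_drift_deg: float = 30.0
    #: Duration of the per-participant noise-only block (for noise covariance).
    noise_block_duration_s: float = 20.0

    @property
    def block_duration_s(self) -> float:
        return self.n_trials_per_block * self.trial_duration_s

    @property
    def samples_per_block(self) -> int:
        return int(round(self.block_duration_s * self.fs))

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_sessions < 1:
            raise ValueError("need at least one participant and session")
        for name in self.coupling_rois:
            if name not in ROI_BASE_NAMES:
                raise ValueError(f"unknown coupling ROI base name: {name}")
        if any(l > 0 for l in self.coupling_lags):
            raise ValueError("coupling lags must be non-positive")


@dataclass
class SyntheticStudy:
    """A generated study: recordings, kinematics and the ground truth."""

    design: StudyDesign
    leadfield: LeadField
    recordings: dict          # (participant, session, block) -> Recording
    kinematics: dict          # (participant, session, block) -> Kinematics
    noise_blocks: dict        # participant -> Recording (no kinematic coupling)
    coupling: dict            # (participant, session) -> B (n_coupled, 4*n_lags)
    coupled_components: np.ndarray  # column indices into leadfield.gain
    coupling_mode: str
    snr_db: float
    seed: int

    @property
    def participants(self) -> list[int]:
        return list(range(self.design.n_participants))

    def block_keys(self) -> list[tuple[int, int, str]]:
        return sorted(self.recordings.keys())


def _pink_noise(rng: np.random.Generator, n_rows: int, n_samples: int) -> np.ndarray:
    """Rows of 1/f-power-spectrum Gaussian noise, each with unit variance."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros(n_freq)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^(-1/2) => power ~ 1/f
    spec = rng.standard_normal((n_rows, n_freq)) + 1j * rng.standard_normal((n_rows, n_freq))
    spec *= shaping[None, :]
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _lagged_drive(kin: Kinematics, lags: tuple[int, ...]) -> np.ndarray:
    """(4*L, T) standardized lagged kinematic drive at the recording rate."""
    z = kin.as_matrix()
    z = z / z.std(axis=1, keepdims=True)
    blocks = []
    for lag in lags:
        shifted = np.roll(z, -lag, axis=1)
        if lag < 0:
            shifted[:, : -lag] = z[:, [0]]
        blocks.append(shifted)
    return np.vstack(blocks)


def _kinematic_rotation(n_drive: int, angle_rad: float) -> np.ndarray:
    """Rotation of the coupling in kinematic space: rotate the (hor, ver)
    plane of positions and of velocities by ``angle_rad`` in every lag block."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    r4 = np.eye(4)
    r4[0, 0] = r4[2, 2] = c
    r4[0, 2], r4[2, 0] = -s, s  # positions
    r4[1, 1] = r4[3, 3] = c
    r4[1, 3], r4[3, 1] = -s, s  # velocities
    n_lags = n_drive // 4
    out = np.zeros((n_drive, n_drive))
    for k in range(n_lags):
        out[4 * k : 4 * k + 4, 4 * k : 4 * k + 4] = r4
    return out


def gen_study(
    design: StudyDesign | None = None,
    coupling_mode: str = "shared",
    snr_db: float = 10.0,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a complete synthetic study.

    ``coupling_mode`` controls how the source-to-kinematics coupling matrix B
    varies: ``shared`` (identical across participants — transfer learning can
    succeed), ``participant_specific`` (independent random B per participant —
    across-participant transfer should fail), or ``session_drift`` (per-
    participant B rotated in kinematic space by a fixed angle per session).

    ``snr_db`` sets white sensor noise power relative to the noiseless sensor
    signal ``G J`` (np.inf disables sensor noise).
    """
    design = design or StudyDesign()
    design.validate()
    if coupling_mode not in COUPLING_MODES:
        raise ValueError(f"unknown coupling_mode {coupling_mode!r}; use one of {COUPLING_MODES}")

    root = np.random.SeedSequence(seed)
    ss_lead, ss_coupling, ss_blocks, ss_noise = root.spawn(4)

    leadfield = gen_leadfield(
        design.n_channels, design.n_locations, seed=ss_lead
    )

    # coupled source components: all 3 orientation components of every location
    # whose ROI base name is in design.coupling_rois
    base = np.asarray([label.split("_", 1)[1] for label in leadfield.roi_map])
    coupled_locs = np.flatnonzero(np.isin(base, design.coupling_rois))
    if coupled_locs.size == 0:
        raise ValueError("no source locations fall inside the coupling ROIs")
    coupled_cols = (3 * coupled_locs[:, None] + np.arange(3)[None, :]).ravel()
    n_coupled = coupled_cols.size
    n_drive = 4 * len(design.coupling_lags)

    # coupling matrices, unit-norm rows
    rng_b = np.random.default_rng(ss_coupling)
    def _draw_b() -> np.ndarray:
        b = rng_b.standard_normal((n_coupled, n_drive))
        return b / np.linalg.norm(b, axis=1, keepdims=True)

    coupling: dict[tuple[int, int], np.ndarray] = {}
    if coupling_mode == "shared":
        b_shared = _draw_b()
        for p in range(design.n_participants):
            for s in range(1, design.n_sessions + 1):
                coupling[(p, s)] = b_shared
    else:
        for p in range(design.n_participants):
            b_p = _draw_b()
            for s in range(1, design.n_sessions + 1):
                if coupling_mode == "session_drift":
                    rot = _kinematic_rotation(
                        n_drive, math.radians(design.session_drift_deg) * (s - 1)
                    )
                    coupling[(p, s)] = b_p @ rot.T
                else:
                    coupling[(p, s)] = b_p

    g_coupled = leadfield.gain[:, coupled_cols]
    bg_cols = np.setdiff1d(np.arange(leadfield.n_components), coupled_cols)
    g_bg = leadfield.gain[:, bg_cols]

    n_keys = design.n_participants * design.n_sessions * len(design.blocks)
    block_seeds = ss_blocks.spawn(n_keys)
    noise_seeds = ss_noise.spawn(design.n_participants)

    ch_names = tuple(f"CH{i+1:02d}" for i in range(design.n_channels))
    t_block = design.samples_per_block
    trial_len = int(round(design.trial_duration_s * design.fs))
    trials = tuple(
        (k * trial_len, (k + 1) * trial_len) for k in range(design.n_trials_per_block)
    )

    def _sensor_block(rng: np.random.Generator, kin: Kinematics | None,
                      b: np.ndarray | None, n_samples: int) -> np.ndarray:
        """X = G_c (B zlag) + G_bg J_bg + sensor noise."""
        x = np.zeros((design.n_channels, n_samples))
        if kin is not None and b is not None:
            j_c = b @ _lagged_drive(kin, design.coupling_lags)
            x += g_coupled @ j_c
        if design.background_rms > 0 and g_bg.shape[1] > 0:
            chunk = 256
            for lo in range(0, g_bg.shape[1], chunk):
                hi = min(lo + chunk, g_bg.shape[1])
                j_bg = _pink_noise(rng, hi - lo, n_samples) * design.background_rms
                x += g_bg[:, lo:hi] @ j_bg
        if np.isfinite(snr_db):
            sig_power = float(np.mean(x**2))
            noise_sd = math.sqrt(sig_power / (10.0 ** (snr_db / 10.0))) if sig_power > 0 else 1.0
            x = x + noise_sd * rng.standard_normal(x.shape)
        return x.astype(np.float32)

    recordings: dict = {}
    kinematics: dict = {}
    k = 0
    for p in range(design.n_participants):
        for s in range(1, design.n_sessions + 1):
            for b_name in design.blocks:
                kin_ss, noise_ss = block_seeds[k].spawn(2)
                k += 1
                kin = gen_snake(
                    design.block_duration_s, design.fs, design.band_hz, seed=kin_ss
                )
                kin = Kinematics(pos=kin.pos, vel=kin.vel, fs=kin.fs, trials=trials)
                rng = np.random.default_rng(noise_ss)
                x = _sensor_block(rng, kin, coupling[(p, s)], t_block)
                recordings[(p, s, b_name)] = Recording(
                    data=x, fs=design.fs, ch_names=ch_names, trials=trials
                )
                kinematics[(p, s, b_name)] = kin

    noise_blocks: dict = {}
    n_noise = int(round(design.noise_block_duration_s * design.fs))
    for p in range(design.n_participants):
        rng = np.random.default_rng(noise_seeds[p])
        x = _sensor_block(rng, None, None, n_noise)
        noise_blocks[p] = Recording(
            data=x, fs=design.fs, ch_names=ch_names, trials=((0, n_noise),)
        )

    return SyntheticStudy(
        design=design,
        leadfield=leadfield,
        recordings=recordings,
        kinematics=kinematics,
        noise_blocks=noise_blocks,
        coupling=coupling,
        coupled_components=coupled_cols,
        coupling_mode=coupling_mode,
        snr_db=snr_db,
        seed=seed,
    )
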