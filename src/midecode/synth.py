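"""Synthetic motor-imagery study generator.

Emulates the block design of the experiment: a cohort of subjects, each
scanned over 20 runs of eight trials (two per condition: aiming, squeezing,
extension-flexion, rest), with instruction (2.5 s), delay (1 s) and an
imagery/rest phase of 6.5 s jittered by +/- half a TR.  Condition-specific
multivoxel patterns are planted in designated ROIs of a synthetic label
volume; voxel time series are baseline + convolved-boxcar signal +
low-frequency drift + white noise.  Motion parameters, forearm EMG (with no
imagery-related activity, the generator's ground-truth null) and 7-point
vividness ratings are generated alongside.

All outputs are a pure function of (config, seed, subject_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import HrfSpec, convolve_boxcars, qc_max_cosine
from .io import (CONDITIONS, IMAGERY_CONDITIONS, AtlasVolume, StudyConfig,
                 Volume3D, Volume4D, default_affine)

# rng stream tags, so every consumer of the master seed is independent
_SCHEDULE, _PATTERN, _NOISE, _MOTION, _EMG, _RATING = 11, 13, 17, 19, 23, 29


# ---------------------------------------------------------------------------
# Atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiSpec:
    label: int
    name: str
    hemisphere: str
    corner: tuple[int, int, int]
    size: tuple[int, int, int] = (3, 3, 3)


def default_rois(grid_shape) -> list[RoiSpec]:
    """Six cubic ROIs: M1 and SPL per hemisphere (decoding targets) plus a
    Heschl-gyrus analogue per hemisphere (auditory control region)."""
    gx, gy, gz = grid_shape
    if min(grid_shape) < 9:
        raise ValueError("default ROI layout needs a grid of at least 9 voxels per axis")
    s = (3, 3, 3)
    return [
        RoiSpec(1, "m1", "L", (1, 1, 1), s),
        RoiSpec(2, "m1", "R", (gx - 4, 1, 1), s),
        RoiSpec(3, "spl", "L", (1, gy - 4, 1), s),
        RoiSpec(4, "spl", "R", (gx - 4, gy - 4, 1), s),
        RoiSpec(5, "heschl", "L", (1, 1, gz - 4), s),
        RoiSpec(6, "heschl", "R", (gx - 4, 1, gz - 4), s),
    ]

#: ROI names treated as no-signal control regions in group reports.
CONTROL_ROI_NAMES = ("heschl",)


def make_atlas(grid_shape, roi_spec: list[RoiSpec] | None = None,
               voxel_size_mm: float = 3.0) -> tuple[AtlasVolume, Volume3D]:
    """Build the synthetic label volume and its gray-matter mask.

    The gray mask is the grid interior (one-voxel border excluded) and is a
    superset of every ROI.  Overlapping or out-of-grid ROIs are errors.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if roi_spec is None:
        roi_spec = default_rois(grid_shape)
    labels = np.zeros(grid_shape, dtype=np.int32)
    name_map: dict[int, tuple[str, str]] = {}
    for roi in roi_spec:
        c, s = roi.corner, roi.size
        if any(c[i] < 0 or c[i] + s[i] > grid_shape[i] for i in range(3)):
            raise ValueError(f"ROI {roi.name} ({roi.label}) does not fit in the grid")
        block = labels[c[0]:c[0] + s[0], c[1]:c[1] + s[1], c[2]:c[2] + s[2]]
        if np.any(block != 0):
            raise ValueError(f"ROI {roi.name} ({roi.label}) overlaps another ROI")
        block[...] = roi.label
        name_map[roi.label] = (roi.name, roi.hemisphere)
    affine = default_affine(voxel_size_mm)
    gray = np.zeros(grid_shape, dtype=np.int16)
    gray[1:-1, 1:-1, 1:-1] = 1
    gray[labels > 0] = 1
    return (AtlasVolume(Volume3D(labels, affine), name_map),
            Volume3D(gray, affine))


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------


def make_schedule(config: StudyConfig, subject_index: int) -> list[pd.DataFrame]:
    """Per-run event tables for one subject.

    Eight trials per run, exactly two per condition, in a pseudo-random
    order; counterbalancing across subjects comes from a Latin-square
    rotation of the base condition order plus a subject-keyed shuffle.
    Onsets/durations refer to the imagery (or rest) phase; the instruction
    and delay phases are unmodelled baseline.
    """
    base = list(CONDITIONS)
    rot = subject_index % len(base)
    rotated = base[rot:] + base[:rot]
    per_trial = (config.instruction_seconds + config.delay_seconds
                 + config.imagery_seconds + config.jitter_range_seconds
                 + config.rating_gap_seconds)
    if config.lead_in_seconds + 8 * per_trial > config.run_duration_seconds:
        raise ValueError("run too short to hold 8 trials at the configured timing")

    tables = []
    for run in range(config.n_runs):
        rng = np.random.default_rng([config.seed, _SCHEDULE, subject_index, run])
        conds = np.array(rotated * 2)
        conds = conds[rng.permutation(len(conds))]
        rows = []
        cursor = config.lead_in_seconds
        for trial, cond in enumerate(conds):
            onset = cursor + config.instruction_seconds + config.delay_seconds
            jitter = (rng.uniform(-config.jitter_range_seconds,
                                  config.jitter_range_seconds)
                      if config.jitter_range_seconds > 0 else 0.0)
            duration = config.imagery_seconds + jitter
            rows.append({"onset": onset, "duration": duration,
                         "condition": cond, "run": run, "trial": trial})
            cursor = onset + duration + config.rating_gap_seconds
        tables.append(pd.DataFrame(rows))
    return tables


# ---------------------------------------------------------------------------
# Planted signal
# ---------------------------------------------------------------------------


@dataclass
class SignalSpec:
    """Condition-specific pattern planted in one ROI.

    ``pattern_maps`` hold a unit-norm weight per ROI voxel per imagery
    condition (rest carries neither pattern nor offset); ``uniform_offsets``
    add the same value to every ROI voxel, the univariate component that the
    mean-centering control is designed to remove.
    """

    roi_label: int
    pattern_maps: dict[str, np.ndarray]
    amplitudes: dict[str, float]
    uniform_offsets: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in IMAGERY_CONDITIONS})

    def pattern_correlations(self) -> dict[tuple[str, str], float]:
        """Pairwise Pearson correlations between condition patterns."""
        out = {}
        conds = list(self.pattern_maps)
        for i, a in enumerate(conds):
            for b in conds[i + 1:]:
                out[(a, b)] = float(np.corrcoef(self.pattern_maps[a],
                                                self.pattern_maps[b])[0, 1])
        return out


def make_signal_specs(config: StudyConfig, atlas: AtlasVolume,
                      subject_index: int) -> list[SignalSpec]:
    """Draw one unit-norm pattern per condition per signal ROI, fixed across
    runs (required for cross-run decodability).

    The pattern-correlation dial rho mixes a shared component into each
    condition's orthonormal direction: p_c = sqrt(1-rho) u_c + sqrt(rho) u0,
    giving expected pairwise correlation ~ rho.
    """
    rho = config.pattern_correlation
    if not 0 <= rho <= 1:
        raise ValueError("pattern_correlation must lie in [0, 1]")
    specs = []
    for label in config.signal_roi_labels:
        mask = atlas.roi_mask(label)
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError(f"signal ROI label {label} is empty")
        rng = np.random.default_rng([config.seed, _PATTERN, subject_index, label])
        raw = rng.normal(size=(n_vox, len(IMAGERY_CONDITIONS) + 1))
        q, _ = np.linalg.qr(raw)  # orthonormal columns
        shared = q[:, 0]
        maps = {}
        for i, cond in enumerate(IMAGERY_CONDITIONS):
            v = np.sqrt(1.0 - rho) * q[:, i + 1] + np.sqrt(rho) * shared
            maps[cond] = v / np.linalg.norm(v)
        specs.append(SignalSpec(
            roi_label=label, pattern_maps=maps,
            amplitudes={c: config.signal_amplitude for c in IMAGERY_CONDITIONS},
            uniform_offsets=dict(config.uniform_offsets)))
    return specs


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 1.0
    drift: tuple = ()  # (period_seconds, amplitude[, phase]) cosines
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.white_sd < 0:
            raise ValueError("white_sd must be non-negative")


def noise_spec_from_config(config: StudyConfig) -> NoiseSpec:
    return NoiseSpec(white_sd=config.white_sd,
                     drift=tuple(config.drift_components),
                     baseline=config.baseline)


def simulate_bold(events: pd.DataFrame, atlas: AtlasVolume,
                  signal_specs: list[SignalSpec], noise_spec: NoiseSpec,
                  config: StudyConfig, rng: np.random.Generator | None = None,
                  hrf: HrfSpec = HrfSpec()) -> Volume4D:
    """Simulate one run.

    Voxel time series = baseline
    + sum over conditions of (boxcar * HRF) x (uniform_offset + amplitude x weight)
    + drift + white noise; voxels outside signal ROIs carry noise only.
    With white_sd = 0 the output is exactly the deterministic expectation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.volumes_per_run
    tr = config.tr_seconds
    shape = config.grid_shape
    t_vol = (np.arange(n) + 0.5) * tr

    data = np.full(shape + (n,), float(noise_spec.baseline))
    drift = np.zeros(n)
    for comp in noise_spec.drift:
        period, amp = comp[0], comp[1]
        phase = comp[2] if len(comp) > 2 else 0.0
        drift += amp * np.cos(2.0 * np.pi * t_vol / period + phase)
    data += drift  # same slow drift everywhere

    regressors = {}
    for cond in IMAGERY_CONDITIONS:
        sel = events[events["condition"] == cond]
        if len(sel):
            regressors[cond] = convolve_boxcars(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(), n, tr, hrf)

    for spec in signal_specs:
        mask = atlas.roi_mask(spec.roi_label)
        if mask.shape != shape:
            raise ValueError("atlas grid does not match config grid_shape")
        effect = np.zeros((int(mask.sum()), n))
        for cond, reg in regressors.items():
            weights = (spec.uniform_offsets.get(cond, 0.0)
                       + spec.amplitudes.get(cond, 0.0) * spec.pattern_maps[cond])
            effect += np.outer(weights, reg)
        data[mask] += effect

    if noise_spec.white_sd > 0:
        data += rng.normal(0.0, noise_spec.white_sd, size=data.shape)
    return Volume4D(data, atlas.labels.affine, tr)


# ---------------------------------------------------------------------------
# Motion, EMG, ratings
# ---------------------------------------------------------------------------


def simulate_motion(config: StudyConfig, condition_columns: np.ndarray,
                    rng: np.random.Generator, max_tries: int = 100,
                    ) -> np.ndarray:
    """Six mean-reverting random-walk motion parameters (AR(1)), generated
    independent of the task and re-sampled until the maximum |cosine| with
    any condition regressor is below the inclusion criterion (0.3)."""
    n = config.volumes_per_run
    if config.motion_step_sd == 0:
        return np.zeros((n, 6))
    phi = config.motion_ar
    for _ in range(max_tries):
        steps = rng.normal(0.0, config.motion_step_sd, size=(n, 6))
        walk = np.empty_like(steps)
        walk[0] = steps[0]
        for t in range(1, n):
            walk[t] = phi * walk[t - 1] + steps[t]
        if qc_max_cosine(walk, condition_columns) < config.motion_max_cosine:
            return walk
    raise RuntimeError(
        f"could not draw motion with max cosine < {config.motion_max_cosine} "
        f"in {max_tries} tries")


def simulate_emg(schedule: list[pd.DataFrame], config: StudyConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Rectifiable forearm EMG: stationary Gaussian noise with the same
    distribution during imagery and rest (no imagery-related activity)."""
    frames = []
    n_samples = int(round(config.run_duration_seconds * config.emg_fs_hz))
    time = np.arange(n_samples) / config.emg_fs_hz
    for events in schedule:
        run = int(events["run"].iloc[0]) if len(events) else 0
        frames.append(pd.DataFrame({
            "run": run, "time": time,
            "emg": rng.normal(0.0, config.emg_sd, size=n_samples)}))
    return pd.concat(frames, ignore_index=True)


def simulate_ratings(schedule: list[pd.DataFrame], config: StudyConfig,
                     rng: np.random.Generator) -> pd.DataFrame:
    """7-point vividness ratings for every imagery trial, i.i.d. across
    conditions (equal means by construction, mean > 5.5 by default)."""
    probs = np.asarray(config.rating_probs, dtype=float)
    if probs.shape != (7,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
        raise ValueError("rating_probs must be 7 non-negative values summing to 1")
    rows = []
    for events in schedule:
        for ev in events.itertuples():
            if ev.condition == "rest":
                continue
            rows.append({"run": ev.run, "trial": ev.trial,
                         "condition": ev.condition,
                         "rating": int(rng.choice(np.arange(1, 8), p=probs))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole-subject / whole-study assembly
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    subject_index: int
    bold_runs: list[Volume4D]
    events: list[pd.DataFrame]
    motion: list[np.ndarray]
    emg: pd.DataFrame
    ratings: pd.DataFrame
    signal_specs: list[SignalSpec]


def simulate_subject(config: StudyConfig, subject_index: int,
                     atlas: AtlasVolume,
                     signal_specs: list[SignalSpec] | None = None,
                     ) -> SubjectData:
    """Generate all runs and auxiliary tables for one subject."""
    if signal_specs is None:
        signal_specs = make_signal_specs(config, atlas, subject_index)
    schedule = make_schedule(config, subject_index)
    noise = noise_spec_from_config(config)

    bold_runs, motion_tables = [], []
    for run, events in enumerate(schedule):
        rng_noise = np.random.default_rng([config.seed, _NOISE, subject_index, run])
        bold_runs.append(simulate_bold(events, atlas, signal_specs, noise,
                                       config, rng_noise))
        cond_cols = np.column_stack([
            convolve_boxcars(events.loc[events["condition"] == c, "onset"].to_numpy(),
                             events.loc[events["condition"] == c, "duration"].to_numpy(),
                             config.volumes_per_run, config.tr_seconds)
            for c in CONDITIONS])
        rng_motion = np.random.default_rng([config.seed, _MOTION, subject_index, run])
        motion_tables.append(simulate_motion(config, cond_cols, rng_motion))

    rng_emg = np.random.default_rng([config.seed, _EMG, subject_index])
    rng_rating = np.random.default_rng([config.seed, _RATING, subject_index])
    return SubjectData(
        subject_index=subject_index, bold_runs=bold_runs, events=schedule,
        motion=motion_tables,
        emg=simulate_emg(schedule, config, rng_emg),
        ratings=simulate_ratings(schedule, config, rng_rating),
        signal_specs=signal_specs)
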