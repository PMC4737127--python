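"""Domain containers and file I/O for the decoding pipeline.

Volumes travel as NIfTI-1, tabular data (events, motion, EMG, ratings,
reports) as tab-separated text with a header row, and the study
configuration as YAML or JSON.  Voxel indices are 0-based, event onsets
are seconds from run start, and the affine is the single source of world
coordinates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

#: The four experimental conditions, in the fixed order used everywhere
#: (tie-breaks, design-matrix columns, pattern-row ordering).
CONDITIONS = ("aiming", "squeezing", "extflex", "rest")
#: The three motor-imagery conditions (everything except the rest baseline).
IMAGERY_CONDITIONS = CONDITIONS[:3]

EVENT_COLUMNS = ["onset", "duration", "condition", "run", "trial"]


class FormatError(ValueError):
    """Raised when a file on disk does not satisfy the expected format."""


# ---------------------------------------------------------------------------
# Volume containers
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A single 3D scalar volume with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D requires 3D data, got {self.data.ndim}D")
        _check_affine(self.affine)

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class Volume4D:
    """A 4D functional series (x, y, z, t) with affine and repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D requires 4D data, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")
        _check_affine(self.affine)

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def _check_affine(affine: np.ndarray) -> None:
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine must be invertible")


@dataclass
class AtlasVolume:
    """Integer label volume (0 = background) with ROI names per label."""

    labels: Volume3D
    name_map: dict[int, tuple[str, str]]  # label -> (roi_name, hemisphere)

    def __post_init__(self) -> None:
        arr = self.labels.data
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("atlas labels must be integer-valued")
        if arr.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(arr)) - {0}
        missing = present - set(self.name_map)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")

    @property
    def roi_labels(self) -> list[int]:
        return sorted(set(np.unique(self.labels.data)) - {0})

    def roi_mask(self, label: int) -> np.ndarray:
        return self.labels.data == label


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """All knobs of the synthetic study and of the analysis.

    Timing defaults mirror the block design of the experiment: 20 runs of
    eight trials (two per condition), each trial an instruction of 2.5 s, a
    1 s delay and an imagery/rest phase of 6.5 s jittered uniformly by
    +/- 1.25 s (half a TR), at TR 2.5 s with 50 volumes per run.
    """

    # cohort / design
    n_subjects: int = 20
    n_runs: int = 20
    volumes_per_run: int = 50
    tr_seconds: float = 2.5
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    seed: int = 0

    # trial timing (seconds)
    instruction_seconds: float = 2.5
    delay_seconds: float = 1.0
    imagery_seconds: float = 6.5
    jitter_range_seconds: float = 1.25
    rating_gap_seconds: float = 4.0  # rating-phase duration is a knob, not asserted
    lead_in_seconds: float = 2.5

    # signal
    signal_roi_labels: tuple[int, ...] = (1, 3)
    signal_amplitude: float = 0.5
    uniform_offsets: dict = field(
        default_factory=lambda: {c: 0.0 for c in IMAGERY_CONDITIONS}
    )
    pattern_correlation: float = 0.0

    # noise
    baseline: float = 100.0
    white_sd: float = 1.0
    drift_components: tuple = ((300.0, 1.0),)  # (period s, amplitude) cosines
    motion_step_sd: float = 0.02
    motion_ar: float = 0.3  # AR(1) mean reversion of the motion walk
    motion_max_cosine: float = 0.3
    emg_sd: float = 1.0
    emg_fs_hz: float = 50.0
    rating_probs: tuple[float, ...] = (0.0, 0.0, 0.0, 0.05, 0.15, 0.35, 0.45)

    # analysis
    n_components: int = 5
    searchlight_radius: int = 5
    smooth_fwhm_mm: float = 5.0
    searchlight_smooth_fwhm_mm: float = 1.0
    highpass_seconds: float = 128.0
    cluster_forming_p: float = 0.001
    fwe_p: float = 0.05
    n_permutations: int = 1000
    connectivity: int = 6
    pca_within_fold: bool = False
    smooth_before_glm: bool = True
    ridge: float = 1e-6

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        for name in ("n_subjects", "n_runs", "volumes_per_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if min(self.grid_shape) < 1 or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive integers")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.jitter_range_seconds > self.tr_seconds / 2 + 1e-12:
            raise ValueError("jitter range must not exceed half a TR")
        for name in ("cluster_forming_p", "fwe_p"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if isinstance(self.uniform_offsets, dict):
            unknown = set(self.uniform_offsets) - set(IMAGERY_CONDITIONS)
            if unknown:
                raise ValueError(f"unknown conditions in uniform_offsets: {unknown}")

    @property
    def run_duration_seconds(self) -> float:
        return self.volumes_per_run * self.tr_seconds

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "signal_roi_labels", "drift_components",
                    "rating_probs"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key]
                )
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(_listify(raw)))
        else:
            path.write_text(json.dumps(_listify(raw), indent=2))


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# Volume I/O (NIfTI-1)
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> Volume4D | Volume3D:
    """Read a NIfTI-1 file as a :class:`Volume4D` (with TR from the header)
    or :class:`Volume3D`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if data.ndim not in (3, 4) or min(data.shape) < 1:
        raise FormatError(f"{path}: expected non-empty 3D or 4D volume, "
                          f"got shape {data.shape}")
    affine = np.asarray(img.affine)
    if data.ndim == 3:
        return Volume3D(data=data, affine=affine)
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise FormatError(f"{path}: non-positive TR in header")
    return Volume4D(data=data, affine=affine, tr_seconds=tr)


def write_volume(vol: Volume4D | Volume3D, path: str | Path) -> None:
    """Write a volume as NIfTI-1; refuses non-finite data."""
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("volume contains non-finite values; refusing to write")
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    if isinstance(vol, Volume4D):
        zooms = list(img.header.get_zooms())
        zooms[3] = vol.tr_seconds
        img.header.set_zooms(zooms)
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def write_volume_nan_ok(vol: Volume3D, path: str | Path) -> None:
    """Write a 3D map that legitimately carries NaN (e.g. outside a mask)."""
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------


def validate_events(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and type an event table (columns onset, duration, condition,
    run, trial); onsets must increase strictly within each run."""
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"event table missing columns: {sorted(missing)}")
    table = table[EVENT_COLUMNS].copy()
    if len(table) == 0:
        return table
    table["onset"] = table["onset"].astype(float)
    table["duration"] = table["duration"].astype(float)
    table["run"] = table["run"].astype(int)
    table["trial"] = table["trial"].astype(int)
    bad = set(table["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"unknown condition labels: {sorted(bad)}")
    if (table["duration"] <= 0).any():
        raise FormatError("event durations must be positive")
    for run, grp in table.groupby("run"):
        onsets = grp["onset"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise FormatError(f"onsets not strictly increasing in run {run}")
    return table


def read_events(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_events(table)


def write_events(table: pd.DataFrame, path: str | Path) -> None:
    validate_events(table).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic TSV table (motion, EMG, ratings, reports)."""
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Atlas I/O
# ---------------------------------------------------------------------------


def write_atlas(atlas: AtlasVolume, vol_path: str | Path,
                names_path: str | Path) -> None:
    write_volume(Volume3D(atlas.labels.data.astype(np.int16),
                          atlas.labels.affine), vol_path)
    rows = [
        {"label": lab, "roi": name, "hemisphere": hemi}
        for lab, (name, hemi) in sorted(atlas.name_map.items())
    ]
    write_table(pd.DataFrame(rows), names_path)


def read_atlas(vol_path: str | Path, names_path: str | Path) -> AtlasVolume:
    vol = read_volume(vol_path)
    if not isinstance(vol, Volume3D):
        raise FormatError("atlas volume must be 3D")
    vol = Volume3D(np.rint(vol.data).astype(int), vol.affine)
    names = read_table(names_path)
    name_map = {
        int(r.label): (str(r.roi), str(r.hemisphere))
        for r in names.itertuples()
    }
    return AtlasVolume(labels=vol, name_map=name_map)


def default_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff
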