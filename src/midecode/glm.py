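"""First-level GLM: HRF, design construction, high-pass basis, OLS t-maps.

One GLM is fitted per subject and per run.  The design holds four boxcar
regressors (one per condition, spanning the imagery or rest interval)
convolved with a canonical double-gamma haemodynamic response, six motion
covariates, a discrete-cosine high-pass basis (128 s time constant) and an
intercept.  Three contrast maps per run compare each imagery condition with
the explicitly modelled rest condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .io import CONDITIONS, IMAGERY_CONDITIONS, StudyConfig, Volume3D, Volume4D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# Canonical HRF
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF: positive peak at ~6 s, undershoot at ~16 s,
    unit dispersions, undershoot one sixth of the peak; peak scaled to 1."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_seconds: float = 32.0


def _hrf_raw(spec: HrfSpec, t: np.ndarray) -> np.ndarray:
    # gamma densities parameterised by their mode: shape = delay/disp + 1,
    # so the positive lobe peaks at peak_delay seconds
    peak = stats.gamma.pdf(t, spec.peak_delay / spec.peak_dispersion + 1.0,
                           scale=spec.peak_dispersion)
    under = stats.gamma.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion + 1.0,
        scale=spec.undershoot_dispersion)
    return peak - spec.undershoot_ratio * under


def canonical_hrf(spec: HrfSpec, t) -> np.ndarray | float:
    """Evaluate the canonical HRF at times ``t`` (seconds, >= 0), scaled so
    that its peak value is exactly 1."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("HRF is only defined for t >= 0")
    dense = np.arange(0.0, spec.duration_seconds, 1e-3)
    peak_value = _hrf_raw(spec, dense).max()
    out = _hrf_raw(spec, t_arr) / peak_value
    return float(out) if np.isscalar(t) else out


def convolve_boxcars(onsets, durations, n_volumes: int, tr: float,
                     spec: HrfSpec = HrfSpec(), oversample: int = 16,
                     ) -> np.ndarray:
    """Convolve a set of boxcars with the canonical HRF on a fine grid
    (dt = TR/oversample) and sample at volume times t = (i + 0.5) * TR.

    Approximates the continuous convolution (the discrete sum is scaled by
    dt), so superposing events is exactly additive.
    """
    dt = tr / oversample
    run_t = n_volumes * tr
    n_fine = int(np.ceil((run_t + spec.duration_seconds) / dt)) + 1
    box = np.zeros(n_fine)
    for onset, duration in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + duration) / dt))
        box[i0:i1] += 1.0
    h = canonical_hrf(spec, np.arange(0.0, spec.duration_seconds, dt))
    fine = np.convolve(box, h)[:n_fine] * dt
    sample_idx = np.round((np.arange(n_volumes) + 0.5) * tr / dt).astype(int)
    return fine[sample_idx]


# ---------------------------------------------------------------------------
# High-pass basis
# ---------------------------------------------------------------------------


def highpass_basis(n_volumes: int, tr: float,
                   cutoff_seconds: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift columns spanning periods >= the cutoff.

    Returns K = floor(2 * T / cutoff) columns (T = n * tr), the DCT-II
    functions cos(pi * k * (n + 1/2) / N) for k = 1..K; the constant term is
    left to the design intercept.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    if cutoff_seconds <= 2 * tr:
        raise ValueError("high-pass cutoff must exceed twice the TR")
    total = n_volumes * tr
    k_max = int(np.floor(2.0 * total / cutoff_seconds))
    n = np.arange(n_volumes)
    cols = [np.cos(np.pi * k * (n + 0.5) / n_volumes) for k in range(1, k_max + 1)]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_volumes, n_columns)
    names: list[str]
    tr_seconds: float

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def condition_columns(self) -> pd.DataFrame:
        cols = [c for c in CONDITIONS if c in self.names]
        return pd.DataFrame({c: self.column(c) for c in cols})

    def contrast_vector(self, condition: str, against: str = "rest") -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[self.names.index(condition)] = 1.0
        c[self.names.index(against)] = -1.0
        return c


def build_design(events: pd.DataFrame, motion: np.ndarray | None,
                 config: StudyConfig, hrf: HrfSpec = HrfSpec()) -> DesignMatrix:
    """Build the run design: convolved condition boxcars, motion covariates,
    high-pass cosines and an intercept."""
    n = config.volumes_per_run
    tr = config.tr_seconds
    run_end = n * tr
    if len(events) and (events["onset"] + events["duration"]).max() > run_end:
        raise ValueError("event extends beyond the end of the run")

    columns, names = [], []
    for cond in CONDITIONS:
        sel = events[events["condition"] == cond]
        columns.append(convolve_boxcars(sel["onset"].to_numpy(),
                                        sel["duration"].to_numpy(), n, tr, hrf))
        names.append(cond)
    if motion is None or np.size(motion) == 0:
        warnings.warn("no motion covariates supplied; design built without them")
    else:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n:
            raise ValueError("motion table row count does not match volumes")
        for j in range(motion.shape[1]):
            columns.append(motion[:, j])
            names.append(f"motion{j + 1}")
    hp = highpass_basis(n, tr, config.highpass_seconds)
    for k in range(hp.shape[1]):
        columns.append(hp[:, k])
        names.append(f"drift{k + 1}")
    columns.append(np.ones(n))
    names.append("intercept")
    return DesignMatrix(np.column_stack(columns), names, tr)


# ---------------------------------------------------------------------------
# OLS t-contrasts
# ---------------------------------------------------------------------------


@dataclass
class ContrastMap:
    """Per-run voxelwise t-statistics for one condition-vs-rest contrast."""

    t: Volume3D
    condition: str
    run_index: int
    dof: int
    degenerate: np.ndarray = field(default=None)  # mask of zero-RSS voxels

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.t.data.shape, dtype=bool)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    culprits = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        denom = np.linalg.norm(X[:, j])
        if denom == 0 or np.linalg.norm(resid) / denom < 1e-8:
            culprits.append(names[j])
    return culprits


def fit_ols_t(volume: Volume4D, design: DesignMatrix,
              contrast_vector: np.ndarray, condition: str = "",
              run_index: int = 0) -> ContrastMap:
    """Voxelwise OLS with a t-contrast.

    t = c'b / sqrt(s2 * c'(X'X)^-1 c) with s2 = RSS/dof, dof = n - rank(X).
    Voxels with zero residual variance get t = 0 and are flagged degenerate
    so downstream pattern vectors stay finite.
    """
    c = np.asarray(contrast_vector, dtype=float)
    if not np.any(c):
        raise ValueError("contrast vector is all zeros")
    X = design.matrix
    n, p = X.shape
    if c.shape != (p,):
        raise ValueError("contrast length does not match design columns")
    if volume.data.shape[3] != n:
        raise ValueError("volume length does not match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(X, design.names)}")
    dof = n - rank

    Y = volume.data.reshape(-1, n).T  # (n, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    cvar = float(c @ xtx_inv @ c)
    sigma2 = rss / dof
    denom = np.sqrt(sigma2 * cvar)
    numer = c @ beta
    scale = np.maximum(np.einsum("ij,ij->j", Y, Y), 1.0)
    degenerate = rss <= scale * 1e-20
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, 0.0, numer / np.where(denom == 0, 1.0, denom))
    shape = volume.spatial_shape
    return ContrastMap(
        t=Volume3D(t.reshape(shape), volume.affine),
        condition=condition, run_index=run_index, dof=dof,
        degenerate=degenerate.reshape(shape),
    )


def run_contrasts(volume: Volume4D, design: DesignMatrix,
                  run_index: int) -> list[ContrastMap]:
    """The three per-run contrast maps, one per imagery condition vs rest."""
    return [
        fit_ols_t(volume, design, design.contrast_vector(cond), cond, run_index)
        for cond in IMAGERY_CONDITIONS
    ]


# ---------------------------------------------------------------------------
# Smoothing and motion QC
# ---------------------------------------------------------------------------


def smooth_gaussian(volume: Volume3D | Volume4D, fwhm_mm: float):
    """Separable Gaussian smoothing with per-axis sigma = FWHM / (2 sqrt(2 ln 2))
    in millimetres (converted to voxels via the affine), reflect boundary."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return volume
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / volume.voxel_sizes_mm
    if isinstance(volume, Volume4D):
        out = ndimage.gaussian_filter(
            volume.data.astype(float), sigma=tuple(sigma_vox) + (0.0,),
            mode="reflect")
        return Volume4D(out, volume.affine, volume.tr_seconds)
    out = ndimage.gaussian_filter(volume.data.astype(float),
                                  sigma=tuple(sigma_vox), mode="reflect")
    return Volume3D(out, volume.affine)


def qc_max_cosine(motion_table: np.ndarray, design_conditions) -> float:
    """Largest |cosine similarity| between any mean-centered motion column and
    any mean-centered condition regressor; zero-variance columns count as 0."""
    motion = np.asarray(motion_table, dtype=float)
    cond = np.asarray(design_conditions, dtype=float)
    if motion.ndim == 1:
        motion = motion[:, None]
    if cond.ndim == 1:
        cond = cond[:, None]
    if motion.shape[0] != cond.shape[0]:
        raise ValueError("motion and condition regressors differ in length")

    def _centered_unit(cols: np.ndarray) -> np.ndarray:
        centered = cols - cols.mean(axis=0)
        norms = np.linalg.norm(centered, axis=0)
        zero = norms == 0
        if zero.any():
            warnings.warn("zero-variance column in cosine QC; cosine set to 0")
        norms = np.where(zero, 1.0, norms)
        out = centered / norms
        out[:, zero] = 0.0
        return out

    m = _centered_unit(motion)
    d = _centered_unit(cond)
    if m.size == 0 or d.size == 0:
        return 0.0
    return float(np.abs(m.T @ d).max())
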