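"""ROI-wise decoding of imagined action type from GLM t-patterns.

For each ROI, the t-values of the three condition-vs-rest contrast maps are
vectorized run by run (three response vectors per run), optionally
mean-centered (the control for univariate amplitude differences), projected
onto the first five principal components, and classified with a linear
discriminant under leave-one-run-out cross-validation.  Chance level is 1/3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import ContrastMap
from .io import CONDITIONS, IMAGERY_CONDITIONS, AtlasVolume, StudyConfig

#: chance level for the three-way classification
CHANCE_LEVEL = 1.0 / 3.0


# ---------------------------------------------------------------------------
# Pattern extraction
# ---------------------------------------------------------------------------


@dataclass
class PatternSet:
    """t-value patterns: one row per (run, condition), one column per voxel."""

    X: np.ndarray
    labels: np.ndarray  # condition per row
    runs: np.ndarray    # run index per row
    roi_name: str = ""

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs, dtype=int)
        if self.X.ndim != 2 or len(self.labels) != len(self.X) \
                or len(self.runs) != len(self.X):
            raise ValueError("inconsistent PatternSet fields")
        if np.isnan(self.X).any():
            raise ValueError("PatternSet contains NaN")


def _condition_rank(label: str) -> int:
    return CONDITIONS.index(label) if label in CONDITIONS else len(CONDITIONS)


def extract_patterns(contrast_maps: list[ContrastMap], atlas: AtlasVolume,
                     roi_label: int) -> PatternSet:
    """Vectorize the ROI's t-values of every per-run contrast map.

    Rows are ordered (run ascending, condition in the fixed order); columns
    follow the fixed C scan order of the grid.  Voxels flagged degenerate in
    any map are dropped consistently across rows.
    """
    mask = atlas.roi_mask(roi_label)
    if not mask.any():
        raise ValueError(f"ROI label {roi_label} is empty")
    maps = sorted(contrast_maps,
                  key=lambda m: (m.run_index, _condition_rank(m.condition)))
    for m in maps:
        if m.t.data.shape != mask.shape:
            raise ValueError("contrast map grid does not match atlas grid")
    keep = np.ones(int(mask.sum()), dtype=bool)
    for m in maps:
        keep &= ~m.degenerate[mask]
    if not keep.any():
        raise ValueError("all ROI voxels are degenerate")
    rows = np.stack([m.t.data[mask][keep] for m in maps])
    return PatternSet(X=rows,
                      labels=np.array([m.condition for m in maps]),
                      runs=np.array([m.run_index for m in maps]),
                      roi_name=atlas.name_map.get(roi_label, ("", ""))[0])


def mean_center(ps: PatternSet) -> PatternSet:
    """Subtract each pattern's own spatial mean (row-wise centering)."""
    if ps.X.shape[1] < 1:
        raise ValueError("need at least one voxel")
    X = ps.X - ps.X.mean(axis=1, keepdims=True)
    return PatternSet(X=X, labels=ps.labels.copy(), runs=ps.runs.copy(),
                      roi_name=ps.roi_name)


# ---------------------------------------------------------------------------
# PCA feature reduction
# ---------------------------------------------------------------------------


@dataclass
class PcaModel:
    mean: np.ndarray
    components: np.ndarray        # (rank, n_voxels), orthonormal rows
    explained_variance: np.ndarray
    n_components: int             # requested width of the score matrix


def fit_pca(X: np.ndarray, n_components: int = 5) -> PcaModel:
    """Principal components of the column-centered sample covariance, ordered
    by descending eigenvalue, with a deterministic sign (the largest-magnitude
    loading of each component is made positive)."""
    X = np.asarray(X, dtype=float)
    n, v = X.shape
    if v == 0:
        raise ValueError("no voxels to reduce")
    if n < n_components:
        raise ValueError(f"need at least {n_components} samples, got {n}")
    mean = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    rank = min(n - 1, v)  # centering removes one dimension
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(f"rank {rank} < {n_components} components; "
                      "scores padded with zero-variance columns")
    comps = vt[:k]
    flip = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flip[:, None]
    var = (s[:k] ** 2) / max(n - 1, 1)
    return PcaModel(mean=mean, components=comps, explained_variance=var,
                    n_components=n_components)


def pca_transform(model: PcaModel, X: np.ndarray) -> np.ndarray:
    scores = (np.asarray(X, dtype=float) - model.mean) @ model.components.T
    pad = model.n_components - model.components.shape[0]
    if pad > 0:
        scores = np.hstack([scores, np.zeros((scores.shape[0], pad))])
    return scores


def pca_reduce(ps: PatternSet, n_components: int = 5) -> np.ndarray:
    """Scores of every pattern on the first ``n_components`` components."""
    model = fit_pca(ps.X, n_components)
    return pca_transform(model, ps.X)


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------


@dataclass
class LdaModel:
    """Gaussian equal-covariance (pooled) linear discriminant."""

    classes: list[str]
    means: np.ndarray        # (n_classes, d)
    precision: np.ndarray    # inverse of ridge-stabilised pooled covariance
    log_priors: np.ndarray


def lda_fit(features: np.ndarray, labels, ridge: float = 1e-6) -> LdaModel:
    """Fit class means, pooled within-class covariance (+ ridge
    eps * tr(S)/d * I) and empirical priors.

    Classes are ordered by the fixed condition order so that prediction ties
    resolve deterministically.
    """
    F = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()), key=lambda c: (_condition_rank(c), c))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    d = F.shape[1]
    means, counts = [], []
    pooled = np.zeros((d, d))
    for c in classes:
        Fc = F[y == c]
        if len(Fc) < 2:
            raise ValueError(f"class {c!r} needs at least 2 training samples")
        mu = Fc.mean(axis=0)
        means.append(mu)
        counts.append(len(Fc))
        dev = Fc - mu
        pooled += dev.T @ dev
    n = len(F)
    pooled /= (n - len(classes))
    if ridge > 0:
        pooled = pooled + ridge * (np.trace(pooled) / d) * np.eye(d)
    try:
        precision = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pooled covariance is singular; set a positive "
                         "ridge to stabilise it") from exc
    priors = np.array(counts, dtype=float) / n
    return LdaModel(classes=classes, means=np.array(means),
                    precision=precision, log_priors=np.log(priors))


def lda_predict(model: LdaModel, features: np.ndarray) -> np.ndarray:
    """argmax_k of x' P mu_k - mu_k' P mu_k / 2 + log pi_k; ties go to the
    earlier class in the fixed condition order."""
    F = np.asarray(features, dtype=float)
    pm = model.precision @ model.means.T                     # (d, k)
    scores = F @ pm - 0.5 * np.einsum("ik,ik->k", model.means.T, pm) \
        + model.log_priors
    idx = np.argmax(scores, axis=1)
    return np.array([model.classes[i] for i in idx])


# ---------------------------------------------------------------------------
# Leave-one-run-out cross-validation
# ---------------------------------------------------------------------------


def cv_predictions(X: np.ndarray, labels: np.ndarray, runs: np.ndarray, *,
                   n_components: int = 5, pca_within_fold: bool = False,
                   ridge: float = 1e-6) -> list[tuple[int, str, str]]:
    """Fold-level (run, true, predicted) triples of the leave-one-run-out CV.

    Every run must contain every class; with ``pca_within_fold`` the
    components are fitted on the training runs only, otherwise once on all
    samples before the split.
    """
    labels = np.asarray(labels)
    runs = np.asarray(runs)
    unique_runs = np.unique(runs)
    if len(unique_runs) < 2:
        raise ValueError("leave-one-run-out needs at least 2 runs")
    all_classes = set(labels.tolist())
    for r in unique_runs:
        have = set(labels[runs == r].tolist())
        if have != all_classes:
            raise ValueError(f"run {r} is missing conditions: "
                             f"{sorted(all_classes - have)}")

    if not pca_within_fold:
        model = fit_pca(X, n_components)
        F_all = pca_transform(model, X)

    records = []
    for r in unique_runs:
        test = runs == r
        if pca_within_fold:
            model = fit_pca(X[~test], n_components)
            F_train = pca_transform(model, X[~test])
            F_test = pca_transform(model, X[test])
        else:
            F_train, F_test = F_all[~test], F_all[test]
        lda = lda_fit(F_train, labels[~test], ridge)
        pred = lda_predict(lda, F_test)
        for true, p in zip(labels[test], pred):
            records.append((int(r), true, p))
    return records


@dataclass
class DecodingResult:
    accuracy: float
    assignments: pd.DataFrame  # columns: run, true, predicted
    n_correct: int
    n_total: int
    variant: str = "raw"
    roi_name: str = ""


def loro_cv(ps: PatternSet, config: StudyConfig | None = None, *,
            n_components: int | None = None, pca_within_fold: bool | None = None,
            ridge: float | None = None, variant: str = "raw") -> DecodingResult:
    """Leave-one-run-out decoding of one pattern set.

    By default the PCA is fitted once on the full pattern set before the
    split (replicating the stated analysis order); with
    ``pca_within_fold=True`` the components are re-fitted on the training
    runs of each fold, the leakage-free variant.
    """
    if config is not None:
        n_components = config.n_components if n_components is None else n_components
        pca_within_fold = (config.pca_within_fold if pca_within_fold is None
                           else pca_within_fold)
        ridge = config.ridge if ridge is None else ridge
    n_components = 5 if n_components is None else n_components
    pca_within_fold = False if pca_within_fold is None else pca_within_fold
    ridge = 1e-6 if ridge is None else ridge

    records = cv_predictions(ps.X, ps.labels, ps.runs,
                             n_components=n_components,
                             pca_within_fold=pca_within_fold, ridge=ridge)
    assignments = pd.DataFrame(records, columns=["run", "true", "predicted"])
    n_correct = int((assignments["true"] == assignments["predicted"]).sum())
    n_total = len(assignments)
    return DecodingResult(accuracy=n_correct / n_total, assignments=assignments,
                          n_correct=n_correct, n_total=n_total,
                          variant=variant, roi_name=ps.roi_name)


def decode_all_rois(contrast_maps: list[ContrastMap], atlas: AtlasVolume,
                    config: StudyConfig) -> pd.DataFrame:
    """Raw and mean-centered decoding for every atlas ROI (controls included).

    Returns one row per ROI x variant with the cross-validated accuracy.
    """
    rows = []
    for label in atlas.roi_labels:
        ps = extract_patterns(contrast_maps, atlas, label)
        name, hemi = atlas.name_map[label]
        for variant, data in (("raw", ps), ("mean_centered", mean_center(ps))):
            res = loro_cv(data, config, variant=variant)
            rows.append({"label": label, "roi": name, "hemisphere": hemi,
                         "variant": variant, "accuracy": res.accuracy,
                         "n_correct": res.n_correct, "n_total": res.n_total})
    return pd.DataFrame(rows)
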