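"""Group inference and behavioural/physiological control analyses.

Decoding accuracies are tested against chance (1/3) across subjects with
one-sample t-tests, Holm-Bonferroni corrected over the ROI family (control
ROIs are reported separately, outside the family).  Vividness ratings are
compared across imagery conditions with a one-way repeated-measures ANOVA,
and rectified-EMG areas under the curve (5-s epochs) are compared against
the rest baseline with paired t-tests, Holm corrected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io import IMAGERY_CONDITIONS, AtlasVolume
from .mvpa import CHANCE_LEVEL
from .synth import CONTROL_ROI_NAMES


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------


def one_sample_t(values, null_value: float,
                 alternative: str = "two-sided") -> tuple[float, int, float]:
    """t = (mean - null) / (sd / sqrt(n)) with dof = n - 1.

    ``alternative`` is "two-sided" or "greater" (one-sided above null).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        if np.allclose(x, null_value):
            # no deviation from the null at all: t = 0, p = 1 by convention
            return 0.0, n - 1, 1.0
        raise ValueError("zero variance; t-test undefined")
    t = (x.mean() - null_value) / (sd / np.sqrt(n))
    dof = n - 1
    if alternative == "two-sided":
        p = 2.0 * sp_stats.t.sf(abs(t), dof)
    elif alternative == "greater":
        p = sp_stats.t.sf(t, dof)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(t), dof, float(p)


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment.

    Sorted ascending, p_(i) is multiplied by (m - i + 1), a running maximum
    enforces monotonicity, values are capped at 1 and returned in the
    original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# Group decoding tests
# ---------------------------------------------------------------------------


def group_decoding_tests(decoding_table: pd.DataFrame, config=None, *,
                         chance: float = CHANCE_LEVEL,
                         control_rois: tuple[str, ...] = CONTROL_ROI_NAMES,
                         alternative: str = "two-sided") -> pd.DataFrame:
    """t-tests of per-subject accuracies against chance, per ROI x variant.

    The Holm family within each variant comprises all non-control ROIs
    (hemispheres counted separately); control ROIs are tested but reported
    with their raw p (separate analysis, outside the family).
    """
    required = {"subject", "roi", "hemisphere", "variant", "accuracy"}
    missing = required - set(decoding_table.columns)
    if missing:
        raise ValueError(f"decoding table missing columns: {sorted(missing)}")
    subjects = sorted(decoding_table["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for group tests")
    cells = decoding_table.groupby(["roi", "hemisphere", "variant"])
    n_expected = len(subjects)
    rows = []
    for (roi, hemi, variant), grp in cells:
        if len(grp) != n_expected or set(grp["subject"]) != set(subjects):
            raise ValueError(f"missing subject cells for ROI {roi}/{hemi} "
                             f"({variant})")
        acc = grp.sort_values("subject")["accuracy"].to_numpy()
        t, dof, p = one_sample_t(acc, chance, alternative)
        rows.append({"roi": roi, "hemisphere": hemi, "variant": variant,
                     "mean": acc.mean(),
                     "se": acc.std(ddof=1) / np.sqrt(len(acc)),
                     "n": len(acc), "t_statistic": t, "dof": dof, "p_raw": p,
                     "is_control": roi in control_rois})
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for variant in out["variant"].unique():
        fam = (out["variant"] == variant) & ~out["is_control"]
        if fam.any():
            out.loc[fam, "p_holm"] = holm_bonferroni(out.loc[fam, "p_raw"])
        ctl = (out["variant"] == variant) & out["is_control"]
        out.loc[ctl, "p_holm"] = out.loc[ctl, "p_raw"]
    return out.sort_values(["variant", "is_control", "roi", "hemisphere"],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------


def emg_auc(trace, fs_hz: float, window_seconds: tuple[float, float]) -> float:
    """Trapezoidal area under the rectified trace over the epoch window.

    The trace is assumed uniformly sampled from time 0; the window must lie
    within the trace.
    """
    x = np.asarray(trace, dtype=float)
    t0, t1 = window_seconds
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    i0 = int(round(t0 * fs_hz))
    i1 = int(round(t1 * fs_hz))
    if i0 < 0 or i1 >= len(x):
        raise ValueError("epoch window exceeds the trace")
    seg = np.abs(x[i0:i1 + 1])
    return float(np.trapezoid(seg, dx=1.0 / fs_hz))


def emg_condition_aucs(emg: pd.DataFrame, events: list[pd.DataFrame],
                       fs_hz: float, epoch_seconds: float = 5.0) -> pd.DataFrame:
    """Per-trial AUCs over the first ``epoch_seconds`` of each imagery/rest
    phase, for one subject."""
    rows = []
    for ev_run in events:
        if not len(ev_run):
            continue
        run = int(ev_run["run"].iloc[0])
        trace = emg.loc[emg["run"] == run, "emg"].to_numpy()
        for ev in ev_run.itertuples():
            auc = emg_auc(trace, fs_hz, (ev.onset, ev.onset + epoch_seconds))
            rows.append({"run": run, "trial": ev.trial,
                         "condition": ev.condition, "auc": auc})
    return pd.DataFrame(rows)


def emg_tests(subject_epochs: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of per-subject mean AUC: each imagery condition vs
    rest, Holm corrected over the three comparisons.

    Expects columns subject, condition, auc (trial level or already
    averaged)."""
    means = (subject_epochs.groupby(["subject", "condition"])["auc"]
             .mean().unstack())
    if "rest" not in means.columns:
        raise ValueError("no rest condition in EMG epochs")
    rows = []
    for cond in IMAGERY_CONDITIONS:
        a = means[cond].to_numpy()
        b = means["rest"].to_numpy()
        diff = a - b
        if np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = sp_stats.ttest_rel(a, b)
        rows.append({"condition": cond, "t_statistic": float(t),
                     "dof": len(a) - 1, "p_raw": float(p),
                     "mean_imagery": a.mean(), "mean_rest": b.mean()})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(out["p_raw"])
    return out


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------


def ratings_anova(condition_means) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA on per-subject condition means.

    ``condition_means``: (n_subjects, n_conditions) array or wide DataFrame.
    F = MS_condition / MS_(condition x subject); returns (F, dof1, dof2, p).
    """
    M = np.asarray(condition_means, dtype=float)
    if M.ndim != 2:
        raise ValueError("need a subjects x conditions table")
    if np.isnan(M).any():
        raise ValueError("missing cell in the condition-means table")
    n, k = M.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = M.mean()
    ss_cond = n * ((M.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((M.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((M - grand) ** 2).sum()
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    dof1, dof2 = k - 1, (k - 1) * (n - 1)
    if ss_cond == 0:
        return 0.0, dof1, dof2, 1.0
    if ss_err == 0:
        return float("inf"), dof1, dof2, 0.0
    f = (ss_cond / dof1) / (ss_err / dof2)
    return float(f), dof1, dof2, float(sp_stats.f.sf(f, dof1, dof2))


def ratings_condition_means(ratings: pd.DataFrame,
                            subject_col: str = "subject") -> pd.DataFrame:
    """Wide per-subject mean-rating table (subjects x imagery conditions)."""
    wide = (ratings.groupby([subject_col, "condition"])["rating"]
            .mean().unstack())
    return wide[[c for c in IMAGERY_CONDITIONS if c in wide.columns]]


# ---------------------------------------------------------------------------
# Mean-amplitude analysis
# ---------------------------------------------------------------------------


def amplitude_analysis(subject_contrast_maps: list[list], atlas: AtlasVolume,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean t per ROI and condition (averaged over runs and voxels) per
    subject, plus a repeated-measures ANOVA per ROI, Holm corrected across
    ROIs.

    ``subject_contrast_maps``: one list of per-run ContrastMaps per subject.
    """
    mean_rows = []
    for subj, maps in enumerate(subject_contrast_maps):
        for label in atlas.roi_labels:
            mask = atlas.roi_mask(label)
            if not mask.any():
                raise ValueError(f"ROI label {label} is empty")
            name, hemi = atlas.name_map[label]
            for cond in IMAGERY_CONDITIONS:
                vals = [m.t.data[mask].mean() for m in maps
                        if m.condition == cond]
                if not vals:
                    raise ValueError(f"no contrast maps for condition {cond}")
                mean_rows.append({"subject": subj, "roi": name,
                                  "hemisphere": hemi, "label": label,
                                  "condition": cond,
                                  "mean_t": float(np.mean(vals))})
    means = pd.DataFrame(mean_rows)

    test_rows = []
    for (label, roi, hemi), grp in means.groupby(["label", "roi", "hemisphere"]):
        wide = grp.pivot(index="subject", columns="condition", values="mean_t")
        wide = wide[[c for c in IMAGERY_CONDITIONS if c in wide.columns]]
        f, d1, d2, p = ratings_anova(wide.to_numpy())
        test_rows.append({"label": label, "roi": roi, "hemisphere": hemi,
                          "F": f, "dof1": d1, "dof2": d2, "p_raw": p})
    tests = pd.DataFrame(test_rows)
    tests["p_holm"] = holm_bonferroni(tests["p_raw"])
    return means, tests
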