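"""End-to-end pipeline: simulate -> GLM -> ROI decoding -> searchlight -> group.

Each stage reads its inputs from and writes its outputs to ``out_dir``, so
stages can be run individually (the CLI subcommands) or chained with
:func:`run_pipeline`.  Outputs are a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import io, mvpa, searchlight as sl, stats, synth

logger = logging.getLogger("midecode")


def _sub_dir(out_dir: Path, subject: int) -> Path:
    d = out_dir / f"sub-{subject:02d}"
    d.mkdir(parents=True, exist_ok=True)
    return d


def _load_config(config: io.StudyConfig | str | Path,
                 seed: int | None = None) -> io.StudyConfig:
    if not isinstance(config, io.StudyConfig):
        config = io.StudyConfig.from_file(config)
    if seed is not None:
        import dataclasses
        config = dataclasses.replace(config, seed=seed)
    return config


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_simulate(config: io.StudyConfig, out_dir: Path) -> None:
    """Generate and write the full synthetic study."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    atlas, gray = synth.make_atlas(config.grid_shape,
                                   voxel_size_mm=config.voxel_size_mm)
    io.write_atlas(atlas, out_dir / "atlas.nii.gz", out_dir / "atlas_labels.tsv")
    io.write_volume(gray, out_dir / "graymask.nii.gz")
    config.to_file(out_dir / "config_used.json")

    manifest = {"n_subjects": config.n_subjects, "n_runs": config.n_runs,
                "subjects": []}
    for subject in range(config.n_subjects):
        data = synth.simulate_subject(config, subject, atlas)
        sdir = _sub_dir(out_dir, subject)
        runs = []
        for run in range(config.n_runs):
            bold = data.bold_runs[run]
            bold32 = io.Volume4D(bold.data.astype(np.float32), bold.affine,
                                 bold.tr_seconds)
            io.write_volume(bold32, sdir / f"run-{run:02d}_bold.nii.gz")
            io.write_events(data.events[run], sdir / f"run-{run:02d}_events.tsv")
            io.write_table(pd.DataFrame(
                data.motion[run], columns=[f"motion{j+1}" for j in range(6)]),
                sdir / f"run-{run:02d}_motion.tsv")
            runs.append(run)
        io.write_table(data.emg, sdir / "emg.tsv")
        io.write_table(data.ratings, sdir / "ratings.tsv")
        corr = {f"{spec.roi_label}": {f"{a}|{b}": c for (a, b), c in
                                      spec.pattern_correlations().items()}
                for spec in data.signal_specs}
        manifest["subjects"].append({"subject": subject, "runs": runs,
                                     "pattern_correlations": corr})
        logger.info("simulated subject %d", subject)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _subject_contrast_maps(config: io.StudyConfig, out_dir: Path,
                           subject: int) -> list[glm_mod.ContrastMap]:
    """Load this subject's written t-maps back into ContrastMap objects."""
    sdir = _sub_dir(out_dir, subject)
    degen_path = sdir / "degenerate_mask.nii.gz"
    degen = None
    if degen_path.exists():
        degen = io.read_volume(degen_path).data > 0
    maps = []
    for run in range(config.n_runs):
        for cond in io.IMAGERY_CONDITIONS:
            path = sdir / f"sub-{subject:02d}_run-{run:02d}_{cond}-vs-rest_tmap.nii.gz"
            vol = io.read_volume(path)
            m = glm_mod.ContrastMap(t=vol, condition=cond, run_index=run, dof=0)
            if degen is not None:
                m.degenerate = degen
            maps.append(m)
    return maps


def stage_glm(config: io.StudyConfig, out_dir: Path) -> None:
    """Fit the per-run GLMs and write one t-map per (run, condition)."""
    out_dir = Path(out_dir)
    for subject in range(config.n_subjects):
        sdir = _sub_dir(out_dir, subject)
        degenerate = np.zeros(config.grid_shape, dtype=bool)
        qc = []
        for run in range(config.n_runs):
            bold = io.read_volume(sdir / f"run-{run:02d}_bold.nii.gz")
            events = io.read_events(sdir / f"run-{run:02d}_events.tsv")
            motion = io.read_table(sdir / f"run-{run:02d}_motion.tsv").to_numpy()
            if config.smooth_before_glm and config.smooth_fwhm_mm > 0:
                bold = glm_mod.smooth_gaussian(bold, config.smooth_fwhm_mm)
            design = glm_mod.build_design(events, motion, config)
            qc.append({"run": run, "max_cosine": glm_mod.qc_max_cosine(
                motion, design.condition_columns().to_numpy())})
            for cmap in glm_mod.run_contrasts(bold, design, run):
                io.write_volume(
                    io.Volume3D(cmap.t.data.astype(np.float32), cmap.t.affine),
                    sdir / f"sub-{subject:02d}_run-{run:02d}_"
                           f"{cmap.condition}-vs-rest_tmap.nii.gz")
                degenerate |= cmap.degenerate
        if degenerate.any():
            io.write_volume(io.Volume3D(degenerate.astype(np.int16),
                                        io.default_affine(config.voxel_size_mm)),
                            sdir / "degenerate_mask.nii.gz")
        io.write_table(pd.DataFrame(qc), sdir / "motion_qc.tsv")
        logger.info("GLM done for subject %d", subject)


def stage_decode_roi(config: io.StudyConfig, out_dir: Path) -> None:
    """ROI decoding (raw + mean-centered) for every subject."""
    out_dir = Path(out_dir)
    atlas = io.read_atlas(out_dir / "atlas.nii.gz", out_dir / "atlas_labels.tsv")
    for subject in range(config.n_subjects):
        maps = _subject_contrast_maps(config, out_dir, subject)
        table = mvpa.decode_all_rois(maps, atlas, config)
        table.insert(0, "subject", subject)
        io.write_table(table, _sub_dir(out_dir, subject) /
                       f"sub-{subject:02d}_decoding.tsv")
        logger.info("ROI decoding done for subject %d", subject)


def stage_decode_searchlight(config: io.StudyConfig, out_dir: Path) -> None:
    """Per-subject searchlight accuracy maps."""
    out_dir = Path(out_dir)
    gray = io.read_volume(out_dir / "graymask.nii.gz")
    for subject in range(config.n_subjects):
        maps = _subject_contrast_maps(config, out_dir, subject)
        acc = sl.run_searchlight(maps, gray, config)
        io.write_volume_nan_ok(acc, _sub_dir(out_dir, subject) /
                               f"sub-{subject:02d}_accuracy_map.nii.gz")
        logger.info("searchlight done for subject %d", subject)


def stage_group(config: io.StudyConfig, out_dir: Path) -> dict:
    """Group decoding tests, behavioural controls, cluster inference, report."""
    out_dir = Path(out_dir)
    gdir = out_dir / "group"
    gdir.mkdir(exist_ok=True)
    atlas = io.read_atlas(out_dir / "atlas.nii.gz", out_dir / "atlas_labels.tsv")

    decode_tables, ratings_tables, emg_epoch_tables, all_maps = [], [], [], []
    for subject in range(config.n_subjects):
        sdir = _sub_dir(out_dir, subject)
        decode_tables.append(io.read_table(
            sdir / f"sub-{subject:02d}_decoding.tsv"))
        ratings = io.read_table(sdir / "ratings.tsv")
        ratings.insert(0, "subject", subject)
        ratings_tables.append(ratings)
        emg = io.read_table(sdir / "emg.tsv")
        events = [io.read_events(sdir / f"run-{r:02d}_events.tsv")
                  for r in range(config.n_runs)]
        epochs = stats.emg_condition_aucs(emg, events, config.emg_fs_hz)
        epochs.insert(0, "subject", subject)
        emg_epoch_tables.append(epochs)
        all_maps.append(_subject_contrast_maps(config, out_dir, subject))

    decoding = pd.concat(decode_tables, ignore_index=True)
    group_table = stats.group_decoding_tests(decoding, config)
    io.write_table(group_table, gdir / "decoding_group.tsv")

    rating_means = stats.ratings_condition_means(
        pd.concat(ratings_tables, ignore_index=True))
    f, d1, d2, p = stats.ratings_anova(rating_means.to_numpy())
    ratings_out = pd.DataFrame([{"F": f, "dof1": d1, "dof2": d2, "p": p}])
    io.write_table(ratings_out, gdir / "ratings_anova.tsv")

    emg_table = stats.emg_tests(pd.concat(emg_epoch_tables, ignore_index=True))
    io.write_table(emg_table, gdir / "emg_tests.tsv")

    amp_means, amp_tests = stats.amplitude_analysis(all_maps, atlas)
    io.write_table(amp_means, gdir / "amplitude_means.tsv")
    io.write_table(amp_tests, gdir / "amplitude_tests.tsv")

    report = {
        "decoding": group_table.to_dict(orient="records"),
        "ratings_anova": ratings_out.to_dict(orient="records")[0],
        "emg_tests": emg_table.to_dict(orient="records"),
    }
    acc_paths = [
        _sub_dir(out_dir, s) / f"sub-{s:02d}_accuracy_map.nii.gz"
        for s in range(config.n_subjects)]
    if all(p.exists() for p in acc_paths):
        acc_maps = [io.read_volume(p) for p in acc_paths]
        t_map, clusters = sl.group_cluster_inference(acc_maps, config)
        io.write_volume(t_map, gdir / "group_t_map.nii.gz")
        io.write_table(clusters, gdir / "clusters.tsv")
        report["clusters"] = clusters.to_dict(orient="records")
    (gdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    logger.info("group stage done")
    return report


# ---------------------------------------------------------------------------
# In-memory cohort analysis (no files) — used by simulation studies
# ---------------------------------------------------------------------------


def subject_contrast_maps_in_memory(config: io.StudyConfig, subject: int,
                                    atlas) -> list[glm_mod.ContrastMap]:
    """Simulate one subject and fit the per-run GLMs without touching disk."""
    data = synth.simulate_subject(config, subject, atlas)
    maps = []
    for run in range(config.n_runs):
        bold = data.bold_runs[run]
        if config.smooth_before_glm and config.smooth_fwhm_mm > 0:
            bold = glm_mod.smooth_gaussian(bold, config.smooth_fwhm_mm)
        design = glm_mod.build_design(data.events[run], data.motion[run], config)
        maps.extend(glm_mod.run_contrasts(bold, design, run))
    return maps


def decode_cohort(config: io.StudyConfig) -> pd.DataFrame:
    """Simulate a cohort and return the stacked per-subject ROI decoding table."""
    atlas, _ = synth.make_atlas(config.grid_shape,
                                voxel_size_mm=config.voxel_size_mm)
    tables = []
    for subject in range(config.n_subjects):
        maps = subject_contrast_maps_in_memory(config, subject, atlas)
        table = mvpa.decode_all_rois(maps, atlas, config)
        table.insert(0, "subject", subject)
        tables.append(table)
    return pd.concat(tables, ignore_index=True)


def searchlight_cohort(config: io.StudyConfig) -> list[io.Volume3D]:
    """Simulate a cohort and return per-subject searchlight accuracy maps."""
    atlas, gray = synth.make_atlas(config.grid_shape,
                                   voxel_size_mm=config.voxel_size_mm)
    maps_out = []
    for subject in range(config.n_subjects):
        maps = subject_contrast_maps_in_memory(config, subject, atlas)
        maps_out.append(sl.run_searchlight(maps, gray, config))
    return maps_out


_STAGES = (
    ("simulate", stage_simulate),
    ("glm", stage_glm),
    ("decode-roi", stage_decode_roi),
    ("decode-searchlight", stage_decode_searchlight),
    ("group", stage_group),
)


def run_pipeline(config: io.StudyConfig | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run every stage in order; abort with the stage name on failure."""
    config = _load_config(config, seed)
    if config.n_runs < 2:
        raise ValueError("n_runs must be >= 2 (leave-one-run-out undefined)")
    out_dir = Path(out_dir)
    report = {}
    for name, stage in _STAGES:
        logger.info("running stage %s", name)
        try:
            result = stage(config, out_dir)
        except Exception as exc:
            logger.error("stage %s failed: %s", name, exc)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        if result:
            report = result
    return report
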