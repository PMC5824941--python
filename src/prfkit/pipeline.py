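"""End-to-end synthetic study: simulate -> fit -> filter -> coverage ->
group statistics -> gaze, with a plain-text report.

The pipeline emulates the developmental contrast the analysis was built
for: two groups ("children", "adults") whose synthetic pRF populations
differ in how foveal their coverage is, and whose synthetic gaze differs by
a configurable fixation offset. Every stage consumes a named seed from the
config; running the same config twice produces identical manifests and
bit-identical deterministic artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coverage import (GridSpec, coverage_com, coverage_extent, group_coverage,
                       jackknife_se, roi_coverage)
from .css import FitGridSpec, PredictionBank, filter_fits, fit_population
from .gaze import (adult_fixation_zone, bias_vector, fixation_density,
                   group_density, null_quadrant_test, outside_afz_ratio)
from .hrf import HRFSpec
from .io import PipelineConfig, RunManifest, append_jsonl, write_table
from .stats import (coverage_to_points, ks2d_two_sample, size_ecc_fit,
                    welch_ttest)
from .stimulus import generate_bar_apertures
from .synth import (ROISpec, SyntheticGazeConfig, sample_ground_truth_prfs,
                    simulate_bold, simulate_gaze)

# adults more foveal than children, as in high-level face/word regions
GROUP_ROI_SPECS = {
    "children": ROISpec(slope=0.25, intercept=0.8, ecc_range=(1.0, 6.0),
                        n_mean=0.5, scatter=0.1, label="pFus-faces"),
    "adults": ROISpec(slope=0.25, intercept=0.8, ecc_range=(0.3, 4.0),
                      n_mean=0.5, scatter=0.1, label="pFus-faces"),
}

GAZE_BOXES = [(384, 256, 640, 512), (320, 288, 704, 480)]


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full synthetic study; returns artifact paths + summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log.jsonl"
    manifest = RunManifest.for_config(config, __version__)
    manifest.write(out / "manifest.json")
    report: list[str] = ["prfkit synthetic study report", "=" * 32, ""]
    summary: dict = {"out_dir": str(out)}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as e:  # noqa: BLE001 - re-tag with stage name
                raise StageError(f"[{name}] {e}") from e
        return deco

    # ---- stimulus -------------------------------------------------------
    apertures = stage("stimulus")(lambda: generate_bar_apertures(
        field_radius=config.field_radius, bar_width=config.bar_width,
        bar_length=config.bar_length, steps_per_sweep=config.steps_per_sweep,
        grid_px=config.grid_px, tr=config.tr))
    apertures.save(out / "apertures")
    report.append(f"Stimulus: {apertures.n_sweeps} sweeps, "
                  f"{apertures.n_frames} frames, TR {config.tr} s, "
                  f"field radius {config.field_radius} dva")

    hrf = HRFSpec()
    grid = FitGridSpec.for_field(config.field_radius, n_xy=config.fit_grid_nxy,
                                 n_sigma=config.fit_grid_nsigma,
                                 refine=config.refine,
                                 sigma_floor=config.sigma_floor)
    cov_grid = GridSpec(field_radius=config.field_radius,
                        n=config.coverage_grid_n)
    # runs are fit as one concatenated session; the candidate bank is
    # shared across participants
    session = apertures.tiled(config.n_runs)
    bank = PredictionBank(session, hrf, grid)

    # ---- simulate + fit per participant ---------------------------------
    per_participant: dict[str, list] = {g: [] for g in GROUP_ROI_SPECS}
    zero_survivor_flags = []
    for gi, (group, roi_spec) in enumerate(GROUP_ROI_SPECS.items()):
        for p in range(config.n_participants_per_group):
            pid = f"{group}_{p:02d}"
            hemi = "L" if p % 2 == 0 else "R"
            spec_p = ROISpec(**{**roi_spec.__dict__, "hemisphere": hemi})
            k = gi * config.n_participants_per_group + p
            truth = sample_ground_truth_prfs(
                spec_p, config.n_voxels_per_roi, seed=config.seed_truth + k)
            clean = stage("simulate-bold")(lambda t=truth: simulate_bold(
                t, session, hrf, noise_sd=0.0, seed=0))
            signal_scale = float(np.mean(np.std(clean.values, axis=1)))
            tcs = stage("simulate-bold")(lambda t=truth: simulate_bold(
                t, session, hrf, noise_sd=config.noise_sd * signal_scale,
                seed=config.seed_bold + k))
            fits = stage("fit")(lambda t=tcs: fit_population(
                t, session, hrf, grid, bank=bank))
            kept, flog = filter_fits(fits, ve_min=config.ve_min,
                                     ecc_max=config.ecc_max,
                                     sigma_floor=config.sigma_floor)
            flog.update(participant=pid, stage="filter")
            append_jsonl(log_path, flog)
            write_table(fits, out / f"fits_{pid}.tsv",
                        meta={"participant": pid, "hemisphere": hemi})
            if len(kept) == 0:
                zero_survivor_flags.append(pid)
                continue
            cov = stage("coverage")(lambda f=kept, i=k: roi_coverage(
                f, cov_grid, combine_rule=config.combine_rule,
                n_boot=config.n_boot, seed=config.seed_coverage + i,
                provenance={"participant": pid, "hemisphere": hemi}))
            line = size_ecc_fit(kept) if kept["ecc"].nunique() > 1 else None
            per_participant[group].append(
                dict(pid=pid, truth=truth, kept=kept, cov=cov, line=line))

    if zero_survivor_flags:
        report.append(f"WARNING: zero post-filter survivors for "
                      f"{', '.join(zero_survivor_flags)}")
    summary["zero_survivor_participants"] = zero_survivor_flags

    # ---- group statistics ------------------------------------------------
    rows = []
    group_maps = {}
    for group, parts in per_participant.items():
        if not parts:
            continue
        maps = [d["cov"] for d in parts]
        group_maps[group] = group_coverage(maps, flip_rh=True)
        coms = [coverage_com(d["cov"])["distance"] for d in parts]
        exts = [coverage_extent(d["cov"], binarize_at=config.binarize_at)
                for d in parts]
        slopes = [d["line"].slope for d in parts if d["line"]]
        icepts = [d["line"].intercept for d in parts if d["line"]]
        row = dict(group=group, n=len(parts),
                   com_mean=float(np.mean(coms)),
                   com_jackknife_se=(jackknife_se(coms)
                                     if len(coms) >= 2 else np.nan),
                   extent_mean=float(np.mean(exts)),
                   slope_mean=float(np.mean(slopes)) if slopes else np.nan,
                   intercept_mean=float(np.mean(icepts)) if icepts else np.nan)
        rows.append(row)
        for d, c, e in zip(parts, coms, exts):
            append_jsonl(log_path, dict(stage="coverage", participant=d["pid"],
                                        com_distance=c, extent_sq_dva=e))
    group_table = pd.DataFrame(rows)
    write_table(group_table, out / "group_coverage_stats.tsv")
    report.append("")
    report.append("Coverage statistics by group (CoM distance in dva, "
                  "extent in square dva; size-ecc line averaged across "
                  "participants):")
    report.append(group_table.to_string(index=False))

    if len(group_maps) == 2:
        pts = {g: coverage_to_points([d["cov"] for d in per_participant[g]],
                                     samples_per_map=200,
                                     seed=config.seed_stats + i)
               for i, g in enumerate(group_maps)}
        ks = ks2d_two_sample(pts["children"], pts["adults"],
                             p_method="permutation",
                             n_permutations=config.n_permutations,
                             seed=config.seed_stats)
        coms_c = [coverage_com(d["cov"])["distance"]
                  for d in per_participant["children"]]
        coms_a = [coverage_com(d["cov"])["distance"]
                  for d in per_participant["adults"]]
        welch = (welch_ttest(coms_c, coms_a)
                 if min(len(coms_c), len(coms_a)) >= 2 else None)
        summary["ks2d"] = dict(D=ks.D, p=ks.p)
        report.append("")
        report.append(f"2D KS (children vs adults coverage): D = {ks.D:.3f}, "
                      f"permutation p = {ks.p:.4f} "
                      f"(n = {ks.n_a} vs {ks.n_b} sampled points)")
        if welch:
            report.append(f"Welch t-test on CoM distance: t = {welch['t']:.2f},"
                          f" p = {welch['p']:.4f}")

    # ---- gaze ------------------------------------------------------------
    gaze_summary = stage("gaze")(lambda: _gaze_stage(config, out, report))
    summary["gaze"] = gaze_summary

    report_path = out / "report.txt"
    report_path.write_text("\n".join(report) + "\n")
    summary["report"] = str(report_path)
    summary["manifest"] = str(out / "manifest.json")
    summary["group_table"] = str(out / "group_coverage_stats.tsv")
    return summary


def _gaze_stage(config: PipelineConfig, out: Path, report: list) -> dict:
    adult_cfg = SyntheticGazeConfig(
        n_participants=config.n_participants_per_group,
        n_fixations=config.n_gaze_fixations, center_offset=(0.0, 0.0),
        spread=config.gaze_spread_px, seed=config.seed_gaze, group="adults")
    child_cfg = SyntheticGazeConfig(
        n_participants=config.n_participants_per_group,
        n_fixations=config.n_gaze_fixations,
        center_offset=config.child_gaze_offset,
        spread=config.gaze_spread_px, seed=config.seed_gaze + 1,
        group="children")
    adults = simulate_gaze(adult_cfg, GAZE_BOXES)
    children = simulate_gaze(child_cfg, GAZE_BOXES)

    stimuli = sorted({f.stimulus for f in adults})
    ratios, vectors = [], []
    for stim in stimuli:
        a_maps = [fixation_density(f, sigma_px=config.smoothing_sigma_px)
                  for f in adults if f.stimulus == stim]
        c_fix = [f for f in children if f.stimulus == stim]
        c_maps = [fixation_density(f, sigma_px=config.smoothing_sigma_px)
                  for f in c_fix]
        afz = adult_fixation_zone(a_maps, overlap=config.afz_overlap)
        ratios.extend(outside_afz_ratio(f, afz) for f in c_fix)
        vectors.append(bias_vector(group_density(c_maps),
                                   group_density(a_maps), afz, stimulus=stim))
    nqt = null_quadrant_test(vectors, "lower-left") if len(vectors) >= 2 \
        else None
    mean_ratio = float(np.mean(ratios))
    report.append("")
    report.append("Gaze analysis (synthetic children vs adults):")
    report.append(f"  mean outside-AFZ ratio in children: {mean_ratio:.3f} "
                  f"(chance 0.30)")
    for v in vectors:
        report.append(f"  bias vector {v.stimulus}: angle {v.angle:.1f} deg, "
                      f"magnitude {v.magnitude:.1f} px")
    if nqt:
        report.append(f"  null-quadrant test (lower-left): "
                      f"t = {nqt['t']:.2f}, p = {nqt['p']:.4f}")
    rows = pd.DataFrame([dict(stimulus=v.stimulus, dx=v.dx, dy=v.dy,
                              angle=v.angle, magnitude=v.magnitude)
                         for v in vectors])
    write_table(rows, out / "bias_vectors.tsv")
    return dict(mean_outside_afz_ratio=mean_ratio,
                bias_angles=[v.angle for v in vectors],
                null_quadrant_p=(nqt["p"] if nqt else None))
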