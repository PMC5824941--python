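"""Synthetic inputs with known ground truth.

Three generators emulate the study's raw data, none of which is deposited:

* ground-truth pRF populations whose size grows linearly with eccentricity,
* BOLD timecourses produced by the CSS forward model plus Gaussian noise,
* fixation records on a 768 x 1024 screen with controllable group biases.

Everything is driven by explicit seeds through numpy Generators; identical
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .css import predict_timecourse
from .hrf import HRFSpec
from .stimulus import ApertureMovie

SCREEN_SHAPE = (768, 1024)  # rows (y, down-positive), cols (x)

TRUTH_COLUMNS = ["voxel_id", "x", "y", "sigma", "n", "g", "roi_label",
                 "hemisphere", "ecc", "size"]


@dataclass
class ROISpec:
    """Statistical structure of a synthetic ROI's pRF population.

    ``slope``/``intercept`` describe the linear size-vs-eccentricity
    relationship (in dva of effective size per dva of eccentricity);
    ``scatter`` is the Gaussian sd of sizes about that line; ``n_mean`` is
    the compressive exponent shared by the population.
    """

    slope: float = 0.1
    intercept: float = 0.5
    ecc_range: tuple = (0.5, 6.0)
    n_mean: float = 0.5
    scatter: float = 0.05
    gain: float = 1.0
    label: str = "V1"
    hemisphere: str = "L"


def sample_ground_truth_prfs(roi_spec: ROISpec, n_voxels: int,
                             seed: int) -> pd.DataFrame:
    """Draw a ground-truth pRF table with a linear size-ecc relationship.

    Eccentricities are uniform over ``ecc_range``; polar angles are uniform
    over the hemifield contralateral to the hemisphere label (left
    hemisphere represents the right visual field, x > 0). Effective size is
    slope*ecc + intercept + N(0, scatter), clipped positive; sigma is
    derived as size * sqrt(n).
    """
    if n_voxels < 0:
        raise ValueError("n_voxels must be nonnegative")
    if roi_spec.scatter < 0:
        raise ValueError("scatter must be nonnegative")
    lo, hi = roi_spec.ecc_range
    if roi_spec.slope * lo + roi_spec.intercept <= 0 or \
       roi_spec.slope * hi + roi_spec.intercept <= 0:
        raise ValueError("size line must be positive over ecc_range")
    rng = np.random.default_rng(seed)
    ecc = rng.uniform(lo, hi, n_voxels)
    size = roi_spec.slope * ecc + roi_spec.intercept
    if roi_spec.scatter > 0:
        size = size + rng.normal(0.0, roi_spec.scatter, n_voxels)
    size = np.clip(size, 1e-3, None)
    # contralateral hemifield: L hemisphere -> x > 0
    base = -np.pi / 2 if roi_spec.hemisphere == "L" else np.pi / 2
    theta = base + rng.uniform(0.0, np.pi, n_voxels)
    n = np.full(n_voxels, roi_spec.n_mean)
    sigma = size * np.sqrt(n)
    df = pd.DataFrame({
        "voxel_id": np.arange(n_voxels),
        "x": ecc * np.cos(theta),
        "y": ecc * np.sin(theta),
        "sigma": sigma,
        "n": n,
        "g": np.full(n_voxels, roi_spec.gain),
        "roi_label": roi_spec.label,
        "hemisphere": roi_spec.hemisphere,
        "ecc": ecc,
        "size": size,
    }, columns=TRUTH_COLUMNS)
    return df


@dataclass
class VoxelTimecourses:
    """voxels x time BOLD matrix with per-voxel labels."""

    values: np.ndarray
    tr: float
    voxel_ids: list
    roi_labels: list
    hemispheres: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be voxels x time")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("timecourses must be finite")


def simulate_bold(truth: pd.DataFrame, apertures: ApertureMovie,
                  hrf: HRFSpec, noise_sd: float, seed: int) -> VoxelTimecourses:
    """CSS forward model per ground-truth voxel + iid Gaussian noise.

    Noise is independent across voxels and timepoints (no temporal
    autocorrelation). With ``noise_sd`` 0 the output equals
    :func:`prfkit.css.predict_timecourse` for every voxel exactly.
    """
    if len(truth) == 0:
        raise ValueError("ground truth table is empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if apertures.tr <= 0:
        raise ValueError("invalid aperture sampling rate")
    rng = np.random.default_rng(seed)
    clean = np.stack([
        predict_timecourse(row, apertures, hrf)
        for _, row in truth.iterrows()
    ])
    noisy = clean if noise_sd == 0 else clean + rng.normal(
        0.0, noise_sd, clean.shape)
    return VoxelTimecourses(values=noisy, tr=apertures.tr,
                            voxel_ids=list(truth["voxel_id"]),
                            roi_labels=list(truth["roi_label"]),
                            hemispheres=list(truth["hemisphere"]))


def simulate_bold_runs(truth: pd.DataFrame, apertures: ApertureMovie,
                       hrf: HRFSpec, noise_sd: float, seed: int,
                       n_runs: int = 4, average: bool = True) -> VoxelTimecourses:
    """Simulate the full mapping session: ``n_runs`` repeats of the sweep
    protocol, averaged voxel-wise (or concatenated with ``average=False``).

    Run averaging is how repeated mapping runs are combined before fitting;
    it reduces effective noise by sqrt(n_runs) and is what makes the
    compressive exponent — and hence sigma — identifiable at realistic
    single-run noise levels.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = [simulate_bold(truth, apertures, hrf, noise_sd,
                          seed=(seed + 7919 * r) % (2**31 - 1))
            for r in range(n_runs)]
    values = (np.mean([r.values for r in runs], axis=0) if average
              else np.concatenate([r.values for r in runs], axis=1))
    first = runs[0]
    return VoxelTimecourses(values=values, tr=first.tr,
                            voxel_ids=first.voxel_ids,
                            roi_labels=first.roi_labels,
                            hemispheres=first.hemispheres)


# --------------------------------------------------------------------------
# Gaze
# --------------------------------------------------------------------------

@dataclass
class FixationSet:
    """Pre-segmented fixations of one participant on one stimulus.

    ``events`` columns: t_ms, x_px, y_px, duration_ms. Screen pixel
    convention: x rightward, y downward (row index).
    """

    participant: str
    stimulus: str
    events: pd.DataFrame
    screen: tuple = SCREEN_SHAPE

    def __post_init__(self):
        req = {"t_ms", "x_px", "y_px", "duration_ms"}
        if not req.issubset(self.events.columns):
            raise ValueError(f"events must have columns {sorted(req)}")
        if (self.events["duration_ms"] <= 0).any():
            raise ValueError("durations must be positive")


@dataclass
class SyntheticGazeConfig:
    """Group-level fixation generator settings (pixels, milliseconds).

    ``center_offset`` shifts each group's fixation cloud off the stimulus
    center in screen convention (positive dy is downward); it is the knob
    emulating the child/adult viewing-bias contrast.
    """

    n_participants: int = 10
    n_fixations: int = 20
    center_offset: tuple = (0.0, 0.0)
    spread: float = 40.0
    fixation_duration_range: tuple = (150.0, 400.0)
    seed: int = 0
    group: str = "adults"

    def __post_init__(self):
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        lo, hi = self.fixation_duration_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid fixation duration range")


def simulate_gaze(cfg: SyntheticGazeConfig, stimulus_boxes) -> list[FixationSet]:
    """Fixations per participant around each stimulus-box center + offset.

    ``stimulus_boxes`` is a list of (x0, y0, x1, y1) pixel rects within the
    screen. Fixations are isotropic Gaussian around box center +
    ``cfg.center_offset``, clipped to the screen; durations uniform in
    range. Returns one FixationSet per (participant, stimulus).
    """
    n_rows, n_cols = SCREEN_SHAPE
    boxes = list(stimulus_boxes)
    for (x0, y0, x1, y1) in boxes:
        if not (0 <= x0 < x1 <= n_cols and 0 <= y0 < y1 <= n_rows):
            raise ValueError("stimulus box outside the screen grid")
        cx = (x0 + x1) / 2 + cfg.center_offset[0]
        cy = (y0 + y1) / 2 + cfg.center_offset[1]
        if not (0 <= cx < n_cols and 0 <= cy < n_rows):
            raise ValueError("center offset pushes fixation mass off-grid")
    rng = np.random.default_rng(cfg.seed)
    out = []
    for p in range(cfg.n_participants):
        pid = f"{cfg.group}_{p:02d}"
        for s, (x0, y0, x1, y1) in enumerate(boxes):
            cx = (x0 + x1) / 2 + cfg.center_offset[0]
            cy = (y0 + y1) / 2 + cfg.center_offset[1]
            xs = np.clip(rng.normal(cx, cfg.spread, cfg.n_fixations),
                         0, n_cols - 1)
            ys = np.clip(rng.normal(cy, cfg.spread, cfg.n_fixations),
                         0, n_rows - 1)
            durs = rng.uniform(*cfg.fixation_duration_range, cfg.n_fixations)
            t = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
            events = pd.DataFrame({"t_ms": t, "x_px": xs, "y_px": ys,
                                   "duration_ms": durs})
            out.append(FixationSet(participant=pid, stimulus=f"stim{s:02d}",
                                   events=events))
    return out


def gaze_sample_stream(fix: FixationSet, rate_hz: float = 500.0,
                       blinks=()) -> pd.DataFrame:
    """Render fixations as a raw sample stream with optional blink markers.

    Returns the tab-table layout used on disk: participant, stimulus_id,
    t_ms, x_px, y_px, event in {sample, blink_start, blink_end}. Blink
    intervals are (start_ms, end_ms) pairs; samples inside them are kept
    (scrubbing is the analysis's job, not the recorder's).
    """
    dt = 1000.0 / rate_hz
    rows = []
    for _, ev in fix.events.iterrows():
        n = max(1, int(round(ev["duration_ms"] / dt)))
        for k in range(n):
            rows.append((fix.participant, fix.stimulus, ev["t_ms"] + k * dt,
                         ev["x_px"], ev["y_px"], "sample"))
    for (b0, b1) in blinks:
        rows.append((fix.participant, fix.stimulus, float(b0), np.nan,
                     np.nan, "blink_start"))
        rows.append((fix.participant, fix.stimulus, float(b1), np.nan,
                     np.nan, "blink_end"))
    df = pd.DataFrame(rows, columns=["participant", "stimulus_id", "t_ms",
                                     "x_px", "y_px", "event"])
    return df.sort_values("t_ms", kind="stable").reset_index(drop=True)
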