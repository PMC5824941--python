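"""Eye-tracking analysis: blink scrubbing, fixation-density maps, the adult
fixation zone (AFZ), outside-AFZ ratios, bias vectors, and the null-quadrant
test.

Screen data arrive in pixel convention (x rightward, y downward on a
768 x 1024 grid). All directional quantities — bias-vector angles and
quadrant logic — are expressed in the visual-field convention (y upward);
the y axis is inverted exactly once, in :func:`bias_vector`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from .synth import SCREEN_SHAPE, FixationSet

NULL_QUADRANTS = {"lower-left": (180.0, 270.0), "lower-right": (270.0, 360.0)}


def scrub_blinks(samples: pd.DataFrame, pad_ms: float = 100.0) -> pd.DataFrame:
    """Remove gaze samples around blinks.

    ``samples`` has columns t_ms, event (sample / blink_start / blink_end),
    time-ordered. Samples with t in [blink_start - pad_ms, blink_end +
    pad_ms), half-open, are dropped; overlapping scrub windows merge, so
    scrubbing is idempotent and never double-removes.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("samples must be time-ordered")
    ev = samples["event"].to_numpy()
    starts = t[ev == "blink_start"]
    ends = t[ev == "blink_end"]
    if len(starts) != len(ends):
        raise ValueError("unmatched blink markers")
    if len(starts) == 0:
        return samples.loc[ev == "sample"].reset_index(drop=True)
    windows = sorted(zip(starts - pad_ms, ends + pad_ms))
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    keep = ev == "sample"
    for lo, hi in merged:
        keep &= ~((t >= lo) & (t < hi))
    return samples.loc[keep].reset_index(drop=True)


@dataclass
class DensityMap:
    """Max-normalized fixation density on the screen grid (row = y down)."""

    values: np.ndarray
    sigma_px: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("density map must be 2D")


def fixation_density(fix: FixationSet, sigma_px: float = 18.75,
                     duration_weighted: bool = True) -> DensityMap:
    """Duration-weighted fixation histogram, Gaussian-smoothed, peak 1.

    The smoothing sigma (default 18.75 px) makes individual maps
    comparable for averaging across participants; max-normalization
    removes between-participant differences in total viewing time.
    """
    if len(fix.events) == 0:
        raise ValueError("empty fixation set")
    n_rows, n_cols = fix.screen
    grid = np.zeros((n_rows, n_cols))
    rows = np.clip(np.round(fix.events["y_px"]).astype(int), 0, n_rows - 1)
    cols = np.clip(np.round(fix.events["x_px"]).astype(int), 0, n_cols - 1)
    w = fix.events["duration_ms"].to_numpy() if duration_weighted else \
        np.ones(len(fix.events))
    np.add.at(grid, (rows, cols), w)
    smoothed = gaussian_filter(grid, sigma=sigma_px)
    m = smoothed.max()
    return DensityMap(values=smoothed / m if m > 0 else smoothed,
                      sigma_px=sigma_px,
                      provenance={"participant": fix.participant,
                                  "stimulus": fix.stimulus})


def group_density(maps) -> DensityMap:
    """Pointwise mean of per-participant normalized density maps."""
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise ValueError("maps must share the screen grid")
    return DensityMap(values=np.mean([m.values for m in maps], axis=0),
                      sigma_px=maps[0].sigma_px,
                      provenance={"n_maps": len(maps)})


def adult_fixation_zone(adult_maps, overlap: float = 0.70,
                        presence_eps: float = 0.01,
                        method: str = "fraction") -> np.ndarray:
    """Binary AFZ mask: where at least ``overlap`` of adults fixated.

    method "fraction" (default): per pixel, the fraction of adults whose
    normalized density exceeds ``presence_eps``; AFZ = fraction >= overlap.
    method "mean_density": threshold the group-average density at
    ``overlap`` of its peak instead.
    """
    adult_maps = list(adult_maps)
    if not adult_maps:
        raise ValueError("need at least one adult map")
    if method == "fraction":
        presence = np.mean([m.values > presence_eps for m in adult_maps],
                           axis=0)
        if overlap <= 0:  # degenerate threshold: union of supports
            return presence > 0
        return presence >= overlap
    if method == "mean_density":
        mean = group_density(adult_maps).values
        peak = mean.max()
        return mean >= overlap * peak if peak > 0 else np.zeros_like(
            mean, dtype=bool)
    raise ValueError(f"unknown AFZ method: {method}")


def outside_afz_ratio(child_fix: FixationSet, afz: np.ndarray) -> float:
    """(fixation time outside AFZ) / (total fixation time) for one child.

    0 means every fixation fell inside the adult zone; the study's chance
    level for this ratio is 0.30 (the AFZ being a 70% contour).
    """
    n_rows, n_cols = afz.shape
    rows = np.clip(np.round(child_fix.events["y_px"]).astype(int),
                   0, n_rows - 1)
    cols = np.clip(np.round(child_fix.events["x_px"]).astype(int),
                   0, n_cols - 1)
    durs = child_fix.events["duration_ms"].to_numpy(dtype=float)
    total = durs.sum()
    if total <= 0:
        raise ValueError("total fixation time is zero")
    outside = durs[~afz[rows, cols]].sum()
    return float(outside / total)


def _density_com(values: np.ndarray, mask: np.ndarray | None = None):
    w = values if mask is None else np.where(mask, values, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("density has zero mass")
    rows, cols = np.indices(w.shape)
    return float((w * cols).sum() / total), float((w * rows).sum() / total)


@dataclass
class BiasVector:
    """Displacement of child fixation density relative to the adult center.

    dx, dy are in pixels in the visual-field convention (y up); angle is
    atan2(dy, dx) in degrees wrapped to [0, 360).
    """

    stimulus: str
    dx: float
    dy: float

    @property
    def angle(self) -> float:
        return float(np.rad2deg(np.arctan2(self.dy, self.dx)) % 360.0)

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))


def bias_vector(child_map: DensityMap, adult_map: DensityMap,
                afz: np.ndarray, stimulus: str = "") -> BiasVector:
    """Vector from the adult fixation center to the child density CoM.

    The adult center is the CoM of the adult density restricted to the
    AFZ; the child center is the CoM of the full child density. The screen
    y axis (downward) is inverted here so the vector reads in visual-field
    convention.
    """
    ax, ay = _density_com(adult_map.values, afz)
    cx, cy = _density_com(child_map.values)
    return BiasVector(stimulus=stimulus or
                      child_map.provenance.get("stimulus", ""),
                      dx=cx - ax, dy=-(cy - ay))


def angular_distance_from_quadrant(angle: float, quadrant: tuple) -> float:
    """Minimal wrapped angular separation from ``angle`` to the quadrant.

    0 if the angle lies inside [lo, hi]; otherwise the circular distance to
    the nearest quadrant boundary, in degrees (<= 135 for a quadrant).
    """
    lo, hi = quadrant
    a = angle % 360.0
    if lo <= a <= hi:
        return 0.0
    def circ(u, v):
        d = abs(u - v) % 360.0
        return min(d, 360.0 - d)
    return min(circ(a, lo), circ(a, hi))


def null_quadrant_test(vectors, null_quadrant: str = "lower-left") -> dict:
    """Test whether bias vectors avoid the null quadrant.

    The null quadrant is the visual-field quadrant holding the region's
    pRF coverage (lower-left for faces, lower-right for words); a vector
    inside it would displace coverage away from the stimulus. Reports each
    vector's angular distance from the quadrant and a one-sample t-test of
    those distances against zero. Under uniformly random angles, 25% of
    vectors would fall inside any quadrant.
    """
    vectors = list(vectors)
    if len(vectors) < 2:
        raise ValueError("need at least 2 bias vectors")
    quad = NULL_QUADRANTS[null_quadrant]
    dist = np.array([angular_distance_from_quadrant(v.angle, quad)
                     for v in vectors])
    t, p = sps.ttest_1samp(dist, 0.0)
    return {"distances": dist, "t": float(t), "p": float(p),
            "null_quadrant": null_quadrant, "chance_occupancy": 0.25}
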