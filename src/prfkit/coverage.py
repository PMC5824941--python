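"""Visual field coverage (VFC) maps and their summary statistics.

Each surviving pRF contributes a unit-peak Gaussian over the visual field;
an ROI's coverage combines these pointwise (mean or max), bootstrapped over
voxels to downweight outliers, and is normalized so its peak is 1 within
each participant. Group maps average per-participant maps after mirroring
right-hemisphere maps over the vertical meridian. Scalar summaries are the
covered area (square dva) and the center-of-mass distance from fixation,
with leave-one-out jackknife standard errors across participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Square cell-centered grid over [-field_radius, +field_radius]^2."""

    field_radius: float = 7.0
    n: int = 128

    def centers(self) -> np.ndarray:
        r = self.field_radius
        step = 2.0 * r / self.n
        return -r + step * (np.arange(self.n) + 0.5)

    def mesh(self):
        c = self.centers()
        return np.meshgrid(c, c)  # X varies along axis 1, Y along axis 0

    def in_field(self) -> np.ndarray:
        X, Y = self.mesh()
        return X**2 + Y**2 <= self.field_radius**2

    @property
    def cell_area(self) -> float:
        return (2.0 * self.field_radius / self.n) ** 2


@dataclass
class CoverageMap:
    """Normalized coverage density over a visual-field grid.

    values[iy, ix] with y increasing upward along axis 0 and x increasing
    rightward along axis 1 (visual-field convention).
    """

    values: np.ndarray
    grid: GridSpec
    combine_rule: str = "mean"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n, self.grid.n):
            raise ValueError("values shape must match grid")

    def mirrored(self) -> "CoverageMap":
        """Reflection over the vertical meridian (x -> -x)."""
        return CoverageMap(values=self.values[:, ::-1].copy(), grid=self.grid,
                           combine_rule=self.combine_rule,
                           provenance=dict(self.provenance))


def voxel_density(fit, grid: GridSpec) -> np.ndarray:
    """Unit-peak Gaussian footprint of one pRF on the coverage grid.

    ``fit`` is a mapping with keys x, y, size (effective size, already
    folding in the compressive exponent).
    """
    x, y, size = float(fit["x"]), float(fit["y"]), float(fit["size"])
    if size <= 0 or not np.isfinite(size):
        raise ValueError("pRF size must be positive")
    X, Y = grid.mesh()
    return np.exp(-((X - x) ** 2 + (Y - y) ** 2) / (2.0 * size ** 2))


def _combine(stack: np.ndarray, rule: str) -> np.ndarray:
    if rule == "mean":
        return stack.mean(axis=0)
    if rule == "max":
        return stack.max(axis=0)
    raise ValueError(f"unknown combine rule: {rule}")


def _peak_normalize(values: np.ndarray) -> np.ndarray:
    m = values.max()
    return values / m if m > 0 else values


def roi_coverage(fits, grid: GridSpec, combine_rule: str = "mean",
                 n_boot: int = 50, seed: int | None = None,
                 provenance: dict | None = None) -> CoverageMap:
    """Bootstrap-averaged coverage of one participant's ROI.

    Each of ``n_boot`` draws resamples the ROI's voxels with replacement,
    combines their unit-peak densities pointwise by ``combine_rule``, and
    renormalizes to peak 1; the final map is the mean over draws,
    renormalized again.
    """
    if len(fits) == 0:
        raise ValueError("cannot compute coverage of an empty ROI")
    dens = np.stack([voxel_density(row, grid)
                     for _, row in fits.iterrows()])
    rng = np.random.default_rng(seed)
    nv = dens.shape[0]
    acc = np.zeros((grid.n, grid.n))
    for _ in range(n_boot):
        idx = rng.integers(0, nv, nv)
        acc += _peak_normalize(_combine(dens[idx], combine_rule))
    return CoverageMap(values=_peak_normalize(acc / n_boot), grid=grid,
                       combine_rule=combine_rule,
                       provenance=provenance or {})


def group_coverage(maps, flip_rh: bool = True) -> CoverageMap:
    """Pointwise mean of per-participant maps.

    With ``flip_rh``, maps whose provenance marks hemisphere 'R' are first
    mirrored over the vertical meridian so contralateral coverage aligns.
    The output is deliberately not renormalized: inputs are already peak-1
    per participant and the group mean keeps interpretable units.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("no maps to average")
    g0 = maps[0].grid
    if any(m.grid != g0 for m in maps):
        raise ValueError("maps must share a grid")
    arr = []
    for m in maps:
        if flip_rh and m.provenance.get("hemisphere") == "R":
            m = m.mirrored()
        arr.append(m.values)
    return CoverageMap(values=np.mean(arr, axis=0), grid=g0,
                       combine_rule=maps[0].combine_rule,
                       provenance={"n_maps": len(maps),
                                   "flip_rh": bool(flip_rh)})


def coverage_extent(cmap: CoverageMap, binarize_at: float = 0.01,
                    field_radius: float | None = None) -> float:
    """Covered area in square dva.

    Binarizes the map (values >= binarize_at count as covered), takes the
    proportion of in-field grid points covered, and scales by the total
    stimulated area pi r^2.
    """
    r = field_radius if field_radius is not None else cmap.grid.field_radius
    inside = cmap.grid.in_field()
    covered = (cmap.values >= binarize_at) & inside
    prop = covered.sum() / inside.sum()
    return float(prop * np.pi * r**2)


def coverage_com(cmap: CoverageMap) -> dict:
    """Density-weighted centroid of the coverage over in-field points.

    ``distance`` is the centroid's distance from fixation in dva, the
    map-level index of foveal bias.
    """
    inside = cmap.grid.in_field()
    w = np.where(inside, cmap.values, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("coverage map has zero in-field mass")
    X, Y = cmap.grid.mesh()
    cx = float((w * X).sum() / total)
    cy = float((w * Y).sum() / total)
    return {"x": cx, "y": cy, "distance": float(np.hypot(cx, cy))}


def jackknife_se(values, statistic_fn=np.mean) -> float:
    """Leave-one-out jackknife standard error of a group statistic.

    SE = sqrt((n-1)/n * sum((theta_i - theta_bar)^2)) over the n
    leave-one-out estimates theta_i. For the mean this equals the classical
    sd/sqrt(n).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("jackknife requires at least 2 participants")
    loo = np.array([statistic_fn(np.delete(values, i, axis=0))
                    for i in range(n)], dtype=float)
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
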