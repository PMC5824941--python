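"""Cross-group statistics on fitted pRF populations and coverage maps.

Includes the variance-explained-weighted size-vs-eccentricity regression,
a two-dimensional two-sample Kolmogorov-Smirnov test (quadrant statistic
with permutation or large-sample p-values), density-weighted point sampling
from coverage maps, and Pearson age correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .coverage import CoverageMap


@dataclass
class LineFit:
    slope: float
    intercept: float
    n_points: int


def size_ecc_fit(fits: pd.DataFrame) -> LineFit:
    """Weighted least squares of pRF size on eccentricity.

    Each voxel's contribution is weighted by the variance explained of its
    pRF fit; voxels at or below the 5% threshold should already have been
    filtered out. With equal weights this reduces to ordinary least squares.
    """
    ecc = np.asarray(fits["ecc"], dtype=float)
    size = np.asarray(fits["size"], dtype=float)
    w = np.asarray(fits["ve"], dtype=float)
    if len(ecc) < 2 or np.unique(ecc).size < 2:
        raise ValueError("need >= 2 voxels with distinct eccentricities")
    if np.any(w <= 0):
        raise ValueError("weights (variance explained) must be positive")
    model = sm.WLS(size, sm.add_constant(ecc), weights=w).fit()
    return LineFit(slope=float(model.params[1]),
                   intercept=float(model.params[0]), n_points=len(ecc))


@dataclass
class KS2DResult:
    D: float
    p: float
    n_a: int
    n_b: int
    method: str


def _quadrant_membership(xy: np.ndarray) -> np.ndarray:
    """(4 * n_origins, n_points) boolean: point j in quadrant q of origin i."""
    dx = xy[:, 0][None, :] - xy[:, 0][:, None]  # (origin, point)
    dy = xy[:, 1][None, :] - xy[:, 1][:, None]
    quads = [(dx > 0) & (dy > 0), (dx < 0) & (dy > 0),
             (dx < 0) & (dy < 0), (dx > 0) & (dy < 0)]
    return np.concatenate(quads, axis=0)


def ks2d_two_sample(points_a, points_b, p_method: str = "permutation",
                    n_permutations: int = 1000,
                    seed: int | None = None) -> KS2DResult:
    """Two-dimensional two-sample KS test on planar point sets.

    The statistic D is the largest discrepancy between the two samples'
    quadrant fractions, maximized over origins placed at every data point
    of both samples and over the four axis-aligned quadrants. The p-value
    comes from label permutation (default) or the large-sample
    approximation ("approx").
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if a.shape[1] != 2 or b.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    na, nb = len(a), len(b)
    xy = np.vstack([a, b])
    labels = np.zeros(na + nb, dtype=bool)
    labels[:na] = True
    Q = _quadrant_membership(xy).astype(np.float64)  # (4N, N)

    def stat(lab: np.ndarray) -> float:
        ca = Q @ lab  # count of sample-a points per (origin, quadrant)
        tot = Q.sum(axis=1)
        return float(np.max(np.abs(ca / na - (tot - ca) / nb)))

    D = stat(labels.astype(float))
    if p_method == "permutation":
        rng = np.random.default_rng(seed)
        perms = np.zeros((na + nb, n_permutations))
        for j in range(n_permutations):
            perms[rng.permutation(na + nb)[:na], j] = 1.0
        ca = Q @ perms  # (4N, n_permutations)
        tot = Q.sum(axis=1)[:, None]
        d_null = np.max(np.abs(ca / na - (tot - ca) / nb), axis=0)
        p = float((np.sum(d_null >= D - 1e-12) + 1) / (n_permutations + 1))
    elif p_method == "approx":
        # large-sample two-sample form with the Fasano-Franceschini
        # correlation correction, evaluated through the Kolmogorov tail
        n_eff = na * nb / (na + nb)
        r2 = np.mean([abs(sps.pearsonr(s[:, 0], s[:, 1])[0]) ** 2
                      if len(s) > 2 else 0.0 for s in (a, b)])
        z = D * np.sqrt(n_eff) / (1 + np.sqrt(1 - r2)
                                  * (0.25 - 0.75 / np.sqrt(n_eff)))
        p = float(np.clip(sps.kstwobign.sf(z), 0.0, 1.0))
    else:
        raise ValueError(f"unknown p_method: {p_method}")
    return KS2DResult(D=D, p=p, n_a=na, n_b=nb, method=p_method)


def coverage_to_points(maps, samples_per_map: int = 500,
                       seed: int | None = None) -> np.ndarray:
    """Density-weighted grid-point samples pooled across participant maps.

    Turns coverage maps into the planar point sets the 2D KS test
    consumes: per map, grid cells inside the field are sampled with
    probability proportional to coverage density.
    """
    maps = [maps] if isinstance(maps, CoverageMap) else list(maps)
    if not maps:
        raise ValueError("no maps given")
    rng = np.random.default_rng(seed)
    pts = []
    for m in maps:
        inside = m.grid.in_field()
        w = np.where(inside, m.values, 0.0).ravel()
        total = w.sum()
        if total <= 0:
            raise ValueError("coverage map has zero mass")
        idx = rng.choice(w.size, size=samples_per_map, p=w / total)
        X, Y = m.grid.mesh()
        pts.append(np.column_stack([X.ravel()[idx], Y.ravel()[idx]]))
    return np.vstack(pts)


def pearson_age_correlation(values, ages) -> dict:
    """Pearson correlation between a per-participant scalar and age."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(v) != len(a) or len(v) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(v) == 0 or np.std(a) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = sps.pearsonr(v, a)
    return {"r": float(r), "p": float(p), "n": len(v)}


def welch_ttest(group_a, group_b) -> dict:
    """Welch's two-sample t-test on derived scalars (CoM, extent, ...)."""
    t, p = sps.ttest_ind(np.asarray(group_a, float),
                         np.asarray(group_b, float), equal_var=False)
    return {"t": float(t), "p": float(p),
            "n_a": len(group_a), "n_b": len(group_b)}
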