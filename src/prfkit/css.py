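"""Compressive spatial summation (CSS) pRF model: forward prediction,
voxel-wise fitting, variance explained, and exclusion filters.

Each voxel's population receptive field is an isotropic 2D Gaussian with
center (x, y) and width sigma. The per-frame neural drive is the
stimulus-Gaussian overlap raised to a compressive exponent n <= 1; the
predicted BOLD timecourse is that drive convolved with an HRF and scaled
by a gain g. Fitting is a two-stage search: exhaustive grid over
(x, y, sigma, n) with the gain solved in closed form per candidate,
followed by bounded derivative-free refinement from the best grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import toeplitz
from scipy.optimize import minimize

from .hrf import HRFSpec
from .stimulus import ApertureMovie

FIT_COLUMNS = ["voxel_id", "roi", "hemi", "x", "y", "sigma", "n", "g", "ve",
               "ecc", "size", "flag"]


def effective_size(sigma, n):
    """pRF size under compressive summation: sigma / sqrt(n).

    With n = 1 (linear summation) this reduces to plain sigma; compression
    (n < 1) widens the region of space that effectively drives the voxel.
    """
    sigma = np.asarray(sigma, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(sigma <= 0) or np.any(n <= 0):
        raise ValueError("sigma and n must be positive")
    out = sigma / np.sqrt(n)
    return float(out) if out.ndim == 0 else out


def variance_explained(observed, predicted) -> float:
    """Coefficient of determination R^2 about the observed mean.

    Negative raw values (prediction worse than the mean) are clamped to 0.
    """
    y = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("observed and predicted must be equal-length 1D, n >= 2")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed timecourse is constant; R^2 undefined")
    ss_res = np.sum((y - p) ** 2)
    return float(max(0.0, 1.0 - ss_res / ss_tot))


def _convolution_matrix(kernel: np.ndarray, n_time: int) -> np.ndarray:
    """Lower-triangular Toeplitz matrix for causal convolution truncated to T."""
    col = np.zeros(n_time)
    k = min(len(kernel), n_time)
    col[:k] = kernel[:k]
    return toeplitz(col, np.zeros(n_time))


def _gauss_overlap(apertures: ApertureMovie, x: float, y: float,
                   sigma: float) -> np.ndarray:
    """Per-frame overlap of the stimulus with a unit-peak Gaussian."""
    X, Y = apertures.pixel_grid()
    g = np.exp(-((X - x) ** 2 + (Y - y) ** 2) / (2.0 * sigma ** 2))
    s = apertures.frames.reshape(apertures.n_frames, -1)
    return s @ g.ravel()


def predict_timecourse(prf, apertures: ApertureMovie, hrf: HRFSpec) -> np.ndarray:
    """CSS forward model for one voxel.

    ``prf`` is a mapping with keys x, y, sigma, n, g. Returns the length-T
    predicted timecourse g * ((stimulus . Gaussian)^n (*) HRF).
    """
    x, y, sigma, n, g = (float(prf[k]) for k in ("x", "y", "sigma", "n", "g"))
    for v in (x, y, sigma, n, g):
        if not np.isfinite(v):
            raise ValueError("non-finite pRF parameter")
    if sigma <= 0 or n <= 0:
        raise ValueError("sigma and n must be positive")
    drive = _gauss_overlap(apertures, x, y, sigma) ** n
    kern = hrf.kernel(apertures.tr)
    return g * np.convolve(drive, kern)[: apertures.n_frames]


@dataclass
class FitGridSpec:
    """Search grids and refinement settings for the pRF fitter.

    The sigma grid is log-spaced from the floor value upward: pRF size
    uncertainty scales roughly multiplicatively. Exponent grid spans the
    compressive range; refinement then moves all four parameters off-grid.
    """

    x_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    y_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    sigma_grid: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_grid: tuple = (0.25, 0.5, 0.75, 1.0)
    refine: bool = True
    refine_n: bool = False
    sigma_floor: float = 0.21
    max_iter: int = 300
    tolerance: float = 1e-4

    @classmethod
    def for_field(cls, field_radius: float, n_xy: int = 17,
                  n_sigma: int = 8, **kw) -> "FitGridSpec":
        xs = np.linspace(-field_radius, field_radius, n_xy)
        sig = np.geomspace(kw.pop("sigma_floor", 0.21), field_radius, n_sigma)
        return cls(x_grid=xs, y_grid=xs.copy(), sigma_grid=sig,
                   sigma_floor=float(sig[0]), **kw)

    def __post_init__(self):
        if self.x_grid is None or self.y_grid is None or self.sigma_grid is None:
            raise ValueError("x, y, and sigma grids are required "
                             "(use FitGridSpec.for_field)")
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.y_grid = np.asarray(self.y_grid, dtype=float)
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        for g in (self.x_grid, self.y_grid, self.sigma_grid, self.n_grid):
            if len(g) == 0:
                raise ValueError("grids must be nonempty")
        if not np.isclose(self.sigma_grid.min(), self.sigma_floor):
            raise ValueError("sigma grid must start at sigma_floor")


class PredictionBank:
    """Unit-gain CSS predictions for every grid candidate, cached.

    Building the candidate bank is the expensive step of the grid search
    and is shared across voxels (and across fit_population calls on the
    same protocol), so it lives in its own object.
    """

    def __init__(self, apertures: ApertureMovie, hrf: HRFSpec,
                 grid: FitGridSpec):
        self.apertures = apertures
        self.hrf = hrf
        self.grid = grid
        T = apertures.n_frames
        X, Y = apertures.pixel_grid()
        Xf = X.ravel().astype(np.float32)
        Yf = Y.ravel().astype(np.float32)
        S = apertures.frames.reshape(T, -1).astype(np.float32)
        conv = _convolution_matrix(hrf.kernel(apertures.tr), T).astype(np.float32)

        spatial = [(x, y, s) for s in grid.sigma_grid for y in grid.y_grid
                   for x in grid.x_grid]
        overlaps = np.empty((T, len(spatial)), dtype=np.float32)
        chunk = 256
        for lo in range(0, len(spatial), chunk):
            block = spatial[lo:lo + chunk]
            G = np.empty((Xf.size, len(block)), dtype=np.float32)
            for j, (x, y, s) in enumerate(block):
                G[:, j] = np.exp(-((Xf - x) ** 2 + (Yf - y) ** 2)
                                 / (2.0 * s ** 2))
            overlaps[:, lo:lo + chunk] = S @ G

        preds, params = [], []
        for n in grid.n_grid:
            preds.append(conv @ (overlaps ** np.float32(n)))
            params.extend([(x, y, s, n) for (x, y, s) in spatial])
        self.predictions = np.concatenate(preds, axis=1)  # (T, C)
        self.params = np.array(params)  # (C, 4): x, y, sigma, n
        self.energy = np.sum(self.predictions ** 2, axis=0).astype(np.float64)

    def best_candidates(self, tcs: np.ndarray):
        """Grid-stage fit for a (V, T) matrix of timecourses.

        Gain is the nonnegative least-squares projection of each
        timecourse on each unit-gain prediction; variance explained is R^2
        about the voxel mean. Returns (index, gain, ve) arrays; ties and
        all-zero candidate sets resolve to the first candidate in grid order.
        """
        Y = np.asarray(tcs, dtype=np.float64)
        num = self.predictions.astype(np.float64).T @ Y.T  # (C, V)
        denom = self.energy[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            gain = np.where(denom > 0, np.clip(num, 0.0, None) / denom, 0.0)
        ss_y = np.sum(Y ** 2, axis=1)  # (V,)
        ss_res = ss_y[None, :] - 2.0 * gain * num + gain ** 2 * denom
        ss_tot = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ve = np.clip(1.0 - ss_res / ss_tot[None, :], 0.0, 1.0)
        ve[~np.isfinite(ve)] = 0.0
        idx = np.argmax(ve, axis=0)
        v_ix = np.arange(Y.shape[0])
        return idx, gain[idx, v_ix], ve[idx, v_ix]


def _fit_one(tc: np.ndarray, bank: PredictionBank):
    grid = bank.grid
    apertures, hrf = bank.apertures, bank.hrf
    if np.ptp(tc) == 0:
        return dict(x=np.nan, y=np.nan, sigma=np.nan, n=np.nan, g=np.nan,
                    ve=0.0, flag="constant_tc")
    idx, g0, ve0 = bank.best_candidates(tc[None, :])
    idx, g0, ve0 = int(idx[0]), float(g0[0]), float(ve0[0])
    x0, y0, s0, n0 = bank.params[idx]
    if ve0 == 0.0 and bank.energy[idx] == 0:
        return dict(x=np.nan, y=np.nan, sigma=np.nan, n=np.nan, g=0.0,
                    ve=0.0, flag="null_fit")
    best = dict(x=float(x0), y=float(y0), sigma=float(s0), n=float(n0),
                g=g0, ve=ve0, flag="")
    if not grid.refine:
        return best

    T = apertures.n_frames
    conv = _convolution_matrix(hrf.kernel(apertures.tr), T)
    X, Y = apertures.pixel_grid()
    Xf, Yf = X.ravel(), Y.ravel()
    S = apertures.frames.reshape(T, -1).astype(np.float64)
    y_obs = np.asarray(tc, dtype=float)
    ss_tot = np.sum((y_obs - y_obs.mean()) ** 2)

    def fit_at(theta):
        x, y, s, n = theta
        drive = (S @ np.exp(-((Xf - x) ** 2 + (Yf - y) ** 2)
                            / (2.0 * s ** 2))) ** n
        p = conv @ drive
        pp = p @ p
        if pp <= 0:
            return 0.0, 0.0
        g = max(0.0, (p @ y_obs) / pp)
        ve = 1.0 - np.sum((y_obs - g * p) ** 2) / ss_tot
        return g, max(0.0, ve)

    R = apertures.field_radius
    xy_bounds = [(-1.5 * R, 1.5 * R), (-1.5 * R, 1.5 * R),
                 (grid.sigma_floor, 3.0 * R)]
    opts = {"maxiter": grid.max_iter, "xtol": grid.tolerance,
            "ftol": grid.tolerance}
    if grid.refine_n:
        # joint refinement; sigma and n trade off along a flat ridge, so
        # sigma itself becomes poorly determined under noise
        res = minimize(lambda th: 1.0 - fit_at(th)[1],
                       x0=np.array([x0, y0, s0, n0]), method="Powell",
                       bounds=xy_bounds + [(0.05, 1.0)], options=opts)
        cands = [res.x]
    else:
        # sweep x, y, sigma continuously at each discrete exponent; the
        # compressive exponent stays on its grid, which pins sigma
        cands = []
        for n in grid.n_grid:
            res = minimize(lambda th, n=n: 1.0 - fit_at((*th, n))[1],
                           x0=np.array([x0, y0, s0]), method="Powell",
                           bounds=xy_bounds, options=opts)
            cands.append(np.array([*res.x, n]))
    for theta in cands:
        g, ve = fit_at(theta)
        if ve >= best["ve"]:
            x, y, s, n = theta
            best = dict(x=float(x), y=float(y), sigma=float(s), n=float(n),
                        g=float(g), ve=float(ve), flag="")
    return best


def _as_fit_row(d: dict, voxel_id, roi, hemi) -> dict:
    x, y, sigma, n = d["x"], d["y"], d["sigma"], d["n"]
    ecc = float(np.hypot(x, y)) if np.isfinite(x) else np.nan
    size = sigma / np.sqrt(n) if np.isfinite(sigma) and n > 0 else np.nan
    return dict(voxel_id=voxel_id, roi=roi, hemi=hemi, x=x, y=y, sigma=sigma,
                n=n, g=d["g"], ve=d["ve"], ecc=ecc, size=size, flag=d["flag"])


def fit_prf(tc, apertures: ApertureMovie, hrf: HRFSpec,
            grid: FitGridSpec, *, voxel_id=0, roi="", hemi="",
            bank: PredictionBank | None = None) -> pd.Series:
    """Fit the CSS model to a single timecourse; returns one fit row."""
    tc = np.asarray(tc, dtype=float)
    if tc.shape != (apertures.n_frames,):
        raise ValueError("timecourse length must match the aperture movie")
    if bank is None:
        bank = PredictionBank(apertures, hrf, grid)
    return pd.Series(_as_fit_row(_fit_one(tc, bank), voxel_id, roi, hemi))


def fit_population(tcs, apertures: ApertureMovie, hrf: HRFSpec,
                   grid: FitGridSpec,
                   bank: PredictionBank | None = None) -> pd.DataFrame:
    """Fit every voxel of a VoxelTimecourses batch; order-preserving.

    Per-voxel failures (constant or degenerate timecourses) become flagged
    rows rather than aborting the batch.
    """
    values = np.asarray(tcs.values, dtype=float)
    if values.size == 0:
        raise ValueError("no voxels to fit")
    if values.shape[1] != apertures.n_frames:
        raise ValueError("timecourse length must match the aperture movie")
    if bank is None:
        bank = PredictionBank(apertures, hrf, grid)
    rows = []
    hemis = getattr(tcs, "hemispheres", None) or [""] * values.shape[0]
    for i in range(values.shape[0]):
        d = _fit_one(values[i], bank)
        rows.append(_as_fit_row(d, tcs.voxel_ids[i], tcs.roi_labels[i],
                                hemis[i]))
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def filter_fits(fits: pd.DataFrame, ve_min: float = 0.05,
                ecc_max: float = 7.0, sigma_floor: float = 0.21):
    """Apply the three voxel exclusion rules.

    Keeps rows with ve > ve_min, ecc <= ecc_max (centers inside the
    stimulated field), and sigma strictly above the fitting floor. Returns
    (survivors, log) where log counts exclusions per rule (a row may
    violate several rules and is counted under each).
    """
    ve_ok = fits["ve"].to_numpy() > ve_min
    ecc_ok = fits["ecc"].to_numpy() <= ecc_max
    sig_ok = fits["sigma"].to_numpy() > sigma_floor
    keep = ve_ok & ecc_ok & sig_ok
    log = {
        "n_input": int(len(fits)),
        "n_excluded_low_ve": int((~ve_ok).sum()),
        "n_excluded_ecc": int((~ecc_ok).sum()),
        "n_excluded_sigma_floor": int((~sig_ok).sum()),
        "n_survivors": int(keep.sum()),
        "ve_min": ve_min, "ecc_max": ecc_max, "sigma_floor": sigma_floor,
    }
    return fits.loc[keep].reset_index(drop=True), log
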