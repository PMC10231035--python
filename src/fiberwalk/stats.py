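"""Validation statistics: autocovariance, MSD, Hurst recovery, border profiles.

These are diagnostic estimators, not part of the simulation proper: they
verify that generated noise carries the prescribed covariance, that free
trajectories show the MSD scaling MSD ~ t^{2H}, and that confined runs
reproduce the border-accumulation effect expected for superdiffusive
reflected FBM (densities elevated near tissue borders for H > 0.5,
depleted for H < 0.5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from dataclasses import dataclass
from scipy import ndimage

__all__ = [
    "MSDCurve",
    "empirical_autocovariance",
    "ensemble_msd",
    "estimate_hurst",
    "border_distance_profile",
    "convergence_l1",
]


@dataclass(frozen=True)
class MSDCurve:
    """Mean squared displacement (summed over the 3 components) vs lag."""

    lags: np.ndarray
    msd: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags)
        if np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(np.asarray(self.msd) < 0):
            raise ValueError("msd must be non-negative")


def empirical_autocovariance(series, max_lag: int) -> np.ndarray:
    """Sample autocovariance at lags 0..max_lag, unbiased normalization.

    c(tau) = 1/(n - tau) * sum (x_i - xbar)(x_{i+tau} - xbar)
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n <= 4 * max_lag:
        raise ValueError(f"series length {n} too short for max_lag {max_lag}")
    x = x - x.mean()
    out = np.empty(max_lag + 1)
    for tau in range(max_lag + 1):
        out[tau] = (x[: n - tau] @ x[tau:]) / (n - tau)
    return out


def ensemble_msd(trajectories, lags, strict_free: bool = True) -> MSDCurve:
    """Ensemble- and time-averaged MSD over a set of free-space trajectories.

    For each lag the squared displacement |r_{t+lag} - r_t|^2 (all three
    components) is averaged over every time origin of every fiber.  With
    ``strict_free`` a trajectory that shows rejected steps is refused:
    reflected trajectories do not obey the free scaling law.
    """
    trajs = list(trajectories)
    if len(trajs) < 8:
        raise ValueError("need at least 8 trajectories")
    if strict_free and any(getattr(t, "n_rejected", 0) > 0 for t in trajs):
        raise ValueError(
            "reflected trajectories passed to ensemble_msd (strict_free=True)"
        )
    lags = np.asarray(sorted(set(int(l) for l in lags)))
    if lags[0] < 0:
        raise ValueError("lags must be non-negative")
    msd = np.zeros(len(lags))
    for li, lag in enumerate(lags):
        if lag == 0:
            continue
        acc = 0.0
        cnt = 0
        for t in trajs:
            p = t.positions
            d = p[lag:] - p[:-lag]
            acc += float(np.einsum("ij,ij->", d, d))
            cnt += d.shape[0]
        msd[li] = acc / cnt
    return MSDCurve(lags, msd)


def estimate_hurst(curve: MSDCurve, fit_range: tuple[int, int] = (8, 512)) -> float:
    """Hurst index = half the log-log least-squares slope of MSD vs lag."""
    lo, hi = fit_range
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if sel.sum() < 5:
        raise ValueError(f"fewer than 5 MSD points in fit range [{lo}, {hi}]")
    msd = curve.msd[sel]
    if np.any(msd <= 0):
        raise ValueError("non-positive MSD values in fit range")
    slope = np.polyfit(np.log(curve.lags[sel]), np.log(msd), 1)[0]
    return float(slope / 2.0)


def border_distance_profile(grid, volume) -> pd.DataFrame:
    """Mean normalized density d_s as a function of Chebyshev bin-distance
    to the nearest non-allowed bin.

    A pooling bin counts as allowed if any of its grid cells is allowed;
    distance 0 is the outermost shell (bins touching a border or forbidden
    bin).  The distance classes partition the allowed bins.  Columns:
    distance, mean_d_s, mean_d_o, n_bins.
    """
    mask = volume.rasterize()
    bc = grid.bin_cells
    nx, ny, nz = mask.shape
    bshape = grid.counts.shape
    bin_allowed = np.zeros(bshape, dtype=bool)
    # any-allowed pooling of the cell mask
    for dx in range(bc):
        for dy in range(bc):
            for dz in range(bc):
                sub = mask[dx::bc, dy::bc, dz::bc]
                bin_allowed[: sub.shape[0], : sub.shape[1], : sub.shape[2]] |= sub
    if not bin_allowed.any():
        raise ValueError("volume has no allowed bins")
    padded = np.pad(bin_allowed, 1, constant_values=False)
    dist = ndimage.distance_transform_cdt(padded, metric="chessboard")
    dist = dist[1:-1, 1:-1, 1:-1][bin_allowed] - 1
    d_s = grid.d_s[bin_allowed]
    d_o = grid.d_o[bin_allowed]
    df = pd.DataFrame({"distance": dist, "d_s": d_s, "d_o": d_o})
    out = (
        df.groupby("distance")
        .agg(mean_d_s=("d_s", "mean"), mean_d_o=("d_o", "mean"), n_bins=("d_s", "size"))
        .reset_index()
    )
    return out


def convergence_l1(counts_first, counts_second) -> float:
    """Steady-state diagnostic: L1 distance between the normalized density
    fields of two halves of a run (0 = identical, 2 = disjoint support)."""
    a = np.asarray(counts_first, dtype=float)
    b = np.asarray(counts_second, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both halves must contain positions")
    return float(np.abs(a / a.sum() - b / b.sum()).sum())
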