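"""Voxel density mapping and the optical-density transform.

Walker positions are tallied in non-overlapping pooling bins of 2x2x2 grid
cells (pooling suppresses counting noise).  Raw counts are normalized so
the densities d_s sum to one over the whole volume, removing any dependence
on the arbitrarily chosen trajectory length, then transformed to
immunohistochemistry-like "optical densities"

    d_o = 1 - exp(-k * d_s),

a Beer-Lambert-law-like saturation that maps densities into [0, 1).  The
default k = 10^8.3 was tuned for the full-scale simulation's bin count;
because d_s is sum-normalized, smaller volumes or shorter runs shift its
dynamic range, so ``auto_k`` picks k such that the median non-zero d_o is
0.5.  Down-stream comparisons are nearly independent of the exact monotone
transform, so either choice orders the bins identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_LOG10_K = 8.3

__all__ = [
    "DensityGrid",
    "accumulate",
    "normalize",
    "optical_transform",
    "auto_k",
    "profile_cut",
    "export_volume",
    "import_volume",
    "DEFAULT_LOG10_K",
]


def accumulate(positions, volume, bin_cells: int = 2) -> np.ndarray:
    """Tally a stream of positions into pooled bin counts.

    Each position increments the bin containing its floor cell
    (bin index = floor(floor(coord) / bin_cells)).  Grid extents not
    divisible by ``bin_cells`` keep trailing partial bins so no position
    is lost.  Raises if any position falls outside the allowed region.
    """
    from .geometry import is_inside

    nx, ny, nz = volume.shape
    shape = tuple(-(-d // bin_cells) for d in (nx, ny, nz))
    counts = np.zeros(shape, dtype=np.int64)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    cells = np.floor(pos).astype(np.int64)
    mask = volume.rasterize()
    oob = (
        (cells < 0).any(axis=1)
        | (cells[:, 0] >= nx) | (cells[:, 1] >= ny) | (cells[:, 2] >= nz)
    )
    if oob.any():
        raise ValueError(
            f"position outside volume bounds: {pos[np.argmax(oob)]}"
        )
    inside = mask[cells[:, 0], cells[:, 1], cells[:, 2]]
    if not inside.all():
        raise ValueError(
            f"position outside allowed region: {pos[np.argmin(inside)]}"
        )
    bins = cells // bin_cells
    np.add.at(counts, (bins[:, 0], bins[:, 1], bins[:, 2]), 1)
    return counts


def normalize(counts: np.ndarray) -> np.ndarray:
    """Normalized densities d_s = counts / sum(counts); sums to one."""
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero count grid")
    return counts / float(total)


def optical_transform(d_s: np.ndarray, k: float = 10**DEFAULT_LOG10_K) -> np.ndarray:
    """Beer-Lambert-like transform d_o = 1 - exp(-k d_s), elementwise.

    Strictly increasing in d_s with range [0, 1); rank order of bins is
    preserved.  (In float64 the value saturates to exactly 1.0 once
    k * d_s exceeds ~37.)
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    d_s = np.asarray(d_s, dtype=float)
    if (d_s < 0).any():
        raise ValueError("d_s must be non-negative")
    return -np.expm1(-k * d_s)


def auto_k(d_s: np.ndarray) -> float:
    """k such that the median non-zero bin maps to d_o = 0.5."""
    nz = d_s[d_s > 0]
    if nz.size == 0:
        raise ValueError("no non-zero densities")
    return float(np.log(2.0) / np.median(nz))


@dataclass
class DensityGrid:
    """Pooled bin counts with derived normalized and optical densities."""

    counts: np.ndarray
    bin_cells: int = 2
    cell_um: float = 6.6
    k: float = 10**DEFAULT_LOG10_K
    _d_s: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def from_counts(cls, counts, bin_cells=2, cell_um=6.6, k=None) -> "DensityGrid":
        if k == "auto":
            g = cls(counts, bin_cells, cell_um)
            return cls(counts, bin_cells, cell_um, auto_k(g.d_s))
        return cls(counts, bin_cells, cell_um, k if k else 10**DEFAULT_LOG10_K)

    @property
    def d_s(self) -> np.ndarray:
        if self._d_s is None:
            self._d_s = normalize(self.counts)
        return self._d_s

    @property
    def d_o(self) -> np.ndarray:
        return optical_transform(self.d_s, self.k)

    @property
    def bin_um(self) -> float:
        """Physical bin edge, bin_cells x cell_um (default 13.2 um)."""
        return self.bin_cells * self.cell_um


def profile_cut(grid: DensityGrid, axis: str, **fixed) -> pd.DataFrame:
    """One-dimensional density profile along ``axis`` ('x'|'y'|'z') at the
    fixed bin indices of the other two axes.

    Returns a DataFrame with columns bin_index, d_s, d_o, ordered along
    the cut, ready for CSV export or plotting.
    """
    axes = "xyz"
    if axis not in axes:
        raise ValueError(f"axis must be one of x, y, z, got {axis!r}")
    others = [a for a in axes if a != axis]
    try:
        idx = [fixed[a] for a in others]
    except KeyError as exc:
        raise ValueError(f"missing fixed index for axis {exc}") from exc
    sel: list = [slice(None)] * 3
    for a, i in zip(others, idx):
        dim = grid.counts.shape[axes.index(a)]
        if not 0 <= i < dim:
            raise ValueError(f"fixed index {a}={i} out of bounds [0, {dim})")
        sel[axes.index(a)] = i
    d_s = grid.d_s[tuple(sel)]
    d_o = grid.d_o[tuple(sel)]
    return pd.DataFrame(
        {"bin_index": np.arange(len(d_s)), "d_s": d_s, "d_o": d_o}
    )


def export_volume(grid: DensityGrid, path, which: str = "d_o") -> None:
    """Write a density field as NIfTI with the bin size in the header.

    ``which`` selects counts (integer, lossless), d_s, or d_o.  Voxel
    size is bin_cells * cell_um micrometres, recorded in mm.
    """
    import nibabel as nib

    arrays = {"counts": grid.counts, "d_s": grid.d_s, "d_o": grid.d_o}
    if which not in arrays:
        raise ValueError(f"which must be one of {sorted(arrays)}, got {which!r}")
    data = arrays[which]
    if which == "counts":
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    vox_mm = grid.bin_um / 1000.0
    affine = np.diag([vox_mm, vox_mm, vox_mm, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((vox_mm,) * 3)
    nib.save(img, str(path))


def import_volume(path) -> np.ndarray:
    """Read back an exported NIfTI volume as an array."""
    import nibabel as nib

    return np.asarray(nib.load(str(path)).dataobj)
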