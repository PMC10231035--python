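"""Stacked-section 3D geometry: contour rows, interpolation, inside tests.

A 3D shape is described as a rostro-caudal stack of coronal sections.
Each section holds one or more contours; a contour is an ordered list of
rows ``(y, x_left, x_right)`` giving, for each consecutive dorsoventral
integer level y, the leftmost and rightmost mediolateral x-coordinates.
Dorsoventrally-oriented concavities and internal voids (ventricles) cannot
be captured by a single such span list, so they are coded as separate
"forbidden" contours subtracted from the allowed region.

Physical sections are cut at 80 um steps; each is subdivided into 12
virtual slices of ~6.6 um by linear interpolation, so the simulation
voxels are cubes of 6.6 um side.  Coordinates are a 0-based integer grid:
cell (i, j, k) occupies [i,i+1) x [j,j+1) x [k,k+1); x is mediolateral,
y dorsoventral (increasing ventral), z rostrocaudal (increasing caudal).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "ContourRows",
    "PhysicalSection",
    "VolumeModel",
    "symmetrize_contour",
    "interpolate_sections",
    "build_volume",
    "is_inside",
    "read_stack",
    "write_stack",
]

ALLOWED = "allowed"
FORBIDDEN = "forbidden"


class GeometryError(ValueError):
    """Invalid contour-stack geometry."""


@dataclass(frozen=True)
class ContourRows:
    """One closed contour as consecutive (y, x_left, x_right) rows."""

    kind: str
    rows: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if self.kind not in (ALLOWED, FORBIDDEN):
            raise GeometryError(f"unknown contour kind {self.kind!r}")
        if not self.rows:
            raise GeometryError("contour has no rows")
        ys = [r[0] for r in self.rows]
        for i, (y, xl, xr) in enumerate(self.rows):
            if xl > xr:
                raise GeometryError(
                    f"row {i} (y={y}): x_left {xl} > x_right {xr}"
                )
        if any(b - a != 1 for a, b in zip(ys, ys[1:])):
            raise GeometryError("y values must be consecutive with no gaps")

    @property
    def y_range(self) -> tuple[int, int]:
        return self.rows[0][0], self.rows[-1][0]

    @property
    def x_range(self) -> tuple[int, int]:
        return (min(r[1] for r in self.rows), max(r[2] for r in self.rows))

    def row_at(self, y: int) -> tuple[int, int, int] | None:
        y0 = self.rows[0][0]
        if y0 <= y <= self.rows[-1][0]:
            return self.rows[y - y0]
        return None


@dataclass(frozen=True)
class PhysicalSection:
    """One 80-um coronal section; ``present=False`` marks a damaged or
    missing section to be recreated by interpolation."""

    index: int
    contours: tuple[ContourRows, ...] = ()
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and not any(c.kind == ALLOWED for c in self.contours):
            raise GeometryError(
                f"section {self.index}: present section needs >=1 allowed contour"
            )

    def of_kind(self, kind: str) -> tuple[ContourRows, ...]:
        return tuple(c for c in self.contours if c.kind == kind)


@dataclass
class VolumeModel:
    """Interpolated virtual-slice stack with inside/outside queries.

    ``slices[k]`` is the contour set of virtual slice k; ``z_extent`` equals
    ``subdivisions * number_of_physical_sections``.  The most rostral and
    caudal slice faces act as boundaries: any z outside [0, z_extent) is
    outside the volume.
    """

    slices: list[tuple[ContourRows, ...]]
    cell_um: float = 6.6
    subdivisions: int = 12
    _mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def z_extent(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int, int]:
        """(nx, ny, nz) bounding-box extents of the allowed region."""
        xmax = max(c.x_range[1] for s in self.slices for c in s if c.kind == ALLOWED)
        ymax = max(c.y_range[1] for s in self.slices for c in s if c.kind == ALLOWED)
        return (xmax + 1, ymax + 1, self.z_extent)

    def rasterize(self) -> np.ndarray:
        """Boolean allowed-cell mask of shape (nx, ny, nz), cached.

        Built independently of :func:`is_inside` (row-interval painting vs
        per-point lookup); the two routes are asserted equal in tests and
        the mask backs the fast walker kernel.
        """
        if self._mask is None:
            nx, ny, nz = self.shape
            mask = np.zeros((nx, ny, nz), dtype=bool)
            for k, contours in enumerate(self.slices):
                for c in contours:
                    if c.kind == ALLOWED:
                        for y, xl, xr in c.rows:
                            mask[xl : xr + 1, y, k] = True
                for c in contours:
                    if c.kind == FORBIDDEN:
                        for y, xl, xr in c.rows:
                            mask[max(xl, 0) : xr + 1, y, k] = False
            self._mask = mask
        return self._mask


def symmetrize_contour(contour: ContourRows, midline_x: float) -> ContourRows:
    """Bilateral symmetrization: replace each row by the hull of itself
    and its mirror image about ``midline_x``.  Idempotent."""
    lo, hi = contour.x_range
    if not lo <= midline_x <= hi:
        raise GeometryError(
            f"midline {midline_x} outside contour x-range [{lo}, {hi}]"
        )
    rows = []
    for y, xl, xr in contour.rows:
        ml = int(round(2.0 * midline_x - xr))
        mr = int(round(2.0 * midline_x - xl))
        rows.append((y, min(xl, ml), max(xr, mr)))
    return ContourRows(contour.kind, tuple(rows))


def _interp_pair(
    ca: ContourRows, cb: ContourRows, fraction: float
) -> ContourRows | None:
    """Interpolate two rank-matched contours of the same kind."""
    rows = []
    ya0, ya1 = ca.y_range
    yb0, yb1 = cb.y_range
    for y in range(min(ya0, yb0), max(ya1, yb1) + 1):
        ra = ca.row_at(y)
        rb = cb.row_at(y)
        if ra is not None and rb is not None:
            xl = int(round((1 - fraction) * ra[1] + fraction * rb[1]))
            xr = int(round((1 - fraction) * ra[2] + fraction * rb[2]))
            rows.append((y, xl, xr))
        elif ra is not None and fraction < 0.5:
            rows.append((y, ra[1], ra[2]))
        elif rb is not None and fraction > 0.5:
            rows.append((y, rb[1], rb[2]))
    if not rows:
        return None
    # drop rows disconnected from the main body (possible when one-sided
    # rows at the y-extremes are excluded by the nearness rule)
    runs: list[list[tuple[int, int, int]]] = [[rows[0]]]
    for prev, cur in zip(rows, rows[1:]):
        if cur[0] - prev[0] == 1:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    best = max(runs, key=len)
    return ContourRows(ca.kind, tuple(best))


def interpolate_sections(
    a: PhysicalSection, b: PhysicalSection, fraction: float
) -> tuple[ContourRows, ...]:
    """Linear interpolation between two present sections.

    Contours are matched by (kind, rank order); rows by y.  A row or
    contour present on only one side is included iff ``fraction`` lies
    nearer that side (< 0.5 toward it), which avoids topology jumps.
    """
    if not (a.present and b.present):
        raise GeometryError("can only interpolate between present sections")
    if not 0.0 <= fraction <= 1.0:
        raise GeometryError(f"fraction must be in [0, 1], got {fraction}")
    out: list[ContourRows] = []
    for kind in (ALLOWED, FORBIDDEN):
        cas, cbs = a.of_kind(kind), b.of_kind(kind)
        for ca, cb in zip(cas, cbs):
            c = _interp_pair(ca, cb, fraction)
            if c is not None:
                out.append(c)
        if len(cas) > len(cbs) and fraction < 0.5:
            out.extend(cas[len(cbs):])
        elif len(cbs) > len(cas) and fraction > 0.5:
            out.extend(cbs[len(cas):])
    if not any(c.kind == ALLOWED for c in out):
        raise GeometryError(
            f"interpolation between sections {a.index} and {b.index} at "
            f"fraction {fraction} yields no allowed contour"
        )
    return tuple(out)


def _clip_forbidden(
    contours: tuple[ContourRows, ...], slice_idx: int
) -> tuple[ContourRows, ...]:
    """Clip forbidden rows to the allowed extent; warn if clipping occurs."""
    allowed = [c for c in contours if c.kind == ALLOWED]
    out: list[ContourRows] = list(allowed)
    for c in contours:
        if c.kind != FORBIDDEN:
            continue
        rows = []
        clipped = False
        for y, xl, xr in c.rows:
            spans = [a.row_at(y) for a in allowed]
            spans = [s for s in spans if s is not None]
            if not spans:
                clipped = True
                continue
            lo = min(s[1] for s in spans)
            hi = max(s[2] for s in spans)
            nxl, nxr = max(xl, lo), min(xr, hi)
            if (nxl, nxr) != (xl, xr):
                clipped = True
            if nxl <= nxr:
                rows.append((y, nxl, nxr))
        if clipped:
            warnings.warn(
                f"virtual slice {slice_idx}: forbidden contour clipped to "
                "allowed extent",
                stacklevel=3,
            )
        if rows:
            # clipping may leave non-consecutive y runs; keep each run
            runs: list[list[tuple[int, int, int]]] = [[rows[0]]]
            for prev, cur in zip(rows, rows[1:]):
                (runs[-1].append(cur) if cur[0] - prev[0] == 1 else runs.append([cur]))
            out.extend(ContourRows(FORBIDDEN, tuple(r)) for r in runs)
    return tuple(out)


def _fill_missing(stack: list[PhysicalSection]) -> list[PhysicalSection]:
    if len([s for s in stack if s.present]) < 2:
        raise GeometryError("need at least two present sections")
    if not stack[0].present or not stack[-1].present:
        raise GeometryError("missing sections at stack ends cannot be extrapolated")
    present_idx = [i for i, s in enumerate(stack) if s.present]
    filled = list(stack)
    for lo, hi in zip(present_idx, present_idx[1:]):
        for i in range(lo + 1, hi):
            frac = (i - lo) / (hi - lo)
            contours = interpolate_sections(stack[lo], stack[hi], frac)
            filled[i] = PhysicalSection(stack[i].index, contours, present=True)
    return filled


def build_volume(
    stack: list[PhysicalSection],
    subdivisions: int = 12,
    cell_um: float = 6.6,
) -> VolumeModel:
    """Recreate missing sections, then subdivide each physical gap into
    ``subdivisions`` virtual slices by linear interpolation.

    Virtual slice ``12*i + j`` interpolates section i toward section i+1 at
    fraction j/12; the caudal-most section extrudes (it has no neighbor).
    ``z_extent`` is ``subdivisions * len(stack)``.
    """
    stack = sorted(stack, key=lambda s: s.index)
    filled = _fill_missing(stack)
    slices: list[tuple[ContourRows, ...]] = []
    for i, sec in enumerate(filled):
        nxt = filled[i + 1] if i + 1 < len(filled) else sec
        for j in range(subdivisions):
            frac = j / subdivisions
            contours = (
                sec.contours if frac == 0.0 or nxt is sec
                else interpolate_sections(sec, nxt, frac)
            )
            slices.append(_clip_forbidden(contours, len(slices)))
    return VolumeModel(slices, cell_um=cell_um, subdivisions=subdivisions)


def is_inside(volume: VolumeModel, point) -> bool:
    """Local inside-outside test for an arbitrary real point.

    The point is inside iff its floor cell lies in [0, z_extent) along z,
    some allowed contour row of that slice covers the cell, and no
    forbidden row does.  Total function: any real point is answerable.
    """
    x, y, z = point
    k = int(np.floor(z))
    if not 0 <= k < volume.z_extent:
        return False
    i = int(np.floor(x))
    j = int(np.floor(y))
    covered = False
    for c in volume.slices[k]:
        row = c.row_at(j)
        if row is None or not row[1] <= i <= row[2]:
            continue
        if c.kind == FORBIDDEN:
            return False
        covered = True
    return covered


# ---------------------------------------------------------------------------
# stack.json I/O


def write_stack(
    path,
    sections: list[PhysicalSection],
    cell_um: float = 6.6,
    section_step_um: float = 80.0,
    midline_x: float | None = None,
) -> None:
    doc = {
        "cell_um": cell_um,
        "section_step_um": section_step_um,
        "midline_x": midline_x,
        "sections": [
            {
                "index": s.index,
                "present": s.present,
                "contours": [
                    {"kind": c.kind, "rows": [list(r) for r in c.rows]}
                    for c in s.contours
                ],
            }
            for s in sections
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_stack(path):
    """Read and validate a stack.json manifest.

    Returns ``(sections, meta)`` where meta holds cell_um, section_step_um
    and midline_x.  Raises :class:`GeometryError` naming the first
    offending section or row.
    """
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("cell_um", "section_step_um", "sections"):
        if key not in doc:
            raise GeometryError(f"stack manifest missing key {key!r}")
    sections = []
    prev_index = None
    for si, s in enumerate(doc["sections"]):
        try:
            contours = tuple(
                ContourRows(c["kind"], tuple(tuple(int(v) for v in r) for r in c["rows"]))
                for c in s["contours"]
            )
            sec = PhysicalSection(int(s["index"]), contours, bool(s["present"]))
        except (GeometryError, KeyError, TypeError, ValueError) as exc:
            raise GeometryError(f"section entry {si}: {exc}") from exc
        if prev_index is not None and sec.index <= prev_index:
            raise GeometryError(
                f"section entry {si}: index {sec.index} not strictly increasing"
            )
        prev_index = sec.index
        sections.append(sec)
    meta = {
        "cell_um": float(doc["cell_um"]),
        "section_step_um": float(doc["section_step_um"]),
        "midline_x": doc.get("midline_x"),
    }
    return sections, meta
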