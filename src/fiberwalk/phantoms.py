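"""Synthetic contour-stack geometries (phantoms).

Real embryonic-brain contour stacks are produced by expert outlining of
serial sections; the phantoms here are deterministic synthetic stand-ins
with the same structural features — an elongated tapering allowed region,
internal forbidden voids emulating the lateral ventricles, a dorsomedial
forbidden concavity, and an embedded start cuboid standing in for the
rostral raphe region — so that every pipeline stage is testable without
any external data.

All generators are deterministic given their spec and their output passes
the stack reader's validation unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import (
    ALLOWED,
    FORBIDDEN,
    ContourRows,
    GeometryError,
    PhysicalSection,
)
from .walker import StartRegion

__all__ = [
    "PhantomSpec",
    "make_slab",
    "make_sphere_stack",
    "make_brain_phantom",
]


def make_slab(nx: int, ny: int, n_sections: int) -> list[PhysicalSection]:
    """Rectangular slab: identical all-allowed contours in every section."""
    if nx < 1 or ny < 1 or n_sections < 1:
        raise ValueError("slab dimensions must be positive")
    rows = tuple((y, 0, nx - 1) for y in range(ny))
    contour = ContourRows(ALLOWED, rows)
    return [PhysicalSection(i, (contour,)) for i in range(n_sections)]


def _ellipse_rows(cx: float, cy: float, a: float, b: float):
    """Raster rows of an axis-aligned ellipse, cell-center sampled."""
    rows = []
    for y in range(int(math.floor(cy - b)), int(math.ceil(cy + b)) + 1):
        u = (y + 0.5 - cy) / b
        if u * u >= 1.0:
            continue
        h = a * math.sqrt(1.0 - u * u)
        xl = int(math.ceil(cx - h - 0.5))
        xr = int(math.floor(cx + h - 0.5))
        if xl <= xr:
            rows.append((y, xl, xr))
    return rows


def make_sphere_stack(radius: int) -> list[PhysicalSection]:
    """Ball of the given radius, one section per unit z (use
    ``build_volume(..., subdivisions=1)`` so sections are not stretched).

    Sections are discs rasterized at cell centers; by construction every
    section is mirror-symmetric about the midline x = radius - 0.5.
    """
    if radius < 4:
        raise ValueError("radius must be >= 4 to rasterize a ball")
    r = float(radius)
    sections = []
    for k in range(2 * radius):
        dz = k + 0.5 - r
        rr = r * r - dz * dz
        if rr <= 0:
            continue
        disc = math.sqrt(rr)
        rows = _ellipse_rows(r, r, disc, disc)
        if not rows:
            continue
        sections.append(
            PhysicalSection(len(sections), (ContourRows(ALLOWED, tuple(rows)),))
        )
    if len(sections) < 2:
        raise ValueError(f"radius {radius} too small to rasterize")
    return sections


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the brain-like phantom.

    The allowed region is an elongated stack of tapering ellipses;
    ``ventricle_sections`` carry two lateral forbidden voids,
    ``concavity_sections`` a dorsomedial forbidden notch, and
    ``start_fraction`` places the start cuboid (rostral raphe analog)
    along the caudal third of the stack.
    """

    nx: int = 96
    ny: int = 80
    n_sections: int = 20
    ventricle_sections: tuple[int, int] = (4, 10)
    concavity_sections: tuple[int, int] = (6, 12)
    start_fraction: float = 0.65
    subdivisions: int = 12

    def __post_init__(self) -> None:
        if self.nx < 32 or self.ny < 32 or self.n_sections < 8:
            raise ValueError("brain phantom needs nx, ny >= 32 and >= 8 sections")
        if not 0.0 < self.start_fraction < 1.0:
            raise ValueError("start_fraction must be in (0, 1)")


def _clip_to_allowed(rows, allowed_rows, margin: int = 1):
    """Intersect forbidden rows with the allowed span at each y (keeps the
    phantom's forbidden regions inside the allowed extent by construction)."""
    span = {y: (xl, xr) for y, xl, xr in allowed_rows}
    out = []
    for y, xl, xr in rows:
        if y not in span:
            continue
        axl, axr = span[y]
        nxl, nxr = max(xl, axl + margin), min(xr, axr - margin)
        if nxl <= nxr:
            out.append((y, nxl, nxr))
    # keep only the longest consecutive run so the contour stays valid
    if not out:
        return []
    runs = [[out[0]]]
    for prev, cur in zip(out, out[1:]):
        (runs[-1].append(cur) if cur[0] - prev[0] == 1 else runs.append([cur]))
    return max(runs, key=len)


def make_brain_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[list[PhysicalSection], StartRegion]:
    """Brain-like phantom stack plus its embedded start cuboid.

    Returns ``(sections, start_region)``; the start region is expressed in
    virtual-slice grid units (z multiplied by ``spec.subdivisions``) and is
    guaranteed to lie inside the allowed region of every slice it spans.
    """
    spec = spec or PhantomSpec()
    s = spec.n_sections
    cx, cy = spec.nx / 2.0, spec.ny / 2.0
    sections = []
    semi = []
    for i in range(s):
        # smooth taper toward both poles, elongated rostro-caudally
        t = math.sin(math.pi * (i + 1) / (s + 1)) ** 0.6
        a = max(4.0, (spec.nx / 2.0 - 2.0) * t)
        b = max(4.0, (spec.ny / 2.0 - 2.0) * t)
        semi.append((a, b))
        allowed_rows = _ellipse_rows(cx, cy, a, b)
        if not allowed_rows:
            raise GeometryError(f"section {i}: degenerate allowed contour")
        contours = [ContourRows(ALLOWED, tuple(allowed_rows))]
        v0, v1 = spec.ventricle_sections
        if v0 <= i <= v1 and a > 14 and b > 14:
            for side in (-1, 1):
                vent = _ellipse_rows(
                    cx + side * a * 0.45, cy - b * 0.15, a * 0.10, b * 0.32
                )
                vent = _clip_to_allowed(vent, allowed_rows)
                if vent:
                    contours.append(ContourRows(FORBIDDEN, tuple(vent)))
        c0, c1 = spec.concavity_sections
        if c0 <= i <= c1 and b > 12:
            y_top = allowed_rows[0][0]
            depth = max(2, int(b * 0.25))
            notch = [
                (y, int(cx - a * 0.08), int(cx + a * 0.08))
                for y in range(y_top, y_top + depth)
            ]
            notch = _clip_to_allowed(notch, allowed_rows)
            if notch:
                contours.append(ContourRows(FORBIDDEN, tuple(notch)))
        sections.append(PhysicalSection(i, tuple(contours)))
    # start cuboid in the caudal third, ventral to the midline (the raphe
    # sits under the aqueduct); sized well inside the local ellipses
    zi = int(s * spec.start_fraction)
    a, b = semi[zi]
    origin = (cx - a * 0.15, cy + b * 0.10, zi * spec.subdivisions)
    extents = (a * 0.30, b * 0.25, 1.5 * spec.subdivisions)
    return sections, StartRegion(origin, extents)
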