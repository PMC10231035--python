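"""Contour-stack geometry: symmetrization, interpolation, inside tests, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fiberwalk.geometry import (
    ALLOWED,
    FORBIDDEN,
    ContourRows,
    GeometryError,
    PhysicalSection,
    build_volume,
    interpolate_sections,
    is_inside,
    read_stack,
    symmetrize_contour,
    write_stack,
)
from fiberwalk.phantoms import make_slab


def square(kind=ALLOWED, x0=0, x1=9, y0=0, y1=9):
    return ContourRows(kind, tuple((y, x0, x1) for y in range(y0, y1 + 1)))


class TestContourRows:
    def test_invariants_enforced(self):
        with pytest.raises(GeometryError):
            ContourRows(ALLOWED, ((0, 5, 3),))  # x_left > x_right
        with pytest.raises(GeometryError):
            ContourRows(ALLOWED, ((0, 0, 3), (2, 0, 3)))  # y gap
        with pytest.raises(GeometryError):
            ContourRows("void", ((0, 0, 3),))
        with pytest.raises(GeometryError):
            ContourRows(ALLOWED, ())

    def test_row_lookup(self):
        c = ContourRows(ALLOWED, ((3, 1, 5), (4, 0, 6)))
        assert c.row_at(4) == (4, 0, 6)
        assert c.row_at(5) is None
        assert c.y_range == (3, 4)
        assert c.x_range == (0, 6)


class TestSymmetrize:
    def test_already_symmetric_unchanged(self):
        c = ContourRows(ALLOWED, ((0, 3, 7),))
        assert symmetrize_contour(c, 5.0).rows == ((0, 3, 7),)

    def test_hull_of_mirror(self):
        c = ContourRows(ALLOWED, ((0, 2, 10),))
        # mirror of (2, 10) about 5 is (0, 8); hull is (0, 10)
        assert symmetrize_contour(c, 5.0).rows == ((0, 0, 10),)

    def test_idempotent(self):
        c = ContourRows(ALLOWED, ((0, 2, 10), (1, 4, 11)))
        once = symmetrize_contour(c, 5.0)
        assert symmetrize_contour(once, 5.0) == once

    def test_midline_outside_range_rejected(self):
        with pytest.raises(GeometryError):
            symmetrize_contour(ContourRows(ALLOWED, ((0, 2, 10),)), 20.0)


class TestInterpolation:
    def test_linear_midpoint(self):
        a = PhysicalSection(0, (ContourRows(ALLOWED, ((0, 0, 10),)),))
        b = PhysicalSection(1, (ContourRows(ALLOWED, ((0, 0, 22),)),))
        (c,) = interpolate_sections(a, b, 0.5)
        assert c.rows == ((0, 0, 16),)

    def test_endpoint_identity(self):
        a = PhysicalSection(0, (square(x1=7),))
        b = PhysicalSection(1, (square(x1=15),))
        assert interpolate_sections(a, b, 0.0) == a.contours
        assert interpolate_sections(a, b, 1.0) == b.contours

    def test_one_sided_row_nearness_rule(self):
        a = PhysicalSection(0, (ContourRows(ALLOWED, ((0, 0, 10), (1, 0, 10))),))
        b = PhysicalSection(1, (ContourRows(ALLOWED, ((0, 0, 10),)),))
        near_a = interpolate_sections(a, b, 0.25)[0]
        far_a = interpolate_sections(a, b, 0.75)[0]
        assert near_a.row_at(1) == (1, 0, 10)   # row only in a, kept near a
        assert far_a.row_at(1) is None          # dropped near b

    def test_one_sided_contour_nearness_rule(self):
        vent = ContourRows(FORBIDDEN, ((4, 4, 6),))
        a = PhysicalSection(0, (square(), vent))
        b = PhysicalSection(1, (square(),))
        assert len(interpolate_sections(a, b, 0.25)) == 2
        assert len(interpolate_sections(a, b, 0.75)) == 1

    @given(frac=st.floats(0.0, 1.0))
    @settings(max_examples=25, deadline=None)
    def test_self_interpolation_is_identity(self, frac):
        a = PhysicalSection(0, (square(), ContourRows(FORBIDDEN, ((4, 4, 6),))))
        assert interpolate_sections(a, a, frac) == a.contours

    def test_bad_fraction(self):
        a = PhysicalSection(0, (square(),))
        with pytest.raises(GeometryError):
            interpolate_sections(a, a, 1.5)


class TestBuildVolume:
    def test_identical_sections_extrude(self):
        vol = build_volume(make_slab(10, 10, 3))
        assert vol.z_extent == 36
        inside_by_z = [is_inside(vol, (4.5, 4.5, z + 0.5)) for z in range(36)]
        assert all(inside_by_z)
        assert not is_inside(vol, (4.5, 4.5, 36.0))
        assert not is_inside(vol, (4.5, 4.5, -0.1))

    def test_missing_section_recreated_at_midpoint(self):
        a = PhysicalSection(0, (ContourRows(ALLOWED, ((0, 0, 10),)),))
        miss = PhysicalSection(1, (), present=False)
        b = PhysicalSection(2, (ContourRows(ALLOWED, ((0, 0, 22),)),))
        vol = build_volume([a, miss, b])
        # slice 12 is the recreated section at fraction 0.5
        assert is_inside(vol, (16.5, 0.5, 12.5))
        assert not is_inside(vol, (17.5, 0.5, 12.5))

    def test_missing_ends_rejected(self):
        a = PhysicalSection(0, (), present=False)
        b = PhysicalSection(1, (square(),))
        c = PhysicalSection(2, (square(),))
        with pytest.raises(GeometryError):
            build_volume([a, b, c])
        with pytest.raises(GeometryError):
            build_volume([b])

    def test_forbidden_region_excluded(self):
        vent = ContourRows(FORBIDDEN, ((4, 4, 6),))
        secs = [PhysicalSection(i, (square(), vent)) for i in range(2)]
        vol = build_volume(secs)
        assert not is_inside(vol, (5.5, 4.5, 3.0))
        assert is_inside(vol, (7.5, 4.5, 3.0))

    def test_protruding_forbidden_clipped_with_warning(self):
        bad = ContourRows(FORBIDDEN, ((2, 5, 14),))  # exceeds allowed x range
        secs = [PhysicalSection(i, (square(), bad)) for i in range(2)]
        with pytest.warns(UserWarning, match="clipped"):
            vol = build_volume(secs)
        assert not is_inside(vol, (6.5, 2.5, 1.0))


def test_inside_matches_brute_force_rasterization(small_brain):
    """Dual route: the per-point contour-row test agrees cell-for-cell with
    the painted boolean mask on the whole (small) phantom grid."""
    _, _, vol = small_brain
    mask = vol.rasterize()
    nx, ny, nz = mask.shape
    for k in range(nz):
        expect = mask[:, :, k]
        got = np.array(
            [[is_inside(vol, (i + 0.5, j + 0.5, k + 0.5)) for j in range(ny)]
             for i in range(nx)]
        )
        assert np.array_equal(got, expect), f"slice {k} disagrees"


class TestStackIO:
    def test_round_trip(self, tmp_path):
        vent = ContourRows(FORBIDDEN, ((4, 4, 6),))
        secs = [
            PhysicalSection(0, (square(), vent)),
            PhysicalSection(1, (), present=False),
            PhysicalSection(2, (square(),)),
        ]
        path = tmp_path / "stack.json"
        write_stack(path, secs, midline_x=4.5)
        loaded, meta = read_stack(path)
        assert loaded == secs
        assert meta["cell_um"] == 6.6
        assert meta["midline_x"] == 4.5

    def test_reader_reports_offending_section(self, tmp_path):
        import json

        doc = {
            "cell_um": 6.6, "section_step_um": 80.0,
            "sections": [
                {"index": 0, "present": True,
                 "contours": [{"kind": "allowed", "rows": [[0, 5, 3]]}]},
            ],
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(GeometryError, match="section entry 0"):
            read_stack(p)

    def test_reader_rejects_non_increasing_indices(self, tmp_path):
        import json

        sec = {"index": 1, "present": True,
               "contours": [{"kind": "allowed", "rows": [[0, 0, 3]]}]}
        doc = {"cell_um": 6.6, "section_step_um": 80.0,
               "sections": [sec, dict(sec)]}
        p = tmp_path / "dup.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(GeometryError, match="strictly increasing"):
            read_stack(p)
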