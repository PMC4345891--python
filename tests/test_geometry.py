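import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import optomap as om
from optomap.geometry import (
    EmptyMaskWarning,
    ValidationError,
    _split_edges,
    grid_create,
    load_masks,
    save_masks,
)


# ---------------------------------------------------------------------------
# ROI validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind,params", [
    ("rectangle", (0, 0, 10, 10)),
    ("ellipse", (5, 5, 3, 2)),
    ("polygon", [(0, 0), (4, 0), (2, 3)]),
])
def test_make_roi_accepts_valid_geometry(kind, params):
    roi = om.make_roi(kind, params, label="x")
    assert roi.kind == kind
    assert roi.label == "x"


@pytest.mark.parametrize("kind,params,fragment", [
    ("rectangle", (0, 0, 0, 10), "x1 > x0"),
    ("rectangle", (0, 5, 10, 5), "y1 > y0"),
    ("ellipse", (5, 5, 0, 3), "rx"),
    ("ellipse", (5, 5, 3, -1), "ry"),
    ("polygon", [(0, 0), (1, 1)], "3 vertices"),
    ("polygon", [(0, 0), (1, 1), (2, 2)], "zero area"),
])
def test_make_roi_rejects_degenerate_geometry(kind, params, fragment):
    with pytest.raises(ValidationError, match=fragment):
        om.make_roi(kind, params)


def test_roi_ids_are_unique():
    ids = {om.make_roi("rectangle", (0, 0, 1, 1)).id for _ in range(10)}
    assert len(ids) == 10


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def test_full_field_rectangle_turns_every_mirror_on(identity_transform):
    roi = om.make_roi("rectangle", (0, 0, 100, 100))
    mask = om.rasterize(roi, identity_transform, (100, 100))
    assert mask.n_on == 10_000


def test_circle_matches_brute_force_center_count(identity_transform):
    roi = om.make_roi("ellipse", (50, 50, 10, 10))
    mask = om.rasterize(roi, identity_transform, (100, 100))
    count = sum(
        1
        for r in range(100)
        for c in range(100)
        if (c + 0.5 - 50) ** 2 + (r + 0.5 - 50) ** 2 <= 100.0
    )
    assert mask.n_on == count


def test_scaling_transform_maps_rectangle_to_pixel_block():
    roi = om.make_roi("rectangle", (0, 0, 10, 10))
    t = om.CalibrationTransform(np.array([[2.0, 0, 0], [0, 2.0, 0]]))
    mask = om.rasterize(roi, t, (100, 100))
    expected = np.zeros((100, 100), dtype=bool)
    expected[:20, :20] = True
    np.testing.assert_array_equal(mask.grid, expected)


def test_roi_outside_dmd_warns_and_returns_empty_mask(identity_transform):
    roi = om.make_roi("rectangle", (500, 500, 510, 510))
    with pytest.warns(EmptyMaskWarning):
        mask = om.rasterize(roi, identity_transform, (100, 100))
    assert mask.n_on == 0


def test_singular_transform_is_rejected():
    with pytest.raises(ValidationError, match="singular"):
        om.CalibrationTransform(np.array([[1.0, 0, 0], [2.0, 0, 0]]))


# ---------------------------------------------------------------------------
# SmartGrid creation and dimension arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("width,cols,expected", [
    (2172, 3, [724, 724, 724]),
    (10, 3, [4, 3, 3]),
    (7, 1, [7]),
])
def test_column_pixel_widths_follow_remainder_rule(width, cols, expected):
    edges = _split_edges(0, width, cols)
    assert [b - a for a, b in zip(edges, edges[1:])] == expected


def test_one_by_one_grid_is_a_single_leaf_equal_to_bounds():
    g = grid_create((0, 0, 10, 8), 1, 1)
    leaves = g.leaves()
    assert len(leaves) == 1
    assert leaves[0].bounds == (0, 0, 10, 8)


def test_successive_subdivision_reports_printed_cell_sizes():
    """A 2172x1653 um field split 3x3 gives 724x551 um cells; one more
    3x3 level gives 241x184 um and a further one 80x61 um."""
    g = grid_create((0, 0, 2172, 1653), 3, 3)
    assert g.cell_dimensions_um("0.0", 1.0) == (724, 551)
    g.subdivide("0.0", 3, 3)
    for k in range(9):
        assert g.cell_dimensions_um(f"0.0.{k}", 1.0) == (241, 184)
    g.subdivide("0.0.0", 3, 3)
    assert g.cell_dimensions_um("0.0.0.0", 1.0) == (80, 61)


def test_dimensions_scale_with_um_per_px():
    g = grid_create((0, 0, 100, 100), 1, 1)
    assert g.cell_dimensions_um("0", 0.5) == (50, 50)


def test_dimension_query_unknown_cell_errors():
    g = grid_create((0, 0, 10, 10), 2, 2)
    with pytest.raises(KeyError):
        g.cell_dimensions_um("0.99", 1.0)


def test_subdividing_below_one_pixel_errors():
    g = grid_create((0, 0, 2, 2), 2, 2)  # 1x1 px leaves
    with pytest.raises(ValueError, match="pixel limit"):
        g.subdivide("0.0", 2, 2)


def test_subdividing_a_non_leaf_errors():
    g = grid_create((0, 0, 100, 100), 2, 2)
    g.subdivide("0.0", 2, 2)
    with pytest.raises(ValueError, match="not a leaf"):
        g.subdivide("0.0", 2, 2)


def test_subdivision_clears_parent_selection():
    g = grid_create((0, 0, 100, 100), 2, 2)
    g.select(["0.0"])
    g.subdivide("0.0", 2, 2)
    assert not g.cell("0.0").selected


# ---------------------------------------------------------------------------
# Merge
# ---------------------------------------------------------------------------

def test_merging_adjacent_cells_doubles_the_width():
    g = grid_create((0, 0, 40, 20), 1, 2)
    merged = g.merge(["0.0", "0.1"])
    assert merged.bounds == (0, 0, 40, 20)


def test_merge_of_l_shape_errors():
    g = grid_create((0, 0, 30, 30), 2, 2)
    with pytest.raises(ValueError, match="rectangle"):
        g.merge(["0.0", "0.1", "0.2"])


def test_merge_across_parents_errors():
    g = grid_create((0, 0, 40, 40), 2, 2)
    g.subdivide("0.0", 2, 2)
    g.subdivide("0.1", 2, 2)
    with pytest.raises(ValueError, match="parent"):
        g.merge(["0.0.1", "0.1.0"])


def test_subdivide_then_merge_restores_original_tiling():
    g = grid_create((0, 0, 90, 90), 3, 3)
    before = sorted(c.bounds for c in g.leaves())
    g.subdivide("0.4", 2, 2)
    g.merge(["0.4.0", "0.4.1", "0.4.2", "0.4.3"])
    after = sorted(c.bounds for c in g.leaves())
    assert before == after
    assert g.cell("0.4").is_leaf


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def test_grouped_export_is_or_of_individual_masks(identity_transform):
    g = grid_create((0, 0, 20, 20), 2, 2)
    ids = ["0.0", "0.3"]  # disjoint, non-adjacent
    singles = g.export(ids, grouped=False, transform=identity_transform,
                       dmd_shape=(20, 20))
    grouped = g.export(ids, grouped=True, transform=identity_transform,
                       dmd_shape=(20, 20))
    assert len(grouped) == 1
    np.testing.assert_array_equal(grouped[0].grid,
                                  singles[0].grid | singles[1].grid)
    assert grouped[0].n_on == singles[0].n_on + singles[1].n_on
    assert sorted(grouped[0].member_roi_ids) == sorted(ids)


def test_singleton_export_grouped_equals_ungrouped(identity_transform):
    g = grid_create((0, 0, 20, 20), 2, 2)
    (single,) = g.export(["0.0"], grouped=False,
                         transform=identity_transform, dmd_shape=(20, 20))
    (grouped,) = g.export(["0.0"], grouped=True,
                          transform=identity_transform, dmd_shape=(20, 20))
    np.testing.assert_array_equal(single.grid, grouped.grid)


def test_full_selection_masks_partition_the_field(identity_transform):
    """All cells of a 9x9 grid exported individually: their OR covers
    every DMD pixel and no two masks share a pixel."""
    g = grid_create((0, 0, 45, 45), 9, 9)
    masks = g.export([c.id for c in g.leaves()], grouped=False,
                     transform=identity_transform, dmd_shape=(45, 45))
    assert len(masks) == 81
    total = np.zeros((45, 45), dtype=int)
    for m in masks:
        total += m.grid
    assert (total == 1).all()


def test_empty_selection_errors(identity_transform):
    g = grid_create((0, 0, 20, 20), 2, 2)
    with pytest.raises(ValueError, match="empty selection"):
        g.export([], transform=identity_transform, dmd_shape=(20, 20))


def test_selecting_a_non_leaf_errors():
    g = grid_create((0, 0, 40, 40), 2, 2)
    g.subdivide("0.0", 2, 2)
    with pytest.raises(ValueError, match="leaf"):
        g.select(["0.0"])


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

@given(st.data())
def test_tiling_conservation_under_random_subdivide_merge(data):
    """Leaf pixel footprints tile the root bounds exactly after any
    sequence of subdivisions."""
    w = data.draw(st.integers(8, 64))
    h = data.draw(st.integers(8, 64))
    g = grid_create((0, 0, w, h),
                    data.draw(st.integers(1, 3)), data.draw(st.integers(1, 3)))
    for _ in range(data.draw(st.integers(0, 4))):
        leaves = g.leaves()
        cell = leaves[data.draw(st.integers(0, len(leaves) - 1))]
        r = data.draw(st.integers(1, 3))
        c = data.draw(st.integers(1, 3))
        cw, ch = cell.px_size
        if c <= cw and r <= ch:
            g.subdivide(cell.id, r, c)
    paint = np.zeros((h, w), dtype=int)
    for leaf in g.leaves():
        x0, y0, x1, y1 = leaf.bounds
        paint[y0:y1, x0:x1] += 1
    assert (paint == 1).all()


@given(st.integers(5, 200), st.integers(1, 9))
def test_column_widths_are_floor_or_ceil_of_even_split(width, cols):
    edges = _split_edges(0, width, cols)
    widths = [b - a for a, b in zip(edges, edges[1:])]
    assert sum(widths) == width
    assert set(widths) <= {width // cols, -(-width // cols)}
    # remainder pixels are assigned left to right
    assert widths == sorted(widths, reverse=True)


@given(st.floats(0.5, 2000.0), st.floats(0.1, 4.0))
def test_cell_dimensions_round_to_nearest_um(width, um_per_px):
    g = om.SmartGrid((0, 0, max(1, int(width)), 10))
    w_um, _ = g.cell_dimensions_um("0", um_per_px)
    exact = max(1, int(width)) * um_per_px
    assert abs(w_um - exact) <= 0.5


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def test_grid_json_round_trip_preserves_structure(tmp_path):
    g = grid_create((0, 0, 100, 80), 3, 3)
    g.subdivide("0.4", 2, 2)
    g.select(["0.0", "0.4.1"])
    path = tmp_path / "grid.json"
    g.to_json(path)
    g2 = om.SmartGrid.from_json(path)
    assert sorted(c.bounds for c in g2.leaves()) == \
        sorted(c.bounds for c in g.leaves())
    assert g2.selected_ids() == g.selected_ids()
    assert g2.cell("0.4.1").nominal_bounds == g.cell("0.4.1").nominal_bounds


def test_mask_stack_round_trip(tmp_path, identity_transform):
    g = grid_create((0, 0, 20, 20), 2, 2)
    masks = g.export([c.id for c in g.leaves()], grouped=False,
                     transform=identity_transform, dmd_shape=(20, 20))
    save_masks(masks, tmp_path / "masks.tif", transform=identity_transform)
    loaded, transform = load_masks(tmp_path / "masks.tif")
    assert [m.id for m in loaded] == [m.id for m in masks]
    for a, b in zip(loaded, masks):
        np.testing.assert_array_equal(a.grid, b.grid)
    np.testing.assert_allclose(transform.matrix, identity_transform.matrix)
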