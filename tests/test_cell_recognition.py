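"""Template matching: similarity measure and cell classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hvfkit.cell_recognition import (
    UnreadableCell,
    classify_percentile_cell,
    classify_value_cell,
    match_raster,
    similarity,
    strip_triangle,
    GLYPH_ORDER,
)
from hvfkit.glyphs import CHAR_ADVANCE, TemplateSet, glyph_array, scale_raster


def make_cell(shape=(40, 40)):
    return np.zeros(shape, dtype=bool)


def stamp(cell, raster, y, x):
    h, w = raster.shape
    cell[y:y + h, x:x + w] |= raster
    return cell


def draw_token(token, scale=2, shape=(40, 60)):
    cell = make_cell(shape)
    x = 4
    for ch in token:
        g = glyph_array(ch, scale)
        stamp(cell, g, 6, x)
        x += CHAR_ADVANCE * scale
    return cell


@pytest.fixture(scope="module")
def templates():
    return TemplateSet.canonical("V1", 1)


class TestSimilarity:
    def test_identical_rasters_score_one(self):
        g = glyph_array("8", 2)
        assert similarity(g, g) == 1.0

    def test_inversion_of_a_half_ink_glyph_scores_near_zero(self):
        a = glyph_array("8", 2)  # ~49% ink, touches every bbox edge
        assert similarity(a, ~a) <= 0.1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((rng.integers(3, 12), rng.integers(3, 12))) < 0.5
        b = rng.random((rng.integers(3, 12), rng.integers(3, 12))) < 0.5
        if not a.any() or not b.any():
            return
        assert similarity(a, b) == pytest.approx(similarity(b, a), abs=1e-12)

    def test_empty_raster_is_a_contract_violation(self):
        with pytest.raises(ValueError):
            similarity(np.zeros((5, 5), bool), glyph_array("1", 1))

    def test_scale_invariance_of_canonical_glyphs(self):
        for ch in "0123456789":
            assert similarity(glyph_array(ch, 1), glyph_array(ch, 4)) == 1.0


class TestValueCells:
    @pytest.mark.parametrize("token,kind,value", [
        ("24", "NUMBER", 24),
        ("-5", "NUMBER", -5),
        ("0", "NUMBER", 0),
        ("-15", "NUMBER", -15),
        ("<0", "BELOW_THRESHOLD", None),
    ])
    @pytest.mark.parametrize("scale", [1, 3, 5])
    def test_rendered_tokens_classify_exactly(self, token, kind, value, scale,
                                              templates):
        cell = draw_token(token, scale=scale,
                          shape=(20 * scale, 24 * scale))
        got = classify_value_cell(cell, templates)
        assert got.kind == kind and got.value == value

    def test_blank_cell_is_empty_and_never_a_number(self, templates):
        assert classify_value_cell(make_cell(), templates).kind == "EMPTY"

    def test_triangle_only_cell_is_the_blind_spot(self, templates):
        cell = stamp(make_cell(), templates.glyphs["TRIANGLE"], 10, 10)
        assert classify_value_cell(cell, templates).kind == "BLIND_SPOT"

    def test_unparseable_ink_raises_with_coordinates(self, templates):
        cell = draw_token("--", scale=2)  # two dashes parse to nothing legal
        # one structural minus alone is not a number
        with pytest.raises(UnreadableCell) as exc:
            classify_value_cell(cell, templates, coords=(3, 7))
        assert exc.value.coords == (3, 7)

    def test_isolated_speckle_does_not_create_a_value(self, templates):
        cell = make_cell()
        cell[5, 5] = True
        cell[30, 22] = True
        assert classify_value_cell(cell, templates).kind == "EMPTY"


class TestTriangleStripping:
    def test_value_with_adjacent_triangle_fragment_reads_clean(self, templates):
        tri = scale_raster(templates.glyphs["TRIANGLE"], 2)
        cell = draw_token("0", scale=2)
        stamp(cell, tri[:, :10], 18, 38)  # fragment intruding at the edge
        stripped = strip_triangle(cell, templates)
        got = classify_value_cell(stripped, templates)
        assert (got.kind, got.value) == ("NUMBER", 0)
        # classification also strips internally
        direct = classify_value_cell(cell, templates)
        assert (direct.kind, direct.value) == ("NUMBER", 0)

    def test_strip_is_idempotent_and_preserves_clean_cells(self, templates):
        cell = draw_token("24", scale=2)
        once = strip_triangle(cell, templates)
        assert np.array_equal(once, cell)
        assert np.array_equal(strip_triangle(once, templates), once)

    def test_triangle_only_cell_strips_to_blank(self, templates):
        cell = stamp(make_cell(), templates.glyphs["TRIANGLE"], 10, 10)
        assert not strip_triangle(cell, templates).any()


class TestPercentileCells:
    @pytest.mark.parametrize("icon", ["NORMAL", "P5", "P2", "P1", "P05"])
    @pytest.mark.parametrize("scale", [1, 3, 5])
    def test_icons_classify_exactly_at_all_scales(self, icon, scale, templates):
        scaled = TemplateSet.canonical("X", scale)
        cell = stamp(make_cell((20 * scale, 20 * scale)),
                     scaled.icons[icon], 4, 4)
        assert classify_percentile_cell(cell, templates).kind == icon

    def test_blank_cell_is_empty(self, templates):
        assert classify_percentile_cell(make_cell(), templates).kind == "EMPTY"

    def test_classification_is_position_invariant(self, templates):
        icon = templates.icons["P2"]
        kinds = set()
        for y in range(0, 28, 7):
            for x in range(0, 28, 7):
                cell = stamp(make_cell(), icon, y, x)
                kinds.add(classify_percentile_cell(cell, templates).kind)
        assert kinds == {"P2"}

    def test_triangle_in_percentile_plot_is_the_blind_spot(self, templates):
        cell = stamp(make_cell(), templates.glyphs["TRIANGLE"], 10, 10)
        assert classify_percentile_cell(cell, templates).kind == "BLIND_SPOT"


def test_alternate_font_renders_still_classify_with_canonical_templates():
    """Pages printed with the alternate digit artwork are still read
    correctly by the canonical templates (cross-font tolerance)."""
    from hvfkit.layout_registry import get_layout
    from hvfkit.pipeline import extract_report
    from hvfkit.synthetic import random_report, render

    layout = get_layout("V2")
    alt = TemplateSet.alternate("ALT", layout.glyph_scale)
    rep = random_report(21, "24-2", "OD", "MODERATE")
    page = render(rep, layout, templates=alt)
    got, _ = extract_report(page, layout)
    for pid, grid in rep.grids().items():
        assert got.grids()[pid].cells == grid.cells, pid


def test_match_raster_tie_break_is_deterministic(templates):
    g = glyph_array("7", 1)
    first = match_raster(g, templates.glyphs, GLYPH_ORDER)
    assert first.best_id == "7"
    assert first.runner_up_margin >= 0
    again = match_raster(g, templates.glyphs, GLYPH_ORDER)
    assert (first.best_id, first.score) == (again.best_id, again.score)
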