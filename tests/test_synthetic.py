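"""Ground-truth generator, page renderer and seeded degradation."""

import numpy as np
import pytest

from hvfkit.synthetic import (
    NoiseSpec,
    degrade,
    get_pattern,
    load_patterns,
    random_report,
    render,
)

from conftest import make_report


class TestFieldPatterns:
    @pytest.mark.parametrize("pid,n_active,n_blind", [
        ("24-2", 52, 2), ("30-2", 74, 2), ("10-2", 68, 0),
    ])
    def test_standard_point_counts(self, pid, n_active, n_blind):
        p = get_pattern(pid)
        assert (len(p.active), len(p.blind_spot)) == (n_active, n_blind)
        assert not p.active & p.blind_spot

    def test_blind_spot_sits_temporal_on_the_horizontal_midline(self):
        assert get_pattern("24-2").blind_spot == {(4, 7), (5, 7)}
        assert get_pattern("24-2").mirrored().blind_spot == {(4, 2), (5, 2)}

    def test_os_masks_are_exact_column_mirrors(self):
        for p in load_patterns().values():
            mirrored = p.mirrored()
            assert mirrored.active == {(r, 9 - c) for r, c in p.active}
            assert mirrored.mirrored() == p


class TestRandomReport:
    def test_same_seed_is_identical(self):
        assert random_report(42) == random_report(42)
        assert random_report(42) != random_report(43)

    def test_grid_occupancy_matches_the_mask(self):
        rep = random_report(7, "24-2", "OD")
        assert len(rep.raw.nonempty_positions()) == 54  # active + blind spot
        assert len(rep.td_value.nonempty_positions()) == 52
        assert rep.td_perc.nonempty_positions() == \
            rep.td_value.nonempty_positions()
        assert rep.pd_perc.nonempty_positions() == \
            rep.pd_value.nonempty_positions()
        assert not rep.consistency_violations()

    @pytest.mark.parametrize("severity,lo,hi", [
        ("MILD", -6.0, 0.0), ("MODERATE", -12.0, -6.0), ("SEVERE", -99.0, -12.0),
    ])
    def test_mean_deviation_lands_in_its_severity_band(self, severity, lo, hi):
        hits = sum(
            lo <= random_report(s, "24-2", "OD", severity).metadata.mean_deviation < hi
            for s in range(100)
        )
        assert hits >= 99

    def test_os_report_mirrors_od_masks(self):
        od = random_report(5, "30-2", "OD")
        os_ = random_report(5, "30-2", "OS")
        assert os_.raw.nonempty_positions() == \
            {(r, 9 - c) for r, c in od.raw.nonempty_positions()}

    def test_pd_plots_can_be_suppressed(self):
        rep = random_report(9, include_pd=False)
        assert rep.pd_value.nonempty_positions() == set()
        assert rep.pd_perc.nonempty_positions() == set()

    def test_metadata_is_internally_plausible(self):
        rep = random_report(11, "24-2", "OD", "SEVERE")
        md = rep.metadata
        assert md.field_size == "24-2" and md.laterality == "OD"
        td = [c.value for row in rep.td_value.cells for c in row
              if c.kind == "NUMBER"]
        assert md.mean_deviation == pytest.approx(np.mean(td), abs=0.01)


class TestRender:
    def test_canonical_dimensions(self, layouts):
        rep = make_report(0)
        for version, (w, h) in (("V1", (650, 938)), ("V2", (2400, 3180)),
                                ("V3", (3726, 5262))):
            assert render(rep, layouts[version]).shape == (h, w)

    def test_rendering_is_byte_identical(self, layouts):
        rep = make_report(1)
        a = render(rep, layouts["V1"])
        b = render(rep, layouts["V1"])
        assert np.array_equal(a, b)


class TestDegrade:
    def test_clean_is_the_identity(self, layouts):
        img = render(make_report(2), layouts["V1"])
        assert np.array_equal(degrade(img, NoiseSpec.preset("CLEAN")), img)

    def test_same_seed_is_deterministic(self, layouts):
        img = render(make_report(2), layouts["V1"])
        spec = NoiseSpec.preset("L1", seed=3)
        assert np.array_equal(degrade(img, spec), degrade(img, spec))
        other = NoiseSpec.preset("L1", seed=4)
        assert not np.array_equal(degrade(img, spec), degrade(img, other))

    def test_l2_is_strictly_harsher_than_l1(self):
        l1, l2 = NoiseSpec.preset("L1"), NoiseSpec.preset("L2")
        assert l2.downscale_factor < l1.downscale_factor
        assert l2.blur_radius > l1.blur_radius
        assert l2.speckle_density > l1.speckle_density
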