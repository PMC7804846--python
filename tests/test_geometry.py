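"""Geometry module: case construction, the 210-case array, wall curves,
outline assembly."""

import numpy as np
import pytest

from lutflow import geometry as geo
from lutflow.geometry import GeometryError


class TestMakeCase:
    def test_index_case_constants_attached(self):
        s = geo.make_case(3.8, 3.0, 4.2)
        assert (s.bladder_d, s.ru_d, s.ru_len) == (10.0, 0.6, 15.7)

    def test_limit_case_pu_width_equals_ru_width(self):
        s = geo.make_case(3.8, 3.0, 0.6)
        assert s.td_pu == s.ru_d

    @pytest.mark.parametrize("args,fragment", [
        ((3.8, 0.5, 4.2), "ru_d < td_bn"),
        ((3.8, 3.0, 0.3), "td_pu >= ru_d"),
        ((-1.0, 3.0, 4.2), "must be > 0"),
        ((3.8, 11.0, 4.2), "bladder_d > td_bn"),
    ])
    def test_invariant_violations_name_the_constraint(self, args, fragment):
        with pytest.raises(GeometryError, match=fragment.replace(">", ">")):
            geo.make_case(*args)


class TestAmplificationArray:
    def test_shape_and_counts(self, array_specs):
        assert len(array_specs) == 210
        for ld in (3.6, 3.8, 4.0):
            assert sum(1 for s in array_specs if s.ld_pu == ld) == 70
        sub = [s for s in array_specs if s.ld_pu == 3.8 and s.td_bn == 3.0]
        assert sorted({s.td_pu for s in sub}) == [round(2.0 + 0.2 * i, 1)
                                                  for i in range(14)]

    def test_index_case_present(self, array_specs):
        matches = [s for s in array_specs
                   if (s.ld_pu, s.td_bn, s.td_pu) == (3.8, 3.0, 4.2)]
        assert len(matches) == 1
        assert matches[0].case_id == "II-C-12"

    def test_deterministic_enumeration(self, array_specs):
        again = geo.amplification_array()
        assert [s.case_id for s in again] == [s.case_id for s in array_specs]
        assert all(a == b for a, b in zip(again, array_specs))


class TestRpuRatios:
    def test_index_case_values(self, cats_spec):
        r1, r2 = geo.rpu_ratios(cats_spec)
        assert r1 == pytest.approx(1.4)
        assert r2 == pytest.approx(1.4 / 38.0)

    def test_equal_diameters_give_unity(self):
        r1, _ = geo.rpu_ratios(geo.make_case(3.8, 3.0, 3.0))
        assert r1 == pytest.approx(1.0)

    def test_monotonicity(self, array_specs):
        # rpu1 increases with td_pu at fixed td_bn; rpu2 decreases with ld_pu
        sub = sorted((s for s in array_specs
                      if s.ld_pu == 3.8 and s.td_bn == 3.0),
                     key=lambda s: s.td_pu)
        r1s = [geo.rpu_ratios(s)[0] for s in sub]
        assert np.all(np.diff(r1s) > 0)
        fixed_r1 = [geo.make_case(ld, 3.0, 4.2) for ld in (3.6, 3.8, 4.0)]
        r2s = [geo.rpu_ratios(s)[1] for s in fixed_r1]
        assert np.all(np.diff(r2s) < 0)


class TestPuWallProfile:
    def test_index_case_widths(self, cats_spec):
        left, right = geo.pu_wall_profile(cats_spec, n=2001)
        width = right[:, 0] * 2
        assert width[-1] == pytest.approx(3.0)      # BN plane
        assert width[0] == pytest.approx(0.6)       # apex plane
        assert width.max() == pytest.approx(4.2, abs=1e-6)
        assert right[-1, 1] - right[0, 1] == pytest.approx(3.8)

    def test_tapering_case_controls_mid_station(self):
        s = geo.make_case(3.8, 3.4, 2.0)
        left, right = geo.pu_wall_profile(s, n=2001)
        width = right[:, 0] * 2
        assert width.max() == pytest.approx(3.4)    # widest at BN plane
        assert width[1000] == pytest.approx(2.0)    # controlled mid-station
        assert np.all(np.diff(width) >= -1e-12)     # monotone taper

    def test_mirror_symmetry(self, array_specs):
        for s in array_specs[::31]:
            left, right = geo.pu_wall_profile(s)
            assert np.allclose(left[:, 0], -right[:, 0], atol=1e-9)
            assert np.allclose(left[:, 1], right[:, 1], atol=1e-9)


class TestAssembleDomain:
    def test_index_case_outline(self, cats_domain, cats_spec):
        assert cats_domain.tag_length("inlet") == pytest.approx(10.0)
        assert cats_domain.tag_length("outlet") == pytest.approx(0.6)
        ys = cats_domain.points[:, 1]
        assert ys.max() - ys.min() == pytest.approx(
            cats_spec.bladder_d / 2 + cats_spec.ld_pu + cats_spec.ru_len)

    def test_single_inlet_and_outlet_runs(self, cats_domain):
        tags = list(cats_domain.edge_tags)
        for tag in ("inlet", "outlet"):
            # circular count of contiguous runs of this tag
            runs = sum(1 for i, t in enumerate(tags)
                       if t == tag and tags[i - 1] != tag)
            assert runs == 1

    def test_all_210_domains_simple_and_symmetric(self, array_specs):
        for s in array_specs:
            d = geo.assemble_domain(s)
            assert d.is_simple()
            assert d.check_symmetry()

    def test_half_domain_tags_and_area(self, cats_spec):
        full = geo.assemble_domain(cats_spec)
        half = geo.assemble_domain(cats_spec, half=True)
        assert "symmetry" in half.edge_tags
        assert half.tag_length("inlet") == pytest.approx(5.0)
        assert abs(half.area()) == pytest.approx(abs(full.area()) / 2,
                                                 rel=1e-9)


class TestExports:
    def test_csv_roundtrip_headers(self, cats_domain):
        text = geo.domain_to_csv(cats_domain)
        lines = text.strip().splitlines()
        assert lines[1] == "x_cm,y_cm,tag"
        assert len(lines) == 2 + cats_domain.n_edges

    def test_geo_loop_refers_to_all_points(self, cats_domain):
        text = geo.domain_to_geo(cats_domain)
        assert text.count("Point(") == cats_domain.n_edges
        assert 'Physical Curve("inlet")' in text

    def test_manifest_columns(self, array_specs):
        df = geo.manifest(array_specs[:5])
        assert list(df.columns) == ["case_id", "ld_pu_cm", "td_bn_cm",
                                    "td_pu_cm", "rpu1", "rpu2"]
        assert len(df) == 5


class TestWallFamilyProperties:
    """Randomized invariants of the PU wall-curve family."""

    def test_width_constraints_hold_over_parameter_space(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=60, deadline=None, derandomize=True)
        @given(
            ld=st.floats(3.0, 5.0),
            bn=st.floats(2.2, 3.8),
            td=st.floats(0.8, 5.5),
        )
        def check(ld, bn, td):
            spec = geo.make_case(ld, bn, td)
            left, right = geo.pu_wall_profile(spec, n=801)
            width = right[:, 0] * 2
            assert width[0] == pytest.approx(0.6, abs=1e-9)
            assert width[-1] == pytest.approx(bn, abs=1e-9)
            if td >= bn:
                assert width.max() == pytest.approx(td, rel=1e-6)
            else:
                assert width[400] == pytest.approx(td, rel=1e-6)
            assert np.all(width > 0)
            # left curve is the exact mirror
            assert np.allclose(left[:, 0], -right[:, 0], atol=1e-12)

        check()

    def test_domains_simple_over_parameter_space(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=25, deadline=None, derandomize=True)
        @given(
            ld=st.floats(3.2, 4.4),
            bn=st.sampled_from([2.6, 2.8, 3.0, 3.2, 3.4]),
            td=st.floats(1.2, 5.0),
        )
        def check(ld, bn, td):
            d = geo.assemble_domain(geo.make_case(ld, bn, td))
            assert d.is_simple()
            assert d.check_symmetry()

        check()
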