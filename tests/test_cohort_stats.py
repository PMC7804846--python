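"""Cohort statistics: rank test against brute force, regression recovery,
group summaries, thresholds."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lutflow.cohort import (CohortSummary, mann_whitney_u, regress_tdv,
                            summarize_groups, vortex_thresholds)
from lutflow.postprocess import CaseResult


def brute_force_mw(a, b):
    """Exact two-sided Mann-Whitney p by enumerating label assignments.

    Valid for tie-free pooled samples; the U statistic of sample `a` counts
    pairs (x in a, y in b) with x > y.
    """
    a, b = list(a), list(b)
    n, m = len(a), len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    pooled = sorted(a + b)
    us = []
    for pos in itertools.combinations(range(n + m), n):
        sa = [pooled[i] for i in pos]
        sb = [pooled[i] for i in range(n + m) if i not in pos]
        us.append(sum(1 for x in sa for y in sb if x > y))
    us = np.array(us)
    # two-sided: double the smaller tail (the convention of exact tables)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return u_obs, min(1.0, 2.0 * min(p_low, p_high))


class TestMannWhitney:
    @pytest.mark.parametrize("a,b", [
        ([1, 2, 3], [4, 5, 6]),
        ([1.5, 9.1, 2.2, 7.3], [3.1, 4.7, 8.2]),
        ([10, 20, 30, 40, 50], [15, 25, 35]),
        ([0.1, 0.9], [0.5, 1.3, 2.4, 0.2]),
    ])
    def test_matches_brute_force_enumeration(self, a, b):
        u_ref, p_ref = brute_force_mw(a, b)
        u, p = mann_whitney_u(a, b)
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_fully_separated_samples(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)   # 2 * 1/20

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    def test_all_tied_degenerate(self):
        u, p = mann_whitney_u([5.0, 5.0, 5.0], [5.0, 5.0])
        assert p == 1.0

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 60)
        b = rng.normal(1.0, 1.0, 60)
        _, p = mann_whitney_u(a, b)
        assert p < 1e-5

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


def _fake_results(rows):
    out = []
    for i, r in enumerate(rows):
        out.append(CaseResult(
            case_id=r.get("case_id", f"c{i:03d}"),
            ld_pu=r.get("ld_pu", 3.8), td_bn=r.get("td_bn", 3.0),
            td_pu=r.get("td_pu", 4.2), rpu1=r.get("rpu1", 1.4),
            rpu2=r.get("rpu2", 0.0368), converged=r.get("converged", True),
            n_elements=1000, n_iter=10, mv_euo=r.get("mv_euo", 3.0),
            vortex=r.get("vortex", True), td_v=r.get("td_v", 1.0),
            ld_v=r.get("ld_v", 3.0), mass_imbalance=1e-6))
    return out


class TestRegression:
    def test_exactly_linear_data_r2_one(self):
        rows = [{"rpu1": x, "td_v": 2.0 * x - 0.5, "ld_pu": 3.8}
                for x in np.linspace(0.8, 1.6, 10)]
        df = regress_tdv(_fake_results(rows), "rpu1")
        row = df[df["group"] == "II"].iloc[0]
        assert row["r2"] == pytest.approx(1.0)
        assert row["slope"] == pytest.approx(2.0)
        assert row["intercept"] == pytest.approx(-0.5)

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(11)
        xs = np.linspace(0.8, 1.6, 40)
        rows = [{"rpu1": float(x),
                 "td_v": float(2.0 * x + rng.normal(0, 0.01)),
                 "ld_pu": 3.6} for x in xs]
        df = regress_tdv(_fake_results(rows), "rpu1")
        row = df[df["group"] == "I"].iloc[0]
        assert row["slope"] == pytest.approx(2.0, abs=0.05)

    def test_too_few_points_flagged(self):
        df = regress_tdv(_fake_results([{"ld_pu": 3.6}, {"ld_pu": 3.6}]),
                         "rpu1")
        row = df[df["group"] == "I"].iloc[0]
        assert not row["fit"]
        assert np.isnan(row["slope"])

    def test_rejects_unknown_ratio(self):
        with pytest.raises(ValueError):
            regress_tdv(_fake_results([{}] * 4), "rpu3")


class TestThresholds:
    def test_minima_over_vortex_stratum(self):
        rows = [{"rpu1": 0.9, "rpu2": 0.024, "vortex": True},
                {"rpu1": 0.8, "rpu2": 0.021, "vortex": True},
                {"rpu1": 0.7, "rpu2": 0.018, "vortex": False}]
        th = vortex_thresholds(_fake_results(rows))
        assert th["min_rpu1"] == pytest.approx(0.8)
        assert th["min_rpu2"] == pytest.approx(0.021)
        assert th["nearest_nonvortex_rpu1"] == pytest.approx(0.7)

    def test_all_vortex_degenerate(self):
        rows = [{"rpu1": r, "rpu2": r / 38, "vortex": True}
                for r in (0.8, 1.0, 1.2)]
        th = vortex_thresholds(_fake_results(rows))
        assert th["min_rpu1"] == pytest.approx(0.8)
        assert th["nearest_nonvortex_rpu1"] is None

    def test_no_vortex_flagged(self):
        th = vortex_thresholds(_fake_results([{"vortex": False}]))
        assert th["flagged"]
        assert th["min_rpu1"] is None


class TestGroupSummary:
    def _cohort(self):
        rows = []
        for ld in (3.6, 3.8, 4.0):
            for i in range(6):
                rows.append({"ld_pu": ld, "vortex": i < 4,
                             "mv_euo": 3.0 + 0.02 * i, "rpu1": 1.0 + 0.1 * i,
                             "rpu2": (1.0 + 0.1 * i) / (ld * 10),
                             "td_v": 0.9 + 0.05 * i if i < 4 else None})
        return _fake_results(rows)

    def test_counts_and_percentages_consistent(self):
        s = summarize_groups(self._cohort())
        assert isinstance(s, CohortSummary)
        for gcol in ("I", "II", "III", "all"):
            col = s.table[gcol]
            assert col["vortex_n"] + col["non_vortex_n"] == col["cases"]
            assert col["vortex_pct"] == pytest.approx(
                100 * col["vortex_n"] / col["cases"])

    def test_iqr_ordering(self):
        s = summarize_groups(self._cohort())
        for gcol in ("I", "II", "III", "all"):
            col = s.table[gcol]
            for base in ("td_v_mm", "mv_euo_vortex_m_s", "rpu1_vortex"):
                assert col[f"{base}_q1"] <= col[f"{base}_median"] \
                    <= col[f"{base}_q3"]

    def test_identical_values_collapse_iqr(self):
        rows = [{"ld_pu": 3.8, "vortex": True, "td_v": 1.0}] * 5
        s = summarize_groups(_fake_results(rows))
        col = s.table["II"]
        assert col["td_v_mm_q1"] == col["td_v_mm_median"] \
            == col["td_v_mm_q3"] == pytest.approx(10.0)

    def test_empty_stratum_absent_not_zero(self):
        rows = [{"ld_pu": 3.8, "vortex": True}] * 3
        s = summarize_groups(_fake_results(rows))
        col = s.table["II"]
        assert np.isnan(col["rpu1_non_vortex_median"])
        assert col["non_vortex_n"] == 0

    def test_single_case(self):
        s = summarize_groups(_fake_results([{"ld_pu": 3.6, "vortex": True}]))
        assert s.table["I"]["cases"] == 1
        assert s.n_converged == 1
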