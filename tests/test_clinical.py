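"""2x2 association statistics, dichotomization, staining index, survival."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from circsponge.clinical import (
    REFERENCE_COHORT_TABLES,
    SurvivalRecord,
    TwoByTwo,
    association_2x2,
    dichotomize_by_mean,
    kaplan_meier,
    logrank,
    staining_index,
)


class TestDichotomize:
    def test_ties_go_low(self):
        labels, mean = dichotomize_by_mean([1, 2, 3])
        assert labels == ["low", "low", "high"] and mean == 2.0

    def test_skewed_split(self):
        labels, _ = dichotomize_by_mean([0, 0, 0, 4])
        assert labels == ["low", "low", "low", "high"]

    def test_all_identical_warns_all_low(self, caplog):
        labels, _ = dichotomize_by_mean([2.0, 2.0, 2.0])
        assert labels == ["low", "low", "low"]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50))
    def test_partition_property(self, values):
        labels, mean = dichotomize_by_mean(values)
        assert len(labels) == len(values)
        highs = [v for v, l in zip(values, labels) if l == "high"]
        lows = [v for v, l in zip(values, labels) if l == "low"]
        assert all(v > mean for v in highs)
        assert all(v <= mean for v in lows)


class TestAssociation2x2:
    def test_ki67_chi_square(self):
        res = association_2x2(REFERENCE_COHORT_TABLES["ki67"])
        assert round(res.chi2, 3) == 7.119
        assert round(res.p_chi2, 3) == 0.008

    def test_tumor_size_odds_ratio(self):
        res = association_2x2(REFERENCE_COHORT_TABLES["tumor_size"])
        assert round(res.or_value, 3) == 7.389

    def test_independence_table(self):
        res = association_2x2(TwoByTwo("t", ("r1", "r2"), ((10, 10), (10, 10))))
        assert res.chi2 == pytest.approx(0.0)
        assert res.or_value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [((3, 1), (1, 3)), ((45, 8), (53, 30)), ((2, 7), (8, 2)), ((1, 5), (4, 9))],
    )
    def test_fisher_matches_hypergeometric_enumeration(self, counts):
        """Two-sided Fisher p equals the summed hypergeometric probabilities
        of all tables (same margins) no more likely than the observed one."""
        (a, b), (c, d) = counts
        res = association_2x2(TwoByTwo("t", ("r1", "r2"), counts))
        n, K, N = a + b + c + d, a + b, a + c
        p_obs = hypergeom.pmf(a, n, K, N)
        total = 0.0
        for x in range(max(0, K + N - n), min(K, N) + 1):
            p = hypergeom.pmf(x, n, K, N)
            if p <= p_obs * (1 + 1e-9):
                total += p
        assert res.p_fisher == pytest.approx(total, rel=1e-6)

    @given(st.tuples(*[st.integers(1, 40)] * 4))
    def test_symmetries(self, cells):
        a, b, c, d = cells
        t = TwoByTwo("t", ("r1", "r2"), ((a, b), (c, d)))
        swapped = TwoByTwo("t", ("r2", "r1"), ((d, c), (b, a)))  # rows+cols
        row_swapped = TwoByTwo("t", ("r2", "r1"), ((c, d), (a, b)))
        r0, r1, r2 = map(association_2x2, (t, swapped, row_swapped))
        assert r0.chi2 == pytest.approx(r1.chi2, rel=1e-9)
        assert r2.or_value == pytest.approx(1.0 / r0.or_value, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            association_2x2(TwoByTwo("t", ("r1", "r2"), ((0, 0), (5, 5))))

    def test_zero_cell_flags_and_haldane(self):
        t = TwoByTwo("t", ("r1", "r2"), ((5, 0), (3, 4)))
        res = association_2x2(t)
        assert math.isinf(res.or_value) and res.or_flag == "zero_cell_inf"
        hal = association_2x2(t, haldane=True)
        assert math.isfinite(hal.or_value) and hal.or_value > 0


class TestReferenceCohortRegression:
    """Every published effect value must reproduce from the printed counts
    under the row2-vs-row1 odds convention, at printed precision."""

    printed = {
        "age": 0.864,
        "menopause": 0.733,
        "tumor_size": 7.389,
        "ln_status": 13.741,
        "tnm_stage": 17.119,
        "tumor_grade": 1.82,
        "er": 0.289,
        "pr": 0.241,
        "her2": 0.439,
        "subtype": 0.092,
        "ki67": 3.184,
    }

    @pytest.mark.parametrize("variable", sorted(printed))
    def test_odds_ratio_reproduces(self, variable):
        res = association_2x2(REFERENCE_COHORT_TABLES[variable])
        expected = self.printed[variable]
        ndigits = len(str(expected).split(".")[1])
        assert round(res.or_value, ndigits) == expected


class TestStainingIndex:
    @pytest.mark.parametrize(
        "intensity,prop,si", [(3, 0.5, 1.5), (0, 0.9, 0.0), (4, 1.0, 4.0)]
    )
    def test_formula(self, intensity, prop, si):
        assert staining_index(intensity, prop).SI == pytest.approx(si)

    @pytest.mark.parametrize("intensity,prop", [(5, 0.5), (-1, 0.5), (2, 1.2)])
    def test_out_of_range_rejected(self, intensity, prop):
        with pytest.raises(ValueError):
            staining_index(intensity, prop)


def rec(pid, time, event, group="low"):
    return SurvivalRecord(pid, time, event, group)


class TestKaplanMeier:
    def test_single_event_product_limit(self):
        records = [rec("p1", 5, True), rec("p2", 8, False),
                   rec("p3", 9, False), rec("p4", 12, False)]
        curve = kaplan_meier(records)["low"]
        s_at_5 = curve.loc[curve.time == 5.0, "survival"].iloc[0]
        assert s_at_5 == pytest.approx(0.75)

    def test_all_censored_flat_at_one(self):
        records = [rec(f"p{i}", t, False) for i, t in enumerate([3, 6, 9])]
        curve = kaplan_meier(records)["low"]
        assert (curve.survival == 1.0).all()

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        records = [
            rec(f"p{i}", float(t), bool(e))
            for i, (t, e) in enumerate(
                zip(rng.exponential(20, 50), rng.integers(0, 2, 50))
            )
        ]
        curve = kaplan_meier(records)["low"]
        s = curve.survival.to_numpy()
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()

    def test_no_censoring_equals_empirical_survival(self):
        times = [2.0, 4.0, 6.0, 8.0]
        records = [rec(f"p{i}", t, True) for i, t in enumerate(times)]
        curve = kaplan_meier(records)["low"].set_index("time")
        for k, t in enumerate(times):
            empirical = sum(u > t for u in times) / len(times)
            assert curve.loc[t, "survival"] == pytest.approx(empirical)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            rec("p", 0.0, True)


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        low = [rec(f"l{i}", t, True, "low") for i, t in enumerate([3, 5, 8, 13])]
        high = [rec(f"h{i}", t, True, "high") for i, t in enumerate([3, 5, 8, 13])]
        stat, p = logrank(low + high)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank([rec("p1", 4, True), rec("p2", 6, False)])

    def test_requires_an_event(self):
        with pytest.raises(ValueError):
            logrank([rec("p1", 4, False), rec("p2", 6, False, "high")])

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(13)
        low = [rec(f"l{i}", float(t), True, "low")
               for i, t in enumerate(rng.exponential(100, 40))]
        high = [rec(f"h{i}", float(t), True, "high")
                for i, t in enumerate(rng.exponential(10, 40))]
        stat, p = logrank(low + high)
        assert p < 1e-6
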