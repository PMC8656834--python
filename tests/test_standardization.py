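import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from amimap import (
    StandardWeights,
    decile_classify,
    direct_standardize,
    inequality_metrics,
    percent_change,
    standardized_township_rates,
    summarize_table1,
)
from amimap._common import ConfigError


def weights_frame(w, ages=("35-49", "50-64", "65-79", "80+"), sex="male"):
    return pd.DataFrame(
        [(sex, a, x) for a, x in zip(ages, w)], columns=["sex", "age_group", "weight"]
    )


def rates_frame(rates, ages=("35-49", "50-64", "65-79", "80+"), sex="male"):
    return pd.DataFrame(
        [(sex, a, r) for a, r in zip(ages, rates)], columns=["sex", "age_group", "rate"]
    )


class TestDirectStandardization:
    def test_equal_rates_unchanged(self):
        assert direct_standardize(
            rates_frame([250.0] * 4), weights_frame([0.4, 0.3, 0.2, 0.1])
        ) == pytest.approx(250.0)

    def test_weighted_average_arithmetic(self):
        got = direct_standardize(
            rates_frame([100, 300, 700, 1300]), weights_frame([0.4, 0.3, 0.2, 0.1])
        )
        assert got == pytest.approx(400.0)

    def test_own_population_weights_give_crude_rate(self):
        # weights equal to the township's own stratum person-year shares
        py = np.array([5000.0, 3000.0, 1500.0, 500.0])
        events = np.array([5.0, 9.0, 10.0, 6.0])
        rates = events / py * 1e5
        crude = events.sum() / py.sum() * 1e5
        got = direct_standardize(rates_frame(rates), weights_frame(py / py.sum()))
        assert got == pytest.approx(crude)

    def test_missing_stratum_raises(self):
        with pytest.raises(ConfigError, match="missing stratum"):
            direct_standardize(
                rates_frame([100, 200], ages=("35-49", "50-64")),
                weights_frame([0.25, 0.25, 0.25, 0.25]),
            )

    def test_linearity(self):
        w = weights_frame([0.1, 0.2, 0.3, 0.4])
        base = [100.0, 150.0, 400.0, 900.0]
        a = direct_standardize(rates_frame(base), w)
        b = direct_standardize(rates_frame([3.5 * r for r in base]), w)
        assert b == pytest.approx(3.5 * a)


class TestPercentChange:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (216.3, 231.6, 7.1),
            (288.6, 331.1, 14.7),
            (145.9, 134.1, -8.1),
            (96.5, 148.8, 54.2),
            (279.8, 372.6, 33.2),
            (123.4, 123.4, 0.0),
        ],
    )
    def test_published_trend_arithmetic(self, start, end, expected):
        assert percent_change(start, end) == expected

    def test_zero_start_rejected(self):
        with pytest.raises(ConfigError):
            percent_change(0.0, 10.0)


def vector_with_percentiles(p10, p90, n=11):
    """n=11 sorted values whose linear-interpolation 10th/90th percentiles
    land exactly on positions 1 and 9."""
    v = np.linspace(p10, p90, 9)
    return np.concatenate([[p10 - 1.0], v, [p90 + 1.0]])


class TestInequalityMetrics:
    @pytest.mark.parametrize(
        "p10,p90,gap,ratio",
        [
            (146.1, 319.9, 173.8, 2.2),
            (149.8, 337.9, 188.1, 2.3),
            (79.2, 221.4, 142.2, 2.8),
            (5.8, 27.2, 21.4, 4.7),
        ],
    )
    def test_published_inequality_arithmetic(self, p10, p90, gap, ratio):
        s = inequality_metrics(vector_with_percentiles(p10, p90))
        assert s.p10 == p10 and s.p90 == p90
        assert s.absolute_gap == gap
        assert s.relative_ratio == ratio

    def test_equal_rates_degenerate(self):
        s = inequality_metrics(np.full(20, 212.5))
        assert s.absolute_gap == 0.0 and s.relative_ratio == 1.0
        assert s.q1 == s.median == s.q3 == 212.5

    def test_zero_p10_ratio_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            s = inequality_metrics(np.concatenate([np.zeros(5), np.ones(15)]))
        assert s.relative_ratio is None

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(50, 500, 307)
        a = inequality_metrics(x)
        b = inequality_metrics(rng.permutation(x))
        assert a == b

    def test_scale_behaviour(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(100, 900, 100)
        a, b = inequality_metrics(x), inequality_metrics(10 * x)
        assert b.relative_ratio == a.relative_ratio
        assert b.absolute_gap == pytest.approx(10 * a.absolute_gap, abs=0.5)

    def test_too_few_townships(self):
        with pytest.raises(ConfigError):
            inequality_metrics(np.arange(9))


class TestDeciles:
    def test_ten_distinct_rates_one_per_decile(self):
        s = pd.Series(np.arange(10.0) + 1, index=[f"T{i:03d}" for i in range(10)])
        assert sorted(decile_classify(s)) == list(range(1, 11))

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(1)
        s = pd.Series(rng.uniform(50, 500, 307), index=[f"T{i:03d}" for i in range(307)])
        sizes = decile_classify(s).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.uniform(10, 400, 97), index=[f"T{i:03d}" for i in range(97)])
        a = decile_classify(s)
        b = decile_classify(np.log(s) * 7 + 3)
        pd.testing.assert_series_equal(a, b)

    def test_deterministic_tie_break_by_township_id(self):
        s = pd.Series([5.0] * 20, index=[f"T{i:03d}" for i in range(20)])
        a = decile_classify(s)
        b = decile_classify(s.sample(frac=1.0, random_state=0))
        pd.testing.assert_series_equal(a, b)


rate_lists = st.lists(
    st.floats(min_value=1.0, max_value=5000.0, allow_nan=False),
    min_size=10,
    max_size=120,
)


class TestPropertyInvariants:
    @given(rate_lists, st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inequality_invariant_under_permutation(self, rates, rnd):
        shuffled = list(rates)
        rnd.shuffle(shuffled)
        assert inequality_metrics(np.array(rates)) == inequality_metrics(
            np.array(shuffled)
        )

    @given(rate_lists)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decile_bins_balanced_for_arbitrary_rates(self, rates):
        s = pd.Series(rates, index=[f"T{i:03d}" for i in range(len(rates))])
        d = decile_classify(s)
        sizes = d.value_counts()
        assert set(d).issubset(set(range(1, 11)))
        assert sizes.max() - sizes.min() <= 1

    @given(st.floats(min_value=0.1, max_value=1e4), st.floats(min_value=0.0, max_value=1e4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_percent_change_sign_and_identity(self, start, end):
        pc = percent_change(start, end)
        if end > start:
            assert pc >= 0
        elif end < start:
            assert pc <= 0
        assert percent_change(start, start) == 0.0


class TestTable1:
    def make_rate_table(self, n_townships=12):
        rng = np.random.default_rng(6)
        rows = []
        for t in [f"T{i:03d}" for i in range(n_townships)]:
            for sex in ("male", "female"):
                for age in ("35-49", "50-64", "65-79", "80+"):
                    for period in ("2007-2009", "2010-2012", "2013-2015", "2016-2018"):
                        rows.append((t, sex, age, period, rng.uniform(50, 800)))
        return pd.DataFrame(
            rows, columns=["township_id", "sex", "age_group", "period", "rate"]
        )

    def standard(self):
        w = np.array([0.55, 0.27, 0.13, 0.05]) / 2
        rows = [
            (sex, age, wi)
            for sex in ("male", "female")
            for age, wi in zip(("35-49", "50-64", "65-79", "80+"), w)
        ]
        return StandardWeights(pd.DataFrame(rows, columns=["sex", "age_group", "weight"]))

    def test_structure_has_four_period_column_triples(self):
        t1 = summarize_table1(self.make_rate_table(), self.standard())
        assert list(t1["characteristic"][:3]) == ["Total", "Male", "Male 35-49"]
        assert len(t1) == 11  # Total + 2 x (sex + 4 ages)
        for p in ("2007-2009", "2010-2012", "2013-2015", "2016-2018"):
            for suffix in ("median", "q1", "q3"):
                assert f"{p}_{suffix}" in t1.columns

    def test_single_township_degenerate_iqr(self):
        tab = self.make_rate_table(n_townships=1)
        t1 = summarize_table1(tab, self.standard())
        row = t1[t1["characteristic"] == "Male 35-49"].iloc[0]
        assert row["2007-2009_median"] == row["2007-2009_q1"] == row["2007-2009_q3"]

    def test_sex_specific_weights_renormalized(self):
        std = self.standard()
        m = std.sex_specific("male")
        assert m["weight"].sum() == pytest.approx(1.0)

    def test_standardized_rates_positive_and_complete(self):
        tab = self.make_rate_table()
        std = standardized_township_rates(tab, self.standard())
        assert len(std) == 12 * 4
        assert (std["rate"] > 0).all()
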