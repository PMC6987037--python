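"""Consistency (CV) and agreement (Pearson, regression, Bland-Altman) statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from probenum import (
    batch_means,
    bland_altman,
    compare_table,
    method_cv_summary,
    pearson,
    per_batch_cv,
    regress_identity,
)
from probenum.agreement import relative_differences

positive_floats = st.floats(min_value=1e-3, max_value=1e6)


def make_table(rows):
    return pd.DataFrame(rows, columns=["batch_id", "strain", "method", "replicate",
                                       "count_per_g"])


class TestPerBatchCV:
    def test_constant_replicates_have_zero_cv(self):
        assert per_batch_cv([5, 5, 5]) == 0.0

    def test_hand_computed_example(self):
        # sd = 10, mean = 110 -> 9.0909%
        assert per_batch_cv([100, 110, 120]) == pytest.approx(100 / 11, abs=1e-4)

    def test_single_replicate_flagged_missing(self):
        assert math.isnan(per_batch_cv([100]))

    def test_zero_mean_flagged(self):
        assert math.isnan(per_batch_cv([0, 0, 0]))

    @given(st.lists(positive_floats, min_size=2, max_size=10),
           st.floats(min_value=1e-3, max_value=1e4))
    def test_scale_invariance(self, values, c):
        base = per_batch_cv(values)
        scaled = per_batch_cv([c * v for v in values])
        assert scaled == pytest.approx(base, abs=1e-6, rel=1e-6)


class TestMethodCvSummary:
    def test_mean_and_sd_of_batch_cvs(self):
        rows = []
        # three batches whose replicate CVs are exactly 2, 3 and 4%
        for batch, cv in [("b1", 2.0), ("b2", 3.0), ("b3", 4.0)]:
            sd = cv  # mean 100 so sd% equals sd
            for rep, v in enumerate([100 - sd, 100, 100 + sd], start=1):
                rows.append((batch, "NCFM", "Plate", rep, v))
        table = make_table(rows)
        s = method_cv_summary(table, "Plate")
        assert s.mean_cv_pct == pytest.approx(3.0)
        assert s.sd_cv_pct == pytest.approx(1.0)
        assert s.n_batches == 3

    def test_strain_strata(self):
        rows = [("b1", "NCFM", "Plate", r, v) for r, v in enumerate([90, 100, 110], 1)]
        rows += [("b2", "Bl-04", "Plate", r, v) for r, v in enumerate([99, 100, 101], 1)]
        table = make_table(rows)
        all_s = method_cv_summary(table, "Plate", "All")
        ncfm = method_cv_summary(table, "Plate", "NCFM")
        non = method_cv_summary(table, "Plate", "Non-NCFM")
        assert all_s.n_batches == 2
        assert ncfm.n_batches == 1 and non.n_batches == 1
        assert ncfm.mean_cv_pct > non.mean_cv_pct


class TestBatchMeans:
    def test_mean_of_replicates(self):
        table = make_table([("b1", "NCFM", "Plate", 1, 100),
                            ("b1", "NCFM", "Plate", 2, 120)])
        assert batch_means(table, "Plate")["b1"] == pytest.approx(110.0)

    def test_single_value_passes_through(self):
        table = make_table([("b1", "NCFM", "PCR.live", 1, 42.0)])
        assert batch_means(table, "PCR.live")["b1"] == 42.0


class TestPearson:
    def test_perfect_linear_relation(self):
        x = [1, 2, 3, 4]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_perfect_inverse_relation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_constant_vector_flagged(self):
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))

    @given(st.floats(min_value=0.1, max_value=10),
           st.floats(min_value=-5, max_value=5))
    def test_invariance_under_positive_affine_transform(self, a, b):
        x = [1.0, 2.0, 4.0, 8.0]
        y = [2.0, 3.0, 5.0, 11.0]
        assert pearson([a * v + b for v in x], y) == pytest.approx(pearson(x, y))


class TestRegression:
    def test_identity_line(self):
        slope, intercept = regress_identity([1, 2, 3], [1, 2, 3])
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_half_slope(self):
        slope, _ = regress_identity([2, 4, 6], [1, 2, 3])
        assert slope == pytest.approx(0.5)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regress_identity([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_methods_agree_perfectly(self):
        pa = bland_altman([1, 2, 3], [1, 2, 3])
        assert pa.mean_rel_diff_pct == 0.0
        assert pa.loa_low_pct == pa.loa_high_pct == 0.0

    def test_hand_computed_example(self):
        # pairs (100,120), (80,80), (90,110): d = (-200/11, 0, -20)%
        d = np.array([-200 / 11, 0.0, -20.0])
        mean_d = d.mean()
        sd_d = d.std(ddof=1)
        pa = bland_altman([100, 80, 90], [120, 80, 110])
        assert pa.mean_rel_diff_pct == pytest.approx(mean_d, abs=1e-4)
        assert pa.loa_low_pct == pytest.approx(mean_d - 1.96 * sd_d, abs=1e-4)
        assert pa.loa_high_pct == pytest.approx(mean_d + 1.96 * sd_d, abs=1e-4)

    @given(st.lists(st.tuples(positive_floats, positive_floats),
                    min_size=3, max_size=30))
    def test_antisymmetry_under_argument_swap(self, pairs):
        x = [p[0] for p in pairs]
        y = [p[1] for p in pairs]
        assume(len(set(x)) > 1 and len(set(y)) > 1)
        ab = bland_altman(x, y)
        ba = bland_altman(y, x)
        assert ab.mean_rel_diff_pct == pytest.approx(-ba.mean_rel_diff_pct, abs=1e-9)
        assert ab.loa_low_pct == pytest.approx(-ba.loa_high_pct, abs=1e-9)
        assert ab.loa_high_pct == pytest.approx(-ba.loa_low_pct, abs=1e-9)

    @given(st.lists(st.tuples(st.floats(min_value=0, max_value=1e9),
                              st.floats(min_value=0, max_value=1e9)),
                    min_size=1, max_size=30))
    def test_relative_differences_bounded(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        d = relative_differences(x, y)
        assert np.all(d >= -200.0) and np.all(d <= 200.0)

    def test_loa_contains_95pct_of_normal_differences(self):
        rng = np.random.default_rng(31)
        n = 20_000
        base = rng.uniform(100, 200, size=n)
        # relative offsets ~ N(0.02, 0.05) on a shared scale
        y = base * (1 + rng.normal(0.02, 0.05, size=n))
        pa = bland_altman(base, y)
        d = relative_differences(np.asarray(base), np.asarray(y))
        frac = np.mean((d >= pa.loa_low_pct) & (d <= pa.loa_high_pct))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_zero_average_pairs_excluded(self):
        pa = bland_altman([0, 1, 2, 3], [0, 1, 2, 3])
        assert pa.n_pairs == 3


class TestCompareTable:
    def test_two_identical_methods(self):
        rows = []
        for i, v in enumerate([100.0, 150.0, 210.0, 320.0], start=1):
            for method in ("Plate", "PCR.live"):
                for rep in (1, 2):
                    rows.append((f"b{i}", "NCFM", method, rep, v))
        summaries, agreements = compare_table(make_table(rows))
        pa = agreements[0]
        assert pa.pearson_r == pytest.approx(1.0)
        assert pa.mean_rel_diff_pct == 0.0
        assert pa.slope == pytest.approx(1.0)

    def test_missing_batches_dropped_pairwise(self):
        rows = [(f"b{i}", "NCFM", "Plate", 1, 100.0 + i) for i in range(5)]
        rows += [(f"b{i}", "NCFM", "PCR.live", 1, 110.0 + 2 * i) for i in range(4)]
        rows += [("b9", "NCFM", "PCR.live", 1, float("nan"))]
        summaries, agreements = compare_table(make_table(rows))
        assert agreements[0].n_pairs == 4
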