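"""Poisson occupancy quantification of droplet digital PCR wells."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from probenum import (
    BatchTruth,
    DilutionChain,
    DropletWellRecord,
    NoiseModel,
    estimate_ci,
    fit_efficiency,
    merge_wells,
    quantify_well,
    simulate_ddpcr_wells,
)
from probenum.ddpcr import ARM_LIVE


def well(pos, acc=10_000, dilution=1.0, vd=8.5e-4, arm=ARM_LIVE):
    return DropletWellRecord("b1", "w1", arm, acc, pos, dilution, vd)


class TestQuantifyWell:
    def test_zero_positive_droplets_give_zero_concentration(self):
        est = quantify_well(well(0, acc=20_000))
        assert est.copies_per_droplet == 0.0
        assert est.count_per_g == 0.0
        assert est.ci_low == 0.0
        assert not est.saturated

    def test_half_positive_matches_closed_form_occupancy(self):
        # p = 0.5 -> lambda = ln 2; 0.693147 / 8.5e-4 uL = 815.47 copies/uL
        est = quantify_well(well(5_000, acc=10_000))
        assert est.copies_per_droplet == pytest.approx(math.log(2), abs=1e-6)
        assert est.copies_per_ul_reaction == pytest.approx(815.47, abs=0.005)

    def test_monte_carlo_inversion_recovers_occupancy(self):
        # independent oracle: draw droplet occupancies directly from Poisson
        rng = np.random.default_rng(11)
        lam = 0.7
        n = 10_000_000
        positives = int((rng.poisson(lam, size=n) > 0).sum())
        est = quantify_well(well(positives, acc=n))
        assert est.copies_per_droplet == pytest.approx(lam, rel=2e-3)

    def test_saturated_well_is_censored_with_lower_bound_only(self):
        est = quantify_well(well(10_000, acc=10_000))
        assert est.saturated
        assert math.isnan(est.count_per_g)
        assert math.isinf(est.ci_high)
        assert est.ci_low > 0

    def test_zero_accepted_droplets_is_an_error(self):
        with pytest.raises(ValueError):
            quantify_well(well(0, acc=0))

    def test_low_droplet_wells_are_flagged_not_discarded(self):
        est = quantify_well(well(100, acc=5_000))
        assert est.below_min_droplets
        assert est.count_per_g > 0

    def test_dilution_chain_scales_count_per_gram(self):
        base = quantify_well(well(5_000, dilution=1.0))
        diluted = quantify_well(well(5_000, dilution=100.0))
        assert diluted.count_per_g == pytest.approx(100 * base.count_per_g)

    @given(st.integers(min_value=0, max_value=9_998))
    def test_count_strictly_increasing_in_positive_droplets(self, pos):
        lo = quantify_well(well(pos))
        hi = quantify_well(well(pos + 1))
        assert hi.count_per_g > lo.count_per_g

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            DropletWellRecord("b", "w", ARM_LIVE, 100, 101, 1.0)
        with pytest.raises(ValueError):
            DropletWellRecord("b", "w", ARM_LIVE, 100, 10, 0.5)


class TestMergeWells:
    def test_identical_wells_match_single_well_estimate(self):
        recs = [well(3_000), well(3_000), well(3_000)]
        merged = merge_wells(recs)
        single = quantify_well(recs[0])
        assert merged.count_per_g == pytest.approx(single.count_per_g)
        assert merged.wells_used == 3

    def test_pooling_definition(self):
        recs = [well(100), well(110), well(90)]
        merged = merge_wells(recs)
        pooled = quantify_well(well(300, acc=30_000))
        assert merged.count_per_g == pytest.approx(pooled.count_per_g)

    def test_mixed_dilution_factors_rejected(self):
        with pytest.raises(ValueError, match="dilution"):
            merge_wells([well(100, dilution=1.0), well(100, dilution=10.0)])

    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=2, max_size=5))
    def test_merging_conserves_droplet_totals(self, positives):
        recs = [well(p) for p in positives]
        merged = merge_wells(recs)
        # conservation: pooled totals equal sums of inputs
        pooled = quantify_well(
            well(sum(positives), acc=10_000 * len(positives)),
        )
        assert merged.copies_per_droplet == pytest.approx(pooled.copies_per_droplet)

    def test_pooled_vs_mean_of_wells_agree_at_small_occupancy(self):
        # small-lambda linearisation: -ln(1-p) ~ p, so pooling and averaging coincide
        truth = BatchTruth("b1", "NCFM", 1.2e5, 0.0)
        noise = NoiseModel(ddpcr_extra_rel_sd=0.0)
        chain = DilutionChain(ml_per_g=1.0)
        recs = simulate_ddpcr_wells(truth, ARM_LIVE, 1.0, 3, seed=3,
                                    noise=noise, chain=chain)
        merged = merge_wells(recs, chain=chain)
        per_well = np.mean([quantify_well(r, chain=chain).count_per_g for r in recs])
        assert merged.count_per_g == pytest.approx(per_well, rel=1e-4)


class TestConfidenceInterval:
    def test_zero_positives_give_zero_lower_bound(self):
        lo, hi = estimate_ci(well(0))
        assert lo == 0.0
        assert hi > 0

    def test_interval_narrows_with_more_droplets(self):
        lo1, hi1 = estimate_ci(well(1_000, acc=2_000))
        lo2, hi2 = estimate_ci(well(10_000, acc=20_000))
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_interval_brackets_point_estimate(self):
        est = quantify_well(well(4_000))
        assert est.ci_low <= est.count_per_g <= est.ci_high

    def test_small_scale_coverage(self):
        # quick sanity check; the full 500-replicate coverage study is in
        # the acceptance suite
        lam = 0.5
        chain = DilutionChain(ml_per_g=1.0)
        truth_count = chain.copies_per_ul_to_count_per_g(lam / 8.5e-4, 1.0)
        rng = np.random.default_rng(5)
        p = 1 - math.exp(-lam)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            pos = int(rng.binomial(20_000, p))
            est = quantify_well(well(pos, acc=20_000), chain=chain)
            hits += est.ci_low <= truth_count <= est.ci_high
        assert 0.90 <= hits / n_rep <= 0.99


class TestEfficiencyFit:
    def test_identity_series_gives_100_percent(self):
        series = [(1.0, 1000.0), (0.5, 500.0), (0.25, 250.0), (0.025, 25.0)]
        fit = fit_efficiency(series, reference=1000.0)
        assert fit.efficiency_pct == pytest.approx(100.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.within_limits

    def test_half_yield_flagged_outside_limits(self):
        series = [(1.0, 500.0), (0.5, 250.0), (0.25, 125.0)]
        fit = fit_efficiency(series, reference=1000.0)
        assert fit.efficiency_pct == pytest.approx(50.0)
        assert not fit.within_limits

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            fit_efficiency([(1.0, 1000.0), (0.5, 500.0)], reference=1000.0)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            fit_efficiency([(0.5, 1.0)] * 4, reference=0.0)

    def test_unbiased_partition_sampling_recovers_100_percent(self):
        # simulate a dilution series with partition sampling noise only
        rng = np.random.default_rng(17)
        vd, n = 8.5e-4, 20_000
        ref_lambda = 2.0
        series = []
        for frac in (1.0, 0.5, 0.25, 0.1, 0.05, 0.025):
            lam = ref_lambda * frac
            pos = int(rng.binomial(n, 1 - math.exp(-lam)))
            measured = -math.log1p(-pos / n) / vd
            series.append((frac, measured))
        fit = fit_efficiency(series, reference=ref_lambda / vd)
        assert fit.efficiency_pct == pytest.approx(100.0, abs=2.0)
        assert fit.r_squared > 0.999
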