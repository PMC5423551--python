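"""Wald ratios, IVW pooling, heterogeneity and per-SD rescaling."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from vitdmr.errors import (
    DesignError,
    HeterogeneityUndefinedError,
    ValidationError,
)
from vitdmr.mr_core import (
    Instrument,
    WaldRatio,
    heterogeneity,
    ivw_meta_studies,
    ivw_pool,
    per_sd_decrease,
    subset_analysis,
    two_sided_p,
    wald_ratio,
)
from vitdmr.summary_io import HarmonizedPair, SnpAssociation


def _pair(beta_y, se_y, rsid="rs10741657", scale="log_odds"):
    exposure = SnpAssociation(rsid, "C", beta=-0.05, se=0.012, scale="linear")
    outcome = SnpAssociation(rsid, "C", beta=beta_y, se=se_y, scale=scale)
    return HarmonizedPair(rsid, exposure, outcome, flipped=False)


def _instrument(beta_x, rsid="rs10741657", locus="CYP2R1", se_x=None):
    return Instrument(rsid=rsid, locus=locus, beta_x=beta_x,
                      effect_allele="C", se_x=se_x)


class TestWaldRatio:
    def test_asthma_cyp2r1_example(self):
        """beta_y = ln(0.99), se from the 0.97-1.01 CI, beta_x = -0.052."""
        se_y = (math.log(1.01) - math.log(0.97)) / (2 * 1.959963984540054)
        ratio = wald_ratio(_pair(math.log(0.99), se_y), _instrument(-0.052))
        assert ratio.estimate == pytest.approx(0.193276, abs=1e-5)
        assert ratio.se == pytest.approx(0.198245, abs=1e-5)

    def test_null_outcome_gives_exact_zero(self):
        ratio = wald_ratio(_pair(math.log(1.00), 0.028), _instrument(-0.047))
        assert ratio.estimate == 0.0

    def test_second_order_se_reduces_to_first_order_at_zero_se_x(self):
        first = wald_ratio(_pair(0.1, 0.05), _instrument(0.5, se_x=1e-12),
                           method="first_order")
        second = wald_ratio(_pair(0.1, 0.05), _instrument(0.5, se_x=1e-12),
                            method="second_order")
        assert second.se == pytest.approx(first.se, rel=1e-6)
        assert second.se >= first.se

    def test_second_order_requires_se_x(self):
        with pytest.raises(ValidationError):
            wald_ratio(_pair(0.1, 0.05), _instrument(0.5), method="second_order")

    def test_zero_exposure_effect_rejected_at_construction(self):
        with pytest.raises(ValidationError):
            _instrument(0.0)


class TestIvwPool:
    def test_single_ratio_is_identity(self):
        est, se = ivw_pool([WaldRatio("rs1", 0.19, 0.20)])
        assert (est, se) == (0.19, 0.20)

    def test_equal_ses_average_and_shrink_by_sqrt2(self):
        est, se = ivw_pool([WaldRatio("rs1", 0.0, 0.1),
                            WaldRatio("rs2", 0.2, 0.1)])
        assert est == pytest.approx(0.1)
        assert se == pytest.approx(0.1 / math.sqrt(2))

    def test_four_asthma_ratios_match_brute_force(self, harmonized, instruments):
        by_rsid = {p.rsid: p for p in harmonized["asthma"]}
        ratios = [wald_ratio(by_rsid[i.rsid], i) for i in instruments]
        est, se = ivw_pool(ratios)
        assert est == pytest.approx(-0.062345, abs=1e-5)
        assert se == pytest.approx(0.126875, abs=1e-5)

    def test_precise_study_dominates(self):
        merged = ivw_meta_studies(
            [(0.0, 0.01), (1.0, 10.0)],
            template=SnpAssociation("rs1", "A", beta=0.0, se=1.0))
        assert abs(merged.beta) < 1e-5
        assert merged.se == pytest.approx(0.01, rel=1e-4)

    def test_meta_of_identical_studies(self):
        merged = ivw_meta_studies(
            [(0.1, 0.05), (0.1, 0.05)],
            template=SnpAssociation("rs1", "A", beta=0.0, se=1.0))
        assert merged.beta == pytest.approx(0.1)
        assert merged.se == pytest.approx(0.05 / math.sqrt(2))

    def test_empty_pool_rejected(self):
        with pytest.raises(ValidationError):
            ivw_pool([])

    def test_wls_through_origin_oracle(self, harmonized, instruments):
        """IVW pooling equals WLS of beta_y on beta_x through the origin
        with weights 1/se_y^2."""
        by_rsid = {p.rsid: p for p in harmonized["asthma"]}
        bx = np.array([i.beta_x for i in instruments])
        by = np.array([by_rsid[i.rsid].outcome.beta for i in instruments])
        sy = np.array([by_rsid[i.rsid].outcome.se for i in instruments])
        slope = sm.WLS(by, bx, weights=1.0 / sy ** 2).fit().params[0]
        ratios = [wald_ratio(by_rsid[i.rsid], i) for i in instruments]
        assert ivw_pool(ratios)[0] == pytest.approx(slope, abs=1e-10)

    @given(scale=st.floats(-3.0, 3.0).filter(lambda c: abs(c) > 0.05))
    @settings(max_examples=50, derandomize=True)
    def test_scale_invariance_in_beta_x(self, scale, harmonized, instruments):
        """Rescaling every exposure effect by c divides the pooled per-unit
        estimate by c; the per-SD estimate with sigma scaled by |c| is fixed."""
        by_rsid = {p.rsid: p for p in harmonized["asthma"]}
        base = [wald_ratio(by_rsid[i.rsid], i) for i in instruments]
        scaled_ins = [Instrument(rsid=i.rsid, locus=i.locus,
                                 beta_x=i.beta_x * scale,
                                 effect_allele=i.effect_allele)
                      for i in instruments]
        scaled = [wald_ratio(by_rsid[i.rsid], i) for i in scaled_ins]
        est0, _ = ivw_pool(base)
        est1, se1 = ivw_pool(scaled)
        assert est1 == pytest.approx(est0 / scale, rel=1e-9)
        sd0 = per_sd_decrease(ivw_pool(base), sigma=0.47)
        sd1 = per_sd_decrease((est1 * math.copysign(1, scale), se1),
                              sigma=0.47 * abs(scale))
        assert sd1.estimate_per_sd_decrease == pytest.approx(
            sd0.estimate_per_sd_decrease, rel=1e-9)


class TestHeterogeneity:
    def test_identical_estimates_have_zero_q(self):
        ratios = [WaldRatio("rs1", 0.5, 0.1), WaldRatio("rs2", 0.5, 0.2)]
        q, i2, ci = heterogeneity(ratios, 0.5)
        assert q == 0.0 and i2 == 0.0
        assert ci[0] == 0.0 and 0.0 <= ci[1] < 1.0

    def test_two_point_hand_computation(self):
        """Estimates 0 and 2 with unit SEs: mean 1, Q = 1 + 1 = 2, I2 = 0.5."""
        ratios = [WaldRatio("rs1", 0.0, 1.0), WaldRatio("rs2", 2.0, 1.0)]
        pooled, _ = ivw_pool(ratios)
        q, i2, ci = heterogeneity(ratios, pooled)
        assert q == pytest.approx(2.0)
        assert i2 == pytest.approx(0.5)
        assert 0.0 <= ci[0] <= 0.5 <= ci[1] < 1.0

    def test_asthma_i2_from_rounded_inputs(self, harmonized, instruments):
        by_rsid = {p.rsid: p for p in harmonized["asthma"]}
        ratios = [wald_ratio(by_rsid[i.rsid], i) for i in instruments]
        pooled, _ = ivw_pool(ratios)
        q, i2, _ = heterogeneity(ratios, pooled)
        assert i2 == pytest.approx(0.187, abs=0.001)

    def test_single_instrument_undefined(self):
        with pytest.raises(HeterogeneityUndefinedError):
            heterogeneity([WaldRatio("rs1", 0.1, 0.1)], 0.1)

    @given(perm=st.permutations(range(4)))
    @settings(max_examples=24, derandomize=True)
    def test_q_invariant_under_permutation(self, perm):
        ratios = [WaldRatio(f"rs{i}", e, s) for i, (e, s) in
                  enumerate([(0.1, 0.2), (-0.3, 0.1), (0.05, 0.4), (0.2, 0.15)])]
        pooled, _ = ivw_pool(ratios)
        q0, _, _ = heterogeneity(ratios, pooled)
        shuffled = [ratios[i] for i in perm]
        q1, _, _ = heterogeneity(shuffled, pooled)
        assert q1 == pytest.approx(q0, rel=1e-12)


class TestPerSdRescaling:
    def test_asthma_per_sd_or(self):
        est = per_sd_decrease((-0.062345, 0.126872), sigma=0.47)
        assert round(est.odds_ratio, 2) == 1.03

    def test_null_maps_to_null(self):
        est = per_sd_decrease((0.0, 0.5), sigma=0.47)
        assert est.odds_ratio == 1.0
        assert est.ci_lower == pytest.approx(-est.ci_upper)
        assert est.p == pytest.approx(1.0)

    def test_ige_linear_rescaling(self):
        est = per_sd_decrease((0.832540, 1.188846), sigma=0.47, or_scale=False)
        assert est.estimate_per_sd_decrease == pytest.approx(-0.391, abs=1e-3)

    def test_decrease_and_increase_are_mirror_images(self):
        pooled = (-0.062345, 0.126872)
        dec = per_sd_decrease(pooled, sigma=0.47)
        inc = per_sd_decrease((-pooled[0], pooled[1]), sigma=0.47)
        assert inc.estimate_per_sd_decrease == pytest.approx(
            -dec.estimate_per_sd_decrease)
        assert inc.p == pytest.approx(dec.p)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            per_sd_decrease((0.1, 0.1), sigma=0.0)


class TestTwoSidedP:
    @pytest.mark.parametrize("est, se, expected, tol", [
        (0.0, 1.0, 1.0, 1e-12),
        (1.959963984540054, 1.0, 0.05, 1e-10),
        (-0.062345, 0.126872, 0.623, 1e-3),
    ])
    def test_values(self, est, se, expected, tol):
        assert two_sided_p(est, se) == pytest.approx(expected, abs=tol)

    def test_requires_positive_se(self):
        with pytest.raises(ValueError):
            two_sided_p(1.0, 0.0)


class TestSubsets:
    def test_all_equals_unrestricted(self, harmonized, instruments):
        full = subset_analysis(harmonized["asthma"], instruments, "all",
                               outcome="asthma")
        assert full.k == 4
        assert round(full.odds_ratio, 2) == 1.03

    def test_pathway_subsets_partition_instruments(self, harmonized, instruments):
        synth = subset_analysis(harmonized["asthma"], instruments, "synthesis_only")
        metab = subset_analysis(harmonized["asthma"], instruments, "metabolism_only")
        assert synth.k == 2 and metab.k == 2

    def test_unknown_subset_named_in_error(self, harmonized, instruments):
        with pytest.raises(LookupError, match="no_such"):
            subset_analysis(harmonized["asthma"], instruments, "no_such")

    def test_empty_subset_rejected(self, harmonized, instruments):
        synthesis_only = [i for i in instruments if i.pathway == "synthesis"]
        with pytest.raises(DesignError, match="metabolism_only"):
            subset_analysis(harmonized["asthma"], synthesis_only,
                            "metabolism_only")
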