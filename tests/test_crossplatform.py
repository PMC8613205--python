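"""Cross-platform consistency: LD, predicted power, decision tree, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xpqtl import crossplatform, pipeline, synthetic
from xpqtl.types import (
    ConsistencyCall,
    PairedTarget,
    PqtlSignal,
    Region,
)


class TestLdR2:
    def test_identical_vectors(self):
        x = np.array([0.0, 1, 2, 1, 0, 2])
        assert crossplatform.ld_r2(x, x) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([0.0, 1, 2, 1, 0, 2])
        assert crossplatform.ld_r2(x, 2 - x) == pytest.approx(1.0)

    def test_monomorphic_is_nan(self):
        assert np.isnan(crossplatform.ld_r2(np.zeros(5), np.arange(5.0)))

    def test_independent_large_sample_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, 20000).astype(float)
        b = rng.binomial(2, 0.4, 20000).astype(float)
        assert crossplatform.ld_r2(a, b) < 0.001


class TestPredictedP:
    def test_same_n_is_identity(self):
        p_obs = 2 * stats.norm.sf(abs(0.5 / 0.05))
        assert crossplatform.predicted_p(0.5, 0.05, 500, 500) == \
            pytest.approx(p_obs)

    def test_worked_example(self):
        # beta 0.5, se 0.05 at n=10708 rescaled to n=485:
        # se_t = 0.05*sqrt(10708/485) ~ 0.2349, z ~ 2.128, p ~ 0.0333
        p = crossplatform.predicted_p(0.5, 0.05, 10708, 485)
        assert p == pytest.approx(0.0333, abs=2e-4)

    def test_se_scales_with_sqrt_ratio(self):
        p_half = crossplatform.predicted_p(1.0, 0.1, 1000, 500)
        z = 1.0 / (0.1 * np.sqrt(2.0))
        assert p_half == pytest.approx(2 * stats.norm.sf(z))

    def test_monotone_decreasing_in_n_target(self):
        ps = [crossplatform.predicted_p(0.3, 0.05, 10000, n)
              for n in (100, 500, 2000, 10000)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


def _signal(vid, pos, beta, se, p, platform="A_aptamer", rank=1,
            ea="A", oa="G"):
    region = Region("chr1", max(0, pos - 500_000), pos + 500_000, lead=vid,
                    members=(vid,))
    row = pd.Series(dict(variant_id=vid, chrom="chr1", pos=pos,
                         effect_allele=ea, other_allele=oa, eaf=0.3,
                         beta=beta, se=se, p=p, n=1000))
    return PqtlSignal("prot", platform, region, vid, row, cis=True,
                      conditional_rank=rank)


class TestClassifySharedUnits:
    """Direct unit checks on the decision-tree branches."""

    def _genotypes(self, corr="high", seed=0):
        rng = np.random.default_rng(seed)
        a = rng.binomial(2, 0.4, 3000).astype(float)
        if corr == "high":
            b = a.copy()
        else:
            b = rng.binomial(2, 0.4, 3000).astype(float)
        from xpqtl.types import GenotypeMatrix

        meta = pd.DataFrame({
            "variant_id": ["vA", "vB"], "chrom": "chr1",
            "pos": [1_000_000, 1_100_000], "effect_allele": "A",
            "other_allele": "G", "eaf": 0.4, "role": "null",
        })
        return GenotypeMatrix(np.column_stack([a, b]), meta)

    def test_underpowered_when_predicted_p_weak(self):
        pair = PairedTarget("prot", [_signal("vA", 1_000_000, 0.05, 0.04, 1e-9)])
        call = crossplatform.classify_shared(pair, self._genotypes())
        assert call.category == "underpowered"
        assert call.predicted_p >= 1e-5

    def test_shared_when_leads_in_ld_and_concordant(self):
        pair = PairedTarget(
            "prot",
            [_signal("vA", 1_000_000, 0.7, 0.02, 1e-100)],
            [_signal("vB", 1_100_000, 0.6, 0.1, 1e-8, platform="B_antibody")],
        )
        call = crossplatform.classify_shared(pair, self._genotypes("high"))
        assert call.category == "shared"
        assert call.proxy_r2 > 0.99
        assert call.sign_concordant

    def test_discordant_signs_called_distinct(self):
        pair = PairedTarget(
            "prot",
            [_signal("vA", 1_000_000, 0.7, 0.02, 1e-100)],
            [_signal("vB", 1_100_000, -0.6, 0.1, 1e-8, platform="B_antibody")],
        )
        call = crossplatform.classify_shared(pair, self._genotypes("high"))
        assert call.category == "distinct_signals"
        assert call.sign_concordant is False

    def test_flipped_alleles_harmonised_before_sign_test(self):
        pair = PairedTarget(
            "prot",
            [_signal("vA", 1_000_000, 0.7, 0.02, 1e-100, ea="A", oa="G")],
            [_signal("vB", 1_100_000, -0.6, 0.1, 1e-8, platform="B_antibody",
                     ea="G", oa="A")],
        )
        call = crossplatform.classify_shared(pair, self._genotypes("high"))
        assert call.category == "shared"

    def test_unlinked_leads_called_distinct(self):
        pair = PairedTarget(
            "prot",
            [_signal("vA", 1_000_000, 0.7, 0.02, 1e-100)],
            [_signal("vB", 1_100_000, 0.6, 0.1, 1e-8, platform="B_antibody")],
        )
        call = crossplatform.classify_shared(pair, self._genotypes("low"))
        assert call.category == "distinct_signals"
        assert call.proxy_r2 < 0.6

    def test_one_sided_with_supportive_lookup_is_shared(self):
        pair = PairedTarget("prot", [_signal("vA", 1_000_000, 0.7, 0.02, 1e-100)])
        lookup = pd.DataFrame([dict(
            variant_id="vA", chrom="chr1", pos=1_000_000, effect_allele="A",
            other_allele="G", eaf=0.4, beta=0.5, se=0.08, p=1e-7, n=485,
        )])
        call = crossplatform.classify_shared(
            pair, self._genotypes(), sumstats_B=lookup
        )
        assert call.category == "shared"

    def test_one_sided_without_support_is_specific(self):
        pair = PairedTarget("prot", [_signal("vA", 1_000_000, 0.7, 0.02, 1e-100)])
        lookup = pd.DataFrame([dict(
            variant_id="vA", chrom="chr1", pos=1_000_000, effect_allele="A",
            other_allele="G", eaf=0.4, beta=0.01, se=0.08, p=0.9, n=485,
        )])
        call = crossplatform.classify_shared(
            pair, self._genotypes(), sumstats_B=lookup
        )
        assert call.category == "specific_A"

    def test_b_only_signal_routes_to_specific_b(self):
        pair = PairedTarget(
            "prot", [],
            [_signal("vB", 1_100_000, 0.6, 0.1, 1e-8, platform="B_antibody")],
        )
        call = crossplatform.classify_shared(pair, self._genotypes())
        assert call.category == "specific_B"

    def test_no_signals_rejected(self):
        with pytest.raises(ValueError):
            crossplatform.classify_shared(
                PairedTarget("prot"), self._genotypes()
            )


class TestClassifySharedEndToEnd:
    """Scenario generator -> full pipeline -> expected category."""

    @pytest.mark.parametrize(
        "scenario,expected",
        [
            ("shared-pqtl", "shared"),
            ("epitope-a-only", {"specific_A", "shared"}),
            ("distinct-signals", "distinct_signals"),
        ],
    )
    def test_scenario_truths(self, scenario, expected):
        hits = 0
        for seed in range(5):
            cohort = synthetic.simulate_cohort(
                scenario, 2000, 485, seed=100 + seed, technical=False
            )
            call, _, _ = pipeline.evaluate_pair(cohort, normalise=False)
            assert call is not None
            want = expected if isinstance(expected, set) else {expected}
            hits += call.category in want
        assert hits >= 4


class TestInteraction:
    def test_null_interaction_not_significant(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.3, 485).astype(float)
        true = rng.standard_normal(485)
        soma = true + 0.3 * rng.standard_normal(485)
        olink = true + 0.3 * rng.standard_normal(485)
        out = crossplatform.genotype_interaction_test(olink, soma, dosage)
        assert out["interaction_p"] > 0.01
        assert out["spearman_overall"] > 0.8

    def test_planted_interaction_detected(self):
        olink, soma, dosage = synthetic.simulate_measurement_pair(
            n=485, interaction_effect=0.5, seed=3
        )
        out = crossplatform.genotype_interaction_test(olink, soma, dosage)
        assert out["interaction_p"] < 0.01

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.4, 200).astype(float)
        soma = rng.standard_normal(200)
        olink = soma + 0.2 * soma * dosage + rng.standard_normal(200)
        out = crossplatform.genotype_interaction_test(olink, soma, dosage)
        X = sm.add_constant(np.column_stack([soma, dosage, soma * dosage]))
        fit = sm.OLS(olink, X).fit()
        assert out["interaction_beta"] == pytest.approx(fit.params[3], abs=1e-10)
        assert out["interaction_se"] == pytest.approx(fit.bse[3], abs=1e-10)
        assert out["interaction_p"] == pytest.approx(fit.pvalues[3], rel=1e-8)

    def test_small_strata_reported_nan(self):
        rng = np.random.default_rng(5)
        dosage = np.concatenate([np.zeros(50), np.ones(50), np.full(3, 2.0)])
        soma = rng.standard_normal(103)
        olink = soma + 0.1 * rng.standard_normal(103)
        out = crossplatform.genotype_interaction_test(
            olink, soma, dosage, min_stratum=10
        )
        assert np.isnan(out["spearman_by_genotype"][2.0])
        assert not np.isnan(out["spearman_by_genotype"][0.0])

    def test_single_genotype_class_rejected(self):
        with pytest.raises(ValueError):
            crossplatform.genotype_interaction_test(
                np.arange(10.0), np.arange(10.0), np.zeros(10)
            )


class TestBhFdr:
    def test_hand_worked_example(self):
        # q=0.2, m=4: sorted p vs (k/4)*0.2 -> 0.01<0.05, 0.02<0.10,
        # 0.20>0.15 but 0.90>0.20; largest k passing is k=2, reject first two
        mask = crossplatform.bh_fdr(np.array([0.01, 0.02, 0.20, 0.90]), q=0.2)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_step_up_rescues_smaller_p(self):
        # q=0.05, m=3: thresholds 0.0167/0.0333/0.05. 0.02 fails its own rank
        # but the step-up from k=3 (0.04 <= 0.05) rejects all three.
        mask = crossplatform.bh_fdr(np.array([0.02, 0.03, 0.04]), q=0.05)
        np.testing.assert_array_equal(mask, [True, True, True])

    def test_all_null_controls_fdr(self):
        rng = np.random.default_rng(6)
        rejections = [
            crossplatform.bh_fdr(rng.uniform(size=50), q=0.2).any()
            for _ in range(200)
        ]
        assert np.mean(rejections) < 0.35  # FWER under global null <= q

    def test_empty_and_invalid(self):
        assert crossplatform.bh_fdr(np.array([])).size == 0
        with pytest.raises(ValueError):
            crossplatform.bh_fdr(np.array([0.5, 1.5]))


class TestUniqueProteinCount:
    def test_duplicated_proteins_counted_once(self):
        table = pd.DataFrame({
            "measure": [f"m{i}" for i in range(6)],
            "protein": ["P1", "P2", "P2", "P3", "P3", "P3"],
        })
        assert crossplatform.unique_protein_count(table) == 3

    def test_panel_arithmetic(self):
        # 1104 measures where 35 proteins appear twice -> 1069 unique
        proteins = [f"P{i}" for i in range(1069)]
        measures = proteins + proteins[:35]
        table = pd.DataFrame({
            "measure": [f"m{i}" for i in range(1104)], "protein": measures,
        })
        assert len(table) == 1104
        assert crossplatform.unique_protein_count(table) == 1069
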