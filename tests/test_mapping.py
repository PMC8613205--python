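"""pQTL mapping: GWAS, meta-analysis, regions, cis/trans, conditional."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xpqtl import mapping, synthetic
from xpqtl.types import GenotypeMatrix

from conftest import variant_block


def _geno_from_array(arr, start=1_000_000, step=50_000, chrom="chr1"):
    arr = np.asarray(arr, dtype=float)
    meta = pd.DataFrame(
        {
            "variant_id": [f"{chrom}_v{j}" for j in range(arr.shape[1])],
            "chrom": chrom,
            "pos": [start + j * step for j in range(arr.shape[1])],
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": arr.mean(axis=0) / 2.0,
            "role": "null",
        }
    )
    return GenotypeMatrix(dosages=arr, variants=meta)


class TestGwasLinear:
    def test_perfect_fit(self):
        dos = np.array([0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
        g = _geno_from_array(dos.reshape(-1, 1))
        out = mapping.gwas_linear(dos.copy(), g)
        assert out["beta"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-12

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, size=(200, 4)).astype(float)
        y = rng.standard_normal(200)
        g = _geno_from_array(dos)
        out = mapping.gwas_linear(y, g)
        for j in range(4):
            x = dos[:, j]
            xc = x - x.mean()
            yc = y - y.mean()
            beta = (xc @ yc) / (xc @ xc)
            resid = yc - beta * xc
            se = np.sqrt((resid @ resid) / 198 / (xc @ xc))
            p = 2 * stats.t.sf(abs(beta / se), 198)
            assert out["beta"].iloc[j] == pytest.approx(beta, abs=1e-8)
            assert out["se"].iloc[j] == pytest.approx(se, abs=1e-8)
            assert out["p"].iloc[j] == pytest.approx(p, rel=1e-6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        dos = rng.binomial(2, 0.4, size=(400, 1000)).astype(float)
        y = rng.standard_normal(400)
        out = mapping.gwas_linear(y, _geno_from_array(dos, step=1000))
        assert stats.kstest(out["p"], "uniform").pvalue > 0.01

    def test_monomorphic_flagged_unusable(self):
        dos = np.column_stack([np.zeros(50), np.random.default_rng(2).integers(0, 3, 50)])
        out = mapping.gwas_linear(
            np.random.default_rng(3).standard_normal(50),
            _geno_from_array(dos),
        )
        assert not out["usable"].iloc[0]
        assert out["se"].iloc[0] == np.inf
        assert out["usable"].iloc[1]

    def test_missing_dosages_dropped_pairwise(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, size=(100, 1)).astype(float)
        dos[:10, 0] = np.nan
        y = rng.standard_normal(100)
        out = mapping.gwas_linear(y, _geno_from_array(dos))
        assert out["n"].iloc[0] == 90


class TestMetaFixed:
    def _stats(self, beta, se, ea="A", oa="G", vid="v1"):
        return pd.DataFrame(
            [dict(variant_id=vid, chrom="chr1", pos=100, effect_allele=ea,
                  other_allele=oa, eaf=0.3, beta=beta, se=se, p=0.5, n=100)]
        )

    def test_equal_weights(self):
        out = mapping.meta_fixed([self._stats(1.0, 1.0), self._stats(1.0, 1.0)])
        assert out["beta"].iloc[0] == pytest.approx(1.0)
        assert out["se"].iloc[0] == pytest.approx(1 / np.sqrt(2))

    def test_hand_computed_weights(self):
        out = mapping.meta_fixed([self._stats(0.5, 0.1), self._stats(0.9, 0.3)])
        w1, w2 = 100.0, 1 / 0.09
        assert out["beta"].iloc[0] == pytest.approx((0.5 * w1 + 0.9 * w2) / (w1 + w2))
        assert out["se"].iloc[0] == pytest.approx(1 / np.sqrt(w1 + w2), abs=1e-4)
        assert out["se"].iloc[0] == pytest.approx(0.0949, abs=1e-4)

    def test_single_subset_identity(self):
        s = self._stats(0.7, 0.2)
        out = mapping.meta_fixed([s])
        assert out["beta"].iloc[0] == pytest.approx(0.7)
        assert out["se"].iloc[0] == pytest.approx(0.2)

    def test_allele_flip_harmonised(self):
        out = mapping.meta_fixed(
            [self._stats(1.0, 1.0, "A", "G"), self._stats(-1.0, 1.0, "G", "A")]
        )
        assert out["beta"].iloc[0] == pytest.approx(1.0)

    def test_irreconcilable_alleles_dropped(self):
        out = mapping.meta_fixed(
            [self._stats(1.0, 1.0, "A", "G"), self._stats(1.0, 1.0, "C", "T")]
        )
        assert out.empty
        assert any("irreconcilable" in d for d in out.attrs["dropped"])

    def test_partition_approximates_pooled(self):
        rng = np.random.default_rng(5)
        for rep in range(10):
            dos = rng.binomial(2, 0.3, size=(1500, 1)).astype(float)
            y = 0.2 * dos[:, 0] + rng.standard_normal(1500)
            g = _geno_from_array(dos)
            pooled = mapping.gwas_linear(y, g)
            parts = []
            for sl in (slice(0, 500), slice(500, 1000), slice(1000, 1500)):
                sub = GenotypeMatrix(
                    dosages=dos[sl], variants=g.variants.copy()
                )
                parts.append(mapping.gwas_linear(y[sl], sub))
            meta = mapping.meta_fixed(parts)
            assert abs(meta["beta"].iloc[0] - pooled["beta"].iloc[0]) < \
                3 * pooled["se"].iloc[0]


class TestThresholdsAndRegions:
    def test_reagent_bonferroni_thresholds(self):
        assert mapping.significance_threshold(4979) == pytest.approx(
            1.004e-11, rel=5e-4
        )
        assert mapping.significance_threshold(1104) == pytest.approx(
            4.5e-11, rel=1e-2
        )
        assert mapping.significance_threshold(1) == 5e-8

    def _sig(self, rows):
        return pd.DataFrame(
            [dict(variant_id=f"v{i}", chrom=c, pos=p, effect_allele="A",
                  other_allele="G", eaf=0.3, beta=1.0, se=0.1, p=pv, n=100)
             for i, (c, p, pv) in enumerate(rows)]
        )

    def test_overlapping_intervals_merge(self):
        regs = mapping.define_regions(
            self._sig([("chr1", 1_000_000, 1e-12), ("chr1", 1_800_000, 1e-10)])
        )
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (500_000, 2_300_000)
        assert regs[0].lead == "v0"

    def test_distant_variants_stay_separate(self):
        regs = mapping.define_regions(
            self._sig([("chr1", 1_000_000, 1e-12), ("chr1", 2_200_001, 1e-10)])
        )
        assert len(regs) == 2

    def test_mhc_collapsed_to_fixed_window(self):
        regs = mapping.define_regions(
            self._sig([("chr6", 30_000_000, 1e-12)])
        )
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (25_500_000, 34_000_000)
        assert regs[0].is_mhc

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_order_invariant_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        rows = [("chr" + str(rng.integers(1, 3)),
                 int(rng.integers(1, 10) * 400_000),
                 float(rng.uniform(1e-15, 1e-9))) for _ in range(6)]
        sig = self._sig(rows)
        a = mapping.define_regions(sig)
        b = mapping.define_regions(sig.sample(frac=1, random_state=1))
        assert [(r.chrom, r.start, r.end, r.lead) for r in a] == \
            [(r.chrom, r.start, r.end, r.lead) for r in b]
        # idempotence: regions of the leads reproduce containing windows
        for r in a:
            assert r.start <= r.end

    def test_cis_trans_boundaries(self):
        gene = ("chr1", 1_000_000, 1_050_000)
        assert mapping.classify_cis_trans("chr1", 1_020_000, gene) == "cis"
        assert mapping.classify_cis_trans("chr1", 1_000_000 - 499_999, gene) == "cis"
        assert mapping.classify_cis_trans("chr1", 1_000_000 - 500_001, gene) == "trans"
        assert mapping.classify_cis_trans("chr2", 1_020_000, gene) == "trans"
        assert mapping.classify_cis_trans("chr1", 1_020_000, None) == "trans"


class TestConditionalSignals:
    def test_single_causal_recovers_marginal(self):
        g = synthetic.simulate_genotypes(
            3000, variant_block(10, step=20_000), ld_rho=0.3, seed=6
        )
        y = 0.5 * g.column("chr1_v4") + np.random.default_rng(7).standard_normal(3000)
        res = mapping.conditional_signals(g, y)
        assert res.selected == ["chr1_v4"]
        marg = mapping.gwas_linear(y, g).set_index("variant_id")
        joint_beta = res.joint_stats.set_index("variant_id").loc["chr1_v4", "beta"]
        assert joint_beta == pytest.approx(marg.loc["chr1_v4", "beta"], rel=1e-9)

    def test_two_unlinked_causals_both_recovered(self):
        g = synthetic.simulate_genotypes(
            4000, variant_block(10, step=20_000), ld_rho=0.0, seed=8
        )
        rng = np.random.default_rng(9)
        y = (0.4 * g.column("chr1_v2") + 0.3 * g.column("chr1_v7")
             + rng.standard_normal(4000))
        res = mapping.conditional_signals(g, y)
        assert set(res.selected) == {"chr1_v2", "chr1_v7"}
        js = res.joint_stats.set_index("variant_id")
        # joint betas match an exhaustive two-variant fit
        X = np.column_stack(
            [np.ones(4000), g.column("chr1_v2"), g.column("chr1_v7")]
        )
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert js.loc["chr1_v2", "beta"] == pytest.approx(oracle[1], abs=1e-9)
        assert js.loc["chr1_v7", "beta"] == pytest.approx(oracle[2], abs=1e-9)
        for vid, true_beta in [("chr1_v2", 0.4), ("chr1_v7", 0.3)]:
            assert abs(js.loc[vid, "beta"] - true_beta) < 2 * js.loc[vid, "se"]

    def test_null_region_empty(self):
        g = synthetic.simulate_genotypes(500, variant_block(5), 0.2, seed=10)
        y = np.random.default_rng(11).standard_normal(500)
        res = mapping.conditional_signals(g, y)
        assert res.selected == []

    def test_duplicate_variants_never_both_selected(self):
        rng = np.random.default_rng(12)
        col = rng.binomial(2, 0.4, size=2000).astype(float)
        dos = np.column_stack([col, col.copy(), rng.binomial(2, 0.4, 2000)])
        g = _geno_from_array(dos)
        y = 0.6 * col + rng.standard_normal(2000)
        res = mapping.conditional_signals(g, y)
        assert len({s for s in res.selected} & {"chr1_v0", "chr1_v1"}) <= 1


class TestBetaRecovery:
    def test_unbiased_over_effect_grid(self):
        # parameter recovery across a grid of true effect sizes
        rng = np.random.default_rng(13)
        errors = []
        for i, beta_true in enumerate(np.linspace(0.1, 1.0, 40)):
            dos = rng.binomial(2, 0.3, size=(2000, 1)).astype(float)
            y = beta_true * dos[:, 0] + rng.standard_normal(2000)
            out = mapping.gwas_linear(y, _geno_from_array(dos))
            errors.append(out["beta"].iloc[0] - beta_true)
        errors = np.asarray(errors)
        mc_se = errors.std(ddof=1) / np.sqrt(len(errors))
        assert abs(errors.mean()) < 2 * mc_se + 1e-3
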