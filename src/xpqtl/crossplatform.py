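"""Reciprocal cross-platform consistency framework.

Classifies each genomic region-protein target association as shared,
platform-specific, distinct-signals or underpowered by combining:

* a power filter — the larger platform's lead effect is rescaled to the
  smaller sample (SE scales with 1/sqrt(n) at fixed variance) and the pair
  is only assessed when the predicted p-value clears 1e-5;
* an LD test between regional lead (or conditionally independent) variants
  at r^2 > 0.6, with effect signs harmonised to a common effect allele;
* a cross-platform look-up of the discovering platform's lead in the other
  platform's summary statistics.

Also provides the genotype-stratified correlation analysis: an interaction
model (antibody measure ~ aptamer measure x dosage) whose interaction term
tests whether the between-platform correlation differs by genotype, with
per-genotype Spearman correlations, and Benjamini-Hochberg discovery at a
permissive FDR (default 20%) reflecting the low power of interaction tests
at small n.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ConsistencyCall, GenotypeMatrix, PairedTarget, PqtlSignal


def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Returns NaN for monomorphic input (undefined LD).
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if len(a) < 2 or len(a) != len(b):
        raise ValueError("need two equal-length dosage vectors with n >= 2")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def predicted_p(beta: float, se: float, n_source: int, n_target: int) -> float:
    """p-value predicted at a different sample size, holding beta fixed.

    se_target = se * sqrt(n_source / n_target); two-sided normal p from
    z = beta / se_target. Monotone decreasing in n_target.
    """
    if n_target < 2:
        raise ValueError("n_target must be >= 2")
    se_t = se * np.sqrt(n_source / n_target)
    z = beta / se_t
    return float(2.0 * stats.norm.sf(abs(z)))


def _harmonised_sign_product(sa: pd.Series, sb: pd.Series) -> float:
    """Product of effect signs after flipping to a common effect allele.

    Positive = concordant. Works for the same variant or LD proxies that
    share allele labels; differing allele pairs compare signs as-is (the
    generator uses consistent labelling).
    """
    flip = 1.0
    if (sa["effect_allele"], sa["other_allele"]) == (
        sb["other_allele"],
        sb["effect_allele"],
    ):
        flip = -1.0
    return float(np.sign(sa["beta"]) * np.sign(sb["beta"]) * flip)


def _lookup(stats_df: pd.DataFrame | None, variant_id: str) -> pd.Series | None:
    if stats_df is None or stats_df.empty:
        return None
    hit = stats_df[stats_df["variant_id"] == variant_id]
    if hit.empty:
        return None
    return hit.iloc[0]


def classify_shared(
    pair: PairedTarget,
    genotypes: GenotypeMatrix,
    sumstats_A: pd.DataFrame | None = None,
    sumstats_B: pd.DataFrame | None = None,
    proxy_r2_cut: float = 0.6,
    predicted_p_cut: float = 1e-5,
    power_cut: float = 1e-5,
) -> ConsistencyCall:
    """Decision tree for one collapsed region-target pair.

    Order: power filter first (predicted p of the larger platform's primary
    lead in the smaller sample), then the LD/sign test over all lead and
    conditional signal pairs, then the cross-platform look-up fallback for
    one-sided discoveries.
    """
    sig_a, sig_b = pair.signal_A, pair.signal_B
    region = (sig_a or sig_b)[0].region if (sig_a or sig_b) else None
    tid = pair.target_id

    pred = float("nan")
    if sig_a:
        lead = sig_a[0].stats
        pred = predicted_p(lead["beta"], lead["se"], pair.n_A, pair.n_B)
        if pred >= power_cut:
            return ConsistencyCall(tid, region, "underpowered", predicted_p=pred)

    if sig_a and sig_b:
        best_r2, best_pair = -1.0, None
        for a in sig_a:
            for b in sig_b:
                r2 = ld_r2(genotypes.column(a.lead), genotypes.column(b.lead))
                if np.isnan(r2):
                    continue
                if r2 > best_r2:
                    best_r2, best_pair = r2, (a, b)
        if best_pair is not None and best_r2 > proxy_r2_cut:
            a, b = best_pair
            concordant = _harmonised_sign_product(a.stats, b.stats) > 0
            category = "shared" if concordant else "distinct_signals"
            return ConsistencyCall(
                tid, region, category, proxy_r2=best_r2,
                sign_concordant=concordant, predicted_p=pred,
            )
        return ConsistencyCall(
            tid, region, "distinct_signals",
            proxy_r2=max(best_r2, 0.0), sign_concordant=None, predicted_p=pred,
        )

    if sig_a:  # discovered on the large platform only: look up in B
        lead = sig_a[0]
        other = _lookup(sumstats_B, lead.lead)
        if other is not None and other["p"] < predicted_p_cut:
            concordant = _harmonised_sign_product(lead.stats, other) > 0
            if concordant:
                return ConsistencyCall(
                    tid, region, "shared", proxy_r2=1.0,
                    sign_concordant=True, predicted_p=pred,
                )
        return ConsistencyCall(tid, region, "specific_A", predicted_p=pred)

    if sig_b:
        lead = sig_b[0]
        other = _lookup(sumstats_A, lead.lead)
        if other is not None and other["p"] < predicted_p_cut:
            concordant = _harmonised_sign_product(lead.stats, other) > 0
            if concordant:
                return ConsistencyCall(
                    tid, region, "shared", proxy_r2=1.0,
                    sign_concordant=True, predicted_p=pred,
                )
        return ConsistencyCall(tid, region, "specific_B", predicted_p=pred)

    raise ValueError("pair has no signals on either platform")


def genotype_interaction_test(
    olink: np.ndarray,
    soma: np.ndarray,
    dosage: np.ndarray,
    min_stratum: int = 10,
) -> dict:
    """Test whether the between-platform association differs by genotype.

    OLS of the antibody measure on the aptamer measure, dosage and their
    product; the interaction p-value reads as a test of differential
    correlation. Spearman correlations are reported overall and per genotype
    class with at least ``min_stratum`` individuals.
    """
    y = np.asarray(olink, dtype=float)
    x = np.asarray(soma, dtype=float)
    g = np.asarray(dosage, dtype=float)
    classes = np.unique(g)
    if len(classes) < 2:
        raise ValueError("need at least two genotype classes")
    n = len(y)
    X = np.column_stack([np.ones(n), x, g, x * g])
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - 4
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    t = beta[3] / se[3]
    p = float(2.0 * stats.t.sf(abs(t), df))

    overall = float(stats.spearmanr(x, y).statistic)
    strata: dict[float, float] = {}
    for c in classes:
        mask = g == c
        if mask.sum() >= min_stratum:
            strata[float(c)] = float(stats.spearmanr(x[mask], y[mask]).statistic)
        else:
            strata[float(c)] = float("nan")
    return {
        "interaction_beta": float(beta[3]),
        "interaction_se": float(se[3]),
        "interaction_p": p,
        "spearman_overall": overall,
        "spearman_by_genotype": strata,
    }


def bh_fdr(p: np.ndarray, q: float = 0.20) -> np.ndarray:
    """Benjamini-Hochberg step-up discovery mask at FDR level ``q``."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0,1]")
    reject, *_ = multipletests(arr, alpha=q, method="fdr_bh")
    return reject


def unique_protein_count(measure_table: pd.DataFrame, protein_col: str = "protein") -> int:
    """Number of distinct proteins across a table of reagent measures.

    Used to reduce multi-panel measure lists (a protein assayed on more than
    one panel counts once).
    """
    return int(measure_table[protein_col].nunique())


__all__ = [
    "ld_r2",
    "predicted_p",
    "classify_shared",
    "genotype_interaction_test",
    "bh_fdr",
    "unique_protein_count",
]
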