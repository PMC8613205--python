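"""Colocalisation of protein and phenotype signals, and network assembly.

Implements the single-causal-variant Bayesian colocalisation framework on
GWAS summary statistics: per-variant Wakefield approximate Bayes factors
under a normal effect-size prior, five-hypothesis posteriors (no signal,
trait-1 only, trait-2 only, two distinct causal variants, one shared causal
variant) with per-variant priors p1, p2 and a conservative shared prior p12
(default 1e-6), all evaluated in log space for numerical stability.

The screen pairs each protein cis region showing at least suggestive
evidence (p < 1e-6) with every phenotype showing suggestive regional
evidence, retains pairs with PP4 above 0.8 whose regional lead variants are
in strong LD (r^2 > 0.8), reruns on lead-conditioned protein statistics
where a secondary signal exists, and assembles the resulting edges into a
genetically anchored protein-phenotype network with per-edge direction
(phenotype sign aligned to the protein-increasing allele) and a
cross-platform consistency class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .crossplatform import ld_r2
from .types import ColocResult, GenotypeMatrix, NetworkEdge, SUMSTATS_COLUMNS

DEFAULT_W_QUANT = 0.15
DEFAULT_W_BINARY = 0.2
DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-6


def wakefield_abf(beta: float | np.ndarray, se: float | np.ndarray,
                  prior_sd: float = DEFAULT_W_QUANT) -> np.ndarray:
    """Log approximate Bayes factor for a single-variant association.

    lABF = 0.5 * [ln(se^2/(se^2+W^2)) + z^2 * W^2/(se^2+W^2)] with
    z = beta/se and effect-size prior sd W. W = 0 gives lABF = 0.
    """
    b = np.asarray(beta, dtype=float)
    s = np.asarray(se, dtype=float)
    if np.any(s <= 0):
        raise ValueError("se must be > 0")
    if prior_sd < 0:
        raise ValueError("prior sd must be >= 0")
    if prior_sd == 0:
        return np.zeros_like(b)
    v = s * s
    w2 = prior_sd * prior_sd
    z2 = (b / s) ** 2
    shrink = w2 / (v + w2)
    return 0.5 * (np.log(v / (v + w2)) + z2 * shrink)


def coloc_posteriors(
    labf_1: np.ndarray,
    labf_2: np.ndarray,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> np.ndarray:
    """Five-hypothesis posteriors PP0..PP4 from per-variant log ABFs.

    Unnormalised weights (1, p1*S1, p2*S2, p1*p2*(S1*S2 - S12), p12*S12)
    with S1 = sum(e^lABF1), S2 = sum(e^lABF2), S12 = sum(e^(lABF1+lABF2)),
    computed via log-sum-exp. The cross term is the sum over distinct
    variant pairs; it is clamped at -inf when numerically non-positive
    (degenerate single-variant regions).
    """
    a = np.asarray(labf_1, dtype=float)
    b = np.asarray(labf_2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traits must cover identical variant sets")
    l1 = logsumexp(a)
    l2 = logsumexp(b)
    l12 = logsumexp(a + b)
    # log(S1*S2 - S12) = l1 + l2 + log(1 - exp(l12 - l1 - l2))
    delta = l12 - (l1 + l2)
    if delta >= 0:
        lcross = -np.inf
    else:
        lcross = l1 + l2 + np.log1p(-np.exp(delta))
    logw = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + lcross,
            np.log(p12) + l12,
        ]
    )
    return np.exp(logw - logsumexp(logw))


def conditional_sumstats(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    lead: str,
) -> pd.DataFrame:
    """Per-variant association statistics conditioned on a lead variant.

    For every remaining variant the trait is regressed on that variant plus
    the lead as covariate; the variant's own conditional beta/se/p are
    reported. The lead must be polymorphic.
    """
    y = np.asarray(trait, dtype=float)
    g_lead = genotypes.column(lead)
    if g_lead.std() == 0:
        raise ValueError(f"lead variant {lead!r} is monomorphic")
    meta = genotypes.variants
    rows = []
    n = len(y)
    for j, vid in enumerate(meta["variant_id"]):
        if vid == lead:
            continue
        g = genotypes.dosages[:, j]
        X = np.column_stack([np.ones(n), g, g_lead])
        if np.linalg.matrix_rank(X) < 3:  # variant collinear with the lead
            continue
        XtX = X.T @ X
        beta = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta
        df = n - 3
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * np.linalg.inv(XtX)
        se = float(np.sqrt(cov[1, 1]))
        t = beta[1] / se
        row = meta.iloc[j]
        rows.append(
            dict(
                variant_id=vid, chrom=row["chrom"], pos=int(row["pos"]),
                effect_allele=row["effect_allele"], other_allele=row["other_allele"],
                eaf=float(np.mean(g) / 2.0), beta=float(beta[1]), se=se,
                p=float(2.0 * stats.t.sf(abs(t), df)), n=n,
            )
        )
    return pd.DataFrame(rows, columns=SUMSTATS_COLUMNS)


def _lead_variant(stats_df: pd.DataFrame) -> pd.Series:
    return stats_df.sort_values(["p", "pos"]).iloc[0]


def coloc_region(
    protein_stats: pd.DataFrame,
    pheno_stats: pd.DataFrame,
    genotypes: GenotypeMatrix,
    target_id: str,
    platform: str,
    phenotype_id: str,
    prior_sd: float = DEFAULT_W_QUANT,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    conditioned_on: str | None = None,
) -> ColocResult:
    """Colocalise one protein-phenotype pair over a common variant set."""
    merged = protein_stats.merge(
        pheno_stats, on="variant_id", suffixes=("_prot", "_phe")
    )
    if merged.empty:
        raise ValueError("no common variants between traits")
    la = wakefield_abf(merged["beta_prot"].to_numpy(), merged["se_prot"].to_numpy(),
                       prior_sd)
    lb = wakefield_abf(merged["beta_phe"].to_numpy(), merged["se_phe"].to_numpy(),
                       prior_sd)
    pp = coloc_posteriors(la, lb, p1=p1, p2=p2, p12=p12)
    lead_prot = _lead_variant(protein_stats)
    lead_phe = _lead_variant(pheno_stats)
    r2 = ld_r2(
        genotypes.column(lead_prot["variant_id"]),
        genotypes.column(lead_phe["variant_id"]),
    )
    # direction: phenotype sign at the protein lead, aligned to the
    # protein-increasing allele
    phe_at_lead = pheno_stats[pheno_stats["variant_id"] == lead_prot["variant_id"]]
    if phe_at_lead.empty:
        direction = 0
    else:
        direction = int(
            np.sign(lead_prot["beta"]) * np.sign(phe_at_lead.iloc[0]["beta"])
        )
    return ColocResult(
        target_id=target_id, platform=platform, phenotype_id=phenotype_id,
        pp=pp, lead_protein=lead_prot["variant_id"],
        lead_phenotype=lead_phe["variant_id"],
        lead_r2=float(r2) if not np.isnan(r2) else float("nan"),
        direction=direction, conditioned_on=conditioned_on,
    )


def coloc_screen(
    protein_stats: dict[str, pd.DataFrame],
    phenotype_stats: dict[str, pd.DataFrame],
    genotypes: GenotypeMatrix,
    target_id: str,
    suggestive_p: float = 1e-6,
    pp_cut: float = 0.8,
    lead_r2_cut: float = 0.8,
    secondary_p: float = 5e-8,
    protein_traits: dict[str, np.ndarray] | None = None,
    prior_sd: float = DEFAULT_W_QUANT,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
) -> list[ColocResult]:
    """Phenome screen for one protein cis region.

    ``protein_stats`` maps platform -> regional summary statistics;
    ``phenotype_stats`` maps phenotype id -> regional summary statistics.
    Platforms without suggestive evidence, or phenotypes without a
    suggestive regional variant, are skipped. Retained results require
    PP4 > ``pp_cut`` and lead-variant LD r^2 > ``lead_r2_cut``. Where a
    secondary protein signal exists (conditional p < ``secondary_p``) and
    individual-level protein scores are supplied via ``protein_traits``,
    the screen is repeated on lead-conditioned statistics.
    """
    out: list[ColocResult] = []
    for platform, pstats in protein_stats.items():
        if pstats.empty or pstats["p"].min() >= suggestive_p:
            continue
        lead = _lead_variant(pstats)["variant_id"]
        for phe_id, phstats in phenotype_stats.items():
            if phstats.empty or phstats["p"].min() >= suggestive_p:
                continue
            res = coloc_region(
                pstats, phstats, genotypes, target_id, platform, phe_id,
                prior_sd=prior_sd, p1=p1, p2=p2, p12=p12,
            )
            if res.pp4 > pp_cut and res.lead_r2 > lead_r2_cut:
                out.append(res)
        # secondary-signal rerun on conditional statistics
        if protein_traits is not None and platform in protein_traits:
            cond = conditional_sumstats(genotypes, protein_traits[platform], lead)
            if not cond.empty and cond["p"].min() < secondary_p:
                for phe_id, phstats in phenotype_stats.items():
                    if phstats.empty or phstats["p"].min() >= suggestive_p:
                        continue
                    common = phstats[phstats["variant_id"].isin(cond["variant_id"])]
                    res = coloc_region(
                        cond, common, genotypes, target_id, platform, phe_id,
                        prior_sd=prior_sd, p1=p1, p2=p2, p12=p12,
                        conditioned_on=lead,
                    )
                    if res.pp4 > pp_cut and res.lead_r2 > lead_r2_cut:
                        out.append(res)
    return out


def build_network(results: list[ColocResult]) -> list[NetworkEdge]:
    """Collapse colocalisation results into protein-phenotype edges.

    One edge per pair; the consistency class is "consistent" when both
    platforms are present with the same direction, "opposing" when both are
    present with discordant directions, and platform-specific otherwise.
    Output ordering is deterministic (protein, then phenotype).
    """
    grouped: dict[tuple[str, str], dict[str, int]] = {}
    for r in results:
        key = (r.target_id, r.phenotype_id)
        grouped.setdefault(key, {})
        # keep the first (unconditioned preferred) direction per platform
        if r.platform not in grouped[key] or r.conditioned_on is None:
            grouped[key][r.platform] = r.direction
    edges = []
    for (prot, phe), dirs in sorted(grouped.items()):
        platforms = tuple(sorted(dirs))
        vals = [dirs[p] for p in platforms]
        if len(platforms) == 2:
            consistency = "consistent" if vals[0] == vals[1] else "opposing"
            direction = vals[0] if vals[0] == vals[1] else 0
        else:
            consistency = f"specific_{platforms[0][0].upper()}" \
                if platforms[0][0].lower() in "ab" else f"specific_{platforms[0]}"
            direction = vals[0]
        edges.append(
            NetworkEdge(
                protein=prot, phenotype=phe, platforms=platforms,
                direction=direction, consistency=consistency,
            )
        )
    return edges


__all__ = [
    "wakefield_abf",
    "coloc_posteriors",
    "conditional_sumstats",
    "coloc_region",
    "coloc_screen",
    "build_network",
    "DEFAULT_W_QUANT",
    "DEFAULT_W_BINARY",
    "DEFAULT_P1",
    "DEFAULT_P2",
    "DEFAULT_P12",
]
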