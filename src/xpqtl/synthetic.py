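"""Synthetic two-platform proteogenomic cohort generator.

Emulates the data structure of a large plasma-proteomics cohort measured on
an aptamer-based platform (A) with a small nested subsample additionally
measured on an antibody-based platform (B): LD-structured hard-call
genotypes, a latent (true) protein abundance with cis/trans genetic effects,
platform-specific epitope artifacts that shift the *measured* signal per
allele without touching the latent abundance, per-sample multiplicative
technical scale factors organised in dilution bins, buffer (blank) samples,
below-floor censoring, and quantitative phenotypes driven either by protein
abundance or directly by a proteoform allele.

All measurement effects are additive on the natural-log scale; intensities
are exponentiated before the technical layer so raw values stay positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    DILUTION_BINS,
    PLATFORM_A,
    PLATFORM_B,
    AssayMatrix,
    CohortBundle,
    EffectSpec,
    GenotypeMatrix,
    VariantSpec,
)

# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _latent_rho_for_allele_corr(target: float, af1: float, af2: float) -> float:
    """Latent-Gaussian correlation giving allele-level correlation ``target``.

    Haplotype alleles are indicators {z < Phi^-1(af)}; their correlation under
    a bivariate normal with correlation rho is
    (Phi2(t1, t2; rho) - af1*af2) / sqrt(af1 q1 af2 q2).  Solved by bisection.
    """
    if target == 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(af1), stats.norm.ppf(af2)
    denom = np.sqrt(af1 * (1 - af1) * af2 * (1 - af2))

    def allele_corr(rho: float) -> float:
        cdf = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
        ).cdf([t1, t2])
        return (cdf - af1 * af2) / denom

    lo, hi = 0.0, 1.0 - 1e-9
    # allele correlation is monotone increasing in rho
    from scipy.optimize import brentq

    f = lambda r: allele_corr(r) - target
    if f(hi) < 0:  # target unreachable for very different AFs; use max
        return hi
    return float(brentq(f, lo, hi, xtol=1e-6))


def _validate_variants(variants: list[VariantSpec]) -> None:
    by_chrom: dict[str, int] = {}
    for v in variants:
        if not 0.0 < v.effect_allele_freq < 1.0:
            raise ValueError(
                f"variant {v.variant_id}: effect allele frequency "
                f"{v.effect_allele_freq} outside (0,1)"
            )
        last = by_chrom.get(v.chrom)
        if last is not None and v.pos <= last:
            raise ValueError(
                f"variant {v.variant_id}: positions must be strictly "
                f"increasing within chromosome {v.chrom}"
            )
        by_chrom[v.chrom] = v.pos


def simulate_genotypes(
    n_individuals: int,
    variants: list[VariantSpec],
    ld_rho: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate hard-call dosages from two AR-1 latent haplotypes.

    Each haplotype is an AR-1 latent Gaussian across the variants of a
    chromosome, thresholded at the allele-frequency quantile; the latent
    autocorrelation is calibrated so the *allele-level* correlation between
    adjacent variants matches ``ld_rho``. Dosage = sum of the two haplotype
    alleles, giving values in {0,1,2} with exact marginal frequency.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError(f"ld_rho must be in [0,1), got {ld_rho}")
    _validate_variants(variants)

    rng = np.random.default_rng(seed)
    m = len(variants)
    afs = np.array([v.effect_allele_freq for v in variants])
    thresholds = stats.norm.ppf(afs)

    # latent AR-1 coefficients between adjacent variants (0 at chrom breaks)
    rhos = np.zeros(m)
    cache: dict[tuple[float, float], float] = {}
    for j in range(1, m):
        if variants[j].chrom != variants[j - 1].chrom or ld_rho == 0.0:
            continue
        key = (round(afs[j - 1], 6), round(afs[j], 6))
        if key not in cache:
            cache[key] = _latent_rho_for_allele_corr(ld_rho, *key)
        rhos[j] = cache[key]

    dosage = np.zeros((n_individuals, m), dtype=float)
    for _hap in range(2):
        z = np.empty((n_individuals, m))
        eps = rng.standard_normal((n_individuals, m))
        z[:, 0] = eps[:, 0]
        for j in range(1, m):
            r = rhos[j]
            z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j]
        dosage += (z < thresholds).astype(float)

    meta = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "other_allele": [v.other_allele for v in variants],
            "eaf": afs,
            "role": [v.role for v in variants],
        }
    )
    return GenotypeMatrix(dosages=dosage, variants=meta)


# ---------------------------------------------------------------------------
# protein pair and phenotype
# ---------------------------------------------------------------------------


def simulate_protein_pair(
    genotypes: GenotypeMatrix,
    effects: list[EffectSpec],
    noise_sd_A: float = 0.3,
    noise_sd_B: float = 0.3,
    corr_bio: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent abundance plus platform-specific measurements (log scale).

    true = sum(beta_true * G) + shared biological noise (variance
    ``corr_bio``); measured_A = true + sum(epitope_shift_A * G) + platform
    noise (sd ``noise_sd_A``), analogously for B. Epitope shifts act on the
    measurements only. Returns (raw_A, raw_B, true_abundance) as log-scale
    vectors.
    """
    ids = set(genotypes.variants["variant_id"])
    missing = [e.variant_id for e in effects if e.variant_id not in ids]
    if missing:
        raise ValueError(f"effect variants missing from genotypes: {missing}")

    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    true = np.zeros(n)
    shift_a = np.zeros(n)
    shift_b = np.zeros(n)
    for e in effects:
        g = genotypes.column(e.variant_id)
        true += e.beta_true * g
        shift_a += e.epitope_shift_A * g
        shift_b += e.epitope_shift_B * g
    true = true + np.sqrt(corr_bio) * rng.standard_normal(n)
    raw_a = true + shift_a + noise_sd_A * rng.standard_normal(n)
    raw_b = true + shift_b + noise_sd_B * rng.standard_normal(n)
    return raw_a, raw_b, true


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    true_abundance: np.ndarray,
    mode: str = "abundance",
    effect_size: float = 0.5,
    noise_sd: float = 1.0,
    seed: int = 0,
    proteoform_variant: str | None = None,
) -> np.ndarray:
    """Quantitative phenotype driven by abundance or by a proteoform allele.

    In abundance mode the phenotype loads on the latent abundance; in
    proteoform mode it loads on the allele count of the designated proteoform
    variant and is conditionally independent of abundance given genotype.
    """
    if mode not in ("abundance", "proteoform"):
        raise ValueError(f"unknown phenotype mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(true_abundance)
    noise = noise_sd * rng.standard_normal(n)
    if mode == "abundance":
        return effect_size * np.asarray(true_abundance) + noise
    if proteoform_variant is None:
        roles = genotypes.variants
        hits = roles.loc[roles["role"] == "proteoform", "variant_id"].tolist()
        if not hits:
            raise ValueError("proteoform mode requires a designated proteoform variant")
        proteoform_variant = hits[0]
    g = genotypes.column(proteoform_variant)
    return effect_size * g + noise


# ---------------------------------------------------------------------------
# technical layer
# ---------------------------------------------------------------------------


def apply_technical_layer(
    raw: np.ndarray | pd.DataFrame,
    scale_sd: float = 0.1,
    n_blanks: int = 24,
    dilution_bins: dict[str, str] | None = None,
    floor: float = 20.0,
    seed: int = 0,
    platform: str = PLATFORM_A,
    blank_sd: float = 0.25,
) -> tuple[AssayMatrix, AssayMatrix, pd.DataFrame]:
    """Exponentiate log-scale signals and add technical structure.

    Each test sample gets one lognormal multiplicative factor per dilution
    bin (sd ``scale_sd`` on the log scale) applied to all analytes of that
    bin; blank (buffer) samples are drawn as low-intensity lognormal noise
    around ``floor``; any value below ``floor`` is censored at ``floor``.

    Returns (test AssayMatrix, blank AssayMatrix, truth scale-factor table).
    """
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if isinstance(raw, np.ndarray):
        arr = raw.reshape(-1, 1) if raw.ndim == 1 else raw
        raw = pd.DataFrame(arr, columns=[f"analyte{j}" for j in range(arr.shape[1])])
    if dilution_bins is None:
        dilution_bins = {a: DILUTION_BINS[0] for a in raw.columns}
    if not dilution_bins:
        raise ValueError("dilution bin map must not be empty")
    missing = [a for a in raw.columns if a not in dilution_bins]
    if missing:
        raise ValueError(f"analytes without a dilution bin: {missing}")

    rng = np.random.default_rng(seed)
    n, m = raw.shape
    bins = sorted(set(dilution_bins[a] for a in raw.columns))
    factors = pd.DataFrame(
        np.exp(scale_sd * rng.standard_normal((n, len(bins)))),
        columns=bins,
    )
    intens = np.exp(raw.to_numpy(dtype=float))
    for j, a in enumerate(raw.columns):
        intens[:, j] *= factors[dilution_bins[a]].to_numpy()
    intens = np.maximum(intens, floor)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    test = AssayMatrix(
        values=pd.DataFrame(intens, index=sample_ids, columns=raw.columns),
        platform=platform,
        sample_type=pd.Series("test", index=sample_ids),
        dilution_bin=dict(dilution_bins),
    )

    blank_ids = [f"BLANK{i:03d}" for i in range(n_blanks)]
    blank_vals = floor * np.exp(blank_sd * rng.standard_normal((n_blanks, m)))
    blank_vals = np.maximum(blank_vals, floor * 0.5)
    blanks = AssayMatrix(
        values=pd.DataFrame(blank_vals, index=blank_ids, columns=raw.columns),
        platform=platform,
        sample_type=pd.Series("blank", index=blank_ids),
        dilution_bin=dict(dilution_bins),
    )
    factors.index = sample_ids
    return test, blanks, factors


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class ScenarioConfig:
    """One named simulation scenario: variants, effects and noise levels."""

    name: str
    variants: list[VariantSpec]
    effects: list[EffectSpec]
    noise_sd_A: float = 0.3
    noise_sd_B: float = 0.3
    corr_bio: float = 0.5
    ld_rho: float = 0.4
    phenotype_mode: str = "abundance"
    phenotype_effect: float = 0.3
    phenotype_noise_sd: float = 1.0
    scale_sd: float = 0.1
    n_blanks: int = 24
    floor: float = 20.0
    extra: dict = field(default_factory=dict)


def _region_variants(
    n_null: int = 18,
    chrom: str = "chr1",
    start: int = 1_000_000,
    step: int = 20_000,
    causal: dict[int, tuple[str, float]] | None = None,
) -> list[VariantSpec]:
    """A block of variants on one chromosome; ``causal`` maps index ->
    (role, eaf)."""
    causal = causal or {}
    rng = np.random.default_rng(12345)  # fixed layout; cohorts vary via seed
    out = []
    for j in range(n_null):
        role, eaf = causal.get(j, ("null", float(rng.uniform(0.1, 0.5))))
        out.append(
            VariantSpec(
                variant_id=f"{chrom}_v{j}",
                chrom=chrom,
                pos=start + j * step,
                effect_allele_freq=eaf,
                role=role,
            )
        )
    return out


def scenario(name: str) -> ScenarioConfig:
    """Return one of the five shipped scenarios.

    shared-pqtl: one cis variant drives true abundance -> same signal on
    both platforms.  epitope-a-only / epitope-b-only: a binding artifact on
    one platform, no true genetic effect.  distinct-signals: two unlinked
    causal variants, one affecting each platform's measurement.
    proteoform-phenotype: phenotype driven by the allele itself, protein
    abundance uninformative.
    """
    tid = "target1"
    if name == "shared-pqtl":
        variants = _region_variants(causal={8: ("cis_abundance", 0.3)})
        effects = [EffectSpec(tid, "chr1_v8", beta_true=0.7)]
        return ScenarioConfig(name, variants, effects)
    if name == "epitope-a-only":
        variants = _region_variants(causal={8: ("epitope_A", 0.3)})
        effects = [EffectSpec(tid, "chr1_v8", epitope_shift_A=-0.8)]
        return ScenarioConfig(name, variants, effects)
    if name == "epitope-b-only":
        variants = _region_variants(causal={8: ("epitope_B", 0.3)})
        effects = [EffectSpec(tid, "chr1_v8", epitope_shift_B=-0.8)]
        return ScenarioConfig(name, variants, effects)
    if name == "distinct-signals":
        variants = _region_variants(
            causal={4: ("epitope_A", 0.3), 13: ("epitope_B", 0.35)}
        )
        effects = [
            EffectSpec(tid, "chr1_v4", epitope_shift_A=-0.8),
            EffectSpec(tid, "chr1_v13", epitope_shift_B=-0.8),
        ]
        # unlinked causal variants: keep background LD low
        return ScenarioConfig(name, variants, effects, ld_rho=0.1)
    if name == "proteoform-phenotype":
        variants = _region_variants(
            causal={6: ("cis_abundance", 0.3), 11: ("proteoform", 0.25)}
        )
        effects = [EffectSpec(tid, "chr1_v6", beta_true=0.7)]
        return ScenarioConfig(
            name,
            variants,
            effects,
            phenotype_mode="proteoform",
            phenotype_effect=0.4,
        )
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = (
    "shared-pqtl",
    "epitope-a-only",
    "epitope-b-only",
    "distinct-signals",
    "proteoform-phenotype",
)


def simulate_cohort(
    config: ScenarioConfig | str,
    n_individuals: int = 2000,
    n_subsample: int = 485,
    seed: int = 0,
    technical: bool = True,
    n_background: int = 40,
) -> CohortBundle:
    """Generate a full cohort bundle for one scenario.

    Platform A is measured on everyone and passed through the technical
    layer (scale factors, blanks, floor censoring on the raw intensity
    scale); platform B is measured on a fixed uniformly drawn nested
    subsample and delivered as log-scale scores (NPX-like). With
    ``technical=False`` platform A is also left on the log scale.
    """
    if isinstance(config, str):
        config = scenario(config)
    if n_subsample > n_individuals:
        raise ValueError("subsample cannot exceed the full sample")
    rng = np.random.default_rng(seed)
    gseed, pseed, phseed, tseed, cseed = rng.integers(0, 2**31 - 1, size=5)

    geno = simulate_genotypes(n_individuals, config.variants, config.ld_rho, gseed)
    raw_a, raw_b, true = simulate_protein_pair(
        geno,
        config.effects,
        noise_sd_A=config.noise_sd_A,
        noise_sd_B=config.noise_sd_B,
        corr_bio=config.corr_bio,
        seed=pseed,
    )

    # mild demographic structure so covariate adjustment has work to do
    crng = np.random.default_rng(cseed)
    age = crng.uniform(30, 65, n_individuals)
    sex = crng.integers(0, 2, n_individuals).astype(float)
    covariates = pd.DataFrame({"age": age, "sex": sex})
    raw_a = raw_a + 0.004 * (age - age.mean()) + 0.05 * (sex - sex.mean())
    raw_b = raw_b + 0.004 * (age - age.mean()) + 0.05 * (sex - sex.mean())

    pheno = simulate_phenotype(
        geno,
        true,
        mode=config.phenotype_mode,
        effect_size=config.phenotype_effect,
        noise_sd=config.phenotype_noise_sd,
        seed=phseed,
    )
    phenotypes = pd.DataFrame({"pheno1": pheno})

    subsample = np.sort(
        np.random.default_rng(seed + 1).choice(
            n_individuals, size=n_subsample, replace=False
        )
    )

    target = config.effects[0].target_id if config.effects else "target1"
    baseline = 7.0  # log-intensity offset keeping raw signals above the floor
    if technical:
        # background null analytes give the per-sample/per-bin scale-factor
        # estimator something to take a median over, as on the real platform
        brng = np.random.default_rng(seed + 2)
        raw_df = pd.DataFrame({target: raw_a + baseline})
        bins = {target: DILUTION_BINS[0]}
        for j in range(n_background):
            raw_df[f"bg{j:03d}"] = baseline + 0.3 * brng.standard_normal(
                n_individuals
            )
            bins[f"bg{j:03d}"] = DILUTION_BINS[j % len(DILUTION_BINS)]
        assay_a, blanks_a, factors = apply_technical_layer(
            raw_df,
            scale_sd=config.scale_sd,
            n_blanks=config.n_blanks,
            dilution_bins=bins,
            floor=config.floor,
            seed=tseed,
            platform=PLATFORM_A,
        )
    else:
        ids = [f"S{i:05d}" for i in range(n_individuals)]
        assay_a = AssayMatrix(
            values=pd.DataFrame({target: raw_a}, index=ids),
            platform=PLATFORM_A,
            sample_type=pd.Series("test", index=ids),
            dilution_bin={target: DILUTION_BINS[0]},
        )
        blank_ids = [f"BLANK{i:03d}" for i in range(config.n_blanks)]
        blanks_a = AssayMatrix(
            values=pd.DataFrame(
                config.floor * np.ones((config.n_blanks, 1)),
                index=blank_ids,
                columns=[target],
            ),
            platform=PLATFORM_A,
            sample_type=pd.Series("blank", index=blank_ids),
            dilution_bin={target: DILUTION_BINS[0]},
        )
        factors = pd.DataFrame(
            {DILUTION_BINS[0]: np.ones(n_individuals)},
            index=ids,
        )

    sub_ids = [f"S{i:05d}" for i in subsample]
    assay_b = AssayMatrix(
        values=pd.DataFrame({target: raw_b[subsample]}, index=sub_ids),
        platform=PLATFORM_B,
        sample_type=pd.Series("test", index=sub_ids),
        dilution_bin={target: DILUTION_BINS[0]},
    )

    truth = {
        "effects": pd.DataFrame([e.__dict__ for e in config.effects]),
        "scale_factors": factors,
        "true_abundance": np.asarray(true),
        "scenario": config.name,
        "phenotype_mode": config.phenotype_mode,
    }
    return CohortBundle(
        genotypes=geno,
        assay_A=assay_a,
        assay_B=assay_b,
        blanks_A=blanks_a,
        phenotypes=phenotypes,
        truth=truth,
        covariates=covariates,
        subsample_index=subsample,
    )


def simulate_measurement_pair(
    n: int = 485,
    interaction_effect: float = 0.0,
    eaf: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired platform measurements with optional genotype-dependent scaling.

    Shared biology ``true ~ N(0,1)``; the aptamer-like measure is scaled by
    (1 + interaction_effect * dosage) before its platform noise while the
    antibody-like measure is not, so ``interaction_effect != 0`` makes the
    between-platform correlation differ by genotype class (the null model
    has no such dependence). Returns (olink-like, soma-like, dosage).
    """
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, eaf, size=n).astype(float)
    true = rng.standard_normal(n)
    soma = true * (1.0 + interaction_effect * g) + noise_sd * rng.standard_normal(n)
    olink = true + noise_sd * rng.standard_normal(n)
    return olink, soma, g


__all__ = [
    "simulate_genotypes",
    "simulate_protein_pair",
    "simulate_phenotype",
    "apply_technical_layer",
    "simulate_measurement_pair",
    "ScenarioConfig",
    "scenario",
    "SCENARIOS",
    "simulate_cohort",
]
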