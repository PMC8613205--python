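"""Shared domain containers for the cross-platform pQTL pipeline.

Conventions used throughout:

* genomic coordinates are 1-based inclusive in memory (BED files are
  converted at the I/O boundary);
* genotype dosages are hard calls in {0, 1, 2} counting copies of the
  effect allele;
* summary statistics live in pandas DataFrames with the column schema
  :data:`SUMSTATS_COLUMNS`;
* assay intensities are strictly positive on the raw scale and are
  log-transformed before any statistical modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# roles a simulated variant can play
VARIANT_ROLES = (
    "null",
    "cis_abundance",
    "trans_abundance",
    "epitope_A",
    "epitope_B",
    "proteoform",
)

PLATFORM_A = "A_aptamer"
PLATFORM_B = "B_antibody"

DILUTION_BINS = ("bin20", "bin0.5", "bin0.005")

#: column schema for per-variant association results (one trait)
SUMSTATS_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
]


@dataclass(frozen=True)
class VariantSpec:
    """A simulated bi-allelic variant and the causal role it plays."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele_freq: float
    role: str = "null"
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self) -> None:
        if not 0.0 < self.effect_allele_freq < 1.0:
            raise ValueError(
                f"variant {self.variant_id}: effect_allele_freq must be in (0,1), "
                f"got {self.effect_allele_freq}"
            )
        if self.role not in VARIANT_ROLES:
            raise ValueError(
                f"variant {self.variant_id}: unknown role {self.role!r}"
            )


@dataclass(frozen=True)
class EffectSpec:
    """Per-variant causal effects on a protein target and phenotype.

    ``beta_true`` acts on the latent (true) abundance; the epitope shifts act
    only on the *measured* level of the respective platform, never on the
    latent abundance or the phenotype. ``phenotype_beta`` is interpreted per
    unit of abundance (abundance mode) or per effect allele (proteoform mode).
    """

    target_id: str
    variant_id: str
    beta_true: float = 0.0
    epitope_shift_A: float = 0.0
    epitope_shift_B: float = 0.0
    phenotype_beta: float = 0.0


@dataclass
class GenotypeMatrix:
    """Hard-call dosage matrix with variant metadata.

    ``dosages`` is samples x variants, values in {0,1,2} (float to allow NaN
    for missing calls). ``variants`` has one row per variant with columns
    variant_id, chrom, pos, effect_allele, other_allele, eaf, role.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant metadata does not match dosage columns")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:05d}" for i in range(self.dosages.shape[0])]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.index_of(variant_id)
        return self.dosages[:, idx]

    def index_of(self, variant_id: str) -> int:
        ids = self.variants["variant_id"].tolist()
        try:
            return ids.index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant id {variant_id!r}") from None

    def subset_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            dosages=self.dosages[index, :].copy(),
            variants=self.variants.copy(),
            sample_ids=[self.sample_ids[i] for i in index],
        )


@dataclass
class AssayMatrix:
    """Samples x analytes intensity matrix for one affinity platform.

    ``values`` is a DataFrame indexed by sample id with one column per
    analyte; raw intensities are strictly positive. ``sample_type`` maps each
    sample to "test" or "blank"; ``dilution_bin`` maps each analyte to its
    dilution set. ``scale_factors`` (samples x bins) is filled by adaptive
    median normalisation.
    """

    values: pd.DataFrame
    platform: str
    sample_type: pd.Series
    dilution_bin: dict[str, str]
    scale_factors: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [a for a in self.values.columns if a not in self.dilution_bin]
        if missing:
            raise ValueError(f"analytes without a dilution bin: {missing}")
        self.sample_type = self.sample_type.reindex(self.values.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def test_samples(self) -> pd.DataFrame:
        return self.values.loc[self.sample_type == "test"]

    def copy(self) -> "AssayMatrix":
        return AssayMatrix(
            values=self.values.copy(),
            platform=self.platform,
            sample_type=self.sample_type.copy(),
            dilution_bin=dict(self.dilution_bin),
            scale_factors=None if self.scale_factors is None else self.scale_factors.copy(),
        )


@dataclass(frozen=True)
class Region:
    """A merged genomic association region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    lead: str
    members: tuple[str, ...]
    is_mhc: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class PqtlSignal:
    """A primary or conditionally independent pQTL for one target/platform."""

    target_id: str
    platform: str
    region: Region
    lead: str
    stats: pd.Series  # one SUMSTATS_COLUMNS row
    cis: bool
    conditional_rank: int = 1


@dataclass
class PairedTarget:
    """Signals for the same protein target on both platforms."""

    target_id: str
    signal_A: list[PqtlSignal] = field(default_factory=list)
    signal_B: list[PqtlSignal] = field(default_factory=list)
    n_A: int = 10708
    n_B: int = 485


@dataclass
class ConsistencyCall:
    """Outcome of the reciprocal cross-platform consistency decision tree."""

    target_id: str
    region: Optional[Region]
    category: str  # shared / specific_A / specific_B / distinct_signals / underpowered
    proxy_r2: float = float("nan")
    sign_concordant: Optional[bool] = None
    predicted_p: float = float("nan")


@dataclass
class ColocResult:
    """Five-hypothesis colocalisation posteriors for one protein-phenotype pair."""

    target_id: str
    platform: str
    phenotype_id: str
    pp: np.ndarray  # PP0..PP4
    lead_protein: str
    lead_phenotype: str
    lead_r2: float
    direction: int = 0  # phenotype sign aligned to the protein-increasing allele
    conditioned_on: Optional[str] = None

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, dtype=float)
        if self.pp.shape != (5,):
            raise ValueError("pp must hold exactly PP0..PP4")
        if not np.isclose(self.pp.sum(), 1.0, atol=1e-9):
            raise ValueError("posteriors must sum to 1")
        if np.any(self.pp < -1e-12) or np.any(self.pp > 1 + 1e-12):
            raise ValueError("posteriors must lie in [0,1]")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


@dataclass(frozen=True)
class NetworkEdge:
    """Protein-phenotype edge in the genetically anchored network."""

    protein: str
    phenotype: str
    platforms: tuple[str, ...]
    direction: int
    consistency: str  # consistent / specific_A / specific_B / opposing


@dataclass
class CohortBundle:
    """Everything the synthetic generator emits for one scenario."""

    genotypes: GenotypeMatrix
    assay_A: AssayMatrix
    assay_B: AssayMatrix
    blanks_A: AssayMatrix
    phenotypes: pd.DataFrame
    truth: dict
    covariates: pd.DataFrame
    subsample_index: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.subsample_index, dtype=int)
        if idx.min(initial=0) < 0 or idx.max(initial=-1) >= self.genotypes.n_samples:
            raise ValueError("subsample indices must index into the full sample")
        self.subsample_index = idx


@dataclass
class FeatureTable:
    """Per-unit feature matrix with an outcome for determinant models.

    ``mode`` is "regression" (outcome = cross-platform correlation) or
    "classification" (outcome = platform-specificity flag in {0,1}).
    """

    features: pd.DataFrame
    outcome: pd.Series
    mode: str = "regression"

    def __post_init__(self) -> None:
        if self.mode not in ("regression", "classification"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.outcome.isna().any():
            raise ValueError("outcome must have no missing values")
        if not np.all(np.isfinite(self.features.to_numpy(dtype=float))):
            raise ValueError("features must be finite after transformation")


def empty_sumstats() -> pd.DataFrame:
    return pd.DataFrame(columns=SUMSTATS_COLUMNS)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    """Check the SummaryStats invariants; return the frame unchanged."""
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    # monomorphic rows carry se=inf, which is > 0 and therefore allowed
    if np.any(df["se"].to_numpy(dtype=float) <= 0):
        raise ValueError("se must be > 0")
    eaf = df["eaf"].to_numpy(dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie in (0,1)")
    return df


__all__ = [
    "VariantSpec",
    "EffectSpec",
    "GenotypeMatrix",
    "AssayMatrix",
    "Region",
    "PqtlSignal",
    "PairedTarget",
    "ConsistencyCall",
    "ColocResult",
    "NetworkEdge",
    "CohortBundle",
    "FeatureTable",
    "SUMSTATS_COLUMNS",
    "PLATFORM_A",
    "PLATFORM_B",
    "DILUTION_BINS",
    "VARIANT_ROLES",
    "empty_sumstats",
    "validate_sumstats",
    "replace",
]
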