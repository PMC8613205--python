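import numpy as np
import pandas as pd
import pytest

from xpqtl.types import DILUTION_BINS, PLATFORM_A, AssayMatrix, VariantSpec


def make_assay(values: np.ndarray, analytes=None, sample_type="test",
               bins=None, platform=PLATFORM_A) -> AssayMatrix:
    """Small AssayMatrix builder for QC tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, m = values.shape
    analytes = analytes or [f"a{j}" for j in range(m)]
    ids = [f"S{i:05d}" for i in range(n)]
    bins = bins or {a: DILUTION_BINS[0] for a in analytes}
    return AssayMatrix(
        values=pd.DataFrame(values, index=ids, columns=analytes),
        platform=platform,
        sample_type=pd.Series(sample_type, index=ids),
        dilution_bin=bins,
    )


def variant_block(n=5, chrom="chr1", start=1_000_000, step=50_000, eaf=0.3,
                  roles=None):
    roles = roles or {}
    return [
        VariantSpec(
            variant_id=f"{chrom}_v{j}", chrom=chrom, pos=start + j * step,
            effect_allele_freq=eaf if np.isscalar(eaf) else eaf[j],
            role=roles.get(j, "null"),
        )
        for j in range(n)
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231001)
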