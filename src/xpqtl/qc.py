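"""Assay QC: adaptive median normalisation, LOD, outliers, transforms.

The measurement pre-processing applied before any association analysis:

* adaptive median normalisation — per sample and per dilution bin, a scale
  factor equal to the median ratio of reference to measured intensity over
  the analytes of that bin; samples with any factor outside an acceptance
  range (default 0.25–4) are excluded;
* limit of detection via the "robust estimate" rule on buffer (blank)
  samples: LOD = blank median + 4.9 x MAD (unscaled MAD);
* outlier flagging at median +/- 5 x MAD of the test-sample signals;
* rank-based inverse normal transformation and covariate residualisation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssayMatrix


def _mad(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Raw median absolute deviation, no consistency constant."""
    med = np.median(x, axis=axis, keepdims=True)
    return np.median(np.abs(x - med), axis=axis)


def adaptive_median_normalise(
    assay: AssayMatrix,
    reference_medians: pd.Series | dict | None = None,
    accept_range: tuple[float, float] = (0.25, 4.0),
) -> tuple[AssayMatrix, list[str]]:
    """Adaptive median normalisation with sample acceptance criteria.

    For each test sample and dilution bin the scale factor is the median over
    the bin's analytes of reference/measured; all analytes of the bin are
    multiplied by it. Samples with any bin factor outside ``accept_range``
    are excluded from the returned matrix and listed. When no external
    reference is supplied, the cohort's own per-analyte medians serve as the
    reference.

    Returns (normalised AssayMatrix with ``scale_factors`` filled for the
    retained samples, list of excluded sample ids).
    """
    test = assay.test_samples()
    if reference_medians is None:
        reference_medians = test.median(axis=0)
    else:
        reference_medians = pd.Series(reference_medians)
    missing = [a for a in assay.analytes if a not in reference_medians.index]
    if missing:
        raise ValueError(f"reference median missing for analytes: {missing}")
    if (reference_medians[assay.analytes] <= 0).any():
        bad = reference_medians[reference_medians <= 0].index.tolist()
        raise ValueError(f"reference medians must be > 0: {bad}")

    bins = sorted(set(assay.dilution_bin[a] for a in assay.analytes))
    factors = pd.DataFrame(index=test.index, columns=bins, dtype=float)
    normed = test.copy()
    for b in bins:
        cols = [a for a in assay.analytes if assay.dilution_bin[a] == b]
        ratio = reference_medians[cols].to_numpy() / test[cols].to_numpy()
        f = np.median(ratio, axis=1)
        factors[b] = f
        normed[cols] = test[cols].to_numpy() * f[:, None]

    lo, hi = accept_range
    bad_mask = ((factors < lo) | (factors > hi)).any(axis=1)
    excluded = factors.index[bad_mask].tolist()
    keep = factors.index[~bad_mask]

    out = AssayMatrix(
        values=normed.loc[keep],
        platform=assay.platform,
        sample_type=assay.sample_type.loc[keep],
        dilution_bin=dict(assay.dilution_bin),
        scale_factors=factors.loc[keep],
    )
    return out, excluded


def estimate_lod(blanks: AssayMatrix) -> pd.DataFrame:
    """Per-analyte limit of detection from buffer samples.

    LOD = median(blanks) + 4.9 * MAD(blanks), with the raw (unscaled) MAD.
    Requires at least 3 blank samples.
    """
    vals = blanks.values.loc[blanks.sample_type == "blank"]
    if vals.empty:  # allow passing a matrix that is all blanks untagged
        vals = blanks.values
    if len(vals) < 3:
        raise ValueError(f"need >= 3 blank samples, got {len(vals)}")
    x = vals.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = _mad(x, axis=0)
    return pd.DataFrame(
        {
            "analyte": vals.columns,
            "blank_median": med,
            "blank_mad": mad,
            "lod": med + 4.9 * mad,
        }
    ).set_index("analyte")


def flag_outliers(assay: AssayMatrix, k: float = 5.0) -> pd.DataFrame:
    """Boolean mask of values outside median +/- k*MAD per analyte.

    Computed over test samples only. Analytes with MAD = 0 (constant or
    heavily censored columns) are never flagged.
    """
    test = assay.test_samples()
    x = test.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = _mad(x, axis=0)
    lo = med - k * mad
    hi = med + k * mad
    mask = (x < lo) | (x > hi)
    mask[:, mad == 0] = False
    return pd.DataFrame(mask, index=test.index, columns=test.columns)


def outlier_fraction(assay: AssayMatrix, k: float = 5.0) -> pd.Series:
    """Per-analyte fraction of flagged outliers (a downstream feature)."""
    return flag_outliers(assay, k).mean(axis=0)


def below_lod_fraction(assay: AssayMatrix, lod: pd.DataFrame) -> pd.Series:
    """Per-analyte fraction of test-sample values below the LOD."""
    test = assay.test_samples()
    thr = lod["lod"].reindex(test.columns).to_numpy()
    return pd.Series((test.to_numpy() < thr).mean(axis=0), index=test.columns)


def inverse_normal_transform(x: np.ndarray | pd.Series) -> np.ndarray:
    """Rank-based inverse normal transformation.

    z_i = Phi^-1((r_i - 0.5)/n) with average ranks for ties; invariant to
    monotone transformations of the input. Requires >= 2 distinct values.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("input must be a vector")
    if np.unique(arr).size < 2:
        raise ValueError("inverse normal transform needs >= 2 distinct values")
    ranks = stats.rankdata(arr, method="average")
    return stats.norm.ppf((ranks - 0.5) / arr.size)


def residualise(y: np.ndarray | pd.Series, covariates: pd.DataFrame | None) -> np.ndarray:
    """OLS residuals of ``y`` on an intercept plus ``covariates``.

    Residuals are orthogonal to every covariate. Collinear covariate sets
    are rejected with the offending columns named.
    """
    yv = np.asarray(y, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return yv - yv.mean()
    X = np.column_stack([np.ones(len(yv)), covariates.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j, col in enumerate(covariates.columns):
            sub = X[:, : j + 2]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(col)
        raise ValueError(f"collinear covariate columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    return yv - X @ beta


__all__ = [
    "adaptive_median_normalise",
    "estimate_lod",
    "flag_outliers",
    "outlier_fraction",
    "below_lod_fraction",
    "inverse_normal_transform",
    "residualise",
]
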