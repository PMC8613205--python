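"""Determinants of cross-platform concordance.

Three complementary analyses of why affinity platforms agree or disagree:

* shadow-feature random-forest selection (Boruta-style) of the technical and
  protein characteristics that predict the between-platform correlation —
  each round appends permuted shadow copies of every feature, fits a random
  forest and scores a "hit" when a real feature's importance exceeds the
  best shadow's; decisions come from two-sided binomial tests on hit counts
  with Bonferroni adjustment, plus bootstrap importance distributions for
  confirmed features;
* univariate logistic models for the odds of platform-specificity of a pQTL
  with heteroskedasticity-consistent (sandwich) standard errors and the
  skew-reducing transformations applied to the named factor kinds;
* variance decomposition of rank-transformed between-platform measurement
  differences into per-predictor fixed-effect variance shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.inspection import permutation_importance

from .types import FeatureTable

RF_N_TREES = 500  # fixed forest size, exposed here for configuration


# ---------------------------------------------------------------------------
# Boruta-style shadow-feature selection
# ---------------------------------------------------------------------------


@dataclass
class BorutaResult:
    decisions: pd.Series  # feature -> confirmed / rejected / tentative
    hits: pd.Series
    n_iter: int
    bootstrap_importances: pd.DataFrame  # n_boot x confirmed features


def _forest(mode: str, seed: int, n_trees: int = RF_N_TREES):
    # classic random-forest feature subsampling: p/3 (regression), sqrt(p)
    # (classification)
    if mode == "regression":
        return RandomForestRegressor(
            n_estimators=n_trees, max_features=1.0 / 3.0,
            random_state=seed, n_jobs=1,
        )
    return RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )


def _importances(rf, X, y, measure: str, repeats: int,
                 rng: np.random.Generator) -> pd.Series:
    if measure == "impurity":
        return pd.Series(rf.feature_importances_, index=X.columns)
    imp = permutation_importance(
        rf, X, y, n_repeats=repeats,
        random_state=int(rng.integers(0, 2**31 - 1)), n_jobs=1,
    ).importances_mean
    return pd.Series(imp, index=X.columns)


def boruta_select(
    table: FeatureTable,
    n_iter: int = 20,
    alpha: float = 0.01,
    n_boot: int = 500,
    seed: int = 0,
    n_trees: int = RF_N_TREES,
    importance: str = "impurity",
    importance_repeats: int = 3,
) -> BorutaResult:
    """Shadow-feature random-forest selection.

    Constant features are rejected outright (with a warning). For each of
    ``n_iter`` rounds the feature matrix is extended with independently
    permuted shadow copies, a random forest is fitted and permutation
    importance computed; a feature scores a hit when its importance exceeds
    the maximum shadow importance. Hits follow Binomial(n_iter, 1/2) under
    the null; two-sided binomial tests with Bonferroni adjustment across
    features at level ``alpha`` yield confirmed / rejected / tentative.
    Bootstrap importance distributions (``n_boot`` resamples) are reported
    for confirmed features; pass ``n_boot=0`` to skip them.

    ``importance`` selects the measure: "impurity" (mean decrease in
    impurity, the convention of the reference Python implementation) or
    "permutation" (slower; ``importance_repeats`` shuffles per feature).
    """
    if importance not in ("impurity", "permutation"):
        raise ValueError(f"unknown importance measure {importance!r}")
    X = table.features.copy()
    y = table.outcome.to_numpy()
    if len(X) < 20:
        raise ValueError("need at least 20 units")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    rng = np.random.default_rng(seed)

    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant features rejected: {constant}")
    live = [c for c in X.columns if c not in constant]

    hits = pd.Series(0, index=live, dtype=int)
    for it in range(n_iter):
        shadows = X[live].apply(lambda col: rng.permutation(col.to_numpy()))
        shadows.columns = [f"shadow__{c}" for c in live]
        Xa = pd.concat([X[live], shadows], axis=1)
        rf = _forest(table.mode, int(rng.integers(0, 2**31 - 1)), n_trees)
        rf.fit(Xa, y)
        imp = _importances(rf, Xa, y, importance, importance_repeats, rng)
        shadow_max = imp[shadows.columns].max()
        hits[imp[live] > shadow_max] += 1

    m = len(live)
    decisions = pd.Series("tentative", index=X.columns, dtype=object)
    decisions[constant] = "rejected"
    for c in live:
        res = stats.binomtest(int(hits[c]), n_iter, 0.5, alternative="two-sided")
        if res.pvalue * m <= alpha:
            decisions[c] = "confirmed" if hits[c] > n_iter / 2 else "rejected"

    confirmed = [c for c in live if decisions[c] == "confirmed"]
    boots = pd.DataFrame(columns=confirmed, dtype=float)
    if n_boot > 0 and confirmed:
        rows = np.empty((n_boot, len(confirmed)))
        n = len(X)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            rf = _forest(table.mode, int(rng.integers(0, 2**31 - 1)), n_trees)
            Xb, yb = X[live].iloc[idx], y[idx]
            rf.fit(Xb, yb)
            imp = _importances(rf, Xb, yb, importance, importance_repeats, rng)
            rows[b] = imp[confirmed].to_numpy()
        boots = pd.DataFrame(rows, columns=confirmed)
    return BorutaResult(
        decisions=decisions, hits=hits.reindex(X.columns).fillna(0).astype(int),
        n_iter=n_iter, bootstrap_importances=boots,
    )


# ---------------------------------------------------------------------------
# platform-specificity logistic models
# ---------------------------------------------------------------------------

#: factor-kind -> skew-reducing transformation applied before fitting
DEFAULT_TRANSFORMS = {
    "apparent_kd": "log",
    "n_coloc_traits": "sqrt",
    "abs_effect": "sqrt",
    "explained_variance": "sqrt",
}


def _apply_transform(x: pd.Series, kind: str | None) -> pd.Series:
    if kind is None:
        return x
    if kind == "log":
        return np.log(x)
    if kind == "sqrt":
        return np.sqrt(x)
    raise ValueError(f"unknown transform {kind!r}")


def platform_specificity_model(
    table: FeatureTable,
    transforms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Univariate logistic odds of platform-specificity per factor.

    One logistic fit per factor with HC1 sandwich covariance for the robust
    95% CI. Factors causing complete separation or degeneracy are flagged
    with NaN estimates instead of aborting the table.
    """
    if table.mode != "classification":
        raise ValueError("requires a classification-mode feature table")
    y = table.outcome.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    rows = []
    for c in table.features.columns:
        x = _apply_transform(table.features[c], transforms.get(c))
        flagged = False
        or_, lo, hi, p = (np.nan,) * 4
        if x.nunique() <= 1:
            flagged = True
        else:
            X = sm.add_constant(np.asarray(x, dtype=float))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X).fit(disp=0, cov_type="HC1", maxiter=100)
                b, se = fit.params[1], fit.bse[1]
                if not np.isfinite(b) or not np.isfinite(se) or abs(b) > 15:
                    flagged = True  # quasi-separation
                else:
                    or_ = float(np.exp(b))
                    lo = float(np.exp(b - 1.96 * se))
                    hi = float(np.exp(b + 1.96 * se))
                    p = float(fit.pvalues[1])
            except Exception:  # separation raises inside the optimiser
                flagged = True
        rows.append(
            dict(factor=c, odds_ratio=or_, ci_low=lo, ci_high=hi, p=p,
                 flagged=flagged)
        )
    return pd.DataFrame(rows).set_index("factor")


# ---------------------------------------------------------------------------
# variance decomposition
# ---------------------------------------------------------------------------


def variance_decomposition(
    diff: np.ndarray,
    explanatory: pd.DataFrame,
) -> pd.Series:
    """Fixed-effect variance shares of between-platform differences.

    Joint OLS of ``diff`` on all explanatory variables; the share of
    variable j is Var(x_j * beta_j) / Var(diff) and the residual share is
    1 - R^2. With correlated predictors the shares need not sum to one;
    a warning notes this when predictor correlations are material.
    """
    y = np.asarray(diff, dtype=float)
    Xdf = explanatory.astype(float)
    X = np.column_stack([np.ones(len(y)), Xdf.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("explanatory table is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    var_y = float(np.var(y))
    shares = {
        c: float(np.var(Xdf[c].to_numpy() * beta[j + 1]) / var_y)
        for j, c in enumerate(Xdf.columns)
    }
    r2 = float(np.var(fitted) / var_y)
    shares["residual"] = 1.0 - r2
    corr = Xdf.corr().to_numpy()
    off = corr[~np.eye(len(corr), dtype=bool)]
    if off.size and np.nanmax(np.abs(off)) > 0.3:
        warnings.warn(
            "correlated predictors: variance shares reported as-is and may "
            "not sum to one"
        )
    return pd.Series(shares)


def select_pqtl_for_diff(
    diff: np.ndarray,
    candidates: pd.DataFrame,
    positions: pd.Series | None = None,
) -> str:
    """Choose the single pQTL best explaining the measurement differences.

    Simple regression of ``diff`` on each candidate dosage column; smallest
    p-value wins, ties broken by smallest genomic position (or column
    order when positions are not given).
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    y = np.asarray(diff, dtype=float)
    ps = {}
    for c in candidates.columns:
        g = candidates[c].to_numpy(dtype=float)
        if g.std() == 0:
            ps[c] = 1.0
            continue
        r = stats.linregress(g, y)
        ps[c] = float(r.pvalue)
    order = list(candidates.columns)
    if positions is not None:
        order = sorted(order, key=lambda c: (ps[c], positions.get(c, np.inf)))
    else:
        order = sorted(order, key=lambda c: (ps[c], order.index(c)))
    return order[0]


# ---------------------------------------------------------------------------
# feature assembly and synthetic feature tables
# ---------------------------------------------------------------------------


def assemble_feature_table(
    units: pd.DataFrame,
    outcome: str,
    mode: str = "regression",
) -> FeatureTable:
    """Build a FeatureTable from a per-unit frame with an outcome column."""
    if outcome not in units.columns:
        raise ValueError(f"missing outcome column {outcome!r}")
    feats = units.drop(columns=[outcome])
    return FeatureTable(features=feats, outcome=units[outcome], mode=mode)


def simulate_feature_table(
    n_units: int = 200,
    n_noise: int = 9,
    snr: float = 2.0,
    seed: int = 0,
    duplicate_planted: bool = False,
) -> FeatureTable:
    """Synthetic regression-mode table with one planted determinant.

    outcome = planted + noise with sd 1/snr relative to the planted
    feature's unit variance; remaining features are independent noise.
    """
    rng = np.random.default_rng(seed)
    planted = rng.standard_normal(n_units)
    cols = {"planted": planted}
    if duplicate_planted:
        cols["planted_copy"] = planted.copy()
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n_units)
    outcome = planted + rng.standard_normal(n_units) / snr
    feats = pd.DataFrame(cols)
    return FeatureTable(features=feats, outcome=pd.Series(outcome),
                        mode="regression")


def simulate_specificity_table(
    n_units: int = 500,
    log_or: float = np.log(2.0),
    n_noise: int = 3,
    seed: int = 0,
    heteroskedastic: bool = False,
) -> FeatureTable:
    """Synthetic classification-mode table with one factor of known OR."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_units)
    if heteroskedastic:
        x = x * (1.0 + 0.5 * np.abs(rng.standard_normal(n_units)))
    eta = -0.2 + log_or * x
    y = rng.uniform(size=n_units) < 1.0 / (1.0 + np.exp(-eta))
    cols = {"factor": x}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.standard_normal(n_units)
    return FeatureTable(
        features=pd.DataFrame(cols),
        outcome=pd.Series(y.astype(int)),
        mode="classification",
    )


__all__ = [
    "BorutaResult",
    "boruta_select",
    "platform_specificity_model",
    "variance_decomposition",
    "select_pqtl_for_diff",
    "assemble_feature_table",
    "simulate_feature_table",
    "simulate_specificity_table",
    "DEFAULT_TRANSFORMS",
    "RF_N_TREES",
]
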