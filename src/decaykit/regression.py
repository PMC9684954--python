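"""L1-regularized linear models of half-life over named feature groups.

The modeling strategy is deliberately simple: concatenate feature groups,
z-score everything, fit lasso regression with the penalty weight chosen by
inner cross-validation, and score held-out Pearson correlation on 10 outer
folds.  Feature groups are then judged by *nested model comparison*: a
group earns its place only if the model containing it beats the model
without it by a one-sided paired t-test over the 10 per-fold correlations,
Bonferroni-corrected over the declared number of comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV

from .features import FeatureTable

__all__ = [
    "ModelSpec",
    "assign_folds",
    "LassoFitResult",
    "NestedComparisonResult",
    "fit_lasso_cv",
    "compare_nested_models",
    "interpret_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """A model code over the feature-group alphabet, e.g. ``"BC3MS"``."""

    code: str

    def __post_init__(self):
        if len(set(self.code)) != len(self.code):
            raise ValueError(f"duplicate group letters in model code {self.code!r}")
        if not self.code:
            raise ValueError("empty model code")

    def resolve(self, table: FeatureTable) -> FeatureTable:
        return table.select_groups(self.code)


def assign_folds(
    genes: list[str], n_folds: int = 10, seed: int = 0
) -> pd.Series:
    """Random balanced partition of genes into folds 1..n_folds."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    folds = np.empty(len(genes), dtype=int)
    folds[order] = np.arange(len(genes)) % n_folds + 1
    return pd.Series(folds, index=genes, name="fold")


def _lambda_grid(X: np.ndarray, y: np.ndarray, n: int, decades: float) -> np.ndarray:
    lam_max = np.max(np.abs(X.T @ y)) / len(y)
    return np.geomspace(lam_max, lam_max * 10.0 ** (-decades), n)


def _zscore(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    sd = df.std(ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"dropping {int(const.sum())} constant feature(s): "
            f"{list(df.columns[const][:5])}"
        )
    df = df.loc[:, ~const]
    return (df - df.mean()) / df.std(ddof=1), df.columns


@dataclass
class LassoFitResult:
    """Held-out predictions and per-fold metrics for one model code."""

    code: str
    predictions: pd.Series
    fold_r: pd.Series  # indexed by fold id
    chosen_alpha: dict[int, float]
    coefficients: dict[int, pd.Series]
    degenerate_folds: list[int] = field(default_factory=list)


def fit_lasso_cv(
    features: FeatureTable,
    target: pd.Series,
    folds: pd.Series,
    *,
    code: str = "",
    n_lambda: int = 100,
    grid_decades: float = 4.0,
    inner_cv: int = 10,
    standardize: str = "global",
    selection: str = "min",
    seed: int = 0,
) -> LassoFitResult:
    """Outer-fold lasso with inner-CV penalty selection.

    Features and target are z-scored globally by default (the
    reproduction-faithful choice; ``standardize="fold"`` refits the scaler
    on each training split to avoid the mild leakage).  For each outer fold
    the penalty is picked over a log-spaced grid -- spanning four decades
    down from the smallest penalty with empty support -- by ``inner_cv``-fold
    mean-MSE cross-validation on the training portion (``selection="1se"``
    applies the one-standard-error rule instead), then the model is refit
    and the held-out fold predicted.
    """
    genes = features.values.index.intersection(target.dropna().index).intersection(
        folds.index
    )
    X_df = features.values.loc[genes]
    if X_df.isna().any().any():
        raise ValueError("features contain missing values; impute or drop first")
    y_raw = target.loc[genes].astype(float)
    if y_raw.std(ddof=1) == 0 or not np.isfinite(y_raw.std(ddof=1)):
        raise ValueError("constant target")
    f = folds.loc[genes]

    if standardize == "global":
        X_df, cols = _zscore(X_df)
        y = ((y_raw - y_raw.mean()) / y_raw.std(ddof=1)).to_numpy()
        X = X_df.to_numpy(dtype=float)
    elif standardize == "fold":
        warnings.warn(
            "fold-wise standardization: feature scaling refit per training split"
        )
        cols = X_df.columns
        X = X_df.to_numpy(dtype=float)
        y = y_raw.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown standardize mode {standardize!r}")

    preds = pd.Series(np.nan, index=genes, name="prediction")
    fold_ids = sorted(f.unique())
    fold_r: dict[int, float] = {}
    alphas: dict[int, float] = {}
    coefs: dict[int, pd.Series] = {}
    degenerate: list[int] = []
    for k in fold_ids:
        test = (f == k).to_numpy()
        train = ~test
        Xtr, ytr = X[train], y[train]
        Xte, yte = X[test], y[test]
        if standardize == "fold":
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
            ymu, ysd = ytr.mean(), ytr.std(ddof=1)
            ytr = (ytr - ymu) / ysd
            yte = (yte - ymu) / ysd
        grid = _lambda_grid(Xtr, ytr, n_lambda, grid_decades)
        cv = LassoCV(
            alphas=grid, cv=inner_cv, fit_intercept=True, max_iter=5000,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv.fit(Xtr, ytr)
        alpha = float(cv.alpha_)
        if selection == "1se":
            mse = cv.mse_path_.mean(axis=1)
            se = cv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv.mse_path_.shape[1])
            best = int(np.argmin(mse))
            bound = mse[best] + se[best]
            ok = np.where(mse <= bound)[0]
            alpha = float(cv.alphas_[ok[0]])  # alphas_ sorted descending
        elif selection != "min":
            raise ValueError(f"unknown selection rule {selection!r}")
        model = Lasso(alpha=alpha, fit_intercept=True, max_iter=20000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, ytr)
        p = model.predict(Xte)
        preds.iloc[np.where(test)[0]] = p
        if np.std(p) == 0 or np.std(yte) == 0:
            fold_r[k] = 0.0
            degenerate.append(k)
        else:
            fold_r[k] = float(stats.pearsonr(yte, p)[0])
        alphas[k] = alpha
        coefs[k] = pd.Series(model.coef_, index=cols)
    return LassoFitResult(
        code=code,
        predictions=preds,
        fold_r=pd.Series(fold_r).sort_index(),
        chosen_alpha=alphas,
        coefficients=coefs,
        degenerate_folds=degenerate,
    )


# ---------------------------------------------------------------------------
# nested model comparison
# ---------------------------------------------------------------------------

@dataclass
class NestedComparisonResult:
    """Pairwise one-sided paired t-tests between nested model codes."""

    fold_r: pd.DataFrame  # folds x model codes
    comparisons: list[tuple[str, str]]
    p_values: pd.Series
    p_adjusted: pd.Series
    winners: pd.Series


def _paired_onesided_p(simple: np.ndarray, complex_: np.ndarray) -> float:
    """One-sided paired t-test p-value for H1: complex > simple."""
    d = complex_ - simple
    if np.allclose(d.std(ddof=1), 0):
        if d.mean() > 0:
            return 0.0  # t -> +inf convention
        return 1.0
    res = stats.ttest_rel(complex_, simple, alternative="greater")
    return float(res.pvalue)


def compare_nested_models(
    results: dict[str, LassoFitResult] | pd.DataFrame,
    comparisons: list[tuple[str, str]],
    n_tests: int | None = None,
) -> NestedComparisonResult:
    """Compare (simpler, complex) model pairs on their per-fold correlations.

    ``n_tests`` defaults to the number of declared comparisons and sets the
    Bonferroni factor.
    """
    if isinstance(results, dict):
        fold_r = pd.DataFrame({c: r.fold_r for c, r in results.items()})
    else:
        fold_r = results
    if fold_r.isna().any().any():
        raise ValueError("fold metrics contain NaN; models must share fold splits")
    n_tests = n_tests if n_tests is not None else len(comparisons)
    pvals, winners = {}, {}
    for simple, complex_ in comparisons:
        for c in (simple, complex_):
            if c not in fold_r.columns:
                raise KeyError(f"model {c!r} not evaluated")
        key = f"{simple}->{complex_}"
        p = _paired_onesided_p(
            fold_r[simple].to_numpy(), fold_r[complex_].to_numpy()
        )
        pvals[key] = p
        winners[key] = complex_ if min(1.0, p * n_tests) < 0.05 else simple
    p_ser = pd.Series(pvals)
    return NestedComparisonResult(
        fold_r=fold_r,
        comparisons=list(comparisons),
        p_values=p_ser,
        p_adjusted=(p_ser * n_tests).clip(upper=1.0),
        winners=pd.Series(winners),
    )


# ---------------------------------------------------------------------------
# interpretation
# ---------------------------------------------------------------------------

def interpret_model(
    features: FeatureTable,
    target: pd.Series,
    *,
    top_n: int = 30,
    corr_threshold: float = 0.8,
    n_lambda: int = 100,
    grid_decades: float = 4.0,
    inner_cv: int = 10,
    seed: int = 0,
) -> dict:
    """Full-data lasso fit with coefficient ranking and collinearity report.

    Returns the nonzero coefficients sorted by magnitude (at most ``top_n``)
    and, for each, every other feature whose absolute Pearson correlation
    with it reaches ``corr_threshold``.
    """
    genes = features.values.index.intersection(target.dropna().index)
    X_df, cols = _zscore(features.values.loc[genes])
    y = target.loc[genes].astype(float)
    y = ((y - y.mean()) / y.std(ddof=1)).to_numpy()
    X = X_df.to_numpy(dtype=float)
    grid = _lambda_grid(X, y, n_lambda, grid_decades)
    cv = LassoCV(alphas=grid, cv=inner_cv, fit_intercept=True, max_iter=5000,
                 random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv.fit(X, y)
        model = Lasso(alpha=float(cv.alpha_), fit_intercept=True, max_iter=20000)
        model.fit(X, y)
    coef = pd.Series(model.coef_, index=cols)
    support = coef[coef != 0]
    top = support.reindex(support.abs().sort_values(ascending=False).index)[:top_n]
    collinear = {}
    if len(top):
        Xc = X_df.to_numpy()
        norm = Xc / np.sqrt((Xc**2).sum(axis=0))
        for feat in top.index:
            v = norm[:, X_df.columns.get_loc(feat)]
            r = norm.T @ v
            hits = pd.Series(r, index=X_df.columns)
            hits = hits[(hits.abs() >= corr_threshold) & (hits.index != feat)]
            collinear[feat] = hits.sort_values(key=np.abs, ascending=False)
    return {
        "alpha": float(cv.alpha_),
        "coefficients": coef,
        "top": top,
        "collinear": collinear,
    }
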