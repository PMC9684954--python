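"""Harmonization of heterogeneous mRNA half-life datasets.

Public measurements of transcriptome-wide mRNA half-life disagree strongly
across laboratories, cell types and protocols (pulse labeling with modified
nucleosides vs. transcriptional shutoff with inhibitors).  This module
carries a sparse gene x sample matrix through a fixed pipeline --

    raw -> transformed -> filtered -> standardized -> imputed -> normalized

-- and summarizes the harmonized matrix by its first principal component,
a cell-type-agnostic consensus half-life per gene.  Two statistical probes
quantify what the harmonization removed: a rank-sum test for systematic
offsets between the two method classes, and a rank-sum test for residual
cell-type specificity in cross-study sample correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleMeta",
    "HalfLifeMatrix",
    "ConsensusHalfLife",
    "STAGES",
    "method_class_of",
    "preprocess_halflives",
    "filter_genes",
    "standardize_samples",
    "impute_iterative_pca",
    "quantile_normalize",
    "consensus_pc1",
    "sample_pca",
    "method_bias_test",
    "celltype_specificity_test",
]

STAGES = ("raw", "transformed", "filtered", "standardized", "imputed", "normalized")

#: measurement protocol -> method class
_PULSE = {"4su", "bru", "5eu", "bru4su", "4su+bru", "slam-seq", "tt-seq", "timelapse-seq"}
_SHUTOFF = {"actd", "alpha-amanitin", "a-amanitin", "α-amanitin", "amanitin"}


def method_class_of(method: str) -> str:
    """Deterministic map from measurement method to its class.

    Pulse-labeling protocols introduce modified nucleosides (4sU, BrU, 5EU);
    transcriptional-shutoff protocols poison polymerase (ActD, alpha-Amanitin).
    """
    m = method.strip().lower()
    base = m.split("(")[0].strip()
    if base in _PULSE or any(tag in m for tag in ("4su", "bru", "5eu")):
        return "pulse_labeling"
    if base in _SHUTOFF or "amanitin" in m or "actd" in m:
        return "transcriptional_shutoff"
    raise ValueError(f"unknown measurement method: {method!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one half-life sample (one matrix column)."""

    sample_id: str
    study: str
    species: str
    cell_type: str
    method: str
    unit: str | None = None  # "hours" | "minutes"; may be None for rates
    is_degradation_rate: bool = False

    def __post_init__(self):
        if self.species not in ("human", "mouse"):
            raise ValueError(f"species must be human|mouse, got {self.species!r}")
        if not self.is_degradation_rate and self.unit not in ("hours", "minutes"):
            raise ValueError(
                f"sample {self.sample_id!r}: unit is required for half-lives "
                f"(got {self.unit!r})"
            )
        method_class_of(self.method)  # validate eagerly

    @property
    def method_class(self) -> str:
        return method_class_of(self.method)


@dataclass
class HalfLifeMatrix:
    """Gene x sample half-life matrix with per-sample metadata and a stage tag.

    ``values`` is a pandas DataFrame indexed by gene ID with one column per
    sample; missing measurements are NaN.  ``stage`` advances monotonically
    through :data:`STAGES`; from ``imputed`` onward no NaN remains.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != ids:
            raise ValueError("values columns must match sample metadata order")
        if STAGES.index(self.stage) >= STAGES.index("imputed"):
            if self.values.isna().any().any():
                raise ValueError(f"stage {self.stage} forbids missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def _advance(self, values: pd.DataFrame, stage: str) -> "HalfLifeMatrix":
        if STAGES.index(stage) < STAGES.index(self.stage):
            raise ValueError(f"stage may not regress: {self.stage} -> {stage}")
        return HalfLifeMatrix(values=values, samples=list(self.samples), stage=stage)


@dataclass
class ConsensusHalfLife:
    """Per-gene PC1 scores with variance fractions and the sign-anchor rule."""

    gene_scores: pd.Series
    variance_explained: np.ndarray
    sign_anchor: str = "corr(PC1, per-gene mean) > 0"


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------

def _transform_sample(values: pd.Series, meta: SampleMeta) -> pd.Series:
    """Log-transform one sample column; rates are sign-flipped afterwards.

    Pseudocount is 0.1 for hours and 1 for minutes, chosen so the transform
    is stable near zero on either unit scale.  Degradation rates are
    monotonically *decreasing* in half-life, so their transformed values are
    negated to share the half-life orientation.
    """
    v = values.astype(float)
    if meta.is_degradation_rate:
        pc = {"hours": 0.1, "minutes": 1.0}.get(meta.unit, 0.1)
        if (v.dropna() > 0).all():
            return -np.log10(v + pc)
        # deposited on a log/linear scale that already crosses zero
        return -v
    if meta.unit == "hours":
        pc = 0.1
    elif meta.unit == "minutes":
        pc = 1.0
    else:  # unreachable for validated SampleMeta, defensive for raw dicts
        raise ValueError(f"sample {meta.sample_id!r}: unknown unit {meta.unit!r}")
    neg = v < 0
    if neg.any():
        warnings.warn(
            f"sample {meta.sample_id!r}: dropped {int(neg.sum())} negative "
            f"half-life value(s)"
        )
        v = v.mask(neg)
    return np.log10(v + pc)


def preprocess_halflives(
    table: pd.DataFrame, samples: list[SampleMeta]
) -> HalfLifeMatrix:
    """Build the transformed sparse matrix from per-sample raw values.

    ``table`` holds raw half-lives (or degradation rates) with gene IDs as
    index (duplicates allowed) and one column per sample.  Columns are
    log10-transformed with a unit-dependent pseudocount, rate samples are
    negated, and duplicated gene IDs are averaged.
    """
    ids = [s.sample_id for s in samples]
    missing_cols = set(ids) - set(table.columns)
    if missing_cols:
        raise ValueError(f"table lacks columns for samples: {sorted(missing_cols)}")
    cols = {}
    for meta in samples:
        cols[meta.sample_id] = _transform_sample(table[meta.sample_id], meta)
    out = pd.DataFrame(cols, index=table.index)[ids]
    if out.index.has_duplicates:
        out = out.groupby(level=0, sort=False).mean()
    return HalfLifeMatrix(values=out, samples=list(samples), stage="transformed")


def filter_genes(m: HalfLifeMatrix, min_samples: int) -> HalfLifeMatrix:
    """Keep genes observed in at least ``min_samples`` samples."""
    if m.stage != "transformed":
        raise ValueError(f"filter_genes expects stage=transformed, got {m.stage}")
    if min_samples > len(m.samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {len(m.samples)}"
        )
    keep = m.values.notna().sum(axis=1) >= min_samples
    return m._advance(m.values.loc[keep], "filtered")


def standardize_samples(m: HalfLifeMatrix) -> HalfLifeMatrix:
    """z-score each sample column over its observed entries (ddof=1)."""
    if m.stage != "filtered":
        raise ValueError(f"standardize_samples expects stage=filtered, got {m.stage}")
    out = {}
    for sid in m.values.columns:
        col = m.values[sid]
        obs = col.dropna()
        if len(obs) < 2:
            raise ValueError(f"sample {sid!r} has <2 observed values")
        sd = obs.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"sample {sid!r} has zero variance")
        out[sid] = (col - obs.mean()) / sd
    return m._advance(pd.DataFrame(out, index=m.values.index), "standardized")


# -- iterative PCA imputation ------------------------------------------------

def _impute_fixed_ncp(
    X: np.ndarray,
    miss: np.ndarray,
    ncp: int,
    tol: float,
    max_iter: int,
    regularized: bool = True,
) -> np.ndarray:
    """EM-style rank-``ncp`` completion; only missing cells are rewritten.

    With ``regularized=True`` (the standard form of the cited procedure)
    the retained singular values are shrunk by the mean discarded noise
    variance, which stabilizes the fit on noisy data and makes the EM
    iteration converge geometrically; on exactly low-rank input the
    shrinkage vanishes and the reconstruction is exact.
    """
    Xf = X.copy()
    col_means = np.nanmean(X, axis=0)
    rr, cc = np.where(miss)
    Xf[rr, cc] = col_means[cc]
    if ncp == 0:
        return Xf
    delta = np.inf
    for _ in range(max_iter):
        mu = Xf.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xf - mu, full_matrices=False)
        if regularized and len(s) > ncp:
            sigma2 = float(np.mean(s[ncp:] ** 2))
            s_use = np.maximum(s[:ncp] ** 2 - sigma2, 0.0) / np.where(
                s[:ncp] > 0, s[:ncp], 1.0
            )
        else:
            s_use = s[:ncp]
        recon = (U[:, :ncp] * s_use) @ Vt[:ncp] + mu
        new = recon[rr, cc]
        delta = np.max(np.abs(new - Xf[rr, cc])) if len(rr) else 0.0
        Xf[rr, cc] = new
        if delta < tol:
            return Xf
    raise RuntimeError(
        f"iterative PCA imputation did not converge in {max_iter} iterations "
        f"(last max |delta| = {delta:.3e})"
    )


def _cv_choose_ncp(
    X: np.ndarray,
    miss: np.ndarray,
    ncp_max: int,
    k_folds: int,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
) -> int:
    """Pick the component number by K-fold masking CV of imputation MSE."""
    obs_idx = np.argwhere(~miss)
    perm = rng.permutation(len(obs_idx))
    folds = np.array_split(perm, k_folds)
    grid = range(ncp_max + 1)
    errs = np.zeros((len(folds), ncp_max + 1))
    for fi, fold in enumerate(folds):
        hold = obs_idx[fold]
        miss_cv = miss.copy()
        miss_cv[hold[:, 0], hold[:, 1]] = True
        # guard: a fully masked row/column cannot be imputed from data
        if (~miss_cv).sum(axis=1).min() == 0 or (~miss_cv).sum(axis=0).min() == 0:
            errs[fi] = np.nan
            continue
        Xcv = X.copy()
        Xcv[miss_cv] = np.nan
        truth = X[hold[:, 0], hold[:, 1]]
        for ncp in grid:
            done = _impute_fixed_ncp(Xcv, miss_cv, ncp, tol, max_iter)
            pred = done[hold[:, 0], hold[:, 1]]
            errs[fi, ncp] = np.mean((pred - truth) ** 2)
    mean_err = np.nanmean(errs, axis=0)
    return int(np.nanargmin(mean_err))


def impute_iterative_pca(
    m: HalfLifeMatrix,
    ncp_max: int,
    *,
    ncp: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[HalfLifeMatrix, int]:
    """Impute missing cells by EM-style iterative PCA.

    Missing cells are initialized at column means, then repeatedly replaced
    by a rank-``ncp`` SVD reconstruction of the completed matrix until the
    largest change on a missing cell falls below ``tol``.  When ``ncp`` is
    not given it is chosen over ``0..ncp_max`` by ``cv_folds``-fold
    cross-validated imputation error on additionally masked observed cells.
    Observed cells are bit-identical to the input.
    """
    if m.stage != "standardized":
        raise ValueError(f"impute expects stage=standardized, got {m.stage}")
    n_samples = len(m.samples)
    if not (0 <= ncp_max < n_samples):
        raise ValueError(f"require 0 <= ncp_max < n_samples, got {ncp_max}")
    X = m.values.to_numpy(dtype=float)
    miss = np.isnan(X)
    if miss.all(axis=1).any():
        bad = m.values.index[miss.all(axis=1)][:5].tolist()
        raise ValueError(f"gene(s) with all values missing: {bad}")
    if miss.all(axis=0).any():
        bad = m.values.columns[miss.all(axis=0)][:5].tolist()
        raise ValueError(f"sample(s) with all values missing: {bad}")
    if not miss.any():
        return m._advance(m.values.copy(), "imputed"), (ncp if ncp is not None else 0)
    if ncp is None:
        rng = np.random.default_rng(seed)
        # candidate scoring only compares MSEs; a looser tolerance suffices
        ncp = _cv_choose_ncp(
            X, miss, ncp_max, cv_folds, max(tol, 1e-4), max_iter, rng
        )
    done = _impute_fixed_ncp(X, miss, ncp, tol, max_iter)
    done[~miss] = X[~miss]  # exact preservation, not just numerical
    out = pd.DataFrame(done, index=m.values.index, columns=m.values.columns)
    return m._advance(out, "imputed"), ncp


def quantile_normalize(m: HalfLifeMatrix) -> HalfLifeMatrix:
    """Force every sample column onto the mean-of-order-statistics distribution.

    Ties within a column receive the average of their tied reference
    quantiles; with tie-free data each column's sorted vector equals the
    reference exactly.
    """
    if m.stage != "imputed":
        raise ValueError(f"quantile_normalize expects stage=imputed, got {m.stage}")
    X = m.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values present; impute first")
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    ranks = np.apply_along_axis(lambda c: stats.rankdata(c, method="average"), 0, X)
    out = np.interp(ranks, np.arange(1, n + 1), reference)
    return m._advance(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), "normalized"
    )


# -- principal components ----------------------------------------------------

def consensus_pc1(m: HalfLifeMatrix) -> ConsensusHalfLife:
    """Consensus per-gene half-life as PC1 of the normalized matrix.

    Samples are the variables (columns centered, unscaled); genes are the
    observations.  The PC1 sign is anchored so scores correlate positively
    with per-gene means, removing the orientation ambiguity introduced by
    rate-deposited samples.
    """
    if m.stage != "normalized":
        raise ValueError(f"consensus_pc1 expects stage=normalized, got {m.stage}")
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples for PCA")
    X = m.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * s[0]
    var_frac = s**2 / np.sum(s**2)
    row_means = X.mean(axis=1)
    if np.corrcoef(scores, row_means)[0, 1] < 0:
        scores = -scores
    return ConsensusHalfLife(
        gene_scores=pd.Series(scores, index=m.values.index, name="pc1_score"),
        variance_explained=var_frac,
    )


def sample_pca(m: HalfLifeMatrix, n_pcs: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the transposed matrix: per-sample coordinates for relatedness plots.

    Genes are the variables (centered over samples); returns each sample's
    coordinates on the first ``n_pcs`` PCs plus all variance fractions.
    """
    if m.stage != "normalized":
        raise ValueError(f"sample_pca expects stage=normalized, got {m.stage}")
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples for PCA")
    Y = m.values.to_numpy(dtype=float).T  # samples x genes
    Yc = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    coords = U[:, :n_pcs] * s[:n_pcs]
    var_frac = s**2 / np.sum(s**2)
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=m.values.columns, columns=cols),
        var_frac,
    )


# -- statistical probes --------------------------------------------------------

@dataclass
class RankSumReport:
    """Result of a Wilcoxon rank-sum comparison between two groups."""

    group_a: pd.Series
    group_b: pd.Series
    statistic: float
    p_value: float
    alternative: str


def method_bias_test(
    coords: pd.DataFrame, samples: list[SampleMeta], pc: str = "PC2"
) -> RankSumReport:
    """Test for a systematic offset between the two method classes.

    Replicates are first averaged within (study, method class), then the
    study-level values of the two classes are compared by an exact two-sided
    Wilcoxon rank-sum test.
    """
    meta = pd.DataFrame(
        {
            "study": [s.study for s in samples],
            "method_class": [s.method_class for s in samples],
        },
        index=[s.sample_id for s in samples],
    )
    df = meta.join(coords[pc])
    study_means = df.groupby(["study", "method_class"])[pc].mean()
    pulse = study_means.xs("pulse_labeling", level="method_class")
    shut = study_means.xs("transcriptional_shutoff", level="method_class")
    for name, grp in (("pulse_labeling", pulse), ("transcriptional_shutoff", shut)):
        if len(grp) < 2:
            raise ValueError(f"method class {name} has <2 study-level values")
    res = stats.mannwhitneyu(pulse, shut, alternative="two-sided", method="exact")
    return RankSumReport(pulse, shut, float(res.statistic), float(res.pvalue), "two-sided")


def celltype_specificity_test(
    m: HalfLifeMatrix, samples: list[SampleMeta] | None = None
) -> RankSumReport:
    """Do same-cell-type cross-study pairs correlate more than different-type pairs?

    Pearson correlation is computed for every pair of samples from different
    studies (same-study pairs are excluded as replicate-inflated); for
    pre-imputation matrices the correlation uses pairwise-complete genes.
    One-sided rank-sum test of same > different.
    """
    if samples is None:
        samples = m.samples
    ids = [s.sample_id for s in samples]
    same, diff = {}, {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = samples[i], samples[j]
            if a.study == b.study:
                continue
            x = m.values[a.sample_id]
            y = m.values[b.sample_id]
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                continue
            r = float(np.corrcoef(x[ok], y[ok])[0, 1])
            key = f"{a.sample_id}|{b.sample_id}"
            (same if a.cell_type == b.cell_type else diff)[key] = r
    if not same or not diff:
        raise ValueError(
            "need >=1 same-cell-type and >=1 different-cell-type cross-study pair "
            f"(got {len(same)} same, {len(diff)} different)"
        )
    s_ser = pd.Series(same, name="same")
    d_ser = pd.Series(diff, name="different")
    method = "exact" if (len(s_ser) <= 20 and len(d_ser) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(s_ser, d_ser, alternative="greater", method=method)
    return RankSumReport(s_ser, d_ser, float(res.statistic), float(res.pvalue), "greater")
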