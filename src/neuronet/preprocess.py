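"""Count filtering, log-CPM transformation, covariate screening, variance
decomposition and surrogate-variable estimation.

Transcripts with fewer than 1 CPM in more than ``max_low_samples`` samples are
removed (both thresholds are parameters); the surviving counts are transformed
to variance-stabilized log2 counts per million. Covariates are screened for
widespread expression effects by testing per-gene ANOVA/regression p-values
against uniformity (Kolmogorov-Smirnov), expression variance is decomposed
per covariate from a joint linear fit, and hidden structure is captured as
surrogate variables via an SVD of the residuals with a permutation
(parallel-analysis) rule for the number of components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("rin", "pmi", "age", "race")


class PipelineError(RuntimeError):
    """A fatal analysis-stage error."""


@dataclass
class ExpressionMatrix:
    """Filtered log-CPM values (genes x samples) with optional
    per-observation precision weights of the same shape."""

    logcpm: pd.DataFrame
    weights: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            if self.weights.shape != self.logcpm.shape:
                raise ValueError("weights shape does not match logcpm")
            w = self.weights.to_numpy()
            if not np.all(np.isfinite(w)) or (w <= 0).any():
                raise ValueError("weights must be strictly positive and finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.logcpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.logcpm.columns)


@dataclass
class CovariateScreenResult:
    """Per-covariate uniformity screen and variance decomposition."""

    anova_pvalues: dict[str, pd.Series] = field(default_factory=dict)
    ks_statistic: dict[str, float] = field(default_factory=dict)
    ks_pvalue: dict[str, float] = field(default_factory=dict)
    widespread: dict[str, bool] = field(default_factory=dict)
    variance_fraction: pd.DataFrame | None = None  # genes x (covariates+residual)

    def summary(self) -> pd.DataFrame:
        rows = []
        for cov in self.ks_statistic:
            row = {
                "covariate": cov,
                "ks_statistic": self.ks_statistic[cov],
                "ks_pvalue": self.ks_pvalue[cov],
                "widespread": self.widespread[cov],
            }
            if (
                self.variance_fraction is not None
                and cov in self.variance_fraction.columns
            ):
                row["median_variance_fraction"] = float(
                    self.variance_fraction[cov].median()
                )
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SurrogateVariables:
    """Estimated hidden covariates: samples x n_sv scores plus the
    permutation p-value of each tested residual component."""

    sv_matrix: pd.DataFrame
    n_sv: int
    eigenvalue_pvalues: np.ndarray


# ---------------------------------------------------------------------------
# design helpers


def build_design(
    meta: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    include_status: bool = True,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Model matrix: intercept, status (control=0, case=1), standardized
    continuous covariates, one-hot categorical covariates (first level as
    reference), plus optional extra columns (e.g. surrogate variables)."""
    n = len(meta)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(n)}
    if include_status:
        cols["status"] = (meta["status"] == "case").to_numpy(dtype=float)
    for cov in covariates:
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            sd = col.std(ddof=0)
            if sd == 0:
                logger.warning("covariate %r is constant; excluded from design", cov)
                continue
            cols[cov] = ((col - col.mean()) / sd).to_numpy()
        else:
            levels = sorted(col.astype(str).unique())
            for lv in levels[1:]:
                cols[f"{cov}[{lv}]"] = (col.astype(str) == lv).to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=meta["sample_id"].to_numpy())
    if extra is not None:
        for c in extra.columns:
            design[c] = np.asarray(extra[c])
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # report the columns whose removal restores rank
        bad = []
        for j, name in enumerate(design.columns):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise PipelineError(f"design matrix is rank deficient; collinear columns: {bad}")


def _hat_matrix(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q @ q.T


# ---------------------------------------------------------------------------
# filtering and transformation


class LowExpressionFilter(TransformerMixin, BaseEstimator):
    """Remove genes with CPM below ``cpm_threshold`` in more than
    ``max_low_samples`` samples (X is samples x genes; CPM is computed on the
    raw integer scale without a prior count)."""

    def __init__(self, cpm_threshold: float = 1.0, max_low_samples: int = 10):
        self.cpm_threshold = cpm_threshold
        self.max_low_samples = max_low_samples

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.library_size_ = X.sum(axis=1)
        if (self.library_size_ <= 0).any():
            raise PipelineError("sample with zero total counts")
        cpm = X / self.library_size_[:, None] * 1e6
        n_low = (cpm < self.cpm_threshold).sum(axis=0)
        self.support_ = n_low <= self.max_low_samples
        if not self.support_.any():
            raise PipelineError(
                "all transcripts removed by the expression filter; "
                "review cpm_threshold / max_low_samples"
            )
        return self

    def transform(self, X):
        X = np.asarray(X)
        return X[:, self.support_]

    def get_support(self) -> np.ndarray:
        return self.support_


def filter_low_expression(
    counts: CountMatrix, cpm_threshold: float = 1.0, max_low_samples: int = 10
) -> CountMatrix:
    """Spec'd filter rule on a CountMatrix. Library sizes are carried over
    from the matrix (pre-filter column sums), so filtering does not redefine
    sequencing depth. Idempotent."""
    cpm = counts.counts.to_numpy() / counts.library_size.to_numpy()[None, :] * 1e6
    n_low = (cpm < cpm_threshold).sum(axis=1)
    keep = n_low <= max_low_samples
    if not keep.any():
        raise PipelineError(
            "all transcripts removed by the expression filter; "
            "review cpm_threshold / max_low_samples"
        )
    return CountMatrix(
        counts=counts.counts.loc[keep], library_size=counts.library_size
    )


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    reference: int | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    Per sample, the log2 ratio to a reference sample (the one whose upper
    quartile is closest to the mean upper quartile) is averaged over genes
    after trimming the extremes of the M (log-ratio) and A (log-abundance)
    distributions, weighting by approximate inverse variances.
    """
    arr = counts.counts.to_numpy(dtype=float)
    lib = counts.library_size.to_numpy(dtype=float)
    frac = arr / lib[None, :]
    if reference is None:
        uq = np.array([np.quantile(frac[:, j][frac[:, j] > 0], 0.75)
                       for j in range(arr.shape[1])])
        reference = int(np.argmin(np.abs(uq - uq.mean())))
    log_factors = np.zeros(arr.shape[1])
    fr = frac[:, reference]
    for j in range(arr.shape[1]):
        if j == reference:
            continue
        fj = frac[:, j]
        ok = (fj > 0) & (fr > 0)
        m = np.log2(fj[ok] / fr[ok])
        a = 0.5 * np.log2(fj[ok] * fr[ok])
        w = 1.0 / (
            (lib[j] - arr[ok, j].clip(min=1)) / (lib[j] * arr[ok, j].clip(min=1))
            + (lib[reference] - arr[ok, reference].clip(min=1))
            / (lib[reference] * arr[ok, reference].clip(min=1))
        )
        m_lo, m_hi = np.quantile(m, [trim_m, 1 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if keep.sum() >= 1:
            log_factors[j] = np.average(m[keep], weights=w[keep])
    log_factors -= log_factors.mean()
    return pd.Series(2.0**log_factors, index=counts.sample_ids)


def log_cpm(
    counts: CountMatrix, prior_count: float = 0.5, normalize: str = "none"
) -> ExpressionMatrix:
    """log2((count + prior) / (effective library + 2 * prior) * 1e6).

    ``normalize="tmm"`` scales library sizes by TMM factors before the
    transform; the default is no normalization (no such step is part of the
    reference analysis).
    """
    lib = counts.library_size.to_numpy(dtype=float)
    if normalize == "tmm":
        lib = lib * tmm_factors(counts).to_numpy()
    elif normalize != "none":
        raise ValueError(f"unknown normalization {normalize!r}")
    arr = counts.counts.to_numpy(dtype=float)
    vals = np.log2((arr + prior_count) / (lib + 2.0 * prior_count)[None, :] * 1e6)
    return ExpressionMatrix(
        logcpm=pd.DataFrame(
            vals, index=counts.counts.index, columns=counts.counts.columns
        )
    )


# ---------------------------------------------------------------------------
# covariate screening


def _covariate_f_pvalues(Y: np.ndarray, x: pd.Series) -> np.ndarray | None:
    """Per-gene F-test p-values for a single covariate (regression F for
    continuous, one-way ANOVA F for categorical). Y is genes x samples."""
    n = Y.shape[1]
    if pd.api.types.is_numeric_dtype(x):
        if x.std(ddof=0) == 0:
            return None
        Xc = (x - x.mean()).to_numpy()[:, None]
    else:
        levels = sorted(x.astype(str).unique())
        if len(levels) < 2:
            return None
        dummies = np.column_stack(
            [(x.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
        Xc = dummies - dummies.mean(axis=0)
    df1 = np.linalg.matrix_rank(Xc)
    df2 = n - 1 - df1
    if df2 <= 0:
        return None
    Yc = Y - Y.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(Xc)
    proj = Yc @ q  # genes x df1
    ess = (proj**2).sum(axis=1)
    tss = (Yc**2).sum(axis=1)
    tss = np.where(tss == 0, np.nan, tss)
    rss = np.clip(tss - ess, 1e-300, None)
    F = (ess / df1) / (rss / df2)
    p = scipy.stats.f.sf(F, df1, df2)
    return np.where(np.isnan(tss), 1.0, p)


def screen_covariates(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    alpha: float = 0.01,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> CovariateScreenResult:
    """Flag covariates with widespread expression effects.

    For each covariate, per-gene p-values (single-covariate F-tests) are
    tested against Uniform(0, 1) with a one-sample KS test; ``widespread``
    means KS p < alpha.
    """
    Y = expr.logcpm.to_numpy(dtype=float)
    result = CovariateScreenResult()
    for cov in covariates:
        if cov not in meta.columns:
            raise KeyError(f"covariate {cov!r} not in metadata")
        pvals = _covariate_f_pvalues(Y, meta[cov])
        if pvals is None:
            logger.warning("covariate %r is constant; excluded from screen", cov)
            continue
        ks = scipy.stats.kstest(pvals, "uniform")
        result.anova_pvalues[cov] = pd.Series(pvals, index=expr.gene_ids)
        result.ks_statistic[cov] = float(ks.statistic)
        result.ks_pvalue[cov] = float(ks.pvalue)
        result.widespread[cov] = bool(ks.pvalue < alpha)
    return result


def variance_fractions(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    result: CovariateScreenResult | None = None,
) -> CovariateScreenResult:
    """Decompose per-gene expression variance across covariates.

    All covariates enter one joint linear model; each covariate's share is its
    drop-one increment in R^2, rescaled so the shares sum to the full-model
    R^2 (exact for orthogonal designs), with residual = 1 - R^2.
    """
    design = build_design(meta, covariates, include_status=False)
    _check_full_rank(design)
    if design.shape[1] >= design.shape[0]:
        raise PipelineError("covariate design has rank >= n_samples")
    Y = expr.logcpm.to_numpy(dtype=float)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    tss = (Yc**2).sum(axis=1)
    tss = np.where(tss == 0, np.nan, tss)

    def r2_for(cols: list[str]) -> np.ndarray:
        X = design[cols].to_numpy(dtype=float)
        H = _hat_matrix(X)
        fitted = Yc @ H.T
        return ((fitted**2).sum(axis=1)) / tss

    groups = {
        cov: [c for c in design.columns if c == cov or c.startswith(f"{cov}[")]
        for cov in covariates
    }
    groups = {cov: cols for cov, cols in groups.items() if cols}
    all_cols = list(design.columns)
    r2_full = r2_for(all_cols)
    delta = {}
    for cov, cols in groups.items():
        reduced = [c for c in all_cols if c not in cols]
        delta[cov] = np.clip(r2_full - r2_for(reduced), 0.0, None)
    total_delta = np.sum(list(delta.values()), axis=0)
    scale = np.where(total_delta > 0, r2_full / np.where(total_delta > 0, total_delta, 1.0), 0.0)
    frac = {cov: d * scale for cov, d in delta.items()}
    table = pd.DataFrame(frac, index=expr.gene_ids)
    table["residual"] = 1.0 - table.sum(axis=1)
    table = table.fillna(0.0)
    if result is None:
        result = CovariateScreenResult()
    result.variance_fraction = table
    return result


# ---------------------------------------------------------------------------
# surrogate variables


class SurrogateVariableAnalysis(BaseEstimator, TransformerMixin):
    """Hidden-covariate estimation from design residuals.

    Expression (samples x genes) is residualized on the known design; the
    number of surrogate variables is the number of leading residual singular
    values exceeding their permutation null (per-gene shuffles, parallel
    analysis) at ``alpha``. Fitted attributes: ``surrogate_variables_``
    (samples x n_sv, orthonormal), ``n_sv_``, ``pvalues_``.
    """

    def __init__(self, n_perm: int = 100, alpha: float = 0.05, random_state: int | None = None):
        self.n_perm = n_perm
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, design=None):
        X = np.asarray(X, dtype=float)
        if design is None:
            design = np.ones((X.shape[0], 1))
        Xd = np.asarray(design, dtype=float)
        rank = np.linalg.matrix_rank(Xd)
        H = _hat_matrix(Xd)
        R = X - H @ X  # samples x genes residuals
        max_k = X.shape[0] - rank
        u, s, vt = np.linalg.svd(R, full_matrices=False)
        s = s[:max_k]
        # parallel analysis on variance PROPORTIONS: comparing raw singular
        # values against row-permutation nulls over-selects on correlated
        # data (every observed value beats a null that has destroyed all
        # correlation); proportions deflate trailing components once the
        # leading ones absorb real structure
        obs_stat = s**2 / (s**2).sum()
        rng = np.random.default_rng(self.random_state)
        null = np.empty((self.n_perm, len(s)))
        Rt = R.T.copy()  # genes x samples; permute within each gene
        for b in range(self.n_perm):
            Rp = rng.permuted(Rt, axis=1)
            vals = np.linalg.svd(Rp, compute_uv=False)[: len(s)] ** 2
            null[b] = vals / vals.sum()
        pvals = (1.0 + (null >= obs_stat[None, :]).sum(axis=0)) / (self.n_perm + 1.0)
        n_sv = 0
        for p in pvals:
            if p < self.alpha:
                n_sv += 1
            else:
                break
        self.singular_values_ = s
        self.pvalues_ = pvals
        self.n_sv_ = n_sv
        self.surrogate_variables_ = u[:, :n_sv]
        return self

    def fit_transform(self, X, design=None, **fit_params):
        return self.fit(X, design).surrogate_variables_

    def transform(self, X=None):
        return self.surrogate_variables_


def estimate_surrogate_variables(
    expr: ExpressionMatrix,
    known_design: pd.DataFrame,
    n_perm: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> SurrogateVariables:
    """Spec'd wrapper over :class:`SurrogateVariableAnalysis`."""
    est = SurrogateVariableAnalysis(n_perm=n_perm, alpha=alpha, random_state=seed)
    est.fit(expr.logcpm.to_numpy(dtype=float).T, known_design.to_numpy(dtype=float))
    sv = pd.DataFrame(
        est.surrogate_variables_,
        index=expr.sample_ids,
        columns=[f"sv{i + 1}" for i in range(est.n_sv_)],
    )
    return SurrogateVariables(sv_matrix=sv, n_sv=est.n_sv_, eigenvalue_pvalues=est.pvalues_)


def residualize(
    expr: ExpressionMatrix,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> ExpressionMatrix:
    """Remove known covariate effects (not status) from log-CPM; the
    covariate-corrected matrix feeds the co-expression analysis."""
    design = build_design(meta, covariates, include_status=False)
    _check_full_rank(design)
    H = _hat_matrix(design.to_numpy(dtype=float))
    Y = expr.logcpm.to_numpy(dtype=float)
    resid = Y - Y @ H.T
    # keep gene means so the matrix still looks like expression
    resid += Y.mean(axis=1, keepdims=True)
    return ExpressionMatrix(
        logcpm=pd.DataFrame(resid, index=expr.gene_ids, columns=expr.sample_ids)
    )
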