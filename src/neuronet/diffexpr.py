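"""Precision-weighted, covariate-adjusted differential expression with
empirical-Bayes moderation.

The count mean-variance relationship is estimated by a lowess trend of the
square-root residual standard deviation against mean log2 count; predicted
per-observation standard deviations are inverted to precision weights
(sd^-4). Per-gene weighted least squares on the full design is followed by
moderation of the residual variances: a scaled inverse-chi-square prior whose
degrees of freedom and scale are moment-matched on the log residual
variances (Smyth-style), yielding moderated t statistics with
``residual df + prior df`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .preprocess import ExpressionMatrix, PipelineError, log_cpm


@dataclass
class MeanVarianceTrend:
    """Lowess curve mapping mean log2 count to sqrt(residual sd)."""

    x: np.ndarray
    y: np.ndarray
    span: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(x, self.x[0], self.x[-1])
        return np.interp(x, self.x, self.y)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma, limma-style)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / scipy.special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior on residual variances.

    Returns (prior_df, prior_var); prior_df is ``inf`` when the observed
    log-variance spread is no larger than the chi-square sampling spread.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - scipy.special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0 = float(
        np.exp(e_mean + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0


class VoomModeratedDE(BaseEstimator):
    """Voom-style weighted DE estimator (sklearn surface).

    fit(X, design) with X integer counts of shape (n_samples, n_genes) and a
    full-rank design DataFrame containing ``coef``. Fitted attributes:
    ``weights_`` (n_samples x n_genes), ``trend_``, ``results_`` (per-gene
    table), ``prior_df_``, ``prior_var_``.
    """

    def __init__(
        self,
        coef: str = "status",
        span: float = 0.5,
        prior_count: float = 0.5,
        prior_df: float | str = "auto",
        nominal_alpha: float = 0.05,
    ):
        self.coef = coef
        self.span = span
        self.prior_count = prior_count
        self.prior_df = prior_df
        self.nominal_alpha = nominal_alpha

    # -- voom weights -------------------------------------------------------

    def _voom(self, counts: np.ndarray, design: np.ndarray, lib: np.ndarray):
        n, g = counts.shape
        p = np.linalg.matrix_rank(design)
        if p >= n:
            raise PipelineError("design rank >= n_samples; no residual df")
        y = np.log2(
            (counts + self.prior_count) / (lib + 2 * self.prior_count)[:, None] * 1e6
        )
        q, _ = np.linalg.qr(design)
        fitted = q @ (q.T @ y)
        resid = y - fitted
        sigma = np.sqrt((resid**2).sum(axis=0) / (n - p))
        sqrt_sd = np.sqrt(np.clip(sigma, 1e-8, None))
        mean_logcount = y.mean(axis=0) + np.log2(np.exp(np.mean(np.log(lib + 1.0)))) - np.log2(1e6)
        smooth = lowess(sqrt_sd, mean_logcount, frac=self.span, return_sorted=True)
        xs, ys = smooth[:, 0], np.clip(smooth[:, 1], 1e-4, None)
        xs, uniq = np.unique(xs, return_index=True)
        trend = MeanVarianceTrend(x=xs, y=ys[uniq], span=self.span)
        lam = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[:, None]
        w = trend.predict(lam) ** -4.0
        return y, w, trend

    # -- moderated fit ------------------------------------------------------

    def _wls(self, y: np.ndarray, w: np.ndarray, design: np.ndarray, j: int):
        """Per-gene WLS: returns coef, unscaled coef variance, residual s2."""
        n, g = y.shape
        p = design.shape[1]
        beta = np.empty(g)
        var_unscaled = np.empty(g)
        s2 = np.empty(g)
        for i in range(g):
            sw = np.sqrt(w[:, i])
            Xw = design * sw[:, None]
            yw = y[:, i] * sw
            coefs, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            resid = yw - Xw @ coefs
            xtx_inv = np.linalg.pinv(Xw.T @ Xw)
            beta[i] = coefs[j]
            var_unscaled[i] = xtx_inv[j, j]
            s2[i] = (resid**2).sum() / (n - p)
        return beta, var_unscaled, s2

    def fit(self, X, design):
        counts = np.asarray(X, dtype=float)
        if not isinstance(design, pd.DataFrame):
            raise TypeError("design must be a DataFrame with named columns")
        if self.coef not in design.columns:
            raise KeyError(f"coefficient {self.coef!r} not in design")
        Xd = design.to_numpy(dtype=float)
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise PipelineError("design matrix is rank deficient")
        lib = counts.sum(axis=1)
        y, w, trend = self._voom(counts, Xd, lib)
        self.trend_ = trend
        self.weights_ = w
        j = list(design.columns).index(self.coef)
        n, p = Xd.shape
        beta, var_unscaled, s2 = self._wls(y, w, Xd, j)
        df_resid = n - p
        if df_resid <= 0:
            raise PipelineError("zero residual degrees of freedom")
        if self.prior_df == "auto":
            d0, s0 = fit_variance_prior(s2, df_resid)
        else:
            d0 = float(self.prior_df)
            _, s0 = fit_variance_prior(s2, df_resid)
            if not np.isinf(d0):
                # moment-matched scale conditional on the forced df
                e = np.log(s2[s2 > 0]) - scipy.special.digamma(df_resid / 2) + np.log(df_resid / 2)
                s0 = float(np.exp(e.mean() + scipy.special.digamma(d0 / 2) - np.log(d0 / 2)))
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0)
            df_total = np.inf
        else:
            s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
            df_total = df_resid + d0
        t = beta / np.sqrt(var_unscaled * s2_post)
        if np.isinf(df_total):
            pvals = 2.0 * scipy.stats.norm.sf(np.abs(t))
        else:
            pvals = 2.0 * scipy.stats.t.sf(np.abs(t), df_total)
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        self.prior_df_ = d0
        self.prior_var_ = s0
        self.df_residual_ = df_resid
        self.df_total_ = df_total
        self.s2_post_ = s2_post
        self.results_ = pd.DataFrame(
            {
                "log2fc": beta,
                "mean_logcpm": y.mean(axis=0),
                "moderated_t": t,
                "pvalue": pvals,
                "bh_fdr": fdr,
                "significant": pvals < self.nominal_alpha,
            }
        )
        return self


@dataclass
class DEResult:
    """Per-gene DE table (log2fc is case minus control) plus moderation
    metadata."""

    table: pd.DataFrame
    prior_df: float
    prior_var: float
    df_residual: int
    nominal_alpha: float = 0.05

    @property
    def significant_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["significant"]])

    @property
    def upregulated_genes(self) -> frozenset[str]:
        up = self.table["significant"] & (self.table["log2fc"] > 0)
        return frozenset(self.table.index[up])


def voom_weights(
    counts: CountMatrix, design: pd.DataFrame, span: float = 0.5, prior_count: float = 0.5
) -> ExpressionMatrix:
    """Log-CPM with voom precision weights for the given design."""
    est = VoomModeratedDE(span=span, prior_count=prior_count, coef=design.columns[0])
    Xd = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise PipelineError("design matrix is rank deficient")
    arr = counts.counts.to_numpy(dtype=float).T  # samples x genes
    lib = counts.library_size.to_numpy(dtype=float)
    y, w, trend = est._voom(arr, Xd, lib)
    logcpm = log_cpm(counts, prior_count=prior_count).logcpm
    weights = pd.DataFrame(w.T, index=counts.gene_ids, columns=counts.sample_ids)
    expr = ExpressionMatrix(logcpm=logcpm, weights=weights)
    return expr


def moderated_fit(
    expr: ExpressionMatrix,
    design: pd.DataFrame,
    coef: str = "status",
    prior_df: float | str = "auto",
    nominal_alpha: float = 0.05,
) -> DEResult:
    """Weighted least squares + empirical-Bayes moderated t for ``coef``.

    Operates on an ExpressionMatrix that already carries voom weights (or
    unit weights when absent).
    """
    if coef not in design.columns:
        raise KeyError(f"coefficient {coef!r} not in design")
    Xd = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise PipelineError("design matrix is rank deficient")
    y = expr.logcpm.to_numpy(dtype=float).T  # samples x genes
    if expr.weights is not None:
        w = expr.weights.to_numpy(dtype=float).T
    else:
        w = np.ones_like(y)
    est = VoomModeratedDE(coef=coef, prior_df=prior_df, nominal_alpha=nominal_alpha)
    j = list(design.columns).index(coef)
    n, p = Xd.shape
    df_resid = n - p
    if df_resid <= 0:
        raise PipelineError("zero residual degrees of freedom")
    beta, var_unscaled, s2 = est._wls(y, w, Xd, j)
    if prior_df == "auto":
        d0, s0 = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        e = np.log(s2[s2 > 0]) - scipy.special.digamma(df_resid / 2) + np.log(df_resid / 2)
        if np.isinf(d0):
            s0 = float(np.exp(e.mean()))
        else:
            s0 = float(np.exp(e.mean() + scipy.special.digamma(d0 / 2) - np.log(d0 / 2)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
        tvals = beta / np.sqrt(var_unscaled * s2_post)
        pvals = 2.0 * scipy.stats.norm.sf(np.abs(tvals))
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
        tvals = beta / np.sqrt(var_unscaled * s2_post)
        pvals = 2.0 * scipy.stats.t.sf(np.abs(tvals), df_total)
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {
            "log2fc": beta,
            "mean_logcpm": y.mean(axis=0),
            "moderated_t": tvals,
            "pvalue": pvals,
            "bh_fdr": fdr,
            "significant": pvals < nominal_alpha,
        },
        index=expr.gene_ids,
    )
    return DEResult(
        table=table,
        prior_df=d0,
        prior_var=s0,
        df_residual=df_resid,
        nominal_alpha=nominal_alpha,
    )


def signature_composition(
    de: DEResult, anno: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Biotype counts among genes with p < alpha (the DE signature)."""
    sig = de.table.index[de.table["pvalue"] < alpha]
    biotype = anno.set_index("gene_id")["biotype"]
    counts = biotype.reindex(sig).fillna("unknown").value_counts()
    out = counts.rename_axis("biotype").reset_index(name="n_significant")
    out["fraction"] = out["n_significant"] / max(len(sig), 1)
    return out


def biotype_overrepresentation(
    de: DEResult, anno: pd.DataFrame, group: set[str] | frozenset[str]
):
    """Fisher test of biotype-group membership against DE significance, with
    all tested genes as background."""
    from .enrichment import fisher_enrichment

    if not group:
        raise ValueError("biotype group must be non-empty")
    biotype = anno.set_index("gene_id")["biotype"]
    background = frozenset(de.table.index)
    in_group = frozenset(
        g for g in background if biotype.get(g, "unknown") in group
    )
    return fisher_enrichment(in_group, de.significant_genes, background)
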