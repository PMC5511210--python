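"""Exact 2x2 enrichment machinery shared by every intersection analysis:
module x DE, hub x DE, module x gene set, biotype x DE.

The two-sided Fisher p-value sums hypergeometric probabilities no larger
than the observed table's. The odds ratio is the sample OR (ad/bc) with a
Haldane-Anscombe 0.5 correction when any cell is zero, and the 95% CI uses
the Woolf logit method on the (corrected) table. Multiple-testing control is
Bonferroni (over modules) or Benjamini-Hochberg (over gene sets).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .coexpression import ModuleAssignment
from .diffexpr import DEResult


@dataclass
class EnrichmentResult:
    """2x2 table (a=in-set&in-target, b=in-set only, c=in-target only,
    d=neither) with OR, Woolf CI and exact p."""

    table: tuple[int, int, int, int]
    odds_ratio: float
    ci_low: float
    ci_high: float
    pvalue: float
    corrected_p: float | None = None
    method: str | None = None
    name: str | None = None
    is_negative_control: bool = False

    @property
    def background_size(self) -> int:
        return sum(self.table)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities at most
    the observed one (relative tie tolerance 1e-7)."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = scipy.stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(p, 1.0)


def _odds_ratio_ci(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    cells = np.array([a, b, c, d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    se = float(np.sqrt((1.0 / cells).sum()))
    log_or = np.log(or_)
    return float(or_), float(np.exp(log_or - 1.96 * se)), float(np.exp(log_or + 1.96 * se))


def fisher_table(a: int, b: int, c: int, d: int, name: str | None = None) -> EnrichmentResult:
    """Enrichment result from explicit 2x2 cell counts."""
    or_, lo, hi = _odds_ratio_ci(a, b, c, d)
    return EnrichmentResult(
        table=(a, b, c, d),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        pvalue=fisher_exact_p(a, b, c, d),
        name=name,
    )


def fisher_enrichment(
    set_a: frozenset[str] | set[str],
    set_b: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    name: str | None = None,
) -> EnrichmentResult:
    """Fisher exact test of the overlap of two gene sets within a background."""
    background = frozenset(background)
    if not background:
        raise ValueError("background is empty")
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    stray = (set_a | set_b) - background
    if stray:
        raise ValueError(
            f"sets contain genes outside the background: {sorted(stray)[:10]}"
        )
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(background) - a - b - c
    return fisher_table(a, b, c, d, name=name)


def module_de_enrichment(
    assignment: ModuleAssignment, de: DEResult
) -> list[EnrichmentResult]:
    """Per-module Fisher enrichment of DE genes, Bonferroni-corrected over
    modules; grey genes stay in the background but are not tested."""
    background = frozenset(assignment.module_of_gene.index) & frozenset(de.table.index)
    sig = de.significant_genes & background
    modules = assignment.modules
    results = []
    for m in modules:
        members = frozenset(assignment.members(m)) & background
        res = fisher_enrichment(members, sig, background, name=m)
        results.append(res)
    n_tests = max(len(modules), 1)
    for res in results:
        res.corrected_p = min(1.0, res.pvalue * n_tests)
        res.method = "bonferroni"
    return results


def hub_de_enrichment(
    assignment: ModuleAssignment, de: DEResult, module: str
) -> EnrichmentResult:
    """Fisher test of a module's hubs against upregulated DE genes, with all
    network genes as the background."""
    hubs = frozenset(assignment.hubs(module))
    if not hubs:
        raise ValueError(f"module {module!r} has no hubs")
    background = frozenset(assignment.module_of_gene.index) & frozenset(de.table.index)
    up = de.upregulated_genes & background
    res = fisher_enrichment(hubs & background, up, background, name=f"{module}_hubs")
    return res


def geneset_enrichment(
    target: frozenset[str] | set[str],
    collection,
    background: frozenset[str] | set[str],
    negative_control: str | None = None,
) -> list[EnrichmentResult]:
    """One Fisher test per collection set with BH correction across sets.

    Set members are intersected with the background before testing; the
    negative-control set (if named) is flagged in the output.
    """
    background = frozenset(background)
    target = frozenset(target) & background
    results = []
    for name in collection:
        members = frozenset(collection[name]) & background
        res = fisher_enrichment(members, target, background, name=name)
        res.is_negative_control = name == negative_control
        results.append(res)
    if results:
        _, adj, _, _ = multipletests([r.pvalue for r in results], method="fdr_bh")
        for res, q in zip(results, adj):
            res.corrected_p = float(q)
            res.method = "bh"
    return results


def enrichment_report(results: list[EnrichmentResult], target: str = "") -> pd.DataFrame:
    rows = []
    for r in results:
        a, b, c, d = r.table
        rows.append(
            {
                "target": target,
                "set": r.name,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pvalue": r.pvalue,
                "corrected_p": r.corrected_p,
                "method": r.method,
                "is_negative_control": r.is_negative_control,
            }
        )
    return pd.DataFrame(rows)
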