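"""Weighted gene co-expression network analysis.

Pairwise Pearson correlations are raised to a soft-threshold power beta
(unsigned, |r|^beta, so adjacency lies in [0, 1]); the adjacency is
transformed to the topological overlap matrix (TOM), which credits shared
neighbours; genes are clustered by average-linkage on 1 - TOM and modules are
cut from the dendrogram subject to a minimum size, with unassigned genes
collected in the grey module. Module activity is summarized by the eigengene
(first principal component across samples), module reproducibility by a
resampling/permutation Z score (Z < 2 weak, Z > 10 strong evidence), and
eigengene-status association by the Kruskal-Wallis test. Hubs are the top 10%
most intramodularly connected members of each module.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from sklearn.base import BaseEstimator, ClusterMixin

from .preprocess import ExpressionMatrix, PipelineError

logger = logging.getLogger(__name__)

GREY = "grey"

# WGCNA's conventional color sequence, assigned by decreasing module size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


@dataclass
class SoftThresholdResult:
    table: pd.DataFrame  # power, scale_free_r2, slope, mean_connectivity
    chosen_beta: int


@dataclass
class NetworkModel:
    """Adjacency/TOM matrices with per-gene whole-network connectivity.

    ``expression`` keeps the (standardized-on-demand) genes x samples matrix
    the network was built from, so module detection can score branch
    coherence against a sample-permutation null.
    """

    adjacency: np.ndarray
    connectivity: np.ndarray
    beta: int
    gene_ids: list[str]
    tom: np.ndarray | None = None
    expression: np.ndarray | None = None


@dataclass
class ModuleAssignment:
    """Gene -> module colors, intramodular connectivity and hub flags."""

    module_of_gene: pd.Series  # gene id -> color (grey = unassigned)
    kim: pd.Series  # intramodular connectivity
    hub_flag: pd.Series
    module_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.module_sizes if m != GREY]

    def members(self, module: str) -> list[str]:
        return list(self.module_of_gene.index[self.module_of_gene == module])

    def hubs(self, module: str) -> list[str]:
        mask = (self.module_of_gene == module) & self.hub_flag
        return list(self.module_of_gene.index[mask])


@dataclass
class ModuleSummary:
    """Per-module eigengene and association/robustness statistics."""

    eigengene: pd.Series  # per-sample, unit norm
    variance_explained: float
    robustness_z: float | None = None
    kw_statistic: float | None = None
    kw_pvalue: float | None = None


# ---------------------------------------------------------------------------
# scale-free fit and soft threshold


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 p(k) regressed on log10 k.

    Connectivities are histogrammed into ``n_bins`` equal-width bins (empty
    bins dropped); the fit uses each bin's mean connectivity and occupancy
    fraction.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        raise PipelineError("connectivity values have no spread")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            continue
        xs.append(k[sel].mean())
        ys.append(sel.mean())
    if len(xs) < 3:
        raise PipelineError("too few occupied connectivity bins for a scale-free fit")
    lx, ly = np.log10(xs), np.log10(ys)
    slope, intercept, r, _, _ = scipy.stats.linregress(lx, ly)
    return float(r**2), float(slope)


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: range | list[int] = range(1, 21),
    r2_cut: float = 0.8,
    n_bins: int = 10,
) -> SoftThresholdResult:
    """Scan candidate powers for scale-free topology fit.

    chosen_beta is the smallest power reaching ``r2_cut`` with a negative
    slope, falling back to the power with the best R^2.
    """
    Y = expr.logcpm.to_numpy(dtype=float)
    if Y.shape[0] < 30:
        raise PipelineError("need at least 30 genes to assess scale-free fit")
    abs_cor = np.abs(np.corrcoef(Y))
    np.fill_diagonal(abs_cor, 0.0)
    rows = []
    for p in powers:
        a = abs_cor**p
        k = a.sum(axis=1)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {
                "power": int(p),
                "scale_free_r2": r2,
                "slope": slope,
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[(table["scale_free_r2"] >= r2_cut) & (table["slope"] < 0)]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        beta = int(table.loc[table["scale_free_r2"].idxmax(), "power"])
    return SoftThresholdResult(table=table, chosen_beta=beta)


# ---------------------------------------------------------------------------
# adjacency and TOM


def adjacency_matrix(
    expr: ExpressionMatrix, beta: int, signed: bool = False
) -> NetworkModel:
    """Soft-threshold adjacency |cor|^beta (or ((1+cor)/2)^beta when signed)
    with unit diagonal; connectivity k = row sums - 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    Y = expr.logcpm.to_numpy(dtype=float)
    sd = Y.std(axis=1)
    if (sd == 0).any():
        bad = [expr.gene_ids[i] for i in np.where(sd == 0)[0][:10]]
        raise PipelineError(f"zero-variance genes cannot enter the network: {bad}")
    cor = np.corrcoef(Y)
    cor = np.clip(cor, -1.0, 1.0)
    if signed:
        a = ((1.0 + cor) / 2.0) ** beta
    else:
        a = np.abs(cor) ** beta
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    return NetworkModel(
        adjacency=a,
        connectivity=k,
        beta=int(beta),
        gene_ids=expr.gene_ids,
        expression=Y.copy(),
    )


def tom_matrix(net: NetworkModel) -> NetworkModel:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with l_ij the shared-neighbour sum and unit diagonal."""
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom = np.clip(np.nan_to_num(tom, nan=0.0), 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    np.fill_diagonal(tom, 1.0)
    net.tom = tom
    return net


# ---------------------------------------------------------------------------
# module detection


def _pve(M: np.ndarray) -> float:
    """Variance fraction explained by the first principal component of a
    (standardized) genes x samples block."""
    s = np.linalg.svd(M, compute_uv=False)
    return float(s[0] ** 2 / (s**2).sum())


def _tree_arrays(Z: np.ndarray, n: int):
    size = np.ones(2 * n - 1, dtype=int)
    left = np.full(2 * n - 1, -1, dtype=int)
    right = np.full(2 * n - 1, -1, dtype=int)
    for i in range(n - 1):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        size[n + i] = size[a] + size[b]
        left[n + i], right[n + i] = a, b
    return size, left, right


def _leaves_per_node(left: np.ndarray, right: np.ndarray, n: int) -> dict[int, list[int]]:
    leav: dict[int, list[int]] = {node: [node] for node in range(n)}
    for node in range(n, 2 * n - 1):
        leav[node] = leav[left[node]] + leav[right[node]]
    return leav


def _standardize_rows(Y: np.ndarray) -> np.ndarray:
    Ys = Y - Y.mean(axis=1, keepdims=True)
    sd = Ys.std(axis=1)
    sd[sd == 0] = 1.0
    return Ys / sd[:, None]


def _null_pve_curve(
    Ys: np.ndarray, beta: int, min_size: int, n_perm: int, rng: np.random.Generator
):
    """Node-PVE null from dendrograms of sample-permuted expression.

    Permuting each gene's samples independently destroys all co-expression
    while keeping marginals; re-clustering the permuted data reproduces the
    selection effect of agglomeration, so branch coherence can be compared
    against branches of equally "cherry-picked" null trees. Permuted rows are
    projected back onto the observed row space first: covariate-residualized
    expression lives in a reduced sample subspace, and a full-rank null would
    understate the leading-eigenvalue share (rank-mismatched
    Marchenko-Pastur), flagging spurious whole-matrix "modules".
    """
    n = Ys.shape[0]
    # orthonormal basis of the observed sample-space span
    _, svals, vt = np.linalg.svd(Ys, full_matrices=False)
    rank = int((svals > svals[0] * 1e-9).sum())
    proj = vt[:rank].T @ vt[:rank]
    null_sizes: list[int] = []
    null_pves: list[float] = []
    for _ in range(n_perm):
        Yp = rng.permuted(Ys, axis=1) @ proj
        Yp = _standardize_rows(Yp)
        with np.errstate(invalid="ignore"):
            cp = np.abs(np.nan_to_num(np.corrcoef(Yp))) ** beta
        dp = 1.0 - cp
        np.fill_diagonal(dp, 0.0)
        Zp = scipy.cluster.hierarchy.linkage(
            scipy.spatial.distance.squareform(dp, checks=False), method="average"
        )
        sizep, leftp, rightp = _tree_arrays(Zp, n)
        leavp = _leaves_per_node(leftp, rightp, n)
        for node in range(n, 2 * n - 1):
            if sizep[node] >= min_size:
                null_sizes.append(int(sizep[node]))
                null_pves.append(_pve(Yp[leavp[node]]))
    sizes_arr = np.asarray(null_sizes)
    pves_arr = np.asarray(null_pves)
    edges = np.unique(np.geomspace(min_size, max(n, min_size + 1), 12).astype(int))
    mu_x, mu_y, sd_y = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (sizes_arr >= lo) & (sizes_arr < hi) if hi != edges[-1] else (
            (sizes_arr >= lo) & (sizes_arr <= hi)
        )
        if sel.sum() >= 3:
            mu_x.append(float(np.sqrt(lo * hi)))
            mu_y.append(float(pves_arr[sel].mean()))
            sd_y.append(float(max(pves_arr[sel].std(ddof=1), 1e-3)))
    if not mu_x:
        mu_x = [float(min_size)]
        mu_y = [float(pves_arr.mean()) if pves_arr.size else 0.2]
        sd_y = [float(max(pves_arr.std(), 1e-3)) if pves_arr.size else 0.05]
    lx = np.log(mu_x)
    return (
        lambda s: float(np.interp(np.log(s), lx, mu_y)),
        lambda s: float(np.interp(np.log(s), lx, sd_y)),
    )


def _harvest_branches(
    Ys: np.ndarray,
    Z: np.ndarray,
    beta: int,
    min_size: int,
    z_min: float,
    merge_eigengene_cor: float,
    n_perm: int,
    random_state: int,
) -> np.ndarray:
    """Select coherent dendrogram branches as modules.

    Every branch of at least ``min_size`` genes is scored by the variance its
    first principal component explains, relative to same-size branches of
    sample-permuted null trees. Branches with a null z-score of at least
    ``z_min`` are claimed greedily by descending coherence mass
    ``(PVE - null_mean) * sqrt(size)`` (which peaks at the true module
    boundary of a planted block), and detected modules whose eigengenes
    correlate at ``merge_eigengene_cor`` or above are merged. Returns integer
    labels, -1 = grey.
    """
    n = Ys.shape[0]
    size, left, right = _tree_arrays(Z, n)
    leav = _leaves_per_node(left, right, n)
    cands = [node for node in range(n, 2 * n - 1) if size[node] >= min_size]
    labels = np.full(n, -1, dtype=int)
    if not cands:
        return labels
    rng = np.random.default_rng(random_state)
    null_mu, null_sd = _null_pve_curve(Ys, beta, min_size, n_perm, rng)
    score: dict[int, float] = {}
    active = set()
    for node in cands:
        p = _pve(Ys[leav[node]])
        s = size[node]
        if (p - null_mu(s)) / null_sd(s) >= z_min:
            active.add(node)
            score[node] = (p - null_mu(s)) * np.sqrt(s)
    used = np.zeros(n, dtype=bool)
    k = 0
    while active:
        best = max(active, key=lambda c: (score[c], -c))
        lv = leav[best]
        labels[lv] = k
        used[lv] = True
        k += 1
        active = {c for c in active if not used[leav[c]].any()}
    # merge modules whose eigengenes are near-collinear (split branches of
    # one underlying factor)
    changed = True
    while changed and k > 1:
        changed = False
        eigs = {}
        for kk in sorted(set(labels[labels >= 0])):
            idx = np.where(labels == kk)[0]
            eigs[kk] = np.linalg.svd(Ys[idx], full_matrices=False)[2][0]
        ks = sorted(eigs)
        for i in range(len(ks)):
            for j in range(i + 1, len(ks)):
                if abs(np.corrcoef(eigs[ks[i]], eigs[ks[j]])[0, 1]) >= merge_eigengene_cor:
                    labels[labels == ks[j]] = ks[i]
                    changed = True
                    break
            if changed:
                break
    out = np.full(n, -1, dtype=int)
    for newk, kk in enumerate(sorted(set(labels[labels >= 0]))):
        out[labels == kk] = newk
    return out


def cut_modules(
    net: NetworkModel,
    min_module_size: int = 30,
    cut_height: float | None = None,
    hub_fraction: float = 0.10,
    z_min: float = 4.0,
    merge_eigengene_cor: float = 0.8,
    n_null_trees: int = 3,
    random_state: int = 0,
) -> ModuleAssignment:
    """Detect modules from average-linkage clustering on 1 - TOM.

    With ``cut_height=None`` (default) branches are selected adaptively by
    eigengene coherence against a sample-permutation null (see
    :func:`_harvest_branches`); 1 - TOM merge heights compress into a narrow
    data-dependent band near 1, so no fixed height separates modules across
    datasets. A numeric ``cut_height`` instead performs the literal static
    cut at that dissimilarity. Either way, only branches of at least
    ``min_module_size`` genes become modules (labelled by decreasing size
    through the conventional color list); all other genes are grey.
    """
    if net.tom is None:
        raise PipelineError("TOM not computed; call tom_matrix first")
    genes = net.gene_ids
    n = len(genes)
    if n < min_module_size:
        logger.warning(
            "fewer genes (%d) than min_module_size (%d): all grey", n, min_module_size
        )
        return _assignment_from_labels(net, np.full(n, 0, dtype=int), hub_fraction)
    dissim = 1.0 - net.tom
    np.fill_diagonal(dissim, 0.0)
    condensed = scipy.spatial.distance.squareform(dissim, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    if cut_height is not None:
        flat = scipy.cluster.hierarchy.fcluster(Z, t=cut_height, criterion="distance")
        labels = np.zeros(n, dtype=int)  # 0 = grey
        sizes = pd.Series(flat).value_counts()
        next_label = 1
        for cluster_id, csize in sizes.items():
            if csize >= min_module_size:
                labels[flat == cluster_id] = next_label
                next_label += 1
        return _assignment_from_labels(net, labels, hub_fraction)
    if net.expression is None:
        raise PipelineError(
            "adaptive module detection needs the expression matrix on the "
            "NetworkModel; rebuild the adjacency with adjacency_matrix or "
            "pass an explicit cut_height"
        )
    Ys = _standardize_rows(net.expression)
    harvested = _harvest_branches(
        Ys,
        Z,
        beta=net.beta,
        min_size=min_module_size,
        z_min=z_min,
        merge_eigengene_cor=merge_eigengene_cor,
        n_perm=n_null_trees,
        random_state=random_state,
    )
    return _assignment_from_labels(net, harvested + 1, hub_fraction)


def _assignment_from_labels(
    net: NetworkModel, labels: np.ndarray, hub_fraction: float
) -> ModuleAssignment:
    genes = np.asarray(net.gene_ids)
    # order modules by size (desc), then by smallest member index for ties
    module_ids = [m for m in np.unique(labels) if m != 0]
    order = sorted(
        module_ids, key=lambda m: (-int((labels == m).sum()), int(np.argmax(labels == m)))
    )
    colors = np.full(len(genes), GREY, dtype=object)
    for rank, m in enumerate(order):
        name = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        colors[labels == m] = name
    module_of = pd.Series(colors, index=genes)
    a = net.adjacency.copy()
    np.fill_diagonal(a, 0.0)
    kim = np.zeros(len(genes))
    for name in pd.unique(module_of[module_of != GREY]):
        idx = np.where(module_of.to_numpy() == name)[0]
        kim[idx] = a[np.ix_(idx, idx)].sum(axis=1)
    assignment = ModuleAssignment(
        module_of_gene=module_of,
        kim=pd.Series(kim, index=genes),
        hub_flag=pd.Series(False, index=genes),
        module_sizes={
            **{
                str(name): int((module_of == name).sum())
                for name in pd.unique(module_of[module_of != GREY])
            },
            GREY: int((module_of == GREY).sum()),
        },
    )
    return find_hubs(assignment, hub_fraction=hub_fraction)


def find_hubs(assignment: ModuleAssignment, hub_fraction: float = 0.10) -> ModuleAssignment:
    """Flag the top ceil(hub_fraction * size) genes per module by
    intramodular connectivity; boundary ties resolved by gene-id order."""
    if not 0 < hub_fraction <= 1:
        raise ValueError("hub_fraction must be in (0, 1]")
    hub = pd.Series(False, index=assignment.module_of_gene.index)
    for module in assignment.modules:
        members = assignment.members(module)
        n_hubs = int(np.ceil(hub_fraction * len(members)))
        ranked = sorted(members, key=lambda g: (-assignment.kim[g], g))
        hub[ranked[:n_hubs]] = True
    assignment.hub_flag = hub
    return assignment


# ---------------------------------------------------------------------------
# eigengenes and trait association


def module_eigengene(
    expr: ExpressionMatrix, assignment: ModuleAssignment, module: str
) -> ModuleSummary:
    """First principal component of the module's standardized expression.

    The eigengene is the unit-norm first right singular vector across
    samples, sign-fixed to correlate non-negatively with the module's mean
    standardized profile.
    """
    members = assignment.members(module)
    if module == GREY or len(members) < 2:
        raise ValueError(f"module {module!r} is grey or too small for an eigengene")
    M = expr.logcpm.loc[members].to_numpy(dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1)
    sd[sd == 0] = 1.0
    M = M / sd[:, None]
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    eig = vt[0]
    mean_profile = M.mean(axis=0)
    if np.corrcoef(eig, mean_profile)[0, 1] < 0:
        eig = -eig
    var_explained = float(s[0] ** 2 / (s**2).sum())
    return ModuleSummary(
        eigengene=pd.Series(eig, index=expr.sample_ids),
        variance_explained=var_explained,
    )


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for lv in levels:
        if (groups == lv).sum() == 0:
            raise ValueError(f"group {lv!r} is empty")
    n = len(values)
    ranks = scipy.stats.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[groups == lv].sum() ** 2 / (groups == lv).sum() for lv in levels
    ) - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0:
        return 0.0, 1.0
    h /= correction
    p = float(scipy.stats.chi2.sf(h, len(levels) - 1))
    return float(h), p


def kruskal_wallis_exact(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """H plus the exact permutation p-value by enumerating all assignments
    of the observed group sizes (small n only)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    h_obs, _ = kruskal_wallis(values, groups)
    levels, counts = np.unique(groups, return_counts=True)
    n = len(values)
    if n > 12:
        raise ValueError("exact enumeration limited to n <= 12")
    idx = list(range(n))
    total = 0
    extreme = 0
    for combo in _group_assignments(idx, counts):
        h, _ = kruskal_wallis(values, combo)
        total += 1
        if h >= h_obs - 1e-12:
            extreme += 1
    return h_obs, extreme / total


def _group_assignments(idx: list[int], counts: np.ndarray):
    """Yield group-label vectors for every split of idx into the given sizes."""
    n = len(idx)
    if len(counts) == 2:
        for chosen in itertools.combinations(range(n), int(counts[0])):
            labels = np.ones(n, dtype=int)
            labels[list(chosen)] = 0
            yield labels
    else:
        remaining = set(range(n))
        def rec(level: int, rem: frozenset, labels):
            if level == len(counts) - 1:
                lab = labels.copy()
                lab[list(rem)] = level
                yield lab
                return
            for chosen in itertools.combinations(sorted(rem), int(counts[level])):
                lab = labels.copy()
                lab[list(chosen)] = level
                yield from rec(level + 1, rem - set(chosen), lab)
        yield from rec(0, frozenset(remaining), np.full(n, -1, dtype=int))


def eigengene_status_association(
    summary: ModuleSummary, meta: pd.DataFrame
) -> ModuleSummary:
    """Kruskal-Wallis association of the eigengene with case/control status."""
    status = meta.set_index("sample_id")["status"].reindex(summary.eigengene.index)
    if status.isna().any():
        raise ValueError("metadata does not cover all eigengene samples")
    h, p = kruskal_wallis(summary.eigengene.to_numpy(), status.to_numpy())
    summary.kw_statistic = h
    summary.kw_pvalue = p
    return summary


# ---------------------------------------------------------------------------
# robustness


def module_robustness(
    expr: ExpressionMatrix,
    assignment: ModuleAssignment,
    beta: int,
    n_splits: int = 50,
    n_perm: int = 200,
    seed: int | None = None,
) -> dict[str, float]:
    """Resampling module-preservation Z per module.

    Samples are repeatedly split in half; in each half an unsigned |cor|^beta
    adjacency is rebuilt. Two preservation statistics are computed per module
    — the cross-half correlation of intramodular connectivity and the mean
    within-module adjacency in the test half — each standardized against
    ``n_perm`` random gene sets of the same size. The module score is the
    median Z across statistics, averaged over splits. Z < 2 is weak and
    Z > 10 strong evidence of robustness.
    """
    rng = np.random.default_rng(seed)
    Y = expr.logcpm.to_numpy(dtype=float)
    genes = np.asarray(expr.gene_ids)
    n_genes, n_samples = Y.shape
    if n_samples < 6:
        raise PipelineError("too few samples to split for robustness")
    gene_pos = {g: i for i, g in enumerate(genes)}
    modules = {}
    for m in assignment.modules:
        members = [gene_pos[g] for g in assignment.members(m) if g in gene_pos]
        if len(members) < 3:
            logger.warning("module %s has < 3 genes in the matrix; skipped", m)
            continue
        modules[m] = np.asarray(members)
    z_accum = {m: [] for m in modules}
    for _ in range(n_splits):
        perm = rng.permutation(n_samples)
        half = n_samples // 2
        idx1, idx2 = perm[:half], perm[half:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a1 = np.abs(np.nan_to_num(np.corrcoef(Y[:, idx1]))) ** beta
            a2 = np.abs(np.nan_to_num(np.corrcoef(Y[:, idx2]))) ** beta
        np.fill_diagonal(a1, 0.0)
        np.fill_diagonal(a2, 0.0)
        for m, members in modules.items():
            obs = _preservation_stats(a1, a2, members)
            null = np.empty((n_perm, len(obs)))
            for b in range(n_perm):
                rand = rng.choice(n_genes, size=len(members), replace=False)
                null[b] = _preservation_stats(a1, a2, rand)
            mu = null.mean(axis=0)
            sd = null.std(axis=0, ddof=1)
            sd[sd == 0] = np.inf
            z = (obs - mu) / sd
            z_accum[m].append(float(np.median(z)))
    return {m: float(np.mean(zs)) for m, zs in z_accum.items()}


def _preservation_stats(a1: np.ndarray, a2: np.ndarray, members: np.ndarray) -> np.ndarray:
    sub1 = a1[np.ix_(members, members)]
    sub2 = a2[np.ix_(members, members)]
    kim1 = sub1.sum(axis=1)
    kim2 = sub2.sum(axis=1)
    if kim1.std() == 0 or kim2.std() == 0:
        cor = 0.0
    else:
        cor = float(np.corrcoef(kim1, kim2)[0, 1])
    m = len(members)
    mean_adj = float(sub2.sum() / (m * (m - 1)))
    return np.array([cor, mean_adj])


# ---------------------------------------------------------------------------
# sklearn-style front end


class CoexpressionNetwork(ClusterMixin, BaseEstimator):
    """WGCNA-style clustering estimator.

    fit(X) with X of shape (n_samples, n_genes) computes the unsigned
    soft-threshold adjacency, TOM, module labels (``labels_``; -1 = grey),
    module colors, intramodular connectivity and hubs, plus per-module
    eigengenes.
    """

    def __init__(
        self,
        beta: int = 9,
        min_module_size: int = 30,
        cut_height: float | None = None,
        hub_fraction: float = 0.10,
        signed: bool = False,
    ):
        self.beta = beta
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.hub_fraction = hub_fraction
        self.signed = signed

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        gene_ids = [f"g{i}" for i in range(X.shape[1])]
        expr = ExpressionMatrix(
            logcpm=pd.DataFrame(
                X.T, index=gene_ids, columns=[f"s{i}" for i in range(X.shape[0])]
            )
        )
        net = adjacency_matrix(expr, beta=self.beta, signed=self.signed)
        net = tom_matrix(net)
        assignment = cut_modules(
            net,
            min_module_size=self.min_module_size,
            cut_height=self.cut_height,
            hub_fraction=self.hub_fraction,
        )
        self.network_ = net
        self.assignment_ = assignment
        colors = assignment.module_of_gene.to_numpy()
        module_order = sorted(
            assignment.modules, key=lambda m: -assignment.module_sizes[m]
        )
        color_to_label = {m: i for i, m in enumerate(module_order)}
        self.labels_ = np.array(
            [color_to_label.get(c, -1) for c in colors], dtype=int
        )
        self.colors_ = colors
        self.kim_ = assignment.kim.to_numpy()
        self.hub_mask_ = assignment.hub_flag.to_numpy()
        eigs = {}
        for m in assignment.modules:
            eigs[m] = module_eigengene(expr, assignment, m).eigengene.to_numpy()
        self.eigengenes_ = pd.DataFrame(eigs) if eigs else pd.DataFrame(
            index=range(X.shape[0])
        )
        return self
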