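"""Synthetic neuronal-nuclei RNA-seq data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a case/control cohort with quality covariates (RIN, PMI, age, race),
mixed transcript biotypes, a minority of differentially expressed transcripts,
and planted co-expression modules whose shared latent factor can be shifted in
cases.

Observation model
-----------------
Per gene g and sample s the log2 expression is

    z[g, s] = latent_scale * ( sqrt(c) * f_m[s] + sqrt(1 - c) * e[g, s] )

for a member of module m with within-correlation ``c`` (``f_m`` and ``e``
standard normal, so the within-module correlation equals ``c`` exactly), and
``latent_scale * e[g, s]`` otherwise. Case samples add ``status_shift`` to the
module factor, a signed ``log2fc`` to DE genes, and gene-specific linear
covariate effects. Counts are negative-binomial with

    mean = library_size * 2**(baseline_g + z[g, s]) / 1e6

so the planted quantities live on the counts-per-million scale used by the
analysis. Everything is drawn from a single seeded RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

RACE_LEVELS = ("AA", "H", "C")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class ModuleSpec:
    """A planted co-expressed module.

    size
        number of member genes.
    within_correlation
        target pairwise Pearson correlation of the latent log expression.
    status_shift
        shift (in latent-factor standard deviations) added to the module
        factor in case samples; 0 means the module ignores status.
    """

    size: int
    within_correlation: float
    status_shift: float = 0.0


@dataclass
class DESpec:
    """Planted differential expression: ``n_de`` genes move by ``log2fc`` in
    cases, a ``fraction_up`` of them upward."""

    n_de: int
    log2fc: float
    fraction_up: float = 0.5


@dataclass
class CovariateEffect:
    """A covariate touching a random ``fraction_affected`` of genes with
    gene-specific slopes (or categorical level offsets) of sd ``effect_sd``
    log2-units per standardized covariate unit."""

    fraction_affected: float
    effect_sd: float


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_control: int = 17
    n_case: int = 19
    module_spec: Sequence[ModuleSpec] = field(default_factory=list)
    de_spec: DESpec = field(default_factory=lambda: DESpec(n_de=0, log2fc=0.0))
    biotype_proportions: Mapping[str, float] = field(
        default_factory=lambda: {"protein_coding": 1.0}
    )
    covariate_effects: Mapping[str, CovariateEffect] = field(default_factory=dict)
    dispersion: float = 0.005
    mean_log_expression: float = 6.0
    gene_mean_sd: float = 1.2
    latent_scale: float = 0.6
    library_size_range: tuple[int, int] = (1_500_000, 2_500_000)
    seed: int = 0

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_genes <= 0:
            errors.append("n_genes must be positive")
        if self.n_control <= 0 or self.n_case <= 0:
            errors.append("n_control and n_case must be positive")
        total_module = sum(m.size for m in self.module_spec)
        if total_module > self.n_genes:
            errors.append(
                f"module sizes sum to {total_module} > n_genes={self.n_genes}"
            )
        for i, m in enumerate(self.module_spec):
            if not 0.0 <= m.within_correlation <= 1.0:
                errors.append(f"module {i}: within_correlation not in [0, 1]")
            if m.size <= 0:
                errors.append(f"module {i}: size must be positive")
        if not 0.0 <= self.de_spec.fraction_up <= 1.0:
            errors.append("de_spec.fraction_up not in [0, 1]")
        if self.de_spec.n_de < 0 or self.de_spec.n_de > self.n_genes:
            errors.append("de_spec.n_de out of range")
        total = float(sum(self.biotype_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            errors.append(f"biotype proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.biotype_proportions.values()):
            errors.append("biotype proportions must be non-negative")
        for name, eff in self.covariate_effects.items():
            if not 0.0 <= eff.fraction_affected <= 1.0:
                errors.append(f"covariate {name}: fraction_affected not in [0, 1]")
            if eff.effect_sd < 0:
                errors.append(f"covariate {name}: effect_sd must be >= 0")
        if self.dispersion < 0:
            errors.append("dispersion must be >= 0")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            errors.append("library_size_range must be positive and ordered")
        if errors:
            raise ConfigurationError("; ".join(errors))


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset, keyed by gene id."""

    module_of_gene: dict[str, int | None]
    de_genes: dict[str, float]  # gene id -> signed true log2fc
    covariate_affected_genes: dict[str, frozenset[str]]
    status_module_indices: frozenset[int]

    def module_members(self, index: int) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == index]


def default_paper_like_config(seed: int = 0) -> SimulationConfig:
    """Study-shaped defaults: 17 control + 19 case samples, three planted
    modules (the largest status-shifted), a minority of DE transcripts, a
    protein-coding-dominated biotype mix and widespread RIN/PMI effects."""
    return SimulationConfig(
        n_genes=2000,
        n_control=17,
        n_case=19,
        module_spec=[
            ModuleSpec(size=300, within_correlation=0.6, status_shift=1.0),
            ModuleSpec(size=100, within_correlation=0.6, status_shift=0.0),
            ModuleSpec(size=50, within_correlation=0.6, status_shift=0.0),
        ],
        de_spec=DESpec(n_de=150, log2fc=1.0, fraction_up=0.6),
        biotype_proportions={
            "protein_coding": 0.55,
            "pseudogene": 0.17,
            "lincRNA": 0.12,
            "antisense": 0.08,
            "misc_RNA": 0.04,
            "snRNA": 0.025,
            "snoRNA": 0.015,
        },
        covariate_effects={
            "rin": CovariateEffect(fraction_affected=0.5, effect_sd=0.6),
            "pmi": CovariateEffect(fraction_affected=0.5, effect_sd=0.5),
            "age": CovariateEffect(fraction_affected=0.15, effect_sd=0.3),
            "race": CovariateEffect(fraction_affected=0.10, effect_sd=0.3),
        },
        seed=seed,
    )


def _race_allocation(n: int, rng: np.random.Generator) -> np.ndarray:
    """Race composition allocated deterministically within a status group
    (largest-remainder rounding of the cohort proportions, shuffled): the
    study matched race across groups, so the generator avoids chance
    race-status confounding rather than drawing labels independently."""
    props = np.array((0.40, 0.34, 0.26))
    counts = np.floor(props * n).astype(int)
    remainder = props * n - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    levels = np.repeat(RACE_LEVELS, counts)
    return rng.permutation(levels)


def _simulate_metadata(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_control + config.n_case
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    status = ["control"] * config.n_control + ["case"] * config.n_case
    rin = np.clip(rng.normal(2.9, 0.6, size=n), 1.0, None)
    pmi = np.clip(rng.normal(16.6, 5.0, size=n), 1.0, None)
    age = np.clip(rng.normal(35.0, 9.0, size=n), 18.0, None)
    # emulate the matched case/control selection: group means of the quality
    # covariates are equalized, as in the study cohort where RIN, PMI and age
    # did not differ between groups
    is_case = np.arange(n) >= config.n_control
    for vals in (rin, pmi, age):
        overall = vals.mean()
        for grp in (is_case, ~is_case):
            vals[grp] += overall - vals[grp].mean()
    race = np.concatenate(
        [_race_allocation(config.n_control, rng), _race_allocation(config.n_case, rng)]
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": status,
            "rin": np.round(rin, 3),
            "pmi": np.round(pmi, 3),
            "age": np.round(age, 1),
            "race": race,
        }
    )


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate counts, metadata, annotation and ground truth.

    Deterministic given ``config.seed``: a single RNG stream with a fixed
    draw order backs every random choice.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_samples = config.n_control + config.n_case
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]

    meta = _simulate_metadata(config, rng)
    case_mask = (meta["status"] == "case").to_numpy()

    biotypes = rng.choice(
        list(config.biotype_proportions),
        size=config.n_genes,
        p=list(config.biotype_proportions.values()),
    )
    anno = pd.DataFrame(
        {"gene_id": gene_ids, "symbol": [g.replace("G", "SYM") for g in gene_ids],
         "biotype": biotypes}
    )

    # module membership: disjoint random gene subsets
    perm = rng.permutation(config.n_genes)
    module_of = np.full(config.n_genes, -1, dtype=int)
    offset = 0
    for idx, mod in enumerate(config.module_spec):
        module_of[perm[offset : offset + mod.size]] = idx
        offset += mod.size

    # DE genes: prefer non-module genes so the two planted signals stay
    # identifiable in the truth record
    free = perm[offset:]
    n_de = config.de_spec.n_de
    if n_de <= len(free):
        de_idx = rng.choice(free, size=n_de, replace=False)
    else:
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = int(round(config.de_spec.fraction_up * n_de))
    de_sign = np.array([1.0] * n_up + [-1.0] * (n_de - n_up))

    # latent log2-expression
    noise = rng.standard_normal((config.n_genes, n_samples))
    z = noise.copy()
    for idx, mod in enumerate(config.module_spec):
        members = module_of == idx
        factor = rng.standard_normal(n_samples)
        factor = factor + mod.status_shift * case_mask
        c = mod.within_correlation
        z[members] = np.sqrt(c) * factor + np.sqrt(1.0 - c) * noise[members]
    z *= config.latent_scale

    # covariate effects on standardized covariates / categorical levels
    affected: dict[str, frozenset[str]] = {}
    for name, eff in config.covariate_effects.items():
        if name not in meta.columns:
            raise ConfigurationError(f"covariate {name!r} not in metadata")
        n_aff = int(round(eff.fraction_affected * config.n_genes))
        aff_idx = rng.choice(config.n_genes, size=n_aff, replace=False)
        col = meta[name]
        if pd.api.types.is_numeric_dtype(col):
            x = (col - col.mean()) / col.std(ddof=0)
            betas = rng.normal(0.0, eff.effect_sd, size=n_aff)
            z[aff_idx] += betas[:, None] * x.to_numpy()[None, :]
        else:
            levels = sorted(col.unique())
            codes = col.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
            offsets = rng.normal(0.0, eff.effect_sd, size=(n_aff, len(levels)))
            offsets -= offsets.mean(axis=1, keepdims=True)
            z[aff_idx] += offsets[:, codes]
        affected[name] = frozenset(gene_ids[i] for i in aff_idx)

    # planted DE shifts in cases
    if n_de:
        z[de_idx[:, None], np.where(case_mask)[0][None, :]] += (
            de_sign[:, None] * config.de_spec.log2fc
        )

    baseline = rng.normal(
        config.mean_log_expression, config.gene_mean_sd, size=config.n_genes
    )

    lo, hi = config.library_size_range
    library = rng.integers(lo, hi + 1, size=n_samples)

    log2_cpm = np.clip(baseline[:, None] + z, None, 25.0)
    mu = library[None, :] * np.exp2(log2_cpm) / 1e6
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu * config.dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(
        counts.astype(np.int64), index=gene_ids, columns=meta["sample_id"]
    )
    counts_df.columns.name = None
    # The simulated transcripts are a subset of a library of nominal depth
    # ``library``; carrying that depth (rather than the subset's column sums)
    # keeps CPM values on the planted scale and avoids the compositional
    # distortion a large planted module would otherwise inject into a small
    # simulated transcriptome.
    cm = CountMatrix(
        counts=counts_df,
        library_size=pd.Series(library, index=list(meta["sample_id"])),
    )

    truth = SimulationTruth(
        module_of_gene={
            g: (int(m) if m >= 0 else None) for g, m in zip(gene_ids, module_of)
        },
        de_genes={
            gene_ids[i]: float(s * config.de_spec.log2fc)
            for i, s in zip(de_idx, de_sign)
        },
        covariate_affected_genes=affected,
        status_module_indices=frozenset(
            i for i, m in enumerate(config.module_spec) if m.status_shift != 0.0
        ),
    )
    return cm, meta, anno, truth


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """Persist ground truth as a sidecar TSV (one row per gene)."""
    genes = sorted(truth.module_of_gene)
    rows = []
    for g in genes:
        cov = ";".join(
            sorted(c for c, gs in truth.covariate_affected_genes.items() if g in gs)
        )
        rows.append(
            {
                "gene_id": g,
                "module": truth.module_of_gene[g]
                if truth.module_of_gene[g] is not None
                else "",
                "true_log2fc": truth.de_genes.get(g, 0.0),
                "covariates_affecting": cov,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
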