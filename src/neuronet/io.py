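"""Tabular input/output: count matrices, sample metadata, transcript
annotation, gene-set collections (GMT) and stage outputs.

All tables are tab-separated UTF-8 with a mandatory header row and no
quoting, so writer/reader pairs round-trip losslessly. Count matrices can
also be exchanged as MatrixMarket (``.mtx`` plus sidecar row/column index
files). Gene identity for set intersections is the upper-cased symbol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

STATUS_LEVELS = ("control", "case")
METADATA_COLUMNS = ("sample_id", "status", "rin", "pmi", "age", "race")
ANNOTATION_COLUMNS = ("gene_id", "symbol", "biotype")


class FormatError(ValueError):
    """A parsed file violates the expected format; the message carries the
    file and the offending row/column or line."""


@dataclass
class CountMatrix:
    """Integer transcript-by-sample counts plus per-sample library sizes.

    ``library_size`` defaults to the column sums but is carried separately so
    that filtering genes does not redefine sequencing depth.
    """

    counts: pd.DataFrame
    library_size: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dup = counts.index[counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r} in count matrix")
        if counts.columns.has_duplicates:
            dup = counts.columns[counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in count matrix")
        arr = counts.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            _check_integral(counts)
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and arr.min() < 0:
            g, s = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene {counts.index[g]!r}, "
                f"sample {counts.columns[s]!r}"
            )
        self.library_size = self.library_size.reindex(counts.columns)
        if self.library_size.isna().any() or (self.library_size <= 0).any():
            bad = self.library_size.index[
                self.library_size.isna() | (self.library_size <= 0)
            ][0]
            raise FormatError(f"non-positive library size for sample {bad!r}")

    @classmethod
    def from_counts(
        cls, counts: pd.DataFrame, library_size: pd.Series | None = None
    ) -> "CountMatrix":
        if library_size is None:
            library_size = counts.sum(axis=0)
        return cls(counts=counts, library_size=library_size)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_genes(self, genes: Iterable[str]) -> "CountMatrix":
        """Row subset keeping the original library sizes."""
        return CountMatrix(
            counts=self.counts.loc[list(genes)], library_size=self.library_size
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (upper-cased symbols) with optional descriptions."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets


def _check_integral(counts: pd.DataFrame) -> None:
    arr = counts.to_numpy()
    frac = arr != np.floor(arr)
    if frac.any():
        g, s = np.argwhere(frac)[0]
        raise FormatError(
            f"non-integer count {arr[g, s]!r} at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}"
        )


# ---------------------------------------------------------------------------
# counts


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a genes x samples count matrix from TSV or MatrixMarket.

    Library sizes are set to the column sums of the full matrix.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        try:
            return CountMatrix.from_counts(df)
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    if format == "mtx":
        mat = scipy.io.mmread(path)
        genes = Path(str(path) + ".rows").read_text().split()
        samples = Path(str(path) + ".cols").read_text().split()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        df = pd.DataFrame(dense, index=genes, columns=samples)
        try:
            return CountMatrix.from_counts(df)
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from None
    raise ValueError(f"unknown count format {format!r}")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.counts.rename_axis("gene_id").to_csv(path, sep="\t")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse, field="integer")
        Path(str(path) + ".rows").write_text("\n".join(cm.gene_ids) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count format {format!r}")


# ---------------------------------------------------------------------------
# metadata / annotation


def validate_metadata(meta: pd.DataFrame, path: str = "<metadata>") -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    bad = ~meta["status"].isin(STATUS_LEVELS)
    if bad.any():
        row = meta.index[bad][0]
        raise FormatError(
            f"{path}: row {row}: status {meta.loc[row, 'status']!r} not in "
            f"{STATUS_LEVELS}"
        )
    for col, low in (("rin", 0.0), ("pmi", -1e-12), ("age", 0.0)):
        vals = pd.to_numeric(meta[col], errors="coerce")
        bad = vals.isna() | (vals <= low)
        if bad.any():
            row = meta.index[bad][0]
            raise FormatError(
                f"{path}: row {row}: invalid {col} value {meta.loc[row, col]!r}"
            )
        meta[col] = vals
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"), str(path))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_annotation(anno: pd.DataFrame, path: str = "<annotation>") -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in anno.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    anno = anno.copy()
    anno["gene_id"] = anno["gene_id"].astype(str)
    if anno["gene_id"].duplicated().any():
        dup = anno.loc[anno["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"{path}: duplicate gene_id {dup!r}")
    empty = anno["biotype"].isna() | (anno["biotype"].astype(str) == "")
    if empty.any():
        row = anno.index[empty][0]
        raise FormatError(f"{path}: row {row}: empty biotype")
    return anno


def read_annotation(path: str | Path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"), str(path))


def write_annotation(anno: pd.DataFrame, path: str | Path) -> None:
    anno.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name <tab> description <tab> members...

    Members are upper-cased and de-duplicated; blank lines are ignored;
    set order is preserved.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, members...), got {len(fields)}"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m.upper() for m in fields[2:] if m)
            if not members:
                raise FormatError(f"{path}: line {lineno}: set {name!r} is empty")
            coll.sets[name] = members
            coll.descriptions[name] = desc
    if not coll.sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# alignment


def align_inputs(
    counts: CountMatrix, meta: pd.DataFrame, anno: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Order metadata to the count columns and annotation to the count rows.

    Metadata rows without a matching sample are dropped with a warning; genes
    lacking annotation get biotype ``unknown`` and their id as symbol. A fatal
    error is raised when no sample is shared.
    """
    meta = validate_metadata(meta)
    anno = validate_annotation(anno)
    shared = [s for s in counts.sample_ids if s in set(meta["sample_id"])]
    if not shared:
        raise FormatError("no overlap between count matrix and metadata samples")
    missing_meta = [s for s in counts.sample_ids if s not in set(meta["sample_id"])]
    if missing_meta:
        raise FormatError(f"samples missing from metadata: {missing_meta}")
    extra = sorted(set(meta["sample_id"]) - set(counts.sample_ids))
    if extra:
        logger.warning("dropping %d metadata rows without counts: %s", len(extra), extra)
    meta = (
        meta.set_index("sample_id")
        .loc[counts.sample_ids]
        .reset_index()
    )
    anno_idx = anno.set_index("gene_id")
    aligned = anno_idx.reindex(counts.gene_ids)
    missing = aligned["biotype"].isna()
    if missing.any():
        logger.warning(
            "%d genes lack annotation; assigning biotype 'unknown'", int(missing.sum())
        )
        aligned.loc[missing, "biotype"] = "unknown"
        aligned.loc[aligned["symbol"].isna(), "symbol"] = aligned.index[
            aligned["symbol"].isna()
        ]
    anno = aligned.reset_index().rename(columns={"index": "gene_id"})
    return counts, meta, anno


def symbols_for(
    genes: Iterable[str], anno: pd.DataFrame
) -> frozenset[str]:
    """Map gene ids to upper-cased symbols using an annotation table."""
    table: Mapping[str, str] = dict(zip(anno["gene_id"], anno["symbol"]))
    return frozenset(str(table.get(g, g)).upper() for g in genes)
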