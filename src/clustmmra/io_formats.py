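"""Readers and writers for the external formats the pipeline touches.

Formats: TSV expression matrices (features x samples, header = sample ids),
per-sample subtype labels (TSV), miRBase-dialect GFF3 for miRNA gene
coordinates, GMT gene-set collections, multi-source miRNA->gene target
tables (TSV) and an optional identifier alias map (old_id TAB new_id).

Expression input is assumed already normalized and on log2 scale; pass
``linear_input=True`` to apply log2(x+1).  Coordinates are 1-based inclusive
throughout.  Readers never silently drop data: every skipped or collapsed
record is logged.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from clustmmra.cluster_annotation import GenomicLocus

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Log2-scale expression, features x samples, backed by a DataFrame."""

    values: pd.DataFrame
    feature_kind: str  # "mirna" | "mrna"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("mirna", "mrna"):
            raise ValueError(f"feature_kind must be mirna|mrna, got {self.feature_kind!r}")
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            raise ValueError(f"duplicate feature ids: {sorted(idx[idx.duplicated()])}")
        if cols.has_duplicates:
            raise ValueError(f"duplicate sample ids: {sorted(cols[cols.duplicated()])}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError("need at least 1 feature and 2 samples")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise ValueError("expression values must all be finite numbers")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.feature_kind)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


def read_expression_matrix(
    path: str | os.PathLike,
    feature_kind: str,
    linear_input: bool = False,
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column feature ids, header sample ids).

    Duplicate feature rows collapse by mean (logged); duplicate sample ids and
    non-numeric cells are fatal, the latter reported with their coordinates.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample ids {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy().nonzero()
    if bad[0].size:
        r, c = bad[0][0], bad[1][0]
        raise ValueError(
            f"{path}: non-numeric cell {raw.iat[r, c]!r} at "
            f"feature {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.index.has_duplicates:
        dups = sorted(set(numeric.index[numeric.index.duplicated()]))
        logger.warning("%s: collapsing duplicated feature rows by mean: %s", path, dups)
        numeric = numeric.groupby(level=0, sort=False).mean()
    if linear_input:
        if (numeric.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative values are incompatible with --linear-input")
        numeric = np.log2(numeric + 1.0)
    numeric.index.name = None
    numeric.columns.name = None
    return ExpressionMatrix(numeric.astype(float), feature_kind)


# ---------------------------------------------------------------------------
# subtype labels
# ---------------------------------------------------------------------------

@dataclass
class SubtypeLabels:
    """Categorical subtype per sample (e.g. LumA/LumB/HER2/TNBC)."""

    assignments: dict[str, str]
    min_per_subtype: int = 3

    def __post_init__(self) -> None:
        counts = pd.Series(list(self.assignments.values())).value_counts()
        if len(counts) < 2:
            raise ValueError("need at least 2 distinct subtypes")
        small = counts[counts < self.min_per_subtype]
        if len(small):
            raise ValueError(
                f"subtypes with fewer than {self.min_per_subtype} samples: "
                f"{dict(small)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignments)

    @property
    def subtypes(self) -> list[str]:
        return sorted(set(self.assignments.values()))

    def samples_of(self, subtype: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == subtype]

    def as_series(self) -> pd.Series:
        return pd.Series(self.assignments, name="subtype")

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.as_series().rename_axis("sample_id").to_csv(path, sep="\t")


def read_labels(path: str | os.PathLike) -> SubtypeLabels:
    """Read a two-column TSV (sample_id, subtype; header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, subtype)")
    if df.iloc[0, 0] in ("sample_id", "sample"):
        df = df.iloc[1:]
    samples, subtypes = df.iloc[:, 0], df.iloc[:, 1]
    if samples.duplicated().any():
        dups = sorted(set(samples[samples.duplicated()]))
        raise ValueError(f"{path}: samples labelled more than once: {dups}")
    return SubtypeLabels(dict(zip(samples, subtypes)))


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    """Read a GMT file: one set per line, name TAB description TAB gene..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            genes = frozenset(g for g in fields[2:] if g)
            sets.append(GeneSet(fields[0], fields[1], genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# miRBase-dialect GFF3
# ---------------------------------------------------------------------------

def read_mirna_gff(
    path: str | os.PathLike,
    feature_type: str = "miRNA_primary_transcript",
) -> list[GenomicLocus]:
    """Read miRNA gene loci from a miRBase-style GFF3 file.

    Keeps records of ``feature_type`` (precursor hairpins by default;
    pass "miRNA" for mature products).  Coordinates stay 1-based inclusive;
    the locus name is the Name attribute, falling back to ID.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    loci: list[GenomicLocus] = []
    n_skipped = 0
    for feat in db.all_features():
        if feat.featuretype != feature_type:
            n_skipped += 1
            continue
        name = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        # GenomicLocus validates start <= end and the strand symbol
        loci.append(GenomicLocus(name, feat.seqid, feat.start, feat.end, feat.strand))
    if n_skipped:
        logger.info("%s: skipped %d records not of type %r", path, n_skipped, feature_type)
    return loci


def write_mirna_gff(loci: Iterable[GenomicLocus], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for l in loci:
            fh.write(
                "\t".join(
                    [
                        l.chromosome, ".", "miRNA_primary_transcript",
                        str(l.start), str(l.end), ".", l.strand, ".",
                        f"ID={l.name};Name={l.name}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# target tables and alias maps
# ---------------------------------------------------------------------------

@dataclass
class TargetTable:
    """Merged miRNA->gene predictions: unique (mirna_id, gene_id, source) rows."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["mirna_id", "gene_id", "source"]))

    def __post_init__(self) -> None:
        expect = ["mirna_id", "gene_id", "source"]
        if list(self.rows.columns) != expect:
            raise ValueError(f"target table must have columns {expect}")
        self.rows = self.rows.drop_duplicates(ignore_index=True)

    @property
    def sources(self) -> list[str]:
        return sorted(self.rows["source"].unique())

    def __len__(self) -> int:
        return len(self.rows)

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def read_alias_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column TSV alias map (old_id TAB new_id), no header."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: alias map needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def apply_alias(ids: pd.Series, alias: Mapping[str, str] | None) -> pd.Series:
    if not alias:
        return ids
    return ids.map(lambda x: alias.get(x, x))


def read_target_table(
    paths: list[str | os.PathLike],
    source_names: list[str] | None = None,
    alias: Mapping[str, str] | None = None,
) -> TargetTable:
    """Merge one TSV per source into a single table.

    Each file carries columns mirna_id and gene_id (a third column may name
    the source; otherwise the supplied source name or the file stem is used).
    Identifiers are passed through the alias map before merging; within-source
    duplicates collapse to one row.  An empty file warns, a missing column is
    fatal.
    """
    if source_names is not None and len(source_names) != len(paths):
        raise ValueError("source_names must match paths in length")
    frames = []
    for i, path in enumerate(paths):
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame(columns=["mirna_id", "gene_id"])
        if df.empty:
            logger.warning("%s: empty target file", path)
        for col in ("mirna_id", "gene_id"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        if source_names is not None:
            src = source_names[i]
        elif "source" in df.columns:
            src = None  # per-row source from column 3
        else:
            src = os.path.splitext(os.path.basename(str(path)))[0]
        out = pd.DataFrame(
            {
                "mirna_id": apply_alias(df["mirna_id"], alias),
                "gene_id": apply_alias(df["gene_id"], alias),
                "source": df["source"] if src is None else src,
            }
        )
        frames.append(out)
    merged = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["mirna_id", "gene_id", "source"])
    )
    return TargetTable(merged)
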