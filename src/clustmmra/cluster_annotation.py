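"""Grouping of miRNA genes into genomic clusters.

A miRNA cluster (polycistron) is a set of miRNA genes lying within a short
genomic window on the same chromosome and strand, typically co-transcribed
as a single primary transcript.  Here clusters are built by chaining loci
whose end-to-start gap does not exceed ``max_gap`` (default 10 kb).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicLocus:
    """A miRNA gene location, 1-based inclusive coordinates."""

    name: str
    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"locus {self.name!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in _STRANDS:
            raise ValueError(
                f"locus {self.name!r}: unknown strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class MirnaCluster:
    """Two or more miRNA loci chained within ``max_gap`` on one strand."""

    cluster_id: str
    members: list[GenomicLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")
        chroms = {m.chromosome for m in self.members}
        strands = {m.strand for m in self.members}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("cluster members must share chromosome and strand")
        self.members = sorted(self.members, key=lambda m: (m.start, m.end, m.name))

    @property
    def chromosome(self) -> str:
        return self.members[0].chromosome

    @property
    def strand(self) -> str:
        return self.members[0].strand

    @property
    def start(self) -> int:
        return self.members[0].start

    @property
    def end(self) -> int:
        return max(m.end for m in self.members)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def member_names(self) -> list[str]:
        return [m.name for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def _elide_common_prefix(first: str, last: str) -> str:
    """Join two member names as "first/last-suffix", e.g. mir-199a-2 + mir-214
    -> "mir-199a-2/214" (the shared "mir-" prefix is elided from the second)."""
    n = 0
    for a, b in zip(first, last):
        if a != b:
            break
        n += 1
    # back off to the last separator so the suffix starts at a name component
    prefix = first[:n]
    cut = max(prefix.rfind("-"), prefix.rfind("/")) + 1
    suffix = last[cut:]
    if not suffix:
        suffix = last
    return f"{first}/{suffix}"


def cluster_name(members: list[GenomicLocus]) -> str:
    first = members[0].name
    last = members[-1].name
    return _elide_common_prefix(first, last)


def build_clusters(
    loci: list[GenomicLocus],
    max_gap: int = 10_000,
    linkage: str = "single",
) -> list[MirnaCluster]:
    """Chain loci into clusters along each (chromosome, strand).

    With single linkage a locus joins the current chain iff its start lies
    within ``max_gap`` of the end of the previous member, so a chain may span
    more than ``max_gap`` overall.  With complete linkage the gap to every
    current member must be within ``max_gap``.  Chains with >= 2 members
    become clusters; singleton miRNAs are discarded.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    if linkage not in ("single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    names = [l.name for l in loci]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate locus names: {dup}")

    by_group: dict[tuple[str, str], list[GenomicLocus]] = {}
    for locus in loci:
        by_group.setdefault((locus.chromosome, locus.strand), []).append(locus)

    clusters: list[MirnaCluster] = []
    for key in sorted(by_group):
        group = sorted(by_group[key], key=lambda m: (m.start, m.end, m.name))
        chain: list[GenomicLocus] = []
        min_end = None  # earliest end in the chain; complete-linkage bound
        for locus in group:
            if not chain:
                chain, min_end = [locus], locus.end
                continue
            ref_end = chain[-1].end if linkage == "single" else min_end
            if locus.start - ref_end <= max_gap:
                chain.append(locus)
                min_end = min(min_end, locus.end)
            else:
                if len(chain) >= 2:
                    clusters.append(MirnaCluster(cluster_name(chain), chain))
                chain, min_end = [locus], locus.end
        if len(chain) >= 2:
            clusters.append(MirnaCluster(cluster_name(chain), chain))

    n_clustered = sum(len(c) for c in clusters)
    logger.info(
        "clustered %d/%d loci into %d clusters (max_gap=%d, %s linkage)",
        n_clustered, len(loci), len(clusters), max_gap, linkage,
    )
    return clusters


def _chrom_sort_key(chrom: str) -> tuple:
    m = re.match(r"(?:chr)?(\d+|[XYM]T?)$", chrom, flags=re.IGNORECASE)
    if m:
        token = m.group(1).upper()
        if token.isdigit():
            return (0, int(token), "")
        return (1, 0, token)
    return (2, 0, chrom)


def clusters_summary(clusters: list[MirnaCluster]) -> pd.DataFrame:
    """Deterministic per-cluster report, sorted by chromosome then start."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "n_members": len(c),
            "chromosome": c.chromosome,
            "strand": c.strand,
            "start": c.start,
            "end": c.end,
            "span": c.span,
            "members": ",".join(c.member_names),
        }
        for c in clusters
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_members", "chromosome", "strand",
            "start", "end", "span", "members",
        ],
    )
    if len(df):
        df = df.sort_values(
            by=["chromosome", "start"],
            key=lambda col: col.map(_chrom_sort_key) if col.name == "chromosome" else col,
        ).reset_index(drop=True)
    return df
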