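"""Step (i): subtype-specific miRNA expression and candidate clusters.

Each miRNA is tested per subtype against all other samples with a
two-sample Kolmogorov-Smirnov test plus a fold-change cutoff; a genomic
cluster becomes a candidate for a (subtype, direction) when at least two of
its members are deregulated in that subtype in the same direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from clustmmra.cluster_annotation import MirnaCluster
from clustmmra.io_formats import ExpressionMatrix, SubtypeLabels
from clustmmra.signature_builder import _adjust

logger = logging.getLogger(__name__)

DIFFEXP_COLUMNS = ["mirna_id", "subtype", "ks_stat", "p", "adj_p", "logFC", "direction"]


@dataclass
class CandidateCluster:
    """A (cluster, subtype, direction) surviving the step-(i) gate."""

    cluster_id: str
    subtype: str
    direction: str  # "up" | "down"
    deregulated_members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up|down, got {self.direction!r}")
        if not self.deregulated_members:
            raise ValueError("candidate needs at least one deregulated member")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.cluster_id, self.subtype, self.direction)


def ks_diffexp(
    mirna_matrix: ExpressionMatrix,
    labels: SubtypeLabels,
    p_max: float = 0.05,
    lfc_min: float = 0.5,
    p_adjust: str = "bh",
    exact_below: int = 30,
) -> pd.DataFrame:
    """Two-sided two-sample KS test of each miRNA, per subtype vs rest.

    P-values use the asymptotic distribution, falling back to the exact one
    when either group has fewer than ``exact_below`` samples.  BH adjustment
    is applied within each subtype contrast; a direction is called when
    adj_p < p_max and |logFC| > lfc_min.
    """
    cols = set(mirna_matrix.sample_ids)
    rows = []
    for subtype in labels.subtypes:
        in_samples = [s for s in labels.samples_of(subtype) if s in cols]
        rest = [
            s for s in labels.sample_ids
            if labels.assignments[s] != subtype and s in cols
        ]
        if len(in_samples) < 3 or len(rest) < 3:
            raise ValueError(f"subtype {subtype!r}: need >=3 samples per group")
        a = mirna_matrix.values[in_samples].to_numpy()
        b = mirna_matrix.values[rest].to_numpy()
        method = "exact" if min(a.shape[1], b.shape[1]) < exact_below else "asymp"
        ks = np.empty(a.shape[0])
        pv = np.empty(a.shape[0])
        for i in range(a.shape[0]):
            res = stats.ks_2samp(a[i], b[i], alternative="two-sided", method=method)
            ks[i], pv[i] = res.statistic, res.pvalue
        adj = _adjust(pv, p_adjust)
        logfc = a.mean(axis=1) - b.mean(axis=1)
        significant = (adj < p_max) & (np.abs(logfc) > lfc_min)
        direction = np.where(significant, np.where(logfc > 0, "up", "down"), "none")
        for i, mirna in enumerate(mirna_matrix.feature_ids):
            rows.append((mirna, subtype, ks[i], pv[i], adj[i], logfc[i], direction[i]))
    return pd.DataFrame(rows, columns=DIFFEXP_COLUMNS)


def select_candidate_clusters(
    diffexp: pd.DataFrame,
    clusters: list[MirnaCluster],
    min_dereg: int = 2,
    alias: Mapping[str, str] | None = None,
) -> list[CandidateCluster]:
    """Select (cluster, subtype, direction) triples with >= min_dereg
    members deregulated in the same direction.

    ``alias`` maps expression-row miRNA ids (typically mature names) to the
    precursor locus names used in the clusters; rows are tested
    individually and never averaged across a cluster.
    """
    dereg = diffexp[diffexp["direction"].isin(("up", "down"))].copy()
    if alias:
        dereg["locus"] = dereg["mirna_id"].map(lambda x: alias.get(x, x))
    else:
        dereg["locus"] = dereg["mirna_id"]
    by_key: dict[tuple[str, str], dict[str, list[str]]] = {}
    for row in dereg.itertuples(index=False):
        by_key.setdefault((row.subtype, row.direction), {}).setdefault(
            row.locus, []
        ).append(row.mirna_id)

    candidates: list[CandidateCluster] = []
    for cluster in clusters:
        member_set = set(cluster.member_names)
        for (subtype, direction), locus_map in sorted(by_key.items()):
            hit_loci = member_set & set(locus_map)
            if len(hit_loci) >= min_dereg:
                members = sorted(m for locus in hit_loci for m in locus_map[locus])
                candidates.append(
                    CandidateCluster(cluster.cluster_id, subtype, direction, members)
                )
    logger.info(
        "step (i): %d candidate (cluster, subtype, direction) triples from %d clusters",
        len(candidates), len(clusters),
    )
    return candidates


def candidates_table(candidates: list[CandidateCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "subtype": c.subtype,
                "direction": c.direction,
                "n_deregulated": len(c.deregulated_members),
                "deregulated_members": ",".join(c.deregulated_members),
            }
            for c in candidates
        ],
        columns=[
            "cluster_id", "subtype", "direction",
            "n_deregulated", "deregulated_members",
        ],
    )
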