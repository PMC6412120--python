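"""Step (ii): permutation-null enrichment of cluster targets in signatures.

MiRNA->gene predictions from several databases are merged, keeping pairs
supported by at least ``min_sources`` distinct sources.  A candidate
cluster's target set is the union of the targets of its deregulated members
only.  The gate compares the observed overlap with the subtype signature to
the 95th percentile of overlaps of 1000 random gene sets of the same size
drawn from the expression universe; a candidate passes on a strictly larger
observed overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clustmmra.io_formats import ExpressionMatrix, TargetTable
from clustmmra.signature_builder import SignatureSet
from clustmmra.subtype_diffexp import CandidateCluster

logger = logging.getLogger(__name__)


@dataclass
class TargetMap:
    """miRNA -> target gene sets after the multi-source support filter."""

    targets: dict[str, frozenset[str]]
    min_sources: int
    support: pd.DataFrame | None = None  # (mirna_id, gene_id, n_sources)

    def genes_of(self, mirna_id: str) -> frozenset[str]:
        return self.targets.get(mirna_id, frozenset())

    @property
    def all_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.targets.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class EnrichmentResult:
    cluster_id: str
    subtype: str
    direction: str
    target_set_size: int
    observed_overlap: int
    null_threshold: int
    empirical_p: float
    passed: bool
    null_summary: dict[str, float]

    def as_row(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "subtype": self.subtype,
            "direction": self.direction,
            "target_set_size": self.target_set_size,
            "observed_overlap": self.observed_overlap,
            "null_threshold": self.null_threshold,
            "empirical_p": self.empirical_p,
            "passed": self.passed,
            **{f"null_{k}": v for k, v in self.null_summary.items()},
        }


def aggregate_targets(table: TargetTable, min_sources: int = 2) -> TargetMap:
    """Keep (miRNA, gene) pairs predicted by >= min_sources distinct sources.

    Experimental and computational sources count identically; duplicate
    listings within one source count once.
    """
    if not len(table.rows):
        return TargetMap({}, min_sources, table.rows.assign(n_sources=[]))
    support = (
        table.rows.groupby(["mirna_id", "gene_id"], sort=True)["source"]
        .nunique()
        .rename("n_sources")
        .reset_index()
    )
    kept = support[support["n_sources"] >= min_sources]
    targets = {
        mirna: frozenset(sub["gene_id"])
        for mirna, sub in kept.groupby("mirna_id", sort=True)
    }
    logger.info(
        "aggregate_targets: kept %d/%d pairs at min_sources=%d",
        len(kept), len(support), min_sources,
    )
    return TargetMap(targets, min_sources, support)


def cluster_target_set(candidate: CandidateCluster, targets: TargetMap) -> frozenset[str]:
    """Union of targets over the candidate's deregulated members only."""
    out: set[str] = set()
    for mirna in candidate.deregulated_members:
        out |= targets.genes_of(mirna)
    if not out:
        logger.warning(
            "candidate %s/%s: no member has annotated targets; "
            "it will fail the enrichment gate", candidate.cluster_id, candidate.subtype,
        )
    return frozenset(out)


def filter_targets_by_correlation(
    targets: TargetMap,
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    rho_max: float = 0.0,
    method: str = "spearman",
) -> TargetMap:
    """Optional filter: keep a pair iff corr(miRNA, gene) < rho_max.

    The canonical repression model predicts negative miRNA-target
    correlation, so the default rho_max=0 keeps anti-correlated pairs.
    """
    if mirna_matrix.sample_ids != mrna_matrix.sample_ids:
        raise ValueError("miRNA and mRNA matrices must have identical sample order")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")

    def _prep(v: np.ndarray) -> np.ndarray:
        if method == "spearman":
            v = stats.rankdata(v)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    n = len(mirna_matrix.sample_ids)
    kept: dict[str, frozenset[str]] = {}
    n_in = n_out = 0
    for mirna, genes in targets.targets.items():
        if mirna not in mirna_matrix.values.index:
            kept[mirna] = genes
            continue
        x = _prep(mirna_matrix.values.loc[mirna].to_numpy())
        present = [g for g in genes if g in mrna_matrix.values.index]
        keep = set(genes) - set(present)  # pairs without expression stay
        for g in present:
            y = _prep(mrna_matrix.values.loc[g].to_numpy())
            if float(x @ y) / n < rho_max:
                keep.add(g)
        n_in += len(genes)
        n_out += len(keep)
        kept[mirna] = frozenset(keep)
    logger.info(
        "correlation filter (%s < %.3g): kept %d/%d pairs", method, rho_max, n_out, n_in
    )
    return TargetMap(kept, targets.min_sources, targets.support)


def empirical_overlap_threshold(
    set_size: int,
    signature_genes: frozenset[str] | set[str],
    universe: list[str] | frozenset[str],
    n_rand: int = 1000,
    quantile: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[int, np.ndarray]:
    """Null overlap threshold from random same-size gene sets.

    Draws ``n_rand`` uniform subsets of ``set_size`` genes from the universe
    without replacement, records their overlap with the signature, and
    returns the ceiling of the empirical ``quantile`` (linear-interpolation,
    type 7) as an integer count, together with the null overlap counts.
    """
    universe_list = sorted(universe) if not isinstance(universe, list) else universe
    n_universe = len(universe_list)
    if set_size > n_universe:
        raise ValueError(f"set_size {set_size} exceeds universe size {n_universe}")
    stray = set(signature_genes) - set(universe_list)
    if stray:
        raise ValueError(f"signature genes outside universe: {sorted(stray)[:5]}")
    if rng is None:
        rng = np.random.default_rng()
    if set_size == 0:
        return 0, np.zeros(n_rand, dtype=int)
    is_sig = np.fromiter(
        (g in signature_genes for g in universe_list), dtype=bool, count=n_universe
    )
    # uniform random subset = indices of the set_size smallest uniform keys
    nulls = np.empty(n_rand, dtype=int)
    block = max(1, int(2e7) // max(n_universe, 1))  # bound temporary memory
    for lo in range(0, n_rand, block):
        hi = min(lo + block, n_rand)
        keys = rng.random((hi - lo, n_universe))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        nulls[lo:hi] = is_sig[idx].sum(axis=1)
    threshold = int(math.ceil(np.quantile(nulls, quantile, method="linear")))
    return threshold, nulls


def target_enrichment_filter(
    candidate: CandidateCluster,
    targets: TargetMap,
    signatures: SignatureSet,
    universe: frozenset[str] | list[str],
    n_rand: int = 1000,
    quantile: float = 0.95,
    rng: np.random.Generator | None = None,
    directional: bool = False,
) -> EnrichmentResult:
    """Gate a candidate on signature overlap of its targets vs the null.

    By default the gate uses up ∪ down of the subtype signature (clusters
    and signatures may deregulate with either relative sign); with
    ``directional=True`` only the signature component opposite in sign to
    the cluster is used (canonical repression model).  The candidate passes
    iff observed overlap strictly exceeds the null threshold; the add-one
    empirical p-value (1 + #{null >= obs}) / (1 + n_rand) is reported.
    """
    sig = signatures.signatures[candidate.subtype]
    if directional:
        sig_genes = sig.up if candidate.direction == "down" else sig.down
    else:
        sig_genes = sig.genes
    universe_list = sorted(universe) if not isinstance(universe, list) else universe
    universe_set = set(universe_list)
    sig_genes = frozenset(sig_genes) & universe_set

    target_set = cluster_target_set(candidate, targets) & universe_set
    observed = len(target_set & sig_genes)
    if not target_set:
        return EnrichmentResult(
            candidate.cluster_id, candidate.subtype, candidate.direction,
            0, 0, 0, 1.0, False,
            {"min": 0.0, "median": 0.0, "p95": 0.0, "max": 0.0},
        )
    threshold, nulls = empirical_overlap_threshold(
        len(target_set), sig_genes, universe_list, n_rand, quantile, rng
    )
    empirical_p = (1 + int((nulls >= observed).sum())) / (1 + n_rand)
    return EnrichmentResult(
        candidate.cluster_id,
        candidate.subtype,
        candidate.direction,
        len(target_set),
        observed,
        threshold,
        empirical_p,
        observed > threshold,
        {
            "min": float(nulls.min()),
            "median": float(np.median(nulls)),
            "p95": float(np.quantile(nulls, 0.95)),
            "max": float(nulls.max()),
        },
    )
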