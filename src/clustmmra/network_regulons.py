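"""Step (iii): mutual-information networks, regulons and their enrichment.

For each candidate cluster an ARACNE-style miRNA-mRNA network is inferred:
mutual information (MI) is estimated for every miRNA-gene pair over all
expressed genes, edges below a permutation-derived significance threshold
are dropped, and the data-processing inequality (DPI) prunes, within each
triangle, the weakest edge as likely indirect.  The genes within a fixed
graph radius of the cluster's miRNAs form its regulon, tested for
enrichment in the subtype signature by a one-sided Fisher exact test.

The MI estimator is a rank (copula) equal-frequency-binning plug-in: both
vectors are rank-transformed, partitioned into a bins x bins
equal-frequency grid, and MI = sum p_ij ln(p_ij / (p_i p_j)) in nats.
It is deterministic, symmetric and exactly invariant under strictly
monotone transforms of either input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from clustmmra.io_formats import ExpressionMatrix
from clustmmra.subtype_diffexp import CandidateCluster
from clustmmra.target_enrichment import TargetMap

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# MI estimation
# ---------------------------------------------------------------------------

def default_bins(n: int) -> int:
    """Equal-frequency grid resolution: floor(sqrt(n/5)), clipped to [2, 10]."""
    return int(np.clip(int(np.sqrt(n / 5)), 2, 10))


def _bin_ranks(v: np.ndarray, bins: int) -> np.ndarray:
    """Ordinal ranks (stable ties) mapped to equal-frequency bin indices."""
    n = v.shape[-1]
    order = np.argsort(v, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    idx = np.arange(n)
    if v.ndim == 1:
        ranks[order] = idx
    else:
        np.put_along_axis(ranks, order, np.broadcast_to(idx, order.shape), axis=-1)
    return (ranks * bins) // n


def _mi_from_joint_counts(counts: np.ndarray, n: int) -> float:
    # marginals from integer counts and fsum over the cells keep the result
    # exact, hence invariant to the cell permutations induced by monotone
    # transforms of the inputs
    p = counts / n
    pi = counts.sum(axis=1, keepdims=True) / n
    pj = counts.sum(axis=0, keepdims=True) / n
    mask = p > 0
    return math.fsum(p[mask] * np.log(p[mask] / (pi @ pj)[mask]))


def _mi_binned(bx: np.ndarray, by: np.ndarray, bins: int) -> float:
    n = bx.size
    counts = np.bincount(bx * bins + by, minlength=bins * bins).reshape(bins, bins)
    return _mi_from_joint_counts(counts, n)


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """Plug-in MI (nats) between two sample vectors of equal length >= 8."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("mutual_information: constant vector -> MI 0")
        return 0.0
    if bins is None:
        bins = default_bins(x.size)
    return _mi_binned(_bin_ranks(x, bins), _bin_ranks(y, bins), bins)


def _mi_one_vs_many(bx: np.ndarray, by_rows: np.ndarray, bins: int) -> np.ndarray:
    """MI of one binned vector against each row of a binned matrix."""
    out = np.empty(by_rows.shape[0])
    for i in range(by_rows.shape[0]):
        out[i] = _mi_binned(bx, by_rows[i], bins)
    return out


def mi_significance_threshold(
    rows: np.ndarray,
    n_perm: int = 100,
    alpha: float = 0.05,
    n_pairs: int = 50,
    bonferroni_pairs: int | None = None,
    bins: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """MI cutoff from a pooled permutation null.

    Randomly selected feature pairs have one member's sample order permuted
    ``n_perm`` times; all null MIs are pooled and the (1 - alpha) quantile
    is returned.  ``bonferroni_pairs`` optionally rescales alpha to
    alpha / n_pairs_tested for a family-wise cutoff.
    """
    rows = np.asarray(rows, dtype=float)
    m, n = rows.shape
    if m < 2:
        raise ValueError("need at least 2 features")
    if rng is None:
        rng = np.random.default_rng()
    if bins is None:
        bins = default_bins(n)
    binned = _bin_ranks(rows, bins)
    nulls = np.empty(n_pairs * n_perm)
    k = 0
    for _ in range(n_pairs):
        i, j = rng.choice(m, size=2, replace=False)
        bx = binned[i]
        for _ in range(n_perm):
            nulls[k] = _mi_binned(bx, rng.permutation(binned[j]), bins)
            k += 1
    level = alpha if bonferroni_pairs is None else alpha / bonferroni_pairs
    return float(np.quantile(nulls, 1.0 - level))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

@dataclass
class MiNetwork:
    """MI-weighted miRNA-gene network after thresholding and DPI."""

    graph: nx.Graph
    mirna_ids: list[str]
    mi_threshold: float
    dpi_tolerance: float
    mirna_gene_mi: pd.DataFrame  # full pre-threshold MI, miRNAs x genes

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "mi": d["mi"]}
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "mi"])

    def to_edge_tsv(self, path) -> None:
        self.edges_frame().to_csv(path, sep="\t", index=False)


@dataclass
class Regulon:
    cluster_id: str
    subtype: str
    genes: frozenset[str]
    radius: int
    fisher_p: float | None = None
    odds_ratio: float | None = None
    passed: bool | None = None


def expressed_genes(
    mrna_matrix: ExpressionMatrix, fraction: float = 0.2
) -> frozenset[str]:
    """Genes above the matrix-wide median in at least ``fraction`` of samples."""
    arr = mrna_matrix.values.to_numpy()
    above = (arr > np.median(arr)).mean(axis=1)
    return frozenset(np.asarray(mrna_matrix.feature_ids)[above >= fraction])


def apply_dpi(graph: nx.Graph, tolerance: float) -> int:
    """Data-processing-inequality pruning, multiplicative tolerance.

    For every triangle (a, b, c), the edge (a, c) is marked for removal iff
    MI(a,c) < min(MI(a,b), MI(b,c)) * (1 - tolerance); all removals are
    decided on the original MI values, then applied together, so the
    strongest edge of a triangle is never removed.
    """
    to_remove: set[tuple] = set()
    for a, c, data in graph.edges(data=True):
        mi_ac = data["mi"]
        common = set(graph[a]) & set(graph[c])
        for b in common:
            bound = min(graph[a][b]["mi"], graph[c][b]["mi"]) * (1.0 - tolerance)
            if mi_ac < bound:
                to_remove.add((a, c) if a <= c else (c, a))
                break
    graph.remove_edges_from(to_remove)
    return len(to_remove)


def build_aracne_network(
    candidate: CandidateCluster,
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    expressed: frozenset[str],
    mi_threshold: float,
    dpi_tolerance: float = 0.15,
    gene_cap: int | None = 3000,
    bins: int | None = None,
) -> MiNetwork:
    """ARACNE-style network for one candidate cluster.

    Nodes are the candidate's deregulated miRNAs plus all expressed genes;
    MI is computed for every miRNA-gene pair and, to enable DPI, for
    gene-gene pairs among genes adjacent to at least one miRNA.  Edges with
    MI >= mi_threshold are kept and DPI prunes likely-indirect ones.
    """
    if mirna_matrix.sample_ids != mrna_matrix.sample_ids:
        raise ValueError("miRNA and mRNA matrices must have identical sample order")
    mirnas = [m for m in candidate.deregulated_members if m in mirna_matrix.values.index]
    genes = [g for g in mrna_matrix.feature_ids if g in expressed]
    if gene_cap is not None and len(genes) > gene_cap:
        variances = mrna_matrix.values.loc[genes].var(axis=1)
        genes = list(variances.nlargest(gene_cap).index)
        logger.info("network gene cap applied: top-%d variance genes kept", gene_cap)
    n = len(mrna_matrix.sample_ids)
    if bins is None:
        bins = default_bins(n)

    gene_rows = mrna_matrix.values.loc[genes].to_numpy()
    gene_binned = _bin_ranks(gene_rows, bins)
    graph = nx.Graph()
    graph.add_nodes_from(mirnas)
    graph.add_nodes_from(genes)

    mi_rows = {}
    for mirna in mirnas:
        x = mirna_matrix.values.loc[mirna].to_numpy()
        if np.ptp(x) == 0:
            mi_rows[mirna] = np.zeros(len(genes))
            continue
        bx = _bin_ranks(x, bins)
        mis = _mi_one_vs_many(bx, gene_binned, bins)
        mi_rows[mirna] = mis
        for j in np.nonzero(mis >= mi_threshold)[0]:
            graph.add_edge(mirna, genes[j], mi=float(mis[j]))
    mirna_gene_mi = pd.DataFrame(mi_rows, index=genes).T

    # gene-gene MI among genes adjacent to any miRNA, for DPI triangles
    adjacent = sorted(
        {g for mirna in mirnas for g in graph[mirna]} if mirnas else set()
    )
    if adjacent:
        gene_pos = {g: i for i, g in enumerate(genes)}
        adj_idx = [gene_pos[g] for g in adjacent]
        for ai in range(len(adjacent)):
            bx = gene_binned[adj_idx[ai]]
            rest = gene_binned[adj_idx[ai + 1:]]
            if rest.size == 0:
                continue
            mis = _mi_one_vs_many(bx, rest, bins)
            for off in np.nonzero(mis >= mi_threshold)[0]:
                graph.add_edge(
                    adjacent[ai], adjacent[ai + 1 + off], mi=float(mis[off])
                )

    n_before = graph.number_of_edges()
    n_removed = apply_dpi(graph, dpi_tolerance)
    logger.info(
        "network %s/%s: %d edges after threshold %.4g, DPI removed %d",
        candidate.cluster_id, candidate.subtype, n_before, mi_threshold, n_removed,
    )
    return MiNetwork(graph, mirnas, mi_threshold, dpi_tolerance, mirna_gene_mi)


def extract_regulon(
    network: MiNetwork, candidate: CandidateCluster, radius: int = 1
) -> Regulon:
    """Genes within graph distance <= radius of any candidate miRNA.

    radius=1 keeps direct MI partners; radius=2 additionally includes
    indirect interactions through one intermediate gene.
    """
    genes: set[str] = set()
    for mirna in network.mirna_ids:
        if mirna not in network.graph:
            continue
        reach = nx.single_source_shortest_path_length(network.graph, mirna, cutoff=radius)
        genes |= set(reach)
    genes -= set(network.mirna_ids)
    return Regulon(candidate.cluster_id, candidate.subtype, frozenset(genes), radius)


def regulon_signature_test(
    regulon: Regulon,
    signature_genes: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
    alpha: float = 0.05,
) -> Regulon:
    """One-sided Fisher exact enrichment of the regulon in the signature."""
    universe = set(universe)
    reg = set(regulon.genes) & universe
    sig = set(signature_genes) & universe
    if not reg:
        regulon.fisher_p, regulon.odds_ratio, regulon.passed = 1.0, 0.0, False
        return regulon
    k = len(reg & sig)
    table = [
        [k, len(reg) - k],
        [len(sig) - k, len(universe) - len(reg) - len(sig) + k],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    regulon.fisher_p = float(p)
    regulon.odds_ratio = float(odds)
    regulon.passed = bool(p < alpha) and len(reg) > 0
    return regulon


def target_mi_qc(
    network: MiNetwork,
    targets: TargetMap,
    candidate: CandidateCluster,
    min_group: int = 5,
) -> pd.DataFrame:
    """Per-miRNA check that predicted targets carry higher MI than non-targets.

    One-sided Mann-Whitney U on the full (pre-threshold) miRNA-gene MI
    values, targets vs non-targets; NaN with a warning when either group has
    fewer than ``min_group`` genes.
    """
    rows = []
    genes = np.asarray(network.mirna_gene_mi.columns)
    for mirna in candidate.deregulated_members:
        if mirna not in network.mirna_gene_mi.index:
            rows.append((mirna, np.nan, 0, 0))
            continue
        mis = network.mirna_gene_mi.loc[mirna].to_numpy()
        is_target = np.isin(genes, sorted(targets.genes_of(mirna)))
        t_mi, nt_mi = mis[is_target], mis[~is_target]
        if len(t_mi) < min_group or len(nt_mi) < min_group:
            logger.warning(
                "target_mi_qc %s: too few genes (%d targets, %d non-targets)",
                mirna, len(t_mi), len(nt_mi),
            )
            rows.append((mirna, np.nan, len(t_mi), len(nt_mi)))
            continue
        method = "exact" if max(len(t_mi), len(nt_mi)) <= 20 else "asymptotic"
        res = stats.mannwhitneyu(t_mi, nt_mi, alternative="greater", method=method)
        rows.append((mirna, float(res.pvalue), len(t_mi), len(nt_mi)))
    return pd.DataFrame(
        rows, columns=["mirna_id", "rank_sum_p", "n_targets", "n_non_targets"]
    )
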