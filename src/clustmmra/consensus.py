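"""Cross-dataset consensus statistics and regulon pathway prioritization.

When the pipeline is run on two independent cohorts, the significance of
the intersection of their surviving cluster lists is scored with an exact
one-sided hypergeometric tail over the universe of clusters analyzed.
Regulons are further characterized by Fisher enrichment against pathway
collections (GMT), with BH correction, and pathway hits can be aggregated
into function-level scores (sum of |log10 p| per function group).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from clustmmra.io_formats import GeneSet


@dataclass
class OverlapStat:
    universe_n: int
    size_a: int
    size_b: int
    overlap: int
    p: float


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(universe_n: int, size_a: int, size_b: int, overlap: int) -> float:
    """P(X >= overlap), X ~ Hypergeometric(N=universe_n, K=size_a, n=size_b).

    Exact summation of the point masses in log space (log-gamma binomial
    coefficients combined with logsumexp), so deep tails stay accurate.
    """
    if not (0 <= size_a <= universe_n and 0 <= size_b <= universe_n):
        raise ValueError("set sizes must lie within the universe")
    if overlap < 0 or overlap > min(size_a, size_b):
        raise ValueError("overlap must lie in [0, min(size_a, size_b)]")
    k_min = max(overlap, size_a + size_b - universe_n)
    if overlap <= max(0, size_a + size_b - universe_n):
        return 1.0
    k = np.arange(k_min, min(size_a, size_b) + 1)
    log_pmf = (
        _log_binom(size_a, k)
        + _log_binom(universe_n - size_a, size_b - k)
        - _log_binom(universe_n, np.array(size_b))
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def intersect_outputs(
    list_a: Iterable[str], list_b: Iterable[str], universe_n: int
) -> tuple[list[str], OverlapStat]:
    """Intersection of two cluster-id lists plus its hypergeometric tail p."""
    set_a, set_b = set(list_a), set(list_b)
    if universe_n < len(set_a | set_b):
        raise ValueError("universe_n smaller than the union of the two lists")
    common = sorted(set_a & set_b)
    p = hypergeometric_tail(universe_n, len(set_a), len(set_b), len(common))
    return common, OverlapStat(universe_n, len(set_a), len(set_b), len(common), p)


PATHWAY_COLUMNS = ["pathway_name", "overlap", "pathway_size", "p", "fdr_q"]


def regulon_pathway_enrichment(
    regulon_genes: frozenset[str] | set[str],
    collection: Sequence[GeneSet],
    universe: frozenset[str] | set[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a regulon in each pathway of a GMT
    collection, BH-corrected across the collection; keeps fdr_q < fdr_max."""
    if not collection:
        raise ValueError("empty pathway collection")
    universe = set(universe)
    reg = set(regulon_genes) & universe
    if not reg:
        return pd.DataFrame(columns=PATHWAY_COLUMNS)
    rows = []
    for gene_set in collection:
        pw = set(gene_set.genes) & universe
        k = len(reg & pw)
        table = [
            [k, len(reg) - k],
            [len(pw) - k, len(universe) - len(reg) - len(pw) + k],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append((gene_set.name, k, len(pw), float(p)))
    df = pd.DataFrame(rows, columns=["pathway_name", "overlap", "pathway_size", "p"])
    df["fdr_q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df[df["fdr_q"] < fdr_max].sort_values(["p", "pathway_name"]).reset_index(drop=True)
    return df[PATHWAY_COLUMNS]


def function_group_summary(
    rows: pd.DataFrame,
    grouping: Mapping[str, str],
    log_base: float = 10.0,
) -> pd.Series:
    """Aggregate pathway hits to function-level scores.

    score(function) = sum over its pathways of |log p| (base 10 by
    default).  Pathways absent from the grouping fall into "other".
    """
    if rows.empty:
        return pd.Series(dtype=float, name="score")
    labels = rows["pathway_name"].map(lambda n: grouping.get(n, "other"))
    scores = np.abs(np.log(rows["p"].to_numpy()) / np.log(log_base))
    return (
        pd.Series(scores, index=labels.values, name="score")
        .groupby(level=0)
        .sum()
        .sort_values(ascending=False)
    )
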