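"""Per-subtype gene-signature construction and validation.

For each subtype, genes differentially expressed against all other samples
(Welch t-test, BH-adjusted p < 0.05, |log2 fold change| > 0.5) form a
candidate signature.  Genes significant in more than one subtype, or whose
two largest |logFC| across subtypes differ by less than 0.2, are discarded
so each retained gene marks a single subtype.  The surviving genes split
into 'up' and 'down' components by the sign of the fold change.

Signatures are validated two ways: nearest-template prediction (NTP)
classification of samples, and a one-sided Fisher exact test of the overlap
with external gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from clustmmra.io_formats import ExpressionMatrix, GeneSet, SubtypeLabels

logger = logging.getLogger(__name__)


@dataclass
class GeneSignature:
    subtype: str
    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError(f"{self.subtype}: up and down signatures overlap")

    @property
    def genes(self) -> frozenset[str]:
        return self.up | self.down

    def __len__(self) -> int:
        return len(self.up) + len(self.down)


@dataclass
class SignatureSet:
    signatures: dict[str, GeneSignature]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for subtype, sig in self.signatures.items():
            for g in sig.genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} appears in signatures of both "
                        f"{seen[g]!r} and {subtype!r}"
                    )
                seen[g] = subtype
            stray = sig.genes - self.universe
            if stray:
                raise ValueError(f"{subtype}: signature genes outside universe: {sorted(stray)[:5]}")

    def to_gene_sets(self) -> list[GeneSet]:
        sets = []
        for subtype in sorted(self.signatures):
            sig = self.signatures[subtype]
            sets.append(GeneSet(f"{subtype}_up", f"{subtype} up-regulated", sig.up))
            sets.append(GeneSet(f"{subtype}_down", f"{subtype} down-regulated", sig.down))
        return sets

    @classmethod
    def from_gene_sets(cls, sets: list[GeneSet], universe: frozenset[str]) -> "SignatureSet":
        halves: dict[str, dict[str, frozenset[str]]] = {}
        for s in sets:
            if s.name.endswith("_up"):
                subtype, part = s.name[:-3], "up"
            elif s.name.endswith("_down"):
                subtype, part = s.name[:-5], "down"
            else:
                raise ValueError(f"signature set name {s.name!r} must end in _up or _down")
            halves.setdefault(subtype, {})[part] = s.genes
        sigs = {
            subtype: GeneSignature(
                subtype,
                parts.get("up", frozenset()),
                parts.get("down", frozenset()),
            )
            for subtype, parts in halves.items()
        }
        return cls(sigs, universe)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p
    scheme = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=scheme)[1]


def differential_stats(
    matrix: ExpressionMatrix,
    labels: SubtypeLabels,
    subtype: str,
    p_adjust: str = "bh",
) -> pd.DataFrame:
    """Welch t-test of one subtype against all other labelled samples.

    Returns a per-gene frame (t_stat, p, adj_p, logFC); logFC is the
    difference of group means on the log2 scale.  A gene with zero variance
    in both groups gets t=0, p=1 (logged, not fatal).
    """
    in_samples = [s for s in labels.samples_of(subtype) if s in matrix.values.columns]
    rest = [
        s for s in labels.sample_ids
        if labels.assignments[s] != subtype and s in matrix.values.columns
    ]
    if len(in_samples) < 3 or len(rest) < 3:
        raise ValueError(
            f"subtype {subtype!r}: need >=3 samples per group "
            f"(got {len(in_samples)} vs {len(rest)})"
        )
    a = matrix.values[in_samples].to_numpy()
    b = matrix.values[rest].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        logger.info(
            "%s: %d genes with zero variance in both groups -> p=1",
            subtype, int(degenerate.sum()),
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    return pd.DataFrame(
        {"t_stat": t, "p": p, "adj_p": _adjust(p, p_adjust), "logFC": logfc},
        index=matrix.values.index,
    )


def build_signatures(
    matrix: ExpressionMatrix,
    labels: SubtypeLabels,
    p_max: float = 0.05,
    lfc_min: float = 0.5,
    gap_min: float = 0.2,
    p_adjust: str = "bh",
) -> SignatureSet:
    """Construct per-subtype up/down signatures with the uniqueness filters.

    A gene enters subtype s iff it is significant (adj_p < p_max,
    |logFC| > lfc_min) in s and in no other subtype, and the top two
    |logFC| values across subtypes differ by at least gap_min.
    """
    subtypes = labels.subtypes
    stats_by = {s: differential_stats(matrix, labels, s, p_adjust) for s in subtypes}
    lfc = pd.DataFrame({s: stats_by[s]["logFC"] for s in subtypes})
    sig_mask = pd.DataFrame(
        {
            s: (stats_by[s]["adj_p"] < p_max) & (lfc[s].abs() > lfc_min)
            for s in subtypes
        }
    )
    abs_sorted = np.sort(lfc.abs().to_numpy(), axis=1)
    gap_ok = pd.Series(
        abs_sorted[:, -1] - abs_sorted[:, -2] >= gap_min, index=lfc.index
    )
    unique_hit = sig_mask.sum(axis=1) == 1

    signatures = {}
    for s in subtypes:
        keep = sig_mask[s] & unique_hit & gap_ok
        genes = lfc.index[keep]
        up = frozenset(genes[lfc.loc[genes, s] > 0])
        down = frozenset(genes[lfc.loc[genes, s] < 0])
        if not (up or down):
            logger.warning("subtype %s: empty signature at the current thresholds", s)
        signatures[s] = GeneSignature(s, up, down)
    return SignatureSet(signatures, frozenset(matrix.feature_ids))


def ntp_classify(matrix: ExpressionMatrix, signature_set: SignatureSet) -> pd.DataFrame:
    """Nearest-template prediction over the signature genes.

    Each subtype's template assigns +1 to its up genes and -1 to its down
    genes.  For each sample, its expression over each subtype's signature
    genes is z-scored and the subtype with the minimal cosine distance to
    the template wins.  Samples with zero variance over a subtype's
    signature genes cannot be scored for it; samples scoreable for no
    subtype are flagged unclassified (NaN prediction).
    """
    templates = {}
    for subtype, sig in signature_set.signatures.items():
        genes = [g for g in matrix.feature_ids if g in sig.genes]
        if not genes:
            continue
        tmpl = np.array([1.0 if g in sig.up else -1.0 for g in genes])
        templates[subtype] = (genes, tmpl)
    if not templates:
        raise ValueError("no signature gene is present in the expression matrix")

    records = []
    for sample in matrix.sample_ids:
        best, best_d = None, np.inf
        for subtype, (genes, tmpl) in templates.items():
            v = matrix.values.loc[genes, sample].to_numpy()
            sd = v.std()
            if sd == 0:
                continue
            z = (v - v.mean()) / sd
            denom = np.linalg.norm(z) * np.linalg.norm(tmpl)
            d = 1.0 - float(z @ tmpl) / denom
            if d < best_d:
                best, best_d = subtype, d
        if best is None:
            logger.warning("sample %s: zero variance over signature genes; unclassified", sample)
            records.append((sample, np.nan, np.nan))
        else:
            records.append((sample, best, best_d))
    return pd.DataFrame(
        records, columns=["sample_id", "predicted_subtype", "distance"]
    ).set_index("sample_id")


def signature_overlap_test(
    sig_a: frozenset[str] | set[str],
    sig_b: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> tuple[int, float, float]:
    """One-sided (enrichment) Fisher exact test of two gene sets' overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not (set(sig_a) <= set(universe) and set(sig_b) <= set(universe)):
        raise ValueError("signatures must be subsets of the universe")
    k = len(set(sig_a) & set(sig_b))
    a_only = len(sig_a) - k
    b_only = len(sig_b) - k
    neither = len(universe) - len(sig_a) - b_only
    odds, p = stats.fisher_exact([[k, a_only], [b_only, neither]], alternative="greater")
    return k, float(odds), float(p)
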