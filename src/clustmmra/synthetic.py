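"""Synthetic subtype-structured datasets with planted driver clusters.

The generator emits every input the pipeline consumes — miRNA gene loci
(GFF3), paired miRNA/mRNA log2 expression matrices, subtype labels and
multi-source target tables — together with the ground truth needed to score
recovery.  Expression is Gaussian on the log2 scale (baseline mean 6):
signature genes are shifted by ±effect in their subtype, the planted
cluster's miRNAs are shifted by −effect (direction configurable) in the
target subtype, and genes targeted by planted miRNAs are anti-correlated
with their miRNA through a linear coupling on the miRNA's within-subtype
residual, so that true MI edges exist without perturbing group means.

Three decoy clusters each violate exactly one selection criterion:
(a) only one member deregulated; (b) two members deregulated in discordant
directions; (c) members deregulated concordantly but with target sets that
avoid every signature.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from clustmmra.cluster_annotation import GenomicLocus, MirnaCluster, build_clusters
from clustmmra.io_formats import (
    ExpressionMatrix,
    SubtypeLabels,
    TargetTable,
    write_mirna_gff,
)
from clustmmra.signature_builder import GeneSignature, SignatureSet

DECOY_SINGLE_DE = "single_deregulated_member"      # fails step (i)
DECOY_DISCORDANT = "discordant_directions"         # fails step (i)
DECOY_OFF_SIGNATURE = "targets_avoid_signature"    # fails step (ii)


@dataclass
class GeneratorConfig:
    n_samples: int = 200
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: {"LumA": 0.25, "LumB": 0.25, "HER2": 0.25, "TNBC": 0.25}
    )
    n_mirnas: int = 120
    n_clusters: int = 30
    cluster_size_range: tuple[int, int] = (2, 5)
    planted_cluster_size: int = 3
    n_genes: int = 2000
    signature_size: int = 80
    effect: float = 1.2
    noise_sd: float = 1.0
    baseline: float = 6.0
    target_subtype: str = "TNBC"
    planted_direction: str = "down"
    target_fraction_signature: float = 0.3
    planted_target_set_size: int = 150
    coupling_beta: float = 0.8
    background_targets_per_mirna: int = 60
    n_target_sources: int = 3
    source_recall: float = 0.8
    source_fp_rate: float = 0.2

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if any(v <= 0 for v in self.subtype_proportions.values()):
            raise ValueError("subtype proportions must be positive")
        for name in (
            "n_samples", "n_mirnas", "n_clusters", "n_genes", "signature_size",
            "planted_target_set_size", "n_target_sources",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_direction not in ("up", "down"):
            raise ValueError("planted_direction must be up|down")
        if len(self.subtype_proportions) * self.signature_size > self.n_genes:
            raise ValueError("signatures larger than the gene universe")


@dataclass
class SyntheticTruth:
    planted: list[tuple[str, str, str]]  # (cluster_id, subtype, direction)
    decoys: dict[str, str]               # cluster_id -> violated criterion
    planted_pairs: list[tuple[str, str]]
    signature_up: dict[str, list[str]]
    signature_down: dict[str, list[str]]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    loci: list[GenomicLocus]
    clusters: list[MirnaCluster]
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    labels: SubtypeLabels
    target_table: TargetTable
    signatures: SignatureSet  # planted (true) signatures
    truth: SyntheticTruth
    config: GeneratorConfig


def _sample_labels(config: GeneratorConfig) -> SubtypeLabels:
    subtypes = sorted(config.subtype_proportions)
    counts = {s: int(round(config.subtype_proportions[s] * config.n_samples)) for s in subtypes}
    drift = config.n_samples - sum(counts.values())
    counts[subtypes[-1]] += drift
    assignments = {}
    i = 0
    for s in subtypes:
        for _ in range(counts[s]):
            assignments[f"S{i:04d}"] = s
            i += 1
    return SubtypeLabels(assignments)


def _layout_loci(config: GeneratorConfig, sizes: list[int], rng: np.random.Generator):
    """Place clusters far apart (same-chromosome offsets >> 10 kb) with
    members spaced 3 kb apart, then isolated singleton loci."""
    loci: list[GenomicLocus] = []
    members: list[list[str]] = []
    for ci, size in enumerate(sizes):
        chrom = f"chr{(ci % 22) + 1}"
        base = 1_000_000 + (ci // 22) * 7_000_000
        strand = "+" if ci % 2 == 0 else "-"
        names = []
        for j in range(size):
            name = f"syn-mir-{ci:02d}-{j}"
            start = base + j * 3_000
            loci.append(GenomicLocus(name, chrom, start, start + 99, strand))
            names.append(name)
        members.append(names)
    n_singletons = config.n_mirnas - sum(sizes)
    for k in range(n_singletons):
        chrom = f"chr{(k % 22) + 1}"
        start = 80_000_000 + k * 1_000_000
        loci.append(GenomicLocus(f"syn-mir-s{k:03d}", chrom, start, start + 99, "+"))
    return loci, members


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticDataset:
    """Generate a full synthetic input set with known ground truth."""
    rng = np.random.default_rng(seed)
    labels = _sample_labels(config)
    subtypes = labels.subtypes
    if config.target_subtype not in subtypes:
        raise ValueError(f"target subtype {config.target_subtype!r} not among {subtypes}")
    samples = labels.sample_ids
    subtype_of = labels.assignments

    # --- genomic layout -----------------------------------------------------
    if config.n_clusters < 4:
        raise ValueError("need at least 4 clusters (one planted + three decoys)")
    lo, hi = config.cluster_size_range
    sizes = [config.planted_cluster_size, 3, 2, 2] + [
        int(rng.integers(lo, hi + 1)) for _ in range(config.n_clusters - 4)
    ]
    if sum(sizes) > config.n_mirnas:
        raise ValueError("n_mirnas too small for the requested clusters")
    loci, cluster_members = _layout_loci(config, sizes, rng)
    clusters = build_clusters(loci)
    if len(clusters) != config.n_clusters:
        raise AssertionError("generated layout does not reproduce the cluster count")
    id_of = {}
    for c in clusters:
        id_of[frozenset(c.member_names)] = c.cluster_id
    cluster_ids = [id_of[frozenset(m)] for m in cluster_members]

    planted_members = cluster_members[0]
    decoy_ids = {
        cluster_ids[1]: DECOY_SINGLE_DE,
        cluster_ids[2]: DECOY_DISCORDANT,
        cluster_ids[3]: DECOY_OFF_SIGNATURE,
    }

    # --- gene universe and signatures --------------------------------------
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    perm = rng.permutation(config.n_genes)
    sig_up: dict[str, list[str]] = {}
    sig_down: dict[str, list[str]] = {}
    pos = 0
    half = config.signature_size // 2
    for s in subtypes:
        block = perm[pos: pos + config.signature_size]
        pos += config.signature_size
        sig_up[s] = sorted(genes[i] for i in block[:half])
        sig_down[s] = sorted(genes[i] for i in block[half:])
    signature_genes = {g for s in subtypes for g in sig_up[s] + sig_down[s]}
    non_signature = [g for g in genes if g not in signature_genes]

    # --- planted / decoy target assignments ---------------------------------
    tgt = config.target_subtype
    sign = -1.0 if config.planted_direction == "down" else 1.0
    # targets opposite in sign to the cluster (canonical repression pattern)
    opposite_pool = sig_up[tgt] if config.planted_direction == "down" else sig_down[tgt]
    n_sig_targets = min(
        int(round(config.target_fraction_signature * config.signature_size)),
        len(opposite_pool),
    )
    sig_targets = list(rng.choice(opposite_pool, size=n_sig_targets, replace=False))
    n_other = max(config.planted_target_set_size - n_sig_targets, 0)
    other_targets = list(rng.choice(non_signature, size=n_other, replace=False))
    planted_targets = sig_targets + other_targets
    owner = {
        g: planted_members[i % len(planted_members)]
        for i, g in enumerate(planted_targets)
    }
    planted_pairs = sorted((m, g) for g, m in owner.items())

    decoy_c_members = cluster_members[3]
    off_sig_pool = [g for g in non_signature if g not in set(other_targets)]
    decoy_c_targets = list(
        rng.choice(off_sig_pool, size=min(config.planted_target_set_size, len(off_sig_pool)),
                   replace=False)
    )

    # --- miRNA expression ----------------------------------------------------
    mirna_names = [l.name for l in loci]
    subtype_idx = np.array([subtype_of[s] == tgt for s in samples])
    mirna_shift = pd.DataFrame(0.0, index=mirna_names, columns=samples)
    for m in planted_members:
        mirna_shift.loc[m, subtype_idx] = sign * config.effect
    mirna_shift.loc[cluster_members[1][0], subtype_idx] = sign * config.effect
    mirna_shift.loc[cluster_members[2][0], subtype_idx] = sign * config.effect
    mirna_shift.loc[cluster_members[2][1], subtype_idx] = -sign * config.effect
    for m in decoy_c_members:
        mirna_shift.loc[m, subtype_idx] = sign * config.effect

    mirna_noise = rng.normal(0.0, config.noise_sd, size=(len(mirna_names), len(samples)))
    mirna_values = config.baseline + mirna_shift.to_numpy() + mirna_noise
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_values, index=mirna_names, columns=samples), "mirna"
    )
    noise_of = {m: mirna_noise[i] for i, m in enumerate(mirna_names)}

    # --- mRNA expression -----------------------------------------------------
    gene_shift = pd.DataFrame(0.0, index=genes, columns=samples)
    for s in subtypes:
        mask = np.array([subtype_of[x] == s for x in samples])
        gene_shift.loc[sig_up[s], mask] = config.effect
        gene_shift.loc[sig_down[s], mask] = -config.effect
    mrna_values = (
        config.baseline
        + gene_shift.to_numpy()
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    )
    mrna = pd.DataFrame(mrna_values, index=genes, columns=samples)
    # coupling to the miRNA's within-subtype residual: preserves group means,
    # creates the anti-correlation the repression model predicts
    for g, m in owner.items():
        mrna.loc[g] = mrna.loc[g] - config.coupling_beta * noise_of[m]
    mrna = ExpressionMatrix(mrna, "mrna")

    # --- target tables -------------------------------------------------------
    true_pairs: list[tuple[str, str]] = list(planted_pairs)
    for i, g in enumerate(decoy_c_targets):
        true_pairs.append((decoy_c_members[i % len(decoy_c_members)], g))
    for m in mirna_names:
        if m in set(planted_members) or m in set(decoy_c_members):
            continue
        bg = rng.choice(config.n_genes, size=config.background_targets_per_mirna, replace=False)
        true_pairs.extend((m, genes[i]) for i in bg)

    rows = []
    n_true = len(true_pairs)
    for k in range(config.n_target_sources):
        source = f"source_{k}"
        keep = rng.random(n_true) < config.source_recall
        for flag, (m, g) in zip(keep, true_pairs):
            if flag:
                rows.append((m, g, source))
        n_fp = int(config.source_fp_rate * n_true)
        fp_m = rng.choice(mirna_names, size=n_fp)
        fp_g = rng.choice(genes, size=n_fp)
        rows.extend(zip(fp_m, fp_g, [source] * n_fp))
    target_table = TargetTable(pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source"]))

    signatures = SignatureSet(
        {
            s: GeneSignature(s, frozenset(sig_up[s]), frozenset(sig_down[s]))
            for s in subtypes
        },
        frozenset(genes),
    )
    truth = SyntheticTruth(
        planted=[(cluster_ids[0], tgt, config.planted_direction)],
        decoys=decoy_ids,
        planted_pairs=planted_pairs,
        signature_up=sig_up,
        signature_down=sig_down,
        seed=seed,
    )
    return SyntheticDataset(
        loci, clusters, mirna, mrna, labels, target_table, signatures, truth, config
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every standard-format input file plus the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff": outdir / "mirna_loci.gff3",
        "mirna": outdir / "mirna_expression.tsv",
        "mrna": outdir / "mrna_expression.tsv",
        "labels": outdir / "labels.tsv",
        "truth": outdir / "truth.json",
    }
    write_mirna_gff(ds.loci, paths["gff"])
    ds.mirna.to_tsv(paths["mirna"])
    ds.mrna.to_tsv(paths["mrna"])
    ds.labels.to_tsv(paths["labels"])
    ds.truth.to_json(paths["truth"])
    target_paths = []
    for source, sub in ds.target_table.rows.groupby("source", sort=True):
        p = outdir / f"targets_{source}.tsv"
        sub[["mirna_id", "gene_id", "source"]].to_csv(p, sep="\t", index=False)
        target_paths.append(p)
    paths["targets"] = target_paths
    return paths


def truth_eval(report: pd.DataFrame, truth: SyntheticTruth) -> tuple[float, int]:
    """Score a final report against the planted truth.

    Returns (sensitivity over planted (cluster, subtype, direction) triples,
    number of reported triples that are not planted)."""
    planted = {tuple(t) for t in truth.planted}
    if report.empty:
        return 0.0, 0
    reported = {
        (row.cluster_id, row.subtype, row.direction)
        for row in report.itertuples(index=False)
    }
    recovered = len(planted & reported)
    return recovered / len(planted), len(reported - planted)
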