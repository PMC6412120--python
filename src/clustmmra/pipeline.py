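"""End-to-end orchestration of the three-step cluster selection funnel.

``run_clustmmra`` executes: genomic cluster annotation -> step (i)
subtype-specific differential expression -> step (ii) permutation-null
target enrichment -> step (iii) MI network / regulon enrichment.  Each step
consumes only the previous step's survivors; the funnel counts are recorded
and every output directory receives the resolved configuration and tool
version for provenance.  All randomness is driven by the config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from clustmmra import network_regulons as net
from clustmmra import target_enrichment as te
from clustmmra.cluster_annotation import MirnaCluster, build_clusters, clusters_summary
from clustmmra.io_formats import (
    ExpressionMatrix,
    SubtypeLabels,
    TargetTable,
    read_alias_map,
    read_expression_matrix,
    read_gmt,
    read_labels,
    read_mirna_gff,
    read_target_table,
    write_gmt,
)
from clustmmra.signature_builder import SignatureSet, build_signatures
from clustmmra.subtype_diffexp import (
    CandidateCluster,
    candidates_table,
    ks_diffexp,
    select_candidate_clusters,
)

logger = logging.getLogger(__name__)

FINAL_REPORT_COLUMNS = [
    "cluster_id", "chromosome", "n_deregulated_members", "subtype", "direction",
    "signature_direction", "target_set_size", "observed_overlap",
    "null_threshold", "empirical_p", "regulon_size", "fisher_p",
]


@dataclass
class PipelineConfig:
    """All thresholds of the pipeline, with their defaults.

    Thresholds marked default_unverified are not printed in the source
    publication and are echoed loudly once per run.
    """

    # input paths (optional when data is supplied in memory)
    gff: str | None = None
    mirna: str | None = None
    mrna: str | None = None
    labels: str | None = None
    targets: list[str] = field(default_factory=list)
    target_sources: list[str] | None = None
    signatures: str | None = None  # GMT of <subtype>_up/_down sets; built if absent
    alias: str | None = None
    out_dir: str | None = None
    linear_input: bool = False
    gff_feature_type: str = "miRNA_primary_transcript"

    # cluster annotation
    max_gap: int = 10_000
    linkage: str = "single"

    # signature construction
    sig_p_max: float = 0.05
    sig_lfc_min: float = 0.5
    sig_gap_min: float = 0.2
    p_adjust: str = "bh"

    # step (i)  [default_unverified: thresholds mirror the signature ones]
    p_max: float = 0.05
    lfc_min: float = 0.5
    min_dereg: int = 2

    # step (ii)
    min_sources: int = 2
    n_rand: int = 1000
    overlap_quantile: float = 0.95
    directional: bool = False
    correlation_filter: bool = False
    rho_max: float = 0.0
    corr_method: str = "spearman"

    # step (iii)  [default_unverified: MI estimator internals]
    expressed_fraction: float = 0.2
    mi_alpha: float = 0.01
    mi_n_perm: int = 100
    mi_n_pairs: int = 50
    mi_bins: int | None = None
    dpi_tolerance: float = 0.15
    radius: int = 1
    fisher_alpha: float = 0.05
    gene_cap: int = 3000

    seed: int = 0

    DEFAULT_UNVERIFIED = (
        "p_max", "lfc_min", "mi_alpha", "mi_n_perm", "mi_n_pairs",
        "dpi_tolerance", "radius", "fisher_alpha", "expressed_fraction",
    )

    def to_yaml(self, path: str | Path) -> None:
        from clustmmra import __version__

        payload = dataclasses.asdict(self)
        payload["clustmmra_version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.pop("clustmmra_version", None)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass
class PipelineData:
    """In-memory pipeline inputs (clusters + matrices + labels + targets)."""

    clusters: list[MirnaCluster]
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    labels: SubtypeLabels
    target_table: TargetTable
    signatures: SignatureSet | None = None
    alias: dict[str, str] | None = None

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "PipelineData":
        for name in ("gff", "mirna", "mrna", "labels"):
            if getattr(cfg, name) is None:
                raise ValueError(f"config path {name!r} is required")
        if not cfg.targets:
            raise ValueError("at least one target table path is required")
        alias = read_alias_map(cfg.alias) if cfg.alias else None
        loci = read_mirna_gff(cfg.gff, cfg.gff_feature_type)
        clusters = build_clusters(loci, cfg.max_gap, cfg.linkage)
        mirna = read_expression_matrix(cfg.mirna, "mirna", cfg.linear_input)
        mrna = read_expression_matrix(cfg.mrna, "mrna", cfg.linear_input)
        labels = read_labels(cfg.labels)
        table = read_target_table(cfg.targets, cfg.target_sources, alias)
        signatures = None
        if cfg.signatures:
            signatures = SignatureSet.from_gene_sets(
                read_gmt(cfg.signatures), frozenset(mrna.feature_ids)
            )
        return cls(clusters, mirna, mrna, labels, table, signatures, alias)

    @classmethod
    def from_synthetic(cls, ds, use_true_signatures: bool = False) -> "PipelineData":
        return cls(
            ds.clusters,
            ds.mirna,
            ds.mrna,
            ds.labels,
            ds.target_table,
            ds.signatures if use_true_signatures else None,
        )


@dataclass
class PipelineResult:
    final_report: pd.DataFrame
    funnel: dict[str, int]
    diffexp: pd.DataFrame
    candidates: pd.DataFrame
    enrichment: pd.DataFrame
    regulons: pd.DataFrame
    qc: pd.DataFrame
    signatures: SignatureSet
    config: PipelineConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.final_report.to_csv(out / "final_report.tsv", sep="\t", index=False)
        self.diffexp.to_csv(out / "step1_mirna_diffexp.tsv", sep="\t", index=False)
        self.candidates.to_csv(out / "step1_candidates.tsv", sep="\t", index=False)
        self.enrichment.to_csv(out / "step2_enrichment.tsv", sep="\t", index=False)
        self.regulons.to_csv(out / "step3_regulons.tsv", sep="\t", index=False)
        self.qc.to_csv(out / "step3_target_mi_qc.tsv", sep="\t", index=False)
        pd.Series(self.funnel, name="count").rename_axis("stage").to_csv(
            out / "funnel.tsv", sep="\t"
        )
        write_gmt(self.signatures.to_gene_sets(), out / "signatures.gmt")
        self.config.to_yaml(out / "config.yaml")


def _align_samples(
    mirna: ExpressionMatrix, mrna: ExpressionMatrix, labels: SubtypeLabels
) -> tuple[ExpressionMatrix, ExpressionMatrix, SubtypeLabels]:
    if set(mirna.sample_ids) != set(mrna.sample_ids):
        raise ValueError("inconsistent sample pairing between miRNA and mRNA matrices")
    samples = [s for s in labels.sample_ids if s in set(mirna.sample_ids)]
    if len(samples) < len(labels.sample_ids):
        logger.warning(
            "%d labelled samples missing from the matrices are dropped",
            len(labels.sample_ids) - len(samples),
        )
    kept = SubtypeLabels({s: labels.assignments[s] for s in samples})
    return mirna.subset_samples(samples), mrna.subset_samples(samples), kept


def run_clustmmra(data: PipelineData, cfg: PipelineConfig) -> PipelineResult:
    """Run the full funnel and return per-step tables plus the final report."""
    for key in cfg.DEFAULT_UNVERIFIED:
        logger.info("threshold %s=%r (default_unverified)", key, getattr(cfg, key))
    mirna, mrna, labels = _align_samples(data.mirna, data.mrna, data.labels)
    universe = frozenset(mrna.feature_ids)
    rng_step2, rng_step3 = [
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    ]

    signatures = data.signatures
    if signatures is None:
        signatures = build_signatures(
            mrna, labels, cfg.sig_p_max, cfg.sig_lfc_min, cfg.sig_gap_min, cfg.p_adjust
        )

    # ---- step (i): subtype-specific expression of clustered miRNAs ----------
    diffexp = ks_diffexp(mirna, labels, cfg.p_max, cfg.lfc_min, cfg.p_adjust)
    candidates = select_candidate_clusters(
        diffexp, data.clusters, cfg.min_dereg, data.alias
    )

    # ---- step (ii): permutation-null target enrichment ----------------------
    target_map = te.aggregate_targets(data.target_table, cfg.min_sources)
    if cfg.correlation_filter:
        target_map = te.filter_targets_by_correlation(
            target_map, mirna, mrna, cfg.rho_max, cfg.corr_method
        )
    enrichment_results = [
        te.target_enrichment_filter(
            c, target_map, signatures, sorted(universe),
            cfg.n_rand, cfg.overlap_quantile, rng_step2, cfg.directional,
        )
        for c in candidates
    ]
    step2_survivors = [
        c for c, r in zip(candidates, enrichment_results) if r.passed
    ]

    # ---- step (iii): MI network, regulon, Fisher enrichment -----------------
    regulon_rows: list[dict] = []
    qc_frames: list[pd.DataFrame] = []
    final_rows: list[dict] = []
    if step2_survivors:
        expressed = net.expressed_genes(mrna, cfg.expressed_fraction)
        mi_threshold = net.mi_significance_threshold(
            mrna.values.to_numpy(),
            n_perm=cfg.mi_n_perm,
            alpha=cfg.mi_alpha,
            n_pairs=cfg.mi_n_pairs,
            bins=cfg.mi_bins,
            rng=rng_step3,
        )
        logger.info("MI significance threshold: %.4g nats", mi_threshold)
        enr_by_key = {r.cluster_id + r.subtype + r.direction: r for r in enrichment_results}
        chrom_of = {c.cluster_id: c.chromosome for c in data.clusters}
        for cand in step2_survivors:
            network = net.build_aracne_network(
                cand, mirna, mrna, expressed, mi_threshold,
                cfg.dpi_tolerance, cfg.gene_cap, cfg.mi_bins,
            )
            regulon = net.extract_regulon(network, cand, cfg.radius)
            sig = signatures.signatures[cand.subtype]
            regulon = net.regulon_signature_test(
                regulon, sig.genes, universe, cfg.fisher_alpha
            )
            qc = net.target_mi_qc(network, target_map, cand)
            qc.insert(0, "cluster_id", cand.cluster_id)
            qc.insert(1, "subtype", cand.subtype)
            qc_frames.append(qc)
            regulon_rows.append(
                {
                    "cluster_id": cand.cluster_id,
                    "subtype": cand.subtype,
                    "direction": cand.direction,
                    "regulon_size": len(regulon.genes),
                    "fisher_p": regulon.fisher_p,
                    "odds_ratio": regulon.odds_ratio,
                    "passed": regulon.passed,
                }
            )
            if regulon.passed:
                enr = enr_by_key[cand.cluster_id + cand.subtype + cand.direction]
                tset = te.cluster_target_set(cand, target_map) & universe
                n_up = len(tset & sig.up)
                n_down = len(tset & sig.down)
                sig_dir = "up" if n_up >= n_down else "down"
                final_rows.append(
                    {
                        "cluster_id": cand.cluster_id,
                        "chromosome": chrom_of.get(cand.cluster_id, "NA"),
                        "n_deregulated_members": len(cand.deregulated_members),
                        "subtype": cand.subtype,
                        "direction": cand.direction,
                        "signature_direction": sig_dir,
                        "target_set_size": enr.target_set_size,
                        "observed_overlap": enr.observed_overlap,
                        "null_threshold": enr.null_threshold,
                        "empirical_p": enr.empirical_p,
                        "regulon_size": len(regulon.genes),
                        "fisher_p": regulon.fisher_p,
                    }
                )

    final_report = pd.DataFrame(final_rows, columns=FINAL_REPORT_COLUMNS)
    funnel = {
        "clusters_analyzed": len(data.clusters),
        "step1_candidates": len(candidates),
        "step2_survivors": len(step2_survivors),
        "step3_survivors": len(final_report),
    }
    logger.info("funnel: %s", funnel)
    result = PipelineResult(
        final_report=final_report,
        funnel=funnel,
        diffexp=diffexp,
        candidates=candidates_table(candidates),
        enrichment=pd.DataFrame([r.as_row() for r in enrichment_results]),
        regulons=pd.DataFrame(
            regulon_rows,
            columns=[
                "cluster_id", "subtype", "direction", "regulon_size",
                "fisher_p", "odds_ratio", "passed",
            ],
        ),
        qc=(
            pd.concat(qc_frames, ignore_index=True)
            if qc_frames
            else pd.DataFrame(
                columns=["cluster_id", "subtype", "mirna_id", "rank_sum_p",
                         "n_targets", "n_non_targets"]
            )
        ),
        signatures=signatures,
        config=cfg,
    )
    if cfg.out_dir:
        result.write(cfg.out_dir)
    return result


def run_single_mirna_mode(
    data: PipelineData, cfg: PipelineConfig
) -> tuple[PipelineResult, pd.DataFrame]:
    """Degenerate single-miRNA mode for comparison with the cluster pipeline.

    Every miRNA is treated as its own candidate (min_dereg = 1) through
    steps (ii) and (iii); a genomic cluster then counts as detected iff at
    least two of its members individually survive the whole funnel for the
    same (subtype, direction).  Returns the per-miRNA result and the
    cluster-level detection table.
    """
    single_cfg = dataclasses.replace(cfg, min_dereg=1, out_dir=None)
    mirna, mrna, labels = _align_samples(data.mirna, data.mrna, data.labels)
    diffexp = ks_diffexp(mirna, labels, cfg.p_max, cfg.lfc_min, cfg.p_adjust)
    dereg = diffexp[diffexp["direction"].isin(("up", "down"))]
    singles = [
        CandidateCluster(row.mirna_id, row.subtype, row.direction, [row.mirna_id])
        for row in dereg.itertuples(index=False)
    ]
    # reuse the funnel machinery on singleton candidates
    pseudo = dataclasses.replace(data)

    result = _run_candidates(pseudo, single_cfg, mirna, mrna, labels, diffexp, singles)

    alias = data.alias or {}
    detected_rows = []
    surviving = result.final_report
    for cluster in data.clusters:
        members = set(cluster.member_names)
        if surviving.empty:
            hits = pd.DataFrame(columns=["subtype", "direction", "cluster_id"])
        else:
            locus = surviving["cluster_id"].map(lambda m: alias.get(m, m))
            hits = surviving[locus.isin(members)]
        for (subtype, direction), sub in hits.groupby(["subtype", "direction"]):
            detected_rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "subtype": subtype,
                    "direction": direction,
                    "n_members_detected": len(sub),
                    "detected": len(sub) >= 2,
                }
            )
    detection = pd.DataFrame(
        detected_rows,
        columns=["cluster_id", "subtype", "direction", "n_members_detected", "detected"],
    ).astype({"n_members_detected": int, "detected": bool})
    return result, detection


def _run_candidates(data, cfg, mirna, mrna, labels, diffexp, candidates):
    """Steps (ii)+(iii) on a prebuilt candidate list (single-miRNA mode)."""
    inner = PipelineData(
        data.clusters, mirna, mrna, labels, data.target_table,
        data.signatures, data.alias,
    )
    universe = frozenset(mrna.feature_ids)
    rng_step2, rng_step3 = [
        np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(2)
    ]
    signatures = inner.signatures
    if signatures is None:
        signatures = build_signatures(
            mrna, labels, cfg.sig_p_max, cfg.sig_lfc_min, cfg.sig_gap_min, cfg.p_adjust
        )
    target_map = te.aggregate_targets(inner.target_table, cfg.min_sources)
    if cfg.correlation_filter:
        target_map = te.filter_targets_by_correlation(
            target_map, mirna, mrna, cfg.rho_max, cfg.corr_method
        )
    enrichment_results = [
        te.target_enrichment_filter(
            c, target_map, signatures, sorted(universe),
            cfg.n_rand, cfg.overlap_quantile, rng_step2, cfg.directional,
        )
        for c in candidates
    ]
    survivors = [c for c, r in zip(candidates, enrichment_results) if r.passed]
    final_rows = []
    regulon_rows = []
    if survivors:
        expressed = net.expressed_genes(mrna, cfg.expressed_fraction)
        mi_threshold = net.mi_significance_threshold(
            mrna.values.to_numpy(), n_perm=cfg.mi_n_perm, alpha=cfg.mi_alpha,
            n_pairs=cfg.mi_n_pairs, bins=cfg.mi_bins, rng=rng_step3,
        )
        for cand in survivors:
            network = net.build_aracne_network(
                cand, mirna, mrna, expressed, mi_threshold,
                cfg.dpi_tolerance, cfg.gene_cap, cfg.mi_bins,
            )
            regulon = net.extract_regulon(network, cand, cfg.radius)
            sig = signatures.signatures[cand.subtype]
            regulon = net.regulon_signature_test(
                regulon, sig.genes, universe, cfg.fisher_alpha
            )
            regulon_rows.append(
                {
                    "cluster_id": cand.cluster_id, "subtype": cand.subtype,
                    "direction": cand.direction, "regulon_size": len(regulon.genes),
                    "fisher_p": regulon.fisher_p, "odds_ratio": regulon.odds_ratio,
                    "passed": regulon.passed,
                }
            )
            if regulon.passed:
                final_rows.append(
                    {
                        "cluster_id": cand.cluster_id,
                        "chromosome": "NA",
                        "n_deregulated_members": 1,
                        "subtype": cand.subtype,
                        "direction": cand.direction,
                        "signature_direction": "NA",
                        "target_set_size": 0,
                        "observed_overlap": 0,
                        "null_threshold": 0,
                        "empirical_p": np.nan,
                        "regulon_size": len(regulon.genes),
                        "fisher_p": regulon.fisher_p,
                    }
                )
    final_report = pd.DataFrame(final_rows, columns=FINAL_REPORT_COLUMNS)
    funnel = {
        "clusters_analyzed": len(candidates),
        "step1_candidates": len(candidates),
        "step2_survivors": len(survivors),
        "step3_survivors": len(final_report),
    }
    return PipelineResult(
        final_report=final_report,
        funnel=funnel,
        diffexp=diffexp,
        candidates=candidates_table(candidates),
        enrichment=pd.DataFrame([r.as_row() for r in enrichment_results]),
        regulons=pd.DataFrame(
            regulon_rows,
            columns=["cluster_id", "subtype", "direction", "regulon_size",
                     "fisher_p", "odds_ratio", "passed"],
        ),
        qc=pd.DataFrame(columns=["cluster_id", "subtype", "mirna_id",
                                 "rank_sum_p", "n_targets", "n_non_targets"]),
        signatures=signatures,
        config=cfg,
    )


def write_clusters_tsv(clusters: list[MirnaCluster], path: str | Path) -> None:
    clusters_summary(clusters).to_csv(path, sep="\t", index=False)
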