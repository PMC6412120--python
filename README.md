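# clustmmra

Identification of **genomically clustered miRNAs** (polycistronic
transcripts) whose coordinated deregulation drives molecular subtypes of
cancer, from paired miRNA/mRNA expression matrices and per-sample subtype
labels.

More than 30 % of human miRNAs lie in genomic clusters — miRNA genes
within 10 kb on the same strand, typically co-transcribed as one primary
transcript — and clustered miRNAs frequently co-target components of the
same pathways.  Methods that score one miRNA at a time miss this
cooperative mode of action: a cluster can jointly regulate a subtype's
gene-expression signature even though no single member shows a
significant target enrichment on its own.  `clustmmra` is built for
computational biologists who have expression cohorts classified into
subtypes (e.g. LumA / LumB / HER2+ / TNBC in breast cancer) and want a
ranked list of candidate driver clusters.

## Method

Candidate clusters pass through a three-step filtering funnel:

1. **Subtype-specific expression.**  Each miRNA is tested per subtype
   against all other samples with a two-sample Kolmogorov–Smirnov test
   plus a fold-change cutoff (BH-adjusted *p* < 0.05, |log₂FC| > 0.5).
   A cluster survives when ≥ 2 members are deregulated in the same
   direction in the same subtype.
2. **Target enrichment against a permutation null.**  Multi-source
   target predictions are merged (a pair must be supported by ≥ 2
   databases); the cluster's target set is the union over its
   deregulated members.  1000 random gene sets of the same size are
   drawn from the expression universe, and the cluster passes only if
   |targets ∩ signature| strictly exceeds the 95th percentile of the
   null overlaps.
3. **Network analysis.**  An ARACNE-style mutual-information network is
   inferred between the cluster's miRNAs and all expressed genes
   (rank-binned plug-in MI estimator, permutation-calibrated edge
   threshold, DPI pruning of indirect edges).  The genes within graph
   radius of the cluster — its *regulon* — are tested for signature
   enrichment with a one-sided Fisher exact test
   (P(X ≥ k) under the hypergeometric null).

Per-subtype up/down signatures can be built in-package (Welch *t*-test
with uniqueness filters, validated by nearest-template prediction), and
runs on independent cohorts can be compared with exact hypergeometric
intersection statistics.  A synthetic-data module generates full input
sets with planted driver clusters and decoys for validation.

## Worked example

Generate a synthetic cohort (200 samples, 4 subtypes, 30 clusters, 2000
genes) with one planted driver cluster — 3 miRNAs down-regulated in TNBC
whose targets cover 30 % of the TNBC signature — and three decoy
clusters, then run the full funnel:

```bash
clustmmra simulate --seed 7 --out fixtures
# wrote synthetic dataset to fixtures (120 loci, 30 clusters)
# planted truth: [('syn-mir-00-0/2', 'TNBC', 'down')]

cat > run.yaml <<EOF
gff: fixtures/mirna_loci.gff3
mirna: fixtures/mirna_expression.tsv
mrna: fixtures/mrna_expression.tsv
labels: fixtures/labels.tsv
targets: [fixtures/targets_source_0.tsv, fixtures/targets_source_1.tsv, fixtures/targets_source_2.tsv]
seed: 7
EOF
clustmmra run --config run.yaml --out-dir out
# funnel:
#   clusters_analyzed: 30
#   step1_candidates: 2
#   step2_survivors: 1
#   step3_survivors: 1
```

`out/final_report.tsv` then contains exactly the planted cluster:

```
cluster_id      chromosome  n_deregulated_members  subtype  direction  signature_direction  target_set_size  observed_overlap  null_threshold  empirical_p  regulon_size  fisher_p
syn-mir-00-0/2  chr1        3                      TNBC     down       up                   133              16                6               0.000999     218           5.84e-11
```

Reading the row: all 3 members of the chr1 cluster are down-regulated in
TNBC; of its 133 aggregated targets, 16 fall in the TNBC signature where
random same-size sets reach at most 6 at the 95th percentile
(empirical *p* ≈ 1e-3); and its 218-gene MI regulon is enriched in the
signature at Fisher *p* ≈ 6e-11.  The decoy clusters (one deregulated
member; discordant directions; targets outside the signature) die at
steps (i), (i) and (ii) — the funnel above shows only the planted
cluster and the off-signature decoy reaching step (ii), and only the
planted cluster surviving it.  Two runs with the same config and seed
reproduce every output file byte-for-byte.

Other subcommands: `clustmmra clusters` (genomic annotation only),
`clustmmra signatures` (build the GMT of subtype signatures),
`clustmmra consensus --a runA/final_report.tsv --b runB/final_report.tsv
--universe-n 131` (cross-cohort intersection significance),
`clustmmra run --single-mirna` (degenerate one-miRNA-at-a-time mode for
method comparison).

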