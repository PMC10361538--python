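# tilmotif

Analysis of T-cell receptor (TCR) β-chain repertoires from tumor,
healthy-tissue, blood and tumor-infiltrating-lymphocyte (TIL) culture
samples, built for studying what happens to tumor-reactive T-cell clones
when TILs are expanded for adoptive cell therapy.

The package is aimed at computational immunologists working with bulk
TCRβ-seq clonotype tables (AIRR / immunoSEQ-style TSV) and single-cell
clonotype–phenotype tables. It covers:

- **Repertoire I/O and filters** — productive-only filtering, exclusion of
  samples under 10,000 reads, singleton removal, seeded
  multivariate-hypergeometric downsampling.
- **Diversity and clonality** — Gini index, Shannon entropy, inverse
  Simpson, Chao1 richness, and clonality `1 − H/ln S`.
- **Clonotype dynamics** — top-clone tracking across samples, overlap with
  Spearman correlation on log frequencies, clonal-expansion testing
  between paired samples, and exact-match annotation against
  epitope-labelled reference TCR tables.
- **CDR3β motif discovery** — GLIPH2-style local motifs: contiguous 3/4-mers
  and single-wildcard patterns from the central CDR3 region, shared by ≥3
  distinct TCRs and enriched over a naive background repertoire.
- **Tumor association** — motifs classified *exclusive* (absent from
  comparator-tissue discovery), *enriched* (two-sided Wilcoxon on
  per-sample pooled frequencies, BH-adjusted p < 0.05 and log₂fc > 1), or
  *rejected*; motifs found in control cohorts or viral motif lists are
  pruned.
- **Motif burden** — fraction of a repertoire's reads (and of its distinct
  clonotypes) carried by motif-bearing TCRs, with same-location matching
  at the discovery offsets, plus burden-to-antiviral ratios.
- **Phenotype assignment** — for each motif with ≥5 supporting single
  cells, per-phenotype odds ratios (Haldane–Anscombe corrected) and the
  largest-OR dominant phenotype; Tirosh-style module scores (cytotoxicity,
  exhaustion, tissue residency) with binned expression-matched controls.
- **Synthetic cohorts** — a generator that emulates the statistical
  structure of such a study (Zipf clone sizes, planted tumor-biased
  motifs, mass-balanced expansion truths, viral spike-ins,
  phenotype-biased single cells) with a complete ground-truth manifest, so
  every stage is testable without patient data.

## Core statistics

For a repertoire with clone frequencies *p₁ … p_S*:

- Gini = Σᵢ(2i − S − 1)·p₍ᵢ₎ / S (sorted ascending); inverse Simpson
  = 1/Σpᵢ²; clonality = 1 − H/ln S with H = −Σpᵢ ln pᵢ;
  Chao1 = S + F₁²/(2F₂), falling back to the bias-corrected form when no
  doubletons exist.
- Expansion of a clonotype between samples A and B: two-sided Fisher exact
  test on [[count_A, total_A − count_A], [count_B, total_B − count_B]],
  Benjamini–Hochberg correction across all clonotypes in the union, called
  expanded when p_adj < 0.05 **and** the clone reaches ≥0.1% in either
  sample.
- Motif enrichment at discovery: one-sided Fisher (hypergeometric
  survival) of carrier counts in the pooled cohort vs a naive reference,
  BH-adjusted, with a fold floor (default 10×).

## Worked example

```python
import tilmotif as tm

cohort = tm.generate_cohort(tm.GeneratorConfig(), seed=7)

tumor = cohort.tumor[0]
pre, rep = cohort.til_pairs[0]
print(f"gini(tumor)   = {tm.gini_index(tumor):.3f}")
print(f"gini(pre-REP) = {tm.gini_index(pre):.3f}")

reference = tm.MotifCounts(tm.naive_reference())
idx = {t: tm.discover_cohort_motifs(c, reference, tissue=t)
       for t, c in [("tumor", cohort.tumor),
                    ("healthy_kidney", cohort.healthy), ("pb", cohort.pb)]}
assoc = tm.classify_motifs(idx["tumor"],
                           {k: v for k, v in idx.items() if k != "tumor"},
                           cohort.tumor,
                           {"healthy_kidney": cohort.healthy, "pb": cohort.pb})
assoc = tm.prune_against_controls(
    assoc, sorted((n, set(m)) for n, m in cohort.manifest.control_sets.items()))
records = [idx["tumor"][a.motif] for a in tm.associated_motifs(assoc)]
for t in (tumor, pre, rep):
    b = tm.motif_burden(t, records)
    print(f"motif burden {t.tissue:<12} = {100 * b.fraction_reads:5.1f}% of reads")

res = tm.test_expansion(pre, rep, mode="aa")
print(f"expanded clonotypes: {(res['expanded_in'] != 'none').sum()} of {len(res)}")
```

prints

```
gini(tumor)   = 0.736
gini(pre-REP) = 0.928
motif burden tumor        =  24.2% of reads
motif burden pre_rep_til  =  32.5% of reads
motif burden rep_til      =  14.9% of reads
expanded clonotypes: 14 of 128
```

The pre-expansion TIL culture is far more clonal than the tumor (Gini 0.93
vs 0.74) and carries the largest share of tumor-associated-motif TCRs;
that share drops after rapid expansion, and the expansion test flags the
clones behind the shift. The discovered motif set contains the ten planted
tumor-associated motifs plus their sub-patterns, while the two motifs
planted into the control sets are pruned.

A `tilmotif` command-line interface wraps each stage
(`tilmotif simulate|io|diversity|expand|motifs|burden|phenotype|run`);
`tilmotif run --config pipeline.yaml` executes everything end to end and
writes per-stage TSVs plus a provenance record.

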