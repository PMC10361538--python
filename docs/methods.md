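# Methods

This note documents the models and procedures implemented in `tilmotif`,
the defaults they use, and what the synthetic-data tests do and do not
demonstrate.

## Repertoire model and filters

A repertoire sample is a table of TCRβ clonotypes (CDR3 nucleotide and
amino-acid sequence, V/J gene calls, read/template count, productive
flag). "Reads" and "templates" are treated as one `count` column; the
dialect mappings (AIRR, immunoSEQ-style, simple TSV) are documented in
`repertoire.py`. Three keying granularities are supported: CDR3aa only
(used for cross-sample tracking and expansion testing, where nucleotide
convergence should not split a clone), CDR3aa+V+J (default for overlap
analyses), and exact nucleotide (reserved for single-cell joins, where a
clonotype is defined by its exact rearrangement).

Validation drops, with a per-sample log rather than a hard failure:
non-positive counts, empty CDR3aa, CDR3aa shorter than 5 residues (too
short to host a length-3 motif in the trimmed central region), and
productive-flagged rows containing a stop codon. Real immunoSEQ exports
contain such rows routinely, so read-time validation is permissive;
`filter_productive` applied to an in-memory table treats the
productive-with-stop combination as an invariant violation and raises.

Standard cohort filters: productive-only; exclusion of samples under
10,000 total reads; singleton (count = 1) removal for blood samples before
motif quantification; a 100-read floor for shallow RNA-derived
repertoires; and downsampling to 40,000 reads for depth comparability.
Downsampling is a seeded multivariate-hypergeometric draw (without
replacement) over the clone-count vector — the conservative choice, since
sampling reads with replacement would inflate the tail. Clones reduced to
zero are dropped; the target total is hit exactly.

## Diversity and clonality

Gini, Shannon, inverse Simpson and clonality are computed on the observed
clone-frequency vector with no unseen-species correction; Chao1 is the
richness estimator S + F₁²/(2F₂) with the bias-corrected fallback
S + F₁(F₁−1)/(2(F₂+1)) when F₂ = 0. Clonality is defined as one minus
Pielou evenness (1 − H/ln S) and returns 0 for the degenerate single-clone
repertoire, which is also flagged in the summary. Gini, inverse Simpson
and clonality are invariant to scaling all counts; Chao1 is not, which is
why diversity outputs are emitted both for the full samples and for
samples downsampled to the smallest repertoire within each tissue group —
which variant is appropriate depends on whether richness or dominance is
the question.

## Expansion testing

For two paired repertoires (e.g. pre-expansion vs post-expansion TIL
cultures), every clonotype in the union is tested with a two-sided Fisher
exact test on its 2×2 read table, on *full* (non-downsampled) counts.
P-values are Benjamini–Hochberg corrected across the whole union — the
union is the natural testing universe since a clone absent from one sample
is exactly the interesting case. A clone is called expanded when
p_adj < α (default 0.05) and its frequency reaches the floor (default
0.1%, inclusive) in at least one sample; the direction is the sample with
the larger frequency. The min-frequency gate is applied after correction,
so significance and abundance are independent conditions.

The two-sided Fisher p is the conventional one: the sum of probabilities
of all tables no more probable than the observed table. Implementations
differ on tie handling; ours follows scipy's relative-tolerance convention
and is verified against full hypergeometric enumeration to 1e-10 for
margins up to 200. BH is implemented as the textbook step-up
(adjᵢ = min over j ≥ i of p₍ⱼ₎·m/j) so that it agrees *exactly* with an
independent step-up oracle.

## Motif discovery

Local motifs are enumerated from the central CDR3β region after trimming a
conserved head (default 3 residues) and tail (default 2): all contiguous
k-mers for k ∈ {3, 4}, plus, for each k, all (k+1)-mers with exactly one
internal position replaced by the wildcard `*`. Offsets are recorded in
full-CDR3 coordinates. This reimplements the local-motif concept behind
GLIPH2-style specificity grouping; global similarity clustering,
HLA scoring and V-gene bias are deliberately out of scope because every
downstream step here consumes motif strings and offsets only.

Discovery pools distinct TCRs (CDR3aa + V gene) across the cohort's
samples, counts carriers of each candidate motif in the cohort and in a
naive reference repertoire, and tests one-sided enrichment (hypergeometric
survival ≡ Fisher "greater") with BH correction across all candidates that
meet the cluster floor (≥3 distinct TCRs — tested candidates only, so the
correction is not diluted by unreportable patterns). Retention requires
p_adj < 0.05 and fold ≥ 10, where fold is the carrier-proportion ratio
with the reference count floored at one carrier (a motif absent from the
reference otherwise has infinite fold). These defaults mirror common
GLIPH2-style settings and are all configurable.

The reference background is generated deterministically from a fixed seed
by the synthetic module (2,000 clonotypes with the same V/J scaffolds and
length distribution, no planted signal) and is user-replaceable by any
repertoire. Using the same scaffold model for cohort and reference is what
makes scaffold-driven k-mers non-enriched.

## Tumor association and pruning

A motif discovered in the tumor cohort is **exclusive** when absent from
every comparator-tissue discovery index. Shared motifs are compared on
per-sample *pooled frequencies*: within each sample, the summed frequency
of all TCRs carrying the motif at a discovery offset, with samples lacking
the motif contributing 0. Read-weighted pooling is the default (the
quantity is a repertoire proportion); unique-clonotype weighting is also
available. The tumor vector is tested against each comparator vector with
a two-sided Wilcoxon rank-sum test — exact enumeration (tie-aware, needed
because the vectors are zero-inflated) when C(n₁+n₂, n₁) ≤ 2·10⁵,
otherwise the normal approximation with tie and continuity corrections —
BH-corrected per comparator across motifs. **Enriched** requires
p_adj < 0.05 and log₂ fold change > 1 against the healthy-kidney and/or
blood comparator; either comparator suffices by default (an
all-comparators mode exists). log₂fc uses the mean of per-sample pooled
frequencies (median available), with the zero-comparator pseudocount set
to the smallest representable nonzero frequency in that comparator pool
(one read in its deepest sample). A motif with zero pooled frequency in
every tumor sample is rejected with an undefined-log₂fc flag rather than
given an arbitrary fold.

Pruning removes any motif appearing in a control set (validation-cohort
motif lists, viral motif lists); it is order-independent and idempotent,
and the surviving exclusive ∪ enriched motifs form the tumor-associated
set. Every discovered motif therefore ends in exactly one of four states:
exclusive, enriched, rejected, pruned.

## Motif burden

A clonotype is motif-bearing when at least one motif of the query set
occurs in its CDR3aa at one of that motif's discovery offsets ("same
location" matching — the most literal reading; offset-free matching is a
switch). The union fraction is reported read-weighted and
unique-weighted, along with each motif's own carrier-read fraction (a TCR
can carry several motifs, so per-motif contributions may sum to more than
the union). Burden-to-reference ratios (e.g. against the anti-viral TCR
fraction from exact reference-table matching) return NaN for a zero
reference fraction rather than inventing a value.

## Phenotype assignment and module scores

For each motif, supporting cells are those whose CDR3β carries the motif
at an allowed offset. Per phenotype P, the 2×2 table over all phenotyped
cells (motif × P) gives an odds ratio; when any cell is zero all four
cells get +0.5 (Haldane–Anscombe), keeping the arg-max well defined. The
dominant phenotype is the largest OR, ties broken by more supporting cells
in that phenotype, then lexicographically. Calls require ≥5 supporting
cells; smaller motifs are skipped and logged.

Module scores follow the binned-control procedure: genes are ranked by
average expression across cells and cut into 24 equal-occupancy bins; each
module gene draws 100 control genes with replacement from its bin,
*excluding module genes from the control pool*; the per-cell score is the
mean over module genes minus the mean over all sampled controls, on the
log-normalized matrix (ln(1 + 10⁴·count/cell-total)). Scores are seeded
and deterministic. Shipped gene sets: cytotoxicity (GZMB, GZMA, GZMH,
PRF1, GNLY, FGFBP2), exhaustion (PDCD1, LAG3, CTLA4, TIGIT, TOX, HAVCR2),
tissue residency (ITGA1, ITGAE, ZNF683, CD69, IFNG, CCR5).

## Synthetic cohorts: what they emulate

The generator's defaults define the study conditions used throughout the
tests: 20 tumor / 20 healthy-kidney / 20 blood discovery samples, 7
matched TIL culture pairs, 100–120 clones and ~20,000 reads per sample.
CDR3s are a V-scaffold prefix (e.g. `CASS`), a stochastic core over the
19-letter alphabet (no internal cysteine), and a J suffix; lengths 11–19.
Clone sizes follow a Zipf law with compartment exponents 1.2 (tumor), 1.0
(healthy, blood), 2.0 (pre-expansion TIL) and 1.4 (post-expansion) —
chosen so pre-expansion cultures are dominated by their top clones, the
dominance structure such cultures show, without claiming a measured
exponent. Counts are multinomial draws from the Zipf frequencies.

Ten tumor-associated motifs are planted (half exclusive, half enriched;
lengths cycling 4,4,4,5 with length-5 patterns carrying one internal
wildcard) at a fixed per-motif offset, into 5 distinct carrier clones per
tumor sample (mid-rank clones, ranks 20–90); enriched motifs also appear
in comparator tissues at one tenth the tumor incidence. Two additional
contaminant motifs are planted in tumor *and* listed in a control set to
exercise pruning. TIL pairs share a clone backbone; designated expansion
clones come in mass-balanced mirrored pairs (a motif-carrying clone at
5–8% before expansion shrinking by a uniform 10–40× fold, matched by a
non-carrier clone growing by the same construction), so all non-designated
clones keep identical true frequencies in both samples and the expansion
truth list is exact. Viral spike-ins come from a packaged *synthetic*
VDJdb-like table (fabricated CDR3s and epitope labels, no real database
entries) at fixed read counts, so annotated fractions are exactly
recoverable. The single-cell generator draws 2,000 cells over 8 phenotype
labels; motif-bearing cells take their motif's target phenotype with
probability 0.9; the expression matrix is negative-binomial background
with log-normal elevation of each signature's genes in its owning
phenotype.

Scoring discovery against the manifest counts a discovered motif as
*plant-derived* when more than half of its carrier TCRs are
manifest-recorded planted carriers: enumeration necessarily reports
sub-patterns and boundary-shifted variants of a planted insert, and their
support is the planted signal, not a false discovery. Sensitivity is
stricter — it requires the exact planted motif strings in the final
associated set.

What passing these tests does *not* show: recovery on real repertoires
with V(D)J-generation sequence biases, HLA-driven convergence, or clone
size distributions deviating from a power law; robustness to batch effects
between cohorts sequenced on different platforms; or agreement with
GLIPH2's exact output (global-similarity clusters in particular). The
synthetic nulls are exchangeable by construction; real comparator cohorts
are not.

## Numerical choices and problem sizes

Ties in top-clone tracking are broken lexicographically by clonotype key.
Spearman correlations on fewer than 3 shared clones are reported as
undefined (NaN) rather than computed. Expansion odds ratios with a zero
denominator are NaN; the p-value, not the OR, carries the inference. All
pipeline TSVs are written with sorted, stable orderings and a fixed float
format so that identical seeds yield byte-identical outputs.

The acceptance script and test suite run discovery over 100 synthetic
cohorts, expansion testing over 200 simulated pairs, and phenotype calling
over 10 replicates of 2,000 cells — sizes at which the recovery
proportions are stable to within a point or two while a full run completes
in minutes on a single CPU.

## Known limitations

- Local motifs only; no edit-distance clustering of whole CDR3s.
- Exact-string reference annotation stands in for probabilistic
  TCR-specificity prediction; it has near-zero false positives but misses
  near-matches.
- The Wilcoxon exact path enumerates combinations and is intentionally
  capped; for group sizes just above the cap the normal approximation with
  tie correction takes over, which is slightly conservative with heavy
  zero-inflation.
- Chao1 on downsampled data estimates the richness of the downsampled
  pool, not of the original sample.
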