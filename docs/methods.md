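# Methods

This note documents the models, numerical choices and known limitations of
cernaforge. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Study design emulated

The pipeline targets a two-phase, two-phenotype bulk RNA-seq design: four
groups (LH, LL, FH, FL — luteal/follicular phase × high/low fertility) with
four replicates each, 16 libraries in total, analyzed as two independent
contrasts (LH vs LL, FH vs FL). All group labels are configurable; the
contrasts are always read as (high, low) with fold changes reported relative
to the high group.

## lncRNA identification

A transcript is called a lncRNA iff all four criteria hold:

* length > 200 nt (strict — a 200-nt transcript is rejected);
* exon count ≥ 2 ("more than one exon");
* declared biotype not in {protein_coding, miRNA, tRNA, snoRNA, rRNA,
  pseudogene};
* every coding-potential scorer votes noncoding (unanimous-noncoding veto: a
  single "coding" verdict discards the transcript). This is the conservative
  intersection reading of a multi-tool veto.

Two internal scorers replace external coding-potential tools:

* **ORF scorer** — coding iff the longest ATG→stop ORF (three forward frames
  of the spliced, stranded sequence; length includes the stop codon) is
  ≥ `orf_min` = 300 nt *and* covers ≥ `cov_min` = 0.35 of the transcript.
  Both thresholds are configurable. ORFs without an in-frame stop codon do
  not count.
* **Hexamer scorer** — coding iff the mean in-frame hexamer log-ratio over
  the scoring region is > 0. The table is trained on the run's own declared
  coding set: in-frame (step-3) hexamer counts over each coding transcript's
  longest ORF versus the same count over a deterministic shuffle of the
  sequence (fixed internal seed, so the table is a pure function of the
  training sequences), pseudocount 1 per hexamer. The scoring region is the
  transcript's longest ORF when one exists, else the whole sequence in frame
  0; sequences shorter than 6 nt score 0 (noncoding).

A protein-domain (HMM) search is out of scope; the biotype exclusion plus the
ORF scorer stand in for it.

Classification: a lncRNA is *antisense* iff at least one exonic base overlaps
the genomic span of a protein-coding transcript on the opposite strand,
otherwise *intergenic*. Overlap is against the coding transcript's span (not
its exons), so a lncRNA inside a coding gene's intron on the opposite strand
is antisense — the arrangement the generator uses.

## Expression and differential calls

FPKM_fs = count_fs × 10⁹ / (length_f × total_s) with total_s the raw column
sum; effective length is the transcript length (no fragment-length
correction). DE between groups H and L uses a Welch two-sample t-test on
log2(FPKM + pseudocount), pseudocount 1.0 (configurable), with fold change
log2((mean_H + pc) / (mean_L + pc)) from raw group-mean FPKM. A feature is
significant iff p < 0.05 and |log₂FC| ≥ 1 (inclusive). No multiple-testing
correction is applied to DE calls — the dual raw-p threshold is the decision
rule throughout. Degenerate case: zero variance in both groups gives p = 1
for equal means, p = 0 otherwise.

The Welch test at n = 4 per group on log-NB data is mildly conservative: a
200,000-feature Monte-Carlo run puts the true type-I rate at ≈ 0.040 at
nominal 0.05. The acceptance experiment (2,000 structure-free null features,
both contrasts pooled) reproduces this, and power on planted |log₂FC| = 2
effects is ≈ 0.97 under the default noise model.

2^−ΔΔCt is the plain arithmetic: 2^−[(Ct_target,test − Ct_ref,test) −
(Ct_target,calib − Ct_ref,calib)].

## cis neighbors

Gene span = union of the gene's transcript spans. Candidate pairs are
coding:coding and lncRNA:coding pairs on one chromosome with span gap
< 10,000 nt (strict; gap 0 when spans overlap or touch). Distances are
span-gap, not TSS distance. Orientation is decided on the pair ordered by
(start, end): same strand → tandem; left gene on '−' → divergent
(both genes transcribe away from the shared upstream region); left gene on
'+' → convergent. Ordering by coordinates makes the rule total, including for
overlapping opposite-strand genes. Correlations are Pearson r across all 16
samples on gene-level FPKM (transcript sum); zero-variance features drop
their pairs with a count. The neighbor-vs-random contrast uses a two-sided
Mann–Whitney U test against seeded uniform random distinct coding pairs.
Whether to correlate over all samples or per-phase subsets is a free choice;
the default is all samples.

## MRE prediction

Seed = miRNA nucleotides 2–8. The scanner finds reverse-complement matches to
the 6mer core (positions 2–7) and classifies: 8mer (m8 complement present and
target A opposite position 1), 7mer-m8 (m8 only), 7mer-A1 (A1 only); bare
6mers are not emitted, and only Watson–Crick pairing counts inside the seed.
Candidates are then scored by an ungapped alignment of the full miRNA against
the target window anchored at the A1 position: +5 per Watson–Crick pair, +2
per G:U wobble outside the seed, −3 per mismatch, floored at 0; windows
truncated at sequence ends are scored over the available overlap. The
pseudo-energy is −(2·#GC + 1·#AU + 0.5·#GU) over paired positions. Default
emission thresholds: align_score ≥ 80, energy ≤ −7.0 pseudo-kcal/mol. The
weights are declared stand-ins that preserve the structure of
alignment-plus-energy target predictors (they are not a thermodynamic model);
they are calibrated so that a planted full-length perfect duplex always
passes (a 22-mer scores 110) while uniform-random background essentially
never reaches 80. lncRNAs are searched over their whole sequence, mRNAs over
the annotated 3'UTR (whole transcript when no CDS is annotated).

Trans targets are purely correlational: all lncRNA × gene pairs with
|Pearson r| > 0.95, strict, over the shared samples.

## Networks and triads

A "negative interaction" is an opposite DE direction within one contrast,
evidenced by at least one predicted site. Triads are the join of
lncRNA–miRNA and miRNA–mRNA edges on the shared miRNA; the two negativity
constraints force lncRNA and mRNA into the same direction, opposite the
miRNA — the ceRNA sponge pattern — so no separate sign check is needed (it is
asserted anyway). Networks are built per contrast; mixing contrasts is an
error. An optional lncRNA–mRNA expression-correlation filter is deliberately
not applied by default. Exports: Cytoscape SIF, node-attribute TSV (type and
direction), triad TSV, and a node-link JSON graph with node/edge counts.

## Enrichment

Hypergeometric upper tail P(X ≥ k) for k query hits in a term of K background
genes, query size n, background N (scipy's log-space survival function; the
test suite checks it against exact rational enumeration for all N ≤ 60 to
1e-10). Correction is Benjamini–Hochberg step-up (configurable to
Bonferroni); significance at adjusted p < 0.05. The background defaults to
the term map's gene universe; terms with no background gene are skipped and
terms with zero hits are reported with p = 1.

## The synthetic-data generator

The generator is first-class, tested code. What it emulates, and how:

* **Annotation** — two chromosomes; protein-coding genes with 2–7 exons,
  UTR5 (30–120 nt), codon-biased CDS (480–960 nt, GC-biased third positions —
  this is what gives the hexamer scorer its signal), UTR3 (250–450 nt);
  lncRNAs of 400–2000 nt with 2–4 exons. A configurable fraction
  (default 0.26) of lncRNAs is antisense, hosted inside a coding gene's first
  intron on the opposite strand; the rest are intergenic. Exons of distinct
  transcripts never share genomic bases, so the emitted genome (random
  background with exon patches) is consistent with every spliced transcript
  sequence even after motif editing. A configurable fraction of adjacent gene
  units (default 0.35) is laid out as divergent pairs with gaps of
  0.5–9 kb; all other gaps are ≥ 11 kb.
* **miRNAs** — mature lengths 20–24 nt with mode 22, 5' U, unique seeds; no
  miRNA's seed reverse-complement occurs inside another miRNA's planted-site
  sequence, so site attribution is unambiguous.
* **Planted truth** — each true triad takes a distinct (lncRNA, miRNA, mRNA):
  a full-length perfect-duplex 8mer site (revcomp of miRNA positions 2..L
  followed by A) is written into the lncRNA and into the mRNA 3'UTR, and all
  three members get signed log2 effects for the triad's contrast, miRNA
  opposite to its partners. Extra non-triad DE features are planted up to
  `n_de_features_per_contrast`. After planting, a sanitizer removes every
  stray seed match across all transcripts and re-enforces the lncRNA
  noncoding guarantees (no ORF ≥ 300 nt, hexamer score ≤ 0) without touching
  planted windows or creating CDS stops — so generator truth is exact:
  planted sites are the only seed matches, and the filter cascade's recovery
  can be scored at sensitivity = specificity = 1.
* **Counts** — negative binomial with var = μ + φμ², common dispersion
  φ = 0.1 (an "overdispersed but well-powered bulk RNA-seq" choice; the count
  noise model is a stand-in isolated behind the config). Baseline means are
  log-normal shares (log-sd 1.0) of a 10⁶-read target library; per-sample
  library factors are log-normal (log-sd 0.1). DE features are shifted by
  2^effect in the H group of their contrast (default effect 2.0, i.e. 4-fold,
  comfortably past the |log₂FC| ≥ 1 threshold as required). Members of
  divergent neighbor pairs share a per-sample log-normal factor
  (log2-sd 0.6), planting the positive cis-correlation that the
  neighbor-vs-random contrast detects.
* **Orthogonality of planted mechanisms** — genes carrying the shared
  co-expression factor are excluded from DE/triad planting. Overlapping the
  two mechanisms on one feature would inflate its within-group variance and
  mask its planted fold change, making the two ground truths mutually
  confounding; keeping them disjoint means each downstream check isolates
  exactly one planted signal.
* **Determinism** — all randomness flows from the single config seed through
  named `numpy.random.Generator` streams (separate streams for annotation,
  miRNAs, planting, counts, terms, genome background); identical configs give
  byte-identical GTF/FASTA/TSV/JSON outputs.

What the generator does **not** emulate: realistic genome composition and
repeat structure, isoform diversity (one transcript per gene), fragment-level
read sampling, GC or length biases in quantification, partially complementary
(non-seed) miRNA binding, and correlated dispersion structure. Passing tests
therefore demonstrate the correctness and calibration of the inference chain
under its stated model, not performance on real libraries — in real data,
imperfect sites, shared MREs across miRNA families and quantification biases
will reduce precision and recall below the clean-room values reported here.

## Problem sizes and defaults

Default study conditions: 150 coding genes, 60 lncRNAs, 20 miRNAs, 10 true
triads, 25 DE features per contrast — a deliberately compact catalog on
which the full pipeline runs in seconds while keeping ≥ 200 background
features around the planted triads. The calibration experiments use 2,000
features (type-I, correlation null), 400 features with 100 planted effects
per contrast (power), and 520 transcripts (recovery). The random-pair null
uses 2,000 seeded pairs.

## Numerical and degenerate-input choices

* Coordinates: 0-based half-open internally, 1-based inclusive at the GTF
  boundary; minus-strand spliced sequences are reverse complements of the
  genomic exon concatenation.
* Zero-count configurations yield empty catalogs, not errors; zero-length
  features and zero-total samples are errors naming the offender; malformed
  GTF lines are errors naming the line number.
* Pearson correlations drop zero-variance features with a count rather than
  emitting NaN; Mann–Whitney U requires ≥ 2 values per group.
* Tie-free orientation classification comes from ordering pairs by
  (start, end) under distinct coordinates.
* The hypergeometric test validates 0 ≤ k ≤ min(K, n) and K, n ≤ N before
  computing; k = 0 short-circuits to p = 1.
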