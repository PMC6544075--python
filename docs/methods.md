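# Methods

## Scope and model

`splicevet` implements a validation workflow for candidate splicing
mutations in three layers: an information-theoretic assessment of each
variant's effect on splice-site strength, an expression check that counts
abnormally spliced RNA-seq reads in the index case against a control
cohort, and a rule-based classifier that assigns each case a molecular
phenotype.

### Individual-information splice-site models

Donor and acceptor sites are modelled with positional bit-weight matrices.
With `f(b, l)` the pseudocounted frequency of base `b` at aligned position
`l` of a training set of sites,

    weight(b, l) = 2 + log2 f(b, l)

so a uniformly random position contributes exactly 0 bits.  The individual
information of a candidate window is `Ri = Σ_l weight(window[l], l)`; only
sites with `Ri > 0` are treated as bindable.  The mean training-set score
is `Rsequence`.  A variant's effect on a site is `ΔRi = Ri,final −
Ri,initial`, and `|ΔRi|` bits imply a minimum `2^|ΔRi|`-fold change in
binding affinity (3 bits ≥ 8-fold, 2 bits ≥ 4-fold, 4 bits ≥ 16-fold).

No small-sample correction is applied to the weights: training-set sizes
are controlled here (1000 sites by default) and the pseudocount (0.25 per
base per position) regularizes unobserved bases.

Geometry defaults are donor −3..+6 and acceptor −25..+2 relative to the
exon/intron junction (no position 0; GT at donor +1/+2, AG at acceptor
−2/−1).  Both are configurable: different matrices in the literature use
different extents, and nothing downstream depends on the specific spans.

Candidate filtering retains natural-site impacts only when weakened
(`ΔRi < 0`) and cryptic impacts only when strengthened by ≥ 2 bits, with
`Ri,final > 0` and `Ri,final` above the nearest natural site of the same
polarity.  The cryptic scan considers every junction placement within 300
nt of the variant for which the variant lies inside the model window (the
window span itself is the binding constraint; the radius is a cap for
indels and long alleles).

Coordinate conventions: all domain records (variants, exons, junctions)
are 1-based inclusive, matching VCF/GTF/SAM; sequences are sliced 0-based
internally.  A site's `junction_coord` is the base at relative position +1
(first intronic base for donors, first exonic base for acceptors), which
makes split-read junction matching exact-coordinate.  Minus-strand windows
are reverse-complemented before scoring.  Indels are rescored by
re-extracting the window from the mutated sequence anchored at the
(coordinate-mapped) junction; coordinates inside a deleted interval anchor
to the variant position.  This is the only supported indel convention.

"Nearest natural site of the same polarity" means minimal absolute genomic
distance among the transcript's annotated sites of that polarity, ties
broken toward the 5′ site on the transcript strand.

### Read-evidence categories

Reads around a flagged variant are categorized as:

* junction-spanning cryptic use — a skip edge coincides exactly with the
  candidate cryptic junction (splice-aware aligners report junctions
  base-precisely, so no fuzz window is applied);
* exon skipping — a single skip spanning the entire affected exon,
  joining its flanking exons;
* intron inclusion — a contiguous alignment crossing the natural
  exon/intron boundary with ≥ 6 aligned bases on each side (the
  `min_overhang` default; small enough to keep power at 100-nt reads,
  large enough to reject alignment-end noise);
* intron inclusion with variant — inclusion where the read carries the
  alternate allele at the variant position, reconstructed from the
  alignment.  Deletions or skips over the position give "unknown", which
  never counts as with-variant.

Categorization is partition-like (with-variant ⊂ total inclusion is the
only overlap).  Reads whose skips all match annotated introns are normal;
reads with unrecognized skips are ignored rather than guessed.  Control
samples lack the variant, so their with-variant count is defined as the
number of boundary-crossing reads.

### Count statistics

Per category, the control counts are Yeo-Johnson transformed,

    x ≥ 0: ((x+1)^λ − 1)/λ          (log(x+1) at λ = 0)
    x < 0: −((−x+1)^(2−λ) − 1)/(2−λ)  (−log(−x+1) at λ = 2)

with λ chosen by maximizing the profile normal log-likelihood over
λ ∈ [−5, 5] (bounded scalar optimization; a 10⁻³ grid search is the test
oracle).  λ is fit on the controls only, keeping the null model
independent of the tested value.  The index count is transformed with the
same λ, standardized by the control mean and ddof-1 standard deviation,
and the one-sided upper-tail standard-normal probability is reported:
every category is an abnormal-read count, so only an excess is evidence.
Degenerate controls (zero spread after transformation) give p = 0 if the
index exceeds the common value and p = 1 otherwise; an all-identical
sample leaves λ = 1 with a warning.  Thresholds: α = 0.05, "highly
significant" 0.005, reporting threshold 0.01; all configurable.  No
multiple-testing correction is applied across variants or categories; the
method treats each category test as a per-case flag, and consumers should
interpret the p-values accordingly.

### Classification

The rule table in `phenotype_classifier.classify_case` encodes, with
explicit precedence (heterozygosity gate → evidence conditions →
information conditions):

1. average heterozygosity > 0.01 → allele-specific alternative splicing,
   unconditionally;
2. strong evidence S = any strongly-corroborating category at p ≤ 0.005,
   or ≥ 2 categories at p ≤ 0.05 with ≥ 1 strongly corroborating; weak
   evidence W = any strongly-corroborating category at p ≤ 0.05.
   "Strongly corroborating" is the junction-level/variant-bearing set
   {cryptic use, exon skipping, inclusion-with-variant}; bulk intron
   inclusion is weak evidence because it cannot distinguish the mutant
   allele;
3. natural sites: I_ab = ΔRi ≤ −4 bits; I_char = ΔRi ≤ −2.7 bits with
   heterozygosity ≤ 0.002 or unknown; losses of < 2 bits are treated as
   benign-leaning.  Aberrant iff (I_ab ∧ W) ∨ (I_char ∧ S); likely
   aberrant iff (I_char ∧ W) ∨ (I_ab ∧ any p ≤ 0.05); else
   allele-specific;
4. cryptic sites: aberrant iff S, likely aberrant iff W, else
   allele-specific.

Missing heterozygosity is treated as rare (≤ 0.002): variants absent from
the polymorphism catalogue are predominantly novel.  With no evidence
tests at all, classification rests on the information conditions and is
capped at likely-aberrant (natural: either information condition; cryptic:
gain ≥ 4 bits) — expression corroboration is required for the top class.
Tissue expression level is surfaced in reports but never enters
classification: in calibration it consistently lowered MCC.

The evidence bar maps a ±1 point score (supporting items: strong
information change, S, W, exonic cryptic location, rarity; contrasting:
weak information change, no significant test, intermediate heterozygosity)
affinely into [0, 1] with 0 points at 0.5; positive scores are normalized
by the number of applicable supporting items and negative by contrasting
items, so "all supporting" is exactly 1.0 and "all contrasting" exactly
0.0.  The point values are presentation choices, not statistics.

Cross-site reclassification promotes every site of a variant (within one
tumour type) to aberrant when any site is aberrant; it is idempotent.  The
consensus phenotype is the argmax of per-case classification counts, with
ties reported as multiple consensus phenotypes.

Reporting screens: screenshot-grade cases need ≥ 5 reads in a
strongly-corroborating category, population frequency < 1% (or unknown)
and some p ≤ 0.01.  The masquerade screen tiers the mean control activity
(>0, ≥1, ≥3, ≥5 reads) of categories not significant in the index —
naturally alternatively spliced exons posing as splicing mutations — and a
cryptic-use tier additionally requires the wildtype site to have been
functional (`Ri,initial > 1.6` bits); violations are flagged as
inconsistencies instead of tiers.

### Calibration

Seven binary characteristics are defined; four apply to natural sites
({1 natural ΔRi, 4 evidence, 5 heterozygosity, 6 expression}) and six to
cryptic sites ({2, 3, 4, 5, 6, 7}) — the split follows from which
characteristics are defined for each site type.  Weights come from the
0.2-step grid {0, 0.2, …, 1.0}; all 6⁴ (natural) or 6⁶ (cryptic) schemes
are evaluated, excluding all-zero, by weighted-majority voting (ties vote
conservatively allele-specific-like) and scored with the Matthews
correlation coefficient (zero denominator → 0).  Equal-MCC ties resolve
to the fewest nonzero weights — predictions are scale-invariant, so the
sparsest scheme is the canonical representative — then to the
lexicographically greatest weight vector.  Default binarization thresholds
(ΔRi ≤ −2.7, heterozygosity ≤ 0.002, …) are configuration, calibrated
values serving as defaults.  The module consumes any labelled TSV; no
external annotation database is fetched.

## Synthetic data: what it emulates, what it does not

The generator produces a 6-kb contig with one plus-strand three-exon gene
(exons 1001–1200, 1801–2100, 2701–3000), donor/acceptor training sets
sampled from consensus-biased positional frequencies ("strong" profile:
Rsequence ≈ 7.5 bits donor, ≈ 9.4 bits acceptor), natural sites planted as
consensus-with-one-weak-base (leaving headroom so a fully-consensus
cryptic site can overtake them), and single-end, error-free 100-nt reads.

Study conditions (fixed defaults): depth 200 reads per sample, 20 control
samples (real cohorts ran up to 100 mixed-tissue controls; 20 keeps runs
desk-scale while leaving the statistics non-trivial), a 0.02
intron-inclusion background in every sample, and planted abnormal
fractions of 0.30 (exon skipping), 0.30 (inclusion-with-variant), 0.25
(cryptic use) and 0.10/0.10 index/control for the masquerade scenario.
Index counts are planted deterministically at `round(fraction × depth)`;
control counts are Binomial(depth, fraction) per sample.  One
`numpy.random.default_rng(seed)` drives everything, so a seed determines
every output byte.

Not emulated: expression-level variation between genes and tissues, GC and
positional coverage bias, sequencing error, paired-end fragments,
multi-gene interference, nonsense-mediated decay.  Passing tests on this
generator therefore demonstrate the *logic* of the pipeline — window
arithmetic, category definitions, statistics and rule table — not its
operating characteristics on real tumour transcriptomes, where coverage
and expression effects dominate sensitivity.

## Numerical choices

* λ optimization: bounded Brent on [−5, 5], `xatol = 1e-6`; degenerate
  inputs short-circuit to λ = 1 with a warning.
* Ambiguous bases score the position's minimum weight (most conservative
  bindability assumption).
* Exact-coordinate junction matching; no fuzz window.
* Weight/Ri comparisons in filters are strict (`>`), so a cryptic site
  exactly tying its natural site is not retained.
* Problem sizes in the test and acceptance suites (200 end-to-end cases,
  1000-replicate null calibration, 10⁴ sampled windows) were chosen as the
  smallest sizes at which the checked quantities are statistically stable.

## Known limitations

* One transcript model per gene is assumed when locating the affected
  exon; overlapping isoforms with conflicting boundaries are not arbitrated.
* `assess_variant` materializes the variant's contig in memory — adequate
  for desk-scale fixtures and single-gene regions, not whole-genome scans.
* The indel coordinate-anchoring convention can place a junction inside a
  deleted interval at the variant position; such windows are rescored but
  their biological interpretation is limited.
* Reads are treated as single-end; mate information is ignored even if
  present in the SAM.
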