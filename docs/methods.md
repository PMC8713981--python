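# Methods

This note documents the statistical models behind allomap, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions. It states no empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## Regulatory classification model

### Quantities

For gene *g*, with log2-scale normalized expression, define

- `L_DE` — mean difference between species-A and species-B parental samples;
- `L_ASE` — mean difference between the A allele and the B allele within the
  allotetraploid hybrid, where both alleles share one trans environment;
- `C = L_ASE` — the cis component: regulatory divergence linked to the
  allele persists in the hybrid;
- `T = L_DE − L_ASE` — the trans component: divergence mediated by
  diffusible factors vanishes in the hybrid, so it appears as the gap
  between the parental and the allelic contrast. By construction
  `C + T = L_DE` to machine precision.

### Normalization

Size factors use median-of-ratios against the geometric-mean reference over
genes expressed in every sample, rescaled to geometric mean 1; when fewer
than 50 genes qualify, total-count scaling is used instead. Expression is
`log2(count/factor + pseudocount)` with pseudocount 0.5 — half a count
stabilizes low-expression genes without materially shifting moderate counts.

### Tests

DE and ASE contrasts are Welch two-sample t-tests on the log2 values,
unpaired (hybrid allele pairs are treated as independent samples; a paired
layout changes the df but not the estimator and can be emulated by passing
per-line differences). Per-gene, per-group variances are floored at the 10th
percentile of all per-group variances in the matrix: with 3–4 replicates,
occasional near-zero sample variances would otherwise produce absurd t
statistics; the floor is configurable (`variance_floor_quantile`) and
setting it to 0 recovers the textbook Welch test exactly. The trans test is
a two-tailed normal z on `T / sqrt(SE_DE² + SE_ASE²)`, treating the two
contrasts as independent — they are computed from disjoint sample sets.
Count-level engines (negative-binomial GLMs) are a deliberate non-choice
here: the t-on-log2 engine is self-contained, fast at panel scale, and sits
behind a narrow seam (`estimate_contrast`) that an NB engine could replace.

Each family of p-values (DE, ASE, trans) is Benjamini–Hochberg adjusted
separately; significance means q < α with α = 0.05. BH is the standard
step-up procedure; NaN inputs propagate as NaN.

### Decision table

With sig(X) ≡ q_X < α:

| DE | ASE | trans | sign condition | category |
|----|-----|-------|----------------|----------|
| no | no | no | | conserved |
| yes | yes | no | | cis |
| yes | no | yes | | trans |
| yes | yes | yes | sign(C) = sign(T) | cis+trans |
| yes | yes | yes | sign(C) ≠ sign(T) | cis−trans |
| no | yes | yes | | compensatory |
| — | — | — | any other pattern | ambiguous |

Tie-break: a zero C or T in the all-significant row counts as (vacuous) sign
agreement, so the gene falls in cis+trans. Summary percentages use two
denominators — conserved/compensatory out of the no-net-change genes, the
four change categories out of the regulatory-change genes — and ambiguous is
reported separately, since it is a statement about test power rather than
regulation.

Category effect sizes are compared by two-tailed Mann–Whitney U on |L_DE|
with BH across pairs; the annotation-burden test compares a user-supplied
per-gene non-negative burden (e.g. number of body systems a gene influences)
between each category and the conserved set, restricting cis, trans and
cis+trans to genes with |L_DE| ≥ 1 (at least twofold) and skipping filtered
categories with fewer than 6 genes, where the rank test is uninformative.

## Linked-read recombination model

### Molecule reconstruction

Per-site species calls come from diagnostic variants (positions where the
two species' alleles differ): a base matching neither allele, or a position
absent from the table, is dropped and counted. Conflicting duplicate
observations of one (barcode, position) resolve by majority; exact ties drop
the site — damping sequencing error at the site level before run detection.
Calls grouped by (barcode, chromosome) are split into molecules wherever
consecutive sites are more than `gap_threshold = 50 kb` apart (a gap exactly
at the threshold joins). 50 kb is the typical linked-read molecule scale;
the threshold's job is to separate distinct molecules that collided on one
barcode, and it is exposed as a flag.

### Recombinant calls

A molecule is recombinant iff its ordered calls form exactly two maximal
runs with both run lengths ≥ `min_support` (default 5: roughly five
supporting variants per species, strictly enforced as ≥ 5). One junction per
molecule is the model; multi-switch patterns (3+ runs) are rejected as
likely barcode collisions or error bursts. The junction is reported as the
closed 1-based interval between the flanking diagnostic sites. A reference
per-molecule implementation and a vectorized caller implement the same rule
and are tested for exact agreement against brute-force enumeration.

### Rate conversion

The base model is `rate = f · (G / mean span) / g`: the per-molecule
junction fraction `f`, scaled by how many molecule-spans tile the callable
genome `G`, per generation. That formula has two documented biases on
realistic data, both removed when `correct_detection=True`:

1. **Junction detectability.** A junction is only callable if it falls
   between the `min_support`-th observed variant from each molecule end.
   Each molecule's detectable fraction is that window divided by its
   estimated true length; `f` is divided by the mean detectable fraction.
2. **Span vs length.** The observed site span underestimates the true
   molecule length. For n uniform points on length L, E[span] =
   L·(n−1)/(n+1), giving the per-molecule correction; the cohort mean
   length is estimated as (total sites)/(fitted site density)/(number of
   molecules), which also credits the length of molecules observed at only
   0–1 sites.

The 95% CI is a nonparametric bootstrap over molecules (default 1,000
resamples, seeded). The treated-vs-control comparison is a one-tailed paired
t-test on per-replicate recombinant fractions (alternative: treated higher);
identical pairs give p = 0.5 by the sign convention of a zero t statistic.

## Chromosome mapping

### Dosage classes

Dosage is renormalized per line and species by the control autosome, making
the classification invariant to the qPCR normalization constant. Windows are
symmetric around copy numbers 0, 1, 2: lost < 0.25, single in [0.75, 1.25],
gained ≥ 1.6 — wide enough for qPCR noise, narrow enough that 0, 1 and 2
copies cannot be confused; all three are configurable. Exactly one species
lost distally with the other single-copy is a deletion; with the other
doubled, a recombinant gain; lost proximally too, a whole-chromosome loss.
Anything else is flagged unresolved rather than forced into a class.

### Breakpoint fitting

Human read counts per feature are modeled binomial(total, p_left) left of a
candidate split and binomial(total, p_right) right of it, with closed-form
MLE fractions; the split maximizing the likelihood is found by exhaustive
scan (leftmost on ties — the fit *is* the scan, and tests hold it to an
independent quadratic re-implementation). No changepoint is reported when
the improvement over the single-fraction model is under 10 nats (strong
evidence, avoiding per-track multiple-testing machinery) or the fractions
differ by less than 0.1 (too small to be a chromosomal event). Features may
be genes ordered by position (RNA tracks) or fixed-width bins (DNA tracks).
Only a single terminal changepoint is modeled; subclonal breakpoint
heterogeneity appears instead as the staggered interval: features whose
lost-species retention (allele ratio relative to the proximal/control
expectation) is between 0.15 and 0.7, contiguous with the breakpoint.

### Trans-target mapping

Autosomal genes (features off the deleted chromosome) are contrasted per
deletion panel against controls (Welch, BH within panel). A gene is a
species-specific trans target when it is significant in exactly one panel
and every line of that panel deviates from the control mean with the group's
sign — the consistent-sign rule is this package's operational definition of
a species-specific signature. `fraction_trans_explained` reports the
deletion-induced shift as a percentage of an externally supplied trans
component, sign-aware, flagging discordant (negative) recoveries.

### Microhomology

Junction coordinates are 0-based cut positions marking the *outer* edges of
any shared block: `left_ext` is the longest suffix of the retained A segment
equal to the prefix of the retained B segment, `right_ext` the symmetric
overlap on the other side, and their sum is the junction microhomology. This
matches how structural-variant junctions with homology are reported: the
true crossover is ambiguous anywhere within the shared block.

## Synthetic generators

All three generators derive child random streams from one root seed keyed by
stage name, so outputs are byte-identical for a fixed config + seed and
stages never perturb each other's draws.

- **Expression panel.** Per-gene baselines are log-normal; counts are
  negative binomial parameterized by mean m and dispersion φ with variance
  m + φm² (φ = 0.05 default, a typical RNA-seq replicate dispersion).
  Expected means: species-B parental s·μ, species-A parental s·μ·2^(C+T),
  hybrid B allele s·μ, hybrid A allele s·μ·2^C — hybrid allele baselines
  equal the parental per-allele baseline, with library-size factors s
  absorbing depth differences (no ploidy term). Effect magnitudes |C|, |T|
  are |Normal(2.0, 0.5)| log2 units by default, truncated away from zero;
  category proportions default to a conserved-majority mixture. For the
  cis−trans category the two magnitudes are kept unequal so the net effect
  cannot cancel (which would be compensatory by definition).
- **Haplotag molecules.** Diagnostic variants follow a homogeneous Poisson
  process (default 1/kb); molecules start uniformly with exponential lengths
  (default mean 50 kb); a configured fraction carries exactly one junction,
  uniform along the molecule (multi-switch molecules arise only through
  barcode collisions); per-site detection is Bernoulli; species-call errors
  are symmetric; collisions reuse an earlier molecule's barcode. Default
  molecule length and variant density are plausible linked-read values, not
  measurements.
- **Deletion panel.** Each deletion line zeroes the targeted species' allele
  for focal-chromosome genes distal to its breakpoint; with staggered width
  w the per-cell breakpoint is uniform on [b − w/2, b + w/2], so genes in
  that window retain the expected intermediate fraction. Trans targets shift
  both alleles of chosen autosomal genes in the matching deletion group
  only.

What the generators do **not** emulate — and hence what passing tests do not
establish about real data: alignment and mapping-bias artifacts, GC/length
effects, reference bias between the two genomes, karyotype abnormalities,
PCR duplicates, overdispersed variant spacing, and cross-contamination.
Recovery results on synthetic data bound the statistical behavior of the
estimators, not the quality of an upstream alignment pipeline.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 2,000-gene panels with 4
replicates per context for specificity, 600 genes for power, 10⁴–2×10⁵
molecules for detector error rates and rate recovery (toy 200–500 Mb
genomes), 100 noisy tracks for breakpoint accuracy. Positions are 1-based
inclusive in all TSVs and 0-based half-open in BED exports. Degenerate
inputs are contracts, not crashes: all-zero count matrices, zero-SE trans
tests, all-zero ratio tracks and empty molecule sets raise named errors;
zero recombinants yield rate 0 with a CI anchored at 0.

## Known limitations

- The t-on-log2 engine loses power relative to count-level models at very
  low counts; the pseudocount shrinks extreme fold changes slightly.
- The rate model assumes at most one junction per true molecule and
  independence across molecules; pervasive barcode sharing beyond the
  collision model would bias `f` upward.
- The changepoint model is single-step; interstitial deletions (two steps)
  are out of scope.
- The consistent-sign rule for species specificity is conservative with
  noisy small panels: one wayward line vetoes the call.
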