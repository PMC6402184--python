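# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the places where the design was genuinely open.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Count model and differential expression

The test statistic is the Audic–Claverie conditional count comparison for
two pooled libraries.  Conditioning on the first count `x`, the second
count is negative-binomially distributed with `x+1` successes and success
probability `1/(1+ρ)`, `ρ = N2/N1`; the implementation uses that identity
(via the regularised incomplete beta function) rather than explicit tail
summation, which overflows factorials and loses precision beyond counts of
a few hundred.  The test suite checks the identity against an independent
log-space tail-summation oracle to 1e-10 for all counts ≤ 50 at three
depth ratios.

Two-sided p-values double the smaller tail and cap at 1.  Note one
property this definition does **not** have: `p(x, y, N1, N2)` is not equal
to `p(y, x, N2, N1)` — the conditional pmf picks up a factor ρ under the
swap, and even at equal depths the two tail sums run over different
slices.  What does hold, and is tested, is invariance under joint scaling
of both depths (only ρ matters).

The test conditions on `x` and assumes Poisson sampling within a library.
It is calibrated when counts are Poisson (the suite checks a 5.0% ± 2.0%
type-I rate on a 5000-feature Poisson null) and is anti-conservative under
extra-Poisson noise; in the recovery design below, the effect-size gate
(`|log2FC| ≥ 1`) is what keeps the empirical FDR low despite NB dispersion,
exactly as in the emulated screening standard.

Fold changes are computed on RPKM with a pseudocount of 0.1 RPKM on both
sides (divide-by-zero guard; the value is small relative to the ~1–500
RPKM range of the simulated data).  BH q-values are computed within each
feature class, since the three classes are screened as separate
experiments with different q cutoffs (q < 0.001 for lncRNA/mRNA; q < 0.05
for miRNA — the miRNA cutoff is configurable because sources for the
emulated design state it inconsistently).  The screening gate reads
`|log2FC| ≥ 1` inclusively.

## Synthetic-data generator

The generator emulates a pooled two-condition sequencing design: per-sample
negative-binomial counts (dispersion d, variance `m + d·m²`; d = 0 gives
Poisson) around a **flat** baseline mean, with case-group means of planted
features multiplied by `2^±log2FC`.  A flat baseline (default 100 counts)
was chosen deliberately so the marginal-mean check is exact per feature;
real transcriptomes have lognormal baselines, which affects power per
feature but nothing structural.  Planted signs alternate so both
directions are always represented.  A pooling operator sums samples into
libraries, so pooled (e.g. 5-vs-5) and per-sample designs are both
expressible.

`library_size` is emitted as the constant nominal design depth rather than
the realised column totals.  The simulator has no depth variation, so the
true normalising factor is constant; using realised totals would inject
composition effects from high-variance planted modules into every RPKM
profile (a real phenomenon — it is why median-of-ratios normalisation
exists — but noise with respect to the planted truth).  Realised totals
remain available from the matrix for anyone who wants them.

Coexpression modules add a shared latent Gaussian factor on the log2 scale:
member i in sample s gets `c·(√φ·z_s + √(1−φ)·u_is)` added to its log2
mean, giving latent pairwise correlation φ (default modules use φ = 0.95)
attenuated by count noise to a realised pairwise r ≈ c²φ/(c²+v), where v
is the log-scale count-noise variance (≈ 2.08·(1/m + d)).  The module
amplitude default c = 2.5 is a compromise: larger amplitudes push the low
tail of `2^(c·z)` into single-digit counts where discretisation noise
destroys correlations.

The toy genome places the requested lincRNA/gene pairs at exact gaps
(endpoint-distance convention: `gap = gene.start − linc.end`, 0 for
overlap, so a gene at `linc.end + w` is the outermost interval inside a
window of w) and all other features in isolated blocks more than a window
apart.  Pairs with gaps beyond the window are recorded as planted-negative
controls.

Planted miRNA sites are near-full-length reverse complements of the miRNA
whose terminal 8-nt window realises the requested seed class exactly, with
30-nt AU-rich flanks.  Full-length pairing and AU flanks are deliberate:
the triad-recovery analysis requires planted sites to pass all three
stand-in predictors, so the generator plants sites a strong predictor
ensemble would accept.  Background sequence is uniform random RNA, which
is the appropriate null for predictor calibration but lacks the
composition bias, repeats and secondary structure of real transcripts —
recovery rates on this background say nothing about sensitivity/specificity
on real 3'UTRs.

The validation arm simulates qPCR Ct tables (reference Ct ≈ 20, control
ΔCt = 5, case ΔCt shifted by the planted log2FC, 0.25 cycles technical
noise) and a clinical table from a Gaussian copula with latent correlation
0.8 between biomarker and activity score.

All randomness flows from one integer seed through named substreams, so
any generator can be called independently and reproducibly.

## Novel-lncRNA cascade

Gates run strictly in order and evaluation stops at the first failure
(verdict records the failing gate; an evaluation log supports the
order-faithfulness test).  Choices on the points the gate definitions
leave open:

- "longer than 200 nt" is implemented inclusively (≥ 200, the canonical
  lncRNA definition); an exclusive flag exists.
- "ORF < 300 nt" refers to the **longest** ORF (standard practice); an ORF
  is AUG through the first in-frame stop, sense strand only, length
  including the stop codon.
- The domain screen is a pluggable regular-expression scan over the three
  forward-frame translations.  **The default pattern set is empty**, i.e.
  gate 4 passes everything unless patterns are supplied; the demo supplies
  one motif so the gate is exercised.
- The coding-potential score is an explicit stand-in for SVM-based
  classifiers, not a reimplementation of any of them:
  `score = 2·(ORF coverage − 0.5) + 4·(mean in-frame hexamer log-odds of
  the longest ORF)`, with the hexamer table trained from user-supplied
  coding/noncoding FASTA (in-frame hexamers of coding ORFs vs all-frame
  noncoding hexamers, unit pseudocounts).  The packaged toy training set
  uses GC-biased codons against uniform-random noncoding sequence; under
  it, coding-like transcripts score well above 0 and random sequence
  scores below −1 in the large majority of draws — the odd random
  sequence with a long chance ORF can cross −1, which is why the
  engineered cascade fixture constructs its passer to clear the gate
  rather than sampling blindly.  The acceptance threshold stays at −1.

## Coexpression network

Sample Pearson correlation on per-sample `log2(RPKM + 0.1)` profiles
(pseudocount matched to the DE fold change; a pseudocount of 1 RPKM
saturates the dynamic range at the simulated expression levels).  Edges
are retained on `|r| ≥ 0.85` **only** — the p-value (t transform, n−2 df)
is reported but never screens, and the absolute value means negative
edges survive and are counted separately.  Zero-variance profiles are
skipped with a log message.  The recovery analysis uses 50-vs-50 samples:
at the realised module correlation (~0.92 after count-noise attenuation)
the per-edge miss probability at threshold 0.85 is below 1%, so ≥ 95%
module-edge recall is expected rather than hoped for; at 5-vs-5 the same
threshold misses a third of true edges, which is a property of n = 10
correlation estimates, not of the code.

## Target prediction

Cis: strand-agnostic interval query, 1-based closed coordinates, window
10 kb to either side; exact-set equivalence against a brute-force
all-pairs oracle is part of acceptance.  Trans: best local alignment of
the lincRNA against the reversed mRNA under a complementarity scoring
matrix (GC +3, AU +2, GU +1, mismatch −4, linear gap −6), so antiparallel
hybridisation becomes standard Smith–Waterman (delegated to Biopython's
PairwiseAligner; an independent textbook DP is the test oracle).  No
published scheme exists for this step; the matrix and the default
threshold 60 (roughly a 20–30-nt strong duplex) are declared stand-ins.
On kb-scale random transcripts the null score distribution reaches the
low 60s occasionally, so isolated trans links at threshold 60 should be
read as candidates, not detections.  The candidate gene universe is
restricted to differential mRNAs by default (lifting the restriction is a
flag), and links found by both modes collapse to one row with both
evidences.

## ceRNA consensus and triads

The three predictors are stand-ins chosen so the ensemble-voting
arithmetic (2-of-3 for lncRNA–miRNA, 3-of-3 for miRNA–mRNA) is preserved
with N = 3:

- **seed**: best site class ≥ 7mer (8mer, 7mer-m8 or 7mer-A1); seed
  matching is strict Watson–Crick, GU wobble does not count, and the
  position-1 adenine is an identity requirement (TargetScan-style).
- **energy**: duplex energy of the miRNA against the site region
  ≤ −25 kcal/mol.  The energy model is a dynamic programme over
  antiparallel pairs: adjacent pairs add a 10-value Watson–Crick
  nearest-neighbour stack table (keyed by the guide dinucleotide), each
  GU pair costs +1.0, internal loops +3.0 and bulges +3.5 flat.
- **context**: any site ≥ 6mer with A/U fraction ≥ 0.7 in the 30-nt
  flanks.

The energy and AU thresholds were calibrated on uniform-random sequence
(22-nt miRNAs × 1.5-kb transcripts): at these settings the 2-of-3
consensus fires on under 1% of random pairs and the 3-of-3 consensus on
essentially none, while planted full-complement sites pass all three
votes.  Looser, seemingly natural settings (energy −14, AU 0.5) admit a
~20% random 2-of-3 rate — dominated by chance 7mers with AU-average
flanks — and make a zero-false-triad outcome impossible; with three
binary predictors, consensus voting only suppresses noise if each vote is
individually stringent.  All thresholds are configurable.

One caveat on the energy model: because stacks are keyed by the guide
dinucleotide and GU wobble breaks strand complementarity, the energy is
**not** invariant under reverse-complementing both strands when wobble
pairs participate (the reverse complement of G·U is C·A, which does not
pair).  The invariance holds exactly for pure Watson–Crick helices and is
tested there.

Triads join consensus edge sets on the shared miRNA.  Strict mode (the
default) enforces `sign(lncRNA) = sign(mRNA) = −sign(miRNA)`; permissive
mode keeps every join, because published ceRNA networks sometimes include
direction-inconsistent pairs and the intended rule is not always
recoverable.  Members must be differentially expressed; dangling ids are
dropped with a log entry.  Output is deduplicated and sorted.

## Enrichment and validation statistics

Over-representation is the upper-tail hypergeometric
`P(overlap ≥ k | K, n, N)` via the survival function; the universe
defaults to all annotated genes and is overridable; BH q is reported but
the significance flag follows the raw p < 0.05 screen.  qPCR fold changes
are Livak 2^−ΔΔCt against the reference gene and the control-group mean
ΔCt (control folds therefore have geometric mean exactly 1).  The
two-group test defaults to Welch (pooled-variance by flag); the
biomarker–score correlation is Spearman (average ranks for ties).

## Problem sizes and determinism

The analysis designs are scaled-down analogues of the emulated study: the
DE recovery design uses 2000 features (10% planted at |log2FC| = 2,
5-vs-5 pooled), the null calibration 5000 Poisson features, coexpression
recovery two 21-member modules over 100 samples, and the demo pipeline
230 features end to end.  These sizes make every analysis run in seconds
to a minute while keeping each statistical check adequately powered; the
power analyses behind the coexpression design are sketched above.

Every run is deterministic given its configuration: one seed feeds named
substreams, outputs carry no timestamps, and rerunning a configuration
reproduces every output byte for byte (checked in the suite and by the
acceptance script).

## Known limitations

- The count test ignores biological replication within groups (it is a
  two-library test by construction); modern dispersion-estimating models
  would be preferred on real data and are deliberately out of scope.
- The coding-potential score, trans-alignment scoring, and all three
  binding predictors are transparent stand-ins for external tools; their
  absolute outputs are not comparable to those tools, only their roles in
  the pipeline's combination logic.
- Uniform-random background sequence and a flat expression baseline make
  planted-truth recovery measurable but optimistic relative to real data.
- Annotation handling covers single-exon, single-transcript features; no
  splice structure.
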