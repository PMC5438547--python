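# Methods

This note documents the models, statistics, and design choices behind the
`tstv` pipeline: a four-arm analysis asking whether transversions (Tv,
purine↔pyrimidine substitutions) perturb regulatory DNA more than
transitions (Ts, A↔G or C↔T). The four arms address, in order, local DNA
structure, predicted transcription-factor (TF) binding, measured
allele-specific TF binding, and regulatory element activity in reporter
assays.

## Substitution classification

Of the 12 ordered single-base substitutions, 4 are transitions, so uniform
mutation yields a 1:2 Ts:Tv ratio; this ratio is the combinatorial
backbone of every arm (quartets contribute 2 Ts and 4 Tv pairs, each motif
position 2 Ts and 4 Tv mutation pairs, each saturated position 1 Ts and 2
Tv records). The class is symmetric in the two bases and invariant under
complementation. Only unambiguous A/C/G/T biallelic SNVs are accepted;
IUPAC ambiguity codes and indels raise errors rather than being guessed
at.

## DNA shape arm

**Model.** A pentamer lookup table assigns each 5-mer four structural
parameters: minor groove width (MGW, Å) and propeller twist (ProT, °) per
base pair, and roll and helical twist (HelT, °) per base-pair step. The
profile of a sequence takes the base-pair parameters from the pentamer
centred on each position; a step parameter is the mean of the values of
the two pentamers flanking the step. The first/last two positions (and
first/last two steps) have no covering pentamer and are undefined (NaN);
undefined entries are excluded from all sums rather than zero-filled.
The mean-of-flanking-pentamers rule for step parameters is this package's
fixed convention: it is symmetric and order-independent.

**Experiment.** `run_shape_experiment` draws random sequences of odd
length (default 503 bp, configurable), substitutes the middle base to all
three alternatives, and scores all 6 unordered pairs of the resulting
4-variant quartet. The effect of a substitution is, per parameter, the
summed absolute profile difference between the two sequences. Because the
pentamer model is local, a central substitution can only change positions
within ±2 bp (steps −3..+2) of the mutation; the implementation therefore
computes deltas inside an 11-bp window, which is provably equal to
full-profile subtraction and is verified against it elementwise in the
tests.

**Comparison.** Mean |Δ| per class and the Tv/Ts ratio are reported per
parameter, along with a linear model of |Δ| on a Tv indicator with the
originating sequence (quartet) absorbed as a fixed effect. Absorption is
done by within-quartet demeaning of response and indicator, which is
algebraically identical to one dummy column per quartet
(Frisch–Waugh–Lovell); residual degrees of freedom are adjusted for the
absorbed means. Mean and median are both reported; the mean is primary.
The shipped synthetic pentamer table has no planted Ts/Tv asymmetry — a
random table gives class ratios near 1 — so directional shape conclusions
require the empirically derived Monte-Carlo pentamer table, which is a
pluggable external resource (`load_shape_table`).

## TF binding motif arm

A position frequency matrix (PFM) with a pseudocount of 0.1 added to every
element becomes per-position frequencies f(b,i) = (count+0.1)/(total+0.4)
and a position-specific scoring matrix (PSSM) of log-odds scores
log2(f/background) in bits (uniform background by default; bits are used
so information content IC(i) = 2 + Σ_b f log2 f is bounded by [0, 2]).
The consensus takes the argmax per column, ties resolving to the first
base in A<C<G<T order. A sequence's score is the sum of its per-position
scores, so a single-base change moves the score by exactly the
within-column difference; the exhaustive scan therefore records
|score(b1,i) − score(b2,i)| for all 6 unordered base pairs at every
position. Magnitudes are symmetric, so unordered pairs avoid duplicating
every value.

Motif position is folded to distance-from-edge scaled to [0,1]
(0 = either edge, 1 = centre, defined as 1 for single-position motifs),
reflecting the approximate edge/centre symmetry of motif specificity.
Records are stratified into equal-width bins over position [0,1]
(default 11 bins) or IC [0,2] (default 20 bins) and each bin is tested
with a two-sided Welch t-test of Tv vs Ts deltas; p-values are reported
unadjusted with the Bonferroni threshold α/n_bins alongside. Welch was
chosen over the pooled-variance t-test as the robust default for unequal
class sizes (Tv records outnumber Ts 2:1).

**Calibration caveat.** The 6 deltas of one position share that position's
4 column scores, so the Ts- and Tv-bin means are positively correlated
and the Welch test is *conservative* on motif-derived records (empirical
rejection ≈2.5% at nominal 5%); it is never anticonservative, which the
tests assert. The uniformity calibration therefore uses a record-level
null in which deltas are drawn iid from a common distribution over the
record structure of a synthetic motif library.

## Allele-specific binding arm

SNPs tested for allele-specific binding (ASB) carry a chromosome,
position, ref/alt alleles, a group (TF or cell line), and an ASB flag.
Pooling across groups collapses variants to unique (chrom, pos, ref, alt)
keys, keeping the ASB flag if set in any group; collapsing is idempotent
and deterministically sorted. The Tv fraction among collapsed ASB
variants (p1, n1) is compared with the Tv fraction among all tested
variants (p0) by a pooled-variance two-proportion Z-test:
z = (p1−p0)/√(p̂(1−p̂)(1/n1+1/n0)), p = 2Φ(−|z|). When the overlap of
tested SNPs across groups is unknown, the null sample size n0 defaults to
the mean number of SNPs tested per group (`across_groups_mean_n`);
`union` pooling uses the collapsed tested count instead. A one-sample
variant (fixed null proportion) is provided. ASB variants remain in the
null set (they are a subset of the tested variants and are not excluded).

## Reporter-assay haplotype arm

Haplotypes are grouped by amplicon so each is compared only with
haplotypes of identical coordinates. One haplotype per group is the
reference — drawn uniformly at random with a recorded seed, or designated
explicitly. Each non-reference haplotype yields a contrast:
|log2(effect) − log2(effect_ref)| plus the number of Ts and Tv differences
from the reference at segregating sites, re-counted within the middle
third of the element's DNase-hypersensitive site ([start+⌊L/3⌋,
start+⌊2L/3⌋) of the DHS interval; BED intervals are 0-based half-open,
variant positions 1-based). Groups with no haplotype reaching effect
p < 0.05 (the reference included) are excluded before fitting.

Three OLS models relate contrast magnitude to substitution content, each
with the amplicon as a categorical covariate: presence (has_ts + has_tv),
count (n_ts + n_tv), and middle-third count (n_ts_mid + n_tv_mid). The
presence terms are fitted jointly by default (separate fits are
available). The middle-third restriction defaults to re-counting within
the DHS middle third while keeping all haplotypes (`mid_mode="recount"`);
a subset mode drops contrasts with no middle-third difference.

**Synthetic generator.** The planted scenario makes log2 activity
additive in alt-allele content: relative to the all-reference-allele
haplotype (emitted first per amplicon), a haplotype's magnitude is
c_amplicon + β_ts·n_ts + β_tv·n_tv + |ε| with ε ~ N(0, noise_sd) and a
random sign applied to the signed log2 difference. Defaults: 100
amplicons × 8 haplotypes, Poisson(3) segregating sites, β_ts = 0.06,
β_tv = 0.12 (the coefficient scale observed in population reporter
assays), noise_sd = 0.8 (giving coefficient standard errors near 0.03 at
this scale, matching reported uncertainty). With the true reference
designated, the count model is exactly correctly specified and recovery
is clean; with a random reference the absolute value breaks additivity,
which mirrors the blinded random-reference convention of the emulated
assay — the CLI supports multi-seed re-runs to show the spread of β
across reference choices. Uniform alt-base drawing yields the theoretical
1:2 Ts:Tv site ratio; an optional `ts_bias` reproduces the Ts-rich ratios
seen in real population variants. The generator does not emulate linkage
disequilibrium, sequencing error, or barcode-level noise, so passing
recovery tests demonstrate correctness of the estimator under the stated
model, not robustness to those real-data features.

## Saturation-mutagenesis arm

Every position of each enhancer is mutated to all three alternatives;
replicate fold changes are averaged on the ratio scale first and the
response is |log2(mean fold change)| (so replicates (2.0, 2.0) → 1.0 and
a neutral mutation → 0.0). The pooled model is OLS of the response on a
Tv indicator, the element as a categorical covariate, and the scaled
centre distance |position − centre|/length; per-element fits use the Tv
indicator alone. The Tv test is one-sided (β_TV > 0), obtained from the
symmetric t distribution as half the two-sided p when the estimate is
positive. The pooled-model formula is this package's reading of
"adjusting for element and location"; per-element fits drop both
covariates. The generator plants half-normal effect magnitudes with a Tv
scale multiplier (default 1.5) and optional centre weighting, plus
lognormal replicate noise.

## Problem sizes and numerical choices

Simulation-based tests use 1,000 quartets × 503 bp for the shape oracle,
200 synthetic motifs for motif calibration, 1,000 replicates for Z-test
type-I error, 200 replicates of 100 amplicons × 8 haplotypes for
coefficient recovery, and 200 null / 50 planted replicates for the
saturation arm — sizes at which Monte-Carlo error is small relative to
the asserted tolerances while the whole suite runs in well under a
minute per arm. Ties in consensus columns resolve deterministically;
rank-deficient regression designs raise a dedicated error naming the
model rather than silently dropping terms; IC is clipped to [0, 2] only
to guard float round-off at the boundaries. All randomness flows through
`numpy.random.default_rng` seeded per run; generators are byte-identical
across re-runs of the same seed.

## Known limitations

- The synthetic pentamer table is range-plausible but structurally
  uninformative; directional shape results require the external
  Monte-Carlo table.
- The ASB generator plants marginal Tv fractions but no genomic
  clustering or per-TF heterogeneity.
- Binning for the motif tests is equal-width; the bin edges are
  configurable because equal-count binning is an equally defensible
  convention.
- The haplotype effect sizes are consumed as inputs; computing them from
  raw reporter-assay reads (barcode counting, normalisation) is out of
  scope.
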