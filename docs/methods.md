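# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Hotspot calling

Mutation identity is genomic — `(chrom, pos, ref, alt)` — never
protein-level: non-coding hotspots (e.g. 5′-UTR changes) are first-class
citizens and protein annotation is carried along as metadata.  The
recurrence threshold is the smallest integer `t` for which the number
of mutations recurring more than `t` times exceeds the number recurring
exactly `t` times.  When no mutation recurs exactly `t` times but some
recur more (a gappy tail), the ratio is treated as satisfied, which
preserves the smallest-integer semantics.  Sample de-duplication keeps
the lexicographically smallest sample id per patient — an arbitrary but
deterministic rule, stated here because any choice is defensible.

## Motif annotation

APOBEC deaminates cytosine, so every mutation is first mapped to the
strand carrying the pyrimidine (reverse complement when the reference
base is a purine).  A change is APOBEC-type when it reads TC→TG or
TC→TT, i.e. C>G or C>T in a TCN trinucleotide.  The classical TCW
motif (W = A/T) is deliberately not enforced: well-documented
APOBEC-induced hotspots occur in TCN-but-not-TCW contexts.  The base 5′
of the T separates the APOBEC3A-preferred YTCN (Y = C/T) from the
APOBEC3B-preferred RTCN (R = A/G) tetranucleotides; it needs a ±2
window and degrades to "NA" when unavailable.  Annotation is invariant
under simultaneous reverse-complementation of window and substitution
(property-tested).

## Signature refitting

Per-sample 96-channel catalogs (6 pyrimidine substitutions × 16
flanking contexts, lexicographic) are refit against a *fixed* reference
of signature profiles; profiles are inputs and are never learned.  The
exposures maximise the multinomial likelihood of the catalog under the
mixture `sum_k E_k S_k`, by EM with the standard multiplicative update.
Convergence is declared when the per-sample log-likelihood gain falls
below `1e-8 * (1 + |loglik|)`; the log-likelihood path is monotone
(tested).  Samples with zero usable mutations get all-zero exposures
flagged undefined.  The APOBEC score of a sample is the summed exposure
of the reference's two APOBEC slots.

The packaged reference (`data/signatures_synthetic30.tsv`) is a
**synthetic** 30-profile catalogue laid out like COSMIC v2 — an
ageing-like slot 1 (C>T at NpCpG), APOBEC-like slots 2 (C>T at TCN) and
13 (C>G at TCN), a flat slot 5 and random sparse profiles elsewhere —
because the published profiles are not redistributed here.  One
consequence worth knowing: a flat profile is only weakly identifiable
against a large pool of random profiles (their average is close to
flat), so per-component recovery of the flat slot carries a few
percentage points of leakage while the mean absolute exposure error
across all components stays well under 0.05 at 2000 mutations.

## Carrier association

For each APOBEC-type candidate hotspot, carriers' APOBEC scores are
compared against tumours carrying *none* of the candidates (not merely
not this one), with a one-sided ('greater') Wilcoxon rank-sum test.
Across candidates we apply Benjamini–Hochberg at α = 0.05; the
correction can be disabled.  Non-candidate hotspots are "not
APOBEC-associated" by definition; candidates with no scored carriers
are left undetermined.  Type-I error of the whole procedure is
calibrated on null simulations (carriers drawn from the background
score distribution).

## Replication strand

RFD tracks (bedGraph, 0-based half-open) assign each C/G mutation an
indicator: +1 when the strand carrying the mutated cytosine (Watson for
ref C, Crick for ref G) is replicated mostly as a lagging-strand
template in that cell line, −1 otherwise.  RFD exactly 0 carries no
strand preference and is treated as missing, as are uncovered positions
and non-C/G references.  The lagging probability averages
`(indicator+1)/2` over non-missing cell lines, with the coverage count
reported.  Group comparisons: two-sided rank-sum between
APOBEC-associated and other hotspots, one-sided signed-rank of a
group's probabilities against 0.5.

## Hairpin folding

`fold_mfe` is a Zuker-style minimum-free-energy dynamic programme over
unimolecular, non-pseudoknotted structures **without multiloops**:
every helix is a single chain of nested pairs closed by a terminal loop
of ≥ 3 nt; bulges (≤ 8 nt) and internal loops (≤ 10 unpaired nt total)
are allowed inside a chain, and several hairpins may sit side by side
in the exterior.  Energies are nearest-neighbour DNA stack free
energies at 37 °C plus hairpin/bulge/internal initiation penalties,
shipped as editable TSV tables (`data/nn_stacks_dna.tsv`,
`data/loop_penalties_dna.tsv`); loop penalties are linearly
interpolated between tabulated sizes and Jacobson–Stockmayer
extrapolated beyond them.  A 1-nt bulge keeps the stack of its closing
pairs.  G·T wobble pairs are off by default; the opt-in flag uses a
crude fixed stack value (−1.0 kcal/mol per wobble-containing step) and
is excluded from the oracle-backed guarantees.  Ties are broken by a
deterministic fixed-scan-order traceback.  Absolute ΔG values are a
surrogate for full folding servers; every downstream use relies on
ordering and thresholding, not on absolute equality, which is why the
guarantees are stated against an in-package exhaustive enumeration of
the same structure class (exact agreement for all tested windows of
length ≤ 17).

"In loop" means: unpaired and strictly inside the innermost closing
pair of a terminal loop.  Bulge and internal-loop positions do *not*
count, matching the biochemical picture of APOBEC3A engaging exposed
terminal-loop cytosines.

The window-escalation scan folds centred windows of 13, 17, 21, 25, 29
nt and reports the smallest length from which the centre's stem (pairs
enclosing the centre, in centre-relative coordinates) stays identical
at every longer window, plus the first length at which secondary stems
appear.  25 nt is the default analysis window.

## Loop stability score and matched null

The normalised loop stability score min–max rescales ΔG over the
panel's in-loop, ΔG < 0 entries (most stable → 0); sites not in a loop
or with ΔG ≥ 0 score exactly 1.  A degenerate range (all equal) maps
qualifying sites to 0 with a warning.  The expression-matched null
samples (seeded, without replacement) non-recurrent APOBEC-motif
mutations in genes within ±1 percentile point of any known-passenger
gene's expression rank, folds their 25-nt windows, records ΔG (zero
when not in loop or non-negative) and locates each known passenger in
that empirical distribution.

## Expression ranks

Each gene's expression is divided by the housekeeping anchor (GAPDH)
per sample; genes are ranked on a percentile scale in (0, 1] by the
median relative value across samples, with average ranks for ties.
Anchor normalisation cancels any sample-wise positive rescaling
(property-tested).  Percentiles are computed over all genes present in
the matrix.

## Driver/passenger classification

Both features live on [0, 1] so the Euclidean metric weighs them
equally.  Per sweep, each unresolved mutation's distances to all
current driver and passenger references are compared by a two-sided
Welch t-test (α = 0.05); significant points join the closer class and
become references for the next sweep; iteration stops when everything
is assigned or a sweep assigns nothing, leaving the rest undetermined.
Seeds are never reassigned.  MDoD is reported as mean distance to the
seed passengers minus mean distance to the seed drivers (positive =
driver-like).

The permutation p-value enumerates **all** relabelings of the seed
coordinates preserving the driver-set size — C(16,9) = 11,440 for the
canonical 9 + 7 seeding (some summaries of this design misprint the
count as 114,400) — and counts relabelings at least as extreme in the
prediction's direction, with a 1e-9 tolerance so the observed labeling
always counts.  Benjamini–Hochberg runs across predictions;
undetermined points get no p/FDR.  Seed configurations other than
(9, 7) enumerate C(n, k) exactly up to a size cap, beyond which a
seeded Monte-Carlo null substitutes.

The two-step GLR alternative multiplies two logistic probabilities —
P(functional gene | expression rank) and P(driver | loop score) —
with a penalised (ridge) fallback on perfect separation, flagged.

## Clonality, selection surrogate, two-cluster split

Clonality enrichment of hotspots within the panel's genes uses Fisher's
exact test on the (hotspot × clonal) table plus a logistic mixed model
`clonal ~ hotspot + log(mutation count)` with a per-gene random
intercept, fitted by variational Bayes (OR, normal-approximation CI and
p are reported; the estimator contract is deliberately loose).  The
selection-intensity surrogate divides a site's observed recurrence by
its cohort mutability mass `sum_s sum_k E[s,k] * S_k[channel]`; it is a
relative ranking device only — no attempt is made to reproduce a full
cancer-effect-size likelihood.  The two-group split of such scores is
an exact weighted 1-D k-means (optimal clusters on a line are
contiguous, so a threshold scan over the sorted values is exact;
verified against exhaustive partitioning).

## Regulon construction and activity

Candidates are genes whose Spearman correlation with both the factor
and its prototypical target is at least the anchors' mutual
correlation, after dropping the lowest-variance 20% of genes; anchors
are excluded from their own candidate set.  Knockdown validation uses
the DESeq2 model (via pydeseq2): median-of-ratios size factors,
NB dispersion estimation, unshrunk Wald log2 fold changes, BH FDR.
Genes are ranked with significantly downregulated ones on top — the
key is descending `(−log2FC)·(−log10 FDR)` restricted to downregulated
genes, an isolated and swappable choice — and candidate enrichment at
the top is tested by seeded randomisation of same-size gene sets with
the add-one estimator `p = (1 + hits) / (n_rand + 1)` (never zero).
The validated regulon is the intersection of candidates with
significantly downregulated genes.  Per-sample activity is an
ssGSEA-style weighted running-sum on within-sample ranks (weight
exponent 0.25); it is invariant to strictly monotone per-sample
transforms, which is the property the group comparisons rely on.
Dependency comparisons match each group-A score to group B's empirical
quantile function by local linear interpolation and test the paired
deltas by signed rank.

## Synthetic data: what it emulates, and what it does not

The default configuration is a scaled-down exome cohort: 200 tumours
(a realistic cohort is ~3× larger; 200 keeps the full test battery
fast while leaving every test well-powered), negative-binomial mutation
loads with mean 150, bimodal APOBEC activity (Beta(0.6, 0.6)) split
between the two APOBEC slots, the remainder split between the
ageing-like and flat slots.  28 APOBEC-motif recurrent sites are
planted — 9 known drivers and 7 known passengers seed the classifier,
12 hidden-role sites are the prediction targets — plus 2 non-APOBEC
recurrent sites.  Carrier probability is
`baseline × (1 + (multiplier − 1) × APOBEC score)` with baseline 0.02
and multiplier 8 for APOBEC-role sites, mirroring carrier fractions of
published hotspot panels (roughly 2–25% of samples).  Drivers sit in
highly expressed functional-stratum genes outside stable loops;
passengers sit in strong hairpin loops of low-expressed genes.  Hairpin
tiers embed reverse-complement arms around the mutated base; loop and
flank alphabets are chosen so unintended pairing cannot relocate the
terminal loop.  Clonality is 0.8 for planted sites vs 0.5 elsewhere.
RFD tracks are noisy sawtooths between randomly spaced origins;
knockdown counts are gamma-Poisson (dispersion 0.05, 4 vs 4) with a
25-gene regulon downregulated 4-fold.

Contexts are synthesised, never drawn from a real genome, so passing
tests demonstrate the machinery's correctness and calibration — they do
not demonstrate robustness to real-genome features the generator lacks:
mutation-rate covariates (replication timing, chromatin), gene-length
and coverage biases, subclonal copy-number structure, or correlated
hotspot co-occurrence.

A note on one recovery bound: with dispersion 0.05 and four replicates
per arm, the sampling standard deviation of an unshrunk log2 fold
change has a floor of `sqrt(2 × 0.05 / 4) / ln 2 ≈ 0.23` even at
unbounded counts, so roughly a fifth of planted knockdown genes will
fall outside ±0.3 of the true value no matter the implementation; the
FDR component of that recovery check is comfortably met while the
±0.3-for-90% component is not attainable under those design
parameters.

## Determinism

All randomness flows from one master seed through named per-stage
substreams (`SeedSequence((seed, stage_key))`), so stages can be rerun
in isolation and identical configurations reproduce byte-identical
artifacts (tested).
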