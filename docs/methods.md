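# Methods

## Window statistic and null model

The genome is tiled with sliding windows of width 240 bp every 10 bp,
anchored at multiples of the step from position 0 per chromosome; the final
partial window at a chromosome end is dropped.  A sequencing tag enters a
window when its 5′ position (BED interval start on the + strand, end − 1 on
the − strand) lies in the half-open window interval.  Duplicate tags are
kept: no deduplication step is part of the model, and the Poisson marginals
are estimated from the data as they are.  Windows overlapping a repeat-mask
interval by at least one base are excluded from all statistics — tags cannot
be uniquely mapped there, so their counts are unreliable in both libraries.

Per window, D = R − N with R the WT count and N the matched-KO count.  With
R ~ Pois(λ_R) and N ~ Pois(λ_N) independent, D is Skellam; the pmf is
computed in log space via `scipy.special.ive` (scaled Bessel) to avoid
under/overflow at small rates and large |d|.  λ_R = 0 or λ_N = 0 degenerate
to (negated) Poisson distributions, where the Bessel form is undefined.  The
survival function truncates the support where the remaining mass is below
1e−15 (40 σ plus a constant margin around the mean).

λ is estimated per library over non-excluded windows, by default as the
arithmetic mean count per window.  A `null_fit` alternative (mean over
windows with count ≤ 3) is selectable when strong enrichment would otherwise
inflate the background rate; with realistic signal fractions (~10⁻⁴) the two
differ negligibly.

## Local FDR and the critical difference

The observed density f̂ of D is its integer histogram over non-excluded
windows, with empty interior bins given a 0.5 pseudo-count before
normalization so the fdr is defined at every d in the observed range.  The
null weight p0 is either supplied or estimated by central matching:
p0 = min(1, min over d ∈ [−2, 2] of f̂(d)/f0(d)) — the central bins are
overwhelmingly null, so their density ratio bounds the null weight.  Then

    fdr(d) = clip(p0 · f0(d) / f̂(d), 0, 1).

Sparse high-d bins make the raw fdr noisy and possibly non-monotone, which
would leave the threshold ill-defined; for d ≥ 1 a running minimum enforces
a non-increasing fdr, and the critical difference d0 is the smallest d ≥ 1
with regularized fdr(d) ≤ f_p (default 0.01).  The tail analogue
FDR(d) = clip(p0 · P0(D ≥ d)/P̂(D ≥ d), 0, 1) equals the f̂-weighted mean of
the raw fdr over the declared set and is reported as a diagnostic; it is
undefined (None) beyond the observed maximum.

At the study rates (λ_R = 0.15273, λ_N = 0.21607) on 10⁷-window mixtures
with signal fraction 10⁻⁴ and +5 expected WT reads per signal window, the
fit yields d0 = 6 with high reproducibility across seeds — this is the
quantity `scripts/acceptance.py` recomputes.

## Peak assembly

Each significant window (D ≥ d0, not excluded) contributes its **central**
step-bin [start + (width − step)/2, start + (width + step)/2).  A window's
count is evidence about its middle — the same tag cluster makes all ~24
covering windows significant, and the union of their central bins sits on
the cluster, whereas left-edge bins would place the footprint up to
width − step bp upstream of the binding site.  The central-bin union keeps
the minimum peak size equal to the step (10 bp).  Runs of adjacent bins
become one peak; peaks separated by ≤ 100 bp are merged into their spanning
interval (idempotent); merged regions of length ≤ 20 bp are set aside,
flagged "too short", because a 10–15 bp motif cannot be meaningfully
searched in them.

## Motif discovery

The sampler is a ZOOPS (zero-or-one occurrence per sequence) Gibbs site
sampler over both strands: per iteration one sequence is withheld, the
position frequency matrix is rebuilt from the remaining site assignments
(pseudocount 0.25 per base), and the withheld sequence's site variable is
resampled across all offsets × strands × an explicit absent state, with a
uniform positional prior and absent-state prior weight 0.1 (absence must be
representable: a minority of true peaks carry no instance).  Site
likelihoods are ratios against an order-3 Markov background with add-one
pseudocounts and lower-order fallback at sequence starts.  After every full
sweep a greedy phase-shift move tries displacing the whole alignment by
−2..2 positions (sites that cannot shift stay put and are resampled next
sweep); site samplers without such a move routinely lock into registers
displaced by one or two bases.  The best-scoring assignment across sweeps
and restarts is returned; everything is deterministic given the seed.

The background training corpus matters more than its order: order-3
conditionals estimated from only a few kb of peak sequence are so noisy that
every sequence's rarest k-mer outscores genuine sites (a stable degenerate
attractor).  The pipeline therefore trains the background on the full
genome sequence; the motif-recovery tests train it on a large generated
background corpus.  Training on the small peak set itself is possible but
not recommended.

The sampler score is the total log2 likelihood ratio of the assigned sites
against the background — additive over sites, zero for an empty site list.
It is used to rank restarts and to compare signal against control region
sets as an ordering; its absolute scale is not comparable to scores of
other motif finders.

The IUPAC consensus calls a single base when its column frequency is ≥ 0.6,
a two-base degeneracy code when the top two sum to ≥ 0.8, else N; per-column
information content is 2 + Σ p log2 p bits.  A discovered motif's
orientation is arbitrary, so the pipeline orients the returned model toward
the reference site before scanning and classification.  Scanning reports
the maximal log-odds site over offsets and strands (ties: smallest offset,
then + strand); sites below a configurable log-odds floor (default 0, i.e.
no better than background) are reported "none", sequences shorter than the
motif "too short".

## Affinity classification

Competition-EMSA mutagenesis of the reference site AAAGCGAGGC defines
per-position requirements: preferred bases at positions 1 (A), 3 (A), 6 (G),
7 (A), 8 (G), 9 (G), 10 (C); positions 2, 4, 5 unconstrained.  A 10-mer is
Low affinity if it deviates at any of positions 3/6/7/8 (these changes
essentially eliminate binding), otherwise Medium if it deviates at any of
1/9/10 (partial impairment), otherwise High.  Position 1 is judged against
the strict reference base A rather than the looser R the in-vivo consensus
would allow; this is the conservative reading of the mutagenesis series and
is configurable only by editing the preferred-base table.  The partition
over all 4^10 sites is 64 High / 4,032 Medium / 1,044,480 Low, verified by
enumeration.

## SELEX simulation and consensus

Oligos carry a random 16 bp insert between fixed 25 bp primer flanks (66 bp
total).  Selection keeps an oligo with probability
logistic(strength · (best-site PWM log-odds − midpoint)) — the standard
occupancy form; a midpoint-free logistic saturates for every moderately
scoring site and produces no differential enrichment.  Defaults: strength
1.5, midpoint 12 bits, 4 rounds, pool 50,000.  The pool size is a
deliberately scaled-down surrogate for real 10¹³-molecule pools, but it
cannot be much smaller: the founder pool must contain consensus-quality
sites at all (the best of 5,000 random inserts is a two-mismatch site).
After the final round 62 clones are sampled, mirroring the
cloning-and-sequencing step of a real screen.

The flank constants were chosen once, like real primers, to be dissimilar to
the consensus PWM (best flank-context log-odds < −8); otherwise selection
enriches flank-boundary pseudo-sites.  Consensus construction runs the Gibbs
sampler over the insert anchored with width//4 flank bases per side: windows
lying wholly inside the constant flanks are perfectly "conserved" in every
oligo and form an inescapable attractor for any motif finder, while the
anchored context still allows sites straddling the insert/flank boundary.
The per-round enrichment trace (mean best-site log-odds) is a diagnostic of
selection pressure; only its monotonicity is asserted on synthetic data.

Recovered and planted degenerate patterns are compared at their best
alignment over both strands and register shifts within ±2 (a sampler's
register is arbitrary), counting positions whose IUPAC base sets intersect.

## Expression comparison

Per-sample target abundance is divided by the reference-gene (Gapdh)
measure from the same sample, and ratios are rescaled so the WT group mean
is 1.  Inputs are linear-scale abundances by default; a Ct-scale mode
(ratio = 2^−ΔCt) is available behind a flag since normalized qPCR values
can be reported on either scale.  Group differences use the classical
pooled-variance two-tailed unpaired t-test; groups with zero pooled
variance short-circuit to p = 1 (equal means) or p = 0 (unequal).

## Synthetic data: what it does and does not emulate

Generators cover per-window count mixtures (independent windows), full
genome + tag-track fixtures (uniform background tag placement at per-base
rate λ/width, planted footprints receiving Poisson-distributed extra WT
tags and one embedded motif instance), planted-motif sequence sets, SELEX
pools, and two-group expression tables; each is deterministic under its
seed and serializes its ground truth.  The defaults are the study
conditions: λ_R = 0.15273, λ_N = 0.21607 per 240 bp window; signal-window
fraction 10⁻⁴ with +5 expected WT reads for mixture-level analyses; 20
planted 60 bp regions with ~15 extra WT tags each on a 200 kb genome for
end-to-end fixtures (chosen so that per-region recovery at d0 = 6 has high
power: P(Pois(15) ≥ 6) ≈ 0.998); motif datasets of 50 × 100 bp sequences at
ZOOPS occupancy 0.9.

Not emulated: overlapping-window count correlation (mixture windows are
independent, whereas 24 consecutive real windows share tags), fragment-size
and strand-shift structure, mappability variation, chromatin accessibility
bias, sequence composition beyond order-0 background (an order-3 genome
generator is deliberately not the default because window statistics are
composition-blind), PCR errors or amplification bias in SELEX, and qPCR
efficiency curves.  Passing tests therefore demonstrate the statistical
machinery under its own assumptions, not robustness to these real-data
effects.

## Numerical and degenerate-input choices

Skellam pmf in log space; sf truncation at mass < 1e−15; empty empirical
bins pseudo-counted with 0.5; running-minimum fdr regularization; clip of
all fdr values to [0, 1]; ties in TSS assignment broken toward the upstream
(smaller-coordinate) TSS, then lexicographic gene symbol; scanning ties
toward the smallest offset, then the + strand; a locFDR fit with no
qualifying d returns d0 = None, which downstream calling treats as "nothing
significant" in the pipeline and as an error requiring an explicit override
in direct API use.  "Within 10 kB of an annotated gene" is implemented as
|center − TSS| ≤ 10,000 (TSS distance, inclusive), not distance to the gene
body.

## Problem sizes

Test and acceptance runs use 10⁷-window mixtures (10 seeds) for the
critical-difference check, 10⁶-window labelled mixtures (20 seeds) for FDR
calibration, 20 planted-motif datasets with 8 restarts × 3,000 sampler
iterations each, and 200 kb end-to-end genomes.  These sizes were chosen so
the full suite completes in a few minutes while every stochastic assertion
retains comfortable statistical margin; the sampler's production defaults
(20 trials × 10,000 iterations) remain the CLI defaults.

## Known limitations

The locFDR machinery assumes integer-valued D and a unimodal null around
0; very deep libraries would need a continuous treatment.  p0 central
matching is biased upward when signal mass reaches into d ∈ [−2, 2].  The
Gibbs sampler models exactly zero or one site per sequence; multi-site
peaks are represented by their best site only.  The affinity classifier
encodes a specific mutagenesis series and does not generalize to other
motif widths.  SELEX simulation selects on a fixed PWM and cannot discover
binding modes the PWM does not encode.
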