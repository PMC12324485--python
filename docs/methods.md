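# Methods

This note documents the models, defaults and numerical choices behind
`tdmdkit`, and what the synthetic-study design does and does not establish.

## The pipeline's model of TDMD trigger discovery

A TDMD trigger binds a miRNA-loaded Argonaute and recruits the
ZSWIM8/EBAX-1 E3 ligase, destroying the complex. Two observable signatures
drive the pipeline:

1. **Hybrid enrichment.** In a decay-deficient genotype the trigger-bound
   complexes that would have been degraded accumulate, so the trigger's
   chimeric (miRNA-ligated-to-target) reads are over-represented relative to
   wild type. Enrichment is computed per (miRNA, transcript, binding site)
   as `(mean RPM_mut + p) / (mean RPM_wt + p)` with pseudocount
   `p = 0.01 RPM` on both sides (zero-handling that keeps depletion
   visible), after requiring `max(group means) > 0.1 RPM`. The abundance
   filter uses the max of the two group means — the permissive reading when
   the filter is not tied to one group — and is configurable. Ranks carry no
   p-value: the ranking is descriptive, and statistical significance lives
   in the count-based decay analysis.
2. **Guide-specific stabilization.** Disabling decay raises the
   Argonaute-loaded guide strand only; passenger strands report on
   transcription/biogenesis and stay flat. The `strand_level_inference`
   rule calls `decay_level` when the guide is up (fold ≥ 1.5, q ≤ 0.05)
   while the passenger fold stays below 1.3, and `biogenesis_level` when
   both strands rise.

Pathway congruence formalizes single-vs-double-mutant epistasis on log2
fold changes: `same_pathway` if the double mutant is within 0.5 log2 units
of the stronger single mutant, `additive` if within 0.5 of their sum,
otherwise `intermediate`. The 0.5 tolerance is a design choice (about a
1.4-fold band), not an estimated quantity.

## Chimera calling

Preprocessing follows the order adapter-trim → exact-duplicate collapse →
UMI removal (4 nt from each end) → length filter (≥ 18 nt). Collapsing
*before* UMI removal means molecules sharing an insert but differing in UMI
stay distinct, which is what makes the collapse PCR-duplicate-specific.
Hybrid detection requires a full-length guide-strand occurrence (Hamming
distance ≤ 0 by default; passengers are never searched — trigger discovery
concerns guide-loaded RISC) and a flanking fragment of ≥ 16 nt mapping
uniquely to the transcriptome via an exact 12-mer index with ungapped
extension; "unique" means the best locus beats the second best by ≥ 2
matches, a deterministic margin with no free parameter. Reads with two
disjoint guide occurrences are rejected rather than split. Coordinates are
0-based half-open on the sense strand throughout. Binding sites are
single-linkage clusters of target spans (overlap ≥ 1 nt), with the summit
at the leftmost position of maximal coverage. When several samples are
compared, per-sample site spans are re-keyed to their cross-sample union
(`harmonize_sites`) so that a few nucleotides of fragment jitter cannot
misalign the enrichment contrast.

## Duplex prediction and architecture

The duplex predictor maximizes an additive score over non-crossing base
pair sets, global on the miRNA and local on the target window, with
deterministic tie-breaking (more Watson-Crick pairs, then more seed pairs,
then leftmost target start). Defaults:

| term | value | rationale |
|---|---|---|
| WC pair | +2 | |
| G:U pair | +0.5 | wobble pairs are weak; they extend helices but cannot seed them |
| internal mismatch | −3 | an isolated pair across a 1×1 loop nets 2−3 < 0 and is excluded |
| gap open / extend | −3 / −0.5 | long one-sided target bulges are cheap, as in real trigger sites |
| miRNA end overhang | −0.5 per nt | mild dangling-end charge; target overhangs are free |

The stiff interior penalties matter: with all per-position penalties at −1,
random 3' sequence against a ~40-nt window supports long chains of isolated
pairs, and the 3'-pairing extent underlying the TDMD/TDTT calls loses all
contrast between planted and background complementarity. The chosen values
make predicted duplexes contiguous helices optionally separated by a
target-side bulge — the shapes a nearest-neighbor thermodynamic model
produces — while a long 3' complement across a 12-nt bulge (the planted
site-1 geometry) still wins. The score is a topology heuristic, not a free
energy; temperature has no analog in it.

Regions are fixed at seed g2–g8, central g9–g12, supplemental g13–g16,
tail g17–end. `perfect_2_8` requires all seed pairs to be Watson-Crick
(G:U counts toward region totals but not toward "perfect"). The
tailing/trimming-prone call (`tdtt_prone`) requires ≥ 2 pairs within the
last 3 miRNA positions *and* 3' extent ≥ 8 — thresholds for "extensive" 3'
pairing are design choices, exposed in `classify_architecture`. The
classification window is the binding site span (plus the ≤ 3 nt of
clustering jitter); classification is deliberately site-local, so sequence
far outside the site cannot change the calls. t-positions extrapolate
5'-ward along the trigger with unit steps beyond the miRNA 3' end (t35 is
27 nt upstream of t8), even across unpaired positions.

## isomiR decomposition

A read is assigned to a miRNA by an exact 14-nt 5' anchor (5' isomiRs are
out of scope) and decomposed by maximal prefix matching against canonical +
downstream genomic context. The greedy maximal rule resolves trim-vs-tail
ambiguity conservatively: a tail nucleotide identical to the next templated
base is absorbed into the template (such reads are genuinely
indistinguishable), and templated 3' extensions are classified canonical
with a logged flag. Tails longer than 5 nt mark the read unassigned.
Because pure 3' truncations are always prefixes of the canonical sequence,
trimming fractions are never distorted by re-templating; only tails can be.
Genotype comparison uses a pooled two-proportion z-test per miRNA with
Benjamini-Hochberg adjustment; `trimmed_tailed` reads count toward both the
trimmed and tailed metrics. At 10⁴ reads per miRNA the test resolves
sub-percent fluctuations, so downstream interpretation should combine
q-values with an effect-size floor (the test suite uses Δ ≥ 0.05, a third
of the planted effect).

## Count normalization and differential abundance

Size factors are per-sample normalizer-class totals divided by their
geometric mean (classes: total mapped reads, piRNAs, or spike-ins — the
choice is exposed because different figures of merit warrant different
normalizers, e.g. piRNAs when miRNA composition itself shifts). This is
class-total scaling, not median-of-ratios over features. Cross-stage
amplitudes fit one set of factors over both stages jointly; per-table
factors would leave the stages on different scales.

Differential abundance is a normalized log2 fold change with pseudocount
0.5 and a permutation p-value on |log2fc| over sample-label reassignments:
all distinct assignments when there are ≤ 5040, else 10⁴ random draws with
a fixed seed. The negative-binomial machinery of dedicated differential
expression tools is intentionally replaced: downstream logic consumes only
a fold change and a significance flag. Permutation p-values are discrete —
assignments come in complement pairs with identical |log2fc|, so with four
replicates per group the smallest attainable p is 2/70 — hence significance
calls use `p ≤ α`, and type-I calibration is run at five replicates per
group (252 assignments) where the attainable p-grid brackets 0.05
comfortably. Guides and passengers are tested as separate
multiple-testing families: they answer different questions (decay vs
biogenesis) and pooling them with discrete p-values would make q ≤ 0.05
unattainable at realistic replicate counts. Features with base mean < 10
are excluded.

## Stoichiometry

Standard curves are ordinary least squares of Ct on log10(copies), ≥ 4
points spanning ≥ 3 decades, with efficiency `10^(−1/slope) − 1`. Copies
per reaction invert the curve; copies per ng divide by RNA input. Excess
family molecules in a decay mutant are
`Σ_i ratio_i · ref_copies · (FC_i − 1)` over members (ratios relative to
the absolutely-quantified reference member); molecules degraded per
trigger copy divide by trigger copies per ng. Reported ratios round to the
nearest integer at ≥ 20 and to one decimal below 20. Peak expression from a
stage-mixed sample inverts `measured = peak · Σ w_s r_s` for stage weights
w and a temporal profile r relative to peak (both inputs, since the stage
composition of a mixed sample is experiment-specific). smFISH spots are
binned as `max(1, round(intensity / unit))` molecules with the unit
intensity from the median of reference-stage (single-molecule) spots; the
1-molecule floor is a design choice for sub-unit spots.

## The synthetic study design

The generator's defaults are the study conditions: an 8-member family
(22-nt guides sharing positions 2–8, 5' U), a trigger lncRNA of 882 nt with
site 1 (perfect seed complement for all members; planted 3' complements of
12 and 11 nt for two members, the basis of the TDTT contrast) and site 2
(g3–g8 complement with a non-pairing run opposite g2; 14-nt 3' complement
for the designated fourth member), 30 decoy transcripts of 600 nt (half
with seed-only conventional sites, log-uniform expression 1–10× the
trigger so trigger hybrids stay a small fraction of the library), hybrid
libraries of 2 × 10⁵ molecules with 10% target-only background and
Poisson(1) PCR duplication, enrichment λ = 4, four replicates per genotype,
count tables of 10⁶ reads with negative-binomial dispersion 0.05, planted
guide stabilization 7.1-fold at L1 in the decay-deficient genotype over a
10-fold wild-type embryo→L1 decay, passenger strands at 2% of guide
abundance and genotype-independent, 50 piRNAs and 5 spike-ins as
normalizer classes, isomiR probabilities 5% trim / 5% tail at baseline with
trimming elevated to 20% only for the 3'-paired members and only in the
decay-deficient genotype, a U-dominated tail alphabet (70/20/5/5), a qPCR
model with efficiency 0.95, Ct at one copy 38, Ct noise SD 0.1 and
standards in triplicate over 10²–10⁷ copies, and an smFISH model with unit
intensity 1000 (CV 0.2), 50 embryos per stage, and per-stage spot-count /
molecules-per-spot mixtures whose means put the late stage 37.6-fold above
the early stage. The planted absolute quantities (89,836 trigger copies
per ng at L1; 192,252 reference-miRNA copies per ng; stage-mixed samples
consistent with peaks of 398,941 and 346,742 copies per ng under two
stage-weighting variants) make the quantification fixtures round-trip to
the published scale of the motivating system. The hybrid:background ratio
is a free parameter, not a measured quantity.

Enrichment in the decay-deficient genotype is modeled per interaction: the
multiplier interpolates from 1 to λ with the planted decay fold of the
miRNA, so an interaction that drives no decay gains nothing. This is what
makes the seed-retargeting counterfactual (swapping site 1's seed
complement to a ninth, non-family miRNA) flip both the enrichment ranking
and the stabilization phenotype to the new miRNA, while the site-2 member
retains a mild (2-fold) redundant effect.

Planted-architecture fidelity is enforced, not assumed: low-3'-pairing
members' tails are rejection-sampled against the assembled site-1 sequence
(chance complementarity, including wobble, would otherwise contradict the
recorded truth), and the site flanks are redrawn until every member's
optimal duplex in the jitter-margin window matches its planted
architecture. A small fraction of seeds (~1 in 10) can retain one
non-engineered member just past the TDTT extent threshold after the
bounded redraw budget; the discovery, decay and stoichiometry analyses are
unaffected by this residual.

What the generator does **not** emulate: sequencing errors (beyond an
all-or-nothing match model), 5' isomiRs, splice variation or paired-end
read merging, real pre-miRNA hairpin folding (passengers follow a
synthetic reverse-complement-plus-overhang rule; only the guide/passenger
labels matter downstream), intramolecular RNA structure, crosslink-site
mutations, and amplification-efficiency drift. Passing the recovery suite
therefore shows the estimators are correct under the stated generative
model, not that they are robust to every artifact of real libraries.

## Problem sizes and determinism

Simulation-based checks use 20 independent studies at the default design;
hybrid-library analyses run at the count level (the multinomial interaction
model) with the full FASTQ → preprocessing → hybrid-calling path exercised
end-to-end at 3–5 × 10³ molecules, which already yields 100% assignment
accuracy on error-free reads. The exhaustive duplex oracle covers 200
random instances with both lengths ≤ 9; the isomiR oracle covers the full
read space (lengths 4–9) of a 6-nt toy miRNA with 3-nt context. Every
stochastic component draws from `numpy` Generators seeded from a single
`rng_seed` through fixed per-operation streams, so identical configurations
produce identical outputs byte for byte.
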