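# Methods

## Model overview

`stromix` calls somatic copy number and allelic imbalance from the two
per-SNP signals a genotyping array produces after normalization: the log R
ratio (LRR, log2 of observed over expected total intensity, ≈0 at two
copies) and the B-allele frequency (BAF, the normalized proportion of the
'B' allele signal, in [0,1]). The hidden states of the HMM are chromosomal
configurations of the two parental homologs F and M: 'O' (homozygous
deletion) plus every word F^a M^b with a ≥ b and 1 ≤ a+b ≤ 7 — 20 states in
all. Array data cannot distinguish which homolog is amplified, so 'FMM' is
identified with 'FFM' and names are written with F's first. Each state is
summarized by its copy number CN = #F + #M and its allelic imbalance
AI = 1/2 − MCP, where the minor-copy proportion MCP = #M / CN; AI is 0 for
balanced states, 1/2 for LOH states (no M), and in between for imbalanced
amplifications such as 'FFM'. This state space detects events that
6-state callers cannot express: high-copy LOH, imbalanced amplification,
and copy numbers up to 7.

Every state is assumed to arise from the germline 'FM' state by deletions
and amplifications. Consequently each tumor genotype belongs to one of four
classes by germline origin — g1 from AA (tumor A^CN), g2 from BB (B^CN), g3
from AB with A majority (#B = #M), g4 its mirror — and the probability of
observing class g at a SNP equals the germline Hardy–Weinberg frequency at
that SNP's population B-allele frequency pB: ((1−pB)², pB², pB(1−pB),
pB(1−pB)). LOH states have exactly two distinct genotypes (the
heterozygous-derived classes coincide with the homozygous ones), balanced
states three, all other heterozygous states four.

## Transition model

SNP spacing is irregular, so the transition matrix is a function of the
distance d between adjacent SNPs. With stationary probabilities π_i and
characteristic region lengths L_i, the probability of leaving state i over
distance d is ρ_i(d) = (1 − π_i)(1 − e^(−d/L_i)); given a change, the
destination is independent of the origin, a_ij(d) = ρ_i(d)·π_j/(1 − π_i).
This gives the identity matrix as d → 0, the stationary vector as d → ∞,
and mean region lengths ≈ L_i. Defaults: 'FM' holds π = 0.70 with
L = 100 Mb; the 19 aberrant states share the remaining 0.30 equally with
L = 5 Mb. Detection is robust to these transition-side values; they mainly
set the prior cost of opening a region.

## Emission model

LRR given state i is a mixture π₀·U(r) + (1 − π₀)·N(r; μ_i, σ_i): the
uniform component (support [−6, 3]) absorbs assay fluctuations with weight
π₀ = 0.01 (Illumina BeadArray default). States with the same copy number
share the same LRR distribution; LRR separates copy numbers while BAF
separates states within a copy number.

BAF given state i mixes the uniform on [0,1] with the four genotype-class
Gaussians, weighted by the class priors at that SNP's pB. Each class
Gaussian is **censored** at 0 and 1: mass that would fall outside the unit
interval is placed as point masses at the boundaries via the normal CDF,
reproducing the spikes real homozygous bands show at exactly 0 and 1. The
density over (0,1) plus the two point masses integrates to exactly 1.
LRR and BAF are treated as independent given the state.

The model file stores only the g3 Gaussian per state; the rest is derived:
g1 takes the g3 parameters of the LOH state with the same copy number
(whose g3 genotype is all-A), and g2/g4 mirror g1/g3 about 0.5. The state
'O' has no genotypes; its BAF is a single noise band N(0.5, 0.2),
represented internally as four identical pseudo-classes so the per-class
mixing update applies uniformly.

Default parameters (all user-editable in the model file): LRR means per
copy number (−4, −0.66, 0, 0.40, 0.68, 0.89, 1.06, 1.21 for CN 0–7), a
saturating curve anchored at 0 for the diploid state, with −4 reflecting
background signal at zero copies; LRR SDs 0.18–0.25 growing mildly with
copy number and 1.0 for 'O' (noise-dominated); g3 BAF mean equal to the
state's MCP; BAF band SDs 0.02 (homozygous), 0.04 (heterozygous-derived),
0.20 ('O'). These are typical magnitudes for normalized Illumina BeadArray
output.

Decoding is Viterbi in log space per chromosome, with a 1e−300 floor on
mixture values; ties break toward the lower canonical state index (lower
copy number), making decoding deterministic. No training is required or
supported — forward–backward posteriors and Baum–Welch are deliberately out
of scope. The decoded per-SNP path is collapsed into maximal same-state
regions, each annotated with CN and AI from the state name. Genotypes are
optionally called per SNP as the class with the greatest censored-Gaussian
value at the observed BAF (ties toward fewer B's).

## Stromal mixing

A contaminated sample is modeled as a fraction w of normal diploid cells
('FM' by default) plus 1 − w of tumor cells. Contamination leaves states,
priors and transitions untouched and only moves emissions toward the
normal state's.

**LRR.** The linear intensity ratio of the mixture is R = w·R_N +
(1 − w)·R_T with both components lognormal (LRR = log2 R). The sum is
approximated as lognormal by matching its first two linear-space moments
under independence (Fenton–Wilkinson), giving closed-form mixed (μ, σ) in
log2 units; w = 0 and w = 1 return the tumor and normal parameters
exactly. The apparent copy number of the mixture is w·c_N + (1 − w)·c_T.

**BAF.** A mixed genotype derives from tumor and normal genotypes of the
same germline class, so class priors are unchanged. The class-g band is the
copy-weighted combination with α = w·c_N / (w·c_N + (1 − w)·c_T) on the
normal component: mean α·μ_N,g + (1 − α)·μ_T,g. SDs combine **linearly**,
σ = α·σ_N,g + (1 − α)·σ_T,g, not in quadrature: both "components" are read
out by the same probe in a single hybridization, so the band width
interpolates between the two pure widths rather than shrinking as
independent errors would. This choice makes the balanced states 'FM' and
'FFMM' exactly invariant under mixing — the behaviour a mixture of
identical diploid genomes must have — whereas quadrature weights would
narrow them by up to 1/√2. It is the one place where the LRR side
(independence moments) and the BAF side (comonotonic noise) make different
assumptions; the LRR variance genuinely does shrink toward the diploid
state's as normal DNA dominates the total intensity.

Consequences worth knowing:

* LOH states grow two contamination bands (e.g. 'F' g3 = 'A' mixed with
  'AB' lands at α/2), which is also what the purity estimator reads.
* A tumor with zero copies contributes no DNA: for any w > 0 the 'O'
  state's BAF becomes exactly the normal state's. At w = 0 exactly the
  no-DNA convention (noise band at 0.5) applies instead, so the 'O' BAF
  parameter curve has a corner at w = 0; every other parameter is
  continuous on [0, 1].
* Different configurations can mix to identical observables — ('FFM',
  w = 0.5) and ('FFFM', w = 0.75) share mixed CN 2.5 and all four band
  means. This is an identifiability limit of bulk two-component data, not
  an implementation artifact; it is why an accurate w matters.

**Purity estimation.** Given an annotated contamination-band BAF value b in
a region of known tumor genotype (nB_T, c_T) — normally the 'A' band of an
'F' region or the 'AA' band of an 'FF' region — solving
b = (w·nB_N + (1 − w)·nB_T)/(w·c_N + (1 − w)·c_T) for w gives w = b/(1 − b)
and w = 2b for those two cases. The band annotation is semi-manual (the
`baf_band_median` helper takes the median BAF in (0.08, 0.48)); the result
is clipped to [0, 1] with a warning for small overshoots, since tumor cells
often carry more DNA than normal cells and inflate the apparent normal
proportion. A genome-wide LRR baseline shift (diploid band not at 0) should
be corrected first by subtracting the annotated diploid-band median from
every SNP. w is a single global value per sample, appropriate for one
dominant clone; multi-clone deconvolution is out of scope.

## Simulator

The generator draws each SNP's genotype class from the Hardy–Weinberg
priors at its pB, then BAF from that class's (mixed, if w > 0) censored
Gaussian and LRR from the state's (mixed) Gaussian, replacing either by a
uniform outlier with probability π₀ — i.e. it samples exactly the emission
model. Positions sit on a uniform 5 kb grid (≈550k-array density); the
decoder sees positions only through inter-SNP distances, so a real array
manifest adds nothing for validation purposes. pB values are drawn from a
symmetric Beta(2, 2), a mild central concentration reflecting array
content's bias toward common variants, or can be held at 0.5. The standard
validation layout is one 100- or 300-SNP region per state, all 20 states
per chromosome in shuffled order with per-chromosome offsets (440 regions
over 22 autosomes).

What this does **not** emulate: genomic waves and GC-correlated LRR trends,
asymmetric BAF bands, saturation at high copy number, linkage between
neighbouring SNPs' genotypes, inherited CNVs in the stromal genome, and
multi-clone heterogeneity. Passing recovery tests therefore demonstrates
correctness of the decoder under the model's own assumptions — a
well-specified-model round trip — not performance on un-normalized or
heterogeneous clinical data, which depends on upstream preprocessing
quality.

## Evaluation

Recovery rate is the proportion of SNPs whose detected value (CN or AI)
exactly equals the truth, computed separately for the two quantities;
border SNPs count. For comparison with 6-state callers, full states
collapse to {0n, 1n, FF, FM, 3n, ≥4n} (CN 2 splits by AI into copy-neutral
LOH and normal). The FDR of a class is the fraction of SNPs detected as
that class whose truth differs, NaN when the class was never detected.
Collapsed recovery is never lower than raw recovery on the same decode.

## Numerical choices

* Exact w = 0 / w = 1 short-circuits in the mixing formulas avoid drift at
  the endpoints.
* Transition matrices are cached by distance (uniform simulated spacing
  makes this a single matrix in practice).
* Model files store floats at 17 significant digits so read/write round
  trips are bit-exact.
* Emission quadrature in tests anchors integration points at band means so
  narrow (σ = 0.02) bands are not missed.
* The Viterbi oracle in the test suite enumerates all |S|^n paths
  vectorized; it shares no code with the decoder.

## Problem sizes used in checks

Validation runs decode one simulated chromosome of 6,000 SNPs (20 × 300)
per contamination level w ∈ {0, 0.2, 0.4, 0.6, 0.8}, seed-reproducible;
the purity round trip uses single 300-SNP regions at w ∈ {0.2, 0.4, 0.6}.
CN recovery in these runs is ≥ 0.99 at every w up to 0.8 — errors
concentrate at region borders, where runs of homozygous genotypes (whose
expected BAF is 0/1 in every state) make the exact boundary ambiguous, and
among high-copy states whose mixed distributions converge as w grows.
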