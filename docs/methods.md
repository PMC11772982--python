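# Methods

This note records the models, conventions, defaults and open design
choices behind `sulcalvar`, in the order the pipeline runs them.

## Score sign convention

Functional scores are signed as *alternative minus reference*: a
positive score means the model predicts a stronger epigenetic signal
from the alternative allele, a negative score a weaker one.  Published
descriptions of such scoring schemes are not always consistent about
the subtraction order; this package fixes alt − ref throughout and all
tail logic (lower quartile = predicted loss of signal, upper quartile
= predicted gain) follows from it.

## Extreme-quartile directional test

Per annotation, Q1 and Q3 are linear-interpolation quantiles of the
*pooled* case + control scores.  Pooling is a deliberate choice (the
procedure could also use per-cohort quartiles): a common cut makes the
two tails comparable between cohorts, and the test statistic is then a
plain one-sided Mann-Whitney U on the retained strict tails.  The
exact null distribution is used for combined n ≤ 20 without ties;
otherwise the tie-corrected normal approximation.  Annotation/tail
pairs with an empty cohort are marked untestable and logged; the
Bonferroni multiplicity is the number of *configured* tests
(2 × annotations), not the testable subset, so the control is
conservative.

## Sulcal graphs

Depth is oriented so that larger = deeper; sulcal pits are local depth
maxima.  Smoothing is iterative umbrella averaging (vertex replaced by
the mean of itself and its 1-ring), default 10 iterations — enough to
suppress vertex-level noise on meshes of the resolution used here
without erasing basin structure.  Watershed flooding proceeds in order
of decreasing smoothed depth; a vertex with no labeled neighbor founds
a basin, otherwise it joins its deepest labeled neighbor.  When two
basins first meet at ridge depth d_r they merge iff

    d_pit(deeper) − d_r < merge_ridge_fraction × d_pit(deeper)

with default `merge_ridge_fraction = 0.3`; the published watershed
variants this reconstructs do not state their merging thresholds, so
the fraction is exposed in configuration.  Node area is the sum of
one-third incident face areas over the basin (so areas exactly
partition the mesh area); the topology descriptor is (degree, mean
within-component shortest-path hop count), a pluggable choice standing
in for "number of edges and paths between nodes".

## Spectral matching

Node affinity is a product-free weighted sum of Gaussian kernels
exp(−Δ²_f / 2σ²_f) with defaults σ_position = 15 mm, σ_depth = 5 mm,
σ_area = 200 mm², σ_topology = 2 and equal weights (0.25 each) for the
"total" score; the σ values are set to the scale of across-subject
variation of each feature in adult cortical data and are configurable.
Before matching, both graphs are centered at their node centroid and
rescaled to the *geometric mean of their two RMS node radii*: this
removes translation and size mismatch while keeping coordinates in mm,
so the σ defaults stay meaningful (scaling each graph to unit RMS
would not).  Registration to a population template is out of scope;
normalization can be disabled when inputs are already co-registered.

The assignment affinity matrix has node affinity on the diagonal and,
for compatible candidate pairs, a consistency term
exp(−(‖p_i−p_k‖−‖p_j−p_l‖)²/2σ²_pos) · exp(−(h_A−h_B)²/2σ²_topo) with
h the hop count; cross-component pairs contribute zero.  The principal
eigenvector (power iteration) is discretized greedily by descending
entry subject to injectivity (ties: lower node ids), followed by
local-swap refinement, and finally an exact linear-assignment pass on
the matched-node-affinity objective: the reported similarity
normalizes the summed matched affinity by max(|V_A|, |V_B|), which is
a linear assignment objective, and the Hungarian step guarantees the
matcher attains its optimum (verified against exhaustive enumeration
on small graphs) while the eigenvector correspondence is kept whenever
it already does.  The normalization penalizes unmatched nodes, forces
self-similarity 1 and makes the score symmetric.

Traits: for each (feature, region, side), a participant's trait is the
mean pairwise similarity against every member of the reference cohort;
a reference participant is excluded from its own reference
(leave-one-out).  Per-feature similarities reuse the *same*
correspondence found with all features combined.

## Weighted correlation network

Built from first principles rather than by calling the reference R
implementation.  Profiles are per-participant score maxima (and,
separately, minima — negated before correlation so "more extreme
negative" aligns with larger values).  One outlier participant is
removed first: average-linkage clustering of participants on Euclidean
distance, dropping the singleton that joins the dendrogram last.
Signed-hybrid adjacency a = cor^β for cor > 0, else 0.  Soft power β
defaults to 9; `pick_soft_threshold` implements the approximate
scale-free criterion (10 equal-count connectivity bins, log-log
regression, signed R² target 0.8, smallest qualifying power).
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij).

Module detection is a *static* average-linkage cut of 1 − TOM at
height 0.995 with a 20-member minimum; the Dynamic Hybrid deep-split
sensitivity heuristic is intentionally not reimplemented (its
`deep_split` parameter is recorded in configuration for provenance
only).  The package's guarantees are therefore about planted-structure
recovery, not label-for-label parity with the R package.  Modules
whose eigengenes correlate above 1 − merge_height (default 0.25) are
merged iteratively to a fixed point.  Eigengenes are the first left
singular vector of the standardized member profiles, sign-oriented to
correlate positively with members on average; the grey non-module is
summarized the same way and included in the module-trait grid, so the
Bonferroni multiplicity is (modules + grey) × traits.  Module-trait
p-values are Student asymptotic, t = r√(n−2)/√(1−r²); partial
correlations residualize both variables on covariates + intercept and
use df = n − 2 − #covariates.

## Cohort statistics

Trait comparisons are per-trait OLS with a binary status term and a
categorical scanner field-strength covariate (a fixed effect; site
random effects are out of scope), BH-adjusted across traits.  The
subgroup comparison is a pooled-variance two-sided t-test by default
(Welch by flag).  Correlation power uses the plain Fisher z
approximation — it reproduces the reference values 99.3 %
(r = 0.7, n = 29, α = 0.05) and ≈ 63.5 % (α = 4.54e−5) — rather than a
bias-corrected variant.

## Target genes

The target of a prioritized variant is the gene with the nearest
transcription start site within 20 kb, strand-agnostic, ties to the
lower gene id; BED6 strand information is read (TSS = start for +,
end − 1 for −) but otherwise unused.  Enrichment is a one-sided
hypergeometric upper tail P[X ≥ k] per gene set, BH-adjusted, with the
background defined as all genes assigned to any analyzed variant —
this keeps "is the top-variant gene set special" distinct from "is any
gene near a variant".  Variant-in-region overlap uses the half-open
convention: 1-based position p overlaps [s, e) iff s < p ≤ e.

## Synthetic generator

The generator emulates the *statistical* structure of a genome + MRI
case/control study; it does not simulate DNA sequence, MRI volumes or
realistic epigenomic tracks, and the generative link between variant
impact and sulcal geometry is a testing device, not a biological
claim.  Defaults (chosen once, at design time): 30 case and 94
reference participants mirroring a genome+MRI case cohort and an
imaging reference cohort; Poisson(20) variants per participant on one
10 Mb synthetic chromosome `chrS`; 100 annotations of which two
planted modules of 25 and 10 disjoint "effect" annotations;
tail_inflation 1.5; planted trait correlation −0.7.

Mechanics and their rationale:

* **Effect annotations** multiply the case cohort's score standard
  deviation (variance inflation, not mean shift) so *both* directional
  tails are exercised.  Effect and module annotations are disjoint
  blocks; overlapping them would corrupt the planted module
  correlation with inflation noise.
* **Modules**: each participant carries one designated variant whose
  score on every module-member annotation is 3.5 + u_i + 0.5·ν, with
  u_i ~ N(0,1) the participant's module factor.  The 3.5 offset keeps
  this variant above the background maximum (≈ 1.9 for 20 standard
  normal draws), so per-participant maxima inherit the factor and the
  within-module correlation of maxima reaches its design value of
  ≈ 0.8 = 1/(1 + 0.5²).
* **Sulcal graphs** are perturbed copies of a Delaunay-triangulated
  template (log-normal depths ≈ 7–8 mm and areas ≈ 250 mm²): feature
  noise sd = ε·σ_f in units of the matching kernel scales, edges
  rewired with probability ∝ ε.  Case ε is log-normally shaped around
  perturbation_sd_case = 0.6 (log-sd 0.25, mild enough that Pearson
  recovery is barely attenuated) and driven by
  −r·z(module score) + √(1−r²)·noise.  The sign is deliberate:
  similarity *decreases* in ε, so tying ε positively to the module
  score (for r < 0) makes the downstream module-trait correlation come
  out at the planted r, matching the convention that a stronger
  predicted regulatory impact corresponds to a larger sulcal
  disruption.  The recovered module-trait correlation is attenuated to
  ≈ −0.6 by the nonlinear ε → similarity map; recovery is asserted
  within ±0.15.
* **Gene annotation**: TSSs are spread over `chrS`; for 80 % of case
  participants' top variants on the first effect annotation, an
  enriched-set gene TSS is relocated within 20 kb (cycling the set so
  it is broadly hit); decoy sets are random.  Planting acts on
  *assignment*, not recurrence — with desk-scale cohorts a single TSS
  is rarely within 20 kb of two independent uniform variants, so
  recurrence tiers are tested with constructed fixtures instead.

What passing synthetic tests does **not** show: robustness to
registration error, scanner- or site-specific trait distortions,
realistic linkage or mutational clustering of variants, non-Gaussian
score distributions, or module structure that overlaps differential
annotations — all properties of real data the generator intentionally
omits.

## Problem sizes and numerical choices

Tests and the acceptance script run the full machinery at reduced
scale — 40–200 annotations, 20–200 participants, 50–100 Monte-Carlo
replicates, templates of 6–12 sulcal nodes — sizes chosen so every
planted effect is comfortably detectable while the whole suite runs in
about a minute.  All randomness flows from explicit seeds
(`numpy.random.default_rng`; named SeedSequence substreams per stage in
the pipeline), so every reported number is bit-reproducible.  Plateau
ties in the watershed break by lowest vertex index; matching ties by
lowest node ids; equal-height outliers by lowest participant id;
constant columns are dropped with a warning before correlation or SVD;
identical-score quartile splits yield empty tails (logged) rather than
errors.

## Known limitations

* Module labels are not expected to match the reference R
  implementation's Dynamic Hybrid labels on real data.
* The spectral matcher is a faithful-in-spirit reconstruction of
  published spectral correspondence methods; their exact affinity
  weighting is not public, so absolute similarity values are not
  comparable across implementations — only relative/recovered
  structure is.
* Whole-gene (body) distance is not considered in target assignment,
  only TSS distance.
* Networks above ~20,000 annotations would need block-wise TOM
  computation, which is not implemented.
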