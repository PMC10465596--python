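# Methods

This note documents the models behind each glomnet module, the conventions
and tunable parameters that matter, what the synthetic-data generators do and
do not emulate, and the design choices made where the methods literature
leaves the details open.

## Data model and coordinate conventions

All data live in one shared Cartesian frame with coordinates in nanometres.
Skeletons follow the standard 7-column SWC convention (1-based node ids, root
parent −1, one neuron per file). The synapse table is polyadic: one row per
(pre → post) pairing, and rows sharing a `connector_id` share one presynaptic
neuron and site, mirroring how dense EM reconstructions export synapses. Each
pairing counts as exactly one connection in every tally — a polyadic
presynaptic site with three partners contributes three outputs. Glomeruli are
closed triangulated surfaces (Wavefront OBJ, triangles only); non-watertight
meshes are rejected. Reciprocal pre/post roles at a single connector are not
modelled: a row is strictly one direction.

## Point-in-mesh assignment

Synapse sites are assigned to glomeruli by even–odd ray casting: a ray along
+x per query point, counting triangle crossings via a vectorized
Möller–Trumbore test. Rays that graze a triangle edge or vertex (a
barycentric coordinate within 1e−10 of zero) have ambiguous parity and are
recast along a slightly perturbed direction, up to 16 deterministic restarts.
Points on the surface itself count as inside; because a ray from an
on-surface point can stay ambiguous indefinitely (e.g. a point on a face
diagonal), parity-outside points within 1e−6 of the mesh diagonal length of
the surface are accepted as inside by an explicit point-to-triangle distance
check. An axis-aligned bounding-box prefilter keeps the cost linear in the
number of points actually near each glomerulus. Meshes are non-overlapping by
construction, so the first containing mesh wins.

## Per-glomerulus polarity metrics

For neuron *n* and glomerulus *g*, `I_g` counts connection rows where *n* is
postsynaptic with its post-site inside *g*; `O_g` counts rows where *n* is
presynaptic with its pre-site inside *g* — i.e. assignment always uses the
site on the query neuron. The ratio `R_g = (I_g − O_g)/(I_g + O_g)` is −1 for
a pure-output glomerulus, +1 for pure input, and undefined (null) exactly
when `I_g + O_g = 0`. When annotations carry laterality metadata, only
ipsilateral connections are counted; the synthetic generator produces a
single hemisphere, so the filter is a no-op there.

Transmitter-class input breakdowns attribute each input synapse to a
glomerulus by a two-rule precedence: inputs from uniglomerular partner types
(OSNs, uniglomerular PNs) go to the partner's annotated home glomerulus;
inputs from multiglomerular partners go to the glomerulus containing the
post-site. Uniglomerular partners lacking a home glomerulus are excluded and
the exclusion counts are logged and returned. The methods this follows
describe both home-glomerulus and coordinate attribution without stating a
precedence; this split (home glomerulus when the partner type defines one,
coordinates otherwise) is our documented interpretation. Transmitter classes
come from the annotation table, not from code: the default synthetic mapping
treats OSNs/uPNs as excitatory (cholinergic), all LNs as inhibitory
(GABAergic or glutamatergic), and the CSD marker neuron as modulatory.
Co-transmission is not modelled.

## Flow centrality and the segregation index

With `I_d(v)`, `O_d(v)` the input/output counts in the subtree at-or-distal
to node *v* (a synapse mapped to *v* counts in *v*'s subtree) and `I`, `O`
the totals, the centrifugal flow is `I_d(v)·(O − O_d(v))`, the centripetal
flow `(I − I_d(v))·O_d(v)`, and `C(v)` their sum — the number of
input→output synapse pairs whose path traverses the edge between *v* and its
parent. The split node maximizes `C`; ties break to the node with the
smallest root-path cable distance, then the smallest node id. The
at-or-distal side of the split and its complement form the two compartments;
the side holding the larger share of output sites is labelled the axon (tie:
the distal side). The segregation index uses natural-log binary entropies:
`S = 1 − [Σ_i n_i H(p_i)]/[N·H(p)]` with `p_i` the input fraction of
compartment *i*; `S = 0` by convention when the pooled mix is already pure,
and a neuron with zero inputs or zero outputs is reported with a degenerate
flag (`C ≡ 0`, no split). `S` is invariant under globally swapping the
input/output labels.

## NBLAST

Arbors are resampled to ~1 µm spacing along each unbranched run and each
point's tangent is the dominant principal direction of its 5 nearest
neighbours (sign-free). The directed raw score of query *Q* against target
*T* sums `f(d, |u·v|)` over query points, with *d* the nearest-target
distance and `u·v` the tangent dot product; the normalized score divides by
the query's self raw score, so `normalized(Q, Q) = 1` exactly, and the
symmetric similarity is the mean of the two directions' normalized scores.
The default scoring function is the parametric form
`f = exp(−d/σ)·|u·v|` with σ = 3 µm; a binned log-odds score table
(distance × |dot| bins, delimited text) is fully supported as an alternative
scoring mode for users who have a trained table, and the candidate-filter
threshold (default 0.80, applied to the maximum mean-normalized score against
any reference) is well defined under either. Scores are invariant under
rigid motion of both clouds and under point-order permutation.

## Candidate filter

The filter is an ordered predicate chain with cheap annotation predicates
first: category = LN, subtype = patchy, synaptic input from a designated
marker neuron set, NBLAST score above threshold against a reference library,
tracing status = Traced. Any stage can be disabled. The ledger records, per
stage, the survivor count and the eliminated ids, so every exclusion is
attributable; survivor counts are non-increasing by construction, the final
set is independent of neuron ordering, and relaxing the NBLAST threshold can
only grow the set. The filter deliberately does not attempt to shrink the
candidate set down to the immunoreactivity-derived ensemble size; all
survivors are reported.

## Clone innervation statistics

Co-innervation uses product-moment Pearson correlation between binary
glomerulus columns, with two-sided p-values from
`t = r·√((n−2)/(1−r²))` on n−2 degrees of freedom. (The upstream methods
phrase this as a "rank" correlation, but the routine they cite computes
product-moment r by default, which is what reproduces the printed
coefficients on binary data; the worked anchor r = 0.49 at n = 50 gives
p ≈ 3.0 × 10⁻⁴ by this transform.) Constant columns yield flagged undefined
entries, never zero fills. No multiplicity correction is applied by default,
matching how such matrices are conventionally reported; a Holm step-down
switch is available. Clustering order comes from Ward linkage on Euclidean
distances (scipy's `ward`, equivalent to the "ward.D2" update), with scipy's
deterministic leaf ordering standing in for an explicit lower-index-first
tie-break.

The coupon-collector design gives the exact expectation `E[T] = n·H_n`, the
exact quantile `t* = min{t : P(T ≤ t) ≥ q}` via the inclusion–exclusion
probability `P(T ≤ t) = Σ_k (−1)^k C(n,k)((n−k)/n)^t`, and the asymptotic
form `n(ln n + γ + 1/2n)`, which is also defined for non-integer type counts
such as a mean labelled-cell count (13.2 cells gives ⌈42.2⌉ = 43 samples);
both modes are exposed without asserting which a given study used.

## Calcium-imaging metrics

Traces are ROI-mean scalars per frame (image registration and ROI tracing
are upstream and out of scope). The processing order is: optional Gaussian
low-pass (σ in frames, default 1), optional bleach correction dividing by a
single-exponential fit to the pre-onset and final-second samples, baseline
`F0` = mean over the 2 s before onset (≥2 s of pre-onset frames required,
`F0 > 0`), `ΔF/F = (F − F0)/F0`. Peak is the maximum ΔF/F in
[onset, onset + 1 s]. AUC integrates, by composite Simpson's rule (an odd
final interval is closed by a trapezoid), the ΔF/F minus its mean over the
1 s before onset, from onset to onset + 1 s. The response window is anchored
at odor onset by default: anchoring at the trace start would make the AUC
depend on arbitrary pre-trial recording length; a config toggle provides the
trace-start reading. ΔF/F, peak, and AUC are invariant under positive
rescaling of the raw trace. Anatomical density tables are normalized
within-indicator to that indicator's maximum, so each indicator's densest
glomerulus scores exactly 1. Trials are averaged within animal (3–4 trials)
before any cross-animal pooling.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (spec, seed); per-neuron substreams derive
from the master seed so adding a neuron never perturbs the others.

* **Glomeruli** are axis-aligned tessellated ellipsoids (icosphere
  subdivision 3; discrete volume within ~1% of analytic), semi-axes 4–7 µm,
  placed without overlap in a 120 µm box. Real glomeruli are neither
  ellipsoidal nor axis-aligned; nothing downstream depends on that.
* **Population** defaults follow the studied system: ~200 LNs with a planted
  patchy peptidergic ensemble of 9; each patchy LN innervates a glomerulus
  with probability 0.5 (at the AL's real ~50-glomerulus count this predicts
  ~12 co-innervated glomeruli for a clone pair, matching sister-clone
  observations). The glomerulus count (15), OSN/uPN counts per glomerulus
  (5/3), and synapses per innervated glomerulus (20) are desk-scale choices
  that keep the full pipeline in seconds while leaving every statistic
  well-posed; recovery tests that need tighter sampling error raise the
  synapse count explicitly.
* **Polarity planting:** within an innervated glomerulus, the LN's input
  count is Binomial(n, (1+r_g)/2) of n total pairings, so the expected ratio
  equals the planted r_g and r_g = ±1 forces pure input/output. Partner
  categories are drawn from a configurable mix (default 35% OSN, 30% uPN,
  30% LN, 5% multiglomerular PN); every generated count is recorded as
  ground truth.
* **Filter distractors:** non-patchy LN subtypes, a patchy LN without marker
  input, patchy LNs with alien (serpentine, extra-glomerular) morphology,
  and an incompletely traced jittered clone — one per filter stage. The
  reference library is jittered copies (σ = 200 nm) of the planted ensemble,
  emulating a driver line that labels the same cells.
* **Clone matrices** are sampled by thresholding a latent Gaussian whose
  pairwise correlations are calibrated — by inverting the bivariate-normal
  orthant probability with root finding — so the *binary-scale* (phi)
  correlations hit their targets; the latent matrix is repaired to the
  nearest positive-definite correlation matrix by eigenvalue clipping, and
  the achieved (post-repair) binary targets are returned for recovery tests.
  Infeasible targets (beyond the phi bounds of the marginals) are rejected.
  Real animal-to-animal variability has no known distributional model; the
  Bernoulli/copula model is a stand-in, stated as such.
* **Traces** follow `baseline · exp(−t/τ_bleach) · (1 + kernel) + noise`
  with an exponentially decaying response kernel whose value at onset equals
  the planted amplitude; defaults are 40 frames at 9 Hz with onset at frame
  20. The generator produces scalars, not frames: image-stack artefacts
  (movement, segmentation error) are outside what passing tests can show.

Passing the recovery tests therefore demonstrates correctness of the
computations under the stated statistical model — not robustness to the
biological and imaging nuisances the model omits (truncated glomeruli,
co-transmission, registration error, non-exponential bleaching).

## Numerical choices and degenerate inputs

Entropies use natural logarithms (S is scale-free regardless). Flow
centrality ties break by root distance then node id. NBLAST of a
single-node skeleton yields one point with an arbitrary unit tangent,
flagged. Simpson integration falls back to a trapezoid only for a final odd
interval. Ratio cells with no connections are null, not zero. Correlation of
a constant column is undefined and flagged. The copula Cholesky adds 1e−12
to the diagonal for numerical safety. All validation is report-based: the
pipeline refuses downstream stages on a failed report unless explicitly
forced via config.

## Pipeline sizes

The default test-suite and acceptance runs use 3–15 glomeruli, 2–14 planted
LNs, 20–600 synapses per innervated glomerulus, 10⁴-clone copula matrices,
10⁵ coupon-collector simulations, and 200 random trees for the
flow-centrality oracle — sizes at which every recovery tolerance (±0.05 on
ratios and correlations, ±0.1 on the coupon-collector mean) sits at several
standard errors.

## Known limitations

No truncated-glomerulus corrections; no electrical synapses; no NBLAST score
table training (a published table can be supplied as delimited text); no
PCA/valence enrichment analyses (standard statistics on externally assigned
labels); the CLI reads whole connectomes into memory and targets desk-scale
data, not full EM volumes.
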