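# Methods

This note documents the statistical procedures, the generative model behind
the synthetic cohorts, the numerical choices, and the limits of what the
simulation-based tests can show.

## Data model

A subject's connectome is a symmetric nonnegative `n × n` matrix with zero
diagonal over a fixed region atlas (default: the 90 cortical/subcortical
AAL regions, cerebellum excluded; smaller numbered atlases are supported
for simulation studies). Five edge metrics are carried: SC (weighted
streamline count, unitless, unbounded above), FA (unitless, in [0, 1]), and
AD/RD/MD (diffusivities, consistent arbitrary units, here ~µm²/ms).
Filtering state (unfiltered/filtered) is part of a connectome's identity;
analyses always run the full {5 metrics} × {2 filtering states} grid when
the data provide it. Matrices are read from delimited text (comma or
whitespace, optional header); upper-triangular-only files are mirrored, and
nonzero diagonals are zeroed with a warning rather than rejected, since
self-connections are meaningless here but appear in some tool outputs.

## Edge-level inference (TFNBS)

Per edge, a Welch two-sample t statistic (PD minus HC). Welch rather than
pooled-variance: the design is unbalanced (default 67 vs 166) and
equal-variance has nothing to recommend it here. Both one-sided hypotheses
are scored separately by sign-flipping the t matrix.

Threshold-free enhancement: the ladder is `n_steps` (default 100) evenly
spaced heights over `(h_min, h_max]` with `h_max` data-driven (the maximum
observed |t| over both hypotheses) unless set explicitly; each
suprathreshold edge accumulates `extent^E · h^H · Δh` with extent = number
of edges in its connected component. Defaults `E = 0.5`, `H = 3.0` follow
the ranges recommended in the threshold-free network-statistics literature;
both are exposed because reasonable analyses differ. Components are
labeled by union-find inside a compiled kernel; the scorer is tested for
exact agreement against an independent per-threshold component-labeling
oracle.

FWE control: `n_permutations` (default 5000) random group-label
permutations, a single permutation stream shared by both hypotheses (halves
the work and removes spurious asymmetry between t1 and t2); the ladder is
frozen at the observed `h_max` so permuted scores are commensurable.
`p_fwe = (1 + #{perm max ≥ observed}) / (1 + n_permutations)`; when the
number of distinct group assignments is below `n_permutations` the test
switches to exhaustive enumeration, in which the observed labeling is one
enumerated member and is not counted twice. The smallest achievable p is
therefore `1/(n_permutations + 1)` (or `1/N` exhaustively). Calibration:
over 400 simulated null cohorts (20 nodes, 15 + 15, 500 permutations) the
family-wise rejection rate at α = 0.05 measured 0.052.

## Graph measures

* strength: `s_i = Σ_j w_ij`;
* betweenness: Brandes on edge lengths `1/w` ("strong edge = short path" —
  the standard convention for connectivity weights), fractional credit for
  tied shortest paths, normalized by `(N−1)(N−2)/2`; disconnected pairs
  contribute nothing, isolated nodes get 0;
* clustering: the Onnela weighted form (geometric-mean triangle intensity
  with weights normalized by the graph maximum) — the dominant convention
  in the brain-connectivity literature; nodes with fewer than two
  neighbors get 0;
* assortativity: Pearson correlation of endpoint *strengths* over the edge
  list, each undirected edge in both orientations; undefined (NaN, excluded
  pairwise downstream) when endpoint strengths are constant, as in regular
  graphs.

Betweenness and clustering delegate to networkx; all four measures are
verified against brute-force oracles (path enumeration, triple summation,
explicit edge-list correlation) at N ≤ 8 to 1e-9. No thresholding is
applied anywhere — dense weighted graphs are analyzed as-is.

## Group statistics

Node-level and whole-brain comparisons use two-sided Welch tests (a
Mann-Whitney switch exists because the field is split on this; nothing
downstream depends on the choice under the simulated Gaussian-scale data).
BY (Benjamini–Yekutieli) adjustment — valid under arbitrary dependence,
which dense connectome-derived measures certainly exhibit — is applied
across the nodes within one (metric, filtering, measure) family, never
pooled across metrics. Significance stars (\*, \*\*) intentionally reflect
*pre-correction* p-values, mirroring the common reporting convention for
node-level screens; BY-adjusted values sit in their own column. Cohen's d
uses the classical pooled sd; its 95% CI uses the normal approximation
`se(d) ≈ sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2)))`. The filtering-impact
taxonomy is a pure function of the two pre-correction significance patterns
at α = 0.05: both significant → null effect; only unfiltered → removal;
only filtered → emergence; neither → never significant.

No covariate adjustment is performed; age and sex are generated and carried
in the manifest so users can extend the tests, but the default inference is
unadjusted.

## Classification

SVM: linear kernel, C = 1.0 (configurable), features z-scored per training
fold. SVM64: PCA fitted on the training fold only, keeping
`min(64, rank)` components. Folds are stratified (the 67/166 imbalance
makes unstratified folds fragile) and seeded. PD is the positive class for
precision/recall/F1 — the disease-detection framing; AUC uses the decision
function.

GNNs are implemented in numpy with fused numba kernels and hand-derived
reverse-mode gradients (verified against finite differences). Message for
the ordered pair (i, j), j a neighbor of i: `MLP(x_i ‖ x_j)` (GCN) or
`MLP(x_i ‖ x_j a_ij)` (GAT), where the MLP is linear-then-ReLU of the
concatenation, aggregation is the neighborhood mean, readout is mean
pooling plus a linear classifier, and the single-head attention
`a_ij = softmax_j(leakyrelu(u_a·x_i + u_b·x_j))`. Because the first MLP
stage is linear, the pair tensor is never materialized: the i-part and
j-part are projected separately and combined per pair inside the kernel.
With `a_ij ≡ 1` the GAT forward equals the GCN forward bit-for-bit (a
tested identity). Training: Adam (lr 1e-2), inverse-frequency
class-weighted cross-entropy, weight decay 1e-4 on projection matrices,
defaults 2 layers × hidden 32 (the library default is 16 for the harness)
and 30 epochs — sizes chosen so a full 2 × 5 × 4 model grid runs in
minutes on a laptop CPU; all are configurable. Runs are deterministic
given the seed.

## Synthetic cohorts

The generator emulates the *output statistics* of a tractography +
filtering pipeline, not its mechanics.

* Cohort composition defaults to the motivating study: 67 HC (24 F / 43 M)
  and 166 PD (61 F / 105 M), ages drawn per group and sex from the
  published means/sds (e.g. HC-F 58.8 ± 8.6, PD-M 61.7 ± 9.7 years).
* SC: log-normal per edge around a population log-mean with latent hub
  propensities and distance decay over random 3-D region positions (so
  hubs and weak long-range edges exist), per-edge log noise sd 0.25, plus
  one global log-normal scale factor per subject (sd 10%, the
  streamline-count variability between subjects).
* FA: logit-normal (mean logit 0 ≈ FA 0.5 along streamlines, between-edge
  sd 0.5, within sd 0.15). AD, RD: log-normal (≈1.35 and 0.67 µm²/ms);
  MD ≡ (AD + 2·RD)/3 exactly, mimicking tensor coupling — effects
  targeted at MD are planted on AD and RD jointly so MD inherits them.
* Filtering: per-edge multipliers `m_ij ~ Beta` with mean decreasing from
  0.95 to 0.35 in a latent "implausibility" rank (weak edges are the ones
  filtering down-weights) and concentration 30; no group dependence, by
  design. Filtered SC = `m ⊙ SC`; filtered mean-metrics are pulled toward
  the subject's multiplier-weighted mean value, staying in range. Realized
  multipliers are stored per subject (the `FilteringTrace`) as ground
  truth for filtering analyses.
* Effects: a standardized shift of the PD mean on the analysis scale
  (log/logit), so the planted Cohen's d is exact there; on the raw weight
  scale the empirical d matches to within transform curvature plus
  Monte-Carlo error (measured bias ≤ 0.07 at d ≤ 1.5, per-cohort sd ≈ 0.11
  at n = 100/group). Stages: `both` (survives filtering);
  `unfiltered_only` (the shift exists only in the unfiltered state and the
  affected edges get small, high-variance multipliers — filtering removes
  the difference); `masked_until_filtered` (heavy-tailed artifact weight,
  an order of magnitude above clean edge weights, is added to the
  unfiltered state only — filtering reveals the difference). The removal
  and emergence scenario presets confine the effect to a clique among the
  targeted regions so that it cannot spill into other nodes' strengths.

## What the tests do and do not show

Passing tests show that the procedures are correctly implemented and
statistically calibrated *under this generator*: Gaussian noise on
transform scales, independent edges given the population structure,
exchangeable groups under the null, and a filtering model that acts
independently per edge. Real connectomes have spatially correlated noise,
subject-level confounds (age, sex, motion, scanner), non-Gaussian edge
distributions, and filtering that acts on streamlines rather than edges —
none of which the simulation reproduces. Calibration results here
therefore do not certify error control on real data, and classifier
performance on planted effects says nothing about attainable accuracy on
real cohorts.

One construction deserves a note: the classifier separability check plants
d = 5 on a single edge of a *3-region* cohort (25 + 25 subjects). With
thousands of edge features a max-margin classifier provably dilutes a
single-feature signal across noise directions (measured fold AUC ≈ 0.6 at
90 regions despite a raw-scale d ≈ 3.5 on the planted edge), and exact
AUC = 1.0 tolerates not a single rank inversion, whose per-pair probability
is already ≈ Φ(−5/√2) ≈ 2·10⁻⁴ at d = 5. The compact atlas keeps the
validation-pair count low and the training-samples-to-features ratio high,
which is the regime in which constructed separability is actually
observable. The chance-level and PCA-rank checks run at the full 90-region,
233-subject scale.

## Numerical choices and degenerate inputs

* Zero-variance edges/nodes: t is set to 0 (one-sided p 0.5) at the edge
  level; node cells are marked untestable and excluded from BY families.
* Undefined assortativity (zero strength variance) is NaN, excluded
  pairwise with a logged count.
* Ties in the top-connection ranking break by larger |t|; ties between
  permutation max and observed score count toward the p-value
  (conservative).
* Exact symmetry is enforced after validation by averaging `W` and `Wᵀ`
  (tolerance 1e-10); file round-trips write 17 significant digits.
* Seeds: a master `SeedSequence` spawns independent child streams for the
  population structure, the manifest, and each subject, so cohorts are
  reproducible and subjects independent.

## Problem sizes in the shipped analyses

The `analysis/` scripts and the acceptance script run on reduced cohorts
(20–30 regions, 90–200 subjects, 500–1000 permutations) — sizes chosen so
the complete sequence reruns in a few minutes while keeping every
statistical property measurable; the generator defaults reproduce the full
90-region, 233-subject composition when more compute is available.
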