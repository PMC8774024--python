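# Methods

This note documents the models, conventions and numerical choices behind
`connkit`, the parameters that matter, and what the synthetic cohorts do and
do not establish about real data.

## Data model

The unit of analysis is a cohort: subjects × groups × weightings over one
atlas. The packaged atlas holds 28 bilateral motor-sensory subregions
(precentral, postcentral, paracentral, and medial/dorsolateral premotor
areas, Brainnetome-style labels). Six left-hemisphere regions are flagged as
tumor-invaded by default, leaving 22 retained nodes; the exact membership of
the excluded set in the motivating study is not public, so the packaged list
is a documented stand-in chosen so that every node that appears in reported
group differences (A6m, A4t, A4ul, A4ll, A123tru, A123ulhf, A4hf) is
retained. Excluded nodes never appear in any matrix or metric.

Matrices are CSV/TSV with a node-id header row and column; rows are
reindexed to atlas order on read. Asymmetry up to a relative 1e-6 is
averaged away; larger asymmetry is rejected as file corruption, because
tractography connectomes are symmetric by construction. FA entries must lie
in [0, 1]; all weights must be nonnegative with a zero diagonal.

## Backbone thresholding

Edge (i, j) survives iff the fraction of subjects with a nonzero FN entry is
*strictly greater* than the threshold (default 0.75). Presence is judged on
FN because the streamline count is the primitive observation from which the
other weightings derive; the strict reading follows the usual phrasing
"above 75%". Both choices, and pooled- vs per-group scope, are flags. One
mask per study is applied to all four weightings of every subject, so group
comparisons always address the same edge set.

## Distances and metrics

* Edge length = 1/weight for FA, FN and FL alike (reciprocal-strength, the
  dominant connectome convention); binary edges get unit length. Treating FL
  as a cost directly (longer tract = longer step) is available via
  `edge_lengths(..., fl_as_cost=True)` for sensitivity analyses.
* Shortest paths are computed with Dijkstra (scipy csgraph); a dense
  Floyd–Warshall implementation is kept in the package purely as an
  independent oracle for testing.
* Disconnected pairs contribute 0 to efficiency sums; the characteristic
  path length averages *reachable* pairs only and reports the unreachable
  fraction alongside, keeping both metrics finite and comparable across
  subjects whose backbones disconnect. A harmonic-mean mode (the reciprocal
  of global efficiency) is available as an alternative.
* Degree centrality in weighted networks is node strength (summed incident
  weights); binary networks use the edge count.
* Clustering uses binary triangle density and the Onnela geometric-mean form
  for weighted graphs (weights scaled by the maximum); nodes of degree < 2
  get 0. Local efficiency of a node is the global efficiency of the subgraph
  induced on its neighbours.
* Betweenness shares equal-length path multiplicity fractionally
  (Brandes, via networkx) and is normalized by (N−1)(N−2)/2.

## Small-world null models

Gamma, lambda and sigma = gamma/lambda are computed against degree-preserving
Maslov–Sneppen double-edge-swap nulls: 10 attempted swaps per edge, 100 null
networks by default, weights travelling with the rewired edges so the weight
distribution is preserved exactly. Each null's path length uses the
reachable-pair mean, so an occasionally disconnected null contributes a
finite value rather than destroying the average. All rewiring is
deterministic under a seed.

## Network-based statistic

Per-edge one-way F statistics are computed on the backbone edge values; the
component-forming threshold is the F(k−1, n−k) upper quantile at a primary
alpha of 0.01 (a flag — the choice is conventional, not canonical).
Suprathreshold edges form connected components scored by extent (edge count)
by default, or intensity (summed excess F). Group labels are permuted
preserving group sizes; each permutation contributes its maximal component
score; observed components receive the add-one estimator
p = (1 + #{null ≥ obs}) / (n_perm + 1), so p is never zero and is bounded
below by 1/(n_perm+1). The permutation sweep exploits the fact that the
total sum of squares per edge is permutation-invariant, so each permutation
costs only group sums; 5000 permutations over ~100 edges take well under a
second. Edges with between-group spread but zero within-group variance get
a large sentinel F and are flagged rather than producing infinities.

## Group statistics on topological properties

Properties are z-scored across the pooled subjects per (property, weighting,
node) before ANOVA, so that group comparisons are on a common scale across
weightings. A sample SD smaller than 1e-12 of the largest value is treated
as zero variance (the input is constant up to float rounding) and flagged
instead of amplifying rounding noise. FDR families are the nodes within one
(property, weighting) pair — matching the per-weighting corrected thresholds
reported in this literature — and the family definition is configurable.
Post-hoc tests are uncorrected pairwise Welch t on the z-scores: Welch is
robust to the small, possibly unequal-variance groups; Tukey-type
alternatives were considered but the uncorrected pairwise convention matches
how post-hoc columns are reported in the motivating tables.

Demographics helpers operate on printed summaries: the unpaired t-test uses
t = (m₁−m₂)/√(se₁²+se₂²) with df = n₁+n₂−2, and the Fisher exact test
enumerates every 2×2 or 2×3 table with the observed margins, summing the
hypergeometric point probabilities not exceeding the observed one
(Freeman–Halton). On the 6/4, 5/5, 5/5 sex split this enumeration gives
exactly p = 1.0 (confirmed against R's `fisher.test`).

## Synthetic cohorts

The generator emulates the study conditions: three groups of n = 10, 22
retained nodes, four weightings sharing one binary support per subject
(deterministic tractography derives all weights from a single streamline
set).

* **Template.** Hub nodes (A6m_L, A6m_R) connect to ≥ 80% of other nodes;
  homotopic left/right pairs are always connected; other pairs are present
  with probability `edge_density` = 0.35; the template is redrawn until
  connected. Edge weights: FN lognormal (log-mean 4.0, log-sd 0.8, median
  ≈ 55 streamlines); FA truncated normal, mean 0.5, sd 0.1 on (0.2, 0.8)
  (the lower bound mirrors the usual tractography FA threshold); FL
  truncated normal, mean 60 mm, sd 15.
* **Subjects.** Template × i.i.d. multiplicative lognormal noise per edge
  per weighting (sd 0.05), FA clipped back into (0.2, 0.8) before effects.
* **Planted edge effects** are multiplicative reductions (multiplier 0.6 by
  default): FA at A6m_L–A6m_R in Ep only; FN at A123tru_L–A4ul_L and
  A123tru_R–A4t_R in both patient groups. Multiplicative effects keep FA in
  range and encode the reduced-connectivity directionality without
  inventing units. 0.6 yields power ≈ 0.8–0.9 at n = 10 under the default
  noise.
* **Hub dropout** deletes each hub-incident, non-homotopic support edge from
  a patient subject with probability 0.30 (Ep) or 0.15 (nEp). This is the
  mechanism that degrades binary as well as weighted global/nodal
  efficiency and hub degree centrality with the Ep < nEp < con ordering;
  edge-level multipliers alone cannot touch the binary support. Homotopic
  pairs are spared so the interhemispheric SMA connection weakens rather
  than vanishes, keeping it inside the consistency backbone.
* **Null cohorts** strip all effects and dropout; groups then differ only by
  label, which is the ground truth for the type-I-error suites.

What the generator does **not** model: spatial autocorrelation of edge noise,
tumor mass-effect deformation, distance-dependent connection probability,
correlated weightings beyond the shared support, or any biophysics of
diffusion. Passing tests therefore establish the correctness and calibration
of the *statistical machinery* under study-shaped conditions, not the
generalizability of any clinical finding.

## Problem sizes and determinism

Simulation-based checks use: 200 label-only cohorts × 500 permutations for
NBS family-wise error (observed rejection ≈ 0.5–2% at α = 0.05); 200
label-only cohorts for FDR family control (observed ≪ 5%); 50 planted
cohorts × 1000 permutations for recovery rates. These sizes put the
Monte-Carlo standard error of each rate near or below 0.02 while keeping a
full acceptance run around half a minute on one CPU.

Every stochastic stage takes an explicit seed; the pipeline derives stage
seeds from one master seed via `SeedSequence([master, stage_index])` with a
fixed stage numbering, so stages can be rerun in isolation. Identical
config + seed reproduces byte-identical output files.

## Known limitations

* The 28-subregion membership and the 6 excluded nodes are stand-ins (see
  Data model); real atlases should be supplied as JSON when available.
* The NBS assumes exchangeability of subjects under the null; no covariate
  adjustment (GLM-based NBS) is provided.
* Weighted local efficiency inherits the reciprocal-length convention of the
  global metric; other conventions exist and would change absolute values
  (not group contrasts) of that metric.
* The extent component statistic has limited power for strong effects
  confined to one or two edges; the intensity statistic is available where
  that regime is expected.
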