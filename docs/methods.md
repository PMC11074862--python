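# Methods

`diffconn` implements a case–control resting-state connectome analysis:
functional-connectivity (FC) network construction, covariate-adjusted
differential-edge selection, graph-neural-network classification with
self-attention pooling, and model interpretation. Everything runs on a
bundled synthetic-cohort generator, so the full pipeline is testable
without any imaging data.

## Functional connectivity

Each subject contributes an ROI × time matrix (default 116 AAL regions,
~150 retained volumes). FC is the sample Pearson correlation between
region time courses, variance-stabilized with the Fisher transform
z = atanh(r). Self-connections carry no information, so the diagonal is
fixed at 0 rather than atanh(1) = ∞. Degenerate inputs (constant
series, |r| = 1 off-diagonal, fewer than 3 time points) raise errors
naming the offending region. Binarization supports an absolute |z|
cutoff, a proportional density rule (exact edge count, ties broken
lexicographically for determinism), and a differential-edge mask — the
mask rule is the default route into classification because the
analysis' discriminative input is the differential network.

## Differential-edge selection

For every ROI pair the subjects' z values are residualized by OLS on
nuisance covariates — age, sex, handedness, acquisition site (one-hot,
reference = first site alphabetically) and six motion parameters — with
the group label never in the design, then compared between groups with
a pooled-variance two-sample t-test (Welch and a one-step joint model
with a group term are config alternatives). Each edge records the
direction of the difference and both the smaller one-sided tail
(`p_tail`) and the two-sided `p_value`; selection thresholds the
two-sided p. Thresholding the smaller tail directly would double the
null selection rate (either tail can fire), whereas the two-sided rule
with direction recorded is equivalent to running the two one-sided
families at α/2 each and keeps the overall null rejection rate at its
nominal level — which the calibration tests check. No dof adjustment is
applied for the residualization step: projecting out q covariate
dimensions slightly deflates the pooled variance (anticonservative) but
also absorbs the chance overlap between the group contrast and the
covariate space (conservative); at n ≫ q the two effects cancel almost
exactly, and simulation confirms the unadjusted test is closest to
nominal. A sweep over thresholds 0.005–0.05 (step 0.005) yields nested
edge sets with directional counts.

No multiple-testing correction is applied at selection: the threshold
on raw p is a feature-screening device, not an inference. The
exploratory correlation analyses (below) are likewise uncorrected by
default, with Benjamini–Hochberg FDR available.

## Graph construction

All subjects share one topology — the binary differential-edge mask —
so graphs differ only in node features. Node i's feature vector
(length = ROI count) is row i of the subject's masked Fisher-Z matrix:
its own selected-edge values, zeros elsewhere. Two alternatives are
configurable: "incident" (row restricted to columns of any ROI incident
to a selected edge) and "full" (unmasked row). The default was chosen
by measurement: with hundreds of selected edges the incident set covers
nearly all regions, so incident masking leaves ~13k mostly-noise
feature entries per subject and a linear probe on node-averaged
versions of those features classifies at chance; restricting each node
to its own differential connections preserves the signal entries with
far less noise and is an equally direct reading of "differential
connectivity as node features". Batches are standard disjoint unions
with node indices offset per graph; unbatching is an exact inverse.

## Classifier

The propagation rule is the Chebyshev-K=1 renormalized graph
convolution H⁽ˡ⁺¹⁾ = σ(D̃^{-1/2}(A+I)D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾) with ReLU; the
spectral derivation motivates it but no eigendecomposition is ever
performed. Self-attention pooling scores each node by a single-channel
graph convolution of the current features squashed with tanh, keeps the
top ⌈0.35·N⌉ nodes (ties → lower index, so 41 of 116, then 15 of 41)
and multiplies kept features by their scores. Fixed study settings:
channels (32, 16), pooling ratio 0.35, ReLU, learning rate 0.034,
weight decay 5e-5. Package choices (unspecified by the study design):
softmax cross-entropy loss; Adam with a 10% linear learning-rate
warmup (a cold start at lr 0.034 can kill every ReLU unit on some
initializations; training that still collapses to a constant predictor
is deterministically re-initialized from a shifted seed, at most
twice); epochs 300 and batch size 32 by default (reduced in tests and
the acceptance script to fit their problem sizes); Glorot
initialization.

The readout scatters retained node features back into fixed ROI slots
and flattens them before the linear head. This identity-preserving
readout is deliberate: connectome group differences are mean shifts in
specific (region, connection) entries, and mean/max readouts over nodes
— offered as config options — destroy exactly that structure (a
logistic probe on node-averaged features of planted-effect cohorts
performs at chance while the same probe on identity-preserving features
exceeds 0.9 accuracy).

The network is plain NumPy with hand-written, fully vectorized
forward/backward passes (verified against finite differences to 1e-10
and against an independent per-graph reimplementation). Exact input
gradients double as the saliency signal for attribution. Baselines
behind the same evaluation interface: the identical GCN without
attention pooling, and an RBF-kernel SVM on flattened selected-edge z
values.

## Evaluation

Two cross-validation schemes: site-stratified k-fold (subjects of each
site dealt evenly across folds, so every fold mirrors the site mix) and
leave-one-site-out (train on the other sites, test on the held-out
site). Sensitivity, specificity and accuracy are computed per fold in
percent and aggregated as mean ± SD; a fold lacking a class reports the
undefined metric as missing with a warning. By default the edge mask is
re-estimated on each fold's training subjects only, so held-out
subjects never influence residualization, the t-tests or training;
whole-cohort selection is available behind a flag for protocol
comparison. A p-threshold sweep produces accuracy-vs-p curves, and a
label-permutation null (full re-selection per shuffle) provides a
chance reference; because a chance-level classifier's accuracy
distribution does not depend on fold count or training length, the null
uses 3-fold CV at reduced epochs with whole-cohort selection, which is
two orders of magnitude cheaper than repeating the full protocol.

## Interpretation

Node contributions: for each fold's trained model and its correctly
classified held-out subjects, the absolute gradient of the
case-minus-control logit margin with respect to both feature entries of
every selected edge is averaged, summed over each node's incident
edges, and normalized to percentages (sum = 100). Nodes above 2% are
flagged. A literal second mode sums absolute first-layer weights
weighted by pooling-retention frequency. If every importance is zero
(e.g. a head that ignores its input) the table falls back to uniform by
documented convention.

Inattention correlation (case group only): per subject and node, |z| of
incident selected edges is summed separately for the case>control and
case<control directions — so strengthened and weakened connections
cannot cancel — and each directional sum is Pearson-correlated
(Spearman optional) with the inattention score; edge-level correlations
use the signed z. Significance is uncorrected p < 0.05 by default
(exploratory screening), FDR optional. The discriminative-region
intersection reports nodes that both exceed the contribution threshold
and correlate with inattention, tagged with correlation sign and
direction class. BrainNet-Viewer-style `.node`/`.edge` exports are
provided; shipped node coordinates are synthetic stand-ins (real MNI
centroids can be passed in).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:
~460 subjects across 4 sites (configurable proportions), 116 ROIs, 150
retained volumes, balanced groups. Each subject's series are drawn from
a zero-mean Gaussian whose correlation matrix is the inverse-Fisher-Z
of a per-subject target Z-matrix, so empirical FC matches the target in
expectation. The background is a random Wishart-factor correlation
mixture a·C₀ + r̄·J + 0.1·I with off-diagonal mean ≈ 0.2 and SD ≈ 0.1
in z units (weak positive background connectivity): positive definite
by construction with a 0.1 eigenvalue cushion. An i.i.d. background of
the same strength would be far from PD and the necessary projection
would distort every edge; with the factor construction the safety
projection (eigenvalue clipping + unit-diagonal rescale) is a no-op in
the common case. Onto this, per subject: a site offset on all edges
(default ±0.05 z), covariate slopes on all edges (configurable), and —
for cases only — the planted edge effects Δz plus a per-case latent
severity (SD `subject_sd`, default 0.15, shared across the subject's
planted edges). Dense planted hub stars can still exceed the PD
cushion, in which case the projection attenuates them; ground truth
(per-subject realized planted strength) is therefore always computed
from the realized, post-projection network.

The inattention score exists for cases only (missing for controls) and
equals 18 + coupling × realized planted strength + Gaussian noise, on a
clinically plausible rating-scale footing. `calibrate_attention_noise`
solves for the noise SD that makes the true correlation between a hub's
measured directional strength and the score equal a chosen target,
using the generator's own realized strengths and the per-edge
measurement variance 1/(T−3). The default planted layout
(`hub_planted_edges`) concentrates effects on a few hub regions, as
case–control connectome differences typically cluster on hubs rather
than scattering uniformly.

What the generator does not emulate: temporal autocorrelation and
physiological noise structure, scanner-specific covariance (site
effects are additive shifts only), heavy-tailed motion artifacts,
missing data, and diagnosis-covariate correlation. Passing tests
therefore demonstrate correctness of the statistical machinery under a
faithful idealization, not performance on real multi-site fMRI.

## Numerical and protocol choices

- Problem sizes: tests and the acceptance script use cohorts of 80–400
  subjects, 40–116 ROIs and 15–80 training epochs — sizes at which each
  check's statistic is stable.
- Determinism: every stochastic step (generation, fold shuffling,
  initialization, batching, restarts, permutations) is driven by
  explicit seeds; identical configs give bit-identical outputs.
- Ties: density binarization and top-k pooling break ties toward the
  lexicographically first edge / lowest node index.
- Degenerate inputs raise informative errors (empty masks suggest a
  larger p; collinear designs name the offending columns; missing
  covariates name the subject).

## Known limitations

- Subjects must share the ROI set and the mask-defined topology;
  per-subject topologies are out of scope by design.
- The NumPy network targets ~10²-subject cohorts on one CPU; it has no
  GPU path and no hyperparameter search.
- The two-step residualize-then-test procedure is standard practice but
  not exactly equivalent to the joint model at small n; both are
  provided.
- Attribution is gradient saliency — a local explanation that inherits
  the classifier's biases; planted-hub recovery is verified on
  synthetic cohorts only.
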