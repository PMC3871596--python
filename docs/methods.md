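# Methods

This note documents the models, defaults and numerical choices behind
`fisonmf`, and what the synthetic benchmark does and does not establish.

## Data model

Spectra live on a fixed chemical-shift axis — by default 195 points spanning
[4.24, 0.50] ppm, descending, the clinically relevant window for in-vivo
brain ¹H-MRS — and are stored as a `d × n` matrix (frequencies × cases)
with per-case class labels and an echo-time tag (STE ≈ 20–32 ms,
LTE ≈ 135–144 ms).  Every case is scaled to unit Euclidean norm (UL2).
Normalization is applied after any windowing to the axis; the axis itself is
metadata and no resampling or interpolation is performed.  Unlabeled columns
are accepted everywhere except where a posterior model must be fitted.

## Synthetic cohorts

Real multi-center SV-MRS databases are not redistributable, so the
generator produces cohorts with matched structure and full ground truth.
Two constituent tissue signatures are built from Gaussian metabolite peaks:

* *proliferating* — total choline 3.21 ppm (dominant), myo-inositol/glycine
  3.55, creatine 3.03/3.93, residual NAA 2.01, faint lipids;
* *necrotic* — mobile lipids 1.29/0.90 ppm (dominant), a lactate doublet at
  1.31/1.36, residual choline and creatine.

At long echo time the short-T2 lipid amplitudes are reduced (×0.35) and the
J-modulated lactate doublet is inverted (amplitude −0.9), reproducing the
negative peaks of real LTE spectra; short-TE signatures are element-wise
non-negative.  Gaussian lineshapes are the default (Lorentzian available);
the aim is qualitative fidelity of peak positions and sign patterns, not
physical MR simulation — no relaxation, J-coupling evolution or phasing is
modeled.

Each class archetype is a Dirichlet distribution over the two constituents:

| class | Dirichlet α (proliferating, necrotic) | character |
| --- | --- | --- |
| A2 (low-grade astrocytoma-like) | (27, 3) | homogeneous, proliferating |
| GL (glioblastoma-like) | (4, 6) | heterogeneous mixture |
| ME (metastasis-like) | (3, 17) | dominantly necrotic |

A case is drawn by sampling constituent weights from its class's Dirichlet,
mixing the signatures, adding i.i.d. Gaussian noise of standard deviation
`noise_sd` (default 0.01 on unit-norm spectra ≈ a few percent of the tallest
peak) *before* UL2 normalization, so normalization acts as on real data.
The concentrations were chosen once so that `overlap = 0` gives clearly
separated classes while the GL archetype stays visibly heterogeneous; the
`overlap ∈ [0, 1]` control pulls every class's mean composition toward the
average of the others, driving the class-mean correlation toward ≳0.99 at
`overlap = 0.6` — the regime emulating the near-indistinguishable
aggressive-tumor pair.  Outlier injection reverses the constituent weights
of a chosen fraction of one class while keeping labels, mimicking, e.g.,
non-necrotic glioblastomas that resemble low-grade tumors.  Default class
sizes (22/86/38 at STE, 20/78/31 at LTE) mirror the cohort sizes of the
motivating clinical problem so table-shaped outputs are comparable.

What passing tests on these cohorts do **not** show: robustness to baseline
or phasing artifacts, chemical-shift misregistration, non-Gaussian noise,
scanner batch effects, or metabolite patterns outside the two-constituent
model.

## Posterior model

`MLPPosterior` is a single-hidden-layer network (default 8 tanh units,
softmax output) trained by deterministic full-batch gradient descent on the
cross-entropy with L2 weight decay (default 1e-3).  The step size adapts by
back-tracking: a step is accepted only if the training loss does not
increase, so the recorded loss curve is monotone.  When a holdout set is
supplied (the pipeline uses a stratified 2/3–1/3 split), training keeps the
best-holdout-loss weights and stops after 50 stale epochs; holdout accuracy
is recorded.  Seeds control only the weight initialization.  The
deliberately small, smooth architecture keeps the induced metric
well-conditioned; no deep variants, GPU paths or post-hoc calibration are
provided.  Gradients of the log-posteriors with respect to the *input* are
computed analytically (closed-form backpropagation through the two layers)
and are finite-difference-checked in the tests.

## Fisher metric and geodesic graph

The local metric is `J(x) = Σ_c p(c|x) g_c(x) g_c(x)ᵀ + ε I` with
`g_c = ∇_x log p(c|x)`.  With two classes the first term has rank one, so a
ridge `ε` (default 1e-6 × the mean diagonal of `J` over the training
points) keeps the metric positive definite.  The distance between nearby
points is `√(Δxᵀ J(m) Δx)` with `J` at the segment midpoint — symmetric in
the endpoints and second-order accurate for the geodesic path integral.
Edge weights sum this midpoint rule over `subdivisions` (default 4) equal
pieces of the straight chord; doubling the subdivision count changes edge
weights by <2% on smooth posterior fields.  Pairwise geodesic distances are
shortest paths on a symmetric k-NN graph (default k = 10, neighborhoods by
chord length) unioned with the minimum spanning tree of the chord-length
matrix, which guarantees connectivity; exact geodesic solvers and curvature
computations are out of scope.  A new point is attached to its k nearest
training points by chord length; its distance to training point `j` is
`min_a (w(new, a) + D[a, j])`.  Attaching one-sidedly leaves the training
distances untouched, which is what the fixed-source test protocol requires;
it is *not* identical to rebuilding the graph with the point included
(which would also rewire its neighbors).  All distances are computed in the
UL2-normalized space the classifier was trained in.

## Embeddings

All three embeddings start from classical (Torgerson) MDS of the Fisher
distance matrix, making the stage deterministic.  Latent dimensionality
defaults to `max(2, C)` for `C` classes and is overridable; the achieved
stress is recorded so users can audit adequacy.

* **Sammon** minimizes `E = (Σd_ij)⁻¹ Σ (d_ij − δ_ij)²/d_ij` by gradient
  descent with step halving (accepted iterates never increase `E`).
  Duplicate points (zero off-diagonal distance) are merged before
  optimization and share coordinates afterwards.
* **SMACOF metric MDS** minimizes raw stress `Σ (d_ij − δ_ij)²` by the
  Guttman transform; each majorization iterate provably does not increase
  the stress.
* **IMA** constrains the configuration to `Y = Φ V`, where
  `Φ_ij = exp(−d_F(x_i, c_j)²/(2σ²))` over basis centers (default: all
  training points) with `σ` = the median off-diagonal Fisher distance, and
  minimizes the same raw stress over `V` by iterative majorization — each
  iteration solves one ridge-regularized (default 1e-8, auto-increased on
  singularity) least-squares subproblem.  The unweighted stress is the
  default; a `sammon_weighting` flag switches to 1/d weights.

Out of sample, IMA simply applies its parametric map to the new Fisher
distances; Sammon/MDS minimize the new point's own stress contribution with
training coordinates frozen, starting from its nearest training neighbor's
coordinates (L-BFGS, falling back to the start if no improvement).  A new
point duplicating a training point reproduces that point's coordinates.
Convergence for the iterative methods: relative stress change < 1e-7 or 500
iterations.  Nonmetric MDS and neighbor-embedding methods (t-SNE/UMAP) are
deliberately absent.

## Convex-NMF

`X ≈ X W H` with `W (n×k), H (k×n) ≥ 0`, optimized by the Ding–Li–Jordan
multiplicative updates driven by the positive/negative parts of `XᵀX`;
denominators are floored at 1e-12 against 0/0 (a finite-arithmetic
necessity).  Initialization clusters the cases with K-means (best of 10
seeded restarts) and smooths the one-hot indicator `G` as
`W0 = (G + 0.2E) Dn⁻¹`, `H0 = (G + 0.2E)ᵀ`.  The stopping rule is a
relative change of the Frobenius reconstruction error below 1e-5
(scale-invariant under UL2 data; an absolute mode is available), with
max_iter 2000.  The objective trace is recorded and is non-increasing; on
inputs admitting an exact factorization the updates approach it at a ~1/t
rate, because the multiplicative pressure on spurious weight entries decays
with the residual itself — near-exact recovery therefore needs a far larger
iteration budget than the default stopping rule uses.  Fixed-source
transforms for new data iterate the mixing-only update with `S = X_basis W`
held fixed (semi-NMF H-update), from a clipped ridge least-squares
initialization, reusing the fit's stopping rule.  Source rescaling
normalizes each source to unit norm and compensates the mixing matrix,
leaving the product unchanged; it is idempotent and flags zero-norm
sources.

**Latent-space gauge.**  A distance-preserving embedding fixes coordinates
only up to rotation and translation, while Convex-NMF is
translation-sensitive: on a mean-centered configuration whose class
clusters straddle the origin, the conic constraints are vacuous (any
interior mixture of the clusters spans the same cone) and the unmixing
matrix retains whatever class mixing its initialization carried.  The
pipeline therefore anchors the latent configuration before factorizing:
the cloud is translated into the positive orthant, offset from the origin
by its own coordinate range, so every case is a ray with a well-defined
angle and the cone constraints force sources toward the angular extremes —
the class clusters.  The same translation is applied to out-of-sample
embeddings.  With this gauge, the backprojected sources of all three
semi-supervised variants reach correlations ≈ 1.0 with the class means on
separated synthetic cohorts; without it, Sammon/MDS stall near the
initialization's class purity.

## Interpretation and scoring

Latent-space factorizations are carried back to the spectral domain as
`X_original W` (columns UL2-normalized).  Sources are assigned to classes
by maximizing total Pearson correlation with the class-mean spectra under
the constraint that every class receives a source whenever `k ≥ C`;
with `k ≤ 6` the optimum is found exhaustively.  A source anti-correlated
with every class mean is sign-flipped first (latent sign indeterminacy,
logged); a zero-variance source falls back to Euclidean proximity and is
flagged.  Cases take the class of the source with the largest mixing
weight (ties break to the lowest source index; all-zero columns fall back
to a declared class with a warning).  Reports carry per-class
(correct/total) counts, percentage accuracies, and
BER = mean over classes of the per-class error rate, which is invariant
to class imbalance.  No significance testing or ROC analysis is included.

## Pipelines and reproducibility

The unsupervised route factorizes the UL2 spectra directly; the
semi-supervised route runs split → posterior → geodesics (over *all*
training cases) → embedding → anchored Convex-NMF → backprojection, and
labels every training case.  Superclasses (e.g. aggressive = GL ∪ ME)
remap labels before the posterior fit.  Test cases flow through
fixed-source machinery only: geodesic extension, out-of-sample embedding,
mixing-only updates.  One master seed spawns independent per-stage seeds
(numpy `SeedSequence`), so the four approaches consume identical training
matrices and identical K-means streams and differ only in their declared
stages; reruns are bit-reproducible.

The bundled benchmark (`scripts/acceptance.py` and the test suite) uses a
60-case clean cohort (22 + 38) and a 124-case high-overlap cohort
(86 + 38), sizes chosen to mirror the motivating cohorts while keeping a
full multi-seed sweep fast on one CPU.

## Known limitations

* The Fisher metric saturates on cleanly separable cohorts (posteriors
  near 0/1 make within-class distances collapse); the geodesic graph and
  the gauge anchoring keep the pipeline well-behaved there, but latent
  within-class structure is essentially discarded in that regime.
* Convex-NMF converges to local minima; K-means restarts mitigate but do
  not remove initialization dependence, and near-exact factorizations are
  approached only at a ~1/t rate.
* The source-count choice (k = 2 or 3) is user-specified; no model
  selection for k is provided.
* The constrained source/class matching assumes at most six sources.
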