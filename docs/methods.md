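# Methods

`microtraj` reconstructs a latent "landscape" of chronic-disease progression
from cross-sectional microbiome samples. The premise: each static sample is a
snapshot of a slow process, and with enough samples their footprints populate
the progression trajectories, which can then be recovered geometrically. The
pipeline is: select disease-related taxa, cluster samples into community
states, fit a principal tree, root it at the healthy states, read pseudo-time
off the rooted paths, and run downstream association, diversity and
interaction analyses on the pseudo-time ordering.

## Preprocessing

Counts are validated (features x samples, non-negative integers, ids unique,
every sample covered by metadata), samples with fewer than `min_reads`
(default 10^4) reads are dropped (strict `<`, so a sample at exactly the
threshold is kept), counts are closed to relative abundances, and a transform
is applied: `log10(rel + 1e-6)` by default, or CLR (`ln(rel + pseudo)` minus
the per-sample mean) for compositionally-aware runs. The 10^-6 pseudo-count
is reused for CLR unless overridden. No prevalence filter is applied by
default.

## Margin-based feature selection

For a labelled sample, the *margin* is the weighted-Manhattan distance to its
nearest miss (closest other-class sample) minus the distance to its nearest
hit. Because the true neighbours depend on the unknown feature weights, each
candidate neighbour receives an Epanechnikov-kernel probability,
`K(d) = 0.75 (1 - (d/b)^2)` for `d <= b`, with the bandwidth `b` set to the
distance to the (k+1)-th nearest member of the candidate set (k = 10;
for smaller sets, the farthest member plus machine epsilon). Miss
probabilities normalise over all other-class samples, hit probabilities over
same-class samples excluding self; when the kernel mass degenerates (all
candidates at the bandwidth) the mass falls back to a uniform distribution
over the k nearest, ties included. The expected margin components
`zbar_n` are then the probability-weighted absolute-difference sums, and the
weights solve

    min_{w >= 0}  sum_n log(1 + exp(-w' zbar_n)) + lambda ||w||_1

by proximal gradient with backtracking (non-negativity and l1 handled in the
prox). Multiclass data use the natural nearest-miss-of-any-other-class
formulation; merging phenotype labels (e.g. the two late-stage behaviours)
is a caller decision.

The alternation between neighbour probabilities and weights is *not* a joint
descent: the probability update is a kernel re-estimate, not a minimisation,
so the objective can rise when the context is recomputed (we observed
sustained oscillation on mean-shift fixtures). We therefore track the
penalised loss at each iterate's own neighbour context and apply a monotone
acceptance rule: an iterate that raises this self-consistent objective is
rejected and iteration stops, returning the previous iterate. In practice
the loop ends after the first few refinements, at the iterate with the best
self-consistent loss, and the recorded loss trace is non-increasing by
construction.

The penalty is tuned by repeated stratified cross-validation (10 folds, 3
repeats) scored by the held-out error of a 1-nearest-neighbour rule in the
learned weighted metric. Two safeguards stabilise the noisy error curve: if
the best error is within 2 SE of the majority-class chance level, the data
carry no detectable signal and the largest grid penalty is returned (so
pure-noise inputs select nothing); otherwise the one-standard-error rule
returns the sparsest penalty statistically indistinguishable from the best.
Features with weight above the 0.001 cutoff are selected.

## Clustering

k-means (k-means++ starts, best of 50 restarts) on the selected-feature
space. The number of clusters comes from the gap statistic with uniform
reference sets drawn over the PCA-aligned bounding box (B = 50), choosing
the smallest k with `gap(k) >= gap(k+1) - se(k+1)`. Stability comes from
resampling consensus: 1000 k-means runs on random 80% subsamples, aggregated
into a consensus matrix (co-clustering count over co-sampling count; pairs
never co-sampled are flagged and imputed 0), with final labels from an
average-linkage cut of `1 - consensus` at k. Per-sample silhouette widths on
Euclidean distances validate the partition.

## Principal tree

The trajectory model is a reversed graph embedding: an orthonormal map
`W (D x d)` connects a d-dimensional latent space (d = 3) to the feature
space, latent sample positions `Y` are softly assigned to latent tree nodes
`Z` (one node per sample), and the tree is a minimum spanning tree over `Z`
whose total squared edge length is penalised:

    sum_n ||x_n - W y_n||^2  +  (lambda/2) sum_ij b_ij ||z_i - z_j||^2
      +  gamma sum_ij p_ij ( ||y_i - z_j||^2 + sigma log p_ij )

with gamma = 2 fixed. Optimisation alternates exact block updates — (W, Y)
by a Procrustes/ridge pair, Z by the Laplacian-regularised linear solve
`Z (lambda L + gamma diag(P'1)) = gamma Y P`, P by row-softmax of
`-||y_i - z_j||^2 / sigma` (log-sum-exp guarded), and edges by Kruskal's
algorithm on squared latent distances with deterministic (cost, index)
tie-breaking — so the objective is non-increasing; iteration stops at
relative change < 1e-5 or 100 iterations. Initialisation is the top-d PCA
scores for both Y and Z.

`sigma` and `lambda` are tuned per dataset by the elbow (maximum discrete
second difference of the final objective over a log-spaced grid, sigma first,
then lambda). The module-level defaults (0.5, 150) are the elbow values for
the original gut-cohort data scale; the pipeline default is `auto` (tune on
the data at hand).

Because every sample contributes a tree node, the raw MST carries hair-like
micro-branches. Topology queries (leaf counting, branch membership) first
prune leaf twigs holding fewer than 2% of nodes (minimum 2), folding their
nodes onto the attachment point; populated branches are never pruned.
Branches are the backbone segments between junctions and leaves.

## Progression model and pseudo-time

Cluster centroids (latent means) are projected to their closest points on
the piecewise-linear tree. The cluster graph connects centroids that are
adjacent along the tree; this is realised as the MST of the centroid
curve-distance matrix, which coincides with consecutive-adjacency when
centroids lie along a path and resolves the degenerate cycles that arise
when no centroid sits exactly on a junction. Curve distance is arc length
along the piecewise-linear tree.

Origins are the healthy-dominated extremes: clusters with an HC-sample
majority that are leaves of the HC-induced subgraph (an HC cluster wedged
between other HC clusters is a way-station). One progression path runs from
each origin to each non-origin leaf; two healthy community types and two
disease endpoints give four paths. Samples are projected onto each path's
polyline; pseudo-time is the curve distance from the origin, after per-edge
branch scaling. Scaling is a general per-edge factor (default 1); a helper
computes the factor that equalises the two origin branches so progression
distance is independent of the origin used (the role the constant 1.66
plays for the original cohort), and the pipeline applies it by default when
exactly two origins exist. Per-subject variability is summarised as
1.5 x MAD of progression distances, restricted to subjects with at least 5
serial samples.

## Path association

For each path, every feature's |Spearman rho| (average ranks on ties)
against the pseudo-time order is compared with a permutation null built by
reshuffling the sample order jointly for all features (preserving the
between-feature correlation). The estimated FDR at threshold t is the mean
null exceedance count divided by the observed exceedance count; the largest
rejection set with estimated FDR below target (0.01) is kept, then filtered
by mean relative abundance >= 0.001 (computed on untransformed proportions
over the path's samples) and |rho| >= 0.3. Filters come after the FDR step,
which is conservative for the FDR denominator. Defaults: 1000 permutations;
permutations are of the within-path order.

## Alpha diversity

Bias-corrected Chao1 `S_obs + F1(F1-1)/(2(F2+1))` (defined even without
doubletons) and Shannon entropy in natural log. Rarefaction draws
multivariate-hypergeometric subsamples (without replacement) at depth 10^4,
1000 repetitions, and reports the mean.

## Lotka-Volterra interaction networks

On a pseudo-time-ordered series the gLV model
`dx_i/dt = x_i (alpha_i + sum_j beta_ij x_j)` is linear in the parameters
after dividing by `x_i`. Estimation is two-step: cubic smoothing splines of
`ln x_i(t)` (floored at the 1e-6 pseudo-count; smoothing by GCV) give
gradients on a 100-point uniform grid; each species' gradient is then
regressed on the smoothed abundances under ecological sign constraints
(`alpha_i > 0`, `beta_ii < 0`, enforced at 1e-6) with an l1 penalty on
off-diagonal interactions — a sign-constrained sparse regression standing in
for a Bayesian adaptive-lasso sampler. Each equation warm-starts from the
box-clipped least-squares solution (the design is strongly collinear, so a
cold proximal start converges too slowly). The penalty is chosen by 5-fold
CV over the grid 10^-3..10^1 on held-out gradient prediction error. The
directed network draws an edge j -> i for `|beta_ij|` above a threshold
(default 10% of the largest off-diagonal magnitude); node influence is
out-degree, and nodes with out-degree above 10 carry the annotation flag.
Every network run logs a compositionality caveat: relative abundances can
induce artificial links.

## Synthetic cohorts

The trajectory generator emulates the cohort structure the pipeline assumes:
~50 subjects each holding a short run of consecutive latent-time samples,
balanced across the four origin/endpoint arms; a double-bifurcating latent
trajectory (two healthy community types merging at latent time 0.25-0.32
into a common dysbiotic trunk that splits at 0.6-0.67 into two disease
endpoints); group labels HC / B1 / B2-or-B3 by latent-time thresholds.
Informative taxa split into three roles: trunk markers follow a logistic
trend in latent time, and origin/endpoint markers switch on only in their
arm (both at log-scale amplitude 2.5, separately configurable via
`branch_effect`). Arm markers necessarily carry weaker class signal than
trunk markers — origin markers do not separate the HC/B1/late classes at
all, and endpoint markers lose half their contrast to the B2+B3 merge — so
the recovered arms are thinner than the trunk after feature selection; this
is a property of the emulated design, not a generator artifact. All other
taxa are i.i.d.
log-normal noise (sd 0.3 on top of baseline spread 1.0). Intensities are
closed by softmax and converted to integer counts by multinomial draws at
depth 2x10^4, making every fixture compositional and filter-compatible.
Ground truth (latent time, arm, geometric segment, informative set) is
returned alongside.

What the generator does not emulate: phylogenetic correlation among taxa,
overdispersion beyond multinomial sampling, batch effects, varying
sequencing depth, and real enterotype taxonomy. Passing tests therefore
demonstrate recovery of the assumed geometric structure under compositional
noise, not performance on real cohorts.

The classification generator produces the 3-class mean-shift datasets used
for the selector (class c shifts informative features by `c * shift`), and
the gLV simulator integrates the ODE with an adaptive Runge-Kutta method
(divergence raises, naming the unstable species) plus optional multiplicative
log-normal noise.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; the pipeline fans one global
seed out to per-stage seeds by stable hashing, so stages are independently
reproducible and a rerun under the same seed is byte-identical. Default
study sizes for the bundled experiments: cohorts of 300 samples x 100
features (30 informative), selector fixtures of 150 x 200 (10 informative),
3-species interaction systems sampled at 80 transient-rich time points, and
consensus/permutation replicates of 200-1000. These sizes were chosen so the
geometric and statistical structure is well-resolved at desk scale.

## Known limitations

- Compositionality is not modelled in the default pipeline (the CLR option
  exists); interaction networks in particular can carry artificial links.
- The principal tree uses a linear map W; strongly curved manifolds may need
  more latent dimensions than 3.
- The monotone acceptance rule for the selector stops at a local refinement;
  it does not search for a global optimum of the (nonconvex) margin loss.
- Pseudo-time is ordinal; it is not calibrated to calendar time.
- The origin-equalising branch scale is an interpretation of the original
  procedure (the derivation of the published constant is not specified).
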