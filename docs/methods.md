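# Methods

## The centrality

The node-influence centrality of node $v_i$ is the limit, as the walk
length $k$ grows, of the share of $k$-walks ending at an arbitrary
node that start at $v_i$. Because $A = P D P^{\top}$ for a symmetric
weight matrix, $A^k = P D^k P^{\top}$, and dividing numerator and
denominator of the walk ratio by $\lambda_{\max}^k$ kills every
eigendirection except the leading one; the limit is the normalized
Perron eigenvector component. The implementation therefore treats the
eigendecomposition as the definition (`method="eigen"`) and keeps the
literal iterated-power route (`method="power_k"`, and
`walk_influence` / `walk_influence_trace`) for validation and
convergence diagnostics.

Assumptions and excluded cases:

- **Connected.** A disconnected graph has no single limit;
  `node_influence` raises `DisconnectedGraphError`.
- **Non-bipartite.** A bipartite spectrum is symmetric about zero, so
  $|\lambda_1| = |\lambda_N|$ and the ratio oscillates with the parity
  of $k$; `node_influence` raises `BipartiteGraphError`. Bipartiteness
  is decided by 2-coloring the unweighted support graph; any self-loop
  (an odd closed walk) breaks it.
- The `check_convergence` diagnostic never raises and reports
  connectivity, bipartiteness, the absolute spectral gap
  $|\lambda_1| - \max_{i>1}|\lambda_i|$ (which controls the
  convergence *rate*: the finite-$k$ ratio contracts like
  $(|\lambda_2|/|\lambda_1|)^k$), and the numerical multiplicity of
  the leading eigenvalue. A repeated leading root is handled by
  summing the eigenspace basis columns, and cannot occur for the
  connected graphs the classifier builds (Perron-Frobenius).

Numerical choices: the Perron sign is fixed by requiring a positive
sum; the accepted eigen-residual is $10^{-10}$ relative to
$\lambda_1$. For graphs that are *nearly* disconnected (very small
bandwidths), `eigh` can lose the sign of components many orders of
magnitude below the dominant block; the implementation then refines
with a power iteration started from a uniform positive vector, whose
iterates are nonnegative by construction. Intermediate matrix powers
in the walk routines are rescaled by their maximum entry only when
entries leave $[10^{-50}, 10^{50}]$ — the ratio is exactly invariant
to positive rescaling, and small-$k$ results on 0/1 adjacencies stay
exact.

Invariance properties (all tested): components sum to 1; the vector is
unchanged by $A \mapsto A + cI$ (eigenvectors are shift-invariant) and
by $A \mapsto cA$, $c>0$; graph automorphisms permute it accordingly.

## The classifiers

NIM1/NIM2 are transductive: the min-max normalization statistics, the
similarity graph, and the influence weights are all computed over the
union of training and test samples. Adding a test sample changes the
graph and hence every weight; there is no inductive (frozen-weight)
mode, since freezing would change the method. Consequences worth
knowing:

- Only training nodes *receive* weights in the class score, but test
  nodes shape those weights through the graph.
- With joint normalization and a fixed bandwidth, the graph over all
  $N$ samples does not depend on which single sample is held out, so
  LOOCV can compute the graph and influence vector once. That cached
  path is the default; the literal per-fold recomputation
  (`cache=False`) agrees with it (exactly in exact arithmetic; to
  ~$10^{-12}$ in floats, because reordering rows perturbs `eigh`), and
  the equality is a test.
- Two samples total (one train, one test) form $K_2$, which is
  bipartite: the pipeline legitimately refuses. Three or more distinct
  samples give a complete graph with an odd cycle, so the convergence
  precondition holds by construction.

Parameter glossary (all bandwidths in units of normalized feature
space, i.e. after each feature is mapped to $[0,1]$):

| parameter | role | default |
|---|---|---|
| `delta` (NIM1) | bandwidth of both graphs | none (required) |
| `delta1`, `delta2` (NIM2) | influence graph / scoring bandwidths | none (required) |
| `metric` | pairwise distance | `euclidean` |
| `diagonal_policy` | self-loop weight 0 or 1 | `zero` |
| `exponent` | kernel on $d^2$ (standard RBF) or on $d$ | `squared` |
| `tie_break` | equal-score rule | earliest declared class |

The diagonal policy is provably irrelevant to the influence vector
(uniform diagonal shift) and, with policy `zero`, keeps self-matches
out of the class sums. The `squared` exponent is the standard Gaussian
kernel; the `raw` variant exists for reproducing studies that apply
the kernel to the unsquared distance. A useful bandwidth heuristic is
the median pairwise distance of the normalized data: far below it the
graph fragments into near-disconnected blocks, far above it all
similarities flatten toward 1 and scores become uninformative.

Min-max normalization maps each feature by $(x - \min)/(\max - \min)$;
constant features map to 0 and are kept, so feature indices remain
stable. Duplicated training samples each carry their own influence
weight; the class score follows the weighted-mean formula literally,
so duplicating a member can change the score.

## Evaluation

`loocv` runs $N$ folds of size one; folds whose held-out sample
empties a class are recorded as errored and excluded from the accuracy
denominator with a warning. `holdout` is a single fit/predict on a
labeled test set. `grid_search` sweeps the bandwidth axis (NIM1) or
the $\delta_1 \times \delta_2$ product grid (NIM2) and reports the
accuracy surface and its argmax; since the NIM1 axis embeds in the
NIM2 diagonal, the best NIM2 grid accuracy is never below the best
NIM1 accuracy on a shared axis. Default grid resolutions are
deliberately coarse; full-resolution sweeps (thousands of points) are
supported but not the default.

## Synthetic data

The generator emulates the regime the classifiers target: thousands
of features, tens-to-hundreds of samples, 2–7 classes, unbalanced
class sizes. Each class is a Gaussian bump: the informative block of
features is split into one group per class, the class mean is constant
on its own group and scaled so that every pair of class means is
exactly `class_separation` apart, and all features (informative or
not) carry i.i.d. Gaussian noise `noise_sd`. Defaults mirror a
typical two-class tumor/normal study: 62 samples (22 vs 40), 2000
genes, 50 informative, unit noise, separation 5.

What this emulates and what it does not: it captures high dimension,
small $n$, class imbalance, and a tunable signal-to-noise ratio; it
does **not** model probe effects, batch structure, heavy-tailed or
correlated noise, or differential variance between classes. Passing
tests on this generator show the pipeline is implemented correctly
and behaves sensibly as separation varies — not that the accuracies
transfer to any particular real microarray dataset.

For the test and acceptance runs the feature count is scaled to 300
genes (30 informative) with classes of 10 and 30 samples — the same
sample regime at a problem size the whole suite can sweep repeatedly.
At class separation 10× the noise SD, LOOCV accuracy is 1.0 for
bandwidths across $\delta \in [2, 8]$ (roughly 0.35–1.4× the median
pairwise distance of the normalized data, ~5.7 here). This holds for
the default seed and for nearly all seeds tried; occasional single
misclassifications (1/40) can occur at unlucky draws, which is the
expected tail behavior of a stochastic generator at finite
separation. Mean accuracy across 10 seeds is monotone non-decreasing
in the separation.

## Known limitations

- No inductive prediction for samples unseen at graph-construction
  time; no feature selection or gene ranking.
- Dense $N \times N$ graphs and a full eigendecomposition: fine for
  the hundreds-of-samples regime, not intended for $N \gg 10^4$.
- Very small bandwidths push edge weights toward the underflow
  threshold; the power-iteration fallback keeps the influence vector
  nonnegative, but class scores in that regime are dominated by
  nearest neighbors and the graph view adds little.
- The bipartite refusal applies to the *support* graph; a weighted
  graph whose support is bipartite is refused even though generic
  weights already break the eigenvalue tie in magnitude only in
  non-bipartite cases.
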