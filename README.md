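# nimclass

Graph-based transductive classification of expression profiles with a
walk-counting node centrality.

`nimclass` addresses a common regime in tumor transcriptomics: matrices
with thousands of genes, only tens to a couple hundred samples, and
unbalanced class sizes, where conventional classifiers struggle. It
embeds all samples — training and test alike — as nodes of a dense
Gaussian similarity graph and classifies each test sample by its
influence-weighted similarity to every class. The package is aimed at
anyone working with labeled sample-by-gene matrices (bulk microarray or
pseudobulked single-cell) who wants a simple, nearly parameter-free
graph classifier, plus the centrality itself as a standalone tool.

## The model

**Node-influence centrality.** For an undirected graph with adjacency
(or edge-weight) matrix $A$, the entry $A^k(v_i, v_j)$ counts the
(weighted) walks of length $k$ between $v_i$ and $v_j$. The $k$-step
influence of $v_i$ on $v_j$ is the fraction of all $k$-walks ending at
$v_j$ that start at $v_i$:

$$\mathrm{Influence}^k_{i \to j} \;=\; \frac{A^k(v_i, v_j)}{\sum_m A^k(v_m, v_j)}.$$

If the graph is connected and **not** bipartite, this ratio converges
as $k \to \infty$ to a limit independent of $j$: the $i$-th component
of the entrywise-positive leading (Perron) eigenvector $P_{\max}$ of
$A$, normalized to sum to one,

$$\mathrm{Influence}(v_i) \;=\; \frac{P_{v_i \max}}{\sum_m P_{m \max}}.$$

Bipartite graphs are the excluded case: their spectrum is symmetric
about zero, the extreme eigenvalues tie in absolute value, and the
ratio oscillates with the parity of $k$. `nimclass` computes the limit
by symmetric eigendecomposition, keeps the finite-$k$ walk ratio as an
independent validation path, and reports a convergence diagnostic
(connectivity, bipartiteness, spectral gap).

**NIM1 / NIM2 classifiers.** Given labeled training samples and
unlabeled test samples (with classes $C_1,\dots,C_n$):

1. jointly min-max normalize every feature of train + test to $[0,1]$;
2. compute pairwise Euclidean distances;
3. connect every pair of samples with the Gaussian edge weight
   $\exp(-d^2 / 2\delta^2)$, giving one dense graph over all samples;
4. compute the node-influence centrality of the full graph and use the
   training components as weights $w(x)$;
5. score each test sample against each class by the influence-weighted
   mean similarity
   $\mathrm{score}(x_{\text{test}}, C_i) = \sum_{x \in C_i} \mathrm{Sim}(x_{\text{test}}, x)\, w(x) \big/ \sum_{x \in C_i} w(x)$;
6. predict the argmax class (ties go to the earliest declared class).

NIM1 uses one bandwidth $\delta$ throughout; NIM2 decouples the
influence-graph bandwidth $\delta_1$ from the scoring bandwidth
$\delta_2$ and reduces exactly to NIM1 when $\delta_1=\delta_2$. The
method is transductive: test samples help shape the graph and hence
the weights, so predictions are defined for a fixed, known test set.

## Worked example

The six-node toy network with edges 1–2, 2–3, 2–4, 3–4, 4–5, 5–6 ships
with the package. Its influence vector:

```
$ nim influence --graph example
1       0.1043
2       0.2433
3       0.2121
4       0.2517
5       0.1321
6       0.0566
```

The values sum to 1; node 4 — which sits on the triangle 2–3–4 *and*
bridges to the 4–5–6 tail — is the most influential at 0.2517, the
large-$k$ limit of the fraction of walks ending anywhere that start at
node 4.

An end-to-end classification run on synthetic data in the microarray
regime (2 classes of 10 and 30 samples, 300 genes of which 30 carry
class signal, class means 10 noise-SDs apart):

```python
from nimclass import SynthSpec, generate, write_dataset
write_dataset(generate(SynthSpec(2, (10, 30), 300, 30, 10.0, 1.0, seed=0)),
              "demo.csv")
```

```
$ nim loocv --data demo.csv --variant nim1 --delta 3.0
accuracy        1.000000        (40/40)
$ nim loocv --data demo.csv --variant nim2 --delta1 2.0 --delta2 4.0
accuracy        1.000000        (40/40)
```

Leave-one-out cross-validation classifies all 40 held-out samples
correctly: with this separation the two Gaussian clusters are cleanly
resolved by the similarity graph for any bandwidth in roughly
$\delta \in [2, 8]$. Other subcommands: `nim synth`, `nim normalize`,
`nim graph`, `nim classify`, `nim holdout`, `nim grid` (bandwidth
sweeps), `nim trace` (convergence traces); see `nim <cmd> --help`.

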