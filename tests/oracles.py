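"""Independent straight-loop oracles used by the test suite.

Everything here is written with plain Python loops and ``math`` only —
no shared code with the package — so tests can compare the library's
vectorized/spectral paths against a second, independent route.
"""

import math


def loop_euclidean(x, y):
    assert len(x) == len(y)
    total = 0.0
    for a, b in zip(x, y):
        total += (a - b) ** 2
    return math.sqrt(total)


def loop_minmax(rows):
    """Column-wise (x - min) / (max - min); constant columns -> 0."""
    n, m = len(rows), len(rows[0])
    out = [[0.0] * m for _ in range(n)]
    for j in range(m):
        col = [rows[i][j] for i in range(n)]
        lo, hi = min(col), max(col)
        for i in range(n):
            out[i][j] = 0.0 if hi == lo else (rows[i][j] - lo) / (hi - lo)
    return out


def loop_similarity(d, delta):
    return math.exp(-(d * d) / (2.0 * delta * delta))


def loop_perron(w, tol=1e-15, maxiter=200_000):
    """Leading eigenvector of a symmetric nonnegative matrix by pure
    power iteration, normalized to sum 1."""
    n = len(w)
    v = [1.0 / math.sqrt(n)] * n
    for _ in range(maxiter):
        av = [sum(w[i][j] * v[j] for j in range(n)) for i in range(n)]
        lam = math.sqrt(sum(a * a for a in av))
        v_new = [a / lam for a in av]
        resid = max(
            abs(sum(w[i][j] * v_new[j] for j in range(n)) - lam * v_new[i])
            for i in range(n)
        )
        v = v_new
        if resid <= tol * lam:
            break
    else:
        raise RuntimeError("oracle power iteration did not converge")
    s = sum(v)
    return [x / s for x in v]


def loop_nim(train_rows, train_labels, test_rows, delta_graph, delta_score):
    """Full transductive pipeline, step by step, in plain loops.

    Joint min-max normalization; pairwise Euclidean distances; Gaussian
    similarity graph (zero diagonal) with ``delta_graph``; leading-
    eigenvector node influence over the full graph; class scores from a
    second ``delta_score`` similarity; argmax with first-class
    tie-break. Returns (list of per-test score dicts, predicted labels).
    """
    n_train = len(train_rows)
    rows = [list(r) for r in train_rows] + [list(r) for r in test_rows]
    rows = loop_minmax(rows)
    n = len(rows)

    dist = [[loop_euclidean(rows[i], rows[j]) for j in range(n)] for i in range(n)]
    w1 = [
        [0.0 if i == j else loop_similarity(dist[i][j], delta_graph) for j in range(n)]
        for i in range(n)
    ]
    influence = loop_perron(w1)
    w2 = [
        [0.0 if i == j else loop_similarity(dist[i][j], delta_score) for j in range(n)]
        for i in range(n)
    ]

    classes = []
    for lb in train_labels:
        if lb not in classes:
            classes.append(lb)

    all_scores = []
    predicted = []
    for t in range(n_train, n):
        scores = {}
        for c in classes:
            num = den = 0.0
            for j in range(n_train):
                if train_labels[j] == c:
                    num += w2[t][j] * influence[j]
                    den += influence[j]
            scores[c] = num / den
        best = classes[0]
        for c in classes[1:]:
            if scores[c] > scores[best]:
                best = c
        all_scores.append(scores)
        predicted.append(best)
    return all_scores, predicted
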