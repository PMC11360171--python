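import numpy as np
import pytest

from qgexar import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Two-cell-line cohort with 5 planted genes, strong shift, tiny catalog."""
    config = SynthConfig(
        n_chemicals=120,
        n_landmark=40,
        n_best_inferred=12,
        n_inferred=8,
        n_informative=5,
        effect_shift=2.5,
        prevalence=0.35,
        seed=11,
    )
    matrices, activity, truth = generate_cohort(config)
    return config, matrices, activity, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def multisurf_reference(X, y):
    """Exhaustive double-loop MultiSURF, independent of the vectorized path.

    Pure-python loops over instances, neighbors and features; Manhattan
    distance over range-normalized values; dead band = half the
    population SD of the target's distances; prior-weighted misses.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    n, p = X.shape
    span = [max(X[i][f] for i in range(n)) - min(X[i][f] for i in range(n)) for f in range(p)]
    span = [s if s != 0 else 1.0 for s in span]

    def diff(f, i, j):
        return abs(X[i][f] - X[j][f]) / span[f]

    def dist(i, j):
        return sum(diff(f, i, j) for f in range(p))

    classes = sorted(set(y))
    prior = {c: sum(1 for v in y if v == c) / n for c in classes}
    W = [0.0] * p
    for i in range(n):
        ds = [dist(i, j) for j in range(n) if j != i]
        mu = sum(ds) / len(ds)
        sd = (sum((d - mu) ** 2 for d in ds) / len(ds)) ** 0.5
        cut = mu - sd / 2.0
        near = [j for j in range(n) if j != i and dist(i, j) < cut]
        hits = [j for j in near if y[j] == y[i]]
        for f in range(p):
            if hits:
                W[f] -= sum(diff(f, i, j) for j in hits) / len(hits)
            for c in classes:
                if c == y[i]:
                    continue
                miss = [j for j in near if y[j] == c]
                if miss:
                    W[f] += (prior[c] / (1.0 - prior[y[i]])) * (
                        sum(diff(f, i, j) for j in miss) / len(miss)
                    )
    return np.array(W) / n


def reference_near_sets(D):
    """Brute-force near-neighbor sets from a distance matrix."""
    n = len(D)
    out = []
    for i in range(n):
        ds = [D[i][j] for j in range(n) if j != i]
        mu = sum(ds) / len(ds)
        sd = (sum((d - mu) ** 2 for d in ds) / len(ds)) ** 0.5
        out.append(sorted(j for j in range(n) if j != i and D[i][j] < mu - sd / 2.0))
    return out
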