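"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration / dense linear
algebra, sharing no code path with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def absorbing_chain_probabilities(image: np.ndarray, seeds: np.ndarray,
                                  beta: float) -> np.ndarray:
    """Per-label absorption probabilities of the lattice random walk.

    Builds the full transition matrix of the random walk whose step
    probabilities are proportional to edge weights exp(-beta * dI^2), treats
    seed pixels as absorbing, and solves the fundamental-matrix system
    (I - Q) B = R directly.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape
    n = H * W
    A = np.zeros((n, n))
    for y in range(H):
        for x in range(W):
            i = y * W + x
            if x + 1 < W:
                j = y * W + x + 1
                w = np.exp(-beta * (image[y, x] - image[y, x + 1]) ** 2)
                A[i, j] = A[j, i] = w
            if y + 1 < H:
                j = (y + 1) * W + x
                w = np.exp(-beta * (image[y, x] - image[y + 1, x]) ** 2)
                A[i, j] = A[j, i] = w
    P = A / A.sum(axis=1, keepdims=True)
    s = seeds.ravel()
    transient = np.flatnonzero(s == 0)
    absorbing = np.flatnonzero(s > 0)
    labels = np.unique(s[s > 0])
    probs = np.zeros((len(labels), n))
    if len(transient):
        Q = P[np.ix_(transient, transient)]
        R = P[np.ix_(transient, absorbing)]
        B = np.linalg.solve(np.eye(len(transient)) - Q, R)
        for k, lab in enumerate(labels):
            probs[k, transient] = B[:, s[absorbing] == lab].sum(axis=1)
    for k, lab in enumerate(labels):
        probs[k, absorbing[s[absorbing] == lab]] = 1.0
    return probs.reshape(len(labels), H, W)


def enumerate_hmm(pi: np.ndarray, A: np.ndarray, logB: np.ndarray):
    """Total likelihood and best path by exhaustive path enumeration.

    Iterates all K^T state paths in lexicographic order; the best path keeps
    the first maximum, i.e. ties break toward lower state indices.
    """
    T, K = logB.shape
    total = 0.0
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=T):
        logp = (np.log(pi[path[0]]) if pi[path[0]] > 0 else -np.inf) + logB[0, path[0]]
        for t in range(1, T):
            a = A[path[t - 1], path[t]]
            logp += (np.log(a) if a > 0 else -np.inf) + logB[t, path[t]]
        if np.isfinite(logp):
            total += np.exp(logp)
        if logp > best_logp:
            best_logp, best_path = logp, path
    return total, np.asarray(best_path)


def random_lr_hmm_instance(rng: np.random.Generator, max_states=4, max_len=8,
                           n_features=2):
    """A random left-to-right Gaussian HMM plus one observation sequence."""
    K = int(rng.integers(1, max_states + 1))
    T = int(rng.integers(1, max_len + 1))
    A = np.triu(rng.uniform(0.05, 1.0, (K, K)))
    A /= A.sum(axis=1, keepdims=True)
    pi = rng.dirichlet(np.ones(K))
    means = rng.normal(0.0, 2.0, (K, n_features))
    variances = rng.uniform(0.3, 2.0, (K, n_features))
    X = rng.normal(0.0, 2.0, (T, n_features))
    return pi, A, means, variances, X
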