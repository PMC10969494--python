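"""Shared fixtures and independent oracle helpers.

The oracles here are deliberately naive (double loops, dense linear algebra)
so they stay independent of the implementation paths they check.
"""

import os

# pin BLAS to one thread before numpy initialises it: threaded reductions
# reorder floating-point sums and break bit-level reproducibility (and are
# slower than serial for the small matrices used here)
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from carmap.graph import AdjacencyGraph, from_edge_list


@pytest.fixture
def rng():
    return np.random.default_rng(20240216)


def make_random_connected_graph(rng: np.random.Generator, n: int) -> AdjacencyGraph:
    """Random spanning tree plus a handful of extra edges (always connected)."""
    perm = rng.permutation(n)
    edges = [(int(perm[i]), int(perm[rng.integers(0, i)])) for i in range(1, n)]
    for _ in range(n // 2):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.append((int(a), int(b)))
    return from_edge_list(edges, list(range(n)))


def morans_i_bruteforce(values, W) -> float:
    """Double-loop Moran's I, the reference implementation."""
    z = np.asarray(values, dtype=float)
    z = z - z.mean()
    W = np.asarray(W)
    n = z.size
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return (n / s0) * num / float(z @ z)


def dense_gaussian_conditional(mu, Sigma, mis, obs, x_obs):
    """Brute-force conditional of a dense joint Gaussian."""
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    mis = np.asarray(mis, dtype=int)
    obs = np.asarray(obs, dtype=int)
    S_oo = Sigma[np.ix_(obs, obs)]
    S_mo = Sigma[np.ix_(mis, obs)]
    S_mm = Sigma[np.ix_(mis, mis)]
    sol = np.linalg.solve(S_oo, np.asarray(x_obs) - mu[obs])
    mean = mu[mis] + S_mo @ sol
    cov = S_mm - S_mo @ np.linalg.solve(S_oo, S_mo.T)
    return mean, cov
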