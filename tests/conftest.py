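"""Shared fixtures: fast penalty-path profile, small synthetic cohorts, and
independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import mminet as mm
from mminet.mrf import PenaltyPath

#: The five planted isolated, outcome-unlinked items of the default cohort.
PLANTED_REMOVAL = frozenset({"Can", "DVT", "Dia", "HBP", "LD"})


@pytest.fixture(scope="session")
def fast_path() -> PenaltyPath:
    """Short penalty path used throughout the suite (12 log-spaced points
    down to 5% of the maximum penalty)."""
    return PenaltyPath(n_points=12, min_ratio=0.05)


@pytest.fixture(scope="session")
def small_cohort():
    """One default-structure synthetic cohort at modest size."""
    return mm.generate_cohort(mm.CohortConfig(n=1500, seed=7))


@pytest.fixture(scope="session")
def small_dv(small_cohort):
    dataset, _ = small_cohort
    return mm.dichotomized_view(dataset)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def ising_enumeration_moments(weights: np.ndarray, fields: np.ndarray):
    """Exact moments of a 0/1 Ising model by exhaustive state enumeration
    (p <= 10). Returns (P(state) dict over tuples, marginal vector,
    pairwise E[x_i x_j] matrix)."""
    p = len(fields)
    states = list(itertools.product((0.0, 1.0), repeat=p))
    logw = np.array(
        [float(fields @ np.array(s) + np.array(s) @ weights @ np.array(s) / 2.0)
         for s in states]
    )
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    marg = np.zeros(p)
    second = np.zeros((p, p))
    for prob, s in zip(probs, states):
        arr = np.array(s)
        marg += prob * arr
        second += prob * np.outer(arr, arr)
    return dict(zip(states, probs)), marg, second


def brute_force_betweenness(weights: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration (p <= 8).

    Edge lengths are 1/|w|; for every unordered pair the geodesics are
    found among all simple paths and interior nodes receive fractional
    credit 1/(number of tied geodesics).
    """
    p = weights.shape[0]
    adj = {i: [j for j in range(p) if weights[i, j] != 0] for i in range(p)}

    def all_simple_paths(s, t):
        paths = []

        def extend(path):
            node = path[-1]
            if node == t:
                paths.append(list(path))
                return
            for nxt in adj[node]:
                if nxt not in path:
                    path.append(nxt)
                    extend(path)
                    path.pop()

        extend([s])
        return paths

    bc = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = all_simple_paths(s, t)
            if not paths:
                continue
            lengths = [sum(1.0 / abs(weights[a, b]) for a, b in zip(q, q[1:]))
                       for q in paths]
            best = min(lengths)
            geodesics = [q for q, l in zip(paths, lengths)
                         if np.isclose(l, best, rtol=1e-12)]
            for q in geodesics:
                for interior in q[1:-1]:
                    bc[interior] += 1.0 / len(geodesics)
    return bc


@pytest.fixture(scope="session")
def ising_oracle():
    return ising_enumeration_moments


@pytest.fixture(scope="session")
def betweenness_oracle():
    return brute_force_betweenness


def random_network_model(p: int, seed: int, density: float = 0.4) -> mm.NetworkModel:
    """A random symmetric weighted network for oracle comparisons."""
    rng = np.random.default_rng(seed)
    w = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(-1, 1, len(iu[0])) * mask
    vals[np.abs(vals) < 0.05] = 0.0
    w[iu] = vals
    w = w + w.T
    return mm.NetworkModel(family="ggm", node_names=tuple(f"V{i}" for i in range(p)),
                           weights=w, gamma=0.5)
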