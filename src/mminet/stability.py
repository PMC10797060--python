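"""Bootstrap accuracy and stability of estimated networks.

Two resampling schemes, following the standard network-psychometrics
workflow:

* nonparametric edge bootstrap — resample rows with replacement, refit,
  and form percentile intervals per edge; two edges (or two nodes'
  centralities) differ significantly when the bootstrap interval of their
  difference excludes zero;
* case-dropping subsampling — refit on subsamples retaining a shrinking
  fraction of rows and correlate the subsample centralities with the
  full-sample ones. The CS-coefficient summarizes the curves: the largest
  drop proportion at which, with probability >= 0.95, that correlation
  stays >= 0.7.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import METRICS, metric_vector
from .data_model import MminetError
from .mrf import NetworkModel

__all__ = [
    "EdgeBootstrap",
    "DropCurves",
    "StabilityReport",
    "bootstrap_edges",
    "correlation_stability",
    "cs_coefficient",
    "centrality_difference_test",
    "stability_report",
    "DEFAULT_DROP_GRID",
]

#: Case-drop proportions examined for the CS-coefficient.
DEFAULT_DROP_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))


@dataclass
class EdgeBootstrap:
    """Row-resampling bootstrap of a network fit.

    Holds per-edge percentile intervals, the per-resample weight matrices'
    upper triangles, per-resample centralities, and bookkeeping about
    failed refits (a report with more than 10% failures is flagged
    unstable).
    """

    node_names: tuple[str, ...]
    point_weights: np.ndarray          # (p, p) full-sample weights
    boot_edges: np.ndarray             # (B_ok, n_edges) upper-triangle weights
    boot_centralities: dict            # metric -> (B_ok, p)
    edge_ci: pd.DataFrame              # i, j, estimate, lo, hi
    n_failures: int
    B: int
    seed: int

    @property
    def flagged_unstable(self) -> bool:
        return self.n_failures > 0.1 * self.B

    def edge_index(self) -> list[tuple[str, str]]:
        p = len(self.node_names)
        iu, ju = np.triu_indices(p, k=1)
        return [(self.node_names[a], self.node_names[b]) for a, b in zip(iu, ju)]

    def edge_difference_test(self, alpha: float = 0.05) -> pd.DataFrame:
        """Symmetric edge-pair matrix: True where the bootstrap interval of
        the difference between two edge weights excludes 0.

        Every pair of potential edges is compared, including edges absent
        from the full-sample fit (a strong edge differs significantly from
        an absent one). Computed in chunks to bound memory on large
        networks.
        """
        p = len(self.node_names)
        iu, ju = np.triu_indices(p, k=1)
        labels = [f"{self.node_names[a]}--{self.node_names[b]}" for a, b in zip(iu, ju)]
        m = len(labels)
        ai, bi = np.triu_indices(m, k=1)
        lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
        diff = np.zeros((m, m), dtype=bool)
        chunk = max(1, 20_000_000 // max(self.boot_edges.shape[0], 1))
        for start in range(0, len(ai), chunk):
            a = ai[start:start + chunk]
            b = bi[start:start + chunk]
            d = self.boot_edges[:, a] - self.boot_edges[:, b]
            lo, hi = np.percentile(d, [lo_q, hi_q], axis=0)
            sig = (lo > 0) | (hi < 0)
            diff[a, b] = sig
            diff[b, a] = sig
        return pd.DataFrame(diff, index=labels, columns=labels)


def bootstrap_edges(
    data: pd.DataFrame,
    fitter: Callable[[pd.DataFrame], NetworkModel],
    B: int = 1000,
    seed: int = 0,
    centrality_metrics: Sequence[str] = METRICS,
) -> EdgeBootstrap:
    """Nonparametric bootstrap of the edge weights (rows with replacement).

    Each resample is refit with ``fitter``; failed refits are dropped and
    counted. Per-edge 95% percentile intervals are formed from the
    successful refits, and per-resample centralities are retained for the
    node-difference test.
    """
    if B < 1:
        raise ValueError("B must be a positive integer")
    rng = np.random.default_rng(seed)
    full = fitter(data)
    p = full.p
    iu, ju = np.triu_indices(p, k=1)
    n = len(data)

    edges_list: list[np.ndarray] = []
    cents: dict[str, list[np.ndarray]] = {m: [] for m in centrality_metrics}
    failures = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        try:
            model = fitter(sample)
        except MminetError:
            failures += 1
            continue
        edges_list.append(model.weights[iu, ju])
        for m in centrality_metrics:
            cents[m].append(metric_vector(model, m))
    if not edges_list:
        raise MminetError("every bootstrap refit failed")
    boot_edges = np.vstack(edges_list)
    lo, hi = np.percentile(boot_edges, [2.5, 97.5], axis=0)
    edge_ci = pd.DataFrame(
        {
            "i": [full.node_names[a] for a in iu],
            "j": [full.node_names[b] for b in ju],
            "estimate": full.weights[iu, ju],
            "lo": lo,
            "hi": hi,
        }
    )
    if failures > 0.1 * B:
        warnings.warn(
            f"{failures}/{B} bootstrap refits failed; report flagged unstable",
            stacklevel=2,
        )
    return EdgeBootstrap(
        node_names=full.node_names,
        point_weights=full.weights,
        boot_edges=boot_edges,
        boot_centralities={m: np.vstack(v) for m, v in cents.items()},
        edge_ci=edge_ci,
        n_failures=failures,
        B=B,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# case-dropping stability
# ---------------------------------------------------------------------------

@dataclass
class DropCurves:
    """Correlations between subsample and full-sample metric vectors, per
    case-drop proportion."""

    metric: str
    curves: dict[float, np.ndarray]    # drop proportion -> correlations (NaN = undefined)
    B: int
    seed: int

    @property
    def grid(self) -> tuple[float, ...]:
        return tuple(sorted(self.curves))


def _stability_correlation(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    """Pearson correlation, Spearman for betweenness (heavily tied and
    zero-inflated). Undefined (constant input) -> NaN."""
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if metric == "betweenness":
            r = stats.spearmanr(a, b).statistic
        else:
            r = stats.pearsonr(a, b).statistic
    return float(r)


def correlation_stability(
    data: pd.DataFrame,
    fitter: Callable[[pd.DataFrame], NetworkModel],
    metric: str = "strength",
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    B: int = 250,
    seed: int = 0,
) -> DropCurves:
    """Case-dropping subsampling curves for one metric.

    For each drop proportion q, ``B`` subsamples without replacement
    retaining ceil((1-q) n) rows are refit, and the correlation between
    the subsample and full-sample metric vectors is recorded. Grid points
    whose retained size falls below 2p are skipped with a warning.
    """
    if metric not in (*METRICS, "edge_weight"):
        raise ValueError(f"unknown metric {metric!r}")
    if any(not 0 < q < 1 for q in drop_grid):
        raise ValueError("drop proportions must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    full = fitter(data)
    ref = metric_vector(full, metric)
    n = len(data)
    p = full.p

    curves: dict[float, np.ndarray] = {}
    for q in drop_grid:
        keep = int(np.ceil((1 - q) * n))
        if keep < 2 * p:
            warnings.warn(
                f"drop {q:.2f} retains {keep} < 2p = {2 * p} rows; skipped",
                stacklevel=2,
            )
            continue
        rs = np.empty(B)
        for b in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                model = fitter(data.iloc[idx].reset_index(drop=True))
                rs[b] = _stability_correlation(ref, metric_vector(model, metric), metric)
            except MminetError:
                rs[b] = np.nan
        curves[float(q)] = rs
    return DropCurves(metric=metric, curves=curves, B=B, seed=seed)


def cs_coefficient(
    drop_curves: DropCurves,
    r_threshold: float = 0.7,
    prob: float = 0.95,
) -> float:
    """Correlation-stability coefficient of a drop-curve set.

    The largest drop proportion q on the grid such that at every grid point
    up to and including q, the proportion of subsample correlations >=
    ``r_threshold`` is at least ``prob`` (the prefix rule guards against
    non-monotone curve artifacts). 0 if no grid point qualifies; NaN (with
    a warning) for empty curves. Undefined correlations count as failures.
    """
    if not drop_curves.curves:
        warnings.warn("no drop curves available; CS undefined", stacklevel=2)
        return float("nan")
    cs = 0.0
    for q in drop_curves.grid:
        rs = drop_curves.curves[q]
        pass_rate = np.mean(np.where(np.isnan(rs), False, rs >= r_threshold))
        if pass_rate >= prob:
            cs = q
        else:
            break
    return cs


def centrality_difference_test(
    bootstraps: EdgeBootstrap,
    metric: str = "strength",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Symmetric node-pair matrix: True where the bootstrap interval of the
    centrality difference excludes 0 (diagonal False)."""
    cent = bootstraps.boot_centralities[metric]
    p = cent.shape[1]
    names = list(bootstraps.node_names)
    diff = np.zeros((p, p), dtype=bool)
    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    for i in range(p):
        for j in range(i + 1, p):
            d = cent[:, i] - cent[:, j]
            lo, hi = np.percentile(d, [lo_q, hi_q])
            sig = lo > 0 or hi < 0
            diff[i, j] = diff[j, i] = sig
    return pd.DataFrame(diff, index=names, columns=names)


@dataclass
class StabilityReport:
    """Bundle of the bootstrap and case-dropping results for one network."""

    edge_bootstrap: EdgeBootstrap
    drop_curves: Mapping[str, DropCurves]
    cs: Mapping[str, float]
    edge_diff: pd.DataFrame
    cent_diff: Mapping[str, pd.DataFrame]
    B_edges: int
    B_drop: int
    seed: int

    def summary(self) -> dict:
        return {
            "cs": dict(self.cs),
            "B_edges": self.B_edges,
            "B_drop": self.B_drop,
            "n_bootstrap_failures": self.edge_bootstrap.n_failures,
            "flagged_unstable": self.edge_bootstrap.flagged_unstable,
            "seed": self.seed,
        }


def stability_report(
    data: pd.DataFrame,
    fitter: Callable[[pd.DataFrame], NetworkModel],
    metrics: Sequence[str] = ("strength", "expected_influence", "betweenness", "edge_weight"),
    B_edges: int = 1000,
    B_drop: int = 250,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    seed: int = 0,
) -> StabilityReport:
    """Full stability analysis: edge bootstrap, CS per metric, difference
    tests."""
    boot = bootstrap_edges(data, fitter, B=B_edges, seed=seed)
    curves: dict[str, DropCurves] = {}
    cs: dict[str, float] = {}
    for k, metric in enumerate(metrics):
        dc = correlation_stability(
            data, fitter, metric=metric, drop_grid=drop_grid, B=B_drop,
            seed=seed + 1 + k,
        )
        curves[metric] = dc
        cs[metric] = cs_coefficient(dc)
    cent_diff = {
        m: centrality_difference_test(boot, metric=m)
        for m in metrics
        if m != "edge_weight"
    }
    return StabilityReport(
        edge_bootstrap=boot,
        drop_curves=curves,
        cs=cs,
        edge_diff=boot.edge_difference_test(),
        cent_diff=cent_diff,
        B_edges=B_edges,
        B_drop=B_drop,
        seed=seed,
    )
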