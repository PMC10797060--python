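"""Synthetic survey cohorts sampled from planted network structures.

The restricted community-survey data cannot be shared, so every downstream
stage (screening, network estimation, stability, short-form derivation,
regression comparison) is exercised on synthetic cohorts whose generative
truth is known and retained. The default cohort emulates the qualitative
structure reported for spinal-cord-injury survey data:

* 30 sparse, mostly positively coupled binary SHC items, of which five
  (cancer, DVT, diabetes, high blood pressure, liver disease analogues) are
  isolated — no couplings and no outcome link — and one (the autonomic
  dysreflexia analogue ``AD``) is a hub with six couplings;
* a strong planted item pair (elbow/wrist-shoulder analogue);
* two correlated continuous health-status scores (PCS/MCS), with the
  depression item specifically depressing the MCS score;
* ordinal satisfaction items (1-6 and 1-5) generated by thresholding latent
  scores that share a common "wellbeing" factor, so the two quality-of-life
  outcomes correlate strongly, as they do in real surveys;
* a binary "felt needed care was not received" outcome whose log-odds rise
  with the count of outcome-linked conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import MminetError, SurveyDataset, VariableSpec

__all__ = [
    "TruthNetwork",
    "CohortConfig",
    "ConfigError",
    "ValidityError",
    "make_truth_network",
    "sample_gaussian",
    "sample_ising_gibbs",
    "sample_mixed",
    "generate_cohort",
    "default_truth_network",
    "default_cohort_config",
    "SHC_NAMES",
    "DEFAULT_ISOLATED",
    "DEFAULT_HUB",
]


class ConfigError(MminetError):
    """Invalid simulation configuration."""


class ValidityError(MminetError):
    """Planted structure does not define a valid distribution."""


# The 30 SHC item labels of the full instrument (hub: AD; the five isolated
# items double as the expected short-form removal set).
SHC_NAMES: tuple[str, ...] = (
    "AD", "BI", "Can", "Cons", "DA", "Depre", "Dia", "DVT", "EP", "Fati",
    "HBP", "HD", "Head", "Inj", "JC", "KS", "LD", "ND", "NP", "Oste",
    "PU", "RI", "SD", "SP", "Spas", "TS", "Ulcer", "UI", "UTI", "WP",
)

DEFAULT_ISOLATED: frozenset[str] = frozenset({"Can", "DVT", "Dia", "HBP", "LD"})
DEFAULT_HUB: str = "AD"

OUTCOME_NAMES: tuple[str, ...] = ("Care", "PCS", "MCS", "Satis", "QoL")
COVARIATE_NAMES: tuple[str, ...] = ("age", "sex", "incomplete", "days_since_injury", "own_home")


@dataclass
class TruthNetwork:
    """A planted pairwise Markov-random-field structure.

    ``weights`` is the symmetric coupling matrix with zero diagonal; for
    binary nodes ``fields`` are the per-node intercepts of the 0/1 Ising
    parameterization (the logistic nodewise conditionals' intercepts).
    """

    node_names: tuple[str, ...]
    weights: np.ndarray
    fields: np.ndarray | None = None
    kinds: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        p = len(self.node_names)
        if w.shape != (p, p):
            raise ConfigError(f"weights must be {p}x{p}")
        if not np.allclose(w, w.T):
            raise ConfigError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ConfigError("weights must have a zero diagonal")
        self.weights = w
        if self.fields is None:
            self.fields = np.zeros(p)
        else:
            self.fields = np.asarray(self.fields, dtype=float)
            if self.fields.shape != (p,):
                raise ConfigError("fields must have one entry per node")
        if self.kinds is None:
            self.kinds = tuple("binary" for _ in self.node_names)

    @property
    def p(self) -> int:
        return len(self.node_names)

    def index(self, name: str) -> int:
        return self.node_names.index(name)

    def isolated_names(self) -> set[str]:
        deg = np.count_nonzero(self.weights, axis=1)
        return {n for n, d in zip(self.node_names, deg) if d == 0}


def make_truth_network(
    p: int | Sequence[str],
    edge_spec: Sequence[tuple[int, int, float]],
    isolated: set[str] | set[int] | None = None,
    fields: Sequence[float] | None = None,
    kinds: Sequence[str] | None = None,
) -> TruthNetwork:
    """Build a truth network with exactly the listed edges.

    ``p`` may be a node count (names become ``V0..V{p-1}``) or a name list.
    ``isolated`` nodes (names or indices) must not be touched by any edge.
    """
    names = tuple(f"V{i}" for i in range(p)) if isinstance(p, int) else tuple(p)
    n = len(names)
    iso_idx: set[int] = set()
    for item in isolated or ():
        iso_idx.add(item if isinstance(item, int) else names.index(item))
    w = np.zeros((n, n))
    for i, j, weight in edge_spec:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ConfigError(f"invalid edge ({i}, {j})")
        if i in iso_idx or j in iso_idx:
            raise ConfigError(
                f"edge ({i}, {j}) touches isolated node "
                f"{names[i] if i in iso_idx else names[j]!r}"
            )
        w[i, j] = w[j, i] = weight
    return TruthNetwork(
        node_names=names,
        weights=w,
        fields=None if fields is None else np.asarray(fields, float),
        kinds=tuple(kinds) if kinds is not None else None,
    )


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def implied_precision(truth: TruthNetwork) -> np.ndarray:
    """Unit-diagonal precision matrix whose partial correlations equal the
    planted weights: K = I - W."""
    return np.eye(truth.p) - truth.weights


def sample_gaussian(truth: TruthNetwork, n: int, seed: int) -> pd.DataFrame:
    """Draw ``n`` zero-mean Gaussian rows whose partial correlation matrix
    equals ``truth.weights``.

    Raises a validity error naming the smallest eigenvalue when the implied
    precision matrix I - W is not positive definite.
    """
    K = implied_precision(truth)
    eigvals = np.linalg.eigvalsh(K)
    if eigvals[0] <= 1e-12:
        raise ValidityError(
            f"implied precision not positive definite (smallest eigenvalue "
            f"{eigvals[0]:.3g})"
        )
    cov = np.linalg.inv(K)
    L = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, truth.p)) @ L.T
    return pd.DataFrame(X, columns=list(truth.node_names))


def sample_ising_gibbs(
    truth: TruthNetwork,
    n: int,
    burn_in: int = 200,
    thin: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` rows from the 0/1 Ising model with the planted couplings.

    Runs ``n`` independent Gibbs chains in parallel (one per row), each for
    ``burn_in + thin`` full sweeps; node j is resampled from its logistic
    conditional sigma(field_j + sum_k w_jk x_k). Deterministic given seed.
    """
    if any(k != "binary" for k in truth.kinds):
        raise ConfigError("Ising sampler requires all nodes binary")
    if burn_in < 0 or thin < 0:
        raise ConfigError("burn_in and thin must be nonnegative")
    rng = np.random.default_rng(seed)
    p = truth.p
    W = truth.weights
    h = truth.fields
    # independent start from the field-only marginals
    X = (rng.random((n, p)) < 1.0 / (1.0 + np.exp(-h))).astype(float)
    for _ in range(burn_in + thin):
        for j in range(p):
            eta = h[j] + X @ W[:, j]
            pj = 1.0 / (1.0 + np.exp(-eta))
            X[:, j] = (rng.random(n) < pj).astype(float)
    return pd.DataFrame(X, columns=list(truth.node_names))


def sample_mixed(truth: TruthNetwork, n: int, seed: int = 0,
                 burn_in: int = 200) -> pd.DataFrame:
    """Draw ``n`` rows from a conditional-Gaussian mixed MRF.

    Binary nodes are Gibbs-sampled from the Ising model restricted to the
    binary block; continuous nodes are then drawn from the conditional
    Gaussian with precision K_cc = I - W_cc and mean K_cc^{-1} W_cb x_b.
    The planted couplings equal the joint model's conditional structure
    exactly when binary nodes do not share continuous neighbours (the
    marginalization term W_bc K_cc^{-1} W_cb is then diagonal and only
    shifts fields); planted truths used with this sampler should respect
    that layout.
    """
    kinds = np.asarray(truth.kinds)
    bin_idx = np.flatnonzero(kinds == "binary")
    con_idx = np.flatnonzero(kinds == "continuous")
    if len(con_idx) == 0:
        return sample_ising_gibbs(truth, n, burn_in=burn_in, seed=seed)
    rng = np.random.default_rng(seed)
    W = truth.weights
    Xb = np.empty((n, 0))
    if len(bin_idx):
        sub = TruthNetwork(
            node_names=tuple(truth.node_names[i] for i in bin_idx),
            weights=W[np.ix_(bin_idx, bin_idx)],
            fields=truth.fields[bin_idx],
        )
        Xb = sample_ising_gibbs(sub, n, burn_in=burn_in,
                                seed=int(rng.integers(2**31 - 1))).to_numpy()
    Kcc = np.eye(len(con_idx)) - W[np.ix_(con_idx, con_idx)]
    eig = np.linalg.eigvalsh(Kcc)
    if eig[0] <= 1e-12:
        raise ValidityError(
            f"continuous-block precision not positive definite "
            f"(smallest eigenvalue {eig[0]:.3g})"
        )
    mean = np.linalg.solve(Kcc, (W[np.ix_(con_idx, bin_idx)] @ Xb.T)).T
    L = np.linalg.cholesky(np.linalg.inv(Kcc))
    Xc = mean + rng.standard_normal((n, len(con_idx))) @ L.T
    out = np.empty((n, truth.p))
    out[:, bin_idx] = Xb
    out[:, con_idx] = Xc
    return pd.DataFrame(out, columns=list(truth.node_names))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def default_truth_network(
    coupling_scale: float = 1.0,
    isolated: frozenset[str] = DEFAULT_ISOLATED,
) -> TruthNetwork:
    """The default planted 30-item SHC structure.

    A hub (``AD``) with six positive couplings, one strong planted pair
    (``EP``-``SP``), a positive background of pairwise couplings so every
    non-isolated item has at least one edge, and five isolated items. All
    couplings are positive, matching the predominantly positive association
    structure of multimorbidity items.
    """
    edges_by_name = [
        # hub: autonomic dysreflexia analogue
        ("AD", "Head", 1.0), ("AD", "Spas", 0.9), ("AD", "UTI", 0.8),
        ("AD", "BI", 0.8), ("AD", "Cons", 0.7), ("AD", "PU", 0.7),
        # strong planted pair: elbow/wrist - shoulder analogue
        ("EP", "SP", 1.8),
        # positive background
        ("Depre", "TS", 0.9), ("Depre", "Fati", 0.8), ("Fati", "TS", 0.7),
        ("NP", "Spas", 0.7), ("NP", "TS", 0.6), ("UI", "UTI", 0.9),
        ("UI", "BI", 0.7), ("RI", "Fati", 0.6), ("Oste", "JC", 0.7),
        ("JC", "Spas", 0.6), ("DA", "SP", 0.7), ("DA", "EP", 0.6),
        ("SD", "Depre", 0.6), ("WP", "Fati", 0.6), ("HD", "WP", 0.6),
        ("KS", "UTI", 0.7), ("ND", "Spas", 0.6), ("Inj", "PU", 0.7),
        ("Ulcer", "Cons", 0.6), ("Head", "Fati", 0.6),
        # second couplings so no retained item hangs on a single weak edge
        ("HD", "Fati", 0.5), ("Inj", "NP", 0.5), ("KS", "UI", 0.5),
        ("ND", "NP", 0.5), ("Oste", "DA", 0.5), ("RI", "UTI", 0.5),
        ("SD", "UI", 0.5), ("Ulcer", "WP", 0.5),
    ]
    name_to_idx = {n: i for i, n in enumerate(SHC_NAMES)}
    edges = [
        (name_to_idx[a], name_to_idx[b], w * coupling_scale)
        for a, b, w in edges_by_name
    ]
    # fields: moderate prevalence for connected items, lower for the
    # isolated comorbidity analogues (roughly rare chronic diseases)
    fields = np.full(len(SHC_NAMES), -1.2)
    for name in isolated:
        fields[name_to_idx[name]] = -1.5
    return make_truth_network(SHC_NAMES, edges, isolated=set(isolated), fields=fields)


@dataclass
class CohortConfig:
    """Configuration of one synthetic survey cohort.

    ``outcome_effect`` is the coefficient of the (centered) count of
    outcome-linked SHCs on every outcome's linear predictor, oriented so a
    higher count means poorer outcomes. ``isolated_items`` carry no network
    couplings and are excluded from the outcome-linked count, so they are
    both network-isolated and outcome-unlinked — the planted ground truth
    for the short-form removal set.
    """

    n: int = 4000
    truth: TruthNetwork | None = None
    isolated_items: frozenset[str] = DEFAULT_ISOLATED
    hub_item: str = DEFAULT_HUB
    outcome_effect: float = 0.2
    wellbeing_loading: float = 1.0
    noise_scales: Mapping[str, float] = field(
        default_factory=lambda: {"PCS": 7.0, "MCS": 7.0, "latent": 0.7}
    )
    depression_effect: float = 4.5
    burn_in: int = 200
    seed: int = 0
    cohort_label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.truth is None:
            self.truth = default_truth_network(isolated=frozenset(self.isolated_items))
        if self.hub_item in self.isolated_items:
            raise ConfigError("hub item cannot be isolated")
        if self.n < 10:
            raise ConfigError("cohort size must be at least 10")

    @property
    def linked_items(self) -> tuple[str, ...]:
        return tuple(n for n in self.truth.node_names if n not in self.isolated_items)


def _cohort_specs(shc_names: Sequence[str]) -> list[VariableSpec]:
    specs = [VariableSpec(n, "binary", "shc") for n in shc_names]
    specs += [
        VariableSpec("Care", "binary", "outcome"),
        VariableSpec("PCS", "continuous", "outcome"),
        VariableSpec("MCS", "continuous", "outcome"),
        VariableSpec("Satis", "ordinal", "outcome", levels=tuple(range(1, 7))),
        VariableSpec("QoL", "ordinal", "outcome", levels=tuple(range(1, 6))),
        VariableSpec("age", "continuous", "covariate"),
        VariableSpec("sex", "binary", "covariate"),
        VariableSpec("incomplete", "binary", "covariate"),
        VariableSpec("days_since_injury", "continuous", "covariate"),
        VariableSpec("own_home", "binary", "covariate"),
    ]
    return specs


def _threshold_ordinal(latent: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    """Map a latent score to consecutive integer levels 1..len(cuts)+1."""
    return 1 + np.searchsorted(np.asarray(cuts), latent)


def generate_cohort(config: CohortConfig) -> tuple[SurveyDataset, dict]:
    """Sample a full survey-like cohort from the planted truth.

    Returns the coded dataset together with a truth record (the planted
    network, the isolated/linked item sets and the generative coefficients)
    for use in recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth
    n = config.n

    shc = sample_ising_gibbs(
        truth, n, burn_in=config.burn_in, seed=int(rng.integers(2**31 - 1))
    )
    linked = list(config.linked_items)
    count = shc[linked].sum(axis=1).to_numpy()
    count_c = count - count.mean()
    eff = config.outcome_effect

    # shared wellbeing factor: induces the strong mutual correlation of the
    # satisfaction/QoL/mental-health outcomes seen in real survey data
    wb = config.wellbeing_loading * rng.standard_normal(n)
    depre = shc["Depre"].to_numpy() if "Depre" in shc else np.zeros(n)

    # wellbeing loadings chosen to reproduce the outcome intercorrelations
    # reported for community health surveys: satisfaction/QoL single items
    # r ~ 0.6-0.7, MCS vs satisfaction ~ 0.5, PCS and the unmet-care flag
    # more weakly related (~0.2-0.35)
    noise = config.noise_scales
    pcs = 34.0 - 3.0 * eff * count_c + 3.0 * wb + rng.normal(0, noise["PCS"], n)
    mcs = (
        51.0
        - 3.0 * eff * count_c
        - config.depression_effect * (depre - depre.mean())
        + 5.5 * wb
        + rng.normal(0, noise["MCS"], n)
    )
    care_logit = -1.3 + eff * count_c - 1.3 * wb
    care = (rng.random(n) < 1.0 / (1.0 + np.exp(-care_logit))).astype(int)

    # the two overall-satisfaction items rate the same construct, so both
    # threshold one shared latent score (at their own cut-points)
    qol_lat = -eff * count_c + 1.4 * wb + rng.normal(0, noise["latent"], n)
    # fixed cut-points chosen so the dichotomized margins sit near 40-50%
    satis = _threshold_ordinal(qol_lat, cuts=(-2.0, -1.2, -0.6, 0.1, 1.2))
    qol = _threshold_ordinal(qol_lat, cuts=(-1.6, -0.8, 0.0, 1.1))

    values = shc.copy()
    values["Care"] = care
    values["PCS"] = pcs
    values["MCS"] = mcs
    values["Satis"] = satis
    values["QoL"] = qol
    values["age"] = np.clip(rng.normal(49, 13, n), 18, 90)
    values["sex"] = (rng.random(n) < 0.7).astype(int)
    values["incomplete"] = (rng.random(n) < 0.61).astype(int)
    values["days_since_injury"] = np.clip(rng.normal(6750, 4700, n), 30, None)
    values["own_home"] = (rng.random(n) < 0.7).astype(int)

    dataset = SurveyDataset(
        values=values,
        specs=_cohort_specs(truth.node_names),
        cohort_label=config.cohort_label,
    )
    truth_record = {
        "truth": truth,
        "isolated_items": set(config.isolated_items),
        "linked_items": set(linked),
        "hub_item": config.hub_item,
        "outcome_effect": eff,
        "seed": config.seed,
    }
    return dataset, truth_record


def default_cohort_config(n: int = 4000, seed: int = 0, **kwargs) -> CohortConfig:
    """The study-default synthetic cohort configuration."""
    return CohortConfig(n=n, seed=seed, **kwargs)
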