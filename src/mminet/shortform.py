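"""Short-form derivation and end-to-end pipeline orchestration.

The short form is derived by combining two evidence streams: SHC items
that are *isolated* (zero degree) in the fitted networks, and items that
are null in the bivariate screen on every outcome. The default combination
rule removes items that are bivariate-null AND isolated in at least one
fitted model — nullity is treated as necessary and network isolation as
corroborating, which reproduces the published workflow's behaviour of
retaining isolated-but-outcome-associated items.

``run_pipeline`` executes the whole analysis: cohort generation (or
loading), coding and dichotomization, bivariate screening, the three
network fits, centrality, optional bootstrap stability, removal-set
derivation (unioned across cohorts into one generalized index), and the
full-vs-reduced regression comparison.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .centrality import centrality_table
from .data_model import (
    MMIDefinition,
    MminetError,
    SurveyDataset,
    dichotomized_view,
)
from .mrf import DEFAULT_GAMMA, NetworkModel, PenaltyPath, fit_ggm, fit_ising, fit_mgm, make_fitter
from .regression import DEFAULT_COVARIATES, IndexComparison, compare_indices
from .screening import null_items, screen_all
from .stability import StabilityReport, stability_report
from .synthetic import CohortConfig, generate_cohort

__all__ = [
    "ShortFormReport",
    "PipelineConfig",
    "PipelineError",
    "PipelineResult",
    "isolated_nodes",
    "derive_removal_set",
    "run_pipeline",
]

RemovalRule = Literal["null_and_any_isolated", "null_only", "isolated_in_all"]


class PipelineError(MminetError):
    """A pipeline stage failed; ``partial`` carries the outputs produced so
    far."""

    def __init__(self, stage: str, message: str, partial=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.partial = partial


def isolated_nodes(model: NetworkModel, node_subset: Sequence[str]) -> set[str]:
    """Nodes in the subset whose weight row is entirely zero (exact-zero
    criterion: any nonzero edge, however small, counts as connected)."""
    unknown = [n for n in node_subset if n not in model.node_names]
    if unknown:
        raise KeyError(f"unknown node(s): {unknown}")
    out = set()
    for name in node_subset:
        i = model.node_names.index(name)
        if not np.any(model.weights[i]):
            out.add(name)
    return out


def derive_removal_set(
    isolation_sets: Mapping[str, set] | Sequence[set],
    bivariate_null: set,
    rule: RemovalRule = "null_and_any_isolated",
) -> set[str]:
    """Combine network-isolation and bivariate-null evidence into the set
    of items to drop from the index.

    Rules: ``null_and_any_isolated`` (default) — bivariate-null items that
    are isolated in at least one fitted model; ``null_only`` — the
    bivariate null set as-is; ``isolated_in_all`` — the intersection of
    all isolation sets.
    """
    sets = list(isolation_sets.values()) if isinstance(isolation_sets, Mapping) else list(isolation_sets)
    if rule == "null_only":
        return set(bivariate_null)
    if not sets:
        raise ValueError(f"rule {rule!r} needs at least one fitted model")
    if rule == "null_and_any_isolated":
        any_isolated = set().union(*sets)
        return set(bivariate_null) & any_isolated
    if rule == "isolated_in_all":
        return set.intersection(*map(set, sets))
    raise ValueError(f"unknown removal rule {rule!r}")


@dataclass
class ShortFormReport:
    """Provenance of one short-form derivation."""

    isolation_sets: dict            # "cohort/family" -> set of isolated SHCs
    bivariate_null: dict            # cohort label -> null set
    removal_set: set
    retained_index: MMIDefinition
    rule_used: dict                 # rule tag + parameters

    def to_dict(self) -> dict:
        return {
            "isolation_sets": {k: sorted(v) for k, v in self.isolation_sets.items()},
            "bivariate_null": {k: sorted(v) for k, v in self.bivariate_null.items()},
            "removal_set": sorted(self.removal_set),
            "retained_index": list(self.retained_index.item_names),
            "rule_used": self.rule_used,
        }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Settings for one end-to-end run.

    By default two synthetic cohorts are analysed (mirroring a two-cohort
    survey) and their removal sets are unioned into one generalized
    reduced index. Stability analysis is opt-in because of its cost.
    """

    cohorts: Sequence[CohortConfig] | None = None
    n_cohorts: int = 2
    cohort_n: int = 4000
    gamma: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GAMMA))
    path: PenaltyPath = field(default_factory=PenaltyPath)
    rule: Literal["AND", "OR"] = "AND"
    alpha: float = 0.05
    removal_rule: RemovalRule = "null_and_any_isolated"
    include_age_in_mgm: bool = True
    with_stability: bool = False
    with_comparison: bool = True
    stability_families: Sequence[str] = ("ggm",)
    stability_B_edges: int = 1000
    stability_B_drop: int = 250
    covariates: Sequence[str] = DEFAULT_COVARIATES
    seed: int = 0

    def resolve_cohorts(self) -> list[CohortConfig]:
        if self.cohorts is not None:
            return list(self.cohorts)
        seeds = np.random.default_rng(self.seed).integers(2**31 - 1, size=self.n_cohorts)
        return [
            CohortConfig(n=self.cohort_n, seed=int(s), cohort_label=f"cohort{i}")
            for i, s in enumerate(seeds)
        ]


@dataclass
class CohortResult:
    """All per-cohort artifacts produced by the pipeline."""

    dataset: SurveyDataset
    truth_record: dict | None
    screen: pd.DataFrame
    null_set: set
    models: dict                 # family -> NetworkModel
    centralities: dict           # family -> DataFrame
    isolation_sets: dict         # family -> set
    removal_set: set
    stability: dict              # family -> StabilityReport (may be empty)
    comparison: IndexComparison | None = None


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort_results: list
    report: ShortFormReport
    full_index: MMIDefinition

    def save(self, outdir: str | Path) -> None:
        """Serialize every stage's output under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cr in self.cohort_results:
            label = cr.dataset.cohort_label
            cdir = outdir / label
            cdir.mkdir(exist_ok=True)
            cr.screen.to_csv(cdir / "bivariate_screen.csv", index=False)
            for family, model in cr.models.items():
                model.to_json(cdir / f"network_{family}.json")
                model.edge_list().to_csv(cdir / f"edges_{family}.csv", index=False)
                cr.centralities[family].to_csv(cdir / f"centrality_{family}.csv", index=False)
            for family, rep in cr.stability.items():
                (cdir / f"stability_{family}.json").write_text(
                    json.dumps(rep.summary(), indent=2)
                )
            if cr.comparison is not None:
                cr.comparison.agreement.to_csv(cdir / "index_comparison.csv")
                for arm, results in (("full", cr.comparison.results_full),
                                     ("reduced", cr.comparison.results_reduced)):
                    for outcome, rr in results.items():
                        rr.table.to_csv(
                            cdir / f"regression_{outcome}_{arm}.csv",
                            index_label="term",
                        )
        (outdir / "shortform_report.json").write_text(
            json.dumps(self.report.to_dict(), indent=2)
        )
        (outdir / "retained_index.txt").write_text(
            "\n".join(self.report.retained_index.item_names) + "\n"
        )
        import mminet

        manifest = {
            "mminet_version": mminet.__version__,
            "seed": self.config.seed,
            "config": _config_to_jsonable(self.config),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def conv(v):
        if isinstance(v, PenaltyPath):
            return dataclasses.asdict(v)
        if isinstance(v, Mapping):
            return dict(v)
        if isinstance(v, (list, tuple)):
            return list(v)
        if isinstance(v, (CohortConfig,)):
            return {"n": v.n, "seed": v.seed, "cohort_label": v.cohort_label}
        return v

    return {
        f.name: conv(getattr(config, f.name))
        for f in dataclasses.fields(config)
        if f.name != "cohorts"
    } | {"cohorts": [conv(c) for c in (config.cohorts or [])]}


def _complete_case(df: pd.DataFrame) -> pd.DataFrame:
    return df.dropna()


def _fit_cohort_networks(
    dv: SurveyDataset, config: PipelineConfig
) -> dict[str, NetworkModel]:
    """Fit the three families with their study-default node sets.

    GGM: SHCs plus all five (dichotomized) outcomes, Pearson correlations
    on the coded 0/1 and continuous values. Ising: SHCs plus the binary
    outcomes only (continuous variables excluded). MGM: SHCs, all
    outcomes and optionally age, with declared kinds.
    """
    shc = dv.shc_names
    outcomes = dv.outcome_names
    binary_outcomes = [o for o in outcomes if dv.spec(o).kind == "binary"]

    models: dict[str, NetworkModel] = {}
    ggm_data = _complete_case(dv.values[shc + outcomes])
    models["ggm"] = fit_ggm(ggm_data, gamma=config.gamma["ggm"], path=config.path)

    ising_data = _complete_case(dv.values[shc + binary_outcomes])
    models["ising"] = fit_ising(
        ising_data, gamma=config.gamma["ising"], path=config.path, rule=config.rule
    )

    mgm_cols = shc + outcomes + (["age"] if config.include_age_in_mgm else [])
    mgm_data = _complete_case(dv.values[mgm_cols])
    kinds = {c: ("continuous" if dv.spec(c).kind == "continuous" else "binary")
             for c in mgm_cols}
    models["mgm"] = fit_mgm(
        mgm_data, kinds=kinds, gamma=config.gamma["mgm"], path=config.path,
        rule=config.rule,
    )
    return models


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Execute the full analysis; deterministic given ``config.seed``.

    Stages per cohort: generate/load -> dichotomize -> bivariate screen ->
    three network fits -> centrality -> (optional) stability -> per-cohort
    removal set. Removal sets are unioned across cohorts into one
    generalized reduced index, and the full-vs-reduced regression
    comparison runs per cohort. Any stage failure raises a stage-tagged
    :class:`PipelineError` carrying the partial outputs.
    """
    config = config or PipelineConfig()
    cohort_results: list[CohortResult] = []
    stage = "setup"
    try:
        stage = "simulate"
        cohort_configs = config.resolve_cohorts()
        datasets: list[tuple[SurveyDataset, dict | None]] = [
            generate_cohort(cc) for cc in cohort_configs
        ]

        full_items = None
        for dataset, truth in datasets:
            label = dataset.cohort_label
            stage = f"code:{label}"
            dv = dichotomized_view(dataset)
            if full_items is None:
                full_items = tuple(dv.shc_names)

            stage = f"screen:{label}"
            screen = screen_all(dv)
            null_set = null_items(screen, alpha=config.alpha)

            stage = f"fit:{label}"
            models = _fit_cohort_networks(dv, config)

            stage = f"centrality:{label}"
            centralities = {fam: centrality_table(m) for fam, m in models.items()}
            isolation = {
                fam: isolated_nodes(m, dv.shc_names) for fam, m in models.items()
            }

            stability: dict[str, StabilityReport] = {}
            if config.with_stability:
                stage = f"stability:{label}"
                shc_out = dv.shc_names + dv.outcome_names
                stab_data = _complete_case(dv.values[shc_out])
                for fam in config.stability_families:
                    fitter = make_fitter(
                        fam, gamma=config.gamma[fam], path=config.path,
                        rule=config.rule,
                        kinds={c: ("continuous" if dv.spec(c).kind == "continuous"
                                   else "binary") for c in shc_out},
                    )
                    stability[fam] = stability_report(
                        stab_data, fitter,
                        B_edges=config.stability_B_edges,
                        B_drop=config.stability_B_drop,
                        seed=config.seed,
                    )

            stage = f"removal:{label}"
            removal = derive_removal_set(isolation, null_set, rule=config.removal_rule)
            cohort_results.append(
                CohortResult(
                    dataset=dataset, truth_record=truth, screen=screen,
                    null_set=null_set, models=models, centralities=centralities,
                    isolation_sets=isolation, removal_set=removal,
                    stability=stability,
                )
            )

        stage = "shortform"
        union_removal = set().union(*(cr.removal_set for cr in cohort_results))
        # a removed item must remain a strict subset of the instrument
        full_index = MMIDefinition(full_items)
        retained = full_index.without(union_removal)
        report = ShortFormReport(
            isolation_sets={
                f"{cr.dataset.cohort_label}/{fam}": iso
                for cr in cohort_results
                for fam, iso in cr.isolation_sets.items()
            },
            bivariate_null={cr.dataset.cohort_label: cr.null_set for cr in cohort_results},
            removal_set=union_removal,
            retained_index=retained,
            rule_used={
                "rule": config.removal_rule,
                "alpha": config.alpha,
                "cohort_combination": "union",
            },
        )

        if config.with_comparison:
            stage = "compare"
            for cr in cohort_results:
                dv = dichotomized_view(cr.dataset)
                cr.comparison = compare_indices(
                    dv, full_index, retained, covariates=list(config.covariates),
                    alpha=config.alpha,
                )
    except MminetError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc), partial=cohort_results) from exc

    return PipelineResult(
        config=config,
        cohort_results=cohort_results,
        report=report,
        full_index=full_index,
    )
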