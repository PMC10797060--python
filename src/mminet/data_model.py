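"""Survey variable metadata, coding rules, multimorbidity scoring, and tabular I/O.

The instrument modelled here is a 30-item multimorbidity index (MMI) for
spinal-cord-injury community surveys: each secondary health condition (SHC)
is a binary present/absent item, and the index score is the plain sum of the
items. Outcome measures are a binary healthcare-utilization flag ("felt
needed care was not received"), two continuous health-status summaries
(PCS/MCS), and two ordinal satisfaction items (a 1-6 life-satisfaction item
and a 1-5 overall quality-of-life item) that are dichotomized before any
modelling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VariableSpec",
    "SurveyDataset",
    "MMIDefinition",
    "CodingError",
    "SchemaError",
    "MminetError",
    "code_shc",
    "dichotomize_outcome",
    "score_mmi",
    "load_cohort",
    "save_cohort",
    "load_specs",
    "dichotomized_view",
    "SHC_RESPONSE_CODES",
    "DICHOTOMY_CUTS",
]

Kind = Literal["binary", "continuous", "ordinal"]
Role = Literal["shc", "outcome", "covariate"]


class MminetError(Exception):
    """Base class for package errors."""


class CodingError(MminetError):
    """Unrecognized survey response token or out-of-range rating."""


class SchemaError(MminetError):
    """Dataset does not match its declared variable specs."""


# ---------------------------------------------------------------------------
# variable metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one survey variable.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"AD"`` (autonomic dysreflexia) or ``"PCS"``.
    kind : {"binary", "continuous", "ordinal"}
    role : {"shc", "outcome", "covariate"}
    levels : tuple of int, optional
        Admissible values for non-continuous kinds. Binary variables use
        ``(0, 1)``; ordinal levels must be consecutive integers.
    """

    name: str
    kind: Kind
    role: Role
    levels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "continuous", "ordinal"):
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role not in ("shc", "outcome", "covariate"):
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.role == "shc":
            if self.kind != "binary":
                raise SchemaError(f"SHC variable {self.name!r} must be binary")
        levels = self.levels
        if self.kind == "binary":
            levels = (0, 1) if levels is None else tuple(levels)
            if tuple(levels) != (0, 1):
                raise SchemaError(f"binary variable {self.name!r} must have levels (0, 1)")
        elif self.kind == "ordinal":
            if levels is None:
                raise SchemaError(f"ordinal variable {self.name!r} needs explicit levels")
            levels = tuple(int(v) for v in levels)
            if list(levels) != list(range(levels[0], levels[-1] + 1)):
                raise SchemaError(
                    f"ordinal levels for {self.name!r} must be consecutive integers"
                )
        elif levels is not None:
            raise SchemaError(f"continuous variable {self.name!r} cannot declare levels")
        object.__setattr__(self, "levels", levels)


@dataclass
class SurveyDataset:
    """A coded participant-by-variable table with its metadata.

    ``values`` rows are participants (unique index), columns are variables;
    every column must be declared in ``specs``. Binary columns contain only
    0/1/NaN, ordinal columns only their declared levels or NaN.
    """

    values: pd.DataFrame
    specs: list[VariableSpec]
    cohort_label: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in specs")
        missing = [c for c in self.values.columns if c not in names]
        if missing:
            raise SchemaError(f"columns without a spec: {missing}")
        if self.values.index.has_duplicates:
            raise SchemaError("duplicate participant identifiers")
        for s in self.specs:
            if s.name not in self.values.columns:
                continue
            col = self.values[s.name]
            if s.kind in ("binary", "ordinal"):
                ok = col.dropna().isin(s.levels)
                if not ok.all():
                    bad = sorted(col.dropna()[~ok].unique().tolist())
                    raise SchemaError(
                        f"column {s.name!r} contains values outside levels "
                        f"{s.levels}: {bad}"
                    )

    # -- convenience accessors ------------------------------------------------
    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def names_by_role(self, role: Role) -> list[str]:
        return [s.name for s in self.specs if s.role == role and s.name in self.values]

    @property
    def shc_names(self) -> list[str]:
        return self.names_by_role("shc")

    @property
    def outcome_names(self) -> list[str]:
        return self.names_by_role("outcome")

    @property
    def covariate_names(self) -> list[str]:
        return self.names_by_role("covariate")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MMIDefinition:
    """An ordered list of SHC item names making up a multimorbidity index."""

    item_names: tuple[str, ...]

    def __post_init__(self) -> None:
        items = tuple(self.item_names)
        if len(items) != len(set(items)):
            raise SchemaError("duplicate items in index definition")
        if not 1 <= len(items) <= 30:
            raise SchemaError("index must contain between 1 and 30 items")
        object.__setattr__(self, "item_names", items)

    def __len__(self) -> int:
        return len(self.item_names)

    def without(self, removed: Iterable[str]) -> "MMIDefinition":
        removed = set(removed)
        return MMIDefinition(tuple(i for i in self.item_names if i not in removed))


# ---------------------------------------------------------------------------
# coding rules
# ---------------------------------------------------------------------------

#: Survey response tokens for an SHC item. "do not know" is coded as not
#: having the condition; a missing answer stays missing.
SHC_RESPONSE_CODES: dict[str, float] = {
    "present": 1.0,
    "absent": 0.0,
    "do_not_know": 0.0,
    "missing": np.nan,
}

#: Dichotomization rules for ordinal satisfaction scales, given as
#: (scale range, first level coded "satisfied"). The 1-6 life-satisfaction
#: item is split 1-4 vs 5-6; the 1-5 quality-of-life item 1-3 vs 4-5.
DICHOTOMY_CUTS: dict[str, tuple[tuple[int, int], int]] = {
    "lisat6": ((1, 6), 5),
    "qol5": ((1, 5), 4),
}


def code_shc(raw_response: str) -> float:
    """Code one SHC survey response to 0/1 (NaN for a missing answer).

    ``present`` -> 1; ``absent`` and ``do_not_know`` -> 0 (participants who
    do not know whether they have a condition are treated as not having it);
    ``missing`` -> NaN.
    """
    try:
        return SHC_RESPONSE_CODES[raw_response]
    except KeyError:
        raise CodingError(f"unrecognized SHC response token {raw_response!r}") from None


def dichotomize_outcome(value: float, scale: str, cut: int | None = None) -> int:
    """Dichotomize an ordinal satisfaction rating into 0 (not satisfied) / 1.

    Parameters
    ----------
    value : int
        The rating, within the scale's range.
    scale : {"lisat6", "qol5"}
    cut : int, optional
        Override the first level coded as 1 (defaults to the scale's
        standard cut: 5 for the 1-6 item, 4 for the 1-5 item).
    """
    if scale not in DICHOTOMY_CUTS:
        raise CodingError(f"unknown scale {scale!r}")
    (lo, hi), default_cut = DICHOTOMY_CUTS[scale]
    cut = default_cut if cut is None else cut
    if not (lo <= value <= hi) or value != int(value):
        raise CodingError(f"rating {value!r} outside {scale} range {lo}-{hi}")
    return int(value >= cut)


def score_mmi(dataset: SurveyDataset, index: MMIDefinition) -> pd.Series:
    """Per-participant index score: the sum of the index's SHC items.

    A participant with any missing item gets a missing score. The score
    ranges from 0 to the number of items (30 for the full instrument).
    """
    unknown = [i for i in index.item_names if i not in dataset.values.columns]
    if unknown:
        raise SchemaError(f"index items not in dataset: {unknown}")
    block = dataset.values[list(index.item_names)]
    score = block.sum(axis=1, skipna=False)
    score.name = f"MMI{len(index)}"
    return score


def dichotomized_view(dataset: SurveyDataset, cuts: dict[str, str] | None = None) -> SurveyDataset:
    """Return a copy of the dataset with ordinal outcome items dichotomized.

    ``cuts`` maps column name -> scale tag ("lisat6" or "qol5"); by default
    every ordinal-kind outcome variable is matched to a scale by its level
    range. The replaced columns become binary outcome variables with the
    same names, so downstream networks and screens see 0/1 columns.
    """
    values = dataset.values.copy()
    specs: list[VariableSpec] = []
    cuts = dict(cuts or {})
    for s in dataset.specs:
        if s.role == "outcome" and s.kind == "ordinal":
            scale = cuts.get(s.name)
            if scale is None:
                scale = "lisat6" if s.levels[-1] == 6 else "qol5"
            col = values[s.name]
            coded = col.map(lambda v: np.nan if pd.isna(v) else dichotomize_outcome(v, scale))
            values[s.name] = coded
            specs.append(VariableSpec(s.name, "binary", "outcome"))
        else:
            specs.append(s)
    return SurveyDataset(values=values, specs=specs, cohort_label=dataset.cohort_label)


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def load_specs(path: str | Path) -> list[VariableSpec]:
    """Read variable metadata from a YAML or JSON spec file.

    The file holds a list of mappings with keys ``name``, ``kind``, ``role``
    and optional ``levels``.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return [
        VariableSpec(
            name=d["name"],
            kind=d["kind"],
            role=d["role"],
            levels=tuple(d["levels"]) if d.get("levels") else None,
        )
        for d in raw
    ]


def load_cohort(
    path: str | Path,
    specs: Sequence[VariableSpec],
    cohort_label: str = "",
) -> SurveyDataset:
    """Load a delimited cohort file and apply the coding rules per spec.

    SHC columns may contain either response tokens (``present`` /
    ``absent`` / ``do_not_know`` / ``missing``) or already-coded 0/1 values.
    Columns not declared in ``specs`` are dropped with a warning; a declared
    column absent from the file is a schema error.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"cohort file not found: {path}")
    raw = pd.read_csv(path)
    if "participant_id" in raw.columns:
        raw = raw.set_index("participant_id")

    declared = {s.name: s for s in specs}
    missing = [n for n in declared if n not in raw.columns]
    if missing:
        raise SchemaError(f"declared columns missing from {path.name}: {missing}")
    extra = [c for c in raw.columns if c not in declared]
    if extra:
        warnings.warn(f"ignoring undeclared columns: {extra}", stacklevel=2)
        raw = raw.drop(columns=extra)

    coded = pd.DataFrame(index=raw.index)
    for name, s in declared.items():
        col = raw[name]
        if s.role == "shc" and col.dtype == object:
            col = col.map(lambda v: np.nan if pd.isna(v) else code_shc(str(v)))
        else:
            try:
                col = pd.to_numeric(col)
            except (ValueError, TypeError):
                bad = col[pd.to_numeric(col, errors="coerce").isna() & col.notna()]
                row = bad.index[0] if len(bad) else "?"
                raise SchemaError(
                    f"non-numeric value in column {name!r} at row {row!r}"
                ) from None
        coded[name] = col
    return SurveyDataset(values=coded, specs=list(specs), cohort_label=cohort_label)


def save_cohort(dataset: SurveyDataset, path: str | Path) -> None:
    """Write coded values to CSV plus a JSON sidecar with coding provenance."""
    path = Path(path)
    dataset.values.to_csv(path, index_label="participant_id")
    sidecar = {
        "cohort_label": dataset.cohort_label,
        "n": dataset.n,
        "coding": {
            "shc_tokens": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                           for k, v in SHC_RESPONSE_CODES.items()},
            "dichotomy_cuts": {k: {"range": v[0], "first_satisfied": v[1]}
                               for k, v in DICHOTOMY_CUTS.items()},
        },
        "specs": [
            {"name": s.name, "kind": s.kind, "role": s.role,
             "levels": list(s.levels) if s.levels else None}
            for s in dataset.specs
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
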