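"""Cohort table I/O, the biomarker panel, and blood-pressure classification.

A cohort is a participant-level table: demographics (sex, race, smoking
status, age), serum biomarker concentrations, and optional systolic/diastolic
blood pressure.  Missing entries (blank cells, ``NA``) are carried as NaN.
The biomarker panel declares each marker's role in the allostatic-load
construction: *primary* mediators (stress-axis hormones) feed the acute
stress score, *secondary* mediators (downstream cardiometabolic and
inflammatory markers) feed the secondary mediator score, each with a sign
encoding whether higher concentrations indicate more dysregulation (+1) or
less (-1, e.g. HDL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Biomarker",
    "BiomarkerPanel",
    "CohortTable",
    "ValidationError",
    "BPScheme",
    "classify_blood_pressure",
    "classify_bp_frame",
    "read_cohort",
    "write_scores",
    "DEMOGRAPHIC_COLUMNS",
    "SCORE_COLUMNS",
]


class ValidationError(ValueError):
    """A cohort table or panel violated a structural requirement."""


DEMOGRAPHIC_COLUMNS = ("participant_id", "sex", "race", "smoking_status", "age")
BP_COLUMNS = ("systolic_bp", "diastolic_bp")
#: deterministic output order for score files
SCORE_COLUMNS = ("acute_two", "acute_three", "secondary", "al_two", "al_three")

Role = Literal["primary", "secondary"]
BPScheme = Literal["two_class", "three_class"]


@dataclass(frozen=True)
class Biomarker:
    """One panel entry: a serum marker with its role, sign and units."""

    name: str
    role: Role
    sign: int
    units: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("biomarker name must be non-empty")
        if self.role not in ("primary", "secondary"):
            raise ValidationError(f"unknown role {self.role!r} for {self.name}")
        if self.sign not in (1, -1):
            raise ValidationError(f"sign must be +1 or -1, got {self.sign} for {self.name}")


@dataclass(frozen=True)
class BiomarkerPanel:
    """An ordered collection of biomarkers with unique names.

    The default panel is the seven-marker serum panel used throughout this
    package: primary mediators cortisol, epinephrine and noradrenaline (all
    sign +1), secondary mediators fibrinogen, CRP and HbA1c (sign +1) and HDL
    (sign -1, protective).
    """

    entries: tuple[Biomarker, ...]

    def __post_init__(self) -> None:
        names = [b.name for b in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("biomarker names must be unique")
        if not any(b.role == "primary" for b in self.entries):
            raise ValidationError("panel needs at least one primary mediator")
        if not any(b.role == "secondary" for b in self.entries):
            raise ValidationError("panel needs at least one secondary mediator")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.entries)

    @property
    def primary(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.entries if b.role == "primary")

    @property
    def secondary(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.entries if b.role == "secondary")

    def sign(self, name: str) -> int:
        for b in self.entries:
            if b.name == name:
                return b.sign
        raise KeyError(name)

    def subset(self, keep: Sequence[str]) -> "BiomarkerPanel":
        """Panel restricted to ``keep``, preserving order."""
        return BiomarkerPanel(tuple(b for b in self.entries if b.name in set(keep)))

    @classmethod
    def default(cls) -> "BiomarkerPanel":
        return cls(
            (
                Biomarker("cortisol", "primary", +1, "ng/mL"),
                Biomarker("epinephrine", "primary", +1, "ng/mL"),
                Biomarker("noradrenaline", "primary", +1, "ng/mL"),
                Biomarker("fibrinogen", "secondary", +1, "ug/mL"),
                Biomarker("crp", "secondary", +1, "ug/mL"),
                Biomarker("hba1c", "secondary", +1, "mg/mL"),
                Biomarker("hdl", "secondary", -1, "mg/mL"),
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BiomarkerPanel":
        """Load a panel from YAML: a list of {name, role, sign, units} maps."""
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        entries = tuple(
            Biomarker(
                name=e["name"],
                role=e["role"],
                sign=int(e.get("sign", 1)),
                units=e.get("units", ""),
            )
            for e in spec
        )
        return cls(entries)


# ---------------------------------------------------------------------------
# Blood-pressure classification
# ---------------------------------------------------------------------------
# Raw categories, ACC/AHA-style thresholds in mm Hg, highest severity wins:
#   stage 2   : systolic >= 140 or diastolic >= 90
#   stage 1   : systolic in [130, 140) or diastolic in [80, 90)
#   elevated  : systolic in [120, 130) and diastolic < 80
#   normal    : systolic < 120 and diastolic < 80

_THREE_CLASS = {0: 0, 1: 1, 2: 2, 3: 2}  # stage 1+2 collapse to "hypertensive"
_TWO_CLASS = {0: 0, 1: 1, 2: 1, 3: 1}  # anything above normal collapses


def _raw_bp_category(systolic: float, diastolic: float) -> int:
    if systolic >= 140 or diastolic >= 90:
        return 3
    if 130 <= systolic < 140 or 80 <= diastolic < 90:
        return 2
    if 120 <= systolic < 130 and diastolic < 80:
        return 1
    return 0


def classify_blood_pressure(
    systolic: float, diastolic: float, scheme: BPScheme = "three_class"
) -> float:
    """Ordinal blood-pressure class for one reading.

    ``three_class``: 0 = normal, 1 = elevated, 2 = hypertensive (stage 1 or 2).
    ``two_class``:   0 = normal, 1 = elevated or hypertensive.
    Missing input (NaN) yields NaN; such participants keep their biomarker
    scores but are excluded from weight fitting.
    """
    if scheme not in ("two_class", "three_class"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if systolic is None or diastolic is None:
        return float("nan")
    if np.isnan(systolic) or np.isnan(diastolic):
        return float("nan")
    if systolic <= 0 or diastolic <= 0:
        raise ValidationError(
            f"blood pressure must be positive, got {systolic}/{diastolic}"
        )
    raw = _raw_bp_category(float(systolic), float(diastolic))
    return float(_THREE_CLASS[raw] if scheme == "three_class" else _TWO_CLASS[raw])


def classify_bp_frame(data: pd.DataFrame, scheme: BPScheme) -> pd.Series:
    """Vectorised :func:`classify_blood_pressure` over a cohort frame."""
    return pd.Series(
        [
            classify_blood_pressure(s, d, scheme)
            for s, d in zip(data["systolic_bp"], data["diastolic_bp"])
        ],
        index=data.index,
        name=f"bp_{scheme}",
    )


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """A validated participant x {demographics, concentrations, BP} table.

    ``data`` holds one row per participant; biomarker columns are those named
    in ``panel``.  Concentration missingness is NaN.  BP columns may be absent
    entirely (treated as all-missing).
    """

    data: pd.DataFrame
    panel: BiomarkerPanel = field(default_factory=BiomarkerPanel.default)

    def __post_init__(self) -> None:
        df = self.data
        if len(df) == 0:
            raise ValidationError("empty cohort")
        if "participant_id" not in df.columns:
            raise ValidationError("missing participant_id column")
        dup = df["participant_id"][df["participant_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate participant ids: {sorted(set(dup))}")
        for col in BP_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        for name in self.panel.names:
            if name not in df.columns:
                raise ValidationError(f"panel biomarker {name!r} missing from table")
            vals = pd.to_numeric(df[name], errors="coerce")
            neg = vals < 0
            if neg.any():
                row = df.loc[neg, "participant_id"].iloc[0]
                raise ValidationError(
                    f"negative concentration for {name!r} at participant {row!r}"
                )
            df[name] = vals
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def concentrations(self) -> pd.DataFrame:
        """Participant x biomarker concentration matrix (NaN = missing)."""
        return self.data[list(self.panel.names)]

    def with_concentrations(self, values: pd.DataFrame) -> "CohortTable":
        """Copy of the cohort with biomarker columns replaced by ``values``."""
        df = self.data.copy()
        for col in values.columns:
            df[col] = values[col].to_numpy()
        return CohortTable(df, self.panel)


def _load_column_map(column_map: Mapping[str, str] | str | Path | None) -> dict:
    if column_map is None:
        return {}
    if isinstance(column_map, (str, Path)):
        with open(column_map) as fh:
            column_map = yaml.safe_load(fh) or {}
    return {str(k): str(v) for k, v in dict(column_map).items()}


def read_cohort(
    path: str | Path,
    panel: BiomarkerPanel | None = None,
    column_map: Mapping[str, str] | str | Path | None = None,
    delimiter: str | None = None,
) -> CohortTable:
    """Read a delimited cohort table and validate it against ``panel``.

    The file needs a header row; the delimiter is sniffed unless given.
    ``column_map`` (dict or YAML file) renames arbitrary input headers to the
    canonical names (``participant_id``, demographics, panel biomarker names,
    ``systolic_bp``/``diastolic_bp``).  Blank cells and ``NA`` become missing.
    Unrecognised columns are dropped with a warning.
    """
    panel = panel or BiomarkerPanel.default()
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        na_values=["", "NA"],
        keep_default_na=True,
        skipinitialspace=True,
    )
    mapping = _load_column_map(column_map)
    if mapping:
        df = df.rename(columns=mapping)
    known = set(DEMOGRAPHIC_COLUMNS) | set(BP_COLUMNS) | set(panel.names)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"ignoring unrecognised columns: {unknown}", stacklevel=2)
        df = df.drop(columns=unknown)
    if len(df) == 0:
        raise ValidationError("empty cohort")
    return CohortTable(df, panel)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a score table as CSV with a deterministic column order.

    Expects the frame produced by the scoring pipeline: demographics followed
    by the five score columns (acute and AL under both weight schemes, plus
    the secondary mediator score).
    """
    if scores is None or len(scores) == 0:
        raise ValidationError("refusing to write an empty score set")
    missing = [c for c in SCORE_COLUMNS if c not in scores.columns]
    if missing:
        raise ValidationError(f"score set lacks columns {missing}")
    lead = [c for c in DEMOGRAPHIC_COLUMNS if c in scores.columns]
    rest = [
        c for c in scores.columns if c not in lead and c not in SCORE_COLUMNS
    ]
    ordered = scores[lead + sorted(rest) + list(SCORE_COLUMNS)]
    ordered.to_csv(path, index=False)
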