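"""Inclusion filtering and design-matrix encoding of Utstein-style records.

Encoding follows the registry-modelling convention for this kind of cohort:

* categorical items are one-hot encoded with an explicit ``missing`` level,
* always-observed continuous items (age, intervention counts) are
  standardized with statistics fitted on the training records only,
* the adjustable response/transport times (call-to-contact,
  contact-to-arrival) are kept as raw, unstandardized minutes so that
  counterfactual deltas act in natural units,
* interventions not performed on everyone (defibrillation, adrenaline) are
  one-hot encoded jointly for non-performance and for the contact-to-
  performance time, by integer minute bin (the default schema), or
  alternatively as a non-performance flag plus a raw time channel.

The default shipped schema encodes the 24 activity items into exactly 145
input columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .cohort import CATEGORICAL_LEVELS

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "DataError",
    "Encoder",
    "FeatureSchema",
    "EncodedMatrix",
    "apply_inclusion_filters",
    "build_schema",
    "default_declarations",
    "default_schema",
    "fit_encode",
    "transform",
]


class SchemaError(ValueError):
    """Invalid or mismatched feature-schema declaration."""


class DataError(ValueError):
    """Record data violating a preprocessing precondition."""


# ---------------------------------------------------------------------------
# inclusion filters

def apply_inclusion_filters(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep adult (>= 18 y) cardiogenic arrests; tally exclusions by reason.

    Returns the included records (original row index preserved) and a tally
    with keys ``recorded``, ``under_18``, ``non_cardiogenic``,
    ``excluded`` (union) and ``included``.
    """
    for col in ("age_years", "cause_cardiogenic"):
        if col not in records.columns:
            raise DataError(f"records are missing required column {col!r}")
        bad = records.index[pd.isna(records[col])]
        if len(bad):
            raise DataError(f"{col!r} missing for row(s) {list(bad[:5])}")
    under18 = records["age_years"].to_numpy(dtype=float) < 18
    noncardio = records["cause_cardiogenic"].to_numpy(dtype=float) == 0
    keep = ~(under18 | noncardio)
    tally = {
        "recorded": int(len(records)),
        "under_18": int(under18.sum()),
        "non_cardiogenic": int(noncardio.sum()),
        "excluded": int((~keep).sum()),
        "included": int(keep.sum()),
    }
    return records.loc[keep].copy(), tally


# ---------------------------------------------------------------------------
# schema

@dataclass(frozen=True)
class Encoder:
    """One source item (or intervention item pair) -> encoded column block.

    kind is one of
      ``onehot_missing``          levels + explicit missing level
      ``standardized``            z-scored continuous column
      ``raw_minutes``             unstandardized minutes (adjustable channel)
      ``intervention_onehot``     not_performed + one column per minute bin
      ``intervention_flag_time``  non-performance flag + raw time channel
    """

    name: str
    kind: str
    fields: tuple[str, ...]
    levels: tuple[str, ...] = ()
    max_minute: int = 0

    @property
    def width(self) -> int:
        if self.kind == "onehot_missing":
            return len(self.levels) + 1
        if self.kind in ("standardized", "raw_minutes"):
            return 1
        if self.kind == "intervention_onehot":
            return self.max_minute + 2
        if self.kind == "intervention_flag_time":
            return 2
        raise SchemaError(f"unknown encoder kind {self.kind!r}")

    @property
    def columns(self) -> list[str]:
        if self.kind == "onehot_missing":
            return [f"{self.name}={lv}" for lv in self.levels] + [f"{self.name}=missing"]
        if self.kind == "standardized":
            return [f"{self.name}_z"]
        if self.kind == "raw_minutes":
            return [f"{self.name}_min"]
        if self.kind == "intervention_onehot":
            return [f"{self.name}=not_performed"] + [
                f"{self.name}=min{m}" for m in range(self.max_minute + 1)
            ]
        return [f"{self.name}=not_performed", f"{self.name}_time_min"]


@dataclass(frozen=True)
class FeatureSchema:
    encoders: tuple[Encoder, ...]

    @property
    def width(self) -> int:
        return sum(e.width for e in self.encoders)

    @property
    def columns(self) -> list[str]:
        return [c for e in self.encoders for c in e.columns]

    @property
    def standardized_fields(self) -> list[str]:
        return [e.fields[0] for e in self.encoders if e.kind == "standardized"]

    @property
    def adjustable_columns(self) -> list[str]:
        """Raw-minute channels on which counterfactual deltas act directly."""
        return [e.columns[0] for e in self.encoders if e.kind == "raw_minutes"]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": e.name, "kind": e.kind, "fields": list(e.fields),
                    "levels": list(e.levels), "max_minute": e.max_minute,
                }
                for e in self.encoders
            ],
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "FeatureSchema":
        return FeatureSchema(tuple(
            Encoder(d["name"], d["kind"], tuple(d["fields"]),
                    tuple(d.get("levels", ())), int(d.get("max_minute", 0)))
            for d in json.loads(text)
        ))


def build_schema(declarations: Iterable[Encoder | dict]) -> FeatureSchema:
    """Assemble a FeatureSchema, rejecting duplicate source fields."""
    encs = []
    for d in declarations:
        encs.append(d if isinstance(d, Encoder) else Encoder(**d))
    seen: set[str] = set()
    for e in encs:
        e.width  # validates kind
        for f in e.fields:
            if f in seen:
                raise SchemaError(f"field {f!r} declared by more than one encoder")
            seen.add(f)
    return FeatureSchema(tuple(encs))


def default_declarations() -> list[Encoder]:
    """The shipped 24-item declaration set (total encoded width 145).

    Breakdown: 13 categoricals with a missing level (3+3+3+10+3+4+3+3+3+6
    +3+3+3 = 50), two standardized counts and standardized age (3), two raw
    adjustable minute channels (2), defibrillation one-hot over
    {not_performed, 0..38 min} (40) and adrenaline one-hot over
    {not_performed, 0..48 min} (50): 50+3+2+40+50 = 145.
    """
    cat = lambda f: Encoder(f, "onehot_missing", (f,), CATEGORICAL_LEVELS[f])
    return [
        Encoder("age_years", "standardized", ("age_years",)),
        cat("sex"),
        cat("guideline_era"),
        cat("witnessed"),
        cat("witness_type"),
        cat("bystander_cpr"),
        cat("bystander_cpr_actions"),
        cat("bystander_aed"),
        cat("ems_lifesaver"),
        cat("ems_doctor"),
        cat("first_rhythm"),
        cat("medication_route"),
        cat("advanced_airway"),
        cat("prehospital_rosc"),
        Encoder("defib_count", "standardized", ("defib_count",)),
        Encoder("adrenaline_count", "standardized", ("adrenaline_count",)),
        Encoder("call_to_contact", "raw_minutes", ("call_to_contact_min",)),
        Encoder("contact_to_arrival", "raw_minutes", ("contact_to_arrival_min",)),
        Encoder("defib", "intervention_onehot",
                ("defib_performed", "defib_time_min"), max_minute=38),
        Encoder("adrenaline", "intervention_onehot",
                ("adrenaline_given", "adrenaline_time_min"), max_minute=48),
    ]


def default_schema() -> FeatureSchema:
    return build_schema(default_declarations())


# ---------------------------------------------------------------------------
# encoding

@dataclass
class EncodedMatrix:
    values: np.ndarray
    columns: list[str]
    standardization: dict[str, tuple[float, float]]
    row_index: pd.Index = field(default_factory=lambda: pd.Index([]))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns, index=self.row_index)


def _encode_block(e: Encoder, records: pd.DataFrame,
                  standardization: dict[str, tuple[float, float]]) -> np.ndarray:
    n = len(records)
    if e.kind == "onehot_missing":
        raw = records[e.fields[0]].astype(object).fillna("").to_numpy()
        out = np.zeros((n, e.width))
        index = {lv: j for j, lv in enumerate(e.levels)}
        missing_j = e.width - 1
        unseen = 0
        for i, v in enumerate(raw):
            j = index.get(v)
            if j is None:
                if v != "":
                    unseen += 1
                j = missing_j
            out[i, j] = 1.0
        if unseen:
            logger.warning("%d unseen level(s) in %r mapped to the missing level",
                           unseen, e.name)
        return out
    if e.kind == "standardized":
        x = records[e.fields[0]].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise DataError(f"standardized field {e.fields[0]!r} contains missing values")
        mean, sd = standardization[e.name]
        return ((x - mean) / sd)[:, None]
    if e.kind == "raw_minutes":
        x = records[e.fields[0]].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise DataError(f"raw-minute field {e.fields[0]!r} contains missing values")
        return x[:, None]
    flag_f, time_f = e.fields
    performed = records[flag_f].to_numpy(dtype=float) != 0
    t = records[time_f].to_numpy(dtype=float)
    if np.isnan(t[performed]).any():
        raise DataError(f"{time_f!r} missing for performed intervention rows")
    if e.kind == "intervention_onehot":
        out = np.zeros((n, e.width))
        bins = np.clip(np.floor(np.nan_to_num(t)), 0, e.max_minute).astype(int)
        out[~performed, 0] = 1.0
        rows = np.nonzero(performed)[0]
        out[rows, 1 + bins[rows]] = 1.0
        return out
    # intervention_flag_time: not-performed flag, time channel 0 when absent
    out = np.zeros((n, 2))
    out[:, 0] = (~performed).astype(float)
    out[:, 1] = np.where(performed, np.nan_to_num(t), 0.0)
    return out


def fit_encode(records: pd.DataFrame, schema: FeatureSchema) -> EncodedMatrix:
    """Fit standardization on these records and encode them.

    Standardization statistics (population mean / sd) come from exactly the
    rows passed here — hand in the training portion only to avoid leakage.
    Zero-variance continuous columns fall back to sd = 1 with a warning.
    """
    standardization: dict[str, tuple[float, float]] = {}
    for e in schema.encoders:
        if e.kind == "standardized":
            x = records[e.fields[0]].to_numpy(dtype=float)
            if np.isnan(x).any():
                raise DataError(f"standardized field {e.fields[0]!r} contains missing values")
            mean = float(np.mean(x)) if len(x) else 0.0
            sd = float(np.std(x)) if len(x) else 1.0
            if sd == 0.0:
                logger.warning("zero variance in %r; falling back to sd = 1", e.name)
                sd = 1.0
            standardization[e.name] = (mean, sd)
    return transform(records, schema, standardization)


def transform(records: pd.DataFrame, schema: FeatureSchema,
              standardization: dict[str, tuple[float, float]]) -> EncodedMatrix:
    """Encode records with previously fitted statistics (never re-fits)."""
    expected = {e.name for e in schema.encoders if e.kind == "standardized"}
    if set(standardization) != expected:
        raise SchemaError(
            f"standardization parameters {sorted(standardization)} do not match "
            f"schema's standardized encoders {sorted(expected)}"
        )
    missing_cols = [f for e in schema.encoders for f in e.fields if f not in records.columns]
    if missing_cols:
        raise SchemaError(f"records lack source field(s) {missing_cols}")
    blocks = [_encode_block(e, records, standardization) for e in schema.encoders]
    values = np.hstack(blocks) if blocks else np.zeros((len(records), 0))
    if not np.isfinite(values).all():
        raise DataError("encoded matrix contains non-finite values")
    return EncodedMatrix(values, schema.columns, dict(standardization), records.index)


def save_encoded(matrix: EncodedMatrix, csv_path, sidecar_path) -> None:
    """Dense CSV of the design matrix plus a JSON sidecar of fitted statistics."""
    matrix.frame().to_csv(csv_path, index_label="row", lineterminator="\n")
    with open(sidecar_path, "w") as fh:
        json.dump({"columns": matrix.columns,
                   "standardization": matrix.standardization}, fh, indent=1)
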