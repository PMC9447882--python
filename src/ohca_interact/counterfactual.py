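"""Counterfactual single- and two-factor time sweeps on held-out records.

The what-if question: how would the mean predicted probability of a
favorable outcome (CPC 1/2) over the test cohort change if EMS had been
faster (or slower) on one or two time factors — transport to hospital,
first defibrillation, first drug — for the records where the intervention
applies?  Each sweep adjusts the *raw* records (minutes added or
subtracted, floored at zero), re-encodes them with the stored training-time
transform, averages the four cross-validation models' predictions, and
reports the percent change relative to the unadjusted baseline.

Eligibility follows clinical practice: defibrillation times are only
adjusted for cases whose initial rhythm was shockable (VF / pulseless VT)
and who were actually defibrillated; drug times only for cases given
adrenaline whose arrest was not witnessed by EMS personnel (fire fighter,
paramedic, emergency lifesaver — for those the drug is given almost
immediately and the counterfactual is meaningless).  Ineligible records are
passed through untouched and dilute the averaged change, mirroring a
baseline defined over the full test set.

Grid cells outside the range of times seen in training are extrapolations;
:class:`HeatmapGrid` therefore records, per axis delta, the fraction of
training records whose factor value lies within the adjusted eligible
range ("trained-region" coverage).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import EMS_WITNESS_TYPES, SHOCKABLE_RHYTHMS

__all__ = [
    "AdjustmentSpec",
    "HeatmapGrid",
    "AdjustmentError",
    "adjust_records",
    "eligibility_mask",
    "summarize_predictions",
    "relative_change",
    "single_factor_sweep",
    "two_factor_grid",
    "interaction_logit_residual",
    "DEFAULT_SINGLE_FACTOR_DELTAS",
]


class AdjustmentError(ValueError):
    pass


#: factor name -> (record column, default eligibility predicate)
FACTORS: dict[str, tuple[str, str]] = {
    "age_years": ("age_years", "all"),
    "call_to_contact": ("call_to_contact_min", "all"),
    "contact_to_arrival": ("contact_to_arrival_min", "all"),
    "contact_to_first_defib": ("defib_time_min", "shockable_initial_rhythm"),
    "contact_to_first_drug": ("adrenaline_time_min", "drug_eligible_not_ems_witnessed"),
}

#: the conventional single-factor sensitivity deltas
DEFAULT_SINGLE_FACTOR_DELTAS: dict[str, tuple[float, ...]] = {
    "age_years": (-5.0, 5.0),
    "call_to_contact": (10.0, 20.0),
    "contact_to_arrival": (-5.0, 10.0, 20.0),
}


@dataclass(frozen=True)
class AdjustmentSpec:
    """One factor perturbation: delta minutes (years for age) + eligibility."""

    factor: str
    delta: float
    eligibility: str | None = None  # default predicate of the factor
    clamp_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.factor not in FACTORS:
            raise AdjustmentError(
                f"unknown factor {self.factor!r}; expected one of {sorted(FACTORS)}"
            )

    @property
    def column(self) -> str:
        return FACTORS[self.factor][0]

    @property
    def predicate(self) -> str:
        return self.eligibility or FACTORS[self.factor][1]


def eligibility_mask(records: pd.DataFrame, spec: AdjustmentSpec) -> np.ndarray:
    """Boolean mask of records whose factor value the spec may modify."""
    name = spec.predicate
    if name == "all":
        mask = np.ones(len(records), dtype=bool)
    elif name == "shockable_initial_rhythm":
        mask = (
            records["first_rhythm"].isin(SHOCKABLE_RHYTHMS)
            & (records["defib_performed"].to_numpy(dtype=float) != 0)
        ).to_numpy()
    elif name == "drug_eligible_not_ems_witnessed":
        mask = (
            (records["adrenaline_given"].to_numpy(dtype=float) != 0)
            & ~records["witness_type"].isin(EMS_WITNESS_TYPES).to_numpy()
        )
    else:
        raise AdjustmentError(f"unknown eligibility predicate {name!r}")
    # never touch an absent value (intervention not performed)
    return mask & ~pd.isna(records[spec.column]).to_numpy()


def adjust_records(records: pd.DataFrame, spec: AdjustmentSpec) -> pd.DataFrame:
    """Return a copy with the factor shifted for eligible records only."""
    out = records.copy()
    mask = eligibility_mask(records, spec)
    col = spec.column
    vals = out.loc[mask, col].to_numpy(dtype=float) + spec.delta
    out.loc[mask, col] = np.maximum(vals, spec.clamp_floor)
    return out


def summarize_predictions(
    predict: Callable[[pd.DataFrame], np.ndarray],
    records: pd.DataFrame,
    summary_mode: str = "mean_probability",
    threshold: float = 0.5,
) -> float:
    """Collapse ensemble predictions over a record set to one summary number.

    ``predict`` maps raw records to the stacked member probabilities (shape
    (n_models, n_records)) or to a single probability vector.  In
    ``mean_probability`` mode the summary is the grand mean over models and
    records; in ``predicted_positive_count`` mode it is the mean over models
    of the count of records at or above the threshold.
    """
    if len(records) == 0:
        raise AdjustmentError("cannot summarize predictions over an empty record set")
    p = np.atleast_2d(np.asarray(predict(records), dtype=float))
    if summary_mode == "mean_probability":
        return float(p.mean())
    if summary_mode == "predicted_positive_count":
        return float((p >= threshold).sum(axis=1).mean())
    raise AdjustmentError(f"unknown summary_mode {summary_mode!r}")


def relative_change(adjusted: float, baseline: float) -> float:
    """Percent change of the adjusted summary versus the unadjusted baseline."""
    if baseline == 0:
        raise AdjustmentError("baseline summary is 0; relative change undefined")
    return 100.0 * (adjusted - baseline) / baseline


def single_factor_sweep(
    predict: Callable[[pd.DataFrame], np.ndarray],
    records: pd.DataFrame,
    factor: str,
    deltas: Sequence[float] | None = None,
    summary_mode: str = "mean_probability",
    threshold: float = 0.5,
) -> dict[float, float]:
    """delta -> percent change of the summary, one factor at a time."""
    if deltas is None:
        deltas = DEFAULT_SINGLE_FACTOR_DELTAS.get(factor)
        if deltas is None:
            raise AdjustmentError(f"no default deltas for factor {factor!r}")
    if len(deltas) == 0:
        raise AdjustmentError("deltas must be nonempty")
    baseline = summarize_predictions(predict, records, summary_mode, threshold)
    out: dict[float, float] = {}
    for d in deltas:
        adj = adjust_records(records, AdjustmentSpec(factor, float(d)))
        out[float(d)] = relative_change(
            summarize_predictions(predict, adj, summary_mode, threshold), baseline
        )
    return out


@dataclass
class HeatmapGrid:
    """Two-factor sweep result: percent change per (delta_a, delta_b) cell."""

    factor_a: str
    factor_b: str
    deltas_a: list[float]
    deltas_b: list[float]
    values: np.ndarray  # shape (len(deltas_a), len(deltas_b)), percent
    baseline: float
    summary_mode: str
    n_eligible: dict[str, int]
    train_coverage_a: list[float] | None = None
    train_coverage_b: list[float] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.deltas_a, columns=self.deltas_b)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(
            path, index_label=f"{self.factor_a}\\{self.factor_b}", lineterminator="\n"
        )

    def sidecar(self) -> dict:
        return {
            "factor_a": self.factor_a,
            "factor_b": self.factor_b,
            "deltas_a": self.deltas_a,
            "deltas_b": self.deltas_b,
            "baseline": self.baseline,
            "summary_mode": self.summary_mode,
            "n_eligible": self.n_eligible,
            "train_coverage_a": self.train_coverage_a,
            "train_coverage_b": self.train_coverage_b,
        }


def interaction_logit_residual(
    predict: Callable[[pd.DataFrame], np.ndarray],
    records: pd.DataFrame,
    factor_a: str,
    delta_a: float,
    factor_b: str,
    delta_b: float,
    clamp_floor: float = 0.0,
) -> float:
    """Interaction diagnostic: mean log-odds difference-in-differences.

    Percent-change grids conflate true factor interaction with the curvature
    of the logistic link — two purely additive log-odds effects still
    multiply on the probability scale, so the percent-scale DiD
    ``cell(a,b) - cell(a,0) - cell(0,b) + cell(0,0)`` is nonzero (and its
    sign follows the product of the main effects) even without interaction.
    On the log-odds scale that curvature vanishes: under a generative model
    ``logit p = ... + g * t_a * t_b`` the per-record DiD

        logit p(a,b) - logit p(a,0) - logit p(0,b) + logit p(0,0)

    equals exactly ``g * delta_a * delta_b`` (absent clamping), so the mean
    over jointly eligible records estimates the interaction coefficient's
    contribution, sign included.  Restricted to records eligible for both
    factors (ineligible records contribute exactly zero).
    """
    spec_a = AdjustmentSpec(factor_a, float(delta_a), clamp_floor=clamp_floor)
    spec_b = AdjustmentSpec(factor_b, float(delta_b), clamp_floor=clamp_floor)
    mask = eligibility_mask(records, spec_a) & eligibility_mask(records, spec_b)
    if not mask.any():
        raise AdjustmentError("no records are eligible for both factors")
    sub = records.loc[mask]

    def mean_member_prob(frame: pd.DataFrame) -> np.ndarray:
        return np.atleast_2d(np.asarray(predict(frame), dtype=float)).mean(axis=0)

    def logit(p: np.ndarray) -> np.ndarray:
        # robust down to denormal probabilities (log(p) - log1p(-p))
        p = np.clip(p, 1e-300, np.nextafter(1.0, 0.0))
        return np.log(p) - np.log1p(-p)

    p00 = logit(mean_member_prob(sub))
    pa0 = logit(mean_member_prob(adjust_records(sub, spec_a)))
    p0b = logit(mean_member_prob(adjust_records(sub, spec_b)))
    pab = logit(mean_member_prob(adjust_records(adjust_records(sub, spec_a), spec_b)))
    return float(np.mean(pab - pa0 - p0b + p00))


def _train_coverage(train_records: pd.DataFrame, spec_proto: AdjustmentSpec,
                    eligible_values: np.ndarray, deltas: Sequence[float]) -> list[float]:
    """Fraction of training values inside each delta's adjusted eligible range."""
    train_vals = train_records[spec_proto.column].dropna().to_numpy(dtype=float)
    cover = []
    for d in deltas:
        adj = np.maximum(eligible_values + d, spec_proto.clamp_floor)
        if len(adj) == 0 or len(train_vals) == 0:
            cover.append(float("nan"))
            continue
        lo, hi = float(adj.min()), float(adj.max())
        cover.append(float(np.mean((train_vals >= lo) & (train_vals <= hi))))
    return cover


def two_factor_grid(
    predict: Callable[[pd.DataFrame], np.ndarray],
    records: pd.DataFrame,
    factor_a: str,
    deltas_a: Sequence[float],
    factor_b: str,
    deltas_b: Sequence[float],
    summary_mode: str = "mean_probability",
    threshold: float = 0.5,
    clamp_floor: float = 0.0,
    train_records: pd.DataFrame | None = None,
) -> HeatmapGrid:
    """Simultaneous two-factor sweep rendered as a percent-change grid.

    Cell (i, j) adjusts factor_a by ``deltas_a[i]`` and factor_b by
    ``deltas_b[j]`` (each under its own eligibility mask), re-predicts, and
    reports the percent change versus the single unadjusted baseline.  Both
    axes must contain 0 so the grid has an exact zero at no adjustment.
    """
    if factor_a == factor_b:
        raise AdjustmentError("the two axes must target different factors")
    deltas_a = [float(d) for d in deltas_a]
    deltas_b = [float(d) for d in deltas_b]
    if 0.0 not in deltas_a or 0.0 not in deltas_b:
        raise AdjustmentError("each axis must include delta = 0 (the baseline cell)")

    proto_a = AdjustmentSpec(factor_a, 0.0, clamp_floor=clamp_floor)
    proto_b = AdjustmentSpec(factor_b, 0.0, clamp_floor=clamp_floor)
    baseline = summarize_predictions(predict, records, summary_mode, threshold)
    values = np.empty((len(deltas_a), len(deltas_b)))
    for i, da in enumerate(deltas_a):
        adj_a = adjust_records(records, replace(proto_a, delta=da))
        for j, db in enumerate(deltas_b):
            if da == 0.0 and db == 0.0:
                values[i, j] = 0.0  # exact by construction
                continue
            adj = adjust_records(adj_a, replace(proto_b, delta=db))
            values[i, j] = relative_change(
                summarize_predictions(predict, adj, summary_mode, threshold), baseline
            )

    mask_a = eligibility_mask(records, proto_a)
    mask_b = eligibility_mask(records, proto_b)
    cov_a = cov_b = None
    if train_records is not None:
        cov_a = _train_coverage(
            train_records, proto_a,
            records.loc[mask_a, proto_a.column].to_numpy(dtype=float), deltas_a)
        cov_b = _train_coverage(
            train_records, proto_b,
            records.loc[mask_b, proto_b.column].to_numpy(dtype=float), deltas_b)
    return HeatmapGrid(
        factor_a=factor_a, factor_b=factor_b,
        deltas_a=deltas_a, deltas_b=deltas_b,
        values=values, baseline=baseline, summary_mode=summary_mode,
        n_eligible={factor_a: int(mask_a.sum()), factor_b: int(mask_b.sum())},
        train_coverage_a=cov_a, train_coverage_b=cov_b,
    )
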