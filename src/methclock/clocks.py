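"""Linear epigenetic estimators with mean imputation.

All four estimators handled here — the Hannum-style and VISAGE-style
chronological-age clocks, the pace-of-aging score (PoAm) and the
continuous mortality risk score (MRS) — share one mathematical form:

    value = intercept + sum_i  weight_i * beta_i

over a fixed marker set, differing only in their marker lists, weights
and output units (years, pace-of-aging units, MRS units).  Markers absent
from a measurement (sub-threshold depth, platform gaps) are mean-imputed
before prediction; imputation counts are carried on every output so
heavily-imputed predictions are visible downstream.

The categorical mortality score is exposed through two routes: a
per-marker threshold rule (:func:`mrs_categorical`) counting risk-aberrant
CpGs on a 0-10 scale, and a quadratic map from the continuous score
(:func:`mrs_categorical_from_continuous`) for use with the published
cross-platform calibration.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .calibrate import Transform, apply_transform

INTERCEPT_KEY = "(Intercept)"


class ClockError(ValueError):
    """Raised for invalid clock models or incomplete inputs."""


@dataclass(frozen=True)
class ClockModel:
    """One linear estimator: intercept, per-marker weights, imputation means.

    ``output_units`` is purely descriptive ("years", "poam", "mrs").
    Every weighted marker must have an imputation mean in [0, 1].
    """

    name: str
    intercept: float
    weights: Mapping[str, float]
    imputation_means: Mapping[str, float]
    output_units: str = "years"

    def __post_init__(self) -> None:
        if not self.weights:
            raise ClockError(f"clock {self.name!r}: empty weight map")
        missing = set(self.weights) - set(self.imputation_means)
        if missing:
            raise ClockError(
                f"clock {self.name!r}: weighted markers lacking an imputation mean: "
                f"{sorted(missing)[:5]}"
            )
        for mid in self.weights:
            mu = self.imputation_means[mid]
            if not 0.0 <= mu <= 1.0:
                raise ClockError(f"clock {self.name!r}: imputation mean for {mid} "
                                 f"outside [0,1]: {mu}")

    @property
    def markers(self) -> tuple:
        return tuple(self.weights)


@dataclass(frozen=True)
class MrsRule:
    """Per-marker threshold rule for the categorical mortality score.

    ``directions[m]`` is +1 if a beta *above* ``thresholds[m]`` counts as
    risk-aberrant at marker ``m``, -1 if a beta below does.
    """

    thresholds: Mapping[str, float]
    directions: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.thresholds) != set(self.directions):
            raise ClockError("MrsRule thresholds and directions cover different markers")
        for m, t in self.thresholds.items():
            if not 0.0 <= t <= 1.0:
                raise ClockError(f"MrsRule threshold for {m} outside [0,1]: {t}")
        if not all(d in (-1, 1) for d in self.directions.values()):
            raise ClockError("MrsRule directions must be +1 or -1")

    @property
    def markers(self) -> tuple:
        return tuple(self.thresholds)


@dataclass(frozen=True)
class ClockOutput:
    sample_id: str
    clock: str
    value: float
    n_imputed: int


# --- model I/O --------------------------------------------------------------

def load_clock_model(coef_path, means_path, name: str | None = None,
                     output_units: str = "years") -> ClockModel:
    """Load a clock from a coefficient TSV and an imputation-means TSV.

    Coefficient file columns: ``marker_id``, ``weight``; the intercept
    sits on a reserved ``(Intercept)`` row.  Means file columns:
    ``marker_id``, ``mean_beta``.  A weighted marker without a mean is an
    error naming the marker.
    """
    coef_path = Path(coef_path)
    weights: dict[str, float] = {}
    intercept = 0.0
    with coef_path.open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["marker_id"] == INTERCEPT_KEY:
                intercept = float(row["weight"])
            else:
                weights[row["marker_id"]] = float(row["weight"])
    means: dict[str, float] = {}
    with Path(means_path).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            means[row["marker_id"]] = float(row["mean_beta"])
    missing = set(weights) - set(means)
    if missing:
        raise ClockError(f"{means_path}: no imputation mean for marker(s) {sorted(missing)[:5]}")
    return ClockModel(name or coef_path.stem, intercept, weights,
                      {m: means[m] for m in weights}, output_units)


def write_clock_model(model: ClockModel, coef_path, means_path) -> None:
    """Write a clock in the format :func:`load_clock_model` reads.

    Coefficients are serialized with :func:`repr` so a round-trip
    preserves them to full float precision.
    """
    with Path(coef_path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker_id", "weight"])
        w.writerow([INTERCEPT_KEY, repr(model.intercept)])
        for mid, wt in model.weights.items():
            w.writerow([mid, repr(wt)])
    with Path(means_path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["marker_id", "mean_beta"])
        for mid in model.weights:
            w.writerow([mid, repr(model.imputation_means[mid])])


# --- prediction -------------------------------------------------------------

def impute_missing(beta_row: pd.Series, model: ClockModel) -> tuple[pd.Series, int]:
    """Complete ``beta_row`` over the model's markers by mean imputation.

    Observed values are never altered; markers missing from the row (or
    present as NaN) are filled from ``model.imputation_means``.  Returns
    the completed row (indexed by the model's marker order) and the
    number of imputed markers.
    """
    values = []
    n_imputed = 0
    for mid in model.markers:
        v = beta_row.get(mid, np.nan)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            v = model.imputation_means[mid]
            n_imputed += 1
        values.append(float(v))
    return pd.Series(values, index=list(model.markers), dtype=float), n_imputed


def predict_linear_clock(beta_row: pd.Series, model: ClockModel,
                         sample_id: str = "", n_imputed: int = 0) -> ClockOutput:
    """Evaluate the linear predictor on a *complete* beta row.

    Raises :class:`ClockError` if any model marker is missing or NaN —
    call :func:`impute_missing` first.
    """
    total = model.intercept
    for mid, w in model.weights.items():
        v = beta_row.get(mid, np.nan)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ClockError(
                f"clock {model.name!r}: marker {mid} missing from beta row; "
                "impute_missing() must be applied first"
            )
        total += w * float(v)
    return ClockOutput(sample_id, model.name, float(total), n_imputed)


def mrs_categorical(beta_row: pd.Series, rule: MrsRule) -> int:
    """Count risk-aberrant markers: the categorical mortality score.

    A marker scores 1 when its beta lies strictly on the risk side of its
    threshold (above for direction +1, below for -1).
    """
    score = 0
    for mid, thr in rule.thresholds.items():
        v = beta_row.get(mid, np.nan)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ClockError(f"MRS rule: marker {mid} missing from beta row")
        d = rule.directions[mid]
        if (v - thr) * d > 0:
            score += 1
    return score


def mrs_categorical_from_continuous(value: float, mapping: Transform,
                                    n_categories: int = 10) -> int:
    """Map a (calibrated) continuous mortality score to the 0-10 scale.

    The quadratic ``mrs_cat_hts`` builtin transform is the intended
    ``mapping``; the result is rounded to the nearest integer and clipped
    into [0, n_categories].
    """
    raw = apply_transform(float(value), mapping)
    return int(np.clip(round(raw), 0, n_categories))


def interpret_mrs(score: int) -> str:
    """All-cause mortality relative-risk label for a categorical score.

    Relative to score 0 (reference), a score of 1 carries roughly a
    two-fold, 2-5 a three-fold and above 5 a seven-fold increased risk of
    death.
    """
    if score < 0:
        raise ClockError(f"MRS categorical score must be >= 0, got {score}")
    if score == 0:
        return "reference (1x)"
    if score == 1:
        return "two-fold risk (2x)"
    if score <= 5:
        return "three-fold risk (3x)"
    return "seven-fold risk (7x)"


def run_all_clocks(beta_matrix: pd.DataFrame, models: Iterable[ClockModel],
                   mrs_rule: MrsRule | None = None) -> pd.DataFrame:
    """Apply every clock (with imputation) to every row of a beta matrix.

    ``beta_matrix`` is samples x markers with NaN for missing.  Returns a
    long-format frame with columns ``sample_id, clock, value, units,
    n_imputed``; when ``mrs_rule`` is given an extra ``MRS_categorical``
    clock row is emitted per sample (its ``value`` is the integer score).
    """
    records = []
    for sample_id, row in beta_matrix.iterrows():
        for model in models:
            complete, n_imp = impute_missing(row, model)
            out = predict_linear_clock(complete, model, sample_id=str(sample_id),
                                       n_imputed=n_imp)
            records.append((out.sample_id, out.clock, out.value, model.output_units,
                            out.n_imputed))
        if mrs_rule is not None:
            filled = row.copy()
            n_imp = 0
            for mid in mrs_rule.markers:
                v = filled.get(mid, np.nan)
                if v is None or (isinstance(v, float) and math.isnan(v)):
                    filled[mid] = mrs_rule.thresholds[mid]  # on-threshold: not aberrant
                    n_imp += 1
            score = mrs_categorical(filled, mrs_rule)
            records.append((str(sample_id), "MRS_categorical", float(score),
                            "mrs_categories", n_imp))
    return pd.DataFrame(records,
                        columns=["sample_id", "clock", "value", "units", "n_imputed"])


def write_clock_outputs(outputs: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        outputs.to_csv(fh, sep="\t", index=False)


def read_clock_outputs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
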