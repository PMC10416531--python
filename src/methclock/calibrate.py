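"""Cross-technology calibration of clock outputs.

Epigenetic predictors trained on one measurement technology (typically
Infinium methylation microarrays) show a systematic shift when applied to
beta values measured by targeted high-throughput sequencing.  This module
models that shift as a low-degree polynomial acting on the *clock output*
(never on betas): degree-1 transforms for age clocks, pace-of-aging and
the continuous mortality risk score, and one degree-2 transform mapping
the continuous mortality score onto its categorical scale.

:func:`builtin_transforms` ships the published calibration equations for
this marker panel as constants; :func:`fit_linear_transform` and
:func:`fit_quadratic_transform` re-derive such transforms on paired data
by ordinary least squares.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm


class CalibrationError(ValueError):
    """Raised for invalid transforms or degenerate fits."""


@dataclass(frozen=True)
class Transform:
    """Polynomial map from a raw predictor output to a calibrated output.

    ``coefficients`` are in increasing-power order: ``(a, b)`` for
    ``a + b*x`` (degree 1) or ``(a, b, c)`` for ``a + b*x + c*x**2``
    (degree 2).  ``source_label`` / ``target_label`` are free-text
    provenance, e.g. ``"HTS"`` → ``"chronological age"``.
    """

    name: str
    degree: int
    coefficients: tuple
    source_label: str = ""
    target_label: str = ""

    def __post_init__(self) -> None:
        if self.degree not in (1, 2):
            raise CalibrationError(f"transform {self.name!r}: degree must be 1 or 2")
        if len(self.coefficients) != self.degree + 1:
            raise CalibrationError(
                f"transform {self.name!r}: degree {self.degree} needs "
                f"{self.degree + 1} coefficients, got {len(self.coefficients)}"
            )
        if not all(np.isfinite(self.coefficients)):
            raise CalibrationError(f"transform {self.name!r}: non-finite coefficients")

    def __call__(self, x):
        return apply_transform(x, self)


#: Identity transform, convenient as an "unbiased platform" default.
IDENTITY = Transform("identity", 1, (0.0, 1.0))


def apply_transform(value, t: Transform):
    """Evaluate ``t`` at ``value`` (scalar or array)."""
    x = np.asarray(value, dtype=float)
    out = np.polynomial.polynomial.polyval(x, np.asarray(t.coefficients, dtype=float))
    return float(out) if np.isscalar(value) or x.ndim == 0 else out


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise CalibrationError(f"unpaired lengths: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def fit_linear_transform(x, y, name: str = "fitted", source_label: str = "",
                         target_label: str = "") -> Transform:
    """OLS fit of ``y ~ a + b*x`` returning a degree-1 :class:`Transform`.

    Requires at least 3 finite pairs and non-constant ``x``.  Plain least
    squares is used even though both axes may carry error; the fitted
    direction matches how the calibration is applied (raw output on x,
    reference on y).
    """
    x, y = _paired(x, y)
    if x.size < 3:
        raise CalibrationError(f"need >= 3 paired finite observations, got {x.size}")
    if np.ptp(x) == 0:
        raise CalibrationError("x is constant; slope is unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    a, b = res.params
    return Transform(name, 1, (float(a), float(b)), source_label, target_label)


def fit_quadratic_transform(x, y, name: str = "fitted_quadratic", source_label: str = "",
                            target_label: str = "") -> Transform:
    """Least-squares fit of ``y ~ a + b*x + c*x**2`` (degree-2 transform)."""
    x, y = _paired(x, y)
    if x.size < 4:
        raise CalibrationError(f"need >= 4 paired finite observations, got {x.size}")
    design = np.column_stack([np.ones_like(x), x, x * x])
    if np.linalg.matrix_rank(design) < 3:
        raise CalibrationError("design matrix is rank deficient (x values too degenerate)")
    res = sm.OLS(y, design).fit()
    a, b, c = res.params
    return Transform(name, 2, (float(a), float(b), float(c)), source_label, target_label)


def builtin_transforms() -> dict[str, Transform]:
    """Registry of the published calibration equations for this panel.

    Six transforms: two for the Hannum age clock (from sequencing-derived
    and from microarray-derived betas to chronological age), one for the
    VISAGE blood-age model on amplicon sequencing data, one for
    pace-of-aging on sequencing data, one for the continuous mortality
    risk score on sequencing data, and a quadratic mapping the calibrated
    continuous mortality score onto the 0-10 categorical scale.
    """
    entries = [
        Transform("hannum_hts", 1, (0.64, 0.89), "Hannum age (HTS)", "chronological age"),
        Transform("hannum_epic", 1, (-5.16, 1.10), "Hannum age (EPIC)", "chronological age"),
        Transform("visage_ampliseq", 1, (-1.61, 0.93), "VISAGE blood age (amplicon HTS)",
                  "chronological age"),
        Transform("poam_hts", 1, (0.23, 0.72), "PoAm (HTS)", "PoAm (array scale)"),
        Transform("mrs_cont_hts", 1, (-1.72, 0.61), "MRS continuous (HTS)",
                  "MRS continuous (array scale)"),
        Transform("mrs_cat_hts", 2, (25.76, 13.29, 1.81), "MRS continuous (HTS, transformed)",
                  "MRS categorical"),
    ]
    return {t.name: t for t in entries}


# --- registry serialization -------------------------------------------------

_REGISTRY_COLUMNS = ("name", "degree", "a", "b", "c", "source_label", "target_label")


def write_registry(transforms: dict[str, Transform], path) -> None:
    """Serialize a transform registry as TSV (column ``c`` empty for degree 1)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_REGISTRY_COLUMNS)
        for t in transforms.values():
            coefs = list(t.coefficients) + [""] * (3 - len(t.coefficients))
            w.writerow([t.name, t.degree, *[repr(c) if c != "" else "" for c in coefs],
                        t.source_label, t.target_label])


def read_registry(path) -> dict[str, Transform]:
    """Load a transform registry written by :func:`write_registry`."""
    out: dict[str, Transform] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            degree = int(row["degree"])
            coefs = tuple(float(row[k]) for k in ("a", "b", "c")[: degree + 1])
            out[row["name"]] = Transform(row["name"], degree, coefs,
                                         row.get("source_label", ""),
                                         row.get("target_label", ""))
    return out
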