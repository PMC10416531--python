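"""Assay-performance statistics.

Repeatability (mean absolute difference between technical replicates),
accuracy against methylation standards of known level, sensitivity
across DNA inputs, cross-technology agreement (Spearman correlation and
mean absolute beta difference over shared markers), and age-prediction
error.  Conventions used throughout:

* missing beta cells are handled *pairwise-complete*: a (pair, marker)
  cell is dropped when either side is missing — metrics describe
  measured values only, never imputed ones;
* all standard deviations use the n-1 (sample) denominator;
* Spearman correlation is the product-moment correlation of mid-ranks
  (scipy's convention), so ties are averaged;
* every summary carries the number of cells it was computed from, so
  results from differently sized runs are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class EvaluationError(ValueError):
    """Raised for inputs on which a statistic is undefined."""


@dataclass(frozen=True)
class SummaryStat:
    """A mean +/- SD with the cell count it was computed over."""

    mean: float
    sd: float
    n: int


def _mean_sd(values: np.ndarray) -> SummaryStat:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise EvaluationError("no finite values to summarize")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return SummaryStat(float(np.mean(values)), sd, int(values.size))


def summarize_ages(ages: Sequence[float]) -> SummaryStat:
    """Mean and sample SD (n-1 denominator) of a cohort's ages."""
    return _mean_sd(np.asarray(ages, dtype=float))


# --- repeatability -----------------------------------------------------------

def replicate_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Derive replicate pairings from a sample-metadata frame.

    Samples sharing a ``source_id`` are paired in replicate order; each
    sample appears in at most one pair.  Sources with fewer than two
    samples are skipped.
    """
    pairs = []
    for _, grp in samples.groupby("source_id", sort=False):
        ids = grp.sort_values("replicate")["sample_id"].tolist()
        pairs.extend((ids[i], ids[i + 1]) for i in range(0, len(ids) - 1, 2))
    return pairs


def replicate_mad(beta_matrix: pd.DataFrame,
                  pairing: Sequence[tuple[str, str]]) -> SummaryStat:
    """Mean +/- SD of |beta_rep1 - beta_rep2| over all (pair, marker) cells.

    Markers missing in either replicate of a pair are excluded pairwise.
    """
    if not pairing:
        raise EvaluationError("replicate_mad: no replicate pairs supplied")
    seen: set[str] = set()
    for a, b in pairing:
        for s in (a, b):
            if s in seen:
                raise EvaluationError(f"sample {s!r} appears in more than one pair")
            seen.add(s)
    diffs = []
    for a, b in pairing:
        d = (beta_matrix.loc[a] - beta_matrix.loc[b]).abs().to_numpy(dtype=float)
        diffs.append(d[np.isfinite(d)])
    all_diffs = np.concatenate(diffs) if diffs else np.array([])
    if all_diffs.size == 0:
        raise EvaluationError("replicate_mad: no overlapping non-missing markers")
    return _mean_sd(all_diffs)


def per_level_sd(beta_matrix: pd.DataFrame, expected: Mapping[str, float],
                 pooled: bool = False) -> pd.Series:
    """Spread of observed betas per standard level.

    Default (``pooled=False``): the SD of observed betas is computed per
    marker across the level's replicate samples, then averaged over
    markers ("mean standard deviation").  ``pooled=True`` instead takes
    one SD over all (sample, marker) cells of the level.
    """
    levels = pd.Series(expected, dtype=float)
    out = {}
    for lv in sorted(levels.unique()):
        ids = levels.index[levels == lv]
        sub = beta_matrix.loc[list(ids)]
        if pooled:
            vals = sub.to_numpy(dtype=float).ravel()
            vals = vals[np.isfinite(vals)]
            out[lv] = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
        else:
            sds = sub.std(axis=0, ddof=1, skipna=True)
            out[lv] = float(sds.mean(skipna=True))
    return pd.Series(out, name="sd")


# --- accuracy ----------------------------------------------------------------

def accuracy_vs_expected(beta_matrix: pd.DataFrame,
                         expected: Mapping[str, float]) -> SummaryStat:
    """Mean +/- SD of |observed - expected| pooled over all cells.

    ``expected`` maps each standard sample to its truth level; a sample
    in the matrix without a truth level is an error.
    """
    missing = set(map(str, beta_matrix.index)) - set(expected)
    if missing:
        raise EvaluationError(f"no expected level for sample(s) {sorted(missing)[:5]}")
    devs = []
    for sid, row in beta_matrix.iterrows():
        d = (row - float(expected[str(sid)])).abs().to_numpy(dtype=float)
        devs.append(d[np.isfinite(d)])
    return _mean_sd(np.concatenate(devs))


def sensitivity_summary(beta_matrix: pd.DataFrame,
                        metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of observed beta per (DNA input, expected level) group.

    ``metadata`` needs columns ``sample_id, input_ng, expected_beta``.
    Groups without samples in the matrix are skipped with a warning.
    """
    meta = metadata.set_index("sample_id")
    missing = set(map(str, beta_matrix.index)) - set(map(str, meta.index))
    if missing:
        raise EvaluationError(f"metadata does not cover sample(s) {sorted(missing)[:5]}")
    rows = []
    for (ng, lv), grp in meta.groupby(["input_ng", "expected_beta"], sort=True):
        ids = [s for s in grp.index if s in beta_matrix.index]
        if not ids:
            warnings.warn(f"sensitivity group (input={ng}, level={lv}) has no samples")
            continue
        vals = beta_matrix.loc[ids].to_numpy(dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        stat = _mean_sd(vals)
        rows.append((float(ng), float(lv), stat.mean, stat.sd, stat.n))
    return pd.DataFrame(rows, columns=["input_ng", "expected_beta", "mean", "sd", "n"])


# --- cross-method agreement ---------------------------------------------------

def method_correlation(matrices: Mapping[str, pd.DataFrame],
                       shared_markers: Sequence[str] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation and mean |delta beta| between technologies.

    Each matrix is samples x markers for one technology; comparisons use
    the flattened (sample, marker) cells over the shared marker set,
    pairwise-complete.  Returns (correlation matrix, mean-absolute-
    difference matrix), both symmetric with diagonals 1 and 0.
    """
    if len(matrices) < 2:
        raise EvaluationError("method_correlation needs >= 2 technologies")
    techs = list(matrices)
    if shared_markers is None:
        shared = set(matrices[techs[0]].columns)
        for t in techs[1:]:
            shared &= set(matrices[t].columns)
        shared_markers = [c for c in matrices[techs[0]].columns if c in shared]
    if not shared_markers:
        raise EvaluationError("no shared markers between technologies")
    shared_samples = set(matrices[techs[0]].index)
    for t in techs[1:]:
        shared_samples &= set(matrices[t].index)
    sample_order = [s for s in matrices[techs[0]].index if s in shared_samples]

    corr = pd.DataFrame(np.eye(len(techs)), index=techs, columns=techs)
    madm = pd.DataFrame(np.zeros((len(techs), len(techs))), index=techs, columns=techs)
    for i, ti in enumerate(techs):
        for j in range(i + 1, len(techs)):
            tj = techs[j]
            x = matrices[ti].loc[sample_order, list(shared_markers)].to_numpy(dtype=float).ravel()
            y = matrices[tj].loc[sample_order, list(shared_markers)].to_numpy(dtype=float).ravel()
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 3:
                raise EvaluationError(f"fewer than 3 shared non-missing cells for "
                                      f"{ti} vs {tj}")
            rho = stats.spearmanr(x[keep], y[keep]).statistic
            corr.loc[ti, tj] = corr.loc[tj, ti] = float(rho)
            mad = float(np.mean(np.abs(x[keep] - y[keep])))
            madm.loc[ti, tj] = madm.loc[tj, ti] = mad
    return corr, madm


# --- prediction error ---------------------------------------------------------

def mae_age(predicted: Sequence[float], chronological: Sequence[float]) -> SummaryStat:
    """Mean +/- SD of |predicted - chronological| age."""
    pred = np.asarray(predicted, dtype=float)
    chrono = np.asarray(chronological, dtype=float)
    if pred.shape != chrono.shape:
        raise EvaluationError(f"length mismatch: {pred.shape} vs {chrono.shape}")
    return _mean_sd(np.abs(pred - chrono))


def clock_cross_correlation(outputs: pd.DataFrame,
                            ages: Mapping[str, float] | None = None,
                            ) -> pd.DataFrame:
    """Product-moment correlation matrix between clocks (and age).

    ``outputs`` is the long frame from
    :func:`methclock.clocks.run_all_clocks`; an ``age`` column is added
    when ``ages`` maps sample ids to chronological age.  Constant
    columns yield NaN (undefined), not an error.  A warning is emitted
    below 10 samples, where correlations are unstable.
    """
    wide = outputs.pivot(index="sample_id", columns="clock", values="value")
    if ages is not None:
        wide["age"] = pd.Series({str(k): float(v) for k, v in ages.items()})
    complete = wide.dropna(axis=0, how="any")
    if len(complete) < 3:
        raise EvaluationError("clock_cross_correlation needs >= 3 complete samples")
    if len(complete) < 10:
        warnings.warn(f"clock correlations computed on only n={len(complete)} samples; "
                      "interpret with caution")
    with np.errstate(invalid="ignore"):  # constant columns -> NaN, by design
        return complete.corr(method="pearson")
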