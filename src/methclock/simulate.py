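"""Synthetic targeted-bisulfite-sequencing data with known truth.

No raw sequencing data accompany the assay designs this package models,
so every analysis here is exercised on simulated inputs whose
statistical structure matches what the pipeline assumes:

* **standard dilution series** — artificially methylated controls at beta
  levels 0, 0.10, 0.25, 0.50, 0.75, 0.90 and 1, analyzed in duplicate;
* **blood cohorts** — donors of known chronological age (defaults 7, 28,
  46, 61, 78 years, in duplicate), with per-marker betas constructed by
  *inverting* a linear clock so the clock applied to the noise-free betas
  returns each donor's age exactly;
* **read counts** — per-site methylated/unmethylated tallies drawn
  binomially at heavy-tailed (log-normal) per-target depth, through two
  bisulfite error channels: conversion failure (an unmethylated cytosine
  read as methylated, probability ``1 - conversion_rate``) and
  inappropriate conversion (a methylated cytosine read as unmethylated,
  probability ``inappropriate_conversion``), so the probability a read
  reports methylation is ``p = beta*(1-f) + (1-beta)*(1-c)``;
* **lambda spike-ins** — unmethylated phage lambda control amplicons
  whose methylated reads arise only from conversion failure;
* **platform bias** — an optional :class:`~methclock.calibrate.Transform`
  applied to true betas before sampling, emulating the systematic offset
  between sequencing-based and array-based measurement;
* **input-mass bottleneck** — at low DNA input the number of template
  molecules per target limits precision regardless of read depth; this is
  modeled as a per-target binomial subsampling of the methylation state
  over ``round(input_ng * 300)`` molecules (~300 haploid genome copies
  per nanogram).

All randomness flows through one :class:`numpy.random.Generator` (PCG64,
``numpy.random.default_rng``) seeded from ``SimulationConfig.seed``, so a
fixed seed reproduces count tables bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibrate import Transform, apply_transform
from .clocks import ClockModel, predict_linear_clock
from .panel import TargetCytosine

#: Approximate haploid genome copies per nanogram of human DNA.
MOLECULES_PER_NG = 300

#: The seven standard methylation levels of the repeatability design.
STANDARD_LEVELS = (0.0, 0.10, 0.25, 0.50, 0.75, 0.90, 1.0)
#: Donor ages (years) of the blood-cohort design.
BLOOD_AGES = (7, 28, 46, 61, 78)

COUNT_COLUMNS = ("sample_id", "marker_id", "strand", "n_meth", "n_unmeth")


class SimulationError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generation parameters; defaults are the package's study conditions.

    ``coverage_mu``/``coverage_sigma`` are the log-scale mean and SD of
    the per-target read depth (log-normal; defaults give a median depth
    of ~3000 reads with a heavy right tail, the order observed for
    amplicon sequencing of this panel).  ``conversion_rate`` (c) and
    ``inappropriate_conversion`` (f) are the two bisulfite error
    channels.  ``platform_bias`` transforms true betas before sampling
    (``None`` = unbiased).  ``input_ng`` sets the template-molecule
    bottleneck; ``n_replicates`` the technical replicates per source.
    """

    seed: int = 0
    coverage_mu: float = 8.0064  # log(3000)
    coverage_sigma: float = 1.0
    conversion_rate: float = 0.998
    inappropriate_conversion: float = 0.005
    strand_split: float = 0.5
    platform_bias: Transform | None = None
    n_replicates: int = 2
    input_ng: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise SimulationError(f"conversion_rate outside [0,1]: {self.conversion_rate}")
        if not 0.0 <= self.inappropriate_conversion <= 1.0:
            raise SimulationError(
                f"inappropriate_conversion outside [0,1]: {self.inappropriate_conversion}")
        if not 0.0 < self.strand_split < 1.0:
            raise SimulationError(f"strand_split outside (0,1): {self.strand_split}")
        if self.coverage_sigma < 0:
            raise SimulationError(f"coverage_sigma must be >= 0: {self.coverage_sigma}")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.input_ng <= 0:
            raise SimulationError("input_ng must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for a simulated dataset.

    ``betas``: one row per (sample, marker) with ``true_beta`` (the
    biological truth) and ``sampling_beta`` (after platform bias; equal
    to ``true_beta`` when unbiased).  ``samples``: per-sample metadata
    (source id, replicate, sample type, expected beta or age, DNA input).
    """

    betas: pd.DataFrame
    samples: pd.DataFrame


# --- core samplers ----------------------------------------------------------

def _meth_read_probability(beta: float, config: SimulationConfig) -> float:
    c = config.conversion_rate
    f = config.inappropriate_conversion
    return beta * (1.0 - f) + (1.0 - beta) * (1.0 - c)


def simulate_site_counts(true_beta: float, depth: int, config: SimulationConfig,
                         rng: np.random.Generator | None = None,
                         strands: str = "both") -> dict[str, tuple[int, int]]:
    """Draw per-strand (methylated, unmethylated) counts for one site.

    Reads are split between Watson and Crick by ``strand_split`` for
    ``strands="both"`` markers, otherwise all land on the single
    available strand.  Depth 0 yields zero counts.
    """
    if not 0.0 <= true_beta <= 1.0:
        raise SimulationError(f"true_beta outside [0,1]: {true_beta}")
    if depth < 0:
        raise SimulationError(f"depth must be >= 0: {depth}")
    if rng is None:
        rng = config.rng()
    p = _meth_read_probability(true_beta, config)
    if strands == "both":
        n_w = int(rng.binomial(depth, config.strand_split))
        split = {"W": n_w, "C": depth - n_w}
    else:
        split = {strands: depth}
    out = {}
    for strand, n in split.items():
        n_meth = int(rng.binomial(n, p)) if n > 0 else 0
        out[strand] = (n_meth, n - n_meth)
    return out


def _bottleneck_beta(beta: float, input_ng: float, rng: np.random.Generator) -> float:
    """Resample beta over the finite template molecules of a library."""
    m = max(1, int(round(input_ng * MOLECULES_PER_NG)))
    return float(rng.binomial(m, beta)) / m


def _draw_depth(config: SimulationConfig, rng: np.random.Generator,
                scale: float = 1.0) -> int:
    return int(round(scale * float(rng.lognormal(config.coverage_mu, config.coverage_sigma))))


def _sample_counts(sample_id: str, panel: Sequence[TargetCytosine],
                   beta_by_marker: dict[str, float], config: SimulationConfig,
                   rng: np.random.Generator, depth_scale: float = 1.0,
                   input_ng: float | None = None) -> list[tuple]:
    """Counts for one library over the whole panel (lambda rows included)."""
    input_ng = config.input_ng if input_ng is None else input_ng
    rows = []
    for m in panel:
        beta = 0.0 if m.is_control else beta_by_marker[m.marker_id]
        if not m.is_control:
            beta = _bottleneck_beta(beta, input_ng, rng)
        depth = _draw_depth(config, rng, depth_scale)
        for strand, (nm, nu) in simulate_site_counts(
                beta, depth, config, rng=rng, strands=m.strands).items():
            rows.append((sample_id, m.marker_id, strand, nm, nu))
    return rows


def apply_platform_bias(truth: TruthTable, bias: Transform) -> TruthTable:
    """Replace sampling betas by ``clamp(bias(true_beta), 0, 1)``.

    The original ``true_beta`` column is retained so calibration can be
    evaluated against the unbiased truth.
    """
    betas = truth.betas.copy()
    betas["sampling_beta"] = np.clip(
        apply_transform(betas["true_beta"].to_numpy(dtype=float), bias), 0.0, 1.0)
    return TruthTable(betas=betas, samples=truth.samples.copy())


# --- standard dilution series ----------------------------------------------

def simulate_standard_series(panel: Sequence[TargetCytosine],
                             levels: Sequence[float] = STANDARD_LEVELS,
                             config: SimulationConfig = SimulationConfig(),
                             ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the methylation-standard repeatability design.

    For each beta level and technical replicate one library is generated
    with the level as the true beta at every clock marker (lambda
    spike-ins stay at 0).  Default seven levels in duplicate = 14
    libraries.
    """
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise SimulationError(f"standard level outside [0,1]: {lv}")
    rng = config.rng()
    clock_markers = [m for m in panel if not m.is_control]
    beta_rows, sample_rows, count_rows = [], [], []
    for lv in levels:
        for rep in range(1, config.n_replicates + 1):
            sid = f"std{lv:g}_r{rep}"
            betas = {m.marker_id: float(lv) for m in clock_markers}
            if config.platform_bias is not None:
                betas = {k: float(np.clip(apply_transform(v, config.platform_bias), 0, 1))
                         for k, v in betas.items()}
            for m in clock_markers:
                beta_rows.append((sid, m.marker_id, float(lv), betas[m.marker_id]))
            sample_rows.append((sid, f"std{lv:g}", rep, "standard", float(lv),
                                np.nan, config.input_ng))
            count_rows.extend(_sample_counts(sid, panel, betas, config, rng))
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    truth = TruthTable(
        betas=pd.DataFrame(beta_rows,
                           columns=["sample_id", "marker_id", "true_beta", "sampling_beta"]),
        samples=pd.DataFrame(sample_rows,
                             columns=["sample_id", "source_id", "replicate", "sample_type",
                                      "expected_beta", "age", "input_ng"]),
    )
    return counts, truth


def simulate_sensitivity_series(panel: Sequence[TargetCytosine],
                                levels: Sequence[float] = (0.25, 0.75),
                                inputs_ng: Sequence[float] = (50.0, 25.0, 10.0, 1.0),
                                config: SimulationConfig = SimulationConfig(),
                                ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate the DNA-input dilution (sensitivity) design.

    Two methylation levels at four DNA inputs in duplicate = 16
    libraries by default.  Read depth scales proportionally with input
    mass and the template-molecule bottleneck tightens as input drops,
    so measurement variability rises at low input.
    """
    rng = config.rng()
    clock_markers = [m for m in panel if not m.is_control]
    ref_input = max(inputs_ng)
    beta_rows, sample_rows, count_rows = [], [], []
    for lv in levels:
        if not 0.0 <= lv <= 1.0:
            raise SimulationError(f"standard level outside [0,1]: {lv}")
        for ng in inputs_ng:
            for rep in range(1, config.n_replicates + 1):
                sid = f"sens{lv:g}_ng{ng:g}_r{rep}"
                betas = {m.marker_id: float(lv) for m in clock_markers}
                for m in clock_markers:
                    beta_rows.append((sid, m.marker_id, float(lv), float(lv)))
                sample_rows.append((sid, f"sens{lv:g}_ng{ng:g}", rep, "standard",
                                    float(lv), np.nan, float(ng)))
                count_rows.extend(_sample_counts(sid, panel, betas, config, rng,
                                                 depth_scale=ng / ref_input, input_ng=ng))
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    truth = TruthTable(
        betas=pd.DataFrame(beta_rows,
                           columns=["sample_id", "marker_id", "true_beta", "sampling_beta"]),
        samples=pd.DataFrame(sample_rows,
                             columns=["sample_id", "source_id", "replicate", "sample_type",
                                      "expected_beta", "age", "input_ng"]),
    )
    return counts, truth


# --- blood cohort via clock inversion ---------------------------------------

def invert_clock_betas(clock: ClockModel, age: float,
                       reference_age: float) -> dict[str, float]:
    """Construct betas at the clock's markers that predict ``age`` exactly.

    With weights ``w`` and imputation means ``mu``, a baseline
    ``m = mu + delta*w`` is chosen so the clock evaluates to
    ``reference_age`` at ``m``, then each marker moves along its weight
    direction: ``beta_i = m_i + w_i*(age - reference_age)/sum(w^2)``, so
    the weighted sum contributes exactly ``age - reference_age``.
    Betas are clamped to [0.01, 0.99]; if clamping shifts the round-trip
    prediction by more than 0.1 years a :class:`SimulationError` is
    raised instructing the caller to rescale the generating clock.
    """
    w = np.array([clock.weights[m] for m in clock.markers], dtype=float)
    mu = np.array([clock.imputation_means[m] for m in clock.markers], dtype=float)
    ssw = float(w @ w)
    if ssw == 0.0:
        raise SimulationError(f"clock {clock.name!r} has all-zero weights")
    delta = (reference_age - clock.intercept - float(w @ mu)) / ssw
    base = mu + delta * w
    betas = base + w * (age - reference_age) / ssw
    clamped = np.clip(betas, 0.01, 0.99)
    roundtrip = clock.intercept + float(w @ clamped)
    if abs(roundtrip - age) > 0.1:
        raise SimulationError(
            f"clock {clock.name!r}: age {age} needs betas outside [0.01, 0.99] "
            f"(round-trip error {abs(roundtrip - age):.2f} y); rescale the generating "
            "clock (larger weights or means nearer 0.5)"
        )
    return dict(zip(clock.markers, clamped.tolist()))


def simulate_blood_cohort(panel: Sequence[TargetCytosine], ages: Sequence[float],
                          clock: ClockModel, noise_sd: float = 0.0,
                          config: SimulationConfig = SimulationConfig(),
                          ) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate an age-structured blood cohort in technical replicates.

    True betas at the generating clock's markers come from
    :func:`invert_clock_betas` (so ``clock`` applied to the noise-free
    betas returns the donor's age exactly); other panel markers sit at a
    stable per-marker baseline.  Gaussian biological noise ``noise_sd``
    (beta scale) is added per donor, shared between that donor's
    technical replicates.  Default ages in duplicate = 10 libraries.
    """
    if not any(w != 0 for w in clock.weights.values()):
        raise SimulationError("generating clock has no nonzero weight")
    if noise_sd < 0:
        raise SimulationError("noise_sd must be >= 0")
    rng = config.rng()
    clock_markers = [m for m in panel if not m.is_control]
    reference_age = float(np.mean(ages))
    # Stable non-clock baselines: drawn once per run, shared by all samples.
    baselines = {m.marker_id: float(rng.uniform(0.05, 0.95)) for m in clock_markers
                 if m.marker_id not in clock.weights}
    beta_rows, sample_rows, count_rows = [], [], []
    for age in ages:
        truth_betas = dict(baselines)
        truth_betas.update(invert_clock_betas(clock, float(age), reference_age))
        # biological noise is a property of the donor, not of the library
        noise = {mid: float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                 for mid in truth_betas}
        donor_betas = {mid: float(np.clip(v + noise[mid], 0.0, 1.0))
                       for mid, v in truth_betas.items()}
        for rep in range(1, config.n_replicates + 1):
            sid = f"blood_a{age:g}_r{rep}"
            sampling = donor_betas
            if config.platform_bias is not None:
                sampling = {k: float(np.clip(apply_transform(v, config.platform_bias), 0, 1))
                            for k, v in donor_betas.items()}
            for m in clock_markers:
                beta_rows.append((sid, m.marker_id, donor_betas[m.marker_id],
                                  sampling[m.marker_id]))
            sample_rows.append((sid, f"blood_a{age:g}", rep, "blood", np.nan,
                                float(age), config.input_ng))
            count_rows.extend(_sample_counts(sid, panel, sampling, config, rng))
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    truth = TruthTable(
        betas=pd.DataFrame(beta_rows,
                           columns=["sample_id", "marker_id", "true_beta", "sampling_beta"]),
        samples=pd.DataFrame(sample_rows,
                             columns=["sample_id", "source_id", "replicate", "sample_type",
                                      "expected_beta", "age", "input_ng"]),
    )
    return counts, truth


# --- lambda spike-in ---------------------------------------------------------

def simulate_lambda_spikein(depth: int, config: SimulationConfig,
                            lambda_markers: Sequence[TargetCytosine] = (),
                            sample_id: str = "lambda_qc",
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Counts at unmethylated lambda control markers.

    True beta is 0, so methylated reads arise only from conversion
    failure at rate ``1 - conversion_rate``.  With no markers given a
    single anonymous lambda amplicon is simulated.
    """
    if depth < 0:
        raise SimulationError(f"depth must be >= 0: {depth}")
    if rng is None:
        rng = config.rng()
    if not lambda_markers:
        lambda_markers = [TargetCytosine("lambda_ctrl_1", "lambda", 1, "CG", "W")]
    rows = []
    for m in lambda_markers:
        for strand, (nm, nu) in simulate_site_counts(
                0.0, depth, config, rng=rng, strands=m.strands).items():
            rows.append((sample_id, m.marker_id, strand, nm, nu))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


# --- manifest ----------------------------------------------------------------

def write_manifest(config: SimulationConfig, path, **extra) -> None:
    """Echo all generation parameters (and the seed) to a JSON manifest."""
    payload = dataclasses.asdict(config)
    if config.platform_bias is not None:
        payload["platform_bias"] = {
            "name": config.platform_bias.name,
            "degree": config.platform_bias.degree,
            "coefficients": list(config.platform_bias.coefficients),
        }
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
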