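"""Beta-value calling from per-strand read counts, with QC.

The quantification contract: per (sample, marker), methylated and
unmethylated reads from the Watson and Crick strands are summed when
both are available, and the beta value is the ratio of methylated reads
to total reads.  Sites whose merged depth falls below a read threshold
(default 50) are reported as *missing*, never as zero.  Two comparators
are deliberately different and should not be "fixed" to match:

* the pass/fail threshold is inclusive — total >= min_reads passes
  (only sites with *fewer than* ``min_reads`` reads become missing);
* coverage summaries use a strict ``depth > t`` comparison ("covered
  more than t x").

Conversion QC: the bisulfite conversion rate is estimated from pooled
counts at unmethylated lambda spike-in markers (any methylated call
there is a conversion failure), or from non-CpG cytosines within the
targets for capture protocols without a spike-in.  Pooling sums counts
across control amplicons before taking the ratio.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import TargetCytosine

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS = 50
DEFAULT_COVERAGE_THRESHOLDS = (50, 200, 1000)
LOW_COVERAGE_CUTOFF = 20


class QuantError(ValueError):
    """Raised for invalid counts or quantification inputs."""


@dataclass(frozen=True)
class BetaCall:
    """One strand-merged methylation call.

    ``beta`` is NaN iff ``passed_threshold`` is False.
    """

    sample_id: str
    marker_id: str
    beta: float
    total_reads: int
    passed_threshold: bool


@dataclass
class QCReport:
    """Per-sample quality summary."""

    sample_id: str
    conversion_rate_lambda: float | None
    conversion_rate_noncpg: float | None
    coverage_fractions: dict
    n_low_coverage: int
    n_missing_markers: int


# --- elementary operations ---------------------------------------------------

def merge_strands(w: tuple | None, c: tuple | None) -> tuple[int, int]:
    """Sum (n_meth, n_unmeth) across the strands that are available."""
    if w is None and c is None:
        raise QuantError("merge_strands: at least one strand record required")
    nm = nu = 0
    for rec in (w, c):
        if rec is None:
            continue
        m, u = rec
        if m < 0 or u < 0:
            raise QuantError(f"negative read counts: {rec}")
        nm += int(m)
        nu += int(u)
    return nm, nu


def call_beta(n_meth: int, n_unmeth: int, min_reads: int = DEFAULT_MIN_READS,
              sample_id: str = "", marker_id: str = "") -> BetaCall:
    """Beta = meth/(meth+unmeth), missing when total < min_reads."""
    if n_meth < 0 or n_unmeth < 0:
        raise QuantError(f"negative read counts: ({n_meth}, {n_unmeth})")
    if min_reads < 1:
        raise QuantError(f"min_reads must be >= 1, got {min_reads}")
    total = int(n_meth) + int(n_unmeth)
    if total < min_reads:
        return BetaCall(sample_id, marker_id, float("nan"), total, False)
    return BetaCall(sample_id, marker_id, n_meth / total, total, True)


def quantify_sample(counts: pd.DataFrame, panel: Sequence[TargetCytosine],
                    min_reads: int = DEFAULT_MIN_READS) -> tuple[list[BetaCall], QCReport]:
    """Strand-merge and call betas for one sample over a panel.

    Returns exactly one :class:`BetaCall` per non-control panel marker
    (missing where counts are absent or sub-threshold).  Lambda control
    markers are excluded from the beta calls and routed into the QC
    report's conversion-rate estimate.  Counts at markers not in the
    panel are logged and skipped.
    """
    sample_ids = counts["sample_id"].unique() if len(counts) else []
    if len(sample_ids) > 1:
        raise QuantError(f"quantify_sample expects one sample, got {list(sample_ids)}")
    sample_id = str(sample_ids[0]) if len(sample_ids) else ""

    by_marker = {m.marker_id: m for m in panel}
    unknown = set(counts["marker_id"]) - set(by_marker) if len(counts) else set()
    if unknown:
        logger.warning("sample %s: skipping %d off-panel marker(s): %s",
                       sample_id, len(unknown), sorted(unknown)[:5])
        counts = counts[~counts["marker_id"].isin(unknown)]

    merged = (counts.groupby("marker_id")[["n_meth", "n_unmeth"]].sum()
              if len(counts) else pd.DataFrame(columns=["n_meth", "n_unmeth"]))

    calls, depths = [], []
    lambda_meth = lambda_unmeth = 0
    for m in panel:
        if m.marker_id in merged.index:
            nm = int(merged.loc[m.marker_id, "n_meth"])
            nu = int(merged.loc[m.marker_id, "n_unmeth"])
        else:
            nm = nu = 0
        if m.is_control:
            lambda_meth += nm
            lambda_unmeth += nu
            continue
        calls.append(call_beta(nm, nu, min_reads, sample_id, m.marker_id))
        depths.append(nm + nu)

    conv = conversion_rate_lambda(lambda_meth, lambda_unmeth)
    fractions = coverage_summary(depths, DEFAULT_COVERAGE_THRESHOLDS) if depths else {}
    report = QCReport(
        sample_id=sample_id,
        conversion_rate_lambda=conv,
        conversion_rate_noncpg=None,
        coverage_fractions=fractions,
        n_low_coverage=int(sum(d < LOW_COVERAGE_CUTOFF for d in depths)),
        n_missing_markers=int(sum(not c.passed_threshold for c in calls)),
    )
    return calls, report


def quantify(counts: pd.DataFrame, panel: Sequence[TargetCytosine],
             min_reads: int = DEFAULT_MIN_READS) -> tuple[pd.DataFrame, list[QCReport]]:
    """Quantify every sample in a long-format count table.

    Returns a beta matrix (rows = samples in first-appearance order,
    columns = non-control panel markers in panel order, NaN = missing)
    and one :class:`QCReport` per sample.
    """
    marker_order = [m.marker_id for m in panel if not m.is_control]
    rows, reports = {}, []
    for sid in counts["sample_id"].drop_duplicates():
        calls, report = quantify_sample(counts[counts["sample_id"] == sid], panel, min_reads)
        rows[str(sid)] = {c.marker_id: c.beta for c in calls}
        reports.append(report)
    matrix = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    matrix = matrix.reindex(columns=marker_order)
    matrix.index.name = "sample_id"
    return matrix, reports


# --- conversion QC -----------------------------------------------------------

def conversion_rate_lambda(n_meth: int, n_unmeth: int) -> float | None:
    """Conversion rate (%) from pooled unmethylated-lambda counts.

    Every unmethylated-lambda read *should* be called unmethylated, so
    the rate is ``100 * n_unmeth / (n_meth + n_unmeth)``.  Zero pooled
    depth yields ``None`` (undefined, not 0).
    """
    total = int(n_meth) + int(n_unmeth)
    if total == 0:
        return None
    return 100.0 * n_unmeth / total


def conversion_rate_noncpg(n_converted: int, n_unconverted: int) -> float | None:
    """Conversion rate (%) pooled over non-CpG cytosines within targets."""
    total = int(n_converted) + int(n_unconverted)
    if total == 0:
        return None
    return 100.0 * n_converted / total


# --- coverage ----------------------------------------------------------------

def coverage_summary(depths: Sequence[int],
                     thresholds: Sequence[int] = DEFAULT_COVERAGE_THRESHOLDS) -> dict:
    """Fraction of markers with depth strictly greater than each threshold."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise QuantError("coverage_summary: empty depth vector")
    if any(t <= 0 for t in thresholds):
        raise QuantError("coverage thresholds must be positive")
    return {int(t): float(np.mean(depths > t)) for t in thresholds}


def normalized_depth(depths: Sequence[int], total_mapped: int) -> np.ndarray:
    """Per-marker depth as a fraction of total mapped reads.

    Under a perfectly uniform distribution of on-target reads every
    marker would sit at ``1 / n_markers`` of the on-target total; the
    returned fractions sum to (on-target reads) / (total mapped) <= 1.
    """
    if total_mapped <= 0:
        raise QuantError(f"total mapped reads must be > 0, got {total_mapped}")
    return np.asarray(depths, dtype=float) / float(total_mapped)


# --- file formats ------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        counts.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"sample_id": str, "marker_id": str, "strand": str})
    required = {"sample_id", "marker_id", "strand", "n_meth", "n_unmeth"}
    missing = required - set(counts.columns)
    if missing:
        raise QuantError(f"{path}: missing count columns {sorted(missing)}")
    if (counts[["n_meth", "n_unmeth"]] < 0).any().any():
        raise QuantError(f"{path}: negative read counts")
    return counts


def write_bismark_coverage(counts: pd.DataFrame, panel: Sequence[TargetCytosine],
                           path) -> None:
    """Write one sample's counts as a Bismark-style cytosine coverage file.

    Columns: chromosome, start, end (both 1-based, start == end for a
    single cytosine), methylation percentage, count methylated, count
    unmethylated.  Strands are collapsed per site, matching how Bismark's
    ``coverage2cytosine --merge_CpG`` output is consumed downstream.
    """
    by_marker = {m.marker_id: m for m in panel}
    merged = counts.groupby("marker_id", sort=False)[["n_meth", "n_unmeth"]].sum()
    with Path(path).open("w", encoding="utf-8") as fh:
        for mid, row in merged.iterrows():
            m = by_marker.get(mid)
            if m is None:
                continue
            nm, nu = int(row["n_meth"]), int(row["n_unmeth"])
            pct = 100.0 * nm / (nm + nu) if nm + nu else 0.0
            fh.write(f"{m.chrom}\t{m.pos}\t{m.pos}\t{pct:.6g}\t{nm}\t{nu}\n")


def read_bismark_coverage(path, panel: Sequence[TargetCytosine],
                          sample_id: str) -> pd.DataFrame:
    """Read a Bismark cytosine coverage file into the internal count frame.

    Counts come from columns 5-6; the percentage column is ignored and
    recomputed downstream, guarding against inconsistent inputs.  Sites
    are matched to panel markers by (chromosome, 1-based position);
    unmatched sites are logged and skipped.  Strand-collapsed input is
    recorded on the marker's single strand, or on ``W`` for
    both-strand markers (the merge step sums strands anyway).
    """
    by_pos = {(m.chrom, m.pos): m for m in panel}
    rows, skipped = [], 0
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise QuantError(f"{path}: malformed coverage line: {line!r}")
            chrom, start = parts[0], int(parts[1])
            nm, nu = int(parts[4]), int(parts[5])
            m = by_pos.get((chrom, start))
            if m is None:
                skipped += 1
                continue
            strand = m.strands if m.strands in ("W", "C") else "W"
            rows.append((sample_id, m.marker_id, strand, nm, nu))
    if skipped:
        logger.warning("%s: skipped %d off-panel site(s)", path, skipped)
    return pd.DataFrame(rows, columns=["sample_id", "marker_id", "strand",
                                       "n_meth", "n_unmeth"])


def write_beta_matrix(matrix: pd.DataFrame, path, header_comment: str | None = None) -> None:
    """Beta matrix TSV: rows = samples, columns = markers, empty cell = missing."""
    with Path(path).open("w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        matrix.to_csv(fh, sep="\t", na_rep="")


def read_beta_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", comment="#", index_col="sample_id")
    return matrix.astype(float)


def write_qc_reports(reports: Sequence[QCReport], path) -> None:
    payload = [asdict(r) for r in reports]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
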