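"""Synthetic fixture panel and clock models.

The published coefficients of the four estimators (the 71-CpG Hannum
clock, the 6-CpG VISAGE blood-age model, the 46-CpG pace-of-aging score
and the 10-CpG mortality risk score) and the full marker list of the
161-site panel are external resources that users plug in as coefficient
and panel files.  So that every part of the pipeline runs and is testable
offline, this module builds *synthetic stand-ins* with the correct
structure:

* a 161-marker CG/CA panel with the real per-clock marker counts
  (71 HANNUM, 44 VISAGE, 46 POAM, 10 MRS), the real overlap structure
  (9 markers shared between VISAGE and HANNUM, 1 between MRS and POAM),
  plus two lambda conversion-control amplicons;
* an amplicon-assay design over 155 of the 161 markers (6 design
  failures) with 134 both-strand, 16 Watson-only and 5 Crick-only
  targets;
* one linear fixture clock per estimator, with weight scales chosen so
  that blood-cohort inversion (see
  :func:`methclock.simulate.invert_clock_betas`) keeps betas well inside
  [0.01, 0.99] for ages 1-100.

Marker identifiers, genomic positions, weights and imputation means are
deterministic pseudo-random draws (fixed internal seed) and carry no
biological meaning; the few recognizable CpG names included (e.g. the
ELOVL2 age marker cg16867657) mark where the synthetic panel mirrors
well-known loci.
"""

from __future__ import annotations

import numpy as np

from .clocks import ClockModel, MrsRule
from .panel import TargetCytosine, clock_panels

_FIXTURE_SEED = 161

#: Named age-associated loci mirrored in the synthetic VISAGE marker set.
_NAMED_VISAGE = [
    ("cg16867657", "chr6", 11044644, "ELOVL2"),
    ("cg08097417", "chr7", 130734372, "KLF14"),
    ("cg10501210", "chr1", 207823675, "MIR29B2CHG"),
    ("cg22454769", "chr2", 105399310, "FHL2"),
    ("cg17861230", "chr19", 18233091, "PDE4C"),
    ("cg09809672", "chr1", 236394382, "EDARADD"),
]

PANEL_HEADER_COMMENT = (
    "Synthetic fixture panel: 161 CG/CA clock markers + 2 lambda controls.\n"
    "Per-clock counts and overlaps are structural; marker ids and genomic\n"
    "positions are pseudo-random placeholders, not real panel content."
)


def _new_ids(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        cand = f"cg{rng.integers(0, 10**8):08d}"
        if cand not in taken:
            taken.add(cand)
            out.append(cand)
    return out


def _build():
    rng = np.random.default_rng(_FIXTURE_SEED)
    taken = {mid for mid, *_ in _NAMED_VISAGE}

    shared_hv = _new_ids(rng, 9, taken)              # VISAGE & HANNUM
    hannum_only = _new_ids(rng, 71 - 9, taken)
    visage_named = [mid for mid, *_ in _NAMED_VISAGE]
    visage_only = visage_named + _new_ids(rng, 44 - 9 - len(visage_named), taken)
    shared_pm = _new_ids(rng, 1, taken)              # POAM & MRS
    poam_only = _new_ids(rng, 46 - 1, taken)
    mrs_only = _new_ids(rng, 10 - 1, taken)

    membership: list[tuple[str, frozenset]] = []
    membership += [(m, frozenset({"HANNUM", "VISAGE"})) for m in shared_hv]
    membership += [(m, frozenset({"HANNUM"})) for m in hannum_only]
    membership += [(m, frozenset({"VISAGE"})) for m in visage_only]
    membership += [(m, frozenset({"POAM", "MRS"})) for m in shared_pm]
    membership += [(m, frozenset({"POAM"})) for m in poam_only]
    membership += [(m, frozenset({"MRS"})) for m in mrs_only]
    assert len(membership) == 161

    named_pos = {mid: (chrom, pos, region) for mid, chrom, pos, region in _NAMED_VISAGE}

    # Amplicon design: 6 failures; of the 155 designed markers 134 read
    # both strands, 16 Watson only, 5 Crick only.
    order = rng.permutation(161)
    failed = {membership[i][0] for i in order[:6]}
    designed_order = [membership[i][0] for i in order[6:]]
    strand_for = {m: "both" for m in failed}
    strand_for.update({m: "both" for m in designed_order[:134]})
    strand_for.update({m: "W" for m in designed_order[134:150]})
    strand_for.update({m: "C" for m in designed_order[150:]})

    markers: list[TargetCytosine] = []
    for mid, clocks in membership:
        if mid in named_pos:
            chrom, pos, region = named_pos[mid]
        else:
            chrom = f"chr{rng.integers(1, 23)}"
            pos = int(rng.integers(10**5, 2 * 10**8))
            region = f"locus_{mid[-5:]}"
        context = "CA" if rng.random() < 0.06 else "CG"
        markers.append(TargetCytosine(mid, chrom, pos, context, strand_for[mid],
                                      region, clocks))
    markers.append(TargetCytosine("lambda_ctrl_1", "lambda", 4500, "CG", "both",
                                  "lambda_amplicon_1", frozenset()))
    markers.append(TargetCytosine("lambda_ctrl_2", "lambda", 31000, "CG", "both",
                                  "lambda_amplicon_2", frozenset()))

    # --- fixture clocks -----------------------------------------------------
    panels = clock_panels(markers)

    def linear_clock(name, marker_ids, w_lo, w_hi, target_at_means, units):
        w = {m: float(rng.uniform(w_lo, w_hi) * rng.choice([-1.0, 1.0]))
             for m in marker_ids}
        mu = {m: float(rng.uniform(0.3, 0.7)) for m in marker_ids}
        intercept = target_at_means - sum(w[m] * mu[m] for m in marker_ids)
        return ClockModel(name, float(intercept), w, mu, units)

    visage_6 = [mid for mid, *_ in _NAMED_VISAGE]
    clocks = {
        "hannum_like": linear_clock("hannum_like", panels["HANNUM"].markers,
                                    3.0, 9.0, 44.0, "years"),
        "visage_like": linear_clock("visage_like", visage_6, 20.0, 60.0, 44.0, "years"),
        "poam_like": linear_clock("poam_like", panels["POAM"].markers,
                                  0.1, 0.5, 1.0, "poam"),
        "mrs_like": linear_clock("mrs_like", panels["MRS"].markers,
                                 0.5, 2.0, -2.5, "mrs"),
    }
    return markers, sorted(failed), clocks


_MARKERS, _FAILED, _CLOCKS = _build()


def fixture_panel() -> list[TargetCytosine]:
    """The synthetic 163-row panel (161 clock markers + 2 lambda controls)."""
    return list(_MARKERS)


def ampliseq_failed_markers() -> list[str]:
    """The 6 markers for which the synthetic amplicon design failed."""
    return list(_FAILED)


def fixture_ampliseq_design() -> list[TargetCytosine]:
    """The amplicon-assay subset: 155 designed markers + lambda controls."""
    failed = set(_FAILED)
    return [m for m in _MARKERS if m.marker_id not in failed]


def fixture_clocks() -> dict[str, ClockModel]:
    """The four synthetic linear estimators, keyed by fixture name."""
    return dict(_CLOCKS)


def fixture_mrs_rule() -> MrsRule:
    """Threshold rule for the categorical mortality score.

    Default convention: threshold = the marker's imputation mean,
    direction = the sign of its continuous weight (a beta on the side
    the weight pushes the continuous score toward higher risk counts as
    aberrant).
    """
    mrs = _CLOCKS["mrs_like"]
    thresholds = dict(mrs.imputation_means)
    directions = {m: (1 if w >= 0 else -1) for m, w in mrs.weights.items()}
    return MrsRule(thresholds, directions)
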