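"""Splicing-efficiency formulas for quantified gel / RT-PCR product intensities.

Inputs are background-subtracted band or product intensities (arbitrary
densitometry units); no image analysis happens here. All percentages are
held internally as fractions in [0, 1] and rendered x100 in reports.

Implemented quantities:

* ``percent_splicing``       spliced / (unspliced + spliced), one lane
* ``percent_pt_splicing``    post-transcriptional gain after a transcription
  block: (spliced_120 - spliced_45) / (unspliced + (spliced_120 - spliced_45)),
  the unspliced term taken from the later (120-min) lane
* ``percent_inclusion``      included / (included + skipped), a PSI-style
  measure for one alternative exon
* ``transcription_level``    total (unspliced + spliced) signal relative to a
  reference lane set to 100%
* ``compare_to_control``     replicate-level comparison of two conditions
  (Welch's unequal-variance t test by default, exact permutation optional)
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from statistics import fmean
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .errors import ConfigError, UnquantifiableLaneError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LaneQuant:
    """Quantified spliced/unspliced intensities of one reaction lane."""

    sample_id: str
    unspliced: float
    spliced: float
    timepoint_min: float | None = None

    def __post_init__(self) -> None:
        if self.unspliced < 0 or self.spliced < 0:
            raise ValueError(f"lane {self.sample_id}: negative intensity")

    @property
    def total(self) -> float:
        return self.unspliced + self.spliced


@dataclass(frozen=True)
class InclusionQuant:
    """Included/skipped isoform intensities for one alternative exon."""

    sample_id: str
    included_intensity: float
    skipped_intensity: float
    exon_label: str = ""

    def __post_init__(self) -> None:
        if self.included_intensity < 0 or self.skipped_intensity < 0:
            raise ValueError(f"sample {self.sample_id}: negative intensity")


def percent_splicing(lane: LaneQuant) -> float:
    """Fraction of spliced product in one lane: spliced/(unspliced+spliced)."""
    if lane.total <= 0:
        raise UnquantifiableLaneError(f"lane {lane.sample_id}: zero total signal")
    return lane.spliced / lane.total


def percent_pt_splicing(lane_45: LaneQuant, lane_120: LaneQuant) -> float:
    """Post-transcriptional splicing between an early and a late timepoint.

    The spliced signal present at the early timepoint is subtracted so only
    splicing that happened after the transcription block is counted; the
    unspliced denominator term is the late lane's. A negative raw gain
    (spliced signal apparently decreasing) is measurement noise and clamps
    to 0 with a warning.
    """
    if lane_45.timepoint_min is None or lane_120.timepoint_min is None:
        raise ValueError("both lanes need a timepoint_min to order them")
    if not lane_45.timepoint_min < lane_120.timepoint_min:
        raise ValueError(
            f"early lane ({lane_45.timepoint_min} min) must precede late lane "
            f"({lane_120.timepoint_min} min)")
    gain = lane_120.spliced - lane_45.spliced
    if gain < 0:
        logger.warning(
            "lane %s -> %s: spliced signal decreased (%.3g); clamping gain to 0",
            lane_45.sample_id, lane_120.sample_id, gain)
        gain = 0.0
    denom = lane_120.unspliced + gain
    if denom <= 0:
        raise UnquantifiableLaneError(
            f"lane {lane_120.sample_id}: no unspliced signal and no spliced gain")
    return gain / denom


def percent_inclusion(q: InclusionQuant) -> float:
    """Fraction of the included isoform: included/(included+skipped)."""
    total = q.included_intensity + q.skipped_intensity
    if total <= 0:
        raise UnquantifiableLaneError(f"sample {q.sample_id}: zero total isoform signal")
    return q.included_intensity / total


def transcription_level(lanes: Sequence[LaneQuant], reference: str) -> dict[str, float]:
    """Total RNA signal per lane as a percentage of a reference lane (=100)."""
    by_id = {lane.sample_id: lane for lane in lanes}
    if reference not in by_id:
        raise ValueError(f"reference lane {reference!r} not among lanes")
    ref_total = by_id[reference].total
    if ref_total <= 0:
        raise UnquantifiableLaneError(f"reference lane {reference!r} has zero total signal")
    return {lane.sample_id: 100.0 * lane.total / ref_total for lane in lanes}


@dataclass(frozen=True)
class ComparisonResult:
    """Replicate comparison of treated vs control splicing fractions."""

    difference_pp: float  # mean difference, percentage points
    p_value: float
    significant: bool
    method: str
    n_treated: int
    n_control: int


def _exact_permutation_p(treated: Sequence[float], control: Sequence[float]) -> float:
    """Two-sided exact permutation p for the difference of group means,
    enumerating every reassignment of the pooled values."""
    pooled = list(treated) + list(control)
    nt = len(treated)
    observed = abs(fmean(treated) - fmean(control))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nt):
        chosen = set(idx)
        a = [pooled[i] for i in chosen]
        b = [pooled[i] for i in range(len(pooled)) if i not in chosen]
        if abs(fmean(a) - fmean(b)) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def compare_to_control(
    treated: Sequence[float],
    control: Sequence[float],
    alpha: float = 0.05,
    method: str = "welch",
) -> ComparisonResult:
    """Compare replicate splicing fractions of a treated condition to control.

    Default is Welch's two-sided unequal-variance t test; ``method=
    "permutation"`` enumerates all group reassignments exactly (suited to
    triplicate designs). Both groups need >= 2 replicates in [0, 1]. The
    difference is reported in percentage points (fraction x 100). When both
    groups are constant the test degenerates: p = 1 if the means agree,
    p = 0 otherwise.
    """
    for name, grp in (("treated", treated), ("control", control)):
        if len(grp) < 2:
            raise ValueError(f"{name} group needs >= 2 replicates, got {len(grp)}")
        if any(not (0 <= v <= 1) for v in grp):
            raise ValueError(f"{name} group holds values outside [0, 1]")
    if not 0 < alpha < 1:
        raise ConfigError(f"alpha must be in (0, 1), got {alpha!r}")

    diff = fmean(treated) - fmean(control)
    var_t = stats.tvar(treated) if len(set(treated)) > 1 else 0.0
    var_c = stats.tvar(control) if len(set(control)) > 1 else 0.0

    if method == "permutation":
        p = _exact_permutation_p(treated, control)
    elif method == "welch":
        if var_t == 0 and var_c == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(treated, control, equal_var=False).pvalue)
    else:
        raise ConfigError(f"unknown method {method!r}")

    return ComparisonResult(
        difference_pp=100.0 * diff,
        p_value=p,
        significant=p < alpha,
        method=method,
        n_treated=len(treated),
        n_control=len(control),
    )
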