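"""Screen statistic and decision rules for the dual-luciferase splicing screen.

The readout of one well is the R/F ratio — Renilla over Firefly luminescence —
which reports reporter splicing normalized to transcription. Effects are
computed in log2(R/F) space, anchored to the on-plate controls:

    delta(siRNA)        = mean log2(R/F | siRNA wells) - mean log2(R/F | negative-control wells)
    normalized magnitude = |delta(siRNA)| / |delta(positive control)|

A siRNA is a hit when its normalized magnitude reaches at least 0.5 (50% of
the positive-control effect, boundary inclusive). A gene is a hit when at
least two of its siRNAs are hits; a gene whose every siRNA (three or more) is
a hit is a "triple hit". Both R/F increases and decreases count as effects:
the magnitude is taken before thresholding, and gene direction records the
common sign of the hit siRNAs.

Working in log space makes the statistic invariant to rescaling a plate's
luminescence and to multiplicative plate effects — both cancel in the
control-anchored subtraction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from statistics import fmean, stdev
from typing import Iterable, Mapping, Sequence

from . import screen_io
from .errors import (
    ConfigError,
    DegenerateControlError,
    IntegrityError,
    InvalidWellError,
    MissingConditionError,
)
from .screen_io import (
    ROLE_LIBRARY,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ScreenDataset,
    WellMeasurement,
)

logger = logging.getLogger(__name__)

DIRECTION_DOWN = "-1"
DIRECTION_UP = "+1"
DIRECTION_NONE = "none"
DIRECTION_DISCORDANT = "discordant"

STATUS_NOT_HIT = "not_hit"
STATUS_HIT = "hit"
STATUS_TRIPLE_HIT = "triple_hit"


@dataclass(frozen=True)
class RFRatio:
    """Renilla/Firefly ratio of one well; log2 is NaN when the ratio is 0."""

    value: float
    log2_value: float

    @property
    def in_log_domain(self) -> bool:
        return math.isfinite(self.log2_value)


def compute_rf_ratio(renilla: float, firefly: float) -> RFRatio:
    """R/F ratio of one well. Renilla may be zero (ratio 0, excluded from
    log-domain summaries); firefly must be strictly positive."""
    if not math.isfinite(firefly) or firefly <= 0:
        raise InvalidWellError(f"firefly luminescence must be > 0, got {firefly!r}")
    if not math.isfinite(renilla) or renilla < 0:
        raise InvalidWellError(f"renilla luminescence must be >= 0, got {renilla!r}")
    value = renilla / firefly
    return RFRatio(value=value, log2_value=math.log2(value) if value > 0 else math.nan)


@dataclass(frozen=True)
class ConditionSummary:
    """Mean log2(R/F) over the usable wells of one condition on one scope."""

    mean_log2: float
    sd: float
    n: int


def summarize_condition(wells: Iterable[WellMeasurement]) -> ConditionSummary:
    """Aggregate one siRNA's (or control's) wells: arithmetic mean of
    log2(R/F) over valid wells with renilla > 0; sample sd (0 when n = 1)."""
    logs = []
    for w in wells:
        if not w.valid:
            continue
        ratio = compute_rf_ratio(w.renilla, w.firefly)
        if ratio.in_log_domain:
            logs.append(ratio.log2_value)
        else:
            logger.warning("well %s/%s has zero renilla; excluded from log summary",
                           w.plate_id, w.well_id)
    if not logs:
        raise MissingConditionError("no valid wells with renilla > 0")
    return ConditionSummary(
        mean_log2=fmean(logs),
        sd=stdev(logs) if len(logs) > 1 else 0.0,
        n=len(logs),
    )


@dataclass(frozen=True)
class SiRNAEffect:
    """Control-anchored effect of one siRNA.

    ``delta`` is log2 units; ``normalized_magnitude`` expresses |delta| as a
    fraction of the positive-control effect on the same scope; ``direction``
    is the sign of delta (0 iff delta == 0).
    """

    sirna_id: str
    delta: float
    normalized_magnitude: float
    direction: int
    n_wells: int


def compute_effect(
    sirna_summary: ConditionSummary,
    negative_summary: ConditionSummary,
    positive_summary: ConditionSummary,
    sirna_id: str = "",
) -> SiRNAEffect:
    """Anchor a siRNA summary to controls from the same normalization scope."""
    delta = sirna_summary.mean_log2 - negative_summary.mean_log2
    delta_positive = positive_summary.mean_log2 - negative_summary.mean_log2
    if delta_positive == 0:
        raise DegenerateControlError(
            "positive-control effect is zero; normalized magnitude undefined")
    return SiRNAEffect(
        sirna_id=sirna_id,
        delta=delta,
        normalized_magnitude=abs(delta) / abs(delta_positive),
        direction=0 if delta == 0 else (1 if delta > 0 else -1),
        n_wells=sirna_summary.n,
    )


@dataclass(frozen=True)
class SiRNACall:
    sirna_id: str
    effect: SiRNAEffect
    is_hit: bool


def call_sirna(effect: SiRNAEffect, threshold: float = 0.5) -> SiRNACall:
    """Hit iff normalized magnitude >= threshold ("at least 50%" is inclusive)."""
    if not (threshold > 0 and math.isfinite(threshold)):
        raise ConfigError(f"hit threshold must be a positive finite fraction, got {threshold!r}")
    return SiRNACall(
        sirna_id=effect.sirna_id,
        effect=effect,
        is_hit=effect.normalized_magnitude >= threshold,
    )


@dataclass(frozen=True)
class GeneCall:
    """Gene-level decision aggregated over that gene's siRNAs."""

    gene: str
    gene_ncbi_id: int | None
    n_sirnas: int
    n_hits: int
    direction: str
    status: str
    sirna_calls: tuple[SiRNACall, ...] = ()

    @property
    def is_hit(self) -> bool:
        return self.status != STATUS_NOT_HIT


def aggregate_gene(
    gene: str,
    calls: Sequence[SiRNACall],
    min_hits: int = 2,
    require_concordance: bool = True,
    gene_ncbi_id: int | None = None,
) -> GeneCall:
    """Apply the gene selection rule to one gene's siRNA calls.

    A gene is a hit with >= ``min_hits`` hit siRNAs; a triple hit additionally
    requires >= 3 siRNAs, every one of them a hit. When
    ``require_concordance`` is on, hit siRNAs pointing in opposite directions
    demote the gene to not_hit (direction reported as "discordant" —
    opposite-signed effects for the same gene suggest off-target artifacts).
    """
    if not calls:
        raise ValueError(f"gene {gene}: no siRNA calls to aggregate")
    hits = [c for c in calls if c.is_hit]
    n_hits = len(hits)
    hit_signs = {c.effect.direction for c in hits}
    concordant = len(hit_signs) <= 1

    if concordant:
        direction = DIRECTION_NONE if not hits else (
            DIRECTION_UP if hits[0].effect.direction >= 0 else DIRECTION_DOWN)
    else:
        direction = DIRECTION_DISCORDANT

    qualifies = n_hits >= min_hits and (concordant or not require_concordance)
    if qualifies and n_hits == len(calls) and len(calls) >= 3:
        status = STATUS_TRIPLE_HIT
    elif qualifies:
        status = STATUS_HIT
    else:
        status = STATUS_NOT_HIT
    return GeneCall(
        gene=gene,
        gene_ncbi_id=gene_ncbi_id,
        n_sirnas=len(calls),
        n_hits=n_hits,
        direction=direction,
        status=status,
        sirna_calls=tuple(calls),
    )


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable decision parameters of the screen analysis."""

    threshold: float = 0.5
    min_hits: int = 2
    require_concordance: bool = True
    normalization_scope: str = "plate"  # "plate" (screen-wide fallback) or "screen"

    def __post_init__(self) -> None:
        if self.normalization_scope not in ("plate", "screen"):
            raise ConfigError(f"unknown normalization_scope {self.normalization_scope!r}")
        if self.min_hits < 1:
            raise ConfigError("min_hits must be >= 1")


@dataclass
class ScreenSummary:
    """Screen-level report: counts and the per-plate control effects."""

    n_genes: int
    n_hit_genes: int
    n_triple_hits: int
    control_effects: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


def _control_summaries(
    dataset: ScreenDataset, config: ScreenConfig
) -> tuple[Mapping[str, tuple[ConditionSummary, ConditionSummary]], list[str]]:
    """Per-plate (negative, positive) control summaries with screen-wide
    fallback. Returns a mapping plate_id -> summaries and warning strings."""
    index = dataset.library_index()
    by_plate: dict[str, dict[str, list[WellMeasurement]]] = {}
    screen_wide: dict[str, list[WellMeasurement]] = {ROLE_NEGATIVE: [], ROLE_POSITIVE: []}
    plates: set[str] = set()
    for w in dataset.wells:
        plates.add(w.plate_id)
        rec = index.get(w.sirna_id)
        if rec is None or rec.role == ROLE_LIBRARY:
            continue
        by_plate.setdefault(w.plate_id, {ROLE_NEGATIVE: [], ROLE_POSITIVE: []})
        by_plate[w.plate_id][rec.role].append(w)
        screen_wide[rec.role].append(w)

    def summarize_pair(neg: list, pos: list, scope: str):
        try:
            return summarize_condition(neg), summarize_condition(pos)
        except MissingConditionError:
            raise MissingConditionError(f"unusable control wells on scope {scope!r}") from None

    warnings: list[str] = []
    out: dict[str, tuple[ConditionSummary, ConditionSummary]] = {}
    if config.normalization_scope == "screen":
        pair = summarize_pair(screen_wide[ROLE_NEGATIVE], screen_wide[ROLE_POSITIVE], "screen")
        for p in plates:
            out[p] = pair
        return out, warnings

    fallback: tuple[ConditionSummary, ConditionSummary] | None = None
    for p in sorted(plates):
        plate_controls = by_plate.get(p, {ROLE_NEGATIVE: [], ROLE_POSITIVE: []})
        if plate_controls[ROLE_NEGATIVE] and plate_controls[ROLE_POSITIVE]:
            out[p] = summarize_pair(plate_controls[ROLE_NEGATIVE],
                                    plate_controls[ROLE_POSITIVE], p)
        else:
            if fallback is None:
                fallback = summarize_pair(screen_wide[ROLE_NEGATIVE],
                                          screen_wide[ROLE_POSITIVE], "screen")
            msg = f"plate {p} lacks on-plate controls; using screen-wide controls"
            warnings.append(msg)
            logger.warning(msg)
            out[p] = fallback
    return out, warnings


def run_screen(
    dataset: ScreenDataset, config: ScreenConfig | None = None
) -> tuple[list[GeneCall], ScreenSummary]:
    """Run the full decision chain on a validated screen.

    Deterministic in its inputs: wells are grouped (never ordered) and the
    output is sorted by gene key, so permuting input rows cannot change any
    call. When a siRNA's wells span several plates each plate contributes a
    control-anchored delta and the per-plate deltas and positive-control
    effects are combined by a well-count-weighted mean.
    """
    config = config or ScreenConfig()
    blocking = {"ORPHAN_WELL", "DUPLICATE_WELL", "EMPTY_LIBRARY", "EMPTY_WELLS",
                "NO_NEGATIVE_CONTROL", "NO_POSITIVE_CONTROL"}
    problems = [v for v in screen_io.validate_screen(dataset) if v.code in blocking]
    if problems:
        raise IntegrityError(
            "screen fails validation: " + "; ".join(f"{v.code}: {v.message}" for v in problems))

    controls, warnings = _control_summaries(dataset, config)
    for plate, (neg, pos) in controls.items():
        if pos.mean_log2 - neg.mean_log2 == 0:
            raise DegenerateControlError(
                f"plate {plate!r}: positive- and negative-control means coincide")

    index = dataset.library_index()
    # per-siRNA wells, split by plate
    sirna_wells: dict[str, dict[str, list[WellMeasurement]]] = {}
    for w in dataset.wells:
        rec = index[w.sirna_id]
        if rec.role != ROLE_LIBRARY:
            continue
        sirna_wells.setdefault(w.sirna_id, {}).setdefault(w.plate_id, []).append(w)

    effects: dict[str, SiRNAEffect] = {}
    for sid in sorted(sirna_wells):
        per_plate: list[tuple[float, float, int]] = []  # (delta, delta_pos, n)
        for plate, wells in sirna_wells[sid].items():
            try:
                summary = summarize_condition(wells)
            except MissingConditionError:
                continue
            neg, pos = controls[plate]
            per_plate.append((summary.mean_log2 - neg.mean_log2,
                              pos.mean_log2 - neg.mean_log2, summary.n))
        if not per_plate:
            logger.warning("siRNA %s has no usable wells; excluded", sid)
            continue
        n_total = sum(n for _, _, n in per_plate)
        delta = sum(d * n for d, _, n in per_plate) / n_total
        delta_pos = sum(dp * n for _, dp, n in per_plate) / n_total
        effects[sid] = SiRNAEffect(
            sirna_id=sid,
            delta=delta,
            normalized_magnitude=abs(delta) / abs(delta_pos),
            direction=0 if delta == 0 else (1 if delta > 0 else -1),
            n_wells=n_total,
        )

    # group siRNA calls by gene identity key
    by_gene: dict[str, list[SiRNACall]] = {}
    gene_meta: dict[str, tuple[str, int | None]] = {}
    for rec in dataset.library:
        if rec.role != ROLE_LIBRARY or rec.sirna_id not in effects:
            continue
        key = rec.gene_key
        by_gene.setdefault(key, []).append(call_sirna(effects[rec.sirna_id], config.threshold))
        gene_meta.setdefault(key, (rec.gene_symbol, rec.gene_ncbi_id))

    calls = []
    for key in sorted(by_gene):
        symbol, ncbi = gene_meta[key]
        calls.append(aggregate_gene(
            symbol or key,
            sorted(by_gene[key], key=lambda c: c.sirna_id),
            min_hits=config.min_hits,
            require_concordance=config.require_concordance,
            gene_ncbi_id=ncbi,
        ))

    summary = ScreenSummary(
        n_genes=len(calls),
        n_hit_genes=sum(1 for c in calls if c.is_hit),
        n_triple_hits=sum(1 for c in calls if c.status == STATUS_TRIPLE_HIT),
        control_effects={p: pos.mean_log2 - neg.mean_log2 for p, (neg, pos) in controls.items()},
        warnings=warnings,
    )
    return calls, summary
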