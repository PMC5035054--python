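"""Synthetic screens, lane tables and factor tables with known ground truth.

No public accession holds the raw screen luminescence, so every analysis
module here is exercised on generated data whose generating process matches
the assumptions of the statistic: multiplicative (log-normal) well noise on
both luciferases, a multiplicative per-plate factor on R/F, and siRNA
knockdown effects acting multiplicatively on the R/F ratio (additively in
log2). Truth tables ride along so recovery can be scored exactly.

Default design = the published screen's stated conditions: 375 genes covered
by 1155 siRNAs (345 genes x 3 siRNAs + 30 genes x 4 — the one composition of
3s and 4s matching both totals), duplicate wells per siRNA, 96-well plates,
and a positive control that halves the R/F ratio (effect -1 in log2). Control
wells (4 negative + 4 positive per plate) occupy the first half-row of each
plate; the layout is a convention of this generator, not a reproduced fact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError
from .factor_overlap import GROUPS, PTM_TAGS, FactorRecord
from .hit_calling import GeneCall
from .screen_io import (
    CONTROL_GENE_LABEL,
    ROLE_LIBRARY,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ScreenDataset,
    SiRNARecord,
    WellMeasurement,
)
from .splicing_quant import LaneQuant

NEGATIVE_CONTROL_ID = "siNEG"
POSITIVE_CONTROL_ID = "siPOS"

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


@dataclass(frozen=True)
class ScreenDesign:
    """Generative specification of one synthetic screen.

    ``sirnas_per_gene`` is either one integer (every gene gets that many
    siRNAs) or a mapping {siRNAs-per-gene: number-of-genes} summing to
    ``n_genes``. ``effect_table`` maps gene symbol -> per-siRNA log2 R/F
    effects (a scalar applies to all of that gene's siRNAs); genes absent
    from it have effect 0 and are the true negatives.
    """

    n_genes: int = 375
    sirnas_per_gene: Union[int, Mapping[int, int]] = field(
        default_factory=lambda: {3: 345, 4: 30})
    n_replicates: int = 2
    plate_size: int = 96
    effect_table: Mapping[str, Union[float, Sequence[float]]] = field(default_factory=dict)
    positive_control_effect: float = -1.0
    noise_sd: float = 0.1
    baseline_firefly: float = 1e5
    baseline_rf: float = 1.0
    plate_factor_sd: float = 0.1
    n_neg_controls_per_plate: int = 4
    n_pos_controls_per_plate: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.noise_sd < 0 or self.plate_factor_sd < 0:
            raise ConfigError("noise sd parameters must be >= 0")
        if self.positive_control_effect == 0:
            raise ConfigError("positive_control_effect must be nonzero")
        if isinstance(self.sirnas_per_gene, Mapping):
            if sum(self.sirnas_per_gene.values()) != self.n_genes:
                raise ConfigError(
                    "sirnas_per_gene mapping must account for every gene "
                    f"(sums to {sum(self.sirnas_per_gene.values())}, n_genes={self.n_genes})")
            if any(k < 1 for k in self.sirnas_per_gene):
                raise ConfigError("siRNA counts must be >= 1")
        elif self.sirnas_per_gene < 1:
            raise ConfigError("sirnas_per_gene must be >= 1")

    def sirna_counts(self) -> list[int]:
        """Per-gene siRNA counts, in gene order."""
        if isinstance(self.sirnas_per_gene, int):
            return [self.sirnas_per_gene] * self.n_genes
        counts: list[int] = []
        for per_gene in sorted(self.sirnas_per_gene):
            counts.extend([per_gene] * self.sirnas_per_gene[per_gene])
        return counts


@dataclass
class SimulatedScreen:
    """A generated dataset plus the truth table it was generated from."""

    dataset: ScreenDataset
    truth: dict[str, bool]  # gene key -> is a true effector
    design: ScreenDesign


def _gene_symbol(i: int) -> str:
    return f"GENE{i + 1:04d}"


def generate_library(design: ScreenDesign) -> tuple[SiRNARecord, ...]:
    """Deterministic library for a design: numbered genes with sequential
    NCBI-style ids, per-gene siRNA counts from the design, plus the two
    control records."""
    records: list[SiRNARecord] = []
    for g, count in enumerate(design.sirna_counts()):
        symbol = _gene_symbol(g)
        ncbi = 100001 + g
        for s in range(count):
            records.append(SiRNARecord(
                sirna_id=f"{symbol}_si{s + 1}",
                gene_symbol=symbol,
                gene_ncbi_id=ncbi,
                role=ROLE_LIBRARY,
            ))
    records.append(SiRNARecord(NEGATIVE_CONTROL_ID, CONTROL_GENE_LABEL, None, ROLE_NEGATIVE))
    records.append(SiRNARecord(POSITIVE_CONTROL_ID, CONTROL_GENE_LABEL, None, ROLE_POSITIVE))
    return tuple(records)


def _effects_for_gene(design: ScreenDesign, symbol: str, n_sirnas: int) -> list[float]:
    spec = design.effect_table.get(symbol, 0.0)
    if isinstance(spec, (int, float)):
        return [float(spec)] * n_sirnas
    effects = [float(x) for x in spec]
    if len(effects) != n_sirnas:
        raise ConfigError(
            f"effect_table[{symbol!r}] lists {len(effects)} effects for {n_sirnas} siRNAs")
    return effects


def _well_id(idx: int) -> str:
    return f"{PLATE_ROWS[idx // PLATE_COLS]}{idx % PLATE_COLS + 1}"


def generate_screen(design: ScreenDesign) -> SimulatedScreen:
    """Simulate luminescence for a full screen.

    Per well: firefly = baseline * 2^N(0, noise_sd); R/F = baseline_rf *
    2^(effect + plate_factor + N(0, noise_sd)); renilla = R/F * firefly.
    Each siRNA's replicate wells sit on one plate; each plate carries its own
    control wells, so control anchoring absorbs the plate factor.
    """
    rng = np.random.default_rng(design.seed)
    library = generate_library(design)
    lib_records = [r for r in library if r.role == ROLE_LIBRARY]

    n_controls = design.n_neg_controls_per_plate + design.n_pos_controls_per_plate
    per_sirna = design.n_replicates
    capacity = (design.plate_size - n_controls) // per_sirna
    if capacity < 1:
        raise ConfigError(
            f"plate of {design.plate_size} wells cannot fit {n_controls} control wells "
            f"plus {per_sirna} replicate wells for any siRNA")

    # effect per siRNA id
    counts = design.sirna_counts()
    effect_of: dict[str, float] = {}
    for g, count in enumerate(counts):
        symbol = _gene_symbol(g)
        for s, eff in enumerate(_effects_for_gene(design, symbol, count)):
            effect_of[f"{symbol}_si{s + 1}"] = eff

    wells: list[WellMeasurement] = []
    n_plates = math.ceil(len(lib_records) / capacity)
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        plate_factor = rng.normal(0.0, design.plate_factor_sd) if design.plate_factor_sd else 0.0
        idx = 0

        def emit(sirna_id: str, effect: float, replicate: int) -> None:
            nonlocal idx
            firefly = design.baseline_firefly * 2.0 ** rng.normal(0.0, design.noise_sd)
            rf = design.baseline_rf * 2.0 ** (
                effect + plate_factor + rng.normal(0.0, design.noise_sd))
            wells.append(WellMeasurement(
                plate_id=plate_id,
                well_id=_well_id(idx),
                sirna_id=sirna_id,
                renilla=rf * firefly,
                firefly=firefly,
                replicate_index=replicate,
            ))
            idx += 1

        for r in range(design.n_neg_controls_per_plate):
            emit(NEGATIVE_CONTROL_ID, 0.0, r + 1)
        for r in range(design.n_pos_controls_per_plate):
            emit(POSITIVE_CONTROL_ID, design.positive_control_effect, r + 1)
        for rec in lib_records[p * capacity:(p + 1) * capacity]:
            for r in range(design.n_replicates):
                emit(rec.sirna_id, effect_of[rec.sirna_id], r + 1)

    truth: dict[str, bool] = {}
    for g, count in enumerate(counts):
        symbol = _gene_symbol(g)
        key = str(100001 + g)
        truth[key] = any(e != 0 for e in _effects_for_gene(design, symbol, count))

    dataset = ScreenDataset(library=library, wells=tuple(wells),
                            metadata={"generator": "splicescreen.synthetic_data",
                                      "seed": design.seed})
    return SimulatedScreen(dataset=dataset, truth=truth, design=design)


def generate_lane_table(
    true_percent_splicing: float,
    total_intensity: float = 1000.0,
    noise_cv: float = 0.05,
    n: int = 3,
    seed: int = 0,
) -> tuple[LaneQuant, ...]:
    """Lanes whose spliced fraction scatters around a known truth.

    Spliced and unspliced intensities each get independent multiplicative
    log-normal noise with coefficient of variation ``noise_cv``, so the mean
    recovered fraction approaches the truth as n grows.
    """
    if not 0 <= true_percent_splicing <= 1:
        raise ConfigError("true_percent_splicing must lie in [0, 1]")
    if noise_cv < 0:
        raise ConfigError("noise_cv must be >= 0")
    if total_intensity <= 0:
        raise ConfigError("total_intensity must be > 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1 + noise_cv ** 2)) if noise_cv > 0 else 0.0
    lanes = []
    for i in range(n):
        noise_s = math.exp(rng.normal(-sigma ** 2 / 2, sigma)) if sigma else 1.0
        noise_u = math.exp(rng.normal(-sigma ** 2 / 2, sigma)) if sigma else 1.0
        lanes.append(LaneQuant(
            sample_id=f"lane{i + 1}",
            spliced=total_intensity * true_percent_splicing * noise_s,
            unspliced=total_intensity * (1 - true_percent_splicing) * noise_u,
        ))
    return tuple(lanes)


def generate_factor_table(n_per_group: Mapping[str, int], seed: int = 0) -> tuple[FactorRecord, ...]:
    """Synthetic factor evidence records, ``n_per_group`` keyed by the frozen
    group vocabulary. PTM tags are drawn only for the histone-PTM group."""
    unknown = [g for g in n_per_group if g not in GROUPS]
    if unknown:
        raise ConfigError(f"unknown group(s): {unknown}")
    rng = np.random.default_rng(seed)
    records = []
    i = 0
    for group in GROUPS:
        for _ in range(int(n_per_group.get(group, 0))):
            i += 1
            peptides = int(rng.integers(1, 30))
            records.append(FactorRecord(
                symbol=f"FCT{i:03d}",
                alias=f"ALT{i:03d}",
                ncbi_gene_id=900000 + i,
                mr_kd=float(np.round(rng.uniform(15, 500), 1)),
                unique_peptides=peptides,
                percent_coverage=float(np.round(rng.uniform(1, 45), 0)),
                log_e=float(np.round(-1.5 - 11.0 * peptides * rng.uniform(0.5, 1.5), 1)),
                group=group,
                ptm_tag=(str(rng.choice(PTM_TAGS))
                         if group == "Histone PTMs regulators" else None),
            ))
    return tuple(records)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Confusion-matrix fractions of a screen's gene calls against truth."""

    sensitivity: float
    specificity: float
    false_positive_rate: float
    n_true: int
    n_null: int


def recovery_metrics(calls: Sequence[GeneCall], truth: Mapping[str, bool]) -> RecoveryMetrics:
    """Score gene-level calls against a generator truth table (keyed by gene
    identity key)."""
    from .screen_io import gene_key

    tp = fp = tn = fn = 0
    for c in calls:
        key = gene_key(c.gene, c.gene_ncbi_id)
        if key not in truth:
            raise IntegrityError(f"called gene {key!r} absent from the truth table")
        if truth[key]:
            tp, fn = (tp + 1, fn) if c.is_hit else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if c.is_hit else (fp, tn + 1)
    n_true, n_null = tp + fn, fp + tn
    return RecoveryMetrics(
        sensitivity=tp / n_true if n_true else float("nan"),
        specificity=tn / n_null if n_null else float("nan"),
        false_positive_rate=fp / n_null if n_null else float("nan"),
        n_true=n_true,
        n_null=n_null,
    )


def write_screen_tables(sim: SimulatedScreen, out_dir: str | Path) -> dict[str, Path]:
    """Emit library.csv, measurements.csv and truth.csv for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": out / "library.csv",
        "measurements": out / "measurements.csv",
        "truth": out / "truth.csv",
    }
    pd.DataFrame([
        {"sirna_id": r.sirna_id, "gene_symbol": r.gene_symbol,
         "gene_ncbi_id": "" if r.gene_ncbi_id is None else r.gene_ncbi_id,
         "role": r.role}
        for r in sim.dataset.library
    ]).to_csv(paths["library"], index=False)
    pd.DataFrame([
        {"plate_id": w.plate_id, "well_id": w.well_id, "sirna_id": w.sirna_id,
         "replicate_index": w.replicate_index,
         "renilla": repr(w.renilla), "firefly": repr(w.firefly)}
        for w in sim.dataset.wells
    ]).to_csv(paths["measurements"], index=False)
    pd.DataFrame(
        [{"gene_key": k, "true_effector": v} for k, v in sim.truth.items()]
    ).to_csv(paths["truth"], index=False)
    return paths
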