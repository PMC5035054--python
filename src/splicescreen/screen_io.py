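"""Data model and validated I/O for siRNA screen libraries and plate readouts.

The screen couples a splicing readout (Renilla luciferase, produced only when
the reporter's alternative exons are spliced in-frame) to a transcription
readout (Firefly luciferase) in 96-well plates. This module holds the typed
records for library entries and per-well luminescence pairs, the delimited-text
readers/writers, and structural validation of an assembled screen dataset.

Tables are comma-separated UTF-8 with one header row; tab-separated input is
accepted through the ``delimiter`` option. Wells with a non-positive Firefly
signal are flagged invalid rather than dropped or raised on: a single dead
well must not abort a screen, and downstream summaries exclude invalid wells
explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError, TableParseError

logger = logging.getLogger(__name__)

ROLE_LIBRARY = "library"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLES = (ROLE_LIBRARY, ROLE_NEGATIVE, ROLE_POSITIVE)

#: reserved gene label carried by control siRNA records
CONTROL_GENE_LABEL = "CONTROL"

LIBRARY_COLUMNS = ("sirna_id", "gene_symbol", "gene_ncbi_id", "role")
MEASUREMENT_COLUMNS = (
    "plate_id", "well_id", "sirna_id", "replicate_index", "renilla", "firefly",
)
HIT_TABLE_COLUMNS = ("gene", "gene_ncbi_id", "n_sirnas", "n_hits", "direction", "status")


def gene_key(symbol: str, ncbi_id: int | None) -> str:
    """Canonical gene identity: the NCBI Gene Id when present, else the
    upper-cased symbol. Both identifier styles occur in screen libraries and
    proteomics tables; the numeric id is unambiguous when available."""
    if ncbi_id is not None and not (isinstance(ncbi_id, float) and math.isnan(ncbi_id)):
        return str(int(ncbi_id))
    return symbol.strip().upper()


@dataclass(frozen=True)
class SiRNARecord:
    """One library or control siRNA and the gene it targets."""

    sirna_id: str
    gene_symbol: str
    gene_ncbi_id: int | None = None
    role: str = ROLE_LIBRARY

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown siRNA role {self.role!r}")
        if self.role == ROLE_LIBRARY and not self.gene_symbol:
            raise ValueError(f"library siRNA {self.sirna_id} lacks a gene identifier")

    @property
    def gene_key(self) -> str:
        return gene_key(self.gene_symbol, self.gene_ncbi_id)

    @property
    def is_control(self) -> bool:
        return self.role != ROLE_LIBRARY


@dataclass(frozen=True)
class WellMeasurement:
    """One well's paired luminescence readout.

    ``valid`` is False when firefly <= 0 or either count is non-finite; such
    wells are retained so that record counts always reconcile with input rows.
    """

    plate_id: str
    well_id: str
    sirna_id: str
    renilla: float
    firefly: float
    replicate_index: int = 1
    valid: bool = True


@dataclass
class ScreenDataset:
    """A full screen: library, well measurements and free-form metadata."""

    library: tuple[SiRNARecord, ...]
    wells: tuple[WellMeasurement, ...]
    metadata: dict = field(default_factory=dict)

    def library_index(self) -> dict[str, SiRNARecord]:
        return {r.sirna_id: r for r in self.library}

    def wells_by_sirna(self) -> dict[str, list[WellMeasurement]]:
        out: dict[str, list[WellMeasurement]] = {}
        for w in self.wells:
            out.setdefault(w.sirna_id, []).append(w)
        return out


@dataclass(frozen=True)
class Violation:
    """One machine-readable validation finding."""

    code: str
    message: str


def _read_table(path: str | Path, required: Sequence[str], delimiter: str = ",") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected a header row") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    return df


def read_library_table(path: str | Path, delimiter: str = ",") -> tuple[SiRNARecord, ...]:
    """Read an siRNA library table (columns: sirna_id, gene_symbol,
    gene_ncbi_id, role). Duplicate sirna_id raises IntegrityError."""
    df = _read_table(path, LIBRARY_COLUMNS, delimiter)
    records: list[SiRNARecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.sirna_id).strip()
        if sid in seen:
            raise IntegrityError(f"duplicate sirna_id {sid!r}")
        seen.add(sid)
        raw_id = getattr(row, "gene_ncbi_id")
        ncbi: int | None
        if raw_id is None or (isinstance(raw_id, float) and math.isnan(raw_id)) or str(raw_id).strip() in ("", "nan"):
            ncbi = None
        else:
            try:
                ncbi = int(float(raw_id))
            except ValueError:
                raise TableParseError(f"gene_ncbi_id {raw_id!r} is not an integer", row=i) from None
        role = str(row.role).strip() or ROLE_LIBRARY
        records.append(SiRNARecord(sid, str(row.gene_symbol).strip(), ncbi, role))
    n_genes = len({r.gene_key for r in records if r.role == ROLE_LIBRARY})
    logger.info("read %d siRNA records targeting %d distinct genes from %s",
                len(records), n_genes, path)
    return tuple(records)


def read_well_measurements(path: str | Path, delimiter: str = ",") -> tuple[WellMeasurement, ...]:
    """Read per-well luminescence pairs. Wells with firefly <= 0 or
    non-finite numbers come back with valid=False, never silently dropped."""
    df = _read_table(path, MEASUREMENT_COLUMNS, delimiter)
    wells: list[WellMeasurement] = []
    n_flagged = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            renilla = float(row.renilla)
            firefly = float(row.firefly)
            rep = int(float(row.replicate_index))
        except (TypeError, ValueError):
            raise TableParseError(
                f"unparseable numeric cell (renilla={row.renilla!r}, "
                f"firefly={row.firefly!r}, replicate_index={row.replicate_index!r})",
                row=i,
            ) from None
        valid = math.isfinite(renilla) and math.isfinite(firefly) and firefly > 0 and renilla >= 0
        if not valid:
            n_flagged += 1
        wells.append(WellMeasurement(
            plate_id=str(row.plate_id).strip(),
            well_id=str(row.well_id).strip(),
            sirna_id=str(row.sirna_id).strip(),
            renilla=renilla,
            firefly=firefly,
            replicate_index=rep,
            valid=valid,
        ))
    if n_flagged:
        logger.warning("%d of %d wells flagged invalid (firefly <= 0 or non-finite)",
                       n_flagged, len(wells))
    return tuple(wells)


def validate_screen(dataset: ScreenDataset) -> list[Violation]:
    """Check ScreenDataset invariants; violations are returned, not raised.

    Codes: DUPLICATE_WELL, ORPHAN_WELL, NO_NEGATIVE_CONTROL,
    NO_POSITIVE_CONTROL, EMPTY_LIBRARY, EMPTY_WELLS.
    """
    violations: list[Violation] = []
    if not dataset.library:
        violations.append(Violation("EMPTY_LIBRARY", "library holds no siRNA records"))
    if not dataset.wells:
        violations.append(Violation("EMPTY_WELLS", "dataset holds no well measurements"))
    index = dataset.library_index()
    seen_wells: set[tuple[str, str]] = set()
    for w in dataset.wells:
        key = (w.plate_id, w.well_id)
        if key in seen_wells:
            violations.append(Violation("DUPLICATE_WELL", f"well {key} appears twice"))
        seen_wells.add(key)
        if w.sirna_id not in index:
            violations.append(Violation(
                "ORPHAN_WELL", f"well {key} references unknown sirna_id {w.sirna_id!r}"))

    # controls may be declared per-plate or screen-wide; any valid control
    # well anywhere satisfies the screen-wide fallback
    for role, code in ((ROLE_NEGATIVE, "NO_NEGATIVE_CONTROL"),
                       (ROLE_POSITIVE, "NO_POSITIVE_CONTROL")):
        has = any(
            w.valid and w.sirna_id in index and index[w.sirna_id].role == role
            for w in dataset.wells
        )
        if dataset.wells and not has:
            violations.append(Violation(code, f"no valid {role} well in the screen"))
    return violations


def write_hit_table(calls: Sequence, path: str | Path, delimiter: str = ",") -> None:
    """Serialize gene-level calls (one row per gene). Raises on empty input."""
    if not calls:
        raise ValueError("refusing to write an empty hit table")
    rows = [
        {
            "gene": c.gene,
            "gene_ncbi_id": "" if c.gene_ncbi_id is None else int(c.gene_ncbi_id),
            "n_sirnas": c.n_sirnas,
            "n_hits": c.n_hits,
            "direction": c.direction,
            "status": c.status,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=HIT_TABLE_COLUMNS).to_csv(path, sep=delimiter, index=False)


def read_hit_table(path: str | Path, delimiter: str = ","):
    """Read a hit table back into GeneCall records (without per-siRNA detail)."""
    from .hit_calling import GeneCall  # deferred: avoids a module cycle

    df = _read_table(path, HIT_TABLE_COLUMNS, delimiter)
    calls = []
    for row in df.itertuples(index=False):
        raw = str(row.gene_ncbi_id).strip()
        ncbi = None if raw in ("", "nan") else int(float(raw))
        calls.append(GeneCall(
            gene=str(row.gene),
            gene_ncbi_id=ncbi,
            n_sirnas=int(row.n_sirnas),
            n_hits=int(row.n_hits),
            direction=str(row.direction),
            status=str(row.status),
        ))
    return calls
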