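"""Proteomics factor tables and the proteomics/screen overlap analysis.

The co-purification experiment yields a table of chromatin factors physically
associated with spliceosome complexes, each row carrying mass-spectrometry
evidence (unique peptides, % protein coverage, log(e) confidence — more
negative is more confident) and one of five fixed functional groups. This
module parses and filters such tables and intersects them with the RNAi
screen hit list by gene identity, optionally attaching a hypergeometric
enrichment tail as a plumbing statistic (the underlying comparison in the
source experiments is qualitative).

A transcription of the published factor table ships with the package and is
available through :func:`load_reference_factor_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import IntegrityError, SchemaError
from .screen_io import gene_key

#: the five functional groups, frozen verbatim
GROUPS = (
    "Chromatin Remodelling Factors",
    "Histone PTMs regulators",
    "Transcriptional regulators",
    "Nucleosome components",
    "Others",
)

PTM_TAGS = ("Ac", "Me", "Ph", "Ub")

FACTOR_COLUMNS = (
    "symbol", "alias", "ncbi_gene_id", "mr_kd",
    "unique_peptides", "percent_coverage", "log_e", "group",
)


@dataclass(frozen=True)
class FactorRecord:
    """One co-purified factor with its mass-spectrometry evidence."""

    symbol: str
    alias: str
    ncbi_gene_id: int
    mr_kd: float
    unique_peptides: int
    percent_coverage: float
    log_e: float
    group: str
    ptm_tag: Optional[str] = None

    def __post_init__(self) -> None:
        if self.unique_peptides < 1:
            raise ValueError(f"{self.symbol}: a reported factor needs >= 1 unique peptide")
        if self.log_e > 0:
            raise ValueError(f"{self.symbol}: log(e) must be <= 0, got {self.log_e}")
        if not 0 <= self.percent_coverage <= 100:
            raise ValueError(f"{self.symbol}: % coverage outside [0, 100]")
        if self.group not in GROUPS:
            raise ValueError(f"{self.symbol}: unknown group {self.group!r}")
        if self.ptm_tag is not None and self.ptm_tag not in PTM_TAGS:
            raise ValueError(f"{self.symbol}: unknown PTM tag {self.ptm_tag!r}")

    @property
    def gene_key(self) -> str:
        return gene_key(self.symbol, self.ncbi_gene_id)


def read_factor_table(path: str | Path, delimiter: str = ",") -> tuple[FactorRecord, ...]:
    """Read a factor evidence table; the group vocabulary and the evidence
    invariants are enforced row by row."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        group = str(row.group).strip()
        if group not in GROUPS:
            raise SchemaError(f"{path} row {i}: unknown group label {group!r}")
        raw_tag = getattr(row, "ptm_tag", None)
        tag = None if raw_tag is None or str(raw_tag).strip() in ("", "nan") else str(raw_tag).strip()
        try:
            records.append(FactorRecord(
                symbol=str(row.symbol).strip(),
                alias=str(row.alias).strip(),
                ncbi_gene_id=int(float(row.ncbi_gene_id)),
                mr_kd=float(row.mr_kd),
                unique_peptides=int(float(row.unique_peptides)),
                percent_coverage=float(row.percent_coverage),
                log_e=float(row.log_e),
                group=group,
                ptm_tag=tag,
            ))
        except ValueError as exc:
            raise ValueError(f"{path} row {i}: {exc}") from None
    return tuple(records)


def load_reference_factor_table() -> tuple[FactorRecord, ...]:
    """The packaged transcription of the published co-purification table."""
    ref = resources.files("splicescreen.data").joinpath("table1_factors.csv")
    with resources.as_file(ref) as path:
        return read_factor_table(path)


def filter_factors(
    records: Iterable[FactorRecord],
    min_unique_peptides: int = 1,
    max_log_e: float = 0.0,
) -> tuple[FactorRecord, ...]:
    """Evidence filter: keep records with >= min unique peptides and
    log(e) <= max; input order is preserved."""
    return tuple(
        r for r in records
        if r.unique_peptides >= min_unique_peptides and r.log_e <= max_log_e
    )


def group_summary(records: Iterable[FactorRecord]) -> dict[str, int]:
    """Record count per functional group; counts partition the input."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.group] = counts.get(r.group, 0) + 1
    return counts


@dataclass(frozen=True)
class OverlapReport:
    """Intersection of the proteomics factor list with the screen hit list."""

    set_a_size: int
    set_b_size: int
    intersection_size: int
    intersection_members: tuple[str, ...]
    universe_size: Optional[int] = None
    enrichment_p: Optional[float] = None


def hypergeometric_tail(k: int, universe: int, size_a: int, size_b: int) -> float:
    """P(X >= k) for the overlap of two sets drawn from a common universe."""
    return float(stats.hypergeom.sf(k - 1, universe, size_a, size_b))


def intersect_with_hits(
    factors: Sequence[FactorRecord],
    hits: Sequence,
    universe: Optional[Iterable[str]] = None,
) -> OverlapReport:
    """Intersect factor and hit gene sets by identity key.

    ``hits`` are gene-level calls (only genes whose status is a hit count).
    When ``universe`` (an iterable of gene keys) is given, a hypergeometric
    upper-tail enrichment probability is attached; every hit gene must then
    belong to the universe.
    """
    set_a = {f.gene_key for f in factors}
    set_b = {gene_key(c.gene, c.gene_ncbi_id) for c in hits if c.is_hit}
    if universe is not None:
        uni = set(universe)
        outside = set_b - uni
        if outside:
            raise IntegrityError(
                f"hit gene(s) outside the declared universe: {sorted(outside)}")
        set_a = set_a & uni  # factors outside the screened universe cannot overlap
    members = tuple(sorted(set_a & set_b))
    enrichment = None
    universe_size = None
    if universe is not None:
        universe_size = len(uni)
        enrichment = hypergeometric_tail(len(members), universe_size, len(set_a), len(set_b))
    return OverlapReport(
        set_a_size=len(set_a),
        set_b_size=len(set_b),
        intersection_size=len(members),
        intersection_members=members,
        universe_size=universe_size,
        enrichment_p=enrichment,
    )
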