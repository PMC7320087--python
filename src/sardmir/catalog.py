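"""The packaged sardine miRNA catalog and its summary statistics.

The package ships a 101-row tab-separated transcription of the published
*Sardina pilchardus* miRNA catalog (one row per conserved miRNA: mature
sequence, hairpin arm, precursor length LP, precursor GC%, minimum folding
free energy MFE, and the stability index MFEI).  This module loads it,
validates every row, computes the catalog-level summary statistics, and
recomputes the MFEI column from the printed MFE / LP / GC values to check
internal consistency.

MFEI is reported with two-decimal *truncation* (floor), not rounding: the
published column is only reproducible under truncation (e.g. 33.40/59x100/
42.37 = 1.3361 prints as 1.33, where rounding would give 1.34).
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import CatalogIntegrityError, CatalogParseError, DomainError
from .hairpin import compute_mfei, truncate2
from .sequence import normalize_to_rna

_FIXTURE = "table1_catalog.tsv"
_COLUMNS = [
    "name",
    "length_mature",
    "query",
    "mature_seq",
    "arm",
    "length_precursor",
    "gc_percent",
    "mfe",
    "mfei",
]

#: Expected number of records in the packaged catalog.
CATALOG_SIZE = 101


class Arm(str, enum.Enum):
    """Which arm of the precursor hairpin carries the mature miRNA."""

    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


@dataclass(frozen=True)
class MiRNARecord:
    """One catalog row.

    Attributes
    ----------
    name, query_name
        Identifier of the predicted miRNA and of the reference (zebrafish
        ``dre-`` or cod ``gmo-``) mature it was mapped from.
    length_mature, length_precursor
        Lengths in nt (LM and LP).
    mature_seq
        Mature sequence, RNA alphabet.
    arm
        5' or 3' arm of the precursor stem-loop.
    gc_percent
        G+C percentage of the precursor.
    mfe
        Minimum folding free energy of the precursor, kcal/mol (negative).
    mfei
        Published minimum folding free energy index (dimensionless).
    """

    name: str
    length_mature: int
    query_name: str
    mature_seq: str
    arm: Arm
    length_precursor: int
    gc_percent: float
    mfe: float
    mfei: float

    def __post_init__(self) -> None:
        if self.length_mature != len(self.mature_seq):
            raise CatalogParseError(
                f"{self.name}: length_mature={self.length_mature} but "
                f"mature_seq has {len(self.mature_seq)} nt"
            )
        if set(self.mature_seq) - set("ACGU"):
            raise CatalogParseError(f"{self.name}: mature_seq is not pure RNA")
        if self.length_precursor < self.length_mature:
            raise CatalogParseError(
                f"{self.name}: precursor shorter than mature sequence"
            )
        if not self.mfe < 0:
            raise CatalogParseError(f"{self.name}: MFE must be negative")
        if not self.mfei > 0:
            raise CatalogParseError(f"{self.name}: MFEI must be positive")
        if not 0 < self.gc_percent < 100:
            raise CatalogParseError(f"{self.name}: GC% out of (0, 100)")


@dataclass(frozen=True)
class CatalogSummary:
    """Catalog-level descriptive statistics (published rounding conventions).

    Percentages are over the total record count; ``precursor_mean`` is
    rounded to the nearest integer, arm percentages to 1 decimal,
    ``pct_u_start`` to the nearest integer, and the GC/MFE/MFEI aggregates
    to 2 decimals.
    """

    n_records: int
    modal_mature_length: int
    precursor_min: int
    precursor_max: int
    precursor_mean: int
    pct_three_prime: float
    pct_five_prime: float
    pct_u_start: int
    gc_mean: float
    mfe_min: float
    mfe_max: float
    mfe_mean: float
    mfei_min: float
    mfei_max: float
    mfei_mean: float


def _fixture_path() -> Path:
    return Path(str(resources.files("sardmir").joinpath("data", _FIXTURE)))


def load_catalog(
    path: str | Path | None = None,
    *,
    expected_count: int | None = None,
) -> list[MiRNARecord]:
    """Load a catalog TSV into validated records.

    With no ``path`` the packaged 101-row catalog is loaded and the record
    count is enforced.  For user files ``expected_count`` is optional.
    Malformed rows raise :class:`CatalogParseError` naming the row; a wrong
    record count raises :class:`CatalogIntegrityError`.
    """
    if path is None:
        path = _fixture_path()
        if expected_count is None:
            expected_count = CATALOG_SIZE
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != _COLUMNS:
        raise CatalogParseError(
            f"{path}: header must be {chr(9).join(_COLUMNS)!r}"
        )
    records: list[MiRNARecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise CatalogParseError(
                f"{path} line {lineno}: expected {len(_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        try:
            records.append(
                MiRNARecord(
                    name=parts[0],
                    length_mature=int(parts[1]),
                    query_name=parts[2],
                    mature_seq=normalize_to_rna(parts[3]),
                    arm=Arm(parts[4]),
                    length_precursor=int(parts[5]),
                    gc_percent=float(parts[6]),
                    mfe=float(parts[7]),
                    mfei=float(parts[8]),
                )
            )
        except (ValueError, CatalogParseError) as exc:
            raise CatalogParseError(
                f"{path} line {lineno} ({parts[0]!r}): {exc}"
            ) from exc
    if expected_count is not None and len(records) != expected_count:
        raise CatalogIntegrityError(
            f"{path}: expected {expected_count} records, found {len(records)}"
        )
    return records


def summarize_catalog(records: Sequence[MiRNARecord]) -> CatalogSummary:
    """Descriptive statistics over a set of catalog records.

    Order-invariant; raises :class:`DomainError` on an empty list.
    """
    if not records:
        raise DomainError("cannot summarize an empty catalog")
    n = len(records)
    lengths = Counter(r.length_mature for r in records)
    # deterministic mode: most common, ties broken by smaller length
    modal = min(
        (length for length, c in lengths.items() if c == max(lengths.values()))
    )
    lps = [r.length_precursor for r in records]
    n3 = sum(r.arm is Arm.THREE_PRIME for r in records)
    gcs = [r.gc_percent for r in records]
    mfes = [r.mfe for r in records]
    mfeis = [r.mfei for r in records]
    return CatalogSummary(
        n_records=n,
        modal_mature_length=modal,
        precursor_min=min(lps),
        precursor_max=max(lps),
        precursor_mean=round(sum(lps) / n),
        pct_three_prime=round(100.0 * n3 / n, 1),
        pct_five_prime=round(100.0 * (n - n3) / n, 1),
        pct_u_start=round(
            100.0 * sum(r.mature_seq.startswith("U") for r in records) / n
        ),
        gc_mean=round(sum(gcs) / n, 2),
        mfe_min=round(min(mfes), 2),
        mfe_max=round(max(mfes), 2),
        mfe_mean=round(sum(mfes) / n, 2),
        mfei_min=round(min(mfeis), 2),
        mfei_max=round(max(mfeis), 2),
        mfei_mean=round(sum(mfeis) / n, 2),
    )


@dataclass(frozen=True)
class MfeiRecomputation:
    name: str
    printed: float
    recomputed: float

    @property
    def agrees(self) -> bool:
        return abs(self.printed - self.recomputed) < 1e-9


def recompute_mfei_column(
    records: Iterable[MiRNARecord],
) -> tuple[list[MfeiRecomputation], int]:
    """Recompute MFEI = (|MFE| / LP x 100) / GC% for every record.

    The recomputed value is truncated to two decimals (the published
    convention); returns the per-row comparison and the number of rows whose
    recomputation equals the printed column exactly.
    """
    rows = [
        MfeiRecomputation(
            name=r.name,
            printed=truncate2(r.mfei),
            recomputed=compute_mfei(
                r.mfe, r.length_precursor, r.gc_percent, report=True
            ),
        )
        for r in records
    ]
    return rows, sum(row.agrees for row in rows)


def summary_to_tsv(summary: CatalogSummary) -> str:
    """Two-column TSV rendering of a summary (field, value)."""
    out = ["field\tvalue"]
    for f in fields(summary):
        out.append(f"{f.name}\t{getattr(summary, f.name)}")
    return "\n".join(out) + "\n"


def summary_report(summary: CatalogSummary) -> str:
    """Human-readable, publication-style summary paragraph."""
    s = summary
    return (
        f"{s.n_records} miRNAs; modal mature length {s.modal_mature_length} nt.\n"
        f"Precursors {s.precursor_min}-{s.precursor_max} nt "
        f"(mean {s.precursor_mean} nt); GC mean {s.gc_mean:.2f}%.\n"
        f"Arm location: {s.pct_three_prime}% 3', {s.pct_five_prime}% 5'; "
        f"{s.pct_u_start}% begin with U.\n"
        f"MFE {s.mfe_min:.2f} to {s.mfe_max:.2f} kcal/mol "
        f"(mean {s.mfe_mean:.2f}).\n"
        f"MFEI {s.mfei_min:.2f} to {s.mfei_max:.2f} (mean {s.mfei_mean:.2f}).\n"
    )
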