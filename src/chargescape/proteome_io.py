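"""Protein sequence and annotation I/O.

Reads FASTA proteomes (tolerating the UniProt ``db|ACC|NAME ... OS=...``
header dialect), attaches sidecar annotation tables keyed by accession
(signal-peptide flags, GO subcellular locations, ORF lengths,
monosome:polysome scores/labels, chaperone-client maps) and builds
filtered subsets for the grouped analyses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|(?P<acc>[^|]+)\|(?P<name>\S+)")
_OS_FIELD = re.compile(r"\bOS=(.+?)(?=\s+[A-Z]{2}=|$)")

#: GO IDs for the membrane-organelle composite group (mitochondrion, ER,
#: Golgi apparatus, vacuole).
MEMBRANE_ORGANELLE_GO = frozenset(
    {"GO:0005739", "GO:0005783", "GO:0005794", "GO:0005773"}
)
GO_MITOCHONDRION = "GO:0005739"
GO_CYTOSOL = "GO:0005829"

#: Chaperone-client groups at or below this size are dropped.
MIN_CHAPERONE_CLIENTS = 31


@dataclass
class ProteinRecord:
    """One protein with optional annotations.

    ``None`` marks an unknown annotation, distinct from an explicit
    negative (e.g. ``has_signal_peptide=False``).
    """

    id: str
    sequence: str
    organism: str = ""
    has_signal_peptide: bool | None = None
    go_locations: set[str] = field(default_factory=set)
    orf_length_nt: int | None = None
    mp_score: float | None = None
    mp_label: str | None = None
    is_mitochondrial: bool | None = None
    chaperones: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence.isalpha():
            raise ValueError(f"sequence of {self.id!r} contains non-letter symbols")
        self.sequence = self.sequence.upper()

    def __len__(self) -> int:
        return len(self.sequence)


def parse_header(header: str) -> tuple[str, str]:
    """Extract (id, organism) from a FASTA header line (``>`` stripped)."""
    match = _UNIPROT_HEADER.match(header)
    acc = match.group("acc") if match else header.split()[0]
    os_match = _OS_FIELD.search(header)
    organism = os_match.group(1).strip() if os_match else ""
    return acc, organism


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords, order preserved.

    Duplicate ids and sequence lines before the first header are errors;
    an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">") and first.strip():
            raise ValueError(f"{path}: sequence data before first FASTA header")
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            acc, organism = parse_header(header)
            if acc in seen:
                raise ValueError(f"{path}: duplicate record id {acc!r}")
            seen.add(acc)
            records.append(ProteinRecord(id=acc, sequence=seq, organism=organism))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    else:
        logger.info("%s: read %d protein records", path, len(records))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def _read_table(table_path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(table_path, sep="\t", dtype={"accession": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{table_path}: missing required column(s) {missing}")
    return df


def attach_annotations(
    records: Sequence[ProteinRecord],
    table_path: str | Path,
    kind: str,
) -> Sequence[ProteinRecord]:
    """Attach a sidecar TSV of annotations to matching records, in place.

    ``kind`` selects the schema (all keyed by an ``accession`` column):

    - ``signal``: ``has_signal_peptide`` (0/1/true/false)
    - ``go``: ``go_id`` (one row per accession, GO pair); mitochondrion
      GO id also sets ``is_mitochondrial``
    - ``orf_length``: ``orf_length_nt``
    - ``mp``: ``mp_score`` and/or ``mp_label``
    - ``chaperone``: ``chaperone`` (chaperone id per client accession);
      chaperones with fewer than 31 clients in the table are dropped

    Unmatched table rows are counted and logged, never an error.
    """
    by_id = {rec.id: rec for rec in records}
    unmatched = 0
    updated = 0

    if kind == "signal":
        df = _read_table(table_path, ["accession", "has_signal_peptide"])
        for row in df.itertuples(index=False):
            rec = by_id.get(row.accession)
            if rec is None:
                unmatched += 1
                continue
            rec.has_signal_peptide = str(row.has_signal_peptide).lower() in ("1", "true", "yes")
            updated += 1
    elif kind == "go":
        df = _read_table(table_path, ["accession", "go_id"])
        for row in df.itertuples(index=False):
            rec = by_id.get(row.accession)
            if rec is None:
                unmatched += 1
                continue
            rec.go_locations.add(row.go_id)
            if row.go_id == GO_MITOCHONDRION:
                rec.is_mitochondrial = True
            updated += 1
    elif kind == "orf_length":
        df = _read_table(table_path, ["accession", "orf_length_nt"])
        for row in df.itertuples(index=False):
            rec = by_id.get(row.accession)
            if rec is None:
                unmatched += 1
                continue
            length = int(row.orf_length_nt)
            rec.orf_length_nt = length
            # annotations may disagree with the sequence; log, don't enforce
            if length < 3 * len(rec.sequence):
                logger.warning(
                    "%s: ORF length %d nt shorter than 3x protein length %d",
                    rec.id, length, len(rec.sequence),
                )
            updated += 1
    elif kind == "mp":
        df = _read_table(table_path, ["accession"])
        if "mp_score" not in df.columns and "mp_label" not in df.columns:
            raise ValueError(f"{table_path}: needs an mp_score or mp_label column")
        for row in df.itertuples(index=False):
            rec = by_id.get(row.accession)
            if rec is None:
                unmatched += 1
                continue
            if hasattr(row, "mp_score") and pd.notna(row.mp_score):
                rec.mp_score = float(row.mp_score)
            if hasattr(row, "mp_label") and pd.notna(row.mp_label):
                rec.mp_label = str(row.mp_label)
            updated += 1
    elif kind == "chaperone":
        df = _read_table(table_path, ["accession", "chaperone"])
        sizes = df.groupby("chaperone")["accession"].nunique()
        kept = set(sizes[sizes >= MIN_CHAPERONE_CLIENTS].index)
        dropped = set(sizes.index) - kept
        if dropped:
            logger.info("dropping %d chaperone group(s) with <=30 clients", len(dropped))
        for row in df.itertuples(index=False):
            if row.chaperone not in kept:
                continue
            rec = by_id.get(row.accession)
            if rec is None:
                unmatched += 1
                continue
            rec.chaperones.add(row.chaperone)
            updated += 1
    else:
        raise ValueError(f"unknown annotation kind: {kind!r}")

    if unmatched:
        logger.warning("%s: %d table row(s) matched no record", table_path, unmatched)
    if updated == 0:
        logger.warning("%s: no records updated", table_path)
    return records


FilterFn = Callable[[ProteinRecord], bool]

_KNOWN_FIELDS = {
    "has_signal_peptide",
    "go_locations",
    "orf_length_nt",
    "mp_score",
    "mp_label",
    "is_mitochondrial",
    "organism",
    "min_length",
    "go_contains",
}


def select(
    records: Sequence[ProteinRecord],
    filter: FilterFn | dict[str, object],
) -> list[ProteinRecord]:
    """Filter records by a predicate or a {field: value} expression.

    Dict filters support record fields plus the pseudo-fields
    ``min_length`` (length >= value) and ``go_contains`` (GO id
    membership).  Unknown fields raise.
    """
    if callable(filter):
        pred = filter
    else:
        for key in filter:
            if key not in _KNOWN_FIELDS:
                raise ValueError(f"unknown filter field: {key!r}")
        criteria = dict(filter)

        def pred(rec: ProteinRecord) -> bool:
            for key, value in criteria.items():
                if key == "min_length":
                    if len(rec) < int(value):  # type: ignore[arg-type]
                        return False
                elif key == "go_contains":
                    if value not in rec.go_locations:
                        return False
                elif getattr(rec, key) != value:
                    return False
            return True

    kept = [rec for rec in records if pred(rec)]
    logger.info("select: kept %d of %d records", len(kept), len(records))
    return kept


def membrane_organelle_set(
    records: Sequence[ProteinRecord], exclude_mitochondrial: bool = False
) -> list[ProteinRecord]:
    """Union of mitochondrion/ER/Golgi/vacuole-annotated proteins.

    ``exclude_mitochondrial`` reproduces the variant with mitochondrial
    proteins removed from the membrane set.
    """
    go = MEMBRANE_ORGANELLE_GO - ({GO_MITOCHONDRION} if exclude_mitochondrial else set())
    return [rec for rec in records if rec.go_locations & go]
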