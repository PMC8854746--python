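"""Readers and writers for the external formats the pipeline touches.

Every reader validates strictly and every reader/writer pair round-trips:
``read(write(x)) == x`` up to the stated float precision. Malformed records
are never silently dropped — parse errors name the offending line, and
legitimate drops (duplicate edges, BLAST self-hits) are logged with counts.

Formats: two-column TSV edge lists, 12-column BLAST tabular (outfmt 6),
FASTA, TSV localization tables, and a TSV embedding table with a ``dim=``
header line.
"""

from __future__ import annotations

import logging
import math
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("hetlink")


class ParseError(ValueError):
    """A file violated its declared format; message names the line."""


class ValidationError(ValueError):
    """Parsed content violated a semantic invariant."""


# IUPAC nucleotide codes plus the extended amino-acid alphabet (which
# together cover A-Z), gap and stop characters.
_SEQ_ALPHABET = frozenset(string.ascii_uppercase) | {"*", "-"}


@dataclass(frozen=True)
class EdgeRecord:
    """One known lncRNA-protein interaction."""

    source_id: str  # lncRNA identifier
    target_id: str  # protein identifier

    def __post_init__(self) -> None:
        for name, value in (("source_id", self.source_id), ("target_id", self.target_id)):
            if not value:
                raise ValidationError(f"{name} is empty")
            if any(c.isspace() for c in value):
                raise ValidationError(f"{name} {value!r} contains whitespace")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source_id, self.target_id)


@dataclass(frozen=True)
class AlignmentHit:
    """Best local-alignment hit for one ordered (query, subject) pair."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError(f"negative e-value for ({self.query_id}, {self.subject_id})")
        if self.bitscore < 0:
            raise ValidationError(f"negative bitscore for ({self.query_id}, {self.subject_id})")
        if self.query_id == self.subject_id:
            raise ValidationError(f"self-hit retained for {self.query_id}")


def read_edge_list(path: str | Path) -> list[EdgeRecord]:
    """Read a two-column TSV of (lncRNA id, protein id) interaction pairs.

    Lines starting with ``#`` are skipped. Duplicate pairs are collapsed,
    preserving first-seen order. A line with fewer than two tab-separated
    fields raises :class:`ParseError` naming the line number.
    """
    path = Path(path)
    records: list[EdgeRecord] = []
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected >=2 tab-separated fields, got {line!r}")
            try:
                rec = EdgeRecord(fields[0], fields[1])
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if rec.pair in seen:
                n_dupes += 1
                continue
            seen.add(rec.pair)
            records.append(rec)
    if n_dupes:
        logger.info("read_edge_list(%s): collapsed %d duplicate pairs", path, n_dupes)
    if not records:
        logger.warning("read_edge_list(%s): empty edge list", path)
    return records


def write_edge_list(records: Iterable[EdgeRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f"{rec.source_id}\t{rec.target_id}\n")


def read_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``).

    Columns used: qseqid, sseqid, evalue, bitscore. Self-hits are discarded
    (counted in the log); multiple HSPs for the same ordered pair collapse to
    the minimum e-value and its bitscore.
    """
    path = Path(path)
    best: dict[tuple[str, str], tuple[float, float]] = {}
    order: list[tuple[str, str]] = []
    n_self = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}")
            qseqid, sseqid = fields[0], fields[1]
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric e-value/bitscore") from exc
            if not math.isfinite(evalue) or evalue < 0:
                raise ParseError(f"{path}:{lineno}: invalid e-value {fields[10]!r}")
            if qseqid == sseqid:
                n_self += 1
                continue
            key = (qseqid, sseqid)
            if key not in best:
                best[key] = (evalue, bitscore)
                order.append(key)
            elif evalue < best[key][0]:
                best[key] = (evalue, bitscore)
    if n_self:
        logger.info("read_blast_tabular(%s): dropped %d self-hits", path, n_self)
    return [AlignmentHit(q, s, *best[(q, s)]) for q, s in order]


def write_blast_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back in the 12-column dialect (unused columns zero-filled)."""
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0\t0\t0\t0\t0\t0\t0\t0\t{h.evalue:.6g}\t{h.bitscore:.6g}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercased sequence map.

    Record id is the header token up to the first whitespace. Duplicate ids
    and characters outside the IUPAC nucleotide/amino-acid alphabets raise
    :class:`ValidationError`.
    """
    path = Path(path)
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValidationError(f"{path}: duplicate FASTA id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise ValidationError(
                f"{path}: record {record.id!r} has invalid characters {sorted(bad)!r}"
            )
        out[record.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    del width  # Biopython wraps at 60 columns; kept for signature stability


def read_localization(path: str | Path) -> dict[str, set[str]]:
    """Read a TSV of (molecule id, compartment label) rows into id -> label set.

    Repeated rows for one molecule accumulate labels.
    """
    path = Path(path)
    table: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ParseError(f"{path}:{lineno}: expected (id, compartment), got {line!r}")
            table.setdefault(fields[0], set()).add(fields[1])
    for mol, comps in table.items():
        if not comps:
            raise ValidationError(f"molecule {mol!r} has no compartment")
    return table


def write_localization(table: Mapping[str, set[str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for mol in table:
            for comp in sorted(table[mol]):
                fh.write(f"{mol}\t{comp}\n")


def write_embeddings(table: Mapping[str, "list[float]"], path: str | Path) -> None:
    """Write node embeddings as TSV: a ``dim=<d>`` header, then id + values.

    Values are printed with 6 significant digits. Ragged vectors raise
    :class:`ValidationError`.
    """
    dims = {len(vec) for vec in table.values()}
    if len(dims) > 1:
        raise ValidationError(f"ragged embedding table: dimensions {sorted(dims)}")
    dim = dims.pop() if dims else 0
    with Path(path).open("w") as fh:
        fh.write(f"dim={dim}\n")
        for node, vec in table.items():
            values = "\t".join(f"{float(v):.6g}" for v in vec)
            fh.write(f"{node}\t{values}\n" if dim else f"{node}\n")


def read_embeddings(path: str | Path) -> dict[str, list[float]]:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("dim="):
            raise ParseError(f"{path}:1: expected 'dim=<d>' header, got {header!r}")
        try:
            dim = int(header[4:])
        except ValueError as exc:
            raise ParseError(f"{path}:1: non-integer dimension in {header!r}") from exc
        out: dict[str, list[float]] = {}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != dim + 1:
                raise ParseError(f"{path}:{lineno}: expected {dim + 1} fields, got {len(fields)}")
            try:
                out[fields[0]] = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric embedding value") from exc
    return out


def check_disjoint_namespaces(lnc_ids: Iterable[str], prot_ids: Iterable[str]) -> None:
    """Typed graphs need unambiguous node typing: the two id sets must not overlap."""
    overlap = set(lnc_ids) & set(prot_ids)
    if overlap:
        raise ValidationError(
            f"lncRNA and protein identifier namespaces overlap: {sorted(overlap)[:5]!r}..."
        )
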