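"""Readers and writers for the plain-text formats the pipeline consumes and emits.

FASTA records are normalized on input: RNA ``U`` becomes DNA ``T`` and
lowercase becomes uppercase, so every downstream comparison is an exact string
comparison over ``{A, C, G, T, N}``.  All genomic intervals inside the package
are 0-based half-open; the single conversion to GFF3's 1-based inclusive
convention happens in :func:`write_gff3`.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "MirnaId",
    "CountTable",
    "GffFeature",
    "FormatError",
    "normalize_sequence",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "parse_mirna_id",
    "read_gff3",
    "write_gff3",
    "read_count_table",
]

_VALID_INPUT = re.compile(r"^[ACGTUNacgtun]*$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, normalized to uppercase DNA."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class MirnaId:
    """A miRBase-style identifier split into species prefix, name and arm.

    ``hsa-let-7a-3p`` parses to prefix ``hsa``, name ``let-7a-3p``, arm ``3p``.
    The arm is ``unknown`` when the id carries no ``-5p``/``-3p`` suffix.
    """

    species_prefix: str
    name: str

    @property
    def arm(self) -> str:
        if self.name.endswith("-5p"):
            return "5p"
        if self.name.endswith("-3p"):
            return "3p"
        return "unknown"

    @property
    def full(self) -> str:
        return f"{self.species_prefix}-{self.name}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.full


@dataclass
class CountTable:
    """Collapsed small-RNA-seq reads from one experiment: sequence -> count."""

    experiment_id: str
    rows: dict[str, int] = field(default_factory=dict)

    def get(self, sequence: str) -> int:
        return self.rows.get(sequence, 0)


@dataclass(frozen=True)
class GffFeature:
    """A located feature with 0-based half-open coordinates."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    attributes: Mapping[str, str] = field(default_factory=dict)
    source: str = "mirhunt"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) on {self.seqid}"
            )


def normalize_sequence(raw: str, *, where: str = "sequence") -> str:
    """Uppercase *raw* and map U to T; reject anything outside the RNA/DNA alphabet."""
    if not _VALID_INPUT.match(raw):
        bad = sorted(set(raw) - set("ACGTUNacgtun"))
        raise FormatError(f"{where}: invalid characters {bad}")
    return raw.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized records, preserving order.

    Multi-line sequences are concatenated; ``U``→``T``, lowercase→uppercase.
    An empty file or a record with characters outside ``{A,C,G,T,U,N}`` (any
    case) is a :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        seq = normalize_sequence(str(rec.seq), where=f"record {rec.id!r} in {path.name}")
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def parse_mirna_id(identifier: str) -> MirnaId:
    """Split a miRBase-style id into (species prefix, name)."""
    if "-" not in identifier:
        raise FormatError(f"miRNA id {identifier!r} has no '-' separator")
    prefix, name = identifier.split("-", 1)
    if not prefix or not name:
        raise FormatError(f"miRNA id {identifier!r} has an empty prefix or name")
    return MirnaId(species_prefix=prefix, name=name)


def _escape_attr(value: str) -> str:
    return urllib.parse.quote(value, safe=" !\"'()*+./:<>@^`{|}~[]?-_")


def write_gff3(features: Iterable[GffFeature], path: str | Path) -> None:
    """Write features as GFF3, converting to 1-based inclusive coordinates.

    Output order is deterministic: (seqid, start, type, attribute string).
    """
    rows = []
    for f in features:
        attrs = ";".join(f"{k}={_escape_attr(str(v))}" for k, v in f.attributes.items())
        rows.append((f.seqid, f.start, f.type, attrs, f))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, start, ftype, attrs, f in rows:
            fh.write(
                "\t".join(
                    [
                        seqid,
                        f.source,
                        ftype,
                        str(start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs or ".",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GffFeature]:
    """Read a GFF3 file back into 0-based half-open features.

    Only the columns the pipeline needs are interpreted; comment and directive
    lines are skipped.
    """
    features: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            attrs: dict[str, str] = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if not item:
                        continue
                    key, _, value = item.partition("=")
                    attrs[key] = urllib.parse.unquote(value)
            features.append(
                GffFeature(
                    seqid=cols[0],
                    source=cols[1],
                    type=cols[2],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )
    return features


def read_count_table(path: str | Path, experiment_id: str, *, header: bool = False) -> CountTable:
    """Read a two-column (sequence, count) TSV of collapsed reads.

    Duplicate sequences (including duplicates created by U/T normalization)
    have their counts summed.  Zero-count rows are retained.
    """
    path = Path(path)
    rows: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            seq = normalize_sequence(parts[0], where=f"{path.name}:{lineno}")
            try:
                count = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: count {parts[1]!r} is not an integer")
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            rows[seq] = rows.get(seq, 0) + count
    return CountTable(experiment_id=experiment_id, rows=rows)
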