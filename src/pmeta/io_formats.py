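"""Readers and writers for the pipeline's external file formats.

Everything downstream works on the domain types defined here:
:class:`SequenceRecord` for reads, fragments and reference sequences,
:class:`TaxonomyMap` for the reference annotation, and
:class:`TabularHit` for 12-column similarity-search results.

Conventions
-----------
* All internal coordinates are 0-based half-open.  The 12-column tabular
  format uses the 1-based inclusive convention of its ecosystem
  (minus-strand hits carry subject start > subject end); conversion
  happens only at (de)serialization.
* Gzip-compressed files are accepted transparently by ``.gz`` extension.
* FASTQ qualities are Sanger/Phred+33.
* Residues are uppercased on input and ``U`` is mapped to ``T``; IUPAC
  ambiguity codes are preserved (they score as mismatches in alignment
  and emit at background probability in the HMM).
* Record order is never changed by reading or writing: the deterministic
  chunk/merge contract of the parallel stages depends on file order.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Sequence

IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")
CANONICAL_DNA = frozenset("ACGT")

__all__ = [
    "ParseError",
    "SequenceRecord",
    "TaxonomyMap",
    "TabularHit",
    "read_sequences",
    "write_sequences",
    "read_taxonomy",
    "write_taxonomy",
    "read_tabular_hits",
    "write_tabular_hits",
]


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""

    def __init__(self, message: str, path=None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc = f"{path}:"
            if line is not None:
                loc += f"{line}:"
            loc += " "
        super().__init__(loc + message)
        self.path = None if path is None else str(path)
        self.line = line


@dataclass
class SequenceRecord:
    """One DNA sequence: a read, an extracted fragment or a reference.

    ``qualities`` (Phred scores, one per residue) are present only for
    records read from FASTQ.
    """

    id: str
    residues: str
    description: str = ""
    qualities: Optional[tuple] = None

    def __post_init__(self):
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a non-empty token: {self.id!r}")
        if not self.residues:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-IUPAC residues: {sorted(bad)}"
            )
        if self.qualities is not None:
            self.qualities = tuple(self.qualities)
            if len(self.qualities) != len(self.residues):
                raise ValueError(
                    f"record {self.id!r}: {len(self.qualities)} quality values "
                    f"for {len(self.residues)} residues"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TaxonomyMap:
    """Reference sequence id -> raw semicolon-delimited lineage string."""

    entries: dict

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.entries

    def get(self, ref_id: str, default=None):
        return self.entries.get(ref_id, default)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class TabularHit:
    """One query-to-reference local alignment, 12-column tabular semantics.

    Coordinates are stored 0-based half-open on the forward strand of
    both sequences; ``strand`` records orientation.  Serialization emits
    the conventional 1-based inclusive columns, with subject start >
    subject end on the minus strand.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"
    raw_score: Optional[int] = field(default=None, compare=False)

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"percent identity out of range: {self.pident}")
        if self.qstart > self.qend or self.qstart < 0:
            raise ValueError(f"bad query interval [{self.qstart}, {self.qend})")
        if self.sstart > self.send or self.sstart < 0:
            raise ValueError(f"bad subject interval [{self.sstart}, {self.send})")
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"non-finite bit score: {self.bitscore}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")


# ---------------------------------------------------------------------------
# sequence files


def _open_text(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


def _detect_format(path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            first = line.lstrip()[0]
            if first == ">":
                return "fasta"
            if first == "@":
                return "fastq"
            raise ParseError(
                f"cannot detect sequence format from leading character {first!r}",
                path=path,
                line=1,
            )
    return "fasta"  # empty file: format is moot


def _check_residues(residues: str, rec_id: str, path, line: int) -> None:
    bad = set(residues) - IUPAC_DNA
    if bad:
        raise ParseError(
            f"record {rec_id!r} contains non-IUPAC residues {sorted(bad)}",
            path=path,
            line=line,
        )


def _iter_fasta(fh: IO[str], path) -> Iterator[SequenceRecord]:
    header: Optional[str] = None
    header_line = 0
    parts: list = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            if header is not None:
                yield _fasta_record(header, parts, path, header_line)
            header = line[1:].strip()
            header_line = lineno
            parts = []
        else:
            if header is None:
                raise ParseError("sequence data before first '>' header", path, lineno)
            parts.append(line.strip())
    if header is not None:
        yield _fasta_record(header, parts, path, header_line)


def _fasta_record(header: str, parts: list, path, lineno: int) -> SequenceRecord:
    if not header:
        raise ParseError("empty FASTA header", path, lineno)
    fields = header.split(None, 1)
    residues = _normalize("".join(parts))
    if not residues:
        raise ParseError(f"header {fields[0]!r} has no sequence", path, lineno)
    _check_residues(residues, fields[0], path, lineno)
    return SequenceRecord(
        id=fields[0],
        residues=residues,
        description=fields[1] if len(fields) > 1 else "",
    )


def _iter_fastq(fh: IO[str], path) -> Iterator[SequenceRecord]:
    lineno = 0
    while True:
        block = []
        start = lineno + 1
        for _ in range(4):
            raw = fh.readline()
            lineno += 1
            if raw == "":
                break
            block.append(raw.rstrip("\n"))
        if not block or (len(block) == 1 and not block[0].strip()):
            return
        if len(block) < 4:
            raise ParseError("truncated FASTQ record", path, start + len(block) - 1)
        head, seq, sep, qual = block
        if not head.startswith("@"):
            raise ParseError(f"expected '@' header, got {head!r}", path, start)
        if not sep.startswith("+"):
            raise ParseError(f"expected '+' separator, got {sep!r}", path, start + 2)
        fields = head[1:].split(None, 1)
        if not fields:
            raise ParseError("empty FASTQ header", path, start)
        residues = _normalize(seq.strip())
        if not residues:
            raise ParseError(f"record {fields[0]!r} has no sequence", path, start + 1)
        _check_residues(residues, fields[0], path, start + 1)
        if len(qual) != len(residues):
            raise ParseError(
                f"record {fields[0]!r}: quality string length {len(qual)} "
                f"!= sequence length {len(residues)}",
                path,
                start + 3,
            )
        scores = []
        for ch in qual:
            q = ord(ch) - 33
            if not (0 <= q <= 93):
                raise ParseError(
                    f"record {fields[0]!r}: invalid Phred+33 character {ch!r}",
                    path,
                    start + 3,
                )
            scores.append(q)
        yield SequenceRecord(
            id=fields[0],
            residues=residues,
            description=fields[1] if len(fields) > 1 else "",
            qualities=tuple(scores),
        )


def read_sequences(path, format: str = "auto") -> list:
    """Read FASTA or FASTQ into a list of :class:`SequenceRecord`.

    Records are returned in file order (order is load-bearing: the
    deterministic merge of the parallel stages relies on it).  An empty
    file yields an empty list.
    """
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    with _open_text(path) as fh:
        if format == "fasta":
            return list(_iter_fasta(fh, path))
        return list(_iter_fastq(fh, path))


def write_sequences(records: Iterable[SequenceRecord], path, format: Optional[str] = None,
                    line_width: int = 70) -> None:
    """Write records as FASTA or FASTQ (chosen by extension when not given)."""
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        format = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown sequence format {format!r}")
    with _open_text(path, "wt") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            if format == "fasta":
                fh.write(f">{rec.id}{desc}\n")
                for i in range(0, len(rec.residues), line_width):
                    fh.write(rec.residues[i : i + line_width] + "\n")
            else:
                if rec.qualities is None:
                    raise ValueError(
                        f"record {rec.id!r} has no qualities; cannot write FASTQ"
                    )
                qual = "".join(chr(q + 33) for q in rec.qualities)
                fh.write(f"@{rec.id}{desc}\n{rec.residues}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# taxonomy


def read_taxonomy(path) -> TaxonomyMap:
    """Read a 2-column (id TAB lineage) taxonomy table."""
    entries: dict = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(
                    "taxonomy line needs >= 2 tab-separated columns", path, lineno
                )
            ref_id, lineage = cols[0].strip(), cols[1].strip()
            if ref_id in entries:
                raise ParseError(
                    f"duplicate reference id {ref_id!r} in taxonomy", path, lineno
                )
            entries[ref_id] = lineage
    return TaxonomyMap(entries=entries)


def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with _open_text(path, "wt") as fh:
        for ref_id, lineage in taxonomy.entries.items():
            fh.write(f"{ref_id}\t{lineage}\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits


def write_tabular_hits(hits: Iterable[TabularHit], path) -> None:
    """Serialize hits in the standard 12-column tab-separated layout.

    Internal 0-based half-open coordinates become 1-based inclusive;
    minus-strand hits are written with subject start > subject end.
    """
    with _open_text(path, "wt") as fh:
        for h in hits:
            if h.strand == "+":
                s1, s2 = h.sstart + 1, h.send
            else:
                s1, s2 = h.send, h.sstart + 1
            fh.write(
                f"{h.qseqid}\t{h.sseqid}\t{h.pident:.2f}\t{h.length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart + 1}\t{h.qend}\t"
                f"{s1}\t{s2}\t{h.evalue:.2e}\t{h.bitscore:.1f}\n"
            )


def read_tabular_hits(path) -> list:
    hits = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(cols)}", path, lineno
                )
            try:
                q1, q2 = int(cols[6]), int(cols[7])
                a, b = int(cols[8]), int(cols[9])
                if a <= b:
                    strand, sstart, send = "+", a - 1, b
                else:
                    strand, sstart, send = "-", b - 1, a
                hits.append(
                    TabularHit(
                        qseqid=cols[0],
                        sseqid=cols[1],
                        pident=float(cols[2]),
                        length=int(cols[3]),
                        mismatch=int(cols[4]),
                        gapopen=int(cols[5]),
                        qstart=q1 - 1,
                        qend=q2,
                        sstart=sstart,
                        send=send,
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno) from exc
    return hits
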