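"""Readers and writers for the standard formats the scaffolder touches.

Internal coordinates are 0-based half-open everywhere.  The 1-based
inclusive conventions of RepeatMasker ``.out``, BLAST tabular, AGP and
GFF3 are converted exactly once, at the format boundary, so every
read/write pair is an involution on valid data.

Parsers reject malformed records with :class:`FormatError`; they never
silently truncate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "SequenceRecord",
    "RepeatAnnotation",
    "AgpComponent",
    "TabularAlignment",
    "read_fasta",
    "write_fasta",
    "parse_repeatmasker_out",
    "write_repeatmasker_out",
    "parse_alignment_tabular",
    "write_alignment_tabular",
    "write_agp",
    "read_agp",
    "write_unique_regions_gff",
    "read_unique_regions_gff",
    "write_cycle_log_tsv",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


_VALID_CHARS = frozenset("ACGTNacgtn")


@dataclass
class SequenceRecord:
    """A named DNA sequence over {A,C,G,T,N}, uppercased on read.

    Lowercase letters in the input are interpreted as pre-existing
    softmasking (e.g. RepeatMasker ``-xsmall`` output) and recorded in
    ``softmask`` as 0-based half-open intervals before uppercasing.
    """

    id: str
    seq: str
    description: str = ""
    softmask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat interval on a contig, 0-based half-open.

    ``repeat_class`` is the full RepeatMasker class/family string (e.g.
    ``LTR/Gypsy``); ``family`` is the part after the slash (``Gypsy``),
    or the whole string when there is no slash.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    family: str
    repeat_class: str
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end}) on {self.contig_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.family:
            raise ValueError("empty repeat family")


@dataclass(frozen=True)
class AgpComponent:
    """One W-line of an AGP layout (both coordinate systems 1-based inclusive)."""

    scaffold_id: str
    scaffold_start: int
    scaffold_end: int
    part_number: int
    component_id: str
    component_start: int
    component_end: int
    orientation: str

    def __post_init__(self) -> None:
        if self.scaffold_end - self.scaffold_start != self.component_end - self.component_start:
            raise ValueError(
                f"span mismatch in {self.scaffold_id} part {self.part_number}: "
                f"scaffold {self.scaffold_start}-{self.scaffold_end} vs "
                f"component {self.component_start}-{self.component_end}"
            )
        if self.orientation not in ("+", "-"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass(frozen=True)
class TabularAlignment:
    """One row of 12-column BLAST tabular output, coordinates normalized.

    ``s_start < s_end`` always; a subject hit reported descending in the
    file is normalized to ascending coordinates with ``strand == '-'``.
    Internally coordinates are 0-based half-open.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    evalue: float
    bitscore: float


# ---------------------------------------------------------------------------
# FASTA


def _softmask_intervals(raw: str) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(raw):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(raw)))
    return out


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Record order is preserved.  Duplicate ids, empty files and letters
    outside {A,C,G,T,N,a,c,g,t,n} are errors; the offending position is
    reported for bad letters.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal header, chunks
        if header is None:
            return
        fields = header.split(None, 1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        raw = "".join(chunks)
        if rid in seen:
            raise FormatError(f"duplicate sequence id {rid!r} in {path}")
        if not raw:
            raise FormatError(f"record {rid!r} has no sequence in {path}")
        for i, c in enumerate(raw):
            if c not in _VALID_CHARS:
                raise FormatError(
                    f"invalid character {c!r} at position {i} of record {rid!r} in {path}"
                )
        seen.add(rid)
        records.append(
            SequenceRecord(id=rid, seq=raw.upper(), description=desc,
                           softmask=_softmask_intervals(raw))
        )
        header, chunks = None, []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"empty FASTA header in {path}")
            else:
                if header is None:
                    raise FormatError(f"sequence before first header in {path}")
                chunks.append(line.strip())
        flush()
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA with fixed line wrap (default 60 columns)."""
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# RepeatMasker .out

_RM_HEADER = (
    "   SW   perc perc perc  query     position in query    matching"
    "  repeat       position in repeat\n"
    "score   div. del. ins.  sequence  begin end    (left)  repeat"
    "       class/family  begin  end    (left)\n\n"
)


def parse_repeatmasker_out(path: str | Path) -> list[RepeatAnnotation]:
    """Parse RepeatMasker ``.out`` annotations.

    Query coordinates (1-based inclusive) become 0-based half-open; an
    orientation column of ``C`` (complement) maps to strand ``-``.
    """
    path = Path(path)
    out: list[RepeatAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            first = stripped.split()[0]
            # header lines start with "SW" / "score"; data lines with a score
            if not re.fullmatch(r"-?\d+(\.\d+)?", first):
                continue
            cols = stripped.split()
            if len(cols) < 14:
                raise FormatError(f"{path}:{lineno}: expected >=14 columns, got {len(cols)}")
            score = float(cols[0])
            contig_id = cols[4]
            begin, end = int(cols[5]), int(cols[6])
            strand_col = cols[8]
            repeat_class = cols[10]
            if end < begin:
                raise FormatError(f"{path}:{lineno}: end < begin ({end} < {begin})")
            if strand_col == "C":
                strand = "-"
            elif strand_col == "+":
                strand = "+"
            else:
                raise FormatError(f"{path}:{lineno}: bad orientation column {strand_col!r}")
            family = repeat_class.split("/", 1)[1] if "/" in repeat_class else repeat_class
            out.append(
                RepeatAnnotation(
                    contig_id=contig_id,
                    start=begin - 1,
                    end=end,
                    strand=strand,
                    family=family,
                    repeat_class=repeat_class,
                    score=score,
                )
            )
    return out


def write_repeatmasker_out(annotations: Sequence[RepeatAnnotation], path: str | Path) -> None:
    """Write annotations in RepeatMasker ``.out`` layout (inverse of the parser)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, a in enumerate(annotations, 1):
            strand = "C" if a.strand == "-" else "+"
            score = f"{a.score:g}" if a.score is not None else "0"
            name = a.family
            fh.write(
                f"{score:>5} {0.0:>6.1f} {0.0:>4.1f} {0.0:>4.1f}  {a.contig_id:<10} "
                f"{a.start + 1:>7} {a.end:>7} (0)  {strand} {name:<12} "
                f"{a.repeat_class:<14} {1:>6} {a.end - a.start:>6} (0) {i:>4}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (12-column, outfmt 6)


def parse_alignment_tabular(path: str | Path) -> list[TabularAlignment]:
    """Parse 12-column BLAST tabular rows into normalized alignments."""
    path = Path(path)
    out: list[TabularAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            (qid, sid, pident, length, mism, gapo,
             qstart, qend, sstart, send, evalue, bits) = cols
            identity = float(pident)
            if not (0.0 <= identity <= 100.0):
                raise FormatError(f"{path}:{lineno}: identity {identity} outside [0,100]")
            qs, qe = int(qstart), int(qend)
            ss, se = int(sstart), int(send)
            if ss <= se:
                strand, s0, s1 = "+", ss - 1, se
            else:
                strand, s0, s1 = "-", se - 1, ss
            out.append(
                TabularAlignment(
                    query_id=qid,
                    subject_id=sid,
                    identity=identity,
                    aln_len=int(length),
                    mismatches=int(mism),
                    gap_opens=int(gapo),
                    q_start=qs - 1,
                    q_end=qe,
                    s_start=s0,
                    s_end=s1,
                    strand=strand,
                    evalue=float(evalue),
                    bitscore=float(bits),
                )
            )
    return out


def write_alignment_tabular(alignments: Sequence[TabularAlignment], path: str | Path) -> None:
    """Write alignments as 12-column BLAST tabular (inverse of the parser)."""
    with open(path, "w") as fh:
        for a in alignments:
            if a.strand == "+":
                ss, se = a.s_start + 1, a.s_end
            else:
                ss, se = a.s_end, a.s_start + 1
            fh.write(
                "\t".join(
                    [
                        a.query_id,
                        a.subject_id,
                        f"{a.identity:.2f}",
                        str(a.aln_len),
                        str(a.mismatches),
                        str(a.gap_opens),
                        str(a.q_start + 1),
                        str(a.q_end),
                        str(ss),
                        str(se),
                        f"{a.evalue:.2g}",
                        f"{a.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1


def write_agp(layouts: dict[str, Sequence[AgpComponent]], path: str | Path,
              contained: dict[str, Sequence[tuple[str, str]]] | None = None) -> None:
    """Write scaffold layouts as AGP v2.1 W-lines.

    ``layouts`` maps scaffold id to its ordered components.  Components
    must tile the scaffold contiguously starting at 1.  Contigs absorbed
    by containment (not part of the tiling) may be passed per scaffold in
    ``contained`` and are emitted as comment lines.
    """
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for sid, comps in layouts.items():
            expected_start = 1
            for part, c in enumerate(comps, 1):
                if c.part_number != part:
                    raise FormatError(f"{sid}: part_number {c.part_number}, expected {part}")
                if c.scaffold_start != expected_start:
                    raise FormatError(
                        f"{sid}: component part {part} starts at {c.scaffold_start}, "
                        f"expected {expected_start} (overlap or gap)"
                    )
                expected_start = c.scaffold_end + 1
                fh.write(
                    "\t".join(
                        [
                            sid,
                            str(c.scaffold_start),
                            str(c.scaffold_end),
                            str(c.part_number),
                            "W",
                            c.component_id,
                            str(c.component_start),
                            str(c.component_end),
                            c.orientation,
                        ]
                    )
                    + "\n"
                )
            for comp_id, orient in (contained or {}).get(sid, ()):
                fh.write(f"# contained\t{sid}\t{comp_id}\t{orient}\n")


def read_agp(path: str | Path) -> dict[str, list[AgpComponent]]:
    """Read AGP W-lines back into per-scaffold component lists."""
    path = Path(path)
    layouts: dict[str, list[AgpComponent]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            if cols[4] != "W":
                raise FormatError(f"{path}:{lineno}: unsupported component type {cols[4]!r}")
            comp = AgpComponent(
                scaffold_id=cols[0],
                scaffold_start=int(cols[1]),
                scaffold_end=int(cols[2]),
                part_number=int(cols[3]),
                component_id=cols[5],
                component_start=int(cols[6]),
                component_end=int(cols[7]),
                orientation=cols[8],
            )
            layouts.setdefault(comp.scaffold_id, []).append(comp)
    return layouts


# ---------------------------------------------------------------------------
# GFF3 for unique regions


def write_unique_regions_gff(regions: Sequence, path: str | Path,
                             contig_lengths: dict[str, int] | None = None) -> None:
    """Write unique regions as GFF3 ``unique_region`` features (ID=UID)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in regions:
            if contig_lengths is not None:
                clen = contig_lengths.get(r.contig_id)
                if clen is not None and not (0 <= r.start < r.end <= clen):
                    raise FormatError(
                        f"region {r.uid} [{r.start},{r.end}) outside contig "
                        f"{r.contig_id} of length {clen}"
                    )
            fh.write(
                "\t".join(
                    [
                        r.contig_id,
                        "uidscaffold",
                        "unique_region",
                        str(r.start + 1),
                        str(r.end),
                        ".",
                        "+",
                        ".",
                        f"ID={r.uid}",
                    ]
                )
                + "\n"
            )


def read_unique_regions_gff(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read unique-region features back as (uid, contig_id, start, end) tuples."""
    path = Path(path)
    out: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            uid = attrs.get("ID")
            if uid is None:
                raise FormatError(f"{path}:{lineno}: missing ID attribute")
            out.append((uid, cols[0], int(cols[3]) - 1, int(cols[4])))
    return out


# ---------------------------------------------------------------------------
# Cycle log


def write_cycle_log_tsv(log, path: str | Path) -> None:
    """Write the per-cycle merge log as TSV."""
    with open(path, "w") as fh:
        fh.write(
            "cycle\tcandidates\taccepted\tmerged\tcontigs_before\tcontigs_after\t"
            "n50_before\tn50_after\n"
        )
        for c in log.cycles:
            fh.write(
                f"{c.cycle}\t{c.n_candidates}\t{c.n_accepted}\t{c.n_merged}\t"
                f"{c.contigs_before}\t{c.contigs_after}\t{c.n50_before}\t{c.n50_after}\n"
            )
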