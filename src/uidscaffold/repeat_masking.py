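"""Repeat masking: external annotations, plus a simple built-in masker.

The primary path applies externally produced repeat annotations
(RepeatMasker ``.out`` or softmasked FASTA) to the assembly.  A k-mer
copy-number masker and an exact tandem-unit masker are provided so the
pipeline can run de novo on inputs without annotations; they are a
testing convenience, deliberately subordinate to external annotations
(when both are supplied the interval sets are unioned).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import RepeatAnnotation, SequenceRecord

__all__ = [
    "MaskedContig",
    "MaskerParams",
    "merge_intervals",
    "apply_annotations",
    "kmer_mask",
    "tandem_mask",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MaskedContig:
    """A contig plus its sorted, disjoint repeat intervals.

    ``masks`` entries are ``(start, end, family)`` with 0-based half-open
    coordinates; overlapping intervals are merged on construction and
    adjacent intervals of equal family coalesced.
    """

    record: SequenceRecord
    masks: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def seq(self) -> str:
        return self.record.seq

    def __len__(self) -> int:
        return len(self.record.seq)

    def masked_bases(self, start: int = 0, end: int | None = None) -> int:
        """Number of masked bases within [start, end)."""
        if end is None:
            end = len(self)
        total = 0
        for s, e, _ in self.masks:
            total += max(0, min(e, end) - max(s, start))
        return total

    def masks_in(self, start: int, end: int) -> list[tuple[int, int, str]]:
        """Mask intervals clipped to [start, end)."""
        out = []
        for s, e, fam in self.masks:
            cs, ce = max(s, start), min(e, end)
            if cs < ce:
                out.append((cs, ce, fam))
        return out


@dataclass(frozen=True)
class MaskerParams:
    """Parameters of the built-in k-mer / tandem maskers."""

    k: int = 15
    min_kmer_count: int = 4
    tandem_min_unit: int = 2
    tandem_max_unit: int = 10
    tandem_min_span: int = 50

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("k must be >= 8")
        if self.min_kmer_count < 2:
            raise ValueError("min_kmer_count must be >= 2")


def merge_intervals(intervals: Iterable[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Merge overlapping intervals into disjoint ones.

    The family of a merged run is the input family covering the most
    bases of the union (ties broken by lexicographically smallest name);
    adjacent disjoint intervals of equal family are coalesced.
    """
    ivs = sorted(intervals, key=lambda t: (t[0], t[1], t[2]))
    if not ivs:
        return []
    merged: list[tuple[int, int, str]] = []
    # group into overlapping runs
    group: list[tuple[int, int, str]] = [ivs[0]]
    group_end = ivs[0][1]
    for iv in ivs[1:]:
        if iv[0] < group_end:  # strict overlap joins the run
            group.append(iv)
            group_end = max(group_end, iv[1])
        else:
            merged.append(_collapse_group(group))
            group = [iv]
            group_end = iv[1]
    merged.append(_collapse_group(group))
    # coalesce adjacent equal-family intervals
    out: list[tuple[int, int, str]] = []
    for s, e, fam in merged:
        if out and out[-1][1] == s and out[-1][2] == fam:
            out[-1] = (out[-1][0], e, fam)
        else:
            out.append((s, e, fam))
    return out


def _collapse_group(group: list[tuple[int, int, str]]) -> tuple[int, int, str]:
    start = min(s for s, _, _ in group)
    end = max(e for _, e, _ in group)
    votes: Counter[str] = Counter()
    for s, e, fam in group:
        votes[fam] += e - s
    top = max(votes.values())
    fam = min(f for f, n in votes.items() if n == top)  # tie -> lexicographically smallest
    return (start, end, fam)


def n_run_intervals(seq: str) -> list[tuple[int, int, str]]:
    """Maximal runs of N, always masked (family ``N``)."""
    out: list[tuple[int, int, str]] = []
    start = None
    for i, c in enumerate(seq):
        if c == "N":
            if start is None:
                start = i
        elif start is not None:
            out.append((start, i, "N"))
            start = None
    if start is not None:
        out.append((start, len(seq), "N"))
    return out


def apply_annotations(
    records: Sequence[SequenceRecord],
    annotations: Sequence[RepeatAnnotation],
    include_softmask: bool = True,
) -> list[MaskedContig]:
    """Mask contigs from external repeat annotations.

    Per-contig intervals are merged; N runs are always masked; softmask
    intervals recorded on read (lowercase FASTA) are included unless
    disabled.  Unknown contig ids or out-of-bounds annotations raise.
    """
    by_id = {r.id: r for r in records}
    per_contig: dict[str, list[tuple[int, int, str]]] = {r.id: [] for r in records}
    for a in annotations:
        rec = by_id.get(a.contig_id)
        if rec is None:
            raise KeyError(f"annotation references unknown contig {a.contig_id!r}")
        if a.end > len(rec.seq):
            raise ValueError(
                f"annotation [{a.start},{a.end}) exceeds contig {a.contig_id} "
                f"length {len(rec.seq)}"
            )
        per_contig[a.contig_id].append((a.start, a.end, a.family))
    out: list[MaskedContig] = []
    for rec in records:
        ivs = per_contig[rec.id] + n_run_intervals(rec.seq)
        if include_softmask:
            ivs += [(s, e, "Softmask") for s, e in rec.softmask]
        out.append(MaskedContig(record=rec, masks=merge_intervals(ivs)))
    return out


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_mask(records: Sequence[SequenceRecord], params: MaskerParams = MaskerParams()) -> list[MaskedContig]:
    """Mask positions covered by high-copy canonical k-mers.

    A position is masked (family ``KmerRepeat``) when any canonical
    k-mer covering it occurs at least ``min_kmer_count`` times across
    the whole assembly.  N positions are always masked.  Contigs shorter
    than k are returned unmasked (N runs aside).
    """
    k = params.k
    counts: Counter[str] = Counter()
    for rec in records:
        seq = rec.seq
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[canonical_kmer(kmer)] += 1
    out: list[MaskedContig] = []
    for rec in records:
        seq = rec.seq
        ivs: list[tuple[int, int, str]] = n_run_intervals(seq)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            if counts[canonical_kmer(kmer)] >= params.min_kmer_count:
                ivs.append((i, i + k, "KmerRepeat"))
        out.append(MaskedContig(record=rec, masks=merge_intervals(ivs)))
    return out


def tandem_mask(record: SequenceRecord, params: MaskerParams = MaskerParams()) -> list[tuple[int, int, str]]:
    """Mask maximal exact tandem runs (family ``Tandem``).

    A maximal periodic stretch for unit length ``u`` (tandem_min_unit..
    tandem_max_unit) is the closure of consecutive positions with
    ``seq[i] == seq[i - u]``; it is masked when it spans at least
    ``tandem_min_span`` bases and contains at least two full units.
    Stretches found at different unit lengths are unioned.
    """
    seq = record.seq
    n = len(seq)
    ivs: list[tuple[int, int, str]] = []
    for u in range(params.tandem_min_unit, params.tandem_max_unit + 1):
        j: int | None = None  # start of current match run
        for i in range(u, n + 1):
            ok = i < n and seq[i] == seq[i - u] and seq[i] != "N"
            if ok and j is None:
                j = i
            elif not ok and j is not None:
                span = i - j + u  # periodic region is [j - u, i)
                if span >= params.tandem_min_span and span >= 2 * u:
                    ivs.append((j - u, i, "Tandem"))
                j = None
    return merge_intervals(ivs)
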