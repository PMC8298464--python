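"""Unique-region extraction and contig partitioning.

A unique region (unique tag) is a maximal unmasked stretch of a contig
at least ``min_unique_len`` (default 100 bp) long.  Each gets a
deterministic UID ``<contig_id>.u<ordinal>``.  Contigs with no unique
region are "repeat-only": excluded from matching and merging, carried
through to the final output unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .repeat_masking import MaskedContig

__all__ = ["UniqueRegion", "ContigPartition", "extract_unique_regions", "partition_contigs"]

DEFAULT_MIN_UNIQUE_LEN = 100


@dataclass(frozen=True)
class UniqueRegion:
    """An unmasked stretch >= min_unique_len, the unit of merge evidence."""

    uid: str
    contig_id: str
    ordinal: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ContigPartition:
    """Contig ids split by presence of at least one unique region."""

    tagged: tuple[str, ...]
    repeat_only: tuple[str, ...]


def extract_unique_regions(
    contig: MaskedContig, min_unique_len: int = DEFAULT_MIN_UNIQUE_LEN
) -> list[UniqueRegion]:
    """Complement the mask set and keep stretches >= min_unique_len.

    Ordinals are the 0-based rank of the region along the contig; UIDs
    are ``<contig_id>.u<ordinal>``.
    """
    n = len(contig)
    gaps: list[tuple[int, int]] = []
    pos = 0
    for s, e, _ in contig.masks:
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < n:
        gaps.append((pos, n))
    out: list[UniqueRegion] = []
    for start, end in gaps:
        if end - start >= min_unique_len:
            ordinal = len(out)
            out.append(
                UniqueRegion(
                    uid=f"{contig.id}.u{ordinal}",
                    contig_id=contig.id,
                    ordinal=ordinal,
                    start=start,
                    end=end,
                )
            )
    return out


def partition_contigs(
    contigs: Sequence[MaskedContig], min_unique_len: int = DEFAULT_MIN_UNIQUE_LEN
) -> ContigPartition:
    """Split contigs into unique-tagged and repeat-only bins."""
    tagged: list[str] = []
    repeat_only: list[str] = []
    for c in contigs:
        if extract_unique_regions(c, min_unique_len):
            tagged.append(c.id)
        else:
            repeat_only.append(c.id)
    return ContigPartition(tagged=tuple(tagged), repeat_only=tuple(repeat_only))
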