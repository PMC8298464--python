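"""Assembly summary statistics (contig count, N50, total bases, GC%)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["AssemblyStats", "n50", "assembly_stats"]


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    max_len: int
    mean_len: float
    n50: int
    gc_percent: float

    def as_table(self) -> str:
        """Human-readable table in the style of an assembly report."""
        rows = [
            ("Total contigs", f"{self.n_contigs:,}"),
            ("Maximum contig Length", f"{self.max_len:,}"),
            ("N50", f"{self.n50:,}"),
            ("Total base", f"{self.total_bp:,}"),
            ("Total average", f"{self.mean_len:,.2f}"),
            ("GC Percentage", f"{self.gc_percent:.2f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def n50(lengths: Sequence[int]) -> int:
    """Smallest length L with all contigs >= L summing to >= half the total.

    Computed by descending sort and cumulative sum.
    """
    if len(lengths) == 0:
        raise ValueError("n50 of empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if np.any(arr <= 0):
        raise ValueError("contig lengths must be positive")
    half = arr.sum() / 2
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def assembly_stats(records: Iterable) -> AssemblyStats:
    """Summary statistics over sequence records (anything with ``.seq``).

    GC% counts G+C over A+C+G+T only: N bases are excluded from both
    numerator and denominator.
    """
    lengths: list[int] = []
    gc = 0
    acgt = 0
    for rec in records:
        seq = rec.seq
        lengths.append(len(seq))
        g = seq.count("G") + seq.count("C")
        a = seq.count("A") + seq.count("T")
        gc += g
        acgt += g + a
    if not lengths:
        raise ValueError("empty assembly")
    total = int(sum(lengths))
    return AssemblyStats(
        n_contigs=len(lengths),
        total_bp=total,
        max_len=int(max(lengths)),
        mean_len=total / len(lengths),
        n50=n50(lengths),
        gc_percent=100.0 * gc / acgt if acgt else 0.0,
    )
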