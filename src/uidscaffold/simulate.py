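"""Synthetic repeat-rich genomes with known fragmentation truth.

The generator emulates the situation the scaffolder is built for: a
genome dominated by multi-kilobase interspersed repeat families
(LTR-retrotransposon-like, with per-copy divergence) separated by
unique sequence, fragmented into contigs whose ends terminate inside
repeat copies so that merge evidence is confined to internal unique
anchors.  Fragment adjacency and orientation truth is recorded so a
reconstruction can be scored exactly.

Repeat copies are interleaved with two kinds of unique gaps: short
"anchor gaps" (0.8-1.6 kb, every second inter-copy gap), which are the
designated fragmentation sites, and larger background gaps carrying the
rest of the unique sequence.  A fragment breakpoint window covers one
complete anchor gap with both window ends inside the flanking repeat
copies — the hard case of repeat-terminated contig ends — falling back
to uniform placement when no such window exists (e.g. a repeat-free
genome).

All randomness flows from one seeded generator; identical parameters
and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import AgpComponent, RepeatAnnotation, SequenceRecord
from .repeat_masking import revcomp

__all__ = [
    "SimParams",
    "TruthAdjacency",
    "FragmentedGenome",
    "ReconstructionReport",
    "simulate_genome",
    "fragment_genome",
    "evaluate_reconstruction",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = np.array(list("ACGT"))

_FAMILY_NAMES = [
    ("Gypsy", "LTR/Gypsy"),
    ("Copia", "LTR/Copia"),
    ("L1", "LINE/L1"),
    ("hAT", "DNA/hAT"),
    ("Helitron", "RC/Helitron"),
]

ANCHOR_GAP_RANGE = (800, 1600)  # length of designated unique anchor gaps, bp


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the synthetic benchmark.

    Defaults plant 3 repeat families x 8 copies x 5 kb = 120 kb of
    repeat into a 200 kb genome (60% repeat bases), with 2% per-copy
    substitution divergence; fragments of at least 10 kb share 2 kb
    overlaps at repeat-terminated breakpoints.
    """

    genome_len: int = 200_000
    n_repeat_families: int = 3
    repeat_unit_len: int = 5_000
    copies_per_family: int = 8
    divergence: float = 0.02
    target_repeat_fraction: float = 0.6
    overlap_len: int = 2_000
    min_fragment_len: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_len <= 0 or self.overlap_len < 0 or self.min_fragment_len <= 0:
            raise ValueError("lengths must be positive")
        if not (0.0 <= self.target_repeat_fraction < 1.0):
            raise ValueError("target_repeat_fraction must be in [0, 1)")
        if self.overlap_len >= self.min_fragment_len:
            raise ValueError("overlap_len must be smaller than min_fragment_len")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError("divergence must be in [0, 1)")

    @property
    def n_copies(self) -> int:
        return self.n_repeat_families * self.copies_per_family

    @property
    def planted_repeat_bases(self) -> int:
        return self.n_copies * self.repeat_unit_len


@dataclass(frozen=True)
class TruthAdjacency:
    """One true neighbor pair of the fragmentation, with orientation.

    ``relative_orientation`` is '+' when the two fragments were emitted
    on the same strand of the planted genome, '-' otherwise; the overlap
    interval is in genome coordinates.
    """

    left_id: str
    right_id: str
    relative_orientation: str
    overlap_start: int
    overlap_end: int

    @property
    def key(self) -> tuple[frozenset, str]:
        return (frozenset((self.left_id, self.right_id)), self.relative_orientation)


@dataclass
class FragmentedGenome:
    """Fragmentation output: contigs, their repeat annotations, and truth."""

    contigs: list[SequenceRecord]
    annotations: list[RepeatAnnotation]
    adjacencies: list[TruthAdjacency]
    flipped: dict[str, bool] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_genome(params: SimParams) -> tuple[SequenceRecord, list[RepeatAnnotation]]:
    """Generate a repeat-rich genome with ground-truth repeat annotations.

    Raises ``ValueError`` before generation when the planted repeat
    content cannot land within 5 percentage points of the target
    fraction.
    """
    planted = params.planted_repeat_bases
    achieved = planted / params.genome_len
    if abs(achieved - params.target_repeat_fraction) > 0.05:
        raise ValueError(
            f"planted repeat fraction {achieved:.3f} not within 0.05 of target "
            f"{params.target_repeat_fraction:.3f}; adjust family/copy/unit lengths"
        )
    rng = np.random.default_rng(params.seed)
    n_copies = params.n_copies
    if n_copies == 0:
        return SequenceRecord(id="genome", seq=_random_seq(rng, params.genome_len)), []

    free = params.genome_len - planted
    n_gaps = n_copies + 1
    # every second interior gap is a short anchor gap; the rest of the
    # unique sequence spreads over the remaining gaps
    anchor_idx = [i for i in range(1, n_gaps - 1) if i % 2 == 1]
    lo, hi = ANCHOR_GAP_RANGE
    anchor_lens = {i: int(rng.integers(lo, hi + 1)) for i in anchor_idx}
    while sum(anchor_lens.values()) > free - (n_gaps - len(anchor_lens)):
        # genome too repeat-dense for full-size anchors: shrink them
        anchor_lens = {i: max(10, v // 2) for i, v in anchor_lens.items()}
        if all(v == 10 for v in anchor_lens.values()):
            break
    remaining = free - sum(anchor_lens.values())
    other_idx = [i for i in range(n_gaps) if i not in anchor_lens]
    shares = rng.multinomial(remaining, np.full(len(other_idx), 1.0 / len(other_idx)))
    gap_lens = dict(anchor_lens)
    for i, share in zip(other_idx, shares):
        gap_lens[i] = int(share)

    fam_idx = list(range(params.n_repeat_families))
    names = [
        _FAMILY_NAMES[i] if i < len(_FAMILY_NAMES) else (f"Fam{i}", f"Unknown/Fam{i}")
        for i in fam_idx
    ]
    consensus = [_random_seq(rng, params.repeat_unit_len) for _ in fam_idx]
    slots = np.repeat(fam_idx, params.copies_per_family)
    rng.shuffle(slots)

    parts: list[str] = []
    annotations: list[RepeatAnnotation] = []
    pos = 0
    for copy_i, fam in enumerate(slots):
        parts.append(_random_seq(rng, gap_lens[copy_i]))
        pos += gap_lens[copy_i]
        copy_seq = _mutate(rng, consensus[fam], params.divergence)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            copy_seq = revcomp(copy_seq)
        family, repeat_class = names[fam]
        annotations.append(
            RepeatAnnotation(
                contig_id="genome",
                start=pos,
                end=pos + len(copy_seq),
                strand=strand,
                family=family,
                repeat_class=repeat_class,
                score=1000.0,
            )
        )
        parts.append(copy_seq)
        pos += len(copy_seq)
    parts.append(_random_seq(rng, gap_lens[n_gaps - 1]))
    genome = "".join(parts)
    assert len(genome) == params.genome_len
    return SequenceRecord(id="genome", seq=genome), annotations


# ---------------------------------------------------------------------------
# Fragmentation


def _breakpoint_windows(
    genome_len: int,
    annotations: Sequence[RepeatAnnotation],
    params: SimParams,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Candidate overlap windows, each straddling one inter-repeat gap
    with both window ends inside the flanking repeat copies."""
    L = params.overlap_len
    repeats = sorted((a.start, a.end) for a in annotations)
    windows: list[tuple[int, int]] = []
    for (ls, le), (rs, re) in zip(repeats, repeats[1:]):
        gap = rs - le
        if gap <= 0 or gap > L - 2:
            continue
        margin = L - gap
        dl = min(margin - 1, le - ls, margin // 2 + margin % 2)
        dr = margin - dl
        if dl < 1 or dr < 1 or dr > re - rs:
            continue
        windows.append((le - dl, rs + dr))
    if windows:
        return windows
    # fallback: no suitable repeat-flanked gap (e.g. repeat-free genome):
    # uniform windows
    out = []
    pos = params.min_fragment_len
    while pos + L + params.min_fragment_len <= genome_len:
        jitter = int(rng.integers(0, params.min_fragment_len // 2 + 1))
        start = pos + jitter
        if start + L + params.min_fragment_len > genome_len:
            break
        out.append((start, start + L))
        pos = start + params.min_fragment_len
    return out


def fragment_genome(
    genome: SequenceRecord,
    annotations: Sequence[RepeatAnnotation],
    params: SimParams,
) -> FragmentedGenome:
    """Cut the genome into overlapping fragments with recorded truth.

    Neighboring fragments share exactly one breakpoint window
    (``overlap_len`` bases); windows are placed at repeat-flanked unique
    gaps when available.  Each fragment is independently
    reverse-complemented with probability 1/2.  Fragment repeat
    annotations are remapped onto fragment coordinates.
    """
    n = len(genome.seq)
    if n <= 2 * params.min_fragment_len:
        raise ValueError("genome too short to fragment at min_fragment_len")
    rng = np.random.default_rng([params.seed, 1])
    candidates = sorted(_breakpoint_windows(n, annotations, params, rng))
    chosen: list[tuple[int, int]] = []
    prev_start = 0
    for w_s, w_e in candidates:
        if w_e - prev_start < params.min_fragment_len:
            continue
        if n - w_s < params.min_fragment_len:
            break
        chosen.append((w_s, w_e))
        prev_start = w_s

    bounds: list[tuple[int, int]] = []
    start = 0
    for w_s, w_e in chosen:
        bounds.append((start, w_e))
        start = w_s
    bounds.append((start, n))

    contigs: list[SequenceRecord] = []
    frag_annotations: list[RepeatAnnotation] = []
    flips: dict[str, bool] = {}
    for i, (s, e) in enumerate(bounds):
        cid = f"ctg{i + 1:04d}"
        seq = genome.seq[s:e]
        flip = bool(rng.random() < 0.5)
        flips[cid] = flip
        if flip:
            seq = revcomp(seq)
        contigs.append(SequenceRecord(id=cid, seq=seq, description=f"genome:{s}-{e}"))
        flen = e - s
        for a in annotations:
            cs, ce = max(a.start, s), min(a.end, e)
            if cs >= ce:
                continue
            fs, fe = cs - s, ce - s
            strand = a.strand
            if flip:
                fs, fe = flen - fe, flen - fs
                strand = "-" if strand == "+" else "+"
            frag_annotations.append(
                RepeatAnnotation(
                    contig_id=cid,
                    start=fs,
                    end=fe,
                    strand=strand,
                    family=a.family,
                    repeat_class=a.repeat_class,
                    score=a.score,
                )
            )

    adjacencies = [
        TruthAdjacency(
            left_id=contigs[i].id,
            right_id=contigs[i + 1].id,
            relative_orientation="+" if flips[contigs[i].id] == flips[contigs[i + 1].id] else "-",
            overlap_start=chosen[i][0],
            overlap_end=chosen[i][1],
        )
        for i in range(len(chosen))
    ]
    return FragmentedGenome(
        contigs=contigs,
        annotations=frag_annotations,
        adjacencies=adjacencies,
        flipped=flips,
    )


# ---------------------------------------------------------------------------
# Reconstruction scoring


@dataclass
class ReconstructionReport:
    precision: float
    recall: float
    n_predicted: int
    n_true: int
    n_recovered: int
    adjacency_status: dict[tuple[frozenset, str], str]


def evaluate_reconstruction(
    layouts: Mapping[str, Sequence[AgpComponent]],
    truth: Sequence[TruthAdjacency],
    known_contigs: Sequence[str] | None = None,
) -> ReconstructionReport:
    """Score predicted scaffold layouts against fragmentation truth.

    A predicted adjacency is a consecutive component pair in any
    scaffold; it is a true positive when its unordered id pair and
    relative orientation match a truth adjacency.  Precision is defined
    as 1.0 when nothing is predicted.
    """
    known = set(known_contigs) if known_contigs is not None else None
    predicted: set[tuple[frozenset, str]] = set()
    for sid, comps in layouts.items():
        comps = sorted(comps, key=lambda c: c.part_number)
        for c in comps:
            if known is not None and c.component_id not in known:
                raise KeyError(f"AGP references unknown contig {c.component_id!r}")
        for c1, c2 in zip(comps, comps[1:]):
            rel = "+" if c1.orientation == c2.orientation else "-"
            predicted.add((frozenset((c1.component_id, c2.component_id)), rel))
    truth_keys = {t.key for t in truth}
    tp = predicted & truth_keys
    status = {k: ("recovered" if k in tp else "missed") for k in truth_keys}
    precision = len(tp) / len(predicted) if predicted else 1.0
    recall = len(tp) / len(truth_keys) if truth_keys else 1.0
    return ReconstructionReport(
        precision=precision,
        recall=recall,
        n_predicted=len(predicted),
        n_true=len(truth_keys),
        n_recovered=len(tp),
        adjacency_status=status,
    )


# ---------------------------------------------------------------------------
# Truth TSV


def write_truth_tsv(adjacencies: Sequence[TruthAdjacency], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("left_id\tright_id\trelative_orientation\toverlap_start\toverlap_end\n")
        for t in adjacencies:
            fh.write(
                f"{t.left_id}\t{t.right_id}\t{t.relative_orientation}\t"
                f"{t.overlap_start}\t{t.overlap_end}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthAdjacency]:
    out: list[TruthAdjacency] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("left_id"):
            raise ValueError(f"not a truth TSV: {path}")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 5:
                raise ValueError(f"bad truth row: {line!r}")
            out.append(
                TruthAdjacency(cols[0], cols[1], cols[2], int(cols[3]), int(cols[4]))
            )
    return out
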