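"""Similarity search between unique regions and collinear anchor chaining.

The search is seed-and-extend: a canonical k-mer index over all unique
regions proposes region pairs sharing enough seeds; each proposed pair
is then aligned with a full local alignment (Smith–Waterman scoring
match +1, mismatch −2, linear gap −2.5, via Bio.Align.PairwiseAligner)
on both strands.  An alignment is kept as an *anchor* only at
``identity >= min_identity`` (default 80%) and ``aln_len >=
min_anchor_len`` (default 500 bp).

Anchors between one contig pair are chained per strand into the
maximum-weight strictly order-preserving chain over (a-ordinal,
b-ordinal) pairs — a weighted longest-increasing-subsequence — so a
chain never scrambles the sequential appearance of unique regions and
all its anchors share one relative orientation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

from .repeat_masking import revcomp
from .unique_tagging import UniqueRegion

__all__ = [
    "MatchParams",
    "RegionMatch",
    "AnchorChain",
    "build_seed_index",
    "align_pair",
    "find_candidate_matches",
    "chain_collinear",
]

DEFAULT_MIN_IDENTITY = 80.0
DEFAULT_MIN_ANCHOR_LEN = 500
DEFAULT_SEED_K = 15
DEFAULT_MIN_SHARED_SEEDS = 3


@dataclass(frozen=True)
class MatchParams:
    """Thresholds of the similarity search."""

    min_identity: float = DEFAULT_MIN_IDENTITY
    min_anchor_len: int = DEFAULT_MIN_ANCHOR_LEN
    seed_k: int = DEFAULT_SEED_K
    min_shared_seeds: int = DEFAULT_MIN_SHARED_SEEDS


@dataclass(frozen=True)
class RegionMatch:
    """A filtered local alignment between two unique regions (an anchor).

    Coordinates are 0-based half-open *within* each region; ``strand``
    is the orientation of the subject region relative to the query, with
    subject coordinates always given on the subject's forward strand.
    ``identity`` is 100 x matched columns / alignment columns.
    """

    query_uid: str
    subject_uid: str
    identity: float
    aln_len: int
    strand: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float


@dataclass(frozen=True)
class Anchor:
    """A RegionMatch lifted onto contig coordinates for chaining/merging."""

    match: RegionMatch
    a_region: UniqueRegion
    b_region: UniqueRegion
    a_start: int  # contig-a coordinates of the aligned span
    a_end: int
    b_start: int  # contig-b forward-strand coordinates
    b_end: int

    @property
    def aln_len(self) -> int:
        return self.match.aln_len

    @property
    def identity(self) -> float:
        return self.match.identity

    @property
    def strand(self) -> str:
        return self.match.strand


@dataclass(frozen=True)
class AnchorChain:
    """An ordered, orientation-consistent set of anchors linking two contigs."""

    contig_a: str
    contig_b: str
    orientation: str
    anchors: tuple[Anchor, ...]

    @property
    def total_anchor_len(self) -> int:
        return sum(a.aln_len for a in self.anchors)

    @property
    def a_span(self) -> tuple[int, int]:
        return (min(a.a_start for a in self.anchors), max(a.a_end for a in self.anchors))

    @property
    def b_span(self) -> tuple[int, int]:
        return (min(a.b_start for a in self.anchors), max(a.b_end for a in self.anchors))


# ---------------------------------------------------------------------------
# Seeding


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def build_seed_index(
    regions: Sequence[UniqueRegion],
    sequences: Mapping[str, str],
    seed_k: int = DEFAULT_SEED_K,
) -> dict[str, list[tuple[str, int]]]:
    """Canonical k-mer -> list of (uid, offset) postings.

    ``sequences`` maps uid to the region's sequence.  Seeds containing N
    are skipped.
    """
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for region in regions:
        seq = sequences[region.uid]
        for i in range(len(seq) - seed_k + 1):
            kmer = seq[i : i + seed_k]
            if "N" in kmer:
                continue
            index[canonical(kmer)].append((region.uid, i))
    return dict(index)


# ---------------------------------------------------------------------------
# Pairwise local alignment


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1.0
    al.mismatch_score = -2.0
    al.open_gap_score = -2.5
    al.extend_gap_score = -2.5
    return al


_ALIGNER = _aligner()


def _best_local(a: str, b: str):
    """Best local alignment of a vs b; returns (score, columns, identities,
    q_start, q_end, s_start, s_end) or None when no positive-score alignment."""
    try:
        alns = _ALIGNER.align(a, b)
    except (ValueError, OverflowError):
        return None
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    if columns == 0:
        return None
    blocks_a, blocks_b = aln.aligned
    q_start, q_end = int(blocks_a[0][0]), int(blocks_a[-1][1])
    s_start, s_end = int(blocks_b[0][0]), int(blocks_b[-1][1])
    return (float(aln.score), int(columns), int(counts.identities),
            q_start, q_end, s_start, s_end)


def align_pair(
    query_seq: str,
    subject_seq: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_ANCHOR_LEN,
    query_uid: str = "q",
    subject_uid: str = "s",
) -> RegionMatch | None:
    """Best local alignment of two region sequences on either strand.

    Returns a :class:`RegionMatch` only when identity >= ``min_identity``
    and alignment length >= ``min_len``; otherwise None.  Ties between
    strands prefer '+'; subject coordinates of a '-' hit are reported on
    the subject's forward strand.
    """
    fwd = _best_local(query_seq, subject_seq)
    rev = _best_local(query_seq, revcomp(subject_seq))
    if fwd is None and rev is None:
        return None
    # score ties prefer the + strand
    if rev is not None and (fwd is None or rev[0] > fwd[0]):
        best, strand = rev, "-"
    else:
        best, strand = fwd, "+"
    score, columns, identities, q_start, q_end, s_start, s_end = best
    identity = 100.0 * identities / columns
    if identity < min_identity or columns < min_len:
        return None
    if strand == "-":
        n = len(subject_seq)
        s_start, s_end = n - s_end, n - s_start
    return RegionMatch(
        query_uid=query_uid,
        subject_uid=subject_uid,
        identity=identity,
        aln_len=columns,
        strand=strand,
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        score=score,
    )


# ---------------------------------------------------------------------------
# Candidate search


def find_candidate_matches(
    regions: Sequence[UniqueRegion],
    sequences: Mapping[str, str],
    params: MatchParams = MatchParams(),
) -> list[RegionMatch]:
    """All-vs-all seeded search over unique regions of different contigs.

    Region pairs sharing at least ``min_shared_seeds`` distinct canonical
    seeds are aligned with :func:`align_pair`.  Self and intra-contig
    pairs are excluded; each unordered region pair is reported once, with
    the query being the region of the lexicographically smaller
    (contig_id, ordinal).
    """
    by_uid = {r.uid: r for r in regions}
    index = build_seed_index(regions, sequences, params.seed_k)
    shared: dict[tuple[str, str], set[str]] = defaultdict(set)
    for seed, postings in index.items():
        if len(postings) < 2:
            continue
        uids = sorted({uid for uid, _ in postings})
        for i in range(len(uids)):
            for j in range(i + 1, len(uids)):
                u, v = uids[i], uids[j]
                if by_uid[u].contig_id == by_uid[v].contig_id:
                    continue
                shared[(u, v)].add(seed)
    out: list[RegionMatch] = []
    for (u, v) in sorted(shared):
        if len(shared[(u, v)]) < params.min_shared_seeds:
            continue
        ra, rb = by_uid[u], by_uid[v]
        if (rb.contig_id, rb.ordinal) < (ra.contig_id, ra.ordinal):
            ra, rb = rb, ra
        m = align_pair(
            sequences[ra.uid],
            sequences[rb.uid],
            params.min_identity,
            params.min_anchor_len,
            query_uid=ra.uid,
            subject_uid=rb.uid,
        )
        if m is not None:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# Collinear chaining


def _lift(match: RegionMatch, by_uid: Mapping[str, UniqueRegion]) -> Anchor:
    ra = by_uid[match.query_uid]
    rb = by_uid[match.subject_uid]
    return Anchor(
        match=match,
        a_region=ra,
        b_region=rb,
        a_start=ra.start + match.q_start,
        a_end=ra.start + match.q_end,
        b_start=rb.start + match.s_start,
        b_end=rb.start + match.s_end,
    )


def chain_collinear(
    matches: Sequence[RegionMatch],
    by_uid: Mapping[str, UniqueRegion],
) -> list[AnchorChain]:
    """Chain matches of one contig pair into <=1 chain per strand.

    Within each strand the maximum-total-anchor-length chain that is
    strictly increasing in a-ordinal and in (orientation-adjusted)
    b-ordinal is kept: a weighted longest-increasing-subsequence over
    ordinal pairs.  Crossing anchors are therefore never emitted.
    """
    if not matches:
        return []
    anchors = [_lift(m, by_uid) for m in matches]
    pair = {(a.a_region.contig_id, a.b_region.contig_id) for a in anchors}
    if len(pair) != 1:
        raise ValueError(f"matches span multiple contig pairs: {sorted(pair)}")
    contig_a, contig_b = next(iter(pair))
    chains: list[AnchorChain] = []
    for strand in ("+", "-"):
        sub = [a for a in anchors if a.strand == strand]
        if not sub:
            continue
        sign = 1 if strand == "+" else -1
        sub.sort(key=lambda a: (a.a_region.ordinal, sign * a.b_region.ordinal))
        best = _max_weight_increasing(
            [(a.a_region.ordinal, sign * a.b_region.ordinal, a.aln_len) for a in sub]
        )
        if best:
            chains.append(
                AnchorChain(
                    contig_a=contig_a,
                    contig_b=contig_b,
                    orientation=strand,
                    anchors=tuple(sub[i] for i in best),
                )
            )
    return chains


def _max_weight_increasing(items: Sequence[tuple[int, int, int]]) -> list[int]:
    """Indices of the max-weight subsequence strictly increasing in both keys.

    O(n^2) dynamic programme; deterministic tie-break toward the earliest
    predecessor.
    """
    n = len(items)
    if n == 0:
        return []
    weight = [items[i][2] for i in range(n)]
    back = [-1] * n
    for i in range(n):
        for j in range(i):
            if items[j][0] < items[i][0] and items[j][1] < items[i][1]:
                cand = weight[j] + items[i][2]
                if cand > weight[i]:
                    weight[i] = cand
                    back[i] = j
    end = max(range(n), key=lambda i: (weight[i], -i))
    out = []
    while end != -1:
        out.append(end)
        end = back[end]
    return out[::-1]
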