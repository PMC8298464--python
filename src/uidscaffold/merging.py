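"""Five-criteria contig merging and the iterative scaffolding cycle.

A candidate merge between two contigs is an anchor chain (see
:mod:`uidscaffold.matching`).  It is accepted only when all five
criteria hold:

1. sequential appearance — the chain's anchors preserve the order of
   unique regions on both contigs (no crossings, no scrambling);
2. length — every anchor alignment is at least ``min_anchor_len``
   (default 500 bp) long;
3. orientation — all anchors share one relative orientation;
4. consensus — when one contig end attracts several candidates, the
   competing partner contigs must themselves be mutually alignable, in
   which case they are laid out transitively into one path; otherwise
   only the best-scoring candidate survives;
5. repeat agreement — the repeat families in the gaps between
   consecutive anchors must agree between the two contigs, scored as a
   weighted Jaccard over per-family base coverage (threshold 0.5).

Accepted merges are executed as anchor-delimited overlap joins (the
overlap donor is the contig with fewer masked bases in the overlap) and
the whole tag → match → chain → evaluate → resolve → merge cycle is
repeated until a cycle performs no merge.  Every base of a scaffold is
traceable to one source contig through an AGP-style layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from .io_formats import AgpComponent, RepeatAnnotation, SequenceRecord
from .matching import Anchor, AnchorChain, MatchParams, chain_collinear, find_candidate_matches
from .repeat_masking import MaskedContig, apply_annotations, merge_intervals, revcomp
from .stats import n50
from .unique_tagging import UniqueRegion, extract_unique_regions

__all__ = [
    "MergeParameters",
    "MergeDecision",
    "LayoutComponent",
    "SupraContig",
    "CycleRecord",
    "CycleLog",
    "ScaffoldResult",
    "check_repeat_agreement",
    "evaluate_candidate",
    "resolve_conflicts",
    "execute_merge",
    "run_cycles",
]


@dataclass(frozen=True)
class MergeParameters:
    """Thresholds of the five merge criteria and the cycle loop.

    Defaults follow the published strategy: unique stretches of at least
    100 bp, anchor alignments of at least 500 bp at minimum 80%
    identity; the repeat-agreement threshold (0.5 weighted Jaccard) and
    the cycle cap are this implementation's configuration points.
    """

    min_unique_len: int = 100
    min_anchor_len: int = 500
    min_identity: float = 80.0
    repeat_agreement_min: float = 0.5
    min_chain_len: int = 0
    max_cycles: int = 32
    seed_k: int = 15
    min_shared_seeds: int = 3
    keep_repeat_only: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 100.0):
            raise ValueError("min_identity must be in (0, 100]")
        if min(self.min_unique_len, self.min_anchor_len, self.max_cycles) <= 0:
            raise ValueError("thresholds must be positive")

    def match_params(self) -> MatchParams:
        return MatchParams(
            min_identity=self.min_identity,
            min_anchor_len=self.min_anchor_len,
            seed_k=self.seed_k,
            min_shared_seeds=self.min_shared_seeds,
        )


@dataclass
class MergeDecision:
    """Per-criterion verdicts for one candidate merge."""

    chain: AnchorChain
    c1_sequential_ok: bool
    c2_length_ok: bool
    c3_orientation_ok: bool
    c4_consensus_ok: bool
    c5_repeat_ok: bool
    repeat_agreement_score: float
    composite_score: float
    from_consensus: bool = False

    @property
    def accepted(self) -> bool:
        return (
            self.c1_sequential_ok
            and self.c2_length_ok
            and self.c3_orientation_ok
            and self.c4_consensus_ok
            and self.c5_repeat_ok
        )

    def passes_static(self) -> bool:
        """Criteria 1, 2, 3 and 5 (criterion 4 is resolved jointly)."""
        return (
            self.c1_sequential_ok
            and self.c2_length_ok
            and self.c3_orientation_ok
            and self.c5_repeat_ok
        )


@dataclass(frozen=True)
class LayoutComponent:
    """One stretch of a scaffold traced to a source contig (0-based)."""

    component_id: str
    start: int
    end: int
    orientation: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SupraContig:
    """A (possibly merged) working contig with full base provenance.

    ``components`` tile the sequence; ``contained`` lists source contigs
    absorbed whole inside another component's span.  An un-merged input
    contig is a SupraContig with a single component covering itself.
    """

    id: str
    seq: str
    masks: list[tuple[int, int, str]]
    components: list[LayoutComponent]
    contained: list[tuple[str, str]] = field(default_factory=list)
    cycle_created: int = 0

    def __len__(self) -> int:
        return len(self.seq)

    # mask helpers mirror MaskedContig so unique tagging works unchanged
    masked_bases = MaskedContig.masked_bases
    masks_in = MaskedContig.masks_in

    @classmethod
    def from_masked(cls, mc: MaskedContig) -> "SupraContig":
        return cls(
            id=mc.id,
            seq=mc.seq,
            masks=list(mc.masks),
            components=[LayoutComponent(mc.id, 0, len(mc), "+")],
        )

    def agp_components(self) -> list[AgpComponent]:
        """Layout as 1-based AGP W-line components."""
        out: list[AgpComponent] = []
        pos = 0
        for part, c in enumerate(self.components, 1):
            out.append(
                AgpComponent(
                    scaffold_id=self.id,
                    scaffold_start=pos + 1,
                    scaffold_end=pos + c.length,
                    part_number=part,
                    component_id=c.component_id,
                    component_start=c.start + 1,
                    component_end=c.end,
                    orientation=c.orientation,
                )
            )
            pos += c.length
        return out


@dataclass(frozen=True)
class CycleRecord:
    cycle: int
    n_candidates: int
    n_accepted: int
    n_merged: int
    contigs_before: int
    contigs_after: int
    n50_before: int
    n50_after: int


@dataclass
class CycleLog:
    cycles: list[CycleRecord] = field(default_factory=list)
    converged: bool = False

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class ScaffoldResult:
    contigs: list[SupraContig]
    log: CycleLog
    repeat_only_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Criterion 5: repeat-family agreement


def check_repeat_agreement(
    gap_a_masks: Sequence[tuple[int, int, str]],
    gap_b_masks: Sequence[tuple[int, int, str]],
) -> float:
    """Weighted Jaccard of per-family base coverage between two gaps.

    score = sum_f min(cov_a[f], cov_b[f]) / sum_f max(cov_a[f], cov_b[f])
    over the union of families; 1.0 when both gaps are repeat-free.
    """
    cov_a: dict[str, int] = {}
    cov_b: dict[str, int] = {}
    for s, e, fam in gap_a_masks:
        cov_a[fam] = cov_a.get(fam, 0) + (e - s)
    for s, e, fam in gap_b_masks:
        cov_b[fam] = cov_b.get(fam, 0) + (e - s)
    fams = set(cov_a) | set(cov_b)
    if not fams:
        return 1.0
    num = sum(min(cov_a.get(f, 0), cov_b.get(f, 0)) for f in fams)
    den = sum(max(cov_a.get(f, 0), cov_b.get(f, 0)) for f in fams)
    return num / den if den else 1.0


# ---------------------------------------------------------------------------
# Chain geometry


@dataclass(frozen=True)
class _Geometry:
    """Placement of oriented contig b relative to a implied by a chain."""

    kind: str  # a_left | b_left | b_in_a | a_in_b
    delta: int  # offset of oriented-b origin on a's coordinate axis
    ov_a: tuple[int, int]
    ov_b: tuple[int, int]  # in oriented-b coordinates


def _oriented_b_coords(anchor: Anchor, len_b: int, orientation: str) -> tuple[int, int]:
    if orientation == "+":
        return anchor.b_start, anchor.b_end
    return len_b - anchor.b_end, len_b - anchor.b_start


def chain_geometry(chain: AnchorChain, len_a: int, len_b: int) -> _Geometry:
    anchors = sorted(chain.anchors, key=lambda a: a.a_start)
    first = anchors[0]
    ob_start, _ = _oriented_b_coords(first, len_b, chain.orientation)
    delta = first.a_start - ob_start
    ov_a_start = max(0, delta)
    ov_a_end = min(len_a, delta + len_b)
    ov = (ov_a_start, ov_a_end)
    ov_b = (ov_a_start - delta, ov_a_end - delta)
    if delta >= 0 and delta + len_b <= len_a:
        kind = "b_in_a"
    elif delta <= 0 and -delta + len_a <= len_b:
        kind = "a_in_b"
    elif delta >= 0:
        kind = "a_left"
    else:
        kind = "b_left"
    return _Geometry(kind=kind, delta=delta, ov_a=ov, ov_b=ov_b)


def _ends_used(decision: MergeDecision, contigs: Mapping[str, SupraContig]) -> list[tuple[str, str]]:
    """Contig attachment points (id, 'L'/'R') a decision consumes."""
    ch = decision.chain
    g = chain_geometry(ch, len(contigs[ch.contig_a]), len(contigs[ch.contig_b]))
    o = ch.orientation
    if g.kind == "b_in_a":
        return [(ch.contig_b, "L"), (ch.contig_b, "R")]
    if g.kind == "a_in_b":
        return [(ch.contig_a, "L"), (ch.contig_a, "R")]
    if g.kind == "a_left":
        b_end = "L" if o == "+" else "R"
        return [(ch.contig_a, "R"), (ch.contig_b, b_end)]
    b_end = "R" if o == "+" else "L"
    return [(ch.contig_a, "L"), (ch.contig_b, b_end)]


# ---------------------------------------------------------------------------
# Criterion evaluation


def evaluate_candidate(
    chain: AnchorChain,
    contigs: Mapping[str, SupraContig],
    params: MergeParameters = MergeParameters(),
) -> MergeDecision:
    """Evaluate criteria 1, 2, 3 and 5 on one anchor chain.

    Criterion 4 is provisional here (True); it is settled jointly by
    :func:`resolve_conflicts`.
    """
    if chain.contig_a not in contigs or chain.contig_b not in contigs:
        raise KeyError(f"chain references unknown contig: {chain.contig_a}/{chain.contig_b}")
    ca = contigs[chain.contig_a]
    cb = contigs[chain.contig_b]
    anchors = sorted(chain.anchors, key=lambda a: a.a_region.ordinal)

    # criterion 1: strictly order-preserving in both contigs
    sign = 1 if chain.orientation == "+" else -1
    c1 = len(anchors) >= 1 and all(
        anchors[i].a_region.ordinal < anchors[i + 1].a_region.ordinal
        and sign * anchors[i].b_region.ordinal < sign * anchors[i + 1].b_region.ordinal
        for i in range(len(anchors) - 1)
    )

    # criterion 2: anchor length
    c2 = (
        len(anchors) >= 1
        and all(a.aln_len >= params.min_anchor_len for a in anchors)
        and chain.total_anchor_len >= params.min_chain_len
    )

    # criterion 3: one shared orientation
    c3 = {a.strand for a in anchors} == {chain.orientation}

    # criterion 5: repeat families between consecutive anchors must agree
    scores: list[float] = []
    for prev, nxt in zip(anchors, anchors[1:]):
        gap_a = (prev.a_end, nxt.a_start)
        if chain.orientation == "+":
            gap_b = (prev.b_end, nxt.b_start)
        else:
            gap_b = (nxt.b_end, prev.b_start)
        a_masks = ca.masks_in(*gap_a) if gap_a[0] < gap_a[1] else []
        b_masks = cb.masks_in(*gap_b) if gap_b[0] < gap_b[1] else []
        scores.append(check_repeat_agreement(a_masks, b_masks))
    agreement = min(scores) if scores else 1.0
    c5 = agreement >= params.repeat_agreement_min

    composite = sum(a.aln_len * a.identity / 100.0 for a in anchors)
    return MergeDecision(
        chain=chain,
        c1_sequential_ok=c1,
        c2_length_ok=c2,
        c3_orientation_ok=c3,
        c4_consensus_ok=True,
        c5_repeat_ok=c5,
        repeat_agreement_score=agreement,
        composite_score=composite,
    )


# ---------------------------------------------------------------------------
# Criterion 4: conflict resolution


def _decision_order(d: MergeDecision) -> tuple:
    return (-d.composite_score, d.chain.contig_a, d.chain.contig_b, d.chain.orientation)


def resolve_conflicts(
    decisions: Sequence[MergeDecision],
    contigs: Mapping[str, SupraContig],
    params: MergeParameters = MergeParameters(),
    pair_evaluator: Callable[[str, str], MergeDecision | None] | None = None,
) -> list[MergeDecision]:
    """Settle criterion 4: one merge per contig end, consensus paths allowed.

    Decisions are taken in descending composite score (ties by contig
    ids, then '+' strand first).  When a decision claims an end already
    taken, the two competing partner contigs are aligned against each
    other (``pair_evaluator``): if they form a passing chain, that chain
    joins the pool — laying the partners out transitively into one path
    — and the losing direct decision is marked failed on criterion 4;
    otherwise only the incumbent survives.  The result is an end-disjoint
    accepted set.
    """
    pool = sorted((d for d in decisions if d.passes_static()), key=_decision_order)
    ends_used: dict[tuple[str, str], MergeDecision] = {}
    accepted: list[MergeDecision] = []
    tried: set[frozenset[str]] = set()
    queue = list(pool)
    i = 0
    while i < len(queue):
        d = queue[i]
        i += 1
        ends = _ends_used(d, contigs)
        conflicts = [e for e in ends if e in ends_used]
        if not conflicts:
            for e in ends:
                ends_used[e] = d
            accepted.append(d)
            continue
        d.c4_consensus_ok = False
        if pair_evaluator is None:
            continue
        shared = conflicts[0]
        incumbent = ends_used[shared]
        pair_d = {d.chain.contig_a, d.chain.contig_b}
        pair_i = {incumbent.chain.contig_a, incumbent.chain.contig_b}
        partners = (pair_d | pair_i) - {shared[0]}
        if len(partners) != 2:
            continue
        key = frozenset(partners)
        if key in tried:
            continue
        tried.add(key)
        p, q = sorted(partners)
        nd = pair_evaluator(p, q)
        if nd is not None and nd.passes_static():
            nd.from_consensus = True
            # insert keeping score order among the unprocessed tail
            queue.append(nd)
            queue[i:] = sorted(queue[i:], key=_decision_order)
    return accepted


# ---------------------------------------------------------------------------
# Merge execution


def _flip_masks(masks: Sequence[tuple[int, int, str]], length: int) -> list[tuple[int, int, str]]:
    return sorted((length - e, length - s, fam) for s, e, fam in masks)


def _flip_layout(components: Sequence[LayoutComponent]) -> list[LayoutComponent]:
    return [
        LayoutComponent(c.component_id, c.start, c.end, "-" if c.orientation == "+" else "+")
        for c in reversed(components)
    ]


def _slice_layout(components: Sequence[LayoutComponent], start: int, end: int) -> list[LayoutComponent]:
    """Layout restricted to scaffold interval [start, end), re-based."""
    out: list[LayoutComponent] = []
    pos = 0
    for c in components:
        c_start, c_end = pos, pos + c.length
        pos = c_end
        lo, hi = max(c_start, start), min(c_end, end)
        if lo >= hi:
            continue
        o1, o2 = lo - c_start, hi - c_start
        if c.orientation == "+":
            src = (c.start + o1, c.start + o2)
        else:
            src = (c.end - o2, c.end - o1)
        out.append(LayoutComponent(c.component_id, src[0], src[1], c.orientation))
    return out


def _oriented_copy(c: SupraContig, orientation: str) -> SupraContig:
    if orientation == "+":
        return c
    return SupraContig(
        id=c.id,
        seq=revcomp(c.seq),
        masks=_flip_masks(c.masks, len(c)),
        components=_flip_layout(c.components),
        contained=[(cid, "-" if o == "+" else "+") for cid, o in c.contained],
        cycle_created=c.cycle_created,
    )


def execute_merge(
    a: SupraContig,
    b: SupraContig,
    chain: AnchorChain,
    new_id: str | None = None,
    cycle: int = 0,
) -> SupraContig:
    """Join two contigs along an accepted chain into one supracontig.

    The chain implies an overlap interval on each contig; the overlap's
    bases come from the *donor* — the contig with fewer masked bases in
    the overlap (ties: the longer contig, then the lexicographically
    smaller id).  Containments keep the container's sequence and record
    the contained contig.  Masks and the component layout are lifted
    onto the merged coordinates.
    """
    if chain.contig_a != a.id or chain.contig_b != b.id:
        raise ValueError("chain does not connect the given contigs")
    bo = _oriented_copy(b, chain.orientation)
    g = chain_geometry(chain, len(a), len(b))
    _verify_anchors(a, bo, chain)
    if g.kind == "b_in_a":
        result = SupraContig(
            id=new_id or a.id,
            seq=a.seq,
            masks=list(a.masks),
            components=list(a.components),
            contained=a.contained + [(c.component_id, c.orientation) for c in bo.components] + bo.contained,
            cycle_created=cycle,
        )
        return result
    if g.kind == "a_in_b":
        result = SupraContig(
            id=new_id or b.id,
            seq=bo.seq,
            masks=list(bo.masks),
            components=list(bo.components),
            contained=bo.contained + [(c.component_id, c.orientation) for c in a.components] + a.contained,
            cycle_created=cycle,
        )
        return result
    if g.kind == "a_left":
        left, right = a, bo
        ov_left, ov_right = g.ov_a, g.ov_b
    else:  # b_left: bo starts before a
        left, right = bo, a
        ov_left, ov_right = g.ov_b, g.ov_a
    # donor = fewer masked bases in overlap; tie -> longer contig, then smaller id
    lm = _masked_in(left.masks, *ov_left)
    rm = _masked_in(right.masks, *ov_right)
    if lm != rm:
        donor_left = lm < rm
    elif len(left) != len(right):
        donor_left = len(left) > len(right)
    else:
        donor_left = left.id <= right.id
    if donor_left:
        cut_left, cut_right = ov_left[1], ov_right[1]
    else:
        cut_left, cut_right = ov_left[0], ov_right[0]
    seq = left.seq[:cut_left] + right.seq[cut_right:]
    components = _slice_layout(left.components, 0, cut_left) + _slice_layout(
        right.components, cut_right, len(right)
    )
    masks = [m for m in left.masks if m[0] < cut_left]
    masks = [(s, min(e, cut_left), fam) for s, e, fam in masks]
    shift = cut_left - cut_right
    masks += [
        (max(s, cut_right) + shift, e + shift, fam)
        for s, e, fam in right.masks
        if e > cut_right
    ]
    return SupraContig(
        id=new_id or f"{left.id}+{right.id}",
        seq=seq,
        masks=merge_intervals(masks),
        components=components,
        contained=left.contained + right.contained,
        cycle_created=cycle,
    )


def _masked_in(masks: Sequence[tuple[int, int, str]], start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e, _ in masks)


def _verify_anchors(a: SupraContig, bo: SupraContig, chain: AnchorChain) -> None:
    """Defensive re-verification that anchor spans exist on both sequences."""
    len_b = len(bo)
    for anchor in chain.anchors:
        if anchor.a_end > len(a) or anchor.a_start < 0:
            raise ValueError(f"anchor span [{anchor.a_start},{anchor.a_end}) outside {a.id}")
        ob = _oriented_b_coords(anchor, len_b, chain.orientation)
        if ob[1] > len_b or ob[0] < 0:
            raise ValueError(f"anchor span {ob} outside {bo.id}")


# ---------------------------------------------------------------------------
# The cycle loop


def _cycle_once(
    contigs: dict[str, SupraContig],
    params: MergeParameters,
    cycle: int,
) -> tuple[dict[str, SupraContig], CycleRecord, list[MergeDecision]]:
    order = sorted(contigs)
    regions: list[UniqueRegion] = []
    seqs: dict[str, str] = {}
    regions_by_contig: dict[str, list[UniqueRegion]] = {}
    for cid in order:
        c = contigs[cid]
        rs = extract_unique_regions(c, params.min_unique_len)
        regions_by_contig[cid] = rs
        for r in rs:
            regions.append(r)
            seqs[r.uid] = c.seq[r.start : r.end]

    tagged_regions = [r for r in regions if regions_by_contig[r.contig_id]]
    matches = find_candidate_matches(tagged_regions, seqs, params.match_params())

    by_pair: dict[tuple[str, str], list] = {}
    by_uid = {r.uid: r for r in regions}
    for m in matches:
        key = (by_uid[m.query_uid].contig_id, by_uid[m.subject_uid].contig_id)
        by_pair.setdefault(key, []).append(m)

    decisions: list[MergeDecision] = []
    for key in sorted(by_pair):
        chains = chain_collinear(by_pair[key], by_uid)
        pair_decisions = [evaluate_candidate(ch, contigs, params) for ch in chains]
        passing = [d for d in pair_decisions if d.passes_static()]
        if len(passing) == 2:
            # a physical join has one relative orientation per pair: keep the
            # heavier chain (tie -> '+'), fail the other on criterion 4
            passing.sort(key=lambda d: (-d.chain.total_anchor_len, d.chain.orientation))
            passing[1].c4_consensus_ok = False
        decisions.extend(pair_decisions)

    def pair_evaluator(x: str, y: str) -> MergeDecision | None:
        """Criterion-4 consensus probe: best passing chain between x and y."""
        pool = list(by_pair.get((x, y), []))
        if not pool:
            from .matching import align_pair

            for rx in regions_by_contig.get(x, []):
                for ry in regions_by_contig.get(y, []):
                    m = align_pair(
                        seqs[rx.uid],
                        seqs[ry.uid],
                        params.min_identity,
                        params.min_anchor_len,
                        query_uid=rx.uid,
                        subject_uid=ry.uid,
                    )
                    if m is not None:
                        pool.append(m)
        if not pool:
            return None
        chains = chain_collinear(pool, by_uid)
        cand = [evaluate_candidate(ch, contigs, params) for ch in chains]
        cand = [d for d in cand if d.passes_static()]
        if not cand:
            return None
        cand.sort(key=lambda d: (-d.chain.total_anchor_len, d.chain.orientation))
        return cand[0]

    accepted = resolve_conflicts(
        [d for d in decisions if d.passes_static() and d.c4_consensus_ok],
        contigs,
        params,
        pair_evaluator,
    )

    lengths_before = [len(c) for c in contigs.values()]
    new_contigs = dict(contigs)
    consumed: set[str] = set()
    n_merged = 0
    for d in sorted(accepted, key=_decision_order):
        ch = d.chain
        if ch.contig_a in consumed or ch.contig_b in consumed:
            continue  # re-discovered next cycle on the merged contig
        a, b = new_contigs[ch.contig_a], new_contigs[ch.contig_b]
        merged = execute_merge(a, b, ch, new_id=f"supra_c{cycle}_{n_merged}", cycle=cycle)
        del new_contigs[ch.contig_a]
        del new_contigs[ch.contig_b]
        new_contigs[merged.id] = merged
        consumed.update((ch.contig_a, ch.contig_b))
        n_merged += 1

    lengths_after = [len(c) for c in new_contigs.values()]
    record = CycleRecord(
        cycle=cycle,
        n_candidates=len(decisions),
        n_accepted=len(accepted),
        n_merged=n_merged,
        contigs_before=len(contigs),
        contigs_after=len(new_contigs),
        n50_before=n50(lengths_before),
        n50_after=n50(lengths_after),
    )
    return new_contigs, record, decisions


def run_cycles(
    records: Sequence[SequenceRecord],
    annotations: Sequence[RepeatAnnotation] = (),
    params: MergeParameters = MergeParameters(),
) -> ScaffoldResult:
    """Iterate tag → match → chain → evaluate → resolve → merge to a fixed point.

    Stops when a cycle performs no merge, or after ``max_cycles`` (then
    flagged as not converged in the log).  Repeat-only contigs never
    merge but are carried through; set ``params.keep_repeat_only=False``
    to drop them from the returned contig list.
    """
    masked = apply_annotations(records, list(annotations))
    contigs: dict[str, SupraContig] = {m.id: SupraContig.from_masked(m) for m in masked}
    log = CycleLog()
    for cycle in range(1, params.max_cycles + 1):
        contigs, record, _ = _cycle_once(contigs, params, cycle)
        log.cycles.append(record)
        if record.n_merged == 0:
            log.converged = True
            break
    final = [contigs[cid] for cid in sorted(contigs)]
    repeat_only = tuple(
        c.id for c in final if not extract_unique_regions(c, params.min_unique_len)
    )
    if not params.keep_repeat_only:
        final = [c for c in final if c.id not in set(repeat_only)]
    return ScaffoldResult(contigs=final, log=log, repeat_only_ids=repeat_only)
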