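"""Five merge criteria, conflict resolution, merge execution, cycle loop."""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from _oracles import rc, weighted_jaccard_brute
from uidscaffold.io_formats import RepeatAnnotation, SequenceRecord
from uidscaffold.matching import Anchor, AnchorChain, RegionMatch, align_pair, chain_collinear
from uidscaffold.merging import (
    MergeParameters,
    SupraContig,
    check_repeat_agreement,
    evaluate_candidate,
    execute_merge,
    resolve_conflicts,
    run_cycles,
)
from uidscaffold.repeat_masking import MaskedContig, apply_annotations, merge_intervals
from uidscaffold.unique_tagging import UniqueRegion, extract_unique_regions


def _rand_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _supra(cid: str, seq: str, masks=()) -> SupraContig:
    mc = MaskedContig(record=SequenceRecord(id=cid, seq=seq), masks=merge_intervals(masks))
    return SupraContig.from_masked(mc)


def _best_chain(a: SupraContig, b: SupraContig, params: MergeParameters):
    """Build the heaviest passing chain between two contigs via the
    package's own region extraction + exhaustive pairwise alignment."""
    regions, seqs = [], {}
    for c in (a, b):
        rs = extract_unique_regions(c, params.min_unique_len)
        for r in rs:
            regions.append(r)
            seqs[r.uid] = c.seq[r.start : r.end]
    matches = []
    for ra in [r for r in regions if r.contig_id == a.id]:
        for rb in [r for r in regions if r.contig_id == b.id]:
            m = align_pair(seqs[ra.uid], seqs[rb.uid], params.min_identity,
                           params.min_anchor_len, query_uid=ra.uid, subject_uid=rb.uid)
            if m is not None:
                matches.append(m)
    by_uid = {r.uid: r for r in regions}
    chains = chain_collinear(matches, by_uid)
    chains.sort(key=lambda c: -c.total_anchor_len)
    return chains[0] if chains else None


def _manual_chain(anchor_specs, orientation="+"):
    """Chain from (a_ordinal, b_ordinal, aln_len, strand) tuples; regions
    are laid out 1 kb apart on contigs 'a' and 'b'."""
    anchors = []
    for a_ord, b_ord, ln, strand in anchor_specs:
        ra = UniqueRegion(uid=f"a.u{a_ord}", contig_id="a", ordinal=a_ord,
                          start=2000 * a_ord, end=2000 * a_ord + ln)
        rb = UniqueRegion(uid=f"b.u{b_ord}", contig_id="b", ordinal=b_ord,
                          start=2000 * b_ord, end=2000 * b_ord + ln)
        m = RegionMatch(query_uid=ra.uid, subject_uid=rb.uid, identity=95.0,
                        aln_len=ln, strand=strand, q_start=0, q_end=ln,
                        s_start=0, s_end=ln, score=float(ln))
        anchors.append(Anchor(match=m, a_region=ra, b_region=rb,
                              a_start=ra.start, a_end=ra.end,
                              b_start=rb.start, b_end=rb.end))
    return AnchorChain(contig_a="a", contig_b="b", orientation=orientation,
                       anchors=tuple(anchors))


class TestCheckRepeatAgreement:
    @pytest.mark.parametrize(
        "cov_a,cov_b,expected",
        [
            ({"Gypsy": 600}, {"Gypsy": 600}, 1.0),
            ({"Gypsy": 600}, {"LINE": 600}, 0.0),
            ({}, {}, 1.0),
            ({"Gypsy": 600, "Copia": 400}, {"Gypsy": 600, "LINE": 400}, 600 / 1400),
            ({"Gypsy": 100}, {"Gypsy": 300}, 100 / 300),
            ({"Gypsy": 500, "Copia": 500}, {"Gypsy": 250, "Copia": 750}, 750 / 1250),
            ({"A": 1}, {}, 0.0),
            ({"A": 10, "B": 20, "C": 30}, {"A": 10, "B": 20, "C": 30}, 1.0),
            ({"A": 10, "B": 20}, {"B": 10, "C": 5}, 10 / 35),
            ({"Gypsy": 1000}, {"Gypsy": 999}, 999 / 1000),
        ],
    )
    def test_hand_computed_values(self, cov_a, cov_b, expected):
        def as_masks(cov):
            out, pos = [], 0
            for fam, n in cov.items():
                out.append((pos, pos + n, fam))
                pos += n
            return out

        got = check_repeat_agreement(as_masks(cov_a), as_masks(cov_b))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(weighted_jaccard_brute(cov_a, cov_b), abs=1e-12)

    def test_split_intervals_accumulate_per_family(self):
        a = [(0, 300, "Gypsy"), (500, 800, "Gypsy")]
        b = [(0, 600, "Gypsy")]
        assert check_repeat_agreement(a, b) == pytest.approx(1.0)


class TestEvaluateCandidate:
    def _contigs(self):
        rng = random.Random(0)
        return {
            "a": _supra("a", _rand_seq(rng, 20000)),
            "b": _supra("b", _rand_seq(rng, 20000)),
        }

    def test_short_anchor_fails_length_criterion(self):
        chain = _manual_chain([(0, 0, 499, "+")])
        d = evaluate_candidate(chain, self._contigs())
        assert not d.c2_length_ok and not d.accepted
        assert d.c1_sequential_ok and d.c3_orientation_ok and d.c5_repeat_ok

    def test_500bp_anchor_passes_length_criterion(self):
        chain = _manual_chain([(0, 0, 500, "+")])
        d = evaluate_candidate(chain, self._contigs())
        assert d.c2_length_ok and d.accepted

    def test_mixed_strand_fails_orientation_criterion(self):
        chain = _manual_chain([(0, 0, 600, "+"), (1, 1, 600, "-")])
        d = evaluate_candidate(chain, self._contigs())
        assert not d.c3_orientation_ok and not d.accepted

    def test_crossing_anchors_fail_sequential_criterion(self):
        chain = _manual_chain([(0, 1, 600, "+"), (1, 0, 600, "+")])
        d = evaluate_candidate(chain, self._contigs())
        assert not d.c1_sequential_ok and not d.accepted

    def test_unknown_contig_rejected(self):
        chain = _manual_chain([(0, 0, 600, "+")])
        with pytest.raises(KeyError):
            evaluate_candidate(chain, {})

    def test_composite_score_weights_length_by_identity(self):
        chain = _manual_chain([(0, 0, 600, "+"), (1, 1, 500, "+")])
        d = evaluate_candidate(chain, self._contigs())
        assert d.composite_score == pytest.approx(1100 * 0.95)

    def test_disagreeing_gap_repeats_fail_criterion5(self):
        rng = random.Random(1)
        u1, u2 = _rand_seq(rng, 600), _rand_seq(rng, 600)
        ra, rb = _rand_seq(rng, 1000), _rand_seq(rng, 1000)
        a = _supra("a", u1 + ra + u2, [(600, 1600, "Gypsy")])
        b = _supra("b", u1 + rb + u2, [(600, 1600, "LINE")])
        params = MergeParameters()
        chain = _best_chain(a, b, params)
        assert chain is not None and len(chain.anchors) == 2
        d = evaluate_candidate(chain, {"a": a, "b": b}, params)
        assert d.repeat_agreement_score == pytest.approx(0.0)
        assert not d.c5_repeat_ok and not d.accepted

    def test_agreeing_gap_repeats_pass_criterion5(self):
        rng = random.Random(2)
        u1, u2 = _rand_seq(rng, 600), _rand_seq(rng, 600)
        r = _rand_seq(rng, 1000)
        a = _supra("a", u1 + r + u2, [(600, 1600, "Gypsy")])
        b = _supra("b", u1 + r + u2, [(600, 1600, "Gypsy")])
        params = MergeParameters()
        chain = _best_chain(a, b, params)
        d = evaluate_candidate(chain, {"a": a, "b": b}, params)
        assert d.repeat_agreement_score == pytest.approx(1.0)
        assert d.accepted


class TestResolveConflicts:
    def _three_node_fixture(self):
        """A's right end is claimed by B (900 bp overlap) and C (500 bp
        overlap of an interior A segment); B and C share nothing."""
        rng = random.Random(3)
        x = _rand_seq(rng, 5000)
        o1 = _rand_seq(rng, 900)
        a = _supra("a", x + o1)
        b = _supra("b", o1 + _rand_seq(rng, 5000))
        c = _supra("c", x[4500:5000] + _rand_seq(rng, 5000))
        contigs = {"a": a, "b": b, "c": c}
        params = MergeParameters()
        d_ab = evaluate_candidate(_best_chain(a, b, params), contigs, params)
        d_ac = evaluate_candidate(_best_chain(a, c, params), contigs, params)
        assert d_ab.composite_score == pytest.approx(900, abs=5)
        assert d_ac.composite_score == pytest.approx(500, abs=5)
        return contigs, d_ab, d_ac, params

    def test_single_candidate_accepted(self):
        contigs, d_ab, _, params = self._three_node_fixture()
        assert resolve_conflicts([d_ab], contigs, params) == [d_ab]
        assert d_ab.c4_consensus_ok

    def test_higher_score_wins_without_consensus(self):
        contigs, d_ab, d_ac, params = self._three_node_fixture()
        accepted = resolve_conflicts([d_ac, d_ab], contigs, params,
                                     pair_evaluator=lambda x, y: None)
        assert accepted == [d_ab]
        assert not d_ac.c4_consensus_ok

    def test_choice_maximizes_score_over_end_disjoint_subsets(self):
        from uidscaffold.merging import _ends_used

        contigs, d_ab, d_ac, params = self._three_node_fixture()
        accepted = resolve_conflicts([d_ab, d_ac], contigs, params,
                                     pair_evaluator=lambda x, y: None)
        best_score, best = -1.0, None
        for r in range(3):
            for combo in combinations([d_ab, d_ac], r):
                ends = [e for d in combo for e in _ends_used(d, contigs)]
                if len(ends) != len(set(ends)):
                    continue
                score = sum(d.composite_score for d in combo)
                if score > best_score:
                    best_score, best = score, set(map(id, combo))
        assert set(map(id, accepted)) == best

    def test_mutually_alignable_partners_form_consensus_path(self):
        """B overlapping C: both claim A's right end, so the B-C chain is
        pulled in and both joins survive as the path A-B-C."""
        rng = random.Random(4)
        g = _rand_seq(rng, 20000)
        a = _supra("a", g[0:8000])
        b = _supra("b", g[6000:14000])
        c = _supra("c", g[7000:20000])
        contigs = {"a": a, "b": b, "c": c}
        params = MergeParameters()
        d_ab = evaluate_candidate(_best_chain(a, b, params), contigs, params)
        d_ac = evaluate_candidate(_best_chain(a, c, params), contigs, params)

        def pair_evaluator(x, y):
            ch = _best_chain(contigs[x], contigs[y], params)
            return evaluate_candidate(ch, contigs, params) if ch else None

        accepted = resolve_conflicts([d_ab, d_ac], contigs, params, pair_evaluator)
        assert d_ab in accepted
        consensus = [d for d in accepted if d.from_consensus]
        assert len(consensus) == 1
        assert {consensus[0].chain.contig_a, consensus[0].chain.contig_b} == {"b", "c"}


class TestExecuteMerge:
    def test_exact_dovetail(self):
        rng = random.Random(5)
        p, o, q = _rand_seq(rng, 2000), _rand_seq(rng, 600), _rand_seq(rng, 2000)
        a = _supra("a", p + o)
        b = _supra("b", o + q)
        params = MergeParameters()
        chain = _best_chain(a, b, params)
        merged = execute_merge(a, b, chain, new_id="s")
        assert len(merged) == len(a) + len(b) - 600
        assert merged.seq == p + o + q
        comps = merged.agp_components()
        assert [c.part_number for c in comps] == [1, 2]
        assert comps[0].scaffold_end + 1 == comps[1].scaffold_start

    def test_reverse_complemented_input_gives_same_sequence(self):
        rng = random.Random(6)
        p, o, q = _rand_seq(rng, 2000), _rand_seq(rng, 600), _rand_seq(rng, 2000)
        a = _supra("a", p + o)
        b_rev = _supra("b", rc(o + q))
        params = MergeParameters()
        chain = _best_chain(a, b_rev, params)
        assert chain.orientation == "-"
        merged = execute_merge(a, b_rev, chain, new_id="s")
        assert merged.seq == p + o + q
        # the reversed component is recorded with '-' orientation
        assert [c.orientation for c in merged.agp_components()] == ["+", "-"]

    def test_containment_keeps_container_and_records_contained(self):
        rng = random.Random(7)
        p, blk, q = _rand_seq(rng, 3000), _rand_seq(rng, 1000), _rand_seq(rng, 3000)
        a = _supra("a", p + blk + q)
        b = _supra("b", blk)
        params = MergeParameters()
        chain = _best_chain(a, b, params)
        merged = execute_merge(a, b, chain, new_id="s")
        assert merged.seq == a.seq
        assert ("b", "+") in merged.contained
        # every contained base is present verbatim in the container
        assert a.seq[3000:4000] == b.seq

    def test_donor_prefers_less_masked_overlap(self):
        rng = random.Random(8)
        p, o, q = _rand_seq(rng, 2000), _rand_seq(rng, 700), _rand_seq(rng, 2000)
        o_b = o[:300] + rc(rc(o[300:]))  # identical overlap content
        a = _supra("a", p + o, [(2000, 2100, "Gypsy")])  # 100 masked in overlap
        b = _supra("b", o_b + q)
        params = MergeParameters(min_anchor_len=400)
        chain = _best_chain(a, b, params)
        merged = execute_merge(a, b, chain, new_id="s")
        # b donates the whole overlap: component 1 is only a's prefix
        comps = merged.agp_components()
        assert comps[0].component_id == "a"
        assert comps[1].component_id == "b"
        assert comps[1].component_start == 1  # b contributes from its start
        assert merged.seq == p + o + q


class TestRunCycles:
    def test_dissimilar_contigs_are_a_fixed_point(self):
        rng = random.Random(9)
        records = [SequenceRecord(id=f"c{i}", seq=_rand_seq(rng, 5000)) for i in range(4)]
        res = run_cycles(records, [], MergeParameters())
        assert res.log.n_cycles == 1
        assert res.log.converged
        assert sorted(c.seq for c in res.contigs) == sorted(r.seq for r in records)

    def test_three_contig_path_reassembles_planted_segment(self):
        rng = random.Random(10)
        g = _rand_seq(rng, 30000)
        records = [
            SequenceRecord(id="a", seq=g[0:12000]),
            SequenceRecord(id="b", seq=g[10000:22000]),
            SequenceRecord(id="c", seq=g[20000:30000]),
        ]
        res = run_cycles(records, [], MergeParameters())
        assert len(res.contigs) == 1
        assert res.contigs[0].seq in (g, rc(g))
        # merging cycles precede the terminal 0-merge cycle
        assert res.log.cycles[-1].n_merged == 0
        assert res.log.n_cycles <= 3

    def test_rerunning_converged_output_is_idempotent(self):
        rng = random.Random(10)
        g = _rand_seq(rng, 30000)
        records = [
            SequenceRecord(id="a", seq=g[0:12000]),
            SequenceRecord(id="b", seq=g[10000:22000]),
            SequenceRecord(id="c", seq=g[20000:30000]),
        ]
        res = run_cycles(records, [], MergeParameters())
        again_records = [SequenceRecord(id=c.id, seq=c.seq) for c in res.contigs]
        again = run_cycles(again_records, [], MergeParameters())
        assert again.log.n_cycles == 1 and again.log.cycles[0].n_merged == 0
        assert [c.seq for c in again.contigs] == [c.seq for c in res.contigs]

    def test_repeat_only_contigs_carried_through(self):
        rng = random.Random(11)
        records = [
            SequenceRecord(id="u", seq=_rand_seq(rng, 3000)),
            SequenceRecord(id="r", seq=_rand_seq(rng, 1500)),
        ]
        anns = [RepeatAnnotation("r", 0, 1500, "+", "Gypsy", "LTR/Gypsy")]
        res = run_cycles(records, anns, MergeParameters())
        assert res.repeat_only_ids == ("r",)
        assert {c.id for c in res.contigs} == {"r", "u"}
        dropped = run_cycles(records, anns, MergeParameters(keep_repeat_only=False))
        assert {c.id for c in dropped.contigs} == {"u"}
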