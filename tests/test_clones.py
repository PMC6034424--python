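import itertools
import random

import pytest

from clonescape import (
    UniqueSequence,
    assign_clones,
    cdr3_similarity,
    eligible,
    rescue_low_copy,
)
from clonescape.clones import window_identity_ok


def useq(
    useq_id,
    cdr3_aa,
    copies={"R1": 2},
    v=("IGHV1-2",),
    j=("IGHJ4",),
    sequence="A" * 90,
    germline=None,
):
    return UniqueSequence(
        useq_id=useq_id,
        subject_id="D1",
        sequence=sequence,
        v_call=frozenset(v),
        j_call=frozenset(j),
        cdr3_nt="NNN" * len(cdr3_aa),  # placeholder of consistent length
        cdr3_aa=cdr3_aa,
        copies_by_replicate=dict(copies),
        germline=germline,
    )


class TestEligibility:
    def test_low_copy_excluded(self):
        r = eligible(useq("u1", "CARDYW", copies={"R1": 1}))
        assert r.excluded_reason == "low_copy"

    def test_two_copies_eligible(self):
        assert eligible(useq("u1", "CARDYW", copies={"R1": 2})).eligible

    def test_cdr3_stop_excluded(self):
        r = eligible(useq("u1", "CARDY*W"))
        assert r.excluded_reason == "cdr3_stop"

    def test_indel_window_excluded_by_brute_force_oracle(self):
        # 17/30 matching positions in one window: 0.567 < 0.60
        germ = "A" * 90
        seq = "A" * 30 + "A" * 17 + "C" * 13 + "A" * 30
        assert not window_identity_ok(seq, germ)
        r = eligible(useq("u1", "CARDYW", sequence=seq, germline=germ))
        assert r.excluded_reason == "indel_window"

    def test_window_boundary_18_of_30_passes(self):
        germ = "A" * 90
        seq = "A" * 30 + "A" * 18 + "C" * 12 + "A" * 30
        # brute-force every window: minimum identity is exactly 18/30 = 0.60
        worst = min(
            sum(1 for k in range(i, i + 30) if seq[k] == germ[k]) / 30
            for i in range(len(seq) - 29)
        )
        assert worst == pytest.approx(0.60)
        assert window_identity_ok(seq, germ)

    def test_window_excludes_n_positions_from_both_sides(self):
        # mismatches hidden under N's do not count against identity
        germ = "A" * 60
        seq = "N" * 30 + "A" * 30
        assert window_identity_ok(seq, germ)

    def test_missing_germline_skips_window_check(self):
        assert eligible(useq("u1", "CARDYW", germline=None)).eligible


class TestCdr3Similarity:
    def test_identity(self):
        assert cdr3_similarity("CARDYWGQGT", "CARDYWGQGT") == 1.0

    def test_single_mismatch(self):
        assert cdr3_similarity("CARDYWGQGT", "CARDYWGQGA") == pytest.approx(0.9)

    def test_two_mismatches_fail_threshold(self):
        sim = cdr3_similarity("CARDYWGQGT", "CARDYWGQAA")
        assert sim == pytest.approx(0.8) and sim < 0.85

    def test_x_matches_anything(self):
        assert cdr3_similarity("CXRDYW", "CARDYW") == 1.0

    def test_unequal_lengths_raise(self):
        with pytest.raises(ValueError):
            cdr3_similarity("CAR", "CARD")


def oracle_greedy_partition(seqs, min_sim=0.85):
    """Exhaustive check: the greedy copy-ordered partition must be a valid
    complete-linkage partition, verified by enumerating all partitions of
    the small instance and confirming membership."""

    def valid(partition):
        return all(
            cdr3_similarity(a.cdr3_aa, b.cdr3_aa) >= min_sim
            for block in partition
            for a, b in itertools.combinations(block, 2)
        )

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1 :]
            yield [[first]] + part

    return [p for p in partitions(list(seqs)) if valid(p)]


class TestAssignClones:
    def test_pair_above_threshold_merges(self):
        a = useq("a", "CARDYWGQGT", copies={"R1": 5})
        b = useq("b", "CARDYWGQGA", copies={"R1": 2})
        (clone,) = assign_clones([a, b])
        assert clone.uniques == 2
        assert clone.copies == 7

    def test_different_cdr3_length_never_compared(self):
        a = useq("a", "CARDYWGQGT")
        b = useq("b", "CARDYWGQG")
        assert len(assign_clones([a, b])) == 2

    def test_different_j_gene_never_compared(self):
        a = useq("a", "CARDYWGQGT", j=("IGHJ4",))
        b = useq("b", "CARDYWGQGT", j=("IGHJ6",))
        assert len(assign_clones([a, b])) == 2

    def test_v_tie_sets_merge_on_intersection(self):
        a = useq("a", "CARDYWGQGT", v=("IGHV1-2", "IGHV1-69"), copies={"R1": 5})
        b = useq("b", "CARDYWGQGT", v=("IGHV1-2",), copies={"R1": 2})
        (clone,) = assign_clones([a, b])
        assert clone.v_gene == frozenset({"IGHV1-2"})

    def test_disjoint_v_sets_stay_apart(self):
        a = useq("a", "CARDYWGQGT", v=("IGHV1-2",))
        b = useq("b", "CARDYWGQGT", v=("IGHV3-23",))
        assert len(assign_clones([a, b])) == 2

    def test_complete_linkage_triple_matches_oracle(self):
        # sims: (A,B)=0.9, (A,C)=0.9, (B,C)=0.8; copies A>B>C
        a = useq("a", "CARDYWGQGT", copies={"R1": 5})
        b = useq("b", "CARDYWGQGA", copies={"R1": 3})
        c = useq("c", "AARDYWGQGT", copies={"R1": 2})
        assert cdr3_similarity(a.cdr3_aa, b.cdr3_aa) == pytest.approx(0.9)
        assert cdr3_similarity(a.cdr3_aa, c.cdr3_aa) == pytest.approx(0.9)
        assert cdr3_similarity(b.cdr3_aa, c.cdr3_aa) == pytest.approx(0.8)
        clones = assign_clones([a, b, c])
        got = sorted(tuple(sorted(m.useq_id for m in cl.members)) for cl in clones)
        assert got == [("a", "b"), ("c",)]
        # and that partition is among the valid complete-linkage partitions
        valid = oracle_greedy_partition([a, b, c])
        assert any(
            sorted(tuple(sorted(u.useq_id for u in blk)) for blk in p) == got
            for p in valid
        )

    def test_every_emitted_clone_satisfies_pairwise_invariant(self, sim_pipeline):
        for clone in sim_pipeline["clones"]:
            for a, b in itertools.combinations(clone.members, 2):
                assert cdr3_similarity(a.cdr3_aa, b.cdr3_aa) >= 0.85
                assert len(a.cdr3_nt) == clone.cdr3_len_nt == len(b.cdr3_nt)

    def test_copy_conservation_over_eligible_set(self, sim_pipeline):
        assert sum(c.copies for c in sim_pipeline["clones"]) == sum(
            u.total_copies for u in sim_pipeline["eligible"]
        )

    def test_partition_deterministic_under_shuffle(self, sim_pipeline):
        eligible_useqs = list(sim_pipeline["eligible"])
        baseline = [
            sorted(m.useq_id for m in c.members)
            for c in assign_clones(eligible_useqs)
        ]
        rng = random.Random(3)
        for _ in range(3):
            shuffled = list(eligible_useqs)
            rng.shuffle(shuffled)
            got = [
                sorted(m.useq_id for m in c.members)
                for c in assign_clones(shuffled)
            ]
            assert got == baseline


class TestRescue:
    def test_cross_replicate_singletons_are_rescued(self):
        u = useq("u", "CARDYW", copies={"R1": 1, "R2": 1})
        assert rescue_low_copy([u]) == [u]

    def test_within_replicate_pair_not_rescued(self):
        assert rescue_low_copy([useq("u", "CARDYW", copies={"R1": 2})]) == []

    def test_true_singleton_not_rescued(self):
        assert rescue_low_copy([useq("u", "CARDYW", copies={"R1": 1})]) == []
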