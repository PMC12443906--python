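import random

import pytest

from conftest import make_chromosome
from syntelog import (
    UNPLACED,
    BlockMap,
    DecayParams,
    HitRecord,
    consensus_blocks,
    initial_assignment,
    synteny_correct,
)

FWD = DecayParams(decay=0.9, scan_mode="forward", step_rule="every_locus")


def closed_form_sums(blocks, scores, decay, step_rule="every_locus"):
    """Independent O(n^2) oracle: S_B(i) = sum_{j<=i, block j = B}
    b_j * decay^(steps between j and i)."""
    n = len(blocks)
    step_no = []
    steps = 0
    for i in range(n):
        if step_rule == "every_locus" or blocks[i] is not None:
            steps += 1
        step_no.append(steps)
    out = []
    for i in range(n):
        sums = {}
        for j in range(i + 1):
            if blocks[j] is None:
                continue
            sums[blocks[j]] = sums.get(blocks[j], 0.0) + scores[j] * decay ** (
                step_no[i] - step_no[j]
            )
        out.append(sums)
    return out


def random_instance(rng, n_max=200):
    n = rng.randint(2, n_max)
    labels = [chr(65 + i) for i in range(rng.randint(1, 8))] + [UNPLACED]
    blocks = [
        None if rng.random() < 0.15 else rng.choice(labels) for _ in range(n)
    ]
    scores = [rng.uniform(1.0, 500.0) for _ in range(n)]
    return blocks, scores


def test_worked_example_sums_and_flags():
    """Blocks [A,A,B,A], scores [100,100,50,100], decay 0.9, forward scan:
    hand-derived sums at the third and fourth loci."""
    order, initials = make_chromosome(["A", "A", "B", "A"], [100, 100, 50, 100])
    res = consensus_blocks(order, initials, FWD)
    assert res["g2"].sums["A"] == pytest.approx(171.0)
    assert res["g2"].sums["B"] == pytest.approx(50.0)
    assert res["g2"].consensus == "A"
    assert res["g3"].sums["A"] == pytest.approx(253.9)
    assert res["g3"].sums["B"] == pytest.approx(45.0)
    assert [res[f"g{i}"].flag for i in range(4)] == [
        "syntenic",
        "syntenic",
        "non_syntenic",
        "syntenic",
    ]


def test_worked_example_correction_picks_best_in_block_hit():
    order, initials = make_chromosome(["A", "A", "B", "A"], [100, 100, 50, 100])
    res = consensus_blocks(order, initials, FWD)
    block_map = BlockMap({"r0": "A", "r1": "A", "r2": "B", "r3": "A", "r9": "A"})
    fwd_hits = [HitRecord(f"g{i}", f"r{i}", s) for i, s in
                enumerate([100, 100, 50, 100])]
    fwd_hits.append(HitRecord("g2", "r9", 40.0))
    calls = synteny_correct(initials, res, fwd_hits, block_map)
    assert calls["g2"].reference_id == "r9"
    assert calls["g2"].corrected
    # untouched syntenic genes keep their references
    assert calls["g0"].reference_id == "r0" and not calls["g0"].corrected


def test_no_in_block_hit_keeps_initial_reference():
    order, initials = make_chromosome(["A", "A", "B", "A"], [100, 100, 50, 100])
    res = consensus_blocks(order, initials, FWD)
    block_map = BlockMap({"r0": "A", "r1": "A", "r2": "B", "r3": "A"})
    fwd_hits = [HitRecord(f"g{i}", f"r{i}", s) for i, s in
                enumerate([100, 100, 50, 100])]
    calls = synteny_correct(initials, res, fwd_hits, block_map)
    assert calls["g2"].reference_id == "r2"
    assert not calls["g2"].corrected
    assert calls["g2"].flag == "non_syntenic"


@pytest.mark.parametrize("scan_mode", ["forward", "forward_plus_backward"])
def test_decay_zero_never_flags_non_syntenic(scan_mode):
    rng = random.Random(1)
    for _ in range(10):
        blocks, scores = random_instance(rng)
        order, initials = make_chromosome(blocks, scores)
        params = DecayParams(decay=0.0, scan_mode=scan_mode)
        res = consensus_blocks(order, initials, params)
        assert not any(r.flag == "non_syntenic" for r in res.values())


@pytest.mark.parametrize("decay", [0.0, 0.5, 0.9, 1.0])
def test_homogeneous_chromosome_has_no_flags(decay):
    order, initials = make_chromosome(["A"] * 20, [10.0 * (i + 1) for i in range(20)])
    res = consensus_blocks(order, initials, DecayParams(decay=decay))
    assert all(r.flag == "syntenic" for r in res.values())


@pytest.mark.parametrize("step_rule", ["every_locus", "hit_loci_only"])
def test_streaming_recurrence_matches_closed_form(step_rule):
    rng = random.Random(42)
    for _ in range(30):
        blocks, scores = random_instance(rng)
        decay = rng.choice([0.9, rng.uniform(0.1, 1.0)])
        order, initials = make_chromosome(blocks, scores)
        params = DecayParams(decay=decay, scan_mode="forward", step_rule=step_rule)
        res = consensus_blocks(order, initials, params)
        oracle = closed_form_sums(blocks, scores, decay, step_rule)
        for i, expected in enumerate(oracle):
            got = res[f"g{i}"].sums
            for b in set(expected) | set(got):
                assert got.get(b, 0.0) == pytest.approx(
                    expected.get(b, 0.0), rel=1e-9
                )


def test_bidirectional_scan_matches_symmetric_closed_form():
    """forward_plus_backward sums equal sum_j b_j * decay^|i-j| with the
    focal locus counted once."""
    rng = random.Random(7)
    for _ in range(10):
        blocks, scores = random_instance(rng, n_max=80)
        decay = 0.9
        order, initials = make_chromosome(blocks, scores)
        res = consensus_blocks(
            order, initials, DecayParams(decay=decay, scan_mode="forward_plus_backward")
        )
        n = len(blocks)
        for i in range(n):
            expected = {}
            for j in range(n):
                if blocks[j] is None:
                    continue
                expected[blocks[j]] = expected.get(blocks[j], 0.0) + scores[
                    j
                ] * decay ** abs(i - j)
            got = res[f"g{i}"].sums
            for b in set(expected) | set(got):
                assert got.get(b, 0.0) == pytest.approx(
                    expected.get(b, 0.0), rel=1e-9
                )


def test_interloper_is_flagged_once_context_dominates():
    """A single gene of block B with score b inside a run of block-A genes
    scoring >= b is flagged non-syntenic whenever the preceding decayed A
    context exceeds b (forward scan, per-locus steps)."""
    decay = 0.9
    b = 100.0
    for run in range(1, 12):
        blocks = ["A"] * run + ["B"] + ["A"] * 3
        scores = [b] * len(blocks)
        order, initials = make_chromosome(blocks, scores)
        res = consensus_blocks(order, initials, FWD)
        context = sum(b * decay ** (k + 1) for k in range(run))
        expected = "non_syntenic" if context > b else "syntenic"
        assert res[f"g{run}"].flag == expected


def test_unplaced_contributions_never_define_consensus():
    order, initials = make_chromosome(
        [UNPLACED, UNPLACED, "A"], [1000.0, 1000.0, 10.0]
    )
    res = consensus_blocks(order, initials, FWD)
    assert res["g2"].consensus == "A"
    assert res["g2"].flag == "syntenic"
    assert res["g0"].flag == "unblocked"
    # the shadow bucket is still tracked
    assert res["g2"].sums[UNPLACED] > 0


def test_argmax_tie_prefers_initial_block():
    # decay 1.0: at g2 (block B, 100) sums are A=100, B=100 -> keep B
    order, initials = make_chromosome(["A", "B"], [100.0, 100.0])
    res = consensus_blocks(order, initials, DecayParams(decay=1.0, scan_mode="forward"))
    assert res["g1"].consensus == "B"
    assert res["g1"].flag == "syntenic"


def test_sums_reset_at_chromosome_boundaries():
    from syntelog import GeneOrder, InitialAssignment, Locus

    loci = [
        Locus("g0", "chr1", 0, 50),
        Locus("g1", "chr2", 0, 50),
    ]
    initials = [
        InitialAssignment("g0", "r0", 500.0, "A"),
        InitialAssignment("g1", "r1", 10.0, "B"),
    ]
    res = consensus_blocks(GeneOrder(loci), initials, FWD)
    assert "A" not in res["g1"].sums
    assert res["g1"].flag == "syntenic"


def test_gene_missing_from_order_is_an_error():
    order, initials = make_chromosome(["A"], [100.0])
    from syntelog import InitialAssignment

    initials.append(InitialAssignment("ghost", "r9", 50.0, "A"))
    with pytest.raises(ValueError, match="ghost"):
        consensus_blocks(order, initials, FWD)


def test_initial_assignment_uses_block_map_with_sentinel():
    bm = BlockMap({"r1": "A"})
    ias = initial_assignment({"q1": ("r1", 200.0), "q2": ("r2", 100.0)}, bm)
    by_q = {ia.query_id: ia for ia in ias}
    assert by_q["q1"].block == "A"
    assert by_q["q2"].block == UNPLACED


def test_result_invariant_to_hit_row_order():
    rng = random.Random(3)
    blocks, scores = random_instance(rng, n_max=60)
    order, initials = make_chromosome(blocks, scores)
    res = consensus_blocks(order, initials, FWD)
    shuffled = initials[:]
    rng.shuffle(shuffled)
    res2 = consensus_blocks(order, shuffled, FWD)
    assert res == res2
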