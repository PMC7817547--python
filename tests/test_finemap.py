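"""Breakpoint inference, recombinant detection and interval refinement."""

import numpy as np
import pytest

from hifflux.finemap import (
    Breakpoint,
    BreakpointSet,
    CandidateInterval,
    FinemapError,
    GenotypeTable,
    InconsistentSegregationError,
    MarkerMap,
    SegregationCall,
    consensus_refine,
    detect_recombinants,
    het_interval,
    infer_breakpoints,
    progeny_test,
    refine_candidate_interval,
    select_arhif_pair,
)
from hifflux.finemap import LineEvidence

from conftest import brute_force_refine, random_refine_instance

MB = 1_000_000


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "calls, expected",
    [
        ("AAHH", [(2 * MB, 3 * MB, "A", "H")]),
        ("AAAA", []),
        ("AUHH", [(1 * MB, 3 * MB, "A", "H")]),  # U widens to nearest informative
        ("HHHH", []),
        ("ABAB", [(1 * MB, 2 * MB, "A", "B"), (2 * MB, 3 * MB, "B", "A"), (3 * MB, 4 * MB, "A", "B")]),
    ],
)
def test_infer_breakpoints_transitions(calls, expected):
    mm = MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 5))
    bps = infer_breakpoints("L1", calls, mm)
    got = [(b.left_pos, b.right_pos, b.left_state, b.right_state) for b in bps.breakpoints]
    assert got == expected


def test_infer_breakpoints_errors():
    mm = MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 5))
    with pytest.raises(FinemapError, match="no informative markers"):
        infer_breakpoints("L1", "UUUU", mm)
    with pytest.raises(FinemapError, match="calls for"):
        infer_breakpoints("L1", "AAH", mm)


def test_detect_recombinants_counts_transitions_only():
    mm = MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 5))
    rows = [("r1", "AAHH"), ("r2", "AAAA"), ("r3", "HHHH"), ("r4", "UUUU"), ("r5", "HHBB")]
    table = GenotypeTable(rows, mm)
    assert detect_recombinants(table) == ["r1", "r5"]
    assert detect_recombinants(GenotypeTable([], mm)) == []


def test_detect_recombinants_engineered_census():
    """A 276-line screen built to contain exactly 77 single-crossover lines."""
    mm = MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 11))
    rows = []
    for i in range(77):  # recombinants: transition at a varying interval
        cut = 1 + i % 9
        rows.append((f"R{i:03d}", "A" * cut + "H" * (10 - cut)))
    for i in range(276 - 77):  # non-recombinants, a mix of fixed and uniform-H
        rows.append((f"N{i:03d}", "H" * 10 if i % 3 else "A" * 10))
    table = GenotypeTable(rows, mm)
    assert len(detect_recombinants(table)) == 77


def test_detect_recombinants_invariant_to_row_order_and_relabeling():
    rng = np.random.default_rng(11)
    mm = MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 8))
    rows = [
        (f"L{i}", "".join(rng.choice(list("ABHU"), size=7))) for i in range(40)
    ]
    table = GenotypeTable(rows, mm)
    n = len(detect_recombinants(table))

    shuffled = rows.copy()
    rng.shuffle(shuffled)
    assert len(detect_recombinants(GenotypeTable(shuffled, mm))) == n

    relabeled = MarkerMap((f"x{i}", "c1", i * MB) for i in range(1, 8))
    assert len(detect_recombinants(GenotypeTable(rows, relabeled))) == n


def test_het_interval_inner_and_widened():
    mm = MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 7))
    calls = "AUHHUB"
    assert het_interval("L", calls, mm, widen=False) == (3 * MB, 4 * MB)
    # widened across the flanking U gaps to the nearest informative markers
    assert het_interval("L", calls, mm, widen=True) == (1 * MB, 6 * MB)
    assert het_interval("L", "AABB", MarkerMap((f"m{i}", "c1", i * MB) for i in range(1, 5))) is None


# ---------------------------------------------------------------------------
# progeny testing
# ---------------------------------------------------------------------------


def test_progeny_test_identical_groups_do_not_segregate():
    call = progeny_test("L", [10, 10, 10], [10, 10, 10], (1, 2))
    assert call.verdict == "non_segregating"
    assert call.p_value == 1.0


def test_progeny_test_welch_against_hand_computed_oracle():
    # t = 27/sqrt(25/3 + 9/3) = 8.0202, df = 3.2748, p = 0.0029 (hand-derived)
    call = progeny_test("L", [30, 35, 40], [5, 8, 11], (1, 2), alpha=0.05)
    assert call.verdict == "segregating"
    assert call.p_value == pytest.approx(0.0029211, rel=1e-4)


def test_progeny_test_insufficient_replication_is_inconclusive():
    call = progeny_test("L", [12], [30, 31], (1, 2))
    assert call.verdict == "inconclusive"
    assert np.isnan(call.p_value)


def test_progeny_test_empty_group_is_an_error():
    with pytest.raises(FinemapError, match="empty"):
        progeny_test("L", [], [1, 2], (1, 2))


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------


def _calls(*specs):
    return [
        SegregationCall(f"L{i}", (s * MB, e * MB), verdict, 0.5)
        for i, (s, e, verdict) in enumerate(specs)
    ]


def test_refine_segregating_vs_non_segregating(mb_map):
    ivs = refine_candidate_interval(
        _calls((2, 4, "segregating"), (3, 5, "non_segregating")), mb_map, (1 * MB, 5 * MB)
    )
    assert [(iv.start_bp, iv.end_bp) for iv in ivs] == [(2 * MB, 3 * MB)]


def test_refine_two_segregating_lines_intersect(mb_map):
    ivs = refine_candidate_interval(
        _calls((2, 4, "segregating"), (3, 5, "segregating")), mb_map, (1 * MB, 5 * MB)
    )
    assert [(iv.start_bp, iv.end_bp) for iv in ivs] == [(3 * MB, 4 * MB)]


def test_refine_reproduces_final_candidate_interval(paper_map):
    """Constructed call set consistent only with the 7,875-bp interval."""
    calls = [
        SegregationCall("seg1", (8_211_624, 8_329_176), "segregating", 1e-6),
        SegregationCall("ns_north", (7_180_000, 8_290_453), "non_segregating", 0.6),
        SegregationCall("ns_south", (8_298_328, 13_079_020), "non_segregating", 0.7),
    ]
    (iv,) = refine_candidate_interval(calls, paper_map, (7_180_000, 13_079_020))
    assert (iv.start_bp, iv.end_bp) == (8_290_453, 8_298_328)
    assert iv.width_bp == 7_875


def test_refine_subtraction_can_split_the_region(mb_map):
    ivs = refine_candidate_interval(
        _calls((2, 4, "non_segregating")), mb_map, (1 * MB, 5 * MB)
    )
    assert [(iv.start_bp, iv.end_bp) for iv in ivs] == [(1 * MB, 2 * MB), (4 * MB, 5 * MB)]


def test_refine_inconsistent_calls_raise_with_line_ids(mb_map):
    calls = _calls((1, 3, "segregating"), (1, 5, "non_segregating"))
    with pytest.raises(InconsistentSegregationError) as exc:
        refine_candidate_interval(calls, mb_map, (1 * MB, 5 * MB))
    assert set(exc.value.line_ids) == {"L0", "L1"}


def test_refine_matches_bruteforce_oracle_on_random_instances():
    rng = np.random.default_rng(202)
    for _ in range(300):
        marker_map, positions, calls, prior = random_refine_instance(rng)
        expected = brute_force_refine(calls, positions, prior)
        try:
            got = [
                (iv.start_bp, iv.end_bp)
                for iv in refine_candidate_interval(calls, marker_map, prior)
            ]
        except InconsistentSegregationError:
            got = []
        assert got == expected


def test_refine_adding_a_line_never_enlarges(mb_map):
    rng = np.random.default_rng(7)
    for _ in range(200):
        marker_map, positions, calls, prior = random_refine_instance(rng)
        if len(calls) < 2:
            continue

        def surviving(cs):
            try:
                return {
                    (iv.start_bp, iv.end_bp)
                    for iv in refine_candidate_interval(cs, marker_map, prior)
                }
            except InconsistentSegregationError:
                return set()

        full = surviving(calls)
        partial = surviving(calls[:-1])
        # every surviving point of the full set survives the smaller set
        for a, b in full:
            assert any(pa <= a and b <= pb for pa, pb in partial)


def test_consensus_matches_strict_on_clean_calls(mb_map):
    """With unambiguous evidence, consensus refinement equals the strict algebra."""
    evidence = [
        LineEvidence("L0", (2 * MB, 4 * MB), (2 * MB, 4 * MB), 12.0),
        LineEvidence("L1", (3 * MB, 5 * MB), (3 * MB, 5 * MB), 0.1),
    ]
    res = consensus_refine(evidence, mb_map, (1 * MB, 5 * MB))
    assert [(iv.start_bp, iv.end_bp) for iv in res.intervals] == [(2 * MB, 3 * MB)]
    assert res.conflicts == ()


# ---------------------------------------------------------------------------
# arHIF pair selection
# ---------------------------------------------------------------------------


def _bps(line_id, left, right):
    return BreakpointSet(line_id, (Breakpoint(left * MB, right * MB, "A", "H"),))


def test_select_arhif_pair_abutting_bounds():
    target = CandidateInterval("c1", 4 * MB, 5 * MB)
    north = _bps("n1", 3, 4)
    south = _bps("s1", 5, 6)
    assert select_arhif_pair([north, south], target) == ("n1", "s1")


def test_select_arhif_pair_prefers_nearest_then_narrowest_then_id():
    target = CandidateInterval("c1", 10 * MB, 11 * MB)
    lines = [
        _bps("far", 1, 2),
        _bps("near", 8, 9),
        _bps("nearer", 9, 10),
        _bps("s1", 11, 12),
    ]
    assert select_arhif_pair(lines, target)[0] == "nearer"

    # equal distance: narrower breakpoint wins, then lexicographic id
    wide = BreakpointSet("wide", (Breakpoint(7 * MB, 10 * MB, "A", "H"),))
    narrow = BreakpointSet("narrow", (Breakpoint(9 * MB, 10 * MB, "A", "H"),))
    assert select_arhif_pair([wide, narrow, _bps("s1", 11, 12)], target)[0] == "narrow"


def test_select_arhif_pair_missing_side_is_an_error():
    target = CandidateInterval("c1", 4 * MB, 5 * MB)
    with pytest.raises(FinemapError, match="south"):
        select_arhif_pair([_bps("n1", 3, 4), _bps("n2", 2, 3)], target)
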