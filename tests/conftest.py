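import numpy as np
import pytest

from hifflux.finemap import MarkerMap, SegregationCall

#: The six marker positions (bp, chromosome 4) that bound the successive
#: candidate intervals of the emulated campaign.
PAPER_POSITIONS = (7_180_000, 8_211_624, 8_290_453, 8_298_328, 8_329_176, 13_079_020)


@pytest.fixture(scope="session")
def paper_map() -> MarkerMap:
    return MarkerMap(
        (f"m{i + 1}", "chr4", p) for i, p in enumerate(PAPER_POSITIONS)
    )


@pytest.fixture(scope="session")
def mb_map() -> MarkerMap:
    """Markers at 1..5 Mb on one chromosome."""
    return MarkerMap((f"m{i}", "c1", i * 1_000_000) for i in range(1, 6))


def brute_force_refine(
    calls: list[SegregationCall], positions: list[int], prior: tuple[int, int]
) -> list[tuple[int, int]]:
    """Independent per-cell consistency scan used as the refinement oracle.

    Tests every marker-bounded cell against every call: a cell is compatible
    with a segregating line iff it lies inside the line's het interval, and
    with a non-segregating line iff it avoids the open interior of it.
    Adjacent surviving cells are merged.
    """
    cells = [
        (a, b)
        for a, b in zip(positions, positions[1:])
        if a >= prior[0] and b <= prior[1]
    ]
    keep = []
    for a, b in cells:
        compatible = True
        for c in calls:
            if c.verdict == "inconclusive":
                continue
            s, e = c.het_interval
            if c.verdict == "segregating" and not (s <= a and b <= e):
                compatible = False
                break
            if c.verdict == "non_segregating" and not (b <= s or a >= e):
                compatible = False
                break
        if compatible:
            keep.append((a, b))
    merged: list[tuple[int, int]] = []
    for a, b in keep:
        if merged and merged[-1][1] == a:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return [tuple(m) for m in merged]


def random_refine_instance(rng: np.random.Generator):
    """A random small map + segregation-call set with marker-bounded intervals."""
    n_m = int(rng.integers(3, 13))
    positions = np.sort(rng.choice(np.arange(1, 200), size=n_m, replace=False))
    positions = [int(p) for p in positions]
    marker_map = MarkerMap((f"m{i}", "c1", p) for i, p in enumerate(positions))
    n_l = int(rng.integers(1, 21))
    calls = []
    for j in range(n_l):
        i1, i2 = sorted(rng.choice(n_m, size=2, replace=False))
        verdict = "segregating" if rng.random() < 0.5 else "non_segregating"
        calls.append(
            SegregationCall(f"L{j}", (positions[i1], positions[i2]), verdict, 0.5)
        )
    prior = (positions[0], positions[-1])
    return marker_map, positions, calls, prior
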