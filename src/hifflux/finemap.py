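"""Recombinant detection, breakpoint inference, and candidate-interval refinement.

This module carries the computational content of a heterogeneous-inbred-family
(HIF) fine-mapping campaign.  A HIF is the selfed progeny of a recombinant
inbred line that is still heterozygous over one residual genomic region; the
siblings are near-isogenic elsewhere.  Screening the progeny for crossovers
inside the residual region yields recombinant lines (rHIFs) whose heterozygous
intervals tile the region, and testing each rHIF's fixed progeny for
segregation of the phenotype localises the causal locus: the candidate
interval is the part of the region compatible with every segregation verdict.

Coordinates are 1-based base pairs.  Intervals are closed on marker positions
and the width of an interval is ``end - start``.  Breakpoints are never point
estimates: genotyping resolves marker states only, so a crossover is known
only to lie between the two flanking informative markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

ALLELE_CODES = frozenset("ABHU")

#: Lines with more than this fraction of missing (U) calls inside the region
#: are flagged and excluded from interval refinement.
MAX_MISSING_FRACTION = 0.5


class FinemapError(ValueError):
    """Base class for fine-mapping input or consistency errors."""


class InconsistentSegregationError(FinemapError):
    """No part of the prior interval is compatible with every segregation call."""

    def __init__(self, line_ids: Sequence[str]):
        self.line_ids = list(line_ids)
        super().__init__(
            "inconsistent segregation calls: no surviving region "
            f"(lines involved: {', '.join(self.line_ids)})"
        )


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Ordered genomic marker positions.

    Parameters
    ----------
    markers :
        Sequence of ``(marker_id, chromosome, position_bp)`` tuples, ordered
        by position within each chromosome.
    """

    markers: tuple[tuple[str, str, int], ...]

    def __init__(self, markers: Iterable[tuple[str, str, int]]):
        object.__setattr__(self, "markers", tuple(markers))
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        per_chrom: dict[str, list[int]] = {}
        for mid, chrom, pos in self.markers:
            if mid in seen:
                raise FinemapError(f"duplicate marker id {mid!r}")
            seen.add(mid)
            if pos <= 0:
                raise FinemapError(f"marker {mid!r}: position must be positive, got {pos}")
            per_chrom.setdefault(chrom, []).append(pos)
        for chrom, positions in per_chrom.items():
            if len(positions) < 2:
                raise FinemapError(f"chromosome {chrom!r}: at least 2 markers required")
            if any(b <= a for a, b in zip(positions, positions[1:])):
                raise FinemapError(
                    f"chromosome {chrom!r}: positions must be strictly increasing"
                )

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(m[0] for m in self.markers)

    def chromosome(self, chrom: str) -> "MarkerMap":
        sub = [m for m in self.markers if m[1] == chrom]
        if not sub:
            raise FinemapError(f"no markers on chromosome {chrom!r}")
        return MarkerMap(sub)

    def positions(self, chrom: str | None = None) -> np.ndarray:
        if chrom is None:
            chroms = {m[1] for m in self.markers}
            if len(chroms) != 1:
                raise FinemapError("chromosome must be given for a multi-chromosome map")
            (chrom,) = chroms
        return np.array([m[2] for m in self.markers if m[1] == chrom], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.markers)


@dataclass(frozen=True)
class GenotypeTable:
    """Line-by-marker allele calls aligned to a :class:`MarkerMap`.

    Allele codes: ``A`` (first-parent homozygote, e.g. Col-0), ``B``
    (second-parent homozygote, e.g. Ct-1), ``H`` (heterozygote),
    ``U`` (missing).
    """

    line_ids: tuple[str, ...]
    calls: tuple[str, ...]  # one string of allele codes per line
    marker_map: MarkerMap

    def __init__(self, rows: Iterable[tuple[str, str]], marker_map: MarkerMap):
        line_ids, calls = [], []
        n = len(marker_map)
        for line_id, row in rows:
            row = "".join(row)
            if len(row) != n:
                raise FinemapError(
                    f"line {line_id!r}: {len(row)} calls for {n} markers"
                )
            bad = set(row) - ALLELE_CODES
            if bad:
                raise FinemapError(
                    f"line {line_id!r}: invalid allele code(s) {sorted(bad)}"
                )
            line_ids.append(line_id)
            calls.append(row)
        if len(set(line_ids)) != len(line_ids):
            raise FinemapError("duplicate line ids in genotype table")
        object.__setattr__(self, "line_ids", tuple(line_ids))
        object.__setattr__(self, "calls", tuple(calls))
        object.__setattr__(self, "marker_map", marker_map)

    def row(self, line_id: str) -> str:
        return self.calls[self.line_ids.index(line_id)]

    def __len__(self) -> int:
        return len(self.line_ids)


@dataclass(frozen=True)
class Breakpoint:
    """A crossover localised between two flanking informative markers."""

    left_pos: int
    right_pos: int
    left_state: str
    right_state: str

    def __post_init__(self):
        if self.left_pos >= self.right_pos:
            raise FinemapError("breakpoint bounds must satisfy left < right")
        if self.left_state == self.right_state:
            raise FinemapError("breakpoint states must differ")

    @property
    def width(self) -> int:
        return self.right_pos - self.left_pos


@dataclass(frozen=True)
class BreakpointSet:
    line_id: str
    breakpoints: tuple[Breakpoint, ...]

    def __len__(self) -> int:
        return len(self.breakpoints)


@dataclass(frozen=True)
class SegregationCall:
    """Verdict of a (fixed-)progeny test over a line's heterozygous interval."""

    line_id: str
    het_interval: tuple[int, int]
    verdict: str  # segregating | non_segregating | inconclusive
    p_value: float
    method: str = "fixed_progeny"  # fixed_progeny | progeny

    def __post_init__(self):
        if self.verdict not in {"segregating", "non_segregating", "inconclusive"}:
            raise FinemapError(f"unknown verdict {self.verdict!r}")
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise FinemapError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateInterval:
    """A marker-bounded genomic interval compatible with the segregation calls."""

    chromosome: str
    start_bp: int
    end_bp: int
    supporting: tuple[str, ...] = ()
    conflicts: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start_bp >= self.end_bp:
            raise FinemapError("candidate interval requires start < end")

    @property
    def width_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# breakpoint inference
# ---------------------------------------------------------------------------


def _region_slice(positions: np.ndarray, region: tuple[int, int]) -> slice:
    start, end = region
    if start >= end:
        raise FinemapError("region requires start < end")
    lo = int(np.searchsorted(positions, start, side="left"))
    hi = int(np.searchsorted(positions, end, side="right"))
    return slice(lo, hi)


def infer_breakpoints(
    line_id: str,
    calls: str,
    marker_map: MarkerMap,
    region: tuple[int, int] | None = None,
) -> BreakpointSet:
    """Locate every state transition between consecutive informative markers.

    Missing (``U``) calls are uninformative and widen the breakpoint bounds to
    the nearest informative markers on either side.  A row with no informative
    marker in the region is an error.
    """
    positions = marker_map.positions()
    if len(calls) != len(positions):
        raise FinemapError(
            f"line {line_id!r}: {len(calls)} calls for {len(positions)} markers"
        )
    sl = _region_slice(positions, region) if region is not None else slice(None)
    pos = positions[sl]
    row = calls[sl]

    informative = [(p, c) for p, c in zip(pos, row) if c != "U"]
    if not informative:
        raise FinemapError(f"line {line_id!r}: no informative markers in region")

    breakpoints = []
    for (lp, lc), (rp, rc) in zip(informative, informative[1:]):
        if lc != rc:
            breakpoints.append(Breakpoint(int(lp), int(rp), lc, rc))
    return BreakpointSet(line_id, tuple(breakpoints))


def detect_recombinants(
    table: GenotypeTable,
    region: tuple[int, int] | None = None,
) -> list[str]:
    """Return the lines carrying at least one state transition inside ``region``.

    A line uniformly heterozygous (or uniformly fixed) across the region has no
    transition and is not a recombinant.  All-missing lines are uninformative
    and skipped.
    """
    out = []
    for line_id, calls in zip(table.line_ids, table.calls):
        try:
            bps = infer_breakpoints(line_id, calls, table.marker_map, region)
        except FinemapError:
            continue  # no informative markers: cannot witness a crossover
        if len(bps):
            out.append(line_id)
    return out


def het_interval(
    line_id: str,
    calls: str,
    marker_map: MarkerMap,
    region: tuple[int, int] | None = None,
    widen: bool = False,
) -> tuple[int, int] | None:
    """Span of heterozygous calls for a line, or ``None`` if it has none.

    With ``widen=False`` the interval runs from the first to the last H-called
    marker (the region that is *certainly* heterozygous).  With ``widen=True``
    it is extended outward to the nearest informative non-H markers (or region
    bounds), covering the breakpoint uncertainty gaps: the region that *may*
    be heterozygous.  Segregation logic subtracts inner intervals but
    intersects widened ones, so that a causal site lying inside an uncertainty
    gap is never excluded.
    """
    positions = marker_map.positions()
    sl = _region_slice(positions, region) if region is not None else slice(None)
    pos = positions[sl]
    row = calls[sl]
    h_idx = [i for i, c in enumerate(row) if c == "H"]
    if not h_idx:
        return None
    first, last = h_idx[0], h_idx[-1]
    if not widen:
        return int(pos[first]), int(pos[last])
    left = first
    for i in range(first - 1, -1, -1):
        if row[i] != "U":
            left = i
            break
    else:
        left = 0
    right = last
    for i in range(last + 1, len(row)):
        if row[i] != "U":
            right = i
            break
    else:
        right = len(row) - 1
    return int(pos[left]), int(pos[right])


def missing_fraction(calls: str, marker_map: MarkerMap, region: tuple[int, int] | None = None) -> float:
    positions = marker_map.positions()
    sl = _region_slice(positions, region) if region is not None else slice(None)
    row = calls[sl]
    return row.count("U") / len(row) if row else 1.0


# ---------------------------------------------------------------------------
# progeny testing
# ---------------------------------------------------------------------------


def progeny_test(
    line_id: str,
    group_a: Sequence[float],
    group_b: Sequence[float],
    het_interval: tuple[int, int],
    alpha: float = 0.05,
    method: str = "fixed_progeny",
) -> SegregationCall:
    """Welch two-sample t test between progeny fixed for alternative alleles.

    ``segregating`` if p < alpha, ``non_segregating`` otherwise,
    ``inconclusive`` if either group has fewer than two values.
    """
    if not (0.0 < alpha < 1.0):
        raise FinemapError("alpha must lie in (0, 1)")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise FinemapError(f"line {line_id!r}: empty phenotype group")
    if a.size < 2 or b.size < 2:
        return SegregationCall(line_id, het_interval, "inconclusive", float("nan"), method)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # Welch statistic is 0/0 for two zero-variance groups
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    verdict = "segregating" if p < alpha else "non_segregating"
    return SegregationCall(line_id, het_interval, verdict, p, method)


# ---------------------------------------------------------------------------
# candidate-interval refinement (strict interval algebra)
# ---------------------------------------------------------------------------


def _snap_outward(interval: tuple[int, int], positions: np.ndarray) -> tuple[int, int]:
    """Widen interval bounds to the nearest flanking marker positions."""
    start, end = interval
    lo = int(np.searchsorted(positions, start, side="right")) - 1
    hi = int(np.searchsorted(positions, end, side="left"))
    lo = max(lo, 0)
    hi = min(hi, len(positions) - 1)
    return int(positions[lo]), int(positions[hi])


def _intersect(pieces: list[tuple[int, int]], other: tuple[int, int]) -> list[tuple[int, int]]:
    s, e = other
    out = []
    for a, b in pieces:
        lo, hi = max(a, s), min(b, e)
        if lo <= hi:
            out.append((lo, hi))
    return out


def _subtract_open(pieces: list[tuple[int, int]], other: tuple[int, int]) -> list[tuple[int, int]]:
    """Remove the open interior ``(s, e)`` so shared bound markers survive."""
    s, e = other
    out = []
    for a, b in pieces:
        if b <= s or a >= e:
            out.append((a, b))
            continue
        if a <= s:
            out.append((a, s))
        if b >= e:
            out.append((e, b))
    return out


def refine_candidate_interval(
    calls: Sequence[SegregationCall],
    marker_map: MarkerMap,
    prior: tuple[int, int],
    chromosome: str | None = None,
) -> list[CandidateInterval]:
    """Intersect/subtract segregation constraints over the prior interval.

    The surviving region is ``prior ∩ (∩ het intervals of segregating lines)``
    minus the union of the *open interiors* of the het intervals of
    non-segregating lines, snapped outward to marker positions.  Inconclusive
    calls are ignored.  If subtraction splits the region, every disjoint
    surviving interval is returned.  Zero-width remnants (a single marker
    position) are dropped: the candidate is resolved at the granularity of
    marker-bounded cells.

    Raises
    ------
    InconsistentSegregationError
        If nothing survives — at least one segregation call must be wrong.
    """
    if not calls:
        raise FinemapError("at least one segregation call is required")
    if chromosome is None:
        chroms = {m[1] for m in marker_map.markers}
        if len(chroms) != 1:
            raise FinemapError("chromosome must be given for a multi-chromosome map")
        (chromosome,) = chroms
    cmap = marker_map.chromosome(chromosome)
    positions = cmap.positions()

    pieces = [_snap_outward(prior, positions)]
    for call in calls:
        if call.verdict == "inconclusive":
            continue
        iv = _snap_outward(call.het_interval, positions)
        if call.verdict == "segregating":
            pieces = _intersect(pieces, iv)
        else:
            pieces = _subtract_open(pieces, iv)

    pieces = [(a, b) for a, b in pieces if b > a]
    if not pieces:
        raise InconsistentSegregationError([c.line_id for c in calls if c.verdict != "inconclusive"])

    # merge touching pieces (subtraction can leave abutting fragments)
    pieces.sort()
    merged = [pieces[0]]
    for a, b in pieces[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))

    result = []
    for a, b in merged:
        supporting = tuple(
            c.line_id
            for c in calls
            if c.verdict != "inconclusive" and {a, b} & set(_snap_outward(c.het_interval, positions))
        )
        conflicts = tuple(
            c.line_id
            for c in calls
            if c.verdict == "segregating"
            and (c.het_interval[1] < a or c.het_interval[0] > b)
        )
        result.append(CandidateInterval(chromosome, a, b, supporting, conflicts))
    return result


# ---------------------------------------------------------------------------
# evidence-weighted consensus refinement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LineEvidence:
    """Per-line inputs to consensus refinement.

    ``inner``/``outer`` are the certain/possible heterozygous spans of the
    line (see :func:`het_interval`), and ``t_stat`` the Welch t statistic of
    its progeny test.
    """

    line_id: str
    inner: tuple[int, int]
    outer: tuple[int, int]
    t_stat: float


@dataclass(frozen=True)
class ConsensusResult:
    intervals: tuple[CandidateInterval, ...]
    noncentrality: float
    conflicts: tuple[str, ...]


def estimate_noncentrality(t_stats: Sequence[float], min_ncp: float = 4.0) -> float:
    """Estimate the |t| scale of truly segregating lines.

    Campaign t statistics are bimodal: near 0 for non-segregating lines and
    near the test's noncentrality for segregating ones.  The estimate is the
    median of the upper cluster (|t| above half the campaign maximum), floored
    at ``min_ncp`` so the two hypotheses stay separated even in degenerate
    campaigns.
    """
    t = np.abs(np.asarray(t_stats, dtype=float))
    t = t[np.isfinite(t)]
    if t.size == 0:
        return min_ncp
    top = t[t >= 0.5 * t.max()]
    return float(max(np.median(top), min_ncp))


def consensus_refine(
    evidence: Sequence[LineEvidence],
    marker_map: MarkerMap,
    prior: tuple[int, int],
    chromosome: str | None = None,
    noncentrality: float | None = None,
) -> ConsensusResult:
    """Score every marker-bounded cell by segregation-test likelihood.

    For a hypothesised causal cell, each tested line is predicted to be
    segregating (cell inside its certain heterozygous span), non-segregating
    (cell outside its possible span), or uninformative (cell inside a
    breakpoint uncertainty gap).  Each line contributes the Gaussian
    log-likelihood of its observed t statistic under the predicted state
    (mean ``ncp`` if segregating, 0 otherwise); uninformative lines
    contribute the better of the two.  Cells with the maximal total score
    form the candidate region.  Unlike the strict algebra this degrades
    gracefully when a few verdicts are wrong, which real campaigns contain.
    """
    if not evidence:
        raise FinemapError("at least one evidence line is required")
    if chromosome is None:
        chroms = {m[1] for m in marker_map.markers}
        if len(chroms) != 1:
            raise FinemapError("chromosome must be given for a multi-chromosome map")
        (chromosome,) = chroms
    cmap = marker_map.chromosome(chromosome)
    positions = cmap.positions()
    lo, hi = _snap_outward(prior, positions)
    cell_pos = positions[(positions >= lo) & (positions <= hi)]
    if len(cell_pos) < 2:
        raise FinemapError("prior interval spans no marker cell")
    cells = list(zip(cell_pos[:-1], cell_pos[1:]))

    if noncentrality is None:
        noncentrality = estimate_noncentrality([e.t_stat for e in evidence])
    ncp = noncentrality

    scores = np.zeros(len(cells))
    per_line_state = np.empty((len(evidence), len(cells)), dtype=object)
    for i, ev in enumerate(evidence):
        t = abs(ev.t_stat)
        l_seg = -0.5 * (t - ncp) ** 2
        l_non = -0.5 * t**2
        for j, (a, b) in enumerate(cells):
            in_inner = ev.inner[0] <= a and b <= ev.inner[1]
            in_outer = ev.outer[0] <= a and b <= ev.outer[1]
            if in_inner:
                scores[j] += l_seg
                per_line_state[i, j] = "segregating"
            elif in_outer:
                scores[j] += max(l_seg, l_non)
                per_line_state[i, j] = "uninformative"
            else:
                scores[j] += l_non
                per_line_state[i, j] = "non_segregating"

    best = scores.max()
    keep = np.nonzero(scores >= best - 1e-9)[0]

    # lines whose alpha-level verdict contradicts the state implied by every
    # winning cell are reported as conflicts, never silently dropped
    conflicts = []
    for i, ev in enumerate(evidence):
        observed = "segregating" if abs(ev.t_stat) >= 0.5 * ncp else "non_segregating"
        implied = {per_line_state[i, j] for j in keep}
        if "uninformative" not in implied and observed not in implied:
            conflicts.append(ev.line_id)

    pieces = [(int(cells[j][0]), int(cells[j][1])) for j in keep]
    pieces.sort()
    merged = [pieces[0]]
    for a, b in pieces[1:]:
        la, lb = merged[-1]
        if a <= lb:
            merged[-1] = (la, max(lb, b))
        else:
            merged.append((a, b))
    intervals = tuple(
        CandidateInterval(chromosome, a, b, conflicts=tuple(conflicts)) for a, b in merged
    )
    return ConsensusResult(intervals, float(ncp), tuple(conflicts))


# ---------------------------------------------------------------------------
# arHIF pair selection
# ---------------------------------------------------------------------------


def select_arhif_pair(
    lines: Sequence[BreakpointSet],
    target: CandidateInterval,
) -> tuple[str, str]:
    """Pick the rHIF pair whose cross is heterozygous only over ``target``.

    Returns one line recombined immediately north (lower coordinates) and one
    immediately south (higher coordinates) of the target, each with the
    breakpoint interval nearest to the corresponding target bound.  Ties are
    broken by smaller breakpoint-interval width, then lexicographic line id.
    """
    if len(lines) < 2:
        raise FinemapError("at least two candidate lines are required")

    def best(side: str) -> str:
        candidates = []
        for bs in lines:
            for bp in bs.breakpoints:
                if side == "north" and bp.right_pos <= target.start_bp:
                    dist = target.start_bp - bp.right_pos
                elif side == "south" and bp.left_pos >= target.end_bp:
                    dist = bp.left_pos - target.end_bp
                else:
                    continue
                candidates.append((dist, bp.width, bs.line_id))
        if not candidates:
            raise FinemapError(f"no qualifying line {side} of the target interval")
        candidates.sort()
        return candidates[0][2]

    return best("north"), best("south")
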