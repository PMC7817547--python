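"""Leaf-senescence scoring, leaf-rank grouping and chlorophyll-decline onset.

Senescence is scored as the fraction of rosette leaves that have yellowed,
relative to the leaf count at bolting.  Chlorophyll kinetics per leaf rank
rise to a plateau and then decline; the first sustained decline marks the
onset of senescence for that leaf.  An onset before flower-bud emergence is
sequential (age-driven) senescence, an onset at or after it is monocarpic
(reproduction-driven).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Leaf ranks are pooled by tens for elemental analysis.
LEAF_GROUPS = (("OL", 1, 10), ("ML", 11, 20), ("YL", 21, 30), ("NL", 31, None))

#: Default sustained-decline rule: 5 % below the series maximum held for two
#: consecutive observations, robust to single-measurement noise.
DROP_THRESHOLD_DEFAULT = 0.05
K_CONSECUTIVE_DEFAULT = 2


class SenescenceError(ValueError):
    """Invalid senescence-kinetics input."""


@dataclass(frozen=True)
class ChlorophyllSeries:
    """Chlorophyll-index observations for one leaf of one plant."""

    plant_id: str
    leaf_rank: int
    das: tuple[float, ...]
    chl_index: tuple[float, ...]
    flower_bud_das: float

    def __post_init__(self):
        if self.leaf_rank < 1:
            raise SenescenceError("leaf rank must be >= 1")
        if len(self.das) != len(self.chl_index):
            raise SenescenceError("das and chlorophyll arrays differ in length")
        if any(b <= a for a, b in zip(self.das, self.das[1:])):
            raise SenescenceError("das must be strictly increasing")


def senescent_leaf_fraction(n_yellow: int, n_total_at_bolting: int) -> float:
    """Fraction of rosette leaves yellowed, of the leaf count at bolting."""
    if n_total_at_bolting < 1:
        raise SenescenceError("total leaf count at bolting must be >= 1")
    if n_yellow < 0 or n_yellow > n_total_at_bolting:
        raise SenescenceError("yellow leaf count must lie in [0, n_total_at_bolting]")
    return n_yellow / n_total_at_bolting


def assign_leaf_group(rank: int) -> str:
    """OL (ranks 1-10), ML (11-20), YL (21-30) or NL (31 and above)."""
    if rank < 1:
        raise SenescenceError("leaf rank must be >= 1")
    for label, lo, hi in LEAF_GROUPS:
        if rank >= lo and (hi is None or rank <= hi):
            return label
    raise AssertionError("unreachable")  # groups partition all ranks >= 1


def detect_senescence_onset(
    series: ChlorophyllSeries,
    drop_threshold: float = DROP_THRESHOLD_DEFAULT,
    k_consecutive: int = K_CONSECUTIVE_DEFAULT,
) -> tuple[float | None, str]:
    """First sustained chlorophyll decline, and the senescence phase it implies.

    The onset is the first observation after the series maximum at which the
    index has dropped by at least ``drop_threshold`` of the maximum, for
    ``k_consecutive`` successive observations (the onset observation
    included).  Returns ``(onset_das, phase)`` with phase ``sequential`` if
    the onset precedes flower-bud emergence, ``monocarpic`` if not, and
    ``(None, "none")`` if no sustained decline occurs.  The rule depends only
    on relative drops, so it is invariant to rescaling of the index.
    """
    if drop_threshold <= 0:
        raise SenescenceError("drop_threshold must be positive")
    if k_consecutive < 1:
        raise SenescenceError("k_consecutive must be >= 1")
    values = np.asarray(series.chl_index, dtype=float)
    if values.size < 3:
        raise SenescenceError("at least 3 observations are required")
    i_max = int(np.argmax(values))
    cutoff = values[i_max] * (1.0 - drop_threshold)
    below = values <= cutoff
    for j in range(i_max + 1, values.size - k_consecutive + 1):
        if below[j : j + k_consecutive].all():
            onset = float(series.das[j])
            phase = "sequential" if onset < series.flower_bud_das else "monocarpic"
            return onset, phase
    return None, "none"


def onset_table(
    series_set: Sequence[ChlorophyllSeries],
    drop_threshold: float = DROP_THRESHOLD_DEFAULT,
    k_consecutive: int = K_CONSECUTIVE_DEFAULT,
):
    """Onset day and phase for every series, as a tidy DataFrame."""
    import pandas as pd

    rows = []
    for s in series_set:
        onset, phase = detect_senescence_onset(s, drop_threshold, k_consecutive)
        rows.append(
            {
                "plant_id": s.plant_id,
                "leaf_rank": s.leaf_rank,
                "leaf_group": assign_leaf_group(s.leaf_rank),
                "onset_das": onset,
                "phase": phase,
                "flower_bud_das": s.flower_bud_das,
            }
        )
    return pd.DataFrame(rows)
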