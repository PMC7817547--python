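"""Isotope bookkeeping formulas, per-plant indices and genotype contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hifflux.flux import (
    A_CONTROL_DEFAULT,
    FluxError,
    OrganSample,
    PlantPartition,
    atom_percent,
    enrichment,
    flux_summary_table,
    genotype_contrast,
    n_quantities,
    partition_fractions,
    remobilization_efficiency,
    translocation_profile,
    uptake_efficiency,
)


def make_plant(dw, n_pct, a_pct, organs=("rosette", "stem", "seeds"), experiment="remobilization"):
    samples = tuple(
        OrganSample("P1", "g", organ, dw[i], n_pct[i], a_pct[i])
        for i, organ in enumerate(organs)
    )
    return PlantPartition("P1", experiment, samples)


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n15, n14, expected",
    [(1, 99, 1.0), (0, 5, 0.0), (0.366, 99.634, 0.366)],
)
def test_atom_percent(n15, n14, expected):
    assert atom_percent(n15, n14) == pytest.approx(expected)


def test_atom_percent_zero_signals_error():
    with pytest.raises(FluxError):
        atom_percent(0, 0)


@pytest.mark.parametrize(
    "a_sample, expected",
    [(0.3660, 0.0), (0.4660, 0.001), (10.0, 0.09634)],
)
def test_enrichment(a_sample, expected):
    e, flagged = enrichment(a_sample, 0.3660)
    assert e == pytest.approx(expected, abs=1e-12)
    assert not flagged


def test_enrichment_below_control_clipped_and_flagged():
    e, flagged = enrichment(0.36595, 0.3660)  # within tolerance: noise
    assert e == 0.0 and not flagged
    e, flagged = enrichment(0.3000, 0.3660)  # beyond tolerance: flagged
    assert e == 0.0 and flagged


@pytest.mark.parametrize(
    "dw, n_pct, e, expected",
    [
        (100, 5, 0.0, (5.0, 0.0)),
        (200, 4, 0.001, (8.0, 0.008)),
        (100, 0, 0.0, (0.0, 0.0)),
    ],
)
def test_n_quantities(dw, n_pct, e, expected):
    assert n_quantities(dw, n_pct, e) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# per-plant indices
# ---------------------------------------------------------------------------


def test_partition_fractions_symmetric_plant():
    a = A_CONTROL_DEFAULT + 1.0  # equal excess everywhere
    plant = make_plant([100, 100, 100], [2, 2, 2], [a, a, a])
    s = partition_fractions(plant)
    assert s.hi == pytest.approx(1 / 3)
    for frac in list(s.n_alloc.values()) + list(s.n15_alloc.values()):
        assert frac == pytest.approx(1 / 3)
    assert s.nre == pytest.approx(1.0)


def test_partition_fractions_harvest_index():
    a = A_CONTROL_DEFAULT + 0.5
    plant = make_plant([50, 30, 20], [2, 2, 2], [a, a, a])
    assert partition_fractions(plant).hi == pytest.approx(0.2)


def test_partition_fractions_zero_tracer_flagged_not_nan():
    a = A_CONTROL_DEFAULT
    plant = make_plant([50, 30, 20], [2, 2, 2], [a, a, a])
    s = partition_fractions(plant)
    assert s.n15_alloc is None and s.nhi15 is None and s.nre is None
    assert any("undefined" in f for f in s.flags)


def test_remobilization_organ_set_is_enforced():
    with pytest.raises(FluxError, match="rosette, stem and seeds"):
        make_plant([1, 1], [1, 1], [1, 1], organs=("rosette", "stem"))


def test_remobilization_efficiency():
    assert remobilization_efficiency(0.3, 0.3) == pytest.approx(1.0)
    assert remobilization_efficiency(0.6, 0.3) == pytest.approx(2.0)
    with pytest.raises(FluxError):
        remobilization_efficiency(0.5, 0.0)


def test_uptake_efficiency_and_scale_invariance():
    qty15 = {"root": 0.1, "rosette": 0.2, "seeds": 0.2}
    assert uptake_efficiency(qty15, 0.10, 1000.0) == pytest.approx(0.005)  # mg/mg
    doubled = {k: 2 * v for k, v in qty15.items()}
    assert uptake_efficiency(doubled, 0.10, 2000.0) == pytest.approx(0.005)
    assert uptake_efficiency({"root": 0.0}, 0.10, 1000.0) == 0.0
    with pytest.raises(FluxError):
        uptake_efficiency(qty15, 0.0, 1000.0)


def test_translocation_profile():
    a0 = A_CONTROL_DEFAULT
    organs = ("root", "rosette", "stem", "silique")
    plant = make_plant(
        [100, 100, 100, 100], [2, 2, 2, 2], [a0 + 1, a0, a0, a0],
        organs=organs, experiment="uptake_postflowering",
    )
    profile = translocation_profile(plant)
    assert profile["root"] == pytest.approx(1.0)
    assert sum(profile.values()) == pytest.approx(1.0)

    plant = make_plant(
        [100, 100, 100, 100], [2, 2, 2, 2], [a0 + 1] * 4,
        organs=organs, experiment="uptake_postflowering",
    )
    assert all(v == pytest.approx(0.25) for v in translocation_profile(plant).values())

    plant = make_plant(
        [100, 100, 100, 100], [2, 2, 2, 2], [a0] * 4,
        organs=organs, experiment="uptake_postflowering",
    )
    assert translocation_profile(plant) is None


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

organ_triplet = st.tuples(
    st.floats(1.0, 1000.0), st.floats(0.1, 10.0), st.floats(0.3660, 5.0)
)


@settings(max_examples=100, deadline=None)
@given(st.lists(organ_triplet, min_size=3, max_size=3), st.floats(0.01, 100.0))
def test_conservation_and_scale_invariance(triplets, c):
    """Allocations sum to 1, tracer never exceeds total N, and every index is
    invariant under proportional scaling of the organ dry weights."""
    dw = [t[0] for t in triplets]
    n_pct = [t[1] for t in triplets]
    a_pct = [t[2] for t in triplets]
    s = partition_fractions(make_plant(dw, n_pct, a_pct))
    assert sum(s.n_alloc.values()) == pytest.approx(1.0, abs=1e-9)
    if s.n15_alloc is not None:
        assert sum(s.n15_alloc.values()) == pytest.approx(1.0, abs=1e-9)

    scaled = partition_fractions(make_plant([c * x for x in dw], n_pct, a_pct))
    assert scaled.hi == pytest.approx(s.hi)
    assert scaled.nhi == pytest.approx(s.nhi)
    if s.nre is not None:
        assert scaled.nre == pytest.approx(s.nre)


# ---------------------------------------------------------------------------
# genotype contrasts
# ---------------------------------------------------------------------------


def test_contrast_identical_values_share_one_letter():
    df = pd.DataFrame(
        {"genotype": ["a"] * 4 + ["b"] * 4, "experiment": ["e1"] * 8, "value": 1.0}
    )
    gc = genotype_contrast(df)
    letters = set(gc.tukey_letters.values())
    assert letters == {"a"}


def test_contrast_separated_groups_get_distinct_letters():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(
        {
            "genotype": ["g1"] * 10 + ["g2"] * 10,
            "experiment": ["e1"] * 20,
            "value": np.r_[rng.normal(1.0, 0.01, 10), rng.normal(2.0, 0.01, 10)],
        }
    )
    gc = genotype_contrast(df)
    assert gc.tukey_letters["g1"] != gc.tukey_letters["g2"]
    assert gc.pairwise_p.loc["g1", "g2"] < 1e-6


def test_contrast_lsmeans_remove_pure_batch_effect():
    """Balanced two-batch design with a pure batch shift: the adjusted
    genotype means coincide."""
    base = {"g1": 5.0, "g2": 5.0}
    rows = []
    for g in base:
        for b, shift in (("e1", 0.0), ("e2", 3.0)):
            for r in range(6):
                rows.append({"genotype": g, "experiment": b, "value": base[g] + shift + 0.01 * r})
    gc = genotype_contrast(pd.DataFrame(rows))
    assert gc.lsmeans["g1"] == pytest.approx(gc.lsmeans["g2"], abs=1e-9)


def test_contrast_singular_design_is_an_error():
    df = pd.DataFrame({"genotype": ["a"] * 4, "experiment": ["e1"] * 4, "value": 1.0})
    with pytest.raises(FluxError):
        genotype_contrast(df)


def test_flux_summary_table_remobilization_columns():
    from hifflux.simulate import SimConfig, simulate_labeling_dataset

    samples, truth = simulate_labeling_dataset(SimConfig(seed=4))
    summary = flux_summary_table(samples, "remobilization")
    assert {"hi", "nhi", "nhi15", "nre"} <= set(summary.columns)
    assert len(summary) == truth.shape[0]
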