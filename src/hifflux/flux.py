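"""¹⁵N tracer bookkeeping: abundance → enrichment → N quantities → flux indices.

A pulse of ¹⁵N-labelled nitrate is applied for 24 h, and at harvest each organ
is weighed and analysed for total N (percent of dry weight) and ¹⁵N atom
percent.  From those three measurements per organ the module computes, per
plant:

* ``HI``      harvest index, seed dry weight over total dry weight
* ``n_alloc`` fraction of total plant N in each organ (seed fraction = NHI)
* ``n15_alloc`` fraction of tracer ¹⁵N in each organ (seed fraction = ¹⁵NHI)
* ``NRE``     nitrogen remobilization efficiency, ¹⁵NHI / HI
* ``NUpE``    nitrogen uptake efficiency, N absorbed during the pulse per
              unit plant biomass (uptake experiments only)

Internal units are mg for masses and dimensionless fractions for enrichment
and allocations; percents appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: ¹⁵N natural abundance of unlabelled plant material, atom percent.
A_CONTROL_DEFAULT = 0.3660

#: Enrichment of the labelling solution as an atom fraction: a 10 % ¹⁵N
#: solution minus the natural background.
E_SOLUTION_DEFAULT = (10.0 - A_CONTROL_DEFAULT) / 100.0

#: Samples whose atom percent falls below the control by more than this
#: tolerance are flagged; smaller deficits are clipped to zero enrichment.
NEGATIVE_ENRICHMENT_TOL = 1e-4

REMOBILIZATION_ORGANS = frozenset({"rosette", "stem", "seeds"})

#: In post-flowering uptake harvests the seed compartment is the silique.
ORGAN_ALIASES = {"silique": "silique", "seeds": "seeds"}


class FluxError(ValueError):
    """Invalid isotope-flux input."""


@dataclass(frozen=True)
class OrganSample:
    plant_id: str
    genotype: str
    organ: str
    dw_mg: float
    n_pct: float
    a_pct: float

    def __post_init__(self):
        if self.dw_mg <= 0:
            raise FluxError(f"{self.plant_id}/{self.organ}: dry weight must be > 0")
        if not (0.0 <= self.n_pct <= 100.0):
            raise FluxError(f"{self.plant_id}/{self.organ}: N% must lie in [0, 100]")
        if not (0.0 <= self.a_pct <= 100.0):
            raise FluxError(f"{self.plant_id}/{self.organ}: atom percent must lie in [0, 100]")


@dataclass(frozen=True)
class PlantPartition:
    """The organ set of one harvested plant."""

    plant_id: str
    experiment: str  # remobilization | uptake_vegetative | uptake_postflowering
    organs: tuple[OrganSample, ...]
    a_control: float = A_CONTROL_DEFAULT

    def __post_init__(self):
        if self.a_control <= 0:
            raise FluxError("a_control must be positive")
        names = [o.organ for o in self.organs]
        if len(set(names)) != len(names):
            raise FluxError(f"plant {self.plant_id}: duplicate organ sample")
        if self.experiment == "remobilization" and set(names) != REMOBILIZATION_ORGANS:
            # roots are lost in the sand at harvest and are deliberately absent
            raise FluxError(
                f"plant {self.plant_id}: remobilization harvest requires exactly "
                f"rosette, stem and seeds (got {sorted(names)})"
            )

    def organ(self, name: str) -> OrganSample:
        for o in self.organs:
            if o.organ == name:
                return o
        raise FluxError(f"plant {self.plant_id}: no organ {name!r}")


@dataclass(frozen=True)
class FluxSummary:
    plant_id: str
    hi: float
    n_alloc: Mapping[str, float]
    n15_alloc: Mapping[str, float] | None
    nhi: float
    nhi15: float | None
    nre: float | None
    nupe: float | None = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# elementary quantities
# ---------------------------------------------------------------------------


def atom_percent(n15_signal: float, n14_signal: float) -> float:
    """A% = 100 × ¹⁵N / (¹⁵N + ¹⁴N)."""
    if n15_signal < 0 or n14_signal < 0:
        raise FluxError("isotope signals must be non-negative")
    total = n15_signal + n14_signal
    if total == 0:
        raise FluxError("both isotope signals are zero")
    return 100.0 * n15_signal / total


def enrichment(
    a_sample: float,
    a_control: float = A_CONTROL_DEFAULT,
    tol: float = NEGATIVE_ENRICHMENT_TOL,
) -> tuple[float, bool]:
    """E = (A%sample − A%control) / 100, as an atom fraction.

    Returns ``(E, flagged)``.  Deficits below the control within ``tol`` atom
    percent are instrument noise and clipped to zero; larger deficits are
    clipped but flagged.
    """
    for name, v in (("a_sample", a_sample), ("a_control", a_control)):
        if not (0.0 <= v <= 100.0):
            raise FluxError(f"{name} must lie in [0, 100]")
    e = (a_sample - a_control) / 100.0
    if e >= 0.0:
        return e, False
    return 0.0, a_control - a_sample > tol


def n_quantities(dw_mg: float, n_pct: float, e: float) -> tuple[float, float]:
    """QtyN = DW × N% and Qty¹⁵N = DW × E × N%, in mg.

    ``e`` is the enrichment as an atom fraction, so Qty¹⁵N ≤ QtyN always.
    """
    if dw_mg < 0 or n_pct < 0 or e < 0:
        raise FluxError("dry weight, N% and enrichment must be non-negative")
    qty_n = dw_mg * n_pct / 100.0
    return qty_n, qty_n * e


def organ_quantities(
    plant: PlantPartition,
) -> tuple[dict[str, float], dict[str, float], dict[str, float], list[str]]:
    """Per-organ (DW, QtyN, Qty¹⁵N) for a plant, with enrichment flags."""
    dw, qty_n, qty_15 = {}, {}, {}
    flags = []
    for o in plant.organs:
        e, flagged = enrichment(o.a_pct, plant.a_control)
        if flagged:
            flags.append(f"{o.organ}: atom percent below control")
        qn, q15 = n_quantities(o.dw_mg, o.n_pct, e)
        dw[o.organ] = o.dw_mg
        qty_n[o.organ] = qn
        qty_15[o.organ] = q15
    return dw, qty_n, qty_15, flags


# ---------------------------------------------------------------------------
# per-plant indices
# ---------------------------------------------------------------------------


def partition_fractions(plant: PlantPartition) -> FluxSummary:
    """HI, N and ¹⁵N allocation fractions, NHI and ¹⁵NHI for one plant.

    When the plant carries no tracer (all enrichments zero) the ¹⁵N
    allocations, ¹⁵NHI and NRE are undefined: they are returned as ``None``
    with a flag rather than propagating NaN.
    """
    dw, qty_n, qty_15, flags = organ_quantities(plant)
    total_dw = sum(dw.values())
    seed_organ = "seeds" if "seeds" in dw else ("silique" if "silique" in dw else None)
    if seed_organ is None:
        raise FluxError(f"plant {plant.plant_id}: no seed/silique compartment")
    hi = dw[seed_organ] / total_dw

    total_n = sum(qty_n.values())
    if total_n == 0:
        raise FluxError(f"plant {plant.plant_id}: total N quantity is zero")
    n_alloc = {k: v / total_n for k, v in qty_n.items()}
    nhi = n_alloc[seed_organ]

    total_15 = sum(qty_15.values())
    if total_15 == 0:
        flags = flags + ["no tracer recovered: 15N allocation undefined"]
        return FluxSummary(plant.plant_id, hi, n_alloc, None, nhi, None, None, flags=tuple(flags))

    n15_alloc = {k: v / total_15 for k, v in qty_15.items()}
    nhi15 = n15_alloc[seed_organ]
    nre = remobilization_efficiency(nhi15, hi)
    return FluxSummary(plant.plant_id, hi, n_alloc, n15_alloc, nhi, nhi15, nre, flags=tuple(flags))


def remobilization_efficiency(nhi15: float, hi: float) -> float:
    """NRE = ¹⁵NHI / HI — tracer routing to seeds relative to biomass routing.

    Dimensionless and may exceed 1 (seeds receive proportionally more of the
    remobilized tracer than of the biomass).
    """
    if hi <= 0:
        raise FluxError("HI must be positive to compute NRE")
    return nhi15 / hi


def uptake_efficiency(
    qty15_by_organ: Mapping[str, float],
    e_solution: float,
    total_dw_mg: float,
) -> float:
    """NUpE: total N absorbed during the 24-h pulse per unit plant biomass.

    ``(Σ organ Qty¹⁵N / E_solution) / total DW`` where ``e_solution`` is the
    enrichment of the labelling solution as an atom fraction.  With masses in
    mg the result is mg N per mg DW per 24 h; callers typically rescale to
    mg N g⁻¹ DW.
    """
    if e_solution <= 0:
        raise FluxError("labelling-solution enrichment must be positive")
    if total_dw_mg <= 0:
        raise FluxError("total dry weight must be positive")
    return (sum(qty15_by_organ.values()) / e_solution) / total_dw_mg


def translocation_profile(plant: PlantPartition) -> dict[str, float] | None:
    """Per-organ share of the absorbed tracer (root included); sums to 1.

    Returns ``None`` (undefined) if no tracer was recovered.
    """
    if len(plant.organs) < 2:
        raise FluxError(f"plant {plant.plant_id}: at least 2 organs required")
    _, _, qty_15, _ = organ_quantities(plant)
    total = sum(qty_15.values())
    if total == 0:
        return None
    return {k: v / total for k, v in qty_15.items()}


# ---------------------------------------------------------------------------
# table-level summaries
# ---------------------------------------------------------------------------


def plants_from_table(
    samples: pd.DataFrame,
    experiment: str,
    a_control: float | None = None,
) -> list[tuple[str, PlantPartition]]:
    """Group an organ-sample table into per-plant partitions.

    ``samples`` columns: plant_id, genotype, experiment, organ, dw_mg, n_pct,
    a15n_pct.  Rows with ``experiment == "control"`` are unlabelled controls:
    their mean atom percent overrides the default natural-abundance constant
    unless ``a_control`` is given explicitly.
    """
    controls = samples[samples["experiment"] == "control"]
    if a_control is None:
        a_control = float(controls["a15n_pct"].mean()) if len(controls) else A_CONTROL_DEFAULT
    sub = samples[samples["experiment"] == experiment]
    if sub.empty:
        raise FluxError(f"no samples for experiment {experiment!r}")
    out = []
    for (plant_id, genotype), grp in sub.groupby(["plant_id", "genotype"], sort=False):
        organs = tuple(
            OrganSample(str(plant_id), str(genotype), str(r.organ), float(r.dw_mg), float(r.n_pct), float(r.a15n_pct))
            for r in grp.itertuples()
        )
        out.append((str(genotype), PlantPartition(str(plant_id), experiment, organs, a_control)))
    return out


def flux_summary_table(
    samples: pd.DataFrame,
    experiment: str,
    a_control: float | None = None,
    e_solution: float = E_SOLUTION_DEFAULT,
) -> pd.DataFrame:
    """Per-plant flux summary for one experiment, as a tidy DataFrame.

    For uptake experiments NUpE (mg N g⁻¹ DW per 24-h pulse) and per-organ
    tracer shares are included; for the remobilization experiment NRE is.
    """
    rows = []
    for genotype, plant in plants_from_table(samples, experiment, a_control):
        summary = partition_fractions(plant)
        dw, _, qty_15, _ = organ_quantities(plant)
        row = {
            "plant_id": plant.plant_id,
            "genotype": genotype,
            "experiment": experiment,
            "hi": summary.hi,
            "nhi": summary.nhi,
            "nhi15": summary.nhi15,
            "nre": summary.nre,
            "flags": ";".join(summary.flags),
        }
        for organ, frac in summary.n_alloc.items():
            row[f"n_alloc_{organ}"] = frac
        if summary.n15_alloc is not None:
            for organ, frac in summary.n15_alloc.items():
                row[f"n15_alloc_{organ}"] = frac
        if experiment.startswith("uptake"):
            total_dw = sum(dw.values())
            # NUpE rescaled from mg/mg to the conventional mg N per g DW
            row["nupe"] = uptake_efficiency(qty_15, e_solution, total_dw) * 1000.0
            profile = translocation_profile(plant)
            if profile is not None:
                for organ, frac in profile.items():
                    row[f"transloc_{organ}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotype contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenotypeContrast:
    anova: pd.DataFrame
    group_means: pd.Series
    lsmeans: pd.Series
    tukey_letters: Mapping[str, str]
    pairwise_p: pd.DataFrame


def _letter_display(groups: Sequence[str], different: set[frozenset]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Letters tag the maximal cliques of the "not significantly different"
    graph, ordered along the given group order (typically by descending
    mean).  Group counts are small, so cliques are enumerated directly.
    """
    n = len(groups)
    compatible = lambda c: all(
        frozenset((groups[i], groups[j])) not in different for i, j in combinations(c, 2)
    )
    cliques: list[tuple[int, ...]] = []
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            if compatible(combo) and not any(set(combo) <= set(c) for c in cliques):
                cliques.append(combo)
    cliques.sort(key=lambda c: c[0])
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for i in clique:
            letters[groups[i]] += letter
    return letters


def genotype_contrast(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "genotype",
    batch: str = "experiment",
    alpha: float = 0.05,
) -> GenotypeContrast:
    """ANOVA, Tukey HSD letters, pairwise Welch t and least-square means.

    Least-square means adjust genotype means for the experiment batch by
    averaging additive-model predictions over the batch levels, so a pure
    batch effect in a balanced design leaves the genotype contrast untouched.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = data.rename(columns={value: "_y", group: "_g", batch: "_b"} if batch in data else {value: "_y", group: "_g"})
    groups = df["_g"].astype(str)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise FluxError("at least two genotype groups are required")
    if groups.value_counts().min() < 2:
        raise FluxError("at least two replicates per group are required")

    has_batch = "_b" in df and df["_b"].nunique() > 1
    formula = "_y ~ C(_g) + C(_b)" if has_batch else "_y ~ C(_g)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    group_means = df.groupby("_g")["_y"].mean().rename("mean")

    if has_batch:
        batches = df["_b"].unique()
        grid = pd.DataFrame(
            [(g, b) for g in levels for b in batches], columns=["_g", "_b"]
        )
        pred = model.predict(grid)
        lsmeans = pd.Series(
            [pred[grid["_g"] == g].mean() for g in levels], index=levels, name="lsmean"
        )
    else:
        lsmeans = group_means.reindex(levels).rename("lsmean")

    if df["_y"].var(ddof=1) == 0.0:
        # identical values everywhere: nothing distinguishes the groups
        different: set[frozenset] = set()
    else:
        tukey = pairwise_tukeyhsd(df["_y"], groups, alpha=alpha)
        different = {
            frozenset((str(a), str(b)))
            for (a, b), rej in zip(
                combinations(tukey.groupsunique, 2), tukey.reject
            )
            if rej
        }
    ordered = list(group_means.sort_values(ascending=False).index)
    letters = _letter_display(ordered, different)

    pmat = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    for a, b in combinations(levels, 2):
        va = df.loc[groups == a, "_y"]
        vb = df.loc[groups == b, "_y"]
        if va.var(ddof=1) == 0.0 and vb.var(ddof=1) == 0.0:
            p = 1.0 if va.mean() == vb.mean() else 0.0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        pmat.loc[a, b] = pmat.loc[b, a] = p

    return GenotypeContrast(anova, group_means, lsmeans, letters, pmat)
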