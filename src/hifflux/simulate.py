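"""Forward generators for both experimental designs, with known ground truth.

Two designs are emulated so that every analysis stage can be checked by
parameter recovery:

* a **fine-mapping campaign**: selfed progeny of a line heterozygous over one
  residual region, with crossovers drawn per gamete under the Haldane map
  function (no interference), a biallelic causal locus with an additive
  phenotype effect plus Gaussian noise, and fixed-progeny testing of each
  recombinant;
* a **¹⁵N labelling harvest**: per-plant organ dry weights (lognormal),
  tracer split across organs by Dirichlet-perturbed shares, and organ atom
  percents back-computed from the tracer quantities so that the flux formulas
  are exact inverses of the generator at zero noise; multiplicative
  measurement noise is applied last.

Default parameter values follow the emulated study conditions: 276 progeny
screened over a 5.9-Mb region of chromosome 4 (7 180 000–13 079 020 bp), a
10 %-enriched labelling solution against a 0.3660 atom-percent natural
background, and flower-bud emergence at 52 days after sowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .finemap import GenotypeTable, MarkerMap
from .flux import A_CONTROL_DEFAULT, E_SOLUTION_DEFAULT
from .senescence import ChlorophyllSeries


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MapSpec:
    """Evenly spaced markers across the residual heterozygous region."""

    chromosome: str = "chr4"
    region: tuple[int, int] = (7_180_000, 13_079_020)
    n_markers: int = 24
    cm_per_mb: float = 3.0

    def build(self) -> MarkerMap:
        lo, hi = self.region
        if lo >= hi:
            raise SimulationError("region requires start < end")
        if self.n_markers < 2:
            raise SimulationError("at least 2 markers are required")
        positions = np.linspace(lo, hi, self.n_markers).round().astype(np.int64)
        return MarkerMap(
            (f"m{i + 1:02d}", self.chromosome, int(p)) for i, p in enumerate(positions)
        )


@dataclass(frozen=True)
class CampaignSpec:
    """Fine-mapping screen and fixed-progeny phenotype test settings."""

    n_progeny: int = 276
    causal_pos_bp: int = 8_295_000
    baseline: float = 0.2  # senescent-leaf fraction of the A/A class
    effect_size: float = 0.2  # added at full B dosage; B hastens senescence
    noise_sd: float = 0.05
    alpha: float = 0.05
    n_replicates: int = 12  # phenotyped progeny per fixed allele group


@dataclass(frozen=True)
class LabelingSpec:
    """Forward model of one pulse-labelling harvest.

    ``organ_dw_mg`` / ``organ_n_pct`` are genotype-level means; per-plant
    organ dry weights are lognormal around them with coefficient of variation
    ``biological_cv``.  ``tracer_shares`` are the mean per-organ shares of
    the absorbed tracer; per-plant shares are Dirichlet with concentration
    ``share_concentration`` × mean.  ``measurement_cv`` is multiplicative
    lognormal noise applied to dry weight and N% and, scaled by the excess
    atom percent, additively to A%.
    """

    experiment: str = "remobilization"
    n_plants: int = 18
    organ_dw_mg: Mapping[str, float] = field(
        default_factory=lambda: {"rosette": 450.0, "stem": 300.0, "seeds": 250.0}
    )
    organ_n_pct: Mapping[str, float] = field(
        default_factory=lambda: {"rosette": 1.5, "stem": 1.0, "seeds": 4.0}
    )
    tracer_shares: Mapping[str, float] = field(
        default_factory=lambda: {"rosette": 0.3, "stem": 0.2, "seeds": 0.5}
    )
    absorbed_tracer_mg: float = 0.012  # mg 15N excess from the 1-ml 10-mM pulse
    biological_cv: float = 0.10
    share_concentration: float = 200.0
    measurement_cv: float = 0.0
    a_control: float = A_CONTROL_DEFAULT
    e_solution: float = E_SOLUTION_DEFAULT
    n_controls: int = 3

    def __post_init__(self):
        share_sum = sum(self.tracer_shares.values())
        if abs(share_sum - 1.0) > 1e-9:
            raise SimulationError(f"tracer shares must sum to 1 (got {share_sum})")
        if set(self.organ_dw_mg) != set(self.organ_n_pct) or set(self.organ_dw_mg) != set(
            self.tracer_shares
        ):
            raise SimulationError("organ keys must agree across dw, N% and shares")
        if self.biological_cv < 0 or self.measurement_cv < 0:
            raise SimulationError("coefficients of variation must be >= 0")


#: Post-flowering uptake harvest: roots are sampled and the seed compartment
#: is the silique.
UPTAKE_POSTFLOWERING = LabelingSpec(
    experiment="uptake_postflowering",
    n_plants=15,
    organ_dw_mg={"root": 120.0, "rosette": 400.0, "stem": 280.0, "silique": 200.0},
    organ_n_pct={"root": 1.2, "rosette": 2.0, "stem": 1.2, "silique": 3.5},
    tracer_shares={"root": 0.15, "rosette": 0.2, "stem": 0.25, "silique": 0.4},
    absorbed_tracer_mg=0.10,
)


@dataclass(frozen=True)
class ChlorophyllSpec:
    """Piecewise chlorophyll kinetics: logistic rise, plateau, linear decline.

    ``onset_das`` is the first *sampled* day at which the index has declined;
    the plateau runs through the preceding observation.  ``onset_shift_days``
    moves the onset of a second genotype relative to the first.
    """

    leaf_ranks: tuple[int, ...] = (2, 6, 12, 18, 24)
    das_start: float = 20.0
    das_stop: float = 88.0
    das_step: float = 4.0
    flower_bud_das: float = 52.0
    onset_das: float = 56.0
    rank_onset_slope_days: float = 1.0  # later onset for younger leaves
    plateau_base: float = 30.0
    plateau_per_rank: float = 0.6  # chlorophyll rises with leaf rank
    rise_rate: float = 0.12
    rise_lead_days: float = 20.0  # logistic midpoint precedes the onset by this
    decline_per_day: float = 0.03  # fraction of peak lost per day after onset
    noise_sd_frac: float = 0.0  # Gaussian noise, fraction of plateau


@dataclass(frozen=True)
class SimConfig:
    """Complete study configuration with one master seed."""

    seed: int = 0
    map: MapSpec = field(default_factory=MapSpec)
    campaign: CampaignSpec = field(default_factory=CampaignSpec)
    labeling: LabelingSpec = field(default_factory=LabelingSpec)
    chlorophyll: ChlorophyllSpec = field(default_factory=ChlorophyllSpec)


# ---------------------------------------------------------------------------
# meiosis / genotypes
# ---------------------------------------------------------------------------


def haldane_recombination_fraction(d_morgan: np.ndarray | float) -> np.ndarray | float:
    """r = (1 − e^(−2d)) / 2 for a map distance in Morgans (no interference)."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_morgan, dtype=float))) / 2.0


def _interval_rec_fractions(positions: np.ndarray, cm_per_mb: float) -> np.ndarray:
    d_morgan = np.diff(positions) / 1e6 * cm_per_mb / 100.0
    return haldane_recombination_fraction(d_morgan)


def simulate_gametes(
    rng: np.random.Generator, positions: np.ndarray, cm_per_mb: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` gametes from a fully heterozygous parent.

    Returns ``(alleles, crossover_pos)``: an (n, markers) 0/1 allele matrix
    and an (n, intervals) float matrix holding the crossover base-pair
    position drawn uniformly inside each recombined interval (NaN where no
    crossover occurred).  One crossover at most is drawn per marker interval,
    which is adequate at the sub-chromosome scales simulated here.
    """
    r = _interval_rec_fractions(positions, cm_per_mb)
    n_int = len(r)
    start = rng.integers(0, 2, size=n)
    xo = rng.random((n, n_int)) < r
    # allele along the gamete flips at every crossover
    flips = np.concatenate([start[:, None], xo.astype(np.int64)], axis=1)
    alleles = np.cumsum(flips, axis=1) % 2
    left = positions[:-1]
    span = np.diff(positions)
    xo_pos = np.where(xo, left + rng.random((n, n_int)) * span, np.nan)
    return alleles, xo_pos


def simulate_progeny_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Selfed-progeny genotypes over the residual heterozygous region.

    Each progeny receives two independent gametes; marker calls are A/B for
    matching parental homozygotes and H otherwise.  The returned truth table
    records, per line, the exact crossover positions of both gametes and the
    line's true genotype at any position (reconstructable from the gamete
    allele tracks, which are included per marker).
    """
    marker_map = cfg.map.build()
    positions = marker_map.positions()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.campaign.n_progeny

    g1, xo1 = simulate_gametes(rng, positions, cfg.map.cm_per_mb, n)
    g2, xo2 = simulate_gametes(rng, positions, cfg.map.cm_per_mb, n)

    codes = np.where((g1 == 0) & (g2 == 0), "A", np.where((g1 == 1) & (g2 == 1), "B", "H"))
    line_ids = [f"L{i + 1:04d}" for i in range(n)]
    table = GenotypeTable(
        ((lid, "".join(row)) for lid, row in zip(line_ids, codes)), marker_map
    )

    records = []
    for i, lid in enumerate(line_ids):
        for gamete, (alleles, xo) in enumerate(((g1, xo1), (g2, xo2)), start=1):
            for j in np.nonzero(np.isfinite(xo[i]))[0]:
                records.append(
                    {
                        "line_id": lid,
                        "gamete": gamete,
                        "interval_left_bp": int(positions[j]),
                        "interval_right_bp": int(positions[j + 1]),
                        "crossover_bp": float(xo[i, j]),
                    }
                )
    truth = pd.DataFrame(
        records,
        columns=["line_id", "gamete", "interval_left_bp", "interval_right_bp", "crossover_bp"],
    )
    truth.attrs["gamete_alleles"] = (g1, g2)
    return table, truth


def true_dosage_at(
    positions: np.ndarray,
    truth: pd.DataFrame,
    pos_bp: float,
    line_ids: Sequence[str],
) -> np.ndarray:
    """True B-allele dosage (0/1/2) of each line at an arbitrary position.

    Uses the exact crossover positions, so the dosage is well defined even
    between markers.
    """
    g1, g2 = truth.attrs["gamete_alleles"]
    j = int(np.searchsorted(positions, pos_bp, side="right")) - 1
    j = min(max(j, 0), len(positions) - 2)
    base = g1[:, j] + g2[:, j]
    dosage = base.astype(np.int64).copy()
    if len(truth):
        # a crossover between marker j and pos flips that gamete's allele
        sel = truth[
            (truth["interval_left_bp"] == positions[j])
            & (truth["crossover_bp"] <= pos_bp)
        ]
        idx = {lid: i for i, lid in enumerate(line_ids)}
        for r in sel.itertuples():
            i = idx[r.line_id]
            g = g1 if r.gamete == 1 else g2
            dosage[i] += 1 - 2 * g[i, int(np.searchsorted(positions, r.interval_left_bp))]
    return dosage


def simulate_phenotypes(
    dosage: np.ndarray,
    effect_size: float,
    noise_sd: float,
    seed: int,
    baseline: float = 0.0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Additive biallelic phenotype: baseline + effect × dosage/2 + noise."""
    rng = np.random.default_rng(seed)
    dosage = np.asarray(dosage)
    means = baseline + effect_size * dosage / 2.0
    values = rng.normal(means.repeat(n_replicates), noise_sd)
    return pd.DataFrame(
        {
            "unit": np.arange(len(dosage)).repeat(n_replicates),
            "dosage": dosage.repeat(n_replicates),
            "replicate": np.tile(np.arange(n_replicates), len(dosage)),
            "value": values,
        }
    )


# ---------------------------------------------------------------------------
# labelling harvest
# ---------------------------------------------------------------------------


def simulate_labeling_dataset(
    cfg: SimConfig,
    genotype: str = "sim",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Organ-sample table plus per-plant ground-truth flux summary.

    At zero ``measurement_cv`` the analysis pipeline inverts the generator
    exactly: per-organ atom percents are back-computed from the drawn tracer
    quantities, so enrichment → QtyN/Qty¹⁵N → allocations reproduce the drawn
    shares to machine precision.
    """
    spec = cfg.labeling
    rng = np.random.default_rng(cfg.seed)
    organs = list(spec.organ_dw_mg)
    n = spec.n_plants

    mean_dw = np.array([spec.organ_dw_mg[o] for o in organs])
    mean_n = np.array([spec.organ_n_pct[o] for o in organs])
    shares = np.array([spec.tracer_shares[o] for o in organs])

    cv = spec.biological_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        dw = mean_dw * rng.lognormal(-0.5 * sigma**2, sigma, size=(n, len(organs)))
    else:
        dw = np.tile(mean_dw, (n, 1))
    if cv > 0 and spec.share_concentration > 0:
        plant_shares = rng.dirichlet(shares * spec.share_concentration, size=n)
    else:
        plant_shares = np.tile(shares, (n, 1))

    qty_n = dw * mean_n / 100.0
    qty_15 = spec.absorbed_tracer_mg * plant_shares
    e_organ = qty_15 / qty_n
    if (e_organ > spec.e_solution).any():
        raise SimulationError(
            "organ enrichment exceeds the labelling solution; lower absorbed_tracer_mg"
        )
    a_pct = spec.a_control + 100.0 * e_organ

    n_pct = np.tile(mean_n, (n, 1)).astype(float)
    mcv = spec.measurement_cv
    if mcv > 0:
        msig = np.sqrt(np.log1p(mcv**2))
        noise = lambda shape: rng.lognormal(-0.5 * msig**2, msig, size=shape)
        dw_obs = dw * noise(dw.shape)
        n_obs = n_pct * noise(n_pct.shape)
        # additive on A%, scaled by the excess so controls stay near background
        a_obs = spec.a_control + (a_pct - spec.a_control) * noise(a_pct.shape)
    else:
        dw_obs, n_obs, a_obs = dw, n_pct, a_pct

    rows = []
    for i in range(n):
        pid = f"P{i + 1:03d}"
        for j, organ in enumerate(organs):
            rows.append(
                {
                    "plant_id": pid,
                    "genotype": genotype,
                    "experiment": spec.experiment,
                    "organ": organ,
                    "dw_mg": dw_obs[i, j],
                    "n_pct": n_obs[i, j],
                    "a15n_pct": a_obs[i, j],
                }
            )
    for k in range(spec.n_controls):
        rows.append(
            {
                "plant_id": f"C{k + 1:03d}",
                "genotype": genotype,
                "experiment": "control",
                "organ": "rosette",
                "dw_mg": float(mean_dw[0]),
                "n_pct": float(mean_n[0]),
                "a15n_pct": spec.a_control,
            }
        )
    samples = pd.DataFrame(rows)

    seed_organ = "seeds" if "seeds" in organs else "silique"
    si = organs.index(seed_organ)
    total_dw = dw.sum(axis=1)
    hi = dw[:, si] / total_dw
    nhi15 = plant_shares[:, si]
    truth = pd.DataFrame(
        {
            "plant_id": [f"P{i + 1:03d}" for i in range(n)],
            "genotype": genotype,
            "hi": hi,
            "nhi": qty_n[:, si] / qty_n.sum(axis=1),
            "nhi15": nhi15,
            "nre": nhi15 / hi,
            "nupe_mg_per_g": spec.absorbed_tracer_mg / spec.e_solution / total_dw * 1000.0,
        }
    )
    return samples, truth


# ---------------------------------------------------------------------------
# chlorophyll kinetics
# ---------------------------------------------------------------------------


def simulate_chlorophyll_kinetics(
    cfg: SimConfig,
    onset_shift_days: float = 0.0,
    plant_id: str = "sim",
) -> tuple[list[ChlorophyllSeries], pd.DataFrame]:
    """Chlorophyll series per leaf rank, with the programmed onset as truth.

    The curve rises logistically to a rank-dependent plateau and declines
    linearly from the programmed onset (shifted per rank, snapped to the
    sampling grid).  ``onset_shift_days`` displaces every onset, emulating a
    genotype that senesces earlier (negative shift) or later.
    """
    spec = cfg.chlorophyll
    rng = np.random.default_rng(cfg.seed)
    das = np.arange(spec.das_start, spec.das_stop + 1e-9, spec.das_step)
    step = spec.das_step

    series, truth_rows = [], []
    for rank in spec.leaf_ranks:
        plateau = spec.plateau_base + spec.plateau_per_rank * rank
        onset = spec.onset_das + spec.rank_onset_slope_days * rank + onset_shift_days
        onset = spec.das_start + round((onset - spec.das_start) / step) * step
        # the index keeps rising until its own decline starts, so each rank
        # traces the same trajectory shifted in time
        rise = plateau / (1.0 + np.exp(-spec.rise_rate * (das - (onset - spec.rise_lead_days))))
        # first declined sample sits at the programmed onset itself
        drop = np.where(das >= onset, spec.decline_per_day * (das - onset + step), 0.0)
        values = rise * np.clip(1.0 - drop, 0.0, None)
        if spec.noise_sd_frac > 0:
            values = values + rng.normal(0.0, spec.noise_sd_frac * plateau, size=values.shape)
        series.append(
            ChlorophyllSeries(
                plant_id, rank, tuple(das), tuple(values), spec.flower_bud_das
            )
        )
        truth_rows.append({"plant_id": plant_id, "leaf_rank": rank, "onset_das": float(onset)})
    return series, pd.DataFrame(truth_rows)
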