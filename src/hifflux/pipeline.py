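"""End-to-end campaign and labelling pipelines over the core modules.

``run_campaign`` simulates one complete fine-mapping campaign and analyses it
with the same functions a real campaign would use: recombinant screening,
fixed-progeny Welch tests, and evidence-weighted candidate-interval
refinement.  It returns the refined interval together with the simulation
truth, so parameter-recovery rates can be measured directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import finemap as fm
from .finemap import (
    CandidateInterval,
    ConsensusResult,
    LineEvidence,
    MarkerMap,
    SegregationCall,
)
from .simulate import SimConfig, simulate_progeny_genotypes, true_dosage_at


@dataclass(frozen=True)
class CampaignResult:
    intervals: tuple[CandidateInterval, ...]
    causal_pos_bp: int
    causal_inside: bool
    n_recombinants: int
    n_tested: int
    calls: tuple[SegregationCall, ...]
    conflicts: tuple[str, ...]


def run_campaign(cfg: SimConfig) -> CampaignResult:
    """Simulate and analyse one fine-mapping campaign.

    Screens ``cfg.campaign.n_progeny`` selfed progeny for crossovers inside
    the region, runs a fixed-progeny Welch test on every informative
    recombinant (sibling groups fixed for alternative alleles over the
    residual heterozygous interval), and refines the candidate interval by
    per-cell likelihood consensus.
    """
    camp = cfg.campaign
    table, truth = simulate_progeny_genotypes(cfg)
    marker_map = table.marker_map
    positions = marker_map.positions()
    region = cfg.map.region

    recombinants = fm.detect_recombinants(table, region)

    causal = camp.causal_pos_bp
    dosage_all = true_dosage_at(positions, truth, causal, table.line_ids)
    idx = {lid: i for i, lid in enumerate(table.line_ids)}

    rng = np.random.default_rng(np.random.default_rng(cfg.seed).integers(2**31))
    evidence: list[LineEvidence] = []
    calls: list[SegregationCall] = []
    for lid in recombinants:
        row = table.row(lid)
        if fm.missing_fraction(row, marker_map, region) > fm.MAX_MISSING_FRACTION:
            continue
        inner = fm.het_interval(lid, row, marker_map, region, widen=False)
        if inner is None:
            continue  # both gametes recombined: nothing left segregating
        outer = fm.het_interval(lid, row, marker_map, region, widen=True)

        # fixed-progeny groups differ at the causal locus only if the line
        # is truly heterozygous there
        d = dosage_all[idx[lid]]
        mean_a = camp.baseline + camp.effect_size * (0 if d == 1 else d) / 2.0
        mean_b = camp.baseline + camp.effect_size * (2 if d == 1 else d) / 2.0
        group_a = rng.normal(mean_a, camp.noise_sd, camp.n_replicates)
        group_b = rng.normal(mean_b, camp.noise_sd, camp.n_replicates)

        call = fm.progeny_test(lid, group_a, group_b, inner, camp.alpha)
        calls.append(call)
        t = _welch_t(group_a, group_b)
        evidence.append(LineEvidence(lid, inner, outer, t))

    consensus: ConsensusResult = fm.consensus_refine(evidence, marker_map, region)
    inside = any(iv.start_bp <= causal <= iv.end_bp for iv in consensus.intervals)
    return CampaignResult(
        consensus.intervals,
        causal,
        inside,
        len(recombinants),
        len(evidence),
        tuple(calls),
        consensus.conflicts,
    )


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / len(a) + vb / len(b))
    if denom == 0.0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / denom)


def finemap_from_tables(
    marker_map: MarkerMap,
    genotypes: fm.GenotypeTable,
    phenotypes: pd.DataFrame,
    region: tuple[int, int],
    alpha: float = 0.05,
    policy: str = "strict",
) -> tuple[list[CandidateInterval], list[SegregationCall]]:
    """Fine-map from observed tables: genotype screen plus phenotype groups.

    ``phenotypes`` columns: line_id, allele (A/B sibling group), replicate,
    value.  Lines with more than half missing calls in the region are
    excluded.  ``policy`` selects the strict interval algebra or the
    likelihood consensus for the refinement step.
    """
    recombinants = fm.detect_recombinants(genotypes, region)
    calls: list[SegregationCall] = []
    evidence: list[LineEvidence] = []
    for lid in recombinants:
        row = genotypes.row(lid)
        if fm.missing_fraction(row, marker_map, region) > fm.MAX_MISSING_FRACTION:
            continue
        inner = fm.het_interval(lid, row, marker_map, region, widen=False)
        if inner is None:
            continue
        outer = fm.het_interval(lid, row, marker_map, region, widen=True)
        sub = phenotypes[phenotypes["line_id"] == lid]
        if sub.empty:
            continue
        group_a = sub.loc[sub["allele"] == "A", "value"].to_numpy()
        group_b = sub.loc[sub["allele"] == "B", "value"].to_numpy()
        if group_a.size == 0 or group_b.size == 0:
            continue
        call = fm.progeny_test(lid, group_a, group_b, inner, alpha)
        calls.append(call)
        if group_a.size >= 2 and group_b.size >= 2:
            evidence.append(LineEvidence(lid, inner, outer, _welch_t(group_a, group_b)))

    if policy == "strict":
        strict_calls = [
            SegregationCall(
                c.line_id,
                _call_interval(genotypes, marker_map, region, c),
                c.verdict,
                c.p_value,
                c.method,
            )
            for c in calls
        ]
        intervals = fm.refine_candidate_interval(strict_calls, marker_map, region)
    elif policy == "consensus":
        intervals = list(fm.consensus_refine(evidence, marker_map, region).intervals)
    else:
        raise ValueError(f"unknown refinement policy {policy!r}")
    return intervals, calls


def _call_interval(
    genotypes: fm.GenotypeTable,
    marker_map: MarkerMap,
    region: tuple[int, int],
    call: SegregationCall,
) -> tuple[int, int]:
    """Constraint interval for a strict call: widened when segregating.

    A segregating line constrains the causal site to its *possible*
    heterozygous span (the causal site may sit in a breakpoint uncertainty
    gap); a non-segregating line only licenses removal of its *certain*
    heterozygous span.
    """
    widen = call.verdict == "segregating"
    iv = fm.het_interval(
        call.line_id, genotypes.row(call.line_id), marker_map, region, widen=widen
    )
    return iv if iv is not None else call.het_interval
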