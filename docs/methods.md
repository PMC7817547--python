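# Methods

This note documents the models, conventions and defaults behind `hifflux`,
what the synthetic-data generators do and do not emulate, and the design
choices made where the design was genuinely open. No empirical claim here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Coordinates and interval algebra

Genomic positions are 1-based base pairs. All intervals are closed on marker
positions and interval width is `end − start`; with the campaign's bounding
markers this convention yields the successive candidate-interval widths
exactly (e.g. 8,298,328 − 8,290,453 = 7,875 bp). Genotyping resolves marker
states only, so a crossover is represented as an uncertainty interval between
the two flanking informative markers, never as a point. Missing calls (`U`)
are uninformative: they widen breakpoint bounds to the nearest informative
markers, and a line with more than 50% missing calls inside the region
(configurable) is excluded from refinement.

### Segregation constraints

Each tested recombinant line contributes a constraint through two versions of
its heterozygous interval:

- the **inner** span, from its first to its last H-called marker — the part
  that is *certainly* heterozygous;
- the **outer** span, widened to the nearest informative non-H markers (or
  region bounds) — the part that *may* be heterozygous, covering the
  breakpoint uncertainty gaps.

A segregating verdict constrains the causal site to the line's outer span
(the site may sit inside an uncertainty gap); a non-segregating verdict
licenses removal of the *open interior* of the inner span only. Open-interior
subtraction lets a marker shared between a segregating and a non-segregating
interval survive: a causal site can sit exactly at a bound marker. This
inner/outer asymmetry is what makes refinement sound — with error-free
verdicts the true causal position can never be excluded, which the test suite
verifies over simulated campaigns.

`refine_candidate_interval` applies these rules as strict interval algebra:
intersect the prior with every segregating constraint, subtract every
non-segregating open interior, snap outward to marker positions, and drop
zero-width remnants (the candidate is resolved at the granularity of
marker-bounded cells; a single shared marker position is not a cell). If
subtraction splits the region, all surviving intervals are returned; if
nothing survives, the calls are mutually inconsistent and an error naming the
lines is raised. Equivalence with a brute-force per-cell consistency scan is
asserted on 1,000 random instances.

### Progeny tests

Fixed-progeny and progeny testing reduce to a Welch two-sample t test between
sibling groups fixed for alternative alleles. Default alpha is 0.05
(configurable); the test is two-sided. Fewer than two replicates in a group
gives an `inconclusive` verdict. Two identical zero-variance groups are
declared non-segregating with p = 1 (the Welch statistic is undefined there).

### Consensus refinement

Real campaigns contain phenotyping errors: at alpha 0.05, a campaign that
tests ~40 truly non-segregating recombinants expects about two false
"segregating" verdicts, and under strict algebra a single one can silently
exclude the causal position. The pipeline therefore refines by per-cell
likelihood consensus (`consensus_refine`). For each marker-bounded cell, the
hypothesis "the causal site is in this cell" predicts each tested line's true
state: segregating if the cell lies in the line's inner span, non-segregating
if outside its outer span, uninformative in between. The cell's score sums,
over lines, the Gaussian log-likelihood of the observed t statistic under the
predicted state — mean `ncp` if segregating, mean 0 if not, unit scale;
uninformative lines contribute whichever state explains their t better. The
noncentrality `ncp` is estimated as the median |t| of the clearly segregating
cluster (|t| above half the campaign maximum), floored at 4. Cells with the
maximal score form the candidate region; lines whose alpha-level verdict
contradicts the winning cells are reported as conflicts, never silently
dropped. Because a truly segregating line's t sits many standard errors from
zero at the campaign's power, a misleading verdict carries weak likelihood
weight and is outvoted; misclassification of a line requires |t| near ncp/2,
which at the simulated settings is vanishingly rare. Strict algebra remains
the default of the public refinement function; the consensus is the
pipeline's robustness layer, and the two agree whenever the verdicts are
mutually consistent.

### arHIF pair selection

To build a line segregating only for the final interval, one parent
recombined immediately north (lower coordinates) and one immediately south of
the target are selected: the breakpoint interval nearest the corresponding
target bound, ties broken by narrower breakpoint interval, then lexicographic
line id. A missing side raises an error naming the side.

## ¹⁵N flux bookkeeping

Masses are mg and enrichments/allocations dimensionless fractions internally;
percents appear only at I/O boundaries, which removes the ×100 ambiguity in
"DW × N%". Per organ: A% = 100·¹⁵N/(¹⁵N+¹⁴N); E = (A%_sample − A%_control)/100;
QtyN = DW·N%/100; Qty¹⁵N = QtyN·E (so the tracer can never exceed total N).
The unlabelled control defaults to A%_control = 0.3660 but per-experiment
control samples override the constant when present. A sample below the
control by ≤ 1e-4 atom percent is clipped to zero enrichment (instrument
noise at natural abundance); larger deficits are clipped and flagged.

Per plant: HI = DW_seeds/ΣDW; N and ¹⁵N allocation fractions per organ (each
set sums to 1; the seed fractions are NHI and ¹⁵NHI); NRE = ¹⁵NHI/HI, which
is dimensionless and may exceed 1. A remobilization harvest must consist of
exactly rosette, stem and seeds — roots are lost in the sand at harvest and
deliberately absent. In post-flowering uptake harvests the seed compartment
is the silique. When no tracer is recovered, ¹⁵N allocations, ¹⁵NHI and NRE
are returned as undefined with a flag — never as propagated NaN.

NUpE = (ΣQty¹⁵N / E_solution)/ΣDW per 24-h pulse. `E_solution` is the
labelling-solution enrichment as an atom fraction, default
(10 − 0.366)/100 = 0.09634 for a 10% solution net of natural background; it
is configurable because the denominator's units change the result 100-fold
and no worked value exists to disambiguate. NUpE is reported per pulse with
no rate extrapolation; the summary table rescales it to mg N g⁻¹ DW.

Genotype contrasts use ordinary least squares with additive genotype and
experiment-batch terms: type-II ANOVA, Tukey HSD at alpha 0.05 with a compact
letter display (maximal cliques of the not-significantly-different graph,
letters ordered by descending group mean), pairwise Welch t tests, and
least-square means computed by averaging model predictions over batch levels,
so a pure batch effect in a balanced design leaves genotype contrasts
untouched.

## Senescence kinetics

The senescence score is the fraction of yellow rosette leaves over the leaf
count at bolting (whole-leaf binary scoring; no partial yellowing). Leaf
ranks count true rosette leaves from oldest to youngest — cauline leaves,
recognisable by their lack of petioles, are excluded — and are pooled as OL
(1–10), ML (11–20), YL (21–30), NL (≥31).

Onset detection: the onset is the first observation after the series maximum
at which the chlorophyll index has dropped by at least `drop_threshold` of
that maximum for `k_consecutive` successive observations. Defaults are 5% and
2 — "start of the decrease" is not quantified anywhere, and these values are
robust to single-measurement noise; both are configurable. The rule uses only
relative drops, so it is invariant to rescaling of the index. An onset before
flower-bud emergence (52 days after sowing in the emulated design) is
sequential senescence; at or after it, monocarpic; no sustained decline means
no onset. At least 3 observations are required.

## Synthetic-data generators

The generators define the study conditions; analysis code never sees the
truth tables except in tests.

**Meiosis.** Selfed progeny of a parent heterozygous across the region
(default: 24 evenly spaced markers over chromosome 4, 7,180,000–13,079,020
bp). Each progeny receives two independent gametes; per adjacent-marker
interval a crossover occurs with Haldane probability
r = (1 − e^(−2d))/2, d = Mb × cM/Mb / 100 Morgans, without interference and
with at most one crossover per interval (adequate at sub-chromosome scales).
Genotypes combine the gametes (A+A→A, B+B→B, else H). The default 3.0 cM/Mb
is of the order implied by the emulated screen (77 recombinants among 276
selfed progeny over 5.9 Mb) and is a free parameter — the realized rates of
the two emulated screens differ ~10-fold, so no single value is "correct".
Exact crossover positions are drawn uniformly within their interval and
recorded, so the true genotype at any base pair is defined.

**Phenotypes.** value = baseline + effect × dosage(B)/2 + N(0, sd), with the
B allele hastening senescence. Campaign defaults (baseline 0.2, effect 0.2,
sd 0.05, 12 phenotyped progeny per fixed-allele group) put the fixed-progeny
test's power near 1, emulating a trait contrast strong enough to score by
eye.

**Labelling harvest.** Organ dry weights are lognormal around genotype means
(mean-preserving parameterisation), tracer shares Dirichlet around the mean
shares, and organ atom percents are back-computed from the drawn quantities
so that the analysis formulas invert the generator exactly at zero
measurement noise. Measurement noise is multiplicative lognormal on dry
weight and N%, and is applied to A% on the excess above control so unlabelled
controls stay at natural abundance. Defaults (DW 450/300/250 mg with equal
allocation arithmetic giving HI = 0.25, tracer shares 0.3/0.2/0.5, absorbed
tracer 0.012 mg ≈ the 1-ml 10-mM 10%-¹⁵N pulse) make the ground-truth
NRE = 0.5/0.25 = 2.0. Because per-plant NRE is a ratio of noisy quantities,
its cohort mean carries a small positive ratio bias of order CV²; at 10% CV
this stays within the 2% recovery band the tests assert.

**Chlorophyll kinetics.** Each leaf rank follows a logistic rise whose
midpoint precedes that rank's onset by 20 days — the index climbs until its
own decline begins, as in staggered per-rank senescence — then declines
linearly at 3% of peak per day. The programmed onset is defined as the first
*sampled* day on which the index has declined (sampling every 4 days from day
20 to 88), matching the detector's "first declined observation" convention,
so zero-noise detection recovers the programmed onset exactly; the 3%/day
decline makes the first declined sample clear the 5% rule net of the residual
rise. Noise is additive Gaussian, scaled to the rank's plateau.

**What the generators do not emulate.** Genotyping error, segregation
distortion, crossover interference, double crossovers within one marker
interval, plant-to-plant flowering-time variation, organ-correlated
measurement error, isotope-ratio instrument drift, and any gene-expression or
hormonal dynamics. Passing recovery tests therefore demonstrates that the
analysis inverts its own forward models under realistic noise magnitudes —
not that it is robust to every artefact of real campaigns.

## Numerical choices and problem sizes

Determinism: every generator consumes a single seeded `numpy` Generator; the
same configuration and seed reproduce byte-identical tables, and
`scripts/acceptance.py` derives independent sub-streams from its one `--seed`
via `SeedSequence.spawn`. Allocation sums are asserted to 1 within 1e-9.
Tie-breaks: equal consensus scores keep all maximal cells (wider, never
biased intervals); arHIF ties prefer narrower breakpoints then lexicographic
ids. Degenerate inputs (all-missing genotype rows, empty phenotype groups,
zero total N or tracer, zero-variance groups) raise typed errors or flagged
undefined values as documented above.

The shipped checks use 200 simulated campaigns of 276 progeny, 1,000 random
refinement instances, 500 labelled plants, 10,000 gametes and 500 noisy
chlorophyll series — sizes chosen so the whole suite completes in well under
a minute while keeping Monte Carlo error far from the asserted margins.

## Known limitations

- `select_arhif_pair` ranks candidates by breakpoint geometry only; it does
  not verify the lines' genotypes outside the target interval.
- The consensus refiner assumes a roughly common noncentrality across truly
  segregating lines (one causal locus of fixed effect); linked secondary loci
  would violate it.
- The strict refiner reports all participating lines when the calls are
  mutually inconsistent rather than isolating a minimal conflicting subset.
- Leaf-rank grouping assumes monotone whole-leaf yellowing; reversion in raw
  scores is not modelled.
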