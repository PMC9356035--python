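# Methods

This note documents the model implemented by `danubesim`, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not emulate.

## Demographic model

The simulation area is a lattice of square cells of 100 × 100 km. Every
cell hosts two demes stacked in two *layers*: a hunter-gatherer (HG) deme
and a farmer (FA) deme. All densities are effective haploid females;
census sizes are three times the effective size and both sexes double it,
so a carrying capacity of K = 100 corresponds to 200 × 3 / 10,000 = 0.06
individuals/km². One generation is 25 years. A run spans 1,600
generations (~40,000 years): the HG layer is founded at generation 0 with
100 individuals in a Near-East deme; the FA layer at generation 1,200
(~10,000 years ago) with 100 individuals in eastern Anatolia. Dates in
BCE convert through years_BP = years_BCE + 1950 and gen = 1600 −
round(years_BP / 25).

Each generation applies, in this order: **growth → competition →
admixture → Mdec update → migration**. The order is fixed and documented
because it changes traces; nothing in the science dictates one order.

**Growth** is the discrete logistic N' = N + rN(1 − N/K), the standard
choice for this family of spatial simulators. HG: r = 0.2, m = 0.15,
K = 100 (fixed; they fill the map before farming and carry no inference).
FA: r = 0.53, m = 0.4, with K_FA a parameter of interest (prior
U[500, 1000]). Eighty generations before present K_FA jumps to 24,000
(~14.4 individuals/km², Roman-period densities); compressed test fixtures
place this jump proportionally (5% of the run before the end). K = 0
demes collapse to zero within the generation and absorb immigrants at the
end of it (a hard cap at K).

**Competition** mimics the replacement of foraging by farming: the HG
logistic gains a Lotka–Volterra cross term with a density-dependent
coefficient,

    N_HG' = N_HG + r_HG N_HG (1 − (N_HG + (K_HG/K_FA)·c·N_FA)/K_HG),
    c = c_max · min(1, N_FA/K_FA).

Farmers are unaffected by the much smaller HG demes (their dynamics are
the K_FA ≫ K_HG limit). `c_max = 3.0` was chosen so that, with r_HG =
0.2, a saturated farmer deme excludes the local HG deme on the order of
ten generations after farmer saturation; the exact coefficients of the
original simulator are not published, so the functional form satisfies the
stated behavioural contract rather than reproducing unpublished code. A
declining HG deme below 0.5 effective females under active competition is
set extinct, which makes the local "end of cohabitation" well defined; the
rule never fires on growing front cells, so it does not slow colonisation
fronts. In a central-European region the competition coefficients are 0
until generation 1,424 (prolonging cohabitation up to 224 generations so
the HG layer can be sampled at the dates of the real samples), after which
K_HG is set to 0 there. Protected demes are exempt from the 0.5-female
extinction rule: they may persist at low density while slowly draining
into extinct neighbours.

**Admixture** transfers ancestry from hunter-gatherers to farmers at rate
γ: the number of farmer-deme individuals per generation with an HG parent
is A = γ · N_HG N_FA / (N_HG + N_FA) (contact-proportional). A is
*gametic* gene flow: it is recorded in the trace and drives the backward
layer-switch probability A/N_FA, but no individuals are moved between
layers demographically. A demographic transfer would empty HG demes
within a few generations for γ near the upper prior bound (0.4), making
the late HG sampling dates unreachable for most prior draws.

Four admixture scenarios combine a time model with a region:

| scenario | time model | where |
|---|---|---|
| SN1 | constant γ | everywhere |
| SN2 | linear ramp 0 → γ over the local cohabitation period | everywhere |
| SN3 | constant γ | central Europe only |
| SN4 | linear ramp | central Europe only |

The ramp's anchor — the local cohabitation length T_cohab(deme) — is
endogenous (it depends on when competition excludes the local HG deme), so
ramp scenarios run a pilot forward pass with constant γ = γ_max, measure
T_cohab = hg_extinction − fa_arrival per deme, and rerun with the ramp
anchored on it (one fixed-point iteration). Demes whose HG never go
extinct within the run anchor the ramp to the end of the simulation.

**Mdec** models post-colonisation sedentism: once a farmer deme reaches
90% of K_FA, its emigration rate is divided by Mdec, permanently (a
reversible trigger would re-accelerate mobility, contradicting the meaning
of a mobility reduction "after the initial spread"). Mdec = 1 disables
the mechanism exactly.

**Migration** is a stepping-stone exchange: each deme sends a fraction m
of its population, split equally among its land neighbours
(4-neighbourhood). Flux that would enter the sea is redistributed to the
land neighbours (the emigrant pool is divided by the number of *land*
neighbours); a deme without land neighbours retains everyone. Total
population is conserved to 1e-9 relative.

The forward demography is deterministic on real-valued densities (the
convention of this simulator family): reproducible traces, cheap
reruns, and all stochasticity concentrated in the coalescent. A deme
counts as occupied/colonised once it holds 0.5 effective females.

## Backward coalescent

Sampled lineages (arbitrary demes, generations, layers — serial sampling
is the point) walk backwards through the recorded trace. Per generation,
in order: (1) a farmer lineage switches to the HG layer with probability
A/N_FA of its deme; (2) each lineage picks its source deme with
probabilities proportional to the forward emigrant counts into its deme
(staying with the complementary probability); (3) within each deme-layer
group, every pair of lineages coalesces with probability 1/N, where N is
the local density at the parental generation, floored at 1 when
0 < N < 1. The number of successful pair draws per group-generation is
Binomial(C(j,2), 1/N) with a uniformly chosen subset of pairs; pairs
sharing a lineage with an earlier merge in the same generation are
skipped (binary mergers only). The backward event order mirrors the
reversed forward order up to the switch/migration transposition, which is
fixed and documented because it marginally changes switch rates.

Farmer lineages reaching the farmer founding generation must sit in the
founder deme (anything else is a trace inconsistency and raises) and join
the local HG layer — the Palaeolithic layer creates the initial Neolithic
source population. Lineages reaching generation 0 continue in a single
panmictic founder deme of 100 (the founding propagule size) until the
MRCA, with geometric skip-ahead between coalescent events; the skip-ahead
samples exactly the same law as stepping generation by generation (the
probability of a silent generation is (1 − 1/N)^C(j,2)), and a unit test
verifies the two paths against each other by a two-sample KS test. A
lineage landing in a deme the trace records as empty is a hard error.

## Mutation model

Finite-site mtDNA (HVS-I): L = 347 sites, μ = 7.5 × 10⁻⁶ per site per
generation, transition fraction 0.9841. Two interpretation choices are
exposed as configuration because the conventions are ambiguous in this
literature: μ may be read per site (default) or per sequence
(`per_site=False`); and the quoted "0.9841" is interpreted as the
*transition* fraction — HVS-I is strongly transition-biased and a 98.4%
transversion rate is biologically implausible. Mutations are Poisson per
branch, placed on uniform sites (recurrent hits allowed); transversions
choose between the two alternatives uniformly. The root sequence is
all-'A' by convention; every statistic downstream is distance-based, so
the convention is unobservable.

## Summary statistics

Arlequin-style indices under the Kimura 2-parameter model: gene diversity
H = n/(n−1)(1 − Σp²); haplotype count k; mean pairwise difference π
(K2P-corrected per site by default, raw counts optionally — both exposed
because the convention used for the published π values is ambiguous); and
AMOVA-based ΦST with the distance matrix entries treated as squared
Euclidean distances (the Arlequin convention). Negative ΦST estimates
are clamped to 0 for reporting (matching how "Fst = 0.0" is reported) but
retained internally. Saturated K2P pairs (log argument ≤ 0) raise or are
excluded with a warning, depending on context. Pairwise ΦST significance
uses label permutations with +1 smoothing.

The 14-statistic vector of the seven-population design: mean and sample
SD (n−1 denominator) of k, H, π across the seven samples, then mean and
SD of pairwise ΦST within four pair groups — HG vs central-European
farmers (Early, Late), among the three Early Neolithic samples, among the
three Late Neolithic samples, and Early vs Late of the same area. The
fixed ordering is part of the file schema.

## ABC

Statistics are standardised by the reference-table mean/SD (pooled across
scenarios for model choice, so marginal densities are comparable);
distances are Euclidean; retention keeps ⌈δN⌉ rows. The posterior is
ABC-GLM: an OLS fit of (standardised) statistics on parameters among the
retained rows gives s = a + Bθ + ε, ε ~ N(0, Σ), and the posterior is the
truncated uniform prior times N(s_obs; a + Bθ, Σ), evaluated on a joint
parameter grid (1,024 / 257 / 81 / 41 points per dimension for 1-4
parameters) and marginalised; marginals are reported on 1,024-point
grids, from which mode, mean and HDIs are read deterministically. HDIs
are the shortest single window reaching the requested mass (two-pointer
on the gridded CDF, ties broken towards the heavier window; multimodal
densities yield one interval with a warning). A singular regression falls
back to the rejection posterior (KDE of retained draws) with a warning.

A known numerical property, deliberately not "corrected": when the
retention window is *narrower* than the statistic noise, the OLS fit of s
on θ is attenuated by the selection on s and the GLM posterior widens
towards the truncated prior; when the window is wide relative to the
noise the conjugate linear-Gaussian oracle is reproduced closely (the
acceptance test fits on the full table, δ = 1, where the oracle match is
tight). Overdispersion makes HDIs conservative, which is the safe
direction for the coverage diagnostics.

The marginal density P-value (0 = no fit, 1 = good fit) is the fraction
of retained simulations whose own statistics have a smaller GLM marginal
density (likelihood averaged over the retained parameter draws) than the
observed statistics. Several variants of this diagnostic exist; the
density-rank definition is used because it is the one whose stated range
and interpretation match.

Model choice reports, per scenario: the GLM marginal density of the
observed statistics; posterior probabilities proportional to those
densities under equal model priors; the Bayes factor of each scenario
against the mean of the others; and the acceptance-fraction method (share
of each model among the globally closest pooled simulations) at tolerance
levels 0.25%, 1% and 2.5%. Cross-validation holds out table rows as
pseudo-observations and reports PR, the fraction recovered by highest
posterior probability. Point estimators are configurable per parameter;
the reporting convention is the mode for γ and Mdec and the mean for
K_FA. Calibration diagnostics compute, over pseudo-observed datasets,
the posterior quantile of each true value and the mass of the smallest
highest-density region containing it; both are uniform for unbiased
posteriors, and deviations are flagged by Kolmogorov–Smirnov tests.
BIAS = mean(|θ̂−θ|/θ), RMSE = √(mean((θ̂−θ)²))/θ̄, and Factor2 = the
proportion of estimates within [0.5θ, 2θ], bounds inclusive.

## Structured population continuity (SPC) test

The test asks whether the ΦST observed between an older and a younger
sample from the same area is compatible with continuity once spatial
structure and gene flow are accounted for. Continuity datasets are
simulated with γ = 0 and Mdec = 1 (the HG layer only seeds the farmer
expansion) with m_FA ~ U[0.3, 0.5] and K_FA ~ U[100, 2000], spanning Nm
of roughly 30–1000. Each simulation is summarised by the *older*
sample's (H, π, k); the 1,000 (of 20,000 at full scale) simulations
closest to the observed older-sample statistics (standardised Euclidean
distance — the scaling is unstated in the sources, standardisation is
this package's choice) are retained; their fit is confirmed by the
marginal density P-value (> 0.05, otherwise the result is flagged invalid
but still reported); and the one-tailed P-value is the proportion of
retained serial ΦST values at least as large as the observed one.
Continuity is rejected at α = 5%.

Ties count as "at least as large" by default: with clamping, both the
observed and many simulated ΦST values sit exactly at 0, and counting
ties makes the test conservative (an observed 0 can never reject). The
strict convention ("larger than") and the unclamped ΦST are both exposed;
the tie-free unclamped variant has approximately uniform P-values under
continuity, which is what the calibration test checks.

Because the reference pool depends only on the priors and the sampling
design — not on the observed data — error-rate studies over many
pseudo-observed pairs share one pool; the retention step remains
per-dataset. This introduces a weak dependence between replicates and is
noted where used.

## Synthetic fixtures

`europe_like` is a stylised Europe on a 60 × 55 lattice: a Mediterranean
basin with Iberian, Italian and Balkan peninsulas, a Bosporus land
bridge, a Black Sea, a Baltic separating a Fennoscandia reached from the
north-east, a Norwegian coastal arm behind a North Sea, a Near-East HG
origin, an Anatolian FA origin and a central-European region mask. The
true map raster of the original study is not published; the fixture's
geometry was designed so that the documented calibration of the HG layer
holds — r = 0.2 and m = 0.15 were chosen (in the source analysis) to
colonise Europe in approximately 500 generations, and on this map the
last land deme (the Norwegian arm) is colonised at generation 510. The
fixture approximates region-level sampling locations, not real site
coordinates.

The `danubian_7groups` scheme reproduces the seven-population design: 328
ancient lineages — 19 hunter-gatherers (central Europe), Early Neolithic
farmers from Greece (20), the Balkans (44) and central Europe (113), and
Middle/Late-Final Neolithic farmers from Greece (25), the Balkans (39)
and central Europe (68) — with regional totals of 45 (northern Greece),
83 (Balkans) and 200 (central Europe). Only the seven group totals and
the three regional totals are published; the Balkans/central-Europe split
within periods is this package's allocation consistent with both margins.
`greece_serial` places the northern-Greece serial samples (n = 20 Early,
n = 25 Middle-Late/Final, n = 319 present-day) in one deme.

`mini` (8 × 8, 170 generations, farmers founded at generation 60) and
`strip_1d` (1 × 30) are compressed fixtures for fast tests; their
sampling dates maintain the same ordering and margins relative to front
arrivals as the full timeline. `island_pair` is deliberately
disconnected, for error-path tests.

Reduced problem sizes used by the test suite: reference tables of 2,000
simulations per scenario on the mini fixture (δ = 5%, so ~100 retained),
20 pseudo-observed sets for coverage, a 2,000-simulation continuity pool
with 100 pseudo-observed serial pairs for the SPC error rate, and 10,000
replicates for the neutral-coalescent diversity check.

## What passing tests do and do not show

The fixtures emulate the *structure* of the study design (two layers,
serial spatial sampling, the seven-group statistics, wide priors), not
real European geography, radiocarbon-calibrated dates, or real mtDNA
data. Passing tests therefore demonstrate that the machinery is
self-consistent and calibrated on synthetic data of the right shape; they
say nothing about fit to the deposited ancient sequences, and the
published real-data estimates (γ ≈ 0.1, five-fold mobility reduction,
K_FA ≈ 771; the continuity rejections against present-day Greeks) require
those sequences and full-scale simulation, which are out of scope here.

Other known limitations: the deterministic demography ignores demographic
stochasticity (all drift is coalescent-side); the competition coefficients
satisfy a behavioural contract rather than matching unpublished code; the
finite-site model's recurrent hits bias observed pairwise differences
slightly below 2NμL (visible only beyond the test tolerances at these
rates); and GLM posteriors under narrow retention are overdispersed, as
documented above.
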