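"""Forward-in-time demography of two superimposed population layers.

The simulation area is a lattice of square demes (cells of
``cell_size_km`` x ``cell_size_km``, 100 km by default).  Every cell hosts
two demes stacked in separate *layers*: a hunter-gatherer (HG) deme and a
farmer (FA) deme.  Each layer expands from its own origin deme following
logistic growth and stepping-stone migration to the four cardinal land
neighbours.  Where both layers occupy the same cell they interact through

* Lotka-Volterra-type competition with density-dependent coefficients,
  which progressively replaces the foraging by the farming subsistence
  strategy, and
* assimilation: a fraction ``gamma`` of HG-FA contacts per generation
  results in gene flow from the hunter-gatherer into the farmer deme.

A third mechanism, ``Mdec``, divides the farmer emigration rate in a deme
once the deme has reached 90% of its carrying capacity, modelling reduced
mobility (sedentism) after the initial colonisation phase.

The demography is deterministic on real-valued densities (densities are
effective haploid females); all stochasticity lives in the backward
coalescent (:mod:`danubesim.coalescent`).  The complete per-generation
state is recorded in a :class:`DemographyTrace`, which is the bridge that
conditions the coalescent on the forward demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "WorldConfig",
    "LayerParams",
    "ScenarioConfig",
    "DemographyTrace",
    "density_from_K",
    "generations_to_years",
    "step_growth",
    "step_competition",
    "apply_mdec",
    "gamma_at",
    "step_admixture",
    "step_migration",
    "run_forward",
    "colonization_complete_gen",
    "OCCUPANCY_THRESHOLD",
    "DEFAULT_COMPETITION_CMAX",
]

#: A deme counts as occupied once it holds at least half an effective female.
#: The same threshold defines local extinction of a declining population.
OCCUPANCY_THRESHOLD = 0.5

#: Maximum density-dependent competition coefficient.  Chosen so that, with
#: r_HG = 0.2, the hunter-gatherer deme goes locally extinct on the order of
#: ten generations after the farmer deme saturates (see docs/methods.md).
DEFAULT_COMPETITION_CMAX = 3.0


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WorldConfig:
    """Geometry and clock of the simulation area.

    Parameters
    ----------
    land_mask
        Boolean raster, ``True`` for land cells.
    n_generations
        Number of forward generations to simulate.
    cell_size_km
        Side length of a cell in km (100 by default).
    generation_years
        Years per generation (25 by default).
    census_factor
        Census size is ``census_factor`` times the effective size (3).
    """

    land_mask: np.ndarray
    n_generations: int = 1600
    cell_size_km: float = 100.0
    generation_years: float = 25.0
    census_factor: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        mask = np.asarray(self.land_mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("land_mask must be a 2-D raster")
        object.__setattr__(self, "land_mask", mask)
        if self.cell_size_km <= 0:
            raise ValueError("cell_size_km must be positive")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.land_mask.shape

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2


@dataclass(frozen=True)
class LayerParams:
    """Demographic parameters of one layer (HG or FA).

    ``K_schedule`` is a sorted list of ``(generation, K)`` pairs giving a
    piecewise-constant carrying capacity in effective haploid females; e.g.
    the farmer layer switches to K = 24,000 eighty generations before the
    end of the run to reflect the population increase of the Roman period.
    """

    layer_id: str
    r: float
    m: float
    K_schedule: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if self.layer_id not in ("HG", "FA"):
            raise ValueError("layer_id must be 'HG' or 'FA'")
        if not 0.0 <= self.m < 1.0:
            raise ValueError("emigration fraction m must be in [0, 1)")
        if self.r < 0.0:
            raise ValueError("growth rate r must be >= 0")
        sched = tuple(sorted((int(g), float(k)) for g, k in self.K_schedule))
        if not sched:
            raise ValueError("K_schedule must not be empty")
        if any(k < 0 for _, k in sched):
            raise ValueError("carrying capacities must be >= 0")
        object.__setattr__(self, "K_schedule", sched)

    @classmethod
    def constant_K(cls, layer_id: str, r: float, m: float, K: float) -> "LayerParams":
        return cls(layer_id=layer_id, r=r, m=m, K_schedule=((0, K),))

    def K_at(self, gen: int) -> float:
        """Carrying capacity in force at generation ``gen``."""
        K = self.K_schedule[0][1]
        for g, k in self.K_schedule:
            if gen >= g:
                K = k
            else:
                break
        return K


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario of the two-layer expansion.

    ``scenario_id`` is one of SN1-SN4 (Danubian-expansion admixture
    scenarios) or SPC (continuity-test demography); free-form ids are
    accepted for custom experiments.  The admixture model is the
    combination of ``admixture_time_model`` (``constant`` or
    ``linear_ramp``) and ``admixture_region`` (``everywhere`` or
    ``region``, the latter restricted to ``region_mask``, i.e. central
    Europe in the Europe-like fixture).
    """

    scenario_id: str
    hg_origin: tuple[int, int]
    fa_origin: Optional[tuple[int, int]] = None
    gamma_max: float = 0.0
    admixture_time_model: str = "constant"
    admixture_region: str = "everywhere"
    region_mask: Optional[np.ndarray] = None
    mdec: float = 1.0
    mdec_threshold: float = 0.9
    hg_start_gen: int = 0
    fa_start_gen: Optional[int] = 1200
    founder_size: float = 100.0
    competition_off_region: Optional[np.ndarray] = None
    competition_off_until_gen: int = 1424
    competition_cmax: float = DEFAULT_COMPETITION_CMAX

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_max <= 1.0:
            raise ValueError("gamma_max must be in [0, 1]")
        if self.mdec < 1.0:
            raise ValueError("Mdec must be >= 1")
        if not 0.0 < self.mdec_threshold <= 1.0:
            raise ValueError("mdec_threshold must be in (0, 1]")
        if self.admixture_time_model not in ("constant", "linear_ramp"):
            raise ValueError("admixture_time_model must be 'constant' or 'linear_ramp'")
        if self.admixture_region not in ("everywhere", "region"):
            raise ValueError("admixture_region must be 'everywhere' or 'region'")
        if self.admixture_region == "region" and self.region_mask is None:
            raise ValueError("region_mask required when admixture_region='region'")

    @classmethod
    def preset(
        cls,
        scenario_id: str,
        hg_origin: tuple[int, int],
        fa_origin: Optional[tuple[int, int]],
        region_mask: Optional[np.ndarray] = None,
        **kwargs,
    ) -> "ScenarioConfig":
        """Build SN1-SN4 with their admixture model wired in."""
        presets = {
            "SN1": dict(admixture_time_model="constant", admixture_region="everywhere"),
            "SN2": dict(admixture_time_model="linear_ramp", admixture_region="everywhere"),
            "SN3": dict(admixture_time_model="constant", admixture_region="region"),
            "SN4": dict(admixture_time_model="linear_ramp", admixture_region="region"),
            "SPC": dict(admixture_time_model="constant", admixture_region="everywhere"),
        }
        opts = dict(presets.get(scenario_id.upper(), {}))
        opts.update(kwargs)
        return cls(
            scenario_id=scenario_id.upper(),
            hg_origin=hg_origin,
            fa_origin=fa_origin,
            region_mask=region_mask,
            **opts,
        )


# ---------------------------------------------------------------------------
# Elementary operations (scalar or elementwise on arrays)
# ---------------------------------------------------------------------------


def density_from_K(K_eff: float, config: WorldConfig) -> float:
    """Convert a carrying capacity in effective haploid females to a census
    density in individuals per km^2.

    K effective females correspond to 2K effective individuals of both
    sexes, and census size is ``census_factor`` times the effective size.
    With the defaults, K = 100 gives 200 * 3 / 10,000 = 0.06 ind/km^2.
    """
    if K_eff < 0:
        raise ValueError("K_eff must be >= 0")
    return 2.0 * K_eff * config.census_factor / config.cell_area_km2


def generations_to_years(gens: float, config: WorldConfig) -> float:
    """Convert a number of generations to years (25 y/generation default)."""
    if gens < 0:
        raise ValueError("gens must be >= 0")
    return gens * config.generation_years


def step_growth(N, r: float, K):
    """One generation of discrete logistic growth, N' = N + rN(1 - N/K).

    Accepts scalars or arrays (elementwise).  Where K = 0 the population
    collapses to 0 within the generation.  The result is clipped at 0.
    """
    N = np.asarray(N, dtype=float)
    K = np.asarray(K, dtype=float)
    K_safe = np.where(K > 0, K, 1.0)
    out = N + r * N * (1.0 - N / K_safe)
    out = np.where(K > 0, np.maximum(out, 0.0), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def step_competition(
    N_hg,
    N_fa,
    r_hg: float,
    K_hg,
    K_fa,
    c_max: float = DEFAULT_COMPETITION_CMAX,
    competition_on=True,
):
    """Hunter-gatherer growth under density-dependent competition.

    The HG deme follows a Lotka-Volterra logistic in which the farmer
    density enters with a coefficient ``c`` that ramps linearly from 0 to
    ``c_max`` as the farmer deme fills up (c = c_max * min(1, N_FA/K_FA)):

        N' = N + r N (1 - (N + (K_HG/K_FA) c N_FA) / K_HG)

    so farmers only start to exclude hunter-gatherers once they are
    established, and exclusion completes within roughly ten generations of
    farmer saturation for the default ``c_max``.  Farmer dynamics are not
    affected by the (much smaller) HG demes.  Where ``competition_on`` is
    False the plain logistic applies.  Declining HG demes falling below
    :data:`OCCUPANCY_THRESHOLD` are set extinct, which makes the end of the
    cohabitation period well defined.
    """
    N_hg = np.asarray(N_hg, dtype=float)
    N_fa = np.asarray(N_fa, dtype=float)
    K_hg = np.asarray(K_hg, dtype=float)
    K_fa = np.asarray(K_fa, dtype=float)
    on = np.asarray(competition_on, dtype=float)

    K_hg_safe = np.where(K_hg > 0, K_hg, 1.0)
    K_fa_safe = np.where(K_fa > 0, K_fa, 1.0)
    c = c_max * np.minimum(1.0, N_fa / K_fa_safe) * on * (K_fa > 0)
    cross = (K_hg / K_fa_safe) * c * N_fa
    grown = N_hg + r_hg * N_hg * (1.0 - (N_hg + cross) / K_hg_safe)
    grown = np.maximum(grown, 0.0)
    # declining populations below half a female go extinct, but only under
    # active competition: protected demes may persist at low density
    dying = (grown < OCCUPANCY_THRESHOLD) & (grown < N_hg) & (on > 0)
    grown = np.where(dying, 0.0, grown)
    out = np.where(K_hg > 0, grown, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def apply_mdec(
    N_fa,
    K_fa,
    m_fa: float,
    mdec: float,
    triggered,
    threshold: float = 0.9,
):
    """Update the per-deme Mdec trigger and return (m_current, triggered).

    Once a farmer deme reaches ``threshold`` (90%) of its carrying capacity
    its emigration rate is divided by ``mdec``; the trigger is permanent.
    """
    N_fa = np.asarray(N_fa, dtype=float)
    K_fa = np.asarray(K_fa, dtype=float)
    triggered = np.asarray(triggered, dtype=bool)
    newly = (K_fa > 0) & (N_fa >= threshold * K_fa)
    triggered = triggered | newly
    m_cur = np.where(triggered, m_fa / mdec, m_fa)
    if m_cur.ndim == 0:
        return float(m_cur), bool(triggered)
    return m_cur, triggered


def gamma_at(
    gen: int,
    scen: ScenarioConfig,
    fa_arrival_gen,
    t_cohab,
    deme: Optional[tuple[int, int]] = None,
):
    """Effective assimilation rate gamma_t per deme at generation ``gen``.

    Under the constant model gamma_t equals ``gamma_max`` wherever admixture
    is allowed.  Under the linear ramp gamma_t rises from 0 at the local
    farmer arrival time to ``gamma_max`` at the end of the local
    cohabitation period (of length ``t_cohab`` generations).  With
    ``admixture_region='region'`` gamma_t is 0 outside ``region_mask``.

    With ``deme`` given, returns the scalar rate for that deme and raises
    ``ValueError`` if farmers never colonised it.
    """
    fa_arrival_gen = np.asarray(fa_arrival_gen)
    t_cohab = np.asarray(t_cohab, dtype=float)
    colonized = fa_arrival_gen >= 0
    if scen.admixture_time_model == "constant":
        g = np.where(colonized, scen.gamma_max, 0.0)
    else:
        frac = np.zeros(fa_arrival_gen.shape)
        ok = colonized & (t_cohab > 0)
        frac[ok] = np.clip((gen - fa_arrival_gen[ok]) / t_cohab[ok], 0.0, 1.0)
        frac[colonized & (t_cohab <= 0)] = 1.0
        g = np.where(colonized, scen.gamma_max * frac, 0.0)
    if scen.admixture_region == "region":
        g = np.where(np.asarray(scen.region_mask, dtype=bool), g, 0.0)
    if deme is not None:
        if not colonized[deme]:
            raise ValueError(f"deme {deme} was never colonised by farmers")
        return float(g[deme])
    return g


def step_admixture(N_hg, N_fa, gamma_t):
    """Contact-proportional assimilation count A = gamma * N_HG N_FA / (N_HG + N_FA).

    A is the number of farmer-deme individuals per generation whose parent
    is a hunter-gatherer: gametic gene flow HG -> FA.  It is recorded in
    the trace and drives the backward layer-switch probability A/N_FA; the
    deme densities themselves are not transferred (assimilation models
    interbreeding and adoption of farming, not a demographic migration).
    A is 0 wherever either layer is empty.
    """
    N_hg = np.asarray(N_hg, dtype=float)
    N_fa = np.asarray(N_fa, dtype=float)
    tot = N_hg + N_fa
    denom = np.where(tot > 0, tot, 1.0)
    A = np.asarray(gamma_t, dtype=float) * N_hg * N_fa / denom
    A = np.minimum(A, N_hg)
    if A.ndim == 0:
        return float(A)
    return A


def _land_neighbor_count(land: np.ndarray) -> np.ndarray:
    """Number of 4-neighbourhood land neighbours of each cell."""
    padded = np.pad(land.astype(int), 1)
    n = (
        padded[:-2, 1:-1]
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
    )
    return np.where(land, n, 0)


def _inflow(share: np.ndarray, land: np.ndarray) -> np.ndarray:
    """Sum of the per-direction shares arriving at each land cell."""
    padded = np.pad(share, 1)
    inflow = (
        padded[:-2, 1:-1]  # from the north neighbour
        + padded[2:, 1:-1]
        + padded[1:-1, :-2]
        + padded[1:-1, 2:]
    )
    return np.where(land, inflow, 0.0)


def step_migration(N: np.ndarray, m, land: np.ndarray, n_nb: Optional[np.ndarray] = None):
    """Stepping-stone migration: each deme sends a fraction ``m`` of its
    population split equally among its land neighbours (4-neighbourhood).

    Flux towards sea cells is redistributed among the land neighbours by
    construction (the emigrant pool is divided by the number of *land*
    neighbours).  A deme without land neighbours retains everyone.  Returns
    ``(N_new, outflux, share)`` where ``share`` is the per-direction
    emigrant count of each source deme; total population is conserved.
    """
    if n_nb is None:
        n_nb = _land_neighbor_count(land)
    N = np.where(land, N, 0.0)
    m = np.broadcast_to(np.asarray(m, dtype=float), N.shape)
    can_move = n_nb > 0
    outflux = np.where(can_move, m * N, 0.0)
    share = np.where(can_move, outflux / np.where(can_move, n_nb, 1), 0.0)
    N_new = N - outflux + _inflow(share, land)
    return N_new, outflux, share


# ---------------------------------------------------------------------------
# Demography trace
# ---------------------------------------------------------------------------


@dataclass
class DemographyTrace:
    """Per-generation record of the forward demography.

    Time index t runs 0..n_generations; ``n_hg_end[t]`` / ``n_fa_end[t]``
    are the densities at the end of generation t (t = 0 is the seeded
    initial state).  ``*_mid`` arrays hold the densities after growth,
    competition and admixture but before migration of generation t, and
    ``admix[t]`` the number of hunter-gatherers assimilated into the farmer
    deme during generation t.  Emigrant counts per directed neighbour pair
    are derivable (equal split of ``m * N_mid`` among land neighbours) and
    exposed via :meth:`emigration`.
    """

    config: WorldConfig
    scenario: ScenarioConfig
    hg: LayerParams
    fa: Optional[LayerParams]
    n_hg_end: np.ndarray
    n_fa_end: np.ndarray
    n_hg_mid: np.ndarray
    n_fa_mid: np.ndarray
    admix: np.ndarray
    mdec_trigger_gen: np.ndarray  # first generation with reduced m_FA; -1 = never
    fa_arrival_gen: np.ndarray  # -1 = never colonised
    hg_arrival_gen: np.ndarray
    hg_extinction_gen: np.ndarray  # -1 = still occupied at the end
    t_cohab: np.ndarray
    land_nb: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.land_nb = _land_neighbor_count(self.config.land_mask)

    @property
    def n_generations(self) -> int:
        return self.config.n_generations

    def n_end(self, layer: str) -> np.ndarray:
        return self.n_hg_end if layer == "HG" else self.n_fa_end

    def n_mid(self, layer: str) -> np.ndarray:
        return self.n_hg_mid if layer == "HG" else self.n_fa_mid

    def m_current(self, layer: str, gen: int) -> np.ndarray:
        """Per-deme emigration rate in force during generation ``gen``."""
        if layer == "HG":
            return np.full(self.config.shape, self.hg.m)
        assert self.fa is not None
        trig = (self.mdec_trigger_gen >= 0) & (gen >= self.mdec_trigger_gen)
        return np.where(trig, self.fa.m / self.scenario.mdec, self.fa.m)

    def emigration(self, layer: str, gen: int):
        """(outflux, share) of the migration stage of generation ``gen``.

        ``share`` is the emigrant count sent to each land neighbour of a
        source deme (equal split).
        """
        N_mid = self.n_mid(layer)[gen]
        m = self.m_current(layer, gen)
        can_move = self.land_nb > 0
        outflux = np.where(can_move, m * N_mid, 0.0)
        share = np.where(can_move, outflux / np.where(can_move, self.land_nb, 1), 0.0)
        return outflux, share

    def occupied(self, layer: str, gen: int) -> np.ndarray:
        return self.n_end(layer)[gen] >= OCCUPANCY_THRESHOLD

    @classmethod
    def single_deme(
        cls,
        N: float,
        n_generations: int,
        layer: str = "FA",
        founder_size: Optional[float] = None,
    ) -> "DemographyTrace":
        """Constant-size single-deme trace (no migration), for calibration
        checks and small experiments."""
        land = np.ones((1, 1), dtype=bool)
        cfg = WorldConfig(land_mask=land, n_generations=n_generations)
        G = n_generations
        const = np.full((G + 1, 1, 1), float(N))
        zeros = np.zeros((G + 1, 1, 1))
        hg = LayerParams.constant_K("HG", r=0.0, m=0.0, K=N if layer == "HG" else 0.0)
        fa = LayerParams.constant_K("FA", r=0.0, m=0.0, K=N if layer == "FA" else 0.0)
        scen = ScenarioConfig(
            scenario_id="SINGLE",
            hg_origin=(0, 0),
            fa_origin=(0, 0),
            fa_start_gen=0,
            founder_size=float(N if founder_size is None else founder_size),
        )
        n_hg = const if layer == "HG" else zeros
        n_fa = const if layer == "FA" else zeros
        neg = np.full((1, 1), -1, dtype=np.int64)
        arr0 = np.zeros((1, 1), dtype=np.int64)
        return cls(
            config=cfg,
            scenario=scen,
            hg=hg,
            fa=fa,
            n_hg_end=n_hg,
            n_fa_end=n_fa,
            n_hg_mid=n_hg.copy(),
            n_fa_mid=n_fa.copy(),
            admix=np.zeros((G + 1, 1, 1)),
            mdec_trigger_gen=neg.copy(),
            fa_arrival_gen=arr0 if layer == "FA" else neg.copy(),
            hg_arrival_gen=arr0 if layer == "HG" else neg.copy(),
            hg_extinction_gen=neg.copy(),
            t_cohab=np.zeros((1, 1)),
        )

    def save(self, path) -> None:
        """Serialise the recorded arrays to an ``.npz`` container."""
        np.savez_compressed(
            path,
            land_mask=self.config.land_mask,
            n_hg_end=self.n_hg_end,
            n_fa_end=self.n_fa_end,
            n_hg_mid=self.n_hg_mid,
            n_fa_mid=self.n_fa_mid,
            admix=self.admix,
            mdec_trigger_gen=self.mdec_trigger_gen,
            fa_arrival_gen=self.fa_arrival_gen,
            hg_arrival_gen=self.hg_arrival_gen,
            hg_extinction_gen=self.hg_extinction_gen,
            t_cohab=self.t_cohab,
        )


# ---------------------------------------------------------------------------
# Main forward loop
# ---------------------------------------------------------------------------


def _forward_pass(
    config: WorldConfig,
    hg: LayerParams,
    fa: Optional[LayerParams],
    scen: ScenarioConfig,
    t_cohab: Optional[np.ndarray],
) -> DemographyTrace:
    land = config.land_mask
    R, C = config.shape
    G = config.n_generations
    n_nb = _land_neighbor_count(land)

    if not land[scen.hg_origin]:
        raise ValueError("hg_origin must be on land")
    fa_active = fa is not None and scen.fa_origin is not None and scen.fa_start_gen is not None
    if fa_active and not land[scen.fa_origin]:
        raise ValueError("fa_origin must be on land")
    if fa_active and scen.fa_start_gen <= scen.hg_start_gen:
        raise ValueError("fa_start_gen must be after hg_start_gen")

    n_hg_end = np.zeros((G + 1, R, C))
    n_fa_end = np.zeros((G + 1, R, C))
    n_hg_mid = np.zeros((G + 1, R, C))
    n_fa_mid = np.zeros((G + 1, R, C))
    admix = np.zeros((G + 1, R, C))
    mdec_trigger_gen = np.full((R, C), -1, dtype=np.int64)
    fa_arrival = np.full((R, C), -1, dtype=np.int64)
    hg_arrival = np.full((R, C), -1, dtype=np.int64)
    hg_extinct = np.full((R, C), -1, dtype=np.int64)
    triggered = np.zeros((R, C), dtype=bool)

    off_region = (
        np.asarray(scen.competition_off_region, dtype=bool)
        if scen.competition_off_region is not None
        else np.zeros((R, C), dtype=bool)
    )

    N_hg = np.zeros((R, C))
    N_fa = np.zeros((R, C))
    if scen.hg_start_gen == 0:
        N_hg[scen.hg_origin] = scen.founder_size
    if fa_active and scen.fa_start_gen == 0:
        N_fa[scen.fa_origin] = scen.founder_size
    n_hg_end[0], n_fa_end[0] = N_hg, N_fa
    n_hg_mid[0], n_fa_mid[0] = N_hg, N_fa
    hg_arrival[N_hg >= OCCUPANCY_THRESHOLD] = 0
    fa_arrival[N_fa >= OCCUPANCY_THRESHOLD] = 0

    ramp = scen.admixture_time_model == "linear_ramp"
    if t_cohab is None:
        t_cohab = np.zeros((R, C))  # pilot pass: constant gamma

    for t in range(1, G + 1):
        if t == scen.hg_start_gen:
            N_hg[scen.hg_origin] += scen.founder_size
        if fa_active and t == scen.fa_start_gen:
            N_fa[scen.fa_origin] += scen.founder_size

        # growth (FA) and growth + competition (HG)
        K_fa_t = fa.K_at(t) if fa_active else 0.0
        K_hg_t = np.full((R, C), hg.K_at(t))
        in_off = off_region & (t < scen.competition_off_until_gen)
        K_hg_t[off_region & (t >= scen.competition_off_until_gen)] = 0.0
        comp_on = ~in_off
        if fa_active:
            N_fa = step_growth(N_fa, fa.r, np.where(land, K_fa_t, 0.0))
        N_hg = step_competition(
            N_hg,
            N_fa,
            hg.r,
            np.where(land, K_hg_t, 0.0),
            K_fa_t,
            c_max=scen.competition_cmax,
            competition_on=comp_on,
        )

        # admixture HG -> FA (gametic gene flow; densities unchanged)
        if fa_active and scen.gamma_max > 0:
            if ramp:
                g_t = gamma_at(t, scen, fa_arrival, t_cohab)
            else:
                g_t = gamma_at(t, scen, np.where(N_fa > 0, t, fa_arrival), t_cohab)
            A = step_admixture(N_hg, N_fa, g_t)
        else:
            A = np.zeros((R, C))
        admix[t] = A
        n_hg_mid[t], n_fa_mid[t] = N_hg, N_fa

        # Mdec trigger update (permanent per deme)
        if fa_active:
            newly = (~triggered) & (K_fa_t > 0) & (N_fa >= scen.mdec_threshold * K_fa_t)
            mdec_trigger_gen[newly] = t
            triggered |= newly
            m_fa_cur = np.where(triggered, fa.m / scen.mdec, fa.m)

        # migration; K = 0 demes absorb immigrants (hard cap at K)
        N_hg, _, _ = step_migration(N_hg, hg.m, land, n_nb)
        N_hg = np.where(np.where(land, K_hg_t, 0.0) > 0, N_hg, 0.0)
        if fa_active:
            N_fa, _, _ = step_migration(N_fa, m_fa_cur, land, n_nb)

        n_hg_end[t], n_fa_end[t] = N_hg, N_fa

        hg_arrival[(hg_arrival < 0) & (N_hg >= OCCUPANCY_THRESHOLD)] = t
        fa_arrival[(fa_arrival < 0) & (N_fa >= OCCUPANCY_THRESHOLD)] = t
        newly_ext = (hg_arrival >= 0) & (hg_extinct < 0) & (N_hg < OCCUPANCY_THRESHOLD)
        hg_extinct[newly_ext] = t

    return DemographyTrace(
        config=config,
        scenario=scen,
        hg=hg,
        fa=fa,
        n_hg_end=n_hg_end,
        n_fa_end=n_fa_end,
        n_hg_mid=n_hg_mid,
        n_fa_mid=n_fa_mid,
        admix=admix,
        mdec_trigger_gen=mdec_trigger_gen,
        fa_arrival_gen=fa_arrival,
        hg_arrival_gen=hg_arrival,
        hg_extinction_gen=hg_extinct,
        t_cohab=np.asarray(t_cohab, dtype=float),
    )


def run_forward(
    config: WorldConfig,
    hg: LayerParams,
    fa: Optional[LayerParams],
    scen: ScenarioConfig,
) -> DemographyTrace:
    """Run the deterministic forward demography and return its trace.

    Per-generation event order: growth -> competition -> admixture -> Mdec
    update -> migration.  Under the linear-ramp admixture models the local
    cohabitation length that anchors the ramp is endogenous: a pilot pass
    with constant gamma = gamma_max measures per-deme farmer arrival and
    hunter-gatherer extinction times, then the final pass runs the ramp
    anchored on T_cohab = extinction - arrival (one fixed-point iteration).
    """
    if scen.admixture_time_model == "linear_ramp" and scen.gamma_max > 0 and fa is not None:
        pilot_scen = ScenarioConfig(
            **{
                **{f: getattr(scen, f) for f in scen.__dataclass_fields__},
                "admixture_time_model": "constant",
            }
        )
        pilot = _forward_pass(config, hg, fa, pilot_scen, t_cohab=None)
        ext = np.where(
            pilot.hg_extinction_gen >= 0, pilot.hg_extinction_gen, config.n_generations
        )
        t_cohab = np.where(
            pilot.fa_arrival_gen >= 0,
            np.maximum(ext - pilot.fa_arrival_gen, 1),
            0,
        ).astype(float)
        return _forward_pass(config, hg, fa, scen, t_cohab=t_cohab)
    return _forward_pass(config, hg, fa, scen, t_cohab=None)


def colonization_complete_gen(trace: DemographyTrace, layer: str = "HG") -> int:
    """First generation at which every land deme of ``layer`` is occupied.

    Raises ``ValueError`` (reporting the unreached demes) if colonisation
    never completes within the simulated span.
    """
    arrival = trace.hg_arrival_gen if layer == "HG" else trace.fa_arrival_gen
    land = trace.config.land_mask
    unreached = land & (arrival < 0)
    if np.any(unreached):
        coords = np.argwhere(unreached)
        raise ValueError(
            f"{coords.shape[0]} land demes never colonised by {layer}; first: "
            f"{tuple(coords[0])}"
        )
    return int(arrival[land].max())
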