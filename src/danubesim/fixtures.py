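"""Synthetic maps, sampling schemes and pseudo-observed datasets.

Everything needed to exercise the full pipeline without external data is
generated here: a stylised Europe-like land raster with a Near-East
hunter-gatherer origin, an Anatolian farmer origin and a central-European
region mask; a small all-purpose lattice for fast experiments; sampling
schemes emulating the seven-population Danubian design (328 ancient mtDNA
lineages) and the northern-Greece serial samples; and pseudo-observed
statistic vectors simulated under known parameters.

The Europe-like raster is an explicit approximation: cell geometry,
coastlines and sampling locations are stylised, and the hunter-gatherer
layer parameters (r = 0.2, m = 0.15, K = 100) colonise it in roughly 500
generations, the calibration the demographic model is built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .coalescent import MutationModel, SamplingScheme, sample_population_sequences
from .sumstats import (
    GroupingPlan,
    gene_diversity,
    haplotype_count,
    mean_pairwise_diff,
    pairwise_phist,
    stats_vector,
)
from .world import LayerParams, ScenarioConfig, WorldConfig, run_forward

__all__ = [
    "MapFixture",
    "make_map",
    "make_sampling_scheme",
    "default_layers",
    "scenario_for",
    "simulate_scenario_stats",
    "make_pseudo_observed",
]

MAP_PRESETS = ("europe_like", "strip_1d", "island_pair", "mini")
SCHEME_PRESETS = (
    "danubian_7groups",
    "danubian_7groups_small",
    "greece_serial",
    "spc_serial",
)


@dataclass
class MapFixture:
    """A land raster plus the named places the schemes refer to."""

    name: str
    land: np.ndarray
    hg_origin: tuple[int, int]
    fa_origin: tuple[int, int]
    region_mask: np.ndarray  # central Europe: prolonged cohabitation + SN3/SN4
    locations: dict = field(default_factory=dict)
    n_generations: int = 1600
    fa_start_gen: int = 1200
    competition_off_until_gen: int = 1424
    roman_k_gen: Optional[int] = None  # farmer K jumps to 24,000 here
    dates: dict = field(default_factory=dict)  # sampling generations by label

    def __post_init__(self) -> None:
        if self.roman_k_gen is None:
            # 80 generations before the end on the full timeline, scaled
            # proportionally on compressed fixtures
            self.roman_k_gen = self.n_generations - max(
                int(round(80 * self.n_generations / 1600)), 5
            )

    def world_config(self, n_generations: Optional[int] = None) -> WorldConfig:
        return WorldConfig(
            land_mask=self.land,
            n_generations=self.n_generations if n_generations is None else n_generations,
        )


def _europe_land() -> tuple[np.ndarray, np.ndarray, dict]:
    """Stylised Europe on a 60 x 55 lattice of 100 km cells.

    Row 0 is the northern edge, column 0 the Atlantic edge.  The
    Mediterranean, Black Sea and Baltic force the colonisation front onto
    land corridors: Anatolia connects to the Balkans across a Bosporus
    land bridge, Scandinavia is reached through the far north-east, and
    Iberia through a Pyrenees corridor.
    """
    R, C = 60, 55
    land = np.zeros((R, C), dtype=bool)
    # mainland Europe and western Russia
    land[6:42, 2:55] = True
    # northern Russia shelf connecting to Fennoscandia
    land[0:6, 33:55] = True
    # Fennoscandia, separated from the mainland by the Baltic
    land[0:10, 14:33] = True
    land[10:14, 20:28] = False  # Baltic sea
    land[8:10, 14:20] = True
    land[6:14, 14:20] = False  # Skagerrak gap: Scandinavia only via the NE
    land[0:6, 28:33] = True  # Finland corridor
    # Norwegian coastal arm, reached around the top of the Gulf of Bothnia
    land[0:2, 3:14] = True
    land[2:13, 3:6] = True
    land[5:14, 6:14] = False  # Norwegian Sea / North Sea
    land[6:14, 2:3] = False
    land[13, 3:6] = False
    # Atlantic margin
    land[:, 0:2] = False
    # Mediterranean basin
    land[42:60, :] = False
    # Iberia behind a Pyrenees corridor
    land[43:53, 2:13] = True
    land[42, 2:55] = False
    land[42, 6:9] = True  # Pyrenees corridor
    # Italy
    land[42, 22:26] = True
    land[43:52, 22:26] = True
    # Balkans and Greece
    land[42, 29:37] = True
    land[43:54, 29:37] = True
    land[50:54, 29:31] = False  # Ionian indentation
    # Anatolia and the Levant
    land[44:51, 40:55] = True
    land[45:47, 36:40] = True  # Bosporus land bridge
    land[51:58, 47:55] = True  # Levant / Mesopotamia
    # Black Sea between the Pontic steppe and Anatolia
    land[38:44, 40:49] = False
    land[36:38, 41:47] = False

    region = np.zeros((R, C), dtype=bool)
    region[12:28, 14:30] = True  # central Europe
    region &= land

    locations = {
        "hg_origin": (54, 50),  # Near East (P)
        "fa_origin": (46, 49),  # eastern Anatolia (N)
        "northern_greece": (46, 33),
        "balkans": (38, 32),
        "central_europe": (20, 22),
        "iberia_tip": (52, 3),
        "north_cape": (0, 15),
    }
    return land, region, locations


def make_map(preset: str, seed: int = 0) -> MapFixture:
    """Build one of the packaged map fixtures (deterministic per preset)."""
    if preset == "europe_like":
        land, region, loc = _europe_land()
        return MapFixture(
            name=preset,
            land=land,
            hg_origin=loc["hg_origin"],
            fa_origin=loc["fa_origin"],
            region_mask=region,
            locations=loc,
            n_generations=1600,
            fa_start_gen=1200,
            competition_off_until_gen=1424,
            dates={
                "hg_ce": 1282,
                "en": {"greece": 1270, "balkans": 1290, "central_europe": 1320},
                "ln": {"greece": 1342, "balkans": 1352, "central_europe": 1362},
                "modern": 1600,
            },
        )
    if preset == "strip_1d":
        land = np.ones((1, 30), dtype=bool)
        region = np.zeros_like(land)
        region[0, 20:] = True
        return MapFixture(
            name=preset,
            land=land,
            hg_origin=(0, 0),
            fa_origin=(0, 0),
            region_mask=region,
            locations={
                "far_end": (0, 29),
                "northern_greece": (0, 5),
                "balkans": (0, 15),
                "central_europe": (0, 25),
            },
            n_generations=400,
            fa_start_gen=150,
            competition_off_until_gen=300,
            dates={
                "hg_ce": 240,
                "en": {"greece": 215, "balkans": 230, "central_europe": 245},
                "ln": {"greece": 265, "balkans": 270, "central_europe": 280},
                "modern": 400,
            },
        )
    if preset == "island_pair":
        land = np.zeros((5, 9), dtype=bool)
        land[1:4, 1:4] = True
        land[1:4, 6:8] = True
        region = np.zeros_like(land)
        return MapFixture(
            name=preset,
            land=land,
            hg_origin=(2, 2),
            fa_origin=(2, 2),
            region_mask=region,
            locations={"island_a": (2, 2), "island_b": (2, 6)},
            n_generations=200,
            fa_start_gen=100,
            competition_off_until_gen=150,
        )
    if preset == "mini":
        land = np.ones((8, 8), dtype=bool)
        land[0:2, 0:2] = False  # a corner of sea
        region = np.zeros_like(land)
        region[2:8, 0:4] = True
        region &= land
        return MapFixture(
            name=preset,
            land=land,
            hg_origin=(6, 6),
            fa_origin=(5, 6),
            region_mask=region,
            locations={
                "northern_greece": (5, 5),
                "balkans": (4, 4),
                "central_europe": (4, 1),
            },
            n_generations=170,
            fa_start_gen=60,
            competition_off_until_gen=140,
            dates={
                "hg_ce": 100,
                "en": {"greece": 85, "balkans": 95, "central_europe": 105},
                "ln": {"greece": 130, "balkans": 133, "central_europe": 136},
                "modern": 170,
            },
        )
    raise ValueError(f"unknown map preset {preset!r} (choose from {MAP_PRESETS})")


def default_layers(K_fa: float = 750.0, m_fa: float = 0.4, fixture: Optional[MapFixture] = None):
    """Table-1 layer parameters: HG fixed, FA with the requested K and m.

    The farmer carrying capacity jumps to 24,000 near the end of the run
    (Roman-period densities; 80 generations before the end on the full
    timeline, proportionally earlier on compressed fixtures).
    """
    hg = LayerParams.constant_K("HG", r=0.2, m=0.15, K=100.0)
    boost = 1520 if fixture is None else fixture.roman_k_gen
    fa = LayerParams(
        layer_id="FA",
        r=0.53,
        m=m_fa,
        K_schedule=((0, K_fa), (boost, 24000.0)),
    )
    return hg, fa


def scenario_for(
    fixture: MapFixture,
    scenario_id: str,
    gamma: float = 0.0,
    mdec: float = 1.0,
) -> ScenarioConfig:
    """ScenarioConfig for SN1-SN4 or SPC on the given map fixture."""
    return ScenarioConfig.preset(
        scenario_id,
        hg_origin=fixture.hg_origin,
        fa_origin=fixture.fa_origin,
        region_mask=fixture.region_mask,
        gamma_max=gamma,
        mdec=mdec,
        fa_start_gen=fixture.fa_start_gen,
        competition_off_region=fixture.region_mask,
        competition_off_until_gen=fixture.competition_off_until_gen,
    )


def _scheme_rows(fixture: MapFixture, sizes: dict) -> list[dict]:
    d = fixture.dates
    loc = fixture.locations
    areas = {
        "greece": loc["northern_greece"],
        "balkans": loc["balkans"],
        "central_europe": loc["central_europe"],
    }
    rows = [
        dict(
            sample_id="HG_CE",
            row=areas["central_europe"][0],
            col=areas["central_europe"][1],
            generation=d["hg_ce"],
            layer="HG",
            n=sizes["HG_CE"],
            group_id="HG_CE",
        )
    ]
    for area, deme in areas.items():
        gen_e = d["en"][area]
        gen_l = d["ln"][area]
        rows.append(
            dict(
                sample_id=f"EN_{area}",
                row=deme[0],
                col=deme[1],
                generation=gen_e,
                layer="FA",
                n=sizes[f"EN_{area}"],
                group_id=f"EN_{area}",
            )
        )
        rows.append(
            dict(
                sample_id=f"LN_{area}",
                row=deme[0],
                col=deme[1],
                generation=gen_l,
                layer="FA",
                n=sizes[f"LN_{area}"],
                group_id=f"LN_{area}",
            )
        )
    return rows


def make_sampling_scheme(preset: str, fixture: MapFixture) -> SamplingScheme:
    """Build a sampling scheme preset on a map fixture.

    ``danubian_7groups`` reproduces the seven-population design: 328
    ancient lineages, 19 hunter-gatherers, Early Neolithic farmers from
    Greece (20), the Balkans (44) and central Europe (113), and Middle-Late
    Neolithic farmers from Greece (25), the Balkans (39) and central Europe
    (68); regional totals 45 (Greece), 83 (Balkans), 200 (central Europe).
    ``greece_serial`` adds 319 modern lineages to the two northern-Greece
    serial samples; ``spc_serial`` is the serial pair alone.  The ``_small``
    variant keeps the seven-group structure at n = 8 per group for fast
    reference tables.
    """
    loc = fixture.locations
    d = fixture.dates
    if preset == "danubian_7groups":
        sizes = {
            "HG_CE": 19,
            "EN_greece": 20,
            "EN_balkans": 44,
            "EN_central_europe": 113,
            "LN_greece": 25,
            "LN_balkans": 39,
            "LN_central_europe": 68,
        }
        return SamplingScheme.from_rows(_scheme_rows(fixture, sizes))
    if preset == "danubian_7groups_small":
        sizes = {
            g: 8
            for g in (
                "HG_CE",
                "EN_greece",
                "EN_balkans",
                "EN_central_europe",
                "LN_greece",
                "LN_balkans",
                "LN_central_europe",
            )
        }
        return SamplingScheme.from_rows(_scheme_rows(fixture, sizes))
    if preset in ("greece_serial", "spc_serial"):
        deme = loc["northern_greece"]
        rows = [
            dict(
                sample_id="EN_greece",
                row=deme[0],
                col=deme[1],
                generation=d["en"]["greece"],
                layer="FA",
                n=20,
                group_id="older",
            ),
            dict(
                sample_id="MLFN_greece",
                row=deme[0],
                col=deme[1],
                generation=d["ln"]["greece"],
                layer="FA",
                n=25,
                group_id="younger",
            ),
        ]
        if preset == "greece_serial":
            rows.append(
                dict(
                    sample_id="modern_greece",
                    row=deme[0],
                    col=deme[1],
                    generation=d["modern"],
                    layer="FA",
                    n=319,
                    group_id="modern",
                )
            )
        return SamplingScheme.from_rows(rows)
    raise ValueError(f"unknown scheme preset {preset!r} (choose from {SCHEME_PRESETS})")


# ---------------------------------------------------------------------------
# Pipeline glue: one simulation = forward demography + coalescent + stats
# ---------------------------------------------------------------------------


def simulate_scenario_stats(
    fixture: MapFixture,
    scheme: SamplingScheme,
    scenario_id: str,
    params: dict,
    seed: int,
    model: Optional[MutationModel] = None,
    plan: Optional[GroupingPlan] = None,
    trace_cache: Optional[dict] = None,
) -> np.ndarray:
    """Run one full simulation and summarise it by the 14-statistic vector.

    ``params`` holds the varying parameters: ``gamma``, ``K_FA`` and
    ``Mdec`` (``m_FA`` optionally overrides the fixed farmer migration
    rate).  The forward demography is deterministic, so identical
    parameter draws can share a trace via ``trace_cache`` (keyed on the
    rounded parameter values).
    """
    model = model or MutationModel()
    plan = plan or GroupingPlan.danubian()
    trace = _trace_for(fixture, scenario_id, params, trace_cache)
    samples = sample_population_sequences(scheme, trace, model, seed)
    groups = {s.group_id: s for s in samples}
    return stats_vector(groups, plan)


def _trace_for(fixture, scenario_id, params, trace_cache=None):
    key = (
        scenario_id,
        round(float(params.get("gamma", 0.0)), 10),
        round(float(params.get("K_FA", 750.0)), 10),
        round(float(params.get("Mdec", 1.0)), 10),
        round(float(params.get("m_FA", 0.4)), 10),
    )
    if trace_cache is not None and key in trace_cache:
        return trace_cache[key]
    hg, fa = default_layers(
        K_fa=float(params.get("K_FA", 750.0)),
        m_fa=float(params.get("m_FA", 0.4)),
        fixture=fixture,
    )
    scen = scenario_for(
        fixture,
        scenario_id,
        gamma=float(params.get("gamma", 0.0)),
        mdec=float(params.get("Mdec", 1.0)),
    )
    trace = run_forward(fixture.world_config(), hg, fa, scen)
    if trace_cache is not None:
        trace_cache[key] = trace
    return trace


def make_serial_pair(
    fixture: MapFixture,
    params: dict,
    seed: int,
    scheme: Optional[SamplingScheme] = None,
    model: Optional[MutationModel] = None,
) -> tuple:
    """Simulate one (older, younger) serial sample pair under continuity."""
    scheme = scheme or make_sampling_scheme("spc_serial", fixture)
    model = model or MutationModel()
    trace = _trace_for(
        fixture,
        "SPC",
        dict(
            gamma=0.0,
            Mdec=1.0,
            K_FA=float(params.get("K_FA", 750.0)),
            m_FA=float(params.get("m_FA", 0.4)),
        ),
    )
    samples = sample_population_sequences(scheme, trace, model, seed)
    d = {s.group_id: s for s in samples}
    return d["older"], d["younger"]


def spc_simulator(
    fixture: MapFixture,
    scheme: Optional[SamplingScheme] = None,
    model: Optional[MutationModel] = None,
):
    """Continuity-model simulator for the SPC test on this fixture.

    Returns ``sim(params, seed) -> ((H, pi, k) of the older sample, serial
    PhiST)``; PhiST is returned unclamped (the test applies its reporting
    convention).
    """

    def sim(params: dict, seed: int):
        older, younger = make_serial_pair(
            fixture, params, seed, scheme=scheme, model=model
        )
        stats3 = (
            gene_diversity(older),
            mean_pairwise_diff(older),
            float(haplotype_count(older)),
        )
        fst = pairwise_phist(older, younger, clamp=False)
        return stats3, fst

    return sim


def make_pseudo_observed(
    scenario_id: str,
    true_params: dict,
    fixture: MapFixture,
    seed: int,
    scheme: Optional[SamplingScheme] = None,
    model: Optional[MutationModel] = None,
    plan: Optional[GroupingPlan] = None,
    return_samples: bool = False,
):
    """One full simulation under known parameters, treated as observed data."""
    scheme = scheme or make_sampling_scheme(
        "danubian_7groups" if fixture.name == "europe_like" else "danubian_7groups_small",
        fixture,
    )
    model = model or MutationModel()
    plan = plan or GroupingPlan.danubian()
    trace = _trace_for(fixture, scenario_id, true_params)
    samples = sample_population_sequences(scheme, trace, model, seed)
    groups = {s.group_id: s for s in samples}
    stats = stats_vector(groups, plan)
    if return_samples:
        return stats, samples
    return stats
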