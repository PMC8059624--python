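"""Synthetic two-region borealization surveys with known ground truth.

The generator emulates the structure of a high-latitude shelf-sea
ecosystem survey: two zoogeographic regions (an Arctic and a boreal one)
share a species pool of demersal fish, with an Arctic pool of smaller,
benthivore specialists and a boreal pool of larger, more piscivorous
generalists.  Over the survey years the occupancy of boreal species at
Arctic stations rises linearly (borealization), so every downstream
statistic — diversity indices, functional variance PC1, trend models —
has a constructed expectation it can be validated against.

All magnitudes (occupancy baselines, lognormal abundance parameters,
trait effect sizes) are invented defaults exposed in the config; they
aim for a clear but noisy signal at survey scale, not for realism of any
particular sea.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .traits import FUZZY, QUANTITATIVE, TraitMeta, TraitTable
from .diversity import CommunityMatrix

logger = logging.getLogger(__name__)

ARCTIC = "arctic"
BOREAL = "boreal"


@dataclass
class QuantTraitSpec:
    """Pool-specific normal distributions for one quantitative trait."""

    name: str
    group: str  # trait category: habitat, life_history, body_size, feeding, foodweb
    mean_arctic: float
    mean_boreal: float
    sd_arctic: float
    sd_boreal: float


@dataclass
class FuzzyTraitSpec:
    """Pool-specific Dirichlet memberships for one fuzzy-coded trait."""

    name: str
    group: str
    categories: list[str]
    alpha_arctic: list[float]
    alpha_boreal: list[float]


def default_trait_spec(
    sd_arctic: float = 0.6, sd_boreal: float = 1.0
) -> list[QuantTraitSpec | FuzzyTraitSpec]:
    """15 traits in five categories; boreal species are larger, mature
    later, sit higher in the food web and feed more on fish, while
    Arctic species are benthivore specialists with larger offspring."""
    q = lambda name, group, gap: QuantTraitSpec(name, group, 0.0, gap, sd_arctic, sd_boreal)
    return [
        q("depth_preference", "habitat", 0.0),
        q("temperature_affinity", "habitat", 1.2),
        FuzzyTraitSpec(
            "habitat_use", "habitat",
            ["demersal", "benthopelagic", "pelagic"],
            [8.0, 1.5, 0.5], [3.0, 4.0, 3.0],
        ),
        q("age_at_maturity", "life_history", 1.2),
        q("fecundity", "life_history", 1.0),
        q("lifespan", "life_history", 0.5),
        q("offspring_size", "life_history", -1.0),
        q("max_length", "body_size", 1.2),
        q("growth_rate", "body_size", 1.0),
        FuzzyTraitSpec(
            "diet", "feeding",
            ["benthivory", "piscivory", "planktivory"],
            [8.0, 1.0, 1.0], [2.0, 5.0, 3.0],
        ),
        q("trophic_level", "feeding", 1.0),
        q("prey_size_ratio", "feeding", 0.8),
        q("fish_prey_links", "foodweb", 1.2),
        q("bird_mammal_predator_links", "foodweb", 1.0),
        q("omnivory_index", "foodweb", 0.5),
    ]


def null_trait_spec(sd: float = 0.8) -> list[QuantTraitSpec | FuzzyTraitSpec]:
    """Identical pool distributions (no Arctic/boreal contrast)."""
    spec = default_trait_spec(sd_arctic=sd, sd_boreal=sd)
    out: list[QuantTraitSpec | FuzzyTraitSpec] = []
    for t in spec:
        if isinstance(t, QuantTraitSpec):
            out.append(QuantTraitSpec(t.name, t.group, 0.0, 0.0, sd, sd))
        else:
            alpha = [3.0] * len(t.categories)
            out.append(FuzzyTraitSpec(t.name, t.group, t.categories, alpha, alpha))
    return out


@dataclass
class SyntheticConfig:
    """Full parameterization of the two-pool borealization generator.

    Defaults: 20 Arctic + 29 boreal species (a 49-species pool), 14
    survey years, 20 stations per region-year, boreal occupancy at
    Arctic stations rising by ``borealization_rate`` per year from
    ``occupancy_cross``.  ``arctic_decline_rate`` is a local-extinction
    knob (per-year drop of Arctic-species occupancy in the Arctic,
    default off).
    """

    n_arctic_species: int = 20
    n_boreal_species: int = 29
    n_stations_per_region_year: int = 20
    first_year: int = 2004
    last_year: int = 2017
    borealization_rate: float = 0.05
    occupancy_within: float = 0.5
    occupancy_cross: float = 0.02
    arctic_decline_rate: float = 0.0
    abundance_mu: float = 0.0
    abundance_sigma: float = 0.8
    trait_spec: list = field(default_factory=default_trait_spec)
    station_year_override: dict = field(default_factory=dict)  # {(region, year): n}
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_arctic_species, self.n_boreal_species) < 1:
            raise ValueError("species counts must be positive")
        if self.n_stations_per_region_year < 1:
            raise ValueError("station count must be positive")
        if self.last_year < self.first_year:
            raise ValueError("empty year range")

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    @property
    def n_species(self) -> int:
        return self.n_arctic_species + self.n_boreal_species

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d["trait_spec"] = [
            {"kind": type(t).__name__, **asdict(t)} for t in self.trait_spec
        ]
        d["station_year_override"] = {
            f"{r}:{y}": n for (r, y), n in self.station_year_override.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        spec = []
        for t in d.pop("trait_spec", []):
            kind = t.pop("kind")
            spec.append(QuantTraitSpec(**t) if kind == "QuantTraitSpec" else FuzzyTraitSpec(**t))
        override = {
            (k.split(":")[0], int(k.split(":")[1])): n
            for k, n in d.pop("station_year_override", {}).items()
        }
        return cls(trait_spec=spec or default_trait_spec(),
                   station_year_override=override, **d)


def generate_species_pool(cfg: SyntheticConfig) -> tuple[TraitTable, pd.Series]:
    """Draw the species pool and its trait table.

    Returns the TraitTable and a species-indexed pool-label Series
    ('arctic'/'boreal').  Quantitative traits come from pool-specific
    normals, fuzzy traits from pool-specific Dirichlets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    ids = [f"A{i:02d}" for i in range(cfg.n_arctic_species)] + [
        f"B{i:02d}" for i in range(cfg.n_boreal_species)
    ]
    pools = pd.Series(
        [ARCTIC] * cfg.n_arctic_species + [BOREAL] * cfg.n_boreal_species,
        index=ids, name="pool",
    )
    cols: dict[str, np.ndarray] = {}
    metas: list[TraitMeta] = []
    na, nb = cfg.n_arctic_species, cfg.n_boreal_species
    for t in cfg.trait_spec:
        if isinstance(t, QuantTraitSpec):
            vals = np.concatenate(
                [
                    rng.normal(t.mean_arctic, t.sd_arctic, size=na),
                    rng.normal(t.mean_boreal, t.sd_boreal, size=nb),
                ]
            )
            cols[t.name] = vals
            metas.append(TraitMeta(name=t.name, type=QUANTITATIVE))
        else:
            mem = np.vstack(
                [
                    rng.dirichlet(t.alpha_arctic, size=na),
                    rng.dirichlet(t.alpha_boreal, size=nb),
                ]
            )
            for k, cat in enumerate(t.categories):
                cols[f"{t.name}.{cat}"] = mem[:, k]
            metas.append(TraitMeta(name=t.name, type=FUZZY, categories=list(t.categories)))
    values = pd.DataFrame(cols, index=ids)
    values.index.name = "species_id"
    return TraitTable(species_ids=ids, values=values, trait_meta=metas), pools


def occupancy_probability(
    cfg: SyntheticConfig, species_pool: str, station_region: str, year: int
) -> float:
    """Bernoulli presence probability of one species at one station."""
    t = year - cfg.first_year
    if species_pool == station_region:
        p = cfg.occupancy_within
        if species_pool == ARCTIC and cfg.arctic_decline_rate > 0:
            p -= cfg.arctic_decline_rate * t
    elif species_pool == BOREAL and station_region == ARCTIC:
        p = cfg.occupancy_cross + cfg.borealization_rate * t
    else:  # arctic species straying into the boreal region: stationary
        p = cfg.occupancy_cross
    return float(np.clip(p, 0.0, 1.0))


def _station_grid(region: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Jittered grid of (lat, lon) inside the region's rectangle."""
    lat_lo, lat_hi = (75.5, 79.5) if region == ARCTIC else (70.0, 74.0)
    lon_lo, lon_hi = 20.0, 50.0
    ncol = int(np.ceil(np.sqrt(n)))
    nrow = int(np.ceil(n / ncol))
    lats = np.linspace(lat_lo, lat_hi, nrow)
    lons = np.linspace(lon_lo, lon_hi, ncol)
    grid = np.array([(la, lo) for la in lats for lo in lons])[:n]
    jitter = rng.uniform(-0.1, 0.1, size=grid.shape)
    return grid + jitter


def generate_survey(cfg: SyntheticConfig, pools: pd.Series) -> CommunityMatrix:
    """Simulate the station x species abundance table over all years.

    Presence is Bernoulli(occupancy); abundances of present species are
    lognormal(mu, sigma).  A station that draws no species is redrawn up
    to 100 times, then assigned the single most likely species (warned).

    Each (year, region) cell uses its own child RNG stream, so changing
    the borealization rate leaves the boreal-region draws bit-identical.
    """
    species = list(pools.index)
    pool_arr = pools.to_numpy()
    rows, meta_rows, ids = [], [], []
    counter = 0
    for year in cfg.years:
        for ridx, region in enumerate((ARCTIC, BOREAL)):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(cfg.seed), 1, year - cfg.first_year, ridx])
            )
            n_st = cfg.station_year_override.get((region, year), cfg.n_stations_per_region_year)
            coords = _station_grid(region, n_st, rng)
            probs = np.array(
                [occupancy_probability(cfg, pl, region, year) for pl in pool_arr]
            )
            for lat, lon in coords:
                for _ in range(100):
                    present = rng.random(len(species)) < probs
                    if present.any():
                        break
                else:
                    logger.warning(
                        "station in %s/%d drew no species after 100 tries; "
                        "seeding the most likely species", region, year,
                    )
                    present = np.zeros(len(species), dtype=bool)
                    present[int(np.argmax(probs))] = True
                ab = np.zeros(len(species))
                ab[present] = rng.lognormal(
                    cfg.abundance_mu, cfg.abundance_sigma, size=int(present.sum())
                )
                rows.append(ab)
                meta_rows.append({"region": region, "year": year, "lat": lat, "lon": lon})
                ids.append(f"st{counter:05d}")
                counter += 1
    abundance = pd.DataFrame(np.asarray(rows), index=ids, columns=species)
    meta = pd.DataFrame(meta_rows, index=ids)
    return CommunityMatrix(abundance=abundance, station_meta=meta)


def ground_truth(cfg: SyntheticConfig) -> dict:
    """Constructed expectations used by validation harnesses.

    Returns pool trait-mean gaps, the boreal-in-Arctic occupancy
    trajectory and qualitative trend descriptors implied by the config.
    """
    gaps = {
        t.name: t.mean_boreal - t.mean_arctic
        for t in cfg.trait_spec
        if isinstance(t, QuantTraitSpec)
    }
    contrasted = any(abs(g) > 0 for g in gaps.values()) or any(
        isinstance(t, FuzzyTraitSpec) and t.alpha_arctic != t.alpha_boreal
        for t in cfg.trait_spec
    )
    occ = {
        y: occupancy_probability(cfg, BOREAL, ARCTIC, y) for y in cfg.years
    }
    increasing = cfg.borealization_rate > 0 and contrasted
    if increasing and cfg.arctic_decline_rate > 0:
        arctic_trend = "increase_then_decline"
    elif increasing:
        arctic_trend = "increasing"
    else:
        arctic_trend = "flat"
    return {
        "trait_mean_gaps": gaps,
        "pools_contrasted": contrasted,
        "boreal_occupancy_in_arctic": occ,
        "arctic_functional_variance_trend": arctic_trend,
        "boreal_functional_variance_trend": "flat",
        "years": cfg.years,
    }
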