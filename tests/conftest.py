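"""Shared fixtures: small hand-built trait tables and random generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from funcvar.traits import FUZZY, QUANTITATIVE, TraitMeta, TraitTable
from funcvar.diversity import CommunityMatrix


def make_trait_table(values: dict[str, list], metas: list[TraitMeta],
                     species: list[str] | None = None) -> TraitTable:
    n = len(next(iter(values.values())))
    species = species or [f"sp{i}" for i in range(n)]
    df = pd.DataFrame(values, index=species)
    return TraitTable(species_ids=species, values=df, trait_meta=metas)


def random_trait_table(rng: np.random.Generator, n_species: int,
                       with_missing: bool = False) -> TraitTable:
    """Mixed-type random trait table: 2 quantitative, 1 ordinal, 1 fuzzy."""
    species = [f"sp{i}" for i in range(n_species)]
    q1 = rng.normal(0, 2, n_species)
    q2 = rng.uniform(-5, 5, n_species)
    o1 = rng.integers(1, 5, n_species).astype(float)
    mem = rng.dirichlet([2.0, 3.0, 1.0], size=n_species)
    if with_missing and n_species > 3:
        q1[rng.integers(0, n_species)] = np.nan
        mem[rng.integers(0, n_species)] = np.nan
    values = {
        "size": q1,
        "depth": q2,
        "motility": o1,
        "diet.benthos": mem[:, 0],
        "diet.fish": mem[:, 1],
        "diet.plankton": mem[:, 2],
    }
    metas = [
        TraitMeta(name="size", type=QUANTITATIVE, weight=1.0),
        TraitMeta(name="depth", type=QUANTITATIVE, weight=2.0),
        TraitMeta(name="motility", type="ordinal", weight=1.0),
        TraitMeta(name="diet", type=FUZZY,
                  categories=["benthos", "fish", "plankton"], weight=1.5),
    ]
    return make_trait_table(values, metas, species)


def make_community(abundance: np.ndarray, species: list[str],
                   regions=None, years=None) -> CommunityMatrix:
    n = abundance.shape[0]
    ids = [f"st{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "region": regions if regions is not None else ["arctic"] * n,
            "year": years if years is not None else [2004] * n,
            "lat": np.linspace(70, 80, n),
            "lon": np.linspace(20, 50, n),
        },
        index=ids,
    )
    ab = pd.DataFrame(np.asarray(abundance, dtype=float), index=ids, columns=species)
    return CommunityMatrix(abundance=ab, station_meta=meta)


def make_regression_table(rng, n=200, n_years=5, beta=(0.1, 2.0, -0.5, 0.3),
                          year_sd=0.0, noise_sd=0.0,
                          regions=("arctic", "boreal")) -> pd.DataFrame:
    """Station table with known fixed effects (intercept, S, J, FRic),
    year-level random shifts and iid noise, for model-recovery checks."""
    years = rng.integers(0, n_years, n) + 2004
    S = rng.integers(1, 30, n).astype(float)
    J = rng.uniform(0, 0.8, n)
    FRic = rng.uniform(0, 5, n)
    year_effects = dict(zip(range(2004, 2004 + n_years),
                            rng.normal(0, year_sd, n_years)))
    q = (beta[0] + beta[1] * S + beta[2] * J + beta[3] * FRic
         + np.array([year_effects[y] for y in years])
         + rng.normal(0, noise_sd, n))
    return pd.DataFrame(
        {
            "Q": q, "S": S, "J": J, "FRic": FRic, "year": years,
            "region": rng.choice(list(regions), n),
            "lat": rng.uniform(70, 80, n), "lon": rng.uniform(20, 50, n),
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_table():
    """3 species x 2 quantitative traits, for hand-checked Gower/UPGMA."""
    return make_trait_table(
        {"size": [1.0, 2.0, 4.0], "depth": [0.0, 10.0, 5.0]},
        [TraitMeta(name="size", type=QUANTITATIVE),
         TraitMeta(name="depth", type=QUANTITATIVE)],
        species=["A", "B", "C"],
    )
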