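"""Per-station taxonomic and functional diversity indices.

For each sampled community (station) the module computes species
richness S, Shannon entropy H (natural log), the evenness variant
J = H / (ln S + 1), dendrogram-based functional richness FRic (total
branch length of the minimal subtree spanning the species present) and
functional dispersion as Rao's quadratic entropy
Q = sum_i sum_j p_i p_j d_ij, with p the relative abundances and d the
Gower distance between species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traits import Dendrogram, DistanceMatrix, TraitTable, gower_distance, upgma

logger = logging.getLogger(__name__)

META_COLS = ("region", "year", "lat", "lon")


@dataclass
class CommunityMatrix:
    """Station x species abundances plus station metadata.

    ``abundance`` rows are stations, columns are species (non-negative
    reals); ``station_meta`` carries region label, integer year and
    lat/lon in degrees for the same station index.
    """

    abundance: pd.DataFrame
    station_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.abundance.index) != list(self.station_meta.index):
            raise ValueError("abundance and station_meta indices differ")
        for c in META_COLS:
            if c not in self.station_meta.columns:
                raise ValueError(f"station_meta lacks required column {c!r}")
        a = self.abundance.to_numpy(dtype=float)
        if np.any(a < 0):
            raise ValueError("negative abundance")

    @property
    def station_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def drop_empty_stations(self) -> "CommunityMatrix":
        """Remove stations with zero total abundance (logged)."""
        tot = self.abundance.sum(axis=1)
        keep = tot > 0
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("dropping %d station(s) with zero total abundance", n_drop)
        return CommunityMatrix(self.abundance.loc[keep], self.station_meta.loc[keep])


def read_community_csv(path: str) -> CommunityMatrix:
    """Wide-format reader: one row per station; species columns plus
    ``region``, ``year``, ``lat``, ``lon`` metadata columns; first column
    ``station_id``."""
    df = pd.read_csv(path)
    if df.columns[0] != "station_id":
        raise ValueError("first column of the abundance CSV must be 'station_id'")
    df = df.set_index("station_id")
    meta = df[list(META_COLS)].copy()
    meta["year"] = meta["year"].astype(int)
    ab = df.drop(columns=list(META_COLS)).astype(float)
    return CommunityMatrix(abundance=ab, station_meta=meta)


def read_community_long(path: str, stations_path: str) -> CommunityMatrix:
    """Long-format reader: (station_id, species_id, abundance) triples
    plus a stations CSV with station_id, region, year, lat, lon."""
    long = pd.read_csv(path)
    meta = pd.read_csv(stations_path).set_index("station_id")
    meta["year"] = meta["year"].astype(int)
    ab = (
        long.pivot_table(
            index="station_id", columns="species_id", values="abundance", fill_value=0.0,
            aggfunc="sum",
        )
        .reindex(meta.index)
        .fillna(0.0)
    )
    ab.columns.name = None
    return CommunityMatrix(abundance=ab.astype(float), station_meta=meta[list(META_COLS)])


def write_community_csv(cm: CommunityMatrix, path: str) -> None:
    out = pd.concat([cm.station_meta[list(META_COLS)], cm.abundance], axis=1)
    out.index.name = "station_id"
    out.to_csv(path)


def relative_abundance(row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative abundances over the species present in one station.

    Returns (p, present_mask): p sums to one over the species with
    strictly positive abundance; zero-abundance species are dropped.
    """
    a = np.asarray(row, dtype=float)
    present = a > 0
    total = a[present].sum()
    if total <= 0:
        raise ValueError("station has no positive abundance")
    return a[present] / total, present


def species_richness(row: np.ndarray) -> int:
    """Count of species with strictly positive abundance."""
    return int(np.count_nonzero(np.asarray(row, dtype=float) > 0))


def shannon(p: np.ndarray, base: float | None = None) -> float:
    """Shannon entropy of a probability vector (natural log by default)."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def pielou_evenness(row: np.ndarray, base: float | None = None) -> float:
    """Evenness J = H / (log S + 1).

    This is the regularized variant with the +1 in the denominator (not
    the classical H / log S), which is finite at S = 1 where it equals 0.
    Natural log by default; ``base`` switches both H and the denominator.
    """
    p, _ = relative_abundance(row)
    s = len(p)
    h = shannon(p, base=base)
    log_s = np.log(s) if base is None else np.log(s) / np.log(base)
    return float(h / (log_s + 1.0))


def rao_q(p: np.ndarray, d: np.ndarray) -> float:
    """Rao's quadratic entropy Q = sum_ij p_i p_j d_ij.

    The full double sum over ordered pairs (no division by two); d must
    be the distance submatrix aligned with p.
    """
    p = np.asarray(p, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.shape != (len(p), len(p)):
        raise ValueError("p and d are misaligned")
    return float(p @ d @ p)


def functional_richness(present_ids: list[str], tree: Dendrogram) -> float:
    """Total branch length of the minimal subtree spanning the present leaves.

    Abundance-free: it grows as species with differing trait values are
    added.  A single species spans a degenerate subtree of length 0.
    """
    leaf_index = {s: i for i, s in enumerate(tree.leaf_ids)}
    try:
        wanted = frozenset(leaf_index[s] for s in present_ids)
    except KeyError as e:
        raise KeyError(f"species {e.args[0]!r} is not a leaf of the dendrogram") from None
    if len(wanted) <= 1:
        return 0.0
    sets = tree.leaf_sets()
    edges = tree.edge_lengths()
    total = 0.0
    for child, length in edges.items():
        below = sets[child] & wanted
        # edge is in the spanning subtree iff it separates some but not
        # all of the present leaves from the rest
        if below and below != wanted:
            total += length
    return float(total)


@dataclass
class DiversityResult:
    """Per-station indices and their per-region-per-year means."""

    per_station: pd.DataFrame  # index station_id; S, H, J, FRic, Q + metadata
    regional_means: pd.DataFrame  # region, year, mean of each index


def compute_diversity(
    cm: CommunityMatrix,
    tt: TraitTable,
    distance: DistanceMatrix | None = None,
    tree: Dendrogram | None = None,
) -> DiversityResult:
    """All five indices for every station, plus regional yearly means.

    The Gower distance and UPGMA dendrogram are computed once on the full
    species pool so station values are comparable across stations and
    years; they can be passed in to avoid recomputation.
    """
    if list(cm.species_ids) != list(tt.species_ids):
        raise ValueError("community matrix and trait table species do not align")
    cm = cm.drop_empty_stations()
    if distance is None:
        distance = gower_distance(tt)
    if tree is None:
        tree = upgma(distance)
    species = np.asarray(cm.species_ids)
    rows = []
    for sid, row in zip(cm.station_ids, cm.abundance.to_numpy(dtype=float)):
        p, present = relative_abundance(row)
        ids = list(species[present])
        d_sub = distance.values[np.ix_(np.flatnonzero(present), np.flatnonzero(present))]
        rows.append(
            {
                "station_id": sid,
                "S": species_richness(row),
                "H": shannon(p),
                "J": pielou_evenness(row),
                "FRic": functional_richness(ids, tree),
                "Q": rao_q(p, d_sub),
            }
        )
    per_station = pd.DataFrame(rows).set_index("station_id")
    per_station = pd.concat([cm.station_meta[list(META_COLS)], per_station], axis=1)
    regional = (
        per_station.groupby(["region", "year"], sort=True)[["S", "H", "J", "FRic", "Q"]]
        .mean()
        .reset_index()
    )
    return DiversityResult(per_station=per_station, regional_means=regional)
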