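"""Trait tables, fuzzy coding, Gower distance and the UPGMA trait dendrogram.

Species are characterized by mixed-type functional traits: quantitative
(e.g. maximum body length), ordinal (rank-coded and then treated as
quantitative) and fuzzy-coded categorical traits (e.g. diet expressed as
graded memberships over prey categories summing to one per species).
This module ingests and validates such tables, standardizes them,
computes the Gower dissimilarity between species and builds the
average-linkage (UPGMA) dendrogram that underlies the branch-length
flavour of functional richness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

QUANTITATIVE = "quantitative"
ORDINAL = "ordinal"
FUZZY = "fuzzy"

_FUZZY_SUM_TOL = 1e-6


@dataclass
class TraitMeta:
    """Metadata for one trait: its type, fuzzy categories and Gower weight."""

    name: str
    type: str
    categories: list[str] = field(default_factory=list)
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in (QUANTITATIVE, ORDINAL, FUZZY):
            raise ValueError(f"unknown trait type {self.type!r} for trait {self.name!r}")
        if self.weight <= 0:
            raise ValueError(f"trait {self.name!r} has non-positive weight {self.weight}")
        if self.type == FUZZY and len(self.categories) < 2:
            raise ValueError(f"fuzzy trait {self.name!r} needs >= 2 categories")

    @property
    def columns(self) -> list[str]:
        """CSV column names this trait occupies."""
        if self.type == FUZZY:
            return [f"{self.name}.{c}" for c in self.categories]
        return [self.name]


@dataclass
class TraitTable:
    """Species x trait values plus per-trait metadata.

    ``values`` holds one column per quantitative/ordinal trait and one
    column per fuzzy category (named ``trait.category``).  Missing values
    are NaN and are handled pairwise inside the Gower distance; a fuzzy
    trait is either fully present or fully missing for a species.
    """

    species_ids: list[str]
    values: pd.DataFrame
    trait_meta: list[TraitMeta]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def meta(self, name: str) -> TraitMeta:
        for m in self.trait_meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def validate(self) -> None:
        declared = [c for m in self.trait_meta for c in m.columns]
        unknown = set(self.values.columns) - set(declared)
        if unknown:
            raise ValueError(f"undeclared column(s) in trait table: {sorted(unknown)}")
        missing = set(declared) - set(self.values.columns)
        if missing:
            raise ValueError(f"column(s) declared but absent: {sorted(missing)}")
        if list(self.values.index) != list(self.species_ids):
            raise ValueError("values index does not match species_ids")
        self.values = self.values[declared]
        for m in self.trait_meta:
            if m.type != FUZZY:
                continue
            block = self.values[m.columns].to_numpy(dtype=float)
            present = ~np.all(np.isnan(block), axis=1)
            if np.any(np.isnan(block[present])):
                raise ValueError(
                    f"fuzzy trait {m.name!r}: partial missingness within a species"
                )
            if np.any(block[present] < 0):
                raise ValueError(f"fuzzy trait {m.name!r} has negative memberships")
            sums = block[present].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > _FUZZY_SUM_TOL):
                bad = np.asarray(self.species_ids)[present][np.abs(sums - 1.0) > _FUZZY_SUM_TOL]
                raise ValueError(
                    f"fuzzy trait {m.name!r}: memberships of {list(bad)} do not sum to 1"
                )
            # renormalize residual rounding error away
            block[present] /= sums[:, None]
            self.values.loc[:, m.columns] = block


@dataclass
class ExpandedTraitMatrix:
    """Species x expanded-column matrix after standardization.

    Quantitative and ordinal traits occupy one z-scored column each;
    fuzzy traits occupy one column per category carrying the raw
    memberships (already commensurate on [0, 1], so not z-scored).
    """

    values: pd.DataFrame
    column_map: dict[str, tuple[str, str]]  # column -> (parent trait, category|"self")
    scaling_params: dict[str, tuple[float, float]]  # column -> (mean, sd)

    @property
    def species_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class DistanceMatrix:
    """Square symmetric species dissimilarity in [0, 1] (Gower units)."""

    species_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        n = len(self.species_ids)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape does not match species count")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("non-zero self-distance")
        if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
            raise ValueError("distances outside [0, 1]")
        self.values = np.clip(d, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.species_ids)

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self.species_ids.index(s) for s in ids]
        return self.values[np.ix_(idx, idx)]


@dataclass
class Dendrogram:
    """Rooted ultrametric merge tree over species (UPGMA output).

    Nodes ``0..n-1`` are leaves at height 0; internal node ``n+k`` is the
    k-th merge.  ``children[j]`` gives the two children of internal node
    ``n+j`` and ``heights[j]`` its (ultrametric) height, i.e. half the
    average-linkage distance at the merge.
    """

    leaf_ids: list[str]
    children: list[tuple[int, int]]
    heights: list[float]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.children) - 1

    def node_height(self, node: int) -> float:
        n = self.n_leaves
        return 0.0 if node < n else self.heights[node - n]

    def parent_map(self) -> dict[int, int]:
        n = self.n_leaves
        parents: dict[int, int] = {}
        for j, (a, b) in enumerate(self.children):
            parents[a] = n + j
            parents[b] = n + j
        return parents

    def edge_lengths(self) -> dict[int, float]:
        """child node -> length of the edge to its parent."""
        parents = self.parent_map()
        return {
            c: self.node_height(p) - self.node_height(c) for c, p in parents.items()
        }

    def total_branch_length(self) -> float:
        return float(sum(self.edge_lengths().values()))

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """node -> set of leaf indices below it."""
        n = self.n_leaves
        out: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for j, (a, b) in enumerate(self.children):
            out[n + j] = out[a] | out[b]
        return out

    def cophenetic(self) -> np.ndarray:
        """Pairwise leaf-to-leaf path distance (2 x merge height)."""
        n = self.n_leaves
        d = np.zeros((n, n))
        sets = {i: [i] for i in range(n)}
        for j, (a, b) in enumerate(self.children):
            h = self.heights[j]
            for x in sets[a]:
                for y in sets[b]:
                    d[x, y] = d[y, x] = 2.0 * h
            sets[n + j] = sets[a] + sets[b]
        return d


def load_trait_meta(meta_path: str) -> list[TraitMeta]:
    """Read the YAML trait-metadata sidecar (``traits.yml``)."""
    with open(meta_path) as fh:
        raw = yaml.safe_load(fh)
    metas = []
    for entry in raw["traits"]:
        metas.append(
            TraitMeta(
                name=entry["name"],
                type=entry["type"],
                categories=list(entry.get("categories", [])),
                weight=float(entry.get("weight", 1.0)),
            )
        )
    return metas


def load_trait_table(path: str, meta_path: str) -> TraitTable:
    """Load a species x trait CSV plus its YAML metadata sidecar.

    The CSV's first column must be ``species_id``; every other column must
    be declared in the metadata (fuzzy traits as ``trait.category``).
    Fuzzy memberships are renormalized when within 1e-6 of summing to 1,
    otherwise loading fails.
    """
    metas = load_trait_meta(meta_path)
    df = pd.read_csv(path)
    if df.columns[0] != "species_id":
        raise ValueError("first column of the trait CSV must be 'species_id'")
    df = df.set_index("species_id")
    df.index = df.index.astype(str)
    return TraitTable(species_ids=list(df.index), values=df.astype(float), trait_meta=metas)


def write_trait_table(tt: TraitTable, path: str, meta_path: str) -> None:
    out = tt.values.copy()
    out.index.name = "species_id"
    out.to_csv(path)
    meta = {
        "traits": [
            {
                "name": m.name,
                "type": m.type,
                **({"categories": m.categories} if m.type == FUZZY else {}),
                "weight": m.weight,
            }
            for m in tt.trait_meta
        ]
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def expand_and_scale(tt: TraitTable) -> ExpandedTraitMatrix:
    """Standardize the trait table into the matrix used by CWM/CWV.

    Quantitative and ordinal columns are z-scored over the full species
    pool (population sd); fuzzy membership columns are carried unchanged.
    A zero-variance quantitative column is retained as all zeros (sd
    treated as 1) with a logged warning, so downstream shapes are stable.
    """
    cols: dict[str, np.ndarray] = {}
    column_map: dict[str, tuple[str, str]] = {}
    scaling: dict[str, tuple[float, float]] = {}
    for m in tt.trait_meta:
        if m.type == FUZZY:
            for cat, col in zip(m.categories, m.columns):
                cols[col] = tt.values[col].to_numpy(dtype=float)
                column_map[col] = (m.name, cat)
                scaling[col] = (0.0, 1.0)
        else:
            x = tt.values[m.name].to_numpy(dtype=float)
            if m.type == ORDINAL:
                # rank-code, then treat as quantitative
                x = pd.Series(x).rank(method="average").to_numpy()
            mu = float(np.nanmean(x))
            sd = float(np.nanstd(x))
            if sd == 0.0:
                logger.warning(
                    "trait %r has zero variance; standardized to all zeros", m.name
                )
                sd = 1.0
            cols[m.name] = (x - mu) / sd
            column_map[m.name] = (m.name, "self")
            scaling[m.name] = (mu, sd)
    values = pd.DataFrame(cols, index=tt.species_ids)
    return ExpandedTraitMatrix(values=values, column_map=column_map, scaling_params=scaling)


def gower_distance(tt: TraitTable) -> DistanceMatrix:
    """Gower dissimilarity between species over mixed trait types.

    For each trait t with weight w_t, the per-trait dissimilarity is

    * quantitative/ordinal: |x_i - x_j| / range_t (range over the pool),
    * fuzzy: half the L1 distance between membership vectors
      (total-variation distance, in [0, 1]); the categories of one fuzzy
      trait jointly carry that trait's single weight.

    d_ij averages the per-trait dissimilarities with weights w_t over the
    traits where both species have values (pairwise deletion).
    """
    n = tt.n_species
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for m in tt.trait_meta:
        w = m.weight
        if m.type == FUZZY:
            block = tt.values[m.columns].to_numpy(dtype=float)
            present = ~np.all(np.isnan(block), axis=1)
            # total variation distance between membership rows
            delta = 0.5 * np.abs(block[:, None, :] - block[None, :, :]).sum(axis=2)
        else:
            x = tt.values[m.name].to_numpy(dtype=float)
            if m.type == ORDINAL:
                x = pd.Series(x).rank(method="average").to_numpy()
            present = ~np.isnan(x)
            rng = np.nanmax(x) - np.nanmin(x) if present.any() else 0.0
            if rng == 0.0:
                delta = np.zeros((n, n))
            else:
                delta = np.abs(x[:, None] - x[None, :]) / rng
        both = np.outer(present, present)
        num += np.where(both, w * np.nan_to_num(delta), 0.0)
        den += np.where(both, w, 0.0)
    if np.any(den[~np.eye(n, dtype=bool)] == 0):
        i, j = np.argwhere((den == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"species pair ({tt.species_ids[i]!r}, {tt.species_ids[j]!r}) "
            "shares no non-missing trait"
        )
    d = num / den
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)  # symmetrize away float noise
    return DistanceMatrix(species_ids=list(tt.species_ids), values=d)


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) clustering of the species distance matrix.

    Produces an ultrametric dendrogram: the merge creating the ancestor
    of clusters A and B sits at height = (average pairwise distance
    between A and B) / 2, so the leaf-to-leaf path distance equals the
    linkage distance.  Ties are broken by the lowest (i, j) index pair of
    the clusters' smallest member indices, which makes the tree
    bit-reproducible.
    """
    n = len(d.species_ids)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 species")
    dist = d.values.astype(float).copy()
    active: dict[int, dict] = {
        i: {"size": 1, "min_leaf": i} for i in range(n)
    }
    # working distances keyed by node id
    cur = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    children: list[tuple[int, int]] = []
    heights: list[float] = []
    next_id = n
    while len(active) > 1:
        # pick the minimum distance; ties -> lowest (min_leaf_i, min_leaf_j)
        best = None
        for (a, b), v in cur.items():
            key = (
                v,
                min(active[a]["min_leaf"], active[b]["min_leaf"]),
                max(active[a]["min_leaf"], active[b]["min_leaf"]),
            )
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab = cur[(a, b)] if (a, b) in cur else cur[(b, a)]
        sa, sb = active[a]["size"], active[b]["size"]
        new = {
            "size": sa + sb,
            "min_leaf": min(active[a]["min_leaf"], active[b]["min_leaf"]),
        }
        children.append((a, b) if active[a]["min_leaf"] < active[b]["min_leaf"] else (b, a))
        heights.append(dab / 2.0)
        # UPGMA update: distance to new cluster is size-weighted average
        updates = {}
        for c in active:
            if c in (a, b):
                continue
            dca = cur[(min(a, c), max(a, c))]
            dcb = cur[(min(b, c), max(b, c))]
            updates[c] = (sa * dca + sb * dcb) / (sa + sb)
        for pair in list(cur):
            if a in pair or b in pair:
                del cur[pair]
        del active[a], active[b]
        for c, v in updates.items():
            cur[(min(c, next_id), max(c, next_id))] = v
        active[next_id] = new
        next_id += 1
    # enforce monotone heights (average linkage is monotone, but guard float noise)
    for j in range(1, len(heights)):
        heights[j] = max(heights[j], heights[j - 1])
    return Dendrogram(leaf_ids=list(d.species_ids), children=children, heights=heights)
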