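"""Community-weighted trait means/variances and the functional-variance PCA.

The community-weighted mean of a trait at a station is
CWM_t = sum_i p_i x_it; the community-weighted variance is
CWV_t = sum_i p_i (x_it - CWM_t)^2, with p_i the relative abundances of
the species present.  Computing CWV for all (expanded, standardized)
traits simultaneously yields a station x trait matrix whose principal
component analysis summarizes multi-trait functional variance: a
station's PC1 score ("functional variance PC1") measures its magnitude
and the PC1 loadings identify the traits that drive it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import CommunityMatrix, compute_diversity, relative_abundance
from .traits import ExpandedTraitMatrix, TraitTable, expand_and_scale, gower_distance, upgma


def cwm(p: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Abundance-weighted mean of each trait column over present species."""
    p = np.asarray(p, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(p):
        raise ValueError("p and X are misaligned")
    return p @ X


def cwv(p: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Abundance-weighted variance of each trait column.

    Population-style weighted variance (relative abundances are weights,
    not sample counts): sum_i p_i (x_i - m)^2 = E[x^2] - E[x]^2.
    """
    p = np.asarray(p, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(p):
        raise ValueError("p and X are misaligned")
    m = p @ X
    return p @ (X - m) ** 2


def _weighted_matrix(
    cm: CommunityMatrix, X: ExpandedTraitMatrix, fn
) -> pd.DataFrame:
    if list(cm.species_ids) != list(X.species_ids):
        raise ValueError("community matrix and trait matrix species do not align")
    cm = cm.drop_empty_stations()
    Xv = X.values.to_numpy(dtype=float)
    out = np.empty((len(cm.station_ids), Xv.shape[1]))
    for k, row in enumerate(cm.abundance.to_numpy(dtype=float)):
        p, present = relative_abundance(row)
        out[k] = fn(p, Xv[present])
    return pd.DataFrame(out, index=cm.station_ids, columns=X.values.columns)


def cwm_matrix(cm: CommunityMatrix, X: ExpandedTraitMatrix) -> pd.DataFrame:
    """Station x expanded-trait matrix of community-weighted means."""
    return _weighted_matrix(cm, X, cwm)


def cwv_matrix(cm: CommunityMatrix, X: ExpandedTraitMatrix) -> pd.DataFrame:
    """Station x expanded-trait matrix of community-weighted variances."""
    return _weighted_matrix(cm, X, cwv)


@dataclass
class PCAResult:
    """Eigendecomposition of a station x trait matrix.

    ``scores`` are projections of the centered (optionally unit-scaled)
    rows onto the orthonormal ``loadings``; ``explained`` are the
    per-component eigenvalue fractions.  ``sign_convention`` records how
    the PC1 sign was fixed (PCA signs are otherwise arbitrary).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    sign_convention: str = "unoriented"

    def flip_component(self, k: int) -> None:
        col = self.scores.columns[k]
        self.scores[col] = -self.scores[col]
        self.loadings[col] = -self.loadings[col]


def pca(M: pd.DataFrame, scale_columns: bool = False) -> PCAResult:
    """PCA of a station x trait matrix via SVD of the centered data.

    Columns are mean-centered; with ``scale_columns`` they are also
    divided by their sd (correlation-matrix PCA).  By default CWV
    columns are left on their native scale: species-level traits were
    already standardized, so CWV columns are commensurate.
    """
    if M.shape[0] < 2:
        raise ValueError("PCA needs at least 2 stations")
    V = M.to_numpy(dtype=float)
    center = V.mean(axis=0)
    C = V - center
    if scale_columns:
        scale = C.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        C = C / scale
    else:
        scale = np.ones(V.shape[1])
    if not np.any(C != 0):
        raise ValueError("no variance to decompose: all stations identical")
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    ncomp = min(C.shape)
    names = [f"PC{k + 1}" for k in range(ncomp)]
    scores = pd.DataFrame(U[:, :ncomp] * s[:ncomp], index=M.index, columns=names)
    loadings = pd.DataFrame(Vt[:ncomp].T, index=M.columns, columns=names)
    lam = s[:ncomp] ** 2
    explained = lam / lam.sum()
    return PCAResult(
        scores=scores, loadings=loadings, explained=explained, center=center, scale=scale
    )


def pca_of_cwv(
    V: pd.DataFrame,
    scale_columns: bool = False,
    rao_q_values: pd.Series | None = None,
) -> PCAResult:
    """PCA of the CWV matrix with the PC1 sign oriented against Rao's Q.

    When station-aligned Rao's Q values are supplied, PC1 is flipped if
    needed so that corr(PC1 scores, Q) >= 0 — functional variance PC1 is
    then an indicator of functional dispersion with a positive sense.
    """
    res = pca(V, scale_columns=scale_columns)
    if rao_q_values is not None:
        q = rao_q_values.reindex(res.scores.index).to_numpy(dtype=float)
        s1 = res.scores["PC1"].to_numpy()
        if np.std(q) > 0 and np.std(s1) > 0 and np.corrcoef(s1, q)[0, 1] < 0:
            res.flip_component(0)
        res.sign_convention = "corr(PC1, RaoQ) >= 0"
    return res


def correlate_pc1_dispersion(scores: pd.Series, q: pd.Series) -> float:
    """Squared Pearson correlation between PC1 scores and Rao's Q."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(q, dtype=float)
    if len(x) != len(y):
        raise ValueError("misaligned station vectors")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in scores or dispersion values")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


@dataclass
class FunctionalVariancePC1:
    """Bundle returned by the end-to-end functional-variance pipeline."""

    pca_result: PCAResult
    per_station: pd.DataFrame  # station metadata + PC1 score + Q
    regional_means: pd.DataFrame  # region, year, mean PC1 (and mean Q)
    trait_ranking: pd.DataFrame  # expanded trait, |loading| on PC1, sign
    r2_with_dispersion: float


def functional_variance_pc1(
    cm: CommunityMatrix, tt: TraitTable, scale_columns: bool = False
) -> FunctionalVariancePC1:
    """Full pipeline: expand/scale traits -> CWV matrix -> PCA -> PC1.

    Returns per-station functional variance PC1 scores, their regional
    yearly means, the trait |loading| ranking characterizing what drives
    the variance, and the squared correlation of PC1 with Rao's Q.
    """
    X = expand_and_scale(tt)
    dist = gower_distance(tt)
    tree = upgma(dist)
    div = compute_diversity(cm, tt, distance=dist, tree=tree)
    V = cwv_matrix(cm, X)
    q = div.per_station["Q"].reindex(V.index)
    res = pca_of_cwv(V, scale_columns=scale_columns, rao_q_values=q)
    per_station = pd.concat(
        [
            div.per_station.loc[V.index, ["region", "year", "lat", "lon"]],
            res.scores["PC1"].rename("PC1"),
            q.rename("Q"),
        ],
        axis=1,
    )
    regional = (
        per_station.groupby(["region", "year"], sort=True)[["PC1", "Q"]]
        .mean()
        .reset_index()
    )
    ranking = (
        pd.DataFrame(
            {
                "loading": res.loadings["PC1"],
                "abs_loading": res.loadings["PC1"].abs(),
            }
        )
        .sort_values("abs_loading", ascending=False)
        .drop(columns="abs_loading")
    )
    r2 = correlate_pc1_dispersion(res.scores["PC1"], q)
    return FunctionalVariancePC1(
        pca_result=res,
        per_station=per_station,
        regional_means=regional,
        trait_ranking=ranking,
        r2_with_dispersion=r2,
    )


def theil_sen_slope(y: np.ndarray, x: np.ndarray | None = None) -> float:
    """Median-of-pairwise-slopes trend estimate (robust to outliers)."""
    y = np.asarray(y, dtype=float)
    if x is None:
        x = np.arange(len(y), dtype=float)
    res = stats.theilslopes(y, x)
    return float(res.slope)


def convergence_half_life(a: pd.Series, b: pd.Series) -> int | None:
    """First year at which the |a - b| gap drops to half its initial value.

    ``a`` and ``b`` are year-indexed regional mean series (e.g. Arctic
    and boreal functional variance PC1).  Returns the year label, or
    None if the gap never halves within the series.
    """
    years = sorted(set(a.index) & set(b.index))
    gap = (a.reindex(years) - b.reindex(years)).abs()
    g0 = gap.iloc[0]
    if g0 == 0:
        return int(years[0])
    hit = gap[gap <= g0 / 2.0]
    return int(hit.index[0]) if len(hit) else None
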