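"""Cellular-neighborhood (CN) analysis.

Each cell is described by the cell-type composition of its k-nearest-
neighbor window (the cell itself plus its k closest intra-region
neighbors). Windows are clustered with k-means into cellular
neighborhoods; CNs are optionally grouped into named niches, and
summarized by type enrichment, frequency per anatomic location,
tumor-cell fraction, and distance-to-tumor distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, distance
from sklearn.cluster import KMeans, MiniBatchKMeans

__all__ = [
    "build_windows",
    "cluster_windows",
    "enrichment_matrix",
    "group_niches",
    "niche_summaries",
    "NicheSummary",
]

_MINIBATCH_THRESHOLD = 200_000


def build_windows(
    cells: pd.DataFrame, k: int = 10, include_self: bool = True
) -> pd.DataFrame:
    """Cell-type composition of each cell's k-NN window, built per region.

    The window of cell *i* is *i* itself plus its ``k`` nearest neighbors
    within the same region (Euclidean distance on centroids, ties broken
    by ascending cell id). Regions with at most ``k`` other cells use all
    of their cells. Rows are type fractions over the window members and
    sum to 1.

    Returns a DataFrame indexed like ``cells`` with one column per cell
    type present in the table.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    types = sorted(cells["cell_type"].unique())
    type_idx = {t: i for i, t in enumerate(types)}
    comp = np.zeros((len(cells), len(types)))
    flat = cells.reset_index(drop=True)

    for _, sub in flat.groupby("region_id", sort=True):
        pos = np.asarray(sub.index)
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        ids = sub["cell_id"].to_numpy()
        tcodes = sub["cell_type"].map(type_idx).to_numpy()
        n = len(sub)
        k_eff = min(k, n - 1)
        if n <= 2000:
            # exact path: full pairwise distances, lexicographic tie-break
            d = distance.squareform(distance.pdist(xy))
            order = np.lexsort((np.broadcast_to(ids, (n, n)), d), axis=1)
        else:
            tree = cKDTree(xy)
            kq = min(n, k_eff + 1 + 16)
            dists, idx = tree.query(xy, k=kq, workers=-1)
            sub_order = np.lexsort((ids[idx], dists), axis=1)
            order = np.take_along_axis(idx, sub_order, axis=1)
        members = order[:, : k_eff + 1]
        if not include_self:
            keep = members != np.arange(n)[:, None]
            # drop self, then pad back to k_eff members
            members = np.array(
                [row[keep_row][:k_eff] for row, keep_row in zip(members, keep)]
            )
        window_types = tcodes[members]
        counts = np.zeros((n, len(types)))
        for j in range(len(types)):
            counts[:, j] = (window_types == j).sum(axis=1)
        comp[pos] = counts / members.shape[1]

    return pd.DataFrame(comp, index=cells.index, columns=types)


def cluster_windows(
    compositions: pd.DataFrame, n_clusters: int = 30, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """K-means over composition rows (k-means++ init, best of 10 restarts).

    Returns (CN label per cell, cluster centroid matrix).
    """
    x = np.asarray(compositions, dtype=float)
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > len(x):
        raise ValueError(f"n_clusters={n_clusters} exceeds n_cells={len(x)}")
    cls = MiniBatchKMeans if len(x) > _MINIBATCH_THRESHOLD else KMeans
    km = cls(n_clusters=n_clusters, n_init=10, random_state=seed).fit(x)
    return km.labels_.copy(), km.cluster_centers_.copy()


def enrichment_matrix(cells: pd.DataFrame, cn_col: str = "cn") -> pd.DataFrame:
    """CN x cell-type enrichment: type fractions per CN, z-scored per type.

    Each column is centered and scaled (population sd) across CNs, so a
    positive entry means the type is over-represented in that CN relative
    to the other CNs. Zero-variance columns are set to 0.
    """
    frac = (
        pd.crosstab(cells[cn_col], cells["cell_type"], normalize="index")
        .sort_index()
    )
    vals = frac.to_numpy(dtype=float)
    mu = vals.mean(axis=0)
    sd = vals.std(axis=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance cell-type columns set to 0: {list(frac.columns[zero])}"
        )
    sd = np.where(zero, 1.0, sd)
    z = (vals - mu) / sd
    z[:, zero] = 0.0
    return pd.DataFrame(z, index=frac.index, columns=frac.columns)


def group_niches(cn_labels: Sequence[int], mapping: Mapping[int, str]) -> np.ndarray:
    """Relabel CN ids into named niches; every observed CN must be mapped."""
    labels = np.asarray(cn_labels)
    observed = set(np.unique(labels).tolist())
    missing = sorted(observed - set(mapping))
    if missing:
        raise ValueError(f"CN ids without a niche mapping: {missing}")
    lut = {cn: mapping[cn] for cn in observed}
    return np.array([lut[cn] for cn in labels], dtype=object)


@dataclass
class NicheSummary:
    """Per-niche frequency by location, tumor fraction and distance data."""

    frequency_by_location: pd.DataFrame  # niche x location, columns sum to 1
    target_fraction: pd.Series           # per niche
    distances: pd.DataFrame | None       # per macrophage: niche + distance_um


def niche_summaries(
    cells: pd.DataFrame,
    target_type: str,
    location_col: str | None = None,
    distances: pd.DataFrame | None = None,
    niche_col: str = "niche",
) -> NicheSummary:
    """Summaries of each niche relative to the target (tumor) cells.

    * per-location niche frequencies (each location column sums to 1);
    * per-niche target-cell fraction (target cells / all cells in niche);
    * optionally, per-query-cell distances joined with niche labels, ready
      for mixed-model comparison across niches.
    """
    if niche_col not in cells.columns:
        raise ValueError(f"cells table lacks a {niche_col!r} column")
    if location_col is not None:
        bad = cells[location_col].isna()
        if bad.any():
            raise ValueError(f"{int(bad.sum())} cells have unknown location values")
        freq = pd.crosstab(cells[niche_col], cells[location_col], normalize="columns")
    else:
        freq = pd.crosstab(cells[niche_col], np.repeat("all", len(cells)), normalize="columns")

    target_frac = (
        cells.assign(_is_target=(cells["cell_type"] == target_type).astype(float))
        .groupby(niche_col)["_is_target"]
        .mean()
    )

    dist = None
    if distances is not None:
        dist = distances.merge(
            cells[["cell_id", niche_col]], on="cell_id", how="inner"
        )
    return NicheSummary(freq, target_frac, dist)
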