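"""Intensity-based cell phenotyping.

Marker intensities are z-normalized over the whole table, cells are
clustered by Leiden community detection on a k-nearest-neighbor graph in
marker space, and clusters (or cells directly) are mapped to named types
through an explicit, ordered gating scheme. The gating table replaces the
manual visual annotation step of typical imaging studies so that typing is
fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import yaml
from sklearn.neighbors import kneighbors_graph

__all__ = [
    "GateRule",
    "GatingScheme",
    "default_gating_scheme",
    "znormalize",
    "cluster_cells",
    "cluster_profiles",
    "annotate_clusters",
    "gate_cells",
]

UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class GateRule:
    """One first-match gating rule on z-scored marker means.

    A cell (or cluster mean) matches when every positive marker is at or
    above ``threshold`` and every negative marker is strictly below it.
    """

    cell_type: str
    positive: tuple
    negative: tuple = ()
    threshold: float = 0.5

    def __post_init__(self):
        if not self.positive:
            raise ValueError(f"rule for {self.cell_type!r} names no positive marker")


@dataclass(frozen=True)
class GatingScheme:
    rules: tuple

    def __post_init__(self):
        if not self.rules:
            raise ValueError("gating scheme has no rules")
        names = [r.cell_type for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("gating rule type names must be unique")

    @property
    def markers(self) -> tuple:
        out: list[str] = []
        for r in self.rules:
            for m in (*r.positive, *r.negative):
                if m not in out:
                    out.append(m)
        return tuple(out)

    @classmethod
    def from_yaml(cls, path) -> "GatingScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = tuple(
            GateRule(
                cell_type=r["cell_type"],
                positive=tuple(r.get("positive", ())),
                negative=tuple(r.get("negative", ())),
                threshold=float(r.get("threshold", 0.5)),
            )
            for r in raw["rules"]
        )
        return cls(rules)

    def to_yaml(self, path) -> None:
        raw = {
            "rules": [
                {
                    "cell_type": r.cell_type,
                    "positive": list(r.positive),
                    "negative": list(r.negative),
                    "threshold": r.threshold,
                }
                for r in self.rules
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_gating_scheme() -> GatingScheme:
    """Gating rules matching the default simulated marker panel."""
    return GatingScheme((
        GateRule("Tumor", ("PanCK",)),
        GateRule("IL4I1 TAM", ("IL4I1",)),
        GateRule("SPP1 TAM", ("SPP1",)),
        GateRule("FOLR2 TRM", ("FOLR2",)),
    ))


def znormalize(
    cells: pd.DataFrame, markers: Sequence[str], per_region: bool = False
) -> pd.DataFrame:
    """Z-score marker columns (population sd) over the whole table.

    Zero-variance columns become all zeros with a warning instead of NaN.
    ``per_region=True`` normalizes within each ``region_id`` stratum.
    """
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise ValueError(f"markers not in table: {missing}")
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to z-normalize")
    out = cells.copy()

    def _z(block: pd.DataFrame) -> pd.DataFrame:
        vals = block.to_numpy(dtype=float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0)  # population sd
        zero = sd == 0
        if zero.any():
            names = [m for m, z in zip(markers, zero) if z]
            warnings.warn(f"zero-variance marker columns set to 0: {names}")
        sd = np.where(zero, 1.0, sd)
        z = (vals - mu) / sd
        z[:, zero] = 0.0
        return pd.DataFrame(z, index=block.index, columns=block.columns)

    cols = list(markers)
    if per_region:
        out[cols] = (
            out.groupby("region_id", group_keys=False)[cols].apply(_z)
        )
    else:
        out[cols] = _z(out[cols])
    return out


def cluster_cells(
    cells: pd.DataFrame,
    markers: Sequence[str],
    n_neighbors: int = 30,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on a k-NN graph of marker vectors.

    Deterministic for a given seed; every cell receives a label.
    """
    x = cells[list(markers)].to_numpy(dtype=float)
    n = len(x)
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n_cells={n}")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    adj = kneighbors_graph(x, n_neighbors=n_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_profiles(
    cells: pd.DataFrame, markers: Sequence[str], labels: np.ndarray
) -> pd.DataFrame:
    """Per-cluster mean marker z-score and cell count."""
    df = cells[list(markers)].copy()
    df["cluster"] = np.asarray(labels)
    prof = df.groupby("cluster").mean()
    prof["n_cells"] = df.groupby("cluster").size()
    return prof.reset_index()


def _match_rules(z: np.ndarray, markers: Sequence[str], scheme: GatingScheme) -> np.ndarray:
    """First-matching-rule assignment for an array of z-vectors."""
    col = {m: i for i, m in enumerate(markers)}
    for r in scheme.rules:
        for m in (*r.positive, *r.negative):
            if m not in col:
                raise ValueError(f"rule marker {m!r} not in table")
    out = np.full(len(z), UNASSIGNED, dtype=object)
    unassigned = np.ones(len(z), dtype=bool)
    for r in scheme.rules:
        ok = unassigned.copy()
        for m in r.positive:
            ok &= z[:, col[m]] >= r.threshold
        for m in r.negative:
            ok &= z[:, col[m]] < r.threshold
        out[ok] = r.cell_type
        unassigned &= ~ok
    return out


def annotate_clusters(
    profiles: pd.DataFrame, scheme: GatingScheme, markers: Sequence[str] | None = None
) -> dict:
    """Map each cluster to the first gating rule its mean z-profile satisfies."""
    markers = list(markers) if markers is not None else list(scheme.markers)
    z = profiles[markers].to_numpy(dtype=float)
    assigned = _match_rules(z, markers, scheme)
    return dict(zip(profiles["cluster"].tolist(), assigned.tolist()))


def gate_cells(
    cells: pd.DataFrame, scheme: GatingScheme, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Deterministic per-cell gating on z-scored markers (no clustering)."""
    markers = list(markers) if markers is not None else list(scheme.markers)
    z = cells[markers].to_numpy(dtype=float)
    out = cells.copy()
    out["cell_type"] = _match_rules(z, markers, scheme)
    return out
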