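"""Nearest-tumor-cell distances and their statistical comparison.

For every query cell (e.g. each macrophage subtype) the Euclidean distance
to the closest target cell (e.g. tumor) is computed strictly within its
tissue region. Within one region, groups are compared with a two-sided
Wilcoxon rank-sum test; across regions a linear mixed model with a region
random intercept is fit and all pairwise group contrasts are tested with
Holm-Bonferroni control of the family-wise error.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "nearest_target_distance",
    "compare_distances_wilcoxon",
    "compare_distances_lmm",
    "holm_bonferroni",
]


def nearest_target_distance(
    cells: pd.DataFrame,
    query_types: Sequence[str],
    target_type: str,
    log1p: bool = False,
) -> pd.DataFrame:
    """Distance from each query cell to the nearest target cell in its region.

    Regions without any target cell have their query cells flagged
    (``flagged=True``, distance NaN) rather than silently dropped; the
    count is logged. Distances are in microns (``x_um``/``y_um`` columns).
    """
    known = set(cells["cell_type"].unique())
    unknown = [t for t in (*query_types, target_type) if t not in known]
    if unknown:
        raise ValueError(f"unknown cell types: {unknown}")

    results = []
    n_flagged = 0
    for region, sub in cells.groupby("region_id", sort=True):
        queries = sub[sub["cell_type"].isin(query_types)]
        targets = sub[sub["cell_type"] == target_type]
        if queries.empty:
            continue
        if targets.empty:
            n_flagged += len(queries)
            dist = np.full(len(queries), np.nan)
            flagged = True
        else:
            tree = cKDTree(targets[["x_um", "y_um"]].to_numpy())
            qxy = queries[["x_um", "y_um"]].to_numpy()
            same = queries["cell_id"].isin(targets["cell_id"]).to_numpy()
            if same.any():
                # a query that is itself a target must not match itself
                d2, idx2 = tree.query(qxy, k=2)
                dist = np.where(same, d2[:, 1], d2[:, 0])
            else:
                dist, _ = tree.query(qxy)
            flagged = False
        results.append(
            pd.DataFrame(
                {
                    "cell_id": queries["cell_id"].to_numpy(),
                    "region_id": region,
                    "group": queries["cell_type"].to_numpy(),
                    "distance_um": np.log1p(dist) if log1p else dist,
                    "flagged": flagged,
                }
            )
        )
    if n_flagged:
        log.warning("%d query cells flagged: their region has no target cells", n_flagged)
    if not results:
        raise ValueError("no query cells found")
    return pd.concat(results, ignore_index=True)


def compare_distances_wilcoxon(
    result: pd.DataFrame, group_a: str, group_b: str
) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two groups in one region.

    Exact enumeration when both samples have at most 20 untied values;
    otherwise a tie-corrected normal approximation.
    """
    usable = result[~result["flagged"]]
    if usable["region_id"].nunique() > 1:
        raise ValueError(
            "multiple tissue regions present; use compare_distances_lmm "
            "with a region random intercept instead"
        )
    a = usable.loc[usable["group"] == group_a, "distance_um"].to_numpy()
    b = usable.loc[usable["group"] == group_b, "distance_um"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if max(len(a), len(b)) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def holm_bonferroni(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def compare_distances_lmm(
    result: pd.DataFrame,
    value_col: str = "distance_um",
    normal_df_threshold: int = 200,
) -> pd.DataFrame:
    """Random-intercept model ``distance ~ group + (1 | region)`` by REML.

    All pairwise group contrasts are tested on t-ratios (residual-df t
    reference, switching to the normal reference above
    ``normal_df_threshold`` residual df) and Holm-Bonferroni adjusted over
    the contrast family.

    Returns the contrast table: group_a, group_b, estimate (mean
    difference, a - b), stat, p_raw, p_holm.
    """
    usable = result[~result["flagged"]].copy()
    regions = usable["region_id"].unique()
    if len(regions) < 2:
        raise ValueError("need >= 2 tissue regions; use the Wilcoxon path for one region")
    groups = sorted(usable["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to form contrasts")
    for g in groups:
        if usable.loc[usable["group"] == g, "region_id"].nunique() < 2:
            log.warning("group %r present in fewer than 2 regions; included anyway", g)

    # dummy-code groups against the first level
    y = usable[value_col].to_numpy(dtype=float)
    x = pd.get_dummies(usable["group"], dtype=float)[groups]
    exog = np.column_stack([np.ones(len(y)), x[groups[1:]].to_numpy()])
    model = sm.MixedLM(y, exog, groups=usable["region_id"].to_numpy())
    fit = model.fit(reml=True)
    beta = fit.fe_params
    cov = fit.cov_params()[: len(beta), : len(beta)]

    # group mean vector in coefficient space: first level = intercept only
    def coef_vec(g: str) -> np.ndarray:
        v = np.zeros(len(beta))
        v[0] = 1.0
        if g != groups[0]:
            v[groups[1:].index(g) + 1] = 1.0
        return v

    n = len(y)
    df_resid = n - len(beta) - len(regions) + 1
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        c = coef_vec(ga) - coef_vec(gb)
        est = float(c @ beta)
        se = float(np.sqrt(c @ cov @ c))
        t = est / se
        if df_resid > normal_df_threshold:
            p = 2.0 * stats.norm.sf(abs(t))
        else:
            p = 2.0 * stats.t.sf(abs(t), df=df_resid)
        rows.append((ga, gb, est, t, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "estimate", "stat", "p_raw"])
    out["p_holm"] = holm_bonferroni(out["p_raw"])
    return out
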