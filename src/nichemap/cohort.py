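"""Cohort-level statistics.

Per-sample cell-cluster frequencies with a strict minimum-cell filter,
between-group mean-frequency log2 ratios, chi-squared tests with
margin-corrected standardized-residual post-hocs, gene-signature scoring,
univariable Cox proportional-hazards z-scores per dataset, and their
sample-size-weighted (Liptak/Stouffer) meta-analytic integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .simulate import SurvivalCohort

log = logging.getLogger(__name__)

__all__ = [
    "SampleFrequencyTable",
    "MetaZResult",
    "sample_frequencies",
    "mean_frequency_log2_ratio",
    "chisq_posthoc",
    "score_signature",
    "cox_z",
    "meta_z",
]


@dataclass
class SampleFrequencyTable:
    counts: pd.DataFrame       # retained samples x clusters, integer counts
    frequencies: pd.DataFrame  # retained samples x clusters, rows sum to 1
    groups: pd.Series          # group label per retained sample
    excluded: pd.Series        # total cell count of excluded samples


@dataclass
class MetaZResult:
    per_dataset: pd.DataFrame  # dataset_id, z, n
    meta_z: float
    p: float
    signed_log10_p: float


def sample_frequencies(
    annotations: pd.DataFrame, min_cells: int = 35
) -> SampleFrequencyTable:
    """Per-sample cluster frequencies with a strict ``total > min_cells`` filter.

    ``annotations`` has one row per cell with ``sample_id``, ``cluster``
    and optionally ``group`` columns. Samples at or below the threshold
    are excluded and logged.
    """
    if annotations.empty:
        raise ValueError("empty annotation table")
    counts = pd.crosstab(annotations["sample_id"], annotations["cluster"])
    totals = counts.sum(axis=1)
    keep = totals > min_cells
    excluded = totals[~keep]
    if len(excluded):
        log.info(
            "excluded %d samples with <= %d cells: %s",
            len(excluded), min_cells, dict(excluded),
        )
    counts = counts[keep]
    if counts.empty:
        raise ValueError(f"no sample has more than {min_cells} cells")
    freqs = counts.div(counts.sum(axis=1), axis=0)
    if "group" in annotations.columns:
        groups = (
            annotations.drop_duplicates("sample_id")
            .set_index("sample_id")["group"]
            .reindex(counts.index)
        )
    else:
        groups = pd.Series(index=counts.index, dtype=object)
    return SampleFrequencyTable(counts, freqs, groups, excluded)


def mean_frequency_log2_ratio(
    table: SampleFrequencyTable, group_a: str, group_b: str
) -> pd.DataFrame:
    """log2 of (mean frequency in group A / mean frequency in group B).

    A zero mean in either group yields +/-inf and is flagged, never
    silently dropped.
    """
    for g in (group_a, group_b):
        if (table.groups == g).sum() == 0:
            raise ValueError(f"no retained samples in group {g!r}")
    mean_a = table.frequencies[table.groups == group_a].mean(axis=0)
    mean_b = table.frequencies[table.groups == group_b].mean(axis=0)
    with np.errstate(divide="ignore"):
        ratio = np.log2(mean_a.to_numpy() / mean_b.to_numpy())
    out = pd.DataFrame(
        {
            "cluster": mean_a.index,
            "mean_freq_a": mean_a.to_numpy(),
            "mean_freq_b": mean_b.to_numpy(),
            "log2_ratio": ratio,
        }
    )
    out["degenerate"] = ~np.isfinite(out["log2_ratio"])
    return out


def chisq_posthoc(counts: pd.DataFrame) -> tuple[float, float, pd.DataFrame]:
    """Pearson chi-squared test with standardized-residual post-hocs.

    Per-cell post-hoc statistic is the margin-corrected standardized
    Pearson residual r = (O - E) / sqrt(E (1 - row_total/N) (1 - col_total/N)),
    referred to the standard normal two-sided, Bonferroni-adjusted by the
    number of table cells.

    Returns (chi2 statistic, chi2 p-value, residual table with raw and
    adjusted p per cell).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need a table with >= 2 rows and >= 2 columns")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("counts must be nonnegative integers")
    n = obs.sum()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if (expected == 0).any():
        raise ValueError("table has a zero expected count")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)

    denom = np.sqrt(expected * (1 - row / n) * (1 - col / n))
    resid = (obs - expected) / denom
    p_raw = 2.0 * stats.norm.sf(np.abs(resid))
    n_cells = obs.size
    p_adj = np.minimum(1.0, p_raw * n_cells)

    idx = counts.index if isinstance(counts, pd.DataFrame) else range(obs.shape[0])
    cols = counts.columns if isinstance(counts, pd.DataFrame) else range(obs.shape[1])
    rows = []
    for i, r_name in enumerate(idx):
        for j, c_name in enumerate(cols):
            rows.append((r_name, c_name, resid[i, j], p_raw[i, j], p_adj[i, j]))
    table = pd.DataFrame(rows, columns=["row", "column", "residual", "p_raw", "p_adj"])
    return float(chi2), float(p), table


def score_signature(
    cohort: SurvivalCohort, genes: Sequence[str]
) -> pd.Series:
    """Per-sample signature score: mean of per-gene z across samples.

    Genes are z-normalized across the samples of the dataset (population
    sd); missing genes are logged, and an empty overlap is an error.
    """
    present = [g for g in genes if g in cohort.expression.index]
    missing = [g for g in genes if g not in cohort.expression.index]
    if missing:
        log.info("dataset %s: %d signature genes absent: %s",
                 cohort.dataset_id, len(missing), missing)
    if not present:
        raise ValueError(
            f"none of the signature genes are present in dataset {cohort.dataset_id}"
        )
    x = cohort.expression.loc[present].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    return pd.Series(z.mean(axis=0), index=cohort.expression.columns, name="score")


def cox_z(score: Sequence[float], time: Sequence[float], event: Sequence[int]) -> float:
    """Wald z of a univariable Cox proportional-hazards fit on a continuous score."""
    df = pd.DataFrame(
        {"score": np.asarray(score, float),
         "time": np.asarray(time, float),
         "event": np.asarray(event, int)}
    )
    if df["event"].sum() == 0:
        raise ValueError("no events observed; Cox model is undefined")
    if df["score"].nunique() == 1:
        raise ValueError("score is constant; Cox model is undefined")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    coef = float(cph.params_["score"])
    se = float(cph.standard_errors_["score"])
    return coef / se


def meta_z(zs: Sequence[float], ns: Sequence[int],
           weighted: bool = True) -> MetaZResult:
    """Liptak/Stouffer integration of per-dataset Cox z-scores.

    meta-z = sum(sqrt(n_d) * z_d) / sqrt(sum(n_d)) with sample-size
    weights (``weighted=False`` gives the unweighted Stouffer sum). The
    signed -log10 p carries the meta-z sign.
    """
    zs = np.asarray(zs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if zs.shape != ns.shape or zs.ndim != 1 or len(zs) == 0:
        raise ValueError("z and n must be equal-length non-empty vectors")
    w = np.sqrt(ns) if weighted else np.ones_like(ns)
    mz = float((w * zs).sum() / np.sqrt((w ** 2).sum()))
    p = float(2.0 * stats.norm.sf(abs(mz)))
    # guard log of exact zero for astronomically large |z|
    signed = float(np.sign(mz) * -np.log10(max(p, np.finfo(float).tiny)))
    per = pd.DataFrame({"z": zs, "n": ns.astype(int)})
    return MetaZResult(per, mz, p, signed)
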