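"""Validation experiments on synthetic tissue with planted ground truth.

Every function here generates its own data with the study-condition
defaults of :mod:`nichemap.simulate`, runs the relevant slice of the
analysis pipeline, and returns a measured quantity: recovery accuracy of
planted structure, calibration of the statistical machinery, or a digest
proving end-to-end determinism. The test suite and the reproduction
script both call these functions.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import celltyping, cohort, neighborhoods, quantify, simulate, spatial

__all__ = [
    "typing_accuracy",
    "cn_recovery_ari",
    "distance_ordering_rate",
    "log2_ratio_recovery",
    "lmm_familywise_type1",
    "lmm_power",
    "cox_null_calibration",
    "metaz_null_calibration",
    "run_full_pipeline",
]


def typing_accuracy(separation: float = 2.0, seed: int = 0,
                    count_per_type: int = 250) -> float:
    """End-to-end typing accuracy on balanced four-type tissue.

    znormalize -> Leiden cluster -> annotate against the default gating
    scheme, scored against the planted cell types.
    """
    cfg = simulate.typing_tissue_config(seed=seed, separation=separation,
                                        count_per_type=count_per_type)
    _, _, cells, _ = simulate.simulate_tissue(cfg)
    scheme = celltyping.default_gating_scheme()
    markers = list(cfg.markers)
    z = celltyping.znormalize(cells, markers)
    labels = celltyping.cluster_cells(z, markers, n_neighbors=30,
                                      resolution=1.0, seed=seed)
    profiles = celltyping.cluster_profiles(z, markers, labels)
    mapping = celltyping.annotate_clusters(profiles, scheme, markers)
    pred = np.array([mapping[c] for c in labels])
    return float((pred == cells["cell_type"].to_numpy()).mean())


def cn_recovery_ari(seed: int = 0, k: int = 10, n_clusters: int = 3) -> float:
    """ARI between k-NN-window k-means clusters and the geometric niches.

    The default tissue plants three spatial niches (tumor nest interior,
    peri-tumoral band, distal stroma) with distinct type composition.
    """
    cfg = simulate.default_tissue_config(seed=seed)
    _, _, cells, truth = simulate.simulate_tissue(cfg)
    comp = neighborhoods.build_windows(cells, k=k)
    labels, _ = neighborhoods.cluster_windows(comp, n_clusters=n_clusters, seed=seed)
    return float(adjusted_rand_score(truth.niche_id.to_numpy(), labels))


def _ordering_tissue_config(seed: int) -> simulate.SimTissueConfig:
    return simulate.SimTissueConfig(
        image_shape=(340, 340),
        n_regions=2,
        tumor_nests=(((120.0, 120.0), 62.0),),
        cell_types=(
            simulate.CellTypeSpec("Tumor", 60, ("in_nest",)),
            simulate.CellTypeSpec("IL4I1 TAM", 30, ("ring", 38.0, 10.0)),
            simulate.CellTypeSpec("FOLR2 TRM", 30, ("ring", 100.0, 15.0)),
        ),
        markers=("PanCK",),
        marker_model=simulate.make_marker_model(
            {"Tumor": ("PanCK",), "IL4I1 TAM": (), "FOLR2 TRM": ()}, ("PanCK",)
        ),
        seed=seed,
    )


def distance_ordering_rate(n_replicates: int = 50, seed: int = 0) -> float:
    """Fraction of replicates where the planted-near type fits nearer.

    Tumor-adjacent macrophages are planted at 38 um and resident
    macrophages at 100 um; each replicate fits the mixed model and asks
    whether the fitted mean distance orders the two types correctly.
    """
    correct = 0
    for r in range(n_replicates):
        cfg = _ordering_tissue_config(seed=seed * 100_003 + r)
        _, _, cells, _ = simulate.simulate_tissue(cfg)
        res = spatial.nearest_target_distance(
            cells, ["IL4I1 TAM", "FOLR2 TRM"], "Tumor"
        )
        con = spatial.compare_distances_lmm(res)
        row = con.iloc[0]
        est = row.estimate if row.group_a == "FOLR2 TRM" else -row.estimate
        correct += est > 0
    return correct / n_replicates


def log2_ratio_recovery(planted: float = 3.5, seed: int = 0,
                        n_samples_per_group: int = 50) -> float:
    """Estimated log2 mean-frequency ratio of a cluster planted at ``planted``."""
    cfg = simulate.SimCohortConfig(
        n_samples_per_group=n_samples_per_group,
        planted_log2_ratio=(planted, 0.0, 0.0, 0.0, 0.0),
        cells_per_sample=(80, 400),
        seed=seed,
    )
    counts, _ = simulate.simulate_frequency_cohort(cfg)
    ann = counts.melt(id_vars=["sample_id", "group"],
                      var_name="cluster", value_name="n")
    ann = ann.loc[ann.index.repeat(ann["n"])].drop(columns="n")
    table = cohort.sample_frequencies(ann, min_cells=35)
    out = cohort.mean_frequency_log2_ratio(table, "A", "B").set_index("cluster")
    return float(out.loc[cfg.clusters[0], "log2_ratio"])


def lmm_familywise_type1(n_sims: int = 200, seed: int = 0,
                         alpha: float = 0.05) -> float:
    """Family-wise false-positive rate of the Holm-adjusted LMM contrasts.

    Null data: three equal groups, region sd 10 um, residual sd 15 um,
    8 regions x 40 cells per group.
    """
    hits = 0
    for s in range(n_sims):
        df = simulate.simulate_grouped_measurements(
            {"a": 50.0, "b": 50.0, "c": 50.0},
            n_regions=8, cells_per_group_per_region=40,
            region_sd=10.0, residual_sd=15.0, seed=seed * 1_000_003 + s,
        )
        con = spatial.compare_distances_lmm(df.assign(flagged=False))
        hits += bool((con["p_holm"] < alpha).any())
    return hits / n_sims


def lmm_power(n_sims: int = 100, seed: int = 0, shift: float = 30.0,
              alpha: float = 0.05) -> float:
    """Detection rate for a planted group shift (10 regions x 50 cells)."""
    hits = 0
    for s in range(n_sims):
        df = simulate.simulate_grouped_measurements(
            {"near": 40.0, "far": 40.0 + shift},
            n_regions=10, cells_per_group_per_region=50,
            region_sd=10.0, residual_sd=15.0, seed=seed * 1_000_033 + s,
        )
        con = spatial.compare_distances_lmm(df.assign(flagged=False))
        hits += bool((con["p_holm"] < alpha).any())
    return hits / n_sims


def cox_null_calibration(n_sims: int = 500, seed: int = 0,
                         n_samples: int = 100) -> tuple[float, float]:
    """(mean, variance) of the Cox Wald z under a null signature effect."""
    zs = []
    for s in range(n_sims):
        cfg = simulate.SimCohortConfig(
            n_datasets=1, samples_per_dataset=n_samples,
            planted_log_hazard=0.0, censoring_rate=0.3,
            seed=seed * 1_000_099 + s,
        )
        cohorts, _ = simulate.simulate_survival_cohorts(cfg)
        c = cohorts[0]
        score = cohort.score_signature(c, cfg.signature_genes)
        zs.append(cohort.cox_z(score.to_numpy(), c.survival["time"],
                               c.survival["event"]))
    zs = np.asarray(zs)
    return float(zs.mean()), float(zs.var())


def metaz_null_calibration(n_sims: int = 500, seed: int = 0,
                           n_datasets: int = 4,
                           n_samples: int = 60) -> tuple[float, float]:
    """(mean, variance) of the integrated meta-z under the null."""
    mzs = []
    for s in range(n_sims):
        cfg = simulate.SimCohortConfig(
            n_datasets=n_datasets, samples_per_dataset=n_samples,
            planted_log_hazard=0.0, censoring_rate=0.3,
            seed=seed * 1_000_121 + s,
        )
        cohorts, _ = simulate.simulate_survival_cohorts(cfg)
        zs, ns = [], []
        for c in cohorts:
            score = cohort.score_signature(c, cfg.signature_genes)
            zs.append(cohort.cox_z(score.to_numpy(), c.survival["time"],
                                   c.survival["event"]))
            ns.append(c.n)
        mzs.append(cohort.meta_z(zs, ns).meta_z)
    mzs = np.asarray(mzs)
    return float(mzs.mean()), float(mzs.var())


def run_full_pipeline(seed: int = 0) -> dict:
    """Full pipeline at default synthetic scale; returns key results + digest.

    simulate -> quantify -> znormalize/cluster/annotate -> neighborhoods ->
    nearest-tumor distances + mixed-model contrasts -> cohort ratio and
    survival meta-z. The digest hashes every intermediate array so two runs
    with the same seed can be compared byte for byte.
    """
    h = hashlib.sha256()

    cfg = simulate.default_tissue_config(seed=seed)
    mask, stack, cells, truth = simulate.simulate_tissue(cfg)
    h.update(mask.tobytes())
    h.update(stack.tobytes())
    h.update(cells.to_csv(index=False).encode())

    quantified = pd.concat(
        [
            quantify.quantify_cells(mask[r], stack[r], cfg.markers, radius=3,
                                    microns_per_pixel=cfg.microns_per_pixel,
                                    region_id=r)
            for r in range(cfg.n_regions)
        ],
        ignore_index=True,
    )
    h.update(quantified.to_csv(index=False).encode())

    scheme = celltyping.default_gating_scheme()
    markers = list(cfg.markers)
    z = celltyping.znormalize(quantified, markers)
    labels = celltyping.cluster_cells(z, markers, n_neighbors=30,
                                      resolution=1.0, seed=seed)
    profiles = celltyping.cluster_profiles(z, markers, labels)
    mapping = celltyping.annotate_clusters(profiles, scheme, markers)
    typed = quantified.copy()
    typed["cell_type"] = [mapping[c] for c in labels]
    h.update(typed["cell_type"].to_csv().encode())
    typing_acc = float(
        (typed["cell_type"].to_numpy()
         == cells["cell_type"].replace({"Stroma": celltyping.UNASSIGNED}).to_numpy()
         ).mean()
    )

    comp = neighborhoods.build_windows(typed, k=10)
    cn, _ = neighborhoods.cluster_windows(comp, n_clusters=10, seed=seed)
    typed["cn"] = cn
    enrich = neighborhoods.enrichment_matrix(typed)
    h.update(comp.to_numpy().tobytes())
    h.update(cn.tobytes())
    h.update(enrich.to_csv().encode())

    res = spatial.nearest_target_distance(
        typed, ["IL4I1 TAM", "SPP1 TAM", "FOLR2 TRM"], "Tumor"
    )
    con = spatial.compare_distances_lmm(res)
    h.update(res.to_csv(index=False).encode())
    h.update(con.round(10).to_csv(index=False).encode())
    group_means = res.groupby("group")["distance_um"].mean()

    ccfg = simulate.SimCohortConfig(
        planted_log2_ratio=(3.5, 0.0, 0.0, 0.0, 0.0), seed=seed
    )
    counts, _ = simulate.simulate_frequency_cohort(ccfg)
    ann = counts.melt(id_vars=["sample_id", "group"],
                      var_name="cluster", value_name="n")
    ann = ann.loc[ann.index.repeat(ann["n"])].drop(columns="n")
    freq = cohort.sample_frequencies(ann, min_cells=35)
    ratios = cohort.mean_frequency_log2_ratio(freq, "A", "B")
    h.update(ratios.round(10).to_csv(index=False).encode())

    scfg = simulate.SimCohortConfig(n_datasets=4, samples_per_dataset=80,
                                    planted_log_hazard=0.5, censoring_rate=0.3,
                                    seed=seed)
    cohorts, _ = simulate.simulate_survival_cohorts(scfg)
    zs, ns = [], []
    for c in cohorts:
        score = cohort.score_signature(c, scfg.signature_genes)
        zs.append(cohort.cox_z(score.to_numpy(), c.survival["time"],
                               c.survival["event"]))
        ns.append(c.n)
    meta = cohort.meta_z(zs, ns)
    h.update(np.asarray([meta.meta_z, meta.signed_log10_p]).round(10).tobytes())

    return {
        "digest": h.hexdigest(),
        "n_cells": len(cells),
        "typing_accuracy": typing_acc,
        "mean_distance_um": group_means.to_dict(),
        "contrasts": con,
        "log2_ratio_nlrp3_like": float(
            ratios.set_index("cluster").loc[ccfg.clusters[0], "log2_ratio"]
        ),
        "meta_z": meta.meta_z,
        "signed_log10_p": meta.signed_log10_p,
    }
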