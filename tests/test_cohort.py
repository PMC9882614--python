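"""Cohort statistics: frequencies, ratios, chi-squared post-hoc, Cox, meta-z."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichemap import cohort, simulate


def annotations_from_counts(counts_by_sample, groups=None):
    rows = []
    for sample, counts in counts_by_sample.items():
        for cluster, n in counts.items():
            for _ in range(n):
                rows.append(
                    (sample, cluster, groups.get(sample) if groups else "g")
                )
    return pd.DataFrame(rows, columns=["sample_id", "cluster", "group"])


class TestSampleFrequencies:
    def test_strict_filter_boundary(self):
        ann = annotations_from_counts(
            {"s35": {"A": 35}, "s36": {"A": 36}},
        )
        table = cohort.sample_frequencies(ann, min_cells=35)
        assert list(table.counts.index) == ["s36"]
        assert list(table.excluded.index) == ["s35"]

    def test_hand_frequencies(self):
        ann = annotations_from_counts({"S": {"A": 10, "B": 30}})
        table = cohort.sample_frequencies(ann, min_cells=35)
        assert table.frequencies.loc["S", "A"] == pytest.approx(0.25)
        assert table.frequencies.loc["S", "B"] == pytest.approx(0.75)

    def test_rows_sum_to_one(self):
        cfg = simulate.SimCohortConfig(n_samples_per_group=10, seed=0)
        counts, _ = simulate.simulate_frequency_cohort(cfg)
        ann = counts.melt(
            id_vars=["sample_id", "group"], var_name="cluster", value_name="n"
        )
        ann = ann.loc[ann.index.repeat(ann["n"])].drop(columns="n")
        table = cohort.sample_frequencies(ann)
        assert np.allclose(table.frequencies.sum(axis=1), 1.0, atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cohort.sample_frequencies(pd.DataFrame(columns=["sample_id", "cluster"]))


class TestLog2Ratio:
    def make_table(self, freq_a, freq_b):
        ann = annotations_from_counts(
            {
                "a1": {c: int(f * 1000) for c, f in freq_a.items()},
                "b1": {c: int(f * 1000) for c, f in freq_b.items()},
            },
            groups={"a1": "A", "b1": "B"},
        )
        return cohort.sample_frequencies(ann)

    def test_identical_means_zero(self):
        t = self.make_table({"x": 0.5, "y": 0.5}, {"x": 0.5, "y": 0.5})
        out = cohort.mean_frequency_log2_ratio(t, "A", "B")
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_fourfold_is_two(self):
        t = self.make_table({"x": 0.4, "y": 0.6}, {"x": 0.1, "y": 0.9})
        out = cohort.mean_frequency_log2_ratio(t, "A", "B").set_index("cluster")
        assert out.loc["x", "log2_ratio"] == pytest.approx(2.0)

    def test_zero_mean_flagged_not_dropped(self):
        t = self.make_table({"x": 1.0, "y": 0.0}, {"x": 0.5, "y": 0.5})
        out = cohort.mean_frequency_log2_ratio(t, "A", "B").set_index("cluster")
        assert out.loc["y", "degenerate"]
        assert np.isneginf(out.loc["y", "log2_ratio"])

    def test_unknown_group_rejected(self):
        t = self.make_table({"x": 1.0}, {"x": 1.0})
        with pytest.raises(ValueError):
            cohort.mean_frequency_log2_ratio(t, "A", "C")

    def test_planted_ratio_recovered_through_pipeline(self):
        cfg = simulate.SimCohortConfig(
            n_samples_per_group=50,
            planted_log2_ratio=(3.5, 0.0, 0.0, 0.0, 0.0),
            cells_per_sample=(80, 400),
            seed=9,
        )
        counts, truth = simulate.simulate_frequency_cohort(cfg)
        ann = counts.melt(
            id_vars=["sample_id", "group"], var_name="cluster", value_name="n"
        )
        ann = ann.loc[ann.index.repeat(ann["n"])].drop(columns="n")
        table = cohort.sample_frequencies(ann, min_cells=35)
        out = cohort.mean_frequency_log2_ratio(table, "A", "B").set_index("cluster")
        est = out.loc[cfg.clusters[0], "log2_ratio"]
        assert est == pytest.approx(truth.group_log2_ratio[cfg.clusters[0]], abs=0.5)
        assert est == pytest.approx(3.5, abs=0.5)


class TestChisqPosthoc:
    def test_independent_table_is_null(self):
        # outer product of margins: chi2 exactly 0
        table = pd.DataFrame(np.outer([10, 20], [3, 7]))
        chi2, p, resid = cohort.chisq_posthoc(table)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(resid["residual"], 0.0, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        chi2, p, resid = cohort.chisq_posthoc(pd.DataFrame([[10, 20], [20, 10]]))
        assert chi2 == pytest.approx(20 / 3)
        # |r| = 5 / sqrt(15 * 0.5 * 0.5) = 2.582 for every cell
        assert np.allclose(np.abs(resid["residual"]), 5 / np.sqrt(3.75), atol=1e-12)
        assert np.allclose(np.abs(resid["residual"]), 2.582, atol=1e-3)

    def test_bonferroni_definition(self):
        _, _, resid = cohort.chisq_posthoc(pd.DataFrame([[10, 20], [20, 10]]))
        assert np.allclose(
            resid["p_adj"], np.minimum(1.0, resid["p_raw"] * 4), atol=1e-15
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_textbook_formula_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        obs = rng.integers(5, 60, size=(4, 3)).astype(float)
        _, _, resid = cohort.chisq_posthoc(pd.DataFrame(obs))
        n = obs.sum()
        row = obs.sum(1)
        col = obs.sum(0)
        for _, r in resid.iterrows():
            i, j = int(r["row"]), int(r["column"])
            e = row[i] * col[j] / n
            expected = (obs[i, j] - e) / np.sqrt(
                e * (1 - row[i] / n) * (1 - col[j] / n)
            )
            assert r["residual"] == pytest.approx(expected, rel=1e-12)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            cohort.chisq_posthoc(pd.DataFrame([[1, 2]]))
        with pytest.raises(ValueError):
            cohort.chisq_posthoc(pd.DataFrame([[0, 0], [1, 2]]))


class TestSignatureAndCox:
    def make_cohort(self, expr, **kw):
        n = expr.shape[1]
        surv = pd.DataFrame(
            {"sample_id": expr.columns, "time": np.arange(1, n + 1, dtype=float),
             "event": 1}
        )
        return simulate.SurvivalCohort("d0", expr, surv)

    def test_single_gene_score_is_its_z(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 6.0]], index=["G1"],
            columns=[f"s{i}" for i in range(4)],
        )
        c = self.make_cohort(expr)
        score = cohort.score_signature(c, ["G1"])
        z = stats.zscore(expr.loc["G1"].to_numpy())
        assert np.allclose(score.to_numpy(), z)

    def test_anticorrelated_pair_cancels(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        expr = pd.DataFrame([x, -x], index=["G1", "G2"],
                            columns=[f"s{i}" for i in range(4)])
        c = self.make_cohort(expr)
        score = cohort.score_signature(c, ["G1", "G2"])
        assert np.allclose(score.to_numpy(), 0.0, atol=1e-12)

    def test_scores_centered(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(size=(6, 40)), index=[f"G{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(40)],
        )
        c = self.make_cohort(expr)
        score = cohort.score_signature(c, [f"G{i}" for i in range(6)])
        assert abs(score.mean()) < 1e-9

    def test_absent_genes(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["a", "b"])
        c = self.make_cohort(expr)
        with pytest.raises(ValueError, match="none"):
            cohort.score_signature(c, ["MISSING"])
        # partial overlap works and uses present genes only
        score = cohort.score_signature(c, ["G1", "MISSING"])
        assert len(score) == 2

    def test_cox_contract_errors(self):
        with pytest.raises(ValueError, match="events"):
            cohort.cox_z([1.0, 2.0], [1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="constant"):
            cohort.cox_z([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1, 1, 1])

    def test_strong_effect_gives_large_positive_z(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=300)
        t = rng.exponential(1.0 / np.exp(1.0 * u))
        z = cohort.cox_z(u, t, np.ones(300, dtype=int))
        assert z > 5


class TestMetaZ:
    def test_single_dataset_identity(self):
        r = cohort.meta_z([1.7], [80])
        assert r.meta_z == pytest.approx(1.7)

    def test_equal_n_identical_z_scales_sqrt_k(self):
        r = cohort.meta_z([2.0] * 4, [50] * 4)
        assert r.meta_z == pytest.approx(2.0 * 2.0)

    def test_order_and_scale_invariance(self):
        z = [0.5, -1.2, 2.0]
        n = [30, 60, 90]
        a = cohort.meta_z(z, n).meta_z
        b = cohort.meta_z(z[::-1], n[::-1]).meta_z
        c = cohort.meta_z(z, [10 * x for x in n]).meta_z
        assert a == pytest.approx(b)
        assert a == pytest.approx(c)

    def test_signed_log10_p_carries_sign(self):
        pos = cohort.meta_z([2.0], [50])
        neg = cohort.meta_z([-2.0], [50])
        assert pos.signed_log10_p > 0 > neg.signed_log10_p
        assert pos.signed_log10_p == pytest.approx(-np.log10(pos.p))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cohort.meta_z([1.0, 2.0], [10])
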