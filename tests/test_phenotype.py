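"""Growth-curve AUC phenotyping, normalization, clustering and ANOVA."""

import numpy as np
import pandas as pd
import pytest

from intertaxon.phenotype import (
    GrowthCurve,
    PhenotypeMatrix,
    anova_by_condition,
    auc_empirical,
    build_matrix,
    cluster,
    fit_logistic,
    zscore_columns,
)
from intertaxon.simulate import simulate_growth


def make_curve(times, od, strain="s1", condition="c1", rep=1):
    return GrowthCurve(strain, condition, np.asarray(times), np.asarray(od), rep)


def logistic_samples(K=1.0, r=0.5, N0=0.05, noise=0.0, seed=1, duration=48.0):
    df = simulate_growth(K=K, r=r, N0=N0, duration=duration, step=0.5,
                         noise_sd=noise, seed=seed)
    return make_curve(df["time_h"].to_numpy(), df["od"].to_numpy())


class TestEmpiricalAuc:
    def test_constant_od(self):
        t = np.linspace(0, 48, 97)
        assert auc_empirical(make_curve(t, np.ones_like(t))) == pytest.approx(48.0)

    def test_linear_ramp(self):
        t = np.linspace(0, 24, 49)
        assert auc_empirical(make_curve(t, t / 24)) == pytest.approx(12.0)

    def test_single_interval(self):
        assert auc_empirical(make_curve([0, 1], [0, 2])) == pytest.approx(1.0)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            auc_empirical(make_curve([0, 2, 1], [1, 1, 1]))


class TestLogisticFit:
    def test_noiseless_parameters_recovered_within_one_percent(self):
        fit = fit_logistic(logistic_samples())
        assert fit.converged
        assert fit.K == pytest.approx(1.0, rel=0.01)
        assert fit.r == pytest.approx(0.5, rel=0.01)
        assert fit.N0 == pytest.approx(0.05, rel=0.01)
        assert fit.auc_fit == pytest.approx(fit.auc_empirical, rel=0.01)

    def test_carrying_capacity_robust_to_noise_across_seeds(self):
        ks = [fit_logistic(logistic_samples(noise=0.01, seed=s)).K for s in range(20)]
        assert np.all(np.abs(np.array(ks) - 1.0) < 0.05)

    def test_decreasing_curve_falls_back_to_empirical(self):
        t = np.linspace(0, 48, 97)
        fit = fit_logistic(make_curve(t, 1.0 - t / 100))
        assert not fit.converged
        assert fit.auc == fit.auc_empirical

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(make_curve([0, 1, 2], [0.1, 0.2, 0.3]))


class TestMatrix:
    def _fits(self, aucs: dict[tuple[str, str], list[float]]):
        from intertaxon.phenotype import GrowthModelFit

        fits = []
        for (strain, cond), values in aucs.items():
            for rep, value in enumerate(values):
                fits.append(GrowthModelFit(strain, cond, rep + 1, 1, 1, 0.05,
                                           value, value, True))
        return fits

    def test_replicate_means(self):
        fits = self._fits({
            ("s1", "c1"): [10, 12, 14], ("s1", "c2"): [1, 2, 3],
            ("s2", "c1"): [20, 20, 20], ("s2", "c2"): [4, 4, 4],
        })
        m = build_matrix(fits)
        assert m.values.loc["s1", "c1"] == pytest.approx(12.0)
        assert m.values.shape == (2, 2)

    def test_missing_cell_raises_unless_allowed(self):
        fits = self._fits({("s1", "c1"): [10], ("s1", "c2"): [1], ("s2", "c1"): [20]})
        with pytest.raises(ValueError, match="s2/c2"):
            build_matrix(fits)
        m = build_matrix(fits, allow_missing=True)
        assert pd.isna(m.values.loc["s2", "c2"])

    def test_zscore_simple_column(self):
        m = PhenotypeMatrix(pd.DataFrame({"c1": [1.0, 2.0, 3.0]},
                                         index=["s1", "s2", "s3"]), {})
        z = zscore_columns(m)
        assert list(z.values["c1"]) == pytest.approx([-1.0, 0.0, 1.0], abs=1e-12)

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(3)
        m = PhenotypeMatrix(
            pd.DataFrame(rng.normal(size=(6, 3)), columns=list("abc")), {}
        )
        z1 = zscore_columns(m)
        z2 = zscore_columns(z1)
        assert np.allclose(z1.values, z2.values, atol=1e-12)

    def test_zero_variance_column_named_in_error(self):
        m = PhenotypeMatrix(pd.DataFrame({"glycerol": [2.0, 2.0, 2.0]}), {})
        with pytest.raises(ValueError, match="glycerol"):
            zscore_columns(m)

    def test_identical_strains_stay_identical_after_scaling(self):
        m = PhenotypeMatrix(
            pd.DataFrame({"c1": [1.0, 1.0, 5.0], "c2": [2.0, 2.0, 9.0]},
                         index=["s1", "s2", "s3"]), {}
        )
        z = zscore_columns(m)
        assert np.allclose(z.values.loc["s1"], z.values.loc["s2"])


class TestClustering:
    def test_well_separated_lineages_form_top_bipartition(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = rng.normal(0.0, 1.0, size=(4, 5))
            b = rng.normal(3.0, 1.0, size=(4, 5))
            df = pd.DataFrame(
                np.vstack([a, b]),
                index=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
            )
            from scipy.cluster import hierarchy

            Z = hierarchy.linkage(df.sort_index().to_numpy(), method="average")
            sides = hierarchy.fcluster(Z, 2, "maxclust")
            labels = dict(zip(sorted(df.index), sides))
            if (
                len({labels[f"a{i}"] for i in range(4)}) == 1
                and len({labels[f"b{i}"] for i in range(4)}) == 1
                and labels["a0"] != labels["b0"]
            ):
                hits += 1
        assert hits >= 18

    def test_duplicate_strains_merge_first_at_zero_height(self):
        df = pd.DataFrame({"c1": [1.0, 1.0, 8.0], "c2": [2.0, 2.0, 9.0]},
                          index=["s1", "s2", "s3"])
        newick, order = cluster(PhenotypeMatrix(df, {}))
        assert "(s1:0,s2:0)" in newick.replace(" ", "")
        assert set(order) == {"s1", "s2", "s3"}

    def test_two_strains_single_join(self):
        df = pd.DataFrame({"c1": [0.0, 1.0]}, index=["x", "y"])
        newick, order = cluster(PhenotypeMatrix(df, {}))
        assert newick.count("(") == 1
        assert sorted(order) == ["x", "y"]


class TestAnova:
    def test_identical_groups_share_a_letter(self):
        df = pd.DataFrame({"c1": [5.0] * 6}, index=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = anova_by_condition(PhenotypeMatrix(df, {}), groups)
        row = res.iloc[0]
        assert row["F"] == 0.0
        assert row["p_value"] == 1.0
        assert row["letter_g1"] == row["letter_g2"] == "a"

    def test_zero_within_variance_gives_tiny_p(self):
        df = pd.DataFrame({"c1": [1.0, 1.0, 1.0, 9.0, 9.0, 9.0]},
                          index=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        res = anova_by_condition(PhenotypeMatrix(df, {}), groups)
        assert res.iloc[0]["p_value"] < 1e-10
        assert res.iloc[0]["letter_g1"] != res.iloc[0]["letter_g2"]

    def test_matches_textbook_sum_of_squares(self):
        values = [3.0, 5.0, 4.0, 8.0, 9.0, 7.0, 12.0, 14.0, 13.0]
        df = pd.DataFrame({"c1": values}, index=[f"s{i}" for i in range(9)])
        groups = {f"s{i}": f"g{i // 3}" for i in range(9)}
        arr = np.array(values).reshape(3, 3)
        grand = arr.mean()
        ssb = 3 * np.sum((arr.mean(axis=1) - grand) ** 2)
        ssw = np.sum((arr - arr.mean(axis=1, keepdims=True)) ** 2)
        f_oracle = (ssb / 2) / (ssw / 6)
        res = anova_by_condition(PhenotypeMatrix(df, {}), groups)
        assert res.iloc[0]["F"] == pytest.approx(f_oracle, abs=1e-10)

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=8)
        df1 = pd.DataFrame({"c1": values}, index=[f"s{i}" for i in range(8)])
        df2 = df1 + 100.0
        groups = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(8)}
        f1 = anova_by_condition(PhenotypeMatrix(df1, {}), groups).iloc[0]["F"]
        f2 = anova_by_condition(PhenotypeMatrix(df2, {}), groups).iloc[0]["F"]
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_undersized_group_rejected(self):
        df = pd.DataFrame({"c1": [1.0, 2.0, 3.0]}, index=["s0", "s1", "s2"])
        groups = {"s0": "g1", "s1": "g1", "s2": "g2"}
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_by_condition(PhenotypeMatrix(df, {}), groups)
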