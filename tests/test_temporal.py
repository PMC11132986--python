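"""Temporal statistics: filtering, imputation, permutation FDR, profiles, ruler."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spatmap.synthetic import TemporalSimSpec, simulate_temporal
from spatmap.tables import ProteinGroupTable
from spatmap.temporal import (
    conserved_trajectory,
    filter_valid,
    fold_change_classes,
    hierarchical_cluster,
    impute_gaussian,
    permutation_anova,
    proteomic_ruler,
    ranked_copy_zscores,
    two_group_test,
    width_adjust,
    zscore_profiles,
)

AVOGADRO = 6.02214076e23


def groups_series(cols, labels):
    return pd.Series(labels, index=pd.Index(cols, name="sample_id"))


class TestFilterValid:
    @staticmethod
    def _df():
        # protein 0: 2/3 valid in g1, none in g2; protein 1: all missing
        return pd.DataFrame(
            {
                "a1": [1.0, np.nan],
                "a2": [2.0, np.nan],
                "a3": [np.nan, np.nan],
                "b1": [np.nan, np.nan],
                "b2": [np.nan, np.nan],
                "b3": [np.nan, np.nan],
            }
        )

    def test_any_group_keeps_half_quantified(self):
        g = groups_series(self._df().columns, ["g1"] * 3 + ["g2"] * 3)
        assert list(filter_valid(self._df(), g, 2, "any-group").index) == [0]

    def test_per_group_drops_it(self):
        g = groups_series(self._df().columns, ["g1"] * 3 + ["g2"] * 3)
        assert len(filter_valid(self._df(), g, 2, "per-group")) == 0

    def test_min_valid_above_group_size_rejected(self):
        g = groups_series(self._df().columns, ["g1"] * 3 + ["g2"] * 3)
        with pytest.raises(ValueError, match="min_valid"):
            filter_valid(self._df(), g, 4)


class TestWidthAdjust:
    def test_hand_computed_robust_z(self):
        # median 5, IQR 4: value 9 -> (9-5)/(4/1.349) = 1.349
        vals = np.array([1.0, 3.0, 4.0, 4.5, 5.0, 5.5, 6.0, 7.0, 9.0, 5.0, 5.0])
        df = pd.DataFrame({"s": vals})
        med = np.median(vals)
        iqr = np.percentile(vals, 75) - np.percentile(vals, 25)
        out = width_adjust(df)
        assert out["s"].iloc[8] == pytest.approx((9 - med) / (iqr / 1.349))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"s": rng.normal(20, 3, 200)})
        once = width_adjust(df)
        twice = width_adjust(once)
        np.testing.assert_allclose(twice["s"], once["s"], atol=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="zero IQR"):
            width_adjust(pd.DataFrame({"bad": np.full(20, 7.0)}))

    def test_missing_untouched(self):
        vals = np.concatenate([np.arange(12.0), [np.nan]])
        out = width_adjust(pd.DataFrame({"s": vals}))
        assert np.isnan(out["s"].iloc[-1])


class TestImputation:
    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"s": np.arange(10.0)})
        pd.testing.assert_frame_equal(impute_gaussian(df, seed=1), df)

    def test_moments_match_downshifted_normal(self):
        rng = np.random.default_rng(2)
        obs = rng.standard_normal(1000)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 20.0
        df = pd.DataFrame({"s": np.concatenate([obs, np.full(10_000, np.nan)])})
        imp = impute_gaussian(df, downshift=1.8, width=0.3, seed=3)["s"].to_numpy()[1000:]
        se_mean = 0.6 / np.sqrt(10_000)
        assert abs(imp.mean() - 16.4) < 3 * se_mean
        se_sd = 0.6 / np.sqrt(2 * 10_000)
        assert abs(imp.std(ddof=1) - 0.6) < 3 * se_sd

    def test_same_seed_reproduces(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0, np.nan, np.nan, 4.0]})
        pd.testing.assert_frame_equal(impute_gaussian(df, seed=9), impute_gaussian(df, seed=9))

    def test_observed_values_untouched(self):
        df = pd.DataFrame({"s": [1.0, 2.0, 3.0, np.nan]})
        out = impute_gaussian(df, seed=0)
        np.testing.assert_array_equal(out["s"].iloc[:3], df["s"].iloc[:3])


class TestPermutationAnova:
    @staticmethod
    def _null_data(seed, n=400):
        rng = np.random.default_rng(seed)
        cols = [f"{g}{r}" for g in "abcd" for r in range(3)]
        df = pd.DataFrame(rng.normal(20, 1, (n, 12)), columns=cols)
        return df, groups_series(cols, [c[0] for c in cols])

    def test_global_null_controls_fdr(self):
        df, g = self._null_data(1, n=1000)
        res = permutation_anova(df, g, n_permutations=250, fdr=0.01, seed=1)
        assert res.table["significant"].mean() <= 0.02

    def test_strong_effect_detected(self):
        df, g = self._null_data(2)
        # group means 10 SDs apart: 0 / 10 / 20 / 30 on noise SD 1
        df.iloc[0] += np.repeat([0.0, 10.0, 20.0, 30.0], 3)
        res = permutation_anova(df, g, n_permutations=100, fdr=0.01, seed=2)
        assert res.table.loc[0, "significant"]
        assert res.table.loc[0, "q"] < 0.01

    def test_constant_protein_f_zero_q_one(self):
        df, g = self._null_data(3, n=10)
        df.iloc[5] = 7.0
        res = permutation_anova(df, g, n_permutations=50, seed=3)
        assert res.table.loc[5, "statistic"] == 0.0
        assert res.table.loc[5, "q"] == 1.0

    def test_q_monotone_in_f(self):
        df, g = self._null_data(4)
        res = permutation_anova(df, g, n_permutations=100, seed=4)
        t = res.table.sort_values("statistic", ascending=False)
        assert (t["q"].diff().dropna() >= -1e-12).all()


class TestTwoGroup:
    def test_identical_groups_null(self):
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        df = pd.DataFrame([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0]], columns=cols)
        g = groups_series(cols, ["x", "x", "x", "y", "y", "y"])
        res = two_group_test(df, g, n_permutations=50, seed=0)
        assert res.table.loc[0, "statistic"] == 0.0
        assert res.table.loc[0, "q"] == 1.0

    def test_global_null_false_call_rate(self):
        rng = np.random.default_rng(5)
        cols = [f"{g}{r}" for g in "xy" for r in range(4)]
        df = pd.DataFrame(rng.normal(0, 1, (800, 8)), columns=cols)
        g = groups_series(cols, [c[0] for c in cols])
        res = two_group_test(df, g, n_permutations=250, fdr=0.01, seed=5)
        assert res.table["significant"].mean() <= 0.02

    def test_paired_close_to_unpaired_without_pairing(self):
        rng = np.random.default_rng(6)
        cols = [f"{g}{r}" for g in "xy" for r in range(6)]
        df = pd.DataFrame(rng.normal(0, 1, (300, 12)), columns=cols)
        g = groups_series(cols, [c[0] for c in cols])
        r_u = two_group_test(df, g, n_permutations=200, seed=6)
        r_p = two_group_test(df, g, n_permutations=200, paired=True, seed=6)
        # same nulls apply when pairing is uninformative: similar call rates
        assert abs(r_u.table["significant"].mean() - r_p.table["significant"].mean()) < 0.02

    def test_paired_requires_matched_sizes(self):
        cols = ["a1", "a2", "b1", "b2", "b3"]
        df = pd.DataFrame(np.ones((2, 5)), columns=cols)
        g = groups_series(cols, ["x", "x", "y", "y", "y"])
        with pytest.raises(ValueError, match="matched"):
            two_group_test(df, g, paired=True)


def temporal_table(values_by_model, tps, n_rep=1):
    """Tiny temporal ProteinGroupTable from {model: protein x timepoint array}."""
    cols, data, meta_rows = [], [], []
    for model, arr in values_by_model.items():
        for j, t in enumerate(tps[model] if isinstance(tps, dict) else tps):
            for r in range(1, n_rep + 1):
                cols.append(f"{model}_t{t:g}_r{r}")
                data.append(np.asarray(arr)[:, j])
                meta_rows.append((model, float(t), r, f"{model}_t{t:g}"))
    intens = pd.DataFrame(np.column_stack(data), columns=cols)
    intens.index.name = "protein_id"
    meta = pd.DataFrame(
        meta_rows,
        columns=["model", "timepoint_days", "replicate", "condition"],
        index=pd.Index(cols, name="sample_id"),
    )
    meta["fraction_index"] = np.nan
    return ProteinGroupTable(intens, meta)


class TestZScoreProfiles:
    def test_population_sd_convention(self):
        table = temporal_table({"M1": [[2.0, 4.0, 8.0]]}, [0, 1, 2])  # log2 -> [1,2,3]
        z, degen = zscore_profiles(table)
        np.testing.assert_allclose(
            z.loc[(0, "M1")].to_numpy(), [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )
        assert not degen.iloc[0]

    def test_constant_profile_flagged_zero(self):
        table = temporal_table({"M1": [[4.0, 4.0, 4.0]]}, [0, 1, 2])
        z, degen = zscore_profiles(table)
        assert (z.loc[(0, "M1")] == 0).all()
        assert degen.iloc[0]

    def test_uncommon_timepoints_excluded_everywhere(self):
        table = temporal_table(
            {"M1": [[2.0, 4.0, 8.0, 16.0]], "M2": [[2.0, 4.0, 8.0]]},
            {"M1": [0, 1, 2, 3], "M2": [0, 1, 2]},
        )
        z, _ = zscore_profiles(table)
        assert list(z.columns) == [0.0, 1.0, 2.0]


class TestConservedTrajectory:
    def test_identical_profiles_conserved(self):
        table = temporal_table({m: [[2.0, 4.0, 8.0]] for m in ("M1", "M2", "M3")}, [0, 1, 2])
        z, d = zscore_profiles(table)
        assert conserved_trajectory(z, d).iloc[0]

    def test_one_negated_model_not_conserved(self):
        table = temporal_table({"M1": [[2.0, 4.0, 8.0]], "M2": [[8.0, 4.0, 2.0]]}, [0, 1, 2])
        z, d = zscore_profiles(table)
        assert not conserved_trajectory(z, d).iloc[0]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        models = ["M1", "M2", "M3", "M4"]
        raw = {m: rng.standard_normal((1000, 6)) for m in models}
        frames, keys = [], []
        for m in models:
            X = raw[m]
            z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            frames.append(pd.DataFrame(z, columns=range(6)))
            keys.extend((i, m) for i in range(1000))
        zdf = pd.concat(frames)
        zdf.index = pd.MultiIndex.from_tuples(keys, names=["protein_id", "model"])
        called = conserved_trajectory(zdf)
        for i in range(1000):
            expect = all(
                stats.pearsonr(raw[m1][i], raw[m2][i]).statistic > 0
                for m1, m2 in itertools.combinations(models, 2)
            )
            assert called[i] == expect


class TestFoldChangeClasses:
    @staticmethod
    def _run(ref_vals, cmp_vals):
        cols = ["r1", "r2", "c1", "c2"]
        df = pd.DataFrame([ref_vals + cmp_vals], columns=cols)
        g = groups_series(cols, ["ref", "ref", "cmp", "cmp"])
        return fold_change_classes(df, g, "ref", "cmp")

    def test_fifteen_fold_up(self):
        assert self._run([100.0, 100.0], [1500.0, 1500.0]).iloc[0] == "up>10x"

    def test_nine_fold_is_other(self):
        assert self._run([100.0, 100.0], [900.0, 900.0]).iloc[0] == "other"

    def test_exclusive_undifferentiated(self):
        assert (
            self._run([100.0, 100.0], [np.nan, np.nan]).iloc[0] == "exclusive-undifferentiated"
        )

    def test_exclusive_mature(self):
        assert self._run([np.nan, np.nan], [500.0, 600.0]).iloc[0] == "exclusive-mature"

    def test_both_invalid_skipped(self):
        assert len(self._run([np.nan, np.nan], [np.nan, np.nan])) == 0


class TestHierarchicalCluster:
    def test_two_planted_archetypes_split_exactly(self):
        up = np.tile([-1.0, 0.0, 1.0], (10, 1))
        down = np.tile([1.0, 0.0, -1.0], (10, 1))
        mat = pd.DataFrame(np.vstack([up, down]))
        labels, _ = hierarchical_cluster(mat, n_clusters=2)
        assert labels.iloc[:10].nunique() == 1
        assert labels.iloc[10:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_partition_invariant_under_row_permutation(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.standard_normal((40, 5)))
        labels, _ = hierarchical_cluster(mat, 4)
        perm = rng.permutation(40)
        labels_p, _ = hierarchical_cluster(mat.iloc[perm], 4)
        assert adjusted_rand_score(labels.iloc[perm], labels_p) == 1.0

    def test_planted_archetypes_recovered_from_simulation(self):
        from sklearn.metrics import adjusted_rand_score

        spec = TemporalSimSpec(seed=9, n_models=1, frac_nonconserved=0.0, mnar_quantile=0.0)
        table, truth = simulate_temporal(spec)
        z, _ = zscore_profiles(table)
        zm = z.xs("M1", level="model")
        prot = truth.proteins
        nonflat = prot.index[(~prot["is_histone"]) & (prot["archetype_M1"] != "flat")]
        labels, _ = hierarchical_cluster(zm.loc[nonflat], 3)
        ari = adjusted_rand_score(prot.loc[nonflat, "archetype_M1"], labels)
        assert ari >= 0.9

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(pd.DataFrame(np.eye(3)), 4)


class TestProteomicRuler:
    @staticmethod
    def _table(hist=1e9, prot=1e9, mass_p=15000.0):
        meta = pd.DataFrame(
            {
                "model": "M1",
                "timepoint_days": 0.0,
                "replicate": 1,
                "condition": "d0",
                "fraction_index": np.nan,
            },
            index=pd.Index(["s1"], name="sample_id"),
        )
        intens = pd.DataFrame({"s1": [hist, prot]}, index=pd.Index(["H1", "P1"], name="protein_id"))
        return ProteinGroupTable(
            intens, meta, molar_mass_da=pd.Series([15000.0, mass_p], index=intens.index)
        )

    def test_closed_form_single_histone(self):
        copies, _ = proteomic_ruler(self._table(), ["H1"], dna_mass_per_cell_pg=6.5)
        expected = 6.5e-12 * AVOGADRO / 15000.0
        assert copies.loc["P1", "s1"] == pytest.approx(expected, rel=1e-12)

    def test_intensity_unit_invariance(self):
        c1, _ = proteomic_ruler(self._table(1e9, 1e9), ["H1"])
        c2, _ = proteomic_ruler(self._table(2e9, 2e9), ["H1"])
        pd.testing.assert_frame_equal(c1, c2)

    def test_halving_histone_sum_doubles_copies(self):
        c1, _ = proteomic_ruler(self._table(1e9, 1e9), ["H1"])
        c2, _ = proteomic_ruler(self._table(0.5e9, 1e9), ["H1"])
        assert c2.loc["P1", "s1"] == pytest.approx(2 * c1.loc["P1", "s1"], rel=1e-12)

    def test_missing_molar_mass_skipped(self):
        table = self._table(mass_p=np.nan)
        copies, _ = proteomic_ruler(table, ["H1"])
        assert "P1" not in copies.index
        assert "H1" in copies.index

    def test_ranked_zscores_have_unit_moments(self):
        rng = np.random.default_rng(10)
        ranks = pd.DataFrame(rng.random((20, 6)) * 100)
        z = ranked_copy_zscores(ranks)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)
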