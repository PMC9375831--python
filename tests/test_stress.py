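"""Stress labeling, normality screen, ANOVA/Tukey, SMOTE, classifiers."""

import numpy as np
import pandas as pd
import pytest

from pulsebench import (
    assign_stress_labels,
    fit_eval_classifiers,
    normality_screen,
    oneway_anova,
    smote_balance,
    tukey_pairwise,
)
from pulsebench.errors import InvalidArgument, InvalidLabel
from pulsebench.stress import NON_STRESS, STRESS, SplitConfig


def cohort_manifest(n_test=26, n_ctrl=30):
    rows = []
    for i in range(n_test + n_ctrl):
        group = "test" if i < n_test else "ctrl"
        for task in ("T1", "T2", "T3"):
            rows.append({"subject": f"s{i:02d}", "task": task, "group": group})
    return pd.DataFrame(rows)


def anova_bruteforce(groups):
    """Explicit sums-of-squares oracle."""
    allx = np.concatenate(groups)
    grand = allx.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - np.mean(g)) ** 2 for x in g) for g in groups)
    dfb, dfw = len(groups) - 1, len(allx) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestLabeling:
    @pytest.mark.parametrize(
        "task,group,expected",
        [
            ("T1", "test", NON_STRESS),
            ("T1", "ctrl", NON_STRESS),
            ("T2", "test", STRESS),
            ("T2", "ctrl", NON_STRESS),
            ("T3", "test", STRESS),
            ("T3", "ctrl", NON_STRESS),
        ],
    )
    def test_labeling_rule(self, task, group, expected):
        df = pd.DataFrame([{"subject": "s", "task": task, "group": group}])
        assert assign_stress_labels(df)["stress_label"].iloc[0] == expected

    def test_cohort_shape_counts(self):
        labeled = assign_stress_labels(cohort_manifest())
        counts = labeled["stress_label"].value_counts()
        assert len(labeled) == 168
        assert counts[STRESS] == 52 and counts[NON_STRESS] == 116

    def test_unknown_codes_rejected(self):
        df = pd.DataFrame([{"subject": "s", "task": "T9", "group": "test"}])
        with pytest.raises(InvalidLabel):
            assign_stress_labels(df)


class TestNormalityScreen:
    def test_gaussian_retained_skewed_rejected(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"gauss": rng.normal(0, 1, 168), "skewed": rng.exponential(1.0, 168)}
        )
        retained, pvals, _ = normality_screen(df, ["gauss", "skewed"])
        assert "gauss" in retained and "skewed" not in retained
        assert pvals["skewed"] < 0.05

    def test_constant_feature_degenerate(self):
        df = pd.DataFrame({"const": np.ones(20)})
        retained, _, degenerate = normality_screen(df, ["const"])
        assert degenerate == ["const"] and retained == []


class TestOnewayAnova:
    def test_equal_means_f_zero(self):
        df = pd.DataFrame(
            {"y": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0], "g": ["a"] * 3 + ["b"] * 3}
        )
        res = oneway_anova(df, "y", "g")
        assert res.F == pytest.approx(0.0)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "y": np.concatenate([rng.normal(0, 1, 84), rng.normal(1, 1, 84)]),
                "g": ["a"] * 84 + ["b"] * 84,
            }
        )
        res = oneway_anova(df, "y", "g")
        assert res.p < 0.05
        assert (res.df_between, res.df_within) == (1, 166)

    @pytest.mark.parametrize("k,sizes", [(2, (5, 7)), (3, (4, 9, 10)), (4, (3, 3, 3, 3))])
    def test_matches_bruteforce_sums_of_squares(self, k, sizes):
        rng = np.random.default_rng(k)
        groups = [rng.normal(i * 0.5, 1.0, n) for i, n in enumerate(sizes)]
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat([f"g{i}" for i in range(k)], sizes),
            }
        )
        res = oneway_anova(df, "y", "g")
        assert res.F == pytest.approx(anova_bruteforce(groups), rel=1e-12)


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 30)
        df = pd.DataFrame(
            {"y": np.concatenate([base, base, base]), "g": np.repeat(list("abc"), 30)}
        )
        out = tukey_pairwise(df, "y", "g")
        assert len(out) == 3 and not out["significant"].any()

    def test_single_shifted_group_flags_its_two_pairs(self):
        # mirrors a rest task separated from two similar activity tasks
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {
                "y": np.concatenate(
                    [rng.normal(3.0, 1, 40), rng.normal(0, 1, 40), rng.normal(0, 1, 40)]
                ),
                "g": np.repeat(["T1", "T2", "T3"], 40),
            }
        )
        out = tukey_pairwise(df, "y", "g")
        sig = out[out["significant"]]
        assert len(sig) == 2
        assert all("T1" in (a, b) for a, b in zip(sig["group_a"], sig["group_b"]))

    def test_two_groups_single_comparison(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {"y": rng.normal(0, 1, 20), "g": ["a"] * 10 + ["b"] * 10}
        )
        assert len(tukey_pairwise(df, "y", "g")) == 1


class TestSmote:
    @staticmethod
    def labeled_features(n_min=52, n_maj=116, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            {
                "f1": rng.normal(0, 1, n_min + n_maj),
                "f2": rng.normal(0, 1, n_min + n_maj),
                "stress_label": [STRESS] * n_min + [NON_STRESS] * n_maj,
            }
        )
        return df

    def test_cohort_counts_balance_to_232(self):
        bal = smote_balance(self.labeled_features(), ["f1", "f2"], seed=9)
        assert len(bal) == 232
        counts = bal["stress_label"].value_counts()
        assert counts[STRESS] == counts[NON_STRESS] == 116

    def test_originals_unchanged(self):
        df = self.labeled_features()
        bal = smote_balance(df, ["f1", "f2"], seed=9)
        original = bal[~bal["synthetic"]]
        pd.testing.assert_frame_equal(
            original[["f1", "f2", "stress_label"]].reset_index(drop=True),
            df[["f1", "f2", "stress_label"]],
        )

    def test_synthetic_points_lie_on_neighbor_segments(self):
        from sklearn.neighbors import NearestNeighbors

        df = self.labeled_features(n_min=20, n_maj=60, seed=3)
        bal = smote_balance(df, ["f1", "f2"], seed=4)
        X_min = df.loc[df["stress_label"] == STRESS, ["f1", "f2"]].to_numpy()
        nn = NearestNeighbors(n_neighbors=6).fit(X_min)
        neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]
        synth = bal.loc[bal["synthetic"], ["f1", "f2"]].to_numpy()
        for s in synth:
            on_segment = False
            for i, x in enumerate(X_min):
                for j in neigh[i]:
                    d = X_min[j] - x
                    denom = float(d @ d)
                    if denom == 0:
                        continue
                    u = float((s - x) @ d) / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(s, x + u * d, atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_balanced_input_returned_unchanged(self):
        df = self.labeled_features(n_min=30, n_maj=30)
        bal = smote_balance(df, ["f1", "f2"], seed=1)
        assert len(bal) == 60 and not bal["synthetic"].any()

    def test_seeded_reproducibility(self):
        df = self.labeled_features()
        a = smote_balance(df, ["f1", "f2"], seed=5)
        b = smote_balance(df, ["f1", "f2"], seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_tiny_minority_rejected(self):
        df = self.labeled_features(n_min=4, n_maj=20)
        with pytest.raises(InvalidArgument):
            smote_balance(df, ["f1", "f2"], k_neighbors=5)


class TestClassifiers:
    @staticmethod
    def dataset(separation, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack(
            [rng.normal(0, 1, (n // 2, 4)), rng.normal(separation, 1, (n // 2, 4))]
        )
        df = pd.DataFrame(X, columns=[f"x{i}" for i in range(4)])
        df["stress_label"] = [NON_STRESS] * (n // 2) + [STRESS] * (n // 2)
        return df

    def test_separable_data_high_accuracy(self):
        df = self.dataset(separation=4.0, seed=1)
        table = fit_eval_classifiers(df, [f"x{i}" for i in range(4)], seed=2)
        assert set(table["model"]) == {"RF", "SVM", "KNN", "LightGBM"}
        assert (table["accuracy"] > 90.0).all()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(10)
        df = self.dataset(separation=3.0, n=240, seed=3)
        df["stress_label"] = rng.permutation(df["stress_label"].to_numpy())
        table = fit_eval_classifiers(df, [f"x{i}" for i in range(4)], seed=4)
        assert ((table["accuracy"] - 50.0).abs() <= 10.0).all()

    def test_configured_hyperparameters(self):
        from pulsebench.stress import _make_models

        models = _make_models(n_trees=20, knn_k=5, seed=0)
        assert models["RF"].n_estimators == 20
        assert models["KNN"].n_neighbors == 5
        assert models["SVM"].kernel == "linear"

    def test_deterministic_given_seed(self):
        df = self.dataset(separation=1.0, seed=5)
        a = fit_eval_classifiers(df, [f"x{i}" for i in range(4)], seed=7)
        b = fit_eval_classifiers(df, [f"x{i}" for i in range(4)], seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_split_config(self):
        df = self.dataset(separation=2.0, n=90, seed=6)
        table = fit_eval_classifiers(
            df, [f"x{i}" for i in range(4)], seed=1, split=SplitConfig(test_fraction=0.5)
        )
        assert (table["n_test"] == 45).all()
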