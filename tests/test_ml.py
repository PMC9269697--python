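import numpy as np
import pandas as pd
import pytest

from mobiso.ml import (
    correlation_prune,
    cross_domain,
    cross_validate,
    domain_view,
    fuse,
    train_eval,
)


def window_table(user_ids, day_epochs, rng, kind="indoor", scale=1.0):
    """Minimal window-level feature frame with the domain's column names."""
    rows = []
    for uid in user_ids:
        for day in day_epochs:
            for w in range(6):
                start = day + 2400.0 * w
                base = {
                    "user_id": uid,
                    "window_start": start,
                    "window_end": start + 2400.0,
                    "avg_distance": scale * rng.uniform(1, 10),
                    "cluster_id": int(rng.integers(0, 3)),
                }
                if kind == "indoor":
                    base["avg_speed"] = base["avg_distance"] / 2400.0
                    base["emotion"] = 0
                else:
                    base["avg_estimated_speed"] = base["avg_distance"] / 2400.0
                    base["speed_over_ground"] = scale * rng.uniform(0.1, 1.5)
                    base["avg_course"] = float(rng.uniform(0, 360))
                rows.append(base)
    return pd.DataFrame(rows)


DAY0 = 1_651_449_600.0  # four consecutive days
DAYS = [DAY0 + 86400.0 * i for i in range(4)]


class TestCorrelationPrune:
    def test_duplicated_column_dropped_once(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"]
        df["c"] = rng.normal(size=50)
        pruned, corr, dropped = correlation_prune(df, threshold=0.9)
        assert dropped == ["b"] or dropped == ["a"]
        assert len({"a", "b"} & set(pruned.columns)) == 1  # never both removed

    def test_orthogonal_features_untouched(self, rng):
        df = pd.DataFrame(rng.normal(size=(1000, 4)), columns=list("wxyz"))
        pruned, corr, dropped = correlation_prune(df, threshold=0.9)
        assert dropped == []
        assert np.all(np.abs(corr.to_numpy()[~np.eye(4, dtype=bool)]) < 0.3)

    def test_distance_speed_pair_flagged_with_distance_kept(self, cohort):
        pruned, corr, dropped = correlation_prune(cohort["indoor_tab"])
        assert corr.loc["avg_distance", "avg_speed"] > 0.9
        assert "avg_speed" in dropped
        assert "avg_distance" in pruned.columns

    def test_constant_feature_flagged_and_excluded(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        pruned, _, dropped = correlation_prune(df)
        assert "b" in dropped and "b" not in pruned.columns

    def test_too_few_features_rejected(self, rng):
        with pytest.raises(ValueError):
            correlation_prune(pd.DataFrame({"a": rng.normal(size=10)}))


class TestFuse:
    def test_disjoint_user_sets_rejected(self, rng):
        ind = window_table([1, 2], DAYS, rng, kind="indoor")
        out = window_table([8, 9], DAYS, rng, kind="outdoor")
        with pytest.raises(ValueError, match="no user-days"):
            fuse(ind, out)

    def test_five_users_with_both_domains_all_retained(self, rng):
        users = [1, 2, 3, 4, 7]
        ind = window_table(users, DAYS, rng, kind="indoor")
        out = window_table(users, DAYS, rng, kind="outdoor")
        fused = fuse(ind, out)
        assert sorted(fused.user_id.unique()) == users
        assert len(fused) == len(users) * len(DAYS)

    def test_fused_columns_are_the_shared_mobility_selection(self, rng):
        ind = window_table([1], DAYS, rng, kind="indoor")
        out = window_table([1], DAYS, rng, kind="outdoor")
        fused = fuse(ind, out)
        assert {
            "in_cluster_id", "out_cluster_id", "in_distance", "out_distance",
            "out_speed_over_ground",
        } <= set(fused.columns)

    def test_only_common_user_days_survive(self, rng):
        ind = window_table([1], DAYS, rng, kind="indoor")
        out = window_table([1], DAYS[:2], rng, kind="outdoor")
        fused = fuse(ind, out)
        assert len(fused) == 2


def separable_table(rng, n_per_class=40, n_classes=3):
    """Classes sit on disjoint feature ranges: any sane learner is perfect.

    Feature values repeat within a class so both folds of any split share
    the same support (tree learners bin thresholds at observed values).
    """
    rows = []
    for c in range(n_classes):
        for i in range(n_per_class):
            rows.append(
                {
                    "user_id": c + 1,
                    "window_start": DAY0 + i,
                    "window_end": DAY0 + i + 10,
                    "feat_a": 100.0 * c + (i % 3),
                    "feat_b": -50.0 * c + (i % 2),
                    "cluster_id": c,
                }
            )
    return pd.DataFrame(rows)


class TestTrainEval:
    @pytest.mark.parametrize("algorithm", ["svm", "rf", "xgb"])
    def test_separable_classes_score_100_with_identity_confusion(
        self, rng, algorithm
    ):
        table = separable_table(rng)
        report = train_eval(table, target="user", algorithm=algorithm, seed=0)
        assert report.accuracy == 100.0
        assert np.allclose(report.confusion, 100.0 * np.eye(3))

    def test_confusion_rows_sum_to_100(self, cohort):
        report = train_eval(
            cohort["indoor_tab"], target="user", algorithm="rf", seed=0,
            n_estimators=30,
        )
        assert np.allclose(report.confusion.sum(axis=1), 100.0, atol=1e-6)

    def test_permuted_labels_fall_to_chance(self, rng):
        table = separable_table(rng, n_per_class=60)
        table = table.copy()
        table["user_id"] = rng.permutation(table["user_id"].to_numpy())
        report = train_eval(table, target="user", algorithm="xgb", seed=0)
        n_test = int(0.2 * len(table))
        chance = 100.0 / 3
        se = 100.0 * np.sqrt((1 / 3) * (2 / 3) / n_test)
        assert abs(report.accuracy - chance) <= 3 * se

    def test_single_class_target_rejected(self, rng):
        table = separable_table(rng, n_classes=1)
        with pytest.raises(ValueError, match="single class"):
            train_eval(table, target="user", algorithm="rf")

    @pytest.mark.parametrize("algorithm", ["svm", "rf", "xgb"])
    def test_fixed_seed_reproduces_report(self, rng, algorithm):
        table = separable_table(rng)
        table["feat_a"] += rng.normal(scale=60.0, size=len(table))  # not trivial
        a = train_eval(table, target="user", algorithm=algorithm, seed=3)
        b = train_eval(table, target="user", algorithm=algorithm, seed=3)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_cross_validation_returns_fold_accuracies(self, rng):
        table = separable_table(rng)
        accs = cross_validate(table, target="user", algorithm="rf", n_splits=3)
        assert len(accs) == 3
        assert all(90.0 <= a <= 100.0 for a in accs)


class TestCrossDomain:
    def test_self_transfer_control_is_positive(self, rng):
        # both "domains" drawn from one distribution with a learnable
        # speed→distance relation
        def make(n):
            speed = rng.uniform(0.2, 2.0, size=n)
            return pd.DataFrame(
                {
                    "user_id": rng.integers(1, 4, size=n),
                    "avg_distance": speed * 600.0 + rng.normal(0, 5.0, size=n),
                    "avg_speed": speed,
                }
            )

        report = cross_domain(make(300), make(300), mode="regression")
        assert report.r2 > 0.5

    def test_mismatched_scales_give_negative_r2(self, rng):
        speed = rng.uniform(0.2, 2.0, size=300)
        indoor = pd.DataFrame(
            {
                "user_id": np.ones(300, dtype=int),
                "avg_distance": speed * 6.0 + rng.normal(0, 0.5, size=300),
                "avg_speed": speed,
            }
        )
        outdoor = pd.DataFrame(
            {
                "user_id": np.ones(300, dtype=int),
                "avg_distance": speed * 6000.0 + rng.normal(0, 50.0, size=300),
                "avg_estimated_speed": speed,
            }
        )
        report = cross_domain(indoor, outdoor, mode="regression")
        assert report.r2 < 0.0  # reported unclipped

    def test_domain_specific_signatures_give_chance_recall(self, rng):
        n = 200

        def domain(shuffle_map):
            uid = rng.integers(1, 5, size=n)
            centre = np.array([0.0, 5.0, 10.0, 15.0])[shuffle_map][uid - 1]
            return pd.DataFrame(
                {
                    "user_id": uid,
                    "avg_distance": centre + rng.normal(0, 0.3, size=n),
                    "avg_speed": centre / 10 + rng.normal(0, 0.05, size=n),
                }
            )

        train = domain(np.array([0, 1, 2, 3]))
        test = domain(np.array([2, 3, 0, 1]))  # signatures remapped
        report = cross_domain(train, test, mode="classification")
        assert report.accuracy < 40.0  # near 1/4 chance, far from self-transfer

    def test_shared_features_required(self, rng):
        bad = pd.DataFrame({"user_id": [1, 2], "something": [0.1, 0.2]})
        with pytest.raises(ValueError, match="shared features"):
            domain_view(bad)

    def test_above_chance_classification_on_identical_domains(self, rng):
        def domain():
            uid = rng.integers(1, 4, size=300)
            centre = np.array([0.0, 8.0, 16.0])[uid - 1]
            return pd.DataFrame(
                {
                    "user_id": uid,
                    "avg_distance": centre + rng.normal(0, 0.5, size=300),
                    "avg_speed": centre / 10 + rng.normal(0, 0.05, size=300),
                }
            )

        report = cross_domain(domain(), domain(), mode="classification")
        assert report.accuracy > 80.0
        assert set(report.per_class_recall) == {1, 2, 3}
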