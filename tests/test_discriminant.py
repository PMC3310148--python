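import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petvoi.discriminant import (FeatureTable, LinearDiscriminant,
                                 exhaustive_search, fit_lda, loocv_pct,
                                 permutation_test)


def make_table(X, labels, mmse=None):
    df = pd.DataFrame(X, columns=[f"r{i+1}" for i in range(X.shape[1])])
    df.insert(0, "group", labels)
    df.insert(0, "subject_id", [f"s{i:02d}" for i in range(len(df))])
    if mmse is not None:
        df["mmse"] = mmse
    return FeatureTable(df)


def random_3group_table(rng, n_features=3, counts=(10, 6, 7), shift=0.0):
    labels = np.repeat(["control", "MCI", "AD"], counts)
    X = rng.standard_normal((sum(counts), n_features))
    if shift:
        X[labels == "AD"] += shift
        X[labels == "MCI"] += shift / 2
    return make_table(X, rng.permutation(labels) if not shift else labels)


def oracle_fit(X, y, n_groups, priors="equal"):
    """Independent LDA fit: per-group means and pooled covariance built with
    explicit group loops, inverted directly."""
    n = len(y)
    means, scatters, counts = [], [], []
    for g in range(n_groups):
        Xg = X[y == g]
        counts.append(len(Xg))
        means.append(Xg.mean(axis=0))
        d = Xg - Xg.mean(axis=0)
        scatters.append(d.T @ d)
    cov = sum(scatters) / (n - n_groups)
    cov_inv = np.linalg.inv(cov)
    pri = (np.full(n_groups, 1 / n_groups) if priors == "equal"
           else np.asarray(counts) / n)
    return means, cov_inv, pri


def oracle_classify(X, means, cov_inv, pri):
    """Direct evaluation of mu'S^-1 x - mu'S^-1 mu/2 + ln pi per row."""
    preds = []
    for xi in np.atleast_2d(X):
        scores = [
            m @ cov_inv @ xi - 0.5 * m @ cov_inv @ m + np.log(pri[g])
            for g, m in enumerate(means)
        ]
        preds.append(int(np.argmax(scores)))
    return np.asarray(preds)


def oracle_predict(table, features, priors="equal"):
    X = table.X(features)
    means, cov_inv, pri = oracle_fit(X, table.y, table.n_groups, priors)
    return oracle_classify(X, means, cov_inv, pri)


# ---------------------------------------------------------------------------
# Model fitting and classification
# ---------------------------------------------------------------------------

class TestFitLda:
    def test_1d_two_group_boundary_at_midpoint(self):
        """Means 0 and 4, pooled variance 1, equal priors: boundary at 2."""
        rng = np.random.default_rng(0)
        a = rng.standard_normal(20)
        a = (a - a.mean()) / a.std(ddof=1)          # exact mean 0, var 1
        b = a + 4.0                                  # exact mean 4, var 1
        table = make_table(np.concatenate([a, b])[:, None],
                           ["g1"] * 20 + ["g2"] * 20)
        res = fit_lda(table, ("r1",))
        probe = make_table(np.array([[1.9], [2.1]]), ["g1", "g2"])
        assert list(res.predict(probe)) == ["g1", "g2"]

    def test_separable_clusters_classify_perfectly(self, rng):
        X = np.concatenate([
            rng.standard_normal((8, 2)) * 0.1 + c
            for c in ([0, 0], [10, 0], [0, 10])
        ])
        table = make_table(X, ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        res = fit_lda(table, ("r1", "r2"))
        assert res.classification_pct() == 100.0

    def test_predictions_match_score_formula_oracle(self, rng):
        for _ in range(100):
            table = random_3group_table(rng)
            for priors in ("equal", "proportional"):
                res = fit_lda(table, ("r1", "r2", "r3"), priors)
                got = np.array([table.groups.index(g)
                                for g in res.predict()])
                assert np.array_equal(got, oracle_predict(
                    table, ("r1", "r2", "r3"), priors))

    def test_predictions_match_sklearn_on_balanced_groups(self, rng):
        """Independent library cross-check.  sklearn weights class
        covariances by the priors (ddof 0) instead of pooling with N-G
        degrees of freedom; for balanced groups the two covariances are
        proportional and the priors constant, so predictions must agree."""
        sklearn_lda = pytest.importorskip(
            "sklearn.discriminant_analysis"
        ).LinearDiscriminantAnalysis
        for seed in range(20):
            rng2 = np.random.default_rng(seed)
            table = random_3group_table(rng2, n_features=4,
                                        counts=(8, 8, 8))
            res = fit_lda(table, ("r1", "r2", "r3", "r4"),
                          priors="proportional")
            clf = sklearn_lda(solver="lsqr")
            X = table.X(("r1", "r2", "r3", "r4"))
            clf.fit(X, table.y)
            assert np.array_equal(
                np.array([table.groups.index(g) for g in res.predict()]),
                clf.predict(X),
            )

    def test_rounding_contract_22_of_23(self):
        """22 correct out of 23 reports as 95.7%."""
        assert round(100 * 22 / 23, 1) == 95.7
        rng = np.random.default_rng(1)
        for seed in range(50):
            t = random_3group_table(np.random.default_rng(seed), shift=2.0)
            res = fit_lda(t, ("r1", "r2", "r3"))
            pct = res.classification_pct()
            n_correct = round(pct * 23 / 100)
            assert pct == round(100 * n_correct / 23, 1)

    def test_constant_features_fall_back_to_modal_class(self, caplog):
        """Zero-variance features engage the ridge and predictions reduce to
        the largest prior; with proportional priors accuracy equals the
        modal-class frequency."""
        X = np.ones((23, 2))
        labels = ["control"] * 10 + ["MCI"] * 6 + ["AD"] * 7
        table = make_table(X, labels)
        with caplog.at_level("INFO", logger="petvoi.discriminant"):
            res = fit_lda(table, ("r1", "r2"), priors="proportional")
        assert res.regularization > 0
        assert "ridge" in caplog.text
        assert res.classification_pct() == round(100 * 10 / 23, 1)

    def test_unknown_feature_rejected(self, rng):
        table = random_3group_table(rng)
        with pytest.raises(KeyError):
            fit_lda(table, ("r1", "does_not_exist"))

    def test_tiny_group_rejected(self):
        table = make_table(np.arange(8, dtype=float)[:, None],
                           ["a"] * 7 + ["b"])
        with pytest.raises((ValueError, RuntimeError)):
            fit_lda(table, ("r1",))

    def test_summary_mentions_features_and_accuracy(self, rng):
        res = fit_lda(random_3group_table(rng), ("r1", "r2"))
        text = res.summary()
        assert "r1, r2" in text and "Classification" in text

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-5.0, 5.0),
           seed=st.integers(0, 500))
    def test_affine_rescaling_invariance(self, scale, shift, seed):
        """Applying x -> a x + b identically to every subject leaves the
        predicted labels unchanged."""
        rng = np.random.default_rng(seed)
        table = random_3group_table(rng)
        base = fit_lda(table, ("r1", "r2", "r3")).predict()
        X2 = table.X(("r1", "r2", "r3")) * scale + shift
        table2 = make_table(X2, table.df["group"].tolist())
        assert list(fit_lda(table2, ("r1", "r2", "r3")).predict()) == list(base)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

class TestLoocv:
    def test_separated_clusters_reach_100(self, rng):
        X = np.concatenate([
            rng.standard_normal((8, 2)) * 0.1 + c
            for c in ([0, 0], [20, 0], [0, 20])
        ])
        table = make_table(X, ["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        assert loocv_pct(table, ("r1", "r2")) == 100.0

    def test_equals_per_fold_refit_oracle(self, rng):
        """LOOCV equals an oracle that literally refits n models via the
        independent score-formula evaluation."""
        for _ in range(100):
            table = random_3group_table(rng)
            feats = ("r1", "r2", "r3")
            got = loocv_pct(table, feats)
            X, y = table.X(feats), table.y
            correct = 0
            for i in range(table.n):
                tr = np.arange(table.n) != i
                means, cov_inv, pri = oracle_fit(X[tr], y[tr],
                                                 table.n_groups)
                if oracle_classify(X[i], means, cov_inv, pri)[0] == y[i]:
                    correct += 1
            assert got == round(100 * correct / table.n, 1)

    def test_loocv_not_above_resub_on_average(self, rng):
        gaps = []
        for _ in range(100):
            table = random_3group_table(rng)
            res = fit_lda(table, ("r1", "r2", "r3"))
            gaps.append(res.classification_pct()
                        - loocv_pct(table, ("r1", "r2", "r3")))
        assert np.mean(gaps) >= 0


# ---------------------------------------------------------------------------
# Exhaustive search
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def table9():
    rng = np.random.default_rng(3)
    labels = np.repeat(["control", "MCI", "AD"], (10, 6, 7))
    X = rng.standard_normal((23, 9))
    X[labels == "AD", 3] += 2.0
    mmse = rng.integers(20, 31, size=23)
    return make_table(X, labels, mmse=mmse)


class TestExhaustiveSearch:

    def test_enumerates_511_subsets(self, table9):
        assert len(exhaustive_search(table9)) == 511
        assert len(exhaustive_search(table9, include_mmse=True)) == 511

    def test_top_model_attains_max_loocv(self, table9):
        ranked = exhaustive_search(table9)
        best = max(r.loocv_pct for r in ranked)
        assert ranked[0].loocv_pct == best

    def test_ranking_key_respected(self, table9):
        ranked = exhaustive_search(table9)
        keys = [(-r.loocv_pct, -r.resub_pct, len(r.features), r.features)
                for r in ranked]
        assert keys == sorted(keys)
        assert [r.rank for r in ranked] == list(range(1, 512))

    def test_mmse_included_in_every_subset_when_flagged(self, table9):
        ranked = exhaustive_search(table9, include_mmse=True)
        assert all(r.features[-1] == "mmse" for r in ranked)

    def test_independent_of_column_order(self, table9):
        shuffled = FeatureTable(
            table9.df[["subject_id", "group", "mmse"]
                      + [f"r{i}" for i in (9, 3, 5, 1, 7, 2, 8, 4, 6)]]
        )
        a = exhaustive_search(table9)
        b = exhaustive_search(shuffled)
        assert [(r.features, r.loocv_pct, r.resub_pct) for r in a] == \
               [(r.features, r.loocv_pct, r.resub_pct) for r in b]

    def test_missing_columns_rejected(self, rng):
        table = random_3group_table(rng, n_features=5)
        with pytest.raises(KeyError):
            exhaustive_search(table)


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_null_counts_preserved(self, rng):
        y = np.repeat([0, 1, 2], (10, 6, 7))
        for _ in range(200):
            assert np.array_equal(
                np.bincount(rng.permutation(y)), np.bincount(y)
            )

    def test_fixed_seed_reproduces_null(self, rng):
        table = random_3group_table(rng, shift=1.0)
        a = permutation_test(table, ("r1", "r2"), n_perm=200, seed=5)
        b = permutation_test(table, ("r1", "r2"), n_perm=200, seed=5)
        assert np.array_equal(a.null_pcts, b.null_pcts)
        assert a.p_value == b.p_value

    def test_planted_effect_is_significant(self, rng):
        table = random_3group_table(rng, shift=3.0)
        res = permutation_test(table, ("r1", "r2", "r3"), n_perm=500, seed=1)
        assert res.p_value < 0.05

    def test_p_value_on_lattice_and_reported_as_bound_when_zero(self, rng):
        table = random_3group_table(rng, shift=5.0)
        res = permutation_test(table, ("r1", "r2", "r3"), n_perm=200, seed=2)
        assert res.p_value in {i / 200 for i in range(201)}
        if res.exceed_count == 0:
            assert res.p_str == "P < 0.005"

    def test_monotone_in_true_score(self, rng):
        """On the same null draw, a strictly better true score never yields a
        larger p-value."""
        table = random_3group_table(rng, shift=1.0)
        res = permutation_test(table, ("r1", "r2"), n_perm=300, seed=7)
        for better in (res.true_pct, res.true_pct + 5.0):
            worse_p = np.mean(res.null_pcts >= res.true_pct - 5.0)
            better_p = np.mean(res.null_pcts >= better)
            assert better_p <= worse_p

    def test_loocv_statistic_option(self, rng):
        table = random_3group_table(rng, shift=2.0)
        res = permutation_test(table, ("r1", "r2"), n_perm=50, seed=3,
                               statistic="loocv")
        assert res.n_perm == 50
        assert 0 <= res.p_value <= 1

    def test_invalid_arguments_rejected(self, rng):
        table = random_3group_table(rng)
        with pytest.raises(ValueError):
            permutation_test(table, ("r1",), n_perm=0)
        with pytest.raises(ValueError):
            permutation_test(table, ("r1",), n_perm=10, statistic="auc")


def test_model_results_round_trip_properties(rng):
    table = random_3group_table(rng)
    res = LinearDiscriminant(table, ("r1", "r2"), "equal").fit()
    assert res.priors.sum() == pytest.approx(1.0)
    cov = res.pooled_cov.to_numpy()
    assert np.allclose(cov, cov.T)
    assert np.all(np.linalg.eigvalsh(cov) > -1e-12)
    assert res.class_means.shape == (3, 2)
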