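"""Normalization and the screening chain: ICC, univariate, pruning, sparse."""

import itertools

import numpy as np
import pandas as pd
import pytest

from habikit.selection import (
    SelectionConfig,
    apply_normalizer,
    correlation_prune,
    fit_normalizer,
    icc21,
    icc_filter,
    run_selection,
    sparse_select,
    univariate_filter,
)


class TestNormalization:
    def test_minmax_maps_to_unit_interval(self):
        df = pd.DataFrame({"a": [0.0, 10.0], "b": [5.0, 15.0]})
        params = fit_normalizer(df, "minmax")
        out = apply_normalizer(params, df)
        np.testing.assert_allclose(out["a"], [0.0, 1.0])
        np.testing.assert_allclose(out["b"], [0.0, 1.0])

    def test_zscore_training_moments(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, size=(50, 4)), columns=list("abcd"))
        out = apply_normalizer(fit_normalizer(df, "zscore"), df)
        np.testing.assert_allclose(out.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(ddof=1), 1.0, atol=1e-12)

    def test_test_rows_outside_training_range_not_clipped(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        params = fit_normalizer(train, "minmax")
        out = apply_normalizer(params, pd.DataFrame({"a": [20.0]}))
        assert out["a"].iloc[0] == 2.0

    def test_constant_column_passed_through_as_zero(self):
        train = pd.DataFrame({"a": [3.0, 3.0, 3.0], "b": [0.0, 1.0, 2.0]})
        params = fit_normalizer(train, "minmax")
        assert params.constant_columns == ["a"]
        out = apply_normalizer(params, train)
        np.testing.assert_allclose(out["a"], 0.0)


class TestIcc:
    def test_identical_tables_all_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        kept, iccs = icc_filter(df, df.copy())
        assert kept == list("abcde")
        np.testing.assert_allclose(iccs.values, 1.0)

    def test_shuffled_column_dropped(self):
        rng = np.random.default_rng(2)
        df1 = pd.DataFrame(rng.normal(size=(30, 2)), columns=["good", "bad"])
        df2 = df1.copy()
        df2["bad"] = rng.permutation(df2["bad"].values)
        df2["good"] = df2["good"] + rng.normal(scale=0.01, size=30)
        kept, iccs = icc_filter(df1, df2)
        assert "good" in kept and "bad" not in kept
        assert abs(iccs["bad"]) < 0.4

    def test_bias_attenuates_absolute_agreement(self):
        """A constant reader offset lowers ICC(2,1) below consistency ICC."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + 3.0  # pure bias
        val = icc21(x, y)
        # consistency ICC (ICC(3,1)) of pure-bias data is 1
        assert val < 0.5

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = x + rng.normal(scale=0.5, size=25) + 0.3
        data = pd.DataFrame(
            {
                "case": np.tile(np.arange(25), 2),
                "rater": np.repeat(["r1", "r2"], 25),
                "value": np.concatenate([x, y]),
            }
        )
        ref = pingouin.intraclass_corr(
            data=data, targets="case", raters="rater", ratings="value"
        )
        # absolute-agreement single-rater row; label differs across versions
        sel = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        expected = ref.loc[sel, "ICC"].iloc[0]
        assert icc21(x, y) == pytest.approx(expected, abs=1e-9)


class TestUnivariate:
    def test_identical_distribution_not_kept(self):
        rng = np.random.default_rng(0)
        labels = np.array([0, 1] * 25)
        df = pd.DataFrame({"flat": np.ones(50), "noise": rng.normal(size=50)})
        kept, pvals = univariate_filter(df, labels)
        assert "flat" not in kept
        assert pvals["flat"] == 1.0

    def test_overwhelming_effect_kept(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 50 + [1] * 50)
        df = pd.DataFrame({"strong": np.where(labels, 5.0, 0.0) + rng.normal(size=100)})
        kept, _ = univariate_filter(df, labels)
        assert kept == ["strong"]

    def test_mannwhitney_close_to_exact_enumeration(self):
        """Asymptotic MWU p approximates the exact permutation p on 6 vs 6."""
        values = np.array([1.2, 3.4, 0.5, 2.2, 4.1, 1.9, 2.8, 5.0, 3.9, 4.6, 2.1, 3.1])
        labels = np.array([0] * 6 + [1] * 6)
        g0, g1 = values[:6], values[6:]
        u_obs = sum((a > b) + 0.5 * (a == b) for a in g1 for b in g0)
        # exact two-sided p by enumerating all C(12,6) group splits
        stats = []
        for idx in itertools.combinations(range(12), 6):
            sel = np.zeros(12, dtype=bool)
            sel[list(idx)] = True
            u = sum((a > b) + 0.5 * (a == b) for a in values[sel] for b in values[~sel])
            stats.append(abs(u - 18))
        exact_p = np.mean(np.array(stats) >= abs(u_obs - 18) - 1e-12)
        from scipy.stats import mannwhitneyu

        asym_p = mannwhitneyu(
            g0, g1, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert asym_p == pytest.approx(exact_p, abs=0.03)


class TestCorrelationPrune:
    def test_duplicate_column_one_survives(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=40)
        df = pd.DataFrame({"a": a, "a_copy": a, "b": rng.normal(size=40)})
        kept = correlation_prune(df)
        assert "b" in kept
        assert len([c for c in kept if c.startswith("a")]) == 1

    def test_independent_noise_all_survive(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(100, 8)), columns=list("abcdefgh"))
        assert len(correlation_prune(df)) == 8

    def test_three_mutual_duplicates_one_survives(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=40)
        df = pd.DataFrame({"x": a, "y": a.copy(), "z": a.copy()})
        assert len(correlation_prune(df)) == 1


class TestSparseSelect:
    def test_planted_informative_columns_recovered(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 200
            labels = rng.integers(0, 2, size=n)
            noise = rng.normal(size=(n, 50))
            df = pd.DataFrame(noise, columns=[f"n{i}" for i in range(50)])
            df["inf1"] = labels * 1.5 + rng.normal(size=n)
            df["inf2"] = labels * -1.5 + rng.normal(size=n)
            kept, _ = sparse_select(df, labels, seed=seed)
            hits += ("inf1" in kept) and ("inf2" in kept)
        assert hits >= 8

    def test_pure_noise_keeps_few(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, size=100)
        df = pd.DataFrame(rng.normal(size=(100, 30)))
        df.columns = [f"c{i}" for i in range(30)]
        kept, log = sparse_select(df, labels, seed=0)
        assert len(kept) <= 10 or log["fallback"]

    def test_perfect_separator_kept(self):
        labels = np.array([0] * 20 + [1] * 20)
        df = pd.DataFrame({"sep": labels.astype(float)})
        kept, _ = sparse_select(df, labels, seed=0)
        assert kept == ["sep"]


class TestFullChain:
    def test_determinism_and_training_only(self):
        rng = np.random.default_rng(5)
        n = 80
        labels = rng.integers(0, 2, size=n)
        df = pd.DataFrame(rng.normal(size=(n, 20)), columns=[f"f{i}" for i in range(20)])
        df["planted"] = labels * 2.0 + rng.normal(size=n)
        r1 = run_selection(df, labels, config=SelectionConfig(seed=9))
        r2 = run_selection(df, labels, config=SelectionConfig(seed=9))
        assert r1.kept == r2.kept
        assert "planted" in r1.kept
        assert [s["step"] for s in r1.steps] == ["univariate", "correlation", "sparse"]
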