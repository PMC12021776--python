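"""Reader-study primitives: consensus, binarization, rounds, strata, Sankey."""

import numpy as np
import pandas as pd
import pytest

from habikit.readers import (
    compare_rounds,
    consensus_call,
    consensus_from_assessments,
    per_score_metrics,
    rads_binarize,
    sankey_data,
)


class TestConsensus:
    @pytest.mark.parametrize(
        "repeats,expected",
        [((1, 1, 0), 1), ((0, 0, 0), 0), ((1, 0, 0), 0), ((1, 1, 1), 1)],
    )
    def test_majority_vote(self, repeats, expected):
        assert consensus_call(repeats) == expected

    def test_wrong_repeat_count_rejected(self):
        with pytest.raises(ValueError):
            consensus_call([1, 0])

    def test_consensus_from_table(self):
        rows = []
        for rep, call in enumerate([1, 0, 1], start=1):
            rows.append(
                {"case_id": "c1", "reader_id": "r1", "round": 1, "repeat": rep,
                 "call": call, "rads_score": 3}
            )
        table = consensus_from_assessments(pd.DataFrame(rows))
        assert table["call"].iloc[0] == 1
        assert table["rads_score"].iloc[0] == 3


class TestBinarize:
    @pytest.mark.parametrize("score,expected", [(1, 0), (2, 0), (3, 1), (4, 1), (5, 1)])
    def test_threshold_at_three(self, score, expected):
        assert rads_binarize([score])[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rads_binarize([0, 3])


class TestCompareRounds:
    def test_perfect_second_round(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        r1 = rng.integers(0, 2, size=60)
        out = compare_rounds(r1, labels.copy(), labels)
        assert out["round2"].auc == 1.0
        assert out["delta_auc"] >= 0

    def test_identical_rounds_p_one(self):
        labels = np.array([0, 1] * 20)
        calls = np.array([0, 0, 1, 1] * 10)
        out = compare_rounds(calls, calls.copy(), labels)
        assert out["p_auc_delong"] == 1.0
        assert out["p_accuracy_mcnemar"] == 1.0

    def test_assistance_power_simulation(self):
        """Raising sensitivity 0.5 -> 0.8 at n = 300 is usually detected."""
        detections = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            labels = (rng.uniform(size=300) < 0.5).astype(int)
            p1 = np.where(labels == 1, 0.5, 0.2)
            p2 = np.where(labels == 1, 0.8, 0.2)
            r1 = (rng.uniform(size=300) < p1).astype(int)
            r2 = (rng.uniform(size=300) < p2).astype(int)
            out = compare_rounds(r1, r2, labels)
            detections += out["p_accuracy_mcnemar"] < 0.05
        assert detections >= 80

    def test_reduces_to_stats_primitives(self):
        from habikit.stats import delong_test, eval_report, mcnemar_test

        rng = np.random.default_rng(5)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        r1 = rng.integers(0, 2, size=80)
        r2 = rng.integers(0, 2, size=80)
        out = compare_rounds(r1, r2, labels)
        assert out["round1"].auc == eval_report(r1, r1, labels).auc
        assert out["p_auc_delong"] == delong_test(r2, r1, labels)[1]
        assert out["p_accuracy_mcnemar"] == mcnemar_test(r2, r1, labels)


class TestPerScoreMetrics:
    def test_all_negative_stratum_flags_sensitivity(self):
        scores = np.array([1, 1, 1])
        labels = np.zeros(3, dtype=int)
        calls = np.zeros(3, dtype=int)
        table = per_score_metrics(scores, calls, calls, labels)
        row = table[(table["rads_score"] == 1) & (table["rater"] == "reader")].iloc[0]
        assert row["specificity"] == 1.0
        assert row["sensitivity"] is None

    def test_model_equals_labels_perfect_accuracy(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(1, 6, size=40)
        labels = rng.integers(0, 2, size=40)
        table = per_score_metrics(scores, rng.integers(0, 2, 40), labels, labels)
        model_rows = table[(table["rater"] == "model") & (table["n"] > 0)]
        assert (model_rows["accuracy"] == 1.0).all()

    def test_pooled_strata_reproduce_overall_two_by_two(self):
        rng = np.random.default_rng(2)
        scores = rng.integers(1, 6, size=100)
        labels = rng.integers(0, 2, size=100)
        reader_calls = rads_binarize(scores)
        table = per_score_metrics(scores, reader_calls, reader_calls, labels)
        reader_rows = table[table["rater"] == "reader"]
        # pooled accuracy equals overall accuracy
        num = sum(
            r["accuracy"] * r["n"] for _, r in reader_rows.iterrows() if r["n"] > 0
        )
        assert num / 100 == pytest.approx((reader_calls == labels).mean())


class TestSankey:
    def test_no_reclassification_when_model_agrees(self):
        scores = np.array([1, 2, 3, 4, 5])
        model_calls = rads_binarize(scores)
        labels = np.array([0, 0, 1, 1, 1])
        sk, table = sankey_data(scores, model_calls, labels)
        assert table.reclassified_positive == []
        assert table.reclassified_negative == []
        assert sk.check_conservation()

    def test_single_reclassified_positive(self):
        scores = np.array([2])
        model_calls = np.array([1])
        labels = np.array([1])
        sk, table = sankey_data(scores, model_calls, labels, case_ids=["p1"])
        assert table.reclassified_positive == ["p1"]
        links = [l for l in sk.links if l["flow"] == "reclassified-positive"]
        assert len(links) == 1 and links[0]["count"] == 1

    def test_flow_conservation_on_random_cases(self):
        rng = np.random.default_rng(3)
        n = 20
        scores = rng.integers(1, 6, size=n)
        model_calls = rng.integers(0, 2, size=n)
        labels = rng.integers(0, 2, size=n)
        sk, _ = sankey_data(scores, model_calls, labels)
        stage1 = sum(
            l["count"] for l in sk.links
            if any(node["id"] == l["source"] and node["stage"] == "score" for node in sk.nodes)
        )
        stage2 = sum(
            l["count"] for l in sk.links
            if any(node["id"] == l["source"] and node["stage"] == "model" for node in sk.nodes)
        )
        assert stage1 == n and stage2 == n
        assert sk.check_conservation()
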