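"""Outcome trees, ZigZag induction, classification, evaluation and ROC."""

import itertools
from collections import Counter

import pandas as pd
import pytest

import natfreq as nf
from natfreq.fft import OUTCOME, base_rate_exit_depth, cue_statistics


def toy_dataset():
    """Eight enumerable records over two binary cues."""
    rows = [
        ("+", "+", "sick"), ("+", "+", "well"), ("+", "-", "sick"), ("+", "-", "well"),
        ("-", "+", "well"), ("-", "+", "well"), ("-", "-", "well"), ("-", "-", "sick"),
    ]
    df = pd.DataFrame(rows, columns=["A", "B", OUTCOME])
    return nf.CaseDataset(
        df=df,
        cue_names=("A", "B"),
        categories={"A": ("+", "-"), "B": ("+", "-")},
        positive_values={"A": "+", "B": "+"},
        positive_outcome="sick",
    )


class TestBuildOutcomeTree:
    def test_chest_pain_root_and_leaf_sums(self, chest_pain):
        tree = nf.build_outcome_tree(chest_pain, ["ST", "CP", "OS"])
        assert tree.root_count == 89
        leaves = [p for p in tree.paths() if len(p) == 4]
        assert sum(tree.nodes[p] for p in leaves) == 89
        assert tree.violations() == []

    def test_counts_match_brute_force_tally(self):
        data = toy_dataset()
        tree = nf.build_outcome_tree(data, ["A", "B"])
        # oracle: tally every value combination by direct enumeration
        tally = Counter(
            (r.A, r.B, r.outcome) for r in data.df.itertuples())
        for a, b, o in itertools.product("+-", "+-", ("sick", "well")):
            assert tree.nodes[(a, b, o)] == tally.get((a, b, o), 0)

    def test_empty_dataset_rejected(self):
        with pytest.raises(nf.DomainError):
            nf.CaseDataset(
                df=pd.DataFrame(columns=["A", OUTCOME]),
                cue_names=("A",),
                categories={"A": ("+", "-")},
                positive_values={"A": "+"},
                positive_outcome="sick",
            )


class TestCueStatistics:
    def test_chest_pain_st_statistics(self, chest_pain):
        s = cue_statistics(chest_pain, "ST")
        # fixture: 10 of 15 positives are ST+; 23 of 74 negatives are ST+
        assert s.sensitivity == pytest.approx(10 / 15)
        assert s.specificity == pytest.approx(51 / 74)
        assert s.ppv == pytest.approx(10 / 33)
        assert s.npv == pytest.approx(51 / 56)

    def test_undefined_statistic_is_none(self):
        df = pd.DataFrame({"A": ["-", "-"], OUTCOME: ["sick", "well"]})
        data = nf.CaseDataset(
            df=df, cue_names=("A",), categories={"A": ("+", "-")},
            positive_values={"A": "+"}, positive_outcome="sick")
        assert cue_statistics(data, "A").ppv is None


class TestZigZag:
    def test_base_rate_exit_depth_from_chest_pain_rates(self):
        # 15 positive vs 74 negative: 1/2^3 = 0.125 < 15/74 <= 1/2^2
        assert base_rate_exit_depth(15, 74, 3) == 3

    def test_chest_pain_k(self, chest_pain):
        tree = nf.zigzag_fft(chest_pain, "val", seed=0)
        assert tree.k == 3

    def test_single_cue_dataset_one_level_both_exits(self):
        df = pd.DataFrame({"A": ["+", "-", "+", "-"],
                           OUTCOME: ["sick", "well", "well", "well"]})
        data = nf.CaseDataset(
            df=df, cue_names=("A",), categories={"A": ("+", "-")},
            positive_values={"A": "+"}, positive_outcome="sick")
        tree = nf.zigzag_fft(data, "val", seed=0)
        assert tree.k == 1
        assert tree.levels == ()
        assert tree.final_cue == "A"
        assert set(tree.final_labels.values()) == {"sick", "well"}

    def test_tied_cues_reproducible_per_seed(self):
        # two copies of the same cue: identical statistics, pure tie
        df = pd.DataFrame({
            "A": ["+", "+", "-", "-", "-", "-", "-", "-"],
            "B": ["+", "+", "-", "-", "-", "-", "-", "-"],
            OUTCOME: ["sick", "well"] + ["well"] * 6,
        })
        data = nf.CaseDataset(
            df=df, cue_names=("A", "B"),
            categories={"A": ("+", "-"), "B": ("+", "-")},
            positive_values={"A": "+", "B": "+"}, positive_outcome="sick")
        trees = [nf.zigzag_fft(data, "val", seed=7) for _ in range(3)]
        assert trees[0] == trees[1] == trees[2]

    def test_record_order_invariance(self, chest_pain):
        shuffled = nf.CaseDataset(
            df=chest_pain.df.sample(frac=1, random_state=5).reset_index(drop=True),
            cue_names=chest_pain.cue_names,
            categories=chest_pain.categories,
            positive_values=chest_pain.positive_values,
            positive_outcome=chest_pain.positive_outcome,
        )
        for variant in ("val", "sens"):
            assert nf.zigzag_fft(chest_pain, variant, 3) == nf.zigzag_fft(shuffled, variant, 3)

    def test_majority_positive_class_swapped(self):
        df = pd.DataFrame({"A": ["+", "+", "+", "-"],
                           OUTCOME: ["sick", "sick", "sick", "well"]})
        data = nf.CaseDataset(
            df=df, cue_names=("A",), categories={"A": ("+", "-")},
            positive_values={"A": "+"}, positive_outcome="sick")
        tree = nf.zigzag_fft(data, "val", seed=0)
        # the rarer class ("well") plays the positive role
        assert tree.final_labels["+"] == "well" or tree.final_labels["-"] == "well"

    def test_one_outcome_dataset_rejected(self):
        df = pd.DataFrame({"A": ["+", "-"], OUTCOME: ["sick", "sick"]})
        data = nf.CaseDataset(
            df=df, cue_names=("A",), categories={"A": ("+", "-")},
            positive_values={"A": "+"}, positive_outcome="sick")
        with pytest.raises(nf.DomainError):
            nf.zigzag_fft(data, "val", seed=0)


class TestClassifyCase:
    @pytest.mark.parametrize(
        "case, label, inspected",
        [
            ({"ST": "+", "CP": "+", "OS": "+"}, "heart attack", 1),
            ({"ST": "-", "CP": "-", "OS": "+"}, "no heart attack", 2),
            ({"ST": "-", "CP": "+", "OS": "+"}, "heart attack", 3),
            ({"ST": "-", "CP": "+", "OS": "-"}, "no heart attack", 3),
        ],
    )
    def test_published_tree_routing(self, chest_pain_tree, case, label, inspected):
        assert nf.classify_case(chest_pain_tree, case) == (label, inspected)

    def test_missing_cue_value_rejected(self, chest_pain_tree):
        with pytest.raises(nf.DomainError):
            nf.classify_case(chest_pain_tree, {"ST": "-"})

    def test_unknown_category_passes_to_next_level(self, chest_pain_tree):
        label, inspected = nf.classify_case(
            chest_pain_tree, {"ST": "?", "CP": "?", "OS": "?"})
        assert inspected == 3
        assert label == "no heart attack"  # final default


class TestEvaluate:
    def test_chest_pain_confusion_counts(self, chest_pain, chest_pain_tree):
        ev = nf.evaluate_fft(chest_pain_tree, chest_pain)
        c = ev.confusion
        assert (c.hits, c.false_alarms, c.misses, c.correct_rejections) == (15, 35, 0, 39)
        assert c.hits + c.false_alarms == 50   # classified high risk
        assert c.misses + c.correct_rejections == 39  # classified low risk

    def test_chest_pain_frugality(self, chest_pain, chest_pain_tree):
        ev = nf.evaluate_fft(chest_pain_tree, chest_pain)
        assert ev.frugality == pytest.approx((33 * 1 + 29 * 2 + 27 * 3) / 89)

    @pytest.mark.parametrize("sides", [("positive", "positive"), ("negative", "positive")])
    def test_confusion_counts_always_partition_dataset(self, chest_pain, sides):
        tree = nf.fft_from_exit_structure(chest_pain, ["ST", "CP", "OS"], sides)
        c = nf.evaluate_fft(tree, chest_pain).confusion
        assert c.n == 89
        assert c.hits + c.misses == 15


class TestNaiveBayes:
    def test_matches_task_posterior_under_independence(self, two_test):
        p = nf.naive_bayes_posterior(
            0.01, {"M": (0.80, 0.096), "U": (0.95, 0.04)}, {"M": True, "U": True})
        r = nf.posterior(two_test, {"mammogram": "positive", "ultrasound": "positive"})
        assert abs(p - r.distribution["cancer"]) < 1e-12
        assert p == pytest.approx(0.6665, abs=5e-4)

    def test_uninformative_ratios_return_base_rate(self):
        p = nf.naive_bayes_posterior(0.2, {"A": (0.5, 0.5)}, {"A": True})
        assert p == pytest.approx(0.2)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_exact_joint_posterior(self, seed):
        task = nf.random_task(seed=seed, n_hypotheses=2, max_categories=2)
        params = {}
        for cue in task.cues:
            pos = cue.categories[0]
            params[cue.name] = (
                cue.likelihoods[(task.hypothesis_space.labels[0], frozenset())][pos],
                cue.likelihoods[(task.hypothesis_space.labels[1], frozenset())][pos],
            )
        case = {cue.name: bool(seed % 2 == 0) for cue in task.cues}
        evidence = {cue.name: cue.categories[0 if case[cue.name] else 1]
                    for cue in task.cues}
        nb = nf.naive_bayes_posterior(
            float(task.hypothesis_space.priors[task.hypothesis_space.labels[0]]),
            params, case)
        exact = nf.posterior(task, evidence).distribution[task.hypothesis_space.labels[0]]
        assert abs(nb - exact) < 1e-12


class TestExitStructureROC:
    def test_includes_degenerate_classifiers(self, chest_pain):
        points = nf.exit_structure_roc(chest_pain, ["ST", "CP", "OS"])
        assert (0.0, 0.0) in points
        assert (1.0, 1.0) in points
        assert points == sorted(points)

    def test_contains_published_tree_point(self, chest_pain):
        points = nf.exit_structure_roc(chest_pain, ["ST", "CP", "OS"])
        assert any(far == pytest.approx(35 / 74) and hr == 1.0 for far, hr in points)

    def test_too_many_levels_refused(self, chest_pain):
        with pytest.raises(nf.DomainError):
            nf.exit_structure_roc(chest_pain, ["c"] * 13)
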