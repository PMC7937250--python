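"""External validation: set construction, truth rule, similarity subsets."""

import numpy as np
import pytest

from casel.learning import ConsensusPrediction
from casel.metrics import OVERALL, PROBABILITY_BINS, ConfusionCounts
from casel.validation import (
    build_validation_set,
    mean_training_similarity,
    outcome,
    score_similarity_subsets,
    score_validation,
    similarity_subsets,
)


def _prediction(cid, final, score, repeats=None, isoform="hCA_II"):
    labels = np.array(repeats if repeats is not None else [final] * 10)
    from casel.metrics import probability_bin
    return ConsensusPrediction(
        compound_id=cid, isoform=isoform,
        repeat_labels=labels, repeat_scores=np.full(len(labels), score),
        mean_label=float(labels.mean()), sd_label=float(labels.std()),
        mean_score=score, sd_score=0.0,
        final_label=final, probability_bin=probability_bin(score),
    )


class TestBuildValidationSet:
    ACTS = {"train1": 5.0, "mid": 50.0, "weak": 150.0, "hot": 12.0,
            "edge_lo": 20.0, "edge_hi": 100.0}

    def test_membership_rules(self):
        truths = build_validation_set(self.ACTS, sampled_ids={"train1"})
        by_id = {t.compound_id: t for t in truths}
        assert "train1" not in by_id          # sampled -> excluded
        assert "mid" not in by_id             # intermediate band
        assert "edge_lo" not in by_id and "edge_hi" not in by_id
        assert by_id["hot"].true_class == "active"
        assert by_id["weak"].true_class == "inactive"
        assert by_id["hot"].true_label == 1 and by_id["weak"].true_label == 0

    def test_empty_validation_set_is_legitimate(self):
        assert build_validation_set({"a": 50.0}, set()) == []


@pytest.mark.parametrize("true,pred,expected", [
    (1, 1, "TP"), (1, 0, "FN"), (0, 1, "FP"), (0, 0, "TN"),
])
def test_truth_rule(true, pred, expected):
    assert outcome(true, pred) == expected


class TestScoreValidation:
    def _setup(self):
        truths = build_validation_set(
            {"a": 5.0, "b": 10.0, "c": 500.0, "d": 900.0}, set()
        )
        preds = [
            _prediction("a", 1, 1.0),                      # TP in 1.0 bin
            _prediction("b", 0, 0.72),                     # FN in 0.7 bin
            _prediction("c", 1, 0.61),                     # FP in 0.6 bin
            _prediction("d", 0, 0.88),                     # TN in 0.9 bin
        ]
        return preds, truths

    def test_consensus_mode_counts(self):
        preds, truths = self._setup()
        strat = score_validation(preds, truths)
        overall = strat[OVERALL][0]
        assert (overall.tp, overall.fn, overall.fp, overall.tn) == (1, 1, 1, 1)
        assert strat[1.0][0].tp == 1 and strat[0.7][0].fn == 1
        total = ConfusionCounts(0, 0, 0, 0)
        for b in PROBABILITY_BINS:
            total = total + strat[b][0]
        assert total == overall

    def test_missing_prediction_is_error(self):
        preds, truths = self._setup()
        with pytest.raises(ValueError, match="missing predictions"):
            score_validation(preds[:-1], truths)

    def test_averaged_mode_accounting_within_rounding(self):
        truths = build_validation_set({"a": 5.0, "b": 500.0}, set())
        preds = [
            _prediction("a", 1, 0.9, repeats=[1] * 7 + [0] * 3),
            _prediction("b", 0, 0.8, repeats=[0] * 9 + [1]),
        ]
        strat = score_validation(preds, truths, mode="averaged")
        overall = strat[OVERALL][0]
        assert overall.tp == round(7 / 10) * 1 or overall.tp == 1  # 0.7 -> 1
        binned = ConfusionCounts(0, 0, 0, 0)
        for b in PROBABILITY_BINS:
            binned = binned + strat[b][0]
        for name in ("tp", "fn", "fp", "tn"):
            assert abs(getattr(binned, name) - getattr(overall, name)) <= 1


class TestSimilarity:
    TRAIN = ["NS(=O)(=O)c1ccccc1", "NS(=O)(=O)c1ccc(C)cc1"]

    def test_identity_gives_unit_similarity(self):
        tc = mean_training_similarity({"v": self.TRAIN[0]}, [self.TRAIN[0]])
        assert tc["v"] == pytest.approx(1.0)

    def test_disjoint_atom_pairs_give_zero(self):
        tc = mean_training_similarity({"v": "CC"}, ["OO"])
        assert tc["v"] == 0.0

    def test_mean_is_average_over_training_set(self):
        tc_each = [
            mean_training_similarity({"v": "NS(=O)(=O)c1ccc(CC)cc1"}, [t])["v"]
            for t in self.TRAIN
        ]
        tc_mean = mean_training_similarity(
            {"v": "NS(=O)(=O)c1ccc(CC)cc1"}, self.TRAIN
        )["v"]
        assert tc_mean == pytest.approx(np.mean(tc_each))

    def test_max_mode_takes_nearest_neighbour(self):
        tc = mean_training_similarity(
            {"v": self.TRAIN[0]}, self.TRAIN, mode="max"
        )
        assert tc["v"] == 1.0

    def test_symmetry(self):
        a, b = self.TRAIN
        assert (mean_training_similarity({"x": a}, [b])["x"]
                == pytest.approx(mean_training_similarity({"x": b}, [a])["x"]))

    def test_threshold_membership_at_0336(self):
        subsets = similarity_subsets({"at": 0.336, "below": 0.3359, "above": 0.5})
        assert "at" in subsets["similar"] and "above" in subsets["similar"]
        assert subsets["not_similar"] == ["below"]

    def test_unparseable_validation_smiles_excluded(self):
        tc = mean_training_similarity({"bad": "((("}, self.TRAIN)
        assert tc == {}


def test_similarity_subset_counts_sum_to_overall():
    truths = build_validation_set(
        {"a": 5.0, "b": 10.0, "c": 500.0, "d": 900.0}, set()
    )
    preds = [_prediction(c, 1, 1.0) for c in "abcd"]
    mean_tc = {"a": 0.5, "b": 0.1, "c": 0.4, "d": 0.2}
    by_subset = score_similarity_subsets(preds, truths, mean_tc)
    combined = by_subset["similar"][0] + by_subset["not_similar"][0]
    assert (combined.tp, combined.fn, combined.fp, combined.tn) == (2, 0, 2, 0)
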