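"""Splits, cross-validation, stopping rule, evaluation, and reporting."""

import numpy as np
import pytest

from contrastshift import phantom
from contrastshift.grids import LabelVolume
from contrastshift.harness import (
    EvalRecord,
    StoppingPolicy,
    build_report,
    evaluate_fold,
    largest_remainder_sizes,
    make_cv_folds,
    make_split,
    paired_condition_comparison,
    report_markdown,
)


class TestSplits:
    @pytest.mark.parametrize("n,expected", [(40, (30, 2, 8)), (66, (50, 3, 13)),
                                            (20, (15, 1, 4))])
    def test_largest_remainder_allocation(self, n, expected):
        assert largest_remainder_sizes(n, (0.75, 0.05, 0.20)) == expected

    def test_split_disjoint_and_complete(self):
        ids = [f"c{i}" for i in range(40)]
        plan = make_split(ids, seed=3)
        assert len(plan.train_ids) == 30 and len(plan.val_ids) == 2 and len(plan.test_ids) == 8
        assert set(plan.train_ids) | set(plan.val_ids) | set(plan.test_ids) == set(ids)
        plan.assert_disjoint()

    def test_split_too_small_or_empty_partition(self):
        with pytest.raises(ValueError):
            make_split(["a", "b", "c"])
        with pytest.raises(ValueError, match="empty"):
            make_split([f"c{i}" for i in range(6)], ratios=(0.9, 0.05, 0.05))

    def test_cv_each_case_tested_once(self):
        ids = [f"c{i}" for i in range(40)]
        folds = make_cv_folds(ids, k=5, seed=1)
        tested = [cid for f in folds for cid in f.test_ids]
        assert sorted(tested) == sorted(ids)
        assert all(len(f.test_ids) == 8 for f in folds)
        assert all(len(f.train_ids) == 30 and len(f.val_ids) == 2 for f in folds)

    def test_cv_deterministic(self):
        ids = [f"c{i}" for i in range(23)]
        f1 = make_cv_folds(ids, k=5, seed=9)
        f2 = make_cv_folds(ids, k=5, seed=9)
        assert [f.test_ids for f in f1] == [f.test_ids for f in f2]

    def test_cv_k_too_large(self):
        with pytest.raises(ValueError):
            make_cv_folds(["a", "b"], k=5)


class TestStoppingRule:
    def simulate(self, val_scores, patience):
        """Hand simulation of the stopping automaton on a fixed score stream."""
        best = -np.inf
        without = 0
        epochs = 0
        for s in val_scores:
            epochs += 1
            if s > best:
                best = s
                without = 0
            else:
                without += 1
            if without >= patience:
                break
        return epochs

    def test_constant_score_stops_after_two_epochs(self):
        assert self.simulate([0.5] * 100, patience=1) == 2

    def test_estimator_matches_automaton(self):
        """The trained estimator stops exactly when the hand automaton does."""
        from contrastshift.unet import UNet3DSegmenter

        pairs = [(np.zeros((16, 16, 16), dtype=np.float32),
                  np.ones((16, 16, 16), dtype=np.float32))]
        est = UNet3DSegmenter(input_shape=(16, 16, 16), base_channels=4, depth=1,
                              groupnorm_groups=2, max_iterations=1000,
                              patience_epochs=1, steps_per_epoch=1,
                              learning_rate=0.0, seed=0)

        est.fit_sampler(lambda rng: pairs[0], pairs)
        # zero learning rate => constant validation score => 2 epochs
        assert len(est.history_) == 2

    def test_policy_invariants(self):
        with pytest.raises(ValueError):
            StoppingPolicy(patience_epochs=0)


class _OracleModel:
    """Predicts the ground-truth mask (or a fixed constant mask)."""

    def __init__(self, masks, empty=False):
        self.masks = masks
        self.empty = empty

    def predict(self, volume, case_id=""):
        from contrastshift.unet import SegPrediction

        truth = self.masks[case_id]
        values = np.zeros_like(truth.values) if self.empty else truth.values
        return SegPrediction(probabilities=values.astype(float),
                             mask=LabelVolume(values), case_id=case_id)


@pytest.fixture(scope="module")
def cases(small_config):
    return phantom.sample_dataset(small_config, 4, base_seed=17,
                                  jitter=phantom.default_jitter())


class TestEvaluation:

    def test_oracle_model_perfect(self, cases):
        model = _OracleModel({c.case_id: c.masks["kidney"] for c in cases})
        records = evaluate_fold(model, cases[:2], cases[2:], "kidney", "standard", 0)
        assert len(records) == 4
        assert all(r.dice == 1.0 and r.vol_error == 0.0 for r in records)
        domains = {r.domain for r in records}
        assert domains == {"in_distribution", "out_of_distribution"}

    def test_empty_prediction_conventions(self, cases):
        model = _OracleModel({c.case_id: c.masks["kidney"] for c in cases}, empty=True)
        records = evaluate_fold(model, cases[:1], [], "kidney", "none", 0)
        assert records[0].dice == 0.0
        assert records[0].vol_error == 1.0

    def test_full_ood_set_per_fold(self, cases):
        model = _OracleModel({c.case_id: c.masks["kidney"] for c in cases})
        n_ood = 0
        for fold in range(5):
            recs = evaluate_fold(model, [], cases[2:], "kidney", "cyclegan", fold)
            n_ood += len(recs)
        assert n_ood == 2 * 5  # every fold evaluates the complete OOD set


class TestReport:
    def make_records(self):
        recs = []
        for fold, dice in ((0, 0.6), (1, 0.8)):
            recs.append(EvalRecord("c1", "standard", "in_distribution", fold, dice, 0.1))
        return recs

    def test_fold_level_mean_sd(self):
        summary = build_report(self.make_records())
        row = summary.iloc[0]
        assert row.dice_mean == pytest.approx(0.7)
        assert row.dice_sd == pytest.approx(0.1414, abs=1e-4)

    def test_single_fold_sd_undefined(self):
        recs = [EvalRecord("c1", "standard", "in_distribution", 0, 0.8, 0.1)]
        summary = build_report(recs)
        assert summary.iloc[0].dice_mean == pytest.approx(0.8)
        assert np.isnan(summary.iloc[0].dice_sd)
        assert "n/a" in report_markdown(summary)

    def test_row_ordering_deterministic(self):
        recs = self.make_records() + [
            EvalRecord("c1", "cyclegan", "in_distribution", 0, 0.9, 0.05),
            EvalRecord("c1", "cyclegan", "out_of_distribution", 0, 0.7, 0.2),
        ]
        s1 = build_report(recs)
        s2 = build_report(list(recs))
        assert list(s1.condition) == list(s2.condition)

    def test_paired_comparison_matches_wilcoxon(self, rng):
        recs = []
        for i in range(12):
            d = float(rng.random())
            recs.append(EvalRecord(f"c{i}", "standard", "out_of_distribution", 0, d, 0.1))
            recs.append(EvalRecord(f"c{i}", "cyclegan", "out_of_distribution", 0,
                                   min(1.0, d + 0.2 + 0.01 * i), 0.1))
        res = paired_condition_comparison(recs, "standard", "cyclegan",
                                          "out_of_distribution")
        assert res.n_pairs == 12
        assert res.p_value < 0.01  # consistent uplift must be detected
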