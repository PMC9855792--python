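"""Prediction, classification metrics against counting oracles, learning, CV."""

import itertools

import numpy as np
import pytest

import larynxbn as lx
from larynxbn.validation import PredictionRecord


def make_preds(rows, target="larynx_surgery"):
    """rows: (p_true, predicted, truth) triples -> PredictionRecord list."""
    return [
        PredictionRecord(
            case_id=f"c{i}", target=target, p_true=p, predicted=pred, truth=truth,
            complete_evidence=True,
        )
        for i, (p, pred, truth) in enumerate(rows)
    ]


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def auc_by_pair_counting(scores_pos, scores_neg):
    """Mann-Whitney: fraction of concordant (pos, neg) pairs, ties count 1/2."""
    wins = 0.0
    for sp in scores_pos:
        for sn in scores_neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))


def ap_by_staircase(scored_labels):
    """AP = sum over recall steps of precision, walking down by score."""
    ranked = sorted(scored_labels, key=lambda x: -x[0])
    n_pos = sum(lab for _, lab in ranked)
    tp = 0
    ap = 0.0
    for i, (_, lab) in enumerate(ranked, start=1):
        if lab:
            tp += 1
            ap += tp / i
    return ap / n_pos


# ---------------------------------------------------------------------------
# Prediction harness
# ---------------------------------------------------------------------------


class TestPredictTargets:
    def test_empty_cohort_gives_empty_records(self, larynx_model):
        assert len(lx.predict_targets(larynx_model, [])) == 0

    def test_anchor_case_posterior(self, larynx_model):
        rec = lx.PatientRecord(
            case_id="p1", T="T2", N="N2a", M="M0", chemo_tolerance="tolerant",
            treatments={tr: "false" for tr in lx.TREATMENTS},
        )
        preds = lx.predict_targets(larynx_model, [rec])
        surgery = next(r for r in preds if r.target == "larynx_surgery")
        assert surgery.p_true == pytest.approx(0.74, abs=1e-12)
        assert surgery.predicted == "true"
        assert surgery.complete_evidence

    def test_missing_staging_is_marginalized_not_dropped(self, larynx_model):
        rec = lx.PatientRecord(case_id="p1", T="T2", treatments={})
        preds = lx.predict_targets(larynx_model, [rec])
        assert len(preds) == 5
        assert not preds.records[0].complete_evidence
        direct = lx.posterior(larynx_model, {"T": "T2"}, "larynx_surgery")
        assert preds.for_target("larynx_surgery")[0].p_true == pytest.approx(
            direct["true"], abs=1e-12
        )

    def test_invalid_state_label_flags_case_instead_of_dropping_silently(
        self, larynx_model
    ):
        good = lx.PatientRecord(case_id="ok", T="T2", treatments={})
        bad = lx.PatientRecord(case_id="bad", T="T99", treatments={})
        preds = lx.predict_targets(larynx_model, [good, bad])
        assert len(preds) == 5  # only the valid case predicted
        assert preds.flagged == [("bad", "T='T99' is not a valid state")]

    def test_targets_must_have_target_role(self, larynx_model):
        with pytest.raises(ValueError, match="not a target"):
            lx.predict_targets(larynx_model, [], targets=["T"])


class TestAccuracy:
    def test_perfect_predictions(self):
        preds = make_preds([(0.9, "true", "true"), (0.1, "false", "false")])
        assert lx.accuracy(preds).overall == 1.0

    def test_three_of_four_correct(self):
        preds = make_preds(
            [
                (0.9, "true", "true"),
                (0.8, "true", "true"),
                (0.7, "true", "false"),
                (0.2, "false", "false"),
            ]
        )
        report = lx.accuracy(preds)
        assert report.overall == 0.75
        assert report.per_target["larynx_surgery"] == (3, 4, 0.75)

    def test_overall_decomposes_into_per_target_sums(self, larynx_model):
        cfg = lx.CohortConfig(n=30, inconsistency_rate=0.0, seed=21)
        cohort = lx.generate_cohort(cfg, larynx_model)
        report = lx.accuracy(lx.predict_targets(larynx_model, cohort))
        assert report.overall_correct == sum(
            c for c, _, _ in report.per_target.values()
        )
        assert report.overall_total == sum(n for _, n, _ in report.per_target.values())
        assert report.overall_total == 30 * 5


class TestF1:
    def test_perfect_both_classes(self):
        preds = make_preds([(0.9, "true", "true"), (0.1, "false", "false")])
        f1 = lx.f1_scores(preds, "larynx_surgery")
        assert (f1.f1_positive, f1.f1_negative, f1.weighted) == (1.0, 1.0, 1.0)

    def test_hand_confusion_matrix(self):
        # TP=2 FP=1 FN=1 TN=6 -> precision=2/3, recall=2/3, F1 = 2/3
        rows = (
            [(0.9, "true", "true")] * 2
            + [(0.8, "true", "false")] * 1
            + [(0.2, "false", "true")] * 1
            + [(0.1, "false", "false")] * 6
        )
        f1 = lx.f1_scores(make_preds(rows), "larynx_surgery")
        assert f1.f1_positive == pytest.approx(2 / 3, abs=1e-12)
        # negative class: TP=6 FP=1 FN=1 -> F1 = 6/7
        assert f1.f1_negative == pytest.approx(6 / 7, abs=1e-12)
        assert f1.weighted == pytest.approx(
            (3 * (2 / 3) + 7 * (6 / 7)) / 10, abs=1e-12
        )

    def test_absent_class_scores_zero_by_convention(self):
        preds = make_preds([(0.1, "false", "false")] * 5)
        f1 = lx.f1_scores(preds, "larynx_surgery")
        assert f1.f1_positive == 0.0
        assert f1.f1_negative == 1.0
        assert f1.weighted == 1.0  # weight of the empty class is zero


class TestRoc:
    def test_perfect_separation_auc_one(self):
        preds = make_preds(
            [(0.9, "true", "true"), (0.8, "true", "true"),
             (0.2, "false", "false"), (0.1, "false", "false")]
        )
        assert lx.roc_curve(preds, "larynx_surgery").auc == 1.0

    def test_auc_equals_mann_whitney_pair_counting(self):
        # one swap: negatives at 0.7 > positive at 0.6
        rows = [(0.9, "true", "true"), (0.8, "true", "true"),
                (0.7, "true", "false"), (0.6, "true", "true"),
                (0.4, "false", "false"), (0.2, "false", "false")]
        auc = lx.roc_curve(make_preds(rows), "larynx_surgery").auc
        oracle = auc_by_pair_counting(
            [p for p, _, t in rows if t == "true"],
            [p for p, _, t in rows if t == "false"],
        )
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(17)
        rows = [
            (float(rng.random()), "true", "true" if rng.random() < 0.5 else "false")
            for _ in range(10_000)
        ]
        auc = lx.roc_curve(make_preds(rows), "larynx_surgery").auc
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_auc_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(23)
        rows = [
            (float(rng.random()), "true", "true" if rng.random() < 0.4 else "false")
            for _ in range(200)
        ]
        base = lx.roc_curve(make_preds(rows), "larynx_surgery").auc
        squashed = [(p ** 3 / 2, pr, t) for p, pr, t in rows]  # strictly monotone
        assert lx.roc_curve(make_preds(squashed), "larynx_surgery").auc == pytest.approx(
            base, abs=1e-12
        )

    def test_single_class_truth_is_undefined_marker_not_number(self):
        preds = make_preds([(0.9, "true", "true")] * 4)
        result = lx.roc_curve(preds, "larynx_surgery")
        assert not result.defined
        assert result.auc is None
        assert "single-class" in result.reason


class TestPrecisionRecall:
    def test_perfect_predictions_ap_one_both_classes_and_micro(self):
        preds = make_preds(
            [(0.9, "true", "true"), (0.8, "true", "true"),
             (0.1, "false", "false"), (0.2, "false", "false")]
        )
        result = lx.pr_curve(preds, "larynx_surgery")
        assert result.per_class["true"].ap == 1.0
        assert result.per_class["false"].ap == 1.0
        assert result.micro_ap == 1.0

    def test_ap_matches_hand_staircase(self):
        rows = [(0.95, "true", "true"), (0.85, "true", "false"),
                (0.75, "true", "true"), (0.55, "true", "true"),
                (0.35, "false", "false"), (0.15, "false", "false")]
        result = lx.pr_curve(make_preds(rows), "larynx_surgery")
        oracle = ap_by_staircase([(p, 1 if t == "true" else 0) for p, _, t in rows])
        assert result.per_class["true"].ap == pytest.approx(oracle, abs=1e-12)
        neg_oracle = ap_by_staircase(
            [(1 - p, 1 if t == "false" else 0) for p, _, t in rows]
        )
        assert result.per_class["false"].ap == pytest.approx(neg_oracle, abs=1e-12)

    def test_class_without_true_members_is_omitted_with_marker(self):
        preds = make_preds([(0.2, "false", "false")] * 6)
        result = lx.pr_curve(preds, "larynx_surgery")
        assert not result.per_class["true"].defined
        assert result.per_class["false"].defined
        assert not result.micro_defined and result.micro_ap is None


# ---------------------------------------------------------------------------
# Parameter learning
# ---------------------------------------------------------------------------


class TestFitParameters:
    def toy_structure(self):
        a = lx.Variable("A", ("x", "y"))
        b = lx.Variable("B", ("u", "v"))
        return lx.Network(
            [a, b],
            [
                lx.CPT("A", (), {(): (0.5, 0.5)}),
                lx.CPT("B", ("A",), {("x",): (0.5, 0.5), ("y",): (0.5, 0.5)}),
            ],
        )

    def test_single_row_laplace_counting(self):
        import pandas as pd

        net = self.toy_structure()
        data = pd.DataFrame({"A": ["x"], "B": ["u"]})
        learned = lx.fit_parameters(net, data, prior_strength=1.0)
        # observed cell: (1+1)/(1+2) Laplace posterior mean
        assert learned.network.cpts["A"].table[()] == pytest.approx(
            (2 / 3, 1 / 3), abs=1e-12
        )
        assert learned.network.cpts["B"].table[("x",)] == pytest.approx(
            (2 / 3, 1 / 3), abs=1e-12
        )
        # unobserved combo stays at the uniform prior mean
        assert learned.network.cpts["B"].table[("y",)] == (0.5, 0.5)

    def test_no_data_gives_uniform_cpts(self):
        import pandas as pd

        net = self.toy_structure()
        learned = lx.fit_parameters(
            net, pd.DataFrame({"A": [], "B": []}), prior_strength=1.0
        )
        for cpt in learned.network.cpts.values():
            assert all(col == (0.5, 0.5) for col in cpt.table.values())

    def test_zero_prior_unobserved_column_reported_undefined(self):
        import pandas as pd

        net = self.toy_structure()
        data = pd.DataFrame({"A": ["x", "x"], "B": ["u", "v"]})
        learned = lx.fit_parameters(net, data, prior_strength=0.0)
        assert any("B" in c and "'y'" in c for c in learned.undefined_columns)

    def test_em_on_missing_data_recovers_toy_parameters(self):
        import pandas as pd

        # ground truth: P(A=x)=0.8, B copies A with fidelity 0.9
        truth = lx.Network(
            [lx.Variable("A", ("x", "y")), lx.Variable("B", ("u", "v"))],
            [
                lx.CPT("A", (), {(): (0.8, 0.2)}),
                lx.CPT("B", ("A",), {("x",): (0.9, 0.1), ("y",): (0.1, 0.9)}),
            ],
        )
        rng = np.random.default_rng(3)
        frame = lx.forward_sample(truth, 3000, rng)
        # hide 30% of A values: EM must reconstruct them through B
        mask = rng.random(len(frame)) < 0.3
        frame.loc[mask, "A"] = None
        learned = lx.fit_parameters(self.toy_structure(), frame, prior_strength=1.0)
        assert learned.n_incomplete_rows > 0
        assert learned.em_iterations >= 1
        got = learned.network.cpts["A"].table[()]
        assert got[0] == pytest.approx(0.8, abs=0.05)
        fidelity = learned.network.cpts["B"].table[("x",)][0]
        assert fidelity == pytest.approx(0.9, abs=0.05)

    def test_learned_columns_are_normalized(self, larynx_model):
        rng = np.random.default_rng(4)
        frame = lx.forward_sample(larynx_model, 500, rng)
        learned = lx.fit_parameters(larynx_model, frame, prior_strength=1.0)
        report = lx.validate_network(learned.network)
        assert report.ok

    def test_recovery_error_decreases_with_sample_size(self, larynx_model):
        errors = []
        for n in (500, 5000, 20000):
            frame = lx.forward_sample(larynx_model, n, np.random.default_rng(13))
            learned = lx.fit_parameters(larynx_model, frame, prior_strength=1.0)
            counts = lx.observation_counts(larynx_model, frame)
            errors.append(
                lx.cpt_recovery_weighted_error(
                    larynx_model, learned.network, counts
                )
            )
        assert errors[0] > errors[1] > errors[2]


class TestKfoldCv:
    def test_constant_truth_perfectly_learnable(self, larynx_model):
        # every case identical and labelled with the model argmax: CV = 1.0
        rec = lx.PatientRecord(
            case_id="c", T="T1a", N="N0", M="M0", chemo_tolerance="tolerant",
            treatments={},
        )
        ev = rec.staging_evidence()
        labels = {
            tr: lx.map_state(lx.posterior(larynx_model, ev, tr), ("false", "true"))
            for tr in lx.TREATMENTS
        }
        cohort = [
            lx.PatientRecord(
                case_id=f"c{i}", T="T1a", N="N0", M="M0", chemo_tolerance="tolerant",
                treatments=dict(labels),
            )
            for i in range(20)
        ]
        result = lx.kfold_cv(larynx_model, cohort, k=10, seed=1)
        assert result.mean_accuracy == 1.0

    def test_same_seed_reproduces_folds_and_accuracies(self, larynx_model):
        cfg = lx.CohortConfig(n=40, inconsistency_rate=0.0, seed=31)
        cohort = lx.generate_cohort(cfg, larynx_model)
        a = lx.kfold_cv(larynx_model, cohort, k=5, seed=7)
        b = lx.kfold_cv(larynx_model, cohort, k=5, seed=7)
        assert a.fold_accuracies == b.fold_accuracies
        assert a.fold_sizes == b.fold_sizes

    def test_k_larger_than_cohort_rejected(self, larynx_model):
        with pytest.raises(ValueError, match="exceeds"):
            lx.kfold_cv(larynx_model, [], k=10, seed=0)
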