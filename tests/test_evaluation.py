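"""Evaluation metrics: micro-F1 null policies, win/loss/tie rates,
concordance — each checked against independent brute-force recounts."""

import math

import numpy as np
import pandas as pd
import pytest

from tnfiswitch.evaluation import (
    LabelSet,
    concordance,
    correctness_vector,
    derive_silver_labels,
    evaluate_suite,
    micro_f1,
    pairwise_win_rates,
    split_validation_test,
    win_minus_loss_vs_baseline,
)
from tnfiswitch.extraction import (
    NA,
    ExtractionRecord,
    NoisyBackend,
    ReferenceBackend,
    REASON_CATEGORIES,
    run_extraction,
)
from tnfiswitch.cohort import SwitchEvent

A, B, C = "adalimumab", "etanercept", "golimumab"


def rec(note_id, last=NA, new=NA, reason=NA, backend="m"):
    return ExtractionRecord(note_id, new, last, reason, "", True, backend)


def labels(values, field="last_tnfi", source="gold"):
    df = pd.DataFrame({field: values},
                      index=[f"n{i}" for i in range(len(values))])
    df.index.name = "note_id"
    return LabelSet(source, df)


# ---------------------------------------------------------------------------
# micro-F1


class TestMicroF1:
    def test_perfect_prediction_scores_1(self):
        lab = labels([A, B, C])
        records = [rec(f"n{i}", last=v) for i, v in enumerate([A, B, C])]
        assert micro_f1(records, lab, "last_tnfi").micro_f1 == 1.0

    def test_hand_pooled_example(self):
        # gold (A,B,C), pred (A,B,B): TP=2, FP=1, FN=1 -> 2/3
        lab = labels([A, B, C])
        records = [rec("n0", last=A), rec("n1", last=B), rec("n2", last=B)]
        assert micro_f1(records, lab, "last_tnfi").micro_f1 == pytest.approx(2 / 3)

    def test_na_policy_hand_example(self):
        # gold (A, na), pred (na, na): all_values -> 0; null_dropped -> n=0
        lab = labels([A, NA])
        records = [rec("n0"), rec("n1")]
        res_all = micro_f1(records, lab, "last_tnfi", "all_values")
        assert res_all.micro_f1 == 0.0 and res_all.n_evaluated == 2
        res_nd = micro_f1(records, lab, "last_tnfi", "null_dropped")
        assert math.isnan(res_nd.micro_f1) and res_nd.n_evaluated == 0

    def test_null_dropping_filters_on_own_reason_output(self):
        lab = labels([A, B])
        records = [rec("n0", last=A, reason="other"), rec("n1", last=C, reason=NA)]
        res = micro_f1(records, lab, "last_tnfi", "null_dropped")
        assert res.n_evaluated == 1 and res.micro_f1 == 1.0

    def test_null_dropped_never_evaluates_more_notes(self, switch_notes, gold_labels):
        be = NoisyBackend(0.3, seed=2)
        records = run_extraction(switch_notes, be)
        for field in gold_labels.fields:
            n_all = micro_f1(records, gold_labels, field, "all_values").n_evaluated
            n_nd = micro_f1(records, gold_labels, field, "null_dropped").n_evaluated
            assert n_nd <= n_all

    def test_oracle_equivalence_random_instances(self):
        """Pooled-count micro-F1 equals an independent per-note recount on
        random small instances."""
        rng = np.random.default_rng(17)
        values = [A, B, C, NA]
        for _ in range(100):
            n = int(rng.integers(1, 51))
            gold = [values[i] for i in rng.integers(0, 4, n)]
            pred = [values[i] for i in rng.integers(0, 4, n)]
            lab = labels(gold)
            records = [rec(f"n{i}", last=v) for i, v in enumerate(pred)]
            got = micro_f1(records, lab, "last_tnfi").micro_f1
            tp = sum(p == g != NA for p, g in zip(pred, gold))
            fp = sum(p != NA and p != g for p, g in zip(pred, gold))
            fn = sum(g != NA and g != p for p, g in zip(pred, gold))
            if 2 * tp + fp + fn == 0:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(2 * tp / (2 * tp + fp + fn))

    def test_silver_labels_have_no_reason_field(self):
        ev = SwitchEvent("p", 1, A, B, pd.Timestamp("2020-01-01"),
                         pd.Timestamp("2020-02-01"), note_id="n0")
        silver = derive_silver_labels([ev])
        assert silver.fields == ("last_tnfi", "new_tnfi")
        with pytest.raises(ValueError, match="not labeled"):
            micro_f1([rec("n0", last=A, new=B)], silver, "reason")


class TestSilverLabels:
    def test_switch_note_labeled_with_drug_pair(self):
        ev = SwitchEvent("p", 1, B, A, pd.Timestamp("2020-01-01"),
                         pd.Timestamp("2020-02-01"), note_id="n9")
        silver = derive_silver_labels([ev])
        assert silver.labels.loc["n9", "last_tnfi"] == B
        assert silver.labels.loc["n9", "new_tnfi"] == A

    def test_empty_events_give_empty_label_set(self):
        assert len(derive_silver_labels([])) == 0

    def test_silver_matches_generator_truth(self, synth, cohort, gold_labels):
        silver = derive_silver_labels(cohort.switches)
        joined = silver.labels.join(gold_labels.labels, rsuffix="_gold")
        assert (joined["last_tnfi"] == joined["last_tnfi_gold"]).all()
        assert (joined["new_tnfi"] == joined["new_tnfi_gold"]).all()

    def test_duplicate_note_linkage_rejected(self):
        evs = [
            SwitchEvent("p", 1, A, B, pd.Timestamp("2020-01-01"),
                        pd.Timestamp("2020-02-01"), note_id="n0"),
            SwitchEvent("p", 2, B, A, pd.Timestamp("2020-02-01"),
                        pd.Timestamp("2020-03-01"), note_id="n0"),
        ]
        with pytest.raises(ValueError, match="multiple switch events"):
            derive_silver_labels(evs)


class TestSplit:
    def test_validation_size_is_rounded_fraction(self):
        note_patient = {f"n{i}": f"p{i % 100}" for i in range(300)}
        val, test = split_validation_test(note_patient, 0.05, seed=0)
        val_patients = {note_patient[n] for n in val}
        assert len(val_patients) == 5

    def test_same_seed_reproduces_partition(self):
        note_patient = {f"n{i}": f"p{i % 40}" for i in range(120)}
        assert split_validation_test(note_patient, 0.1, seed=7) == \
            split_validation_test(note_patient, 0.1, seed=7)

    def test_partition_is_disjoint_exhaustive_and_patient_level(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_pat = int(rng.integers(20, 80))
            note_patient = {
                f"n{i}": f"p{rng.integers(n_pat)}" for i in range(n_pat * 3)
            }
            val, test = split_validation_test(note_patient, 0.1, seed=int(rng.integers(100)))
            assert set(val) | set(test) == set(note_patient)
            assert not (set(val) & set(test))
            assert not ({note_patient[n] for n in val} &
                        {note_patient[n] for n in test})

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_validation_test({"n1": "p1", "n2": "p2"}, 0.05, seed=0)


# ---------------------------------------------------------------------------
# win rates


def brute_force_win_rates(correct):
    """Independent double-loop recount of win/loss/tie fractions."""
    out = {}
    models = list(correct)
    for a in models:
        for b in models:
            if a == b:
                continue
            va, vb = correct[a], correct[b]
            win = sum(x and not y for x, y in zip(va, vb)) / len(va)
            loss = sum(y and not x for x, y in zip(va, vb)) / len(va)
            out[(a, b)] = (win, loss, 1.0 - win - loss)
    return out


class TestWinRates:
    def test_dominant_model_wins_everything(self):
        m = pairwise_win_rates({"good": [True] * 5, "bad": [False] * 5})
        assert m.win.loc["good", "bad"] == 1.0
        assert m.tie.loc["good", "bad"] == 0.0

    def test_identical_models_always_tie(self):
        v = [True, False, True]
        m = pairwise_win_rates({"a": v, "b": v})
        assert m.win.loc["a", "b"] == 0.0
        assert m.tie.loc["a", "b"] == 1.0

    def test_oracle_equivalence_and_identities_random(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(1, 51))
            correct = {f"m{k}": list(rng.random(n) < rng.random())
                       for k in range(3)}
            m = pairwise_win_rates(correct)
            brute = brute_force_win_rates(correct)
            for (a, b), (w, l, t) in brute.items():
                assert m.win.loc[a, b] == pytest.approx(w)
                assert m.loss.loc[a, b] == pytest.approx(l)
                assert m.tie.loc[a, b] == pytest.approx(t)
                # identities: partition of unity and antisymmetry
                assert m.win.loc[a, b] + m.loss.loc[a, b] + m.tie.loc[a, b] == \
                    pytest.approx(1.0, abs=1e-12)
                assert m.win.loc[a, b] == m.loss.loc[b, a]

    def test_mean_win_rate_averages_over_opponents(self):
        correct = {"a": [True, True], "b": [True, False], "c": [False, False]}
        m = pairwise_win_rates(correct)
        mw = m.mean_win_rates()
        expected_a = (m.win.loc["a", "b"] + m.win.loc["a", "c"]) / 2
        assert mw.loc["a", "mean_win_rate"] == pytest.approx(expected_a)
        sd_a = np.std([m.win.loc["a", "b"], m.win.loc["a", "c"]])
        assert mw.loc["a", "sd"] == pytest.approx(sd_a)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            pairwise_win_rates({"a": [True], "b": [True, False]})


class TestWinMinusLoss:
    def test_baseline_against_itself_is_zero(self):
        m = pairwise_win_rates({"base": [True, False], "m": [False, True]})
        wml = win_minus_loss_vs_baseline(m, "base")
        assert wml["base"] == 0.0

    def test_strictly_better_model_is_positive(self):
        m = pairwise_win_rates({"base": [True, False, False],
                                "better": [True, True, False]})
        wml = win_minus_loss_vs_baseline(m, "base")
        assert wml["better"] > 0

    def test_agrees_with_direct_recount(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            correct = {f"m{k}": list(rng.random(n) < 0.5) for k in range(3)}
            m = pairwise_win_rates(correct)
            wml = win_minus_loss_vs_baseline(m, "m0")
            brute = brute_force_win_rates(correct)
            for model in ("m1", "m2"):
                w, l, _ = brute[(model, "m0")]
                assert wml[model] == pytest.approx(w - l)

    def test_unknown_baseline_rejected(self):
        m = pairwise_win_rates({"a": [True], "b": [False]})
        with pytest.raises(ValueError, match="baseline"):
            win_minus_loss_vs_baseline(m, "zzz")


class TestConcordance:
    def test_self_concordance_is_100_with_sd_0(self):
        records = [rec(f"n{i}", last=A, new=B, reason="other") for i in range(5)]
        res = concordance(records, records)
        assert res.mean == 100.0 and res.sd == 0.0

    def test_single_field_disagreement_lowers_mean_and_raises_sd(self):
        ra = [rec("n0", last=A, new=B, reason="other")]
        rb = [rec("n0", last=A, new=B, reason=NA)]
        res = concordance(ra, rb)
        assert res.mean < 100.0 and res.sd > 0.0
        assert res.per_field["reason"] == 0.0

    def test_na_agreeing_with_na_counts(self):
        ra = [rec("n0")]
        rb = [rec("n0")]
        assert concordance(ra, rb).mean == 100.0

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(53)
        drugs = [A, B, C, NA]
        reasons = list(REASON_CATEGORIES)
        for _ in range(50):
            n = int(rng.integers(1, 51))
            ra = [rec(f"n{i}", last=drugs[rng.integers(4)],
                      new=drugs[rng.integers(4)],
                      reason=reasons[rng.integers(7)]) for i in range(n)]
            rb = [rec(f"n{i}", last=drugs[rng.integers(4)],
                      new=drugs[rng.integers(4)],
                      reason=reasons[rng.integers(7)]) for i in range(n)]
            res = concordance(ra, rb)
            for f in ("last_tnfi", "new_tnfi", "reason"):
                agree = sum(getattr(x, f) == getattr(y, f)
                            for x, y in zip(ra, rb))
                assert res.per_field[f] == pytest.approx(100 * agree / n)
            vals = list(res.per_field.values())
            assert res.mean == pytest.approx(float(np.mean(vals)))
            assert res.sd == pytest.approx(float(np.std(vals)))

    def test_disjoint_note_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            concordance([rec("n0")], [rec("n1")])


class TestEvaluateSuite:
    def test_reference_backend_is_perfect_on_noise_free_data(
        self, synth, cohort, gold_labels, switch_notes
    ):
        silver = derive_silver_labels(cohort.switches)
        records = run_extraction(switch_notes, ReferenceBackend())
        report = evaluate_suite({"reference": records}, silver, gold_labels,
                                "reference")
        for res in report.eval_results:
            assert res.micro_f1 == 1.0

    def test_reference_beats_noisy_backends(self, switch_notes, gold_labels):
        backends = {
            "reference": ReferenceBackend(),
            "noisy15": NoisyBackend(0.15, seed=3, backend_id="noisy15"),
            "noisy40": NoisyBackend(0.40, seed=3, backend_id="noisy40"),
        }
        records = {bid: run_extraction(switch_notes, be)
                   for bid, be in backends.items()}
        report = evaluate_suite(records, None, gold_labels, "reference")
        mw = report.win_matrix.mean_win_rates()["mean_win_rate"]
        assert mw["reference"] > mw["noisy15"] > mw["noisy40"]
        assert report.win_minus_loss["noisy15"] < 0
        assert report.concordance_vs_baseline["reference"].mean == 100.0

    def test_noise_monotonicity_of_reason_accuracy(self, gold_labels, switch_notes):
        truth = gold_labels.labels
        accs = []
        for rate in (0.1, 0.3, 0.5):
            records = run_extraction(
                switch_notes, NoisyBackend({"reason": rate}, seed=11)
            )
            acc = np.mean([r.reason == truth.loc[r.note_id, "reason"]
                           for r in records])
            accs.append(acc)
        assert accs[0] > accs[1] > accs[2]

    def test_empty_backend_list_rejected(self, gold_labels):
        with pytest.raises(ValueError, match="no backends"):
            evaluate_suite({}, None, gold_labels, "reference")
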