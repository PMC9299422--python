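"""Metric implementations against brute-force oracles; CIs; strata counting."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from scipy import stats

from holterpaf.evaluation import (
    analytic_two_gaussian_auroc,
    assign_folds,
    auroc,
    bootstrap_ci,
    confusion_metrics,
    elapsed_time_sensitivity,
    f_scores,
    fold_ci,
    optimal_cutoff,
)
from holterpaf.io import CohortManifest, PatientRecord


def brute_auroc(scores, labels):
    """Exhaustive pairwise comparator: ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_best_cutoff_sum(scores, labels):
    """Best achievable sensitivity+specificity over observed thresholds."""
    best = -1.0
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        best = max(best, sens + spec)
    return best


class TestAuroc:
    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_equals_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 51)
            labels = np.zeros(n, int)
            labels[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(0, 1, n), 2)  # force some ties
            assert auroc(scores, labels) == pytest.approx(
                brute_auroc(scores, labels), abs=1e-12)


class TestOptimalCutoff:
    def test_separable_canonical_threshold(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr = optimal_cutoff(scores, labels)
        assert thr == pytest.approx(0.8)
        cm = confusion_metrics(scores, labels, thr)
        assert cm["sensitivity"] == 1.0 and cm["specificity"] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            optimal_cutoff([0.4, 0.6], [1, 1])

    def test_achieves_oracle_maximum_on_random_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = 50
            labels = (rng.uniform(size=n) < 0.4).astype(int)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.uniform(0, 1, n), 2)
            thr = optimal_cutoff(scores, labels)
            cm = confusion_metrics(scores, labels, thr)
            achieved = cm["sensitivity"] + cm["specificity"]
            assert achieved == pytest.approx(
                brute_best_cutoff_sum(scores, labels), abs=1e-12)


class TestConfusionAndF:
    def test_perfect_panel(self):
        cm = confusion_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 0.5)
        assert all(cm[k] == 1.0 for k in cm)

    def test_contingency_arithmetic(self):
        # TP=3, FP=7, FN=2, TN=88
        scores = [1.0] * 10 + [0.0] * 90
        labels = [1] * 3 + [0] * 7 + [1] * 2 + [0] * 88
        cm = confusion_metrics(scores, labels, 0.5)
        assert cm["sensitivity"] == pytest.approx(0.6)
        assert cm["specificity"] == pytest.approx(88 / 95, abs=1e-3)
        assert cm["ppv"] == pytest.approx(0.3)
        assert cm["npv"] == pytest.approx(88 / 90, abs=1e-3)

    def test_no_predicted_positives_ppv_absent(self):
        cm = confusion_metrics([0.1, 0.2], [1, 0], cutoff=0.9)
        assert cm["ppv"] is None

    def test_f_scores_reported_panel_identity(self):
        # reference SVE-burden operating point: PPV 0.30, sens 0.40 -> F1 0.34
        f1, f2 = f_scores(0.30, 0.40)
        assert f1 == pytest.approx(2 * 0.12 / 0.70, abs=1e-12)
        assert round(f1, 2) == 0.34
        assert f2 == pytest.approx(5 * 0.12 / 1.60, abs=1e-12)

    def test_f_scores_edge_cases(self):
        assert f_scores(1.0, 1.0) == (1.0, 1.0)
        f1, f2 = f_scores(0.5, 1.0)
        assert f2 == pytest.approx(5 * 0.5 / 3.0)
        assert f_scores(0.0, 0.0) == (0.0, 0.0)


class TestFoldCI:
    def test_identical_values_zero_width(self):
        mean, lo, hi = fold_ci([0.8, 0.8, 0.8])
        assert mean == pytest.approx(0.8)
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_two_values_symmetric(self):
        mean, lo, hi = fold_ci([0.8, 0.9])
        assert mean == pytest.approx(0.85)
        assert hi - mean == pytest.approx(mean - lo)

    def test_matches_closed_form_t_interval(self):
        vals = np.array([0.80, 0.82, 0.84, 0.86, 0.88])
        mean, lo, hi = fold_ci(vals)
        half = stats.t.ppf(0.975, 4) * vals.std(ddof=1) / np.sqrt(5)
        assert mean == pytest.approx(0.84)
        assert lo == pytest.approx(0.84 - half, abs=1e-12)
        assert hi == pytest.approx(0.84 + half, abs=1e-12)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            fold_ci([0.8])


class TestBootstrapCI:
    def test_degenerate_scores_collapse_to_half(self):
        p, lo, hi = bootstrap_ci(auroc, [0.5] * 20, [0, 1] * 10,
                                 n_boot=100, seed=0)
        assert (p, lo, hi) == (0.5, 0.5, 0.5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 1, 40)
        labels = (rng.uniform(size=40) < 0.5).astype(int)
        a = bootstrap_ci(auroc, scores, labels, n_boot=200, seed=7)
        b = bootstrap_ci(auroc, scores, labels, n_boot=200, seed=7)
        assert a == b

    def test_coverage_close_to_nominal(self):
        """Percentile-bootstrap coverage of a known true AUROC."""
        mu = 1.0  # true AUROC = Phi(mu / sqrt(2))
        true = analytic_two_gaussian_auroc(0, 1, mu, 1)
        rng = np.random.default_rng(3)
        n_reps, covered = 40, 0
        for rep in range(n_reps):
            scores = np.concatenate([rng.normal(0, 1, 100),
                                     rng.normal(mu, 1, 100)])
            labels = np.array([0] * 100 + [1] * 100)
            _, lo, hi = bootstrap_ci(auroc, scores, labels, n_boot=200,
                                     seed=rep)
            covered += lo <= true <= hi
        # binomial(40, 0.95) two-sided 99.9% region
        assert covered >= 33


def _manifest(n_paf=5, n_ctrl=5, elapsed_months=None):
    exam = datetime(2020, 6, 1)
    patients = []
    for i in range(n_paf):
        m = elapsed_months[i] if elapsed_months else 12.0
        patients.append(PatientRecord(
            f"A{i}", True, exam, index_date=exam - timedelta(days=m * 30.44)))
    for i in range(n_ctrl):
        patients.append(PatientRecord(f"C{i}", False, exam))
    return CohortManifest(patients)


class TestFoldAssignment:
    def test_balanced_ten_patients(self):
        fa = assign_folds(_manifest(5, 5), k=5, seed=0)
        for fold in range(5):
            _, test = fa.train_test(fold)
            assert len(test) == 2
            assert sum(pid.startswith("A") for pid in test) == 1

    def test_deterministic(self):
        m = _manifest(6, 10)
        assert assign_folds(m, 5, seed=3).assignment \
            == assign_folds(m, 5, seed=3).assignment

    def test_union_disjoint(self):
        m = _manifest(7, 9)
        fa = assign_folds(m, 5, seed=1)
        all_ids = {p.patient_id for p in m}
        seen = []
        for fold in range(5):
            train, test = fa.train_test(fold)
            assert set(train) | set(test) == all_ids
            seen.extend(test)
        assert sorted(seen) == sorted(all_ids)

    def test_too_few_per_class_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(_manifest(3, 10), k=5, seed=0)


class TestElapsedTime:
    def _preds(self, manifest, detected):
        import pandas as pd
        rows = []
        for p in manifest:
            rows.append({"patient_id": p.patient_id,
                         "score": 0.9 if detected.get(p.patient_id, True)
                         else 0.1,
                         "label": int(p.paf_label), "fold": 0})
        return pd.DataFrame(rows)

    def test_all_detected_every_rate_one(self):
        m = _manifest(4, 4, elapsed_months=[1, 5, 20, 48])
        table = elapsed_time_sensitivity(self._preds(m, {}), m, cutoff=0.5)
        assert np.all(table["detection_rate"].dropna() == 1.0)

    def test_hand_built_strata_counts(self):
        elapsed = [1.0, 2.0, 5.0, 10.0, 20.0, 48.0]
        m = _manifest(6, 2, elapsed_months=elapsed)
        detected = {"A0": False, "A1": True, "A2": True,
                    "A3": False, "A4": True, "A5": True}
        table = elapsed_time_sensitivity(self._preds(m, detected), m, 0.5)
        t3_gt = table[(table.T_months == 3) & (table.stratum == ">3")].iloc[0]
        t3_lt = table[(table.T_months == 3) & (table.stratum == "<3")].iloc[0]
        assert t3_gt["n"] == 4 and t3_gt["n_detected"] == 3
        assert t3_lt["n"] == 2 and t3_lt["n_detected"] == 1
        t36_gt = table[(table.T_months == 36)
                       & (table.stratum == ">36")].iloc[0]
        assert t36_gt["n"] == 1 and t36_gt["detection_rate"] == 1.0

    def test_strata_partition_paf_patients(self):
        m = _manifest(5, 3, elapsed_months=[1, 3.0, 6.0, 13, 40])
        table = elapsed_time_sensitivity(self._preds(m, {}), m, 0.5)
        for t in (3, 6, 12, 36):
            sub = table[table.T_months == t]
            assert sub["n"].sum() == 5  # elapsed == T goes to the < stratum

    def test_empty_stratum_rate_absent(self):
        m = _manifest(2, 2, elapsed_months=[1.0, 2.0])
        table = elapsed_time_sensitivity(self._preds(m, {}), m, 0.5)
        row = table[(table.T_months == 36) & (table.stratum == ">36")].iloc[0]
        assert row["n"] == 0 and np.isnan(row["detection_rate"])
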