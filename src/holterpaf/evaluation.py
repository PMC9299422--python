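"""Evaluation protocol: patient-level 5-fold CV, ROC metrics, CIs, drivers.

Implements the full benchmarking protocol around the two-stage model:
stratified patient-level fold assignment (no patient appears in both train
and test), AUROC, a Youden-style cutoff maximising sensitivity +
specificity, the sensitivity/specificity/PPV/NPV/F1/F2 panel, fold-based
t-interval CIs for the model and percentile-bootstrap CIs for the
SVE-burden baseline, a diurnal (day/night) sub-analysis, an elapsed-time
sensitivity analysis over cutoffs T in {3, 6, 12, 36} months, and the
CNN-only ablation (segment-level AUROC without the patient-level GBM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .baselines import sve_burden_score
from .encoder import SegmentEncoderClassifier, score_segments
from .io import CohortManifest
from .patient import PatientBoostedClassifier, aggregate_latents
from .preprocess import (
    Diurnal,
    Setting,
    preprocess_patient,
    segments_to_spectrograms,
)
from .simulate import DAYS_PER_MONTH

logger = logging.getLogger(__name__)

__all__ = [
    "FoldAssignment",
    "MetricsReport",
    "ExperimentResult",
    "assign_folds",
    "auroc",
    "optimal_cutoff",
    "confusion_metrics",
    "f_scores",
    "fold_ci",
    "bootstrap_ci",
    "analytic_two_gaussian_auroc",
    "run_experiment",
    "diurnal_experiment",
    "elapsed_time_sensitivity",
    "summarize_experiment",
]

T_CUTOFFS_MONTHS = (3, 6, 12, 36)


# ---------------------------------------------------------------------------
# Core metrics


def auroc(scores, labels) -> float:
    """AUROC = normalized Mann-Whitney U; ties count one half."""
    labels = np.asarray(labels).astype(int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes")
    return float(roc_auc_score(labels, scores))


def optimal_cutoff(scores, labels) -> float:
    """Observed-score threshold maximising sensitivity + specificity.

    Prediction is positive iff score >= threshold.  Ties in the objective
    are broken toward higher sensitivity, then toward the lower threshold.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if len(np.unique(labels)) < 2:
        raise ValueError("cutoff selection requires both classes")
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None  # (sum, sens, -threshold)
    best_thr = None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        key = (sens + spec, sens, -thr)
        if best is None or key > best:
            best, best_thr = key, float(thr)
    return best_thr


def confusion_metrics(scores, labels, cutoff: float) -> dict[str, float | None]:
    """Sensitivity/specificity/PPV/NPV at a cutoff (positive iff >= cutoff).

    Ratios with a zero denominator are reported as None, not zero.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    pred = scores >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())

    def ratio(a, b):
        return a / b if b > 0 else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def f_scores(ppv: float, sensitivity: float) -> tuple[float, float]:
    """(F1, F2) from precision and recall; (0, 0) when both vanish."""
    out = []
    for beta in (1.0, 2.0):
        denom = beta**2 * ppv + sensitivity
        out.append((1 + beta**2) * ppv * sensitivity / denom if denom > 0 else 0.0)
    return out[0], out[1]


def fold_ci(values, confidence: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-interval across fold-level metric values."""
    values = np.asarray([v for v in values if v is not None], dtype=float)
    k = len(values)
    if k < 2:
        raise ValueError("fold CI requires at least 2 fold values")
    mean = float(values.mean())
    half = float(stats.t.ppf(0.5 + confidence / 2, k - 1)
                 * values.std(ddof=1) / np.sqrt(k))
    return mean, mean - half, mean + half


def bootstrap_ci(
    metric_fn, scores, labels, n_boot: int = 1000, seed: int = 0,
    confidence: float = 0.95, max_retries: int = 100,
) -> tuple[float, float, float]:
    """Percentile bootstrap over patients; deterministic given the seed.

    Each replicate resamples patients with replacement and is redrawn (up to
    ``max_retries`` times) until both classes are present; if the metric is
    undefined on more than half the replicates the CI is refused.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    rng = np.random.default_rng(seed)
    n = len(scores)
    point = metric_fn(scores, labels)
    vals = []
    n_failed = 0
    for _ in range(n_boot):
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) == 2:
                break
        else:
            n_failed += 1
            continue
        try:
            v = metric_fn(scores[idx], labels[idx])
        except (ValueError, ZeroDivisionError):
            n_failed += 1
            continue
        if v is None:
            n_failed += 1
            continue
        vals.append(v)
    if n_failed > n_boot // 2:
        raise ValueError("metric undefined on most bootstrap replicates")
    lo, hi = np.percentile(vals, [50 * (1 - confidence), 50 * (1 + confidence)])
    return float(point), float(lo), float(hi)


def analytic_two_gaussian_auroc(mu0: float, sd0: float,
                                mu1: float, sd1: float) -> float:
    """AUROC of two Gaussian score distributions: Phi(d / sqrt(s1^2+s0^2))."""
    return float(stats.norm.cdf((mu1 - mu0) / np.sqrt(sd0**2 + sd1**2)))


# ---------------------------------------------------------------------------
# Fold assignment


@dataclass
class FoldAssignment:
    assignment: dict[str, int]
    k: int
    seed: int

    def train_test(self, fold: int) -> tuple[list[str], list[str]]:
        test = [p for p, f in self.assignment.items() if f == fold]
        train = [p for p, f in self.assignment.items() if f != fold]
        assert not set(train) & set(test)
        return train, test


def assign_folds(manifest: CohortManifest, k: int = 5, seed: int = 0
                 ) -> FoldAssignment:
    """Stratified random patient-level fold assignment, deterministic by seed."""
    ids = np.array([p.patient_id for p in manifest])
    y = manifest.labels.astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"need at least k={k} patients per class; have {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(skf.split(ids, y)):
        for i in test_idx:
            assignment[str(ids[i])] = fold
    return FoldAssignment(assignment=assignment, k=k, seed=seed)


# ---------------------------------------------------------------------------
# Experiment driver


@dataclass
class MetricsReport:
    """Point estimates with CI provenance for one model/subgroup."""

    tag: str
    model: str
    ci_method: str  # "FOLDS" or "BOOTSTRAP"
    n_patients: int
    cutoff: float
    metrics: dict[str, tuple[float | None, float | None, float | None]]

    def to_dict(self) -> dict:
        return {
            "tag": self.tag,
            "model": self.model,
            "ci_method": self.ci_method,
            "n_patients": self.n_patients,
            "cutoff": self.cutoff,
            "metrics": {
                k: {"point": v[0], "ci_low": v[1], "ci_high": v[2]}
                for k, v in self.metrics.items()
            },
        }


@dataclass
class ExperimentResult:
    predictions: pd.DataFrame  # patient_id, score, label, fold
    fold_aurocs: list[float]
    pooled_auroc: float
    segment_fold_aurocs: list[float]
    segment_pooled_auroc: float
    baseline: pd.DataFrame  # patient_id, burden, label
    baseline_auroc: float
    folds: FoldAssignment
    setting: Setting
    seed: int
    period: str | None = None
    segment_counts: dict[str, int] = field(default_factory=dict)


def _prepare_cohort(manifest, data, setting, period, apply_noise_gate):
    """Per-patient segments (analysis setting + setting-1 for the baseline)."""
    seg_map, seg1_map = {}, {}
    for p in manifest:
        rec, anns = data[p.patient_id]
        seg1 = preprocess_patient(rec, anns, p, Setting.WITH_SVE,
                                  apply_noise_gate)
        if setting == Setting.WITH_SVE:
            segs = seg1
        else:
            segs = preprocess_patient(rec, anns, p, Setting.WITHOUT_SVE,
                                      apply_noise_gate)
        if period is not None:
            segs = [s for s in segs if s.diurnal == period]
        seg_map[p.patient_id] = segs
        seg1_map[p.patient_id] = seg1
    return seg_map, seg1_map


def run_experiment(
    manifest: CohortManifest,
    data: dict,
    setting: Setting = Setting.WITH_SVE,
    *,
    encoder_params: dict | None = None,
    gbm_params: dict | None = None,
    n_bins: int = 24,
    k: int = 5,
    seed: int = 0,
    period: Diurnal | None = None,
    max_train_segments: int = 2500,
    apply_noise_gate: bool = True,
    stft_window: int = 50,
    stft_hop: int = 25,
) -> ExperimentResult:
    """Full two-stage experiment under patient-level k-fold CV.

    For every fold: the CNN encoder is trained on training-fold segments
    only (subsampled to ``max_train_segments`` for tractability), every
    patient's segments are scored and pooled into feature vectors, the GBM
    is trained on training-fold patients, and test-fold patients receive
    their scores.  Also computes the segment-level (CNN-only) ablation
    AUROC and the SVE-burden baseline on the same patients.

    ``data`` maps patient_id -> (HolterRecording, annotations).
    """
    encoder_params = dict(encoder_params or {})
    gbm_params = dict(gbm_params or {})
    seg_map, seg1_map = _prepare_cohort(
        manifest, data, setting, period, apply_noise_gate)
    patients = {p.patient_id: p for p in manifest}

    spec_map = {
        pid: segments_to_spectrograms(segs, stft_window, stft_hop)
        .astype(np.float32)
        for pid, segs in seg_map.items()
    }
    folds = assign_folds(manifest, k=k, seed=seed)
    rng = np.random.default_rng(seed)

    rows = []
    fold_aurocs, seg_fold_aurocs = [], []
    seg_pool_scores, seg_pool_labels = [], []
    for fold in range(k):
        train_pids, test_pids = folds.train_test(fold)
        assert not set(train_pids) & set(test_pids), "patient-level leakage"

        X_parts, y_parts, g_parts = [], [], []
        for pid in train_pids:
            n_seg = len(seg_map[pid])
            if n_seg == 0:
                continue
            X_parts.append(spec_map[pid])
            y_parts.append(np.full(n_seg, patients[pid].paf_label, dtype=int))
            g_parts.append(np.full(n_seg, pid))
        X_tr = np.concatenate(X_parts)
        y_tr = np.concatenate(y_parts)
        g_tr = np.concatenate(g_parts)
        if len(X_tr) > max_train_segments:
            sub = rng.choice(len(X_tr), size=max_train_segments, replace=False)
            sub.sort()
            X_tr, y_tr, g_tr = X_tr[sub], y_tr[sub], g_tr[sub]

        enc = SegmentEncoderClassifier(
            **encoder_params,
            random_state=(seed * 31 + fold) % (2**31 - 1))
        enc.fit(X_tr, y_tr, groups=g_tr)
        latent_dim = enc.latent_dim

        feats, labels_map, probs_map = {}, {}, {}
        for pid, segs in seg_map.items():
            rec = data[pid][0]
            if len(segs):
                probs, latents = score_segments(enc, spec_map[pid])
            else:
                probs = np.empty(0)
                latents = np.empty((0, latent_dim))
            probs_map[pid] = probs
            feats[pid] = aggregate_latents(
                probs, latents, [s.start_time for s in segs],
                rec.start_time,
                rec.start_time + timedelta(seconds=rec.duration_s),
                n_bins=n_bins,
                contains_sve=np.array([s.contains_sve for s in segs]),
                latent_dim=latent_dim,
            )
            labels_map[pid] = int(patients[pid].paf_label)
            if pid in test_pids and len(segs):
                seg_pool_scores.append(probs)
                seg_pool_labels.append(
                    np.full(len(segs), labels_map[pid], dtype=int))

        gbm = PatientBoostedClassifier(
            **gbm_params, random_state=(seed * 31 + fold) % (2**31 - 1))
        gbm.fit(np.vstack([feats[p] for p in train_pids]),
                np.array([labels_map[p] for p in train_pids]))
        test_scores = gbm.predict_proba(
            np.vstack([feats[p] for p in test_pids]))[:, 1]
        for pid, s in zip(test_pids, test_scores):
            rows.append({"patient_id": pid, "score": float(s),
                         "label": labels_map[pid], "fold": fold})

        fold_labels = np.array([labels_map[p] for p in test_pids])
        fold_aurocs.append(auroc(test_scores, fold_labels))
        fold_seg_scores = np.concatenate(
            [probs_map[p] for p in test_pids if len(seg_map[p])])
        fold_seg_labels = np.concatenate(
            [np.full(len(seg_map[p]), labels_map[p], dtype=int)
             for p in test_pids if len(seg_map[p])])
        seg_fold_aurocs.append(auroc(fold_seg_scores, fold_seg_labels))

    predictions = pd.DataFrame(rows).sort_values("patient_id")\
        .reset_index(drop=True)
    pooled = auroc(predictions["score"], predictions["label"])
    seg_pooled = auroc(np.concatenate(seg_pool_scores),
                       np.concatenate(seg_pool_labels))

    base_rows = []
    for p in manifest:
        b = sve_burden_score(seg1_map[p.patient_id])
        if b is None:
            continue
        base_rows.append({"patient_id": p.patient_id, "burden": b.burden,
                          "label": int(p.paf_label)})
    baseline = pd.DataFrame(base_rows)
    baseline_auroc = auroc(baseline["burden"], baseline["label"])

    return ExperimentResult(
        predictions=predictions,
        fold_aurocs=fold_aurocs,
        pooled_auroc=pooled,
        segment_fold_aurocs=seg_fold_aurocs,
        segment_pooled_auroc=seg_pooled,
        baseline=baseline,
        baseline_auroc=baseline_auroc,
        folds=folds,
        setting=setting,
        seed=seed,
        period=period.value if period is not None else None,
        segment_counts={pid: len(s) for pid, s in seg_map.items()},
    )


def diurnal_experiment(
    manifest: CohortManifest,
    data: dict,
    setting: Setting,
    period: Diurnal,
    **kwargs,
) -> ExperimentResult:
    """Run the full pipeline restricted to daytime or nighttime segments.

    The period filter is applied before both training stages; folds are the
    same as the all-day run for the same seed.
    """
    return run_experiment(manifest, data, setting, period=period, **kwargs)


def elapsed_time_sensitivity(
    predictions: pd.DataFrame,
    manifest: CohortManifest,
    cutoff: float,
    t_list: tuple[int, ...] = T_CUTOFFS_MONTHS,
) -> pd.DataFrame:
    """Detection rate among pAF patients, stratified by elapsed time vs T.

    Elapsed time is (exam date - index date) in 30.44-day months.  Patients
    with elapsed exactly equal to T fall in the "< T" stratum.  Empty strata
    report a rate of NaN with count 0.
    """
    by_id = {p.patient_id: p for p in manifest}
    rows = []
    paf = predictions[predictions["label"] == 1]
    elapsed = {}
    for _, r in paf.iterrows():
        p = by_id[r["patient_id"]]
        elapsed[r["patient_id"]] = (
            (p.exam_date - p.index_date).total_seconds() / 86400.0
            / DAYS_PER_MONTH)
    detected = {r["patient_id"]: r["score"] >= cutoff
                for _, r in paf.iterrows()}
    for t in t_list:
        for stratum, sel in (
            (f">{t}", [pid for pid, e in elapsed.items() if e > t]),
            (f"<{t}", [pid for pid, e in elapsed.items() if e <= t]),
        ):
            n = len(sel)
            n_det = sum(detected[pid] for pid in sel)
            rows.append({
                "T_months": t,
                "stratum": stratum,
                "n": n,
                "n_detected": int(n_det),
                "detection_rate": n_det / n if n else float("nan"),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reporting


def _panel_at_cutoff(scores, labels, cutoff):
    cm = confusion_metrics(scores, labels, cutoff)
    if cm["ppv"] is not None and cm["sensitivity"] is not None:
        f1, f2 = f_scores(cm["ppv"], cm["sensitivity"])
    else:
        f1 = f2 = None
    return {**cm, "f1": f1, "f2": f2}


def summarize_experiment(
    result: ExperimentResult,
    n_boot: int = 1000,
    tag: str = "ALL",
) -> dict[str, MetricsReport]:
    """Model report (fold-based CIs) and baseline report (bootstrap CIs).

    The model cutoff is the Youden-style optimum on the pooled cross-
    validated predictions; fold CIs are t-intervals over per-fold metrics at
    that cutoff.  The baseline cutoff is chosen the same way on burdens.
    """
    preds = result.predictions
    scores = preds["score"].to_numpy()
    labels = preds["label"].to_numpy()
    cutoff = optimal_cutoff(scores, labels)

    per_fold: dict[str, list] = {m: [] for m in
                                 ("auroc", "sensitivity", "specificity",
                                  "ppv", "npv", "f1", "f2")}
    for fold in sorted(preds["fold"].unique()):
        sub = preds[preds["fold"] == fold]
        panel = _panel_at_cutoff(sub["score"].to_numpy(),
                                 sub["label"].to_numpy(), cutoff)
        per_fold["auroc"].append(auroc(sub["score"], sub["label"]))
        for m in ("sensitivity", "specificity", "ppv", "npv", "f1", "f2"):
            per_fold[m].append(panel[m])

    model_metrics = {}
    for m, vals in per_fold.items():
        present = [v for v in vals if v is not None]
        if len(present) >= 2:
            model_metrics[m] = fold_ci(present)
        elif present:
            model_metrics[m] = (present[0], None, None)
        else:
            model_metrics[m] = (None, None, None)

    model_report = MetricsReport(
        tag=tag, model=f"two_stage_setting{int(result.setting)}",
        ci_method="FOLDS", n_patients=len(preds), cutoff=cutoff,
        metrics=model_metrics,
    )

    b = result.baseline
    b_scores = b["burden"].to_numpy()
    b_labels = b["label"].to_numpy()
    b_cut = optimal_cutoff(b_scores, b_labels)
    seed = result.seed

    def metric_fn_factory(name):
        def fn(s, l):
            if name == "auroc":
                return auroc(s, l)
            return _panel_at_cutoff(s, l, b_cut)[name]
        return fn

    base_metrics = {}
    for m in ("auroc", "sensitivity", "specificity", "ppv", "npv", "f1", "f2"):
        try:
            base_metrics[m] = bootstrap_ci(
                metric_fn_factory(m), b_scores, b_labels,
                n_boot=n_boot, seed=seed)
        except ValueError:
            # metric undefined on most replicates (tiny or degenerate
            # cohorts): reported as absent, never fabricated
            base_metrics[m] = (None, None, None)
    base_report = MetricsReport(
        tag=tag, model="sve_burden", ci_method="BOOTSTRAP",
        n_patients=len(b), cutoff=b_cut, metrics=base_metrics,
    )
    return {"model": model_report, "baseline": base_report}
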