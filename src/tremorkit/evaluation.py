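"""Detector evaluation: leave-one-subject-out CV and test-retest reliability.

Leave-one-subject-out cross-validation (LOSO-CV) retrains the full detector
(classifier, tau calibration and theta_move) on all subjects but one and
scores the held-out subject, preventing any within-subject leakage.  Per
fold we report sensitivity, specificity (with windows rejected as arm
movement excluded from the specificity denominator), a secondary unfiltered
specificity (logistic regression + clinical criterion only), per-activity
specificities and an activity-prevalence-weighted specificity that corrects
subject comparisons for how much time each spent in each activity.

Week-to-week test-retest reliability of the weekly measures uses the
two-way, absolute-agreement, single-measurement intraclass correlation
ICC(A,1) with a 95% CI from the F-distribution method.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .tremor_detector import classify_features, fit_detector


@dataclass
class FoldResult:
    subject_id: str
    sensitivity: float | None
    specificity: float | None
    specificity_unfiltered: float | None
    per_activity_specificity: dict = field(default_factory=dict)
    weighted_specificity: float | None = None
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


@dataclass
class ReliabilityResult:
    measure: str
    icc: float
    ci95: tuple[float, float]
    n_subjects: int


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def _fold_metrics(subject: str, labelled: pd.DataFrame,
                  classified: pd.DataFrame) -> FoldResult:
    y = labelled["label_tremor"].to_numpy(dtype=bool)
    pred_tremor = (classified["final_state"] == "tremor").to_numpy()
    rejected = (classified["final_state"] == "rejected_movement").to_numpy()
    lr_clinical = (classified["lr_positive"]
                   & classified["peak_in_rest_band"]).to_numpy()
    # confusion over all labelled windows (positives = final tremor)
    tp = int((y & pred_tremor).sum())
    fn = int((y & ~pred_tremor).sum())
    fp = int((~y & pred_tremor).sum())
    tn = int((~y & ~pred_tremor).sum())
    # filtered specificity excludes rejected windows from the denominator
    neg_kept = ~y & ~rejected
    spec = _safe_ratio(int((neg_kept & ~pred_tremor).sum()),
                       int(neg_kept.sum()))
    sens = _safe_ratio(tp, tp + fn)
    spec_unf = _safe_ratio(int((~y & ~lr_clinical).sum()), int((~y).sum()))
    per_act = {}
    acts = labelled["label_activity"].to_numpy()
    for a in pd.unique(acts[~pd.isna(acts)]):
        m = neg_kept & (acts == a)
        per_act[a] = _safe_ratio(int((m & ~pred_tremor).sum()), int(m.sum()))
    return FoldResult(subject_id=subject, sensitivity=sens, specificity=spec,
                      specificity_unfiltered=spec_unf,
                      per_activity_specificity=per_act,
                      tp=tp, fp=fp, tn=tn, fn=fn)


def pooled_activity_prevalence(features: pd.DataFrame,
                               activities: list[str] | None = None
                               ) -> dict[str, float]:
    """Share of each activity among all subjects' non-tremor labelled windows."""
    neg = features[features["label_tremor"].notna()
                   & ~features["label_tremor"].astype(bool)]
    counts = neg["label_activity"].value_counts()
    if activities is not None:
        counts = counts[counts.index.isin(activities)]
    total = counts.sum()
    if total == 0:
        raise ValueError("no non-tremor windows to derive prevalence from")
    return (counts / total).to_dict()


def weighted_specificity(fold: FoldResult,
                         reference_prevalence: dict[str, float]
                         ) -> float | None:
    """Prevalence-weighted mean of per-activity specificities.

    Weights renormalize over the reference activities for which the fold has
    a defined specificity; None when no reference activity is present.
    """
    avail = {a: s for a, s in fold.per_activity_specificity.items()
             if a in reference_prevalence and s is not None}
    if not avail:
        return None
    w = np.array([reference_prevalence[a] for a in avail])
    w = w / w.sum()
    return float(np.dot(w, list(avail.values())))


def _summary(folds: list[FoldResult]) -> dict:
    def agg(name):
        vals = [getattr(f, name) for f in folds if getattr(f, name) is not None]
        if not vals:
            return None, None
        return float(np.mean(vals)), float(np.std(vals))  # population SD

    out = {}
    for name in ("sensitivity", "specificity", "specificity_unfiltered",
                 "weighted_specificity"):
        out[f"{name}_mean"], out[f"{name}_sd"] = agg(name)
    out["n_folds"] = len(folds)
    return out


def loso_cv(features: pd.DataFrame,
            config: PipelineConfig = PipelineConfig(),
            movement_filter: bool = True,
            weighting: str | None = None
            ) -> tuple[list[FoldResult], dict]:
    """Leave-one-subject-out evaluation of the full detection cascade.

    ``features`` is a featurized window table with ``subject_id``,
    ``label_tremor`` and ``label_activity`` columns.  Folds whose training
    pool collapses to a single class are skipped with a warning.
    """
    subjects = list(pd.unique(features["subject_id"]))
    if len(subjects) < 3:
        raise ValueError("LOSO-CV needs at least 3 subjects")
    labelled_any = features["label_tremor"].notna()
    if not features.loc[labelled_any, "label_tremor"].astype(bool).any():
        raise ValueError("no subject has tremor-labelled windows")
    weighting = weighting or config.evaluation.specificity_weighting
    if weighting == "pooled_prevalence":
        prevalence = pooled_activity_prevalence(features)
    else:
        acts = features.loc[labelled_any, "label_activity"].dropna().unique()
        prevalence = {a: 1.0 / len(acts) for a in acts}
    folds = []
    for subject in subjects:
        held = features["subject_id"] == subject
        train = features[~held]
        train_lab = train[train["label_tremor"].notna()]
        classes = train_lab["label_tremor"].astype(bool)
        if classes.all() or not classes.any():
            warnings.warn(f"fold {subject}: single-class training set, skipped")
            continue
        model = fit_detector(train, config)
        test_lab = features[held & labelled_any]
        classified = classify_features(model, test_lab, config,
                                       movement_filter=movement_filter)
        fold = _fold_metrics(subject, test_lab, classified)
        fold.weighted_specificity = weighted_specificity(fold, prevalence)
        folds.append(fold)
    return folds, _summary(folds)


# ---------------------------------------------------------------------------
# test-retest reliability


def icc_test_retest(week1: np.ndarray, week2: np.ndarray,
                    measure: str = "measure") -> ReliabilityResult:
    """ICC(A,1) between two repeated weekly measurements.

    Two-way, absolute-agreement, single-measurement ICC (McGraw-Wong
    ICC(A,1); computed via pingouin's ICC2, the identical estimator) with
    the F-method 95% CI.  Pairs with a missing value are dropped; degenerate
    zero between-subject variance yields ICC 0 with a warning.
    """
    import pingouin as pg

    w1 = np.asarray(week1, dtype=float)
    w2 = np.asarray(week2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("week1 and week2 must be paired (same subjects)")
    keep = np.isfinite(w1) & np.isfinite(w2)
    w1, w2 = w1[keep], w2[keep]
    n = w1.size
    if n < 5:
        raise ValueError(f"need at least 5 paired subjects, got {n}")
    both = np.concatenate([w1, w2])
    if np.ptp(both) < 1e-12 or np.var(np.vstack([w1, w2]).mean(axis=0)) < 1e-24:
        warnings.warn("zero between-subject variance; ICC undefined, using 0")
        return ReliabilityResult(measure, 0.0, (0.0, 0.0), n)
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "week": np.repeat([1, 2], n),
        "value": both,
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(data=long, targets="subject",
                                   raters="week", ratings="value")
    row = table[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    icc = float(row["ICC"])
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = (float(v) for v in row[ci_col])
    if not np.isfinite(lo):
        lo = icc
    if not np.isfinite(hi):
        hi = icc
    lo, hi = min(lo, icc), max(hi, icc)
    return ReliabilityResult(measure, icc, (lo, hi), n)


def icc_anova_oracle(week1: np.ndarray, week2: np.ndarray) -> float:
    """Closed-form ICC(A,1) from two-way ANOVA mean squares.

    Independent of pingouin; kept as the cross-check route for the ICC
    estimator (and exported for tests).
    """
    x = np.vstack([np.asarray(week1, float), np.asarray(week2, float)]).T
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sst = np.sum((x - grand) ** 2)
    mse = (sst - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
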