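"""Tremor classification: training, calibration and the decision cascade.

The detector is a binary logistic regression on the 12 standardized MFCCs of
each 4-s window, with three deliberate asymmetries towards specificity:

1. the probability threshold tau is not 0.5 but calibrated so that 95% of
   non-tremor training windows score below it;
2. a clinical criterion requires the window's spectral peak to lie inside
   the 3-7 Hz rest-tremor band;
3. windows with simultaneous non-tremor arm movement (0.5-3 Hz band power
   above a data-driven threshold theta_move, the midpoint of a two-cluster
   K-means split of the log10 band-power distribution) are rejected outright
   - both to cut false positives (e.g. gait arm swing whose harmonics reach
   the tremor band) and because the slow movement's harmonics would corrupt
   the measured tremor power.

During training, cycling windows are oversampled (weight 100) to penalise
the classic failure mode of calling rhythmic cycling "tremor".

Final per-window states: ``tremor``, ``no_tremor``, ``rejected_movement``.
The rejected windows also define "inactive time", the denominator of the
weekly tremor-time measure.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .config import PipelineConfig

MFCC_COLS = [f"mfcc_{i}" for i in range(1, 13)]

FINAL_STATES = ("tremor", "no_tremor", "rejected_movement")

_EPS = 1e-12


class ConfigMismatchError(RuntimeError):
    """A model refused to score features produced under a different config."""


@dataclass
class TremorDetectionModel:
    feature_means: np.ndarray
    feature_sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    prob_threshold: float
    movement_power_threshold: float
    config_hash: str
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(self.feature_sds > 0):
            raise ValueError("feature_sds must be positive")
        if not (0.0 < self.prob_threshold < 1.0):
            raise ValueError("prob_threshold must lie in (0, 1)")
        if not self.movement_power_threshold > 0:
            raise ValueError("movement_power_threshold must be positive")

    # -- persistence -------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "feature_means": list(map(float, self.feature_means)),
            "feature_sds": list(map(float, self.feature_sds)),
            "coefficients": list(map(float, self.coefficients)),
            "intercept": float(self.intercept),
            "prob_threshold": float(self.prob_threshold),
            "movement_power_threshold": float(self.movement_power_threshold),
            "config_hash": self.config_hash,
            "config": self.config,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "TremorDetectionModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(feature_means=np.asarray(d["feature_means"]),
                   feature_sds=np.asarray(d["feature_sds"]),
                   coefficients=np.asarray(d["coefficients"]),
                   intercept=d["intercept"],
                   prob_threshold=d["prob_threshold"],
                   movement_power_threshold=d["movement_power_threshold"],
                   config_hash=d["config_hash"],
                   config=d.get("config", {}))

    # -- scoring -----------------------------------------------------------
    def predict_proba(self, mfcc: np.ndarray) -> np.ndarray:
        z = (np.asarray(mfcc, dtype=float) - self.feature_means) / self.feature_sds
        logit = z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-logit))


@dataclass
class WindowClassification:
    p_tremor: float
    lr_positive: bool
    peak_in_rest_band: bool
    arm_movement: bool
    final_state: str
    tremor_power: float | None


# ---------------------------------------------------------------------------
# training


def train_classifier(mfcc: np.ndarray, tremor_labels: np.ndarray,
                     activity_labels: np.ndarray | None = None,
                     cycling_oversample: float = 100.0,
                     l2_strength: float = 0.01, seed: int = 0,
                     max_iter: int = 1000):
    """Fit the logistic regression on standardized MFCCs.

    Cycling windows receive sample weight ``cycling_oversample`` (likelihood-
    equivalent to replication).  Returns ``(coefficients, intercept, means,
    sds)``; a constant feature has its SD floored to 1 so its z-score is 0
    and its coefficient stays finite.
    """
    X = np.asarray(mfcc, dtype=float)
    y = np.asarray(tremor_labels, dtype=bool)
    if X.ndim != 2:
        raise ValueError("mfcc must be 2-D (n_windows, n_coefficients)")
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    sds = np.where(sds < 1e-12, 1.0, sds)
    Z = (X - means) / sds
    weights = np.ones(len(y))
    if activity_labels is not None:
        weights[np.asarray(activity_labels) == "cycling"] = cycling_oversample
    clf = LogisticRegression(C=1.0 / max(l2_strength, 1e-12), solver="lbfgs",
                             max_iter=max_iter, tol=1e-6, random_state=seed)
    clf.fit(Z, y, sample_weight=weights)
    return clf.coef_[0].copy(), float(clf.intercept_[0]), means, sds


def calibrate_threshold(probs_nontremor: np.ndarray,
                        target_specificity: float = 0.95) -> float:
    """Smallest tau such that >= ``target_specificity`` of the non-tremor
    probabilities fall strictly below it.

    A window is later called positive when ``p >= tau``, so the training
    specificity at the returned tau is ``ceil(target * n) / n`` (in
    [0.95, 0.96] for tie-free probabilities and n >= 100); at target 1.0 the
    threshold sits just above the largest negative probability.
    """
    p = np.sort(np.asarray(probs_nontremor, dtype=float))
    n = p.size
    if n == 0:
        raise ValueError("no non-tremor windows to calibrate on")
    if n < 20:
        warnings.warn(f"calibrating on only {n} non-tremor windows")
    if not (0.0 < target_specificity <= 1.0):
        raise ValueError("target_specificity must lie in (0, 1]")
    k = int(np.ceil(target_specificity * n - 1e-12))
    if k >= n:
        return float(min(np.nextafter(p[-1], np.inf), 1.0 - 1e-15))
    return float(p[k])


def fit_movement_threshold(low_band_power: np.ndarray, seed: int = 0,
                           n_init: int = 10) -> float:
    """theta_move from a two-cluster K-means split of log10 band power.

    K-means (k=2, k-means++ with fixed seed, best of ``n_init`` restarts) on
    ``log10(P + eps)`` across all windows; the threshold is 10^(midpoint of
    the two cluster centres), separating the quiescent-wrist mode from the
    voluntary-movement mode of the band-power distribution.
    """
    x = np.log10(np.asarray(low_band_power, dtype=float) + _EPS)
    if x.size < 2 or np.ptp(x) < 1e-12:
        raise ValueError("degenerate band-power distribution")
    if x.size < 100:
        warnings.warn(f"fitting movement threshold on only {x.size} windows")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed,
                algorithm="lloyd")
    km.fit(x.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    return float(10.0 ** centers.mean())


def fit_detector(features: pd.DataFrame,
                 config: PipelineConfig = PipelineConfig()
                 ) -> TremorDetectionModel:
    """Full training sequence on a featurized window table.

    Labelled rows (non-null ``label_tremor``) train the classifier and
    calibrate tau; theta_move is fitted on the band power of *all* windows.
    """
    det = config.detector
    labelled = features[features["label_tremor"].notna()]
    if labelled.empty:
        raise ValueError("no labelled windows")
    coef, intercept, means, sds = train_classifier(
        labelled[MFCC_COLS].to_numpy(),
        labelled["label_tremor"].to_numpy(dtype=bool),
        labelled["label_activity"].to_numpy()
        if "label_activity" in labelled else None,
        cycling_oversample=det.cycling_oversample,
        l2_strength=det.l2_strength, seed=det.seed, max_iter=det.max_iter)
    model = TremorDetectionModel(
        feature_means=means, feature_sds=sds, coefficients=coef,
        intercept=intercept, prob_threshold=0.5,
        movement_power_threshold=1.0,
        config_hash=config.hash(), config=config.to_dict())
    neg = labelled[~labelled["label_tremor"].astype(bool)]
    probs_neg = model.predict_proba(neg[MFCC_COLS].to_numpy())
    model.prob_threshold = calibrate_threshold(probs_neg,
                                               det.target_specificity)
    model.movement_power_threshold = fit_movement_threshold(
        features["low_band_power"].to_numpy(), seed=det.seed)
    return model


# ---------------------------------------------------------------------------
# classification cascade


def classify_features(model: TremorDetectionModel, features: pd.DataFrame,
                      config: PipelineConfig | None = None,
                      movement_filter: bool = True) -> pd.DataFrame:
    """Vectorised decision cascade over a featurized window table.

    Returns the input keys plus ``p_tremor``, ``lr_positive``,
    ``peak_in_rest_band``, ``arm_movement``, ``final_state`` and
    ``tremor_power`` (non-null only for final tremor windows).  With
    ``movement_filter=False`` the arm-movement flag is still computed but no
    window is rejected (the published ablation).
    """
    if config is not None:
        cfg = config
    elif model.config:
        cfg = PipelineConfig.from_dict(model.config)
    else:
        cfg = PipelineConfig()
    if config is not None and config.hash() != model.config_hash:
        raise ConfigMismatchError(
            "feature config hash differs from the model's training config")
    lo, hi = cfg.bands.rest_tremor_band
    p = model.predict_proba(features[MFCC_COLS].to_numpy())
    lr_positive = p >= model.prob_threshold
    peak = features["peak_freq_hz"].to_numpy(dtype=float)
    peak_in_band = np.isfinite(peak) & (peak >= lo) & (peak <= hi)
    arm_movement = features["low_band_power"].to_numpy(dtype=float) \
        > model.movement_power_threshold
    rejected = arm_movement & movement_filter
    is_tremor = lr_positive & peak_in_band & ~rejected
    final = np.where(rejected, "rejected_movement",
                     np.where(is_tremor, "tremor", "no_tremor"))
    out = features[[c for c in ("subject_id", "window_start")
                    if c in features.columns]].copy()
    out["p_tremor"] = p
    out["lr_positive"] = lr_positive
    out["peak_in_rest_band"] = peak_in_band
    out["arm_movement"] = arm_movement
    out["final_state"] = final
    out["tremor_power"] = np.where(
        is_tremor, features["tremor_power"].to_numpy(dtype=float), np.nan)
    return out


def classify_window(model: TremorDetectionModel, features,
                    config: PipelineConfig | None = None,
                    movement_filter: bool = True) -> WindowClassification:
    """Single-window cascade over a :class:`WindowFeatures` object."""
    row = pd.DataFrame({
        **{c: [v] for c, v in zip(MFCC_COLS, np.asarray(features.mfcc))},
        "peak_freq_hz": [np.nan if features.peak_freq_hz is None
                         else features.peak_freq_hz],
        "low_band_power": [features.low_band_power],
        "tremor_power": [features.tremor_power],
    })
    r = classify_features(model, row, config, movement_filter).iloc[0]
    return WindowClassification(
        p_tremor=float(r.p_tremor), lr_positive=bool(r.lr_positive),
        peak_in_rest_band=bool(r.peak_in_rest_band),
        arm_movement=bool(r.arm_movement), final_state=str(r.final_state),
        tremor_power=None if np.isnan(r.tremor_power) else float(r.tremor_power))
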