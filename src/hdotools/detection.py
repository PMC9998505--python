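"""HDO detection: spectral + autocorrelation features and a small MLP.

A time course is summarized by 22 numbers: 17 linearly detrended amplitude-
spectrum values over the interval [f_o - 4 sigma, f_o + 4 sigma] at a
resolution of sigma/2, and 5 phase-averaged autocorrelation values.  The
autocorrelation is evaluated at integer-second lags 1..15 on the
1-s-resampled course, linearly detrended over lag, and averaged in the five
groups {1,6,11}, {2,7,12}, {3,8,13}, {4,9,14}, {5,10,15}: for an
oscillation with a 5-s period the three members of each group sit at the
same oscillation phase, so the group means trace one period of the
autocorrelation while noise averages out.

The classifier is a single-hidden-layer perceptron (8 tanh hidden units,
logistic output) on standardized features, trained with L-BFGS from a fixed
seed.  Scoring runs through an explicit numpy forward pass so that a model
serialized to JSON reproduces its scores exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .preprocess import resample_to_1s
from .spectral import HDOBand, band_interval_downsample, compute_spectrum
from .timecourse import TimeCourse

__all__ = [
    "FeatureVector",
    "DetectorModel",
    "extract_features",
    "train_detector",
    "detect",
    "evaluate_detector",
]

_LAGS = np.arange(1, 16)  # seconds
_N_GROUPS = 5


@dataclass(frozen=True)
class FeatureVector:
    """Detection features for one time course."""

    spectral: np.ndarray  # 17 values over the feature interval
    autocorr: np.ndarray  # 5 phase-averaged autocorrelation values
    band: HDOBand

    def as_array(self) -> np.ndarray:
        return np.concatenate([self.spectral, self.autocorr])


def _autocorrelation(values: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Biased sample autocorrelation (normalized by N) of the centered signal."""
    x = values - values.mean()
    denom = np.dot(x, x)
    if denom == 0:
        raise ValueError("autocorrelation undefined for a zero-variance course")
    return np.array([np.dot(x[:-k], x[k:]) / denom for k in lags])


def extract_features(tc: TimeCourse, band: HDOBand) -> FeatureVector:
    """Compute the 17 + 5 detection features.

    Requires dt <= 1 s and at least 60 s of signal.  The spectral branch
    uses the course at full temporal resolution; the autocorrelation branch
    uses the 1-s bin-averaged course so the lags are exactly 1..15 s.
    """
    if tc.dt > 1.0 + 1e-9:
        raise ValueError(f"detection requires dt <= 1 s, got {tc.dt}")
    if tc.duration < 60.0:
        raise ValueError(f"detection requires >= 60 s of signal, got {tc.duration}")
    if np.ptp(tc.values) == 0:
        raise ValueError("autocorrelation undefined for a zero-variance course")
    spec = compute_spectrum(tc)
    spectral = band_interval_downsample(spec, band, detrend=True)
    tc1 = resample_to_1s(tc)
    ac = _autocorrelation(tc1.values, _LAGS)
    ac = signal.detrend(ac)
    groups = ac.reshape(3, _N_GROUPS).mean(axis=0)
    return FeatureVector(spectral=spectral, autocorr=groups, band=band)


@dataclass
class DetectorModel:
    """Trained HDO classifier plus the feature configuration it expects."""

    band: HDOBand
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    weights: list  # [W1, b1, W2, b2]
    activation: str = "tanh"
    threshold: float = 0.5
    n_train: int = 0
    seed: int = 0
    class_balance: float = 0.5
    cv_accuracy: float = float("nan")

    def score(self, features: FeatureVector) -> float:
        if not np.isclose(features.band.f_o, self.band.f_o) or \
                not np.isclose(features.band.sigma, self.band.sigma):
            raise ValueError(
                "feature band does not match the band this model was trained with")
        x = (features.as_array() - self.scaler_mean) / self.scaler_scale
        w1, b1, w2, b2 = self.weights
        h = np.tanh(x @ w1 + b1)
        logit = float(h @ w2 + b2)
        return float(1.0 / (1.0 + np.exp(-logit)))

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "band": {"f_o": self.band.f_o, "sigma": self.band.sigma},
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "weights": [np.asarray(w).tolist() for w in self.weights],
            "activation": self.activation,
            "threshold": self.threshold,
            "n_train": self.n_train,
            "seed": self.seed,
            "class_balance": self.class_balance,
            "cv_accuracy": self.cv_accuracy,
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "DetectorModel":
        try:
            payload = json.loads(source)
        except (TypeError, json.JSONDecodeError):
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            band=HDOBand(**payload["band"]),
            scaler_mean=np.asarray(payload["scaler_mean"]),
            scaler_scale=np.asarray(payload["scaler_scale"]),
            weights=[np.asarray(w) for w in payload["weights"]],
            activation=payload["activation"],
            threshold=payload["threshold"],
            n_train=payload["n_train"],
            seed=payload["seed"],
            class_balance=payload["class_balance"],
            cv_accuracy=payload["cv_accuracy"],
        )


def train_detector(features: list[FeatureVector], labels, seed: int = 0,
                   hidden_units: int = 8, cv_folds: int = 5) -> DetectorModel:
    """Train the MLP detector; deterministic given ``seed``.

    ``labels[i]`` is True when course ``i`` contains HDO.  Returns the model
    with a stratified cross-validation accuracy estimate in
    ``cv_accuracy``.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("training needs both classes present")
    band = features[0].band
    X = np.vstack([fv.as_array() for fv in features])
    y = labels.astype(int)

    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    def make_mlp(rs):
        return MLPClassifier(hidden_layer_sizes=(hidden_units,),
                             activation="tanh", solver="lbfgs",
                             alpha=1e-3, max_iter=2000, random_state=rs)

    # CV estimate on held-out folds, then final fit on everything
    folds = min(cv_folds, int(np.bincount(y).min()))
    cv_acc = float("nan")
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(Xs, y):
            clf = make_mlp(seed).fit(Xs[tr], y[tr])
            accs.append(float((clf.predict(Xs[te]) == y[te]).mean()))
        cv_acc = float(np.mean(accs))

    mlp = make_mlp(seed).fit(Xs, y)
    weights = [mlp.coefs_[0], mlp.intercepts_[0],
               mlp.coefs_[1][:, 0], float(mlp.intercepts_[1][0])]
    return DetectorModel(band=band, scaler_mean=mean, scaler_scale=scale,
                         weights=weights, n_train=len(features), seed=seed,
                         class_balance=float(y.mean()), cv_accuracy=cv_acc)


def detect(tc: TimeCourse, model: DetectorModel) -> dict:
    """Classify one time course; returns ``{"oscillatory": bool, "score": p}``."""
    fv = extract_features(tc, model.band)
    score = model.score(fv)
    return {"oscillatory": bool(score >= model.threshold), "score": score}


def evaluate_detector(model: DetectorModel, courses: list[TimeCourse],
                      labels) -> dict:
    """Confusion counts plus specificity and sensitivity on a labelled set."""
    labels = np.asarray(labels, dtype=bool)
    if len(courses) == 0:
        raise ValueError("empty test set")
    pred = np.array([detect(tc, model)["oscillatory"] for tc in courses])
    tp = int(np.sum(pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    fn = int(np.sum(~pred & labels))
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    return {"specificity": specificity, "sensitivity": sensitivity,
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}
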