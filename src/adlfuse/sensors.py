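"""IMU/GPS windowing, feature extraction, and the calibrated sensor classifier.

The inertial stream (3-axis accelerometer + 3-axis gyroscope at 90 Hz) is cut
into non-overlapping 3-second windows, each centered on an image timestamp so
the sensor evidence describes the same instant as the image evidence.  Every
window becomes a 127-dimensional feature vector; a multiclass RBF-kernel
max-margin classifier with sigmoid-calibrated posteriors turns the vector
into the sensor-source BBA.

Feature layout (fixed order, 127 components):

====================================  =====  ==============================
block                                 count  notes
====================================  =====  ==============================
per-channel mean                          6  channel order ax ay az gx gy gz
per-channel standard deviation            6
per-channel range (max − min)             6
per-channel root mean square              6
per-channel AR coefficients (order 6)    36  Burg estimate on the demeaned
                                             channel; constant channel → 0
per-channel binned distribution          60  10 equal-width bins over the
                                             channel's min–max, normalized;
                                             degenerate channel → bin 1
accelerometer pairwise correlations       3  (ax,ay) (ax,az) (ay,az); a
                                             zero-variance channel → 0
signal magnitude area                     1  (Σ|ax|+Σ|ay|+Σ|az|)/N
GPS speed, latitude, longitude            3  carried forward when missing
====================================  =====  ==============================
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.regression.linear_model import burg

from adlfuse.dsmt import BBA, make_bayesian_bba
from adlfuse.frame import Frame

logger = logging.getLogger(__name__)

CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
IMU_RATE = 90.0  # Hz
WINDOW_SECONDS = 3.0
WINDOW_SAMPLES = round(WINDOW_SECONDS * IMU_RATE)  # 270
AR_ORDER = 6
N_BINS = 10
N_FEATURES = 127

#: Default (C, gamma) cross-validation grid for the RBF classifier; spans the
#: optima reported for comparable activity datasets, (16, 0.33) and
#: (5.29, 0.57), on a logarithmic lattice.
DEFAULT_GRID = {
    "svc__C": [1.0, 4.0, 16.0, 64.0],
    "svc__gamma": [0.005, 0.02, 0.08, 0.33, 0.57],
}


def feature_names() -> list[str]:
    """The 127 feature names, in extraction order."""
    names: list[str] = []
    names += [f"mean_{c}" for c in CHANNELS]
    names += [f"std_{c}" for c in CHANNELS]
    names += [f"range_{c}" for c in CHANNELS]
    names += [f"rms_{c}" for c in CHANNELS]
    for c in CHANNELS:
        names += [f"ar{i + 1}_{c}" for i in range(AR_ORDER)]
    for c in CHANNELS:
        names += [f"bin{i + 1}_{c}" for i in range(N_BINS)]
    names += ["corr_ax_ay", "corr_ax_az", "corr_ay_az", "sma"]
    names += ["gps_speed", "gps_lat", "gps_lon"]
    assert len(names) == N_FEATURES
    return names


FEATURE_NAMES = feature_names()


@dataclass
class GpsFix:
    """One GPS sample: time (epoch s), position (deg) and speed (m/s)."""

    time: float
    lat: float
    lon: float
    speed: float

    def __post_init__(self) -> None:
        if not -90 <= self.lat <= 90:
            raise ValueError("latitude out of range")
        if not -180 <= self.lon <= 180:
            raise ValueError("longitude out of range")
        if self.speed < 0:
            raise ValueError("negative speed")


@dataclass
class ImuWindow:
    """One 3-s, 6-channel inertial segment centered on an image timestamp."""

    data: np.ndarray  # shape (6, WINDOW_SAMPLES)
    center_time: float
    padded: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(CHANNELS), WINDOW_SAMPLES):
            raise ValueError(
                f"window must be {len(CHANNELS)}×{WINDOW_SAMPLES}, got {self.data.shape}"
            )


def window_stream(
    imu: pd.DataFrame,
    image_times: np.ndarray,
    rate: float = IMU_RATE,
) -> tuple[list[ImuWindow], list[float]]:
    """Cut an IMU stream into windows centered on image timestamps.

    ``imu`` needs a monotone ``time`` column (epoch seconds) plus the six
    channel columns.  A window is emitted for every image timestamp that has
    at least one sample within ±1.5 s; windows short of the expected 270
    samples are padded by edge replication and flagged.  Timestamps with no
    nearby samples are skipped (returned separately).
    """
    t = imu["time"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("IMU timestamps must be monotone")
    sig = imu[list(CHANNELS)].to_numpy(dtype=float).T  # (6, n)
    half = WINDOW_SECONDS / 2
    n_expect = round(WINDOW_SECONDS * rate)
    windows: list[ImuWindow] = []
    skipped: list[float] = []
    for ts in np.asarray(image_times, dtype=float):
        lo, hi = np.searchsorted(t, (ts - half, ts + half))
        n = hi - lo
        if n == 0:
            logger.warning("no IMU samples within ±%.1f s of %.3f; skipping", half, ts)
            skipped.append(float(ts))
            continue
        chunk = sig[:, lo:hi]
        if n >= n_expect:
            chunk = chunk[:, :n_expect]
            padded = False
        else:
            # short window: pad by edge replication and flag it
            chunk = _edge_pad(chunk, n_expect, t[lo] > ts - half)
            padded = True
        windows.append(ImuWindow(chunk, float(ts), padded=padded))
    return windows, skipped


def _edge_pad(chunk: np.ndarray, n_expect: int, pad_left: bool) -> np.ndarray:
    miss = n_expect - chunk.shape[1]
    if pad_left:
        return np.pad(chunk, ((0, 0), (miss, 0)), mode="edge")
    return np.pad(chunk, ((0, 0), (0, miss)), mode="edge")


# ---------------------------------------------------------------------------
# Feature extraction


def _ar_coefficients(x: np.ndarray) -> np.ndarray:
    if np.std(x) < 1e-12:
        return np.zeros(AR_ORDER)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        coeffs, _ = burg(x, order=AR_ORDER, demean=True)
    if not np.all(np.isfinite(coeffs)):
        return np.zeros(AR_ORDER)
    return np.asarray(coeffs)


def _binned_distribution(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        out = np.zeros(N_BINS)
        out[0] = 1.0  # degenerate channel: all mass in bin 1
        return out
    counts, _ = np.histogram(x, bins=N_BINS, range=(lo, hi))
    return counts / x.size


def extract_features(
    window: ImuWindow,
    gps: GpsFix | None = None,
    last_gps: GpsFix | None = None,
) -> np.ndarray:
    """127-dimensional descriptor of one window (layout in module docstring).

    GPS carry-forward: if no fix accompanies the window the most recent one
    is used; with neither, the three GPS components are zero.
    """
    d = window.data
    feats: list[float] = []
    feats += d.mean(axis=1).tolist()
    feats += d.std(axis=1).tolist()
    feats += (d.max(axis=1) - d.min(axis=1)).tolist()
    feats += np.sqrt((d**2).mean(axis=1)).tolist()
    for ch in d:
        feats += _ar_coefficients(ch).tolist()
    for ch in d:
        feats += _binned_distribution(ch).tolist()
    for i, j in ((0, 1), (0, 2), (1, 2)):
        si, sj = d[i].std(), d[j].std()
        if si < 1e-12 or sj < 1e-12:
            feats.append(0.0)  # correlation of a constant channel := 0
        else:
            feats.append(float(np.corrcoef(d[i], d[j])[0, 1]))
    feats.append(float(np.abs(d[:3]).sum() / d.shape[1]))  # SMA, accel only
    fix = gps if gps is not None else last_gps
    if fix is None:
        feats += [0.0, 0.0, 0.0]
    else:
        feats += [fix.speed, fix.lat, fix.lon]
    out = np.asarray(feats)
    assert out.shape == (N_FEATURES,)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value")
    return out


# ---------------------------------------------------------------------------
# Classifier


@dataclass
class SensorModel:
    """Fitted RBF max-margin classifier with sigmoid posterior calibration."""

    pipeline: Pipeline
    classes: tuple[str, ...]
    c: float
    gamma: float
    cv_score: float
    seed: int = 0

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features, got {features.shape[1]}")
        return self.pipeline.predict_proba(features)


def train_sensor_model(
    features: np.ndarray,
    labels: np.ndarray,
    grid: dict | None = None,
    *,
    cv: int = 5,
    seed: int = 0,
) -> SensorModel:
    """Cross-validated (C, γ) selection, then a calibrated one-against-one fit.

    Features are standardized with training statistics before the kernel.
    Hyper-parameters are chosen by stratified k-fold accuracy over the grid;
    the winning pair is refitted with per-pair sigmoid probability
    calibration.  Deterministic for a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples")
    grid = grid if grid is not None else DEFAULT_GRID
    n_folds = min(cv, int(counts.min()))
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
    )
    search = GridSearchCV(
        pipe,
        grid,
        cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X, y)
    best_c = float(search.best_params_["svc__C"])
    best_g = float(search.best_params_["svc__gamma"])
    final = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                CalibratedClassifierCV(
                    SVC(kernel="rbf", C=best_c, gamma=best_g, random_state=seed),
                    method="sigmoid",
                    cv=StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed),
                    ensemble=False,
                ),
            ),
        ]
    )
    final.fit(X, y)
    logger.info(
        "sensor model: C=%g gamma=%g cv-accuracy=%.3f", best_c, best_g, search.best_score_
    )
    return SensorModel(
        pipeline=final,
        classes=tuple(str(c) for c in final.named_steps["svc"].classes_),
        c=best_c,
        gamma=best_g,
        cv_score=float(search.best_score_),
        seed=seed,
    )


def sensor_bba(model: SensorModel, features: np.ndarray, frame: Frame) -> BBA:
    """Calibrated posteriors as a Bayesian BBA on the frame.

    Frame labels the model was not trained on receive zero mass.
    """
    unknown = [c for c in model.classes if c not in frame]
    if unknown:
        raise ValueError(f"model classes not in frame: {unknown}")
    proba = model.predict_proba(features)[0]
    weights = np.zeros(len(frame))
    for c, p in zip(model.classes, proba):
        weights[frame.index(c)] = p
    return make_bayesian_bba(frame, weights)
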