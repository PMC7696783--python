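"""Cycle-window feature extraction for thermal-cycled sensor recordings.

The analyzer's informative signal is the heating transient between the
cooling-to-heating and heating-to-cooling turning points of each thermal
cycle.  The pipeline locates those turning points, cuts one 175-sample
window per cycle (3.5 s at 50 Hz), averages windows across the ~9 cycles of
a recording, keeps every 10th sample (17 values per sensor) and concatenates
sensors, yielding a 238-value vector per subject for the 14-sensor default.
An optional per-feature min-max scaler maps features into [-1, 1], the
operating range of the tanh network downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError, ShapeError, SignalStructureError
from .simulate import SensorRecording

AGGREGATIONS = ("mean", "first-cycle")
NORMALIZATIONS = ("none", "per-sensor-scale")


@dataclass
class PreprocessConfig:
    """Windowing, decimation and scaling choices for featurization."""

    window_samples: int = 175
    decimation_step: int = 10
    cycle_aggregation: str = "mean"
    normalization: str = "per-sensor-scale"
    expected_sensors: int = 14
    cycle_period_hint_s: float = 10.0

    @property
    def features_per_sensor(self) -> int:
        # 175 samples at step 10 keep 17 values (indices 0, 10, ..., 160):
        # floor division, matching the instrument's printed 175 -> 17.
        return max(1, self.window_samples // self.decimation_step)

    @property
    def n_features(self) -> int:
        return self.expected_sensors * self.features_per_sensor

    def validate(self) -> None:
        if self.window_samples < 1:
            raise ParameterError("window_samples must be >= 1")
        if self.decimation_step < 1:
            raise ParameterError("decimation_step must be >= 1")
        if self.expected_sensors < 1:
            raise ParameterError("expected_sensors must be >= 1")
        if self.cycle_period_hint_s <= 0:
            raise ParameterError("cycle_period_hint_s must be > 0")
        if self.cycle_aggregation not in AGGREGATIONS:
            raise ParameterError(
                f"cycle_aggregation must be one of {AGGREGATIONS}")
        if self.normalization not in NORMALIZATIONS:
            raise ParameterError(
                f"normalization must be one of {NORMALIZATIONS}")


@dataclass
class FeatureVector:
    """A subject's decimated cycle features, sensor-major order."""

    subject_id: str
    label: str
    values: np.ndarray


def detect_cycle_starts(recording: SensorRecording,
                        cycle_period_hint: float) -> np.ndarray:
    """Locate cooling-to-heating turning points (cycle starts).

    The channel-mean trace is folded at the hinted period and averaged
    across cycles; the within-cycle minimum of the folded profile gives the
    common phase of the turning points, and starts are laid out one period
    apart from that phase.  Folding averages away sample noise that would
    otherwise let a per-cycle argmin wander along the nearly flat cooling
    tail.
    """
    if cycle_period_hint <= 0:
        raise ParameterError("cycle_period_hint must be > 0")
    period = int(round(cycle_period_hint * recording.sampling_rate))
    n = recording.n_timepoints
    if n < period or n == 0:
        raise SignalStructureError(
            f"recording of {n} samples is shorter than one cycle "
            f"({period} samples)")
    trace = recording.samples.mean(axis=0)
    n_full = n // period
    folded = trace[: n_full * period].reshape(n_full, period).mean(axis=0)
    phase = int(np.argmin(folded))
    starts = np.arange(phase, n, period)
    if starts.size < 1:
        raise SignalStructureError("no cycle start detected")
    return starts


def extract_windows(recording: SensorRecording, starts: Sequence[int],
                    config: PreprocessConfig) -> np.ndarray:
    """Cut one window per retained cycle; trailing incomplete cycles drop.

    Returns an array of shape (n_windows, n_sensors, window_samples) copied
    verbatim from the recording.
    """
    W = config.window_samples
    n = recording.n_timepoints
    kept = [int(s) for s in starts if s + W <= n]
    if not kept:
        raise SignalStructureError(
            f"no complete {W}-sample window fits in {n} samples at the "
            "detected cycle starts")
    return np.stack([recording.samples[:, s:s + W].copy() for s in kept])


def aggregate_cycles(windows: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return windows.mean(axis=0)
    if mode == "first-cycle":
        return windows[0]
    raise ParameterError(f"unknown cycle_aggregation {mode!r}")


def featurize(recording: SensorRecording, config: PreprocessConfig,
              normalizer: "FeatureScaler | None" = None) -> FeatureVector:
    """Full per-subject featurization: detect, window, aggregate, decimate.

    ``normalizer`` must already be fitted (on training subjects only); when
    omitted, or when ``config.normalization == "none"``, raw decimated ADC
    values are returned.
    """
    config.validate()
    if recording.n_sensors != config.expected_sensors:
        raise ShapeError(
            f"recording has {recording.n_sensors} channels, expected "
            f"{config.expected_sensors}")
    starts = detect_cycle_starts(recording, config.cycle_period_hint_s)
    windows = extract_windows(recording, starts, config)
    agg = aggregate_cycles(windows, config.cycle_aggregation)
    idx = config.decimation_step * np.arange(config.features_per_sensor)
    decimated = agg[:, idx]  # (sensors, features_per_sensor)
    values = decimated.reshape(-1)
    if normalizer is not None and config.normalization == "per-sensor-scale":
        values = normalizer.transform(values[None, :])[0]
    return FeatureVector(subject_id=recording.subject_id,
                         label=recording.label, values=values)


class CycleFeaturizer(BaseEstimator, TransformerMixin):
    """Stateless transformer from recordings to the decimated feature matrix.

    ``transform`` accepts a list of :class:`SensorRecording` (or
    :class:`SubjectRecord`) and returns an (n_subjects, n_features) array.
    Scaling is handled separately by :class:`FeatureScaler` so that
    cohort-level statistics can be fitted on training folds only.
    """

    def __init__(self, window_samples: int = 175, decimation_step: int = 10,
                 cycle_aggregation: str = "mean", expected_sensors: int = 14,
                 cycle_period_hint_s: float = 10.0):
        self.window_samples = window_samples
        self.decimation_step = decimation_step
        self.cycle_aggregation = cycle_aggregation
        self.expected_sensors = expected_sensors
        self.cycle_period_hint_s = cycle_period_hint_s

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            window_samples=self.window_samples,
            decimation_step=self.decimation_step,
            cycle_aggregation=self.cycle_aggregation,
            normalization="none",
            expected_sensors=self.expected_sensors,
            cycle_period_hint_s=self.cycle_period_hint_s)

    def fit(self, X, y=None):
        self._config().validate()
        self.n_features_out_ = self._config().n_features
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        rows = []
        for item in X:
            rec = getattr(item, "recording", item)
            rows.append(featurize(rec, cfg).values)
        return np.stack(rows)


class FeatureScaler(BaseEstimator, TransformerMixin):
    """Min-max scaling of each feature to [-1, 1], clamped on unseen data.

    Statistics are per feature (each sensor's 17 decimated values get their
    own min/max across the fitted cohort).  A zero-range feature maps to 0
    regardless of input, with a warning at fit time.
    """

    def fit(self, X: np.ndarray, y=None) -> "FeatureScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ShapeError("FeatureScaler.fit expects a non-empty 2-D array")
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.range_ = self.data_max_ - self.data_min_
        self.n_features_in_ = X.shape[1]
        n_degenerate = int(np.sum(self.range_ == 0))
        if n_degenerate:
            warnings.warn(
                f"{n_degenerate} feature(s) have zero range in the training "
                "cohort; they will map to 0", UserWarning, stacklevel=2)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ShapeError(
                f"expected shape (*, {self.n_features_in_}), got {X.shape}")
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = 2.0 * (X - self.data_min_) / self.range_ - 1.0
        scaled = np.where(self.range_ == 0, 0.0, scaled)
        return np.clip(scaled, -1.0, 1.0)


def fit_normalizer(features_train: Sequence[FeatureVector]) -> FeatureScaler:
    """Fit the [-1, 1] scaler on training-fold feature vectors only."""
    if len(features_train) == 0:
        raise ParameterError("fit_normalizer requires a non-empty training set")
    X = np.stack([fv.values for fv in features_train])
    return FeatureScaler().fit(X)
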