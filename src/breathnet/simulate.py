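"""Synthetic thermal-cycled MOS sensor-array breath recordings.

A metal-oxide-semiconductor (MOS) gas sensor operated under cyclic heating
produces a periodic transient: a fast resistance excursion while the heater
ramps, followed by a relaxation while it cools.  The simulator emulates a
14-sensor analyzer sampling at 50 Hz for 90 s, so that each recording holds
about nine 10-second thermal cycles and each 3.5-second heating segment spans
exactly 175 samples.

Volatile-metabolite differences between classes are modelled as per-sensor
additive amplitude offsets expressed only inside the heating window (where
temperature-modulated MOS selectivity lives), on top of per-sensor baselines,
i.i.d. Gaussian sample noise and a per-cycle random-walk drift.  Subject
metadata (age, sex, tumor localization, stage) is generated for realism but
is never fed to the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .exceptions import EmptyCohortError, ParameterError

HEALTHY = "healthy"
CANCER = "cancer"
LABELS = (HEALTHY, CANCER)

#: Tumor localizations with cohort proportions mirroring a head-and-neck +
#: lung screening population (lungs dominate, single-digit counts elsewhere).
_LOCALIZATIONS = ("lungs", "larynx", "oral cavity", "oropharynx",
                  "hypopharynx", "tongue", "lower jaw mucosa")
_LOCALIZATION_P = np.array([21, 9, 5, 7, 1, 6, 3], dtype=float) / 52.0
_STAGES = ("I", "II", "III", "IV")
_STAGE_P = np.array([8, 23, 15, 6], dtype=float) / 52.0

_DEFAULT_CLASS_EFFECT_14 = np.array(
    [6.0, -4.0, 8.0, 0.0, 5.0, -3.0, 7.0, 2.0, -5.0, 4.0, 0.0, 6.0, -4.0, 3.0]
)


def _default_baseline(n_sensors: int) -> np.ndarray:
    return 400.0 + 40.0 * np.arange(n_sensors, dtype=float)


def _default_amplitude(n_sensors: int) -> np.ndarray:
    return 150.0 + 10.0 * np.arange(n_sensors, dtype=float)


def _default_class_effect(n_sensors: int) -> np.ndarray:
    return np.resize(_DEFAULT_CLASS_EFFECT_14, n_sensors).astype(float)


@dataclass
class SimulatorParams:
    """Geometry, amplitudes and noise levels of the simulated analyzer.

    Defaults reproduce the measurement cadence of the hardware being
    emulated: 14 sensors, 50 Hz for 90 s (4500 samples), 10 s thermal cycles
    (9 per recording) with a 3.5 s heating window (175 samples).
    """

    n_sensors: int = 14
    sampling_rate: float = 50.0
    duration: float = 90.0
    cycle_period: float = 10.0
    heat_window: float = 3.5
    cooling_tau: float = 2.0
    baseline_per_sensor: Optional[np.ndarray] = None
    amplitude_per_sensor: Optional[np.ndarray] = None
    class_effect: Optional[np.ndarray] = None
    effect_scale: float = 1.0
    noise_sd: float = 5.0
    drift_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_per_sensor is None:
            self.baseline_per_sensor = _default_baseline(self.n_sensors)
        if self.amplitude_per_sensor is None:
            self.amplitude_per_sensor = _default_amplitude(self.n_sensors)
        if self.class_effect is None:
            self.class_effect = _default_class_effect(self.n_sensors)
        self.baseline_per_sensor = np.asarray(self.baseline_per_sensor, float)
        self.amplitude_per_sensor = np.asarray(self.amplitude_per_sensor, float)
        self.class_effect = np.asarray(self.class_effect, float)

    # -- derived geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.duration))

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.sampling_rate * self.cycle_period))

    @property
    def heat_samples(self) -> int:
        return int(round(self.sampling_rate * self.heat_window))

    @property
    def n_cycles(self) -> int:
        return self.n_samples // self.samples_per_cycle

    def validate(self) -> None:
        """Raise :class:`ParameterError` naming the violated invariant."""
        if self.n_sensors < 1:
            raise ParameterError("n_sensors must be >= 1")
        total = self.sampling_rate * self.duration
        if abs(total - round(total)) > 1e-9 or total < 1:
            raise ParameterError(
                "sampling_rate * duration must be a positive integer "
                f"number of samples, got {total}")
        if self.duration / self.cycle_period < 1:
            raise ParameterError(
                "duration / cycle_period must be >= 1 (at least one cycle)")
        if not self.heat_window < self.cycle_period:
            raise ParameterError("heat_window must be < cycle_period")
        heat = self.sampling_rate * self.heat_window
        if abs(heat - round(heat)) > 1e-9 or heat < 2:
            raise ParameterError(
                "heat_window * sampling_rate must be an integer >= 2, "
                f"got {heat}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.drift_sd < 0:
            raise ParameterError("drift_sd must be >= 0")
        if self.cooling_tau <= 0:
            raise ParameterError("cooling_tau must be > 0")
        for name in ("baseline_per_sensor", "amplitude_per_sensor",
                     "class_effect"):
            arr = getattr(self, name)
            if arr.shape != (self.n_sensors,):
                raise ParameterError(
                    f"{name} must have length n_sensors={self.n_sensors}, "
                    f"got shape {arr.shape}")


@dataclass
class SensorRecording:
    """One subject's raw multi-channel ADC time series."""

    subject_id: str
    label: str
    samples: np.ndarray  # (n_sensors, n_timepoints), ADC counts
    sampling_rate: float

    @property
    def n_sensors(self) -> int:
        return self.samples.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.samples.shape[1]


@dataclass
class SubjectRecord:
    """A recording plus the subject metadata stored beside it on disk.

    Metadata is carried for provenance only; the classifier never sees it.
    """

    subject_id: str
    label: str
    metadata: dict
    recording: SensorRecording


def cycle_template(params: SimulatorParams) -> np.ndarray:
    """Noise-free single-cycle waveform, shape (n_sensors, samples_per_cycle).

    A linear heating ramp from baseline to baseline + amplitude over the
    heating window, then exponential relaxation back towards baseline with
    time constant ``cooling_tau``.  The unique within-cycle minimum sits at
    sample 0 — the cooling-to-heating turning point.
    """
    P, H = params.samples_per_cycle, params.heat_samples
    k = np.arange(P, dtype=float)
    elev = np.empty(P)
    elev[:H] = k[:H] / (H - 1)
    elev[H:] = np.exp(-((k[H:] - (H - 1)) / params.sampling_rate)
                      / params.cooling_tau)
    return (params.baseline_per_sensor[:, None]
            + params.amplitude_per_sensor[:, None] * elev[None, :])


def heating_mask(params: SimulatorParams) -> np.ndarray:
    """Boolean mask over timepoints: True inside heating windows."""
    idx = np.arange(params.n_samples)
    return (idx % params.samples_per_cycle) < params.heat_samples


def simulate_recording(params: SimulatorParams, label: str,
                       subject_seed: int) -> SensorRecording:
    """Simulate one subject's recording, deterministic in all arguments.

    The noise and drift streams do not depend on ``label``, so recordings of
    the two classes under the same seed differ only by the class effect.
    """
    params.validate()
    if label not in LABELS:
        raise ParameterError(f"label must be one of {LABELS}, got {label!r}")
    rng = np.random.default_rng(subject_seed)
    n, P = params.n_samples, params.samples_per_cycle
    n_cycles_total = math.ceil(n / P)

    template = cycle_template(params)
    trace = np.tile(template, n_cycles_total)[:, :n]

    # Random-walk drift: constant within a cycle, Gaussian steps between.
    steps = rng.normal(0.0, params.drift_sd,
                       size=(n_cycles_total, params.n_sensors))
    drift = np.cumsum(steps, axis=0)
    trace = trace + np.repeat(drift, P, axis=0)[:n].T
    trace = trace + rng.normal(0.0, params.noise_sd, size=(params.n_sensors, n))

    if label == CANCER:
        effect = params.class_effect * params.effect_scale
        trace[:, heating_mask(params)] += effect[:, None]

    return SensorRecording(subject_id="", label=label,
                           samples=trace, sampling_rate=params.sampling_rate)


def _subject_seed(seed: int, index: int) -> int:
    state = np.random.SeedSequence([int(seed), int(index)]).generate_state(1)
    return int(state[0]) % (2 ** 31)


def _draw_metadata(rng: np.random.Generator, label: str) -> dict:
    if label == CANCER:
        age = int(np.clip(round(rng.normal(60, 10)), 22, 95))
        sex = "M" if rng.random() < 0.827 else "F"
        localization = str(rng.choice(_LOCALIZATIONS, p=_LOCALIZATION_P))
        stage = str(rng.choice(_STAGES, p=_STAGE_P))
    else:
        age = int(np.clip(round(rng.normal(50, 12)), 22, 95))
        sex = "M" if rng.random() < 0.203 else "F"
        localization = None
        stage = None
    return {"age": age, "sex": sex, "localization": localization,
            "stage": stage}


def simulate_cohort(params: SimulatorParams, n_healthy: int, n_cancer: int,
                    seed: int) -> list[SubjectRecord]:
    """Simulate a labelled cohort with deterministic per-subject seeds.

    Subject ``i`` (0-based over healthy then cancer) draws its signal seed
    from ``SeedSequence([seed, i])``, so enlarging a cohort never reshuffles
    the subjects already generated.
    """
    if n_healthy < 0 or n_cancer < 0:
        raise ParameterError("cohort counts must be non-negative")
    if n_healthy + n_cancer < 1:
        raise EmptyCohortError("cohort must contain at least one subject")
    params.validate()

    records: list[SubjectRecord] = []
    labels = [HEALTHY] * n_healthy + [CANCER] * n_cancer
    for i, label in enumerate(labels):
        sid = f"subj{i + 1:03d}"
        rec = simulate_recording(params, label, _subject_seed(seed, i))
        rec.subject_id = sid
        meta_rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), int(i), 1]))
        meta = _draw_metadata(meta_rng, label)
        records.append(SubjectRecord(subject_id=sid, label=label,
                                     metadata=meta, recording=rec))
    return records
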