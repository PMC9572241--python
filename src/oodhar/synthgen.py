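"""Synthetic multi-domain accelerometer corpus generation.

Real wearable-sensor activity corpora differ along three nested levels:
datasets (device placement and calibration conventions), subjects (gait
cadence and vigour), and devices (noise floors, bias).  This module
generates triaxial accelerometer recordings with the same nested
structure and *controllable* shift magnitudes at each level, so the
downstream domain-generalization machinery can be exercised end to end
without any external downloads.

The waveform families are deliberately minimal: quasi-sinusoidal signals
with harmonics and amplitude modulation for the dynamic activities
(walk, run, stairs) and a gravity projection plus postural sway and
tremor for the static ones (sit, stand).  They are not biomechanical
models; they exist to make the five classes separable by both spectral
and statistical descriptors while keeping every domain-shift knob
explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

GRAVITY = 9.81  # m/s^2; accelerometers at rest measure the gravity vector

CANONICAL_ACTIVITIES = ("walk", "run", "sit", "stand", "stairs")

#: Per-activity waveform traits beyond the ActivityModel fields:
#: second-harmonic weight, amplitude-modulation depth and frequency (Hz),
#: anterior-posterior / medio-lateral amplitude ratios, and the
#: heel-strike impulse train as (cycle phase, relative amplitude,
#: von-Mises sharpness) tuples.  Walking shows two moderate impacts per
#: cycle (one per foot), running two strong ones, stair climbing a
#: single dominant strike — a shape cue that survives cadence overlap.
_WAVEFORM = {
    "walk":   dict(h2=0.35, mod_depth=0.10, mod_freq=0.20, ap=0.50, ml=0.25,
                   impulses=((0.0, 0.8, 12.0), (np.pi, 0.6, 12.0))),
    "run":    dict(h2=0.45, mod_depth=0.15, mod_freq=0.25, ap=0.55, ml=0.30,
                   impulses=((0.0, 1.5, 16.0), (np.pi, 1.2, 16.0))),
    "stairs": dict(h2=0.30, mod_depth=0.55, mod_freq=0.35, ap=0.45, ml=0.25,
                   impulses=((0.8, 1.8, 20.0),)),
    "sit":    dict(sway_freq=0.10),
    "stand":  dict(sway_freq=0.25),
}


class ConfigurationError(ValueError):
    """Raised for invalid generator or registry configuration."""


@dataclass(frozen=True)
class ActivityModel:
    """Parametric signal model for one activity class.

    ``base_frequency`` is the fundamental cadence in Hz (0 for the static
    activities), ``base_amplitude`` the dynamic (or sway) amplitude in
    m/s^2, ``gravity_axis_weights`` the unit body-frame direction of the
    gravity component, and ``noise_floor`` the standard deviation of the
    activity's intrinsic tremor/impact noise in m/s^2.
    """

    activity: str
    base_frequency: float
    base_amplitude: float
    gravity_axis_weights: tuple[float, float, float] = (0.0, 0.0, 1.0)
    noise_floor: float = 0.0

    def __post_init__(self):
        if self.activity not in CANONICAL_ACTIVITIES:
            raise ConfigurationError(f"unknown activity {self.activity!r}")
        dynamic = self.activity in ("walk", "run", "stairs")
        if dynamic and not self.base_frequency > 0:
            raise ConfigurationError(
                f"{self.activity} requires base_frequency > 0"
            )
        if not dynamic and self.base_frequency != 0:
            raise ConfigurationError(
                f"{self.activity} is static and requires base_frequency = 0"
            )
        w = np.asarray(self.gravity_axis_weights, dtype=float)
        if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-8):
            raise ConfigurationError("gravity_axis_weights must be unit norm")


def default_activity_models() -> dict[str, ActivityModel]:
    """The stock five-class model set.

    Cadences and amplitudes sit in the ranges typical of waist/chest-worn
    accelerometry: walking near 2 Hz, running near 3 Hz with much larger
    dynamic amplitude, stair climbing slower than level walking with a
    strongly modulated envelope, sitting as a reclined low-tremor posture
    and standing as an upright posture with slow postural sway.
    """
    return {
        "walk": ActivityModel("walk", 2.0, 3.0, (0.0, 0.0, 1.0), 0.40),
        "run": ActivityModel("run", 2.8, 7.0, (0.0, 0.0, 1.0), 0.60),
        "stairs": ActivityModel("stairs", 1.8, 3.3, (0.0, 0.0, 1.0), 0.45),
        "sit": ActivityModel("sit", 0.0, 0.06, (0.0, 0.17364817766693, 0.984807753012208), 0.04),
        "stand": ActivityModel("stand", 0.0, 0.35, (0.0, 0.0, 1.0), 0.12),
    }


@dataclass(frozen=True)
class DomainParams:
    """One (dataset, subject, device) domain.

    ``orientation`` rotates the body frame into the sensor frame and is
    the dataset/position effect; ``calibration_offset`` (m/s^2) and
    ``device_noise_sd`` (m/s^2) are device effects; the dimensionless
    ``subject_freq_scale`` / ``subject_amp_scale`` multiply each
    activity's cadence and amplitude and are the subject (gait) effect.
    """

    dataset_id: str
    subject_id: str
    native_rate: float
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    device_noise_sd: float = 0.0
    calibration_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    subject_freq_scale: float = 1.0
    subject_amp_scale: float = 1.0
    #: expected motion artifacts (brief high-amplitude spikes) per second
    artifact_rate: float = 0.0
    rate_tolerance: float = 0.05

    def __post_init__(self):
        R = np.asarray(self.orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ConfigurationError("orientation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ConfigurationError("orientation must be a proper rotation (det +1)")
        if self.native_rate < 50.0 * (1.0 - self.rate_tolerance):
            raise ConfigurationError(
                f"native_rate {self.native_rate} Hz below the 50 Hz selection criterion"
            )
        object.__setattr__(self, "orientation", R)


@dataclass
class Recording:
    """One subject's continuous labelled triaxial stream from one dataset.

    ``samples`` is [n_samples x n_channels] in m/s^2 (3 channels as
    generated; 4 after the magnitude channel is appended downstream) and
    ``labels`` holds one activity label per sample.
    """

    samples: np.ndarray
    rate: float
    labels: np.ndarray
    subject_id: str
    dataset_id: str

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D [n_samples x channels] array")
        if len(self.labels) != len(self.samples):
            raise ValueError("labels must align with samples")

    def __len__(self) -> int:
        return len(self.samples)


def _slow_drift(rng: np.random.Generator, t: np.ndarray, sd: float,
                knot_seconds: float = 2.0) -> np.ndarray:
    """Smooth zero-mean drift: linear interpolation between random knots.

    Emulates the minute-scale wander of cadence and vigour seen in real
    recordings, so consecutive windows of one recording are correlated
    but not near-identical."""
    if len(t) == 0 or sd == 0:
        return np.zeros_like(t)
    span = t[-1] if t[-1] > 0 else 1.0
    n_knots = max(int(span / knot_seconds) + 2, 2)
    knot_t = np.linspace(0.0, span, n_knots)
    return np.interp(t, knot_t, rng.normal(0.0, sd, size=n_knots))


def _dynamic_body_signal(model: ActivityModel, scale_f: float, scale_a: float,
                         t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    traits = _WAVEFORM[model.activity]
    f = model.base_frequency * scale_f
    a = model.base_amplitude * scale_a
    phase = rng.uniform(0, 2 * np.pi)
    # cadence wander: instantaneous frequency f*(1+w), integrated to a phase
    wander = _slow_drift(rng, t, 0.03, knot_seconds=3.0)
    dt = np.diff(t, prepend=0.0)
    ph = 2 * np.pi * np.cumsum(f * (1.0 + wander) * dt) + phase
    env = 1.0 + traits["mod_depth"] * np.sin(2 * np.pi * traits["mod_freq"] * t + rng.uniform(0, 2 * np.pi))
    env *= 1.0 + _slow_drift(rng, t, 0.08)
    vertical = a * env * (np.sin(ph) + traits["h2"] * np.sin(2 * ph + 0.4))
    # heel-strike impacts: periodic von-Mises bumps locked to the gait phase
    for phi, rel_amp, kappa in traits["impulses"]:
        vertical += a * env * rel_amp * np.exp(kappa * (np.cos(ph - phi) - 1.0))
    ap = traits["ap"] * a * env * np.sin(ph + np.pi / 2)
    ml = traits["ml"] * a * env * np.sin(0.5 * ph + rng.uniform(0, 2 * np.pi))
    body = np.column_stack([ml, ap, vertical])
    body += GRAVITY * np.asarray(model.gravity_axis_weights)
    return body


def _static_body_signal(model: ActivityModel, scale_a: float,
                        t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    traits = _WAVEFORM[model.activity]
    a = model.base_amplitude * scale_a
    env = 1.0 + _slow_drift(rng, t, 0.15, knot_seconds=4.0)
    sway = env[:, None] * np.column_stack([
        0.6 * a * np.sin(2 * np.pi * traits["sway_freq"] * t + rng.uniform(0, 2 * np.pi)),
        a * np.sin(2 * np.pi * traits["sway_freq"] * t + rng.uniform(0, 2 * np.pi)),
        0.3 * a * np.sin(4 * np.pi * traits["sway_freq"] * t + rng.uniform(0, 2 * np.pi)),
    ])
    return sway + GRAVITY * np.asarray(model.gravity_axis_weights)


def generate_recording(activity_model: ActivityModel, domain: DomainParams,
                       duration: float, seed: int) -> Recording:
    """Generate one constant-activity recording in the sensor frame.

    The body-frame waveform is rotated by the domain orientation, the
    calibration offset is added, and activity tremor plus device noise
    are superimposed.  The seed fixes all randomness (phases and noise).
    """
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * domain.native_rate))
    t = np.arange(n) / domain.native_rate
    if activity_model.base_frequency > 0:
        body = _dynamic_body_signal(
            activity_model, domain.subject_freq_scale, domain.subject_amp_scale, t, rng)
    else:
        body = _static_body_signal(activity_model, domain.subject_amp_scale, t, rng)
    sensor = body @ domain.orientation.T
    sensor = sensor + np.asarray(domain.calibration_offset, dtype=float)
    if activity_model.noise_floor > 0:
        sensor = sensor + rng.normal(0.0, activity_model.noise_floor, size=sensor.shape)
    if domain.device_noise_sd > 0:
        sensor = sensor + rng.normal(0.0, domain.device_noise_sd, size=sensor.shape)
    if domain.artifact_rate > 0:
        # motion artifacts: rare 1-3-sample spikes on one axis (strap
        # slip, impact); they corrupt window-level summary statistics far
        # more than the local waveform shape
        for _ in range(rng.poisson(domain.artifact_rate * duration)):
            t0 = int(rng.integers(0, max(n - 2, 1)))
            width = int(rng.integers(1, 3))
            axis = int(rng.integers(0, 3))
            amp = rng.choice([-1.0, 1.0]) * rng.uniform(20.0, 50.0)
            sensor[t0:t0 + width, axis] += amp
    labels = np.full(n, activity_model.activity, dtype=object)
    return Recording(sensor, domain.native_rate, labels,
                     domain.subject_id, domain.dataset_id)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Shape and shift magnitudes of a synthetic multi-dataset corpus.

    ``sigma_dataset`` scales the dataset-level orientation draw (rotation
    vector sd, radians) and calibration offset (m/s^2); ``sigma_subject``
    is the log-sd of the per-subject cadence/amplitude scales;
    ``sigma_device`` the sd of the per-subject device noise floor
    (m/s^2).  Native rates cycle through ``native_rates`` per dataset to
    exercise resampling.
    """

    dataset_names: tuple[str, ...] = ("DS1", "DS2", "DS3")
    n_subjects: int = 8
    activity_seconds: float = 120.0  # 24 five-second windows per activity
    #: each activity block is recorded as this many independent sessions
    #: (fresh phase and drift realizations), like separate lab visits
    sessions_per_activity: int = 3
    native_rates: tuple[float, ...] = (50.0, 100.0, 200.0)
    sigma_subject: float = 0.08
    sigma_device: float = 0.05
    sigma_dataset: float = 0.4
    base_device_noise: float = 0.03
    artifact_rate: float = 0.0  # motion-artifact spikes per second, Poisson
    activities: tuple[str, ...] = CANONICAL_ACTIVITIES

    def __post_init__(self):
        if len(self.dataset_names) < 2:
            raise ConfigurationError("need at least 2 datasets")
        if self.n_subjects < 2:
            raise ConfigurationError(
                "need at least 2 subjects per dataset (leave-user-out split impossible)")
        if self.n_subjects < 4:
            warnings.warn("fewer than 4 subjects per dataset; splits will be coarse")


def make_benchmark(config: BenchmarkConfig, seed: int,
                   activity_models: dict[str, ActivityModel] | None = None,
                   ) -> dict[str, list[Recording]]:
    """Generate the full corpus: one recording per (dataset, subject, activity).

    All subjects within a dataset share that dataset's orientation/offset
    draw; subject- and device-level parameters are drawn independently
    per subject.  Identical (config, seed) yields an identical corpus.
    """
    models = activity_models or default_activity_models()
    for a in config.activities:
        if a not in models:
            raise ConfigurationError(f"no activity model for {a!r}")
    root = np.random.SeedSequence(seed)
    dataset_seeds = root.spawn(len(config.dataset_names))
    corpus: dict[str, list[Recording]] = {}
    for d_idx, (ds_name, ds_ss) in enumerate(zip(config.dataset_names, dataset_seeds)):
        ds_rng = np.random.default_rng(ds_ss)
        rotvec = config.sigma_dataset * ds_rng.standard_normal(3)
        R = Rotation.from_rotvec(rotvec).as_matrix()
        offset = config.sigma_dataset * ds_rng.standard_normal(3)
        rate = config.native_rates[d_idx % len(config.native_rates)]
        subject_seeds = ds_ss.spawn(config.n_subjects)
        recs: list[Recording] = []
        for s_idx, s_ss in enumerate(subject_seeds):
            s_rng = np.random.default_rng(s_ss)
            # each subject wears the device slightly differently: a small
            # placement rotation on top of the dataset's orientation; kept
            # below the sit/stand postural tilt so statics stay separable
            jitter = Rotation.from_rotvec(
                0.5 * config.sigma_subject * s_rng.standard_normal(3)).as_matrix()
            domain = DomainParams(
                dataset_id=ds_name,
                subject_id=f"{ds_name}_s{s_idx:02d}",
                native_rate=rate,
                orientation=R @ jitter,
                device_noise_sd=config.base_device_noise + abs(s_rng.normal(0, config.sigma_device)),
                calibration_offset=tuple(offset),
                subject_freq_scale=float(np.exp(s_rng.normal(0, config.sigma_subject))),
                subject_amp_scale=float(np.exp(s_rng.normal(0, config.sigma_subject))),
                artifact_rate=config.artifact_rate,
            )
            n_sessions = max(1, config.sessions_per_activity)
            session_len = config.activity_seconds / n_sessions
            rec_seeds = s_rng.integers(0, 2**31 - 1,
                                       size=len(config.activities) * n_sessions)
            k = 0
            for act in config.activities:
                for _ in range(n_sessions):
                    recs.append(generate_recording(
                        models[act], domain, session_len, int(rec_seeds[k])))
                    k += 1
        corpus[ds_name] = recs
    return corpus


# ---------------------------------------------------------------------------
# Plain-text recording I/O: header lines + whitespace-separated columns.

def write_recording(recording: Recording, path) -> None:
    """Write one recording: ``# key: value`` header, then t ax ay az label rows."""
    with open(path, "w") as fh:
        fh.write(f"# dataset: {recording.dataset_id}\n")
        fh.write(f"# subject: {recording.subject_id}\n")
        fh.write(f"# rate: {recording.rate:.17g}\n")
        t = np.arange(len(recording)) / recording.rate
        for i in range(len(recording)):
            vals = " ".join(f"{v:.17g}" for v in recording.samples[i, :3])
            fh.write(f"{t[i]:.17g} {vals} {recording.labels[i]}\n")


def read_recording(path) -> Recording:
    header: dict[str, str] = {}
    samples, labels = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                header[key.strip()] = value.strip()
                continue
            parts = line.split()
            samples.append([float(v) for v in parts[1:4]])
            labels.append(parts[4])
    return Recording(np.asarray(samples), float(header["rate"]),
                     np.asarray(labels, dtype=object),
                     header["subject"], header["dataset"])


def write_benchmark(corpus: dict[str, list[Recording]], directory) -> None:
    """One file per recording plus a YAML manifest naming them."""
    import os

    os.makedirs(directory, exist_ok=True)
    manifest: dict[str, list[str]] = {}
    for ds_name, recs in corpus.items():
        manifest[ds_name] = []
        for i, rec in enumerate(recs):
            fname = f"{rec.dataset_id}_{rec.subject_id}_{i:03d}_{rec.labels[0]}.txt"
            write_recording(rec, os.path.join(directory, fname))
            manifest[ds_name].append(fname)
    with open(os.path.join(directory, "manifest.yaml"), "w") as fh:
        yaml.safe_dump({"datasets": manifest}, fh)


def read_benchmark(directory) -> dict[str, list[Recording]]:
    import os

    with open(os.path.join(directory, "manifest.yaml")) as fh:
        manifest = yaml.safe_load(fh)["datasets"]
    return {ds: [read_recording(os.path.join(directory, f)) for f in files]
            for ds, files in manifest.items()}
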