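"""Synthetic quasi-periodic test signals with ground-truth annotations.

The generator places stylized event pulses at jittered multiples of a
mean cycle period and corrupts them with a baseline-wander sinusoid and
additive white Gaussian noise.  Three pulse shapes cover the event
morphologies the detector targets:

``gaussian``
    A smooth unimodal bump — PPG-systolic-like.
``biphasic``
    A derivative-of-Gaussian up/down deflection — QRS-like.
``burst``
    A Gaussian-enveloped cosine tone — heart-sound-like.

These are deliberately minimal stylizations, not physiological
simulators: the detector assumes only an event of roughly known duration
recurring with a roughly known period, which these shapes realize
controllably.  The annotation for each pulse is the sample index of its
extremum (maximum absolute amplitude), matching the detector's peak
definition.  Output is fully determined by ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .core import SignalRecord, TermaParams
from .evaluation import AnnotationSet

__all__ = [
    "SyntheticSpec",
    "generate",
    "standard_suite",
    "matched_params",
    "recovery_training_specs",
    "load_spec_file",
    "fixture_path",
    "FIXTURE_NAMES",
]

#: Shipped example generator configurations (see the package's fixtures/).
FIXTURE_NAMES = ("qrs_like", "ppg_like", "s1s2_like")

_SHAPES = ("gaussian", "biphasic", "burst")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic record.

    Attributes
    ----------
    fs : float
        Sampling frequency in Hz.
    duration_s : float
        Record length in seconds.
    cycle_ms : float
        Mean event-to-event period, milliseconds.
    cycle_jitter_frac : float
        Fractional standard deviation of the period (0 = metronomic).
    event_width_ms : float
        Full width of each pulse, milliseconds; must be below ``cycle_ms``
        and span at least 2 samples at ``fs``.
    event_shape : str
        One of ``gaussian``, ``biphasic``, ``burst``.
    event_amplitude : float
        Peak pulse amplitude, arbitrary units.
    noise_std : float
        Standard deviation of additive white Gaussian noise.
    baseline_amp, baseline_hz : float
        Amplitude and frequency of a baseline-wander sinusoid.
    seed : int
        RNG seed; fully determines the output.
    """

    fs: float = 360.0
    duration_s: float = 20.0
    cycle_ms: float = 1000.0
    cycle_jitter_frac: float = 0.0
    event_width_ms: float = 80.0
    event_shape: str = "biphasic"
    event_amplitude: float = 1.0
    noise_std: float = 0.0
    baseline_amp: float = 0.0
    baseline_hz: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_shape not in _SHAPES:
            raise ValueError(
                f"event_shape must be one of {_SHAPES}, got {self.event_shape!r}"
            )
        if not (self.event_width_ms < self.cycle_ms):
            raise ValueError(
                f"event_width_ms ({self.event_width_ms}) must be below "
                f"cycle_ms ({self.cycle_ms})"
            )
        if self.event_width_ms * self.fs / 1000.0 < 2:
            raise ValueError(
                f"fs ({self.fs} Hz) too low: event_width_ms "
                f"({self.event_width_ms}) spans fewer than 2 samples"
            )
        for field_name in ("fs", "duration_s", "cycle_ms", "event_amplitude"):
            if not (getattr(self, field_name) > 0):
                raise ValueError(f"{field_name} must be > 0")
        for field_name in ("cycle_jitter_frac", "noise_std", "baseline_amp"):
            if getattr(self, field_name) < 0:
                raise ValueError(f"{field_name} must be >= 0")


def _pulse(shape: str, width_samples: int, fs: float) -> np.ndarray:
    """Unit-amplitude pulse waveform of odd length ``2*half+1``."""
    half = width_samples // 2
    t = np.arange(-half, half + 1, dtype=float)
    sigma = width_samples / 6.0  # +-3 sigma spans the nominal width
    gauss = np.exp(-0.5 * (t / sigma) ** 2)
    if shape == "gaussian":
        wave = gauss
    elif shape == "biphasic":
        wave = -t / sigma * gauss  # up-then-down deflection
    else:  # burst: enveloped tone; carrier peak aligned with envelope center
        carrier_hz = min(40.0, 0.4 * fs)
        wave = gauss * np.cos(2 * np.pi * carrier_hz * t / fs)
    return wave / np.max(np.abs(wave))


def generate(spec: SyntheticSpec) -> tuple[SignalRecord, AnnotationSet]:
    """Synthesize one record and its ground-truth annotations.

    Pulse centers sit at ``(k + 1/2) * cycle_ms`` plus Gaussian jitter;
    pulses whose support would cross a record boundary are dropped.  Each
    annotation is the exact sample of the pulse's extremum (earliest
    sample on an exact tie), before noise is added.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    x = np.zeros(n)

    width = int(round(spec.event_width_ms * spec.fs / 1000.0))
    wave = spec.event_amplitude * _pulse(spec.event_shape, width, spec.fs)
    half = (wave.size - 1) // 2
    extremum_offset = int(np.argmax(np.abs(wave))) - half

    cycle_s = spec.cycle_ms / 1000.0
    n_cycles = int(np.floor(spec.duration_s / cycle_s))
    jitter = rng.normal(0.0, spec.cycle_jitter_frac * cycle_s, size=n_cycles)
    centers_s = (np.arange(n_cycles) + 0.5) * cycle_s + jitter

    events = []
    for c in centers_s:
        center = int(round(c * spec.fs))
        if center - half < 0 or center + half >= n:
            continue
        x[center - half : center + half + 1] += wave
        events.append(center + extremum_offset)

    t = np.arange(n) / spec.fs
    if spec.baseline_amp > 0:
        x += spec.baseline_amp * np.sin(2 * np.pi * spec.baseline_hz * t)
    if spec.noise_std > 0:
        x += rng.normal(0.0, spec.noise_std, size=n)

    label = f"synthetic-{spec.event_shape}-seed{spec.seed}"
    record = SignalRecord(samples=x, fs=spec.fs, label=label)
    annotations = AnnotationSet(
        events=np.asarray(sorted(events), dtype=int), fs=spec.fs, label=spec.event_shape
    )
    return record, annotations


#: Band-pass edges (Hz) and offset fraction suiting each pulse shape's
#: spectral content, mirroring the published optima for the corresponding
#: physiological events.
_SHAPE_BANDS = {
    "biphasic": (8.0, 20.0, 0.08),
    "gaussian": (0.5, 8.0, 0.02),
    "burst": (0.0, 60.0, 0.03),
}


def matched_params(spec: SyntheticSpec, ratio: float = 6.0) -> TermaParams:
    """Detector parameters matched to a synthetic spec.

    The event window equals the pulse width, the cycle window is
    ``ratio`` times it (default 6, the dominant coupling ratio), and the
    band and offset follow the pulse shape.
    """
    f1, f2, beta = _SHAPE_BANDS[spec.event_shape]
    return TermaParams(
        F1=f1, F2=f2,
        W1_ms=spec.event_width_ms,
        W2_ms=ratio * spec.event_width_ms,
        beta=beta,
    )


def standard_suite(
    seed: int = 0, noise_std: float = 0.0, cycle_jitter_frac: float = 0.03
) -> list[SyntheticSpec]:
    """The three-shape reference suite used throughout the test battery.

    One 20 s record per pulse shape, with cycle and width choices typical
    of the corresponding physiological event (QRS-like biphasic at 360 Hz,
    PPG-like Gaussian at 200 Hz, heart-sound-like burst at 1000 Hz).
    """
    base = dict(
        duration_s=20.0,
        cycle_jitter_frac=cycle_jitter_frac,
        noise_std=noise_std,
        event_amplitude=1.0,
    )
    return [
        SyntheticSpec(
            fs=360.0, cycle_ms=1000.0, event_width_ms=80.0,
            event_shape="biphasic", seed=seed, **base,
        ),
        SyntheticSpec(
            fs=200.0, cycle_ms=900.0, event_width_ms=110.0,
            event_shape="gaussian", seed=seed + 1, **base,
        ),
        SyntheticSpec(
            fs=1000.0, cycle_ms=500.0, event_width_ms=100.0,
            event_shape="burst", seed=seed + 2, **base,
        ),
    ]


def recovery_training_specs(seed: int = 0, n_records: int = 3) -> list[SyntheticSpec]:
    """Training set for event-window (W1) recovery by grid search.

    Emulates a noisy exercise-ECG-like condition: 80 ms biphasic events at
    150 beats/min with 10 % cycle jitter and white noise at 0.6 of the
    event amplitude.  In this regime the event window is identifiable:
    an under-sized window admits noise blocks wide enough to survive the
    width threshold (false positives), while an over-sized window merges
    closely spaced beats into single blocks (false negatives), so the
    true 80 ms window maximises the pooled overall accuracy.
    """
    return [
        SyntheticSpec(
            fs=360.0, duration_s=20.0, cycle_ms=400.0, cycle_jitter_frac=0.10,
            event_width_ms=80.0, event_shape="biphasic", event_amplitude=1.0,
            noise_std=0.6, seed=seed * 10 + k,
        )
        for k in range(n_records)
    ]


def fixture_path(name: str):
    """Filesystem path of a shipped generator configuration."""
    from importlib.resources import files

    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}")
    return files("terma").joinpath("fixtures", f"{name}.yaml")


def load_spec_file(path) -> tuple[SyntheticSpec, TermaParams | None]:
    """Load a generator configuration (and optional matched detector params).

    The YAML file holds a ``spec`` mapping with SyntheticSpec fields and
    may add a ``params`` mapping with matched detector parameters
    (``F1_hz, F2_hz, W1_ms, W2_ms, beta``).
    """
    text = path.read_text() if hasattr(path, "read_text") else Path(path).read_text()
    data = yaml.safe_load(text)
    spec = SyntheticSpec(**data["spec"])
    params = None
    if "params" in data:
        p = data["params"]
        params = TermaParams(
            F1=float(p["F1_hz"]), F2=float(p["F2_hz"]),
            W1_ms=float(p["W1_ms"]), W2_ms=float(p["W2_ms"]),
            beta=float(p["beta"]),
        )
    return spec, params
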