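"""Two event-related moving averages (TERMA) event detector.

The detector finds quasi-periodic events (QRS complexes, PPG systolic
waves, heart sounds, ...) in a single-channel signal by comparing a short,
event-scale moving average of the squared band-passed signal against a
long, cycle-scale moving average raised by a signal-dependent offset.
Maximal runs where the event average strictly exceeds the offset cycle
average form *blocks of interest*; blocks narrower than the event window
are rejected as noise, and each surviving block contributes one peak: the
sample of maximum absolute filtered amplitude inside it.

All window durations at the interface are in milliseconds and are
converted per record using the sampling frequency, so one parameter set
works unchanged across sampling rates.  Sample indices are 0-based and
block intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "SignalRecord",
    "TermaParams",
    "IntermediateSignals",
    "BlockSet",
    "DetectionResult",
    "RateReport",
    "ms_to_odd_samples",
    "bandpass_filter",
    "enhance",
    "moving_average",
    "compute_offset",
    "generate_blocks",
    "reject_blocks",
    "locate_peaks",
    "detect",
    "check_terma_rate",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalRecord:
    """A sampled single-channel signal with its sampling frequency.

    Parameters
    ----------
    samples : array-like of float
        Signal samples in arbitrary amplitude units. Must be finite.
    fs : float
        Sampling frequency in Hz, strictly positive.
    label : str
        Free-text identifier used in output files and log messages.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            bad = int(np.count_nonzero(~np.isfinite(samples)))
            raise ValueError(f"samples contain {bad} non-finite values")
        if not (self.fs > 0):
            raise ValueError(f"fs must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class TermaParams:
    """The five decision variables of the detector.

    Attributes
    ----------
    F1, F2 : float
        Band-pass corner frequencies in Hz; ``F1 = 0`` selects a pure
        low-pass at ``F2``.
    W1_ms : float
        Event-duration moving-average window, milliseconds.
    W2_ms : float
        Cycle-duration moving-average window, milliseconds.
    beta : float
        Offset fraction of the mean squared signal, dimensionless
        (0.08 means 8 %).
    """

    F1: float
    F2: float
    W1_ms: float
    W2_ms: float
    beta: float

    def __post_init__(self) -> None:
        if self.F1 < 0:
            raise ValueError(f"F1 must be >= 0, got {self.F1}")
        if not (self.F2 > self.F1):
            raise ValueError(f"F2 must exceed F1, got F1={self.F1}, F2={self.F2}")
        if not (self.W1_ms > 0):
            raise ValueError(f"W1_ms must be > 0, got {self.W1_ms}")
        if not (self.W2_ms > self.W1_ms):
            raise ValueError(
                f"W2_ms must exceed W1_ms, got W1_ms={self.W1_ms}, W2_ms={self.W2_ms}"
            )
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")

    @property
    def rate_ok(self) -> bool:
        """Whether the window-ratio design rule 8·W1 >= W2 >= 2·W1 holds."""
        return check_terma_rate(self).holds


@dataclass(frozen=True)
class IntermediateSignals:
    """Every intermediate stage of a detection, kept for inspection."""

    filtered: np.ndarray
    squared: np.ndarray
    ma_event: np.ndarray
    ma_cycle: np.ndarray
    alpha: float
    thr1: np.ndarray
    z_bar: float


@dataclass(frozen=True)
class BlockSet:
    """Ordered half-open sample intervals marking blocks of interest."""

    blocks: tuple[tuple[int, int], ...]
    thr2_samples: int = 0

    def __post_init__(self) -> None:
        prev_end = -1
        for onset, offset in self.blocks:
            if offset <= onset:
                raise ValueError(f"empty or inverted block [{onset}, {offset})")
            if onset < prev_end:
                raise ValueError("blocks overlap or are unsorted")
            prev_end = offset

    def __len__(self) -> int:
        return len(self.blocks)

    def widths(self) -> np.ndarray:
        return np.array([off - on for on, off in self.blocks], dtype=int)


@dataclass(frozen=True)
class DetectionResult:
    """Detected peaks plus the full processing trace."""

    peaks: np.ndarray
    blocks: BlockSet
    intermediates: IntermediateSignals
    params: TermaParams
    record: SignalRecord
    peak_on: str = "filtered"


@dataclass(frozen=True)
class RateReport:
    """Outcome of the window-ratio design rule check."""

    holds: bool
    ratio: float
    bounds: tuple[float, float] = (2.0, 8.0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def ms_to_odd_samples(duration_ms: float, fs: float) -> int:
    """Convert a duration in ms to the nearest odd sample count (minimum 1).

    Equidistant cases (the duration lands on an even sample count) round up.
    """
    if not (duration_ms > 0):
        raise ValueError(f"duration_ms must be > 0, got {duration_ms}")
    if not (fs > 0):
        raise ValueError(f"fs must be > 0, got {fs}")
    x = duration_ms * fs / 1000.0
    lower = 2 * math.floor((x - 1) / 2) + 1  # greatest odd <= x (or nearest below)
    upper = lower + 2
    if x - lower < upper - x:
        n = lower
    else:
        n = upper
    return max(1, n)


class SignalTooShortError(ValueError):
    """Raised when a record is too short for zero-phase filtering."""


def bandpass_filter(
    record: SignalRecord, F1: float, F2: float, order: int = 3
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of ``record`` between F1 and F2 Hz.

    The filter is applied forward and backward (``filtfilt``) so the output
    has no phase lag.  ``F1 = 0`` selects a pure low-pass of the same
    order.  An ``F2`` at or above the Nyquist frequency is clipped to
    0.99·Nyquist with a logged warning, so presets expressed in Hz remain
    usable at low sampling rates.
    """
    if F1 < 0 or F1 >= F2:
        raise ValueError(f"need 0 <= F1 < F2, got F1={F1}, F2={F2}")
    nyq = record.fs / 2.0
    if F2 >= nyq:
        clipped = 0.99 * nyq
        logger.warning(
            "F2=%g Hz is at or above Nyquist (%g Hz) for record %r; clipping to %g Hz",
            F2, nyq, record.label, clipped,
        )
        F2 = clipped
        if F1 >= F2:
            raise ValueError(
                f"F1={F1} Hz not below the clipped F2={F2} Hz at fs={record.fs}"
            )
    if F1 == 0:
        sos = sps.butter(order, F2, btype="lowpass", fs=record.fs, output="sos")
    else:
        sos = sps.butter(order, [F1, F2], btype="bandpass", fs=record.fs, output="sos")
    # sosfiltfilt pads with edge reflections; it needs a minimum length.
    ntaps = 2 * sos.shape[0] + 1
    padlen = 3 * ntaps
    if len(record) <= padlen:
        raise SignalTooShortError(
            f"record {record.label!r} has {len(record)} samples; zero-phase "
            f"filtering needs more than {padlen}"
        )
    return sps.sosfiltfilt(sos, record.samples)


def enhance(filtered: np.ndarray) -> np.ndarray:
    """Square the signal point by point, boosting large deflections."""
    filtered = np.asarray(filtered, dtype=float)
    return filtered * filtered


def moving_average(signal: np.ndarray, window_samples: int) -> np.ndarray:
    """Centered moving mean with an odd window, same length as the input.

    Edges are handled by symmetric (edge-repeating) extension of the
    signal, which avoids spurious threshold crossings at record
    boundaries.
    """
    signal = np.asarray(signal, dtype=float)
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window_samples}")
    if window_samples > signal.size:
        raise ValueError(
            f"window of {window_samples} samples exceeds signal length {signal.size}"
        )
    if window_samples == 1:
        return signal.copy()
    half = (window_samples - 1) // 2
    padded = np.pad(signal, half, mode="symmetric")
    kernel = np.full(window_samples, 1.0 / window_samples)
    return np.convolve(padded, kernel, mode="valid")


def compute_offset(squared: np.ndarray, beta: float) -> float:
    """Threshold offset: ``beta`` times the mean of the squared signal.

    The mean is taken over the whole record (batch processing).
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    return float(beta * np.mean(np.asarray(squared, dtype=float)))


def generate_blocks(ma_event: np.ndarray, thr1: np.ndarray) -> BlockSet:
    """Maximal runs where the event average strictly exceeds the threshold.

    Returned as sorted half-open intervals; runs touching either record
    boundary are kept.
    """
    ma_event = np.asarray(ma_event, dtype=float)
    thr1 = np.asarray(thr1, dtype=float)
    if ma_event.shape != thr1.shape:
        raise ValueError(
            f"length mismatch: ma_event has {ma_event.size}, thr1 has {thr1.size}"
        )
    above = ma_event > thr1
    edges = np.diff(above.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    offsets = np.flatnonzero(edges == -1) + 1
    if above.size and above[0]:
        onsets = np.concatenate(([0], onsets))
    if above.size and above[-1]:
        offsets = np.concatenate((offsets, [above.size]))
    blocks = tuple((int(a), int(b)) for a, b in zip(onsets, offsets))
    return BlockSet(blocks=blocks)


def reject_blocks(blocks: BlockSet, w1_samples: int) -> BlockSet:
    """Keep only blocks at least ``w1_samples`` wide (width threshold THR2).

    A block exactly as wide as the event window is retained, so events of
    the anticipated duration survive.
    """
    kept = tuple(b for b in blocks.blocks if b[1] - b[0] >= w1_samples)
    return BlockSet(blocks=kept, thr2_samples=int(w1_samples))


def locate_peaks(filtered: np.ndarray, blocks: BlockSet) -> np.ndarray:
    """One peak per block: the index of maximum absolute amplitude.

    Ties break to the earliest index.
    """
    filtered = np.asarray(filtered, dtype=float)
    peaks = []
    for onset, offset in blocks.blocks:
        if onset < 0 or offset > filtered.size:
            raise ValueError(f"block [{onset}, {offset}) outside signal bounds")
        seg = np.abs(filtered[onset:offset])
        peaks.append(onset + int(np.argmax(seg)))
    return np.asarray(peaks, dtype=int)


def check_terma_rate(params: TermaParams) -> RateReport:
    """Check the window-ratio design rule 8·W1 >= W2 >= 2·W1 (inclusive).

    Ratios outside the bounds tend to decouple the two moving averages so
    that no blocks of interest are generated; the rule is empirical, so
    violations warn rather than fail.
    """
    ratio = params.W2_ms / params.W1_ms
    holds = (8.0 * params.W1_ms >= params.W2_ms) and (params.W2_ms >= 2.0 * params.W1_ms)
    return RateReport(holds=holds, ratio=ratio)


def detect(
    record: SignalRecord,
    params: TermaParams,
    *,
    peak_on: str = "filtered",
    order: int = 3,
) -> DetectionResult:
    """Run the full detection pipeline on one record.

    Stages: band-pass filter, point-wise squaring, event and cycle moving
    averages, offset threshold, block generation, width-based block
    rejection, per-block peak localisation.

    Parameters
    ----------
    record : SignalRecord
    params : TermaParams
    peak_on : {"filtered", "raw", "squared"}
        Signal on which the per-block maximum-absolute-value search runs.
        Default is the band-passed signal, whose polarity is preserved.
    order : int
        Butterworth filter order (default 3).
    """
    if peak_on not in ("filtered", "raw", "squared"):
        raise ValueError(f"peak_on must be filtered/raw/squared, got {peak_on!r}")

    w1 = ms_to_odd_samples(params.W1_ms, record.fs)
    w2 = ms_to_odd_samples(params.W2_ms, record.fs)
    n = len(record)
    for name, w in (("W1", w1), ("W2", w2)):
        if w > n:
            raise ValueError(
                f"window {name} = {w} samples exceeds record length {n} "
                f"(record {record.label!r} at fs={record.fs} Hz)"
            )

    rate = check_terma_rate(params)
    logger.info(
        "record %r: W1=%d samples, W2=%d samples, ratio W2/W1=%.2f, rate rule %s",
        record.label, w1, w2, rate.ratio, "holds" if rate.holds else "VIOLATED",
    )
    if not rate.holds:
        logger.warning(
            "W2/W1 ratio %.2f outside [2, 8] for record %r; the moving averages "
            "may fail to couple and generate no blocks",
            rate.ratio, record.label,
        )

    filtered = bandpass_filter(record, params.F1, params.F2, order=order)
    squared = enhance(filtered)
    ma_event = moving_average(squared, w1)
    ma_cycle = moving_average(squared, w2)
    z_bar = float(np.mean(squared))
    alpha = compute_offset(squared, params.beta)
    thr1 = ma_cycle + alpha

    blocks = generate_blocks(ma_event, thr1)
    blocks = reject_blocks(blocks, w1)

    peak_signal = {"filtered": filtered, "raw": record.samples, "squared": squared}[
        peak_on
    ]
    peaks = locate_peaks(peak_signal, blocks)

    intermediates = IntermediateSignals(
        filtered=filtered,
        squared=squared,
        ma_event=ma_event,
        ma_cycle=ma_cycle,
        alpha=alpha,
        thr1=thr1,
        z_bar=z_bar,
    )
    return DetectionResult(
        peaks=peaks,
        blocks=blocks,
        intermediates=intermediates,
        params=params,
        record=record,
        peak_on=peak_on,
    )
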