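"""Signal conditioning: EMG rectification + filtering, GRF low-pass filtering,
vertical-GRF gait-cycle segmentation, quality screening, and mean normalization.

All filters are 4th-order Butterworth IIR applied forward-backward (zero phase);
EMG is full-wave rectified, band-passed 25-499 Hz and notch-filtered at 60 Hz and
its harmonics; GRF is low-passed at 100 Hz. "Gait cycle" is operationalized as the
stance phase captured by the force plate (the vertical GRF is zero off-plate), and
sample intervals are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, NormalizationError, SegmentTooShortError

EMG_BAND = (25.0, 499.0)
GRF_CUTOFF = 100.0
NOTCH_BASE = 60.0
NOTCH_Q = 30.0
FILTER_ORDER = 4


@dataclass(frozen=True)
class FilterSpec:
    """Specification of one zero-phase IIR filtering stage."""

    kind: str  # bandpass | lowpass | notch
    order: int = FILTER_ORDER
    cutoffs: tuple[float, ...] = ()
    zero_phase: bool = True
    notch_base: float = NOTCH_BASE
    notch_harmonics: int | None = None
    notch_q: float = NOTCH_Q


@dataclass
class GaitCycleSegment:
    """One preprocessed, mean-normalized per-cycle channel signal."""

    subject_id: str
    label: str
    channel_name: str
    samples: np.ndarray
    span: tuple[int, int]
    normalized: bool = True

    def __post_init__(self) -> None:
        start, end = self.span
        if end <= start:
            raise ConfigurationError(f"empty span {self.span}")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("segment contains non-finite samples")


def _padlen(x: np.ndarray, fs: float) -> int:
    # narrow notches have impulse responses far longer than scipy's default
    # padding; extend up to one second (capped by the signal length)
    return int(min(len(x) - 1, fs))


# even-extension padding preserves the local mean at the boundaries, which keeps
# the rectified (positive-mean) EMG from exciting a DC-step edge transient
_PADTYPE = "even"


def _sosfiltfilt(sos: np.ndarray, x: np.ndarray, fs: float) -> np.ndarray:
    try:
        return sps.sosfiltfilt(sos, x, padtype=_PADTYPE, padlen=_padlen(x, fs))
    except ValueError as exc:  # padlen exceeds signal length
        raise SegmentTooShortError(f"signal too short for zero-phase filtering: {exc}") from exc


def _emg_zero_phase_response(n_fft: int, fs: float) -> np.ndarray:
    """|H|^2 of the EMG chain (Butterworth band-pass 25-499 Hz cascaded with the
    60 Hz harmonic notches) on the rfft grid of length ``n_fft``."""
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    w = 2 * np.pi * freqs / fs
    lo, hi = EMG_BAND
    sos = sps.butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=w)
    response = np.abs(h) ** 2
    k = 1
    while (k * NOTCH_BASE) < fs / 2:
        b, a = sps.iirnotch(k * NOTCH_BASE, NOTCH_Q, fs=fs)
        _, hn = sps.freqz(b, a, worN=w)
        response *= np.abs(hn) ** 2
        k += 1
    return response


def preprocess_emg(raw: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Full-wave rectify then zero-phase band-pass (25-499 Hz, Butterworth order 4)
    and notch out 60 Hz and its harmonics up to Nyquist. Length is preserved.

    The zero-phase stage applies the cascade's squared magnitude response on a
    symmetric signal extension: the exact forward-backward filter, free of the
    numerical asymmetry an IIR realization suffers with a band edge this close to
    Nyquist.
    """
    raw = np.asarray(raw, dtype=float)
    lo, hi = EMG_BAND
    if fs / 2 <= hi:
        raise ConfigurationError(
            f"fs={fs} too low for the {hi} Hz band edge (need fs > {2 * hi})"
        )
    if raw.size < 3 * FILTER_ORDER:
        raise SegmentTooShortError(f"EMG segment of {raw.size} samples is too short to filter")
    x = np.abs(raw)
    n = x.size
    extended = np.concatenate([x, x[::-1]])  # even (mirror) extension
    spectrum = np.fft.rfft(extended)
    spectrum *= _emg_zero_phase_response(extended.size, fs)
    return np.fft.irfft(spectrum, n=extended.size)[:n]


def preprocess_grf(raw: np.ndarray, fs: float = 1000.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass at 100 Hz; length preserved."""
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * GRF_CUTOFF:
        raise ConfigurationError(f"fs={fs} too low for the {GRF_CUTOFF} Hz cutoff")
    sos = sps.butter(FILTER_ORDER, GRF_CUTOFF, btype="lowpass", fs=fs, output="sos")
    return _sosfiltfilt(sos, raw, fs)


def segment_gait_cycles(
    vgrf: np.ndarray,
    fs: float,
    threshold_frac: float = 0.05,
    min_sustain: float = 0.050,
) -> list[tuple[int, int]]:
    """Detect stance intervals where the vertical GRF exceeds ``threshold_frac`` of
    its per-recording maximum for at least ``min_sustain`` seconds.

    Returns disjoint, ordered half-open ``[start, end)`` sample intervals; an
    all-zero (or never-loaded) signal yields an empty list.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ConfigurationError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    vgrf = np.asarray(vgrf, dtype=float)
    peak = vgrf.max(initial=0.0)
    if peak <= 0.0:
        return []
    mask = vgrf > threshold_frac * peak
    # run-length extraction of contiguous True stretches
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = list(edges[~mask[edges]] + 1)
    ends = list(edges[mask[edges]] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    min_len = int(np.ceil(min_sustain * fs))
    return [(s, e) for s, e in zip(starts, ends) if e - s >= min_len]


@dataclass(frozen=True)
class ScreenResult:
    accepted: bool
    reason: str | None = None


def quality_screen(
    segment_interval: tuple[int, int],
    fs: float,
    signal: np.ndarray | None = None,
    min_dur: float = 0.3,
    max_dur: float = 1.5,
) -> ScreenResult:
    """Automatic stand-in for the study's semi-manual screening: accept a stance
    interval iff its duration lies in ``[min_dur, max_dur]`` seconds and (when the
    signal is supplied) its peak amplitude is positive."""
    start, end = segment_interval
    dur = (end - start) / fs
    if dur < min_dur:
        return ScreenResult(False, "too short")
    if dur > max_dur:
        return ScreenResult(False, "too long")
    if signal is not None and np.asarray(signal)[start:end].max(initial=0.0) <= 0.0:
        return ScreenResult(False, "non-positive peak")
    return ScreenResult(True, None)


def normalize_by_mean(segment: np.ndarray, channel: str = "") -> np.ndarray:
    """Divide a segment by its mean so the output has mean exactly 1."""
    segment = np.asarray(segment, dtype=float)
    m = segment.mean()
    scale = np.abs(segment).mean()
    if scale == 0.0 or np.abs(m) < 1e-12 * max(scale, 1.0):
        raise NormalizationError(f"zero-mean segment cannot be mean-normalized ({channel or 'unnamed'})")
    return segment / m


def normalize_by_abs_mean(segment: np.ndarray, channel: str = "") -> np.ndarray:
    """Divide a segment by its mean absolute value.

    Used for bipolar channels (band-passed EMG, GRF shear components) whose plain
    mean is ~0 and would make division meaningless.
    """
    segment = np.asarray(segment, dtype=float)
    m = np.abs(segment).mean()
    if m == 0.0:
        raise NormalizationError(f"all-zero segment cannot be normalized ({channel or 'unnamed'})")
    return segment / m
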