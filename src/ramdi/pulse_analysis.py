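"""Artifact gating, pulse-peak detection, heart rate and amplitude trends.

All operations act on the output of the filtering chain.  Windowed series
(RMS, envelope, heart rate) are laid on a fixed grid from t = 0 with hop
half the window length; a window is referenced by its centre time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DataError, ValidationError

__all__ = [
    "ValidityMask",
    "RMSSeries",
    "PulsePeakSeries",
    "EnvelopeTrend",
    "HeartRateSeries",
    "OcclusionReport",
    "rms_series",
    "gate_invalid",
    "mark_transient",
    "detect_peaks",
    "heart_rate",
    "pulse_envelope",
    "amplitude_scale",
    "verify_occlusion",
]

#: Minimum inter-beat interval (s); 0.33 s corresponds to 180 bpm.
DEFAULT_REFRACTORY_S = 0.33
DEFAULT_MIN_PROMINENCE = 0.3
DEFAULT_RMS_BOUNDS = (0.2, 5.0)
DEFAULT_OCCLUSION_THRESHOLD = 0.1
#: Band (Hz) regarded as carrying the pulse fundamental.
PULSE_BAND_HZ = (0.4, 3.0)


@dataclass
class ValidityMask:
    """Per-sample validity with labelled invalid segments.

    Segments are half-open sample intervals with a reason tag drawn from
    {"rms_out_of_range", "transient", "manual"}.
    """

    valid: np.ndarray
    segments: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)
        self.segments = sorted(self.segments)
        last = 0
        for lo, hi, reason in self.segments:
            if not (0 <= lo < hi <= self.valid.size):
                raise ValidationError(f"segment [{lo}, {hi}) out of bounds for mask of {self.valid.size}")
            if lo < last:
                raise ValidationError("invalid segments must be disjoint and sorted")
            last = hi

    @classmethod
    def all_valid(cls, n: int) -> "ValidityMask":
        return cls(valid=np.ones(n, dtype=bool))

    def invalidate(self, lo: int, hi: int, reason: str) -> None:
        lo, hi = max(0, lo), min(self.valid.size, hi)
        if lo >= hi:
            return
        self.valid[lo:hi] = False
        self.segments = _merge_segments(self.segments + [(lo, hi, reason)])

    def fraction_valid(self, interval: tuple[int, int] | None = None) -> float:
        lo, hi = interval if interval is not None else (0, self.valid.size)
        seg = self.valid[lo:hi]
        return float(seg.mean()) if seg.size else 0.0


def _merge_segments(segments: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Merge overlapping segments (same reason) so the list stays disjoint/sorted."""
    out: list[tuple[int, int, str]] = []
    for lo, hi, reason in sorted(segments):
        if out and lo <= out[-1][1] and reason == out[-1][2]:
            plo, phi, preason = out.pop()
            lo, hi = plo, max(phi, hi)
        elif out and lo < out[-1][1]:  # overlap across reasons: clip
            lo = out[-1][1]
            if lo >= hi:
                continue
        out.append((lo, hi, reason))
    return out


def _window_grid(n: int, fs: float, window: float, hop: float | None = None):
    """Yield (start, stop, centre_s) for windows fully inside [0, n)."""
    w = int(round(window * fs))
    h = int(round((hop if hop is not None else window / 2) * fs))
    if w < 1 or h < 1:
        raise ValidationError("window and hop must be positive")
    starts = range(0, n - w + 1, h)
    return [(s, s + w, (s + w / 2) / fs) for s in starts]


@dataclass(frozen=True)
class RMSSeries:
    centers_s: np.ndarray
    values: np.ndarray
    window_s: float


def rms_series(x: np.ndarray, window: float, fs: float) -> RMSSeries:
    """Sliding-window root-mean-square with hop = window/2."""
    x = np.asarray(x, dtype=float)
    if window < 1.0:
        raise ValidationError(f"RMS window must be >= 1 s, got {window}")
    if int(round(window * fs)) > x.size:
        raise DataError(f"RMS window of {window} s exceeds series duration {x.size / fs:.2f} s")
    grid = _window_grid(x.size, fs, window)
    centers = np.array([c for _, _, c in grid])
    vals = np.array([math.sqrt(float(np.mean(x[a:b] ** 2))) for a, b, _ in grid])
    return RMSSeries(centers_s=centers, values=vals, window_s=window)


def gate_invalid(
    x: np.ndarray,
    rms: RMSSeries,
    bounds: tuple[float, float] = DEFAULT_RMS_BOUNDS,
    baseline: tuple[int, int] | None = None,
    fs: float = 200.0,
    margin_s: float = 1.0,
) -> ValidityMask:
    """Mark windows whose RMS leaves ``bounds`` x the baseline-phase median RMS.

    ``baseline`` is the sample interval of the baseline phase, used as the
    reference for what "in range" means for this subject and session.
    Flagged windows are dilated by ``margin_s`` on each side: artifact onsets
    and tails ramp through the RMS bound, so samples adjacent to an
    out-of-range window are not trustworthy either.
    """
    x = np.asarray(x, dtype=float)
    if baseline is None:
        raise ConfigurationError("gate_invalid requires the baseline phase interval as reference")
    lo_rel, hi_rel = bounds
    b_lo, b_hi = baseline
    w = int(round(rms.window_s * fs))
    in_baseline = [
        i
        for i, c in enumerate(rms.centers_s)
        if b_lo <= int(round(c * fs - w / 2)) and int(round(c * fs + w / 2)) <= b_hi
    ]
    if not in_baseline:
        raise ConfigurationError("no RMS windows fall inside the baseline phase")
    ref = float(np.median(rms.values[in_baseline]))
    mask = ValidityMask.all_valid(x.size)
    if ref == 0.0:
        # Degenerate baseline: every window with the same zero RMS stays valid,
        # anything non-zero is out of range.  With lo > 0 a zero signal is fully invalid.
        ref = 0.0
    margin = int(round(margin_s * fs))
    for i, c in enumerate(rms.centers_s):
        a = int(round(c * fs - w / 2))
        b = a + w
        v = rms.values[i]
        out = v < lo_rel * ref or v > hi_rel * ref if ref > 0 else v > 0 or lo_rel > 0
        if out:
            mask.invalidate(a - margin, b + margin, "rms_out_of_range")
    return mask


def mark_transient(mask: ValidityMask, fs: float, duration_s: float = 1.0) -> ValidityMask:
    """Flag the filter start-up transient at the head of the record."""
    mask.invalidate(0, int(round(duration_s * fs)), "transient")
    return mask


@dataclass(frozen=True)
class PulsePeakSeries:
    """Detected beat peaks: strictly increasing indices and their amplitudes."""

    peak_indices: np.ndarray
    peak_amplitudes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=int)
        amp = np.asarray(self.peak_amplitudes, dtype=float)
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "peak_amplitudes", amp)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValidationError("peak indices must be strictly increasing")
        if idx.size != amp.size:
            raise ValidationError("peak indices and amplitudes must have equal length")

    @property
    def times_s(self) -> np.ndarray:
        return self.peak_indices / self.fs

    def __len__(self) -> int:
        return int(self.peak_indices.size)


def amplitude_scale(x: np.ndarray, fs: float, interval: tuple[int, int] | None = None) -> float:
    """Robust peak-to-trough amplitude scale: median of 2-s window ranges.

    Serves as the reference for relative prominence thresholds, so detection
    is invariant to rescaling the input.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = interval if interval is not None else (0, x.size)
    seg = x[lo:hi]
    w = max(1, int(round(2.0 * fs)))
    if seg.size < w:
        return float(seg.max() - seg.min()) if seg.size else 0.0
    ranges = [float(seg[a : a + w].max() - seg[a : a + w].min()) for a in range(0, seg.size - w + 1, w)]
    return float(np.median(ranges))


def detect_peaks(
    x: np.ndarray,
    fs: float,
    mask: ValidityMask | None = None,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    refractory_s: float = DEFAULT_REFRACTORY_S,
    baseline: tuple[int, int] | None = None,
) -> PulsePeakSeries:
    """Detect beat peaks as prominent local maxima with a refractory spacing.

    Prominence is relative: ``min_prominence`` times the baseline amplitude
    scale (from ``baseline`` if given, else the whole record).  Peaks falling
    in invalid mask segments are discarded.
    """
    x = np.asarray(x, dtype=float)
    scale = amplitude_scale(x, fs, baseline)
    if scale <= 0:
        return PulsePeakSeries(np.empty(0, int), np.empty(0, float), fs)
    distance = max(1, int(round(refractory_s * fs)))
    idx, _ = sps.find_peaks(x, distance=distance, prominence=min_prominence * scale)
    if mask is not None:
        idx = idx[mask.valid[idx]]
    return PulsePeakSeries(peak_indices=idx, peak_amplitudes=x[idx], fs=fs)


@dataclass(frozen=True)
class HeartRateSeries:
    """Windowed heart-rate estimates (bpm); windows with < 3 beats are invalid."""

    centers_s: np.ndarray
    bpm: np.ndarray
    valid: np.ndarray
    window_s: float


def heart_rate(peaks: PulsePeakSeries, n_samples: int, window: float = 60.0) -> HeartRateSeries:
    """Estimate heart rate by counting peaks per window, scaled to beats/min."""
    if len(peaks) == 0:
        return HeartRateSeries(np.empty(0), np.empty(0), np.empty(0, bool), window)
    grid = _window_grid(n_samples, peaks.fs, window)
    centers = np.array([c for _, _, c in grid])
    bpm = np.empty(len(grid))
    valid = np.empty(len(grid), dtype=bool)
    t = peaks.peak_indices
    for i, (a, b, _) in enumerate(grid):
        count = int(np.count_nonzero((t >= a) & (t < b)))
        bpm[i] = count * 60.0 / ((b - a) / peaks.fs)
        valid[i] = count >= 3
    bpm[~valid] = np.nan
    return HeartRateSeries(centers_s=centers, bpm=bpm, valid=valid, window_s=window)


@dataclass(frozen=True)
class EnvelopeTrend:
    """Smoothed pulse-amplitude trend: mean per-beat peak-to-trough per window."""

    centers_s: np.ndarray
    values: np.ndarray
    window_s: float

    def __post_init__(self) -> None:
        c = np.asarray(self.centers_s, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "centers_s", c)
        object.__setattr__(self, "values", v)
        if c.size and np.any(np.diff(c) <= 0):
            raise ValidationError("envelope windows must be ordered")
        if np.any(v < 0):
            raise ValidationError("envelope values must be >= 0")

    def restrict(self, interval_s: tuple[float, float]) -> "EnvelopeTrend":
        """Windows fully inside the half-open time interval (seconds)."""
        lo, hi = interval_s
        half = self.window_s / 2
        keep = (self.centers_s - half >= lo - 1e-9) & (self.centers_s + half <= hi + 1e-9)
        return EnvelopeTrend(self.centers_s[keep], self.values[keep], self.window_s)


def pulse_envelope(
    x: np.ndarray,
    peaks: PulsePeakSeries,
    window: float = 30.0,
    min_beats: int = 3,
    mask: ValidityMask | None = None,
) -> EnvelopeTrend:
    """Per-window mean beat amplitude (peak minus preceding trough).

    The trough of beat *i* is the signal minimum between peaks *i-1* and *i*;
    the first detected peak therefore contributes no amplitude.  A beat is
    discarded if any sample of its trough-to-peak span is masked invalid
    (artifact tails otherwise leak into the trough).  Windows with fewer
    than ``min_beats`` surviving beats are omitted.
    """
    x = np.asarray(x, dtype=float)
    if len(peaks) < 2:
        return EnvelopeTrend(np.empty(0), np.empty(0), window)
    idx = peaks.peak_indices
    bad_cum = np.concatenate([[0], np.cumsum(~mask.valid)]) if mask is not None else None
    beat_amp = np.full(idx.size - 1, np.nan)
    for i in range(1, idx.size):
        if bad_cum is not None and bad_cum[idx[i] + 1] - bad_cum[idx[i - 1]] > 0:
            continue
        trough = float(np.min(x[idx[i - 1] : idx[i] + 1]))
        beat_amp[i - 1] = max(0.0, float(x[idx[i]]) - trough)
    keep = np.isfinite(beat_amp)
    beat_amp = beat_amp[keep]
    beat_t = (idx[1:] / peaks.fs)[keep]
    grid = _window_grid(x.size, peaks.fs, window)
    centers, values = [], []
    for a, b, c in grid:
        in_w = (beat_t >= a / peaks.fs) & (beat_t < b / peaks.fs)
        if int(np.count_nonzero(in_w)) >= min_beats:
            centers.append(c)
            values.append(float(beat_amp[in_w].mean()))
    return EnvelopeTrend(np.array(centers), np.array(values), window)


@dataclass(frozen=True)
class OcclusionReport:
    complete: bool
    residual_ratio: float


def _band_rms(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """RMS of the signal content in ``band`` (Hz), via a Welch power estimate."""
    x = np.asarray(x, dtype=float)
    nperseg = min(x.size, int(round(30.0 * fs)))  # 30 s segments -> 0.033 Hz resolution
    # Median averaging across segments keeps short motion bursts from
    # dominating the phase power estimate.
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg, average="median")
    sel = (f >= band[0]) & (f <= band[1])
    power = float(np.trapezoid(pxx[sel], f[sel]))
    return math.sqrt(max(power, 0.0))


def verify_occlusion(
    x_filtered: np.ndarray,
    baseline: tuple[int, int],
    occlusion: tuple[int, int],
    fs: float,
    band: tuple[float, float] = PULSE_BAND_HZ,
    threshold: float = DEFAULT_OCCLUSION_THRESHOLD,
) -> OcclusionReport:
    """Check that cuff occlusion actually suppressed the occluded-arm pulse.

    The residual ratio is the pulse-band RMS of the occlusion phase over that
    of the baseline phase on the (filtered) occluded-arm signal; occlusion is
    complete iff the ratio is strictly below ``threshold``.  A spectral
    measure is used because a complete occlusion leaves no detectable beats
    for a peak-driven envelope.
    """
    x = np.asarray(x_filtered, dtype=float)
    for name, (lo, hi) in (("baseline", baseline), ("occlusion", occlusion)):
        if not (0 <= lo < hi <= x.size):
            raise ConfigurationError(f"{name} interval [{lo}, {hi}) outside the record")
    base = _band_rms(x[baseline[0] : baseline[1]], fs, band)
    if base == 0:
        raise ConfigurationError("baseline phase has no pulse-band power; cannot verify occlusion")
    occ = _band_rms(x[occlusion[0] : occlusion[1]], fs, band)
    ratio = occ / base
    return OcclusionReport(complete=bool(ratio < threshold), residual_ratio=float(ratio))
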