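"""Three-stage filtering chain for magnetically sensed pulse waveforms.

Stage 1 is a constrained second-order IIR notch at the mains frequency
(zeros on the unit circle at the notch angle, poles at the same angle
inside it; the pole radius sets the bandwidth).  Stage 2 is a linear-phase
FIR low-pass at 30 Hz.  Stage 3 subtracts a moving-average DC/baseline
estimate.

Notch design convention
-----------------------
The notch transfer function is

    H(z) = b0 * (1 + (b1/b0) z^-1 + z^-2) / (1 + a0 z^-1 + a1 z^-2)

with ``b1 = -2 b0 cos(w0)``, ``a0 = b1``, ``a1 = 2 b0 - 1`` and

    b0 = 1 / (1 + beta),    beta = sqrt((1 - Gb^2)/Gb^2) * tan(pi * delta_f / fs)

where ``Gb^2 = 2^(A_b/3)`` is the magnitude-squared response at the two
bandwidth-edge frequencies ``f0 +- delta_f/2``.  A_b follows the
engineering convention that -3 dB is exactly the half-power point, so the
default design removes exactly 50% of the power of a band-edge sinusoid
and the closed form reduces to ``b0 = 1/(1 + tan(pi delta_f/fs))``; the
edge level in strict decibels is ``A_b * (10 log10 2)/3 ~= 1.0034 A_b``.

A widely circulated reference coefficient set for this filter
(a0 = b1 = 0.0302984, a1 = 0.9229900, b0 = 0.9614950 at fs = 200 Hz) is
consistent with this closed form only for delta_f ~= 2.55 Hz — not the
nominally quoted 5 Hz stopband — and places the spectral null at 50.50 Hz
rather than 50 Hz.  The default ``delta_f`` reproduces that coefficient
set's pole radius; both parameterizations are supported by setting the spec
fields explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .errors import DataError, ValidationError

__all__ = [
    "NotchDesignSpec",
    "BiquadNotch",
    "FIRLowpassSpec",
    "TABLE_COEFFICIENTS",
    "DELTA_F_REFERENCE",
    "design_notch",
    "frequency_response",
    "null_frequency",
    "apply_iir",
    "design_fir_lowpass",
    "apply_fir",
    "remove_dc",
    "filter_chain",
]

#: Bandwidth (Hz, at fs=200) for which the constrained closed form reproduces
#: the reference coefficient set's b0 = 0.9614950 at the default half-power
#: bandwidth level.
DELTA_F_REFERENCE = 2.5481102407223535


@dataclass(frozen=True)
class NotchDesignSpec:
    """Design parameters: centre f0, rate fs, bandwidth delta_f at level a_b (dB)."""

    f0: float = 50.0
    fs: float = 200.0
    delta_f: float = DELTA_F_REFERENCE
    a_b: float = -3.0

    def __post_init__(self) -> None:
        if not (0 < self.f0 < self.fs / 2):
            raise ValidationError(f"f0 must lie in (0, fs/2), got f0={self.f0}, fs={self.fs}")
        if not (0 < self.delta_f < self.fs / 2):
            raise ValidationError(f"delta_f must lie in (0, fs/2), got {self.delta_f}")
        if not self.a_b < 0:
            raise ValidationError(f"a_b must be negative (dB), got {self.a_b}")


@dataclass(frozen=True)
class BiquadNotch:
    """Coefficients of the constrained notch biquad (see module docstring)."""

    a0: float
    a1: float
    b0: float
    b1: float

    def __post_init__(self) -> None:
        num_dc = 2 * self.b0 + self.b1
        den_dc = 1 + self.a0 + self.a1
        if abs(num_dc / den_dc - 1) >= 1e-9:
            raise ValidationError(f"unity DC gain violated: H(1) = {num_dc / den_dc!r}")
        if abs(self.b1 / self.b0) >= 2:
            raise ValidationError("numerator zeros must lie on the unit circle (|b1/b0| < 2)")
        if abs(self.a1) >= 1:
            raise ValidationError(f"pole radius^2 = |a1| = {abs(self.a1)} must be < 1")
        roots = np.roots([1.0, self.a0, self.a1])
        if np.any(np.abs(roots) >= 1):
            raise ValidationError("denominator poles must lie strictly inside the unit circle")

    @property
    def ba(self) -> tuple[np.ndarray, np.ndarray]:
        """(numerator, denominator) in scipy convention."""
        return (np.array([self.b0, self.b1, self.b0]), np.array([1.0, self.a0, self.a1]))


#: Reference coefficient set at fs = 200 Hz (null at 50.50 Hz, -3 dB width ~2.55 Hz).
TABLE_COEFFICIENTS = BiquadNotch(a0=0.0302984, a1=0.9229900, b0=0.9614950, b1=0.0302984)


def design_notch(spec: NotchDesignSpec) -> BiquadNotch:
    """Design the constrained second-order notch for the given spec.

    The magnitude-squared response equals ``2^(a_b/3)`` (half power at the
    default -3 dB) exactly at the two bandwidth-edge frequencies
    ``f0 +- delta_f/2``; the DC gain is exactly 1.
    """
    w0 = 2 * math.pi * spec.f0 / spec.fs
    gb2 = 2.0 ** (spec.a_b / 3.0)
    beta = math.sqrt((1.0 - gb2) / gb2) * math.tan(math.pi * spec.delta_f / spec.fs)
    b0 = 1.0 / (1.0 + beta)
    a1 = 2.0 * b0 - 1.0
    b1 = -2.0 * b0 * math.cos(w0)
    a0 = b1
    return BiquadNotch(a0=a0, a1=a1, b0=b0, b1=b1)


def frequency_response(notch: BiquadNotch, f: float | np.ndarray, fs: float) -> complex | np.ndarray:
    """Complex gain H(e^{j 2 pi f / fs}) of the notch at frequency ``f`` (Hz)."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > fs / 2):
        raise ValidationError(f"frequency must lie in [0, fs/2] = [0, {fs / 2}], got {f}")
    z1 = np.exp(-2j * np.pi * f_arr / fs)  # z^-1 on the unit circle
    h = (notch.b0 + notch.b1 * z1 + notch.b0 * z1**2) / (1 + notch.a0 * z1 + notch.a1 * z1**2)
    return complex(h) if np.isscalar(f) or f_arr.ndim == 0 else h


def null_frequency(notch: BiquadNotch, fs: float) -> float:
    """Frequency (Hz) of the spectral zero, from the numerator zero angle."""
    return fs / (2 * math.pi) * math.acos(-notch.b1 / (2 * notch.b0))


def apply_iir(notch: BiquadNotch, x: np.ndarray) -> np.ndarray:
    """Causal direct-form filtering with zero initial state.

    Implements y[n] = b0 x[n] + b1 x[n-1] + b0 x[n-2] - a0 y[n-1] - a1 y[n-2].
    The first ~1 s of output carries the start-up transient and is flagged
    downstream rather than trimmed here (output length equals input length).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DataError("input samples must be finite")
    b, a = notch.ba
    return signal.lfilter(b, a, x)


@dataclass(frozen=True)
class FIRLowpassSpec:
    """Linear-phase windowed-sinc low-pass (Hamming window, unity DC gain)."""

    cutoff: float
    fs: float
    n_taps: int
    taps: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        taps = np.asarray(self.taps, dtype=float)
        object.__setattr__(self, "taps", taps)
        if self.cutoff >= self.fs / 2:
            raise ValidationError(f"cutoff {self.cutoff} Hz must be below Nyquist {self.fs / 2} Hz")
        if self.n_taps % 2 == 0:
            raise ValidationError(f"n_taps must be odd for a type-I linear-phase FIR, got {self.n_taps}")
        if taps.size != self.n_taps:
            raise ValidationError("taps length must equal n_taps")
        if not np.allclose(taps, taps[::-1], rtol=0, atol=1e-12):
            raise ValidationError("taps must be symmetric (linear phase)")
        if abs(taps.sum() - 1.0) > 1e-6:
            raise ValidationError(f"taps must sum to 1 (unity DC gain), got {taps.sum()!r}")


def design_fir_lowpass(cutoff: float = 30.0, fs: float = 200.0, n_taps: int = 101) -> FIRLowpassSpec:
    """Design the second-stage low-pass (windowed sinc, Hamming window)."""
    if n_taps % 2 == 0:
        raise ValidationError(f"n_taps must be odd, got {n_taps}")
    if not (0 < cutoff < fs / 2):
        raise ValidationError(f"cutoff must lie in (0, fs/2), got {cutoff}")
    taps = signal.firwin(n_taps, cutoff, fs=fs, window="hamming")
    return FIRLowpassSpec(cutoff=cutoff, fs=fs, n_taps=n_taps, taps=taps)


def apply_fir(spec: FIRLowpassSpec, x: np.ndarray) -> np.ndarray:
    """Filter with group-delay compensation; output aligned with input.

    Edge policy: reflect-pad by half the filter length at both ends, convolve,
    centre-crop back to the input length.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= spec.n_taps:
        raise DataError(f"series length {x.size} must exceed the filter length {spec.n_taps}")
    half = spec.n_taps // 2
    padded = np.pad(x, half, mode="reflect")
    return signal.fftconvolve(padded, spec.taps, mode="valid")


def remove_dc(x: np.ndarray, window: float = 10.0, fs: float = 200.0) -> np.ndarray:
    """Subtract a centred moving-average DC estimate over ``window`` seconds."""
    x = np.asarray(x, dtype=float)
    if window < 2.0:
        raise ValidationError(f"DC window must be >= 2 s, got {window}")
    w = int(round(window * fs))
    if w > x.size:
        raise DataError(f"DC window of {w} samples exceeds series length {x.size}")
    dc = ndimage.uniform_filter1d(x, size=w, mode="reflect")
    return x - dc


def filter_chain(
    x: np.ndarray,
    fs: float,
    notch: BiquadNotch | None = None,
    fir: FIRLowpassSpec | None = None,
    dc_window: float = 10.0,
) -> np.ndarray:
    """Full three-stage chain: notch -> FIR low-pass -> DC removal."""
    if notch is None:
        notch = design_notch(NotchDesignSpec(fs=fs))
    if fir is None:
        fir = design_fir_lowpass(fs=fs)
    return remove_dc(apply_fir(fir, apply_iir(notch, x)), window=dc_window, fs=fs)
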