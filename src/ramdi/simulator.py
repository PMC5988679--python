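"""Ground-truth simulator: dual-arm reactive-hyperaemia sessions and cohorts.

The session generator emulates what the measurement pipeline must cope with:
pulsatile beats at physiological heart rates (a stylized two-component beat,
not a hemodynamic model), a 5-min cuff occlusion that suppresses the
occluded-arm pulsation to a small residual, a post-release response (an
immediate flow surge plus a dilation bump peaking ~75 s after release),
mains interference, slow baseline drift, white sensor noise and occasional
motion-artifact bursts.  Every synthesized beat, the true amplitude envelope
and all artifact intervals are returned as annotations, so downstream
detection and index code can be scored against construction-time truth.

The cohort generator emulates the group structure of a two-group clinical
table (healthy controls vs type-2 diabetes): per-group covariate and
risk-score marginals (truncated log-normals matched by median/IQR, truncated
normals for mean/SD entries) and an index column linked to a latent risk
variable through a Gaussian copula, calibrated so the pooled population
Spearman correlation between the index and each risk score equals a target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sstats

from .errors import ValidationError
from .signal_model import (
    HIGH_RISK_CUTOFFS,
    DualArmRecording,
    PhaseAnnotation,
    SubjectProfile,
    validate_cohort,
)

__all__ = [
    "HyperaemiaResponse",
    "NoiseModel",
    "CohortSimSpec",
    "SessionAnnotations",
    "synth_beat",
    "synth_beat_train",
    "synth_session",
    "synth_repeatability_pair",
    "synth_cohort",
    "TruncLogNormal",
    "TruncNormal",
]


# ---------------------------------------------------------------------------
# Beat morphology and beat trains
# ---------------------------------------------------------------------------

def _beat_template(n: int) -> np.ndarray:
    """One-beat waveform on n samples: raised-cosine systolic peak plus a
    smaller diastolic shoulder, zero at both ends (C0-continuous when tiled),
    normalized to unit peak-to-trough amplitude."""
    u = np.arange(n) / n
    y = np.zeros(n)
    sys_on = (u >= 0.02) & (u <= 0.50)
    y[sys_on] += 0.5 * (1 - np.cos(2 * np.pi * (u[sys_on] - 0.02) / 0.48))
    # Dicrotic shoulder overlapping the systolic downslope, as in arterial
    # pulses: its standalone prominence stays < 5% of the beat amplitude so
    # it never competes with the systolic peak in detection.
    dia_on = (u >= 0.34) & (u <= 0.78)
    y[dia_on] += 0.22 * 0.5 * (1 - np.cos(2 * np.pi * (u[dia_on] - 0.34) / 0.44))
    return y / y.max()


def synth_beat(hr: float, amplitude: float, fs: float) -> np.ndarray:
    """One beat at ``hr`` bpm with the given peak-to-trough amplitude."""
    if not (30 <= hr <= 180):
        raise ValidationError(f"heart rate must be in [30, 180] bpm, got {hr}")
    n = max(2, int(round(60.0 / hr * fs)))
    if amplitude == 0:
        return np.zeros(n)
    return amplitude * _beat_template(n)


def synth_beat_train(
    duration_s: float,
    fs: float,
    hr_start: float,
    hr_end: float | None = None,
    amplitude=1.0,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Concatenated beats with linearly interpolated heart rate.

    ``amplitude`` may be a scalar or a callable of time (seconds) evaluated at
    each beat's peak.  ``jitter_sd`` is the relative SD of beat-to-beat period
    variation.  Returns ``(x, peak_times_s, hr_of_t)``.
    """
    if hr_end is None:
        hr_end = hr_start
    if rng is None:
        rng = np.random.default_rng(0)
    amp_fn = amplitude if callable(amplitude) else (lambda t: amplitude)

    def hr_of_t(t):
        return hr_start + (hr_end - hr_start) * np.clip(np.asarray(t) / duration_s, 0, 1)

    n_total = int(round(duration_s * fs))
    x = np.zeros(n_total)
    peak_times: list[float] = []
    t = 0.0
    while t < duration_s:
        hr_now = float(hr_of_t(t))
        period = 60.0 / hr_now
        if jitter_sd > 0:
            period *= max(0.5, 1.0 + jitter_sd * float(rng.standard_normal()))
        n = max(2, int(round(period * fs)))
        beat = _beat_template(n)
        peak_off = int(np.argmax(beat))
        t_peak = t + peak_off / fs
        a = float(amp_fn(t_peak))
        i0 = int(round(t * fs))
        seg = beat[: max(0, n_total - i0)] * a
        if seg.size == 0:
            break
        x[i0 : i0 + seg.size] += seg
        if i0 + peak_off < n_total:
            peak_times.append(t_peak)
        t += n / fs
    return x, np.asarray(peak_times), hr_of_t


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperaemiaResponse:
    """Post-release response: immediate flow surge + delayed dilation bump.

    The dilation bump is log-normal in time: unit height at ``time_to_peak``,
    falling to exp(-1/2) of the peak ``decay_tau`` seconds later.  The surge
    decays exponentially with ``surge_tau``.
    """

    flow_surge: float = 0.25          # fractional amplitude increase at release
    dilation_amplitude: float = 0.5   # fractional envelope increase at peak
    time_to_peak: float = 75.0        # s after release
    decay_tau: float = 40.0           # s
    surge_tau: float = 15.0           # s

    def __post_init__(self) -> None:
        for name in ("flow_surge", "dilation_amplitude", "time_to_peak", "decay_tau", "surge_tau"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def envelope_gain(self, tau) -> np.ndarray:
        """Multiplicative envelope factor as a function of time since release."""
        tau = np.asarray(tau, dtype=float)
        out = np.ones_like(tau)
        pos = tau > 0
        sigma = math.log(1.0 + self.decay_tau / self.time_to_peak)
        bump = np.zeros_like(tau)
        bump[pos] = np.exp(-np.log(tau[pos] / self.time_to_peak) ** 2 / (2 * sigma**2))
        surge = np.zeros_like(tau)
        surge[pos] = np.exp(-tau[pos] / self.surge_tau)
        out[pos] += self.dilation_amplitude * bump[pos] + self.flow_surge * surge[pos]
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Additive disturbances, amplitudes relative to the baseline pulse amplitude."""

    mains_amplitude: float = 0.5
    mains_freq: float = 50.0
    drift_amplitude: float = 0.3
    drift_period: float = 60.0
    motion_burst_rate: float = 0.2    # events per minute, per arm
    burst_gain: float = 10.0
    burst_duration_s: float = 3.0
    white_noise_sigma: float = 0.02

    def __post_init__(self) -> None:
        for name in ("mains_amplitude", "mains_freq", "drift_amplitude", "drift_period",
                     "motion_burst_rate", "burst_gain", "burst_duration_s", "white_noise_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def quiet(cls) -> "NoiseModel":
        """No disturbances at all (construction-truth testing)."""
        return cls(mains_amplitude=0, drift_amplitude=0, motion_burst_rate=0, white_noise_sigma=0)


@dataclass(frozen=True)
class SessionAnnotations:
    """Construction-time ground truth for one synthesized session."""

    beat_peak_times_s: np.ndarray          # shared by both arms (one heart)
    hr_bpm: float
    envelope_times_s: np.ndarray           # 1 Hz grid
    envelope_occluded: np.ndarray          # true peak-to-trough amplitude
    envelope_control: np.ndarray
    burst_intervals_occluded: list[tuple[float, float]]
    burst_intervals_control: list[tuple[float, float]]
    response: HyperaemiaResponse
    noise: NoiseModel
    occlusion_residual: float
    base_amplitude: float
    seed: int


def _motion_bursts(rng, n_total, fs, noise: NoiseModel, scale: float):
    """Random motion-artifact bursts: smoothed noise with a Hann on/off envelope."""
    x = np.zeros(n_total)
    intervals: list[tuple[float, float]] = []
    duration_min = n_total / fs / 60.0
    n_bursts = int(rng.poisson(noise.motion_burst_rate * duration_min))
    nb = max(4, int(round(noise.burst_duration_s * fs)))
    for _ in range(n_bursts):
        i0 = int(rng.integers(0, max(1, n_total - nb)))
        raw = rng.standard_normal(nb)
        raw = ndimage.uniform_filter1d(raw, size=max(1, int(fs / 8)))
        rms = float(np.sqrt(np.mean(raw**2)))
        if rms > 0:
            raw = raw / rms
        burst = noise.burst_gain * scale * 0.35 * raw * np.hanning(nb)
        x[i0 : i0 + nb] += burst
        intervals.append((i0 / fs, (i0 + nb) / fs))
    return x, sorted(intervals)


def synth_session(
    subject: SubjectProfile,
    resp: HyperaemiaResponse = HyperaemiaResponse(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    fs: float = 200.0,
    baseline_s: float = 330.0,
    occlusion_s: float = 300.0,
    release_s: float = 300.0,
    hr_bpm: float = 70.0,
    hr_jitter_sd: float = 0.02,
    base_amplitude: float = 1.0,
    occlusion_residual: float = 0.02,
) -> tuple[DualArmRecording, SessionAnnotations]:
    """Synthesize one dual-arm session with full ground-truth annotations.

    Both arms share one beat train (one heart) and the common-mode mains and
    drift disturbances; white noise and motion bursts are independent per arm.
    The occluded arm's pulse amplitude drops to ``occlusion_residual`` of
    baseline during occlusion and follows the hyperaemic response after
    release; the control arm is unaffected by the cuff.
    """
    if not (30 <= hr_bpm <= 180):
        raise ValidationError(f"hr_bpm must be in [30, 180], got {hr_bpm}")
    if resp.time_to_peak >= release_s:
        raise ValidationError("response time_to_peak must fall inside the release window")
    rng = np.random.default_rng(seed)
    duration = baseline_s + occlusion_s + release_s
    n_total = int(round(duration * fs))
    t_occ0, t_rel0 = baseline_s, baseline_s + occlusion_s
    A0 = base_amplitude

    def amp_occluded(t: float) -> float:
        if t < t_occ0:
            return A0
        if t < t_rel0:
            return A0 * occlusion_residual
        return A0 * float(resp.envelope_gain(np.array([t - t_rel0]))[0])

    def amp_control(t: float) -> float:
        return A0

    # One heart: the same seeded jitter stream schedules the beats of both
    # arms identically; only the amplitude profile differs.
    beat_seed = int(rng.integers(2**31))
    occ_clean, peak_times, _ = synth_beat_train(
        duration, fs, hr_bpm, amplitude=amp_occluded, jitter_sd=hr_jitter_sd,
        rng=np.random.default_rng(beat_seed),
    )
    ctl_clean, _, _ = synth_beat_train(
        duration, fs, hr_bpm, amplitude=amp_control, jitter_sd=hr_jitter_sd,
        rng=np.random.default_rng(beat_seed),
    )

    t = np.arange(n_total) / fs
    mains = noise.mains_amplitude * A0 * np.sin(
        2 * np.pi * noise.mains_freq * t + rng.uniform(0, 2 * np.pi)
    )
    drift = (
        noise.drift_amplitude * A0 * np.sin(2 * np.pi * t / noise.drift_period + rng.uniform(0, 2 * np.pi))
        if noise.drift_amplitude > 0
        else 0.0
    )
    white_occ = noise.white_noise_sigma * A0 * rng.standard_normal(n_total)
    white_ctl = noise.white_noise_sigma * A0 * rng.standard_normal(n_total)
    bursts_occ, iv_occ = _motion_bursts(rng, n_total, fs, noise, A0)
    bursts_ctl, iv_ctl = _motion_bursts(rng, n_total, fs, noise, A0)

    occluded = occ_clean + mains + drift + white_occ + bursts_occ
    control = ctl_clean + mains + drift + white_ctl + bursts_ctl

    phases = PhaseAnnotation.from_seconds((0, baseline_s), (baseline_s, t_rel0), (t_rel0, duration), fs)
    rec = DualArmRecording(fs=fs, occluded_arm=occluded, control_arm=control,
                           phases=phases, subject=subject)

    env_t = np.arange(0.0, duration, 1.0)
    ann = SessionAnnotations(
        beat_peak_times_s=peak_times,
        hr_bpm=hr_bpm,
        envelope_times_s=env_t,
        envelope_occluded=np.array([amp_occluded(tt) for tt in env_t]),
        envelope_control=np.full(env_t.size, A0),
        burst_intervals_occluded=iv_occ,
        burst_intervals_control=iv_ctl,
        response=resp,
        noise=noise,
        occlusion_residual=occlusion_residual,
        base_amplitude=base_amplitude,
        seed=seed,
    )
    return rec, ann


def synth_repeatability_pair(
    subject: SubjectProfile,
    resp: HyperaemiaResponse = HyperaemiaResponse(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    **session_kwargs,
):
    """Two sessions with identical subject/response parameters and independent
    noise realizations (seeds ``seed`` and ``seed + 1``)."""
    first = synth_session(subject, resp, noise, seed=seed, **session_kwargs)
    second = synth_session(subject, resp, noise, seed=seed + 1, **session_kwargs)
    return first, second


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

_Z75 = sstats.norm.ppf(0.75)


class TruncLogNormal:
    """Log-normal matched to a median/IQR summary, truncated to [lo, hi]."""

    def __init__(self, median: float, iqr: float, lo: float, hi: float):
        if not (0 < lo < median < hi):
            raise ValidationError(f"require 0 < lo < median < hi, got {lo}, {median}, {hi}")
        self.m = math.log(median)
        self.s = math.asinh(iqr / (2.0 * median)) / _Z75
        a = (math.log(lo) - self.m) / self.s
        b = (math.log(hi) - self.m) / self.s
        self._tn = sstats.truncnorm(a, b, loc=self.m, scale=self.s)

    def ppf(self, u):
        return np.exp(self._tn.ppf(u))

    def cdf(self, y):
        return self._tn.cdf(np.log(np.maximum(np.asarray(y, dtype=float), 1e-300)))


class TruncNormal:
    """Normal matched to a mean/SD summary, truncated to [lo, hi]."""

    def __init__(self, mean: float, sd: float, lo: float, hi: float):
        self._tn = sstats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)

    def ppf(self, u):
        return self._tn.ppf(u)

    def cdf(self, y):
        return self._tn.cdf(y)


class _Mixture:
    """Two-component mixture with interpolated inverse CDF."""

    def __init__(self, components, weights, grid_n: int = 4001):
        self.components = components
        self.weights = np.asarray(weights, dtype=float) / np.sum(weights)
        lo = min(float(c.ppf(1e-6)) for c in components)
        hi = max(float(c.ppf(1 - 1e-6)) for c in components)
        self._grid = np.linspace(lo, hi, grid_n)
        self._cdf = self.cdf(self._grid)

    def cdf(self, y):
        y = np.asarray(y, dtype=float)
        return sum(w * c.cdf(y) for w, c in zip(self.weights, self.components))

    def ppf(self, u):
        return np.interp(np.asarray(u, dtype=float), self._cdf, self._grid)


#: Per-group marginal summaries emulating a two-group clinical cohort
#: (healthy volunteers vs type-2 diabetes).  Continuous entries are either
#: (median, IQR, min, max) -> truncated log-normal, or mean/SD -> truncated
#: normal on a plausible range.
def _default_marginals() -> dict:
    return {
        "control": {
            "age": TruncLogNormal(27.5, 9, 22, 55),
            "bmi": TruncLogNormal(21.6, 6.8, 17.6, 43.3),
            "sbp": TruncNormal(115.5, 11.3, 90, 160),
            "dbp": TruncNormal(67.4, 9.1, 45, 95),
            "hba1c": TruncLogNormal(5.4, 0.3, 5.0, 6.4),
            "cimt_avg": TruncLogNormal(0.5, 0.1, 0.4, 0.6),
            "male_fraction": 0.34,
            "ra_mdi": TruncLogNormal(0.28, 0.13, 0.03, 0.81),
            "fhs10_lipids": TruncLogNormal(0.9, 0.8, 0.2, 7.5),
            "fhs10_bmi": TruncLogNormal(0.9, 1.0, 0.2, 13.7),
            "fhs30_lipids_full": TruncLogNormal(6, 5, 1, 28),
            "fhs30_lipids_hard": TruncLogNormal(3, 2, 0.5, 16),
            "fhs30_bmi_full": TruncLogNormal(5, 5, 1, 44),
            "fhs30_bmi_hard": TruncLogNormal(2, 3, 0.3, 30),
            "advance": None,
            "ukpds": None,
        },
        "t2dm": {
            "age": TruncLogNormal(55, 15, 30, 69),
            "bmi": TruncLogNormal(26.3, 4.5, 17.4, 38.6),
            "sbp": TruncNormal(133.5, 14.5, 100, 180),
            "dbp": TruncNormal(75.7, 9.6, 50, 105),
            "hba1c": TruncLogNormal(7.8, 2.0, 6.2, 13.1),
            "cimt_avg": TruncLogNormal(0.7, 0.2, 0.5, 1.0),
            "male_fraction": 0.522,
            "ra_mdi": TruncLogNormal(0.76, 0.46, 0.22, 2.72),
            "fhs10_lipids": TruncLogNormal(18.1, 14.4, 3, 30),
            "fhs10_bmi": TruncLogNormal(24.15, 15.3, 1.9, 30),
            "fhs30_lipids_full": TruncLogNormal(65.5, 19, 16, 87),
            "fhs30_lipids_hard": TruncLogNormal(46, 21, 8, 81),
            "fhs30_bmi_full": TruncLogNormal(73, 18, 11, 89),
            "fhs30_bmi_hard": TruncLogNormal(58, 23, 6, 84),
            "advance": TruncLogNormal(3, 4, 0.2, 13),
            "ukpds": TruncLogNormal(11, 28, 1, 52),
        },
    }


_SCORE_COLUMNS = [
    "fhs10_lipids", "fhs10_bmi",
    "fhs30_lipids_full", "fhs30_lipids_hard", "fhs30_bmi_full", "fhs30_bmi_hard",
]
_PRIMARY_SCORE = "fhs10_lipids"
#: Within-group rank correlation of covariates with the latent risk driver.
_COVARIATE_LINKS = {"age": 0.5, "bmi": 0.4, "sbp": 0.4, "dbp": 0.3, "hba1c": 0.7, "cimt_avg": 0.6}


@dataclass(frozen=True)
class CohortSimSpec:
    """Cohort generator spec: group sizes, marginals and the index-risk link.

    ``link_strength`` is the target pooled population Spearman correlation
    between the generated index column and each risk score.
    """

    n_control: int = 50
    n_t2dm: int = 46
    link_strength: float = 0.70
    seed: int = 0
    marginals: dict = field(default_factory=_default_marginals)

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_t2dm <= 0:
            raise ValidationError("group counts must be positive")
        if not (-1.0 <= self.link_strength <= 1.0):
            raise ValidationError(
                f"target rank correlation must lie in [-1, 1], got {self.link_strength}"
            )


def synth_cohort(spec: CohortSimSpec, seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table plus ground truth.

    A Gaussian copula links the index to a latent risk driver: with latent
    pair correlation r = 2 sin(pi * rho / 6), two standard-normal scores
    mapped through strictly monotone continuous marginal transforms have
    pooled population Spearman correlation exactly rho.  Risk scores are
    monotone transforms of the same latent driver, so each score attains the
    same target correlation with the index.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    marg = spec.marginals
    rho = spec.link_strength
    r = 2.0 * math.sin(math.pi * rho / 6.0)

    n = spec.n_control + spec.n_t2dm
    groups = np.array(["control"] * spec.n_control + ["t2dm"] * spec.n_t2dm)
    weights = [spec.n_control / n, spec.n_t2dm / n]

    # Primary score drawn from its exact per-group marginal.
    u_prim = rng.uniform(size=n)
    primary = np.empty(n)
    for g in ("control", "t2dm"):
        sel = groups == g
        primary[sel] = marg[g][_PRIMARY_SCORE].ppf(u_prim[sel])

    # Latent risk driver = pooled normal score of the primary risk score.
    pooled_prim = _Mixture([marg["control"][_PRIMARY_SCORE], marg["t2dm"][_PRIMARY_SCORE]], weights)
    z_latent = sstats.norm.ppf(np.clip(pooled_prim.cdf(primary), 1e-12, 1 - 1e-12))

    # Index column through the copula on the pooled index marginal.
    eps = rng.standard_normal(n)
    z_index = r * z_latent + math.sqrt(max(0.0, 1.0 - r * r)) * eps
    pooled_mdi = _Mixture([marg["control"]["ra_mdi"], marg["t2dm"]["ra_mdi"]], weights)
    ra_mdi = pooled_mdi.ppf(sstats.norm.cdf(z_index))

    data: dict = {
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "group": groups,
        "ra_mdi": ra_mdi,
        _PRIMARY_SCORE: primary,
    }

    # Other pooled scores: monotone transforms of the latent driver.
    u_latent = sstats.norm.cdf(z_latent)
    for col in _SCORE_COLUMNS:
        if col == _PRIMARY_SCORE:
            continue
        pooled = _Mixture([marg["control"][col], marg["t2dm"][col]], weights)
        data[col] = pooled.ppf(u_latent)

    # Diabetes-only engines: exact t2dm marginal, rank-aligned within group.
    t2 = groups == "t2dm"
    u_within_t2 = marg["t2dm"][_PRIMARY_SCORE].cdf(primary[t2])
    for col in ("advance", "ukpds"):
        vals = np.full(n, np.nan)
        if marg["t2dm"][col] is not None:
            vals[t2] = marg["t2dm"][col].ppf(np.clip(u_within_t2, 1e-12, 1 - 1e-12))
        data[col] = vals

    # Covariates: exact per-group marginals, partially rank-linked to risk.
    z_within = np.empty(n)
    for g in ("control", "t2dm"):
        sel = groups == g
        z_within[sel] = sstats.norm.ppf(
            np.clip(marg[g][_PRIMARY_SCORE].cdf(primary[sel]), 1e-12, 1 - 1e-12)
        )
    for col, link in _COVARIATE_LINKS.items():
        eta = rng.standard_normal(n)
        z_cov = link * z_within + math.sqrt(1 - link * link) * eta
        vals = np.empty(n)
        for g in ("control", "t2dm"):
            sel = groups == g
            vals[sel] = marg[g][col].ppf(sstats.norm.cdf(z_cov[sel]))
        data[col] = vals

    sex = np.empty(n, dtype=object)
    for g in ("control", "t2dm"):
        sel = groups == g
        sex[sel] = np.where(rng.uniform(size=int(sel.sum())) < marg[g]["male_fraction"], "male", "female")
    data["sex"] = sex

    for score, cutoff in HIGH_RISK_CUTOFFS.items():
        data[f"high_risk_{score}"] = (np.asarray(data[score]) >= cutoff).astype(int)

    df = pd.DataFrame(data)
    order = ["subject_id", "group", "ra_mdi", "age", "sex", "bmi", "sbp", "dbp", "hba1c", "cimt_avg"]
    df = df[order + [c for c in df.columns if c not in order]]
    validate_cohort(df)
    truth = {
        "target_rho": rho,
        "copula_r": r,
        "z_latent": z_latent,
        "z_index": z_index,
        "n_control": spec.n_control,
        "n_t2dm": spec.n_t2dm,
    }
    return df, truth
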