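"""Phase summaries and the radial-artery maximum distensibility index.

The raw index is the control-normalized maximum relative increase of the
pulse-amplitude envelope over the 5-minute post-release window:

    raw = max over release windows t of [ E_occ(t)/B_occ  -  E_ctl(t)/B_ctl ],
    floored at 0,

where E is the windowed envelope on each arm and B the median baseline-phase
envelope of the same arm.  Subtracting the control-arm ratio cancels slow
common-mode gain and perfusion drift; a session with no hyperaemic response
scores ~0.  An alternative index built from per-beat area under the curve
(AUC) ratios is selectable via configuration.

A multiplicative covariate adjustment (sex, mean arterial pressure, age,
resting-vs-release heart rate) is available but ships disabled: no published
coefficients exist, so all exponents default to zero and the adjustment
factor to exactly 1 for the reference profile.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import filters, pulse_analysis as pa
from .errors import ComputationError, ConfigurationError
from .signal_model import DualArmRecording, SubjectProfile

__all__ = [
    "NotchConfig",
    "FIRConfig",
    "PipelineConfig",
    "PhaseSummary",
    "MDIResult",
    "beat_auc",
    "summarize_phase",
    "raw_distensibility",
    "covariate_adjust",
    "compute_ra_mdi",
]

PHASE_NAMES = {"baseline": "resting", "occlusion": "occlusion", "release": "relaxation"}


@dataclass(frozen=True)
class NotchConfig:
    f0_hz: float = 50.0
    delta_f_hz: float = filters.DELTA_F_REFERENCE
    a_b_db: float = -3.0


@dataclass(frozen=True)
class FIRConfig:
    cutoff_hz: float = 30.0
    n_taps: int = 101


@dataclass(frozen=True)
class GateConfig:
    rms_lo: float = 0.2
    rms_hi: float = 5.0
    # Short RMS windows resolve brief motion bursts that a longer average
    # would dilute below the upper bound.
    rms_window_s: float = 2.0


@dataclass(frozen=True)
class PeaksConfig:
    refractory_s: float = pa.DEFAULT_REFRACTORY_S
    min_prominence: float = pa.DEFAULT_MIN_PROMINENCE


@dataclass(frozen=True)
class AdjustConfig:
    enabled: bool = False
    gamma_map: float = 0.0
    gamma_age: float = 0.0
    gamma_hr: float = 0.0
    sex_factor_female: float = 1.0
    map_ref: float = 93.0   # mmHg, reference mean arterial pressure
    age_ref: float = 40.0   # years


@dataclass(frozen=True)
class PipelineConfig:
    notch: NotchConfig = field(default_factory=NotchConfig)
    fir: FIRConfig = field(default_factory=FIRConfig)
    dc_window_s: float = 10.0
    gate: GateConfig = field(default_factory=GateConfig)
    peaks: PeaksConfig = field(default_factory=PeaksConfig)
    envelope_window_s: float = 30.0
    occlusion_threshold: float = pa.DEFAULT_OCCLUSION_THRESHOLD
    index_mode: str = "envelope"  # "envelope" | "auc"
    adjust: AdjustConfig = field(default_factory=AdjustConfig)
    transient_s: float = 1.0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        """Build from a (possibly partial) nested dict, e.g. parsed JSON.

        Accepts both nested sections ({"notch": {"f0_hz": 60}}) and flat
        dotted keys ({"notch.f0_hz": 60}).
        """
        nested: dict = {}
        for k, v in d.items():
            if "." in k:
                sec, leaf = k.split(".", 1)
                nested.setdefault(sec, {})[leaf] = v
            else:
                nested[k] = v
        kw: dict = {}
        sections = {"notch": NotchConfig, "fir": FIRConfig, "gate": GateConfig,
                    "peaks": PeaksConfig, "adjust": AdjustConfig}
        alias = {"dc": {"window_s": "dc_window_s"},
                 "envelope": {"window_s": "envelope_window_s"},
                 "occlusion": {"threshold": "occlusion_threshold"},
                 "index": {"mode": "index_mode"}}
        for sec, val in nested.items():
            if sec in sections:
                kw[sec] = sections[sec](**val)
            elif sec in alias:
                for leaf, target in alias[sec].items():
                    if leaf in val:
                        kw[target] = val[leaf]
            else:
                kw[sec] = val
        return cls(**kw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PhaseSummary:
    """Aggregates over valid windows fully inside one protocol phase."""

    phase: str                  # resting | occlusion | relaxation
    mean_hr: float              # bpm; NaN when unavailable or valid_fraction < 0.5
    median_envelope: float      # unitless flux; NaN when no envelope windows
    mean_beat_auc: float        # flux * seconds; NaN when no complete beats
    valid_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.valid_fraction <= 1.0):
            raise ValueError(f"valid_fraction must be in [0, 1], got {self.valid_fraction}")


@dataclass(frozen=True)
class MDIResult:
    raw_index: float
    ra_mdi: float
    adjustment_factor: float
    phase_summaries: dict[str, dict[str, PhaseSummary]]  # arm -> phase -> summary
    occlusion: pa.OcclusionReport
    qc_flags: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "raw_index": self.raw_index,
            "ra_mdi": self.ra_mdi,
            "adjustment_factor": self.adjustment_factor,
            "occlusion": asdict(self.occlusion),
            "phase_summaries": {
                arm: {ph: asdict(s) for ph, s in by_phase.items()}
                for arm, by_phase in self.phase_summaries.items()
            },
            "qc_flags": list(self.qc_flags),
        }


def beat_auc(x: np.ndarray, peaks: pa.PulsePeakSeries, fs: float) -> np.ndarray:
    """Trapezoidal area of |x| per beat, between consecutive beat onsets.

    Beat onsets are the troughs between consecutive detected peaks, so beat
    *k* spans trough(k) .. trough(k+1); the result has len(peaks) - 2 areas
    (the first and last partial beats are dropped).  Units: flux * seconds.
    """
    x = np.asarray(x, dtype=float)
    if len(peaks) < 2:
        return np.empty(0)
    idx = peaks.peak_indices
    onsets = np.array(
        [idx[i] + int(np.argmin(x[idx[i] : idx[i + 1] + 1])) for i in range(idx.size - 1)]
    )
    if onsets.size < 2:
        return np.empty(0)
    return np.array(
        [float(np.trapezoid(np.abs(x[a : b + 1]), dx=1.0 / fs)) for a, b in zip(onsets[:-1], onsets[1:])]
    )


def summarize_phase(
    phase_interval: tuple[int, int],
    phase_name: str,
    fs: float,
    mask: pa.ValidityMask,
    hr: pa.HeartRateSeries,
    env: pa.EnvelopeTrend,
    beat_aucs: np.ndarray | None = None,
    beat_auc_times: np.ndarray | None = None,
) -> PhaseSummary:
    """Aggregate heart rate / envelope / beat AUC over one phase.

    Windows straddling the phase boundary belong to no phase and are ignored.
    Mean heart rate is reported only when at least half the phase samples are
    valid.
    """
    lo_s, hi_s = phase_interval[0] / fs, phase_interval[1] / fs
    valid_fraction = mask.fraction_valid(phase_interval)

    half_hr = hr.window_s / 2 if hr.centers_s.size else 0.0
    in_phase = (
        (hr.centers_s - half_hr >= lo_s - 1e-9) & (hr.centers_s + half_hr <= hi_s + 1e-9)
        if hr.centers_s.size
        else np.empty(0, bool)
    )
    hr_vals = hr.bpm[in_phase & hr.valid] if hr.centers_s.size else np.empty(0)
    mean_hr = float(np.mean(hr_vals)) if hr_vals.size and valid_fraction >= 0.5 else float("nan")

    env_phase = env.restrict((lo_s, hi_s))
    median_env = float(np.median(env_phase.values)) if env_phase.values.size else float("nan")

    mean_auc = float("nan")
    if beat_aucs is not None and beat_auc_times is not None and beat_aucs.size:
        sel = (beat_auc_times >= lo_s) & (beat_auc_times < hi_s)
        if np.any(sel):
            mean_auc = float(np.mean(beat_aucs[sel]))

    return PhaseSummary(
        phase=PHASE_NAMES.get(phase_name, phase_name),
        mean_hr=mean_hr,
        median_envelope=median_env,
        mean_beat_auc=mean_auc,
        valid_fraction=valid_fraction,
    )


def raw_distensibility(
    baseline_occluded: PhaseSummary,
    release_env_occluded: pa.EnvelopeTrend,
    baseline_control: PhaseSummary | None,
    release_env_control: pa.EnvelopeTrend | None,
) -> tuple[float, list[str]]:
    """Control-normalized maximum relative envelope increase over release.

    Returns (raw_index, qc_flags).  If the control arm is unusable the control
    ratio term is taken as 1 and a ``control_unusable`` flag is set.
    """
    flags: list[str] = []
    b_occ = baseline_occluded.median_envelope
    if not np.isfinite(b_occ) or b_occ <= 0:
        raise ComputationError("raw_distensibility: occluded-arm baseline envelope is zero or invalid")
    if release_env_occluded.values.size == 0:
        raise ComputationError("raw_distensibility: no valid release-phase envelope on the occluded arm")

    occ_ratio = release_env_occluded.values / b_occ
    centers = release_env_occluded.centers_s

    control_ok = (
        baseline_control is not None
        and release_env_control is not None
        and np.isfinite(baseline_control.median_envelope)
        and baseline_control.median_envelope > 0
        and release_env_control.values.size > 0
    )
    if control_ok:
        ctl_at = dict(zip(np.round(release_env_control.centers_s, 6), release_env_control.values))
        ctl_ratio = np.array(
            [ctl_at.get(c, np.nan) for c in np.round(centers, 6)]
        ) / baseline_control.median_envelope
        missing = ~np.isfinite(ctl_ratio)
        ctl_ratio[missing] = 1.0  # windows gated out on the control arm only
        if missing.all():
            control_ok = False
    if not control_ok:
        ctl_ratio = np.ones_like(occ_ratio)
        flags.append("control_unusable")

    raw = max(0.0, float(np.max(occ_ratio - ctl_ratio)))
    return raw, flags


def covariate_adjust(
    raw: float,
    subject: SubjectProfile,
    phase_summaries: dict[str, PhaseSummary],
    cfg: AdjustConfig = AdjustConfig(),
) -> tuple[float, float, list[str]]:
    """Multiplicative covariate/heart-rate adjustment of the raw index.

    factor = g_sex * (MAP_ref/MAP)^gamma_map * (age_ref/age)^gamma_age
             * (HR_rest/HR_release)^gamma_hr

    The reference profile (male, MAP = map_ref, age = age_ref, equal resting
    and release heart rates) has factor exactly 1.  A missing covariate makes
    the adjustment unavailable: the raw index is returned with an
    ``unadjusted`` flag rather than a silently assumed default.
    """
    if not cfg.enabled:
        return raw, 1.0, []
    hr_rest = phase_summaries["resting"].mean_hr
    hr_relax = phase_summaries["relaxation"].mean_hr
    missing = (
        subject.sex is None
        or subject.age is None
        or subject.map_mmHg is None
        or not np.isfinite(hr_rest)
        or not np.isfinite(hr_relax)
    )
    if missing:
        return raw, 1.0, ["unadjusted"]
    g_sex = cfg.sex_factor_female if subject.sex == "female" else 1.0
    factor = (
        g_sex
        * (cfg.map_ref / subject.map_mmHg) ** cfg.gamma_map
        * (cfg.age_ref / subject.age) ** cfg.gamma_age
        * (hr_rest / hr_relax) ** cfg.gamma_hr
    )
    if not (np.isfinite(factor) and factor > 0):
        return raw, 1.0, ["unadjusted"]
    return raw * factor, float(factor), []


def compute_ra_mdi(rec: DualArmRecording, config: PipelineConfig | None = None) -> MDIResult:
    """Run the full measurement chain on a dual-arm recording.

    Stages: three-stage filtering on each arm, RMS artifact gating against the
    baseline phase, beat detection, heart-rate and envelope trends, occlusion
    verification, raw index over the release window, covariate adjustment.
    Deterministic given the recording and configuration.
    """
    cfg = config or PipelineConfig()
    fs = rec.fs
    notch = filters.design_notch(
        filters.NotchDesignSpec(f0=cfg.notch.f0_hz, fs=fs, delta_f=cfg.notch.delta_f_hz, a_b=cfg.notch.a_b_db)
    )
    fir = filters.design_fir_lowpass(cutoff=cfg.fir.cutoff_hz, fs=fs, n_taps=cfg.fir.n_taps)

    arms: dict[str, dict] = {}
    for arm in ("occluded", "control"):
        x = filters.filter_chain(rec.arm(arm), fs, notch=notch, fir=fir, dc_window=cfg.dc_window_s)
        rms = pa.rms_series(x, window=cfg.gate.rms_window_s, fs=fs)
        mask = pa.gate_invalid(
            x, rms, bounds=(cfg.gate.rms_lo, cfg.gate.rms_hi), baseline=rec.phases["baseline"], fs=fs
        )
        pa.mark_transient(mask, fs, cfg.transient_s)
        peaks = pa.detect_peaks(
            x,
            fs,
            mask=mask,
            min_prominence=cfg.peaks.min_prominence,
            refractory_s=cfg.peaks.refractory_s,
            baseline=rec.phases["baseline"],
        )
        if arm == "occluded" and len(peaks) == 0:
            raise ComputationError("peak detection: no beats found on the occluded arm")
        hr = pa.heart_rate(peaks, n_samples=x.size)
        env = pa.pulse_envelope(x, peaks, window=cfg.envelope_window_s, mask=mask)
        aucs = beat_auc(x, peaks, fs)
        auc_times = peaks.peak_indices[1 : 1 + aucs.size] / fs if aucs.size else np.empty(0)
        summaries = {
            PHASE_NAMES[name]: summarize_phase(
                interval, name, fs, mask, hr, env, beat_aucs=aucs, beat_auc_times=auc_times
            )
            for name, interval in rec.phases.items()
        }
        arms[arm] = {"x": x, "mask": mask, "peaks": peaks, "hr": hr, "env": env,
                     "aucs": aucs, "auc_times": auc_times, "summaries": summaries}

    qc: list[str] = []
    occ_report = pa.verify_occlusion(
        arms["occluded"]["x"],
        rec.phases["baseline"],
        rec.phases["occlusion"],
        fs,
        threshold=cfg.occlusion_threshold,
    )
    if not occ_report.complete:
        qc.append("occlusion_incomplete")

    release_s = tuple(i / fs for i in rec.phases["release"])
    baseline_s = tuple(i / fs for i in rec.phases["baseline"])
    for arm in ("occluded", "control"):
        for phase_key in ("resting", "relaxation"):
            if arms[arm]["summaries"][phase_key].valid_fraction < 0.5 and "low_valid_fraction" not in qc:
                qc.append("low_valid_fraction")

    if cfg.index_mode == "envelope":
        occ_env_rel = arms["occluded"]["env"].restrict(release_s)
        ctl_env_rel = arms["control"]["env"].restrict(release_s)
        raw, flags = raw_distensibility(
            arms["occluded"]["summaries"]["resting"],
            occ_env_rel,
            arms["control"]["summaries"]["resting"],
            ctl_env_rel,
        )
    elif cfg.index_mode == "auc":
        raw, flags = _auc_index(arms, baseline_s, release_s, cfg)
    else:
        raise ConfigurationError(f"unknown index mode {cfg.index_mode!r}")
    qc.extend(f for f in flags if f not in qc)

    ra_mdi, factor, adj_flags = covariate_adjust(
        raw, rec.subject, arms["occluded"]["summaries"], cfg.adjust
    )
    qc.extend(f for f in adj_flags if f not in qc)

    return MDIResult(
        raw_index=raw,
        ra_mdi=ra_mdi,
        adjustment_factor=factor,
        phase_summaries={arm: arms[arm]["summaries"] for arm in arms},
        occlusion=occ_report,
        qc_flags=tuple(qc),
    )


def _auc_index(arms: dict, baseline_s, release_s, cfg: PipelineConfig) -> tuple[float, list[str]]:
    """Alternative index: windowed mean beat-AUC ratios instead of envelopes."""
    flags: list[str] = []

    def windowed_auc(arm: str, interval_s) -> pa.EnvelopeTrend:
        aucs, times = arms[arm]["aucs"], arms[arm]["auc_times"]
        grid_w = cfg.envelope_window_s
        lo, hi = interval_s
        centers, values = [], []
        c = lo + grid_w / 2
        while c + grid_w / 2 <= hi + 1e-9:
            sel = (times >= c - grid_w / 2) & (times < c + grid_w / 2)
            if np.count_nonzero(sel) >= 3:
                centers.append(c)
                values.append(float(np.mean(aucs[sel])))
            c += grid_w / 2
        return pa.EnvelopeTrend(np.array(centers), np.array(values), grid_w)

    base_occ = windowed_auc("occluded", baseline_s)
    rel_occ = windowed_auc("occluded", release_s)
    base_ctl = windowed_auc("control", baseline_s)
    rel_ctl = windowed_auc("control", release_s)
    if base_occ.values.size == 0 or rel_occ.values.size == 0:
        raise ComputationError("auc index: insufficient beats on the occluded arm")
    b_occ = float(np.median(base_occ.values))
    occ_ratio = rel_occ.values / b_occ
    if base_ctl.values.size and rel_ctl.values.size:
        b_ctl = float(np.median(base_ctl.values))
        ctl_at = dict(zip(np.round(rel_ctl.centers_s, 6), rel_ctl.values / b_ctl))
        ctl_ratio = np.array([ctl_at.get(c, 1.0) for c in np.round(rel_occ.centers_s, 6)])
    else:
        ctl_ratio = np.ones_like(occ_ratio)
        flags.append("control_unusable")
    return max(0.0, float(np.max(occ_ratio - ctl_ratio))), flags
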