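"""Domain model and I/O for dual-arm reactive-hyperaemia pulse recordings.

A measurement session records the magnetically sensed radial-artery pulse on
both wrists while a blood-pressure cuff occludes one arm: ~5 min of baseline,
~5 min of supra-systolic occlusion, and ~5 min after cuff release.  Signals
are stored as unitless flux amplitude sampled uniformly (200 Hz by default);
time is serialized in seconds and converted to 0-based, half-open sample-index
intervals internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "SubjectProfile",
    "PhaseAnnotation",
    "DualArmRecording",
    "mean_arterial_pressure",
    "read_recording",
    "write_recording",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "COHORT_SCORE_COLUMNS",
    "HIGH_RISK_CUTOFFS",
]

SEXES = ("male", "female")
GROUPS = ("control", "t2dm", "unknown")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject covariates used for the index adjustment.

    Covariates may be missing (``None``); downstream adjustment is then
    skipped and the result carries an ``unadjusted`` QC flag.
    """

    subject_id: str
    age: float | None = None          # years
    sex: str | None = None            # "male" | "female"
    sbp: float | None = None          # systolic blood pressure, mmHg
    dbp: float | None = None          # diastolic blood pressure, mmHg
    bmi: float | None = None          # kg/m^2
    group: str = "unknown"

    def __post_init__(self) -> None:
        if self.age is not None and not (18 <= self.age <= 100):
            raise ValidationError(f"age must be in [18, 100], got {self.age}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if (self.sbp is None) != (self.dbp is None):
            raise ValidationError("sbp and dbp must be given together")
        if self.sbp is not None:
            if not (self.sbp > self.dbp > 0):
                raise ValidationError(
                    f"pressures must satisfy sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}"
                )
        if self.bmi is not None and not (10 < self.bmi < 70):
            raise ValidationError(f"bmi must be in (10, 70), got {self.bmi}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def map_mmHg(self) -> float | None:
        if self.sbp is None or self.dbp is None:
            return None
        return mean_arterial_pressure(self.sbp, self.dbp)


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """Mean arterial pressure by the clinical convention dbp + (sbp - dbp)/3."""
    if not (sbp > dbp > 0):
        raise ValidationError(f"require sbp > dbp > 0, got sbp={sbp}, dbp={dbp}")
    return dbp + (sbp - dbp) / 3.0


# Nominal phase durations (seconds) and the default relative tolerance on them.
BASELINE_RANGE_S = (300.0, 360.0)   # protocol: 5-6 min
OCCLUSION_S = 300.0                 # protocol: 5 min
RELEASE_S = 300.0                   # protocol: 5 min
DEFAULT_DURATION_TOL = 0.10


@dataclass(frozen=True)
class PhaseAnnotation:
    """Half-open sample-index intervals for baseline, occlusion and release."""

    baseline: tuple[int, int]
    occlusion: tuple[int, int]
    release: tuple[int, int]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.items():
            if not (0 <= lo < hi):
                raise ValidationError(f"{name} interval must satisfy 0 <= start < end, got [{lo}, {hi})")
        if not (self.baseline[1] <= self.occlusion[0] and self.occlusion[1] <= self.release[0]):
            raise ValidationError(
                "phase intervals must be ordered baseline < occlusion < release without overlap"
            )

    def items(self) -> list[tuple[str, tuple[int, int]]]:
        return [("baseline", self.baseline), ("occlusion", self.occlusion), ("release", self.release)]

    def __getitem__(self, name: str) -> tuple[int, int]:
        return dict(self.items())[name]

    @property
    def end(self) -> int:
        return self.release[1]

    def durations_s(self, fs: float) -> dict[str, float]:
        return {name: (hi - lo) / fs for name, (lo, hi) in self.items()}

    def validate_durations(self, fs: float, tol: float = DEFAULT_DURATION_TOL) -> None:
        """Check protocol durations: baseline 5-6 min, occlusion/release ~5 min (relative tol)."""
        d = self.durations_s(fs)
        lo, hi = BASELINE_RANGE_S
        if not (lo * (1 - tol) <= d["baseline"] <= hi * (1 + tol)):
            raise ValidationError(
                f"baseline duration {d['baseline']:.1f} s outside [{lo * (1 - tol):.0f}, {hi * (1 + tol):.0f}] s"
            )
        for name, nominal in (("occlusion", OCCLUSION_S), ("release", RELEASE_S)):
            if abs(d[name] - nominal) > tol * nominal:
                raise ValidationError(
                    f"{name} duration {d[name]:.1f} s deviates more than {tol:.0%} from {nominal:.0f} s"
                )

    @classmethod
    def from_seconds(
        cls,
        baseline_s: tuple[float, float],
        occlusion_s: tuple[float, float],
        release_s: tuple[float, float],
        fs: float,
    ) -> "PhaseAnnotation":
        def idx(t: float) -> int:
            return int(round(t * fs))

        return cls(
            baseline=(idx(baseline_s[0]), idx(baseline_s[1])),
            occlusion=(idx(occlusion_s[0]), idx(occlusion_s[1])),
            release=(idx(release_s[0]), idx(release_s[1])),
        )

    def to_seconds(self, fs: float) -> dict[str, list[float]]:
        return {f"{name}_s": [lo / fs, hi / fs] for name, (lo, hi) in self.items()}


# The second-stage low-pass cutoff; fs must exceed twice this for the chain to apply.
FIR_CUTOFF_HZ = 30.0


@dataclass(frozen=True)
class DualArmRecording:
    """Two synchronized pulse sample series (occluded + control arm)."""

    fs: float
    occluded_arm: np.ndarray
    control_arm: np.ndarray
    phases: PhaseAnnotation
    subject: SubjectProfile
    duration_tol: float = DEFAULT_DURATION_TOL

    def __post_init__(self) -> None:
        occ = np.asarray(self.occluded_arm, dtype=float)
        ctl = np.asarray(self.control_arm, dtype=float)
        object.__setattr__(self, "occluded_arm", occ)
        object.__setattr__(self, "control_arm", ctl)
        if occ.ndim != 1 or ctl.ndim != 1:
            raise ValidationError("arm series must be one-dimensional")
        if occ.size == 0:
            raise ValidationError("arm series must be non-empty")
        if occ.shape != ctl.shape:
            raise ValidationError(
                f"both arm series must have the same length, got {occ.size} and {ctl.size}"
            )
        if self.fs <= 2 * FIR_CUTOFF_HZ:
            raise ValidationError(
                f"sampling rate {self.fs} Hz must exceed twice the {FIR_CUTOFF_HZ:.0f} Hz low-pass cutoff"
            )
        if occ.size < self.phases.end:
            raise ValidationError(
                f"series length {occ.size} is shorter than the last annotated index {self.phases.end}"
            )
        self.phases.validate_durations(self.fs, self.duration_tol)

    def arm(self, which: str) -> np.ndarray:
        if which == "occluded":
            return self.occluded_arm
        if which == "control":
            return self.control_arm
        raise ValidationError(f"arm must be 'occluded' or 'control', got {which!r}")

    @property
    def n_samples(self) -> int:
        return int(self.occluded_arm.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


# ---------------------------------------------------------------------------
# Recording I/O: CSV sample table + JSON metadata sidecar
# ---------------------------------------------------------------------------

_SIGNAL_COLUMNS = ["time_s", "occluded_arm", "control_arm"]


def write_recording(rec: DualArmRecording, signal_path: str | Path, meta_path: str | Path) -> None:
    """Write the signal CSV and JSON sidecar; lossless under :func:`read_recording`.

    Samples are serialized with 17 significant digits so the decimal round
    trip is bit-exact.
    """
    signal_path, meta_path = Path(signal_path), Path(meta_path)
    df = pd.DataFrame(
        {
            "time_s": np.arange(rec.n_samples) / rec.fs,
            "occluded_arm": rec.occluded_arm,
            "control_arm": rec.control_arm,
        }
    )
    df.to_csv(signal_path, index=False, float_format="%.17g")
    s = rec.subject
    meta = {
        "fs_hz": rec.fs,
        "subject": {
            "id": s.subject_id,
            "age_years": s.age,
            "sex": s.sex,
            "sbp_mmHg": s.sbp,
            "dbp_mmHg": s.dbp,
            "bmi": s.bmi,
            "group": s.group,
        },
        "phases": rec.phases.to_seconds(rec.fs),
    }
    meta_path.write_text(json.dumps(meta, indent=2))


def read_recording(
    signal_path: str | Path,
    meta_path: str | Path,
    duration_tol: float = DEFAULT_DURATION_TOL,
) -> DualArmRecording:
    """Read a recording written by :func:`write_recording` (or the same dialect)."""
    signal_path, meta_path = Path(signal_path), Path(meta_path)
    try:
        df = pd.read_csv(signal_path, float_precision="round_trip")
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise ParseError(f"{signal_path}: cannot parse signal CSV: {exc}") from exc
    missing = [c for c in _SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{signal_path}: missing column(s) {missing}; header must be {_SIGNAL_COLUMNS}")
    for col in _SIGNAL_COLUMNS:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ParseError(f"{signal_path}: non-numeric value in field '{col}' at line {line}")

    try:
        meta = json.loads(Path(meta_path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{meta_path}: invalid JSON: {exc}") from exc
    for key in ("fs_hz", "subject", "phases"):
        if key not in meta:
            raise ParseError(f"{meta_path}: missing key '{key}'")
    fs = float(meta["fs_hz"])
    sub = meta["subject"]
    subject = SubjectProfile(
        subject_id=str(sub.get("id", "unknown")),
        age=sub.get("age_years"),
        sex=sub.get("sex"),
        sbp=sub.get("sbp_mmHg"),
        dbp=sub.get("dbp_mmHg"),
        bmi=sub.get("bmi"),
        group=sub.get("group", "unknown"),
    )
    ph = meta["phases"]
    try:
        phases = PhaseAnnotation.from_seconds(
            tuple(ph["baseline_s"]), tuple(ph["occlusion_s"]), tuple(ph["release_s"]), fs
        )
    except KeyError as exc:
        raise ParseError(f"{meta_path}: phases must contain baseline_s/occlusion_s/release_s") from exc

    # Check the time column is the uniform grid it claims to be.
    t = df["time_s"].to_numpy()
    expected = np.arange(len(t)) / fs
    if len(t) and np.max(np.abs(t - expected)) > 0.5 / fs:
        raise ParseError(f"{signal_path}: time_s is not a uniform grid at fs={fs} Hz")

    return DualArmRecording(
        fs=fs,
        occluded_arm=df["occluded_arm"].to_numpy(),
        control_arm=df["control_arm"].to_numpy(),
        phases=phases,
        subject=subject,
        duration_tol=duration_tol,
    )


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

COHORT_SCORE_COLUMNS = [
    "fhs10_lipids",
    "fhs10_bmi",
    "fhs30_lipids_full",
    "fhs30_lipids_hard",
    "fhs30_bmi_full",
    "fhs30_bmi_hard",
    "advance",
    "ukpds",
]

#: Published high-risk cutoffs (percent): FHS10 >= 20, FHS30 full-CVD >= 40.
HIGH_RISK_CUTOFFS = {
    "fhs10_lipids": 20.0,
    "fhs10_bmi": 20.0,
    "fhs30_lipids_full": 40.0,
    "fhs30_bmi_full": 40.0,
}

COHORT_REQUIRED_COLUMNS = (
    ["subject_id", "group", "ra_mdi", "age", "sex", "bmi", "sbp", "dbp", "hba1c", "cimt_avg"]
    + COHORT_SCORE_COLUMNS
    + [f"high_risk_{k}" for k in HIGH_RISK_CUTOFFS]
)


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table against the column contract and value invariants."""
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort table missing column(s): {missing}")
    if (df["ra_mdi"].dropna() < 0).any():
        raise ValidationError("ra_mdi must be >= 0")
    for col in COHORT_SCORE_COLUMNS:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise ValidationError(f"risk score column '{col}' must lie in [0, 100] percent")
    bad_groups = set(df["group"].unique()) - set(GROUPS)
    if bad_groups:
        raise ValidationError(f"unknown group label(s): {sorted(bad_groups)}")
    for score, cutoff in HIGH_RISK_CUTOFFS.items():
        lab = df[f"high_risk_{score}"].dropna()
        expect = (df.loc[lab.index, score] >= cutoff).astype(int)
        if not set(np.unique(lab)) <= {0, 1}:
            raise ValidationError(f"high_risk_{score} must be binary")
        if not (lab.astype(int) == expect).all():
            raise ValidationError(f"high_risk_{score} inconsistent with the >= {cutoff:.0f}% cutoff")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df)
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(Path(path))
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse cohort CSV: {exc}") from exc
    return validate_cohort(df)
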