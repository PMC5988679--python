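"""Statistical battery for index validation.

Bland-Altman repeatability, Spearman rank correlation, Mann-Whitney U,
ordinary least-squares regression and ROC analysis, with the conventions
used for this index:

* Bland-Altman agreement limits are mean +- 2 SD (sample SD, n-1
  denominator), not 1.96 SD; the multiplier is configurable.
* The Mann-Whitney statistic is U = #{(i, j): a_i < b_j} + 1/2 #ties,
  i.e. referenced to the second sample; the complementary convention is
  n1*n2 - U.  Exact two-sided p-values are computed by enumeration (with
  ties) or by the classical count recursion (tie-free) for small samples,
  and by a tie-corrected normal approximation otherwise.
* Spearman's rho is the Pearson correlation of mid-ranks; for n <= 10 the
  two-sided p-value is exact over all n! pairings.
* ROC curves are empirical over all distinct thresholds (score >= cutoff
  predicts the positive class); AUC by trapezoid, confidence intervals by
  seeded stratified bootstrap, operating cutoff by Youden's J with ties
  broken toward the smallest cutoff.

No multiple-testing adjustment is applied; reports echo a fixed
significance note instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sstats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import DataError, ValidationError
from .signal_model import COHORT_SCORE_COLUMNS, HIGH_RISK_CUTOFFS

__all__ = [
    "BlandAltmanResult",
    "CorrelationResult",
    "RankTestResult",
    "RegressionResult",
    "ROCResult",
    "bland_altman",
    "spearman_rho",
    "mann_whitney_u",
    "linear_regression",
    "roc_auc",
    "cohort_report",
    "render_report",
]

SIGNIFICANCE_NOTE = "P value < 0.01 is considered significant."


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    n: int
    differences: np.ndarray = field(repr=False)
    sd_multiplier: float = 2.0

    def all_within_limits(self) -> bool:
        return bool(
            np.all((self.differences >= self.lower_limit) & (self.differences <= self.upper_limit))
        )


def bland_altman(x, y, sd_multiplier: float = 2.0) -> BlandAltmanResult:
    """Agreement analysis of paired measurements: differences d = x - y,
    limits mean(d) +- ``sd_multiplier`` * SD(d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("paired measurements must be 1-d arrays of equal length")
    if x.size < 2:
        raise DataError(f"need at least 2 pairs, got {x.size}")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        lower_limit=mean - sd_multiplier * sd,
        upper_limit=mean + sd_multiplier * sd,
        n=int(d.size),
        differences=d,
        sd_multiplier=sd_multiplier,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    ties_present: bool
    method: str  # "exact_permutation" | "t_approx" | "undefined"


_EXACT_SPEARMAN_N = 10


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman's rho as the Pearson correlation of mid-ranks.

    Exact permutation p (all n! pairings) for n <= 10, otherwise the
    t-distribution approximation.  Constant inputs give an undefined rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise DataError("need paired 1-d arrays with n >= 3")
    n = x.size
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n,
                                 ties_present=True, method="undefined")
    rx = sstats.rankdata(x)
    ry = sstats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = (np.unique(x).size < n) or (np.unique(y).size < n)

    if n <= _EXACT_SPEARMAN_N:
        p = _exact_spearman_p(rx, ry, rho)
        return CorrelationResult(rho=rho, p_value=p, n=n, ties_present=ties,
                                 method="exact_permutation")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = float(2 * sstats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n=n, ties_present=ties,
                             method="t_approx")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p: fraction of all pairings with |rho| >= |rho_obs|."""
    n = rx.size
    rxc = rx - rx.mean()
    sx = float(np.sqrt((rxc**2).sum()))
    ryc = ry - ry.mean()
    sy = float(np.sqrt((ryc**2).sum()))
    target = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list = []
    chunk_size = 40320
    for perm in itertools.permutations(ryc):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            count += _count_extreme(np.asarray(chunk), rxc, sx, sy, target)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(np.asarray(chunk), rxc, sx, sy, target)
        total += len(chunk)
    return count / total


def _count_extreme(perms: np.ndarray, rxc: np.ndarray, sx: float, sy: float, target: float) -> int:
    rhos = perms @ rxc / (sx * sy)
    return int(np.count_nonzero(np.abs(rhos) >= target))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float   # U = #(a_i < b_j) + 1/2 ties (second-sample referenced)
    p_value: float
    n1: int
    n2: int
    method: str          # "exact_enumeration" | "exact_recursion" | "normal_approx"

    @property
    def u_complement(self) -> float:
        return self.n1 * self.n2 - self.u_statistic


_ENUM_MAX_SPLITS = 50_000
_DP_MAX_PRODUCT = 400


def mann_whitney_u(a, b) -> RankTestResult:
    """Two-sample rank test; see the module docstring for the U convention."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be non-empty")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = sstats.rankdata(pooled)
    r2 = float(ranks[n1:].sum())
    u = r2 - n2 * (n2 + 1) / 2.0  # == #(a < b) + 0.5 * #ties

    has_ties = np.unique(pooled).size < pooled.size
    n_splits = math.comb(n1 + n2, n1)
    if has_ties and n_splits <= _ENUM_MAX_SPLITS:
        p = _enumerate_mw_p(pooled, n1, n2, u)
        method = "exact_enumeration"
    elif not has_ties and n1 * n2 <= _DP_MAX_PRODUCT:
        p = _exact_mw_p_recursion(n1, n2, u) if n_splits > _ENUM_MAX_SPLITS else _enumerate_mw_p(pooled, n1, n2, u)
        method = "exact_recursion" if n_splits > _ENUM_MAX_SPLITS else "exact_enumeration"
        # enumeration and recursion agree on tie-free data; prefer enumeration when cheap
    else:
        p = _normal_mw_p(pooled, n1, n2, u)
        method = "normal_approx"
    return RankTestResult(u_statistic=float(u), p_value=float(min(1.0, p)), n1=n1, n2=n2, method=method)


def _enumerate_mw_p(pooled: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Exact two-sided p over all label arrangements (handles ties)."""
    n = n1 + n2
    less = (pooled[:, None] < pooled[None, :]).astype(float)
    less += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(less, 0.5)  # only cross-group pairs are summed below
    mu = n1 * n2 / 2.0
    target = abs(u_obs - mu) - 1e-9
    count = total = 0
    idx = np.arange(n)
    for a_idx in itertools.combinations(idx, n1):
        b_idx = np.setdiff1d(idx, a_idx, assume_unique=True)
        u = float(less[np.ix_(a_idx, b_idx)].sum())
        if abs(u - mu) >= target:
            count += 1
        total += 1
    return count / total


def _exact_mw_p_recursion(n1: int, n2: int, u_obs: float) -> float:
    """Exact two-sided p from the classical tie-free U count recursion.

    Builds the coefficients of the Gaussian binomial [n1+n2 choose n1]_q,
    whose q^u coefficient counts arrangements with statistic u.
    """
    m = n1 * n2
    poly = np.zeros(m + 1)
    poly[0] = 1.0
    for k in range(1, n1 + 1):
        shifted = np.zeros_like(poly)
        shifted[n2 + k :] = poly[: m + 1 - (n2 + k)] if n2 + k <= m else 0.0
        poly = poly - shifted          # multiply by (1 - q^(n2+k))
        for j in range(k, m + 1):      # divide by (1 - q^k)
            poly[j] += poly[j - k]
    total = poly.sum()
    mu = m / 2.0
    target = abs(u_obs - mu) - 1e-9
    us = np.arange(m + 1)
    return float(poly[np.abs(us - mu) >= target].sum() / total)


def _normal_mw_p(pooled: np.ndarray, n1: int, n2: int, u: float) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    return float(2 * sstats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Linear regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict[str, dict[str, float]]  # name -> {coef, ci_low, ci_high, p_value}
    reference_levels: dict[str, str]
    n: int
    r_squared: float


def linear_regression(
    y, X: pd.DataFrame, reference_levels: dict[str, str] | None = None
) -> RegressionResult:
    """OLS of ``y`` on the columns of ``X`` with 95% t-based CIs.

    Categorical (object/category/bool) columns are dummy-coded against a
    reference level — the given one, else the lexicographically first.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    reference_levels = dict(reference_levels or {})
    design_cols: dict[str, np.ndarray] = {}
    used_refs: dict[str, str] = {}
    for col in X.columns:
        s = X[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(map(str, pd.unique(s.astype(str))))
            ref = str(reference_levels.get(col, levels[0]))
            if ref not in levels:
                raise ValidationError(f"reference level {ref!r} not found in column {col!r}")
            used_refs[col] = ref
            for lev in levels:
                if lev != ref:
                    design_cols[f"{col}[{lev}]"] = (s.astype(str) == lev).to_numpy(dtype=float)
        else:
            design_cols[str(col)] = s.to_numpy(dtype=float)
    design = pd.DataFrame(design_cols)
    design.insert(0, "intercept", 1.0)
    if y.size <= design.shape[1]:
        raise DataError(f"n = {y.size} must exceed the number of parameters {design.shape[1]}")

    mat = design.to_numpy()
    r = np.linalg.qr(mat, mode="r")
    bad = [design.columns[i] for i in range(mat.shape[1]) if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
    if bad:
        raise DataError(f"design matrix is rank deficient; collinear column(s): {bad}")

    fit = sm.OLS(y, mat).fit()
    ci = fit.conf_int(alpha=0.05)
    coefs = {
        name: {
            "coef": float(fit.params[i]),
            "ci_low": float(ci[i][0]),
            "ci_high": float(ci[i][1]),
            "p_value": float(fit.pvalues[i]),
        }
        for i, name in enumerate(design.columns)
    }
    return RegressionResult(
        coefficients=coefs,
        reference_levels=used_refs,
        n=int(y.size),
        r_squared=float(fit.rsquared),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    thresholds: np.ndarray = field(repr=False)
    cutoff: float
    sensitivity: float
    specificity: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0) -> ROCResult:
    """Empirical ROC of ``scores`` against binary ``labels``.

    Positive prediction is score >= cutoff.  AUC by trapezoid over all
    distinct thresholds (equals the tie-adjusted rank statistic
    U / (n_pos * n_neg)); the 95% CI is a seeded stratified bootstrap; the
    operating cutoff maximizes Youden's J, ties resolved to the smallest
    cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    classes = np.unique(labels)
    if not np.array_equal(classes, [0, 1]):
        raise DataError(f"labels must contain both classes 0 and 1, got {classes}")
    pos = scores[labels == 1]
    neg = scores[labels == 0]

    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))

    finite = np.isfinite(thr)
    j = tpr - fpr
    j_f, thr_f = j[finite], thr[finite]
    best_j = j_f.max()
    cutoff = float(thr_f[np.isclose(j_f, best_j)].min())
    sens = float(np.mean(pos >= cutoff))
    spec = float(np.mean(neg < cutoff))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=pos.size, replace=True)
        bn = rng.choice(neg, size=neg.size, replace=True)
        boots[i] = _rank_auc(bn, bp)
    lo, hi = np.percentile(boots, [2.5, 97.5])

    return ROCResult(
        auc=auc,
        auc_ci=(float(lo), float(hi)),
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def _rank_auc(neg: np.ndarray, pos: np.ndarray) -> float:
    """AUC via the rank identity U / (n_neg * n_pos)."""
    pooled = np.concatenate([neg, pos])
    ranks = sstats.rankdata(pooled)
    u = ranks[neg.size :].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (neg.size * pos.size))


# ---------------------------------------------------------------------------
# Cohort report
# ---------------------------------------------------------------------------

_CORRELATES = COHORT_SCORE_COLUMNS + ["hba1c", "cimt_avg"]


def cohort_report(table: pd.DataFrame, seed: int = 0) -> dict:
    """Run the full validation battery on a cohort table.

    Group comparison of the index (Mann-Whitney), Spearman correlations
    against every risk score plus HbA1c and mean carotid intima-media
    thickness, univariate regressions of the index on each correlate, and
    ROC analysis against each high-risk label.  Deterministic given the
    table and seed.
    """
    required = ["group", "ra_mdi"] + _CORRELATES + [f"high_risk_{k}" for k in HIGH_RISK_CUTOFFS]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing column(s): {missing}")

    ctrl = table.loc[table["group"] == "control", "ra_mdi"].dropna().to_numpy()
    t2dm = table.loc[table["group"] == "t2dm", "ra_mdi"].dropna().to_numpy()
    report: dict = {"n": int(len(table)), "significance_note": SIGNIFICANCE_NOTE}
    if ctrl.size and t2dm.size:
        mw = mann_whitney_u(ctrl, t2dm)
        report["group_comparison"] = {
            "median_control": float(np.median(ctrl)),
            "iqr_control": float(np.subtract(*np.percentile(ctrl, [75, 25]))),
            "median_t2dm": float(np.median(t2dm)),
            "iqr_t2dm": float(np.subtract(*np.percentile(t2dm, [75, 25]))),
            "u_statistic": mw.u_statistic,
            "u_convention": "U = #(control < t2dm) + 1/2 ties",
            "p_value": mw.p_value,
            "method": mw.method,
        }

    report["spearman"] = {}
    report["regression"] = {}
    for col in _CORRELATES:
        sub = table[["ra_mdi", col]].dropna()
        if len(sub) < 3:
            continue
        corr = spearman_rho(sub[col].to_numpy(), sub["ra_mdi"].to_numpy())
        report["spearman"][col] = {"rho": corr.rho, "p_value": corr.p_value, "n": corr.n}
        reg = linear_regression(sub["ra_mdi"].to_numpy(), sub[[col]])
        report["regression"][col] = reg.coefficients[col] | {"n": reg.n, "r_squared": reg.r_squared}

    report["roc"] = {}
    for score in HIGH_RISK_CUTOFFS:
        sub = table[["ra_mdi", f"high_risk_{score}"]].dropna()
        labels = sub[f"high_risk_{score}"].to_numpy().astype(int)
        if np.unique(labels).size < 2:
            report["roc"][score] = {"note": "single-class labels; ROC not defined"}
            continue
        roc = roc_auc(sub["ra_mdi"].to_numpy(), labels, seed=seed)
        report["roc"][score] = {
            "auc": roc.auc,
            "auc_ci": list(roc.auc_ci),
            "cutoff": roc.cutoff,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            "n_pos": roc.n_pos,
            "n_neg": roc.n_neg,
        }
    return report


def render_report(report: dict) -> str:
    """Readable text rendering of :func:`cohort_report` output."""
    lines = [f"Cohort validation report (n = {report['n']})", "=" * 42]
    gc = report.get("group_comparison")
    if gc:
        lines += [
            "Index by group:",
            f"  control: median {gc['median_control']:.3f} (IQR {gc['iqr_control']:.3f})",
            f"  t2dm:    median {gc['median_t2dm']:.3f} (IQR {gc['iqr_t2dm']:.3f})",
            f"  Mann-Whitney {gc['u_convention']}: U = {gc['u_statistic']:.1f}, "
            f"p = {gc['p_value']:.3g} ({gc['method']})",
            "",
        ]
    if report.get("spearman"):
        lines.append("Spearman correlations with the index:")
        for col, d in report["spearman"].items():
            lines.append(f"  {col:20s} rho = {d['rho']:+.3f}  p = {d['p_value']:.3g}  (n = {d['n']})")
        lines.append("")
    if report.get("regression"):
        lines.append("Univariate regressions (index on correlate):")
        for col, d in report["regression"].items():
            lines.append(
                f"  {col:20s} coef = {d['coef']:+.4f}  95% CI [{d['ci_low']:+.4f}, {d['ci_high']:+.4f}]"
                f"  p = {d['p_value']:.3g}"
            )
        lines.append("")
    if report.get("roc"):
        lines.append("ROC against high-risk labels (positive if index >= cutoff):")
        for score, d in report["roc"].items():
            if "note" in d:
                lines.append(f"  {score:20s} {d['note']}")
            else:
                lines.append(
                    f"  {score:20s} AUC = {d['auc']:.3f} (95% CI {d['auc_ci'][0]:.3f}-{d['auc_ci'][1]:.3f})"
                    f"  cutoff >= {d['cutoff']:.3f}  sens {d['sensitivity']:.2f}  spec {d['specificity']:.2f}"
                )
        lines.append("")
    lines.append(report["significance_note"])
    return "\n".join(lines)
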