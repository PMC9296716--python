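"""Observer-agreement statistics for MFI and Goutallier ratings.

Continuous MFI measurements are compared with the intraclass correlation
coefficient in its two-way random-effects, absolute-agreement,
single-measures form — ICC(A,1) in the McGraw & Wong taxonomy — with the
F-distribution confidence interval.  Categorical Goutallier grades are
compared with Gwet's AC1, the chance-corrected agreement coefficient that
avoids the high-agreement/low-kappa paradox under skewed category
prevalence.  Pairwise measurement differences are summarised by
Bland-Altman bias and 95% limits of agreement.

Agreement analyses are strictly complete-case: a subject (patient, level,
side) enters a ratings matrix only when every required observer/session
cell is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass
class RatingsMatrix:
    """Complete subjects × raters (or sessions) matrix of ratings."""

    values: np.ndarray           # shape (n_subjects, k_raters)
    subjects: list               # (patient_id, level, side) tuples
    columns: list                # observer ids or session labels
    n_dropped: int = 0           # incomplete subjects removed during assembly

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass
class AnovaDecomposition:
    """Two-way crossed ANOVA mean squares (subjects × raters, one obs/cell)."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    k_raters: int


@dataclass
class ReliabilityResult:
    statistic: str               # "ICC" or "AC1"
    estimate: float
    ci_low: float
    ci_high: float
    band: str
    n_subjects: int
    k_raters: int
    ci_method: str = ""
    notes: list = field(default_factory=list)


@dataclass
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    n_pairs: int
    sd_diff: float
    coordinates: pd.DataFrame = field(repr=False, default=None)


def assemble_complete_cases(
    records: pd.DataFrame,
    value_col: str,
    mode: str = "interobserver",
    observer=None,
) -> RatingsMatrix:
    """Build a complete ratings matrix from long-format measurement records.

    ``records`` needs columns patient_id, level, side, observer, session and
    the value column.  Interobserver mode uses the session-1 reading of
    every observer (one column per observer); intraobserver mode uses
    sessions 1 and 2 of the single requested observer.  Subjects missing any
    required cell are dropped and counted in ``n_dropped``.
    """
    required = {"patient_id", "level", "side", "observer", "session", value_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")

    if mode == "interobserver":
        sub = records[records["session"] == 1]
        col_field = "observer"
    elif mode == "intraobserver":
        if observer is None:
            raise ValueError("intraobserver mode requires an observer id")
        sub = records[records["observer"] == observer]
        col_field = "session"
    else:
        raise ValueError(f"unknown mode {mode!r}")

    wide = sub.pivot_table(
        index=["patient_id", "level", "side"],
        columns=col_field,
        values=value_col,
        aggfunc="first",
    )
    if wide.shape[1] < 2:
        raise ValueError(
            f"need at least 2 {col_field}s for agreement analysis, found {wide.shape[1]}"
        )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 2:
        raise ValueError(
            f"fewer than 2 complete subjects after the complete-case rule "
            f"({len(complete)} complete, {n_dropped} dropped)"
        )
    return RatingsMatrix(
        values=complete.to_numpy(dtype=float),
        subjects=list(complete.index),
        columns=list(complete.columns),
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# ICC


def anova_decomposition(values: np.ndarray) -> AnovaDecomposition:
    """Mean squares of the two-way crossed design (one observation per cell)."""
    y = np.asarray(values, dtype=float)
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    return AnovaDecomposition(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        n_subjects=n,
        k_raters=k,
    )


def icc_absolute_agreement(
    matrix: RatingsMatrix | np.ndarray, confidence: float = 0.95
) -> ReliabilityResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measures.

    Point estimate (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)) and
    the McGraw & Wong F-distribution confidence interval.  A matrix with no
    variance at all is perfect agreement by convention: ICC 1 with a
    degenerate CI [1, 1] and a warning note.
    """
    values = matrix.values if isinstance(matrix, RatingsMatrix) else np.asarray(matrix, float)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 subjects and >= 2 raters")
    if np.isnan(values).any():
        raise ValueError("ratings matrix must be complete (no missing cells)")
    n, k = values.shape
    notes: list[str] = []

    if np.ptp(values) == 0:
        est, lo, hi = 1.0, 1.0, 1.0
        notes.append("degenerate data: zero total variance, ICC defined as 1.0")
    else:
        dec = anova_decomposition(values)
        msr, msc, mse = dec.ms_rows, dec.ms_cols, dec.ms_error
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom

        alpha = 1.0 - confidence
        if mse == 0.0:
            # columns reproduce each other exactly; absolute agreement is perfect
            lo = hi = est = 1.0 if msc == 0 else est
            if msc == 0:
                notes.append("zero residual and zero rater variance: exact agreement")
            else:
                lo, hi = est, est
                notes.append("zero residual variance: CI collapsed to the estimate")
        else:
            # McGraw & Wong (1996) CI for ICC(A,1)
            a = (k * est) / (n * (1.0 - est)) if est < 1.0 else np.inf
            b = 1.0 + (k * est * (n - 1.0)) / (n * (1.0 - est)) if est < 1.0 else np.inf
            if np.isfinite(a) and np.isfinite(b):
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                )
                f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
                f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f_l * mse) / (
                    f_l * (k * msc + (k * n - k - n) * mse) + n * msr
                )
                hi = n * (f_u * msr - mse) / (
                    k * msc + (k * n - k - n) * mse + n * f_u * msr
                )
            else:
                lo = hi = 1.0
        lo, hi = float(np.clip(lo, -1, est)), float(np.clip(hi, est, 1))

    result = ReliabilityResult(
        statistic="ICC",
        estimate=float(est),
        ci_low=float(lo),
        ci_high=float(hi),
        band=interpret_band(float(est), "ICC"),
        n_subjects=n,
        k_raters=k,
        ci_method="F-distribution (McGraw & Wong, ICC(A,1))",
        notes=notes,
    )
    if notes:
        warnings.warn(notes[0], stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# Gwet's AC1


def _category_counts(values: np.ndarray, q: int) -> np.ndarray:
    """r_ik: number of raters assigning category k to subject i."""
    vals = np.asarray(values)
    n, _ = vals.shape
    counts = np.zeros((n, q), dtype=float)
    for k in range(q):
        counts[:, k] = (vals == k).sum(axis=1)
    return counts


def gwet_ac1(
    matrix: RatingsMatrix | np.ndarray, q: int = 5, confidence: float = 0.95
) -> ReliabilityResult:
    """Gwet's first-order agreement coefficient for q nominal categories.

    AC1 = (p_a − p_e)/(1 − p_e) with p_a the average pairwise agreement per
    subject and p_e = (1/(q−1))·Σ_k π_k(1 − π_k), π_k the mean prevalence of
    category k across subjects.  The CI uses Gwet's linearised variance
    estimator with a t(n−1) reference distribution, truncated to [−1, 1].
    """
    values = matrix.values if isinstance(matrix, RatingsMatrix) else np.asarray(matrix)
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 subjects and >= 2 raters")
    vals = np.rint(values).astype(int)
    if (vals < 0).any() or (vals >= q).any():
        raise ValueError(f"categorical ratings must lie in 0..{q - 1}")
    n, r = vals.shape

    counts = _category_counts(vals, q)           # r_ik
    pi_k = counts.mean(axis=0) / r               # mean prevalence per category
    p_e = float((pi_k * (1.0 - pi_k)).sum() / (q - 1))
    if p_e >= 1.0:
        raise ValueError(
            "degenerate prevalence: chance agreement p_e = 1, AC1 undefined "
            "(all probability mass in one chance configuration)"
        )

    p_a_i = (counts * (counts - 1.0)).sum(axis=1) / (r * (r - 1.0))
    p_a = float(p_a_i.mean())
    ac1 = (p_a - p_e) / (1.0 - p_e)

    # Gwet (2008) linearised variance: per-subject AC1 components corrected
    # for the variability of the chance-agreement term.
    ac1_i_star = (p_a_i - p_e) / (1.0 - p_e)
    p_e_i = ((counts / r) * (1.0 - pi_k)).sum(axis=1) / (q - 1)
    ac1_i = ac1_i_star - 2.0 * (1.0 - ac1) * (p_e_i - p_e) / (1.0 - p_e)
    var = float(((ac1_i - ac1) ** 2).sum() / (n * (n - 1.0)))
    se = np.sqrt(var)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=n - 1)
    lo = float(np.clip(ac1 - tcrit * se, -1.0, 1.0))
    hi = float(np.clip(ac1 + tcrit * se, -1.0, 1.0))

    return ReliabilityResult(
        statistic="AC1",
        estimate=float(ac1),
        ci_low=lo,
        ci_high=hi,
        band=interpret_band(float(ac1), "AC1"),
        n_subjects=n,
        k_raters=r,
        ci_method="Gwet linearised variance, t(n-1) normal-approximation",
    )


# ---------------------------------------------------------------------------
# Bland-Altman


def bland_altman(first, second) -> BlandAltmanResult:
    """Bias and 95% limits of agreement for paired measurements.

    Differences are (first − second) in the supplied order; bias is their
    mean and the limits are bias ± 1.96 × sample SD (n−1 denominator).  Also
    returns the per-pair (mean, difference) coordinates used for plotting.
    """
    a = np.asarray(first, dtype=float)
    b = np.asarray(second, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be 1D arrays of equal length")
    if len(a) < 2:
        raise ValueError(f"need at least 2 pairs, got {len(a)}")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    coords = pd.DataFrame({"mean": (a + b) / 2.0, "difference": d})
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n_pairs=len(a),
        sd_diff=sd,
        coordinates=coords,
    )


# ---------------------------------------------------------------------------
# Interpretation bands

# Contiguous half-open closures of the published verbal thresholds, so every
# estimate (including boundary values like 0.505) gets exactly one label.
_ICC_BANDS = [(0.50, "poor"), (0.755, "moderate"), (0.905, "good"), (np.inf, "excellent")]
_AC1_BANDS = [
    (0.005, "poor"),
    (0.205, "slight"),
    (0.405, "fair"),
    (0.605, "moderate"),
    (0.805, "substantial"),
    (np.inf, "almost perfect"),
]


def interpret_band(estimate: float, scale: str) -> str:
    """Verbal interpretation of an agreement estimate.

    ICC: poor < 0.50 ≤ moderate < 0.755 ≤ good < 0.905 ≤ excellent.
    AC1: poor ≤ 0.005 < slight ≤ 0.205 < fair ≤ 0.405 < moderate ≤ 0.605
    < substantial ≤ 0.805 < almost perfect ≤ 1.
    """
    if not -1.0 <= estimate <= 1.0 + 1e-12:
        raise ValueError(f"agreement estimate must lie in [-1, 1], got {estimate}")
    if scale == "ICC":
        for upper, label in _ICC_BANDS:
            if estimate < upper:
                return label
    elif scale == "AC1":
        for upper, label in _AC1_BANDS:
            if estimate <= upper:
                return label
    else:
        raise ValueError(f"unknown scale {scale!r}; expected 'ICC' or 'AC1'")
    raise AssertionError("unreachable")
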