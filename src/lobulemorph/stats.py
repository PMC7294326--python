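"""Statistical and assay formulas used by the lobule analysis.

Covers the nested-model F-test for the radial regressions, the unpaired
t-test on branch-type proportions, and the plate-assay arithmetic: LDH
viability %, protein recovery % and relative qPCR quantification by the
2^-ΔΔCT method with housekeeping-gene selection by CT stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["LinearFitResult", "QpcrComputation", "fit_linear_ftest",
           "branch_type_test", "ldh_viability", "protein_recovery",
           "ddct_fold", "housekeeping_stability"]


@dataclass(frozen=True)
class LinearFitResult:
    """OLS line fit with the F-test against an intercept-only model."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def fit_linear_ftest(x, y) -> LinearFitResult:
    """Ordinary least squares y = a + b*x with a nested-model F-test.

    The F statistic compares the one-slope model to the intercept-only
    model: F = (TSS - RSS) / (RSS / (n - 2)), with the p-value from the
    F(1, n-2) distribution.  R² = 1 - RSS/TSS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three points for the F-test")
    if np.ptp(x) == 0:
        raise ValueError("x values are all equal; slope is undefined")
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((y - ym) ** 2))
    if tss == 0.0:
        # y constant: the line explains nothing beyond the mean
        return LinearFitResult(slope=0.0, intercept=ym, r_squared=0.0,
                               f_statistic=0.0, p_value=1.0, n=n)
    df_resid = n - 2
    if rss == 0.0:
        return LinearFitResult(slope=slope, intercept=intercept, r_squared=1.0,
                               f_statistic=np.inf, p_value=0.0, n=n)
    f_stat = (tss - rss) / (rss / df_resid)
    p = float(sps.f.sf(f_stat, 1, df_resid))
    return LinearFitResult(slope=float(slope), intercept=float(intercept),
                           r_squared=1.0 - rss / tss,
                           f_statistic=float(f_stat), p_value=p, n=n)


def branch_type_test(triple_props, quad_props, *, welch: bool = False):
    """Two-sample unpaired t-test on per-lobule branch-type proportions.

    Returns ``(t, p)`` two-sided.  ``welch=True`` drops the equal-variance
    assumption.  Two identical zero-variance groups give (0, 1) by
    convention.
    """
    a = np.asarray(triple_props, dtype=float)
    b = np.asarray(quad_props, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def ldh_viability(sample: float, ctrl_0pct: float, ctrl_100pct: float, *,
                  corrected: bool = False) -> float:
    """Percent viability from LDH-release optical densities.

    The default implements the published formula literally,
    ``100 - (sample - ctrl_100pct) / ctrl_0pct * 100``, where ``ctrl_0pct``
    is the fully lysed (0% viable) control and ``ctrl_100pct`` the 100%
    viable control.  ``corrected=True`` uses the internally consistent
    denominator ``ctrl_0pct - ctrl_100pct`` instead, which maps the lysis
    control to exactly 0%.
    """
    denom = (ctrl_0pct - ctrl_100pct) if corrected else ctrl_0pct
    if denom == 0:
        raise ZeroDivisionError("zero denominator in the viability formula")
    return 100.0 - (sample - ctrl_100pct) / denom * 100.0


def protein_recovery(conc_t: float, conc_t0: float) -> float:
    """Percent protein recovery relative to the T0 concentration (=100%)."""
    if conc_t0 <= 0:
        raise ZeroDivisionError("T0 concentration must be positive")
    return conc_t / conc_t0 * 100.0


@dataclass(frozen=True)
class QpcrComputation:
    """Relative expression by the 2^-ΔΔCT method."""

    ct_target_cond: float
    ct_hk_cond: float
    ct_target_cal: float
    ct_hk_cal: float
    delta_ct_cond: float
    delta_ct_cal: float
    delta_delta_ct: float
    fold: float


def ddct_fold(ct_target_cond: float, ct_hk_cond: float,
              ct_target_cal: float, ct_hk_cal: float) -> QpcrComputation:
    """2^-ΔΔCT relative expression of a condition against a calibrator.

    ΔCT = CT(target) - CT(housekeeping) per condition,
    ΔΔCT = ΔCT(condition) - ΔCT(calibrator), fold = 2^-ΔΔCT.
    """
    cts = (ct_target_cond, ct_hk_cond, ct_target_cal, ct_hk_cal)
    if not all(np.isfinite(cts)):
        raise ValueError("all CT values must be finite")
    d_cond = ct_target_cond - ct_hk_cond
    d_cal = ct_target_cal - ct_hk_cal
    ddct = d_cond - d_cal
    return QpcrComputation(*cts, delta_ct_cond=d_cond, delta_ct_cal=d_cal,
                           delta_delta_ct=ddct, fold=float(2.0 ** (-ddct)))


def housekeeping_stability(ct_by_gene: dict[str, "np.ndarray | list"]) -> str:
    """Pick the housekeeping gene with the most stable CT across samples.

    Stability is the sample standard deviation of each gene's CT values;
    the smallest wins, ties broken by input order.
    """
    if len(ct_by_gene) < 2:
        raise ValueError("need at least two candidate genes")
    best_gene, best_sd = None, np.inf
    for gene, cts in ct_by_gene.items():
        arr = np.asarray(cts, dtype=float)
        if arr.size < 2:
            raise ValueError(f"gene {gene!r} needs at least two samples")
        sd = float(np.std(arr, ddof=1))
        if sd < best_sd:
            best_gene, best_sd = gene, sd
    return best_gene
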