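"""Concentration-response validation: three-parameter logistic fits and the
extra sum-of-squares F test.

β-arrestin recruitment measured by BRET against agonist concentration is
fitted with the three-parameter logistic (Hill slope fixed at 1):

    y = bottom + (top - bottom) / (1 + 10^(log10 EC50 - log10 [L]))

reported as pEC50 = -log10 EC50 (M), Emax (top) and baseline (bottom), all
in % of the wild-type/wild-type maximum. Two datasets (e.g. wild type vs a
charge-reversal mutant) are compared by fitting them jointly with shared
parameters versus separately, and referring

    F = ((SSE_shared - SSE_separate) / (df_shared - df_separate))
        / (SSE_separate / df_separate)

to the F distribution. A small p value means one curve cannot describe both
datasets — the mutant genuinely shifted potency and/or efficacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import EmptyInputError, FitFailureError, XlgeomError

__all__ = [
    "DoseResponseCurve",
    "FitResult",
    "FTestResult",
    "fit_logistic3",
    "f_test_nested",
    "normalize_surface_expression",
    "logistic3",
]


def logistic3(conc_m: np.ndarray, bottom: float, top: float, log_ec50: float) -> np.ndarray:
    """Three-parameter agonist curve with unit Hill slope; ``conc_m`` in M."""
    conc_m = np.asarray(conc_m, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (log_ec50 - np.log10(conc_m)))


@dataclass
class DoseResponseCurve:
    """One ligand/receptor concentration-response dataset (replicates pooled)."""

    ligand: str
    receptor: str
    concentration_m: np.ndarray  # molar, > 0
    response_pct: np.ndarray  # % of reference maximum
    replicate: np.ndarray | None = None

    def __post_init__(self):
        self.concentration_m = np.asarray(self.concentration_m, dtype=float)
        self.response_pct = np.asarray(self.response_pct, dtype=float)
        if self.concentration_m.shape != self.response_pct.shape:
            raise XlgeomError("concentration and response lengths differ")
        if np.any(self.concentration_m <= 0):
            raise XlgeomError("concentrations must be positive")
        if len(np.unique(self.concentration_m)) < 4:
            raise XlgeomError("need >= 4 distinct concentrations for a fit")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ligand: str, receptor: str) -> "DoseResponseCurve":
        sub = df[(df["ligand"] == ligand) & (df["receptor"] == receptor)]
        if sub.empty:
            raise EmptyInputError(f"no rows for {ligand}/{receptor}")
        return cls(
            ligand=ligand,
            receptor=receptor,
            concentration_m=sub["conc_M"].to_numpy(),
            response_pct=sub["response_pct"].to_numpy(),
            replicate=sub["replicate"].to_numpy() if "replicate" in sub else None,
        )


@dataclass
class FitResult:
    """Logistic fit estimates with asymptotic standard errors.

    ``summary()`` prints a Table-1-style line: pEC50 ± SE and Emax ± SE.
    """

    pec50: float
    emax: float
    baseline: float
    se: dict = field(default_factory=dict)
    rss: float = 0.0
    n: int = 0
    ec50_in_range: bool = True
    incomplete_curve: bool = False
    curve: DoseResponseCurve | None = None

    @property
    def params(self) -> np.ndarray:
        return np.array([self.baseline, self.emax, -self.pec50])

    def predict(self, conc_m) -> np.ndarray:
        return logistic3(conc_m, self.baseline, self.emax, -self.pec50)

    def summary(self) -> str:
        lab = ""
        if self.curve is not None:
            lab = f"{self.curve.receptor} + {self.curve.ligand}: "
        note = " [curve incomplete]" if self.incomplete_curve else ""
        note += "" if self.ec50_in_range else " [EC50 outside tested range]"
        return (
            f"{lab}pEC50 {self.pec50:.2f} ± {self.se.get('pec50', float('nan')):.2f}, "
            f"Emax {self.emax:.1f}% ± {self.se.get('emax', float('nan')):.1f}%, "
            f"baseline {self.baseline:.1f}%, RSS {self.rss:.3g}, n {self.n}{note}"
        )


@dataclass
class FTestResult:
    sse_shared: float
    sse_separate: float
    df_shared: int
    df_separate: int
    f_statistic: float
    p_value: float

    def __post_init__(self):
        if self.sse_separate > self.sse_shared + 1e-9 * max(self.sse_shared, 1.0):
            raise ValueError("separate-fit SSE exceeds shared-fit SSE")
        if self.f_statistic < 0:
            raise ValueError("negative F statistic")


def _rss(params, x, y) -> float:
    return float(np.sum((y - logistic3(x, *params)) ** 2))


def _fit_once(x, y, p0):
    try:
        popt, pcov = optimize.curve_fit(
            logistic3, x, y, p0=p0, maxfev=20_000, full_output=False
        )
        return popt, pcov, _rss(popt, x, y)
    except (RuntimeError, optimize.OptimizeWarning):
        return None


def fit_logistic3(curve: DoseResponseCurve, flat_threshold: float = 1e-2) -> FitResult:
    """Least-squares three-parameter logistic fit with multistart initialization.

    log10 EC50 starting values span the tested concentration range; the
    lowest-RSS solution wins (ties by lower pEC50). A dataset whose response
    barely varies, or whose fitted top is never approached within the tested
    range, is flagged as an incomplete curve.
    """
    x = curve.concentration_m
    y = curve.response_pct
    span = y.max() - y.min()
    if span < flat_threshold * max(abs(y).max(), 1.0):
        raise FitFailureError(
            f"{curve.receptor}/{curve.ligand}: response is flat; no curve to fit"
        )
    log_lo, log_hi = np.log10(x.min()), np.log10(x.max())
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        for log_ec50_0 in np.linspace(log_lo, log_hi, 7):
            res = _fit_once(x, y, p0=[y.min(), y.max(), log_ec50_0])
            if res is None:
                continue
            popt, pcov, rss = res
            key = (round(rss, 12), -popt[2])
            if best is None or key < best[0]:
                best = (key, popt, pcov, rss)
    if best is None:
        raise FitFailureError(
            f"{curve.receptor}/{curve.ligand}: no multistart fit converged "
            f"({len(x)} points, range 10^{log_lo:.1f}..10^{log_hi:.1f} M)"
        )
    _, popt, pcov, rss = best
    bottom, top, log_ec50 = popt
    if top < bottom:
        # relabel plateaus so emax >= baseline (fit is symmetric in them)
        bottom, top = top, bottom
        pcov = pcov[[1, 0, 2]][:, [1, 0, 2]]
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    in_range = log_lo <= log_ec50 <= log_hi
    if not in_range:
        warnings.warn(
            f"{curve.receptor}/{curve.ligand}: fitted EC50 outside tested range"
        )
    # incomplete curve: the observed maximum stays well below the fitted top
    incomplete = bool(y.max() < bottom + 0.8 * (top - bottom))
    return FitResult(
        pec50=-float(log_ec50),
        emax=float(top),
        baseline=float(bottom),
        se={"baseline": perr[0], "emax": perr[1], "pec50": perr[2]},
        rss=rss,
        n=len(x),
        ec50_in_range=bool(in_range),
        incomplete_curve=incomplete,
        curve=curve,
    )


def f_test_nested(curves: list[DoseResponseCurve]) -> FTestResult:
    """Shared-vs-separate three-parameter logistic comparison.

    The shared (null) model fits one parameter triple to the pooled data;
    the separate (alternative) model fits each dataset its own triple. The
    extra sum-of-squares F statistic with (df_shared - df_separate,
    df_separate) degrees of freedom tests whether separate curves are
    warranted.
    """
    if len(curves) < 2:
        raise XlgeomError("need >= 2 datasets to compare")
    fits = [fit_logistic3(c) for c in curves]
    sse_sep = sum(f.rss for f in fits)
    n_total = sum(f.n for f in fits)
    pooled = DoseResponseCurve(
        ligand="+".join(c.ligand for c in curves),
        receptor="+".join(c.receptor for c in curves),
        concentration_m=np.concatenate([c.concentration_m for c in curves]),
        response_pct=np.concatenate([c.response_pct for c in curves]),
    )
    shared_fit = fit_logistic3(pooled)
    sse_shared = shared_fit.rss
    k = 3
    df_sep = n_total - k * len(curves)
    df_shared = n_total - k
    if df_sep <= 0:
        raise XlgeomError("not enough points for the separate-fits model")
    sse_shared = max(sse_shared, sse_sep)  # guard tiny numerical inversions
    f_stat = ((sse_shared - sse_sep) / (df_shared - df_sep)) / (sse_sep / df_sep) \
        if sse_sep > 0 else np.inf
    p = float(stats.f.sf(f_stat, df_shared - df_sep, df_sep)) if np.isfinite(f_stat) else 0.0
    return FTestResult(
        sse_shared=sse_shared,
        sse_separate=sse_sep,
        df_shared=df_shared,
        df_separate=df_sep,
        f_statistic=float(f_stat),
        p_value=p,
    )


def normalize_surface_expression(mutant_gmfi: float, wt_gmfi: float) -> float:
    """Receptor surface expression as % of wild type."""
    if wt_gmfi <= 0:
        raise XlgeomError("wild-type GMFI must be positive")
    return 100.0 * mutant_gmfi / wt_gmfi
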