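"""Dose–response summarization: 4PL IC50 fits and log-dose AUC.

Viability (percent of vehicle) measured over an ascending dose series is
summarized two ways: a four-parameter logistic fit

    y = bottom + (top - bottom) / (1 + (x / ic50)^hill)

estimated by bounded least squares on log10 dose with multi-start IC50
initialization, and the trapezoidal area under the viability-vs-log10(dose)
curve (lower AUC = greater sensitivity).  Group sensitivity is compared with
a two-sided Mann–Whitney U test, exact for small groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


class DoseRangeError(ValueError):
    pass


class FlatResponseError(ValueError):
    """All responses equal: IC50 is not estimable."""


@dataclass
class DoseResponseCurve:
    compound_id: str
    subject_id: str
    concentrations: np.ndarray  # μM, strictly increasing, > 0
    viability: np.ndarray       # percent of vehicle

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.ndim != 1 or (
            len(self.concentrations) != len(self.viability)
        ):
            raise ValueError("concentrations and viability must align")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")
        if (np.diff(self.concentrations) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if not np.isfinite(self.viability).all():
            raise ValueError("viability must be finite")


@dataclass
class FitResult:
    ic50: float
    hill: float
    top: float
    bottom: float
    converged: bool
    residual_sse: float


@dataclass
class AUCResult:
    auc_raw: float   # percent × log10(μM)
    auc_norm: float  # auc_raw / (100 × log-range)
    log_range: float


def four_pl(x: np.ndarray, bottom: float, top: float, ic50: float,
            hill: float) -> np.ndarray:
    """Variable-slope four-parameter logistic, decreasing for hill > 0."""
    return bottom + (top - bottom) / (1.0 + (x / ic50) ** hill)


def fit_four_pl(
    curve: DoseResponseCurve,
    bottom_bounds: tuple[float, float] = (-10.0, 50.0),
    top_bounds: tuple[float, float] = (50.0, 120.0),
    hill_bounds: tuple[float, float] = (0.1, 10.0),
    n_starts: int = 5,
) -> FitResult:
    """Bounded least-squares 4PL fit with multi-start IC50 initialization.

    Starts from ``n_starts`` log-spaced IC50 seeds spanning the tested
    range; the best converged solution wins.  A flat response raises
    :class:`FlatResponseError`; non-convergence is reported honestly via
    ``converged=False`` with the best parameters still returned.
    """
    x = curve.concentrations
    y = curve.viability
    if len(np.unique(x)) < 4:
        raise DoseRangeError("4PL fitting needs >= 4 distinct concentrations")
    if np.ptp(y) == 0:
        raise FlatResponseError(
            "flat response: ic50 not estimable (no inhibition)"
        )
    logx = np.log10(x)

    def resid(theta):
        bottom, top, log_ic50, hill = theta
        return four_pl(x, bottom, top, 10.0 ** log_ic50, hill) - y

    lo = [bottom_bounds[0], top_bounds[0], logx.min() - 2, hill_bounds[0]]
    hi = [bottom_bounds[1], top_bounds[1], logx.max() + 2, hill_bounds[1]]
    b0 = float(np.clip(y.min(), *bottom_bounds))
    t0 = float(np.clip(y.max(), *top_bounds))
    best = None
    for log_ic50_0 in np.linspace(logx.min(), logx.max(), n_starts):
        theta0 = np.clip([b0, t0, log_ic50_0, 1.0], lo, hi)
        try:
            sol = optimize.least_squares(resid, theta0, bounds=(lo, hi),
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except ValueError:
            continue
        sse = float(2 * sol.cost)
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        return FitResult(np.nan, np.nan, np.nan, np.nan, False, np.inf)
    sse, sol = best
    bottom, top, log_ic50, hill = sol.x
    return FitResult(
        ic50=float(10.0 ** log_ic50), hill=float(hill), top=float(top),
        bottom=float(bottom), converged=bool(sol.success), residual_sse=sse,
    )


def auc_log_dose(curve: DoseResponseCurve, floor: float = 0.0) -> AUCResult:
    """Trapezoidal area under viability vs log10(concentration).

    Viability is clipped at ``floor`` (default 0) so a super-effective dose
    cannot contribute negative area.  ``auc_norm`` rescales by 100 × the
    log10-dose range so a fully viable curve scores 1.
    """
    if len(curve.concentrations) < 2:
        raise DoseRangeError("AUC needs >= 2 concentrations")
    logx = np.log10(curve.concentrations)
    y = np.clip(curve.viability, floor, None)
    raw = float(np.trapezoid(y, logx))
    rng = float(logx[-1] - logx[0])
    return AUCResult(auc_raw=raw, auc_norm=raw / (100.0 * rng), log_range=rng)


def normalize_to_vehicle(
    value: float, vehicle_value: float, as_percent: bool = False
) -> float:
    """Express a readout relative to its vehicle control (fold or percent)."""
    if not vehicle_value > 0:
        raise ZeroDivisionError("vehicle value must be positive")
    fold = value / vehicle_value
    return 100.0 * fold if as_percent else fold


def compare_sensitivity(
    group_a, group_b, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparing two groups of AUC values.

    Exact null distribution when both groups have ≤ ``exact_max_n``
    observations and no ties; normal approximation with tie correction
    otherwise.  Returns ``(U, p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    if max(len(a), len(b)) <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def summarize_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Fit + AUC summary for a long-format dose–response table.

    Expects columns ``compound_id, subject_id, concentration_uM,
    viability_pct`` (replicates averaged per concentration).
    """
    rows = []
    for (comp, subj), sub in table.groupby(["compound_id", "subject_id"]):
        avg = sub.groupby("concentration_uM")["viability_pct"].mean()
        curve = DoseResponseCurve(comp, subj, avg.index.to_numpy(),
                                  avg.to_numpy())
        rec = {"compound_id": comp, "subject_id": subj}
        try:
            fit = fit_four_pl(curve)
            rec.update(ic50=fit.ic50, hill=fit.hill, top=fit.top,
                       bottom=fit.bottom, converged=fit.converged,
                       residual_sse=fit.residual_sse)
        except (DoseRangeError, FlatResponseError) as exc:
            rec.update(ic50=np.nan, hill=np.nan, top=np.nan, bottom=np.nan,
                       converged=False, residual_sse=np.nan,
                       fit_note=str(exc))
        auc = auc_log_dose(curve)
        rec.update(auc_raw=auc.auc_raw, auc_norm=auc.auc_norm,
                   log_range=auc.log_range)
        rows.append(rec)
    return pd.DataFrame(rows)
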