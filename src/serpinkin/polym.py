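"""FRET polymerisation kinetics: half-times, Arrhenius analysis, fold-change.

Heat-induced serpin polymerisation is followed as a rising FRET signal at a
fixed hold temperature.  Each progress curve is reduced to a half-time t0.5
(time at which the signal has completed half of its total change), the
temperature dependence of t0.5 is summarised by an Arrhenius regression of
ln(t0.5) on 1/T, and variants are compared by the ratio of half-times
interpolated at a common reference temperature (default 54.8 degC).  With
this sign convention the slope is positive (half-times shrink as T rises)
and Ea = slope * R > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._regression import ols
from .constants import R_GAS
from .errors import DomainError, IncompleteCurveError, InsufficientDataError

HALF_TIME_METHODS = ("plateau_crossing", "exponential_fit")


@dataclass
class HalfTime:
    """Half-time of one polymerisation progress curve."""

    t05_s: float
    method: str
    lower_plateau: float
    upper_plateau: float
    temperature_k: float | None = None
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "t05_s": self.t05_s, "method": self.method,
            "lower_plateau": self.lower_plateau,
            "upper_plateau": self.upper_plateau,
            "temperature_K": self.temperature_k, "flags": list(self.flags),
        }


@dataclass
class ArrheniusFit:
    """OLS of ln(t0.5) on 1/T: slope (K), intercept; Ea = slope * R."""

    slope_k: float
    intercept: float
    cov: np.ndarray  # 2x2 covariance of (intercept, slope)
    r_squared: float
    n: int
    t_min_k: float
    t_max_k: float
    label: str = ""

    @property
    def ea_kj_mol(self) -> float:
        return self.slope_k * R_GAS / 1e3

    @property
    def ea_se_kj_mol(self) -> float:
        return float(np.sqrt(self.cov[1, 1])) * R_GAS / 1e3

    def to_dict(self) -> dict:
        return {
            "slope_K": self.slope_k, "intercept": self.intercept,
            "Ea_kJ_mol": self.ea_kj_mol, "Ea_se_kJ_mol": self.ea_se_kj_mol,
            "r_squared": self.r_squared, "n": self.n,
            "T_range_K": [self.t_min_k, self.t_max_k], "label": self.label,
        }


@dataclass
class InterpolatedHalfTime:
    t05_s: float
    tref_k: float
    extrapolated: bool


@dataclass
class FoldChange:
    """Ratio of half-times t05_a / t05_b at a reference temperature."""

    ratio: float
    ratio_se: float
    tref_k: float
    extrapolated: bool


def _saturating(t, a, b, k):
    return a - b * np.exp(-k * t)


def _exp_rise(t, y0, delta, k):
    return y0 + delta * (1.0 - np.exp(-k * t))


def half_time(time_s, signal, method: str = "plateau_crossing",
              temperature_k: float | None = None) -> HalfTime:
    """Half-time of a monotone-trend polymerisation trace.

    ``plateau_crossing`` (default, model-free): the lower plateau is the
    median of the first 5% of points, the upper plateau the asymptote of a
    monotone saturating fit; t0.5 is the first crossing of the normalized
    signal through 0.5, linearly interpolated between bracketing samples
    (earliest time on a flat segment).  ``exponential_fit`` fits
    y = y0 + delta*(1 - exp(-k t)) and returns ln2/k, usable on truncated
    curves.  The result is invariant to affine transforms of the signal.
    """
    if method not in HALF_TIME_METHODS:
        raise ValueError(f"method must be one of {HALF_TIME_METHODS}, got {method!r}")
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    n = t.size
    if n < 8:
        raise InsufficientDataError(f"need >= 8 points, got {n}")

    n_low = max(1, int(np.ceil(0.05 * n)))
    lower = float(np.median(y[:n_low]))
    tscale = float(np.ptp(t))
    # upper plateau: saturating-exponential asymptote fitted on the tail
    # (points past half the observed rise, where the approach is monotone);
    # the asymptote is bounded to half a dynamic range above the observed
    # maximum so a truncated curve cannot fake completion
    ymax = float(y.max())
    rise = max(ymax - lower, 1e-300)
    mask = y >= lower + 0.75 * rise
    tt, yy = (t[mask], y[mask]) if mask.sum() >= 4 else (t, y)
    p0 = [ymax, max(ymax - yy[0], 1e-12),
          3.0 / max(float(tt[-1] - tt[0]), 1e-12)]
    try:
        popt, _ = curve_fit(_saturating, tt, yy, p0=p0,
                            bounds=([lower, 0, 1e-12 / tscale],
                                    [ymax + 0.5 * rise, np.inf, np.inf]),
                            maxfev=20000)
        upper = float(popt[0])
    except RuntimeError:
        upper = float(np.median(y[-n_low:]))

    if method == "exponential_fit":
        p0 = [lower, max(upper - lower, 1e-12), 3.0 / tscale]
        popt, _ = curve_fit(_exp_rise, t, y, p0=p0,
                            bounds=([-np.inf, 0, 1e-12 / tscale],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=20000)
        k = float(popt[2])
        flags = ()
        if (y[-1] - lower) / max(popt[1], 1e-300) < 0.8:
            flags = ("incomplete_curve",)
        return HalfTime(float(np.log(2) / k), method, float(popt[0]),
                        float(popt[0] + popt[1]), temperature_k, flags)

    if upper <= lower:
        raise IncompleteCurveError("upper plateau not above lower plateau")

    def crossing(lo_plateau: float) -> float:
        ynorm = (y - lo_plateau) / (upper - lo_plateau)
        if ynorm[-1] < 0.8:
            raise IncompleteCurveError(
                f"final normalized signal {ynorm[-1]:.3f} < 0.8: curve "
                "incomplete (use exponential_fit for truncated curves)"
            )
        above = np.nonzero(ynorm >= 0.5)[0]
        if above.size == 0 or above[0] == 0:
            # crossing before the first sample is not resolvable
            raise DomainError("0.5 crossing not bracketed by the sampled times")
        j = int(above[0])
        y0n, y1n = ynorm[j - 1], ynorm[j]
        frac = (0.5 - y0n) / (y1n - y0n) if y1n > y0n else 0.0
        return float(t[j - 1] + frac * (t[j] - t[j - 1]))

    # refine the lower plateau once: on slow traces the first 5% of samples
    # can already be rising, so re-estimate it from the pre-transition
    # segment (times before 10% of the provisional half-time)
    t05 = crossing(lower)
    early = t <= t[0] + 0.1 * (t05 - t[0])
    if early.sum() >= 3:
        refined = float(np.median(y[early]))
        if refined < lower:
            lower = refined
            t05 = crossing(lower)
    return HalfTime(t05, method, lower, upper, temperature_k)


def arrhenius_fit(points, label: str = "") -> ArrheniusFit:
    """Fit ln(t0.5) vs 1/T by OLS over >= 3 distinct temperatures.

    ``points`` is an iterable of (T in K, t0.5 in s).
    """
    pts = [(float(T), float(t05)) for T, t05 in points]
    if any(t05 <= 0 for _, t05 in pts):
        raise DomainError("all half-times must be positive")
    temps = np.array([T for T, _ in pts])
    if len(set(temps)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct temperatures, got {len(set(temps))}"
        )
    t05s = np.array([t05 for _, t05 in pts])
    res = ols(1.0 / temps, np.log(t05s))
    return ArrheniusFit(
        slope_k=res.slope, intercept=res.intercept, cov=res.cov,
        r_squared=res.r_squared, n=res.n,
        t_min_k=float(temps.min()), t_max_k=float(temps.max()), label=label,
    )


def interpolate_half_time(fit: ArrheniusFit, tref_k: float) -> InterpolatedHalfTime:
    """t0.5 at a reference temperature: exp(intercept + slope/Tref).

    Temperatures more than 2 K outside the fitted range are permitted but
    flagged as extrapolation.
    """
    extrapolated = not (fit.t_min_k - 2.0 <= tref_k <= fit.t_max_k + 2.0)
    t05 = float(np.exp(fit.intercept + fit.slope_k / tref_k))
    return InterpolatedHalfTime(t05, float(tref_k), extrapolated)


def fold_change(fit_a: ArrheniusFit, fit_b: ArrheniusFit,
                tref_k: float) -> FoldChange:
    """Ratio t05_a(Tref) / t05_b(Tref) with a delta-method standard error.

    Since ln(ratio) = (ia - ib) + (sa - sb)/Tref is linear in the regression
    coefficients, its variance follows from the two (independent) fit
    covariances; SE(ratio) = ratio * SE(ln ratio).
    """
    ia, ib = interpolate_half_time(fit_a, tref_k), interpolate_half_time(fit_b, tref_k)
    ratio = ia.t05_s / ib.t05_s
    g = np.array([1.0, 1.0 / tref_k])  # gradient of ln t05 wrt (intercept, slope)
    var_ln = float(g @ fit_a.cov @ g + g @ fit_b.cov @ g)
    se = ratio * np.sqrt(var_ln) if np.isfinite(var_ln) else np.nan
    return FoldChange(float(ratio), float(se), float(tref_k),
                      ia.extrapolated or ib.extrapolated)
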