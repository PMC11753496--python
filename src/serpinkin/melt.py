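"""Thermal-denaturation analysis: two-state melt fitting and scan-rate kinetics.

A dye-reported melt curve is fitted with a two-state sigmoid on linear
baselines to obtain the observed midpoint Tm.  For an irreversible
denaturation step N -> I with Arrhenius rate k(T) = A exp(-Ea/RT) under a
linear temperature ramp of rate v, the midpoint shifts with v; ordinary
least squares of ln(v/Tm^2) on 1/Tm has slope -Ea/R (the classical
scan-rate / Kissinger-type transformation), giving the apparent activation
energy of the native-to-intermediate transition.  An alternative
transformation ln(v) vs 1/Tm is exposed; it differs by ~2RTm, well inside
typical replicate error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._regression import ols
from .constants import R_GAS, c_to_k
from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    NoTransitionError,
)

EA_MODES = ("kissinger", "lnv")


@dataclass
class TwoStateFit:
    """Result of fitting F(T) = B_pre(T) + [B_post(T) - B_pre(T)] / (1 + exp((Tm - T)/m))."""

    tm_c: float
    tm_se_c: float
    width_c: float
    pre_baseline: tuple[float, float]   # intercept, slope per degC
    post_baseline: tuple[float, float]
    residual_norm: float
    converged: bool
    window_c: tuple[float, float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "tm_C": self.tm_c, "tm_se_C": self.tm_se_c, "width_C": self.width_c,
            "pre_baseline": list(self.pre_baseline),
            "post_baseline": list(self.post_baseline),
            "residual_norm": self.residual_norm, "converged": self.converged,
            "window_C": list(self.window_c), "n_points": self.n_points,
        }


@dataclass
class RampSeries:
    """(scan rate, Tm) pairs for one variant, Tm in kelvin, ordered by rate."""

    v_k_per_min: np.ndarray
    tm_k: np.ndarray
    tm_se_k: np.ndarray
    variant: str = ""

    def __post_init__(self):
        self.v_k_per_min = np.asarray(self.v_k_per_min, dtype=float)
        self.tm_k = np.asarray(self.tm_k, dtype=float)
        self.tm_se_k = np.asarray(self.tm_se_k, dtype=float)
        if np.any(self.v_k_per_min <= 0):
            raise DomainError("scan rates must be positive")
        if len(set(self.v_k_per_min)) < 3:
            raise InsufficientDataError(
                f"need >= 3 distinct scan rates, got {len(set(self.v_k_per_min))}"
            )


@dataclass
class ActivationEnergyResult:
    """Apparent activation energy from the scan-rate dependence of Tm."""

    ea_kj_mol: float
    ea_se_kj_mol: float
    slope: float
    intercept: float
    r_squared: float
    n: int
    mode: str
    flags: tuple = ()
    gas_constant: float = R_GAS

    def to_dict(self) -> dict:
        return {
            "Ea_kJ_mol": self.ea_kj_mol, "Ea_se_kJ_mol": self.ea_se_kj_mol,
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "n": self.n, "mode": self.mode,
            "flags": list(self.flags), "R": self.gas_constant,
        }


def _two_state(t, tm, m, a_pre, b_pre, a_post, b_post):
    pre = a_pre + b_pre * t
    post = a_post + b_post * t
    frac = 1.0 / (1.0 + np.exp(np.clip((tm - t) / m, -500, 500)))
    return pre + (post - pre) * frac


def _noise_mad(y: np.ndarray) -> float:
    """Robust noise scale from successive differences (MAD-based)."""
    d = np.diff(y)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def fit_two_state(temperature_c, signal, window_c=None) -> TwoStateFit:
    """Fit a two-state transition with linear baselines to one melt trace.

    If no window is given, the fit runs from the first temperature to the
    temperature of the global signal maximum (dye signal decays above the
    transition, invalidating the two-state model there).  Initial Tm is the
    temperature of the maximum of a smoothed first derivative (ties broken
    towards lower temperature).
    """
    t = np.asarray(temperature_c, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size != y.size:
        raise ValueError("temperature and signal must have equal length")
    order = np.argsort(t, kind="stable")
    t, y = t[order], y[order]
    if window_c is None:
        # locate the global maximum on a lightly smoothed trace so that
        # point noise cannot move the window endpoint along the peak
        ks = max(3, t.size // 50) | 1
        ysm = np.convolve(y, np.ones(ks) / ks, mode="same")
        window_c = (float(t[0]), float(t[int(np.argmax(ysm))]))
    lo, hi = float(window_c[0]), float(window_c[1])
    mask = (t >= lo) & (t <= hi)
    tw, yw = t[mask], y[mask]
    if tw.size < 8:
        raise InsufficientDataError(
            f"need >= 8 points in the fit window, got {tw.size}"
        )
    span = float(np.ptp(tw))
    noise = _noise_mad(yw)
    # judge the dynamic range on a smoothed trace so that pure noise cannot
    # masquerade as a transition
    ks = max(3, tw.size // 10) | 1
    ysm_range = float(np.ptp(np.convolve(yw, np.ones(ks) / ks, mode="valid")))
    if ysm_range == 0 or (noise > 0 and ysm_range < 5 * noise):
        raise NoTransitionError(
            "dynamic range below 5x the noise level: no resolvable transition"
        )

    # initial Tm from smoothed first derivative; first (lowest-T) maximum
    dy = np.gradient(yw, tw)
    k = max(3, tw.size // 10) | 1
    kern = np.ones(k) / k
    dys = np.convolve(dy, kern, mode="same")
    tm0 = float(tw[int(np.argmax(dys))])
    m0 = max(span / 20.0, 1e-3)
    n_edge = max(2, tw.size // 5)
    pre0 = np.polyfit(tw[:n_edge], yw[:n_edge], 1)
    post0 = np.polyfit(tw[-n_edge:], yw[-n_edge:], 1)
    p0 = [np.clip(tm0, lo, hi), m0, pre0[1], pre0[0], post0[1], post0[0]]
    bounds = ([lo, 1e-6, -np.inf, -np.inf, -np.inf, -np.inf],
              [hi, span if span > 0 else np.inf, np.inf, np.inf, np.inf, np.inf])
    # fluorescence noise is predominantly multiplicative, so weight by the
    # observed signal (floored at 5% of its maximum to keep near-zero
    # baseline points from dominating): homoscedastic relative residuals
    sigma = np.maximum(np.abs(yw), 0.05 * float(np.max(np.abs(yw))))
    try:
        popt, pcov = curve_fit(_two_state, tw, yw, p0=p0, bounds=bounds,
                               sigma=sigma, absolute_sigma=False,
                               maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return TwoStateFit(np.nan, np.nan, np.nan, (np.nan, np.nan),
                           (np.nan, np.nan), np.nan, False, (lo, hi), tw.size)
    resid = yw - _two_state(tw, *popt)
    tm_se = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.nan
    return TwoStateFit(
        tm_c=float(popt[0]), tm_se_c=tm_se, width_c=float(popt[1]),
        pre_baseline=(float(popt[2]), float(popt[3])),
        post_baseline=(float(popt[4]), float(popt[5])),
        residual_norm=float(np.linalg.norm(resid)), converged=converged,
        window_c=(lo, hi), n_points=int(tw.size),
    )


def build_ramp_series(fits, variant: str = "") -> RampSeries:
    """Assemble (scan rate, Tm) pairs from per-rate two-state fits.

    ``fits`` is a list of (v in degC/min, TwoStateFit).  All fits must have
    converged.  Duplicate rates are aggregated to the mean Tm with
    propagated SE; Tm is converted to kelvin and the series ordered by rate.
    """
    agg: dict[float, list[TwoStateFit]] = {}
    for v, fit in fits:
        if not fit.converged:
            raise DomainError(f"unconverged fit at scan rate {v}")
        agg.setdefault(float(v), []).append(fit)
    vs, tms, ses = [], [], []
    for v in sorted(agg):
        group = agg[v]
        tm = float(np.mean([f.tm_c for f in group]))
        se = float(np.sqrt(np.nansum([f.tm_se_c ** 2 for f in group])) / len(group))
        vs.append(v)
        tms.append(c_to_k(tm))
        ses.append(se)
    return RampSeries(np.array(vs), np.array(tms), np.array(ses), variant=variant)


def ramp_series_from_table(df, variant: str) -> RampSeries:
    """RampSeries from a table with columns variant, v_C_per_min, tm_C, tm_se_C."""
    sub = df[df["variant"] == variant].sort_values("v_C_per_min")
    if sub.empty:
        raise KeyError(f"variant {variant!r} not in table")
    return RampSeries(
        sub["v_C_per_min"].to_numpy(dtype=float),
        c_to_k(sub["tm_C"].to_numpy(dtype=float)),
        sub["tm_se_C"].to_numpy(dtype=float) if "tm_se_C" in sub else
        np.full(len(sub), np.nan),
        variant=variant,
    )


def ramp_rate_activation_energy(series: RampSeries, mode: str = "kissinger",
                                weighted: bool = False) -> ActivationEnergyResult:
    """Apparent Ea from the scan-rate dependence of the melt midpoint.

    Default ``kissinger`` mode regresses ln(v/Tm^2) on 1/Tm; ``lnv`` mode
    regresses ln(v) on 1/Tm.  In both, Ea = -slope * R.  A non-monotone
    Tm-vs-rate series is flagged as non-kinetic behaviour rather than
    rejected.
    """
    if mode not in EA_MODES:
        raise ValueError(f"mode must be one of {EA_MODES}, got {mode!r}")
    v, tm = series.v_k_per_min, series.tm_k
    x = 1.0 / tm
    y = np.log(v / tm ** 2) if mode == "kissinger" else np.log(v)
    weights = None
    if weighted:
        se = series.tm_se_k
        if np.any(~np.isfinite(se)) or np.any(se <= 0):
            raise DomainError("weighted mode requires finite positive Tm SEs")
        weights = 1.0 / se ** 2
    if np.ptp(x) == 0:
        raise DegenerateInputError("all Tm identical: zero regressor variance")
    res = ols(x, y, weights=weights)
    flags = ()
    order = np.argsort(v)
    if not np.all(np.diff(tm[order]) > 0):
        flags = ("non-kinetic behaviour",)
    return ActivationEnergyResult(
        ea_kj_mol=-res.slope * R_GAS / 1e3,
        ea_se_kj_mol=res.slope_se * R_GAS / 1e3,
        slope=res.slope, intercept=res.intercept, r_squared=res.r_squared,
        n=res.n, mode=mode, flags=flags,
    )
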