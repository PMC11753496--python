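"""Sphere-of-action Stern-Volmer analysis of stepwise quenching titrations.

Tryptophan fluorescence is suppressed by stepwise addition of a small-molecule
quencher (acrylamide) to the cuvette.  Each addition both raises the quencher
concentration and dilutes the protein, so the raw signal is corrected by the
current/initial volume ratio before analysis.  The corrected ratio F0/F vs
[Q] is fitted with the sphere-of-action model

    F0/F = Yint + KSV * [Q] * exp(V * [Q])

where KSV (M^-1) is the dynamic Stern-Volmer constant and V (M^-1) encodes
static quenching by quenchers already within a critical volume of the
fluorophore at excitation, producing the upward curvature seen in plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from ._regression import ols
from .errors import DomainError, InsufficientDataError

#: upper bound on the sphere term; a fit pinned here is unidentifiable
V_MAX = 50.0


@dataclass
class QuenchTitration:
    """Dilution-corrected titration: [Q] (M), F_corr, running volume (uL)."""

    q_m: np.ndarray
    f_corr: np.ndarray
    volume_ul: np.ndarray

    def __post_init__(self):
        self.q_m = np.asarray(self.q_m, dtype=float)
        self.f_corr = np.asarray(self.f_corr, dtype=float)
        self.volume_ul = np.asarray(self.volume_ul, dtype=float)
        if self.q_m[0] != 0:
            raise DomainError("first titration point must have [Q] = 0")
        if np.any(np.diff(self.q_m) <= 0):
            raise DomainError("[Q] must be strictly increasing")
        if np.any(np.diff(self.volume_ul) < 0):
            raise DomainError("volumes must be non-decreasing")
        if np.any(self.f_corr <= 0):
            raise DomainError("corrected fluorescence must be positive")

    @property
    def f0(self) -> float:
        return float(self.f_corr[0])


@dataclass
class SternVolmerFit:
    ksv_m: float       # M^-1
    v_m: float         # M^-1
    yint: float
    ksv_se: float
    v_se: float
    yint_se: float
    residual_norm: float
    converged: bool
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {
            "KSV_M^-1": self.ksv_m, "V_M^-1": self.v_m, "Yint": self.yint,
            "KSV_se": self.ksv_se, "V_se": self.v_se, "Yint_se": self.yint_se,
            "residual_norm": self.residual_norm, "converged": self.converged,
            "flags": list(self.flags),
        }


def build_titration(raw, initial_volume_ul: float,
                    stock_conc_m: float) -> QuenchTitration:
    """Assemble a dilution-corrected titration from stepwise additions.

    ``raw`` is a list of (F_raw, added volume in uL per step), the first
    entry with added volume 0.  [Q]_i is cumulative quencher moles over the
    current volume; F_corr_i = F_raw_i * (current volume / initial volume).
    """
    if stock_conc_m <= 0:
        raise DomainError("stock concentration must be positive")
    rows = [(float(f), float(dv)) for f, dv in raw]
    if not rows or rows[0][1] != 0:
        raise DomainError("first point must have added volume 0")
    if any(dv < 0 for _, dv in rows):
        raise DomainError("shrinking volume: negative addition")
    if any(f <= 0 for f, _ in rows):
        raise DomainError("raw fluorescence must be positive")
    vol = float(initial_volume_ul)
    added_total = 0.0
    qs, fs, vols = [], [], []
    for f_raw, dv in rows:
        vol += dv
        added_total += dv
        q = added_total * stock_conc_m / vol  # uL cancels: mol/L
        qs.append(q)
        fs.append(f_raw * vol / initial_volume_ul)
        vols.append(vol)
    return QuenchTitration(np.array(qs), np.array(fs), np.array(vols))


def _sphere_of_action(q, yint, ksv, v):
    return yint + ksv * q * np.exp(v * q)


def fit_sphere_of_action(titration: QuenchTitration,
                         fix_yint: bool = False) -> SternVolmerFit:
    """Nonlinear least squares of F0/F on the sphere-of-action model.

    Initial values: Yint = 1, KSV from the OLS slope of the first three
    points, V = 0.  V is bounded to [0, 50] M^-1; a fit pinned at the upper
    bound is flagged as having an unidentifiable sphere term.  With
    ``fix_yint`` the intercept is held at exactly 1.
    """
    q, ratio = titration.q_m, titration.f0 / titration.f_corr
    if q.size < 4:
        raise InsufficientDataError(f"need >= 4 titration points, got {q.size}")
    ksv0 = max(ols(q[:3], ratio[:3]).slope, 1e-6)
    flags: tuple = ()
    if fix_yint:
        def model(qq, ksv, v):
            return _sphere_of_action(qq, 1.0, ksv, v)
        p0, lb, ub = [ksv0, 0.0], [0.0, 0.0], [np.inf, V_MAX]
    else:
        model = _sphere_of_action
        p0, lb, ub = [1.0, ksv0, 0.0], [-np.inf, 0.0, 0.0], [np.inf, np.inf, V_MAX]
    try:
        popt, pcov = curve_fit(model, q, ratio, p0=p0, bounds=(lb, ub),
                               maxfev=20000)
        converged = True
    except RuntimeError:
        popt = np.full(len(p0), np.nan)
        pcov = np.full((len(p0), len(p0)), np.nan)
        converged = False
    se = np.sqrt(np.diag(pcov))
    if fix_yint:
        yint, yint_se = 1.0, 0.0
        ksv, v = popt
        ksv_se, v_se = se
    else:
        yint, ksv, v = popt
        yint_se, ksv_se, v_se = se
    if converged and v >= V_MAX - 1e-6:
        flags += ("sphere term unidentifiable",)
    if converged and abs(yint - 1.0) > 0.1:
        flags += ("intercept far from 1",)
    resid = ratio - model(q, *popt) if converged else np.full_like(q, np.nan)
    return SternVolmerFit(
        ksv_m=float(ksv), v_m=float(v), yint=float(yint),
        ksv_se=float(ksv_se), v_se=float(v_se), yint_se=float(yint_se),
        residual_norm=float(np.linalg.norm(resid)), converged=converged,
        flags=flags,
    )
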