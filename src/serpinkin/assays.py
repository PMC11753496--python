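"""Bulk solution-state assays: spectral summaries and inhibition stoichiometry.

Covers the centre of spectral mass (COSM, the intensity-weighted mean
emission wavelength), intensity ratios between sample and reference spectra
(peak or integral mode), the stoichiometry of inhibition (SI) from a
protease residual-activity titration, and the conversion of SI to a percent
loss of inhibitory activity.  An SI above 1 means some inhibitor molecules
are consumed as substrate rather than forming the covalent complex; the
productive fraction is 1/SI, so the activity reduction is (1 - 1/SI) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._regression import ols
from .errors import DomainError, InsufficientDataError
from .io import SpectrumRecord

#: residual-activity readings at or below this are treated as saturated zeros
ACTIVITY_FLOOR = 0.05


@dataclass
class CosmResult:
    cosm_nm: float
    range_nm: tuple[float, float]
    total_intensity: float


@dataclass
class SIResult:
    """Stoichiometry of inhibition: x-intercept of the activity titration."""

    si: float
    si_se: float
    slope: float
    intercept: float
    n: int
    flags: tuple = ()

    def to_dict(self) -> dict:
        return {"SI": self.si, "SI_se": self.si_se, "slope": self.slope,
                "intercept": self.intercept, "n": self.n, "flags": list(self.flags)}


def cosm(spectrum: SpectrumRecord, range_nm=None) -> CosmResult:
    """Centre of spectral mass: sum(lambda_i * F_i) / sum(F_i) over the range."""
    wl, inten = spectrum.wavelength, spectrum.intensity
    if range_nm is not None:
        lo, hi = float(range_nm[0]), float(range_nm[1])
        mask = (wl >= lo) & (wl <= hi)
        wl, inten = wl[mask], inten[mask]
    else:
        lo, hi = float(spectrum.wavelength[0]), float(spectrum.wavelength[-1])
    total = float(inten.sum())
    if total <= 0:
        raise DomainError("zero total intensity in the requested range")
    return CosmResult(float((wl * inten).sum() / total), (lo, hi), total)


def _trapz_overlap(spec: SpectrumRecord, lo: float, hi: float) -> float:
    """Trapezoidal area of a spectrum over [lo, hi], interpolating endpoints."""
    wl, inten = spec.wavelength, spec.intensity
    grid = np.unique(np.concatenate([wl[(wl > lo) & (wl < hi)], [lo, hi]]))
    return float(np.trapezoid(np.interp(grid, wl, inten), grid))


def intensity_ratio(sample: SpectrumRecord, reference: SpectrumRecord,
                    mode: str = "peak") -> float:
    """Sample/reference intensity ratio.

    ``peak``: ratio of maxima; ``integral``: ratio of trapezoidal areas over
    the overlapping wavelength range.
    """
    if mode not in ("peak", "integral"):
        raise ValueError(f"mode must be 'peak' or 'integral', got {mode!r}")
    lo = max(sample.wavelength[0], reference.wavelength[0])
    hi = min(sample.wavelength[-1], reference.wavelength[-1])
    if hi <= lo:
        raise DomainError("sample and reference wavelength ranges do not overlap")
    if mode == "peak":
        ref_max = float(reference.intensity.max())
        if ref_max <= 0:
            raise DomainError("reference spectrum has zero peak intensity")
        return float(sample.intensity.max()) / ref_max
    ref_area = _trapz_overlap(reference, lo, hi)
    if ref_area <= 0:
        raise DomainError("reference spectrum has zero area in the overlap")
    return _trapz_overlap(sample, lo, hi) / ref_area


def fit_si(series) -> SIResult:
    """Stoichiometry of inhibition from (I:E ratio, residual activity) pairs.

    OLS of activity on ratio using only points above the saturation floor
    (activity > 0.05); SI is the x-intercept -intercept/slope, with a
    delta-method SE.  An activity at ratio 0 outside [0.8, 1.2] flags bad
    normalization; a non-negative slope means no inhibition.
    """
    pts = [(float(r), float(a)) for r, a in series]
    if len(pts) < 3:
        raise InsufficientDataError(f"need >= 3 titration points, got {len(pts)}")
    acts = [a for _, a in pts]
    if not (max(acts) > 0.5 and min(acts) < 0.5):
        raise DomainError("titration must bracket 50% residual activity")
    used = [(r, a) for r, a in pts if a > ACTIVITY_FLOOR]
    if len(used) < 3:
        raise InsufficientDataError("fewer than 3 points above the activity floor")
    r = np.array([p[0] for p in used])
    a = np.array([p[1] for p in used])
    res = ols(r, a)
    if res.slope >= 0:
        raise DomainError("non-negative slope: no inhibition detected")
    si = -res.intercept / res.slope
    # delta method on g(b0, b1) = -b0/b1
    grad = np.array([-1.0 / res.slope, res.intercept / res.slope ** 2])
    si_se = float(np.sqrt(grad @ res.cov @ grad))
    flags: tuple = ()
    zero_pts = [a_ for r_, a_ in pts if r_ == 0]
    if zero_pts and not (0.8 <= zero_pts[0] <= 1.2):
        flags = ("activity at ratio 0 outside [0.8, 1.2]",)
    return SIResult(float(si), si_se, res.slope, res.intercept, res.n, flags)


def activity_reduction(si: SIResult | float) -> float:
    """Percent reduction in inhibitory activity implied by an SI >= 1.

    With SI moles of inhibitor needed per mole of protease, only a fraction
    1/SI of molecules inhibit productively: reduction = (1 - 1/SI) * 100.
    """
    value = si.si if isinstance(si, SIResult) else float(si)
    if value < 1.0:
        raise DomainError(f"SI must be >= 1, got {value}")
    return (1.0 - 1.0 / value) * 100.0
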