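"""Forward simulators providing ground-truth inputs for every analysis stage.

The kinetic core is a minimal mass-action scheme for serpin polymerisation:
a native monomer M reversibly activates to a polymerisation-prone
intermediate M*, and two intermediates associate irreversibly,

    M <-> M*         (k1 forward, k-1 back, first order)
    M* + M* -> P     (k2, second order, irreversible)

with every rate constant Arrhenius-parameterized, k(T) = A exp(-Ea/RT).
Thermal melts are the same activation step under a linear temperature ramp
of rate v: the surviving native fraction obeys dN/dT = -k_d(T) N / v, and
the observed midpoint (N = 1/2) shifts up with v — the behaviour the
scan-rate analysis inverts.  Each simulator returns its ground truth
(true Tm, true t0.5, true model parameters) as machine-readable metadata so
parameter-recovery tests close the loop generator -> analysis -> truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp
from scipy.optimize import brentq

from .constants import R_GAS, k_to_c
from .errors import DomainError
from .quench import _sphere_of_action


@dataclass(frozen=True)
class ArrheniusRate:
    """k(T) = A exp(-Ea/RT); A in min^-1 (first order) or M^-1 min^-1
    (second order), Ea in J/mol."""

    prefactor: float
    ea_j_mol: float

    def __post_init__(self):
        if self.prefactor <= 0 or self.ea_j_mol < 0:
            raise DomainError("need prefactor > 0 and Ea >= 0")

    def rate_per_min(self, t_k):
        return self.prefactor * np.exp(-self.ea_j_mol / (R_GAS * np.asarray(t_k, dtype=float)))

    def scaled(self, factor: float) -> "ArrheniusRate":
        return ArrheniusRate(self.prefactor * factor, self.ea_j_mol)


@dataclass(frozen=True)
class SimScheme:
    """Arrhenius-parameterized rate constants for denaturation and the
    activation/association polymerisation scheme, plus the starting monomer
    concentration (uM)."""

    denaturation: ArrheniusRate
    activation: ArrheniusRate     # k1, M -> M*
    reversion: ArrheniusRate      # k-1, M* -> M
    association: ArrheniusRate    # k2, M* + M* -> P (M^-1 min^-1)
    m0_um: float = 5.0

    def __post_init__(self):
        if self.m0_um <= 0:
            raise DomainError("M0 must be positive")

    def scaled_rates(self, factor: float) -> "SimScheme":
        """All four rate constants multiplied by ``factor`` at every T."""
        return SimScheme(
            self.denaturation.scaled(factor), self.activation.scaled(factor),
            self.reversion.scaled(factor), self.association.scaled(factor),
            self.m0_um,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative + additive Gaussian noise with a fixed seed."""

    mult_sigma: float = 0.0
    add_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mult_sigma < 0 or self.add_sigma < 0:
            raise DomainError("noise sigmas must be >= 0")

    def apply(self, y: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        if rng is None:
            rng = np.random.default_rng(self.seed)
        y = np.asarray(y, dtype=float)
        out = y * (1.0 + self.mult_sigma * rng.standard_normal(y.shape))
        return out + self.add_sigma * rng.standard_normal(y.shape)


def calibrate_prefactor(ea_j_mol: float, tm_k: float, v_k_per_min: float) -> float:
    """Prefactor A (min^-1) placing the true melt midpoint at ``tm_k`` for
    scan rate ``v`` given Ea, from the closed-form midpoint condition
    k(Tm) R Tm^2 / (v Ea) = ln 2."""
    return (np.log(2.0) * v_k_per_min * ea_j_mol / (R_GAS * tm_k ** 2)
            * np.exp(ea_j_mol / (R_GAS * tm_k)))


def true_melt_tm(rate: ArrheniusRate, v_k_per_min: float) -> float:
    """Closed-form true midpoint (K) of a first-order irreversible melt under
    a linear ramp: solves k(Tm) R Tm^2 / (v Ea) = ln 2.

    This uses the standard asymptotic evaluation of the temperature integral
    (leading order in RT/Ea), so it agrees with direct integration to
    O(2RT/Ea) in the exponent — about 0.06 K here."""
    def f(t):
        return (rate.rate_per_min(t) * R_GAS * t ** 2
                / (v_k_per_min * rate.ea_j_mol) - np.log(2.0))
    return brentq(f, 200.0, 500.0)


# Default study conditions.  The denaturation step uses the wild-type
# apparent activation energy with the prefactor calibrated (via
# calibrate_prefactor) so the 1 K/min midpoint sits at 58.6 degC, placing the
# four-rate midpoints in the observed 56-63 degC band.  The polymerisation
# rates are calibrated constructs (no experimental rate constants exist):
# activation-limited, giving half-times from hours at 50 degC to minutes at
# 65 degC with Arrhenius-linear ln(t0.5).
DEFAULT_SCHEME = SimScheme(
    denaturation=ArrheniusRate(5.8138e43, 282.2e3),
    activation=ArrheniusRate(0.02 / np.exp(-250e3 / (R_GAS * 328.0)), 250e3),
    reversion=ArrheniusRate(0.01 / np.exp(-100e3 / (R_GAS * 328.0)), 100e3),
    association=ArrheniusRate(1e5 / np.exp(-50e3 / (R_GAS * 328.0)), 50e3),
    m0_um=5.0,
)

#: melt reporter baselines (intercept, slope) as functions of degC
DEFAULT_PRE_BASELINE = (0.25, 0.002)
DEFAULT_POST_BASELINE = (3.3, 0.004)

#: dye-release decay above the transition: onset offset (K above the true
#: midpoint, past transition completion) and sigmoid width (K) of the
#: post-peak signal loss
DEFAULT_DECAY = (12.0, 1.5)


@dataclass
class MeltSim:
    temperature_c: np.ndarray
    signal: np.ndarray
    native_fraction: np.ndarray
    true_tm_k: float
    v_k_per_min: float

    def truth(self) -> dict:
        return {"true_tm_K": self.true_tm_k, "true_tm_C": k_to_c(self.true_tm_k),
                "v_K_per_min": self.v_k_per_min}


def simulate_melt(scheme: SimScheme, v_k_per_min: float,
                  t_range_k: tuple[float, float] = (298.15, 363.15),
                  step_k: float = 0.1,
                  noise: NoiseModel | None = None,
                  pre_baseline: tuple[float, float] = DEFAULT_PRE_BASELINE,
                  post_baseline: tuple[float, float] = DEFAULT_POST_BASELINE,
                  decay: tuple[float, float] | None = DEFAULT_DECAY,
                  ) -> MeltSim:
    """Dye-reported melt curve under a linear ramp at scan rate v (K/min).

    Integrates the surviving native fraction N(T) = exp(-(1/v) int k_d dT)
    on a fine grid and mixes pre/post linear baselines by 1-N; the true
    midpoint (N = 1/2 crossing) is returned as oracle metadata.  ``decay``
    = (offset K, width K) applies a sigmoidal post-peak signal loss starting
    ``offset`` above the midpoint, emulating dye release once unfolding is
    complete (the reason melt traces peak and then fall); None disables it.
    """
    if v_k_per_min <= 0:
        raise DomainError("scan rate must be positive")
    t_k = np.arange(t_range_k[0], t_range_k[1] + step_k / 2, step_k)
    k = scheme.denaturation.rate_per_min(t_k)
    integral = cumulative_trapezoid(k / v_k_per_min, t_k, initial=0.0)
    n_frac = np.exp(-integral)
    if n_frac[0] < 0.99 or n_frac[-1] > 0.5:
        raise DomainError(
            "temperature range does not span the transition for this scheme"
        )
    # true Tm: interpolate the N = 1/2 crossing on ln N (locally linear)
    j = int(np.searchsorted(-n_frac, -0.5))
    ln_n = np.log(n_frac[j - 1:j + 1])
    frac = (np.log(0.5) - ln_n[0]) / (ln_n[1] - ln_n[0])
    true_tm = float(t_k[j - 1] + frac * step_k)
    t_c = k_to_c(t_k)
    pre = pre_baseline[0] + pre_baseline[1] * t_c
    post = post_baseline[0] + post_baseline[1] * t_c
    signal = pre * n_frac + post * (1.0 - n_frac)
    if decay is not None:
        offset, width = decay
        signal = signal / (1.0 + np.exp((t_k - (true_tm + offset)) / width))
    if noise is not None:
        signal = noise.apply(signal)
    return MeltSim(t_c, signal, n_frac, true_tm, v_k_per_min)


@dataclass
class PolymSim:
    time_s: np.ndarray
    signal: np.ndarray
    true_t05_s: float
    temperature_k: float
    final_polymer_fraction: float
    flags: tuple = ()

    def truth(self) -> dict:
        return {"true_t05_s": self.true_t05_s, "T_K": self.temperature_k,
                "final_polymer_fraction": self.final_polymer_fraction,
                "flags": list(self.flags)}


def _polym_rhs(k1_s, km1_s, k2_s):
    def rhs(t, y):
        m, ms, _ = y
        assoc = 2.0 * k2_s * ms * ms
        return [-k1_s * m + km1_s * ms,
                k1_s * m - km1_s * ms - assoc,
                assoc]
    return rhs


def solve_polym_dense(scheme: SimScheme, t_k: float, t_end_s: float | None = None):
    """Stiff-capable dense solution of the activation/association scheme at a
    hold temperature.  Returns (solve_ivp result, M0 in M, t_end used).

    Concentrations in M, time in s; state is (M, M*, P_mass) where P_mass
    counts monomer equivalents in polymer, so M + M* + P_mass = M0.
    """
    m0 = scheme.m0_um * 1e-6
    k1 = float(scheme.activation.rate_per_min(t_k)) / 60.0
    km1 = float(scheme.reversion.rate_per_min(t_k)) / 60.0
    k2 = float(scheme.association.rate_per_min(t_k)) / 60.0
    rhs = _polym_rhs(k1, km1, k2)
    if t_end_s is None:
        # find the 95% completion time by event, then pad
        def ev(t, y):
            return y[2] - 0.95 * m0
        ev.terminal = True
        ev.direction = 1
        probe = solve_ivp(rhs, (0.0, 1e9), [m0, 0.0, 0.0], method="LSODA",
                          rtol=1e-8, atol=1e-14, events=ev)
        if probe.t_events[0].size == 0:
            raise DomainError("polymerisation does not reach 95% within 1e9 s")
        t_end_s = 1.5 * float(probe.t_events[0][0])
    sol = solve_ivp(rhs, (0.0, t_end_s), [m0, 0.0, 0.0], method="LSODA",
                    rtol=1e-8, atol=1e-14, dense_output=True)
    if not sol.success:
        raise DomainError(f"integration failure: {sol.message}")
    return sol, m0, t_end_s


def true_polym_t05(scheme: SimScheme, t_k: float) -> float:
    """Oracle half-time (s): time at which polymer mass reaches M0/2, located
    by event detection on the dense ODE solution."""
    m0 = scheme.m0_um * 1e-6
    k1 = float(scheme.activation.rate_per_min(t_k)) / 60.0
    km1 = float(scheme.reversion.rate_per_min(t_k)) / 60.0
    k2 = float(scheme.association.rate_per_min(t_k)) / 60.0

    def ev(t, y):
        return y[2] - 0.5 * m0
    ev.terminal = True
    ev.direction = 1
    sol = solve_ivp(_polym_rhs(k1, km1, k2), (0.0, 1e9), [m0, 0.0, 0.0],
                    method="LSODA", rtol=1e-10, atol=1e-16, events=ev)
    if sol.t_events[0].size == 0:
        raise DomainError("half-completion not reached within 1e9 s")
    return float(sol.t_events[0][0])


def simulate_polym(scheme: SimScheme, t_k: float, t_end_s: float | None = None,
                   n_points: int = 200,
                   noise: NoiseModel | None = None) -> PolymSim:
    """FRET-like polymerisation progress curve at a hold temperature.

    The signal is the polymer mass fraction P_mass/M0 sampled at n_points
    evenly spaced times (plus noise); the true t0.5 comes from event
    detection on the dense solution.  A curve not reaching 90% completion is
    flagged incomplete but still returned.
    """
    sol, m0, t_end_s = solve_polym_dense(scheme, t_k, t_end_s)
    times = np.linspace(0.0, t_end_s, n_points)
    states = sol.sol(times)
    if states.min() < -1e-6 * m0:
        raise DomainError("negative concentrations beyond tolerance")
    signal = states[2] / m0
    final_frac = float(signal[-1])
    flags = () if final_frac >= 0.9 else ("incomplete",)
    if noise is not None:
        signal = noise.apply(signal)
    return PolymSim(times, signal, true_polym_t05(scheme, t_k), float(t_k),
                    final_frac, flags)


@dataclass
class QuenchSim:
    rows: list          # (F_raw, added_uL) pairs, analysis-reader ready
    initial_volume_ul: float
    stock_conc_m: float
    true_params: dict   # KSV, V, Yint


def simulate_quench(ksv_m: float, v_m: float, yint: float,
                    protocol: tuple[float, float, float, int] = (90.5, 1.9, 5.26, 5),
                    f0_raw: float = 1000.0,
                    noise: NoiseModel | None = None) -> QuenchSim:
    """Raw stepwise quenching titration — the exact inverse of the analysis.

    ``protocol`` is (initial volume uL, per-step addition uL, stock
    concentration M, number of steps); defaults follow a 90.5 -> 100 uL
    titration reaching ~0.5 M quencher in five equal steps.  Model F0/F
    values are un-corrected for dilution to produce the raw F the reader
    consumes.
    """
    initial_ul, step_ul, stock_m, n_steps = protocol
    if initial_ul <= 0 or step_ul < 0 or stock_m <= 0:
        raise DomainError("protocol volumes and stock must be positive")
    vol, added = float(initial_ul), 0.0
    rows: list[tuple[float, float]] = []
    raws = []
    for i in range(n_steps + 1):
        dv = 0.0 if i == 0 else float(step_ul)
        vol += dv
        added += dv
        q = added * stock_m / vol
        ratio = _sphere_of_action(q, yint, ksv_m, v_m)
        f_corr = f0_raw / ratio
        raws.append(f_corr * initial_ul / vol)
        rows.append(dv)
    raw_arr = np.array(raws)
    if noise is not None:
        raw_arr = noise.apply(raw_arr)
    return QuenchSim([(float(f), dv) for f, dv in zip(raw_arr, rows)],
                     float(initial_ul), float(stock_m),
                     {"KSV_M^-1": ksv_m, "V_M^-1": v_m, "Yint": yint})


def simulate_si(si_true: float, n_points: int = 8,
                noise: NoiseModel | None = None,
                r_max: float | None = None) -> tuple[list, dict]:
    """Linear residual-activity titration a(r) = max(0, 1 - r/SI) on an even
    inhibitor:enzyme ratio grid spanning past the intercept."""
    if si_true < 1.0:
        raise DomainError("SI must be >= 1")
    if r_max is None:
        r_max = 1.25 * si_true
    r = np.linspace(0.0, r_max, n_points)
    a = np.clip(1.0 - r / si_true, 0.0, None)
    if noise is not None:
        a = np.clip(noise.apply(a), 0.0, None)
    return list(zip(r.tolist(), a.tolist())), {"SI_true": si_true}


def make_toy_structures(out_dir, n_res: int = 40, base_b: float = 20.0,
                        b_spread: float = 2.0,
                        region: tuple[int, int] | None = None,
                        delta_b: float = 10.0, seed: int = 0,
                        ) -> tuple[str, str, dict]:
    """Synthetic PDB pair for the B-factor pipeline (labelled synthetic).

    Two files with identical ideal-helix backbone coordinates (poly-Ala,
    N/CA/C/O per residue) and a shared seeded per-residue B profile
    (base_b +/- b_spread); the second structure's B values are inflated by
    ``delta_b`` over the inclusive author-numbered ``region``.  Returns the
    two paths and the ground-truth perturbation.
    """
    import gemmi
    from pathlib import Path

    if region is None:
        mid = n_res // 2
        region = (max(1, mid - 3), min(n_res, mid + 3))
    if not (1 <= region[0] <= region[1] <= n_res):
        raise DomainError(f"region {region} outside residues 1..{n_res}")
    rng = np.random.default_rng(seed)
    profile = base_b + b_spread * rng.standard_normal(n_res)
    profile = np.clip(profile, 2.0, None)

    # ideal alpha-helix CA trace: 100 deg twist, 1.5 A rise, 2.3 A radius
    def build(b_values, name):
        st = gemmi.Structure()
        st.name = name
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        offsets = {"N": (-0.9, -0.8, -0.6), "CA": (0.0, 0.0, 0.0),
                   "C": (1.0, 0.6, 0.5), "O": (1.4, 1.6, 0.4)}
        for i in range(n_res):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            res.het_flag = "A"
            ang = np.deg2rad(100.0 * i)
            cx, cy, cz = 2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i
            for atom_name, (dx, dy, dz) in offsets.items():
                atom = gemmi.Atom()
                atom.name = atom_name
                atom.element = gemmi.Element(atom_name[0])
                atom.pos = gemmi.Position(cx + dx, cy + dy, cz + dz)
                atom.occ = 1.0
                atom.b_iso = float(b_values[i])
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        return st

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path_a = out_dir / "toy_reference.pdb"
    path_b = out_dir / "toy_perturbed.pdb"
    perturbed = profile.copy()
    lo, hi = region
    perturbed[lo - 1:hi] += delta_b
    build(profile, "synthetic reference").write_pdb(str(path_a))
    build(perturbed, "synthetic perturbed").write_pdb(str(path_b))
    truth = {"region": [int(lo), int(hi)], "delta_b": float(delta_b),
             "n_res": int(n_res), "seed": int(seed)}
    return str(path_a), str(path_b), truth
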