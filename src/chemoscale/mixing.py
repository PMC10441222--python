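"""Stirred-tank mixing and oxygen-transfer characterisation.

Covers the physical side of a constant-kLa scale-up: impeller tip speed,
ungassed and aerated (gassed) power input, superficial gas velocity, the
dynamic gassing-out estimator for the volumetric oxygen mass-transfer
coefficient kLa, a power/velocity kLa correlation, and root-solving for the
stirrer speed that realises a target kLa at a given gas flow.

The gassing-out experiment records dissolved oxygen (% air saturation)
after switching the sparge gas from nitrogen to air; in a well-mixed vessel
the response is C(t) = C* (1 - exp(-kLa t)), so kLa is the negative slope of
ln(1 - C/C*) against time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

RPM_TO_PER_SECOND = 1.0 / 60.0

#: Default mole fraction of O2 in air.
AIR_O2_FRACTION = 0.2095

#: Default admissible stirrer-speed range for operating-point solving [rpm].
DEFAULT_RPM_RANGE = (50.0, 1500.0)

#: Default %DO window for the log-linear kLa fit.  Points near saturation
#: make ln(1 - C/C*) ill-conditioned; points near zero may still be purging.
DEFAULT_FIT_WINDOW = (10.0, 90.0)

#: Michel-Miller gassed-power prefactor (SI inputs: W, 1/s, m, m^3/s).
MICHEL_MILLER_C = 0.72


@dataclass(frozen=True)
class ImpellerSpec:
    """One impeller stage: diameter [m], turbulent ungassed power number,
    and how many identical stages are mounted."""

    diameter: float
    power_number: float
    count: int = 1

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("impeller diameter must be > 0")
        if self.power_number <= 0:
            raise ValueError("power_number must be > 0")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass(frozen=True)
class ReactorSetup:
    """Geometry and operating point of a stirred, sparged bioreactor.

    ``gas_flow`` is the normalised air flow [L/min]; ``stirrer_speed`` is in
    rpm; ``total_volume``/``working_volume`` in L; diameters in m.
    """

    vessel_diameter: float
    total_volume: float
    working_volume: float
    impellers: tuple[ImpellerSpec, ...] = field(default_factory=tuple)
    sparger: str = "ring"
    stirrer_speed: float = 0.0
    gas_flow: float = 0.0
    overpressure: float = 0.0
    temperature: float = 75.0
    inlet_o2_fraction: float = AIR_O2_FRACTION

    def __post_init__(self) -> None:
        if self.working_volume > self.total_volume:
            raise ValueError("working_volume must not exceed total_volume")
        if self.stirrer_speed < 0 or self.gas_flow < 0:
            raise ValueError("stirrer_speed and gas_flow must be >= 0")
        if not 0.0 <= self.inlet_o2_fraction <= 1.0:
            raise ValueError("inlet_o2_fraction must be a mole fraction")
        if self.sparger not in ("ring", "micro"):
            raise ValueError("sparger must be 'ring' or 'micro'")


@dataclass(frozen=True)
class DOTrace:
    """A gassing-out dissolved-oxygen transient.

    ``time`` [h] strictly increasing, ``do_percent`` in % air saturation,
    ``saturation_value`` the calibrated 100 % level.
    """

    time: np.ndarray
    do_percent: np.ndarray
    saturation_value: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        d = np.asarray(self.do_percent, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "do_percent", d)
        if t.size < 5:
            raise ValueError("a DO trace needs at least 5 points")
        if t.size != d.size:
            raise ValueError("time and do_percent length mismatch")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class KlaEstimate:
    kla: float
    r_squared: float
    fit_window: tuple[float, float]
    n_points_used: int

    def __post_init__(self) -> None:
        if self.kla <= 0:
            raise ValueError("estimated kla must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class KlaCorrelation:
    """Power-law oxygen-transfer correlation kLa = a (Pg/VL)^x vs^y.

    ``coefficient`` carries the 1/h scale; exponents are on the aerated
    power input [kW/m^3] and the superficial gas velocity [m/s].
    """

    coefficient: float
    exponent_power: float
    exponent_gas: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("coefficient must be > 0")

    def predict(self, power_per_volume: float, gas_velocity: float) -> float:
        """Predicted kLa [1/h] at an aerated power input [kW/m^3] and
        superficial gas velocity [m/s]."""
        if power_per_volume <= 0 or gas_velocity <= 0:
            raise ValueError("correlation inputs must be > 0")
        return (self.coefficient
                * power_per_volume ** self.exponent_power
                * gas_velocity ** self.exponent_gas)


# ---------------------------------------------------------------------------
# Power and geometry
# ---------------------------------------------------------------------------

def tip_speed(setup: ReactorSetup) -> float:
    """Impeller tip speed [m/s]: pi * d * n with n in 1/s."""
    if not setup.impellers:
        raise ValueError("no impeller diameter defined")
    d = setup.impellers[0].diameter
    return math.pi * d * setup.stirrer_speed * RPM_TO_PER_SECOND


def geometry_ratio(setup: ReactorSetup, convention: str = "mm_per_L") -> float:
    """Reactor diameter over total volume, D_R/V_R.

    The default display convention is mm/L, which puts benchtop vessels in
    the tens and pilot vessels near unity; ``m_per_m3`` gives the same
    number (1 mm/L = 1 m/m^3).
    """
    if setup.total_volume <= 0:
        raise ValueError("total_volume must be > 0")
    if convention in ("mm_per_L", "m_per_m3"):
        return setup.vessel_diameter * 1000.0 / setup.total_volume
    raise ValueError(f"unknown convention {convention!r}")


def reynolds_number(setup: ReactorSetup, broth_density: float = 1000.0,
                    viscosity: float = 1e-3) -> float:
    """Impeller Reynolds number rho n d^2 / mu for the first impeller."""
    if not setup.impellers:
        raise ValueError("no impeller defined")
    n = setup.stirrer_speed * RPM_TO_PER_SECOND
    d = setup.impellers[0].diameter
    return broth_density * n * d * d / viscosity


def ungassed_power(setup: ReactorSetup, broth_density: float = 1000.0) -> float:
    """Ungassed agitation power [W]: sum over impellers of Np rho n^3 d^5.

    Valid in the turbulent regime (Re >= 1e4); a warning is emitted below
    that, where the constant power number overestimates the draw.
    """
    if broth_density <= 0:
        raise ValueError("broth density must be > 0")
    if not setup.impellers:
        raise ValueError("no impeller defined")
    n = setup.stirrer_speed * RPM_TO_PER_SECOND
    if n > 0 and reynolds_number(setup, broth_density) < 1e4:
        warnings.warn("impeller Reynolds number below 1e4; constant power "
                      "number assumes fully turbulent flow", stacklevel=2)
    return sum(imp.count * imp.power_number * broth_density * n ** 3
               * imp.diameter ** 5 for imp in setup.impellers)


def gassed_power(setup: ReactorSetup, ungassed: float,
                 coefficient: float = MICHEL_MILLER_C) -> float:
    """Aerated power draw [W] via the Michel-Miller correlation.

    Pg = c (P^2 n d^3 / Q^0.56)^0.45 with SI inputs (Q in m^3/s), capped at
    the ungassed power so that Pg -> P as Q -> 0.
    """
    if ungassed < 0:
        raise ValueError("ungassed power must be >= 0")
    if setup.gas_flow == 0 or ungassed == 0:
        return ungassed
    n = setup.stirrer_speed * RPM_TO_PER_SECOND
    d = setup.impellers[0].diameter
    q = setup.gas_flow / 1000.0 / 60.0  # L/min -> m^3/s
    pg = coefficient * (ungassed ** 2 * n * d ** 3 / q ** 0.56) ** 0.45
    return min(pg, ungassed)


def power_per_volume(gassed: float, working_volume: float) -> float:
    """Specific power input [kW/m^3] from power [W] and volume [L]
    (W/L and kW/m^3 are the same unit)."""
    if working_volume <= 0:
        raise ValueError("working_volume must be > 0")
    return gassed / working_volume


def superficial_gas_velocity(setup: ReactorSetup) -> float:
    """Superficial gas velocity [m/s]: volumetric flow over vessel
    cross-section."""
    if setup.vessel_diameter <= 0:
        raise ValueError("vessel_diameter must be > 0")
    area = math.pi * setup.vessel_diameter ** 2 / 4.0
    return setup.gas_flow / 1000.0 / 60.0 / area


def aerated_power_per_volume(setup: ReactorSetup,
                             broth_density: float = 1000.0) -> float:
    """Convenience chain: ungassed -> gassed -> per working volume
    [kW/m^3]."""
    pu = ungassed_power(setup, broth_density)
    pg = gassed_power(setup, pu)
    return power_per_volume(pg, setup.working_volume)


# ---------------------------------------------------------------------------
# Dynamic gassing-out
# ---------------------------------------------------------------------------

def simulate_do_step(kla: float, duration: float = 0.2,
                     sample_interval: float = 2e-4, probe_lag: float = 0.0,
                     noise_sd: float = 0.0, seed: int | None = None,
                     saturation: float = 100.0) -> DOTrace:
    """Synthesise a gassing-out DO transient for a known kLa [1/h].

    The liquid-phase response after the N2 -> air switch is
    C(t) = C* (1 - exp(-kLa t)); with a first-order probe lag tau [h] the
    measured signal is the two-exponential cascade response.  Gaussian noise
    of SD ``noise_sd`` [%DO] is added when requested; the trace is
    reproducible for a fixed seed.
    """
    if kla <= 0:
        raise ValueError("kla must be > 0")
    t = np.arange(0.0, duration + 0.5 * sample_interval, sample_interval)
    if probe_lag > 0:
        tau1, tau2 = 1.0 / kla, probe_lag
        if abs(tau1 - tau2) < 1e-12:
            c = saturation * (1 - np.exp(-t / tau1) * (1 + t / tau1))
        else:
            c = saturation * (1 - (tau1 * np.exp(-t / tau1)
                                   - tau2 * np.exp(-t / tau2)) / (tau1 - tau2))
    else:
        c = saturation * (1.0 - np.exp(-kla * t))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        c = c + rng.normal(0.0, noise_sd, size=c.shape)
    return DOTrace(time=t, do_percent=c, saturation_value=saturation)


def fit_kla(trace: DOTrace,
            window: tuple[float, float] = DEFAULT_FIT_WINDOW) -> KlaEstimate:
    """Estimate kLa [1/h] from a gassing-out trace.

    Linear regression of ln(1 - C/C*) against time over the %DO window;
    the negative slope is kLa and R^2 is reported for the regression.
    Points at or above the calibrated saturation are excluded.
    """
    lo, hi = window
    c_star = trace.saturation_value
    if np.max(trace.do_percent) >= c_star and np.min(trace.do_percent) >= c_star:
        raise ValueError("trace never below saturation; nothing to fit")
    mask = ((trace.do_percent >= lo) & (trace.do_percent <= hi)
            & (trace.do_percent < c_star))
    if int(mask.sum()) < 5:
        raise ValueError(
            f"fewer than 5 points inside the {lo}-{hi} %DO window")
    t = trace.time[mask]
    y = np.log(1.0 - trace.do_percent[mask] / c_star)
    res = stats.linregress(t, y)
    kla = -res.slope
    if kla <= 0:
        raise ValueError("non-decaying trace: fitted kla is not positive")
    return KlaEstimate(kla=kla, r_squared=float(res.rvalue ** 2),
                       fit_window=(lo, hi), n_points_used=int(mask.sum()))


# ---------------------------------------------------------------------------
# Correlation and scale translation
# ---------------------------------------------------------------------------

def fit_kla_correlation(points: list[tuple[float, float, float]]) -> KlaCorrelation:
    """Fit kLa = a (Pg/VL)^x vs^y by least squares on logs.

    ``points`` are (Pg/VL [kW/m^3], vs [m/s], kLa [1/h]) triples from
    gassing-out experiments at distinct operating conditions.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points to fit the correlation")
    arr = np.asarray(points, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all correlation inputs must be > 0")
    design = np.column_stack([np.ones(len(arr)), np.log(arr[:, 0]),
                              np.log(arr[:, 1])])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate design: conditions do not span "
                         "power and gas-velocity variation")
    coef, *_ = np.linalg.lstsq(design, np.log(arr[:, 2]), rcond=None)
    return KlaCorrelation(coefficient=float(np.exp(coef[0])),
                          exponent_power=float(coef[1]),
                          exponent_gas=float(coef[2]))


def predict_kla(setup: ReactorSetup, corr: KlaCorrelation,
                broth_density: float = 1000.0) -> float:
    """kLa [1/h] predicted by a fitted correlation for an operating point."""
    return corr.predict(aerated_power_per_volume(setup, broth_density),
                        superficial_gas_velocity(setup))


def solve_operating_point(target_kla: float, setup: ReactorSetup,
                          corr: KlaCorrelation,
                          fixed_gas_flow: float | None = None,
                          rpm_range: tuple[float, float] = DEFAULT_RPM_RANGE,
                          tolerance: float = 0.01,
                          broth_density: float = 1000.0) -> ReactorSetup:
    """Find the stirrer speed that realises a target kLa at fixed gas flow.

    Root-solves predicted-kLa(rpm) = target over the admissible rpm range;
    returns a copy of ``setup`` at the solved speed. Raises with the
    achievable kLa interval when the target is outside it.
    """
    if target_kla <= 0:
        raise ValueError("target_kla must be > 0")
    gas_flow = setup.gas_flow if fixed_gas_flow is None else fixed_gas_flow
    base = replace(setup, gas_flow=gas_flow)

    def predicted(rpm: float) -> float:
        return predict_kla(replace(base, stirrer_speed=rpm), corr,
                           broth_density)

    current = predict_kla(base, corr, broth_density) if base.stirrer_speed > 0 else None
    if current is not None and abs(current - target_kla) / target_kla <= tolerance:
        return base

    lo, hi = rpm_range
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # low-rpm bracket probes may be laminar
        k_lo, k_hi = predicted(lo), predicted(hi)
        if not (min(k_lo, k_hi) <= target_kla <= max(k_lo, k_hi)):
            raise ValueError(
                f"target kLa {target_kla:.3g} 1/h outside achievable range "
                f"[{min(k_lo, k_hi):.3g}, {max(k_lo, k_hi):.3g}] 1/h for "
                f"rpm in [{lo:g}, {hi:g}]")
        rpm = optimize.brentq(lambda r: predicted(r) - target_kla, lo, hi,
                              xtol=1e-6, rtol=1e-12)
    solved = replace(base, stirrer_speed=float(rpm))
    achieved = predict_kla(solved, corr, broth_density)
    if abs(achieved - target_kla) / target_kla > tolerance:
        raise RuntimeError("root solve did not reach the requested tolerance")
    return solved
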