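"""Synthetic three-phase cultivation with known ground truth.

Simulates batch -> exponential fed-batch -> chemostat operation of a
thermoacidophilic archaeal culture growing on two carbon substrates
(glucose and monosodium glutamate) with dual-substrate Monod kinetics,
constant-rate extracellular trehalose formation, carbon-conserving CO2
production, oxygen consumption tied to CO2 via a true respiratory
quotient, kLa-driven dissolved-oxygen dynamics, and off-gas generation.
The state trajectory is sampled into the tabular schemas the analysis
pipeline consumes, with optional multiplicative measurement noise.

Growth model: the specific growth rate is split between the two substrates
in proportion to their carbon share in the feed, each share saturating by
its own Monod term:

    mu = mu_max * (phi_glc * S_glc/(Ks_glc+S_glc) + phi_msg * S_msg/(Ks_msg+S_msg))

Carbon is conserved exactly: CO2 production is the carbon consumed from
the substrates minus the carbon fixed in biomass and trehalose, and O2
consumption is CO2 production divided by the true RQ.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from . import composition as comp
from .mixing import AIR_O2_FRACTION, DOTrace, ImpellerSpec, ReactorSetup, simulate_do_step
from .physiology import FeedComposition, OffGasRecord, SampleRecord

#: Effective dissolved-oxygen saturation under air at process temperature
#: and pressure [mmol/L].  Not a tabulated solubility: a lumped process
#: constant, configurable per vessel.
DEFAULT_DO_SATURATION = 0.28

#: Inlet CO2 mole fraction of air.
AIR_CO2_FRACTION = 0.0004

#: Broth/feed density assumed when converting gravimetric feed rates to
#: volumetric flows [g/L].
FEED_DENSITY = 1000.0

#: Batch phase ends when total residual substrate falls below this [g/L].
BATCH_END_SUBSTRATE = 0.02

_CF = comp.DEFAULT_BIOMASS.carbon_fraction / comp.CARBON_MOLAR_MASS  # C-mol/g DCW
_C_GLC = comp.GLUCOSE.carbon_atoms / comp.GLUCOSE.molar_mass          # C-mol/g
_C_MSG = comp.MSG.carbon_atoms / comp.MSG.molar_mass
_C_TRE = comp.TREHALOSE.carbon_atoms / comp.TREHALOSE.molar_mass


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and observation parameters of the synthetic culture.

    Defaults are realistic for a slow-growing thermoacidophile on a
    defined glucose/glutamate medium: mu_max 0.05 1/h, affinity constants
    well below residual-substrate levels, biomass yields 0.30 g/g on both
    substrates, a small constant trehalose formation rate, and RQ 1 (full
    oxidative carbon metabolism).
    """

    mu_max: float = 0.05
    Ks_glc: float = 0.05
    Ks_msg: float = 0.10
    Y_xs_glc: float = 0.30
    Y_xs_msg: float = 0.30
    q_tre_const: float = 0.001
    rq_true: float = 1.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu_max", "Ks_glc", "Ks_msg", "Y_xs_glc", "Y_xs_msg",
                     "rq_true"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.q_tre_const < 0 or self.noise_cv < 0:
            raise ValueError("q_tre_const and noise_cv must be >= 0")

    def _core(self) -> tuple:
        """Fields that affect the deterministic trajectory (not the noise)."""
        return (self.mu_max, self.Ks_glc, self.Ks_msg, self.Y_xs_glc,
                self.Y_xs_msg, self.q_tre_const, self.rq_true)


@dataclass(frozen=True)
class ProcessSchedule:
    """Phase structure of the cultivation.

    The batch starts at ``batch_volume`` on the batch medium carbon loads;
    an exponential feed ramp (``feed_start_rate`` [g/h] growing at
    ``feed_mu_set``) raises the volume to ``target_volume``; the chemostat
    then holds the volume by a constant-height bleed while the feed sets
    the dilution rate ``chemostat_D``.
    """

    batch_volume: float = 1.5
    batch_glc: float = 1.0
    batch_msg: float = 2.0
    inoculum_dcw: float = 0.05
    feed_start_rate: float = 14.8
    feed_mu_set: float = 0.035
    target_volume: float = 2.0
    chemostat_D: float = 0.03
    chemostat_duration: float = 340.0
    feed_msg: float = 9.5
    feed_glc: float = 4.5
    feed_trehalose: float = 0.0
    acid_fraction: float = 0.02
    sample_interval: float = 24.0
    weekend_gap: bool = False

    def __post_init__(self) -> None:
        if self.target_volume <= self.batch_volume:
            raise ValueError("target_volume must exceed batch_volume")
        if self.chemostat_D <= 0:
            raise ValueError("chemostat_D must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")

    @property
    def feed(self) -> FeedComposition:
        return FeedComposition(msg=self.feed_msg, glucose=self.feed_glc,
                               trehalose=self.feed_trehalose)


@dataclass
class SimOutput:
    """Simulator output: sampled tables plus the realised ground truth."""

    samples: list[SampleRecord]
    offgas: list[OffGasRecord]
    do_trace: DOTrace
    truth: dict
    schedule: ProcessSchedule
    kinetics: KineticParams
    setup: ReactorSetup


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

# State vector layout.
_V, _X, _SG, _SM, _P, _CO2, _O2, _FEED, _ACID, _BLEED, _BC, _CDO = range(12)


def _kinetic_rates(y: np.ndarray, k: KineticParams, sched: ProcessSchedule
                   ) -> dict[str, float]:
    """Instantaneous biological rates from a state vector (per hour)."""
    V = y[_V]
    X = max(y[_X], 0.0)
    s_g = max(y[_SG], 0.0) / V
    s_m = max(y[_SM], 0.0) / V
    c_g_feed = sched.feed_glc * _C_GLC
    c_m_feed = sched.feed_msg * _C_MSG
    phi_g = c_g_feed / (c_g_feed + c_m_feed)
    phi_m = 1.0 - phi_g
    mu_g = k.mu_max * phi_g * s_g / (k.Ks_glc + s_g)
    mu_m = k.mu_max * phi_m * s_m / (k.Ks_msg + s_m)
    r_tre = k.q_tre_const * X                      # g trehalose / h
    # Trehalose carbon is drawn from the glucose pool (glucose-equivalent
    # mass), keeping the overall carbon balance closed.
    r_glc = mu_g * X / k.Y_xs_glc + r_tre * _C_TRE / _C_GLC
    r_msg = mu_m * X / k.Y_xs_msg
    mu = mu_g + mu_m
    co2_cmol = (r_glc * _C_GLC + r_msg * _C_MSG
                - mu * X * _CF - r_tre * _C_TRE)
    co2_mol = max(co2_cmol, 0.0)
    o2_mol = co2_mol / k.rq_true
    return dict(mu=mu, r_glc=r_glc, r_msg=r_msg, r_tre=r_tre,
                co2_mol=co2_mol, o2_mol=o2_mol)


def _flows(t: float, y: np.ndarray, phase: str, sched: ProcessSchedule,
           t_phase_start: float) -> tuple[float, float, float]:
    """(F_feed, F_acid, F_bleed) in L/h for a phase at time t."""
    if phase == "batch":
        return 0.0, 0.0, 0.0
    if phase == "fedbatch":
        f = (sched.feed_start_rate / FEED_DENSITY
             * np.exp(sched.feed_mu_set * (t - t_phase_start)))
        return f, sched.acid_fraction * f, 0.0
    # chemostat: feed + acid set D; bleed holds the volume constant
    f_total = sched.chemostat_D * sched.target_volume
    f_feed = f_total / (1.0 + sched.acid_fraction)
    return f_feed, sched.acid_fraction * f_feed, f_total


def _rhs(t: float, y: np.ndarray, phase: str, t_phase_start: float,
         sched: ProcessSchedule, k: KineticParams, kla: float,
         do_sat: float) -> np.ndarray:
    V = y[_V]
    f_feed, f_acid, f_bleed = _flows(t, y, phase, sched, t_phase_start)
    r = _kinetic_rates(y, k, sched)
    x = max(y[_X], 0.0) / V
    s_g = max(y[_SG], 0.0) / V
    s_m = max(y[_SM], 0.0) / V
    p = max(y[_P], 0.0) / V
    dy = np.empty_like(y)
    dy[_V] = f_feed + f_acid - f_bleed
    dy[_X] = r["mu"] * y[_X] - f_bleed * x
    dy[_SG] = f_feed * sched.feed_glc - r["r_glc"] - f_bleed * s_g
    dy[_SM] = f_feed * sched.feed_msg - r["r_msg"] - f_bleed * s_m
    dy[_P] = f_feed * sched.feed_trehalose + r["r_tre"] - f_bleed * p
    dy[_CO2] = r["co2_mol"]
    dy[_O2] = r["o2_mol"]
    dy[_FEED] = f_feed
    dy[_ACID] = f_acid
    dy[_BLEED] = f_bleed
    dy[_BC] = f_bleed * (x * _CF + s_g * _C_GLC + s_m * _C_MSG + p * _C_TRE)
    our_vol = 1000.0 * r["o2_mol"] / V            # mmol/L/h
    dy[_CDO] = kla * (do_sat - y[_CDO]) - our_vol
    return dy


@lru_cache(maxsize=8)
def _integrate(sched: ProcessSchedule, core: tuple, kla: float,
               do_sat: float) -> tuple:
    """Integrate the three phases; returns ((phase, t0, t1, sol), ...).

    Cached on the deterministic inputs so that repeated noisy samplings of
    the same process (seed sweeps) do not re-run the ODE solver.
    """
    k = KineticParams(*core)
    y0 = np.zeros(12)
    y0[_V] = sched.batch_volume
    y0[_X] = sched.inoculum_dcw * sched.batch_volume
    y0[_SG] = sched.batch_glc * sched.batch_volume
    y0[_SM] = sched.batch_msg * sched.batch_volume
    y0[_CDO] = do_sat
    phases = []
    t = 0.0

    def run(phase: str, t_end: float, events=None):
        nonlocal t, y0
        sol = solve_ivp(_rhs, (t, t_end), y0, method="LSODA",
                        args=(phase, t, sched, k, kla, do_sat),
                        events=events, dense_output=True,
                        rtol=1e-8, atol=1e-10, max_step=5.0)
        if not sol.success:
            raise RuntimeError(f"{phase} integration failed: {sol.message}")
        t1 = sol.t[-1]
        phases.append((phase, t, t1, sol))
        t, y0 = t1, sol.y[:, -1].copy()

    def substrate_gone(tt, yy, *a):
        return (yy[_SG] + yy[_SM]) / yy[_V] - BATCH_END_SUBSTRATE
    substrate_gone.terminal = True
    substrate_gone.direction = -1

    def volume_reached(tt, yy, *a):
        return yy[_V] - sched.target_volume
    volume_reached.terminal = True
    volume_reached.direction = 1

    run("batch", 400.0, events=substrate_gone)
    run("fedbatch", t + 400.0, events=volume_reached)
    chemostat_start = t
    run("chemostat", t + sched.chemostat_duration)
    return tuple(phases), chemostat_start


def _state_at(phases: tuple, t: float) -> tuple[str, float, np.ndarray]:
    for phase, t0, t1, sol in phases:
        if t <= t1 or (phase, t0, t1, sol) is phases[-1]:
            return phase, t0, sol.sol(min(t, t1))
    raise ValueError(f"time {t} outside the simulated horizon")


def _sample_times(sched: ProcessSchedule, t_end: float) -> np.ndarray:
    """Sampling grid; with ``weekend_gap`` every sixth interval is 72 h
    (five daily samples, then a weekend skip)."""
    if not sched.weekend_gap:
        return np.arange(0.0, t_end + 1e-9, sched.sample_interval)
    times, t, i = [0.0], 0.0, 0
    while t < t_end:
        t += 72.0 if (i % 6 == 5) else sched.sample_interval
        i += 1
        if t <= t_end:
            times.append(t)
    return np.asarray(times)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def simulate_cultivation(schedule: ProcessSchedule = ProcessSchedule(),
                         kinetics: KineticParams = KineticParams(),
                         setup: ReactorSetup | None = None,
                         kla: float = 38.8,
                         do_saturation: float = DEFAULT_DO_SATURATION,
                         viability_level: float = 91.0) -> SimOutput:
    """Run the three-phase cultivation and sample it into pipeline tables.

    Multiplicative Gaussian noise with CV ``kinetics.noise_cv`` is applied
    to the measured quantities (DCW, OD, concentrations, viability and the
    off-gas mole-fraction differences); flows and volumes are balance
    readings and stay exact. Reproducible for a fixed ``kinetics.seed``.
    A chemostat dilution rate above the achievable growth rate washes the
    culture out; the output is still valid and carries a washout flag.
    """
    if setup is None:
        setup = PRESETS["2L"].setup
    phases, chemostat_start = _integrate(schedule, kinetics._core(), kla,
                                         do_saturation)
    t_end = phases[-1][2]
    rng = np.random.default_rng(kinetics.seed)
    cv = kinetics.noise_cv

    def jitter(v: float) -> float:
        return v * (1.0 + cv * rng.standard_normal()) if cv > 0 else v

    q_gas = setup.gas_flow * 60.0  # L/min -> L/h
    samples: list[SampleRecord] = []
    offgas: list[OffGasRecord] = []
    for t in _sample_times(schedule, t_end):
        phase, t0, y = _state_at(phases, t)
        V = y[_V]
        x, s_g, s_m, p = (max(y[i], 0.0) / V for i in (_X, _SG, _SM, _P))
        dcw = jitter(x)
        samples.append(SampleRecord(
            time=t, volume=V, dcw=dcw,
            od=jitter(x * comp.OD540_PER_DCW),
            dcw_sd=cv * x if cv > 0 else float("nan"),
            glucose=jitter(s_g), msg=jitter(s_m), trehalose=jitter(p),
            viability=jitter(viability_level),
            cum_feed=y[_FEED], cum_acid=y[_ACID], cum_bleed=y[_BLEED]))
        r = _kinetic_rates(y, kinetics, schedule)
        if q_gas <= 0:
            raise ValueError("setup.gas_flow must be > 0 to generate off-gas")
        dy_co2 = jitter(r["co2_mol"] * comp.GAS_MOLAR_VOLUME / q_gas)
        dy_o2 = jitter(r["o2_mol"] * comp.GAS_MOLAR_VOLUME / q_gas)
        offgas.append(OffGasRecord(
            time=t, y_o2_in=setup.inlet_o2_fraction,
            y_o2_out=max(setup.inlet_o2_fraction - dy_o2, 0.0),
            y_co2_in=AIR_CO2_FRACTION,
            y_co2_out=min(AIR_CO2_FRACTION + dy_co2, 1.0),
            gas_flow=q_gas))

    do_trace = simulate_do_step(kla=kla, noise_sd=1.0 if cv > 0 else 0.0,
                                seed=kinetics.seed + 1)
    truth = _realized_truth(phases, chemostat_start, schedule, kinetics,
                            setup, kla, do_saturation)
    return SimOutput(samples=samples, offgas=offgas, do_trace=do_trace,
                     truth=truth, schedule=schedule, kinetics=kinetics,
                     setup=setup)


def _realized_truth(phases: tuple, chemostat_start: float,
                    sched: ProcessSchedule, k: KineticParams,
                    setup: ReactorSetup, kla: float,
                    do_saturation: float = DEFAULT_DO_SATURATION) -> dict:
    t_end = phases[-1][2]
    _, _, y = _state_at(phases, t_end)
    V = y[_V]
    x = y[_X] / V
    r = _kinetic_rates(y, k, sched)
    X = y[_X]
    # Washout check: biomass decline over the last dwell time.
    t_back = max(t_end - 1.0 / sched.chemostat_D, chemostat_start)
    _, _, y_back = _state_at(phases, t_back)
    washout = y[_X] < 0.95 * y_back[_X]
    return {
        "kinetics": dataclasses.asdict(k),
        "kla": kla,
        "chemostat_start": chemostat_start,
        "t_end": t_end,
        "D": sched.chemostat_D,
        "washout": bool(washout),
        "x_ss": x,
        "s_glc_ss": y[_SG] / V,
        "s_msg_ss": y[_SM] / V,
        "trehalose_ss": y[_P] / V,
        "mu_ss": r["mu"],
        "q_glc_ss": r["r_glc"] / X,
        "q_msg_ss": r["r_msg"] / X,
        "q_tre_ss": r["r_tre"] / X,
        "cer_ss": 1000.0 * r["co2_mol"] / V,
        "our_ss": 1000.0 * r["o2_mol"] / V,
        "rq_ss": k.rq_true,
        "do_percent_ss": 100.0 * y[_CDO] / do_saturation,
    }


def carbon_closure(sim: SimOutput) -> float:
    """Cumulative carbon recovery of the realised trajectory.

    Carbon out (broth inventory + CO2 + bleed losses) over carbon in
    (initial broth + cumulative feed); 1.0 means exact conservation.
    """
    phases, _ = _integrate(sim.schedule, sim.kinetics._core(),
                           sim.truth["kla"], DEFAULT_DO_SATURATION)
    _, _, y = _state_at(phases, sim.truth["t_end"])
    sched = sim.schedule
    c_in = (sched.batch_volume * (sched.batch_glc * _C_GLC
                                  + sched.batch_msg * _C_MSG
                                  + sched.inoculum_dcw * _CF)
            + y[_FEED] * (sched.feed_glc * _C_GLC + sched.feed_msg * _C_MSG
                          + sched.feed_trehalose * _C_TRE))
    c_out = (y[_X] * _CF + max(y[_SG], 0) * _C_GLC + max(y[_SM], 0) * _C_MSG
             + y[_P] * _C_TRE + y[_CO2] + y[_BC])
    return c_out / c_in


def emit_fixtures(sim: SimOutput, out_dir: str | Path) -> dict[str, Path]:
    """Write the sample, off-gas and DO-trace CSVs plus the truth JSON."""
    from . import io as cio
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out / "samples.csv",
        "offgas": out / "offgas.csv",
        "dotrace": out / "dotrace.csv",
        "truth": out / "truth.json",
    }
    cio.write_samples(sim.samples, paths["samples"])
    cio.write_offgas(sim.offgas, paths["offgas"])
    cio.write_dotrace(sim.do_trace, paths["dotrace"])
    paths["truth"].write_text(json.dumps(sim.truth, indent=2, sort_keys=True))
    return paths


# ---------------------------------------------------------------------------
# Scenario presets (benchtop, lab, pilot scale)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    name: str
    setup: ReactorSetup
    schedule: ProcessSchedule
    kla: float


def _preset(name: str, vessel_d: float, total_v: float, working_v: float,
            imp_d: float, rpm: float, gas_lpm: float, overpressure: float,
            kla: float, batch_v: float, feed0: float) -> Scenario:
    setup = ReactorSetup(
        vessel_diameter=vessel_d, total_volume=total_v,
        working_volume=working_v,
        impellers=(ImpellerSpec(diameter=imp_d, power_number=5.0, count=2),),
        sparger="ring", stirrer_speed=rpm, gas_flow=gas_lpm,
        overpressure=overpressure, temperature=75.0,
        inlet_o2_fraction=AIR_O2_FRACTION)
    schedule = ProcessSchedule(batch_volume=batch_v, target_volume=working_v,
                               feed_start_rate=feed0)
    return Scenario(name=name, setup=setup, schedule=schedule, kla=kla)


#: Benchtop (2 L), lab (20 L) and pilot (200 L) scale presets at matched
#: kLa ~ 40 1/h: stirrer speed, airflow and geometry follow the study
#: conditions; impeller power numbers are generic Rushton-class values.
PRESETS: dict[str, Scenario] = {
    "2L": _preset("2L", 0.1224, 3.0, 2.0, 0.0522, 500.0, 0.51, 0.0,
                  38.8, 1.5, 14.8),
    "20L": _preset("20L", 0.2388, 30.0, 20.0, 0.0952, 285.0, 5.1, 0.2,
                   40.5, 15.0, 148.0),
    "200L": _preset("200L", 0.4710, 300.0, 200.0, 0.2008, 117.0, 37.5, 0.2,
                    41.1, 150.0, 1480.0),
}
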