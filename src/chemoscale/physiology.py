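"""Chemostat physiology: interval-wise rates, yields, gas exchange and
carbon-balance closure from sampling and off-gas tables.

All rates are computed per sampling interval from total amounts in the
broth (concentration x volume), with explicit correction for material
carried out by the bleed. Sign conventions: substrate uptake rates are
consumption-positive, product formation rates production-positive, and the
oxygen uptake rate is reported positive for consumption, so that all
yields and the respiratory quotient are positive numbers.

The carbon balance sums the biomass, CO2 and trehalose yields on the fed
substrate carbon, all in C-mol per C-mol; closure near 1.0 means the fate
of every fed carbon atom is accounted for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .composition import (
    CARBON_MOLAR_MASS,
    GAS_MOLAR_VOLUME,
    GLUCOSE,
    MSG,
    TREHALOSE,
    BiomassComposition,
    Compound,
    DEFAULT_BIOMASS,
    mass_to_cmol,
)

#: Dwell times (1/D) that must elapse after the chemostat start before
#: samples count as steady state.
STEADY_STATE_DWELL_TIMES = 4.0


@dataclass(frozen=True)
class SampleRecord:
    """One broth sampling point.

    ``msg`` is the substrate concentration on an MSG basis; assayed
    glutamic-acid readings are converted with the 1.15 factor before a
    record is built (see :func:`chemoscale.composition.msg_from_glutamate`).
    Cumulative feed/acid/bleed volumes [L] are totals since inoculation.
    """

    time: float
    volume: float
    dcw: float
    glucose: float
    msg: float
    trehalose: float
    od: float = float("nan")
    dcw_sd: float = float("nan")
    viability: float = float("nan")
    cum_feed: float = 0.0
    cum_acid: float = 0.0
    cum_bleed: float = 0.0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        for name in ("volume", "dcw", "glucose", "msg", "trehalose"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_biomass(self) -> float:
        """Total biomass in the broth [g]."""
        return self.dcw * self.volume


@dataclass(frozen=True)
class OffGasRecord:
    """Gas-phase mole fractions and normalised gas flow [L/h] at a time."""

    time: float
    y_o2_in: float
    y_o2_out: float
    y_co2_in: float
    y_co2_out: float
    gas_flow: float

    def __post_init__(self) -> None:
        for name in ("y_o2_in", "y_o2_out", "y_co2_in", "y_co2_out"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a mole fraction")
        if self.gas_flow < 0:
            raise ValueError("gas_flow must be >= 0")


@dataclass(frozen=True)
class FeedComposition:
    """Substrate concentrations in the feed [g/L]; trehalose normally 0."""

    msg: float
    glucose: float
    trehalose: float = 0.0

    def __post_init__(self) -> None:
        if min(self.msg, self.glucose, self.trehalose) < 0:
            raise ValueError("feed concentrations must be >= 0")


@dataclass(frozen=True)
class IntervalRates:
    """Rates over one sampling interval, stamped at its midpoint."""

    t_mid: float
    dt: float
    D: float
    mu: float
    dx: float                     # space-time yield D*x [g/L/h]
    q_glc: float
    q_msg: float
    q_tre: float
    cer: float = float("nan")
    our: float = float("nan")
    rq: float = float("nan")
    q_o2: float = float("nan")
    q_co2: float = float("nan")
    y_xs: float = float("nan")        # g/g on the gram-summed substrates
    y_xs_cmol: float = float("nan")   # C-mol/C-mol
    y_tre_s: float = float("nan")     # C-mol/C-mol
    y_co2_s: float = float("nan")     # C-mol/C-mol
    c_balance: float = float("nan")   # C-mol/C-mol


@dataclass(frozen=True)
class SteadyStateSummary:
    """Mean and STD% (100 * sample SD / mean) per parameter over the
    steady-state sampling intervals."""

    mean: dict[str, float] = field(default_factory=dict)
    std_percent: dict[str, float | None] = field(default_factory=dict)
    n_samples: int = 0


# ---------------------------------------------------------------------------
# Elementary rate operations
# ---------------------------------------------------------------------------

def dilution_rate(feed_flow: float, acid_flow: float, volume: float) -> float:
    """D [1/h] = (F_feed + F_acid) / V."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if feed_flow < 0 or acid_flow < 0:
        raise ValueError("flows must be >= 0")
    return (feed_flow + acid_flow) / volume


def specific_growth_rate(prev: SampleRecord, curr: SampleRecord) -> float:
    """mu [1/h] over a sampling interval, bleed-corrected.

    mu = (dX + dV_bleed * x_mean) / (X_mean * dt), where dX is the change in
    total broth biomass [g], dV_bleed the bleed volume removed in the
    interval, x_mean the mean DCW concentration and X_mean the mean total
    biomass.
    """
    dt = curr.time - prev.time
    if dt <= 0:
        raise ValueError("sampling times must be increasing")
    x_mean = 0.5 * (prev.dcw + curr.dcw)
    big_x_mean = 0.5 * (prev.total_biomass + curr.total_biomass)
    if big_x_mean <= 0:
        raise ValueError("mean biomass is zero; growth rate undefined")
    d_x = curr.total_biomass - prev.total_biomass
    d_v_bleed = curr.cum_bleed - prev.cum_bleed
    return (d_x + d_v_bleed * x_mean) / (big_x_mean * dt)


def space_time_yield(dcw: float, dilution: float) -> float:
    """Continuous biomass space-time yield D*x [g/L/h]."""
    if dcw < 0 or dilution < 0:
        raise ValueError("inputs must be >= 0")
    return dcw * dilution


def batch_space_time_yield(final_titer: float, duration: float) -> float:
    """Average batch/fed-batch space-time yield [g/L/h]: titer over time."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return final_titer / duration


def specific_consumption_rate(prev: SampleRecord, curr: SampleRecord,
                              feed_conc: float, broth_attr: str) -> float:
    """Consumption-positive specific uptake rate q_S [g/g/h] over an
    interval.

    q_S = (dS_reactor + S_in - S_out) / (dt * X_mean) with
    dS_reactor = S(prev) - S(curr) in grams of broth inventory, S_in the
    feed supply (feed concentration x feed volume; acid is substrate-free)
    and S_out the bleed discharge at the mean broth concentration.
    """
    if feed_conc is None or feed_conc < 0:
        raise ValueError("feed composition missing or negative")
    dt = curr.time - prev.time
    if dt <= 0:
        raise ValueError("sampling times must be increasing")
    big_x_mean = 0.5 * (prev.total_biomass + curr.total_biomass)
    if big_x_mean <= 0:
        raise ValueError("mean biomass is zero")
    s_prev = getattr(prev, broth_attr) * prev.volume
    s_curr = getattr(curr, broth_attr) * curr.volume
    s_in = feed_conc * (curr.cum_feed - prev.cum_feed)
    s_mean_conc = 0.5 * (getattr(prev, broth_attr) + getattr(curr, broth_attr))
    s_out = s_mean_conc * (curr.cum_bleed - prev.cum_bleed)
    return ((s_prev - s_curr) + s_in - s_out) / (dt * big_x_mean)


def specific_production_rate(prev: SampleRecord, curr: SampleRecord,
                             feed_conc: float = 0.0,
                             broth_attr: str = "trehalose") -> float:
    """Production-positive specific formation rate q_P [g/g/h]:
    q_P = (dP_reactor + P_out - P_in) / (dt * X_mean)."""
    # Same balance as consumption with both signs flipped.
    return -specific_consumption_rate(prev, curr, feed_conc, broth_attr)


def biomass_yield(mu: float, q_s_total: float) -> float:
    """Y_X/S [g/g] = mu / q_S."""
    if q_s_total == 0:
        raise ValueError("q_S is zero; yield undefined")
    return mu / q_s_total


def trehalose_yield(q_tre: float, q_s_cmol: float,
                    tre: Compound = TREHALOSE) -> float:
    """Y_Tre/S [C-mol/C-mol] from q_Tre [g/g/h] and the total substrate
    uptake already expressed in C-mol/g/h."""
    if q_s_cmol == 0:
        raise ValueError("q_S is zero; yield undefined")
    return mass_to_cmol(q_tre, tre) / q_s_cmol


def cer(record: OffGasRecord, volume: float) -> float:
    """Carbon evolution rate [mmol/L/h] from the CO2 gas-phase balance:
    (Qg / V) * (y_out - y_in) / Vm * 1000."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return (record.gas_flow / volume / GAS_MOLAR_VOLUME
            * (record.y_co2_out - record.y_co2_in) * 1000.0)


def our(record: OffGasRecord, volume: float) -> float:
    """Oxygen uptake rate [mmol/L/h], positive for consumption:
    (Qg / V) * (y_in - y_out) / Vm * 1000."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    return (record.gas_flow / volume / GAS_MOLAR_VOLUME
            * (record.y_o2_in - record.y_o2_out) * 1000.0)


def rq(cer_value: float, our_value: float) -> float:
    """Respiratory quotient CER/OUR."""
    if our_value <= 0:
        raise ValueError("OUR must be > 0 for RQ")
    return cer_value / our_value


def q_co2(cer_value: float, dcw: float) -> float:
    """Specific CO2 production rate [mmol/g/h] = CER / x."""
    if dcw <= 0:
        raise ValueError("DCW must be > 0")
    return cer_value / dcw


def q_o2(our_value: float, dcw: float) -> float:
    """Specific O2 consumption rate [mmol/g/h] = OUR / x."""
    if dcw <= 0:
        raise ValueError("DCW must be > 0")
    return our_value / dcw


def co2_yield(q_co2_value: float, q_s_cmol: float) -> float:
    """Y_CO2/S [C-mol/C-mol]; 1 mmol CO2 carries 1 mC-mol of carbon."""
    if q_s_cmol == 0:
        raise ValueError("q_S is zero; yield undefined")
    return (q_co2_value / 1000.0) / q_s_cmol


def c_balance(y_xs_cmol: float, y_co2_s: float, y_tre_s: float) -> float:
    """Carbon balance: Y_X/S + Y_CO2/S + Y_Tre/S, all in C-mol/C-mol."""
    if min(y_xs_cmol, y_co2_s, y_tre_s) < 0:
        raise ValueError("yields must be >= 0")
    return y_xs_cmol + y_co2_s + y_tre_s


# ---------------------------------------------------------------------------
# Steady-state selection and interval pipeline
# ---------------------------------------------------------------------------

def steady_state_window(records: Sequence[SampleRecord], chemostat_start: float,
                        dilution: float,
                        dwell_times: float = STEADY_STATE_DWELL_TIMES
                        ) -> list[SampleRecord]:
    """Samples taken after ``dwell_times`` theoretical dwell times (1/D)
    have elapsed in the chemostat, the point at which the culture is
    treated as steady."""
    if dilution <= 0:
        raise ValueError("dilution rate must be > 0")
    cutoff = chemostat_start + dwell_times / dilution
    kept = [r for r in records if r.time >= cutoff]
    if not kept:
        raise ValueError(
            f"no samples at or after the steady-state cutoff t = {cutoff:.1f} h")
    return kept


def _interp_offgas(offgas: Sequence[OffGasRecord], t: float) -> OffGasRecord:
    """Linear interpolation of the off-gas signals to time t."""
    times = np.array([g.time for g in offgas])
    def interp(attr: str) -> float:
        return float(np.interp(t, times, [getattr(g, attr) for g in offgas]))
    return OffGasRecord(time=t, y_o2_in=interp("y_o2_in"),
                        y_o2_out=interp("y_o2_out"),
                        y_co2_in=interp("y_co2_in"),
                        y_co2_out=interp("y_co2_out"),
                        gas_flow=interp("gas_flow"))


def interval_rates(samples: Sequence[SampleRecord],
                   offgas: Sequence[OffGasRecord] | None,
                   feed: FeedComposition,
                   biomass: BiomassComposition = DEFAULT_BIOMASS,
                   glucose: Compound = GLUCOSE, msg: Compound = MSG,
                   ) -> list[IntervalRates]:
    """Compute the full rate/yield set for every consecutive sample pair.

    Off-gas signals, when given, are interpolated to the interval midpoint;
    without off-gas the gas-derived fields are NaN. Irregular sampling
    intervals (weekend gaps) need no special handling: every balance is
    written over the actual dt.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for interval rates")
    out: list[IntervalRates] = []
    for prev, curr in zip(samples[:-1], samples[1:]):
        dt = curr.time - prev.time
        t_mid = 0.5 * (prev.time + curr.time)
        v_mean = 0.5 * (prev.volume + curr.volume)
        x_mean = 0.5 * (prev.dcw + curr.dcw)
        feed_flow = (curr.cum_feed - prev.cum_feed) / dt
        acid_flow = (curr.cum_acid - prev.cum_acid) / dt
        D = dilution_rate(feed_flow, acid_flow, v_mean)
        mu = specific_growth_rate(prev, curr)
        q_glc = specific_consumption_rate(prev, curr, feed.glucose, "glucose")
        q_msg = specific_consumption_rate(prev, curr, feed.msg, "msg")
        q_tre = specific_production_rate(prev, curr, feed.trehalose, "trehalose")

        q_s_gram = q_glc + q_msg
        q_s_cmol = (mass_to_cmol(max(q_glc, 0.0), glucose)
                    + mass_to_cmol(max(q_msg, 0.0), msg))
        y_xs = mu / q_s_gram if q_s_gram > 0 else float("nan")
        y_xs_cmol = ((mu * biomass.carbon_fraction / CARBON_MOLAR_MASS)
                     / q_s_cmol if q_s_cmol > 0 else float("nan"))
        y_tre_s = (trehalose_yield(max(q_tre, 0.0), q_s_cmol)
                   if q_s_cmol > 0 else float("nan"))

        cer_v = our_v = rq_v = qo2_v = qco2_v = y_co2_s = c_bal = float("nan")
        if offgas:
            gas = _interp_offgas(offgas, t_mid)
            cer_v = cer(gas, v_mean)
            our_v = our(gas, v_mean)
            if our_v > 0:
                rq_v = rq(cer_v, our_v)
            if x_mean > 0:
                qco2_v = q_co2(cer_v, x_mean)
                qo2_v = q_o2(our_v, x_mean)
                if q_s_cmol > 0 and qco2_v >= 0:
                    y_co2_s = co2_yield(qco2_v, q_s_cmol)
            if not any(map(math.isnan, (y_xs_cmol, y_co2_s, y_tre_s))):
                c_bal = c_balance(max(y_xs_cmol, 0.0), max(y_co2_s, 0.0),
                                  max(y_tre_s, 0.0))

        out.append(IntervalRates(
            t_mid=t_mid, dt=dt, D=D, mu=mu, dx=space_time_yield(x_mean, D),
            q_glc=q_glc, q_msg=q_msg, q_tre=q_tre,
            cer=cer_v, our=our_v, rq=rq_v, q_o2=qo2_v, q_co2=qco2_v,
            y_xs=y_xs, y_xs_cmol=y_xs_cmol, y_tre_s=y_tre_s,
            y_co2_s=y_co2_s, c_balance=c_bal))
    return out


_SUMMARY_FIELDS = ("D", "mu", "dx", "q_glc", "q_msg", "q_tre", "cer", "our",
                   "rq", "q_o2", "q_co2", "y_xs", "y_xs_cmol", "y_tre_s",
                   "y_co2_s", "c_balance")


def summarize_steady_state(rates: Sequence[IntervalRates]) -> SteadyStateSummary:
    """Mean and STD% (100 * sample SD / mean) per parameter over the
    steady-state intervals; STD% is None where the mean is zero or fewer
    than two finite values exist."""
    if len(rates) < 2:
        raise ValueError("need at least 2 intervals for a steady-state summary")
    mean: dict[str, float] = {}
    stdp: dict[str, float | None] = {}
    for name in _SUMMARY_FIELDS:
        vals = np.array([getattr(r, name) for r in rates], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        m = float(np.mean(vals))
        mean[name] = m
        if vals.size >= 2 and m != 0:
            stdp[name] = float(100.0 * np.std(vals, ddof=1) / m)
        else:
            stdp[name] = None
    return SteadyStateSummary(mean=mean, std_percent=stdp, n_samples=len(rates))
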