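"""File schemas, configuration and the end-to-end analysis pipeline.

CSV dialect: comma-separated, period decimal, UTF-8, mandatory header row.

Schemas
-------
samples.csv   time_h, volume_L, dcw_g_L, od540, glucose_g_L,
              msg_g_L *or* glutamate_g_L, trehalose_g_L, viability_pct,
              cum_feed_L, cum_acid_L, cum_bleed_L   (dcw_sd_g_L optional)
offgas.csv    time_h, y_o2_in, y_o2_out, y_co2_in, y_co2_out, gas_flow_L_h
dotrace.csv   time_h, do_percent

Assayed glutamic-acid columns (``glutamate_g_L``) are converted to an MSG
basis with the 1.15 factor on read.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .composition import msg_from_glutamate
from .mixing import DEFAULT_FIT_WINDOW, DOTrace
from .physiology import (
    FeedComposition,
    IntervalRates,
    OffGasRecord,
    SampleRecord,
    STEADY_STATE_DWELL_TIMES,
    SteadyStateSummary,
    interval_rates,
    steady_state_window,
    summarize_steady_state,
)

log = logging.getLogger("chemoscale")

SAMPLE_COLUMNS = ("time_h", "volume_L", "dcw_g_L", "glucose_g_L",
                  "trehalose_g_L", "cum_feed_L", "cum_acid_L", "cum_bleed_L")
OFFGAS_COLUMNS = ("time_h", "y_o2_in", "y_o2_out", "y_co2_in", "y_co2_out",
                  "gas_flow_L_h")
DOTRACE_COLUMNS = ("time_h", "do_percent")


def _load_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric value in column "
                             f"{col!r}, row {row}")
        df[col] = coerced
    if len(df) == 0:
        log.warning("%s: header-only file, no records", path)
    elif (df["time_h"].diff().dropna() <= 0).any():
        row = int(np.flatnonzero(df["time_h"].diff() <= 0)[0]) + 2
        raise ValueError(f"{path}: time_h not strictly increasing at row {row}")
    return df


def read_samples(path: str | Path) -> list[SampleRecord]:
    """Read a sampling table; glutamate columns are converted to MSG."""
    df = _load_table(path, SAMPLE_COLUMNS)
    if "msg_g_L" in df.columns:
        msg = df["msg_g_L"]
    elif "glutamate_g_L" in df.columns:
        msg = df["glutamate_g_L"].map(msg_from_glutamate)
        log.info("%s: converted glutamate_g_L to MSG basis (x 1.15)", path)
    else:
        raise ValueError(f"{path}: needs an msg_g_L or glutamate_g_L column")
    records = []
    for i, row in df.iterrows():
        records.append(SampleRecord(
            time=row["time_h"], volume=row["volume_L"], dcw=row["dcw_g_L"],
            od=row.get("od540", float("nan")),
            dcw_sd=row.get("dcw_sd_g_L", float("nan")),
            glucose=row["glucose_g_L"], msg=float(msg.iloc[i]),
            trehalose=row["trehalose_g_L"],
            viability=row.get("viability_pct", float("nan")),
            cum_feed=row["cum_feed_L"], cum_acid=row["cum_acid_L"],
            cum_bleed=row["cum_bleed_L"]))
    return records


def read_offgas(path: str | Path) -> list[OffGasRecord]:
    df = _load_table(path, OFFGAS_COLUMNS)
    return [OffGasRecord(time=r["time_h"], y_o2_in=r["y_o2_in"],
                         y_o2_out=r["y_o2_out"], y_co2_in=r["y_co2_in"],
                         y_co2_out=r["y_co2_out"], gas_flow=r["gas_flow_L_h"])
            for _, r in df.iterrows()]


def read_dotrace(path: str | Path, saturation: float = 100.0) -> DOTrace:
    df = _load_table(path, DOTRACE_COLUMNS)
    return DOTrace(time=df["time_h"].to_numpy(),
                   do_percent=df["do_percent"].to_numpy(),
                   saturation_value=saturation)


def write_samples(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame({
        "time_h": [r.time for r in records],
        "volume_L": [r.volume for r in records],
        "dcw_g_L": [r.dcw for r in records],
        "dcw_sd_g_L": [r.dcw_sd for r in records],
        "od540": [r.od for r in records],
        "glucose_g_L": [r.glucose for r in records],
        "msg_g_L": [r.msg for r in records],
        "trehalose_g_L": [r.trehalose for r in records],
        "viability_pct": [r.viability for r in records],
        "cum_feed_L": [r.cum_feed for r in records],
        "cum_acid_L": [r.cum_acid for r in records],
        "cum_bleed_L": [r.cum_bleed for r in records],
    }).to_csv(path, index=False)


def write_offgas(records: Sequence[OffGasRecord], path: str | Path) -> None:
    pd.DataFrame({
        "time_h": [r.time for r in records],
        "y_o2_in": [r.y_o2_in for r in records],
        "y_o2_out": [r.y_o2_out for r in records],
        "y_co2_in": [r.y_co2_in for r in records],
        "y_co2_out": [r.y_co2_out for r in records],
        "gas_flow_L_h": [r.gas_flow for r in records],
    }).to_csv(path, index=False)


def write_dotrace(trace: DOTrace, path: str | Path) -> None:
    pd.DataFrame({"time_h": trace.time,
                  "do_percent": trace.do_percent}).to_csv(path, index=False)


def intervals_to_frame(rates: Sequence[IntervalRates]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in rates])


# ---------------------------------------------------------------------------
# Run configuration and pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything the ``rates`` pipeline needs for one run.

    Either point at measured tables (``samples_path``/``offgas_path``) or
    name a simulator scenario (``scenario`` with ``noise_cv``/``seed``)
    to generate them. ``chemostat_start`` [h] marks the switch to
    continuous mode; the steady-state window opens ``dwell_times``/D hours
    later.
    """

    scenario: str | None = "2L"
    samples_path: str | None = None
    offgas_path: str | None = None
    feed: FeedComposition = field(
        default_factory=lambda: FeedComposition(msg=9.5, glucose=4.5))
    chemostat_start: float | None = None
    dilution_rate: float = 0.03
    dwell_times: float = STEADY_STATE_DWELL_TIMES
    fit_window: tuple[float, float] = DEFAULT_FIT_WINDOW
    noise_cv: float = 0.0
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "feed" in raw:
            raw["feed"] = FeedComposition(**raw["feed"])
        if "fit_window" in raw:
            raw["fit_window"] = tuple(raw["fit_window"])
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) "
                             f"{', '.join(sorted(unknown))}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute steady-state windowing -> interval rates -> yields ->
    C-balance -> summary; returns (and optionally writes) the report.

    The report carries the applied conventions (sign conventions, gas
    interpolation, steady-state rule) so every number is auditable.
    """
    from .simulate import KineticParams, PRESETS, simulate_cultivation

    if config.samples_path:
        samples = read_samples(config.samples_path)
        offgas = read_offgas(config.offgas_path) if config.offgas_path else None
        chemostat_start = config.chemostat_start
        if chemostat_start is None:
            raise ValueError("chemostat_start must be given for file input")
        truth = None
    else:
        scenario = PRESETS[config.scenario or "2L"]
        sim = simulate_cultivation(
            schedule=scenario.schedule,
            kinetics=KineticParams(noise_cv=config.noise_cv, seed=config.seed),
            setup=scenario.setup, kla=scenario.kla)
        samples, offgas, truth = sim.samples, sim.offgas, sim.truth
        chemostat_start = truth["chemostat_start"]
        log.info("simulated scenario %s: chemostat from t = %.1f h",
                 scenario.name, chemostat_start)

    window = steady_state_window(samples, chemostat_start,
                                 config.dilution_rate, config.dwell_times)
    log.info("steady state window: %d samples from t = %.1f h",
             len(window), window[0].time)
    rates = interval_rates(window, offgas, config.feed)
    summary = summarize_steady_state(rates)

    report = {
        "n_steady_samples": len(window),
        "steady_state_cutoff_h": chemostat_start
        + config.dwell_times / config.dilution_rate,
        "summary_mean": summary.mean,
        "summary_std_percent": summary.std_percent,
        "conventions": {
            "uptake_sign": "consumption-positive (dS = prev - curr)",
            "production_sign": "production-positive (dP = curr - prev)",
            "our_sign": "inlet minus outlet (positive for consumption)",
            "offgas_interpolation": "linear to interval midpoints",
            "steady_state_rule": f"{config.dwell_times} dwell times after "
                                 "chemostat start",
            "glutamate_to_msg_factor": 1.15,
        },
    }
    if truth is not None:
        report["truth"] = truth
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        intervals_to_frame(rates).to_csv(out / "interval_rates.csv",
                                         index=False)
        (out / "steady_state_summary.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def summary_from_report(report: dict) -> SteadyStateSummary:
    """Rebuild a SteadyStateSummary from a written report dict."""
    return SteadyStateSummary(mean=dict(report["summary_mean"]),
                              std_percent=dict(report["summary_std_percent"]),
                              n_samples=report["n_steady_samples"])
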