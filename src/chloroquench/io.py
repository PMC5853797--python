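"""File formats and run configuration.

All tabular interchange is plain CSV with fixed, documented headers;
image bursts are multi-page TIFF plus a CSV burst index. Times are
minutes from photoperiod start, intensities µmol photons m⁻² s⁻¹.

Trace CSV columns:   time_min, reflectance, r0
Pulse CSV columns:   time_min, f_s, f_m_prime, f_m_dprime, t_dprime
                     (plus constant f_0, f_m columns for the dark pair)
Quenching CSV:       time_min, phi_ii, npq, qe_sv, qi, corrected
Burst index CSV:     time_min, path
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, Field, field_validator

from .errors import SchemaError
from .fluorescence import PulseEvent, PulseEventSeries, QuenchingSeries
from .profiles import PRESETS
from .reflectance import ReflectanceTrace

log = logging.getLogger("chloroquench")

TRACE_COLUMNS = ["time_min", "reflectance", "r0"]
PULSE_COLUMNS = ["time_min", "f_s", "f_m_prime", "f_m_dprime", "t_dprime",
                 "f_0", "f_m"]
QUENCH_COLUMNS = ["time_min", "phi_ii", "npq", "qe_sv", "qi", "corrected"]


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check_numeric(df: pd.DataFrame, columns: list[str], path) -> None:
    for c in columns:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = coerced.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {df.at[row, c]!r} "
                f"in column {c!r}, row {row}"
            )
        df[c] = coerced


def write_trace(trace: ReflectanceTrace, path) -> None:
    pd.DataFrame({
        "time_min": trace.times,
        "reflectance": trace.R,
        "r0": trace.R_0,
        "relative_reflectance": trace.relative,
    }).to_csv(path, index=False)


def read_trace(path, genotype: str | None = None) -> ReflectanceTrace:
    df = pd.read_csv(path)
    _check_columns(df, TRACE_COLUMNS, path)
    _check_numeric(df, TRACE_COLUMNS, path)
    return ReflectanceTrace(df["time_min"].to_numpy(),
                            df["reflectance"].to_numpy(),
                            R_0=float(df["r0"].iloc[0]),
                            genotype=genotype)


def write_pulses(series: PulseEventSeries, path) -> None:
    rows = [{
        "time_min": e.time, "f_s": e.F_s, "f_m_prime": e.F_m_prime,
        "f_m_dprime": np.nan if e.F_m_dprime is None else e.F_m_dprime,
        "t_dprime": np.nan if e.t_dprime is None else e.t_dprime,
        "f_0": series.F_0, "f_m": series.F_m,
    } for e in series.events]
    pd.DataFrame(rows, columns=PULSE_COLUMNS).to_csv(path, index=False)


def read_pulses(path, genotype: str | None = None) -> PulseEventSeries:
    df = pd.read_csv(path)
    _check_columns(df, PULSE_COLUMNS, path)
    _check_numeric(df, PULSE_COLUMNS, path)
    if df.empty:
        raise SchemaError(f"{path}: no pulse events")
    events = [
        PulseEvent(
            time=float(r.time_min), F_s=float(r.f_s),
            F_m_prime=float(r.f_m_prime),
            F_m_dprime=None if pd.isna(r.f_m_dprime) else float(r.f_m_dprime),
            t_dprime=None if pd.isna(r.t_dprime) else float(r.t_dprime),
        )
        for r in df.itertuples()
    ]
    return PulseEventSeries(F_0=float(df["f_0"].iloc[0]),
                            F_m=float(df["f_m"].iloc[0]),
                            events=events, genotype=genotype)


def write_quenching(qs: QuenchingSeries, path) -> None:
    out = qs.frame.copy()
    out["corrected"] = qs.corrected
    out.to_csv(path, index=False)


def read_quenching(path) -> QuenchingSeries:
    df = pd.read_csv(path)
    _check_columns(df, QUENCH_COLUMNS, path)
    corrected = bool(df["corrected"].iloc[0]) if not df.empty else False
    return QuenchingSeries(df.drop(columns=["corrected"]), corrected=corrected)


def write_bursts(times, bursts, directory) -> Path:
    """Write one multi-page TIFF per time point plus a burst index CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (t, stack) in enumerate(zip(times, bursts)):
        name = f"burst_{k:04d}.tif"
        tifffile.imwrite(directory / name, np.asarray(stack, np.float32),
                         photometric="minisblack")
        rows.append({"time_min": float(t), "path": name})
    index = directory / "burst_index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_bursts(index_path):
    """Yield (time_min, stack) pairs from a burst index CSV."""
    index_path = Path(index_path)
    df = pd.read_csv(index_path)
    _check_columns(df, ["time_min", "path"], index_path)
    for r in df.itertuples():
        tif = index_path.parent / r.path
        if not tif.exists():
            raise FileNotFoundError(f"burst index references missing file: {tif}")
        yield float(r.time_min), tifffile.imread(tif)


class RegimeSpec(BaseModel):
    """Which light schedule to build, with its knobs."""

    kind: str = "single_fluctuating_day"  # photorelocation | five_day | single_fluctuating_day
    intensity_ladder: list[float] = Field(
        default=[10.0, 50.0, 100.0, 250.0, 500.0])
    step_minutes: float = 60.0
    peak_intensity: float = 500.0
    constant_intensity: float = 100.0
    photoperiod_minutes: float = 960.0
    dark_minutes: float = 480.0

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        allowed = {"photorelocation", "five_day", "single_fluctuating_day"}
        if v not in allowed:
            raise ValueError(f"regime kind must be one of {sorted(allowed)}")
        return v

    def build(self):
        from . import regimes
        if self.kind == "photorelocation":
            return regimes.build_photorelocation_regime(
                self.intensity_ladder, self.step_minutes)
        if self.kind == "five_day":
            return regimes.build_five_day_regime(
                self.constant_intensity, self.peak_intensity,
                self.photoperiod_minutes, self.dark_minutes)
        return regimes.build_single_fluctuating_day(
            self.peak_intensity, self.photoperiod_minutes, self.dark_minutes)


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    regime: RegimeSpec = RegimeSpec()
    genotypes: list[str] = ["WT", "large", "intermediate", "small"]
    wt_label: str = "WT"
    seed: int = 0
    n_replicates: int = 6
    noise_sd: float = 0.005
    cv_noise: float = 0.02
    m: float = 1.0
    t_acc: float = 120.0
    t_avoid: float = 600.0
    alpha: float = 0.05
    outdir: str = "chloroquench_out"

    @field_validator("genotypes")
    @classmethod
    def _known_presets(cls, v: list[str]) -> list[str]:
        unknown = [g for g in v if g not in PRESETS]
        if unknown:
            raise ValueError(
                f"unknown genotype preset(s) {unknown}; available {sorted(PRESETS)}")
        return v

    @field_validator("n_replicates")
    @classmethod
    def _min_reps(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_replicates must be >= 1")
        return v


def load_config(path) -> RunConfig:
    import yaml
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_resolved_config(cfg: RunConfig, outdir) -> None:
    import yaml
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)


def log_run_header(cfg: RunConfig) -> None:
    import matplotlib
    import scipy
    log.info("config hash %s, seed %d", config_hash(cfg), cfg.seed)
    log.info("versions: numpy %s, scipy %s, pandas %s, matplotlib %s",
             np.__version__, scipy.__version__, pd.__version__,
             matplotlib.__version__)
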