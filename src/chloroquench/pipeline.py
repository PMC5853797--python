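"""Experiment templates chaining the pipeline stages over an output tree.

A run simulates a genotype panel under a configured light regime, renders
observed pulse series, computes apparent and movement-corrected quenching
parameters, and emits movement summaries and genotype-vs-WT heat maps.
Every artefact is a plain CSV (figures PNG); a manifest CSV ties files to
genotype/replicate/day. Deterministic given config + seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .compare import heatmap_matrix, movement_table, plot_heatmap
from .correction import correct_series
from .errors import ChloroquenchError
from .fluorescence import process_series
from .profiles import get_profile
from .reflectance import ReflectanceTrace
from .simulate import render_observed_pulses, simulate_experiment

HEATMAP_PARAMETERS = ("phi_ii", "npq", "qe_sv", "qi")


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


def _regime_list(cfg: io.RunConfig):
    built = cfg.regime.build()
    return built if isinstance(built, list) else [built]


def stage_simulate(cfg: io.RunConfig, outdir) -> pd.DataFrame:
    """Simulate the panel; write traces, pulses and truth; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_resolved_config(cfg, outdir)
    io.log_run_header(cfg)
    rows = []
    for d, regime in enumerate(_regime_list(cfg), start=1):
        for gi, gname in enumerate(cfg.genotypes):
            profile = get_profile(gname)
            for rep in range(1, cfg.n_replicates + 1):
                s_mov = _derive_seed(cfg.seed, d, gi, rep, 0)
                s_pulse = _derive_seed(cfg.seed, d, gi, rep, 1)
                trace, truth = simulate_experiment(
                    regime, profile, noise_sd=cfg.noise_sd, seed=s_mov,
                    m_true=cfg.m)
                # yields respond to the true chloroplast position; the
                # measured (noisy) trace is what the correction later sees
                trace_true = ReflectanceTrace.from_relative(
                    truth.frame["time_min"], truth.frame["x"],
                    genotype=gname)
                pulses = render_observed_pulses(
                    truth, trace_true, m=cfg.m, cv_noise=cfg.cv_noise,
                    seed=s_pulse)
                tag = f"{gname}_day{d}_rep{rep}"
                io.write_trace(trace, outdir / f"trace_{tag}.csv")
                io.write_pulses(pulses, outdir / f"pulses_{tag}.csv")
                truth.frame.to_csv(outdir / f"truth_{tag}.csv", index=False)
                rows.append({
                    "genotype": gname, "day": d, "replicate": rep,
                    "trace": f"trace_{tag}.csv",
                    "pulses": f"pulses_{tag}.csv",
                    "truth": f"truth_{tag}.csv",
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    io.log.info("simulate: %d series written", len(manifest))
    return manifest


def _load_manifest(outdir) -> pd.DataFrame:
    path = Path(outdir) / "manifest.csv"
    if not path.exists():
        raise ChloroquenchError(f"no manifest at {path}; run the simulate stage first")
    return pd.read_csv(path)


def stage_fluorescence(outdir, manifest: pd.DataFrame | None = None) -> None:
    """Apparent Φ_II/NPQ/qE_SV/qI per pulse series."""
    outdir = Path(outdir)
    manifest = _load_manifest(outdir) if manifest is None else manifest
    for r in manifest.itertuples():
        series = io.read_pulses(outdir / r.pulses, genotype=r.genotype)
        qs = process_series(series)
        io.write_quenching(qs, outdir / r.pulses.replace("pulses_", "apparent_"))
    io.log.info("fluorescence: %d series processed", len(manifest))


def stage_correct(cfg: io.RunConfig, outdir,
                  manifest: pd.DataFrame | None = None) -> None:
    """Movement-corrected quenching per pulse series."""
    outdir = Path(outdir)
    manifest = _load_manifest(outdir) if manifest is None else manifest
    for r in manifest.itertuples():
        series = io.read_pulses(outdir / r.pulses, genotype=r.genotype)
        trace = io.read_trace(outdir / r.trace, genotype=r.genotype)
        qs = correct_series(series, trace, m=cfg.m)
        io.write_quenching(qs, outdir / r.pulses.replace("pulses_", "corrected_"))
    io.log.info("correct: %d series corrected (m=%g)", len(manifest), cfg.m)


def stage_movement(cfg: io.RunConfig, outdir,
                   manifest: pd.DataFrame | None = None) -> pd.DataFrame:
    """Accumulation/avoidance summary table (first simulated day)."""
    outdir = Path(outdir)
    manifest = _load_manifest(outdir) if manifest is None else manifest
    first_day = manifest[manifest["day"] == manifest["day"].min()]
    traces = {
        g: [io.read_trace(outdir / r.trace, genotype=g)
            for r in sub.itertuples()]
        for g, sub in first_day.groupby("genotype", sort=False)
    }
    table = movement_table(traces, cfg.wt_label, cfg.t_acc, cfg.t_avoid,
                           alpha=cfg.alpha)
    table.to_csv(outdir / "movement_summary.csv", index=False)
    io.log.info("movement: %d genotypes summarised", len(table))
    return table


def _tidy_quenching(outdir, manifest: pd.DataFrame, prefix: str,
                    parameter: str) -> pd.DataFrame:
    rows = []
    for r in manifest.itertuples():
        qs = io.read_quenching(
            Path(outdir) / r.pulses.replace("pulses_", f"{prefix}_"))
        frame = qs.frame
        # multi-day runs share one time axis by offsetting each day
        offset = (r.day - 1) * 1440.0
        for _, q in frame.iterrows():
            v = q[parameter]
            if pd.notna(v):
                rows.append({"genotype": r.genotype, "replicate": r.replicate,
                             "time_min": q["time_min"] + offset, "value": v})
    return pd.DataFrame(rows)


def stage_compare(cfg: io.RunConfig, outdir,
                  manifest: pd.DataFrame | None = None,
                  prefix: str = "corrected") -> dict:
    """Heat-map matrices (and figures) for each quenching parameter."""
    outdir = Path(outdir)
    manifest = _load_manifest(outdir) if manifest is None else manifest
    if cfg.wt_label not in set(manifest["genotype"]):
        raise ChloroquenchError(
            f"wild-type label {cfg.wt_label!r} missing from the panel")
    matrices = {}
    for param in HEATMAP_PARAMETERS:
        tidy = _tidy_quenching(outdir, manifest, prefix, param)
        if tidy.empty:
            continue
        matrix = heatmap_matrix(tidy, cfg.wt_label, parameter=param,
                                alpha=cfg.alpha)
        matrix.cells.to_csv(outdir / f"heatmap_{param}.csv")
        matrix.p_values.to_csv(outdir / f"heatmap_{param}_pvalues.csv")
        plot_heatmap(matrix, outdir / f"heatmap_{param}.png")
        matrices[param] = matrix
    io.log.info("compare: %d heat maps written", len(matrices))
    return matrices


def run_full(cfg: io.RunConfig, outdir) -> None:
    """Chain simulate → fluorescence → correct → movement → compare."""
    manifest = stage_simulate(cfg, outdir)
    stage_fluorescence(outdir, manifest)
    stage_correct(cfg, outdir, manifest)
    stage_movement(cfg, outdir, manifest)
    stage_compare(cfg, outdir, manifest)
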