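"""Genotype-versus-wild-type comparison: replicate statistics, per-time-point
t-tests, log-fold heat-map matrices, and pigment-table summaries.

Mutant phenotypes are expressed as the log₂ fold change of the mutant
replicate mean over the parental wild-type mean at each time point, with
a per-cell two-sample Student's t-test (pooled variance, two-sided,
α = 0.05 by default, no multiple-testing correction — each time point is
tested on its own).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ChloroquenchError
from .reflectance import ReflectanceTrace, movement_summary, percent_of_wt
from .reflectance import T_ACCUMULATION, T_AVOIDANCE

DEFAULT_ALPHA = 0.05
#: Wild-type means below this are reported as missing in log-fold cells
#: (near-zero denominators make the log ratio meaningless).
DEFAULT_WT_FLOOR = 1e-6


@dataclass
class ReplicateSet:
    """Per-plant measurements of one parameter for one genotype/time point."""

    genotype: str
    values: np.ndarray
    parental_wt: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.size < 1:
            raise ChloroquenchError(f"{self.genotype}: empty replicate set")

    @property
    def n(self) -> int:
        return self.values.size


def replicate_stats(r: ReplicateSet) -> tuple[float, float]:
    """Mean and sample standard deviation (n−1); sd is NaN for n = 1."""
    mean = float(r.values.mean())
    sd = float(r.values.std(ddof=1)) if r.n >= 2 else float("nan")
    return mean, sd


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    significant: bool


def t_test(a: ReplicateSet, b: ReplicateSet,
           alpha: float = DEFAULT_ALPHA, welch: bool = False) -> TTestResult:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    ``welch=True`` switches to the unequal-variance form. Groups with
    zero pooled variance are handled explicitly: equal means give
    (t = 0, p = 1); unequal means give (t = ±inf, p = 0).
    """
    if a.n < 2 or b.n < 2:
        raise ChloroquenchError("t-test needs at least two replicates per group")
    va, vb = a.values.var(ddof=1), b.values.var(ddof=1)
    if va == 0 and vb == 0:
        diff = a.values.mean() - b.values.mean()
        if diff == 0:
            return TTestResult(0.0, 1.0, False)
        return TTestResult(float(np.sign(diff)) * float("inf"), 0.0, 0.0 <= alpha)
    t, p = stats.ttest_ind(a.values, b.values, equal_var=not welch)
    return TTestResult(float(t), float(p), bool(p <= alpha))


def log_fold(mutant_mean: float, wt_mean: float) -> float:
    """log₂ fold change of the mutant mean over the wild-type mean."""
    if mutant_mean <= 0 or wt_mean <= 0:
        raise ChloroquenchError(
            f"log-fold needs positive means, got {mutant_mean} and {wt_mean}"
        )
    return float(np.log2(mutant_mean / wt_mean))


@dataclass
class HeatMapMatrix:
    """Genotype × time matrix of log-fold changes with significance flags."""

    parameter: str
    genotypes: list[str]
    times: np.ndarray
    cells: pd.DataFrame          # index genotypes, columns times
    significance: pd.DataFrame   # same shape, boolean
    p_values: pd.DataFrame       # same shape


def heatmap_matrix(data: pd.DataFrame, wt_label: str, parameter: str = "value",
                   alpha: float = DEFAULT_ALPHA,
                   wt_floor: float = DEFAULT_WT_FLOOR,
                   welch: bool = False) -> HeatMapMatrix:
    """Log-fold heat-map matrix of each genotype against the wild type.

    ``data`` is tidy with columns (genotype, replicate, time_min, value);
    all genotypes must share the wild type's time grid. Cells where either
    mean is below ``wt_floor`` are NaN (missing, not clipped); the WT row
    is identically zero and never significant.
    """
    required = {"genotype", "replicate", "time_min", "value"}
    missing = required - set(data.columns)
    if missing:
        raise ChloroquenchError(f"tidy data lacks columns: {sorted(missing)}")
    genotypes = list(dict.fromkeys(data["genotype"]))
    if wt_label not in genotypes:
        raise ChloroquenchError(f"wild-type label {wt_label!r} absent from panel")
    wt_times = np.sort(data.loc[data["genotype"] == wt_label, "time_min"].unique())
    cells, sig, pvals = {}, {}, {}
    for g in genotypes:
        sub = data[data["genotype"] == g]
        g_times = np.sort(sub["time_min"].unique())
        if not np.array_equal(g_times, wt_times):
            raise ChloroquenchError(
                f"{g}: time grid does not match the wild type's"
            )
    wt_data = data[data["genotype"] == wt_label]
    for g in genotypes:
        sub = data[data["genotype"] == g]
        row_lf, row_sig, row_p = [], [], []
        for t in wt_times:
            mut = ReplicateSet(g, sub.loc[sub["time_min"] == t, "value"].to_numpy())
            wt = ReplicateSet(wt_label,
                              wt_data.loc[wt_data["time_min"] == t, "value"].to_numpy())
            if g == wt_label:
                row_lf.append(0.0)
                row_sig.append(False)
                row_p.append(1.0)
                continue
            m_mean, w_mean = mut.values.mean(), wt.values.mean()
            if m_mean < wt_floor or w_mean < wt_floor:
                row_lf.append(np.nan)
            else:
                row_lf.append(log_fold(m_mean, w_mean))
            res = t_test(mut, wt, alpha=alpha, welch=welch)
            row_sig.append(res.significant)
            row_p.append(res.p_value)
        cells[g], sig[g], pvals[g] = row_lf, row_sig, row_p
    idx = pd.Index(genotypes, name="genotype")
    return HeatMapMatrix(
        parameter=parameter,
        genotypes=genotypes,
        times=wt_times,
        cells=pd.DataFrame(cells, index=wt_times).T.set_axis(idx),
        significance=pd.DataFrame(sig, index=wt_times).T.set_axis(idx),
        p_values=pd.DataFrame(pvals, index=wt_times).T.set_axis(idx),
    )


def plot_heatmap(matrix: HeatMapMatrix, path=None, vmax: float | None = None):
    """Render a heat-map matrix with a diverging blue–black–red palette.

    Red marks log-fold increases over the wild type, blue decreases,
    black no change; missing cells are white. Returns the figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    cmap = LinearSegmentedColormap.from_list(
        "fold", ["#2166ac", "#000000", "#b2182b"])
    cmap.set_bad("#ffffff")
    vals = matrix.cells.to_numpy(float)
    if vmax is None:
        finite = np.abs(vals[np.isfinite(vals)])
        vmax = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.35 * len(matrix.genotypes)))
    im = ax.imshow(np.ma.masked_invalid(vals), aspect="auto", cmap=cmap,
                   vmin=-vmax, vmax=vmax, interpolation="nearest")
    ax.set_yticks(range(len(matrix.genotypes)), matrix.genotypes)
    step = max(1, len(matrix.times) // 12)
    ax.set_xticks(range(0, len(matrix.times), step),
                  [f"{t:.0f}" for t in matrix.times[::step]])
    ax.set_xlabel("time (min)")
    fig.colorbar(im, ax=ax, label=f"log2 fold vs WT ({matrix.parameter})")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def movement_table(traces: dict[str, list[ReflectanceTrace]], wt_label: str,
                   t_acc: float = T_ACCUMULATION, t_avoid: float = T_AVOIDANCE,
                   alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Accumulation/avoidance summary table across replicate traces.

    One row per genotype with mean ± SD of the two read-outs, the
    percentage of the wild-type response, and per-read-out t-test
    p-values against the wild type.
    """
    if wt_label not in traces:
        raise ChloroquenchError(f"wild-type label {wt_label!r} absent from panel")
    readouts = {
        g: np.array([[movement_summary(tr, t_acc, t_avoid).accumulation_value,
                      movement_summary(tr, t_acc, t_avoid).avoidance_value]
                     for tr in reps])
        for g, reps in traces.items()
    }
    wt = readouts[wt_label]
    rows = []
    for g, vals in readouts.items():
        row = {"genotype": g, "n": vals.shape[0]}
        for j, which in enumerate(("accumulation", "avoidance")):
            rset = ReplicateSet(g, vals[:, j])
            mean, sd = replicate_stats(rset)
            row[f"{which}_value"] = mean
            row[f"{which}_sd"] = sd
            row[f"{which}_percent_of_wt"] = percent_of_wt(mean, wt[:, j].mean())
            row[f"{which}_percent_of_wt_raw"] = percent_of_wt(
                mean, wt[:, j].mean(), rounded=False)
            if g != wt_label and vals.shape[0] >= 2 and wt.shape[0] >= 2:
                res = t_test(rset, ReplicateSet(wt_label, wt[:, j]), alpha=alpha)
                row[f"{which}_p"] = res.p_value
                row[f"{which}_significant"] = res.significant
            else:
                row[f"{which}_p"] = np.nan
                row[f"{which}_significant"] = False
        rows.append(row)
    return pd.DataFrame(rows)


def load_pigment_table() -> pd.DataFrame:
    """Published leaf pigment summary table shipped with the package.

    Total chlorophyll (µg g⁻¹ FW), Chl a/b and Chl/carotenoid ratios per
    genotype, before and after the 5-day light treatment, with the
    parental wild type of each block.
    """
    ref = importlib.resources.files("chloroquench.data") / "pigment_contents.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def pigment_summary(records: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percent-of-wild-type chlorophyll summaries from a pigment table.

    ``records`` needs columns (block, genotype, parental_wt, condition,
    chl_content, chl_a_b, chl_car); the wild-type row of each
    block/condition is the one whose genotype equals its parental_wt.
    Percentages are reported rounded half-away-from-zero to one decimal
    (the raw value is kept in ``percent_of_wt_raw``); ratios pass through.
    """
    df = (records if records is not None else load_pigment_table()).copy()
    required = {"block", "genotype", "parental_wt", "condition", "chl_content"}
    missing = required - set(df.columns)
    if missing:
        raise ChloroquenchError(f"pigment table lacks columns: {sorted(missing)}")
    out_rows = []
    for (block, condition), sub in df.groupby(["block", "condition"], sort=False):
        wt_rows = sub[sub["genotype"] == sub["parental_wt"]]
        if wt_rows.empty:
            raise ChloroquenchError(
                f"no wild-type row for block {block!r}, condition {condition!r}"
            )
        wt_by_label = {r["genotype"]: r["chl_content"] for _, r in wt_rows.iterrows()}
        for _, r in sub.iterrows():
            wt_val = wt_by_label.get(r["parental_wt"])
            if wt_val is None:
                raise ChloroquenchError(
                    f"{r['genotype']}: parental wild type {r['parental_wt']!r} "
                    f"missing from block {block!r}, condition {condition!r}"
                )
            out = dict(r)
            out["percent_of_wt"] = percent_of_wt(r["chl_content"], wt_val)
            out["percent_of_wt_raw"] = percent_of_wt(r["chl_content"], wt_val,
                                                     rounded=False)
            out_rows.append(out)
    return pd.DataFrame(out_rows)
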