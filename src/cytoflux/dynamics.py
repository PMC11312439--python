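"""Time-course read-outs: fold changes, ANOVA contrasts, cluster dynamics.

All operations act on tidy pandas DataFrames so they compose with the
upstream pipeline but remain usable on any events table:

* per-sample mean marker intensities and vehicle-normalized fold-change
  series (FC(t) = mean at t / the same replicate's t = 0 vehicle mean);
* two-way (group x time) fixed-effects ANOVA with per-timepoint Sidak-
  adjusted group contrasts, and one-way ANOVA with Dunnett many-to-one
  comparisons against a control;
* per-condition cluster-abundance matrices over time, time-normalized
  ("cow-plot") trajectories with an abundance-weighted mean-time ordering
  index, terminal-cluster fractions, and the RMSE between the cluster-
  abundance vectors at two timepoints (return-to-baseline statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .events import EventTable
from .panel import DEFAULT_COFACTOR

GROUP_COLS = ["condition", "stimulus", "replicate"]


class DynamicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Marker summaries and fold changes
# ---------------------------------------------------------------------------

def mean_intensity(
    table: EventTable,
    marker: str,
    scale: str = "raw",
    cofactor: float = DEFAULT_COFACTOR,
) -> tuple[float, int]:
    """Arithmetic mean of one marker over the table's events.

    Returns (mean, n_events); the mean is NaN for an empty table.  ``scale``
    is ``"raw"`` (ion counts) or ``"transformed"`` (arcsinh).
    """
    if marker not in table.data.columns:
        raise DynamicsError(f"marker {marker!r} not present")
    x = table.data[marker].to_numpy(dtype=float)
    if scale == "transformed" and not table.sample_meta.get("arcsinh_cofactor"):
        x = np.arcsinh(x / cofactor)
    elif scale not in ("raw", "transformed"):
        raise DynamicsError(f"unknown scale {scale!r}")
    if len(x) == 0:
        return float("nan"), 0
    return float(x.mean()), int(len(x))


def sample_means(
    table: EventTable,
    markers: list[str],
    by: pd.DataFrame,
    scale: str = "raw",
    cofactor: float = DEFAULT_COFACTOR,
) -> pd.DataFrame:
    """Tidy per-sample means: one row per (group, marker).

    ``by`` holds per-event sample annotations (condition, stimulus,
    timepoint_h, replicate) aligned with the table's events.
    """
    X = table.data[markers].to_numpy(dtype=float)
    if scale == "transformed" and not table.sample_meta.get("arcsinh_cofactor"):
        X = np.arcsinh(X / cofactor)
    frame = pd.concat(
        [by.reset_index(drop=True), pd.DataFrame(X, columns=markers)], axis=1
    )
    keys = GROUP_COLS + ["timepoint_h"]
    grouped = frame.groupby(keys, dropna=True, observed=True)
    means = grouped[markers].mean()
    counts = grouped.size().rename("n_events")
    out = (
        means.join(counts)
        .reset_index()
        .melt(
            id_vars=keys + ["n_events"],
            value_vars=markers,
            var_name="marker",
            value_name="mean",
        )
    )
    return out


def fold_change_series(
    means: pd.DataFrame, baseline_timepoint: float = 0.0
) -> pd.DataFrame:
    """Vehicle-normalized fold changes per replicate.

    For every (marker, condition, stimulus, replicate), FC(t) = mean(t) /
    mean(baseline_timepoint).  FC at the baseline timepoint is 1 by
    construction.
    """
    out = []
    for keys, grp in means.groupby(
        ["marker"] + GROUP_COLS, dropna=True, observed=True
    ):
        base = grp.loc[grp["timepoint_h"] == baseline_timepoint, "mean"]
        if base.empty:
            raise DynamicsError(
                f"no baseline (t={baseline_timepoint}) sample for {keys}"
            )
        b = float(base.iloc[0])
        if not b > 0:
            raise DynamicsError(
                f"zero baseline mean for marker={keys[0]!r}, "
                f"replicate={keys[3]!r}"
            )
        g = grp.copy()
        g["fold_change"] = g["mean"] / b
        out.append(g)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# ANOVA procedures
# ---------------------------------------------------------------------------

def sidak_adjust(p: np.ndarray, m: int) -> np.ndarray:
    """Sidak multiple-comparison adjustment p_adj = 1 - (1 - p)^m."""
    if m < 1:
        raise DynamicsError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    return 1.0 - np.power(1.0 - p, m)


@dataclass
class TwoWayAnovaResult:
    table: pd.DataFrame  # per-timepoint contrasts with adjusted p
    anova: dict  # F and p for group, time, interaction
    df_resid: int
    mse: float


def twoway_anova_sidak(
    data: pd.DataFrame,
    group_col: str,
    time_col: str = "timepoint_h",
    value_col: str = "fold_change",
) -> TwoWayAnovaResult:
    """Two-factor fixed-effects ANOVA with Sidak per-timepoint contrasts.

    Requires a balanced design with exactly two groups and >= 2 replicates
    per (group, time) cell.  Per-timepoint group differences are tested with
    the pooled residual variance; p-values are Sidak-adjusted with m = the
    number of timepoints compared.
    """
    d = data[[group_col, time_col, value_col]].dropna()
    groups = sorted(d[group_col].unique())
    times = sorted(d[time_col].unique())
    if len(groups) != 2:
        raise DynamicsError(
            f"expected exactly 2 groups, found {len(groups)}"
        )
    counts = d.groupby([group_col, time_col], observed=True).size()
    if counts.min() < 2:
        raise DynamicsError("need >= 2 replicates per design cell")
    if counts.nunique() != 1 or len(counts) != len(groups) * len(times):
        raise DynamicsError("unbalanced design (missing or unequal cells)")
    n = int(counts.iloc[0])
    a, b, t_n = len(groups), len(times), n

    y = d[value_col].to_numpy(dtype=float)
    grand = y.mean()
    cell_means = d.groupby([group_col, time_col], observed=True)[
        value_col
    ].mean()
    g_means = d.groupby(group_col, observed=True)[value_col].mean()
    t_means = d.groupby(time_col, observed=True)[value_col].mean()

    ss_total = ((y - grand) ** 2).sum()
    ss_group = b * t_n * ((g_means - grand) ** 2).sum()
    ss_time = a * t_n * ((t_means - grand) ** 2).sum()
    ss_cells = t_n * ((cell_means - grand) ** 2).sum()
    ss_inter = ss_cells - ss_group - ss_time
    ss_resid = ss_total - ss_cells
    df_resid = a * b * (t_n - 1)
    mse = ss_resid / df_resid

    def f_p(ss, df):
        if mse == 0 or df == 0:
            return float("nan"), float("nan")
        f = (ss / df) / mse
        return float(f), float(stats.f.sf(f, df, df_resid))

    anova = {
        "group": f_p(ss_group, a - 1),
        "time": f_p(ss_time, b - 1),
        "interaction": f_p(ss_inter, (a - 1) * (b - 1)),
    }

    rows = []
    se = math.sqrt(mse * 2.0 / t_n) if mse > 0 else 0.0
    for tp in times:
        m1 = float(cell_means[(groups[0], tp)])
        m2 = float(cell_means[(groups[1], tp)])
        diff = m1 - m2
        if se > 0:
            tstat = diff / se
            p = 2.0 * stats.t.sf(abs(tstat), df_resid)
        else:
            tstat, p = float("nan"), 1.0
        rows.append(
            {
                time_col: tp,
                "mean_diff": diff,
                "t": tstat,
                "p_raw": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = sidak_adjust(table["p_raw"].to_numpy(), len(times))
    return TwoWayAnovaResult(table, anova, int(df_resid), float(mse))


def oneway_anova_dunnett(
    data: pd.DataFrame,
    group_col: str,
    value_col: str,
    control: str,
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett many-to-one comparisons vs a control.

    Returns one row per non-control group with the Dunnett-adjusted p-value
    (multivariate-t critical values via scipy) and attaches the one-way
    ANOVA F/p in the frame's ``attrs``.
    """
    d = data[[group_col, value_col]].dropna()
    labels = list(pd.unique(d[group_col]))
    if control not in labels:
        raise DynamicsError(f"control label {control!r} absent")
    counts = d.groupby(group_col, observed=True).size()
    if counts.min() < 2:
        raise DynamicsError("need >= 2 replicates per group")
    treat_labels = [g for g in labels if g != control]
    control_vals = d.loc[d[group_col] == control, value_col].to_numpy()
    treat_vals = [
        d.loc[d[group_col] == g, value_col].to_numpy() for g in treat_labels
    ]
    if np.ptp(d[value_col].to_numpy()) == 0:
        # all observations identical: nothing to reject
        f_stat, p_anova = float("nan"), 1.0
        p_adj = np.ones(len(treat_labels))
        diffs = [0.0] * len(treat_labels)
    else:
        f_stat, p_anova = stats.f_oneway(control_vals, *treat_vals)
        if len(treat_vals) == 1:
            # one comparison: the multivariate t collapses to a plain
            # two-sided t test, so use the exact closed form
            p_adj = np.array(
                [stats.ttest_ind(treat_vals[0], control_vals).pvalue]
            )
        else:
            res = stats.dunnett(
                *treat_vals, control=control_vals, alternative="two-sided"
            )
            p_adj = np.asarray(res.pvalue)
        diffs = [tv.mean() - control_vals.mean() for tv in treat_vals]
    out = pd.DataFrame(
        {
            "group": treat_labels,
            "mean_diff": diffs,
            "p_adj": p_adj,
        }
    )
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(p_anova)
    return out


def simulate_null_fwer_twoway(
    n_runs: int = 1000,
    n_reps: int = 3,
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error rate of the two-way ANOVA + Sidak contrasts under
    a simulated null (both groups drawn from the same normal)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    base = pd.DataFrame(
        {
            "group": np.repeat(["A", "B"], len(timepoints) * n_reps),
            "timepoint_h": np.tile(
                np.repeat(timepoints, n_reps), 2
            ),
        }
    )
    for _ in range(n_runs):
        d = base.copy()
        d["fold_change"] = rng.standard_normal(len(d))
        res = twoway_anova_sidak(d, "group")
        if (res.table["p_adj"] < alpha).any():
            rejections += 1
    return rejections / n_runs


def simulate_null_fwer_dunnett(
    n_runs: int = 1000,
    k_groups: int = 4,
    n_reps: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error rate of one-way ANOVA + Dunnett comparisons under
    a simulated null (all groups from the same normal)."""
    rng = np.random.default_rng(seed)
    labels = ["ctrl"] + [f"g{i}" for i in range(1, k_groups)]
    rejections = 0
    for _ in range(n_runs):
        d = pd.DataFrame(
            {
                "group": np.repeat(labels, n_reps),
                "value": rng.standard_normal(k_groups * n_reps),
            }
        )
        res = oneway_anova_dunnett(d, "group", "value", "ctrl")
        if (res["p_adj"] < alpha).any():
            rejections += 1
    return rejections / n_runs


def max_foldchange_difference(
    series_a: pd.DataFrame, series_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-marker signed maximal fold-change difference between two series.

    Replicate-mean FC is computed per (marker, timepoint); the returned
    delta is FC_a - FC_b at the timepoint where |delta| is maximal (sign
    preserved: positive = greater in series a).  Antisymmetric under
    swapping a and b.
    """
    def rep_mean(s):
        return (
            s.groupby(["marker", "timepoint_h"], observed=True)["fold_change"]
            .mean()
            .unstack("timepoint_h")
        )

    fa, fb = rep_mean(series_a), rep_mean(series_b)
    if not fa.columns.equals(fb.columns):
        raise DynamicsError("timepoint grids differ between series")
    common = fa.index.intersection(fb.index)
    delta = fa.loc[common] - fb.loc[common]
    idx = np.abs(delta.to_numpy()).argmax(axis=1)
    rows = [
        {
            "marker": marker,
            "max_difference": float(delta.iloc[i, j]),
            "timepoint_h": float(delta.columns[j]),
        }
        for i, (marker, j) in enumerate(zip(delta.index, idx))
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cluster abundance dynamics
# ---------------------------------------------------------------------------

def cluster_abundance(events: pd.DataFrame) -> pd.DataFrame:
    """Cluster fractions per sample from per-event assignments.

    ``events`` needs columns cluster, condition, stimulus, timepoint_h,
    replicate; rows with cluster <= 0 (excluded events) are dropped.
    Fractions sum to 1 within each sample.
    """
    d = events.loc[events["cluster"] > 0].copy()
    if d.empty:
        raise DynamicsError("no clustered events")
    keys = GROUP_COLS + ["timepoint_h"]
    counts = (
        d.groupby(keys + ["cluster"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = counts.groupby(keys, observed=True)["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    return counts


def _replicate_mean_matrix(
    abundance: pd.DataFrame, condition: str, stimulus: str
) -> pd.DataFrame:
    """clusters x timepoints replicate-averaged fraction matrix."""
    d = abundance[
        (abundance["condition"] == condition)
        & (abundance["stimulus"] == stimulus)
    ]
    if d.empty:
        raise DynamicsError(f"no abundance rows for {condition}/{stimulus}")
    mat = (
        d.groupby(["cluster", "timepoint_h"], observed=True)["fraction"]
        .mean()
        .unstack("timepoint_h", fill_value=0.0)
        .sort_index()
    )
    return mat


def normalize_abundance_by_time(
    abundance: pd.DataFrame,
    condition: str,
    stimulus: str,
    mode: str = "max",
) -> pd.DataFrame:
    """Per-cluster time-normalized trajectories with an ordering index.

    Each cluster's replicate-averaged trajectory is divided by its own
    maximum over time (``mode="max"``) or by its sum (``mode="sum"``).  The
    ordering index is the abundance-weighted mean time; clusters are sorted
    ascending, so early-peaking clusters come first (upper-left in the
    cow-plot).  All-zero clusters keep zero trajectories and sort last.
    """
    mat = _replicate_mean_matrix(abundance, condition, stimulus)
    times = mat.columns.to_numpy(dtype=float)
    vals = mat.to_numpy(dtype=float)
    denom = (
        vals.max(axis=1) if mode == "max" else vals.sum(axis=1)
    )
    if mode not in ("max", "sum"):
        raise DynamicsError(f"unknown normalization mode {mode!r}")
    norm = np.zeros_like(vals)
    nonzero = denom > 0
    norm[nonzero] = vals[nonzero] / denom[nonzero, None]
    totals = vals.sum(axis=1)
    index = np.full(len(mat), np.inf)
    index[totals > 0] = (vals[totals > 0] * times).sum(axis=1) / totals[
        totals > 0
    ]
    out = pd.DataFrame(norm, index=mat.index, columns=mat.columns)
    out["ordering_index"] = index
    return out.sort_values("ordering_index")


def rmse_between_timepoints(
    abundance: pd.DataFrame,
    t0: float,
    t1: float,
    condition: str,
    stimulus: str,
) -> float:
    """RMSE between the replicate-averaged cluster-abundance vectors at two
    timepoints: sqrt(mean over clusters of (f(t1) - f(t0))^2).

    Zero iff the two vectors are identical; small values mean the cluster
    composition has returned toward its state at ``t0``.
    """
    mat = _replicate_mean_matrix(abundance, condition, stimulus)
    for t in (t0, t1):
        if t not in mat.columns:
            raise DynamicsError(f"timepoint {t} absent")
    diff = mat[t1].to_numpy() - mat[t0].to_numpy()
    return float(np.sqrt(np.mean(diff**2)))


def fraction_in_cluster(
    abundance: pd.DataFrame, cluster: int, timepoint: float
) -> pd.DataFrame:
    """Replicate-wise fraction of events in one cluster at one timepoint.

    Returns one row per (condition, stimulus) with mean, SEM and replicate
    values; replicates without the cluster contribute fraction 0.
    """
    if not (abundance["cluster"] == cluster).any():
        raise DynamicsError(f"unknown cluster {cluster}")
    d = abundance[abundance["timepoint_h"] == timepoint]
    if d.empty:
        raise DynamicsError(f"timepoint {timepoint} absent")
    rows = []
    for (cond, stim), grp in d.groupby(
        ["condition", "stimulus"], observed=True
    ):
        reps = sorted(grp["replicate"].unique())
        vals = []
        for r in reps:
            sub = grp[(grp["replicate"] == r) & (grp["cluster"] == cluster)]
            vals.append(float(sub["fraction"].sum()))
        vals = np.asarray(vals)
        sem = (
            float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1
            else float("nan")
        )
        rows.append(
            {
                "condition": cond,
                "stimulus": stim,
                "mean_fraction": float(vals.mean()),
                "sem": sem,
                "n_replicates": len(vals),
                "fractions": vals.tolist(),
            }
        )
    return pd.DataFrame(rows)
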