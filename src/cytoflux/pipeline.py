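"""End-to-end driver: simulate -> normalize -> debarcode -> gate -> cluster
-> dynamics, carrying ground truth alongside for validation.

This is the composition layer the command-line interface and the worked
examples use; each stage is the public function from its own module, so any
step can be swapped or rerun in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .cluster import (
    ClusterAssignment,
    exclude_nonmicroglia,
    round1_identity,
    round2_signaling,
)
from .debarcode import (
    DebarcodeFilter,
    assign_code,
    compute_mahalanobis,
    filter_debarcoded,
    rescale_pd,
)
from .events import EventTable, concat_tables
from .gating import (
    GateReport,
    default_bead_residual_spec,
    default_gate_chain,
    run_gate_chain,
)
from .normalize import apply_normalization, fit_drift, identify_bead_events
from .panel import Panel
from .simulate import GroundTruth, SimConfig, simulate_run


@dataclass
class RunResult:
    """One acquisition after preprocessing, with per-event bookkeeping."""

    table: EventTable  # normalized intensities for kept events
    truth: GroundTruth  # ground truth for kept events
    keep_mask: np.ndarray  # over the raw run's events
    debarcode_report: dict
    gate_report: GateReport
    drift_window: int


def preprocess_run(
    table: EventTable,
    key,
    truth: GroundTruth | None = None,
    debarcode_filter: DebarcodeFilter | None = None,
    drift_window: int = 500,
    normalize: bool | str = "auto",
) -> RunResult:
    """Normalize, debarcode and gate one pooled acquisition.

    Follows the acquisition-processing order: bead normalization first,
    then barcode deconvolution and confidence filtering, then the clean-up
    gate chain (singlets, viability, residual beads, CD11b/CD45,
    GFAP-negative).  ``normalize="auto"`` skips the bead correction when the
    run carries too few bead events to fit a drift model.
    """
    from .normalize import NormalizationError

    work = table
    if normalize:
        try:
            bead_mask = identify_bead_events(work)
            model = fit_drift(work, bead_mask, window=drift_window)
            work = apply_normalization(work, model)
        except NormalizationError:
            if normalize != "auto":
                raise

    work = rescale_pd(work)
    result = assign_code(work, key)
    result = compute_mahalanobis(result, work)
    keep_db, db_report = filter_debarcoded(result, debarcode_filter)

    work = work.with_annotation("sample_id", result.sample_id)
    work = work.with_annotation("separation", result.separation)
    work = work.with_annotation("bc_neg", result.bc_neg)
    work = work.with_annotation("mahalanobis", result.mahalanobis)

    gated = work.subset(keep_db)
    truth_db = truth.subset(keep_db) if truth is not None else None
    keep_gates, gate_report = run_gate_chain(gated)
    final = gated.subset(keep_gates)
    truth_final = truth_db.subset(keep_gates) if truth_db is not None else None

    keep_mask = np.zeros(table.n_events, dtype=bool)
    idx = np.flatnonzero(keep_db)
    keep_mask[idx[keep_gates]] = True
    return RunResult(
        final, truth_final, keep_mask, db_report, gate_report, drift_window
    )


def sample_annotations(run: RunResult, config: SimConfig) -> pd.DataFrame:
    """Per-event sample metadata recovered from the barcode assignment."""
    sid = run.table.annotations["sample_id"].to_numpy()
    tp_by_sid = {
        s: t
        for s, t in zip(config.barcode_key.sample_ids, config.timepoints)
    }
    meta = run.table.sample_meta
    return pd.DataFrame(
        {
            "sample_id": sid,
            "condition": meta.get("condition"),
            "stimulus": meta.get("stimulus"),
            "replicate": meta.get("replicate"),
            "timepoint_h": [tp_by_sid.get(s, np.nan) for s in sid],
        }
    )


@dataclass
class StudyResult:
    """Pooled, clustered study with dynamics inputs."""

    table: EventTable
    annotations: pd.DataFrame  # per-event sample metadata
    truth_events: pd.DataFrame | None
    assignment: ClusterAssignment
    runs: dict = field(default_factory=dict)

    def events_frame(self) -> pd.DataFrame:
        out = self.annotations.copy()
        out["cluster"] = self.assignment.round2_label
        out["round1_cluster"] = self.assignment.round1_label
        out["excluded"] = self.assignment.round1_excluded
        return out


def run_study(
    config: SimConfig,
    conditions: list[tuple[str, str]] | None = None,
    replicates: int = 1,
    seed: int = 0,
    round1_resolution: float = 1.0,
    round2_resolution: float = 1.0,
    target_clusters: int | None = None,
    cluster_seed: int = 0,
) -> StudyResult:
    """Simulate and process a full multi-condition study.

    One pooled run per (condition, stimulus, replicate); preprocessed runs
    are pooled for the two-round clustering so all conditions share one
    cluster vocabulary (the study clusters its conditions together).
    """
    if conditions is None:
        conditions = list(config.conditions)
    tables, annos, truths = [], [], []
    reports = {}
    for rep in range(1, replicates + 1):
        for cond, stim in conditions:
            run_seed = seed + 7919 * rep + 101 * conditions.index((cond, stim))
            raw, truth = simulate_run(config, cond, stim, rep, seed=run_seed)
            res = preprocess_run(raw, config.barcode_key, truth)
            tables.append(res.table)
            annos.append(sample_annotations(res, config))
            truths.append(res.truth.events)
            reports[(cond, stim, rep)] = {
                "debarcode": res.debarcode_report,
                "gates": res.gate_report.to_frame(),
            }
    pooled = concat_tables(tables)
    annotations = pd.concat(annos, ignore_index=True)
    truth_events = pd.concat(truths, ignore_index=True)

    assign = round1_identity(
        pooled, config.panel, resolution=round1_resolution, seed=cluster_seed
    )
    assign = exclude_nonmicroglia(assign)
    assign = round2_signaling(
        pooled,
        assign,
        config.panel,
        resolution=round2_resolution,
        seed=cluster_seed,
        target_clusters=target_clusters,
    )
    return StudyResult(pooled, annotations, truth_events, assign, reports)


def study_dynamics(
    study: StudyResult,
    markers: list[str],
    baseline_timepoint: float = 0.0,
) -> dict:
    """Fold-change series and cluster-abundance dynamics for a study."""
    retained = study.assignment.retained
    table = study.table.subset(retained)
    by = study.annotations.loc[retained].reset_index(drop=True)
    means = dyn.sample_means(table, markers, by)
    fc = dyn.fold_change_series(means, baseline_timepoint)
    abundance = dyn.cluster_abundance(study.events_frame())
    return {"means": means, "fold_changes": fc, "abundance": abundance}
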