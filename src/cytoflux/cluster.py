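"""Two-round Leiden clustering and UMAP embedding.

Round 1 partitions events on a fixed 13-marker identity set to find cell
lineages; clusters with low median CD11b, low CD45 or high GFAP are excluded
(contaminating astrocytes/fibroblasts).  Round 2 re-partitions the retained
(microglial) events on every panel marker except the four lineage-only ones
(CD11b, CD45, GFAP, Olig2) to resolve signaling states.

Clustering operates on arcsinh-transformed, per-channel z-scaled values over
a k-nearest-neighbour graph (k matching the UMAP neighbourhood scale), with
Leiden modularity optimization at a configurable resolution; an optional
bisection mode tunes the resolution to a requested cluster count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from sklearn.neighbors import kneighbors_graph

from .events import EventTable
from .panel import DEFAULT_COFACTOR, ROUND2_EXCLUDED, Panel
from .utils import two_means_split

EXCLUDE_CHANNELS = ("CD11b", "CD45", "GFAP")
REASON_LOW_CD11B = "low_CD11b"
REASON_LOW_CD45 = "low_CD45"
REASON_HIGH_GFAP = "high_GFAP"


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class EmbeddingConfig:
    """UMAP parameters; defaults are the analysis settings."""

    n_neighbors: int = 15
    metric: str = "euclidean"
    local_connectivity: int = 1
    n_components: int = 2
    epochs: int = 1000
    seed: int = 0


@dataclass
class ClusterAssignment:
    """Per-event labels for both rounds plus per-cluster marker profiles.

    Cluster ids are contiguous from 1 (0 = not assigned in that round:
    round-2 labels exist only for retained events).
    """

    round1_label: np.ndarray
    round1_profiles: pd.DataFrame  # cluster x marker medians (arcsinh scale)
    round1_excluded: np.ndarray = field(default=None)
    exclusion_reasons: dict[int, list[str]] = field(default_factory=dict)
    round2_label: np.ndarray | None = None
    round2_profiles: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.round1_excluded is None:
            self.round1_excluded = np.zeros(
                len(self.round1_label), dtype=bool
            )

    @property
    def retained(self) -> np.ndarray:
        return ~self.round1_excluded


def _feature_matrix(
    table: EventTable,
    markers: Sequence[str],
    cofactor: float,
    z_scale: bool,
) -> np.ndarray:
    missing = [m for m in markers if m not in table.data.columns]
    if missing:
        raise ClusterError(f"missing marker channels: {missing}")
    X = table.data[list(markers)].to_numpy(dtype=float)
    if not table.sample_meta.get("arcsinh_cofactor"):
        X = np.arcsinh(X / cofactor)
    if z_scale:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X


def leiden_partition(
    table: EventTable,
    markers: Sequence[str],
    resolution: float = 1.0,
    seed: int = 0,
    k_neighbors: int = 15,
    cofactor: float = DEFAULT_COFACTOR,
    z_scale: bool = True,
) -> tuple[np.ndarray, float]:
    """Leiden labels (contiguous from 1, by decreasing size) and modularity.

    Builds an unweighted symmetric k-nearest-neighbour graph (euclidean) on
    the transformed marker matrix and optimizes RB-configuration modularity
    at the given resolution; deterministic for fixed seed and inputs.
    """
    n = table.n_events
    if n < k_neighbors + 1:
        raise ClusterError(
            f"{n} events < k_neighbors+1 = {k_neighbors + 1}"
        )
    X = _feature_matrix(table, markers, cofactor, z_scale)
    if np.allclose(X, X[0]):
        # degenerate input: identical events carry no partition structure
        return np.ones(n, dtype=int), 0.0
    A = kneighbors_graph(
        X, n_neighbors=k_neighbors, mode="connectivity", include_self=False
    )
    A = A.maximum(A.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(A.row, A.col) if i < j]
    g = ig.Graph(n=n, edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    raw = np.asarray(part.membership)
    # relabel contiguous from 1, largest cluster first
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[int(v)] for v in raw])
    return labels, float(part.modularity)


def leiden_partition_target_k(
    table: EventTable,
    markers: Sequence[str],
    target_clusters: int,
    seed: int = 0,
    k_neighbors: int = 15,
    cofactor: float = DEFAULT_COFACTOR,
    z_scale: bool = True,
    resolution_bounds: tuple[float, float] = (1e-3, 50.0),
    max_iter: int = 40,
) -> tuple[np.ndarray, float, float]:
    """Bisect the Leiden resolution to reach a requested cluster count.

    Returns (labels, modularity, resolution).  Raises if the count cannot be
    bracketed or hit within ``max_iter`` bisection steps.
    """
    lo, hi = resolution_bounds

    def run(res):
        return leiden_partition(
            table, markers, res, seed, k_neighbors, cofactor, z_scale
        )

    labels_lo, _ = run(lo)
    labels_hi, _ = run(hi)
    k_lo, k_hi = labels_lo.max(), labels_hi.max()
    if not k_lo <= target_clusters <= k_hi:
        raise ClusterError(
            f"target {target_clusters} clusters outside achievable range "
            f"[{k_lo}, {k_hi}] for resolutions {resolution_bounds}"
        )
    for _ in range(max_iter):
        mid = float(np.sqrt(lo * hi))  # bisect on log scale
        labels, mod = run(mid)
        k = labels.max()
        if k == target_clusters:
            return labels, mod, mid
        if k < target_clusters:
            lo = mid
        else:
            hi = mid
    raise ClusterError(
        f"bisection failed to reach exactly {target_clusters} clusters"
    )


def _profiles(
    table: EventTable,
    labels: np.ndarray,
    markers: Sequence[str],
    cofactor: float,
) -> pd.DataFrame:
    X = _feature_matrix(table, markers, cofactor, z_scale=False)
    frame = pd.DataFrame(X, columns=list(markers))
    frame["__cluster"] = labels
    prof = (
        frame[frame["__cluster"] > 0]
        .groupby("__cluster")
        .median()
        .sort_index()
    )
    prof.index.name = "cluster"
    return prof


def round1_identity(
    table: EventTable,
    panel: Panel,
    resolution: float = 1.0,
    seed: int = 0,
    k_neighbors: int = 15,
    cofactor: float = DEFAULT_COFACTOR,
) -> ClusterAssignment:
    """Round-1 clustering on the 13-marker identity set."""
    markers = panel.round1_markers
    missing = [m for m in markers if m not in table.data.columns]
    if missing:
        raise ClusterError(f"missing identity markers: {missing}")
    labels, mod = leiden_partition(
        table, markers, resolution, seed, k_neighbors, cofactor
    )
    profile_markers = list(
        dict.fromkeys(markers + ["CD11b", "CD45", "GFAP", "Olig2"])
    )
    profiles = _profiles(table, labels, profile_markers, cofactor)
    return ClusterAssignment(
        round1_label=labels,
        round1_profiles=profiles,
        params={
            "round1_resolution": resolution,
            "seed": seed,
            "k_neighbors": k_neighbors,
            "cofactor": cofactor,
            "round1_modularity": mod,
            "z_scaled": True,
        },
    )


def exclude_nonmicroglia(
    assign: ClusterAssignment,
    thresholds: dict[str, float] | None = None,
    min_gap: float = 1.0,
) -> ClusterAssignment:
    """Mark round-1 clusters with low CD11b, low CD45 or high GFAP medians.

    Thresholds default to the midpoint between the two modes of the cluster
    medians for each channel (1-D two-means split); a channel whose cluster
    medians are not bimodal at the ``min_gap`` scale triggers no exclusions.
    Events inherit their cluster's exclusion flag.
    """
    prof = assign.round1_profiles
    if len(prof) < 2 and thresholds is None:
        raise ClusterError(
            "cannot auto-derive exclusion thresholds from a single cluster; "
            "pass explicit thresholds"
        )
    resolved: dict[str, float | None] = {}
    for ch in ("CD11b", "CD45", "GFAP"):
        if thresholds is not None and ch in thresholds:
            resolved[ch] = float(thresholds[ch])
        else:
            resolved[ch] = two_means_split(
                prof[ch].to_numpy(), min_gap=min_gap
            )
    reasons: dict[int, list[str]] = {}
    for cid, row in prof.iterrows():
        why = []
        if resolved["CD11b"] is not None and row["CD11b"] < resolved["CD11b"]:
            why.append(REASON_LOW_CD11B)
        if resolved["CD45"] is not None and row["CD45"] < resolved["CD45"]:
            why.append(REASON_LOW_CD45)
        if resolved["GFAP"] is not None and row["GFAP"] > resolved["GFAP"]:
            why.append(REASON_HIGH_GFAP)
        if why:
            reasons[int(cid)] = why
    excluded = np.isin(assign.round1_label, list(reasons))
    assign.round1_excluded = excluded
    assign.exclusion_reasons = reasons
    assign.params["exclusion_thresholds"] = {
        k: (None if v is None else float(v)) for k, v in resolved.items()
    }
    return assign


def round2_signaling(
    table: EventTable,
    assign: ClusterAssignment,
    panel: Panel,
    resolution: float = 1.0,
    seed: int = 0,
    k_neighbors: int = 15,
    cofactor: float = DEFAULT_COFACTOR,
    target_clusters: int | None = None,
) -> ClusterAssignment:
    """Round-2 clustering of retained events on the signaling marker set.

    The marker set is every panel marker except CD11b, CD45, GFAP and Olig2;
    this is asserted on the list actually used.  Labels are 0 for excluded
    events; per-cluster full-panel median profiles are stored.
    """
    retained = assign.retained
    if not retained.any():
        raise ClusterError("all events excluded before round 2")
    markers = panel.round2_markers
    assert not set(markers) & set(ROUND2_EXCLUDED)
    sub = table.subset(retained)
    if target_clusters is not None:
        labels_sub, mod, resolution = leiden_partition_target_k(
            sub, markers, target_clusters, seed, k_neighbors, cofactor
        )
    else:
        labels_sub, mod = leiden_partition(
            sub, markers, resolution, seed, k_neighbors, cofactor
        )
    labels = np.zeros(table.n_events, dtype=int)
    labels[retained] = labels_sub
    assign.round2_label = labels
    assign.round2_profiles = _profiles(
        table, labels, panel.names, cofactor
    )
    assign.params.update(
        {"round2_resolution": resolution, "round2_modularity": mod}
    )
    return assign


def umap_embed(
    table: EventTable,
    markers: Sequence[str],
    config: EmbeddingConfig | None = None,
    cofactor: float = DEFAULT_COFACTOR,
) -> np.ndarray:
    """2-D UMAP coordinates; deterministic for a fixed config seed."""
    import umap  # deferred: numba compilation is slow to import

    if config is None:
        config = EmbeddingConfig()
    if table.n_events < config.n_neighbors + 1:
        raise ClusterError(
            f"{table.n_events} events < n_neighbors+1 = "
            f"{config.n_neighbors + 1}"
        )
    X = _feature_matrix(table, markers, cofactor, z_scale=True)
    reducer = umap.UMAP(
        n_neighbors=config.n_neighbors,
        metric=config.metric,
        local_connectivity=config.local_connectivity,
        n_components=config.n_components,
        n_epochs=config.epochs,
        random_state=config.seed,
    )
    return np.asarray(reducer.fit_transform(X))
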