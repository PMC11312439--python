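"""Two-round Leiden clustering, exclusion rule, UMAP embedding."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from cytoflux.cluster import (
    ClusterError,
    EmbeddingConfig,
    exclude_nonmicroglia,
    leiden_partition,
    leiden_partition_target_k,
    round1_identity,
    round2_signaling,
    umap_embed,
)
from cytoflux.events import EventTable
from cytoflux.panel import ROUND2_EXCLUDED
from cytoflux.pipeline import preprocess_run
from cytoflux.simulate import default_config, simulate_run
from cytoflux.utils import two_means_split


def _gaussian_table(n=1000, sep=6.0, seed=0, d=4):
    """Two spherical unit-SD populations, centers ``sep`` SDs apart along
    every coordinate."""
    rng = np.random.default_rng(seed)
    half = n // 2
    X = rng.standard_normal((n, d))
    X[half:] += sep
    cols = [f"m{i}" for i in range(d)]
    table = EventTable(
        pd.DataFrame(np.abs(X) + 0.0 - X.min() + 1, columns=cols),
        {c: "marker" for c in cols},
        sample_meta={"arcsinh_cofactor": 5.0},  # treat values as transformed
    )
    table.data[cols] = X  # raw gaussian features, no re-transform
    labels = np.array([0] * half + [1] * (n - half))
    return table, cols, labels


@pytest.fixture(scope="module")
def clustered_mixed(mixed_run):
    """Preprocessed mixed-culture run up to the bead gate (contaminants
    retained so the round-1 exclusion rule has work to do)."""
    from cytoflux.debarcode import (
        assign_code,
        compute_mahalanobis,
        filter_debarcoded,
        rescale_pd,
    )
    from cytoflux.gating import (
        default_bead_residual_spec,
        default_singlet_spec,
        default_viability_spec,
        run_gate_chain,
    )
    from cytoflux.normalize import (
        apply_normalization,
        fit_drift,
        identify_bead_events,
    )

    config, table, truth = mixed_run
    work = apply_normalization(
        table, fit_drift(table, identify_bead_events(table), window=200)
    )
    work = rescale_pd(work)
    res = compute_mahalanobis(assign_code(work, config.barcode_key), work)
    keep, _ = filter_debarcoded(res)
    sub, tsub = work.subset(keep), truth.subset(keep)
    km, _ = run_gate_chain(
        sub,
        [
            default_singlet_spec(),
            default_viability_spec(),
            default_bead_residual_spec(),
        ],
    )
    return config, sub.subset(km), tsub.subset(km)


class TestLeiden:
    def test_planted_partition_recovered_exactly(self):
        """Two well-separated spherical populations are recovered as
        exactly two clusters with perfect agreement (resolution set to the
        two-community scale; higher resolutions legitimately subdivide)."""
        table, cols, truth = _gaussian_table(n=2000, sep=6.0)
        labels, _ = leiden_partition(table, cols, resolution=0.1, seed=0)
        assert labels.max() == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_identical_events_form_one_cluster(self):
        table, cols, _ = _gaussian_table(n=200)
        table.data[cols] = 1.0
        labels, _ = leiden_partition(table, cols, seed=0)
        assert labels.max() == 1

    def test_fixed_seed_is_deterministic(self):
        table, cols, _ = _gaussian_table(n=800, sep=2.0, seed=3)
        l1, m1 = leiden_partition(table, cols, resolution=1.5, seed=42)
        l2, m2 = leiden_partition(table, cols, resolution=1.5, seed=42)
        assert np.array_equal(l1, l2) and m1 == m2

    def test_too_few_events_rejected(self):
        table, cols, _ = _gaussian_table(n=10)
        with pytest.raises(ClusterError, match="k_neighbors"):
            leiden_partition(table, cols, k_neighbors=15)

    def test_bisection_hits_target_cluster_count(self):
        table, cols, _ = _gaussian_table(n=1500, sep=6.0, seed=5)
        for k in (2, 4):
            labels, _, res = leiden_partition_target_k(
                table, cols, target_clusters=k, seed=0
            )
            assert labels.max() == k


class TestRound1:
    def test_thirteen_identity_markers_used(self, panel):
        assert len(panel.round1_markers) == 13

    def test_missing_identity_marker_is_named(self, clustered_mixed, panel):
        _, table, _ = clustered_mixed
        broken = table.copy()
        broken.data = broken.data.drop(columns=["Sox2"])
        broken.roles.pop("Sox2")
        with pytest.raises(ClusterError, match="Sox2"):
            round1_identity(broken, panel)

    def test_populations_map_to_distinct_clusters(self, clustered_mixed):
        config, table, truth = clustered_mixed
        assign = round1_identity(table, config.panel, seed=0)
        te = truth.events
        singlet = (~te["is_doublet"] & ~te["is_bead"]).to_numpy()
        frame = pd.DataFrame(
            {
                "pop": te["population"].to_numpy()[singlet],
                "cluster": assign.round1_label[singlet],
            }
        )
        frame["lineage"] = frame["pop"].str.replace(
            r"microglia_.*", "microglia", regex=True
        )
        for lineage, grp in frame.groupby("lineage"):
            if lineage == "debris" or len(grp) < 50:
                continue
            # purity of this lineage's modal cluster(s)
            counts = grp["cluster"].value_counts()
            modal = counts.index[0]
            cluster_members = frame[frame["cluster"] == modal]
            purity = (cluster_members["lineage"] == lineage).mean()
            assert purity >= 0.8, lineage


class TestExclusion:
    def test_rule_matches_brute_force_predicates(self, clustered_mixed):
        config, table, _ = clustered_mixed
        assign = round1_identity(table, config.panel, seed=0)
        assign = exclude_nonmicroglia(assign)
        thr = assign.params["exclusion_thresholds"]
        prof = assign.round1_profiles
        for cid, row in prof.iterrows():
            expect = []
            if thr["CD11b"] is not None and row["CD11b"] < thr["CD11b"]:
                expect.append("low_CD11b")
            if thr["CD45"] is not None and row["CD45"] < thr["CD45"]:
                expect.append("low_CD45")
            if thr["GFAP"] is not None and row["GFAP"] > thr["GFAP"]:
                expect.append("high_GFAP")
            assert assign.exclusion_reasons.get(int(cid), []) == expect

    def test_contaminants_excluded_microglia_retained(self, clustered_mixed):
        config, table, truth = clustered_mixed
        assign = exclude_nonmicroglia(
            round1_identity(table, config.panel, seed=0)
        )
        te = truth.events
        singlet = (~te["is_doublet"] & ~te["is_bead"]).to_numpy()
        pop = te["population"].to_numpy()
        contaminant = np.isin(pop, ["astrocyte", "fibroblast"]) & singlet
        microglia = (
            np.char.startswith(pop.astype(str), "microglia") & singlet
        )
        assert assign.round1_excluded[contaminant].mean() >= 0.95
        assert assign.retained[microglia].mean() >= 0.90

    def test_explicit_high_gfap_threshold_triggers_reason(
        self, clustered_mixed
    ):
        config, table, _ = clustered_mixed
        assign = round1_identity(table, config.panel, seed=0)
        gfap = assign.round1_profiles["GFAP"]
        assign = exclude_nonmicroglia(
            assign,
            thresholds={
                "CD11b": -np.inf,
                "CD45": -np.inf,
                "GFAP": float(gfap.median()) - 1e-9,
            },
        )
        flagged = {
            cid
            for cid, why in assign.exclusion_reasons.items()
            if "high_GFAP" in why
        }
        assert flagged == set(gfap.index[gfap > gfap.median() - 1e-9])

    def test_homogeneous_clusters_trigger_no_exclusion(self, microglia_run):
        config, table, truth = microglia_run
        micro = truth.events["population"].str.startswith("microglia")
        sub = table.subset(micro.to_numpy())
        assign = round1_identity(sub, config.panel, seed=0)
        if len(assign.round1_profiles) < 2:
            pytest.skip("single cluster; auto-derivation not applicable")
        assign = exclude_nonmicroglia(assign)
        assert not assign.round1_excluded.any()

    def test_single_cluster_without_thresholds_is_an_error(self):
        table, cols, _ = _gaussian_table(n=300)
        prof = pd.DataFrame(
            {"CD11b": [3.0], "CD45": [3.0], "GFAP": [0.5]},
            index=pd.Index([1], name="cluster"),
        )
        from cytoflux.cluster import ClusterAssignment

        assign = ClusterAssignment(
            round1_label=np.ones(300, dtype=int), round1_profiles=prof
        )
        with pytest.raises(ClusterError, match="single cluster"):
            exclude_nonmicroglia(assign)


class TestRound2:
    def test_marker_set_excludes_lineage_markers(self, panel):
        assert set(ROUND2_EXCLUDED).isdisjoint(panel.round2_markers)
        assert len(panel.round2_markers) == 29

    def test_round2_labels_zero_on_excluded_events(self, clustered_mixed):
        config, table, _ = clustered_mixed
        assign = exclude_nonmicroglia(
            round1_identity(table, config.panel, seed=0)
        )
        assign = round2_signaling(table, assign, config.panel, seed=0)
        assert (assign.round2_label[assign.round1_excluded] == 0).all()
        assert (assign.round2_label[assign.retained] >= 1).all()

    def test_transient_mapk_population_recovered(self, clustered_mixed):
        config, table, truth = clustered_mixed
        assign = exclude_nonmicroglia(
            round1_identity(table, config.panel, seed=0)
        )
        assign = round2_signaling(
            table, assign, config.panel, seed=0, target_clusters=4
        )
        te = truth.events
        mapk = (te["population"] == "microglia_mapk_high").to_numpy()
        mapk &= assign.retained
        labels, counts = np.unique(
            assign.round2_label[mapk], return_counts=True
        )
        modal = int(labels[np.argmax(counts)])
        prof = assign.round2_profiles
        for marker in ("pERK", "pp38"):
            assert prof.loc[modal, marker] > prof[marker].median()

    def test_planted_signaling_ari(self, clustered_mixed):
        from sklearn.metrics import adjusted_rand_score

        config, table, truth = clustered_mixed
        assign = exclude_nonmicroglia(
            round1_identity(table, config.panel, seed=0)
        )
        assign = round2_signaling(
            table, assign, config.panel, seed=0, target_clusters=4
        )
        te = truth.events
        singlet = (~te["is_doublet"] & ~te["is_bead"]).to_numpy()
        micro = np.char.startswith(
            te["population"].to_numpy().astype(str), "microglia"
        )
        mask = assign.retained & singlet & micro
        ari = adjusted_rand_score(
            te["population"].to_numpy()[mask], assign.round2_label[mask]
        )
        assert ari >= 0.9


class TestUmap:
    def test_default_config_echoes_analysis_settings(self):
        cfg = EmbeddingConfig()
        assert (
            cfg.n_neighbors,
            cfg.metric,
            cfg.local_connectivity,
            cfg.n_components,
            cfg.epochs,
        ) == (15, "euclidean", 1, 2, 1000)

    def test_separated_populations_stay_separated(self):
        table, cols, truth = _gaussian_table(n=400, sep=8.0, seed=7)
        coords = umap_embed(
            table, cols, EmbeddingConfig(epochs=200, seed=1)
        )
        assert silhouette_score(coords, truth) > 0

    def test_fixed_seed_reproducible(self):
        table, cols, _ = _gaussian_table(n=300, sep=4.0, seed=9)
        cfg = EmbeddingConfig(epochs=100, seed=5)
        c1 = umap_embed(table, cols, cfg)
        c2 = umap_embed(table, cols, cfg)
        np.testing.assert_array_equal(c1, c2)

    def test_too_few_events_rejected(self):
        table, cols, _ = _gaussian_table(n=10)
        with pytest.raises(ClusterError, match="n_neighbors"):
            umap_embed(table, cols)
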