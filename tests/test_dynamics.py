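"""Fold changes, ANOVA procedures, cluster-abundance dynamics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cytoflux import dynamics as dyn
from cytoflux.events import EventTable
from cytoflux.simulate import default_config, simulate_run


def _means_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "condition", "stimulus", "replicate",
            "timepoint_h", "mean",
        ],
    )


def _table(values, meta=None):
    return EventTable(
        pd.DataFrame({"pERK": values}),
        {"pERK": "marker"},
        sample_meta=meta or {},
    )


class TestMeanIntensity:
    def test_constant_channel(self):
        mean, n = dyn.mean_intensity(_table([7.0] * 5), "pERK")
        assert mean == 7.0 and n == 5

    def test_scales_differ(self):
        raw, _ = dyn.mean_intensity(_table([10.0, 20.0]), "pERK", "raw")
        tr, _ = dyn.mean_intensity(
            _table([10.0, 20.0]), "pERK", "transformed"
        )
        assert raw != tr
        assert tr == pytest.approx(
            np.mean(np.arcsinh(np.array([10, 20]) / 5))
        )

    def test_empty_table_is_nan_sentinel(self):
        mean, n = dyn.mean_intensity(_table([]), "pERK")
        assert math.isnan(mean) and n == 0

    def test_population_mean_recovered(self):
        """Sample mean matches the configured lognormal-Poisson mean."""
        from cytoflux.simulate import PopulationSpec

        pop = PopulationSpec("p", loc={"pERK": math.log(50)},
                             scale={"pERK": 0.3})
        rng = np.random.default_rng(0)
        n = 20000
        latent = rng.normal(math.log(50), 0.3, n)
        x = rng.poisson(np.exp(latent)).astype(float)
        mean, _ = dyn.mean_intensity(_table(x), "pERK")
        se = x.std() / math.sqrt(n)
        assert abs(mean - pop.mean_count("pERK")) < 3 * se


class TestFoldChange:
    def test_flat_series_gives_unity(self):
        rows = [
            ("pERK", "microglia", "LPS", r, t, 4.0)
            for r in (1, 2)
            for t in (0.0, 1.0, 2.0)
        ]
        fc = dyn.fold_change_series(_means_frame(rows))
        assert np.allclose(fc["fold_change"], 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        rows = [
            ("pERK", "microglia", "LPS", r, t, rng.uniform(1, 10))
            for r in (1, 2)
            for t in (0.0, 1.0, 2.0)
        ]
        base = dyn.fold_change_series(_means_frame(rows))
        scaled_rows = [(*r[:5], r[5] * 3.7) for r in rows]
        scaled = dyn.fold_change_series(_means_frame(scaled_rows))
        np.testing.assert_allclose(
            base["fold_change"], scaled["fold_change"]
        )

    def test_zero_baseline_names_marker(self):
        rows = [("CD40", "microglia", "LPS", 1, 0.0, 0.0),
                ("CD40", "microglia", "LPS", 1, 1.0, 2.0)]
        with pytest.raises(dyn.DynamicsError, match="CD40"):
            dyn.fold_change_series(_means_frame(rows))

    def test_simulated_marker_doubling_recovered(self):
        """A preset that doubles a marker's population mean at t=1 h yields
        FC(1 h) ~ 2."""
        import cytoflux.simulate as sim

        base = math.log(40)
        pops = {
            "microglia_baseline": sim.PopulationSpec(
                "microglia_baseline", loc={"pS6": base}
            ),
            "high": sim.PopulationSpec(
                "high", loc={"pS6": base + math.log(2)}
            ),
        }
        from cytoflux.panel import default_barcode_key, default_panel

        config = sim.SimConfig(
            populations=pops,
            state_weights={
                ("microglia", "LPS"): {0.0: {}, 1.0: {"high": 1.0}}
            },
            compartments={"microglia": {}},
            barcode_key=default_barcode_key(2),
            panel=default_panel(),
            timepoints=(0.0, 1.0),
            n_events=8000,
            seed=9,
        )
        t0, _ = sim.simulate_sample(config, "S01", 0.0, "microglia", "LPS")
        t1, _ = sim.simulate_sample(config, "S02", 1.0, "microglia", "LPS")
        m0, _ = dyn.mean_intensity(t0, "pS6")
        m1, _ = dyn.mean_intensity(t1, "pS6")
        assert m1 / m0 == pytest.approx(2.0, rel=0.05)


class TestSidak:
    def test_single_comparison_is_identity(self):
        assert dyn.sidak_adjust(np.array([0.2]), 1)[0] == pytest.approx(
            0.2, abs=1e-12
        )

    def test_closed_form_value(self):
        assert dyn.sidak_adjust(np.array([0.01]), 3)[0] == pytest.approx(
            0.029701, abs=1e-12
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.floats(0, 1), m=st.integers(1, 50))
    def test_dominated_by_bonferroni(self, p, m):
        adj = float(dyn.sidak_adjust(np.array([p]), m)[0])
        assert p - 1e-12 <= adj <= min(1.0, m * p) + 1e-9


def _balanced_data(rng, effect=0.0, n=3, times=(0.0, 1.0, 2.0, 4.0)):
    rows = []
    for g, shift in (("A", effect), ("B", 0.0)):
        for t in times:
            for r in range(n):
                rows.append(
                    {
                        "group": g,
                        "timepoint_h": t,
                        "fold_change": rng.normal(shift, 1.0),
                    }
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_matches_statsmodels_f_statistics(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(5)
        d = _balanced_data(rng, effect=0.8)
        res = dyn.twoway_anova_sidak(d, "group")
        model = smf.ols(
            "fold_change ~ C(group) * C(timepoint_h)", data=d
        ).fit()
        table = anova_lm(model, typ=2)
        assert res.anova["group"][0] == pytest.approx(
            table.loc["C(group)", "F"], rel=1e-9
        )
        assert res.anova["time"][0] == pytest.approx(
            table.loc["C(timepoint_h)", "F"], rel=1e-9
        )
        assert res.anova["interaction"][0] == pytest.approx(
            table.loc["C(group):C(timepoint_h)", "F"], rel=1e-9
        )
        assert res.mse == pytest.approx(
            table.loc["Residual", "sum_sq"]
            / table.loc["Residual", "df"],
            rel=1e-9,
        )

    def test_contrast_with_m_equal_1(self):
        rng = np.random.default_rng(6)
        d = _balanced_data(rng, effect=1.0, times=(0.0,))
        res = dyn.twoway_anova_sidak(d, "group")
        assert res.table["p_adj"].iloc[0] == pytest.approx(
            res.table["p_raw"].iloc[0]
        )

    def test_unbalanced_design_rejected(self):
        rng = np.random.default_rng(7)
        d = _balanced_data(rng)
        with pytest.raises(dyn.DynamicsError, match="nbalanced|replicates"):
            dyn.twoway_anova_sidak(d.iloc[:-1], "group")

    def test_detects_large_group_effect(self):
        rng = np.random.default_rng(8)
        d = _balanced_data(rng, effect=5.0, n=3)
        res = dyn.twoway_anova_sidak(d, "group")
        assert (res.table["p_adj"] < 0.05).all()


class TestDunnett:
    def test_two_groups_reduce_to_t_test(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 8)
        b = rng.normal(1, 1, 8)
        d = pd.DataFrame(
            {
                "group": ["ctrl"] * 8 + ["trt"] * 8,
                "value": np.concatenate([a, b]),
            }
        )
        res = dyn.oneway_anova_dunnett(d, "group", "value", "ctrl")
        t_p = stats.ttest_ind(b, a).pvalue
        assert res["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_identical_constants_never_reject(self):
        d = pd.DataFrame(
            {"group": ["c", "c", "a", "a", "b", "b"], "value": [1.0] * 6}
        )
        res = dyn.oneway_anova_dunnett(d, "group", "value", "c")
        assert np.allclose(res["p_adj"], 1.0)

    def test_missing_control_rejected(self):
        d = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                          "value": range(6)})
        with pytest.raises(dyn.DynamicsError, match="control"):
            dyn.oneway_anova_dunnett(d, "group", "value", "zzz")


class TestMaxFoldChangeDifference:
    def _series(self, fcs, marker="CD40"):
        rows = []
        for t, v in zip((0.0, 1.0, 2.0), fcs):
            rows.append(
                {
                    "marker": marker,
                    "condition": "x",
                    "stimulus": "LPS",
                    "replicate": 1,
                    "timepoint_h": t,
                    "fold_change": v,
                }
            )
        return pd.DataFrame(rows)

    def test_identical_series_give_zero(self):
        s = self._series((1.0, 2.0, 3.0))
        out = dyn.max_foldchange_difference(s, s.copy())
        assert out["max_difference"].iloc[0] == 0.0

    def test_stated_example(self):
        a = self._series((1.0, 3.0, 2.0))
        b = self._series((1.0, 1.0, 1.0))
        out = dyn.max_foldchange_difference(a, b)
        assert out["max_difference"].iloc[0] == 2.0
        assert out["timepoint_h"].iloc[0] == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(10)
        a = self._series(tuple(rng.uniform(0.5, 4, 3)))
        b = self._series(tuple(rng.uniform(0.5, 4, 3)))
        ab = dyn.max_foldchange_difference(a, b)
        ba = dyn.max_foldchange_difference(b, a)
        assert ab["max_difference"].iloc[0] == -ba["max_difference"].iloc[0]

    def test_grid_mismatch_rejected(self):
        a = self._series((1.0, 2.0, 3.0))
        b = self._series((1.0, 2.0, 3.0))
        b["timepoint_h"] = b["timepoint_h"] + 0.5
        with pytest.raises(dyn.DynamicsError, match="grid"):
            dyn.max_foldchange_difference(a, b)


def _events_frame(clusters, tp=0.0, cond="m", stim="LPS", rep=1):
    return pd.DataFrame(
        {
            "cluster": clusters,
            "condition": cond,
            "stimulus": stim,
            "timepoint_h": tp,
            "replicate": rep,
        }
    )


class TestClusterAbundance:
    def test_single_cluster_all_mass(self):
        ab = dyn.cluster_abundance(_events_frame([1] * 10))
        assert ab["fraction"].tolist() == [1.0]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(11)
        frames = [
            _events_frame(rng.integers(1, 6, 200), tp=t, rep=r)
            for t in (0.0, 2.0)
            for r in (1, 2)
        ]
        ab = dyn.cluster_abundance(pd.concat(frames, ignore_index=True))
        sums = ab.groupby(
            ["condition", "stimulus", "replicate", "timepoint_h"]
        )["fraction"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_planted_weights_recovered(self):
        rng = np.random.default_rng(12)
        n = 5000
        clusters = rng.choice([1, 2], size=n, p=[0.7, 0.3])
        ab = dyn.cluster_abundance(_events_frame(clusters))
        f1 = float(ab.loc[ab["cluster"] == 1, "fraction"].iloc[0])
        assert abs(f1 - 0.7) < 3 * math.sqrt(0.7 * 0.3 / n)

    def test_excluded_events_dropped(self):
        ab = dyn.cluster_abundance(_events_frame([0, 0, 1, 2]))
        assert ab["n"].sum() == 2


class TestNormalizeAbundance:
    def _abundance(self, trajs, times=(0.0, 1.0, 2.0)):
        rows = []
        for cid, traj in trajs.items():
            for t, f in zip(times, traj):
                rows.append(
                    {
                        "cluster": cid,
                        "condition": "m",
                        "stimulus": "LPS",
                        "replicate": 1,
                        "timepoint_h": t,
                        "fraction": f,
                    }
                )
        return pd.DataFrame(rows)

    def test_stated_example_and_ordering(self):
        ab = self._abundance({1: (0.2, 0.1, 0.1), 2: (0.1, 0.1, 0.2)})
        out = dyn.normalize_abundance_by_time(ab, "m", "LPS")
        np.testing.assert_allclose(
            out.loc[1, [0.0, 1.0, 2.0]], [1.0, 0.5, 0.5]
        )
        assert list(out.index) == [1, 2]  # early cluster first

    def test_constant_trajectory(self):
        ab = self._abundance({1: (0.5, 0.5, 0.5)})
        out = dyn.normalize_abundance_by_time(ab, "m", "LPS")
        np.testing.assert_allclose(out.loc[1, [0.0, 1.0, 2.0]], 1.0)
        assert out.loc[1, "ordering_index"] == pytest.approx(1.0)

    def test_all_zero_cluster_sorted_last(self):
        ab = self._abundance({1: (0.0, 0.0, 0.0), 2: (0.5, 0.3, 0.2)})
        out = dyn.normalize_abundance_by_time(ab, "m", "LPS")
        assert list(out.index) == [2, 1]
        np.testing.assert_allclose(out.loc[1, [0.0, 1.0, 2.0]], 0.0)

    def test_simulated_early_before_late(self):
        """The planted early (MAPK) population orders before the planted
        terminal population, using ground-truth labels as clusters."""
        config = default_config(n_events=400, seed=17)
        _, truth = simulate_run(config, "microglia", "LPS", 1)
        te = truth.events
        keep = te["population"].isin(
            ["microglia_mapk_high", "microglia_terminal",
             "microglia_baseline"]
        )
        codes = {"microglia_mapk_high": 1, "microglia_baseline": 2,
                 "microglia_terminal": 3}
        ev = pd.DataFrame(
            {
                "cluster": te.loc[keep, "population"].map(codes),
                "condition": "microglia",
                "stimulus": "LPS",
                "timepoint_h": te.loc[keep, "timepoint_h"],
                "replicate": 1,
            }
        )
        out = dyn.normalize_abundance_by_time(
            dyn.cluster_abundance(ev), "microglia", "LPS"
        )
        order = list(out.index)
        assert order.index(1) < order.index(3)


class TestRmse:
    def _ab(self, f0, f1):
        rows = []
        for cid, (a, b) in enumerate(zip(f0, f1), start=1):
            for t, f in ((0.0, a), (48.0, b)):
                rows.append(
                    {
                        "cluster": cid, "condition": "m",
                        "stimulus": "LPS", "replicate": 1,
                        "timepoint_h": t, "fraction": f,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_vectors_zero(self):
        ab = self._ab((0.5, 0.5), (0.5, 0.5))
        assert dyn.rmse_between_timepoints(ab, 0.0, 48.0, "m", "LPS") == 0.0

    def test_hand_computed_value(self):
        ab = self._ab((0.5, 0.5), (1.0, 0.0))
        assert dyn.rmse_between_timepoints(
            ab, 0.0, 48.0, "m", "LPS"
        ) == pytest.approx(0.5, abs=1e-15)

    def test_missing_timepoint_rejected(self):
        ab = self._ab((0.5, 0.5), (1.0, 0.0))
        with pytest.raises(dyn.DynamicsError, match="absent"):
            dyn.rmse_between_timepoints(ab, 0.0, 24.0, "m", "LPS")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(data=st.data())
    def test_metric_properties_on_simplex(self, data):
        k = data.draw(st.integers(2, 6))
        def vec():
            v = np.array(
                data.draw(
                    st.lists(st.floats(0.01, 1), min_size=k, max_size=k)
                )
            )
            return v / v.sum()
        a, b, c = vec(), vec(), vec()
        def rmse(x, y):
            return float(np.sqrt(np.mean((x - y) ** 2)))
        assert rmse(a, b) == rmse(b, a)
        assert rmse(a, c) <= rmse(a, b) + rmse(b, c) + 1e-12
        assert rmse(a, a) == 0.0


class TestFractionInCluster:
    def test_single_cluster_is_one(self):
        ev = _events_frame([3] * 20, tp=48.0)
        ab = dyn.cluster_abundance(ev)
        out = dyn.fraction_in_cluster(ab, 3, 48.0)
        assert out["mean_fraction"].iloc[0] == 1.0

    def test_fractions_sum_to_one_across_clusters(self):
        rng = np.random.default_rng(13)
        ev = _events_frame(rng.integers(1, 5, 500), tp=48.0)
        ab = dyn.cluster_abundance(ev)
        total = sum(
            dyn.fraction_in_cluster(ab, c, 48.0)["mean_fraction"].iloc[0]
            for c in sorted(ab["cluster"].unique())
        )
        assert total == pytest.approx(1.0)

    def test_unknown_cluster_rejected(self):
        ab = dyn.cluster_abundance(_events_frame([1] * 5))
        with pytest.raises(dyn.DynamicsError, match="cluster"):
            dyn.fraction_in_cluster(ab, 99, 0.0)

    def test_planted_terminal_weight_recovered(self):
        rng = np.random.default_rng(14)
        n = 4000
        ev = _events_frame(
            rng.choice([1, 2], size=n, p=[0.6, 0.4]), tp=48.0
        )
        ab = dyn.cluster_abundance(ev)
        out = dyn.fraction_in_cluster(ab, 1, 48.0)
        assert abs(
            out["mean_fraction"].iloc[0] - 0.6
        ) < 3 * math.sqrt(0.6 * 0.4 / n)
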