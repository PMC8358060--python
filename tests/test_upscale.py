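"""Bagged-tree upscaling: importance, selection, CV, gridded prediction."""

import warnings

import numpy as np
import pandas as pd
import pytest

import flnrmap as fm
from flnrmap.upscale import haversine_km, spatial_exclusion_filter


def _table(n, n_noise, seed, signal=None, names=("a", "b")):
    """Observation table with named signal columns plus noise columns."""
    rng = np.random.default_rng(seed)
    data = {name: rng.normal(size=n) for name in names}
    for k in range(n_noise):
        data[f"noise{k}"] = rng.normal(size=n)
    df = pd.DataFrame(data)
    if signal is None:
        df["vcmax25"] = rng.normal(size=n)
    else:
        df["vcmax25"] = signal(df) + 0.0
    return df


class TestImportanceRanking:
    def test_single_informative_predictor_ranked_first(self):
        df = _table(300, 10, seed=1, signal=lambda d: 3.0 * d["a"],
                    names=("a",))
        model = fm.VcmaxForest(df, ["a"] + [f"noise{k}" for k in range(10)],
                               n_trees=50, seed=2)
        ranking = model.rank_importance()
        assert next(iter(ranking)) == "a"
        assert ranking["a"] > 5 * max(
            v for k, v in ranking.items() if k != "a"
        )

    def test_pure_noise_response_not_significant_vs_null(self):
        """Sign test: the max importance on a noise response should not
        systematically beat the max importance after permuting y."""
        wins = 0
        reseeds = 10
        for s in range(reseeds):
            df = _table(100, 8, seed=100 + s)  # y is independent noise
            cands = [f"noise{k}" for k in range(8)]
            m_obs = fm.VcmaxForest(df, cands, n_trees=30, seed=s)
            obs_max = max(m_obs.rank_importance().values())
            rng = np.random.default_rng(1000 + s)
            df_null = df.assign(vcmax25=rng.permutation(df["vcmax25"].to_numpy()))
            m_null = fm.VcmaxForest(df_null, cands, n_trees=30, seed=s)
            null_max = max(m_null.rank_importance().values())
            wins += obs_max > null_max
        # one-sided binomial(10, 0.5): >=9 wins would be significant at 5%
        assert wins < 9

    def test_duplicated_column_dilutes_importance(self):
        df = _table(400, 3, seed=3, signal=lambda d: 2.0 * d["a"] + d["b"])
        cands = ["a", "b"] + [f"noise{k}" for k in range(3)]
        single = fm.VcmaxForest(df, cands, n_trees=60, seed=4).rank_importance()
        df2 = df.assign(a_copy=df["a"])
        both = fm.VcmaxForest(df2, cands + ["a_copy"], n_trees=60,
                              seed=4).rank_importance()
        combined = both["a"] + both["a_copy"]
        assert combined == pytest.approx(single["a"], rel=0.5)

    def test_constant_predictor_gets_zero_importance(self):
        df = _table(100, 3, seed=5, signal=lambda d: d["a"])
        df["flat"] = 1.0
        model = fm.VcmaxForest(df, ["a", "flat", "noise0"], n_trees=30, seed=6)
        assert model.rank_importance()["flat"] == 0.0


class TestForwardSelection:
    def test_informative_pair_recovered_in_most_reseeds(self):
        hits = 0
        reseeds = 10
        for s in range(reseeds):
            df = _table(
                400, 10, seed=200 + s,
                signal=lambda d: 3.0 * d["a"] - 2.0 * d["b"],
            )
            cands = ["a", "b"] + [f"noise{k}" for k in range(10)]
            model = fm.VcmaxForest(df, cands, n_trees=50, seed=s)
            selected, _ = model.select_predictors()
            if {"a", "b"} <= set(selected) and len(selected) <= 4:
                hits += 1
        assert hits >= 8

    def test_perfect_copy_selected_first(self):
        df = _table(200, 5, seed=7, signal=lambda d: d["a"], names=("a",))
        model = fm.VcmaxForest(df, ["a"] + [f"noise{k}" for k in range(5)],
                               n_trees=40, seed=8)
        selected, trace = model.select_predictors()
        assert selected[0] == "a"
        # r2 trace never decreases before the stopping step
        r2s = [r for r, _ in trace[: len(selected)]]
        assert all(b >= a - 1e-6 for a, b in zip(r2s, r2s[1:]))

    def test_selection_is_deterministic(self, wide_world):
        obs = wide_world["obs"]
        cands = list(wide_world["grid"].layers) + ["pft"]
        sel1, tr1 = fm.VcmaxForest(obs, cands, n_trees=40,
                                   seed=9).select_predictors()
        sel2, tr2 = fm.VcmaxForest(obs, cands, n_trees=40,
                                   seed=9).select_predictors()
        assert sel1 == sel2 and tr1 == tr2


class TestFit:
    def test_refit_same_seed_identical_oob(self):
        df = _table(300, 2, seed=10, signal=lambda d: d["a"] ** 2 + d["b"])
        m = fm.VcmaxForest(df, ["a", "b"], n_trees=60, seed=11)
        assert m.fit().oob_r2 == m.fit().oob_r2

    def test_noiseless_functional_response_high_oob_r2(self):
        df = _table(2000, 0, seed=12,
                    signal=lambda d: 3 * d["a"] + np.sin(2 * d["b"]))
        res = fm.VcmaxForest(df, ["a", "b"], n_trees=100, seed=13).fit()
        assert res.oob_r2 > 0.9

    def test_permuted_response_near_zero_oob_r2(self):
        df = _table(500, 0, seed=14, signal=lambda d: 3 * d["a"] + d["b"])
        rng = np.random.default_rng(15)
        df["vcmax25"] = rng.permutation(df["vcmax25"].to_numpy())
        res = fm.VcmaxForest(df, ["a", "b"], n_trees=60, seed=16).fit()
        assert res.oob_r2 <= 0.05

    def test_too_few_rows_rejected(self):
        df = _table(10, 0, seed=17, signal=lambda d: d["a"])
        with pytest.raises(ValueError, match="at least"):
            fm.VcmaxForest(df, ["a", "b"], n_trees=10, seed=18)


class TestCrossValidation:
    def test_close_validation_site_excluded_by_distance_rule(self):
        # two sites 55 km apart (~0.5 deg of latitude): inside a 150 km
        # radius, the validation one must be dropped
        lat = np.array([0.0, 0.494])
        lon = np.array([0.0, 0.0])
        assert 50 < haversine_km(lat[0], lon[0], lat[1], lon[1]) < 60
        kept = spatial_exclusion_filter(lat, lon, np.array([0]), np.array([1]),
                                        150.0)
        assert kept.size == 0
        far = spatial_exclusion_filter(lat, lon, np.array([0]), np.array([1]),
                                       50.0)
        assert list(far) == [1]

    def test_no_retained_row_within_radius_brute_force(self, wide_world):
        obs = wide_world["obs"]
        rng = np.random.default_rng(19)
        perm = rng.permutation(len(obs))
        test_idx, train_idx = perm[:60], perm[60:]
        kept = spatial_exclusion_filter(
            obs["lat"].to_numpy(), obs["lon"].to_numpy(),
            train_idx, test_idx, 150.0,
        )
        lat, lon = obs["lat"].to_numpy(), obs["lon"].to_numpy()
        for k in kept:
            d = haversine_km(lat[k], lon[k], lat[train_idx], lon[train_idx])
            assert d.min() >= 150.0
        assert 0 < kept.size < test_idx.size

    def test_spatial_mode_r2_more_variable_than_conventional(self, wide_world):
        obs = wide_world["obs"]
        wins = 0
        reseeds = 5
        for s in range(reseeds):
            model = fm.VcmaxForest(obs, ["lnc", "lpc", "lma", "vpd"],
                                   n_trees=40, seed=300 + s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                conv = model.cross_validate(model.candidates, "conventional",
                                            n_reps=6, seed=400 + s)
                spat = model.cross_validate(model.candidates, "spatial",
                                            n_reps=6, seed=400 + s)
            assert spat.n_validation_effective < conv.n_validation_effective
            wins += spat.r2_sd >= conv.r2_sd
        assert wins >= 3

    def test_zero_radius_spatial_equals_conventional(self, wide_world):
        obs = wide_world["obs"]
        model = fm.VcmaxForest(obs, ["lnc", "lpc"], n_trees=30, seed=20)
        conv = model.cross_validate(["lnc", "lpc"], "conventional",
                                    n_reps=3, seed=21)
        spat = model.cross_validate(["lnc", "lpc"], "spatial",
                                    exclusion_radius_km=0.0, n_reps=3, seed=21)
        assert conv.r2_mean == spat.r2_mean
        assert conv.rmse_mean == spat.rmse_mean

    def test_unknown_mode_rejected(self, wide_world):
        model = fm.VcmaxForest(wide_world["obs"], ["lnc"], n_trees=10, seed=22)
        with pytest.raises(ValueError):
            model.cross_validate(["lnc"], mode="blocked")


class TestGridPrediction:
    def test_constant_response_zero_tree_spread(self, wide_world):
        obs = wide_world["obs"].copy()
        obs["vcmax25"] = 42.0
        res = fm.VcmaxForest(obs, ["lnc", "lpc"], n_trees=30, seed=23).fit()
        vmap = res.predict_grid(wide_world["grid"])
        on = wide_world["grid"].mask
        np.testing.assert_allclose(vmap.mean[on], 42.0)
        np.testing.assert_allclose(vmap.sd[on], 0.0)

    def test_masked_cells_missing_in_mean_and_sd(self, wide_world):
        obs = wide_world["obs"]
        res = fm.VcmaxForest(obs, ["lnc", "lpc"], n_trees=30, seed=24).fit()
        vmap = res.predict_grid(wide_world["grid"])
        off = ~wide_world["grid"].mask
        assert np.all(np.isnan(vmap.mean[off]))
        assert np.all(np.isnan(vmap.sd[off]))

    def test_missing_predictor_layer_named(self, wide_world):
        obs = wide_world["obs"].copy()
        obs["exotic"] = 1.0
        res = fm.VcmaxForest(obs, ["lnc", "exotic"], n_trees=10, seed=25).fit()
        with pytest.raises(ValueError, match="exotic"):
            res.predict_grid(wide_world["grid"])

    def test_duplicated_noiseless_sites_memorized(self):
        base = _table(80, 0, seed=26, signal=lambda d: 5 * d["a"] - 2 * d["b"])
        df = pd.concat([base] * 4, ignore_index=True)
        res = fm.VcmaxForest(df, ["a", "b"], n_trees=60, seed=27).fit()
        mean, _ = res.predict_table(base)
        np.testing.assert_allclose(mean, base["vcmax25"], rtol=0.05, atol=0.3)

    def test_tree_spread_shrinks_with_ensemble_size(self):
        df = _table(200, 0, seed=28, signal=lambda d: 3 * d["a"] + d["b"] ** 2)
        df["vcmax25"] += np.random.default_rng(29).normal(0, 1.0, len(df))
        probe = _table(100, 0, seed=30, signal=lambda d: 0 * d["a"])
        sds = []
        for n_trees in (50, 200, 800):
            res = fm.VcmaxForest(df, ["a", "b"], n_trees=n_trees, seed=31).fit()
            _, sd = res.predict_table(probe)
            sds.append(sd.mean())
        # per-tree spread estimates the same bootstrap variance; the
        # *estimate* stabilises rather than shrinking to zero, so allow a
        # loose monotone-with-tolerance check on the sampling jitter
        assert sds[2] <= sds[0] * 1.15 and sds[1] <= sds[0] * 1.15
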