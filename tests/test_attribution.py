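"""PCA grouping, additive-model attribution, and sensitivity equations."""

import numpy as np
import pandas as pd
import pytest

import flnrmap as fm
from flnrmap.attribution import DEFAULT_GROUPS, GroupSpec
from flnrmap.synthetic import GLOBAL_FLNR_COEFFICIENTS


class TestGroupSpec:
    def test_lnc_banned_from_groups(self):
        with pytest.raises(ValueError, match="lnc"):
            GroupSpec({"leaf_traits": ["lnc", "lma"]})

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupSpec({"a": ["lma"], "b": ["lma", "ph"]})

    def test_default_grouping_matches_analysis_design(self):
        spec = GroupSpec()
        assert set(spec.groups) == {"leaf_traits", "climate", "soil"}
        assert "lnc" not in {v for vs in spec.groups.values() for v in vs}


class TestGroupPCA:
    def test_perfectly_correlated_pair_is_rank_one(self, rng):
        x = rng.normal(size=2000)
        df = pd.DataFrame({"lpc": x, "lma": 3 * x + 1})
        pca = fm.group_pca(df, GroupSpec({"leaf_traits": ["lpc", "lma"]}))
        assert pca.explained["leaf_traits"][0] == pytest.approx(1.0, abs=1e-10)

    def test_isotropic_variables_share_variance_equally(self, rng):
        df = pd.DataFrame(
            {v: rng.normal(size=5000) for v in DEFAULT_GROUPS["climate"]}
        )
        pca = fm.group_pca(df, GroupSpec({"climate": DEFAULT_GROUPS["climate"]}))
        np.testing.assert_allclose(pca.explained["climate"], 0.2, atol=0.05)

    def test_loadings_are_orthonormal(self, noiseless_attribution):
        for L in noiseless_attribution["pca"].loadings.values():
            np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_explained_fractions_sorted_and_normalized(self, noiseless_attribution):
        for e in noiseless_attribution["pca"].explained.values():
            assert np.all(np.diff(e) <= 1e-12)
            assert e.sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_variable_dropped_with_warning(self, rng):
        df = pd.DataFrame({"lpc": rng.normal(size=200), "lma": 1.0})
        with pytest.warns(UserWarning, match="zero variance"):
            pca = fm.group_pca(df, GroupSpec({"leaf_traits": ["lpc", "lma"]}))
        assert pca.variables["leaf_traits"] == ["lpc"]

    def test_sign_convention_is_deterministic(self, small_grid):
        a = fm.group_pca(small_grid.table())
        b = fm.group_pca(small_grid.table())
        for g in a.loadings:
            np.testing.assert_array_equal(a.loadings[g], b.loadings[g])
            j = np.argmax(np.abs(a.loadings[g]), axis=0)
            assert np.all(a.loadings[g][j, np.arange(len(j))] > 0)


def _two_group_world(rng, n=2000):
    df = pd.DataFrame({"lpc": rng.normal(size=n), "vpd": rng.normal(size=n)})
    spec = GroupSpec({"leaf_traits": ["lpc"], "climate": ["vpd"]})
    return df, fm.group_pca(df, spec)


class TestAttributionGAM:
    def test_linear_truth_in_one_pc_recovered(self, rng):
        df, pca = _two_group_world(rng)
        flnr = 2.0 * pca.scores["leaf_traits_pc1"].to_numpy() + 10.0
        pft = np.array(["CRO"] * len(df))
        res = fm.FLNRAttribution(flnr, pca, pft, n_pcs=1).fit()
        curve = res.partial_curve("leaf_traits", 1)
        slope = np.polyfit(curve["score"], curve["dflnr"], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.02)
        other = res.partial_curve("climate", 1)
        assert np.max(np.abs(other["dflnr"])) < 0.1

    def test_constant_response_gives_flat_partials(self, rng):
        df, pca = _two_group_world(rng, n=500)
        res = fm.FLNRAttribution(
            np.full(len(df), 17.0), pca, np.array(["GRA"] * len(df)), n_pcs=1
        ).fit()
        for g in ("leaf_traits", "climate"):
            assert np.max(np.abs(res.partial_curve(g, 1)["dflnr"])) < 0.1

    def test_partial_curves_centered_over_cells(self, noiseless_attribution):
        res = noiseless_attribution["results"]
        centered = res.smooth_values - res.offsets
        np.testing.assert_allclose(centered.mean(axis=0), 0.0, atol=1e-9)

    def test_additivity_reproduces_fitted_values(self, noiseless_attribution):
        res = noiseless_attribution["results"]
        ge = res.compute_group_effects()
        recon = (
            sum(ge.effects.values()) + res.lin_values + res.offsets.sum()
        )
        np.testing.assert_allclose(recon, res.fitted(), atol=1e-6)

    def test_noise_pcs_do_not_change_explained_deviance(self, rng):
        n = 1500
        df = pd.DataFrame(
            {v: rng.normal(size=n) for v in ("lpc", "lma", "vpd", "ph")}
        )
        spec = GroupSpec({"leaf_traits": ["lpc", "lma"], "climate": ["vpd", "ph"]})
        pca = fm.group_pca(df, spec)
        flnr = 3 * pca.scores["leaf_traits_pc1"].to_numpy() + rng.normal(
            0, 0.5, n
        )
        pft = np.array(["SH"] * n)
        r2_small = fm.FLNRAttribution(flnr, pca, pft, n_pcs=1).fit().r_squared()
        r2_big = fm.FLNRAttribution(flnr, pca, pft, n_pcs=2).fit().r_squared()
        assert abs(r2_big - r2_small) < 0.01

    def test_rare_pft_level_merged_with_warning(self, rng):
        df, pca = _two_group_world(rng, n=300)
        pft = np.array(["CRO"] * 295 + ["WET"] * 5)
        flnr = pca.scores["leaf_traits_pc1"].to_numpy()
        with pytest.warns(UserWarning, match="merged"):
            model = fm.FLNRAttribution(flnr, pca, pft, n_pcs=1)
        assert set(model.pft_levels) == {"CRO"}


class TestGroupEffects:
    def test_single_group_truth_dominates_everywhere(self, small_grid,
                                                     small_traits):
        truth = fm.make_truth(
            small_grid, small_traits,
            coefficients={"lma": -0.19, "lpc": 42.2},
            intercept=40.0, noise_sd=0.0, seed=31,
        )
        table = small_grid.table()
        pca = fm.group_pca(table)
        res = fm.FLNRAttribution(
            truth.flnr_true[small_grid.mask], pca, table["pft"].to_numpy(),
            n_pcs=8,
        ).fit()
        ge = res.compute_group_effects()
        assert np.mean(ge.shares["leaf_traits"] > 0.9) > 0.95
        assert ge.dominance[ge.dominance != ""].tolist().count("leaf_traits") \
            == np.sum(ge.dominance != "")

    def test_symmetric_groups_share_equally(self, rng):
        df, pca = _two_group_world(rng, n=3000)
        flnr = (
            pca.scores["leaf_traits_pc1"].to_numpy()
            + pca.scores["climate_pc1"].to_numpy()
        )
        res = fm.FLNRAttribution(flnr, pca, np.array(["MF"] * 3000),
                                 n_pcs=1).fit()
        ge = res.compute_group_effects()
        m1 = np.nanmean(ge.shares["leaf_traits"])
        m2 = np.nanmean(ge.shares["climate"])
        assert abs(m1 - m2) < 0.1

    def test_group_effects_invariant_under_pc_rotation(self, small_grid,
                                                       noiseless_truth):
        """Only the sum of a group's smooths enters the group effect, so a
        joint orthogonal rotation of the group's PCs must not change it
        (exact for a linear truth)."""
        table = small_grid.table()
        pca = fm.group_pca(table)
        flnr = noiseless_truth.flnr_true[small_grid.mask]
        pft = table["pft"].to_numpy()
        base = fm.FLNRAttribution(flnr, pca, pft, n_pcs=8).fit()
        eff_base = base.group_effect("climate")
        # rotate the climate scores (and loadings) by a random orthogonal map
        rng = np.random.default_rng(32)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        rotated = fm.PCAResult(
            variables=dict(pca.variables),
            loadings={**pca.loadings, "climate": pca.loadings["climate"] @ q},
            explained=dict(pca.explained),
            means=dict(pca.means),
            sds=dict(pca.sds),
            scores=pca.scores.copy(),
        )
        S = pca.scores[[f"climate_pc{k}" for k in range(1, 6)]].to_numpy() @ q
        for k in range(5):
            rotated.scores[f"climate_pc{k + 1}"] = S[:, k]
        eff_rot = fm.FLNRAttribution(flnr, rotated, pft,
                                     n_pcs=8).fit().group_effect("climate")
        np.testing.assert_allclose(eff_rot, eff_base, atol=1e-6)


class TestSensitivities:
    def test_noiseless_linear_truth_recovered_exactly(self, noiseless_attribution):
        sens = noiseless_attribution["results"].fit_sensitivities(
            noiseless_attribution["table"]
        )
        for v, c in GLOBAL_FLNR_COEFFICIENTS.items():
            assert sens.coefficient(v) == pytest.approx(c, rel=0.01)
        assert sens.intercepts["global"] == pytest.approx(55.0, rel=0.01)
        # variables absent from the generating equation come out near zero
        assert abs(sens.coefficient("tair")) < 0.01

    def test_direct_ols_path_is_machine_precise(self, small_grid,
                                                noiseless_truth):
        table = small_grid.table().assign(
            flnr=noiseless_truth.flnr_true[small_grid.mask]
        )
        direct = fm.direct_sensitivity_fit(table)
        for v, c in GLOBAL_FLNR_COEFFICIENTS.items():
            assert direct.coefficient(v) == pytest.approx(c, rel=1e-8)
        assert direct.intercepts["global"] == pytest.approx(55.0, rel=1e-8)

    def test_null_coefficient_ci_covers_zero(self):
        covered = 0
        reseeds = 10
        for s in range(reseeds):
            rng = np.random.default_rng(600 + s)
            table = fm.make_uniform_covariate_table(400, seed=700 + s)
            table["flnr"] = 30.0 - 0.19 * table["lma"] + rng.normal(0, 2, 400)
            sens = fm.direct_sensitivity_fit(table)
            half = float(
                sens.table.set_index("variable").loc["vpd", "ci95"]
            )
            covered += abs(sens.coefficient("vpd")) <= half
        assert covered >= 9

    def test_rescaling_units_rescales_coefficient_exactly(self, small_grid,
                                                          noiseless_truth):
        table = small_grid.table().assign(
            flnr=noiseless_truth.flnr_true[small_grid.mask]
        )
        base = fm.direct_sensitivity_fit(table)
        table2 = table.assign(vpd=table["vpd"] * 2)
        doubled = fm.direct_sensitivity_fit(table2)
        assert doubled.coefficient("vpd") == pytest.approx(
            base.coefficient("vpd") / 2, rel=1e-9
        )

    def test_per_pft_scope_skips_small_classes(self, noiseless_attribution):
        res = noiseless_attribution["results"]
        table = noiseless_attribution["table"]
        with pytest.warns(UserWarning, match="skipped"):
            sens = res.fit_sensitivities(table, scope="per_pft",
                                         min_cells=10 ** 6)
        assert sens.table.empty

    def test_equation_string_and_csv_roundtrip(self, tmp_path, small_grid,
                                               noiseless_truth):
        table = small_grid.table().assign(
            flnr=noiseless_truth.flnr_true[small_grid.mask]
        )
        sens = fm.direct_sensitivity_fit(table)
        eq = sens.equation_string("global")
        assert eq.startswith("fLNR =") and "lma" in eq
        sens.to_csv(tmp_path / "sens.csv")
        back = pd.read_csv(tmp_path / "sens.csv")
        assert {"scope", "variable", "coefficient", "ci95", "intercept"} <= set(
            back.columns
        )
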