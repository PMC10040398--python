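import numpy as np
import pandas as pd
import pytest

import finsoc as fs
from finsoc.dyadic import FIXED_EFFECTS, vif_check, zib_logpmf


class TestZIBLogPmf:
    def test_hand_enumerated_pmf(self):
        # n=2, p=0.5, pi=0.1: P(0)=0.325, P(1)=0.45, P(2)=0.225
        probs = np.exp(zib_logpmf(np.array([0, 1, 2]), 2, 0.5, 0.1))
        assert probs == pytest.approx([0.325, 0.45, 0.225])
        assert probs.sum() == pytest.approx(1.0)

    def test_full_inflation_forces_zero(self):
        assert np.exp(zib_logpmf(0, 10, 0.3, 1.0)) == pytest.approx(1.0)
        assert np.exp(zib_logpmf(3, 10, 0.3, 1.0)) == pytest.approx(0.0)

    def test_no_inflation_reduces_to_binomial(self):
        from scipy import stats

        y = np.arange(8)
        ours = zib_logpmf(y, 7, 0.37, 0.0)
        ref = stats.binom.logpmf(y, 7, 0.37)
        assert ours == pytest.approx(ref)

    def test_domain_violations_raise(self):
        with pytest.raises(ValueError):
            zib_logpmf(5, 3, 0.5, 0.1)
        with pytest.raises(ValueError):
            zib_logpmf(1, 3, 1.5, 0.1)

    def test_normalises_over_grid(self):
        # the acceptance suite runs the full grid; spot-check here
        for n in (1, 5, 17):
            for p in (0.0, 0.2, 0.95):
                for pi in (0.0, 0.5, 1.0):
                    total = np.exp(zib_logpmf(np.arange(n + 1), n, p, pi)).sum()
                    assert total == pytest.approx(1.0, abs=1e-12)


class TestDyadTable:
    def test_covariates_and_row_count(self, small_society):
        soc = small_society
        ids = [i.id for i in soc["individuals"]][:10]
        assoc = fs.compute_sri(soc["sightings"], ids)
        dyads = fs.build_dyad_table(assoc, soc["attributes"], soc["relatedness"])
        unmasked = (assoc.mask[np.triu_indices(10, 1)] == 0).sum()
        assert len(dyads) == unmasked <= 45

        attrs = soc["attributes"].set_index("individual_id")
        row = dyads.iloc[0]
        a, b = row["id_a"], row["id_b"]
        assert row["depth_diff"] == pytest.approx(
            abs(attrs.at[a, "mean_depth"] - attrs.at[b, "mean_depth"])
        )
        expected_class = (
            "SS"
            if attrs.at[a, "sponger"] and attrs.at[b, "sponger"]
            else "NN"
            if not attrs.at[a, "sponger"] and not attrs.at[b, "sponger"]
            else "MIX"
        )
        assert row["foraging"] == expected_class
        assert row["relatedness"] == pytest.approx(soc["relatedness"].at[a, b])

    def test_both_spongers_coded_ss(self):
        ids = ["a", "b"]
        sri = np.array([[np.nan, 0.5], [0.5, np.nan]])
        assoc = fs.AssociationMatrix(
            ids,
            sri,
            np.zeros((2, 2), dtype=np.int8),
            together=np.array([[0, 5], [5, 0]]),
            n_either=np.array([[0, 10], [10, 0]]),
        )
        attrs = pd.DataFrame(
            {
                "individual_id": ids,
                "haplotype": ["H", "H"],
                "sponger": [True, True],
                "mean_depth": [12.0, 7.2],
            }
        )
        rel = pd.DataFrame(np.eye(2), index=ids, columns=ids)
        dyads = fs.build_dyad_table(assoc, attrs, rel)
        assert dyads.at[0, "foraging"] == "SS"
        assert dyads.at[0, "depth_diff"] == pytest.approx(4.8)
        assert dyads.at[0, "y"] == 5 and dyads.at[0, "n"] == 10

    def test_unknown_individual_raises(self, small_society):
        soc = small_society
        ids = [i.id for i in soc["individuals"]][:5]
        assoc = fs.compute_sri(soc["sightings"], ids)
        with pytest.raises(ValueError):
            fs.build_dyad_table(
                assoc, soc["attributes"].iloc[:2], soc["relatedness"]
            )


class TestVIF:
    @staticmethod
    def _table(X):
        n = len(X)
        return pd.DataFrame(
            {
                "id_a": [f"a{i}" for i in range(n)],
                "id_b": [f"b{i}" for i in range(n)],
                "y": 0,
                "n": 10,
                "relatedness": X[:, 0],
                "same_haplotype": X[:, 1],
                "foraging": "MIX",
                "depth_diff": X[:, 2],
                "complete": True,
            }
        )

    def test_orthogonal_covariates_give_unit_vif(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = rng.normal(size=(n, 3))
        vif = vif_check(self._table(X))
        for name in ("relatedness", "same_haplotype", "depth_diff"):
            assert vif[name] == pytest.approx(1.0, abs=0.01)

    def test_correlated_pair_matches_closed_form(self):
        rng = np.random.default_rng(1)
        n = 200_00
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.normal(size=n)
        X = np.column_stack([x, y, rng.normal(size=n)])
        vif = vif_check(self._table(X))
        assert vif["relatedness"] == pytest.approx(1 / (1 - 0.64), rel=0.05)
        assert vif["same_haplotype"] == pytest.approx(1 / (1 - 0.64), rel=0.05)
        assert vif["depth_diff"] == pytest.approx(1.0, abs=0.01)

    def test_duplicated_covariate_is_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        X = np.column_stack([x, x, rng.normal(size=500)])
        vif = vif_check(self._table(X))
        assert np.isinf(vif["relatedness"])


class TestFit:
    def test_reports_all_diagnostics(self, small_fit):
        fit = small_fit["fit"]
        assert set(fit.odds_ratios["effect"]) == set(FIXED_EFFECTS)
        assert (fit.odds_ratios["ci_low"] <= fit.odds_ratios["odds_ratio"]).all()
        assert (fit.odds_ratios["odds_ratio"] <= fit.odds_ratios["ci_high"]).all()
        # R-hat exists for every parameter group
        import arviz as az

        rhat = az.rhat(fit.idata)
        for group in ("beta", "u", "sigma_u", "zi"):
            assert np.isfinite(np.asarray(rhat[group])).all()
        assert 0.0 <= fit.zero_inflation_mean <= 1.0
        assert 0.0 <= fit.bayes_r2_mean <= 1.0

    def test_recovers_planted_effect_signs(self, small_fit):
        """The generator plants positive kin/haplotype/foraging homophily and
        a negative depth effect; posterior mass should sit on those sides."""
        beta = small_fit["fit"].beta_draws()
        cols = {name: k for k, name in enumerate(FIXED_EFFECTS)}
        assert (beta[:, cols["depth_diff"]] < 0).mean() > 0.9
        assert (beta[:, cols["same_haplotype"]] > 0).mean() > 0.9

    def test_multimembership_symmetry(self, small_fit):
        """Swapping the member order of every dyad leaves the likelihood
        unchanged: u_i + u_j is symmetric."""
        from scipy.special import expit

        dyads = small_fit["dyads"]
        fit = small_fit["fit"]
        beta = fit.beta_draws()[-1]
        u = (
            fit.idata.posterior["u"].isel(chain=-1, draw=-1).to_numpy()
        )
        ids = list(fit.idata.posterior["u_dim"].to_numpy())
        idx = {ind: k for k, ind in enumerate(ids)}
        complete = dyads[dyads["complete"]].reset_index(drop=True)
        from finsoc.dyadic import _design

        X, _ = _design(complete, standardize=False)
        ui = complete["id_a"].map(idx).to_numpy()
        uj = complete["id_b"].map(idx).to_numpy()
        pi = float(fit.idata.posterior["zi"].isel(chain=-1, draw=-1))
        p_fwd = expit(X @ beta + u[ui] + u[uj])
        p_swp = expit(X @ beta + u[uj] + u[ui])
        y, n = complete["y"].to_numpy(), complete["n"].to_numpy()
        ll_fwd = zib_logpmf(y, n, p_fwd, pi).sum()
        ll_swp = zib_logpmf(y, n, p_swp, pi).sum()
        assert ll_fwd == pytest.approx(ll_swp, abs=1e-9)

    def test_too_few_dyads_raises(self, small_society):
        soc = small_society
        ids = [i.id for i in soc["individuals"]][:4]
        assoc = fs.compute_sri(soc["sightings"], ids)
        dyads = fs.build_dyad_table(assoc, soc["attributes"], soc["relatedness"])
        with pytest.raises(ValueError):
            fs.fit_zib_glmm(dyads, seed=0)

    def test_null_simulation_covers_one(self):
        """Data with no homophily: the 95% interval of each covariate's OR
        should usually contain 1."""
        from finsoc.simulate import HomophilyEffects

        covered = {name: 0 for name in FIXED_EFFECTS[1:]}
        n_rep = 6
        for seed in range(n_rep):
            cfg = fs.PopulationConfig(
                n_females=30,
                n_surveys=80,
                homophily_effects=HomophilyEffects(0.0, 0.0, 0.0, 0.0),
                seed=seed + 200,
            )
            inds, ped = fs.generate_population(cfg)
            rel = fs.simulate.population_relatedness(inds, ped)
            sightings = fs.simulate_surveys(inds, rel, cfg)
            assoc = fs.compute_sri(sightings, fs.filter_individuals(sightings))
            dyads = fs.build_dyad_table(
                assoc, fs.simulate.attributes_frame(inds), rel
            )
            fit = fs.fit_zib_glmm(
                dyads,
                fs.ZIBModelSpec(chains=2, iterations=1200),
                seed=seed,
                max_retries=0,
            )
            for _, row in fit.odds_ratios.iterrows():
                if row["effect"] == "intercept":
                    continue
                if row["ci_low"] <= 1.0 <= row["ci_high"]:
                    covered[row["effect"]] += 1
        for name, k in covered.items():
            assert k >= n_rep - 1, f"{name} covered 1 in only {k}/{n_rep} runs"


class TestForagingContrasts:
    def test_three_contrasts_with_adjusted_intervals(self, small_fit):
        contrasts = fs.foraging_contrasts(small_fit["fit"])
        assert list(contrasts["contrast"]) == ["NN_vs_MIX", "SS_vs_MIX", "NN_vs_SS"]
        assert (contrasts["ci_low"] <= contrasts["odds_ratio"]).all()
        assert (contrasts["odds_ratio"] <= contrasts["ci_high"]).all()

    def test_self_contrast_is_exactly_one(self, small_fit):
        beta = small_fit["fit"].beta_draws()
        k = FIXED_EFFECTS.index("foraging_NN")
        self_or = np.exp(beta[:, k] - beta[:, k])
        assert np.all(self_or == 1.0)

    def test_adjusted_intervals_are_wider_than_unadjusted(self, small_fit):
        beta = small_fit["fit"].beta_draws()
        k = FIXED_EFFECTS.index("foraging_NN")
        ors = np.exp(beta[:, k])
        lo_raw, hi_raw = np.quantile(ors, [0.025, 0.975])
        row = fs.foraging_contrasts(small_fit["fit"]).iloc[0]
        assert row["ci_low"] <= lo_raw and row["ci_high"] >= hi_raw
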