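"""Mixed-model estimation: recovery, oracles and prediction identities."""

import dataclasses
import math

import numpy as np
import pytest

import epagrowth as eg
from epagrowth.growth import arcsin_sqrt_transform
from epagrowth.nlme import (
    MODEL_SERIES,
    ModelSpec,
    fit_per_clone_nls,
    fit_nlme,
    marginal_loglik,
    predict_growth,
)


def _clone_records(cfg, recs, clone_id):
    return [r for r in recs if r.clone_id == clone_id]


class TestModelSpec:
    def test_canonical_series(self):
        names = [s.name for s in MODEL_SERIES]
        assert names == ["A1", "A2", "A3", "B1", "B2", "B3"]
        assert ModelSpec.from_name("B2").random_set == ("g0", "ginf")
        assert ModelSpec.from_name("A3").random_set == ("g0", "ginf", "KS")

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec.from_name("C1")


class TestPerCloneNLS:
    def test_noise_free_exact_recovery(self, default_cfg):
        cfg = default_cfg.noise_free()
        recs = eg.simulate_growth(cfg)
        clone = cfg.clones[3]
        pf = fit_per_clone_nls(_clone_records(cfg, recs, clone.clone_id))
        truth = cfg.true_params(clone)
        assert pf.params.g0 == pytest.approx(truth.g0, abs=1e-6)
        assert pf.params.ginf == pytest.approx(truth.ginf, abs=1e-6)
        assert pf.params.KS == pytest.approx(truth.KS, abs=1e-6)
        assert pf.rss == pytest.approx(0.0, abs=1e-16)
        assert pf.identifiable

    def test_flat_data_flagged_non_identifiable(self):
        recs = [
            eg.GrowthRecord("c", float(s), 1, growth_rate_g=0.2)
            for s in (0.0, 1.0, 2.0, 5.0, 10.0)
        ]
        with pytest.warns(RuntimeWarning, match="not identifiable"):
            pf = fit_per_clone_nls(recs)
        assert not pf.identifiable
        assert pf.params.ginf == pytest.approx(pf.params.g0, abs=1e-8)

    def test_matches_brute_force_grid_oracle(self, default_cfg):
        recs = eg.simulate_growth(default_cfg)
        sub = _clone_records(default_cfg, recs, "Dg")
        pf = fit_per_clone_nls(sub)
        S = np.array([r.epa_conc_S for r in sub])
        y = np.array([r.growth_rate_g for r in sub])
        # exhaustive grid over (g0, ginf, KS)
        g0s = np.linspace(y.min() - 0.05, y.max() + 0.05, 60)
        ginfs = np.linspace(y.min() - 0.05, y.max() + 0.1, 60)
        ks = np.geomspace(0.02, 20.0, 80)
        m = S[None, :] / (S[None, :] + ks[:, None])  # (K, n)
        mu = (
            g0s[:, None, None, None] * (1.0 - m[None, None, :, :])
            + ginfs[None, :, None, None] * m[None, None, :, :]
        )
        ssr = ((y - mu) ** 2).sum(axis=-1)
        i, j, k = np.unravel_index(np.argmin(ssr), ssr.shape)
        assert pf.rss <= ssr[i, j, k] + 1e-12
        # within one (geometric) grid cell of the oracle optimum
        step = ks[1] / ks[0]
        assert ks[k] / step <= pf.params.KS <= ks[k] * step

    def test_too_few_levels_rejected(self):
        recs = [
            eg.GrowthRecord("c", float(s), 1, growth_rate_g=0.2) for s in (0, 1, 2)
        ]
        with pytest.raises(ValueError, match="4 distinct"):
            fit_per_clone_nls(recs)


class TestFitNlme:
    def test_noise_free_fixed_effect_recovery_family_A(self, default_cfg):
        # common truth for every clone: family A is the generative structure
        cfg = dataclasses.replace(
            default_cfg.noise_free(),
            true_g0_by_clone={c.clone_id: 0.2 for c in default_cfg.clones},
            true_K0=1.1,
            true_KL=0.0,
        )
        recs = eg.simulate_growth(cfg)
        fit = fit_nlme(recs, list(cfg.clones), ModelSpec.from_name("A1"))
        assert fit.converged
        assert fit.fixed_estimates["g0"] == pytest.approx(0.2, abs=1e-5)
        assert fit.fixed_estimates["ginf"] == pytest.approx(0.55, abs=1e-5)
        assert fit.fixed_estimates["KS"] == pytest.approx(1.1, abs=1e-5)
        assert fit.random_sd["g0"] == pytest.approx(0.0, abs=1e-6)

    def test_noise_free_size_law_recovery_family_B(self, default_cfg):
        cfg = dataclasses.replace(
            default_cfg.noise_free(),
            true_g0_by_clone={c.clone_id: 0.25 for c in default_cfg.clones},
        )
        recs = eg.simulate_growth(cfg)
        fit = fit_nlme(recs, list(cfg.clones), ModelSpec.from_name("B1"))
        assert fit.converged
        assert fit.fixed_estimates["K0"] == pytest.approx(cfg.true_K0, abs=1e-4)
        assert fit.fixed_estimates["KL"] == pytest.approx(cfg.true_KL, abs=1e-4)

    def test_df_counting_matches_series_convention(self, growth_data):
        recs, clones = growth_data
        dfs = {}
        for spec in MODEL_SERIES:
            dfs[spec.name] = fit_nlme(recs, clones, spec).Df
        assert dfs == {"A1": 5, "A2": 6, "A3": 7, "B1": 6, "B2": 7, "B3": 8}

    def test_nested_loglik_ordering(self, growth_data):
        recs, clones = growth_data
        ll = {s.name: fit_nlme(recs, clones, s).logLik for s in MODEL_SERIES}
        tol = 1e-4
        assert ll["A3"] >= ll["A2"] - tol >= ll["A1"] - 2 * tol
        for k in "123":
            assert ll[f"B{k}"] >= ll[f"A{k}"] - tol

    def test_needs_two_clones(self, default_cfg):
        recs = eg.simulate_growth(default_cfg)
        one = [c for c in default_cfg.clones][:1]
        with pytest.raises(ValueError, match="2 clones"):
            fit_nlme(
                [r for r in recs if r.clone_id == one[0].clone_id],
                one,
                ModelSpec.from_name("A1"),
            )


class TestLikelihoodOracles:
    def test_laplace_matches_gauss_hermite_linear_effect(self, small_growth):
        recs, clones = small_growth
        spec = ModelSpec.from_name("A1")
        fit = fit_nlme(recs, clones, spec)
        args = (recs, clones, spec, fit.fixed_estimates,
                {"g0": max(fit.random_sd["g0"], 0.01)}, fit.residual_sd)
        ll_lap = marginal_loglik(*args, method="laplace")
        ll_gh = marginal_loglik(*args, method="gh", gh_nodes=20)
        assert ll_lap == pytest.approx(ll_gh, abs=0.05)

    def test_laplace_close_to_gauss_hermite_nonlinear_effect(self, small_growth):
        # a random half-saturation constant enters the mean nonlinearly, so
        # the Laplace value is approximate; 20-node adaptive quadrature is
        # the reference
        recs, clones = small_growth
        spec = ModelSpec(name="A1", family="A", random_set=("KS",))
        fixed = {"g0": 0.3, "ginf": 0.55, "KS": 1.2}
        ll_lap = marginal_loglik(
            recs, clones, spec, fixed, {"KS": 0.3}, 0.02, method="laplace"
        )
        ll_gh = marginal_loglik(
            recs, clones, spec, fixed, {"KS": 0.3}, 0.02, method="gh", gh_nodes=20
        )
        assert ll_lap == pytest.approx(ll_gh, abs=0.05)

    def test_zero_variance_equals_pooled_nls(self, small_growth):
        recs, clones = small_growth
        fit = fit_nlme(
            recs, clones, ModelSpec.from_name("A1"), random_sd_fixed={"g0": 0.0}
        )
        # independent pooled oracle: profile (g0, ginf) on a dense KS grid
        S = np.array([r.epa_conc_S for r in recs])
        y = np.array([r.growth_rate_g for r in recs])

        def pooled_ssr(k):
            m = S / (S + k)
            X = np.column_stack([1.0 - m, m])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ coef) ** 2))

        from scipy.optimize import minimize_scalar

        grid = np.geomspace(1e-3, 1e3, 400)
        k0 = grid[int(np.argmin([pooled_ssr(k) for k in grid]))]
        res = minimize_scalar(
            lambda lk: pooled_ssr(math.exp(lk)),
            bounds=(math.log(k0) - 0.1, math.log(k0) + 0.1),
            method="bounded",
            options={"xatol": 1e-14},
        )
        rss = pooled_ssr(math.exp(res.x))
        n = len(y)
        sigma2 = rss / n
        ll_oracle = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
        assert fit.logLik == pytest.approx(ll_oracle, abs=1e-6)
        assert fit.Df == 4  # pinned variance component not counted


@pytest.fixture(scope="module")
def b1_fit(growth_data):
    recs, clones = growth_data
    return fit_nlme(recs, clones, ModelSpec.from_name("B1"))


class TestPredictGrowth:
    def test_zero_concentration_gives_clone_baseline(self, b1_fit):
        cid = b1_fit.clone_ids[0]
        expected = (
            b1_fit.fixed_estimates["g0"] + b1_fit.clone_deviations[cid]["g0"]
        )
        assert predict_growth(b1_fit, cid, 0.0) == pytest.approx(expected)

    def test_large_concentration_approaches_asymptote(self, b1_fit):
        cid = b1_fit.clone_ids[0]
        assert predict_growth(b1_fit, cid, 1e6) == pytest.approx(
            b1_fit.fixed_estimates["ginf"], abs=1e-4
        )

    def test_half_saturation_midpoint(self, b1_fit):
        cid = b1_fit.clone_ids[5]
        p = b1_fit.params_for_clone(cid)
        assert predict_growth(b1_fit, cid, p.KS) == pytest.approx(
            (p.g0 + p.ginf) / 2.0
        )

    def test_unknown_clone_needs_body_size_for_family_B(self, b1_fit):
        with pytest.warns(RuntimeWarning, match="population"):
            v = predict_growth(b1_fit, "new-clone", 1.0, L=2.0)
        assert np.isfinite(v)
        with pytest.raises(ValueError, match="body size"):
            with pytest.warns(RuntimeWarning):
                predict_growth(b1_fit, "new-clone", 1.0)


class TestClutchSeries:
    def test_constructed_single_structure_data_recovered(self, default_cfg):
        # clutch curve generated directly from the fitted model's structure
        # (Monod on the transformed scale, size-law KS, no clone variation)
        law = eg.reference_size_law()
        cmax, a0, ainf = 8.0, 0.1, 0.8
        records = []
        for c in default_cfg.clones:
            K = law.K0 + law.KL * c.body_size_L
            for S in default_cfg.epa_grid:
                a = a0 + (ainf - a0) * S / (S + K)
                for rep in (1, 2, 3):
                    records.append(
                        eg.ClutchRecord(
                            c.clone_id, S, rep,
                            cmax * math.sin(math.pi * a / 2.0) ** 2,
                        )
                    )
        fit = eg.fit_clutch_series(
            records, list(default_cfg.clones), ModelSpec.from_name("B1"), scale=cmax
        )
        assert fit.converged
        assert fit.fixed_estimates["g0"] == pytest.approx(a0, abs=1e-4)
        assert fit.fixed_estimates["ginf"] == pytest.approx(ainf, abs=1e-4)
        assert fit.fixed_estimates["K0"] == pytest.approx(law.K0, abs=1e-4)
        assert fit.fixed_estimates["KL"] == pytest.approx(law.KL, abs=1e-4)
        assert fit.meta["clutch_scale"] == cmax

    def test_eggless_clones_excluded(self, default_cfg):
        records = eg.simulate_clutch(default_cfg)
        fit = eg.fit_clutch_series(
            records, list(default_cfg.clones), ModelSpec.from_name("B1"),
            scale=default_cfg.clutch_scale,
        )
        for cid in default_cfg.eggless_clones:
            assert cid not in fit.clone_deviations
            assert cid not in fit.clone_ids

    def test_all_eggless_is_error(self, default_cfg):
        records = [
            eg.ClutchRecord(c.clone_id, 1.0, 1, 0.0) for c in default_cfg.clones
        ]
        with pytest.raises(ValueError, match="eggless"):
            eg.fit_clutch_series(
                records, list(default_cfg.clones), ModelSpec.from_name("B1")
            )

    def test_transform_weakens_mean_variance_coupling(self, default_cfg):
        # on default synthetic clutch data the residual spread grows with
        # the cell mean on the raw scale; the arcsin-sqrt transform should
        # reduce that rank correlation
        from scipy.stats import spearmanr

        records = [
            r
            for r in eg.simulate_clutch(default_cfg)
            if r.clone_id not in default_cfg.eggless_clones and r.epa_conc_S > 0
        ]
        cmax = default_cfg.clutch_scale

        def mean_vs_spread(values_by_cell):
            means = np.array([np.mean(v) for v in values_by_cell])
            spread = np.array([np.std(v) for v in values_by_cell])
            keep = spread > 0
            rho, _ = spearmanr(means[keep], spread[keep])
            return abs(rho)

        cells_raw, cells_tr = {}, {}
        for r in records:
            cells_raw.setdefault((r.clone_id, r.epa_conc_S), []).append(
                r.clutch_size_c
            )
            cells_tr.setdefault((r.clone_id, r.epa_conc_S), []).append(
                arcsin_sqrt_transform(r.clutch_size_c / cmax)
            )
        rho_raw = mean_vs_spread(list(cells_raw.values()))
        rho_tr = mean_vs_spread(list(cells_tr.values()))
        assert rho_tr < rho_raw
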