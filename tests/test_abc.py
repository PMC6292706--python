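"""ABC machinery: rejection, regression adjustment, model choice, CV, GoF."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rcdkit.abc import (
    PriorSpec,
    ReferenceTable,
    cross_validate,
    estimate_params,
    goodness_of_fit,
    mad_scale,
    model_choice,
    retain_nearest,
    simulate_reference_table,
    weighted_quantile,
)


def _gaussian_table(rng, n_per_model=2000, shift=0.0, n_stats=6, t_sp_uniform=True):
    """Synthetic reference table whose 'models' are Gaussian stat clouds and
    whose single informative parameter enters stat 0 linearly.  Cheap stand-in
    for coalescent output when testing the inference machinery itself."""
    priors = PriorSpec()
    labels, stats, params, internal, row_of = [], [], {}, {}, {}
    r = 0
    for mid, mu in (("NM", 0.0), ("CM", shift)):
        t_sp = rng.uniform(*priors.t_sp, size=n_per_model)
        X = rng.normal(mu, 1.0, size=(n_per_model, n_stats))
        X[:, 0] += (t_sp - np.mean(priors.t_sp)) / np.ptp(priors.t_sp) * 4
        stats.append(X)
        labels += [mid] * n_per_model
        rows = []
        for t in t_sp:
            row = dict(t_sp=t, t_reg_c=t / 2, t_reg_f=t / 2,
                       n_now=1e5, n_anc=1e4, m_intra=0.01)
            if mid != "NM":
                row["m_inter"] = 0.01
            rows.append(row)
        params[mid] = pd.DataFrame(rows)
        internal[mid] = np.array([priors.to_internal(mid, p) for p in rows])
        row_of[mid] = np.arange(r, r + n_per_model)
        r += n_per_model
    cols = [f"s{i}" for i in range(n_stats)]
    return ReferenceTable(
        model_labels=np.array(labels),
        stats=pd.DataFrame(np.vstack(stats), columns=cols),
        params=params, internal=internal, row_of=row_of,
        priors=priors, sim_settings={}, seed=0,
    )


class TestRejectionCore:
    def test_poisson_gamma_conjugate_oracle(self, rng):
        """Rejection-ABC posterior for a Poisson rate matches the analytic
        Gamma posterior (Kolmogorov distance < 0.05 at tolerance 0.01)."""
        a, b, n_obs = 2.0, 1.0, 10
        y = rng.poisson(3.0, size=n_obs)
        n_sims = 200_000
        lam = rng.gamma(a, 1.0 / b, size=n_sims)
        means = rng.poisson(lam[:, None].repeat(n_obs, 1)).mean(axis=1)
        idx, d, w = retain_nearest(
            np.array([y.mean()]), means[:, None], tolerance=0.01,
            scale=np.array([1.0]),
        )
        post = sps.gamma(a + y.sum(), scale=1.0 / (b + n_obs))
        ks = sps.kstest(lam[idx], post.cdf).statistic
        assert ks < 0.05

    def test_posterior_sharpens_as_tolerance_shrinks(self, rng):
        a, b, n_obs = 2.0, 1.0, 10
        y = rng.poisson(3.0, size=n_obs)
        lam = rng.gamma(a, 1.0 / b, size=100_000)
        means = rng.poisson(lam[:, None].repeat(n_obs, 1)).mean(axis=1)
        post = sps.gamma(a + y.sum(), scale=1.0 / (b + n_obs))
        ks = []
        for tol in (0.25, 0.01):
            idx, _, _ = retain_nearest(np.array([y.mean()]), means[:, None],
                                       tolerance=tol, scale=np.array([1.0]))
            ks.append(sps.kstest(lam[idx], post.cdf).statistic)
        assert ks[1] < ks[0]

    def test_retain_guards(self, rng):
        X = rng.normal(size=(50, 3))
        with pytest.raises(ValueError, match="tolerance"):
            retain_nearest(np.zeros(3), X, tolerance=0.0)

    def test_weighted_quantile_matches_numpy_for_uniform_weights(self, rng):
        x = rng.normal(size=500)
        w = np.ones(500)
        got = weighted_quantile(x, [0.25, 0.5, 0.75], w)
        want = np.quantile(x, [0.25, 0.5, 0.75])
        assert np.allclose(got, want, atol=0.02)

    def test_zero_mad_columns_ignored(self, rng):
        X = rng.normal(size=(100, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero spread"):
            scale = mad_scale(X)
        assert np.isinf(scale[1])


class TestModelChoice:
    def test_identical_models_split_the_posterior(self, rng):
        table = _gaussian_table(rng, shift=0.0)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        for method in ("rejection", "mnlogistic"):
            res = model_choice(obs, table, tolerance=0.1, method=method)
            assert res.posteriors["NM"] == pytest.approx(0.5, abs=0.1)
            assert sum(res.posteriors.values()) == pytest.approx(1.0)

    def test_separated_models_identified(self, rng):
        table = _gaussian_table(rng, shift=4.0)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        res = model_choice(obs, table, tolerance=0.1)
        assert res.best_model == "NM"
        assert res.posteriors["NM"] > 0.9
        obs2 = pd.Series(np.full(6, 4.0), index=table.stats.columns)
        obs2.iloc[0] = 4.0
        assert model_choice(obs2, table, tolerance=0.1).best_model == "CM"

    def test_reproducible_given_inputs(self, rng):
        table = _gaussian_table(rng, shift=1.0, n_per_model=800)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        r1 = model_choice(obs, table, tolerance=0.1)
        r2 = model_choice(obs, table, tolerance=0.1)
        assert r1.posteriors == r2.posteriors

    def test_projection_option(self, rng):
        table = _gaussian_table(rng, shift=2.0, n_per_model=500)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        res = model_choice(obs, table, tolerance=0.2, method="rejection", projection="none")
        assert res.best_model == "NM"
        with pytest.raises(ValueError, match="projection"):
            model_choice(obs, table, tolerance=0.2, method="rejection", projection="plaid")

    def test_classifier_method(self, rng):
        table = _gaussian_table(rng, shift=3.0, n_per_model=800)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        res = model_choice(obs, table, method="classifier")
        assert res.method == "classifier"
        assert res.best_model == "NM"
        assert sum(res.posteriors.values()) == pytest.approx(1.0)
        # identical clouds: the classifier cannot prefer either model strongly
        table0 = _gaussian_table(rng, shift=0.0, n_per_model=800)
        res0 = model_choice(obs, table0, method="classifier")
        assert res0.posteriors["NM"] == pytest.approx(0.5, abs=0.15)


class TestEstimateParams:
    def test_accept_all_returns_the_prior(self, rng):
        """At tolerance 1.0 the rejection sample is the prior sample."""
        table = _gaussian_table(rng, n_per_model=3000)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        post = estimate_params(obs, table, "NM", tolerance=1.0, adjust=False)
        lo, hi = table.priors.t_sp
        ks = sps.kstest(post.rejection_samples["t_sp"],
                        sps.uniform(lo, hi - lo).cdf).statistic
        assert ks < 0.05

    def test_adjustment_improves_on_rejection(self, rng):
        """With a linear stat-parameter link, the regression adjustment
        concentrates the posterior around the truth."""
        table = _gaussian_table(rng, n_per_model=4000)
        priors = table.priors
        truth = 7e5
        obs_stat = (truth - np.mean(priors.t_sp)) / np.ptp(priors.t_sp) * 4
        obs = pd.Series([obs_stat, 0, 0, 0, 0, 0], index=table.stats.columns)
        post = estimate_params(obs, table, "NM", tolerance=0.25)
        q = post.quantiles()
        assert q.loc["t_sp", "q0.025"] <= truth <= q.loc["t_sp", "q0.975"]
        spread_adj = q.loc["t_sp", "q0.975"] - q.loc["t_sp", "q0.025"]
        qr = post.quantiles(adjusted=False)
        spread_rej = qr.loc["t_sp", "q0.975"] - qr.loc["t_sp", "q0.025"]
        assert spread_adj < spread_rej
        err_adj = abs(q.loc["t_sp", "q0.5"] - truth)
        err_rej = abs(qr.loc["t_sp", "q0.5"] - truth)
        assert err_adj < err_rej

    def test_mode_and_summary(self, rng):
        table = _gaussian_table(rng, n_per_model=1000)
        obs = pd.Series(np.zeros(6), index=table.stats.columns)
        post = estimate_params(obs, table, "NM", tolerance=0.5)
        assert table.priors.t_sp[0] <= post.mode("t_sp") <= table.priors.t_sp[1]
        assert "t_sp" in post.summary()


class TestPriorSpec:
    def test_transform_round_trip(self, rng):
        priors = PriorSpec()
        for mid in ("NM", "CM", "RM", "AM"):
            for _ in range(20):
                model = priors.sample_model(mid, rng)
                p = {k: getattr(model, k) for k in priors.param_names(mid)}
                back = priors.to_natural(mid, priors.to_internal(mid, p))
                for k, v in p.items():
                    assert back[k] == pytest.approx(v, rel=1e-6)

    def test_sampled_models_satisfy_invariants(self, rng):
        priors = PriorSpec()
        for mid in ("NM", "CM", "RM", "AM"):
            for _ in range(50):
                priors.sample_model(mid, rng).validate()  # raises on violation

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(t_sp=(2e6, 1e5))
        with pytest.raises(ValueError):
            PriorSpec(t_sc=5e4)


class TestCrossValidate:
    def test_identical_models_confuse_symmetrically(self, rng):
        table = _gaussian_table(rng, shift=0.0, n_per_model=600)
        conf = cross_validate(table, n_pods=20, tolerance=0.1, seed=4)
        assert conf.sum(axis=1).eq(20).all()
        # neither model should dominate its own row under exchangeability
        assert conf.loc["NM", "NM"] < 20
        assert conf.loc["CM", "CM"] < 20

    def test_separated_models_give_diagonal_dominance(self, rng):
        table = _gaussian_table(rng, shift=5.0, n_per_model=600)
        conf = cross_validate(table, n_pods=15, tolerance=0.1, seed=4)
        assert conf.loc["NM", "NM"] >= 13
        assert conf.loc["CM", "CM"] >= 13

    def test_zero_pods_is_an_error(self, rng):
        table = _gaussian_table(rng, n_per_model=100)
        with pytest.raises(ValueError, match="n_pods"):
            cross_validate(table, n_pods=0, seed=1)


class TestGoodnessOfFit:
    def test_central_observation_inside_envelope(self, rng):
        table = _gaussian_table(rng, shift=1.0, n_per_model=800)
        obs = pd.Series(table.stats.mean(), index=table.stats.columns)
        gof = goodness_of_fit(obs, table)
        assert any(gof.inside_envelope.values())

    def test_outlier_outside_every_envelope(self, rng):
        table = _gaussian_table(rng, shift=1.0, n_per_model=800)
        obs = pd.Series(np.full(6, 30.0), index=table.stats.columns)
        gof = goodness_of_fit(obs, table)
        assert not any(gof.inside_envelope.values())


def test_reference_table_simulation_is_deterministic():
    priors = PriorSpec()
    t1 = simulate_reference_table(("NM",), priors, 5, seed=31, n_tags=25)
    t2 = simulate_reference_table(("NM",), priors, 5, seed=31, n_tags=25)
    assert np.allclose(t1.stats.to_numpy(), t2.stats.to_numpy())
    pd.testing.assert_frame_equal(t1.params["NM"], t2.params["NM"])
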