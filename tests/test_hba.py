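"""Hierarchical Bayesian fitting: diagnostics, summaries, and cross-checks.

The expensive posterior fit is shared through the session-scoped
``recovery_fit`` fixture; an independent ensemble sampler (emcee) provides an
external oracle for the posterior of a deliberately tiny model.
"""

import numpy as np
import pandas as pd
import pytest

import fairshare as fs
from fairshare.hba import (
    HierarchicalChoiceModel,
    McmcConfig,
    PosteriorFit,
    PriorSpec,
    load_fit,
    rhat,
    summarize,
)


class TestRhat:
    def test_degenerate_constant_chains_flagged(self):
        assert np.isnan(rhat(np.ones((3, 100))))

    def test_stationary_chains_converge(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 10_000))
        assert rhat(chains) < 1.01

    def test_separated_chains_diverge(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 2000), rng.normal(5, 1, 2000)])
        assert rhat(chains) > 1.5

    def test_single_short_chain_rejected(self):
        with pytest.raises(ValueError):
            rhat(np.zeros((1, 3)))

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 400)) + rng.normal(0, 0.2, size=(3, 1))
        mine = rhat(chains)
        ref = float(
            np.asarray(az.rhat(az.convert_to_dataset(chains[:, :, None]), method="split")["x"]).ravel()[0]
        )
        assert mine == pytest.approx(ref, abs=0.01)


class TestConfig:
    def test_default_config_retains_6000_draws(self):
        cfg = McmcConfig()
        assert (cfg.chains, cfg.warmup, cfg.samples) == (3, 2000, 2000)
        assert cfg.total_draws == 6000

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(chains=0)

    def test_prior_defaults(self):
        pr = PriorSpec()
        assert (pr.mean_loc, pr.mean_scale, pr.sd_scale) == (0.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            PriorSpec(sd_scale=-1)


class TestModelConstruction:
    def test_multi_group_dataset_rejected(self, two_group_dataset):
        with pytest.raises(ValueError, match="group"):
            HierarchicalChoiceModel(two_group_dataset, "M4")

    def test_missing_condition_rejected(self, small_dataset):
        sub = fs.ChoiceDataset(small_dataset.table.query("role == 'first'").copy())
        with pytest.raises(ValueError, match="condition"):
            HierarchicalChoiceModel(sub, "M4")

    def test_parameter_count_per_model(self, small_dataset):
        n = len(small_dataset.participants)
        dims = {
            mid: HierarchicalChoiceModel(small_dataset, mid).layout.dim
            for mid in ("M1", "M3", "M4")
        }
        assert dims["M1"] == 2 * 4 + 2 + n * 5
        assert dims["M3"] == dims["M1"]
        assert dims["M4"] == 2 * 8 + 2 + n * 9

    def test_gradient_matches_finite_differences(self, small_dataset):
        m = HierarchicalChoiceModel(small_dataset, "M4")
        rng = np.random.default_rng(7)
        x = m._initial_point(rng)
        lp, g = m.logp_and_grad(x)
        eps = 1e-6
        for i in rng.choice(x.size, 10, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (m.logp_and_grad(xp)[0] - m.logp_and_grad(xm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)


class TestSummarize:
    def _stub_fit(self, draws_matrix, names):
        class Stub:
            def draws_of(self, name):
                return draws_matrix[:, names.index(name)]

        return Stub()

    def test_normal_sample_hdi_near_closed_form(self):
        rng = np.random.default_rng(3)
        d = rng.standard_normal(200_000)
        fit = self._stub_fit(d[:, None], ["x"])
        mean, (lo, hi) = summarize(fit, "x", 0.95)
        assert mean == pytest.approx(0.0, abs=0.02)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_constant_draws_zero_width(self):
        fit = self._stub_fit(np.full((100, 1), 2.5), ["x"])
        mean, (lo, hi) = summarize(fit, "x", 0.95)
        assert mean == lo == hi == 2.5

    def test_full_mass_returns_range(self):
        d = np.array([[1.0], [4.0], [2.0], [3.0]])
        fit = self._stub_fit(d, ["x"])
        _, (lo, hi) = summarize(fit, "x", 1.0)
        assert (lo, hi) == (1.0, 4.0)


class TestFit:
    def test_recovery_of_individual_alphas(self, recovery_fit, recovery_cohort):
        """Posterior-mean individual advantageous-inequity weights track the
        generating values across participants and conditions."""
        est = recovery_fit.individual_posterior_means("alpha")
        truth = recovery_cohort.ground_truth.query("parameter == 'alpha'").rename(
            columns={"value": "true"}
        )
        merged = est.merge(truth, on=["participant_id", "k"])
        r = np.corrcoef(merged["mean"], merged["true"])[0, 1]
        assert r >= 0.7

    def test_draw_count_and_shapes(self, recovery_fit, recovery_cohort):
        assert recovery_fit.n_draws == 2 * 500
        pw = recovery_fit.pointwise_loglik()
        assert pw.shape == (1000, len(recovery_cohort))
        assert np.all(pw <= 0)

    def test_temperature_group_mean_recovered(self, recovery_fit):
        mean = recovery_fit.draws_of("mu_lam").mean()
        assert mean == pytest.approx(np.log(0.2), abs=0.35)

    def test_shrinkage_toward_group_mean(self, recovery_fit, recovery_cohort):
        """Partial pooling: individual posterior means are less dispersed than
        the generating individual values around the group mean (third-party
        gain condition, where alpha is well identified)."""
        est = recovery_fit.individual_posterior_means("alpha").query("k == 3")
        truth = recovery_cohort.ground_truth.query("parameter == 'alpha' and k == 3")
        merged = est.merge(truth.rename(columns={"value": "true"}), on="participant_id")
        assert merged["mean"].std() < merged["true"].std() * 1.2

    def test_summary_table_shape(self, recovery_fit):
        s = recovery_fit.summary()
        assert set(s.columns) >= {"parameter", "mean", "sd", "rhat"}
        assert len(s) == 2 * 8 + 2  # group-level mus and log-sigmas
        assert s["rhat"].max() < 1.2

    def test_save_load_round_trip(self, tmp_path, recovery_fit, recovery_cohort):
        path = tmp_path / "fit.csv"
        recovery_fit.save(path)
        back = load_fit(path, recovery_cohort)
        assert back.n_draws == recovery_fit.n_draws
        np.testing.assert_allclose(
            back.draws_of("mu_alpha[3]"), recovery_fit.draws_of("mu_alpha[3]")
        )

    def test_unknown_parameter_rejected(self, recovery_fit):
        with pytest.raises(KeyError):
            recovery_fit.draws_of("mu_gamma[1]")


class TestEmceeCrossCheck:
    def test_group_level_posterior_matches_ensemble_sampler(self, small_dataset):
        """An affine-invariant ensemble sampler run on the identical log
        posterior reproduces the HMC group-level means (independent sampler,
        same density)."""
        emcee = pytest.importorskip("emcee")
        m = HierarchicalChoiceModel(small_dataset, "M1")
        hmc = m.fit(chains=2, warmup=400, samples=400, seed=5)

        ndim = m.layout.dim
        nwalkers = 2 * ndim + 2
        rng = np.random.default_rng(11)
        p0 = np.array([m._initial_point(rng) for _ in range(nwalkers)])
        sampler = emcee.EnsembleSampler(nwalkers, ndim, lambda x: m.logp_and_grad(x)[0])
        sampler._random = np.random.RandomState(12)
        sampler.run_mcmc(p0, 4000, progress=False)
        flat = sampler.get_chain(discard=2000, thin=10, flat=True)
        names = m.layout.coord_names(m.participants)
        for k in (1, 3):
            a = hmc.draws_of(f"mu_alpha[{k}]")
            b = flat[:, names.index(f"mu_alpha[{k}]")]
            scale = max(a.std(), 0.05)
            assert a.mean() == pytest.approx(b.mean(), abs=3.0 * scale)
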