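"""Likelihood, HPDI/contrast machinery and small-scale posterior sanity."""

import numpy as np
import pytest
from scipy import stats

from compgrowth.data_prep import (
    EGG_HEIGHT_CM,
    EGG_WEIGHT_G,
    MeasurementRecord,
    prepare_dataset,
)
from compgrowth.growth_core import composite_height, composite_mass
from compgrowth.inference import (
    GrowthModel,
    HierarchicalGrowthModel,
    PriorConfig,
    build_model,
    contrast,
    hpdi,
    log_likelihood,
)
from compgrowth.presets import reference_composite
from compgrowth.transforms import PARAM_NAMES


class TestLogLikelihood:
    def test_exact_observation_gives_normalizing_constant(self, reference_f):
        t = 10.0
        h_obs = EGG_HEIGHT_CM + composite_height(reference_f, t)
        rec = [MeasurementRecord("A", "ref", "F", t, height_cm=h_obs)]
        ds = prepare_dataset(rec, add_conception=False)
        sigma = 0.05
        ll = log_likelihood(ds, {"A": reference_f}, sigma_h=sigma, sigma_w=0.1)
        assert ll == pytest.approx(-np.log(sigma) - 0.5 * np.log(2 * np.pi))

    def test_additivity_over_records(self, reference_f):
        t = 8.0
        h_obs = 1.05 * (EGG_HEIGHT_CM + composite_height(reference_f, t))
        one = prepare_dataset(
            [MeasurementRecord("A", "ref", "F", t, height_cm=h_obs)],
            add_conception=False,
        )
        two = prepare_dataset(
            [
                MeasurementRecord("A", "ref", "F", t, height_cm=h_obs),
                MeasurementRecord("A", "ref", "F", t, height_cm=h_obs),
            ],
            add_conception=False,
        )
        ll1 = log_likelihood(one, {"A": reference_f}, 0.03, 0.08)
        ll2 = log_likelihood(two, {"A": reference_f}, 0.03, 0.08)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_matches_elementwise_normal_oracle(self, rng, reference_f):
        # brute-force oracle: loop over records, scipy normal logpdf on logs
        persons = {"A": reference_f, "B": reference_composite("M")}
        recs = []
        for pid in persons:
            for t in rng.uniform(1.0, 20.0, size=4):
                h = composite_height(persons[pid], t)
                m = composite_mass(persons[pid], t)
                recs.append(
                    MeasurementRecord(
                        pid,
                        "ref",
                        "F",
                        float(t),
                        height_cm=float(h * rng.lognormal(0, 0.05)),
                        weight_g=float(m * rng.lognormal(0, 0.05)),
                    )
                )
        ds = prepare_dataset(recs, add_conception=False)
        sh, sw = 0.03, 0.08
        expected = 0.0
        for r in recs:
            cp = persons[r.person_id]
            expected += stats.norm.logpdf(
                np.log(r.height_cm),
                np.log(EGG_HEIGHT_CM + composite_height(cp, r.t)),
                sh,
            )
            expected += stats.norm.logpdf(
                np.log(r.weight_g),
                np.log(EGG_WEIGHT_G + composite_mass(cp, r.t)),
                sw,
            )
        got = log_likelihood(ds, persons, sh, sw)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_observation_rejected(self):
        rec = [MeasurementRecord("A", "ref", "F", 1.0, height_cm=10.0)]
        ds = prepare_dataset(rec, add_conception=False)
        ds.frame.loc[0, "height_cm"] = -5.0
        with pytest.raises(ValueError):
            build_model(ds)

    def test_mixed_sexes_rejected(self):
        recs = [
            MeasurementRecord("A", "ref", "F", 5.0, height_cm=100.0),
            MeasurementRecord("B", "ref", "M", 5.0, height_cm=100.0),
        ]
        ds = prepare_dataset(recs, add_conception=False)
        with pytest.raises(ValueError, match="separate models"):
            build_model(ds)


class TestHpdi:
    def test_constant_draws_zero_width(self):
        lo, hi = hpdi(np.full(50, 3.7), 0.9)
        assert lo == hi == 3.7

    def test_uniform_ties_earliest_window(self):
        lo, hi = hpdi(np.arange(1, 101, dtype=float), 0.9)
        assert hi - lo == 90
        assert lo == 1.0  # earliest of the tied 91-point windows

    def test_standard_normal_endpoints(self):
        rng = np.random.default_rng(123)
        x = rng.standard_normal(1_000_000)
        lo, hi = hpdi(x, 0.9)
        assert lo == pytest.approx(-1.645, abs=0.02)
        assert hi == pytest.approx(1.645, abs=0.02)

    def test_agrees_with_arviz(self):
        import arviz as az

        rng = np.random.default_rng(5)
        x = rng.gamma(3.0, 1.0, size=20_000)
        lo, hi = hpdi(x, 0.9)
        ref_lo, ref_hi = az.hdi(x, hdi_prob=0.9)
        assert lo == pytest.approx(ref_lo, abs=0.02)
        assert hi == pytest.approx(ref_hi, abs=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            hpdi(np.array([1.0]), 0.9)
        with pytest.raises(ValueError):
            hpdi(np.arange(10.0), 1.5)


class TestContrast:
    def test_identical_draws_not_detectable(self):
        x = np.arange(100.0)
        res = contrast(x, x)
        assert np.all(res.draws == 0.0)
        assert not res.detectable

    def test_constant_shift_detectable(self):
        x = np.arange(100.0)
        res = contrast(x + 10.0, x)
        assert res.detectable

    def test_normal_difference(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0.3, 0.1, size=10_000)
        b = rng.normal(0.0, 0.1, size=10_000)
        res = contrast(a, b)
        assert res.detectable
        assert res.interval[0] == pytest.approx(0.07, abs=0.03)
        assert res.interval[1] == pytest.approx(0.53, abs=0.03)

    def test_unequal_lengths_resampled(self):
        res = contrast(np.arange(100.0), np.arange(50.0))
        assert res.draws.size == 50


class TestFittedPosterior:
    """Checks on the session-scoped reduced fit (12 dense persons)."""

    def test_constraints_hold_in_every_draw(self, small_fit):
        assert small_fit["posterior"].check_constraints()

    def test_trajectories_recovered_at_measured_ages(self, small_fit):
        # posterior-mean person trajectories close to truth at measured ages
        from compgrowth.summaries import group_mean_curve
        from compgrowth.transforms import natural_array
        from compgrowth.summaries import _component_heights

        post = small_fit["posterior"]
        pop = small_fit["pop"]
        ds = small_fit["dataset"]
        ages = np.array([2.75, 5.75, 10.75, 18.75])
        order = {f"{g}_{k:04d}": k for k, g in enumerate(pop.person_groups)}
        rel_errs = []
        for pid, code in ds.person_index.items():
            true_h = composite_height(pop.persons[order[pid]], ages)
            theta_draws = post.theta[:, :, code, :].reshape(-1, 19)
            est_h = _component_heights(natural_array(theta_draws), ages).sum(-1).mean(0)
            rel_errs.append(np.abs(est_h / true_h - 1).max())
        assert np.median(rel_errs) < 0.05

    def test_posterior_predictive_brackets_observations(self, small_fit):
        # 50% predictive interval covers >= 30% of held observations
        post = small_fit["posterior"]
        model = small_fit["estimator"].model_
        rng = np.random.default_rng(0)
        C, S = post.n_chains, post.n_draws
        idx = rng.integers(0, C * S, size=60)
        sims = []
        for k in idx:
            c, s = divmod(k, S)
            means = model.model_log_means(post.theta[c, s])
            sig = np.where(model.is_weight, post.sigma_w[c, s], post.sigma_h[c, s])
            sims.append(rng.normal(means, sig))
        sims = np.array(sims)
        lo, hi = np.percentile(sims, [25, 75], axis=0)
        covered = np.mean((model.ln_y >= lo) & (model.ln_y <= hi))
        assert covered >= 0.30

    def test_estimator_api(self, small_fit):
        est = small_fit["estimator"]
        params = est.get_params()
        assert params["chains"] == 2
        pred = est.predict(np.array([5.75, 26.75]))
        assert pred.shape == (2,)
        assert 80 < pred[0] < 140 and 140 < pred[1] < 190

    def test_reproducible_with_fixed_seed(self, small_fit):
        from compgrowth.inference import fit as fit_fn

        est = small_fit["estimator"]
        post2 = fit_fn(
            est.model_, chains=2, iterations=(est.warmup, est.draws), seed=est.seed
        )
        np.testing.assert_array_equal(small_fit["posterior"].mu, post2.mu)

    def test_near_noiseless_recovery(self):
        # 8 dense persons simulated with vanishing measurement noise: the
        # posterior-mean trajectory of every person matches the truth to
        # within 1% at all measured ages
        from compgrowth.growth_core import composite_height
        from compgrowth.inference import fit as fit_fn
        from compgrowth.summaries import _component_heights
        from compgrowth.synthetic_data import (
            PopulationConfig,
            ScheduleDesign,
            prepare_study,
            simulate_study,
        )
        from compgrowth.transforms import natural_array

        cfg = PopulationConfig(
            group_sizes={"reference": 8}, seed=77, sigma_h=1e-12, sigma_w=1e-12
        )
        records, pop = simulate_study(
            cfg, designs={"reference": ScheduleDesign(kind="dense")}, seed=77
        )
        ds = prepare_study(records)
        post = fit_fn(build_model(ds), chains=2, iterations=(400, 300), seed=9)
        ages = np.array([1.0, 2.75, 5.75, 10.75, 18.75])
        order = {f"reference_{j:04d}": j for j in range(8)}
        for pid, code in ds.person_index.items():
            true_h = composite_height(pop.persons[order[pid]], ages)
            th = post.theta[:, :, code, :].reshape(-1, 19)
            est = _component_heights(natural_array(th), ages).sum(-1).mean(0)
            assert np.abs(est / true_h - 1).max() < 0.01

    def test_sparse_uncertainty_comparable_to_dense(self):
        # with equal population sizes, sparse-design posterior SDs of the
        # population means stay within 3x of dense-design SDs: the
        # hierarchical pooling (plus informative priors) makes single-
        # measurement persons nearly as informative about the mean curve
        from compgrowth.inference import fit as fit_fn
        from compgrowth.synthetic_data import (
            PopulationConfig,
            ScheduleDesign,
            prepare_study,
            simulate_study,
        )

        sds = {}
        for kind in ("dense", "sparse"):
            cfg = PopulationConfig(group_sizes={"reference": 15}, seed=31)
            designs = {"reference": ScheduleDesign(kind=kind)}
            records, _ = simulate_study(cfg, designs=designs, seed=31)
            ds = prepare_study(records, designs)
            post = fit_fn(build_model(ds), chains=2, iterations=(300, 300), seed=8)
            sds[kind] = post.mu.reshape(-1, 19).std(axis=0)
        ratio = sds["sparse"] / sds["dense"]
        assert np.all(ratio < 3.0)

    def test_prior_only_run_reproduces_prior_quantiles(self):
        # with the likelihood silenced (huge measurement SDs), posterior
        # draws of mu match the prior within MC error
        recs = [
            MeasurementRecord("A", "ref", "F", 10.0, height_cm=130.0, weight_g=25000.0)
        ]
        ds = prepare_dataset(recs, add_conception=False)
        pri = PriorConfig(sd0=0.3, sigma_h_scale=2000.0, sigma_w_scale=2000.0)
        model = build_model(ds, priors=pri)
        from compgrowth.inference import fit as fit_fn

        post = fit_fn(model, chains=2, iterations=(300, 700), seed=3)
        mu0 = pri.resolved_mu0()
        z = (post.mu.reshape(-1, 19) - mu0) / 0.3
        # pooled standardized draws should look standard normal
        assert abs(z.mean()) < 0.1
        assert z.std() == pytest.approx(1.0, abs=0.12)
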