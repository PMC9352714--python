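"""Count-likelihood menu, winsorized-mean operator and the hierarchical fit."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import umifit as u
from umifit.fitness_model import (
    ModelSpec,
    ScreenDataset,
    _nbmix_winsorized_mean,
    split_rhat,
    stepping_stone_evidence,
)


class TestCountPmf:
    def test_yule_simon_rho_one(self):
        assert u.count_pmf("ys", {"rho": 1.0}, 1) == pytest.approx(0.5)

    def test_nb_large_dispersion_approaches_truncated_poisson(self):
        k = np.arange(1, 30)
        nb = u.count_pmf("nb", {"mu": 4.0, "r": 1e6}, k)
        pois = u.count_pmf("poisson", {"mu": 4.0}, k)
        assert np.max(np.abs(nb / pois - 1.0)) < 1e-3

    @pytest.mark.parametrize(
        "family,params",
        [
            ("poisson", {"mu": 3.0}),
            ("nb", {"mu": 8.0, "r": 0.7}),
            ("mix_nb", {"mu1": 5.0, "mu2": 50.0, "r1": 1.0, "r2": 1.0, "w": 0.3}),
            ("bnb", {"n": 5.0, "a": 3.0, "b": 4.0}),
            ("ys", {"rho": 2.0}),
        ],
    )
    def test_normalization(self, family, params):
        k = np.arange(1, 200_000)
        assert u.count_pmf(family, params, k).sum() == pytest.approx(1.0, abs=1e-3)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            u.count_pmf("nb", {"mu": -1.0, "r": 1.0}, 1)
        with pytest.raises(ValueError):
            u.count_pmf("mix_nb", {"mu1": 5, "mu2": 5, "r1": 1, "r2": 1, "w": 1.4}, 1)
        with pytest.raises(ValueError):
            u.count_pmf("nb", {"mu": 5.0, "r": 1.0}, 0)


class TestWinsorizedMean:
    def test_point_mass(self):
        pmf = lambda k: np.where(k == 5, 1.0, 0.0)  # noqa: E731
        for frac in (0.0, 0.02, 0.3):
            assert u.winsorized_mean_of_pmf(pmf, upper_fraction=frac) == pytest.approx(5.0)

    def test_zero_fraction_recovers_truncated_mean(self):
        mu, r = 7.0, 2.0
        got = u.winsorized_mean_of_pmf("nb", {"mu": mu, "r": r}, upper_fraction=0.0)
        p0 = (r / (r + mu)) ** r
        assert got == pytest.approx(mu / (1 - p0), rel=1e-9)

    def test_truncated_poisson_matches_bruteforce_with_explicit_q(self):
        lam, frac = 3.0, 0.02
        # independent oracle: direct summation over k = 1..1000
        k = np.arange(1, 1001)
        pmf = stats.poisson.pmf(k, lam) / (1 - math.exp(-lam))
        cdf = np.cumsum(pmf)
        q = int(k[np.argmax(cdf >= 1 - frac)])
        oracle = float((k[k <= q] * pmf[k <= q]).sum() + q * (1 - cdf[q - 1]))
        assert u.winsorized_mean_of_pmf("poisson", {"mu": lam}, frac) == pytest.approx(oracle)

    def test_infinite_mean_requires_winsorization(self):
        with pytest.raises(ValueError, match="infinite mean"):
            u.winsorized_mean_of_pmf("ys", {"rho": 0.8}, upper_fraction=0.0)
        assert u.winsorized_mean_of_pmf("ys", {"rho": 0.8}, upper_fraction=0.02) > 0

    def test_fast_path_matches_generic(self):
        cases = [
            (5.0, 50.0, 1.0, 1.0, 0.3),
            (5.0, 60.0, 1.0, 0.25, 0.3),
            (2.0, 10.0, 2.0, 0.5, 0.6),
        ]
        for mu1, mu2, r1, r2, w in cases:
            gen = u.winsorized_mean_of_pmf(
                "mix_nb", dict(mu1=mu1, mu2=mu2, r1=r1, r2=r2, w=w), 0.02
            )
            fast = float(_nbmix_winsorized_mean(mu1, mu2, r1, r2, w, 0.02))
            assert fast == pytest.approx(gen, rel=1e-9)

    def test_monotone_in_location(self):
        vals = [
            u.winsorized_mean_of_pmf("nb", {"mu": mu, "r": 1.0}, 0.02)
            for mu in (2.0, 5.0, 10.0, 40.0)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_support_below_quantile_is_untouched(self):
        # all mass on {1..4}; q = 4 so winsorization changes nothing
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        pmf = lambda k: np.where((k >= 1) & (k <= 4), probs[np.clip(k, 1, 4) - 1], 0.0)  # noqa: E731
        mean = float((np.arange(1, 5) * probs).sum())
        assert u.winsorized_mean_of_pmf(pmf, upper_fraction=0.05) == pytest.approx(mean)


def _dataset(lib, sizes_by_guide, initial=None):
    initial = initial or {g: 100 for g in lib.guide_ids}
    return ScreenDataset("manual", sizes_by_guide, initial, lib)


class TestFit:
    def test_exchangeable_guides_have_overlapping_posteriors(self, lib24):
        """With iid clones and equal initial counts, every guide's median must
        sit inside every other guide's 95% interval."""
        cfg = u.SimulationConfig(
            library=lib24, seed=31, clones_per_guide=150, library_sigma=0.0,
            family="mix_nb",
            family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
        )
        sim = u.simulate_screen(cfg)
        post = u.fit_fitness_model(
            sim.dataset, ModelSpec(chains=2, warmup=800, draws=600, seed=3, ppc_draws=50)
        )
        s = post.summary()
        assert s["median"].max() <= s["hi95"].min() + 1e-9
        assert s["median"].min() >= s["lo95"].max() - 1e-9

    def test_twofold_rate_and_scale_gives_fourfold_fitness(self, fit_hetero48, sim_hetero48):
        truth = sim_hetero48.truth.set_index("guide_id")
        s = fit_hetero48.summary().set_index("guide_id")
        up = truth.index[(truth.eps_star == 2.0)]
        neutral = truth.index[(truth.eps_star == 1.0) & (truth.phi_star == 1.0)]
        neutral = [g for g in neutral if s.loc[g, "n_clones"] > 0]
        ratio = s.loc[up, "median"].median() / s.loc[neutral, "median"].median()
        assert 3.0 <= ratio <= 5.0

    def test_zero_clone_guide_ranks_below_populated_guides(self, lib24):
        rng = np.random.default_rng(0)
        sizes = {
            g: (rng.poisson(9, 120) + 1).tolist() for g in lib24.guide_ids
        }
        sizes[lib24.guide_ids[0]] = []
        post = u.fit_fitness_model(
            _dataset(lib24, sizes),
            ModelSpec(likelihood="nb", chains=2, warmup=300, draws=300, seed=1, ppc_draws=50),
        )
        s = post.summary().set_index("guide_id")
        empty = s.loc[lib24.guide_ids[0], "median"]
        assert (s.drop(lib24.guide_ids[0])["median"] > empty).all()

    def test_grouped_replicates_narrow_intervals(self, lib24):
        first = u.simulate_screen(
            u.SimulationConfig(
                library=lib24, seed=40, clones_per_guide=100,
                family="mix_nb",
                family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
            )
        )
        sims = [first] + [
            u.simulate_screen(
                u.SimulationConfig(
                    library=lib24, seed=40 + i, clones_per_guide=100,
                    initial_counts=first.initial_counts,  # shared plasmid pool
                    family="mix_nb",
                    family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
                )
            )
            for i in (1, 2)
        ]
        datasets = [
            ScreenDataset(f"rep{i}", s.dataset.clone_sizes, first.initial_counts, lib24)
            for i, s in enumerate(sims)
        ]
        spec = lambda seed: ModelSpec(chains=2, warmup=400, draws=300, seed=seed, ppc_draws=50)  # noqa: E731

        def median_width(post):
            s = post.summary()
            return float((s["hi95"] - s["lo95"]).median())

        singles = [median_width(u.fit_fitness_model(d, spec(50 + i))) for i, d in enumerate(datasets)]
        grouped = median_width(u.fit_fitness_model(datasets, spec(60)))
        assert all(grouped <= w for w in singles)

    def test_rank_draws_are_permutations(self, fit_neutral48):
        r = fit_neutral48.ranks
        T = r.shape[-1]
        expected = np.arange(1, T + 1)
        flat = r.reshape(-1, T)
        for row in flat[:: max(1, len(flat) // 20)]:
            assert np.array_equal(np.sort(row), expected)

    def test_posterior_calibration_on_wellspecified_truth(self, lib48):
        """95% intervals should cover the true generative fitness for ~95% of
        guides when the truth has the model's own hierarchical spread."""
        rng = np.random.default_rng(12)
        eps = {g: float(np.exp(rng.normal(0, 0.2))) for g in lib48.guide_ids}
        phi = {g: float(np.exp(rng.normal(0, 0.2))) for g in lib48.guide_ids}
        cfg = u.SimulationConfig(
            library=lib48, seed=13, clones_per_guide=200, eps_star=eps, phi_star=phi,
            family="mix_nb",
            family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
        )
        sim = u.simulate_screen(cfg)
        post = u.fit_fitness_model(
            sim.dataset, ModelSpec(chains=2, warmup=600, draws=400, seed=14, ppc_draws=50)
        )
        s = post.summary().set_index("guide_id")
        truth = sim.truth.set_index("guide_id")["true_fitness"]
        covered = [
            s.loc[g, "lo95"] <= truth[g] <= s.loc[g, "hi95"] for g in s.index
        ]
        assert np.mean(covered) >= 0.88


class TestLikelihoodMenu:
    @pytest.mark.parametrize(
        "family", ["poisson", "nb", "mix_nb", "bnb", "mix_bnb", "mix_bnb_local", "ys"]
    )
    def test_every_family_fits_with_finite_fitness(self, lib24, family):
        """Each likelihood in the menu must run end to end: finite fitness
        draws, valid ranks, and a posterior-predictive mean array."""
        rng = np.random.default_rng(0)
        sizes = {g: (rng.poisson(6, 20) + 1).tolist() for g in lib24.guide_ids[:8]}
        ds = ScreenDataset("m", sizes, {g: 100 for g in lib24.guide_ids}, lib24)
        post = u.fit_fitness_model(
            ds,
            ModelSpec(likelihood=family, chains=2, warmup=100, draws=60, seed=1,
                      ppc_draws=10, slow_w_draws=20),
        )
        f = post.fitness_flat
        assert np.isfinite(f).all() and (f >= 0).all()
        assert np.isfinite(post.mean_size_flat[:, :8]).all()

    def test_bnb_winsorized_mean_matches_generic_oracle(self):
        from umifit.fitness_model import _BnbMixFamily

        fam = _BnbMixFamily(1)
        theta = np.array([[math.log(5.0), math.log(1.5), math.log(3.0)]])
        fast = float(fam.winsorized_mean(theta, np.zeros((1, 1)), 0.02)[0, 0])
        gen = u.winsorized_mean_of_pmf("bnb", {"n": 5.0, "a": 2.5, "b": 3.0}, 0.02)
        assert fast == pytest.approx(gen, rel=1e-9)

    def test_ys_winsorized_mean_matches_generic_oracle(self):
        from umifit.fitness_model import _ys_winsorized_mean

        for rho in (0.7, 1.5, 3.0):
            gen = u.winsorized_mean_of_pmf("ys", {"rho": rho}, 0.02)
            fast = float(_ys_winsorized_mean(np.array([[rho]]), 0.02)[0, 0])
            assert fast == pytest.approx(gen, rel=1e-3)


class TestGofCoverage:
    def test_perfect_posterior_scores_100(self, lib24):
        rng = np.random.default_rng(0)
        sizes = {g: (rng.poisson(9, 50) + 1).tolist() for g in lib24.guide_ids}
        ds = _dataset(lib24, sizes)
        obs = np.array([np.mean(sizes[g]) for g in lib24.guide_ids])
        T = len(lib24.guide_ids)
        mean_size = obs[None, None, :] + np.linspace(-1, 1, 50)[None, :, None]
        post = u.FitnessPosterior(
            guide_ids=list(lib24.guide_ids),
            fitness=np.ones((1, 50, T)),
            ranks=np.tile(np.arange(1, T + 1), (1, 50, 1)),
            mean_size=mean_size,
            rhat=np.ones(T),
            converged=True,
            excluded_guides=[],
            clone_totals=np.full(T, 50),
            spec=ModelSpec(),
        )
        assert u.gof_coverage(ds, post) == 100.0

    def test_misspecified_poisson_fit_further_from_nominal(self, sim_neutral48, fit_neutral48):
        """A Poisson likelihood cannot represent heavy-tailed clone sizes; its
        guide-level size factor absorbs all dispersion, so its predictive
        check sits further from the nominal 90% than the well-specified fit."""
        pois = u.fit_fitness_model(
            sim_neutral48.dataset,
            ModelSpec(likelihood="poisson", chains=2, warmup=300, draws=300, seed=8,
                      ppc_draws=150),
        )
        cov_pois = u.gof_coverage(sim_neutral48.dataset, pois)
        cov_good = u.gof_coverage(sim_neutral48.dataset, fit_neutral48)
        assert abs(cov_pois - 90.0) > abs(cov_good - 90.0)


class TestSplitRhat:
    def test_identical_chains_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 400, 3))
        draws = np.concatenate([x, x + rng.normal(0, 1e-6, x.shape)], axis=0)
        assert np.all(split_rhat(draws) < 1.02)

    def test_shifted_chain_flagged(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(1, 400, 1))
        b = rng.normal(3.0, 1.0, size=(1, 400, 1))
        assert split_rhat(np.concatenate([a, b], axis=0))[0] > 1.5


class TestMarginalLikelihood:
    def test_stepping_stone_matches_conjugate_poisson_gamma(self):
        data = np.array([3, 5, 2, 4, 6])
        a0, b0 = 2.0, 0.5

        def log_prior(th):
            return float(stats.gamma.logpdf(np.exp(th[0]), a0, scale=1 / b0) + th[0])

        def log_lik(th):
            return float(stats.poisson.logpmf(data, np.exp(th[0])).sum())

        lml, se = stepping_stone_evidence(
            log_prior, log_lik, np.array([1.0]), seed=3, n_rungs=16, warmup=400, draws=400
        )
        n, s = len(data), data.sum()
        exact = float(
            gammaln(a0 + s) - gammaln(a0) + a0 * math.log(b0)
            - (a0 + s) * math.log(b0 + n) - gammaln(data + 1).sum()
        )
        assert abs(lml - exact) < 3 * max(se, 0.05)

    def test_same_seed_reproduces_estimate(self, lib24):
        rng = np.random.default_rng(3)
        sizes = {g: (rng.poisson(6, 25) + 1).tolist() for g in lib24.guide_ids[:8]}
        initial = {g: 100 for g in lib24.guide_ids}
        ds = ScreenDataset("m", sizes, initial, lib24)
        spec = ModelSpec(likelihood="nb", seed=5)
        a = u.log_marginal_likelihood(ds, spec, n_rungs=6, warmup=100, draws=100)
        b = u.log_marginal_likelihood(ds, spec, n_rungs=6, warmup=100, draws=100)
        assert a == b

    def test_mixture_beats_poisson_on_heavy_tailed_clones(self, lib24):
        cfg = u.SimulationConfig(
            library=lib24, seed=9, clones_per_guide=40,
            family="mix_nb",
            family_params=dict(mu1=5.0, mu2=50.0, r1=1.0, r2=1.0, w=0.3),
        )
        ds = u.simulate_screen(cfg).dataset
        lml_mix, _ = u.log_marginal_likelihood(
            ds, ModelSpec(likelihood="mix_nb", seed=2), n_rungs=8, warmup=150, draws=150
        )
        lml_pois, _ = u.log_marginal_likelihood(
            ds, ModelSpec(likelihood="poisson", seed=2), n_rungs=8, warmup=150, draws=150
        )
        assert lml_mix > lml_pois
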