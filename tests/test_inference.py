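import numpy as np
import pytest

from splinemap import inference as inf
from splinemap import simulate as sim
from splinemap.inference import PosteriorSamples, mae, run_mcmc, variance_proportion, waic
from splinemap.spatial_models import ModelSpec
from splinemap.tprs import build_tprs_basis

from conftest import INFORMATIVE_POP, random_coords


def intercept_spec(n, offset=None):
    return ModelSpec(
        family="poisson",
        offset=np.zeros(n) if offset is None else offset,
        smooth_terms=[],
        include_iid=False,
    )


class TestRunMCMC:
    def test_conjugate_poisson_intercept(self):
        """Gamma-Poisson oracle: y = (3, 5), xi = 1 => posterior mean rate ~ 4."""
        spec = intercept_spec(2)
        s = run_mcmc(spec, np.array([3.0, 5.0]), chains=2, iterations=3000, burnin=1000, seed=1)
        rate = np.exp(s.draws["alpha"])
        # oracle: flat-ish prior => Gamma(8 + eps, 2); mean ~ 4
        assert rate.mean() == pytest.approx(4.0, abs=0.4)

    def test_fixed_seed_identical(self):
        spec = intercept_spec(4)
        y = np.array([2.0, 0.0, 3.0, 1.0])
        a = run_mcmc(spec, y, chains=2, iterations=500, burnin=200, seed=42)
        b = run_mcmc(spec, y, chains=2, iterations=500, burnin=200, seed=42)
        np.testing.assert_array_equal(a.draws["alpha"], b.draws["alpha"])
        np.testing.assert_array_equal(a.loglik, b.loglik)

    def test_different_seed_differs(self):
        spec = intercept_spec(4)
        y = np.array([2.0, 0.0, 3.0, 1.0])
        a = run_mcmc(spec, y, chains=1, iterations=400, burnin=200, seed=1)
        b = run_mcmc(spec, y, chains=1, iterations=400, burnin=200, seed=2)
        assert not np.array_equal(a.draws["alpha"], b.draws["alpha"])

    def test_rhat_below_101_on_well_specified_model(self):
        rng = np.random.default_rng(3)
        n = 200
        y = rng.poisson(3.0, size=n).astype(float)
        s = run_mcmc(intercept_spec(n), y, chains=4, iterations=1500, burnin=500, seed=4)
        assert s.rhat("alpha") < 1.01

    def test_retained_draw_count(self):
        spec = intercept_spec(3)
        y = np.array([1.0, 2.0, 3.0])
        s = run_mcmc(spec, y, chains=3, iterations=400, burnin=150, thin=5, seed=5)
        assert s.n_draws == 3 * ((400 - 150) // 5)
        assert s.loglik.shape == (s.n_draws, 3)

    def test_intercept_only_glm_limit(self):
        """Posterior mean of alpha approaches log(sum y / sum xi) with rich data."""
        rng = np.random.default_rng(6)
        n = 500
        xi = np.exp(rng.normal(0, 0.5, n))
        y = rng.poisson(xi * np.exp(0.7)).astype(float)
        spec = intercept_spec(n, offset=np.log(xi))
        s = run_mcmc(spec, y, chains=2, iterations=1200, burnin=500, seed=7)
        target = np.log(y.sum() / xi.sum())
        assert s.draws["alpha"].mean() == pytest.approx(target, abs=0.02)

    def test_iterations_must_exceed_burnin(self):
        with pytest.raises(ValueError):
            run_mcmc(intercept_spec(2), np.array([1.0, 1.0]), iterations=100, burnin=100)

    def test_counts_length_checked(self):
        with pytest.raises(ValueError, match="counts"):
            run_mcmc(intercept_spec(3), np.array([1.0, 2.0]))

    def test_negbin_large_dispersion_matches_poisson(self):
        rng = np.random.default_rng(8)
        geog, _ = sim.synthetic_geography(80, seed=9, pop_median=INFORMATIVE_POP)
        coords = random_coords(80, 10)
        basis = build_tprs_basis(coords, K=12)
        xi = geog.populations / 1e5
        y = rng.poisson(xi).astype(float)
        common = dict(offset=np.log(xi), smooth_terms=[("s", basis)], include_iid=False)
        pois = ModelSpec(family="poisson", **common)
        nb = ModelSpec(family="negbin", priors={"psi_fixed": 1e6}, **common)
        sp = run_mcmc(pois, y, chains=2, iterations=1200, burnin=600, seed=11)
        sn = run_mcmc(nb, y, chains=2, iterations=1200, burnin=600, seed=11)
        np.testing.assert_allclose(sp.mu.mean(axis=0), sn.mu.mean(axis=0), rtol=0.1, atol=0.2)

    def test_binomial_family(self):
        rng = np.random.default_rng(12)
        n = 300
        trials = np.full(n, 20.0)
        y = rng.binomial(20, 0.3, size=n).astype(float)
        spec = ModelSpec(family="binomial", trials=trials, smooth_terms=[], include_iid=False)
        s = run_mcmc(spec, y, chains=2, iterations=1000, burnin=400, seed=13)
        from scipy.special import expit

        assert expit(s.draws["alpha"]).mean() == pytest.approx(0.3, abs=0.03)


class TestVarianceProportion:
    @staticmethod
    def make_samples(terms):
        n_draws = next(iter(terms.values())).shape[0]
        return PosteriorSamples(
            draws={}, terms=terms, mu=np.zeros((n_draws, 1)), loglik=np.zeros((n_draws, 1)), meta={}
        )

    def test_zero_iid_gives_one(self):
        u = np.random.default_rng(0).normal(size=(20, 10))
        s = self.make_samples({"u": u, "v": np.zeros((20, 10))})
        d = variance_proportion(s)
        assert d.summary["u"]["mean"] == pytest.approx(1.0)

    def test_zero_term_gives_zero(self):
        v = np.random.default_rng(1).normal(size=(20, 10))
        s = self.make_samples({"u": np.zeros((20, 10)), "v": v})
        assert variance_proportion(s).summary["u"]["mean"] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        u = np.array([[1.0, -1.0, 0.0]])
        v = np.array([[2.0, -2.0, 0.0]])
        s = self.make_samples({"u": u, "v": v})
        d = variance_proportion(s)
        assert d.summary["u"]["mean"] == pytest.approx(1.0 / 9.0)

    def test_zero_variance_draws_dropped(self):
        u = np.vstack([np.zeros(4), [1.0, -1.0, 1.0, -1.0]])
        s = self.make_samples({"u": u})
        d = variance_proportion(s)
        assert d.n_dropped == 1
        assert d.summary["u"]["mean"] == pytest.approx(1.0)

    def test_missing_term_raises(self):
        s = self.make_samples({"u": np.ones((3, 2))})
        with pytest.raises(KeyError):
            variance_proportion(s, ["nope"])

    def test_interval_ordering(self):
        rng = np.random.default_rng(2)
        s = self.make_samples({"u": rng.normal(size=(50, 8)), "v": rng.normal(size=(50, 8))})
        d = variance_proportion(s)
        for lab in ("u", "v"):
            assert d.summary[lab]["lo95"] <= d.summary[lab]["mean"] <= d.summary[lab]["hi95"]


class TestWAIC:
    def test_identical_draws(self):
        ll = np.tile([-1.3, -0.7, -2.0], (5, 1))
        assert waic(ll) == pytest.approx(-2 * ll[0].sum())

    def test_hand_case(self):
        ll = np.array([[-1.0], [-2.0]])
        lppd = np.log((np.exp(-1) + np.exp(-2)) / 2)
        assert waic(ll) == pytest.approx(-2 * (lppd - 0.5))
        assert waic(ll) == pytest.approx(3.7597709860834447)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        ll = rng.normal(-2, 0.3, size=(40, 7))
        lppd = sum(np.log(np.mean(np.exp(ll[:, i]))) for i in range(7))
        p = sum(np.var(ll[:, i], ddof=1) for i in range(7))
        assert waic(ll) == pytest.approx(-2 * (lppd - p), abs=1e-10)

    def test_rejects_nonfinite(self):
        ll = np.array([[-1.0, np.inf], [-2.0, -1.0]])
        with pytest.raises(ValueError):
            waic(ll)

    def test_rejects_single_draw(self):
        with pytest.raises(ValueError):
            waic(np.array([[-1.0, -2.0]]))


class TestMAE:
    @staticmethod
    def with_mu(mu):
        S = mu.shape[0]
        return PosteriorSamples(draws={}, terms={}, mu=mu, loglik=np.zeros_like(mu), meta={})

    def test_perfect_fit(self):
        y = np.array([1.0, 4.0, 2.0])
        s = self.with_mu(np.tile(y, (10, 1)))
        assert mae(s, y) == 0.0

    def test_hand_case(self):
        s = self.with_mu(np.ones((5, 2)))
        assert mae(s, np.array([0.0, 2.0])) == pytest.approx(1.0)

    def test_matches_naive(self):
        rng = np.random.default_rng(4)
        mu = rng.uniform(1, 5, size=(20, 6))
        y = rng.poisson(3, size=6).astype(float)
        naive = np.mean([abs(y[i] - mu[:, i].mean()) for i in range(6)])
        assert mae(self.with_mu(mu), y) == pytest.approx(naive)


class TestRecoveryProperties:
    """Lighter-weight recovery checks complementing the acceptance suite."""

    @pytest.fixture(scope="class")
    def bases(self, geography150, coords150, basis150, movement150):
        from splinemap.tprs import build_tprs_basis

        geog, _ = geography150
        return geog, coords150, movement150, basis150, build_tprs_basis(movement150, K=30)

    def test_swapping_coordinate_systems_swaps_proportions(self, bases):
        geog, cd, cm, b1, b2 = bases

        def shares(ds, seed):
            spec = ModelSpec(
                family="poisson",
                offset=np.log(ds.offsets),
                smooth_terms=[("distance", b1), ("movement", b2)],
                include_iid=True,
            )
            s = run_mcmc(spec, ds.counts, chains=2, iterations=1500, burnin=750, seed=seed)
            return {k: v["mean"] for k, v in variance_proportion(s).summary.items()}

        da = sim.two_source(geog, cd, cm, 0.7, 0.2, 0.1, seed=21)
        db = sim.two_source(geog, cm, cd, 0.7, 0.2, 0.1, seed=21)
        ra, rb = shares(da, 22), shares(db, 23)
        assert ra["distance"] == pytest.approx(rb["movement"], abs=0.15)
        assert ra["movement"] == pytest.approx(rb["distance"], abs=0.15)

    def test_waic_prefers_spline_on_structured_data(self, bases):
        geog, cd, _, b1, _ = bases
        ds = sim.single_source(geog, cd, 1.0, seed=30)
        off = np.log(ds.offsets)
        spline = ModelSpec(family="poisson", offset=off, smooth_terms=[("distance", b1)], include_iid=True)
        null = ModelSpec(family="poisson", offset=off, smooth_terms=[], include_iid=False)
        w_spline = waic(run_mcmc(spline, ds.counts, chains=2, iterations=1200, burnin=600, seed=31).loglik)
        w_null = waic(run_mcmc(null, ds.counts, chains=2, iterations=1200, burnin=600, seed=32).loglik)
        assert w_spline < w_null
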