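import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

import pedgibbs as pg
from pedgibbs.design import build_design
from pedgibbs.models import _check_chain
from pedgibbs.pedigree import a_inverse, nrm
from pedgibbs.simulate import TraitSpec, simulate_breeding_values, simulate_pedigree, simulate_records
from pedgibbs import _gibbs
from conftest import small_sim_config


class TestHeritability:
    @pytest.mark.parametrize(
        "sa2, se2, printed",
        [
            (3.48, 22.71, 0.13),
            (0.40, 3.81, 0.09),
            (0.79, 2.03, 0.28),
            (0.55, 1.77, 0.24),
            (3.91, 8.29, 0.32),
            (6.75, 9.55, 0.41),
            (62.23, 52.78, 0.54),
        ],
    )
    def test_worked_examples(self, sa2, se2, printed):
        """Two-decimal variance components reproduce the published ratios,
        within the rounding uncertainty of the inputs themselves."""
        h2 = pg.heritability(sa2, se2)
        lo = (sa2 - 0.005) / (sa2 - 0.005 + se2 + 0.005)
        hi = (sa2 + 0.005) / (sa2 + 0.005 + se2 - 0.005)
        assert lo - 0.005 <= printed <= hi + 0.005
        assert abs(h2 - printed) < 0.0051

    def test_zero_genetic_variance(self):
        assert pg.heritability(0.0, 1.7) == 0.0

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            pg.heritability(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pg.heritability(-1.0, 2.0)


class TestGeneticCorrelation:
    def test_diagonal_gives_zero(self):
        assert pg.genetic_correlation(np.diag([2.0, 3.0])) == 0.0

    def test_degenerate_limit_is_one(self):
        assert pg.genetic_correlation(np.ones((2, 2))) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert pg.genetic_correlation([[2.0, 0.6], [0.6, 0.5]]) == pytest.approx(0.6)

    def test_zero_diagonal_undefined(self):
        with pytest.raises(ValueError):
            pg.genetic_correlation([[0.0, 0.0], [0.0, 1.0]])


class TestCategoryProb:
    def test_binary_symmetry(self):
        assert pg.category_prob(0.0, [0.0], 1) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(eta=st.floats(-4, 4))
    def test_probabilities_sum_to_one(self, eta):
        t = [0.0, 1.0, 2.0, 3.0]
        assert sum(pg.category_prob(eta, t, j) for j in range(1, 6)) == pytest.approx(1.0)

    def test_against_numerical_integration(self):
        # P(y=2 | eta=0.7, t=(0,1,2,3)) = integral of N(0.7,1) density over (0,1)
        oracle, _ = integrate.quad(lambda u: stats.norm.pdf(u, loc=0.7), 0.0, 1.0)
        assert pg.category_prob(0.7, [0.0, 1.0, 2.0, 3.0], 2) == pytest.approx(oracle, abs=1e-10)
        assert oracle == pytest.approx(0.37597, abs=1e-4)

    def test_category_out_of_range(self):
        with pytest.raises(ValueError):
            pg.category_prob(0.0, [0.0], 3)


class TestSampleLiability:
    def test_truncation_contract_lowest_and_highest(self):
        rng = np.random.default_rng(0)
        t = [0.0, 1.0, 2.0, 3.0]
        lows = [pg.sample_liability(0.3, t, 1, rng) for _ in range(200)]
        highs = [pg.sample_liability(0.3, t, 5, rng) for _ in range(200)]
        assert max(lows) <= 0.0
        assert min(highs) > 3.0

    def test_half_normal_mean_kernel(self):
        """The numba truncated-normal sampler reproduces the half-normal mean
        phi(0)/(1-Phi(0)) = sqrt(2/pi)."""
        from numba import njit

        @njit
        def draws(n):
            np.random.seed(99)
            out = np.empty(n)
            for i in range(n):
                out[i] = _gibbs._truncnorm(0.0, 1.0, 0.0, np.inf)
            return out

        x = draws(100_000)
        assert x.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_half_normal_mean_public(self):
        rng = np.random.default_rng(1)
        x = [pg.sample_liability(0.0, [0.0], 2, rng) for _ in range(3000)]
        assert np.mean(x) == pytest.approx(np.sqrt(2 / np.pi), abs=0.05)


class TestChainConfig:
    def test_study_scale_retains_4000(self):
        assert _check_chain(2_000_000, 1_000_000, 250) == 4000

    @pytest.mark.parametrize(
        "n, b, t",
        [(100, 100, 1), (100, 0, 0), (100, 10, 7), (0, 0, 1)],
    )
    def test_invalid_configs_rejected(self, n, b, t):
        with pytest.raises(ValueError):
            _check_chain(n, b, t)

    def test_retained_count_matches(self, small_study):
        ped, recs, _, _ = small_study
        mdl = pg.LinearAnimalModel(n_cycles=600, burn_in=200, thin=4, seed=0).fit(recs, ped, "anchor")
        assert mdl.samples_.n_retained == 100


class TestReproducibility:
    def test_linear_chain_bit_reproducible(self, small_study):
        ped, recs, _, _ = small_study
        kw = dict(n_cycles=800, burn_in=400, thin=4, seed=123)
        a = pg.LinearAnimalModel(**kw).fit(recs, ped, "anchor")
        b = pg.LinearAnimalModel(**kw).fit(recs, ped, "anchor")
        assert a.samples_.draws.equals(b.samples_.draws)

    def test_threshold_chain_bit_reproducible(self, small_study):
        ped, recs, _, _ = small_study
        kw = dict(n_cycles=800, burn_in=400, thin=4, seed=9)
        a = pg.ThresholdAnimalModel(**kw).fit(recs, ped, "score")
        b = pg.ThresholdAnimalModel(**kw).fit(recs, ped, "score")
        assert a.samples_.draws.equals(b.samples_.draws)

    def test_different_seeds_differ(self, small_study):
        ped, recs, _, _ = small_study
        a = pg.LinearAnimalModel(n_cycles=800, burn_in=400, thin=4, seed=1).fit(recs, ped, "anchor")
        b = pg.LinearAnimalModel(n_cycles=800, burn_in=400, thin=4, seed=2).fit(recs, ped, "anchor")
        assert not a.samples_.draws.equals(b.samples_.draws)


def test_mme_solution_matches_dense_solve(small_study):
    """The blocked mixed-model-equation solver agrees with a dense solve —
    the flat-prior posterior mode of the location effects at fixed variances."""
    ped, recs, _, _ = small_study
    mm = build_design(recs, ped, trait="anchor")
    ainv = a_inverse(ped)
    lam = 1.5
    beta, alpha = pg.solve_mme(mm, ainv, lam)
    X, Z = mm.X.toarray(), mm.Z.toarray()
    C = np.block([[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * ainv.toarray()]])
    rhs = np.concatenate([X.T @ mm.y, Z.T @ mm.y])
    sol = np.linalg.solve(C, rhs)
    assert np.allclose(np.concatenate([beta, alpha]), sol, atol=1e-8)


def _reml_h2(mm, ped):
    """Restricted-likelihood oracle: maximize the REML log-likelihood of
    y ~ N(X beta, sa2 * A_obs + se2 * I) directly."""
    a_obs = nrm(ped)[np.ix_(mm.animal_index, mm.animal_index)]
    w, u = np.linalg.eigh(a_obs)
    yt = u.T @ mm.y
    xt = u.T @ mm.X.toarray()

    def neg_llr(params):
        sa2, se2 = np.exp(params)
        d = sa2 * w + se2
        xtd = xt / d[:, None]
        xvx = xt.T @ xtd
        bhat = np.linalg.solve(xvx, xtd.T @ yt)
        resid = yt - xt @ bhat
        rss = np.sum(resid**2 / d)
        sign, logdet_xvx = np.linalg.slogdet(xvx)
        return 0.5 * (np.sum(np.log(d)) + logdet_xvx + rss)

    vy = np.var(mm.y)
    res = optimize.minimize(neg_llr, np.log([0.5 * vy, 0.5 * vy]), method="Nelder-Mead")
    sa2, se2 = np.exp(res.x)
    return sa2 / (sa2 + se2)


def test_linear_sampler_agrees_with_reml_oracle():
    """Posterior mean h2 within 0.1 of the REML estimate on the same data."""
    cfg = small_sim_config(
        seed=5,
        n_recorded=400,
        traits=[TraitSpec("anchor", h2=0.4, mean=0.0, phenotypic_var=1.0)],
        genetic_corr={},
    )
    cfg.n_per_generation = 140
    ped = simulate_pedigree(cfg)
    bvs = simulate_breeding_values(ped, cfg.g0(), seed=6)
    recs = simulate_records(ped, bvs, cfg)
    mdl = pg.LinearAnimalModel(n_cycles=15_000, burn_in=7_500, thin=5, seed=3).fit(recs, ped, "anchor")
    mm = build_design(recs, ped, trait="anchor")
    reml = _reml_h2(mm, ped)
    assert abs(mdl.h2_mean_ - reml) < 0.1


def test_linear_no_genetic_signal_concentrates_near_zero():
    cfg = small_sim_config(
        seed=17,
        n_recorded=400,
        traits=[TraitSpec("anchor", h2=0.0, mean=0.0, phenotypic_var=1.0)],
        genetic_corr={},
    )
    cfg.n_per_generation = 140
    ped = simulate_pedigree(cfg)
    bvs = simulate_breeding_values(ped, cfg.g0(), seed=18)
    recs = simulate_records(ped, bvs, cfg)
    mdl = pg.LinearAnimalModel(n_cycles=10_000, burn_in=5_000, thin=5, seed=2).fit(recs, ped, "anchor")
    assert mdl.h2_mean_ < 0.1


def test_threshold_no_genetic_signal_concentrates_near_zero():
    cfg = small_sim_config(
        seed=19,
        n_recorded=400,
        traits=[TraitSpec("score", h2=0.0, mean=1.2, n_categories=5)],
        genetic_corr={},
    )
    cfg.n_per_generation = 140
    ped = simulate_pedigree(cfg)
    bvs = simulate_breeding_values(ped, cfg.g0(), seed=20)
    recs = simulate_records(ped, bvs, cfg)
    mdl = pg.ThresholdAnimalModel(n_cycles=10_000, burn_in=5_000, thin=5, seed=2).fit(recs, ped, "score")
    assert mdl.h2_mean_ < 0.1


def test_threshold_smoke_on_study_design(default_study):
    """BCS-like 5-category trait at the study's size runs a full chain without
    non-finite states; h2 draws stay in (0, 1)."""
    ped, recs, _, _ = default_study
    mdl = pg.ThresholdAnimalModel(n_cycles=20_000, burn_in=10_000, thin=10, seed=0).fit(recs, ped, "bcs")
    d = mdl.samples_.draws
    assert np.isfinite(d.to_numpy()).all()
    assert ((d["h2"] > 0) & (d["h2"] < 1)).all()
    assert (d["sigma_a2"] > 0).all()
    t = mdl.thresholds_mean_[1:5]
    assert np.all(np.diff(t) > 0) and t[0] == 0.0


def test_bivariate_draw_contracts(small_study):
    """Retained bivariate draws satisfy |rg| <= 1 and keep G0, R0 positive
    definite."""
    ped, recs, _, _ = small_study
    mdl = pg.BivariateAnimalModel(n_cycles=4000, burn_in=2000, thin=4, seed=5).fit(
        recs, ped, ("score", "anchor")
    )
    d = mdl.samples_.draws
    assert (d["rg"].abs() <= 1).all()
    assert (d["g11"] > 0).all() and (d["g22"] > 0).all()
    assert (d["g11"] * d["g22"] - d["g12"] ** 2 > 0).all()
    assert (d["r11"] > 0).all() and (d["r11"] * d["r22"] - d["r12"] ** 2 > 0).all()
    assert ((d["h2_cat"] > 0) & (d["h2_cat"] < 1)).all()


def test_bivariate_requires_three_categories(small_study):
    ped, recs, _, _ = small_study
    import pandas as pd

    data = recs.data.copy()
    data["bin"] = (data["score"] > 2).astype(int) + 1
    recs2 = pg.RecordSet(
        data.drop(columns=["cg"], errors="ignore"), ordinal_traits={"score": 5, "bin": 2}
    )
    with pytest.raises(ValueError, match=">= 3"):
        pg.BivariateAnimalModel(n_cycles=400, burn_in=200, thin=2).fit(recs2, ped, ("bin", "anchor"))


def test_predict_returns_labeled_ebv(small_study):
    ped, recs, _, _ = small_study
    mdl = pg.LinearAnimalModel(n_cycles=800, burn_in=400, thin=4, seed=0).fit(recs, ped, "anchor")
    ebv = mdl.predict()
    assert len(ebv) == ped.n_animals
    subset = mdl.predict(ped.labels[:5])
    assert list(subset.index) == ped.labels[:5]


def test_unobserved_category_raises(small_study):
    ped, recs, _, _ = small_study
    data = recs.data.copy()
    data.loc[data["score"] == 5, "score"] = 4
    recs2 = pg.RecordSet(data.drop(columns=["cg"], errors="ignore"), ordinal_traits={"score": 5})
    with pytest.raises(ValueError, match="merge"):
        pg.ThresholdAnimalModel(n_cycles=400, burn_in=200, thin=2).fit(recs2, ped, "score")
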