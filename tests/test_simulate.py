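import numpy as np
import pytest
from scipy import stats

from pedgibbs.pedigree import nrm
from pedgibbs.simulate import (
    SimConfig,
    TraitSpec,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_records,
    simulate_study,
)


class TestSimulatePedigree:
    def test_default_size_targets_study(self):
        ped = simulate_pedigree(SimConfig(seed=0))
        assert abs(ped.n_animals - 793) <= 0.1 * 793

    def test_founders_only(self):
        cfg = SimConfig(n_founders=10, n_generations=0, seed=1)
        ped = simulate_pedigree(cfg)
        assert ped.n_animals == 10
        assert ped.is_founder().all()

    @pytest.mark.parametrize("seed", [0, 5])
    def test_output_is_valid_pedigree(self, seed):
        # Pedigree.__post_init__ enforces topological order; check parent sexes
        cfg = SimConfig(n_founders=30, n_generations=3, n_per_generation=40, seed=seed)
        ped = simulate_pedigree(cfg)
        nonf = ~ped.is_founder()
        assert np.all(ped.sex[ped.sire[nonf] - 1] == "M")
        assert np.all(ped.sex[ped.dam[nonf] - 1] == "F")
        assert np.all(ped.sire[nonf] != ped.dam[nonf])  # no selfing

    def test_too_few_founders(self):
        with pytest.raises(ValueError):
            simulate_pedigree(SimConfig(n_founders=1))

    def test_deterministic_under_seed(self):
        a = simulate_pedigree(SimConfig(seed=3))
        b = simulate_pedigree(SimConfig(seed=3))
        assert np.array_equal(a.sire, b.sire) and np.array_equal(a.dam, b.dam)


class TestBreedingValues:
    def test_zero_g0_gives_zero_bvs(self):
        ped = simulate_pedigree(SimConfig(n_founders=20, n_generations=2, n_per_generation=20, seed=2))
        bv = simulate_breeding_values(ped, np.zeros((2, 2)), seed=0)
        assert np.all(bv == 0.0)

    def test_founder_variance_matches_g0(self):
        cfg = SimConfig(n_founders=10_000, n_generations=0, seed=4)
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, [[2.0]], seed=5)
        assert np.var(bv) == pytest.approx(2.0, abs=0.1)

    def test_gene_dropping_tracks_relationship_diagonal(self):
        """Across replicates, per-animal BV variance follows sigma_a2 * diag(A)
        = sigma_a2 * (1 + F), the gene-dropping oracle."""
        trip = [("x", "s", "d"), ("y", "s", "d"), ("o", "x", "y"), ("q", "x", "y"), ("z", "o", "y")]
        from pedgibbs.pedigree import renumber_and_sort

        ped = renumber_and_sort(trip)
        sa2 = 1.0
        reps = np.stack(
            [simulate_breeding_values(ped, [[sa2]], seed=s).ravel() for s in range(4000)]
        )
        emp = reps.var(axis=0)
        expect = sa2 * np.diag(nrm(ped))
        assert np.allclose(emp, expect, rtol=0.1)

    def test_nonpsd_g0_rejected(self):
        ped = simulate_pedigree(SimConfig(n_founders=5, n_generations=0, seed=0))
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_breeding_values(ped, [[1.0, 2.0], [2.0, 1.0]], seed=0)


class TestSimulateRecords:
    def test_default_study_shape(self, default_study):
        ped, recs, bvs, g0 = default_study
        assert recs.n_records == 385
        assert ped.n_animals == 793
        assert recs.ordinal_traits == {"bcs": 5, "mre": 6}
        for trait, k in recs.ordinal_traits.items():
            codes = recs.data[trait]
            assert set(codes.unique()) == set(range(1, k + 1))

    def test_records_pass_validation(self, default_study):
        ped, recs, _, _ = default_study
        recs.validate_against(ped)  # no raise

    def test_binary_symmetric_split(self):
        cfg = SimConfig(
            n_founders=4000,
            n_generations=0,
            n_recorded=4000,
            traits=[TraitSpec("b", h2=0.2, mean=0.0, n_categories=2, thresholds=(0.0,))],
            genetic_corr={},
            fixed_effect_scale=0.0,
            seed=6,
        )
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg.g0(), seed=7)
        recs = simulate_records(ped, bv, cfg)
        share = (recs.data["b"] == 1).mean()
        assert share == pytest.approx(0.5, abs=0.03)

    def test_category_frequencies_match_probit_probabilities(self):
        """With no fixed effects the ordinal codes follow the Phi-difference
        probabilities at liability sd sqrt(1 + sigma_a2)."""
        spec = TraitSpec("s", h2=0.2, mean=1.0, n_categories=5)
        cfg = SimConfig(
            n_founders=4000,
            n_generations=0,
            n_recorded=4000,
            traits=[spec],
            genetic_corr={},
            fixed_effect_scale=0.0,
            seed=8,
        )
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg.g0(), seed=9)
        recs = simulate_records(ped, bv, cfg)
        counts = np.bincount(recs.data["s"], minlength=6)[1:]
        sd = np.sqrt(1.0 + spec.sigma_a2)
        t = np.concatenate([[-np.inf], spec.thresholds, [np.inf]])
        probs = np.diff(stats.norm.cdf((t - spec.mean) / sd))
        chi = stats.chisquare(counts, probs * counts.sum())
        assert chi.pvalue > 1e-3

    def test_empty_category_resample_then_error(self):
        cfg = SimConfig(
            n_founders=60,
            n_generations=0,
            n_recorded=50,
            traits=[TraitSpec("s", h2=0.1, mean=0.0, n_categories=5, thresholds=(0.0, 15.0, 30.0, 45.0))],
            genetic_corr={},
            seed=10,
        )
        ped = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, cfg.g0(), seed=11)
        with pytest.warns(UserWarning, match="resampling"):
            with pytest.raises(ValueError, match="categories"):
                simulate_records(ped, bv, cfg)

    def test_full_determinism(self):
        a = simulate_study(seed=12)
        b = simulate_study(seed=12)
        assert a[1].data.equals(b[1].data)
        assert np.array_equal(a[2], b[2])

    def test_g0_positive_definite_after_assembly(self):
        g0 = SimConfig().g0()
        assert np.linalg.eigvalsh(g0).min() > 0

    def test_trait_spec_validation(self):
        with pytest.raises(ValueError):
            TraitSpec("x", h2=1.5)
        with pytest.raises(ValueError):
            TraitSpec("x", h2=0.3, n_categories=4, thresholds=(0.0, 2.0, 1.0))
        with pytest.raises(ValueError):
            TraitSpec("x", h2=0.3, n_categories=4, thresholds=(0.0,))
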