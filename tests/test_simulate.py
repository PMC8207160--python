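import numpy as np
import pytest

from fluctasym.popgen import observed_heterozygosity
from fluctasym.simulate import (
    GenotypeModel,
    LandmarkModel,
    gen_genotypes,
    gen_habitat_raster,
    gen_landmark_dataset,
    gen_study,
    habitat_fa_scenario,
)


def _noise_free_model(**kw):
    defaults = dict(
        sigma_ind=0.0, sigma_fa=0.0, sigma_image=0.0, sigma_digit=0.0,
        rotation_jitter=0.0, translation_jitter=0.0,
        n_individuals=2, n_images=2, n_digitizings=2, scale=1.0, seed=0,
    )
    defaults.update(kw)
    return LandmarkModel(**defaults)


class TestLandmarkGenerator:
    def test_degenerate_noise_reproduces_the_mean_shape(self):
        model = _noise_free_model()
        ds = gen_landmark_dataset(model)
        for c in ds:
            expected = model.mean_shape.copy()
            if c.side == "right":
                expected = expected * np.array([-1.0, 1.0])
            np.testing.assert_allclose(c.coords, expected, atol=1e-12)

    def test_seed_contract(self):
        model_a = LandmarkModel(n_individuals=3, seed=1)
        model_b = LandmarkModel(n_individuals=3, seed=2)
        a1 = gen_landmark_dataset(model_a).coords_array()
        a2 = gen_landmark_dataset(model_a).coords_array()
        b = gen_landmark_dataset(model_b).coords_array()
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)

    def test_signed_asymmetry_variance_matches_sigma_fa(self):
        # only FA noise: left - mirror(right) equals the drawn asymmetry a_i,
        # whose per-coordinate variance is sigma_fa^2 = 4e-4
        sigma_fa = 0.02
        model = _noise_free_model(sigma_fa=sigma_fa, n_individuals=200, seed=3)
        ds = gen_landmark_dataset(model)
        by_key = {c.key(): c.coords for c in ds}
        asym = []
        for i in range(1, 201):
            spec = f"sp{i:03d}"
            left = by_key[(spec, "left", 1, 1)]
            right = by_key[(spec, "right", 1, 1)] * np.array([-1.0, 1.0])
            asym.append(left - right)
        var = np.asarray(asym).var(axis=0, ddof=1).mean()
        assert var == pytest.approx(sigma_fa**2, rel=0.20)

    def test_validation_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            LandmarkModel(sigma_fa=-0.1)
        with pytest.raises(ValueError):
            LandmarkModel(n_images=0)
        with pytest.raises(ValueError):
            LandmarkModel(mean_shape=np.array([[0, 0], [1, 1], [2, 2]]))  # collinear


class TestGenotypeGenerator:
    def test_no_inbreeding_heterozygosity_near_half(self):
        model = GenotypeModel(
            allele_freqs=[np.array([0.5, 0.5])], inbreeding_f=0.0,
            n_individuals=10_000, seed=0,
        )
        het = observed_heterozygosity(gen_genotypes(model))
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(het.population.iloc[0] - 0.5) < 3 * se

    def test_near_total_inbreeding_gives_homozygotes(self):
        model = GenotypeModel(
            allele_freqs=[np.array([0.5, 0.5])], inbreeding_f=0.999,
            n_individuals=2000, seed=0,
        )
        het = observed_heterozygosity(gen_genotypes(model))
        assert het.population.iloc[0] < 0.01

    def test_expected_heterozygosity_under_inbreeding(self):
        # E[Ho] = (1 - F)(1 - sum p^2) = 0.88 * 0.8 per locus
        F = 0.12
        model = GenotypeModel(
            allele_freqs=[np.full(5, 0.2)] * 7, inbreeding_f=F,
            n_individuals=500, seed=1,
        )
        het = observed_heterozygosity(gen_genotypes(model))
        assert het.population.iloc[0] == pytest.approx((1 - F) * 0.8, abs=0.03)

    def test_frequency_validation(self):
        with pytest.raises(ValueError, match="sum"):
            GenotypeModel(allele_freqs=[np.array([0.5, 0.4])])
        with pytest.raises(ValueError):
            GenotypeModel(allele_freqs=[np.array([0.5, 0.5])], inbreeding_f=1.0)


class TestRasterGenerator:
    def test_extreme_proportions(self):
        assert gen_habitat_raster(1.0, shape=(20, 20)).habitat_fraction() == 1.0
        assert gen_habitat_raster(0.0, shape=(20, 20)).habitat_fraction() == 0.0

    def test_target_fraction_achieved(self):
        r = gen_habitat_raster(0.3, shape=(200, 200), seed=5)
        assert 0.29 <= r.habitat_fraction() <= 0.31

    def test_seed_determinism(self):
        a = gen_habitat_raster(0.4, shape=(50, 50), seed=9).grid
        b = gen_habitat_raster(0.4, shape=(50, 50), seed=9).grid
        np.testing.assert_array_equal(a, b)

    def test_proportion_bounds(self):
        with pytest.raises(ValueError):
            gen_habitat_raster(1.2)


class TestStudyGenerator:
    def test_single_site_bookkeeping(self):
        scen = habitat_fa_scenario(
            habitat_proportions=(0.5,), sample_sizes=(11,), seed=0
        )
        bundle = gen_study(scen)
        # 11 specimens x 2 sides x 2 images x 3 digitizings
        assert len(bundle.landmarks) == 11 * 2 * 2 * 3
        assert bundle.landmarks.k == 10
        assert len(bundle.genotypes) == 11
        assert len(bundle.genotypes.loci) == 7
        assert list(bundle.sites["site_id"]) == ["site1"]
        assert len(bundle.specimens) == 11
        assert set(bundle.specimens["specimen_id"]) == set(
            bundle.genotypes.individuals["individual_id"]
        )

    def test_bundle_is_seed_reproducible(self):
        b1 = gen_study(habitat_fa_scenario(seed=4))
        b2 = gen_study(habitat_fa_scenario(seed=4))
        np.testing.assert_array_equal(
            b1.landmarks.coords_array(), b2.landmarks.coords_array()
        )
        np.testing.assert_array_equal(b1.genotypes.alleles, b2.genotypes.alleles)
        np.testing.assert_array_equal(
            b1.rasters["site1"].grid, b2.rasters["site1"].grid
        )

    def test_sigma_fa_rule_decreases_with_habitat(self):
        scen = habitat_fa_scenario(effect=0.005, sigma_fa_base=0.005)
        sigmas = [s.sigma_fa for s in scen.sites]
        habitats = [s.habitat_proportion for s in scen.sites]
        assert all(
            s2 <= s1 for (s1, s2), (h1, h2) in zip(
                zip(sigmas, sigmas[1:]), zip(habitats, habitats[1:])
            ) if h2 >= h1
        )
        assert scen.sites[-1].sigma_fa == pytest.approx(0.005)
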