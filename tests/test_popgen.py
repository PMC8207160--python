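import numpy as np
import pandas as pd
import pytest

from conftest import make_genotype_table
from fluctasym.popgen import (
    GenotypeTable,
    fis_nei,
    fis_weir_cockerham,
    hwe_exact,
    ld_permutation,
    observed_heterozygosity,
)
from fluctasym.simulate import GenotypeModel, gen_genotypes


class TestObservedHeterozygosity:
    def test_individual_ho_arithmetic(self):
        # one individual heterozygous at 4 of 7 loci
        calls = {f"L{j}": [(101, 103) if j <= 4 else (101, 101)] for j in range(1, 8)}
        het = observed_heterozygosity(make_genotype_table(calls))
        assert het.individual["ho"].iloc[0] == pytest.approx(4 / 7)

    def test_all_homozygous_population(self):
        calls = {"L1": [(101, 101)] * 5, "L2": [(103, 103)] * 5}
        het = observed_heterozygosity(make_genotype_table(calls))
        assert het.population.iloc[0] == 0.0

    def test_missing_loci_do_not_change_individual_ho(self):
        with_missing = make_genotype_table(
            {"L1": [(101, 103)], "L2": [(0, 0)], "L3": [(101, 101)]}
        )
        het = observed_heterozygosity(with_missing)
        assert het.individual["ho"].iloc[0] == pytest.approx(0.5)
        assert het.individual["n_typed"].iloc[0] == 2

    def test_fully_missing_individual_excluded(self):
        t = make_genotype_table({"L1": [(0, 0), (101, 103)]})
        het = observed_heterozygosity(t)
        assert het.excluded == ["i1"]
        assert len(het.individual) == 1

    def test_simulated_half_frequency_locus(self):
        model = GenotypeModel(
            allele_freqs=[np.array([0.5, 0.5])], n_individuals=10_000, seed=2
        )
        het = observed_heterozygosity(gen_genotypes(model))
        assert abs(het.population.iloc[0] - 0.5) < 3 * np.sqrt(0.25 / 10_000)


class TestWeirCockerham:
    def test_all_homozygotes_give_f_one(self):
        calls = {"L1": [(101, 101)] * 5 + [(103, 103)] * 5}
        f = fis_weir_cockerham(make_genotype_table(calls)).loc["p", "fis"]
        assert f == pytest.approx(1.0)

    def test_all_heterozygotes_give_f_minus_one(self):
        calls = {"L1": [(101, 103)] * 10}
        f = fis_weir_cockerham(make_genotype_table(calls)).loc["p", "fis"]
        assert f == pytest.approx(-1.0)

    def test_monomorphic_locus_is_skipped(self):
        calls = {"L1": [(101, 101)] * 4, "L2": [(101, 103), (101, 101), (103, 103), (101, 103)]}
        out = fis_weir_cockerham(make_genotype_table(calls))
        assert np.isnan(out.loc["p", "L1"])
        assert np.isfinite(out.loc["p", "fis"])

    def test_parameter_recovery(self):
        hits = 0
        for seed in range(25):
            model = GenotypeModel(
                allele_freqs=[np.full(5, 0.2)] * 7, inbreeding_f=0.12,
                n_individuals=500, seed=seed,
            )
            f = fis_weir_cockerham(gen_genotypes(model)).loc["pop1", "fis"]
            hits += 0.08 <= f <= 0.16
        assert hits >= 23  # >= 90% of seeds

    def test_bias_shrinks_with_sample_size(self):
        errors = []
        for n in (100, 500, 2000):
            fs = []
            for seed in range(8):
                model = GenotypeModel(
                    allele_freqs=[np.full(4, 0.25)] * 5, inbreeding_f=0.10,
                    n_individuals=n, seed=100 + seed,
                )
                fs.append(fis_weir_cockerham(gen_genotypes(model)).loc["pop1", "fis"])
            errors.append(abs(np.mean(fs) - 0.10))
        assert errors[-1] < 0.02  # consistent at large n

    def test_nei_estimator_agrees_roughly(self):
        model = GenotypeModel(
            allele_freqs=[np.full(5, 0.2)] * 7, inbreeding_f=0.12,
            n_individuals=800, seed=0,
        )
        t = gen_genotypes(model)
        wc = fis_weir_cockerham(t).loc["pop1", "fis"]
        nei = fis_nei(t).loc["pop1", "fis_nei"]
        assert wc == pytest.approx(nei, abs=0.03)


class TestHWE:
    def test_perfect_proportions_give_p_one(self):
        calls = {"L1": [(101, 101)] * 25 + [(101, 103)] * 50 + [(103, 103)] * 25}
        res = hwe_exact(make_genotype_table(calls), "L1")
        assert res.method == "enumeration"
        assert res.p == pytest.approx(1.0)

    def test_total_heterozygote_excess_is_extreme(self):
        calls = {"L1": [(101, 103)] * 20}
        res = hwe_exact(make_genotype_table(calls), "L1")
        assert res.p <= 0.01

    def test_monomorphic_flagged(self):
        res = hwe_exact(make_genotype_table({"L1": [(101, 101)] * 6}), "L1")
        assert res.monomorphic and res.p == 1.0

    @pytest.mark.parametrize("seed_data", [3, 8, 21])
    def test_monte_carlo_agrees_with_enumeration(self, seed_data):
        rng = np.random.default_rng(seed_data)
        calls = {"L1": [tuple(sorted(rng.choice([101, 103, 105], size=2)))
                        for _ in range(25)]}
        t = make_genotype_table(calls)
        exact = hwe_exact(t, "L1", method="enumeration")
        reps = 20000
        mc = hwe_exact(t, "L1", method="mc", reps=reps, seed=1)
        se = np.sqrt(exact.p * (1 - exact.p) / reps)
        assert abs(mc.p - exact.p) < 3 * se + 1.0 / (reps + 1)


class TestLD:
    def test_duplicated_locus_is_maximally_associated(self):
        rng = np.random.default_rng(0)
        pairs = [tuple(sorted(rng.choice([101, 103, 105], size=2))) for _ in range(50)]
        t = make_genotype_table({"L1": pairs, "L2": pairs})
        p = ld_permutation(t, "L1", "L2", n_perm=999, seed=0)
        assert p == pytest.approx(1.0 / 1000.0, abs=5e-3)

    def test_seed_contract(self):
        model = GenotypeModel(
            allele_freqs=[np.full(3, 1 / 3)] * 2, n_individuals=40, seed=5
        )
        t = gen_genotypes(model)
        p1 = ld_permutation(t, "locus_1", "locus_2", n_perm=500, seed=7)
        p2 = ld_permutation(t, "locus_1", "locus_2", n_perm=500, seed=7)
        assert p1 == p2

    def test_insufficient_joint_typing(self):
        t = make_genotype_table({"L1": [(101, 103)] * 4, "L2": [(101, 101)] * 4})
        with pytest.raises(ValueError, match="5 individuals"):
            ld_permutation(t, "L1", "L2")


class TestGenotypeTableIO:
    def test_csv_round_trip(self, tmp_path):
        model = GenotypeModel(
            allele_freqs=[np.full(4, 0.25)] * 3, n_individuals=12, seed=1
        )
        t = gen_genotypes(model)
        t.alleles[2, 1, :] = 0  # a missing call survives the round trip
        t.to_csv(tmp_path / "g.csv")
        back = GenotypeTable.from_csv(tmp_path / "g.csv")
        assert back.loci == t.loci
        np.testing.assert_array_equal(back.alleles, t.alleles)

    def test_half_missing_call_rejected(self):
        ind = pd.DataFrame({"individual_id": ["i1"], "population": ["p"]})
        with pytest.raises(ValueError, match="both"):
            GenotypeTable(ind, ["L1"], np.array([[[101, 0]]]))
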