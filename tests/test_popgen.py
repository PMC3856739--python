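import numpy as np
import pytest

from hybridorigin.datatypes import GenotypeTable
from hybridorigin.popgen import allele_freqs, fst_wc, hwe_test, ld_test
from hybridorigin.synthetic_data import (
    GenealogicalClass,
    draw_parental_freqs,
    simulate_genotypes,
)

from conftest import random_table


def wc_theta_oracle(pop_genotypes: dict[str, list[tuple[int, int]]]) -> float:
    """Independently coded textbook Weir-Cockerham theta for one locus.

    Direct transcription of the two-level diploid ANOVA: per-allele sample
    frequencies p_i, heterozygote frequencies h_i, components a, b, c.
    Written as plain loops so it shares no code with the implementation.
    """
    pops = list(pop_genotypes)
    r = len(pops)
    n_i = [len(pop_genotypes[p]) for p in pops]
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
    alleles = sorted({a for p in pops for g in pop_genotypes[p] for a in g})
    sum_a = sum_abc = 0.0
    for allele in alleles:
        p_i, h_i = [], []
        for p, n in zip(pops, n_i):
            count = sum(g.count(allele) for g in pop_genotypes[p])
            het = sum(
                1 for g in pop_genotypes[p] if allele in g and g[0] != g[1]
            )
            p_i.append(count / (2 * n))
            h_i.append(het / n)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


WORKED_POP_A = [(1, 1), (1, 2), (1, 2), (2, 2)]
WORKED_POP_B = [(2, 2), (2, 2), (1, 2), (2, 2)]


def table_from_pops(pop_genotypes: dict[str, list[list[tuple[int, int]]]],
                    loci=None) -> GenotypeTable:
    inds, pops, rows = [], [], []
    for p, genos in pop_genotypes.items():
        for i, row in enumerate(genos):
            inds.append(f"{p}_{i + 1}")
            pops.append(p)
            rows.append(row)
    n_loci = len(rows[0])
    return GenotypeTable(inds, pops, loci or [f"L{j + 1}" for j in range(n_loci)],
                         np.array(rows))


class TestAlleleFreqs:
    def test_monomorphic_and_direct_count(self):
        t = table_from_pops({"A": [[(1, 1)], [(1, 1)]], "B": [[(1, 2)], [(2, 2)]]})
        assert allele_freqs(t, "A")["L1"] == {1: 1.0}
        assert allele_freqs(t, "B")["L1"] == {1: 0.25, 2: 0.75}

    def test_unknown_population_raises(self, tiny_table):
        with pytest.raises(KeyError):
            allele_freqs(tiny_table, "nope")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_tally(self, seed):
        t = random_table(seed, n_per_pop=8, n_loci=4)
        for pop in t.population_names:
            freqs = allele_freqs(t, pop)
            sub = t.restrict_population(pop)
            for l, locus in enumerate(t.loci):
                tally: dict[int, int] = {}
                total = 0
                for i in range(sub.n_individuals):
                    a1, a2 = sub.genotypes[i, l]
                    if a1 == 0:
                        continue
                    for a in (a1, a2):
                        tally[a] = tally.get(a, 0) + 1
                        total += 1
                expect = {a: c / total for a, c in tally.items()} if total else {}
                assert freqs[locus] == pytest.approx(expect)


class TestFstWeirCockerham:
    def test_worked_biallelic_case_matches_oracle_and_frozen_value(self):
        t = table_from_pops({"A": [[g] for g in WORKED_POP_A],
                             "B": [[g] for g in WORKED_POP_B]})
        oracle = wc_theta_oracle({"A": WORKED_POP_A, "B": WORKED_POP_B})
        r = fst_wc(t, "A", "B")
        assert r.theta_multilocus == pytest.approx(oracle, abs=1e-10)
        assert r.theta_multilocus == pytest.approx(1 / 6, abs=1e-10)

    def test_fixed_difference_gives_theta_one(self):
        t = table_from_pops({"A": [[(1, 1)]] * 5, "B": [[(2, 2)]] * 5})
        assert fst_wc(t, "A", "B").theta_multilocus == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive_theta_and_large_p(self):
        genos = [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)], [(1, 1)]]
        t = table_from_pops({"A": genos, "B": genos})
        r = fst_wc(t, "A", "B", n_perm=199, seed=1)
        assert r.theta_multilocus <= 1e-12
        assert r.p_value > 0.5

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_oracle_on_random_multiallelic_tables(self, seed):
        t = random_table(seed, n_per_pop=10, n_loci=1, missing_rate=0.0)
        pops = {
            p: [tuple(t.restrict_population(p).genotypes[i, 0])
                for i in range(t.restrict_population(p).n_individuals)]
            for p in t.population_names
        }
        assert fst_wc(t, "pop1", "pop2").theta_multilocus == pytest.approx(
            wc_theta_oracle(pops), abs=1e-10
        )

    def test_invariant_to_allele_relabeling_and_locus_order(self):
        t = random_table(11, n_per_pop=10, n_loci=3, missing_rate=0.05)
        base = fst_wc(t, "pop1", "pop2").theta_multilocus
        relabeled = GenotypeTable(
            t.individuals, t.populations, t.loci, (t.genotypes * 7) % 997 + 1
        )
        # relabeling must be injective on observed codes; (x*7)%997+1 is for x<997
        relabeled.genotypes[t.genotypes == 0] = 0
        relabeled = GenotypeTable(t.individuals, t.populations, t.loci,
                                  relabeled.genotypes)
        assert fst_wc(relabeled, "pop1", "pop2").theta_multilocus == pytest.approx(
            base, abs=1e-12
        )
        perm = [2, 0, 1]
        shuffled = GenotypeTable(t.individuals, t.populations,
                                 [t.loci[j] for j in perm], t.genotypes[:, perm])
        assert fst_wc(shuffled, "pop1", "pop2").theta_multilocus == pytest.approx(
            base, abs=1e-12
        )

    def test_multilocus_theta_between_per_locus_extremes(self):
        fr = draw_parental_freqs(5, 8, 0.2, seed=6)
        a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 60, 7, population="A")
        b = simulate_genotypes(fr, GenealogicalClass.PURE_B, 60, 8, population="B")
        r = fst_wc(a.concat(b), "A", "B")
        per_locus = list(r.per_locus_theta.values())
        assert min(per_locus) - 1e-12 <= r.theta_multilocus <= max(per_locus) + 1e-12

    def test_undefined_without_shared_polymorphic_locus(self):
        t = table_from_pops({"A": [[(1, 1)]] * 3, "B": [[(1, 1)]] * 3})
        with pytest.raises(ValueError, match="undefined"):
            fst_wc(t, "A", "B")


class TestHwe:
    def test_maximal_heterozygosity_is_excess_with_small_p(self):
        t = table_from_pops({"P": [[(1, 2)]] * 20})
        r = hwe_test(t, "P", "L1", n_reps=499, seed=1)
        assert r.direction == "excess"
        assert r.p_value < 0.05

    def test_monomorphic_locus_flagged_untestable(self):
        t = table_from_pops({"P": [[(3, 3)]] * 10})
        r = hwe_test(t, "P", "L1", seed=1)
        assert not r.testable and r.p_value is None

    def test_too_few_genotypes_raises(self):
        t = table_from_pops({"P": [[(1, 2)]] * 4})
        with pytest.raises(ValueError, match=">= 5"):
            hwe_test(t, "P", "L1")

    def test_p_values_lie_in_unit_interval_and_smoothed(self):
        fr = draw_parental_freqs(1, 6, 0.0, seed=2)
        t = simulate_genotypes(fr, GenealogicalClass.PURE_A, 40, 3, population="P")
        r = hwe_test(t, "P", "loc1", n_reps=99, seed=4)
        assert 0 < r.p_value <= 1
        assert 0 <= r.obs_het <= 1 and 0 <= r.exp_het <= 1


class TestLd:
    def test_duplicated_locus_is_maximally_significant(self):
        fr = draw_parental_freqs(1, 8, 0.0, seed=5)
        t = simulate_genotypes(fr, GenealogicalClass.PURE_A, 40, 6, population="P")
        dup = GenotypeTable(
            t.individuals, t.populations, ["loc1", "loc2"],
            np.concatenate([t.genotypes, t.genotypes], axis=1),
        )
        r = ld_test(dup, "P", "loc1", "loc2", n_perm=499, seed=7)
        assert r.p_value <= 2 / 500

    def test_too_few_individuals_raises(self):
        t = table_from_pops({"P": [[(1, 2), (3, 4)]] * 4})
        with pytest.raises(ValueError, match=">= 5"):
            ld_test(t, "P", "L1", "L2")

    def test_monomorphic_locus_flagged_untestable(self):
        t = table_from_pops({"P": [[(1, 1), (i % 3 + 1, 3)] for i in range(8)]})
        r = ld_test(t, "P", "L1", "L2", n_perm=99, seed=8)
        assert not r.testable and r.p_value is None
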