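import itertools

import numpy as np
import pytest

from hybridorigin.datatypes import GenotypeTable
from hybridorigin.hybrid_classes import (
    class_genotype_prob,
    classify,
    floored_freqs,
    posterior_frame,
)
from hybridorigin.synthetic_data import (
    CLASS_ORDER,
    GenealogicalClass,
    diagnostic_freqs,
    simulate_genotypes,
)

DIAG_A = {1: 1.0}
DIAG_B = {2: 1.0}


def enumeration_oracle(genotype, fa, fb, cls):
    """P(genotype | class) by exhaustive enumeration of ordered ancestries
    and ordered gene copies — independent of the closed-form kernel."""
    w = dict(zip(["AA", "AB", "BB"], cls.ancestry_weights))
    pools = {"A": fa, "B": fb}
    target = tuple(sorted(genotype))
    total = 0.0
    for anc, w_anc in w.items():
        # ordered ancestry assignments consistent with the unordered pair
        ordered = {"AA": [("A", "A")], "BB": [("B", "B")], "AB": [("A", "B"), ("B", "A")]}
        for pair in ordered[anc]:
            weight = w_anc / len(ordered[anc])
            for x, y in itertools.product(fa.keys() | fb.keys(), repeat=2):
                if tuple(sorted((x, y))) != target:
                    continue
                total += weight * pools[pair[0]].get(x, 0.0) * pools[pair[1]].get(y, 0.0)
    return total


class TestClassGenotypeProb:
    def test_diagnostic_heterozygote_forced_by_class_weights(self):
        assert class_genotype_prob((1, 2), DIAG_A, DIAG_B, GenealogicalClass.F1) == 1.0
        assert class_genotype_prob((1, 2), DIAG_A, DIAG_B, GenealogicalClass.PURE_A) == 0.0

    def test_diagnostic_homozygote_under_f2_is_one_quarter(self):
        assert class_genotype_prob((1, 1), DIAG_A, DIAG_B, GenealogicalClass.F2) == 0.25

    def test_backcross_hand_computation(self):
        fa = {1: 0.7, 2: 0.3}
        fb = {1: 0.2, 2: 0.8}
        # 1/2 * 2*0.7*0.3 + 1/2 * (0.7*0.8 + 0.3*0.2)
        assert class_genotype_prob((1, 2), fa, fb, GenealogicalClass.BC_A) == pytest.approx(0.52)

    @pytest.mark.parametrize("cls", CLASS_ORDER)
    @pytest.mark.parametrize("genotype", [(1, 1), (1, 2), (2, 3), (3, 3)])
    def test_matches_enumeration_oracle(self, cls, genotype):
        fa = {1: 0.5, 2: 0.3, 3: 0.2}
        fb = {1: 0.1, 2: 0.2, 3: 0.7}
        assert class_genotype_prob(genotype, fa, fb, cls) == pytest.approx(
            enumeration_oracle(genotype, fa, fb, cls), abs=1e-12
        )

    @pytest.mark.parametrize("cls", CLASS_ORDER)
    def test_sums_to_one_over_all_genotypes(self, cls):
        fa = {1: 0.6, 2: 0.4}
        fb = {1: 0.25, 2: 0.45, 3: 0.3}
        genotypes = [(x, y) for x in (1, 2, 3) for y in (1, 2, 3) if y >= x]
        total = sum(class_genotype_prob(g, fa, fb, cls) for g in genotypes)
        assert total == pytest.approx(1.0, abs=1e-12)


def single_locus_posterior(genotype):
    """Closed-form posterior with one fully diagnostic locus: the normalized
    ancestry-pair weights consistent with the observed genotype."""
    probs = np.array(
        [class_genotype_prob(genotype, DIAG_A, DIAG_B, c) for c in CLASS_ORDER]
    )
    return probs / probs.sum()


class TestClassify:
    def test_single_diagnostic_locus_closed_form(self):
        expected_het = single_locus_posterior((1, 2))
        # weights with w_AB > 0: F1 (1), F2 (1/2), BC_A (1/2), BC_B (1/2)
        np.testing.assert_allclose(
            expected_het, np.array([0, 0, 1.0, 0.5, 0.5, 0.5]) / 2.5, atol=1e-12
        )
        expected_hom = single_locus_posterior((1, 1))
        # w_AA > 0: PURE_A (1), F2 (1/4), BC_A (1/2)
        np.testing.assert_allclose(
            expected_hom, np.array([1.0, 0, 0, 0.25, 0.5, 0]) / 1.75, atol=1e-12
        )

    def test_parental_individual_with_many_diagnostic_loci(self):
        fr = diagnostic_freqs(15)
        a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 30, 1, population="A")
        b = simulate_genotypes(fr, GenealogicalClass.PURE_B, 30, 2, population="B")
        post = classify(a.subset(np.arange(5)), a, b)
        for p in post:
            assert p.posterior[GenealogicalClass.PURE_A] >= 0.999

    def test_f1_recovery_on_diagnostic_rich_loci(self):
        """Simulated F1s are modally classified F1 in >= 95% of individuals."""
        hits = total = 0
        for s in range(10):
            fr = diagnostic_freqs(7, alleles_per_pool=2)
            a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 40, 100 + s,
                                   population="A")
            b = simulate_genotypes(fr, GenealogicalClass.PURE_B, 24, 200 + s,
                                   population="B")
            f1 = simulate_genotypes(fr, GenealogicalClass.F1, 20, 300 + s,
                                    population="H")
            df = posterior_frame(classify(f1, a, b))
            hits += (df.modal_class == "F1").sum()
            total += len(df)
        assert hits / total >= 0.95

    def test_posteriors_sum_to_one_and_are_locus_order_invariant(self, study_table):
        table, _ = study_table
        hyb = table.restrict_population("pHYB").subset(np.arange(10))
        a = table.restrict_population("histrionica")
        b = table.restrict_population("lehmanni")
        post = classify(hyb, a, b)
        for p in post:
            assert sum(p.posterior.values()) == pytest.approx(1.0, abs=1e-10)
            assert all(0 <= v <= 1 for v in p.posterior.values())
        perm = [3, 1, 6, 0, 2, 5, 4]

        def reorder(t):
            return GenotypeTable(t.individuals, t.populations,
                                 [t.loci[j] for j in perm], t.genotypes[:, perm])

        post2 = classify(reorder(hyb), reorder(a), reorder(b))
        for p1, p2 in zip(post, post2):
            for c in CLASS_ORDER:
                assert p1.posterior[c] == pytest.approx(p2.posterior[c], abs=1e-10)

    def test_swapping_parental_tables_applies_label_involution(self, study_table):
        table, _ = study_table
        hyb = table.restrict_population("pHYB").subset(np.arange(10))
        a = table.restrict_population("histrionica")
        b = table.restrict_population("lehmanni")
        swap = {
            GenealogicalClass.PURE_A: GenealogicalClass.PURE_B,
            GenealogicalClass.PURE_B: GenealogicalClass.PURE_A,
            GenealogicalClass.F1: GenealogicalClass.F1,
            GenealogicalClass.F2: GenealogicalClass.F2,
            GenealogicalClass.BC_A: GenealogicalClass.BC_B,
            GenealogicalClass.BC_B: GenealogicalClass.BC_A,
        }
        post_ab = classify(hyb, a, b)
        post_ba = classify(hyb, b, a)
        for p1, p2 in zip(post_ab, post_ba):
            for c in CLASS_ORDER:
                assert p1.posterior[c] == pytest.approx(
                    p2.posterior[swap[c]], abs=1e-10
                )

    def test_all_missing_individual_gets_prior_with_warning(self):
        fr = diagnostic_freqs(3)
        a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 10, 1, population="A")
        b = simulate_genotypes(fr, GenealogicalClass.PURE_B, 10, 2, population="B")
        ghost = GenotypeTable(["x_1"], ["x"], a.loci, np.zeros((1, 3, 2), dtype=int))
        with pytest.warns(RuntimeWarning, match="no genotyped locus"):
            (p,) = classify(ghost, a, b)
        assert p.all_missing
        for c in CLASS_ORDER:
            assert p.posterior[c] == pytest.approx(1 / 6)

    def test_unseen_allele_floor_keeps_likelihood_finite(self):
        fr = diagnostic_freqs(3)
        a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 10, 1, population="A")
        b = simulate_genotypes(fr, GenealogicalClass.PURE_B, 10, 2, population="B")
        # individual carrying an allele absent from both references
        alien = GenotypeTable(["x_1"], ["x"], a.loci,
                              np.array([[(9, 9), (1, 2), (1, 1)]]))
        (p,) = classify(alien, a, b)
        assert sum(p.posterior.values()) == pytest.approx(1.0, abs=1e-10)

    def test_floored_freqs_sum_to_one(self):
        fr = diagnostic_freqs(2)
        a = simulate_genotypes(fr, GenealogicalClass.PURE_A, 12, 1, population="A")
        registry = [np.array([1, 2, 5]), np.array([1, 2])]
        out = floored_freqs(a, registry)
        for f in out:
            assert sum(f.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v > 0 for v in f.values())

    def test_empty_parental_table_rejected(self, study_table):
        table, _ = study_table
        hyb = table.restrict_population("pHYB")
        empty = GenotypeTable([], [], table.loci,
                              np.zeros((0, table.n_loci, 2), dtype=int))
        with pytest.raises(ValueError, match="non-empty"):
            classify(hyb, empty, table.restrict_population("lehmanni"))
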