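"""Classical population-genetic statistics for multiallelic diploid data.

Implements the Weir-Cockerham variance-components estimator of FST (theta)
with a permutation test permuting whole individuals between populations,
a Monte-Carlo Hardy-Weinberg exact-style probability test, and a genotypic
likelihood-ratio test of linkage disequilibrium with permutation
significance. All permutation p-values use add-one smoothing
(x + 1) / (n + 1), so p lies strictly in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datatypes import GenotypeTable


@dataclass
class FstResult:
    """Multilocus Weir-Cockerham theta with permutation significance.

    The multilocus estimate is the ratio of variance components summed over
    loci and alleles (not the mean of per-locus theta).
    """

    theta_multilocus: float
    per_locus_theta: dict[str, float]
    p_value: float | None
    n_permutations: int


@dataclass
class HweResult:
    locus: str
    population: str
    obs_het: float
    exp_het: float
    p_value: float | None
    direction: str  # "deficit", "excess" or "none"
    n_replicates: int
    testable: bool


@dataclass
class LdResult:
    locus_a: str
    locus_b: str
    g_statistic: float | None
    p_value: float | None
    n_permutations: int
    testable: bool


def allele_freqs(
    table: GenotypeTable, population: str
) -> dict[str, dict[int, float]]:
    """Observed allele frequencies per locus within one population.

    Missing genotypes are excluded locus-wise; a locus with no data maps to
    an empty dict.
    """
    sub = table.restrict_population(population)
    out: dict[str, dict[int, float]] = {}
    for l, locus in enumerate(sub.loci):
        codes = sub.genotypes[:, l, :].ravel()
        codes = codes[codes != 0]
        if codes.size == 0:
            out[locus] = {}
            continue
        vals, counts = np.unique(codes, return_counts=True)
        out[locus] = {
            int(v): float(c) / codes.size for v, c in zip(vals, counts)
        }
    return out


def _locus_arrays(table: GenotypeTable, l: int):
    """Per-individual allele-count and heterozygote-indicator matrices.

    Returns (alleles, counts, het, present): ``counts[i, a]`` is how many
    copies of allele ``a`` individual ``i`` carries at locus ``l`` (0/1/2),
    ``het[i, a]`` is 1 if ``i`` is heterozygous and carries ``a``, and
    ``present[i]`` marks non-missing genotypes.
    """
    g = table.genotypes[:, l, :]
    present = g[:, 0] != 0
    alleles = np.unique(g[present])
    idx = {a: j for j, a in enumerate(alleles)}
    n, A = g.shape[0], len(alleles)
    counts = np.zeros((n, A))
    het = np.zeros((n, A))
    for i in np.flatnonzero(present):
        a1, a2 = g[i]
        counts[i, idx[a1]] += 1
        counts[i, idx[a2]] += 1
        if a1 != a2:
            het[i, idx[a1]] = 1
            het[i, idx[a2]] = 1
    return alleles, counts, het, present


def _wc_components(counts, het, present, assign):
    """Weir-Cockerham per-allele variance components for one locus.

    ``assign`` is a 0/1 vector giving the population of each individual.
    Returns (a, b, c) arrays over alleles (among-population, between-
    individual-within-population, within-individual components).
    """
    r = 2
    comp_a, comp_b, comp_c = [], [], []
    n_i = np.array([np.sum(present & (assign == k)) for k in range(r)], float)
    if (n_i < 1).any():
        raise ValueError("each population needs at least one genotyped individual")
    nbar = n_i.mean()
    if nbar <= 1:
        raise ValueError("Weir-Cockerham theta needs more than one individual per population on average")
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    A = counts.shape[1]
    p_ik = np.zeros((r, A))
    h_ik = np.zeros((r, A))
    for k in range(r):
        sel = present & (assign == k)
        p_ik[k] = counts[sel].sum(axis=0) / (2 * n_i[k])
        h_ik[k] = het[sel].sum(axis=0) / n_i[k]
    pbar = (n_i[:, None] * p_ik).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_ik - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_ik).sum(axis=0) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def _theta_from_locus_data(locus_data, assign):
    """(multilocus theta, per-locus theta list) for a 0/1 assignment vector."""
    tot_a = 0.0
    tot_abc = 0.0
    per_locus = []
    for _, counts, het, present in locus_data:
        a, b, c = _wc_components(counts, het, present, assign)
        sa, sabc = a.sum(), (a + b + c).sum()
        per_locus.append(sa / sabc if sabc != 0 else np.nan)
        tot_a += sa
        tot_abc += sabc
    if tot_abc == 0:
        raise ValueError("theta undefined: no polymorphic locus shared by the populations")
    return tot_a / tot_abc, per_locus


def fst_wc(
    table: GenotypeTable,
    pop_a: str,
    pop_b: str,
    n_perm: int = 0,
    seed: int | np.random.SeedSequence | None = None,
) -> FstResult:
    """Weir-Cockerham theta between two populations, with permutation test.

    Negative variance components are retained (theta may be slightly
    negative), following the estimator's convention. The permutation null
    shuffles whole individuals between the two populations; p is the
    add-one-smoothed proportion of permuted theta >= observed.
    """
    idx_a = table.population_indices(pop_a)
    idx_b = table.population_indices(pop_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both populations need at least 2 individuals")
    sub = table.subset(np.concatenate([idx_a, idx_b]))
    assign = np.array([0] * len(idx_a) + [1] * len(idx_b))
    locus_data = []
    for l in range(sub.n_loci):
        alleles, counts, het, present = _locus_arrays(sub, l)
        if len(alleles) < 2:
            continue  # monomorphic or empty loci carry no information
        if not (present & (assign == 0)).any() or not (present & (assign == 1)).any():
            continue
        locus_data.append((sub.loci[l], counts, het, present))
    if not locus_data:
        raise ValueError("theta undefined: no polymorphic locus shared by the populations")
    theta, per_locus = _theta_from_locus_data(locus_data, assign)
    per_locus_theta = {
        name: t for (name, *_), t in zip(locus_data, per_locus)
    }
    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        perm_assign = assign.copy()
        for _ in range(n_perm):
            rng.shuffle(perm_assign)
            try:
                t_perm, _ = _theta_from_locus_data(locus_data, perm_assign)
            except ValueError:
                continue  # a permutation emptied one population at all loci
            if t_perm >= theta:
                hits += 1
        p_value = (hits + 1) / (n_perm + 1)
    return FstResult(float(theta), per_locus_theta, p_value, n_perm)


def _genotype_log_prob_kernel(het_count: float, geno_counts: np.ndarray) -> float:
    """log of the allele-count-conditional genotype-array probability, up to
    a constant that depends only on the allele counts (shared by all
    rearrangements, so comparable across Monte-Carlo replicates)."""
    return het_count * np.log(2.0) - gammaln(geno_counts + 1.0).sum()


def hwe_test(
    table: GenotypeTable,
    population: str,
    locus: str,
    n_reps: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> HweResult:
    """Monte-Carlo Hardy-Weinberg probability test for one locus/population.

    The statistic is the conditional probability of the observed genotype
    array given the allele counts (Levene's distribution); null replicates
    re-pair the observed allele pool at random, and p is the smoothed
    proportion of replicates with probability <= observed. A monomorphic
    locus is flagged untestable rather than raising.
    """
    sub = table.restrict_population(population)
    l = sub.loci.index(locus)
    g = sub.genotypes[:, l, :]
    g = g[g[:, 0] != 0]
    n = g.shape[0]
    if n < 5:
        raise ValueError(
            f"HWE test needs >= 5 non-missing genotypes at {locus!r}, got {n}"
        )
    pool = g.ravel()
    alleles, allele_counts = np.unique(pool, return_counts=True)
    if len(alleles) < 2:
        return HweResult(locus, population, 0.0, 0.0, None, "none", 0, False)
    freqs = allele_counts / pool.size
    obs_het = float(np.mean(g[:, 0] != g[:, 1]))
    # small-sample-corrected expected (gene diversity)
    exp_het = float((1.0 - (freqs**2).sum()) * (2 * n) / (2 * n - 1))

    idx = np.searchsorted(alleles, g)
    A = len(alleles)
    gid = idx[:, 0] * A + idx[:, 1]  # rows are sorted pairs, so gid is canonical
    obs_counts = np.bincount(gid, minlength=A * A).astype(float)
    obs_stat = _genotype_log_prob_kernel((g[:, 0] != g[:, 1]).sum(), obs_counts)

    rng = np.random.default_rng(seed)
    pool_idx = np.searchsorted(alleles, pool)
    hits = 0
    for _ in range(n_reps):
        perm = rng.permutation(pool_idx)
        pairs = np.sort(perm.reshape(n, 2), axis=1)
        rid = pairs[:, 0] * A + pairs[:, 1]
        rep_counts = np.bincount(rid, minlength=A * A).astype(float)
        rep_stat = _genotype_log_prob_kernel(
            (pairs[:, 0] != pairs[:, 1]).sum(), rep_counts
        )
        if rep_stat <= obs_stat + 1e-12:
            hits += 1
    p = (hits + 1) / (n_reps + 1)
    direction = "deficit" if obs_het < exp_het else "excess" if obs_het > exp_het else "none"
    return HweResult(locus, population, obs_het, exp_het, p, direction, n_reps, True)


def ld_test(
    table: GenotypeTable,
    population: str,
    locus_a: str,
    locus_b: str,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = None,
) -> LdResult:
    """Genotypic likelihood-ratio test of linkage disequilibrium.

    G = 2 [lnL(joint two-locus genotype table) - lnL(independence of the
    single-locus genotype margins)]; significance from permuting one
    locus's genotypes among individuals (margins fixed). Monomorphic loci
    are flagged untestable.
    """
    sub = table.restrict_population(population)
    la, lb = sub.loci.index(locus_a), sub.loci.index(locus_b)
    ga = sub.genotypes[:, la, :]
    gb = sub.genotypes[:, lb, :]
    ok = (ga[:, 0] != 0) & (gb[:, 0] != 0)
    ga, gb = ga[ok], gb[ok]
    n = ga.shape[0]
    if n < 5:
        raise ValueError(
            f"LD test needs >= 5 individuals genotyped at both loci, got {n}"
        )

    def geno_ids(g):
        pairs, ids = np.unique(g, axis=0, return_inverse=True)
        return len(pairs), ids

    ka, ida = geno_ids(ga)
    kb, idb = geno_ids(gb)
    if ka < 2 or kb < 2:
        return LdResult(locus_a, locus_b, None, None, 0, False)

    def g_stat(ida, idb):
        joint = np.bincount(ida * kb + idb, minlength=ka * kb).astype(float)
        ma = np.bincount(ida, minlength=ka).astype(float)
        mb = np.bincount(idb, minlength=kb).astype(float)
        nz = joint > 0
        ll_joint = (joint[nz] * np.log(joint[nz] / n)).sum()
        ll_indep = (ma[ma > 0] * np.log(ma[ma > 0] / n)).sum() + (
            mb[mb > 0] * np.log(mb[mb > 0] / n)
        ).sum()
        return 2.0 * (ll_joint - ll_indep)

    g_obs = g_stat(ida, idb)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if g_stat(ida, rng.permutation(idb)) >= g_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return LdResult(locus_a, locus_b, float(g_obs), p, n_perm, True)
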