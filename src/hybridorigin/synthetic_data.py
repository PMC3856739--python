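"""Synthetic genotype and behavioral data with the structure the analyses assume.

Parental allele frequencies follow the Balding-Nichols construction: an
ancestral frequency vector per locus is drawn from a symmetric Dirichlet,
and each daughter population's vector from a Dirichlet centered on it with
concentration ``(1 - F) / F``, so the single divergence parameter ``F``
maps directly onto the FST scale. Individuals are simulated by drawing,
independently per locus, a diploid ancestry pair (both copies from A, one
from each, both from B) according to their genealogical class, then
sampling each gene copy from the corresponding population's frequencies.

The default study preset emulates the field design this package was built
around: three populations of 40 / 24 / 40 individuals (two parentals and a
putative-hybrid group of F2 ancestry) typed at 7 microsatellite loci with
10-23 alleles each, parental divergence F = 0.11, and 2% missing genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .datatypes import GenotypeTable, PreferenceTrial, PreferenceTrialSet


class GenealogicalClass(Enum):
    """Diploid genealogical categories with expected ancestry-pair proportions.

    Each value is the probability that, at a given locus, the two gene
    copies have ancestries (AA, AB, BB) in the two parental gene pools.
    """

    PURE_A = (1.0, 0.0, 0.0)
    PURE_B = (0.0, 0.0, 1.0)
    F1 = (0.0, 1.0, 0.0)
    F2 = (0.25, 0.5, 0.25)
    BC_A = (0.5, 0.5, 0.0)
    BC_B = (0.0, 0.5, 0.5)

    @property
    def ancestry_weights(self) -> np.ndarray:
        return np.array(self.value)


CLASS_ORDER = [
    GenealogicalClass.PURE_A,
    GenealogicalClass.PURE_B,
    GenealogicalClass.F1,
    GenealogicalClass.F2,
    GenealogicalClass.BC_A,
    GenealogicalClass.BC_B,
]


@dataclass
class ParentalFreqs:
    """Per-locus allele frequencies for two parental populations.

    ``alleles[l]`` is the shared allele-code registry of locus ``l``;
    ``freqs_a[l]`` / ``freqs_b[l]`` the frequency vectors of populations A
    and B over that registry.
    """

    loci: list[str]
    alleles: list[np.ndarray]
    freqs_a: list[np.ndarray]
    freqs_b: list[np.ndarray]
    F: float

    def __post_init__(self) -> None:
        for l, (a, fa, fb) in enumerate(
            zip(self.alleles, self.freqs_a, self.freqs_b)
        ):
            if len(a) != len(fa) or len(a) != len(fb):
                raise ValueError(f"locus {l}: registry and frequency sizes differ")
            for f in (fa, fb):
                if (np.asarray(f) < 0).any() or abs(f.sum() - 1.0) > 1e-12:
                    raise ValueError(
                        f"locus {l}: frequencies must be non-negative and sum to 1"
                    )

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def draw_parental_freqs(
    n_loci: int,
    alleles_per_locus: int | tuple[int, int],
    F: float,
    seed: int | np.random.SeedSequence,
) -> ParentalFreqs:
    """Draw Balding-Nichols parental allele frequencies for two populations.

    Parameters
    ----------
    n_loci
        Number of loci (>= 1).
    alleles_per_locus
        Either a fixed allele count per locus, or an inclusive ``(lo, hi)``
        range from which each locus's count is drawn uniformly.
    F
        Divergence parameter in ``[0, 1)``; ``F = 0`` returns both
        populations equal to the ancestral vector.
    seed
        Seed for all randomness.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if not (0.0 <= F < 1.0):
        raise ValueError(f"F must lie in [0, 1), got {F}")
    rng = np.random.default_rng(seed)
    if isinstance(alleles_per_locus, tuple):
        lo, hi = alleles_per_locus
    else:
        lo = hi = int(alleles_per_locus)
    if lo < 2:
        raise ValueError("alleles_per_locus must be >= 2")

    loci, alleles, freqs_a, freqs_b = [], [], [], []
    for l in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        ancestral = rng.dirichlet(np.ones(k))
        if F == 0.0:
            fa = ancestral.copy()
            fb = ancestral.copy()
        else:
            conc = (1.0 - F) / F
            fa = rng.dirichlet(ancestral * conc)
            fb = rng.dirichlet(ancestral * conc)
            # Dirichlet can return exact zeros at tiny parameters; keep the
            # registry strictly observable-in-principle
            fa = np.maximum(fa, 1e-300)
            fb = np.maximum(fb, 1e-300)
            fa /= fa.sum()
            fb /= fb.sum()
        loci.append(f"loc{l + 1}")
        alleles.append(np.arange(1, k + 1, dtype=np.int64))
        freqs_a.append(fa)
        freqs_b.append(fb)
    return ParentalFreqs(loci, alleles, freqs_a, freqs_b, F)


def diagnostic_freqs(n_loci: int, alleles_per_pool: int = 1) -> ParentalFreqs:
    """Fully diagnostic loci: populations A and B carry disjoint allele sets.

    Useful for forcing deterministic ancestry readout in tests; with one
    allele per pool, allele 1 is the A allele and allele 2 the B allele.
    """
    loci, alleles, freqs_a, freqs_b = [], [], [], []
    k = alleles_per_pool
    for l in range(n_loci):
        registry = np.arange(1, 2 * k + 1, dtype=np.int64)
        fa = np.zeros(2 * k)
        fb = np.zeros(2 * k)
        fa[:k] = 1.0 / k
        fb[k:] = 1.0 / k
        loci.append(f"loc{l + 1}")
        alleles.append(registry)
        freqs_a.append(fa)
        freqs_b.append(fb)
    return ParentalFreqs(loci, alleles, freqs_a, freqs_b, 1.0 - 1e-12)


def simulate_genotypes(
    freqs: ParentalFreqs,
    cls: GenealogicalClass,
    n: int,
    seed: int | np.random.SeedSequence,
    missing_rate: float = 0.0,
    population: str = "sim",
    id_prefix: str | None = None,
) -> GenotypeTable:
    """Simulate ``n`` individuals of one genealogical class.

    For each individual x locus the diploid ancestry pair is drawn from the
    class's (AA, AB, BB) proportions, independently across loci, then each
    gene copy is drawn from the corresponding population's allele
    frequencies. Missingness is applied i.i.d. per genotype.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    prefix = population if id_prefix is None else id_prefix
    L = freqs.n_loci
    w = cls.ancestry_weights
    genotypes = np.zeros((n, L, 2), dtype=np.int64)
    for l in range(L):
        registry = freqs.alleles[l]
        fa, fb = freqs.freqs_a[l], freqs.freqs_b[l]
        pair = rng.choice(3, size=n, p=w)  # 0=AA, 1=AB, 2=BB
        copy_pop = np.empty((n, 2), dtype=np.int64)  # 0=A, 1=B per copy
        copy_pop[pair == 0] = (0, 0)
        copy_pop[pair == 1] = (0, 1)
        copy_pop[pair == 2] = (1, 1)
        for c in range(2):
            is_b = copy_pop[:, c] == 1
            draws_a = registry[rng.choice(len(registry), size=n, p=fa)]
            draws_b = registry[rng.choice(len(registry), size=n, p=fb)]
            genotypes[:, l, c] = np.where(is_b, draws_b, draws_a)
    if missing_rate > 0:
        miss = rng.random((n, L)) < missing_rate
        genotypes[miss] = 0
    individuals = [f"{prefix}_{i + 1:03d}" for i in range(n)]
    return GenotypeTable(individuals, [population] * n, freqs.loci, genotypes)


def inject_null_alleles(
    table: GenotypeTable,
    null_allele: dict[str, int],
    seed: int | np.random.SeedSequence | None = None,
) -> GenotypeTable:
    """Render one allele per locus invisible, mimicking amplification failure.

    Heterozygotes carrying the null allele are miscalled as homozygotes for
    their visible allele; null homozygotes become missing genotypes. Off the
    default simulation path; no correction for the induced heterozygote
    deficit is applied anywhere in this package.
    """
    geno = table.genotypes.copy()
    for locus, allele in null_allele.items():
        l = table.loci.index(locus)
        g = geno[:, l, :]
        both = (g[:, 0] == allele) & (g[:, 1] == allele)
        g[both] = 0
        for c, other in ((0, 1), (1, 0)):
            hit = (g[:, c] == allele) & (g[:, other] != allele) & (g[:, other] != 0)
            g[hit, c] = g[hit, other]
    return GenotypeTable(
        list(table.individuals), list(table.populations), list(table.loci), geno
    )


# study preset: sample sizes and marker properties of the field design
PRESET = {
    "n_loci": 7,
    "alleles_per_locus": (10, 23),
    "F": 0.11,
    "n_parental_a": 40,
    "n_parental_b": 24,
    "n_hybrid": 40,
    "missing_rate": 0.02,
    "pop_a": "histrionica",
    "pop_b": "lehmanni",
    "pop_hybrid": "pHYB",
    "hybrid_class": GenealogicalClass.F2,
}


def simulate_study(
    seed: int | np.random.SeedSequence,
    F: float | None = None,
    n_hybrid: int | None = None,
    missing_rate: float | None = None,
    hybrid_class: GenealogicalClass | None = None,
) -> tuple[GenotypeTable, ParentalFreqs]:
    """Simulate the full three-population study dataset under the preset.

    Returns the combined 104-individual (default) table — parental A,
    parental B, then the putative-hybrid group — together with the true
    parental frequencies used, for oracle checks.
    """
    p = dict(PRESET)
    if F is not None:
        p["F"] = F
    if n_hybrid is not None:
        p["n_hybrid"] = n_hybrid
    if missing_rate is not None:
        p["missing_rate"] = missing_rate
    if hybrid_class is not None:
        p["hybrid_class"] = hybrid_class
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_freq, s_a, s_b, s_h = ss.spawn(4)
    freqs = draw_parental_freqs(p["n_loci"], p["alleles_per_locus"], p["F"], s_freq)
    tab_a = simulate_genotypes(
        freqs, GenealogicalClass.PURE_A, p["n_parental_a"], s_a,
        missing_rate=p["missing_rate"], population=p["pop_a"],
    )
    tab_b = simulate_genotypes(
        freqs, GenealogicalClass.PURE_B, p["n_parental_b"], s_b,
        missing_rate=p["missing_rate"], population=p["pop_b"],
    )
    tab_h = simulate_genotypes(
        freqs, p["hybrid_class"], p["n_hybrid"], s_h,
        missing_rate=p["missing_rate"], population=p["pop_hybrid"],
    )
    return tab_a.concat(tab_b).concat(tab_h), freqs


def simulate_trials(
    P_true: float,
    n_females: int,
    total_time: float,
    concentration: float,
    seed: int | np.random.SeedSequence,
    female_pop: str = "pHYB",
    combination: str = "focal_vs_other",
) -> PreferenceTrialSet:
    """Simulate two-choice preference trials.

    Each female's share of time with the focal male is drawn from a Beta
    distribution with mean ``P_true`` and the given concentration (alpha +
    beta), capturing between-female overdispersion; her times are then
    ``m = share * total_time`` and ``n = (1 - share) * total_time``.
    The default concentration used by the study preset (8) reproduces a
    spread of roughly 0.12-0.13 SD in time share across females.
    """
    if not (0.0 <= P_true <= 1.0):
        raise ValueError(f"P_true must lie in [0, 1], got {P_true}")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    rng = np.random.default_rng(seed)
    if P_true == 0.0:
        shares = np.zeros(n_females)
    elif P_true == 1.0:
        shares = np.ones(n_females)
    else:
        a = P_true * concentration
        b = (1.0 - P_true) * concentration
        shares = rng.beta(a, b, size=n_females)
        # guard degenerate draws that would zero out a whole trial
        shares = np.clip(shares, 1e-12, 1.0 - 1e-12)
    trials = [
        PreferenceTrial(
            female_id=f"{female_pop}_f{i + 1}",
            female_pop=female_pop,
            combination=combination,
            m=float(s * total_time),
            n=float((1.0 - s) * total_time),
        )
        for i, s in enumerate(shares)
    ]
    return PreferenceTrialSet(trials)


# behavioral preset: 7 females per group, 50-minute trials in seconds,
# concentration 8 reproduces the observed between-female spread in shares
TRIAL_PRESET = {"n_females": 7, "total_time": 3000.0, "concentration": 8.0}


def simulate_trial_study(seed: int | np.random.SeedSequence) -> PreferenceTrialSet:
    """Three experimental groups mirroring the two-choice design.

    P is always the share of time with the focal (homotypic) male:
    hybrid females vs a parental-B male prefer the heterotypic male
    (P = 0.15); hybrid females vs a parental-A male prefer their own
    (P = 0.74); parental-B females vs a hybrid male prefer their own
    (P = 0.85).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s1, s2, s3 = ss.spawn(3)
    p = TRIAL_PRESET
    g1 = simulate_trials(
        0.15, p["n_females"], p["total_time"], p["concentration"], s1,
        female_pop="pHYB", combination="pHYB_vs_lehmanni",
    )
    g2 = simulate_trials(
        0.74, p["n_females"], p["total_time"], p["concentration"], s2,
        female_pop="pHYB", combination="pHYB_vs_histrionica",
    )
    g3 = simulate_trials(
        0.85, p["n_females"], p["total_time"], p["concentration"], s3,
        female_pop="lehmanni", combination="lehmanni_vs_pHYB",
    )
    return PreferenceTrialSet(g1.trials + g2.trials + g3.trials)
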