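"""Core in-memory containers shared by all analysis stages.

Genotypes are unordered diploid pairs of positive integer allele codes;
``0`` marks a missing gene copy, and a genotype is missing only when both
copies are 0 (half-missing genotypes are rejected at construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 0


@dataclass
class GenotypeTable:
    """Individuals x loci diploid multiallelic genotypes with population labels.

    Parameters
    ----------
    individuals
        Individual identifiers, one per row.
    populations
        Population label per individual; labels partition the rows.
    loci
        Locus names, one per genotype column.
    genotypes
        Integer array of shape ``(n_individuals, n_loci, 2)``. Allele codes
        are positive integers; ``(0, 0)`` is a missing genotype.
    """

    individuals: list[str]
    populations: list[str]
    loci: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        n, L = len(self.individuals), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("populations must have one label per individual")
        if self.genotypes.shape != (n, L, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L}, 2)"
            )
        if (self.genotypes < 0).any():
            raise ValueError("allele codes must be non-negative integers")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"half-missing genotype for individual {self.individuals[i]!r} "
                f"at locus {self.loci[l]!r}: one allele code is 0"
            )
        # canonical order within the unordered pair, so equality is well defined
        self.genotypes = np.sort(self.genotypes, axis=2)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) array, True where genotype is missing."""
        return self.genotypes[:, :, 0] == MISSING

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.array(
            [i for i, p in enumerate(self.populations) if p == population],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise KeyError(f"unknown population label {population!r}")
        return idx

    def subset(self, indices: np.ndarray) -> "GenotypeTable":
        indices = np.asarray(indices, dtype=np.intp)
        return GenotypeTable(
            individuals=[self.individuals[i] for i in indices],
            populations=[self.populations[i] for i in indices],
            loci=list(self.loci),
            genotypes=self.genotypes[indices].copy(),
        )

    def restrict_population(self, population: str) -> "GenotypeTable":
        return self.subset(self.population_indices(population))

    def concat(self, other: "GenotypeTable") -> "GenotypeTable":
        if self.loci != other.loci:
            raise ValueError("cannot concatenate tables with different loci")
        return GenotypeTable(
            individuals=self.individuals + other.individuals,
            populations=self.populations + other.populations,
            loci=list(self.loci),
            genotypes=np.concatenate([self.genotypes, other.genotypes]),
        )

    def alleles_at(self, locus_index: int) -> np.ndarray:
        """Sorted distinct observed allele codes at one locus (missing excluded)."""
        codes = self.genotypes[:, locus_index, :].ravel()
        return np.unique(codes[codes != MISSING])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class PreferenceTrial:
    """One two-choice trial: time with the focal male (m) vs the other (n)."""

    female_id: str
    female_pop: str
    combination: str
    m: float
    n: float

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0:
            raise ValueError(
                f"negative time in trial for female {self.female_id!r}"
            )
        if self.m + self.n <= 0:
            raise ValueError(
                f"trial for female {self.female_id!r} has m + n = 0; "
                "every trial needs positive total interaction time"
            )


@dataclass
class PreferenceTrialSet:
    """Collection of two-choice preference trials.

    ``m`` and ``n`` are the times a female spent in the interaction zone of
    the focal (homotypic) and alternative male. Units are whatever the input
    used (seconds by convention); the likelihood is unit-invariant for the
    preference estimate but G statistics scale with the unit.
    """

    trials: list[PreferenceTrial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def combinations(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.combination)
        return list(seen)

    def female_populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.female_pop)
        return list(seen)

    def for_combination(self, combination: str) -> "PreferenceTrialSet":
        return PreferenceTrialSet(
            [t for t in self.trials if t.combination == combination]
        )

    def for_population(self, female_pop: str) -> "PreferenceTrialSet":
        return PreferenceTrialSet(
            [t for t in self.trials if t.female_pop == female_pop]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "female_id": [t.female_id for t in self.trials],
                "female_pop": [t.female_pop for t in self.trials],
                "combination": [t.combination for t in self.trials],
                "m": [t.m for t in self.trials],
                "n": [t.n for t in self.trials],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PreferenceTrialSet):
            return NotImplemented
        return self.trials == other.trials
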