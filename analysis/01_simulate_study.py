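"""Simulate the study dataset: two parental populations and a putative hybrid.

Writes a GENEPOP file (40 + 24 individuals from the two parental gene pools
and 40 individuals of F2 ancestry, 7 microsatellite loci, divergence
F = 0.11, 2% missing genotypes) plus the two-choice behavioral trials
(3 groups x 7 females, 50-minute trials in seconds) under results/data/.
"""

import sys
from pathlib import Path

from hybridorigin import simulate_study, simulate_trial_study, write_genepop, write_trials

SEED = 20130809  # fixed master seed for the whole analysis
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table, freqs = simulate_study(SEED)
    trials = simulate_trial_study(SEED + 1)
    write_genepop(table, OUT / "genotypes.gen")
    write_trials(trials, OUT / "trials.csv")
    n_alleles = [len(a) for a in freqs.alleles]
    print(f"simulated {table.n_individuals} individuals x {table.n_loci} loci "
          f"({min(n_alleles)}-{max(n_alleles)} alleles/locus, F = {freqs.F})")
    print(f"populations: {table.population_names}")
    print(f"trials: {len(trials)} across {trials.combinations()}")
    print(f"wrote {OUT / 'genotypes.gen'} and {OUT / 'trials.csv'}")


if __name__ == "__main__":
    sys.exit(main())
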