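"""hybridorigin: hybrid-origin inference for multiallelic genotype data.

Tools for testing whether a population is of hybrid origin: GENEPOP I/O,
synthetic-data generation for the study design, Weir-Cockerham FST with
permutation tests, Hardy-Weinberg and linkage-disequilibrium tests,
EM admixture clustering with Evanno delta-K model selection, genealogical-
class (pure/F1/F2/backcross) posteriors, correspondence-analysis
ordination, and a maximum-likelihood model of two-choice mate preference.
"""

__version__ = "0.1.0"

from .datatypes import GenotypeTable, PreferenceTrial, PreferenceTrialSet
from .io_formats import read_genepop, read_trials, write_genepop, write_trials
from .synthetic_data import (
    GenealogicalClass,
    ParentalFreqs,
    draw_parental_freqs,
    simulate_genotypes,
    simulate_study,
    simulate_trial_study,
    simulate_trials,
)
from .popgen import allele_freqs, fst_wc, hwe_test, ld_test
from .admixture import fit_admixture, select_K
from .hybrid_classes import class_genotype_prob, classify, posterior_frame
from .fca import fca, fca_of_table, genotype_indicator_matrix
from .mate_choice import (
    fit_preference,
    lrt_combination,
    lrt_homotypic,
    support_limits,
)
from .pipeline import AnalysisConfig, AnalysisReport, run_pipeline

__all__ = [
    "GenotypeTable",
    "PreferenceTrial",
    "PreferenceTrialSet",
    "read_genepop",
    "write_genepop",
    "read_trials",
    "write_trials",
    "GenealogicalClass",
    "ParentalFreqs",
    "draw_parental_freqs",
    "simulate_genotypes",
    "simulate_trials",
    "simulate_study",
    "simulate_trial_study",
    "allele_freqs",
    "fst_wc",
    "hwe_test",
    "ld_test",
    "fit_admixture",
    "select_K",
    "class_genotype_prob",
    "classify",
    "posterior_frame",
    "fca",
    "fca_of_table",
    "genotype_indicator_matrix",
    "fit_preference",
    "support_limits",
    "lrt_homotypic",
    "lrt_combination",
    "AnalysisConfig",
    "AnalysisReport",
    "run_pipeline",
]
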