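"""Posterior classification into six genealogical classes.

Given allele frequencies of two parental gene pools, each diploid genotype
has probability under a genealogical class (pure A, pure B, F1, F2, first-
generation backcross to A or B) obtained by mixing the three ordered-copy
ancestry configurations (AA, AB, BB) with the class's expected proportions.
Individuals are scored by summing log-probabilities over their non-missing
loci (loci treated as unlinked) and combining with a prior over classes.

Parental frequencies are plugged in from labeled parental reference
samples, with a small floor for alleles unseen in a reference sample, so
the classifier is deterministic given the data — a maximum-likelihood
surrogate for MCMC genealogical-class programs that integrate over the
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable
from .synthetic_data import CLASS_ORDER, GenealogicalClass


@dataclass
class HybridClassPosterior:
    individual: str
    posterior: dict[GenealogicalClass, float]
    per_locus_loglik: pd.DataFrame  # loci x classes diagnostic matrix
    all_missing: bool = False

    @property
    def modal_class(self) -> GenealogicalClass:
        return max(self.posterior, key=self.posterior.get)


def class_genotype_prob(
    genotype: tuple[int, int],
    freqs_a: dict[int, float],
    freqs_b: dict[int, float],
    cls: GenealogicalClass,
) -> float:
    """P(unordered genotype | class) at one locus.

    For copy-ancestry (X, Y) with frequency vectors f and h, the unordered
    genotype (x, y) has probability f(x) h(y) + f(y) h(x) when x != y and
    f(x) h(x) otherwise; the class probability mixes the three ancestry
    configurations with the class's (AA, AB, BB) weights.
    """
    x, y = genotype
    w_aa, w_ab, w_bb = cls.ancestry_weights

    def g(f: dict[int, float], h: dict[int, float]) -> float:
        fx, fy = f.get(x, 0.0), f.get(y, 0.0)
        hx, hy = h.get(x, 0.0), h.get(y, 0.0)
        if x == y:
            return fx * hx
        return fx * hy + fy * hx

    return (
        w_aa * g(freqs_a, freqs_a)
        + w_ab * g(freqs_a, freqs_b)
        + w_bb * g(freqs_b, freqs_b)
    )


def floored_freqs(
    reference: GenotypeTable,
    registry: list[np.ndarray],
    freq_floor: float | None = None,
) -> list[dict[int, float]]:
    """Allele frequencies from a reference sample with an unseen-allele floor.

    Every allele in the union registry that the reference sample did not
    observe at a locus gets frequency ``freq_floor`` (default
    1 / (2 n_l + 1), where n_l is the number of genotyped reference
    individuals at that locus); observed frequencies are rescaled so the
    vector still sums to 1.
    """
    out = []
    for l in range(reference.n_loci):
        codes = reference.genotypes[:, l, :]
        codes = codes[codes[:, 0] != 0]
        n_l = codes.shape[0]
        obs: dict[int, float] = {}
        if n_l > 0:
            vals, counts = np.unique(codes.ravel(), return_counts=True)
            obs = {int(v): c / (2 * n_l) for v, c in zip(vals, counts)}
        floor = 1.0 / (2 * n_l + 1) if freq_floor is None else freq_floor
        unseen = [int(a) for a in registry[l] if int(a) not in obs]
        total_floor = floor * len(unseen)
        scale = max(1.0 - total_floor, 1e-12)
        f = {a: p * scale for a, p in obs.items()}
        f.update({a: floor for a in unseen})
        if not f:
            # no reference data at this locus: uniform over the registry
            f = {int(a): 1.0 / len(registry[l]) for a in registry[l]}
        out.append(f)
    return out


def classify(
    table: GenotypeTable,
    parental_a: GenotypeTable,
    parental_b: GenotypeTable,
    prior: dict[GenealogicalClass, float] | None = None,
    freq_floor: float | None = None,
) -> list[HybridClassPosterior]:
    """Six-class posteriors for every individual in ``table``.

    Parental allele frequencies are estimated from the two reference
    tables over the union allele registry of all three tables, with the
    unseen-allele floor of :func:`floored_freqs`. An individual with all
    loci missing receives the prior back as its posterior, with a warning.
    """
    if parental_a.n_individuals == 0 or parental_b.n_individuals == 0:
        raise ValueError("parental reference tables must be non-empty")
    if table.loci != parental_a.loci or table.loci != parental_b.loci:
        raise ValueError("all tables must share the same loci in the same order")
    if prior is None:
        prior = {c: 1.0 / len(CLASS_ORDER) for c in CLASS_ORDER}
    pvec = np.array([prior[c] for c in CLASS_ORDER])
    if abs(pvec.sum() - 1.0) > 1e-9 or (pvec < 0).any():
        raise ValueError("prior must be a probability vector over the six classes")

    registry = [
        np.unique(
            np.concatenate(
                [t.alleles_at(l) for t in (table, parental_a, parental_b)]
            )
        )
        for l in range(table.n_loci)
    ]
    fa = floored_freqs(parental_a, registry, freq_floor)
    fb = floored_freqs(parental_b, registry, freq_floor)

    results = []
    for i, ind in enumerate(table.individuals):
        rows = []
        for l, locus in enumerate(table.loci):
            g = table.genotypes[i, l]
            if g[0] == 0:
                rows.append([np.nan] * len(CLASS_ORDER))
                continue
            rows.append(
                [
                    np.log(
                        max(
                            class_genotype_prob(tuple(g), fa[l], fb[l], c),
                            1e-300,
                        )
                    )
                    for c in CLASS_ORDER
                ]
            )
        mat = pd.DataFrame(
            rows, index=table.loci, columns=[c.name for c in CLASS_ORDER]
        )
        ll = np.nansum(mat.to_numpy(), axis=0)
        all_missing = bool(np.all(np.isnan(mat.to_numpy())))
        if all_missing:
            warn(
                f"individual {ind!r} has no genotyped locus; posterior equals the prior",
                RuntimeWarning,
                stacklevel=2,
            )
            post = pvec.copy()
        else:
            logpost = ll + np.log(np.maximum(pvec, 1e-300))
            logpost -= logpost.max()
            post = np.exp(logpost)
            post /= post.sum()
        results.append(
            HybridClassPosterior(
                individual=ind,
                posterior={c: float(p) for c, p in zip(CLASS_ORDER, post)},
                per_locus_loglik=mat,
                all_missing=all_missing,
            )
        )
    return results


def posterior_frame(posteriors: list[HybridClassPosterior]) -> pd.DataFrame:
    """Tidy individuals x classes posterior table."""
    return pd.DataFrame(
        [
            {"individual": p.individual}
            | {c.name: p.posterior[c] for c in CLASS_ORDER}
            | {"modal_class": p.modal_class.name}
            for p in posteriors
        ]
    )
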