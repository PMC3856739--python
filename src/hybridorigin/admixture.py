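"""Maximum-likelihood admixture clustering of multiallelic genotypes.

The model: each individual i carries ancestry proportions q_i over K
clusters; every gene copy independently picks a cluster with probability
q_ik and then an allele from that cluster's frequency vector at its locus.
Parameters (Q and the cluster frequencies) are fit by EM from seeded random
starts; missing genotypes contribute nothing to the likelihood.

This is a deterministic maximum-likelihood surrogate for Bayesian MCMC
admixture programs: the downstream Evanno delta-K model selection consumes
only log-likelihoods, for which the independent-frequency EM fit is an
adequate stand-in at the divergence levels this package targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeTable


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_individuals, K), rows sum to 1
    cluster_freqs: list[np.ndarray]  # per locus: (K, n_alleles_at_locus)
    alleles: list[np.ndarray]  # per locus allele registry matching cluster_freqs
    loglik: float
    loglik_path: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class DeltaKTable:
    """Evanno model-selection table over a range of K.

    ``delta_k`` is |L(K+1) - 2 L(K) + L(K-1)| / SD(K), defined only for
    interior K; ``chosen_k`` is the interior argmax (ties toward smaller K).
    ``no_strong_structure`` flags datasets where the delta-K peak does not
    dominate the remaining values (max < 2x their median), since the
    criterion cannot evaluate K = 1 directly.
    """

    table: pd.DataFrame  # columns: K, mean_loglik, sd_loglik, delta_k
    chosen_k: int
    no_strong_structure: bool
    fits: dict[int, list[AdmixtureFit]] = field(default_factory=dict, repr=False)


def _copy_arrays(table: GenotypeTable):
    """Flatten non-missing gene copies to (individual, locus, allele-index) arrays."""
    inds, locs, als = [], [], []
    registries = [table.alleles_at(l) for l in range(table.n_loci)]
    for l in range(table.n_loci):
        g = table.genotypes[:, l, :]
        present = g[:, 0] != 0
        reg = registries[l]
        for c in range(2):
            ii = np.flatnonzero(present)
            inds.append(ii)
            locs.append(np.full(ii.size, l))
            als.append(np.searchsorted(reg, g[ii, c]))
    return (
        np.concatenate(inds),
        np.concatenate(locs),
        np.concatenate(als),
        registries,
    )


def fit_admixture(
    table: GenotypeTable,
    K: int,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> AdmixtureFit:
    """EM fit of the K-cluster admixture model from one seeded random start.

    The log-likelihood is non-decreasing across iterations (an EM
    guarantee, asserted in the test suite); convergence is declared when
    the per-iteration gain drops below ``tol``.
    """
    n = table.n_individuals
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K = {K} exceeds the number of individuals ({n})")
    ind, loc, al, registries = _copy_arrays(table)
    L = table.n_loci
    n_copies = ind.size
    if n_copies == 0:
        raise ValueError("table has no non-missing genotypes")
    rng = np.random.default_rng(seed)

    Q = rng.dirichlet(np.ones(K), size=n)  # (n, K)
    # initial M-step from the random Q as soft assignment of every copy
    freqs = []
    for l in range(L):
        A = len(registries[l])
        f = np.full((K, A), 1.0 / A)
        freqs.append(f)

    # per-copy column index into a per-locus stacked allele axis for fast
    # gather: flat_freq[k, offset[l] + a]
    offsets = np.concatenate([[0], np.cumsum([len(r) for r in registries])])
    col = offsets[loc] + al
    n_cols = offsets[-1]
    flat_f = np.full((K, n_cols), 0.0)
    for l in range(L):
        flat_f[:, offsets[l]:offsets[l + 1]] = freqs[l]

    copies_per_ind = np.bincount(ind, minlength=n).astype(float)
    loglik_path = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities of clusters for every gene copy
        w = Q[ind].T * flat_f[:, col]  # (K, n_copies)
        tot = w.sum(axis=0)
        tot = np.maximum(tot, 1e-300)
        ll = float(np.log(tot).sum())
        loglik_path.append(ll)
        resp = w / tot  # (K, n_copies)
        # M-step
        Qnum = np.zeros((n, K))
        for k in range(K):
            Qnum[:, k] = np.bincount(ind, weights=resp[k], minlength=n)
        Q = Qnum / np.maximum(copies_per_ind, 1.0)[:, None]
        Q = np.maximum(Q, 1e-300)
        Q /= Q.sum(axis=1, keepdims=True)
        for k in range(K):
            fk = np.bincount(col, weights=resp[k], minlength=n_cols)
            for l in range(L):
                seg = fk[offsets[l]:offsets[l + 1]]
                s = seg.sum()
                flat_f[k, offsets[l]:offsets[l + 1]] = (
                    seg / s if s > 0 else 1.0 / len(seg)
                )
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll

    freqs = [flat_f[:, offsets[l]:offsets[l + 1]].copy() for l in range(L)]
    return AdmixtureFit(
        K=K,
        Q=Q,
        cluster_freqs=freqs,
        alleles=registries,
        loglik=loglik_path[-1],
        loglik_path=np.array(loglik_path),
        n_iter=it,
        converged=converged,
    )


def admixture_loglik(
    table: GenotypeTable, Q: np.ndarray, cluster_freqs: list[np.ndarray]
) -> float:
    """Log-likelihood of given parameters (used for label-switching checks)."""
    ind, loc, al, registries = _copy_arrays(table)
    offsets = np.concatenate([[0], np.cumsum([len(r) for r in registries])])
    flat_f = np.concatenate(cluster_freqs, axis=1)
    col = offsets[loc] + al
    w = (Q[ind].T * flat_f[:, col]).sum(axis=0)
    return float(np.log(np.maximum(w, 1e-300)).sum())


def select_K(
    table: GenotypeTable,
    K_min: int,
    K_max: int,
    n_replicates: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    keep_fits: bool = False,
) -> DeltaKTable:
    """Evanno delta-K model selection over K in [K_min, K_max].

    Fits ``n_replicates`` seeded random starts per K, pools the replicate
    log-likelihoods into mean and SD, and computes
    delta-K(K) = |L(K+1) - 2 L(K) + L(K-1)| / SD(K) for interior K.
    A replicate SD of zero yields delta-K = +inf (with a warning), which
    still compares under argmax. Ties break toward smaller K.
    """
    if K_max < K_min + 2:
        raise ValueError("K_max must be >= K_min + 2 so delta-K has interior points")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2 to estimate an SD")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ks = list(range(K_min, K_max + 1))
    child_seeds = ss.spawn(len(ks) * n_replicates)
    mean_ll, sd_ll = {}, {}
    fits: dict[int, list[AdmixtureFit]] = {}
    for j, K in enumerate(ks):
        reps = [
            fit_admixture(
                table, K, seed=child_seeds[j * n_replicates + r],
                max_iter=max_iter, tol=tol,
            )
            for r in range(n_replicates)
        ]
        lls = np.array([f.loglik for f in reps])
        mean_ll[K] = lls.mean()
        sd_ll[K] = lls.std(ddof=1)
        if keep_fits:
            fits[K] = reps
        else:
            fits[K] = [reps[int(np.argmax(lls))]]  # keep the best replicate
    delta = {}
    for K in ks[1:-1]:
        second_diff = mean_ll[K + 1] - 2 * mean_ll[K] + mean_ll[K - 1]
        if sd_ll[K] < 1e-12:
            warnings.warn(
                f"replicate log-likelihoods at K={K} have zero SD; delta-K is +inf",
                RuntimeWarning,
                stacklevel=2,
            )
            delta[K] = np.inf
        else:
            delta[K] = abs(second_diff) / sd_ll[K]
    dvals = np.array([delta[K] for K in ks[1:-1]])
    chosen = ks[1:-1][int(np.argmax(dvals))]  # argmax takes first max: ties -> smaller K
    others = np.delete(dvals, int(np.argmax(dvals)))
    if others.size == 0 or not np.isfinite(np.max(dvals)):
        no_structure = False
    else:
        # the peak must dominate the remaining delta-K values to count as structure
        no_structure = bool(np.max(dvals) < 2.0 * np.median(others))
    table_df = pd.DataFrame(
        {
            "K": ks,
            "mean_loglik": [mean_ll[K] for K in ks],
            "sd_loglik": [sd_ll[K] for K in ks],
            "delta_k": [delta.get(K, np.nan) for K in ks],
        }
    )
    return DeltaKTable(table_df, chosen, no_structure, fits)
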