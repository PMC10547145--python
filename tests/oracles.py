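"""Independent oracles used to cross-check the implementation.

Each oracle computes the same quantity as a production routine by a
different route: gene-dropping Monte Carlo for pedigree kinship, a dense
generic multivariate-normal density for the likelihoods, Henderson's
mixed-model equations for BLUP, and the raw normal equations for OLS
residuals.  They deliberately share no code with the package internals
beyond data containers.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from famgxe.pedigree import Pedigree


def gene_drop_kinship(ped: Pedigree, n_loci: int, seed: int) -> np.ndarray:
    """Monte-Carlo estimate of K = 2Φ by dropping founder alleles.

    Each founder receives two unique alleles per locus; every offspring
    inherits one random parental allele from each parent.  The kinship
    coefficient is estimated as the probability that one random allele
    from each individual is identical by descent, averaged over loci.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    pat = np.zeros((n, n_loci), dtype=np.int32)
    mat = np.zeros((n, n_loci), dtype=np.int32)
    next_allele = 0
    for i in ped._topo:
        ind = ped.individuals[i]
        if ind.father_id is None:
            pat[i] = next_allele
            next_allele += 1
        else:
            f = ped.index_of(ind.father_id)
            pick = rng.integers(0, 2, n_loci, dtype=np.int32)
            pat[i] = np.where(pick == 0, pat[f], mat[f])
        if ind.mother_id is None:
            mat[i] = next_allele
            next_allele += 1
        else:
            m = ped.index_of(ind.mother_id)
            pick = rng.integers(0, 2, n_loci, dtype=np.int32)
            mat[i] = np.where(pick == 0, pat[m], mat[m])
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            share = (
                (pat[i] == pat[j]).mean()
                + (pat[i] == mat[j]).mean()
                + (mat[i] == pat[j]).mean()
                + (mat[i] == mat[j]).mean()
            )
            # phi = E[share]/4; K = 2 phi
            k[i, j] = k[j, i] = share / 2.0
    return k


def dense_mvn_loglik(y, mean, sigma) -> float:
    """Generic dense multivariate-normal log-density via scipy."""
    return float(
        stats.multivariate_normal(mean=mean, cov=sigma, allow_singular=False)
        .logpdf(y)
    )


def henderson_blup(y, X, K, sigma_g2, sigma_e2):
    """Genetic-effect solution of Henderson's mixed-model equations.

    Solves [X'X/σe²  X'/σe²; X/σe²  I/σe² + (Kσg²)⁻¹][β; u] = [X'y/σe²; y/σe²]
    with Z = I, and returns (β, u).
    """
    n, p = X.shape
    Ginv = np.linalg.inv(K * sigma_g2)
    Rinv = np.eye(n) / sigma_e2
    top = np.hstack([X.T @ Rinv @ X, X.T @ Rinv])
    bot = np.hstack([Rinv @ X, Rinv + Ginv])
    lhs = np.vstack([top, bot])
    rhs = np.concatenate([X.T @ Rinv @ y, Rinv @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], sol[p:]


def ols_normal_equations_residuals(y, X):
    """Residuals from explicitly solved normal equations X'Xb = X'y."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ beta
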