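"""Independent reference estimators used to validate the EM implementation.

These deliberately share no code with :mod:`gwaslink.ld_core`: haplotype
frequencies are found by direct likelihood maximization over the one free
parameter (pAB, with allele-frequency margins fixed at their observed
values, which are the MLEs), using a dense grid over its feasible interval.
"""

from __future__ import annotations

import numpy as np
from scipy.special import xlogy

__all__ = ["brute_force_haplotype_freqs", "ld_from_two_by_two"]


def _loglik_grid(counts: np.ndarray, pAB: np.ndarray, pA: float, pB: float):
    pAB = np.maximum(np.asarray(pAB, dtype=float), 0.0)
    pAb = np.maximum(pA - pAB, 0.0)
    paB = np.maximum(pB - pAB, 0.0)
    pab = np.maximum(1.0 - pA - pB + pAB, 0.0)
    c = counts
    return (
        xlogy(c[0, 0], pab ** 2) + xlogy(c[0, 1], 2 * paB * pab)
        + xlogy(c[0, 2], paB ** 2) + xlogy(c[1, 0], 2 * pAb * pab)
        + xlogy(c[1, 1], 2 * (pAB * pab + pAb * paB))
        + xlogy(c[1, 2], 2 * pAB * paB) + xlogy(c[2, 0], pAb ** 2)
        + xlogy(c[2, 1], 2 * pAB * pAb) + xlogy(c[2, 2], pAB ** 2)
    )


def brute_force_haplotype_freqs(counts, grid: int = 8193):
    """Maximum-likelihood haplotype frequencies by grid + bounded search.

    Parameters
    ----------
    counts
        3x3 genotype-count table (rows: dosage at locus 1; cols: locus 2).
    grid
        Number of pAB grid points across its feasible interval.

    Returns ``(pAB, pAb, paB, pab)`` or None if either locus is monomorphic
    or the table is empty.  Likelihood ties are broken toward larger pAB.
    """
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n == 0:
        return None
    pA = (2 * c[2, :].sum() + c[1, :].sum()) / (2 * n)
    pB = (2 * c[:, 2].sum() + c[:, 1].sum()) / (2 * n)
    if pA <= 0 or pA >= 1 or pB <= 0 or pB >= 1:
        return None
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    if hi - lo <= 0:
        best = lo
    else:
        xs = np.linspace(lo, hi, grid)
        with np.errstate(invalid="ignore", divide="ignore"):
            ll = _loglik_grid(c, xs, pA, pB)
        top = ll.max()
        # Tie window just above float round-off: exactly symmetric likelihoods
        # (two analytic maxima) must register as ties so the larger-pAB rule
        # applies, while merely flat regions must not.  The grid is fine
        # enough (spacing < 1e-4 for grid >= 8193) that no refinement is
        # needed at the comparison scale.
        near = np.flatnonzero(ll >= top - 1e-14 * max(1.0, abs(top)))
        best = xs[near[-1]]
    return (best, pA - best, pB - best, 1.0 - pA - pB + best)


def ld_from_two_by_two(nAB: int, nAb: int, naB: int, nab: int):
    """D, |D'| and r^2 straight from a phased 2x2 haplotype-count table.

    r^2 is computed as the squared Pearson correlation of the two allele
    indicator vectors over the enumerated haplotypes, which is an
    implementation-independent route to the same quantity.
    """
    n = nAB + nAb + naB + nab
    a1 = np.repeat([1, 1, 0, 0], [nAB, nAb, naB, nab])
    a2 = np.repeat([1, 0, 1, 0], [nAB, nAb, naB, nab])
    pAB = nAB / n
    pA = (nAB + nAb) / n
    pB = (nAB + naB) / n
    D = pAB - pA * pB
    if D > 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        dmax = 0.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r = np.corrcoef(a1, a2)[0, 1]
    return D, dprime, float(r * r)
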