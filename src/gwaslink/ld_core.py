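"""Two-locus linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies are estimated by EM over the 3x3 genotype table: the
only latent quantity is the phase of double heterozygotes.  From the four
haplotype frequencies the standard summaries follow:

    D   = pAB - pA*pB
    r^2 = D^2 / (pA*pa*pB*pb)
    D'  = D / Dmax,  Dmax = min(pA*pb, pa*pB) if D > 0 else min(pA*pB, pa*pb)

and D' is reported as |D'|.  Missing genotypes are handled by pairwise-
complete deletion.  A vectorized EM computes all n(n-1)/2 pairs of a panel
at once for the triangle matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import xlogy

from .formats_io import GenotypeMatrix, MarkerMeta

__all__ = [
    "HaplotypeFreqs",
    "LDResult",
    "LDMatrix",
    "MatchResult",
    "em_haplotype_freqs",
    "ld_pair",
    "ld_pair_from_dosages",
    "ld_matrix",
    "lead_snp_ld",
    "match_markers",
]

EM_TOL = 1e-8
EM_MAX_ITER = 1000

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_INSUFFICIENT = "insufficient_data"
_STATUS_BY_CODE = {0: STATUS_OK, 1: STATUS_MONOMORPHIC, 2: STATUS_INSUFFICIENT}


@dataclass
class HaplotypeFreqs:
    """EM-estimated two-locus haplotype frequencies.

    Labels: A/a are the minor/major alleles at locus 1, B/b at locus 2.
    ``loglik_path`` holds the log-likelihood after every M step of the
    winning EM run (non-decreasing by construction of EM).
    """

    pAB: float
    pAb: float
    paB: float
    pab: float
    n_used: int
    loglik: float = float("nan")
    iterations: int = 0
    status: str = STATUS_OK
    loglik_path: tuple = ()


@dataclass
class LDResult:
    """LD summaries for one marker pair; values are NaN unless status == ok."""

    marker_i: MarkerMeta
    marker_j: MarkerMeta
    D: float
    Dprime: float
    r2: float
    freqs: Optional[HaplotypeFreqs]
    status: str = STATUS_OK


def _genotype_table(dos_i, dos_j) -> np.ndarray:
    """3x3 table of genotype counts over samples non-missing at both loci."""
    di = np.asarray(dos_i, dtype=float)
    dj = np.asarray(dos_j, dtype=float)
    if di.shape != dj.shape:
        raise ValueError("dosage vectors must have equal length")
    mask = ~(np.isnan(di) | np.isnan(dj))
    counts = np.zeros((3, 3))
    np.add.at(counts, (di[mask].astype(int), dj[mask].astype(int)), 1.0)
    return counts


def _table_loglik(counts: np.ndarray, pAB, pAb, paB, pab) -> float:
    """Multinomial log-likelihood of a 3x3 genotype table (constant dropped)."""
    probs = np.array([
        [pab * pab, 2 * paB * pab, paB * paB],
        [2 * pAb * pab, 2 * (pAB * pab + pAb * paB), 2 * pAB * paB],
        [pAb * pAb, 2 * pAB * pAb, pAB * pAB],
    ])
    return float(xlogy(counts, probs).sum())


def _em_run(counts: np.ndarray, pAB0: float, pA: float, pB: float,
            tol: float, max_iter: int):
    """One EM run from a given pAB start (margins fixed at observed freqs)."""
    n2 = 2.0 * counts.sum()
    c = counts
    pAB = min(max(pAB0, max(0.0, pA + pB - 1.0)), min(pA, pB))
    pAb = pA - pAB
    paB = pB - pAB
    pab = 1.0 - pA - pB + pAB
    path = []
    it = 0
    for it in range(1, max_iter + 1):
        den = pAB * pab + pAb * paB
        x = (pAB * pab / den) if den > 0 else 0.5
        nAB = 2 * c[2, 2] + c[2, 1] + c[1, 2] + x * c[1, 1]
        nAb = 2 * c[2, 0] + c[2, 1] + c[1, 0] + (1 - x) * c[1, 1]
        naB = 2 * c[0, 2] + c[0, 1] + c[1, 2] + (1 - x) * c[1, 1]
        nab = 2 * c[0, 0] + c[0, 1] + c[1, 0] + x * c[1, 1]
        new = (nAB / n2, nAb / n2, naB / n2, nab / n2)
        delta = max(abs(new[0] - pAB), abs(new[1] - pAb),
                    abs(new[2] - paB), abs(new[3] - pab))
        pAB, pAb, paB, pab = new
        path.append(_table_loglik(c, pAB, pAb, paB, pab))
        if delta < tol:
            break
    return (pAB, pAb, paB, pab), path[-1], it, tuple(path)


def em_haplotype_freqs(dosages_i, dosages_j, *, tol: float = EM_TOL,
                       max_iter: int = EM_MAX_ITER) -> HaplotypeFreqs:
    """Estimate two-locus haplotype frequencies from unphased dosages.

    Only samples non-missing at both loci are used.  EM is started at
    linkage equilibrium (product of observed allele frequencies); because
    that point can be a stationary point of the likelihood when the data
    are dominated by double heterozygotes, two additional near-boundary
    starts are run and the highest-likelihood solution returned (ties
    broken toward larger pAB).  Convergence: max absolute frequency change
    < ``tol`` or ``max_iter`` iterations.
    """
    counts = _genotype_table(dosages_i, dosages_j)
    n = int(counts.sum())
    if n == 0:
        return HaplotypeFreqs(math.nan, math.nan, math.nan, math.nan,
                              0, status=STATUS_INSUFFICIENT)
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA <= 0 or pA >= 1 or pB <= 0 or pB >= 1:
        return HaplotypeFreqs(math.nan, math.nan, math.nan, math.nan,
                              n, status=STATUS_MONOMORPHIC)
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    starts = [pA * pB]
    if counts[1, 1] > 0 and hi - lo > 0:
        w = hi - lo
        starts += [lo + 1e-3 * w, hi - 1e-3 * w]
    best = None
    for s in starts:
        freqs, ll, it, path = _em_run(counts, s, pA, pB, tol, max_iter)
        if (best is None or ll > best[1] + 1e-12
                or (abs(ll - best[1]) <= 1e-12 and freqs[0] > best[0][0])):
            best = (freqs, ll, it, path)
    (pAB, pAb, paB, pab), ll, it, path = best
    return HaplotypeFreqs(pAB, pAb, paB, pab, n, loglik=ll,
                          iterations=it, status=STATUS_OK, loglik_path=path)


def ld_pair(freqs: HaplotypeFreqs,
            marker_i: Optional[MarkerMeta] = None,
            marker_j: Optional[MarkerMeta] = None) -> LDResult:
    """Compute D, |D'| and r^2 from estimated haplotype frequencies."""
    if freqs.status != STATUS_OK:
        return LDResult(marker_i, marker_j, math.nan, math.nan, math.nan,
                        freqs, status=freqs.status)
    pA = freqs.pAB + freqs.pAb
    pB = freqs.pAB + freqs.paB
    pa, pb = 1.0 - pA, 1.0 - pB
    if pA <= 0 or pa <= 0 or pB <= 0 or pb <= 0:
        return LDResult(marker_i, marker_j, math.nan, math.nan, math.nan,
                        freqs, status=STATUS_MONOMORPHIC)
    D = freqs.pAB - pA * pB
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        dmax = 0.0
    dprime = abs(D) / dmax if dmax > 0 else 0.0
    r2 = D * D / (pA * pa * pB * pb)
    return LDResult(marker_i, marker_j, D,
                    float(np.clip(dprime, 0.0, 1.0)),
                    float(np.clip(r2, 0.0, 1.0)),
                    freqs, status=STATUS_OK)


def ld_pair_from_dosages(dos_i, dos_j,
                         marker_i: Optional[MarkerMeta] = None,
                         marker_j: Optional[MarkerMeta] = None) -> LDResult:
    """Convenience: EM + closed-form LD for one pair of dosage vectors."""
    return ld_pair(em_haplotype_freqs(dos_i, dos_j), marker_i, marker_j)


# ---------------------------------------------------------------------------
# vectorized EM over all pairs of a panel

def _pair_counts(G: np.ndarray):
    """Genotype-table counts for all marker pairs via indicator matmuls.

    Returns a dict (a, b) -> matrix of shape (m, m) where entry (i, j) is the
    number of samples with dosage a at marker i and b at marker j.
    """
    I = [(G == a).astype(np.float64) for a in (0.0, 1.0, 2.0)]
    return {(a, b): I[a] @ I[b].T for a in range(3) for b in range(3)}


def _em_pairs_condensed(c: dict, tol: float, max_iter: int):
    """Vectorized EM over P pairs given condensed 3x3 counts ``c[(a,b)]`` (P,)."""
    n = sum(c.values())
    n2 = 2.0 * n
    nA = 2 * (c[2, 0] + c[2, 1] + c[2, 2]) + (c[1, 0] + c[1, 1] + c[1, 2])
    nB = 2 * (c[0, 2] + c[1, 2] + c[2, 2]) + (c[0, 1] + c[1, 1] + c[2, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.where(n > 0, nA / n2, np.nan)
        pB = np.where(n > 0, nB / n2, np.nan)
    status = np.zeros(n.shape, dtype=np.int8)
    status[n == 0] = 2
    mono = (n > 0) & ((pA <= 0) | (pA >= 1) | (pB <= 0) | (pB >= 1))
    status[mono] = 1
    ok = status == 0

    lo = np.maximum(0.0, pA + pB - 1.0)
    hi = np.minimum(pA, pB)
    w = hi - lo
    start_list = [pA * pB, lo + 1e-3 * w, hi - 1e-3 * w]

    best = None
    iters_total = 0
    for s in start_list:
        pAB = np.clip(s, lo, hi)
        pAb = pA - pAB
        paB = pB - pAB
        pab = 1.0 - pA - pB + pAB
        # active-set iteration: only unconverged ok-pairs keep updating
        active = np.flatnonzero(ok)
        aAB, aAb, aaB, aab = (arr[active].copy() for arr in (pAB, pAb, paB, pab))
        ac = {k: v[active] for k, v in c.items()}
        an2 = n2[active]
        for _ in range(max_iter):
            if active.size == 0:
                break
            iters_total += 1
            den = aAB * aab + aAb * aaB
            x = np.where(den > 0, aAB * aab / np.where(den > 0, den, 1.0), 0.5)
            nAB = 2 * ac[2, 2] + ac[2, 1] + ac[1, 2] + x * ac[1, 1]
            nAb = 2 * ac[2, 0] + ac[2, 1] + ac[1, 0] + (1 - x) * ac[1, 1]
            naB = 2 * ac[0, 2] + ac[0, 1] + ac[1, 2] + (1 - x) * ac[1, 1]
            nab = 2 * ac[0, 0] + ac[0, 1] + ac[1, 0] + x * ac[1, 1]
            uAB, uAb, uaB, uab = nAB / an2, nAb / an2, naB / an2, nab / an2
            delta = np.maximum(
                np.maximum(np.abs(uAB - aAB), np.abs(uAb - aAb)),
                np.maximum(np.abs(uaB - aaB), np.abs(uab - aab)),
            )
            aAB, aAb, aaB, aab = uAB, uAb, uaB, uab
            done = delta < tol
            if done.any():
                idx = active[done]
                pAB[idx], pAb[idx] = aAB[done], aAb[done]
                paB[idx], pab[idx] = aaB[done], aab[done]
                keep = ~done
                active = active[keep]
                aAB, aAb, aaB, aab = aAB[keep], aAb[keep], aaB[keep], aab[keep]
                ac = {k: v[keep] for k, v in ac.items()}
                an2 = an2[keep]
        if active.size:  # hit the iteration cap
            pAB[active], pAb[active] = aAB, aAb
            paB[active], pab[active] = aaB, aab
        with np.errstate(invalid="ignore", divide="ignore"):
            ll = (xlogy(c[0, 0], pab ** 2) + xlogy(c[0, 1], 2 * paB * pab)
                  + xlogy(c[0, 2], paB ** 2) + xlogy(c[1, 0], 2 * pAb * pab)
                  + xlogy(c[1, 1], 2 * (pAB * pab + pAb * paB))
                  + xlogy(c[1, 2], 2 * pAB * paB) + xlogy(c[2, 0], pAb ** 2)
                  + xlogy(c[2, 1], 2 * pAB * pAb) + xlogy(c[2, 2], pAB ** 2))
        if best is None:
            best = [pAB, pAb, paB, pab, ll]
        else:
            better = ok & ((ll > best[4] + 1e-12)
                           | (np.abs(ll - best[4]) <= 1e-12) & (pAB > best[0]))
            for k, arr in enumerate((pAB, pAb, paB, pab, ll)):
                best[k] = np.where(better, arr, best[k])
    pAB, pAb, paB, pab, ll = best
    return pAB, pAb, paB, pab, ll, n.astype(np.int64), status, iters_total


def _ld_from_freqs_vec(pAB, pAb, paB, pab, status):
    """Vectorized closed-form D, |D'|, r^2 with monomorphic guards."""
    pA = pAB + pAb
    pB = pAB + paB
    pa, pb = 1.0 - pA, 1.0 - pB
    D = pAB - pA * pB
    with np.errstate(invalid="ignore", divide="ignore"):
        dmax = np.where(D > 0, np.minimum(pA * pb, pa * pB),
                        np.minimum(pA * pB, pa * pb))
        dprime = np.where(dmax > 0, np.abs(D) / dmax, 0.0)
        denom = pA * pa * pB * pb
        r2 = np.where(denom > 0, D * D / denom, np.nan)
    bad = status != 0
    for arr in (D, dprime, r2):
        arr[bad] = np.nan
    return D, np.clip(dprime, 0.0, 1.0), np.clip(r2, 0.0, 1.0)


@dataclass
class LDMatrix:
    """Strict-lower-triangle store of pairwise LD for an ordered marker panel.

    Pairs are keyed by (i, j) with i < j in the panel's position order and
    held in condensed arrays (row-major over the upper triangle, i.e.
    ``np.triu_indices`` order); :meth:`get` materializes an :class:`LDResult`.
    """

    markers: list
    pair_i: np.ndarray
    pair_j: np.ndarray
    D: np.ndarray
    Dprime: np.ndarray
    r2: np.ndarray
    n_used: np.ndarray
    status_codes: np.ndarray
    measure: str = "r2"
    freqs: Optional[tuple] = None  # (pAB, pAb, paB, pab) condensed arrays

    def __len__(self) -> int:
        return len(self.pair_i)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def _flat(self, i: int, j: int) -> int:
        if not 0 <= i < j < self.n_markers:
            raise IndexError(f"need 0 <= i < j < {self.n_markers}, got ({i}, {j})")
        n = self.n_markers
        return i * (2 * n - i - 1) // 2 + (j - i - 1)

    def value(self, i: int, j: int) -> float:
        """The configured measure (r2 or Dprime) for pair (i, j), i < j."""
        k = self._flat(i, j)
        return float(self.r2[k] if self.measure == "r2" else self.Dprime[k])

    def values(self) -> np.ndarray:
        return self.r2 if self.measure == "r2" else self.Dprime

    def get(self, i: int, j: int) -> LDResult:
        k = self._flat(i, j)
        status = _STATUS_BY_CODE[int(self.status_codes[k])]
        if self.freqs is not None:
            fr = HaplotypeFreqs(
                float(self.freqs[0][k]), float(self.freqs[1][k]),
                float(self.freqs[2][k]), float(self.freqs[3][k]),
                int(self.n_used[k]), status=status,
            )
        else:
            fr = HaplotypeFreqs(math.nan, math.nan, math.nan, math.nan,
                                int(self.n_used[k]), status=status)
        return LDResult(self.markers[i], self.markers[j],
                        float(self.D[k]), float(self.Dprime[k]),
                        float(self.r2[k]), fr, status=status)

    def iter_results(self):
        for i, j in zip(self.pair_i, self.pair_j):
            yield self.get(int(i), int(j))


def ld_matrix(gt: GenotypeMatrix, markers: Optional[Sequence[int]] = None,
              measure: str = "r2", *, tol: float = EM_TOL,
              max_iter: int = EM_MAX_ITER, keep_freqs: bool = False) -> LDMatrix:
    """All-pairs EM LD for a marker subset of a genotype panel.

    ``markers`` are row indices into ``gt`` (default: all), expected in
    position order.  Exactly n(n-1)/2 pairs are stored; per-pair failures
    (monomorphic, no jointly observed samples) are recorded in the status
    codes rather than raised.
    """
    if measure not in {"r2", "Dprime"}:
        raise ValueError(f"measure must be 'r2' or 'Dprime', got {measure!r}")
    idx = list(range(gt.n_markers)) if markers is None else list(markers)
    panel = [gt.markers[k] for k in idx]
    m = len(panel)
    if m < 2:
        warnings.warn("fewer than 2 markers: empty LD matrix")
        empty = np.empty(0)
        return LDMatrix(panel, np.empty(0, int), np.empty(0, int),
                        empty, empty.copy(), empty.copy(),
                        np.empty(0, int), np.empty(0, np.int8), measure)
    G = gt.dosages[idx]
    full = _pair_counts(G)
    iu, ju = np.triu_indices(m, k=1)
    c = {k: v[iu, ju] for k, v in full.items()}
    del full
    pAB, pAb, paB, pab, ll, n, status, _ = _em_pairs_condensed(c, tol, max_iter)
    D, dprime, r2 = _ld_from_freqs_vec(pAB, pAb, paB, pab, status)
    return LDMatrix(panel, iu, ju, D, dprime, r2, n, status, measure,
                    freqs=(pAB, pAb, paB, pab) if keep_freqs else None)


def lead_snp_ld(gt: GenotypeMatrix, lead,
                markers: Optional[Sequence[int]] = None) -> list:
    """LD of the lead marker against every other marker of a panel subset.

    ``lead`` is a MarkerMeta or (chrom, pos) pair and must be resolvable in
    ``gt`` by exact (chrom, pos).  Returns one LDResult per other marker in
    position order; the lead-vs-lead entry is omitted.
    """
    if isinstance(lead, MarkerMeta):
        chrom, pos = lead.chrom, lead.pos
    else:
        chrom, pos = lead
    li = gt.index_of(chrom, pos)
    if li is None:
        raise LookupError(
            f"lead marker ({chrom}, {pos}) not present in the genotype panel"
        )
    idx = list(range(gt.n_markers)) if markers is None else list(markers)
    out = []
    lead_dos = gt.dosages[li]
    for k in idx:
        if k == li:
            continue
        out.append(ld_pair_from_dosages(lead_dos, gt.dosages[k],
                                        gt.markers[li], gt.markers[k]))
    return out


@dataclass
class MatchResult:
    """Exact (chrom, pos) matching of association markers into an LD panel."""

    mapping: dict          # marker name -> panel index or None
    unmatched: list        # marker names with no (chrom, pos) match

    @property
    def n_matched(self) -> int:
        return sum(1 for v in self.mapping.values() if v is not None)


def match_markers(assoc, ld_gt: GenotypeMatrix,
                  panel: Optional[Sequence[int]] = None) -> MatchResult:
    """Map association rows to LD-panel markers by exact (chrom, pos).

    ``panel`` optionally restricts/matches against a subset of ``ld_gt``
    (indices in panel order); mapped values are then positions *within* the
    subset, which is what the triangle layout indexes.  Partial matching is
    the expected regime when the LD genotypes come from a different dataset;
    unmatched markers are reported, not errors.
    """
    if panel is None:
        lookup = {(str(m.chrom), m.pos): k for k, m in enumerate(ld_gt.markers)}
    else:
        lookup = {
            (str(ld_gt.markers[g].chrom), ld_gt.markers[g].pos): k
            for k, g in enumerate(panel)
        }
    mapping, unmatched = {}, []
    table = assoc.table if hasattr(assoc, "table") else assoc
    for row in table.itertuples(index=False):
        hit = lookup.get((str(row.chrom), int(row.pos)))
        mapping[row.marker] = hit
        if hit is None:
            unmatched.append(row.marker)
    return MatchResult(mapping=mapping, unmatched=unmatched)
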