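"""Synthetic genotype, association and annotation fixtures with tunable LD.

Genotypes follow a haplotype-block generative model: within a block every
site shares one minor-allele frequency f and each of the 2N haplotypes is a
copy of one of two ancestral haplotypes (all-minor, carried with probability
f, or all-major) whose alleles are independently resampled from Bernoulli(f)
with per-site probability eps.  For any within-block pair this gives exactly

    E[D] = (1 - eps)^2 f (1 - f)   =>   |D'| = (1 - eps)^2

so a target |D'| = d is hit by eps = 1 - sqrt(d), independent of f.  Blocks
are mutually independent.  Haplotypes are paired at random into unphased
diploids, so the EM estimator sees exactly the kind of data it models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy import stats

from .formats_io import (
    AnnotationSet,
    AssociationTable,
    GeneModel,
    GenotypeMatrix,
    TranscriptModel,
    genotype_matrix_from_calls,
    write_association,
    write_gtf,
    write_hapmap,
)
from .regions import RegionSpec

__all__ = [
    "BlockSpec",
    "simulate_genotypes",
    "simulate_association",
    "toy_gtf",
    "score_test_pvalues",
    "within_block_dprime",
    "cross_block_r2",
]

_LETTER_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"),
                 ("A", "T"), ("C", "G")]


@dataclass(frozen=True)
class BlockSpec:
    """Parameters of the haplotype-block genotype simulator."""

    n_blocks: int
    markers_per_block: int
    within_block_dprime: float
    n_samples: int
    seed: int
    maf_range: tuple = (0.1, 0.5)

    def __post_init__(self):
        if self.n_blocks < 1 or self.markers_per_block < 1 or self.n_samples < 1:
            raise ValueError("n_blocks, markers_per_block, n_samples must be >= 1")
        if not 0.0 <= self.within_block_dprime <= 1.0:
            raise ValueError("within_block_dprime must be in [0, 1]")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")


def simulate_genotypes(spec: BlockSpec, region: RegionSpec,
                       path: Optional[Union[str, Path]] = None,
                       ) -> GenotypeMatrix:
    """Simulate an unphased diploid panel with block-structured LD.

    Marker positions are drawn uniformly (without replacement) in the region
    and blocks are consecutive runs of ``markers_per_block`` markers.  The
    returned matrix is canonicalized exactly as the HapMap reader would
    (empirical minor allele), so writing with ``path`` and re-reading
    round-trips.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_blocks * spec.markers_per_block
    span = region.right - region.left + 1
    if span < m:
        raise ValueError(f"region of {span} bp cannot host {m} distinct positions")
    positions = np.sort(rng.choice(span, size=m, replace=False)) + region.left
    n_hap = 2 * spec.n_samples
    eps = 1.0 - np.sqrt(spec.within_block_dprime)

    hap = np.empty((n_hap, m), dtype=np.int8)
    lo, hi = spec.maf_range
    for b in range(spec.n_blocks):
        cols = slice(b * spec.markers_per_block, (b + 1) * spec.markers_per_block)
        f = rng.uniform(lo, hi)
        z = rng.random(n_hap) < f                        # ancestral choice
        base = np.broadcast_to(z[:, None], (n_hap, spec.markers_per_block))
        noise = rng.random((n_hap, spec.markers_per_block)) < eps
        fresh = rng.random((n_hap, spec.markers_per_block)) < f
        hap[:, cols] = np.where(noise, fresh, base)

    dosage = hap[0::2] + hap[1::2]                       # (n_samples, m)

    names = [f"mk{k + 1:05d}" for k in range(m)]
    samples = [f"S{k + 1:04d}" for k in range(spec.n_samples)]
    calls = []
    for k in range(m):
        minor, major = _LETTER_PAIRS[int(rng.integers(len(_LETTER_PAIRS)))]
        col = dosage[:, k]
        calls.append([
            (minor, minor) if d == 2 else (minor, major) if d == 1
            else (major, major)
            for d in col
        ])
    gt = genotype_matrix_from_calls(
        names, [region.chrom] * m, positions.tolist(), calls, samples
    )
    if path is not None:
        write_hapmap(gt, path)
    return gt


def score_test_pvalues(G: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-marker two-sided p-values for dosage-vs-phenotype association.

    Pearson-correlation t test per marker row of ``G`` (missing dosages
    excluded pairwise); markers with < 3 informative samples or zero dosage
    variance get p = 1.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    p = np.ones(G.shape[0])
    finite = np.isfinite(G)
    if finite.all():
        n = G.shape[1]
        gc = G - G.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sg = np.sqrt((gc ** 2).sum(axis=1))
        sy = np.sqrt((yc ** 2).sum())
        ok = (sg > 0) & (sy > 0)
        r = np.zeros(G.shape[0])
        r[ok] = gc[ok] @ yc / (sg[ok] * sy)
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        t = r * np.sqrt((n - 2) / (1 - r ** 2))
        p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df=n - 2)
        return p
    for k in range(G.shape[0]):
        mask = finite[k]
        if mask.sum() < 3 or np.std(G[k, mask]) == 0:
            continue
        r, pk = stats.pearsonr(G[k, mask], y[mask])
        p[k] = pk
    return p


def simulate_association(gt: GenotypeMatrix, causal, effect: float, seed: int,
                         path: Optional[Union[str, Path]] = None,
                         ) -> AssociationTable:
    """GWAS results for a simulated quantitative trait.

    The phenotype is ``effect * dosage(causal) + N(0, 1)`` noise; every
    marker is then tested against it.  ``causal`` is a marker index or name.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if isinstance(causal, str):
        idx = [k for k, m in enumerate(gt.markers) if m.name == causal]
        if not idx:
            raise LookupError(f"causal marker {causal!r} not in panel")
        causal = idx[0]
    if not 0 <= causal < gt.n_markers:
        raise IndexError(f"causal index {causal} out of range")
    dos = np.nan_to_num(gt.dosages[causal], nan=np.nanmean(gt.dosages[causal]))
    y = effect * dos + rng.standard_normal(gt.n_samples)
    p = score_test_pvalues(gt.dosages, y)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame({
        "marker": [m.name for m in gt.markers],
        "chrom": [str(m.chrom) for m in gt.markers],
        "pos": gt.positions(),
        "p": p,
    })
    table = AssociationTable(table=df, n_dropped=0)
    if path is not None:
        write_association(table, path)
    return table


def within_block_dprime(gt: GenotypeMatrix, spec: BlockSpec) -> np.ndarray:
    """Per-block recovered |D'| for a panel generated by :func:`simulate_genotypes`.

    Within a block both loci of every pair share one allele frequency f, so
    the model-implied maximum of |D| is fbar*(1-fbar) with fbar the pooled
    estimated margin; |D'| is estimated as |D_hat| / (fbar*(1-fbar)).  Pooling
    the margins this way uses the generator's equal-frequency structure and
    avoids the small-sample bias of min(pA*pb, pa*pB), whose arguments are
    exactly tied here.  Returns one mean |D'| per block (NaN if a block has
    no informative pair).
    """
    from itertools import combinations

    from .ld_core import ld_matrix

    mat = ld_matrix(gt, keep_freqs=True)
    pAB, pAb, paB, _ = mat.freqs
    out = np.full(spec.n_blocks, np.nan)
    k_per = spec.markers_per_block
    for b in range(spec.n_blocks):
        vals = []
        for i, j in combinations(range(b * k_per, (b + 1) * k_per), 2):
            k = mat._flat(i, j)
            if not np.isfinite(mat.D[k]):
                continue
            fbar = (2 * pAB[k] + pAb[k] + paB[k]) / 2  # (pA + pB) / 2
            dmax = fbar * (1 - fbar)
            if dmax > 0:
                vals.append(abs(mat.D[k]) / dmax)
        if vals:
            out[b] = float(np.mean(np.clip(vals, 0.0, 1.0)))
    return out


def cross_block_r2(gt: GenotypeMatrix, spec: BlockSpec) -> float:
    """Mean estimated r^2 over all marker pairs lying in different blocks."""
    from .ld_core import ld_matrix

    mat = ld_matrix(gt)
    k_per = spec.markers_per_block
    block = np.arange(gt.n_markers) // k_per
    mask = block[mat.pair_i] != block[mat.pair_j]
    return float(np.nanmean(mat.r2[mask]))


def toy_gtf(region: RegionSpec, n_genes: int, seed: int,
            path: Optional[Union[str, Path]] = None) -> AnnotationSet:
    """Deterministic toy gene models: 2-6 exons, CDS inside exons, end UTRs.

    Genes alternate strand and occupy non-overlapping slots across the
    region, one transcript each (ids ``GENE{k}`` / ``GENE{k}_T01``).
    """
    rng = np.random.default_rng(seed)
    span = region.right - region.left + 1
    if span < n_genes * 200:
        raise ValueError(f"region of {span} bp is too narrow for {n_genes} genes")
    slot = span // n_genes
    transcripts, genes = {}, {}
    for g in range(n_genes):
        slot_left = region.left + g * slot
        glen = int(slot * rng.uniform(0.4, 0.7))
        gstart = slot_left + int(rng.integers(0, slot - glen))
        gend = gstart + glen - 1
        strand = "+" if g % 2 == 0 else "-"
        n_exons = int(rng.integers(2, 7))
        # exon boundaries: split the span into alternating exon/intron runs
        cuts = np.sort(rng.choice(np.arange(1, glen - 1), size=2 * n_exons - 2,
                                  replace=False))
        edges = np.concatenate([[0], cuts, [glen - 1]])
        exons = [(gstart + int(edges[2 * k]), gstart + int(edges[2 * k + 1]))
                 for k in range(n_exons)]
        first, last = exons[0], exons[-1]
        cds_start = first[0] + max(1, (first[1] - first[0]) // 3)
        cds_end = last[1] - max(1, (last[1] - last[0]) // 3)
        features = []
        for es, ee in exons:
            features.append(("exon", es, ee))
            cs, ce = max(es, cds_start), min(ee, cds_end)
            if cs <= ce:
                features.append(("CDS", cs, ce))
            if es < cds_start:
                kind = "five_prime_UTR" if strand == "+" else "three_prime_UTR"
                features.append((kind, es, min(ee, cds_start - 1)))
            if ee > cds_end:
                kind = "three_prime_UTR" if strand == "+" else "five_prime_UTR"
                features.append((kind, max(es, cds_end + 1), ee))
        gid = f"GENE{g + 1:03d}"
        tid = f"{gid}_T01"
        transcripts[tid] = TranscriptModel(tid, gid, region.chrom, strand,
                                           features)
        genes[gid] = GeneModel(gid, region.chrom, gstart, gend, strand, [tid])
    ann = AnnotationSet(transcripts=transcripts, genes=genes)
    if path is not None:
        write_gtf(ann, path)
    return ann
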