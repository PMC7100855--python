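"""Shared fixtures: a synthetic regional locus written to disk once per session."""

import numpy as np
import pytest

import gwaslink as gl
from gwaslink.formats_io import GenotypeMatrix, write_hapmap

# the regional window exercised throughout: chr 9, 94,178,074 +/- 200 kb
REGION = dict(chrom="9", left=94178074 - 200000, right=94178074 + 200000)


@pytest.fixture(scope="session")
def region9():
    return gl.RegionSpec(**REGION)


@pytest.fixture(scope="session")
def locus(tmp_path_factory, region9):
    """A full fixture locus on disk: genotypes, annotation, association.

    200 markers (20 blocks x 10), 104 samples, 10 genes, one causal marker
    with a strong effect so the locus has genome-wide-significant signals.
    """
    d = tmp_path_factory.mktemp("locus")
    spec = gl.BlockSpec(n_blocks=20, markers_per_block=10,
                        within_block_dprime=0.8, n_samples=104, seed=5)
    gt = gl.simulate_genotypes(spec, region9, path=d / "genotypes.hmp.txt")
    ann = gl.toy_gtf(region9, 10, seed=5, path=d / "annotation.gtf")
    assoc = gl.simulate_association(gt, 100, effect=1.0, seed=6,
                                    path=d / "association.tsv")
    return {
        "dir": d,
        "spec": spec,
        "gt": gt,
        "ann": ann,
        "assoc": assoc,
        "hapmap": d / "genotypes.hmp.txt",
        "gtf": d / "annotation.gtf",
        "association": d / "association.tsv",
    }


@pytest.fixture(scope="session")
def cross_panel(tmp_path_factory, locus, region9):
    """A second genotype panel sharing half of the locus positions plus others."""
    d = tmp_path_factory.mktemp("panel2")
    gt = locus["gt"]
    other = gl.simulate_genotypes(
        gl.BlockSpec(n_blocks=30, markers_per_block=10,
                     within_block_dprime=0.9, n_samples=104, seed=99),
        region9,
    )
    keep = list(range(0, gt.n_markers, 2))
    markers = [gt.markers[k] for k in keep] + other.markers
    dosages = np.vstack([gt.dosages[keep], other.dosages])
    order = sorted(range(len(markers)), key=lambda k: markers[k].pos)
    merged = GenotypeMatrix([markers[k] for k in order], gt.samples,
                            dosages[order])
    path = d / "genotypes_ld.hmp.txt"
    write_hapmap(merged, path)
    return {"gt": merged, "hapmap": path, "shared": len(keep)}


@pytest.fixture(scope="session")
def scope5(locus, region9):
    """The locus resolved at threshold 5 with its lead SNP."""
    scope = gl.resolve_region(locus["assoc"], locus["ann"], region9)
    scope.threshold = 5.0
    scope.significant = gl.filter_significant(scope, 5.0)
    scope.lead = gl.find_lead(scope)
    return scope


def dosages_from_table(table):
    """Expand a 3x3 genotype-count table into a pair of dosage vectors."""
    t = np.asarray(table)
    di = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], t.flatten())
    dj = np.repeat([0, 1, 2, 0, 1, 2, 0, 1, 2], t.flatten())
    return di.astype(float), dj.astype(float)


def all_genotype_tables(n_max):
    """Every 3x3 genotype-count table with total sample count <= n_max."""
    import itertools

    for n in range(n_max + 1):
        for cells in itertools.product(range(n + 1), repeat=8):
            s = sum(cells)
            if s <= n:
                yield np.array(list(cells) + [n - s]).reshape(3, 3)
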