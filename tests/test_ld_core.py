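"""EM haplotype-frequency estimation and LD summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gwaslink as gl
from gwaslink.ld_core import (
    HaplotypeFreqs,
    em_haplotype_freqs,
    ld_matrix,
    ld_pair,
    ld_pair_from_dosages,
    lead_snp_ld,
    match_markers,
)
from gwaslink.reference import brute_force_haplotype_freqs, ld_from_two_by_two

from conftest import all_genotype_tables, dosages_from_table


def _diploids_from_haplotypes(pairs):
    """Dosage vectors from explicit (hap1, hap2) tuples of (a, b) alleles."""
    di = np.array([h1[0] + h2[0] for h1, h2 in pairs], dtype=float)
    dj = np.array([h1[1] + h2[1] for h1, h2 in pairs], dtype=float)
    return di, dj


class TestEmHaplotypeFreqs:
    def test_phase_known_data_equals_direct_counting(self):
        # AB=40, Ab=10, aB=10, ab=40 over 50 diploids, paired so that no
        # double heterozygote occurs: EM must reproduce the phased counts.
        pairs = ([((1, 1), (1, 1))] * 20 + [((1, 0), (1, 0))] * 5
                 + [((0, 1), (0, 1))] * 5 + [((0, 0), (0, 0))] * 20)
        di, dj = _diploids_from_haplotypes(pairs)
        f = em_haplotype_freqs(di, dj)
        assert f.status == "ok" and f.n_used == 50
        assert f.pAB == pytest.approx(0.40, abs=1e-9)
        assert f.pAb == pytest.approx(0.10, abs=1e-9)
        assert f.paB == pytest.approx(0.10, abs=1e-9)
        assert f.pab == pytest.approx(0.40, abs=1e-9)

    def test_duplicated_marker_gives_coupling_only(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, size=200).astype(float)
        f = em_haplotype_freqs(d, d)
        maf = d.sum() / (2 * len(d))
        assert f.pAb == pytest.approx(0.0, abs=1e-9)
        assert f.paB == pytest.approx(0.0, abs=1e-9)
        assert f.pAB == pytest.approx(maf, abs=1e-9)

    def test_independent_loci_recover_equilibrium(self):
        rng = np.random.default_rng(42)
        n = 5000
        di = (rng.random(n) < 0.5).astype(float) + (rng.random(n) < 0.5)
        dj = (rng.random(n) < 0.5).astype(float) + (rng.random(n) < 0.5)
        f = em_haplotype_freqs(di, dj)
        se = np.sqrt(0.25 * 0.75 / (2 * n))  # binomial SE of a haplotype freq
        assert abs(f.pAB - 0.25) < 3 * se

    def test_monomorphic_and_insufficient_status(self):
        ok = np.array([0.0, 1.0, 2.0, 1.0])
        mono = np.zeros(4)
        f = em_haplotype_freqs(ok, mono)
        assert f.status == "monomorphic"
        empty = np.full(4, np.nan)
        f = em_haplotype_freqs(ok, empty)
        assert f.status == "insufficient_data" and f.n_used == 0

    def test_loglik_monotone_every_iteration(self):
        for table in ([[5, 2, 0], [1, 6, 2], [0, 3, 4]],
                      [[0, 0, 1], [0, 4, 0], [1, 0, 0]],
                      [[2, 1, 1], [1, 1, 1], [1, 1, 2]]):
            f = em_haplotype_freqs(*dosages_from_table(table))
            path = f.loglik_path
            assert all(b >= a - 1e-9 for a, b in zip(path, path[1:]))

    def test_em_matches_brute_force_small_tables(self):
        # full n <= 6 enumeration lives in the acceptance suite
        for table in all_genotype_tables(4):
            f = em_haplotype_freqs(*dosages_from_table(table))
            bf = brute_force_haplotype_freqs(table)
            if f.status != "ok":
                assert bf is None
                continue
            assert bf is not None
            assert max(abs(f.pAB - bf[0]), abs(f.pAb - bf[1]),
                       abs(f.paB - bf[2]), abs(f.pab - bf[3])) <= 1e-4


class TestLdPair:
    def test_worked_example_against_2x2_oracle(self):
        f = HaplotypeFreqs(0.40, 0.10, 0.10, 0.40, 50)
        r = ld_pair(f)
        assert r.D == pytest.approx(0.15)
        assert r.r2 == pytest.approx(0.36)
        assert r.Dprime == pytest.approx(0.60)
        oD, oDp, or2 = ld_from_two_by_two(40, 10, 10, 40)
        assert r.D == pytest.approx(oD)
        assert r.Dprime == pytest.approx(oDp)
        assert r.r2 == pytest.approx(or2)

    def test_equilibrium_gives_zero(self):
        f = HaplotypeFreqs(0.15, 0.35, 0.15, 0.35, 100)  # pAB = pA*pB = 0.5*0.3
        r = ld_pair(f)
        assert r.D == pytest.approx(0.0, abs=1e-12)
        assert r.r2 == pytest.approx(0.0, abs=1e-12)
        assert r.Dprime == pytest.approx(0.0, abs=1e-12)

    def test_complete_coupling_is_perfect_ld(self):
        f = HaplotypeFreqs(0.3, 0.0, 0.0, 0.7, 100)
        r = ld_pair(f)
        assert r.Dprime == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_invariant_to_locus_swap_and_allele_relabel(self, a, b, c, d):
        n = a + b + c + d
        if n == 0:
            return
        f = HaplotypeFreqs(a / n, b / n, c / n, d / n, n)
        r = ld_pair(f)
        swap = ld_pair(HaplotypeFreqs(a / n, c / n, b / n, d / n, n))
        relabel = ld_pair(HaplotypeFreqs(b / n, a / n, d / n, c / n, n))
        if r.status != "ok":
            assert swap.status != "ok" and relabel.status != "ok"
            return
        for other in (swap, relabel):
            assert other.r2 == pytest.approx(r.r2, abs=1e-12)
            assert other.Dprime == pytest.approx(r.Dprime, abs=1e-12)


class TestLdMatrix:
    def test_pair_count_identity(self, locus):
        gt = locus["gt"]
        for n in (2, 5, 17):
            m = ld_matrix(gt, list(range(n)))
            assert len(m) == n * (n - 1) // 2

    def test_fewer_than_two_markers_warns_empty(self, locus):
        with pytest.warns(UserWarning, match="fewer than 2"):
            m = ld_matrix(locus["gt"], [0])
        assert len(m) == 0

    def test_monomorphic_marker_flags_its_pairs(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(4, 60)).astype(float)
        dos[2] = 0.0  # monomorphic marker
        markers = [gl.MarkerMeta(f"m{k}", "1", 10 * (k + 1)) for k in range(4)]
        gt = gl.GenotypeMatrix(markers, [f"s{k}" for k in range(60)], dos)
        m = ld_matrix(gt)
        assert len(m) == 6
        flagged = [(i, j) for i, j in zip(m.pair_i, m.pair_j)
                   if m.get(int(i), int(j)).status == "monomorphic"]
        assert sorted(flagged) == [(0, 2), (1, 2), (2, 3)]

    def test_vectorized_agrees_with_scalar_em(self):
        rng = np.random.default_rng(8)
        dos = rng.integers(0, 3, size=(12, 80)).astype(float)
        dos[rng.random(dos.shape) < 0.07] = np.nan  # sprinkle missingness
        markers = [gl.MarkerMeta(f"m{k}", "1", 10 * (k + 1)) for k in range(12)]
        gt = gl.GenotypeMatrix(markers, [f"s{k}" for k in range(80)], dos)
        m = ld_matrix(gt)
        for i, j in zip(m.pair_i, m.pair_j):
            vec = m.get(int(i), int(j))
            sca = ld_pair_from_dosages(dos[i], dos[j])
            assert vec.status == sca.status
            if vec.status == "ok":
                assert vec.r2 == pytest.approx(sca.r2, abs=1e-6)
                assert vec.Dprime == pytest.approx(sca.Dprime, abs=1e-6)


class TestLeadSnpLd:
    def test_vector_excludes_self(self, locus):
        gt = locus["gt"]
        lead = gt.markers[10]
        res = lead_snp_ld(gt, lead, list(range(5, 15)))
        assert len(res) == 9
        assert all(r.marker_i.name == lead.name for r in res)

    def test_duplicated_marker_has_perfect_ld(self):
        rng = np.random.default_rng(1)
        row = rng.integers(0, 3, size=100).astype(float)
        dos = np.vstack([row, row, rng.integers(0, 3, 100)])
        markers = [gl.MarkerMeta(f"m{k}", "1", 10 * (k + 1)) for k in range(3)]
        gt = gl.GenotypeMatrix(markers, [f"s{k}" for k in range(100)], dos)
        res = lead_snp_ld(gt, markers[0])
        dup = next(r for r in res if r.marker_j.name == "m1")
        assert dup.r2 == pytest.approx(1.0)
        assert dup.Dprime == pytest.approx(1.0)

    def test_absent_lead_raises_lookup(self, locus):
        with pytest.raises(LookupError, match="999"):
            lead_snp_ld(locus["gt"], ("9", 999))

    def test_block_ld_recovered_within_3se(self, region9):
        # two markers in a |D'|=1 block share haplotypes: r2 is high and the
        # estimate sits within 3 binomial SEs of the truth implied by freqs
        spec = gl.BlockSpec(n_blocks=1, markers_per_block=2,
                            within_block_dprime=1.0, n_samples=500, seed=21,
                            maf_range=(0.3, 0.3))
        gt = gl.simulate_genotypes(spec, region9)
        res = lead_snp_ld(gt, gt.markers[0])[0]
        assert res.status == "ok"
        # with a single shared ancestral pattern r2 = 1 exactly in the pool
        assert res.r2 > 1 - 3 * np.sqrt(1.0 / (2 * 500))


class TestMatchMarkers:
    def test_identity_mapping(self, locus):
        res = match_markers(locus["assoc"], locus["gt"])
        assert res.n_matched == len(locus["assoc"])
        assert res.unmatched == []

    def test_shifted_panel_matches_nothing(self, locus):
        gt = locus["gt"]
        shifted = gl.GenotypeMatrix(
            [gl.MarkerMeta(m.name, m.chrom, m.pos + 1, m.alleles,
                           m.minor, m.major) for m in gt.markers],
            gt.samples, gt.dosages,
        )
        res = match_markers(locus["assoc"], shifted)
        assert res.n_matched == 0
        assert len(res.unmatched) == len(locus["assoc"])

    def test_partial_overlap_bookkeeping(self, locus, cross_panel):
        assoc = locus["assoc"]
        sub = gl.AssociationTable(assoc.table.iloc[:10].reset_index(drop=True))
        res = match_markers(sub, cross_panel["gt"])
        # every second locus marker was carried into the merged panel
        expected = sum(1 for k in range(10) if k % 2 == 0)
        assert res.n_matched == expected
        assert len(res.unmatched) == 10 - expected
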