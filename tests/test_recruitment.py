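"""Aligner, identity/length cutoffs, RPKG, ANIr and subsampling."""

import numpy as np
import pytest

from popmicrodiv import recruitment, seqio, simulate
from popmicrodiv.recruitment import (
    align_reads,
    compute_anir,
    compute_rpkg,
    filter_alignments,
    read_sam,
    subsample_alignments,
    write_sam,
)

from conftest import make_reads


@pytest.fixture(scope="module")
def genome():
    return simulate.generate_genome(20_000, 20, seed=3)


class TestAligner:
    def test_exact_substring(self, genome):
        reads = make_reads([genome.sequence[100:200]])
        aln = align_reads(reads, genome)
        assert len(aln) == 1
        assert aln.ref_start[0] == 100
        assert aln.identity[0] == 100.0

    def test_single_mismatch_identity(self, genome):
        s = list(genome.sequence[500:600])
        s[50] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s[50]]
        aln = align_reads(make_reads(["".join(s)]), genome)
        assert aln.ref_start[0] == 500
        assert aln.identity[0] == pytest.approx(99.0)

    def test_empty_read_set(self, genome):
        aln = align_reads(seqio.ReadSet(np.empty(0, np.uint8), np.zeros(1, np.int64)), genome)
        assert len(aln) == 0

    def test_genome_shorter_than_read_is_error(self):
        g = seqio.AnnotatedGenome("g", "ACGTACGTACGTACGTACGT")
        with pytest.raises(ValueError, match="shorter"):
            align_reads(make_reads(["A" * 50]), g)

    def test_masked_read_dropped(self, genome):
        masked = seqio.mask_regions(genome, [(1000, 1200)])
        inside = genome.sequence[1040:1140]   # fully masked span
        outside = genome.sequence[3000:3100]
        aln = align_reads(make_reads([inside, outside]), masked)
        assert len(aln) == 1
        assert aln.ref_start[0] == 3000

    def test_median_identity_tracks_divergence(self, genome):
        """Population at exactly 5% divergence, error-free reads."""
        pop = simulate.evolve_population(genome, 10, theta=0.05, seed=4,
                                         divergence="exact")
        reads = simulate.simulate_reads(pop, 20_000, read_len=100, seed=5)
        aln = filter_alignments(align_reads(reads, genome), 80.0, 50)
        assert np.median(aln.identity) == pytest.approx(95.0, abs=0.2)


class TestFilter:
    def test_boundaries(self, genome):
        reads = make_reads([genome.sequence[0:100]])
        aln = align_reads(reads, genome)
        aln.matches[0] = 98  # force identity 98.0
        assert len(filter_alignments(aln, 98.0, 50)) == 1
        aln.matches[0] = 97  # 97.0 < 98
        assert len(filter_alignments(aln, 98.0, 50)) == 0
        aln.matches[0] = 100
        assert len(filter_alignments(aln, 98.0, 101)) == 0

    def test_matches_brute_force_predicate(self, genome):
        pop = simulate.evolve_population(genome, 8, theta=0.02, seed=6)
        reads = simulate.simulate_reads(pop, 5_000, read_len=100, seed=7)
        aln = align_reads(reads, genome)
        kept = filter_alignments(aln, 98.0, 50)
        brute = sum(
            1 for i in range(len(aln))
            if 100.0 * aln.matches[i] / aln.aligned_len[i] >= 98.0
            and aln.aligned_len[i] >= 50
        )
        assert len(kept) == brute


class TestRpkg:
    def _aln(self, n, meta_bases, mean_rl=100.0):
        return recruitment.AlignmentSet(
            "g", np.zeros(n, np.int64), np.full(n, 100), np.full(n, 100),
            np.zeros(n * 100, np.uint8), np.arange(n + 1) * 100,
            metagenome_bases=meta_bases, metagenome_reads=n, mean_read_len=mean_rl,
        )

    def test_unit_definition(self):
        assert compute_rpkg(self._aln(1000, 10**9), 10**6) == pytest.approx(1.0)

    def test_linearity_in_metagenome_size(self):
        a = compute_rpkg(self._aln(1000, 10**9), 10**6)
        b = compute_rpkg(self._aln(1000, 2 * 10**9), 10**6)
        assert a == pytest.approx(2 * b)

    def test_read_adjusted_mode(self):
        v = compute_rpkg(self._aln(1000, 10**9, mean_rl=100.0), 10**6,
                         norm_mode="read_adjusted")
        assert v == pytest.approx(100.0)

    def test_masking_scales_inverse(self):
        a = self._aln(1000, 10**9)
        full = compute_rpkg(a, 10**6)
        masked = compute_rpkg(a, int(0.9 * 10**6))
        assert masked == pytest.approx(full / 0.9)

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_rpkg(self._aln(10, 10**9), 0)
        with pytest.raises(ValueError):
            compute_rpkg(self._aln(10, 0), 1000)

    def test_subsampling_keeps_denominators(self, genome):
        """RPKG invariance: the metagenome denominator must come from the full
        read set, not from the subsample."""
        pop = simulate.evolve_population(genome, 4, theta=0.01, seed=8)
        reads = simulate.simulate_reads(pop, 4_000, read_len=100, seed=9)
        aln = filter_alignments(align_reads(reads, genome), 98.0, 50)
        sub = subsample_alignments(aln, len(aln) // 4, seed=1)
        assert sub.metagenome_bases == aln.metagenome_bases == reads.total_bases
        assert compute_rpkg(sub, len(genome)) == pytest.approx(
            compute_rpkg(aln, len(genome)) * len(sub) / len(aln)
        )


class TestAnir:
    def _aln_with_identities(self, idents):
        n = len(idents)
        alen = np.full(n, 1000, np.int64)
        matches = np.round(np.asarray(idents) * 10).astype(np.int64)
        return recruitment.AlignmentSet(
            "g", np.zeros(n, np.int64), alen, matches,
            np.zeros(n, np.uint8), np.arange(n + 1), 10**6, n, 100.0,
        )

    def test_two_point_statistics(self):
        med, mean, (edges, hist) = compute_anir(self._aln_with_identities([90.0, 100.0]))
        assert med == 95.0 and mean == 95.0
        assert hist.sum() == 2

    def test_identity_case(self):
        med, mean, _ = compute_anir(self._aln_with_identities([100.0] * 5))
        assert med == mean == 100.0

    def test_empty_is_nan_not_zero(self):
        med, mean, (edges, hist) = compute_anir(self._aln_with_identities([]))
        assert np.isnan(med) and np.isnan(mean)
        assert hist.sum() == 0

    def test_cutoff_floor_property(self, genome):
        pop = simulate.evolve_population(genome, 10, theta=0.02, seed=10)
        reads = simulate.simulate_reads(pop, 5_000, read_len=100, seed=11)
        aln = filter_alignments(align_reads(reads, genome), 98.0, 50)
        med, mean, _ = compute_anir(aln)
        assert med >= 98.0


class TestSubsample:
    def test_determinism_and_fallback(self, genome):
        reads = make_reads([genome.sequence[i : i + 100] for i in range(0, 3000, 30)])
        aln = align_reads(reads, genome)
        a = subsample_alignments(aln, 20, seed=3)
        b = subsample_alignments(aln, 20, seed=3)
        assert (a.ref_start == b.ref_start).all()
        allr = subsample_alignments(aln, 10**6, seed=3)
        assert len(allr) == len(aln)

    def test_composition_within_hypergeometric_bounds(self, genome):
        pop = simulate.evolve_population(genome, 2, theta=0.01, seed=12)
        reads = simulate.simulate_reads(pop, 50_000, read_len=100, seed=13)
        aln = align_reads(reads, genome)
        sub = subsample_alignments(aln, 5_000, seed=14)
        p = (aln.lineages == 0).mean()
        n = len(sub)
        sd = np.sqrt(n * p * (1 - p) * (len(aln) - n) / (len(aln) - 1))
        assert abs((sub.lineages == 0).sum() - n * p) < 3 * sd


class TestSam:
    def test_roundtrip(self, genome, tmp_path):
        reads = make_reads([genome.sequence[100:200], genome.sequence[5000:5100]])
        aln = align_reads(reads, genome)
        write_sam(aln, genome, tmp_path / "a.sam")
        back = read_sam(tmp_path / "a.sam", genome)
        assert (back.ref_start == aln.ref_start).all()
        assert (back.matches == aln.matches).all()
        assert (back.bases == aln.bases).all()

    def test_gapped_cigar_import(self, genome, tmp_path):
        # 30M2D20M: 52 reference columns, 2 of them deletion (mismatch) columns
        seq = genome.sequence[100:130] + genome.sequence[132:152]
        sam = (
            f"@HD\tVN:1.6\n@SQ\tSN:{genome.id}\tLN:{len(genome)}\n"
            f"r1\t0\t{genome.id}\t101\t255\t30M2D20M\t*\t0\t0\t{seq}\t*\tNM:i:2\n"
        )
        (tmp_path / "g.sam").write_text(sam)
        aln = read_sam(tmp_path / "g.sam", genome)
        assert len(aln) == 1
        assert aln.ref_start[0] == 100
        assert aln.span[0] == 52
        assert aln.aligned_len[0] == 52
        assert aln.matches[0] == 50
        assert aln.identity[0] == pytest.approx(100 * 50 / 52)
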