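"""Codon pileups, variant filters, expected sites and per-gene statistics."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from popmicrodiv import genetics, microdiv, simulate
from popmicrodiv.microdiv import (
    GenePileup,
    aggregate_genome,
    build_codon_pileups,
    call_codon_variants,
    expected_sites,
    gene_stats,
)
from popmicrodiv.recruitment import align_reads, filter_alignments
from popmicrodiv.seqio import GeneRecord

from conftest import make_reads

ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
SENSE = [c for c in ALL_CODONS if str(Seq(c).translate()) != "*"]


def enumeration_oracle(codon: str) -> tuple[float, float]:
    """Independent Nei-Gojobori oracle: exhaustive 9-neighbor enumeration via
    Biopython translation."""
    aa = str(Seq(codon).translate())
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if str(Seq(alt).translate()) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


class TestExpectedSites:
    def test_phenylalanine(self):
        s, n = expected_sites("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_tryptophan_has_no_synonymous_neighbor(self):
        assert expected_sites("TGG") == (0.0, 3.0)

    @pytest.mark.parametrize("codon", SENSE)
    def test_matches_enumeration_oracle_and_partition(self, codon):
        s, n = expected_sites(codon)
        s_ref, n_ref = enumeration_oracle(codon)
        assert s == pytest.approx(s_ref, abs=1e-12)
        assert s + n == pytest.approx(3.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            expected_sites("TAA")  # stop
        with pytest.raises(ValueError):
            expected_sites("TNT")


def _pileup(ref_codon="GGC", counts=None, gene_id="g", n_codons=1):
    gene = GeneRecord(gene_id, 0, 3 * max(n_codons, 2) if n_codons == 1 else 3 * n_codons)
    ref = np.full(gene.n_codons, genetics.codon_index(genetics.encode(ref_codon)))
    mat = np.zeros((gene.n_codons, 64), dtype=np.int64)
    if counts:
        for codon, c in counts.items():
            mat[0, genetics.codon_index(genetics.encode(codon))] = c
    return GenePileup(gene, ref, mat)


class TestCallVariants:
    def test_count_rule(self):
        gp = _pileup("GGC", {"GGC": 997, "GGA": 3})
        assert len(call_codon_variants([gp])) == 0

    def test_coverage_rule(self):
        gp = _pileup("GGC", {"GGA": 4})  # coverage 4 < 5
        assert len(call_codon_variants([gp])) == 0

    def test_inclusive_boundaries(self):
        gp = _pileup("GGC", {"GGC": 3996, "GGA": 4})  # count 4, freq 0.001, cov 4000
        out = call_codon_variants([gp])
        assert len(out) == 1
        assert out.iloc[0].classification == "synonymous"
        assert out.iloc[0].frequency == pytest.approx(0.001)

    def test_multiple_alts_and_classification(self):
        gp = _pileup("GGC", {"GGC": 90, "GGT": 5, "AGC": 5})
        out = call_codon_variants([gp])
        assert set(out.alt_codon) == {"GGT", "AGC"}
        cls = dict(zip(out.alt_codon, out.classification))
        assert cls["GGT"] == "synonymous" and cls["AGC"] == "nonsynonymous"

    def test_matches_brute_force_scan(self):
        """Vectorized filter equals a per-pileup triple-predicate scan."""
        rng = np.random.default_rng(5)
        gene = GeneRecord("g", 0, 3 * 400)
        ref = rng.choice([genetics.codon_index(genetics.encode(c)) for c in SENSE], 400)
        counts = np.zeros((400, 64), dtype=np.int64)
        for k in range(400):
            cov = int(rng.integers(0, 50))
            obs = rng.multinomial(cov, np.full(64, 1 / 64))
            counts[k] = obs
        gp = GenePileup(gene, ref, counts)
        got = call_codon_variants([gp], min_count=2, min_freq=0.05, min_cov=5)
        expected = []
        for cp in gp.pileups():
            if cp.spanning_coverage < 5:
                continue
            if genetics.IS_STOP64[genetics.codon_index(genetics.encode(cp.ref_codon))]:
                continue
            for alt, c in cp.observed.items():
                if alt == cp.ref_codon:
                    continue
                if c >= 2 and c / cp.spanning_coverage >= 0.05:
                    expected.append((cp.codon_index, alt, c))
        got_set = set(zip(got.codon_index, got.alt_codon, got["count"]))
        assert got_set == set(expected)


class TestPileups:
    def test_read_covering_two_codon_gene(self, toy_genome):
        reads = make_reads([toy_genome.sequence[10:25]])
        aln = align_reads(reads, toy_genome, k=13)
        tables = {t.gene_id: t for t in build_codon_pileups(aln, toy_genome)}
        g1 = tables["g1"]
        assert (g1.spanning_coverage == 1).all()
        for k in range(g1.counts.shape[0]):
            assert g1.counts[k, g1.ref_codons[k]] == 1

    def test_partial_codon_contributes_nothing(self, toy_genome):
        # covers positions 10..21: codons 0-3 fully, codon 4 (22-24) not at all
        reads = make_reads([toy_genome.sequence[10:22]])
        aln = align_reads(reads, toy_genome, k=12)
        g1 = {t.gene_id: t for t in build_codon_pileups(aln, toy_genome)}["g1"]
        assert g1.spanning_coverage.tolist() == [1, 1, 1, 1, 0]

    def test_minus_strand_codon_in_gene_frame(self, toy_genome):
        reads = make_reads([toy_genome.sequence[38:58]])
        aln = align_reads(reads, toy_genome, k=13)
        g2 = {t.gene_id: t for t in build_codon_pileups(aln, toy_genome)}["g2"]
        assert (g2.spanning_coverage == 1).all()
        # observed codons equal the reverse-complement frame codons: ATG CCT GAA TAA
        for k, codon in enumerate(["ATG", "CCT", "GAA", "TAA"]):
            assert g2.counts[k, genetics.codon_index(genetics.encode(codon))] == 1

    def test_masked_gene_skipped(self, toy_genome):
        from popmicrodiv.seqio import mask_regions

        masked = mask_regions(toy_genome, [(12, 14)])
        reads = make_reads([toy_genome.sequence[0:40]])
        tables = build_codon_pileups(align_reads(reads, masked, k=13), masked)
        assert [t.gene_id for t in tables] == ["g2"]


class TestGeneStats:
    def test_no_variants(self):
        gp = _pileup("GGC", {"GGC": 50})
        table = gene_stats(call_codon_variants([gp]), [gp])
        row = table.iloc[0]
        assert row.pn == 0 and row.ps == 0 and row.pps == 0
        assert np.isnan(row.pnps)

    def test_zero_coverage_flagged(self):
        gp = _pileup("GGC", {})
        row = gene_stats(pd.DataFrame(), [gp]).iloc[0]
        assert row.covered_codons == 0
        assert np.isnan(row.pps)

    def test_single_synonymous_variant_scaling(self):
        """pS = 100 / S_exp for one synonymous variant position."""
        rng = np.random.default_rng(8)
        n_codons = 100
        gene = GeneRecord("g", 0, 3 * n_codons)
        ref = rng.choice([genetics.codon_index(genetics.encode(c)) for c in SENSE], n_codons)
        counts = np.zeros((n_codons, 64), dtype=np.int64)
        counts[np.arange(n_codons), ref] = 100
        # add one synonymous alt at codon 0: pick a codon with a 4-fold site
        ref[0] = genetics.codon_index(genetics.encode("GGC"))
        counts[0] = 0
        counts[0, ref[0]] = 90
        counts[0, genetics.codon_index(genetics.encode("GGA"))] = 10
        gp = GenePileup(gene, ref, counts)
        variants = call_codon_variants([gp])
        row = gene_stats(variants, [gp]).iloc[0]
        s_exp = genetics.SYN_SITES64[ref].sum()
        assert row.s_exp == pytest.approx(s_exp)
        assert row.ps == pytest.approx(100.0 / s_exp)
        assert row.pn == 0.0
        # exactly one nucleotide position polymorphic
        assert row.pps == pytest.approx(100.0 / (3 * n_codons))


class TestAggregate:
    def _table(self, pnps_values, pps=5.0):
        rows = []
        for i, v in enumerate(pnps_values):
            rows.append({
                "gene_id": f"g{i}", "covered_codons": 10, "s_exp": 7.0, "n_exp": 23.0,
                "n_syn": 1, "n_nonsyn": 1, "pn": 1.0, "ps": 2.0, "pnps": v, "pps": pps,
            })
        return pd.DataFrame(rows)

    def test_singleton(self):
        s = aggregate_genome(self._table([0.5]), rpkg=3.0, anir=95.0)
        assert s.median_pnps == 0.5 and s.mean_pps == 5.0
        assert s.rpkg == 3.0 and s.anir == 95.0

    def test_undefined_excluded_from_median_and_fraction(self):
        s = aggregate_genome(self._table([0.5, 1.5, np.nan]))
        assert s.median_pnps == pytest.approx(1.0)
        assert s.frac_pnps_gt1 == pytest.approx(0.5)

    def test_matches_brute_force_resummation(self):
        rng = np.random.default_rng(3)
        vals = rng.random(50) * 2
        vals[rng.random(50) < 0.2] = np.nan
        table = self._table(vals, pps=7.5)
        s = aggregate_genome(table)
        defined = sorted(v for v in vals if not np.isnan(v))
        assert s.median_pnps == pytest.approx(float(np.median(defined)))
        assert s.frac_pnps_gt1 == pytest.approx(sum(v > 1 for v in defined) / len(defined))
        assert s.mean_pps == pytest.approx(7.5)

    def test_empty_is_error(self):
        empty = self._table([np.nan])
        empty["covered_codons"] = 0
        with pytest.raises(ValueError):
            aggregate_genome(empty)


class TestEndToEndNeutrality:
    def test_purifying_limit_pn_zero(self):
        """omega=0, error-free reads: no nonsynonymous variant can pass."""
        g = simulate.generate_genome(30_000, 30, seed=17)
        pop = simulate.evolve_population(g, 10, theta=0.03, omega=0.0, seed=18)
        reads = simulate.simulate_reads(pop, 20_000, read_len=100, seed=19)
        aln = filter_alignments(align_reads(reads, g), 98.0, 50)
        pileups = build_codon_pileups(aln, g)
        variants = call_codon_variants(pileups)
        table = gene_stats(variants, pileups)
        assert len(variants) > 50
        assert (variants.classification == "synonymous").all()
        assert (table.pn.dropna() == 0).all()
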