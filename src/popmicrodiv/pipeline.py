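"""End-to-end driver: simulate -> QC -> recruit -> microdiversity ->
recombination, writing the standard TSV outputs.

Everything downstream of the seed is deterministic, so re-running with the
same parameters reproduces every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import microdiv, recombination, recruitment, seqio, simulate

#: the recruitment cutoffs used for abundance/microdiversity and for ANIr
STRICT_IDENTITY, ANIR_IDENTITY, MIN_ALEN = 98.0, 80.0, 50


@dataclass
class PipelineResult:
    pop: simulate.PopulationTruth
    aln_strict: recruitment.AlignmentSet
    aln_anir: recruitment.AlignmentSet
    gene_table: pd.DataFrame
    variants: pd.DataFrame
    summary: microdiv.GenomeSummary
    profile: recombination.CorrelationProfile
    estimate: recombination.RecombinationEstimate


def run_pipeline(
    seed: int,
    out_dir: str | Path | None = None,
    length: int = 60_000,
    n_genes: int = 80,
    gc: float = 0.35,
    n_lineages: int = 20,
    theta: float = 0.02,
    omega: float = 0.1,
    rho_over_theta: float = 0.0,
    fbar: float = 500.0,
    n_reads: int = 60_000,
    read_len: int = 100,
    err_rate: float = 0.0,
    subsample: int | None = None,
    branch_model: str = "equal",
    max_l: int = 90,
) -> PipelineResult:
    """Run the whole chain on one synthetic population; write TSVs if
    ``out_dir`` is given."""
    genome = simulate.generate_genome(length, n_genes, gc=gc, seed=seed)
    pop = simulate.evolve_population(
        genome, n_lineages, theta, omega=omega, rho_over_theta=rho_over_theta,
        fbar=fbar, seed=seed + 1, branch_model=branch_model,
    )
    reads = simulate.simulate_reads(pop, n_reads, read_len=read_len,
                                    err_rate=err_rate, seed=seed + 2)
    reads = seqio.qc_filter_reads(reads)
    aln = recruitment.align_reads(reads, genome)
    aln_strict = recruitment.filter_alignments(aln, STRICT_IDENTITY, MIN_ALEN)
    aln_anir = recruitment.filter_alignments(aln, ANIR_IDENTITY, MIN_ALEN)
    if subsample is not None:
        aln_strict = recruitment.subsample_alignments(aln_strict, subsample, seed=seed + 3)

    rpkg = recruitment.compute_rpkg(aln_strict, genome.effective_length)
    anir_med, anir_mean, hist = recruitment.compute_anir(aln_anir)

    pileups = microdiv.build_codon_pileups(aln_strict, genome)
    variants = microdiv.call_codon_variants(pileups)
    gene_table = microdiv.gene_stats(variants, pileups)
    summary = microdiv.aggregate_genome(
        gene_table, rpkg=rpkg, anir=anir_med, genome_id=genome.id,
        sample_id=f"sim{seed}",
    )

    profile = recombination.correlation_profile(aln_strict, genome, max_l=max_l)
    estimate = recombination.fit_recombination(profile)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta([(genome.id, genome.sequence)], out / "reference.fasta")
        seqio.write_bed_genes(genome.genes, genome.id, out / "genes.bed")
        seqio.write_tsv(pop.variants, out / "truth.tsv")
        seqio.write_tsv(pop.recomb_events, out / "truth_events.tsv")
        seqio.write_tsv(gene_table, out / "gene_stats.tsv")
        seqio.write_tsv(variants, out / "variants.tsv")
        seqio.write_tsv(summary.as_frame(), out / "genome_summary.tsv")
        seqio.write_tsv(
            pd.DataFrame({
                "metric": ["rpkg", "anir_median", "anir_mean", "n_recruited_98", "n_recruited_80"],
                "value": [rpkg, anir_med, anir_mean, float(len(aln_strict)), float(len(aln_anir))],
            }),
            out / "recruitment.tsv",
        )
        edges, counts = hist
        seqio.write_tsv(
            pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}),
            out / "identity_hist.tsv",
        )
        seqio.write_tsv(profile.as_frame(), out / "profile.tsv")
        seqio.write_tsv(estimate.as_frame(), out / "recomb_fit.tsv")
    return PipelineResult(pop, aln_strict, aln_anir, gene_table, variants, summary,
                          profile, estimate)
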