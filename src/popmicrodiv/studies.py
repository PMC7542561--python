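"""Canonical synthetic study conditions used by the validation suite and the
reproduction script.

Each function simulates a population under fixed scientific conditions
(deriving sub-seeds from one master seed), runs the relevant pipeline stage,
and returns the measured quantities.  The conditions themselves — divergence
levels, lineage frequency spectra, read depths, recombination grid — are part
of the study design and are documented in the methods note; they are not
tuning knobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import microdiv, recombination, recruitment, simulate, trees

_M = 2**31 - 1  # keep derived seeds in int32 range


def _sub(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % _M


# ---------------------------------------------------------------------------
# microdiversity: neutral and purifying endpoints, coverage invariance
# ---------------------------------------------------------------------------

def microdiversity_endpoint(seed: int, omega: float, coverage: float = 50.0):
    """One endpoint simulation: 200 genes, theta=0.02, error-free reads at the
    given coverage; returns (genome summary, variants table)."""
    genome = simulate.generate_genome(140_000, 200, seed=_sub(seed, 1))
    pop = simulate.evolve_population(
        genome, 10, theta=0.02, omega=omega, seed=_sub(seed, 2)
    )
    n_reads = int(coverage * len(genome) / 100)
    reads = simulate.simulate_reads(pop, n_reads, read_len=100, err_rate=0.0,
                                    seed=_sub(seed, 3))
    aln = recruitment.filter_alignments(
        recruitment.align_reads(reads, genome), 98.0, 50
    )
    pileups = microdiv.build_codon_pileups(aln, genome)
    variants = microdiv.call_codon_variants(pileups)
    table = microdiv.gene_stats(variants, pileups)
    return microdiv.aggregate_genome(table), variants, table


def neutral_limit(seed: int, n_seeds: int = 3) -> list[float]:
    """Median genome pN/pS under neutral evolution (omega=1), one value per
    replicate seed; expected-site normalization should hold them near 1."""
    return [
        microdiversity_endpoint(_sub(seed, 10 + i), omega=1.0)[0].median_pnps
        for i in range(n_seeds)
    ]


def purifying_limit(seed: int):
    """omega=0: no nonsynonymous variant can exist; pN must be identically 0."""
    summary, variants, table = microdiversity_endpoint(_sub(seed, 20), omega=0.0)
    return summary, variants, table


#: lineage frequency spectrum for the depth study: a common tier detectable at
#: ~50x and a rare tier that only ~500x resolves (so PPS grows with depth
#: while the pN/pS ratio, fed proportionally by both tiers, stays put)
def _tiered_frequencies() -> np.ndarray:
    f = np.concatenate([np.full(8, 0.75 / 8), np.full(15, 0.25 / 15)])
    return f / f.sum()


def coverage_invariance(seed: int, depths=(100_000, 1_000_000)):
    """pN/pS and PPS at fixed subsample depths from one deep simulation."""
    genome = simulate.generate_genome(200_000, 140, seed=_sub(seed, 31),
                                      min_gene_len=900, max_gene_len=1500)
    pop = simulate.evolve_population(
        genome, 23, theta=0.007, omega=0.45, seed=_sub(seed, 32),
        frequencies=_tiered_frequencies(),
    )
    reads = simulate.simulate_reads(pop, int(1.15 * max(depths)), read_len=100,
                                    err_rate=0.0, seed=_sub(seed, 33))
    aln = recruitment.filter_alignments(
        recruitment.align_reads(reads, genome), 98.0, 50
    )
    out = {}
    for n in depths:
        sub = recruitment.subsample_alignments(aln, n, seed=_sub(seed, 34))
        pileups = microdiv.build_codon_pileups(sub, genome)
        table = microdiv.gene_stats(microdiv.call_codon_variants(pileups), pileups)
        out[n] = microdiv.aggregate_genome(table)
    return out


# ---------------------------------------------------------------------------
# recruitment: ANIr recovery and RPKG algebra
# ---------------------------------------------------------------------------

def anir_recovery(seed: int):
    """Population at uniform 5% divergence, error-free reads, 80% recruitment
    cutoff; returns (median, mean) ANIr, expected at 95.0."""
    genome = simulate.generate_genome(100_000, 100, seed=_sub(seed, 41))
    pop = simulate.evolve_population(
        genome, 20, theta=0.05, omega=1.0, seed=_sub(seed, 42), divergence="exact"
    )
    reads = simulate.simulate_reads(pop, 100_000, read_len=100, err_rate=0.0,
                                    seed=_sub(seed, 43))
    aln = recruitment.filter_alignments(
        recruitment.align_reads(reads, genome), 80.0, 50
    )
    med, mean, _ = recruitment.compute_anir(aln)
    return med, mean, len(aln)


def rpkg_algebra() -> dict[str, float]:
    """Deterministic RPKG arithmetic: metagenome-size linearity and the
    masked-length denominator."""
    n = 1_000
    aln = recruitment.AlignmentSet(
        "g", np.zeros(n, np.int64), np.full(n, 100), np.full(n, 100),
        np.zeros(n, np.uint8), np.arange(n + 1), metagenome_bases=10**9,
        metagenome_reads=n, mean_read_len=100.0,
    )
    base = recruitment.compute_rpkg(aln, 10**6)
    aln_half = recruitment.AlignmentSet(
        "g", np.zeros(n, np.int64), np.full(n, 100), np.full(n, 100),
        np.zeros(n, np.uint8), np.arange(n + 1), metagenome_bases=5 * 10**8,
        metagenome_reads=n, mean_read_len=100.0,
    )
    return {
        "base": base,
        "half_metagenome": recruitment.compute_rpkg(aln_half, 10**6),
        "masked_10pct": recruitment.compute_rpkg(aln, int(0.9 * 10**6)),
    }


# ---------------------------------------------------------------------------
# recombination: rank recovery over a rho_over_theta grid
# ---------------------------------------------------------------------------

#: study conditions for the recombination grid (see methods note): 1 Mb
#: genome so the 4-fold site-pair pool, not read depth, no longer limits the
#: profile; theta*fbar chosen to keep the fragment-coverage intensity
#: lambda = rho*theta*fbar inside the identifiable range
RECOMB_CONDITIONS = dict(
    length=1_000_000, n_genes=1_000, theta=0.0025, fbar=100.0,
    n_lineages=80, n_reads=250_000, read_len=400, max_l=380,
)


def recombination_estimate(seed: int, rho_over_theta: float, genome=None):
    p = RECOMB_CONDITIONS
    if genome is None:
        genome = simulate.generate_genome(p["length"], p["n_genes"], seed=_sub(seed, 51))
    pop = simulate.evolve_population(
        genome, p["n_lineages"], theta=p["theta"], omega=1.0,
        rho_over_theta=rho_over_theta, fbar=p["fbar"], seed=_sub(seed, 52),
        branch_model="exponential",
    )
    reads = simulate.simulate_reads(pop, p["n_reads"], read_len=p["read_len"],
                                    err_rate=0.0, seed=_sub(seed, 53))
    aln = recruitment.filter_alignments(
        recruitment.align_reads(reads, genome), 98.0, 50
    )
    profile = recombination.correlation_profile(aln, genome, max_l=p["max_l"])
    return pop, recombination.fit_recombination(profile)


def recombination_grid(seed: int, rhos=(0.0, 5.0, 20.0), n_seeds: int = 5):
    """Median gamma/mu and c per rho level (one shared reference genome)."""
    p = RECOMB_CONDITIONS
    genome = simulate.generate_genome(p["length"], p["n_genes"], seed=_sub(seed, 50))
    rows = []
    for rho in rhos:
        for i in range(n_seeds):
            pop, est = recombination_estimate(_sub(seed, 60 + 10 * int(rho) + i),
                                              rho, genome=genome)
            rows.append((rho, i, pop.true_c, est.gamma_over_mu, est.c))
    df = pd.DataFrame(rows, columns=["rho_over_theta", "rep", "true_c",
                                     "gamma_over_mu", "c"])
    med = df.groupby("rho_over_theta")[["gamma_over_mu", "c", "true_c"]].median()
    return df, med


# ---------------------------------------------------------------------------
# tree congruence
# ---------------------------------------------------------------------------

CONGRUENCE_TREE = (
    "(((A:0.2,B:0.2):0.25,(C:0.2,D:0.2):0.25):0.2,"
    "((E:0.2,F:0.2):0.25,(G:0.2,H:0.2):0.25):0.2):0;"
)
FOCAL_SPLITS = [{"A", "B", "C", "D"}, {"A", "B"}, {"C", "D"}]


def congruence_study(seed: int, n_transfer: int = 20):
    """50-gene, 8-leaf simulation: support for the three deepest branches
    before and after transferring ``n_transfer`` whole genes across the root
    split (E -> A)."""
    genome = simulate.generate_genome(45_000, 50, seed=_sub(seed, 71),
                                      min_gene_len=600, max_gene_len=900)
    pop = simulate.evolve_population(genome, 0, theta=0.08, omega=1.0,
                                     seed=_sub(seed, 72), tree=CONGRUENCE_TREE)
    leaves = set(pop.params["leaf_names"])
    focal = [trees.normalize_bipartition(s, leaves) for s in FOCAL_SPLITS]

    ref = trees.concat_tree(trees.gene_alignments_from_population(pop))

    def report(p):
        alns = trees.gene_alignments_from_population(p)
        gene_trees = {
            genome.genes[i].gene_id: trees.nj_tree(alns[i]) for i in range(len(alns))
        }
        return trees.congruence_counts(gene_trees, ref, focal)

    before = report(pop)
    names = pop.params["leaf_names"]
    donor, recipient = names.index("E"), names.index("A")
    for gene in genome.genes[:n_transfer]:
        simulate.transfer_gene(pop, gene.gene_id, donor=donor, recipient=recipient)
    after = report(pop)
    return before, after
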