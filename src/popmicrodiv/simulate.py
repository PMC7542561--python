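"""Synthetic community generator: annotated reference genomes, a
lineage-structured population with controlled mutation/selection/recombination,
and shotgun reads with full ground truth.

The population model is deliberately simple so that every downstream estimator
can be validated against exactly computable truth:

* lineages radiate from the reference (star phylogeny) or, optionally, along a
  user-supplied guide tree;
* selection is an acceptance/rejection rule at mutation time: an attempted
  nonsynonymous coding change is accepted with probability ``omega``, otherwise
  it is resampled among the synonymous alternatives of the same site;
* homologous recombination copies geometric-length fragments between lineages,
  applied sequentially, which yields a "most recent event wins" ancestry mosaic.

Per-lineage divergence times ``t_k`` default to 1 (the homogeneous model).
``branch_model="exponential"`` scales them by fixed exponential quantiles,
mimicking the pair-coalescence-time heterogeneity that real populations carry;
without that heterogeneity a reference-based correlation profile is flat and
carries no linkage signal, so the recombination analyses use this mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import genetics
from .genetics import AA64, COMP, SYN_NEIGHBOUR
from .seqio import AnnotatedGenome, GeneRecord, ReadSet

logger = logging.getLogger("popmicrodiv")

_AA_ID64 = np.searchsorted(np.unique(AA64), AA64)  # amino acid as small int per codon
_STOP_ID = int(_AA_ID64[genetics.codon_index(genetics.encode("TAA"))])


# ---------------------------------------------------------------------------
# reference genome generation
# ---------------------------------------------------------------------------

def generate_genome(
    length: int,
    n_genes: int,
    gc: float = 0.4,
    seed: int = 0,
    min_gene_len: int = 300,
    max_gene_len: int = 900,
    min_spacer: int = 20,
    genome_id: str = "synth1",
) -> AnnotatedGenome:
    """Generate a random annotated genome: non-overlapping genes (ATG start, no
    in-frame stops, stop codon included) tiled with intergenic spacers.

    Deterministic for a fixed seed.  Raises if the requested genes cannot be
    packed into ``length`` with the minimum spacers.
    """
    rng = np.random.default_rng(seed)
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0,1)")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    lens = 3 * rng.integers(min_gene_len // 3, max_gene_len // 3 + 1, size=n_genes)
    demand = int(lens.sum()) + (n_genes + 1) * min_spacer
    if demand > length:
        raise ValueError(
            f"cannot pack {n_genes} genes (total {int(lens.sum())} bp"
            f" + {(n_genes + 1) * min_spacer} bp spacers = {demand} bp) into {length} bp"
        )

    # split the slack over the n_genes+1 gaps at random
    slack = length - demand
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes)) if slack > 0 else np.zeros(n_genes, dtype=int)
    gaps = np.diff(np.concatenate(([0], cuts, [slack]))) + min_spacer

    seq = rng.choice(4, size=length, p=probs).astype(np.uint8)
    genes: list[GeneRecord] = []
    cursor = 0
    for gi in range(n_genes):
        cursor += int(gaps[gi])
        glen = int(lens[gi])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_seq = _random_cds(glen, probs, rng)
        if strand == "-":
            gene_seq = genetics.revcomp_codes(gene_seq)
        seq[cursor : cursor + glen] = gene_seq
        genes.append(GeneRecord(f"gene{gi + 1:04d}", cursor, cursor + glen, strand))
        cursor += glen
    return AnnotatedGenome(id=genome_id, sequence=genetics.decode(seq), genes=genes)


def _random_cds(glen: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """ATG + interior sense codons (no in-frame stop) + one stop codon."""
    n_codons = glen // 3
    cod = rng.choice(4, size=(n_codons, 3), p=probs).astype(np.uint8)
    cod[0] = genetics.encode("ATG")
    idx = 16 * cod[:, 0].astype(int) + 4 * cod[:, 1] + cod[:, 2]
    bad = np.flatnonzero(genetics.IS_STOP64[idx])
    while bad.size:
        cod[bad] = rng.choice(4, size=(bad.size, 3), p=probs).astype(np.uint8)
        idx = 16 * cod[:, 0].astype(int) + 4 * cod[:, 1] + cod[:, 2]
        bad = np.flatnonzero(genetics.IS_STOP64[idx])
    stops = [genetics.encode(s) for s in ("TAA", "TAG", "TGA")]
    w = np.array([np.prod(probs[s]) for s in stops])
    cod[-1] = stops[rng.choice(3, p=w / w.sum())]
    return cod.reshape(-1)


# ---------------------------------------------------------------------------
# population truth
# ---------------------------------------------------------------------------

@dataclass
class PopulationTruth:
    """Ground truth of an evolved population.

    ``haplotypes`` is the (n_lineages, genome_length) base-code matrix;
    ``ancestry[k, i]`` is the lineage whose mutation history produced base
    ``i`` of lineage ``k`` (== k where no recombination touched the site).
    ``variants`` has one row per accepted substitution (position, base before,
    base after, lineage it was applied to, classification).
    """

    reference: AnnotatedGenome
    haplotypes: np.ndarray
    frequencies: np.ndarray
    variants: pd.DataFrame
    recomb_events: pd.DataFrame
    params: dict = field(default_factory=dict)
    ancestry: np.ndarray | None = None

    @property
    def n_lineages(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def lineages(self) -> list[tuple[str, float]]:
        return [
            (genetics.decode(self.haplotypes[k]), float(self.frequencies[k]))
            for k in range(self.n_lineages)
        ]

    @property
    def true_c(self) -> float:
        """Fraction of the sampled genome whose ancestry is recombinant."""
        if self.ancestry is None:
            return 0.0
        native = self.ancestry == np.arange(self.n_lineages)[:, None]
        return float(np.average(1.0 - native.mean(axis=1), weights=self.frequencies))


class _SiteContext:
    """Per-position coding context of a genome, for fast mutation bookkeeping."""

    def __init__(self, genome: AnnotatedGenome) -> None:
        L = len(genome)
        self.gene_of = np.full(L, -1, dtype=np.int32)
        self.frame_pos = np.full(L, -1, dtype=np.int8)  # 0..2 in gene frame
        self.codon_sites = np.full((L, 3), -1, dtype=np.int64)  # genome coords, gene frame
        self.minus = np.zeros(L, dtype=bool)
        for gi, gene in enumerate(genome.genes):
            pos = gene.codon_positions()  # (n_codons, 3) in gene frame
            flat = pos.reshape(-1)
            self.gene_of[flat] = gi
            self.frame_pos[flat] = np.tile(np.arange(3, dtype=np.int8), gene.n_codons)
            self.codon_sites[flat] = np.repeat(pos, 3, axis=0)
            if gene.strand == "-":
                self.minus[flat] = True


def _lineage_times(n_lineages: int, branch_model: str) -> np.ndarray:
    if branch_model == "equal":
        return np.ones(n_lineages)
    if branch_model == "exponential":
        # fixed exponential quantiles: coalescent-like heterogeneity, mean ~1,
        # reproducible across seeds (the heterogeneity is a study condition,
        # not noise)
        q = (np.arange(n_lineages) + 0.5) / n_lineages
        return -np.log(q)
    raise ValueError(f"unknown branch_model {branch_model!r}")


def evolve_population(
    genome: AnnotatedGenome,
    n_lineages: int,
    theta: float,
    omega: float = 1.0,
    rho_over_theta: float = 0.0,
    fbar: float = 500.0,
    seed: int = 0,
    branch_model: str = "equal",
    divergence: str = "poisson",
    frequencies: Sequence[float] | None = None,
    tree=None,
) -> PopulationTruth:
    """Evolve ``n_lineages`` haplotypes from the reference.

    theta
        Expected per-site mutational divergence of a lineage (attempted
        substitutions per site); must lie in (0, 0.25].
    omega
        Probability that an attempted nonsynonymous coding substitution is
        accepted; rejected attempts are resampled among the synonymous
        alternatives of the same site (discarded if none exist).
    rho_over_theta, fbar
        Attempted recombination events per attempted mutation, and the mean
        (geometric) recombined fragment length in bp.
    divergence
        "poisson" draws Poisson(theta*t_k*L) attempts per lineage;
        "exact" realises exactly round(theta*t_k*L) *accepted* substitutions at
        distinct sites (uniform realized divergence, e.g. for ANIr conditions).
    tree
        Optional guide tree (newick string or skbio TreeNode with branch
        lengths); mutations are then placed branch-wise and shared by all
        descendant leaves, and ``n_lineages``/``branch_model`` are ignored.
    """
    if not 0.0 < theta <= 0.25:
        raise ValueError("theta must be in (0, 0.25]: larger divergence leaves the sequence-discrete regime")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0, 1]")
    if rho_over_theta < 0:
        raise ValueError("rho_over_theta must be >= 0")
    if rho_over_theta > 0 and fbar < 100:
        raise ValueError("fbar must be >= 100 bp")

    rng = np.random.default_rng(seed)
    L = len(genome)
    ctx = _SiteContext(genome)
    ref = genome.codes.copy()
    if ref.max(initial=0) > 3:
        raise ValueError("reference contains non-ACGT bases")

    rows: list[tuple] = []
    total_attempts = 0

    if tree is not None:
        hap, leaf_names, total_attempts = _evolve_on_tree(
            genome, ref, ctx, tree, theta, omega, rng, rows
        )
        n_lineages = hap.shape[0]
    else:
        times = _lineage_times(n_lineages, branch_model)
        hap = np.tile(ref, (n_lineages, 1))
        leaf_names = [f"lineage{k}" for k in range(n_lineages)]
        for k in range(n_lineages):
            target = theta * times[k] * L
            if divergence == "poisson":
                total_attempts += _mutate(
                    hap[k], ctx, int(rng.poisson(target)), omega, rng, rows, k, exact=False
                )
            elif divergence == "exact":
                total_attempts += _mutate(
                    hap[k], ctx, int(round(target)), omega, rng, rows, k, exact=True
                )
            else:
                raise ValueError(f"unknown divergence mode {divergence!r}")

    n_accepted = len(rows)

    ancestry = np.tile(np.arange(n_lineages, dtype=np.int16)[:, None], (1, L))
    ev_rows = []
    if rho_over_theta > 0 and n_lineages > 1:
        # fragments are drawn from the donor's clonal background (no serial
        # transfer of already-imported material); later events overwrite
        # earlier ones, yielding a most-recent-event ancestry mosaic whose
        # fragment scale stays at fbar
        snapshot = hap.copy()
        n_events = int(rng.poisson(rho_over_theta * total_attempts))
        recips = rng.integers(0, n_lineages, size=n_events)
        donors = rng.integers(0, n_lineages - 1, size=n_events)
        donors[donors >= recips] += 1  # uniform over lineages != recipient
        starts = rng.integers(0, L, size=n_events)
        lens = rng.geometric(1.0 / fbar, size=n_events)
        for i in range(n_events):
            s = int(starts[i])
            e = min(L, s + int(lens[i]))
            d, r = int(donors[i]), int(recips[i])
            hap[r, s:e] = snapshot[d, s:e]
            ancestry[r, s:e] = d
            ev_rows.append((d, r, s, e))

    freqs = (
        np.full(n_lineages, 1.0 / n_lineages)
        if frequencies is None
        else np.asarray(frequencies, dtype=float)
    )
    if len(freqs) != n_lineages or not np.isclose(freqs.sum(), 1.0):
        raise ValueError("lineage frequencies must sum to 1 (one per lineage)")

    variants = pd.DataFrame(
        rows, columns=["position", "ref", "alt", "lineage", "classification"]
    )
    events = pd.DataFrame(ev_rows, columns=["donor", "recipient", "start", "end"])
    params = dict(
        theta=theta, omega=omega, rho_over_theta=rho_over_theta, fbar=fbar, seed=seed,
        branch_model=branch_model, divergence=divergence, n_lineages=n_lineages,
        leaf_names=leaf_names, total_attempted_mutations=total_attempts,
        accepted_mutations=n_accepted,
    )
    logger.info(
        "evolve_population: %d lineages, %d accepted substitutions, %d recombination events",
        n_lineages, n_accepted, len(ev_rows),
    )
    return PopulationTruth(
        reference=genome, haplotypes=hap, frequencies=freqs, variants=variants,
        recomb_events=events, params=params, ancestry=ancestry,
    )


def _mutate(
    hap: np.ndarray,
    ctx: _SiteContext,
    n: int,
    omega: float,
    rng: np.random.Generator,
    rows: list,
    lineage: int,
    exact: bool,
) -> int:
    """Apply mutations to ``hap`` in place; returns the number of attempts made.

    ``exact=False``: ``n`` is the number of *attempts* (some may be discarded).
    ``exact=True``: exactly ``n`` substitutions are accepted, at distinct sites.
    """
    L = hap.shape[0]
    if exact:
        if n > L:
            raise ValueError("exact divergence mode: more substitutions requested than sites")
        attempts = iter(rng.permutation(L))
    done = 0
    k = 0
    n_attempts = 0
    while (done < n) if exact else (k < n):
        if exact:
            p = int(next(attempts))
        else:
            p = int(rng.integers(0, L))
            k += 1
        n_attempts += 1
        cur = int(hap[p])
        alt = (cur + 1 + int(rng.integers(0, 3))) % 4
        gi = ctx.gene_of[p]
        if gi < 0:
            cls = "intergenic"
        else:
            sites = ctx.codon_sites[p]
            frame = int(ctx.frame_pos[p])
            cod = hap[sites]
            if ctx.minus[p]:
                cod = COMP[cod]
                alt_frame = int(COMP[alt])
            else:
                alt_frame = alt
            ci = 16 * int(cod[0]) + 4 * int(cod[1]) + int(cod[2])
            if SYN_NEIGHBOUR[ci, frame, alt_frame]:
                cls = "synonymous"
            elif rng.random() < omega:
                cls = "nonsynonymous"
            else:
                syn_alts = np.flatnonzero(SYN_NEIGHBOUR[ci, frame])
                if syn_alts.size == 0:
                    continue  # attempt discarded
                alt_frame = int(syn_alts[rng.integers(0, syn_alts.size)])
                alt = int(COMP[alt_frame]) if ctx.minus[p] else alt_frame
                cls = "synonymous"
        hap[p] = alt
        rows.append((p, genetics.BASES[cur], genetics.BASES[alt], lineage, cls))
        done += 1
    return n_attempts


def _evolve_on_tree(genome, ref, ctx, tree, theta, omega, rng, rows):
    """Evolve along a guide tree: each branch gets Poisson(theta*bl*L) attempts
    applied to the ancestral haplotype, inherited by all descendant leaves."""
    from skbio import TreeNode

    if isinstance(tree, str):
        import io as _io

        tree = TreeNode.read(_io.StringIO(tree))
    L = ref.shape[0]
    leaves = list(tree.tips())
    leaf_names = [t.name for t in leaves]
    leaf_index = {t.name: i for i, t in enumerate(leaves)}
    hap = np.zeros((len(leaves), L), dtype=np.uint8)
    attempts = 0

    def recurse(node, anc_hap):
        nonlocal attempts
        h = anc_hap
        if node.length:
            h = anc_hap.copy()
            n_att = int(rng.poisson(theta * float(node.length) * L))
            label = leaf_index[node.name] if node.is_tip() else -1
            attempts += _mutate(h, ctx, n_att, omega, rng, rows, label, exact=False)
        if node.is_tip():
            hap[leaf_index[node.name]] = h
        else:
            for child in node.children:
                recurse(child, h)

    recurse(tree, ref.copy())
    return hap, leaf_names, attempts


def transfer_gene(pop: PopulationTruth, gene_id: str, donor: int, recipient: int) -> None:
    """Copy one whole gene from ``donor`` into ``recipient`` (homologous,
    same coordinates), logging it as a recombination event."""
    gene = next(g for g in pop.reference.genes if g.gene_id == gene_id)
    pop.haplotypes[recipient, gene.start : gene.end] = pop.haplotypes[donor, gene.start : gene.end]
    if pop.ancestry is not None:
        pop.ancestry[recipient, gene.start : gene.end] = pop.ancestry[donor, gene.start : gene.end]
    pop.recomb_events.loc[len(pop.recomb_events)] = (donor, recipient, gene.start, gene.end)


# ---------------------------------------------------------------------------
# shotgun reads
# ---------------------------------------------------------------------------

def simulate_reads(
    pop: PopulationTruth,
    n_reads: int,
    read_len: int = 100,
    err_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Draw error-prone single-end reads from the population.

    Reads come from lineages proportionally to their frequencies, start
    positions are uniform, and each base is substituted with probability
    ``err_rate`` (uniformly among the 3 alternatives).  Phred qualities are the
    constant consistent with ``err_rate`` (Q40 when error-free).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= err_rate <= 0.05:
        raise ValueError("err_rate must be in [0, 0.05]")
    L = pop.haplotypes.shape[1]
    if read_len > L:
        raise ValueError("read_len exceeds haplotype length")
    rng = np.random.default_rng(seed)
    lineage = rng.choice(pop.n_lineages, size=n_reads, p=pop.frequencies).astype(np.int32)
    start = rng.integers(0, L - read_len + 1, size=n_reads)
    q = 40 if err_rate == 0 else min(40, int(round(-10 * np.log10(err_rate))))

    bases = np.empty(n_reads * read_len, dtype=np.uint8)
    offs = np.arange(n_reads + 1, dtype=np.int64) * read_len
    chunk = 100_000
    col = np.arange(read_len)
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        block = pop.haplotypes[lineage[lo:hi, None], start[lo:hi, None] + col[None, :]]
        if err_rate > 0:
            emask = rng.random(block.shape) < err_rate
            n_err = int(emask.sum())
            if n_err:
                block[emask] = (block[emask] + rng.integers(1, 4, size=n_err)) % 4
        bases[lo * read_len : hi * read_len] = block.reshape(-1)
    quals = np.full(n_reads * read_len, q, dtype=np.uint8)
    return ReadSet(bases, offs, quals, ids=None, lineages=lineage)


# ---------------------------------------------------------------------------
# ground-truth summary statistics
# ---------------------------------------------------------------------------

@dataclass
class TrueSummary:
    gene_stats: pd.DataFrame
    mean_ref_identity: float      # mean lineage-vs-reference identity, % (ANIr target)
    mean_pairwise_identity: float  # mean lineage-vs-lineage identity, %
    median_pnps: float
    mean_pps: float
    true_c: float


def true_summary(pop: PopulationTruth) -> TrueSummary:
    """Ground-truth per-gene pN/pS/PPS and identity, from haplotypes directly."""
    genome = pop.reference
    H = pop.haplotypes
    ref = genome.codes
    n_lin, L = H.shape
    unmasked = ~genome.mask_array()

    diff = (H != ref[None, :]) & unmasked[None, :]
    ref_id = 100.0 * (1.0 - np.average(diff.sum(axis=1) / unmasked.sum(), weights=pop.frequencies))

    if n_lin > 1:
        pid = []
        w = []
        for a in range(n_lin):
            for b in range(a + 1, n_lin):
                d = np.count_nonzero((H[a] != H[b]) & unmasked)
                pid.append(1.0 - d / unmasked.sum())
                w.append(pop.frequencies[a] * pop.frequencies[b])
        pair_id = 100.0 * float(np.average(pid, weights=w))
    else:
        pair_id = 100.0

    rows = []
    for gene in genome.genes:
        pos = gene.codon_positions()
        ref_cod = genome.gene_ref_codons(gene)
        sense = ~genetics.IS_STOP64[ref_cod]
        bases = H[:, pos]  # (n_lin, n_codons, 3)
        if gene.strand == "-":
            bases = COMP[bases]
        cij = (16 * bases[..., 0].astype(np.int64) + 4 * bases[..., 1] + bases[..., 2])
        aa = _AA_ID64[cij]
        aa_ref = _AA_ID64[ref_cod]
        is_var = cij != ref_cod[None, :]
        syn_any = ((is_var & (aa == aa_ref[None, :])).any(axis=0)) & sense
        nonsyn_any = ((is_var & (aa != aa_ref[None, :])).any(axis=0)) & sense
        s_exp = float(genetics.SYN_SITES64[ref_cod[sense]].sum())
        n_exp = float(3.0 * sense.sum() - s_exp)
        base_var = (bases != _gene_ref_bases(genome, gene)[None, :, :]).any(axis=0)
        pps = 100.0 * base_var[sense].mean() if sense.any() else np.nan
        ps = 100.0 * syn_any.sum() / s_exp if s_exp > 0 else np.nan
        pn = 100.0 * nonsyn_any.sum() / n_exp if n_exp > 0 else np.nan
        pnps = pn / ps if ps and ps > 0 else np.nan
        rows.append((gene.gene_id, int(sense.sum()), s_exp, n_exp,
                     int(syn_any.sum()), int(nonsyn_any.sum()), pn, ps, pnps, pps))
    df = pd.DataFrame(rows, columns=[
        "gene_id", "sense_codons", "s_exp", "n_exp", "n_syn", "n_nonsyn",
        "pn", "ps", "pnps", "pps",
    ])
    defined = df["pnps"].dropna()
    return TrueSummary(
        gene_stats=df,
        mean_ref_identity=float(ref_id),
        mean_pairwise_identity=float(pair_id),
        median_pnps=float(defined.median()) if len(defined) else np.nan,
        mean_pps=float(df["pps"].mean()),
        true_c=pop.true_c,
    )


def _gene_ref_bases(genome: AnnotatedGenome, gene: GeneRecord) -> np.ndarray:
    b = genome.codes[gene.codon_positions()]
    return COMP[b] if gene.strand == "-" else b
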