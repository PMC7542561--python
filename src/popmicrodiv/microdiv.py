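"""Codon-level polymorphism statistics from recruited alignments.

The chain is: codon pileups (only reads spanning all three positions of a
codon contribute) -> codon variants under three joint filters (absolute count,
frequency among spanning reads, coverage) -> per-gene pN, pS, pN/pS and the
percentage of polymorphic sites (PPS) -> genome-level aggregation.

Expected synonymous/nonsynonymous site counts use Nei-Gojobori fractional
site counting: each codon position contributes (number of synonymous
single-base alternatives)/3 synonymous sites, the remainder nonsynonymous, so
s + n = 3 for every sense codon.  Under neutrality a uniform substitution
process then yields pN/pS = 1 by construction, which is the module's main
calibration property.  Reference stop codons are excluded throughout.

pN and pS are reported per 100 expected sites (percent scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genetics
from .genetics import AA64, SYN_SITES64
from .recruitment import AlignmentSet
from .seqio import AnnotatedGenome, GeneRecord

logger = logging.getLogger("popmicrodiv")

_AA_ID64 = np.searchsorted(np.unique(AA64), AA64)
# base identity of each codon index at each codon position
_BASE_AT = np.stack([(np.arange(64) >> s) & 3 for s in (4, 2, 0)], axis=0)  # (3, 64)


@dataclass(frozen=True)
class CodonPileup:
    """Observed codon counts at one (gene, codon) from codon-spanning reads."""

    gene_id: str
    codon_index: int
    ref_codon: str
    observed: dict[str, int]
    spanning_coverage: int


class GenePileup:
    """Dense codon-count table for one gene.

    ``counts[k, c]`` is the number of spanning reads observing codon ``c``
    (0..63) at codon ``k``; ``sense`` flags codons whose reference codon is
    not a stop (only those enter the statistics).
    """

    def __init__(self, gene: GeneRecord, ref_codons: np.ndarray, counts: np.ndarray) -> None:
        self.gene = gene
        self.gene_id = gene.gene_id
        self.ref_codons = np.asarray(ref_codons, dtype=np.int64)
        self.counts = np.asarray(counts, dtype=np.int64)
        self.sense = ~genetics.IS_STOP64[self.ref_codons]

    @property
    def spanning_coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def pileups(self) -> list[CodonPileup]:
        out = []
        cov = self.spanning_coverage
        for k in np.flatnonzero(cov >= 1):
            obs = {
                _codon_str(c): int(self.counts[k, c])
                for c in np.flatnonzero(self.counts[k])
            }
            out.append(
                CodonPileup(self.gene_id, int(k), _codon_str(int(self.ref_codons[k])),
                            obs, int(cov[k]))
            )
        return out


def _codon_str(ci: int) -> str:
    return genetics.BASES[(ci >> 4) & 3] + genetics.BASES[(ci >> 2) & 3] + genetics.BASES[ci & 3]


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

def build_codon_pileups(aln: AlignmentSet, genome: AnnotatedGenome) -> list[GenePileup]:
    """One dense pileup table per gene; reads partially covering a codon
    contribute nothing to it.  Genes overlapping masked regions are skipped."""
    masked = genome.masked
    tables: list[GenePileup] = []

    order = np.argsort(aln.ref_start, kind="stable")
    starts = aln.ref_start[order]
    spans = aln.span[order]
    uniform = len(spans) > 0 and bool((spans == spans[0]).all())

    for gene in genome.genes:
        if any(s < gene.end and gene.start < e for s, e in masked):
            logger.warning("build_codon_pileups: gene %s overlaps mask; skipped", gene.gene_id)
            continue
        ref_codons = genome.gene_ref_codons(gene)
        n_codons = gene.n_codons
        counts = np.zeros((n_codons, 64), dtype=np.int64)
        if len(aln) > 0:
            if uniform:
                _fill_counts_uniform(aln, order, starts, int(spans[0]), gene, counts)
            else:
                _fill_counts_general(aln, order, starts, spans, gene, counts)
        tables.append(GenePileup(gene, ref_codons, counts))
    return tables


def _codon_first_positions(gene: GeneRecord) -> np.ndarray:
    """Leftmost genome coordinate of each codon (gene-frame order)."""
    k = np.arange(gene.n_codons)
    return gene.start + 3 * k if gene.strand == "+" else gene.end - 3 - 3 * k


def _fill_counts_uniform(aln, order, starts, span, gene, counts):
    g0 = _codon_first_positions(gene)
    lo = np.searchsorted(starts, g0 + 3 - span, side="left")
    hi = np.searchsorted(starts, g0, side="right")
    reps = np.maximum(hi - lo, 0)
    total = int(reps.sum())
    if total == 0:
        return
    codon_flat = np.repeat(np.arange(gene.n_codons), reps)
    base = np.repeat(lo, reps)
    within = np.arange(total) - np.repeat(np.concatenate(([0], np.cumsum(reps)))[:-1], reps)
    ridx = order[base + within]  # indices into aln records
    col0 = np.repeat(g0, reps) - aln.ref_start[ridx]
    offs = aln.offsets[ridx]
    b0 = aln.bases[offs + col0]
    b1 = aln.bases[offs + col0 + 1]
    b2 = aln.bases[offs + col0 + 2]
    _accumulate(counts, codon_flat, b0, b1, b2, gene.strand)


def _fill_counts_general(aln, order, starts, spans, gene, counts):
    ends = starts + spans
    sel = np.flatnonzero((starts < gene.end) & (ends > gene.start))
    g0 = _codon_first_positions(gene)
    for j in sel:
        i = order[j]
        s, e = int(starts[j]), int(ends[j])
        ks = np.flatnonzero((g0 >= s) & (g0 + 3 <= e))
        if ks.size == 0:
            continue
        off = int(aln.offsets[i])
        c0 = g0[ks] - s + off
        _accumulate(counts, ks, aln.bases[c0], aln.bases[c0 + 1], aln.bases[c0 + 2], gene.strand)


def _accumulate(counts, codon_flat, b0, b1, b2, strand):
    if strand == "-":
        # gene-frame codon reads right-to-left complemented on the genome
        b0, b1, b2 = genetics.COMP[b2], genetics.COMP[b1], genetics.COMP[b0]
    valid = (b0 <= 3) & (b1 <= 3) & (b2 <= 3)
    ci = 16 * b0[valid].astype(np.int64) + 4 * b1[valid] + b2[valid]
    flat = codon_flat[valid] * 64 + ci
    counts.reshape(-1)[:] += np.bincount(flat, minlength=counts.size)


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

def call_codon_variants(
    pileups: list[GenePileup],
    min_count: int = 4,
    min_freq: float = 0.001,
    min_cov: int = 5,
) -> pd.DataFrame:
    """Emit every alternative codon passing all three filters jointly:
    count >= min_count, frequency among spanning reads >= min_freq, and
    spanning coverage >= min_cov (all boundaries inclusive).

    Returns one row per (gene, codon, alt codon) with its classification by
    direct translation of the observed codon against the reference codon.
    """
    rows = []
    for gp in pileups:
        cov = gp.spanning_coverage
        eligible = (cov >= min_cov) & gp.sense
        if not eligible.any():
            continue
        for k in np.flatnonzero(eligible):
            ci_ref = int(gp.ref_codons[k])
            c = gp.counts[k]
            alts = np.flatnonzero(
                (c >= min_count) & (c >= min_freq * cov[k]) & (np.arange(64) != ci_ref)
            )
            for a in alts:
                cls = "synonymous" if _AA_ID64[a] == _AA_ID64[ci_ref] else "nonsynonymous"
                rows.append(
                    (gp.gene_id, int(k), _codon_str(ci_ref), _codon_str(int(a)),
                     int(c[a]), float(c[a] / cov[k]), cls)
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "codon_index", "ref_codon", "alt_codon", "count", "frequency",
                 "classification"],
    )


# ---------------------------------------------------------------------------
# expected sites (Nei-Gojobori)
# ---------------------------------------------------------------------------

def expected_sites(ref_codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) expected site counts of a sense codon.

    Per position, the synonymous contribution is the fraction of the 3
    single-base alternatives that preserve the amino acid; changes creating a
    stop count as nonsynonymous.  s + n = 3 for every sense codon.
    """
    codes = genetics.encode(ref_codon)
    if len(codes) != 3 or codes.max() > 3:
        raise ValueError(f"not a valid codon: {ref_codon!r}")
    ci = genetics.codon_index(codes)
    if genetics.IS_STOP64[ci]:
        raise ValueError(f"{ref_codon} is a stop codon; excluded from site counting")
    s = float(SYN_SITES64[ci])
    return s, 3.0 - s


# ---------------------------------------------------------------------------
# gene and genome statistics
# ---------------------------------------------------------------------------

def gene_stats(
    variants: pd.DataFrame,
    pileups: list[GenePileup],
    min_cov: int = 5,
    min_count: int = 4,
    min_freq: float = 0.001,
) -> pd.DataFrame:
    """Per-gene pN, pS, pN/pS and PPS over sufficiently covered codons.

    A codon counts once per classification no matter how many alternative
    codons pass there.  PPS is nucleotide-level: a covered position is
    polymorphic if any alternative base at that position passes the count and
    frequency filters among codon-spanning reads.
    """
    var_by_gene = (
        {g: df for g, df in variants.groupby("gene_id")} if len(variants) else {}
    )
    rows = []
    for gp in pileups:
        cov = gp.spanning_coverage
        covered = (cov >= min_cov) & gp.sense
        n_covered = int(covered.sum())
        if n_covered == 0:
            rows.append((gp.gene_id, 0, np.nan, np.nan, 0, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        s_exp = float(SYN_SITES64[gp.ref_codons[covered]].sum())
        n_exp = 3.0 * n_covered - s_exp

        gv = var_by_gene.get(gp.gene_id)
        n_syn = n_nonsyn = 0
        if gv is not None:
            in_cov = gv["codon_index"].map(lambda k: bool(covered[k]))
            gv = gv[in_cov]
            n_syn = gv.loc[gv["classification"] == "synonymous", "codon_index"].nunique()
            n_nonsyn = gv.loc[gv["classification"] == "nonsynonymous", "codon_index"].nunique()

        # nucleotide-level PPS from per-position base counts
        kk = np.flatnonzero(covered)
        poly = 0
        for j in range(3):
            bc = np.zeros((len(kk), 4), dtype=np.int64)
            for b in range(4):
                bc[:, b] = gp.counts[kk][:, _BASE_AT[j] == b].sum(axis=1)
            refb = _BASE_AT[j, gp.ref_codons[kk]]
            bc[np.arange(len(kk)), refb] = 0  # reference base is not an alt
            passing = (bc >= min_count) & (bc >= min_freq * cov[kk][:, None])
            poly += int(passing.any(axis=1).sum())
        pps = 100.0 * poly / (3 * n_covered)

        pn = 100.0 * n_nonsyn / n_exp
        ps = 100.0 * n_syn / s_exp if s_exp > 0 else np.nan
        pnps = pn / ps if ps and ps > 0 else np.nan
        rows.append((gp.gene_id, n_covered, s_exp, n_exp, n_syn, n_nonsyn, pn, ps, pnps, pps))
    df = pd.DataFrame(rows, columns=[
        "gene_id", "covered_codons", "s_exp", "n_exp", "n_syn", "n_nonsyn",
        "pn", "ps", "pnps", "pps",
    ])
    return df


@dataclass
class GenomeSummary:
    """The per-(genome, sample) summary row."""

    genome_id: str
    sample_id: str
    n_genes: int
    mean_pps: float
    median_pnps: float
    mean_pn: float
    mean_ps: float
    frac_pnps_gt1: float
    rpkg: float = float("nan")
    anir: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def aggregate_genome(
    gene_table: pd.DataFrame,
    rpkg: float = float("nan"),
    anir: float = float("nan"),
    genome_id: str = "",
    sample_id: str = "",
) -> GenomeSummary:
    """Genome-level aggregation: mean PPS, median pN/pS over genes where it is
    defined, and the fraction of genes with pN/pS > 1 (among defined)."""
    ok = gene_table[gene_table["covered_codons"] > 0]
    if len(ok) == 0:
        raise ValueError("no gene has defined statistics")
    defined = ok["pnps"].dropna()
    return GenomeSummary(
        genome_id=genome_id,
        sample_id=sample_id,
        n_genes=len(ok),
        mean_pps=float(ok["pps"].mean()),
        median_pnps=float(defined.median()) if len(defined) else float("nan"),
        mean_pn=float(ok["pn"].mean()),
        mean_ps=float(ok["ps"].mean()),
        frac_pnps_gt1=float((defined > 1).mean()) if len(defined) else float("nan"),
        rpkg=float(rpkg),
        anir=float(anir),
    )
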