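"""Phylogenetic congruence: per-gene trees against a reference topology.

Heavily recombining populations scramble gene histories, so individual gene
trees fail to reproduce the deep branches of the genome (concatenated) tree.
This module clusters single-copy orthologs, builds neighbor-joining trees on
p-distances (topologies are all the congruence statistic needs, so distance
trees stand in for likelihood trees), and counts, per focal branch of the
reference tree, how many gene trees contain ("rescue") the same bipartition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from io import StringIO

import edlib
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger("popmicrodiv")

Bipartition = frozenset  # the side of the split not containing the anchor leaf


@dataclass
class OrthologSet:
    """One single-copy cluster: exactly one (aligned) sequence per genome."""

    cluster_id: str
    sequences: dict[str, str]
    alignment_length: int


@dataclass
class Tree:
    """Unrooted tree with leaf names and its non-trivial bipartition set."""

    root: TreeNode

    @property
    def leaves(self) -> frozenset:
        return frozenset(t.name for t in self.root.tips())

    def bipartitions(self) -> set[Bipartition]:
        leaves = self.leaves
        anchor = min(leaves)
        out: set[Bipartition] = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if anchor in side:
                side = leaves - side
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(Bipartition(side))
        return out

    def newick(self) -> str:
        buf = StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()


def normalize_bipartition(side, leaves) -> Bipartition:
    """Canonical form of a split given one side (anchor-free side is stored)."""
    side = frozenset(side)
    leaves = frozenset(leaves)
    if min(leaves) in side:
        side = leaves - side
    if not 2 <= len(side) <= len(leaves) - 2:
        raise ValueError("trivial bipartition")
    return Bipartition(side)


# ---------------------------------------------------------------------------
# single-copy ortholog clustering
# ---------------------------------------------------------------------------

def _pair_identity(a: str, b: str) -> tuple[float, float]:
    """(global identity over the longer sequence, shorter/longer length ratio)."""
    if len(a) < len(b):
        a, b = b, a
    ed = edlib.align(b, a, task="distance")["editDistance"]
    return 1.0 - ed / len(a), len(b) / len(a)


def select_single_copy(
    gene_sets: dict[str, list[tuple[str, str]]],
    id_threshold: float = 0.70,
    len_threshold: float = 0.80,
) -> list[OrthologSet]:
    """Greedy clustering of genes across genomes; only clusters with exactly
    one member in every genome survive.

    The longest unassigned sequence seeds each cluster; a sequence joins if
    its identity to the seed is >= ``id_threshold`` over an alignment spanning
    >= ``len_threshold`` of the shorter sequence.  Ordering is deterministic.
    """
    genomes = sorted(gene_sets)
    if len(genomes) < 3:
        raise ValueError("need at least 3 genomes")
    pool = [
        (genome, gene_id, seq)
        for genome in genomes
        for gene_id, seq in gene_sets[genome]
    ]
    pool.sort(key=lambda t: (-len(t[2]), t[0], t[1]))
    assigned = [False] * len(pool)
    clusters: list[list[int]] = []
    for i in range(len(pool)):
        if assigned[i]:
            continue
        members = [i]
        assigned[i] = True
        seed_seq = pool[i][2]
        for j in range(i + 1, len(pool)):
            if assigned[j]:
                continue
            ident, ratio = _pair_identity(seed_seq, pool[j][2])
            if ident >= id_threshold and ratio >= len_threshold:
                members.append(j)
                assigned[j] = True
        clusters.append(members)

    out: list[OrthologSet] = []
    for ci, members in enumerate(clusters):
        per_genome: dict[str, list[tuple[str, str]]] = {}
        for m in members:
            genome, gene_id, seq = pool[m]
            per_genome.setdefault(genome, []).append((gene_id, seq))
        if sorted(per_genome) != genomes or any(len(v) != 1 for v in per_genome.values()):
            continue  # missing in some genome, or duplicated: discarded
        seqs = {g: per_genome[g][0][1] for g in genomes}
        lens = {len(s) for s in seqs.values()}
        if len(lens) != 1:
            logger.warning("cluster %d members have unequal lengths; discarded", ci)
            continue
        out.append(OrthologSet(f"cluster{ci:04d}", seqs, lens.pop()))
    return out


# ---------------------------------------------------------------------------
# neighbor-joining trees
# ---------------------------------------------------------------------------

def _p_distance_matrix(alignment: dict[str, str], min_site_coverage: float = 0.8):
    names = sorted(alignment)
    mat = np.array([list(alignment[n]) for n in names])
    present = (mat != "-") & (mat != "N")
    keep = present.mean(axis=0) >= min_site_coverage
    mat = mat[:, keep]
    present = present[:, keep]
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = present[i] & present[j]
            nb = int(both.sum())
            dm[i, j] = dm[j, i] = (
                float((mat[i, both] != mat[j, both]).mean()) if nb else 0.0
            )
    return names, dm


def nj_tree(alignment: dict[str, str], min_site_coverage: float = 0.8) -> Tree:
    """Neighbor-joining tree on p-distances; positions with under
    ``min_site_coverage`` non-gap characters are excluded; negative branch
    lengths are clamped to zero."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    if len({len(s) for s in alignment.values()}) != 1:
        raise ValueError("sequences must be aligned to equal length")
    names, dm = _p_distance_matrix(alignment, min_site_coverage)
    tree = nj(DistanceMatrix(dm, ids=names))
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return Tree(tree)


def concat_tree(alignments: list[dict[str, str]], min_site_coverage: float = 0.8) -> Tree:
    """NJ tree of the column-wise concatenation of the given alignments."""
    if not alignments:
        raise ValueError("no alignments given")
    names = set(alignments[0])
    for a in alignments[1:]:
        if set(a) != names:
            raise ValueError("alignments cover different genome sets")
    cat = {n: "".join(a[n] for a in alignments) for n in names}
    return nj_tree(cat, min_site_coverage)


# ---------------------------------------------------------------------------
# congruence
# ---------------------------------------------------------------------------

def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds distance (symmetric difference of bipartition sets)."""
    if t1.leaves != t2.leaves:
        raise ValueError("trees have different leaf sets")
    return len(t1.bipartitions() ^ t2.bipartitions())


def focal_branches(tree: Tree, k: int = 3) -> list[Bipartition]:
    """The ``k`` deepest branches of the reference tree: internal bipartitions
    ranked by the size of their smaller side (ties broken lexicographically)."""
    bps = sorted(
        tree.bipartitions(),
        key=lambda s: (-min(len(s), len(tree.leaves) - len(s)), tuple(sorted(s))),
    )
    return bps[:k]


@dataclass
class CongruenceReport:
    branch_table: pd.DataFrame  # one row per focal branch: n_support, n_conflict
    gene_table: pd.DataFrame    # one row per gene tree: rf distance, supports-all flag


def congruence_counts(
    gene_trees: dict[str, Tree],
    reference_tree: Tree,
    focal: list | None = None,
) -> CongruenceReport:
    """Count gene trees that do / do not contain each focal bipartition of the
    reference tree, plus per-gene RF distances."""
    leaves = reference_tree.leaves
    for name, t in gene_trees.items():
        if t.leaves != leaves:
            missing = sorted(leaves ^ t.leaves)
            raise ValueError(f"gene tree {name}: leaf set mismatch ({missing})")
    if focal is None:
        focal = focal_branches(reference_tree)
    focal = [normalize_bipartition(b, leaves) for b in focal]
    ref_bps = reference_tree.bipartitions()
    for b in focal:
        if b not in ref_bps:
            raise ValueError(f"focal branch {sorted(b)} is not in the reference tree")

    gene_bps = {name: t.bipartitions() for name, t in gene_trees.items()}
    branch_rows = []
    for b in focal:
        n_support = sum(b in bps for bps in gene_bps.values())
        branch_rows.append((",".join(sorted(b)), n_support, len(gene_trees) - n_support))
    gene_rows = [
        (name, len(bps ^ ref_bps), all(b in bps for b in focal))
        for name, bps in gene_bps.items()
    ]
    return CongruenceReport(
        branch_table=pd.DataFrame(branch_rows, columns=["branch", "n_support", "n_conflict"]),
        gene_table=pd.DataFrame(gene_rows, columns=["gene", "rf_distance", "supports_all_focal"]),
    )


# ---------------------------------------------------------------------------
# extracting per-gene alignments from a simulated population
# ---------------------------------------------------------------------------

def gene_alignments_from_population(pop) -> list[dict[str, str]]:
    """Per-gene leaf alignments (genome-strand nucleotides) from simulator truth."""
    from . import genetics as _g

    names = pop.params.get("leaf_names") or [f"lineage{k}" for k in range(pop.n_lineages)]
    out = []
    for gene in pop.reference.genes:
        seg = pop.haplotypes[:, gene.start : gene.end]
        out.append({names[k]: _g.decode(seg[k]) for k in range(pop.n_lineages)})
    return out
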