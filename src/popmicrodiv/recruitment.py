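"""Read recruitment: placing reads on a reference, identity/length cutoffs,
RPKG and ANIr, and fixed-depth subsampling.

The internal aligner is an ungapped seed-and-extend mapper (k-mer seeds on a
few read offsets, exhaustive seed scan as fallback, best hit per read, ties
broken by leftmost reference position).  Simulated reads are indel-free; gapped
real-world alignments can be imported from SAM, where a gap column scores as a
mismatch.  Only the best hit per read is kept, so RPKG never double-counts.

Masked reference positions never score (and never count in the alignment
length); reads whose aligned span overlaps masked regions by more than half
are dropped outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from . import genetics
from .seqio import AnnotatedGenome, FormatError, ReadSet

logger = logging.getLogger("popmicrodiv")

_NOMATCH = 250  # scoring sentinel for masked reference positions


@dataclass(frozen=True)
class AlignmentRecord:
    """One read placed on the reference (per-column calls vs the reference)."""

    read_id: str
    ref_id: str
    ref_start: int
    aligned_len: int
    matches: int
    bases: np.ndarray  # per-column base codes; 4 marks a deletion column

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.aligned_len


class AlignmentSet:
    """Array-backed alignments of one read set against one reference.

    The metagenome denominators (``metagenome_bases``, ``metagenome_reads``)
    describe the *source* read set before recruitment and are carried unchanged
    through filtering and subsampling, as RPKG requires.
    """

    def __init__(
        self,
        ref_id: str,
        ref_start: np.ndarray,
        aligned_len: np.ndarray,
        matches: np.ndarray,
        bases: np.ndarray,
        offsets: np.ndarray,
        metagenome_bases: int,
        metagenome_reads: int,
        mean_read_len: float,
        lineages: np.ndarray | None = None,
        read_ids: list[str] | None = None,
    ) -> None:
        self.ref_id = ref_id
        self.ref_start = np.asarray(ref_start, dtype=np.int64)
        self.aligned_len = np.asarray(aligned_len, dtype=np.int64)
        self.matches = np.asarray(matches, dtype=np.int64)
        self.bases = np.asarray(bases, dtype=np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.metagenome_bases = int(metagenome_bases)
        self.metagenome_reads = int(metagenome_reads)
        self.mean_read_len = float(mean_read_len)
        n = len(self.ref_start)
        self.lineages = (
            np.full(n, -1, dtype=np.int32) if lineages is None else np.asarray(lineages, dtype=np.int32)
        )
        self.read_ids = read_ids

    def __len__(self) -> int:
        return len(self.ref_start)

    @property
    def identity(self) -> np.ndarray:
        return 100.0 * self.matches / np.maximum(self.aligned_len, 1)

    @property
    def span(self) -> np.ndarray:
        """Number of reference columns each record occupies (incl. masked)."""
        return np.diff(self.offsets)

    def record(self, i: int) -> AlignmentRecord:
        s, e = int(self.offsets[i]), int(self.offsets[i + 1])
        rid = self.read_ids[i] if self.read_ids is not None else f"read{i:08d}"
        return AlignmentRecord(
            rid, self.ref_id, int(self.ref_start[i]), int(self.aligned_len[i]),
            int(self.matches[i]), self.bases[s:e].copy(),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self.record(i)

    def subset(self, index: np.ndarray) -> "AlignmentSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        spans = self.span[index]
        offs = np.concatenate(([0], np.cumsum(spans)))
        take = (
            np.concatenate([np.arange(self.offsets[i], self.offsets[i + 1]) for i in index])
            if len(index)
            else np.empty(0, dtype=np.int64)
        )
        return AlignmentSet(
            self.ref_id, self.ref_start[index], self.aligned_len[index],
            self.matches[index], self.bases[take], offs,
            self.metagenome_bases, self.metagenome_reads, self.mean_read_len,
            self.lineages[index],
            None if self.read_ids is None else [self.read_ids[i] for i in index],
        )


# ---------------------------------------------------------------------------
# the aligner
# ---------------------------------------------------------------------------

def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    win = np.lib.stride_tricks.sliding_window_view(codes.astype(np.int64), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (win <= 3).all(axis=1)
    out = win @ powers
    out[~valid] = -1
    return out


def align_reads(reads: ReadSet, genome: AnnotatedGenome, k: int = 13) -> AlignmentSet:
    """Assign each read its best ungapped alignment on the reference.

    Empty read sets yield an empty AlignmentSet; a genome shorter than a read
    is an error.  Reads with no seed hit anywhere are left unrecruited.
    """
    L = len(genome)
    if len(reads) == 0:
        return AlignmentSet(
            genome.id, *(np.empty(0, dtype=np.int64),) * 3,
            np.empty(0, dtype=np.uint8), np.zeros(1, dtype=np.int64), 0, 0, 0.0,
        )
    max_rl = int(reads.lengths.max())
    if max_rl > L:
        raise ValueError(f"genome ({L} bp) shorter than longest read ({max_rl} bp)")

    mask = genome.mask_array()
    ref_score = genome.codes.copy()
    ref_score[mask] = _NOMATCH
    mask_cum = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))

    ref_k = _kmer_codes(genome.codes, k)
    pos_all = np.arange(len(ref_k), dtype=np.int64)
    ok = ref_k >= 0
    order = np.lexsort((pos_all[ok], ref_k[ok]))
    sorted_k = ref_k[ok][order]
    sorted_pos = pos_all[ok][order]

    if reads.is_uniform:
        return _align_uniform(reads, genome, ref_score, mask_cum, sorted_k, sorted_pos, k)
    # ragged path: small imported sets; reuse the uniform machinery per length class
    lens = reads.lengths
    parts = []
    for ln in np.unique(lens):
        sub = reads.subset(lens == ln)
        parts.append((_align_uniform(sub, genome, ref_score, mask_cum, sorted_k, sorted_pos, k),
                      np.flatnonzero(lens == ln)))
    return _concat_alignments(genome.id, parts, reads)


def _candidate_diags(M, codes_at, offsets_used, sorted_k, sorted_pos, L, Lr):
    """(read, diagonal) candidate pairs from seed lookups."""
    reads_rep, diags = [], []
    for s, kc in zip(offsets_used, codes_at):
        lo = np.searchsorted(sorted_k, kc, side="left")
        hi = np.searchsorted(sorted_k, kc, side="right")
        counts = hi - lo
        counts[kc < 0] = 0
        ridx = np.repeat(np.arange(len(kc)), counts)
        flat = np.concatenate(
            [sorted_pos[a:b] for a, b in zip(lo, hi) if b > a]
        ) if counts.sum() else np.empty(0, dtype=np.int64)
        d = flat - s
        good = (d >= 0) & (d <= L - Lr)
        reads_rep.append(ridx[good])
        diags.append(d[good])
    return np.concatenate(reads_rep), np.concatenate(diags)


def _align_uniform(reads, genome, ref_score, mask_cum, sorted_k, sorted_pos, k):
    M = reads.as_matrix()
    n, Lr = M.shape
    L = len(genome)
    if Lr < k:
        raise ValueError(f"reads shorter than seed size {k}")
    offsets_used = sorted({0, max(0, Lr // 2 - k // 2), Lr - k})
    codes_at = []
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for s in offsets_used:
        win = M[:, s : s + k].astype(np.int64)
        kc = win @ powers
        kc[(win > 3).any(axis=1)] = -1
        codes_at.append(kc)
    ridx, diag = _candidate_diags(M, codes_at, offsets_used, sorted_k, sorted_pos, L, Lr)

    # exhaustive fallback for reads with no candidate at the sampled offsets
    have = np.zeros(n, dtype=bool)
    have[ridx] = True
    missing = np.flatnonzero(~have)
    if missing.size:
        extra_r, extra_d = [], []
        for i in missing:
            row = M[i].astype(np.int64)
            for s in range(0, Lr - k + 1):
                win = row[s : s + k]
                if (win > 3).any():
                    continue
                kc = int(win @ powers)
                lo = np.searchsorted(sorted_k, kc, side="left")
                hi = np.searchsorted(sorted_k, kc, side="right")
                if hi > lo:
                    d = sorted_pos[lo:hi] - s
                    good = (d >= 0) & (d <= L - Lr)
                    if good.any():
                        extra_r.append(np.full(int(good.sum()), i, dtype=np.int64))
                        extra_d.append(d[good])
                        break
        if extra_r:
            ridx = np.concatenate([ridx, np.concatenate(extra_r)])
            diag = np.concatenate([diag, np.concatenate(extra_d)])

    # dedupe (read, diagonal)
    key = ridx * np.int64(L + 1) + diag
    key = np.unique(key)
    ridx = key // (L + 1)
    diag = key % (L + 1)

    # score candidates in chunks
    matches = np.empty(len(ridx), dtype=np.int64)
    col = np.arange(Lr)
    chunk = max(1, 20_000_000 // max(Lr, 1))
    for lo_i in range(0, len(ridx), chunk):
        hi_i = min(lo_i + chunk, len(ridx))
        seg = ref_score[diag[lo_i:hi_i, None] + col[None, :]]
        matches[lo_i:hi_i] = (M[ridx[lo_i:hi_i]] == seg).sum(axis=1)

    # best candidate per read: max matches, then leftmost diagonal
    sel = np.lexsort((diag, -matches, ridx))
    ridx_s, diag_s, match_s = ridx[sel], diag[sel], matches[sel]
    first = np.concatenate(([True], ridx_s[1:] != ridx_s[:-1]))
    ridx_b, diag_b, match_b = ridx_s[first], diag_s[first], match_s[first]

    # masked-overlap rule and masked-column bookkeeping
    overlap = mask_cum[diag_b + Lr] - mask_cum[diag_b]
    keep = overlap <= 0.5 * Lr
    n_dropped_mask = int((~keep).sum())
    ridx_b, diag_b, match_b, overlap = ridx_b[keep], diag_b[keep], match_b[keep], overlap[keep]
    alen = Lr - overlap

    order2 = np.argsort(ridx_b, kind="stable")  # preserve read order
    ridx_b, diag_b, match_b, alen = ridx_b[order2], diag_b[order2], match_b[order2], alen[order2]

    bases = M[ridx_b].reshape(-1)
    offs = np.arange(len(ridx_b) + 1, dtype=np.int64) * Lr
    logger.info(
        "align_reads: %d/%d reads recruited (%d dropped by mask overlap)",
        len(ridx_b), n, n_dropped_mask,
    )
    return AlignmentSet(
        genome.id, diag_b, alen, match_b, bases, offs,
        metagenome_bases=reads.total_bases, metagenome_reads=len(reads),
        mean_read_len=reads.mean_length,
        lineages=reads.lineages[ridx_b],
        read_ids=None if reads.ids is None else [reads.ids[i] for i in ridx_b],
    )


def _concat_alignments(ref_id, parts, reads):
    sets = [p[0] for p in parts]
    return AlignmentSet(
        ref_id,
        np.concatenate([a.ref_start for a in sets]),
        np.concatenate([a.aligned_len for a in sets]),
        np.concatenate([a.matches for a in sets]),
        np.concatenate([a.bases for a in sets]),
        np.concatenate(([0], np.cumsum(np.concatenate([a.span for a in sets])))),
        metagenome_bases=reads.total_bases,
        metagenome_reads=len(reads),
        mean_read_len=reads.mean_length,
        lineages=np.concatenate([a.lineages for a in sets]),
    )


# ---------------------------------------------------------------------------
# cutoffs, RPKG, ANIr, subsampling
# ---------------------------------------------------------------------------

def filter_alignments(aln: AlignmentSet, min_identity: float, min_alen: int) -> AlignmentSet:
    """Keep records with identity >= ``min_identity`` (percent) and aligned
    length >= ``min_alen``; metagenome denominators are untouched."""
    keep = (aln.identity >= min_identity) & (aln.aligned_len >= min_alen)
    return aln.subset(keep)


def compute_rpkg(
    aln: AlignmentSet, genome_effective_len: int, norm_mode: str = "bases"
) -> float:
    """Reads recruited per kb of (unmasked) genome per Gb of metagenome.

    ``norm_mode="bases"`` uses the metagenome size in bases; ``"read_adjusted"``
    first divides the metagenome size by its mean read length (the read-length
    normalization has two defensible readings; both are provided).
    """
    if genome_effective_len <= 0:
        raise ValueError("genome effective length must be positive")
    if aln.metagenome_bases <= 0:
        raise ValueError("metagenome size is zero")
    if norm_mode == "bases":
        meta = aln.metagenome_bases
    elif norm_mode == "read_adjusted":
        if aln.mean_read_len <= 0:
            raise ValueError("mean read length unknown")
        meta = aln.metagenome_bases / aln.mean_read_len
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")
    return len(aln) / ((genome_effective_len / 1e3) * (meta / 1e9))


def compute_anir(aln: AlignmentSet) -> tuple[float, float, tuple[np.ndarray, np.ndarray]]:
    """(median %, mean %, (bin_edges, counts)) of per-read identities.

    The histogram uses 1% bins over [80, 100].  An empty set returns NaNs with
    a warning (never 0, which would masquerade as a real identity).
    """
    edges = np.linspace(80.0, 100.0, 21)
    if len(aln) == 0:
        logger.warning("compute_anir: empty alignment set; ANIr undefined")
        return float("nan"), float("nan"), (edges, np.zeros(20, dtype=np.int64))
    ident = aln.identity
    hist, _ = np.histogram(ident, bins=edges)
    return float(np.median(ident)), float(ident.mean()), (edges, hist)


def subsample_alignments(aln: AlignmentSet, n: int, seed: int = 0) -> AlignmentSet:
    """Uniform without-replacement subsample of records (deterministic per seed).

    Mirrors fixed-depth downsampling of mapped reads so that uneven coverage
    does not drive the polymorphism statistics.  If fewer than ``n`` records
    exist they are all returned, with a warning.
    """
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    if n >= len(aln):
        if n > len(aln):
            logger.warning(
                "subsample_alignments: requested %d but only %d records; returning all",
                n, len(aln),
            )
        return aln.subset(np.arange(len(aln)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(aln), size=n, replace=False))
    return aln.subset(idx)


# ---------------------------------------------------------------------------
# SAM import/export (minimal subset: header + M/I/D/S CIGAR, NM tag)
# ---------------------------------------------------------------------------

def write_sam(aln: AlignmentSet, genome: AnnotatedGenome, path: str | Path) -> Path:
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": genome.id, "LN": len(genome)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i in range(len(aln)):
            s, e = int(aln.offsets[i]), int(aln.offsets[i + 1])
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_ids[i] if aln.read_ids is not None else f"read{i:08d}"
            seg.query_sequence = genetics.decode(aln.bases[s:e])
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = int(aln.ref_start[i])
            seg.mapping_quality = 255
            seg.cigartuples = [(0, e - s)]
            seg.set_tag("NM", int(aln.aligned_len[i] - aln.matches[i]))
            out.write(seg)
    return path


def read_sam(path: str | Path, genome: AnnotatedGenome) -> AlignmentSet:
    """Import alignments from a (text) SAM file against ``genome``.

    Per-column calls are rebuilt from the CIGAR: M/=/X copy read bases,
    I and S consume the read only, D emits a gap column (scored as mismatch).
    Metagenome denominators are set from the reads present in the file; when
    the SAM holds recruited reads only, set them explicitly afterwards.
    """
    starts, alens, matches, cols, ids = [], [], [], [], []
    total_bases = 0
    n_reads = 0
    ref = genome.codes
    mask = genome.mask_array()
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            n_reads += 1
            total_bases += seg.query_length or len(seg.query_sequence or "")
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            q = genetics.encode(seg.query_sequence)
            out = []
            qi = 0
            for op, ln in seg.cigartuples:
                if op in (0, 7, 8):  # M, =, X
                    out.append(q[qi : qi + ln])
                    qi += ln
                elif op in (1, 4):  # I, S consume query only
                    qi += ln
                elif op == 2:  # D: gap column
                    out.append(np.full(ln, genetics.N_CODE, dtype=np.uint8))
                elif op == 3:  # N skip: treat as deletion columns
                    out.append(np.full(ln, genetics.N_CODE, dtype=np.uint8))
                else:
                    raise FormatError(f"unsupported CIGAR op {op} in {seg.query_name}")
            col = np.concatenate(out) if out else np.empty(0, dtype=np.uint8)
            start = int(seg.reference_start)
            span = len(col)
            unmasked = ~mask[start : start + span]
            m = int(((col == ref[start : start + span]) & unmasked).sum())
            starts.append(start)
            alens.append(int(unmasked.sum()))
            matches.append(m)
            cols.append(col)
            ids.append(seg.query_name)
    offs = np.concatenate(([0], np.cumsum([len(c) for c in cols]))).astype(np.int64)
    bases = np.concatenate(cols) if cols else np.empty(0, dtype=np.uint8)
    mean_rl = total_bases / n_reads if n_reads else 0.0
    return AlignmentSet(
        genome.id,
        np.array(starts, dtype=np.int64),
        np.array(alens, dtype=np.int64),
        np.array(matches, dtype=np.int64),
        bases, offs, total_bases, n_reads, mean_rl, read_ids=ids,
    )
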