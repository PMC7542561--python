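"""Readers/writers for the standard formats the pipeline touches, read QC and
reference masking.

Coordinates are 0-based half-open everywhere inside the package; BED is native,
GFF3 (1-based closed) is converted at the boundary.  Masking never rewrites the
sequence: an explicit interval set is carried on :class:`AnnotatedGenome` and
excluded from alignment scoring and from every length denominator downstream
(soft-masking by case would be ambiguous, so it is not used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import genetics

logger = logging.getLogger("popmicrodiv")


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene on the reference (0-based, half-open, stop included)."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end must exceed start")
        if (self.end - self.start) % 3 != 0:
            raise ValueError(f"gene {self.gene_id}: length is not a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        return (self.end - self.start) // 3

    def codon_positions(self) -> np.ndarray:
        """(n_codons, 3) genome coordinates of each codon position in gene frame.

        For minus-strand genes codon 0 starts at the right edge and the three
        columns run 3'->5' on the genome, so reading the (complemented) genome
        bases along a row yields the codon in gene orientation.
        """
        k = np.arange(self.n_codons)
        if self.strand == "+":
            first = self.start + 3 * k
            return first[:, None] + np.arange(3)[None, :]
        first = self.end - 1 - 3 * k
        return first[:, None] - np.arange(3)[None, :]


@dataclass
class AnnotatedGenome:
    """Reference sequence plus gene coordinates; the frame for codon statistics."""

    id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    masked: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for g in self.genes:
            if g.start < 0 or g.end > n:
                raise ValueError(f"gene {g.gene_id} interval [{g.start},{g.end}) outside genome")
        self.masked = merge_intervals(self.masked)
        for s, e in self.masked:
            if s < 0 or e > n:
                raise ValueError(f"masked interval [{s},{e}) outside genome of length {n}")
        self._codes: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            self._codes = genetics.encode(self.sequence)
        return self._codes

    @property
    def masked_length(self) -> int:
        return sum(e - s for s, e in self.masked)

    @property
    def effective_length(self) -> int:
        """Genome length minus masked bases; the RPKG denominator."""
        return len(self.sequence) - self.masked_length

    def mask_array(self) -> np.ndarray:
        m = np.zeros(len(self.sequence), dtype=bool)
        for s, e in self.masked:
            m[s:e] = True
        return m

    def gene_ref_codons(self, gene: GeneRecord) -> np.ndarray:
        """Codon-table indices (0..63) of the gene's reference codons in gene frame."""
        pos = gene.codon_positions()
        bases = self.codes[pos]
        if gene.strand == "-":
            bases = genetics.COMP[bases]
        if bases.max(initial=0) > 3:
            raise ValueError(f"gene {gene.gene_id} contains non-ACGT reference bases")
        return (16 * bases[:, 0].astype(np.int64) + 4 * bases[:, 1] + bases[:, 2]).astype(np.int64)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sorted union of half-open intervals (overlaps and abutments merged)."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"invalid interval [{s},{e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass(frozen=True)
class ReadRecord:
    """A single read; ``truth_lineage`` is simulator provenance (-1 = unknown)."""

    read_id: str
    sequence: str
    qualities: np.ndarray | None = None
    truth_lineage: int = -1

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


class ReadSet:
    """Array-backed collection of reads (ragged storage, uniform fast path).

    ``bases`` holds the concatenated base codes of all reads, ``offsets`` the
    read boundaries; ``quals`` is parallel to ``bases`` (or None when the
    source carried no qualities).
    """

    def __init__(
        self,
        bases: np.ndarray,
        offsets: np.ndarray,
        quals: np.ndarray | None = None,
        ids: list[str] | None = None,
        lineages: np.ndarray | None = None,
    ) -> None:
        self.bases = np.asarray(bases, dtype=np.uint8)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.quals = None if quals is None else np.asarray(quals, dtype=np.uint8)
        if self.quals is not None and self.quals.shape != self.bases.shape:
            raise ValueError("quality array must be parallel to base array")
        n = len(self.offsets) - 1
        self.ids = ids
        self.lineages = (
            np.full(n, -1, dtype=np.int32) if lineages is None else np.asarray(lineages, dtype=np.int32)
        )

    def __len__(self) -> int:
        return len(self.offsets) - 1

    @property
    def lengths(self) -> np.ndarray:
        return np.diff(self.offsets)

    @property
    def total_bases(self) -> int:
        return int(self.offsets[-1])

    @property
    def mean_length(self) -> float:
        return float(self.total_bases / max(len(self), 1))

    def read_id(self, i: int) -> str:
        return self.ids[i] if self.ids is not None else f"read{i:08d}"

    def __getitem__(self, i: int) -> ReadRecord:
        s, e = int(self.offsets[i]), int(self.offsets[i + 1])
        return ReadRecord(
            read_id=self.read_id(i),
            sequence=genetics.decode(self.bases[s:e]),
            qualities=None if self.quals is None else self.quals[s:e].copy(),
            truth_lineage=int(self.lineages[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @property
    def is_uniform(self) -> bool:
        lens = self.lengths
        return len(lens) > 0 and bool((lens == lens[0]).all())

    def as_matrix(self) -> np.ndarray:
        """(n_reads, read_len) base-code matrix; only for uniform-length sets."""
        if not self.is_uniform:
            raise ValueError("read set has heterogeneous lengths")
        return self.bases.reshape(len(self), int(self.lengths[0]))

    def subset(self, index: np.ndarray) -> "ReadSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        lens = self.lengths[index]
        offs = np.concatenate(([0], np.cumsum(lens)))
        take = np.concatenate(
            [np.arange(self.offsets[i], self.offsets[i + 1]) for i in index]
        ) if len(index) else np.empty(0, dtype=np.int64)
        return ReadSet(
            self.bases[take],
            offs,
            None if self.quals is None else self.quals[take],
            None if self.ids is None else [self.ids[i] for i in index],
            self.lineages[index],
        )

    @classmethod
    def from_records(cls, records: Sequence[ReadRecord]) -> "ReadSet":
        seqs = [genetics.encode(r.sequence) for r in records]
        offs = np.concatenate(([0], np.cumsum([len(s) for s in seqs]))).astype(np.int64)
        bases = np.concatenate(seqs) if seqs else np.empty(0, dtype=np.uint8)
        have_q = all(r.qualities is not None for r in records) and records
        quals = (
            np.concatenate([np.asarray(r.qualities, dtype=np.uint8) for r in records])
            if have_q
            else None
        )
        return cls(
            bases,
            offs,
            quals,
            [r.read_id for r in records],
            np.array([r.truth_lineage for r in records], dtype=np.int32),
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` (uppercased)."""
    path = Path(path)
    with open(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise FormatError(f"{path}: empty FASTA file (no records at line 1)")
        if not first[1].startswith(">"):
            raise FormatError(f"{path}: line {first[0]} is not a FASTA header")
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> Path:
    path = Path(path)
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)
    return path


def read_fastq(path: str | Path) -> ReadSet:
    """Read FASTQ (Phred+33) into a :class:`ReadSet`."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    ids: list[str] = []
    seqs: list[np.ndarray] = []
    quals: list[np.ndarray] = []
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            ids.append(title.split()[0])
            seqs.append(genetics.encode(seq))
            quals.append(np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33)
    if not ids:
        raise FormatError(f"{path}: empty FASTQ file")
    offs = np.concatenate(([0], np.cumsum([len(s) for s in seqs]))).astype(np.int64)
    return ReadSet(np.concatenate(seqs), offs, np.concatenate(quals), ids)


def write_fastq(reads: ReadSet, path: str | Path) -> Path:
    path = Path(path)
    if reads.quals is None:
        raise ValueError("cannot write FASTQ: reads carry no qualities")
    with open(path, "w") as fh:
        offs = reads.offsets
        qchars = (reads.quals + 33).tobytes().decode("ascii")
        for i in range(len(reads)):
            s, e = int(offs[i]), int(offs[i + 1])
            fh.write(
                f"@{reads.read_id(i)}\n{genetics.decode(reads.bases[s:e])}\n+\n{qchars[s:e]}\n"
            )
    return path


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def read_bed_genes(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    return [
        GeneRecord(str(r.name_), int(r.start), int(r.end), str(r.strand))
        for r in df.rename(columns={"name": "name_"}).itertuples()
    ]


def write_bed_genes(genes: Iterable[GeneRecord], chrom: str, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    return path


def read_bed_intervals(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    return [(int(r.start), int(r.end)) for r in df.itertuples()]


def read_gff3_genes(path: str | Path) -> list[GeneRecord]:
    """CDS features only; 1-based closed converted to 0-based half-open."""
    cols = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols)
    genes = []
    for r in df[df["type"] == "CDS"].itertuples():
        attrs = dict(
            kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv
        )
        gene_id = attrs.get("ID", attrs.get("Parent", f"cds_{r.Index}"))
        genes.append(GeneRecord(gene_id, int(r.start) - 1, int(r.end), str(r.strand)))
    return genes


def write_gff3_genes(genes: Iterable[GeneRecord], chrom: str, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{chrom}\tpopmicrodiv\tCDS\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t0"
                f"\tID={g.gene_id}\n"
            )
    return path


# ---------------------------------------------------------------------------
# tabular output (TSV with a commented header line)
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, float_format=float_format)
    return path


def read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: line 1 is not a commented TSV header")
        cols = header[1:].rstrip("\n").split("\t")
        return pd.read_csv(fh, sep="\t", header=None, names=cols)


# ---------------------------------------------------------------------------
# read QC and reference masking
# ---------------------------------------------------------------------------

def qc_filter_reads(
    reads: ReadSet,
    min_phred: float = 30.0,
    min_len: int = 50,
    forbid_n: bool = True,
) -> ReadSet:
    """Keep reads with mean Phred >= ``min_phred``, length >= ``min_len`` and
    (optionally) no ambiguous bases; order preserved.

    The Phred rule aggregates per read as the *mean* base quality (a single
    interpretable scalar; sliding-window trimming is out of scope).
    """
    n = len(reads)
    keep = reads.lengths >= min_len
    if min_phred > 0:
        if reads.quals is None:
            raise ValueError("reads carry no qualities but a Phred filter was requested")
        qsum = np.add.reduceat(reads.quals.astype(np.float64), reads.offsets[:-1])
        qsum[reads.lengths == 0] = 0.0
        mean_q = qsum / np.maximum(reads.lengths, 1)
        keep &= mean_q >= min_phred
    if forbid_n:
        is_n = (reads.bases >= genetics.N_CODE).astype(np.int64)
        n_count = np.add.reduceat(is_n, reads.offsets[:-1])
        n_count[reads.lengths == 0] = 0
        keep &= n_count == 0
    out = reads.subset(np.flatnonzero(keep))
    logger.info("qc_filter_reads: kept %d / %d reads (discarded %d)", len(out), n, n - len(out))
    return out


def mask_regions(genome: AnnotatedGenome, intervals: Iterable[tuple[int, int]]) -> AnnotatedGenome:
    """Return a copy of ``genome`` with ``intervals`` added to the masked set.

    Masked positions are excluded from alignment scoring and from every length
    denominator (RPKG uses the effective length); coordinates are untouched.
    """
    intervals = list(intervals)
    n = len(genome.sequence)
    for s, e in intervals:
        if s < 0 or e > n or e < s:
            raise ValueError(f"masked interval [{s},{e}) outside genome of length {n}")
    return AnnotatedGenome(
        id=genome.id,
        sequence=genome.sequence,
        genes=list(genome.genes),
        masked=merge_intervals(list(genome.masked) + intervals),
    )
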