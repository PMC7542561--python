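import numpy as np
import pytest

from popmicrodiv import genetics, seqio


@pytest.fixture
def toy_genome() -> seqio.AnnotatedGenome:
    """60-bp genome with one plus-strand and one minus-strand gene.

    gene g1 (+) at [10, 25): ATG GGC TTT TGG TAA
    gene g2 (-) at [40, 52): revcomp(ATG CCT GAA TAA)
    """
    seq = "ACGTACGTAC"                      # 0-9 intergenic
    seq += "ATGGGCTTTTGGTAA"                # 10-24 g1
    seq += "TTTTTTTTTTTTTTT"                # 25-39 intergenic
    seq += genetics.revcomp("ATGCCTGAATAA")  # 40-51 g2 on minus strand
    seq += "ACGTACGT"                       # 52-59 intergenic
    genes = [
        seqio.GeneRecord("g1", 10, 25, "+"),
        seqio.GeneRecord("g2", 40, 52, "-"),
    ]
    return seqio.AnnotatedGenome("toy", seq, genes)


def make_reads(seqs, quals=None, lineages=None) -> seqio.ReadSet:
    """Build a ReadSet from plain strings (constant Q40 when not given)."""
    recs = []
    for i, s in enumerate(seqs):
        q = np.full(len(s), 40, dtype=np.uint8) if quals is None else np.asarray(quals[i])
        lin = -1 if lineages is None else lineages[i]
        recs.append(seqio.ReadRecord(f"r{i}", s, q, lin))
    return seqio.ReadSet.from_records(recs)
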