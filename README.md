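# popmicrodiv

Metagenomic population genetics at desk scale: how much nucleotide
diversity does a natural microbial population carry, how strongly is it
purified, and how much of it was moved by homologous recombination rather
than mutation?

Populations of free-living marine bacteria — SAR11 being the extreme case —
recruit metagenomic reads to a reference genome across a broad identity
range, and the within-population variation in those reads encodes their
evolutionary regime.  `popmicrodiv` re-implements that analysis chain as a
reusable, fully testable library:

* **Read recruitment** — ungapped seed-and-extend alignment (or SAM import),
  the 98%/50-bp and 80%/50-bp identity cutoffs, fixed-depth subsampling,
  **RPKG** (reads per kb genome per Gb metagenome) and **ANIr** (read-based
  average nucleotide identity).
* **Codon-level microdiversity** — codon pileups from spanning reads,
  variant calling under joint count (≥4) / frequency (≥0.1%) / coverage
  (≥5×) filters, Nei–Gojobori expected-site normalization, per-gene
  **pN, pS, pN/pS** and the **percentage of polymorphic sites (PPS)**.
* **Recombination inference** — the correlation profile d(ℓ) of joint
  mismatches over 4-fold degenerate site pairs within reads, fit by a
  fragment-mosaic model to give **γ/μ** (recombination-to-mutation
  substitution ratio) and the **recombination coverage c** ∈ [0, 1].
* **Gene-tree congruence** — single-copy ortholog clustering (70% identity /
  80% length), neighbor-joining gene trees vs the concatenated tree, and
  counts of genes that do or do not rescue each deep branch.
* **A synthetic community simulator** — lineage-structured populations with
  controlled mutation (θ), selection at mutation time (ω), homologous
  recombination (ρ/θ, mean fragment f̄) and shotgun reads, with exact ground
  truth for every quantity above.

The statistics, in brief: with S_exp and N_exp the Nei–Gojobori expected
synonymous/nonsynonymous site counts over covered codons,
pN/pS = (n_nonsyn/N_exp)/(n_syn/S_exp); RPKG = reads / (genome kb ×
metagenome Gb); the profile model is d(ℓ) = d_s²(1 + V·S(ℓ)) with
S(ℓ) = e^{−λ(2−κ)} + κ/(2−κ)(1−e^{−λ(2−κ)}), κ = e^{−ℓ/f̄}, giving
γ/μ = λ and c = 1 − e^{−λ}.  See `docs/methods.md` for derivations,
assumptions and limitations.

## Worked example

```python
import popmicrodiv as pm

genome = pm.generate_genome(60_000, 80, gc=0.32, seed=42)
pop    = pm.evolve_population(genome, 20, theta=0.02, omega=0.1, seed=43)
reads  = pm.qc_filter_reads(pm.simulate_reads(pop, 50_000, read_len=100, seed=44))
aln    = pm.filter_alignments(pm.align_reads(reads, genome), 98.0, 50)

pileups  = pm.build_codon_pileups(aln, genome)
variants = pm.call_codon_variants(pileups)          # count>=4, freq>=0.1%, cov>=5x
table    = pm.gene_stats(variants, pileups)
summary  = pm.aggregate_genome(table)
print(f"median pN/pS = {summary.median_pnps:.3f}, mean PPS = {summary.mean_pps:.2f}%")
```

prints

```
median pN/pS = 0.059, mean PPS = 6.93%
```

a strongly purified population (at ω = 0.1 roughly one attempted amino-acid
change in ten survives): pN/pS sits far below 1 — the regime reported for
surface-ocean SAR11 — while several percent of covered sites are
polymorphic.  Re-running the same chain with `omega=1.0` prints
`median pN/pS = 0.960, mean PPS = 7.38%`: near-identical diversity, no
purifying signal — the two statistics separate selection strength from
diversity.

The same chain is scripted as five narrative analyses under `analysis/`
(`01_simulate_community.py` … `05_gene_tree_congruence.py`), each writing
its tables under `results/`, and as a CLI (`popmicrodiv simulate / recruit /
microdiv / recomb / trees`) for file-based use.

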