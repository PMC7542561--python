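# Methods

This note records the models, conventions and numerical choices behind
`popmicrodiv`, and what the synthetic validation studies do and do not
demonstrate about real metagenomic data.

## The synthetic community model

The simulator produces an annotated reference genome, a set of lineage
haplotypes diverged from it, and shotgun reads with known provenance.  Its
purpose is validation: every estimator in the package can be checked against
exactly computable ground truth.

**Reference genome.** Protein-coding genes (ATG start, no in-frame stops,
stop codon included, random strand) are tiled with intergenic spacers.  Base
composition is i.i.d. with a target GC fraction; codons that would form
in-frame stops are resampled, which perturbs realized GC by well under 1%.

**Mutation and selection.** Each lineage k receives
Poisson(θ·t_k·L) attempted substitutions at uniform positions (alternative
base uniform among the three).  Selection is an acceptance/rejection rule at
mutation time: an attempted nonsynonymous coding change (evaluated against
the current codon, in gene frame, strand-aware) is accepted with probability
ω; otherwise it is resampled among the synonymous single-base alternatives of
the same site, or discarded if none exist.  ω = 0 therefore yields a
population with literally zero nonsynonymous variants (the purifying
endpoint), ω = 1 a neutral population in which pN/pS = 1 holds by
construction under Nei–Gojobori site normalization.  This is not a fitness
model: there are no dynamics, sweeps, or epistasis, and selection strength
maps to ω only qualitatively.

**Divergence-time heterogeneity.** By default every lineage has t_k = 1 (a
star phylogeny with equal branch lengths).  This homogeneous default is kept
for the polymorphism studies, but it carries *no linkage signal*: with equal
per-site mutation probabilities across lineages, the two-site mismatch
probability factorizes and the correlation profile is flat at d_sample²
regardless of recombination.  `branch_model="exponential"` therefore scales
t_k by fixed exponential quantiles (−ln((k+½)/n)), mimicking the exponential
pair-coalescence times of a neutral population while keeping the mean
divergence at θ and the realization reproducible.  The recombination studies
use this mode; the congruence studies instead evolve along an explicit guide
tree (branch-wise Poisson mutations shared by all descendant leaves).

**Divergence realization.** `divergence="exact"` places exactly
round(θ·t_k·L) accepted substitutions at distinct sites.  It exists because
"a population at 5% divergence" is a statement about realized divergence:
under the Poisson default, multi-hit sites make the realized rate ≈ 4.84% at
θ = 0.05, which matters when ANIr is asserted to 0.1%.

**Recombination.** Poisson(ρ/θ-ratio × attempted mutations) events; each
copies a geometric(mean f̄)-length fragment from a uniformly chosen donor
lineage into a recipient at the same coordinates.  Fragments are taken from
the donor's *clonal background* (its state after mutation, before any
recombination), and later events overwrite earlier ones.  This makes the
final ancestry a "most-recent-event" mosaic whose fragment scale stays at f̄
— the regime the profile model below describes exactly.  Real serial
transfer would let imported material carry earlier breakpoints along,
shortening effective blocks as recombination intensifies; we exclude it so
that ground truth (per-site ancestry, recombination coverage) remains
analytic.  Whole-gene transfers (`transfer_gene`) are provided for the
phylogenetic congruence studies.

**Reads.** Single-end, uniform starts, lineage drawn by frequency, per-base
substitution errors at a constant rate with the matching constant Phred
quality.  No indels, no quality decay along the read, no GC or strand bias,
no paired ends — which is precisely why the internal aligner can be ungapped.

## Read QC, alignment and recruitment

QC keeps reads with **mean** Phred ≥ 30 (the per-read aggregation is a
documented choice; sliding-window trimming is out of scope), length ≥ 50 bp,
and no ambiguous bases.  The aligner is a seed-and-extend ungapped mapper:
13-mer seeds at three read offsets against a sorted reference k-mer index,
exhaustive seed scan as fallback, every candidate diagonal scored over the
full read, best hit only (ties to the leftmost coordinate).  Gapped real
data can be imported from SAM, where deletion columns score as mismatches.
Masked reference intervals (e.g. the ribosomal operon region of a real
genome) never match, are excluded from alignment-length denominators, and
reads overlapping a mask by more than half their span are dropped.

Recruitment metrics follow the standard definitions: records are filtered at
98% identity / 50 bp for abundance and microdiversity, 80% / 50 bp for ANIr;
RPKG = recruited reads / (unmasked genome kb × metagenome Gb), with an
alternative `read_adjusted` normalization (metagenome size divided by its
mean read length) exposed because the read-length correction in the
literature admits both readings.  The metagenome denominators always
describe the pre-recruitment read set and survive filtering and subsampling
unchanged.  Fixed-depth subsampling (uniform, without replacement, seeded)
mirrors the common practice of downsampling mapped reads per genome so that
coverage differences do not drive the polymorphism statistics.

## Codon-level microdiversity

Only reads spanning all three positions of a codon contribute to that
codon's pileup.  A codon variant is an observed non-reference codon passing
all three filters jointly: count ≥ 4, frequency ≥ 0.1% of the codon-spanning
reads, spanning coverage ≥ 5× (all boundaries inclusive).  The frequency
denominator is per-codon, not per-sample.  Codons whose reference codon is a
stop are excluded; observed codons containing more than one changed base are
classified by direct translation against the reference codon, with no
mutational-pathway decomposition.

Expected sites use Nei–Gojobori fractional counting: position j of a codon
contributes (synonymous single-base alternatives at j)/3 synonymous sites;
stop-creating changes are nonsynonymous; s + n = 3 per sense codon.  Then

  pN = 100 × (codons with ≥1 nonsynonymous variant) / N_exp,
  pS = 100 × (codons with ≥1 synonymous variant) / S_exp,

summed over codons with coverage ≥ 5×; a codon counts once per
classification however many alternative codons pass.  pN/pS is undefined
(not zero) when pS = 0.  PPS is nucleotide-level: a covered position is
polymorphic if any alternative base there passes the count and frequency
filters.  Genome aggregation reports mean PPS, the median pN/pS over genes
where it is defined, and the fraction of genes with pN/pS > 1.  pN and pS
are on a percent (per-100-sites) scale throughout.

The neutral-limit study (ω = 1, θ = 0.02, 200 genes, 50× coverage) is the
module's calibration property: the expected-site normalization is exactly
what makes the genome median pN/pS land in [0.9, 1.1] there.  The
coverage-invariance study uses a 23-lineage population with a tiered
frequency spectrum (8 lineages at ~9.4%, 15 at ~1.7%), θ = 0.007, ω = 0.45,
140 genes of 0.9–1.5 kb: the common tier is detectable at ~50× and the rare
tier only near ~500×, so mean PPS grows ~4-fold between 10⁵ and 10⁶
subsampled alignments while the median pN/pS moves by only a few percent.
Both tiers feed synonymous and nonsynonymous counts proportionally; the
residual depth drift comes from once-per-codon saturation, which affects the
denser synonymous class and the sparser nonsynonymous class in opposite
directions, and ω ≈ 0.45 sits at the balance point where the two cancel.

## Recombination from the correlation profile

Over all pairs of 4-fold degenerate third positions jointly covered by one
read at distance l, d(l) is the probability that both differ from the
reference, and d_sample the single-site synonymous diversity.  With
heterogeneous lineage divergence, linked sites share a divergence draw:
d(l) = ds²(1 + V·S(l)), where S(l) is the probability the two sites share
ancestry and V = E[t²]/E[t]² − 1 (≈1 for exponential times).  For the
most-recent-event fragment mosaic,

  S(l) = e^{−λ(2−κ)} + κ/(2−κ)·(1 − e^{−λ(2−κ)}),  κ = e^{−l/f̄},

with λ the expected number of fragments covering a site.  λ is also the
ratio of recombination-imported to mutational substitutions in this model,
so γ/μ = λ and the recombination coverage is c = 1 − e^{−λ} (0 = clonal,
→1 = fully recombined).  The fit is bounded, pair-count-weighted least
squares over (V, λ, f̄, ε) on a 10-bp-binned profile, multi-started in λ;
ε ∈ [0, 0.03] absorbs the long-range ancestry-coincidence floor a
many-lineage donor pool leaves (~1/(n−1)), which would otherwise bias λ
downward.

The curve fit pins V, f̄ and ε well, but λ rides a ridge: beyond λ ≈ 2 the
(λ, f̄) family shadows any moderate-λ curve everywhere except in the
long-range floor.  Whenever the window resolves the fragment scale
(f̄ ≤ max_l/3), λ is therefore re-derived by matching the observed ratio of
long-range (ℓ ≥ 0.65·max_l) to short-range (ℓ ≤ max_l/7) linkage excess to
the model's window-averaged ratio — a strictly decreasing 1-D function of λ
in which V cancels — with λ capped at 20 when the observed floor is at or
below the irreducible ε residue (saturation).

Numerical guards: f̄ is bounded to [25, 2·max_l] — beyond the within-read
window fragment length is unidentifiable, and an unbounded f̄ makes a flat
clonal profile fit arbitrarily well at any λ; a nested F-test (α = 0.05, 3
parameters) compares the full model against the flat λ = 0 model, and the
decay is kept only when it significantly improves the fit, so noise cannot
masquerade as recombination.  Identifiability remains one-sided: above the
floor's resolution only c, not λ, is precisely determined, and estimates
there are lower bounds.

Study conditions for the rank-recovery grid (ρ/θ ∈ {0, 5, 20}): 1 Mb
genome (~74,000 4-fold sites), 80 lineages, θ = 0.0025, f̄ = 100 bp,
250,000 error-free 400-bp reads, max_l = 380.  The genome is large because
the profile's effective sample size is limited by distinct (site-pair ×
lineage) combinations, not by read count; the lineage count keeps the
donor-coincidence floor (~0.013) below the moderate condition's clonal
floor; θ·f̄ places λ at {0, 1.25, 5} — clonal, identifiable, saturated.

## Gene trees and congruence

Single-copy ortholog clusters come from greedy identity clustering (seed =
longest sequence; membership at ≥70% identity over ≥80% of the shorter
length, edit distance via edlib); clusters missing a genome or duplicated in
one are discarded.  Trees are neighbor joining on p-distances with columns
under 80% occupancy removed and negative branch lengths clamped to zero —
distance topologies are all the congruence statistic consumes, so maximum
likelihood machinery is deliberately not used.  A gene tree "rescues" a
focal reference branch iff its bipartition set contains that branch;
Robinson–Foulds distances are the symmetric difference of bipartition sets.
Focal branches default to the deepest splits (largest minority side), and
are user-specifiable.  The validation study evolves 50 genes along a fixed
balanced 8-leaf tree (θ = 0.08): every gene tree then recovers the three
deepest branches, and transferring 20 whole genes across the root split
flips exactly those genes into conflict at the affected branches.

## What the synthetic studies do not show

The simulator omits indels, chimeras, contamination, conserved-region
recruitment of non-population reads, uneven coverage, paired ends and
serial recombinant transfer; lineage structure is a star (or a fixed guide
tree), not a coalescent.  Passing these studies therefore demonstrates the
*estimators* are correct under their stated models — not that the biological
conclusions those estimators support on real ocean metagenomes are immune to
the additional structure real data carry.  Absolute γ/μ values from the
literature (≈20 for surface-ocean populations) are not reproducible at desk
scale and are out of scope; the package validates endpoint fidelity and rank
recovery instead.

## Problem sizes and determinism

All studies run on a single CPU: the microdiversity endpoints use ~140 kb /
200 genes at 50×; the depth study 200 kb at up to ~575×, subsampled to 10⁵
and 10⁶ records; the recombination grid 15 simulations at 1 Mb; congruence
45 kb / 50 genes.  Every stage consumes a `numpy` Generator seeded from one
master seed, so identical seeds reproduce every output byte for byte —
including all TSVs, which carry a commented header line and fixed float
formatting.
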