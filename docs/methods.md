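# Methods notes

This note records the models, conventions, parameter choices and known
limitations of the package, in the order a user meets them in the
pipeline.

## Coordinate and sequence conventions

All internal coordinates are 0-based half-open intervals ascending by
start; GFF3 (1-based inclusive) is converted at the I/O boundary in both
directions. Sequences are uppercased on read. IUPAC ambiguity codes other
than N are retained in sequence but treated as ambiguous by every GC
counter: ambiguous bases are excluded from numerator *and* denominator, so
N-rich assemblies neither inflate nor deflate GC. A GC value with zero
countable bases is reported as NaN, never as 0.

The primary transcript of a gene is the one with the greatest summed CDS
length, ties broken by lexicographically smallest transcript id. This
mirrors the longest-isoform convention used by orthology pipelines when
collapsing annotations to one protein per gene; the tie-break is this
package's convention, chosen for determinism.

## Length filters

* `min_chrom_len = 1,000,000` bases: sequences below this are treated as
  unplaced scaffolds and excluded from genome GC and chromosome-level
  statistics.
* `min_cds_len = 950` nt: shorter CDS are treated as gene fragments and
  excluded from CDS GC.

Both cutoffs are inclusive (a 950 nt CDS is retained, exclusion is
"< 950") and configurable. Species-level GC is count-pooled across
retained sequences/genes rather than averaged over per-unit fractions:
this matches the "GC of the complete genome" reading and is invariant to
how chromosomes are split. Whether species GC3 should pool codons or
average per-orthogroup values is genuinely open; pooling is the default
and an unweighted per-orthogroup mean is exposed as `method="mean"`.

## Alignment trimming and back-translation

The trimming rule keeps exactly the columns where *every* species carries
a standard residue (no gap, no X). This strict rule guarantees that only
codons homologous across the whole orthogroup are compared, and is
reproducible without an external trimming binary; externally trimmed
alignments can be supplied instead, since any aligned FASTA whose rows
pass the translation check is accepted. Back-translation maps kept column
k of species s to codon number "count of non-gap residues of s strictly
before k" of its unaligned CDS (one trailing stop codon tolerated), and
verifies that each mapped codon translates (standard nuclear code — valid
for all four insect orders targeted) to the aligned residue. The check
exists to reject frameshifted or mis-annotated gene models, which this
kind of filtering is designed to exclude; a mismatch is an error naming
the species and column, not a silent drop.

## Phylogenetically informed means

The "phylogenetically informed mean" is operationalized as the
intercept-only GLS estimate with Brownian-motion covariance
V_ij = depth of MRCA(i, j): the BM root/ancestral-state estimate. The
implementation solves the symmetric positive-definite system by Cholesky
factorization (never explicit inversion) and is cross-checked in the test
suite against R's `nlme::gls` with `corBrownian`, agreeing to 1e-9
relative. Trees must be rooted with branch lengths; zero-length terminal
branches get a diagonal jitter of 1e-8 x tree depth (logged) so duplicate
tips do not make V singular. For per-orthogroup means, species without
values are pruned from the tree (root-to-MRCA depths preserved);
orthogroups with fewer than 3 remaining species are skipped and logged.
Rooting and scaling of the input tree affect the estimate; the package
takes the tree as given and does not re-root.

## ANOVA and Tukey HSD

The two-way ANOVA is restricted to the design the order-level analysis
produces: a complete DNA-type x order table with one observation per cell
and no interaction term, fitted via statsmodels OLS (`value ~ C(A)+C(B)`);
the design is balanced so the classical sums of squares are
unambiguous. Degenerate cases: if the residual sum of squares is exactly
zero the F statistics are 0/0 and reported NaN, except that a factor whose
own sum of squares is exactly zero gets F = 0, p = 1. Tukey HSD compares
factor-level means with SE = sqrt(MSE / n_per_level) and adjusted p-values
from the studentized range distribution on the residual df; it is
implemented directly (the replicated-one-way helper in statsmodels does
not accept an external MSE) and its p-values are validated against a Monte
Carlo studentized-range oracle in the tests.

## Chromosome geometry

A gene's reference point is the midpoint of its CDS span,
floor((start + end)/2), chosen for symmetry under coordinate reflection
(a start-based mode is provided); telomere distance is
min(m, L - m) with L the assembly sequence length — chromosome ends are
taken as telomeres without repeat detection, which is appropriate for
telomere-to-telomere assemblies and wrong for fragmented ones. Distances
enter regressions in Mb. The size-GC classification is
"significant-negative" iff r < 0 and two-sided p < 0.05 (alpha
configurable); slopes are OLS on raw (not log) length. Landscape tables
sort SCOs by midpoint per chromosome and optionally smooth with a centred
rolling mean over `window` genes (default 10; window 1 is the identity).

## Divergence scoring

Columns where the three designated outgroups carry one identical standard
residue define the ancestral state. The ingroup score sums the
dissimilarity d(ancestral, observed) over those columns — skipping (and
not counting) columns where the ingroup has a gap or X, since the score
measures substitution divergence, not indels — and divides by total
alignment columns. The denominator is deliberately the alignment length;
normalizing by the conserved-column count instead is available as
`normalize_by="conserved"`, since "protein length" and "alignment length"
readings differ and both are defensible. Untrimmed alignments are the
intended input here: outgroup conservation already restricts the scored
columns.

The dissimilarity matrix is pluggable (any symmetric, non-negative 20x20
matrix with zero diagonal, e.g. the classical Sneath 1966 chemical
dissimilarity supplied as TSV). The built-in default is derived at runtime
from BLOSUM62 as d(a, b) = s(a,a) + s(b,b) - 2 s(a,b), which satisfies the
same axioms with solid provenance; because all calibration properties
(zero iff no mismatch, d/L for one substitution, monotonicity in
substitution load) hold for any admissible matrix, the choice rescales
scores without changing their structure. Cross-species comparisons should
use one matrix throughout.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analyses assume:

* **Species tree**: pure-birth (Yule) tree, default birth rate 1, tips
  sp01..spNN, ultrametric by construction. Simplest controllable model;
  empirical topologies can be supplied to any downstream function.
* **Per-species baseline GC3**: Brownian motion on that tree, root 0.35,
  sigma^2 = 0.01 per unit depth — giving realistic between-species spread
  (~0.3-0.5) at depth ~1.
* **Telomere gradient**: p(d) = p_far + delta * exp(-d / lambda) with
  defaults p_far = 0.35, delta = 0.10, lambda = 2 Mb. The exponential form
  is a modelling choice with a single interpretable length scale; real
  data show a monotone decline without committing to a functional form.
  The gradient shapes intergenic base composition (around p_far) and
  per-gene target GC3 (as an elevation over the species baseline).
* **Genes**: 1-3 exons, introns 100-1000 bp, both strands, placed
  uniformly without overlap, chromosome assignment proportional to
  length; protein lengths uniform 150-400 aa. Synonymous codons are
  sampled so the protein's expected GC3 equals its target, with the
  forced G/C third bases of Met/Trp compensated at degenerate sites
  (unachievable targets are clamped; realized GC3 is recorded).
* **tRNA counts**: 1 + Poisson(300 x codon frequency) per sense codon,
  either aligned with the species' own codon usage ("coupled") or with
  the same count multiset permuted across codons ("decoupled"), emitted
  in tRNAscan-SE-like tabular form with planted pseudogene and
  undetermined-anticodon rows that parsers must drop.
* **Divergence panels**: outgroups copy an ancestral protein exactly;
  each ingroup receives Poisson(rho x length) substitutions at uniform
  positions to uniform different residues, with true positions recorded.

One global seed determines every file byte-for-byte; stage seeds are
derived by hashing the seed with a stage label, so components can be
regenerated independently. Truth tables (per-gene target and realized
GC3, positions, species baselines) are the contract for all recovery
tests.

Not modelled, hence not demonstrated by passing tests: indel evolution
(alignments are gapless, so trimming is only exercised by hand-built
fixtures), repeat landscapes and isochore structure, assembly error,
annotation error beyond what the translation check rejects, and selection
on codon usage. Real-data runs exercise exactly the same code paths but
can show effects (alignment uncertainty, fragmented chromosomes,
non-equilibrium base composition) the generator does not produce.

## Problem sizes and determinism

Test and acceptance runs use deliberately desk-scale conditions chosen to
keep each check's statistical power high: 4-species orders with 1-2 Mb
chromosomes and 12-30 SCOs for GC summaries; 500 SCOs on 8-12 Mb
chromosomes (the regime where a 2 Mb gradient is identifiable) for the
telomere regression, with a delta = 0 control; 1,000 replicates on a fixed
32-tip tree for BM root recovery; 20 seeds per substitution rate for
divergence monotonicity. Every stochastic step flows from an explicit
seed, and end-to-end outputs are byte-deterministic given config.

## Known limitations

* The strict trimming rule removes more columns than permissive trimmers;
  kept-column sets from external tools will differ, which changes GC3
  denominators slightly (not systematically).
* The BM-GLS mean inherits the input tree's rooting and branch-length
  units; unrooted or arbitrarily scaled trees give different means.
* The two-way ANOVA layout is fixed at one observation per cell without
  interaction; richer designs need a general linear-model tool.
* Telomere distance assumes assembly ends are telomeres; do not use on
  scaffold-level assemblies.
* The published per-species supplementary dataset of the original insect
  study is not redistributed here; the three tests that recompute its
  order-level statistics fail with an explanatory message until it is
  exported under `data/published/`.
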