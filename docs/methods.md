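# Methods

This note documents the models and procedures behind `indelmark`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Variant retention model

An INDEL call is *detected* when it passes the site-quality box: read depth
≥ 5, mapping quality ≥ 20, and INDEL length ≥ 5 bp (all inclusive; the
5 bp floor is the smallest allele-size difference reliably resolved on a
12 % polyacrylamide gel). Detected calls are then pruned in two steps that
the summary object tracks as exact conservation identities:

1. heterozygous calls are set aside (`homozygous = detected − het`) — an
   inbred line should be homozygous, so residual heterozygosity, whether
   biological or a calling artifact, is uninformative for marker design;
2. calls on unanchored scaffolds are excluded
   (`retained = homozygous − unanchored`) — they cannot be placed on a map.

SNPs are retained when depth and mapping quality pass, the record carries
exactly one ALT allele (applied per record, before any splitting), and
neither allele contains an N.

Zygosity is read from the genotype (GT) field, never inferred from allele
depths. Multi-allelic INDEL records are classified per ALT but retained at
most once per site, represented by the longest qualifying ALT, so counts
are per locus. Input VCFs are assumed left-aligned; the module does not
re-normalize. A record missing DP or MQ is flagged un-filterable and is
never silently retained.

Genome-wide density is reported as retained count ÷ anchored chromosome
length (Mb); when the genome model declares a larger total assembly length
the full-assembly density is reported as well, since either denominator is
defensible. Pericentromeric membership is 1-based inclusive interval
containment; window counts default to 5 Mb tiling windows with a
configurable step.

## Primer design

Constraints: primer length 18–30 nt, GC 40–60 %, |Tm_f − Tm_r| ≤ 3 °C,
product 100–600 bp *on both alleles*, and the amplicon must contain the
full variable site. Melting temperature is the linear GC-fraction formula
Tm = 64.9 + 41·(n_GC − 16.4)/N, standard for 18–30-mers; it is
deterministic and dependency-free, and the `tm` argument of
`design_primers` accepts any replacement (e.g. a nearest-neighbor model).
No primer-dimer or hairpin screening is performed, and no in-silico PCR
against off-target sites — known limitations.

The search is fully deterministic: forward-primer 3′ ends walk outward
(upstream) from the INDEL with lengths tried short-to-long, and for each
feasible forward primer the reverse primer walks outward downstream. The
first feasible pair wins, which makes the nearest primers with the smallest
product the canonical answer. Design failure (homopolymer flank,
insufficient flank near a contig end) is an explicit result object, not an
exception.

Anchor-set selection apportions markers to chromosomes proportionally to
length with largest-remainder rounding (every chromosome holding a
designable candidate gets at least one), then solves the within-chromosome
placement exactly: binary search over achievable minimum gaps with a
greedy-leftmost feasibility check, the classic max-min placement algorithm.
This is deterministic and provably optimal for the min-gap objective, which
a one-pass greedy is not.

## Panel scoring and clustering

A marker is *polymorphic* between two cultivars iff both amplified and the
product sizes differ; a pair with a missing product is uninformative and
excluded from the count, but the percentage denominator stays at the full
marker total — the convention that reproduces published panel tables, where
percentages are consistent with count ÷ total even for markers with failed
amplifications. Percentages round half-away-from-zero to integers. A third
allele still scores as polymorphic whenever the two sizes differ.

Clustering is classic UPGMA on the polymorphic-fraction distance
(count ÷ total): merge the closest pair, average distances weighted by
cluster sizes, node height = merge distance / 2 (so cophenetic distance =
merge distance and the tree is ultrametric). Ties are broken toward the
lexicographically smallest pair of cluster labels (a cluster's label is its
smallest leaf name), making the tree identical across platforms. The
implementation is independent of SciPy; SciPy's average-linkage cophenetic
distances serve as the cross-check in the test suite. No bootstrap values
and no other linkage methods are provided.

## F2 mapping

Segregation: χ² = Σ (obs − exp)²/exp over the two phenotype classes with
expected 3:1 wild-type:mutant, no continuity correction, df = 1. The
consistency verdict uses the 5 % critical value 3.841; the survival-function
p-value is reported alongside.

Recombinant counting uses the recessive-class scheme: over phenotypically
mutant plants (homozygous causal allele), genotype A contributes 0
recombinant gametes, H contributes 1, B contributes 2; each non-missing
plant contributes 2 informative gametes. Missing genotypes are never
imputed. The recombination-fraction estimate is recombinants ÷ informative.

Interval delimitation takes the contiguous run of markers sharing the
minimum recombinant count (the run containing its first occurrence in
position order) and extends to the nearest marker on each side that carries
at least one recombinant — the innermost recombinant-bearing flanks.
Physical length is right − left with no +1, matching how deletion spans
from sequenced boundary coordinates are conventionally reported
(end − start). A side with no recombinant-bearing marker is flagged open,
never silently truncated.

A maximal run of consecutive markers that fail to amplify in all mutant
plants inside the interval is reported as a candidate deletion; given
sequenced boundary coordinates, span = end − start in bp and rounded kb.

## Synthetic-data generator

The generator emits *variant calls*, not reads: sequencing, trimming and
alignment are upstream of the package's scope, so simulating them would
test nothing the package contains. Defaults are calibrated to a
soybean-scale resequencing study: INDEL rate 5.2 × 10⁻⁵/bp and SNP rate
2.55 × 10⁻⁴/bp (≈ 49 k INDELs and 242 k SNPs on a 950 Mb genome),
heterozygous fraction 43/49 276, unanchored fraction 620/49 276, mean depth
30.3. Depth is negative-binomial (shape 8) and mapping quality a discretized
normal clipped to [0, 60], drawn independently per site; their joint law in
real callers is more structured, so quality-filter marginals, not
correlations, are what passing tests certify. INDEL lengths follow a capped
geometric decay starting at 1 bp (p = 0.25), echoing the monotone decline of
real size spectra; real spectra also carry polymer-motif periodicity the
generator does not attempt. Unanchored calls are relabeled with a reserved
`scaffold_` name prefix so exclusion is purely name-based. Sites are drawn
without collision, so multi-variant loci never occur in synthetic data.

The cultivar-panel generator fixes the first two cultivars as the reference
and alternate parents (guaranteeing two observed alleles per marker), draws
the rest uniformly, adds a third product size to a marker with probability
14/165 (assigned to 1–4 cultivars), and knocks out cells independently at
rate 0.02 — chosen so that the expected share of markers with ≥ 1 missing
cell over 14 cultivars (1 − 0.98¹⁴ ≈ 0.25) matches the ~40/165 observed in
real panels. Real missingness clusters by cultivar (shared primer-site
variants); the generator's independence assumption does not capture that.

F2 gametes follow the Haldane model (no interference): marker alleles form
a Markov chain along each chromosome with flip probability
r = (1 − e^(−2d))/2 between adjacent loci, d in Morgans from a uniform
cM-per-Mb scale (default 2.5). The closed form is what makes
recombination-fraction oracles and 3σ tests possible; real genomes have
interference and non-uniform recombination (suppressed pericentromerically),
so simulated intervals are cleaner than real ones.
`simulate_mutant_class` conditions both gametes on carrying the mutant
allele at the causal locus, which is equivalent to (and much cheaper than)
rejection-sampling mutants from full F2 populations. A deletion scenario
marks every marker whose primer footprint lies inside the region as failing
in homozygous carriers.

One global seed is split into fixed per-generator streams (reference,
variants, panel, F2), so a module's output can be regenerated independently
and every run is byte-reproducible.

## Problem sizes

The test suite and the acceptance script run on deliberately small inputs:
2 × 150–400 kb genomes with rates elevated to 5 × 10⁻⁴ (INDEL) and 10⁻³
(SNP) for ledger-equivalence checks, a 2 × 5 Mb genome for the end-to-end
demo, 21 markers every 500 kb for the mapping suites, and 124-mutant
populations over 200 replicates. These sizes keep every statistical check
(binomial/Poisson 3σ bounds, ≥ 95 % interval recovery) well-powered while a
full run of suite plus acceptance script completes in well under a minute.

## Known limitations

* No read-level simulation, alignment or variant calling; no VCF
  re-normalization.
* Primer design screens thermodynamics only through the linear Tm formula;
  no secondary-structure or off-target checks.
* The marker-validation rate observed in wet labs (primer failure plus
  monomorphism) is modeled as an input label on markers, not predicted.
* Single-locus recessive model only: no dominant scheme, no multi-locus or
  quantitative traits, no genetic-map (cM) estimation beyond per-marker
  recombination fractions.
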