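# Methods

## Model and assumptions

The package treats the male-specific region of the Y chromosome (MSY) as a
single non-recombining locus.  Under the infinite-sites ideal, every true
SNP arose once on the sample genealogy, so the set of samples carrying the
derived allele is exactly one clade, and any two true variants have
derived-carrier sets that are nested or disjoint (a laminar family — the
perfect-phylogeny condition).  Departures from this ideal are exactly what
the pipeline is built to absorb or flag:

* **mapping artefacts** concentrate in sequence with strong self- or
  X-homology (Ampliconic palindromes, X-transposed block) and masquerade
  as recurrent variants — they end up *discarded*;
* **genuinely recurrent or back-mutations** are rare on the Y but not
  absent — also *discarded*;
* **low-pass coverage** leaves many calls missing — these are imputed from
  the haplogroup structure before classification;
* **private variation** cannot be validated against the tree at all — it
  is set aside as *singletons* unless a variant is already a described
  marker.

The reference haplogroup tree (ISOGG-style: named clades, parent links,
defining markers with ancestral/derived alleles) is taken as ground truth
about deep structure; the pipeline validates the *new* variants against
it, it does not re-estimate the reference topology.

## Pipeline rules and their rationale

**MQ filter (default threshold 60, Phred).** MQ 60 corresponds to an
unambiguously placed read pair.  The threshold is inclusive (MQ = 60 is
kept) and configurable.

**Sample placement.** A sample descends from the root into a child clade
when the child's subtree shows at least one observed derived marker and
the child itself shows no observed ancestral marker.  Missing marker calls
neither support nor contradict; a node whose markers are all uncalled for
a sample is still traversed when a deeper marker is observed derived,
because on a non-recombining chromosome a derived descendant state implies
derived ancestral states.  Samples supporting two incomparable children
are flagged inconsistent and held at the deepest common ancestor rather
than excluded — exclusion would silently change every denominator
downstream.

**Polarization.** Outgroup = REF ⇒ ALT derived; outgroup = ALT ⇒ REF
derived, in which case the carrier set is recomputed as the REF-callers
before classification (an outgroup matching ALT logically makes the
reference base the derived state).  A third outgroup allele, or an absent
position, leaves polarity *unresolved*; such sites are retained and
placed with ALT treated as derived, carrying a per-site flag, and are
excluded from polarity-dependent statistics only.

**Missing-call resolution.** With C the smallest haplogroup clade
containing all observed derived carriers: if C's observed members are all
derived, missing members of C become derived and everything outside C
ancestral; if C is mixed, every missing call becomes ancestral.  The
conservative branch means imputation can only ever *shrink* a carrier set
toward the observed carriers, never invent a clade that was not seen —
classification errors caused by imputation are therefore always discards,
never false informative variants.  Resolution runs before classification.

**Classification.** Single carriers are singletons unless the site is a
known marker consistent with its carrier's placement (then informative,
mirroring the convention that previously described variants are trusted at
single occurrence).  Multi-carrier sites are informative when their
carriers equal the sample set of exactly one haplogroup clade (deepest
such clade on ties), or when they fall inside the set of samples assigned
*directly* to a single haplogroup node (its paragroup) and are pairwise
compatible with every variant already accepted there — this is how new
subclades below the known tree are admitted.  For a terminal haplogroup
the paragroup is the whole clade; extending the subset rule to internal
paragroups is this package's choice, made so that genuine clades falling
between two named haplogroups are not lost.  Everything else is
discarded.  Subset-type candidates are scanned in decreasing carrier-set
size with ties broken by position, which makes the compatibility test
deterministic and the output independent of input order.

**Network construction.** For compatible binary characters the
median-joining network at ε = 0 *is* the unique perfect phylogeny, so the
network is built directly as the inclusion lattice of carrier sets:
distinct carrier sets become nodes (variants sharing a carrier set share
an edge — collapsed haplotypes), each set's parent is its smallest proper
superset, samples sit at the node of the smallest set containing them,
and the root is the all-ancestral haplotype.  General median-vector
search is deliberately out of scope; the classification stage guarantees
its precondition.

**Skeleton.** The skeleton is the set of SNPs on edges whose descendant
haplotypes hold at least `min_descendants` samples (default 2, i.e.
internal edges).  This is one defensible operationalization of "the deep
branches constituting the roots of the main clades"; the cutoff is a
parameter precisely because the concept is not sharply defined.  By
default only informative variants are placed in the network, so the
skeleton fraction is computed relative to them; singletons (whose size-1
carrier sets are compatible with anything) can be placed explicitly to
hang private variants off each haplotype, as drawn in median-joining
figures — with them placed, the off-skeleton mass tracks the singleton
fraction of the data.

**Summaries.** Percentages are count / status-total × 100 rounded to one
decimal, densities count / (class length / 10 kbp) to two decimals, both
half-away-from-zero (matching hand-tabulated tables).  Class lengths come
from the region map; the fallback defaults (8.6 / 3.4 / 2.8 + 6.9 / 0.4 /
1.0 Mbp for X-degenerate / X-transposed / Ampliconic split / Other /
readable heterochromatin) approximate the published class sizes, since no
exact mask is published — recomputed densities with these lengths agree
with published ones only to ~1%.  A zero-length class with a nonzero
count reports an undefined (NaN) density rather than raising.  Published
percentage tables of this kind also contain a few entries that disagree
with their own printed counts by ≤ 0.06 pp (presumably slightly different
denominators upstream); the test suite asserts printed precision where
the arithmetic supports it and 0.1 pp on those entries.

## Synthetic data: what it emulates, what it does not

`msy.simdata` generates a Yule (pure-birth) genealogy by uniform random
leaf attachment, labels the smaller root child "A" (mirroring the deep
A-versus-rest split at the MSY root) plus the largest clades as named
haplogroups (the top-k-by-size rule automatically yields properly nested
labels), and plants three kinds of sites: clean (carriers = one clade),
singletons (one terminal branch) and recurrent (union of two disjoint
clades, rejection-sampled so the union is neither a true clade nor inside
a single paragroup — i.e. so the site genuinely conflicts with the tree).
Each named haplogroup receives equivalent defining markers on its stem
branch, reported in an ISOGG-style table.  On top of the true genotypes it
layers independent Bernoulli missingness, sub-threshold mapping qualities,
and an outgroup that is the true ancestral allele except for occasional
third alleles.

Default study conditions (chosen once, as a desk-scale emulation of a
~1,200-male low-pass cohort): 200 samples; 50 named haplogroups with 5
equivalent markers each (ISOGG nomenclature is fine-grained and lists many
equivalent SNPs per clade; marker redundancy is what makes placement
robust to missing calls — with k markers a clade loses its anchor for a
sample with probability `missing_rate^k`); class layout = 1/10-scale
published class sizes with the published total-density profile (25 / 13 /
17.2 / 2.9 / 25.7 / 49.5 SNPs per 10 kbp), giving ≈ 4,100 sites;
recurrent fraction 0.15 and singleton fraction 0.34 (the published
discarded and singleton shares); missing rate 0.30 (typical of low-pass
calls); outgroup third-allele rate 0.001 (≈ the published 23/20,155);
low-MQ fraction 0.10.

Not emulated: read-level error and coverage structure (missingness is
independent per call, whereas real low-pass missingness is correlated
along the genome and across samples), linked recurrences from gene
conversion in palindromes (recurrent branch pairs are drawn uniformly),
reference bias (the reference allele is always ancestral in simulation —
the REF-derived code path is exercised by hand-built fixtures instead),
and indels/STRs (excluded by design).  Passing tests therefore show the
*logic* is right under controlled violations, not that real palindromic
sequence will yield any particular informative fraction.

## Numerical and degenerate-input choices

* Ties for "deepest clade with this sample set" resolve to the deepest
  node; ties in subset-candidate order resolve by position.
* A carrier set that becomes empty or universal after resolution is
  dropped with a warning (not counted in the three classes).
* An all-missing site is dropped as monomorphic.
* Haplogroup trees must have exactly one root and acyclic parent links; a
  haplogroup listed with two different parents is an error, but repeated
  rows per haplogroup are the normal way to list multiple markers.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical config + seed reproduces
  byte-identical output files.

## Problem sizes used by the test and acceptance runs

Tests run the full pipeline at 200 samples × ≈ 4,100 sites (seconds per
fit); the randomized accounting sweep uses 100 draws at 10–40 samples ×
≈ 440 sites; the compatibility oracle checks ≤ 120-site informative sets
exhaustively.  These sizes make the whole suite complete in well under a
minute while keeping every assertion exact (recovery and discard rates are
asserted at 100%, not approximately).

## Known limitations

* The "univocal association" and "skeleton" concepts have no published
  operational definition; the rules here are explicit, configurable
  readings, and other readings would shift the informative/discarded split
  and the skeleton fraction.
* Imputation accuracy is bounded by the conservative mixed-clade branch:
  derived calls missing at sites of clades *between* named haplogroups are
  imputed ancestral (≈ 0.8% of imputed calls at the default label density).
  This is the price of never fabricating clades.
* Hard calls only: genotype likelihoods, imputation quality scores and
  recurrent-mutation modelling beyond the discard rule are out of scope.
* At high missing rates, distinct observed subsets of the same unlabelled
  clade are mutually incompatible and all but the largest are discarded;
  the discarded class in noisy runs therefore overstates true homoplasy.
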