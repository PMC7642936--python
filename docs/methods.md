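# Methods

## The analysis pipeline

`corediv` analyzes biallelic SNP-array genotypes of an allotetraploid
germplasm collection. The stages, and the conventions each one fixes:

### Sequence representation

Array calls (AA / AB / BB / missing) are converted to one DNA base per locus:
AA maps to the marker's A-allele base, BB to the B-allele base, and both AB
and missing to the gap symbol `-`. Mapping heterozygotes to `-` is a
deliberate choice: the representation is haploid, the crop is highly selfing
so heterozygous calls are rare, and a het carries no single base that
identity scoring could use. A consequence used as a test invariant: the gap
count of a sample equals its heterozygous-plus-missing call count. Loci are
emitted in genomic order (chromosome, then 1-based position, VCF
convention); markers without a consensus position sort last.

### In-silico assembly calls

A marker is called against a genome assembly by searching both strands for
its 71-mer flanking sequence with the variant base (position 36 of 71) set to
each allele in turn. A qualifying hit is a contiguous exact match of at
least 65 of the 71 bases that covers the variant position; a call is made
only when all qualifying hits across both allele versions identify exactly
one genomic location. The matcher exploits the fact that any qualifying
match must contain one of the seven 65-mers starting at offsets 0–6, so
searching those windows and de-duplicating by implied variant coordinate is
exhaustive; an independent brute-force sliding-window matcher confirms
equivalence in the tests. Requiring the variant inside the matched region is
a design decision (the criterion is meaningless otherwise). Minus-strand
hits report the allele on the marker (plus) strand.

Merging the two progenitor call sets into a synthetic-tetraploid sample:
one call → that base; equal calls → that base; conflicting calls → `-`.
The conflict rule is conservative — such loci are subsequently removed when
the alignment is restricted to loci present in the synthetic tetraploid —
and keeps the downstream A-like/B-like taxonomy clean. Consensus positions
are assigned by assembly priority (diploid progenitors first, then the
tetraploid assemblies in a caller-supplied order).

### Replicate concordance

Identity between two samples is direct positional comparison over loci where
both have non-gap bases (the rows are pre-aligned by construction, so a
local aligner would add only edge effects): `100 × matches / n_compared`.
With zero comparable positions the identity is undefined and the pairing is
neither observed nor similar. Thresholds: **observed** means identity
strictly greater than 70%, **similar** means identity ≥ 98%. An accession is
homogeneous iff all of its C(N,2) pairings are similar; single-sample
accessions are excluded from purity statistics. Collection-level mean and
median identity are computed over observed pairings only.

### Centroid clustering

Samples are processed in input order (all rows have equal length, so no
length sort is needed); each is assigned to the best-identity centroid at or
above the threshold, with ties going to the earliest centroid, else it
founds a new cluster. Best-hit assignment is the default because it is more
robust to input order; a first-hit mode is provided to emulate greedy tools
that accept the first qualifying centroid. The guaranteed contract is
member-to-centroid identity ≥ threshold; member-to-member identity within a
cluster can be below it.

### Population-genetic summaries

All operate on dosage (count of B alleles, 0/1/2, NaN missing):

- **Marker filtering** drops monomorphic markers and markers with minor
  allele frequency below the cutoff (default 5%), frequencies computed over
  non-missing calls.
- **LD r²** is the squared Pearson correlation of dosages over
  pairwise-complete samples (composite LD — no phasing needed). Zero
  variance gives undefined r², which never prunes.
- **LD pruning** scans each chromosome in position order keeping a running
  set; a candidate is discarded iff r² with any kept marker within the
  window (default |Δpos| ≤ 1 Mb, r² > 0.2) exceeds the threshold. The kept
  set is audited exhaustively in the tests.
- **PCA** standardizes each marker by its B-allele frequency p̂ — center by
  2p̂, scale by √(p̂(1−p̂)) — sets missing entries to 0 after
  standardization, and eigendecomposes the sample×sample covariance.
  Coordinates are eigenvectors scaled by √eigenvalue; explained fractions
  divide by the sum of positive eigenvalues. Coordinates are only defined up
  to per-component sign, so all structure statements use sign-invariant
  contrasts (group-mean separation).
- **F_ST** is Weir & Cockerham (1984) θ from diploid genotype counts: per
  locus, variance components a (among populations), b (among individuals
  within populations) and c (within individuals, from observed
  heterozygosity), with θ = Σa / Σ(a+b+c) over loci where every group has
  data (per-locus complete cases). Using genotype rather than allele counts
  lets heterozygosity enter component c, matching the cited estimator. The
  missing-data conventions above are stated explicitly because reference
  implementations delegate them to package defaults.

### Subgenome-exchange detection

At each locus a tetraploid base is classified against the progenitor
alleles: **A-like** iff it equals the A-genome allele and not the B-genome
allele, **B-like** for the mirror case, **other** when the progenitors are
invariant or the base matches neither, **unevaluable** when any of the three
calls is missing. The classification is exhaustive and mutually exclusive
(property-tested over the full input space). A trans-subgenome allele —
B-like on chromosomes A01–A10 or A-like on B01–B10 — flags an exchange.

A collection-level summary over an accession panel counts **evaluable**
positions (no panel accession unevaluable) and **exchanged** positions
(≥1 panel accession flagged). Tract segmentation runs per accession per
chromosome over that accession's *informative* loci (classified A-like or
B-like); uninformative loci are transparent — they neither extend nor break
a run — because a real invasion tract necessarily skips loci where the
progenitors are invariant. A tract is a maximal run of ≥ `min_run`
(default 3) consecutive flagged informative loci; the default separates
tract-scale invasion from single-locus exchange or genotyping error, while
single flagged loci still count toward the exchanged-position total. The
panel is always caller-supplied, never hard-coded.

Note that the alignment-width filter (loci present in the synthetic
tetraploid) and the exchange evaluability filter (data present for all panel
lines) are different restrictions; the pipeline reports both rather than
forcing agreement.

## The synthetic collection generator

The generator produces truth-known collections with the statistical
structure the analysis consumes, at desk scale.

**What it emulates.** A 20-chromosome tetraploid (A01..A10, B01..B10,
100 Mb each) genotyped at 2,000 jittered, roughly evenly spaced markers;
five clades nested in two subspecies-analogue groups, 30 accessions per
clade; a replicate design of 42 duplicated / 9 triplicate / 3 quadruplicate
/ 1 quintuplicate accessions (the remaining 95 single-sampled), giving 223
samples; a diploid progenitor allele table with differing alleles at 55% of
markers and 3% progenitor missingness; per-cell missing (1%) and
heterozygous (0.5%) call injection; replicate contamination at 10% per
replicate beyond the first; and planted subgenome exchanges — a terminal
tract of 5–20 Mb with probability 0.25 per accession, Poisson(0.7)
interstitial tracts of 1–4 Mb, and single-locus exchanges at 1% of
diagnostic loci per accession. This is roughly a 1/7-density,
1/5-accession-count rendition of a real core-collection genotyping study;
the replicate design scales the real 193/43/16/1 shape by ~1/4.6.

**Model choices.**

- *Drift model.* Clade structure is independent per-locus founder-allele
  flipping (ancestor → subspecies founder at 0.10 → clade founder at 0.06 →
  accession at 0.004), not a coalescent. This produces the between-group
  allele-frequency differentiation that PCA and F_ST consume, at a fraction
  of the cost, but has no linkage, no site-frequency-spectrum realism and no
  within-accession heterozygosity structure.
- *Subgenome-diagnostic loci are exchange-only.* At loci where the
  progenitor alleles differ, a tetraploid switching to the trans allele *is*
  a homoeologous exchange in this system — so lineage drift is confined to
  non-diagnostic loci, and diagnostic loci change only through planted
  tract or single-locus exchange events. This keeps planted-truth recovery
  well defined (an in-tract diagnostic locus is exactly the trans allele)
  and mirrors the interpretation that much of the allelic diversity at
  diagnostic positions arises from exchanges.
- *Order of operations.* Founders → accession drift → exchange tracts →
  replicate copying (contaminated replicates copy a different accession,
  never the first replicate) → missing/het injection last.

**What passing tests do and do not show.** Recovery results on this
generator demonstrate the pipeline's correctness and calibration under the
stated model: independent loci, exact within-accession copies, exchange
signal uncontaminated by drift at diagnostic loci. They do not demonstrate
robustness to linkage disequilibrium between nearby markers, array-specific
genotyping error modes, residual heterozygosity in recently admixed lines,
or reference-allele ambiguity at diagnostic loci — all present in real
data, where modest deviations from planted-truth-style perfection are
expected.

## Recovery experiments (tests and acceptance script)

Problem sizes were chosen so the full suite runs in seconds on one CPU:

- Mixture detection: 10 default collections; sensitivity over planted
  contaminations whose source diverges >10% from the host (contaminations
  from near-identical lines are not detectable at a 98% threshold by
  construction and are excluded); false-positive rate over truly pure
  replicated accessions.
- Clade-partition recovery: one noise-free collection (contamination,
  missingness, heterozygosity, accession drift and exchange all off),
  clustering at 99%.
- F_ST ordering: 100 compact two-clade collections (4 chromosomes × 75
  markers, 16 accessions per clade); between-clade θ vs θ of a random split
  of one clade. The null check draws 500 samples × 1,000 loci from one
  panmictic pool (|θ| < 0.01).
- Tract recovery: 5 default collections, a 16-accession panel spread over
  the clades; a planted tract is eligible when ≥3 informative evaluable loci
  fall inside it, and boundary error is measured in intervals of the
  chromosome's informative-evaluable marker grid — the resolution limit of
  any marker-based detector.
- PCA: PC1 group-mean separation of the subspecies-analogue groups,
  standardized by within-group spread, sign-invariant.

## Known limitations

- The greedy clustering reproduces the *method* of greedy centroid tools,
  not any specific tool's k-mer prefilter heuristics; counts on real data
  may differ slightly between best-hit and first-hit modes (both provided).
- The in-silico caller is exact-match only: no gapped alignment, no
  e-values, so a single SNP in an assembly within 6 bp of the variant
  suppresses a call that a tolerant aligner might still make.
- F_ST has no bootstrap confidence intervals; values between groups with
  very unequal or very small sizes should be interpreted cautiously.
- Sample exclusion (e.g. suspected label-tracking errors) is an explicit
  caller-provided list (`GenotypeMatrix.drop_samples`); the pipeline does
  not infer mislabeling.
- The marker subset feeding PCA/F_ST is an explicit input (the LD-pruned
  list), keeping the choice visible rather than baked in.
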