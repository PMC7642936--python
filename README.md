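# corediv

Genotype-diversity analysis for allotetraploid germplasm core collections,
built around the kind of data produced when a crop collection — cultivated
peanut (*Arachis hypogaea*) is the motivating system — is genotyped on a
biallelic SNP array with replicate samples per accession.

Curators and breeders who genotype a core collection face a recurring set of
questions: Are the replicate seeds of an accession genetically the same
(accession purity)? How much of the collection is redundant near-duplicates?
What is the population structure, and how differentiated are the named groups
(botanical variety, market type, origin)? And, specific to an allopolyploid:
how much of the variation is due to homoeologous **subgenome exchanges** —
segments of the A subgenome (from *A. duranensis*) replaced by the
corresponding B-subgenome segment (from *A. ipaensis*) or vice versa?

`corediv` implements that full pipeline as a Python library:

- **genotype_io** — VCF in/out, conversion of AA/AB/BB/missing array calls to
  a one-base-per-locus FASTA sequence representation (`AA → A-allele base,
  BB → B-allele base, AB/missing → '-'`), marker/metadata tables.
- **insilico** — base calls for genome assemblies from each marker's 71-mer
  flanking sequence (contiguous exact match of ≥65/71 bases covering the
  variant, unique genomic location, both strands), merging the two diploid
  progenitor call sets into a synthetic-tetraploid sample, and consensus
  position assignment by assembly priority.
- **replicates** — C(N,2) replicate pairings per accession; gap-excluded
  percent identity; pairings "observed" above 70% and "similar" at ≥98%;
  accession purity classification (homogeneous / mixed / single-sample).
- **cluster** — greedy centroid clustering at an identity threshold
  (best-hit default, first-hit mode available) for redundancy assessment and
  reduced representative sets.
- **popgen** — monomorphic/MAF marker filtering, composite-LD r² with
  1 Mb sliding-window pruning, allele-frequency-standardized genotype PCA,
  and pairwise Weir & Cockerham (1984) θ:

  θ = Σ_l a_l / Σ_l (a_l + b_l + c_l),

  with per-locus variance components a (among populations), b (among
  individuals within populations) and c (within individuals, carrying
  observed heterozygosity), computed from diploid genotype counts.
- **subgenome** — classification of each tetraploid call against the
  progenitor alleles (A-like / B-like / other / unevaluable), trans-subgenome
  exchange flags, collection-level exchange summaries over an accession
  panel, and tract segmentation (runs of ≥3 consecutive trans alleles).
- **simulate** — a truth-known synthetic collection generator (clades,
  replicate design, contamination, missingness, planted exchange tracts)
  that every stage is tested against.

## Worked example

`examples/` contains one narrative script per capability. For instance:

```sh
$ python examples/03_replicate_concordance.py
expected pairings: 97
observed (>70% identity): 97
similar (>=98%): 94
mean / median identity of observed pairings: 99.7% / 100.0%
homogeneous / mixed / single-sample accessions: 52 / 3 / 95
planted mixed accessions: 4, detected mixed: 3, overlap: 3
```

Of the 97 replicate pairings in this synthetic collection, 94 are similar at
the 98% threshold; the three accessions with a missed pairing are flagged
mixed, and all of them correspond to planted contaminations (the fourth
planted mixture came from a nearly identical line of the same clade and is
genuinely undetectable at 98%).

```sh
$ python examples/06_subgenome_exchanges.py
evaluable positions (data present for all panel lines): 1488
positions with exchange evidence in >=1 accession: 151 (10.1%)
tracts (>=3 consecutive trans alleles): 3
```

About a tenth of evaluable positions show a trans-subgenome allele in at
least one of the 16 panel accessions; multi-megabase runs are reported as
invasion tracts with their chromosome coordinates.

A thin CLI mirrors the library (`corediv simulate | bases | genome-calls |
replicates | cluster | prune | pca | fst | subgenome`); run
`corediv --help` for the subcommands.

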