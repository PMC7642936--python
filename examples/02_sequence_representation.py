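"""Convert SNP-array calls to the FASTA sequence representation.

Homozygous AA/BB calls become the marker's allele base; heterozygous and
missing calls become '-'.  The resulting one-base-per-locus alignment (in
genomic order) is what identity scoring, clustering and subgenome
classification operate on.
"""

import tempfile
from pathlib import Path

from corediv import SimParams, calls_to_bases, read_vcf, simulate, write_fasta, write_vcf

sim = simulate(SimParams(seed=17))
with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "collection.vcf"
    write_vcf(sim.genotypes, vcf)
    g = read_vcf(vcf)
    b = calls_to_bases(g)
    fasta = Path(tmp) / "collection.fasta"
    write_fasta(b, fasta)
    print(f"{g.n_samples} samples x {g.n_markers} markers -> {b.n_loci}-base alignment")
    first = b.samples[0]
    seq = b.sequence(first)
    print(f"{first}: {seq[:60]}...")
    gaps = seq.count("-")
    print(f"gaps for {first}: {gaps} (= heterozygous + missing calls)")
# Each FASTA record is one sample; the gap count per record equals that
# sample's heterozygous-plus-missing call count.
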