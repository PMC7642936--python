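"""Score replicate concordance and classify accession purity.

Each accession with N replicate samples yields C(N,2) pairings.  A pairing is
"observed" above 70% identity and "similar" at >= 98%; accessions whose
pairings are all similar are homogeneous, the rest are mixed — the synthetic
truth tells us which mixtures were planted.
"""

from corediv import SimParams, calls_to_bases, classify_accessions, score_pairings, simulate
from corediv.genotype_io import accession_of

sim = simulate(SimParams(seed=17))
b = calls_to_bases(sim.genotypes)
counts: dict[str, int] = {}
for s in b.samples:
    counts[accession_of(s)] = counts.get(accession_of(s), 0) + 1

pairs = score_pairings(b)
purities, summary = classify_accessions(pairs, counts)
print(f"expected pairings: {summary['n_expected_pairings']}")
print(f"observed (>70% identity): {summary['n_observed']}")
print(f"similar (>=98%): {summary['n_similar']}")
print(f"mean / median identity of observed pairings: "
      f"{summary['mean_identity_observed']:.1f}% / {summary['median_identity_observed']:.1f}%")
print(f"homogeneous / mixed / single-sample accessions: "
      f"{summary['n_homogeneous']} / {summary['n_mixed']} / {summary['n_single_sample']}")

planted = {
    accession_of(s) for s, src in sim.truth.sample_source.items()
    if accession_of(s) != src
}
detected = {a.accession_id for a in purities if a.status == "mixed"}
print(f"planted mixed accessions: {len(planted)}, detected mixed: {len(detected)}, "
      f"overlap: {len(planted & detected)}")
# Detection misses only contaminations whose source line is nearly identical
# (same clade, above the 98% similarity threshold).
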