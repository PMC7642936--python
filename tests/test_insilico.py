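"""In-silico calling of marker flanks against genome assemblies."""

import numpy as np
import pytest

from corediv import (
    MarkerDef,
    SimParams,
    assign_positions,
    call_from_genome,
    call_genome,
    filter_loci_present_in,
    merge_diploid_calls,
    simulate,
)
from corediv.insilico import GenomeCallSet, Hit, revcomp
from corediv.genotype_io import GAP
from corediv.simulate import make_genome_from_markers

from conftest import make_base_matrix

RNG = np.random.default_rng(42)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


def make_marker(rng=RNG, allele_a="G", allele_b="T"):
    flank = random_seq(71, rng)
    flank = flank[:35] + allele_a + flank[36:]
    return MarkerDef("mX", allele_a, allele_b, flank=flank)


def probe_of(m: MarkerDef, allele: str) -> str:
    return m.flank[:35] + allele + m.flank[36:]


def brute_force_hits(probe: str, genome: dict[str, str]) -> set[tuple]:
    """Exhaustive matcher: slide the full 71-mer over every offset of both
    strands; qualify when a contiguous exact run of >=65 bases covers the
    variant (offset 35).  Returns plus-strand variant coordinates."""
    out = set()
    for name, seq in genome.items():
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            n = len(s)
            for off in range(n - 1):
                lo = max(0, -off)
                hi = min(71, n - off)
                if hi - lo < 65:
                    continue
                match = [s[off + k] == probe[k] for k in range(lo, hi)]
                # longest run of True containing the variant index
                vi = 35 - lo
                if vi < 0 or vi >= len(match) or not match[vi]:
                    continue
                left = vi
                while left > 0 and match[left - 1]:
                    left -= 1
                right = vi
                while right < len(match) - 1 and match[right + 1]:
                    right += 1
                if right - left + 1 >= 65:
                    if strand == "+":
                        pos = off + 35 + 1
                    else:
                        pos = n - (off + 35)
                    out.add((name, pos, strand))
    return out


def test_exact_containment_calls_allele_a():
    m = make_marker()
    genome = {"c1": random_seq(300) + probe_of(m, m.allele_a) + random_seq(300)}
    base, hit = call_from_genome(m, genome)
    assert base == m.allele_a
    assert hit.pos == 300 + 36 and hit.strand == "+"


def test_two_locations_yield_no_call():
    m = make_marker()
    p = probe_of(m, m.allele_a)
    genome = {"c1": random_seq(100) + p + random_seq(100) + p + random_seq(50)}
    assert call_from_genome(m, genome) == (None, None)


def test_64_base_submatch_is_rejected():
    """A 2 kb genome containing only a 64-base exact run covering the variant
    must give no call (threshold is 65)."""
    rng = np.random.default_rng(7)
    m = make_marker(rng)
    p = probe_of(m, m.allele_a)

    def corrupt(s, i):
        return s[:i] + ("A" if s[i] != "A" else "C") + s[i + 1 :]

    # breaking positions 2 and 67 leaves the longest run covering the
    # variant at 67-2-1 = 64 bases
    broken = corrupt(corrupt(p, 2), 67)
    genome = {"c1": random_seq(950, rng) + broken + random_seq(1000, rng)}
    assert brute_force_hits(broken, {"c1": p}) == set()  # sanity on the corruption
    assert call_from_genome(m, genome) == (None, None)


def test_reverse_strand_call_reported_on_plus_strand():
    m = make_marker()
    genome = {"c1": random_seq(120) + revcomp(probe_of(m, m.allele_b)) + random_seq(80)}
    base, hit = call_from_genome(m, genome)
    assert base == m.allele_b
    assert hit.strand == "-"


def test_caller_agrees_with_exhaustive_matcher():
    """Equivalence against the brute-force sliding-window matcher on random
    genomes with embedded intact, corrupted, and duplicated probes."""
    rng = np.random.default_rng(123)
    for trial in range(8):
        m = make_marker(rng, "C", "A")
        pa, pb = probe_of(m, "C"), probe_of(m, "A")
        pieces = [random_seq(400, rng)]
        choice = trial % 4
        if choice == 0:
            pieces += [pa, random_seq(200, rng)]
        elif choice == 1:  # corrupted center -> depends on run length
            i = int(rng.integers(0, 71))
            bad = pa[:i] + ("T" if pa[i] != "T" else "G") + pa[i + 1 :]
            pieces += [bad, random_seq(200, rng)]
        elif choice == 2:  # both alleles present -> two locations, no call
            pieces += [pa, random_seq(120, rng), pb]
        else:  # reverse strand
            pieces += [revcomp(pb), random_seq(150, rng)]
        genome = {"c1": "".join(pieces)}
        hits_a = brute_force_hits(pa, genome)
        hits_b = brute_force_hits(pb, genome)
        base, hit = call_from_genome(m, genome)
        if len(hits_a | hits_b) == 1 and (bool(hits_a) != bool(hits_b)):
            expected_base = "C" if hits_a else "A"
            (name, pos, strand) = next(iter(hits_a | hits_b))
            assert base == expected_base
            assert (hit.seq_name, hit.pos, hit.strand) == (name, pos, strand)
        else:
            assert base is None


def test_merge_diploid_calls_rules():
    markers = [MarkerDef(f"m{i}", "G", "T") for i in range(4)]
    a = GenomeCallSet("dur", {"m0": "G", "m1": "G", "m2": "G"}, {})
    b = GenomeCallSet("ipa", {"m1": "G", "m2": "T", "m3": "T"}, {})
    row = merge_diploid_calls(a, b, markers)
    assert row.tobytes().decode() == "GG-T"
    # symmetric in the conflict case, commutative when equal
    assert np.array_equal(merge_diploid_calls(b, a, markers), row)


def test_filter_loci_present_in():
    b = make_base_matrix(
        {"ref_1": "AC-GT-CA-G", "x_1": "ACGGTTCAAG"}
    )
    out = filter_loci_present_in(b, "ref_1")
    assert out.n_loci == 7
    assert out.sequence("ref_1") == "ACGTCAG"
    assert out.sequence("x_1") == "ACGTCAG"
    # gap-free reference is the identity transformation
    same = filter_loci_present_in(b, "x_1")
    assert same.n_loci == b.n_loci
    with pytest.raises(ValueError, match="unknown"):
        filter_loci_present_in(b, "nope")


def test_filter_loci_all_gaps():
    b = make_base_matrix({"ref_1": "----", "x_1": "ACGT"})
    assert filter_loci_present_in(b, "ref_1").n_loci == 0


def test_assign_positions_priority():
    markers = [MarkerDef(f"m{i}", "A", "C", flank=None) for i in range(3)]
    hits = {
        "diploid": {"m0": Hit("A01", 100, "+", "A")},
        "tifrunner": {"m0": Hit("A01", 120, "+", "A"), "m1": Hit("B02", 5, "+", "A")},
        "shitouqi": {},
        "fuhuasheng": {"m1": Hit("B02", 9, "+", "A")},
    }
    out = assign_positions(markers, hits)
    assert (out[0].pos_source, out[0].pos) == ("diploid", 100)
    assert (out[1].pos_source, out[1].pos) == ("tifrunner", 5)
    assert (out[2].pos_source, out[2].chrom, out[2].pos) == ("none", None, None)


def test_full_insilico_pipeline_on_synthetic_genomes():
    """Markers embedded in synthetic progenitor genomes are recovered and the
    merged synthetic-tetraploid row matches the planted alleles."""
    r = simulate(SimParams(n_chromosomes=2, markers_per_chrom=12, seed=5))
    markers = r.genotypes.markers
    dip = r.diploid_calls.set_index("marker_id")
    dur_alleles = {
        m.marker_id: dip.loc[m.marker_id, "duranensis"]
        for m in markers
        if dip.loc[m.marker_id, "duranensis"] != "-"
    }
    ipa_alleles = {
        m.marker_id: dip.loc[m.marker_id, "ipaensis"]
        for m in markers
        if dip.loc[m.marker_id, "ipaensis"] != "-"
    }
    g_dur, _ = make_genome_from_markers(markers, dur_alleles, seed=1)
    g_ipa, _ = make_genome_from_markers(markers, ipa_alleles, seed=2)
    cs_dur = call_genome(markers, g_dur, "duranensis")
    cs_ipa = call_genome(markers, g_ipa, "ipaensis")
    assert cs_dur.calls == dur_alleles
    assert cs_ipa.calls == ipa_alleles
    row = merge_diploid_calls(cs_dur, cs_ipa, markers)
    for j, m in enumerate(markers):
        ca, cb = dur_alleles.get(m.marker_id), ipa_alleles.get(m.marker_id)
        if ca and cb and ca != cb:
            assert row[j] == GAP  # conflicting progenitor calls merge to '-'
        elif ca or cb:
            assert chr(row[j]) == (ca or cb)
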