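"""In-silico base calls for reference genome assemblies.

Each array marker carries a 71-mer flanking sequence with the variant base at
position 36 (1-based).  A base call is made against a genome assembly by
searching, on both strands, for a contiguous exact match of at least 65 of the
71 bases that covers the variant position, once for the A-allele version of
the 71-mer and once for the B-allele version.  A call is accepted only when
the qualifying hits (across both allele versions) identify exactly one
genomic location; the called base is the allele whose 71-mer matched there.

The matcher is exact and deterministic: any qualifying >=65-base match that
covers the variant necessarily contains one of the seven 65-mers starting at
offsets 0..6 of the 71-mer, so searching those windows and de-duplicating by
the implied variant coordinate enumerates all qualifying locations.

The two diploid progenitor call sets (A-genome, B-genome) can be merged into
one synthetic-tetraploid sample, and markers are assigned consensus genomic
positions by assembly priority.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import (
    FLANK_LEN,
    FLANK_VARIANT_POS,
    GAP,
    BaseMatrix,
    MarkerDef,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VAR_IDX = FLANK_VARIANT_POS - 1  # 0-based offset of the variant in the flank
_MIN_MATCH = 65


def revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hit:
    """A qualifying flank match: variant coordinate plus matched allele."""

    seq_name: str
    pos: int  # 1-based position of the variant base on the plus strand
    strand: str  # '+' or '-'
    allele: str  # base on the marker (plus) strand


@dataclass
class GenomeCallSet:
    """Per-marker in-silico calls for one assembly."""

    genome_id: str
    calls: dict[str, str]  # marker_id -> called base (markers with a call only)
    hits: dict[str, Hit]  # marker_id -> unique qualifying hit


def _window_hits(flank: str, seqs: Mapping[str, str], allele: str) -> set[Hit]:
    """All qualifying locations of one allele-specific 71-mer.

    Returns hits keyed by the genomic coordinate of the variant base.
    """
    found: set[Hit] = set()
    windows = [
        (s, flank[s : s + _MIN_MATCH]) for s in range(FLANK_LEN - _MIN_MATCH + 1)
    ]
    for name, seq in seqs.items():
        for offset, window in windows:
            start = seq.find(window)
            while start != -1:
                # plus strand: variant base sits at window start + (35 - offset)
                pos = start + (_VAR_IDX - offset) + 1
                found.add(Hit(name, pos, "+", allele))
                start = seq.find(window, start + 1)
        rc = revcomp(seq)
        n = len(seq)
        for offset, window in windows:
            start = rc.find(window)
            while start != -1:
                # map the variant offset in rc back to plus-strand coordinates
                rc_pos = start + (_VAR_IDX - offset)
                pos = n - rc_pos
                found.add(Hit(name, pos, "-", allele))
                start = rc.find(window, start + 1)
    return found


def call_from_genome(
    m: MarkerDef, genome: Mapping[str, str]
) -> tuple[str | None, Hit | None]:
    """In-silico base call of one marker against one assembly.

    Returns ``(called_base, hit)`` or ``(None, None)`` when no location, more
    than one location, or both alleles at one location qualify.  Markers whose
    flank contains non-ACGT characters are skipped with a warning.
    """
    if m.flank is None:
        return None, None
    flank = m.flank.upper()
    if set(flank) - set("ACGT"):
        warnings.warn(f"{m.marker_id}: flank contains non-ACGT characters; skipped")
        return None, None
    hits: set[Hit] = set()
    for allele in (m.allele_a, m.allele_b):
        probe = flank[:_VAR_IDX] + allele + flank[_VAR_IDX + 1 :]
        hits |= _window_hits(probe, genome, allele)
    locations = {(h.seq_name, h.pos, h.strand) for h in hits}
    if len(locations) != 1:
        return None, None
    alleles = {h.allele for h in hits}
    if len(alleles) != 1:  # both allele versions matched the same spot
        return None, None
    hit = next(iter(hits))
    return hit.allele, hit


def call_genome(
    markers: Sequence[MarkerDef], genome: Mapping[str, str], genome_id: str
) -> GenomeCallSet:
    """Call every marker against one assembly."""
    calls: dict[str, str] = {}
    hits: dict[str, Hit] = {}
    for m in markers:
        base, hit = call_from_genome(m, genome)
        if base is not None:
            calls[m.marker_id] = base
            hits[m.marker_id] = hit
    return GenomeCallSet(genome_id, calls, hits)


def merge_diploid_calls(
    a: GenomeCallSet, b: GenomeCallSet, markers: Sequence[MarkerDef]
) -> np.ndarray:
    """Merge A-genome and B-genome call sets into one synthetic-tetraploid row.

    Per marker: one genome called -> that base; both called and equal -> that
    base; conflicting or absent -> '-'.  Returned in ``markers`` order as
    uint8 ASCII codes.
    """
    out = np.full(len(markers), GAP, dtype=np.uint8)
    for j, m in enumerate(markers):
        ca = a.calls.get(m.marker_id)
        cb = b.calls.get(m.marker_id)
        if ca is not None and cb is None:
            out[j] = ord(ca)
        elif cb is not None and ca is None:
            out[j] = ord(cb)
        elif ca is not None and ca == cb:
            out[j] = ord(ca)
    return out


def filter_loci_present_in(b: BaseMatrix, sample_id: str) -> BaseMatrix:
    """Keep exactly the loci where the named sample has a non-gap base."""
    if sample_id not in b.samples:
        raise ValueError(f"unknown sample: {sample_id}")
    mask = b.row(sample_id) != GAP
    return b.subset_loci(mask)


def assign_positions(
    markers: Sequence[MarkerDef],
    hits_by_assembly: Mapping[str, Mapping[str, Hit]],
) -> list[MarkerDef]:
    """Assign consensus positions by assembly priority.

    ``hits_by_assembly`` maps pos_source label -> (marker_id -> Hit) and is
    consulted in iteration order (highest priority first, e.g. diploid,
    tifrunner, shitouqi, fuhuasheng).  Markers with no hit anywhere get
    ``pos_source='none'`` and sort last in genomic order.
    """
    out: list[MarkerDef] = []
    for m in markers:
        placed = None
        for source, hitmap in hits_by_assembly.items():
            hit = hitmap.get(m.marker_id)
            if hit is not None:
                placed = MarkerDef(
                    m.marker_id,
                    m.allele_a,
                    m.allele_b,
                    flank=m.flank,
                    chrom=hit.seq_name,
                    pos=hit.pos,
                    pos_source=source,
                )
                break
        if placed is None:
            placed = MarkerDef(
                m.marker_id, m.allele_a, m.allele_b, flank=m.flank,
                chrom=None, pos=None, pos_source="none",
            )
        out.append(placed)
    return out


def diploid_hits(
    a: GenomeCallSet, b: GenomeCallSet
) -> dict[str, Hit]:
    """Combined progenitor hit map for position priority: the A-genome hit
    where present, else the B-genome hit."""
    merged = dict(b.hits)
    merged.update(a.hits)
    return merged
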