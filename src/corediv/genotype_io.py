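"""Genotype I/O and conversion to the sequence (FASTA) representation.

SNP-array genotype calls for an allotetraploid collection are held as a
:class:`GenotypeMatrix` (samples x markers, calls AA/AB/BB/missing over the two
array alleles).  For identity-based analyses (replicate concordance, centroid
clustering, subgenome classification) calls are converted to a
:class:`BaseMatrix`: one single-letter base per locus per sample, in genomic
order, over the alphabet ``{A, C, G, T, -}``.

Conversion rules: a homozygous AA call becomes the marker's A-allele base, BB
the B-allele base, and both heterozygous and missing calls become the gap
symbol ``-``.  Heterozygous calls are rare in a highly selfing crop and carry
no haploid base, so they are treated as non-informative for identity scoring.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

GAP = ord("-")
BASES = frozenset(b"ACGT")
ALPHABET = frozenset(b"ACGT-")

#: integer call codes used in GenotypeMatrix.calls
AA, AB, BB, MISSING = 0, 1, 2, -1

POS_SOURCES = ("diploid", "tifrunner", "shitouqi", "fuhuasheng", "none")

_A_CHROMS = tuple(f"A{i:02d}" for i in range(1, 11))
_B_CHROMS = tuple(f"B{i:02d}" for i in range(1, 11))
CHROMOSOMES = _A_CHROMS + _B_CHROMS

#: 1-based position of the variant base inside a 71-mer flanking sequence
FLANK_VARIANT_POS = 36
FLANK_LEN = 71


@dataclass
class MarkerDef:
    """A biallelic SNP-array marker.

    ``flank`` is the 71-mer probe context with the variant base at position 36
    (1-based).  ``chrom``/``pos`` are the consensus genomic location;
    ``pos_source`` records which assembly supplied it (``none`` if unplaced).
    """

    marker_id: str
    allele_a: str
    allele_b: str
    flank: str | None = None
    chrom: str | None = None
    pos: int | None = None
    pos_source: str = "none"

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.marker_id}: allele bases must differ")
        if self.flank is not None and len(self.flank) != FLANK_LEN:
            raise ValueError(
                f"{self.marker_id}: flank length {len(self.flank)} != {FLANK_LEN}"
            )
        if self.pos_source not in POS_SOURCES:
            raise ValueError(f"{self.marker_id}: bad pos_source {self.pos_source!r}")
        placed = self.chrom is not None and self.pos is not None
        if placed != (self.pos_source != "none"):
            raise ValueError(
                f"{self.marker_id}: chrom/pos must be present iff pos_source != 'none'"
            )


def accession_of(sample_id: str) -> str:
    """Accession ID for a sample named ``<ACCESSION>_<replicate ordinal>``.

    Sample IDs without a numeric suffix are their own accession.
    """
    stem, _, suffix = sample_id.rpartition("_")
    if stem and suffix.isdigit():
        return stem
    return sample_id


@dataclass
class GenotypeMatrix:
    """Diploid array calls for samples x markers.

    ``calls`` is int8 with codes ``AA=0, AB=1, BB=2, MISSING=-1``.
    """

    samples: list[str]
    markers: list[MarkerDef]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.markers)})"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def accessions(self) -> list[str]:
        """Accession ID per sample (order preserved)."""
        return [accession_of(s) for s in self.samples]

    def drop_samples(self, exclude: Iterable[str]) -> "GenotypeMatrix":
        """Remove named samples (e.g. a known label-tracking error)."""
        drop = set(exclude)
        keep = [i for i, s in enumerate(self.samples) if s not in drop]
        return GenotypeMatrix(
            [self.samples[i] for i in keep], list(self.markers), self.calls[keep]
        )


@dataclass
class BaseMatrix:
    """Single-letter base representation: samples x loci over ``{A,C,G,T,-}``.

    ``loci`` is a DataFrame with columns ``marker_id``, ``chrom``, ``pos``;
    ``bases`` holds ASCII codes (uint8).  Loci are in non-decreasing genomic
    order within each chromosome.
    """

    samples: list[str]
    loci: pd.DataFrame
    bases: np.ndarray

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=np.uint8)
        if self.bases.shape != (len(self.samples), len(self.loci)):
            raise ValueError("bases shape inconsistent with samples/loci")
        bad = set(np.unique(self.bases)) - {ord(c) for c in "ACGT-"}
        if bad:
            raise ValueError(f"bases outside alphabet ACGT-: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, sample_id: str) -> np.ndarray:
        return self.bases[self.samples.index(sample_id)]

    def sequence(self, sample_id: str) -> str:
        return self.row(sample_id).tobytes().decode("ascii")

    def add_sample(self, sample_id: str, bases: np.ndarray) -> "BaseMatrix":
        """Return a new matrix with one extra sample row appended."""
        bases = np.asarray(bases, dtype=np.uint8)
        if bases.shape != (self.n_loci,):
            raise ValueError("appended row length mismatch")
        return BaseMatrix(
            self.samples + [sample_id],
            self.loci,
            np.vstack([self.bases, bases[None, :]]),
        )

    def subset_loci(self, mask: np.ndarray) -> "BaseMatrix":
        mask = np.asarray(mask)
        return BaseMatrix(
            list(self.samples),
            self.loci.loc[mask].reset_index(drop=True),
            self.bases[:, mask],
        )


def encode_seq(s: str) -> np.ndarray:
    """Encode an ``ACGT-`` string as uint8 ASCII codes."""
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    REF is mapped to allele A and ALT to allele B; missing genotypes are
    preserved.  Multi-allelic records are rejected with the record identifier.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[MarkerDef] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            ident = var.ID or f"{var.CHROM}:{var.POS}"
            raise ValueError(f"multi-allelic record not supported: {ident}")
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            ident = var.ID or f"{var.CHROM}:{var.POS}"
            raise ValueError(f"non-SNP record not supported: {ident}")
        chrom = var.CHROM if var.CHROM else None
        placed = chrom is not None
        markers.append(
            MarkerDef(
                marker_id=var.ID or f"{var.CHROM}_{var.POS}",
                allele_a=var.REF,
                allele_b=var.ALT[0],
                chrom=chrom if placed else None,
                pos=int(var.POS) if placed else None,
                pos_source="diploid" if placed else "none",
            )
        )
        # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = AA
        col[gt == 1] = AB
        col[gt == 3] = BB
        columns.append(col)
    calls = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, markers, calls)


_GT_STRINGS = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 file (GT field only)."""
    contigs: list[str] = []
    for m in g.markers:
        if m.chrom is not None and m.chrom not in contigs:
            contigs.append(m.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=corediv\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples)
            + "\n"
        )
        for j, m in enumerate(g.markers):
            chrom = m.chrom if m.chrom is not None else "."
            pos = str(m.pos) if m.pos is not None else "0"
            gts = "\t".join(_GT_STRINGS[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{chrom}\t{pos}\t{m.marker_id}\t{m.allele_a}\t{m.allele_b}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# call -> base conversion


def genomic_order(markers: Sequence[MarkerDef]) -> np.ndarray:
    """Stable sort order: placed markers by (chrom, pos); unplaced last."""
    keys = []
    for i, m in enumerate(markers):
        if m.pos_source == "none":
            keys.append((1, "", 0, i))
        else:
            keys.append((0, m.chrom, m.pos, i))
    return np.array([k[3] for k in sorted(keys)], dtype=np.intp)


def calls_to_bases(g: GenotypeMatrix) -> BaseMatrix:
    """Convert AA/AB/BB/missing calls to the base representation.

    AA maps to the marker's A-allele base, BB to the B-allele base, AB and
    missing to '-'.  Loci are emitted in genomic order (unplaced markers
    last, in input order).
    """
    order = genomic_order(g.markers)
    n, m = g.n_samples, g.n_markers
    bases = np.full((n, m), GAP, dtype=np.uint8)
    a_codes = np.empty(m, dtype=np.uint8)
    b_codes = np.empty(m, dtype=np.uint8)
    for j, mk in enumerate(g.markers):
        if mk.allele_a not in "ACGT" or mk.allele_b not in "ACGT":
            raise ValueError(f"{mk.marker_id}: allele base undefined or non-ACGT")
        a_codes[j] = ord(mk.allele_a)
        b_codes[j] = ord(mk.allele_b)
    np.copyto(bases, a_codes[None, :], where=g.calls == AA)
    np.copyto(bases, b_codes[None, :], where=g.calls == BB)
    loci = pd.DataFrame(
        {
            "marker_id": [g.markers[i].marker_id for i in order],
            "chrom": [g.markers[i].chrom for i in order],
            "pos": [g.markers[i].pos for i in order],
        }
    )
    return BaseMatrix(list(g.samples), loci, bases[:, order])


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(b: BaseMatrix, path: str | Path) -> None:
    """One FASTA record per sample, ID = sample ID."""
    records = (
        SeqRecord(Seq(b.sequence(s)), id=s, description="") for s in b.samples
    )
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, loci: pd.DataFrame | None = None) -> BaseMatrix:
    """Read a sequence-representation FASTA back into a BaseMatrix.

    Locus annotation is not stored in FASTA; pass ``loci`` to restore it,
    otherwise loci are numbered with unknown coordinates.
    """
    samples: list[str] = []
    rows: list[np.ndarray] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        samples.append(rec.id)
        rows.append(encode_seq(str(rec.seq).upper()))
    if rows:
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"FASTA records of unequal length: {sorted(lengths)}")
        width = lengths.pop()
    else:
        width = 0 if loci is None else len(loci)
    if loci is None:
        loci = pd.DataFrame(
            {
                "marker_id": [f"locus{i}" for i in range(width)],
                "chrom": [None] * width,
                "pos": [None] * width,
            }
        )
    if len(loci) != width:
        raise ValueError("loci table width does not match sequences")
    bases = (
        np.vstack(rows) if rows else np.empty((0, width), dtype=np.uint8)
    )
    return BaseMatrix(samples, loci.reset_index(drop=True), bases)


# ---------------------------------------------------------------------------
# tables


def read_marker_table(path: str | Path) -> list[MarkerDef]:
    """Read a marker definition TSV.

    Required columns: marker_id, allele_a, allele_b; optional flank, chrom,
    pos, pos_source.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for rec in df.to_dict("records"):
        pos = rec.get("pos")
        out.append(
            MarkerDef(
                marker_id=rec["marker_id"],
                allele_a=rec["allele_a"],
                allele_b=rec["allele_b"],
                flank=rec.get("flank") or None,
                chrom=rec.get("chrom") or None,
                pos=int(pos) if pos not in (None, "", "nan") and pd.notna(pos) else None,
                pos_source=rec.get("pos_source") or "none",
            )
        )
    return out


def write_marker_table(markers: Sequence[MarkerDef], path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "allele_a": [m.allele_a for m in markers],
            "allele_b": [m.allele_b for m in markers],
            "flank": [m.flank or "" for m in markers],
            "chrom": [m.chrom or "" for m in markers],
            "pos": [m.pos if m.pos is not None else "" for m in markers],
            "pos_source": [m.pos_source for m in markers],
        }
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata TSV with an ``accession_id`` column; categoricals may
    be ``unknown``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    if "accession_id" not in df.columns:
        raise ValueError("metadata must have an accession_id column")
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ValueError(f"duplicate accession_id in metadata: {dup}")
    return df
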