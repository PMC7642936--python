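"""Truth-known synthetic allotetraploid collection generator.

The generator emulates the statistical shape of an SNP-array-genotyped
germplasm core collection on a 20-chromosome tetraploid (A01..A10, B01..B10):
a small number of genetic clades nested inside two subspecies-analogue
groups, per-accession replicate samples with a controllable contamination
(mixture) rate, missing and heterozygous calls, a diploid-progenitor allele
table, and planted subgenome-exchange events (multi-megabase terminal tracts,
small interstitial tracts, and single-locus exchanges).

Model choices (see docs/methods.md for rationale):

* Clade structure is modeled as independent per-locus allele flips from a
  common ancestor (subspecies founder -> clade founder -> accession), not a
  coalescent; this creates the frequency differentiation that PCA/F_ST
  consume at desk scale.
* Subgenome-diagnostic loci — where the two progenitor alleles differ — change
  state only through exchange events.  A trans-subgenome allele at a
  diagnostic locus *is* a homoeologous exchange in this system, so lineage
  drift is confined to non-diagnostic loci.
* Replicates are exact genotype copies of their accession (contaminated ones
  copy a different accession); missingness and heterozygosity are injected
  last, independently per cell.

Every output is deterministic given the parameter set and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .genotype_io import (
    AA,
    AB,
    BB,
    MISSING,
    BaseMatrix,
    GenotypeMatrix,
    MarkerDef,
    write_marker_table,
    write_vcf,
)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Study-condition parameters of the synthetic collection."""

    n_chromosomes: int = 20  # first half A01.., second half B01..
    markers_per_chrom: int = 100
    chrom_length_bp: int = 100_000_000
    n_clades: int = 5
    n_accessions_per_clade: int = 30
    subspecies_divergence: float = 0.10  # per-locus flip, ancestor -> ssp founder
    clade_divergence: float = 0.06  # ssp founder -> clade founder
    accession_divergence: float = 0.004  # clade founder -> accession
    #: n_samples -> number of accessions genotyped that many times; accessions
    #: not covered by the design get a single sample
    replicate_design: Mapping[int, int] = field(
        default_factory=lambda: {2: 42, 3: 9, 4: 3, 5: 1}
    )
    mixture_rate: float = 0.1  # per replicate beyond the first
    missing_rate: float = 0.01
    het_rate: float = 0.005
    diploid_diff_frac: float = 0.55  # fraction of markers with differing progenitor alleles
    diploid_missing_rate: float = 0.03  # per progenitor per marker
    exchange_accession_prob: float = 0.25  # terminal-tract probability per accession
    terminal_tract_mb: tuple[float, float] = (5.0, 20.0)
    interstitial_rate: float = 0.7  # Poisson mean per accession
    interstitial_tract_mb: tuple[float, float] = (1.0, 4.0)
    exchange_locus_rate: float = 0.01  # single-locus exchange per accession per diagnostic locus
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "subspecies_divergence", "clade_divergence", "accession_divergence",
            "mixture_rate", "missing_rate", "het_rate", "diploid_diff_frac",
            "diploid_missing_rate", "exchange_accession_prob", "exchange_locus_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for rng_mb in (self.terminal_tract_mb, self.interstitial_tract_mb):
            if rng_mb[1] * 1e6 > self.chrom_length_bp:
                raise ValueError("tract length range exceeds chromosome length")
        if self.n_chromosomes % 2:
            raise ValueError("n_chromosomes must be even (A and B subgenomes)")

    def noise_free(self) -> "SimParams":
        """Variant with contamination, missingness, heterozygosity,
        within-clade drift and exchange events all switched off."""
        p = SimParams(**{**asdict(self)})
        p.replicate_design = dict(self.replicate_design)
        p.mixture_rate = 0.0
        p.missing_rate = 0.0
        p.het_rate = 0.0
        p.accession_divergence = 0.0
        p.diploid_missing_rate = 0.0
        p.exchange_accession_prob = 0.0
        p.interstitial_rate = 0.0
        p.exchange_locus_rate = 0.0
        return p


@dataclass
class TruthTables:
    accession_clade: dict[str, int]
    accession_subspecies: dict[str, str]
    sample_source: dict[str, str]  # sample -> accession actually copied
    tracts: list[dict]  # accession, chrom, start_bp, end_bp, kind
    diagnostic_markers: list[str]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTables":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


@dataclass
class SimResult:
    params: SimParams
    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    diploid_calls: pd.DataFrame  # marker_id, duranensis, ipaensis ('-' = absent)
    truth: TruthTables

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(self.genotypes, outdir / "sim.vcf")
        write_marker_table(self.genotypes.markers, outdir / "markers.tsv")
        self.metadata.to_csv(outdir / "meta.tsv", sep="\t", index=False)
        self.diploid_calls.to_csv(outdir / "diploid.tsv", sep="\t", index=False)
        self.truth.to_json(outdir / "truth.json")


# metadata label pools per clade (weights loosely follow a real core
# collection: one subspecies-coherent clade per pool, cosmopolitan origins)
_COUNTRIES = [
    ["Bolivia", "Peru", "Ecuador", "Argentina"],
    ["Brazil", "Argentina", "Cuba", "Uruguay"],
    ["Zambia", "Nigeria", "Zimbabwe", "Bolivia"],
    ["India", "China", "Israel", "Sudan"],
    ["United States", "Brazil", "Senegal", "Paraguay"],
]
_MARKET = ["Virginia", "Runner", "Spanish", "Valencia", "mixed"]
_HABIT = ["erect", "bunch", "spreading-bunch", "prostrate", "mixed"]
_POD = ["hypogaea", "fastigiata", "vulgaris", "peruviana", "mixed"]


def _chrom_names(n: int) -> list[str]:
    half = n // 2
    return [f"A{i + 1:02d}" for i in range(half)] + [
        f"B{i + 1:02d}" for i in range(half)
    ]


def simulate(params: SimParams | None = None) -> SimResult:
    """Generate a truth-known collection under ``params``."""
    p = params or SimParams()
    p.validate()
    rng = np.random.default_rng(p.seed)
    chroms = _chrom_names(p.n_chromosomes)
    m_per = p.markers_per_chrom
    n_markers = p.n_chromosomes * m_per

    # -- markers: jittered, roughly even spacing along each chromosome
    spacing = p.chrom_length_bp // (m_per + 1)
    marker_chrom = np.repeat(chroms, m_per)
    pos = np.empty(n_markers, dtype=np.int64)
    for c in range(p.n_chromosomes):
        base = (np.arange(1, m_per + 1, dtype=np.int64)) * spacing
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=m_per)
        pos[c * m_per : (c + 1) * m_per] = np.sort(base + jitter)
    allele_a_idx = rng.integers(0, 4, size=n_markers)
    allele_b_idx = (allele_a_idx + rng.integers(1, 4, size=n_markers)) % 4
    allele_a = _ACGT[allele_a_idx]
    allele_b = _ACGT[allele_b_idx]
    flanks = _ACGT[rng.integers(0, 4, size=(n_markers, 71))]
    flanks[:, 35] = allele_a

    markers = [
        MarkerDef(
            marker_id=f"AX{j:05d}",
            allele_a=chr(allele_a[j]),
            allele_b=chr(allele_b[j]),
            flank=flanks[j].tobytes().decode("ascii"),
            chrom=str(marker_chrom[j]),
            pos=int(pos[j]),
            pos_source="diploid",
        )
        for j in range(n_markers)
    ]

    # -- diploid progenitor alleles, as array-allele indicators (0=A, 1=B)
    differs = rng.random(n_markers) < p.diploid_diff_frac
    dur_is_b = np.where(differs, rng.integers(0, 2, size=n_markers), 0).astype(bool)
    ipa_is_b = np.where(differs, ~dur_is_b, dur_is_b)
    dur_missing = rng.random(n_markers) < p.diploid_missing_rate
    ipa_missing = rng.random(n_markers) < p.diploid_missing_rate
    diagnostic = differs & ~dur_missing & ~ipa_missing

    # -- ancestral tetraploid: cis progenitor allele per subgenome
    is_a_chrom = np.isin(marker_chrom, chroms[: p.n_chromosomes // 2])
    ancestral_b = np.where(is_a_chrom, dur_is_b, ipa_is_b)  # True = allele B

    # -- hierarchical drift on non-diagnostic loci
    drift_dom = ~diagnostic
    n_ssp = 2
    clade_ssp = np.array([0 if k < (p.n_clades + 1) // 2 else 1 for k in range(p.n_clades)])
    ssp_names = {0: "hypogaea-like", 1: "fastigiata-like"}
    ssp_hap = np.empty((n_ssp, n_markers), dtype=bool)
    for s in range(n_ssp):
        flip = (rng.random(n_markers) < p.subspecies_divergence) & drift_dom
        ssp_hap[s] = ancestral_b ^ flip
    clade_hap = np.empty((p.n_clades, n_markers), dtype=bool)
    for k in range(p.n_clades):
        flip = (rng.random(n_markers) < p.clade_divergence) & drift_dom
        clade_hap[k] = ssp_hap[clade_ssp[k]] ^ flip

    # -- accessions
    n_acc = p.n_clades * p.n_accessions_per_clade
    acc_ids = [f"PI{500000 + i}" for i in range(n_acc)]
    acc_clade = np.repeat(np.arange(p.n_clades), p.n_accessions_per_clade)
    acc_b = np.empty((n_acc, n_markers), dtype=bool)
    for i in range(n_acc):
        flip = (rng.random(n_markers) < p.accession_divergence) & drift_dom
        acc_b[i] = clade_hap[acc_clade[i]] ^ flip

    # -- planted subgenome exchanges
    trans_b = np.where(is_a_chrom, ipa_is_b, dur_is_b)
    tracts: list[dict] = []
    chrom_of = np.asarray(marker_chrom, dtype=object)
    for i in range(n_acc):
        events: list[tuple[str, int, int, str]] = []
        if rng.random() < p.exchange_accession_prob:
            c = chroms[int(rng.integers(0, p.n_chromosomes))]
            length = int(rng.uniform(*p.terminal_tract_mb) * 1e6)
            if rng.random() < 0.5:
                events.append((c, 1, length, "terminal"))
            else:
                events.append((c, p.chrom_length_bp - length + 1, p.chrom_length_bp, "terminal"))
        for _ in range(rng.poisson(p.interstitial_rate)):
            c = chroms[int(rng.integers(0, p.n_chromosomes))]
            length = int(rng.uniform(*p.interstitial_tract_mb) * 1e6)
            start = int(rng.integers(1, p.chrom_length_bp - length + 1))
            events.append((c, start, start + length - 1, "interstitial"))
        for c, start, end, kind in events:
            in_tract = (chrom_of == c) & (pos >= start) & (pos <= end)
            sites = in_tract & diagnostic
            acc_b[i, sites] = trans_b[sites]
            tracts.append(
                {
                    "accession": acc_ids[i],
                    "chrom": c,
                    "start_bp": start,
                    "end_bp": end,
                    "kind": kind,
                }
            )
        # single-locus exchanges at diagnostic loci
        single = (rng.random(n_markers) < p.exchange_locus_rate) & diagnostic
        acc_b[i, single] = trans_b[single]

    # -- replicate design and contamination
    design = dict(p.replicate_design)
    n_replicated = sum(design.values())
    if n_replicated > n_acc:
        raise ValueError("replicate design covers more accessions than exist")
    chosen = rng.choice(n_acc, size=n_replicated, replace=False)
    n_samples_of = np.ones(n_acc, dtype=int)
    cursor = 0
    for n_samples, count in sorted(design.items()):
        for acc in chosen[cursor : cursor + count]:
            n_samples_of[acc] = n_samples
        cursor += count

    sample_ids: list[str] = []
    sample_source: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for i in range(n_acc):
        for k in range(1, n_samples_of[i] + 1):
            sid = f"{acc_ids[i]}_{k}"
            src = i
            if k > 1 and rng.random() < p.mixture_rate:
                src = int(rng.integers(0, n_acc - 1))
                if src >= i:
                    src += 1
            sample_ids.append(sid)
            sample_source[sid] = acc_ids[src]
            rows.append(acc_b[src])

    calls = np.where(np.vstack(rows), BB, AA).astype(np.int8)
    # missingness and heterozygosity injected last
    u = rng.random(calls.shape)
    calls[u < p.missing_rate + p.het_rate] = AB
    calls[u < p.missing_rate] = MISSING

    genotypes = GenotypeMatrix(sample_ids, markers, calls)

    # -- metadata
    meta_rng = np.random.default_rng(rng.integers(0, 2**31))
    variety_pool = {0: ["hypogaea", "hirsuta"], 1: ["fastigiata", "vulgaris", "aequatoriana"]}
    records = []
    for i, acc in enumerate(acc_ids):
        k = int(acc_clade[i])
        s = int(clade_ssp[k])
        records.append(
            {
                "accession_id": acc,
                "clade": f"clade{k + 1}",
                "subspecies": ssp_names[s],
                "country": meta_rng.choice(_COUNTRIES[k % len(_COUNTRIES)]),
                "botanical_variety": meta_rng.choice(variety_pool[s]),
                "market_type": meta_rng.choice(_MARKET),
                "growth_habit": meta_rng.choice(_HABIT),
                "pod_shape": meta_rng.choice(_POD),
                "n_samples": int(n_samples_of[i]),
            }
        )
    metadata = pd.DataFrame(records)

    def base_of(is_b: np.ndarray, missing: np.ndarray) -> list[str]:
        codes = np.where(missing, ord("-"), np.where(is_b, allele_b, allele_a))
        return [chr(c) for c in codes]

    diploid_calls = pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in markers],
            "duranensis": base_of(dur_is_b, dur_missing),
            "ipaensis": base_of(ipa_is_b, ipa_missing),
        }
    )

    truth = TruthTables(
        accession_clade={acc_ids[i]: int(acc_clade[i]) for i in range(n_acc)},
        accession_subspecies={
            acc_ids[i]: ssp_names[int(clade_ssp[acc_clade[i]])] for i in range(n_acc)
        },
        sample_source=sample_source,
        tracts=tracts,
        diagnostic_markers=[markers[j].marker_id for j in np.flatnonzero(diagnostic)],
    )
    return SimResult(p, genotypes, metadata, diploid_calls, truth)


def make_genome_from_markers(
    markers: list[MarkerDef],
    alleles: Mapping[str, str],
    spacing: int = 120,
    seed: int = 0,
    duplicate_ids: tuple[str, ...] = (),
    revcomp_ids: tuple[str, ...] = (),
) -> tuple[dict[str, str], dict[str, tuple[str, int]]]:
    """Build a compact synthetic genome embedding each marker's flank once.

    ``alleles`` chooses the base planted at the variant position of each
    embedded flank; markers absent from it are left out of the genome.
    ``duplicate_ids`` are embedded twice (ambiguity path) and ``revcomp_ids``
    are embedded reverse-complemented (strand path).  Returns the genome
    (name -> sequence) and the 1-based plus-strand position of each variant
    base.
    """
    from .insilico import revcomp

    rng = np.random.default_rng(seed)
    per_chrom: dict[str, list[str]] = {}
    positions: dict[str, tuple[str, int]] = {}
    lengths: dict[str, int] = {}
    for m in markers:
        if m.marker_id not in alleles or m.flank is None:
            continue
        chrom = m.chrom or "contig1"
        parts = per_chrom.setdefault(chrom, [])
        offset = lengths.get(chrom, 0)
        filler = _ACGT[rng.integers(0, 4, size=spacing)].tobytes().decode("ascii")
        probe = m.flank[:35] + alleles[m.marker_id] + m.flank[36:]
        copies = 2 if m.marker_id in duplicate_ids else 1
        for c in range(copies):
            embedded = revcomp(probe) if m.marker_id in revcomp_ids else probe
            # position 36 of 71 is the palindromic center, so the variant
            # coordinate is the same on either strand
            var_offset = len(filler) + 36
            parts.append(filler + embedded)
            if c == 0:
                positions[m.marker_id] = (chrom, offset + var_offset)
            offset += len(filler) + len(embedded)
        lengths[chrom] = offset
    genome = {c: "".join(parts) for c, parts in per_chrom.items()}
    return genome, positions
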