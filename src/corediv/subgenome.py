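"""Subgenome-exchange classification and tract detection.

Allotetraploid peanut carries an A subgenome (from *A. duranensis*,
chromosomes A01-A10) and a B subgenome (from *A. ipaensis*, B01-B10).  At
loci where the two progenitor reference alleles differ, a tetraploid base
call can be classified as A-like (equal to the A-genome allele, unlike the
B-genome allele) or B-like (the mirror case).  A trans-subgenome allele — a
B-like call on an A chromosome or vice versa — is evidence of homoeologous
exchange at that position; runs of consecutive trans calls mark tract-scale
invasions of one subgenome by the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GAP, BaseMatrix

# classification codes
A_LIKE, B_LIKE, OTHER, UNEVALUABLE = 0, 1, 2, 3
CALL_NAMES = {A_LIKE: "A_LIKE", B_LIKE: "B_LIKE", OTHER: "OTHER", UNEVALUABLE: "UNEVALUABLE"}


@dataclass
class Tract:
    accession_id: str
    chrom: str
    start: int  # position of first flagged locus
    end: int  # position of last flagged locus
    n_loci: int  # flagged loci in the run


@dataclass
class ExchangeReport:
    panel: list[str]
    n_evaluable_positions: int
    n_exchanged_positions: int
    exchanged_fraction: float
    per_accession_chrom_flags: pd.DataFrame  # accession x chrom: flagged-locus count
    tracts: list[Tract]


def classify_allele(tetra: str, a_call: str | None, b_call: str | None) -> int:
    """Classify one tetraploid base against the two progenitor alleles.

    A_LIKE iff tetra == a_call != b_call with all three present; B_LIKE the
    mirror; OTHER when the diploids are invariant or the tetraploid matches
    neither; UNEVALUABLE when any of the three calls is missing.
    """

    def _norm(x: str | None) -> str | None:
        if x is None or x == "-" or x == "":
            return None
        return x

    t, a, b = _norm(tetra), _norm(a_call), _norm(b_call)
    if t is None or a is None or b is None:
        return UNEVALUABLE
    if a == b:
        return OTHER
    if t == a:
        return A_LIKE
    if t == b:
        return B_LIKE
    return OTHER


def classify_matrix(
    b: BaseMatrix, a_calls: np.ndarray, b_calls: np.ndarray
) -> np.ndarray:
    """Vectorized classification of every sample x locus cell.

    ``a_calls``/``b_calls`` are uint8 per-locus progenitor alleles with GAP
    for a missing call.  Returns an int8 matrix of classification codes.
    """
    a_calls = np.asarray(a_calls, dtype=np.uint8)
    b_calls = np.asarray(b_calls, dtype=np.uint8)
    if a_calls.shape != (b.n_loci,) or b_calls.shape != (b.n_loci,):
        raise ValueError("diploid call vectors must have one entry per locus")
    t = b.bases
    out = np.full(t.shape, OTHER, dtype=np.int8)
    informative = (a_calls != GAP) & (b_calls != GAP) & (a_calls != b_calls)
    out[(t == a_calls[None, :]) & informative[None, :]] = A_LIKE
    out[(t == b_calls[None, :]) & informative[None, :]] = B_LIKE
    missing = (t == GAP) | (a_calls == GAP)[None, :] | (b_calls == GAP)[None, :]
    out[missing] = UNEVALUABLE
    return out


def _subgenome_of(chrom: str | None) -> str | None:
    if chrom and len(chrom) >= 2 and chrom[0] in "AB" and chrom[1:].isdigit():
        return chrom[0]
    return None


def exchange_flags(calls: np.ndarray, chroms: Sequence[str | None]) -> np.ndarray:
    """Trans-subgenome flags: B-like on A01..A10 or A-like on B01..B10.

    Loci on unrecognized chromosomes are never flagged (warned once).
    """
    calls = np.asarray(calls)
    sub = np.array([_subgenome_of(c) for c in chroms], dtype=object)
    unplaced = sub == None  # noqa: E711 (object-array comparison)
    if unplaced.any():
        warnings.warn(
            f"{int(unplaced.sum())} locus/loci not on A01..B10; excluded from exchange flags"
        )
    flags = ((calls == B_LIKE) & (sub == "A")[None, :]) | (
        (calls == A_LIKE) & (sub == "B")[None, :]
    )
    return flags


def segment_tracts(
    flags: np.ndarray,
    informative: np.ndarray,
    chroms: Sequence[str],
    pos: np.ndarray,
    accession_id: str,
    min_run: int = 3,
) -> list[Tract]:
    """Maximal runs of >= ``min_run`` consecutive flagged informative loci.

    The run domain is the accession's informative loci (classified A-like or
    B-like); uninformative or unevaluable loci are transparent and neither
    extend nor break a run.  Tract start/end are the positions of the first
    and last flagged loci of the run.
    """
    flags = np.asarray(flags, dtype=bool)
    informative = np.asarray(informative, dtype=bool)
    pos = np.asarray(pos)
    tracts: list[Tract] = []
    chroms = np.asarray(chroms, dtype=object)
    for chrom in pd.unique(chroms):
        on = np.flatnonzero((chroms == chrom) & informative)
        on = on[np.argsort(pos[on], kind="stable")]
        run: list[int] = []
        for j in on.tolist() + [-1]:
            if j >= 0 and flags[j]:
                run.append(j)
            else:
                if len(run) >= min_run:
                    tracts.append(
                        Tract(
                            accession_id,
                            str(chrom),
                            int(pos[run[0]]),
                            int(pos[run[-1]]),
                            len(run),
                        )
                    )
                run = []
    return tracts


def exchange_summary(
    calls: np.ndarray,
    b: BaseMatrix,
    panel: Sequence[str],
    min_run: int = 3,
) -> ExchangeReport:
    """Collection-level exchange report over a panel of accessions.

    Evaluable positions have data for every panel accession (no UNEVALUABLE
    cell); exchanged positions are evaluable positions with a trans-subgenome
    allele in at least one panel accession.  Tract segmentation runs per
    accession per chromosome on informative loci.
    """
    if len(panel) == 0:
        raise ValueError("empty accession panel")
    rows = [b.samples.index(s) for s in panel]
    sub = calls[rows]
    chroms = b.loci["chrom"].tolist()
    pos = b.loci["pos"].to_numpy()
    placed = np.array([_subgenome_of(c) is not None for c in chroms])
    evaluable = (sub != UNEVALUABLE).all(axis=0) & placed
    flags = exchange_flags(sub, chroms)
    exchanged = evaluable & flags.any(axis=0)
    n_eval = int(evaluable.sum())
    n_exch = int(exchanged.sum())

    chrom_names = [c for c in pd.unique(np.asarray(chroms, dtype=object)) if _subgenome_of(c)]
    per = pd.DataFrame(0, index=list(panel), columns=chrom_names, dtype=int)
    tracts: list[Tract] = []
    chrom_arr = np.asarray(chroms, dtype=object)
    for i, acc in enumerate(panel):
        informative = np.isin(sub[i], (A_LIKE, B_LIKE)) & evaluable
        for chrom in chrom_names:
            per.loc[acc, chrom] = int((flags[i] & evaluable & (chrom_arr == chrom)).sum())
        tracts.extend(
            segment_tracts(flags[i], informative, chroms, pos, acc, min_run=min_run)
        )
    return ExchangeReport(
        panel=list(panel),
        n_evaluable_positions=n_eval,
        n_exchanged_positions=n_exch,
        exchanged_fraction=(n_exch / n_eval) if n_eval else float("nan"),
        per_accession_chrom_flags=per,
        tracts=tracts,
    )


def tracts_frame(tracts: Sequence[Tract]) -> pd.DataFrame:
    """BED-like tract table (chrom, start, end, accession, n_loci)."""
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in tracts],
            "start": [t.start for t in tracts],
            "end": [t.end for t in tracts],
            "accession": [t.accession_id for t in tracts],
            "n_loci": [t.n_loci for t in tracts],
        }
    )
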