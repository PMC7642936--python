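"""Replicate concordance scoring and accession purity classification.

Accessions genotyped from several seeds yield C(N, 2) replicate pairings.
Identity between two sequence-representation rows is the percentage of
matching bases over positions where both rows are non-gap.  A pairing is
"observed" when identity exceeds 70% and "similar" when identity is at least
98%; an accession is homogeneous when every pairing is similar, and mixed
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GAP, BaseMatrix, accession_of

OBSERVED_MIN_IDENTITY = 70.0  # exclusive
SIMILAR_MIN_IDENTITY = 98.0  # inclusive


@dataclass
class PairingResult:
    accession_id: str
    sample_i: str
    sample_j: str
    identity_pct: float  # NaN when no comparable positions
    n_compared: int
    observed: bool
    similar: bool


@dataclass
class AccessionPurity:
    accession_id: str
    n_samples: int
    n_expected_pairings: int
    n_observed: int
    n_similar: int
    status: str  # homogeneous | mixed | single-sample


def expected_pairings(rep_design: Mapping[int, int]) -> int:
    """Total expected pairings: sum over the design of n_accessions * C(n, 2)."""
    if any(n < 0 or k < 0 for n, k in rep_design.items()):
        raise ValueError("counts must be non-negative")
    return sum(n_acc * comb(n_samples, 2) for n_samples, n_acc in rep_design.items())


def pair_identity(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Percent identity over positions where both rows are non-gap.

    Returns ``(identity_pct, n_compared)``; identity is NaN when no position
    is comparable.
    """
    x = np.asarray(x, dtype=np.uint8)
    y = np.asarray(y, dtype=np.uint8)
    if x.shape != y.shape:
        raise ValueError(f"sequence lengths differ: {x.shape} vs {y.shape}")
    both = (x != GAP) & (y != GAP)
    n = int(both.sum())
    if n == 0:
        return float("nan"), 0
    matches = int(((x == y) & both).sum())
    return 100.0 * matches / n, n


def _pairing(acc: str, si: str, sj: str, x: np.ndarray, y: np.ndarray) -> PairingResult:
    ident, n = pair_identity(x, y)
    observed = n > 0 and ident > OBSERVED_MIN_IDENTITY
    similar = n > 0 and ident >= SIMILAR_MIN_IDENTITY
    return PairingResult(acc, si, sj, ident, n, observed, similar)


def score_pairings(b: BaseMatrix) -> list[PairingResult]:
    """All within-accession replicate pairings of a collection."""
    by_acc: dict[str, list[int]] = {}
    for i, s in enumerate(b.samples):
        by_acc.setdefault(accession_of(s), []).append(i)
    out: list[PairingResult] = []
    for acc, idx in by_acc.items():
        for i, j in combinations(idx, 2):
            out.append(
                _pairing(acc, b.samples[i], b.samples[j], b.bases[i], b.bases[j])
            )
    return out


def classify_accessions(
    pairings: Iterable[PairingResult],
    n_samples_per_accession: Mapping[str, int],
) -> tuple[list[AccessionPurity], dict]:
    """Per-accession purity plus a collection summary.

    The summary reports expected/observed/similar pairing counts, mean and
    median identity over observed pairings only, and the accessions with at
    least one missed (non-similar) pairing.
    """
    by_acc: dict[str, list[PairingResult]] = {}
    for p in pairings:
        by_acc.setdefault(p.accession_id, []).append(p)

    purities: list[AccessionPurity] = []
    for acc, n in n_samples_per_accession.items():
        ps = by_acc.get(acc, [])
        n_obs = sum(p.observed for p in ps)
        n_sim = sum(p.similar for p in ps)
        expected = comb(n, 2)
        if n < 2:
            status = "single-sample"
        elif n_sim == expected:
            status = "homogeneous"
        else:
            status = "mixed"
        purities.append(AccessionPurity(acc, n, expected, n_obs, n_sim, status))

    all_ps = [p for ps in by_acc.values() for p in ps]
    observed_ids = [p.identity_pct for p in all_ps if p.observed]
    missed = sorted(
        a.accession_id
        for a in purities
        if a.n_samples >= 2 and a.n_similar < a.n_expected_pairings
    )
    summary = {
        "n_expected_pairings": sum(a.n_expected_pairings for a in purities),
        "n_observed": sum(a.n_observed for a in purities),
        "n_similar": sum(a.n_similar for a in purities),
        "mean_identity_observed": float(np.mean(observed_ids)) if observed_ids else float("nan"),
        "median_identity_observed": float(np.median(observed_ids)) if observed_ids else float("nan"),
        "n_missed_pairings": sum(
            a.n_expected_pairings - a.n_similar for a in purities if a.n_samples >= 2
        ),
        "accessions_with_missed_pairing": missed,
        "n_homogeneous": sum(a.status == "homogeneous" for a in purities),
        "n_mixed": sum(a.status == "mixed" for a in purities),
        "n_single_sample": sum(a.status == "single-sample" for a in purities),
    }
    return purities, summary


def pairings_frame(pairings: Sequence[PairingResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairings])


def purity_frame(purities: Sequence[AccessionPurity]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in purities])
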