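"""Population-genetic summaries on dosage genotypes.

Operations: monomorphic/MAF marker filtering, composite-LD r² and sliding
window LD pruning, allele-frequency-standardized genotype PCA, and pairwise
Weir & Cockerham (1984) theta between labeled groups.

Missing-data conventions (each stated because reference packages delegate
them to defaults): r² uses pairwise-complete samples; PCA sets missing values
to zero after standardization; F_ST variance components use per-locus
complete cases within each group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import AA, AB, BB, MISSING, GenotypeMatrix


@dataclass
class DosageMatrix:
    """Samples x markers count of B alleles (0/1/2), NaN for missing."""

    samples: list[str]
    marker_ids: np.ndarray  # str
    chrom: np.ndarray  # str, "" for unplaced
    pos: np.ndarray  # int64, -1 for unplaced
    dosage: np.ndarray  # float32 (n_samples, n_markers), NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float32)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, m = len(self.samples), len(self.marker_ids)
        if self.dosage.shape != (n, m) or len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("inconsistent DosageMatrix dimensions")

    @classmethod
    def from_genotypes(cls, g: GenotypeMatrix) -> "DosageMatrix":
        dosage = g.calls.astype(np.float32)
        dosage[g.calls == MISSING] = np.nan
        return cls(
            list(g.samples),
            np.array([m.marker_id for m in g.markers], dtype=object),
            np.array([m.chrom or "" for m in g.markers], dtype=object),
            np.array([m.pos if m.pos is not None else -1 for m in g.markers]),
            dosage,
        )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_markers(self, idx: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            list(self.samples),
            self.marker_ids[idx],
            self.chrom[idx],
            self.pos[idx],
            self.dosage[:, idx],
        )

    def subset_samples(self, idx: Sequence[int]) -> "DosageMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return DosageMatrix(
            [self.samples[i] for i in idx],
            self.marker_ids,
            self.chrom,
            self.pos,
            self.dosage[idx],
        )


def b_allele_freq(d: DosageMatrix) -> np.ndarray:
    """Per-marker B-allele frequency over non-missing dosages (NaN if none)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(d.dosage, axis=0) / 2.0


def filter_markers(d: DosageMatrix, maf_min: float = 0.05) -> DosageMatrix:
    """Drop monomorphic markers and markers with MAF below ``maf_min``."""
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    p = b_allele_freq(d)
    maf = np.minimum(p, 1.0 - p)
    keep = np.isfinite(p) & (p > 0) & (p < 1) & (maf >= maf_min)
    return d.subset_markers(np.flatnonzero(keep))


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosages over
    pairwise-complete samples.  NaN when either vector has zero variance or
    fewer than two complete pairs."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return float("nan")
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def ld_prune(
    d: DosageMatrix,
    window_bp: int = 1_000_000,
    r2_max: float = 0.2,
    keep_unplaced: bool = False,
) -> np.ndarray:
    """Sliding-window LD pruning; returns kept marker indices.

    Per chromosome, markers are scanned in position order; a candidate is
    discarded iff r² with any already-kept marker within ``window_bp``
    exceeds ``r2_max``.  Undefined r² (zero variance) never prunes.  Unplaced
    markers are excluded with a warning unless ``keep_unplaced``.
    """
    placed = np.array([c != "" for c in d.chrom])
    kept: list[int] = []
    if (~placed).any():
        if keep_unplaced:
            kept.extend(np.flatnonzero(~placed).tolist())
        else:
            warnings.warn(
                f"excluding {int((~placed).sum())} unplaced marker(s) from LD pruning"
            )
    for chrom in pd.unique(d.chrom[placed]):
        idx = np.flatnonzero((d.chrom == chrom) & placed)
        idx = idx[np.argsort(d.pos[idx], kind="stable")]
        kept_here: list[int] = []
        for j in idx:
            prune = False
            for k in kept_here:
                if abs(int(d.pos[j]) - int(d.pos[k])) <= window_bp:
                    r2 = ld_r2(d.dosage[:, j], d.dosage[:, k])
                    if np.isfinite(r2) and r2 > r2_max:
                        prune = True
                        break
            if not prune:
                kept_here.append(int(j))
        kept.extend(kept_here)
    return np.array(sorted(kept), dtype=np.intp)


@dataclass
class PCAResult:
    samples: list[str]
    coords: np.ndarray  # (n_samples, n_components); eigvec * sqrt(eigval)
    eigenvalues: np.ndarray  # descending
    explained: np.ndarray  # eigenvalue / sum of positive eigenvalues


def pca(d: DosageMatrix, n_components: int | None = None) -> PCAResult:
    """Allele-frequency standardized genotype PCA.

    Dosages are centered by 2p̂ and scaled by sqrt(p̂(1-p̂)), with p̂ the
    B-allele frequency; missing entries become 0 after standardization.  The
    sample x sample covariance is eigendecomposed; coordinates are
    eigenvectors scaled by the square root of their eigenvalue.
    """
    if d.n_samples < 2 or d.n_markers < 1:
        raise ValueError("need at least 2 samples and 1 marker")
    p = b_allele_freq(d)
    if np.isnan(p).any():
        raise ValueError("all-missing marker present; filter markers first")
    poly = (p > 0) & (p < 1)
    p = p[poly]
    x = d.dosage[:, poly].astype(np.float64)
    denom = np.sqrt(p * (1.0 - p))
    z = (x - 2.0 * p[None, :]) / denom[None, :]
    z[~np.isfinite(z)] = 0.0  # missing -> 0 after standardization
    cov = z @ z.T / z.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    if n_components is None:
        n_components = len(eigval)
    pos = np.clip(eigval, 0.0, None)
    coords = eigvec[:, :n_components] * np.sqrt(pos[:n_components])[None, :]
    total = pos.sum()
    explained = pos / total if total > 0 else np.zeros_like(pos)
    return PCAResult(list(d.samples), coords, eigval[:n_components], explained[:n_components])


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta


def _wc_components(
    dosage: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) for r groups of diploids.

    a: among populations; b: among individuals within populations; c: within
    individuals (heterozygosity).  Loci where any group has no data, or with
    mean sample size <= 1, or zero n_c, contribute NaN.
    """
    r = len(groups)
    m = dosage.shape[1]
    n_i = np.empty((r, m))
    p_i = np.empty((r, m))
    h_i = np.empty((r, m))
    for g, idx in enumerate(groups):
        sub = dosage[idx]
        ok = np.isfinite(sub)
        n = ok.sum(axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nansum(sub, axis=0) / (2.0 * n)
            h = np.nansum(sub == 1, axis=0) / n
        n_i[g] = n
        p_i[g] = p
        h_i[g] = h
    valid = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    sum_n = n_i.sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        nc = (sum_n - (n_i**2).sum(axis=0) / sum_n) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / sum_n
        s2 = (n_i * (p_i - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / sum_n
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = ~valid | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


def wc_fst(
    d: DosageMatrix, labels: Sequence[str], group_a: str, group_b: str
) -> float:
    """Weir-Cockerham theta between two labeled groups.

    theta = sum_l a_l / sum_l (a_l + b_l + c_l) over loci with data in both
    groups.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != d.n_samples:
        raise ValueError("one label per sample required")
    idx_a = np.flatnonzero(labels == group_a)
    idx_b = np.flatnonzero(labels == group_b)
    for name, idx in ((group_a, idx_a), (group_b, idx_b)):
        if len(idx) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples")
        if not np.isfinite(d.dosage[idx]).any():
            raise ValueError(f"group {name!r} has no non-missing data")
    a, b, c = _wc_components(d.dosage.astype(np.float64), [idx_a, idx_b])
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return float("nan")
    return float(a[ok].sum() / denom)


def pairwise_fst(d: DosageMatrix, labels: Sequence[str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise theta over all label pairs.

    Groups with fewer than two samples are skipped with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    names = [g for g in pd.unique(labels)]
    usable = []
    for g in names:
        if (labels == g).sum() >= 2:
            usable.append(g)
        else:
            warnings.warn(f"group {g!r} has < 2 samples; skipped in pairwise FST")
    mat = pd.DataFrame(np.nan, index=usable, columns=usable, dtype=float)
    for ga, gb in combinations(usable, 2):
        theta = wc_fst(d, labels, ga, gb)
        mat.loc[ga, gb] = mat.loc[gb, ga] = theta
    np.fill_diagonal(mat.values, 0.0)
    return mat
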