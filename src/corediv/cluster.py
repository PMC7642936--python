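"""Greedy centroid clustering of sample sequences at an identity threshold.

Sequences are processed in input order.  Each sequence is compared against the
existing centroids with gap-excluded positional identity; it joins the
best-identity centroid at or above the threshold (ties go to the earliest
centroid), otherwise it founds a new cluster.  ``mode='first'`` instead
accepts the first centroid meeting the threshold, emulating greedy tools that
take the first qualifying hit.

All sequences here have equal length (one base per locus), so input order is
the canonical processing order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GAP, BaseMatrix


@dataclass
class Cluster:
    centroid_sample_id: str
    member_ids: list[str]  # includes the centroid, in assignment order

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _identities_vs_centroids(row: np.ndarray, cents: np.ndarray) -> np.ndarray:
    """Gap-excluded identity fraction of one row against each centroid row."""
    both = (cents != GAP) & (row[None, :] != GAP)
    n = both.sum(axis=1)
    matches = ((cents == row[None, :]) & both).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = matches / n
    ident[n == 0] = np.nan
    return ident


def centroid_cluster(
    seqs: BaseMatrix, threshold: float, mode: str = "best"
) -> list[Cluster]:
    """Greedy centroid clustering at an identity threshold in (0, 1]."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if mode not in ("best", "first"):
        raise ValueError("mode must be 'best' or 'first'")
    clusters: list[Cluster] = []
    cent_rows: list[np.ndarray] = []
    for i, sample in enumerate(seqs.samples):
        row = seqs.bases[i]
        if cent_rows:
            ident = _identities_vs_centroids(row, np.vstack(cent_rows))
            ok = np.flatnonzero(np.nan_to_num(ident, nan=-1.0) >= threshold)
        else:
            ok = np.empty(0, dtype=np.intp)
        if ok.size:
            if mode == "first":
                k = int(ok[0])
            else:
                # best identity; earliest centroid on ties
                k = int(ok[np.argmax(ident[ok])])
            clusters[k].member_ids.append(sample)
        else:
            clusters.append(Cluster(sample, [sample]))
            cent_rows.append(row)
    return clusters


def cluster_stats(clusters: list[Cluster]) -> dict:
    """Size distribution and representative (centroid) set."""
    sizes = sorted((c.size for c in clusters), reverse=True)
    return {
        "n_clusters": len(clusters),
        "n_singletons": sum(1 for s in sizes if s == 1),
        "sizes": sizes,
        "n_samples": sum(sizes),
        "representatives": [c.centroid_sample_id for c in clusters],
    }


def membership_partition(clusters: list[Cluster]) -> dict[str, int]:
    """sample ID -> cluster index (founding order)."""
    return {s: k for k, c in enumerate(clusters) for s in c.member_ids}
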