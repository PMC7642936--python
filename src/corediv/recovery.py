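"""End-to-end recovery measurements on truth-known synthetic collections.

Each function runs a full pipeline stage on generated data and scores the
result against the planted truth: mixture (contaminated replicate) detection,
clade-partition recovery by centroid clustering, F_ST ordering between and
within planted clades, subgenome-tract recovery, and PC1 separation of the
subspecies-analogue groups.  These are the package's own calibration
experiments; the test suite and the acceptance script both consume them.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .cluster import centroid_cluster, membership_partition
from .genotype_io import accession_of, calls_to_bases, encode_seq
from .popgen import DosageMatrix, filter_markers, ld_prune, pca, wc_fst
from .replicates import classify_accessions, pair_identity, score_pairings
from .simulate import SimParams, SimResult, simulate
from .subgenome import A_LIKE, B_LIKE, UNEVALUABLE, classify_matrix, exchange_summary

#: divergence threshold for counting a planted contamination as detectable:
#: contaminant and host must differ at >10% of compared loci
MIXTURE_DIVERGENCE_MIN = 10.0


def mixture_recovery(
    n_seeds: int = 10, base_seed: int = 0, params: SimParams | None = None
) -> dict:
    """Sensitivity and false-positive rate of mixed-accession detection.

    Aggregates over ``n_seeds`` collections at the default study conditions.
    Sensitivity is scored over planted contaminations whose source accession
    diverges >10% from the host line; the false-positive rate is the fraction
    of truly pure replicated accessions called mixed.
    """
    n_eligible = n_detected = n_pure = n_false = 0
    for k in range(n_seeds):
        p = params or SimParams()
        p = replace(p, replicate_design=dict(p.replicate_design), seed=base_seed + k)
        r = simulate(p)
        b = calls_to_bases(r.genotypes)
        counts: dict[str, int] = {}
        for s in b.samples:
            counts[accession_of(s)] = counts.get(accession_of(s), 0) + 1
        purities, _ = classify_accessions(score_pairings(b), counts)
        detected = {a.accession_id for a in purities if a.status == "mixed"}
        replicated = {a.accession_id for a in purities if a.n_samples >= 2}
        pure_row = {acc: b.row(f"{acc}_1") for acc in replicated}
        mixed_truth: dict[str, bool] = {}
        for s, src in r.truth.sample_source.items():
            host = accession_of(s)
            if host == src:
                continue
            ident, _ = pair_identity(b.row(f"{host}_1"), b.row(f"{src}_1"))
            eligible = (100.0 - ident) > MIXTURE_DIVERGENCE_MIN
            mixed_truth[host] = mixed_truth.get(host, False) or eligible
        for host, eligible in mixed_truth.items():
            if eligible:
                n_eligible += 1
                n_detected += host in detected
        pure = replicated - set(mixed_truth)
        n_pure += len(pure)
        n_false += len(detected & pure)
    return {
        "sensitivity": n_detected / n_eligible if n_eligible else float("nan"),
        "fpr": n_false / n_pure if n_pure else float("nan"),
        "n_eligible": n_eligible,
        "n_pure": n_pure,
    }


def clustering_clade_recovery(seed: int = 0, threshold: float = 0.99) -> dict:
    """Whether centroid clustering recovers the planted clade partition
    exactly on a noise-free default collection."""
    p = SimParams(seed=seed).noise_free()
    r = simulate(p)
    b = calls_to_bases(r.genotypes)
    part = membership_partition(centroid_cluster(b, threshold))
    clade_of = {s: r.truth.accession_clade[accession_of(s)] for s in b.samples}
    cluster_to_clades: dict[int, set[int]] = {}
    clade_to_clusters: dict[int, set[int]] = {}
    for s, k in part.items():
        cluster_to_clades.setdefault(k, set()).add(clade_of[s])
        clade_to_clusters.setdefault(clade_of[s], set()).add(k)
    exact = all(len(v) == 1 for v in cluster_to_clades.values()) and all(
        len(v) == 1 for v in clade_to_clusters.values()
    )
    return {
        "exact": exact,
        "n_clusters": len(cluster_to_clades),
        "n_clades": p.n_clades,
    }


def _fst_params(seed: int) -> SimParams:
    # compact two-clade collection for repeated F_ST ordering runs
    return SimParams(
        n_chromosomes=4,
        markers_per_chrom=75,
        n_clades=2,
        n_accessions_per_clade=16,
        replicate_design={},
        mixture_rate=0.0,
        seed=seed,
    )


def fst_clade_ordering(n_seeds: int = 100, base_seed: int = 0) -> dict:
    """How often theta between the two planted clades exceeds theta between
    random halves of one clade."""
    wins = 0
    between: list[float] = []
    within: list[float] = []
    for k in range(n_seeds):
        r = simulate(_fst_params(base_seed + k))
        d = DosageMatrix.from_genotypes(r.genotypes)
        clade = np.array(
            [r.truth.accession_clade[accession_of(s)] for s in d.samples]
        )
        labels = np.where(clade == 0, "c0", "c1")
        t_between = wc_fst(d, labels, "c0", "c1")
        rng = np.random.default_rng(base_seed + k + 1_000_003)
        idx0 = np.flatnonzero(clade == 0)
        half = rng.permutation(idx0)
        split = np.array(["other"] * d.n_samples, dtype=object)
        split[half[: len(half) // 2]] = "h1"
        split[half[len(half) // 2 :]] = "h2"
        t_within = wc_fst(d, split, "h1", "h2")
        wins += t_between > t_within
        between.append(t_between)
        within.append(t_within)
    return {
        "n_seeds": n_seeds,
        "n_between_exceeds_within": wins,
        "mean_between": float(np.mean(between)),
        "mean_within": float(np.mean(within)),
    }


def null_split_fst(seed: int = 0, n_samples: int = 500, n_loci: int = 1000) -> float:
    """theta for a random split of one panmictic pool (expected ~0)."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 0.95, n_loci)
    dosage = rng.binomial(2, p, (n_samples, n_loci)).astype(float)
    d = DosageMatrix(
        [f"s{i}_1" for i in range(n_samples)],
        np.array([f"m{j}" for j in range(n_loci)], dtype=object),
        np.array(["A01"] * n_loci, dtype=object),
        np.arange(1, n_loci + 1) * 1000,
        dosage,
    )
    labels = np.array(["a"] * (n_samples // 2) + ["b"] * (n_samples - n_samples // 2))
    rng.shuffle(labels)
    return wc_fst(d, labels, "a", "b")


def _spread_panel(r: SimResult, b, size: int = 16) -> list[str]:
    """Pure first-replicate samples spread evenly across clades."""
    per_clade: dict[int, int] = {}
    quota = math.ceil(size / r.params.n_clades)
    panel: list[str] = []
    for s in b.samples:
        acc = accession_of(s)
        if r.truth.sample_source[s] != acc or not s.endswith("_1"):
            continue
        k = r.truth.accession_clade[acc]
        if per_clade.get(k, 0) < quota and len(panel) < size:
            panel.append(s)
            per_clade[k] = per_clade.get(k, 0) + 1
    return panel


def tract_recovery(seed: int = 0, min_run: int = 3, panel_size: int = 16) -> dict:
    """Recovery of planted exchange tracts on the default collection.

    A planted tract is eligible when it spans >= ``min_run`` informative
    evaluable loci for its accession; it is recovered when an overlapping
    detected tract exists, and the boundary error is the index distance, on
    the chromosome's informative-evaluable marker grid, between detected and
    planted first/last in-tract loci.
    """
    r = simulate(SimParams(seed=seed))
    b = calls_to_bases(r.genotypes)
    dip = r.diploid_calls.set_index("marker_id")
    mid = b.loci["marker_id"]
    a_calls = encode_seq("".join(dip["duranensis"].reindex(mid)))
    b_calls = encode_seq("".join(dip["ipaensis"].reindex(mid)))
    calls = classify_matrix(b, a_calls, b_calls)
    panel = _spread_panel(r, b, panel_size)
    rep = exchange_summary(calls, b, panel, min_run=min_run)

    rows = [b.samples.index(s) for s in panel]
    sub = calls[rows]
    evaluable = (sub != UNEVALUABLE).all(axis=0)
    pos = b.loci["pos"].to_numpy()
    chrom = b.loci["chrom"].to_numpy(dtype=object)
    panel_accs = {accession_of(s): i for i, s in enumerate(panel)}

    n_eligible = n_recovered = 0
    max_err = 0
    for t in r.truth.tracts:
        i = panel_accs.get(t["accession"])
        if i is None:
            continue
        informative = np.isin(sub[i], (A_LIKE, B_LIKE)) & evaluable
        in_tract = (
            (chrom == t["chrom"])
            & (pos >= t["start_bp"])
            & (pos <= t["end_bp"])
            & informative
        )
        if in_tract.sum() < min_run:
            continue
        n_eligible += 1
        sample = panel[i]
        overlapping = [
            d
            for d in rep.tracts
            if d.accession_id == sample
            and d.chrom == t["chrom"]
            and d.end >= t["start_bp"]
            and d.start <= t["end_bp"]
        ]
        if not overlapping:
            continue
        n_recovered += 1
        det = max(overlapping, key=lambda d: d.n_loci)
        grid = np.sort(pos[(chrom == t["chrom"]) & informative])
        first, last = pos[in_tract].min(), pos[in_tract].max()
        e1 = abs(int(np.searchsorted(grid, det.start)) - int(np.searchsorted(grid, first)))
        e2 = abs(int(np.searchsorted(grid, det.end)) - int(np.searchsorted(grid, last)))
        max_err = max(max_err, e1, e2)
    return {
        "n_eligible": n_eligible,
        "n_recovered": n_recovered,
        "recovery_rate": n_recovered / n_eligible if n_eligible else float("nan"),
        "max_boundary_error": max_err,
        "exchanged_fraction": rep.exchanged_fraction,
        "n_evaluable": rep.n_evaluable_positions,
        "n_exchanged": rep.n_exchanged_positions,
    }


def pca_subspecies_separation(seed: int = 0) -> dict:
    """Standardized PC1 group-mean separation of the subspecies-analogue
    clades on the default collection (sign-invariant)."""
    r = simulate(SimParams(seed=seed))
    d = filter_markers(DosageMatrix.from_genotypes(r.genotypes), 0.05)
    d = d.subset_markers(ld_prune(d))
    res = pca(d, n_components=2)
    ssp = np.array(
        [r.truth.accession_subspecies[accession_of(s)] for s in d.samples],
        dtype=object,
    )
    groups = [g for g in dict.fromkeys(ssp)]
    pc1 = res.coords[:, 0]
    m = [pc1[ssp == g].mean() for g in groups]
    v = [pc1[ssp == g].var() for g in groups]
    sep = abs(m[0] - m[1]) / math.sqrt((v[0] + v[1]) / 2)
    return {
        "separation": float(sep),
        "explained_pc1": float(res.explained[0]),
        "n_markers": d.n_markers,
    }
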