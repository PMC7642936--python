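"""Marker filtering, LD pruning, PCA and Weir-Cockerham F_ST."""

import math

import numpy as np
import pytest

from corediv import filter_markers, ld_prune, ld_r2, pairwise_fst, pca, wc_fst
from corediv.popgen import DosageMatrix, b_allele_freq


def dm(dosage, chrom=None, pos=None, samples=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    return DosageMatrix(
        samples or [f"s{i}_1" for i in range(n)],
        np.array([f"m{j}" for j in range(m)], dtype=object),
        np.array(chrom if chrom is not None else ["A01"] * m, dtype=object),
        np.array(pos if pos is not None else [(j + 1) * 1000 for j in range(m)]),
        dosage,
    )


# -- filtering ---------------------------------------------------------------


def test_filter_markers_monomorphic_and_maf():
    # col0 monomorphic; col1 has one B allele in 20 samples (freq 0.025);
    # col2 common polymorphism
    d = np.zeros((20, 3))
    d[0, 1] = 1
    d[:10, 2] = 2
    out = filter_markers(dm(d), 0.05)
    assert out.marker_ids.tolist() == ["m2"]
    out0 = filter_markers(dm(d), 0.0)
    assert out0.marker_ids.tolist() == ["m1", "m2"]


def test_filter_markers_handles_missing():
    d = np.array([[0.0, np.nan], [np.nan, np.nan], [2.0, np.nan]])
    out = filter_markers(dm(d), 0.0)
    assert out.marker_ids.tolist() == ["m0"]  # all-missing marker dropped


# -- LD ----------------------------------------------------------------------


def test_ld_r2_examples():
    x = np.array([0, 0, 1, 2, 2], dtype=float)
    assert ld_r2(x, x) == pytest.approx(1.0)
    y = np.array([0, 1, 1, 2, 2], dtype=float)
    assert ld_r2(x, y) == pytest.approx(45 / 56)  # hand-computed correlation
    assert math.isnan(ld_r2(x, np.ones_like(x)))  # zero variance


def test_ld_r2_independent_vectors_near_zero():
    rng = np.random.default_rng(0)
    x = rng.integers(0, 3, 10_000).astype(float)
    y = rng.integers(0, 3, 10_000).astype(float)
    assert ld_r2(x, y) < 0.01


def test_ld_r2_pairwise_complete():
    x = np.array([0, 1, 2, np.nan, 2])
    y = np.array([0, 1, 2, 2, np.nan])
    assert ld_r2(x, y) == pytest.approx(1.0)


def test_ld_prune_window_semantics():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, 50).astype(float)
    # duplicates 1 kb apart -> second removed; 2 Mb apart -> both kept
    d = dm(np.stack([col, col, col], axis=1), pos=[1_000, 2_000, 2_002_000])
    kept = ld_prune(d, window_bp=1_000_000, r2_max=0.2)
    assert kept.tolist() == [0, 2]


def test_ld_prune_exhaustive_post_hoc_audit():
    """Every kept pair within the window satisfies r2 <= threshold on a
    random 200-marker chromosome with planted local correlation."""
    rng = np.random.default_rng(3)
    n, m = 60, 200
    base = rng.integers(0, 3, (n, m)).astype(float)
    # plant LD: every third marker copies its neighbour with small noise
    for j in range(1, m, 3):
        base[:, j] = base[:, j - 1]
        flip = rng.random(n) < 0.05
        base[flip, j] = rng.integers(0, 3, flip.sum())
    pos = np.sort(rng.choice(np.arange(1, 20_000_000), size=m, replace=False))
    d = dm(base, pos=pos)
    kept = ld_prune(d, window_bp=1_000_000, r2_max=0.2)
    assert len(kept) < m
    for ai, a in enumerate(kept):
        for b in kept[ai + 1 :]:
            if abs(int(d.pos[a]) - int(d.pos[b])) <= 1_000_000:
                r2 = ld_r2(d.dosage[:, a], d.dosage[:, b])
                assert not (np.isfinite(r2) and r2 > 0.2)


def test_ld_prune_unplaced_markers():
    col = np.array([0, 1, 2, 0, 1], dtype=float)
    d = dm(np.stack([col, col], axis=1), chrom=["A01", ""])
    with pytest.warns(UserWarning, match="unplaced"):
        kept = ld_prune(d)
    assert kept.tolist() == [0]
    kept2 = ld_prune(d, keep_unplaced=True)
    assert kept2.tolist() == [0, 1]


# -- PCA ---------------------------------------------------------------------


def test_pca_duplicated_samples_identical_coordinates():
    rng = np.random.default_rng(5)
    base = rng.integers(0, 3, (6, 40)).astype(float)
    dup = np.vstack([base, base[2]])
    res = pca(filter_markers(dm(dup), 0.0))
    # components with near-zero eigenvalue are numerically degenerate
    lead = res.eigenvalues > 1e-8
    np.testing.assert_allclose(res.coords[2, lead], res.coords[6, lead], atol=1e-9)


def test_pca_matches_dense_eigendecomposition_oracle():
    """3 samples x 4 markers vs an explicitly formed covariance matrix."""
    dosage = np.array(
        [[0, 1, 2, 0], [2, 1, 0, 1], [1, 0, 1, 2]], dtype=float
    )
    d = dm(dosage)
    res = pca(d)
    # independent dense oracle, element by element
    p = dosage.mean(axis=0) / 2.0
    z = np.empty_like(dosage)
    for i in range(3):
        for j in range(4):
            z[i, j] = (dosage[i, j] - 2 * p[j]) / math.sqrt(p[j] * (1 - p[j]))
    cov = np.empty((3, 3))
    for i in range(3):
        for k in range(3):
            cov[i, k] = sum(z[i, j] * z[k, j] for j in range(4)) / 4
    w, v = np.linalg.eigh(cov)
    w = w[::-1]
    np.testing.assert_allclose(res.eigenvalues, w, atol=1e-10)
    total = w[w > 0].sum()
    np.testing.assert_allclose(res.explained, np.clip(w, 0, None) / total, atol=1e-10)
    # coordinates match up to per-component sign
    for k in range(2):
        c1 = res.coords[:, k]
        c2 = v[:, ::-1][:, k] * math.sqrt(max(w[k], 0))
        assert np.allclose(c1, c2, atol=1e-9) or np.allclose(c1, -c2, atol=1e-9)


def test_pca_separates_planted_populations():
    rng = np.random.default_rng(9)
    n, m = 40, 300
    p1 = rng.uniform(0.05, 0.95, m)
    shift = rng.choice([-0.5, 0.5], m)
    p2 = np.clip(p1 + shift, 0.02, 0.98)
    g1 = rng.binomial(2, p1, (n, m)).astype(float)
    g2 = rng.binomial(2, p2, (n, m)).astype(float)
    d = filter_markers(dm(np.vstack([g1, g2])), 0.0)
    res = pca(d)
    pc1 = res.coords[:, 0]
    m1, m2 = pc1[:n].mean(), pc1[n:].mean()
    s = math.sqrt((pc1[:n].var() + pc1[n:].var()) / 2)
    assert abs(m1 - m2) / s > 3  # sign-invariant separation


def test_pca_sample_order_invariance():
    rng = np.random.default_rng(13)
    dosage = rng.integers(0, 3, (10, 50)).astype(float)
    d = filter_markers(dm(dosage), 0.0)
    res = pca(d)
    perm = rng.permutation(10)
    d2 = d.subset_samples(perm)
    res2 = pca(d2)
    np.testing.assert_allclose(res2.explained, res.explained, atol=1e-9)


# -- F_ST --------------------------------------------------------------------


def test_wc_fst_matches_hand_computed_components():
    """6 diploids x 2 loci against exact variance components computed by
    hand (rational arithmetic): theta = 31/52."""
    dosage = np.array(
        [[0, 0], [0, 1], [1, 1], [2, 2], [2, 2], [2, 1]], dtype=float
    )
    d = dm(dosage)
    labels = ["p1"] * 3 + ["p2"] * 3
    assert wc_fst(d, labels, "p1", "p2") == pytest.approx(31 / 52, abs=1e-12)


def test_wc_fst_null_two_groups_one_pool():
    rng = np.random.default_rng(17)
    n, m = 500, 1000
    p = rng.uniform(0.05, 0.95, m)
    dosage = rng.binomial(2, p, (n, m)).astype(float)
    labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
    rng.shuffle(labels)
    theta = wc_fst(dm(dosage), labels, "a", "b")
    assert abs(theta) < 0.01


def test_wc_fst_monotone_in_divergence():
    rng = np.random.default_rng(23)
    n, m = 100, 500
    thetas = []
    for shift in (0.05, 0.15, 0.30):
        p = rng.uniform(0.2, 0.8, m)
        p1 = np.clip(p - shift, 0.01, 0.99)
        p2 = np.clip(p + shift, 0.01, 0.99)
        dosage = np.vstack(
            [rng.binomial(2, p1, (n, m)), rng.binomial(2, p2, (n, m))]
        ).astype(float)
        thetas.append(wc_fst(dm(dosage), ["a"] * n + ["b"] * n, "a", "b"))
    assert thetas[0] < thetas[1] < thetas[2]


def test_pairwise_fst_symmetric(default_sim):
    from corediv.genotype_io import accession_of

    g = default_sim.genotypes
    d = filter_markers(DosageMatrix.from_genotypes(g), 0.05)
    meta = default_sim.metadata.set_index("accession_id")
    labels = [str(meta["clade"].get(accession_of(s))) for s in d.samples]
    sub = d.subset_samples(range(0, d.n_samples, 2))
    mat = pairwise_fst(sub, [labels[i] for i in range(0, d.n_samples, 2)])
    np.testing.assert_allclose(mat.values, mat.values.T, atol=1e-12)
    assert (np.diag(mat.values) == 0).all()
    assert (mat.values <= 1).all()


def test_wc_fst_input_validation():
    d = dm(np.array([[0, 1], [1, 2], [2, 0]], dtype=float))
    with pytest.raises(ValueError, match=">= 2 samples"):
        wc_fst(d, ["a", "a", "b"], "a", "b")
    d2 = dm(np.array([[0.0], [1.0], [np.nan], [np.nan]]))
    with pytest.raises(ValueError, match="no non-missing"):
        wc_fst(d2, ["a", "a", "b", "b"], "a", "b")
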