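"""Filtered CNV matrices, distances, PCoA, cluster trees, concordance."""

import numpy as np
import pandas as pd
import pytest

from cnvpop import (
    CopyNumberMatrix,
    build_matrix,
    cluster_tree,
    distance,
    label_concordance,
    pcoa,
    scan,
)
from cnvpop.genome import Feature, Window


def _cnm(cn, labels=None):
    cn = np.asarray(cn)
    n_samples, n_windows = cn.shape
    windows = [Window("s1", i, i * 250, (i + 1) * 250) for i in range(n_windows)]
    samples = [f"x{i}" for i in range(n_samples)]
    half = n_samples // 2
    labels = labels or {
        s: ("pop1" if i < half else "pop2") for i, s in enumerate(samples)
    }
    return CopyNumberMatrix(windows=windows, samples=samples, labels=labels, cn=cn)


def _cds(start, end):
    return Feature("s1", start, end, "CDS", f"g{start}", ".", {})


# -------------------------------------------------------------- build_matrix


def test_gain_and_zero_schemes_select_expected_columns():
    cn = np.full((4, 6), 2)
    cn[0, 1] = 5   # one gain window
    cn[1, 4] = 0   # one loss-to-zero window
    cnm = _cnm(cn)
    gain = build_matrix(cnm, "any_gain")
    zero = build_matrix(cnm, "any_zero")
    assert gain.shape == (4, 1) and gain.columns[0] == "s1:250-500"
    assert zero.shape == (4, 1) and zero.columns[0] == "s1:1000-1250"


def test_all_schemes_error_on_fully_neutral_matrix():
    cnm = _cnm(np.full((4, 6), 2))
    feats = [_cds(0, 1500)]
    track = scan(cnm, K=100, q=0.01)
    for scheme, kwargs in [
        ("all_cds", {"features": feats}),
        ("top1pct_cds", {"features": feats, "vst_track": track}),
        ("any_gain", {}),
        ("any_zero", {}),
    ]:
        with pytest.raises(ValueError, match=scheme):
            build_matrix(cnm, scheme, **kwargs)


def test_all_cds_matches_set_comprehension_oracle(rng):
    cn = rng.integers(1, 4, size=(6, 50))
    cnm = _cnm(cn)
    feats = [_cds(int(s), int(s) + 300) for s in rng.integers(0, 50 * 250, size=12)]
    got = build_matrix(cnm, "all_cds", features=feats)
    # oracle: windows overlapping any CDS where some sample deviates from 2
    expected = {
        f"s1:{w.start}-{w.end}"
        for j, w in enumerate(cnm.windows)
        if any(w.start < f.end and f.start < w.end for f in feats)
        and any(cn[:, j] != 2)
    }
    assert set(got.columns) == expected


def test_top1pct_cds_is_subset_of_all_cds(rng):
    cn = rng.integers(0, 5, size=(8, 300))
    cnm = _cnm(cn)
    feats = [_cds(int(s), int(s) + 400) for s in rng.integers(0, 300 * 250, size=40)]
    track = scan(cnm, K=100, q=0.05)
    top = build_matrix(cnm, "top1pct_cds", features=feats, vst_track=track)
    full = build_matrix(cnm, "all_cds", features=feats)
    assert set(top.columns) <= set(full.columns)


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError, match="unknown scheme"):
        build_matrix(_cnm(np.full((4, 4), 2)), "everything")


# ------------------------------------------------------------------ distance


def test_distance_forced_examples():
    mat = pd.DataFrame([[2, 2], [2, 4]], index=["a", "b"])
    d = distance(mat)
    assert d.loc["a", "a"] == 0
    assert d.loc["a", "b"] == pytest.approx(2.0)
    same = distance(pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"]))
    assert same.loc["a", "b"] == 0


def test_distance_metric_axioms_and_double_loop_oracle(rng):
    mat = pd.DataFrame(rng.integers(0, 8, size=(7, 30)))
    d = distance(mat).to_numpy()
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    for i in range(7):
        for j in range(7):
            oracle = np.sqrt(((mat.iloc[i] - mat.iloc[j]) ** 2).sum())
            assert d[i, j] == pytest.approx(oracle)
            for k in range(7):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
    manhattan = distance(mat, metric="manhattan").to_numpy()
    assert manhattan[0, 1] == pytest.approx(np.abs(mat.iloc[0] - mat.iloc[1]).sum())


# ---------------------------------------------------------------------- PCoA


def test_pcoa_three_equidistant_points_two_equal_eigenvalues():
    d = pd.DataFrame(2 * (1 - np.eye(3)), index=list("abc"), columns=list("abc"))
    ord_ = pcoa(d)
    assert len(ord_.eigenvalues) == 2
    assert ord_.eigenvalues[0] == pytest.approx(ord_.eigenvalues[1])
    assert (ord_.eigenvalues > 0).all()


def test_pcoa_reconstructs_euclidean_distances(rng):
    mat = pd.DataFrame(rng.integers(0, 10, size=(9, 25)).astype(float))
    d = distance(mat)
    ord_ = pcoa(d)
    coords = ord_.coordinates.to_numpy()
    recon = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    assert np.abs(recon - d.to_numpy()).max() < 1e-8
    assert ord_.negative_magnitude < 1e-6
    # eigenvalues non-increasing, proportions sum to 1
    assert (np.diff(ord_.eigenvalues) <= 1e-12).all()
    assert ord_.proportion_explained.sum() == pytest.approx(1.0)


def test_pcoa_two_samples_single_axis_separation_equals_distance():
    d = pd.DataFrame([[0, 3.0], [3.0, 0]], index=["a", "b"], columns=["a", "b"])
    ord_ = pcoa(d)
    assert ord_.coordinates.shape[1] == 1
    sep = abs(ord_.coordinates.iloc[0, 0] - ord_.coordinates.iloc[1, 0])
    assert sep == pytest.approx(3.0)


def test_pcoa_agrees_with_skbio_reference(rng):
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    mat = pd.DataFrame(rng.integers(0, 6, size=(8, 15)).astype(float))
    d = distance(mat)
    mine = pcoa(d)
    ref = skbio_pcoa(DistanceMatrix(d.to_numpy(), [str(i) for i in d.index]))
    ref_eig = np.sort(ref.eigvals.values)[::-1]
    np.testing.assert_allclose(mine.eigenvalues,
                               ref_eig[: len(mine.eigenvalues)], atol=1e-8)


def test_pcoa_rejects_asymmetric_input():
    d = pd.DataFrame([[0, 1.0], [2.0, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        pcoa(d)


# ---------------------------------------------------------------------- trees


def _tree_distances(newick):
    from io import StringIO
    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    return tree


def test_nj_three_equidistant_samples_star_tree():
    d = pd.DataFrame(2 * (1 - np.eye(3)), index=list("abc"), columns=list("abc"))
    tree = _tree_distances(cluster_tree(d, "nj"))
    tips = {t.name: t.length for t in tree.tips()}
    assert set(tips) == {"a", "b", "c"}
    assert all(v == pytest.approx(1.0) for v in tips.values())


def test_nj_recovers_four_point_additive_topology():
    # tree ((a:1,b:2):3,(c:1.5,d:2.5)) -> additive distances
    d = pd.DataFrame(
        [
            [0, 3, 8.5, 9.5],
            [3, 0, 9.5, 10.5],
            [8.5, 9.5, 0, 4],
            [9.5, 10.5, 4, 0],
        ],
        index=list("abcd"), columns=list("abcd"), dtype=float,
    )
    tree = _tree_distances(cluster_tree(d, "nj"))
    # path distances in the NJ tree reproduce the additive input exactly
    tips = {t.name: t for t in tree.tips()}
    for i in "abcd":
        for j in "abcd":
            if i < j:
                path = tips[i].distance(tips[j])
                assert path == pytest.approx(d.loc[i, j])


def test_upgma_recovers_ultrametric_tree():
    # ultrametric: ((a:1,b:1):1,(c:1.5,d:1.5):0.5) root height 2
    d = pd.DataFrame(
        [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 3], [4, 4, 3, 0]],
        index=list("abcd"), columns=list("abcd"), dtype=float,
    )
    tree = _tree_distances(cluster_tree(d, "upgma"))
    tips = {t.name: t for t in tree.tips()}
    for i in "abcd":
        for j in "abcd":
            if i < j:
                assert tips[i].distance(tips[j]) == pytest.approx(d.loc[i, j])


def test_tree_input_validation():
    d2 = pd.DataFrame([[0, 1.0], [1.0, 0]], index=["a", "b"], columns=["a", "b"])
    with pytest.raises(ValueError, match=">= 3"):
        cluster_tree(d2, "nj")
    dup = pd.DataFrame(np.zeros((3, 3)), index=["a", "a", "b"], columns=["a", "a", "b"])
    with pytest.raises(ValueError, match="duplicate"):
        cluster_tree(dup, "nj")


# --------------------------------------------------------------- concordance


def test_concordance_separated_blobs_significant(rng):
    coords = np.vstack([rng.normal(0, 0.3, (6, 4)), rng.normal(10, 0.3, (6, 4))])
    mat = pd.DataFrame(coords, index=[f"x{i}" for i in range(12)])
    labels = {f"x{i}": ("A" if i < 6 else "B") for i in range(12)}
    d = distance(mat)
    res = label_concordance(d, labels, n_permutations=999, seed=1)
    assert res.silhouette > 0.9
    assert res.permutation_p <= 0.01


def test_concordance_random_labels_on_one_blob_not_significant(rng):
    coords = rng.normal(0, 1, (14, 5))
    mat = pd.DataFrame(coords, index=[f"x{i}" for i in range(14)])
    labels = {f"x{i}": ("A" if i % 2 else "B") for i in range(14)}
    res = label_concordance(distance(mat), labels, n_permutations=499, seed=2)
    assert abs(res.silhouette) < 0.3
    assert res.permutation_p > 0.05
    assert 1 / 500 <= res.permutation_p <= 1.0


def test_concordance_requires_two_populations():
    mat = pd.DataFrame(np.eye(4), index=list("abcd"))
    with pytest.raises(ValueError, match="2 populations"):
        label_concordance(distance(mat), {s: "A" for s in "abcd"})
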