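"""Brownian tip covariance and Matérn spatial covariance."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from ethnophylo.dependence import (
    LabelledCovariance,
    MaternParams,
    brownian_vcv,
    matern_cov,
    prune_and_match,
    scale_covariance,
)
from ethnophylo.synthetic import simulate_tree


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)


def test_brownian_vcv_two_tips():
    V = brownian_vcv(_tree("(A:1,B:1);"))
    df = V.to_dataframe()
    assert df.loc["A", "A"] == 1 and df.loc["B", "B"] == 1
    assert df.loc["A", "B"] == 0


def test_brownian_vcv_three_tip_arithmetic():
    V = brownian_vcv(_tree("((A:1,B:1):1,C:2);")).to_dataframe()
    assert V.loc["A", "B"] == 1
    assert V.loc["A", "C"] == 0
    assert V.loc["A", "A"] == 2


def test_brownian_vcv_brute_force_oracle():
    """Matrix equals per-pair MRCA depth computed independently."""
    tree = simulate_tree(20, rng=7)
    V = brownian_vcv(tree).to_dataframe()

    def root_path(leaf):
        path, node = [], leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path

    def depth(node):
        d = 0.0
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    leaves = {l.taxon.label: l for l in tree.leaf_node_iter()}
    for a, la in leaves.items():
        for b, lb in leaves.items():
            ancestors_b = set(id(n) for n in root_path(lb))
            mrca = next(n for n in root_path(la) if id(n) in ancestors_b)
            assert np.isclose(V.loc[a, b], depth(mrca), atol=1e-9), (a, b)


def test_brownian_vcv_ultrametric_constant_diagonal():
    V = brownian_vcv(simulate_tree(15, rng=3))
    d = np.diag(V.matrix)
    assert np.allclose(d, d[0])
    np.linalg.cholesky(V.matrix + 1e-8 * np.eye(len(d)))


def test_brownian_vcv_rejects_negative_branch():
    with pytest.raises(ValueError):
        brownian_vcv(_tree("(A:1,B:-1);"))


def test_prune_and_match_preserves_depths_and_reports_dropped():
    tree = _tree("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
    recs = pd.DataFrame({
        "society_id": ["s1", "s2", "s3"],
        "tip_label": ["A", "C", "ZZZ"],
    })
    pruned, matched, dropped = prune_and_match(tree, recs)
    assert dropped == ["s3"]
    V = brownian_vcv(pruned).to_dataframe()
    assert set(V.index) == {"A", "C"}
    assert V.loc["A", "A"] == 2.0 and V.loc["C", "C"] == 2.0
    assert V.loc["A", "C"] == 0.0


def test_prune_and_match_errors():
    tree = _tree("(A:1,B:1);")
    with pytest.raises(ValueError):
        prune_and_match(tree, pd.DataFrame({"society_id": ["x"], "tip_label": ["Q"]}))
    dup = pd.DataFrame({"society_id": ["x", "y"], "tip_label": ["A", "A"]})
    with pytest.raises(ValueError):
        prune_and_match(tree, dup)


def test_matern_exponential_closed_form():
    """kappa = 0.5 reduces to the exponential kernel to 1e-10."""
    rng = np.random.default_rng(0)
    coords = rng.uniform(-10, 10, size=(15, 2))
    phi = 3.0
    C = matern_cov(coords, MaternParams(smoothness=0.5, range_=phi, nugget=0.0))
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    assert np.allclose(C.matrix, np.exp(-d / phi), atol=1e-10)


def test_matern_known_values():
    from scipy.special import k1

    # kappa=1, d=phi: C = (d/phi) K1(d/phi) = K1(1)
    C = matern_cov(np.array([[0.0, 0.0], [0.0, 1.0]]),
                   MaternParams(smoothness=1.0, range_=1.0, nugget=0.0))
    assert np.isclose(C.matrix[0, 1], float(k1(1.0)), atol=1e-12)
    assert np.isclose(float(k1(1.0)), 0.60191, atol=5e-6)
    assert C.matrix[0, 0] == 1.0  # sigma^2 at zero distance


def test_matern_monotone_nonincreasing_and_psd():
    rng = np.random.default_rng(4)
    coords = rng.uniform(-30, 30, size=(40, 2))
    C = matern_cov(coords, MaternParams(range_=5.0))
    diff = coords[:, None, :] - coords[None, :, :]
    d = (diff**2).sum(-1) ** 0.5
    iu = np.triu_indices(40, 1)
    order = np.argsort(d[iu])
    vals = C.matrix[iu][order]
    assert (np.diff(vals) <= 1e-12).all()
    assert (vals > 0).all() and (vals <= 1.0).all()
    np.linalg.cholesky(C.matrix)


def test_matern_haversine_metric():
    C = matern_cov(np.array([[0.0, 0.0], [0.0, 90.0]]),
                   MaternParams(range_=5000.0), metric="haversine")
    assert 0 < C.matrix[0, 1] < 1


def test_matern_coincident_coordinates():
    C = matern_cov(np.array([[10.0, 10.0], [10.0, 10.0]]), MaternParams())
    assert C.matrix[0, 1] == 1.0
    assert C.matrix[0, 0] > C.matrix[0, 1]  # nugget separates the pair
    np.linalg.cholesky(C.matrix)


def test_scale_covariance():
    I = LabelledCovariance(["a", "b"], np.eye(2), "spatial")
    assert np.allclose(scale_covariance(I).matrix, np.eye(2))
    two = LabelledCovariance(["a", "b"], 2 * np.eye(2), "spatial")
    assert np.allclose(scale_covariance(two).matrix, np.eye(2))
    rng = np.random.default_rng(5)
    A = rng.normal(size=(6, 6))
    psd = LabelledCovariance(list("abcdef"), A @ A.T, "spatial")
    scaled = scale_covariance(psd)
    assert np.isclose(np.diag(scaled.matrix).max(), 1.0)
    np.linalg.cholesky(scaled.matrix + 1e-10 * np.eye(6))


def test_reorder_permutes_consistently():
    rng = np.random.default_rng(6)
    A = rng.normal(size=(4, 4))
    cov = LabelledCovariance(list("abcd"), A @ A.T, "spatial")
    perm = ["c", "a", "d", "b"]
    re = cov.reorder(perm)
    for i, li in enumerate(perm):
        for j, lj in enumerate(perm):
            assert re.matrix[i, j] == cov.to_dataframe().loc[li, lj]
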