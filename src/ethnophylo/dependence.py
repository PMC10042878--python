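"""Group-level covariance structures for Galton's problem.

Societies are not independent datapoints: they share descent (captured by a
language phylogeny) and diffuse traits through space.  Both sources of
non-independence enter the regression as covariance-structured random
effects.  This module builds the two matrices:

* a Brownian-motion tip variance–covariance matrix from the language tree —
  entry (i, j) is the shared root-to-MRCA path length, the expected trait
  covariance under gradual drift along the tree;
* a Matérn covariance over society coordinates with smoothness and variance
  fixed to 1 (κ = 0.5 recovers the exponential kernel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.special import kv

__all__ = [
    "LabelledCovariance",
    "MaternParams",
    "prune_and_match",
    "brownian_vcv",
    "matern_cov",
    "scale_covariance",
]


@dataclass
class LabelledCovariance:
    """A positive-semidefinite matrix aligned to an ordered society list."""

    labels: list[str]
    matrix: np.ndarray
    kind: str  # "phylogenetic" | "spatial"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("covariance labels must be unique")
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")

    def reorder(self, labels) -> "LabelledCovariance":
        """Return a copy with rows/columns aligned to ``labels``."""
        idx = [self.labels.index(l) for l in labels]
        return LabelledCovariance(
            labels=list(labels),
            matrix=self.matrix[np.ix_(idx, idx)],
            kind=self.kind,
            params=dict(self.params),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def cholesky(self, nugget: float = 1e-8) -> np.ndarray:
        """Lower Cholesky factor after adding ``nugget`` to the diagonal."""
        return np.linalg.cholesky(
            self.matrix + nugget * np.eye(len(self.labels))
        )


@dataclass(frozen=True)
class MaternParams:
    """Matérn kernel parameters; the analysis fixes κ = σ² = 1."""

    smoothness: float = 1.0
    variance: float = 1.0
    range_: float = 1.0
    nugget: float = 1e-8

    def __post_init__(self):
        if self.smoothness <= 0 or self.variance <= 0 or self.range_ <= 0:
            raise ValueError("smoothness, variance and range must be positive")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")


def prune_and_match(tree: dendropy.Tree, records: pd.DataFrame):
    """Restrict tree and records to societies present in both.

    Records need a ``tip_label`` column; rows with no matching tip are
    reported and excluded from phylogenetic matching.  Returns
    ``(pruned_tree, matched_records, dropped_society_ids)``; the pruned tree
    preserves tip-to-root path lengths (dendropy sums branches through
    removed degree-two nodes).
    """
    tip_labels = [t.label for t in tree.taxon_namespace]
    if len(set(tip_labels)) != len(tip_labels):
        raise ValueError("duplicate tip labels in tree")
    have = records["tip_label"].astype("string")
    matched = records.loc[have.notna() & have.isin(tip_labels)]
    dropped = records.loc[~records.index.isin(matched.index), "society_id"].tolist()
    if matched.empty:
        raise ValueError("no overlap between tree tips and records")
    if matched["tip_label"].duplicated().any():
        dups = matched.loc[matched["tip_label"].duplicated(), "tip_label"].tolist()
        raise ValueError(f"duplicate tip labels in records: {dups}")

    # independent copy with its own taxon namespace, so pruning can never
    # mutate state shared with the caller's tree
    pruned = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick",
        preserve_underscores=True,
    )
    pruned.is_rooted = tree.is_rooted is not False
    keep = set(matched["tip_label"])
    taxa = [t for t in pruned.taxon_namespace if t.label in keep]
    pruned.retain_taxa(taxa)
    pruned.purge_taxon_namespace()
    return pruned, matched, dropped


def brownian_vcv(tree: dendropy.Tree) -> LabelledCovariance:
    """Brownian-motion variance–covariance matrix of the tree tips.

    cov(i, j) = depth of the most recent common ancestor of tips i and j
    (root-to-MRCA path length); the diagonal holds tip depths.  Requires a
    rooted tree with non-negative branch lengths.
    """
    if tree.is_rooted is False:
        raise ValueError("brownian_vcv requires a rooted tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")

    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {label: i for i, label in enumerate(taxa)}
    n = len(taxa)
    V = np.zeros((n, n))

    # node depth = root-to-node path length
    tree.seed_node.depth = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.edge.length or 0.0
            node.depth = node.parent_node.depth + length

    # shared path of two tips = depth of their MRCA: at each internal node,
    # pairs of tips drawn from different child subtrees meet exactly there.
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            node.tip_set = [i]
            V[i, i] = node.depth
        else:
            children = [c.tip_set for c in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = node.depth
            node.tip_set = [i for ts in children for i in ts]

    return LabelledCovariance(labels=taxa, matrix=V, kind="phylogenetic",
                              params={"model": "brownian"})


def _distance_matrix(coords: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = coords[:, None, :] - coords[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))
    if metric == "haversine":
        lat = np.radians(coords[:, 0])
        lon = np.radians(coords[:, 1])
        dlat = lat[:, None] - lat[None, :]
        dlon = lon[:, None] - lon[None, :]
        a = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        return 2 * 6371.0 * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    raise ValueError(f"unknown metric {metric!r}")


def matern_cov(
    coords: pd.DataFrame | np.ndarray,
    params: MaternParams = MaternParams(),
    metric: str = "euclidean",
    labels=None,
) -> LabelledCovariance:
    """Matérn spatial covariance over society coordinates.

    ``coords`` is (n, 2) latitude/longitude (or a frame with ``latitude``/
    ``longitude``).  For distance d > 0,

        C(d) = σ² · 2^{1−κ} / Γ(κ) · (d/φ)^κ · K_κ(d/φ)

    with K_κ the modified Bessel function of the second kind; C(0) = σ².
    κ = 0.5 reduces to σ²·exp(−d/φ).  The nugget is added to the diagonal.
    """
    if isinstance(coords, pd.DataFrame):
        if labels is None:
            labels = coords.index.astype(str).tolist()
        coords = coords[["latitude", "longitude"]].to_numpy(float)
    coords = np.asarray(coords, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(len(coords))]
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")

    d = _distance_matrix(coords, metric)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    kappa, sigma2, phi = params.smoothness, params.variance, params.range_
    scaled = d / phi
    with np.errstate(invalid="ignore"):
        C = sigma2 * (2.0 ** (1.0 - kappa) / gamma_fn(kappa)) * scaled ** kappa * kv(kappa, scaled)
    C[scaled == 0] = sigma2
    C = C + params.nugget * np.eye(len(coords))
    return LabelledCovariance(
        labels=list(labels), matrix=C, kind="spatial",
        params={"smoothness": kappa, "variance": sigma2, "range": phi,
                "nugget": params.nugget, "metric": metric},
    )


def scale_covariance(cov: LabelledCovariance, mode: str = "unit_diagonal_max") -> LabelledCovariance:
    """Rescale a covariance so random-effect scales are comparable.

    ``unit_diagonal_max`` divides by the largest diagonal entry (PSD is
    preserved under positive scalar multiplication); ``none`` is identity.
    """
    if mode == "none":
        return cov
    if mode != "unit_diagonal_max":
        raise ValueError(f"unknown scaling mode {mode!r}")
    dmax = float(np.max(np.diag(cov.matrix)))
    if dmax <= 0:
        raise ValueError("cannot scale a covariance with non-positive diagonal")
    return LabelledCovariance(
        labels=list(cov.labels), matrix=cov.matrix / dmax, kind=cov.kind,
        params={**cov.params, "scaled_by": dmax},
    )
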