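"""Phylogenetic primitives: tree I/O, cophenetic distances, phylogenetic
eigenvectors, independent contrasts, and Pagel's lambda.

The tree is the substrate for everything downstream: the cophenetic distance
matrix feeds the eigenvector covariates used by the imputation forests, the
Brownian covariance feeds the lambda likelihood, and the pruning recursion
yields independent contrasts for phylogeny-corrected trait correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

__all__ = [
    "PhyloError",
    "Phylogeny",
    "DistanceMatrix",
    "EigenBasis",
    "LambdaFit",
    "read_newick",
    "cophenetic_distances",
    "brownian_covariance",
    "phylo_eigenvectors",
    "pic",
    "pagels_lambda",
    "lambda_loglik",
]


class PhyloError(ValueError):
    """Raised for malformed trees or invalid phylogenetic inputs."""


class Phylogeny:
    """A rooted tree with branch lengths and uniquely labelled tips.

    Polytomies are resolved deterministically (in input order) into
    zero-length binary splits at construction, so every downstream consumer
    sees a binary tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()
        self._tree.resolve_polytomies(update_bipartitions=False)
        # edges created by polytomy resolution carry no length yet
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is not self._tree.seed_node and edge.length is None:
                edge.length = 0.0
        self.tip_labels: list[str] = [
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        ]

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise PhyloError("unlabelled tip in tree")
            labels.append(leaf.taxon.label)
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise PhyloError(f"duplicate tip labels: {sorted(dupes)}")
        if len(labels) < 2:
            raise PhyloError("tree must have at least 2 tips")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None:
                raise PhyloError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise PhyloError("negative branch length")

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def subset(self, labels: Sequence[str]) -> "Phylogeny":
        """Tree restricted to ``labels`` (branch lengths preserved)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise PhyloError(f"labels not in tree: {sorted(missing)}")
        sub = self._tree.extract_tree(
            node_filter_fn=lambda nd: (not nd.is_leaf())
            or (nd.taxon is not None and nd.taxon.label in keep)
        )
        # extract_tree keeps unifurcations collapsed with summed lengths
        return Phylogeny(sub)

    def tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        self._tree.seed_node.depth = 0.0  # type: ignore[attr-defined]
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                node.depth = 0.0
            else:
                node.depth = node.parent_node.depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node.depth
        return depths


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated :class:`Phylogeny`."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloError(f"malformed Newick: {exc}") from exc
    return Phylogeny(tree)


@dataclass
class DistanceMatrix:
    """Symmetric cophenetic (patristic) distance matrix over tips."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.labels), len(self.labels)):
            raise PhyloError("distance matrix shape does not match labels")
        if not np.allclose(D, D.T):
            raise PhyloError("distance matrix is not symmetric")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def _tip_paths(tree: Phylogeny):
    """Postorder accumulation of (tip index, distance-to-node) lists."""
    idx = {lab: i for i, lab in enumerate(tree.tip_labels)}
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            node._tips = [(idx[node.taxon.label], 0.0)]
        else:
            groups = []
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                groups.append([(i, d + bl) for i, d in child._tips])
            node._tips = [t for g in groups for t in g]
            node._groups = groups
    return idx


def cophenetic_distances(tree: Phylogeny) -> DistanceMatrix:
    """Pairwise sum of branch lengths along tip-to-tip paths."""
    n = tree.n_tips
    D = np.zeros((n, n))
    _tip_paths(tree)
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            continue
        groups = node._groups
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                for i, di in groups[a]:
                    for j, dj in groups[b]:
                        D[i, j] = D[j, i] = di + dj
    return DistanceMatrix(labels=list(tree.tip_labels), D=D)


def brownian_covariance(tree: Phylogeny) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance: V_ij = depth of the MRCA of tips i, j."""
    depths = tree.tip_depths()
    labels = list(tree.tip_labels)
    n = len(labels)
    V = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for lab, d in depths.items():
        V[idx[lab], idx[lab]] = d
    # node depth at which a pair coalesces
    tree.tip_depths()  # ensure .depth set
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            node._tipset = [idx[node.taxon.label]]
        else:
            groups = [c._tipset for c in node.child_nodes()]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            V[i, j] = V[j, i] = node.depth
            node._tipset = [i for g in groups for i in g]
    return labels, V


@dataclass
class EigenBasis:
    """Principal-coordinate eigenvectors of the phylogenetic distance matrix.

    ``pct_variance`` is each retained eigenvalue's share of the total
    *positive* eigenvalue mass (negative eigenvalues, possible for
    non-Euclidean distances, are excluded from the denominator).
    """

    labels: list[str]
    vectors: np.ndarray  # n x k, orthogonal columns
    eigenvalues: np.ndarray  # k, nonincreasing
    pct_variance: np.ndarray  # k, shares in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"phylo_ev{i + 1}" for i in range(self.vectors.shape[1])]
        return pd.DataFrame(self.vectors, index=self.labels, columns=cols)


def phylo_eigenvectors(
    dm: DistanceMatrix, k: int, square_distances: bool = True
) -> EigenBasis:
    """Gower-transform the distance matrix and extract leading eigenvectors.

    ``square_distances=True`` gives the principal-coordinates convention
    G = -1/2 C (D*D) C with C the centering projector; ``False`` double
    centres D itself.
    """
    n = len(dm.labels)
    if k >= n:
        raise PhyloError(f"k={k} must be < number of tips ({n})")
    A = dm.D**2 if square_distances else dm.D
    # double centering: row means, column means, grand mean
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    G = -0.5 * (A - row - col + A.mean())
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10 * max(1.0, abs(eigval[0]))
    n_pos = int(pos.sum())
    if k > n_pos:
        raise PhyloError(
            f"k={k} exceeds the {n_pos} positive-eigenvalue axes available"
        )
    vecs = eigvec[:, :k].copy()
    # deterministic sign: largest-magnitude entry positive
    for j in range(k):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    pct = eigval[:k] / eigval[pos].sum()
    return EigenBasis(
        labels=list(dm.labels),
        vectors=vecs,
        eigenvalues=eigval[:k],
        pct_variance=pct,
    )


def _as_tip_values(tree: Phylogeny, x) -> dict[str, float]:
    if isinstance(x, pd.Series):
        x = x.to_dict()
    if isinstance(x, Mapping):
        vals = {}
        for lab in tree.tip_labels:
            if lab not in x or pd.isna(x[lab]):
                raise PhyloError(
                    f"missing trait value for tip {lab!r}; subset the tree "
                    "to scored species first"
                )
            vals[lab] = float(x[lab])
        return vals
    arr = np.asarray(x, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise PhyloError("trait vector length does not match number of tips")
    if np.isnan(arr).any():
        raise PhyloError("missing trait values; subset the tree first")
    return dict(zip(tree.tip_labels, arr))


def pic(tree: Phylogeny, x) -> np.ndarray:
    """Felsenstein's standardized independent contrasts.

    Returns n-1 contrasts in postorder over internal nodes. At each node the
    contrast is the difference of daughter values divided by the square root
    of the summed (adjusted) daughter branch lengths; the node's ancestral
    value is the branch-length-weighted average of the daughters and its
    parent branch is extended by v_l*v_r/(v_l+v_r).
    """
    vals = _as_tip_values(tree, x)
    contrasts = []
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            node._x = vals[node.taxon.label]
            node._v = node.edge.length or 0.0
        else:
            kids = node.child_nodes()
            assert len(kids) == 2  # binary after polytomy resolution
            (l, r) = kids
            vsum = l._v + r._v
            if vsum <= 0:
                raise PhyloError(
                    "zero summed branch lengths in a contrast denominator "
                    "(unresolvable zero-length cherry)"
                )
            contrasts.append((l._x - r._x) / np.sqrt(vsum))
            node._x = (l._x / l._v + r._x / r._v) / (1.0 / l._v + 1.0 / r._v) \
                if l._v > 0 and r._v > 0 else (
                    l._x if l._v == 0 else r._x
                )
            node._v = (node.edge.length or 0.0) + l._v * r._v / vsum
    return np.asarray(contrasts)


@dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's lambda with GLS-profiled nuisance params."""

    lambda_hat: float
    sigma2_hat: float
    root_mean: float
    loglik: float


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of the Brownian covariance by lambda."""
    Vl = lam * V
    np.fill_diagonal(Vl, np.diag(V))
    return Vl


def _profile_loglik(V: np.ndarray, x: np.ndarray, lam: float):
    n = len(x)
    Vl = lambda_transform(V, lam)
    try:
        c, low = cho_factor(Vl, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ones = np.ones(n)
    Vi1 = cho_solve((c, low), ones)
    Vix = cho_solve((c, low), x)
    mu = (ones @ Vix) / (ones @ Vi1)
    r = x - mu
    sig2 = (r @ cho_solve((c, low), r)) / n
    if sig2 <= 0:
        return -np.inf, np.nan, mu
    ll = -0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)
    return ll, sig2, mu


def lambda_loglik(tree: Phylogeny, x, lam: float) -> float:
    """Profile log-likelihood of lambda (sigma^2 and root mean profiled out)."""
    vals = _as_tip_values(tree, x)
    labels, V = brownian_covariance(tree)
    xv = np.array([vals[l] for l in labels])
    return _profile_loglik(V, xv, lam)[0]


def pagels_lambda(tree: Phylogeny, x, min_species: int = 10) -> LambdaFit:
    """ML estimate of Pagel's lambda on [0, 1].

    lambda = 1 corresponds to Brownian motion on the given tree; lambda = 0
    to a star phylogeny (no phylogenetic signal). sigma^2 and the root mean
    are profiled analytically by GLS at each candidate lambda; the bounded
    scalar search uses tolerance 1e-6 and ties at the bounds are reported as
    the bound values.
    """
    vals = _as_tip_values(tree, x)
    if len(vals) < min_species:
        raise PhyloError(
            f"need at least {min_species} species with values, got {len(vals)}"
        )
    labels, V = brownian_covariance(tree)
    xv = np.array([vals[l] for l in labels])
    if np.allclose(xv, xv[0]):
        raise PhyloError("constant trait: lambda likelihood is degenerate")

    def nll(lam: float) -> float:
        return -_profile_loglik(V, xv, lam)[0]

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-6})
    candidates = [(res.x, -res.fun), (0.0, -nll(0.0)), (1.0, -nll(1.0))]
    lam_hat, ll = max(candidates, key=lambda t: t[1])
    _, sig2, mu = _profile_loglik(V, xv, lam_hat)
    return LambdaFit(lambda_hat=float(lam_hat), sigma2_hat=float(sig2),
                     root_mean=float(mu), loglik=float(ll))
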