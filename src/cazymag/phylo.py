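"""Phylogenetic-signal statistics: Abouheif proximity, Moran's I, local
indicators of phylogenetic association (lipaMoran) and the Abouheif test.

The Abouheif proximity between two tips is the product, over the internal
nodes on the nodal path connecting them (including their most recent common
ancestor), of one over the number of direct descendants of each node — the
oriAbouheif convention.  Moran's I on that matrix, with trait values
permuted across tips, yields the Abouheif test of phylogenetic signal;
per-tip local Moran indicators with conditional permutation (the focal
value held fixed) localize the signal to clades.

W is row-normalized before Moran computations by default; under
row-normalized W the local indicators satisfy sum_i I_i = n * I exactly.
"""

from __future__ import annotations


import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .errors import FormatError, ValidationError


@dataclass
class ProximityMatrix:
    tips: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.tips)
        if self.W.shape != (n, n):
            raise ValidationError("proximity matrix shape does not match tip labels")
        if np.any(self.W < 0):
            raise ValidationError("proximity weights must be nonnegative")
        if not np.allclose(np.diag(self.W), 0):
            raise ValidationError("proximity matrix must have a zero diagonal")
        if not np.allclose(self.W, self.W.T):
            raise ValidationError("proximity matrix must be symmetric")

    def row_normalized(self) -> np.ndarray:
        sums = self.W.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValidationError("zero row sum in proximity matrix")
        return self.W / sums


@dataclass
class SignalResult:
    global_I: float
    global_p: float
    local_I: np.ndarray
    local_p: np.ndarray
    tips: list[str]
    n_permutations: int

    @property
    def significant_tips(self) -> list[str]:
        return [t for t, p in zip(self.tips, self.local_p) if p < 0.05]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree; unary nodes collapsed."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"cannot parse Newick: {exc}") from exc
    tree.suppress_unifurcations()
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise FormatError("tree must have at least 2 tips")
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate tip labels")
    return tree


def read_newick(path) -> dendropy.Tree:
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def abouheif_proximity(tree: dendropy.Tree) -> ProximityMatrix:
    """W[i, j] = prod over internal nodes on the nodal path between tips i
    and j of 1 / (number of direct descendants of the node)."""
    leaves = list(tree.leaf_node_iter())
    n = len(leaves)
    if n < 2:
        raise ValidationError("need at least 2 tips")
    tips = [leaf.taxon.label for leaf in leaves]
    # ancestors (excluding the leaf itself) from leaf to root, with 1/ndd
    paths = []
    for leaf in leaves:
        anc = []
        node = leaf.parent_node
        while node is not None:
            anc.append(node)
            node = node.parent_node
        paths.append(anc)
    ndd = {}
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            ndd[node] = len(node.child_nodes())
    W = np.zeros((n, n))
    for i in range(n):
        anc_i = paths[i]
        set_i = set(map(id, anc_i))
        for j in range(i + 1, n):
            # nodal path: ancestors of i up to and incl. MRCA + ancestors of j below MRCA
            mrca = next(a for a in paths[j] if id(a) in set_i)
            prod = 1.0
            for a in paths[i]:
                prod /= ndd[a]
                if a is mrca:
                    break
            for a in paths[j]:
                if a is mrca:
                    break
                prod /= ndd[a]
            W[i, j] = W[j, i] = prod
    return ProximityMatrix(tips=tips, W=W)


def _center(trait: Sequence[float]) -> np.ndarray:
    x = np.asarray(trait, dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("Moran's I undefined for a constant trait")
    return x - x.mean()


def morans_i(trait: Sequence[float], W: ProximityMatrix, row_normalize: bool = True) -> float:
    """Global Moran's I: (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2."""
    z = _center(trait)
    n = len(z)
    if n != len(W.tips):
        raise ValidationError("trait length must match number of tips")
    w = W.row_normalized() if row_normalize else W.W
    s0 = w.sum()
    return float((n / s0) * (z @ w @ z) / (z @ z))


def abouheif_test(
    trait: Sequence[float],
    tree: dendropy.Tree,
    n_permutations: int = 999,
    seed: Optional[int] = None,
    exact: bool = False,
    W: Optional[ProximityMatrix] = None,
) -> tuple[float, float]:
    """Abouheif test: Moran's I on the Abouheif proximity matrix with a
    one-sided (upper tail) trait-permutation p-value."""
    if W is None:
        W = abouheif_proximity(tree)
    z = _center(trait)
    n = len(z)
    if n != len(W.tips):
        raise ValidationError("trait length must match number of tips")
    w = W.row_normalized()
    s0 = w.sum()
    denom = z @ z

    def stat(zp: np.ndarray) -> float:
        return (n / s0) * (zp @ w @ zp) / denom

    observed = stat(z)
    if exact:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            if stat(z[np.asarray(perm)]) >= observed - 1e-12:
                count += 1
            total += 1
        return float(observed), count / total
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    Z = z[perms]  # (n_permutations, n)
    stats_perm = (n / s0) * np.einsum("pi,ij,pj->p", Z, w, Z) / denom
    count = int(np.sum(stats_perm >= observed - 1e-12))
    p = (1 + count) / (1 + n_permutations)
    return float(observed), float(p)


def lipa_moran(
    trait: Sequence[float],
    W: ProximityMatrix,
    n_permutations: int = 999,
    seed: Optional[int] = None,
) -> SignalResult:
    """Per-tip local Moran indicators with conditional permutation p-values.

    Local I_i = n * z_i * sum_j w_ij z_j / sum_k z_k^2 (row-normalized W).
    For each tip the focal value stays fixed while the remaining values are
    permuted; p is one-sided (upper tail), add-one estimator.
    """
    z = _center(trait)
    n = len(z)
    if n != len(W.tips):
        raise ValidationError("trait length must match number of tips")
    w = W.row_normalized()
    denom = (z @ z)
    local = n * z * (w @ z) / denom
    rng = np.random.default_rng(seed)
    local_p = np.empty(n)
    x = np.asarray(trait, dtype=float)
    for i in range(n):
        others = np.delete(x, i)
        count = 0
        perms = np.array([rng.permutation(len(others)) for _ in range(n_permutations)])
        shuffled = others[perms]  # (n_permutations, n-1)
        full = np.empty((n_permutations, n))
        full[:, :i] = shuffled[:, :i]
        full[:, i] = x[i]
        full[:, i + 1:] = shuffled[:, i:]
        zp = full - full.mean(axis=1, keepdims=True)
        denom_p = np.sum(zp**2, axis=1)
        local_perm = n * zp[:, i] * (zp @ w[i]) / denom_p
        count = int(np.sum(local_perm >= local[i] - 1e-12))
        local_p[i] = (1 + count) / (1 + n_permutations)
    # global test on the same W for convenience
    s0 = w.sum()
    global_i = float((n / s0) * (z @ w @ z) / denom)
    perms = np.array([rng.permutation(n) for _ in range(n_permutations)])
    Z = z[perms]
    stats_perm = (n / s0) * np.einsum("pi,ij,pj->p", Z, w, Z) / denom
    global_p = (1 + int(np.sum(stats_perm >= global_i - 1e-12))) / (1 + n_permutations)
    return SignalResult(
        global_I=global_i,
        global_p=float(global_p),
        local_I=local,
        local_p=local_p,
        tips=list(W.tips),
        n_permutations=n_permutations,
    )
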