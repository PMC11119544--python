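"""Phylogenetic trees and Brownian-motion covariance structures.

Newick I/O and subtree pruning are delegated to :mod:`dendropy`; this module
adds the validated tree wrapper and the tip-by-tip (co)variance matrices
that the signal and mixed-model fits consume.

Under Brownian motion, the expected covariance between the trait values of
two tips equals the branch length shared on their root-to-tip paths, i.e.
the depth of their most recent common ancestor.  Pagel's lambda rescales
the off-diagonal of that matrix, interpolating between full Brownian
structure (lambda = 1) and phylogenetic independence (lambda = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "PhyloTree",
    "PhyloCovariance",
    "read_newick",
    "write_newick",
    "extract_subtree",
    "build_vcv",
    "lambda_transform",
    "is_ultrametric",
]


class NewickParseError(ValueError):
    """A Newick string could not be parsed (message includes position)."""


class TreeValidationError(ValueError):
    """A tree violates structural requirements (labels, branch lengths)."""


class PhyloTree:
    """Rooted phylogenetic tree with branch lengths.

    Wraps a dendropy tree and enforces: unique non-empty tip labels,
    branch lengths present and non-negative on every non-root branch.
    Polytomies are permitted.  A length on the root branch is treated as a
    stem shared by all tips (it contributes to every root-to-tip depth).
    Zero-length branches are accepted with a warning because grafted
    megatrees commonly contain them.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- structure ---------------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in deterministic (input) order."""
        return tuple(lf.taxon.label for lf in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def root_stem(self) -> float:
        """Length attached to the root branch (0 when absent)."""
        length = self._tree.seed_node.edge.length
        return float(length) if length is not None else 0.0

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label (including any root stem)."""
        out: dict[str, float] = {}
        stem = self.root_stem
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                node._pd_depth = stem
            else:
                node._pd_depth = parent._pd_depth + float(node.edge.length)
            if node.is_leaf():
                out[node.taxon.label] = node._pd_depth
        return out

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        labels = []
        n_zero = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is None or not (node.taxon.label or "").strip():
                    raise TreeValidationError("tip with missing or empty label")
                labels.append(node.taxon.label)
            length = node.edge.length
            if node.parent_node is not None and length is None:
                raise TreeValidationError(
                    "missing branch length on a non-root branch"
                )
            if length is not None:
                if length < 0:
                    raise TreeValidationError(
                        f"negative branch length {length!r}"
                    )
                if length == 0 and node.parent_node is not None:
                    n_zero += 1
        dup = {lab for lab in labels if labels.count(lab) > 1}
        if dup:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dup)}")
        if n_zero:
            warnings.warn(
                f"tree contains {n_zero} zero-length branch(es)",
                stacklevel=3,
            )


@dataclass(frozen=True)
class PhyloCovariance:
    """Tip-by-tip shared-path-length matrix with its tip-label order.

    Consumers must align by ``labels``, never by position.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("labels and matrix dimension differ")
        object.__setattr__(self, "matrix", m)

    def submatrix(self, labels) -> "PhyloCovariance":
        """Row/column selection (and reordering) by tip label."""
        labels = list(labels)
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in pos]
        if missing:
            raise KeyError(f"labels not in covariance: {missing}")
        idx = np.array([pos[lab] for lab in labels])
        return PhyloCovariance(tuple(labels), self.matrix[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhyloCovariance":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(tuple(df.index), df.to_numpy(dtype=float))


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Quoted labels and bracket comments are accepted; internal node labels
    are ignored.  Malformed input raises :class:`NewickParseError` with the
    parser's position information; duplicate tip labels and negative branch
    lengths raise :class:`TreeValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeValidationError(f"duplicate tip label: {exc}") from exc
    except Exception as exc:
        raise NewickParseError(str(exc)) from exc
    return PhyloTree(dtree)


def read_newick_file(path) -> PhyloTree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick; round-trips topology and branch lengths."""
    s = tree._tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    return s


def extract_subtree(tree: PhyloTree, keep) -> PhyloTree:
    """Prune to ``keep`` tips, preserving all pairwise path lengths.

    Unary internal nodes created by pruning are suppressed with their
    branch lengths summed; a collapsed old root survives as a root stem so
    that root-to-tip depths (hence the Brownian covariance) are preserved.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep must contain at least one tip label")
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise KeyError(f"unknown tip labels: {sorted(unknown)}")
    clone = tree._tree.clone(depth=1)
    clone.retain_taxa_with_labels(list(keep))
    return PhyloTree(clone)


def build_vcv(tree: PhyloTree) -> PhyloCovariance:
    """Brownian-motion expected covariance: depth of each pair's MRCA.

    Entry (i, j) is the shared root-to-tip path length of tips i and j;
    the diagonal holds root-to-tip depths.  Positive semidefinite by
    construction.
    """
    leaves = list(tree._tree.leaf_node_iter())
    labels = tuple(lf.taxon.label for lf in leaves)
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    stem = tree.root_stem
    depth: dict[int, float] = {}
    below: dict[int, list[int]] = {}
    for node in tree._tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (
            stem if parent is None else depth[id(parent)] + float(node.edge.length)
        )
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            C[i, i] = depth[id(node)]
        else:
            child_sets = [below[id(ch)] for ch in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia = np.asarray(child_sets[a])
                    ib = np.asarray(child_sets[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            below[id(node)] = [i for s in child_sets for i in s]
    return PhyloCovariance(labels, C)


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda rescaling: off-diagonals multiplied by ``lam``.

    lam = 1 returns C unchanged (Brownian expectation); lam = 0 removes all
    shared structure (independence).  The result stays positive
    semidefinite for lam in [0, 1].
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    d = np.diag(np.diag(C.matrix))
    return PhyloCovariance(C.labels, lam * (C.matrix - d) + d)


def is_ultrametric(tree: PhyloTree, tol: float = 1e-6) -> bool:
    """True iff all root-to-tip depths agree within relative ``tol``."""
    d = np.array(list(tree.depths().values()))
    if d.size <= 1:
        return True
    scale = max(float(d.max()), 1e-12)
    return bool((d.max() - d.min()) <= tol * scale)
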