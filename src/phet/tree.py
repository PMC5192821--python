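"""Ultrametric phylogeny model.

Parses and validates rooted ultrametric trees (all tips equidistant from the
root) and exposes the two primitives every phylogenetic metric in this package
is built from: the tip-to-tip patristic distance matrix, and spanning
branch-length sums (Faith's phylogenetic diversity in the *rooted* convention,
i.e. the path to the root is always included so single-tip PD is nonzero).

Newick I/O is delegated to dendropy; everything downstream works on plain
numpy arrays so the permutation null models and rarefaction expectations can
be vectorised.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeValidationError",
    "DistanceMatrix",
    "UltrametricTree",
    "parse_newick",
]

#: default relative tolerance on root-to-tip depth spread
DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeValidationError(ValueError):
    """Raised when a tree violates the ultrametric-tree invariants."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of tip-to-tip path lengths.

    ``values[i, j]`` is the sum of branch lengths on the path between tips
    ``labels[i]`` and ``labels[j]`` (zero diagonal).
    """

    labels: tuple[str, ...]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(self.labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self, labels) -> np.ndarray:
        """Integer positions of *labels*, raising KeyError for unknown tips."""
        try:
            return np.array([self._index[l] for l in labels], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"species not in distance matrix: {exc.args[0]!r}") from None

    def distance(self, a: str, b: str) -> float:
        i, j = self.indices([a, b])
        return float(self.values[i, j])

    def submatrix(self, labels) -> np.ndarray:
        idx = self.indices(labels)
        return self.values[np.ix_(idx, idx)]


class UltrametricTree:
    """A rooted, validated ultrametric phylogeny.

    Parameters
    ----------
    tree :
        A rooted :class:`dendropy.Tree` with branch lengths on every
        non-root edge.
    rtol :
        Relative tolerance (as a fraction of tree height) on the spread of
        root-to-tip depths. Real chronograms carry rounding noise, so exact
        equality is not required.
    """

    def __init__(self, tree: dendropy.Tree, rtol: float = DEFAULT_ULTRAMETRIC_RTOL):
        self._dendropy = tree
        self.rtol = float(rtol)
        self._validate_and_index()
        self._distance_matrix: DistanceMatrix | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> "UltrametricTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise TreeValidationError(f"could not parse Newick: {exc}") from exc
        return cls(tree, rtol=rtol)

    @classmethod
    def from_file(cls, path, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> "UltrametricTree":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read(), rtol=rtol)

    def to_newick(self) -> str:
        s = io.StringIO()
        self._dendropy.write(file=s, schema="newick", suppress_rooting=True)
        return s.getvalue().strip()

    # -- validation / indexing --------------------------------------------

    def _validate_and_index(self) -> None:
        t = self._dendropy
        leaves = t.leaf_nodes()
        if len(leaves) < 2:
            raise TreeValidationError("tree must have at least 2 tips")

        labels: list[str] = []
        for lf in leaves:
            label = lf.taxon.label if lf.taxon is not None else lf.label
            if not label:
                raise TreeValidationError("unlabeled tip in tree")
            labels.append(label)
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")

        # branch lengths: required on non-root edges, nonnegative everywhere
        root = t.seed_node
        for nd in t.preorder_node_iter():
            if nd is root:
                continue
            if nd.edge.length is None:
                raise TreeValidationError("missing branch length on a non-root edge")
            if nd.edge.length < 0:
                raise TreeValidationError(f"negative branch length {nd.edge.length}")

        # depths via preorder accumulation
        depth: dict[int, float] = {id(root): float(root.edge.length or 0.0)}
        for nd in t.preorder_node_iter():
            if nd is root:
                continue
            depth[id(nd)] = depth[id(nd.parent_node)] + nd.edge.length

        order = np.argsort(np.array(labels, dtype=object))
        self.tip_labels: tuple[str, ...] = tuple(np.array(labels, dtype=object)[order])
        self._tip_index = {l: i for i, l in enumerate(self.tip_labels)}
        tip_depths = np.array([depth[id(lf)] for lf in leaves], dtype=float)[order]

        height = float(tip_depths.max())
        if height <= 0:
            raise TreeValidationError("tree height must be positive")
        rel_dev = np.abs(tip_depths - height) / height
        if rel_dev.max() > self.rtol:
            bad = self.tip_labels[int(rel_dev.argmax())]
            raise TreeValidationError(
                f"tree is not ultrametric: tip {bad!r} has depth "
                f"{tip_depths[rel_dev.argmax()]:.6g} vs height {height:.6g}"
            )
        self.height = height
        self.tip_depths = tip_depths

        # per-edge decomposition: length + boolean mask of subtended tips,
        # for every edge below the root (root edge length, if any, is ignored
        # as it subtends all tips identically for every metric here).
        n = len(self.tip_labels)
        edge_lengths: list[float] = []
        edge_masks: list[np.ndarray] = []
        below: dict[int, np.ndarray] = {}
        for nd in t.postorder_node_iter():
            if nd.is_leaf():
                label = nd.taxon.label if nd.taxon is not None else nd.label
                mask = np.zeros(n, dtype=bool)
                mask[self._tip_index[label]] = True
            else:
                mask = np.zeros(n, dtype=bool)
                for ch in nd.child_nodes():
                    mask |= below[id(ch)]
            below[id(nd)] = mask
            if nd is not root:
                edge_lengths.append(float(nd.edge.length))
                edge_masks.append(mask)
        self.edge_lengths = np.array(edge_lengths, dtype=float)
        #: (n_edges, n_tips) boolean incidence: edge e on the root path of tip i
        self.edge_tip_incidence = np.array(edge_masks, dtype=bool)

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.tip_labels)

    @property
    def total_length(self) -> float:
        """Sum of all branch lengths (= rooted Faith's PD of the full tip set)."""
        return float(self.edge_lengths.sum())

    def tip_indices(self, tips) -> np.ndarray:
        try:
            return np.array([self._tip_index[t] for t in tips], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown tip: {exc.args[0]!r}") from None

    def pairwise_distances(self) -> DistanceMatrix:
        """Tip-to-tip patristic distance matrix.

        On an ultrametric tree, d(a, b) = depth(a) + depth(b) - 2 depth(MRCA).
        The MRCA depth is recovered from the edge decomposition: the root-path
        length shared by two tips is the summed length of edges subtending both.
        """
        if self._distance_matrix is None:
            inc = self.edge_tip_incidence.astype(float)
            # shared[i, j] = total length of edges on both root paths = depth(MRCA)
            shared = (inc * self.edge_lengths[:, None]).T @ inc
            d = self.tip_depths[:, None] + self.tip_depths[None, :] - 2.0 * shared
            np.fill_diagonal(d, 0.0)
            d = np.maximum(d, 0.0)
            d = (d + d.T) / 2.0
            self._distance_matrix = DistanceMatrix(self.tip_labels, d)
        return self._distance_matrix

    def total_branch_length(self, tips=None) -> float:
        """Rooted Faith's PD: branch-length sum of the minimal subtree
        connecting *tips* and the root.

        With ``tips=None`` the full tip set is used, giving the total branch
        length of the tree.
        """
        if tips is None:
            return self.total_length
        tips = list(tips)
        if len(tips) == 0:
            raise ValueError("tip subset must be nonempty")
        idx = self.tip_indices(tips)
        spanned = self.edge_tip_incidence[:, idx].any(axis=1)
        return float(self.edge_lengths[spanned].sum())


def parse_newick(text: str, rtol: float = DEFAULT_ULTRAMETRIC_RTOL) -> UltrametricTree:
    """Parse a Newick string into a validated :class:`UltrametricTree`."""
    return UltrametricTree.from_newick(text, rtol=rtol)
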