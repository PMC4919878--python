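"""Reading phylogenies and harvesting their branch lengths.

Trees are held as :class:`dendropy.Tree` objects; this module adds the
operations the prior-fitting workflow needs: parsing Newick/Nexus sources
while preserving branch lengths, and converting each tree into a
:class:`BranchLengthSample` — the external/internal branch-length vectors
plus the derived quantities (tree length ``T``, counts ``n``, ``s``, ``m``,
proportions ``x``) that the likelihood functions consume.

Conventions
-----------
* Branch lengths are expected substitutions per site, non-negative reals.
* Rooted input trees are unrooted before harvesting: the two edges adjacent
  to a degree-2 root are merged with lengths summed.  The compound
  Dirichlet is defined on unrooted-tree branch counts (2s-3 edges for s
  tips) and MrBayes' unconstrained branch lengths are unrooted, so a rooted
  tree would otherwise contribute a spurious extra edge.
* Zero-length branches are floored to a small epsilon (default 1e-9) with a
  logged warning, because log-proportions appear in the likelihood; pass
  ``strict=True`` to reject them instead.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import os
from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = [
    "BranchLengthSample",
    "parse_trees",
    "harvest_sample",
    "write_newick",
    "is_length_free",
]

logger = logging.getLogger(__name__)

DEFAULT_ZERO_FLOOR = 1e-9


class TreeFormatError(ValueError):
    """Raised when a tree source cannot be parsed."""


@dataclasses.dataclass(frozen=True)
class BranchLengthSample:
    """Branch lengths of one tree, split by tip-adjacency.

    Attributes
    ----------
    external : ndarray
        Lengths of edges incident to a leaf, in tree traversal order.
    internal : ndarray
        Lengths of all remaining edges.
    """

    external: np.ndarray
    internal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "external", np.asarray(self.external, dtype=float))
        object.__setattr__(self, "internal", np.asarray(self.internal, dtype=float))
        if self.s < 3:
            raise ValueError(f"need at least 3 external branches, got {self.s}")
        for name in ("external", "internal"):
            arr = getattr(self, name)
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr < 0)):
                raise ValueError(f"{name} branch lengths must be finite and non-negative")

    @property
    def s(self) -> int:
        """Number of external (tip) branches."""
        return int(self.external.size)

    @property
    def m(self) -> int:
        """Number of internal branches (s - 3 for an unrooted bifurcating tree)."""
        return int(self.internal.size)

    @property
    def n(self) -> int:
        """Total branch count."""
        return self.s + self.m

    @property
    def T(self) -> float:
        """Tree length: sum of all branch lengths."""
        return float(self.external.sum() + (self.internal.sum() if self.m else 0.0))

    @property
    def x_external(self) -> np.ndarray:
        """Branch-length proportions of external branches, t_i / T."""
        return self.external / self.T

    @property
    def x_internal(self) -> np.ndarray:
        return self.internal / self.T

    @property
    def sum_log_x_external(self) -> float:
        return float(np.sum(np.log(self.x_external)))

    @property
    def sum_log_x_internal(self) -> float:
        return float(np.sum(np.log(self.x_internal))) if self.m else 0.0

    @property
    def all_lengths(self) -> np.ndarray:
        return np.concatenate([self.external, self.internal])


def _detect_schema(text: str) -> str:
    head = text.lstrip()[:200].lower()
    return "nexus" if head.startswith("#nexus") else "newick"


def parse_trees(
    source: str | os.PathLike, schema: str = "auto"
) -> list[dendropy.Tree]:
    """Parse all trees from a Newick or Nexus source.

    Parameters
    ----------
    source : str or path
        A file path, or the tree text itself (anything containing a
        parenthesis or newline is treated as raw text).
    schema : {"auto", "newick", "nexus"}
        Format; ``auto`` sniffs for a leading ``#NEXUS``.

    Returns
    -------
    list of dendropy.Tree
        One tree per tree statement.  Branch lengths are preserved at full
        printed precision.  Trees lacking any branch length are returned but
        flagged: ``is_length_free(tree)`` is True and a count is logged.

    Raises
    ------
    TreeFormatError
        On unparseable input or when the source contains no trees.
    """
    text: str
    src = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(src, str) and "(" not in src and "\n" not in src and os.path.exists(src):
        with open(src) as fh:
            text = fh.read()
    else:
        text = str(src)
    if schema == "auto":
        schema = _detect_schema(text)
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unknown schema {schema!r}; use newick, nexus or auto")

    try:
        tree_list = dendropy.TreeList.get(
            file=io.StringIO(text),
            schema=schema,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises many error types
        raise TreeFormatError(f"could not parse {schema} input: {exc}") from exc
    trees = list(tree_list)
    if not trees:
        raise TreeFormatError("no trees found in input")
    n_free = sum(1 for t in trees if is_length_free(t))
    if n_free:
        logger.warning(
            "%d of %d trees carry no branch lengths and will be excluded from fitting",
            n_free,
            len(trees),
        )
    return trees


def is_length_free(tree: dendropy.Tree) -> bool:
    """True if no edge of the tree has a branch length."""
    return all(
        e.length is None for e in tree.edges() if e.head_node is not tree.seed_node
    )


def _unrooted_copy(tree: dendropy.Tree) -> dendropy.Tree:
    """Clone and, if the tree has a degree-2 root, merge the root-adjacent edges."""
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        t.deroot()  # merges the two root edges, summing their lengths
    return t


def harvest_sample(
    tree: dendropy.Tree,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
    strict: bool = False,
) -> BranchLengthSample:
    """Extract the branch-length sample of one tree.

    External lengths are exactly the lengths of edges incident to a leaf;
    internal lengths are all remaining edges.  Rooted trees are unrooted
    first (root-adjacent edges merged, lengths summed).

    Raises
    ------
    ValueError
        If the tree has fewer than 3 leaves, any edge lacks a length or has
        a negative length, or (with ``strict=True``) a zero length.
    """
    t = _unrooted_copy(tree)
    n_leaves = sum(1 for _ in t.leaf_node_iter())
    if n_leaves < 3:
        raise ValueError(f"tree has {n_leaves} leaves; at least 3 required for fitting")

    external: list[float] = []
    internal: list[float] = []
    n_floored = 0
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue  # root "edge" is not a branch of the unrooted tree
        label = (
            edge.head_node.taxon.label
            if edge.head_node.taxon is not None
            else f"internal node {id(edge.head_node) & 0xFFFF}"
        )
        if edge.length is None:
            raise ValueError(f"edge leading to {label!r} has no branch length")
        length = float(edge.length)
        if not np.isfinite(length) or length < 0:
            raise ValueError(f"edge leading to {label!r} has invalid length {length}")
        if length == 0.0:
            if strict:
                raise ValueError(f"edge leading to {label!r} has zero length (strict mode)")
            length = zero_floor
            n_floored += 1
        (external if edge.head_node.is_leaf() else internal).append(length)
    if n_floored:
        logger.warning("floored %d zero-length branches to %g", n_floored, zero_floor)
    return BranchLengthSample(np.array(external), np.array(internal))


def harvest_samples(
    trees: Iterable[dendropy.Tree], **kwargs
) -> list[BranchLengthSample]:
    """Harvest every tree that carries branch lengths; log the skipped count."""
    samples = []
    skipped = 0
    for tree in trees:
        if is_length_free(tree):
            skipped += 1
            continue
        samples.append(harvest_sample(tree, **kwargs))
    if skipped:
        logger.warning("skipped %d trees without branch lengths", skipped)
    return samples


def write_newick(trees: Sequence[dendropy.Tree], path: str | os.PathLike) -> None:
    """Write trees to a Newick file, one per line, full float precision."""
    tl = dendropy.TreeList(trees)
    tl.write(path=os.fspath(path), schema="newick", suppress_rooting=True)
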