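"""Simulate random unrooted trees with known branch-length distributions.

Used for parameter-recovery testing of the fitters: topologies are sampled
by sequential random edge addition (every labelled unrooted bifurcating
shape is reachable), and branch lengths are drawn from the requested
generative family:

* ``ExpParams(rate)`` — i.i.d. Exponential(rate) on all ``2s - 3`` branches;
* ``CompoundDirichletParams`` — tree length ``T ~ Gamma(alpha_T, rate=beta_T)``,
  proportions ``x ~ Dirichlet`` with concentration ``alpha`` on the ``s``
  tip edges and ``alpha * c`` on the ``s - 3`` internal edges, branch
  lengths ``t = T * x``.

Topology realism is deliberately not modelled (no birth-death process): the
branch-length likelihoods depend only on the lengths and the
internal/external split, never on tree shape.

All randomness flows through one ``numpy`` Generator: the same seed yields
byte-identical Newick output.
"""

from __future__ import annotations

import dataclasses
import os

import dendropy
import numpy as np

from .brldist import CompoundDirichletParams, ExpParams
from .treeio import write_newick

__all__ = ["SimulationSpec", "simulate_trees", "random_topology"]


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """A reproducible tree-simulation request.

    ``generator`` is an :class:`ExpParams` or :class:`CompoundDirichletParams`
    instance naming the branch-length distribution; ``seed`` is mandatory.
    """

    n_tips: int
    n_trees: int
    generator: ExpParams | CompoundDirichletParams
    seed: int

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("need at least 3 tips")
        if isinstance(self.generator, CompoundDirichletParams) and self.n_tips < 4:
            raise ValueError("compound-Dirichlet simulation needs >= 4 tips (internal branches)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not isinstance(self.generator, (ExpParams, CompoundDirichletParams)):
            raise ValueError(f"unknown generator {self.generator!r}")


def random_topology(
    n_tips: int, rng: np.random.Generator, taxon_namespace=None
) -> dendropy.Tree:
    """A random unrooted bifurcating topology on ``n_tips`` labelled tips.

    Built by starting from the 3-tip star and repeatedly attaching the next
    tip to a uniformly chosen existing edge.  The returned tree has a
    degree-3 seed node and ``2*n_tips - 3`` edges, all without lengths.
    """
    if taxon_namespace is None:
        taxon_namespace = dendropy.TaxonNamespace(
            [f"t{i + 1}" for i in range(n_tips)]
        )
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = False
    leaves = []
    for i in range(3):
        leaf = dendropy.Node(taxon=taxon_namespace[i])
        tree.seed_node.add_child(leaf)
        leaves.append(leaf)
    # every non-seed node defines one edge; keep them in insertion order so
    # the same seed always picks the same attachment points
    edge_nodes = list(leaves)
    for i in range(3, n_tips):
        attach = edge_nodes[int(rng.integers(len(edge_nodes)))]
        parent = attach.parent_node
        mid = dendropy.Node()
        parent.remove_child(attach)
        parent.add_child(mid)
        mid.add_child(attach)
        leaf = dendropy.Node(taxon=taxon_namespace[i])
        mid.add_child(leaf)
        edge_nodes.extend([mid, leaf])
    return tree


def _assign_lengths(
    tree: dendropy.Tree,
    generator: ExpParams | CompoundDirichletParams,
    rng: np.random.Generator,
) -> None:
    externals, internals = [], []
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        (externals if edge.head_node.is_leaf() else internals).append(edge)
    s, m = len(externals), len(internals)
    if isinstance(generator, ExpParams):
        draws = rng.exponential(scale=1.0 / generator.rate, size=s + m)
        for edge, t in zip(externals + internals, draws):
            edge.length = float(t)
    else:
        g = generator
        T = rng.gamma(shape=g.alpha_T, scale=1.0 / g.beta_T)
        conc = np.concatenate([np.full(s, g.alpha), np.full(m, g.alpha * g.c)])
        x = rng.dirichlet(conc)
        for edge, xi in zip(externals + internals, x):
            edge.length = float(T * xi)


def simulate_trees(
    spec: SimulationSpec, out: str | os.PathLike | None = None
) -> list[dendropy.Tree]:
    """Simulate ``spec.n_trees`` trees; optionally also write them as Newick."""
    rng = np.random.default_rng(spec.seed)
    namespace = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(spec.n_tips)])
    trees = []
    for _ in range(spec.n_trees):
        tree = random_topology(spec.n_tips, rng, taxon_namespace=namespace)
        _assign_lengths(tree, spec.generator, rng)
        trees.append(tree)
    if out is not None:
        write_newick(trees, out)
    return trees
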