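"""Coalescent and user-supplied genealogies.

Internal trees are rooted and binary.  Coalescent trees are simulated in
generations (E[T2] = 2N) and rescaled to expected substitutions per site
via theta = 4*N*mu*l.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Genealogy:
    root: Node
    provenance: str = "coalescent"  # or "user"

    def tips(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            if node.is_leaf:
                out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    def nodes(self) -> list[Node]:
        out: list[Node] = []

        def walk(node: Node) -> None:
            out.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        return out

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def total_length(self) -> float:
        return sum(nd.length for nd in self.nodes() if nd is not self.root)

    def height(self) -> float:
        def down(node: Node) -> float:
            if node.is_leaf:
                return 0.0
            return max(ch.length + down(ch) for ch in node.children)

        return down(self.root)

    def tip_depths(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: Node, depth: float) -> None:
            if node.is_leaf:
                out[node.name] = depth
            for ch in node.children:
                walk(ch, depth + ch.length)

        walk(self.root, 0.0)
        return out

    def scaled(self, factor: float) -> "Genealogy":
        def copy(node: Node) -> Node:
            return Node(
                name=node.name,
                length=node.length * factor,
                children=[copy(c) for c in node.children],
            )

        return Genealogy(root=copy(self.root), provenance=self.provenance)

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name or ""
            return f"({inner}){label}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner}){self.root.name or ''};"


@dataclass
class DemographicParams:
    n: int
    N: float = 1000.0
    growth_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sample size must be >= 2")
        if self.N < 1:
            raise ValueError("population size must be >= 1")
        if self.growth_rate < 0:
            raise ValueError("growth rate must be >= 0")


@dataclass
class RatePrior:
    low: float = 0.0
    high: float = 500.0
    distribution: str = "uniform"

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError("need 0 <= low < high")
        if self.distribution != "uniform":
            raise ValueError("only the uniform prior is supported")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


def simulate_coalescent(
    params: DemographicParams, seed: int | np.random.Generator
) -> Genealogy:
    """Standard n-coalescent with optional exponential growth.

    Waiting times are exponential with rate k(k-1)/2 per 2N generations;
    growth is a deterministic time change with N(t) = N * exp(-g t)
    backwards in time.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lineages: list[tuple[Node, float]] = [
        (Node(name=f"t{i + 1}"), 0.0) for i in range(params.n)
    ]
    t = 0.0
    g = params.growth_rate
    while len(lineages) > 1:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (2.0 * params.N)
        e = rng.exponential(1.0)
        if g == 0.0:
            t += e / rate
        else:
            t += math.log1p(g * e / (rate * math.exp(g * t))) / g
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node_j, tj = lineages.pop(j)
        node_i, ti = lineages.pop(i)
        node_i.length = t - ti
        node_j.length = t - tj
        lineages.append((Node(children=[node_i, node_j]), t))
    root, _ = lineages[0]
    return Genealogy(root=root, provenance="coalescent")


def scale_tree(tree: Genealogy, theta: float, N: float, l: int) -> Genealogy:
    """Convert a tree in generations to expected substitutions per site."""
    if l <= 0:
        raise ValueError("alignment length must be positive")
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    mu = theta / (4.0 * N * l)
    return tree.scaled(mu)


def parse_newick(text: str) -> Genealogy:
    """Parse a rooted Newick tree; branch lengths are substitutions/site."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    missing = [
        e for e in dtree.preorder_edge_iter()
        if e.head_node is not dtree.seed_node and e.length is None
    ]
    if missing:
        raise ValueError("Newick tree is missing branch lengths")
    if len(dtree.seed_node.child_nodes()) > 2:
        warnings.warn("root polytomy resolved arbitrarily with zero-length branches")

    def convert(dnode) -> Node:
        name = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(
            name=name.replace(" ", "_") if name else None,
            length=float(dnode.edge.length or 0.0),
        )
        children = [convert(c) for c in dnode.child_nodes()]
        while len(children) > 2:  # resolve polytomies with zero-length branches
            b = children.pop()
            a = children.pop()
            children.append(Node(length=0.0, children=[a, b]))
        node.children = children
        return node

    root = convert(dtree.seed_node)
    if len(root.children) == 1 and not root.children[0].is_leaf:
        only = root.children[0]
        only.length += root.length
        root = only
    geneal = Genealogy(root=root, provenance="user")
    if geneal.n_tips < 2:
        raise ValueError("tree needs at least 2 tips")
    for nd in geneal.nodes():
        if nd.length < 0 or not math.isfinite(nd.length):
            raise ValueError("branch lengths must be finite and nonnegative")
    return geneal


def read_newick(path) -> Genealogy:
    from pathlib import Path

    return parse_newick(Path(path).read_text())
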