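"""Syntax and sentence-structure similarity.

Two scorers operate on parses of the proposition and the passage:

* :func:`syntax_score` — Jaccard overlap of the dependency-triple sets
  ``(head surface, relation, dependent surface)`` of the two trees, a cheap
  measure of shared grammatical function.
* :func:`structure_score` — a normalised convolution tree kernel on ordered
  labelled trees, counting co-rooted common subtree fragments weighted by a
  decay factor, so deeper shared structure counts more than isolated labels.

Structure trees can be derived from dependency trees (node label = relation
label) via :func:`dependency_to_structure` or supplied directly in one-line
bracketed form, keeping the module agnostic to the upstream parser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ParseError

__all__ = [
    "DepNode",
    "DependencyTree",
    "StructureTree",
    "syntax_score",
    "dependency_to_structure",
    "structure_score",
    "tree_kernel",
    "parse_bracketed",
]


@dataclass(frozen=True)
class DepNode:
    serial: int
    surface: str
    pos_tag: Optional[str]
    head_serial: int
    relation_label: str


class DependencyTree:
    """A single-rooted dependency analysis of one sentence.

    Validates on construction: unique serials, exactly one root
    (``head_serial == 0``), and head links that form a tree (no cycles).
    """

    def __init__(self, nodes: list[DepNode]):
        if not nodes:
            raise ValueError("dependency tree must have at least one node")
        serials = [n.serial for n in nodes]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate serials in dependency tree")
        roots = [n for n in nodes if n.head_serial == 0]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.nodes = sorted(nodes, key=lambda n: n.serial)
        self._by_serial = {n.serial: n for n in self.nodes}
        # cycle check: every node must reach the root
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.head_serial != 0:
                if cur.serial in seen:
                    raise ValueError(f"cycle through serial {cur.serial}")
                seen.add(cur.serial)
                if cur.head_serial not in self._by_serial:
                    raise ValueError(f"head {cur.head_serial} not in tree")
                cur = self._by_serial[cur.head_serial]
        self.root = roots[0]

    def children(self, serial: int) -> list[DepNode]:
        return [n for n in self.nodes if n.head_serial == serial]

    def triples(self) -> set[tuple[str, str, str]]:
        """(head surface, relation label, dependent surface) for each edge."""
        out = set()
        for n in self.nodes:
            if n.head_serial != 0:
                out.add((self._by_serial[n.head_serial].surface,
                         n.relation_label, n.surface))
        return out


def syntax_score(tq: DependencyTree, tp: DependencyTree) -> float:
    """Jaccard similarity of the two dependency-triple sets.

    Single-node trees have empty triple sets and score 0 (an empty/empty
    Jaccard is not read as perfect agreement).
    """
    a, b = tq.triples(), tp.triples()
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


# --------------------------------------------------------------------------
# structure trees and the convolution kernel

@dataclass(frozen=True)
class StructureTree:
    """Ordered rooted tree of labelled nodes."""

    label: str
    children: tuple["StructureTree", ...] = ()

    def __post_init__(self):
        if not self.label:
            raise ValueError("node label must be non-empty")

    def nodes(self) -> list["StructureTree"]:
        out = [self]
        for c in self.children:
            out.extend(c.nodes())
        return out

    def size(self) -> int:
        return 1 + sum(c.size() for c in self.children)

    def to_bracketed(self) -> str:
        if not self.children:
            return f"({self.label})"
        inner = " ".join(c.to_bracketed() for c in self.children)
        return f"({self.label} {inner})"


def parse_bracketed(text: str) -> StructureTree:
    """Parse a one-line bracketed tree like ``(A (B) (C (D)))``."""
    tokens = text.replace("(", " ( ").replace(")", " ) ").split()
    pos = 0

    def parse() -> StructureTree:
        nonlocal pos
        if pos >= len(tokens) or tokens[pos] != "(":
            raise ParseError(f"expected '(' at token {pos} in {text!r}")
        pos += 1
        if pos >= len(tokens) or tokens[pos] in "()":
            raise ParseError(f"expected label at token {pos} in {text!r}")
        label = tokens[pos]
        pos += 1
        children = []
        while pos < len(tokens) and tokens[pos] == "(":
            children.append(parse())
        if pos >= len(tokens) or tokens[pos] != ")":
            raise ParseError(f"unbalanced parentheses in {text!r}")
        pos += 1
        return StructureTree(label, tuple(children))

    tree = parse()
    if pos != len(tokens):
        raise ParseError(f"trailing tokens in {text!r}")
    return tree


def dependency_to_structure(t: DependencyTree) -> StructureTree:
    """Project a dependency tree onto a relation-labelled structure tree.

    Each dependency node becomes one structure node labelled with its
    relation label (the root is labelled ``ROOT``); children are ordered by
    dependent serial, preserving word order.
    """

    def build(node: DepNode) -> StructureTree:
        label = "ROOT" if node.head_serial == 0 else node.relation_label
        kids = tuple(build(c) for c in t.children(node.serial))
        return StructureTree(label, kids)

    return build(t.root)


def _delta(n1: StructureTree, n2: StructureTree, decay: float,
           memo: dict) -> float:
    key = (id(n1), id(n2))
    if key in memo:
        return memo[key]
    if n1.label != n2.label:
        val = 0.0
    elif tuple(c.label for c in n1.children) != tuple(c.label for c in n2.children):
        val = 0.0
    elif not n1.children:
        val = decay
    else:
        val = decay
        for c1, c2 in zip(n1.children, n2.children):
            val *= 1.0 + _delta(c1, c2, decay, memo)
    memo[key] = val
    return val


def tree_kernel(t1: StructureTree, t2: StructureTree, decay: float = 0.5) -> float:
    """Unnormalised convolution tree kernel: sum of Δ over all node pairs."""
    if not (0.0 < decay <= 1.0):
        raise ValueError("decay must lie in (0, 1]")
    memo: dict = {}
    return sum(_delta(a, b, decay, memo)
               for a in t1.nodes() for b in t2.nodes())


def structure_score(sq: StructureTree, sp: StructureTree,
                    decay: float = 0.5) -> float:
    """Normalised tree kernel K(sq,sp)/sqrt(K(sq,sq)·K(sp,sp)) in [0, 1]."""
    cross = tree_kernel(sq, sp, decay)
    if cross == 0.0:
        return 0.0
    norm = (tree_kernel(sq, sq, decay) * tree_kernel(sp, sp, decay)) ** 0.5
    return min(1.0, cross / norm)
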