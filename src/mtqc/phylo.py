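"""Motif-annotated mtDNA haplogroup phylogeny.

The maternal mtDNA genealogy is a rooted tree whose root represents the
rCRS baseline state; each edge carries the *motif* — the ordered set of
variants acquired on that branch.  A node's *expected profile* is the
cumulative union of motifs on its root path, with back mutations
(reversions to the rCRS allele) removing the ancestral entry at that
position.

The tree file format is bespoke indentation-based text (Newick cannot
annotate edges with variant motifs): one node per line, depth given by
leading two-space indents, ``<name>: <comma-separated tokens>``, back
mutations prefixed ``!``, root line without a motif.  A topology-only
Newick export is provided for interoperability.

A fixture subtree is bundled (``data/fixture_tree.txt``).  Its L1b*/L2*
motifs carry the variants documented for those lineages; the remaining
haplogroups carry plausible implementer-chosen motifs and are fixtures,
not a reproduction of any published phylogeny build.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import dendropy

from .variants import Variant, VariantParseError, format_variant, parse_variant


class PhylogenyError(ValueError):
    """Malformed tree source or invariant violation."""


@dataclass(frozen=True)
class MotifEntry:
    """One motif variant on an edge; back mutations revert to the rCRS allele."""

    variant: Variant
    is_back_mutation: bool = False

    def __str__(self) -> str:
        return ("!" if self.is_back_mutation else "") + format_variant(self.variant)


@dataclass(eq=False)
class HaplogroupNode:
    name: str
    parent: "HaplogroupNode | None" = None
    branch_motif: tuple[MotifEntry, ...] = ()
    children: list["HaplogroupNode"] = field(default_factory=list)

    @property
    def depth(self) -> int:
        d, node = 0, self
        while node.parent is not None:
            d += 1
            node = node.parent
        return d

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def path_from_root(self) -> list["HaplogroupNode"]:
        path: list[HaplogroupNode] = []
        node: HaplogroupNode | None = self
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def __repr__(self) -> str:  # pragma: no cover
        return f"HaplogroupNode({self.name!r}, depth={self.depth})"


class MtPhylogeny:
    """Rooted haplogroup tree with a name index and cumulative-profile queries."""

    def __init__(self, root: HaplogroupNode):
        self.root = root
        self.index: dict[str, HaplogroupNode] = {}
        for node in self._walk(root):
            if node.name in self.index:
                raise PhylogenyError(f"duplicate haplogroup name {node.name!r}")
            self.index[node.name] = node
        self._profile_cache: dict[str, frozenset[Variant]] = {}
        self._validate()

    @staticmethod
    def _walk(node: HaplogroupNode) -> Iterator[HaplogroupNode]:
        yield node
        for child in node.children:
            yield from MtPhylogeny._walk(child)

    def _validate(self) -> None:
        if self.root.branch_motif:
            raise PhylogenyError("root must carry no motif (it is the rCRS baseline)")
        for node in self.nodes():
            positions = [e.variant.position for e in node.branch_motif]
            if len(positions) != len(set(positions)):
                raise PhylogenyError(f"edge to {node.name!r} repeats a position")
            # back mutations must revert something acquired on the root path
            ancestral: set[int] = set()
            anc = node.parent
            while anc is not None:
                ancestral.update(
                    e.variant.position for e in anc.branch_motif if not e.is_back_mutation
                )
                anc = anc.parent
            for e in node.branch_motif:
                if e.is_back_mutation and e.variant.position not in ancestral:
                    raise PhylogenyError(
                        f"edge to {node.name!r}: back mutation at "
                        f"{e.variant.position} has no ancestral counterpart"
                    )

    # ------------------------------------------------------------------
    # queries

    def nodes(self) -> Iterator[HaplogroupNode]:
        """Pre-order traversal."""
        return self._walk(self.root)

    def node(self, name: str) -> HaplogroupNode:
        try:
            return self.index[name]
        except KeyError:
            raise KeyError(f"unknown haplogroup {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self.index

    def __len__(self) -> int:
        return len(self.index)

    def leaves(self) -> list[HaplogroupNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def expected_profile(self, node_name: str) -> frozenset[Variant]:
        """Cumulative variant set on the root path to ``node_name``."""
        if node_name in self._profile_cache:
            return self._profile_cache[node_name]
        node = self.node(node_name)
        state: dict[int, Variant] = {}
        for step in node.path_from_root():
            for entry in step.branch_motif:
                if entry.is_back_mutation:
                    state.pop(entry.variant.position, None)
                else:
                    state[entry.variant.position] = entry.variant
        profile = frozenset(state.values())
        self._profile_cache[node_name] = profile
        return profile

    def mrca(self, a: str, b: str) -> HaplogroupNode:
        pa = self.node(a).path_from_root()
        pb = self.node(b).path_from_root()
        last = self.root
        for x, y in zip(pa, pb):
            if x is not y:
                break
            last = x
        return last

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """True also when the two names coincide."""
        node: HaplogroupNode | None = self.node(descendant)
        target = self.node(ancestor)
        while node is not None:
            if node is target:
                return True
            node = node.parent
        return False

    def path_branch_count(self, a: str, b: str) -> int:
        """Number of edges on the tree path a -> MRCA -> b."""
        m = self.mrca(a, b)
        return (self.node(a).depth - m.depth) + (self.node(b).depth - m.depth)

    def lineage_divergence(self, a: str, b: str) -> tuple[int, frozenset[Variant]]:
        """Variants separating two haplogroups' expected profiles.

        Returns the symmetric difference of the cumulative profiles and its
        cardinality; symmetric in its arguments.
        """
        diff = self.expected_profile(a) ^ self.expected_profile(b)
        return len(diff), frozenset(diff)

    def all_positions(self) -> frozenset[int]:
        """Every position carried by any motif entry in the tree."""
        return frozenset(
            e.variant.position for n in self.nodes() for e in n.branch_motif
        )

    # ------------------------------------------------------------------
    # serialisation

    def to_newick(self) -> str:
        """Topology-only Newick export (motifs are not representable)."""
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)

        def build(src: HaplogroupNode, dst: dendropy.Node) -> None:
            if src.children:
                dst.label = src.name
                for child in src.children:
                    node = dendropy.Node()
                    dst.add_child(node)
                    build(child, node)
            else:
                dst.taxon = taxa.new_taxon(src.name)

        build(self.root, tree.seed_node)
        return tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def _parse_line(line: str, lineno: int) -> tuple[int, str, tuple[MotifEntry, ...]]:
    stripped = line.rstrip()
    indent = len(stripped) - len(stripped.lstrip(" "))
    if indent % 2:
        raise PhylogenyError(f"line {lineno}: odd indentation ({indent} spaces)")
    body = stripped.strip()
    if ":" in body:
        name, motif_s = body.split(":", 1)
    else:
        name, motif_s = body, ""
    name = name.strip()
    if not name:
        raise PhylogenyError(f"line {lineno}: missing haplogroup name")
    entries: list[MotifEntry] = []
    for tok in motif_s.replace(",", " ").split():
        back = tok.startswith("!")
        try:
            v = parse_variant(tok[1:] if back else tok)
        except VariantParseError as exc:
            raise PhylogenyError(f"line {lineno}: {exc}") from exc
        entries.append(MotifEntry(v, back))
    return indent // 2, name, tuple(entries)


def load_phylogeny(source: str) -> MtPhylogeny:
    """Parse the indentation-based tree format into a validated phylogeny."""
    lines = [
        (i, ln) for i, ln in enumerate(source.splitlines(), start=1) if ln.strip()
    ]
    if not lines:
        raise PhylogenyError("empty tree source")
    lineno, first = lines[0]
    depth, name, motif = _parse_line(first, lineno)
    if depth != 0:
        raise PhylogenyError(f"line {lineno}: root line must not be indented")
    if motif:
        raise PhylogenyError(f"line {lineno}: root line must carry no motif")
    root = HaplogroupNode(name)
    stack = [root]  # stack[d] = current node at depth d
    for lineno, line in lines[1:]:
        depth, name, motif = _parse_line(line, lineno)
        if depth == 0:
            raise PhylogenyError(f"line {lineno}: second root {name!r}")
        if depth > len(stack):
            raise PhylogenyError(
                f"line {lineno}: indentation jumps by more than one level"
            )
        if not motif:
            raise PhylogenyError(f"line {lineno}: non-root node {name!r} needs a motif")
        parent = stack[depth - 1]
        node = HaplogroupNode(name, parent=parent, branch_motif=motif)
        parent.children.append(node)
        del stack[depth:]
        stack.append(node)
    try:
        return MtPhylogeny(root)
    except PhylogenyError:
        raise


def load_phylogeny_file(path: str) -> MtPhylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        return load_phylogeny(fh.read())


def format_phylogeny(tree: MtPhylogeny) -> str:
    """Inverse of :func:`load_phylogeny` (canonical variant tokens)."""
    lines: list[str] = []

    def emit(node: HaplogroupNode, depth: int) -> None:
        indent = "  " * depth
        if node.branch_motif:
            motif = ", ".join(str(e) for e in node.branch_motif)
            lines.append(f"{indent}{node.name}: {motif}")
        else:
            lines.append(f"{indent}{node.name}")
        for child in node.children:
            emit(child, depth + 1)

    emit(tree.root, 0)
    return "\n".join(lines) + "\n"


@lru_cache(maxsize=1)
def fixture_tree() -> MtPhylogeny:
    """The bundled haplogroup subtree used by tests, examples and defaults."""
    source = (
        importlib.resources.files("mtqc").joinpath("data/fixture_tree.txt").read_text()
    )
    return load_phylogeny(source)
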