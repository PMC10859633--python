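"""Core domain types: monosaccharides, linkages, glycan graphs.

A glycan is modelled as a rooted tree oriented toward the reducing end:
every residue except the root has exactly one outgoing edge (child ->
parent linkage).  Components whose attachment point is unknown (written
``{Fuc(a1-3)}`` in IUPAC-condensed) are carried as *floating* subgraphs
next to the main tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import StructureError

#: Sort rank used wherever an unknown position must order after known ones.
_UNKNOWN_POS_RANK = 99

#: Residues conventionally drawn perpendicular to the chain they decorate.
#: They never continue a drawn main chain: at equal branch length they are
#: bracketed, keeping e.g. Lewis antigens in their published spelling
#: Gal(b1-4)[Fuc(a1-3)]GlcNAc.
PERPENDICULAR_RESIDUES = frozenset({"Fuc", "Xyl"})


def position_rank(pos: str) -> int:
    """Rank of a linkage/modification position for deterministic ordering.

    Numeric positions sort naturally; ``"?"`` (unknown) and ``"O"``
    (unknown atom) sort after every known position.
    """
    return int(pos) if pos.isdigit() else _UNKNOWN_POS_RANK


@dataclass
class Monosaccharide:
    """One residue: an SNFG base name plus display-relevant decorations.

    ``modifications`` holds ``(position, substituent)`` pairs such as
    ``("6", "S")`` for 6-O-sulfation; position ``"O"`` marks an unknown
    linking atom.  ``ring_form`` is ``"p"`` (pyranose, default) or
    ``"f"`` (furanose).  ``enantiomer`` is an explicit ``"D"``/``"L"``
    prefix from the input, or ``None`` when unspecified.
    """

    node_id: int
    base_name: str
    ring_form: str = "p"
    enantiomer: str | None = None
    modifications: list[tuple[str, str]] = field(default_factory=list)
    alditol: bool = False
    in_catalog: bool = True

    def token(self) -> str:
        """Serialize back to an IUPAC-condensed residue token."""
        parts = []
        if self.enantiomer:
            parts.append(f"{self.enantiomer}-")
        parts.append(self.base_name)
        if self.ring_form == "f":
            parts.append("f")
        for pos, sub in self.modifications:
            parts.append(f"{pos}{sub}")
        if self.alditol:
            parts.append("-ol")
        return "".join(parts)


@dataclass(frozen=True)
class Linkage:
    """A glycosidic bond: anomeric configuration and the joined carbons.

    ``anomer`` is ``"a"``, ``"b"`` or ``"?"``; positions are digit
    strings or ``"?"``.  Serializes as ``(a1-3)``.
    """

    anomer: str = "?"
    child_pos: str = "?"
    parent_pos: str = "?"

    def token(self) -> str:
        return f"({self.anomer}{self.child_pos}-{self.parent_pos})"


class GlycanGraph:
    """Rooted tree of residues plus floating ambiguous components.

    ``parent_of`` maps child node id -> (parent node id, linkage); the
    reducing end (``root``) has no entry.  ``attachment`` is only set on
    floating components and records the linkage written inside the curly
    brackets (the parent side is unknown).
    """

    def __init__(self) -> None:
        self.nodes: dict[int, Monosaccharide] = {}
        self.parent_of: dict[int, tuple[int, Linkage]] = {}
        self.root: int | None = None
        self.floating: list[GlycanGraph] = []
        self.attachment: Linkage | None = None
        self._next_id = 0
        self._order_cache = None

    # -- construction -------------------------------------------------

    def invalidate_caches(self) -> None:
        """Drop derived data (canonical child ordering) after mutation."""
        self._order_cache = None

    def add_node(self, residue: Monosaccharide) -> int:
        if residue.node_id in self.nodes:
            raise StructureError(f"duplicate node id {residue.node_id}")
        self.nodes[residue.node_id] = residue
        self._next_id = max(self._next_id, residue.node_id + 1)
        self.invalidate_caches()
        return residue.node_id

    def new_node(self, **kwargs) -> Monosaccharide:
        residue = Monosaccharide(node_id=self._next_id, **kwargs)
        self.add_node(residue)
        return residue

    def add_edge(self, child: int, parent: int, linkage: Linkage) -> None:
        if child in self.parent_of:
            raise StructureError(f"node {child} already has a parent")
        self.parent_of[child] = (parent, linkage)
        self.invalidate_caches()

    # -- queries -------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.parent_of)

    def children(self, node_id: int) -> list[tuple[int, Linkage]]:
        """Direct children of a node, in insertion order."""
        return [
            (child, link)
            for child, (parent, link) in self.parent_of.items()
            if parent == node_id
        ]

    def edges(self) -> list[tuple[int, int, Linkage]]:
        return [(c, p, l) for c, (p, l) in self.parent_of.items()]

    def subtree_nodes(self, node_id: int) -> list[int]:
        """All node ids in the subtree rooted at ``node_id`` (preorder)."""
        out = [node_id]
        for child, _ in self.children(node_id):
            out.extend(self.subtree_nodes(child))
        return out

    def longest_path_len(self, node_id: int) -> int:
        """Residue count of the longest chain from ``node_id`` to a leaf."""
        kids = self.children(node_id)
        if not kids:
            return 1
        return 1 + max(self.longest_path_len(c) for c, _ in kids)

    def validate(self) -> None:
        """Check the tree invariants; raise :class:`StructureError` if broken."""
        if self.root is None or self.root not in self.nodes:
            raise StructureError("graph has no reducing end")
        if self.root in self.parent_of:
            raise StructureError("reducing end must not have a parent")
        for child, (parent, _) in self.parent_of.items():
            if child not in self.nodes or parent not in self.nodes:
                raise StructureError(f"edge {child}->{parent} references missing node")
        # connectivity: every node reaches the root
        for node in self.nodes:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise StructureError("cycle detected")
                seen.add(cur)
                if cur not in self.parent_of:
                    raise StructureError(f"node {cur} is disconnected from the reducing end")
                cur = self.parent_of[cur][0]
        for comp in self.floating:
            comp.validate()


@dataclass
class Branch:
    """One branch of a decomposition: its own chain of residues.

    ``attach_node`` is the main-component residue the branch hangs off;
    ``depth`` is 1 for branches off the main chain and increases by one
    per nesting level.  ``chain`` lists the branch's internal main path
    from the attachment outward (nearest residue first).
    """

    attach_node: int
    depth: int
    chain: list[int]


@dataclass
class Decomposition:
    """Main chain / branches / nested branches split of a glycan tree."""

    main_chain: list[int]
    branches: list[Branch]
    floating: list[GlycanGraph] = field(default_factory=list)

    def covered_nodes(self) -> list[int]:
        out = list(self.main_chain)
        for b in self.branches:
            out.extend(b.chain)
        return out
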