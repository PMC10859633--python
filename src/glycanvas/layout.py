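"""2D grid layout of glycan trees for SNFG-style figures.

Coordinates live on a grid with the reducing end at (0, 0), x increasing
toward the non-reducing end (drawn leftward) and y increasing upward.
Placement happens in four passes:

1. *initial positions* — main-chain residue k at (k, 0); each branch
   starts at (x_attach + 1) and stacks one row above the rows already
   used by earlier (lower-ordered) sibling subtrees;
2. *step (i)* — terminal single-residue branches of perpendicular
   residues (fucose, xylose) are folded onto their parent's column, one
   unit below (or above on collision), with a vertical bond;
3. *step (ii)* — every branch-point (hub) residue is re-placed at the
   arithmetic mean of its children's y positions, leaves-to-root, and
   single-child residues ride at their child's height so the chain back
   to the root stays level;
4. *step (iii)* — vertical slack opened by centering is removed by
   pulling branch subtrees together until vertically adjacent branches
   sharing a column are exactly 1 unit apart, re-centering hubs after
   every pull until a fixed point.

All y coordinates are exact :class:`fractions.Fraction`s (centering
introduces halves, nested asymmetric branches smaller rationals), so the
fixed-point loop compares positions exactly and cannot drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .model import PERPENDICULAR_RESIDUES, Decomposition, GlycanGraph
from .nomenclature import decompose, ordered_children

Coord = tuple[Fraction, Fraction]

#: Default perpendicular set, re-exported for option construction.
DEFAULT_PERPENDICULAR = PERPENDICULAR_RESIDUES


@dataclass(frozen=True)
class LayoutOptions:
    """Options that shape the coordinate computation (not the topology)."""

    vertical: bool = False
    compact: bool = False
    perpendicular_set: frozenset[str] = DEFAULT_PERPENDICULAR
    perpendicular_below: bool = True


@dataclass
class FloatingLayout:
    """Layout of one floating (ambiguous) component, already offset into
    the reserved band beyond the main structure."""

    component: GlycanGraph
    positions: dict[int, Coord]
    perpendicular: set[int]
    bonds: list[tuple[int, int]]


@dataclass
class LayoutResult:
    """Grid coordinates and bond list for one glycan."""

    positions: dict[int, Coord]
    bonds: list[tuple[int, int]]  # (child, parent)
    perpendicular: set[int] = field(default_factory=set)
    orientation: str = "horizontal"
    floating_layouts: list[FloatingLayout] = field(default_factory=list)

    def debug_dump(self) -> list[dict]:
        """Plain JSON-able dump (node_id, x, y) for golden-file tests."""
        return [
            {"node_id": n, "x": float(x), "y": float(y)}
            for n, (x, y) in sorted(self.positions.items())
        ]


# ---------------------------------------------------------------------------
# Pass 1: initial grid positions

def assign_initial_positions(g: GlycanGraph, d: Decomposition) -> LayoutResult:
    """Place residues on the integer grid before y refinement.

    The reducing end sits at (0, 0); x increments by one per residue
    along every chain; a branch's rows stack directly above the rows
    consumed by its lower-ordered siblings, so each level of branching
    raises y by at least one.
    """
    positions: dict[int, Coord] = {}

    def extent(node: int) -> int:
        kids = ordered_children(g, node)
        if not kids:
            return 1
        return sum(extent(c) for c, _ in kids)

    def place(node: int, x: int, y: int) -> None:
        positions[node] = (Fraction(x), Fraction(y))
        offset = 0
        for child, _ in ordered_children(g, node):
            place(child, x + 1, y + offset)
            offset += extent(child)

    place(g.root, 0, 0)
    bonds = [(c, p) for c, p, _ in g.edges()]
    return LayoutResult(positions=positions, bonds=bonds)


# ---------------------------------------------------------------------------
# Pass 2 — step (i): perpendicular residues

def _perpendicular_nodes(g: GlycanGraph, opts: LayoutOptions) -> list[int]:
    """Terminal single-residue *branches* (not chain continuations) whose
    residue is in the perpendicular set."""
    out = []
    for node in g.nodes:
        if g.children(node):
            continue
        if g.nodes[node].base_name not in opts.perpendicular_set:
            continue
        if node == g.root:
            continue
        parent, _ = g.parent_of[node]
        siblings = ordered_children(g, parent)
        if len(siblings) >= 2 and siblings[0][0] != node:
            out.append(node)
    return out


def fix_perpendicular_overlap(
    g: GlycanGraph, layout: LayoutResult, opts: LayoutOptions | None = None
) -> LayoutResult:
    """Step (i): fold decorating fucose/xylose onto the parent's column.

    Each qualifying residue moves to (x_parent, y_parent − 1), flipping
    above the parent when that slot is taken (two perpendicular residues
    on one parent end up on opposite sides).  The vacated row's slack is
    recovered later by step (iii).
    """
    opts = opts or LayoutOptions()
    occupied = set(layout.positions.values())
    first, second = (-1, 1) if opts.perpendicular_below else (1, -1)
    for node in _perpendicular_nodes(g, opts):
        parent, _ = g.parent_of[node]
        px, py = layout.positions[parent]
        for side in (first, second):
            slot = (px, py + side)
            if slot not in occupied:
                occupied.discard(layout.positions[node])
                layout.positions[node] = slot
                occupied.add(slot)
                layout.perpendicular.add(node)
                break
        # both slots taken (>2 perpendicular residues on one parent):
        # the residue keeps its stacked branch position.
    return layout


# ---------------------------------------------------------------------------
# Pass 3 — step (ii): hub centering

def center_hubs(g: GlycanGraph, layout: LayoutResult) -> LayoutResult:
    """Step (ii): place every branch-point residue centrally between its
    branch connections, leaves toward the root.

    Perpendicular residues are excluded from the mean (they sit on the
    hub's own column) and are re-anchored one unit off their parent
    afterwards.  A residue with a single in-chain child rides at the
    child's height, which propagates the centered height back to the
    reducing end.
    """

    def visit(node: int) -> None:
        kids = [c for c, _ in ordered_children(g, node)]
        for child in kids:
            visit(child)
        inline = [c for c in kids if c not in layout.perpendicular]
        x, y = layout.positions[node]
        if inline:
            ys = [layout.positions[c][1] for c in inline]
            y = sum(ys, Fraction(0)) / len(ys)
            layout.positions[node] = (x, y)
        for child in kids:
            if child in layout.perpendicular:
                cx, cy = layout.positions[child]
                side = 1 if cy > layout.positions[node][1] else -1
                layout.positions[child] = (cx, y + side)

    visit(g.root)
    return layout


# ---------------------------------------------------------------------------
# Pass 4 — step (iii): gap compaction

def _branch_units(g: GlycanGraph, layout: LayoutResult) -> list[list[int]]:
    """Movable units: every subtree hanging off a branch point other than
    the chain continuation (outermost first)."""
    units = []
    for node in g.nodes:
        kids = [c for c, _ in ordered_children(g, node) if c not in layout.perpendicular]
        for child in kids[1:]:
            units.append(g.subtree_nodes(child))
    return units


def _vertical_gap(
    layout: LayoutResult, unit: list[int]
) -> Fraction | None:
    """Smallest vertical distance from a unit's residues down to any
    residue outside the unit in the same column (|Δx| < 1)."""
    unit_set = set(unit)
    best: Fraction | None = None
    for a in unit:
        ax, ay = layout.positions[a]
        for b, (bx, by) in layout.positions.items():
            if b in unit_set or by >= ay or abs(ax - bx) >= 1:
                continue
            gap = ay - by
            if best is None or gap < best:
                best = gap
    return best


def compact_branch_gaps(
    g: GlycanGraph, layout: LayoutResult, max_iter: int | None = None
) -> LayoutResult:
    """Step (iii): pull branch stacks together until vertically adjacent
    branches are exactly 1 unit apart, re-centering hubs after each pull.

    Iterates to a fixed point (each pull strictly lowers a subtree, and
    hub re-centering only averages, so total height is monotone
    non-increasing); a hard iteration cap guards termination.
    """
    n = g.n_nodes
    limit = max_iter if max_iter is not None else n * n + 10
    for _ in range(limit):
        moved = False
        units = _branch_units(g, layout)
        # process lower units first so upper ones see settled neighbours
        units.sort(key=lambda u: min(layout.positions[x][1] for x in u))
        for unit in units:
            gap = _vertical_gap(layout, unit)
            if gap is None:
                continue
            delta = gap - 1
            if delta != 0:
                for node in unit:
                    x, y = layout.positions[node]
                    layout.positions[node] = (x, y - delta)
                moved = True
        if moved:
            center_hubs(g, layout)
        else:
            break
    return layout


# ---------------------------------------------------------------------------
# Composition

def _layout_main(g: GlycanGraph, opts: LayoutOptions) -> LayoutResult:
    layout = assign_initial_positions(g, decompose(g))
    layout = fix_perpendicular_overlap(g, layout, opts)
    layout = center_hubs(g, layout)
    layout = compact_branch_gaps(g, layout)
    return layout


def layout_glycan(g: GlycanGraph, opts: LayoutOptions | None = None) -> LayoutResult:
    """Full layout: decomposition, initial placement, refinement steps
    (i)–(iii), floating-component band, optional portrait transposition.

    Floating components are laid out independently and shifted into a
    band one column beyond the main structure's x extent (drawn to the
    left of the glycan, behind the ambiguity bracket), stacked
    vertically from the main structure's baseline.
    """
    g.validate()
    opts = opts or LayoutOptions()
    layout = _layout_main(g, opts)

    if g.floating:
        band_x = max(x for x, _ in layout.positions.values()) + 2
        band_y = Fraction(0)
        for comp in g.floating:
            sub = _layout_main(comp, opts)
            min_y = min(y for _, y in sub.positions.values())
            max_y = max(y for _, y in sub.positions.values())
            shifted = {
                n: (x + band_x, y - min_y + band_y)
                for n, (x, y) in sub.positions.items()
            }
            layout.floating_layouts.append(
                FloatingLayout(
                    component=comp,
                    positions=shifted,
                    perpendicular=sub.perpendicular,
                    bonds=sub.bonds,
                )
            )
            band_y += max_y - min_y + 2

    if opts.vertical:
        layout.positions = {n: (y, x) for n, (x, y) in layout.positions.items()}
        for fl in layout.floating_layouts:
            fl.positions = {n: (y, x) for n, (x, y) in fl.positions.items()}
        layout.orientation = "vertical"
    return layout


# ---------------------------------------------------------------------------
# Invariant helpers (used by the test-suite and acceptance checks)

def min_symbol_distance_sq(layout: LayoutResult) -> Fraction | None:
    """Exact squared minimum pairwise symbol-center distance."""
    pts = list(layout.positions.values())
    for fl in layout.floating_layouts:
        pts.extend(fl.positions.values())
    best: Fraction | None = None
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            dx = pts[i][0] - pts[j][0]
            dy = pts[i][1] - pts[j][1]
            d2 = dx * dx + dy * dy
            if best is None or d2 < best:
                best = d2
    return best


def adjacent_branch_gaps(g: GlycanGraph, layout: LayoutResult) -> list[Fraction]:
    """The post-compaction vertical gap of every branch unit that has a
    neighbour below in its column; all should equal 1."""
    gaps = []
    for unit in _branch_units(g, layout):
        gap = _vertical_gap(layout, unit)
        if gap is not None:
            gaps.append(gap)
    return gaps


def hub_deviations(g: GlycanGraph, layout: LayoutResult) -> list[float]:
    """|hub y − mean(child y)| over all branch points (in-chain children)."""
    out = []
    for node in g.nodes:
        inline = [
            c for c, _ in g.children(node) if c not in layout.perpendicular
        ]
        if len(inline) >= 2:
            mean = sum((layout.positions[c][1] for c in inline), Fraction(0)) / len(inline)
            out.append(abs(float(layout.positions[node][1] - mean)))
    return out
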