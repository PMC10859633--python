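"""Domon–Costello fragment-ion annotation of glycan drawings.

Glycan MS/MS fragments are named B/C/Y/Z for glycosidic cleavages (B and
C retain the non-reducing side, Y and Z the reducing side) and A/X for
cross-ring cleavages, whose cleaved ring-bond numbers are written as
leading superscripts (e.g. ``2,4A2``).  The annotation overlay draws a
cleavage stroke across the bond (or symbol), with a short hook pointing
toward the retained side, in the style popularized by glycomics
annotation software.

Fragment subscripts are caller-assigned: enumeration conventions differ
between linear and branched glycans, and mass-spectrometric assignment
is out of scope here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from .errors import FragmentError
from .model import GlycanGraph
from .nomenclature import ordered_children
from .renderer import SvgDocument

GLYCOSIDIC_IONS = frozenset("BCYZ")
RING_IONS = frozenset("AX")
#: Ions that retain the reducing end (hook points toward it).
REDUCING_SIDE_IONS = frozenset("XYZ")

_LABEL_RE = re.compile(r"^(?:([0-9]),([0-9]))?([ABCXYZ])([0-9]+)$")


@dataclass(frozen=True)
class FragmentAnnotation:
    """One fragment ion bound to a bond or residue.

    ``edge`` is a (child, parent) node-id pair for glycosidic ions;
    ``node`` a node id for ring ions; exactly one of the two is set.
    ``ring_bonds`` carries the cleaved ring-bond numbers for A/X ions.
    """

    ion_type: str
    index: int
    ring_bonds: tuple[int, int] | None = None
    edge: tuple[int, int] | None = None
    node: int | None = None

    def __post_init__(self):
        if self.ion_type in GLYCOSIDIC_IONS:
            if self.ring_bonds is not None:
                raise FragmentError(
                    f"{self.ion_type} ions carry no ring-bond numbers"
                )
            if self.edge is None or self.node is not None:
                raise FragmentError(f"{self.ion_type} ions must target an edge")
        elif self.ion_type in RING_IONS:
            if self.ring_bonds is None:
                raise FragmentError(
                    f"{self.ion_type} ions require ring-bond numbers"
                )
            if self.node is None or self.edge is not None:
                raise FragmentError(f"{self.ion_type} ions must target a residue")
        else:
            raise FragmentError(f"unknown ion type {self.ion_type!r}")

    def label(self) -> str:
        prefix = f"{self.ring_bonds[0]},{self.ring_bonds[1]}" if self.ring_bonds else ""
        return f"{prefix}{self.ion_type}{self.index}"


def validate_fragment_label(text: str) -> tuple[str, int, tuple[int, int] | None]:
    """Parse a ``B2`` / ``Y1`` / ``2,4A2`` style label.

    Returns (ion_type, index, ring_bonds); inverse of
    :meth:`FragmentAnnotation.label`.
    """
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise FragmentError(f"malformed fragment label {text!r}")
    rb1, rb2, ion, idx = m.groups()
    ring_bonds = (int(rb1), int(rb2)) if rb1 is not None else None
    if ion in RING_IONS and ring_bonds is None:
        raise FragmentError(f"{ion} ions require ring-bond superscripts, got {text!r}")
    if ion in GLYCOSIDIC_IONS and ring_bonds is not None:
        raise FragmentError(f"{ion} ions carry no ring-bond numbers, got {text!r}")
    return ion, int(idx), ring_bonds


def edges_from_reducing_end(g: GlycanGraph) -> list[tuple[int, int]]:
    """Edges numbered from the reducing end along the canonical
    serialization: edge 1 is the rightmost linkage token in the
    serialized string, counting leftward."""
    order: list[tuple[int, int]] = []

    def walk(node: int) -> None:
        for child, _ in ordered_children(g, node):
            walk(child)
            order.append((child, node))

    walk(g.root)
    return list(reversed(order))


def parse_fragment_spec(g: GlycanGraph, spec: str) -> FragmentAnnotation:
    """Parse the batch/CLI syntax ``LABEL@edge:N`` or ``LABEL@node:N``.

    Edges count from the reducing end (1-based) along the canonical
    serialization; nodes are residue indices in the same order (1 =
    reducing end).
    """
    try:
        label, target = spec.split("@")
    except ValueError:
        raise FragmentError(
            f"fragment spec {spec!r} must look like 'Y1@edge:1' or '2,4A2@node:1'"
        ) from None
    ion, idx, ring = validate_fragment_label(label)
    kind, _, num = target.partition(":")
    if not num.isdigit():
        raise FragmentError(f"bad target {target!r} in {spec!r}")
    n = int(num)
    if kind == "edge":
        edges = edges_from_reducing_end(g)
        if not 1 <= n <= len(edges):
            raise FragmentError(f"edge {n} out of range (glycan has {len(edges)} bonds)")
        return FragmentAnnotation(ion, idx, ring, edge=edges[n - 1])
    if kind == "node":
        nodes = [g.root] + [c for c, _ in edges_from_reducing_end(g)]
        if not 1 <= n <= len(nodes):
            raise FragmentError(f"node {n} out of range (glycan has {len(nodes)} residues)")
        return FragmentAnnotation(ion, idx, ring, node=nodes[n - 1])
    raise FragmentError(f"unknown target kind {kind!r} in {spec!r}")


#: Hook length in grid units.
HOOK_LENGTH = 0.3


def apply_fragments(
    doc: SvgDocument,
    g: GlycanGraph,
    anns: list[FragmentAnnotation],
) -> SvgDocument:
    """Overlay cleavage marks onto a rendered document.

    Glycosidic ions get a stroke perpendicular to the bond with a hook
    toward the retained side (reducing end for Y/Z, non-reducing end for
    B/C) and the serialized label on the hook side; ring ions get a
    diagonal stroke across the residue symbol with the superscripted
    label above it.  The base drawing is untouched; each annotation adds
    exactly one ``<g class="fragment">`` group.
    """
    spacing = doc.spacing
    r = doc.symbol_radius
    stroke_w = max(1.2, spacing * 0.045)
    for ann in anns:
        grp = doc.group("fragment", **{"data-label": ann.label()})
        if ann.ion_type in GLYCOSIDIC_IONS:
            child, parent = ann.edge
            if g.parent_of.get(child, (None,))[0] != parent:
                raise FragmentError(
                    f"fragment {ann.label()} targets missing bond {child}->{parent}"
                )
            cxy = doc.node_centers[child]
            pxy = doc.node_centers[parent]
            mx, my = (cxy[0] + pxy[0]) / 2, (cxy[1] + pxy[1]) / 2
            dx, dy = pxy[0] - cxy[0], pxy[1] - cxy[1]
            norm = math.hypot(dx, dy) or 1.0
            ux, uy = dx / norm, dy / norm          # toward parent (reducing end)
            nx, ny = -uy, ux                        # stroke direction
            half = spacing * 0.32
            x1, y1 = mx - nx * half, my - ny * half
            x2, y2 = mx + nx * half, my + ny * half
            # hook at the upper stroke end, toward the retained side
            top = (x1, y1) if y1 <= y2 else (x2, y2)
            sign = 1.0 if ann.ion_type in REDUCING_SIDE_IONS else -1.0
            hx, hy = ux * sign * HOOK_LENGTH * spacing, uy * sign * HOOK_LENGTH * spacing
            doc.line(grp, x1, y1, x2, y2, stroke_w, cls="cleavage")
            doc.line(grp, top[0], top[1], top[0] + hx, top[1] + hy, stroke_w,
                     cls="cleavage-hook")
            prefix = f"{ann.ring_bonds[0]},{ann.ring_bonds[1]}" if ann.ring_bonds else ""
            doc.text(grp, top[0] + hx, top[1] + hy - spacing * 0.18,
                     f"{ann.ion_type}{ann.index}", spacing * 0.26,
                     cls="fragment-label", sup_prefix=prefix)
        else:
            if ann.node not in g.nodes:
                raise FragmentError(
                    f"fragment {ann.label()} targets missing residue {ann.node}"
                )
            cx, cy = doc.node_centers[ann.node]
            d = r * 1.6
            doc.line(grp, cx - d * 0.7, cy + d, cx + d * 0.7, cy - d, stroke_w,
                     cls="cleavage")
            doc.text(grp, cx + d * 0.7, cy - d - spacing * 0.18,
                     f"{ann.ion_type}{ann.index}", spacing * 0.26,
                     cls="fragment-label",
                     sup_prefix=f"{ann.ring_bonds[0]},{ann.ring_bonds[1]}")
    return doc
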