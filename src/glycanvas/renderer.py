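"""Render laid-out glycans to SVG, with PDF export.

The renderer keeps a flat *display list* of geometric primitives
(circles, polygons, lines, text) alongside the SVG element tree it
builds.  The SVG backend serializes the tree directly (byte-stable for
fixed input); the PDF backend replays the same display list through
matplotlib's vector PDF writer, so both formats come from one geometry
pass.

Canvas conventions: one grid unit maps to ``unit_scale`` canvas units
(60% of that in compact mode), symbols have a diameter of half a grid
unit, the reducing end is drawn rightmost (bottom in portrait mode), and
z-order is bonds < symbols < text.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

from .errors import ExportError
from .layout import FloatingLayout, LayoutOptions, LayoutResult, layout_glycan
from .model import GlycanGraph
from .snfg_catalog import SymbolSpec, modification_labels, symbol_for

ANOMER_GLYPH = {"a": "α", "b": "β", "?": "?"}


@dataclass(frozen=True)
class DrawingOptions:
    """User-facing drawing switches.

    ``compact`` shortens bonds to 60% and implies ``show_linkage=False``;
    ``unit_scale`` is the canvas length of one grid unit.
    """

    show_linkage: bool = True
    compact: bool = False
    vertical: bool = False
    unit_scale: float = 50.0
    perpendicular_below: bool = True

    def effective_show_linkage(self) -> bool:
        return self.show_linkage and not self.compact

    def spacing(self) -> float:
        return self.unit_scale * (0.6 if self.compact else 1.0)


def _fmt(v: float) -> str:
    return f"{v:.2f}"


def _rgb(color: tuple[int, int, int]) -> str:
    return f"rgb({color[0]},{color[1]},{color[2]})"


class SvgDocument:
    """An SVG element tree plus the display list that produced it.

    The document also records the grid-to-canvas transform and per-node
    symbol centers so overlays (fragment marks) can be positioned after
    the fact.
    """

    def __init__(self, width: float, height: float):
        self.width = width
        self.height = height
        self.root = ET.Element(
            "svg",
            {
                "xmlns": "http://www.w3.org/2000/svg",
                "width": _fmt(width),
                "height": _fmt(height),
                "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
            },
        )
        self.display_list: list[dict] = []
        self.node_centers: dict[int, tuple[float, float]] = {}
        self.symbol_radius: float = 0.0
        self.spacing: float = 0.0

    # -- primitive emission (records to both trees) --------------------

    def group(self, cls: str, **attrs: str) -> ET.Element:
        g = ET.SubElement(self.root, "g", {"class": cls, **attrs})
        return g

    def line(self, g: ET.Element, x1, y1, x2, y2, width: float, cls: str = "") -> None:
        attrs = {
            "x1": _fmt(x1), "y1": _fmt(y1), "x2": _fmt(x2), "y2": _fmt(y2),
            "stroke": "black", "stroke-width": _fmt(width),
            "stroke-linecap": "round",
        }
        if cls:
            attrs["class"] = cls
        ET.SubElement(g, "line", attrs)
        self.display_list.append(
            {"kind": "line", "x1": x1, "y1": y1, "x2": x2, "y2": y2, "width": width}
        )

    def circle(self, g: ET.Element, cx, cy, r, fill: str, stroke_w: float) -> None:
        ET.SubElement(g, "circle", {
            "cx": _fmt(cx), "cy": _fmt(cy), "r": _fmt(r),
            "fill": fill, "stroke": "black", "stroke-width": _fmt(stroke_w),
        })
        self.display_list.append(
            {"kind": "circle", "cx": cx, "cy": cy, "r": r, "fill": fill,
             "stroke_w": stroke_w}
        )

    def polygon(self, g: ET.Element, points, fill: str, stroke_w: float,
                stroke: str = "black") -> None:
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points)
        ET.SubElement(g, "polygon", {
            "points": pts, "fill": fill, "stroke": stroke,
            "stroke-width": _fmt(stroke_w), "stroke-linejoin": "round",
        })
        self.display_list.append(
            {"kind": "polygon", "points": list(points), "fill": fill,
             "stroke_w": stroke_w, "stroke": stroke}
        )

    def text(self, g: ET.Element, x, y, content: str, size: float,
             cls: str = "", italic: bool = False, sup_prefix: str = "") -> None:
        attrs = {
            "x": _fmt(x), "y": _fmt(y), "font-size": _fmt(size),
            "font-family": "sans-serif", "text-anchor": "middle",
            "dominant-baseline": "central", "fill": "black",
        }
        if italic:
            attrs["font-style"] = "italic"
        if cls:
            attrs["class"] = cls
        el = ET.SubElement(g, "text", attrs)
        if sup_prefix:
            sup = ET.SubElement(el, "tspan", {
                "baseline-shift": "super", "font-size": _fmt(size * 0.65),
            })
            sup.text = sup_prefix
            tail = ET.SubElement(el, "tspan")
            tail.text = content
        else:
            el.text = content
        self.display_list.append(
            {"kind": "text", "x": x, "y": y, "content": content, "size": size,
             "italic": italic, "sup_prefix": sup_prefix}
        )

    # -- serialization -------------------------------------------------

    def tostring(self) -> str:
        return (
            '<?xml version="1.0" encoding="utf-8"?>\n'
            + ET.tostring(self.root, encoding="unicode")
        )

    def count(self, cls: str) -> int:
        return sum(
            1 for el in self.root.iter() if el.get("class", "").split() == [cls]
        )


# ---------------------------------------------------------------------------
# Symbol geometry

def _star_points(cx: float, cy: float, r_out: float) -> list[tuple[float, float]]:
    r_in = r_out * 0.42
    pts = []
    for k in range(10):
        r = r_out if k % 2 == 0 else r_in
        ang = -math.pi / 2 + k * math.pi / 5
        pts.append((cx + r * math.cos(ang), cy + r * math.sin(ang)))
    return pts


def _pentagon_points(cx: float, cy: float, r: float) -> list[tuple[float, float]]:
    return [
        (cx + r * math.cos(-math.pi / 2 + k * 2 * math.pi / 5),
         cy + r * math.sin(-math.pi / 2 + k * 2 * math.pi / 5))
        for k in range(5)
    ]


def _draw_symbol(doc: SvgDocument, g: ET.Element, cx: float, cy: float,
                 r: float, spec: SymbolSpec, stroke_w: float) -> None:
    fill = _rgb(spec.fill_color)
    white = "rgb(255,255,255)"
    shape = spec.shape_class
    if shape == "circle":
        doc.circle(g, cx, cy, r, fill, stroke_w)
    elif shape == "square":
        h = r * 0.9
        doc.polygon(g, [(cx - h, cy - h), (cx + h, cy - h),
                        (cx + h, cy + h), (cx - h, cy + h)], fill, stroke_w)
    elif shape == "crossed_square":
        h = r * 0.9
        sq = [(cx - h, cy - h), (cx + h, cy - h), (cx + h, cy + h), (cx - h, cy + h)]
        doc.polygon(g, sq, white, stroke_w)
        doc.polygon(g, [(cx - h, cy - h), (cx + h, cy + h), (cx - h, cy + h)],
                    fill, stroke_w)
        doc.line(g, cx - h, cy - h, cx + h, cy + h, stroke_w)
    elif shape == "divided_diamond":
        d = r * 1.25
        doc.polygon(g, [(cx, cy - d), (cx + d, cy), (cx, cy + d), (cx - d, cy)],
                    white, stroke_w)
        doc.polygon(g, [(cx, cy - d), (cx + d, cy), (cx - d, cy)], fill, stroke_w)
        doc.line(g, cx - d, cy, cx + d, cy, stroke_w)
    elif shape == "triangle":
        doc.polygon(g, [(cx, cy - r * 1.1), (cx + r, cy + r * 0.75),
                        (cx - r, cy + r * 0.75)], fill, stroke_w)
    elif shape == "divided_triangle":
        tri = [(cx, cy - r * 1.1), (cx + r, cy + r * 0.75), (cx - r, cy + r * 0.75)]
        doc.polygon(g, tri, white, stroke_w)
        doc.polygon(g, [(cx, cy - r * 1.1), (cx - r, cy + r * 0.75),
                        (cx, cy + r * 0.75)], fill, stroke_w)
        doc.line(g, cx, cy - r * 1.1, cx, cy + r * 0.75, stroke_w)
    elif shape == "flat_rectangle":
        w, h = r * 1.25, r * 0.6
        doc.polygon(g, [(cx - w, cy - h), (cx + w, cy - h),
                        (cx + w, cy + h), (cx - w, cy + h)], fill, stroke_w)
    elif shape == "star":
        doc.polygon(g, _star_points(cx, cy, r * 1.25), fill, stroke_w)
    elif shape == "diamond":
        d = r * 1.25
        doc.polygon(g, [(cx, cy - d), (cx + d, cy), (cx, cy + d), (cx - d, cy)],
                    fill, stroke_w)
    elif shape == "flat_hexagon":
        w, h = r * 1.25, r * 0.7
        doc.polygon(g, [(cx - w, cy), (cx - w * 0.5, cy - h), (cx + w * 0.5, cy - h),
                        (cx + w, cy), (cx + w * 0.5, cy + h), (cx - w * 0.5, cy + h)],
                    fill, stroke_w)
    elif shape == "pentagon":
        doc.polygon(g, _pentagon_points(cx, cy, r * 1.15), fill, stroke_w)
    else:  # pragma: no cover - catalog data guarantees a known shape
        raise ExportError(f"unknown shape class {shape!r}")


# ---------------------------------------------------------------------------
# Rendering

def render(g: GlycanGraph, opts: DrawingOptions | None = None) -> SvgDocument:
    """Render a glycan to an SVG document.

    One ``<g class="residue">`` per residue (symbol, inner label,
    modification text), one ``<g class="bond">`` per linkage (line plus
    optional anomer/position labels), plus groups for floating
    components and the ambiguity bracket.  Deterministic: fixed input
    and options give byte-identical output.

    Raises :class:`~glycanvas.errors.NonSNFGResidueError` when a residue
    has no catalog symbol — the only drawing failure mode.
    """
    opts = opts or DrawingOptions()
    layout = layout_glycan(
        g,
        LayoutOptions(
            vertical=opts.vertical,
            compact=opts.compact,
            perpendicular_below=opts.perpendicular_below,
        ),
    )
    # resolve all symbols up front so failures precede any drawing
    specs = {n: symbol_for(res) for n, res in g.nodes.items()}
    float_specs = [
        {n: symbol_for(res) for n, res in fl.component.nodes.items()}
        for fl in layout.floating_layouts
    ]

    spacing = opts.spacing()
    margin = opts.unit_scale * 0.8
    all_pos = list(layout.positions.values())
    for fl in layout.floating_layouts:
        all_pos.extend(fl.positions.values())
    xs = [float(x) for x, _ in all_pos]
    ys = [float(y) for _, y in all_pos]
    min_x, max_x = min(xs), max(xs)
    min_y, max_y = min(ys), max(ys)

    width = (max_x - min_x) * spacing + 2 * margin
    height = (max_y - min_y) * spacing + 2 * margin
    doc = SvgDocument(width, height)
    doc.spacing = spacing
    doc.symbol_radius = 0.25 * spacing

    def to_canvas(pos: tuple[Fraction, Fraction]) -> tuple[float, float]:
        x, y = float(pos[0]), float(pos[1])
        return (margin + (max_x - x) * spacing, margin + (max_y - y) * spacing)

    _render_component(doc, g, layout.positions, specs, opts, to_canvas,
                      cls_prefix="")
    doc.node_centers = {
        n: to_canvas(p) for n, p in layout.positions.items()
    }

    if layout.floating_layouts:
        for fl, fspecs in zip(layout.floating_layouts, float_specs):
            _render_component(doc, fl.component, fl.positions, fspecs, opts,
                              to_canvas, cls_prefix="floating-")
        _draw_ambiguity_bracket(doc, layout, to_canvas, spacing)
    return doc


def _render_component(doc, g, positions, specs, opts, to_canvas, cls_prefix):
    spacing = doc.spacing
    r = doc.symbol_radius
    stroke_w = max(1.0, spacing * 0.035)
    show_linkage = opts.effective_show_linkage()

    # bonds first: lines sit under the symbols
    for child, (parent, link) in g.parent_of.items():
        cx, cy = to_canvas(positions[child])
        px, py = to_canvas(positions[parent])
        grp = doc.group(cls_prefix + "bond", **{"data-child": str(child)})
        doc.line(grp, cx, cy, px, py, stroke_w)
        if show_linkage:
            dx, dy = px - cx, py - cy
            norm = math.hypot(dx, dy) or 1.0
            ox, oy = -dy / norm * spacing * 0.14, dx / norm * spacing * 0.14
            doc.text(grp, cx + dx / 3 + ox, cy + dy / 3 + oy,
                     ANOMER_GLYPH[link.anomer], spacing * 0.22, cls="linkage")
            doc.text(grp, cx + 2 * dx / 3 + ox, cy + 2 * dy / 3 + oy,
                     link.parent_pos, spacing * 0.22, cls="linkage")

    for node, res in g.nodes.items():
        cx, cy = to_canvas(positions[node])
        grp = doc.group(cls_prefix + "residue", **{"data-node": str(node),
                                                   "data-name": res.base_name})
        spec = specs[node]
        _draw_symbol(doc, grp, cx, cy, r, spec, stroke_w)
        if spec.inner_label:
            doc.text(grp, cx, cy, spec.inner_label, r * 1.1, cls="inner-label",
                     italic=spec.inner_label_italic)
        mods = modification_labels(res)
        if mods:
            doc.text(grp, cx, cy - r - spacing * 0.18,
                     " ".join(m.text for m in mods), spacing * 0.22,
                     cls="modification")


def _draw_ambiguity_bracket(doc, layout, to_canvas, spacing):
    """A right curly brace between the floating band and the main glycan."""
    pts = [p for fl in layout.floating_layouts for p in fl.positions.values()]
    main = layout.positions.values()
    if layout.orientation == "vertical":
        # floats sit above the main structure after transposition
        edge = max(y for _, y in main)
        band = min(y for _, y in pts)
        gx = (min(x for x, _ in pts) + max(x for x, _ in pts)) / 2
        gy = (edge + band) / 2
    else:
        edge = max(x for x, _ in main)
        band = min(x for x, _ in pts)
        gx = (edge + band) / 2
        gy = (min(y for _, y in pts) + max(y for _, y in pts)) / 2
    cx, cy = to_canvas((gx, gy))
    grp = doc.group("ambiguity-bracket")
    doc.text(grp, cx, cy, "}", spacing * 1.4, cls="bracket-glyph")


# ---------------------------------------------------------------------------
# Export

SUPPORTED_EXTENSIONS = (".svg", ".pdf")


def export(doc: SvgDocument, path: str | Path) -> Path:
    """Write a document to ``.svg`` (verbatim) or ``.pdf`` (vector).

    Extension dispatch is case-insensitive; anything else raises
    :class:`~glycanvas.errors.ExportError`.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".svg":
        path.write_text(doc.tostring(), encoding="utf-8")
    elif ext == ".pdf":
        _export_pdf(doc, path)
    else:
        raise ExportError(
            f"unsupported extension {path.suffix!r}; supported: "
            + ", ".join(SUPPORTED_EXTENSIONS)
        )
    return path


def _export_pdf(doc: SvgDocument, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle, Polygon

    fig = plt.figure(figsize=(doc.width / 72, doc.height / 72), dpi=72)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, doc.width)
    ax.set_ylim(doc.height, 0)  # canvas y grows downward
    ax.axis("off")
    for prim in doc.display_list:
        kind = prim["kind"]
        if kind == "line":
            ax.plot([prim["x1"], prim["x2"]], [prim["y1"], prim["y2"]],
                    color="black", linewidth=prim["width"],
                    solid_capstyle="round", zorder=1)
        elif kind == "circle":
            ax.add_patch(Circle((prim["cx"], prim["cy"]), prim["r"],
                                facecolor=_css_to_mpl(prim["fill"]),
                                edgecolor="black",
                                linewidth=prim["stroke_w"], zorder=2))
        elif kind == "polygon":
            ax.add_patch(Polygon(prim["points"], closed=True,
                                 facecolor=_css_to_mpl(prim["fill"]),
                                 edgecolor=prim.get("stroke", "black"),
                                 linewidth=prim["stroke_w"], zorder=2))
        elif kind == "text":
            content = prim["sup_prefix"] + prim["content"] if prim["sup_prefix"] \
                else prim["content"]
            ax.text(prim["x"], prim["y"], content,
                    fontsize=prim["size"] * 0.75,  # px -> pt
                    fontstyle="italic" if prim["italic"] else "normal",
                    ha="center", va="center", zorder=3)
    fig.savefig(path, format="pdf")
    plt.close(fig)


def _css_to_mpl(color: str):
    if color.startswith("rgb("):
        r, g, b = (int(c) for c in color[4:-1].split(","))
        return (r / 255, g / 255, b / 255)
    return color
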