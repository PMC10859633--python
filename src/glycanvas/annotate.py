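"""Replace text labels in existing SVG figures with glycan drawings.

Plotting libraries emit axis tick labels, legend entries and point
labels as ``<text>`` elements.  :func:`annotate_figure` walks an SVG
document, finds text whose (tspan-concatenated, whitespace-trimmed)
content matches a mapped label, removes the text and inserts a rendered
glycan group centered on the text anchor, honoring any rotation on the
original element and an optional per-label scale factor.

matplotlib note: set ``plt.rcParams["svg.fonttype"] = "none"`` before
saving — the default renders text as paths, leaving no ``<text>``
elements to match.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from lxml import etree

from .errors import AnnotationError, GlycanvasError
from .nomenclature import canonicalize_iupac, parse_glycan
from .renderer import DrawingOptions, render

SVG_NS = "http://www.w3.org/2000/svg"


@dataclass
class AnnotationJob:
    """One annotation pass over an SVG document.

    ``label_map`` maps exact text content to glycan strings, or the
    string ``"auto"`` to treat every text node that canonicalizes to a
    parseable glycan as its own key.  ``scale_map`` scales individual
    inserted drawings (default 1.0); ``anchor_offset`` shifts every
    insertion in canvas units.  ``base_unit`` is the grid unit size of
    inserted drawings before scaling.
    """

    source: str | bytes
    label_map: dict[str, str] | str
    scale_map: dict[str, float] = field(default_factory=dict)
    anchor_offset: tuple[float, float] = (0.0, 0.0)
    base_unit: float = 16.0


def _text_content(el: etree._Element) -> str:
    return "".join(el.itertext()).strip()


def _text_anchor(el: etree._Element) -> tuple[float, float]:
    """Anchor point of a text element: its own x/y or the first tspan's."""
    for candidate in [el, *el.iterchildren(f"{{{SVG_NS}}}tspan"), *el.iterchildren("tspan")]:
        x, y = candidate.get("x"), candidate.get("y")
        if x is not None and y is not None:
            return float(x.split()[0]), float(y.split()[0])
    return 0.0, 0.0


_ROTATE_RE = re.compile(r"rotate\(\s*(-?[0-9.]+)")


def _to_ns_tree(el, ns: str | None) -> etree._Element:
    """Deep-convert a stdlib ElementTree node into an lxml node in the
    target document's namespace."""
    tag = el.tag if ns is None else f"{{{ns}}}{el.tag}"
    out = etree.Element(tag)
    for k, v in el.attrib.items():
        if k != "xmlns":
            out.set(k, v)
    out.text = el.text
    out.tail = el.tail
    for child in el:
        out.append(_to_ns_tree(child, ns))
    return out


def _resolve_map(job: AnnotationJob, texts: list[str]) -> dict[str, str]:
    if job.label_map != "auto":
        return dict(job.label_map)
    resolved = {}
    for t in texts:
        try:
            canonical = canonicalize_iupac(t)
            g = parse_glycan(canonical)
        except GlycanvasError:
            continue
        # arbitrary words tokenize as one unknown residue; only treat
        # text as a glycan when every residue is catalog-resolvable
        nodes = list(g.nodes.values()) + [
            r for comp in g.floating for r in comp.nodes.values()
        ]
        if all(r.in_catalog for r in nodes):
            resolved[t] = canonical
    return resolved


def annotate_figure(job: AnnotationJob) -> bytes:
    """Run one annotation pass; returns the modified SVG as bytes.

    Every matched text element is replaced in place (same parent, same
    index) by a ``<g class="glycan-annotation">`` holding the rendered
    glycan, translated so the drawing's bounding-box center sits on the
    text anchor.  Unmatched elements are preserved byte-for-byte; a pass
    with no matches warns and returns the source unchanged, which makes
    the operation idempotent.
    """
    src = job.source.encode() if isinstance(job.source, str) else job.source
    try:
        root = etree.fromstring(src)
    except etree.XMLSyntaxError as exc:
        raise AnnotationError(f"source is not well-formed SVG: {exc}") from exc
    ns = root.nsmap.get(None)
    text_tag = f"{{{ns}}}text" if ns else "text"
    texts = list(root.iter(text_tag))
    label_map = _resolve_map(job, [_text_content(t) for t in texts])

    matched = 0
    for el in texts:
        content = _text_content(el)
        if content not in label_map:
            continue
        try:
            glycan = parse_glycan(canonicalize_iupac(label_map[content]))
        except GlycanvasError as exc:
            raise AnnotationError(
                f"glycan for label {content!r} does not parse: {exc}"
            ) from exc
        doc = render(glycan, DrawingOptions(unit_scale=job.base_unit,
                                            show_linkage=False))
        scale = job.scale_map.get(content, 1.0)
        if scale <= 0:
            raise AnnotationError(f"scale for label {content!r} must be > 0")
        ax, ay = _text_anchor(el)
        ox, oy = job.anchor_offset
        transform = (
            f"translate({ax + ox:.2f} {ay + oy:.2f})"
        )
        rot = _ROTATE_RE.search(el.get("transform") or "")
        if rot:
            transform += f" rotate({rot.group(1)})"
        transform += (
            f" scale({scale:.4f})"
            f" translate({-doc.width / 2:.2f} {-doc.height / 2:.2f})"
        )
        grp = etree.Element(f"{{{ns}}}g" if ns else "g")
        grp.set("class", "glycan-annotation")
        grp.set("data-label", content)
        grp.set("transform", transform)
        for child in doc.root:
            grp.append(_to_ns_tree(child, ns))
        parent = el.getparent()
        parent.insert(parent.index(el), grp)
        grp.tail = el.tail
        parent.remove(el)
        matched += 1

    if matched == 0:
        warnings.warn("annotate_figure: no text labels matched; source unchanged",
                      stacklevel=2)
        return src
    return etree.tostring(root, xml_declaration=True, encoding="utf-8")
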