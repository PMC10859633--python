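"""glycanvas: SNFG-compliant glycan figures from IUPAC-condensed strings.

Typical use::

    from glycanvas import draw_glycan
    draw_glycan("Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc", "n_core.svg")
"""

from __future__ import annotations

from pathlib import Path

from .annotate import AnnotationJob, annotate_figure
from .corpus import CorpusSpec, fixture_set, generate_corpus
from .errors import GlycanvasError
from .fragments import FragmentAnnotation, apply_fragments, parse_fragment_spec
from .layout import LayoutOptions, LayoutResult, layout_glycan
from .nomenclature import (
    canonicalize_iupac,
    decompose,
    lookup_motif,
    parse_glycan,
    parse_input,
    serialize_glycan,
)
from .renderer import DrawingOptions, SvgDocument, export, render
from .snfg_catalog import modification_labels, symbol_for

__version__ = "0.1.0"

__all__ = [
    "AnnotationJob", "CorpusSpec", "DrawingOptions", "FragmentAnnotation",
    "GlycanvasError", "LayoutOptions", "LayoutResult", "SvgDocument",
    "annotate_figure", "apply_fragments", "canonicalize_iupac", "decompose",
    "draw_glycan", "export", "fixture_set", "generate_corpus", "layout_glycan",
    "lookup_motif", "modification_labels", "parse_fragment_spec", "parse_glycan",
    "parse_input", "render", "serialize_glycan", "symbol_for",
]


def draw_glycan(
    glycan: str,
    output: str | Path | None = None,
    *,
    show_linkage: bool = True,
    compact: bool = False,
    vertical: bool = False,
    unit_scale: float = 50.0,
) -> SvgDocument:
    """One-call convenience: parse (motif name or IUPAC-condensed),
    lay out, render, and optionally export to ``.svg``/``.pdf``."""
    doc = render(
        parse_input(glycan),
        DrawingOptions(show_linkage=show_linkage, compact=compact,
                       vertical=vertical, unit_scale=unit_scale),
    )
    if output is not None:
        export(doc, output)
    return doc
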