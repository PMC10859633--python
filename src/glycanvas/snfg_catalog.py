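"""SNFG symbol catalog: residue base names -> shapes, colors, inner labels.

The Symbol Nomenclature for Glycans maps each monosaccharide to a colored
geometric symbol: the shape encodes the structural family (circle =
hexose, square = HexNAc, triangle = deoxyhexose, diamond = nonulosonic
acid, ...) and the color the parent stereochemistry (blue = glucose
family, green = mannose, yellow = galactose, ...).  The mapping is
shipped as a plain-text data table, not hard-coded in logic, so the
catalog can be audited and extended row by row.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .errors import NonSNFGResidueError
from .model import Monosaccharide, position_rank

#: Shape classes in the catalog, in SNFG family order.
SHAPE_CLASSES = (
    "circle",
    "square",
    "crossed_square",
    "divided_diamond",
    "triangle",
    "divided_triangle",
    "flat_rectangle",
    "star",
    "diamond",
    "flat_hexagon",
    "pentagon",
)


@dataclass(frozen=True)
class CatalogEntry:
    """One row of the catalog data file."""

    name: str
    family: str
    shape: str
    color_name: str
    rgb: tuple[int, int, int]
    default_enantiomer: str | None


@dataclass(frozen=True)
class SymbolSpec:
    """Everything the renderer needs to draw one residue symbol.

    Divided shapes (hexosamines, hexuronates, deoxyhexNAcs) use
    ``secondary_color`` (white) for the uncolored half.  ``inner_label``
    is an italic ``f`` for furanoses or a ``D``/``L`` enantiomer marker
    shown only when the residue deviates from its SNFG default.
    """

    shape_class: str
    fill_color: tuple[int, int, int]
    color_name: str
    secondary_color: tuple[int, int, int] | None
    inner_label: str | None
    inner_label_italic: bool


@dataclass(frozen=True)
class ModificationLabel:
    """Text shown above a symbol, e.g. ``6S`` for 6-O-sulfation."""

    text: str


_DIVIDED_SHAPES = frozenset({"crossed_square", "divided_diamond", "divided_triangle"})
_WHITE = (255, 255, 255)


def _load_catalog() -> dict[str, CatalogEntry]:
    entries: dict[str, CatalogEntry] = {}
    text = resources.files("glycanvas.data").joinpath("snfg_catalog.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, family, shape, color, r, g, b, enant = line.split("\t")
        entries[name] = CatalogEntry(
            name=name,
            family=family,
            shape=shape,
            color_name=color,
            rgb=(int(r), int(g), int(b)),
            default_enantiomer=None if enant == "-" else enant,
        )
    return entries


CATALOG: dict[str, CatalogEntry] = _load_catalog()

#: Base names ordered longest-first for greedy residue-token matching.
BASE_NAMES_BY_LENGTH: list[str] = sorted(CATALOG, key=len, reverse=True)


def is_catalog_residue(base_name: str) -> bool:
    return base_name in CATALOG


def symbol_for(residue: Monosaccharide) -> SymbolSpec:
    """Resolve a residue to its SNFG symbol.

    Raises :class:`NonSNFGResidueError` for base names absent from the
    catalog — the only drawing failure mode the renderer permits.
    """
    entry = CATALOG.get(residue.base_name)
    if entry is None or not residue.in_catalog:
        raise NonSNFGResidueError(residue.base_name)
    inner = None
    italic = False
    if residue.ring_form == "f":
        inner, italic = "f", True
    elif residue.enantiomer and residue.enantiomer != entry.default_enantiomer:
        inner = residue.enantiomer
    return SymbolSpec(
        shape_class=entry.shape,
        fill_color=entry.rgb,
        color_name=entry.color_name,
        secondary_color=_WHITE if entry.shape in _DIVIDED_SHAPES else None,
        inner_label=inner,
        inner_label_italic=italic,
    )


def modification_labels(residue: Monosaccharide) -> list[ModificationLabel]:
    """Per-modification text labels, ordered by carbon position.

    Each label is the modified carbon number (or the linking atom when
    the position is unknown) followed by the substituent abbreviation,
    e.g. ``6S``, ``9Ac``, ``3Me``.
    """
    mods = sorted(residue.modifications, key=lambda m: (position_rank(m[0]), m[1]))
    labels = [ModificationLabel(f"{pos}{sub}") for pos, sub in mods]
    if residue.alditol:
        labels.append(ModificationLabel("-ol"))
    return labels
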