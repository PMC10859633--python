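"""Exception hierarchy.

All user-facing failures derive from :class:`GlycanvasError` so the CLI can
catch one type and print a one-line diagnostic.
"""

from __future__ import annotations


class GlycanvasError(Exception):
    """Base class for all errors raised by glycanvas."""


class GlycanParseError(GlycanvasError):
    """A glycan string could not be parsed.

    Parameters
    ----------
    message:
        Human-readable description naming the offending token.
    offset:
        0-based character offset of the offending token in the
        (normalized) input string, or ``None`` when not applicable.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


class StructureError(GlycanvasError):
    """A glycan graph violates its tree invariants."""


class NonSNFGResidueError(GlycanvasError):
    """A residue has no symbol in the SNFG catalog.

    This is the only permitted drawing failure mode: parsing and layout
    accept arbitrary residue names, rendering requires a catalog entry.
    """

    def __init__(self, base_name: str):
        self.base_name = base_name
        super().__init__(
            f"residue {base_name!r} is not a catalog-defined SNFG monosaccharide"
        )


class MotifLookupError(GlycanvasError):
    """An unknown motif name, with near-match suggestions."""

    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown motif {name!r}{hint}")


class FragmentError(GlycanvasError):
    """A fragment annotation is malformed or targets a missing bond/residue."""


class AnnotationError(GlycanvasError):
    """Figure annotation failed (e.g. a mapped glycan string does not parse)."""


class ExportError(GlycanvasError):
    """Unsupported output format or unwritable path."""
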