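"""IUPAC-condensed glycan nomenclature: tokenize, canonicalize, parse,
serialize, decompose.

The grammar, informally::

    glycan   := floating* chain
    floating := "{" chain linkage "}"          # attachment point unknown
    chain    := item* residue                  # rightmost residue = reducing end
    item     := residue linkage | "[" chain linkage "]"
    linkage  := "(" anomer pos "-" pos ")"     # e.g. (b1-4); "?" for unknown
    residue  := ["D-"|"L-"] base ["f"] modification* ["-ol"]

A bracketed group attaches to the residue written immediately to its
right.  Branch order is canonical: longest branch first, ties broken by
lowest parent linkage position (unknown last), then alphabetically by
serialization — so equal strings always serialize identically.

``canonicalize_iupac`` additionally accepts common dialect spellings
(Greek-letter anomers, CFG-style linkages without parentheses,
parentheses used as branch delimiters, typographic dashes/arrows) and
rewrites them into the canonical form above.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from difflib import get_close_matches
from importlib import resources

from .errors import GlycanParseError, MotifLookupError, StructureError
from .model import (
    PERPENDICULAR_RESIDUES,
    Branch,
    Decomposition,
    GlycanGraph,
    Linkage,
    Monosaccharide,
    position_rank,
)
from .snfg_catalog import BASE_NAMES_BY_LENGTH

# ---------------------------------------------------------------------------
# Tokenizer

_LINKAGE_RE = re.compile(r"\(([ab?])([1-9?])-([1-9?])\)")
_LINKAGE_CONTENT_RE = re.compile(r"^[ab?][1-9?]-[1-9?]$")
# residue token decorations after the base name: furanose flag, then
# position+substituent modifications (position "O" = unknown linking atom),
# then an optional alditol (open-chain reducing end) marker.
_DECORATION_RE = re.compile(r"^(f)?((?:[1-9O?][A-Z][a-z]{0,2})*)(-ol)?$")
_MODIFICATION_RE = re.compile(r"([1-9O?])([A-Z][a-z]{0,2})")
_STRUCTURAL = "[]{}()"


@dataclass(frozen=True)
class _Token:
    kind: str  # 'res' | 'link' | '[' | ']' | '{' | '}'
    text: str
    offset: int
    linkage: Linkage | None = None


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch == "(":
            m = _LINKAGE_RE.match(text, i)
            if not m:
                end = text.find(")", i)
                bad = text[i : end + 1] if end != -1 else text[i:]
                raise GlycanParseError(f"malformed linkage token {bad!r}", i)
            tokens.append(
                _Token("link", m.group(0), i, Linkage(m.group(1), m.group(2), m.group(3)))
            )
            i = m.end()
        elif ch in "[]{}":
            tokens.append(_Token(ch, ch, i))
            i += 1
        elif ch == ")":
            raise GlycanParseError("unbalanced ')'", i)
        else:
            j = i
            while j < n and text[j] not in _STRUCTURAL:
                j += 1
            tokens.append(_Token("res", text[i:j], i))
            i = j
    return tokens


# ---------------------------------------------------------------------------
# Residue tokens

def parse_residue_token(token: str, offset: int = 0) -> dict:
    """Split a residue token into base name, ring form, enantiomer and
    modifications.  Unrecognized base names are kept whole and flagged
    as outside the SNFG catalog (parsing succeeds; rendering will not).
    """
    if not token:
        raise GlycanParseError("empty residue token", offset)
    enantiomer = None
    body = token
    if body[:2] in ("D-", "L-"):
        enantiomer, body = body[0], body[2:]
    base = next((n for n in BASE_NAMES_BY_LENGTH if body.startswith(n)), None)
    fields = dict(
        base_name=token,
        ring_form="p",
        enantiomer=None,
        modifications=[],
        alditol=False,
        in_catalog=False,
    )
    if base is None:
        return fields
    rest = body[len(base) :]
    m = _DECORATION_RE.match(rest)
    if m is None:
        # catalog prefix but undecipherable tail ("Manose"): non-SNFG residue
        return fields
    mods = [(p, s) for p, s in _MODIFICATION_RE.findall(m.group(2) or "")]
    positions = [p for p, _ in mods]
    if len(set(positions)) != len(positions):
        raise GlycanParseError(f"duplicate modification position in {token!r}", offset)
    fields.update(
        base_name=base,
        ring_form="f" if m.group(1) else "p",
        enantiomer=enantiomer,
        modifications=mods,
        alditol=bool(m.group(3)),
        in_catalog=True,
    )
    return fields


# ---------------------------------------------------------------------------
# Parser

def parse_glycan(iupac: str) -> GlycanGraph:
    """Parse a canonical IUPAC-condensed string into a glycan tree.

    The rightmost residue becomes the reducing end (tree root); square
    brackets open branches attached to the residue to their right;
    curly-bracket prefixes become floating components.  Callers with
    dialect input should chain :func:`canonicalize_iupac` first.
    """
    if not iupac or not iupac.strip():
        raise GlycanParseError("empty glycan string", 0)
    tokens = _tokenize(iupac)
    graph = GlycanGraph()
    i = 0
    # leading floating components
    while i < len(tokens) and tokens[i].kind == "{":
        comp = GlycanGraph()
        root, link, i = _parse_bracket(tokens, i + 1, "}", comp, graph)
        comp.root = root
        comp.attachment = link
        graph.floating.append(comp)
    root, i = _parse_chain(tokens, i, graph, graph)
    if i != len(tokens):
        t = tokens[i]
        raise GlycanParseError(f"unexpected {t.text!r} after reducing end", t.offset)
    graph.root = root
    graph.validate()
    return graph


def _new_residue(target: GlycanGraph, ids: GlycanGraph, tok: _Token) -> int:
    fields = parse_residue_token(tok.text, tok.offset)
    node_id = ids._next_id
    ids._next_id += 1
    residue = Monosaccharide(node_id=node_id, **fields)
    target.add_node(residue)
    if target is not ids:
        target._next_id = ids._next_id
    return node_id


def _parse_chain(
    tokens: list[_Token], i: int, target: GlycanGraph, ids: GlycanGraph
) -> tuple[int, int]:
    """Parse ``item* residue`` starting at ``i``; return (chain root, next i)."""
    pending: list[tuple[int, Linkage]] = []
    while i < len(tokens):
        tok = tokens[i]
        if tok.kind == "[":
            sub_root, link, i = _parse_bracket(tokens, i + 1, "]", target, ids)
            pending.append((sub_root, link))
        elif tok.kind == "res":
            node = _new_residue(target, ids, tok)
            for child, link in pending:
                target.add_edge(child, node, link)
            pending = []
            if i + 1 < len(tokens) and tokens[i + 1].kind == "link":
                pending = [(node, tokens[i + 1].linkage)]
                i += 2
            else:
                return node, i + 1
        elif tok.kind == "{":
            raise GlycanParseError(
                "floating '{...}' components must prefix the glycan", tok.offset
            )
        else:
            raise GlycanParseError(f"unexpected {tok.text!r}", tok.offset)
    if pending:
        raise GlycanParseError("glycan ends with a dangling linkage", tokens[-1].offset)
    raise GlycanParseError("empty glycan string", 0)


def _parse_bracket(
    tokens: list[_Token], i: int, closing: str, target: GlycanGraph, ids: GlycanGraph
) -> tuple[int, Linkage, int]:
    """Parse the inside of ``[...]``/``{...}``: a chain ending in
    residue+linkage.  Returns (group root, its outgoing linkage, next i)."""
    open_offset = tokens[i - 1].offset
    pending: list[tuple[int, Linkage]] = []
    while i < len(tokens) and tokens[i].kind != closing:
        tok = tokens[i]
        if tok.kind == "[":
            sub_root, link, i = _parse_bracket(tokens, i + 1, "]", target, ids)
            pending.append((sub_root, link))
        elif tok.kind == "res":
            node = _new_residue(target, ids, tok)
            for child, link in pending:
                target.add_edge(child, node, link)
            if i + 1 < len(tokens) and tokens[i + 1].kind == "link":
                pending = [(node, tokens[i + 1].linkage)]
                i += 2
            else:
                raise GlycanParseError(
                    f"branch residue {tok.text!r} lacks a linkage before "
                    f"'{closing}'",
                    tok.offset,
                )
        else:
            raise GlycanParseError(f"unexpected {tok.text!r} in branch", tok.offset)
    if i >= len(tokens):
        raise GlycanParseError("unbalanced bracket", open_offset)
    if len(pending) != 1:
        raise GlycanParseError("empty branch", open_offset)
    root, link = pending[0]
    return root, link, i + 1


# ---------------------------------------------------------------------------
# Branch ordering and serialization

class _Ordering:
    """Canonical child ordering plus per-subtree length/serialization,
    computed once per graph in a bottom-up pass and cached on it."""

    def __init__(self, g: GlycanGraph):
        children: dict[int, list[tuple[int, Linkage]]] = {n: [] for n in g.nodes}
        for child, (parent, link) in g.parent_of.items():
            children[parent].append((child, link))
        self.order: dict[int, list[tuple[int, Linkage]]] = {}
        self.length: dict[int, int] = {}
        self.serial: dict[int, str] = {}
        # explicit stack: corpus structures can nest deeper than default
        # recursion limits when chains are long
        roots = [n for n in g.nodes if n not in g.parent_of]
        stack = [(n, False) for n in roots]
        while stack:
            node, ready = stack.pop()
            if not ready:
                stack.append((node, True))
                stack.extend((c, False) for c, _ in children[node])
                continue
            kids = sorted(
                children[node], key=lambda cl: self._key(g, cl[0], cl[1])
            )
            self.order[node] = kids
            self.length[node] = 1 + max(
                (self.length[c] for c, _ in kids), default=0
            )
            parts = []
            if kids:
                first, flink = kids[0]
                parts.append(self.serial[first] + flink.token())
                for child, link in kids[1:]:
                    parts.append("[" + self.serial[child] + link.token() + "]")
            parts.append(g.nodes[node].token())
            self.serial[node] = "".join(parts)

    def _key(self, g: GlycanGraph, child: int, link: Linkage) -> tuple:
        """Canonical branch order: longest > lowest parent linkage
        (unknown last) > alphabetical serialization.

        One convention-driven exception: a terminal perpendicular residue
        (Fuc/Xyl) sorts after in-chain residues of equal length, so it is
        always the bracketed decoration and never the drawn main chain —
        Gal(b1-4)[Fuc(a1-3)]GlcNAc, never Fuc(a1-3)[Gal(b1-4)]GlcNAc.
        """
        is_perp_leaf = (
            not self.order[child]
            and g.nodes[child].base_name in PERPENDICULAR_RESIDUES
        )
        return (
            -self.length[child],
            is_perp_leaf,
            position_rank(link.parent_pos),
            self.serial[child] + link.token(),
        )


def _ordering(g: GlycanGraph) -> _Ordering:
    cache = getattr(g, "_order_cache", None)
    if cache is None:
        cache = _Ordering(g)
        g._order_cache = cache
    return cache


def order_branches(
    g: GlycanGraph, siblings: list[tuple[int, Linkage]]
) -> list[tuple[int, Linkage]]:
    """Sort sibling subtrees at one attachment point into canonical order."""
    o = _ordering(g)
    return sorted(siblings, key=lambda cl: o._key(g, cl[0], cl[1]))


def ordered_children(g: GlycanGraph, node_id: int) -> list[tuple[int, Linkage]]:
    return _ordering(g).order[node_id]


def _serialize_subtree(g: GlycanGraph, node_id: int) -> str:
    return _ordering(g).serial[node_id]


def serialize_glycan(g: GlycanGraph) -> str:
    """Serialize a glycan tree back to canonical IUPAC-condensed text.

    Inverse of :func:`parse_glycan` on canonical input: the main-chain
    continuation is written inline, remaining branches bracketed, and
    floating components emitted as ordered ``{...}`` prefixes.
    """
    if g.root is None:
        raise StructureError("graph has no reducing end")
    g.validate()

    def float_key(comp: GlycanGraph) -> tuple:
        link = comp.attachment or Linkage()
        return (
            -comp.longest_path_len(comp.root),
            position_rank(link.parent_pos),
            _serialize_subtree(comp, comp.root) + link.token(),
        )

    prefix = "".join(
        "{" + _serialize_subtree(c, c.root) + (c.attachment or Linkage()).token() + "}"
        for c in sorted(g.floating, key=float_key)
    )
    return prefix + _serialize_subtree(g, g.root)


# ---------------------------------------------------------------------------
# Canonicalization of dialect input

_GREEK = {"α": "a", "β": "b", "Α": "a", "Β": "b"}
_DASHES = {"–": "-", "—": "-", "−": "-", "→": "-"}
_CFG_LINKAGE_RE = re.compile(r"(?<=[A-Za-z])([ab?])([1-9?])-([1-9?])(?=[A-Z\[\]{}(]|$)")


def _normalize_text(raw: str) -> str:
    text = "".join(raw.split())
    for src, dst in {**_GREEK, **_DASHES}.items():
        text = text.replace(src, dst)
    text = text.replace("->", "-")
    text = _convert_branch_parens(text)
    text = _CFG_LINKAGE_RE.sub(r"(\1\2-\3)", text)
    return text


def _convert_branch_parens(text: str) -> str:
    """Rewrite parentheses used as branch delimiters into square brackets.

    A parenthesized group whose content is a bare linkage (``(a1-3)``)
    is left alone; anything else, e.g. ``(Man(a1-6))`` in the dialect
    ``Mana1-3(Mana1-6)Manb1-4...``, is a branch.  Innermost pairs are
    classified first so nested mixtures resolve correctly.
    """
    chars = list(text)
    stack: list[int] = []
    for i, ch in enumerate(chars):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise GlycanParseError("unbalanced ')'", i)
            start = stack.pop()
            content = "".join(chars[start + 1 : i])
            if not _LINKAGE_CONTENT_RE.match(content):
                chars[start], chars[i] = "[", "]"
    if stack:
        raise GlycanParseError("unbalanced '('", stack[-1])
    return "".join(chars)


def canonicalize_iupac(raw: str) -> str:
    """Normalize a glycan string into canonical IUPAC-condensed form.

    Handles Greek-letter anomers, CFG-style linkages without
    parentheses, parenthesized branches, typographic dashes and arrows,
    and stray whitespace, then reparses and reserializes so branch order
    is canonical.  Idempotent: canonical input round-trips unchanged.
    """
    if not raw or not raw.strip():
        raise GlycanParseError("empty glycan string", 0)
    if ("=" in raw) or re.search(r"\)n\b|\]n\b|\)\d+$", raw):
        raise GlycanParseError(
            "repeating-unit syntax is not supported; expand the repeat explicitly", 0
        )
    return serialize_glycan(parse_glycan(_normalize_text(raw)))


# ---------------------------------------------------------------------------
# Decomposition into main chain / branches / nested branches

def decompose(g: GlycanGraph) -> Decomposition:
    """Split a glycan tree into main chain, branches and nested branches.

    The main chain is the longest path from the reducing end, following
    canonical branch order at every divergence (lowest parent linkage,
    then alphabetical, on ties).  Every remaining subtree becomes a
    branch at nesting depth = parent's depth + 1, recursively.
    """
    g.validate()
    branches: list[Branch] = []

    def walk_chain(start: int, depth: int) -> list[int]:
        chain = [start]
        node = start
        while True:
            kids = ordered_children(g, node)
            if not kids:
                return chain
            for child, _ in kids[1:]:
                branches.append(Branch(node, depth + 1, walk_chain(child, depth + 1)))
            node = kids[0][0]
            chain.append(node)

    main = walk_chain(g.root, 0)
    return Decomposition(main_chain=main, branches=branches, floating=list(g.floating))


# ---------------------------------------------------------------------------
# Motif templates

def _load_motifs() -> dict[str, str]:
    table: dict[str, str] = {}
    text = resources.files("glycanvas.data").joinpath("motifs.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, iupac = line.split("\t")
        table[name] = iupac
    return table


MOTIFS: dict[str, str] = _load_motifs()
_MOTIFS_FOLDED = {name.lower(): name for name in MOTIFS}


def lookup_motif(name: str) -> str:
    """Resolve a named motif (case-insensitive) to its canonical string.

    Unknown names raise :class:`MotifLookupError` listing near matches.
    """
    key = _MOTIFS_FOLDED.get(name.strip().lower())
    if key is None:
        near = get_close_matches(name.strip().lower(), list(_MOTIFS_FOLDED), n=3)
        raise MotifLookupError(name, [_MOTIFS_FOLDED[m] for m in near])
    return MOTIFS[key]


def parse_input(text: str) -> GlycanGraph:
    """Convenience front door: motif name or (dialect) glycan string."""
    try:
        return parse_glycan(canonicalize_iupac(lookup_motif(text)))
    except MotifLookupError:
        return parse_glycan(canonicalize_iupac(text))
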