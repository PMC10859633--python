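# Methods

## Scope and model

`glycanvas` treats a glycan as a rooted tree: nodes are monosaccharides
(base name, ring form, explicit enantiomer prefix, positional chemical
modifications, optional alditol marker), edges are glycosidic linkages
(anomer `a`/`b`/`?`, child and parent carbon positions, `?` for
unknown), and the root is the reducing end. Components whose attachment
point is unknown are *floating* subgraphs written as `{...}` prefixes.
The package draws structures; it does not validate chemical feasibility
of linkages, convert between nomenclatures (WURCS, GlycoCT, SMILES),
enumerate fragments, or compute masses.

## Canonical form and branch ordering

A single canonical serialization underpins round-tripping, motif
storage, corpus generation, and layout. Sibling branches sort by
descending subtree length, then ascending parent linkage position
(unknown `?` after every known position, giving a deterministic total
order), then alphabetical serialization. One deliberate exception:
a terminal perpendicular residue (Fuc, Xyl) sorts after in-chain
residues of equal length. Without it the three-key rule alone would
spell Lewis-type epitopes `Fuc(a1-3)[Gal(b1-4)]GlcNAc` — the reverse of
the universally published spelling — and, worse, make fucose the drawn
main chain so it could never be rendered perpendicular. The exception
affects only ties against terminal Fuc/Xyl; mannose-arm ordering
(`a1-3` before `a1-6`) and all other cases follow the plain rule.

The canonicalizer accepts common dialect spellings before reserializing:
Greek anomers (α/β), CFG-style linkages without parentheses
(`Galb1-4GlcNAc`), parentheses used as branch delimiters
(`Manα1-3(Manα1-6)Man...`), typographic dashes and arrows, embedded
whitespace, and trailing `-ol` open-chain markers. Parenthesized groups
are classified innermost-first: content matching a bare linkage pattern
stays a linkage, anything else becomes a bracketed branch.
Repeating-unit syntax is rejected with an explicit error rather than
silently misparsed. Canonicalization is idempotent by construction
(normalize → parse → serialize).

Floating components are normalized into canonical branch order rather
than preserving author order, so equal structures compare equal as
strings.

## Layout

Initial placement puts main-chain residue *k* at (k, 0) and starts each
branch at `x_attach + 1`, stacked one row above the rows consumed by
lower-ordered siblings (so each branching level raises y by at least 1).
Refinement:

- **Perpendicular folding.** Terminal single-residue Fuc/Xyl branches
  move to the parent's column at `y ± 1`. Default side is below,
  flipping above on collision; two such residues on one parent take
  opposite sides; a third (not chemically meaningful) keeps its stacked
  slot. Only bracketed decorations fold — a fucose that terminates a
  linear chain stays inline.
- **Hub centering.** Processed leaves-to-root: each branch point moves
  to the arithmetic mean of its children's y; single-child residues
  ride at their child's height, which propagates the centered height
  back to the reducing end (the level backbone of standard SNFG
  figures). Perpendicular children are excluded from the mean — they
  sit on the hub's own column and would otherwise pull the backbone off
  level — and are re-anchored at exactly one unit from the parent
  afterwards.
- **Gap compaction.** Movable units are the non-chain subtrees at each
  branch point. For each unit, the minimal vertical distance to any
  residue below it in the same column is driven to exactly 1 by
  translating the unit; hubs are re-centered after every pass and the
  loop runs to a fixed point with a hard `n² + 10` iteration cap.
  Because translations only remove slack and centering only averages,
  total height is monotone non-increasing and the loop terminates; the
  cap is a guard, not a tuning knob.

All y coordinates are `fractions.Fraction`s: centering introduces
halves and nested asymmetric branches smaller rationals, and exact
arithmetic lets the invariant checks (`min pairwise distance ≥ 1`,
`adjacent-branch gap == 1`, `hub y == mean(child y)`) be asserted with
equality rather than tolerances. Coordinates become floats only at the
canvas-mapping step. In rare deeply nested configurations the fixed
point reached may differ aesthetically from other drawing tools; the
invariants above still hold.

Portrait mode transposes the final grid; compact mode is purely a
renderer concern (bond-length scaling) and does not change coordinates.

## Rendering

The renderer emits one `<g class="residue">` per residue and one
`<g class="bond">` per linkage into an SVG element tree while recording
a flat display list of primitives. SVG serialization is byte-stable for
fixed input; PDF export replays the same display list through
matplotlib's vector backend, so both formats come from a single
geometry pass. Defaults: 50 canvas units per grid unit, symbol diameter
half a grid unit, bonds under symbols under text, anomer glyph at one
third of the bond from the child and parent position at two thirds,
modification text above the symbol. `compact=True` multiplies bond
length by 0.6 and implies `show_linkage=False`. The furanose inner
label is an italic `f`; enantiomer labels (`D`/`L`) appear only when
the residue deviates from its SNFG-default enantiomer, which the
catalog stores per residue as data. Font, bracket glyph, and label
offsets are configuration with these documented defaults, not contract.

Symbol shapes and colors live in a plain-text catalog
(`data/snfg_catalog.tsv`, one row per residue: family, shape, color
name, RGB) following the SNFG family system — circle = hexose, square =
HexNAc, crossed square = hexosamine, divided diamond = hexuronate,
triangle = deoxyhexose, divided triangle = deoxyhexNAc, flat rectangle
= di-deoxyhexose, star = pentose, diamond = nonulosonic acid, flat
hexagon = unknown, pentagon = assigned — with the standard ten-color
palette. A residue absent from the catalog is the renderer's only
failure mode; parsing and layout accept arbitrary residue names.

## Fragment overlays

Domon–Costello ions are modelled as caller-supplied annotations: B/C/Y/Z
target an edge, A/X target a residue and carry the cleaved ring-bond
pair rendered as a leading superscript (`2,4A2`). The overlay draws a
stroke perpendicular to the bond (or diagonally across the symbol) with
a 0.3-grid-unit hook toward the retained side — the reducing end for
X/Y/Z, the non-reducing end for A/B/C — and the label on the hook side.
Subscript indices are taken as given, keeping rendering decoupled from
fragmentation and mass logic. The text syntax `Y1@edge:1` numbers
edges (and `@node:` residues) from the reducing end along the canonical
serialization.

## Figure annotation

`annotate_figure` matches `<text>` elements by exact content after
tspan concatenation and whitespace trimming (substring matching would
clobber titles), removes matches, and inserts the rendered glycan group
at the same tree position with its bounding-box center translated onto
the text anchor, honoring `rotate(...)` transforms and per-label scale
factors. Auto mode treats a text node as its own key only when it
canonicalizes to a glycan whose residues all resolve in the catalog,
so ordinary words (which would otherwise tokenize as one unknown
residue) are never clobbered. A pass with no matches warns and returns
the source unchanged, making the operation idempotent. matplotlib must
be configured with `svg.fonttype = "none"`; its default converts text
to paths, leaving nothing to match.

## Synthetic corpus

The generator emulates sampling from a large structure database without
downloads. Residue counts follow a geometric-like distribution with
mean 6 (capped at 40) — a typical mid-size glycan, and configurable;
branches open per residue with probability 0.25 up to nesting depth 3;
linkage positions are drawn from {2,3,4,6} without reuse at a parent;
sialic-type residues link through C2. The default alphabet weights the
residues dominating mammalian glycomes (Gal, GlcNAc, Man, Fuc, Neu5Ac,
Glc, GalNAc, ...) with a small tail across the remaining SNFG families.
Modifications appear at 3% per residue and floating components on 5% of
structures; a `nonstandard_rate` knob deliberately injects a
non-catalog residue to exercise the sole rendering failure mode.
Structures are built as trees and serialized canonically, so every
emitted string parses and round-trips by construction — the corpus
tests parser/serializer consistency and layout robustness, not
recovery from malformed input. What it does not emulate: real
biosynthetic constraints (branch compositions are random, not
pathway-derived), database nomenclature noise beyond the supported
dialects, and very large polysaccharides. Passing corpus tests
therefore demonstrate geometric and grammatical robustness, not
biological plausibility of the sampled structures.

The acceptance script and the suite run this pipeline at n = 1000
structures, which completes in seconds while giving stable rates;
timing bins (≤4, 5–9, ≥10 residues) are sized so medians are stable on
one CPU.

## Known limitations

- Repeating units and multi-valued linkages (`a1-3/6`) are rejected,
  not drawn.
- The di-deoxynonulosonate family (Pse, Leg, Aci; flat diamond) is not
  in the shipped catalog; the catalog covers the eleven shape classes
  listed above and is extensible by adding TSV rows.
- PDF text metrics come from matplotlib and may differ subtly from SVG
  viewer rendering; geometry is identical.
- `annotate_figure` requires genuine `<text>` elements (see above) and
  matches whole labels only.
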