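# glycanvas

Publication-quality SNFG glycan figures from IUPAC-condensed strings,
built for high-throughput, scriptable workflows.

Glycans are branched polymers of monosaccharides, and the community
communicates their structures through the Symbol Nomenclature for
Glycans (SNFG): each monosaccharide is a colored geometric symbol (blue
square = GlcNAc, green circle = Man, red triangle = Fuc, ...) and
structures are assembled with the reducing end drawn rightmost.
`glycanvas` parses glycans written in the compact IUPAC-condensed text
nomenclature — e.g. `Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc`,
where square brackets open branches — into rooted trees, computes
SNFG-style 2D coordinates, and renders deterministic SVG (or vector
PDF) figures. It also overlays Domon–Costello MS/MS fragment-ion marks
and can post-process existing SVG data figures, swapping text labels
for glycan drawings.

## The layout algorithm

A glycan tree is first split into its **main chain** (the longest path
from the reducing end; ties broken by lowest linkage position, then
alphabetically), **branches**, and **nested branches**. The reducing
end sits at grid position (0, 0) with x increasing by one per residue
along every chain and each branch stacking one row above its siblings.
The y coordinates are then refined in three steps:

1. perpendicular residues (fucose, xylose) fold onto their parent's
   column, one unit below or above, with a vertical bond;
2. every branch-point residue is re-placed at the arithmetic mean of
   its children's y positions, from the leaves toward the root;
3. vertical slack opened by centering is compacted until adjacent
   branches sit exactly one grid unit apart, re-centering after every
   pull until a fixed point.

Coordinates are exact rationals internally, so the fixed-point loop
cannot drift and the geometric invariants (no symbol pair closer than
one unit, every adjacent-branch gap exactly one) are checked exactly.

## Worked example

```python
from glycanvas import draw_glycan, parse_glycan, layout_glycan, decompose

s = "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"   # N-glycan core
g = parse_glycan(s)
d = decompose(g)
print("residues:", g.n_nodes, " linkages:", g.n_edges)
print("main chain:", " -> ".join(g.nodes[n].base_name for n in d.main_chain))
layout = layout_glycan(g)
for n, (x, y) in sorted(layout.positions.items()):
    print(f"  {g.nodes[n].base_name:7s} grid=({float(x):.1f}, {float(y):.1f})")
doc = draw_glycan(s, "n_glycan_core.svg")
print("residue groups:", doc.count("residue"), " bond groups:", doc.count("bond"))
```

prints

```
residues: 5  linkages: 4
main chain: GlcNAc -> GlcNAc -> Man -> Man
  Man     grid=(3.0, 0.0)
  Man     grid=(3.0, 1.0)
  Man     grid=(2.0, 0.5)
  GlcNAc  grid=(1.0, 0.5)
  GlcNAc  grid=(0.0, 0.5)
residue groups: 5  bond groups: 4
```

Both mannose arms share x = 3 one unit apart, the branching mannose is
centered between them at y = 0.5, and the chitobiose core rides at the
centered height — the canonical level-backbone SNFG drawing, written to
`n_glycan_core.svg` (use a `.pdf` extension for PDF).

The command line mirrors the library:

```sh
glycanvas draw "LewisX" -o lewisx.svg            # motif names resolve too
glycanvas draw "Gal(b1-4)Glc" -o lac.svg --fragment "Y1@edge:1"
glycanvas batch corpus.txt --outdir figures/     # failures logged, never fatal
glycanvas corpus generate --seed 7 --n 1000 --out corpus.txt
glycanvas annotate --svg heatmap.svg --map labels.tsv --out annotated.svg
```

Dialect input is harmonized automatically:
`canonicalize_iupac("Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAc")` returns
the canonical bracketed string above (Greek anomers, CFG-style linkages
without parentheses, parenthesized branches, typographic dashes).

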