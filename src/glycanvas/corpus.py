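"""Seeded synthetic glycan-string generator and curated fixtures.

Every other module is testable without downloads: the generator emits
canonical IUPAC-condensed strings from a configurable residue alphabet
with realistic topology (geometric-ish size distribution, optional
branching with a nesting cap, occasional modifications and floating
ambiguous components).  The default alphabet is weighted toward the
residues that dominate mammalian glycomes, with a small tail across the
remaining SNFG families so the full catalog stays exercised.

The generator is deterministic under its seed and, by construction
(structures are built as trees and serialized through the canonical
serializer), every emitted string is canonical.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import GlycanvasError
from .model import GlycanGraph, Linkage, Monosaccharide
from .nomenclature import lookup_motif, serialize_glycan

#: Mammalian-weighted default alphabet with a tail of other SNFG residues.
DEFAULT_ALPHABET: dict[str, float] = {
    "Gal": 18, "GlcNAc": 18, "Man": 15, "Fuc": 10, "Neu5Ac": 10,
    "Glc": 8, "GalNAc": 8, "GlcA": 3, "Xyl": 2, "Neu5Gc": 2,
    "Rha": 1.5, "Ara": 1.5, "ManNAc": 0.5, "GlcN": 0.5, "IdoA": 0.5,
    "Rib": 0.5, "Kdn": 0.4, "Kdo": 0.4, "Fru": 0.3, "MurNAc": 0.2,
    "Abe": 0.2, "QuiNAc": 0.2, "Api": 0.1, "Bac": 0.1, "6dAlt": 0.1,
}

#: Residues that glycosidically link through carbon 2 (sialic acids).
_C2_LINKING = frozenset({"Neu5Ac", "Neu5Gc", "Kdn", "Kdo", "Fru"})
_MODIFICATIONS = (("3", "S"), ("6", "S"), ("6", "P"), ("3", "Me"), ("4", "Ac"), ("9", "Ac"))
_FLOATING_POOL = ("Fuc", "Neu5Ac", "Gal")


@dataclass(frozen=True)
class CorpusSpec:
    """Parameters of one synthetic corpus (same spec -> identical corpus)."""

    seed: int = 7
    n_structures: int = 100
    mean_size: float = 6.0
    max_size: int = 40
    branch_probability: float = 0.25
    max_depth: int = 3
    alphabet: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ALPHABET))
    modification_rate: float = 0.03
    ambiguity_rate: float = 0.05
    nonstandard_rate: float = 0.0


def _sample_size(rng: random.Random, spec: CorpusSpec) -> int:
    size = 1
    p_continue = 1.0 - 1.0 / max(spec.mean_size, 1.0)
    while size < spec.max_size and rng.random() < p_continue:
        size += 1
    return size


def _pick_residue(rng: random.Random, alphabet: dict[str, float]) -> str:
    names = list(alphabet)
    return rng.choices(names, weights=[alphabet[n] for n in names], k=1)[0]


def _make_linkage(rng: random.Random, base_name: str, used_parent_pos: set[str]) -> Linkage:
    child_pos = "2" if base_name in _C2_LINKING else "1"
    pool = [p for p in ("2", "3", "4", "6") if p not in used_parent_pos]
    if not pool:
        pool = [p for p in "123456789" if p not in used_parent_pos] or ["?"]
    return Linkage(rng.choice(("a", "b")), child_pos, rng.choice(pool))


def _grow(g: GlycanGraph, rng: random.Random, spec: CorpusSpec,
          parent: int, budget: int, depth: int) -> int:
    """Grow a chain of ``budget`` residues off ``parent``, opening nested
    branches with probability ``branch_probability``; returns residues used."""
    used = 0
    node = parent
    while used < budget:
        base = _pick_residue(rng, spec.alphabet)
        res = g.new_node(base_name=base)
        if rng.random() < spec.modification_rate:
            res.modifications.append(rng.choice(_MODIFICATIONS))
        taken = {l.parent_pos for c, l in g.children(node)}
        g.add_edge(res.node_id, node, _make_linkage(rng, base, taken))
        used += 1
        remaining = budget - used
        if (
            remaining >= 1
            and depth < spec.max_depth
            and rng.random() < spec.branch_probability
        ):
            side = rng.randint(1, max(1, remaining // 2))
            used += _grow(g, rng, spec, res.node_id, side, depth + 1)
        node = res.node_id
    return used


def generate_glycan(rng: random.Random, spec: CorpusSpec) -> str:
    """One canonical synthetic glycan string."""
    g = GlycanGraph()
    root = g.new_node(base_name=_pick_residue(rng, spec.alphabet))
    g.root = root.node_id
    size = _sample_size(rng, spec)
    _grow(g, rng, spec, root.node_id, size - 1, depth=0)
    if spec.nonstandard_rate and rng.random() < spec.nonstandard_rate:
        victim = rng.choice(list(g.nodes.values()))
        victim.base_name = "Xxx"
        victim.in_catalog = False
        victim.modifications = []
    if rng.random() < spec.ambiguity_rate:
        comp = GlycanGraph()
        base = rng.choice(_FLOATING_POOL)
        node = comp.new_node(base_name=base)
        comp.root = node.node_id
        comp.attachment = _make_linkage(rng, base, set())
        g.floating.append(comp)
    return serialize_glycan(g)


def generate_corpus(spec: CorpusSpec) -> list[str]:
    """Deterministic list of ``spec.n_structures`` canonical glycans."""
    if spec.n_structures <= 0:
        raise GlycanvasError("n_structures must be positive")
    if not spec.alphabet:
        raise GlycanvasError("alphabet must be non-empty")
    if spec.mean_size < 1:
        raise GlycanvasError("mean_size must be >= 1")
    rng = random.Random(spec.seed)
    return [generate_glycan(rng, spec) for _ in range(spec.n_structures)]


def fixture_set() -> dict[str, str]:
    """Curated named fixtures: worked examples plus one representative
    per SNFG shape family."""
    return {
        "table1": "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc",
        "sialyllactose": "Neu5Ac(a2-3)Gal(b1-4)Glc",
        "lewisx": lookup_motif("LewisX"),
        "ambiguous_fuc": "{Fuc(a1-3)}Gal(b1-4)GlcNAc",
        "furanose": "Galf(b1-4)GlcNAc",
        "modified": "Gal6S(b1-4)GlcNAc",
        "enantiomer": "L-Gal(b1-4)GlcNAc",
        "biantennary": lookup_motif("G2"),
        "tetraantennary": (
            "Gal(b1-4)GlcNAc(b1-2)[Gal(b1-4)GlcNAc(b1-4)]Man(a1-3)"
            "[Gal(b1-4)GlcNAc(b1-2)[Gal(b1-4)GlcNAc(b1-6)]Man(a1-6)]"
            "Man(b1-4)GlcNAc(b1-4)GlcNAc"
        ),
        "family_hexose": "Man",
        "family_hexnac": "GlcNAc",
        "family_hexosamine": "GlcN",
        "family_hexuronate": "GlcA",
        "family_deoxyhexose": "Rha",
        "family_deoxyhexnac": "FucNAc",
        "family_dideoxyhexose": "Abe",
        "family_pentose": "Xyl",
        "family_nonulosonate": "Neu5Ac",
        "family_unknown": "Kdo",
        "family_assigned": "Fru",
    }


def write_corpus(spec: CorpusSpec, path) -> int:
    """Write the newline-delimited batch format; returns the line count."""
    lines = generate_corpus(spec)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# synthetic glycan corpus "
                 f"(seed={spec.seed}, n={spec.n_structures})\n")
        fh.write("\n".join(lines) + "\n")
    return len(lines)
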