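"""Parsing, canonicalization, serialization and decomposition."""

import re

import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycanvas.corpus import CorpusSpec, generate_corpus
from glycanvas.errors import GlycanParseError, MotifLookupError
from glycanvas.model import Linkage
from glycanvas.nomenclature import (
    MOTIFS,
    canonicalize_iupac,
    decompose,
    lookup_motif,
    order_branches,
    parse_glycan,
    parse_residue_token,
    serialize_glycan,
)

TABLE1 = "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"


def count_residue_tokens(s: str) -> int:
    """Independent oracle: residue tokens are the maximal runs left after
    stripping linkage parentheses and bracket delimiters."""
    no_linkages = re.sub(r"\([^()]*\)", "|", s)
    return sum(1 for run in re.split(r"[|\[\]{}]", no_linkages) if run)


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            # Greek anomers + parenthesized branches
            ("Manα1-3(Manα1-6)Manβ1-4GlcNAcβ1-4GlcNAc", TABLE1),
            # already canonical: unchanged
            (TABLE1, TABLE1),
            # branch reordering: equal length, lowest linkage first
            ("Man(a1-6)[Man(a1-3)]Man", "Man(a1-3)[Man(a1-6)]Man"),
            # CFG style without parentheses
            ("Galb1-4GlcNAc", "Gal(b1-4)GlcNAc"),
            ("Neu5Aca2-3Galb1-4Glc", "Neu5Ac(a2-3)Gal(b1-4)Glc"),
            # typographic dashes and arrows
            ("Neu5Ac(a2→3)Gal(b1–4)Glc", "Neu5Ac(a2-3)Gal(b1-4)Glc"),
            # whitespace
            ("Gal (b1-4) GlcNAc", "Gal(b1-4)GlcNAc"),
            # alditol marker survives
            ("Gal(b1-4)Glc-ol", "Gal(b1-4)Glc-ol"),
            # floating component prefix
            ("{Fuc(a1-3)}Gal(b1-4)GlcNAc", "{Fuc(a1-3)}Gal(b1-4)GlcNAc"),
        ],
    )
    def test_dialects(self, raw, expected):
        assert canonicalize_iupac(raw) == expected

    def test_idempotent(self, corpus_100):
        for s in corpus_100:
            once = canonicalize_iupac(s)
            assert canonicalize_iupac(once) == once

    def test_unparseable_names_offset(self):
        with pytest.raises(GlycanParseError) as exc:
            canonicalize_iupac("Man(a1-3]Gal")
        assert "offset" in str(exc.value)

    def test_repeat_syntax_rejected(self):
        with pytest.raises(GlycanParseError, match="repeat"):
            canonicalize_iupac("[Glc(a1-4)]n")


class TestParse:
    def test_table1_counts(self):
        g = parse_glycan(TABLE1)
        assert (g.n_nodes, g.n_edges) == (5, 4)
        assert g.nodes[g.root].base_name == "GlcNAc"
        # exactly one branch point, with two children
        fanouts = sorted(len(g.children(n)) for n in g.nodes)
        assert fanouts == [0, 0, 1, 1, 2]

    def test_single_residue(self):
        g = parse_glycan("Gal")
        assert (g.n_nodes, g.n_edges) == (1, 0)
        assert g.root in g.nodes

    def test_floating_component(self):
        g = parse_glycan("{Fuc(a1-3)}Gal(b1-4)GlcNAc")
        assert g.n_nodes == 2
        assert len(g.floating) == 1
        assert g.floating[0].n_nodes == 1
        assert g.floating[0].attachment == Linkage("a", "1", "3")

    @pytest.mark.parametrize(
        "bad,match",
        [
            ("Man(a1-3", "malformed linkage"),
            ("[Man(a1-3)", "unbalanced"),
            ("Man(a1-3))Gal", "unbalanced"),
            ("Man(x1-3)Gal", "malformed linkage"),
            ("[]Gal", "empty branch"),
            ("Gal(b1-4)", "dangling linkage"),
            ("", "empty"),
            ("Gal{Fuc(a1-3)}", "after reducing end"),
        ],
    )
    def test_errors_carry_offsets(self, bad, match):
        with pytest.raises(GlycanParseError, match=match):
            parse_glycan(bad)

    def test_node_conservation_against_token_oracle(self, corpus_1000):
        for s in corpus_1000:
            g = parse_glycan(s)
            total = g.n_nodes + sum(c.n_nodes for c in g.floating)
            assert total == count_residue_tokens(s), s


class TestSerialize:
    def test_round_trip_table1(self):
        assert serialize_glycan(parse_glycan(TABLE1)) == TABLE1

    def test_round_trip_corpus(self, corpus_1000):
        assert all(serialize_glycan(parse_glycan(s)) == s for s in corpus_1000)

    def test_equal_length_branches_lowest_linkage_on_main_chain(self):
        g = parse_glycan("Man(a1-6)[Man(a1-3)]Man")
        assert serialize_glycan(g) == "Man(a1-3)[Man(a1-6)]Man"

    def test_floating_prefix_restored(self):
        s = "{Fuc(a1-3)}Gal(b1-4)GlcNAc"
        assert serialize_glycan(parse_glycan(s)) == s


class TestResidueToken:
    @pytest.mark.parametrize(
        "token,base,ring,enant,mods,ol",
        [
            ("Man", "Man", "p", None, [], False),
            ("Galf", "Gal", "f", None, [], False),
            ("L-Gal", "Gal", "p", "L", [], False),
            ("Gal6S", "Gal", "p", None, [("6", "S")], False),
            ("Neu5Ac9Ac", "Neu5Ac", "p", None, [("9", "Ac")], False),
            ("Gal3Me6S", "Gal", "p", None, [("3", "Me"), ("6", "S")], False),
            ("GalOS", "Gal", "p", None, [("O", "S")], False),
            ("Glc-ol", "Glc", "p", None, [], True),
        ],
    )
    def test_grammar(self, token, base, ring, enant, mods, ol):
        f = parse_residue_token(token)
        assert f["base_name"] == base and f["in_catalog"]
        assert f["ring_form"] == ring
        assert f["enantiomer"] == enant
        assert f["modifications"] == mods
        assert f["alditol"] == ol

    def test_unknown_base_flagged_not_rejected(self):
        f = parse_residue_token("Xyz")
        assert f["base_name"] == "Xyz" and not f["in_catalog"]

    def test_duplicate_modification_positions_rejected(self):
        with pytest.raises(GlycanParseError, match="duplicate"):
            parse_residue_token("Gal6S6P")


class TestDecompose:
    def test_table1(self):
        g = parse_glycan(TABLE1)
        d = decompose(g)
        names = [g.nodes[n].base_name for n in d.main_chain]
        assert names == ["GlcNAc", "GlcNAc", "Man", "Man"]
        assert len(d.branches) == 1
        b = d.branches[0]
        assert b.depth == 1 and len(b.chain) == 1
        # branch attaches at the b1-4 Man (the hub) via a1-6
        assert g.nodes[b.attach_node].base_name == "Man"
        assert g.parent_of[b.chain[0]][1] == Linkage("a", "1", "6")

    def test_linear_chain_has_no_branches(self):
        g = parse_glycan("Neu5Ac(a2-3)Gal(b1-4)Glc")
        d = decompose(g)
        assert len(d.main_chain) == 3 and not d.branches

    def test_nested_branch_depth(self):
        # 7-node toy: branch inside a branch; brute-force depth check
        g = parse_glycan(
            "Gal(b1-4)GlcNAc(b1-2)[Gal(b1-4)[Xyl(b1-3)]GlcNAc(b1-6)]Man(b1-4)GlcNAc"
        )
        d = decompose(g)
        depths = sorted(b.depth for b in d.branches)
        assert depths == [1, 2]

    def test_partition_covers_all_nodes_once(self, corpus_100):
        for s in corpus_100:
            g = parse_glycan(s)
            d = decompose(g)
            covered = d.covered_nodes()
            assert sorted(covered) == sorted(g.nodes)
            assert len(covered) == len(set(covered))


class TestOrderBranches:
    def test_longer_branch_first_regardless_of_linkage(self):
        g = parse_glycan("Gal(b1-3)Gal(b1-6)[Man(a1-2)]Man")
        kids = order_branches(g, g.children(g.root))
        assert g.parent_of[kids[0][0]][1].parent_pos == "6"  # len-2 subtree

    def test_unknown_position_sorts_last(self):
        g = parse_glycan("Man(a1-?)[Man(a1-3)]Man")
        kids = order_branches(g, g.children(g.root))
        assert [l.parent_pos for _, l in kids] == ["3", "?"]

    @given(st.permutations(range(3)))
    def test_permutation_invariant_total_order(self, perm):
        g = parse_glycan("Man(a1-2)[Man(a1-4)][Man(a1-6)]Man")
        siblings = g.children(g.root)
        shuffled = [siblings[i] for i in perm]
        assert order_branches(g, shuffled) == order_branches(g, siblings)


class TestMotifs:
    def test_lewisx(self):
        assert lookup_motif("LewisX") == "Gal(b1-4)[Fuc(a1-3)]GlcNAc"

    def test_case_insensitive(self):
        assert lookup_motif("lewisx") == lookup_motif("LewisX")

    def test_unknown_name_suggests(self):
        with pytest.raises(MotifLookupError, match="LewisX"):
            lookup_motif("LewysX")

    def test_all_motifs_are_canonical(self):
        for name, s in MOTIFS.items():
            assert canonicalize_iupac(s) == s, name
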