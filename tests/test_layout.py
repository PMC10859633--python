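"""Grid layout: initial placement, perpendicular folding, hub centering,
gap compaction, and the corpus-wide geometric invariants."""

import time
from fractions import Fraction
from statistics import median

import pytest

from glycanvas.layout import (
    LayoutOptions,
    adjacent_branch_gaps,
    assign_initial_positions,
    center_hubs,
    compact_branch_gaps,
    fix_perpendicular_overlap,
    hub_deviations,
    layout_glycan,
    min_symbol_distance_sq,
)
from glycanvas.nomenclature import decompose, lookup_motif, parse_glycan

TABLE1 = "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc"


def by_name(g, layout):
    """base_name -> list of float positions, sorted."""
    out = {}
    for n, (x, y) in layout.positions.items():
        out.setdefault(g.nodes[n].base_name, []).append((float(x), float(y)))
    return {k: sorted(v) for k, v in out.items()}


class TestInitialPositions:
    def test_linear_chain(self):
        g = parse_glycan("Neu5Ac(a2-3)Gal(b1-4)Glc")
        layout = assign_initial_positions(g, decompose(g))
        assert by_name(g, layout) == {
            "Glc": [(0.0, 0.0)], "Gal": [(1.0, 0.0)], "Neu5Ac": [(2.0, 0.0)],
        }

    def test_table1_branch_row(self):
        g = parse_glycan(TABLE1)
        layout = assign_initial_positions(g, decompose(g))
        pos = by_name(g, layout)
        assert pos["GlcNAc"] == [(0.0, 0.0), (1.0, 0.0)]
        # hub Man on the main chain, a1-3 arm at (3,0), a1-6 arm at (3,1)
        assert pos["Man"] == [(2.0, 0.0), (3.0, 0.0), (3.0, 1.0)]

    def test_single_residue_at_origin(self):
        g = parse_glycan("Gal")
        layout = assign_initial_positions(g, decompose(g))
        assert list(layout.positions.values()) == [(0, 0)]


class TestPerpendicular:
    def test_lewisx_fucose_folds_below_parent(self):
        g = parse_glycan(lookup_motif("LewisX"))
        layout = fix_perpendicular_overlap(
            g, assign_initial_positions(g, decompose(g))
        )
        fuc = next(n for n in g.nodes if g.nodes[n].base_name == "Fuc")
        parent, _ = g.parent_of[fuc]
        px, py = layout.positions[parent]
        assert layout.positions[fuc] == (px, py - 1)
        assert fuc in layout.perpendicular

    def test_no_perpendicular_residue_is_a_noop(self):
        g = parse_glycan(TABLE1)
        before = dict(assign_initial_positions(g, decompose(g)).positions)
        after = fix_perpendicular_overlap(
            g, assign_initial_positions(g, decompose(g))
        ).positions
        assert before == after

    def test_two_perpendicular_on_one_parent_take_opposite_sides(self):
        g = parse_glycan("Gal(b1-4)[Fuc(a1-3)][Fuc(a1-6)]GlcNAc")
        layout = fix_perpendicular_overlap(
            g, assign_initial_positions(g, decompose(g))
        )
        fucs = [n for n in g.nodes if g.nodes[n].base_name == "Fuc"]
        ys = sorted(float(layout.positions[f][1]) for f in fucs)
        parent_y = float(layout.positions[g.parent_of[fucs[0]][0]][1])
        assert ys == [parent_y - 1, parent_y + 1]

    def test_side_option_flips_default(self):
        g = parse_glycan(lookup_motif("LewisX"))
        layout = fix_perpendicular_overlap(
            g,
            assign_initial_positions(g, decompose(g)),
            LayoutOptions(perpendicular_below=False),
        )
        fuc = next(n for n in g.nodes if g.nodes[n].base_name == "Fuc")
        parent, _ = g.parent_of[fuc]
        assert layout.positions[fuc][1] == layout.positions[parent][1] + 1


class TestHubCentering:
    def test_table1_hub_at_half_and_core_rides_along(self):
        g = parse_glycan(TABLE1)
        layout = center_hubs(
            g, fix_perpendicular_overlap(g, assign_initial_positions(g, decompose(g)))
        )
        pos = by_name(g, layout)
        assert pos["Man"] == [(2.0, 0.5), (3.0, 0.0), (3.0, 1.0)]
        # chitobiose core shifted to the centered height
        assert pos["GlcNAc"] == [(0.0, 0.5), (1.0, 0.5)]

    def test_linear_chain_unchanged(self):
        g = parse_glycan("Neu5Ac(a2-3)Gal(b1-4)Glc")
        layout = center_hubs(g, assign_initial_positions(g, decompose(g)))
        assert all(y == 0 for _, y in layout.positions.values())

    def test_symmetric_three_way_branch_centers_at_middle(self):
        g = parse_glycan("Man(a1-2)[Man(a1-4)][Man(a1-6)]Man")
        layout = center_hubs(g, assign_initial_positions(g, decompose(g)))
        assert layout.positions[g.root][1] == 1


class TestCompaction:
    def test_gap_opened_by_centering_closes_to_one(self):
        # asymmetric arms: centering the deep arm's hub opens slack
        s = ("Gal(b1-4)GlcNAc(b1-2)[Gal(b1-4)GlcNAc(b1-4)]Man(a1-3)"
             "[Gal(b1-4)GlcNAc(b1-2)[Gal(b1-4)GlcNAc(b1-6)]Man(a1-6)]"
             "Man(b1-4)GlcNAc(b1-4)GlcNAc")
        g = parse_glycan(s)
        layout = layout_glycan(g)
        gaps = adjacent_branch_gaps(g, layout)
        assert gaps and all(gap == 1 for gap in gaps)

    def test_already_tight_layout_is_fixed_point(self):
        g = parse_glycan(TABLE1)
        layout = layout_glycan(g)
        before = dict(layout.positions)
        compact_branch_gaps(g, layout)
        assert layout.positions == before

    def test_terminates_within_quadratic_cap(self, corpus_100):
        for s in corpus_100:
            g = parse_glycan(s)
            layout = center_hubs(
                g,
                fix_perpendicular_overlap(
                    g, assign_initial_positions(g, decompose(g))
                ),
            )
            # same cap as production; raises nothing and converges
            compact_branch_gaps(g, layout)
            assert all(gap == 1 for gap in adjacent_branch_gaps(g, layout))


class TestComposition:
    def test_linear_chain_spans_x(self):
        g = parse_glycan("Gal(b1-3)Gal(b1-3)Gal(b1-3)Gal")
        layout = layout_glycan(g)
        xs = sorted(float(x) for x, _ in layout.positions.values())
        ys = {float(y) for _, y in layout.positions.values()}
        assert xs == [0.0, 1.0, 2.0, 3.0] and ys == {0.0}

    def test_vertical_transposes(self):
        g = parse_glycan("Neu5Ac(a2-3)Gal(b1-4)Glc")
        layout = layout_glycan(g, LayoutOptions(vertical=True))
        ys = sorted(float(y) for _, y in layout.positions.values())
        assert ys == [0.0, 1.0, 2.0]
        assert layout.orientation == "vertical"

    def test_table1_final_geometry(self):
        g = parse_glycan(TABLE1)
        layout = layout_glycan(g)
        pos = by_name(g, layout)
        arm_lo, arm_hi = pos["Man"][1], pos["Man"][2]
        hub = pos["Man"][0]
        assert arm_lo[0] == arm_hi[0] == 3.0
        assert arm_hi[1] - arm_lo[1] == 1.0
        assert hub[1] == (arm_lo[1] + arm_hi[1]) / 2

    def test_floating_band_beyond_main_extent(self):
        g = parse_glycan("{Fuc(a1-3)}Gal(b1-4)GlcNAc")
        layout = layout_glycan(g)
        main_max_x = max(x for x, _ in layout.positions.values())
        for fl in layout.floating_layouts:
            assert all(x > main_max_x for x, _ in fl.positions.values())

    def test_debug_dump_is_json_plain(self):
        g = parse_glycan(TABLE1)
        dump = layout_glycan(g).debug_dump()
        assert {d["node_id"] for d in dump} == set(g.nodes)
        assert all(isinstance(d["x"], float) for d in dump)


class TestCorpusInvariants:
    def test_no_symbol_pair_closer_than_one_unit(self, corpus_1000):
        for s in corpus_1000:
            g = parse_glycan(s)
            d2 = min_symbol_distance_sq(layout_glycan(g))
            assert d2 is None or d2 >= 1, s

    def test_adjacent_branch_gaps_exactly_one(self, corpus_1000):
        for s in corpus_1000:
            g = parse_glycan(s)
            layout = layout_glycan(g)
            assert all(gap == 1 for gap in adjacent_branch_gaps(g, layout)), s

    def test_hub_mean_property(self, corpus_1000):
        for s in corpus_1000:
            g = parse_glycan(s)
            layout = layout_glycan(g)
            assert all(dev <= 1e-9 for dev in hub_deviations(g, layout)), s

    def test_perpendicular_bond_is_exactly_one_unit(self, corpus_1000):
        for s in corpus_1000:
            g = parse_glycan(s)
            layout = layout_glycan(g)
            for node in layout.perpendicular:
                px, py = layout.positions[g.parent_of[node][0]]
                x, y = layout.positions[node]
                assert x == px and abs(y - py) == 1

    def test_median_layout_time_monotone_in_size(self, corpus_1000):
        bins = {"small": [], "mid": [], "large": []}
        for s in corpus_1000:
            g = parse_glycan(s)
            t0 = time.perf_counter()
            layout_glycan(g)
            dt = time.perf_counter() - t0
            n = g.n_nodes
            key = "small" if n <= 4 else ("mid" if n <= 9 else "large")
            bins[key].append(dt)
        meds = [median(bins[k]) for k in ("small", "mid", "large") if bins[k]]
        assert all(a <= b for a, b in zip(meds, meds[1:]))
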