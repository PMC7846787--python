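import numpy as np
import pandas as pd
import pytest

from mapanchor.config import PipelineConfig
from mapanchor.io.tables import BarcodeAlignmentTable
from mapanchor.scaffold import (
    HEAD,
    TAIL,
    ScaffoldGraph,
    build_scaffold_graph,
    collect_end_barcodes,
    detect_misassemblies,
    greedy_scaffold_paths,
    split_alignment_table,
)
from mapanchor.simulate.fragments import fragment_genome
from mapanchor.simulate.genome import simulate_genome
from mapanchor.simulate.linked_reads import barcodes_for_coverage, simulate_linked_reads


def aln(rows):
    return BarcodeAlignmentTable(
        pd.DataFrame(rows, columns=["barcode", "contig", "pos", "strand"])
    )


def cfg(**kw):
    defaults = dict(min_shared_barcodes=2, seed=0)
    defaults.update(kw)
    return PipelineConfig(**defaults)


# -- end windows -----------------------------------------------------

def test_read_in_head_window_only():
    table = aln([("BC1", "c", 5_000, "+")])
    sets = collect_end_barcodes(table, {"c": 100_000}, cfg())
    assert sets[("c", HEAD)] == {"BC1"}
    assert sets[("c", TAIL)] == set()


def test_short_contig_window_truncated():
    # contig 30 kbp: w = min(20k, floor(30k/2)) = 15k, so the head window is
    # [0, 15k) and the tail window [15k, 30k); a read at 16 kbp therefore
    # leaves the head window it would occupy at full width
    table = aln([("BC1", "c", 16_000, "+")])
    sets = collect_end_barcodes(table, {"c": 30_000}, cfg())
    assert sets[("c", HEAD)] == set()
    assert sets[("c", TAIL)] == {"BC1"}
    table = aln([("BC2", "c", 14_999, "+")])
    sets = collect_end_barcodes(table, {"c": 30_000}, cfg())
    assert sets[("c", HEAD)] == {"BC2"}
    assert sets[("c", TAIL)] == set()


def test_hand_grouping_six_reads():
    table = aln(
        [
            ("B1", "c1", 1_000, "+"),
            ("B1", "c1", 95_000, "+"),
            ("B2", "c1", 50_000, "+"),
            ("B2", "c2", 100, "-"),
            ("B3", "c2", 39_000, "+"),
            ("B3", "c1", 2_000, "-"),
        ]
    )
    sets = collect_end_barcodes(table, {"c1": 100_000, "c2": 40_000}, cfg())
    assert sets[("c1", HEAD)] == {"B1", "B3"}
    assert sets[("c1", TAIL)] == {"B1"}
    assert sets[("c2", HEAD)] == {"B2"}
    assert sets[("c2", TAIL)] == {"B3"}


def test_very_short_contig_barcode_in_both_sets():
    table = aln([("B1", "c", 500, "+")])
    sets = collect_end_barcodes(table, {"c": 1_000}, cfg())
    assert sets[("c", HEAD)] == set()  # w = 500, read at 500 not in [0, 500)
    assert sets[("c", TAIL)] == {"B1"}
    table = aln([("B1", "c", 499, "+")])
    sets = collect_end_barcodes(table, {"c": 1_000}, cfg())
    assert sets[("c", HEAD)] == {"B1"}


# -- graph building --------------------------------------------------

def test_disjoint_sets_no_edges():
    sets = {
        ("c1", HEAD): {"a"}, ("c1", TAIL): {"b"},
        ("c2", HEAD): {"c"}, ("c2", TAIL): {"d"},
    }
    g = build_scaffold_graph(sets, cfg())
    assert len(g.edges) == 0


def test_shared_barcode_count_and_weight():
    shared = {f"B{i}" for i in range(10)}
    sets = {
        ("c1", TAIL): shared | {"x1", "x2"},
        ("c1", HEAD): set(),
        ("c2", HEAD): shared,
        ("c2", TAIL): set(),
    }
    g = build_scaffold_graph(sets, cfg(min_shared_barcodes=5))
    assert len(g.edges) == 1
    e = g.edges.iloc[0]
    assert e["n_shared"] == 10
    assert e["weight"] == pytest.approx(10 / 10)  # min(|12|, |10|) = 10


def test_below_min_shared_dropped():
    sets = {
        ("c1", TAIL): {"a", "b"},
        ("c1", HEAD): set(),
        ("c2", HEAD): {"a", "b"},
        ("c2", TAIL): set(),
    }
    g = build_scaffold_graph(sets, cfg(min_shared_barcodes=3))
    assert len(g.edges) == 0


def test_promiscuous_barcodes_discarded():
    # barcode P occurs at 6 ends (> 4): removed everywhere
    sets = {}
    for c in ("c1", "c2", "c3"):
        sets[(c, HEAD)] = {"P", f"u{c}"}
        sets[(c, TAIL)] = {"P"}
    g = build_scaffold_graph(sets, cfg(min_shared_barcodes=1))
    assert len(g.edges) == 0


def test_no_edge_between_own_ends():
    sets = {("c1", HEAD): {"a", "b"}, ("c1", TAIL): {"a", "b"}}
    g = build_scaffold_graph(sets, cfg(min_shared_barcodes=1))
    assert len(g.edges) == 0


# -- greedy paths ----------------------------------------------------

def graph_from_edges(edges, contigs):
    rows = [(ea, eb, n, w) for ea, eb, n, w in edges]
    return ScaffoldGraph(
        edges=pd.DataFrame(rows, columns=["end_a", "end_b", "n_shared", "weight"]),
        contigs=contigs,
    )


def test_cycle_rejected_stated_example():
    g = graph_from_edges(
        [
            (("A", TAIL), ("B", HEAD), 10, 0.5),
            (("B", TAIL), ("C", HEAD), 8, 0.4),
            (("A", HEAD), ("C", TAIL), 2, 0.1),
        ],
        ["A", "B", "C"],
    )
    paths = greedy_scaffold_paths(g)
    assert len(paths) == 1
    assert paths[0].contigs == [("A", "+"), ("B", "+"), ("C", "+")]


def test_heavier_edge_wins_end_competition():
    g = graph_from_edges(
        [
            (("A", TAIL), ("B", HEAD), 10, 0.9),
            (("A", TAIL), ("C", HEAD), 5, 0.4),
        ],
        ["A", "B", "C"],
    )
    paths = greedy_scaffold_paths(g)
    by_first = {p.contig_ids[0]: p for p in paths}
    assert by_first["A"].contig_ids == ["A", "B"]
    assert by_first["C"].contig_ids == ["C"]


def test_empty_graph_singletons():
    g = graph_from_edges([], ["A", "B", "C"])
    paths = greedy_scaffold_paths(g)
    assert [p.contigs for p in paths] == [
        [("A", "+")], [("B", "+")], [("C", "+")],
    ]


def test_orientation_from_joined_end_types():
    # A.tail-B.tail means B is traversed tail->head: B gets '-'
    g = graph_from_edges([(("A", TAIL), ("B", TAIL), 5, 0.5)], ["A", "B"])
    paths = greedy_scaffold_paths(g)
    assert paths[0].contigs == [("A", "+"), ("B", "-")]


def test_every_contig_exactly_once():
    rng = np.random.default_rng(0)
    contigs = [f"c{i}" for i in range(12)]
    edges = []
    for i in range(25):
        a, b = rng.choice(12, 2, replace=False)
        ea = (contigs[a], HEAD if rng.random() < 0.5 else TAIL)
        eb = (contigs[b], HEAD if rng.random() < 0.5 else TAIL)
        if ea[0] == eb[0]:
            continue
        edges.append((ea, eb, int(rng.integers(5, 50)), float(rng.random())))
    g = graph_from_edges(edges, contigs)
    paths = greedy_scaffold_paths(g)
    seen = [c for p in paths for c in p.contig_ids]
    assert sorted(seen) == sorted(contigs)


def test_permutation_invariance():
    rng = np.random.default_rng(1)
    contigs = [f"c{i}" for i in range(8)]
    edges = []
    for i, a in enumerate(contigs):
        for b in contigs[i + 1 :]:
            for ea, eb in ((HEAD, TAIL), (TAIL, HEAD)):
                if rng.random() < 0.4:
                    edges.append(
                        ((a, ea), (b, eb), int(rng.integers(5, 40)), float(rng.random()))
                    )
    base = greedy_scaffold_paths(graph_from_edges(edges, contigs))
    for _ in range(5):
        rng.shuffle(edges)
        again = greedy_scaffold_paths(graph_from_edges(edges, contigs))
        assert [p.contigs for p in again] == [p.contigs for p in base]


def test_greedy_locally_maximal_weight():
    # the greedy total weight is at least that of random alternative
    # acceptance orders respecting the same feasibility rules
    rng = np.random.default_rng(2)
    contigs = [f"c{i}" for i in range(6)]
    edges = []
    for i, a in enumerate(contigs):
        for b in contigs[i + 1 :]:
            edges.append(((a, TAIL), (b, HEAD), int(rng.integers(5, 30)),
                          float(rng.random())))
    g = graph_from_edges(edges, contigs)
    paths = greedy_scaffold_paths(g)
    greedy_total = sum(w for p in paths for w in p.join_weights)

    def feasible_total(order):
        used, parent = set(), {c: c for c in contigs}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        total = 0.0
        for ea, eb, n, w in order:
            if ea in used or eb in used:
                continue
            ra, rb = find(ea[0]), find(eb[0])
            if ra == rb:
                continue
            parent[rb] = ra
            used.update((ea, eb))
            total += w
        return total

    for _ in range(50):
        alt = list(edges)
        rng.shuffle(alt)
        assert greedy_total >= feasible_total(alt) - 1e-9


# -- misassembly detection ------------------------------------------

def test_clean_contig_no_breaks():
    call = detect_misassemblies(
        "c", 100_000, aln([]), np.array([10_000, 50_000, 90_000]),
        np.array([0, 0, 0]), cfg(),
    )
    assert call.break_positions == [] and not call.unresolvable


def test_single_marker_no_break_possible():
    call = detect_misassemblies(
        "c", 100_000, aln([]), np.array([10_000]), np.array([0]), cfg(),
    )
    assert call.break_positions == []


def test_interleaved_groups_unresolvable():
    call = detect_misassemblies(
        "c", 100_000, aln([]),
        np.array([10_000, 30_000, 50_000, 70_000]),
        np.array([0, 1, 0, 1]), cfg(),
    )
    assert call.unresolvable


def test_break_at_barcode_continuity_minimum():
    # continuous barcode cover everywhere except across 50k
    rows = []
    for i in range(40):
        start = i * 2_000
        if start < 48_000:
            rows.append((f"L{i}", "c", start, "+"))
            rows.append((f"L{i}", "c", start + 1_500, "+"))
        elif start >= 50_000:
            rows.append((f"R{i}", "c", start, "+"))
            rows.append((f"R{i}", "c", start + 1_500, "+"))
    call = detect_misassemblies(
        "c", 80_000, aln(rows),
        np.array([10_000, 40_000, 60_000, 70_000]),
        np.array([0, 0, 1, 1]),
        cfg(misassembly_max_span_barcodes=3),
    )
    assert len(call.break_positions) == 1
    assert abs(call.break_positions[0] - 50_000) <= 5_000


def test_simulated_chimera_break_recovered():
    genome = simulate_genome(2, [2_000_000] * 2, [20.0] * 2, marker_density=60, seed=3)
    _, truth = fragment_genome(genome, 600_000, n_chimeras=1, seed=3,
                               min_chimera_part_bp=150_000)
    contig, junction = next(iter(truth.chimeric_contigs().items()))
    n_bc = barcodes_for_coverage(genome, 30.0, 50_000, 2)
    table = simulate_linked_reads(truth, genome, 50_000, 2, n_bc, 0.2, seed=3)
    # marker groups from truth chromosomes (the genetic evidence oracle)
    parts = truth.parts[truth.parts["contig"] == contig].sort_values("contig_start")
    pos, grp = [], []
    for _, part in parts.iterrows():
        length = int(part["chrom_end"] - part["chrom_start"])
        for off in range(10_000, length - 5_000, 25_000):
            pos.append(int(part["contig_start"]) + off)
            grp.append(0 if part["part_index"] == 0 else 1)
    call = detect_misassemblies(
        contig, truth.contig_lengths[contig], table,
        np.array(pos), np.array(grp), cfg(),
    )
    assert len(call.break_positions) == 1
    assert abs(call.break_positions[0] - junction) <= 20_000


def test_split_alignment_table():
    table = aln([("B", "c", 10, "+"), ("B", "c", 150, "+"), ("B", "d", 5, "+")])
    out = split_alignment_table(table, {"c": [100]})
    df = out.df.sort_values(["contig", "pos"]).reset_index(drop=True)
    assert df["contig"].tolist() == ["c.1", "c.2", "d"]
    assert df["pos"].tolist() == [10, 50, 5]
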