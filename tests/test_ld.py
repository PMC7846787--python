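import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import CALL_A, CALL_B, CALL_H, CALL_MISSING
from mapanchor.ld import (
    batch_r2,
    infer_linkage_groups,
    ld_decay,
    pairwise_r2,
)
from mapanchor.simulate.genome import simulate_genome
from mapanchor.simulate.ril import genotype_population, simulate_ril_population

from conftest import make_matrix

A, B, H, M = CALL_A, CALL_B, CALL_H, CALL_MISSING


def test_identical_vectors():
    assert pairwise_r2([A, A, B, B], [A, A, B, B]) == pytest.approx(1.0)


def test_orthogonal_vectors():
    assert pairwise_r2([A, A, B, B], [A, B, A, B]) == pytest.approx(0.0)


def test_hand_example_one_third():
    # x=[0,0,1,1], y=[0,0,1,0]: r = 2/sqrt(12), r^2 = 1/3
    assert pairwise_r2([A, A, B, B], [A, A, B, A]) == pytest.approx(1 / 3, abs=1e-12)


def test_het_and_missing_excluded_pairwise():
    # after excluding the H and missing samples both vectors are [0,0,1,1]
    a = [A, A, B, B, H, A]
    b = [A, A, B, B, B, M]
    assert pairwise_r2(a, b) == pytest.approx(1.0)


def test_monomorphic_after_exclusion_undefined_not_zero():
    a = [A, A, A, A]
    b = [A, B, A, B]
    assert math.isnan(pairwise_r2(a, b))


def test_fewer_than_two_complete_samples_undefined():
    assert math.isnan(pairwise_r2([A, M, M], [M, B, M]))


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(st.sampled_from([A, B, H, M]), st.sampled_from([A, B, H, M])),
        min_size=2,
        max_size=30,
    )
)
def test_r2_symmetry(pairs):
    a = np.array([p[0] for p in pairs], dtype=np.int8)
    b = np.array([p[1] for p in pairs], dtype=np.int8)
    r_ab = pairwise_r2(a, b)
    r_ba = pairwise_r2(b, a)
    assert (math.isnan(r_ab) and math.isnan(r_ba)) or r_ab == r_ba


def test_r2_in_unit_interval():
    rng = np.random.default_rng(0)
    x = rng.choice([A, B, H, M], size=(50, 40)).astype(np.int8)
    y = rng.choice([A, B, H, M], size=(50, 40)).astype(np.int8)
    r2 = batch_r2(x, y)
    ok = ~np.isnan(r2)
    assert np.all((r2[ok] >= -1e-12) & (r2[ok] <= 1 + 1e-12))


# -- linkage groups ---------------------------------------------------

def test_copied_contigs_one_group(toy_config):
    rng = np.random.default_rng(1)
    block = rng.choice([A, B], size=(5, 30)).astype(np.int8)
    calls = np.vstack([block, block])
    m = make_matrix(calls, contigs=["c1"] * 5 + ["c2"] * 5,
                    positions=list(range(5)) * 2)
    groups, graph = infer_linkage_groups(m, toy_config)
    assert len(set(groups.values())) == 1


def test_independent_chromosomes_separate_groups(toy_config):
    rng = np.random.default_rng(2)
    c1 = np.repeat(rng.choice([A, B], size=(1, 40)), 5, axis=0).astype(np.int8)
    c2 = np.repeat(rng.choice([A, B], size=(1, 40)), 5, axis=0).astype(np.int8)
    m = make_matrix(np.vstack([c1, c2]), contigs=["c1"] * 5 + ["c2"] * 5,
                    positions=list(range(5)) * 2)
    groups, graph = infer_linkage_groups(m, toy_config)
    assert groups["c1"] != groups["c2"]


def test_group_naming_by_total_length(toy_config):
    rng = np.random.default_rng(3)
    c1 = np.repeat(rng.choice([A, B], size=(1, 40)), 3, axis=0).astype(np.int8)
    c2 = np.repeat(rng.choice([A, B], size=(1, 40)), 3, axis=0).astype(np.int8)
    m = make_matrix(np.vstack([c1, c2]), contigs=["small"] * 3 + ["big"] * 3,
                    positions=list(range(3)) * 2)
    groups, _ = infer_linkage_groups(
        m, toy_config, contig_lengths={"small": 10_000, "big": 900_000}
    )
    assert groups["big"] == "LG01"
    assert groups["small"] == "LG02"


def test_components_match_independent_union_find(toy_config):
    # oracle: union-find over the same edge set
    rng = np.random.default_rng(4)
    n_contigs = 20
    base = {c: rng.choice([A, B], size=60).astype(np.int8) for c in range(5)}
    calls, contigs, positions = [], [], []
    assign = {}
    for c in range(n_contigs):
        fam = c % 5
        assign[f"c{c:02d}"] = fam
        for k in range(3):
            calls.append(base[fam])
            contigs.append(f"c{c:02d}")
            positions.append(k)
    m = make_matrix(np.array(calls), contigs=contigs, positions=positions)
    groups, graph = infer_linkage_groups(m, toy_config)

    parent = {c: c for c in graph.graph.nodes}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in graph.graph.edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    oracle = {}
    for c in graph.graph.nodes:
        oracle.setdefault(find(c), set()).add(c)
    mine = {}
    for c, g in groups.items():
        mine.setdefault(g, set()).add(c)
    assert sorted(map(sorted, oracle.values())) == sorted(map(sorted, mine.values()))


def test_raising_threshold_refines_partition():
    rng = np.random.default_rng(5)
    calls, contigs, positions = [], [], []
    base = rng.choice([A, B], size=(1, 50)).astype(np.int8)[0]
    for c in range(6):
        for k in range(4):
            noisy = base.copy()
            flip = rng.random(50) < 0.05 * c
            noisy[flip] = 1 - noisy[flip]
            calls.append(noisy)
            contigs.append(f"c{c}")
            positions.append(k)
    m = make_matrix(np.array(calls), contigs=contigs, positions=positions)
    partitions = []
    for thr in (0.2, 0.5, 0.8, 0.95):
        cfg = PipelineConfig(r2_threshold=thr, min_ld_pairs=1, seed=0)
        groups, _ = infer_linkage_groups(m, cfg)
        partitions.append(groups)
    for lo, hi in zip(partitions[:-1], partitions[1:]):
        # higher threshold must refine: contigs together at hi are together at lo
        for c1 in lo:
            for c2 in lo:
                if hi[c1] == hi[c2]:
                    assert lo[c1] == lo[c2]


def test_singleton_contigs_become_singleton_groups(toy_config):
    rng = np.random.default_rng(6)
    calls = rng.choice([A, B], size=(2, 40)).astype(np.int8)
    m = make_matrix(calls, contigs=["c1", "c2"], positions=[0, 0])
    groups, _ = infer_linkage_groups(m, toy_config)
    assert len(groups) == 2


def test_subsampling_deterministic():
    rng = np.random.default_rng(7)
    calls = rng.choice([A, B], size=(40, 30)).astype(np.int8)
    contigs = ["c1"] * 20 + ["c2"] * 20
    positions = list(range(20)) * 2
    m = make_matrix(calls, contigs=contigs, positions=positions)
    cfg = PipelineConfig(ld_pair_cap=50, min_ld_pairs=1, seed=9)
    g1, _ = infer_linkage_groups(m, cfg)
    g2, _ = infer_linkage_groups(m, cfg)
    assert g1 == g2


# -- LD decay --------------------------------------------------------

def test_decay_identical_markers_all_bins_one():
    rng = np.random.default_rng(8)
    row = rng.choice([A, B], size=50).astype(np.int8)
    calls = np.repeat(row[None, :], 10, axis=0)
    m = make_matrix(calls, positions=list(range(0, 10_000, 1000)))
    curve = ld_decay(m, np.array(["chr1"] * 10), m.markers["pos"].to_numpy(),
                     bin_width=2000, max_distance=10_000)
    filled = curve[curve["n_pairs"] > 0]
    assert np.allclose(filled["mean_r2"], 1.0)


def test_pairs_beyond_max_distance_absent():
    rng = np.random.default_rng(9)
    calls = rng.choice([A, B], size=(2, 50)).astype(np.int8)
    m = make_matrix(calls, positions=[0, 100_000])
    curve = ld_decay(m, np.array(["chr1", "chr1"]),
                     np.array([0, 100_000]), bin_width=10_000, max_distance=50_000)
    assert curve["n_pairs"].sum() == 0


def test_simulated_decay_monotone_trend():
    import pandas as pd

    from mapanchor.simulate.fragments import TruthPlacement

    genome = simulate_genome(1, [5_000_000], [150.0], marker_density=80, seed=10)
    # one full-length '+' contig keeps contig and chromosome coordinates equal
    placement = TruthPlacement(
        parts=pd.DataFrame(
            {
                "contig": ["ctg1"], "part_index": [0], "chrom": ["chr01"],
                "chrom_start": [0], "chrom_end": [5_000_000],
                "strand": ["+"], "contig_start": [0],
            }
        ),
        contig_lengths={"ctg1": 5_000_000},
    )
    pop = simulate_ril_population(genome, 80, 7, seed=10)
    m = genotype_population(pop, genome, placement, seed=10)
    curve = ld_decay(
        m,
        np.array(["chr01"] * m.n_markers),
        m.markers["pos"].to_numpy(),
        bin_width=100_000,
        max_distance=1_000_000,
    )
    assert curve["n_pairs"].sum() >= 5000
    from scipy.stats import spearmanr

    rho = spearmanr(np.arange(10), curve["mean_r2"].to_numpy()[:10]).statistic
    assert rho < 0
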