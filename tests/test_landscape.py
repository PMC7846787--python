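import numpy as np
import pandas as pd
import pytest

from mapanchor.assembly import PseudomoleculeSet, build_object
from mapanchor.config import PipelineConfig
from mapanchor.genetics.genetic_map import GeneticMap
from mapanchor.landscape import (
    RecombinationProfile,
    build_marey_profile,
    call_pericentromeres,
    interpolate_cm,
    map_summary_stats,
    sliding_window_rate,
)


def cfg(**kw):
    return PipelineConfig(**kw)


def gmap_from(markers):
    """markers: list of (marker_id, contig, pos, group, cm)."""
    return GeneticMap(
        markers=pd.DataFrame(
            markers,
            columns=["marker_id", "contig", "position", "linkage_group", "cM"],
        ),
        intervals=pd.DataFrame(
            columns=["linkage_group", "left_marker", "right_marker", "breakpoints", "cM"]
        ),
        n_samples=10,
    )


def single_contig_pseudo(length=3_000_000, name="chr01", contig="c1"):
    return PseudomoleculeSet(objects=[build_object(name, [(contig, "+", length)], 100)])


def test_marey_three_points_monotone():
    gmap = gmap_from(
        [
            ("m1", "c1", 1_000_000, "chr01", 0.0),
            ("m2", "c1", 2_000_000, "chr01", 5.0),
            ("m3", "c1", 2_999_999, "chr01", 5.0),
        ]
    )
    marey = build_marey_profile(gmap, single_contig_pseudo())
    bp, cm = marey["chr01"]
    assert bp.tolist() == [1_000_000, 2_000_000, 2_999_999]
    assert cm.tolist() == [0.0, 5.0, 5.0]


def test_marey_sorting_contract_and_duplicate_collapse():
    # rows in anchored (cM) order but physically unsorted
    gmap = gmap_from(
        [
            ("m1", "c1", 1_000_000, "chr01", 0.0),
            ("m3", "c1", 999_999, "chr01", 0.5),
            ("m4", "c1", 2_000_000, "chr01", 4.0),  # duplicate bp -> max cM
            ("m2", "c1", 2_000_000, "chr01", 5.0),
        ]
    )
    marey = build_marey_profile(gmap, single_contig_pseudo())
    bp, cm = marey["chr01"]
    assert np.all(np.diff(bp) > 0)
    assert np.all(np.diff(cm) >= 0)
    assert cm[bp.tolist().index(2_000_000)] == 5.0


def test_marey_minus_strand_placement():
    # contig placed '-': contig pos p maps to obj_end - 1 - p
    pseudo = PseudomoleculeSet(objects=[build_object("chr01", [("c1", "-", 1000)], 100)])
    # cumulative cM follows the anchored (object) order, so the marker at
    # higher contig position carries the lower cM on a '-' placement
    gmap = gmap_from(
        [("m2", "c1", 900, "chr01", 0.0), ("m1", "c1", 100, "chr01", 2.0)]
    )
    marey = build_marey_profile(gmap, pseudo)
    bp, cm = marey["chr01"]
    assert bp.tolist() == [99, 899]
    assert cm.tolist() == [0.0, 2.0]


def test_chromosome_with_one_marker_excluded(caplog):
    gmap = gmap_from([("m1", "c1", 10, "chr01", 0.0)])
    with caplog.at_level("WARNING"):
        marey = build_marey_profile(gmap, single_contig_pseudo(1000))
    assert marey == {}


# -- sliding windows -------------------------------------------------

def test_linear_marey_constant_rate():
    marey = {"chr01": (np.array([0, 3_000_000]), np.array([0.0, 3.0]))}
    profile = sliding_window_rate(marey, {"chr01": 3_000_000}, cfg())
    assert np.allclose(profile.windows["rate_cM_per_Mbp"], 1.0)


def test_window_count_formula():
    # floor((3e6 - 1e6)/2e5) + 1 = 11
    marey = {"chr01": (np.array([0, 3_000_000]), np.array([0.0, 3.0]))}
    profile = sliding_window_rate(marey, {"chr01": 3_000_000}, cfg())
    assert len(profile.windows) == 11
    assert profile.windows["window_start"].tolist() == [
        i * 200_000 for i in range(11)
    ]


def test_flat_segment_zero_rate():
    marey = {
        "chr01": (
            np.array([0, 1_000_000, 2_500_000, 3_000_000]),
            np.array([0.0, 2.0, 2.0, 3.0]),
        )
    }
    profile = sliding_window_rate(marey, {"chr01": 3_000_000}, cfg())
    w = profile.windows
    flat = w[(w["window_start"] >= 1_000_000) & (w["window_end"] <= 2_500_000)]
    assert len(flat) > 0
    assert np.allclose(flat["rate_cM_per_Mbp"], 0.0)


def test_interpolation_monotone():
    rng = np.random.default_rng(0)
    bp = np.sort(rng.choice(np.arange(1, 5_000_000), 50, replace=False))
    cm = np.sort(rng.uniform(0, 40, 50))
    q = np.sort(rng.integers(0, 5_000_000, 500))
    vals = interpolate_cm((bp, cm), q)
    assert np.all(np.diff(vals) >= -1e-12)


def test_telescoping_identity_step_equals_window():
    rng = np.random.default_rng(1)
    bp = np.sort(rng.choice(np.arange(1, 4_000_000 - 1), 30, replace=False))
    bp[0], bp[-1] = 0, 4_000_000  # markers at both ends
    cm = np.sort(rng.uniform(0, 33, 30))
    cm[0] = 0.0
    config = cfg(marey_window_bp=1_000_000, marey_step_bp=1_000_000)
    profile = sliding_window_rate({"chr01": (bp, cm)}, {"chr01": 4_000_000}, config)
    total = (profile.windows["rate_cM_per_Mbp"] * 1.0).sum()  # rate x 1 Mbp
    assert total == pytest.approx(cm[-1] - cm[0], abs=1e-9)


# -- pericentromere calls -------------------------------------------

def profile_from_rates(rates, window=1_000_000, step=1_000_000):
    rows = [
        ("chr01", i * step, i * step + window, r) for i, r in enumerate(rates)
    ]
    return RecombinationProfile(
        windows=pd.DataFrame(
            rows, columns=["chrom", "window_start", "window_end", "rate_cM_per_Mbp"]
        ),
        window_bp=window,
        step_bp=step,
    )


def test_merge_consecutive_low_windows():
    profile = profile_from_rates([5.0, 0.4, 0.3, 6.0])
    peri = call_pericentromeres(profile, cfg())
    assert len(peri) == 1
    assert peri.iloc[0]["start"] == 1_000_000
    assert peri.iloc[0]["end"] == 3_000_000


def test_all_rates_at_or_above_threshold_empty():
    # exactly 0.5 is NOT low-rate (strict inequality)
    profile = profile_from_rates([0.5, 0.6, 5.0])
    peri = call_pericentromeres(profile, cfg())
    assert len(peri) == 0


def test_overlapping_low_windows_merge():
    profile = profile_from_rates([5.0, 0.4, 0.4, 5.0], window=1_000_000, step=200_000)
    peri = call_pericentromeres(profile, cfg())
    assert len(peri) == 1
    assert peri.iloc[0]["start"] == 200_000
    assert peri.iloc[0]["end"] == 1_400_000


def test_threshold_monotonicity():
    rng = np.random.default_rng(2)
    profile = profile_from_rates(rng.uniform(0, 2, 30))
    prev = None
    # larger Mbp/cM -> lower rate threshold -> intervals shrink
    for mbp_per_cm in (1.0, 2.0, 4.0):
        peri = call_pericentromeres(profile, cfg(pericentromere_mbp_per_cm=mbp_per_cm))
        covered = set()
        for _, row in peri.iterrows():
            covered |= set(range(int(row["start"]) // 1_000_000, int(row["end"]) // 1_000_000))
        if prev is not None:
            assert covered <= prev
        prev = covered


def test_simulated_plateau_jaccard():
    from mapanchor.simulate.genome import simulate_genome

    # arm rate 1.0 cM/Mbp, plateau 0.1 cM/Mbp over the central 30% of 20 Mbp
    L, f, ratio = 20_000_000, 0.3, 0.1
    G = 1.0 * (L / 1e6) * (1 - f + ratio * f)
    genome = simulate_genome(1, [L], [G], plateau_fraction=f,
                             plateau_rate_ratio=ratio, marker_density=50, seed=4)
    c = genome.chromosomes[0]
    pos = genome.markers["pos"].to_numpy()
    marey = {"chr01": (pos, c.marey(pos))}
    profile = sliding_window_rate(marey, {"chr01": L}, cfg())
    peri = call_pericentromeres(profile, cfg())
    assert len(peri) == 1
    a, b = c.plateau
    s, e = int(peri.iloc[0]["start"]), int(peri.iloc[0]["end"])
    inter = max(0, min(b, e) - max(a, s))
    union = max(b, e) - min(a, s)
    assert inter / union >= 0.8


# -- summary stats ---------------------------------------------------

def test_kbp_per_cm_simple_division():
    gmap = gmap_from(
        [("m1", "c1", 0, "chr01", 0.0), ("m2", "c1", 9_999_999, "chr01", 50.0)]
    )
    stats = map_summary_stats(gmap, single_contig_pseudo(10_000_000))
    assert stats["per_chromosome"]["chr01"]["kbp_per_cm"] == pytest.approx(200.0)


def test_mean_cm_spacing():
    gmap = gmap_from(
        [
            ("m1", "c1", 0, "chr01", 0.0),
            ("m2", "c1", 1000, "chr01", 4.0),
            ("m3", "c1", 2000, "chr01", 10.0),
        ]
    )
    stats = map_summary_stats(gmap, single_contig_pseudo(10_000))
    assert stats["mean_cm_spacing"] == pytest.approx(5.0)


def test_cosegregating_markers_collapse_to_one_locus():
    gmap = gmap_from(
        [
            ("m1", "c1", 0, "chr01", 0.0),
            ("m2", "c1", 1000, "chr01", 0.0),  # co-segregating with m1
            ("m3", "c1", 2000, "chr01", 5.0),
        ]
    )
    stats = map_summary_stats(gmap, single_contig_pseudo(10_000))
    assert stats["n_markers"] == 3
    assert stats["n_unique_loci"] == 2
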