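"""Marey profiles, sliding-window recombination rates, pericentromere calls.

Genetic position at an arbitrary bp is obtained by linear interpolation
between flanking anchored markers, with constant extrapolation beyond the
terminal markers. Windows advance from position 0 by the configured step;
trailing partial windows are dropped, so a chromosome of length L carries
floor((L - window) / step) + 1 windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mapanchor.assembly import PseudomoleculeSet
from mapanchor.config import PipelineConfig
from mapanchor.genetics.genetic_map import GeneticMap
from mapanchor.anchoring import marker_object_positions

logger = logging.getLogger(__name__)


def build_marey_profile(
    gmap: GeneticMap, pseudo: PseudomoleculeSet
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (bp, cM) point sets from anchored markers.

    Points are sorted by physical position; duplicated positions collapse
    to the maximum cM; chromosomes with fewer than 2 points are excluded
    with a warning.
    """
    obj_pos = marker_object_positions(pseudo, gmap.markers.rename(columns={"position": "pos"}))
    merged = obj_pos.merge(
        gmap.markers[["marker_id", "cM"]], on="marker_id", how="inner"
    )
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in merged.groupby("chrom", sort=True):
        bp = grp["obj_pos"].to_numpy()
        cm = grp["cM"].to_numpy()
        order = np.argsort(bp, kind="mergesort")
        bp, cm = bp[order], cm[order]
        collapsed = pd.DataFrame({"bp": bp, "cm": cm}).groupby("bp")["cm"].max()
        bp = collapsed.index.to_numpy()
        cm = np.maximum.accumulate(collapsed.to_numpy())
        if len(bp) < 2:
            logger.warning("chromosome %s has <2 anchored markers; excluded", chrom)
            continue
        out[str(chrom)] = (bp, cm)
    return out


@dataclass
class RecombinationProfile:
    """Windowed recombination rates (cM/Mbp) per chromosome."""

    windows: pd.DataFrame  # chrom, window_start, window_end, rate_cM_per_Mbp
    window_bp: int
    step_bp: int


def interpolate_cm(points: tuple[np.ndarray, np.ndarray], at_bp) -> np.ndarray:
    """Linear interpolation of a Marey point set, constant beyond the ends."""
    bp, cm = points
    return np.interp(at_bp, bp, cm)


def sliding_window_rate(
    marey: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
) -> RecombinationProfile:
    """Rate per window: (cM at window end - cM at window start) / window Mbp."""
    w = config.marey_window_bp
    step = config.marey_step_bp
    rows = []
    for chrom in sorted(marey):
        L = chrom_lengths[chrom]
        if L < w:
            logger.warning("chromosome %s shorter than the window; skipped", chrom)
            continue
        n_windows = (L - w) // step + 1
        starts = np.arange(n_windows) * step
        ends = starts + w
        cm_start = interpolate_cm(marey[chrom], starts)
        cm_end = interpolate_cm(marey[chrom], ends)
        rates = (cm_end - cm_start) / (w / 1e6)
        for s, e, r in zip(starts, ends, rates):
            rows.append((chrom, int(s), int(e), float(r)))
    windows = pd.DataFrame(
        rows, columns=["chrom", "window_start", "window_end", "rate_cM_per_Mbp"]
    )
    return RecombinationProfile(windows=windows, window_bp=w, step_bp=step)


def call_pericentromeres(
    profile: RecombinationProfile, config: PipelineConfig
) -> pd.DataFrame:
    """Merge consecutive low-rate windows into pericentromeric intervals.

    A window is low-rate iff its rate is strictly below
    1 / pericentromere_mbp_per_cm cM/Mbp (0.5 at the default 2 Mbp/cM);
    boundary equality is not low-rate. Overlapping/adjacent low windows
    merge into maximal intervals. Returns BED-like (chrom, start, end).
    """
    threshold = 1.0 / config.pericentromere_mbp_per_cm
    rows = []
    for chrom, grp in profile.windows.groupby("chrom", sort=True):
        grp = grp.sort_values("window_start")
        cur: list[int] | None = None
        for _, row in grp.iterrows():
            if row["rate_cM_per_Mbp"] < threshold:
                s, e = int(row["window_start"]), int(row["window_end"])
                if cur is not None and s <= cur[1]:
                    cur[1] = max(cur[1], e)
                else:
                    if cur is not None:
                        rows.append((chrom, cur[0], cur[1]))
                    cur = [s, e]
            else:
                if cur is not None:
                    rows.append((chrom, cur[0], cur[1]))
                    cur = None
        if cur is not None:
            rows.append((chrom, cur[0], cur[1]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def map_summary_stats(gmap: GeneticMap, pseudo: PseudomoleculeSet) -> dict:
    """Headline map statistics.

    Unique loci collapse markers at identical (contig, cM); spacing
    statistics are over adjacent loci along each chromosome;
    kbp-per-cM is physical length / genetic length per chromosome.
    """
    mk = gmap.markers
    n_markers = len(mk)
    loci = mk.drop_duplicates(subset=["contig", "cM"])
    marey = build_marey_profile(gmap, pseudo)
    cm_spacings: list[np.ndarray] = []
    mbp_spacings: list[np.ndarray] = []
    per_chrom = {}
    lengths = {obj.name: obj.length for obj in pseudo.objects}
    for chrom, (bp, cm) in marey.items():
        dcm = np.diff(cm)
        dbp = np.diff(bp)
        cm_spacings.append(dcm)
        mbp_spacings.append(dbp / 1e6)
        total_cm = float(cm[-1] - cm[0])
        phys = lengths.get(chrom, int(bp[-1] - bp[0]))
        per_chrom[chrom] = {
            "genetic_length_cm": total_cm,
            "physical_length_bp": int(phys),
            "kbp_per_cm": (phys / 1000.0) / total_cm if total_cm > 0 else float("inf"),
            "largest_gap_cm": float(dcm.max()) if len(dcm) else 0.0,
        }
    all_dcm = np.concatenate(cm_spacings) if cm_spacings else np.empty(0)
    all_dmbp = np.concatenate(mbp_spacings) if mbp_spacings else np.empty(0)
    return {
        "total_cm": gmap.total_cm(),
        "n_markers": int(n_markers),
        "n_unique_loci": int(len(loci)),
        "mean_cm_spacing": float(all_dcm.mean()) if len(all_dcm) else float("nan"),
        "mean_mbp_spacing": float(all_dmbp.mean()) if len(all_dmbp) else float("nan"),
        "per_chromosome": per_chrom,
    }
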