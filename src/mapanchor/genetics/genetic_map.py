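"""Genetic maps from recombination-breakpoint counts, plus the Kosambi map.

Interval centimorgans follow the breakpoint rule
``cM = 100 * breakpoints / (generations_of_crossover * n_samples)``:
breakpoints are sample label changes across an adjacent-marker interval,
divided by the number of crossover opportunities accumulated by the
population. Cumulative positions are prefix sums along the anchored order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import ParentalHaplotypeMatrix


@dataclass
class GeneticMap:
    """Per-marker (linkage group, cumulative cM) plus interval detail.

    ``markers`` columns: marker_id, contig, position, linkage_group, cM —
    rows in anchored order within each group, cM non-decreasing.
    ``intervals`` columns: linkage_group, left_marker, right_marker,
    breakpoints, cM.
    """

    markers: pd.DataFrame
    intervals: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        for group, grp in self.markers.groupby("linkage_group", sort=False):
            cm = grp["cM"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"cumulative cM decreases within group {group}")
        if (self.intervals["cM"] < 0).any():
            raise ValueError("negative interval cM")

    def total_cm(self) -> float:
        return float(
            self.markers.groupby("linkage_group")["cM"].max().sum()
        )

    def group_cm(self) -> pd.Series:
        return self.markers.groupby("linkage_group")["cM"].max()


def count_breakpoints_and_estimate_cm(
    h: ParentalHaplotypeMatrix,
    order: dict[str, np.ndarray],
    config: PipelineConfig,
) -> GeneticMap:
    """Estimate a genetic map along a fixed anchored marker order.

    Parameters
    ----------
    h : imputed parental labels (no missing entries).
    order : per linkage group, marker row indices of ``h`` in anchored order.
    """
    n = h.n_samples
    denom = config.generations_of_crossover * n
    marker_rows = []
    interval_rows = []
    for group, idx in order.items():
        idx = np.asarray(idx)
        lab = h.labels[idx]
        ids = h.markers["marker_id"].to_numpy()[idx]
        contigs = h.markers["contig"].to_numpy()[idx]
        pos = h.markers["pos"].to_numpy()[idx]
        breaks = (lab[1:] != lab[:-1]).sum(axis=1) if len(idx) > 1 else np.empty(0, int)
        interval_cm = 100.0 * breaks / denom
        cum = np.concatenate(([0.0], np.cumsum(interval_cm)))
        for k in range(len(idx)):
            marker_rows.append((ids[k], contigs[k], int(pos[k]), group, float(cum[k])))
        for k in range(len(breaks)):
            interval_rows.append(
                (group, ids[k], ids[k + 1], int(breaks[k]), float(interval_cm[k]))
            )
    markers = pd.DataFrame(
        marker_rows, columns=["marker_id", "contig", "position", "linkage_group", "cM"]
    )
    intervals = pd.DataFrame(
        interval_rows,
        columns=["linkage_group", "left_marker", "right_marker", "breakpoints", "cM"],
    )
    return GeneticMap(markers=markers, intervals=intervals, n_samples=n)


def kosambi_cm(r):
    """Kosambi map distance in cM: 25 * ln((1 + 2r) / (1 - 2r)).

    Accepts scalars or arrays; requires 0 <= r < 0.5.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    # log1p keeps precision for r near 0
    out = 25.0 * (np.log1p(2.0 * r_arr) - np.log1p(-2.0 * r_arr))
    return float(out) if np.isscalar(r) else out
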