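"""Linkage disequilibrium: pairwise r², contig linkage groups, decay curves.

r² is the squared Pearson correlation of 0/1 allele indicators over samples
that are non-missing homozygotes at both markers (the population is inbred,
so heterozygotes are excluded pairwise). An undefined r² — fewer than two
complete samples, or a marker monomorphic after exclusion — is NaN, never
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import CALL_A, CALL_B, MarkerGenotypeMatrix, ParentalHaplotypeMatrix
from mapanchor.rng import substream


def _calls_and_markers(m) -> tuple[np.ndarray, pd.DataFrame]:
    if isinstance(m, ParentalHaplotypeMatrix):
        return m.labels, m.markers
    if isinstance(m, MarkerGenotypeMatrix):
        cols = m.non_parent_columns()
        return m.calls[:, cols], m.markers
    raise TypeError(f"unsupported matrix type {type(m)!r}")


def batch_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """r² for row-aligned call matrices of shape (k, n); NaN where undefined."""
    x = np.atleast_2d(x)
    y = np.atleast_2d(y)
    hx = (x == CALL_A) | (x == CALL_B)
    hy = (y == CALL_A) | (y == CALL_B)
    valid = hx & hy
    xf = np.where(valid, x, 0).astype(float)
    yf = np.where(valid, y, 0).astype(float)
    n = valid.sum(axis=1).astype(float)
    sx = xf.sum(axis=1)
    sy = yf.sum(axis=1)
    sxy = (xf * yf).sum(axis=1)
    # 0/1 values: sum of squares equals the sum
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = n * sxy - sx * sy
        var_x = n * sx - sx * sx
        var_y = n * sy - sy * sy
        r2 = (cov * cov) / (var_x * var_y)
    r2[(n < 2) | (var_x <= 0) | (var_y <= 0)] = np.nan
    return r2


def pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """r² between two call vectors (A=0, B=1, H/missing excluded pairwise)."""
    return float(batch_r2(np.asarray(a)[None, :], np.asarray(b)[None, :])[0])


@dataclass
class ContigLinkageGraph:
    """Contigs as nodes; an edge records high-LD marker-pair support."""

    graph: nx.Graph

    def edges_table(self) -> pd.DataFrame:
        rows = [
            (a, b, d["n_support"], d["max_r2"])
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["contig_a", "contig_b", "n_support", "max_r2"])


def _subsample_pairs(
    n1: int, n2: int, cap: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    total = n1 * n2
    if total <= cap:
        flat = np.arange(total)
    else:
        flat = rng.choice(total, size=cap, replace=False)
        flat.sort()
    return flat // n2, flat % n2


def infer_linkage_groups(
    m,
    config: PipelineConfig,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[dict[str, str], ContigLinkageGraph]:
    """Cluster contigs into linkage groups via high-LD inter-contig pairs.

    An edge joins two contigs when at least ``min_ld_pairs`` evaluated
    marker pairs (deterministically subsampled to ``ld_pair_cap`` per
    contig pair) have r² above ``r2_threshold``. Groups are the connected
    components, named LG01, LG02, ... by decreasing total contig length
    (ties by lexicographically smallest contig id).
    """
    calls, markers = _calls_and_markers(m)
    by_contig = {
        str(c): grp.index.to_numpy() for c, grp in markers.groupby("contig", sort=True)
    }
    contigs = sorted(by_contig)
    g = nx.Graph()
    g.add_nodes_from(contigs)
    for i, c1 in enumerate(contigs):
        idx1 = by_contig[c1]
        for c2 in contigs[i + 1 :]:
            idx2 = by_contig[c2]
            rng = substream(config.seed, f"ld_pairs/{c1}|{c2}")
            pi, pj = _subsample_pairs(len(idx1), len(idx2), config.ld_pair_cap, rng)
            r2 = batch_r2(calls[idx1[pi]], calls[idx2[pj]])
            high = r2 > config.r2_threshold  # NaN compares False
            n_support = int(high.sum())
            if n_support >= config.min_ld_pairs:
                g.add_edge(c1, c2, n_support=n_support, max_r2=float(np.nanmax(r2)))

    def _length(c: str) -> int:
        if contig_lengths is not None:
            return int(contig_lengths[c])
        return int(markers["pos"].to_numpy()[by_contig[c]].max()) + 1

    comps = sorted(
        nx.connected_components(g),
        key=lambda comp: (-sum(_length(c) for c in comp), min(comp)),
    )
    assignment: dict[str, str] = {}
    for k, comp in enumerate(comps):
        name = f"LG{k + 1:02d}"
        for c in comp:
            assignment[c] = name
    return assignment, ContigLinkageGraph(graph=g)


def marker_group_labels_loo(
    m,
    linkage: ContigLinkageGraph,
    config: PipelineConfig,
    markers_per_neighbor: int = 20,
) -> dict[str, np.ndarray]:
    """Per-marker group labels by leave-one-out linkage, for chimera screening.

    For each contig, the focal contig is removed from the linkage graph and
    its markers are assigned to the remaining connected components they
    link to (r² above threshold against markers of neighbouring contigs).
    A chimeric contig bridges two components, so its markers split between
    them once it is removed. Markers without any high-LD support carry
    label -1.
    """
    calls, markers = _calls_and_markers(m)
    by_contig = {
        str(c): grp.index.to_numpy() for c, grp in markers.groupby("contig", sort=True)
    }
    g = linkage.graph
    out: dict[str, np.ndarray] = {}
    for contig, idx in by_contig.items():
        labels = np.full(len(idx), -1, dtype=int)
        if contig in g and g.degree(contig) > 0:
            rest = g.copy()
            rest.remove_node(contig)
            comp_of: dict[str, int] = {}
            for k, comp in enumerate(
                sorted(nx.connected_components(rest), key=min)
            ):
                for c in comp:
                    comp_of[c] = k
            support = np.zeros((len(idx), max(comp_of.values()) + 1), dtype=int)
            for nbr in sorted(g.neighbors(contig)):
                nidx = by_contig[nbr]
                if len(nidx) > markers_per_neighbor:
                    take = np.linspace(0, len(nidx) - 1, markers_per_neighbor).astype(int)
                    nidx = nidx[np.unique(take)]
                pi = np.repeat(np.arange(len(idx)), len(nidx))
                pj = np.tile(np.arange(len(nidx)), len(idx))
                r2 = batch_r2(calls[idx[pi]], calls[nidx[pj]])
                high = (r2 > config.r2_threshold).reshape(len(idx), len(nidx))
                support[:, comp_of[nbr]] += high.sum(axis=1)
            has = support.sum(axis=1) > 0
            labels[has] = support[has].argmax(axis=1)
        out[contig] = labels
    return out


def ld_discontinuity_blocks(
    calls: np.ndarray,
    rows: np.ndarray,
    config: PipelineConfig,
    flank: int = 5,
) -> np.ndarray:
    """Segment one contig's markers at within-contig LD breaks.

    ``rows`` indexes ``calls`` in positional order. A boundary between
    adjacent markers is open when no pair among the ``flank`` markers on
    each side exceeds the r² threshold — the signature of a chimeric
    junction even when the joined chromosomes are connected elsewhere in
    the contig graph. Returns integer block labels (0, 1, ...).
    """
    n = len(rows)
    labels = np.zeros(n, dtype=int)
    block = 0
    for k in range(1, n):
        left = rows[max(0, k - flank) : k]
        right = rows[k : k + flank]
        pi = np.repeat(np.arange(len(left)), len(right))
        pj = np.tile(np.arange(len(right)), len(left))
        r2 = batch_r2(calls[left[pi]], calls[right[pj]])
        if not np.any(r2 > config.r2_threshold):
            block += 1
        labels[k] = block
    return labels


def refine_block_labels(
    calls: np.ndarray,
    rows: np.ndarray,
    labels: np.ndarray,
    config: PipelineConfig,
    flank: int = 5,
) -> np.ndarray:
    """Denoise per-marker group labels along one contig.

    ``rows`` indexes ``calls`` in positional order along the contig and is
    row-aligned with ``labels``. Adjacent label runs whose flanking
    markers are in direct high LD are relabelled to one group: a noisy or
    mislabelled marker still correlates with its physical neighbours,
    and a contig bridging two arms of its own chromosome links them
    itself — whereas blocks across a true chimera junction show no LD.
    """
    labels = np.asarray(labels).copy()
    n = len(labels)
    # merge adjacent runs in direct LD
    changed = True
    while changed:
        changed = False
        run_starts = []
        k = 0
        while k < n:
            j = k
            while j < n and labels[j] == labels[k]:
                j += 1
            if labels[k] >= 0:
                run_starts.append((k, j))
            k = j
        for (a0, a1), (b0, b1) in zip(run_starts[:-1], run_starts[1:]):
            if labels[a0] == labels[b0]:
                continue
            left = rows[max(a0, a1 - flank) : a1]
            right = rows[b0 : min(b1, b0 + flank)]
            pi = np.repeat(np.arange(len(left)), len(right))
            pj = np.tile(np.arange(len(right)), len(left))
            r2 = batch_r2(calls[left[pi]], calls[right[pj]])
            if np.any(r2 > config.r2_threshold):
                labels[labels == labels[b0]] = labels[a0]
                changed = True
                break
    return labels


def ld_decay(
    m,
    chroms: np.ndarray,
    positions: np.ndarray,
    bin_width: int,
    max_distance: int,
) -> pd.DataFrame:
    """Mean r² in physical-distance bins over same-chromosome marker pairs.

    ``chroms``/``positions`` give each marker's anchored coordinates, row-
    aligned with the matrix. Undefined r² pairs are excluded from both the
    numerator and the pair count. Returns columns bin_start, bin_end,
    mean_r2, n_pairs; empty bins carry NaN mean.
    """
    calls, _ = _calls_and_markers(m)
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    n_bins = int(np.ceil(max_distance / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for ch in np.unique(chroms):
        rows = np.flatnonzero(chroms == ch)
        order = np.argsort(positions[rows], kind="mergesort")
        rows = rows[order]
        pos = positions[rows]
        hi = np.searchsorted(pos, pos + max_distance, side="right")
        ii = []
        jj = []
        for k in range(len(rows)):
            if hi[k] > k + 1:
                ii.append(np.full(hi[k] - k - 1, k))
                jj.append(np.arange(k + 1, hi[k]))
        if not ii:
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        for lo in range(0, len(ii), 200_000):
            sl = slice(lo, lo + 200_000)
            r2 = batch_r2(calls[rows[ii[sl]]], calls[rows[jj[sl]]])
            dist = pos[jj[sl]] - pos[ii[sl]]
            ok = ~np.isnan(r2) & (dist < max_distance)
            b = dist[ok] // bin_width
            np.add.at(sums, b, r2[ok])
            np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_start": np.arange(n_bins) * bin_width,
            "bin_end": np.minimum((np.arange(n_bins) + 1) * bin_width, max_distance),
            "mean_r2": mean,
            "n_pairs": counts,
        }
    )
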