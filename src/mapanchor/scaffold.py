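"""Barcode-sharing scaffold graph over contig ends and greedy path clustering.

Contig ends are (contig, "head"|"tail") nodes; shared barcodes between ends
of different contigs are linkage evidence. Accepted edges plus the implicit
internal edge joining each contig's two ends decompose into simple paths —
the scaffolds. A greedy acceptance in decreasing weight order with
cycle prevention (union-find over contigs) plays the role of the
Hi-C-style clustering step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mapanchor.config import PipelineConfig
from mapanchor.io.tables import BarcodeAlignmentTable

HEAD = "head"
TAIL = "tail"

End = tuple[str, str]


def collect_end_barcodes(
    aln: BarcodeAlignmentTable,
    contig_lengths: dict[str, int],
    config: PipelineConfig,
) -> dict[End, set]:
    """Barcode sets per contig end.

    The head window is [0, w) and the tail window [L - w, L) with
    w = min(end_window_bp, floor(L / 2)); a barcode may land in both sets
    of a short contig. Every contig gets (possibly empty) entries.
    """
    aln.validate(contig_lengths)
    sets: dict[End, set] = {}
    for contig, length in contig_lengths.items():
        sets[(contig, HEAD)] = set()
        sets[(contig, TAIL)] = set()
    df = aln.df
    w = np.minimum(
        config.end_window_bp,
        df["contig"].map(contig_lengths).to_numpy() // 2,
    )
    pos = df["pos"].to_numpy()
    lens = df["contig"].map(contig_lengths).to_numpy()
    in_head = pos < w
    in_tail = pos >= lens - w
    for mask, end in ((in_head, HEAD), (in_tail, TAIL)):
        sub = df[mask]
        for contig, grp in sub.groupby("contig"):
            sets[(str(contig), end)].update(grp["barcode"])
    return sets


@dataclass
class ScaffoldGraph:
    """External edges between contig ends, with shared-barcode evidence."""

    edges: pd.DataFrame  # columns: end_a, end_b, n_shared, weight
    contigs: list[str]

    def __post_init__(self) -> None:
        for _, row in self.edges.iterrows():
            if row["end_a"][0] == row["end_b"][0]:
                raise ValueError("external edge joins the two ends of one contig")


def build_scaffold_graph(
    end_sets: dict[End, set],
    config: PipelineConfig,
) -> ScaffoldGraph:
    """Count shared barcodes between ends of different contigs.

    Barcodes present at more than ``max_end_occurrences`` ends are
    discarded globally as promiscuous (repeat-driven) before counting.
    Edges with fewer than ``min_shared_barcodes`` shared barcodes are
    dropped; the retained weight is count / min(|set1|, |set2|) computed
    on the promiscuity-filtered sets.
    """
    occurrences: dict[str, int] = {}
    for s in end_sets.values():
        for bc in s:
            occurrences[bc] = occurrences.get(bc, 0) + 1
    promiscuous = {bc for bc, n in occurrences.items() if n > config.max_end_occurrences}
    filtered = {end: s - promiscuous for end, s in end_sets.items()}
    barcode_ends: dict[str, list[End]] = {}
    for end, s in filtered.items():
        for bc in s:
            barcode_ends.setdefault(bc, []).append(end)
    counts: dict[tuple[End, End], int] = {}
    for bc, ends in barcode_ends.items():
        ends = sorted(ends)
        for i in range(len(ends)):
            for j in range(i + 1, len(ends)):
                if ends[i][0] == ends[j][0]:
                    continue
                key = (ends[i], ends[j])
                counts[key] = counts.get(key, 0) + 1
    rows = []
    for (ea, eb), n in sorted(counts.items()):
        if n < config.min_shared_barcodes:
            continue
        denom = min(len(filtered[ea]), len(filtered[eb]))
        rows.append((ea, eb, n, n / denom if denom else 0.0))
    edges = pd.DataFrame(rows, columns=["end_a", "end_b", "n_shared", "weight"])
    contigs = sorted({end[0] for end in end_sets})
    return ScaffoldGraph(edges=edges, contigs=contigs)


@dataclass
class ScaffoldPath:
    """Ordered, oriented contigs: tail->head joins keep both '+'."""

    contigs: list[tuple[str, str]]  # (contig_id, orientation)
    join_weights: list[float] = field(default_factory=list)

    @property
    def contig_ids(self) -> list[str]:
        return [c for c, _ in self.contigs]


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def greedy_scaffold_paths(g: ScaffoldGraph) -> list[ScaffoldPath]:
    """Accept edges by decreasing weight; reject used ends and cycles.

    Tie-breaking is total — (weight desc, count desc, lexicographic end
    pair) — so the decomposition is invariant to input edge order.
    Singleton contigs become length-1 '+' paths.
    """
    edges = sorted(
        g.edges.itertuples(index=False),
        key=lambda e: (-e.weight, -e.n_shared, e.end_a, e.end_b),
    )
    uf = _UnionFind(g.contigs)
    used_ends: set[End] = set()
    accepted: dict[End, tuple[End, float]] = {}
    for e in edges:
        if e.end_a in used_ends or e.end_b in used_ends:
            continue
        if not uf.union(e.end_a[0], e.end_b[0]):
            continue  # would close a cycle
        used_ends.update((e.end_a, e.end_b))
        accepted[e.end_a] = (e.end_b, e.weight)
        accepted[e.end_b] = (e.end_a, e.weight)
    paths: list[ScaffoldPath] = []
    visited: set[str] = set()
    # cycles are impossible, so every path has two free ends; traversing
    # from each free end and skipping visited contigs covers all paths once
    for contig in sorted(g.contigs):
        for free_end in (HEAD, TAIL):
            if contig in visited or (contig, free_end) in accepted:
                continue
            chain: list[tuple[str, str]] = []
            weights: list[float] = []
            cur, entry = contig, free_end
            while True:
                # entering at the head means traversing head->tail: '+'
                chain.append((cur, "+" if entry == HEAD else "-"))
                visited.add(cur)
                exit_end = TAIL if entry == HEAD else HEAD
                link = accepted.get((cur, exit_end))
                if link is None:
                    break
                (nxt_contig, nxt_end), w = link
                weights.append(w)
                cur, entry = nxt_contig, nxt_end
            # canonical direction: lexicographically smallest contig sequence
            rev = [(c, "-" if o == "+" else "+") for c, o in reversed(chain)]
            if (rev, [w for w in reversed(weights)]) < (chain, weights):
                chain = rev
                weights = weights[::-1]
            paths.append(ScaffoldPath(contigs=chain, join_weights=weights))
            break
    paths.sort(key=lambda p: p.contig_ids[0])
    return paths


# -- misassembly detection -------------------------------------------


@dataclass
class MisassemblyCall:
    contig: str
    break_positions: list[int]
    unresolvable: bool = False


def _barcode_continuity(
    positions: np.ndarray, barcodes: np.ndarray, breakpoint: int, window: int
) -> int:
    """Barcodes with at least one read on each side of ``breakpoint``
    within ``window`` bp."""
    left = (positions >= breakpoint - window) & (positions < breakpoint)
    right = (positions >= breakpoint) & (positions < breakpoint + window)
    return len(set(barcodes[left]) & set(barcodes[right]))


def detect_misassemblies(
    contig: str,
    contig_length: int,
    aln: BarcodeAlignmentTable,
    marker_positions: np.ndarray,
    marker_groups: np.ndarray,
    config: PipelineConfig,
) -> MisassemblyCall:
    """Call breakpoints where a contig's markers disagree on linkage group.

    ``marker_groups`` holds per-marker group labels (−1 = unassigned,
    ignored). A break is called between consecutive runs of discordant
    groups, at the barcode-continuity minimum scanned across the
    inter-marker gap in ``misassembly_scan_step_bp`` steps — but only when
    fewer than ``misassembly_max_span_barcodes`` barcodes span the best
    candidate, since molecules freely span any genuine junction-free
    position. Interleaved (non-contiguous) groups make the contig
    unresolvable.
    """
    marker_positions = np.asarray(marker_positions)
    marker_groups = np.asarray(marker_groups)
    order = np.argsort(marker_positions, kind="mergesort")
    pos = marker_positions[order]
    grp = marker_groups[order]
    known = grp >= 0
    pos, grp = pos[known], grp[known]
    if len(pos) < 2 or len(np.unique(grp)) < 2:
        return MisassemblyCall(contig=contig, break_positions=[])
    runs = [grp[0]]
    run_bounds = []  # (last pos of run k, first pos of run k+1)
    for k in range(1, len(grp)):
        if grp[k] != runs[-1]:
            runs.append(grp[k])
            run_bounds.append((int(pos[k - 1]), int(pos[k])))
    if len(set(runs)) != len(runs):
        return MisassemblyCall(contig=contig, break_positions=[], unresolvable=True)
    sub = aln.df[aln.df["contig"] == contig]
    apos = sub["pos"].to_numpy()
    abc = sub["barcode"].to_numpy()
    breaks = []
    for lo, hi in run_bounds:
        step = config.misassembly_scan_step_bp
        mid = (lo + hi) / 2.0

        def _best(cands):
            best = None
            for p in cands:
                cont = _barcode_continuity(apos, abc, p, config.end_window_bp)
                key = (cont, abs(p - mid), p)
                if best is None or key < best[0]:
                    best = (key, p)
            return best

        cands = list(range(lo + 1, hi + 1, step))
        if not cands or cands[-1] != hi:
            cands.append(hi)
        coarse = _best(cands)
        # refine around the coarse minimum: the continuity dip at a real
        # junction is much narrower than the coarse scan step
        fine_step = max(step // 10, 500)
        p0 = coarse[1]
        fine = _best(range(max(lo + 1, p0 - step), min(hi, p0 + step) + 1, fine_step))
        best = min(coarse, fine)
        if best[0][0] < config.misassembly_max_span_barcodes:
            breaks.append(int(best[1]))
    return MisassemblyCall(contig=contig, break_positions=breaks)


def split_alignment_table(
    aln: BarcodeAlignmentTable, splits: dict[str, list[int]]
) -> BarcodeAlignmentTable:
    """Rename alignment contigs/positions after breaking contigs.

    ``splits`` maps contig -> sorted break positions; pieces are named
    ``<contig>.<k>`` (1-based), matching
    :meth:`~mapanchor.simulate.fragments.TruthPlacement.split_contig`.
    """
    df = aln.df.copy()
    for contig, breaks in splits.items():
        bounds = np.array(sorted(breaks))
        mask = df["contig"] == contig
        pos = df.loc[mask, "pos"].to_numpy()
        piece = np.searchsorted(bounds, pos, side="right")
        offset = np.concatenate(([0], bounds))[piece]
        df.loc[mask, "contig"] = np.array([f"{contig}.{k + 1}" for k in piece])
        df.loc[mask, "pos"] = pos - offset
    return BarcodeAlignmentTable(df).sorted()


def split_marker_table(markers: pd.DataFrame, splits: dict[str, list[int]]) -> pd.DataFrame:
    """Apply the same contig splitting to a marker table (contig, pos)."""
    mk = markers.copy()
    for contig, breaks in splits.items():
        bounds = np.array(sorted(breaks))
        mask = mk["contig"] == contig
        pos = mk.loc[mask, "pos"].to_numpy()
        piece = np.searchsorted(bounds, pos, side="right")
        offset = np.concatenate(([0], bounds))[piece]
        mk.loc[mask, "contig"] = np.array([f"{contig}.{k + 1}" for k in piece])
        mk.loc[mask, "pos"] = pos - offset
    return mk
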