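"""Order and orient scaffolds into pseudomolecules guided by the genetic map.

Within a linkage group, scaffolds are first chained by recombination
fraction between their terminal markers (smallest fraction joins first,
with cycle prevention) to obtain a provisional marker order; breakpoint
counting along that order yields cumulative centimorgans; scaffolds are
then sorted by median marker cM and oriented by the sign of the Spearman
correlation between within-scaffold physical position and cM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mapanchor.assembly import PseudoObject, PseudomoleculeSet, build_object
from mapanchor.config import PipelineConfig
from mapanchor.genetics.genetic_map import GeneticMap, count_breakpoints_and_estimate_cm
from mapanchor.genotypes import ParentalHaplotypeMatrix
from mapanchor.scaffold import HEAD, TAIL, ScaffoldPath, _UnionFind

logger = logging.getLogger(__name__)


# -- scaffold -> linkage group ---------------------------------------


@dataclass
class GroupAssignment:
    groups: dict[str, str]  # scaffold_id -> group
    unplaced: list[str]
    conflicting: list[str]  # flagged for misassembly review


def assign_to_linkage_groups(
    paths: list[ScaffoldPath],
    scaffold_ids: list[str],
    markers: pd.DataFrame,
    contig_groups: dict[str, str],
    config: PipelineConfig,
) -> GroupAssignment:
    """Majority vote of marker linkage groups over each scaffold's contigs.

    A scaffold whose minority-group marker share strictly exceeds the
    conflict threshold is still assigned to the majority group but flagged
    conflicting; markerless scaffolds are unplaced.
    """
    marker_counts = markers.groupby("contig").size().to_dict()
    out: dict[str, str] = {}
    unplaced: list[str] = []
    conflicting: list[str] = []
    for sid, path in zip(scaffold_ids, paths):
        votes: dict[str, int] = {}
        for contig in path.contig_ids:
            grp = contig_groups.get(contig)
            n = marker_counts.get(contig, 0)
            if grp is not None and n > 0:
                votes[grp] = votes.get(grp, 0) + n
        if not votes:
            unplaced.append(sid)
            continue
        total = sum(votes.values())
        best = max(votes.items(), key=lambda kv: (kv[1], kv[0]))[0]
        out[sid] = best
        if (total - votes[best]) / total > config.conflict_minority_share:
            conflicting.append(sid)
    return GroupAssignment(groups=out, unplaced=unplaced, conflicting=conflicting)


# -- ordering and orientation ----------------------------------------


@dataclass
class AnchoredScaffold:
    """A scaffold with marker evidence expressed in scaffold coordinates."""

    scaffold_id: str
    components: list[tuple[str, str]]  # (contig, orientation) left to right
    length: int
    marker_rows: np.ndarray  # rows into the haplotype matrix, scaffold order
    marker_coords: np.ndarray  # scaffold-local bp, increasing
    marker_cm: np.ndarray | None = None

    @property
    def n_markers(self) -> int:
        return len(self.marker_rows)

    def flipped(self) -> "AnchoredScaffold":
        comps = [(c, "-" if o == "+" else "+") for c, o in reversed(self.components)]
        return AnchoredScaffold(
            scaffold_id=self.scaffold_id,
            components=comps,
            length=self.length,
            marker_rows=self.marker_rows[::-1].copy(),
            marker_coords=(self.length - 1 - self.marker_coords)[::-1].copy(),
            marker_cm=None if self.marker_cm is None else self.marker_cm[::-1].copy(),
        )


def scaffold_marker_layout(
    path: ScaffoldPath,
    scaffold_id: str,
    h: ParentalHaplotypeMatrix,
    contig_lengths: dict[str, int],
    gap_bp: int,
) -> AnchoredScaffold:
    """Express a scaffold's markers in scaffold-local coordinates."""
    by_contig = h.contig_marker_index()
    rows: list[np.ndarray] = []
    coords: list[np.ndarray] = []
    offset = 0
    for k, (contig, orient) in enumerate(path.contigs):
        if k > 0:
            offset += gap_bp
        length = contig_lengths[contig]
        idx = by_contig.get(contig)
        if idx is not None and len(idx):
            pos = h.markers["pos"].to_numpy()[idx]
            if orient == "+":
                rows.append(idx)
                coords.append(offset + pos)
            else:
                rows.append(idx[::-1])
                coords.append(offset + (length - 1 - pos)[::-1])
        offset += length
    if rows:
        marker_rows = np.concatenate(rows)
        marker_coords = np.concatenate(coords)
    else:
        marker_rows = np.empty(0, dtype=int)
        marker_coords = np.empty(0, dtype=int)
    return AnchoredScaffold(
        scaffold_id=scaffold_id,
        components=list(path.contigs),
        length=offset,
        marker_rows=marker_rows,
        marker_coords=marker_coords,
    )


def _label_mismatch(a: np.ndarray, b: np.ndarray) -> float:
    """Mismatch fraction over samples with informative calls at both markers."""
    ok = (a <= 1) & (b <= 1)  # A/B only; H and missing excluded pairwise
    n = int(ok.sum())
    if n == 0:
        return 0.5
    return float((a[ok] != b[ok]).mean())


def chain_scaffolds_by_linkage(
    scaffolds: list[AnchoredScaffold], calls: np.ndarray
) -> list[AnchoredScaffold]:
    """Greedy chaining of scaffolds by terminal-marker recombination fraction.

    ``calls`` may be raw polarized calls (H/missing excluded pairwise) or
    imputed labels. Ends of different scaffolds are joined smallest-
    fraction-first, each end used at most once, cycles rejected; over the
    complete end graph this always yields a single path. Returns the
    scaffolds reordered and flipped so terminal markers of neighbours
    face each other.
    """
    if len(scaffolds) == 1:
        return list(scaffolds)
    ids = [s.scaffold_id for s in scaffolds]
    end_label = {}
    for s in scaffolds:
        end_label[(s.scaffold_id, HEAD)] = calls[s.marker_rows[0]]
        end_label[(s.scaffold_id, TAIL)] = calls[s.marker_rows[-1]]
    cands = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            for ea in (HEAD, TAIL):
                for eb in (HEAD, TAIL):
                    r = _label_mismatch(end_label[(a, ea)], end_label[(b, eb)])
                    cands.append((r, a, ea, b, eb))
    cands.sort()
    uf = _UnionFind(ids)
    used: set[tuple[str, str]] = set()
    link: dict[tuple[str, str], tuple[str, str]] = {}
    for r, a, ea, b, eb in cands:
        if (a, ea) in used or (b, eb) in used:
            continue
        if not uf.union(a, b):
            continue
        used.update(((a, ea), (b, eb)))
        link[(a, ea)] = (b, eb)
        link[(b, eb)] = (a, ea)
    start = None
    for sid in ids:
        for end in (HEAD, TAIL):
            if (sid, end) not in link:
                start = (sid, end)
                break
        if start:
            break
    by_id = {s.scaffold_id: s for s in scaffolds}
    ordered: list[AnchoredScaffold] = []
    cur, free_end = start
    while True:
        s = by_id[cur]
        # free/entry end HEAD means the scaffold is traversed left-to-right
        ordered.append(s if free_end == HEAD else s.flipped())
        nxt = link.get((cur, TAIL if free_end == HEAD else HEAD))
        if nxt is None:
            break
        cur, free_end = nxt
    if ordered[0].scaffold_id > ordered[-1].scaffold_id:
        ordered = [s.flipped() for s in reversed(ordered)]
    return ordered


def order_and_orient(
    scaffolds: list[AnchoredScaffold],
    object_name: str,
    gap_bp: int,
    contig_lengths: dict[str, int],
) -> tuple[PseudoObject, set[str]]:
    """Sort scaffolds by median marker cM and orient by the Spearman sign.

    Each scaffold must carry ``marker_cm``. Ties in the median are broken
    by more-markers-first, then scaffold id. Scaffolds with an undefined
    or zero correlation (including single-marker scaffolds) stay '+' and
    are flagged orientation-unknown.
    """
    for s in scaffolds:
        if s.marker_cm is None or s.n_markers == 0:
            raise ValueError(f"scaffold {s.scaffold_id} lacks cM positions")
    ranked = sorted(
        scaffolds,
        key=lambda s: (float(np.median(s.marker_cm)), -s.n_markers, s.scaffold_id),
    )
    flagged: set[str] = set()
    components: list[tuple[str, str, int]] = []
    for s in ranked:
        rho = 0.0
        if s.n_markers >= 2 and len(set(s.marker_cm)) > 1 and len(set(s.marker_coords)) > 1:
            rho = stats.spearmanr(s.marker_coords, s.marker_cm).statistic
        if not np.isfinite(rho) or rho == 0:
            flagged.add(s.scaffold_id)
            oriented = s
        elif rho < 0:
            oriented = s.flipped()
        else:
            oriented = s
        for contig, orient in oriented.components:
            components.append((contig, orient, contig_lengths[contig]))
    return build_object(object_name, components, gap_bp), flagged


def build_pseudomolecules(
    paths: list[ScaffoldPath],
    assignment: GroupAssignment,
    scaffold_ids: list[str],
    h: ParentalHaplotypeMatrix,
    contig_lengths: dict[str, int],
    config: PipelineConfig,
    linkage_calls: np.ndarray | None = None,
) -> tuple[PseudomoleculeSet, GeneticMap, set[str]]:
    """Assemble one pseudomolecule per linkage group and its genetic map.

    ``linkage_calls`` (defaults to the imputed labels) feeds the scaffold
    chaining step; raw polarized calls are preferable there because
    imputation cannot fill missing data on single-marker scaffolds.
    Objects are named chr01, chr02, ... by decreasing total component
    length. The returned map is recomputed along the final anchored order,
    with linkage groups renamed to the object names.
    """
    if linkage_calls is None:
        linkage_calls = h.labels
    by_id = dict(zip(scaffold_ids, paths))
    group_scaffolds: dict[str, list[str]] = {}
    for sid, grp in assignment.groups.items():
        group_scaffolds.setdefault(grp, []).append(sid)
    raw_objects: list[tuple[PseudoObject, set[str]]] = []
    for grp in sorted(group_scaffolds):
        sids = sorted(group_scaffolds[grp])
        anchored = [
            scaffold_marker_layout(by_id[sid], sid, h, contig_lengths, config.agp_gap_bp)
            for sid in sids
        ]
        anchored = [s for s in anchored if s.n_markers > 0]
        if not anchored:
            continue
        chained = chain_scaffolds_by_linkage(anchored, linkage_calls)
        rows = np.concatenate([s.marker_rows for s in chained])
        provisional = count_breakpoints_and_estimate_cm(h, {grp: rows}, config)
        cm = provisional.markers["cM"].to_numpy()
        cursor = 0
        for s in chained:
            s.marker_cm = cm[cursor : cursor + s.n_markers]
            cursor += s.n_markers
        obj, flags = order_and_orient(chained, grp, config.agp_gap_bp, contig_lengths)
        raw_objects.append((obj, flags))
    raw_objects.sort(key=lambda of: (-of[0].length, of[0].name))
    objects = []
    flagged: set[str] = set()
    for k, (obj, flags) in enumerate(raw_objects):
        objects.append(
            PseudoObject(
                name=f"chr{k + 1:02d}", placements=obj.placements, gaps=obj.gaps
            )
        )
        flagged |= flags
    pseudo = PseudomoleculeSet(objects=objects)
    final_order = anchored_marker_order(pseudo, h)
    gmap = count_breakpoints_and_estimate_cm(h, final_order, config)
    return pseudo, gmap, flagged


def anchored_marker_order(
    pseudo: PseudomoleculeSet, h: ParentalHaplotypeMatrix
) -> dict[str, np.ndarray]:
    """Marker rows of ``h`` in anchored order, per pseudomolecule object."""
    by_contig = h.contig_marker_index()
    out: dict[str, np.ndarray] = {}
    for obj in pseudo.objects:
        rows: list[np.ndarray] = []
        for p in obj.placements:
            idx = by_contig.get(p.component)
            if idx is None or len(idx) == 0:
                continue
            rows.append(idx if p.orientation == "+" else idx[::-1])
        if rows:
            out[obj.name] = np.concatenate(rows)
    return out


def marker_object_positions(
    pseudo: PseudomoleculeSet, markers: pd.DataFrame
) -> pd.DataFrame:
    """Object-space coordinates of anchored markers (chrom, obj_pos)."""
    place: dict[str, tuple[str, str, int, int]] = {}
    for obj in pseudo.objects:
        for p in obj.placements:
            place[p.component] = (obj.name, p.orientation, p.obj_start, p.obj_end)
    rows = []
    for _, row in markers.iterrows():
        info = place.get(row["contig"])
        if info is None:
            continue
        name, orient, start, end = info
        pos = int(row["pos"])
        obj_pos = start + pos if orient == "+" else end - 1 - pos
        rows.append((row["marker_id"], name, obj_pos))
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "obj_pos"])


# -- evaluation against the simulation truth -------------------------


def count_false_joins(paths: list[ScaffoldPath], truth) -> int:
    """Scaffold joins between contigs that are not adjacent in the truth."""
    adjacent = truth.true_adjacent_pairs()
    n = 0
    for p in paths:
        ids = p.contig_ids
        for a, b in zip(ids[:-1], ids[1:]):
            if frozenset((a, b)) not in adjacent:
                n += 1
    return n


@dataclass
class EvaluationReport:
    placement_rate: float
    placement_rate_markered: float
    group_purity: float
    adjacency_accuracy: float
    orientation_accuracy: float
    n_anchored: int
    n_contigs: int
    n_unplaced_markered: int = 0
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "placement_rate": self.placement_rate,
            "placement_rate_markered": self.placement_rate_markered,
            "group_purity": self.group_purity,
            "adjacency_accuracy": self.adjacency_accuracy,
            "orientation_accuracy": self.orientation_accuracy,
            "n_anchored": self.n_anchored,
            "n_contigs": self.n_contigs,
            "n_unplaced_markered": self.n_unplaced_markered,
        }


def evaluate_against_truth(
    result: PseudomoleculeSet,
    truth,
    marker_counts: dict[str, int] | None = None,
    min_markers_orientation: int = 3,
) -> EvaluationReport:
    """Score a reconstruction against a TruthPlacement.

    Orientation is compared after composing the result orientation with
    the truth strand, per pseudomolecule up to a global flip (a chromosome
    reconstructed end-to-start is not an orientation error). Unplaced
    contigs are excluded from the adjacency and orientation denominators.
    """
    marker_counts = marker_counts or {}
    anchored = result.anchored_components
    missing = anchored - set(truth.contig_lengths)
    if missing:
        raise ValueError(f"contigs absent from truth: {sorted(missing)[:5]}")
    n_contigs = len(truth.contig_lengths)
    markered = {c for c, n in marker_counts.items() if n > 0}

    # dominant true chromosome per contig (by part length)
    true_chrom: dict[str, str] = {}
    for contig, grp in truth.parts.groupby("contig"):
        lengths = (grp["chrom_end"] - grp["chrom_start"]).to_numpy()
        true_chrom[str(contig)] = str(grp["chrom"].to_numpy()[lengths.argmax()])

    # group purity via majority chromosome per object
    pure = 0
    for obj in result.objects:
        chroms = [true_chrom[c] for c in obj.components]
        if not chroms:
            continue
        majority = max(set(chroms), key=lambda ch: (chroms.count(ch), ch))
        pure += sum(1 for ch in chroms if ch == majority)
    group_purity = pure / len(anchored) if anchored else float("nan")

    # adjacency among truth-adjacent anchored pairs
    result_pairs = result.adjacent_pairs()
    truth_pairs = [
        p for p in truth.true_adjacent_pairs() if all(c in anchored for c in p)
    ]
    adjacency = (
        sum(1 for p in truth_pairs if p in result_pairs) / len(truth_pairs)
        if truth_pairs
        else float("nan")
    )

    # orientation, per object up to a global flip
    orientations = result.orientations()
    n_orient = 0
    n_orient_ok = 0
    for obj in result.objects:
        considered = []
        for p in obj.placements:
            if marker_counts.get(p.component, 0) < min_markers_orientation:
                continue
            grp = truth.parts[truth.parts["contig"] == p.component]
            if len(grp) != 1:
                continue  # chimeric in truth: orientation undefined
            truth_strand = str(grp.iloc[0]["strand"])
            considered.append(orientations[p.component] == truth_strand)
        if not considered:
            continue
        n_match = sum(considered)
        n_orient += len(considered)
        n_orient_ok += max(n_match, len(considered) - n_match)
    orientation = n_orient_ok / n_orient if n_orient else float("nan")

    unplaced_markered = markered - anchored - {c for c in markered if c not in truth.contig_lengths}
    return EvaluationReport(
        placement_rate=len(anchored) / n_contigs,
        placement_rate_markered=(
            len(anchored & markered) / len(markered & set(truth.contig_lengths))
            if markered
            else float("nan")
        ),
        group_purity=group_purity,
        adjacency_accuracy=adjacency,
        orientation_accuracy=orientation,
        n_anchored=len(anchored),
        n_contigs=n_contigs,
        n_unplaced_markered=len(unplaced_markered),
        details={"unplaced_markered": sorted(unplaced_markered)},
    )
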