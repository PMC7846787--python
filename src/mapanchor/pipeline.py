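"""End-to-end orchestration: filter -> break chimeras -> group -> scaffold
-> anchor -> recombination landscape."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mapanchor.anchoring import (
    GroupAssignment,
    assign_to_linkage_groups,
    build_pseudomolecules,
)
from mapanchor.assembly import PseudomoleculeSet
from mapanchor.config import PipelineConfig
from mapanchor.genetics.filtering import FilterReport, filter_variants
from mapanchor.genetics.genetic_map import GeneticMap
from mapanchor.genetics.impute import assign_parental_haplotypes, polarize_by_parents
from mapanchor.genotypes import MarkerGenotypeMatrix, ParentalHaplotypeMatrix
from mapanchor.io.tables import BarcodeAlignmentTable
from mapanchor.landscape import (
    RecombinationProfile,
    build_marey_profile,
    call_pericentromeres,
    map_summary_stats,
    sliding_window_rate,
)
from mapanchor.ld import (
    ContigLinkageGraph,
    infer_linkage_groups,
    ld_discontinuity_blocks,
    marker_group_labels_loo,
    refine_block_labels,
)
from mapanchor.scaffold import (
    MisassemblyCall,
    ScaffoldPath,
    build_scaffold_graph,
    collect_end_barcodes,
    detect_misassemblies,
    greedy_scaffold_paths,
    split_alignment_table,
    split_marker_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    filter_report: FilterReport
    contig_groups: dict[str, str]
    linkage_graph: ContigLinkageGraph
    misassemblies: list[MisassemblyCall]
    unresolvable_contigs: list[str]
    haplotypes: ParentalHaplotypeMatrix
    scaffold_paths: list[ScaffoldPath]
    scaffold_ids: list[str]
    assignment: GroupAssignment
    pseudomolecules: PseudomoleculeSet
    genetic_map: GeneticMap
    orientation_unknown: set[str]
    profile: RecombinationProfile
    pericentromeres: pd.DataFrame
    summary: dict
    contig_lengths: dict[str, int] = field(default_factory=dict)
    splits: list[tuple[str, list[int]]] = field(default_factory=list)


def split_lengths(
    contig_lengths: dict[str, int], splits: dict[str, list[int]]
) -> dict[str, int]:
    out = dict(contig_lengths)
    for contig, breaks in splits.items():
        length = out.pop(contig)
        bounds = [0] + sorted(breaks) + [length]
        for k in range(len(bounds) - 1):
            out[f"{contig}.{k + 1}"] = bounds[k + 1] - bounds[k]
    return out


def _split_matrix(
    m: MarkerGenotypeMatrix, splits: dict[str, list[int]]
) -> MarkerGenotypeMatrix:
    markers = split_marker_table(m.markers, splits)
    return MarkerGenotypeMatrix(
        markers=markers,
        samples=list(m.samples),
        calls=m.calls.copy(),
        gq=m.gq.copy(),
        parents=m.parents,
    )


def run_pipeline(
    matrix: MarkerGenotypeMatrix,
    aln: BarcodeAlignmentTable,
    contig_lengths: dict[str, int],
    config: PipelineConfig,
) -> PipelineResult:
    """Run every stage from raw genotypes + barcoded alignments to
    pseudomolecules and the recombination landscape."""
    filtered, report = filter_variants(matrix, config)
    polarized, _ = polarize_by_parents(filtered)

    # grouping + chimera screen iterate, since two chimeras bridging the
    # same chromosome pair mask each other until one of them is broken
    haplotypes = assign_parental_haplotypes(polarized, config)
    calls: list[MisassemblyCall] = []
    split_log: list[tuple[str, list[int]]] = []
    unresolvable: list[str] = []
    for _iteration in range(5):
        groups, graph = infer_linkage_groups(polarized, config, contig_lengths)
        loo_labels = marker_group_labels_loo(polarized, graph, config)
        new_splits: dict[str, list[int]] = {}
        for contig, idx in haplotypes.contig_marker_index().items():
            if contig in unresolvable:
                continue
            # combine leave-one-out group labels with within-contig LD
            # discontinuities; the latter catches chimera pairs that keep
            # each other's chromosomes connected in the contig graph, and
            # runs on raw polarized calls because Viterbi smoothing can
            # overwrite a short minority side of a junction
            loo = loo_labels[contig]
            blocks = ld_discontinuity_blocks(polarized.calls, idx, config)
            combined = blocks * 10_000 + (loo + 1)
            labels = refine_block_labels(
                polarized.calls, idx, combined, config
            )
            if len(np.unique(labels[labels >= 0])) < 2:
                continue
            call = detect_misassemblies(
                contig,
                contig_lengths[contig],
                aln,
                haplotypes.markers["pos"].to_numpy()[idx],
                labels,
                config,
            )
            calls.append(call)
            if call.unresolvable:
                unresolvable.append(contig)
            elif call.break_positions:
                new_splits[contig] = call.break_positions
        if not new_splits:
            break
        logger.info("breaking %d contigs at misassembly calls", len(new_splits))
        split_log.extend(sorted(new_splits.items()))
        polarized = _split_matrix(polarized, new_splits)
        aln = split_alignment_table(aln, new_splits)
        contig_lengths = split_lengths(contig_lengths, new_splits)
        haplotypes = assign_parental_haplotypes(polarized, config)
    if split_log:
        groups, graph = infer_linkage_groups(polarized, config, contig_lengths)

    # drop markers on unresolvable contigs so they never anchor
    if unresolvable:
        keep = ~polarized.markers["contig"].isin(unresolvable).to_numpy()
        polarized = polarized.take_markers(np.flatnonzero(keep))
        groups = {c: g for c, g in groups.items() if c not in unresolvable}
        haplotypes = assign_parental_haplotypes(polarized, config)

    end_sets = collect_end_barcodes(aln, contig_lengths, config)
    sgraph = build_scaffold_graph(end_sets, config)
    paths = greedy_scaffold_paths(sgraph)
    scaffold_ids = [f"scaffold{k + 1:04d}" for k in range(len(paths))]

    assignment = assign_to_linkage_groups(
        paths, scaffold_ids, haplotypes.markers, groups, config
    )
    pseudo, gmap, orientation_unknown = build_pseudomolecules(
        paths, assignment, scaffold_ids, haplotypes, contig_lengths, config,
        linkage_calls=polarized.calls,
    )

    marey = build_marey_profile(gmap, pseudo)
    obj_lengths = {obj.name: obj.length for obj in pseudo.objects}
    profile = sliding_window_rate(marey, obj_lengths, config)
    peri = call_pericentromeres(profile, config)
    summary = map_summary_stats(gmap, pseudo)

    return PipelineResult(
        config=config,
        filter_report=report,
        contig_groups=groups,
        linkage_graph=graph,
        misassemblies=calls,
        unresolvable_contigs=unresolvable,
        haplotypes=haplotypes,
        scaffold_paths=paths,
        scaffold_ids=scaffold_ids,
        assignment=assignment,
        pseudomolecules=pseudo,
        genetic_map=gmap,
        orientation_unknown=orientation_unknown,
        profile=profile,
        pericentromeres=peri,
        summary=summary,
        contig_lengths=contig_lengths,
        splits=split_log,
    )
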