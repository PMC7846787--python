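"""The reference simulation used by the test suite and acceptance report.

An 11-chromosome, 55 Mbp inbred genome fragmented into ~130 contigs with
three injected chimeras, genotyped in 100 F8 RILs (20% missing, 1% error)
and covered by 30x linked-read molecules.

Genetic lengths are 25 cM per chromosome so the genome-wide physical-to-
genetic density (~0.2 Mbp/cM) stays within the regime where an r² > 0.8
rule can link physically adjacent contigs; at desk scale (5 Mbp
chromosomes) a ~100 cM chromosome would decay below the threshold within
~100 kbp and no threshold-based grouping could work. The estimator's
generation constant is 2: single-seed-descent selfing to F8 accumulates
just under two observable junctions per Morgan (the F-infinity value of
the Haldane-Waterman map expansion), and the simulator was calibrated
against that value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import MarkerGenotypeMatrix
from mapanchor.io.tables import BarcodeAlignmentTable
from mapanchor.simulate.fragments import TruthPlacement, fragment_genome
from mapanchor.simulate.genome import TrueGenome, simulate_genome
from mapanchor.simulate.linked_reads import barcodes_for_coverage, simulate_linked_reads
from mapanchor.simulate.ril import RILPopulation, genotype_population, simulate_ril_population

N_CHROMOSOMES = 11
CHROMOSOME_BP = 5_000_000
CHROMOSOME_CM = 25.0
MARKER_DENSITY = 60.0
MEAN_CONTIG_BP = 450_000
N_CHIMERAS = 3
MIN_CHIMERA_PART_BP = 100_000
MIN_FRAGMENT_BP = 20_000
N_INDIVIDUALS = 100
SELFING_GENERATIONS = 7  # F1 -> F8
MISSING_RATE = 0.2
ERROR_RATE = 0.01
MOLECULE_COVERAGE = 30.0
MOLECULE_MEAN_BP = 50_000
MOLECULES_PER_BARCODE = 2
READS_PER_KBP = 0.2
GENERATIONS_OF_CROSSOVER = 2  # matches the simulator's junction density


def reference_config(seed: int = 0) -> PipelineConfig:
    # the coverage filter is scaled to the population size (the default
    # threshold of 100 individuals assumes a larger population)
    return PipelineConfig(
        min_genotyped_individuals=50,
        generations_of_crossover=GENERATIONS_OF_CROSSOVER,
        seed=seed,
    )


@dataclass
class ReferenceSimulation:
    genome: TrueGenome
    truth: TruthPlacement
    population: RILPopulation
    matrix: MarkerGenotypeMatrix
    alignments: BarcodeAlignmentTable
    config: PipelineConfig

    @property
    def contig_lengths(self) -> dict[str, int]:
        return dict(self.truth.contig_lengths)


def reference_simulation(
    seed: int = 0,
    n_chimeras: int = N_CHIMERAS,
    with_linked_reads: bool = True,
) -> ReferenceSimulation:
    genome = simulate_genome(
        n_chr=N_CHROMOSOMES,
        lengths=[CHROMOSOME_BP] * N_CHROMOSOMES,
        cm_lengths=[CHROMOSOME_CM] * N_CHROMOSOMES,
        plateau_fraction=0.0,
        marker_density=MARKER_DENSITY,
        seed=seed,
    )
    _, truth = fragment_genome(
        genome,
        MEAN_CONTIG_BP,
        n_chimeras=n_chimeras,
        seed=seed,
        min_chimera_part_bp=MIN_CHIMERA_PART_BP,
        min_fragment_bp=MIN_FRAGMENT_BP,
    )
    population = simulate_ril_population(
        genome, N_INDIVIDUALS, SELFING_GENERATIONS, seed=seed
    )
    matrix = genotype_population(
        population,
        genome,
        truth,
        missing_rate=MISSING_RATE,
        error_rate=ERROR_RATE,
        seed=seed,
    )
    alignments = None
    if with_linked_reads:
        n_barcodes = barcodes_for_coverage(
            genome, MOLECULE_COVERAGE, MOLECULE_MEAN_BP, MOLECULES_PER_BARCODE
        )
        alignments = simulate_linked_reads(
            truth,
            genome,
            molecule_mean_bp=MOLECULE_MEAN_BP,
            molecules_per_barcode=MOLECULES_PER_BARCODE,
            n_barcodes=n_barcodes,
            reads_per_kbp=READS_PER_KBP,
            seed=seed,
        )
    return ReferenceSimulation(
        genome=genome,
        truth=truth,
        population=population,
        matrix=matrix,
        alignments=alignments,
        config=reference_config(seed),
    )


def single_contig_placement(genome: TrueGenome) -> TruthPlacement:
    """One full-length '+' contig per chromosome (identity coordinates)."""
    rows = [
        (f"ctg_{c.name}", 0, c.name, 0, c.length_bp, "+", 0)
        for c in genome.chromosomes
    ]
    return TruthPlacement(
        parts=pd.DataFrame(
            rows,
            columns=[
                "contig", "part_index", "chrom", "chrom_start",
                "chrom_end", "strand", "contig_start",
            ],
        ),
        contig_lengths={f"ctg_{c.name}": c.length_bp for c in genome.chromosomes},
    )


def hmm_imputation_benchmark(
    seed: int = 0,
    n_individuals: int = 100,
    missing_rate: float = 0.2,
    error_rate: float = 0.01,
) -> tuple[float, int]:
    """Parental-assignment accuracy on one 100 cM chromosome, ~500 markers.

    Returns (accuracy, n_compared); accuracy is measured against the true
    mosaic at marker-sample pairs where the true genotype is homozygous.
    """
    from mapanchor.genetics.impute import assign_parental_haplotypes, polarize_by_parents
    from mapanchor.simulate.ril import mosaic_labels_at

    genome = simulate_genome(
        1, [5_000_000], [100.0], plateau_fraction=0.0, marker_density=100, seed=seed
    )
    placement = single_contig_placement(genome)
    pop = simulate_ril_population(genome, n_individuals, SELFING_GENERATIONS, seed=seed)
    matrix = genotype_population(
        pop, genome, placement,
        missing_rate=missing_rate, error_rate=error_rate, seed=seed,
    )
    polarized, _ = polarize_by_parents(matrix)
    h = assign_parental_haplotypes(polarized, PipelineConfig(seed=seed))
    pos = h.markers["pos"].to_numpy()
    chrom = genome.chromosomes[0]
    n_ok = 0
    n_tot = 0
    for j, ind in enumerate(pop.individuals):
        h1, h2 = ind[chrom.name]
        l1 = mosaic_labels_at(h1, pos)
        l2 = mosaic_labels_at(h2, pos)
        hom = l1 == l2
        n_ok += int((h.labels[hom, j] == l1[hom]).sum())
        n_tot += int(hom.sum())
    return n_ok / n_tot, n_tot


def map_length_calibration(seed: int = 0, n_individuals: int = 200) -> float:
    """Estimated map length of a simulated 100 cM chromosome (true order).

    Uses the simulator-matched generation constant; the default constant
    of five is configurable but does not match single-seed-descent
    junction accumulation (just under 2 per Morgan at F8).
    """
    from mapanchor.genetics.genetic_map import count_breakpoints_and_estimate_cm
    from mapanchor.genetics.impute import assign_parental_haplotypes, polarize_by_parents

    genome = simulate_genome(
        1, [5_000_000], [100.0], plateau_fraction=0.0, marker_density=100, seed=seed
    )
    placement = single_contig_placement(genome)
    pop = simulate_ril_population(genome, n_individuals, SELFING_GENERATIONS, seed=seed)
    matrix = genotype_population(pop, genome, placement, seed=seed)
    polarized, _ = polarize_by_parents(matrix)
    config = PipelineConfig(generations_of_crossover=GENERATIONS_OF_CROSSOVER, seed=seed)
    h = assign_parental_haplotypes(polarized, config)
    order = {"LG01": np.arange(h.n_markers)}  # true physical order
    gmap = count_breakpoints_and_estimate_cm(h, order, config)
    return gmap.total_cm()


def pericentromere_benchmark(seed: int = 0) -> float:
    """Jaccard of called pericentromere vs the simulated plateau.

    One 20 Mbp chromosome with a 1 cM/Mbp arm rate and a 0.1 ratio plateau
    over the central 30%; the Marey profile is taken at marker positions.
    """
    from mapanchor.config import PipelineConfig as _Cfg
    from mapanchor.landscape import call_pericentromeres, sliding_window_rate

    L, f, ratio = 20_000_000, 0.3, 0.1
    g_cm = 1.0 * (L / 1e6) * (1 - f + ratio * f)
    genome = simulate_genome(
        1, [L], [g_cm], plateau_fraction=f, plateau_rate_ratio=ratio,
        marker_density=50, seed=seed,
    )
    chrom = genome.chromosomes[0]
    pos = genome.markers["pos"].to_numpy()
    marey = {"chr01": (pos.astype(float), chrom.marey(pos))}
    config = _Cfg(seed=seed)
    profile = sliding_window_rate(marey, {"chr01": L}, config)
    peri = call_pericentromeres(profile, config)
    a, b = chrom.plateau
    inter = 0
    lo, hi = [], []
    for _, row in peri.iterrows():
        s, e = int(row["start"]), int(row["end"])
        inter += max(0, min(b, e) - max(a, s))
        lo.append(s)
        hi.append(e)
    if not lo:
        return 0.0
    union = max(b, max(hi)) - min(a, min(lo))
    return inter / union
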