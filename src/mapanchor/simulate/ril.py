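"""Biparental RIL populations by single-seed descent and their genotyping.

Haplotype mosaics are piecewise-constant maps over a chromosome, stored as
(segment end positions, parent labels). Parent labels use the call coding
of :mod:`mapanchor.genotypes` (A = 0, B = 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mapanchor.genotypes import (
    CALL_A,
    CALL_B,
    CALL_H,
    CALL_MISSING,
    MarkerGenotypeMatrix,
)
from mapanchor.rng import substream
from mapanchor.simulate.genome import TrueGenome

# a haplotype mosaic: (ends, labels); ends[-1] == chromosome length
Mosaic = tuple[np.ndarray, np.ndarray]


def _uniform_mosaic(length_bp: int, label: int) -> Mosaic:
    return np.array([float(length_bp)]), np.array([label], dtype=np.int8)


def mosaic_labels_at(mosaic: Mosaic, pos) -> np.ndarray:
    """Parent label(s) at physical position(s) ``pos`` (0-based bp)."""
    ends, labels = mosaic
    idx = np.searchsorted(ends, np.asarray(pos, dtype=float), side="right")
    idx = np.minimum(idx, len(labels) - 1)
    return labels[idx]


def _append_segment(out_ends: list, out_labels: list, end: float, label: int) -> None:
    if out_labels and out_labels[-1] == label:
        out_ends[-1] = end
    else:
        out_ends.append(end)
        out_labels.append(label)


def _copy_interval(mosaic: Mosaic, a: float, b: float, out_ends: list, out_labels: list) -> None:
    """Copy segments of ``mosaic`` restricted to [a, b) onto the output lists."""
    ends, labels = mosaic
    i = int(np.searchsorted(ends, a, side="right"))
    while True:
        seg_end = min(float(ends[i]), b)
        _append_segment(out_ends, out_labels, seg_end, int(labels[i]))
        if ends[i] >= b:
            return
        i += 1


def _gamete(
    h1: Mosaic,
    h2: Mosaic,
    length_bp: int,
    length_cm: float,
    inverse_marey,
    rng: np.random.Generator,
    crossovers_per_chr_per_gen: float = 1.0,
) -> Mosaic:
    """One meiotic product: Poisson crossover count, positions placed by the
    inverse Marey map (no interference), alternating source homolog."""
    n_cx = rng.poisson(length_cm / 100.0 * crossovers_per_chr_per_gen)
    if n_cx:
        cm_pos = np.sort(rng.uniform(0.0, length_cm, size=n_cx))
        cx = np.unique(inverse_marey(cm_pos))
        cx = cx[(cx > 0) & (cx < length_bp)]
    else:
        cx = np.empty(0)
    sources = (h1, h2)
    current = int(rng.integers(0, 2))
    bounds = np.concatenate(([0.0], cx, [float(length_bp)]))
    out_ends: list = []
    out_labels: list = []
    for k in range(len(bounds) - 1):
        _copy_interval(sources[current], bounds[k], bounds[k + 1], out_ends, out_labels)
        current ^= 1
    return np.array(out_ends), np.array(out_labels, dtype=np.int8)


@dataclass
class RILPopulation:
    """Per-line, per-chromosome pairs of haplotype mosaics.

    ``individuals[i][chrom_name]`` is a (homolog1, homolog2) pair.
    ``generation`` is the filial index (F1 = 1, F8 = 8).
    """

    individuals: list[dict[str, tuple[Mosaic, Mosaic]]]
    generation: int

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def heterozygous_fraction(self, genome: TrueGenome) -> float:
        """Length-weighted fraction of the genome heterozygous, averaged over lines."""
        total = 0.0
        for ind in self.individuals:
            het_bp = 0.0
            for chrom in genome.chromosomes:
                h1, h2 = ind[chrom.name]
                bounds = np.unique(np.concatenate((h1[0], h2[0])))
                starts = np.concatenate(([0.0], bounds[:-1]))
                mids = (starts + bounds) / 2.0
                l1 = mosaic_labels_at(h1, mids)
                l2 = mosaic_labels_at(h2, mids)
                het_bp += ((bounds - starts) * (l1 != l2)).sum()
            total += het_bp / genome.total_bp
        return total / self.n_individuals

    def to_json(self, path: str | Path) -> None:
        data = {
            "generation": self.generation,
            "individuals": [
                {
                    chrom: [[h[0].tolist(), h[1].tolist()] for h in pair]
                    for chrom, pair in ind.items()
                }
                for ind in self.individuals
            ],
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "RILPopulation":
        with open(path) as fh:
            data = json.load(fh)
        individuals = [
            {
                chrom: tuple(
                    (np.array(h[0]), np.array(h[1], dtype=np.int8)) for h in pair
                )
                for chrom, pair in ind.items()
            }
            for ind in data["individuals"]
        ]
        return cls(individuals=individuals, generation=data["generation"])


def simulate_ril_population(
    genome: TrueGenome,
    n_individuals: int,
    n_selfing_generations: int = 7,
    seed: int = 0,
    crossovers_per_chr_per_gen: float = 1.0,
) -> RILPopulation:
    """Advance a biparental F1 by single-seed descent.

    The F1 is heterozygous genome-wide; each selfing generation draws two
    gametes from the current plant (crossover count per chromosome
    ~ Poisson(genetic length / 100), Haldane model) and keeps one offspring
    per line. ``n_selfing_generations = 7`` yields F8 lines.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be at least 2")
    rng = substream(seed, "simulate_ril_population")
    f1 = {
        c.name: (
            _uniform_mosaic(c.length_bp, CALL_A),
            _uniform_mosaic(c.length_bp, CALL_B),
        )
        for c in genome.chromosomes
    }
    individuals = []
    for _ in range(n_individuals):
        plant = f1
        for _gen in range(n_selfing_generations):
            offspring = {}
            for c in genome.chromosomes:
                h1, h2 = plant[c.name]
                g1 = _gamete(
                    h1, h2, c.length_bp, c.length_cm, c.inverse_marey, rng,
                    crossovers_per_chr_per_gen,
                )
                g2 = _gamete(
                    h1, h2, c.length_bp, c.length_cm, c.inverse_marey, rng,
                    crossovers_per_chr_per_gen,
                )
                offspring[c.name] = (g1, g2)
            plant = offspring
        individuals.append(plant)
    return RILPopulation(individuals=individuals, generation=1 + n_selfing_generations)


PARENT_A_ID = "P_A"
PARENT_B_ID = "P_B"


def genotype_population(
    pop: RILPopulation,
    genome: TrueGenome,
    placement,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    gq_pass: int = 40,
    seed: int = 0,
) -> MarkerGenotypeMatrix:
    """Observe the marker catalog on every line, in contig coordinates.

    The true call at a marker is A/B/H from the line's two homologs. Each
    call is independently set to missing with ``missing_rate``, otherwise
    replaced with a uniformly random different non-missing call with
    ``error_rate``. Parent samples are emitted clean (all-A / all-B).
    Marker coordinates are projected into contig space through
    ``placement`` (a :class:`~mapanchor.simulate.fragments.TruthPlacement`),
    so markers on chimeric contigs land on the chimera.
    """
    if not (0.0 <= missing_rate < 1.0 and 0.0 <= error_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    rng = substream(seed, "genotype_population")
    mk = genome.markers
    n_markers = len(mk)
    n_ind = pop.n_individuals
    calls = np.empty((n_markers, n_ind), dtype=np.int8)
    for chrom in genome.chromosomes:
        rows = np.flatnonzero((mk["chrom"] == chrom.name).to_numpy())
        if len(rows) == 0:
            continue
        pos = mk["pos"].to_numpy()[rows]
        for j, ind in enumerate(pop.individuals):
            h1, h2 = ind[chrom.name]
            l1 = mosaic_labels_at(h1, pos)
            l2 = mosaic_labels_at(h2, pos)
            c = np.where(l1 == l2, l1, CALL_H).astype(np.int8)
            calls[rows, j] = c
    # observation noise
    if missing_rate > 0 or error_rate > 0:
        u_miss = rng.random(calls.shape)
        u_err = rng.random(calls.shape)
        alt = rng.integers(1, 3, size=calls.shape)  # offset into the 2 other calls
        err_mask = (u_err < error_rate) & (u_miss >= missing_rate)
        calls = np.where(err_mask, (calls + alt) % 3, calls).astype(np.int8)
        calls = np.where(u_miss < missing_rate, CALL_MISSING, calls).astype(np.int8)
    # project to contig coordinates
    contigs, cpos = placement.project(
        mk["chrom"].to_numpy(), mk["pos"].to_numpy(dtype=np.int64)
    )
    samples = [PARENT_A_ID, PARENT_B_ID] + [f"RIL{i:04d}" for i in range(n_ind)]
    parent_calls = np.empty((n_markers, 2), dtype=np.int8)
    parent_calls[:, 0] = CALL_A
    parent_calls[:, 1] = CALL_B
    all_calls = np.hstack([parent_calls, calls])
    gq = np.full(all_calls.shape, gq_pass, dtype=np.int16)
    markers = pd.DataFrame(
        {
            "marker_id": [f"{c}_{p}" for c, p in zip(contigs, cpos)],
            "contig": contigs,
            "pos": cpos,
        }
    )
    return MarkerGenotypeMatrix(
        markers=markers,
        samples=samples,
        calls=all_calls,
        gq=gq,
        parents=(PARENT_A_ID, PARENT_B_ID),
    )
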