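"""Barcoded molecules drawn on the true genome, observed in contig space.

Molecules are sampled on true chromosomes and their read positions are then
projected through the :class:`~mapanchor.simulate.fragments.TruthPlacement`
into contig coordinates. A molecule straddling a contig junction therefore
deposits the same barcode near the facing ends of the adjacent contigs —
the signal the scaffold graph exploits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mapanchor.io.tables import BarcodeAlignmentTable
from mapanchor.rng import substream
from mapanchor.simulate.fragments import TruthPlacement
from mapanchor.simulate.genome import TrueGenome


def simulate_linked_reads(
    placement: TruthPlacement,
    genome: TrueGenome,
    molecule_mean_bp: int = 50_000,
    molecules_per_barcode: int = 2,
    n_barcodes: int = 10_000,
    reads_per_kbp: float = 0.2,
    seed: int = 0,
) -> BarcodeAlignmentTable:
    """Simulate a barcoded read alignment table.

    Molecule length ~ exponential(``molecule_mean_bp``) truncated at the
    chromosome end; start uniform over the genome (length-weighted
    chromosome choice); reads placed uniformly within the molecule with
    expected density ``reads_per_kbp``.
    """
    if molecule_mean_bp <= 0:
        raise ValueError("molecule_mean_bp must be positive")
    rng = substream(seed, "simulate_linked_reads")
    n_mol = n_barcodes * molecules_per_barcode
    chrom_names = np.array([c.name for c in genome.chromosomes])
    chrom_lengths = np.array([c.length_bp for c in genome.chromosomes], dtype=float)
    probs = chrom_lengths / chrom_lengths.sum()
    mol_chrom_idx = rng.choice(len(chrom_names), size=n_mol, p=probs)
    mol_start = rng.random(n_mol) * chrom_lengths[mol_chrom_idx]
    mol_len = rng.exponential(molecule_mean_bp, size=n_mol)
    mol_end = np.minimum(mol_start + mol_len, chrom_lengths[mol_chrom_idx])
    span = np.maximum(mol_end - mol_start, 1.0)
    n_reads = rng.poisson(reads_per_kbp * span / 1000.0)
    barcodes = np.array([f"BC{i % n_barcodes:06d}" for i in range(n_mol)])

    total = int(n_reads.sum())
    read_mol = np.repeat(np.arange(n_mol), n_reads)
    u = rng.random(total)
    read_pos = (mol_start[read_mol] + u * span[read_mol]).astype(np.int64)
    read_pos = np.minimum(read_pos, (mol_end[read_mol] - 1).astype(np.int64))
    read_chrom = chrom_names[mol_chrom_idx[read_mol]]
    contig, cpos = placement.project(read_chrom, read_pos)
    strand = np.where(rng.random(total) < 0.5, "+", "-")
    df = pd.DataFrame(
        {
            "barcode": barcodes[read_mol],
            "contig": contig,
            "pos": cpos,
            "strand": strand,
        }
    )
    df = df.sort_values(["contig", "pos", "barcode"], kind="mergesort").reset_index(
        drop=True
    )
    return BarcodeAlignmentTable(df)


def barcodes_for_coverage(
    genome: TrueGenome,
    molecule_coverage: float,
    molecule_mean_bp: int,
    molecules_per_barcode: int,
) -> int:
    """Number of barcodes giving the requested mean molecule coverage."""
    n_mol = molecule_coverage * genome.total_bp / molecule_mean_bp
    return max(1, int(round(n_mol / molecules_per_barcode)))
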