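"""Variant filtering for the mapping population.

Order of operations: individual calls failing the genotype-quality
threshold become missing first; markers are then removed by the first
failing rule among minor allele frequency, heterozygosity rate and
genotyped-individual count, so the report attributes each removal to
exactly one rule. MAF and het rate are computed over non-missing calls of
non-parent samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import (
    CALL_MISSING,
    GQ_UNKNOWN,
    EmptyMatrixError,
    MarkerGenotypeMatrix,
)


@dataclass
class FilterReport:
    quality_induced_missing: int = 0
    removed_maf: int = 0
    removed_het: int = 0
    removed_coverage: int = 0
    n_input: int = 0
    n_retained: int = 0

    def to_dict(self) -> dict:
        return {
            "quality_induced_missing": self.quality_induced_missing,
            "removed_maf": self.removed_maf,
            "removed_het": self.removed_het,
            "removed_coverage": self.removed_coverage,
            "n_input": self.n_input,
            "n_retained": self.n_retained,
        }


def filter_variants(
    m: MarkerGenotypeMatrix, config: PipelineConfig
) -> tuple[MarkerGenotypeMatrix, FilterReport]:
    """Apply GQ / MAF / het / coverage filters; returns (matrix, report)."""
    if m.parents is None:
        raise ValueError("parents must be designated before filtering")
    report = FilterReport(n_input=m.n_markers)
    calls = m.calls.copy()
    known_gq = m.gq != GQ_UNKNOWN
    fail_gq = known_gq & (m.gq < config.min_genotype_quality) & (calls != CALL_MISSING)
    report.quality_induced_missing = int(fail_gq.sum())
    calls[fail_gq] = CALL_MISSING

    masked = MarkerGenotypeMatrix(
        markers=m.markers,
        samples=list(m.samples),
        calls=calls,
        gq=m.gq,
        parents=m.parents,
    )
    stats = masked.marker_stats()
    maf = stats["maf"].to_numpy()
    het = stats["het_rate"].to_numpy()
    n_geno = stats["n_genotyped"].to_numpy()

    defined = ~np.isnan(maf)
    fail_maf = defined & (maf < config.min_maf)
    fail_het = defined & ~fail_maf & (het > config.max_het_rate)
    fail_cov = ~fail_maf & ~fail_het & (n_geno < config.min_genotyped_individuals)
    report.removed_maf = int(fail_maf.sum())
    report.removed_het = int(fail_het.sum())
    report.removed_coverage = int(fail_cov.sum())

    keep = ~(fail_maf | fail_het | fail_cov)
    report.n_retained = int(keep.sum())
    if report.n_retained == 0:
        raise EmptyMatrixError("all markers removed by filtering")
    return masked.take_markers(np.flatnonzero(keep)), report
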