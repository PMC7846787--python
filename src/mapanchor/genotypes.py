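"""Core genotype containers shared across the pipeline.

Call coding: A = 0 (first-parent homozygote), B = 1, H = 2 (heterozygote),
MISSING = 3. GQ values are Phred-scaled ints; ``GQ_UNKNOWN`` (-1) marks a
genotype without a quality and is treated as passing quality filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CALL_A = 0
CALL_B = 1
CALL_H = 2
CALL_MISSING = 3

GQ_UNKNOWN = -1

CALL_CHARS = np.array(["A", "B", "H", "."])


class EmptyMatrixError(ValueError):
    """Raised when an operation would produce a matrix with no markers."""


@dataclass
class MarkerGenotypeMatrix:
    """RIL genotype calls at markers located on contigs.

    Attributes
    ----------
    markers : DataFrame with columns ``marker_id``, ``contig``, ``pos``
        (0-based bp on the contig), sorted by (contig, pos), unique coords.
    samples : list of sample ids; may include the two designated parents.
    calls : int8 array of shape (n_markers, n_samples) with the coding above.
    gq : int16 array, same shape; ``GQ_UNKNOWN`` where absent.
    parents : optional (parent_a_id, parent_b_id).
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    gq: np.ndarray
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.gq = np.asarray(self.gq, dtype=np.int16)
        n_m, n_s = self.calls.shape
        if len(self.markers) != n_m:
            raise ValueError("markers/calls shape mismatch")
        if len(self.samples) != n_s:
            raise ValueError("samples/calls shape mismatch")
        if self.gq.shape != self.calls.shape:
            raise ValueError("gq/calls shape mismatch")
        if self.parents is not None:
            for p in self.parents:
                if p not in self.samples:
                    raise ValueError(f"designated parent {p!r} not among samples")
        mk = self.markers
        order = np.lexsort((mk["pos"].to_numpy(), mk["contig"].to_numpy()))
        if not np.array_equal(order, np.arange(n_m)):
            self.markers = mk.iloc[order].reset_index(drop=True)
            self.calls = self.calls[order]
            self.gq = self.gq[order]
        dup = self.markers.duplicated(subset=["contig", "pos"])
        if dup.any():
            raise ValueError("duplicate marker coordinates")

    # -- axis helpers -------------------------------------------------

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def non_parent_columns(self) -> np.ndarray:
        """Boolean mask over samples excluding the designated parents."""
        mask = np.ones(self.n_samples, dtype=bool)
        if self.parents is not None:
            for p in self.parents:
                mask[self.sample_index(p)] = False
        return mask

    # -- per-marker summary statistics --------------------------------

    def marker_stats(self) -> pd.DataFrame:
        """Recompute MAF, het rate and genotyped count over non-parent samples.

        MAF counts alleles (homozygotes contribute 2, heterozygotes 1 of
        each); het rate is the heterozygote fraction among genotyped
        samples. Markers with no genotyped sample get NaN MAF/het.
        """
        cols = self.non_parent_columns()
        c = self.calls[:, cols]
        n_a = (c == CALL_A).sum(axis=1)
        n_b = (c == CALL_B).sum(axis=1)
        n_h = (c == CALL_H).sum(axis=1)
        n_geno = n_a + n_b + n_h
        with np.errstate(divide="ignore", invalid="ignore"):
            freq_b = (2 * n_b + n_h) / (2 * n_geno)
            het = n_h / n_geno
        maf = np.minimum(freq_b, 1.0 - freq_b)
        maf = np.where(n_geno > 0, maf, np.nan)
        het = np.where(n_geno > 0, het, np.nan)
        return pd.DataFrame(
            {
                "marker_id": self.markers["marker_id"],
                "maf": maf,
                "het_rate": het,
                "n_genotyped": n_geno,
            }
        )

    # -- subsetting ---------------------------------------------------

    def take_markers(self, index: np.ndarray) -> "MarkerGenotypeMatrix":
        return MarkerGenotypeMatrix(
            markers=self.markers.iloc[index].reset_index(drop=True),
            samples=list(self.samples),
            calls=self.calls[index].copy(),
            gq=self.gq[index].copy(),
            parents=self.parents,
        )

    def contig_marker_index(self) -> dict[str, np.ndarray]:
        """Row indices per contig, in (contig, pos) order."""
        out: dict[str, np.ndarray] = {}
        for contig, grp in self.markers.groupby("contig", sort=True):
            out[str(contig)] = grp.index.to_numpy()
        return out


@dataclass
class ParentalHaplotypeMatrix:
    """Imputed parent-of-origin labels: A (0) or B (1), no missing entries."""

    markers: pd.DataFrame
    samples: list[str]
    labels: np.ndarray  # int8 (n_markers, n_samples), values in {0, 1}
    low_information_contigs: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.shape != (len(self.markers), len(self.samples)):
            raise ValueError("labels shape mismatch")
        if not np.isin(self.labels, [CALL_A, CALL_B]).all():
            raise ValueError("labels must be A/B only (no missing)")

    @property
    def n_markers(self) -> int:
        return self.labels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]

    def switch_counts(self) -> pd.Series:
        """Adjacent-label changes per sample, counted within each contig."""
        counts = np.zeros(self.n_samples, dtype=int)
        for _, idx in self.markers.groupby("contig", sort=True).indices.items():
            idx = np.sort(np.asarray(idx))
            lab = self.labels[idx]
            if len(idx) > 1:
                counts += (lab[1:] != lab[:-1]).sum(axis=0)
        return pd.Series(counts, index=self.samples, name="switches")

    def contig_marker_index(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for contig, grp in self.markers.groupby("contig", sort=True):
            out[str(contig)] = grp.index.to_numpy()
        return out
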