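"""Plain-text VCF 4.x genotype reading and minimal writing.

The reader extracts only what the mapping pipeline consumes — biallelic
SNVs with GT (and optionally GQ) — and reports malformed input with line
numbers, which is why it parses the text directly instead of delegating to
an htslib binding. Compressed or indexed access is out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from mapanchor.genotypes import (
    CALL_A,
    CALL_B,
    CALL_H,
    CALL_MISSING,
    GQ_UNKNOWN,
    EmptyMatrixError,
    MarkerGenotypeMatrix,
)

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class MalformedVCFError(ValueError):
    """Raised with the offending line number."""


class VCFReadResult(NamedTuple):
    matrix: MarkerGenotypeMatrix
    n_skipped: int


def _parse_gt(gt: str) -> int:
    alleles = gt.replace("|", "/").split("/")
    if any(a == "." for a in alleles):
        return CALL_MISSING
    try:
        vals = sorted(int(a) for a in alleles)
    except ValueError:
        raise ValueError(f"bad GT field {gt!r}") from None
    if len(vals) == 1:  # haploid call treated as homozygote
        vals = vals * 2
    if vals == [0, 0]:
        return CALL_A
    if vals == [1, 1]:
        return CALL_B
    if vals == [0, 1]:
        return CALL_H
    raise ValueError(f"allele index out of range in GT {gt!r}")


def read_genotype_matrix(
    path: str | Path,
    parents: tuple[str, str] | None = None,
) -> VCFReadResult:
    """Read biallelic SNVs from an uncompressed VCF into a genotype matrix.

    0/0 codes A, 1/1 codes B, 0/1 codes H, ./. codes missing. Multiallelic
    and non-SNV records are skipped and counted. A missing GQ becomes
    ``GQ_UNKNOWN`` and passes quality filters downstream.
    """
    samples: list[str] | None = None
    marker_rows = []
    call_rows = []
    gq_rows = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 10:
                    raise MalformedVCFError(
                        f"line {lineno}: header has no sample columns"
                    )
                samples = cols[9:]
                continue
            if samples is None:
                raise MalformedVCFError(f"line {lineno}: record before #CHROM header")
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise MalformedVCFError(
                    f"line {lineno}: expected {9 + len(samples)} columns, got {len(fields)}"
                )
            chrom, pos_s, vid, ref, alt, _qual, _filt, _info, fmt = fields[:9]
            try:
                pos = int(pos_s)
            except ValueError:
                raise MalformedVCFError(f"line {lineno}: non-integer POS {pos_s!r}") from None
            if not (
                len(ref) == 1
                and ref.upper() in _BASES
                and len(alt) == 1
                and alt.upper() in _BASES
            ):
                n_skipped += 1
                continue
            fmt_keys = fmt.split(":")
            if "GT" not in fmt_keys:
                raise MalformedVCFError(f"line {lineno}: FORMAT lacks GT")
            gt_i = fmt_keys.index("GT")
            gq_i = fmt_keys.index("GQ") if "GQ" in fmt_keys else None
            calls = np.empty(len(samples), dtype=np.int8)
            gqs = np.full(len(samples), GQ_UNKNOWN, dtype=np.int16)
            for j, cell in enumerate(fields[9:]):
                sub = cell.split(":")
                try:
                    calls[j] = _parse_gt(sub[gt_i])
                except (ValueError, IndexError) as exc:
                    raise MalformedVCFError(f"line {lineno}: {exc}") from None
                if gq_i is not None and gq_i < len(sub) and sub[gq_i] not in (".", ""):
                    try:
                        gqs[j] = int(float(sub[gq_i]))
                    except ValueError:
                        raise MalformedVCFError(
                            f"line {lineno}: bad GQ {sub[gq_i]!r}"
                        ) from None
            marker_id = vid if vid not in (".", "") else f"{chrom}_{pos - 1}"
            marker_rows.append((marker_id, chrom, pos - 1))
            call_rows.append(calls)
            gq_rows.append(gqs)
    if samples is None:
        raise MalformedVCFError("no #CHROM header found")
    if not marker_rows:
        raise EmptyMatrixError(f"no usable biallelic SNV records in {path}")
    if n_skipped:
        logger.warning("skipped %d multiallelic/non-SNV records in %s", n_skipped, path)
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "contig", "pos"])
    matrix = MarkerGenotypeMatrix(
        markers=markers,
        samples=samples,
        calls=np.vstack(call_rows),
        gq=np.vstack(gq_rows),
        parents=parents,
    )
    return VCFReadResult(matrix=matrix, n_skipped=n_skipped)


_GT_STRINGS = {CALL_A: "0/0", CALL_B: "1/1", CALL_H: "0/1", CALL_MISSING: "./."}


def write_genotype_vcf(
    matrix: MarkerGenotypeMatrix,
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a matrix as a minimal VCF 4.2 (arbitrary A>T alleles).

    Used by the synthetic-data stages; real data enters through
    :func:`read_genotype_matrix`.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        if contig_lengths:
            for contig, length in sorted(contig_lengths.items()):
                fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        mk = matrix.markers
        for i in range(matrix.n_markers):
            cells = []
            for j in range(matrix.n_samples):
                gq = matrix.gq[i, j]
                gq_s = "." if gq == GQ_UNKNOWN else str(int(gq))
                cells.append(f"{_GT_STRINGS[int(matrix.calls[i, j])]}:{gq_s}")
            fh.write(
                f"{mk['contig'].iat[i]}\t{int(mk['pos'].iat[i]) + 1}\t{mk['marker_id'].iat[i]}"
                f"\tA\tT\t.\tPASS\t.\tGT:GQ\t" + "\t".join(cells) + "\n"
            )
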