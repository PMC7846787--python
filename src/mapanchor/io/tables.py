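"""TSV tables: barcoded alignments, genetic maps, profiles, BED intervals.

Barcoded alignments are accepted as a 4-column TSV rather than BAM; a
BX-tagged BAM converts with e.g.::

    samtools view aln.bam | awk -v OFS='\\t' \\
      'match($0, /BX:Z:[^\\t]+/) {print substr($0, RSTART+5, RLENGTH-5), $3, $4-1, ($2%32>=16)?"-":"+"}'
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALN_COLUMNS = ["barcode", "contig", "pos", "strand"]


class TableParseError(ValueError):
    """Raised with a line number when a TSV row cannot be parsed."""


@dataclass
class BarcodeAlignmentTable:
    """Rows of (barcode, contig, pos, strand); pos is 0-based bp."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ALN_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"alignment table missing columns {missing}")
        self.df = self.df[ALN_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self, contig_lengths: dict[str, int] | None = None) -> None:
        df = self.df
        if (df["pos"] < 0).any():
            raise ValueError("negative alignment position")
        if (df["barcode"].astype(str) == "").any():
            raise ValueError("empty barcode")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError("strand must be '+' or '-'")
        if contig_lengths is not None:
            unknown = set(df["contig"]) - set(contig_lengths)
            if unknown:
                raise ValueError(f"alignments reference unknown contigs: {sorted(unknown)[:5]}")
            lens = df["contig"].map(contig_lengths).to_numpy()
            if (df["pos"].to_numpy() >= lens).any():
                raise ValueError("alignment position beyond contig end")

    def sorted(self) -> "BarcodeAlignmentTable":
        return BarcodeAlignmentTable(
            self.df.sort_values(["contig", "pos", "barcode"], kind="mergesort").reset_index(
                drop=True
            )
        )


def read_barcode_alignments(
    path: str | Path, contig_lengths: dict[str, int] | None = None
) -> BarcodeAlignmentTable:
    """Read a 4-column TSV (barcode, contig, position, strand); header optional."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["barcode", "contig"]:
                continue
            if len(fields) != 4:
                raise TableParseError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            barcode, contig, pos_s, strand = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise TableParseError(f"line {lineno}: non-integer position {pos_s!r}") from None
            if pos < 0:
                raise TableParseError(f"line {lineno}: negative position {pos}")
            rows.append((barcode, contig, pos, strand))
    if not rows:
        logger.warning("barcode alignment file %s is empty", path)
        df = pd.DataFrame(columns=ALN_COLUMNS).astype({"pos": np.int64})
    else:
        df = pd.DataFrame(rows, columns=ALN_COLUMNS)
    table = BarcodeAlignmentTable(df)
    table.validate(contig_lengths)
    return table


def write_barcode_alignments(table: BarcodeAlignmentTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# -- genetic map TSV -------------------------------------------------

MAP_COLUMNS = ["marker_id", "contig", "position", "linkage_group", "cM"]


def write_genetic_map(map_df: pd.DataFrame, path: str | Path) -> None:
    """Write a genetic map table (marker_id, contig, position, linkage_group, cM)."""
    out = map_df[MAP_COLUMNS].copy()
    out["cM"] = out["cM"].map(lambda v: format(float(v), ".6f"))
    out.to_csv(path, sep="\t", index=False)


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "marker_id": str,
            "contig": str,
            "position": np.int64,
            "linkage_group": str,
            "cM": float,
        },
    )
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"genetic map missing columns {missing}")
    return df[MAP_COLUMNS]


# -- misc writers ----------------------------------------------------

def write_marey_profile(profile_df: pd.DataFrame, path: str | Path) -> None:
    cols = ["chrom", "window_start", "window_end", "rate_cM_per_Mbp"]
    profile_df[cols].to_csv(path, sep="\t", index=False)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """3-column BED (chrom, start, end), 0-based half-open."""
    intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )
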