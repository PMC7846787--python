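"""Fragment a true genome into contigs, with optional chimeric misjoins.

The :class:`TruthPlacement` records, for every contig, which interval(s) of
which chromosome it carries and on which strand — the evaluation oracle for
the whole pipeline. A chimeric contig has two parts from different
chromosomes; the junction offset is the contig-local start of part 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from mapanchor.rng import substream
from mapanchor.simulate.genome import TrueGenome

PART_COLUMNS = [
    "contig",
    "part_index",
    "chrom",
    "chrom_start",
    "chrom_end",
    "strand",
    "contig_start",
]


@dataclass
class TruthPlacement:
    """Per-contig source intervals on the true genome.

    ``parts`` has one row per (contig, part); non-chimeric contigs have a
    single part. Coordinates are 0-based half-open. A '-' strand part means
    the contig carries the interval reversed: contig-local position x in
    the part maps to chromosome position ``chrom_end - 1 - (x - contig_start)``.
    """

    parts: pd.DataFrame
    contig_lengths: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in PART_COLUMNS if c not in self.parts.columns]
        if missing:
            raise ValueError(f"parts table missing columns {missing}")
        self.parts = self.parts.reset_index(drop=True)
        for contig, grp in self.parts.groupby("contig"):
            total = int((grp["chrom_end"] - grp["chrom_start"]).sum())
            if total != self.contig_lengths[contig]:
                raise ValueError(f"parts of {contig} do not sum to its length")
        for _, row in self.parts.iterrows():
            if row["part_index"] > 0 and row["contig_start"] <= 0:
                raise ValueError("chimera junction must be strictly inside the contig")

    # -- queries ------------------------------------------------------

    @property
    def contigs(self) -> list[str]:
        return sorted(self.contig_lengths)

    def chimeric_contigs(self) -> dict[str, int]:
        """Map chimeric contig id -> junction offset in contig coordinates."""
        out = {}
        for contig, grp in self.parts.groupby("contig"):
            if len(grp) > 1:
                second = grp.sort_values("part_index").iloc[1]
                out[contig] = int(second["contig_start"])
        return out

    def _chrom_index(self) -> dict[str, pd.DataFrame]:
        return {
            str(ch): grp.sort_values("chrom_start").reset_index(drop=True)
            for ch, grp in self.parts.groupby("chrom")
        }

    def project(self, chroms: np.ndarray, positions: np.ndarray):
        """Map true-genome coordinates into contig coordinates (strand-aware)."""
        chroms = np.asarray(chroms)
        positions = np.asarray(positions, dtype=np.int64)
        out_contig = np.empty(len(positions), dtype=object)
        out_pos = np.empty(len(positions), dtype=np.int64)
        index = self._chrom_index()
        for ch, tab in index.items():
            rows = np.flatnonzero(chroms == ch)
            if len(rows) == 0:
                continue
            starts = tab["chrom_start"].to_numpy()
            ends = tab["chrom_end"].to_numpy()
            pi = np.searchsorted(starts, positions[rows], side="right") - 1
            if np.any(pi < 0) or np.any(positions[rows] >= ends[pi]):
                raise ValueError(f"position outside the tiled intervals of {ch}")
            cstart = tab["contig_start"].to_numpy()[pi]
            fwd = tab["strand"].to_numpy()[pi] == "+"
            off = positions[rows] - starts[pi]
            rev_off = ends[pi] - 1 - positions[rows]
            out_pos[rows] = cstart + np.where(fwd, off, rev_off)
            out_contig[rows] = tab["contig"].to_numpy()[pi]
        return out_contig.astype(str), out_pos

    def true_adjacent_pairs(self) -> set[frozenset]:
        """Unordered pairs of contigs adjacent on a true chromosome."""
        pairs: set[frozenset] = set()
        for _, tab in self._chrom_index().items():
            ctgs = tab["contig"].to_numpy()
            for a, b in zip(ctgs[:-1], ctgs[1:]):
                if a != b:
                    pairs.add(frozenset((a, b)))
        return pairs

    def contig_chromosomes(self) -> dict[str, set[str]]:
        return {
            str(c): set(grp["chrom"]) for c, grp in self.parts.groupby("contig")
        }

    def contig_strand(self, contig: str) -> str:
        """Strand of a non-chimeric contig relative to its chromosome."""
        grp = self.parts[self.parts["contig"] == contig]
        if len(grp) != 1:
            raise ValueError(f"{contig} is chimeric; per-part strands apply")
        return str(grp.iloc[0]["strand"])

    # -- editing (misassembly breaking support) -----------------------

    def split_contig(self, contig: str, break_positions: list[int]) -> "TruthPlacement":
        """Return a placement where ``contig`` is cut at contig-local positions.

        Pieces are named ``<contig>.1``, ``<contig>.2``, ... left to right.
        """
        breaks = sorted(set(int(b) for b in break_positions))
        length = self.contig_lengths[contig]
        if any(b <= 0 or b >= length for b in breaks):
            raise ValueError("break positions must be strictly inside the contig")
        bounds = [0] + breaks + [length]
        keep = self.parts[self.parts["contig"] != contig]
        grp = self.parts[self.parts["contig"] == contig].sort_values("contig_start")
        new_rows = []
        new_lengths = dict(self.contig_lengths)
        del new_lengths[contig]
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            name = f"{contig}.{k + 1}"
            new_lengths[name] = hi - lo
            part_index = 0
            for _, row in grp.iterrows():
                p_lo = int(row["contig_start"])
                p_hi = p_lo + int(row["chrom_end"] - row["chrom_start"])
                a, b = max(lo, p_lo), min(hi, p_hi)
                if a >= b:
                    continue
                if row["strand"] == "+":
                    cs = int(row["chrom_start"]) + (a - p_lo)
                    ce = cs + (b - a)
                else:
                    ce = int(row["chrom_end"]) - (a - p_lo)
                    cs = ce - (b - a)
                new_rows.append(
                    {
                        "contig": name,
                        "part_index": part_index,
                        "chrom": row["chrom"],
                        "chrom_start": cs,
                        "chrom_end": ce,
                        "strand": row["strand"],
                        "contig_start": a - lo,
                    }
                )
                part_index += 1
        parts = pd.concat([keep, pd.DataFrame(new_rows)], ignore_index=True)
        return TruthPlacement(parts=parts, contig_lengths=new_lengths)

    def split_for_evaluation(
        self, splits: list[tuple[str, list[int]]]
    ) -> "TruthPlacement":
        """Mirror pipeline contig splits onto the truth.

        When a contig's called break count matches its true junction
        count, the truth is split at the exact junctions (called breaks
        land within a tolerance of them, and splitting at the called
        position would create artificial chimeric slivers); otherwise the
        called positions are used as-is.
        """
        tr = self
        for contig, breaks in splits:
            grp = tr.parts[tr.parts["contig"] == contig].sort_values("contig_start")
            junctions = [int(cs) for cs in grp["contig_start"].iloc[1:]]
            use = junctions if len(junctions) == len(breaks) else breaks
            tr = tr.split_contig(contig, use)
        return tr

    # -- persistence --------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        data = {
            "parts": self.parts[PART_COLUMNS].to_dict(orient="list"),
            "contig_lengths": {k: int(v) for k, v in self.contig_lengths.items()},
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthPlacement":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            parts=pd.DataFrame(data["parts"]),
            contig_lengths=data["contig_lengths"],
        )


def fragment_genome(
    genome: TrueGenome,
    mean_contig_bp: int,
    n_chimeras: int = 0,
    seed: int = 0,
    min_chimera_part_bp: int = 0,
    min_fragment_bp: int = 1,
) -> tuple[pd.DataFrame, TruthPlacement]:
    """Cut each chromosome at exponentially spaced breakpoints into contigs.

    Half of the resulting contigs (at random) are recorded on the '-'
    strand, i.e. their local coordinates run against the chromosome.
    ``n_chimeras`` contigs are built by concatenating two fragments from
    different chromosomes; the junction offset is recorded in the truth.
    ``min_chimera_part_bp`` restricts chimera construction to fragments of
    at least that size, so injected misjoins carry marker evidence on both
    sides of the junction. ``min_fragment_bp`` suppresses cuts that would
    leave a fragment below that size (sliver contigs shorter than a
    molecule carry no usable linking evidence).

    Returns a (catalog, placement) pair where the catalog lists
    (contig, length) sorted by contig id.
    """
    if mean_contig_bp >= min(c.length_bp for c in genome.chromosomes):
        raise ValueError("mean_contig_bp must be below the shortest chromosome")
    rng = substream(seed, "fragment_genome")
    fragments: list[tuple[str, int, int]] = []
    for c in genome.chromosomes:
        cuts = []
        pos = 0.0
        while True:
            pos += rng.exponential(mean_contig_bp)
            if pos >= c.length_bp - 1:
                break
            cuts.append(int(pos))
        bounds = [0]
        for cut in sorted(set(cuts)):
            if cut - bounds[-1] >= min_fragment_bp and c.length_bp - cut >= min_fragment_bp:
                bounds.append(cut)
        bounds.append(c.length_bp)
        for a, b in zip(bounds[:-1], bounds[1:]):
            fragments.append((c.name, a, b))
    order = rng.permutation(len(fragments))
    fragments = [fragments[i] for i in order]
    # pick disjoint fragment pairs from different chromosomes for chimeras
    chimera_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for i in range(len(fragments)):
        if len(chimera_pairs) == n_chimeras:
            break
        if i in used or fragments[i][2] - fragments[i][1] < min_chimera_part_bp:
            continue
        for j in range(i + 1, len(fragments)):
            if j in used or fragments[j][0] == fragments[i][0]:
                continue
            if fragments[j][2] - fragments[j][1] < min_chimera_part_bp:
                continue
            chimera_pairs.append((i, j))
            used.update((i, j))
            break
    if len(chimera_pairs) < n_chimeras:
        raise ValueError(
            f"cannot build {n_chimeras} chimeras from {len(fragments)} fragments"
        )
    strands = np.where(rng.random(len(fragments)) < 0.5, "-", "+")
    rows = []
    lengths: dict[str, int] = {}
    counter = 0

    def _next_name() -> str:
        nonlocal counter
        counter += 1
        return f"ctg{counter:04d}"

    for i, j in chimera_pairs:
        name = _next_name()
        ch_a, a0, a1 = fragments[i]
        ch_b, b0, b1 = fragments[j]
        len_a, len_b = a1 - a0, b1 - b0
        rows.append((name, 0, ch_a, a0, a1, strands[i], 0))
        rows.append((name, 1, ch_b, b0, b1, strands[j], len_a))
        lengths[name] = len_a + len_b
    for i, (ch, a, b) in enumerate(fragments):
        if i in used:
            continue
        name = _next_name()
        rows.append((name, 0, ch, a, b, strands[i], 0))
        lengths[name] = b - a
    parts = pd.DataFrame(rows, columns=PART_COLUMNS)
    placement = TruthPlacement(parts=parts, contig_lengths=lengths)
    catalog = pd.DataFrame(
        sorted(lengths.items()), columns=["contig", "length"]
    )
    return catalog, placement
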