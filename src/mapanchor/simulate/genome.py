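"""True genomes with piecewise-linear Marey maps and a marker catalog."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mapanchor.rng import substream


@dataclass
class Chromosome:
    """One chromosome of the true coordinate system.

    The Marey function is stored as breakpoints (``marey_bp``, ``marey_cm``)
    of a non-decreasing piecewise-linear map with Marey(0) = 0 and
    Marey(length_bp) = length_cm. ``plateau`` is the optional
    low-recombination interval (start_bp, end_bp).
    """

    name: str
    length_bp: int
    length_cm: float
    marey_bp: np.ndarray
    marey_cm: np.ndarray
    plateau: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.marey_bp = np.asarray(self.marey_bp, dtype=float)
        self.marey_cm = np.asarray(self.marey_cm, dtype=float)
        if self.marey_bp[0] != 0 or self.marey_cm[0] != 0:
            raise ValueError("Marey function must start at (0, 0)")
        if self.marey_bp[-1] != self.length_bp:
            raise ValueError("Marey function must end at the chromosome length")
        if not np.isclose(self.marey_cm[-1], self.length_cm):
            raise ValueError("Marey function must end at the genetic length")
        if np.any(np.diff(self.marey_bp) <= 0) or np.any(np.diff(self.marey_cm) < 0):
            raise ValueError("Marey function must be non-decreasing")
        if self.plateau is not None:
            a, b = self.plateau
            if not (0 <= a <= b <= self.length_bp):
                raise ValueError("plateau interval must lie within the chromosome")

    def marey(self, pos_bp) -> np.ndarray:
        """Genetic position (cM) at physical position(s) ``pos_bp``."""
        return np.interp(pos_bp, self.marey_bp, self.marey_cm)

    def inverse_marey(self, cm) -> np.ndarray:
        """Physical position (bp) at genetic position(s) ``cm``.

        Requires the Marey map to be strictly increasing (plateau rate > 0).
        """
        if np.any(np.diff(self.marey_cm) <= 0):
            raise ValueError("Marey map is not invertible (flat segment)")
        return np.interp(cm, self.marey_cm, self.marey_bp)


@dataclass
class TrueGenome:
    chromosomes: list[Chromosome]
    markers: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame({"chrom": [], "pos": []})
    )

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_bp(self) -> int:
        return sum(c.length_bp for c in self.chromosomes)

    # -- JSON persistence (for CLI stage hand-off) --------------------

    def to_json(self, path: str | Path) -> None:
        data = {
            "chromosomes": [
                {
                    "name": c.name,
                    "length_bp": c.length_bp,
                    "length_cm": c.length_cm,
                    "marey_bp": c.marey_bp.tolist(),
                    "marey_cm": c.marey_cm.tolist(),
                    "plateau": list(c.plateau) if c.plateau else None,
                }
                for c in self.chromosomes
            ],
            "markers": {
                "chrom": self.markers["chrom"].tolist(),
                "pos": [int(p) for p in self.markers["pos"]],
            },
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TrueGenome":
        with open(path) as fh:
            data = json.load(fh)
        chroms = [
            Chromosome(
                name=c["name"],
                length_bp=c["length_bp"],
                length_cm=c["length_cm"],
                marey_bp=np.array(c["marey_bp"]),
                marey_cm=np.array(c["marey_cm"]),
                plateau=tuple(c["plateau"]) if c["plateau"] else None,
            )
            for c in data["chromosomes"]
        ]
        markers = pd.DataFrame(data["markers"])
        return cls(chromosomes=chroms, markers=markers)


def _plateau_marey(
    length_bp: int, length_cm: float, plateau_fraction: float, plateau_rate_ratio: float
) -> tuple[np.ndarray, np.ndarray, tuple[int, int] | None]:
    """Two-rate piecewise-linear Marey map with a central plateau.

    With arm rate ``r`` and plateau rate ``ratio * r`` over a central span
    of ``f * L``, the constraint Marey(L) = G fixes
    ``r = G / (L * (1 - f + ratio * f))``.
    """
    L, G, f, ratio = length_bp, length_cm, plateau_fraction, plateau_rate_ratio
    if f == 0.0:
        return np.array([0.0, L]), np.array([0.0, G]), None
    a = int(round(L * (1.0 - f) / 2.0))
    b = int(round(a + L * f))
    arm_rate = G / (L * (1.0 - f + ratio * f))
    cm_a = arm_rate * a
    cm_b = cm_a + ratio * arm_rate * (b - a)
    bp = np.array([0.0, a, b, L])
    cm = np.array([0.0, cm_a, cm_b, G])
    # snap the endpoint exactly
    cm[-1] = G
    return bp, cm, (a, b)


def simulate_genome(
    n_chr: int,
    lengths: list[int],
    cm_lengths: list[float],
    plateau_fraction: float = 0.0,
    plateau_rate_ratio: float = 0.1,
    marker_density: float = 50.0,
    seed: int = 0,
) -> TrueGenome:
    """Simulate an inbred genome with per-chromosome Marey maps and markers.

    Parameters
    ----------
    n_chr : number of chromosomes; ``lengths`` and ``cm_lengths`` must match.
    plateau_fraction : fraction of each chromosome's physical length covered
        by a central low-recombination plateau (0 disables it).
    plateau_rate_ratio : plateau rate as a fraction of the arm rate, in (0, 1].
    marker_density : expected markers per Mbp, placed uniformly at random,
        deduplicated and sorted.
    """
    if len(lengths) != n_chr or len(cm_lengths) != n_chr:
        raise ValueError("lengths and cm_lengths must have n_chr entries")
    if plateau_fraction > 0 and not 0.0 < plateau_rate_ratio <= 1.0:
        raise ValueError("plateau_rate_ratio must lie in (0, 1]")
    rng = substream(seed, "simulate_genome")
    chroms: list[Chromosome] = []
    marker_chrom: list[str] = []
    marker_pos: list[int] = []
    for i, (L, G) in enumerate(zip(lengths, cm_lengths)):
        if G <= 0 and L > 0:
            raise ValueError(f"chromosome {i}: genetic length must be positive")
        name = f"chr{i + 1:02d}"
        bp, cm, plateau = _plateau_marey(L, G, plateau_fraction, plateau_rate_ratio)
        chroms.append(
            Chromosome(
                name=name,
                length_bp=int(L),
                length_cm=float(G),
                marey_bp=bp,
                marey_cm=cm,
                plateau=plateau,
            )
        )
        n_markers = int(round(marker_density * L / 1e6))
        pos = np.unique(rng.integers(0, L, size=n_markers))
        marker_chrom.extend([name] * len(pos))
        marker_pos.extend(int(p) for p in pos)
    markers = pd.DataFrame({"chrom": marker_chrom, "pos": marker_pos})
    return TrueGenome(chromosomes=chroms, markers=markers)
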