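"""Pseudomolecule objects: ordered, oriented component placements.

Internal coordinates are 0-based half-open; AGP emission converts to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class PlacementError(ValueError):
    """Raised when placements overlap or are out of order."""


@dataclass(frozen=True)
class Placement:
    component: str
    orientation: str  # '+' or '-'
    obj_start: int  # 0-based half-open on the object
    obj_end: int

    @property
    def length(self) -> int:
        return self.obj_end - self.obj_start


@dataclass
class PseudoObject:
    name: str
    placements: list[Placement]
    gaps: list[int] = field(default_factory=list)  # gap after placement k

    def __post_init__(self) -> None:
        if self.placements and len(self.gaps) != len(self.placements) - 1:
            raise PlacementError(
                f"{self.name}: need {len(self.placements) - 1} gaps, got {len(self.gaps)}"
            )
        self.validate()

    def validate(self) -> None:
        prev_end = 0
        for k, p in enumerate(self.placements):
            if p.orientation not in ("+", "-"):
                raise PlacementError(f"{self.name}: bad orientation {p.orientation!r}")
            if p.obj_start < prev_end or p.obj_end <= p.obj_start:
                raise PlacementError(
                    f"{self.name}: placement {p.component} overlaps or is out of order"
                )
            expected_start = prev_end if k == 0 else prev_end + self.gaps[k - 1]
            if p.obj_start != expected_start:
                raise PlacementError(
                    f"{self.name}: placement {p.component} does not abut the preceding gap"
                )
            prev_end = p.obj_end

    @property
    def length(self) -> int:
        return self.placements[-1].obj_end if self.placements else 0

    @property
    def components(self) -> list[str]:
        return [p.component for p in self.placements]


@dataclass
class PseudomoleculeSet:
    objects: list[PseudoObject]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for obj in self.objects:
            for comp in obj.components:
                if comp in seen:
                    raise PlacementError(f"component {comp} placed more than once")
                seen.add(comp)

    @property
    def anchored_components(self) -> set[str]:
        return {c for obj in self.objects for c in obj.components}

    def object_of(self, component: str) -> tuple[str, int]:
        """(object name, rank of the component within it)."""
        for obj in self.objects:
            for k, p in enumerate(obj.placements):
                if p.component == component:
                    return obj.name, k
        raise KeyError(component)

    def adjacent_pairs(self) -> set[frozenset]:
        pairs: set[frozenset] = set()
        for obj in self.objects:
            comps = obj.components
            for a, b in zip(comps[:-1], comps[1:]):
                pairs.add(frozenset((a, b)))
        return pairs

    def orientations(self) -> dict[str, str]:
        return {p.component: p.orientation for obj in self.objects for p in obj.placements}


def build_object(
    name: str,
    components: list[tuple[str, str, int]],
    gap_bp: int,
) -> PseudoObject:
    """Assemble an object from ordered (component, orientation, length) triples
    with a uniform gap between consecutive components."""
    placements = []
    cursor = 0
    for k, (comp, orient, length) in enumerate(components):
        if k > 0:
            cursor += gap_bp
        placements.append(
            Placement(component=comp, orientation=orient, obj_start=cursor, obj_end=cursor + length)
        )
        cursor += length
    return PseudoObject(name=name, placements=placements, gaps=[gap_bp] * max(0, len(components) - 1))
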