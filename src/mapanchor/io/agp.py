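"""AGP v2.1 emission and parsing for pseudomolecule sets.

Component lines are type W; gap lines are type U ("scaffold", linkage
"yes", evidence "paired-ends;map"). Writing then reading reproduces the
object structure exactly, and re-writing is byte-identical (canonical
formatting: tab-separated, one trailing newline, version pragma first).
"""

from __future__ import annotations

from pathlib import Path

from mapanchor.assembly import (
    Placement,
    PlacementError,
    PseudoObject,
    PseudomoleculeSet,
)

_GAP_TYPE = "scaffold"
_LINKAGE = "yes"
_EVIDENCE = "paired-ends;map"


class AGPFormatError(ValueError):
    pass


def write_agp(pseudo: PseudomoleculeSet, path: str | Path) -> None:
    """Write a pseudomolecule set as AGP v2.1 (1-based inclusive coordinates)."""
    for obj in pseudo.objects:
        obj.validate()  # refuse to write overlapping placements
    lines = ["##agp-version\t2.1"]
    for obj in pseudo.objects:
        part = 0
        for k, p in enumerate(obj.placements):
            if k > 0:
                gap = obj.gaps[k - 1]
                part += 1
                gap_start = obj.placements[k - 1].obj_end
                lines.append(
                    "\t".join(
                        (
                            obj.name,
                            str(gap_start + 1),
                            str(gap_start + gap),
                            str(part),
                            "U",
                            str(gap),
                            _GAP_TYPE,
                            _LINKAGE,
                            _EVIDENCE,
                        )
                    )
                )
            part += 1
            lines.append(
                "\t".join(
                    (
                        obj.name,
                        str(p.obj_start + 1),
                        str(p.obj_end),
                        str(part),
                        "W",
                        p.component,
                        "1",
                        str(p.length),
                        p.orientation,
                    )
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_agp(path: str | Path) -> PseudomoleculeSet:
    """Parse an AGP v2.1 file produced by :func:`write_agp`."""
    objects: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AGPFormatError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            name, beg_s, end_s, _part, kind = fields[:5]
            try:
                beg, end = int(beg_s), int(end_s)
            except ValueError:
                raise AGPFormatError(f"line {lineno}: non-integer coordinates") from None
            if name not in objects:
                objects[name] = {"placements": [], "gaps": [], "pending_gap": None}
                order.append(name)
            rec = objects[name]
            if kind == "W":
                comp, cbeg_s, cend_s, orient = fields[5:9]
                if orient not in ("+", "-"):
                    raise AGPFormatError(f"line {lineno}: bad orientation {orient!r}")
                if int(cbeg_s) != 1 or int(cend_s) != end - beg + 1:
                    raise AGPFormatError(f"line {lineno}: partial component spans unsupported")
                if rec["placements"] and rec["pending_gap"] is None:
                    raise AGPFormatError(f"line {lineno}: missing gap line before component")
                if rec["pending_gap"] is not None:
                    rec["gaps"].append(rec["pending_gap"])
                    rec["pending_gap"] = None
                rec["placements"].append(
                    Placement(component=comp, orientation=orient, obj_start=beg - 1, obj_end=end)
                )
            elif kind in ("U", "N"):
                gap_len = int(fields[5])
                if gap_len != end - beg + 1:
                    raise AGPFormatError(f"line {lineno}: gap length/coordinate mismatch")
                if rec["pending_gap"] is not None or not rec["placements"]:
                    raise AGPFormatError(f"line {lineno}: misplaced gap line")
                rec["pending_gap"] = gap_len
            else:
                raise AGPFormatError(f"line {lineno}: unsupported component type {kind!r}")
    objs = []
    for name in order:
        rec = objects[name]
        if rec["pending_gap"] is not None:
            raise AGPFormatError(f"object {name} ends with a gap line")
        try:
            objs.append(PseudoObject(name=name, placements=rec["placements"], gaps=rec["gaps"]))
        except PlacementError as exc:
            raise AGPFormatError(str(exc)) from exc
    return PseudomoleculeSet(objects=objs)
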