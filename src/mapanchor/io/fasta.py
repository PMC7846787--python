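"""FASTA helpers: contig lengths in, random-content contigs out.

Only sequence lengths matter downstream, so synthetic contigs carry
uniform random bases.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from mapanchor.rng import substream

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_LINE = 80


def write_random_fasta(contig_lengths: dict[str, int], path: str | Path, seed: int = 0) -> None:
    rng = substream(seed, "write_random_fasta")
    with open(path, "w") as fh:
        for name in sorted(contig_lengths):
            length = contig_lengths[name]
            fh.write(f">{name}\n")
            seq = _ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
            for i in range(0, length, _LINE):
                fh.write(seq[i : i + _LINE] + "\n")


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    name = None
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    lengths[name] = n
                name = line[1:].split()[0]
                n = 0
            elif name is not None:
                n += len(line.strip())
    if name is not None:
        lengths[name] = n
    return lengths
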