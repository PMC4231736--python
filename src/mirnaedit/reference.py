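"""Mature miRNA reference sequences.

A reference set is a list of :class:`MatureMiRNA` records, each holding a
short (19–25 nt) DNA-alphabet sequence stored 5'→3'.  All editing positions
reported downstream are 1-based coordinates on these sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(ALPHABET)}


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence (DNA alphabet, 5'→3')."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("miRNA id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.id}: sequence must be non-empty")
        if set(self.sequence) - set(ALPHABET):
            raise ValueError(
                f"{self.id}: sequence must be over {{A,C,G,T}}, got "
                f"{set(self.sequence) - set(ALPHABET)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(f"position {position} outside {self.id} (len {len(self)})")
        return self.sequence[position - 1]


def _check_unique_ids(mirnas: Sequence[MatureMiRNA]) -> None:
    ids = [m.id for m in mirnas]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate miRNA ids in reference: {dup}")


def generate_reference(
    n_mirnas: int,
    length_range: tuple[int, int] = (19, 25),
    seed: int = 0,
) -> list[MatureMiRNA]:
    """Generate ``n_mirnas`` random, pairwise-distinct mature miRNA sequences.

    Sequences are i.i.d. uniform over ACGT with lengths uniform in
    ``length_range`` (inclusive); collisions are resampled so the returned
    set never contains two identical sequences.  Deterministic given *seed*.
    """
    if n_mirnas < 0:
        raise ValueError(f"n_mirnas must be >= 0, got {n_mirnas}")
    lo, hi = length_range
    if not (15 <= lo <= hi <= 30):
        raise ValueError(f"length_range must satisfy 15 <= lo <= hi <= 30, got {length_range}")
    rng = np.random.default_rng(seed)
    width = len(str(max(n_mirnas, 1)))
    seen: set[str] = set()
    out: list[MatureMiRNA] = []
    while len(out) < n_mirnas:
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(ALPHABET[c] for c in rng.integers(0, 4, size=length))
        if seq in seen:
            continue
        seen.add(seq)
        out.append(MatureMiRNA(id=f"syn-mir-{len(out) + 1:0{width}d}", sequence=seq))
    return out


def write_fasta(mirnas: Iterable[MatureMiRNA], path: str | Path) -> None:
    records = [SeqRecord(Seq(m.sequence), id=m.id, description="") for m in mirnas]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[MatureMiRNA]:
    mirnas = [
        MatureMiRNA(id=rec.id, sequence=str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    _check_unique_ids(mirnas)
    return mirnas
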