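"""Read container, FASTQ I/O, 3' adapter trimming and length filtering.

Small-RNA inserts (~19–25 nt) are shorter than the 36 nt read length, so
every read runs into the 3' sequencing adapter.  ``trim_adapter`` removes
the adapter by locating the leftmost suffix-prefix overlap between the read
and the adapter, allowing substitutions up to a proportional error budget —
the classic 3'-adapter semantics of read trimmers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(Read(id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    return out


def find_adapter_start(
    sequence: str,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> int | None:
    """Leftmost position where a prefix of *adapter* matches a suffix of
    *sequence* with at most ``floor(max_error_rate * overlap)`` mismatches
    and overlap >= *min_overlap*.  Returns None when no position qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    n = len(sequence)
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - start)
        if overlap < min_overlap:
            break
        budget = int(max_error_rate * overlap)
        mismatches = 0
        for a, b in zip(sequence[start : start + overlap], adapter):
            if a != b:
                mismatches += 1
                if mismatches > budget:
                    break
        else:
            return start
    return None


def trim_adapter(
    read: Read,
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> Read:
    """Truncate *read* before the leftmost qualifying adapter occurrence.

    Unchanged if the adapter is not found; matching counts substitutions
    only (no indels).
    """
    start = find_adapter_start(read.sequence, adapter, max_error_rate, min_overlap)
    if start is None:
        return read
    return replace(read, sequence=read.sequence[:start], quality=read.quality[:start])


def trim_reads(
    reads: Sequence[Read],
    adapter: str,
    max_error_rate: float = 0.1,
    min_overlap: int = 3,
) -> list[Read]:
    """Batch adapter trimming; vectorized when all reads share one length.

    Equivalent to mapping :func:`trim_adapter` over *reads*.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not reads:
        return []
    lengths = {len(r) for r in reads}
    if len(lengths) != 1:
        return [trim_adapter(r, adapter, max_error_rate, min_overlap) for r in reads]

    n = lengths.pop()
    mat = np.frombuffer("".join(r.sequence for r in reads).encode(), dtype=np.uint8)
    mat = mat.reshape(len(reads), n)
    ad = np.frombuffer(adapter.encode(), dtype=np.uint8)
    # cut[i] = leftmost qualifying adapter start for read i (or n = keep all)
    cut = np.full(len(reads), n, dtype=np.int64)
    undecided = np.ones(len(reads), dtype=bool)
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(ad), n - start)
        if overlap < min_overlap:
            break
        budget = int(max_error_rate * overlap)
        mism = (mat[:, start : start + overlap] != ad[:overlap]).sum(axis=1)
        hit = undecided & (mism <= budget)
        cut[hit] = start
        undecided &= ~hit
        if not undecided.any():
            break
    return [
        r if c == n else replace(r, sequence=r.sequence[:c], quality=r.quality[:c])
        for r, c in zip(reads, cut)
    ]


def length_filter(
    reads: Iterable[Read],
    min_len: int = 18,
    max_len: int = 28,
) -> list[Read]:
    """Keep reads with min_len <= length <= max_len, preserving order.

    Defaults bracket the 19–25 nt small-RNA isolation window with one base
    of slack on each side for isomiR length variants.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    reads = list(reads)
    kept = [r for r in reads if min_len <= len(r) <= max_len]
    logger.info(
        "length_filter: kept %d / %d reads (discarded %d)",
        len(kept), len(reads), len(reads) - len(kept),
    )
    return kept
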