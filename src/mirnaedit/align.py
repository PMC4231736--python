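"""Strand-specific local alignment of small-RNA reads to mature miRNAs.

Reads are aligned with affine-gap Smith-Waterman against the forward strand
of every reference only — the cloning protocol is strand-specific, so a
read matching a reverse complement is biological noise and is never
reported.  All references attaining the maximal local score are returned;
hits are then filtered on identity (>= 90%, counting each indel column as a
difference) and mismatch count (<= 2), and reads with several equally good
hits are weighted 1/k so that each mapped read contributes unit weight to
downstream count tables.

Default scoring (match +2, mismatch -3, gap open -5, gap extend -2, minimum
score 24, i.e. about 12 matched bases) favors near-full-length ungapped
alignments, appropriate for 19–25 nt mature miRNAs; because the alignment
is local, mismatches at the very ends of a read are clipped rather than
counted, so no explicit end-trimming is needed.

Tie-breaking is deterministic and documented: the alignment ends at the
maximal-score cell that comes first in row-major (read-position, then
reference-position) order, and the traceback prefers diagonal moves over
gaps in the reference (up) over gaps in the read (left), closing a gap as
early as possible.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .readprep import Read
from .reference import MatureMiRNA

NEG_INF = -(10**9)


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores.  The mismatch penalty is deliberately smaller than
    twice the match score: a local alignment clips a terminal mismatch
    whenever the matches outside it are worth less than the penalty saved,
    and with |mismatch| < 2*match only a mismatch at the very first or last
    aligned position can be clipped.  Editing observed at mature-miRNA
    position 2 — inside the seed region, where editing concentrates — would
    otherwise be silently removed from the count tables."""

    match: int = 4
    mismatch: int = -3
    gap_open: int = -10    # score of the first gapped column
    gap_extend: int = -4   # score of each further gapped column
    min_score: int = 48    # ~12 matched bases

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("match must be positive; penalties negative")
        if self.gap_open > self.gap_extend:
            raise ValueError("gap_open must be at most gap_extend (affine)")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentHit:
    """One read-to-miRNA local alignment.

    ``n_mismatches`` counts differences as the identity filter does: one per
    substitution column plus one per indel column.  ``mismatches`` lists the
    substitution columns as (1-based ref position, ref base, read base);
    ``aligned_bases`` lists every aligned reference position with the read
    base observed there (matches and substitutions).  ``n_reads`` is the
    number of identical reads this record represents (mapping collapses
    duplicate sequences); ``weight`` is the per-read multi-mapping weight.
    """

    read_id: str
    mirna_id: str
    ref_start: int
    ref_end: int
    aln_length: int
    n_mismatches: int
    mismatches: tuple[tuple[int, str, str], ...]
    aligned_bases: tuple[tuple[int, str], ...]
    score: int
    read_start: int = 0
    read_end: int = 0
    cigar: str = ""
    weight: float = 1.0
    n_reads: int = 1

    @property
    def identity(self) -> float:
        return (self.aln_length - self.n_mismatches) / self.aln_length


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _sw_fill_pairs(reads: np.ndarray, refs: np.ndarray, scoring: ScoringScheme) -> np.ndarray:
    """Fill the Smith-Waterman H matrix for N (read, reference) pairs at
    once.

    ``reads`` is (N, R) and ``refs`` (N, C), uint8, padded with two distinct
    sentinel values that match nothing (including each other); padded rows
    and columns then never take part in an optimal local alignment, so one
    batched fill handles mixed lengths.  Returns H of shape (N, R+1, C+1).

    Vectorization note: within a row, the left-gap (gap-in-read) term
    normally creates a sequential dependency.  Because gap_open <= gap_extend,
    opening a new gap from a cell whose best path itself ends in a left gap
    is always dominated by extending that gap, so the left-gap term equals a
    running maximum over the gap-free row scores and can be computed with a
    prefix scan.
    """
    n, C = refs.shape
    R = reads.shape[1]
    mo, mi, go, ge = scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    H = np.zeros((n, R + 1, C + 1), dtype=np.int32)
    F = np.full((n, C), NEG_INF, dtype=np.int32)  # gap in reference (up moves)
    og = (np.arange(C, dtype=np.int32) * ge)[None, :]
    base = np.empty((n, C), dtype=np.int32)
    g = np.empty((n, C), dtype=np.int32)
    for i in range(1, R + 1):
        sub = np.where(refs == reads[:, i - 1 : i], mo, mi)
        np.add(H[:, i - 1, :C], sub, out=base)          # diagonal move
        np.maximum(H[:, i - 1, 1:] + go, F + ge, out=F)  # up-gap move
        np.maximum(base, F, out=base)
        np.maximum(base, 0, out=base)
        # left-gap term via prefix scan (see docstring)
        g[:, 0] = 0
        np.subtract(base[:, :-1], og[:, 1:], out=g[:, 1:])
        np.maximum.accumulate(g, axis=1, out=g)
        g += og + go                                     # g is now the E term
        np.maximum(base, g, out=H[:, i, 1:])
    return H


def _sw_fill(read: np.ndarray, refs: np.ndarray, scoring: ScoringScheme) -> np.ndarray:
    """H matrices of one read against a stack of (padded) references."""
    reads = np.tile(read[None, :], (refs.shape[0], 1))
    return _sw_fill_pairs(reads, refs, scoring)


def sw_score(read_seq: str, ref_seq: str, scoring: ScoringScheme = DEFAULT_SCORING) -> int:
    """Optimal local alignment score of a read against one reference."""
    H = _sw_fill(_encode(read_seq), _encode(ref_seq)[None, :], scoring)
    return int(H.max())


def sw_scores(
    read_seq: str, ref_seqs: Sequence[str], scoring: ScoringScheme = DEFAULT_SCORING
) -> np.ndarray:
    """Optimal local scores of one read against several references."""
    C = max(len(r) for r in ref_seqs)
    refs = np.zeros((len(ref_seqs), C), dtype=np.uint8)
    for k, r in enumerate(ref_seqs):
        refs[k, : len(r)] = _encode(r)
    H = _sw_fill(_encode(read_seq), refs, scoring)
    return H.reshape(len(ref_seqs), -1).max(axis=1)


def _traceback(
    read_seq: str,
    ref_seq: str,
    scoring: ScoringScheme,
    H: np.ndarray | None = None,
) -> tuple[int, list[tuple[int | None, int | None]]]:
    """Score and aligned columns [(ref_pos | None, read_pos | None)],
    1-based, applying the documented tie-breaks."""
    read = _encode(read_seq)
    ref = _encode(ref_seq)
    if H is None:
        H = _sw_fill(read, ref[None, :], scoring)[0]
    H = H[: len(read_seq) + 1, : len(ref_seq) + 1]
    mo, mi, go, ge = scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    score = int(H.max())
    if score <= 0:
        return 0, []
    i, j = np.unravel_index(int(H.argmax()), H.shape)  # first in row-major order
    cols: list[tuple[int | None, int | None]] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        sub = mo if read[i - 1] == ref[j - 1] else mi
        if H[i, j] == H[i - 1, j - 1] + sub:
            cols.append((j, i))
            i, j = i - 1, j - 1
            continue
        # gap in reference (consume read bases going up)
        gap = 1
        matched = False
        while i - gap >= 0:
            if H[i, j] == H[i - gap, j] + go + ge * (gap - 1):
                for t in range(gap):
                    cols.append((None, i - t))
                i -= gap
                matched = True
                break
            gap += 1
        if matched:
            continue
        # gap in read (consume reference bases going left)
        gap = 1
        while j - gap >= 0:
            if H[i, j] == H[i, j - gap] + go + ge * (gap - 1):
                for t in range(gap):
                    cols.append((j - t, None))
                j -= gap
                break
            gap += 1
        else:  # pragma: no cover - would indicate a DP fill bug
            raise AssertionError("traceback failed")
    cols.reverse()
    return score, cols


def _columns_to_cigar(cols: list[tuple[int | None, int | None]], read_len: int) -> str:
    ops = []
    for ref_pos, read_pos in cols:
        ops.append("M" if ref_pos and read_pos else ("D" if ref_pos else "I"))
    read_positions = [rp for _, rp in cols if rp]
    left = min(read_positions) - 1
    right = read_len - max(read_positions)
    runs: list[str] = []
    if left:
        runs.append(f"{left}S")
    k = 0
    while k < len(ops):
        j = k
        while j < len(ops) and ops[j] == ops[k]:
            j += 1
        runs.append(f"{j - k}{ops[k]}")
        k = j
    if right:
        runs.append(f"{right}S")
    return "".join(runs)


def _hit_from_traceback(
    read: Read,
    mirna: MatureMiRNA,
    scoring: ScoringScheme,
    H: np.ndarray | None = None,
) -> AlignmentHit | None:
    score, cols = _traceback(read.sequence, mirna.sequence, scoring, H=H)
    if not cols:
        return None
    ref_positions = [rp for rp, _ in cols if rp]
    read_positions = [qp for _, qp in cols if qp]
    mismatches = []
    aligned = []
    n_diff = 0
    for ref_pos, read_pos in cols:
        if ref_pos and read_pos:
            rb = mirna.sequence[ref_pos - 1]
            qb = read.sequence[read_pos - 1]
            aligned.append((ref_pos, qb))
            if rb != qb:
                mismatches.append((ref_pos, rb, qb))
                n_diff += 1
        else:
            n_diff += 1  # indel column counts as a difference
    return AlignmentHit(
        read_id=read.id,
        mirna_id=mirna.id,
        ref_start=min(ref_positions),
        ref_end=max(ref_positions),
        aln_length=len(cols),
        n_mismatches=n_diff,
        mismatches=tuple(mismatches),
        aligned_bases=tuple(aligned),
        score=score,
        read_start=min(read_positions),
        read_end=max(read_positions),
        cigar=_columns_to_cigar(cols, len(read)),
    )


def align_read(
    read: Read,
    reference_set: Sequence[MatureMiRNA],
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[AlignmentHit]:
    """Align one read against every reference; return all hits attaining the
    maximal score, or [] if that score is below ``scoring.min_score``."""
    if not reference_set:
        raise ValueError("reference set is empty")
    if len(read) < 15:
        raise ValueError(f"read {read.id} shorter than 15 nt")
    scores = sw_scores(read.sequence, [m.sequence for m in reference_set], scoring)
    best = int(scores.max())
    if best < scoring.min_score:
        return []
    hits = []
    for k in np.flatnonzero(scores == best):
        hit = _hit_from_traceback(read, reference_set[int(k)], scoring)
        assert hit is not None and hit.score == best
        hits.append(hit)
    return hits


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = 0.90,
    max_mismatches: int = 2,
) -> list[AlignmentHit]:
    """Keep hits with identity >= min_identity (inclusive) and at most
    max_mismatches differences (indel columns count)."""
    return [
        h for h in hits
        if h.identity >= min_identity and h.n_mismatches <= max_mismatches
    ]


def assign_weights(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Uniform 1/k weighting of one read's k retained equal-score hits."""
    if not hits:
        return []
    w = 1.0 / len(hits)
    return [replace(h, weight=w) for h in hits]


class KmerIndex:
    """Exact k-mer index over the reference set, used as a candidate
    prefilter: only references sharing at least one k-mer with a read are
    scored.  Standard seed-and-extend mapper practice; ``map_reads`` can
    bypass it with ``exhaustive=True``."""

    def __init__(self, references: Sequence[MatureMiRNA], k: int = 7):
        if not references:
            raise ValueError("reference set is empty")
        self.k = k
        self.references = list(references)
        self._index: dict[str, set[int]] = defaultdict(set)
        for idx, m in enumerate(references):
            for s in range(len(m.sequence) - k + 1):
                self._index[m.sequence[s : s + k]].add(idx)

    def candidates(self, sequence: str) -> list[int]:
        found: set[int] = set()
        for s in range(len(sequence) - self.k + 1):
            found |= self._index.get(sequence[s : s + self.k], set())
        return sorted(found)


@dataclass
class MappingResult:
    hits: list[AlignmentHit]
    n_reads: int
    n_mapped: int
    n_unmapped: int
    n_multimapper_discarded: int
    n_too_short: int

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0


def map_reads(
    reads: Sequence[Read],
    references: Sequence[MatureMiRNA],
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_identity: float = 0.90,
    max_mismatches: int = 2,
    max_hits: int = 8,
    k: int = 7,
    exhaustive: bool = False,
) -> MappingResult:
    """Map a replicate's reads to the reference set.

    Duplicate read sequences are collapsed and aligned once; each returned
    hit carries the multiplicity in ``n_reads`` and the representative
    read's id.  Reads whose retained equal-score hit set exceeds
    ``max_hits`` references are discarded as unplaceable.
    """
    if not references:
        raise ValueError("reference set is empty")
    index = None if exhaustive else KmerIndex(references, k=k)
    counter: Counter[str] = Counter()
    first_id: dict[str, str] = {}
    n_too_short = 0
    for r in reads:
        if len(r) < 15:
            n_too_short += 1
            continue
        counter[r.sequence] += 1
        first_id.setdefault(r.sequence, r.id)

    uniq = list(counter.items())
    all_refs = list(range(len(references)))
    cand_lists = [
        all_refs if index is None else index.candidates(seq) for seq, _ in uniq
    ]

    out: list[AlignmentHit] = []
    n_mapped = n_unmapped = n_multi = 0
    chunk = 4096  # bound DP workspace memory
    for lo in range(0, len(uniq), chunk):
        block = range(lo, min(lo + chunk, len(uniq)))
        pairs = [(u, c) for u in block for c in cand_lists[u]]
        if pairs:
            R = max(len(uniq[u][0]) for u, _ in pairs)
            C = max(len(references[c]) for _, c in pairs)
            reads_mat = np.full((len(pairs), R), 1, dtype=np.uint8)
            refs_mat = np.full((len(pairs), C), 2, dtype=np.uint8)
            for p, (u, c) in enumerate(pairs):
                s = uniq[u][0]
                reads_mat[p, : len(s)] = _encode(s)
                rseq = references[c].sequence
                refs_mat[p, : len(rseq)] = _encode(rseq)
            H = _sw_fill_pairs(reads_mat, refs_mat, scoring)
            scores = H.reshape(len(pairs), -1).max(axis=1)
        pair_pos = 0
        for u in block:
            seq, mult = uniq[u]
            n_cand = len(cand_lists[u])
            my = slice(pair_pos, pair_pos + n_cand)
            pair_pos += n_cand
            if n_cand == 0:
                n_unmapped += mult
                continue
            my_scores = scores[my]
            best = int(my_scores.max())
            if best < scoring.min_score:
                n_unmapped += mult
                continue
            rep = Read(id=first_id[seq], sequence=seq, quality="I" * len(seq))
            hits = []
            for local in np.flatnonzero(my_scores == best):
                c = cand_lists[u][int(local)]
                hit = _hit_from_traceback(
                    rep, references[c], scoring, H=H[my.start + int(local)]
                )
                hits.append(hit)
            hits = filter_hits(hits, min_identity, max_mismatches)
            if not hits:
                n_unmapped += mult
                continue
            if len(hits) > max_hits:
                n_multi += mult
                continue
            n_mapped += mult
            for h in assign_weights(hits):
                out.append(replace(h, n_reads=mult))
    return MappingResult(
        hits=out,
        n_reads=len(reads),
        n_mapped=n_mapped,
        n_unmapped=n_unmapped + n_too_short,
        n_multimapper_discarded=n_multi,
        n_too_short=n_too_short,
    )


def hits_to_tsv(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            {
                "read_id": h.read_id,
                "mirna_id": h.mirna_id,
                "ref_start": h.ref_start,
                "ref_end": h.ref_end,
                "score": h.score,
                "n_mismatches": h.n_mismatches,
                "mismatches": ";".join(f"{p}:{r}>{a}" for p, r, a in h.mismatches),
                "weight": h.weight,
                "n_reads": h.n_reads,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "mirna_id", "ref_start", "ref_end", "score",
            "n_mismatches", "mismatches", "weight", "n_reads",
        ],
    )


def hits_to_sam(
    hits: Iterable[AlignmentHit],
    references: Sequence[MatureMiRNA],
    path: str,
    read_lookup: Mapping[str, Read] | None = None,
) -> None:
    """Minimal SAM export with miRNA ids as reference names."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for m in references:
            fh.write(f"@SQ\tSN:{m.id}\tLN:{len(m)}\n")
        for h in hits:
            seq = read_lookup[h.read_id].sequence if read_lookup else "*"
            fh.write(
                f"{h.read_id}\t0\t{h.mirna_id}\t{h.ref_start}\t255\t"
                f"{h.cigar or '*'}\t*\t0\t0\t{seq}\t*\tNM:i:{h.n_mismatches}\n"
            )
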