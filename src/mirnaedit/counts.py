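"""Per-position nucleotide count tables and the 12-type mismatch spectrum.

Every retained alignment deposits its weight (1/k for a k-fold multi-mapper,
times the number of identical reads it represents) onto the observed base at
each aligned reference position.  The resulting table is the input to the
editing caller; summing substitution columns by type gives the mismatch
spectrum used to compare genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentHit
from .reference import ALPHABET, MatureMiRNA

#: The 12 ordered substitution types, reference base -> read base.
MISMATCH_TYPES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in ALPHABET for a in ALPHABET if r != a
)

_COL = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class PositionCountTable:
    """Weighted per-(miRNA, position) nucleotide counts for one replicate.

    ``counts[mirna_id]`` is a (4, L) array of weighted A/C/G/T observations;
    ``mirna_read_counts[mirna_id]`` is the total weighted number of reads
    assigned to the miRNA.
    """

    references: dict[str, MatureMiRNA]
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    mirna_read_counts: dict[str, float] = field(default_factory=dict)

    def coverage(self, mirna_id: str) -> np.ndarray:
        return self.counts[mirna_id].sum(axis=0)

    def base_count(self, mirna_id: str, position: int, base: str) -> float:
        return float(self.counts[mirna_id][_COL[base], position - 1])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid in sorted(self.counts):
            ref = self.references[mid]
            arr = self.counts[mid]
            for pos in range(1, len(ref) + 1):
                rows.append(
                    {
                        "mirna_id": mid,
                        "position": pos,
                        "ref_base": ref.sequence[pos - 1],
                        **{b: arr[_COL[b], pos - 1] for b in ALPHABET},
                        "coverage": arr[:, pos - 1].sum(),
                    }
                )
        return pd.DataFrame(
            rows, columns=["mirna_id", "position", "ref_base", *ALPHABET, "coverage"]
        )


def count_positions(
    alignments: Iterable[AlignmentHit],
    references: Sequence[MatureMiRNA] | Mapping[str, MatureMiRNA],
) -> PositionCountTable:
    """Tally weighted base observations per reference position.

    Alignments are expected to be identity-filtered and weighted already;
    each hit contributes ``weight * n_reads`` at every aligned position.
    """
    refmap = (
        dict(references)
        if isinstance(references, Mapping)
        else {m.id: m for m in references}
    )
    table = PositionCountTable(references=refmap)
    for hit in alignments:
        ref = refmap[hit.mirna_id]
        arr = table.counts.get(hit.mirna_id)
        if arr is None:
            arr = table.counts.setdefault(hit.mirna_id, np.zeros((4, len(ref))))
        w = hit.weight * hit.n_reads
        for pos, base in hit.aligned_bases:
            if not 1 <= pos <= len(ref):
                raise RuntimeError(
                    f"aligner bug: position {pos} outside {hit.mirna_id}"
                )
            arr[_COL[base], pos - 1] += w
        table.mirna_read_counts[hit.mirna_id] = (
            table.mirna_read_counts.get(hit.mirna_id, 0.0) + w
        )
    return table


@dataclass
class MismatchProfile:
    """Weighted counts and normalized fractions of the 12 substitution
    types in one replicate."""

    replicate: str
    genotype: str
    counts: dict[str, float]
    no_mismatches: bool = False

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        tot = self.total
        if tot == 0:
            return {t: 0.0 for t in MISMATCH_TYPES}
        return {t: c / tot for t, c in self.counts.items()}


def mismatch_profile(
    alignments: Iterable[AlignmentHit],
    replicate: str = "",
    genotype: str = "",
) -> MismatchProfile:
    """Sum the weighted substitution columns by type and normalize by the
    replicate's total mismatch weight (each replicate is normalized before
    any cross-replicate comparison)."""
    counts = {t: 0.0 for t in MISMATCH_TYPES}
    for hit in alignments:
        w = hit.weight * hit.n_reads
        for _pos, ref_base, read_base in hit.mismatches:
            counts[f"{ref_base}>{read_base}"] += w
    total = sum(counts.values())
    return MismatchProfile(
        replicate=replicate,
        genotype=genotype,
        counts=counts,
        no_mismatches=(total == 0),
    )


def profiles_to_frame(profiles: Sequence[MismatchProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {"replicate": p.replicate, "genotype": p.genotype, **p.fractions}
        )
    return pd.DataFrame(rows, columns=["replicate", "genotype", *MISMATCH_TYPES])


def compare_profiles(
    wt: Sequence[MismatchProfile],
    ko: Sequence[MismatchProfile],
) -> pd.DataFrame:
    """Two-sided equal-variance (classical Student) t-test per substitution
    type on the normalized per-replicate fractions, plus the KO/WT ratio of
    mean fractions."""
    if len(wt) < 2 or len(ko) < 2:
        raise ValueError("need at least 2 replicates per genotype")
    rows = []
    for t in MISMATCH_TYPES:
        x = np.array([p.fractions[t] for p in wt])
        y = np.array([p.fractions[t] for p in ko])
        mean_wt, mean_ko = x.mean(), y.mean()
        if np.allclose(x, x[0]) and np.allclose(y, y[0]):
            # degenerate zero-variance groups
            if np.isclose(x[0], y[0]):
                stat, p = 0.0, 1.0
            else:
                stat, p = float(np.sign(y[0] - x[0]) * np.inf), 0.0
        else:
            stat, p = stats.ttest_ind(y, x, equal_var=True)
        rows.append(
            {
                "mismatch_type": t,
                "mean_wt": mean_wt,
                "mean_ko": mean_ko,
                "ko_over_wt": mean_ko / mean_wt if mean_wt > 0 else np.nan,
                "t_statistic": float(stat),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows)
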