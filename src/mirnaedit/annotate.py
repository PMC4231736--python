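"""Annotation of called editing sites: seed-region membership, enzyme
dependence and sequence context.

The seed region (positions 2–7 of the mature miRNA) mediates target
recognition, so editing there can retarget the miRNA.  Comparing editing
levels between wild type and the ADAR2 knockout classifies each site by
which deaminase prefers it: a site whose editing collapses below the
detection floor in the knockout is ADAR2-exclusive, a >= 50% relative drop
is ADAR2-dependent, a >= 50% relative rise (ADAR1 gaining access in the
absence of ADAR2) is ADAR1-preferred, anything in between is shared.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calling import EditingSiteCall
from .reference import MatureMiRNA

EDGE = "edge"  # sentinel for a neighbor position outside the miRNA


class Dependence(str, Enum):
    ADAR2_EXCLUSIVE = "ADAR2_exclusive"
    ADAR2_DEPENDENT = "ADAR2_dependent"
    ADAR1_PREFERRED = "ADAR1_preferred"
    SHARED = "shared"


def in_seed(position: int, seed_range: tuple[int, int] = (2, 7)) -> bool:
    """True iff the 1-based position lies within the seed region."""
    if position < 1:
        raise ValueError("positions are 1-based")
    return seed_range[0] <= position <= seed_range[1]


def classify_dependence(
    f_wt: float,
    f_ko: float,
    rel_threshold: float = 0.5,
    detect_floor: float = 0.005,
) -> Dependence:
    """Classify a site's enzyme dependence from WT/KO editing levels.

    ADAR2-exclusive: edited in WT but below the detection floor in the
    knockout; ADAR2-dependent: at least a ``rel_threshold`` relative drop;
    ADAR1-preferred: at least a ``rel_threshold`` relative rise; otherwise
    shared.
    """
    if not (0 <= f_wt <= 1 and 0 <= f_ko <= 1):
        raise ValueError("frequencies must be in [0, 1]")
    if f_wt == 0:
        return Dependence.ADAR1_PREFERRED if f_ko > 0 else Dependence.SHARED
    if f_ko < detect_floor:
        return Dependence.ADAR2_EXCLUSIVE
    if f_ko <= (1.0 - rel_threshold) * f_wt:
        return Dependence.ADAR2_DEPENDENT
    if f_ko >= (1.0 + rel_threshold) * f_wt:
        return Dependence.ADAR1_PREFERRED
    return Dependence.SHARED


def seed_fraction(sites: Sequence[bool] | pd.Series) -> float:
    """Fraction of sites with in_seed == True."""
    sites = list(sites)
    if not sites:
        raise ValueError("empty site list")
    return sum(bool(s) for s in sites) / len(sites)


def neighbor_bases(
    mirna: MatureMiRNA, position: int
) -> tuple[str, str]:
    """5' and 3' neighbor bases of a site; EDGE when outside the miRNA."""
    up = mirna.sequence[position - 2] if position >= 2 else EDGE
    down = mirna.sequence[position] if position < len(mirna) else EDGE
    return up, down


def context_table(
    sites: Sequence[tuple[str, int]],
    reference_set: Sequence[MatureMiRNA] | Mapping[str, MatureMiRNA],
) -> pd.DataFrame:
    """Counts of the 5'- and 3'-neighbor bases over (mirna_id, position)
    sites, with rank order; edge sites counted under the EDGE sentinel."""
    refmap = (
        dict(reference_set)
        if isinstance(reference_set, Mapping)
        else {m.id: m for m in reference_set}
    )
    keys = ["A", "C", "G", "T", EDGE]
    up_counts = dict.fromkeys(keys, 0)
    down_counts = dict.fromkeys(keys, 0)
    for mid, pos in sites:
        up, down = neighbor_bases(refmap[mid], pos)
        up_counts[up] += 1
        down_counts[down] += 1
    return pd.DataFrame(
        {"upstream": up_counts, "downstream": down_counts}
    ).rename_axis("base")


def annotate_sites(
    calls: Iterable[EditingSiteCall],
    reference_set: Sequence[MatureMiRNA] | Mapping[str, MatureMiRNA],
    genotypes: tuple[str, str] = ("wt", "adar2ko"),
    seed_range: tuple[int, int] = (2, 7),
    rel_threshold: float = 0.5,
    detect_floor: float = 0.005,
    known_sites: Iterable[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Annotated-site table for called sites: seed membership, dependence
    class, neighbor context and novelty against a user-supplied list of
    previously published (mirna_id, position) sites."""
    refmap = (
        dict(reference_set)
        if isinstance(reference_set, Mapping)
        else {m.id: m for m in reference_set}
    )
    wt_label, ko_label = genotypes
    known = set(known_sites or [])
    rows = []
    for c in calls:
        if not c.called_any:
            continue
        f_wt = c.frequency.get(wt_label, 0.0)
        f_ko = c.frequency.get(ko_label, 0.0)
        up, down = neighbor_bases(refmap[c.mirna_id], c.position)
        rows.append(
            {
                "mirna_id": c.mirna_id,
                "position": c.position,
                "ref_base": c.ref_base,
                "alt_base": c.alt_base,
                f"frequency_{wt_label}": f_wt,
                f"frequency_{ko_label}": f_ko,
                "in_seed": in_seed(c.position, seed_range),
                "dependence": classify_dependence(
                    f_wt, f_ko, rel_threshold, detect_floor
                ).value,
                "context_5p": up,
                "context_3p": down,
                "known": (c.mirna_id, c.position) in known,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "position", "ref_base", "alt_base",
            f"frequency_{wt_label}", f"frequency_{ko_label}",
            "in_seed", "dependence", "context_5p", "context_3p", "known",
        ],
    )
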