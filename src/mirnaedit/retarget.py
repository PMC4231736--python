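"""Canonical seed-match target prediction for edited vs unedited miRNAs.

A-to-I editing inside the seed (positions 2–8 drive target pairing) changes
which 3'UTRs carry a complementary site, so a highly edited miRNA is
effectively retargeted.  This module scans UTRs for the three canonical
site classes — 8mer (perfect match to positions 2–8 plus an A opposite
position 1), 7mer-m8 (match to 2–8) and 7mer-A1 (match to 2–7 plus the A) —
and compares the target sets of the unedited and the seed-edited isoform.
Only seed complementarity is considered; no context scoring, conservation
or 3'-supplementary pairing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    """One canonical seed-match site in a 3'UTR.

    ``utr_position`` is the 1-based start of the matched UTR stretch;
    ``matched_seed`` is that UTR substring (which is the reverse complement
    of the miRNA seed, plus the target A for A1-type sites).
    """

    utr_id: str
    site_type: str  # "8mer" | "7mer-m8" | "7mer-A1"
    utr_position: int
    matched_seed: str


def edit_seed(mirna_sequence: str, position: int) -> str:
    """Apply a single A→G editing event at a 1-based position."""
    if not 1 <= position <= len(mirna_sequence):
        raise ValueError(f"position {position} outside sequence")
    if mirna_sequence[position - 1] != "A":
        raise ValueError(
            f"base at position {position} is {mirna_sequence[position - 1]}, not A"
        )
    return mirna_sequence[: position - 1] + "G" + mirna_sequence[position:]


def find_canonical_sites(
    mirna_sequence: str,
    utr_sequence: str,
    utr_id: str = "",
    include_6mer: bool = False,
) -> list[SeedSite]:
    """All canonical seed-match sites of a miRNA in one UTR.

    Every occurrence of the reverse complement of the 6-nt seed core
    (miRNA positions 2–7) is classified by the flanks: a match extended to
    position 8 on the 5' side and an A opposite position 1 on the 3' side
    makes an 8mer; only one of the two makes a 7mer-m8 or 7mer-A1; with
    ``include_6mer`` the bare core is reported too.  Overlapping
    occurrences are each reported; at one locus only the strongest type is
    emitted (8mer > 7mer-m8 > 7mer-A1).
    """
    if len(mirna_sequence) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    core = reverse_complement(mirna_sequence[1:7])  # pairs positions 2-7
    m8 = reverse_complement(mirna_sequence[7])      # pairs position 8
    sites: list[SeedSite] = []
    start = utr_sequence.find(core)
    while start != -1:
        has_m8 = start >= 1 and utr_sequence[start - 1] == m8
        has_a1 = start + 6 < len(utr_sequence) and utr_sequence[start + 6] == "A"
        if has_m8 and has_a1:
            sites.append(
                SeedSite(utr_id, "8mer", start, utr_sequence[start - 1 : start + 7])
            )
        elif has_m8:
            sites.append(
                SeedSite(utr_id, "7mer-m8", start, utr_sequence[start - 1 : start + 6])
            )
        elif has_a1:
            sites.append(
                SeedSite(utr_id, "7mer-A1", start + 1, utr_sequence[start : start + 7])
            )
        elif include_6mer:
            sites.append(
                SeedSite(utr_id, "6mer", start + 1, utr_sequence[start : start + 6])
            )
        start = utr_sequence.find(core, start + 1)
    return sites


def target_sets(
    mirna_sequence: str,
    edit_position: int,
    utr_collection: Mapping[str, str],
    include_6mer: bool = False,
) -> tuple[set[str], set[str], set[str]]:
    """Target-set comparison of the unedited and seed-edited isoform.

    A UTR is a target of an isoform when it carries at least one canonical
    site for it.  Returns (targets_unedited, targets_edited, overlap).
    """
    if not utr_collection:
        raise ValueError("empty UTR collection")
    edited = edit_seed(mirna_sequence, edit_position)
    targets_unedited = {
        uid
        for uid, utr in utr_collection.items()
        if find_canonical_sites(mirna_sequence, utr, uid, include_6mer)
    }
    targets_edited = {
        uid
        for uid, utr in utr_collection.items()
        if find_canonical_sites(edited, utr, uid, include_6mer)
    }
    return targets_unedited, targets_edited, targets_unedited & targets_edited
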