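"""Per-site χ² detection of A→G (and T→C) editing events.

Inosine base-pairs like guanosine, so A-to-I editing shows up as an A→G
mismatch against the mature miRNA reference.  For every adenosine of every
sufficiently covered miRNA, the observed A/G split among reads is compared
with a goodness-of-fit null in which G arises only from background
substitution noise.  The null alt rate is estimated per replicate from the
global alignment statistics: the overall perfect-match rate over all aligned
columns, and the overall rate of substitutions other than A→G (those cannot
be caused by A-to-I editing, so they estimate the technical noise floor).
P-values are Benjamini–Hochberg adjusted within each replicate, and a site
is called in a genotype when it is significant in the required number of
replicates (all of them by default, or at least k of n).

The analogous T→C test uses a fixed sequencing error rate (0.001) as its
null rate, because T→C counts would otherwise be contaminated by the very
signal under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import AlignmentHit
from .counts import PositionCountTable

SEQUENCING_ERROR_RATE = 1e-3


@dataclass(frozen=True)
class NullRates:
    """Global per-replicate alignment statistics used as the χ² null.

    p_match: fraction of aligned columns matching the reference.
    eps_sub: fraction of aligned columns with a non-A→G substitution.
    eps_seq: fixed sequencing error rate for the T→C analog.
    """

    p_match: float
    eps_sub: float
    eps_seq: float = SEQUENCING_ERROR_RATE

    def __post_init__(self) -> None:
        if not 0.0 <= self.eps_sub <= 1.0 - self.p_match + 1e-12:
            raise ValueError(
                f"require 0 <= eps_sub <= 1 - p_match, got {self.eps_sub}, {self.p_match}"
            )

    def null_alt_rate(self, mode: str = "aggregate") -> float:
        """Expected alt fraction under the null.

        "aggregate" uses the total non-A→G substitution rate directly;
        "per_type" divides it by the 11 possible non-A→G substitution
        types to approximate a single type's rate.
        """
        if mode == "aggregate":
            return self.eps_sub
        if mode == "per_type":
            return self.eps_sub / 11.0
        raise ValueError(f"unknown null mode {mode!r}")


def estimate_null_rates(
    alignments: Iterable[AlignmentHit],
    eps_seq: float = SEQUENCING_ERROR_RATE,
) -> NullRates:
    """Weighted perfect-match and non-A→G substitution rates over all
    aligned columns of one replicate."""
    total = 0.0
    mismatch = 0.0
    ag = 0.0
    for hit in alignments:
        w = hit.weight * hit.n_reads
        total += w * len(hit.aligned_bases)
        for _pos, ref_base, read_base in hit.mismatches:
            mismatch += w
            if ref_base == "A" and read_base == "G":
                ag += w
    if total == 0:
        raise ValueError("no aligned columns; cannot estimate null rates")
    return NullRates(
        p_match=(total - mismatch) / total,
        eps_sub=(mismatch - ag) / total,
        eps_seq=eps_seq,
    )


def _chi2_arrays(
    ref: np.ndarray, alt: np.ndarray, null_alt_rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-df goodness-of-fit with a one-sided gate: only an
    excess of alt reads over expectation can be significant."""
    n = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        exp_alt = n * null_alt_rate
        exp_ref = n * (1.0 - null_alt_rate)
        stat = (alt - exp_alt) ** 2 / exp_alt + (ref - exp_ref) ** 2 / exp_ref
        stat = np.where(n > 0, stat, 0.0)
        p = stats.chi2.sf(stat, df=1)
        frac = np.where(n > 0, alt / np.where(n > 0, n, 1.0), 0.0)
    p = np.where(frac <= null_alt_rate, 1.0, p)
    return stat, p


def chi2_editing_test(
    ref_count: float, alt_count: float, null_alt_rate: float
) -> tuple[float, float]:
    """χ² goodness-of-fit on the {ref, alt} split at one site.

    Expected counts are n·(1−rate) and n·rate; the reported p-value is the
    upper χ²₁ tail, set to 1 whenever the observed alt fraction does not
    exceed the null rate (depletion is never called as editing).
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if ref_count + alt_count == 0:
        raise ValueError("ref_count + alt_count must be positive")
    if not 0.0 < null_alt_rate < 1.0:
        raise ValueError("null_alt_rate must be in (0, 1)")
    stat, p = _chi2_arrays(
        np.array([ref_count], float), np.array([alt_count], float), null_alt_rate
    )
    return float(stat[0]), float(p[0])


def t2c_test(
    t_count: float, c_count: float, eps_seq: float = SEQUENCING_ERROR_RATE
) -> tuple[float, float]:
    """T→C analog of the editing test with the sequencing error rate as
    the null alt rate."""
    return chi2_editing_test(t_count, c_count, eps_seq)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, in [0,1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class ReplicateSiteStats:
    ref_count: float
    alt_count: float
    coverage: float
    frequency: float
    statistic: float
    p_value: float
    q_value: float
    significant: bool


@dataclass
class EditingSiteCall:
    """One (miRNA, position, substitution type) test result across both
    genotypes.  ``frequency`` is the pooled-count editing level
    alt/(ref+alt) per genotype; ``called`` records whether the replicate
    consistency rule was met in each genotype."""

    mirna_id: str
    position: int
    ref_base: str
    alt_base: str
    replicates: dict[str, list[ReplicateSiteStats]] = field(default_factory=dict)
    frequency: dict[str, float] = field(default_factory=dict)
    significant_replicates: dict[str, int] = field(default_factory=dict)
    called: dict[str, bool] = field(default_factory=dict)

    @property
    def called_any(self) -> bool:
        return any(self.called.values())


_MODES = {"AG": ("A", "G"), "TC": ("T", "C")}


def call_sites(
    tables: Mapping[str, Sequence[PositionCountTable]],
    null_rates: Mapping[str, Sequence[NullRates]],
    alpha: float = 0.05,
    min_coverage: float = 100.0,
    consistency: str = "all",
    k: int = 2,
    mode: str = "AG",
    null_mode: str = "aggregate",
) -> list[EditingSiteCall]:
    """Test every reference-base position of every sufficiently covered
    miRNA, BH-adjust within each replicate, and call sites meeting the
    replicate-consistency rule.

    ``tables`` maps genotype -> per-replicate count tables; a miRNA is
    tested in a genotype only if its weighted read count is at least
    ``min_coverage`` in every replicate of that genotype.  ``consistency``
    is "all" (significant in every replicate) or "k_of_n" (at least ``k``).
    For mode "TC" the null alt rate is the fixed sequencing error rate.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}")
    if consistency not in ("all", "k_of_n"):
        raise ValueError(f"consistency must be 'all' or 'k_of_n', got {consistency!r}")
    ref_base, alt_base = _MODES[mode]

    calls: dict[tuple[str, int], EditingSiteCall] = {}
    for genotype, reps in tables.items():
        reps = list(reps)
        if len(reps) < 2:
            raise ValueError(f"{genotype}: need at least 2 replicates")
        rates = list(null_rates[genotype])
        if len(rates) != len(reps):
            raise ValueError(f"{genotype}: one NullRates per replicate required")

        eligible = sorted(
            mid
            for mid in reps[0].counts
            if all(t.mirna_read_counts.get(mid, 0.0) >= min_coverage for t in reps)
        )
        sites = [
            (mid, pos)
            for mid in eligible
            for pos in range(1, len(reps[0].references[mid]) + 1)
            if reps[0].references[mid].sequence[pos - 1] == ref_base
        ]
        if not sites:
            continue

        per_rep: list[list[ReplicateSiteStats]] = []
        for table, rates_r in zip(reps, rates):
            ref = np.array([table.base_count(m, p, ref_base) for m, p in sites])
            alt = np.array([table.base_count(m, p, alt_base) for m, p in sites])
            cov = np.array([float(table.coverage(m)[p - 1]) for m, p in sites])
            rate = (
                rates_r.eps_seq if mode == "TC" else rates_r.null_alt_rate(null_mode)
            )
            stat, p = _chi2_arrays(ref, alt, rate)
            q = bh_adjust(p)
            n = ref + alt
            freq = np.where(n > 0, alt / np.where(n > 0, n, 1.0), 0.0)
            per_rep.append(
                [
                    ReplicateSiteStats(
                        ref_count=float(ref[i]),
                        alt_count=float(alt[i]),
                        coverage=float(cov[i]),
                        frequency=float(freq[i]),
                        statistic=float(stat[i]),
                        p_value=float(p[i]),
                        q_value=float(q[i]),
                        significant=bool(alpha > 0 and q[i] <= alpha),
                    )
                    for i in range(len(sites))
                ]
            )

        needed = len(reps) if consistency == "all" else k
        for i, (mid, pos) in enumerate(sites):
            call = calls.setdefault(
                (mid, pos),
                EditingSiteCall(
                    mirna_id=mid, position=pos, ref_base=ref_base, alt_base=alt_base
                ),
            )
            rep_stats = [per_rep[r][i] for r in range(len(reps))]
            call.replicates[genotype] = rep_stats
            tot_ref = sum(s.ref_count for s in rep_stats)
            tot_alt = sum(s.alt_count for s in rep_stats)
            call.frequency[genotype] = (
                tot_alt / (tot_ref + tot_alt) if tot_ref + tot_alt > 0 else 0.0
            )
            n_sig = sum(s.significant for s in rep_stats)
            call.significant_replicates[genotype] = n_sig
            call.called[genotype] = n_sig >= needed

    return sorted(calls.values(), key=lambda c: (c.mirna_id, c.position))


def calls_to_frame(calls: Sequence[EditingSiteCall]) -> pd.DataFrame:
    """Flat table of the call list: pooled editing level (percent), call
    flag and per-replicate q-values per genotype."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "mirna_id": c.mirna_id,
            "position": c.position,
            "ref_base": c.ref_base,
            "alt_base": c.alt_base,
        }
        for g in sorted(c.replicates):
            row[f"editing_pct_{g}"] = 100.0 * c.frequency.get(g, 0.0)
            row[f"called_{g}"] = c.called.get(g, False)
            row[f"significant_replicates_{g}"] = c.significant_replicates.get(g, 0)
            for r, s in enumerate(c.replicates[g], start=1):
                row[f"q_{g}_rep{r}"] = s.q_value
                row[f"ref_{g}_rep{r}"] = s.ref_count
                row[f"alt_{g}_rep{r}"] = s.alt_count
        rows.append(row)
    return pd.DataFrame(rows)
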