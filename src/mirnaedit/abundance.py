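"""miRNA abundance: RPM normalization, expression filters, signed fold
changes and genotype deregulation tables.

Counts are normalized to reads per million mapped miRNA reads (RPM) per
replicate, which removes sequencing-depth differences between lanes.  A
miRNA is classified as up- or downregulated in the knockout when the signed
fold change exceeds the threshold, the Student t-test on RPMs is below the
p threshold, and the direction is consistent in every replicate pair.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def normalize_rpm(counts: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Reads per million: count_i * 1e6 / total."""
    arr = np.asarray(counts, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("total mapped count must be positive")
    return arr * 1e6 / total


def count_matrix(
    read_counts: Mapping[str, Sequence[Mapping[str, float]]],
) -> pd.DataFrame:
    """Assemble per-replicate count dicts into a miRNA x (genotype, rep)
    matrix with zeros for absent miRNAs.  Column names are
    '<genotype>_rep<i>' with i starting at 1."""
    cols = {}
    for genotype, reps in sorted(read_counts.items()):
        for i, rep in enumerate(reps, start=1):
            cols[f"{genotype}_rep{i}"] = pd.Series(rep, dtype=float)
    return pd.DataFrame(cols).fillna(0.0)


def expression_filters(
    counts: pd.DataFrame,
    inventory_min: float = 10.0,
    analysis_min: float = 100.0,
) -> tuple[list[str], list[str]]:
    """Two nested miRNA sets: the expression inventory (>= inventory_min
    reads in every replicate) and the analysis set (>= analysis_min reads
    in every replicate of both genotypes)."""
    inventory = counts.index[(counts >= inventory_min).all(axis=1)]
    analysis = counts.index[(counts >= analysis_min).all(axis=1)]
    return list(inventory), list(analysis)


def fold_change(wt_rpms: Sequence[float], ko_rpms: Sequence[float]) -> float:
    """Signed fold change of genotype means: r = mean(KO)/mean(WT),
    reported as r when r >= 1 and -1/r otherwise (so |fold| >= 1 and
    downregulation in the knockout is negative)."""
    mean_wt = float(np.mean(wt_rpms))
    mean_ko = float(np.mean(ko_rpms))
    if mean_wt <= 0 or mean_ko <= 0:
        raise ValueError("genotype means must be positive")
    r = mean_ko / mean_wt
    return r if r >= 1 else -1.0 / r


def deregulation_table(
    rpm: pd.DataFrame,
    genotypes: tuple[str, str] = ("wt", "adar2ko"),
    fold_threshold: float = 1.3,
    p_threshold: float = 0.1,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Classify each miRNA as up / down / unchanged in the knockout.

    ``rpm`` is a miRNA x replicate matrix with '<genotype>_rep<i>' columns.
    Classification requires |fold| >= fold_threshold, a two-sided Student
    t-test p < p_threshold (on RPMs, or log RPMs with ``log_scale``) and a
    replicate-consistent direction: every per-replicate KO/WT ratio (paired
    by replicate index) must share the sign of the mean fold.
    """
    wt_label, ko_label = genotypes
    wt_cols = sorted(c for c in rpm.columns if c.startswith(f"{wt_label}_rep"))
    ko_cols = sorted(c for c in rpm.columns if c.startswith(f"{ko_label}_rep"))
    if len(wt_cols) < 2 or len(ko_cols) < 2:
        raise ValueError("need at least 2 replicates per genotype")

    rows = []
    for mid, row in rpm.iterrows():
        wt = row[wt_cols].to_numpy(dtype=float)
        ko = row[ko_cols].to_numpy(dtype=float)
        if wt.mean() <= 0 or ko.mean() <= 0:
            continue
        fold = fold_change(wt, ko)
        x, y = (np.log2(wt), np.log2(ko)) if log_scale else (wt, ko)
        if np.allclose(x, x[0]) and np.allclose(y, y[0]):
            p = 1.0 if np.isclose(x[0], y[0]) else 0.0
        else:
            p = float(stats.ttest_ind(y, x, equal_var=True).pvalue)
        ratios = ko[: len(wt)] / wt[: len(ko)]
        consistent = bool((ratios > 1).all() if fold > 0 else (ratios < 1).all())
        if abs(fold) >= fold_threshold and p < p_threshold and consistent:
            cls = "up" if fold > 0 else "down"
        else:
            cls = "unchanged"
        rows.append(
            {
                "mirna_id": mid,
                "mean_rpm_wt": wt.mean(),
                "mean_rpm_ko": ko.mean(),
                "fold_change": fold,
                "p_value": p,
                "consistent": consistent,
                "class": cls,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "mean_rpm_wt", "mean_rpm_ko",
            "fold_change", "p_value", "consistent", "class",
        ],
    ).set_index("mirna_id")
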