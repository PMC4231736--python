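"""Simulation studies that measure the pipeline's operating
characteristics: null calibration of the editing caller, sensitivity and
frequency accuracy on planted sites, the wild-type/knockout mismatch-
spectrum contrast, and abundance classification accuracy.

Each study generates reads with the synthetic-data model, runs the full
trim → map → count → call chain, and scores the result against the known
truth.  All studies are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import abundance as ab
from .align import map_reads
from .calling import call_sites, estimate_null_rates
from .counts import compare_profiles, count_positions, mismatch_profile
from .readprep import length_filter, trim_reads
from .reference import generate_reference
from .simulate import (
    SimTruth,
    default_truth,
    lognormal_expression,
    plant_editing_sites,
    simulate_reads,
)


def process_replicate(truth: SimTruth, genotype: str, replicate: int):
    """simulate → trim → length-filter → map → count for one replicate.

    Returns (count table, null rates, mismatch profile, mapping result).
    """
    reads, _ = simulate_reads(truth, genotype, replicate)
    kept = length_filter(trim_reads(reads, truth.adapter))
    res = map_reads(kept, truth.mirnas)
    table = count_positions(res.hits, truth.mirnas)
    rates = estimate_null_rates(res.hits, eps_seq=truth.epsilon_seq)
    profile = mismatch_profile(
        res.hits, replicate=f"{genotype}_rep{replicate}", genotype=genotype
    )
    return table, rates, profile, res


def null_calibration(
    seeds: Iterable[int],
    n_mirnas: int = 300,
    depth: int = 100_000,
    n_replicates: int = 3,
    alpha: float = 0.05,
) -> dict:
    """False-call behaviour with no editing at all (ε_seq = 0.001 only).

    For every seed, three replicates of one genotype are simulated without
    any editing and the caller is run with all-replicate consistency.
    Reports the per-replicate fraction of tested A-sites with q <= alpha
    and the fraction of sites called (consistent in all replicates).
    """
    rep_fractions: list[float] = []
    called_fractions: list[float] = []
    for seed in seeds:
        mirnas = generate_reference(n_mirnas, (19, 25), seed=seed)
        truth = SimTruth(
            mirnas=mirnas,
            expression={"wt": lognormal_expression(mirnas, seed=seed + 1)},
            editing={},
            depth=depth,
            seed=seed,
        )
        tables, rates = [], []
        for rep in range(1, n_replicates + 1):
            table, nr, _, _ = process_replicate(truth, "wt", rep)
            tables.append(table)
            rates.append(nr)
        calls = call_sites(
            {"wt": tables}, {"wt": rates}, alpha=alpha, consistency="all"
        )
        if not calls:
            continue
        for r in range(n_replicates):
            sig = [c.replicates["wt"][r].significant for c in calls]
            rep_fractions.append(float(np.mean(sig)))
        called_fractions.append(float(np.mean([c.called["wt"] for c in calls])))
    rep_arr = np.asarray(rep_fractions)
    return {
        "per_replicate_significant_fractions": rep_fractions,
        "mean_significant_fraction": float(rep_arr.mean()),
        "se_significant_fraction": float(rep_arr.std(ddof=1) / np.sqrt(len(rep_arr)))
        if len(rep_arr) > 1 else 0.0,
        "max_significant_fraction": float(rep_arr.max()),
        "mean_called_fraction": float(np.mean(called_fractions)),
    }


def recovery_experiment(
    seed: int = 0,
    freqs: Sequence[float] = (0.05, 0.10, 0.25, 0.50, 0.80),
    sites_per_freq: int = 5,
    n_mirnas: int = 120,
    depth: int = 100_000,
    n_replicates: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity and frequency accuracy on planted well-covered sites.

    Plants ``sites_per_freq`` sites per frequency on hosts with expected
    per-replicate coverage >= 600 reads and scores recovery with
    all-replicate consistency plus the pooled frequency estimate against
    the binomial 3-SE band.
    """
    mirnas = generate_reference(n_mirnas, (19, 25), seed=seed)
    rng = np.random.default_rng(seed + 17)
    # fixed-weight hosts guarantee coverage; a log-normal tail fills the rest
    n_hosts = len(freqs) * sites_per_freq
    host_ids = [m.id for m in mirnas[:n_hosts]]
    tail = lognormal_expression(mirnas[n_hosts:], seed=seed + 1)
    expr = {mid: 0.008 for mid in host_ids}
    expr.update({mid: w * (1 - 0.008 * n_hosts) for mid, w in tail.items()})
    freq_list = [f for f in freqs for _ in range(sites_per_freq)]
    wt_sites, _ = plant_editing_sites(
        mirnas, expr, freq_list, seed=seed + 2, depth=depth,
        min_expected_reads=600.0,
    )
    truth = SimTruth(
        mirnas=mirnas, expression={"wt": expr}, editing={"wt": wt_sites},
        depth=depth, seed=seed,
    )
    tables, rates = [], []
    for rep in range(1, n_replicates + 1):
        table, nr, _, _ = process_replicate(truth, "wt", rep)
        tables.append(table)
        rates.append(nr)
    calls = {
        (c.mirna_id, c.position): c
        for c in call_sites({"wt": tables}, {"wt": rates}, alpha=alpha, consistency="all")
    }
    detected = 0
    within_band = 0
    for (mid, pos), f_true in wt_sites.items():
        call = calls.get((mid, pos))
        if call is None or not call.called["wt"]:
            continue
        detected += 1
        cov = sum(s.ref_count + s.alt_count for s in call.replicates["wt"])
        se = np.sqrt(f_true * (1 - f_true) / cov)
        if abs(call.frequency["wt"] - f_true) <= 3 * se:
            within_band += 1
    n_planted = len(wt_sites)
    return {
        "n_planted": n_planted,
        "n_detected": detected,
        "sensitivity": detected / n_planted,
        "freq_within_3se_fraction": within_band / detected if detected else 0.0,
        "false_sites": sorted(
            k for k, c in calls.items() if c.called["wt"] and k not in wt_sites
        ),
    }


def genotype_contrast(
    seeds: Iterable[int],
    n_mirnas: int = 150,
    depth: int = 30_000,
    n_sites: int = 10,
) -> dict:
    """Does removing A→G editing from the knockout lower its normalized
    A→G mismatch fraction detectably?

    Per seed, a wild type with planted editing and a knockout with all A→G
    editing removed are simulated; the per-replicate-normalized A→G
    fractions are compared with a two-sample Student t-test.  Reports the
    fraction of seeds with a significant (p < 0.05) drop and the mean
    KO/WT ratio.
    """
    n_pass = 0
    ratios = []
    seeds = list(seeds)
    for seed in seeds:
        truth = default_truth(
            seed=seed, n_mirnas=n_mirnas, depth=depth, n_sites=n_sites
        )
        truth.editing["adar2ko"] = {k: 0.0 for k in truth.editing["adar2ko"]}
        profiles = {"wt": [], "adar2ko": []}
        for g in ("wt", "adar2ko"):
            for rep in (1, 2, 3):
                _, _, profile, _ = process_replicate(truth, g, rep)
                profiles[g].append(profile)
        cmp = compare_profiles(profiles["wt"], profiles["adar2ko"]).set_index(
            "mismatch_type"
        )
        row = cmp.loc["A>G"]
        ratios.append(row["ko_over_wt"])
        if row["p_value"] < 0.05 and row["mean_ko"] < row["mean_wt"]:
            n_pass += 1
    return {
        "n_seeds": len(seeds),
        "significant_drop_fraction": n_pass / len(seeds),
        "mean_ko_over_wt_ag_ratio": float(np.mean(ratios)),
    }


def abundance_experiment(
    seed: int = 0,
    n_mirnas: int = 80,
    depth: int = 60_000,
    n_changed: int = 10,
    fold: float = 2.0,
    n_replicates: int = 3,
) -> dict:
    """Recovery of planted two-fold abundance changes.

    ``n_changed`` miRNAs are upregulated and ``n_changed`` downregulated
    ``fold``-fold in the knockout; the deregulation table's sign
    classification and fold estimates are scored against the true RPM
    folds implied by the normalized expression weights.
    """
    mirnas = generate_reference(n_mirnas, (19, 25), seed=seed)
    base = lognormal_expression(mirnas, seed=seed + 1)
    eligible = [m.id for m in mirnas if base[m.id] * depth >= 400]
    rng = np.random.default_rng(seed + 2)
    chosen = rng.choice(len(eligible), size=2 * n_changed, replace=False)
    up = {eligible[i] for i in chosen[:n_changed]}
    down = {eligible[i] for i in chosen[n_changed:]}
    ko = {
        mid: w * (fold if mid in up else (1 / fold if mid in down else 1.0))
        for mid, w in base.items()
    }
    truth = SimTruth(
        mirnas=mirnas,
        expression={"wt": dict(base), "adar2ko": ko},
        editing={},
        depth=depth,
        seed=seed,
    )
    read_counts = {"wt": [], "adar2ko": []}
    for g in ("wt", "adar2ko"):
        for rep in range(1, n_replicates + 1):
            table, _, _, _ = process_replicate(truth, g, rep)
            read_counts[g].append(dict(table.mirna_read_counts))
    counts = ab.count_matrix(read_counts)
    _, analysis = ab.expression_filters(counts)
    rpm = counts.apply(ab.normalize_rpm, axis=0)
    table = ab.deregulation_table(rpm.loc[analysis])

    correct_sign = 0
    fold_errors = []
    n_scored = 0
    for mid in up | down:
        if mid not in table.index:
            continue
        n_scored += 1
        true_ratio = truth.expression["adar2ko"][mid] / truth.expression["wt"][mid]
        true_fold = true_ratio if true_ratio >= 1 else -1 / true_ratio
        row = table.loc[mid]
        if (row["class"] == "up" and true_fold > 0) or (
            row["class"] == "down" and true_fold < 0
        ):
            correct_sign += 1
        fold_errors.append(abs(row["fold_change"] / true_fold - 1.0))
    return {
        "n_planted": 2 * n_changed,
        "n_scored": n_scored,
        "correct_sign_fraction": correct_sign / n_scored if n_scored else 0.0,
        "fold_within_15pct_fraction": float(np.mean([e <= 0.15 for e in fold_errors]))
        if fold_errors else 0.0,
        "median_fold_error": float(np.median(fold_errors)) if fold_errors else np.nan,
        "mean_coverage_analysis_set": float(counts.loc[analysis].to_numpy().mean())
        if analysis else 0.0,
    }
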