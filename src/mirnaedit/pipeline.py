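"""End-to-end orchestration: simulate/load → trim → map → count → call →
annotate → compare, with TSV outputs, a run log and summary figures.

Every stage consumes the previous stage's output only (acyclic dataflow);
all thresholds live in :class:`RunConfig`, which round-trips through YAML,
and the run log records the full configuration and per-stage record counts
for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import abundance as ab
from . import annotate as an
from .align import MappingResult, ScoringScheme, map_reads
from .calling import EditingSiteCall, NullRates, call_sites, calls_to_frame, estimate_null_rates
from .counts import (
    MismatchProfile,
    PositionCountTable,
    compare_profiles,
    count_positions,
    mismatch_profile,
    profiles_to_frame,
)
from .readprep import Read, length_filter, read_fastq, trim_reads
from .reference import MatureMiRNA, read_fasta
from .simulate import DEFAULT_ADAPTER, SimTruth, default_truth, simulate_reads, write_truth_tables

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and thresholds.

    Either ``fastqs`` (genotype -> list of FASTQ paths, one per replicate,
    plus ``reference_fasta``) or ``simulate`` (keyword arguments for the
    synthetic experiment) must be provided.
    """

    output_dir: str = "mirnaedit_out"
    reference_fasta: str | None = None
    fastqs: dict[str, list[str]] | None = None
    simulate: dict[str, Any] | None = None
    genotypes: tuple[str, str] = ("wt", "adar2ko")
    n_replicates: int = 3
    adapter: str = DEFAULT_ADAPTER
    max_error_rate: float = 0.1
    min_overlap: int = 3
    min_len: int = 18
    max_len: int = 28
    min_identity: float = 0.90
    max_mismatches: int = 2
    max_multimap: int = 8
    min_coverage: float = 100.0
    inventory_min: float = 10.0
    alpha: float = 0.05
    fold_threshold: float = 1.3
    p_threshold: float = 0.1
    seed_range: tuple[int, int] = (2, 7)
    consistency: str = "all"
    k_of_n: int = 2
    eps_seq: float = 1e-3
    null_mode: str = "aggregate"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.alpha < 0 or self.alpha > 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        self.genotypes = tuple(self.genotypes)  # type: ignore[assignment]
        self.seed_range = tuple(self.seed_range)  # type: ignore[assignment]

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["genotypes"] = list(self.genotypes)
        data["seed_range"] = list(self.seed_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    references: list[MatureMiRNA]
    truth: SimTruth | None
    mapping: dict[str, list[MappingResult]]
    tables: dict[str, list[PositionCountTable]]
    null_rates: dict[str, list[NullRates]]
    profiles: dict[str, list[MismatchProfile]]
    profile_comparison: pd.DataFrame
    calls_ag: list[EditingSiteCall]
    calls_tc: list[EditingSiteCall]
    annotated: pd.DataFrame
    abundance_table: pd.DataFrame
    summary: dict[str, Any] = field(default_factory=dict)


def _load_inputs(
    config: RunConfig,
) -> tuple[list[MatureMiRNA], dict[str, list[list[Read]]], SimTruth | None]:
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        truth = default_truth(
            seed=sim_kwargs.pop("seed", config.seed),
            genotypes=config.genotypes,
            **sim_kwargs,
        )
        reads = {
            g: [
                simulate_reads(truth, g, rep)[0]
                for rep in range(1, config.n_replicates + 1)
            ]
            for g in config.genotypes
        }
        return truth.mirnas, reads, truth
    if config.reference_fasta is None or config.fastqs is None:
        raise ValueError("either simulate or reference_fasta + fastqs must be set")
    references = read_fasta(config.reference_fasta)
    reads = {}
    for g in config.genotypes:
        paths = config.fastqs.get(g, [])
        if not paths:
            raise FileNotFoundError(f"no FASTQ files configured for genotype {g!r}")
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"missing replicate file: {p}")
        reads[g] = [read_fastq(p) for p in paths]
    return references, reads, None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and write the result bundle under
    ``config.output_dir``.  Deterministic given the configuration."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_hash: {config.config_hash()}"]

    references, raw_reads, truth = _load_inputs(config)
    scoring = ScoringScheme()
    if truth is not None:
        write_truth_tables(truth, outdir)

    mapping: dict[str, list[MappingResult]] = {}
    tables: dict[str, list[PositionCountTable]] = {}
    null_rates: dict[str, list[NullRates]] = {}
    profiles: dict[str, list[MismatchProfile]] = {}
    read_counts: dict[str, list[dict[str, float]]] = {}
    for g in config.genotypes:
        mapping[g], tables[g], null_rates[g], profiles[g] = [], [], [], []
        read_counts[g] = []
        for rep_idx, reads in enumerate(raw_reads[g], start=1):
            trimmed = trim_reads(
                reads, config.adapter, config.max_error_rate, config.min_overlap
            )
            kept = length_filter(trimmed, config.min_len, config.max_len)
            res = map_reads(
                kept,
                references,
                scoring,
                min_identity=config.min_identity,
                max_mismatches=config.max_mismatches,
                max_hits=config.max_multimap,
            )
            table = count_positions(res.hits, references)
            mapping[g].append(res)
            tables[g].append(table)
            null_rates[g].append(estimate_null_rates(res.hits, config.eps_seq))
            profiles[g].append(
                mismatch_profile(res.hits, replicate=f"{g}_rep{rep_idx}", genotype=g)
            )
            read_counts[g].append(dict(table.mirna_read_counts))
            log_lines.append(
                f"{g} rep{rep_idx}: input={len(reads)} trimmed_kept={len(kept)} "
                f"mapped={res.n_mapped} unmapped={res.n_unmapped} "
                f"multimap_discarded={res.n_multimapper_discarded}"
            )

    wt_label, ko_label = config.genotypes
    profile_cmp = compare_profiles(profiles[wt_label], profiles[ko_label])

    calls_ag = call_sites(
        tables, null_rates,
        alpha=config.alpha, min_coverage=config.min_coverage,
        consistency=config.consistency, k=config.k_of_n,
        mode="AG", null_mode=config.null_mode,
    )
    calls_tc = call_sites(
        tables, null_rates,
        alpha=config.alpha, min_coverage=config.min_coverage,
        consistency=config.consistency, k=config.k_of_n,
        mode="TC",
    )

    counts_df = ab.count_matrix(read_counts)
    inventory, analysis = ab.expression_filters(
        counts_df, config.inventory_min, config.min_coverage
    )
    rpm = counts_df.apply(ab.normalize_rpm, axis=0)
    abundance_df = ab.deregulation_table(
        rpm.loc[analysis],
        genotypes=config.genotypes,
        fold_threshold=config.fold_threshold,
        p_threshold=config.p_threshold,
    ) if analysis else pd.DataFrame()

    annotated = an.annotate_sites(
        calls_ag, references, genotypes=config.genotypes,
        seed_range=config.seed_range,
    )

    called_wt = [c for c in calls_ag if c.called.get(wt_label)]
    summary: dict[str, Any] = {
        "n_references": len(references),
        "mapped_fraction": {
            g: [round(m.mapped_fraction, 4) for m in mapping[g]]
            for g in config.genotypes
        },
        "n_mirnas_inventory": len(inventory),
        "n_mirnas_analysis": len(analysis),
        "n_sites_called_wt": len(called_wt),
        "n_sites_called_any": sum(c.called_any for c in calls_ag),
        "n_mirnas_edited_wt": len({c.mirna_id for c in called_wt}),
        "seed_fraction_called_wt": (
            an.seed_fraction([an.in_seed(c.position, config.seed_range) for c in called_wt])
            if called_wt else None
        ),
        "n_deregulated_up": int((abundance_df["class"] == "up").sum())
        if len(abundance_df) else 0,
        "n_deregulated_down": int((abundance_df["class"] == "down").sum())
        if len(abundance_df) else 0,
        "n_tc_sites_called": sum(c.called_any for c in calls_tc),
    }

    # outputs
    for g in config.genotypes:
        for i, t in enumerate(tables[g], start=1):
            t.to_frame().to_csv(outdir / f"counts_{g}_rep{i}.tsv", sep="\t", index=False)
    profiles_to_frame(
        [p for g in config.genotypes for p in profiles[g]]
    ).to_csv(outdir / "mismatch_profiles.tsv", sep="\t", index=False)
    profile_cmp.to_csv(outdir / "profile_comparison.tsv", sep="\t", index=False)
    calls_to_frame(calls_ag).to_csv(outdir / "editing_calls_AG.tsv", sep="\t", index=False)
    calls_to_frame(calls_tc).to_csv(outdir / "editing_calls_TC.tsv", sep="\t", index=False)
    annotated.to_csv(outdir / "annotated_sites.tsv", sep="\t", index=False)
    if len(abundance_df):
        abundance_df.to_csv(outdir / "abundance.tsv", sep="\t")
    config.to_yaml(outdir / "config.yaml")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    return PipelineResult(
        config=config,
        references=references,
        truth=truth,
        mapping=mapping,
        tables=tables,
        null_rates=null_rates,
        profiles=profiles,
        profile_comparison=profile_cmp,
        calls_ag=calls_ag,
        calls_tc=calls_tc,
        annotated=annotated,
        abundance_table=abundance_df,
        summary=summary,
    )


def report(result: PipelineResult, output_dir: str | Path | None = None) -> Path:
    """Human-readable summary: text plus mismatch-spectrum, fold-change and
    editing-position figures.  Returns the summary text path."""
    if not result.profiles:
        raise ValueError("empty result bundle")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(output_dir or result.config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    wt_label, ko_label = result.config.genotypes

    # mismatch spectrum per genotype (mean of per-replicate fractions)
    from .counts import MISMATCH_TYPES

    fig, ax = plt.subplots(figsize=(9, 4))
    width = 0.4
    xs = range(len(MISMATCH_TYPES))
    for off, (g, color) in enumerate(
        [(wt_label, "#1f77b4"), (ko_label, "#d62728")]
    ):
        means = [
            sum(p.fractions[t] for p in result.profiles[g]) / len(result.profiles[g])
            for t in MISMATCH_TYPES
        ]
        ax.bar([x + off * width for x in xs], means, width, label=g, color=color)
    ax.set_xticks([x + width / 2 for x in xs])
    ax.set_xticklabels(MISMATCH_TYPES, rotation=60)
    ax.set_ylabel("fraction of all mismatches")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "mismatch_spectrum.png", dpi=120)
    plt.close(fig)

    # ranked fold change
    if len(result.abundance_table):
        folds = result.abundance_table["fold_change"].sort_values()
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(range(len(folds)), folds.to_numpy(), ".")
        ax.axhline(result.config.fold_threshold, ls=":", c="gray")
        ax.axhline(-result.config.fold_threshold, ls=":", c="gray")
        ax.set_xlabel("miRNA rank")
        ax.set_ylabel(f"signed fold change ({ko_label} vs {wt_label})")
        fig.tight_layout()
        fig.savefig(outdir / "fold_change_ranked.png", dpi=120)
        plt.close(fig)

    # editing position histogram
    lines = [f"run {result.config.config_hash()}"]
    called = [c for c in result.calls_ag if c.called_any]
    if called:
        positions = [c.position for c in called]
        fig, ax = plt.subplots(figsize=(6, 4))
        bins = range(1, max(positions) + 2)
        ax.hist(positions, bins=bins, color="#2ca02c", rwidth=0.8)
        ax.set_xlabel("editing position in mature miRNA")
        ax.set_ylabel("number of called sites")
        fig.tight_layout()
        fig.savefig(outdir / "editing_positions.png", dpi=120)
        plt.close(fig)
    else:
        lines.append("no editing sites were called")

    lines.extend(f"{k}: {v}" for k, v in result.summary.items())
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
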