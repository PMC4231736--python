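"""Synthetic strand-specific small-RNA sequencing reads with ground truth.

The generator emulates the structure of a two-genotype (wild type vs ADAR2
knockout) brain small-RNA experiment: a few hundred expressed miRNAs with a
heavy-tailed abundance distribution in which a handful of miRNAs carry about
half of all reads, per-site A→G (and T→C) editing frequencies between 0 and
80% that differ by genotype, a uniform per-base substitution error, and 3'
adapter read-through on every read (inserts are shorter than the 36 nt read
length).  Reads are emitted sense-strand only, matching a strand-specific
cloning protocol.

Generative model, per read: a source miRNA is drawn from the genotype's
expression weights; each edited site converts independently with its true
frequency (A→G on an A reference base, T→C on a T); the edited insert is
concatenated with the adapter (tiled if needed) and cut to the read length;
finally every base is substituted independently with probability ε_seq,
uniformly to one of the three other bases.  Editing precedes sequencing
error; sites are independent across reads.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .readprep import Read
from .reference import ALPHABET, MatureMiRNA, generate_reference

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_CODE = {b: i for i, b in enumerate(ALPHABET)}
_LUT = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``expression`` maps genotype -> {mirna_id: weight}; weights are
    normalized to sum to 1 within each genotype.  ``editing`` maps
    genotype -> {(mirna_id, 1-based position): true frequency}; a site's
    reference base must be A (A→G truth) or T (T→C truth).
    """

    mirnas: list[MatureMiRNA]
    expression: dict[str, dict[str, float]]
    editing: dict[str, dict[tuple[str, int], float]] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    epsilon_seq: float = 1e-3
    depth: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.epsilon_seq < 1:
            raise ValueError("epsilon_seq must be in [0, 1)")
        by_id = {m.id: m for m in self.mirnas}
        for genotype, weights in self.expression.items():
            total = sum(weights.values())
            if total <= 0 or any(w < 0 for w in weights.values()):
                raise ValueError(f"{genotype}: expression weights must be >= 0 with positive sum")
            self.expression[genotype] = {k: w / total for k, w in weights.items()}
        for genotype, sites in self.editing.items():
            for (mid, pos), f in sites.items():
                if mid not in by_id:
                    raise ValueError(f"edited miRNA {mid!r} not in reference")
                base = by_id[mid].base_at(pos)
                if base not in "AT":
                    raise ValueError(
                        f"editing site {mid}:{pos} has reference base {base}; must be A or T"
                    )
                if not 0 <= f <= 1:
                    raise ValueError(f"editing frequency must be in [0,1], got {f}")

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.expression)

    def mirna(self, mirna_id: str) -> MatureMiRNA:
        return next(m for m in self.mirnas if m.id == mirna_id)

    def editing_table(self) -> pd.DataFrame:
        rows = [
            {"mirna_id": mid, "position": pos, "genotype": g, "f_true": f}
            for g, sites in sorted(self.editing.items())
            for (mid, pos), f in sorted(sites.items())
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "position", "genotype", "f_true"])

    def expression_table(self) -> pd.DataFrame:
        rows = [
            {"mirna_id": mid, "genotype": g, "expression_weight": w}
            for g, weights in sorted(self.expression.items())
            for mid, w in sorted(weights.items())
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "genotype", "expression_weight"])


def _replicate_rng(truth: SimTruth, genotype: str, replicate: int) -> np.random.Generator:
    # stable across processes: crc32 rather than the salted builtin hash
    return np.random.default_rng(
        np.random.SeedSequence(
            [truth.seed & 0x7FFFFFFF, zlib.crc32(genotype.encode()), replicate]
        )
    )


def simulate_reads(
    truth: SimTruth,
    genotype: str,
    replicate: int,
    read_length: int = 36,
) -> tuple[list[Read], pd.DataFrame]:
    """Simulate one replicate's reads for one genotype.

    Returns the reads (exactly ``truth.depth`` of them, deterministic given
    (truth.seed, genotype, replicate)) and the replicate's editing truth
    table (mirna_id, position, genotype, f_true).
    """
    if genotype not in truth.expression:
        raise ValueError(f"unknown genotype {genotype!r}; have {truth.genotypes}")
    max_len = max(len(m) for m in truth.mirnas)
    if read_length < max_len:
        raise ValueError(f"read_length {read_length} < longest miRNA ({max_len})")

    rng = _replicate_rng(truth, genotype, replicate)
    weights = np.array(
        [truth.expression[genotype].get(m.id, 0.0) for m in truth.mirnas], dtype=float
    )
    weights = weights / weights.sum()
    counts = rng.multinomial(truth.depth, weights)
    edits = truth.editing.get(genotype, {})
    eps = truth.epsilon_seq

    chunks: list[np.ndarray] = []
    for mirna, n in zip(truth.mirnas, counts):
        if n == 0:
            continue
        filler = (truth.adapter * (read_length // max(len(truth.adapter), 1) + 2))
        template_seq = (mirna.sequence + filler)[:read_length]
        template = np.array([_CODE[b] for b in template_seq], dtype=np.uint8)
        mat = np.tile(template, (int(n), 1))
        for pos in range(1, len(mirna) + 1):
            f = edits.get((mirna.id, pos))
            if not f:
                continue
            alt = _CODE["G"] if mirna.base_at(pos) == "A" else _CODE["C"]
            mat[rng.random(int(n)) < f, pos - 1] = alt
        if eps > 0:
            err = rng.random(mat.shape) < eps
            n_err = int(err.sum())
            if n_err:
                offsets = rng.integers(1, 4, size=n_err).astype(np.uint8)
                mat[err] = (mat[err] + offsets) % 4
        chunks.append(mat)

    if chunks:
        allmat = np.concatenate(chunks, axis=0)
    else:
        allmat = np.empty((0, read_length), dtype=np.uint8)
    raw = _LUT[allmat].tobytes()
    qual = "I" * read_length
    reads = [
        Read(
            id=f"{genotype}_rep{replicate}_{i:07d}",
            sequence=raw[i * read_length : (i + 1) * read_length].decode(),
            quality=qual,
        )
        for i in range(allmat.shape[0])
    ]
    table = pd.DataFrame(
        [
            {"mirna_id": mid, "position": pos, "genotype": genotype, "f_true": f}
            for (mid, pos), f in sorted(edits.items())
        ],
        columns=["mirna_id", "position", "genotype", "f_true"],
    )
    return reads, table


def lognormal_expression(
    mirnas: Sequence[MatureMiRNA],
    seed: int = 0,
    sigma: float = 1.5,
    head_n: int = 5,
    head_fraction: float = 0.48,
) -> dict[str, float]:
    """Heavy-tailed expression weights: log-normal body with a rescaled head
    so the top ``head_n`` miRNAs jointly carry ``head_fraction`` of reads
    (about half, as observed in brain small-RNA libraries)."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(mirnas))
    head_n = min(head_n, len(mirnas))
    if 0 < head_n < len(mirnas):
        order = np.argsort(w)[::-1]
        head, tail = order[:head_n], order[head_n:]
        w[head] *= head_fraction / w[head].sum()
        w[tail] *= (1.0 - head_fraction) / w[tail].sum()
    w = w / w.sum()
    return {m.id: float(x) for m, x in zip(mirnas, w)}


def plant_editing_sites(
    mirnas: Sequence[MatureMiRNA],
    expression: Mapping[str, float],
    freqs_wt: Sequence[float],
    seed: int = 0,
    depth: int = 100_000,
    min_expected_reads: float = 300.0,
    seed_region_fraction: float = 0.64,
    seed_region: tuple[int, int] = (2, 7),
    dependence_mix: tuple[float, float, float, float] = (0.26, 0.25, 0.11, 0.38),
) -> tuple[dict[tuple[str, int], float], dict[tuple[str, int], float]]:
    """Choose A positions on well-expressed miRNAs and assign WT/KO truth.

    One site per host miRNA, one frequency per entry of ``freqs_wt``.  A
    ``seed_region_fraction`` share of sites is placed at positions 2–7.
    Sites are restricted to internal positions (2..L-1): a substitution at
    the first or last aligned position is clipped by local alignment, so
    editing there is invisible to the read-mapping approach.
    The knockout frequency follows the ``dependence_mix`` proportions
    (lost, reduced by >=50%, increased by >=50%, unchanged/shared) that the
    editing-dependence classification downstream is meant to recover.
    """
    rng = np.random.default_rng(seed)
    eligible = [
        m for m in mirnas
        if expression.get(m.id, 0.0) * depth >= min_expected_reads
        and "A" in m.sequence[1:-1]
    ]
    eligible.sort(key=lambda m: expression.get(m.id, 0.0), reverse=True)
    if len(eligible) < len(freqs_wt):
        raise ValueError(
            f"only {len(eligible)} miRNAs with expected coverage >= "
            f"{min_expected_reads}; cannot plant {len(freqs_wt)} sites"
        )
    hosts = [eligible[i] for i in rng.choice(len(eligible), size=len(freqs_wt), replace=False)]

    lo, hi = seed_region
    wt: dict[tuple[str, int], float] = {}
    ko: dict[tuple[str, int], float] = {}
    kinds = rng.choice(4, size=len(hosts), p=np.asarray(dependence_mix) / sum(dependence_mix))
    # the most highly edited sites lose editing without ADAR2: force the
    # top six frequencies into the lost/reduced classes
    top = np.argsort(np.asarray(freqs_wt))[::-1][:6]
    for idx in top:
        if kinds[idx] >= 2:
            kinds[idx] = 1
    for mirna, f_wt, kind in zip(hosts, freqs_wt, kinds):
        a_pos = [
            i + 1
            for i, b in enumerate(mirna.sequence)
            if b == "A" and 1 <= i < len(mirna.sequence) - 1
        ]
        in_seed = [p for p in a_pos if lo <= p <= hi]
        out_seed = [p for p in a_pos if not lo <= p <= hi]
        if in_seed and (not out_seed or rng.random() < seed_region_fraction):
            pos = int(rng.choice(in_seed))
        else:
            pos = int(rng.choice(out_seed if out_seed else in_seed))
        wt[(mirna.id, pos)] = float(f_wt)
        if kind == 0:        # lost in the knockout (ADAR2-exclusive)
            f_ko = 0.0
        elif kind == 1:      # reduced by at least half (ADAR2-dependent)
            f_ko = f_wt * float(rng.uniform(0.05, 0.5))
        elif kind == 2:      # increased by at least half (ADAR1-preferred)
            f_ko = min(f_wt * float(rng.uniform(1.5, 2.5)), 0.95)
        else:                # shared between enzymes
            f_ko = f_wt * float(rng.uniform(0.8, 1.2))
        ko[(mirna.id, pos)] = float(f_ko)
    return wt, ko


def default_truth(
    seed: int = 0,
    n_mirnas: int = 600,
    depth: int = 100_000,
    n_sites: int = 30,
    genotypes: tuple[str, str] = ("wt", "adar2ko"),
) -> SimTruth:
    """The default simulated experiment: ~600 expressed miRNAs with five of
    them carrying about half the reads, ~30 edited sites with WT
    frequencies from 2% to 80% (the strongest site at 80%), a
    genotype-dependent editing change, and ε_seq = 0.001."""
    mirnas = generate_reference(n_mirnas, (19, 25), seed=seed)
    expr = lognormal_expression(mirnas, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    freqs = np.concatenate([[0.80], rng.uniform(0.02, 0.6, size=n_sites - 1)])
    wt_sites, ko_sites = plant_editing_sites(
        mirnas, expr, freqs.tolist(), seed=seed + 3, depth=depth,
        min_expected_reads=max(150.0, 0.0015 * depth),
    )
    wt_label, ko_label = genotypes
    return SimTruth(
        mirnas=mirnas,
        expression={wt_label: dict(expr), ko_label: dict(expr)},
        editing={wt_label: wt_sites, ko_label: ko_sites},
        depth=depth,
        seed=seed,
    )


def write_truth_tables(truth: SimTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.editing_table().to_csv(outdir / "truth_editing.tsv", sep="\t", index=False)
    truth.expression_table().to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
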