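import numpy as np
import pytest
from Bio import Align

from mirnaedit.align import (
    DEFAULT_SCORING,
    AlignmentHit,
    ScoringScheme,
    align_read,
    assign_weights,
    filter_hits,
    map_reads,
    sw_score,
)
from mirnaedit.reference import MatureMiRNA
from mirnaedit.retarget import reverse_complement

from .conftest import make_read

# ---------------------------------------------------------------------------
# independent full dynamic-programming oracle (plain loops, three matrices)
# ---------------------------------------------------------------------------

NEG = -(10**9)


def oracle_fill(q, r, sc):
    R, C = len(q), len(r)
    H = [[0] * (C + 1) for _ in range(R + 1)]
    E = [[NEG] * (C + 1) for _ in range(R + 1)]
    F = [[NEG] * (C + 1) for _ in range(R + 1)]
    for i in range(1, R + 1):
        for j in range(1, C + 1):
            E[i][j] = max(H[i][j - 1] + sc.gap_open, E[i][j - 1] + sc.gap_extend)
            F[i][j] = max(H[i - 1][j] + sc.gap_open, F[i - 1][j] + sc.gap_extend)
            sub = sc.match if q[i - 1] == r[j - 1] else sc.mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
    return H


def oracle_score(q, r, sc=DEFAULT_SCORING):
    H = oracle_fill(q, r, sc)
    return max(max(row) for row in H)


def oracle_alignment(q, r, sc=DEFAULT_SCORING):
    """Best-score aligned columns with the documented tie-breaks: end at the
    first maximal cell in row-major order; prefer diagonal, then the
    shortest gap in the reference, then the shortest gap in the read."""
    H = oracle_fill(q, r, sc)
    best, bi, bj = 0, 0, 0
    for i in range(len(q) + 1):
        for j in range(len(r) + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    cols = []
    i, j = bi, bj
    while i > 0 and j > 0 and H[i][j] > 0:
        sub = sc.match if q[i - 1] == r[j - 1] else sc.mismatch
        if H[i][j] == H[i - 1][j - 1] + sub:
            cols.append((j, i))
            i, j = i - 1, j - 1
            continue
        moved = False
        for gap in range(1, i + 1):
            if H[i][j] == H[i - gap][j] + sc.gap_open + sc.gap_extend * (gap - 1):
                cols.extend((None, i - t) for t in range(gap))
                i -= gap
                moved = True
                break
        if moved:
            continue
        for gap in range(1, j + 1):
            if H[i][j] == H[i][j - gap] + sc.gap_open + sc.gap_extend * (gap - 1):
                cols.extend((j - t, None) for t in range(gap))
                j -= gap
                break
        else:
            raise AssertionError("oracle traceback failed")
    cols.reverse()
    return best, cols


def oracle_mismatches(q, r, sc=DEFAULT_SCORING):
    _, cols = oracle_alignment(q, r, sc)
    return tuple(
        (rp, r[rp - 1], q[qp - 1])
        for rp, qp in cols
        if rp and qp and r[rp - 1] != q[qp - 1]
    )


def random_pair(rng, related: bool):
    read_len = int(rng.integers(15, 41))
    q = "".join("ACGT"[c] for c in rng.integers(0, 4, read_len))
    if related:
        n = int(rng.integers(15, min(26, read_len + 1)))
        r = list(q[:n])
        for _ in range(int(rng.integers(0, 3))):
            k = int(rng.integers(0, n))
            r[k] = "ACGT"[int(rng.integers(0, 4))]
        r = "".join(r)
    else:
        r = "".join("ACGT"[c] for c in rng.integers(0, 4, int(rng.integers(15, 26))))
    return q, r


class TestSmithWaterman:
    def test_identity_hit(self, tiny_reference):
        m = tiny_reference[0]
        hits = align_read(make_read(m.sequence), tiny_reference)
        assert len(hits) == 1
        h = hits[0]
        assert (h.mirna_id, h.ref_start, h.ref_end) == (m.id, 1, len(m))
        assert h.n_mismatches == 0 and h.score == DEFAULT_SCORING.match * len(m)

    def test_reverse_complement_not_mapped(self, tiny_reference):
        # sense-strand-only mapping: the RC of a miRNA must yield no hit
        m = tiny_reference[0]
        hits = align_read(make_read(reverse_complement(m.sequence)), tiny_reference)
        assert hits == []

    def test_scores_match_oracle_on_random_pairs(self, rng):
        for trial in range(300):
            q, r = random_pair(rng, related=trial % 2 == 0)
            assert sw_score(q, r) == oracle_score(q, r)

    def test_scores_match_biopython_local_aligner(self, rng):
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = DEFAULT_SCORING.match
        aligner.mismatch_score = DEFAULT_SCORING.mismatch
        aligner.open_gap_score = DEFAULT_SCORING.gap_open
        aligner.extend_gap_score = DEFAULT_SCORING.gap_extend
        for trial in range(150):
            q, r = random_pair(rng, related=trial % 2 == 0)
            expected = aligner.score(q, r)
            got = sw_score(q, r)
            assert got == expected or (got == 0 and expected <= 0)

    def test_mismatch_lists_match_oracle(self, rng):
        checked = 0
        for trial in range(400):
            q, r = random_pair(rng, related=True)
            score = sw_score(q, r)
            if score < DEFAULT_SCORING.min_score:
                continue
            hits = align_read(make_read(q), [MatureMiRNA("m", r)])
            assert hits and hits[0].score == oracle_score(q, r)
            assert hits[0].mismatches == oracle_mismatches(q, r)
            checked += 1
        assert checked > 100

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_read(make_read("ACGT" * 5), [])

    def test_nonstandard_scoring_rejected(self):
        with pytest.raises(ValueError):
            ScoringScheme(match=-1)


def _hit(aln_length, n_mismatches):
    return AlignmentHit(
        read_id="r", mirna_id="m", ref_start=1, ref_end=aln_length,
        aln_length=aln_length, n_mismatches=n_mismatches,
        mismatches=(), aligned_bases=(), score=0,
    )


class TestFilterAndWeights:
    @pytest.mark.parametrize(
        "aln_length,n_mismatches,kept",
        [
            (22, 2, True),    # 20/22 = 0.909 >= 0.90
            (22, 3, False),   # 19/22 = 0.864
            (20, 2, True),    # exactly 0.90, inclusive
            (19, 2, False),   # 17/19 = 0.895
            (25, 2, True),
            (30, 3, False),   # identity fine but >2 mismatches
        ],
    )
    def test_identity_and_mismatch_gates(self, aln_length, n_mismatches, kept):
        assert bool(filter_hits([_hit(aln_length, n_mismatches)])) == kept

    @pytest.mark.parametrize("k", [1, 2, 4, 7])
    def test_uniform_weights_sum_to_one(self, k):
        weighted = assign_weights([_hit(22, 0) for _ in range(k)])
        assert all(h.weight == pytest.approx(1 / k) for h in weighted)
        assert sum(h.weight for h in weighted) == pytest.approx(1.0)

    def test_empty_weights_noop(self):
        assert assign_weights([]) == []


class TestMapReads:
    def test_heuristic_equals_exhaustive(self, small_truth):
        from mirnaedit.simulate import simulate_reads

        reads, _ = simulate_reads(small_truth, "wt", 1)
        reads = reads[:4000]
        trimmed_refs = small_truth.mirnas
        from mirnaedit.readprep import length_filter, trim_reads

        kept = length_filter(trim_reads(reads, small_truth.adapter))
        fast = map_reads(kept, trimmed_refs)
        slow = map_reads(kept, trimmed_refs, exhaustive=True)
        key = lambda res: sorted(
            (h.read_id, h.mirna_id, h.score, h.weight, h.n_reads) for h in res.hits
        )
        assert key(fast) == key(slow)
        assert fast.n_mapped == slow.n_mapped

    def test_weight_conservation_per_read(self, small_truth):
        from mirnaedit.readprep import length_filter, trim_reads
        from mirnaedit.simulate import simulate_reads

        reads, _ = simulate_reads(small_truth, "adar2ko", 2)
        kept = length_filter(trim_reads(reads[:3000], small_truth.adapter))
        res = map_reads(kept, small_truth.mirnas)
        by_read = {}
        for h in res.hits:
            by_read[h.read_id] = by_read.get(h.read_id, 0.0) + h.weight
        assert all(w == pytest.approx(1.0) for w in by_read.values())
        total = sum(h.weight * h.n_reads for h in res.hits)
        assert total == pytest.approx(res.n_mapped)

    def test_multimapper_cap_discards(self):
        # three references each one interior substitution away from the
        # read score identically; with max_hits=2 the read is unplaceable
        seq = "TACAGTCCTGAGGTACTTAGC"
        refs = []
        for i, pos in enumerate((5, 8, 11)):
            old = seq[pos]
            new = "A" if old != "A" else "C"
            refs.append(MatureMiRNA(f"m{i}", seq[:pos] + new + seq[pos + 1 :]))
        res = map_reads([make_read(seq)], refs, max_hits=2)
        assert res.n_multimapper_discarded == 1 and res.hits == []
        kept = map_reads([make_read(seq)], refs, max_hits=3)
        assert len(kept.hits) == 3
        assert all(h.weight == pytest.approx(1 / 3) for h in kept.hits)
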