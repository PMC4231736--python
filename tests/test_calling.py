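import numpy as np
import pytest
from scipy import stats

from mirnaedit.calling import (
    NullRates,
    bh_adjust,
    call_sites,
    calls_to_frame,
    chi2_editing_test,
    estimate_null_rates,
    t2c_test,
)
from mirnaedit.counts import PositionCountTable, count_positions
from mirnaedit.reference import MatureMiRNA

from .test_counts import mutated_hit, perfect_hit


def bh_oracle(p):
    """Textbook step-up recursion: q(m)=p(m); q(i)=min(q(i+1), m*p(i)/i)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        val = min(prev, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = val
        prev = val
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestNullRates:
    def test_all_perfect(self, tiny_reference):
        hits = [perfect_hit(tiny_reference[0], rid=f"r{i}") for i in range(5)]
        nr = estimate_null_rates(hits)
        assert nr.p_match == 1.0 and nr.eps_sub == 0.0

    def test_ag_excluded_from_substitution_rate(self, tiny_reference):
        # 1000 aligned columns carrying 10 mismatches, 6 of them A>G
        m = MatureMiRNA("m20", "TACAGTCCTGAGGTACTTAG")  # 20 nt
        hits = [perfect_hit(m, rid=f"p{i}") for i in range(40)]  # 800 columns
        hits += [mutated_hit(m, 4, "G", rid=f"ag{i}") for i in range(6)]
        hits += [mutated_hit(m, 2, "T", rid=f"ac{i}") for i in range(4)]
        assert sum(len(h.aligned_bases) for h in hits) == 1000
        nr = estimate_null_rates(hits)
        assert nr.eps_sub == pytest.approx(4 / 1000)
        assert nr.p_match == pytest.approx(990 / 1000)

    def test_simulated_error_rate_recovered(self, small_truth):
        from mirnaedit.align import map_reads
        from mirnaedit.readprep import length_filter, trim_reads
        from mirnaedit.simulate import SimTruth, simulate_reads

        truth = SimTruth(
            mirnas=small_truth.mirnas,
            expression={"wt": dict(small_truth.expression["wt"])},
            editing={}, depth=100_000, seed=11,
        )
        reads, _ = simulate_reads(truth, "wt", 1)
        kept = length_filter(trim_reads(reads, truth.adapter))
        res = map_reads(kept, truth.mirnas)
        nr = estimate_null_rates(res.hits)
        # expected non-A>G mismatch rate: errors hit 11 of 12 type slots
        # depending on the base composition; crude closed-form expectation
        eps = truth.epsilon_seq
        n_cols = sum(h.weight * h.n_reads * len(h.aligned_bases) for h in res.hits)
        # each erroneous base is one of 3 alternatives; A>G is 1 of 12
        # ref->alt combinations weighted by reference base usage
        a_frac = np.average(
            [m.sequence.count("A") / len(m) for m in truth.mirnas],
            weights=[truth.expression["wt"][m.id] for m in truth.mirnas],
        )
        expected = eps * (1 - a_frac / 3)
        se = np.sqrt(expected * (1 - expected) / n_cols)
        assert abs(nr.eps_sub - expected) < 4 * se + 1e-4

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            NullRates(p_match=0.9, eps_sub=0.2)
        with pytest.raises(ValueError):
            estimate_null_rates([])

    def test_per_type_mode_divides_by_eleven(self):
        nr = NullRates(p_match=0.99, eps_sub=0.0044)
        assert nr.null_alt_rate("per_type") == pytest.approx(0.0044 / 11)
        with pytest.raises(ValueError):
            nr.null_alt_rate("bogus")


class TestChi2Test:
    def test_observed_equals_expected_gives_null(self):
        stat, p = chi2_editing_test(999, 1, 0.001)
        assert stat == pytest.approx(0.0)
        assert p == 1.0

    def test_formula_example(self):
        # n=1000, alt=20, rate 0.001: (20-1)^2/1 + (980-999)^2/999
        stat, p = chi2_editing_test(980, 20, 0.001)
        expected = (20 - 1) ** 2 / 1 + (980 - 999) ** 2 / 999
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(361.361, abs=0.01)
        assert p < 1e-15
        assert p == pytest.approx(float(stats.chi2.sf(expected, 1)))

    def test_one_sided_gate(self):
        _, p = chi2_editing_test(1000, 0, 0.001)
        assert p == 1.0

    def test_monotone_in_alt_count_above_expectation(self):
        stats_seq = [
            chi2_editing_test(1000 - a, a, 0.001)[0] for a in range(2, 50)
        ]
        assert all(b >= a for a, b in zip(stats_seq, stats_seq[1:]))

    @pytest.mark.parametrize("ref,alt,rate", [(-1, 5, 0.001), (5, -1, 0.001),
                                              (0, 0, 0.001), (10, 1, 0.0), (10, 1, 1.0)])
    def test_invalid_arguments(self, ref, alt, rate):
        with pytest.raises(ValueError):
            chi2_editing_test(ref, alt, rate)


class TestT2C:
    def test_exact_null_fraction(self):
        stat, p = t2c_test(999, 1)  # c fraction exactly 0.001
        assert stat == pytest.approx(0.0) and p == 1.0

    def test_detectable_at_paper_scale(self):
        # 1.9% T>C at 10^4 coverage is overwhelmingly significant
        _, p = t2c_test(10_000 - 190, 190)
        assert p < 1e-15

    def test_zero_alt_low_coverage(self):
        _, p = t2c_test(50, 0)
        assert p == 1.0


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_adjust([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_matches_step_up_recursion_on_random_vectors(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            p = rng.random(n) ** float(rng.uniform(0.5, 3))
            assert bh_adjust(p) == pytest.approx(bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def table_from_counts(mirna: MatureMiRNA, pos: int, ref_n: float, alt_n: float) -> PositionCountTable:
    """Synthetic count table: ref_n+alt_n reads at one site, perfect
    elsewhere."""
    hits = [perfect_hit(mirna, rid="bulk", weight=1.0, n_reads=int(ref_n))]
    if alt_n:
        alt_base = "G" if mirna.sequence[pos - 1] == "A" else "C"
        hits.append(mutated_hit(mirna, pos, alt_base, rid="alt",
                                weight=1.0, n_reads=int(alt_n)))
    return count_positions(hits, [mirna])


class TestCallSites:
    def test_paper_style_frequency(self):
        # a site with 268 reference and 732 alternative reads reports an
        # editing level of 73.2% at its position
        m = MatureMiRNA("mir-star", "TACAGTCCTGAGGTACTTGACAT")  # pos 20 = A
        assert m.base_at(20) == "A"
        tables = {"wt": [table_from_counts(m, 20, 268, 732) for _ in range(3)]}
        rates = {"wt": [NullRates(0.99, 0.004)] * 3}
        calls = call_sites(tables, rates, min_coverage=100)
        call = next(c for c in calls if c.position == 20)
        assert call.frequency["wt"] == pytest.approx(0.732)
        assert call.called["wt"]
        frame = calls_to_frame(calls)
        row = frame[frame.position == 20].iloc[0]
        assert row["editing_pct_wt"] == pytest.approx(73.2)

    def test_recovers_simulated_low_frequency_site(self, small_truth):
        from mirnaedit.align import map_reads
        from mirnaedit.readprep import length_filter, trim_reads
        from mirnaedit.simulate import SimTruth, simulate_reads

        truth = SimTruth(
            mirnas=small_truth.mirnas,
            expression={"wt": dict(small_truth.expression["wt"])},
            editing={"wt": {("mir-a", 4): 0.10}},
            depth=20_000, seed=21,
        )
        tables, rates = {"wt": []}, {"wt": []}
        for rep in (1, 2, 3):
            reads, _ = simulate_reads(truth, "wt", rep)
            kept = length_filter(trim_reads(reads, truth.adapter))
            res = map_reads(kept, truth.mirnas)
            tables["wt"].append(count_positions(res.hits, truth.mirnas))
            rates["wt"].append(estimate_null_rates(res.hits))
        calls = call_sites(tables, rates)
        hit = next(c for c in calls if (c.mirna_id, c.position) == ("mir-a", 4))
        assert hit.called["wt"]
        cov = sum(s.ref_count + s.alt_count for s in hit.replicates["wt"])
        se = np.sqrt(0.1 * 0.9 / cov)
        assert abs(hit.frequency["wt"] - 0.10) <= 3 * se
        # nothing else called
        others = [c for c in calls if c.called["wt"] and c.mirna_id != "mir-a"]
        assert others == []

    def test_consistency_modes(self):
        m = MatureMiRNA("m", "TACAGTCCTGAGGTACTTAGC")
        strong = table_from_counts(m, 4, 900, 100)
        null = table_from_counts(m, 4, 1000, 0)
        rates = {"wt": [NullRates(0.99, 0.004)] * 3}
        tables = {"wt": [strong, strong, null]}
        all_mode = call_sites(tables, rates, consistency="all")
        two_mode = call_sites(tables, rates, consistency="k_of_n", k=2)
        site = ("m", 4)
        call_all = next(c for c in all_mode if (c.mirna_id, c.position) == site)
        call_two = next(c for c in two_mode if (c.mirna_id, c.position) == site)
        assert not call_all.called["wt"]
        assert call_two.called["wt"]
        assert call_two.significant_replicates["wt"] == 2

    def test_low_coverage_mirnas_not_tested(self):
        m = MatureMiRNA("m", "TACAGTCCTGAGGTACTTAGC")
        tables = {"wt": [table_from_counts(m, 4, 40, 10)] * 3}
        rates = {"wt": [NullRates(0.99, 0.004)] * 3}
        assert call_sites(tables, rates, min_coverage=100) == []

    def test_determinism(self):
        m = MatureMiRNA("m", "TACAGTCCTGAGGTACTTAGC")
        tables = {"wt": [table_from_counts(m, 4, 900, 100)] * 3}
        rates = {"wt": [NullRates(0.99, 0.004)] * 3}
        a = calls_to_frame(call_sites(tables, rates))
        b = calls_to_frame(call_sites(tables, rates))
        assert a.equals(b)

    def test_invalid_consistency(self):
        with pytest.raises(ValueError):
            call_sites({"wt": []}, {"wt": []}, consistency="bogus")

    def test_too_few_replicates(self):
        m = MatureMiRNA("m", "TACAGTCCTGAGGTACTTAGC")
        with pytest.raises(ValueError):
            call_sites({"wt": [table_from_counts(m, 4, 10, 1)]},
                       {"wt": [NullRates(1.0, 0.0)]})
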