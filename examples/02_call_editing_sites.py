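"""Call A-to-I editing sites on simulated wild-type replicates and compare
the calls with the planted truth.

Each A position of every miRNA with >= 100 reads per replicate is tested
with the chi-squared goodness-of-fit statistic against a null alt rate
estimated from the replicate's global alignment statistics, BH-adjusted
within the replicate, and called when significant in all three replicates.
"""

from mirnaedit import call_sites, default_truth
from mirnaedit.benchmarks import process_replicate

truth = default_truth(seed=5, n_mirnas=200, depth=50_000, n_sites=12)

tables, rates = [], []
for rep in (1, 2, 3):
    table, null_rates, _, _ = process_replicate(truth, "wt", rep)
    tables.append(table)
    rates.append(null_rates)
    print(f"replicate {rep}: perfect-match rate {null_rates.p_match:.4f}, "
          f"non-A>G substitution rate {null_rates.eps_sub:.5f}")

calls = call_sites({"wt": tables}, {"wt": rates}, alpha=0.05, min_coverage=100)
called = [c for c in calls if c.called["wt"]]
planted = truth.editing["wt"]
print(f"\ncalled {len(called)} sites (planted: {len(planted)})")
for c in called:
    f_true = planted.get((c.mirna_id, c.position))
    print(f"  {c.mirna_id} position {c.position}: "
          f"estimated {100 * c.frequency['wt']:.1f}% "
          f"(truth {100 * f_true:.1f}%)" if f_true is not None else
          f"  {c.mirna_id} position {c.position}: FALSE POSITIVE")
# The estimated editing level is the pooled G/(A+G) over replicates; with
# hundreds of reads per site it lands within a few percent of the truth.
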