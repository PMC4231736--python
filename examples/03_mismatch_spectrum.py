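"""Compare the 12-type mismatch spectrum between wild type and the ADAR2
knockout.

A-to-I editing reads as A>G, so the wild type's spectrum is dominated by
A>G while a knockout lacking most editing shows a flatter spectrum; the
per-replicate-normalized fractions are compared with a Student t-test.
"""

from mirnaedit import compare_profiles, default_truth
from mirnaedit.benchmarks import process_replicate

truth = default_truth(seed=3, n_mirnas=150, depth=30_000, n_sites=10)
# remove all editing from the knockout to mimic a complete loss
truth.editing["adar2ko"] = {k: 0.0 for k in truth.editing["adar2ko"]}

profiles = {"wt": [], "adar2ko": []}
for genotype in profiles:
    for rep in (1, 2, 3):
        _, _, profile, _ = process_replicate(truth, genotype, rep)
        profiles[genotype].append(profile)

table = compare_profiles(profiles["wt"], profiles["adar2ko"])
print(table.round(4).to_string(index=False))
ag = table.set_index("mismatch_type").loc["A>G"]
print(f"\nA>G fraction drops to {100 * ag['ko_over_wt']:.0f}% of wild type "
      f"(t = {ag['t_statistic']:.1f}, p = {ag['p_value']:.2e})")
# Only A>G responds to the genotype; the other 11 substitution types stay
# at the sequencing-error floor in both genotypes.
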