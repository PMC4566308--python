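"""Transcript-trait correlation with permutation-derived chance thresholds.

Simulates 105 samples with 40 genes coupled to leaf length at rho = 0.5,
normalizes the counts, computes per-gene PCCs, derives the observed 1 %
tail quantiles and the permutation chance reference, selects the gene
sets and scores them against the planted truth.
"""

import leafcorr as lc
from leafcorr.correlation import analytic_null_quantile

spec = lc.PopulationSpec(
    n_genes=2000,
    seed=11,
    planted=[lc.PlantedSignal(i, "LL", 0.5) for i in range(40)],
)
traits = lc.simulate_traits(spec)
counts, annotation, truth = lc.simulate_counts(spec, traits)
expr = lc.normalize_transform(counts, lc.size_factors(counts))

pcc = lc.transcript_trait_pcc(expr, traits)          # genes x traits PCC
observed = lc.tail_quantiles(pcc)                     # q_0.01 / q_0.99
permuted = lc.permutation_thresholds(expr, traits, n_perm=500, seed=11)
catalog = lc.select_sets(pcc, observed, permuted)

thr = permuted.permuted.loc["LL", "q_high"]
print(f"chance threshold for LL: mean permuted q_0.99 = {thr:.3f} "
      f"(analytic null quantile at n=105: {analytic_null_quantile(0.99, 105):.3f})")
print(f"observed q_0.99 for LL: {observed.observed.loc['LL', 'q_high']:.3f} "
      "(pushed outward by the planted signal)")

table = lc.correlation_count_table(catalog, "q_random")
print("\ngenes correlating better than random, per trait:")
print(table)

report = lc.recovery_metrics(catalog, truth, "q_random")
row = report.iloc[0]
print(f"\nplanted-signal recovery on LL: recall {row['recall']:.2f}, "
      f"false-discovery proportion {row['fdp']:.2f}")
print("(LL rows exceed the ~2 % null rate; other traits sit near 2 % by "
      "construction of the chance threshold)")
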