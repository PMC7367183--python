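"""Switch/mismatch phasing accuracy against parental truth.

Simulates 50,000 heterozygous sites phased in 200-variant blocks with
per-adjacency switch errors planted at 0.0126/site (the long-range-data
regime, where somatic chromosome pairing creates sister-chromosome
contacts), evaluates against the F1 truth haplotypes, and estimates the
fraction of short-read blocks a long-range join would corrupt.
"""

from scaffcheck import block_stats, evaluate_phase, join_switch_fraction
from scaffcheck.synthetic import phasing_benchmark

blocks, truth, bundle = phasing_benchmark(
    n_sites=50_000, block_length=200, switch_rate=0.0126, mismatch_rate=0.0, seed=7
)
report = evaluate_phase(blocks, truth)

print(f"sites={report.n_sites}  blocks={report.n_blocks}")
print(f"planted switch events: {len(bundle.switch_adjacencies)}")
print(f"recovered: switches={report.n_switch}  mismatches={report.n_mismatch}")
print(f"switch rate = {report.switch_rate:.5f}/site  "
      f"combined = {report.combined_rate:.5f}/site")

stats = block_stats(blocks)
print(f"mean block length = {stats['mean_block_len']:.1f} variants, "
      f"mean span = {stats['mean_block_span']:.0f} bp")

frac = join_switch_fraction(0.0126, 14)
print(f"\nblock-join switch fraction: 0.0126/site x 14 variants/block = "
      f"{frac:.4f} (~{int(frac * 100)}%)")
print("\nThe evaluator recovers the planted switch rate to within sampling "
      "error; the last line estimates that ~17% of 14-variant short-read "
      "blocks joined by long-range contacts acquire a switch error.")
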