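"""Detect a mosaic chromosomal alteration from phased array signal.

A CNLOH clone at 45% cell fraction is planted on 9p; the caller segments the
phase-oriented BAF signal, classifies the copy-number state from the median
LRR, and converts the BAF deviation into a cell fraction by allele-copy
accounting (CNLOH: f = 2 * dBAF).
"""

from clonalshift import SimulationConfig, call_mcas, simulate_cohort
from clonalshift.simulate import Mca, default_site_grid, emit_array_signal

sample = simulate_cohort(SimulationConfig(n_samples=1, seed=5))[0]
sample.mca = Mca("CNLOH", "chr9", 1, 8_000_000, cell_fraction=0.45, retained_haplotype=2)

signal = emit_array_signal(sample, default_site_grid(900), baf_sd=0.03, lrr_sd=0.14)
calls = call_mcas(signal)

for c in calls:
    print(
        f"{c.chrom}:{c.start_pos:,}-{c.end_pos:,}  state={c.state}  "
        f"cell_fraction={c.cell_fraction:.3f}  region={c.region_class}  "
        f"n_het={c.segment.n_het}"
    )
print()
print("True event: chr9:1-8,000,000 CNLOH at cell fraction 0.450.")
print("The estimated fraction lands within a few percent despite BAF noise")
print("of 0.03, because the phase-oriented mean shift is unbiased.")
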