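"""Germline-somatic interaction statistics on the published count tables.

These are exact functions of the printed counts, so they reproduce the
published values: allelic-shift binomials over informative heterozygous
carriers, odds ratios from proportions, and the sign test ordering V617F
acquisition before the chromosomal alteration.
"""

from clonalshift import (
    ShiftCount,
    allelic_shift_test,
    binom_one_sided_ge,
    clonal_order_test,
    odds_ratio_from_props,
)

for state, k, n in (("gain", 23, 28), ("loss", 14, 16), ("CNLOH", 51, 59)):
    res = allelic_shift_test(ShiftCount(state, k, n))
    print(f"{state:6s} {k:>2}/{n:<2} favor the risk haplotype  ->  p = {res.p_value:.3g}")

print()
print(f"7/19 telomere variants nominal at 5%: p = {binom_one_sided_ge(7, 19, 0.05):.3g}")
print(f"mCA odds, secondary vs primary: OR = {odds_ratio_from_props(0.7835, 0.7103):.2f}")
print(f"mCA odds, post-PV vs primary:   OR = {odds_ratio_from_props(0.9412, 0.7103):.2f}")

order = clonal_order_test([(0.7, 0.3), (0.9, 0.5), (0.6, 0.55), (0.8, 0.2), (0.4, 0.5)])
print()
print(
    f"toy ordering sign test: AF > CF in {order.k_af_gt_cf}/{order.n} pairs, p = {order.p_value:.3f}"
)
print("A predominance of AF > CF says the point mutation preceded the mCA.")
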