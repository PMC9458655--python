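"""Mendelian randomization of a telomere-length instrument on disease risk.

Nineteen instruments are simulated with a true causal log-odds effect of
log(7.69) per SD of genetically-inferred telomere length; five carry
injected directional pleiotropy.  The filter removes them (leave-one-out
weighted-median residuals, BH at FDR 0.2) and every estimator is reported on
the odds-ratio scale.
"""

import numpy as np

from clonalshift import mr_report
from clonalshift.simulate import emit_instruments

theta = np.log(7.69)
instruments = emit_instruments(
    n_variants=19, true_effect=theta, pleiotropy_spec=(5, 0.8), seed=14
)
report, removed = mr_report(instruments, fdr=0.2, median_boot=2000)

print(f"true OR per SD: {np.exp(theta):.2f}")
print(f"pleiotropic variants removed: {len(removed)} "
      f"(injected: {int(instruments['pleiotropic'].sum())})")
print()
print(report.round(3).to_string(index=False))
print()
print("Each estimator's CI should cover the true OR; the Egger intercept")
print("near 1 (log-odds 0) indicates no residual directional pleiotropy.")
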