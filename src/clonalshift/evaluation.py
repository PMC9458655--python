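"""Parameter-recovery evaluation suites.

The study's headline somatic results live in restricted data, so the
pipeline's calling and estimation stages are validated by recovery on
synthetic cohorts whose generating parameters are known: mCA detection
sensitivity and cell-fraction error, haplotype-call agreement with truth,
replicate concordance, MR confidence-interval coverage, pleiotropy-removal
power, and end-to-end determinism.  Both the test suite and the acceptance
script run these functions.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np

from .config import SimulationConfig
from .longread import build_haplotype_table, call_sample, filter_rare, replicate_concordance
from .mca import McaParams, call_mcas
from .mr import mr_egger, mr_ivw, mr_maxlik, mr_median, pleiotropy_filter
from .simulate import (
    default_site_grid,
    emit_array_signal,
    emit_instruments,
    emit_reads,
    simulate_cohort,
)

Z95 = 1.959964


def evaluate_mca_caller(
    seed: int,
    n_events: int = 200,
    n_nulls: int = 200,
    n_sites: int = 700,
    baf_sd: float = 0.03,
    lrr_sd: float = 0.14,
    min_cf: float = 0.1,
) -> dict:
    """Sensitivity, cell-fraction error and null false-positive rate.

    Events come from the cohort generator with cell fraction >= ``min_cf``;
    spans are drawn wide enough that each event covers >= 100 heterozygous
    sites on the grid, which is the regime the sensitivity statement
    addresses.  A sample counts as detected when any call overlaps the true
    interval; the cell-fraction error uses the overlapping call.
    """
    rng = np.random.default_rng([seed, 10])
    grid = default_site_grid(n_sites)
    chrom_span = int(grid[-1])
    cfg = SimulationConfig(n_samples=4 * (n_events + n_nulls), seed=seed, baf_sd=baf_sd, lrr_sd=lrr_sd)
    cohort = simulate_cohort(cfg)

    events = [s for s in cohort if s.mca is not None and s.mca.cell_fraction >= min_cf][:n_events]
    nulls = [s for s in cohort if s.mca is None][:n_nulls]
    if len(events) < n_events or len(nulls) < n_nulls:
        raise RuntimeError("cohort too small for the requested evaluation sizes")

    params = McaParams()
    detected = 0
    state_match = 0
    cf_errors = []
    for s in events:
        span = int(rng.uniform(0.35, 0.75) * chrom_span)
        start = int(rng.uniform(1, chrom_span - span))
        s.mca.start, s.mca.end = start, start + span
        sig = emit_array_signal(s, grid, baf_sd=baf_sd, lrr_sd=lrr_sd)
        calls = call_mcas(sig, params)
        hits = [c for c in calls if c.start_pos <= s.mca.end and c.end_pos >= s.mca.start]
        if not hits:
            continue
        detected += 1
        best = max(hits, key=lambda c: c.segment.n_het)
        if best.state == s.mca.state:
            state_match += 1
        if best.cell_fraction is not None:
            cf_errors.append(abs(best.cell_fraction - s.mca.cell_fraction))
        else:
            cf_errors.append(1.0)  # undetermined counts as a full-scale error

    false_positives = 0
    for s in nulls:
        sig = emit_array_signal(s, grid, baf_sd=baf_sd, lrr_sd=lrr_sd)
        if call_mcas(sig, params):
            false_positives += 1

    return {
        "n_events": len(events),
        "n_nulls": len(nulls),
        "sensitivity": detected / len(events),
        "state_accuracy": state_match / max(detected, 1),
        "cf_error_p95": float(np.percentile(cf_errors, 95)) if cf_errors else math.nan,
        "cf_error_mean": float(np.mean(cf_errors)) if cf_errors else math.nan,
        "fp_rate": false_positives / len(nulls),
    }


def _truth_phase(s) -> str | None:
    if s.v617f_status in ("hap1", "hap2") and s.het_46_1:
        on_risk = (s.v617f_status == "hap1") == s.is_46_1_hap1
        return "cis" if on_risk else "trans"
    if s.v617f_status != "none":
        return "uninformative"
    return None


def evaluate_hap_caller(
    seed: int, n_samples: int = 400, depth: int = 3155, error_rate: float = 0.01
) -> dict:
    """Fraction of QC-passing samples whose (carrier, mutation, phase)
    triple matches the generator truth, plus the allelic-fraction error on
    heterozygous-background samples and replicate concordance."""
    cohort = simulate_cohort(SimulationConfig(n_samples=n_samples, seed=seed))
    match = total = 0
    af_errors = []
    concordant = pairs = 0
    for i, s in enumerate(cohort):
        r1 = emit_reads(s, depth, error_rate, rng=np.random.default_rng([seed, 20, i]))
        c1 = call_sample(filter_rare(build_haplotype_table(r1)), s.sample_id)
        r2 = emit_reads(s, depth, error_rate, rng=np.random.default_rng([seed, 21, i]))
        c2 = call_sample(filter_rare(build_haplotype_table(r2)), s.sample_id)
        pairs += 1
        concordant += replicate_concordance(c1, c2)
        if c1.qc_status != "pass":
            continue
        total += 1
        ok = (
            c1.carrier_46_1 == s.carrier_46_1
            and c1.v617f_present == (s.v617f_status != "none")
            and c1.phase == _truth_phase(s)
        )
        match += ok
        if c1.v617f_af is not None and s.v617f_af is not None and len(c1.germline_haps) == 2:
            af_errors.append(abs(c1.v617f_af - s.v617f_af))
    return {
        "n_samples": total,
        "truth_match_rate": match / total,
        "af_error_p95": float(np.percentile(af_errors, 95)),
        "replicate_concordance": concordant / pairs,
    }


def evaluate_mr_coverage(
    seed: int,
    n_sims: int = 1000,
    n_instruments: int = 20,
    true_effect: float = 0.5,
    median_boot: int = 400,
) -> dict:
    """95% CI coverage of every estimator over pleiotropy-free simulations,
    plus the IVW vs maximum-likelihood agreement on homogeneous instruments."""
    cover = {"IVW": 0, "MR-Egger": 0, "Simple median": 0, "Weighted median": 0, "Maximum-likelihood": 0}
    for k in range(n_sims):
        inst = emit_instruments(n_instruments, true_effect=true_effect, seed=(seed * 100_003 + k) % 2**31)
        results = [
            mr_ivw(inst),
            mr_maxlik(inst),
            mr_median(inst, weighted=False, n_boot=median_boot, seed=k),
            mr_median(inst, weighted=True, n_boot=median_boot, seed=k),
            mr_egger(inst),
        ]
        for r in results:
            lo, hi = r.ci
            cover[r.method] += lo <= true_effect <= hi
    coverage = {m: c / n_sims for m, c in cover.items()}

    # homogeneous instruments: all Wald ratios identical
    bx = np.linspace(0.04, 0.12, n_instruments)
    import pandas as pd

    homogeneous = pd.DataFrame(
        {
            "variant_id": [f"h{i}" for i in range(n_instruments)],
            "beta_exposure": bx,
            "se_exposure": np.full(n_instruments, 0.01),
            "beta_outcome": true_effect * bx,
            "se_outcome": np.linspace(0.05, 0.2, n_instruments),
        }
    )
    ivw = mr_ivw(homogeneous).estimate
    ml = mr_maxlik(homogeneous).estimate
    return {
        "n_sims": n_sims,
        "coverage": coverage,
        "ivw_ml_abs_diff": abs(ivw - ml),
    }


def evaluate_pleiotropy_power(
    seed: int, n_sims: int = 100, n_instruments: int = 19, alpha_in_se: float = 10.0
) -> dict:
    """Probability that one variant with alpha = 10 * se_outcome injected
    into an otherwise clean instrument set is removed at FDR 0.2."""
    removed_hits = 0
    for k in range(n_sims):
        inst = emit_instruments(n_instruments, true_effect=0.5, seed=(seed * 99_991 + k) % 2**31)
        j = k % n_instruments
        inst.loc[j, "beta_outcome"] += alpha_in_se * inst.loc[j, "se_outcome"]
        _, removed, _ = pleiotropy_filter(inst, fdr=0.2)
        removed_hits += inst.loc[j, "variant_id"] in set(removed["variant_id"])
    return {"n_sims": n_sims, "removal_power": removed_hits / n_sims}


def evaluate_determinism(seed: int, n_samples: int = 40, n_sites: int = 250) -> dict:
    """Two pipeline runs under the same config and seed produce a
    byte-identical summary."""
    from .pipeline import run_pipeline

    cfg = SimulationConfig(n_samples=n_samples, seed=seed)
    with tempfile.TemporaryDirectory() as tmp:
        run_pipeline(cfg, Path(tmp) / "a", n_sites=n_sites, median_boot=200)
        run_pipeline(cfg, Path(tmp) / "b", n_sites=n_sites, median_boot=200)
        a = (Path(tmp) / "a" / "summary.json").read_bytes()
        b = (Path(tmp) / "b" / "summary.json").read_bytes()
    return {"identical": a == b, "n_samples": n_samples}
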