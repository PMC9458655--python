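"""Inherited telomere-length genetics and qPCR telomere measurement.

Covers the weighted polygenic score for genetically-inferred leukocyte
telomere length (standardised to mean 0, sd 1 across the cohort), the
observed-to-liability-scale heritability transformation, and qPCR relative
telomere length (T/S ratio against a reference curve) with the coefficient
of variation and one-way random-effects intraclass correlation QC metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


# ---------------------------------------------------------------------------
# polygenic risk score
# ---------------------------------------------------------------------------


def compute_prs(
    dosages: pd.DataFrame,
    weights: pd.DataFrame,
    counted_alleles: pd.DataFrame | None = None,
) -> pd.Series:
    """Standardised weighted allele-dosage score.

    ``dosages``: one row per sample, one column per variant (values in
    [0, 2]), optionally with a sample_id column used as the index.
    ``weights``: columns variant_id, effect_allele, weight.  When
    ``counted_alleles`` (variant_id, counted_allele, other_allele) is given,
    variants whose counted allele is the non-effect allele are flipped
    (dosage -> 2 - dosage); an unresolvable mismatch raises.  The raw score
    sum(weight * dosage) is z-scored across the cohort.
    """
    dosages = dosages.copy()
    index = None
    if "sample_id" in dosages.columns:
        index = dosages.pop("sample_id")
    if weights["variant_id"].duplicated().any():
        raise ValueError("duplicate variant_id in weights")
    shared = [v for v in weights["variant_id"] if v in dosages.columns]
    if not shared:
        raise ValueError("no overlapping variants between dosages and weights")
    w = weights.set_index("variant_id").loc[shared]

    mat = dosages[shared].to_numpy(dtype=float)
    if np.any((mat < 0) | (mat > 2)):
        raise ValueError("dosages must lie in [0, 2]")
    if counted_alleles is not None:
        ca = counted_alleles.set_index("variant_id")
        for j, v in enumerate(shared):
            counted = ca.loc[v, "counted_allele"]
            effect = w.loc[v, "effect_allele"]
            if counted == effect:
                continue
            if ca.loc[v, "other_allele"] == effect:
                mat[:, j] = 2.0 - mat[:, j]
            else:
                raise ValueError(f"{v}: counted allele {counted!r} cannot be oriented to effect allele {effect!r}")

    raw = mat @ w["weight"].to_numpy(dtype=float)
    sd = raw.std()  # population sd: the score is standardised within the cohort
    if sd == 0:
        raise ValueError("zero variance: all samples share the same raw score")
    z = (raw - raw.mean()) / sd
    return pd.Series(z, index=index, name="prs")


# ---------------------------------------------------------------------------
# liability-scale heritability
# ---------------------------------------------------------------------------


def liability_h2(h2_observed: float, sample_prevalence: float, population_prevalence: float) -> float:
    """Observed-scale to liability-scale heritability for an ascertained
    case-control sample.

    h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)), with K the population
    prevalence, P the sample prevalence, and z the standard normal density
    at the liability threshold Phi^-1(1-K).
    """
    K, P = population_prevalence, sample_prevalence
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("prevalences must be strictly inside (0, 1)")
    if h2_observed < 0:
        raise ValueError("h2_observed must be nonnegative")
    z = norm.pdf(norm.isf(K))
    return h2_observed * K**2 * (1.0 - K) ** 2 / (z**2 * P * (1.0 - P))


# ---------------------------------------------------------------------------
# qPCR relative telomere length
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "exp": math.exp,
    "identity": lambda x: x,
    "log": math.log,
}


@dataclass
class QpcrQc:
    cv_percent: float | None
    icc: float | None
    n_replicated_samples: int


def _interp_quantity(cq_values, curve: pd.DataFrame) -> np.ndarray:
    """Quantities interpolated from Cq on the (log-linear) reference curve."""
    c = curve.sort_values("cq")
    cq = np.asarray(cq_values, dtype=float)
    logq = np.interp(cq, c["cq"].to_numpy(), np.log10(c["quantity"].to_numpy()))
    return 10.0**logq


def qpcr_rtl(
    records: pd.DataFrame,
    curve: pd.DataFrame,
    transform: str = "exp",
    cv_limit_percent: float = 15.0,
) -> pd.DataFrame:
    """Per-record relative telomere length from triplicate Cq values.

    Each record holds triplicate telomere (T) and reference-gene (S) Cq
    values; every reaction quantity is interpolated on the reference curve,
    T and S are the triplicate means, and rTL is the configured transform of
    T/S (default ``exp``, recorded in the output).  Records whose triplicate
    quantity CV exceeds ``cv_limit_percent`` are flagged, not dropped.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; options: {sorted(_TRANSFORMS)}")
    fn = _TRANSFORMS[transform]
    if not curve["cq"].is_monotonic_decreasing and not curve["cq"].is_monotonic_increasing:
        curve = curve.sort_values("cq")
    rows = []
    for _, rec in records.iterrows():
        t_cq = np.asarray(rec["telomere_cq"], dtype=float)
        s_cq = np.asarray(rec["reference_cq"], dtype=float)
        if t_cq.size != 3 or s_cq.size != 3 or not (np.isfinite(t_cq).all() and np.isfinite(s_cq).all()):
            raise ValueError(f"{rec.get('sample_id', '?')}: triplicates must be 3 finite values")
        t_q = _interp_quantity(t_cq, curve)
        s_q = _interp_quantity(s_cq, curve)
        cv_t = 100.0 * t_q.std(ddof=1) / t_q.mean()
        cv_s = 100.0 * s_q.std(ddof=1) / s_q.mean()
        ratio = t_q.mean() / s_q.mean()
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "plate_id": rec.get("plate_id", ""),
                "ts_ratio": ratio,
                "rtl": fn(ratio),
                "transform": transform,
                "flagged": bool(max(cv_t, cv_s) > cv_limit_percent),
            }
        )
    return pd.DataFrame(rows)


def qpcr_cv(control_rtl: pd.Series | np.ndarray) -> float:
    """Coefficient of variation (percent) of an internal control across runs."""
    v = np.asarray(control_rtl, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least 2 control measurements")
    return float(100.0 * v.std(ddof=1) / v.mean())


def icc_oneway(values: pd.DataFrame) -> float:
    """One-way random-effects intraclass correlation, ICC(1,1).

    ``values`` has columns sample_id and rtl with repeated measurements per
    sample.  Handles unbalanced designs via the standard one-way ANOVA
    effective group size k0.
    """
    groups = [g["rtl"].to_numpy(dtype=float) for _, g in values.groupby("sample_id") if len(g) >= 2]
    a = len(groups)
    if a < 2:
        raise ValueError("ICC needs at least 2 samples with replicate measurements")
    sizes = np.array([g.size for g in groups], dtype=float)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(sizes * (np.array([g.mean() for g in groups]) - grand) ** 2))
    ss_within = float(np.sum([np.sum((g - g.mean()) ** 2) for g in groups]))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    k0 = (N - np.sum(sizes**2) / N) / (a - 1)
    return float((ms_between - ms_within) / (ms_between + (k0 - 1) * ms_within))


def qpcr_qc(rtl_records: pd.DataFrame, control_records: pd.DataFrame | None = None) -> QpcrQc:
    """CV of the internal control and ICC over technical replicates."""
    cv = None
    if control_records is not None and len(control_records) >= 2:
        cv = qpcr_cv(control_records["rtl"])
    replicated = rtl_records.groupby("sample_id").size()
    n_rep = int((replicated >= 2).sum())
    icc = icc_oneway(rtl_records[["sample_id", "rtl"]]) if n_rep >= 2 else None
    return QpcrQc(cv_percent=cv, icc=icc, n_replicated_samples=n_rep)
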