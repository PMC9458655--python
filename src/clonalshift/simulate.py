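"""Synthetic myelofibrosis cohort generator.

Produces cohorts whose germline-somatic structure mirrors the analysis this
package implements: a JAK2 46/1 germline risk haplotype (allele string GGC
over rs3780367, rs10974944, rs12343867), somatic JAK2 V617F mutations
enriched among 46/1 carriers and acquired preferentially in *cis*, a single
9p mosaic chromosomal alteration per affected sample that preferentially
retains or duplicates the risk haplotype, cellular fractions typically below
the V617F allelic fraction (mutation first, mCA second), and relative
telomere length declining linearly with clonal fraction.

Randomness is organised as one root seed with documented child streams:
cohort-level draws use ``default_rng([seed, 0])`` and sample ``i`` (0-based)
uses ``default_rng([seed, i + 1, tag])`` with tag 1 for array signal and
tag 2 for read emission.  Identical configs therefore give bitwise-identical
cohorts and emissions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import ConfigurationError, SimulationConfig
from .genome import (
    GRCH38_CHROM_LENGTHS,
    NONRISK_HAPLOTYPE,
    RISK_HAPLOTYPE,
    SNP_ALLELES,
    V617F_CHROM,
    V617F_POS,
)

MCA_STATES = ("gain", "loss", "CNLOH")


@dataclass
class Mca:
    """A single mosaic chromosomal alteration carried by a sample."""

    state: str
    chrom: str
    start: int
    end: int
    cell_fraction: float
    retained_haplotype: int  # 1 or 2: the haplotype retained/duplicated by the event


@dataclass
class CohortSample:
    sample_id: str
    germline_hap1: str
    germline_hap2: str
    v617f_status: str  # none | hap1 | hap2 | both
    v617f_af: float | None
    mca: Mca | None
    rtl: float
    age: float
    sex: str
    dna_source: str
    stream: tuple[int, int] = field(default=(0, 0), repr=False)

    @property
    def is_46_1_hap1(self) -> bool:
        return self.germline_hap1 == RISK_HAPLOTYPE

    @property
    def is_46_1_hap2(self) -> bool:
        return self.germline_hap2 == RISK_HAPLOTYPE

    @property
    def carrier_46_1(self) -> bool:
        return self.is_46_1_hap1 or self.is_46_1_hap2

    @property
    def het_46_1(self) -> bool:
        return self.is_46_1_hap1 != self.is_46_1_hap2


def conditional_mutation_probs(
    carrier_freq: float, prevalence: float, odds_ratio: float
) -> tuple[float, float]:
    """Mutation probabilities (non-carrier, carrier) matching an overall
    prevalence and a carrier odds ratio.

    Solves c*p1 + (1-c)*p0 = prevalence with odds(p1)/odds(p0) = OR.
    """
    if prevalence <= 0.0:
        return 0.0, 0.0
    if prevalence >= 1.0:
        return 1.0, 1.0
    if carrier_freq >= 1.0:
        return prevalence, prevalence  # p0 unidentifiable; never drawn
    if carrier_freq <= 0.0 or odds_ratio == 1.0:
        return prevalence, prevalence

    def gap(p0: float) -> float:
        odds1 = odds_ratio * p0 / (1.0 - p0)
        p1 = odds1 / (1.0 + odds1)
        return carrier_freq * p1 + (1.0 - carrier_freq) * p0 - prevalence

    p0 = brentq(gap, 1e-12, 1.0 - 1e-12)
    odds1 = odds_ratio * p0 / (1.0 - p0)
    return p0, odds1 / (1.0 + odds1)


def risk_hap_allele_freq(carrier_freq: float) -> float:
    """Per-haplotype 46/1 frequency implied by a carrier frequency
    (Hardy-Weinberg): q = 1 - sqrt(1 - carrier_freq)."""
    return 1.0 - math.sqrt(1.0 - carrier_freq)


def simulate_cohort(config: SimulationConfig) -> list[CohortSample]:
    """Draw a full cohort under ``config``.

    Same config (including seed) gives an identical cohort.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_samples

    q = risk_hap_allele_freq(config.risk_hap_carrier_freq)
    p0, p1 = conditional_mutation_probs(
        config.risk_hap_carrier_freq, config.v617f_prevalence, config.v617f_or_given_46_1
    )

    hap1_is_risk = rng.random(n) < q
    hap2_is_risk = rng.random(n) < q
    carrier = hap1_is_risk | hap2_is_risk
    mutated = rng.random(n) < np.where(carrier, p1, p0)

    # mCA presence is coupled to mutation status (mCAs expand mutated clones)
    m0, m1 = conditional_mutation_probs(
        config.v617f_prevalence, config.mca_prevalence, config.mca_or_given_v617f
    )
    has_mca = rng.random(n) < np.where(mutated, m1, m0)

    state_mix = np.asarray(config.mca_state_mix, dtype=float)
    chrom_len = GRCH38_CHROM_LENGTHS[V617F_CHROM]

    samples: list[CohortSample] = []
    for i in range(n):
        h1 = RISK_HAPLOTYPE if hap1_is_risk[i] else NONRISK_HAPLOTYPE
        h2 = RISK_HAPLOTYPE if hap2_is_risk[i] else NONRISK_HAPLOTYPE
        het = hap1_is_risk[i] != hap2_is_risk[i]

        # --- somatic point mutation -----------------------------------
        status = "none"
        af: float | None = None
        if mutated[i]:
            if het:
                on_risk = rng.random() < config.cis_prob_given_het_carrier
                risk_index = 1 if hap1_is_risk[i] else 2
                target = risk_index if on_risk else (3 - risk_index)
            else:
                target = 1 if rng.random() < 0.5 else 2
            status = f"hap{target}"
            if rng.random() < config.biallelic_prob:
                status = "both"
            a, b = config.af_beta
            af = float(config.af_floor + (1.0 - config.af_floor) * rng.beta(a, b))

        # --- mosaic chromosomal alteration ----------------------------
        mca: Mca | None = None
        if has_mca[i]:
            state = MCA_STATES[rng.choice(3, p=state_mix)]
            if het:
                risk_index = 1 if hap1_is_risk[i] else 2
                retain_risk = rng.random() < config.mca_risk_retention_prob[state]
                retained = risk_index if retain_risk else (3 - risk_index)
            else:
                retained = 1 if rng.random() < 0.5 else 2
            if rng.random() < config.whole_chromosome_prob:
                start, end = 1, chrom_len
            else:
                start = int(rng.integers(1, 4_500_000))
                end = int(rng.integers(6_000_000, 43_000_000))
            if af is not None:
                u = rng.random()
                if rng.random() < config.af_gt_cf_prob:
                    lo = min(config.cf_min, af * 0.5)
                    cf = lo + (af - lo) * u * 0.999
                else:
                    cf = af + (1.0 - af) * u
                cf = float(np.clip(cf, 1e-4, 1.0))
            else:
                a, b = config.cf_beta
                cf = float(config.cf_min + (1.0 - config.cf_min) * rng.beta(a, b))
            mca = Mca(state, V617F_CHROM, start, end, cf, retained)

        # --- telomere length ------------------------------------------
        rtl = rng.normal(config.telomere_baseline_mean, config.telomere_baseline_sd)
        if mca is not None:
            spans_jak2 = mca.start <= V617F_POS <= mca.end
            slope = (
                config.telomere_slope_per_cf_jak2 if spans_jak2 else config.telomere_slope_per_cf
            )
            rtl += slope * mca.cell_fraction
        rtl = float(max(rtl, config.telomere_floor))

        samples.append(
            CohortSample(
                sample_id=f"S{i + 1:05d}",
                germline_hap1=h1,
                germline_hap2=h2,
                v617f_status=status,
                v617f_af=af,
                mca=mca,
                rtl=rtl,
                age=float(rng.normal(config.mean_age, config.sd_age)),
                sex="M" if rng.random() < config.male_frac else "F",
                dna_source="pbmc" if rng.random() < config.pbmc_frac else "whole_blood",
                stream=(config.seed, i + 1),
            )
        )
    return samples


def cohort_truth_frame(samples: Iterable[CohortSample]) -> pd.DataFrame:
    """Flatten a cohort into the truth table written by the pipeline."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "germline_hap1": s.germline_hap1,
                "germline_hap2": s.germline_hap2,
                "is_46_1_hap1": s.is_46_1_hap1,
                "is_46_1_hap2": s.is_46_1_hap2,
                "v617f_status": s.v617f_status,
                "v617f_af": s.v617f_af if s.v617f_af is not None else np.nan,
                "mca_state": s.mca.state if s.mca else "none",
                "mca_chrom": s.mca.chrom if s.mca else "",
                "mca_start": s.mca.start if s.mca else 0,
                "mca_end": s.mca.end if s.mca else 0,
                "mca_cell_fraction": s.mca.cell_fraction if s.mca else np.nan,
                "mca_retained_haplotype": s.mca.retained_haplotype if s.mca else 0,
                "rtl": s.rtl,
                "age": s.age,
                "sex": s.sex,
                "dna_source": s.dna_source,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Array signal emission
# ---------------------------------------------------------------------------

_GT_CODES = ("A|A", "A|B", "B|A", "B|B")


def default_site_grid(n_sites: int = 800, chrom: str = V617F_CHROM) -> np.ndarray:
    """Evenly spaced 1-based positions spanning ``chrom``."""
    length = GRCH38_CHROM_LENGTHS[chrom]
    return np.unique(np.linspace(1, length, n_sites).astype(np.int64))


def _event_copies(state: str) -> tuple[int, int]:
    """(copies of retained haplotype, copies of other haplotype) in event cells."""
    if state == "CNLOH":
        return 2, 0
    if state == "loss":
        return 1, 0
    if state == "gain":
        return 2, 1
    raise ValueError(f"unknown mCA state {state!r}")


def expected_baf_lrr(
    b_hap1: np.ndarray, b_hap2: np.ndarray, state: str, cell_fraction: float, retained: int
) -> tuple[np.ndarray, float]:
    """Closed-form BAF and LRR from allele-copy accounting.

    ``b_hap1``/``b_hap2`` are 0/1 indicators of the B allele on each
    haplotype.  Event cells carry ``cell_fraction`` of the sample; the
    retained haplotype has ``c_r`` copies and the other ``c_o``.
    """
    c_r, c_o = _event_copies(state)
    f = cell_fraction
    if retained == 1:
        c1, c2 = c_r, c_o
    else:
        c1, c2 = c_o, c_r
    b_dosage = f * (b_hap1 * c1 + b_hap2 * c2) + (1.0 - f) * (b_hap1 + b_hap2)
    total = f * (c1 + c2) + (1.0 - f) * 2.0
    return b_dosage / total, math.log2(total / 2.0)


def emit_array_signal(
    sample: CohortSample,
    positions: Sequence[int] | np.ndarray | None = None,
    *,
    baf_sd: float = 0.03,
    lrr_sd: float = 0.14,
    chrom: str = V617F_CHROM,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site phased array signal (BAF, LRR, phased genotype) for one sample.

    Inside the sample's mCA interval heterozygous BAF deviates from 0.5 and
    LRR from 0 according to the state and cell fraction; outside, het BAF is
    0.5 and LRR 0, plus Gaussian noise.  Phased genotypes use A|B coding
    with the B-allele indicator per haplotype.
    """
    if positions is None:
        positions = default_site_grid(chrom=chrom)
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("empty site grid")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("site grid must be strictly increasing")
    if rng is None:
        rng = np.random.default_rng([*sample.stream, 1])

    n = positions.size
    gt_idx = rng.integers(0, 4, size=n)
    b1 = (gt_idx >= 2).astype(float)  # B on haplotype 1 for B|A, B|B
    b2 = ((gt_idx == 1) | (gt_idx == 3)).astype(float)

    baf = (b1 + b2) / 2.0
    lrr = np.zeros(n)
    if sample.mca is not None and sample.mca.chrom == chrom:
        inside = (positions >= sample.mca.start) & (positions <= sample.mca.end)
        if inside.any():
            e_baf, e_lrr = expected_baf_lrr(
                b1[inside],
                b2[inside],
                sample.mca.state,
                sample.mca.cell_fraction,
                sample.mca.retained_haplotype,
            )
            baf[inside] = e_baf
            lrr[inside] = e_lrr

    if baf_sd > 0:
        baf = np.clip(baf + rng.normal(0.0, baf_sd, size=n), 0.0, 1.0)
    if lrr_sd > 0:
        lrr = lrr + rng.normal(0.0, lrr_sd, size=n)

    return pd.DataFrame(
        {
            "sample_id": sample.sample_id,
            "chrom": chrom,
            "pos": positions,
            "baf": baf,
            "lrr": lrr,
            "gt": np.array(_GT_CODES, dtype=object)[gt_idx],
        }
    )


# ---------------------------------------------------------------------------
# Long-read emission
# ---------------------------------------------------------------------------


def haplotype_read_share(sample: CohortSample) -> float:
    """Expected fraction of reads drawn from haplotype 1, shifted by the mCA.

    With no event both haplotypes contribute 1/2; an event with cell
    fraction f re-weights by the haplotype copy numbers in event cells
    (e.g. CNLOH retaining hap1 gives (1+f)/2).
    """
    if sample.mca is None or not (sample.mca.start <= V617F_POS <= sample.mca.end):
        return 0.5
    c_r, c_o = _event_copies(sample.mca.state)
    f = sample.mca.cell_fraction
    if sample.mca.retained_haplotype == 1:
        c1, c2 = c_r, c_o
    else:
        c1, c2 = c_o, c_r
    total = f * (c1 + c2) + (1.0 - f) * 2.0
    return (f * c1 + (1.0 - f)) / total


def emit_reads(
    sample: CohortSample,
    n_reads: int = 1500,
    error_rate: float = 0.005,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-read allele observations over the 3 germline SNPs + the somatic site.

    Reads are drawn from the two germline haplotypes in mCA-shifted
    proportions; the V617F allele is appended to reads of its background
    haplotype at frequency ``v617f_af``.  ``error_rate`` is the per-site
    per-read miscall rate; a miscall lands on the specific other tracked
    allele one third of the time (the remaining substitutions produce
    off-alphabet bases that never enter the 4-site haplotype table), so
    tracked-allele flips occur i.i.d. at ``error_rate / 3``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if rng is None:
        rng = np.random.default_rng([*sample.stream, 2])

    share1 = haplotype_read_share(sample)
    from_hap1 = rng.random(n_reads) < share1
    hap_strings = np.where(from_hap1, sample.germline_hap1, sample.germline_hap2)

    mutant = np.zeros(n_reads, dtype=bool)
    if sample.v617f_status != "none" and sample.v617f_af is not None:
        on_hap1 = sample.v617f_status in ("hap1", "both")
        on_hap2 = sample.v617f_status in ("hap2", "both")
        eligible = (from_hap1 & on_hap1) | (~from_hap1 & on_hap2)
        mutant[eligible] = rng.random(int(eligible.sum())) < sample.v617f_af

    flip_rate = error_rate / 3.0
    alleles = np.empty((n_reads, 3), dtype="U1")
    for j in range(3):
        site = np.array([h[j] for h in hap_strings], dtype="U1")
        if flip_rate > 0:
            flip = rng.random(n_reads) < flip_rate
            a, b = SNP_ALLELES[j]
            site[flip] = np.where(site[flip] == a, b, a)
        alleles[:, j] = site
    if flip_rate > 0:
        flip = rng.random(n_reads) < flip_rate
        mutant = np.where(flip, ~mutant, mutant)

    return pd.DataFrame(
        {
            "sample_id": sample.sample_id,
            "read_id": [f"{sample.sample_id}.r{k}" for k in range(n_reads)],
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
            "a3": alleles[:, 2],
            "v617f": np.where(mutant, "mut", "ref"),
        }
    )


def emit_cohort_reads(
    samples: Iterable[CohortSample], n_reads: int = 1500, error_rate: float = 0.005
) -> pd.DataFrame:
    return pd.concat(
        [emit_reads(s, n_reads=n_reads, error_rate=error_rate) for s in samples],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# Mendelian-randomization instrument emission
# ---------------------------------------------------------------------------


def emit_instruments(
    n_variants: int = 20,
    true_effect: float = 0.5,
    pleiotropy_spec: dict[int, float] | tuple[int, float] | None = None,
    seed: int = 0,
    *,
    beta_exposure_range: tuple[float, float] = (0.02, 0.12),
    se_exposure_frac: float = 0.02,
    se_outcome_range: tuple[float, float] = (0.06, 0.15),
) -> pd.DataFrame:
    """Summary-statistic instruments with betaY = theta*betaX + alpha + noise.

    ``pleiotropy_spec`` is either a mapping {variant index: alpha} or a pair
    (n_pleiotropic, alpha) applied to the first n variants; alpha is 0
    elsewhere.  The ``pleiotropic`` column records the injected truth.
    """
    if n_variants < 3:
        raise ValueError("n_variants must be >= 3")
    rng = np.random.default_rng([seed, 3])
    lo, hi = beta_exposure_range
    bx_true = rng.uniform(lo, hi, n_variants)
    sx = np.maximum(bx_true * se_exposure_frac, 1e-6)
    bx = bx_true + rng.normal(0.0, sx)
    sy = rng.uniform(*se_outcome_range, n_variants)

    alpha = np.zeros(n_variants)
    if pleiotropy_spec is not None:
        if isinstance(pleiotropy_spec, dict):
            for idx, a in pleiotropy_spec.items():
                alpha[idx] = a
        else:
            count, a = pleiotropy_spec
            alpha[:count] = a
    by = true_effect * bx_true + alpha + rng.normal(0.0, sy)

    return pd.DataFrame(
        {
            "variant_id": [f"rsSIM{k:04d}" for k in range(n_variants)],
            "beta_exposure": bx,
            "se_exposure": sx,
            "beta_outcome": by,
            "se_outcome": sy,
            "pleiotropic": alpha != 0.0,
        }
    )


# ---------------------------------------------------------------------------
# PRS demonstration cohort
# ---------------------------------------------------------------------------


def emit_prs_cohort(
    n_samples: int = 4000,
    n_variants: int = 19,
    or_per_sd: float = 1.33,
    base_rate: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Dosage matrix, weight table, and a binary outcome with a logistic
    link of ``or_per_sd`` per standard deviation of the true score."""
    rng = np.random.default_rng([seed, 4])
    freqs = rng.uniform(0.2, 0.8, n_variants)
    weights = np.abs(rng.normal(0.03, 0.01, n_variants))
    dosages = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(float)
    raw = dosages @ weights
    z = (raw - raw.mean()) / raw.std()
    logit = math.log(base_rate / (1 - base_rate)) + math.log(or_per_sd) * z
    status = rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))
    variant_ids = [f"rsPRS{k:03d}" for k in range(n_variants)]
    dosage_df = pd.DataFrame(dosages, columns=variant_ids)
    dosage_df.insert(0, "sample_id", [f"P{k:05d}" for k in range(n_samples)])
    weight_df = pd.DataFrame(
        {"variant_id": variant_ids, "effect_allele": "A", "weight": weights}
    )
    return dosage_df, weight_df, pd.Series(status, name="case")


# ---------------------------------------------------------------------------
# qPCR plate emission
# ---------------------------------------------------------------------------


def reference_curve(
    intercept: float = 35.0, slope: float = 3.321928, quantities: Sequence[float] | None = None
) -> pd.DataFrame:
    """Standard-curve table mapping Cq to input quantity (log-linear)."""
    if quantities is None:
        quantities = np.logspace(0, 4, 9)
    q = np.asarray(quantities, dtype=float)
    return pd.DataFrame({"cq": intercept - slope * np.log10(q), "quantity": q})


def emit_qpcr(
    n_samples: int = 40,
    n_replicate_sets: int = 2,
    seed: int = 0,
    *,
    between_sd: float = 0.20,
    within_sd: float = 0.03,
    n_control_plates: int = 8,
    curve: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Telomere/reference qPCR triplicates with known variance components.

    Returns (records, curve, controls).  Each sample is measured in
    ``n_replicate_sets`` independent record rows (technical replicates for
    the ICC); one internal control is measured once per plate (for the CV).
    Log T/S ratios have between-sample sd ``between_sd`` and per-quantity
    multiplicative replicate noise ``within_sd``.
    """
    rng = np.random.default_rng([seed, 5])
    if curve is None:
        curve = reference_curve()
    # invert the log-linear curve: cq(q) = a - b*log10(q)
    logq = np.log10(curve["quantity"].to_numpy())
    b, a = np.polyfit(logq, curve["cq"].to_numpy(), 1)[0:2]

    def to_cq(quantity: np.ndarray) -> np.ndarray:
        return a + b * np.log10(quantity)

    rows = []
    s_quantity = rng.lognormal(math.log(100.0), 0.3, n_samples)
    log_ratio = rng.normal(0.0, between_sd, n_samples)
    for i in range(n_samples):
        t_quantity = s_quantity[i] * math.exp(log_ratio[i])
        for rep in range(n_replicate_sets):
            t_obs = t_quantity * np.exp(rng.normal(0.0, within_sd, 3))
            s_obs = s_quantity[i] * np.exp(rng.normal(0.0, within_sd, 3))
            rows.append(
                {
                    "sample_id": f"Q{i:04d}",
                    "plate_id": f"plate{rep}",
                    "telomere_cq": list(np.round(to_cq(t_obs), 6)),
                    "reference_cq": list(np.round(to_cq(s_obs), 6)),
                }
            )
    control_rows = []
    control_s = 120.0
    for p in range(n_control_plates):
        t_obs = control_s * np.exp(rng.normal(0.0, within_sd, 3))
        s_obs = control_s * np.exp(rng.normal(0.0, within_sd, 3))
        control_rows.append(
            {
                "sample_id": "CONTROL",
                "plate_id": f"plate{p}",
                "telomere_cq": list(np.round(to_cq(t_obs), 6)),
                "reference_cq": list(np.round(to_cq(s_obs), 6)),
            }
        )
    return pd.DataFrame(rows), curve, pd.DataFrame(control_rows)
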