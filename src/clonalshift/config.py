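"""Simulation and pipeline configuration.

:class:`SimulationConfig` carries the statistical structure of the simulated
myelofibrosis cohort.  The defaults are the study conditions the downstream
statistics are designed for: a 46/1 risk-haplotype carrier frequency of
68.61%, JAK2 V617F prevalence of 60.82% with an odds ratio of 2.69 given
carriership, an mCA prevalence of 73.31%, per-state risk-haplotype retention
probabilities of 23/28 (gain), 14/16 (loss) and 51/59 (CNLOH), and relative
telomere length declining with clonal fraction (slope -0.57 overall, -1.17
for JAK2-spanning events).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its admissible range."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Probabilities are cohort-level frequencies; ``seed`` makes the whole
    cohort (including array signal and read emission) bitwise reproducible.
    """

    n_samples: int = 933
    seed: int = 1

    # Germline structure
    risk_hap_carrier_freq: float = 0.6861

    # Somatic point mutation
    v617f_prevalence: float = 0.6082
    v617f_or_given_46_1: float = 2.69
    cis_prob_given_het_carrier: float = 0.80
    biallelic_prob: float = 0.005
    #: V617F allelic fraction on its background haplotype is drawn as
    #: af_floor + (1 - af_floor) * Beta(a, b): a broad left-skewed
    #: distribution (mean ~0.63, median ~0.67) with a floor reflecting the
    #: quantification limit of a targeted assay with a 1% haplotype filter.
    af_beta: tuple[float, float] = (1.2, 0.75)
    af_floor: float = 0.04

    # Mosaic chromosomal alterations (single event per sample, on 9p)
    mca_prevalence: float = 0.7331
    #: Odds ratio of carrying an mCA given V617F mutation status; the
    #: default reproduces a (366, 8 / 196, 354)-shaped co-occurrence table.
    mca_or_given_v617f: float = 82.6
    mca_state_mix: tuple[float, float, float] = (0.20, 0.30, 0.50)  # gain, loss, CNLOH
    mca_risk_retention_prob: dict[str, float] = field(
        default_factory=lambda: {"gain": 23 / 28, "loss": 14 / 16, "CNLOH": 51 / 59}
    )
    #: Beta(a, b) for the mCA cellular fraction when the sample has no V617F.
    cf_beta: tuple[float, float] = (2.0, 2.0)
    cf_min: float = 0.02
    af_gt_cf_prob: float = 0.95
    whole_chromosome_prob: float = 0.10

    # Telomere length (relative T/S units)
    telomere_baseline_mean: float = 1.20
    telomere_baseline_sd: float = 0.25
    telomere_slope_per_cf: float = -0.57
    telomere_slope_per_cf_jak2: float = -1.17
    telomere_floor: float = 0.05

    # Measurement noise
    baf_sd: float = 0.03
    lrr_sd: float = 0.14
    reads_per_sample: int = 1500
    read_error_rate: float = 0.005

    # Demographics
    mean_age: float = 56.9
    sd_age: float = 7.5
    male_frac: float = 0.5806
    pbmc_frac: float = 0.079

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        for name in (
            "risk_hap_carrier_freq",
            "v617f_prevalence",
            "cis_prob_given_het_carrier",
            "biallelic_prob",
            "mca_prevalence",
            "af_gt_cf_prob",
            "whole_chromosome_prob",
            "male_frac",
            "pbmc_frac",
            "read_error_rate",
        ):
            _check_prob(name, getattr(self, name))
        mix = tuple(self.mca_state_mix)
        if len(mix) != 3 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ConfigurationError(
                f"mca_state_mix must be 3 nonnegative probabilities summing to 1, got {mix!r}"
            )
        for state, p in self.mca_risk_retention_prob.items():
            _check_prob(f"mca_risk_retention_prob[{state}]", p)
        if self.v617f_or_given_46_1 <= 0:
            raise ConfigurationError("v617f_or_given_46_1 must be positive")
        if self.mca_or_given_v617f <= 0:
            raise ConfigurationError("mca_or_given_v617f must be positive")
        if self.reads_per_sample < 1:
            raise ConfigurationError("reads_per_sample must be >= 1")
        for name in ("af_beta", "cf_beta"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ConfigurationError(f"{name} shape parameters must be positive")

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mca_state_mix"] = list(self.mca_state_mix)
        d["af_beta"] = list(self.af_beta)
        d["cf_beta"] = list(self.cf_beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("mca_state_mix", "af_beta", "cf_beta"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: expected a YAML mapping")
        return cls.from_dict(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
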