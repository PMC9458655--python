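"""Synthetic-cohort generator: configured frequencies, closed-form signal,
read emission, instruments, and bitwise determinism."""

import copy
import math

import numpy as np
import pandas as pd
import pytest

from clonalshift.config import ConfigurationError, SimulationConfig
from clonalshift.genome import RISK_HAPLOTYPE, V617F_POS
from clonalshift.mr import mr_ivw
from clonalshift.simulate import (
    cohort_truth_frame,
    default_site_grid,
    emit_array_signal,
    emit_instruments,
    emit_qpcr,
    emit_reads,
    simulate_cohort,
)
from conftest import binomial_se


def _frac(samples, predicate):
    return float(np.mean([predicate(s) for s in samples]))


class TestCohortMoments:
    def test_carrier_frequency(self, large_cohort):
        target = 0.6861
        f = _frac(large_cohort, lambda s: s.carrier_46_1)
        assert abs(f - target) <= 3 * binomial_se(target, len(large_cohort))

    def test_v617f_prevalence(self, large_cohort):
        target = 0.6082
        f = _frac(large_cohort, lambda s: s.v617f_status != "none")
        assert abs(f - target) <= 3 * binomial_se(target, len(large_cohort))

    def test_mca_prevalence(self, large_cohort):
        target = 0.7331
        f = _frac(large_cohort, lambda s: s.mca is not None)
        assert abs(f - target) <= 4 * binomial_se(target, len(large_cohort))

    def test_cis_fraction_among_het_carriers(self, large_cohort):
        het_mut = [
            s for s in large_cohort if s.het_46_1 and s.v617f_status in ("hap1", "hap2")
        ]
        on_risk = [
            (s.v617f_status == "hap1") == s.is_46_1_hap1 for s in het_mut
        ]
        target = 0.80
        assert abs(np.mean(on_risk) - target) <= 3 * binomial_se(target, len(het_mut))

    def test_af_exceeds_cf_rate(self, large_cohort):
        both = [s for s in large_cohort if s.v617f_af is not None and s.mca is not None]
        rate = np.mean([s.v617f_af > s.mca.cell_fraction for s in both])
        assert abs(rate - 0.95) <= 4 * binomial_se(0.95, len(both))

    def test_retention_probabilities(self, large_cohort):
        for state, target in (("gain", 23 / 28), ("loss", 14 / 16), ("CNLOH", 51 / 59)):
            events = [
                s
                for s in large_cohort
                if s.het_46_1 and s.mca is not None and s.mca.state == state
            ]
            risk_retained = [
                s.mca.retained_haplotype == (1 if s.is_46_1_hap1 else 2) for s in events
            ]
            assert abs(np.mean(risk_retained) - target) <= 4 * binomial_se(target, len(events))

    def test_telomere_declines_with_clonal_fraction(self, large_cohort):
        with_mca = [s for s in large_cohort if s.mca is not None]
        cf = np.array([s.mca.cell_fraction for s in with_mca])
        rtl = np.array([s.rtl for s in with_mca])
        slope = np.polyfit(cf, rtl, 1)[0]
        assert -1.35 < slope < -0.95  # JAK2-spanning slope -1.17 plus noise


class TestCohortStructure:
    def test_zero_prevalence_means_no_mutation(self):
        samples = simulate_cohort(SimulationConfig(n_samples=500, seed=2, v617f_prevalence=0.0))
        assert all(s.v617f_status == "none" and s.v617f_af is None for s in samples)

    def test_af_present_iff_mutated(self, default_cohort):
        for s in default_cohort:
            assert (s.v617f_af is not None) == (s.v617f_status != "none")
            if s.v617f_af is not None:
                assert 0.0 < s.v617f_af <= 1.0
            if s.mca is not None:
                assert 0.0 < s.mca.cell_fraction <= 1.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(v617f_prevalence=1.3)
        with pytest.raises(ConfigurationError):
            SimulationConfig(mca_state_mix=(0.5, 0.5, 0.5))

    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_samples=80, seed=9)
        a = cohort_truth_frame(simulate_cohort(cfg))
        b = cohort_truth_frame(simulate_cohort(cfg))
        assert a.to_csv() == b.to_csv()
        sa = simulate_cohort(cfg)[3]
        sb = simulate_cohort(cfg)[3]
        assert emit_array_signal(sa).to_csv() == emit_array_signal(sb).to_csv()
        assert emit_reads(sa).to_csv() == emit_reads(sb).to_csv()

    def test_different_seeds_differ(self):
        a = cohort_truth_frame(simulate_cohort(SimulationConfig(n_samples=80, seed=1)))
        b = cohort_truth_frame(simulate_cohort(SimulationConfig(n_samples=80, seed=2)))
        assert a.to_csv() != b.to_csv()


def _signal_oracle(b1, b2, state, f, retained):
    """Independent allele-copy accounting for the expected het BAF/LRR."""
    copies = {"CNLOH": (2, 0), "loss": (1, 0), "gain": (2, 1)}[state]
    c1, c2 = copies if retained == 1 else copies[::-1]
    dosage = f * (b1 * c1 + b2 * c2) + (1 - f) * (b1 + b2)
    total = f * (c1 + c2) + (1 - f) * 2
    return dosage / total, math.log2(total / 2)


class TestArraySignal:
    @pytest.fixture()
    def mca_sample(self, default_cohort):
        s = copy.deepcopy(next(x for x in default_cohort if x.mca is not None))
        s.mca.start, s.mca.end = 1, 120_000_000
        return s

    def test_null_sample_noiseless(self, default_cohort):
        s = next(x for x in default_cohort if x.mca is None)
        sig = emit_array_signal(s, default_site_grid(200), baf_sd=0, lrr_sd=0)
        het = sig[sig["gt"].isin(["A|B", "B|A"])]
        assert set(het["baf"]) == {0.5}
        assert set(sig["lrr"]) == {0.0}

    def test_cnloh_half_fraction(self, mca_sample):
        mca_sample.mca.state, mca_sample.mca.cell_fraction = "CNLOH", 0.5
        sig = emit_array_signal(mca_sample, default_site_grid(300), baf_sd=0, lrr_sd=0)
        het = sig[sig["gt"].isin(["A|B", "B|A"])]
        inside = het[het["pos"] <= mca_sample.mca.end]
        assert set(np.round(inside["baf"], 9)) == {0.25, 0.75}
        assert set(np.round(inside["lrr"], 9)) == {0.0}

    def test_clonal_trisomy_thirds(self, mca_sample):
        mca_sample.mca.state, mca_sample.mca.cell_fraction = "gain", 1.0
        sig = emit_array_signal(mca_sample, default_site_grid(300), baf_sd=0, lrr_sd=0)
        het = sig[sig["gt"].isin(["A|B", "B|A"])]
        inside = het[het["pos"] <= mca_sample.mca.end]
        assert set(np.round(inside["baf"], 9)) == {round(1 / 3, 9), round(2 / 3, 9)}
        assert np.allclose(inside["lrr"], math.log2(1.5))

    @pytest.mark.parametrize("state", ["gain", "loss", "CNLOH"])
    def test_closed_form_grid(self, mca_sample, state):
        """Noiseless signal matches independent allele-copy accounting for
        every cell fraction on a 0.1..1.0 grid."""
        for f in np.arange(0.1, 1.01, 0.1):
            mca_sample.mca.state = state
            mca_sample.mca.cell_fraction = float(f)
            sig = emit_array_signal(mca_sample, default_site_grid(120), baf_sd=0, lrr_sd=0)
            het = sig[sig["gt"].isin(["A|B", "B|A"])].copy()
            inside = het[het["pos"] <= mca_sample.mca.end]
            b1 = (inside["gt"] == "B|A").astype(float) + (inside["gt"] == "B|B").astype(float)
            b2 = (inside["gt"] == "A|B").astype(float) + (inside["gt"] == "B|B").astype(float)
            exp_baf, exp_lrr = _signal_oracle(
                b1.to_numpy(), b2.to_numpy(), state, float(f), mca_sample.mca.retained_haplotype
            )
            assert np.allclose(inside["baf"], exp_baf, atol=1e-12)
            assert np.allclose(inside["lrr"], exp_lrr, atol=1e-12)

    def test_empty_grid_rejected(self, mca_sample):
        with pytest.raises(ValueError):
            emit_array_signal(mca_sample, np.array([], dtype=int))


class TestReads:
    def test_two_haplotypes_balanced(self, default_cohort):
        s = next(
            x
            for x in default_cohort
            if x.mca is None and x.v617f_status == "none" and x.het_46_1
        )
        reads = emit_reads(s, n_reads=4000, error_rate=0.0)
        strings = reads["a1"] + reads["a2"] + reads["a3"]
        counts = strings.value_counts()
        assert set(counts.index) == {s.germline_hap1, s.germline_hap2}
        assert abs(counts.iloc[0] / 4000 - 0.5) <= 3 * binomial_se(0.5, 4000)

    def test_saturated_allelic_fraction(self, default_cohort):
        s = copy.deepcopy(
            next(x for x in default_cohort if x.v617f_status == "hap1" and x.het_46_1)
        )
        s.mca = None
        s.v617f_af = 1.0
        reads = emit_reads(s, n_reads=2000, error_rate=0.0)
        hap1_reads = reads[(reads["a1"] + reads["a2"] + reads["a3"]) == s.germline_hap1]
        assert (hap1_reads["v617f"] == "mut").all()

    def test_cnloh_shifts_haplotype_share(self, default_cohort):
        s = copy.deepcopy(next(x for x in default_cohort if x.het_46_1))
        from clonalshift.simulate import Mca

        s.mca = Mca("CNLOH", "chr9", 1, 10**8, 0.4, retained_haplotype=1)
        s.v617f_status, s.v617f_af = "none", None
        reads = emit_reads(s, n_reads=10_000, error_rate=0.0)
        share1 = ((reads["a1"] + reads["a2"] + reads["a3"]) == s.germline_hap1).mean()
        assert abs(share1 - 0.7) <= 3 * binomial_se(0.7, 10_000)

    def test_n_reads_precondition(self, default_cohort):
        with pytest.raises(ValueError):
            emit_reads(default_cohort[0], n_reads=0)


class TestInstruments:
    def test_null_effect_recovered(self):
        inst = emit_instruments(20, true_effect=0.0, seed=7)
        res = mr_ivw(inst)
        assert abs(res.estimate) <= 3 * res.se

    def test_positive_effect_recovered(self):
        inst = emit_instruments(20, true_effect=2.0, seed=8)
        res = mr_ivw(inst)
        assert abs(res.estimate - 2.0) <= 3 * res.se

    def test_pleiotropy_spec_injected(self):
        inst = emit_instruments(19, true_effect=0.5, pleiotropy_spec=(5, 1.0), seed=9)
        assert inst["pleiotropic"].sum() == 5
        inst2 = emit_instruments(10, true_effect=0.5, pleiotropy_spec={3: 2.0}, seed=9)
        assert inst2["pleiotropic"].tolist().index(True) == 3

    def test_minimum_variants(self):
        with pytest.raises(ValueError):
            emit_instruments(2, true_effect=1.0)


class TestQpcrEmission:
    def test_deterministic_and_shaped(self):
        rec1, curve1, ctrl1 = emit_qpcr(n_samples=10, seed=3)
        rec2, _, _ = emit_qpcr(n_samples=10, seed=3)
        pd.testing.assert_frame_equal(rec1, rec2)
        assert len(rec1) == 20  # two replicate sets per sample
        assert all(len(v) == 3 for v in rec1["telomere_cq"])
        assert curve1["quantity"].is_monotonic_increasing
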