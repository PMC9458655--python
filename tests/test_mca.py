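"""mCA caller: segmentation, state classification, cell fraction, region."""

import copy
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalshift.genome import GRCH38_CHROM_LENGTHS, V617F_POS
from clonalshift.mca import (
    McaParams,
    Segment,
    _best_segment,
    call_mcas,
    classify_region,
    classify_state,
    estimate_cell_fraction,
    segment_baf,
)
from clonalshift.simulate import Mca, default_site_grid, emit_array_signal


def make_signal(n_sites, event=None, baf_sd=0.0, lrr_sd=0.0, seed=0, chrom="chr9"):
    """Hand-built phased signal: alternating A|B / B|A het sites, optional
    (start_idx, end_idx, state, cf, retained) event."""
    rng = np.random.default_rng(seed)
    pos = np.arange(1, n_sites + 1) * 100_000
    gt = np.where(np.arange(n_sites) % 2 == 0, "A|B", "B|A")
    b1 = (gt == "B|A").astype(float)
    b2 = (gt == "A|B").astype(float)
    baf = np.full(n_sites, 0.5)
    lrr = np.zeros(n_sites)
    if event is not None:
        i0, i1, state, f, retained = event
        copies = {"CNLOH": (2, 0), "loss": (1, 0), "gain": (2, 1)}[state]
        c1, c2 = copies if retained == 1 else copies[::-1]
        sel = slice(i0, i1 + 1)
        total = f * (c1 + c2) + (1 - f) * 2
        baf[sel] = (f * (b1[sel] * c1 + b2[sel] * c2) + (1 - f) * (b1[sel] + b2[sel])) / total
        lrr[sel] = math.log2(total / 2)
    baf = np.clip(baf + rng.normal(0, baf_sd, n_sites), 0, 1) if baf_sd else baf
    lrr = lrr + rng.normal(0, lrr_sd, n_sites) if lrr_sd else lrr
    return pd.DataFrame({"chrom": chrom, "pos": pos, "baf": baf, "lrr": lrr, "gt": gt})


class TestSegmentation:
    def test_null_chromosome_clean(self):
        assert segment_baf(make_signal(400, baf_sd=0.03, seed=4)) == []

    def test_noiseless_null(self):
        assert segment_baf(make_signal(200)) == []

    def test_boundaries_within_five_sites(self):
        sig = make_signal(1000, event=(100, 200, "CNLOH", 0.4, 1), baf_sd=0.03, seed=1)
        segs = segment_baf(sig)
        assert len(segs) == 1
        i0 = np.searchsorted(sig["pos"].to_numpy(), segs[0].start_pos)
        i1 = np.searchsorted(sig["pos"].to_numpy(), segs[0].end_pos)
        assert abs(i0 - 100) <= 5 and abs(i1 - 200) <= 5

    def test_two_events_separated(self):
        sig = make_signal(600, event=(50, 150, "CNLOH", 0.5, 1), baf_sd=0.03, seed=2)
        # inject second event manually
        sig2 = make_signal(600, event=(300, 420, "loss", 0.6, 2), baf_sd=0.03, seed=2)
        sig.loc[300:420, ["baf", "lrr"]] = sig2.loc[300:420, ["baf", "lrr"]]
        segs = segment_baf(sig)
        assert len(segs) == 2

    def test_all_homozygous_warns_empty(self):
        sig = make_signal(100)
        sig["gt"] = "A|A"
        sig["baf"] = 0.0
        with pytest.warns(UserWarning):
            assert segment_baf(sig) == []

    def test_matches_exhaustive_changepoint_oracle(self):
        """On small inputs the reported segment equals the brute-force
        best-scoring changepoint pair from an independent double loop."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(0, 1, 28)
            x[8:19] += 2.5
            best = (None, -1.0)
            for i in range(28):
                for j in range(i + 4, 28):  # min length 5
                    score = abs(x[i : j + 1].sum()) / math.sqrt(j - i + 1)
                    if score > best[1]:
                        best = ((i, j), score)
            i, j, score = _best_segment(x, 1.0, 5)
            assert (i, j) == best[0]
            assert score == pytest.approx(best[1], rel=1e-12)


class TestCellFraction:
    def test_zero_shift(self):
        for state in ("gain", "loss", "CNLOH"):
            assert estimate_cell_fraction(0.0, state) == 0.0

    def test_allele_copy_accounting_values(self):
        assert estimate_cell_fraction(0.25, "CNLOH") == pytest.approx(0.5)
        assert estimate_cell_fraction(0.25, "loss") == pytest.approx(2 / 3, abs=1e-4)

    def test_maximal_shift_saturates(self):
        assert estimate_cell_fraction(0.5, "CNLOH") == pytest.approx(1.0)
        assert estimate_cell_fraction(0.5, "loss") == pytest.approx(1.0)
        assert estimate_cell_fraction(1 / 6, "gain") == pytest.approx(1.0)

    def test_gain_beyond_trisomy_capped_with_warning(self):
        with pytest.warns(UserWarning):
            assert estimate_cell_fraction(0.3, "gain") == 1.0

    def test_undetermined_rejected(self):
        with pytest.raises(ValueError):
            estimate_cell_fraction(0.1, "undetermined")

    @given(st.floats(0.0, 0.49), st.floats(0.0, 0.49))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_dbaf(self, d1, d2):
        lo, hi = sorted((d1, d2))
        for state in ("loss", "CNLOH"):
            assert estimate_cell_fraction(lo, state) <= estimate_cell_fraction(hi, state) + 1e-12
        lo_g, hi_g = min(lo, 1 / 6), min(hi, 1 / 6)
        assert estimate_cell_fraction(lo_g, "gain") <= estimate_cell_fraction(hi_g, "gain") + 1e-9


def seg(dbaf, lrr, n_het=100):
    return Segment(
        chrom="chr9",
        start_pos=1,
        end_pos=10_000_000,
        n_het=n_het,
        mean_abs_dbaf=dbaf,
        phased_dbaf=dbaf,
        median_lrr=lrr,
    )


class TestClassifyState:
    def test_balanced_lrr_strong_imbalance_is_cnloh(self):
        assert classify_state(seg(0.25, 0.0)) == "CNLOH"

    def test_positive_lrr_is_gain(self):
        assert classify_state(seg(0.10, 0.20)) == "gain"

    def test_subthreshold_is_undetermined(self):
        assert classify_state(seg(0.02, -0.02)) == "undetermined"

    def test_low_cf_loss_resolved_by_lrr_consistency(self):
        # loss at cf 0.15: dbaf = f/(2(2-f)) ~ 0.0405, LRR ~ -0.1125
        assert classify_state(seg(0.0405, -0.1125)) == "loss"

    def test_low_cf_gain_resolved_by_lrr_consistency(self):
        # gain at cf 0.3: dbaf = f/(2(2+f)) ~ 0.0652, LRR ~ +0.2016
        assert classify_state(seg(0.0652, 0.2016)) == "gain"


class TestClassifyRegion:
    def test_inside_margin_is_telomeric(self):
        s = seg(0.1, 0.0)
        s.start_pos, s.end_pos = 1, 900_000
        assert classify_region(s, 150_000_000) == "telomeric"

    def test_interior_is_interstitial(self):
        s = seg(0.1, 0.0)
        s.start_pos, s.end_pos = 50_000_000, 60_000_000
        assert classify_region(s, 150_000_000) == "interstitial"

    def test_full_extent_is_whole_chromosome(self):
        s = seg(0.1, 0.0)
        s.start_pos, s.end_pos = 200_000, 149_000_000
        assert classify_region(s, 150_000_000, het_extent=(200_000, 149_000_000)) == "whole_chromosome"


class TestCaller:
    def test_round_trip_state_and_cf_exact(self, default_cohort):
        """Noiseless emission -> caller recovers (state, cf) exactly on the
        full (state x cell fraction) grid."""
        s = copy.deepcopy(next(x for x in default_cohort if x.mca is not None))
        s.mca.start, s.mca.end = 1, 100_000_000
        grid = default_site_grid(300)
        for state in ("gain", "loss", "CNLOH"):
            for cf in np.arange(0.1, 1.01, 0.1):
                s.mca.state, s.mca.cell_fraction = state, float(cf)
                sig = emit_array_signal(s, grid, baf_sd=0, lrr_sd=0)
                calls = call_mcas(sig)
                assert len(calls) == 1
                assert calls[0].state == state
                assert calls[0].cell_fraction == pytest.approx(cf, abs=1e-9)
                assert calls[0].retained_haplotype == s.mca.retained_haplotype

    def test_cnloh_fixture_overlaps_v617f(self, default_cohort):
        s = copy.deepcopy(next(x for x in default_cohort if x.mca is not None))
        s.mca = Mca("CNLOH", "chr9", 1, 8_000_000, 0.45, retained_haplotype=2)
        sig = emit_array_signal(s, default_site_grid(900), baf_sd=0.03, lrr_sd=0.14)
        calls = call_mcas(sig)
        hits = [
            c
            for c in calls
            if c.state == "CNLOH" and c.start_pos <= V617F_POS <= c.end_pos
        ]
        assert len(hits) == 1
        assert hits[0].cell_fraction == pytest.approx(0.45, abs=0.05)

    def test_calls_sorted(self):
        sig = pd.concat(
            [
                make_signal(200, event=(50, 150, "CNLOH", 0.5, 1), baf_sd=0.02, seed=5, chrom="chr9"),
                make_signal(200, event=(20, 120, "loss", 0.6, 1), baf_sd=0.02, seed=6, chrom="chr13"),
            ],
            ignore_index=True,
        )
        params = McaParams(chrom_lengths=dict(GRCH38_CHROM_LENGTHS))
        calls = call_mcas(sig, params)
        assert [c.chrom for c in calls] == sorted(c.chrom for c in calls)
        assert len(calls) == 2
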