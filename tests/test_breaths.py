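"""Breath segmentation, true-breath screening and interval summaries."""

import numpy as np
import pytest

from sivent import (
    MechanicsEstimate,
    SegmentedBreath,
    VirtualPatientConfig,
    estimate_peep,
    filter_true_breaths,
    generate_patient_stream,
    process_stream,
    segment_breaths,
    summarize_interval,
)


def arrays(stream):
    return stream["t_s"], stream["pressure_cmH2O"], stream["flow_Lps"]


def stub_breath(pressure, flow, insp_start, exp_start, dt=0.02, **kw):
    n = len(pressure)
    return SegmentedBreath(
        insp_start=insp_start,
        exp_start=exp_start,
        end=n,
        slice_start=0,
        t=np.arange(n) * dt,
        pressure=np.asarray(pressure, dtype=float),
        flow=np.asarray(flow, dtype=float),
        PIP=float(np.max(pressure[insp_start:exp_start])),
        peak_insp_volume=kw.pop("peak_insp_volume", 0.3),
        **kw,
    )


class TestSegmentation:
    def test_clean_stream_yields_one_segment_per_breath(self, clean_stream):
        stream, truth = clean_stream
        segs = segment_breaths(*arrays(stream))
        assert len(segs) == truth["breaths_per_interval"] == 20
        assert all(not b.quality_flags for b in segs)
        assert all(b.insp_start < b.exp_start <= b.end for b in segs)

    def test_constant_pressure_zero_flow_yields_nothing(self):
        t = np.arange(0, 30, 0.02)
        segs = segment_breaths(t, np.full_like(t, 8.0), np.zeros_like(t))
        assert segs == []

    def test_expiration_later_than_criterion_is_rejected(self):
        # inspiration at t=0.4, expiration only at t=5.4 > 4.125 s later
        t = np.arange(0, 8, 0.02)
        flow = np.zeros_like(t)
        pressure = np.full_like(t, 5.0)
        ins = (t >= 0.4) & (t < 1.0)
        exp = (t >= 5.4) & (t < 6.0)
        flow[ins], flow[exp] = 0.5, -0.5
        pressure[(t >= 0.4) & (t < 5.4)] = 20.0
        rejected = segment_breaths(t, pressure, flow, keep_rejected=True)
        assert len(rejected) == 1
        assert "late_expiration" in rejected[0].quality_flags
        assert segment_breaths(t, pressure, flow) == []

    def test_segmentation_insensitive_to_partial_edges(self, clean_stream):
        stream, _ = clean_stream
        t, p, f = arrays(stream)
        # chop mid-inspiration at the start and mid-expiration at the end
        lo, hi = 30, len(t) - 130
        segs_full = segment_breaths(t, p, f)
        segs_cut = segment_breaths(t[lo:hi], p[lo:hi], f[lo:hi])
        assert len(segs_full) - 2 <= len(segs_cut) <= len(segs_full)

    def test_empty_and_nan_streams_raise(self):
        with pytest.raises(ValueError):
            segment_breaths(np.array([]), np.array([]), np.array([]))
        t = np.arange(0, 1, 0.02)
        bad = np.full_like(t, np.nan)
        with pytest.raises(ValueError):
            segment_breaths(t, bad, np.zeros_like(t))


class TestPeepEstimate:
    def test_synthesized_peep_is_recovered(self, clean_stream):
        stream, truth = clean_stream
        segs = segment_breaths(*arrays(stream))
        assert all(b.PEEP_est == truth["PEEP"] for b in segs[1:])

    def test_constant_pressure_window(self):
        p = np.full(100, 7.0)
        f = np.zeros(100)
        f[50:60] = 0.5
        b = stub_breath(p, f, insp_start=50, exp_start=60)
        assert estimate_peep(b) == 7.0

    def test_noisy_peep_rounds_to_truth(self):
        rng = np.random.default_rng(5)
        p = 10.0 + rng.normal(0, 0.3, 100)
        f = np.zeros(100)
        f[50:60] = 0.5
        p[50:60] += 15.0
        b = stub_breath(p, f, insp_start=50, exp_start=60)
        assert estimate_peep(b) == 10.0

    def test_fallback_to_breath_minimum_without_pre_window(self):
        p = np.concatenate([np.full(10, 20.0), np.full(10, 6.0)])
        f = np.concatenate([np.full(10, 0.5), np.full(10, -0.5)])
        b = stub_breath(p, f, insp_start=0, exp_start=10)
        assert estimate_peep(b) == 6.0


class TestTrueBreathFilter:
    def test_clean_cohort_fully_accepted(self, clean_stream):
        stream, truth = clean_stream
        segs = segment_breaths(*arrays(stream))
        filter_true_breaths(segs)
        assert all(not b.quality_flags for b in segs)
        assert all(b.estimate.valid for b in segs)

    def test_distorted_breath_fails_ape_screen(self, clean_stream):
        stream, _ = clean_stream
        t, p, f = (a.copy() for a in arrays(stream))
        segs = segment_breaths(t, p, f)
        b = segs[3]
        i0, i1 = b.insp_start - b.slice_start, b.exp_start - b.slice_start
        # effort-like negative deflection over most of the inspiration —
        # no passive (E, R) pair can explain the dented pressure
        n = i1 - i0
        dip = 0.8 * (b.PIP - b.PEEP_est) * np.sin(np.pi * np.arange(n) / n)
        b.pressure[i0:i1] -= dip
        filter_true_breaths([b])
        assert "ape_exceeded" in b.quality_flags

    def test_zero_elastance_is_rejected(self):
        # purely resistive pressure: fitted elastance sits at the zero bound
        t = np.arange(0, 2.0, 0.02)
        flow = np.where(t < 1.0, 0.5, -0.5)
        pressure = 10.0 * flow + 5.0
        b = stub_breath(pressure, flow, insp_start=0, exp_start=50, PEEP_est=5.0)
        filter_true_breaths([b])
        assert "nonpositive_elastance" in b.quality_flags

    def test_percentile_outlier_rejected_once_history_accrues(self, clean_stream):
        stream, _ = clean_stream
        segs = segment_breaths(*arrays(stream))
        history = list(np.linspace(30, 38, 40))  # patient's accepted E_rs so far
        outlier = segs[2]
        i0 = outlier.insp_start - outlier.slice_start
        i1 = outlier.exp_start - outlier.slice_start
        # inflate elastic pressure: looks like E_rs ~ 2x the history band
        outlier.pressure = outlier.pressure.copy()
        vol = np.concatenate(
            [[0.0], np.cumsum((outlier.flow[1:] + outlier.flow[:-1]) / 2 * 0.02)]
        )
        outlier.pressure += 33.8 * vol
        filter_true_breaths([outlier], history=history)
        assert "percentile_outlier" in outlier.quality_flags

    def test_short_history_skips_percentile_screen(self, clean_stream):
        stream, _ = clean_stream
        segs = segment_breaths(*arrays(stream))
        history: list = []
        filter_true_breaths(segs[:5], history=history)
        assert all(not b.quality_flags for b in segs[:5])
        assert len(history) == 5


class TestIntervalSummary:
    def test_median_of_elastances(self):
        breaths = []
        for e in (40.0, 43.5, 47.0):
            b = stub_breath(np.full(20, 10.0), np.zeros(20), 5, 10, PEEP_est=13.0)
            b.estimate = MechanicsEstimate(e, 12.0, 1.0, 18, True)
            breaths.append(b)
        s = summarize_interval(breaths, N=1)
        assert s.Ers_N == 43.5 and s.Rrs_N == 12.0 and s.PEEP_N == 13.0
        assert s.n_true_breaths == 3

    def test_empty_interval_raises(self):
        with pytest.raises(ValueError):
            summarize_interval([])

    def test_process_stream_round_trip(self, clean_stream):
        stream, truth = clean_stream
        summaries = process_stream(*arrays(stream), interval_len=80.0)
        assert len(summaries) == 1
        s = summaries[0]
        assert s.Ers_N == pytest.approx(truth["trajectory"][0], rel=5e-3)
        assert s.Rrs_N == pytest.approx(truth["R"], rel=5e-3)
        assert s.PEEP_N == truth["PEEP"]
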