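"""Normalization-chain tests: baseline, peaks, rundown, summaries."""

import dataclasses

import numpy as np
import pytest

import chanlink as cl
from chanlink.exceptions import BaselineWindowError, RundownError
from chanlink.traces import PeakRecord


def drift_only_trace(drift=0.05, fs=100.0):
    proto = [cl.PulseEvent("PTX", 1e-3, 30.0, 10.0),
             cl.PulseEvent("PTX", 1e-3, 100.0, 10.0)]
    t = np.arange(0.0, 140.0, 1.0 / fs)
    return cl.Trace("oo1", "L9'T", t, drift * t, proto)


def simulated_pair(l9t, seed=5, noise=0.0, drift=0.0, rundown=0.0, ligand="GABA"):
    """A corrupted trace and its corruption-free twin sharing the noise seed."""
    concs = (0.25e-6 if ligand == "GABA" else 85e-9) * np.logspace(-2, 2, 7)
    proto = cl.bookended_protocol(ligand, concs)
    kw = dict(construct_id="L9'T", mwc=l9t, amplitude_scale=500.0,
              noise_sd=noise, seed=seed)
    dirty = cl.simulate_trace(
        cl.GroundTruth(drift_rate=drift, rundown_fraction=rundown, **kw), proto)
    clean = cl.simulate_trace(cl.GroundTruth(**kw), proto)
    return dirty, clean


class TestBaseline:
    def test_pure_linear_drift_removed_everywhere(self):
        out = cl.subtract_baseline(drift_only_trace())
        assert np.max(np.abs(out.current)) < 1e-9

    def test_window_overlapping_pulse_rejected(self):
        proto = [cl.PulseEvent("PTX", 1e-3, 30.0, 10.0),
                 cl.PulseEvent("GABA", 1e-6, 43.0, 10.0),  # 3 s gap < window
                 cl.PulseEvent("PTX", 1e-3, 120.0, 10.0)]
        t = np.arange(0.0, 160.0, 0.01)
        trace = cl.Trace("oo1", "L9'T", t, np.zeros_like(t), proto)
        with pytest.raises(BaselineWindowError):
            cl.subtract_baseline(trace, window=5.0)

    def test_drift_corrected_peaks_match_drift_free_twin(self, l9t_params):
        dirty, clean = simulated_pair(l9t_params, drift=0.05)
        p_dirty = cl.extract_peaks(cl.subtract_baseline(dirty))
        p_clean = cl.extract_peaks(cl.subtract_baseline(clean))
        for a, b in zip(p_dirty, p_clean):
            assert a.raw_peak == pytest.approx(b.raw_peak, rel=0.01)


class TestPeaks:
    def test_noiseless_peaks_match_ideal_within_1pct(self, l9t_params):
        _, clean = simulated_pair(l9t_params)
        truth = cl.GroundTruth(construct_id="L9'T", mwc=l9t_params,
                               amplitude_scale=500.0)
        peaks = cl.extract_peaks(cl.subtract_baseline(clean))
        for pk, ev in zip(peaks, clean.protocol):
            ideal = cl.ideal_peak(truth, ev)
            assert pk.raw_peak == pytest.approx(ideal, rel=0.01)

    def test_buffer_pulse_reads_zero(self, l9t_params):
        proto = [cl.PulseEvent("PTX", 1e-3, 30.0, 10.0),
                 cl.PulseEvent("buffer", 0.0, 100.0, 10.0),
                 cl.PulseEvent("PTX", 1e-3, 170.0, 10.0)]
        truth = cl.GroundTruth(construct_id="L9'T", mwc=l9t_params,
                               amplitude_scale=500.0, noise_sd=1.0, seed=3)
        trace = cl.simulate_trace(truth, proto)
        peaks = cl.extract_peaks(cl.subtract_baseline(trace))
        assert abs(peaks[1].raw_peak) < 1.0  # within the noise of zero

    def test_repeated_pulses_agree_without_rundown(self, l9t_params):
        proto = [cl.PulseEvent("PTX", 1e-3, 30.0, 10.0),
                 cl.PulseEvent("GABA", 1e-6, 100.0, 10.0),
                 cl.PulseEvent("GABA", 1e-6, 170.0, 10.0),
                 cl.PulseEvent("PTX", 1e-3, 240.0, 10.0)]
        truth = cl.GroundTruth(construct_id="L9'T", mwc=l9t_params,
                               amplitude_scale=500.0, noise_sd=2.0, seed=9)
        peaks = cl.extract_peaks(cl.subtract_baseline(cl.simulate_trace(truth, proto)))
        assert peaks[1].raw_peak == pytest.approx(peaks[2].raw_peak, abs=1.5)


class TestRundown:
    def test_hand_worked_linear_example(self):
        peaks = [PeakRecord(0, "PTX", 1e-3, -100.0, 0.0),
                 PeakRecord(1, "GABA", 1e-6, 45.0, 500.0),
                 PeakRecord(2, "PTX", 1e-3, -80.0, 1000.0)]
        fit = cl.fit_rundown(peaks)
        assert fit.scale(500.0) == pytest.approx(0.9)
        corrected = fit.apply(peaks)
        assert corrected[1].corrected_peak == pytest.approx(50.0)

    def test_equal_bookends_identity(self):
        peaks = [PeakRecord(0, "PTX", 1e-3, -100.0, 0.0),
                 PeakRecord(1, "GABA", 1e-6, 45.0, 500.0),
                 PeakRecord(2, "PTX", 1e-3, -100.0, 1000.0)]
        corrected = cl.correct_peaks(peaks)
        assert corrected[1].corrected_peak == pytest.approx(45.0, rel=1e-12)

    def test_fewer_than_two_ptx_rejected(self):
        with pytest.raises(RundownError):
            cl.fit_rundown([PeakRecord(0, "PTX", 1e-3, -100.0, 0.0)])

    def test_pathological_rundown_rejected(self):
        peaks = [PeakRecord(0, "PTX", 1e-3, -100.0, 0.0),
                 PeakRecord(1, "PTX", 1e-3, -10.0, 900.0),
                 PeakRecord(2, "GABA", 1e-6, 5.0, 1100.0)]
        with pytest.raises(RundownError):
            cl.fit_rundown(peaks)

    def test_correction_is_idempotent(self):
        peaks = [PeakRecord(0, "PTX", 1e-3, -100.0, 0.0),
                 PeakRecord(1, "GABA", 1e-6, 45.0, 500.0),
                 PeakRecord(2, "PTX", 1e-3, -80.0, 1000.0)]
        once = cl.correct_peaks(peaks)
        again = cl.correct_peaks([dataclasses.replace(p, raw_peak=p.corrected_peak)
                                  for p in once])
        for a, b in zip(once, again):
            assert b.corrected_peak == pytest.approx(a.corrected_peak, rel=1e-12)

    def test_rundown_corrected_peaks_match_twin_within_2pct(self, l9t_params):
        dirty, clean = simulated_pair(l9t_params, rundown=0.2, noise=0.0)
        p_dirty = cl.correct_peaks(cl.extract_peaks(cl.subtract_baseline(dirty)))
        p_clean = cl.extract_peaks(cl.subtract_baseline(clean))
        for a, b in zip(p_dirty, p_clean):
            assert a.corrected_peak == pytest.approx(b.raw_peak, rel=0.02)

    def test_bookend_peak_ratio_follows_rundown_fraction(self, l9t_params):
        dirty, _ = simulated_pair(l9t_params, rundown=0.2)
        peaks = cl.extract_peaks(cl.subtract_baseline(dirty))
        ptx = [p for p in peaks if p.ligand == "PTX"]
        assert abs(ptx[-1].raw_peak / ptx[0].raw_peak) == pytest.approx(0.8, rel=0.01)


class TestScaleEquivariance:
    def test_peaks_scale_and_ratios_do_not(self, l9t_params):
        dirty, _ = simulated_pair(l9t_params, rundown=0.1, drift=0.02, noise=1.0)
        scaled = dirty.copy_with(dirty.current * 3.7)
        p1, s1 = cl.process_trace(dirty)
        p2, s2 = cl.process_trace(scaled)
        for a, b in zip(p1, p2):
            assert b.corrected_peak == pytest.approx(3.7 * a.corrected_peak, rel=1e-9)
        assert s2.r_ptx_gaba == pytest.approx(s1.r_ptx_gaba, rel=1e-9)


class TestSummaries:
    def _records(self, with_dz=True, ptx_mag=100.0):
        recs = [PeakRecord(0, "PTX", 1e-3, -ptx_mag, 0.0, -ptx_mag),
                PeakRecord(1, "GABA", 1e-7, 40.0, 100.0, 40.0),
                PeakRecord(2, "GABA", 1e-5, 180.0, 200.0, 180.0)]
        if with_dz:
            recs.append(PeakRecord(3, "DZ", 1e-6, 35.0, 300.0, 35.0))
        recs.append(PeakRecord(4, "PTX", 1e-3, -ptx_mag, 400.0, -ptx_mag))
        return recs

    def test_ratios_reference_ptx_block_zero_level(self):
        s = cl.summarize_oocyte(self._records(), "oo1", "X")
        assert s.I_PTX == pytest.approx(100.0)
        assert s.I_GABA_max == pytest.approx(280.0)  # deflection + I_PTX
        assert s.r_ptx_gaba == pytest.approx(100.0 / 280.0)
        assert s.r_dz_ptx == pytest.approx(135.0 / 100.0)

    def test_exclusion_moves_maximal_concentration(self):
        s = cl.summarize_oocyte(self._records(), "oo1", "X", exclude_conc=[1e-5])
        assert s.I_GABA_max == pytest.approx(140.0)

    def test_ptx_only_gives_absent_ratios(self):
        recs = [PeakRecord(0, "PTX", 1e-3, -50.0, 0.0, -50.0)]
        s = cl.summarize_oocyte(recs, "oo1", "X")
        assert s.I_GABA_max is None and s.r_ptx_gaba is None and s.r_dz_ptx is None

    def test_zero_spontaneous_current_marks_dz_ratio_undefined(self):
        recs = [PeakRecord(0, "PTX", 1e-3, 0.0, 0.0, 0.0),
                PeakRecord(1, "DZ", 1e-6, 30.0, 100.0, 30.0),
                PeakRecord(2, "PTX", 1e-3, 0.0, 200.0, 0.0)]
        s = cl.summarize_oocyte(recs, "oo1", "X")
        assert s.r_dz_ptx is None

    def test_cohort_tuned_to_l9t_reproduces_table_ratios(self, l9t_params):
        """A low-noise cohort generated from the fitted L9'T parameters gives
        mean ratios near the reported 0.36 and 1.35."""
        spec = cl.ConstructSpec(
            construct_id="L9'T", mwc=l9t_params, n_oocytes=3,
            gaba_concs=tuple(0.25e-6 * np.logspace(-2, 2, 7)),
            dz_concs=tuple(85e-9 * np.logspace(-2, 2, 7)))
        cfg = cl.CohortConfig(constructs=[spec], noise_sd=2.0, sample_rate=50.0)
        cohort = cl.generate_cohort(cfg, seed=21)
        summaries = [cl.process_trace(tr)[1] for tr in cohort.traces]
        r_pg = np.mean([s.r_ptx_gaba for s in summaries if s.r_ptx_gaba])
        r_dp = np.mean([s.r_dz_ptx for s in summaries if s.r_dz_ptx])
        assert r_pg == pytest.approx(0.36, abs=0.04)
        assert r_dp == pytest.approx(1.35, abs=0.05)


class TestTraceIO:
    def test_round_trip(self, l9t_params, tmp_path):
        dirty, _ = simulated_pair(l9t_params, noise=1.0)
        cl.write_trace(dirty, tmp_path)
        back = cl.read_trace(tmp_path / f"{dirty.oocyte_id}.csv")
        assert back.construct_id == dirty.construct_id
        assert len(back.protocol) == len(dirty.protocol)
        assert np.allclose(back.current, dirty.current, atol=1e-6)

    def test_rewriting_is_byte_identical(self, l9t_params, tmp_path):
        dirty, _ = simulated_pair(l9t_params, noise=1.0)
        p1 = cl.write_trace(dirty, tmp_path / "a")
        p2 = cl.write_trace(dirty, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()
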