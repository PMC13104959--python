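"""Extrema detection, artifact rejection, greedy matching, shape features."""

import itertools

import numpy as np
import pandas as pd
import pytest

import respshape as rs
from respshape.cycles import (
    PEAK,
    TROUGH,
    ExtremaSequence,
    MatchedCyclePair,
    _cycle_features,
)
from respshape.recording import Recording


def _sine_rec(freq=0.25, fs=500, duration=60, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return Recording(amp * np.sin(2 * np.pi * freq * t), fs)


def _extrema(peaks, troughs, fs=100):
    times = np.sort(np.concatenate([peaks, troughs]))
    peak_set = set(np.asarray(peaks).tolist())
    kinds = [PEAK if t in peak_set else TROUGH for t in times]
    return ExtremaSequence(np.asarray(times, float), kinds, fs)


class TestDetectExtrema:
    def test_sine_yields_one_extremum_per_half_period(self):
        ext = rs.detect_extrema(_sine_rec(), base_height=0.0)
        assert ext.peak_times.size == 15
        assert ext.trough_times.size == 15
        assert np.all(np.abs(np.diff(ext.kinds)) == 2)  # strict alternation

    def test_constant_signal_has_no_extrema(self):
        rec = Recording(np.zeros(5000), 100)
        with pytest.raises(rs.EmptyExtremaError):
            rs.detect_extrema(rec)

    def test_small_ripple_removed_by_pipeline_filter(self):
        # detection operates on band-passed signals, where a 5 Hz ripple is
        # suppressed and extrema times match the clean sine's
        fs = 500
        t = np.arange(int(120 * fs)) / fs
        clean = np.sin(2 * np.pi * 0.25 * t)
        noisy = clean + 0.05 * np.sin(2 * np.pi * 5.0 * t)
        a = rs.detect_extrema(rs.prepare_timedomain(Recording(clean, fs)),
                              base_height=0.0)
        b = rs.detect_extrema(rs.prepare_timedomain(Recording(noisy, fs)),
                              base_height=0.0)
        assert a.times.size == b.times.size
        assert np.max(np.abs(a.times - b.times)) <= 1.0 / fs + 1e-12

    def test_low_amplitude_extrema_removed(self):
        fs = 100
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        # superimpose a tiny extra bump well separated from the main peaks
        x[int(34.0 * fs):int(34.0 * fs) + 50] += 0.12
        ext = rs.detect_extrema(Recording(x, fs), base_height=0.0,
                                relative_amplitude_frac=0.3)
        # the bump (amplitude ~0.12 above median vs median peak ~1) is gone
        assert np.all(np.abs(np.diff(ext.kinds)) == 2)


class TestRejectArtifactCycles:
    def _cycle_signal(self, amps, fs=100, period=4.0):
        """Concatenated raised-cosine cycles with given amplitudes."""
        half = int(period / 2 * fs)
        segs = []
        for a in amps:
            k = np.arange(half)
            segs.append(a * 0.5 * (1 - np.cos(np.pi * k / half)))
            segs.append(a * 0.5 * (1 + np.cos(np.pi * k / half)))
        return Recording(np.concatenate(segs), fs)

    def test_homogeneous_cycles_all_kept(self):
        rec = self._cycle_signal([1.0] * 20)
        ext = rs.detect_extrema(rec, base_height=0.4)
        out = rs.reject_artifact_cycles(ext, rec, mad_k=5.0)
        assert out.peak_times.size == ext.peak_times.size

    def test_single_large_artifact_rejected(self):
        amps = [1.0] * 10 + [50.0] + [1.0] * 10
        rec = self._cycle_signal(amps)
        ext = rs.detect_extrema(rec, base_height=0.4,
                                relative_amplitude_frac=0.0)
        out = rs.reject_artifact_cycles(ext, rec, mad_k=5.0)
        assert out.peak_times.size == ext.peak_times.size - 1
        # the rejected peak is the artifact (at cycle index 10)
        dropped = set(np.round(ext.peak_times, 6)) - set(np.round(out.peak_times, 6))
        assert len(dropped) == 1
        t_dropped = dropped.pop()
        assert 10 * 4.0 < t_dropped < 11 * 4.0

    def test_rejection_count_monotone_in_mad_k(self):
        rng = np.random.default_rng(3)
        amps = rng.lognormal(0.0, 0.5, 30)
        rec = self._cycle_signal(list(amps))
        ext = rs.detect_extrema(rec, base_height=0.05,
                                relative_amplitude_frac=0.0)
        kept = [rs.reject_artifact_cycles(ext, rec, mad_k=k).peak_times.size
                for k in (1.0, 2.0, 4.0, 8.0)]
        assert kept == sorted(kept)

    def test_too_few_cycles_rejected(self):
        rec = self._cycle_signal([1.0] * 3)
        ext = rs.detect_extrema(rec, base_height=0.4)
        with pytest.raises(rs.InsufficientDataError):
            rs.reject_artifact_cycles(ext, rec, mad_k=5.0)


def exhaustive_match(resp_peaks, neural_peaks, tau):
    """Oracle: best injective assignment (max pairs, then min total |dt|)."""
    best = (0, 0.0, ())
    n = len(neural_peaks)
    for r in range(min(len(resp_peaks), n), -1, -1):
        found = None
        for r_sel in itertools.combinations(range(len(resp_peaks)), r):
            for n_sel in itertools.permutations(range(n), r):
                dts = [abs(neural_peaks[j] - resp_peaks[i])
                       for i, j in zip(r_sel, n_sel)]
                if all(d < tau for d in dts):
                    cand = (r, -sum(dts), tuple(zip(r_sel, n_sel)))
                    if found is None or cand > found:
                        found = cand
        if found:
            return sorted(found[2])
    return []


class TestMatchPeaks:
    def _seq_with_cycles(self, peaks, fs=100):
        peaks = np.asarray(peaks, float)
        troughs = np.sort(np.concatenate([peaks - 1.0, [peaks[-1] + 1.0]]))
        return _extrema(peaks, troughs, fs)

    def test_close_peaks_all_match(self):
        resp = self._seq_with_cycles([10, 20, 30])
        neural = self._seq_with_cycles([10.4, 20.3, 30.1])
        pairs = rs.match_peaks(resp, neural, tau=4.0)
        assert [round(p.delay, 6) for p in pairs] == [0.4, 0.3, 0.1]
        oracle = exhaustive_match([10, 20, 30], [10.4, 20.3, 30.1], 4.0)
        assert [(i, j) for i, j in oracle] == [(0, 0), (1, 1), (2, 2)]

    def test_peak_beyond_tau_unmatched(self):
        resp = self._seq_with_cycles([10.0])
        neural = self._seq_with_cycles([14.5])
        assert rs.match_peaks(resp, neural, tau=4.0) == []

    def test_greedy_order_on_contended_peak(self):
        """First-visited respiration peak wins the shared neural peak."""
        resp = _extrema([10.0, 11.0], [9.0, 10.5, 11.5], fs=100)
        neural = self._seq_with_cycles([10.6])
        pairs = rs.match_peaks(resp, neural, tau=4.0)
        assert len(pairs) == 1
        assert pairs[0].resp_peak_t == 10.0
        assert np.isclose(pairs[0].delay, 0.6)

    def test_matching_is_injective(self):
        rng = np.random.default_rng(4)
        resp_peaks = np.sort(rng.uniform(5, 95, 12))
        neural_peaks = np.sort(rng.uniform(5, 95, 12))
        resp = self._seq_with_cycles(resp_peaks)
        neural = self._seq_with_cycles(neural_peaks)
        pairs = rs.match_peaks(resp, neural, tau=3.0)
        used = [p.neural_peak_t for p in pairs]
        assert len(used) == len(set(used))

    def test_agrees_with_exhaustive_oracle_when_separated(self):
        rng = np.random.default_rng(5)
        for trial in range(25):
            k = int(rng.integers(2, 6))
            resp_peaks = 10.0 + np.arange(k) * 3.0 + rng.uniform(0, 0.3, k)
            neural_peaks = resp_peaks + rng.uniform(-0.4, 0.4, k)
            pairs = rs.match_peaks(self._seq_with_cycles(resp_peaks),
                                   self._seq_with_cycles(neural_peaks),
                                   tau=1.0)
            oracle = exhaustive_match(list(resp_peaks), list(neural_peaks), 1.0)
            got = [(float(p.resp_peak_t), float(p.neural_peak_t)) for p in pairs]
            want = [(float(resp_peaks[i]), float(neural_peaks[j]))
                    for i, j in oracle]
            assert got == want

    def test_neural_after_resp_direction(self):
        resp = self._seq_with_cycles([10.0])
        neural = _extrema([9.8, 10.7], [9.0, 10.2, 11.5], fs=100)
        pairs = rs.match_peaks(resp, neural, tau=4.0,
                               match_direction="neural_after_resp")
        assert len(pairs) == 1
        assert pairs[0].neural_peak_t == 10.7


class TestExtractFeatures:
    def test_symmetric_triangle_cycle(self):
        fs = 100
        period = 4.0
        half = int(period / 2 * fs)
        one = np.concatenate([np.linspace(0, 1, half, endpoint=False),
                              np.linspace(1, 0, half, endpoint=False)])
        x = np.tile(one, 5)
        rec = Recording(x, fs)
        feats = _cycle_features((4.0, 6.0, 8.0), rec)
        assert feats["rise_time_s"] == 2.0
        assert feats["decay_time_s"] == 2.0
        assert feats["rise_decay_symmetry"] == 0.5

    def test_unit_sine_cycle_symmetries(self):
        fs = 500
        t = np.arange(int(12 * fs)) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        rec = Recording(x, fs)
        # trough at t=3, peak at t=5, trough at t=7
        feats = _cycle_features((3.0, 5.0, 7.0), rec)
        assert np.isclose(feats["amplitude"], 2.0, atol=1e-4)
        assert np.isclose(feats["inhale_peak_auc"],
                          feats["exhale_trough_auc"], rtol=1e-2)
        # sharpness oracle: mean|dx/dt| over the FWHM window (where sin > 0)
        # = 2*pi*f*mean|cos| = 4f; normalized by amplitude 2 -> 2f = 0.5
        assert np.isclose(feats["inhale_peak_sharpness"], 0.5, rtol=0.01)
        assert np.isclose(feats["exhale_trough_sharpness"], 0.5, rtol=0.01)

    def test_degenerate_cycle_skipped_with_warning(self):
        rec = Recording(np.zeros(2000) + np.linspace(0, 1, 2000), 100)
        with pytest.warns(UserWarning):
            out = _cycle_features((2.0, 5.0, 8.0), rec)
        assert out is None

    def test_noiseless_extraction_matches_truth_within_two_samples(self):
        params = rs.BreathTemplateParams(pause_mean_s=0.0, pause_jitter_sd=0.0,
                                         sensor_noise_sd=0.0)
        rec, truth = rs.simulate_respiration(params, 200, 100, seed=31)
        ext = rs.detect_extrema(rec, base_height=0.3,
                                relative_amplitude_frac=0.0)
        cycles = ext.cycles()
        tol = 2.0 / rec.fs + 1e-9
        matched = 0
        for t1, p, t2 in cycles:
            row = truth[np.abs(truth["t_peak_s"] - p) < 0.5]
            if len(row) != 1:
                continue
            row = row.iloc[0]
            assert abs((p - t1) - row.rise_s) <= tol
            assert abs((t2 - p) - row.decay_s) <= tol
            matched += 1
        assert matched >= len(truth) - 2


class TestOutlierExclusion:
    def _frame(self, values, feature="rise_time_s"):
        n = len(values)
        cols = {f"resp_{f}": np.ones(n) for f in rs.SHAPE_FEATURES}
        cols.update({f"neural_{f}": np.ones(n) for f in rs.SHAPE_FEATURES})
        cols[f"resp_{feature}"] = np.asarray(values, float)
        cols["subject_id"] = "s00"
        cols["channel_id"] = "ch"
        return pd.DataFrame(cols)

    def test_homogeneous_rows_all_kept(self):
        out = rs.exclude_feature_outliers(self._frame([1.0] * 30))
        assert len(out) == 30

    def test_single_extreme_row_dropped(self):
        vals = [1.0] * 99 + [100.0]
        out = rs.exclude_feature_outliers(self._frame(vals))
        assert len(out) == 99
        assert out["resp_rise_time_s"].max() == 1.0

    def test_rule_is_one_sided_above(self):
        vals = [10.0] * 99 + [-100.0]
        out = rs.exclude_feature_outliers(self._frame(vals))
        assert len(out) == 100

    def test_amplitude_not_filtered(self):
        frame = self._frame([1.0] * 50)
        frame["resp_amplitude"] = [1.0] * 49 + [1000.0]
        frame["neural_amplitude"] = 1.0
        out = rs.exclude_feature_outliers(frame)
        assert len(out) == 50


class TestInvariants:
    def test_alternation_after_pipeline(self, coupled_dataset):
        resp = rs.prepare_timedomain(coupled_dataset.get("s00", "airflow"))
        ext = rs.detect_extrema(resp)
        assert np.all(np.abs(np.diff(ext.kinds)) == 2)
        ext2 = rs.reject_artifact_cycles(ext, resp, mad_k=5.0)
        assert np.all(np.abs(np.diff(ext2.kinds)) == 2)

    def test_matched_pair_ordering_and_budget(self, coupled_dataset):
        ds = coupled_dataset
        band = rs.breathing_band_for(ds.get("s00", "airflow"))
        tbl = rs.matched_cycle_table(ds.get("s00", "airflow"),
                                     ds.get("s00", "lfp00"), band=band)
        assert (tbl["delay"].abs() < band.tau).all()
        assert (tbl["resp_rise_time_s"] > 0).all()
        assert (tbl["neural_rise_time_s"] > 0).all()
        total = (tbl["resp_rise_time_s"] + tbl["resp_decay_time_s"]).sum()
        assert total <= ds.get("s00", "airflow").duration_s
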