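"""Synthetic generator: determinism, truth-table consistency, coupling truth."""

import numpy as np
import pandas as pd
import pytest

import respshape as rs


def _symmetric_params(**kw):
    defaults = dict(mean_rise_s=2.0, mean_decay_s=2.0, rise_jitter_sd=0.0,
                    decay_jitter_sd=0.0, pause_mean_s=0.0, pause_jitter_sd=0.0,
                    amplitude_jitter_sd=0.0, sensor_noise_sd=0.0)
    defaults.update(kw)
    return rs.BreathTemplateParams(**defaults)


class TestSimulateRespiration:
    def test_symmetric_template_gives_symmetric_cycles(self):
        rec, truth = rs.simulate_respiration(_symmetric_params(), 120, 100, seed=0)
        ext = rs.detect_extrema(rec, base_height=0.5)
        rows = [rs.cycles._cycle_features(c, rec) for c in ext.cycles()]
        sym = np.array([r["rise_decay_symmetry"] for r in rows])
        dur = np.array([r["cycle_duration_s"] for r in rows])
        assert np.all(sym == 0.5)
        assert np.allclose(dur, 4.0)

    def test_seeded_determinism_is_sample_exact(self):
        a, ta = rs.simulate_respiration(rs.BreathTemplateParams(), 60, 100, seed=7)
        b, tb = rs.simulate_respiration(rs.BreathTemplateParams(), 60, 100, seed=7)
        assert np.array_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seed_changes_signal(self):
        a, _ = rs.simulate_respiration(rs.BreathTemplateParams(), 60, 100, seed=1)
        b, _ = rs.simulate_respiration(rs.BreathTemplateParams(), 60, 100, seed=2)
        assert not np.array_equal(a.samples, b.samples)

    def test_median_extracted_durations_match_template(self):
        params = rs.BreathTemplateParams(
            mean_rise_s=1.5, mean_decay_s=2.5, rise_jitter_sd=0.2,
            decay_jitter_sd=0.2, pause_mean_s=0.0, pause_jitter_sd=0.0,
            sensor_noise_sd=0.0)
        rec, truth = rs.simulate_respiration(params, 300, 100, seed=7)
        prepared = rs.prepare_timedomain(rec)
        ext = rs.detect_extrema(prepared).restrict(10, 290)
        rows = [rs.cycles._cycle_features(c, prepared) for c in ext.cycles()]
        rises = np.median([r["rise_time_s"] for r in rows])
        decays = np.median([r["decay_time_s"] for r in rows])
        assert abs(rises - 1.5) < 0.15
        assert abs(decays - 2.5) < 0.15

    def test_one_peak_per_rendered_cycle(self):
        rec, truth = rs.simulate_respiration(rs.BreathTemplateParams(), 200, 100, seed=4)
        ext = rs.detect_extrema(rec, base_height=0.2)
        # every truth cycle contains exactly one detected peak
        for _, row in truth.iterrows():
            n = np.sum((ext.peak_times >= row.t_trough_s)
                       & (ext.peak_times < row.t_trough_next_s))
            assert n == 1

    def test_truth_durations_tile_the_signal(self):
        rec, truth = rs.simulate_respiration(rs.BreathTemplateParams(), 200, 100, seed=9)
        total = (truth["rise_s"] + truth["decay_s"] + truth["pause_s"]).sum()
        last_end = truth["t_trough_next_s"].iloc[-1] + truth["pause_s"].iloc[-1]
        assert abs(total - last_end) <= 1.0 / rec.fs + 1e-9
        assert last_end <= rec.duration_s + 1e-9

    @pytest.mark.parametrize("duration,fs", [(-5, 100), (60, -1), (10, 100), (60, 50)])
    def test_invalid_arguments_rejected(self, duration, fs):
        with pytest.raises(rs.InvalidArgumentError):
            rs.simulate_respiration(rs.BreathTemplateParams(), duration, fs, seed=0)


class TestSimulateCoupledLFP:
    def test_identity_coupling_reproduces_cycle_durations(self):
        params = _symmetric_params(rise_jitter_sd=0.3, decay_jitter_sd=0.3,
                                   amplitude_jitter_sd=0.1)
        _, truth = rs.simulate_respiration(params, 240, 100, seed=5)
        gt = rs.CouplingGroundTruth(beta_true=1.0, noise_scale=0.0, lag_s=0.3)
        _, ntruth = rs.simulate_coupled_lfp(truth, gt, fs=100, seed=5,
                                            background_amp=0.0)
        merged = truth.merge(ntruth, on="cycle", suffixes=("_r", "_n"))
        assert np.allclose(merged["rise_s_r"], merged["rise_s_n"], atol=1e-9)
        assert np.allclose(merged["period_s_r"], merged["period_s_n"],
                           atol=1.0 / 100 + 1e-9)

    def test_zero_beta_gives_flat_truth_regression(self):
        slopes = []
        for rep in range(20):
            _, truth = rs.simulate_respiration(
                rs.BreathTemplateParams(), 2100, 100, seed=rep)
            gt = rs.CouplingGroundTruth(beta_true=0.0, lag_s=0.3)
            _, ntruth = rs.simulate_coupled_lfp(truth, gt, fs=100, seed=rep,
                                                background_amp=0.0)
            merged = truth.merge(ntruth, on="cycle", suffixes=("_r", "_n"))
            assert len(merged) >= 500
            zx = (merged["rise_s_r"] - merged["rise_s_r"].mean()) / merged["rise_s_r"].std()
            zy = (merged["rise_s_n"] - merged["rise_s_n"].mean()) / merged["rise_s_n"].std()
            slopes.append(np.polyfit(zx, zy, 1)[0])
        assert np.abs(np.mean(slopes)) < 0.05

    def test_excessive_lag_rejected(self):
        _, truth = rs.simulate_respiration(rs.BreathTemplateParams(), 60, 100, seed=0)
        shortest = (truth["rise_s"] + truth["decay_s"] + truth["pause_s"]).min()
        gt = rs.CouplingGroundTruth(beta_true=0.3, lag_s=shortest + 0.1)
        with pytest.raises(rs.ConfigurationError):
            rs.simulate_coupled_lfp(truth, gt, fs=100, seed=0)

    def test_empty_truth_rejected(self):
        gt = rs.CouplingGroundTruth()
        with pytest.raises(rs.InvalidArgumentError):
            rs.simulate_coupled_lfp(pd.DataFrame(), gt, fs=100, seed=0)

    def test_noise_df_must_give_finite_variance(self):
        with pytest.raises(rs.InvalidArgumentError):
            rs.CouplingGroundTruth(noise_df=2.0)


class TestGenerateDataset:
    def test_manifest_counts_recordings(self):
        config = rs.DatasetConfig(n_subjects=1, n_coupled=1, n_uncoupled=1,
                                  duration_s=60, fs=100)
        ds = rs.generate_dataset(config, seed=0)
        assert len(ds.recordings) == 3
        assert len(ds.manifest) == 3
        assert set(ds.manifest["role"]) == {"respiration", "coupled", "uncoupled"}

    def test_same_seed_reproduces_dataset(self):
        config = rs.DatasetConfig(n_subjects=2, duration_s=60, fs=100,
                                  modalities=("airflow", "belt"))
        a = rs.generate_dataset(config, seed=5)
        b = rs.generate_dataset(config, seed=5)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        for ra, rb in zip(a.recordings, b.recordings):
            assert np.array_equal(ra.samples, rb.samples)

    def test_adding_channels_preserves_existing_streams(self):
        base = rs.DatasetConfig(n_subjects=1, n_coupled=1, n_uncoupled=0,
                                duration_s=60, fs=100)
        more = rs.DatasetConfig(n_subjects=1, n_coupled=2, n_uncoupled=0,
                                duration_s=60, fs=100)
        a = rs.generate_dataset(base, seed=5)
        b = rs.generate_dataset(more, seed=5)
        assert np.array_equal(a.get("s00", "lfp00").samples,
                              b.get("s00", "lfp00").samples)

    def test_belt_shares_breath_timing_with_airflow(self):
        config = rs.DatasetConfig(n_subjects=1, duration_s=120, fs=100,
                                  modalities=("airflow", "belt"))
        ds = rs.generate_dataset(config, seed=1)
        ta = ds.resp_truths[("s00", "airflow")]
        tb = ds.resp_truths[("s00", "belt")]
        n = min(len(ta), len(tb))
        # quantizing decay+pause jointly shifts the grid by <= 2 samples
        assert np.allclose(ta["t_peak_s"][:n], tb["t_peak_s"][:n], atol=0.02)
        # belt absorbs the pause into the decay
        assert (tb["pause_s"] == 0).all()

    def test_contradictory_config_rejected(self):
        with pytest.raises(rs.ConfigurationError):
            rs.DatasetConfig(n_coupled=0, n_uncoupled=0)
        with pytest.raises(rs.ConfigurationError):
            rs.DatasetConfig(n_subjects=0)
        with pytest.raises(rs.ConfigurationError):
            rs.DatasetConfig(modalities=())

    def test_save_round_trip(self, tmp_path, coupled_dataset):
        coupled_dataset.save(tmp_path)
        rec = rs.Recording.from_delimited(tmp_path / "s00_airflow.tsv")
        orig = coupled_dataset.get("s00", "airflow")
        assert rec.fs == orig.fs
        assert rec.modality == "airflow"
        assert np.allclose(rec.samples, orig.samples, atol=1e-6)
        assert (tmp_path / "manifest.json").exists()


class TestNoiseScale:
    def test_auto_noise_scale_gives_unit_variance(self):
        gt = rs.CouplingGroundTruth(beta_true=0.3, noise_df=5.0)
        s = gt.effective_noise_scale()
        assert np.isclose(0.3 ** 2 + s ** 2 * 5.0 / 3.0, 1.0)

    def test_p_positive_decreases_with_noise_scale(self):
        """Attenuation: larger feature noise pulls P(beta>0) toward 0.5."""
        from conftest import truth_cycle_frame

        mean_p = []
        for noise in (1.0, 3.0, 8.0):
            ps = []
            for rep in range(10):
                rows = truth_cycle_frame(beta=0.3, n_subjects=4,
                                         cycles_per_subject=75,
                                         seed=rep + 1, noise_scale=noise)
                design = rs.build_design(rows, "rise_time_s")
                res = rs.fit_coupling_model(design, chains=1, iterations=500,
                                            warmup=250, seed=rep)
                ps.append(res.p_positive)
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[1] > mean_p[2]
        assert mean_p[2] > 0.4  # approaching, not crossing, 0.5
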