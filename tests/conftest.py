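"""Shared fixtures: small synthetic recordings reused across test modules."""

import warnings

import numpy as np
import pandas as pd
import pytest

import respshape as rs

warnings.filterwarnings("ignore", message="MCMC may not have converged")


@pytest.fixture(scope="session")
def default_resp():
    """300 s airflow trace at 100 Hz with the default breath template."""
    rec, truth = rs.simulate_respiration(
        rs.BreathTemplateParams(), duration_s=300, fs=100, seed=7)
    return rec, truth


@pytest.fixture(scope="session")
def default_band(default_resp):
    rec, _ = default_resp
    return rs.breathing_band_for(rec)


@pytest.fixture(scope="session")
def coupled_dataset():
    """One subject, one coupled + one uncoupled channel, 300 s at 100 Hz."""
    config = rs.DatasetConfig(n_subjects=1, duration_s=300, fs=100,
                              n_coupled=1, n_uncoupled=1)
    return rs.generate_dataset(config, seed=3)


def truth_cycle_frame(beta: float, n_subjects: int, cycles_per_subject: int,
                      seed: int, noise_scale: float | None = None,
                      noise_df: float = 5.0) -> pd.DataFrame:
    """Cycle table built directly from generator truth tables (no signals).

    Gives the coupling model noiseless-measurement inputs: resp features from
    the drawn breath cycles, neural features from the coupled draws.
    """
    frames = []
    gt = rs.CouplingGroundTruth(beta_true=beta, noise_df=noise_df,
                                noise_scale=noise_scale, lag_s=0.3)
    duration = cycles_per_subject * 4.2 + 30
    for s in range(n_subjects):
        subject = f"s{s:02d}"
        _, truth = rs.simulate_respiration(
            rs.BreathTemplateParams(), duration_s=duration, fs=100,
            seed=seed * 1000 + s, subject_id=subject)
        _, ntruth = rs.simulate_coupled_lfp(
            truth, gt, fs=100, seed=seed * 1000 + s, background_amp=0.0,
            subject_id=subject, channel_id="lfp00")
        merged = truth.merge(ntruth, on="cycle", suffixes=("_r", "_n"))
        merged = merged.iloc[:cycles_per_subject]
        frames.append(pd.DataFrame({
            "subject_id": subject, "channel_id": "lfp00",
            "resp_rise_time_s": merged["rise_s_r"].to_numpy(),
            "neural_rise_time_s": merged["rise_s_n"].to_numpy(),
            "resp_amplitude": merged["amplitude_r"].to_numpy(),
            "neural_amplitude": merged["amplitude_n"].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
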