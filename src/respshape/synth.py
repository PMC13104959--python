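"""Synthetic respiration and LFP generator with known ground-truth coupling.

Every downstream stage of the pipeline (screening, cycle matching, waveform
features, the hierarchical coupling model) is exercised against data from this
module, because the recordings the method was designed for are clinical and
not redistributable. The generator emulates the aspects of real data the
pipeline is sensitive to:

* asymmetric breaths -- independent rise and decay durations per cycle, a flat
  post-expiratory pause, amplitude jitter (all log-jittered around their means
  and truncated to physiological minima);
* two respiration sensor morphologies: nasal *airflow* (sharp cycles with a
  flat pause) and a respiration *belt* (same breath timing, but the pause is
  absorbed into a slower chest-recoil decay and the waveform is low-pass
  smoothed -- belts miss the post-expiratory pause and blunt sharpness);
* neural channels whose per-cycle shape features (rise, decay, amplitude)
  track the matched breath's features with a configurable standardized slope
  ``beta_true`` plus Student-t noise, rendered as oscillatory cycles delayed by
  ``lag_s`` and superimposed on 1/f aperiodic background activity;
* uncoupled control channels (``beta_true = 0`` rendering, or pure background).

Breath cycles are rendered from half-period raised-cosine segments: monotone
and smooth on both flanks, with an analytically known single extremum per
cycle.

Reproducibility: one global integer seed drives named substreams (one per
subject x stream), so adding channels to a configuration does not perturb the
channels that already existed.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import ConfigurationError, InvalidArgumentError
from .recording import Recording

#: shortest admissible rise/decay segment, seconds
MIN_SEGMENT_S = 0.2
#: belt low-pass cutoff, Hz (chest-wall smoothing)
BELT_SMOOTH_HZ = 1.0

TRUTH_COLUMNS = [
    "cycle", "t_trough_s", "t_peak_s", "t_trough_next_s",
    "rise_s", "decay_s", "pause_s", "amplitude", "period_s",
]


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named, collision-resistant random substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# --------------------------------------------------------------------------
# parameter containers


@dataclass
class BreathTemplateParams:
    """Per-cycle breath morphology distribution.

    Defaults describe resting adult breathing near 0.25 Hz: inhale ~1.4 s,
    exhale ~1.8 s, post-expiratory pause ~0.8 s, with moderate cycle-to-cycle
    jitter. Units are seconds except amplitude (arbitrary sensor units).
    """

    mean_rise_s: float = 1.4
    mean_decay_s: float = 1.8
    rise_jitter_sd: float = 0.2
    decay_jitter_sd: float = 0.25
    pause_mean_s: float = 0.8
    pause_jitter_sd: float = 0.3
    amplitude_mean: float = 1.0
    amplitude_jitter_sd: float = 0.15
    modality: str = "airflow"
    sensor_noise_sd: float = 0.005

    def __post_init__(self) -> None:
        for name in ("mean_rise_s", "mean_decay_s", "amplitude_mean"):
            if not getattr(self, name) > 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        for name in ("rise_jitter_sd", "decay_jitter_sd", "pause_jitter_sd",
                     "amplitude_jitter_sd", "pause_mean_s", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")
        if self.modality not in ("airflow", "belt"):
            raise InvalidArgumentError("modality must be 'airflow' or 'belt'")

    @property
    def mean_period_s(self) -> float:
        return self.mean_rise_s + self.mean_decay_s + self.pause_mean_s


@dataclass
class CouplingGroundTruth:
    """Ground-truth respiration->neural shape coupling for one dataset.

    ``beta_true`` is the standardized within-subject slope: per cycle, the
    standardized neural feature is ``beta_true * z_resp + noise`` with
    Student-t noise (``noise_df`` degrees of freedom). When ``noise_scale`` is
    None (the default) the noise scale is set so the standardized neural
    feature has unit variance, making ``beta_true`` exactly the standardized
    slope the coupling model estimates; an explicit ``noise_scale`` (in
    pooled-SD units) overrides this.
    """

    beta_true: float = 0.3
    noise_df: float = 5.0
    noise_scale: float | None = None
    coupled_channel_ids: tuple[str, ...] = ()
    lag_s: float = 0.3

    def __post_init__(self) -> None:
        if not self.noise_df > 2:
            raise InvalidArgumentError("noise_df must be > 2 (finite variance)")
        if self.lag_s < 0:
            raise InvalidArgumentError("lag_s must be >= 0")
        if self.noise_scale is None and abs(self.beta_true) > 1:
            raise InvalidArgumentError(
                "auto noise_scale requires |beta_true| <= 1")
        if self.noise_scale is not None and self.noise_scale < 0:
            raise InvalidArgumentError("noise_scale must be >= 0")

    def effective_noise_scale(self) -> float:
        """Noise scale actually used; 'auto' yields Var(beta*z + eps) = 1."""
        if self.noise_scale is not None:
            return float(self.noise_scale)
        # Student-t(df) variance is df/(df-2); solve s^2 * df/(df-2) = 1-beta^2
        return float(np.sqrt((1.0 - self.beta_true ** 2)
                             * (self.noise_df - 2.0) / self.noise_df))


# --------------------------------------------------------------------------
# respiration


def _draw_cycles(params: BreathTemplateParams, duration_s: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-cycle (rise, decay, pause, amplitude) until duration is filled."""
    rows = []
    t = 0.0
    # generous upper bound on cycle count
    max_cycles = int(duration_s / MIN_SEGMENT_S) + 2
    for _ in range(max_cycles):
        rise = max(MIN_SEGMENT_S,
                   rng.normal(params.mean_rise_s, params.rise_jitter_sd))
        decay = max(MIN_SEGMENT_S,
                    rng.normal(params.mean_decay_s, params.decay_jitter_sd))
        pause = max(0.0, rng.normal(params.pause_mean_s, params.pause_jitter_sd))
        amp = max(0.05 * params.amplitude_mean,
                  rng.normal(params.amplitude_mean, params.amplitude_jitter_sd))
        if t + rise + decay + pause > duration_s:
            break
        rows.append((rise, decay, pause, amp))
        t += rise + decay + pause
    return pd.DataFrame(rows, columns=["rise_s", "decay_s", "pause_s", "amplitude"])


def _raised_cosine_rise(n: int, amplitude: float) -> np.ndarray:
    """Monotone trough->peak half-cycle; sample 0 is the trough, peak is at n."""
    k = np.arange(n)
    return amplitude * 0.5 * (1.0 - np.cos(np.pi * k / n))


def _raised_cosine_decay(n: int, amplitude: float) -> np.ndarray:
    """Monotone peak->trough half-cycle; sample 0 is the peak."""
    k = np.arange(n)
    return amplitude * 0.5 * (1.0 + np.cos(np.pi * k / n))


def _render_respiration(cycles: pd.DataFrame, duration_s: float, fs: float,
                        modality: str) -> tuple[np.ndarray, pd.DataFrame]:
    """Render drawn cycles into samples; returns (signal, truth table).

    Segment durations are quantized to the sample grid and the truth table
    reports the quantized values, so truth and rendered signal agree exactly.
    For the belt modality the pause is absorbed into the decay (belts miss the
    post-expiratory pause) and the rendered trace is low-pass smoothed.
    """
    n_total = int(round(duration_s * fs))
    out = np.zeros(n_total)
    rows = []
    pos = 0
    for i, cyc in enumerate(cycles.itertuples(index=False)):
        if modality == "belt":
            rise_s, decay_s, pause_s = cyc.rise_s, cyc.decay_s + cyc.pause_s, 0.0
        else:
            rise_s, decay_s, pause_s = cyc.rise_s, cyc.decay_s, cyc.pause_s
        n_r = max(int(round(MIN_SEGMENT_S * fs)), int(round(rise_s * fs)))
        n_d = max(int(round(MIN_SEGMENT_S * fs)), int(round(decay_s * fs)))
        n_p = int(round(pause_s * fs))
        if pos + n_r + n_d + n_p > n_total:
            break
        out[pos:pos + n_r] = _raised_cosine_rise(n_r, cyc.amplitude)
        out[pos + n_r:pos + n_r + n_d] = _raised_cosine_decay(n_d, cyc.amplitude)
        # pause stays at baseline 0
        rows.append((i, pos / fs, (pos + n_r) / fs, (pos + n_r + n_d) / fs,
                     n_r / fs, n_d / fs, n_p / fs, cyc.amplitude,
                     (n_r + n_d) / fs))
        pos += n_r + n_d + n_p
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if modality == "belt" and len(truth):
        numtaps = int(3.3 * fs / BELT_SMOOTH_HZ)
        numtaps += 1 - numtaps % 2
        if numtaps >= 3 and 3 * numtaps < n_total:
            b = sps.firwin(numtaps, BELT_SMOOTH_HZ, fs=fs)
            out = sps.filtfilt(b, [1.0], out)
    return out, truth


def simulate_respiration(
    params: BreathTemplateParams,
    duration_s: float,
    fs: float,
    seed: int,
    subject_id: str = "s00",
    channel_id: str | None = None,
) -> tuple[Recording, pd.DataFrame]:
    """Simulate one respiration trace plus its per-cycle truth table.

    Returns ``(recording, truth)`` where ``truth`` has one row per fully
    rendered breath with the realized (sample-quantized) rise, decay, pause
    and amplitude. The same seed reproduces the signal sample-exactly.
    """
    if not duration_s > 0 or not fs > 0:
        raise InvalidArgumentError("duration_s and fs must be positive")
    if duration_s < 30:
        raise InvalidArgumentError("duration_s must be >= 30 s")
    if fs < 100:
        raise InvalidArgumentError("fs must be >= 100 Hz")
    rng = substream_rng(seed, f"{subject_id}/resp/{params.modality}")
    cycles = _draw_cycles(params, duration_s, rng)
    x, truth = _render_respiration(cycles, duration_s, fs, params.modality)
    if params.sensor_noise_sd > 0:
        x = x + rng.normal(0.0, params.sensor_noise_sd, x.size)
    rec = Recording(samples=x, fs=fs, subject_id=subject_id,
                    channel_id=channel_id or params.modality,
                    modality=params.modality)
    return rec, truth


# --------------------------------------------------------------------------
# neural


def colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent (power) noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_coupled_lfp(
    resp_truth: pd.DataFrame,
    truth: CouplingGroundTruth,
    fs: float,
    seed: int,
    background_exponent: float = 1.0,
    background_amp: float = 0.2,
    duration_s: float | None = None,
    subject_id: str = "s00",
    channel_id: str = "lfp00",
    polarity: int = 1,
) -> tuple[Recording, pd.DataFrame]:
    """Render a neural channel whose cycle shapes track the breath cycles.

    For each breath, the standardized neural rise, decay and amplitude equal
    ``beta_true * z_resp + StudentT(noise_df) * noise_scale``; the neural
    oscillation cycle is rendered from raised-cosine flanks with its peak
    delayed ``lag_s`` after the respiration peak, and summed with
    ``1/f^background_exponent`` noise of relative amplitude
    ``background_amp`` (in units of the oscillation SD).

    Returns the recording plus a per-cycle neural truth table (same layout as
    the respiration truth table).
    """
    if resp_truth is None or len(resp_truth) == 0:
        raise InvalidArgumentError("resp_truth must be non-empty")
    periods = resp_truth["rise_s"] + resp_truth["decay_s"] + resp_truth["pause_s"]
    if truth.lag_s >= periods.min():
        raise ConfigurationError(
            f"lag_s={truth.lag_s} >= shortest respiration period {periods.min():.3f}")
    rng = substream_rng(seed, f"{subject_id}/lfp/{channel_id}")
    s = truth.effective_noise_scale()
    beta = truth.beta_true

    feats = {}
    for name, col in (("rise", "rise_s"), ("decay", "decay_s"),
                      ("amp", "amplitude")):
        z_r = _standardize(resp_truth[col].to_numpy())
        eps = rng.standard_t(truth.noise_df, size=len(z_r)) * s
        z_n = beta * z_r + eps
        mu, sd = resp_truth[col].mean(), resp_truth[col].std(ddof=0)
        feats[name] = mu + z_n * sd
    n_rise = np.maximum(MIN_SEGMENT_S, feats["rise"])
    n_decay = np.maximum(MIN_SEGMENT_S, feats["decay"])
    n_amp = np.maximum(0.05 * resp_truth["amplitude"].mean(), feats["amp"])

    if duration_s is None:
        last = resp_truth.iloc[-1]
        duration_s = last["t_trough_next_s"] + last["pause_s"]
    n_total = int(round(duration_s * fs))
    # Render a *continuous* oscillation: the trough after cycle i is the
    # trough before cycle i+1, as in a respiration-entrained LFP. The rise
    # duration and amplitude of each cycle carry the designed coupling
    # exactly; the decay runs from each peak to the next cycle's rise onset
    # (so decay/duration inherit coupling through the breath timing), and the
    # drawn decay is used only for the final cycle.
    peak_idx = np.round((resp_truth["t_peak_s"].to_numpy() + truth.lag_s) * fs
                        ).astype(int)
    min_seg = max(2, int(round(MIN_SEGMENT_S * fs)))
    osc = np.zeros(n_total)
    rows = []
    for i, (npk, r, d, a) in enumerate(zip(peak_idx, n_rise, n_decay, n_amp)):
        n_r = max(min_seg, int(round(r * fs)))
        if i + 1 < peak_idx.size:
            next_rise = max(min_seg, int(round(n_rise[i + 1] * fs)))
            n_d = (peak_idx[i + 1] - next_rise) - npk
            if n_d < min_seg:  # overlapping cycles; shorten deterministically
                n_d = min_seg
        else:
            n_d = max(min_seg, int(round(d * fs)))
        lo, hi = npk - n_r, npk + n_d
        seg = np.concatenate([_raised_cosine_rise(n_r, a),
                              _raised_cosine_decay(n_d, a)])
        clip_lo, clip_hi = max(lo, 0), min(hi, n_total)
        if clip_hi <= clip_lo:
            continue
        osc[clip_lo:clip_hi] += seg[clip_lo - lo:clip_hi - lo]
        rows.append((i, (npk - n_r) / fs, npk / fs, (npk + n_d) / fs,
                     n_r / fs, n_d / fs, 0.0, a, (n_r + n_d) / fs))
    neural_truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    x = polarity * osc
    if background_amp > 0:
        bg = colored_noise(n_total, background_exponent, rng)
        ref = osc.std() if osc.std() > 0 else 1.0
        x = x + background_amp * ref * bg
    rec = Recording(samples=x, fs=fs, subject_id=subject_id,
                    channel_id=channel_id, modality="neural")
    return rec, neural_truth


def simulate_uncoupled_lfp(
    duration_s: float,
    fs: float,
    seed: int,
    background_exponent: float = 1.0,
    subject_id: str = "s00",
    channel_id: str = "lfp00",
) -> Recording:
    """A control channel statistically independent of respiration.

    Pure 1/f^exponent aperiodic background with no respiration-locked
    oscillation: such channels must fail the coherence screen. (Channels
    that are respiration-locked but carry no *shape* coupling are instead
    generated with ``beta_true = 0`` in :func:`simulate_coupled_lfp`.)
    """
    rng = substream_rng(seed, f"{subject_id}/lfp/{channel_id}")
    x = colored_noise(int(round(duration_s * fs)), background_exponent, rng)
    return Recording(samples=x, fs=fs, subject_id=subject_id,
                     channel_id=channel_id, modality="neural")


# --------------------------------------------------------------------------
# dataset


@dataclass
class DatasetConfig:
    """Study-conditions configuration for a full synthetic dataset."""

    n_subjects: int = 1
    duration_s: float = 300.0
    fs: float = 100.0
    modalities: tuple[str, ...] = ("airflow",)
    n_coupled: int = 1
    n_uncoupled: int = 1
    template: BreathTemplateParams = field(default_factory=BreathTemplateParams)
    coupling: CouplingGroundTruth = field(default_factory=CouplingGroundTruth)
    background_exponent: float = 1.0
    background_amp: float = 0.2

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("need >= 1 subject")
        if not self.modalities:
            raise ConfigurationError("need >= 1 respiration modality")
        if self.n_coupled < 0 or self.n_uncoupled < 0:
            raise ConfigurationError("channel counts must be >= 0")
        if self.n_coupled + self.n_uncoupled < 1:
            raise ConfigurationError("need >= 1 neural channel")
        for m in self.modalities:
            if m not in ("airflow", "belt"):
                raise ConfigurationError(f"unknown modality {m!r}")


@dataclass
class SyntheticDataset:
    config: DatasetConfig
    seed: int
    recordings: list[Recording]
    manifest: pd.DataFrame
    resp_truths: dict[tuple[str, str], pd.DataFrame]
    neural_truths: dict[tuple[str, str], pd.DataFrame]

    def get(self, subject_id: str, channel_id: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.channel_id == channel_id:
                return rec
        raise KeyError((subject_id, channel_id))

    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.recordings})

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        for rec in self.recordings:
            rec.to_delimited(os.path.join(
                directory, f"{rec.subject_id}_{rec.channel_id}.tsv"))
        manifest = {
            "seed": self.seed,
            "config": _config_to_jsonable(self.config),
            "recordings": self.manifest.to_dict(orient="records"),
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)


def _config_to_jsonable(config: DatasetConfig) -> dict:
    d = asdict(config)
    d["modalities"] = list(config.modalities)
    d["coupling"]["coupled_channel_ids"] = list(
        config.coupling.coupled_channel_ids)
    return d


def generate_dataset(config: DatasetConfig, seed: int) -> SyntheticDataset:
    """Generate all recordings for one study configuration.

    Per subject: one respiration trace per configured modality (rendered from
    the *same* drawn breath cycles, so airflow and belt describe the same
    breaths), ``n_coupled`` neural channels coupled to the breath truth with
    ``config.coupling.beta_true``, and ``n_uncoupled`` channels rendered by
    the same generator with beta 0.
    """
    recordings: list[Recording] = []
    manifest_rows = []
    resp_truths: dict[tuple[str, str], pd.DataFrame] = {}
    neural_truths: dict[tuple[str, str], pd.DataFrame] = {}

    for si in range(config.n_subjects):
        subject = f"s{si:02d}"
        rng = substream_rng(seed, f"{subject}/cycles")
        cycles = _draw_cycles(config.template, config.duration_s, rng)
        primary_truth = None
        for modality in config.modalities:
            x, truth = _render_respiration(
                cycles, config.duration_s, config.fs, modality)
            if config.template.sensor_noise_sd > 0:
                noise_rng = substream_rng(seed, f"{subject}/sensor/{modality}")
                x = x + noise_rng.normal(
                    0.0, config.template.sensor_noise_sd, x.size)
            rec = Recording(samples=x, fs=config.fs, subject_id=subject,
                            channel_id=modality, modality=modality)
            recordings.append(rec)
            resp_truths[(subject, modality)] = truth
            manifest_rows.append(dict(
                subject_id=subject, channel_id=modality, modality=modality,
                role="respiration", beta_true=np.nan))
            if primary_truth is None:
                primary_truth = truth
        for ci in range(config.n_coupled + config.n_uncoupled):
            coupled = ci < config.n_coupled
            channel = f"lfp{ci:02d}"
            if coupled:
                rec, ntruth = simulate_coupled_lfp(
                    primary_truth, config.coupling, config.fs, seed,
                    background_exponent=config.background_exponent,
                    background_amp=config.background_amp,
                    duration_s=config.duration_s,
                    subject_id=subject, channel_id=channel)
                neural_truths[(subject, channel)] = ntruth
            else:
                rec = simulate_uncoupled_lfp(
                    config.duration_s, config.fs, seed,
                    background_exponent=config.background_exponent,
                    subject_id=subject, channel_id=channel)
            manifest_rows.append(dict(
                subject_id=subject, channel_id=channel, modality="neural",
                role="coupled" if coupled else "uncoupled",
                beta_true=config.coupling.beta_true if coupled else np.nan))
            recordings.append(rec)
    manifest = pd.DataFrame(manifest_rows)
    return SyntheticDataset(config=config, seed=seed, recordings=recordings,
                            manifest=manifest, resp_truths=resp_truths,
                            neural_truths=neural_truths)
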