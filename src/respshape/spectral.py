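"""Spectral screening: breathing band, coherence, surrogate significance.

Per participant, the dominant breathing frequency is the center of the
highest-amplitude periodic peak of the respiration power spectrum (Welch,
40 s Hanning windows, 20 s overlap -> ~0.025 Hz resolution), with a fixed
0.2 Hz analysis band around it and period tau = 1/f_resp.

Neural channels are retained when (i) their magnitude-squared coherence with
respiration, computed on 32 s segments with 27 s overlap (1/32 = 0.03 Hz
resolution), exceeds -- at its maximum inside the breathing band -- the 99th
percentile of the same statistic for phase-randomized surrogate channels, and
(ii) the neural spectrum itself has a periodic peak inside the band. The dual
criterion guards against coherence driven purely by harmonics of a
nonsinusoidal rhythm with no fundamental neural peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidArgumentError, NoBreathingPeakError
from .recording import Recording
from .specfit import SpectrumModel, fit_spectrum


class PSD(NamedTuple):
    freqs: np.ndarray
    power: np.ndarray


class CoherenceSpectrum(NamedTuple):
    freqs: np.ndarray
    coh: np.ndarray


@dataclass
class BreathingBand:
    """Participant's dominant breathing frequency and its analysis band."""

    f_resp: float
    band_lo: float
    band_hi: float
    tau: float

    @classmethod
    def from_frequency(cls, f_resp: float, half_width: float = 0.1) -> "BreathingBand":
        if not 0.05 <= f_resp <= 1.0:
            raise InvalidArgumentError(
                f"breathing frequency {f_resp:.3f} Hz outside [0.05, 1] Hz")
        return cls(f_resp=f_resp, band_lo=f_resp - half_width,
                   band_hi=f_resp + half_width, tau=1.0 / f_resp)


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coh: np.ndarray
    max_coh_in_band: float
    surrogate_threshold: float | None = None
    has_psd_peak_in_band: bool | None = None
    passes: bool | None = None
    band: BreathingBand | None = None
    neural_spectrum: SpectrumModel | None = None


def welch_psd(rec: Recording, window_s: float = 40.0,
              overlap_s: float = 20.0) -> PSD:
    """Welch power spectral density with a Hanning taper.

    The frequency grid spacing is 1/window_s (0.025 Hz at the default 40 s).
    """
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < nperseg:
        raise InvalidArgumentError(
            f"recording ({rec.duration_s:.0f} s) shorter than one "
            f"{window_s:.0f} s window")
    freqs, power = sps.welch(rec.samples, fs=rec.fs, window="hann",
                             nperseg=nperseg,
                             noverlap=int(round(overlap_s * rec.fs)),
                             detrend="constant")
    return PSD(freqs=freqs, power=power)


def find_breathing_band(resp_psd: PSD,
                        resp_range: tuple[float, float] = (0.05, 1.0),
                        fit_range: tuple[float, float] = (0.05, 2.0),
                        ) -> BreathingBand:
    """Locate the breathing frequency via spectral parameterization.

    The respiration PSD is decomposed into an aperiodic 1/f-like component
    plus Gaussian periodic peaks; the highest-amplitude peak inside
    ``resp_range`` defines the breathing frequency. Raises
    :class:`NoBreathingPeakError` when no periodic peak is found (such a
    participant is excluded from the analysis).
    """
    if resp_psd.freqs[-1] < fit_range[1]:
        raise InvalidArgumentError(
            f"PSD must cover {fit_range[0]}-{fit_range[1]} Hz")
    model = fit_spectrum(resp_psd.freqs, resp_psd.power, f_range=fit_range)
    peak = model.highest_peak(*resp_range)
    if peak is None:
        raise NoBreathingPeakError(
            "no periodic respiration peak in "
            f"{resp_range[0]}-{resp_range[1]} Hz")
    f_resp = float(np.clip(peak.center_hz, resp_range[0], resp_range[1]))
    return BreathingBand.from_frequency(f_resp)


def _check_pair(x: Recording, y: Recording) -> None:
    if x.fs != y.fs:
        raise InvalidArgumentError("recordings must share a sampling rate")
    if x.n_samples != y.n_samples:
        raise InvalidArgumentError("recordings must share a length")


def coherence(x: Recording, y: Recording, seg_s: float = 32.0,
              overlap_s: float = 27.0) -> CoherenceSpectrum:
    """Magnitude-squared coherence C(f) = |Pxy|^2 / (Pxx Pyy).

    Welch cross- and auto-spectra on ``seg_s`` segments with ``overlap_s``
    overlap (defaults give a 0.03125 Hz grid). Needs at least two segments --
    the coherence of a single segment is identically one.
    """
    _check_pair(x, y)
    nperseg = int(round(seg_s * x.fs))
    noverlap = int(round(overlap_s * x.fs))
    if x.n_samples < 2 * nperseg - noverlap:
        raise InvalidArgumentError(
            "need at least 2 segments for a meaningful coherence")
    freqs, coh = sps.coherence(x.samples, y.samples, fs=x.fs, window="hann",
                               nperseg=nperseg, noverlap=noverlap,
                               detrend="constant")
    return CoherenceSpectrum(freqs=freqs, coh=np.clip(coh, 0.0, 1.0))


def phase_randomized_surrogate(rec: Recording,
                               seed: int | np.random.Generator) -> Recording:
    """Surrogate with the original amplitude spectrum but random phases.

    The DC bin and (for even lengths) the Nyquist bin are left untouched so
    the output is exactly real with an identical amplitude spectrum.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    x = rec.samples
    spec = np.fft.rfft(x)
    n_bins = spec.size
    phases = rng.uniform(0.0, 2.0 * np.pi, n_bins)
    spec_out = np.abs(spec) * np.exp(1j * phases)
    # keep DC and (even length) Nyquist verbatim so the output is exactly real
    spec_out[0] = spec[0]
    if x.size % 2 == 0:
        spec_out[-1] = spec[-1]
    out = np.fft.irfft(spec_out, n=x.size)
    return rec.with_samples(out, note="phase-randomized surrogate")


def _hann_frames(x: np.ndarray, nperseg: int, noverlap: int) -> np.ndarray:
    """rfft of constant-detrended, Hann-tapered Welch segments (segs, bins).

    Mirrors the segmentation used by :func:`scipy.signal.welch`/``csd`` so
    spectra assembled from these frames match ``scipy.signal.coherence``.
    """
    step = nperseg - noverlap
    n_seg = 1 + (x.size - nperseg) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    frames = frames * sps.get_window("hann", nperseg)
    return np.fft.rfft(frames, axis=1)


def _coherence_from_frames(fx: np.ndarray, fy: np.ndarray,
                           pyy: np.ndarray) -> np.ndarray:
    pxx = np.mean(np.abs(fx) ** 2, axis=0)
    pxy = np.mean(fx * np.conj(fy), axis=0)
    denom = pxx * pyy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(pxy) ** 2 / denom
    return np.clip(np.nan_to_num(coh), 0.0, 1.0)


def _phase_randomize_array(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(x)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.size)
    spec_out = np.abs(spec) * np.exp(1j * phases)
    spec_out[0] = spec[0]
    if x.size % 2 == 0:
        spec_out[-1] = spec[-1]
    return np.fft.irfft(spec_out, n=x.size)


def max_coherence_in_band(cs: CoherenceSpectrum, band: BreathingBand) -> float:
    mask = (cs.freqs >= band.band_lo) & (cs.freqs <= band.band_hi)
    if not mask.any():
        raise InvalidArgumentError("breathing band outside coherence grid")
    return float(cs.coh[mask].max())


def coherence_screen(
    neural: Recording,
    resp: Recording,
    band: BreathingBand,
    n_surrogates: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    seg_s: float = 32.0,
    overlap_s: float = 27.0,
    psd_window_s: float = 40.0,
    psd_overlap_s: float = 20.0,
) -> CoherenceResult:
    """Dual-criterion coherence screen for one neural channel.

    passes = (max in-band coherence exceeds the ``1 - alpha`` percentile of
    the max-in-band coherence of ``n_surrogates`` phase-randomized neural
    surrogates against the real respiration) AND (the neural PSD has a
    parameterized periodic peak inside the breathing band).
    """
    real = coherence(neural, resp, seg_s=seg_s, overlap_s=overlap_s)
    max_real = max_coherence_in_band(real, band)

    # surrogate loop on precomputed respiration segment spectra: only the
    # neural side changes, and only in-band bins feed the max statistic
    nperseg = int(round(seg_s * neural.fs))
    noverlap = int(round(overlap_s * neural.fs))
    fy = _hann_frames(resp.samples, nperseg, noverlap)
    pyy = np.mean(np.abs(fy) ** 2, axis=0)
    band_mask = (real.freqs >= band.band_lo) & (real.freqs <= band.band_hi)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_surrogates)
    for i in range(n_surrogates):
        surr = _phase_randomize_array(neural.samples, rng)
        fx = _hann_frames(surr, nperseg, noverlap)
        coh = _coherence_from_frames(fx, fy, pyy)
        null_max[i] = coh[band_mask].max()
    threshold = float(np.percentile(null_max, 100.0 * (1.0 - alpha)))

    npsd = welch_psd(neural, window_s=psd_window_s, overlap_s=psd_overlap_s)
    try:
        spectrum = fit_spectrum(npsd.freqs, npsd.power)
        has_peak = spectrum.has_peak_in(band.band_lo, band.band_hi)
    except InvalidArgumentError:
        spectrum, has_peak = None, False

    return CoherenceResult(
        freqs=real.freqs, coh=real.coh, max_coh_in_band=max_real,
        surrogate_threshold=threshold, has_psd_peak_in_band=has_peak,
        passes=bool(max_real > threshold and has_peak), band=band,
        neural_spectrum=spectrum)
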