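"""Parameterization of power spectra into aperiodic + periodic components.

A Welch power spectrum is modeled in log10 power as a linear aperiodic
component (``offset - exponent * log10(f)``, i.e. 1/f-like, no knee) plus a
small number of Gaussian periodic peaks. The fitting loop follows the
standard iterative approach: robust-fit the aperiodic slope, flatten, pull
out the largest residual peak, repeat, then jointly refine all Gaussians and
re-fit the aperiodic component on the peak-removed spectrum.

Peak detection thresholds combine a relative criterion (2 SD of the flattened
spectrum) with an absolute floor (0.35 log10 units). The floor is set from
the sampling variability of a Welch log-PSD averaged over ~30 segments, for
which the maximum spurious fluctuation across a 0.05-2 Hz grid stays below
~0.3 log10 units with high probability; a genuine respiration or
respiration-entrained peak exceeds one full log10 unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import InvalidArgumentError


@dataclass
class SpectralPeak:
    center_hz: float
    height_log10: float   # height above the aperiodic component
    bandwidth_hz: float   # 2 * gaussian SD


@dataclass
class SpectrumModel:
    freqs: np.ndarray
    log_power: np.ndarray
    aperiodic_offset: float
    aperiodic_exponent: float
    peaks: list[SpectralPeak] = field(default_factory=list)

    def aperiodic(self, freqs: np.ndarray | None = None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs)
        return self.aperiodic_offset - self.aperiodic_exponent * np.log10(f)

    def model(self) -> np.ndarray:
        out = self.aperiodic()
        for p in self.peaks:
            out = out + _gaussian(self.freqs, p.center_hz, p.height_log10,
                                  p.bandwidth_hz / 2.0)
        return out

    def r_squared(self) -> float:
        resid = self.log_power - self.model()
        tot = self.log_power - self.log_power.mean()
        denom = float(tot @ tot)
        return 1.0 - float(resid @ resid) / denom if denom > 0 else 1.0

    def highest_peak(self, lo_hz: float | None = None,
                     hi_hz: float | None = None) -> SpectralPeak | None:
        """Highest-amplitude peak, optionally restricted to [lo_hz, hi_hz]."""
        cands = [p for p in self.peaks
                 if (lo_hz is None or p.center_hz >= lo_hz)
                 and (hi_hz is None or p.center_hz <= hi_hz)]
        return max(cands, key=lambda p: p.height_log10) if cands else None

    def has_peak_in(self, lo_hz: float, hi_hz: float) -> bool:
        return self.highest_peak(lo_hz, hi_hz) is not None


def _gaussian(f: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * sd ** 2))


def _fit_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Robust linear fit in log-log space, down-weighting periodic bumps."""
    slope, offset = np.polyfit(logf, logp, 1)
    for _ in range(2):
        resid = logp - (offset + slope * logf)
        mask = resid <= np.percentile(resid, 60)
        if mask.sum() < 4:
            break
        slope, offset = np.polyfit(logf[mask], logp[mask], 1)
    return offset, -slope


def fit_spectrum(
    freqs: np.ndarray,
    power: np.ndarray,
    f_range: tuple[float, float] = (0.05, 2.0),
    max_n_peaks: int = 4,
    peak_width_limits_hz: tuple[float, float] = (0.02, 0.5),
    peak_threshold_sd: float = 2.0,
    min_peak_height: float = 0.35,
) -> SpectrumModel:
    """Fit aperiodic + Gaussian-peak model to a power spectrum."""
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs >= f_range[0]) & (freqs <= f_range[1]) & (freqs > 0)
    if mask.sum() < 8:
        raise InvalidArgumentError(
            f"spectrum must cover {f_range} with >= 8 bins")
    f = freqs[mask]
    p = power[mask]
    if np.any(p <= 0):
        p = np.maximum(p, np.finfo(float).tiny)
    logp = np.log10(p)
    logf = np.log10(f)

    offset, exponent = _fit_aperiodic(logf, logp)
    flat = logp - (offset - exponent * logf)

    sd_lo, sd_hi = peak_width_limits_hz[0] / 2.0, peak_width_limits_hz[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    work = flat.copy()
    for _ in range(max_n_peaks):
        i = int(np.argmax(work))
        height = work[i]
        thresh = max(peak_threshold_sd * work.std(), min_peak_height)
        if height < thresh:
            break
        # guess SD from the half-height span; use twice the shortest side so
        # a neighbouring harmonic cannot inflate the width
        half = height / 2.0
        li = i
        while li > 0 and work[li] > half:
            li -= 1
        ri = i
        while ri < work.size - 1 and work[ri] > half:
            ri += 1
        df = f[1] - f[0]
        fwhm = max(2.0 * min(f[i] - f[li], f[ri] - f[i]), df)
        sd = float(np.clip(fwhm / 2.355, sd_lo, sd_hi))
        guesses.append((float(f[i]), float(height), sd))
        work = work - _gaussian(f, f[i], height, sd)

    peaks: list[SpectralPeak] = []
    if guesses:
        def multi_gauss(x, *params):
            out = np.zeros_like(x)
            for j in range(0, len(params), 3):
                out = out + _gaussian(x, params[j], params[j + 1], params[j + 2])
            return out

        p0 = [v for g in guesses for v in g]
        lob, hib = [], []
        for c, h, sd in guesses:
            # keep each center near its guess so peaks cannot migrate onto
            # a neighbouring harmonic during the joint refinement
            lob += [max(f[0], c - 2.0 * sd), 0.0, sd_lo]
            hib += [min(f[-1], c + 2.0 * sd), max(2.0 * h, 1e-3), sd_hi]
        try:
            popt, _ = curve_fit(multi_gauss, f, flat, p0=p0,
                                bounds=(lob, hib), maxfev=5000)
        except RuntimeError:
            popt = np.asarray(p0)
        for j in range(0, len(popt), 3):
            peaks.append(SpectralPeak(center_hz=float(popt[j]),
                                      height_log10=float(popt[j + 1]),
                                      bandwidth_hz=float(2.0 * popt[j + 2])))
        # re-fit aperiodic on the peak-removed spectrum
        peak_model = multi_gauss(f, *popt)
        offset, exponent = _fit_aperiodic(logf, logp - peak_model)
    peaks.sort(key=lambda pk: -pk.height_log10)
    return SpectrumModel(freqs=f, log_power=logp, aperiodic_offset=offset,
                         aperiodic_exponent=exponent, peaks=peaks)
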