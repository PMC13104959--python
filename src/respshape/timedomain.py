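"""Time-domain screening: respiration-peak cross-correlation and PMI.

Channels surviving the coherence screen are kept only when their waveform
demonstrably tracks respiration in the time domain:

* **Mean cross-correlation.** Band-passed, z-scored signals are epoched on
  respiration peaks (window = one mean breath period, centered, so the
  inhale peak and exhale trough both fall inside), each epoch's normalized
  cross-correlation function (CCF) is averaged across epochs, lags are
  restricted to half a respiration cycle, and the maximum absolute mean CCF
  is compared against a permutation null in which respiration epochs are
  paired with random neural segments drawn outside a 10 s margin around the
  original window. Channel polarity (arbitrary after bipolar referencing) is
  flipped when the extremal mean CCF is negative.

* **Phase monotonicity index (PMI).** Per respiration cycle the neural
  signal is split into the rising (trough->peak) and falling (peak->trough)
  phase; within each phase the fraction of consecutive sample-to-sample
  differences that are directionally consistent is computed, the cycle PMI
  is the unweighted mean of the two fractions, and the channel PMI is the
  median over cycles. Significance comes from circularly shifting the neural
  signal by random offsets of at least 10 s. Ties (zero differences) count
  as inconsistent in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

from .cycles import ExtremaSequence
from .exceptions import (
    EmptyEpochsError,
    InsufficientDataError,
    InvalidArgumentError,
    MarginTooLargeError,
)
from .recording import Recording


@dataclass
class Epochs:
    """Respiration-peak-centered paired epochs on a shared sample grid."""

    neural: np.ndarray        # (n_epochs, n_samples)
    resp: np.ndarray          # (n_epochs, n_samples)
    peak_times: np.ndarray    # seconds
    starts: np.ndarray        # start sample of each epoch in the recording
    fs: float

    @property
    def n_epochs(self) -> int:
        return self.neural.shape[0]

    @property
    def n_samples(self) -> int:
        return self.neural.shape[1]


@dataclass
class CCFResult:
    lags: np.ndarray          # seconds, |lag| <= tau/2
    mean_ccf: np.ndarray
    max_abs: float
    lag_at_max: float
    polarity: int             # -1 iff the extremal mean CCF value is negative
    null_threshold: float | None = None
    passes: bool | None = None


@dataclass
class PMIResult:
    per_cycle_pmi: np.ndarray
    channel_pmi: float
    rising_fraction: float    # median rising-phase consistency, for reference
    falling_fraction: float
    null_threshold: float | None = None
    passes: bool | None = None


def epoch_on_respiration_peaks(neural: Recording, resp: Recording,
                               resp_peak_times: np.ndarray,
                               window_s: float) -> Epochs:
    """Cut paired epochs of length ``window_s`` centered on each peak.

    Epochs truncated by the recording edges are dropped; both signals share
    the sample grid.
    """
    if neural.fs != resp.fs or neural.n_samples != resp.n_samples:
        raise InvalidArgumentError("neural and resp must share fs and length")
    fs = neural.fs
    n_win = int(round(window_s * fs))
    if n_win < 2:
        raise InvalidArgumentError("window too short")
    half = n_win // 2
    n = neural.n_samples
    neural_rows, resp_rows, kept_peaks, starts = [], [], [], []
    for t in np.sort(np.asarray(resp_peak_times, dtype=float)):
        ip = int(round(t * fs))
        lo = ip - half
        if lo < 0 or lo + n_win > n:
            continue
        neural_rows.append(neural.samples[lo:lo + n_win])
        resp_rows.append(resp.samples[lo:lo + n_win])
        kept_peaks.append(t)
        starts.append(lo)
    if not neural_rows:
        raise EmptyEpochsError("no usable respiration-peak epochs")
    return Epochs(neural=np.asarray(neural_rows), resp=np.asarray(resp_rows),
                  peak_times=np.asarray(kept_peaks),
                  starts=np.asarray(starts, dtype=int), fs=fs)


def _normalized_mean_ccf(neural_mat: np.ndarray, resp_mat: np.ndarray,
                         fs: float, tau: float,
                         resp_spec: np.ndarray | None = None,
                         nfft: int | None = None,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Epoch-averaged Pearson-normalized CCF, lags clipped to |lag| <= tau/2.

    ``resp_spec``/``nfft`` let permutation callers reuse the FFT of the
    (fixed) respiration epochs.
    """
    n = neural_mat.shape[1]
    if nfft is None:
        nfft = next_fast_len(2 * n - 1)
    a = neural_mat - neural_mat.mean(axis=1, keepdims=True)
    b = resp_mat - resp_mat.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    good = (na > 0) & (nb > 0)
    if not good.any():
        raise InsufficientDataError("all epochs are constant")
    if resp_spec is None:
        resp_spec = np.fft.rfft(b, nfft, axis=1)
    # correlate(a, b)[l] = sum_t a[t] b[t-l]; via FFT of a and conj FFT of b
    corr = np.fft.irfft(np.fft.rfft(a, nfft, axis=1) * np.conj(resp_spec),
                        nfft, axis=1)
    # arrange lags -(n-1) .. (n-1)
    corr = np.concatenate([corr[:, -(n - 1):], corr[:, :n]], axis=1)
    corr = corr[good] / (na[good] * nb[good])[:, None]
    lags = np.arange(-(n - 1), n) / fs
    mean = corr.mean(axis=0)
    keep = np.abs(lags) <= tau / 2.0
    return lags[keep], mean[keep]


def mean_ccf(epochs: Epochs, tau: float) -> CCFResult:
    """Mean normalized CCF across epochs with half-cycle lag restriction."""
    if epochs.n_epochs < 5:
        raise InsufficientDataError(
            f"mean CCF needs >= 5 epochs, got {epochs.n_epochs}")
    lags, mean = _normalized_mean_ccf(epochs.neural, epochs.resp,
                                      epochs.fs, tau)
    i = int(np.argmax(np.abs(mean)))
    extremal = mean[i]
    return CCFResult(lags=lags, mean_ccf=mean, max_abs=float(abs(extremal)),
                     lag_at_max=float(lags[i]),
                     polarity=-1 if extremal < 0 else 1)


def _legal_start_intervals(n: int, length: int, win_lo: int, win_hi: int,
                           margin: int) -> list[tuple[int, int]]:
    """Half-open intervals of legal segment starts outside window +- margin."""
    out = []
    left_hi = win_lo - margin - length + 1
    if left_hi > 0:
        out.append((0, left_hi))
    right_lo = win_hi + margin
    if right_lo <= n - length:
        out.append((right_lo, n - length + 1))
    return out


def ccf_permutation_null(
    neural: Recording,
    resp: Recording,
    epochs: Epochs,
    tau: float,
    n_perm: int = 500,
    margin_s: float = 10.0,
    alpha: float = 0.01,
    seed: int = 0,
) -> CCFResult:
    """Mean-CCF screen against a shuffled-segment permutation null.

    Each permutation pairs the real respiration epochs with random neural
    segments of equal length drawn outside a ``margin_s`` margin around each
    epoch's own original window, recomputes the mean-CCF maximum absolute
    value, and the threshold is the ``1 - alpha`` percentile of those maxima.
    """
    result = mean_ccf(epochs, tau)
    fs = epochs.fs
    n = neural.n_samples
    length = epochs.n_samples
    margin = int(round(margin_s * fs))

    intervals_per_epoch = []
    for lo in epochs.starts:
        iv = _legal_start_intervals(n, length, lo, lo + length, margin)
        if not iv:
            raise MarginTooLargeError(
                "no legal sampling region outside the margin")
        intervals_per_epoch.append(iv)

    rng = np.random.default_rng(seed)
    nfft = next_fast_len(2 * length - 1)
    b = epochs.resp - epochs.resp.mean(axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1)
    resp_spec = np.conj(np.fft.rfft(b, nfft, axis=1))
    lags = np.arange(-(length - 1), length) / fs
    keep = np.abs(lags) <= tau / 2.0

    # per-epoch legal starts, sampled for all permutations at once
    starts = np.empty((n_perm, epochs.n_epochs), dtype=int)
    for e, iv in enumerate(intervals_per_epoch):
        sizes = np.array([hi - lo for lo, hi in iv])
        cum = np.concatenate([[0], np.cumsum(sizes)])
        u = rng.integers(0, cum[-1], size=n_perm)
        which = np.searchsorted(cum, u, side="right") - 1
        starts[:, e] = np.array([iv[w][0] for w in which]) + (u - cum[which])

    offsets = np.arange(length)
    maxima = np.empty(n_perm)
    chunk = max(1, int(2e7 // (epochs.n_epochs * nfft)))
    for p0 in range(0, n_perm, chunk):
        sl = slice(p0, min(p0 + chunk, n_perm))
        segs = neural.samples[starts[sl, :, None] + offsets]
        segs = segs - segs.mean(axis=2, keepdims=True)
        na = np.linalg.norm(segs, axis=2)
        corr = np.fft.irfft(np.fft.rfft(segs, nfft, axis=2)
                            * resp_spec[None, :, :], nfft, axis=2)
        corr = np.concatenate([corr[:, :, -(length - 1):],
                               corr[:, :, :length]], axis=2)
        denom = np.where(na * nb[None, :] > 0, na * nb[None, :], np.inf)
        mean = (corr / denom[:, :, None]).mean(axis=1)
        maxima[sl] = np.abs(mean[:, keep]).max(axis=1)
    threshold = float(np.percentile(maxima, 100.0 * (1.0 - alpha)))
    result.null_threshold = threshold
    result.passes = bool(result.max_abs > threshold)
    return result


# --------------------------------------------------------------------------
# phase monotonicity index


def _pmi_from_signs(pos: np.ndarray, neg: np.ndarray,
                    bounds: np.ndarray) -> np.ndarray:
    """Per-cycle PMI from precomputed difference-sign arrays.

    ``pos``/``neg`` are indicator arrays over the n-1 sample differences;
    ``bounds`` is (n_cycles, 3) of [trough, peak, trough] sample indices.
    Rising-phase consistency uses differences [i_trough, i_peak); falling
    uses [i_peak, i_trough_next).
    """
    cpos = np.concatenate([[0], np.cumsum(pos)])
    cneg = np.concatenate([[0], np.cumsum(neg)])
    i1, ip, i2 = bounds[:, 0], bounds[:, 1], bounds[:, 2]
    n_rise = ip - i1
    n_fall = i2 - ip
    with np.errstate(invalid="ignore", divide="ignore"):
        # a zero-length phase yields nan for that side
        rising = (cpos[ip] - cpos[i1]) / n_rise
        falling = (cneg[i2] - cneg[ip]) / n_fall
    return 0.5 * (rising + falling), rising, falling


def _cycle_bounds(resp_extrema: ExtremaSequence, fs: float, n: int,
                  min_phase_samples: int = 3) -> np.ndarray:
    bounds = []
    for t1, tp, t2 in resp_extrema.cycles():
        i1, ip, i2 = (int(round(t * fs)) for t in (t1, tp, t2))
        if i1 < 0 or i2 >= n:
            continue
        if ip - i1 < min_phase_samples or i2 - ip < min_phase_samples:
            continue  # phases too short to count differences
        bounds.append((i1, ip, i2))
    return np.asarray(bounds, dtype=int)


def phase_monotonicity_index(
    neural: Recording,
    resp_extrema: ExtremaSequence,
    n_perm: int = 500,
    min_shift_s: float = 10.0,
    alpha: float = 0.01,
    seed: int = 0,
) -> PMIResult:
    """Channel PMI with a circular-shift permutation null.

    Requires at least 10 complete respiration cycles. The null circularly
    shifts the neural signal by offsets drawn uniformly from
    [min_shift_s, duration - min_shift_s], preserving its sample multiset and
    autocorrelation while destroying alignment with respiration.
    """
    x = neural.samples
    fs = neural.fs
    bounds = _cycle_bounds(resp_extrema, fs, x.size)
    if len(resp_extrema.cycles()) < 10:
        raise InsufficientDataError("PMI needs >= 10 complete cycles")
    if bounds.size == 0:
        raise InsufficientDataError("all cycles too short for PMI")

    d = np.diff(x)
    pos = (d > 0).astype(np.int64)
    neg = (d < 0).astype(np.int64)
    per_cycle, rising, falling = _pmi_from_signs(pos, neg, bounds)
    channel = float(np.median(per_cycle))

    lo = int(round(min_shift_s * fs))
    hi = x.size - lo
    if hi <= lo:
        raise MarginTooLargeError("recording too short for min_shift_s")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        k = int(rng.integers(lo, hi))
        xs = np.roll(x, -k)           # shifted signal: xs[t] = x[(t+k) % n]
        ds = np.diff(xs)
        ps = (ds > 0).astype(np.int64)
        ns = (ds < 0).astype(np.int64)
        pc, _, _ = _pmi_from_signs(ps, ns, bounds)
        null[p] = np.median(pc)
    threshold = float(np.percentile(null, 100.0 * (1.0 - alpha)))
    return PMIResult(per_cycle_pmi=per_cycle, channel_pmi=channel,
                     rising_fraction=float(np.median(rising)),
                     falling_fraction=float(np.median(falling)),
                     null_threshold=threshold,
                     passes=bool(channel > threshold))
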