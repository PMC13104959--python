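"""Extrema detection, cycle matching, and waveform-shape features.

A cycle is a trough -> peak -> trough triple. Extrema are detected with a
two-stage adaptive procedure (height + minimum-distance candidates, then a
relative-amplitude refinement and strict peak/trough alternation), artifact
cycles are dropped by robust MAD thresholds on amplitude and within-cycle
RMS, respiration and neural peaks are matched one-to-one with a greedy
nearest-neighbor pass bounded by one respiration period tau, and eight shape
features are computed identically for both signals of each matched pair:

rise time, decay time, cycle duration, rise-decay symmetry (= rise/duration),
inhale-peak and exhale-trough sharpness (mean absolute first derivative in
the full-width-at-half-maximum window around the extremum, normalized by the
cycle's peak-to-trough amplitude), and inhale-peak / exhale-trough AUC
(trapezoidal integral between median-crossing boundaries around the
extremum). Amplitude (peak minus trough level) is carried alongside.

Times are seconds from recording start; windows are half-open [start, end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.stats import median_abs_deviation

from .exceptions import EmptyExtremaError, InsufficientDataError, InvalidArgumentError
from .recording import Recording

PEAK = 1
TROUGH = -1

#: the eight outlier-filtered waveform features (amplitude deliberately not
#: among them)
SHAPE_FEATURES = (
    "rise_time_s", "decay_time_s", "cycle_duration_s", "rise_decay_symmetry",
    "inhale_peak_sharpness", "exhale_trough_sharpness",
    "inhale_peak_auc", "exhale_trough_auc",
)
ALL_FEATURES = SHAPE_FEATURES + ("amplitude",)


@dataclass
class ExtremaSequence:
    """Strictly alternating peak/trough times for one recording."""

    times: np.ndarray          # seconds, strictly increasing
    kinds: np.ndarray          # +1 peak, -1 trough, strictly alternating
    fs: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=int)
        if self.times.size != self.kinds.size:
            raise InvalidArgumentError("times and kinds must match in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if self.times.size > 1 and np.any(np.diff(self.kinds) == 0):
            raise InvalidArgumentError("kinds must strictly alternate")

    @property
    def peak_times(self) -> np.ndarray:
        return self.times[self.kinds == PEAK]

    @property
    def trough_times(self) -> np.ndarray:
        return self.times[self.kinds == TROUGH]

    def cycles(self) -> list[tuple[float, float, float]]:
        """(trough, peak, trough) triples in time order."""
        out = []
        for i in range(self.times.size - 2):
            if (self.kinds[i], self.kinds[i + 1], self.kinds[i + 2]) == \
                    (TROUGH, PEAK, TROUGH):
                out.append((self.times[i], self.times[i + 1], self.times[i + 2]))
        return out

    def restrict(self, t_lo: float, t_hi: float) -> "ExtremaSequence":
        mask = (self.times >= t_lo) & (self.times < t_hi)
        return ExtremaSequence(self.times[mask], self.kinds[mask], self.fs)


def _enforce_alternation(times: np.ndarray, kinds: np.ndarray,
                         values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve runs of same-kind extrema, keeping the more extreme point."""
    keep_t, keep_k = [], []
    i = 0
    n = times.size
    while i < n:
        j = i
        while j + 1 < n and kinds[j + 1] == kinds[i]:
            j += 1
        run = slice(i, j + 1)
        vals = values[run]
        best = (np.argmax(vals) if kinds[i] == PEAK else np.argmin(vals)) + i
        keep_t.append(times[best])
        keep_k.append(kinds[best])
        i = j + 1
    return np.asarray(keep_t), np.asarray(keep_k, dtype=int)


def detect_extrema(
    rec: Recording,
    base_height: float | None = None,
    min_distance_factor: float = 1.5,
    relative_amplitude_frac: float = 0.3,
) -> ExtremaSequence:
    """Two-stage adaptive peak/trough detection.

    Stage 1: candidate peaks above ``base_height`` (default: the signal
    median) separated by at least ``min_distance_factor`` seconds (the
    distance passed to the detector is ``min_distance_factor * fs`` samples);
    troughs identically on the negated signal. Stage 2: extrema whose
    amplitude relative to the baseline falls below
    ``relative_amplitude_frac`` times the median extremum amplitude are
    removed, and alternation is enforced by keeping the more extreme of
    consecutive same-kind extrema.
    """
    if rec.duration_s < 10:
        raise InvalidArgumentError("recording must be >= 10 s")
    x = rec.samples
    base = float(np.median(x)) if base_height is None else float(base_height)
    distance = max(1, int(round(min_distance_factor * rec.fs)))
    peaks, _ = sps.find_peaks(x, height=base, distance=distance)
    troughs, _ = sps.find_peaks(-x, height=-base, distance=distance)

    def refine(idx: np.ndarray, amp: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return idx
        return idx[amp >= relative_amplitude_frac * np.median(amp)]

    peaks = refine(peaks, x[peaks] - base)
    troughs = refine(troughs, base - x[troughs])
    if peaks.size == 0 and troughs.size == 0:
        raise EmptyExtremaError("no extrema detected")

    idx = np.concatenate([peaks, troughs])
    kinds = np.concatenate([np.full(peaks.size, PEAK),
                            np.full(troughs.size, TROUGH)])
    order = np.argsort(idx, kind="stable")
    idx, kinds = idx[order], kinds[order]
    times, kinds = _enforce_alternation(idx / rec.fs, kinds, x[idx])
    if times.size == 0:
        raise EmptyExtremaError("no extrema survive alternation")
    return ExtremaSequence(times=times, kinds=kinds, fs=rec.fs)


def reject_artifact_cycles(extrema: ExtremaSequence, rec: Recording,
                           mad_k: float = 5.0) -> ExtremaSequence:
    """Drop cycles with outlying amplitude or within-cycle RMS.

    Per trough->trough cycle, amplitude (peak minus mean of bounding troughs)
    and the RMS of the demeaned cycle samples are computed; cycles where
    either exceeds median + ``mad_k`` * MAD are removed (strict inequality,
    so a zero-MAD homogeneous set rejects nothing), and alternation is
    re-enforced on the surviving extrema.
    """
    cycles = extrema.cycles()
    if len(cycles) < 5:
        raise InsufficientDataError(
            f"artifact rejection needs >= 5 cycles, got {len(cycles)}")
    x = rec.samples
    fs = rec.fs
    amps, rmss = [], []
    for t1, p, t2 in cycles:
        i1, ip, i2 = (int(round(t * fs)) for t in (t1, p, t2))
        amps.append(x[ip] - 0.5 * (x[i1] + x[i2]))
        seg = x[i1:i2 + 1]
        rmss.append(np.sqrt(np.mean((seg - seg.mean()) ** 2)))
    amps, rmss = np.asarray(amps), np.asarray(rmss)

    def bad(v: np.ndarray) -> np.ndarray:
        return v > np.median(v) + mad_k * median_abs_deviation(v)

    reject = bad(amps) | bad(rmss)
    if reject.all():
        raise EmptyExtremaError("all cycles rejected as artifacts")
    bad_peaks = {cycles[i][1] for i in np.nonzero(reject)[0]}
    keep = np.array([not (k == PEAK and t in bad_peaks)
                     for t, k in zip(extrema.times, extrema.kinds)])
    times, kinds = extrema.times[keep], extrema.kinds[keep]
    idx = np.round(times * fs).astype(int)
    times, kinds = _enforce_alternation(times, kinds, x[idx])
    return ExtremaSequence(times=times, kinds=kinds, fs=fs)


# --------------------------------------------------------------------------
# matching


@dataclass
class MatchedCyclePair:
    resp_peak_t: float
    neural_peak_t: float
    delay: float                       # neural minus respiration peak time
    resp_cycle: tuple[float, float, float]
    neural_cycle: tuple[float, float, float]


def _full_cycles_by_peak(seq: ExtremaSequence) -> dict[float, tuple[float, float, float]]:
    return {p: (t1, p, t2) for t1, p, t2 in seq.cycles()}


def match_peaks(resp: ExtremaSequence, neural: ExtremaSequence, tau: float,
                match_direction: str = "absolute") -> list[MatchedCyclePair]:
    """Greedy one-to-one matching of respiration and neural peaks.

    Respiration peaks are visited in time order; each is assigned the
    unmatched neural peak minimizing |dt| (``match_direction='absolute'``) or
    the smallest nonnegative neural-after-respiration delay
    (``'neural_after_resp'``). The pair is kept only when the delay magnitude
    is below one respiration period ``tau`` and both cycles have bounding
    troughs on each side; a rejected candidate is not consumed. Equidistant
    candidates resolve to the earlier neural peak.
    """
    if tau <= 0:
        raise InvalidArgumentError("tau must be positive")
    if match_direction not in ("absolute", "neural_after_resp"):
        raise InvalidArgumentError(f"unknown match_direction {match_direction!r}")
    resp_cycles = _full_cycles_by_peak(resp)
    neural_cycles = _full_cycles_by_peak(neural)
    neural_peaks = sorted(neural_cycles)  # only peaks with both troughs
    matched: set[float] = set()
    pairs: list[MatchedCyclePair] = []
    for rp in sorted(resp_cycles):
        best, best_d = None, np.inf
        for cand in neural_peaks:
            if cand in matched:
                continue
            d = cand - rp
            if match_direction == "neural_after_resp" and d < 0:
                continue
            # strict < keeps the earlier peak on exact ties
            if abs(d) < best_d:
                best, best_d = cand, abs(d)
        if best is not None and best_d < tau:
            matched.add(best)
            pairs.append(MatchedCyclePair(
                resp_peak_t=rp, neural_peak_t=best, delay=best - rp,
                resp_cycle=resp_cycles[rp], neural_cycle=neural_cycles[best]))
    return pairs


# --------------------------------------------------------------------------
# features


def _contiguous_region(x: np.ndarray, center: int, lo: int, hi: int,
                       condition: np.ndarray) -> tuple[int, int]:
    """Largest [a, b] around ``center`` inside [lo, hi] where condition holds."""
    a = center
    while a - 1 >= lo and condition[a - 1]:
        a -= 1
    b = center
    while b + 1 <= hi and condition[b + 1]:
        b += 1
    return a, b


def _sharpness(x: np.ndarray, fs: float, i_ext: int, lo: int, hi: int,
               level: float, above: bool, local_amp: float) -> float:
    cond = x > level if above else x < level
    a, b = _contiguous_region(x, i_ext, lo, hi, cond)
    if b - a < 1:
        return np.nan
    deriv = np.abs(np.diff(x[a:b + 1])) * fs
    return float(deriv.mean() / local_amp)


def _auc(x: np.ndarray, fs: float, i_ext: int, lo: int, hi: int,
         median_level: float, above: bool) -> float:
    cond = x > median_level if above else x < median_level
    if not cond[i_ext]:
        return 0.0
    a, b = _contiguous_region(x, i_ext, lo, hi, cond)
    if b - a < 1:
        return 0.0
    seg = x[a:b + 1] - median_level if above else median_level - x[a:b + 1]
    return float(np.trapezoid(seg, dx=1.0 / fs))


def _cycle_features(cycle: tuple[float, float, float], rec: Recording) -> dict | None:
    """The eight shape features plus amplitude for one cycle; None if degenerate."""
    t1, tp, t2 = cycle
    fs = rec.fs
    x = rec.samples
    i1, ip, i2 = (int(round(t * fs)) for t in (t1, tp, t2))
    if not (0 <= i1 < ip < i2 < x.size):
        return None
    if not (x[ip] > x[i1] and x[ip] > x[i2]):
        warnings.warn("degenerate cycle (peak not above both troughs); skipped",
                      stacklevel=2)
        return None
    rise = (ip - i1) / fs
    decay = (i2 - ip) / fs
    duration = rise + decay
    trough_level = 0.5 * (x[i1] + x[i2])
    amplitude = x[ip] - trough_level
    cyc_median = float(np.median(x[i1:i2 + 1]))

    # exhale-trough windows may extend past the bounding trough into the
    # inter-breath pause, capped at one cycle length
    cap_hi = min(x.size - 1, i2 + (i2 - i1))
    half = 0.5 * amplitude
    feats = {
        "rise_time_s": rise,
        "decay_time_s": decay,
        "cycle_duration_s": duration,
        "rise_decay_symmetry": rise / duration,
        "amplitude": amplitude,
        "inhale_peak_sharpness": _sharpness(
            x, fs, ip, i1, i2, x[ip] - half, True, amplitude),
        "exhale_trough_sharpness": _sharpness(
            x, fs, i2, ip, cap_hi, x[i2] + half, False, amplitude),
        "inhale_peak_auc": _auc(x, fs, ip, i1, i2, cyc_median, True),
        "exhale_trough_auc": _auc(x, fs, i2, ip, cap_hi, cyc_median, False),
    }
    return feats


def extract_features(pair: MatchedCyclePair, resp_rec: Recording,
                     neural_rec: Recording) -> dict | None:
    """One tidy row of resp_* / neural_* features for a matched pair."""
    rfeat = _cycle_features(pair.resp_cycle, resp_rec)
    nfeat = _cycle_features(pair.neural_cycle, neural_rec)
    if rfeat is None or nfeat is None:
        return None
    row = {
        "subject_id": neural_rec.subject_id,
        "channel_id": neural_rec.channel_id,
        "modality": resp_rec.modality,
        "resp_peak_t": pair.resp_peak_t,
        "neural_peak_t": pair.neural_peak_t,
        "delay": pair.delay,
    }
    row.update({f"resp_{k}": v for k, v in rfeat.items()})
    row.update({f"neural_{k}": v for k, v in nfeat.items()})
    return row


def extract_matched_features(pairs: list[MatchedCyclePair],
                             resp_rec: Recording,
                             neural_rec: Recording) -> pd.DataFrame:
    rows = [extract_features(p, resp_rec, neural_rec) for p in pairs]
    rows = [r for r in rows if r is not None]
    return pd.DataFrame(rows)


def exclude_feature_outliers(
    rows: pd.DataFrame,
    k_sd: float = 3.0,
    features: tuple[str, ...] = SHAPE_FEATURES,
    group_cols: tuple[str, ...] = ("subject_id", "channel_id"),
    min_rows: int = 10,
) -> pd.DataFrame:
    """One-sided outlier exclusion: value > median + k_sd * SD, per channel.

    Each of the eight shape features is tested independently (for both the
    respiration and neural version of the column) and flagged in a
    ``outlier_<column>`` column; a row is dropped when any feature is
    flagged, keeping respiration and neural features paired. Channels with
    fewer than ``min_rows`` rows are passed through unfiltered. Amplitude is
    not outlier-filtered.
    """
    if rows.empty:
        return rows.copy()
    cols = [f"{p}_{f}" for p in ("resp", "neural") for f in features
            if f"{p}_{f}" in rows.columns]
    out = rows.copy()
    drop = pd.Series(False, index=out.index)
    grouped = (out.groupby(list(group_cols), sort=False, group_keys=False)
               if all(c in out.columns for c in group_cols) else [(None, out)])
    for _, grp in grouped:
        for col in cols:
            v = grp[col]
            ok = v.notna()
            if ok.sum() < min_rows:
                continue
            thresh = v[ok].median() + k_sd * v[ok].std()
            flagged = ok & (v > thresh)
            out.loc[grp.index, f"outlier_{col}"] = flagged
            drop.loc[grp.index[flagged]] = True
    return out[~drop].reset_index(drop=True)
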