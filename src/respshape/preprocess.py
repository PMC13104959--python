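"""Bring raw recordings to the analysis-ready state.

The pipeline order is: downsample to a common rate, bipolar re-reference the
neural contacts, low-pass the respiration traces at 2 Hz (linear-phase FIR),
and -- for the time-domain screening and cycle extraction -- band-pass both
signals 0.01-2 Hz with a fifth-order Bessel filter applied forward-backward
(zero phase) and z-score over the whole recording.

All filters here are zero-phase, so extrema timing is preserved; a symmetric
pulse's center of mass moves by less than one sample through any of them.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .exceptions import DegenerateSignalError, InvalidArgumentError
from .recording import Recording

#: edge span (seconds) contaminated by filter transients; excluded from
#: cycle extraction downstream
EDGE_EXCLUSION_S = 10.0


def resample_to(rec: Recording, target_fs: float) -> Recording:
    """Anti-aliased downsampling to ``target_fs`` (upsampling is refused)."""
    if not target_fs > 0:
        raise InvalidArgumentError("target_fs must be positive")
    if target_fs > rec.fs:
        raise InvalidArgumentError(
            f"refusing to upsample {rec.fs} Hz -> {target_fs} Hz")
    if target_fs == rec.fs:
        return rec.with_samples(rec.samples.copy())
    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator)
    return rec.with_samples(out, fs=target_fs,
                            note=f"resampled {rec.fs}->{target_fs} Hz")


def bipolar_rereference(channels: list[Recording]) -> list[Recording]:
    """Adjacent-contact differences along one electrode shaft.

    n contacts -> n-1 derived channels; derived channel i is contact i minus
    contact i+1, with a channel id concatenating the pair.
    """
    if len(channels) < 2:
        raise InvalidArgumentError("bipolar reference needs >= 2 contacts")
    fs = channels[0].fs
    n = channels[0].n_samples
    for ch in channels:
        if ch.fs != fs or ch.n_samples != n:
            raise InvalidArgumentError(
                "contacts must share sampling rate and length")
    out = []
    for a, b in zip(channels[:-1], channels[1:]):
        rec = a.with_samples(a.samples - b.samples,
                             note=f"bipolar {a.channel_id}-{b.channel_id}")
        rec.channel_id = f"{a.channel_id}-{b.channel_id}"
        out.append(rec)
    return out


def lowpass_respiration(rec: Recording, cutoff_hz: float = 2.0,
                        transition_hz: float = 1.0) -> Recording:
    """Zero-phase FIR low-pass for respiration traces.

    Windowed-sinc (Hamming) design with a ~1 Hz transition band; applied
    forward-backward so the net group delay is zero. Passband gain is within
    1% below 0.5 Hz.
    """
    if not rec.is_respiration:
        raise InvalidArgumentError(
            f"lowpass_respiration expects airflow/belt, got {rec.modality!r}")
    numtaps = int(3.3 * rec.fs / transition_hz)
    numtaps += 1 - numtaps % 2
    b = sps.firwin(numtaps, cutoff_hz, window="hamming", fs=rec.fs)
    if rec.n_samples <= 3 * numtaps:
        raise InvalidArgumentError(
            "recording too short for the 2 Hz FIR low-pass")
    out = sps.filtfilt(b, [1.0], rec.samples)
    return rec.with_samples(out, note=f"FIR lowpass {cutoff_hz} Hz")


def bandpass_for_timedomain(rec: Recording, lo_hz: float = 0.01,
                            hi_hz: float = 2.0, order: int = 5) -> Recording:
    """Fifth-order Bessel band-pass, forward-backward (zero phase)."""
    # require several time constants of the low corner so the transient decays
    min_duration = 6.0 / (2 * np.pi * lo_hz)
    if rec.duration_s <= min_duration:
        raise InvalidArgumentError(
            f"recording ({rec.duration_s:.0f} s) shorter than "
            f"{min_duration:.0f} s needed for the {lo_hz} Hz corner")
    sos = sps.bessel(order, [lo_hz, hi_hz], btype="bandpass",
                     fs=rec.fs, output="sos")
    # pad beyond several time constants of the low corner, else its edge
    # transient (tau ~ 16 s at 0.01 Hz) bleeds deep into the recording
    padlen = min(rec.n_samples - 1, int(3.0 / (2 * np.pi * lo_hz) * rec.fs))
    x = rec.samples - rec.samples.mean()
    out = sps.sosfiltfilt(sos, x, padlen=padlen)
    return rec.with_samples(out, note=f"Bessel bandpass {lo_hz}-{hi_hz} Hz")


def zscore(rec: Recording) -> Recording:
    """Standardize using the full-recording mean and SD."""
    sd = rec.samples.std()
    if sd == 0:
        raise DegenerateSignalError(
            f"{rec.channel_id}: constant signal cannot be z-scored")
    out = (rec.samples - rec.samples.mean()) / sd
    return rec.with_samples(out, note="zscore")


def prepare_timedomain(rec: Recording, lo_hz: float = 0.01,
                       hi_hz: float = 2.0) -> Recording:
    """Band-pass then z-score -- the screening-stage representation."""
    return zscore(bandpass_for_timedomain(rec, lo_hz, hi_hz))
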