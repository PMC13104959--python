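"""End-to-end orchestration: screen channels, build matched-cycle tables.

Ties the stages together in the analysis order: breathing-band estimation
from the respiration spectrum; the three-stage channel screen (coherence +
surrogates, mean CCF + permutation null, PMI + circular-shift null); and the
cycle extraction path (band-pass + z-score, two-stage extrema detection with
artifact rejection, greedy peak matching bounded by tau, waveform features,
outlier exclusion) that produces the tidy table the coupling model consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cycles import (
    detect_extrema,
    exclude_feature_outliers,
    extract_matched_features,
    match_peaks,
    reject_artifact_cycles,
)
from .preprocess import EDGE_EXCLUSION_S, lowpass_respiration, prepare_timedomain
from .recording import Recording
from .spectral import BreathingBand, CoherenceResult, coherence_screen, find_breathing_band, welch_psd
from .timedomain import (
    CCFResult,
    PMIResult,
    ccf_permutation_null,
    epoch_on_respiration_peaks,
    phase_monotonicity_index,
)


def breathing_band_for(resp: Recording, lowpass: bool = True) -> BreathingBand:
    """Estimate the participant's breathing band from a respiration trace."""
    rec = lowpass_respiration(resp) if lowpass else resp
    return find_breathing_band(welch_psd(rec))


@dataclass
class ScreenResult:
    """All three screening statistics for one neural channel."""

    subject_id: str
    channel_id: str
    coherence: CoherenceResult
    ccf: CCFResult | None
    pmi: PMIResult | None
    polarity: int

    @property
    def passes_all(self) -> bool:
        return bool(self.coherence.passes
                    and self.ccf is not None and self.ccf.passes
                    and self.pmi is not None and self.pmi.passes)

    def to_row(self) -> dict:
        band = self.coherence.band
        row = dict(
            subject_id=self.subject_id, channel_id=self.channel_id,
            f_resp=band.f_resp if band else float("nan"),
            max_coh_in_band=self.coherence.max_coh_in_band,
            coh_threshold=self.coherence.surrogate_threshold,
            has_psd_peak_in_band=self.coherence.has_psd_peak_in_band,
            passes_coherence=self.coherence.passes,
            polarity=self.polarity,
        )
        if self.ccf is not None:
            row.update(ccf_max_abs=self.ccf.max_abs,
                       ccf_lag_s=self.ccf.lag_at_max,
                       ccf_threshold=self.ccf.null_threshold,
                       passes_ccf=self.ccf.passes)
        if self.pmi is not None:
            row.update(channel_pmi=self.pmi.channel_pmi,
                       pmi_threshold=self.pmi.null_threshold,
                       passes_pmi=self.pmi.passes)
        row["passes_all"] = self.passes_all
        return row


def screen_channel(
    neural: Recording,
    resp: Recording,
    band: BreathingBand | None = None,
    n_surrogates: int = 1000,
    n_perm: int = 500,
    alpha: float = 0.01,
    seed: int = 0,
    always_run_timedomain: bool = True,
) -> ScreenResult:
    """Run the full three-stage screen for one neural channel.

    With ``always_run_timedomain=False`` the stages short-circuit: CCF/PMI
    are skipped when the coherence screen already fails. By default all
    statistics are computed so they can be reported side by side.
    """
    if band is None:
        band = breathing_band_for(resp)
    coh = coherence_screen(neural, resp, band, n_surrogates=n_surrogates,
                           alpha=alpha, seed=seed)
    ccf = pmi = None
    polarity = 1
    if always_run_timedomain or coh.passes:
        neural_td = prepare_timedomain(neural)
        resp_td = prepare_timedomain(resp)
        resp_ext = detect_extrema(resp_td).restrict(
            EDGE_EXCLUSION_S, resp_td.duration_s - EDGE_EXCLUSION_S)
        epochs = epoch_on_respiration_peaks(
            neural_td, resp_td, resp_ext.peak_times, window_s=band.tau)
        ccf = ccf_permutation_null(neural_td, resp_td, epochs, tau=band.tau,
                                   n_perm=n_perm, alpha=alpha, seed=seed)
        polarity = ccf.polarity
        pmi = phase_monotonicity_index(neural_td, resp_ext, n_perm=n_perm,
                                       alpha=alpha, seed=seed)
    return ScreenResult(subject_id=neural.subject_id,
                        channel_id=neural.channel_id,
                        coherence=coh, ccf=ccf, pmi=pmi, polarity=polarity)


def matched_cycle_table(
    resp: Recording,
    neural: Recording,
    band: BreathingBand | None = None,
    polarity: int = 1,
    edge_exclusion_s: float = EDGE_EXCLUSION_S,
    mad_k: float = 5.0,
    match_direction: str = "absolute",
    apply_outlier_exclusion: bool = False,
) -> pd.DataFrame:
    """Matched respiration-neural cycles with all shape features, one channel.

    Both signals are band-passed (0.01-2 Hz Bessel, zero phase) and z-scored;
    extrema within ``edge_exclusion_s`` of the recording edges are discarded
    (filter transients); artifact cycles are MAD-rejected; matching is
    bounded by one respiration period.
    """
    if band is None:
        band = breathing_band_for(resp)
    resp_td = prepare_timedomain(resp)
    neural_td = prepare_timedomain(neural)
    if polarity == -1:
        neural_td = neural_td.with_samples(-neural_td.samples,
                                           note="polarity flip")
    lo, hi = edge_exclusion_s, resp_td.duration_s - edge_exclusion_s

    resp_ext = detect_extrema(resp_td).restrict(lo, hi)
    resp_ext = reject_artifact_cycles(resp_ext, resp_td, mad_k=mad_k)
    neural_ext = detect_extrema(neural_td).restrict(lo, hi)
    neural_ext = reject_artifact_cycles(neural_ext, neural_td, mad_k=mad_k)

    pairs = match_peaks(resp_ext, neural_ext, tau=band.tau,
                        match_direction=match_direction)
    table = extract_matched_features(pairs, resp_td, neural_td)
    if apply_outlier_exclusion and not table.empty:
        table = exclude_feature_outliers(table)
    return table


def study_cycle_table(
    dataset,
    channels: list[tuple[str, str]] | None = None,
    modality: str = "airflow",
    apply_outlier_exclusion: bool = True,
    **kw,
) -> pd.DataFrame:
    """Concatenated matched-cycle table across a synthetic dataset.

    ``channels`` restricts to (subject_id, channel_id) pairs; the default is
    every neural channel in the manifest. Outlier exclusion is applied per
    channel at the end.
    """
    man = dataset.manifest
    if channels is None:
        neural = man[man["modality"] == "neural"]
        channels = list(zip(neural["subject_id"], neural["channel_id"]))
    tables = []
    for subject, channel in channels:
        resp = dataset.get(subject, modality)
        band = breathing_band_for(resp)
        tables.append(matched_cycle_table(
            resp, dataset.get(subject, channel), band=band, **kw))
    out = pd.concat([t for t in tables if not t.empty], ignore_index=True)
    if apply_outlier_exclusion and not out.empty:
        out = exclude_feature_outliers(out)
    return out
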