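"""The Recording container and its text-based I/O.

A :class:`Recording` is one labeled time series -- a neural channel (bipolar
LFP, in microvolts) or a respiration trace (nasal airflow or belt, arbitrary
units) -- with its sampling rate and subject/channel identity.

Recordings round-trip through a simple delimited text format: two tab-separated
columns (``time_s``, ``value``) preceded by ``#``-prefixed header lines
carrying the metadata (``# fs=...``, ``# modality=...``). EDF files can be
read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidArgumentError

MODALITIES = ("neural", "airflow", "belt")
RESPIRATION_MODALITIES = ("airflow", "belt")


@dataclass
class Recording:
    samples: np.ndarray
    fs: float
    subject_id: str = "s00"
    channel_id: str = "ch00"
    modality: str = "neural"
    region_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("samples must be one-dimensional")
        if not self.fs > 0:
            raise InvalidArgumentError(f"fs must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("samples must be finite")
        if self.modality not in MODALITIES:
            raise InvalidArgumentError(
                f"modality must be one of {MODALITIES}, got {self.modality!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def is_respiration(self) -> bool:
        return self.modality in RESPIRATION_MODALITIES

    def with_samples(self, samples: np.ndarray, fs: float | None = None,
                     note: str | None = None) -> "Recording":
        """Copy of this recording with new samples (and optionally fs).

        ``note`` is appended to the provenance list in ``meta`` so that the
        processing history survives a round-trip through the text format.
        """
        meta = dict(self.meta)
        if note:
            meta["provenance"] = list(meta.get("provenance", [])) + [note]
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs, meta=meta)

    # ------------------------------------------------------------------ I/O

    def to_delimited(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"# fs={self.fs}\n")
            fh.write(f"# modality={self.modality}\n")
            fh.write(f"# subject={self.subject_id}\n")
            fh.write(f"# channel={self.channel_id}\n")
            if self.region_label:
                fh.write(f"# region={self.region_label}\n")
            for note in self.meta.get("provenance", []):
                fh.write(f"# provenance={note}\n")
            fh.write("time_s\tvalue\n")
            t = self.times
            buf = io.StringIO()
            np.savetxt(buf, np.column_stack([t, self.samples]),
                       fmt="%.6f\t%.9g")
            fh.write(buf.getvalue())

    @classmethod
    def from_delimited(cls, path: str | os.PathLike) -> "Recording":
        header: dict[str, str] = {}
        provenance: list[str] = []
        n_header = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                n_header += 1
                key, _, val = line[1:].strip().partition("=")
                key = key.strip()
                if key == "provenance":
                    provenance.append(val.strip())
                else:
                    header[key] = val.strip()
        if "fs" not in header:
            raise InvalidArgumentError(f"{path}: missing '# fs=' header")
        data = np.loadtxt(path, skiprows=n_header + 1)
        meta = {"provenance": provenance} if provenance else {}
        return cls(
            samples=np.atleast_2d(data)[:, 1],
            fs=float(header["fs"]),
            subject_id=header.get("subject", "s00"),
            channel_id=header.get("channel", "ch00"),
            modality=header.get("modality", "neural"),
            region_label=header.get("region") or None,
            meta=meta,
        )


def read_edf(path: str | os.PathLike, subject_id: str = "s00",
             modality_map: dict[str, str] | None = None) -> list[Recording]:
    """Read every channel of an EDF file as a list of Recordings.

    ``modality_map`` maps channel names to modalities; unmapped channels are
    assumed neural. Requires :mod:`mne`.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    modality_map = modality_map or {}
    out = []
    for name in raw.ch_names:
        data = raw.get_data(picks=[name])[0]
        out.append(Recording(samples=data, fs=float(raw.info["sfreq"]),
                             subject_id=subject_id, channel_id=name,
                             modality=modality_map.get(name, "neural")))
    return out
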