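"""Core signal containers and their plain-text persistence.

A :class:`UniformECG` is the codec's native input: a multi-lead,
uniformly sampled voltage matrix in microvolts together with the
sampling rate and the amplitude resolution of the acquiring ADC.
A :class:`BeatAnnotation` holds the five wave-border fiducial points
(P-onset, P-end, QRS-onset, QRS-end, T-end) of one heartbeat as
fractional sample positions on the uniform grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: 12-bit ADC spanning +/-5 mV -> 2.44140625 uV per least-significant bit.
DEFAULT_RESOLUTION_UV = 10_000.0 / 4096.0

STANDARD_12_LEADS = [
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
]

_CSV_MAGIC = "adaptecg-uniform-ecg"


@dataclass
class UniformECG:
    """Uniformly sampled multi-lead ECG in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_leads)
        Voltages in microvolts.
    fs : float
        Sampling rate in Hz.
    lead_labels : list of str
        One label per column of ``data``.
    resolution_uv : float
        Amplitude quantum of the source ADC in microvolts per LSB.
    """

    data: np.ndarray
    fs: float
    lead_labels: list[str] = field(default_factory=list)
    resolution_uv: float = DEFAULT_RESOLUTION_UV

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (n_samples, n_leads) matrix")
        if self.data.shape[0] == 1 and self.data.shape[1] > 1 and not self.lead_labels:
            # a bare 1-D vector is a single lead, not a single sample
            self.data = self.data.T
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.lead_labels:
            self.lead_labels = [f"L{i + 1}" for i in range(self.data.shape[1])]
        if len(self.lead_labels) != self.data.shape[1]:
            raise ValueError("one lead label per data column required")
        if self.resolution_uv <= 0:
            raise ValueError("amplitude resolution must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_leads(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (first sample at t = 0)."""
        return np.arange(self.n_samples) / self.fs

    def with_data(self, data: np.ndarray) -> "UniformECG":
        return replace(self, data=np.asarray(data, dtype=float))

    def quantized(self) -> "UniformECG":
        """Snap voltages to the ADC grid (integer multiples of the LSB)."""
        q = np.round(self.data / self.resolution_uv) * self.resolution_uv
        return self.with_data(q)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path) -> None:
        """Write one column per lead with a small metadata preamble."""
        with open(path, "w", encoding="ascii") as fh:
            fh.write(f"# {_CSV_MAGIC} v1\n")
            fh.write(f"# fs_hz={self.fs!r}\n")
            fh.write(f"# resolution_uv={self.resolution_uv!r}\n")
            fh.write(",".join(self.lead_labels) + "\n")
            np.savetxt(fh, self.data, fmt="%.6f", delimiter=",")

    @classmethod
    def from_csv(cls, path) -> "UniformECG":
        meta: dict[str, float] = {}
        with open(path, "r", encoding="ascii") as fh:
            first = fh.readline()
            if _CSV_MAGIC not in first:
                raise ValueError(f"{path}: not an adaptecg uniform-ECG CSV")
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = float(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            frame = pd.read_csv(fh)
        return cls(
            data=frame.to_numpy(dtype=float),
            fs=meta["fs_hz"],
            lead_labels=list(frame.columns),
            resolution_uv=meta.get("resolution_uv", DEFAULT_RESOLUTION_UV),
        )


_BORDER_NAMES = ("p_on", "p_end", "qrs_on", "qrs_end", "t_end")


@dataclass(frozen=True)
class BeatAnnotation:
    """Five wave borders of one heartbeat, in fractional sample units."""

    beat_index: int
    p_on: float
    p_end: float
    qrs_on: float
    qrs_end: float
    t_end: float

    def __post_init__(self) -> None:
        b = self.borders
        if not np.all(np.diff(b) > 0):
            raise ValueError(
                f"beat {self.beat_index}: borders must satisfy "
                f"P-on < P-end < QRS-on < QRS-end < T-end, got {b}"
            )

    @property
    def borders(self) -> np.ndarray:
        return np.array(
            [self.p_on, self.p_end, self.qrs_on, self.qrs_end, self.t_end]
        )

    def shifted(self, offset: float) -> "BeatAnnotation":
        return BeatAnnotation(
            self.beat_index, *(self.borders + offset)
        )


def annotations_to_csv(annotations: list[BeatAnnotation], path) -> None:
    """One row per beat; border positions in (fractional) sample units."""
    frame = pd.DataFrame(
        [[a.beat_index, *a.borders] for a in annotations],
        columns=["beat_index", *_BORDER_NAMES],
    )
    frame.to_csv(path, index=False)


def annotations_from_csv(path) -> list[BeatAnnotation]:
    frame = pd.read_csv(path)
    missing = {"beat_index", *_BORDER_NAMES} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return [
        BeatAnnotation(int(row.beat_index), row.p_on, row.p_end,
                       row.qrs_on, row.qrs_end, row.t_end)
        for row in frame.itertuples(index=False)
    ]
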