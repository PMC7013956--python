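"""Medical relevance functions and their beat-wise projection.

A *medical relevance function* (MRF) encodes, per 32 ms bin of a
duration-normalized heartbeat, how much diagnostic information the ECG
trace carries there — originally estimated from the gaze-time
histograms of cardiologists reading records. The generalized variant
(gMRF) covers routine interpretation; specific variants (sMRF) put a
region of interest on a chosen section, e.g. the end of the QRS
complex when conduction defects are being investigated.

Five landmark positions (P-onset, P-end, QRS-onset, QRS-end, T-end)
anchor the template to wave borders. Projecting the template onto one
actual heartbeat stretches or contracts each inter-landmark section
linearly so the template landmarks land exactly on the beat's detected
borders; the resulting per-sample curve is the *adapted* MRF (aMRF)
that drives the local sampling interval.

The exact bin values of the published gaze-derived gMRF exist only in
graphical form; :func:`default_gmrf` ships a hand-drawn approximation
with the published landmark positions and is meant to be replaced by a
user-supplied template (JSON or CSV) where a calibrated one exists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .containers import BeatAnnotation

__all__ = [
    "MRFTemplate",
    "AdaptedMRF",
    "default_gmrf",
    "smrf_qrs_roi",
    "get_template",
    "load_template",
    "save_template",
    "project",
    "adapt",
]

#: Template bin width in seconds (gaze histograms were collected in
#: 32 ms slots of the normalized trace).
DEFAULT_BIN_LENGTH_S = 0.032

#: Landmark sample positions of the packaged templates on a 500 Hz
#: normalized-beat grid: P-onset, P-end, QRS-onset, QRS-end, T-end.
DEFAULT_LANDMARKS = (106, 196, 246, 338, 672)


@dataclass
class MRFTemplate:
    """Relevance-per-bin template on a normalized heartbeat grid.

    ``values[i]`` is the relevance of bin ``i`` (bins of
    ``bin_length_s`` seconds); ``landmarks`` are the five wave-border
    positions in samples of the ``grid_fs`` normalized-beat grid.
    Values are normalized to [0, 1] on construction (divided by the
    maximum when any value exceeds 1).
    """

    values: np.ndarray
    landmarks: tuple[int, int, int, int, int] = DEFAULT_LANDMARKS
    bin_length_s: float = DEFAULT_BIN_LENGTH_S
    grid_fs: float = 500.0
    name: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("template needs at least two bins")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("template values must be finite and non-negative")
        vmax = self.values.max()
        if vmax > 1.0:
            self.values = self.values / vmax
        self.landmarks = tuple(float(a) for a in self.landmarks)
        if len(self.landmarks) != 5:
            raise ValueError("exactly five landmarks required")
        if not np.all(np.diff(self.landmarks) > 0):
            raise ValueError("landmarks must be strictly increasing")
        if self.landmarks[0] < 0 or self.landmarks[-1] > self.duration_s * self.grid_fs:
            raise ValueError("landmarks must lie within the template span")
        if self.bin_length_s <= 0 or self.grid_fs <= 0:
            raise ValueError("bin_length_s and grid_fs must be positive")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_length_s

    @property
    def bin_centers_s(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_length_s

    @property
    def landmark_times_s(self) -> np.ndarray:
        return np.asarray(self.landmarks) / self.grid_fs

    @property
    def floor_value(self) -> float:
        """Relevance held between beats (template edge level)."""
        return float(min(self.values[0], self.values[-1]))

    def evaluate(self, t_s: np.ndarray) -> np.ndarray:
        """Continuous template relevance at normalized-beat times [s].

        Linear interpolation between bin centres, constant beyond the
        first/last bin centre.
        """
        return np.interp(np.asarray(t_s, dtype=float),
                         self.bin_centers_s, self.values)


@dataclass
class AdaptedMRF:
    """Per-sample relevance aligned with a uniformly sampled record."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("adapted MRF cannot be empty")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("adapted MRF values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def __len__(self) -> int:
        return self.values.size


# --------------------------------------------------------------- defaults

# Approximation of the gaze-derived generalized relevance histogram:
# low attention on the baseline, a secondary peak over the P wave,
# maximum over the QRS complex, a broad shoulder over the ST segment
# and T wave decaying towards T-end. 44 bins x 32 ms = 1.408 s beat.
_GMRF_BINS = np.array([
    0.06, 0.05, 0.05, 0.06, 0.08,                 # leading baseline
    0.12, 0.25, 0.40, 0.50, 0.55, 0.55, 0.50,     # P wave
    0.40, 0.35, 0.45,                             # PQ segment
    0.70, 0.95, 1.00, 1.00, 0.95, 0.85, 0.70,     # QRS complex
    0.55, 0.45, 0.40, 0.40, 0.42, 0.45, 0.48,     # ST segment
    0.50, 0.50, 0.48, 0.45, 0.42, 0.38, 0.34,     # T wave
    0.30, 0.26, 0.22, 0.18, 0.14, 0.11, 0.09,     # T decay
    0.06,                                         # trailing baseline
])

# Region-of-interest variant emphasizing the terminal QRS / early ST
# section (infarct or conduction-defect work-up): relevance is saved in
# the P-wave vicinity and concentrated around the QRS-end landmark.
_SMRF_QRS_ROI_BINS = np.array([
    0.05, 0.05, 0.05, 0.05, 0.05,
    0.08, 0.12, 0.15, 0.15, 0.15, 0.15, 0.12,     # de-emphasized P
    0.12, 0.15, 0.30,
    0.55, 0.80, 0.95, 1.00, 1.00, 1.00, 1.00,     # QRS, peak at QRS-end
    0.95, 0.90, 0.85, 0.80, 0.75, 0.70, 0.65,     # ST region of interest
    0.60, 0.55, 0.50, 0.45, 0.40, 0.34, 0.28,
    0.22, 0.17, 0.13, 0.10, 0.08, 0.06, 0.05,
    0.05,
])


def default_gmrf() -> MRFTemplate:
    """Packaged approximation of the generalized relevance function."""
    return MRFTemplate(values=_GMRF_BINS.copy(), name="gmrf_default")


def smrf_qrs_roi() -> MRFTemplate:
    """Packaged specific MRF with a QRS-end region of interest."""
    return MRFTemplate(values=_SMRF_QRS_ROI_BINS.copy(), name="smrf_qrs_roi")


_PACKAGED = {"gmrf_default": default_gmrf, "smrf_qrs_roi": smrf_qrs_roi}


def get_template(name_or_path: str) -> MRFTemplate:
    """Resolve a packaged template name or load one from a file path."""
    if name_or_path in _PACKAGED:
        return _PACKAGED[name_or_path]()
    return load_template(name_or_path)


# ------------------------------------------------------------ persistence

def save_template(template: MRFTemplate, path) -> None:
    """Write a template as JSON (``.json``) or two-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "name": template.name,
            "bin_length_s": template.bin_length_s,
            "grid_fs": template.grid_fs,
            "landmarks": list(template.landmarks),
            "values": template.values.tolist(),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        lines = [
            f"# name={template.name}",
            f"# bin_length_s={template.bin_length_s!r}",
            f"# grid_fs={template.grid_fs!r}",
            "# landmarks=" + ",".join(repr(a) for a in template.landmarks),
            "bin,value",
        ]
        lines += [f"{i},{float(v)!r}" for i, v in enumerate(template.values)]
        path.write_text("\n".join(lines) + "\n")


def load_template(path) -> MRFTemplate:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        try:
            return MRFTemplate(
                values=np.asarray(payload["values"], dtype=float),
                landmarks=tuple(payload["landmarks"]),
                bin_length_s=float(payload.get("bin_length_s", DEFAULT_BIN_LENGTH_S)),
                grid_fs=float(payload.get("grid_fs", 500.0)),
                name=str(payload.get("name", path.stem)),
            )
        except KeyError as exc:
            raise ValueError(f"{path}: missing template field {exc}") from exc
    meta: dict[str, str] = {}
    values = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
        elif not line.startswith("bin,"):
            _, _, val = line.partition(",")
            values.append(float(val))
    if "landmarks" not in meta:
        raise ValueError(f"{path}: template CSV lacks a '# landmarks=' line")
    return MRFTemplate(
        values=np.asarray(values, dtype=float),
        landmarks=tuple(float(a) for a in meta["landmarks"].split(",")),
        bin_length_s=float(meta.get("bin_length_s", DEFAULT_BIN_LENGTH_S)),
        grid_fs=float(meta.get("grid_fs", 500.0)),
        name=meta.get("name", path.stem),
    )


# ------------------------------------------------------------- projection

def _registration(template: MRFTemplate, annotation: BeatAnnotation,
                  fs: float, t_s: np.ndarray) -> np.ndarray:
    """Map record times [s] to normalized-beat times [s].

    Piecewise-linear landmark registration: between consecutive wave
    borders the map is linear and sends border k exactly onto template
    landmark k. Outside the annotated span the map continues at unit
    slope (no stretching), so the template head/tail is replayed as-is.
    """
    a_k = template.landmark_times_s
    b_k = annotation.borders / fs
    t_s = np.asarray(t_s, dtype=float)
    a = np.interp(t_s, b_k, a_k)
    before = t_s < b_k[0]
    after = t_s > b_k[-1]
    a[before] = a_k[0] - (b_k[0] - t_s[before])
    a[after] = a_k[-1] + (t_s[after] - b_k[-1])
    return a


def project(
    template: MRFTemplate,
    annotation: BeatAnnotation,
    positions: np.ndarray,
    fs: float,
) -> np.ndarray:
    """Relevance at uniform-grid ``positions`` (fractional samples).

    Landmark samples map exactly: the projected relevance at border
    ``b_k`` equals the template relevance at landmark ``a_k`` for any
    stretching of the inter-border sections. Outside [P-onset, T-end]
    the template's head and tail are continued at their native speed
    and hold the edge value beyond the template span.
    """
    t_s = np.asarray(positions, dtype=float) / fs
    a = _registration(template, annotation, fs, t_s)
    return template.evaluate(a)


def adapt(
    template: MRFTemplate,
    annotations: list[BeatAnnotation],
    n_samples: int,
    fs: float,
) -> AdaptedMRF:
    """Build the full-record adapted MRF from per-beat annotations.

    Each annotated beat contributes its projected section; between
    T-end and the next P-onset the template tail (continued forward
    from the earlier beat) and head (continued backward from the later
    beat) are blended by pointwise maximum, which decays to the
    template edge value mid-gap. Beats whose annotation cannot be used
    are covered at maximum relevance — the codec never under-samples on
    uncertainty.
    """
    if n_samples < 1:
        raise ValueError("empty signal")
    pos = np.arange(n_samples, dtype=float)
    if not annotations:
        return AdaptedMRF(np.ones(n_samples), fs)

    out = np.full(n_samples, -np.inf)
    valid: list[BeatAnnotation] = []
    for ann in annotations:
        borders = ann.borders
        if (np.any(~np.isfinite(borders)) or np.any(np.diff(borders) <= 0)
                or borders[0] < -0.5 or borders[-1] > n_samples - 0.5):
            lo = max(0, int(np.floor(np.nanmin(borders))))
            hi = min(n_samples, int(np.ceil(np.nanmax(borders))) + 1)
            if hi > lo:
                out[lo:hi] = 1.0  # conservative fallback
            continue
        valid.append(ann)

    if not valid:
        return AdaptedMRF(np.where(np.isfinite(out), np.maximum(out, 0), 1.0), fs)

    # each beat contributes its projection over its annotated span plus
    # one template-length continuation to each side; overlaps between
    # neighbouring beats resolve by pointwise maximum (conservative)
    span = int(round(template.duration_s * fs))
    for ann in sorted(valid, key=lambda a: a.qrs_on):
        lo = max(0, int(np.floor(ann.p_on)) - span)
        hi = min(n_samples, int(np.ceil(ann.t_end)) + span + 1)
        seg = project(template, ann, pos[lo:hi], fs)
        out[lo:hi] = np.maximum(out[lo:hi], seg)

    out = np.where(np.isfinite(out), out, template.floor_value)
    return AdaptedMRF(np.clip(out, 0.0, 1.0), fs)
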