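"""Synthetic multi-lead ECG with ground-truth wave borders.

Each heartbeat is a sum of five Gaussian kernels (P, Q, R, S, T), one
morphology shared by all leads up to a per-lead gain — a deliberately
simple parametric stand-in for the dipole-projection structure of a
real 12-lead recording. Because every wave is an analytic kernel the
wave borders are known by construction: each border is the wave centre
plus/minus three kernel widths (beyond which the kernel carries
~1 % of its peak), clipped so consecutive beats never overlap.

Defaults emulate a clinical resting record: 12 leads, 500 Hz, 12-bit
amplitude over +/-5 mV (~2.44 uV per LSB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import (
    DEFAULT_RESOLUTION_UV,
    STANDARD_12_LEADS,
    BeatAnnotation,
    UniformECG,
)

__all__ = ["WaveParams", "SynthConfig", "generate_ecg", "generate_bandlimited"]


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: amplitude [uV], centre offset from R [s], width [s]."""

    amplitude_uv: float
    center_s: float
    width_s: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("wave width must be positive")


def _default_waves() -> dict[str, WaveParams]:
    # Textbook-shaped resting morphology; amplitudes in lead-II scale.
    return {
        "P": WaveParams(120.0, -0.200, 0.020),
        "Q": WaveParams(-100.0, -0.035, 0.008),
        "R": WaveParams(1000.0, 0.000, 0.010),
        "S": WaveParams(-200.0, 0.030, 0.009),
        "T": WaveParams(250.0, 0.250, 0.045),
    }


def _default_gains(n_leads: int) -> np.ndarray:
    # Fixed, deliberately uneven projection gains (lead III and aVL small,
    # precordial leads large) so multi-lead code paths see real variety.
    base = np.array([1.0, 1.1, 0.45, 0.65, 0.35, 0.85,
                     0.55, 0.9, 1.2, 1.15, 1.0, 0.8])
    if n_leads <= len(base):
        return base[:n_leads].copy()
    reps = int(np.ceil(n_leads / len(base)))
    return np.tile(base, reps)[:n_leads]


@dataclass
class SynthConfig:
    """Parameters of the synthetic recording."""

    heart_rate_bpm: float = 60.0
    duration_s: float = 10.0
    fs: float = 500.0
    n_leads: int = 12
    lead_gains: np.ndarray | None = None
    wave_params: dict[str, WaveParams] = field(default_factory=_default_waves)
    noise_rms_uv: float = 5.0
    quantize_bits: int | None = 12
    resolution_uv: float = DEFAULT_RESOLUTION_UV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("fs, duration_s and heart_rate_bpm must be positive")
        if self.n_leads < 1:
            raise ValueError("at least one lead required")
        if self.noise_rms_uv < 0:
            raise ValueError("noise RMS cannot be negative")
        missing = {"P", "Q", "R", "S", "T"} - set(self.wave_params)
        if missing:
            raise ValueError(f"missing wave parameters: {sorted(missing)}")
        centers = [self.wave_params[w].center_s for w in ("P", "Q", "R", "S", "T")]
        if not np.all(np.diff(centers) > 0):
            raise ValueError("wave centres must be ordered P < Q < R < S < T")
        if self.lead_gains is None:
            self.lead_gains = _default_gains(self.n_leads)
        self.lead_gains = np.asarray(self.lead_gains, dtype=float)
        if self.lead_gains.shape != (self.n_leads,):
            raise ValueError("lead_gains must have one entry per lead")


def _beat_borders_s(waves: dict[str, WaveParams]) -> np.ndarray:
    """Ground-truth borders relative to the R centre, in seconds."""
    p, q, s, t = waves["P"], waves["Q"], waves["S"], waves["T"]
    borders = np.array([
        p.center_s - 3 * p.width_s,       # P-onset
        p.center_s + 3 * p.width_s,       # P-end
        q.center_s - 3 * q.width_s,       # QRS-onset
        s.center_s + 3 * s.width_s,       # QRS-end
        t.center_s + 3 * t.width_s,       # T-end
    ])
    if not np.all(np.diff(borders) > 0):
        raise ValueError("wave geometry yields non-monotone borders")
    return borders


def generate_ecg(config: SynthConfig) -> tuple[UniformECG, list[BeatAnnotation]]:
    """Generate a multi-lead record plus its ground-truth annotations.

    Returns the signal (quantized to the configured ADC grid unless
    ``quantize_bits`` is None) and one :class:`BeatAnnotation` per beat
    that fits entirely — including its P-onset and T-end — inside the
    record. Identical configs (same seed) give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration_s))
    t = np.arange(n) / config.fs
    rr = 60.0 / config.heart_rate_bpm
    borders_rel = _beat_borders_s(config.wave_params)

    margin = 2.0 / config.fs
    first_r = max(0.3, -borders_rel[0] + margin)
    last_allowed = (n - 1) / config.fs - borders_rel[-1] - margin
    r_times = []
    k = 0
    while True:
        r = first_r + k * rr
        if r > last_allowed:
            break
        r_times.append(r)
        k += 1

    base = np.zeros(n)
    for r in r_times:
        for wave in config.wave_params.values():
            u = (t - r - wave.center_s) / wave.width_s
            base += wave.amplitude_uv * np.exp(-0.5 * u * u)

    data = base[:, None] * config.lead_gains[None, :]
    if config.noise_rms_uv > 0:
        data = data + rng.normal(0.0, config.noise_rms_uv, size=data.shape)

    ecg = UniformECG(
        data=data,
        fs=config.fs,
        lead_labels=(STANDARD_12_LEADS[: config.n_leads]
                     if config.n_leads <= 12
                     else [f"L{i + 1}" for i in range(config.n_leads)]),
        resolution_uv=config.resolution_uv,
    )
    if config.quantize_bits is not None:
        ecg = ecg.quantized()
        half = (2 ** (config.quantize_bits - 1)) * config.resolution_uv
        ecg.data = np.clip(ecg.data, -half, half - config.resolution_uv)

    annotations = []
    for i, r in enumerate(r_times):
        b = (r + borders_rel) * config.fs
        # clip against neighbours so annotations never overlap
        if i + 1 < len(r_times):
            next_p_on = (r_times[i + 1] + borders_rel[0]) * config.fs
            b[4] = min(b[4], next_p_on - 1.0)
        annotations.append(BeatAnnotation(i, *b))
    return ecg, annotations


def generate_bandlimited(
    f_components: list[float], fs: float, duration_s: float
) -> UniformECG:
    """Sum of unit-amplitude tones, single lead — an analytic oracle input.

    A zero frequency contributes a unit DC offset. Components at or above
    the Nyquist rate are rejected.
    """
    f = np.asarray(list(f_components), dtype=float)
    if np.any(f >= fs / 2):
        raise ValueError("all components must lie below fs/2 (aliasing)")
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    n = int(round(fs * duration_s))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for fi in f:
        x += 1.0 if fi == 0 else np.sin(2 * np.pi * fi * t)
    # unit-amplitude fixtures need an amplitude quantum matched to their
    # scale (a 12-bit signed range around +/-2 units)
    return UniformECG(data=x[:, None], fs=fs, lead_labels=["L1"],
                      resolution_uv=2.0**-10)
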