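"""Relevance-driven non-uniform sampling codec.

Encoder chain: wave delineation -> beat-wise projection of the
relevance template -> pointwise local sampling interval -> 6-bit
interval quantization -> time-varying anti-alias low-pass ->
cubic-spline resampling of all leads at the non-uniform times.
Decoder: rebuild the sample times from the shared interval-code
stream and cubic-spline interpolate each lead back onto the uniform
grid.

The local sampling interval is linear in relevance,

    ls(t) = Tm + (Ts - Tm) * aMRF(t),

with Ts = 1/fs (native period) and Tm = 1/fm (longest admissible
period), then snapped to the quantized grid Ts + p*(Tm - Ts)/P,
p in {0, ..., P-1}. One code stream is shared by all leads; for the
default fs=500 Hz, fm=100 Hz, 6-bit policy the grid runs from 2 ms to
9.875 ms in 0.125 ms steps.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import firwin2

from .containers import BeatAnnotation, UniformECG
from .delineate import delineate as _delineate_waves
from .delineate import detect_beats as _detect_beats
from .mrf import AdaptedMRF, MRFTemplate, adapt

__all__ = [
    "SamplingPolicy",
    "NonUniformECG",
    "NUECGFormatError",
    "intervals_from_mrf",
    "antialias",
    "encode",
    "decode",
    "write_nuecg",
    "read_nuecg",
]


class NUECGFormatError(ValueError):
    """Raised for malformed or truncated NUECG containers."""


@dataclass(frozen=True)
class SamplingPolicy:
    """Native rate, minimum local rate and interval-code resolution."""

    fs: float = 500.0
    fm: float = 100.0
    quant_bits: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.fm < self.fs:
            raise ValueError("policy requires 0 < fm < fs")
        if not 1 <= self.quant_bits <= 16:
            raise ValueError("quant_bits must be in [1, 16]")

    @property
    def Ts(self) -> float:
        """Native sampling period [s]."""
        return 1.0 / self.fs

    @property
    def Tm(self) -> float:
        """Longest admissible sampling period [s]."""
        return 1.0 / self.fm

    @property
    def n_levels(self) -> int:
        return 2 ** self.quant_bits

    @property
    def step(self) -> float:
        """Interval quantization step [s]."""
        return (self.Tm - self.Ts) / self.n_levels

    def interval(self, code) -> np.ndarray | float:
        """Quantized sampling interval [s] for code(s) p."""
        return self.Ts + np.asarray(code) * self.step

    def code_for_interval(self, ls) -> np.ndarray:
        """Nearest interval code(s) for raw interval(s) [s], clipped."""
        p = np.rint((np.asarray(ls, dtype=float) - self.Ts) / self.step)
        return np.clip(p, 0, self.n_levels - 1).astype(np.int64)

    def local_interval(self, relevance) -> np.ndarray:
        """Unquantized ls(t) for relevance value(s) in [0, 1]."""
        r = np.asarray(relevance, dtype=float)
        return self.Tm + (self.Ts - self.Tm) * r


@dataclass
class NonUniformECG:
    """Adaptively sampled record: shared interval codes + lead values.

    ``codes[m]`` gives the interval from sample m to sample m+1 (the
    final code pads the stream); sample times follow deterministically
    as ``t_m = m*Ts + step * sum(codes[:m])``. Values are stored as
    ADC integers (``resolution_uv`` microvolts per unit) at
    ``bit_depth`` bits each.
    """

    policy: SamplingPolicy
    codes: np.ndarray
    values_int: np.ndarray      # (n_points, n_leads)
    lead_labels: list[str]
    bit_depth: int = 12
    resolution_uv: float = 10_000.0 / 4096.0
    n_uniform: int = 0          # uniform samples of the covered span

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64).ravel()
        self.values_int = np.atleast_2d(np.asarray(self.values_int, dtype=np.int64))
        if self.values_int.shape[0] != self.codes.size:
            raise ValueError("every lead needs exactly len(codes) values")
        if np.any(self.codes < 0) or np.any(self.codes >= self.policy.n_levels):
            raise NUECGFormatError("interval codes outside the quantizer alphabet")
        if len(self.lead_labels) != self.values_int.shape[1]:
            raise ValueError("one label per lead required")

    @property
    def n_points(self) -> int:
        return self.codes.size

    @property
    def n_leads(self) -> int:
        return self.values_int.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Implied sample times [s], identical in encoder and decoder."""
        m = np.arange(self.n_points, dtype=float)
        csum = np.concatenate([[0], np.cumsum(self.codes[:-1])]).astype(float)
        return m * self.policy.Ts + csum * self.policy.step

    @property
    def values_uv(self) -> np.ndarray:
        return self.values_int * self.resolution_uv

    @property
    def payload_bits(self) -> int:
        """Side channel plus sample payload, header excluded."""
        return self.n_points * self.policy.quant_bits \
            + self.n_points * self.n_leads * self.bit_depth

    def __eq__(self, other) -> bool:
        if not isinstance(other, NonUniformECG):
            return NotImplemented
        return (
            self.policy == other.policy
            and self.bit_depth == other.bit_depth
            and self.n_uniform == other.n_uniform
            and self.resolution_uv == other.resolution_uv
            and self.lead_labels == other.lead_labels
            and np.array_equal(self.codes, other.codes)
            and np.array_equal(self.values_int, other.values_int)
        )


# ----------------------------------------------------- interval sequence

def intervals_from_mrf(
    amrf: AdaptedMRF | np.ndarray, policy: SamplingPolicy, fs: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Walk the record, emitting (times, codes) of the non-uniform grid.

    Starting at t=0 the local interval ls(t) is read off the adapted
    relevance (linearly interpolated between uniform samples),
    quantized to the policy's code grid, and the quantized interval
    advances the clock. The walk stops with the first sample at or
    beyond the last uniform sample, so the non-uniform grid covers the
    whole span.
    """
    if isinstance(amrf, AdaptedMRF):
        values, fs = amrf.values, amrf.fs
    else:
        values = np.asarray(amrf, dtype=float)
        if fs is None:
            raise ValueError("fs required when amrf is a bare array")
    if values.size == 0:
        raise ValueError("empty adapted MRF")
    grid_t = np.arange(values.size) / fs
    t_end = grid_t[-1]
    Ts, step, pmax = policy.Ts, policy.step, policy.n_levels - 1

    codes: list[int] = []
    csum = 0
    m = 0
    t = 0.0
    while True:
        rel = float(np.interp(t, grid_t, values))
        ls = policy.Tm + (Ts - policy.Tm) * rel
        p = int(min(max(round((ls - Ts) / step), 0), pmax))
        codes.append(p)
        if t >= t_end - 1e-12:
            break
        csum += p
        m += 1
        t = m * Ts + csum * step

    codes_arr = np.asarray(codes, dtype=np.int64)
    m_idx = np.arange(codes_arr.size, dtype=float)
    csum_arr = np.concatenate([[0], np.cumsum(codes_arr[:-1])]).astype(float)
    times = m_idx * Ts + csum_arr * step
    return times, codes_arr


# ----------------------------------------------------------- anti-alias

_N_TAPS = 11  # FIR order 10


@lru_cache(maxsize=8)
def _kernel_bank(fs: float, fm: float, quant_bits: int) -> np.ndarray:
    """One zero-phase low-pass kernel per interval code.

    Each kernel is an order-10 linear-phase FIR least-squares fitted to
    the gentle first-order magnitude |H(f)| = 1/sqrt(1 + (f/fc)^2)
    (6 dB/octave roll-off) with fc = 0.45 x the code's local sampling
    rate; DC gain is normalized to exactly one. Code 0 (native rate)
    maps to the identity impulse.
    """
    policy = SamplingPolicy(fs=fs, fm=fm, quant_bits=quant_bits)
    nyq = fs / 2.0
    freqs = np.linspace(0.0, nyq, 256)
    bank = np.empty((policy.n_levels, _N_TAPS))
    delta = np.zeros(_N_TAPS)
    delta[_N_TAPS // 2] = 1.0
    bank[0] = delta
    for p in range(1, policy.n_levels):
        fc = 0.45 / policy.interval(p)
        gain = 1.0 / np.sqrt(1.0 + (freqs / fc) ** 2)
        h = firwin2(_N_TAPS, freqs, gain, fs=fs)
        bank[p] = h / h.sum()
    return bank


def design_kernel(code: int, policy: SamplingPolicy) -> np.ndarray:
    """The anti-alias kernel used for a given interval code."""
    bank = _kernel_bank(policy.fs, policy.fm, policy.quant_bits)
    return bank[int(code)].copy()


def antialias(ecg: UniformECG, local_fs: np.ndarray | float,
              policy: SamplingPolicy | None = None) -> UniformECG:
    """Time-varying low-pass on the uniform grid.

    ``local_fs`` gives the local sampling rate (Hz) at every sample (a
    scalar broadcasts); each sample of the output is the input
    convolved with the kernel of the nearest interval code. Kernels are
    symmetric, so the output is phase-aligned with the input (edges use
    reflection padding). Rates outside [fm, fs] are clipped with a
    warning.
    """
    policy = policy or SamplingPolicy(fs=ecg.fs)
    rates = np.broadcast_to(np.asarray(local_fs, dtype=float),
                            (ecg.n_samples,)).copy()
    if np.any(rates < policy.fm - 1e-9) or np.any(rates > policy.fs + 1e-9):
        warnings.warn("local_fs outside [fm, fs]; clipping", stacklevel=2)
        rates = np.clip(rates, policy.fm, policy.fs)
    codes = policy.code_for_interval(1.0 / rates)

    half = _N_TAPS // 2
    padded = np.pad(ecg.data, ((half, half), (0, 0)), mode="reflect")
    bank = _kernel_bank(policy.fs, policy.fm, policy.quant_bits)
    out = np.empty_like(ecg.data)
    for p in np.unique(codes):
        rows = codes == p
        if p == 0:
            out[rows] = ecg.data[rows]
            continue
        kernel = bank[p]
        for j in range(ecg.n_leads):
            filt = np.convolve(padded[:, j], kernel, mode="valid")
            out[rows, j] = filt[rows]
    return ecg.with_data(out)


# -------------------------------------------------------- encode/decode

def encode(
    ecg: UniformECG,
    template: MRFTemplate,
    policy: SamplingPolicy | None = None,
    annotations: list[BeatAnnotation] | None = None,
    amrf: AdaptedMRF | np.ndarray | None = None,
    apply_antialias: bool = True,
    bit_depth: int = 12,
) -> NonUniformECG:
    """Encode a uniform record into its non-uniform representation.

    Wave borders come from ``annotations`` if supplied (the drop-in
    substitute for the built-in delineator), else from
    :func:`adaptecg.delineate.delineate`; ``amrf`` overrides the whole
    relevance-adaptation stage. If no beat is found the record is coded
    at maximum relevance (code 0 everywhere) with a warning.
    """
    policy = policy or SamplingPolicy(fs=ecg.fs)
    if abs(ecg.fs - policy.fs) > 1e-9:
        raise ValueError(
            f"record sampled at {ecg.fs} Hz but policy expects {policy.fs} Hz"
        )

    if amrf is None:
        if annotations is None:
            beats = _detect_beats(ecg)
            annotations = _delineate_waves(ecg, beats) if len(beats) else []
        if not annotations:
            warnings.warn("no beats found; coding at maximum relevance",
                          stacklevel=2)
            amrf = AdaptedMRF(np.ones(ecg.n_samples), ecg.fs)
        else:
            amrf = adapt(template, annotations, ecg.n_samples, ecg.fs)
    elif not isinstance(amrf, AdaptedMRF):
        amrf = AdaptedMRF(np.asarray(amrf, dtype=float), ecg.fs)
    if len(amrf) != ecg.n_samples:
        raise ValueError("adapted MRF must cover the whole record")

    times, codes = intervals_from_mrf(amrf, policy)

    if apply_antialias:
        local_rates = 1.0 / policy.local_interval(amrf.values)
        filtered = antialias(ecg, local_rates, policy)
    else:
        filtered = ecg

    spline = CubicSpline(ecg.times, filtered.data, axis=0, bc_type="not-a-knot")
    sampled = spline(times)

    half_range = 2 ** (bit_depth - 1)
    ints = np.rint(sampled / ecg.resolution_uv).astype(np.int64)
    ints = np.clip(ints, -half_range, half_range - 1)

    return NonUniformECG(
        policy=policy,
        codes=codes,
        values_int=ints,
        lead_labels=list(ecg.lead_labels),
        bit_depth=bit_depth,
        resolution_uv=ecg.resolution_uv,
        n_uniform=ecg.n_samples,
    )


def decode(nu: NonUniformECG) -> UniformECG:
    """Reconstruct the uniform record from a non-uniform representation.

    A not-a-knot cubic spline is fitted per lead through the
    (implied time, value) pairs and evaluated on the original uniform
    grid.
    """
    times = nu.times
    if times.size < 4:
        raise NUECGFormatError("too few samples for cubic reconstruction")
    if np.any(np.diff(times) <= 0):
        raise NUECGFormatError("implied sample times are not increasing")
    n = nu.n_uniform if nu.n_uniform > 0 else int(np.floor(times[-1] * nu.policy.fs)) + 1
    grid = np.arange(n) / nu.policy.fs
    spline = CubicSpline(times, nu.values_uv, axis=0, bc_type="not-a-knot")
    return UniformECG(
        data=spline(grid),
        fs=nu.policy.fs,
        lead_labels=list(nu.lead_labels),
        resolution_uv=nu.resolution_uv,
    )


# ------------------------------------------------------------ container

_MAGIC = b"NUECG1"
_VERSION = 1
# magic, version, n_leads, quant_bits, bit_depth, fs, fm, n_codes,
# n_uniform, resolution in nV/LSB
_HEADER = struct.Struct("<6sBBBBddIId")


def _pack_bits(values: np.ndarray, bits: int) -> bytes:
    shifts = np.arange(bits - 1, -1, -1)
    bitmat = ((values[:, None] >> shifts[None, :]) & 1).astype(np.uint8)
    return np.packbits(bitmat.ravel()).tobytes()


def _unpack_bits(buf: bytes, count: int, bits: int) -> np.ndarray:
    raw = np.frombuffer(buf, dtype=np.uint8)
    bitvec = np.unpackbits(raw)[: count * bits]
    if bitvec.size < count * bits:
        raise NUECGFormatError("truncated payload")
    bitmat = bitvec.reshape(count, bits).astype(np.int64)
    weights = 1 << np.arange(bits - 1, -1, -1)
    return bitmat @ weights


def write_nuecg(nu: NonUniformECG, path) -> None:
    """Write the bit-packed binary NUECG container."""
    header = _HEADER.pack(
        _MAGIC, _VERSION, nu.n_leads, nu.policy.quant_bits, nu.bit_depth,
        nu.policy.fs, nu.policy.fm, nu.n_points, nu.n_uniform,
        nu.resolution_uv * 1000.0,
    )
    labels = b"".join(
        bytes([len(lbl)]) + lbl.encode("ascii") for lbl in nu.lead_labels
    )
    offset = 1 << (nu.bit_depth - 1)
    samples = (nu.values_int.T.ravel() + offset).astype(np.int64)
    if np.any(samples < 0) or np.any(samples >= (1 << nu.bit_depth)):
        raise ValueError("sample values exceed the container bit depth")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(labels)
        fh.write(_pack_bits(nu.codes, nu.policy.quant_bits))
        fh.write(_pack_bits(samples, nu.bit_depth))


def read_nuecg(path) -> NonUniformECG:
    """Read a NUECG container, validating magic, header and length."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < _HEADER.size or blob[:6] != _MAGIC:
        raise NUECGFormatError(f"{path}: not a NUECG container")
    (magic, version, n_leads, quant_bits, bit_depth, fs, fm,
     n_codes, n_uniform, res_nv) = _HEADER.unpack_from(blob)
    if version != _VERSION:
        raise NUECGFormatError(f"{path}: unsupported version {version}")
    pos = _HEADER.size
    labels = []
    for _ in range(n_leads):
        if pos >= len(blob):
            raise NUECGFormatError(f"{path}: truncated lead labels")
        ln = blob[pos]
        pos += 1
        if pos + ln > len(blob):
            raise NUECGFormatError(f"{path}: truncated lead labels")
        labels.append(blob[pos:pos + ln].decode("ascii"))
        pos += ln
    code_bytes = (n_codes * quant_bits + 7) // 8
    sample_bytes = (n_codes * n_leads * bit_depth + 7) // 8
    if len(blob) - pos != code_bytes + sample_bytes:
        raise NUECGFormatError(
            f"{path}: payload length mismatch "
            f"(expected {code_bytes + sample_bytes}, got {len(blob) - pos})"
        )
    codes = _unpack_bits(blob[pos:pos + code_bytes], n_codes, quant_bits)
    pos += code_bytes
    samples = _unpack_bits(blob[pos:], n_codes * n_leads, bit_depth)
    offset = 1 << (bit_depth - 1)
    values = samples.reshape(n_leads, n_codes).T - offset
    return NonUniformECG(
        policy=SamplingPolicy(fs=fs, fm=fm, quant_bits=quant_bits),
        codes=codes,
        values_int=values,
        lead_labels=labels,
        bit_depth=bit_depth,
        resolution_uv=res_nv / 1000.0,
        n_uniform=n_uniform,
    )
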