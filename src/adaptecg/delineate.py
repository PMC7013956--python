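"""Heartbeat detection and wave-border delineation.

QRS detection is a classical band-pass / squared-derivative energy
detector with an adaptive threshold and a 200 ms refractory period.
Wave borders are then sought jointly for all leads on the root-mean-
square combination of the channels: for each wave the smoothed
derivative-energy envelope is followed outward from the wave peak
until it falls below twice the local noise level — the point where the
wave's energy disappears into the background. Two envelope variants
are used: a wider-band, lightly smoothed one for the steep QRS
borders, and a narrower-band, heavier-smoothed one for the gentle
P and T borders.

Externally supplied annotations (e.g. database reference borders) are
a drop-in substitute: every consumer of this module accepts a
``list[BeatAnnotation]`` regardless of origin.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

from .containers import BeatAnnotation, UniformECG

__all__ = ["detect_beats", "delineate"]

REFRACTORY_S = 0.2
_NOISE_PERCENTILE = 20.0
_NOISE_FACTOR = 2.0        # k in the "k x noise RMS" border criterion
# Envelope floor relative to the wave's peak derivative envelope. For a
# Gaussian wave the derivative envelope falls to ~5.5 % of its peak
# three widths from the centre, so 5 % marks the point where the wave
# energy has effectively vanished even in noise-free signals.
_ENV_FLOOR_FRACTION = 0.05


def _rms_combine(data: np.ndarray) -> np.ndarray:
    centered = data - np.median(data, axis=0, keepdims=True)
    return np.sqrt(np.mean(centered**2, axis=1))


def detect_beats(ecg: UniformECG) -> np.ndarray:
    """QRS fiducial positions (sample units), strictly increasing.

    Band-pass 5-25 Hz, square, integrate over 150 ms, pick peaks above
    an adaptive (purely relative) threshold with a 200 ms refractory
    period, then refine each fiducial to the local maximum of the
    band-passed RMS amplitude. A flat record yields an empty list.
    """
    if ecg.duration_s < 2.0:
        raise ValueError("need at least 2 s of signal for beat detection")
    fs = ecg.fs
    sos = butter(2, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    bp = sosfiltfilt(sos, ecg.data, axis=0)
    combined = np.sqrt(np.mean(bp**2, axis=1))
    if combined.max() <= 0:
        return np.array([])

    win = max(1, int(round(0.150 * fs)))
    energy = np.convolve(combined**2, np.ones(win) / win, mode="same")
    height = 0.25 * np.percentile(energy, 99.5)
    if height <= 0:
        return np.array([])
    peaks, _ = find_peaks(energy, height=height,
                          distance=max(1, int(round(REFRACTORY_S * fs))))
    refine = max(1, int(round(0.075 * fs)))
    fiducials = []
    for p in peaks:
        lo, hi = max(0, p - refine), min(len(combined), p + refine + 1)
        fiducials.append(lo + int(np.argmax(combined[lo:hi])))
    fiducials = sorted(set(fiducials))
    out = []
    for f in fiducials:  # enforce refractory after refinement
        if not out or f - out[-1] >= REFRACTORY_S * fs:
            out.append(f)
    return np.asarray(out, dtype=float)


def _cross_backward(env: np.ndarray, start: int, stop: int,
                    thr: float, run: int) -> float | None:
    """First position left of ``start`` where env stays < thr for ``run``."""
    count = 0
    for i in range(start, max(stop, 0) - 1, -1):
        if env[i] < thr:
            count += 1
            if count >= run:
                return float(i + run - 1)
        else:
            count = 0
    return None


def _cross_forward(env: np.ndarray, start: int, stop: int,
                   thr: float, run: int) -> float | None:
    count = 0
    for i in range(start, min(stop, env.size - 1) + 1):
        if env[i] < thr:
            count += 1
            if count >= run:
                return float(i - run + 1)
        else:
            count = 0
    return None


def _lowpass(x: np.ndarray, fc: float, fs: float) -> np.ndarray:
    sos = butter(4, fc, btype="lowpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def delineate(
    ecg: UniformECG, beats: np.ndarray | list[float]
) -> list[BeatAnnotation]:
    """Five wave borders per resolvable beat, jointly over all leads.

    Beats whose P or T wave cannot be separated from the noise floor
    are dropped (flagged); downstream coding covers such spans at
    maximum relevance.
    """
    beats = np.asarray(beats, dtype=float)
    if beats.size == 0:
        return []
    fs = ecg.fs
    n = ecg.n_samples
    xc = _rms_combine(ecg.data)

    x_q = _lowpass(xc, 40.0, fs)
    x_pt = _lowpass(xc, 25.0, fs)
    env_q = np.sqrt(gaussian_filter1d(np.gradient(x_q) ** 2 * fs**2,
                                      sigma=max(1.0, 0.006 * fs)))
    env_pt = np.sqrt(gaussian_filter1d(np.gradient(x_pt) ** 2 * fs**2,
                                       sigma=max(1.0, 0.008 * fs)))
    noise_q = np.percentile(env_q, _NOISE_PERCENTILE)
    noise_pt = np.percentile(env_pt, _NOISE_PERCENTILE)
    base = np.median(x_pt)

    rr = float(np.median(np.diff(beats))) if beats.size > 1 \
        else min(1.0 * fs, n / 2.0)
    run = max(2, int(round(0.006 * fs)))

    annotations: list[BeatAnnotation] = []
    prev_t_end = -1.0
    for idx, r_f in enumerate(beats):
        r = int(round(r_f))
        # --- QRS borders ------------------------------------------------
        lo = max(0, r - int(0.15 * fs))
        hi = min(n - 1, r + int(0.15 * fs))
        pk_q = env_q[max(0, r - int(0.04 * fs)):min(n, r + int(0.04 * fs))].max()
        thr_q = max(_NOISE_FACTOR * noise_q, _ENV_FLOOR_FRACTION * pk_q)
        qrs_on = _cross_backward(env_q, r, lo, thr_q, run)
        qrs_end = _cross_forward(env_q, r, hi, thr_q, run)
        if qrs_on is None or qrs_end is None:
            continue

        # --- T wave -----------------------------------------------------
        t_lo = int(qrs_end + 0.04 * fs)
        t_hi = min(n - 1, int(r + 0.75 * rr))
        if t_hi - t_lo < int(0.06 * fs):
            continue
        tp = t_lo + int(np.argmax(np.abs(x_pt[t_lo:t_hi] - base)))
        fall_lo = min(tp + 1, t_hi)
        fall = fall_lo + int(np.argmax(env_pt[fall_lo:t_hi + 1]))
        pk_t = env_pt[fall]
        if pk_t < _NOISE_FACTOR * noise_pt:
            continue  # T wave below noise floor: unresolvable
        thr_t = max(_NOISE_FACTOR * noise_pt, _ENV_FLOOR_FRACTION * pk_t)
        t_end = _cross_forward(env_pt, fall, t_hi, thr_t, run)
        if t_end is None:  # skirts overlap: take the energy minimum
            t_end = float(fall + np.argmin(env_pt[fall:t_hi + 1]))

        # --- P wave -----------------------------------------------------
        p_lo = max(0, int(r - 0.32 * fs), int(prev_t_end) + 1)
        p_hi = int(qrs_on - 0.012 * fs)
        if p_hi - p_lo < int(0.03 * fs):
            continue
        pp = p_lo + int(np.argmax(np.abs(x_pt[p_lo:p_hi] - base)))
        rise = p_lo + int(np.argmax(env_pt[p_lo:pp + 1]))
        fall_p = pp + int(np.argmax(env_pt[pp:p_hi + 1]))
        pk_p = max(env_pt[rise], env_pt[fall_p])
        if pk_p < _NOISE_FACTOR * noise_pt:
            continue  # P wave below noise floor: unresolvable
        thr_p = max(_NOISE_FACTOR * noise_pt, _ENV_FLOOR_FRACTION * pk_p)
        p_on = _cross_backward(env_pt, rise, p_lo, thr_p, run)
        p_end = _cross_forward(env_pt, fall_p, p_hi, thr_p, run)
        if p_on is None:  # skirts overlap: take the energy minimum
            p_on = float(p_lo + np.argmin(env_pt[p_lo:rise + 1]))
        if p_end is None:
            p_end = float(fall_p + np.argmin(env_pt[fall_p:p_hi + 1]))

        # --- assemble, enforcing strict ordering ------------------------
        p_end = min(p_end, qrs_on - 1.0)
        p_on = min(p_on, p_end - 1.0)
        t_end = max(t_end, qrs_end + 1.0)
        if not (0 <= p_on < p_end < qrs_on < qrs_end < t_end < n):
            continue
        annotations.append(
            BeatAnnotation(len(annotations), p_on, p_end, qrs_on, qrs_end, t_end)
        )
        prev_t_end = t_end
    return annotations
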