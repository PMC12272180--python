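"""Time-frequency analysis of WM retention: ERP subtraction, mirror
padding, Morlet transform, dB baselining, individual alpha frequency and
alpha time-course contrasts at Pz.

The Morlet wavelet has a fixed Gaussian envelope of 5 cycles at every
frequency (sigma_t = n_cycles / (2 pi f)), evaluated on a +-5 sigma_t
support and normalized to unit envelope sum, so that a unit-amplitude
sinusoid at the wavelet frequency yields an amplitude estimate of 1/2
(power 1/4).  All power ratios (dB values) are independent of this
normalization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .permutation import windowed_percentile_test

logger = logging.getLogger(__name__)

__all__ = [
    "TimeFreqMap", "subtract_erp", "mirror_pad", "morlet_wavelet",
    "morlet_tfr", "db_baseline", "individual_alpha", "alpha_contrasts",
    "trim_retention", "ALPHA_BAND", "ANALYSIS_WINDOWS", "RETENTION_TRIM",
]

ALPHA_BAND = (8, 12)
#: Permutation-test windows within retention, seconds (half-open).
ANALYSIS_WINDOWS = ((2.0, 3.5), (3.5, 5.0))
#: Seconds trimmed from each edge of the retention window.
RETENTION_TRIM = 0.5


@dataclass
class TimeFreqMap:
    """Power by (frequency, time) for one channel / trial phase."""

    power: np.ndarray          # (n_freqs, n_times)
    frequencies: np.ndarray    # Hz
    times: np.ndarray          # s
    channel: str = ""
    units: str = "raw"         # "raw" or "dB"


def subtract_erp(data: np.ndarray, rate: float, events: pd.DataFrame,
                 erp_bank: dict, erp_start: float = -0.1) -> np.ndarray:
    """Subtract phase/condition/position-matched average ERPs in place
    of each stimulus event.

    ``erp_bank`` maps ``(phase, position)`` or richer keys (any tuple of
    metadata columns ending with the bank's ``key_cols``) to an average
    ERP array (channels x epoch length) whose first sample sits
    ``erp_start`` seconds before the stimulus.  Events without a bank
    entry are left untouched with a logged warning.
    """
    out = np.array(data, dtype=float, copy=True)
    n = out.shape[1]
    missing = []
    for _, ev in events.iterrows():
        key = ev.get("erp_key", (ev["phase"], ev["position"]))
        erp = erp_bank.get(key)
        if erp is None:
            missing.append(key)
            continue
        i0 = int(round((ev["time"] + erp_start) * rate))
        i1 = i0 + erp.shape[1]
        lo, hi = max(i0, 0), min(i1, n)
        if lo < hi:
            out[:, lo:hi] -= erp[:, lo - i0:hi - i0]
    if missing:
        logger.warning("no ERP bank entry for %d events (e.g. %s); "
                       "nothing subtracted", len(missing), missing[0])
    return out


def mirror_pad(x: np.ndarray, pad_samples: int | None = None,
               rate: float | None = None, pad_s: float = 5.0):
    """Append time-reversed copies of the signal's edges.

    ``padded = reverse(x[:P]) ++ x ++ reverse(x[-P:])`` where P is the pad
    length (5 s by default).  Returns ``(padded, unpad_slice)`` so that
    ``padded[unpad_slice]`` recovers ``x`` exactly.  If the signal is
    shorter than the requested pad, the full signal is reflected instead
    (logged).
    """
    x = np.asarray(x)
    n = x.shape[-1]
    if pad_samples is None:
        if rate is None:
            raise ValueError("give pad_samples or rate")
        pad_samples = int(round(pad_s * rate))
    if pad_samples > n:
        logger.warning("signal (%d samples) shorter than pad (%d); using "
                       "full-length reflection", n, pad_samples)
        pad_samples = n
    left = x[..., :pad_samples][..., ::-1]
    right = x[..., -pad_samples:][..., ::-1]
    padded = np.concatenate([left, x, right], axis=-1)
    return padded, slice(pad_samples, pad_samples + n)


def morlet_wavelet(freq: float, rate: float, n_cycles: float = 5.0,
                   n_sigmas: float = 5.0) -> np.ndarray:
    """Complex Morlet wavelet with a fixed-cycle Gaussian envelope.

    The envelope SD is ``n_cycles / (2 pi f)`` seconds; the wavelet is
    normalized so its envelope sums to 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(n_sigmas * sigma_t * rate))
    t = np.arange(-half, half + 1) / rate
    envelope = np.exp(-0.5 * (t / sigma_t) ** 2)
    w = envelope * np.exp(2j * np.pi * freq * t)
    return w / envelope.sum()


def morlet_tfr(x: np.ndarray, rate: float, freqs, n_cycles: float = 5.0,
               unpad: slice | None = None) -> TimeFreqMap:
    """Continuous Morlet transform: power per (frequency, time).

    ``x`` is a 1-D (already mirror-padded) signal; ``unpad`` trims the
    padding from the output.  Frequencies at or above Nyquist raise.
    """
    x = np.asarray(x, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if (freqs >= rate / 2).any():
        raise ValueError("frequency at or above Nyquist")
    if (freqs <= 0).any():
        raise ValueError("frequencies must be positive")
    power = np.empty((freqs.size, x.size))
    for i, f in enumerate(freqs):
        w = morlet_wavelet(f, rate, n_cycles)
        if w.size > x.size:
            raise ValueError(
                f"signal too short for the {f:g} Hz wavelet; pad it first")
        coef = signal.fftconvolve(x, w, mode="same")
        power[i] = np.abs(coef) ** 2
    if unpad is not None:
        power = power[:, unpad]
        n = power.shape[1]
    else:
        n = x.size
    times = np.arange(n) / rate
    return TimeFreqMap(power=power, frequencies=freqs, times=times)


def db_baseline(tfr: TimeFreqMap, baseline_power: np.ndarray) -> TimeFreqMap:
    """Express power as dB change relative to per-frequency baseline power.

    ``baseline_power`` is the mean power over the pre-trial baseline
    window, averaged across all of a participant's conditions (so that
    permuting condition labels leaves it unchanged).
    """
    base = np.asarray(baseline_power, dtype=float).reshape(-1, 1)
    if base.shape[0] != tfr.power.shape[0]:
        raise ValueError("baseline must provide one value per frequency")
    if (base <= 0).any():
        raise ValueError("baseline power must be positive")
    return TimeFreqMap(power=10.0 * np.log10(tfr.power / base),
                       frequencies=tfr.frequencies, times=tfr.times,
                       channel=tfr.channel, units="dB")


def individual_alpha(db_map: TimeFreqMap, band: tuple = ALPHA_BAND):
    """Individual alpha frequency and three-frequency alpha time course.

    ``db_map`` is the dB change map at Pz over the trimmed retention
    window.  The IAF is the integer frequency in ``band`` at which the
    absolute mean dB change is maximal (ties broken toward the lower
    frequency); the time course is the mean dB power over
    {IAF-1, IAF, IAF+1} Hz.

    Returns ``(iaf, timecourse)``.
    """
    freqs = db_map.frequencies
    band_freqs = np.arange(band[0], band[1] + 1)
    need = np.arange(band[0] - 1, band[1] + 2)
    if not np.isin(need, freqs).all():
        raise ValueError("dB map must cover the band plus 1 Hz margins")
    mean_change = np.array([
        np.abs(db_map.power[np.flatnonzero(freqs == f)[0]].mean())
        for f in band_freqs])
    iaf = int(band_freqs[int(np.argmax(mean_change))])  # argmax: first max wins
    rows = [np.flatnonzero(freqs == f)[0] for f in (iaf - 1, iaf, iaf + 1)]
    return iaf, db_map.power[rows].mean(axis=0)


def trim_retention(times: np.ndarray, retention: tuple = (0.0, 5.5),
                   trim: float = RETENTION_TRIM) -> np.ndarray:
    """Boolean mask for the retention window with 500 ms edges excluded."""
    return (times >= retention[0] + trim) & (times < retention[1] - trim)


def alpha_contrasts(timecourses: dict, times: np.ndarray,
                    contrasts=(("none", "AT"), ("none", "AS"), ("AT", "AS")),
                    windows=ANALYSIS_WINDOWS, n_iter: int = 2000,
                    alpha: float = 0.05, rng=None) -> dict:
    """Window-restricted percentile permutation tests between conditions.

    ``timecourses`` maps an Intervening condition label to a
    (participants x times) array of alpha time courses (WM-domain
    collapsed, one WM modality at a time).  Returns
    ``{(cond_a, cond_b, window): (significant_mask, PermutationResult)}``.
    """
    out = {}
    rng = rng or np.random.default_rng()
    for a, b in contrasts:
        if a not in timecourses or b not in timecourses:
            continue
        for window in windows:
            out[(a, b, window)] = windowed_percentile_test(
                timecourses[a], timecourses[b], times, window,
                n_iter=n_iter, alpha=alpha, rng=rng)
    return out
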