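"""Pupillometry cleaning pipeline.

Blink detection by position/velocity/acceleration thresholds, linear
interpolation over blink segments (edge segments back-projected from a
5-sample least-squares fit), trial rejection at >25% masked data,
binocular averaging, participant-wise z-scoring of the concatenated
trials, and condition averaging / Intervening-minus-none differences.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import (TRIG_BASELINE_START, TRIG_ENCODING,
                         TRIG_ENCODING_OFFSET, TRIG_PROBE, PupilRecording,
                         PupilTrace)

logger = logging.getLogger(__name__)

__all__ = [
    "BlinkThresholds", "auto_thresholds", "detect_blinks",
    "interpolate_blinks", "reject_trials", "average_eyes",
    "zscore_concatenated", "condition_difference", "segment_trials",
    "clean_trace", "condition_average", "UnrecoverableTraceError",
]


class UnrecoverableTraceError(ValueError):
    """A blink segment left too few clean anchor samples to interpolate."""


@dataclass
class BlinkThresholds:
    """Thresholds for blink detection.

    ``position_bounds`` are absolute diameter bounds (a.u.);
    ``velocity_limit`` / ``acceleration_limit`` bound the absolute first /
    second derivative in a.u./s and a.u./s^2.  Each detected event is
    dilated by ``pad_samples`` on both sides and overlapping events are
    merged.
    """

    position_bounds: tuple | None = None
    velocity_limit: float | None = None
    acceleration_limit: float | None = None
    pad_samples: int = 10

    def __post_init__(self) -> None:
        for v in (self.velocity_limit, self.acceleration_limit):
            if v is not None and v <= 0:
                raise ValueError("limits must be > 0")


def auto_thresholds(samples: np.ndarray, rate: float,
                    velocity_mult: float = 10.0,
                    acceleration_mult: float = 10.0,
                    position_mads: float = 5.0,
                    pad_samples: int = 10) -> BlinkThresholds:
    """Data-driven thresholds: multiples of the trace's own robust scale.

    Velocity/acceleration limits are ``mult`` times the median absolute
    first/second difference (converted to per-second units); position
    bounds are ``median +- position_mads * MAD``.
    """
    x = np.asarray(samples, dtype=float)
    d1 = np.abs(np.diff(x))
    d2 = np.abs(np.diff(x, 2))
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    # floor the robust scales at a small fraction of the typical diameter so
    # that near-noise-free traces do not collapse the thresholds to zero
    scale = max(abs(med), float(x.max() - x.min()), 1e-12)
    mad = max(mad, 0.05 * scale)
    vel = max(np.median(d1), 1e-3 * scale) * velocity_mult * rate
    acc = max(np.median(d2), 1e-3 * scale) * acceleration_mult * rate ** 2
    return BlinkThresholds(position_bounds=(med - position_mads * mad,
                                            med + position_mads * mad),
                           velocity_limit=vel, acceleration_limit=acc,
                           pad_samples=pad_samples)


def detect_blinks(samples: np.ndarray, rate: float,
                  thresholds: BlinkThresholds | None = None,
                  extra_mask: np.ndarray | None = None) -> np.ndarray:
    """Boolean blink mask from position/velocity/acceleration thresholds.

    ``extra_mask`` allows a machine-readable override (manually marked
    intervals) to be merged in before padding.
    """
    x = np.asarray(samples, dtype=float)
    thr = thresholds or auto_thresholds(x, rate)
    mask = np.zeros(x.size, dtype=bool)
    if thr.position_bounds is not None:
        lo, hi = thr.position_bounds
        mask |= (x < lo) | (x > hi)
    if thr.velocity_limit is not None and x.size > 1:
        vel = np.abs(np.diff(x)) * rate
        hit = vel > thr.velocity_limit
        mask[:-1] |= hit
        mask[1:] |= hit
    if thr.acceleration_limit is not None and x.size > 2:
        acc = np.abs(np.diff(x, 2)) * rate ** 2
        hit = acc > thr.acceleration_limit
        mask[1:-1] |= hit
    if extra_mask is not None:
        mask |= np.asarray(extra_mask, dtype=bool)
    if thr.pad_samples and mask.any():
        structure = np.ones(2 * thr.pad_samples + 1, dtype=bool)
        mask = ndimage.binary_dilation(mask, structure=structure)
    return mask


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs, stop exclusive."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _lsq_line(y: np.ndarray):
    """Least-squares slope/intercept of y over x = 0..len(y)-1."""
    x = np.arange(y.size, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    return slope, intercept


def interpolate_blinks(samples: np.ndarray, mask: np.ndarray,
                       n_anchor: int = 3, n_edge_fit: int = 5) -> np.ndarray:
    """Replace masked segments by linear interpolation.

    Interior segments are replaced by the straight line joining the mean
    of the ``n_anchor`` clean samples preceding the segment to the mean of
    the ``n_anchor`` following it.  A segment touching the window start is
    filled by back-projecting a least-squares line fit to the
    ``n_edge_fit`` clean samples after it; segments touching the window
    end use the mirrored rule.

    Raises :class:`UnrecoverableTraceError` when a segment does not have
    enough clean anchor samples.
    """
    x = np.asarray(samples, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.size != x.size:
        raise ValueError("mask length must equal sample length")
    for start, stop in _runs(mask):
        at_start, at_end = start == 0, stop == x.size
        seg = np.arange(start, stop)
        if at_start and at_end:
            raise UnrecoverableTraceError("entire trace masked")
        if at_start:
            anchors = x[stop:stop + n_edge_fit]
            if anchors.size < n_edge_fit or mask[stop:stop + n_edge_fit].any():
                raise UnrecoverableTraceError(
                    "edge blink without 5 clean following samples")
            slope, intercept = _lsq_line(anchors)
            x[seg] = intercept + slope * (seg - stop)
        elif at_end:
            anchors = x[start - n_edge_fit:start]
            if anchors.size < n_edge_fit or mask[start - n_edge_fit:start].any():
                raise UnrecoverableTraceError(
                    "edge blink without 5 clean preceding samples")
            slope, intercept = _lsq_line(anchors)
            x[seg] = intercept + slope * (seg - (start - n_edge_fit))
        else:
            pre = x[max(0, start - n_anchor):start]
            post = x[stop:stop + n_anchor]
            if (pre.size < n_anchor or post.size < n_anchor
                    or mask[max(0, start - n_anchor):start].any()
                    or mask[stop:stop + n_anchor].any()):
                raise UnrecoverableTraceError(
                    "interior blink without 3 clean anchor samples per side")
            a, b = pre.mean(), post.mean()
            # line from the pre-anchor value to the post-anchor value
            frac = (seg - (start - 1)) / (stop - (start - 1))
            x[seg] = a + (b - a) * frac
        mask = mask.copy()
        mask[seg] = False  # interpolated samples may anchor later segments
    return x


def clean_trace(trace: PupilTrace,
                thresholds: BlinkThresholds | None = None,
                extra_mask: np.ndarray | None = None) -> PupilTrace:
    """Detect + interpolate blinks; flags the trace rejected if unrecoverable."""
    mask = detect_blinks(trace.samples, trace.rate, thresholds, extra_mask)
    out = PupilTrace(trace.samples, trace.rate, trace.t0, trace.eye,
                     blink_mask=mask, info=dict(trace.info))
    try:
        out.samples = interpolate_blinks(trace.samples, mask)
    except UnrecoverableTraceError as err:
        logger.warning("trace unrecoverable: %s", err)
        out.rejected = True
    return out


def reject_trials(trials, max_masked_fraction: float = 0.25):
    """Keep trials whose masked fraction is <= the limit (strict 'more than').

    Returns ``(kept_trials, report)`` where the report is a DataFrame with
    one row per trial (masked fraction, kept flag, reason).
    """
    kept, rows = [], []
    for k, tr in enumerate(trials):
        frac = 0.0 if tr.blink_mask is None else float(tr.blink_mask.mean())
        ok = (frac <= max_masked_fraction) and not tr.rejected
        reason = ("unrecoverable" if tr.rejected
                  else ("masked_fraction" if frac > max_masked_fraction else ""))
        rows.append({"trial": k, "masked_fraction": frac,
                     "kept": ok, "reason": reason})
        if ok:
            kept.append(tr)
    return kept, pd.DataFrame(rows)


def average_eyes(left: PupilTrace | None, right: PupilTrace | None) -> PupilTrace:
    """Samplewise mean of the two eyes; a single available eye passes through."""
    if left is None and right is None:
        raise ValueError("at least one eye required")
    if left is None or right is None:
        only = left if right is None else right
        return PupilTrace(only.samples.copy(), only.rate, only.t0, only.eye,
                          blink_mask=only.blink_mask, info=dict(only.info))
    if left.samples.size != right.samples.size:
        raise ValueError("eye traces differ in length")
    mask = None
    if left.blink_mask is not None or right.blink_mask is not None:
        lm = left.blink_mask if left.blink_mask is not None else \
            np.zeros(left.samples.size, bool)
        rm = right.blink_mask if right.blink_mask is not None else \
            np.zeros(right.samples.size, bool)
        mask = lm | rm
    return PupilTrace(0.5 * (left.samples + right.samples), left.rate,
                      left.t0, "mean", blink_mask=mask, info=dict(left.info))


def zscore_concatenated(trials):
    """Z-score all of a participant's kept trials as one concatenated series.

    Uses the population SD (ddof=0): the concatenation is treated as the
    full normalization population.  Returns new traces; the concatenated
    output has mean 0 and SD 1 exactly.
    """
    arrays = [np.asarray(tr.samples, dtype=float) for tr in trials]
    if not arrays:
        return []
    cat = np.concatenate(arrays)
    sd = cat.std(ddof=0)
    if sd == 0:
        raise ValueError("concatenated trace has zero variance")
    mu = cat.mean()
    out = []
    for tr, arr in zip(trials, arrays):
        out.append(PupilTrace((arr - mu) / sd, tr.rate, tr.t0, tr.eye,
                              blink_mask=tr.blink_mask, info=dict(tr.info)))
    return out


def segment_trials(recording: PupilRecording, baseline_duration: float = 1.5):
    """Split a continuous recording into (baseline, trial) trace pairs.

    Uses the baseline-start, encoding-start, encoding-offset and
    probe-onset triggers.  The trial window runs from encoding start
    through the sample immediately before probe onset; trials with a
    missing trigger are excluded with a logged reason.

    Returns ``(pairs, exclusions)``.
    """
    trig = sorted(recording.triggers)
    rate = recording.rate
    starts = [t for t, c in trig if c == TRIG_BASELINE_START]
    pairs, exclusions = [], []
    for k, t_base in enumerate(starts):
        t_next = starts[k + 1] if k + 1 < len(starts) else np.inf
        within = [(t, c) for t, c in trig if t_base <= t < t_next]
        codes = dict((c, t) for t, c in within)
        missing = [c for c in (TRIG_ENCODING[0], TRIG_ENCODING_OFFSET,
                               TRIG_PROBE[0]) if c not in codes]
        if missing:
            exclusions.append({"trial": k, "missing_codes": missing})
            logger.warning("trial %d excluded: missing triggers %s", k, missing)
            continue
        enc_start = codes[TRIG_ENCODING[0]]
        enc_off = codes[TRIG_ENCODING_OFFSET]
        probe = codes[TRIG_PROBE[0]]
        i_base = int(round((enc_start - baseline_duration) * rate))
        i_enc = int(round(enc_start * rate))
        i_probe = int(round(probe * rate))  # exclusive: ends 1 sample before
        baseline = PupilTrace(recording.samples[max(0, i_base):i_enc].copy(),
                              rate, t0=enc_start - enc_off - baseline_duration,
                              eye=recording.eye)
        trialw = PupilTrace(recording.samples[i_enc:i_probe].copy(), rate,
                            t0=enc_start - enc_off, eye=recording.eye,
                            info={"trial": k})
        pairs.append((baseline, trialw))
    return pairs, exclusions


def condition_average(traces_by_participant: dict):
    """Participant means then group mean/SEM per time point.

    ``traces_by_participant`` maps participant -> (n_trials x n_times)
    array (already z-scored and aligned).  Returns ``(mean, sem, n)``.
    """
    means = np.array([np.asarray(v).mean(axis=0)
                      for v in traces_by_participant.values()])
    n = means.shape[0]
    return means.mean(axis=0), means.std(axis=0, ddof=1) / np.sqrt(n), n


def condition_difference(with_task: dict, without_task: dict):
    """Intervening-minus-none difference traces per participant.

    Both dicts map participant -> mean trace on a shared time base.
    Returns ``(per_participant_diffs, group_mean, group_sem)``.
    """
    common = sorted(set(with_task) & set(without_task))
    if not common:
        raise ValueError("no shared participants")
    diffs = []
    for p in common:
        a, b = np.asarray(with_task[p]), np.asarray(without_task[p])
        if a.shape != b.shape:
            raise ValueError("time-base mismatch between conditions")
        diffs.append(a - b)
    diffs = np.array(diffs)
    n = diffs.shape[0]
    sem = diffs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
        np.full(diffs.shape[1], np.nan)
    return diffs, diffs.mean(axis=0), sem
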