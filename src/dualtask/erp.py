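"""ERP pipeline: preprocessing, epoching, artifact rejection, P2
extraction and the three-way repeated-measures ANOVA.

Preprocessing follows the standard ERP recipe for this paradigm:
downsample to 256 Hz, re-reference to the mastoid average, zero-phase FIR
band-pass 0.5-20 Hz.  Epochs run from 100 ms before to 500 ms after each
stimulus; any channel exceeding 100 uV peak-to-peak (strictly) rejects
the epoch; surviving epochs are baseline-corrected to the mean of the
first 100 ms.  P2 amplitude is the 190-220 ms mean over the
fronto-central cluster {Fz, FCz, Cz, FC1, FC2}, measured on
Intervening-task onset (position-1) ERPs.

Ocular-artifact removal by ICA is a pluggable hook (``ica_hook``): the
default is a no-op, and an externally computed decomposition can be
applied by passing a callable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from mne.filter import filter_data
from scipy import signal, stats

from .containers import EEGRecording

logger = logging.getLogger(__name__)

__all__ = [
    "FRONTOCENTRAL_CLUSTER", "AUDITORY_DISPLAY_CLUSTER",
    "VISUAL_DISPLAY_CLUSTER", "Epochs", "preprocess", "epoch_and_reject",
    "grand_average", "extract_p2", "rm_anova_3way", "followup_anovas",
]

FRONTOCENTRAL_CLUSTER = ("Fz", "FCz", "Cz", "FC1", "FC2")
AUDITORY_DISPLAY_CLUSTER = ("Fz", "AFz", "Cz", "F1", "F2")
VISUAL_DISPLAY_CLUSTER = ("O1", "O2", "PO3", "PO4", "PO7", "PO8")

P2_WINDOW = (0.190, 0.220)
EPOCH_WINDOW = (-0.1, 0.5)
P2P_THRESHOLD_UV = 100.0


# ------------------------------------------------------------ preprocess

def preprocess(recording: EEGRecording, target_rate: float = 256.0,
               l_freq: float = 0.5, h_freq: float = 20.0,
               l_trans: float = 0.2, h_trans: float = 2.0,
               mastoids=("M1", "M2"),
               ica_hook=None) -> EEGRecording:
    """Downsample, mastoid re-reference and zero-phase band-pass filter.

    ``ica_hook`` may be a callable ``(data, ch_names) -> data`` applied
    after filtering (e.g. an externally computed ocular ICA cleanup).
    """
    for m in mastoids:
        if m not in recording.ch_names:
            raise ValueError(f"missing mastoid channel {m}")
    data = np.asarray(recording.data, dtype=np.float64)
    rate = recording.rate
    if rate > target_rate:
        factor = rate / target_rate
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError("rate must be an integer multiple of target_rate")
        data = signal.resample_poly(data, 1, int(round(factor)), axis=1)
        rate = target_rate
    ref = data[[recording.ch_names.index(m) for m in mastoids]].mean(axis=0)
    data = data - ref
    data = filter_data(data, sfreq=rate, l_freq=l_freq, h_freq=h_freq,
                       l_trans_bandwidth=l_trans, h_trans_bandwidth=h_trans,
                       phase="zero", fir_design="firwin", verbose="error")
    if ica_hook is not None:
        data = ica_hook(data, list(recording.ch_names))
    return EEGRecording(data=data, rate=rate,
                        ch_names=list(recording.ch_names),
                        triggers=list(recording.triggers),
                        info={**recording.info, "preprocessed": True})


# --------------------------------------------------------------- epochs

@dataclass
class Epochs:
    """Stimulus-locked epochs: data (epochs x channels x times) + metadata."""

    data: np.ndarray
    times: np.ndarray
    ch_names: list
    metadata: pd.DataFrame

    def select(self, **criteria) -> "Epochs":
        keep = np.ones(len(self.metadata), dtype=bool)
        for col, val in criteria.items():
            keep &= (self.metadata[col] == val).to_numpy()
        return Epochs(self.data[keep], self.times, self.ch_names,
                      self.metadata[keep].reset_index(drop=True))


def epoch_and_reject(recording: EEGRecording, events: pd.DataFrame,
                     window: tuple = EPOCH_WINDOW,
                     p2p_threshold: float = P2P_THRESHOLD_UV,
                     exclude_channels=("M1", "M2")):
    """Cut epochs around ``events['time']`` and reject by peak-to-peak.

    Epochs are cut at ``[-100, 500]`` ms around each event.  An epoch is
    rejected when any channel's max-minus-min strictly exceeds the 100 uV
    threshold; survivors are baseline-corrected so that the per-channel
    mean over ``[-100, 0)`` ms is zero.  Events too close to the recording
    edges are skipped with a log entry.

    Returns ``(epochs, report)``; the report lists every event with its
    peak-to-peak value and kept/skipped status.
    """
    rate = recording.rate
    n_pre = int(round(-window[0] * rate))
    n_post = int(round(window[1] * rate))
    times = np.arange(-n_pre, n_post) / rate
    n_total = recording.data.shape[1]
    chan_idx = [i for i, ch in enumerate(recording.ch_names)
                if ch not in exclude_channels]
    baseline_sel = times < 0

    cut, meta_rows, report_rows = [], [], []
    for _, ev in events.iterrows():
        i0 = int(round(ev["time"] * rate))
        row = dict(ev)
        if i0 - n_pre < 0 or i0 + n_post > n_total:
            logger.warning("event at %.3f s too close to recording edge; "
                           "skipped", ev["time"])
            report_rows.append({**row, "status": "skipped_edge", "p2p": np.nan})
            continue
        ep = recording.data[:, i0 - n_pre:i0 + n_post].copy()
        p2p = float((ep[chan_idx].max(axis=1) - ep[chan_idx].min(axis=1)).max())
        if p2p > p2p_threshold:
            report_rows.append({**row, "status": "rejected_p2p", "p2p": p2p})
            continue
        ep -= ep[:, baseline_sel].mean(axis=1, keepdims=True)
        cut.append(ep)
        meta_rows.append(row)
        report_rows.append({**row, "status": "kept", "p2p": p2p})
    data = (np.stack(cut) if cut
            else np.empty((0, len(recording.ch_names), times.size)))
    return (Epochs(data, times, list(recording.ch_names),
                   pd.DataFrame(meta_rows)),
            pd.DataFrame(report_rows))


# ------------------------------------------------------------- averaging

def participant_average(epochs: Epochs, by) -> dict:
    """Mean ERP per unique combination of the metadata columns ``by``."""
    out = {}
    if len(epochs.metadata) == 0:
        return out
    for key, idx in epochs.metadata.groupby(list(by)).groups.items():
        pos = epochs.metadata.index.get_indexer(idx)
        out[key if isinstance(key, tuple) else (key,)] = \
            epochs.data[pos].mean(axis=0)
    return out


def grand_average(participant_erps: list, channel_cluster=None,
                  ch_names=None) -> np.ndarray:
    """Mean over participant-average ERPs (plain arithmetic mean).

    With ``channel_cluster`` (and ``ch_names``) the result is additionally
    averaged over the given channels, yielding a 1-D display series.
    """
    if not participant_erps:
        raise ValueError("empty group")
    avg = np.mean(np.stack(participant_erps), axis=0)
    if channel_cluster is not None:
        idx = [ch_names.index(c) for c in channel_cluster]
        avg = avg[idx].mean(axis=0)
    return avg


def extract_p2(epochs: Epochs, window: tuple = P2_WINDOW,
               cluster=FRONTOCENTRAL_CLUSTER) -> pd.DataFrame:
    """P2 amplitude table from Intervening-onset (position-1) epochs.

    One row per participant x WM modality x WM domain x Intervening
    domain: the mean over the 190-220 ms window and the fronto-central
    channel cluster of the participant-average ERP.
    """
    missing = [c for c in cluster if c not in epochs.ch_names]
    if missing:
        raise ValueError(f"missing cluster channels: {missing}")
    sel = epochs.select(phase="intervening", position=1)
    ch_idx = [epochs.ch_names.index(c) for c in cluster]
    t_sel = (epochs.times >= window[0]) & (epochs.times <= window[1])
    rows = []
    group_cols = ["participant", "wm_modality", "wm_domain", "intervening"]
    for key, g in sel.metadata.groupby(group_cols):
        pos = sel.metadata.index.get_indexer(g.index)
        erp = sel.data[pos].mean(axis=0)
        amp = float(erp[np.ix_(ch_idx, np.flatnonzero(t_sel))].mean())
        rows.append(dict(zip(group_cols, key), amplitude=amp))
    return pd.DataFrame(rows)


# ------------------------------------------------------ repeated-measures

def _effect_arrays(y: np.ndarray):
    """Full factorial decomposition of a subject x factors array.

    Returns ``{frozenset(axes): effect_array}`` where axis 0 is subject.
    Each effect array is the marginal-mean array with all lower-order
    effects subtracted (Mobius inversion over subsets).
    """
    ndim = y.ndim
    all_axes = tuple(range(ndim))
    effects = {}

    def marginal(axes_kept):
        collapse = tuple(a for a in all_axes if a not in axes_kept)
        return y.mean(axis=collapse, keepdims=True)

    subsets = []
    for r in range(ndim + 1):
        subsets += list(combinations(all_axes, r))
    for s in subsets:
        e = marginal(s).copy()
        for t in subsets:
            if set(t) < set(s):
                e = e - effects[frozenset(t)]
        effects[frozenset(s)] = e
    return effects


def _ss(effect: np.ndarray, full_shape) -> float:
    reps = np.prod([f // e for f, e in zip(full_shape, effect.shape)])
    return float((effect ** 2).sum() * reps)


def rm_anova_3way(table: pd.DataFrame, dv: str = "amplitude",
                  within=("wm_modality", "wm_domain", "intervening"),
                  subject: str = "participant") -> pd.DataFrame:
    """Fully within-subject factorial ANOVA with eta-squared effect sizes.

    Requires a balanced, fully crossed table (one value per subject x
    cell; replicate rows are averaged first).  For each main effect and
    interaction the error term is its interaction with subject.  Reports
    classical eta-squared (SS_effect / SS_total) and generalized
    eta-squared (SS_effect / (SS_effect + all subject-involving SS)).
    """
    agg = table.groupby([subject, *within])[dv].mean()
    levels = [sorted(table[c].unique()) for c in within]
    subjects = sorted(table[subject].unique())
    shape = (len(subjects), *map(len, levels))
    try:
        y = agg.unstack(list(range(1, len(within) + 1))).to_numpy().reshape(shape)
    except ValueError as err:
        raise ValueError("design must be fully crossed within subjects") from err
    if np.isnan(y).any():
        raise ValueError("missing cells: design must be fully crossed")

    effects = _effect_arrays(y)
    full_shape = y.shape
    ss = {k: _ss(v, full_shape) for k, v in effects.items()}
    ss_total = sum(v for k, v in ss.items() if len(k) > 0)
    ss_subject_all = sum(v for k, v in ss.items() if 0 in k)

    n = len(subjects)
    rows = []
    factor_axes = {within[i]: i + 1 for i in range(len(within))}
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            axes = frozenset(factor_axes[f] for f in combo)
            err_axes = frozenset({0} | axes)
            df1 = int(np.prod([len(levels[factor_axes[f] - 1]) - 1
                               for f in combo]))
            df2 = (n - 1) * df1
            ss_eff, ss_err = ss[axes], ss[err_axes]
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else \
                (0.0 if ss_eff == 0 else np.inf)
            p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            rows.append({
                "term": " x ".join(combo), "F": F, "df1": df1, "df2": df2,
                "p": p,
                "eta_sq": ss_eff / ss_total if ss_total else 0.0,
                "ges": ss_eff / (ss_eff + ss_subject_all)
                if (ss_eff + ss_subject_all) else 0.0,
            })
    return pd.DataFrame(rows)


def followup_anovas(table: pd.DataFrame, split_by: str = "wm_modality",
                    within=("wm_domain", "intervening"),
                    subject: str = "participant", dv: str = "amplitude",
                    alpha: float = 0.05) -> dict:
    """Per-modality follow-up ANOVAs at a Bonferroni-adjusted criterion.

    The adjusted alpha divides by the number of follow-up analyses plus
    the omnibus (e.g. 0.05 / 3 = 0.017 for two follow-ups), matching the
    step-wise criterion used for restricted ANOVAs.
    """
    splits = sorted(table[split_by].unique())
    adjusted = alpha / (len(splits) + 1)
    out = {}
    for level in splits:
        res = rm_anova_3way(table[table[split_by] == level], dv=dv,
                            within=within, subject=subject)
        res["alpha_criterion"] = adjusted
        res["significant"] = res["p"] < adjusted
        out[level] = res
    return out
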