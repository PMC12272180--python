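"""Synthetic dual-task experiment generator.

Produces experiment designs, stimulus sequences, behavioral responses,
pupil traces and EEG recordings with the statistical structure the
analysis stages assume: a blocked 4 (WM condition) x 3 (Intervening
condition) design, logistic behavioral observers with participant random
effects, pupil traces built from a gamma-shaped dilation kernel with
blinks, and EEG built from stimulus-locked ERP templates, a
participant-specific alpha oscillation, and 1/f background noise.

All randomness flows from a single top-level seed; sub-generators derive
child seeds deterministically via :func:`numpy.random.SeedSequence.spawn`.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .containers import (ALL_CELLS, AUDITORY_AZIMUTHS, AUDITORY_FIRST_INDEX,
                         INTERVENING_AZIMUTHS, INTERVENING_JITTER,
                         INTERVENING_LONG_MEAN, INTERVENING_SHORT_MEAN,
                         MODALITIES,
                         N_VISUAL_POSITIONS, STIMULUS_DURATION, TRIG_BASELINE_START,
                         TRIG_ENCODING, TRIG_ENCODING_OFFSET, TRIG_INTERVENING,
                         TRIG_PROBE, TRIG_TRIAL_END, VISUAL_FIRST_INDEX,
                         WM_INTERVALS, ConditionCell, EEGRecording,
                         InterveningSequence, PupilRecording, PupilTrace,
                         StimulusSequence, TrialRecord, trials_to_frame)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig", "ObserverModel", "PupilModel", "EEGModel",
    "generate_design", "generate_wm_sequences", "generate_intervening_sequence",
    "simulate_behavior", "simulate_pupil_trial", "simulate_eeg_trial",
    "simulate_session", "simulate_experiment_tables", "draw_alpha_frequencies",
]


# ---------------------------------------------------------------- config

class InvalidConfigError(ValueError):
    """Raised when an ExperimentConfig violates its invariants."""


@dataclass
class ExperimentConfig:
    """Experiment-level parameters of the dual-task paradigm.

    Defaults reproduce the study conditions: blocks of 20 trials, 40
    trials per condition cell, a 1.5 s pre-trial baseline, 5.5 s of WM
    retention and an Intervening-task onset 2.0 s after encoding offset.
    """

    n_participants: int = 20
    trials_per_block: int = 20
    trials_per_combination: int = 40
    pupil_rate: float = 500.0
    eeg_rate: float = 256.0
    eeg_raw_rate: float = 2048.0
    baseline_duration: float = 1.5
    retention_duration: float = 5.5
    intervening_onset: float = 2.0
    unattended_change_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_block <= 0 or self.trials_per_block % 2:
            raise InvalidConfigError("trials_per_block must be positive and even")
        if self.trials_per_combination % self.trials_per_block:
            raise InvalidConfigError(
                "trials_per_block must divide trials_per_combination")
        for name in ("pupil_rate", "eeg_rate", "baseline_duration",
                     "retention_duration", "intervening_onset"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if self.n_participants < 1:
            raise InvalidConfigError("n_participants must be >= 1")


def _child_rng(rng_or_seed, *key) -> np.random.Generator:
    """Deterministic child generator for a labelled sub-stream."""
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(np.random.SeedSequence([int(rng_or_seed), *key]))


# ---------------------------------------------------------------- design

def _session_cells(modality: str):
    return [c for c in ALL_CELLS if c.wm_modality == modality]


def generate_design(config: ExperimentConfig, seed: int | None = None):
    """Generate the blocked design for every participant.

    Returns a list (participants) of lists of blocks; each block is a list
    of :class:`TrialRecord` with responses unset.  Constraints: every block
    holds a single condition cell; same/different trial types are balanced
    within each block and randomly ordered; within a cycle every cell of a
    session appears once before any repeats; no two adjacent blocks share a
    cell; auditory and visual WM cells live in separate sessions.
    """
    seed = config.seed if seed is None else seed
    n_cycles = config.trials_per_combination // config.trials_per_block
    participants = []
    for p in range(config.n_participants):
        rng = _child_rng(seed, 0, p)
        session_order = list(rng.permutation(MODALITIES))
        blocks = []
        block_id = 0
        for modality in session_order:
            cells = _session_cells(modality)
            order: list[ConditionCell] = []
            for _ in range(n_cycles):
                for attempt in range(100):
                    cycle = list(rng.permutation(len(cells)))
                    if not order or cells[cycle[0]] != order[-1]:
                        break
                else:  # pragma: no cover - 100 failures is (6-1)!/6! ^ 100
                    raise RuntimeError("could not satisfy adjacency constraint")
                order.extend(cells[i] for i in cycle)
            for cell in order:
                blocks.append(_make_block(cell, p, block_id, config, rng))
                block_id += 1
        participants.append(blocks)
    return participants


def _make_block(cell: ConditionCell, participant: int, block_id: int,
                config: ExperimentConfig, rng: np.random.Generator):
    half = config.trials_per_block // 2
    types = ["same"] * half + ["different"] * half
    rng.shuffle(types)
    block = []
    for trial_type in types:
        enc, probe = generate_wm_sequences(cell, trial_type, rng,
                                           config.unattended_change_prob)
        iseq = (generate_intervening_sequence(cell.intervening, rng,
                                              onset=config.intervening_onset)
                if cell.intervening != "none" else None)
        block.append(TrialRecord(participant, block_id, cell, trial_type,
                                 enc, probe, iseq))
    return block


# -------------------------------------------------------------- sequences

def _draw_intervals(modality: str, domain: str, rng) -> tuple:
    if modality == "auditory" and domain == "spatial":
        # Isochronous at the long interval to keep the AS WM task tractable.
        return ("long", "long", "long")
    return tuple(rng.choice(["short", "long"], size=3))


def _draw_locations(modality: str, rng) -> np.ndarray:
    if modality == "auditory":
        first, n = AUDITORY_FIRST_INDEX, len(AUDITORY_AZIMUTHS)
    else:
        first, n = VISUAL_FIRST_INDEX, N_VISUAL_POSITIONS
    locs = rng.integers(0, n, size=4)
    locs[0] = first
    return locs


def _onsets_from_intervals(labels, modality: str) -> np.ndarray:
    gaps = [WM_INTERVALS[modality][lab] for lab in labels]
    onsets = np.concatenate([[0.0], np.cumsum(np.asarray(gaps) + STIMULUS_DURATION)])
    return onsets


def _resample_until_different(draw, reference, rng, max_tries: int = 1000):
    for _ in range(max_tries):
        candidate = draw(rng)
        if not np.array_equal(candidate, reference):
            return candidate
    raise RuntimeError("could not draw a differing sequence")  # pragma: no cover


def generate_wm_sequences(cell: ConditionCell, trial_type: str,
                          rng: np.random.Generator,
                          unattended_change_prob: float = 0.5):
    """Draw matched encoding and probe sequences for one WM trial.

    On "different" trials the probe differs from the encoding sequence in
    the attended domain; on "same" trials the attended domain is identical.
    The unattended domain changes with ``unattended_change_prob`` (except
    timing in auditory-spatial cells, which is isochronous by design).
    """
    modality, domain = cell.wm_modality, cell.wm_domain
    enc_int = _draw_intervals(modality, domain, rng)
    enc_loc = _draw_locations(modality, rng)

    iso = modality == "auditory" and domain == "spatial"
    if domain == "temporal":
        if trial_type == "different":
            probe_int = tuple(_resample_until_different(
                lambda r: np.array(_draw_intervals(modality, domain, r)),
                np.array(enc_int), rng))
        else:
            probe_int = enc_int
        if rng.random() < unattended_change_prob:
            probe_loc = _resample_until_different(
                lambda r: _draw_locations(modality, r), enc_loc, rng)
        else:
            probe_loc = enc_loc.copy()
    else:  # spatial domain attended
        if trial_type == "different":
            probe_loc = _resample_until_different(
                lambda r: _draw_locations(modality, r), enc_loc, rng)
        else:
            probe_loc = enc_loc.copy()
        if iso:
            probe_int = enc_int  # both isochronous long
        elif rng.random() < unattended_change_prob:
            probe_int = tuple(_resample_until_different(
                lambda r: np.array(tuple(r.choice(["short", "long"], size=3))),
                np.array(enc_int), rng))
        else:
            probe_int = enc_int

    enc = StimulusSequence(_onsets_from_intervals(enc_int, modality),
                           enc_loc, tuple(enc_int), modality)
    probe = StimulusSequence(_onsets_from_intervals(probe_int, modality),
                             np.asarray(probe_loc), tuple(probe_int), modality)
    return enc, probe


def generate_intervening_sequence(condition: str, rng: np.random.Generator,
                                  onset: float = 2.0) -> InterveningSequence:
    """Draw one three-burst Intervening sequence.

    One inter-stimulus interval is drawn uniformly around 370 ms, the other
    around 550 ms (+-60 ms jitter, independently), in random order; the
    expected long-short difference is 180 ms.  Locations follow an A-B-A
    pattern over the -4 deg / 0 deg loudspeakers with the first side chosen
    with equal probability.
    """
    if condition not in ("AT", "AS"):
        raise ValueError("condition must be 'AT' or 'AS'")
    short = rng.uniform(INTERVENING_SHORT_MEAN - INTERVENING_JITTER,
                        INTERVENING_SHORT_MEAN + INTERVENING_JITTER)
    long = rng.uniform(INTERVENING_LONG_MEAN - INTERVENING_JITTER,
                       INTERVENING_LONG_MEAN + INTERVENING_JITTER)
    if rng.random() < 0.5:
        intervals, longer = np.array([long, short]), "first"
    else:
        intervals, longer = np.array([short, long]), "second"
    first = INTERVENING_AZIMUTHS[rng.integers(0, 2)]
    middle = INTERVENING_AZIMUTHS[1] if first == INTERVENING_AZIMUTHS[0] \
        else INTERVENING_AZIMUTHS[0]
    onsets = np.concatenate([[onset],
                             onset + np.cumsum(intervals + STIMULUS_DURATION)])
    return InterveningSequence(
        onsets=onsets, interval_durations=intervals, longer_interval=longer,
        locations=np.array([first, middle, first]),
        middle_side="right" if middle > first else "left")


# -------------------------------------------------------------- behavior

@dataclass
class ObserverModel:
    """Logistic observer: error log-odds per condition cell + random effects.

    ``wm_logodds`` maps a :class:`ConditionCell` to the fixed error
    log-odds of the WM same/different judgment; ``intervening_logodds``
    maps cells with an Intervening task to the fixed error log-odds of the
    Intervening judgment.  Per-participant deviations are drawn as a random
    intercept (sd ``re_intercept_sd``) plus independent random slopes on
    the visual-modality, spatial-domain and Intervening-condition
    indicators (sd ``re_slope_sd``).  An all-zero observer errs with
    probability 0.5 on every trial.
    """

    wm_logodds: dict = field(default_factory=dict)
    intervening_logodds: dict = field(default_factory=dict)
    re_intercept_sd: float = 0.0
    re_slope_sd: float = 0.0

    @classmethod
    def guessing(cls) -> "ObserverModel":
        return cls()

    @classmethod
    def study_like(cls, interference: float = 0.8,
                   re_intercept_sd: float = 0.3,
                   re_slope_sd: float = 0.15) -> "ObserverModel":
        """Observer with the interference structure the study reports.

        WM errors rise when the Intervening task shares auditory-temporal
        resources with the WM task; Intervening errors rise when WM holds
        matching-modality (and matching-domain) information.
        """
        wm, iv = {}, {}
        base = {"AT": -1.6, "AS": -0.4, "VT": -0.6, "VS": -1.4}
        for cell in ALL_CELLS:
            eta = base[cell.wm_condition]
            if cell.intervening != "none":
                if cell.wm_condition == "AT":
                    eta += interference
                elif cell.wm_modality == "visual":
                    eta += 0.25 * interference
            wm[cell] = eta
            if cell.intervening != "none":
                eta_i = -1.2 if cell.intervening == "AT" else -2.0
                if cell.wm_modality == "auditory":
                    eta_i += 0.6 * interference
                    if cell.wm_condition == cell.intervening:
                        eta_i += 0.4 * interference
                iv[cell] = eta_i
        return cls(wm, iv, re_intercept_sd, re_slope_sd)

    def wm_eta(self, cell: ConditionCell, re: dict) -> float:
        eta = self.wm_logodds.get(cell, 0.0) + re["intercept"]
        eta += re["visual"] * (cell.wm_modality == "visual")
        eta += re["spatial"] * (cell.wm_domain == "spatial")
        eta += re[f"int_{cell.intervening}"]
        return eta

    def intervening_eta(self, cell: ConditionCell, re: dict) -> float:
        eta = self.intervening_logodds.get(cell, 0.0) + re["i_intercept"]
        eta += re["i_visual"] * (cell.wm_modality == "visual")
        eta += re["i_spatial"] * (cell.wm_domain == "spatial")
        return eta

    def draw_random_effects(self, rng: np.random.Generator) -> dict:
        s, b = self.re_slope_sd, self.re_intercept_sd
        re = {"intercept": rng.normal(0, b) if b else 0.0,
              "i_intercept": rng.normal(0, b) if b else 0.0,
              "int_none": 0.0}
        for k in ("visual", "spatial", "int_AT", "int_AS",
                  "i_visual", "i_spatial"):
            re[k] = rng.normal(0, s) if s else 0.0
        return re


def _flip(response: str) -> str:
    return {"same": "different", "different": "same",
            "first": "second", "second": "first",
            "left": "right", "right": "left"}[response]


def simulate_behavior(design, observer: ObserverModel,
                      rng: np.random.Generator):
    """Fill WM and Intervening responses for a design (in place).

    ``design`` may be a flat list of trials, a list of blocks, or a list of
    participants of blocks, as produced by :func:`generate_design`.  Error
    indicators are Bernoulli draws from the observer's logistic model.
    """
    trials = _flatten(design)
    re_by_participant: dict[int, dict] = {}
    for t in trials:
        re = re_by_participant.setdefault(
            t.participant_id, observer.draw_random_effects(rng))
        p_err = _sigmoid(observer.wm_eta(t.cell, re))
        err = rng.random() < p_err
        t.wm_response = _flip(t.trial_type) if err else t.trial_type
        t.wm_correct = t.wm_response == t.trial_type
        if t.intervening_sequence is not None:
            truth = (t.intervening_sequence.longer_interval
                     if t.cell.intervening == "AT"
                     else t.intervening_sequence.middle_side)
            p_err = _sigmoid(observer.intervening_eta(t.cell, re))
            err = rng.random() < p_err
            t.intervening_response = _flip(truth) if err else truth
            t.intervening_correct = t.intervening_response == truth
    return design


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def _flatten(design):
    if not design:
        return []
    out = design
    while out and isinstance(out[0], list):
        out = [t for sub in out for t in sub]
    return out


# ----------------------------------------------------------------- pupil

@dataclass
class PupilModel:
    """Generative model of task-evoked pupil dilation.

    The dilation impulse response is a gamma kernel whose mode sits
    ``kernel_peak`` seconds after its driving event (0.7 s by default,
    matching the latency of the post-encoding dilation peak).  The
    encoding dilation is driven by a single event at encoding offset (the
    moment the WM load is complete); the Intervening dilation by the three
    Intervening stimulus onsets.  Gains are in the same arbitrary units as
    ``baseline_level`` and may differ by condition cell.
    """

    baseline_level: float = 5.0
    kernel_peak: float = 0.7
    kernel_shape: float = 8.0
    encoding_gain: dict = field(default_factory=dict)
    intervening_gain: dict = field(default_factory=dict)
    anticipatory_gain: dict = field(default_factory=dict)
    blink_rate: float = 0.15
    blink_duration_range: tuple = (0.1, 0.3)
    noise_sd: float = 0.05

    @classmethod
    def study_like(cls, **kw) -> "PupilModel":
        """Condition gains with the structure reported for the study.

        Encoding dilations largest for auditory-spatial WM; Intervening
        dilations largest for auditory-temporal WM, intermediate for
        auditory-spatial, smallest for visual WM; an anticipatory ramp
        only in auditory-temporal WM cells with an Intervening task.
        """
        enc = {c: (0.7 if c.wm_condition == "AS" else 0.45) for c in ALL_CELLS}
        iv = {}
        ant = {}
        for c in ALL_CELLS:
            if c.intervening == "none":
                continue
            iv[c] = {"AT": 0.6, "AS": 0.45, "VT": 0.3, "VS": 0.3}[c.wm_condition]
            ant[c] = 0.15 if c.wm_condition == "AT" else 0.0
        return cls(encoding_gain=enc, intervening_gain=iv,
                   anticipatory_gain=ant, **kw)

    def kernel(self, rate: float, duration: float = 4.0) -> np.ndarray:
        """Gamma dilation kernel sampled at ``rate``, peak normalized to 1."""
        scale = self.kernel_peak / (self.kernel_shape - 1.0)
        t = np.arange(0, duration, 1.0 / rate)
        k = stats.gamma.pdf(t, a=self.kernel_shape, scale=scale)
        return k / k.max()


def simulate_pupil_trial(trial: TrialRecord, model: PupilModel,
                         rng: np.random.Generator,
                         config: ExperimentConfig | None = None) -> PupilTrace:
    """Simulate one trial's pupil trace at 500 Hz.

    The trace spans baseline start through the sample immediately before
    probe onset.  Blinks are encoded as dropouts to zero with steep linear
    flanks; the ground-truth occlusion mask is stored in
    ``trace.info["blink_truth"]``.
    """
    cfg = config or ExperimentConfig()
    rate = cfg.pupil_rate
    cell = trial.cell
    t0 = -trial.encoding_duration - cfg.baseline_duration
    n = int(round((cfg.retention_duration - t0) * rate))  # ends 1 sample before probe
    t = t0 + np.arange(n) / rate

    x = np.full(n, float(model.baseline_level))
    kernel = model.kernel(rate)

    def add_events(times, gain):
        if gain == 0.0:
            return
        drive = np.zeros(n)
        for ev in np.atleast_1d(times):
            idx = int(round((ev - t0) * rate))
            if 0 <= idx < n:
                drive[idx] = 1.0
        x[:] += gain * signal.fftconvolve(drive, kernel)[:n]

    add_events(0.0, model.encoding_gain.get(cell, 0.0))
    if trial.intervening_sequence is not None:
        add_events(trial.intervening_sequence.onsets,
                   model.intervening_gain.get(cell, 0.0))
        ant = model.anticipatory_gain.get(cell, 0.0)
        if ant:
            ramp = np.clip(t / cfg.intervening_onset, 0.0, 1.0)
            ramp[t < 0] = 0.0
            x += ant * ramp

    clean = x.copy()
    if model.noise_sd:
        x += rng.normal(0, model.noise_sd, n)

    truth = np.zeros(n, dtype=bool)
    if model.blink_rate > 0:
        n_blinks = rng.poisson(model.blink_rate * n / rate)
        flank = max(2, int(round(0.008 * rate)))  # steep 8 ms flanks
        for _ in range(n_blinks):
            dur = rng.uniform(*model.blink_duration_range)
            start = rng.integers(0, max(1, n - int(dur * rate)))
            stop = min(n, start + int(dur * rate))
            lo = max(0, start - flank)
            hi = min(n, stop + flank)
            x[lo:start] *= np.linspace(1, 0, start - lo, endpoint=False)
            x[start:stop] = 0.0
            x[stop:hi] *= np.linspace(0, 1, hi - stop, endpoint=False)
            truth[lo:hi] = True

    return PupilTrace(samples=x, rate=rate, t0=t0, eye="mean",
                      info={"blink_truth": truth, "clean": clean,
                            "cell": cell, "participant": trial.participant_id})


# ------------------------------------------------------------------- EEG

#: Standard 10-20 montage subset used by the generator (plus mastoids).
DEFAULT_CHANNELS = ["Fz", "AFz", "Cz", "F1", "F2", "FCz", "FC1", "FC2",
                    "Pz", "O1", "O2", "PO3", "PO4", "PO7", "PO8", "M1", "M2"]

_FC = {"Fz", "AFz", "Cz", "F1", "F2", "FCz", "FC1", "FC2"}
_POST = {"O1", "O2", "PO3", "PO4", "PO7", "PO8"}


def _topo(front: float, parietal: float, posterior: float) -> dict:
    w = {}
    for ch in DEFAULT_CHANNELS:
        if ch in ("M1", "M2"):
            w[ch] = 0.0
        elif ch in _FC:
            w[ch] = front
        elif ch == "Pz":
            w[ch] = parietal
        else:
            w[ch] = posterior
    return w


@dataclass
class EEGModel:
    """Generative EEG model: ERP templates + alpha oscillation + 1/f noise.

    ``erp_components`` maps a component name to ``(latency_s, width_s,
    amplitude_uV, topography)``.  ``p2_gain`` scales the P2 component per
    condition cell.  ``alpha_profile`` maps ``(wm_modality, phase)`` to the
    alpha envelope amplitude in microvolts, with phases ``baseline``,
    ``encoding``, ``retention``, ``intervening`` (the window while the
    Intervening task is on screen) and ``post`` (retention after it).
    """

    channels: list = field(default_factory=lambda: list(DEFAULT_CHANNELS))
    erp_components: dict = field(default_factory=lambda: {
        "N1": (0.100, 0.020, -4.0, _topo(1.0, 0.5, 0.25)),
        "P2": (0.205, 0.012, 5.0, _topo(1.0, 0.5, 0.25)),
        "P3": (0.320, 0.045, 2.5, _topo(0.4, 1.0, 0.6)),
    })
    p2_gain: dict = field(default_factory=dict)
    alpha_profile: dict = field(default_factory=dict)
    alpha_topo: dict = field(default_factory=lambda: _topo(0.2, 1.0, 0.75))
    pink_noise_sd: float = 5.0
    artifact_rate: float = 0.02
    artifact_amplitude: float = 160.0

    @classmethod
    def study_like(cls, **kw) -> "EEGModel":
        """Condition structure reported for the study.

        P2 amplitudes to Intervening stimuli are smaller when WM holds
        auditory information (modality main effect) and smaller when the
        WM and Intervening domains match (domain interaction).  Alpha power
        is elevated during auditory-WM retention and suppressed (then
        rising) for visual WM, with suppression while the Intervening task
        runs.
        """
        gains = {}
        for c in ALL_CELLS:
            g = 1.0
            if c.wm_modality == "auditory":
                g -= 0.25
            if c.intervening != "none" and c.wm_domain == c.intervening[1:].replace(
                    "T", "temporal").replace("S", "spatial"):
                g -= 0.15
            gains[c] = g
        profile = {}
        for phase, a_aud, a_vis in (("baseline", 1.0, 1.0),
                                    ("encoding", 1.6, 0.5),
                                    ("retention", 1.8, 1.2),
                                    ("intervening", 0.9, 1.0),
                                    ("post", 1.6, 0.8)):
            profile[("auditory", phase)] = a_aud
            profile[("visual", phase)] = a_vis
        return cls(p2_gain=gains, alpha_profile=profile, **kw)


def draw_alpha_frequencies(n_participants: int, rng: np.random.Generator):
    """Participant-specific integer alpha frequencies, uniform on 8..12 Hz."""
    return rng.integers(8, 13, size=n_participants)


def _gauss_bump(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def _pink_noise(n_ch: int, n: int, sd: float, rng) -> np.ndarray:
    white = rng.normal(0, 1, (n_ch, n))
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    np.divide(1.0, np.sqrt(f), out=shaping, where=f > 0)
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n, axis=1)
    x *= sd / x.std(axis=1, keepdims=True)
    return x


def simulate_eeg_trial(trial: TrialRecord, model: EEGModel,
                       rng: np.random.Generator,
                       config: ExperimentConfig | None = None,
                       rate: float | None = None,
                       alpha_frequency: float = 10.0) -> EEGRecording:
    """Simulate one trial's EEG segment.

    The segment spans baseline start through the end of the probe sequence
    plus 0.7 s.  Triggers are relative to the segment start.  With noise
    and alpha amplitudes zeroed the epoch average at any channel equals the
    inserted template exactly.
    """
    cfg = config or ExperimentConfig()
    rate = cfg.eeg_rate if rate is None else rate
    cell = trial.cell
    t0 = -trial.encoding_duration - cfg.baseline_duration
    t_end = (cfg.retention_duration + trial.probe_sequence.duration + 0.7)
    n = int(round((t_end - t0) * rate))
    t = t0 + np.arange(n) / rate
    n_ch = len(model.channels)
    data = np.zeros((n_ch, n))

    # --- stimulus events (trial-relative times) and triggers
    enc_onsets = trial.encoding_sequence.onsets + t0 + cfg.baseline_duration
    probe_onsets = cfg.retention_duration + trial.probe_sequence.onsets
    events = [(tt, "encoding", k + 1) for k, tt in enumerate(enc_onsets)]
    triggers = [(0.0, TRIG_BASELINE_START)]
    triggers += [(tt - t0, TRIG_ENCODING[k]) for k, tt in enumerate(enc_onsets)]
    triggers.append((-t0, TRIG_ENCODING_OFFSET))
    int_onsets = np.array([])
    if trial.intervening_sequence is not None:
        int_onsets = trial.intervening_sequence.onsets
        events += [(tt, "intervening", k + 1) for k, tt in enumerate(int_onsets)]
        triggers += [(tt - t0, TRIG_INTERVENING[k]) for k, tt in enumerate(int_onsets)]
    events += [(tt, "probe", k + 1) for k, tt in enumerate(probe_onsets)]
    triggers += [(tt - t0, TRIG_PROBE[k]) for k, tt in enumerate(probe_onsets)]
    triggers.append((t_end - t0 - 1.0 / rate, TRIG_TRIAL_END))

    # --- ERP templates at every stimulus onset (local +-4 sigma windows)
    p2_gain = model.p2_gain.get(cell, 1.0)
    topo_vecs = {name: np.array([comp[3].get(ch, 0.0)
                                 for ch in model.channels])
                 for name, comp in model.erp_components.items()}
    for ev_time, _, _ in events:
        for name, (lat, width, amp, topo) in model.erp_components.items():
            a = amp * (p2_gain if name == "P2" else 1.0)
            mu = ev_time + lat
            lo = max(0, int((mu - 4 * width - t0) * rate))
            hi = min(n, int((mu + 4 * width - t0) * rate) + 1)
            if lo >= hi:
                continue
            bump = a * _gauss_bump(t[lo:hi], mu, width)
            data[:, lo:hi] += topo_vecs[name][:, None] * bump[None, :]

    # --- alpha oscillation with phase-specific envelope
    envelope = _alpha_envelope(t, trial, cfg, model)
    if envelope is not None and envelope.any():
        osc = envelope * np.sin(2 * np.pi * alpha_frequency * (t - t0)
                                + rng.uniform(0, 2 * np.pi))
        for ci, ch in enumerate(model.channels):
            w = model.alpha_topo.get(ch, 0.0)
            if w:
                data[ci] += w * osc

    # --- 1/f background noise (mastoids get a reduced share)
    if model.pink_noise_sd:
        noise = _pink_noise(n_ch, n, model.pink_noise_sd, rng)
        for ci, ch in enumerate(model.channels):
            if ch in ("M1", "M2"):
                noise[ci] *= 0.3
        data += noise

    # --- occasional large artifacts, at the configured per-epoch rate
    artifact_events = []
    if model.artifact_rate:
        for ev_time, phase, pos in events:
            if rng.random() < model.artifact_rate:
                ci = rng.integers(0, n_ch - 2)  # never on the mastoids
                data[ci] += model.artifact_amplitude * _gauss_bump(
                    t, ev_time + 0.2, 0.02)
                artifact_events.append((phase, pos, ev_time))

    return EEGRecording(
        data=data, rate=rate, ch_names=list(model.channels),
        triggers=triggers,
        info={"t0": t0, "cell": cell, "participant": trial.participant_id,
              "alpha_frequency": alpha_frequency,
              "events": [(tt - t0, ph, pos) for tt, ph, pos in events],
              "artifacts": artifact_events})


def _alpha_envelope(t, trial, cfg, model):
    cell = trial.cell
    key = cell.wm_modality
    prof = {ph: model.alpha_profile.get((key, ph), 0.0)
            for ph in ("baseline", "encoding", "retention", "intervening", "post")}
    if not any(prof.values()):
        return None
    env = np.zeros_like(t)
    enc_start = -trial.encoding_duration
    env[t < enc_start] = prof["baseline"]
    env[(t >= enc_start) & (t < 0)] = prof["encoding"]
    if trial.intervening_sequence is None:
        env[(t >= 0) & (t < cfg.retention_duration)] = prof["retention"]
    else:
        i_on = trial.intervening_sequence.onsets[0]
        i_off = (trial.intervening_sequence.onsets[-1] + STIMULUS_DURATION + 0.5)
        env[(t >= 0) & (t < i_on)] = prof["retention"]
        env[(t >= i_on) & (t < i_off)] = prof["intervening"]
        env[(t >= i_off) & (t < cfg.retention_duration)] = prof["post"]
    env[t >= cfg.retention_duration] = prof["baseline"]
    # smooth the step envelope over ~0.25 s to avoid spectral splatter
    rate = 1.0 / (t[1] - t[0])
    w = int(round(0.25 * rate))
    if w > 1:
        kernel = np.hanning(w)
        env = signal.fftconvolve(env, kernel / kernel.sum(), mode="same")
    return env


# ---------------------------------------------------------------- session

def simulate_session(blocks, config: ExperimentConfig,
                     pupil_model: PupilModel, eeg_model: EEGModel,
                     rng: np.random.Generator,
                     alpha_frequency: float = 10.0,
                     gap: float = 2.0,
                     with_eeg: bool = True, with_pupil: bool = True):
    """Assemble continuous recordings for one participant's blocks.

    Returns ``(EEGRecording | None, PupilRecording | None, events)`` where
    ``events`` is a list of dicts with absolute stimulus times and trial
    metadata (used by the ERP and time-frequency stages).
    """
    trials = _flatten(blocks)
    eeg_parts, pupil_parts = [], []
    eeg_triggers, pupil_triggers, events = [], [], []
    t_eeg = t_pup = 0.0
    for k, trial in enumerate(trials):
        if with_eeg:
            seg = simulate_eeg_trial(trial, eeg_model, rng, config,
                                     alpha_frequency=alpha_frequency)
            eeg_parts.append(seg.data)
            eeg_triggers += [(t_eeg + tt, c) for tt, c in seg.triggers]
            for tt, phase, pos in seg.info["events"]:
                events.append({"time": t_eeg + tt, "phase": phase,
                               "position": pos, "trial_index": k,
                               "participant": trial.participant_id,
                               "wm_modality": trial.cell.wm_modality,
                               "wm_domain": trial.cell.wm_domain,
                               "intervening": trial.cell.intervening,
                               "trial_t0": t_eeg - seg.info["t0"]})
            gap_n = int(gap * seg.rate)
            eeg_parts.append(_pink_noise(seg.data.shape[0], gap_n,
                                         eeg_model.pink_noise_sd or 1e-12, rng))
            t_eeg += seg.data.shape[1] / seg.rate + gap
        if with_pupil:
            tr = simulate_pupil_trial(trial, pupil_model, rng, config)
            pupil_parts.append(tr.samples)
            for code_time, code in (
                    (0.0, TRIG_BASELINE_START),
                    (config.baseline_duration, TRIG_ENCODING[0]),
                    (-tr.t0, TRIG_ENCODING_OFFSET),
                    (config.retention_duration - tr.t0, TRIG_PROBE[0])):
                pupil_triggers.append((t_pup + code_time, code))
            gap_n = int(gap * tr.rate)
            pupil_parts.append(pupil_model.baseline_level
                               + rng.normal(0, pupil_model.noise_sd or 0.0, gap_n))
            t_pup += tr.samples.size / tr.rate + gap
    eeg = pupil = None
    if with_eeg:
        eeg = EEGRecording(np.concatenate(eeg_parts, axis=1),
                           config.eeg_rate, list(eeg_model.channels),
                           eeg_triggers)
    if with_pupil:
        pupil = PupilRecording(np.concatenate(pupil_parts), config.pupil_rate,
                               pupil_triggers)
    return eeg, pupil, events


def simulate_experiment_tables(config: ExperimentConfig,
                               observer: ObserverModel | None = None,
                               seed: int | None = None):
    """Design + behavior only: returns the flat trial table (DataFrame)."""
    seed = config.seed if seed is None else seed
    observer = observer or ObserverModel.study_like()
    design = generate_design(config, seed)
    rng = _child_rng(seed, 1)
    simulate_behavior(design, observer, rng)
    return trials_to_frame(_flatten(design))
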