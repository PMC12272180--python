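"""Shared domain containers and the on-disk session format.

Time convention used throughout the package: trial-relative time is in
seconds with **zero at the offset of the final stimulus of the WM encoding
sequence**.  The baseline window therefore ends at ``-encoding_duration``,
the retention window spans ``[0, retention_duration)`` and the probe
sequence starts at ``retention_duration``.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

# ---------------------------------------------------------------- factors

MODALITIES = ("auditory", "visual")
DOMAINS = ("temporal", "spatial")
INTERVENING_CONDITIONS = ("none", "AT", "AS")

_WM_CODE = {("auditory", "temporal"): "AT", ("auditory", "spatial"): "AS",
            ("visual", "temporal"): "VT", ("visual", "spatial"): "VS"}


class ConditionCell(NamedTuple):
    """One cell of the 2 (WM modality) x 2 (WM domain) x 3 (Intervening) design."""

    wm_modality: str
    wm_domain: str
    intervening: str

    @property
    def wm_condition(self) -> str:
        """Four-level WM condition label (AT, AS, VT, VS)."""
        return _WM_CODE[(self.wm_modality, self.wm_domain)]


ALL_CELLS = tuple(
    ConditionCell(m, d, i)
    for m in MODALITIES for d in DOMAINS for i in INTERVENING_CONDITIONS
)

# ------------------------------------------------------------- stimuli

#: Loudspeaker azimuths available to the auditory WM task (degrees).
AUDITORY_AZIMUTHS = (-90.0, -45.0, 0.0, 45.0, 90.0)
#: Index of the central loudspeaker (first auditory stimulus is fixed there).
AUDITORY_FIRST_INDEX = 2
#: Number of circularly arranged visual patch positions.
N_VISUAL_POSITIONS = 12
#: Index of the top-center patch (first visual stimulus is fixed there).
VISUAL_FIRST_INDEX = 0

#: Stimulus duration in seconds (50 ms noise bursts / chords / patch jitters).
STIMULUS_DURATION = 0.050

#: Short/long inter-stimulus interval sets per WM modality, seconds.
WM_INTERVALS = {
    "auditory": {"short": 0.200, "long": 0.340},
    "visual": {"short": 0.200, "long": 0.580},
}

#: Intervening-task interval means and jitter half-width, seconds.
INTERVENING_SHORT_MEAN = 0.370
INTERVENING_LONG_MEAN = 0.550
INTERVENING_JITTER = 0.060

#: Near-frontal loudspeaker azimuths used by the Intervening task (degrees).
INTERVENING_AZIMUTHS = (-4.0, 0.0)

# --------------------------------------------------------- trigger codes

TRIG_BASELINE_START = 1
TRIG_ENCODING = (11, 12, 13, 14)
TRIG_ENCODING_OFFSET = 19
TRIG_INTERVENING = (21, 22, 23)
TRIG_PROBE = (31, 32, 33, 34)
TRIG_TRIAL_END = 40

TRIGGER_NAMES = {TRIG_BASELINE_START: "baseline_start",
                 TRIG_ENCODING_OFFSET: "encoding_offset",
                 TRIG_TRIAL_END: "trial_end"}
TRIGGER_NAMES.update({c: f"encoding_{k + 1}" for k, c in enumerate(TRIG_ENCODING)})
TRIGGER_NAMES.update({c: f"intervening_{k + 1}" for k, c in enumerate(TRIG_INTERVENING)})
TRIGGER_NAMES.update({c: f"probe_{k + 1}" for k, c in enumerate(TRIG_PROBE)})


# ------------------------------------------------------------ sequences

@dataclass
class StimulusSequence:
    """Four-stimulus WM sequence (encoding or probe).

    Parameters
    ----------
    onsets : array of 4 onset times in seconds relative to sequence start.
    locations : 4 location indices (auditory: into ``AUDITORY_AZIMUTHS``;
        visual: 0..11 circular positions).  The first entry is fixed
        (central loudspeaker / top-center patch).
    interval_labels : 3 labels from {"short", "long"}.
    modality : "auditory" or "visual".
    """

    onsets: np.ndarray
    locations: np.ndarray
    interval_labels: tuple
    modality: str

    @property
    def interval_seconds(self) -> np.ndarray:
        table = WM_INTERVALS[self.modality]
        return np.array([table[lab] for lab in self.interval_labels])

    @property
    def duration(self) -> float:
        """Onset-to-offset duration of the whole sequence, seconds."""
        return float(self.onsets[-1] + STIMULUS_DURATION)


@dataclass
class InterveningSequence:
    """Three noise-burst sequence of the auditory Intervening task.

    Onsets are relative to the offset of the final WM encoding stimulus
    (the package time zero); the first onset is the configured intervening
    onset (2.0 s by default).
    """

    onsets: np.ndarray
    interval_durations: np.ndarray  # two offset-to-onset gaps, seconds
    longer_interval: str            # "first" or "second"
    locations: np.ndarray           # azimuths, A-B-A pattern from {-4, 0}
    middle_side: str                # "left" or "right"


@dataclass
class TrialRecord:
    """One trial: condition labels, stimulus sequences and responses."""

    participant_id: int
    block_id: int
    cell: ConditionCell
    trial_type: str                     # "same" or "different"
    encoding_sequence: StimulusSequence
    probe_sequence: StimulusSequence
    intervening_sequence: InterveningSequence | None = None
    wm_response: str | None = None
    wm_correct: bool | None = None
    intervening_response: str | None = None
    intervening_correct: bool | None = None

    def __post_init__(self) -> None:
        has_int = self.intervening_sequence is not None
        if has_int != (self.cell.intervening != "none"):
            raise ValueError(
                "intervening_sequence must be present iff the cell has an "
                "Intervening task")

    @property
    def encoding_duration(self) -> float:
        return self.encoding_sequence.duration


# --------------------------------------------------------- recordings

@dataclass
class PupilTrace:
    """A windowed pupil-diameter trace at a uniform sampling rate.

    ``t0`` is the time of the first sample on the trial-relative axis.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0
    eye: str = "mean"
    blink_mask: np.ndarray | None = None
    rejected: bool = False
    info: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass
class PupilRecording:
    """Continuous pupil recording with event triggers.

    Triggers are ``(time_s, code)`` pairs with times relative to the first
    sample of ``samples``.
    """

    samples: np.ndarray
    rate: float
    triggers: list
    eye: str = "mean"
    info: dict = field(default_factory=dict)


@dataclass
class EEGRecording:
    """Multichannel EEG, microvolts, channels x time, with triggers."""

    data: np.ndarray
    rate: float
    ch_names: list
    triggers: list
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be channels x time")

    def pick(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.ch_names.index(n) for n in names]
        return self.data[idx]


# --------------------------------------------------------- trial table

_SEQ_COLUMNS = """participant block wm_modality wm_domain wm_condition
intervening trial_type enc_intervals enc_locations probe_intervals
probe_locations int_longer_interval int_middle_side wm_response wm_error
intervening_response intervening_error""".split()


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Flatten TrialRecords into the documented one-row-per-trial table."""
    rows = []
    for t in trials:
        iseq = t.intervening_sequence
        rows.append({
            "participant": t.participant_id,
            "block": t.block_id,
            "wm_modality": t.cell.wm_modality,
            "wm_domain": t.cell.wm_domain,
            "wm_condition": t.cell.wm_condition,
            "intervening": t.cell.intervening,
            "trial_type": t.trial_type,
            "enc_intervals": "-".join(t.encoding_sequence.interval_labels),
            "enc_locations": "-".join(map(str, t.encoding_sequence.locations)),
            "probe_intervals": "-".join(t.probe_sequence.interval_labels),
            "probe_locations": "-".join(map(str, t.probe_sequence.locations)),
            "int_longer_interval": None if iseq is None else iseq.longer_interval,
            "int_middle_side": None if iseq is None else iseq.middle_side,
            "wm_response": t.wm_response,
            "wm_error": None if t.wm_correct is None else (not t.wm_correct),
            "intervening_response": t.intervening_response,
            "intervening_error": (None if t.intervening_correct is None
                                  else (not t.intervening_correct)),
        })
    return pd.DataFrame(rows, columns=_SEQ_COLUMNS)


# ------------------------------------------------------- session on disk

def save_session(out_dir: str | Path, participant: int,
                 trials: pd.DataFrame | None = None,
                 eeg: EEGRecording | None = None,
                 pupil: PupilRecording | None = None) -> Path:
    """Write one participant's session: arrays (.npy) + JSON sidecar + CSV."""
    out = Path(out_dir) / f"sub-{participant:02d}"
    out.mkdir(parents=True, exist_ok=True)
    sidecar: dict = {"participant": participant}
    if trials is not None:
        trials.to_csv(out / "trials.csv", index=False)
    if eeg is not None:
        np.save(out / "eeg.npy", eeg.data.astype(np.float32))
        sidecar["eeg"] = {"rate": eeg.rate, "ch_names": list(eeg.ch_names),
                          "triggers": [[float(t), int(c)] for t, c in eeg.triggers],
                          "units": "uV"}
    if pupil is not None:
        np.save(out / "pupil.npy", pupil.samples.astype(np.float32))
        sidecar["pupil"] = {"rate": pupil.rate, "eye": pupil.eye,
                            "triggers": [[float(t), int(c)] for t, c in pupil.triggers]}
    with open(out / "session.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return out


def load_session(session_dir: str | Path):
    """Load a session directory written by :func:`save_session`.

    Returns ``(trials_frame_or_None, EEGRecording_or_None, PupilRecording_or_None)``.
    """
    p = Path(session_dir)
    with open(p / "session.json") as fh:
        sidecar = json.load(fh)
    trials = eeg = pupil = None
    if (p / "trials.csv").exists():
        trials = pd.read_csv(p / "trials.csv")
    if "eeg" in sidecar:
        meta = sidecar["eeg"]
        eeg = EEGRecording(np.load(p / "eeg.npy").astype(float), meta["rate"],
                           list(meta["ch_names"]),
                           [(t, c) for t, c in meta["triggers"]])
    if "pupil" in sidecar:
        meta = sidecar["pupil"]
        pupil = PupilRecording(np.load(p / "pupil.npy").astype(float),
                               meta["rate"],
                               [(t, c) for t, c in meta["triggers"]],
                               eye=meta.get("eye", "mean"))
    return trials, eeg, pupil
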