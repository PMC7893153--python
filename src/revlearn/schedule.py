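"""Trial schedules for trial-structured olfactory conditioning.

A reversal-learning experiment is a fixed sequence of 1-min trials.  Imaging
(and therefore all analysis time) covers only the first ``imaging_window``
seconds of each trial; within that window the odor comes on at
``odor_onset`` seconds for ``odor_duration`` seconds, and on shock trials a
brief electric shock is delivered ``shock_onset`` seconds after odor onset.
Acquisition pairs the CS+ odor with shock; reversal swaps the contingency so
the CS- odor is shocked and the CS+ odor is not.  Mock phases deliver no
shock at all.

The same :class:`TrialSchedule` object drives both the synthetic-data
generator and the analysis pipeline, so timing constants live in exactly one
place.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from .errors import InvalidProtocolError

ODOR_CSPLUS = "CSplus"
ODOR_CSMINUS = "CSminus"
ODORS = (ODOR_CSPLUS, ODOR_CSMINUS)

PHASES = ("pre", "acquisition", "reversal", "mock_acquisition", "mock_reversal")
MOCK_PHASES = ("mock_acquisition", "mock_reversal")

#: Protocol constants: odor pulse at 5 s for 5 s within the imaging window;
#: shock 4 s after odor onset for 100 ms.
ODOR_ONSET_S = 5.0
ODOR_DURATION_S = 5.0
SHOCK_ONSET_S = 4.0
SHOCK_DURATION_S = 0.1


@dataclass(frozen=True)
class TrialRecord:
    """One conditioning trial.

    ``odor_onset`` is in seconds relative to imaging onset within the trial;
    ``shock_onset`` is in seconds relative to *odor* onset.
    """

    index: int
    phase: str
    odor: str
    odor_onset: float = ODOR_ONSET_S
    odor_duration: float = ODOR_DURATION_S
    shock: bool = False
    shock_onset: float = SHOCK_ONSET_S
    shock_duration: float = SHOCK_DURATION_S

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise InvalidProtocolError(f"unknown phase {self.phase!r}")
        if self.odor not in ODORS:
            raise InvalidProtocolError(f"unknown odor {self.odor!r}")
        if self.shock and self.phase in MOCK_PHASES:
            raise InvalidProtocolError(
                f"trial {self.index}: mock phases never carry shock"
            )
        if self.shock and self.shock_onset < 0:
            raise InvalidProtocolError(
                f"trial {self.index}: shock onset precedes odor onset"
            )


@dataclass
class TrialSchedule:
    """Ordered trial list plus the acquisition timing constants."""

    trials: list[TrialRecord]
    frame_rate: float = 5.0
    trial_duration: float = 60.0
    imaging_window: float = 20.0

    def __post_init__(self) -> None:
        idx = [tr.index for tr in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InvalidProtocolError("trial indices must be strictly increasing")
        for tr in self.trials:
            if tr.odor_onset + tr.odor_duration > self.imaging_window:
                raise InvalidProtocolError(
                    f"trial {tr.index}: odor pulse exceeds the imaging window"
                )

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.imaging_window * self.frame_rate))

    def trial(self, index: int) -> TrialRecord:
        for tr in self.trials:
            if tr.index == index:
                return tr
        raise KeyError(f"no trial with index {index}")

    def select(self, phase: str | None = None, odor: str | None = None) -> list[TrialRecord]:
        """Trials matching the given phase and/or odor, in schedule order."""
        out = self.trials
        if phase is not None:
            out = [tr for tr in out if tr.phase == phase]
        if odor is not None:
            out = [tr for tr in out if tr.odor == odor]
        return list(out)

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_rate": self.frame_rate,
            "trial_duration": self.trial_duration,
            "imaging_window": self.imaging_window,
            "trials": [asdict(tr) for tr in self.trials],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrialSchedule":
        payload = json.loads(Path(path).read_text())
        trials = [TrialRecord(**tr) for tr in payload["trials"]]
        return cls(
            trials=trials,
            frame_rate=payload.get("frame_rate", 5.0),
            trial_duration=payload.get("trial_duration", 60.0),
            imaging_window=payload.get("imaging_window", 20.0),
        )


def generate_trial_schedule(
    n_acquisition: int,
    n_reversal: int,
    mock: bool = False,
    frame_rate: float = 5.0,
    trial_duration: float = 60.0,
    imaging_window: float = 20.0,
) -> TrialSchedule:
    """Build the standard alternating CS+/CS- conditioning schedule.

    Each acquisition (or reversal) round is one CS+ trial followed by one
    CS- trial.  During acquisition the CS+ trial carries shock; during
    reversal the contingency is swapped and the CS- trial carries shock.
    ``mock=True`` keeps the identical trial structure but disables every
    shock (the no-conditioning control).

    Parameters
    ----------
    n_acquisition : int
        Number of acquisition rounds (>= 1); 5 in the standard protocol.
    n_reversal : int
        Number of reversal rounds (>= 0); 2 in the standard protocol.
    mock : bool
        Disable all shocks while keeping phases labelled ``mock_*``.
    """
    if n_acquisition < 1 or n_reversal < 0:
        raise InvalidProtocolError(
            f"invalid protocol: n_acquisition={n_acquisition}, n_reversal={n_reversal}"
        )
    trials: list[TrialRecord] = []
    index = 1

    def add(phase: str, odor: str, shock: bool) -> None:
        nonlocal index
        trials.append(TrialRecord(index=index, phase=phase, odor=odor, shock=shock))
        index += 1

    acq_phase = "mock_acquisition" if mock else "acquisition"
    rev_phase = "mock_reversal" if mock else "reversal"
    for _ in range(n_acquisition):
        add(acq_phase, ODOR_CSPLUS, shock=not mock)
        add(acq_phase, ODOR_CSMINUS, shock=False)
    for _ in range(n_reversal):
        add(rev_phase, ODOR_CSPLUS, shock=False)
        add(rev_phase, ODOR_CSMINUS, shock=not mock)
    return TrialSchedule(
        trials=trials,
        frame_rate=frame_rate,
        trial_duration=trial_duration,
        imaging_window=imaging_window,
    )
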