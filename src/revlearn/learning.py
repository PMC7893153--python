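"""Trial-difference learning metrics over a response table.

Learning is quantified per fly and odor as simple trial differences of the
windowed odor-response metric:

* ``diff_acquisition`` — last minus first acquisition trial (trial 5 - trial
  1 in the standard protocol); negative means the response depressed.
* ``diff_reversal``    — second minus first reversal trial; positive means
  the response rebounded after the first experienced contingency change.
* ``relative_trajectory`` — every trial's response minus the response on the
  first acquisition trial (zero there by construction), the per-fly curve
  plotted alongside group means.

All metrics are shift-invariant (adding a constant to a fly's responses
changes nothing) and the phase differences are antisymmetric under reversing
trial order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import IncompletePhaseError

__all__ = [
    "diff_mean_odor_response",
    "relative_to_first_trial",
    "LearningSummary",
    "learning_summary",
]


def _phase_rows(
    responses: pd.DataFrame, fly_id, odor: str, phase: str
) -> pd.DataFrame:
    sel = (
        (responses["fly_id"] == fly_id)
        & (responses["odor"] == odor)
        & (responses["phase"] == phase)
    )
    rows = responses.loc[sel].sort_values("trial_index")
    if len(rows) < 2:
        raise IncompletePhaseError(
            f"fly {fly_id!r}, odor {odor}, phase {phase}: "
            f"need >= 2 trials, found {len(rows)}"
        )
    return rows


def diff_mean_odor_response(
    responses: pd.DataFrame, fly_id, odor: str, phase: str
) -> float:
    """Last-minus-first mean odor response within one phase for one fly/odor.

    Positive values indicate an increase in odor response across the phase.
    """
    rows = _phase_rows(responses, fly_id, odor, phase)
    vals = rows["mean_odor_response"].to_numpy(dtype=float)
    return float(vals[-1] - vals[0])


def relative_to_first_trial(
    responses: pd.DataFrame,
    fly_id,
    odor: str,
    reference_phase: str = "acquisition",
) -> pd.Series:
    """Per-trial odor response minus the first-``reference_phase``-trial response.

    Returns a Series indexed by trial_index covering every trial of that
    (fly, odor) in schedule order; the entry for the reference trial is 0 by
    construction.  For mock experiments pass
    ``reference_phase="mock_acquisition"``.
    """
    sel = (responses["fly_id"] == fly_id) & (responses["odor"] == odor)
    rows = responses.loc[sel].sort_values("trial_index")
    ref = rows.loc[rows["phase"] == reference_phase]
    if ref.empty:
        raise IncompletePhaseError(
            f"fly {fly_id!r}, odor {odor}: no {reference_phase} trial present"
        )
    baseline = float(ref["mean_odor_response"].iloc[0])
    out = rows.set_index("trial_index")["mean_odor_response"] - baseline
    out.name = "relative_response"
    return out


@dataclass
class LearningSummary:
    """Cohort-level learning metrics.

    ``diffs``: one row per (fly, odor) with diff_acquisition / diff_reversal.
    ``trajectories``: long table (fly, odor, trial, relative response).
    ``group``: per (odor, trial) mean and SEM of the relative trajectory.
    """

    diffs: pd.DataFrame
    trajectories: pd.DataFrame
    group: pd.DataFrame


def learning_summary(
    responses: pd.DataFrame, reference_phase: str = "acquisition"
) -> LearningSummary:
    """Compute all per-fly learning metrics plus group mean +/- SEM."""
    mock = reference_phase.startswith("mock")
    acq_phase = "mock_acquisition" if mock else "acquisition"
    rev_phase = "mock_reversal" if mock else "reversal"

    diff_rows, traj_rows = [], []
    for (fly, odor), _ in responses.groupby(["fly_id", "odor"], sort=False):
        row = {"fly_id": fly, "odor": odor}
        for label, phase in (("diff_acquisition", acq_phase), ("diff_reversal", rev_phase)):
            try:
                row[label] = diff_mean_odor_response(responses, fly, odor, phase)
            except IncompletePhaseError:
                row[label] = np.nan
        diff_rows.append(row)
        traj = relative_to_first_trial(responses, fly, odor, reference_phase=acq_phase)
        for trial_index, value in traj.items():
            traj_rows.append(
                {
                    "fly_id": fly,
                    "odor": odor,
                    "trial_index": trial_index,
                    "relative_response": value,
                }
            )

    diffs = pd.DataFrame(diff_rows)
    trajectories = pd.DataFrame(traj_rows)
    group = (
        trajectories.groupby(["odor", "trial_index"])["relative_response"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    return LearningSummary(diffs=diffs, trajectories=trajectories, group=group)
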