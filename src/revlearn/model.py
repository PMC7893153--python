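"""Model/Results interface tying the imaging pipeline together.

:class:`ReversalExperiment` is built from two-channel traces plus the trial
schedule (from CSV/JSON files, from the synthetic generator, or from
in-memory objects); ``fit()`` runs the full pipeline — ratio, bleach
detrend, dR/R0, windowed response metrics, trial-difference learning
metrics, and the statistical battery — and returns a
:class:`ReversalResults` with the estimates, their uncertainties (SEMs),
diagnostics, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import learning, stats, traces as trace_processing
from .schedule import (
    ODOR_CSMINUS,
    ODOR_CSPLUS,
    TrialSchedule,
    generate_trial_schedule,
)
from .simulate import (
    SimulationConfig,
    TwoChannelTrace,
    simulate_experiment,
    traces_from_csv,
)

__all__ = ["ReversalExperiment", "ReversalResults"]


class ReversalExperiment:
    """A trial-structured two-channel imaging experiment ready to analyse."""

    def __init__(self, traces: Sequence[TwoChannelTrace], schedule: TrialSchedule):
        if not traces:
            raise ValueError("experiment needs at least one trace")
        self.traces = list(traces)
        self.schedule = schedule

    # ------------------------------------------------------------ builders
    @classmethod
    def from_csv(
        cls, traces_csv: str | Path, schedule_json: str | Path
    ) -> "ReversalExperiment":
        schedule = TrialSchedule.from_json(schedule_json)
        return cls(traces_from_csv(traces_csv, schedule.frame_rate), schedule)

    @classmethod
    def simulate(
        cls,
        config: SimulationConfig | None = None,
        schedule: TrialSchedule | None = None,
        n_flies: int = 9,
        neuron_class: str = "PAM-b'2a",
        mock: bool = False,
        seed: int | None = None,
    ) -> "ReversalExperiment":
        """Synthetic cohort under the standard 5-acquisition / 2-reversal protocol."""
        if config is None:
            config = SimulationConfig()
        if seed is not None:
            from dataclasses import replace

            config = replace(config, seed=seed)
        if schedule is None:
            schedule = generate_trial_schedule(5, 2, mock=mock)
        return cls(
            simulate_experiment(config, schedule, n_flies=n_flies, neuron_class=neuron_class),
            schedule,
        )

    # ----------------------------------------------------------------- fit
    def fit(self, apply_gg: bool | str = "auto") -> "ReversalResults":
        """Run the full pipeline and test battery; returns the results object."""
        responses = trace_processing.process_experiment(self.traces, self.schedule)
        mock = any(tr.phase.startswith("mock") for tr in self.schedule.trials)
        reference_phase = "mock_acquisition" if mock else "acquisition"
        summary = learning.learning_summary(responses, reference_phase=reference_phase)

        acq_phase = "mock_acquisition" if mock else "acquisition"
        rev_phase = "mock_reversal" if mock else "reversal"
        tests: dict[str, stats.TestResult] = {}

        diffs = summary.diffs
        for label, col in (("acquisition", "diff_acquisition"), ("reversal", "diff_reversal")):
            wide = diffs.pivot(index="fly_id", columns="odor", values=col)
            if (
                ODOR_CSPLUS in wide.columns
                and ODOR_CSMINUS in wide.columns
                and wide.notna().all().all()
                and len(wide) >= 3
            ):
                tests[f"diff_{label}_csplus_vs_csminus"] = stats.paired_compare(
                    wide[ODOR_CSPLUS].to_numpy(), wide[ODOR_CSMINUS].to_numpy()
                )

        # trajectory ANOVA over acquisition trials (the phase with >= 3 levels)
        acq_trials = [tr.index for tr in self.schedule.select(phase=acq_phase)]
        traj = summary.trajectories
        acq_traj = traj[traj["trial_index"].isin(acq_trials)].rename(
            columns={"relative_response": "value"}
        )
        # the within-subject "trial" factor is the per-odor trial ordinal
        # (CS+ and CS- alternate, so their global trial indices differ)
        acq_traj = acq_traj.assign(
            trial=acq_traj.groupby(["fly_id", "odor"])["trial_index"]
            .rank(method="first")
            .astype(int)
        )
        if acq_traj["trial"].nunique() >= 2 and acq_traj["fly_id"].nunique() >= 2:
            tests["acquisition_anova"] = stats.rm_anova_dunnett(
                acq_traj, apply_gg=apply_gg, within="trial"
            )

        # reversal: paired comparison trial 2 vs trial 1 per odor
        resp = responses
        for odor in (ODOR_CSPLUS, ODOR_CSMINUS):
            rev = resp[(resp["phase"] == rev_phase) & (resp["odor"] == odor)]
            wide = rev.pivot(index="fly_id", columns="trial_index", values="mean_odor_response")
            if wide.shape[1] == 2 and wide.notna().all().all() and len(wide) >= 3:
                c1, c2 = sorted(wide.columns)
                tests[f"reversal_{odor}_trial2_vs_trial1"] = stats.paired_compare(
                    wide[c2].to_numpy(), wide[c1].to_numpy()
                )

        return ReversalResults(
            model=self,
            responses=responses,
            diffs=summary.diffs,
            trajectories=summary.trajectories,
            group=summary.group,
            tests=tests,
        )


@dataclass
class ReversalResults:
    """Fitted pipeline output: response metrics, learning statistics, tests."""

    model: ReversalExperiment
    responses: pd.DataFrame
    diffs: pd.DataFrame
    trajectories: pd.DataFrame
    group: pd.DataFrame
    tests: dict

    # ------------------------------------------------------------- queries
    def diff_summary(self) -> pd.DataFrame:
        """Group mean +/- SEM of the phase differences, per odor."""
        rows = []
        for odor, grp in self.diffs.groupby("odor"):
            for col in ("diff_acquisition", "diff_reversal"):
                vals = grp[col].dropna().to_numpy()
                if len(vals) == 0:
                    continue
                rows.append(
                    {
                        "odor": odor,
                        "metric": col,
                        "n": len(vals),
                        "mean": float(vals.mean()),
                        "sem": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                        if len(vals) > 1
                        else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of the learning metrics and test battery."""
        lines = []
        lines.append("Reversal-learning analysis")
        lines.append("=" * 60)
        n_flies = self.responses["fly_id"].nunique()
        n_trials = self.responses["trial_index"].nunique()
        lines.append(f"flies: {n_flies}    trials/fly: {n_trials}")
        lines.append("")
        lines.append("Phase differences (mean odor response, dR/R0 units)")
        lines.append("-" * 60)
        ds = self.diff_summary()
        for _, r in ds.iterrows():
            lines.append(
                f"  {r['odor']:8s} {r['metric']:18s} "
                f"{r['mean']:+.4f} +/- {r['sem']:.4f}  (n={int(r['n'])})"
            )
        lines.append("")
        lines.append("Statistical tests")
        lines.append("-" * 60)
        for name, res in self.tests.items():
            extra = ""
            if res.correction != "none":
                extra = f", GG eps={res.epsilon:.3f}"
            lines.append(
                f"  {name}: {res.test_name}, stat={res.statistic:.3f}, "
                f"p={res.p_value:.4g}{extra}"
            )
            for comp, p in res.posthoc:
                lines.append(f"      {comp}: adj. p={p:.4g}")
        return "\n".join(lines)

    # ------------------------------------------------------------ plotting
    def plot_trajectories(self, ax=None):
        """Group-mean relative trajectories per odor with SEM error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3.5))
        for odor, grp in self.group.groupby("odor"):
            grp = grp.sort_values("trial_index")
            ax.errorbar(
                grp["trial_index"],
                grp["mean"],
                yerr=grp["sem"],
                marker="o",
                capsize=3,
                label=odor,
            )
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.set_xlabel("trial")
        ax.set_ylabel("odor response relative to trial 1 (dR/R0)")
        ax.legend()
        return ax
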