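"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of the real recordings —
not their pixel-level detail:

* two-channel ROI fluorescence with double-exponential photobleaching, a
  multiplicative motion artifact shared by both channels (the reason the
  reference channel exists), additive sensor noise, and odor/shock-evoked
  calcium transients whose amplitudes follow a declarative per-trial
  plasticity profile;
* binomial quadrant occupancy given a preference probability;
* synapse tables with known per-pair counts.

Every generated trace carries its ground-truth per-trial amplitudes so
downstream recovery tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import InvalidConfigError
from .schedule import ODOR_CSMINUS, ODOR_CSPLUS, TrialRecord, TrialSchedule

__all__ = [
    "SimulationConfig",
    "TwoChannelTrace",
    "QuadrantCounts",
    "PairSpec",
    "PLASTICITY_PRESETS",
    "transient_kernel",
    "expected_window_mean",
    "simulate_trace",
    "simulate_experiment",
    "simulate_quadrant_counts",
    "generate_synapse_table",
    "traces_to_csv",
    "traces_from_csv",
    "counts_to_csv",
    "synapses_to_csv",
]

#: Default double-exponential bleach multiplier B(t) = a1 e^{-t/tau1} + a2 e^{-t/tau2} + c,
#: shared by both channels so the ratio is bleach-free by construction.
DEFAULT_BLEACH = (0.3, 30.0, 0.1, 300.0, 0.6)

# Per-trial response-amplitude multipliers, keyed by (phase, odor); each list
# is indexed by the trial's ordinal among same-phase/same-odor trials.  The
# named presets encode the qualitative plasticity of the corresponding
# neuron classes: PAM-b'2a and MBON-g2a'1 depress their CS+ response across
# acquisition and rebound after the first reversal trial (the rebound is
# expressed on reversal trial 2, since learning follows the experienced
# omission); MBON-g5b'2a potentiates during acquisition and depresses after
# reversal.  CS- responses stay flat.
_FLAT = {
    ("acquisition", ODOR_CSPLUS): [1.0] * 5,
    ("acquisition", ODOR_CSMINUS): [1.0] * 5,
    ("reversal", ODOR_CSPLUS): [1.0] * 2,
    ("reversal", ODOR_CSMINUS): [1.0] * 2,
    ("mock_acquisition", ODOR_CSPLUS): [1.0] * 5,
    ("mock_acquisition", ODOR_CSMINUS): [1.0] * 5,
    ("mock_reversal", ODOR_CSPLUS): [1.0] * 2,
    ("mock_reversal", ODOR_CSMINUS): [1.0] * 2,
}

PLASTICITY_PRESETS: dict[str, dict] = {
    "flat": dict(_FLAT),
    "PAM-b'2a": {
        **_FLAT,
        ("acquisition", ODOR_CSPLUS): [1.0, 0.85, 0.7, 0.55, 0.4],
        ("reversal", ODOR_CSPLUS): [0.4, 0.7],
    },
    "MBON-g2a'1": {
        **_FLAT,
        ("acquisition", ODOR_CSPLUS): [1.0, 0.9, 0.75, 0.6, 0.5],
        ("reversal", ODOR_CSPLUS): [0.5, 0.8],
    },
    "MBON-g5b'2a": {
        **_FLAT,
        ("acquisition", ODOR_CSPLUS): [1.0, 1.2, 1.4, 1.6, 1.8],
        ("reversal", ODOR_CSPLUS): [1.8, 1.3],
    },
}


@dataclass
class SimulationConfig:
    """Generative parameters for two-channel trace synthesis.

    Baselines and noise are in raw-fluorescence a.u.; bleach parameters are
    dimensionless multipliers with time constants in seconds; the motion
    artifact is a low-pass log-normal multiplicative process identical on
    both channels.
    """

    seed: int = 0
    bleach_G: tuple[float, float, float, float, float] = DEFAULT_BLEACH
    bleach_T: tuple[float, float, float, float, float] = DEFAULT_BLEACH
    motion_sd: float = 0.05
    motion_smooth_s: float = 0.5
    noise_sd_G: float = 1.5
    noise_sd_T: float = 1.5
    rise_tau: float = 0.2
    decay_tau: float = 1.5
    baseline_G: float = 100.0
    baseline_T: float = 100.0
    response_amp: float = 30.0
    shock_response_amp: float = 40.0
    plasticity_profile: Mapping[str, Mapping] = field(
        default_factory=lambda: {k: dict(v) for k, v in PLASTICITY_PRESETS.items()}
    )

    def __post_init__(self) -> None:
        for name, (a1, t1, a2, t2, c) in (("bleach_G", self.bleach_G), ("bleach_T", self.bleach_T)):
            if t1 <= 0 or t2 <= 0:
                raise InvalidConfigError(f"{name}: bleach time constants must be positive")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise InvalidConfigError("kernel time constants must be positive")
        if self.rise_tau >= self.decay_tau:
            raise InvalidConfigError("kernel rise_tau must be smaller than decay_tau")
        if self.baseline_T <= 0:
            raise InvalidConfigError("reference-channel baseline must be positive")
        if self.baseline_G <= 0:
            raise InvalidConfigError("activity-channel baseline must be positive")
        if min(self.motion_sd, self.noise_sd_G, self.noise_sd_T) < 0:
            raise InvalidConfigError("noise scales must be non-negative")
        if self.response_amp < 0 or self.shock_response_amp < 0:
            raise InvalidConfigError("response amplitudes must be non-negative")

    def amplitude_multiplier(self, neuron_class: str, trial: TrialRecord, ordinal: int) -> float:
        """Per-trial amplitude multiplier from the plasticity profile.

        ``ordinal`` is the 0-based position of the trial among same-phase,
        same-odor trials.  Profiles shorter than the schedule extend with
        their last value; unknown phases default to 1.0.
        """
        profile = self.plasticity_profile.get(neuron_class)
        if profile is None:
            raise InvalidConfigError(f"no plasticity profile for {neuron_class!r}")
        amps = profile.get((trial.phase, trial.odor))
        if amps is None:
            return 1.0
        return float(amps[min(ordinal, len(amps) - 1)])


@dataclass
class TwoChannelTrace:
    """Concatenated per-trial imaging segments for one fly/ROI.

    ``t`` is a uniform grid at ``frame_rate``: trial j occupies
    ``[j*imaging_window, j*imaging_window + imaging_window)`` so the grid is
    continuous across trials while each trial still starts on its own frame.
    ``truth`` records the generative per-trial amplitudes (absolute a.u.,
    ratio units, and the expected windowed odor-response mean) for recovery
    tests.
    """

    fly_id: str
    neuron_class: str
    t: np.ndarray
    G: np.ndarray
    T: np.ndarray
    trial_index: np.ndarray
    frame_rate: float
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.G) == len(self.T) == len(self.trial_index)):
            raise InvalidConfigError("trace arrays must share a length")
        if np.any(self.T <= 0):
            raise InvalidConfigError("reference channel must be strictly positive")


@dataclass(frozen=True)
class QuadrantCounts:
    """Fly counts per quadrant class for one arena configuration."""

    n_csplus: int
    n_csminus: int
    config_id: str = ""

    @property
    def total(self) -> int:
        return self.n_csplus + self.n_csminus


# --------------------------------------------------------------------------
# calcium kernel
# --------------------------------------------------------------------------

def transient_kernel(
    t: np.ndarray, rise_tau: float = 0.2, decay_tau: float = 1.5
) -> np.ndarray:
    """Peak-normalized difference-of-exponentials calcium transient.

    ``k(t) = (e^{-t/decay} - e^{-t/rise}) / k_peak`` for t >= 0, zero before.
    """
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    t_peak = np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return raw / peak


def expected_window_mean(
    onset: float,
    window: tuple[float, float],
    frame_rate: float = 5.0,
    imaging_window: float = 20.0,
    rise_tau: float = 0.2,
    decay_tau: float = 1.5,
) -> float:
    """Mean of the unit-amplitude kernel over the frames of a response window.

    This is the bookkeeping constant linking a generative amplitude (in ratio
    units) to the windowed response mean the pipeline reports.
    """
    t = np.arange(int(round(imaging_window * frame_rate))) / frame_rate
    lo, hi = window
    sel = (t > lo - 1e-6) & (t < hi - 1e-6)
    return float(np.mean(transient_kernel(t[sel] - onset, rise_tau, decay_tau)))


def _bleach(t: np.ndarray, params: Sequence[float]) -> np.ndarray:
    a1, t1, a2, t2, c = params
    return a1 * np.exp(-t / t1) + a2 * np.exp(-t / t2) + c


def _motion_path(
    n: int, config: SimulationConfig, rng: np.random.Generator, frame_rate: float
) -> np.ndarray:
    """Shared multiplicative artifact: exp of low-pass-filtered white noise.

    Positive by construction (log-normal), unit median, with fluctuations on
    the ``motion_smooth_s`` timescale — a caricature of slow brain motion
    moving the ROI across an intensity gradient, which scales both channels
    identically.
    """
    if config.motion_sd == 0:
        return np.ones(n)
    z = rng.standard_normal(n)
    sigma_frames = max(config.motion_smooth_s * frame_rate, 1e-9)
    z = gaussian_filter1d(z, sigma=sigma_frames, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = z / sd
    return np.exp(config.motion_sd * z)


# --------------------------------------------------------------------------
# trace simulation
# --------------------------------------------------------------------------

def simulate_trace(
    config: SimulationConfig,
    schedule: TrialSchedule,
    neuron_class: str = "PAM-b'2a",
    fly_id: str = "fly001",
    rng: np.random.Generator | None = None,
) -> TwoChannelTrace:
    """Synthesize one fly's two-channel trace for a whole schedule.

    Per trial, with local time ``t`` (0 at imaging onset):

    ``G(t) = [baseline_G + sum_events amp * k(t - onset)] * B_G(t_cum) * M(t) + eps_G``
    ``T(t) =  baseline_T                                  * B_T(t_cum) * M(t) + eps_T``

    where ``B`` is the double-exponential bleach evaluated on the cumulative
    illuminated-time clock (bleaching only advances while the excitation
    lights are on), ``M`` the motion artifact shared by both channels, and
    ``k`` the peak-normalized transient kernel.  Deterministic given
    ``config.seed`` (or an explicit ``rng``).
    """
    if not schedule.trials:
        raise InvalidConfigError("schedule must contain at least one trial")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = schedule.frames_per_trial
    fr = schedule.frame_rate
    t_local = np.arange(n) / fr
    ordinals: dict[tuple[str, str], int] = {}

    ts, Gs, Ts, idxs, truth_rows = [], [], [], [], []
    for j, trial in enumerate(schedule.trials):
        key = (trial.phase, trial.odor)
        ordinal = ordinals.get(key, 0)
        ordinals[key] = ordinal + 1

        mult = config.amplitude_multiplier(neuron_class, trial, ordinal)
        amp = config.response_amp * mult
        clean = np.full(n, config.baseline_G)
        clean += amp * transient_kernel(
            t_local - trial.odor_onset, config.rise_tau, config.decay_tau
        )
        if trial.shock:
            shock_t = trial.odor_onset + trial.shock_onset
            clean += config.shock_response_amp * transient_kernel(
                t_local - shock_t, config.rise_tau, config.decay_tau
            )

        t_cum = j * schedule.imaging_window + t_local  # illuminated-time clock
        M = _motion_path(n, config, rng, fr)
        G = clean * _bleach(t_cum, config.bleach_G) * M
        T = config.baseline_T * _bleach(t_cum, config.bleach_T) * M
        if config.noise_sd_G > 0:
            G = G + config.noise_sd_G * rng.standard_normal(n)
        if config.noise_sd_T > 0:
            T = T + config.noise_sd_T * rng.standard_normal(n)

        amp_dff = amp / config.baseline_G  # transient amplitude in dR/R0 units
        truth_rows.append(
            {
                "trial_index": trial.index,
                "phase": trial.phase,
                "odor": trial.odor,
                "multiplier": mult,
                "amp_raw": amp,
                "amp_dff": amp_dff,
                "expected_odor_mean": amp_dff
                * expected_window_mean(
                    trial.odor_onset,
                    (trial.odor_onset, trial.odor_onset + 4.0),
                    fr,
                    schedule.imaging_window,
                    config.rise_tau,
                    config.decay_tau,
                ),
            }
        )
        ts.append(j * schedule.imaging_window + t_local)
        Gs.append(G)
        Ts.append(T)
        idxs.append(np.full(n, trial.index, dtype=int))

    return TwoChannelTrace(
        fly_id=fly_id,
        neuron_class=neuron_class,
        t=np.concatenate(ts),
        G=np.concatenate(Gs),
        T=np.concatenate(Ts),
        trial_index=np.concatenate(idxs),
        frame_rate=fr,
        truth=pd.DataFrame(truth_rows),
    )


def simulate_experiment(
    config: SimulationConfig,
    schedule: TrialSchedule,
    n_flies: int = 9,
    neuron_class: str = "PAM-b'2a",
) -> list[TwoChannelTrace]:
    """Simulate a cohort of flies with independent noise but shared config.

    Per-fly RNG streams are spawned from ``config.seed`` so the whole cohort
    is reproducible and individual flies are statistically independent.
    """
    streams = np.random.SeedSequence(config.seed).spawn(n_flies)
    return [
        simulate_trace(
            config,
            schedule,
            neuron_class=neuron_class,
            fly_id=f"fly{i + 1:03d}",
            rng=np.random.default_rng(streams[i]),
        )
        for i in range(n_flies)
    ]


# --------------------------------------------------------------------------
# quadrant counts
# --------------------------------------------------------------------------

def simulate_quadrant_counts(
    p_csminus: float, n_flies: int, seed: int, config_id: str = ""
) -> QuadrantCounts:
    """Binomial quadrant occupancy: each fly picks the CS- side w.p. ``p_csminus``."""
    if not 0.0 <= p_csminus <= 1.0:
        raise InvalidConfigError("p_csminus must be in [0, 1]")
    if n_flies < 1:
        raise InvalidConfigError("n_flies must be >= 1")
    rng = np.random.default_rng(seed)
    n_minus = int(rng.binomial(n_flies, p_csminus))
    return QuadrantCounts(
        n_csplus=n_flies - n_minus, n_csminus=n_minus, config_id=config_id
    )


# --------------------------------------------------------------------------
# synapse tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairSpec:
    """Requested connectivity block for :func:`generate_synapse_table`.

    ``exact_counts`` may be ``None`` (draw Poisson(``mean_count``) per pair),
    a scalar, or an ``(n_pre, n_post)`` matrix of exact per-pair counts.
    """

    pre_type: str
    post_type: str
    n_pre: int
    n_post: int
    mean_count: float
    roi: str
    exact_counts: object = None

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise InvalidConfigError("mean_count must be >= 0")


def generate_synapse_table(
    pair_specs: Sequence[PairSpec], seed: int = 0
) -> pd.DataFrame:
    """Emit one row per synaptic contact for the requested type blocks.

    Cell ids are ``{type}_{i:03d}``; coordinates are uniform in the unit box;
    all rows carry ``pre_traced = post_traced = True`` (tests flip these to
    exercise the tracing filter).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for spec in pair_specs:
        if spec.exact_counts is None:
            counts = rng.poisson(spec.mean_count, size=(spec.n_pre, spec.n_post))
        else:
            counts = np.broadcast_to(
                np.asarray(spec.exact_counts, dtype=int), (spec.n_pre, spec.n_post)
            )
        for i in range(spec.n_pre):
            for j in range(spec.n_post):
                c = int(counts[i, j])
                if c == 0:
                    continue
                xyz = rng.uniform(size=(c, 3))
                for s in range(c):
                    rows.append(
                        {
                            "pre_id": f"{spec.pre_type}_{i:03d}",
                            "pre_type": spec.pre_type,
                            "post_id": f"{spec.post_type}_{j:03d}",
                            "post_type": spec.post_type,
                            "roi": spec.roi,
                            "x": xyz[s, 0],
                            "y": xyz[s, 1],
                            "z": xyz[s, 2],
                            "pre_traced": True,
                            "post_traced": True,
                        }
                    )
    columns = [
        "pre_id", "pre_type", "post_id", "post_type", "roi",
        "x", "y", "z", "pre_traced", "post_traced",
    ]
    return pd.DataFrame(rows, columns=columns)


def roster_for(pair_specs: Sequence[PairSpec]) -> dict[str, list[str]]:
    """Cell-id roster per type, matching :func:`generate_synapse_table` ids."""
    roster: dict[str, list[str]] = {}
    for spec in pair_specs:
        roster.setdefault(spec.pre_type, [f"{spec.pre_type}_{i:03d}" for i in range(spec.n_pre)])
        roster.setdefault(spec.post_type, [f"{spec.post_type}_{j:03d}" for j in range(spec.n_post)])
    return roster


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def traces_to_csv(traces: Sequence[TwoChannelTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": tr.fly_id,
                    "neuron_class": tr.neuron_class,
                    "trial_index": tr.trial_index,
                    "t_s": tr.t,
                    "G": tr.G,
                    "T": tr.T,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path: str | Path, frame_rate: float = 5.0) -> list[TwoChannelTrace]:
    df = pd.read_csv(path)
    required = {"fly_id", "neuron_class", "trial_index", "t_s", "G", "T"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"trace CSV missing columns: {sorted(missing)}")
    out = []
    for (fly, ncls), grp in df.groupby(["fly_id", "neuron_class"], sort=False):
        grp = grp.sort_values("t_s")
        out.append(
            TwoChannelTrace(
                fly_id=str(fly),
                neuron_class=str(ncls),
                t=grp["t_s"].to_numpy(float),
                G=grp["G"].to_numpy(float),
                T=grp["T"].to_numpy(float),
                trial_index=grp["trial_index"].to_numpy(int),
                frame_rate=frame_rate,
            )
        )
    return out


def counts_to_csv(counts: Sequence[QuadrantCounts], path: str | Path) -> None:
    pd.DataFrame(
        {
            "config_id": [c.config_id for c in counts],
            "n_csplus": [c.n_csplus for c in counts],
            "n_csminus": [c.n_csminus for c in counts],
        }
    ).to_csv(path, index=False)


def synapses_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
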