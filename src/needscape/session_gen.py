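"""Synthetic trial schedules and full synthetic behavioural datasets.

Generates the two layers of synthetic input every other module consumes:

* trial schedules matching the assay's cue statistics (Go cues with
  probability 0.67, inter-trial intervals uniform on [2, 8] s plus a fixed
  1.5 s per-trial allowance for the odour period);
* complete simulated datasets: an experiment-format view (what fitting and
  the statistics pipeline see: trial times, labels, outcomes only) plus a
  hidden ground-truth view (trajectories, true needs, true parameters) for
  recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .dynamics import SessionResult, SimConfig, TrialSchedule, simulate_session
from .landscape import DEFAULT_GEOMETRY, PARAMS_FIT_ALL_SESSIONS, ModelParams, WellGeometry

__all__ = ["ScheduleSpec", "DatasetSpec", "generate_trial_schedule", "generate_dataset"]


@dataclass(frozen=True)
class ScheduleSpec:
    """Cue-schedule statistics of the assay."""

    go_fraction: float = 0.67
    iti_min: float = 2.0
    iti_max: float = 8.0
    trial_allowance: float = 1.5   # maximum odour duration per trial
    duration: float = 7200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.go_fraction < 1.0:
            raise ValueError("go_fraction must be in (0, 1)")
        if not self.iti_min < self.iti_max:
            raise ValueError("iti_min must be < iti_max")


@dataclass(frozen=True)
class DatasetSpec:
    """A batch of simulated sessions with randomized initial needs."""

    n_sessions: int = 22
    T0_range: Tuple[float, float] = (0.8, 1.2)
    H0_range: Tuple[float, float] = (0.8, 1.2)
    schedule: ScheduleSpec = field(default_factory=ScheduleSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


def generate_trial_schedule(spec: ScheduleSpec,
                            rng: Optional[np.random.Generator] = None) -> TrialSchedule:
    """Random cue times and Go/No-Go labels for one session.

    Cue onsets are separated by i.i.d. uniform ITIs plus the fixed per-trial
    allowance; labels are i.i.d. Go with probability ``go_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mean_gap = spec.trial_allowance + 0.5 * (spec.iti_min + spec.iti_max)
    n_guess = int(spec.duration / mean_gap * 1.5) + 16
    gaps = spec.trial_allowance + rng.uniform(spec.iti_min, spec.iti_max, n_guess)
    times = np.cumsum(gaps)
    times = times[times < spec.duration]
    is_go = rng.random(times.size) < spec.go_fraction
    return TrialSchedule(trial_times=times, is_go=is_go)


def generate_dataset(spec: DatasetSpec,
                     geom: WellGeometry = DEFAULT_GEOMETRY,
                     params: ModelParams = PARAMS_FIT_ALL_SESSIONS,
                     ) -> Tuple[pd.DataFrame, Dict]:
    """Simulate a dataset of sessions.

    Returns ``(sessions, ground_truth)``.  ``sessions`` is the
    experiment-format table (columns ``session_id``, ``trial_time_s``,
    ``label``, ``outcome`` only — no hidden state leaks).  ``ground_truth``
    carries the full :class:`SessionResult` per session, the per-session
    initial needs and seeds, and the generating parameters, for parameter
    recovery and annotation-validation tests.
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_sessions)
    frames: List[pd.DataFrame] = []
    results: List[SessionResult] = []
    inits = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        sched_spec = ScheduleSpec(
            go_fraction=spec.schedule.go_fraction,
            iti_min=spec.schedule.iti_min, iti_max=spec.schedule.iti_max,
            trial_allowance=spec.schedule.trial_allowance,
            duration=spec.sim.duration)
        schedule = generate_trial_schedule(sched_spec, rng)
        T0 = rng.uniform(*spec.T0_range)
        H0 = rng.uniform(*spec.H0_range)
        seed_i = int(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            dt=spec.sim.dt, duration=spec.sim.duration, x0=spec.sim.x0,
            T0=T0, H0=H0, r_water=spec.sim.r_water, r_food=spec.sim.r_food,
            feedback_delay=spec.sim.feedback_delay, rng_seed=seed_i,
            miss_termination=spec.sim.miss_termination,
            record_stride=spec.sim.record_stride)
        res = simulate_session(cfg, schedule, geom, params)
        sid = f"sim-{i:03d}"
        view = res.trials[["trial_time_s", "label", "outcome"]].copy()
        view.insert(0, "session_id", sid)
        frames.append(view)
        results.append(res)
        inits.append({"session_id": sid, "T0": T0, "H0": H0, "seed": seed_i})
    sessions = pd.concat(frames, ignore_index=True)
    ground_truth = {
        "results": results,
        "inits": pd.DataFrame(inits),
        "params": params,
        "geometry": geom,
        "spec": spec,
    }
    return sessions, ground_truth
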