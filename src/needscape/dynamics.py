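"""Langevin simulation of position in the need subspace.

The state diffuses on the need landscape under overdamped Langevin dynamics
discretized with the explicit Euler-Maruyama update

    x(t + dt) = x(t) + dt * g * (-grad U(x, t)) + sqrt(dt) * n * N(0, I)

where U is the need-scaled landscape of :mod:`needscape.landscape`.  A trial
schedule couples the diffusion to behaviour: at each Go-cue time the zone of
the current position is emitted as the choice (water / food / miss), and a
rewarded choice enqueues a delayed decrement of the matching need, which
reshapes the landscape going forward.  Needs are clamped at zero.

The integrator core is compiled with numba; a two-hour session at dt = 0.01 s
(720,000 steps) runs in well under a second after the first compilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .landscape import (
    DEFAULT_GEOMETRY,
    PARAMS_FIT_ALL_SESSIONS,
    ModelParams,
    WellGeometry,
)

__all__ = [
    "SimConfig",
    "TrialSchedule",
    "StimProtocol",
    "SessionResult",
    "langevin_step",
    "simulate_session",
    "simulate_opto_behavior",
    "simulate_opto_prebehavior",
    "simulate_forced_transition",
    "goal_projection",
    "opto_scaled",
    "OUTCOME_LABELS",
]

OUTCOME_LABELS = np.array(["nogo", "water", "food", "miss"])
_NOGO, _WATER, _FOOD, _MISS = 0, 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Session-level simulation configuration.

    Defaults are the standard assay settings: dt = 0.01 s, two simulated
    hours, start at the saddle between the reward wells, per-reward need
    decrements r_water = 0.006 and r_food = 0.004 delivered after a fixed
    feedback delay, and termination after 40 consecutive missed Go cues
    (set ``miss_termination=None`` to always run the full duration).
    """

    dt: float = 0.01
    duration: float = 7200.0
    x0: np.ndarray = field(default_factory=lambda: np.array([5.0, 0.0]))
    T0: float = 1.0
    H0: float = 1.0
    r_water: float = 0.006
    r_food: float = 0.004
    feedback_delay: float = 180.0
    rng_seed: int = 0
    miss_termination: Optional[int] = 40
    record_stride: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float).reshape(2))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n_steps = self.duration / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be an integer number of dt steps")
        if self.r_water <= 0 or self.r_food <= 0:
            raise ValueError("reward decrements must be positive")
        if self.T0 < 0 or self.H0 < 0:
            raise ValueError("initial needs must be non-negative")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class TrialSchedule:
    """Cue times and Go/No-Go labels for one session."""

    trial_times: np.ndarray
    is_go: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.trial_times, dtype=float)
        g = np.asarray(self.is_go, dtype=bool)
        if t.ndim != 1 or g.shape != t.shape:
            raise ValueError("trial_times and is_go must be matching 1-D arrays")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("trial times must be strictly increasing and >= 0")
        object.__setattr__(self, "trial_times", t)
        object.__setattr__(self, "is_go", g)

    def __len__(self) -> int:
        return self.trial_times.size


@dataclass(frozen=True)
class StimProtocol:
    """Square-wave additive thirst perturbation epochs."""

    onsets: np.ndarray
    stim_duration: float = 10.0
    stim_magnitude: float = 18.0

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if self.stim_magnitude < 0:
            raise ValueError("stim_magnitude must be >= 0")
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")
        if onsets.size > 1 and np.any(np.diff(np.sort(onsets)) < self.stim_duration):
            raise ValueError("stimulation epochs must not overlap")


@dataclass
class SessionResult:
    """Simulated session: trial table plus full-resolution hidden state."""

    trials: pd.DataFrame            # trial_time_s, label, outcome, thirst, hunger, x, y
    traj_times: np.ndarray          # down-sampled trajectory timestamps
    traj: np.ndarray                # (len(traj_times), 2) positions
    thirst: np.ndarray              # T(t) at traj_times
    hunger: np.ndarray              # H(t) at traj_times
    rng_seed: int
    config: SimConfig
    params: ModelParams
    geometry: WellGeometry

    @property
    def rewarded(self) -> pd.DataFrame:
        return self.trials[self.trials["outcome"].isin(["water", "food"])]

    def goal_series(self) -> np.ndarray:
        return goal_projection(self.traj, self.geometry)


def goal_projection(x, geom: WellGeometry = DEFAULT_GEOMETRY):
    """Projection of position(s) onto the food-to-water goal axis.

    With the default geometry the goal axis is the unit y vector, so the
    projection is simply the second coordinate.
    """
    x = np.asarray(x, dtype=float)
    return x @ geom.goal_axis


def opto_scaled(params: ModelParams = PARAMS_FIT_ALL_SESSIONS,
                factor: float = 3.3) -> ModelParams:
    """Parameters with the gradient scale boosted for perturbation runs."""
    return ModelParams(g=params.g * factor, n=params.n, s=params.s)


def langevin_step(x, needs, geom: WellGeometry, params: ModelParams,
                  dt: float, noise_draw) -> np.ndarray:
    """One Euler-Maruyama update; deterministic given ``noise_draw``."""
    from .landscape import potential_gradient

    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float)
    grad = potential_gradient(x, needs, geom, params.s)
    return x + dt * params.g * (-grad) + math.sqrt(dt) * params.n * np.asarray(noise_draw)


# ---------------------------------------------------------------------------
# Compiled integrator core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _grad_and_mix(px, py, cT, cH, mox, moy, mwx, mwy, mfx, mfy, sigma2, s):
    """Gradient of U at (px, py) for effective needs (cT, cH)."""
    c = 1.0 / (2.0 * math.pi * sigma2)
    do2 = (px - mox) ** 2 + (py - moy) ** 2
    dw2 = (px - mwx) ** 2 + (py - mwy) ** 2
    df2 = (px - mfx) ** 2 + (py - mfy) ** 2
    po = c * math.exp(-do2 / (2.0 * sigma2))
    pw = s * cT * c * math.exp(-dw2 / (2.0 * sigma2))
    pf = s * cH * c * math.exp(-df2 / (2.0 * sigma2))
    m = po + pw + pf
    gx = (po * (px - mox) + pw * (px - mwx) + pf * (px - mfx)) / (sigma2 * m)
    gy = (po * (py - moy) + pw * (py - mwy) + pf * (py - mfy)) / (sigma2 * m)
    return gx, gy


@njit(cache=True)
def _zone_code(px, py, mox, moy, mwx, mwy, mfx, mfy, sigma2):
    """Zone of (px, py) as an outcome code (water/food/miss).

    Uses the unscaled densities; with shared isotropic variance the
    density comparison reduces to a (tie-aware) nearest-centre rule.
    """
    c = 1.0 / (2.0 * math.pi * sigma2)
    po = c * math.exp(-((px - mox) ** 2 + (py - moy) ** 2) / (2.0 * sigma2))
    pw = c * math.exp(-((px - mwx) ** 2 + (py - mwy) ** 2) / (2.0 * sigma2))
    pf = c * math.exp(-((px - mfx) ** 2 + (py - mfy) ** 2) / (2.0 * sigma2))
    if po >= pw and po >= pf:
        return _MISS
    if pw >= pf:
        return _WATER
    return _FOOD


@njit(cache=True)
def _saddle_proj(cT, cH, mwx, mwy, mfx, mfy, mox, moy, sigma2, s):
    """Projection (along the goal axis) of the ridge point between wells.

    Coarse scan of U along the food-to-water segment; returns the goal-axis
    coordinate of the interior maximum.
    """
    ux = mwx - mfx
    uy = mwy - mfy
    norm = math.sqrt(ux * ux + uy * uy)
    ux /= norm
    uy /= norm
    best = -1.0e300
    best_lam = 0.5
    for i in range(1, 200):
        lam = i / 200.0
        px = mfx + lam * (mwx - mfx)
        py = mfy + lam * (mwy - mfy)
        c = 1.0 / (2.0 * math.pi * sigma2)
        po = c * math.exp(-((px - mox) ** 2 + (py - moy) ** 2) / (2.0 * sigma2))
        pw = s * cT * c * math.exp(-((px - mwx) ** 2 + (py - mwy) ** 2) / (2.0 * sigma2))
        pf = s * cH * c * math.exp(-((px - mfx) ** 2 + (py - mfy) ** 2) / (2.0 * sigma2))
        u = -math.log(po + pw + pf)
        if u > best:
            best = u
            best_lam = lam
    px = mfx + best_lam * (mwx - mfx)
    py = mfy + best_lam * (mwy - mfy)
    return px * ux + py * uy


@njit(cache=True)
def _core(x0, T0, H0, mo, mw, mf, sigma2, g, n, s, dt, noise,
          trial_steps, trial_go, r_w, r_f, delay_steps,
          boost, feedback_on, force_steps, force_margin,
          miss_term, stride):
    n_steps = noise.shape[0]
    n_trials = trial_steps.shape[0]
    n_rec = n_steps // stride + 1

    outcomes = np.full(n_trials, -1, dtype=np.int8)
    T_tr = np.empty(n_trials)
    H_tr = np.empty(n_trials)
    X_tr = np.empty((n_trials, 2))
    traj = np.empty((n_rec, 2))
    T_ser = np.empty(n_rec)
    H_ser = np.empty(n_rec)

    due_T = np.zeros(n_steps + delay_steps + 2)
    due_H = np.zeros(n_steps + delay_steps + 2)

    mox, moy = mo[0], mo[1]
    mwx, mwy = mw[0], mw[1]
    mfx, mfy = mf[0], mf[1]
    ugx = mwx - mfx
    ugy = mwy - mfy
    unorm = math.sqrt(ugx * ugx + ugy * ugy)
    ugx /= unorm
    ugy /= unorm

    px, py = x0[0], x0[1]
    T = T0
    H = H0
    sq = math.sqrt(dt)
    j = 0          # next trial index
    k = 0          # next force-event index
    miss_run = 0
    last_step = n_steps

    for i in range(n_steps):
        # delayed need feedback, clamped at zero
        if due_T[i] > 0.0:
            T = max(0.0, T - due_T[i])
        if due_H[i] > 0.0:
            H = max(0.0, H - due_H[i])

        cT = T + boost[i]

        if i % stride == 0:
            r = i // stride
            traj[r, 0] = px
            traj[r, 1] = py
            T_ser[r] = T
            H_ser[r] = H

        # externally forced transition: impulse along the goal axis past
        # the ridge between the reward wells, away from the current side
        while k < force_steps.shape[0] and force_steps[k] == i:
            sp = _saddle_proj(cT, H, mwx, mwy, mfx, mfy, mox, moy, sigma2, s)
            cur = px * ugx + py * ugy
            if cur >= sp:
                target = sp - force_margin
            else:
                target = sp + force_margin
            px += (target - cur) * ugx
            py += (target - cur) * ugy
            k += 1

        # behavioural emissions at cue times
        while j < n_trials and trial_steps[j] == i:
            T_tr[j] = T
            H_tr[j] = H
            X_tr[j, 0] = px
            X_tr[j, 1] = py
            if trial_go[j]:
                out = _zone_code(px, py, mox, moy, mwx, mwy, mfx, mfy, sigma2)
                outcomes[j] = out
                if out == _MISS:
                    miss_run += 1
                else:
                    miss_run = 0
                    if feedback_on:
                        if out == _WATER:
                            due_T[i + delay_steps] += r_w
                        else:
                            due_H[i + delay_steps] += r_f
            else:
                outcomes[j] = _NOGO
            j += 1
        if miss_term > 0 and miss_run >= miss_term:
            last_step = i
            break

        gx, gy = _grad_and_mix(px, py, cT, H, mox, moy, mwx, mwy,
                               mfx, mfy, sigma2, s)
        px += -dt * g * gx + sq * n * noise[i, 0]
        py += -dt * g * gy + sq * n * noise[i, 1]

    if last_step == n_steps:
        # closing record of the final state
        r = n_steps // stride
        traj[r, 0] = px
        traj[r, 1] = py
        T_ser[r] = T
        H_ser[r] = H

    return outcomes, T_tr, H_tr, X_tr, traj, T_ser, H_ser, last_step


# ---------------------------------------------------------------------------
# Python wrappers
# ---------------------------------------------------------------------------

def _run(config: SimConfig, schedule: TrialSchedule, geom: WellGeometry,
         params: ModelParams, boost: Optional[np.ndarray] = None,
         feedback_on: bool = True,
         force_steps: Optional[np.ndarray] = None,
         force_margin: float = 2.0,
         rng: Optional[np.random.Generator] = None) -> SessionResult:
    n_steps = config.n_steps
    if schedule.trial_times.size and schedule.trial_times[-1] > config.duration:
        raise ValueError("trial schedule extends beyond session duration")
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    noise = rng.standard_normal((n_steps, 2))
    trial_steps = np.round(schedule.trial_times / config.dt).astype(np.int64)
    if boost is None:
        boost = np.zeros(n_steps)
    if force_steps is None:
        force_steps = np.empty(0, dtype=np.int64)
    delay_steps = int(round(config.feedback_delay / config.dt))
    miss_term = config.miss_termination if config.miss_termination else 0

    outcomes, T_tr, H_tr, X_tr, traj, T_ser, H_ser, last_step = _core(
        config.x0, float(config.T0), float(config.H0),
        geom.mu_other, geom.mu_water, geom.mu_food, geom.sigma2,
        params.g, params.n, params.s, config.dt, noise,
        trial_steps, schedule.is_go.astype(np.bool_),
        config.r_water, config.r_food, delay_steps,
        boost, feedback_on, np.sort(np.asarray(force_steps, dtype=np.int64)),
        force_margin, miss_term, config.record_stride,
    )

    reached = outcomes >= 0
    trials = pd.DataFrame({
        "trial_time_s": schedule.trial_times[reached],
        "label": np.where(schedule.is_go[reached], "Go", "NoGo"),
        "outcome": OUTCOME_LABELS[outcomes[reached]],
        "thirst": T_tr[reached],
        "hunger": H_tr[reached],
        "x": X_tr[reached, 0],
        "y": X_tr[reached, 1],
    })
    n_rec = last_step // config.record_stride + (1 if last_step < n_steps else 0)
    n_rec = min(n_rec, traj.shape[0]) if last_step < n_steps else traj.shape[0]
    times = np.arange(n_rec) * config.dt * config.record_stride
    return SessionResult(
        trials=trials, traj_times=times, traj=traj[:n_rec],
        thirst=T_ser[:n_rec], hunger=H_ser[:n_rec],
        rng_seed=config.rng_seed, config=config, params=params, geometry=geom,
    )


def simulate_session(config: SimConfig, schedule: TrialSchedule,
                     geom: WellGeometry = DEFAULT_GEOMETRY,
                     params: ModelParams = PARAMS_FIT_ALL_SESSIONS) -> SessionResult:
    """Simulate one full behavioural session of the assay."""
    return _run(config, schedule, geom, params)


def _boost_array(config: SimConfig, stim: StimProtocol) -> np.ndarray:
    boost = np.zeros(config.n_steps)
    for onset in np.sort(stim.onsets):
        a = int(round(onset / config.dt))
        b = int(round((onset + stim.stim_duration) / config.dt))
        boost[a:min(b, config.n_steps)] = stim.stim_magnitude
    return boost


#: Standard initial conditions of the hungry-only perturbation assay.
OPTO_BEHAVIOR_INIT = dict(T0=0.05, H0=0.5)


def simulate_opto_behavior(config: SimConfig, schedule: TrialSchedule,
                           stim: StimProtocol,
                           geom: WellGeometry = DEFAULT_GEOMETRY,
                           params_scaled: ModelParams = None,
                           reward_feedback: bool = False) -> SessionResult:
    """Session with square-wave additive thirst perturbation epochs.

    ``params_scaled`` should carry the boosted gradient scale (see
    :func:`opto_scaled`); reward feedback is disabled by default in this
    protocol.
    """
    if params_scaled is None:
        params_scaled = opto_scaled()
    boost = _boost_array(config, stim)
    return _run(config, schedule, geom, params_scaled, boost=boost,
                feedback_on=reward_feedback)


def simulate_opto_prebehavior(config: SimConfig, stim: StimProtocol,
                              geom: WellGeometry = DEFAULT_GEOMETRY,
                              params_scaled: ModelParams = None,
                              window: tuple = (-10.0, 20.0)):
    """Perturbation epochs without any trials; goal-projection responses.

    Returns ``(delta, bin_centres, result)`` where ``delta`` is the
    per-epoch goal projection in 1-s bins over ``window`` around each
    onset, baseline-subtracted by the pre-onset mean of that epoch.
    """
    if params_scaled is None:
        params_scaled = opto_scaled()
    empty = TrialSchedule(np.empty(0), np.empty(0, dtype=bool))
    boost = _boost_array(config, stim)
    res = _run(config, empty, geom, params_scaled, boost=boost, feedback_on=False)
    proj = goal_projection(res.traj, geom)
    rec_dt = config.dt * config.record_stride
    per_bin = int(round(1.0 / rec_dt))
    lo, hi = window
    n_bins = int(round(hi - lo))
    rows = []
    for onset in np.sort(stim.onsets):
        i0 = int(round((onset + lo) / rec_dt))
        if i0 < 0 or i0 + n_bins * per_bin > proj.size:
            continue
        seg = proj[i0:i0 + n_bins * per_bin].reshape(n_bins, per_bin).mean(axis=1)
        rows.append(seg)
    delta = np.asarray(rows)
    centres = lo + 0.5 + np.arange(n_bins)
    baseline = delta[:, centres < 0].mean(axis=1, keepdims=True)
    return delta - baseline, centres, res


#: "Too persistent" noise level at which no spontaneous switches occur.
FORCED_PARAMS = ModelParams(g=PARAMS_FIT_ALL_SESSIONS.g, n=0.5,
                            s=PARAMS_FIT_ALL_SESSIONS.s)


def simulate_forced_transition(config: SimConfig, schedule: TrialSchedule,
                               geom: WellGeometry = DEFAULT_GEOMETRY,
                               forced_params: ModelParams = FORCED_PARAMS,
                               force_rate: float = 1.0 / 60.0,
                               force_times: Optional[Sequence[float]] = None,
                               force_margin: float = 2.0) -> SessionResult:
    """Alternative model: switches driven only by external impulses.

    The noise scale is reduced so that no switch occurs spontaneously;
    randomly timed impulses (Poisson at ``force_rate`` unless explicit
    ``force_times`` are given) displace the state along the goal axis just
    past the ridge between the reward wells, without any noise on the force.
    """
    rng = np.random.default_rng(config.rng_seed)
    if force_times is None:
        n_events = rng.poisson(force_rate * config.duration)
        force_times = np.sort(rng.uniform(0.0, config.duration, n_events))
    force_steps = np.round(np.asarray(force_times) / config.dt).astype(np.int64)
    return _run(config, schedule, geom, forced_params,
                force_steps=force_steps, force_margin=force_margin, rng=rng)


# ---------------------------------------------------------------------------
# First-passage helper for the transition-rate Monte-Carlo oracle
# ---------------------------------------------------------------------------

@njit(cache=True)
def _first_passage(x0, y0, y_absorb, from_above, mo, mw, mf, sigma2,
                   g, n, s, cT, cH, dt, max_steps, seed):
    np.random.seed(seed)
    px, py = x0, y0
    sq = math.sqrt(dt)
    for i in range(max_steps):
        if from_above:
            if py <= y_absorb:
                return i * dt
        else:
            if py >= y_absorb:
                return i * dt
        gx, gy = _grad_and_mix(px, py, cT, cH, mo[0], mo[1], mw[0], mw[1],
                               mf[0], mf[1], sigma2, s)
        px += -dt * g * gx + sq * n * np.random.normal()
        py += -dt * g * gy + sq * n * np.random.normal()
    return math.nan


def first_passage_times(needs, geom: WellGeometry, params: ModelParams,
                        source: str = "water", n_rep: int = 200,
                        dt: float = 0.01, max_time: float = 2000.0,
                        seed: int = 0, y_absorb: Optional[float] = None,
                        start: Optional[np.ndarray] = None) -> np.ndarray:
    """Monte-Carlo first-passage times from a reward well to the ridge.

    Trajectories start at the source well centre with fixed needs and are
    absorbed when the goal-axis coordinate crosses ``y_absorb`` (the ridge
    projection by default).  Used as an independent check of the Kramers
    rate approximation.
    """
    from .theory import saddle_point

    if y_absorb is None:
        y_absorb = goal_projection(saddle_point(needs, geom, params.s), geom)
    if start is None:
        start = geom.mu_water if source == "water" else geom.mu_food
    from_above = source == "water"
    out = np.empty(n_rep)
    max_steps = int(round(max_time / dt))
    for r in range(n_rep):
        out[r] = _first_passage(
            start[0], start[1], y_absorb, from_above,
            geom.mu_other, geom.mu_water, geom.mu_food, geom.sigma2,
            params.g, params.n, params.s, needs.thirst, needs.hunger,
            dt, max_steps, seed + r,
        )
    return out
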