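"""Maximum-likelihood fitting of the model's scale parameters (g, n, s).

The composite likelihood combines three views of the trial data, each
tied to the closed-form theory of :mod:`needscape.theory`:

1. **Sequential reward pairs** — consecutive rewarded choices with no
   intervening miss, tagged with the needs at the previous reward and the
   elapsed time: likelihood from the two-state transition matrix with
   Kramers rates.
2. **Individual rewarded choices** (excluding trials adjacent to misses):
   likelihood from the two-zone Boltzmann choice probability.
3. **Trials around satiation** (thirst and hunger < 0.5, misses
   included): likelihood from the three-zone Boltzmann probability, which
   is what constrains the foraging weight ``s``.

The loss is the sum of the three per-trial mean negative log-likelihoods.
Gradients with respect to (g, n, s) are computed in closed form: the
Boltzmann terms differentiate into Boltzmann-weighted zone averages of U
and of dU/ds, and the barrier terms use the envelope theorem at the
located extrema (stationarity kills the location derivatives).  Positivity
is enforced by optimizing over (log g, log n, log s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .landscape import DEFAULT_GEOMETRY, ModelParams, WellGeometry
from .theory import (
    kramers_prefactor,
    line_extrema,
    log_zone_integrals,
    thermal_scale,
)

__all__ = [
    "TrialPairSet",
    "ChoiceTrialSet",
    "SatiationTrialSet",
    "FitResult",
    "build_datasets",
    "joint_nll",
    "fit_parameters",
]


@dataclass(frozen=True)
class TrialPairSet:
    """Sequential rewarded-choice pairs with no intervening miss."""

    prev_water: np.ndarray   # bool: previous choice was water
    next_water: np.ndarray   # bool: next choice was water
    dt_s: np.ndarray         # elapsed time between the two rewards
    thirst: np.ndarray       # needs at the previous reward
    hunger: np.ndarray

    def __len__(self) -> int:
        return self.dt_s.size


@dataclass(frozen=True)
class ChoiceTrialSet:
    """Rewarded trials not adjacent to misses."""

    water: np.ndarray
    thirst: np.ndarray
    hunger: np.ndarray

    def __len__(self) -> int:
        return self.water.size


@dataclass(frozen=True)
class SatiationTrialSet:
    """Go trials (misses included) with both needs below the threshold."""

    outcome: np.ndarray      # 0 = water, 1 = food, 2 = miss
    thirst: np.ndarray
    hunger: np.ndarray

    def __len__(self) -> int:
        return self.outcome.size


@dataclass
class FitResult:
    params: ModelParams
    loss: float
    term_nlls: Tuple[float, float, float]
    trace: pd.DataFrame
    converged: bool
    n_epochs: int


def build_datasets(annotated: pd.DataFrame,
                   satiation_threshold: float = 0.5,
                   min_need: float = 1e-4,
                   ) -> Tuple[TrialPairSet, ChoiceTrialSet, SatiationTrialSet]:
    """Partition annotated trials into the three likelihood datasets.

    ``annotated`` must carry behavioural ``thirst`` and ``hunger`` columns
    (see :func:`needscape.behavior_stats.behavioral_needs`).  Needs are
    floored at ``min_need`` in the pair set so that the barrier search
    stays defined for trials at the very end of a reward budget.
    """
    for col in ("session_id", "trial_time_s", "label", "outcome",
                "thirst", "hunger"):
        if col not in annotated.columns:
            raise ValueError(f"annotated table is missing column {col!r}")

    pair_rows = {k: [] for k in ("pw", "nw", "dt", "T", "H")}
    choice_rows = {k: [] for k in ("w", "T", "H")}
    sat_rows = {k: [] for k in ("o", "T", "H")}
    n_sessions_without_pairs = 0
    for sid, d in annotated.groupby("session_id", sort=False):
        go = d[d["label"] == "Go"]
        out = go["outcome"].to_numpy()
        t = go["trial_time_s"].to_numpy()
        T = go["thirst"].to_numpy()
        H = go["hunger"].to_numpy()
        rewarded = np.isin(out, ("water", "food"))
        ridx = np.flatnonzero(rewarded)
        if ridx.size < 2:
            n_sessions_without_pairs += 1
        else:
            a, b = ridx[:-1], ridx[1:]
            # no 'miss' outcomes strictly between the two rewards
            no_miss = np.array(
                [not np.any(out[i + 1:j] == "miss") for i, j in zip(a, b)])
            pair_rows["pw"].append((out[a] == "water")[no_miss])
            pair_rows["nw"].append((out[b] == "water")[no_miss])
            pair_rows["dt"].append((t[b] - t[a])[no_miss])
            pair_rows["T"].append(np.maximum(T[a], min_need)[no_miss])
            pair_rows["H"].append(np.maximum(H[a], min_need)[no_miss])

        # rewarded trials with neither flanking Go trial a miss
        prev_miss = np.concatenate([[False], out[:-1] == "miss"])
        next_miss = np.concatenate([out[1:] == "miss", [False]])
        keep = rewarded & ~prev_miss & ~next_miss
        choice_rows["w"].append(out[keep] == "water")
        choice_rows["T"].append(np.maximum(T[keep], min_need))
        choice_rows["H"].append(np.maximum(H[keep], min_need))

        sat = (T < satiation_threshold) & (H < satiation_threshold)
        code = np.where(out == "water", 0, np.where(out == "food", 1, 2))
        sat_rows["o"].append(code[sat])
        sat_rows["T"].append(T[sat])
        sat_rows["H"].append(H[sat])

    if n_sessions_without_pairs:
        import warnings
        warnings.warn(f"{n_sessions_without_pairs} session(s) contributed no "
                      "reward pairs", RuntimeWarning, stacklevel=2)
    def cat(lst, dtype=float):
        return np.concatenate(lst) if lst else np.empty(0, dtype=dtype)

    return (
        TrialPairSet(prev_water=cat(pair_rows["pw"]), next_water=cat(pair_rows["nw"]),
                     dt_s=cat(pair_rows["dt"]), thirst=cat(pair_rows["T"]),
                     hunger=cat(pair_rows["H"])),
        ChoiceTrialSet(water=cat(choice_rows["w"]), thirst=cat(choice_rows["T"]),
                       hunger=cat(choice_rows["H"])),
        SatiationTrialSet(outcome=cat(sat_rows["o"]), thirst=cat(sat_rows["T"]),
                          hunger=cat(sat_rows["H"])),
    )


# ---------------------------------------------------------------------------
# Loss terms (value + closed-form gradient over (g, n, s))
# ---------------------------------------------------------------------------

def _pair_term(pairs: TrialPairSet, g: float, n: float, s: float,
               geom: WellGeometry):
    if len(pairs) == 0:
        return 0.0, np.zeros(3)
    ext = line_extrema(pairs.thirst, pairs.hunger, s, geom)
    U = ext["U"]               # columns: water min, food min, saddle
    dUs = ext["dU_ds_s"] / s   # dU/ds at the extrema
    dU_w = U[:, 2] - U[:, 0]
    dU_f = U[:, 2] - U[:, 1]
    ds_w = dUs[:, 2] - dUs[:, 0]
    ds_f = dUs[:, 2] - dUs[:, 1]
    c = g / thermal_scale(n)
    pref = kramers_prefactor(geom.sigma2)
    w_wf = pref * np.exp(-c * dU_w)
    w_fw = pref * np.exp(-c * dU_f)
    # d log(omega) / d(g, n, s)
    dc_dg = 1.0 / thermal_scale(n)
    dc_dn = -2.0 * g / thermal_scale(n) / n
    dlw = np.stack([-dU_w * dc_dg, -dU_w * dc_dn, -c * ds_w], axis=1)
    dlf = np.stack([-dU_f * dc_dg, -dU_f * dc_dn, -c * ds_f], axis=1)
    dw_wf = w_wf[:, None] * dlw
    dw_fw = w_fw[:, None] * dlf

    Om = w_wf + w_fw
    t = pairs.dt_s
    decay = np.exp(-Om * t)
    pi_w = w_fw / Om
    pi_f = w_wf / Om
    P_ww = pi_w + (1.0 - pi_w) * decay
    P_ff = pi_f + (1.0 - pi_f) * decay

    # dP/d(omega_wf, omega_fw)
    dpi_w = np.stack([-w_fw / Om**2, w_wf / Om**2], axis=1)
    dpi_f = -dpi_w
    ddecay = (-t * decay)[:, None]          # per unit d(Omega)
    dP_ww = dpi_w * (1.0 - decay)[:, None] + (1.0 - pi_w)[:, None] * ddecay
    dP_ff = dpi_f * (1.0 - decay)[:, None] + (1.0 - pi_f)[:, None] * ddecay

    # chain into theta-space
    dP_ww_th = dP_ww[:, :1] * dw_wf + dP_ww[:, 1:] * dw_fw
    dP_ff_th = dP_ff[:, :1] * dw_wf + dP_ff[:, 1:] * dw_fw

    P_pair = np.where(pairs.prev_water,
                      np.where(pairs.next_water, P_ww, 1.0 - P_ww),
                      np.where(~pairs.next_water, P_ff, 1.0 - P_ff))
    sign = np.where(pairs.prev_water == pairs.next_water, 1.0, -1.0)
    dP_pair = np.where(pairs.prev_water[:, None], dP_ww_th, dP_ff_th) * sign[:, None]
    if np.any(P_pair <= 0):
        raise FloatingPointError("non-positive pair probability in term 1")
    nll = -np.mean(np.log(P_pair))
    grad = -np.mean(dP_pair / P_pair[:, None], axis=0)
    return float(nll), grad


def _boltzmann_term(T, H, zone_index, g, n, s, geom, spacing, three_zone):
    """Mean NLL of zone outcomes under the Boltzmann equilibrium.

    ``zone_index`` selects the observed zone per trial in (water, food,
    other) order; normalization runs over the first two or all three
    zones.
    """
    if T.size == 0:
        return 0.0, np.zeros(3)
    logZ, mean_U, mean_dUs = log_zone_integrals(T, H, g, n, s, geom, spacing)
    nz = 3 if three_zone else 2
    logZ = logZ[:, :nz]
    kT = thermal_scale(n)
    dc = np.array([1.0 / kT, -2.0 * g / kT / n])   # dc/dg, dc/dn
    # d logZ_z / dtheta: for g, n via c (coefficient on -U); for s directly
    dlogZ = np.empty((T.size, nz, 3))
    dlogZ[:, :, 0] = -mean_U[:, :nz] * dc[0]
    dlogZ[:, :, 1] = -mean_U[:, :nz] * dc[1]
    c = g / kT
    dlogZ[:, :, 2] = -c * mean_dUs[:, :nz] / s
    mx = logZ.max(axis=1, keepdims=True)
    w = np.exp(logZ - mx)
    p = w / w.sum(axis=1, keepdims=True)
    rows = np.arange(T.size)
    logp = logZ[rows, zone_index] - (mx[:, 0] + np.log(w.sum(axis=1)))
    dlogp = dlogZ[rows, zone_index, :] - np.einsum("mz,mzk->mk", p, dlogZ)
    nll = -np.mean(logp)
    grad = -np.mean(dlogp, axis=0)
    return float(nll), grad


def joint_nll(params: ModelParams, datasets, geom: WellGeometry = DEFAULT_GEOMETRY,
              spacing: float = 0.125, with_grad: bool = False,
              pair_idx: Optional[np.ndarray] = None,
              choice_idx: Optional[np.ndarray] = None,
              sat_idx: Optional[np.ndarray] = None):
    """Composite loss: sum of the three per-trial mean NLLs.

    Optional index arrays subsample each dataset (mini-batching).  With
    ``with_grad`` also returns the analytic gradient with respect to
    (g, n, s).
    """
    pairs, choices, sat = datasets
    g, n, s = params.g, params.n, params.s
    if pair_idx is not None:
        pairs = TrialPairSet(pairs.prev_water[pair_idx], pairs.next_water[pair_idx],
                             pairs.dt_s[pair_idx], pairs.thirst[pair_idx],
                             pairs.hunger[pair_idx])
    t1, g1 = _pair_term(pairs, g, n, s, geom)

    cw, cT, cH = choices.water, choices.thirst, choices.hunger
    if choice_idx is not None:
        cw, cT, cH = cw[choice_idx], cT[choice_idx], cH[choice_idx]
    t2, g2 = _boltzmann_term(cT, cH, np.where(cw, 0, 1), g, n, s, geom,
                             spacing, three_zone=False)

    so, sT, sH = sat.outcome, sat.thirst, sat.hunger
    if sat_idx is not None:
        so, sT, sH = so[sat_idx], sT[sat_idx], sH[sat_idx]
    t3, g3 = _boltzmann_term(sT, sH, so, g, n, s, geom, spacing,
                             three_zone=True)

    loss = t1 + t2 + t3
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite joint NLL")
    if with_grad:
        return loss, g1 + g2 + g3, (t1, t2, t3)
    return loss


def fit_parameters(datasets, geom: WellGeometry = DEFAULT_GEOMETRY,
                   init: ModelParams = None,
                   optimizer: str = "adam", learning_rate: float = 0.1,
                   max_epochs: int = 400, tol: float = 1e-6,
                   patience: int = 50, batch_fraction: float = 1.0 / 50.0,
                   min_batch: int = 256, spacing: float = 0.25,
                   seed: int = 0) -> FitResult:
    """Minimize the joint NLL over (log g, log n, log s).

    The default optimizer is Adam at learning rate 0.1 with the Boltzmann
    terms mini-batched to ``batch_fraction`` of their datasets (re-drawn
    each epoch); convergence is declared when the improvement of the
    smoothed full-batch loss stays below ``tol`` for ``patience``
    consecutive epochs.  ``optimizer='lbfgs'`` runs a full-batch
    quasi-Newton fit with the same analytic gradient instead.
    Deterministic for a fixed seed.
    """
    if init is None:
        init = ModelParams(g=1.0, n=1.0, s=1.0)
    pairs, choices, sat = datasets
    x = np.log([init.g, init.n, init.s])

    def value_grad(xv, pi=None, ci=None, si=None):
        p = ModelParams(*np.exp(xv))
        loss, grad, terms = joint_nll(p, datasets, geom, spacing,
                                      with_grad=True, pair_idx=pi,
                                      choice_idx=ci, sat_idx=si)
        return loss, grad * np.exp(xv), terms   # chain rule to log-space

    trace_rows = []
    if optimizer == "lbfgs":
        from scipy.optimize import minimize

        def fun(xv):
            loss, grad, _ = value_grad(xv)
            trace_rows.append({"epoch": len(trace_rows), "loss": loss,
                               "g": math.exp(xv[0]), "n": math.exp(xv[1]),
                               "s": math.exp(xv[2])})
            return loss, grad

        res = minimize(fun, x, jac=True, method="L-BFGS-B",
                       options={"ftol": tol, "maxiter": max_epochs})
        x = res.x
        converged = bool(res.success)
        n_epochs = int(res.nit)
    elif optimizer == "adam":
        rng = np.random.default_rng(seed)
        m = np.zeros(3)
        v = np.zeros(3)
        b1, b2, eps = 0.9, 0.999, 1e-8
        best = np.inf
        stall = 0
        ema = None
        n_epochs = max_epochs
        converged = False
        for epoch in range(1, max_epochs + 1):
            ci = (rng.choice(len(choices), min(len(choices), max(
                min_batch, int(batch_fraction * len(choices)))), replace=False)
                if len(choices) else None)
            si = (rng.choice(len(sat), min(len(sat), max(
                min_batch, int(batch_fraction * len(sat)))), replace=False)
                if len(sat) else None)
            loss, grad, terms = value_grad(x, None, ci, si)
            m = b1 * m + (1 - b1) * grad
            v = b2 * v + (1 - b2) * grad**2
            mh = m / (1 - b1**epoch)
            vh = v / (1 - b2**epoch)
            x = x - learning_rate * mh / (np.sqrt(vh) + eps)
            ema = loss if ema is None else 0.9 * ema + 0.1 * loss
            trace_rows.append({"epoch": epoch, "loss": loss, "ema": ema,
                               "g": math.exp(x[0]), "n": math.exp(x[1]),
                               "s": math.exp(x[2])})
            if ema < best - tol:
                best = ema
                stall = 0
            else:
                stall += 1
            if stall >= patience:
                converged = True
                n_epochs = epoch
                break
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    params = ModelParams(*np.exp(x))
    loss, _, terms = value_grad(x)
    return FitResult(params=params, loss=float(loss),
                     term_nlls=tuple(map(float, terms)),
                     trace=pd.DataFrame(trace_rows), converged=converged,
                     n_epochs=n_epochs)
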