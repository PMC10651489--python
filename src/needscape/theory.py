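"""Closed-form predictions of the landscape diffusion model.

Three layers of theory, all sharing the landscape of
:mod:`needscape.landscape`:

* **Kramers escape rates** between the water and food wells: the landscape
  is construed as a one-dimensional potential along the line joining the
  two reward-well centres; the escape rate over the ridge from a harmonic
  source well is ``omega = sqrt(nu_A * nu_ts) / (2 pi gamma) *
  exp(-(E_saddle - E_source) / kT)`` with the well / transition-state
  frequencies approximated by the Gaussian-well curvatures ``nu_A = 1 /
  sigma^2`` and ``nu_ts = 2 / sigma^2`` and friction ``gamma = 1``.

* **Two-state transition matrix**: treating switches between the reward
  wells as a continuous-time two-state Markov process with those rates
  gives the self-transition probability after elapsed time ``t``,
  ``P_ww(t) = (1 - pi_w) exp(-(omega_wf + omega_fw) t) + pi_w`` with
  ``pi_w = omega_fw / (omega_wf + omega_fw)``, and analogously ``P_ff``.

* **Boltzmann equilibrium choice probabilities**: zone-wise quadrature of
  the stationary density ``exp(-E(x)/kT)`` over the plane, normalized over
  the reward zones only or over all three zones.

Throughout, the energy is the gradient-scaled landscape ``E = g * U`` and
the thermal scale is ``kT = n^2 / 2``, the identification under which the
Euler-Maruyama dynamics ``dx = -g grad(U) dt + n dW`` are in detailed
balance with ``exp(-2 g U / n^2)`` (fluctuation-dissipation); see the
methods note for the derivation and for the accuracy of the harmonic
approximations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .landscape import (
    DEFAULT_GEOMETRY,
    ModelParams,
    NeedState,
    WellGeometry,
    zone,
)

__all__ = [
    "TheoryParams",
    "TransitionMatrix",
    "barrier_heights",
    "kramers_rates",
    "transition_matrix",
    "self_transition_probs",
    "boltzmann_choice_probs",
    "saddle_point",
    "thermal_scale",
    "kramers_prefactor",
]


def thermal_scale(n: float) -> float:
    """Effective temperature kT = n^2 / 2 of the Langevin noise."""
    return 0.5 * n * n


@dataclass(frozen=True)
class TheoryParams:
    """Constants of the one-dimensional harmonic transition-state theory."""

    sigma2: float = DEFAULT_GEOMETRY.sigma2
    gamma: float = 1.0

    @property
    def nu_well(self) -> float:
        """Harmonic frequency of a source well, 1/sigma^2."""
        return 1.0 / self.sigma2

    @property
    def nu_ts(self) -> float:
        """Harmonic frequency of the transition state, 2/sigma^2."""
        return 2.0 / self.sigma2


def kramers_prefactor(sigma2: float = DEFAULT_GEOMETRY.sigma2,
                      gamma: float = 1.0) -> float:
    """Rate prefactor sqrt(nu_A * nu_ts) / (2 pi gamma)."""
    tp = TheoryParams(sigma2=sigma2, gamma=gamma)
    return np.sqrt(tp.nu_well * tp.nu_ts) / (2.0 * np.pi * tp.gamma)


# ---------------------------------------------------------------------------
# Extrema of U along the food-to-water line (vectorized over need batches)
# ---------------------------------------------------------------------------

def _line_profile(lam, wT, wH, geom: WellGeometry):
    """U, dU/dlam, d2U/dlam2 along p(lam) = mu_f + lam (mu_w - mu_f).

    ``lam`` and the mixture weights ``wT = s*T``, ``wH = s*H`` broadcast
    together.  Also returns dU/ds * s aux terms via the 'other' fraction.
    """
    d = geom.mu_water - geom.mu_food
    p = geom.mu_food + np.multiply.outer(lam, d)          # (..., 2)
    sig2 = geom.sigma2
    c = 1.0 / (2.0 * np.pi * sig2)
    shape = np.broadcast_shapes(np.shape(lam), np.shape(wT), np.shape(wH))
    M = np.zeros(shape)
    M1 = np.zeros(shape)
    M2 = np.zeros(shape)
    phi_o = None
    for mu, w in ((geom.mu_other, 1.0), (geom.mu_water, wT), (geom.mu_food, wH)):
        diff = p - mu
        a = np.sum(diff * diff, axis=-1)
        da = 2.0 * np.sum(diff * d, axis=-1)
        dda = 2.0 * float(d @ d)
        phi = c * np.exp(-a / (2.0 * sig2))
        if phi_o is None:
            phi_o = phi
        dphi = -phi * da / (2.0 * sig2)
        ddphi = phi * ((da / (2.0 * sig2)) ** 2 - dda / (2.0 * sig2))
        M += w * phi
        M1 += w * dphi
        M2 += w * ddphi
    U = -np.log(M)
    U1 = -M1 / M
    U2 = -(M2 / M) + (M1 / M) ** 2
    dU_ds_times_s = -(1.0 - phi_o / M)   # s * dU/ds (envelope-ready)
    return U, U1, U2, dU_ds_times_s


def line_extrema(T, H, s: float, geom: WellGeometry = DEFAULT_GEOMETRY,
                 tol: float = 1e-8):
    """Locate the two well minima and the intervening saddle of U on the
    food-to-water line, for batches of (T, H).

    Returns a dict of arrays: ``lam`` (..., 3) in (water, food, saddle)
    order, ``U`` values, ``dU_ds_s`` (s times dU/ds at each point, valid by
    the envelope theorem), and a boolean ``degenerate`` flag marking cases
    where no interior barrier exists.
    """
    T = np.atleast_1d(np.asarray(T, dtype=float))
    H = np.atleast_1d(np.asarray(H, dtype=float))
    wT = s * T
    wH = s * H
    grid = np.linspace(-0.15, 1.15, 261)
    Ug, _, _, _ = _line_profile(grid[None, :], wT[:, None], wH[:, None], geom)

    upper = grid >= 0.5
    i_w = np.where(upper, Ug, np.inf).argmin(axis=1)
    i_f = np.where(~upper, Ug, np.inf).argmin(axis=1)
    between = (grid[None, :] > grid[i_f][:, None]) & (grid[None, :] < grid[i_w][:, None])
    i_s = np.where(between, Ug, -np.inf).argmax(axis=1)
    degenerate = (i_s <= i_f + 1) | (i_s >= i_w - 1)

    lam = np.stack([grid[i_w], grid[i_f], grid[i_s]], axis=1)  # (m, 3)
    for _ in range(60):
        _, U1, U2, _ = _line_profile(lam, wT[:, None], wH[:, None], geom)
        step = np.where(np.abs(U2) > 1e-14, U1 / U2, 0.0)
        step = np.clip(step, -0.05, 0.05)
        lam = np.clip(lam - step, -0.2, 1.2)
        if np.max(np.abs(step)) < tol:
            break
    U, _, U2, dU_ds_s = _line_profile(lam, wT[:, None], wH[:, None], geom)
    # Newton converges to whatever stationary point is nearest; in
    # degenerate cases keep the grid values instead.
    if degenerate.any():
        m = degenerate
        lam[m] = np.stack([grid[i_w[m]], grid[i_f[m]], grid[i_s[m]]], axis=1)
        U[m], _, _, dU_ds_s[m] = _line_profile(
            lam[m], wT[m][:, None], wH[m][:, None], geom)
    return {"lam": lam, "U": U, "dU_ds_s": dU_ds_s, "degenerate": degenerate}


def saddle_point(needs: NeedState, geom: WellGeometry = DEFAULT_GEOMETRY,
                 s: float = 1.0) -> np.ndarray:
    """Position of the ridge point between the reward wells."""
    ext = line_extrema(needs.thirst, needs.hunger, s, geom)
    lam_s = ext["lam"][0, 2]
    return geom.mu_food + lam_s * (geom.mu_water - geom.mu_food)


def barrier_heights(needs: NeedState, geom: WellGeometry = DEFAULT_GEOMETRY,
                    params: ModelParams = None) -> Tuple[float, float, float]:
    """Energies g*U at (saddle, water minimum, food minimum) on the line.

    Warns when a reward well has zero need (the well vanishes and the
    harmonic picture degenerates).
    """
    if params is None:
        from .landscape import PARAMS_FIT_ALL_SESSIONS as params
    if needs.thirst == 0 or needs.hunger == 0:
        warnings.warn("a reward well has zero need; landscape is degenerate",
                      RuntimeWarning, stacklevel=2)
    ext = line_extrema(needs.thirst, needs.hunger, params.s, geom)
    U_w, U_f, U_s = ext["U"][0, 0], ext["U"][0, 1], ext["U"][0, 2]
    return params.g * U_s, params.g * U_w, params.g * U_f


def kramers_rates(needs: NeedState, geom: WellGeometry = DEFAULT_GEOMETRY,
                  params: ModelParams = None) -> Tuple[float, float]:
    """Escape rates (omega_wf, omega_fw) between the reward wells, in 1/s."""
    if params is None:
        from .landscape import PARAMS_FIT_ALL_SESSIONS as params
    E_s, E_w, E_f = barrier_heights(needs, geom, params)
    if E_s - E_w <= 0 or E_s - E_f <= 0:
        warnings.warn("non-positive barrier; Kramers approximation invalid",
                      RuntimeWarning, stacklevel=2)
    pref = kramers_prefactor(geom.sigma2)
    kT = thermal_scale(params.n)
    omega_wf = pref * np.exp(-(E_s - E_w) / kT)
    omega_fw = pref * np.exp(-(E_s - E_f) / kT)
    return float(omega_wf), float(omega_fw)


@dataclass(frozen=True)
class TransitionMatrix:
    """Two-state transition probabilities after elapsed time t.

    ``matrix`` is row-stochastic with rows (from food, from water) and
    columns (to food, to water): ``[[P_ff, P_fw], [P_wf, P_ww]]``.
    """

    matrix: np.ndarray
    t: float
    omega_wf: float
    omega_fw: float

    @property
    def P_ff(self) -> float:
        return float(self.matrix[0, 0])

    @property
    def P_fw(self) -> float:
        return float(self.matrix[0, 1])

    @property
    def P_wf(self) -> float:
        return float(self.matrix[1, 0])

    @property
    def P_ww(self) -> float:
        return float(self.matrix[1, 1])


def self_transition_probs(t, omega_wf, omega_fw):
    """Closed-form (P_ww(t), P_ff(t)) of the two-state process; broadcasts."""
    Om = omega_wf + omega_fw
    pi_w = omega_fw / Om
    pi_f = omega_wf / Om
    decay = np.exp(-Om * np.asarray(t, dtype=float))
    return (1.0 - pi_w) * decay + pi_w, (1.0 - pi_f) * decay + pi_f


def transition_matrix(t: float, needs: NeedState,
                      geom: WellGeometry = DEFAULT_GEOMETRY,
                      params: ModelParams = None) -> TransitionMatrix:
    """Full time-dependent 2x2 transition matrix between reward states."""
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    omega_wf, omega_fw = kramers_rates(needs, geom, params)
    P_ww, P_ff = self_transition_probs(t, omega_wf, omega_fw)
    mat = np.array([[P_ff, 1.0 - P_ff], [1.0 - P_ww, P_ww]])
    return TransitionMatrix(matrix=mat, t=float(t),
                            omega_wf=omega_wf, omega_fw=omega_fw)


# ---------------------------------------------------------------------------
# Boltzmann equilibrium via midpoint quadrature
# ---------------------------------------------------------------------------

_GRID_BOUNDS = ((-25.0, 20.0), (-20.0, 20.0))
_grid_cache: Dict[tuple, dict] = {}


def _geom_key(geom: WellGeometry, spacing: float) -> tuple:
    return (tuple(geom.mu_other), tuple(geom.mu_water), tuple(geom.mu_food),
            geom.sigma2, spacing)


def quadrature_grid(geom: WellGeometry = DEFAULT_GEOMETRY,
                    spacing: float = 0.125) -> dict:
    """Cached midpoint-rule grid with per-point densities and zone codes."""
    key = _geom_key(geom, spacing)
    if key not in _grid_cache:
        (x0, x1), (y0, y1) = _GRID_BOUNDS
        xs = np.arange(x0 + spacing / 2, x1, spacing)
        ys = np.arange(y0 + spacing / 2, y1, spacing)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()], axis=-1)
        from .landscape import well_density

        phi = {
            "o": well_density(pts, geom.mu_other, geom.sigma2),
            "w": well_density(pts, geom.mu_water, geom.sigma2),
            "f": well_density(pts, geom.mu_food, geom.sigma2),
        }
        labels = zone(pts, geom)
        masks = {
            "w": labels == "water",
            "f": labels == "food",
            "o": labels == "miss",
        }
        _grid_cache[key] = {"pts": pts, "phi": phi, "masks": masks,
                            "spacing": spacing}
    return _grid_cache[key]


def log_zone_integrals(T, H, g: float, n: float, s: float,
                       geom: WellGeometry = DEFAULT_GEOMETRY,
                       spacing: float = 0.125, chunk: int = 32):
    """log of zone-wise integrals of exp(-g U / kT) for batches of (T, H).

    Returns ``logZ`` of shape (m, 3) in (water, food, other) zone order,
    plus the Boltzmann-weighted zone means of U and of s*dU/ds needed for
    analytic likelihood gradients.
    """
    grid = quadrature_grid(geom, spacing)
    phi_o, phi_w, phi_f = grid["phi"]["o"], grid["phi"]["w"], grid["phi"]["f"]
    masks = [grid["masks"]["w"], grid["masks"]["f"], grid["masks"]["o"]]
    T = np.atleast_1d(np.asarray(T, dtype=float))
    H = np.atleast_1d(np.asarray(H, dtype=float))
    m = T.size
    c = g / thermal_scale(n)          # exp(-cU) = M**c
    log_dA = 2.0 * np.log(grid["spacing"])

    logZ = np.empty((m, 3))
    mean_U = np.empty((m, 3))
    mean_dU_ds_s = np.empty((m, 3))
    for a in range(0, m, chunk):
        b = min(a + chunk, m)
        M = (s * T[a:b, None] * phi_w[None, :]
             + s * H[a:b, None] * phi_f[None, :]
             + phi_o[None, :])
        logM = np.log(M)
        U = -logM
        dU_ds_s = -(1.0 - phi_o[None, :] / M)
        logw = c * logM
        for zi, mask in enumerate(masks):
            lw = logw[:, mask]
            mx = lw.max(axis=1, keepdims=True)
            w = np.exp(lw - mx)
            sw = w.sum(axis=1)
            logZ[a:b, zi] = mx[:, 0] + np.log(sw) + log_dA
            mean_U[a:b, zi] = (w * U[:, mask]).sum(axis=1) / sw
            mean_dU_ds_s[a:b, zi] = (w * dU_ds_s[:, mask]).sum(axis=1) / sw
    return logZ, mean_U, mean_dU_ds_s


def boltzmann_choice_probs(needs: NeedState,
                           geom: WellGeometry = DEFAULT_GEOMETRY,
                           params: ModelParams = None,
                           include_other: bool = False,
                           spacing: float = 0.125,
                           check_convergence: bool = False,
                           convergence_tol: float = 1e-3) -> Dict[str, float]:
    """Equilibrium per-cue choice probabilities from the Boltzmann density.

    Zone-wise integrals of exp(-g U / kT), normalized over the water and
    food zones (``include_other=False``) or over all three zones.  With
    ``check_convergence`` the integral is repeated at half the grid
    spacing and an error is raised if any probability moves by more than
    ``convergence_tol``.
    """
    if params is None:
        from .landscape import PARAMS_FIT_ALL_SESSIONS as params

    def probs_at(sp):
        logZ, _, _ = log_zone_integrals(
            needs.thirst, needs.hunger, params.g, params.n, params.s,
            geom, spacing=sp)
        logZ = logZ[0] if include_other else logZ[0, :2]
        w = np.exp(logZ - logZ.max())
        return w / w.sum()

    p = probs_at(spacing)
    if check_convergence:
        p_fine = probs_at(spacing / 2)
        if np.max(np.abs(p - p_fine)) > convergence_tol:
            raise RuntimeError(
                "Boltzmann quadrature has not converged; refine the grid")
    keys = ("water", "food", "other") if include_other else ("water", "food")
    return dict(zip(keys, map(float, p)))
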