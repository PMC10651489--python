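"""Need-scaled energy landscape over the 2-D need subspace.

The model places three isotropic Gaussian wells in a two-dimensional
subspace: one for thirst-related activity (water), one for hunger-related
activity (food), and one for all other needs.  The landscape is the negative
log of a mixture of the three Gaussian densities, with the water and food
components weighted by the current thirst ``T`` and hunger ``H`` magnitudes
(times a shared foraging weight ``s``) and the "other" component fixed at
weight 1.  Raising a need deepens the matching well; the saddles between
wells stay smooth because the mixture is log-sum-exp shaped.

All functions here are pure and accept either a single position (shape
``(2,)``) or a batch of positions (shape ``(..., 2)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WellGeometry",
    "NeedState",
    "ModelParams",
    "DEFAULT_GEOMETRY",
    "PARAMS_FIT_ALL_SESSIONS",
    "PARAMS_FIT_NEUROPIXELS",
    "well_density",
    "mixture_weights",
    "potential",
    "potential_gradient",
    "zone",
    "ZONE_LABELS",
]


@dataclass(frozen=True)
class WellGeometry:
    """Fixed landscape geometry: three well centres and a shared variance.

    Parameters
    ----------
    mu_other, mu_water, mu_food
        Well centres in dimensionless subspace units.  The defaults place
        the three centres on an equilateral triangle.
    sigma2
        Shared isotropic Gaussian variance sigma^2 (> 0).
    """

    mu_other: np.ndarray = field(default_factory=lambda: np.array([-8.0, 0.0]))
    mu_water: np.ndarray = field(default_factory=lambda: np.array([5.0, 7.5]))
    mu_food: np.ndarray = field(default_factory=lambda: np.array([5.0, -7.5]))
    sigma2: float = 20.0

    def __post_init__(self) -> None:
        for name in ("mu_other", "mu_water", "mu_food"):
            mu = np.asarray(getattr(self, name), dtype=float).reshape(2)
            object.__setattr__(self, name, mu)
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise ValueError("sigma2 must be a positive finite scalar")
        centres = (self.mu_other, self.mu_water, self.mu_food)
        for i in range(3):
            for j in range(i + 1, 3):
                if np.allclose(centres[i], centres[j]):
                    raise ValueError("well centres must be pairwise distinct")

    @property
    def centres(self) -> np.ndarray:
        """Stacked centres in (other, water, food) order, shape (3, 2)."""
        return np.stack([self.mu_other, self.mu_water, self.mu_food])

    @property
    def goal_axis(self) -> np.ndarray:
        """Unit vector from the food well to the water well."""
        d = self.mu_water - self.mu_food
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class NeedState:
    """Instantaneous thirst and hunger magnitudes (normalized need units)."""

    thirst: float
    hunger: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.thirst) and np.isfinite(self.hunger)):
            raise ValueError("needs must be finite")
        if self.thirst < 0 or self.hunger < 0:
            raise ValueError("needs must be non-negative")


@dataclass(frozen=True)
class ModelParams:
    """Scale triple of the model.

    g
        Gradient scale: how strongly the landscape pulls the state.
    n
        Noise scale of the Langevin dynamics.
    s
        Foraging weight scaling thirst and hunger relative to other needs.
    """

    g: float
    n: float
    s: float

    def __post_init__(self) -> None:
        if not (self.g > 0 and self.n > 0 and self.s > 0):
            raise ValueError("g, n, s must all be strictly positive")


DEFAULT_GEOMETRY = WellGeometry()

#: Scale parameters fitted on the full behavioural dataset.
PARAMS_FIT_ALL_SESSIONS = ModelParams(g=2.4383774, n=2.74393, s=6.4874935)

#: Scale parameters fitted on the electrophysiology-session subset.
PARAMS_FIT_NEUROPIXELS = ModelParams(g=2.5563507, n=2.807799, s=6.4874935)

ZONE_LABELS = np.array(["miss", "water", "food"])


def _check_positions(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != 2:
        raise ValueError("positions must have trailing dimension 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("positions must be finite")
    return x


def well_density(x: np.ndarray, centre: np.ndarray, sigma2: float) -> np.ndarray:
    """Isotropic bivariate Gaussian density phi(x; centre, sigma^2 I)."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    x = _check_positions(x)
    centre = np.asarray(centre, dtype=float).reshape(2)
    d2 = np.sum((x - centre) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * sigma2)) / (2.0 * np.pi * sigma2)


def mixture_weights(needs: NeedState, s: float) -> np.ndarray:
    """Mixture weights (1, s*T, s*H) over the (other, water, food) wells."""
    if s <= 0:
        raise ValueError("s must be strictly positive")
    return np.array([1.0, s * needs.thirst, s * needs.hunger])


def _mixture(x: np.ndarray, needs: NeedState, geom: WellGeometry, s: float):
    """Weighted mixture value M(x) and the per-well weighted densities."""
    x = _check_positions(x)
    w = mixture_weights(needs, s)
    phis = np.stack(
        [well_density(x, c, geom.sigma2) for c in geom.centres], axis=-1
    )  # (..., 3) in (other, water, food) order
    weighted = phis * w
    return weighted.sum(axis=-1), weighted, phis


def potential(x, needs: NeedState, geom: WellGeometry = DEFAULT_GEOMETRY,
              s: float = PARAMS_FIT_ALL_SESSIONS.s):
    """Landscape depth U(x) = -log(s*T*phi_w(x) + s*H*phi_f(x) + phi_o(x)).

    Wells are local minima; increasing a need deepens (lowers) the matching
    well.  ``T = H = 0`` is allowed (only the "other" well remains).
    """
    m, _, _ = _mixture(x, needs, geom, s)
    return -np.log(m)


def potential_gradient(x, needs: NeedState, geom: WellGeometry = DEFAULT_GEOMETRY,
                       s: float = PARAMS_FIT_ALL_SESSIONS.s):
    """Analytic spatial gradient of :func:`potential`.

    grad U(x) = sum_i w_i phi_i(x) (x - mu_i) / sigma^2 / M(x), the exact
    closed form of the Gaussian-mixture negative log density.
    """
    x = _check_positions(x)
    m, weighted, _ = _mixture(x, needs, geom, s)
    diffs = x[..., None, :] - geom.centres  # (..., 3, 2)
    num = np.sum(weighted[..., :, None] * diffs, axis=-2) / geom.sigma2
    return num / m[..., None]


def zone(x, geom: WellGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Behavioural zone of position(s): ``'miss'``, ``'water'`` or ``'food'``.

    Maximum-likelihood partition of the *unscaled* densities, independent of
    needs and of ``s``: miss wherever the "other" density is >= both reward
    densities; otherwise water wherever phi_w >= phi_f, else food.  Ties are
    measure-zero and resolved miss-first, then water.
    """
    x = _check_positions(x)
    phi_o = well_density(x, geom.mu_other, geom.sigma2)
    phi_w = well_density(x, geom.mu_water, geom.sigma2)
    phi_f = well_density(x, geom.mu_food, geom.sigma2)
    idx = np.where(
        (phi_o >= phi_w) & (phi_o >= phi_f),
        0,
        np.where(phi_w >= phi_f, 1, 2),
    )
    return ZONE_LABELS[idx]
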