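"""Pointwise kinetics of the growth/edema model, and the initial condition.

The model tracks six fields on the gray/white-matter mask:

``c``  normoxic tumor cells, ``h`` hypoxic tumor cells, ``n`` necrotic cells,
``v`` vascular (endothelial) cells — all stored internally as fractions of
the carrying capacity ``K``; ``a`` angiogenic factors (mmol/cc tissue);
``l`` edematous fluid as a fraction of the capillary fluid level ``l_v``.

With total occupancy ``T = c + h + n + v`` and vascular efficiency
``V = v / (v + c + h)`` (the oxygen-supply surrogate), the local (transport-
free) kinetics per day are::

    dc = rho*c*(1-T) + gamma*h*V - beta*c*(1-V) - alpha_n*n*c
    dh = -gamma*h*V + beta*c*(1-V) - alpha_h*h*(1-V) - alpha_n*n*h
    dn = alpha_h*h*(1-V) + alpha_n*n*(c+h+v)
    dv = mu*a/(K_m+a)*v*(1-T) - alpha_n*n*v
    da = delta_c*c + delta_h*h - q*mu*a/(K_m+a)*v*(1-T) - omega*a*v - lambda*a
    dl = K_trans(a)*(l_v - l) - delta_l*l

where the vessel permeability follows Michaelis-Menten saturation in the
angiogenic-factor level, ``K_trans(a) = K_max * a / (a + K_half)``.

Conversions between c, h, n, v only move mass between compartments: with
proliferation disabled (rho = mu = 0) the kinetics conserve c + h + n + v
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import GeometryError, TissueMap
from .parameters import InternalParameters, ModelParameters

#: Order of the species in stacked arrays.
SPECIES = ("c", "h", "n", "v", "a", "l")


class StateError(ValueError):
    """Invalid state fields (negative values, NaN, shape mismatch)."""


@dataclass
class StateFields:
    """The six model fields at one time point.

    ``c, h, n, v`` are fractions of the carrying capacity; ``a`` is in
    mmol/cc tissue; ``l`` is a fraction of the capillary fluid level.
    Fields are dense 2D arrays over the tissue grid; voxels outside the
    simulation mask stay identically zero.
    """

    c: np.ndarray
    h: np.ndarray
    n: np.ndarray
    v: np.ndarray
    a: np.ndarray
    l: np.ndarray
    time_days: float = 0.0

    @classmethod
    def zeros(cls, shape: tuple[int, int], time_days: float = 0.0) -> "StateFields":
        return cls(*(np.zeros(shape) for _ in SPECIES), time_days=time_days)

    def copy(self) -> "StateFields":
        return StateFields(*(getattr(self, s).copy() for s in SPECIES),
                           time_days=self.time_days)

    def stack(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Stack fields into (n_voxels, 6) over ``mask`` (or the full grid)."""
        if mask is None:
            return np.stack([getattr(self, s).ravel() for s in SPECIES], axis=1)
        return np.stack([getattr(self, s)[mask] for s in SPECIES], axis=1)

    def validate(self, tol: float = 1e-10) -> None:
        """Raise :class:`StateError` on NaN or negative values below -tol."""
        for s in SPECIES:
            arr = getattr(self, s)
            if np.any(np.isnan(arr)):
                raise StateError(f"NaN in field {s!r} at t={self.time_days}")
            if arr.min(initial=0.0) < -tol:
                raise StateError(
                    f"negative values in field {s!r} at t={self.time_days}: "
                    f"min={arr.min()}")


def ktrans(a: np.ndarray | float, params: ModelParameters | InternalParameters):
    """Vessel permeability K_trans (1/day) as a saturating function of the
    angiogenic-factor level: ``K_max * a / (a + K_half)``.

    Strictly increasing in ``a``, zero at zero, saturating at ``K_max``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise StateError("angiogenic-factor level must be nonnegative")
    out = params.K_max * a / (a + params.K_half)
    return float(out) if out.ndim == 0 else out


def total_occupancy(state: StateFields, params=None) -> np.ndarray:
    """Dimensionless occupancy T = (c + h + n + v) / K.

    Fields are stored as fractions of K, so this is a plain sum.
    """
    return state.c + state.h + state.n + state.v


def vascular_efficiency(state: StateFields) -> np.ndarray:
    """Oxygen-supply surrogate V = v / (v + c + h), in [0, 1].

    Where no cells are present (v + c + h = 0) there is no vasculature and
    hence no oxygen delivery, so V is defined as 0 there.
    """
    return _efficiency(state.c, state.h, state.v)


def _efficiency(c, h, v):
    denom = v + c + h
    with np.errstate(invalid="ignore", divide="ignore"):
        V = np.where(denom > 0.0, v / np.where(denom > 0.0, denom, 1.0), 0.0)
    return V


def reaction_rates(state: StateFields, params: InternalParameters,
                   validate: bool = True) -> StateFields:
    """Pointwise time derivatives (per day) of all six fields, transport
    excluded.  Input cell fields are fractions of K."""
    if validate:
        state.validate()
    dc, dh, dn, dv, da, dl = _rates_arrays(
        state.c, state.h, state.n, state.v, state.a, state.l, params)
    return StateFields(dc, dh, dn, dv, da, dl, time_days=state.time_days)


def _rates_arrays(c, h, n, v, a, l, p: InternalParameters):
    """Vectorized kinetics on bare arrays (any matching shape).

    Used both on full 2D grids and on (n_voxels,) masked vectors; this is
    the single implementation the implicit reaction integrator Newton-solves.
    """
    T = c + h + n + v
    V = _efficiency(c, h, v)
    one_mT = 1.0 - T
    one_mV = 1.0 - V

    hyp_to_norm = p.gamma * h * V
    norm_to_hyp = p.beta * c * one_mV
    hyp_to_nec = p.alpha_h * h * one_mV
    contact = p.alpha_n * n

    a_pos = np.maximum(a, 0.0)  # Newton iterates may transiently undershoot
    vprolif = p.mu * a_pos / (p.K_m + a_pos) * v * one_mT

    dc = p.rho * c * one_mT + hyp_to_norm - norm_to_hyp - contact * c
    dh = -hyp_to_norm + norm_to_hyp - hyp_to_nec - contact * h
    dn = hyp_to_nec + contact * (c + h + v)
    dv = vprolif - contact * v
    da = (p.delta_c * c + p.delta_h * h
          - p.q * vprolif - p.omega * a * v - p.lambda_ * a)
    if p.drainage_model == "permeability":
        drain = 0.3 * p.K_max * a_pos / (a_pos + p.K_half)
    else:
        drain = p.delta_l
    dl = p.K_max * a_pos / (a_pos + p.K_half) * (p.l_v - l) - drain * l
    return dc, dh, dn, dv, da, dl


@dataclass(frozen=True)
class SeedSpec:
    """Gaussian inoculum of normoxic cells.

    ``amplitude`` is in cells/mm^3 (converted to a fraction of K when the
    state is built); ``falloff`` is the Gaussian decay constant in 1/mm^2.
    With the default falloff of 100/mm^2 the seed is effectively a
    single-voxel inoculum on a 1 mm grid.  ``snap`` moves the center to the
    nearest voxel center so the seed voxel carries exactly ``amplitude``.
    """

    center: tuple[float, float] = (103.0, 83.0)
    amplitude: float = 1000.0
    falloff: float = 100.0
    snap: bool = True


def initial_state(tissue: TissueMap, seed: SeedSpec,
                  params: ModelParameters) -> StateFields:
    """Build the t = 0 state: a Gaussian normoxic seed, vasculature at 3% of
    the carrying capacity in all gray and white matter, everything else zero.

    Raises :class:`GeometryError` when the seed center is not in gray/white
    matter.
    """
    ix, iy = tissue.voxel_at(*seed.center)
    if not tissue.mask[ix, iy]:
        raise GeometryError(
            f"seed center {seed.center} mm lies in "
            f"{'CSF' if tissue.labels[ix, iy] else 'OUTSIDE'} tissue")

    x, y = tissue.voxel_centers()
    if seed.snap:
        x0 = float(tissue.origin[0] + (ix + 0.5) * tissue.spacing)
        y0 = float(tissue.origin[1] + (iy + 0.5) * tissue.spacing)
    else:
        x0, y0 = seed.center

    state = StateFields.zeros(tissue.labels.shape)
    r2 = (x - x0) ** 2 + (y - y0) ** 2
    amp_fraction = seed.amplitude / params.K
    if amp_fraction > 1.0:
        raise StateError(
            f"seed amplitude {seed.amplitude} exceeds carrying capacity")
    state.c[:] = amp_fraction * np.exp(-seed.falloff * r2)
    state.c[~tissue.mask] = 0.0
    state.v[tissue.mask] = 0.03
    return state
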