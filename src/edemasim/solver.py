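"""Spatial discretization and time integration.

First-order finite volumes on the gray/white-matter mask with homogeneous
Neumann (no-flux) boundaries; one simulated day per step, split into a
reaction step (TR-BDF2, L-stable, per-voxel Newton) followed by an implicit
(backward Euler) diffusion solve for each mobile species.  Necrotic cells do
not move.  The density-limited transport of the cellular species uses a
``(1 - T)`` gate frozen at the step's start, which keeps each diffusion
solve linear; angiogenic factors and edema fluid diffuse ungated.

CSF and outside-brain voxels are removed from the unknown set entirely, so
no mass can leak into them through either transport or reactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import TissueMap
from .imaging import ImagingThresholds, edema_mask, equivalent_radius, t1gd_mask, tumor_extent_mask
from .kinetics import SPECIES, StateFields, _rates_arrays
from .parameters import InternalParameters, ModelParameters
from .therapy import TreatmentProtocol, modified_parameters, treatment_active

log = logging.getLogger(__name__)

#: TR-BDF2 intermediate stage fraction; the standard L-stable choice.
TRBDF2_GAMMA = 2.0 - np.sqrt(2.0)

#: Fraction-of-K threshold below which a voxel is treated as empty by the
#: reaction integrator (the empty state is an exact fixed point).
ACTIVE_EPS = 1e-16

#: Negative-undershoot clamp threshold in fraction-of-K units.
CLAMP_TOL = 1e-10


class SolverError(RuntimeError):
    """Linear-solve or Newton failure."""


# --------------------------------------------------------------- transport

@dataclass
class TransportOperator:
    """Finite-volume coupling structure over the masked voxels.

    Holds the mask flattening and the list of faces between adjacent masked
    voxels with the diffusion coefficient on each side; the assembled
    Laplacian-like matrix ``L`` (symmetric, zero row sums, nonnegative
    off-diagonals) is produced for a given gate field by :meth:`assemble`.
    Face conductances are harmonic means of the per-voxel ``D * gate`` over
    ``spacing**2``; faces to CSF/OUTSIDE carry zero flux.
    """

    mask: np.ndarray
    index: np.ndarray          # (nx, ny) int; -1 outside mask
    faces: np.ndarray          # (n_faces, 2) masked-voxel index pairs
    D: np.ndarray              # (n_unknowns,) diffusion coefficient, mm^2/day
    spacing: float

    @property
    def n_unknowns(self) -> int:
        return int(self.mask.sum())

    def assemble(self, gate: np.ndarray | None = None) -> sp.csc_matrix:
        """Assemble L for per-voxel coefficient ``D * gate`` (gate clamped
        to [0, 1]; ``None`` means no gate)."""
        coeff = self.D.copy()
        if gate is not None:
            coeff = coeff * np.clip(gate, 0.0, 1.0)
        i, j = self.faces[:, 0], self.faces[:, 1]
        ci, cj = coeff[i], coeff[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(ci + cj > 0.0, 2.0 * ci * cj / (ci + cj), 0.0)
        g = g / self.spacing**2
        n = self.n_unknowns
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([g, g, -g, -g])
        return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def build_transport_operator(D_field: np.ndarray, tissue: TissueMap) -> TransportOperator:
    """Build the masked finite-volume structure for a per-voxel diffusion
    coefficient field (mm^2/day)."""
    mask = tissue.mask
    if not mask.any():
        raise SolverError("empty simulation mask")
    if np.any(D_field < 0):
        raise SolverError("diffusion coefficients must be nonnegative")
    nx, ny = mask.shape
    index = -np.ones((nx, ny), dtype=np.int64)
    index[mask] = np.arange(mask.sum())

    pairs = []
    # x-faces
    m = mask[:-1, :] & mask[1:, :]
    pairs.append(np.stack([index[:-1, :][m], index[1:, :][m]], axis=1))
    # y-faces
    m = mask[:, :-1] & mask[:, 1:]
    pairs.append(np.stack([index[:, :-1][m], index[:, 1:][m]], axis=1))
    faces = np.concatenate(pairs, axis=0)
    return TransportOperator(mask=mask, index=index, faces=faces,
                             D=np.asarray(D_field, dtype=float)[mask],
                             spacing=tissue.spacing)


class _ImplicitDiffuser:
    """Backward-Euler solver (I - dt*L) u = u_old with factorization reuse.

    The sparse LU factorization is recomputed only when the gate field has
    moved by more than ``refactor_tol`` in max-norm since it was built — a
    performance contract: within that band the previous gate is reused.
    """

    def __init__(self, op: TransportOperator, dt: float,
                 refactor_tol: float = 0.01):
        self.op = op
        self.dt = dt
        self.refactor_tol = refactor_tol
        self._gate = None
        self._lu = None

    def _ensure_factorization(self, gate: np.ndarray | None) -> None:
        if self._lu is not None:
            if gate is None and self._gate is None:
                return
            if (gate is not None and self._gate is not None
                    and np.max(np.abs(gate - self._gate)) <= self.refactor_tol):
                return
        L = self.op.assemble(gate)
        A = sp.eye(self.op.n_unknowns, format="csc") - self.dt * L
        try:
            self._lu = splu(A)
        except RuntimeError as exc:  # pragma: no cover - pathological input
            raise SolverError(f"diffusion linear solve failed: {exc}") from exc
        self._gate = None if gate is None else gate.copy()

    def step(self, u: np.ndarray, gate: np.ndarray | None) -> np.ndarray:
        self._ensure_factorization(gate)
        return self._lu.solve(u)


def diffuse_implicit(field_2d: np.ndarray, op: TransportOperator,
                     gate_field: np.ndarray | None, dt: float) -> np.ndarray:
    """One backward-Euler diffusion step of a full-grid field.

    ``gate_field`` is the dimensionless density gate (e.g. ``1 - T``)
    sampled on the grid, frozen over the step; ``None`` disables gating.
    Conserves the field total to linear-solver accuracy (no-flux walls).
    """
    if dt <= 0:
        raise SolverError(f"dt must be positive, got {dt}")
    gate = None if gate_field is None else np.asarray(gate_field)[op.mask]
    u = np.asarray(field_2d)[op.mask]
    solver = _ImplicitDiffuser(op, dt)
    out = field_2d.copy()
    out[op.mask] = solver.step(u, gate)
    return out


# ---------------------------------------------------------------- reactions

def _trbdf2_masked(u: np.ndarray, p: InternalParameters, dt: float,
                   tol: float, max_iter: int = 25) -> np.ndarray:
    """One reaction step on stacked states (N, 6).

    The five coupled species (c, h, n, v, a) take one TR-BDF2 step with
    per-voxel Newton iteration.  The edema fluid does not feed back into any
    other equation and relaxes on a much faster scale (K_trans + delta_l can
    exceed 40/day, far outside TR-BDF2's positivity region at a 1-day step),
    so ``l`` is updated with the exact exponential solution of its linear
    ODE, with the permeability frozen at the step-mean factor level — exact
    for constant ``a`` and unconditionally positive.
    """
    g = TRBDF2_GAMMA
    w = u[:, :5]
    f0 = _f(w, p)
    # Stage 1: trapezoidal to t + g*dt
    w1 = _newton(lambda x: x - 0.5 * g * dt * _f(x, p) - (w + 0.5 * g * dt * f0),
                 w, p, 0.5 * g * dt, tol, max_iter, "TR stage")
    # Stage 2: BDF2 to t + dt
    c1 = 1.0 / (g * (2.0 - g))
    c0 = (1.0 - g) ** 2 / (g * (2.0 - g))
    cf = (1.0 - g) / (2.0 - g)
    rhs = c1 * w1 - c0 * w
    w2 = _newton(lambda x: x - cf * dt * _f(x, p) - rhs,
                 w1, p, cf * dt, tol, max_iter, "BDF2 stage")

    out = np.empty_like(u)
    out[:, :5] = w2
    out[:, 5] = _edema_exact(u[:, 5], 0.5 * (np.maximum(u[:, 4], 0.0)
                                             + np.maximum(w2[:, 4], 0.0)),
                             p, dt)
    return out


def _edema_exact(l0: np.ndarray, a: np.ndarray, p: InternalParameters,
                 dt: float) -> np.ndarray:
    """Exact solution of dl/dt = K_trans(a)(l_v - l) - delta_l*l at fixed a."""
    kt = p.K_max * a / (a + p.K_half)
    if p.drainage_model == "permeability":
        drain = 0.3 * kt
    else:
        drain = p.delta_l
    B = kt + drain
    leq = np.where(B > 0.0, kt * p.l_v / np.where(B > 0.0, B, 1.0), 0.0)
    return leq + (l0 - leq) * np.exp(-B * dt)


def _f(u: np.ndarray, p: InternalParameters) -> np.ndarray:
    """Rates of the five coupled species on stacked (N, 5) states."""
    zero_l = np.zeros(u.shape[0])
    rates = _rates_arrays(u[:, 0], u[:, 1], u[:, 2], u[:, 3], u[:, 4], zero_l, p)
    return np.stack(rates[:5], axis=1)


def _newton(residual, u0: np.ndarray, p: InternalParameters, a_dt: float,
            tol: float, max_iter: int, label: str) -> np.ndarray:
    """Newton iteration on G(w) = w - a_dt*f(w) - rhs, batched per voxel.

    The Jacobian of f is formed by forward differences, which is cheap for
    the coupled 5-species system and accurate enough for quadratic-looking
    convergence at the 1e-8 tolerance used here.
    """
    u = u0.copy()
    # Cell species are O(1) fractions; the factor level lives at the
    # K_half scale, so convergence is judged per species.
    scale = np.maximum(_species_scales(p), np.abs(u0).max(axis=0, initial=0.0))
    for _ in range(max_iter):
        r = residual(u)
        err = (np.abs(r) / scale).max() if r.size else 0.0
        if err < tol:
            return u
        J = _fd_jacobian(u, p)
        A = -a_dt * J
        A[:, np.arange(5), np.arange(5)] += 1.0
        try:
            delta = np.linalg.solve(A, -r[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular Newton system in {label}") from exc
        u = u + delta
    worst = int(np.argmax(np.abs(residual(u)).max(axis=1)))
    raise SolverError(
        f"Newton failed to converge in {label} after {max_iter} iterations "
        f"(worst voxel index {worst}); the reaction system may be too stiff "
        f"for this step size")


def _species_scales(p: InternalParameters) -> np.ndarray:
    """Natural magnitude of each coupled species (c, h, n, v as fractions
    of K; a at the half-saturation scale)."""
    return np.array([1.0, 1.0, 1.0, 1.0, p.K_half])


def _fd_jacobian(u: np.ndarray, p: InternalParameters) -> np.ndarray:
    """Forward-difference Jacobian of the coupled reaction rates, (N, 5, 5)."""
    f0 = _f(u, p)
    J = np.empty(u.shape[:1] + (5, 5))
    for k in range(5):
        h = 1e-7 * np.maximum(np.abs(u[:, k]), 1e-4 * _species_scales(p)[k])
        up = u.copy()
        up[:, k] += h
        J[:, :, k] = (_f(up, p) - f0) / h[:, None]
    return J


def reaction_substeps(params: InternalParameters, dt: float) -> int:
    """Sub-steps needed to keep the fastest linear reaction rate inside
    TR-BDF2's positivity region (|z| < ~2.4; 2.0 with margin).

    Relevant for the treated parameter set, whose 10x-boosted
    hypoxic->normoxic rate would otherwise produce oscillatory negative
    populations at a 1-day step.
    """
    fastest = max(params.gamma, params.beta, params.alpha_h,
                  params.alpha_n, params.mu, params.lambda_)
    return max(1, int(np.ceil(dt * fastest / 2.0)))


def react_trbdf2(state: StateFields, params: InternalParameters, dt: float,
                 tol: float = 1e-8, mask: np.ndarray | None = None,
                 clamp_tol: float = CLAMP_TOL,
                 substeps: int | None = None) -> StateFields:
    """TR-BDF2 reaction step over the whole grid (or ``mask``).

    The step is internally divided into :func:`reaction_substeps` equal
    sub-steps when the kinetics are too fast for a positive single step.
    Voxels indistinguishable from the empty/background fixed point are
    skipped.  Final values within the clamp band below zero are clamped;
    anything more negative raises :class:`SolverError` naming the voxel.
    """
    if tol <= 0:
        raise SolverError("tol must be positive")
    state.validate(tol=clamp_tol)
    if mask is None:
        mask = np.ones(state.c.shape, dtype=bool)
    u = state.stack(mask)
    # Background voxels (no tumor, no factors, no fluid) are exact fixed
    # points of the kinetics: only solve where something is present.
    active = (u[:, [0, 1, 2, 4, 5]].max(axis=1) > ACTIVE_EPS)
    out = state.copy()
    out.time_days = state.time_days + dt
    if not active.any():
        return out
    m = substeps if substeps is not None else reaction_substeps(params, dt)
    u_new = u[active]
    for _ in range(m):
        u_new = _trbdf2_masked(u_new, params, dt / m, tol)

    # Clamp band per species: Newton leaves residual errors of order
    # tol * species scale, so the band must sit above them.
    scales = np.append(_species_scales(params), params.l_v)
    band = np.maximum(clamp_tol, 10.0 * tol) * scales
    worst = (u_new / band).min()
    if worst < -1.0:
        vox, spec = np.unravel_index(np.argmin(u_new / band), u_new.shape)
        raise SolverError(
            f"negative undershoot {u_new[vox, spec]:.3e} in species "
            f"{SPECIES[spec]!r} (active voxel {vox}) at t={state.time_days}")
    np.clip(u_new, 0.0, None, out=u_new)

    flat_idx = np.flatnonzero(mask.ravel())[active]
    for k, s in enumerate(SPECIES):
        arr = getattr(out, s).ravel()
        arr[flat_idx] = u_new[:, k]
    return out


# ------------------------------------------------------------------ advance

class SplitStepper:
    """Operator-split day stepper: reactions then implicit diffusion.

    Mobile species and their gates: ``c, h`` diffuse with the tissue
    invasion field and the ``(1 - T)`` gate; ``v`` with ``D_v`` gated by
    ``(1 - T)``; ``a`` with ``D_a`` ungated; ``l`` with ``D_l`` ungated;
    ``n`` is immobile.
    """

    def __init__(self, tissue: TissueMap, params: ModelParameters,
                 dt: float = 1.0, newton_tol: float = 1e-8):
        from .geometry import invasion_field

        self.tissue = tissue
        self.dt = dt
        self.newton_tol = newton_tol
        self.params = params
        p = params.to_internal()
        self.internal = p
        D_cells = invasion_field(tissue, p.D_w, p.D_g)  # already per-day
        D_v = np.where(tissue.mask, p.D_v, 0.0)
        D_a = np.where(tissue.mask, p.D_a, 0.0)
        D_l = np.where(tissue.mask, p.D_l, 0.0)
        self.op_cells = build_transport_operator(D_cells, tissue)
        self.op_v = build_transport_operator(D_v, tissue)
        self.op_a = build_transport_operator(D_a, tissue)
        self.op_l = build_transport_operator(D_l, tissue)
        self._diff_cells = _ImplicitDiffuser(self.op_cells, dt)
        self._diff_v = _ImplicitDiffuser(self.op_v, dt)
        self._diff_a = _ImplicitDiffuser(self.op_a, dt)
        self._diff_l = _ImplicitDiffuser(self.op_l, dt)

    def set_params(self, params: ModelParameters) -> None:
        """Swap the reaction parameters (therapy on/off).  Transport
        coefficients are not modified by therapy."""
        self.params = params
        self.internal = params.to_internal()

    def advance(self, state: StateFields) -> StateFields:
        """One split step: TR-BDF2 reactions, then backward-Euler diffusion
        of each mobile species with the gate frozen at the post-reaction
        densities."""
        mask = self.tissue.mask
        state = react_trbdf2(state, self.internal, self.dt,
                             tol=self.newton_tol, mask=mask)
        gate = 1.0 - (state.c + state.h + state.n + state.v)[mask]
        np.clip(gate, 0.0, 1.0, out=gate)
        state.c[mask] = self._diff_cells.step(state.c[mask], gate)
        state.h[mask] = self._diff_cells.step(state.h[mask], gate)
        state.v[mask] = self._diff_v.step(state.v[mask], gate)
        state.a[mask] = self._diff_a.step(state.a[mask], None)
        state.l[mask] = self._diff_l.step(state.l[mask], None)
        return state


def advance(state: StateFields, tissue: TissueMap, params: ModelParameters,
            dt: float = 1.0) -> StateFields:
    """One operator-split step (convenience wrapper building a fresh
    :class:`SplitStepper`; use the class directly for multi-day runs)."""
    return SplitStepper(tissue, params, dt=dt).advance(state)


# ----------------------------------------------------------------- simulate

@dataclass
class Trajectory:
    """Daily record of a simulation run.

    ``records`` holds one row per day: day, the three imaging radii (mm)
    and whether the step into that day was treated.  ``events`` logs the
    treatment trigger and termination.  ``snapshots`` holds full states at
    requested days.
    """

    records: list[dict] = field(default_factory=list)
    events: list[tuple[float, str]] = field(default_factory=list)
    snapshots: dict[float, StateFields] = field(default_factory=dict)
    trigger_day: float | None = None

    @property
    def days(self) -> np.ndarray:
        return np.array([r["day"] for r in self.records])

    def save_snapshots_hdf5(self, path) -> None:
        """Write all stored snapshots to one HDF5 bundle."""
        import h5py

        with h5py.File(path, "w") as fh:
            for day, snap in sorted(self.snapshots.items()):
                grp = fh.create_group(f"day_{day:g}")
                for s in SPECIES:
                    grp.create_dataset(s, data=getattr(snap, s),
                                       compression="gzip")

    def save_snapshot_nifti(self, day: float, outdir, spacing: float) -> None:
        """Write one snapshot as NIfTI, one file per species."""
        import nibabel as nib
        from pathlib import Path

        snap = self.snapshots[day]
        affine = np.diag([spacing, spacing, 1.0, 1.0])
        for s in SPECIES:
            img = nib.Nifti1Image(np.asarray(getattr(snap, s), dtype=np.float32),
                                  affine)
            nib.save(img, str(Path(outdir) / f"{s}_day{day:g}.nii.gz"))


def simulate(
    initial: StateFields,
    tissue: TissueMap,
    params: ModelParameters,
    protocol: TreatmentProtocol | None = None,
    horizon: float = 365.0,
    thresholds: ImagingThresholds | None = None,
    dt: float = 1.0,
    snapshot_days: list[float] | None = None,
    stop_rule=None,
    observers: list | None = None,
) -> Trajectory:
    """Run the model with daily steps, virtual-imaging observation, and an
    optional anti-angiogenic course.

    When a ``protocol`` is given, the trigger is checked once per simulated
    day on the T1Gd circle-equivalent radius; from the day it first reaches
    the trigger radius, the treated parameter set applies for
    ``protocol.duration_days`` days and then reverts.  ``stop_rule`` (called
    with the trajectory after each day) may end the run early; ``observers``
    are callables ``(day, state, record_dict)`` invoked after each step.
    """
    if horizon < dt:
        raise SolverError(f"horizon {horizon} shorter than one step {dt}")
    thresholds = thresholds or ImagingThresholds()
    snapshot_days = set(snapshot_days or [])

    stepper = SplitStepper(tissue, params, dt=dt)
    treated_params = (modified_parameters(params, protocol)
                      if protocol is not None else None)

    traj = Trajectory()
    state = initial.copy()

    def record(day: float, state: StateFields, on: bool) -> None:
        spacing = tissue.spacing
        row = {
            "day": day,
            "r_t1gd_mm": equivalent_radius(t1gd_mask(state, params, thresholds), spacing),
            "r_tumor_mm": equivalent_radius(tumor_extent_mask(state, params, thresholds), spacing),
            "r_edema_mm": equivalent_radius(edema_mask(state, params, thresholds), spacing),
            "treatment_on": bool(on),
        }
        traj.records.append(row)
        for obs in observers or ():
            obs(day, state, row)
        if day in snapshot_days:
            traj.snapshots[day] = state.copy()

    record(0.0, state, False)
    n_steps = int(round(horizon / dt))
    currently_treated = False
    for k in range(n_steps):
        t = k * dt
        if protocol is not None:
            on = treatment_active(t, traj.trigger_day, protocol)
            if on != currently_treated:
                stepper.set_params(treated_params if on else params)
                currently_treated = on
                traj.events.append(
                    (t, "treatment_start" if on else "treatment_end"))
        try:
            state = stepper.advance(state)
        except SolverError as exc:
            raise SolverError(f"day {t + dt:g}: {exc}") from exc
        day = t + dt
        record(day, state, currently_treated)
        if (protocol is not None and traj.trigger_day is None
                and traj.records[-1]["r_t1gd_mm"] >= protocol.trigger_radius_mm):
            traj.trigger_day = day
            traj.events.append((day, "trigger"))
            log.info("treatment trigger at day %g (r_t1gd=%.2f mm)",
                     day, traj.records[-1]["r_t1gd_mm"])
        if stop_rule is not None and stop_rule(traj):
            traj.events.append((day, "stopped"))
            break
    return traj
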