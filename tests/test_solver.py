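"""Transport and time-integration numerics.

Oracles: hand finite-volume stencils, exact conservation, the heat-kernel
variance growth, closed-form logistic and edema-relaxation solutions, a
high-accuracy adaptive reference integrator, and the pulled-front speed
2*sqrt(D*rho) of the linearized invasion edge.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import edemasim as es
from edemasim.kinetics import SPECIES, StateFields
from edemasim.solver import (SolverError, SplitStepper, _ImplicitDiffuser,
                             build_transport_operator, diffuse_implicit,
                             react_trbdf2, reaction_substeps)

from conftest import random_state


def strip_map(n=120, width=3, spacing=1.0):
    """A homogeneous white-matter strip."""
    labels = np.full((n, width), es.WHITE, dtype=np.int8)
    return es.TissueMap(labels, spacing=spacing)


class TestTransportOperator:
    def test_rows_sum_to_zero_and_offdiagonals_nonnegative(self, phantom):
        D = es.invasion_field(phantom, 53.0, 5.3)
        op = build_transport_operator(D, phantom)
        L = op.assemble(None)
        assert np.abs(L.sum(axis=1)).max() < 1e-12
        off = L.tolil()
        off.setdiag(0.0)
        assert min(off.tocsr().data.min(initial=0.0), 0.0) == 0.0
        asym = (L - L.T).tocsr()
        assert (np.abs(asym.data).max() if asym.nnz else 0.0) < 1e-14

    def test_uniform_field_in_null_space(self, phantom):
        D = es.invasion_field(phantom, 53.0, 5.3)
        op = build_transport_operator(D, phantom)
        L = op.assemble(None)
        u = np.ones(op.n_unknowns)
        assert np.abs(L @ u).max() < 1e-12

    def test_two_voxel_stencil(self):
        """1x2 domain with equal D: off-diagonal entries are D/spacing^2."""
        labels = np.full((2, 1), es.WHITE, dtype=np.int8)
        t = es.TissueMap(labels, spacing=2.0)
        op = build_transport_operator(np.full((2, 1), 5.0), t)
        L = op.assemble(None).toarray()
        assert L[0, 1] == pytest.approx(5.0 / 4.0)
        assert L == pytest.approx(np.array([[-1.25, 1.25], [1.25, -1.25]]))

    def test_harmonic_mean_face_conductance(self):
        labels = np.full((2, 1), es.WHITE, dtype=np.int8)
        t = es.TissueMap(labels, spacing=1.0)
        op = build_transport_operator(np.array([[2.0], [8.0]]), t)
        L = op.assemble(None).toarray()
        assert L[0, 1] == pytest.approx(2 * 2.0 * 8.0 / (2.0 + 8.0))

    def test_empty_mask_rejected(self):
        labels = np.full((4, 4), es.CSF, dtype=np.int8)
        t = es.TissueMap(labels)
        with pytest.raises(SolverError):
            build_transport_operator(np.zeros((4, 4)), t)


class TestDiffuseImplicit:
    def test_uniform_field_unchanged(self, phantom):
        D = es.invasion_field(phantom, 53.0, 5.3)
        op = build_transport_operator(D, phantom)
        u = np.where(phantom.mask, 0.7, 0.0)
        out = diffuse_implicit(u, op, None, dt=1.0)
        assert np.allclose(out[phantom.mask], 0.7, atol=1e-12)

    def test_mass_conserved(self, phantom, rng):
        D = es.invasion_field(phantom, 53.0, 5.3)
        op = build_transport_operator(D, phantom)
        u = np.where(phantom.mask, rng.random(phantom.labels.shape), 0.0)
        gate = np.where(phantom.mask, rng.random(phantom.labels.shape), 0.0)
        out = diffuse_implicit(u, op, gate, dt=1.0)
        assert out.sum() == pytest.approx(u.sum(), rel=1e-10)

    def test_heat_kernel_variance_growth(self):
        """Point mass on a homogeneous domain: after time t the profile's
        variance along each axis grows like 2*D*t (Gaussian solution)."""
        n, D, dt, steps = 81, 1.5, 0.05, 80
        labels = np.full((n, n), es.WHITE, dtype=np.int8)
        t = es.TissueMap(labels, spacing=1.0)
        op = build_transport_operator(np.full((n, n), D), t)
        u = np.zeros((n, n))
        u[n // 2, n // 2] = 1.0
        solver = _ImplicitDiffuser(op, dt)
        vec = u[t.mask]
        for _ in range(steps):
            vec = solver.step(vec, None)
        u = vec.reshape(n, n)
        x = np.arange(n) - n // 2
        var_x = (u * x[:, None] ** 2).sum() / u.sum()
        # Backward Euler adds D*dt per step of numerical variance; with
        # dt << total time the 2*D*t growth dominates.
        assert var_x == pytest.approx(2 * D * dt * steps, rel=0.05)

    def test_csf_blocks_flux(self):
        labels = np.full((3, 1), es.WHITE, dtype=np.int8)
        labels[1, 0] = es.CSF
        t = es.TissueMap(labels)
        op = build_transport_operator(np.full((3, 1), 10.0), t)
        u = np.zeros((3, 1)); u[0, 0] = 1.0
        out = diffuse_implicit(u, op, None, dt=10.0)
        assert out[2, 0] == 0.0 and out[0, 0] == pytest.approx(1.0)


class TestReactTRBDF2:
    def test_zero_state_fixed_point(self, default_params):
        s = StateFields.zeros((3, 3))
        out = react_trbdf2(s, default_params.to_internal(), dt=1.0)
        assert all(np.all(getattr(out, k) == 0.0) for k in SPECIES)
        assert out.time_days == 1.0

    def test_logistic_closed_form(self):
        """Pure normoxic logistic growth (switching, necrosis, angiogenesis
        disabled): one 1-day step matches c(t) = c0/(c0+(1-c0)e^{-rho t})."""
        p = es.ModelParameters(rho=75.0, beta=0.0, gamma=0.0, alpha_h=0.0,
                               alpha_n=0.0, mu=0.0, delta_c=0.0,
                               delta_h=1e-12, lambda_=0.0).to_internal()
        s = StateFields.zeros((1, 1))
        s.c[:] = 0.1
        out = react_trbdf2(s, p, dt=1.0)
        rho = p.rho
        exact = 0.1 / (0.1 + 0.9 * np.exp(-rho * 1.0))
        assert out.c[0, 0] == pytest.approx(exact, rel=1e-3)

    def test_edema_relaxation_closed_form(self, default_params):
        """Voxel with constant factor level: l(t) = l*(1-e^{-(Kt+dl)t}),
        l* = Kt*l_v/(Kt+dl).  The fluid update is exact at fixed a."""
        p = default_params.replace(delta_c=0.0, delta_h=1e-12, lambda_=0.0,
                                   omega=0.0, mu=0.0).to_internal()
        a0 = p.K_half  # K_trans = 18/day
        kt = 18.0
        s = StateFields.zeros((1, 1))
        s.a[:] = a0
        lstar = kt * p.l_v / (kt + p.delta_l)
        state = s
        for k in range(1, 4):
            state = react_trbdf2(state, p, dt=0.25)
            exact = lstar * (1.0 - np.exp(-(kt + p.delta_l) * 0.25 * k))
            assert state.l[0, 0] == pytest.approx(exact, rel=1e-3)

    def test_matches_adaptive_reference_on_random_states(self, rng,
                                                         default_params):
        """20 random voxel states integrated for 2 days agree with a
        high-accuracy adaptive reference integrator to 1e-4 relative."""
        p = default_params.to_internal()
        states = random_state(rng, shape=(20, 1))
        t_end, dt = 2.0, 0.02

        def rhs(t, y):
            from edemasim.kinetics import _rates_arrays
            arr = y.reshape(6, 20)
            return np.stack(_rates_arrays(*arr, p)).ravel()

        y0 = np.stack([getattr(states, k).ravel() for k in SPECIES])
        ref = solve_ivp(rhs, (0, t_end), y0.ravel(), method="Radau",
                        rtol=1e-10, atol=1e-14).y[:, -1].reshape(6, 20)

        state = states
        for _ in range(int(t_end / dt)):
            state = react_trbdf2(state, p, dt=dt)
        got = np.stack([getattr(state, k).ravel() for k in SPECIES])
        scale = np.maximum(np.abs(ref), [[1e-3]] * 4 + [[p.K_half]] + [[1e-3]])
        assert np.max(np.abs(got - ref) / scale) < 1e-4

    def test_substep_count_tracks_fastest_rate(self, default_params):
        p = default_params.to_internal()
        assert reaction_substeps(p, 1.0) == 1
        treated = es.modified_parameters(default_params,
                                         es.TreatmentProtocol()).to_internal()
        assert reaction_substeps(treated, 1.0) > 1

    def test_large_negative_input_rejected(self, default_params):
        s = StateFields.zeros((2, 2))
        s.c[0, 0] = -1e-3
        with pytest.raises(Exception):
            react_trbdf2(s, default_params.to_internal(), dt=1.0)


class TestAdvanceAndSimulate:
    def test_necrotic_cells_do_not_move(self, default_params):
        t = strip_map(20, 3)
        p = default_params.replace(rho=0.0, gamma=0.0, beta=0.0, alpha_h=0.0,
                                   alpha_n=0.0, mu=0.0, delta_c=0.0,
                                   delta_h=1e-12)
        s = StateFields.zeros((20, 3))
        s.n[10, 1] = 0.5
        out = SplitStepper(t, p).advance(s)
        assert np.array_equal(out.n, s.n)

    def test_zero_diffusion_reduces_to_reactions(self, default_params):
        labels = np.full((4, 4), es.WHITE, dtype=np.int8)
        t = es.TissueMap(labels)
        p = default_params.replace(D_w=1e-12, D_g=1e-13, D_v=0.0, D_a=0.0,
                                   D_l=0.0)
        s = StateFields.zeros((4, 4))
        s.c[:] = 0.2; s.h[:] = 0.1; s.v[:] = 0.03; s.a[:] = p.K_half
        stepped = SplitStepper(t, p).advance(s.copy())
        reacted = react_trbdf2(s, p.to_internal(), dt=1.0)
        for k in SPECIES:
            assert np.allclose(getattr(stepped, k), getattr(reacted, k),
                               rtol=1e-7, atol=1e-12)

    def test_advance_composes_reaction_then_diffusion(self, default_params):
        t = strip_map(12, 4)
        s = StateFields.zeros((12, 4))
        s.c[5, 1] = 0.4; s.v[t.mask] = 0.03; s.a[6, 2] = 1e-6; s.l[5, 2] = 0.2
        stepper = SplitStepper(t, default_params)
        got = stepper.advance(s.copy())

        # manual composition with the same operators
        mid = react_trbdf2(s, default_params.to_internal(), dt=1.0,
                           mask=t.mask)
        gate = 1.0 - (mid.c + mid.h + mid.n + mid.v)
        manual = mid.copy()
        manual.c = diffuse_implicit(mid.c, stepper.op_cells, gate, 1.0)
        manual.h = diffuse_implicit(mid.h, stepper.op_cells, gate, 1.0)
        manual.v = diffuse_implicit(mid.v, stepper.op_v, gate, 1.0)
        manual.a = diffuse_implicit(mid.a, stepper.op_a, None, 1.0)
        manual.l = diffuse_implicit(mid.l, stepper.op_l, None, 1.0)
        for k in SPECIES:
            assert np.allclose(getattr(got, k), getattr(manual, k),
                               rtol=1e-9, atol=1e-14)

    def test_simulate_bookkeeping(self, default_params):
        t = strip_map(20, 3)
        s = StateFields.zeros((20, 3))
        s.c[10, 1] = 0.01; s.v[t.mask] = 0.03
        traj = es.simulate(s, t, default_params, horizon=10)
        assert len(traj.records) == 11  # initial + 10 days
        assert traj.records[-1]["day"] == 10.0

    def test_fields_stay_nonnegative_and_bounded(self, default_params):
        """Random small runs keep every field nonnegative and total cell
        occupancy below capacity (up to solver tolerance)."""
        t = strip_map(16, 4)
        s = StateFields.zeros((16, 4))
        s.c[8, 1] = 0.5; s.h[8, 2] = 0.3; s.v[t.mask] = 0.03
        s.a[7, 1] = 2e-6
        state = s
        stepper = SplitStepper(t, default_params)
        for _ in range(30):
            state = stepper.advance(state)
            for k in SPECIES:
                assert getattr(state, k).min() >= -1e-9
            T = state.c + state.h + state.n + state.v
            assert T.max() <= 1.0 + 1e-9

    def test_fisher_front_speed(self, default_params):
        """With hypoxia, necrosis, and angiogenesis disabled, the normoxic
        front on a homogeneous strip travels at the pulled-front speed
        2*sqrt(D*rho) (within 10%, measured over the final third)."""
        # A pulled front converges to its asymptotic speed like
        # v(t) ~ v_inf * (1 - 3/(4*rho*t)), so rho*t must be large over
        # the measurement window.
        D_w, rho = 53.0, 75.0  # mm^2/yr, 1/yr
        p = default_params.replace(rho=rho, D_w=D_w, D_g=D_w / 10,
                                   beta=0.0, alpha_h=0.0, alpha_n=0.0,
                                   mu=0.0, gamma=0.0, delta_c=0.0,
                                   delta_h=1e-12)
        n, days, spacing = 320, 200, 0.5
        t = strip_map(n, 1, spacing=spacing)
        s = StateFields.zeros((n, 1))
        # sub-saturated seed: a fully saturated block has a zero (1-T) gate
        # on every face and cannot spread
        s.c[:12, 0] = 0.5
        stepper = SplitStepper(t, p)
        state = s
        fronts = []
        for day in range(1, days + 1):
            state = stepper.advance(state)
            prof = state.c[:, 0]
            idx = np.flatnonzero(prof >= 0.5)
            fronts.append(idx.max() if idx.size else 0)
        fronts = np.array(fronts, dtype=float) * spacing
        third = days // 3
        speed = np.polyfit(np.arange(days)[-third:], fronts[-third:], 1)[0]
        expected = 2 * np.sqrt((D_w / 365.0) * (rho / 365.0))  # mm/day
        assert speed == pytest.approx(expected, rel=0.10)
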