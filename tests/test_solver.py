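"""Bidomain solver: assembly, splitting step vs dense oracle, conduction."""

import numpy as np
import pytest

from torsoecg import cells
from torsoecg.geometry import (GeometryConfig, Label, LabelField, LesionSpec,
                               apply_infarct, build_tissue)
from torsoecg.solver import (AssemblyError, TissueStimulus, _weighted_laplacian,
                             assemble, conduction_velocity, make_strip_field,
                             reaction_substep_counts, simulate, step)


def heart_block(n=5, label=Label.VENTRICLES, dx=0.002):
    lab = np.full((n, n, n), int(label), dtype=np.int8)
    return LabelField(lab, origin=(0.0, 0.0, 0.0), dx=dx)


class TestAssembly:
    def test_operator_row_sums_vanish(self):
        fld = heart_block(4)
        sys = assemble(fld, dt=5e-5, ground=(0, 0, 0))
        # interior conservation: zero row sums for the sigma_i Laplacian
        # (relative to the coupling weights, which are O(sigma/dx^2))
        wmax = np.abs(sys.Li.diagonal()).max()
        rs = np.asarray(np.abs(sys.Li.sum(axis=1))).ravel()
        assert rs.max() < 1e-12 * wmax
        # pinned elliptic matrix: zero row sums away from the ground.  The
        # ground row is identity and its former face neighbours retain the
        # eliminated coupling in their sums (symmetric-pin bookkeeping).
        rs = np.asarray(sys.A_ell.sum(axis=1)).ravel()
        g = sys.ground_pos
        assert rs[g] == 1.0
        shape = fld.shape
        gnb = {np.ravel_multi_index(ijk, shape)
               for ijk in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]}
        interior = np.ones(sys.n_cond, dtype=bool)
        interior[g] = False
        interior[np.isin(sys.cond_flat, list(gnb))] = False
        assert np.abs(rs[interior]).max() < 1e-12 * np.abs(sys.A_ell.diagonal()).max()

    def test_harmonic_face_coupling(self):
        # two cells with different conductivities: off-diagonal weight is the
        # harmonic mean over dx^2
        mask = np.ones((2, 1, 1), dtype=bool)
        sigma = np.array([0.2, 0.04]).reshape(2, 1, 1)
        dx = 0.004
        L = _weighted_laplacian(mask, sigma, dx).toarray()
        expected = 2 * 0.2 * 0.04 / (0.2 + 0.04) / dx ** 2
        assert L[0, 1] == pytest.approx(expected, rel=1e-12)
        assert L[0, 0] == pytest.approx(-expected, rel=1e-12)

    def test_no_vi_coupling_across_heart_boundary(self):
        lab = np.full((3, 1, 1), int(Label.VENTRICLES), dtype=np.int8)
        lab[2] = Label.TORSO
        fld = LabelField(lab, origin=(0, 0, 0), dx=0.002)
        sys = assemble(fld, dt=5e-5, ground=(2, 0, 0))
        # Li covers the two heart nodes only, coupled to each other alone
        assert sys.Li.shape == (2, 2)
        assert sys.Li[0, 1] != 0

    def test_disconnected_domain_rejected(self):
        lab = np.zeros((5, 1, 1), dtype=np.int8)
        lab[0] = lab[4] = Label.TORSO  # two islands
        fld = LabelField(lab, origin=(0, 0, 0), dx=0.002)
        with pytest.raises(AssemblyError, match="disconnected"):
            assemble(fld, dt=5e-5, ground=(0, 0, 0))

    def test_ground_must_conduct(self):
        fld = heart_block(3)
        lab = fld.labels.copy()
        lab[0, 0, 0] = Label.OUTSIDE
        with pytest.raises(AssemblyError):
            assemble(LabelField(lab, fld.origin, fld.dx), dt=5e-5, ground=(0, 0, 0))


class TestStep:
    def test_rest_is_global_fixed_point(self):
        sys = assemble(heart_block(5), dt=1e-4, ground=(0, 0, 0))
        st = sys.initial_state()
        for _ in range(2000):  # 0.2 s
            st = step(sys, st)
        # drift < 10 uV per simulated second
        assert np.abs(st.Vm + 0.085).max() < 2e-6
        assert np.abs(st.phi).max() < 1e-9

    def test_ground_node_pinned_exactly(self):
        sys = assemble(heart_block(4), dt=1e-4, ground=(1, 1, 1))
        st = sys.initial_state()
        st.Vi[5] = -0.020  # excite one voxel
        for _ in range(20):
            st = step(sys, st)
            assert st.phi[sys.ground_pos] == 0.0

    def test_dt_mismatch_rejected(self):
        sys = assemble(heart_block(3), dt=1e-4, ground=(0, 0, 0))
        with pytest.raises(ValueError, match="assembled for dt"):
            step(sys, sys.initial_state(), dt=5e-5)

    def test_neighbour_spread_after_one_step(self):
        n = 5
        sys = assemble(heart_block(n, dx=0.004), dt=1e-4, ground=(0, 0, 0))
        st = sys.initial_state()
        center = np.ravel_multi_index((2, 2, 2), (n, n, n))
        cpos = int(np.flatnonzero(sys.heart_flat == center)[0])
        st.Vi[cpos] = 0.040  # strongly excited voxel
        new = step(sys, st)
        dvm = new.Vm - st.Vm

        def pos(ijk):
            return int(np.flatnonzero(
                sys.heart_flat == np.ravel_multi_index(ijk, (n, n, n)))[0])

        # locality of the intracellular diffusion operator: the quasi-static
        # extracellular field couples globally, so the check is on Vi
        dvi = new.Vi - st.Vi
        face = pos((3, 2, 2))
        corner = pos((3, 3, 3))
        assert dvm[face] > 0
        assert dvi[face] > 0
        # implicit diffusion reaches the 3D corner only at third order in
        # dt*w (w = sigma/dx^2), two orders below the face neighbour
        w = np.abs(sys.Li.data).max()
        assert abs(dvi[corner]) < 2 * (sys.dt * w) ** 2 * dvi[face]


def _dense_oracle_step(sys, state):
    """Brute-force dense reimplementation of one operator-splitting step."""
    fld = sys.field
    lab = fld.labels
    dx = fld.dx
    dt = sys.dt
    nh, nc = sys.n_heart, sys.n_cond
    hmask = fld.heart_mask().ravel()
    cmask = fld.conducting_mask().ravel()
    shape = lab.shape

    # per-voxel sigma values from the per-node vectors
    from torsoecg.geometry import LABEL_TO_REGION
    from torsoecg.cells import all_region_defaults

    params = all_region_defaults()
    sigma_i = np.zeros(lab.size)
    sigma_ec = np.zeros(lab.size)
    from torsoecg.geometry import DEFAULT_PASSIVE

    for flat in np.flatnonzero(cmask):
        l = Label(lab.ravel()[flat])
        if l in LABEL_TO_REGION:
            p = params[LABEL_TO_REGION[l]]
            sigma_i[flat] = p.sigma_i
            sigma_ec[flat] = p.sigma_e
        else:
            sigma_ec[flat] = DEFAULT_PASSIVE[l.name.lower()]

    def dense_lap(flats, sigma):
        idx = {f: i for i, f in enumerate(flats)}
        L = np.zeros((len(flats), len(flats)))
        for f in flats:
            ijk = np.unravel_index(f, shape)
            for axis in range(3):
                for s in (1, -1):
                    nb = list(ijk)
                    nb[axis] += s
                    if not (0 <= nb[axis] < shape[axis]):
                        continue
                    fn = np.ravel_multi_index(nb, shape)
                    if fn not in idx:
                        continue
                    s1, s2 = sigma[f], sigma[fn]
                    if s1 + s2 == 0:
                        continue
                    w = 2 * s1 * s2 / (s1 + s2) / dx ** 2
                    L[idx[f], idx[fn]] += w
                    L[idx[f], idx[f]] -= w
        return L

    Li = dense_lap(list(sys.heart_flat), sigma_i)
    Le = dense_lap(list(sys.cond_flat), sigma_ec)

    # reaction: scalar loop mirroring the documented sub-cycling rule
    Vm = state.Vm.copy()
    u = state.u.copy()
    counts = reaction_substep_counts(sys, Vm, u, dt)
    for i in range(nh):
        if sys.k[i] == 0:
            continue
        a, b = sys.a[i], sys.b[i]
        c1, c2, d, e, k = sys.c1[i], sys.c2[i], sys.d[i], sys.e[i], sys.k[i]
        A, B = sys.A[i], sys.B[i]
        pm = bool(sys.pacemaker[i])
        h = dt / counts[i]
        x, y = Vm[i], u[i]
        for _ in range(int(counts[i])):
            def f(x_, y_):
                v = (x_ - B) / A
                rec = c2 * y_ if pm else c2 * y_ * (x_ - B)
                fv = -(k * c1 * (x_ - B) * (a - v) * (1 - v) + k * rec)
                fu = k * e * (v - d * y_ - b)
                return fv, fu
            f1v, f1u = f(x, y)
            f2v, f2u = f(x + h * f1v, y + h * f1u)
            x += 0.5 * h * (f1v + f2v)
            y += 0.5 * h * (f1u + f2u)
        Vm[i], u[i] = x, y

    Vi = np.linalg.solve(np.eye(nh) - dt * Li, Vm + state.Ve)
    A_ell = -Le
    g = sys.ground_pos
    A_ell[g, :] = 0.0
    A_ell[:, g] = 0.0
    A_ell[g, g] = 1.0
    rhs = np.zeros(nc)
    rhs[sys.heart_in_cond] = Li @ Vi
    rhs[g] = 0.0
    phi = np.linalg.solve(A_ell, rhs)
    phi[g] = 0.0
    return Vi, u, phi


class TestDenseOracle:
    @pytest.mark.parametrize("labels", ["heart-only", "heart-in-torso"])
    def test_one_step_matches_brute_force(self, labels):
        if labels == "heart-only":
            lab = np.full((4, 4, 4), int(Label.VENTRICLES), dtype=np.int8)
            lab[0, :2, :2] = Label.SAN
            lab[3, 2:, 2:] = Label.PURKINJE
        else:
            lab = np.full((5, 5, 5), int(Label.TORSO), dtype=np.int8)
            lab[1:4, 1:4, 1:4] = Label.VENTRICLES
            lab[2, 2, 2] = Label.BLOOD
        fld = LabelField(lab, origin=(0, 0, 0), dx=0.002)
        sys = assemble(fld, dt=1e-4, ground=(0, 0, 0))
        st = sys.initial_state()
        rng = np.random.default_rng(7)
        st.Vi[:] += rng.uniform(0, 0.05, sys.n_heart)  # scattered excitation
        st.u[:] = rng.uniform(0, 0.2, sys.n_heart)

        new = step(sys, st)
        Vi_ref, u_ref, phi_ref = _dense_oracle_step(sys, st)
        scale_v = max(np.abs(Vi_ref).max(), 1e-3)
        assert np.abs(new.Vi - Vi_ref).max() / scale_v < 1e-8
        assert np.abs(new.u - u_ref).max() / max(np.abs(u_ref).max(), 1e-6) < 1e-8
        assert np.abs(new.phi - phi_ref).max() / max(np.abs(phi_ref).max(), 1e-9) < 1e-6


class TestConservationAndReproducibility:
    def test_elliptic_flux_balance(self):
        sys = assemble(heart_block(4), dt=1e-4, ground=(0, 0, 0))
        st = sys.initial_state()
        st.Vi[10] = -0.020
        for _ in range(50):
            st = step(sys, st)
        rhs = np.zeros(sys.n_cond)
        rhs[sys.heart_in_cond] = sys.Li @ st.Vi
        rhs[sys.ground_pos] = 0.0
        resid = sys.A_ell @ st.phi - rhs
        scale = max(np.abs(rhs).max(), 1e-12)
        assert np.abs(resid).max() < 1e-9 * max(scale, 1.0)
        # the discrete source is conservative: its net current vanishes to
        # rounding (the operator has exactly zero column sums)
        src = sys.Li @ st.Vi
        assert abs(src.sum()) < 1e-12 * np.abs(sys.Li.data).max() * np.abs(st.Vi).max()

    def test_identical_runs_bitwise(self):
        fld = heart_block(4)
        stim = TissueStimulus(center=(0.002, 0.002, 0.002), radius=0.003,
                              t_start=0.001, duration=0.001, amplitude=50.0)
        outs = []
        for _ in range(2):
            sys = assemble(fld, dt=1e-4, ground=(0, 0, 0), stimulus=stim)
            res = simulate(sys, 0.05, electrodes={"P": 0})
            outs.append(res.electrode_traces["P"].to_numpy())
        assert np.array_equal(outs[0], outs[1])

    def test_global_infarct_never_activates(self):
        fld = heart_block(4)
        tissue = build_tissue(fld)
        lesion = LesionSpec("global", center=(0.004, 0.004, 0.004),
                            radii=(1.0, 1.0, 1.0))
        tissue = apply_infarct(fld, tissue, lesion)
        stim = TissueStimulus(center=(0.002, 0.002, 0.002), radius=0.004,
                              t_start=0.001, duration=0.002, amplitude=100.0)
        sys = assemble(fld, tissue, dt=1e-4, ground=(0, 0, 0), stimulus=stim)
        res = simulate(sys, 0.05)
        assert np.all(np.isnan(res.activation_nodes))


class TestConductionVelocity:
    def test_monotone_in_conductivity(self):
        v1 = conduction_velocity(n=60, duration=0.05)
        v2 = conduction_velocity(n=60, duration=0.05, sigma_scale=2.0)
        assert v2 > v1 > 0

    def test_no_intracellular_coupling_no_wave(self):
        assert conduction_velocity(n=40, duration=0.04, sigma_i_scale=0.0) == 0.0

    def test_grid_self_convergence(self):
        v1 = conduction_velocity(n=80, dx=5e-4, duration=0.06)
        v2 = conduction_velocity(n=160, dx=2.5e-4, duration=0.06)
        assert v1 > 0 and v2 > 0
        assert abs(v2 - v1) / v1 < 0.10

    def test_strip_field_single_region(self):
        fld = make_strip_field(20, "Purkinje")
        counts = fld.counts()
        assert counts == {"PURKINJE": 20}
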