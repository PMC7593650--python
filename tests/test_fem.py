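"""Solver verification: elements, constraints, contact, invariants."""

import numpy as np
import pytest
import scipy.sparse as sp

from kneefem.image import LabelMask
from kneefem.meshing import (boundary_and_interfaces, concatenate,
                             voxels_to_tets, _face_normals)
from kneefem.fem import (Constraints, ContactPair, Coupling, LoadProtocol,
                         Material, TiedInterface, apply_coupling, apply_tie,
                         assemble_stiffness, element_operators,
                         element_stresses, reaction_history, solve_linear,
                         solve_contact_steps, von_mises)


def _block(shape=(3, 3, 3), spacing=100.0, tissue="femur_bone", z0_mm=0.0):
    vals = np.ones(shape, bool)
    return voxels_to_tets([LabelMask(vals, spacing, (0, 0, z0_mm), tissue)])


def _stacked_pair(nz=3, spacing=200.0):
    """Two separate 3x3xnz blocks stacked with coincident interface nodes."""
    lower = _block((3, 3, nz), spacing, "tibia_bone")
    upper = _block((3, 3, nz), spacing, "femur_bone",
                   z0_mm=nz * spacing * 1e-3)
    mesh = concatenate(lower, upper)
    z = mesh.nodes[:, 2]
    low = np.unique(mesh.elements[mesh.element_region == 0])
    up = np.unique(mesh.elements[mesh.element_region == 1])
    mesh.node_sets["tibia_distal_fixed"] = low[z[low] <= z[low].min() + 1e-9]
    mesh.node_sets["femur_top_coupled"] = up[z[up] >= z[up].max() - 1e-9]
    bf, br, _, _ = boundary_and_interfaces(mesh)
    nrm = _face_normals(mesh, bf)
    mesh.facet_sets["lower_top"] = bf[(br == 0) & (nrm[:, 2] > 0.9)]
    mesh.facet_sets["upper_bot"] = bf[(br == 1) & (nrm[:, 2] < -0.9)]
    mesh.node_sets["upper_bot_nodes"] = np.unique(mesh.facet_sets["upper_bot"])
    return mesh


def _monolithic(nz=6, spacing=200.0):
    mesh = _block((3, 3, nz), spacing, "tibia_bone")
    z = mesh.nodes[:, 2]
    mesh.node_sets["tibia_distal_fixed"] = np.nonzero(z <= z.min() + 1e-9)[0]
    mesh.node_sets["femur_top_coupled"] = np.nonzero(z >= z.max() - 1e-9)[0]
    return mesh


MATS = {"femur_bone": Material(10.0, 0.3), "tibia_bone": Material(10.0, 0.3)}
SOFT = {"femur_bone": Material(10.0, 1e-4), "tibia_bone": Material(10.0, 1e-4)}


class TestElementStiffness:
    def test_reference_tet_matches_symbolic_quadrature(self):
        """A single-tet stiffness equals the symbolically integrated
        B^T D B over the element (sympy, exact arithmetic)."""
        import sympy as spy

        nodes = np.array([[0.0, 0, 0], [1.2, 0.1, 0], [0.2, 1.0, 0.1],
                          [0.1, 0.2, 0.9]])
        from kneefem.meshing import TetMesh

        mesh = TetMesh(nodes=nodes, elements=np.array([[0, 1, 2, 3]]),
                       element_region=np.zeros(1, np.int16),
                       region_names=["femur_bone"])
        mat = Material(1.0, 0.25)
        K = assemble_stiffness(mesh, {"femur_bone": mat}).toarray()

        x, y, z = spy.symbols("x y z")
        A = spy.Matrix([[1, *nodes[i]] for i in range(4)])
        C = A.inv()
        N = [C[0, i] + C[1, i] * x + C[2, i] * y + C[3, i] * z
             for i in range(4)]
        B = spy.zeros(6, 12)
        for a in range(4):
            gx, gy, gz = (spy.diff(N[a], v) for v in (x, y, z))
            B[0, 3 * a] = gx
            B[1, 3 * a + 1] = gy
            B[2, 3 * a + 2] = gz
            B[3, 3 * a] = gy
            B[3, 3 * a + 1] = gx
            B[4, 3 * a + 1] = gz
            B[4, 3 * a + 2] = gy
            B[5, 3 * a] = gz
            B[5, 3 * a + 2] = gx
        D = spy.Matrix(mat.d_matrix())
        vol = abs(A.det()) / 6
        Ke = (B.T * D * B * vol)
        np.testing.assert_allclose(K, np.array(Ke, dtype=float), atol=1e-12)

    def test_six_rigid_modes_on_free_cube(self):
        mesh = _block((3, 3, 3))
        K = assemble_stiffness(mesh, MATS).toarray()
        w = np.linalg.eigvalsh(K)
        assert w[5] / w[6] < 1e-8
        assert w[6] > 0

    def test_stiffness_linear_in_modulus(self):
        mesh = _block((2, 2, 2))
        K1 = assemble_stiffness(mesh, {"femur_bone": Material(6.0, 0.3)})
        K2 = assemble_stiffness(mesh, {"femur_bone": Material(12.0, 0.3)})
        np.testing.assert_allclose(K2.toarray(), 2 * K1.toarray(), rtol=1e-12)

    def test_missing_material_rejected(self):
        with pytest.raises(ValueError):
            assemble_stiffness(_block(), {})


class TestPatchAndEnergy:
    def test_patch_test_affine_field(self):
        """Constant-strain tets reproduce an affine displacement field
        exactly when it is prescribed on the boundary."""
        mesh = _block((4, 4, 4))
        A = np.array([[0.01, 0.002, 0.003],
                      [0.001, -0.005, 0.002],
                      [0.004, 0.001, 0.008]])
        b = np.array([0.001, -0.002, 0.0005])
        uex = mesh.nodes @ A.T + b
        xyz = mesh.nodes
        lo, hi = xyz.min(0), xyz.max(0)
        on_boundary = np.any((xyz <= lo + 1e-12) | (xyz >= hi - 1e-12), axis=1)
        con = Constraints(3 * mesh.n_nodes)
        for nid in np.nonzero(on_boundary)[0]:
            for c in range(3):
                con.fix_dof(3 * nid + c, uex[nid, c])
        u = solve_linear(mesh, MATS, con).reshape(-1, 3)
        assert np.abs(u - uex).max() / np.abs(uex).max() < 1e-10
        # stresses are spatially constant
        s = element_stresses(mesh, MATS, u.ravel())
        assert np.abs(s - s[0]).max() < 1e-10 * np.abs(s[0]).max()

    def test_energy_balance_without_contact(self):
        mesh = _monolithic()
        proto = LoadProtocol(gap_translation_um=0,
                             initialization_displacement_um=0,
                             loading_displacement_um=50.0, n_steps=1)
        sol = solve_contact_steps(mesh, {"tibia_bone": MATS["tibia_bone"]},
                                  proto, [])
        u = sol.steps[-1].displacement.ravel()
        K = assemble_stiffness(mesh, {"tibia_bone": MATS["tibia_bone"]})
        strain_energy = 0.5 * u @ (K @ u)
        # reactions ramp linearly: external work = 1/2 sum r.u
        r = K @ u
        work = 0.5 * float(r @ u)
        assert abs(work - strain_energy) <= 1e-8 * strain_energy


class TestCouplingAndTies:
    def test_coupling_equals_direct_dirichlet(self):
        mesh = _monolithic()
        mats = {"tibia_bone": MATS["tibia_bone"]}
        proto = LoadProtocol(gap_translation_um=0,
                             initialization_displacement_um=0,
                             loading_displacement_um=40.0, n_steps=1)
        sol = solve_contact_steps(mesh, mats, proto, [])
        top = mesh.node_sets["femur_top_coupled"]
        con = Constraints(3 * mesh.n_nodes)
        con.fix_nodes(mesh.node_sets["tibia_distal_fixed"])
        con.fix_nodes(top, (0.0, 0.0, -0.04))
        u_direct = solve_linear(mesh, mats, con)
        np.testing.assert_allclose(sol.steps[-1].displacement.ravel(),
                                   u_direct, atol=1e-9)

    def test_zero_displacement_zero_reaction(self):
        mesh = _monolithic()
        proto = LoadProtocol(gap_translation_um=0,
                             initialization_displacement_um=0,
                             loading_displacement_um=0.0, n_steps=1)
        sol = solve_contact_steps(mesh, {"tibia_bone": MATS["tibia_bone"]},
                                  proto, [])
        assert abs(sol.steps[-1].axial_reaction_n) < 1e-12

    def test_reaction_balances_fixed_base(self):
        mesh = _monolithic()
        mats = {"tibia_bone": MATS["tibia_bone"]}
        proto = LoadProtocol(gap_translation_um=0,
                             initialization_displacement_um=0,
                             loading_displacement_um=40.0, n_steps=1)
        sol = solve_contact_steps(mesh, mats, proto, [])
        u = sol.steps[-1].displacement.ravel()
        K = assemble_stiffness(mesh, mats)
        r = (K @ u).reshape(-1, 3)
        base = r[mesh.node_sets["tibia_distal_fixed"]].sum(axis=0)
        top = r[mesh.node_sets["femur_top_coupled"]].sum(axis=0)
        np.testing.assert_allclose(base[2], -top[2], rtol=1e-9)

    def test_conflicting_constraints_rejected(self):
        con = Constraints(12)
        con.fix_dof(3, 0.1)
        with pytest.raises(ValueError):
            con.add_mpc(3, [0], [1.0])
        con.add_mpc(4, [0], [1.0])
        con.add_mpc(5, [4], [1.0])  # chained constraint
        with pytest.raises(ValueError, match="chain"):
            con.build()

    def test_tie_matches_monolithic(self):
        """Two stacked blocks bonded by the tie reproduce the monolithic
        column within 1% (here: machine precision, coincident nodes)."""
        mats = {"femur_bone": MATS["femur_bone"],
                "tibia_bone": MATS["tibia_bone"]}
        proto = LoadProtocol(gap_translation_um=0,
                             initialization_displacement_um=0,
                             loading_displacement_um=40.0, n_steps=1)
        tied = _stacked_pair()
        tie = TiedInterface(slave_nodes="upper_bot_nodes",
                            master_facets="lower_top")
        sol_t = solve_contact_steps(tied, mats, proto, [], ties=[tie])
        mono = _monolithic()
        sol_m = solve_contact_steps(mono, {"tibia_bone": MATS["tibia_bone"]},
                                    proto, [])
        # compare via reactions and matched node displacements
        assert abs(sol_t.steps[-1].axial_reaction_n
                   - sol_m.steps[-1].axial_reaction_n) \
            <= 0.01 * sol_m.steps[-1].axial_reaction_n
        norm = np.linalg.norm
        d_t, d_m = sol_t.steps[-1].displacement, sol_m.steps[-1].displacement
        # map tied-mesh nodes onto monolithic nodes by coordinates
        from scipy.spatial import cKDTree
        idx = cKDTree(mono.nodes).query(tied.nodes)[1]
        assert norm(d_t - d_m[idx]) / norm(d_m) < 0.01

    def test_tie_forces_sum_to_zero(self):
        mats = {"femur_bone": MATS["femur_bone"],
                "tibia_bone": MATS["tibia_bone"]}
        proto = LoadProtocol(gap_translation_um=0,
                             initialization_displacement_um=0,
                             loading_displacement_um=40.0, n_steps=1)
        tied = _stacked_pair()
        tie = TiedInterface(slave_nodes="upper_bot_nodes",
                            master_facets="lower_top")
        sol = solve_contact_steps(tied, mats, proto, [], ties=[tie])
        u = sol.steps[-1].displacement.ravel()
        K = assemble_stiffness(tied, mats)
        r = (K @ u).reshape(-1, 3)
        # total internal force over all nodes vanishes (Newton's third law
        # for the tie constraint forces included)
        np.testing.assert_allclose(r.sum(axis=0), 0.0, atol=1e-9)

    def test_tie_beyond_tolerance_errors(self):
        tied = _stacked_pair()
        tied.nodes = tied.nodes.copy()
        # pull the upper block up so the tie gap opens
        up = np.unique(tied.elements[tied.element_region == 1])
        tied.nodes[up, 2] += 0.05
        tie = TiedInterface(slave_nodes="upper_bot_nodes",
                            master_facets="lower_top",
                            gap_tolerance_mm=1e-3)
        con = Constraints(3 * tied.n_nodes)
        with pytest.raises(ValueError, match="gap tolerance"):
            apply_tie(tied, tie, con)


class TestVonMises:
    def test_closed_forms(self):
        hydro = np.array([-3.0, -3.0, -3.0, 0, 0, 0])
        uni = np.array([0, 0, 5.0, 0, 0, 0])
        shear = np.array([0, 0, 0, 2.0, 0, 0])
        assert von_mises(hydro) == pytest.approx(0.0, abs=1e-12)
        assert von_mises(uni) == pytest.approx(5.0)
        assert von_mises(shear) == pytest.approx(2.0 * np.sqrt(3))


class TestContact:
    def _proto(self, disp_um=40.0, n=1):
        return LoadProtocol(gap_translation_um=0,
                            initialization_displacement_um=0,
                            loading_displacement_um=disp_um, n_steps=n)

    def test_open_gap_zero_everything(self):
        mesh = _stacked_pair()
        up = np.unique(mesh.elements[mesh.element_region == 1])
        mesh.nodes = mesh.nodes.copy()
        mesh.nodes[up, 2] += 0.1   # 100 um gap, 40 um travel
        pair = ContactPair(master="lower_top", slave="upper_bot")
        sol = solve_contact_steps(mesh, MATS, self._proto(40.0), [pair])
        last = sol.steps[-1]
        assert last.axial_reaction_n == pytest.approx(0.0, abs=1e-10)
        c = list(last.contact.values())[0]
        assert (c["pressure"] == 0).all()

    def test_flat_contact_approaches_tied_with_growing_penalty(self):
        """Matched-mesh flat-on-flat compression tends to the monolithic
        solution as the penalty stiffness grows (nu ~ 0 so frictionless
        slip is immaterial)."""
        proto = self._proto(40.0)
        mesh = _stacked_pair()
        tie = TiedInterface(slave_nodes="upper_bot_nodes",
                            master_facets="lower_top")
        ref = solve_contact_steps(_stacked_pair(), SOFT, proto, [],
                                  ties=[tie]).steps[-1]
        errs = []
        for scale in (1.0, 10.0):
            kp = 50.0 * 10.0 / 0.2 * scale
            pair = ContactPair(master="lower_top", slave="upper_bot",
                               penalty_stiffness=kp)
            sol = solve_contact_steps(_stacked_pair(), SOFT, proto, [pair])
            d = sol.steps[-1].displacement - ref.displacement
            errs.append(np.linalg.norm(d) / np.linalg.norm(ref.displacement))
        assert errs[0] < 0.01
        assert errs[1] < errs[0] / 3.0

    def test_contact_force_balances_reaction(self):
        mesh = _stacked_pair()
        pair = ContactPair(master="lower_top", slave="upper_bot")
        sol = solve_contact_steps(mesh, MATS, self._proto(40.0, n=2), [pair])
        for step in sol.loading_steps():
            c = list(step.contact.values())[0]
            axial = abs(c["force"][:, 2].sum())
            assert axial == pytest.approx(step.axial_reaction_n,
                                          rel=0.01)

    def test_pressures_nonnegative_and_penetration_bounded(self):
        mesh = _stacked_pair()
        pair = ContactPair(master="lower_top", slave="upper_bot")
        sol = solve_contact_steps(mesh, MATS, self._proto(40.0), [pair])
        last = sol.steps[-1]
        c = list(last.contact.values())[0]
        assert (c["pressure"] >= 0).all()
        kp = 50.0 * 10.0 / np.mean(
            [0.2, 0.2 * np.sqrt(2), 0.2 * np.sqrt(3)])
        # penetration is the penalty-consistent pressure / stiffness scale
        assert last.max_penetration_mm < 5e-3

    def test_reaction_linear_in_displacement_and_modulus(self):
        mesh = _monolithic()
        mats = {"tibia_bone": MATS["tibia_bone"]}
        proto = self._proto(40.0, n=2)
        sol = solve_contact_steps(mesh, mats, proto, [])
        hist = reaction_history(sol)
        assert hist[1][1] == pytest.approx(2 * hist[0][1], rel=1e-9)
        mats2 = {"tibia_bone": Material(20.0, 0.3)}
        sol2 = solve_contact_steps(mesh, mats2, proto, [])
        assert sol2.steps[-1].axial_reaction_n == pytest.approx(
            2 * sol.steps[-1].axial_reaction_n, rel=1e-9)

    def test_frame_invariance_90deg(self):
        """Rotating the whole problem by 90 degrees about x rotates the
        solution accordingly (axial direction becomes +y)."""
        mesh = _stacked_pair()
        pair = ContactPair(master="lower_top", slave="upper_bot")
        sol = solve_contact_steps(mesh, MATS, self._proto(30.0), [pair])
        R = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        rot = _stacked_pair()
        rot.nodes = mesh.nodes @ R.T
        proto_r = LoadProtocol(gap_translation_um=0,
                               initialization_displacement_um=0,
                               loading_displacement_um=30.0, n_steps=1,
                               direction=tuple(R @ (0, 0, -1.0)))
        sol_r = solve_contact_steps(rot, MATS, proto_r, [pair])
        u = sol.steps[-1].displacement
        u_r = sol_r.steps[-1].displacement
        # agreement to well below the contact force tolerance
        np.testing.assert_allclose(u_r, u @ R.T, atol=1e-7)
        assert sol_r.steps[-1].axial_reaction_n == pytest.approx(
            sol.steps[-1].axial_reaction_n, rel=1e-6)
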