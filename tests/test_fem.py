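import numpy as np
import pytest

from scoliofe import defaults, fem, materials, metrics, template
from scoliofe.fem import (LoadCase, apply_gravity_two_pass, gravity_forces,
                          ivd_quadrant_stress, quadrant_stresses,
                          reaction_forces, resolve_tension_only, solve_static)
from scoliofe.template import Spring

from conftest import make_box_model


@pytest.fixture(scope="module")
def loaded_template(straight_template):
    m = straight_template.copy()
    materials.assign_materials(m, materials.default_cards(age=12), None)
    return m


class TestPatchTests:
    def test_uniform_pressure(self):
        m = make_box_model()
        m.fixed[:4, 2] = True
        m.fixed[0, :] = True
        m.fixed[1, 1] = True
        f = np.zeros((8, 3))
        f[4:, 2] = -0.5 / 4   # 0.5 MPa over unit top face
        st = solve_static(m, LoadCase(forces=f))
        np.testing.assert_allclose(st.sigma[:, 2], -0.5, rtol=1e-8)
        np.testing.assert_allclose(st.sigma[:, [0, 1, 3, 4, 5]], 0.0,
                                   atol=1e-8)

    def test_stress_free_eigenstrain_growth(self):
        m = make_box_model()
        # 3-2-1 minimal constraints
        m.fixed[0, :] = True
        m.fixed[1, 1] = m.fixed[1, 2] = True
        m.fixed[3, 2] = True
        eps = np.zeros((1, 6))
        eps[0, 2] = 0.01
        st = solve_static(m, LoadCase(eigenstrain=eps))
        assert np.abs(st.sigma).max() < 1e-8
        new = m.nodes + st.displacements
        height = new[4:, 2].mean() - new[:4, 2].mean()
        assert height == pytest.approx(1.01, rel=1e-10)

    def test_global_equilibrium(self):
        m = make_box_model(2, 2, 4, size=(2, 2, 4))
        m.fixed[m.grid_ids[0].ravel(), :] = True
        rng = np.random.default_rng(0)
        f = rng.normal(0, 1, (m.n_nodes, 3))
        f[m.grid_ids[0].ravel()] = 0.0
        case = LoadCase(forces=f)
        st = solve_static(m, case)
        r = reaction_forces(m, st.displacements, case)
        # sum of reactions balances the applied loads
        fixed_r = r[m.grid_ids[0].ravel()].sum(axis=0)
        scale = np.abs(f).sum()
        np.testing.assert_allclose(fixed_r, -f.sum(axis=0),
                                   atol=1e-8 * scale)
        np.testing.assert_allclose(r.sum(axis=0), -f.sum(axis=0),
                                   atol=1e-8 * scale)

    def test_rigid_rotation_null_space_distorted_element(self):
        # regression guard: gradients must use the transposed Jacobian
        # inverse or distorted elements resist rigid rotation
        rng = np.random.default_rng(11)
        cube = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                         [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                        dtype=float)
        nodes = cube + rng.uniform(-0.15, 0.15, (8, 3))
        Ke = fem.hex_stiffness(nodes, np.array([[0, 1, 2, 3, 4, 5, 6, 7]]),
                               np.array([100.0]), np.array([0.3]))[0]
        for omega in np.eye(3):
            u = np.cross(omega, nodes - nodes.mean(axis=0))
            assert np.abs(Ke @ u.ravel()).max() < 1e-9 * np.abs(Ke).max()

    def test_cantilever_beam_oracle(self):
        # 2x2x20 elements, L=10 b=1; coarse-mesh tolerance 20 %
        L, b_w, E, P = 10.0, 1.0, 1000.0, 1.0
        m = make_box_model(2, 2, 20, size=(b_w, b_w, L), E=E)
        m.fixed[m.grid_ids[0].ravel(), :] = True
        top = m.grid_ids[-1].ravel()
        f = np.zeros((m.n_nodes, 3))
        f[top, 0] = P / len(top)
        st = solve_static(m, LoadCase(forces=f))
        tip = st.displacements[top, 0].mean()
        euler = P * L ** 3 / (3 * E * (b_w ** 4 / 12))
        assert tip == pytest.approx(euler, rel=0.20)

    def test_eigenstrain_bound_enforced(self):
        m = make_box_model()
        eps = np.zeros((1, 6))
        eps[0, 2] = 0.3
        with pytest.raises(ValueError, match="small-strain"):
            LoadCase(eigenstrain=eps).validate(m)


class TestTensionOnly:
    def _guyed_column(self):
        """Column with two antagonist lateral tie-down springs."""
        m = make_box_model(1, 1, 4, size=(1, 1, 4))
        m.fixed[m.grid_ids[0].ravel(), :] = True
        n = m.n_nodes
        anchors = np.array([[0.5, -3.0, 0.0], [0.5, 4.0, 0.0]])
        m.nodes = np.vstack([m.nodes, anchors])
        m.fixed = np.vstack([m.fixed, np.ones((2, 3), dtype=bool)])
        top = int(m.grid_ids[-1, 0, 0])
        m.springs = [Spring(top, n, 5.0, True, "ligament"),
                     Spring(top, n + 1, 5.0, True, "ligament")]
        return m, top

    def test_antagonist_springs(self):
        m, top = self._guyed_column()
        f = np.zeros((m.n_nodes, 3))
        f[top, 1] = 1.0   # push toward +y: the -y spring stretches
        u, active = resolve_tension_only(m, LoadCase(forces=f))
        tension_active = [i for i in active if m.springs[i].tension_only]
        assert tension_active == [0]

    def test_all_slack_matches_pure_hex(self):
        m, _ = self._guyed_column()
        top_face = m.grid_ids[-1].ravel()
        f = np.zeros((m.n_nodes, 3))
        f[top_face, 2] = -1.0 / len(top_face)  # axial: both guys go slack
        u, active = resolve_tension_only(m, LoadCase(forces=f))
        assert [i for i in active if m.springs[i].tension_only] == []
        bare = m.copy()
        bare.springs = []
        u2, _ = resolve_tension_only(bare, LoadCase(forces=f[: bare.n_nodes]))
        np.testing.assert_allclose(u[:len(u2)], u2, atol=1e-12)

    def test_converged_set_stable_under_perturbation(self):
        m, top = self._guyed_column()
        f = np.zeros((m.n_nodes, 3))
        f[top, 1] = 1.0
        _, active = resolve_tension_only(m, LoadCase(forces=f))
        f2 = f.copy()
        f2[top, 1] = 1.001
        _, active2 = resolve_tension_only(m, LoadCase(forces=f2))
        assert active == active2


class TestGravityTwoPass:
    def test_zero_weight(self, loaded_template):
        m = loaded_template.copy()
        before = m.nodes.copy()
        st = apply_gravity_two_pass(m, 0.0,
                                    defaults.default_gravity_table())
        assert np.abs(st.sigma).max() < 1e-12
        np.testing.assert_array_equal(m.nodes, before)

    def test_symmetric_template_left_right_equal(self, loaded_template):
        m = loaded_template.copy()
        st = apply_gravity_two_pass(m, 45.0,
                                    defaults.default_gravity_table())
        for level in ("T5", "T8", "L2"):
            q = quadrant_stresses(m, st, level)
            assert q["ant_left"] == pytest.approx(q["ant_right"], abs=1e-6)
            assert q["post_left"] == pytest.approx(q["post_right"], abs=1e-6)

    def test_restores_imaged_geometry(self, loaded_template):
        m = loaded_template.copy()
        before = m.nodes.copy()
        apply_gravity_two_pass(m, 45.0, defaults.default_gravity_table())
        np.testing.assert_array_equal(m.nodes, before)

    def test_scoliotic_concave_compression_exceeds_convex(
            self, scoliotic_model):
        m = scoliotic_model.copy()
        st = apply_gravity_two_pass(m, 45.0,
                                    defaults.default_gravity_table())
        idx = metrics.measure_indices(template.extract_landmarks(m))
        q = ivd_quadrant_stress(m, st, idx.thoracic.apex,
                                idx.thoracic.convex_side)
        assert q["anterior_concave"] > q["anterior_convex"]
        assert q["posterior_concave"] > q["posterior_convex"]

    def test_negative_fraction_rejected(self, loaded_template):
        with pytest.raises(ValueError):
            gravity_forces(loaded_template, 45.0, {"T1": -0.1})


class TestQuadrantStress:
    def test_symmetric_load_all_equal(self, loaded_template):
        m = loaded_template.copy()
        st = apply_gravity_two_pass(m, 45.0,
                                    defaults.default_gravity_table())
        q = ivd_quadrant_stress(m, st, "T8", "left")
        # left/right symmetric: convex equals concave pairwise
        assert q["anterior_convex"] == pytest.approx(q["anterior_concave"],
                                                     abs=1e-6)
        assert q["posterior_convex"] == pytest.approx(q["posterior_concave"],
                                                      abs=1e-6)

    def test_pure_lateral_moment_antisymmetric(self, loaded_template):
        m = loaded_template.copy()
        f = np.zeros((m.n_nodes, 3))
        t1 = m.groups["T1"]["body_nodes"]
        y = m.nodes[t1, 1]
        f[t1, 2] = 0.5 * (y - y.mean())   # couple about the AP axis
        st = solve_static(m, LoadCase(forces=f))
        q = quadrant_stresses(m, st, "T8")
        assert q["ant_left"] == pytest.approx(-q["ant_right"], rel=0.05)
        assert q["post_left"] == pytest.approx(-q["post_right"], rel=0.05)

    def test_l5_falls_back_to_disc_above(self, loaded_template):
        assert loaded_template.ivd_level_label("L5") == "L4/L5"

    def test_unknown_level_rejected(self, loaded_template):
        with pytest.raises(ValueError):
            loaded_template.ivd_level_label("S1")

    def test_physiological_magnitudes_scoliotic(self, scoliotic_model):
        m = scoliotic_model.copy()
        st = apply_gravity_two_pass(m, 45.0,
                                    defaults.default_gravity_table())
        q = ivd_quadrant_stress(m, st, "T8", "left")
        assert max(abs(v) for v in q.values()) < 1.5
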