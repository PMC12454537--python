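"""Steady-state heat conduction fibre fields and power-law Dirichlet BCs."""

import numpy as np
import pytest

from myofield.mesh import REGION_IDS, box_mesh
from myofield.synth import BipennateSpec, make_bipennate_mesh
from myofield.thermal import (
    ThermalBCParams,
    build_dirichlet_values,
    element_flux_fibres,
    solve_steady_heat,
    thermal_fibre_field,
)

E2 = np.array([0.0, 1.0, 0.0])


class TestDirichletValues:
    def test_ramp_arithmetic(self):
        # node at n = 0.5 with exponent 2 -> 0.25 (independent arithmetic)
        assert 1.0 * 0.5**2 == pytest.approx(0.25, abs=1e-12)
        m = box_mesh((2, 4, 2), (1.0, 2.0, 1.0))
        faces, owner = m.boundary_faces()
        lateral = faces[
            np.all(m.nodes[faces][:, :, 1] > 1e-12, axis=1)
            & np.all(m.nodes[faces][:, :, 1] < 2.0 - 1e-12, axis=1)
        ]
        m.face_sets["muscle_surface"] = lateral
        m.face_sets["aponeurosis_surface"] = lateral[:1]
        params = ThermalBCParams(T1=-5.0, alpha1=2.0, alpha2=2.0,
                                 proximal_high=False)
        idx, vals = build_dirichlet_values(m, params)
        lookup = dict(zip(idx, vals))
        # lateral mid-height node: n = (1.0 - 0.5) / (1.5 - 0.5) = 0.5
        target = [
            i for i in np.unique(lateral)
            if abs(m.nodes[i, 1] - 1.0) < 1e-9
            and i not in np.unique(m.face_sets["aponeurosis_surface"])
        ]
        for i in target:
            assert lookup[i] == pytest.approx(0.25, abs=1e-9)

    def test_proximal_end_of_ramp_meets_inlet_value(self, mesh):
        params = ThermalBCParams(T1=-50.0, alpha1=3.0, alpha2=7.0)
        idx, vals = build_dirichlet_values(mesh, params)
        lookup = dict(zip(idx, vals))
        surf = mesh.face_set_nodes("muscle_surface")
        inlet = set(mesh.face_set_nodes("inlet"))
        surf = [i for i in surf if i not in inlet]
        y = mesh.nodes[surf, 1]
        most_proximal = surf[int(np.argmin(y))]
        # ramp peaks (n = 1 -> T0) at the proximal side
        ymin, ymax = y.min(), y.max()
        n = 1.0 - (mesh.nodes[most_proximal, 1] - ymin) / (ymax - ymin)
        assert lookup[most_proximal] == pytest.approx(n**3.0, abs=1e-12)
        assert lookup[most_proximal] == pytest.approx(1.0, abs=1e-12)

    def test_alpha_zero_constant_ramp(self, mesh):
        params = ThermalBCParams(T1=-50.0, alpha1=0.0, alpha2=0.0)
        idx, vals = build_dirichlet_values(mesh, params)
        lookup = dict(zip(idx, vals))
        inout = set(mesh.face_set_nodes("inlet")) | set(
            mesh.face_set_nodes("outlet")
        )
        for i in mesh.face_set_nodes("muscle_surface"):
            if i not in inout:
                assert lookup[i] == 1.0  # 0^0 := 1 convention included

    def test_precedence_inlet_over_all(self, mesh):
        params = ThermalBCParams(T1=-50.0, alpha1=5.0, alpha2=5.0)
        idx, vals = build_dirichlet_values(mesh, params)
        lookup = dict(zip(idx, vals))
        for i in mesh.face_set_nodes("inlet"):
            assert lookup[i] == params.T0
        for i in mesh.face_set_nodes("outlet"):
            assert lookup[i] == params.T1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ThermalBCParams(T0=1.0, T1=1.0)
        with pytest.raises(ValueError):
            ThermalBCParams(alpha1=-1.0)


class TestSolveSteadyHeat:
    def test_linear_profile_on_box(self):
        m = box_mesh((3, 7, 4), (1.0, 2.0, 1.5))
        idx = np.concatenate(
            [m.face_set_nodes("inlet"), m.face_set_nodes("outlet")]
        )
        vals = np.concatenate(
            [
                np.zeros(len(m.face_set_nodes("inlet"))),
                np.ones(len(m.face_set_nodes("outlet"))),
            ]
        )
        T = solve_steady_heat(m, (idx, vals))
        exact = m.nodes[:, 1] / 2.0
        assert np.abs(T - exact).max() <= 1e-9

    def test_constant_constraints_give_constant_field(self, mesh):
        idx = np.concatenate(
            [mesh.face_set_nodes("inlet"), mesh.face_set_nodes("outlet")]
        )
        vals = np.full(len(idx), 0.7)
        T = solve_steady_heat(mesh, (idx, vals))
        assert np.allclose(T, 0.7, atol=1e-10)

    def test_discrete_maximum_principle(self, mesh):
        params = ThermalBCParams(T1=-40.0, alpha1=2.0, alpha2=9.0)
        dirichlet = build_dirichlet_values(mesh, params)
        T = solve_steady_heat(mesh, dirichlet)
        assert T.min() >= dirichlet[1].min() - 1e-9
        assert T.max() <= dirichlet[1].max() + 1e-9

    def test_flux_conservation_at_free_nodes(self, mesh):
        from myofield.thermal import assemble_stiffness

        params = ThermalBCParams(T1=-40.0, alpha1=2.0, alpha2=9.0)
        idx, vals = build_dirichlet_values(mesh, params)
        T = solve_steady_heat(mesh, (idx, vals))
        K = assemble_stiffness(mesh)
        res = K @ T
        free = np.ones(mesh.n_nodes, dtype=bool)
        free[idx] = False
        assert np.abs(res[free]).max() <= 1e-8 * max(np.abs(vals).max(), 1.0)

    def test_unconstrained_system_rejected(self, mesh):
        with pytest.raises(ValueError):
            solve_steady_heat(mesh, (np.array([], dtype=int), np.array([])))


class TestElementFluxFibres:
    def test_linear_axial_temperature_gives_e2_fibres(self, mesh):
        T = -mesh.nodes[:, 1]  # decreasing distally
        f = element_flux_fibres(mesh, T)
        assert np.all(f.valid)
        assert np.allclose(f.vectors, E2, atol=1e-9)

    def test_kappa_scale_invariance(self, mesh):
        params = ThermalBCParams(T1=-40.0, alpha1=2.0, alpha2=9.0)
        dirichlet = build_dirichlet_values(mesh, params)
        T = solve_steady_heat(mesh, dirichlet)
        f1 = element_flux_fibres(mesh, T, kappa=1.0)
        f2 = element_flux_fibres(mesh, T, kappa=2.0)
        assert np.allclose(f1.vectors, f2.vectors, atol=1e-12)

    def test_axis_alignment(self, mesh):
        params = ThermalBCParams(T1=-40.0, alpha1=2.0, alpha2=9.0)
        f, _ = thermal_fibre_field(mesh, params)
        dots = f.vectors[f.valid] @ E2
        assert np.all(dots >= -1e-12)
        assert np.allclose(
            np.linalg.norm(f.vectors[f.valid], axis=1), 1.0, atol=1e-12
        )

    def test_constant_temperature_masks_elements_invalid(self, mesh):
        T = np.full(mesh.n_nodes, 0.3)
        f = element_flux_fibres(mesh, T)
        assert not f.valid.any()


class TestFeatherPattern:
    def test_ramps_turn_fusiform_into_feather(self, mesh):
        muscle = mesh.region == REGION_IDS["muscle"]
        # end BCs only: near-axial (fusiform) field
        idx = np.concatenate(
            [mesh.face_set_nodes("inlet"), mesh.face_set_nodes("outlet")]
        )
        vals = np.concatenate(
            [
                np.ones(len(mesh.face_set_nodes("inlet"))),
                -30.0 * np.ones(len(mesh.face_set_nodes("outlet"))),
            ]
        )
        T = solve_steady_heat(mesh, (idx, vals))
        fus = element_flux_fibres(mesh, T)
        ang_fus = np.degrees(
            np.arccos(np.clip(fus.vectors[muscle] @ E2, -1, 1))
        )
        # adding the surface/sheet ramps: feather field
        feather, _ = thermal_fibre_field(
            mesh, ThermalBCParams(T1=-30.0, alpha1=2.0, alpha2=8.0)
        )
        ang_fea = np.degrees(
            np.arccos(np.clip(feather.vectors[muscle] @ E2, -1, 1))
        )
        assert ang_fus.mean() < 10.0
        assert ang_fea.mean() > 2.0 * ang_fus.mean()

    def test_fibres_adjacent_to_sheet_point_towards_it(self, mesh, spec):
        # geometric audit: muscle elements sharing a face with an
        # aponeurosis element from above/below the slab (sheet normal +-z)
        # carry flux with a positive component towards the mid-plane
        import collections

        from myofield.mesh import _all_faces

        field, _ = thermal_fibre_field(
            mesh, ThermalBCParams(T1=-30.0, alpha1=2.0, alpha2=8.0)
        )
        cen = mesh.centroids()
        apo = mesh.region == REGION_IDS["aponeurosis"]
        mus = mesh.region == REGION_IDS["muscle"]
        faces, owner = _all_faces(mesh.elements)
        key = np.sort(faces, axis=1)
        _, inv = np.unique(key, axis=0, return_inverse=True)
        face_owners = collections.defaultdict(list)
        for fi, o in zip(inv, owner):
            face_owners[fi].append(o)
        adj = set()
        for pair in face_owners.values():
            if len(pair) == 2:
                a, b = pair
                if apo[a] and mus[b]:
                    adj.add(b)
                if apo[b] and mus[a]:
                    adj.add(a)
        adj = np.array(sorted(adj))
        zmax_apo = np.abs(cen[apo, 2]).max()
        # interior span of the sheet: near its proximal edge the two ramps
        # have not yet separated and near the distal end the outlet sink
        # dominates, so the inward drive is audited over the middle half
        span = spec.muscle_end - spec.apo_start
        y_lo = spec.apo_start + 0.25 * span
        y_hi = spec.apo_start + 0.75 * span
        sel = adj[
            (np.abs(cen[adj, 2]) > zmax_apo)  # above/below, not edge-on
            & (cen[adj, 1] > y_lo)
            & (cen[adj, 1] < y_hi)
        ]
        assert len(sel) > 10
        towards = -np.sign(cen[sel, 2]) * field.vectors[sel, 2]
        assert towards.mean() > 0.0
        assert np.mean(towards > 0) > 0.9


class TestMeshSensitivity:
    def test_fields_converge_across_refinement_ladder(self, spec):
        # four mesh levels (element size / 1.5 per level); the angular
        # difference between consecutive levels shrinks and at the finest
        # pair the field is converged to a few degrees on average, with a
        # stable histogram peak
        from scipy.spatial import cKDTree

        params = ThermalBCParams(T1=-30.0, alpha1=2.5, alpha2=8.0)
        levels = [
            make_bipennate_mesh(
                BipennateSpec(
                    **{
                        **spec.to_dict(),
                        "element_size": spec.element_size / 1.5**k,
                    }
                )
            )
            for k in range(4)
        ]
        fields = [thermal_fibre_field(m, params)[0] for m in levels]
        means, peaks = [], []
        for mc, mf, fc, ff in zip(levels, levels[1:], fields, fields[1:]):
            tree = cKDTree(mc.centroids())
            _, nearest = tree.query(mf.centroids())
            c = np.clip(
                np.einsum("ei,ei->e", ff.vectors, fc.vectors[nearest]), -1, 1
            )
            means.append(np.degrees(np.arccos(c)).mean())
        for m, f in zip(levels, fields):
            a = np.degrees(
                np.arccos(np.clip(f.vectors @ E2, -1, 1))
            )
            counts, edges = np.histogram(a, bins=np.arange(0, 95, 5.0))
            peaks.append(edges[np.argmax(counts)])
        assert means[-1] < means[0]  # differences shrink with refinement
        assert means[-1] <= 5.0  # converged at the finest pair
        assert len(set(peaks)) == 1  # histogram peak bin stable throughout
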