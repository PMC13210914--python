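"""Sphere-model forward fields: geometry, Sarvas identities, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from opmpipe import forward as fwd

SCALP_13 = ["FC1", "C1", "CP1", "FC3", "C3", "CP3", "FC5", "C5", "CP5",
            "FC7", "C7", "CP7", "C9"]


def _random_inner_dipole(rng, head, r_max=0.07):
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    return head.center + rng.uniform(0.01, r_max) * u


class TestGeometry:
    def test_default_array_channel_names(self, array):
        assert array.names[:13] == SCALP_13
        assert array.is_reference.sum() == 3
        assert array.n_channels == 16

    def test_orientations_unit_norm(self, array):
        assert np.allclose(np.linalg.norm(array.orientations, axis=1), 1.0,
                           atol=1e-9)

    def test_scalp_sensors_radial(self, array, head):
        scalp = array.scalp()
        radial = scalp.positions - head.center
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.allclose(scalp.orientations, radial, atol=1e-9)

    def test_reference_axes_mutually_orthogonal(self, array):
        refs = array.orientations[array.is_reference]
        gram = refs @ refs.T - np.eye(3)
        assert np.max(np.abs(gram)) <= 1e-6

    def test_references_are_distant(self, array, head):
        vertex = head.center + head.scalp_radius * np.array([0.0, 0.0, 1.0])
        refs = array.positions[array.is_reference]
        d = np.linalg.norm(refs - vertex, axis=1)
        assert np.all((d >= 0.35) & (d <= 0.40))

    def test_unknown_label_rejected(self):
        with pytest.raises(KeyError):
            fwd.label_direction("Oz9")

    def test_grid_on_source_shell_with_tangential_orientations(self, grid, head):
        r = np.linalg.norm(grid.vertices - head.center, axis=1)
        assert np.allclose(r, head.source_radius, atol=1e-9)
        radial = (grid.vertices - head.center) / head.source_radius
        dots = np.abs(np.sum(radial * grid.orientations, axis=1))
        assert np.max(dots) <= 1e-6

    def test_grid_partitions_into_six_rois(self, grid):
        counts = {r: grid.roi_labels.count(r) for r in fwd.ROI_NAMES}
        assert all(c == 20 for c in counts.values())
        assert sum(counts.values()) == grid.n_sources

    def test_array_tsv_roundtrip(self, array, tmp_path):
        p = tmp_path / "array.tsv"
        array.to_tsv(p)
        back = fwd.SensorArray.from_tsv(p)
        assert back.names == array.names
        assert np.allclose(back.positions, array.positions, atol=1e-6)
        assert np.array_equal(back.is_reference, array.is_reference)

    def test_invalid_head_rejected(self):
        with pytest.raises(ValueError):
            fwd.SphereHeadModel(scalp_radius=0.07, source_radius=0.09)


class TestSarvas:
    def test_radial_dipole_is_silent(self, head, rng):
        for _ in range(20):
            pos = _random_inner_dipole(rng, head)
            # power-of-two scale keeps the moment exactly parallel to the radius
            q = 2.0**-27 * (pos - head.center)
            d = rng.standard_normal(3)
            fp = head.center + 0.12 * d / np.linalg.norm(d)
            b = fwd.sarvas_field(pos, q, fp, head)
            assert np.max(np.abs(b)) <= 1e-30

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_radial_component_matches_biot_savart(self, head, case):
        rng = np.random.default_rng(case)
        pos = _random_inner_dipole(rng, head)
        q = 1e-8 * rng.standard_normal(3)
        d = rng.standard_normal(3)
        fp = head.center + rng.uniform(0.10, 0.3) * d / np.linalg.norm(d)
        rhat = (fp - head.center) / np.linalg.norm(fp - head.center)
        br_sphere = float(np.dot(fwd.sarvas_field(pos, q, fp, head), rhat))
        br_free = float(np.dot(fwd.biot_savart_dipole_field(pos, q, fp), rhat))
        scale = np.linalg.norm(fwd.biot_savart_dipole_field(pos, q, fp))
        assert abs(br_sphere - br_free) <= 1e-9 * scale

    def test_linearity_in_moment(self, head, rng):
        pos = _random_inner_dipole(rng, head)
        q = 1e-8 * rng.standard_normal(3)
        fp = np.array([0.02, 0.05, 0.11])
        b1 = fwd.sarvas_field(pos, q, fp, head)
        b2 = fwd.sarvas_field(pos, 2 * q, fp, head)
        assert np.allclose(b2, 2 * b1, rtol=0, atol=1e-25)

    def test_superposition_of_dipoles(self, head, rng):
        fp = np.array([0.0, 0.04, 0.12])
        p1, p2 = (_random_inner_dipole(rng, head) for _ in range(2))
        q1, q2 = 1e-8 * rng.standard_normal((2, 3))
        b_sum = (fwd.sarvas_field(p1, q1, fp, head)
                 + fwd.sarvas_field(p2, q2, fp, head))
        # same dipoles evaluated jointly via lead-field style accumulation
        b_joint = sum(fwd.sarvas_field(p, q, fp, head)
                      for p, q in ((p1, q1), (p2, q2)))
        assert np.allclose(b_sum, b_joint, rtol=0, atol=0)

    def test_interior_field_point_rejected(self, head):
        with pytest.raises(ValueError):
            fwd.sarvas_field(np.zeros(3) + 0.01, np.array([0, 0, 1e-8]),
                             np.array([0, 0, 0.05]), head)

    def test_exterior_dipole_rejected(self, head):
        with pytest.raises(ValueError):
            fwd.sarvas_field(np.array([0, 0, 0.10]), np.array([0, 1e-8, 0]),
                             np.array([0, 0, 0.2]), head)


class TestLeadField:
    def test_entry_equals_direct_projection(self, head):
        arr = fwd.build_default_array(head).pick(["C3", "REF_SUP", "REF_POST",
                                                  "REF_LEFT"])
        grid = fwd.build_default_grid(head)
        one = fwd.SourceGrid(grid.vertices[:1], grid.orientations[:1],
                             [grid.roi_labels[0]])
        L = fwd.compute_lead_field(arr, one, head)
        b = fwd.sarvas_field(one.vertices[0], one.orientations[0],
                             arr.positions[0], head)
        assert L.matrix[0, 0] == pytest.approx(float(np.dot(
            arr.orientations[0], b)), rel=1e-12)

    def test_shallow_source_stronger_than_deep(self, head, array):
        u = fwd.label_direction("C3")
        yhat = np.array([0.0, 1.0, 0.0])
        tang = yhat - np.dot(yhat, u) * u
        tang /= np.linalg.norm(tang)
        shallow = fwd.SphereHeadModel(source_radius=0.07)
        cols = []
        for depth_r in (0.07, 0.04):
            h = fwd.SphereHeadModel(source_radius=depth_r)
            g = fwd.SourceGrid((h.center + depth_r * u)[None, :],
                               tang[None, :], ["central sulcus"])
            cols.append(np.linalg.norm(
                fwd.compute_lead_field(array, g, h).matrix[:, 0]))
        assert cols[0] > cols[1]

    def test_radial_probe_column_is_zero(self, head, array):
        u = fwd.label_direction("C3")
        g = fwd.SourceGrid((head.center + 0.07 * u)[None, :], u[None, :],
                           ["central sulcus"])
        L = fwd.compute_lead_field(array, g, head)
        assert np.linalg.norm(L.matrix[:, 0]) <= 1e-30

    def test_off_shell_vertex_rejected(self, head, array):
        g = fwd.SourceGrid(np.array([[0.0, 0.0, 0.05]]),
                           np.array([[1.0, 0.0, 0.0]]), ["central sulcus"])
        with pytest.raises(ValueError):
            fwd.compute_lead_field(array, g, head)


class TestSensitivity:
    def test_single_channel_values_are_absolute_entries(self, head, grid):
        arr = fwd.build_default_array(head).pick(
            ["C3", "REF_SUP", "REF_POST", "REF_LEFT"])
        L = fwd.compute_lead_field(arr, grid, head)
        sm = fwd.sensitivity_map(L, grid)
        assert np.allclose(sm.values, np.abs(L.matrix[0]), rtol=1e-12)

    def test_roi_ordering_matches_array_placement(self, lead, grid):
        sm = fwd.sensitivity_map(lead, grid)
        best = max(sm.per_roi_mean, key=sm.per_roi_mean.get)
        assert best in ("precentral gyrus", "postcentral gyrus")
        assert (sm.per_roi_mean["superior parietal lobule"]
                < sm.per_roi_mean["postcentral gyrus"])

    def test_sensitivity_decays_with_depth(self, head, array):
        u = fwd.label_direction("C3")
        yhat = np.array([0.0, 1.0, 0.0])
        tang = yhat - np.dot(yhat, u) * u
        tang /= np.linalg.norm(tang)
        norms = []
        for r in (0.07, 0.06, 0.05, 0.04, 0.03):
            h = fwd.SphereHeadModel(source_radius=r)
            g = fwd.SourceGrid((h.center + r * u)[None, :], tang[None, :],
                               ["central sulcus"])
            norms.append(np.linalg.norm(
                fwd.compute_lead_field(array, g, h).matrix[:, 0]))
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_empty_roi_rejected(self, lead, head):
        g = fwd.build_default_grid(head)
        g2 = fwd.SourceGrid(g.vertices, g.orientations,
                            ["central sulcus"] * g.n_sources)
        with pytest.raises(ValueError, match="postcentral gyrus|precentral"):
            fwd.sensitivity_map(lead, g2)

    def test_multi_subject_sd(self, head, grid, array):
        leads = []
        for standoff in (0.009, 0.010, 0.011):
            arr = fwd.build_default_array(head, standoff=standoff)
            leads.append(fwd.compute_lead_field(arr, grid, head))
        sm = fwd.sensitivity_map(leads[0], grid, subject_leads=leads)
        assert all(sd > 0 for sd in sm.per_roi_sd.values())
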