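"""Co-occurrence fusion head: projections, Gram matrix, bounded flattening."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nephrotext.backends import LayerStack, extract_layer_stack, mean_pooled_primary
from nephrotext.errors import ShapeError
from nephrotext.fusion import (FusedVector, FusionParams, N_FUSION_VECTORS,
                               cooccurrence, fuse, fused_dim, init_fusion_params,
                               project, scale_flatten)
from nephrotext.serialize import Narrative


def _params(d=8, p=6, seed=0):
    return init_fusion_params(d, proj_dim=p, seed=seed)


class TestProject:
    def test_zero_map_gives_zero(self):
        params = FusionParams(weights=np.zeros((10, 6, 8)), biases=np.zeros((10, 6)))
        np.testing.assert_array_equal(project(np.ones(8), 1, params), np.zeros(6))

    def test_identity_on_nonnegative(self):
        eye = np.stack([np.eye(5)] * 10)
        params = FusionParams(weights=eye, biases=np.zeros((10, 5)))
        v = np.array([0.0, 1.0, 2.0, 0.5, 3.0])
        np.testing.assert_array_equal(project(v, 3, params), v)

    def test_matches_explicit_loop_oracle(self, rng):
        params = _params(d=12, p=7, seed=1)
        v = rng.standard_normal(12)
        for j in (1, 5, 10):
            oracle = np.array([
                max(0.0, sum(params.weights[j - 1][r, c] * v[c] for c in range(12))
                    + params.biases[j - 1][r])
                for r in range(7)
            ])
            np.testing.assert_allclose(project(v, j, params), oracle, atol=1e-12)

    def test_output_nonnegative(self, rng):
        params = _params()
        assert np.all(project(rng.standard_normal(8), 2, params) >= 0)

    def test_dimension_mismatch(self):
        with pytest.raises(ShapeError):
            project(np.ones(9), 1, _params(d=8))

    def test_index_out_of_range(self):
        with pytest.raises(ShapeError):
            project(np.ones(8), 11, _params(d=8))


class TestCooccurrence:
    def test_zero_input(self):
        np.testing.assert_array_equal(cooccurrence(np.zeros((10, 6))), np.zeros((10, 10)))

    def test_orthonormal_rows_give_identity(self):
        U = np.eye(10, 16)
        np.testing.assert_allclose(cooccurrence(U), np.eye(10), atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        U = rng.standard_normal((10, 6))
        oracle = np.array([[float(np.dot(U[i], U[j])) for j in range(10)]
                           for i in range(10)])
        np.testing.assert_allclose(cooccurrence(U), oracle, atol=1e-12)

    @given(U=arrays(np.float64, (10, 4), elements=st.floats(-5, 5)))
    def test_symmetric_and_psd(self, U):
        C = cooccurrence(U)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        assert np.linalg.eigvalsh(C).min() >= -1e-8

    def test_wrong_row_count(self):
        with pytest.raises(ShapeError):
            cooccurrence(np.zeros((9, 6)))


class TestScaleFlatten:
    def test_zero_matrix_maps_to_zero(self):
        np.testing.assert_array_equal(scale_flatten(np.zeros((10, 10)), 3.7),
                                      np.zeros(100))

    def test_zero_gamma_maps_to_zero(self, rng):
        C = rng.standard_normal((10, 10))
        np.testing.assert_array_equal(scale_flatten(C, 0.0), np.zeros(100))

    def test_log3_entry_maps_to_half(self):
        C = np.zeros((10, 10))
        C[0, 0] = math.log(3.0)
        p = scale_flatten(C, 1.0)
        assert p[0] == pytest.approx(0.5, abs=1e-12)

    def test_row_major_flattening(self):
        C = np.arange(100, dtype=float).reshape(10, 10)
        p = scale_flatten(C, 0.01)
        # entry (i, j) lands at position 10*i + j
        assert p[13] == pytest.approx(2 / (1 + math.exp(-0.01 * C[1, 3])) - 1)

    @given(gamma=st.floats(0.1, 5.0))
    def test_monotone_and_odd(self, gamma):
        C = np.random.default_rng(0).standard_normal((10, 10))
        eps = 1e-6
        p_lo, p_hi = scale_flatten(C, gamma), scale_flatten(C + eps, gamma)
        assert np.all(p_hi >= p_lo)  # entrywise monotone in c_flat
        np.testing.assert_allclose(scale_flatten(-C, gamma),
                                   -scale_flatten(C, gamma), atol=1e-12)

    def test_bounded_open_interval(self, rng):
        p = scale_flatten(rng.standard_normal((10, 10)) * 100, 10.0)
        assert np.all(np.abs(p) < 1.0)


class TestFuse:
    def _stacks_and_vq(self, be_primary, be_secondary, text="a b c"):
        nar = Narrative("p", text)
        return ([extract_layer_stack(nar, be_primary),
                 extract_layer_stack(nar, be_secondary)],
                mean_pooled_primary(nar, be_primary))

    def test_full_geometry_length(self):
        assert fused_dim(4096) == 4196
        from nephrotext.backends import make_mock_backend
        p = make_mock_backend("q", 4096, 8, 0, role="primary")
        s = make_mock_backend("l", 4096, 8, 1, role="secondary")
        stacks, vq = self._stacks_and_vq(p, s)
        out = fuse(stacks, vq, init_fusion_params(4096, proj_dim=8, seed=0))
        assert len(out.values) == 4196

    def test_mock_geometry_length(self, mock_backends):
        p, s = mock_backends
        stacks, vq = self._stacks_and_vq(p, s)
        out = fuse(stacks, vq, init_fusion_params(32, proj_dim=16, seed=0))
        assert len(out.values) == 132

    def test_tail_is_vq_unchanged(self, mock_backends):
        p, s = mock_backends
        stacks, vq = self._stacks_and_vq(p, s)
        out = fuse(stacks, vq, init_fusion_params(32, proj_dim=16, seed=0))
        np.testing.assert_array_equal(out.values[100:], vq)

    def test_head_strictly_bounded(self, mock_backends):
        p, s = mock_backends
        stacks, vq = self._stacks_and_vq(p, s)
        out = fuse(stacks, vq, init_fusion_params(32, proj_dim=16, seed=0))
        assert np.all(np.abs(out.values[:100]) < 1.0)

    def test_matches_straight_line_reference(self, mock_backends):
        """Explicit-loop re-implementation agrees to 1e-6."""
        p, s = mock_backends
        stacks, vq = self._stacks_and_vq(p, s)
        params = init_fusion_params(32, proj_dim=16, seed=2)
        out = fuse(stacks, vq, params).values

        V = np.vstack([stacks[0].matrix, stacks[1].matrix])
        U = np.zeros((10, 16))
        for j in range(10):
            for r in range(16):
                acc = params.biases[j][r]
                for c in range(32):
                    acc += params.weights[j][r, c] * V[j, c]
                U[j, r] = max(acc, 0.0)
        ref = []
        for i in range(10):
            for j in range(10):
                c_ij = sum(U[i, k] * U[j, k] for k in range(16))
                ref.append(2.0 / (1.0 + math.exp(-params.gamma * c_ij)) - 1.0)
        ref.extend(vq)
        np.testing.assert_allclose(out, np.array(ref), atol=1e-6)

    def test_wrong_stack_count(self, mock_backends):
        p, s = mock_backends
        stacks, vq = self._stacks_and_vq(p, s)
        with pytest.raises(ShapeError):
            fuse(stacks[:1], vq, init_fusion_params(32, proj_dim=16, seed=0))

    def test_fused_vector_bound_enforced(self):
        with pytest.raises(ShapeError):
            FusedVector(values=np.concatenate([np.ones(100), np.zeros(32)]))

    def test_exactly_ten_projections(self):
        assert N_FUSION_VECTORS == 10
        with pytest.raises(ShapeError):
            FusionParams(weights=np.zeros((9, 4, 8)), biases=np.zeros((9, 4)))
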