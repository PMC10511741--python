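"""Statevector simulator, random circuits, quanvolution, and the QNN head.

The independent oracle densifies circuits via Kronecker products (built here
from scratch, never through the package's gate-application code) and compares
against gate-by-gate simulation.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermonet import quanv as qv

# ---------------------------------------------------------------------------
# independent dense oracle: Kronecker-product construction, little-endian
# (qubit 0 is the LAST factor so that basis index b = sum_q bit_q 2^q)
# ---------------------------------------------------------------------------

_I2 = np.eye(2, dtype=complex)


def _kron_1q(m, q):
    ops = [_I2] * 4
    ops[q] = m
    out = np.array([[1.0 + 0j]])
    for op in ops:  # kron(M3, kron(M2, kron(M1, M0))): qubit 0 least significant
        out = np.kron(op, out)
    return out


def _oracle_matrix(gate):
    if gate.name == "CNOT":
        control, target = gate.qubits
        P0 = np.array([[1, 0], [0, 0]], dtype=complex)
        P1 = np.array([[0, 0], [0, 1]], dtype=complex)
        X = np.array([[0, 1], [1, 0]], dtype=complex)
        return _kron_1q(P0, control) + _kron_1q(P1, control) @ _kron_1q(X, target)
    t = (gate.angle or 0) / 2
    mats = {
        "RX": np.array([[np.cos(t), -1j * np.sin(t)], [-1j * np.sin(t), np.cos(t)]]),
        "RY": np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]], dtype=complex),
        "RZ": np.array([[np.exp(-1j * t), 0], [0, np.exp(1j * t)]]),
        "X": np.array([[0, 1], [1, 0]], dtype=complex),
        "H": np.array([[1, 1], [1, -1]]) / np.sqrt(2),
    }
    return _kron_1q(mats[gate.name], gate.qubits[0])


def _oracle_unitary(gates):
    U = np.eye(16, dtype=complex)
    for g in gates:
        U = _oracle_matrix(g) @ U
    return U


def _random_gates(rng, n):
    gates = []
    for _ in range(n):
        kind = rng.choice(["RX", "RY", "RZ", "X", "H", "CNOT"])
        if kind == "CNOT":
            q = tuple(rng.choice(4, size=2, replace=False).tolist())
            gates.append(qv.GateOp("CNOT", q))
        elif kind in ("RX", "RY", "RZ"):
            gates.append(qv.GateOp(kind, (int(rng.integers(4)),),
                                   float(rng.uniform(0, 2 * np.pi))))
        else:
            gates.append(qv.GateOp(kind, (int(rng.integers(4)),)))
    return gates


def _random_state(rng):
    v = rng.normal(size=16) + 1j * rng.normal(size=16)
    return v / np.linalg.norm(v)


class TestGates:
    def test_x_moves_amplitude_little_endian(self):
        out = qv.apply_gate(qv.zero_state(), qv.GateOp("X", (0,)))
        expected = np.zeros(16, dtype=complex)
        expected[1] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-14)

    @pytest.mark.parametrize("q", range(4))
    def test_ry_pi_flips_qubit(self, q):
        out = qv.apply_gate(qv.zero_state(), qv.GateOp("RY", (q,), np.pi))
        assert abs(abs(out[1 << q]) - 1.0) < 1e-12
        assert qv.expectation_z(out, q) == pytest.approx(-1.0, abs=1e-12)

    def test_gate_sequence_matches_dense_oracle(self):
        """Gate-by-gate application equals the densified product matrix on
        100 random circuits applied to random states (max dev < 1e-10)."""
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            gates = _random_gates(rng, 6)
            state = _random_state(rng)
            seq = qv.apply_circuit(state, gates)
            dense = _oracle_unitary(gates) @ state
            worst = max(worst, np.abs(seq - dense).max())
        assert worst < 1e-10

    def test_gate_validation(self):
        with pytest.raises(ValueError):
            qv.GateOp("RY", (0,))          # rotation without angle
        with pytest.raises(ValueError):
            qv.GateOp("X", (0,), 1.0)      # angle on non-rotation
        with pytest.raises(ValueError):
            qv.GateOp("CNOT", (1, 1))      # duplicate qubits
        with pytest.raises(ValueError):
            qv.GateOp("X", (4,))           # out of range

    @given(st.integers(0, 1000))
    def test_norm_preserved_by_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        state = _random_state(rng)
        out = qv.apply_circuit(state, _random_gates(rng, 8))
        assert abs(np.linalg.norm(out) - 1.0) < 1e-10


class TestExpectation:
    def test_ground_state_and_flipped(self):
        assert qv.expectation_z(qv.zero_state(), 3) == 1.0
        flipped = qv.apply_gate(qv.zero_state(), qv.GateOp("RY", (2,), np.pi))
        assert qv.expectation_z(flipped, 2) == pytest.approx(-1.0, abs=1e-12)

    def test_closed_form_cos_theta_on_grid(self):
        for theta in np.linspace(0, 2 * np.pi, 17):
            state = qv.apply_gate(qv.zero_state(), qv.GateOp("RY", (0,), theta))
            assert qv.expectation_z(state, 0) == pytest.approx(np.cos(theta), abs=1e-12)

    def test_bad_qubit_index(self):
        with pytest.raises(IndexError):
            qv.expectation_z(qv.zero_state(), 5)


class TestRandomCircuit:
    def test_zero_layers_is_identity(self):
        circ = qv.build_random_circuit(0, seed=1)
        assert circ.random_layers == ()

    def test_determinism_and_structure(self):
        a = qv.build_random_circuit(2, seed=9)
        b = qv.build_random_circuit(2, seed=9)
        assert a.random_layers == b.random_layers
        names = [g.name for g in a.random_layers]
        assert names == (["RY"] * 4 + ["CNOT"] * 4) * 2
        rings = [g.qubits for g in a.random_layers if g.name == "CNOT"]
        assert rings[:4] == [(0, 1), (1, 2), (2, 3), (3, 0)]

    def test_built_circuits_are_unitary(self):
        for seed in range(5):
            U = qv.circuit_unitary(qv.build_random_circuit(2, seed))
            np.testing.assert_allclose(U.conj().T @ U, np.eye(16), atol=1e-10)

    def test_negative_layers_rejected(self):
        with pytest.raises(ValueError):
            qv.build_random_circuit(-1)


class TestQuanvolution:
    IDENTITY = qv.CircuitSpec(())

    def test_trivial_patches(self):
        np.testing.assert_allclose(
            qv.quanv_patch([0, 0, 0, 0], self.IDENTITY), [1, 1, 1, 1], atol=1e-14
        )
        np.testing.assert_allclose(
            qv.quanv_patch([1, 1, 1, 1], self.IDENTITY), [-1, -1, -1, -1], atol=1e-12
        )
        np.testing.assert_allclose(
            qv.quanv_patch([0.5, 0, 0, 0], self.IDENTITY), [0, 1, 1, 1], atol=1e-12
        )

    def test_identity_circuit_closed_form_cos_pi_x(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (6, 6))
        fmap = qv.quanvolve_image(img, self.IDENTITY)
        patches = img.reshape(3, 2, 3, 2).transpose(0, 2, 1, 3).reshape(-1, 4)
        np.testing.assert_allclose(
            fmap.reshape(-1, 4), np.cos(np.pi * patches), atol=1e-12
        )

    def test_geometry_256_to_128x128x12(self):
        img = np.random.default_rng(0).uniform(0, 1, (256, 256, 3))
        fmap = qv.quanvolve_image(img, qv.build_random_circuit(1, 0))
        assert fmap.shape == (128, 128, 12)
        assert fmap.min() >= -1.0 and fmap.max() <= 1.0

    @pytest.mark.parametrize("h,w", [(2, 2), (5, 5), (7, 4), (3, 9)])
    def test_shrink_law_floors_odd_sizes(self, h, w):
        img = np.random.default_rng(1).uniform(0, 1, (h, w))
        fmap = qv.quanvolve_image(img, self.IDENTITY)
        assert fmap.shape == (h // 2, w // 2, 4)

    def test_single_patch_image_reduces_to_quanv_patch(self):
        circ = qv.build_random_circuit(2, seed=4)
        img = np.random.default_rng(2).uniform(0, 1, (2, 2))
        np.testing.assert_allclose(
            qv.quanvolve_image(img, circ)[0, 0], qv.quanv_patch(img, circ), atol=1e-12
        )

    def test_constant_image_gives_spatially_constant_channels(self):
        circ = qv.build_random_circuit(1, seed=5)
        fmap = qv.quanvolve_image(np.full((8, 8), 0.3), circ)
        for ch in range(4):
            assert np.ptp(fmap[:, :, ch]) < 1e-12

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            qv.quanv_patch([0, 0, 0, 1.5], self.IDENTITY)
        with pytest.raises(ValueError):
            qv.quanvolve_image(np.full((4, 4), 2.0), self.IDENTITY)
        with pytest.raises(ValueError):
            qv.quanvolve_image(np.zeros((1, 5)), self.IDENTITY)

    def test_shot_sampling_converges_to_exact(self):
        circ = qv.build_random_circuit(1, seed=6)
        img = np.random.default_rng(4).uniform(0, 1, (6, 6))
        exact = qv.quanvolve_image(img, circ)
        noisy = qv.quanvolve_image(img, circ, shots=20000,
                                   rng=np.random.default_rng(0))
        assert np.abs(noisy - exact).max() < 0.05
        assert np.abs(noisy - exact).max() > 0  # sampling actually happened

    def test_transformer_band_major_order_and_grayscale(self):
        X = np.random.default_rng(5).uniform(0, 1, (2, 8, 8, 3))
        qt = qv.QuanvolutionTransformer(n_layers=1, seed=0).fit()
        F = qt.transform(X)
        assert F.shape == (2, 4, 4, 12)
        # band b occupies channels 4b..4b+3
        single = qv.quanvolve_image(X[0, :, :, 1], qt.circuit_)
        np.testing.assert_allclose(F[0, :, :, 4:8], single, atol=1e-12)
        Fg = qv.QuanvolutionTransformer(n_layers=1, seed=0, grayscale=True).fit().transform(X)
        assert Fg.shape == (2, 4, 4, 4)

    def test_independent_kernels_mode(self):
        X = np.random.default_rng(6).uniform(0, 1, (1, 6, 6, 3))
        qt = qv.QuanvolutionTransformer(n_layers=1, seed=3, independent_kernels=True).fit()
        F = qt.transform(X)
        assert F.shape == (1, 3, 3, 12)
        # channel (b, k) is <Z_0> of kernel k on band b
        k2 = qv.quanvolve_image(X[0, :, :, 0], qt.circuits_[2])[:, :, 0]
        np.testing.assert_allclose(F[0, :, :, 2], k2, atol=1e-12)


class TestQNNHead:
    def test_untrained_output_is_probability(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (4, 16, 16, 12))
        clf = qv.QNNClassifier(epochs=1, seed=0).fit(X, [0, 1, 0, 1])
        proba = clf.predict_proba(X)
        assert proba.shape == (4, 2)
        assert ((proba > 0) & (proba < 1)).all()
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_memorizes_small_fixture(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 4)
        X = rng.uniform(-0.2, 0.2, (8, 16, 16, 4))
        X[y == 1] += 0.5  # separable offset
        clf = qv.QNNClassifier(epochs=30, batch_size=8, seed=1).fit(X, y)
        assert clf.history_[-1]["train_accuracy"] == 1.0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            qv.QNNClassifier().fit(np.zeros((0, 8, 8, 4)), [])
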