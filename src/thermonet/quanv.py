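"""Quanvolutional preprocessing and the QNN classifier.

A quanvolutional layer replaces the first convolution of a CNN with a quantum
transform: each non-overlapping 2x2 image patch is encoded into a 4-qubit
state by per-qubit Ry(pi * x) rotations of the pixel values, a fixed seeded
random circuit is applied, and the four Pauli-Z expectation values become the
output channels.  A 3-band image therefore maps to an (H/2, W/2, 12) feature
map (band-major channel order) — the image shrinks by a factor of two in each
spatial direction.

Everything is exact statevector simulation: the 16 complex amplitudes of the
4-qubit register evolve under the gate sequence (little-endian basis ordering,
index b = sum_q bit_q * 2**q).  An optional ``shots`` mode replaces the exact
expectations with binomially sampled estimates.  The classical head trained on
the feature maps is a small CNN (conv 32/16/16/8 with 3x3 kernels, each
followed by 2x2 max pooling, then dense 128 -> dense 1 with sigmoid) trained
with Adam (lr 0.001), binary cross-entropy, batch size 64, 30 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "GateOp",
    "CircuitSpec",
    "zero_state",
    "apply_gate",
    "apply_circuit",
    "circuit_unitary",
    "expectation_z",
    "build_random_circuit",
    "quanv_patch",
    "quanvolve_image",
    "QuanvolutionTransformer",
    "QNNClassifier",
    "train_qnn",
]

N_QUBITS = 4
_DIM = 2**N_QUBITS

_ROTATIONS = ("RX", "RY", "RZ")
_GATES_1Q = _ROTATIONS + ("X", "H")


@dataclass(frozen=True)
class GateOp:
    name: str
    qubits: tuple[int, ...]
    angle: float | None = None

    def __post_init__(self):
        if self.name not in _GATES_1Q + ("CNOT",):
            raise ValueError(f"unknown gate {self.name!r}")
        q = self.qubits
        if any(not (0 <= i < N_QUBITS) for i in q) or len(set(q)) != len(q):
            raise ValueError(f"bad qubit indices {q}")
        if len(q) != (2 if self.name == "CNOT" else 1):
            raise ValueError(f"{self.name} takes {'2' if self.name=='CNOT' else '1'} qubit(s)")
        if (self.angle is None) == (self.name in _ROTATIONS):
            raise ValueError("angle required iff rotation gate")


@dataclass(frozen=True)
class CircuitSpec:
    """Seeded random circuit applied after the Ry(pi*x) encoding layer."""

    random_layers: tuple[GateOp, ...]
    seed: int = 0
    n_qubits: int = N_QUBITS


def zero_state() -> np.ndarray:
    state = np.zeros(_DIM, dtype=np.complex128)
    state[0] = 1.0
    return state


def gate_matrix(gate: GateOp) -> np.ndarray:
    """Dense 2x2 (or 4x4 for CNOT, little-endian (target, control) order)."""
    if gate.name in _ROTATIONS:
        t = gate.angle / 2.0
        c, s = np.cos(t), np.sin(t)
        if gate.name == "RX":
            return np.array([[c, -1j * s], [-1j * s, c]])
        if gate.name == "RY":
            return np.array([[c, -s], [s, c]], dtype=np.complex128)
        return np.array([[np.exp(-1j * t), 0], [0, np.exp(1j * t)]])
    if gate.name == "X":
        return np.array([[0, 1], [1, 0]], dtype=np.complex128)
    if gate.name == "H":
        return np.array([[1, 1], [1, -1]], dtype=np.complex128) / np.sqrt(2)
    # CNOT on basis (control_bit, target_bit) pairs handled in apply_gate
    raise ValueError("CNOT has no single-qubit matrix")


def _cnot_permutation(control: int, target: int) -> np.ndarray:
    b = np.arange(_DIM)
    flipped = b ^ (1 << target)
    return np.where((b >> control) & 1 == 1, flipped, b)


def apply_gate(state: np.ndarray, gate: GateOp) -> np.ndarray:
    """Apply one gate by tensor contraction; returns a new state vector."""
    state = np.asarray(state, dtype=np.complex128)
    if state.shape != (_DIM,):
        raise ValueError(f"state must have {_DIM} amplitudes")
    if gate.name == "CNOT":
        perm = _cnot_permutation(*gate.qubits)
        out = np.empty_like(state)
        out[perm] = state
        return out
    q = gate.qubits[0]
    m = gate_matrix(gate)
    # reshape: C-order axes correspond to qubits (3, 2, 1, 0)
    t = state.reshape((2,) * N_QUBITS)
    axis = N_QUBITS - 1 - q
    t = np.moveaxis(t, axis, 0)
    t = np.tensordot(m, t, axes=(1, 0))
    t = np.moveaxis(t, 0, axis)
    return t.reshape(_DIM)


def apply_circuit(state: np.ndarray, gates) -> np.ndarray:
    for g in gates:
        state = apply_gate(state, g)
    return state


def circuit_unitary(circuit: CircuitSpec) -> np.ndarray:
    """Densify the random-layer sequence into its 16x16 unitary."""
    cols = [apply_circuit(np.eye(_DIM, dtype=np.complex128)[:, j], circuit.random_layers)
            for j in range(_DIM)]
    return np.stack(cols, axis=1)


_Z_SIGNS = np.array(
    [[1.0 if ((b >> q) & 1) == 0 else -1.0 for b in range(_DIM)] for q in range(N_QUBITS)]
)


def expectation_z(state: np.ndarray, qubit: int) -> float:
    """<Z_q> = sum_b |a_b|^2 * (+1 if bit_q(b) = 0 else -1)."""
    if not (0 <= qubit < N_QUBITS):
        raise IndexError(f"qubit index {qubit} out of range")
    probs = np.abs(np.asarray(state)) ** 2
    return float(probs @ _Z_SIGNS[qubit])


def build_random_circuit(n_layers: int = 1, seed: int = 0) -> CircuitSpec:
    """Per layer: one Ry per qubit with angle uniform in [0, 2*pi), followed
    by a CNOT ring 0->1, 1->2, 2->3, 3->0.  Deterministic for a fixed seed."""
    if n_layers < 0:
        raise ValueError("n_layers must be >= 0")
    rng = np.random.default_rng(seed)
    gates: list[GateOp] = []
    for _ in range(n_layers):
        for q in range(N_QUBITS):
            gates.append(GateOp("RY", (q,), float(rng.uniform(0, 2 * np.pi))))
        for q in range(N_QUBITS):
            gates.append(GateOp("CNOT", (q, (q + 1) % N_QUBITS)))
    return CircuitSpec(tuple(gates), seed=seed)


def _encode_states(patches: np.ndarray) -> np.ndarray:
    """Product states for Ry(pi * x_q) encodings of (n, 4) patch values.

    Patch pixels are row-major (0,0),(0,1),(1,0),(1,1) -> qubits 0..3.
    amplitude[b] = prod_q (cos(pi x_q / 2) if bit_q = 0 else sin(pi x_q / 2)).
    """
    half = np.pi * patches / 2.0
    c, s = np.cos(half), np.sin(half)
    # little-endian: reshape axes are (q3, q2, q1, q0)
    v = [np.stack([c[:, q], s[:, q]], axis=1) for q in range(N_QUBITS)]
    states = np.einsum("nd,nc,nb,na->ndcba", v[3], v[2], v[1], v[0])
    return states.reshape(-1, _DIM).astype(np.complex128)


def _expectations(states: np.ndarray) -> np.ndarray:
    probs = np.abs(states) ** 2
    return probs @ _Z_SIGNS.T  # (n, 4)


def quanv_patch(patch_2x2, circuit: CircuitSpec) -> np.ndarray:
    """Transform one 2x2 patch (4 values in [0, 1]) into 4 channel values."""
    patch = np.asarray(patch_2x2, dtype=np.float64).reshape(-1)
    if patch.shape != (4,):
        raise ValueError("patch must contain exactly 4 values")
    if patch.min() < 0 or patch.max() > 1:
        raise ValueError("patch values must lie in [0, 1]")
    state = zero_state()
    for q in range(N_QUBITS):
        state = apply_gate(state, GateOp("RY", (q,), np.pi * patch[q]))
    state = apply_circuit(state, circuit.random_layers)
    return np.array([expectation_z(state, q) for q in range(N_QUBITS)])


def _sample_shots(z: np.ndarray, shots: int, rng: np.random.Generator) -> np.ndarray:
    p1 = np.clip((1.0 - z) / 2.0, 0.0, 1.0)
    return 1.0 - 2.0 * rng.binomial(shots, p1) / shots


def quanvolve_image(
    image: np.ndarray,
    circuit: CircuitSpec,
    shots: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Tile each band into non-overlapping 2x2 patches (stride 2, odd edges
    truncated) and emit the four <Z_q> channels per patch.

    Output shape (H//2, W//2, bands * 4), band-major then qubit.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w, bands = img.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2")
    if img.min() < -1e-12 or img.max() > 1 + 1e-12:
        raise ValueError("image values must lie in [0, 1]")
    img = np.clip(img, 0.0, 1.0)
    h2, w2 = h // 2, w // 2
    U = circuit_unitary(circuit) if circuit.random_layers else None
    out = np.empty((h2, w2, bands * 4))
    for band in range(bands):
        x = img[: 2 * h2, : 2 * w2, band].reshape(h2, 2, w2, 2)
        patches = x.transpose(0, 2, 1, 3).reshape(-1, 4)
        states = _encode_states(patches)
        if U is not None:
            states = states @ U.T
        z = _expectations(states)
        if shots is not None:
            rng = rng or np.random.default_rng(circuit.seed)
            z = _sample_shots(z, shots, rng)
        out[:, :, band * 4 : (band + 1) * 4] = z.reshape(h2, w2, 4)
    return out


class QuanvolutionTransformer(BaseEstimator, TransformerMixin):
    """Stateless (fit draws the circuit) patch-wise quanvolution transform.

    ``independent_kernels`` draws four circuits and uses <Z_0> of each as the
    four channels instead of the four per-qubit expectations of one shared
    circuit (two readings of the construction; shared is the default).
    """

    def __init__(self, n_layers: int = 1, seed: int = 0, grayscale: bool = False,
                 shots: int | None = None, independent_kernels: bool = False):
        self.n_layers = n_layers
        self.seed = seed
        self.grayscale = grayscale
        self.shots = shots
        self.independent_kernels = independent_kernels

    def fit(self, X=None, y=None):
        if self.independent_kernels:
            self.circuits_ = tuple(
                build_random_circuit(self.n_layers, self.seed + i) for i in range(4)
            )
        else:
            self.circuit_ = build_random_circuit(self.n_layers, self.seed)
        return self

    def _prep(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 3:
            X = X[:, :, :, None]
        if self.grayscale and X.shape[3] == 3:
            X = X.mean(axis=3, keepdims=True)
        return X

    def transform(self, X):
        check_is_fitted(self)
        X = self._prep(X)
        rng = np.random.default_rng(self.seed + 1) if self.shots else None
        maps = []
        for img in X:
            if self.independent_kernels:
                per = [
                    quanvolve_image(img, c, self.shots, rng)[
                        :, :, 0 :: 4
                    ]  # <Z_0> of each band
                    for c in self.circuits_
                ]
                # band-major then kernel order
                bands = per[0].shape[2]
                fmap = np.empty(per[0].shape[:2] + (bands * 4,))
                for b in range(bands):
                    for k in range(4):
                        fmap[:, :, b * 4 + k] = per[k][:, :, b]
            else:
                fmap = quanvolve_image(img, self.circuit_, self.shots, rng)
            maps.append(fmap)
        return np.stack(maps)


def _qnn_head_layers(in_ch: int, spatial: int, rng, dtype=np.float32):
    layers: list[nn.Layer] = []
    ch = in_ch
    size = spatial
    for out_ch in (32, 16, 16, 8):
        layers.append(nn.Conv2D(ch, out_ch, (3, 3), padding="same", rng=rng, dtype=dtype))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2())
        ch = out_ch
        size //= 2
        if size < 1:
            raise ValueError("feature map too small for the four-block head")
    layers.append(nn.Flatten())
    layers.append(nn.Dense(size * size * ch, 128, rng=rng, dtype=dtype))
    layers.append(nn.ReLU())
    layers.append(nn.Dense(128, 1, rng=rng, dtype=dtype))
    return layers


class QNNClassifier(BaseEstimator, ClassifierMixin):
    """Classical head of the quanvolutional network.

    Four conv blocks (32/16/16/8 filters, 3x3, each followed by 2x2 max
    pooling) then dense 128 (ReLU) and dense 1 (sigmoid); Adam, learning rate
    0.001, binary cross-entropy, batch size 64, 30 epochs.
    """

    def __init__(self, learning_rate: float = 0.001, batch_size: int = 64,
                 epochs: int = 30, checkpoint: bool = True, seed: int = 0):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.checkpoint = checkpoint
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError("X must be (n, H, W, C) feature maps")
        if len(X) == 0:
            raise ValueError("empty training set")
        if X.shape[1] != X.shape[2]:
            raise ValueError("feature maps must be square")
        self.classes_, y_int = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("QNNClassifier is strictly two-class")
        rng = np.random.default_rng(self.seed)
        self.net_ = nn.Network(_qnn_head_layers(X.shape[3], X.shape[1], rng))
        self.loss_ = nn.SigmoidBCE()
        opt = nn.Adam(self.net_.params, lr=self.learning_rate)
        if X_val is not None:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.searchsorted(self.classes_, np.asarray(y_val))
        self.history_, self.best_epoch_ = nn.train_network(
            self.net_, self.loss_, opt, X, y_int, X_val, y_val,
            epochs=self.epochs, batch_size=self.batch_size,
            seed=self.seed + 1, checkpoint=self.checkpoint,
        )
        return self

    def decision_function(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float32)
        return nn._batched_forward(self.net_, X, 64).ravel()

    def predict_proba(self, X):
        return self.loss_.predict_proba(self.decision_function(X))

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def train_qnn(X_train, y_train, X_val=None, y_val=None, **kwargs) -> QNNClassifier:
    return QNNClassifier(**kwargs).fit(X_train, y_train, X_val, y_val)
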