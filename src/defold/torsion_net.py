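"""Backbone torsion prediction from windowed sequence features.

Each residue is described by 24 features in [0, 1] — 20 position-specific
scores, 3 secondary-structure probabilities, 1 solvent accessibility — and a
context window of 17 residues on each side, giving a 35 x 24 input map per
residue (off-chain rows are zero-padded).  A compact convolutional network
maps the window to (sin phi, cos phi, sin psi, cos psi); encoding angles by
their sine and cosine removes the wrap-around discontinuity at +/-180, and
predictions are decoded with the quadrant-aware arctangent
alpha = atan2(sin, cos).

Architecture: conv(16 filters, width 5) -> maxpool(2) -> conv(32, width 3)
-> maxpool(2) -> conv(64, width 3) -> dense(64) -> dense(4), ReLU
activations, MSE loss on the sin/cos 4-vector, Adam updates.  Weights are
initialized from a zero-centered Gaussian with standard deviation 5/N per
layer (N = fan-in), with sqrt(5/N) available as an option.  The network is
small enough that plain numpy forward/backward passes train it in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .geometry import circular_difference

N_FEATURES = 24
DEFAULT_CONTEXT = 17  # residues each side -> 35-row window


class TrainingDivergence(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Features and windows


@dataclass
class FeatureTable:
    """Per-residue features, shape (L, 24), all values in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature table must be (L, {N_FEATURES})")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("features must be normalized to [0, 1]")

    @property
    def L(self) -> int:
        return self.values.shape[0]


def read_feature_table(path) -> FeatureTable:
    """Whitespace-delimited numeric table with a one-line header."""
    return FeatureTable(np.loadtxt(path, skiprows=1))


def write_feature_table(table: FeatureTable, path) -> None:
    header = " ".join(
        [f"pssm{i}" for i in range(20)] + ["ss_h", "ss_e", "ss_c", "sa"]
    )
    np.savetxt(path, table.values, header=header, comments="", fmt="%.6f")


def build_window(features: FeatureTable, position: int,
                 w: int = DEFAULT_CONTEXT) -> np.ndarray:
    """(2w+1, 24) feature window centered on ``position``, zero-padded."""
    if w < 1:
        raise ValueError("context half-width must be >= 1")
    if not 0 <= position < features.L:
        raise IndexError("position outside the chain")
    out = np.zeros((2 * w + 1, N_FEATURES))
    lo = max(0, position - w)
    hi = min(features.L, position + w + 1)
    out[lo - (position - w): lo - (position - w) + (hi - lo)] = \
        features.values[lo:hi]
    return out


def build_all_windows(features: FeatureTable, w: int = DEFAULT_CONTEXT) -> np.ndarray:
    """Stacked windows for every residue, shape (L, 2w+1, 24)."""
    return np.stack([build_window(features, i, w) for i in range(features.L)])


# ---------------------------------------------------------------------------
# Angle encoding


def encode_angles(phi, psi) -> np.ndarray:
    """Angles (degrees) -> (sin phi, cos phi, sin psi, cos psi) rows."""
    phi = np.deg2rad(np.asarray(phi, dtype=float))
    psi = np.deg2rad(np.asarray(psi, dtype=float))
    return np.stack(
        [np.sin(phi), np.cos(phi), np.sin(psi), np.cos(psi)], axis=-1
    )


def decode_angles(raw: np.ndarray) -> tuple[float, float]:
    """Raw (sin phi, cos phi, sin psi, cos psi) -> (phi, psi) in (-180, 180].

    Each (sin, cos) pair is renormalized to the unit circle before the
    quadrant-aware arctangent; an exactly-zero pair has no defined angle.
    """
    raw = np.asarray(raw, dtype=float)
    out = []
    for k in (0, 2):
        s, c = raw[..., k], raw[..., k + 1]
        norm = np.hypot(s, c)
        if np.any(norm == 0):
            raise ValueError("(sin, cos) = (0, 0): angle undefined")
        ang = np.degrees(np.arctan2(s / norm, c / norm))
        ang = np.where(ang <= -180.0, ang + 360.0, ang)
        out.append(ang)
    phi, psi = out
    if phi.ndim == 0:
        return float(phi), float(psi)
    return phi, psi


@dataclass
class TorsionPrediction:
    """Decoded per-residue predictions plus the raw network outputs."""

    phi: np.ndarray
    psi: np.ndarray
    raw: np.ndarray

    @property
    def L(self) -> int:
        return self.phi.shape[0]


def write_prediction_tsv(pred: TorsionPrediction, path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tphi\tpsi\n")
        for i in range(pred.L):
            fh.write(f"{i}\t{pred.phi[i]:.2f}\t{pred.psi[i]:.2f}\n")


# ---------------------------------------------------------------------------
# Network layers


def init_std(fan_in: int, mode: str = "5/N") -> float:
    """Per-layer Gaussian init scale: literal 5/N, or sqrt(5/N)."""
    if mode == "5/N":
        return 5.0 / fan_in
    if mode == "sqrt(5/N)":
        return float(np.sqrt(5.0 / fan_in))
    raise ValueError(f"unknown init mode: {mode!r}")


class _Conv1D:
    def __init__(self, in_ch, out_ch, width, rng, init_mode):
        std = init_std(width * in_ch, init_mode)
        self.W = rng.normal(0.0, std, size=(width, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.width = width

    def forward(self, x):
        # x: (B, L, Cin) -> (B, L-width+1, Cout)
        self._win = sliding_window_view(x, self.width, axis=1)  # (B, Lo, Cin, w)
        return np.einsum("blcw,wco->blo", self._win, self.W) + self.b

    def backward(self, dy):
        self.dW = np.einsum("blcw,blo->wco", self._win, dy)
        self.db = dy.sum(axis=(0, 1))
        B, Lo, _ = dy.shape
        Lin = Lo + self.width - 1
        dx = np.zeros((B, Lin, self.W.shape[1]))
        for k in range(self.width):
            dx[:, k: k + Lo, :] += np.einsum("blo,co->blc", dy, self.W[k])
        return dx

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _Dense:
    def __init__(self, n_in, n_out, rng, init_mode):
        self.W = rng.normal(0.0, init_std(n_in, init_mode), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _ReLU:
    params, grads = [], []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class _MaxPool1D:
    """Width-2, stride-2 max pooling (odd trailing element dropped)."""

    params, grads = [], []

    def forward(self, x):
        B, L, C = x.shape
        Lo = L // 2
        self._Lin = L
        xr = x[:, : 2 * Lo].reshape(B, Lo, 2, C)
        self._arg = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, dy):
        B, Lo, C = dy.shape
        dx = np.zeros((B, self._Lin, C))
        b, l, c = np.meshgrid(np.arange(B), np.arange(Lo), np.arange(C),
                              indexing="ij")
        dx[b, 2 * l + self._arg, c] = dy
        return dx


class _Flatten:
    params, grads = [], []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


@dataclass
class ArchitectureConfig:
    """Tunable architecture knobs; defaults match the printed design."""

    context: int = DEFAULT_CONTEXT
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    conv_widths: tuple[int, int, int] = (5, 3, 3)
    hidden: int = 64
    init_mode: str = "5/N"
    seed: int = 0


class TorsionNet:
    """The windowed-feature -> sin/cos torsion CNN."""

    def __init__(self, spec: ArchitectureConfig | None = None):
        self.spec = spec or ArchitectureConfig()
        s = self.spec
        rng = np.random.default_rng(s.seed)
        rows = 2 * s.context + 1
        c1, c2, c3 = s.conv_channels
        w1, w2, w3 = s.conv_widths
        self.layers = [
            _Conv1D(N_FEATURES, c1, w1, rng, s.init_mode), _ReLU(),
            _MaxPool1D(),
            _Conv1D(c1, c2, w2, rng, s.init_mode), _ReLU(),
            _MaxPool1D(),
            _Conv1D(c2, c3, w3, rng, s.init_mode), _ReLU(),
            _Flatten(),
        ]
        L = rows
        L = (L - w1 + 1) // 2
        L = (L - w2 + 1) // 2
        L = L - w3 + 1
        if L < 1:
            raise ValueError("window too small for the convolution stack")
        self.layers += [
            _Dense(L * c3, s.hidden, rng, s.init_mode), _ReLU(),
            _Dense(s.hidden, 4, rng, s.init_mode),
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, rows, 24) windows -> (B, 4) raw sin/cos outputs."""
        single = x.ndim == 2
        if single:
            x = x[None]
        for layer in self.layers:
            x = layer.forward(x)
        return x[0] if single else x

    def backward(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def parameters(self):
        return [p for layer in self.layers for p in layer.params]

    def gradients(self):
        return [g for layer in self.layers for g in layer.grads]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def save(self, path) -> None:
        np.savez(path, *(p for p in self.parameters()))

    def load(self, path) -> None:
        data = np.load(path)
        for p, key in zip(self.parameters(), data.files):
            p[...] = data[key]


def build_model(spec: ArchitectureConfig | None = None) -> TorsionNet:
    return TorsionNet(spec)


# ---------------------------------------------------------------------------
# Training and evaluation


@dataclass
class Hyperparams:
    lr: float = 1e-3
    epochs: int = 200
    batch_size: int | None = None  # None = full batch
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def train(
    model: TorsionNet,
    windows: np.ndarray,
    phi: np.ndarray,
    psi: np.ndarray,
    hyper: Hyperparams | None = None,
    seed: int = 0,
) -> list[float]:
    """Train on MSE over the sin/cos targets with Adam; returns per-epoch loss.

    Deterministic for a fixed seed (seeded minibatch shuffling); zero epochs
    leave the model untouched.  Full-batch training is invariant under
    duplication of the dataset.
    """
    if windows.shape[0] == 0:
        raise ValueError("empty training set")
    hyper = hyper or Hyperparams()
    targets = encode_angles(phi, psi)
    rng = np.random.default_rng(seed)
    params = model.parameters()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    n = windows.shape[0]
    bs = hyper.batch_size or n
    losses = []
    for _ in range(hyper.epochs):
        order = rng.permutation(n) if bs < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start: start + bs]
            out = model.forward(windows[idx])
            diff = out - targets[idx]
            loss = float((diff**2).mean())
            if not np.isfinite(loss):
                raise TrainingDivergence("loss became non-finite")
            epoch_loss += loss * idx.size
            model.backward(2.0 * diff / diff.size)
            t += 1
            for k, p in enumerate(params):
                g = model.gradients()[k]
                m[k] = hyper.beta1 * m[k] + (1 - hyper.beta1) * g
                v[k] = hyper.beta2 * v[k] + (1 - hyper.beta2) * g * g
                mh = m[k] / (1 - hyper.beta1**t)
                vh = v[k] / (1 - hyper.beta2**t)
                p -= hyper.lr * mh / (np.sqrt(vh) + hyper.eps)
        losses.append(epoch_loss / n)
    return losses


def predict(model: TorsionNet, features: FeatureTable,
            w: int | None = None) -> TorsionPrediction:
    """Per-residue torsion prediction for a whole chain."""
    w = w if w is not None else model.spec.context
    raw = model.forward(build_all_windows(features, w))
    phi, psi = decode_angles(raw)
    return TorsionPrediction(phi=np.asarray(phi), psi=np.asarray(psi), raw=raw)


def mae(pred, exp, periodic: bool = True) -> float:
    """Mean absolute error between predicted and experimental angles (degrees).

    With ``periodic=True`` (default) differences are measured on the circle
    (so 170 vs -170 differ by 20); with ``periodic=False`` the raw absolute
    difference is used.  Terminal residues are the caller's responsibility
    to exclude.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape:
        raise ValueError("length mismatch")
    if pred.size == 0:
        raise ValueError("MAE of an empty set is undefined")
    if periodic:
        return float(np.abs(circular_difference(pred, exp)).mean())
    return float(np.abs(pred - exp).mean())
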