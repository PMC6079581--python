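"""Feature-fusion network: six similarity scores -> one evidence score.

The network is deliberately *not* fully connected.  Its first hidden layer
has one sigmoid node per non-empty subset of the six input features —
C(6,1) + ... + C(6,6) = 63 nodes — and each subset node receives edges only
from the features in its subset.  The second hidden layer has six sigmoid
nodes, one per subset cardinality; node i receives edges only from the
C(6,i) first-layer nodes whose subsets have exactly i members.  The output
is a linear combination S = sum_k lambda_k * beta_k - theta of the six
second-layer activations.  Thresholds: 63 + 6 + 1 = 70 in total.

This structure lets the network weight every feature *combination*
explicitly (a learned feature-subset selection) while keeping only a few
hundred parameters, trainable by plain backpropagation on mean squared
error.  Gradients of absent edges are identically zero by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, ValidationError

__all__ = [
    "SUBSETS",
    "FeatureVector",
    "LabeledScorePair",
    "FusionNetwork",
    "build_network",
    "forward",
    "train",
    "evaluate_accuracy",
    "save_network",
    "load_network",
    "read_dataset_tsv",
    "write_dataset_tsv",
]

N_FEATURES = 6

#: canonical order of the 63 subset nodes: by cardinality, then lexicographic
SUBSETS: tuple[tuple[int, ...], ...] = tuple(
    combo
    for k in range(1, N_FEATURES + 1)
    for combo in itertools.combinations(range(1, N_FEATURES + 1), k)
)

#: (63, 6) connectivity of the subset layer (1-based feature j -> column j-1)
H1_MASK = np.zeros((len(SUBSETS), N_FEATURES))
for _row, _subset in enumerate(SUBSETS):
    for _j in _subset:
        H1_MASK[_row, _j - 1] = 1.0

#: (6, 63) connectivity of the group layer: group i sees cardinality-i nodes
H2_MASK = np.zeros((N_FEATURES, len(SUBSETS)))
for _col, _subset in enumerate(SUBSETS):
    H2_MASK[len(_subset) - 1, _col] = 1.0


@dataclass(frozen=True)
class FeatureVector:
    """The six per-feature scores for one (Q, P) pair, each in [0, 1].

    Order is fixed: frequency, word order, TF-IDF, syntax, structure,
    semantics.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p1, self.p2, self.p3, self.p4, self.p5, self.p6])

    @classmethod
    def from_array(cls, arr) -> "FeatureVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_FEATURES,):
            raise ValidationError(f"feature vector must have 6 entries, got {arr.shape}")
        return cls(*map(float, arr))


@dataclass(frozen=True)
class LabeledScorePair:
    features: FeatureVector
    label: float

    def __post_init__(self):
        if not (0.0 <= self.label <= 1.0):
            raise ValidationError(f"label {self.label} outside [0, 1]")


@dataclass
class FusionNetwork:
    """Weights and thresholds of the subset layer, group layer and combiner.

    ``w1``/``w2`` are stored dense but masked: entries outside the
    connectivity pattern are exactly zero and stay zero through training.
    """

    w1: np.ndarray          # (63, 6), masked by H1_MASK
    theta1: np.ndarray      # (63,)
    w2: np.ndarray          # (6, 63), masked by H2_MASK
    theta2: np.ndarray      # (6,)
    lam: np.ndarray         # (6,)
    theta_out: float

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=float) * H1_MASK
        self.w2 = np.asarray(self.w2, dtype=float) * H2_MASK
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.theta2 = np.asarray(self.theta2, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.w1.shape != (63, 6) or self.w2.shape != (6, 63):
            raise ValidationError("fusion network has wrong layer shapes")
        if self.theta1.shape != (63,) or self.theta2.shape != (6,):
            raise ValidationError("fusion network has wrong threshold shapes")

    @property
    def n_thresholds(self) -> int:
        return self.theta1.size + self.theta2.size + 1

    def copy(self) -> "FusionNetwork":
        return FusionNetwork(self.w1.copy(), self.theta1.copy(),
                             self.w2.copy(), self.theta2.copy(),
                             self.lam.copy(), float(self.theta_out))


def build_network(seed: int = 0) -> FusionNetwork:
    """Fresh network: masked weights uniform in [-0.5, 0.5], thresholds 0."""
    rng = np.random.default_rng(seed)
    w1 = (rng.random((63, 6)) - 0.5) * H1_MASK
    w2 = (rng.random((6, 63)) - 0.5) * H2_MASK
    lam = rng.random(6) - 0.5
    return FusionNetwork(w1, np.zeros(63), w2, np.zeros(6), lam, 0.0)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _forward_batch(net: FusionNetwork, P: np.ndarray):
    """All-layer activations for a (N, 6) feature batch."""
    a1 = _sigmoid(P @ net.w1.T - net.theta1)          # (N, 63)
    a2 = _sigmoid(a1 @ net.w2.T - net.theta2)         # (N, 6)
    s = a2 @ net.lam - net.theta_out                  # (N,)
    return a1, a2, s


def forward(net: FusionNetwork, fv: FeatureVector) -> float:
    """Evidence score S for one feature vector.

    Subset nodes and group nodes are sigmoid units (activation minus
    threshold); the output is linear: S = sum_k lambda_k beta_k - theta.
    """
    p = fv.as_array()
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValidationError(f"feature values outside [0, 1]: {p}")
    _, _, s = _forward_batch(net, p[None, :])
    return float(s[0])


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, tuple) and len(data) == 2:
        P, y = np.asarray(data[0], dtype=float), np.asarray(data[1], dtype=float)
    else:
        P = np.array([d.features.as_array() for d in data], dtype=float)
        y = np.array([d.label for d in data], dtype=float)
    if P.size == 0:
        raise DataError("empty training data")
    return P, y


def gradients(net: FusionNetwork, P: np.ndarray, y: np.ndarray):
    """Analytic MSE gradients, masked to the connectivity pattern."""
    N = len(y)
    a1, a2, s = _forward_batch(net, P)
    ds = 2.0 * (s - y) / N                          # dL/ds
    d_lam = a2.T @ ds
    d_theta_out = -ds.sum()
    da2 = np.outer(ds, net.lam)
    dz2 = da2 * a2 * (1.0 - a2)
    d_w2 = (dz2.T @ a1) * H2_MASK
    d_theta2 = -dz2.sum(axis=0)
    da1 = dz2 @ net.w2
    dz1 = da1 * a1 * (1.0 - a1)
    d_w1 = (dz1.T @ P) * H1_MASK
    d_theta1 = -dz1.sum(axis=0)
    return d_w1, d_theta1, d_w2, d_theta2, d_lam, d_theta_out


def mse(net: FusionNetwork, data) -> float:
    P, y = _as_arrays(data)
    _, _, s = _forward_batch(net, P)
    return float(np.mean((s - y) ** 2))


def train(net: FusionNetwork, data, lr: float = 0.5, epochs: int = 200,
          seed: int = 0, batch_size: int | None = None,
          momentum: float = 0.0) -> FusionNetwork:
    """Backpropagation on mean squared error; returns a trained copy.

    Full-batch gradient descent by default (``batch_size=None``); minibatch
    mode shuffles with the given seed each epoch.  The connectivity mask is
    re-applied to every update, so absent edges never acquire weight.
    """
    if lr <= 0:
        raise ValueError("learning rate must be positive")
    P, y = _as_arrays(data)
    out = net.copy()
    rng = np.random.default_rng(seed)
    vel = [np.zeros_like(out.w1), np.zeros_like(out.theta1),
           np.zeros_like(out.w2), np.zeros_like(out.theta2),
           np.zeros_like(out.lam), 0.0]
    for _ in range(epochs):
        if batch_size is None:
            batches = [(P, y)]
        else:
            order = rng.permutation(len(y))
            batches = [(P[order[i:i + batch_size]], y[order[i:i + batch_size]])
                       for i in range(0, len(y), batch_size)]
        for Pb, yb in batches:
            grads = gradients(out, Pb, yb)
            for k in range(6):
                vel[k] = momentum * vel[k] - lr * grads[k]
            out.w1 += vel[0]
            out.theta1 += vel[1]
            out.w2 += vel[2]
            out.theta2 += vel[3]
            out.lam += vel[4]
            vel5 = vel[5]
            out.theta_out = float(out.theta_out + vel5)
    return out


def predict(net: FusionNetwork, data) -> np.ndarray:
    P, _ = _as_arrays(data)
    _, _, s = _forward_batch(net, P)
    return s


def evaluate_accuracy(net: FusionNetwork, data, tolerance: float = 0.1) -> float:
    """Fraction of pairs whose prediction is within ``tolerance`` of the label."""
    P, y = _as_arrays(data)
    _, _, s = _forward_batch(net, P)
    return float(np.mean(np.abs(s - y) <= tolerance))


# --------------------------------------------------------------------------
# serialisation

_FORMAT_VERSION = 1


def save_network(net: FusionNetwork, path) -> None:
    """Write a network as structured text: subset masks, weights, thresholds."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"evscore-fusion format_version {_FORMAT_VERSION}\n")
        for row, subset in enumerate(SUBSETS):
            members = ",".join(map(str, subset))
            weights = " ".join(repr(float(net.w1[row, j - 1])) for j in subset)
            fh.write(f"h1 {members} {weights} theta {float(net.theta1[row])!r}\n")
        for i in range(6):
            cols = [c for c, s in enumerate(SUBSETS) if len(s) == i + 1]
            weights = " ".join(repr(float(net.w2[i, c])) for c in cols)
            fh.write(f"h2 {i + 1} {weights} theta {float(net.theta2[i])!r}\n")
        lam = " ".join(repr(float(x)) for x in net.lam)
        fh.write(f"output {lam} theta {float(net.theta_out)!r}\n")


def load_network(path) -> FusionNetwork:
    w1 = np.zeros((63, 6))
    theta1 = np.zeros(63)
    w2 = np.zeros((6, 63))
    theta2 = np.zeros(6)
    lam = np.zeros(6)
    theta_out = 0.0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        if header[:2] != ["evscore-fusion", "format_version"]:
            raise ParseError(f"{path}: not a fusion network file")
        if int(header[2]) != _FORMAT_VERSION:
            raise ParseError(f"{path}: unsupported format version {header[2]}")
        h1_row = 0
        for line_no, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "h1":
                subset = tuple(int(x) for x in parts[1].split(","))
                if subset != SUBSETS[h1_row]:
                    raise ParseError(
                        f"{path} line {line_no}: subset {subset} out of "
                        f"canonical order")
                vals = [float(x) for x in parts[2:2 + len(subset)]]
                for j, v in zip(subset, vals):
                    w1[h1_row, j - 1] = v
                theta1[h1_row] = float(parts[-1])
                h1_row += 1
            elif parts[0] == "h2":
                i = int(parts[1]) - 1
                cols = [c for c, s in enumerate(SUBSETS) if len(s) == i + 1]
                vals = [float(x) for x in parts[2:2 + len(cols)]]
                for c, v in zip(cols, vals):
                    w2[i, c] = v
                theta2[i] = float(parts[-1])
            elif parts[0] == "output":
                lam = np.array([float(x) for x in parts[1:7]])
                theta_out = float(parts[-1])
            else:
                raise ParseError(f"{path} line {line_no}: unknown record {parts[0]!r}")
    if h1_row != 63:
        raise ParseError(f"{path}: expected 63 h1 records, found {h1_row}")
    return FusionNetwork(w1, theta1, w2, theta2, lam, theta_out)


# --------------------------------------------------------------------------
# labeled dataset TSV

_COLUMNS = ["p1", "p2", "p3", "p4", "p5", "p6", "label"]


def write_dataset_tsv(data, path) -> None:
    P, y = _as_arrays(data)
    df = pd.DataFrame(np.column_stack([P, y]), columns=_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_dataset_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _COLUMNS:
        raise ParseError(f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}")
    arr = df.to_numpy(dtype=float)
    return arr[:, :6], arr[:, 6]
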