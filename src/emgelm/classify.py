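"""Extreme learning machines with RBF hidden nodes, plus reliability rejection.

An ELM is a single-hidden-layer feedforward network whose input weights and
biases are random and fixed; only the linear output layer is solved, through
the Moore-Penrose pseudoinverse of the hidden-activation matrix H (plain ELM)
or its Tikhonov-regularized ridge counterpart (RELM, regularization factor
C_reg).  Hidden node j maps a standardized feature vector x to
phi(w_j . x + b_j) with phi(z) = exp(-z^2); weights are drawn uniformly in
[-1, 1] and biases in [-1.5, 1.5].

The "reliable" variants (R-ELM / R-RELM) abstain on windows whose maximum
raw network output r falls below th = mean(r) - sd(r) computed over the
evaluated block: low class separation at movement transitions produces low
maxima, and those windows are disproportionately misclassified, so rejecting
them trades a small data discard for a cleaner label stream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .features import FeatureTable

logger = logging.getLogger("emgelm")

#: Label emitted for windows a reliable classifier abstains on.
ABSTAIN = -1

_SD_FLOOR = 1e-12
_WEIGHT_RANGE = (-1.0, 1.0)
_BIAS_RANGE = (-1.5, 1.5)

MODEL_SCHEMA_VERSION = 1


@dataclass
class ElmModel:
    """Trained (R)ELM: random hidden layer + solved output weights.

    ``W`` is L x d, ``b`` length L, ``beta`` L x C; ``C_reg`` is ``None``
    for the plain pseudoinverse solution.  ``feat_mean``/``feat_sd`` are the
    training-set standardization statistics applied before the kernel.
    """

    W: np.ndarray
    b: np.ndarray
    beta: np.ndarray
    classes: np.ndarray
    feat_mean: np.ndarray
    feat_sd: np.ndarray
    L: int
    seed: int
    C_reg: float | None = None

    @property
    def n_features(self) -> int:
        return self.W.shape[1]


@dataclass
class ReliabilityProfile:
    """Max-output stream and the derived abstention threshold th = mu - sigma."""

    r: np.ndarray
    mu: float
    sigma: float
    th: float
    mask: np.ndarray  # True = retained

    @property
    def discard_rate(self) -> float:
        """Fraction of windows rejected as non-reliable, in [0, 1]."""
        return float(np.mean(~self.mask))


def _hidden_layer(L: int, d: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    # single generator; W drawn before b, row-major — the documented order
    rng = np.random.default_rng(seed)
    W = rng.uniform(*_WEIGHT_RANGE, size=(L, d))
    b = rng.uniform(*_BIAS_RANGE, size=L)
    return W, b


def _activations(X: np.ndarray, model_or_Wb, feat_mean, feat_sd) -> np.ndarray:
    W, b = model_or_Wb
    Z = (X - feat_mean) / feat_sd
    return np.exp(-np.square(Z @ W.T + b))


def _prepare(table: FeatureTable, L: int):
    if L < 1:
        raise ValueError("L must be >= 1")
    classes = np.unique(table.y)
    if classes.size < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = table.X
    feat_mean = X.mean(axis=0)
    feat_sd = np.maximum(X.std(axis=0), _SD_FLOOR)
    T = (table.y[:, None] == classes[None, :]).astype(float)  # one-hot {0,1}
    return classes, feat_mean, feat_sd, T


def train_elm(table: FeatureTable, L: int, seed: int = 0) -> ElmModel:
    """Train a plain ELM: beta is the minimum-norm least-squares solution
    of H beta = T, computed via the Moore-Penrose pseudoinverse."""
    classes, feat_mean, feat_sd, T = _prepare(table, L)
    W, b = _hidden_layer(L, table.X.shape[1], seed)
    H = _activations(table.X, (W, b), feat_mean, feat_sd)
    beta, *_ = linalg.lstsq(H, T, lapack_driver="gelsd")
    return ElmModel(W=W, b=b, beta=beta, classes=classes, feat_mean=feat_mean,
                    feat_sd=feat_sd, L=L, seed=seed, C_reg=None)


def train_relm(table: FeatureTable, L: int, C_reg: float = 1.0, seed: int = 0) -> ElmModel:
    """Train a regularized ELM (ridge output layer).

    Solves beta = (H'H + I/C_reg)^-1 H'T when L <= N, or the algebraically
    equivalent dual form beta = H'(HH' + I/C_reg)^-1 T when L > N.  Larger
    C_reg means weaker regularization; beta approaches the plain ELM solution
    as C_reg -> infinity on well-conditioned problems.
    """
    if C_reg is None or C_reg <= 0:
        raise ValueError("C_reg must be positive")
    classes, feat_mean, feat_sd, T = _prepare(table, L)
    W, b = _hidden_layer(L, table.X.shape[1], seed)
    H = _activations(table.X, (W, b), feat_mean, feat_sd)
    N = H.shape[0]
    ridge = np.eye(min(L, N)) / C_reg
    if L <= N:
        beta = linalg.solve(H.T @ H + ridge, H.T @ T, assume_a="pos")
    else:
        beta = H.T @ linalg.solve(H @ H.T + ridge, T, assume_a="pos")
    return ElmModel(W=W, b=b, beta=beta, classes=classes, feat_mean=feat_mean,
                    feat_sd=feat_sd, L=L, seed=seed, C_reg=float(C_reg))


def predict(model: ElmModel, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Network outputs and argmax labels for every window.

    Ties at the maximum break to the lowest class id.
    """
    if table.X.shape[1] != model.n_features:
        raise ValueError(
            f"table has {table.X.shape[1]} features, model expects {model.n_features}"
        )
    H = _activations(table.X, (model.W, model.b), model.feat_mean, model.feat_sd)
    outputs = H @ model.beta
    # classes are sorted ascending and argmax returns the first maximum,
    # so ties resolve to the lowest class id
    labels = model.classes[np.argmax(outputs, axis=1)]
    return outputs, labels


def reliability_threshold(outputs: np.ndarray) -> ReliabilityProfile:
    """Compute the reliability statistic r_i = max_c outputs[i, c] and the
    abstention threshold th = mean(r) - sd(r) (population SD)."""
    outputs = np.atleast_2d(np.asarray(outputs, dtype=float))
    if outputs.shape[0] == 0:
        raise ValueError("empty outputs")
    if outputs.shape[0] < 2:
        raise ValueError("need at least 2 rows to form a reliability threshold")
    r = outputs.max(axis=1)
    mu = float(r.mean())
    sigma = float(r.std())
    th = mu - sigma
    return ReliabilityProfile(r=r, mu=mu, sigma=sigma, th=th, mask=r >= th)


def reliable_predict(
    model: ElmModel, table: FeatureTable
) -> tuple[np.ndarray, ReliabilityProfile]:
    """Predict with abstention: windows whose max output falls below the
    block's reliability threshold receive :data:`ABSTAIN` instead of a class."""
    outputs, labels = predict(model, table)
    profile = reliability_threshold(outputs)
    labels = np.where(profile.mask, labels, ABSTAIN)
    return labels, profile


def select_hidden_neurons(
    train_table: FeatureTable,
    val_table: FeatureTable,
    grid=tuple(range(50, 1001, 50)),
    variant: str = "elm",
    C_reg: float | None = None,
    seed: int = 0,
):
    """Sweep the hidden-neuron count and pick the validation-accuracy argmax.

    Returns ``(best_L, curve)`` where ``curve`` is a list of
    ``(L, accuracy_percent)`` pairs; ties break to the smallest L.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    if any(L < 1 for L in grid):
        raise ValueError("grid must contain positive hidden-neuron counts")
    if variant not in ("elm", "relm"):
        raise ValueError(f"unknown variant {variant!r}")
    curve = []
    for L in grid:
        if variant == "elm":
            model = train_elm(train_table, L, seed=seed)
        else:
            model = train_relm(train_table, L, C_reg=1.0 if C_reg is None else C_reg,
                               seed=seed)
        _, labels = predict(model, val_table)
        acc = float(np.mean(labels == val_table.y) * 100.0)
        curve.append((L, acc))
    best_L = max(curve, key=lambda la: (la[1], -la[0]))[0]
    return best_L, curve


def save_model(model: ElmModel, path) -> None:
    """Serialize a model to a single .npz archive (versioned schema)."""
    meta = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "L": int(model.L),
        "seed": int(model.seed),
        "C_reg": model.C_reg,
    }
    np.savez(
        path,
        W=model.W, b=model.b, beta=model.beta, classes=model.classes,
        feat_mean=model.feat_mean, feat_sd=model.feat_sd,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path) -> ElmModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {meta.get('schema_version')}")
        return ElmModel(
            W=z["W"], b=z["b"], beta=z["beta"], classes=z["classes"],
            feat_mean=z["feat_mean"], feat_sd=z["feat_sd"],
            L=meta["L"], seed=meta["seed"], C_reg=meta["C_reg"],
        )
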