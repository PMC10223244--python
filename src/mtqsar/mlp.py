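"""Minimal two-layer perceptron with the four classical hidden activations.

Architecture is the bottleneck perceptron ``MLP k-m-2``: ``k`` inputs (one
per target site), ``m`` hidden units, two softmax outputs trained with
cross-entropy.  Hidden activations: identity, logistic, tanh, exponential
(``e^x`` with input clamping for stability).  Training is full-batch Adam
with early stopping monitored on the variant's test subset; inputs are
standardized with statistics computed on the training subset only.

Weights are plain numpy arrays so a trained network round-trips losslessly
through the JSON model container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ACTIVATIONS = ("identity", "logistic", "tanh", "exponential")

_EXP_CLAMP = 30.0


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "identity":
        return z
    if name == "logistic":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)))
    if name == "tanh":
        return np.tanh(z)
    if name == "exponential":
        return np.exp(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, h: np.ndarray) -> np.ndarray:
    # expressed through the forward value h
    if name == "identity":
        return np.ones_like(h)
    if name == "logistic":
        return h * (1.0 - h)
    if name == "tanh":
        return 1.0 - h * h
    if name == "exponential":
        return h
    raise ValueError(f"unknown activation {name!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(p: np.ndarray, y: np.ndarray) -> float:
    """Mean negative log-likelihood of binary targets under 2-class softmax."""
    eps = 1e-12
    return float(-np.mean(np.log(p[np.arange(len(y)), y] + eps)))


@dataclass(frozen=True)
class NetworkSpec:
    """Static architecture of one candidate network."""

    n_inputs: int = 17
    n_hidden: int = 8
    hidden_activation: str = "tanh"
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if self.hidden_activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")
        if self.n_outputs != 2:
            raise ValueError("binary gradations require exactly 2 output neurons")
        if self.n_hidden < 1:
            raise ValueError("need at least one hidden unit")

    @property
    def architecture(self) -> str:
        """Human-readable label, e.g. ``MLP 17-16-2 Tanh Softmax``."""
        return (
            f"MLP {self.n_inputs}-{self.n_hidden}-{self.n_outputs} "
            f"{self.hidden_activation.capitalize()} Softmax"
        )


@dataclass
class TrainedNetwork:
    """A fitted ``MLP k-m-2`` plus its standardization and subset accuracies."""

    spec: NetworkSpec
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    mean: np.ndarray  # per-input mean of the training subset
    sd: np.ndarray  # per-input sd of the training subset (zeros replaced by 1)
    level: str = "h"
    variant: int = 0
    acc_train: float = float("nan")
    acc_test: float = float("nan")
    acc_val: float = float("nan")
    seed: int = 0

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax outputs for raw (unstandardized) inputs, shape (n, 2)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = _act(self.spec.hidden_activation, self.standardize(x) @ self.w1 + self.b1)
        return softmax(h @ self.w2 + self.b2)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Binary votes: argmax of the two softmax outputs (class 1 = positive)."""
        return np.argmax(self.predict_proba(x), axis=1)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        return cross_entropy(self.predict_proba(x), np.asarray(y, dtype=int))

    def to_dict(self) -> dict:
        return {
            "spec": {
                "n_inputs": self.spec.n_inputs,
                "n_hidden": self.spec.n_hidden,
                "hidden_activation": self.spec.hidden_activation,
                "n_outputs": self.spec.n_outputs,
            },
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "level": self.level,
            "variant": self.variant,
            "acc_train": self.acc_train,
            "acc_test": self.acc_test,
            "acc_val": self.acc_val,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNetwork":
        return cls(
            spec=NetworkSpec(**d["spec"]),
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=np.asarray(d["b2"], dtype=float),
            mean=np.asarray(d["mean"], dtype=float),
            sd=np.asarray(d["sd"], dtype=float),
            level=d["level"],
            variant=int(d["variant"]),
            acc_train=float(d["acc_train"]),
            acc_test=float(d["acc_test"]),
            acc_val=float(d["acc_val"]),
            seed=int(d["seed"]),
        )


def fit_mlp(
    x_train: np.ndarray,
    y_train: np.ndarray,
    spec: NetworkSpec,
    seed: int,
    x_stop: np.ndarray | None = None,
    y_stop: np.ndarray | None = None,
    max_epochs: int = 400,
    learning_rate: float = 0.02,
    patience: int = 40,
    alpha: float = 0.1,
) -> TrainedNetwork:
    """Train one network by full-batch Adam with early stopping.

    ``x_train`` is raw (unstandardized); standardization statistics are
    computed here, from the training rows only, and stored on the returned
    network.  ``(x_stop, y_stop)`` is the hold-out monitored for early
    stopping (the test subset of the sampling variant); when absent the
    training loss is monitored instead.  ``alpha`` is the L2 penalty on the
    weight matrices (not biases); it also evens out the credit assigned to
    correlated inputs, which matters for downstream sensitivity analysis.
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    mean = x_train.mean(axis=0)
    sd = x_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    xs = (x_train - mean) / sd

    rng = np.random.default_rng(seed)
    k, m = spec.n_inputs, spec.n_hidden
    lim1 = np.sqrt(6.0 / (k + m))
    lim2 = np.sqrt(6.0 / (m + 2))
    params = [
        rng.uniform(-lim1, lim1, size=(k, m)),
        np.zeros(m),
        rng.uniform(-lim2, lim2, size=(m, 2)),
        np.zeros(2),
    ]

    if x_stop is not None and len(x_stop) > 0:
        xs_stop = (np.asarray(x_stop, dtype=float) - mean) / sd
        y_stop = np.asarray(y_stop, dtype=int)
    else:
        xs_stop, y_stop = xs, y_train

    onehot = np.zeros((len(y_train), 2))
    onehot[np.arange(len(y_train)), y_train] = 1.0

    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def forward(p, xin):
        h = _act(spec.hidden_activation, xin @ p[0] + p[1])
        return h, softmax(h @ p[2] + p[3])

    def stop_loss(p) -> float:
        _, prob = forward(p, xs_stop)
        return cross_entropy(prob, y_stop)

    best = [p.copy() for p in params]
    best_loss = stop_loss(params)
    stale = 0
    n = len(xs)
    for t in range(1, max_epochs + 1):
        h, prob = forward(params, xs)
        dz2 = (prob - onehot) / n
        g2 = h.T @ dz2
        gb2 = dz2.sum(axis=0)
        dh = dz2 @ params[2].T
        dz1 = dh * _act_grad(spec.hidden_activation, h)
        g1 = xs.T @ dz1
        gb1 = dz1.sum(axis=0)
        grads = [g1 + alpha * params[0], gb1, g2 + alpha * params[2], gb2]
        for i, g in enumerate(grads):
            adam_m[i] = beta1 * adam_m[i] + (1 - beta1) * g
            adam_v[i] = beta2 * adam_v[i] + (1 - beta2) * g * g
            mhat = adam_m[i] / (1 - beta1**t)
            vhat = adam_v[i] / (1 - beta2**t)
            params[i] = params[i] - learning_rate * mhat / (np.sqrt(vhat) + eps)
        cur = stop_loss(params)
        if cur < best_loss - 1e-7:
            best_loss = cur
            best = [p.copy() for p in params]
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    return TrainedNetwork(
        spec=spec, w1=best[0], b1=best[1], w2=best[2], b2=best[3],
        mean=mean, sd=sd, seed=seed,
    )
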