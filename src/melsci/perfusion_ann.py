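"""The 7→25→3 inverse network and its error metrics.

A single-hidden-layer fully connected network (25 tanh units, linear
output) maps squared multi-exposure contrast K²(T) at the seven exposures
to speed-resolved perfusion in the bands 0–1, 1–10 and >10 mm/s.  Training
minimizes a weighted mean square error in which each sample's squared
errors are normalized by that sample's *total* true perfusion,

    wMSE(j) = (1/N) Σ_i (P_pred,j,i − P_true,j,i)² / P_true,tot,i,

so that a small speed component of a low-perfusion sample is not allowed to
dominate the loss; evaluation uses the analogous weighted MAPE.  Several
networks are trained from random initializations with validation-based
early stopping, and the restart with the lowest test-split wMSE is kept.

The implementation is pure numpy (Adam); the network is small enough that
minibatch updates are sub-millisecond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .config import AnnConfig

__all__ = [
    "Dataset",
    "AnnModel",
    "wmse_loss",
    "wmse_components",
    "wmape",
    "mape",
    "r_squared",
    "train_ann",
    "predict",
    "evaluate_model",
    "activation_suite",
    "tanh",
    "relu",
    "satlu",
    "softplus",
]

EPS_TOTAL = 1e-6  # floor for P_true,tot in the weighted metrics, %RBC·mm/s


# --------------------------------------------------------------------------
# Activations (the architecture-search candidates)


def tanh(x):
    """tanh(x) = (e^{2x} − 1)/(e^{2x} + 1)."""
    return np.tanh(x)


def relu(x):
    return np.maximum(0.0, np.asarray(x, dtype=float))


def satlu(x):
    """Saturated linear unit: min(1, max(0, x))."""
    return np.minimum(1.0, np.maximum(0.0, np.asarray(x, dtype=float)))


def softplus(x):
    """log(1 + e^x), evaluated stably."""
    return np.logaddexp(0.0, np.asarray(x, dtype=float))


def activation_suite(x) -> dict:
    return {"tanh": tanh(x), "relu": relu(x), "satlu": satlu(x),
            "softplus": softplus(x)}


# --------------------------------------------------------------------------
# Metrics


def _check_pair(pred, true) -> tuple[np.ndarray, np.ndarray]:
    p = np.atleast_2d(np.asarray(pred, dtype=float))
    t = np.atleast_2d(np.asarray(true, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    return p, t


def wmse_components(pred, true, eps: float = EPS_TOTAL) -> np.ndarray:
    """Per-component weighted MSE: mean_i (e_ij)² / P_true,tot,i."""
    p, t = _check_pair(pred, true)
    tot = np.maximum(t.sum(axis=1, keepdims=True), eps)
    return np.mean((p - t) ** 2 / tot, axis=0)


def wmse_loss(pred, true, eps: float = EPS_TOTAL) -> float:
    """Scalar training loss: the mean of the per-component weighted MSEs."""
    return float(wmse_components(pred, true, eps).mean())


def wmape(pred, true, eps: float = EPS_TOTAL) -> np.ndarray:
    """Weighted mean absolute percentage error per speed component, %."""
    p, t = _check_pair(pred, true)
    tot = np.maximum(t.sum(axis=1, keepdims=True), eps)
    return 100.0 * np.mean(np.abs(p - t) / tot, axis=0)


def mape(pred, true, eps: float = EPS_TOTAL) -> float:
    """Unweighted mean absolute percentage error, % (totals, P_SE)."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred/true must be equal-length nonempty vectors")
    return float(100.0 * np.mean(np.abs(p - t) / np.maximum(t, eps)))


def r_squared(pred, true) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.shape != t.shape or p.size == 0:
        raise ValueError("pred/true must be equal-length nonempty vectors")
    ss_tot = np.sum((t - t.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant true values")
    return float(1.0 - np.sum((p - t) ** 2) / ss_tot)


# --------------------------------------------------------------------------
# Dataset


@dataclass
class Dataset:
    """Inputs K² (N, 7) and targets P_true (N, 3) with 70/15/15 splits."""

    X: np.ndarray
    Y: np.ndarray
    idx_train: np.ndarray
    idx_val: np.ndarray
    idx_test: np.ndarray
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, X, Y, rng: np.random.Generator,
                    fractions=(0.70, 0.15, 0.15), provenance=None) -> "Dataset":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share the sample axis")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        n = X.shape[0]
        perm = rng.permutation(n)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        return cls(X, Y, perm[:n_tr], perm[n_tr:n_tr + n_va],
                   perm[n_tr + n_va:], provenance or {})

    def split(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = {"train": self.idx_train, "val": self.idx_val,
               "test": self.idx_test}[which]
        return self.X[idx], self.Y[idx]


# --------------------------------------------------------------------------
# Model


@dataclass
class AnnModel:
    """Weights and input scaling of one trained 7-25-3 network."""

    W1: np.ndarray  # (7, n_hidden)
    b1: np.ndarray
    W2: np.ndarray  # (n_hidden, 3)
    b2: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    meta: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        return predict(self, X)

    def save_json(self, path) -> None:
        obj = {"format_version": 1,
               "architecture": [self.W1.shape[0], self.W1.shape[1],
                                self.W2.shape[1]],
               "activation": "tanh",
               "W1": self.W1.tolist(), "b1": self.b1.tolist(),
               "W2": self.W2.tolist(), "b2": self.b2.tolist(),
               "x_mean": self.x_mean.tolist(), "x_std": self.x_std.tolist(),
               "meta": self.meta}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def load_json(cls, path) -> "AnnModel":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(*(np.asarray(obj[k], dtype=float) for k in
                     ("W1", "b1", "W2", "b2", "x_mean", "x_std")),
                   meta=obj.get("meta", {}))


def predict(model: AnnModel, X) -> np.ndarray:
    """Forward pass on a (N, 7) batch (or a single 7-vector).

    Outputs are the raw linear-layer values: slightly negative predictions
    are possible and are *not* clamped here (only image rendering clamps).
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.W1.shape[0]:
        raise ValueError(f"expected {model.W1.shape[0]} input features")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite network inputs")
    xs = (X - model.x_mean) / model.x_std
    out = np.tanh(xs @ model.W1 + model.b1) @ model.W2 + model.b2
    return out[0] if single else out


def _wmse_grad_batch(model_vars, xb, yb, wb):
    """Forward + backward for the weighted MSE on one minibatch."""
    W1, b1, W2, b2 = model_vars
    h = np.tanh(xb @ W1 + b1)
    pred = h @ W2 + b2
    err = pred - yb
    n, k = err.shape
    loss = float(np.sum(err**2 * wb) / (n * k))
    d_out = 2.0 * err * wb / (n * k)
    gW2 = h.T @ d_out
    gb2 = d_out.sum(axis=0)
    d_h = d_out @ W2.T * (1.0 - h**2)
    gW1 = xb.T @ d_h
    gb1 = d_h.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def _train_single(Xs, Y, w, splits, cfg: AnnConfig, rng: np.random.Generator):
    """One restart: Adam + early stopping on validation wMSE."""
    itr, iva = splits
    n_in, n_out = Xs.shape[1], Y.shape[1]
    lim1 = np.sqrt(6.0 / (n_in + cfg.n_hidden))
    lim2 = np.sqrt(6.0 / (cfg.n_hidden + n_out))
    params = [rng.uniform(-lim1, lim1, (n_in, cfg.n_hidden)),
              np.zeros(cfg.n_hidden),
              rng.uniform(-lim2, lim2, (cfg.n_hidden, n_out)),
              np.zeros(n_out)]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1c, b2c = 0.9, 0.999
    t = 0

    Xtr, Ytr, wtr = Xs[itr], Y[itr], w[itr]
    Xva, Yva, wva = Xs[iva], Y[iva], w[iva]
    best_val = np.inf
    best_params = [p.copy() for p in params]
    stall = 0
    n_tr = Xtr.shape[0]

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n_tr)
        for a in range(0, n_tr, cfg.batch_size):
            idx = order[a:a + cfg.batch_size]
            _, grads = _wmse_grad_batch(params, Xtr[idx], Ytr[idx], wtr[idx])
            t += 1
            for p, mp, vp, g in zip(params, m, v, grads):
                mp *= b1c
                mp += (1 - b1c) * g
                vp *= b2c
                vp += (1 - b2c) * g * g
                mhat = mp / (1 - b1c**t)
                vhat = vp / (1 - b2c**t)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
        # validation
        hv = np.tanh(Xva @ params[0] + params[1])
        pv = hv @ params[2] + params[3]
        val = float(np.mean((pv - Yva) ** 2 * wva))
        if val < best_val - 1e-12:
            best_val = val
            best_params = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    return best_params, best_val


def train_ann(dataset: Dataset, cfg: AnnConfig | None = None,
              seed: int = 0) -> AnnModel:
    """Train ``cfg.restarts`` networks and keep the best on the test split.

    Deterministic given (dataset, cfg, seed).  The selected model records
    every restart's test-split wMSE in ``meta["restart_scores"]``.
    """
    cfg = cfg or AnnConfig()
    Y = dataset.Y
    if np.allclose(Y, Y[0]):
        raise ValueError("degenerate dataset: all targets identical")
    Xtr, _ = dataset.split("train")
    x_mean = Xtr.mean(axis=0)
    x_std = Xtr.std(axis=0)
    x_std[x_std == 0] = 1.0
    Xs = (dataset.X - x_mean) / x_std
    w = 1.0 / np.maximum(Y.sum(axis=1, keepdims=True), cfg.eps_total)

    streams = np.random.SeedSequence(seed).spawn(cfg.restarts)
    Xte_idx = dataset.idx_test
    best = None
    scores = []
    for r in range(cfg.restarts):
        rng = np.random.default_rng(streams[r])
        params, val = _train_single(Xs, Y, w, (dataset.idx_train,
                                               dataset.idx_val), cfg, rng)
        h = np.tanh(Xs[Xte_idx] @ params[0] + params[1])
        pred = h @ params[2] + params[3]
        test_score = wmse_loss(pred, Y[Xte_idx], cfg.eps_total)
        scores.append(test_score)
        if best is None or test_score < best[0]:
            best = (test_score, params, val)

    test_score, params, val = best
    return AnnModel(*params, x_mean=x_mean, x_std=x_std,
                    meta={"seed": seed, "restarts": cfg.restarts,
                          "restart_scores": scores,
                          "selected_test_wmse": test_score,
                          "selected_val_wmse": val,
                          "provenance": dataset.provenance})


def evaluate_model(model: AnnModel, X, Y) -> dict:
    """Evaluation metric table: wMAPE per component, total MAPE, R² × 4."""
    pred = predict(model, X)
    Y = np.asarray(Y, dtype=float)
    return {
        "wmape": wmape(pred, Y),
        "mape_total": mape(pred.sum(axis=1), Y.sum(axis=1)),
        "r2": np.array([r_squared(pred[:, j], Y[:, j]) for j in range(3)]
                       + [r_squared(pred.sum(axis=1), Y.sum(axis=1))]),
    }
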