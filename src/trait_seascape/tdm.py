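"""Trait distribution models: a small feedforward network mapping abiotic
predictors to community-level trait responses, applied pixel-wise to a grid.

Architecture: input -> 12 -> 12 -> 1 dense layers with leaky-ReLU hidden
activations (negative slope 0.01) and a linear output head, i.e.
``12*d_in + 181`` trainable parameters (601 for the 35-feature set).
Fitting repeats a random 50/30/20 train/validation/test split and weight
initialization ``n_restarts`` times with full-batch Adam and early
stopping on validation MSE; the restart with the lowest validation MSE
is selected and the distribution of test MSEs reported. Inputs are
z-scored with statistics of the training split only; the substratum
factor enters one-hot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SUBSTRATUM_VAR, SeascapeGrid
from .tables import SUBSTRATUM_LEVELS, EnvironmentTable

logger = logging.getLogger(__name__)

HIDDEN = (12, 12)
LEAKY_SLOPE = 0.01
DEFAULT_FRACTIONS = (0.5, 0.3, 0.2)
DEFAULT_RESTARTS = 50


def parameter_count(d_in: int, hidden=HIDDEN) -> int:
    """Trainable parameters (weights + biases) of the dense net."""
    if d_in < 1:
        raise ValueError("d_in must be >= 1")
    sizes = (d_in, *hidden, 1)
    return sum(sizes[i] * sizes[i + 1] + sizes[i + 1] for i in range(len(sizes) - 1))


# ---------------------------------------------------------------------------
# Feature building
# ---------------------------------------------------------------------------

def build_design(table: pd.DataFrame, feature_names: list[str] | None = None,
                 ) -> pd.DataFrame:
    """Numeric design matrix: quantitative columns plus one-hot substratum."""
    parts = [table.select_dtypes(include=[np.number])]
    if SUBSTRATUM_VAR in table.columns and not pd.api.types.is_numeric_dtype(table[SUBSTRATUM_VAR]):
        onehot = pd.DataFrame(
            {f"{SUBSTRATUM_VAR}={lev}": (table[SUBSTRATUM_VAR].astype(str) == lev).astype(float)
             for lev in SUBSTRATUM_LEVELS},
            index=table.index,
        )
        parts.append(onehot)
    X = pd.concat(parts, axis=1)
    if feature_names is not None:
        missing = [f for f in feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"design is missing feature(s) {missing}")
        X = X[feature_names]
    return X


@dataclass
class Normalizer:
    """Per-feature z-scoring with training-split statistics only."""

    center: pd.Series
    scale: pd.Series
    features: list[str]

    @classmethod
    def fit(cls, X_train: pd.DataFrame) -> "Normalizer":
        if len(X_train) == 0:
            raise ValueError("empty training split")
        center = X_train.mean(axis=0)
        scale = X_train.std(axis=0, ddof=0)
        const = scale <= 0
        if const.any():
            logger.warning("dropping constant feature(s) %s", list(X_train.columns[const]))
        feats = list(X_train.columns[~const])
        return cls(center=center[feats], scale=scale[feats], features=feats)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        return ((X[self.features] - self.center) / self.scale).to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def _init_weights(d_in: int, rng: np.random.Generator) -> list[np.ndarray]:
    sizes = (d_in, *HIDDEN, 1)
    params = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        params.append(rng.normal(0, np.sqrt(2.0 / a), size=(a, b)))
        params.append(np.zeros(b))
    return params


def _forward(params: list[np.ndarray], X: np.ndarray):
    acts = [X]
    h = X
    n_layers = len(params) // 2
    for i in range(n_layers):
        z = h @ params[2 * i] + params[2 * i + 1]
        h = z if i == n_layers - 1 else np.where(z > 0, z, LEAKY_SLOPE * z)
        acts.append(h)
    return acts


def _backward(params, acts, resid):
    """Gradients of mean-squared error w.r.t. every weight and bias."""
    n = acts[0].shape[0]
    grads = [None] * len(params)
    delta = 2.0 * resid / n  # d MSE / d output
    n_layers = len(params) // 2
    for i in reversed(range(n_layers)):
        grads[2 * i] = acts[i].T @ delta
        grads[2 * i + 1] = delta.sum(axis=0)
        if i > 0:
            delta = delta @ params[2 * i].T
            delta = delta * np.where(acts[i] > 0, 1.0, LEAKY_SLOPE)
    return grads


def _train_once(X_tr, y_tr, X_val, y_val, rng, lr=0.02, epochs=3000, patience=300):
    """Full-batch Adam with early stopping on validation MSE."""
    params = _init_weights(X_tr.shape[1], rng)
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    b1, b2, eps = 0.9, 0.999, 1e-8
    best_val, best_params, since = np.inf, [p.copy() for p in params], 0
    for t in range(1, epochs + 1):
        acts = _forward(params, X_tr)
        resid = acts[-1] - y_tr
        grads = _backward(params, acts, resid)
        for i, g in enumerate(grads):
            m[i] = b1 * m[i] + (1 - b1) * g
            v[i] = b2 * v[i] + (1 - b2) * g**2
            mh = m[i] / (1 - b1**t)
            vh = v[i] / (1 - b2**t)
            params[i] -= lr * mh / (np.sqrt(vh) + eps)
        if t % 10 == 0 or t == epochs:
            val = float(np.mean((_forward(params, X_val)[-1] - y_val) ** 2))
            if val < best_val - 1e-12:
                best_val, since = val, 0
                best_params = [p.copy() for p in params]
            else:
                since += 10
                if since >= patience:
                    break
    return best_params, best_val


@dataclass
class TDMModel:
    """A fitted trait distribution model for one response variable."""

    response: str
    feature_names: list[str]
    normalizer: Normalizer
    params: list[np.ndarray]
    fractions: tuple[float, float, float]
    n_restarts: int
    seed: int
    val_mse: float
    test_mse: float
    restart_val_mse: list[float] = field(default_factory=list)
    restart_test_mse: list[float] = field(default_factory=list)
    clip: tuple[float, float] | None = None
    y_center: float = 0.0
    y_scale: float = 1.0

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def predict(self, table: pd.DataFrame) -> pd.Series:
        X = build_design(table)
        Z = self.normalizer.transform(X)
        out = _forward(self.params, Z)[-1][:, 0] * self.y_scale + self.y_center
        if self.clip is not None:
            out = np.clip(out, *self.clip)
        return pd.Series(out, index=table.index, name=self.response)

    def model_card(self) -> dict:
        return {
            "response": self.response,
            "architecture": {"hidden": list(HIDDEN), "activation": "leaky_relu",
                             "negative_slope": LEAKY_SLOPE,
                             "n_parameters": self.n_parameters},
            "features": self.normalizer.features,
            "fractions": list(self.fractions),
            "n_restarts": self.n_restarts,
            "seed": self.seed,
            "val_mse": self.val_mse,
            "test_mse": self.test_mse,
            "test_mse_mean": float(np.mean(self.restart_test_mse)),
            "test_mse_sd": float(np.std(self.restart_test_mse)),
        }

    def save_card(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_card(), fh, indent=2)


def fit_with_restarts(env: EnvironmentTable | pd.DataFrame, y: pd.Series,
                      response: str | None = None,
                      fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
                      n_restarts: int = DEFAULT_RESTARTS, seed: int = 0,
                      lr: float = 0.02, epochs: int = 3000, patience: int = 300,
                      clip: tuple[float, float] | None = None) -> TDMModel:
    """Fit one response with repeated random splits and initializations.

    Each restart draws a fresh train/validation/test partition and
    initialization; the restart with minimal validation MSE wins. The
    same seed reproduces the selected weights bit-for-bit.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    table = env.data if isinstance(env, EnvironmentTable) else env
    y = y.loc[table.index]
    if not np.isfinite(y.to_numpy(dtype=float)).all():
        raise ValueError("response contains non-finite values")
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 sites to fit a TDM")
    X_all = build_design(table)
    yv = y.to_numpy(dtype=float)[:, None]

    root = np.random.SeedSequence([seed, 0x7D])
    best = None
    restart_val, restart_test = [], []
    n_tr = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    for child in root.spawn(n_restarts):
        rng = np.random.default_rng(child)
        order = rng.permutation(n)
        tr, va, te = order[:n_tr], order[n_tr:n_tr + n_val], order[n_tr + n_val:]
        norm = Normalizer.fit(X_all.iloc[tr])
        Z = norm.transform(X_all)
        # the target is z-scored with training statistics too, so the fixed
        # learning rate behaves identically across response scales
        yc = float(yv[tr].mean())
        ys = float(yv[tr].std())
        ys = ys if ys > 0 else 1.0
        yn = (yv - yc) / ys
        params, val_mse = _train_once(Z[tr], yn[tr], Z[va], yn[va], rng,
                                      lr=lr, epochs=epochs, patience=patience)
        val_mse *= ys**2  # report on the original response scale
        test_mse = float(np.mean((_forward(params, Z[te])[-1] - yn[te]) ** 2)) * ys**2
        restart_val.append(val_mse)
        restart_test.append(test_mse)
        if best is None or val_mse < best[0]:
            best = (val_mse, test_mse, params, norm, yc, ys)
    val_mse, test_mse, params, norm, yc, ys = best
    return TDMModel(
        response=response or (y.name or "response"),
        feature_names=list(X_all.columns),
        normalizer=norm, params=params, fractions=tuple(fractions),
        n_restarts=n_restarts, seed=seed, val_mse=val_mse, test_mse=test_mse,
        restart_val_mse=restart_val, restart_test_mse=restart_test, clip=clip,
        y_center=yc, y_scale=ys,
    )


def predict_grid(model: TDMModel, grid: SeascapeGrid) -> SeascapeGrid:
    """Apply a fitted model to every unmasked grid cell.

    Raises if the grid lacks a feature the model needs; masked cells
    carry no prediction (NaN).
    """
    cells = grid.cell_table()
    if len(cells) == 0:
        return grid.with_prediction(model.response, pd.Series(dtype=float))
    X = build_design(cells)
    missing = [f for f in model.normalizer.features if f not in X.columns]
    if missing:
        raise KeyError(f"grid is missing feature(s) {missing}")
    pred = model.predict(cells)
    return grid.with_prediction(model.response, pred)
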