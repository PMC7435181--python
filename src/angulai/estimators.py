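"""Multivariate LAI estimators: NIPALS PLSR and a single-hidden-layer BPNN.

PLSR (partial least squares regression, PLS1) is implemented from scratch
via NIPALS: the centered spectra matrix is iteratively decomposed into
score/loading pairs whose weights maximize covariance with LAI, with rank-1
deflation after each component; the latent-variable count is chosen by
k-fold cross-validated RMSE.  Predictors are mean-centered; unit-variance
scaling is optional and off by default since reflectance bands share units.

The BPNN is a one-hidden-layer feedforward regressor (ReLU activation,
full-batch Adam on mean squared error, inputs standardized to training
statistics).  The hidden size is chosen by k-fold cross-validated RMSE
over a grid, and several random initializations are compared by the same
criterion, with the best retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinearModel",
    "PLSRModel",
    "ComponentSelection",
    "BPNNModel",
    "BPNNSelectionReport",
    "fit_linear",
    "fit_plsr",
    "select_components",
    "plsr_loadings",
    "train_bpnn",
    "kfold_indices",
]


# ---------------------------------------------------------------- linear

@dataclass(frozen=True)
class LinearModel:
    slope: float
    intercept: float

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_linear(x, y) -> LinearModel:
    """Ordinary least squares y = slope * x + intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.ptp(x) == 0:
        raise ValueError("cannot fit a line to constant x")
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    return LinearModel(slope=float(slope), intercept=float(ym - slope * xm))


# ----------------------------------------------------------------- PLSR

@dataclass
class PLSRModel:
    """NIPALS PLS1 model on centered (optionally scaled) spectra."""

    n_components: int
    weights: np.ndarray      # (bands, A) NIPALS weights, unit norm
    x_loadings: np.ndarray   # (bands, A)
    y_loadings: np.ndarray   # (A,)
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray
    regression_vector: np.ndarray = field(init=False)

    def __post_init__(self):
        self.regression_vector = _regression_vector(
            self.weights, self.x_loadings, self.y_loadings
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        return Xc @ self.regression_vector + self.y_mean

    def predict_sequential(self, X: np.ndarray) -> np.ndarray:
        """Prediction via explicit score projection with deflation.

        Independent code path from the assembled regression vector; the two
        agree to numerical precision.
        """
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        yhat = np.full(Xc.shape[0], self.y_mean)
        for a in range(self.n_components):
            t = Xc @ self.weights[:, a]
            Xc = Xc - np.outer(t, self.x_loadings[:, a])
            yhat = yhat + self.y_loadings[a] * t
        return yhat

    def scores(self, X: np.ndarray) -> np.ndarray:
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        T = np.empty((Xc.shape[0], self.n_components))
        for a in range(self.n_components):
            T[:, a] = Xc @ self.weights[:, a]
            Xc = Xc - np.outer(T[:, a], self.x_loadings[:, a])
        return T


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # B = W (P'W)^{-1} q ; P'W is upper triangular with unit-ish diagonal
    A = W.shape[1]
    if A == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q[:A])


def fit_plsr(X: np.ndarray, y: np.ndarray, A: int, scale: bool = False) -> PLSRModel:
    """Fit PLS1 with A latent variables by NIPALS.

    A is truncated (with a warning) if the residual spectra matrix runs out
    of rank before A components are extracted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if A < 1:
        raise ValueError("A must be >= 1")
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, bands)={min(n - 1, p)}")
    if y.std() == 0:
        raise ValueError("y has zero variance")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(x_scale == 0, 1.0, x_scale)
    y_mean = float(y.mean())
    Xc = (X - x_mean) / x_scale
    yc = y - y_mean

    tol = 1e-12 * max(1.0, float(np.abs(Xc).max()) ** 2) * n
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    extracted = 0
    for a in range(A):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw <= tol:
            warnings.warn(f"rank exhausted after {extracted} components; A truncated")
            break
        w = w / nw
        t = Xc @ w
        tt = t @ t
        if tt <= tol:
            warnings.warn(f"rank exhausted after {extracted} components; A truncated")
            break
        p_a = (Xc.T @ t) / tt
        q_a = (yc @ t) / tt
        Xc = Xc - np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        extracted += 1
    return PLSRModel(
        n_components=extracted,
        weights=W[:, :extracted],
        x_loadings=P[:, :extracted],
        y_loadings=q[:extracted],
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=x_scale,
    )


def plsr_loadings(model: PLSRModel, component: int) -> np.ndarray:
    """Spectra loadings of one latent variable (1-indexed)."""
    if not 1 <= component <= model.n_components:
        raise IndexError(f"component must be in 1..{model.n_components}")
    return model.x_loadings[:, component - 1].copy()


@dataclass
class ComponentSelection:
    candidates: list[int]
    cv_rmse: np.ndarray
    chosen: int


def kfold_indices(n: int, k: int, seed: int) -> np.ndarray:
    """Near-equal random fold assignment 1..k for n samples."""
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    sizes = [n // k + (1 if f < n % k else 0) for f in range(k)]
    start = 0
    for f, size in enumerate(sizes, start=1):
        folds[perm[start : start + size]] = f
        start += size
    return folds


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    A_max: int = 15,
    folds: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
    scale: bool = False,
) -> ComponentSelection:
    """Cross-validated RMSE curve over A = 1..A_max; minimum wins, ties to small A.

    ``folds`` may carry a precomputed fold assignment (1..k per sample),
    e.g. the shared experiment partition; otherwise folds are drawn here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    if folds is None:
        folds = kfold_indices(n, k, seed)
    A_max = min(A_max, min(n - max(np.bincount(folds)[1:]) - 1, X.shape[1]))
    sse = np.zeros(A_max)
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        model = fit_plsr(X[tr], y[tr], A_max, scale=scale)
        # nested predictions for every A from one fit
        Xc = (X[te] - model.x_mean) / model.x_scale
        yhat = np.full(te.sum(), model.y_mean)
        for a in range(model.n_components):
            t = Xc @ model.weights[:, a]
            Xc = Xc - np.outer(t, model.x_loadings[:, a])
            yhat = yhat + model.y_loadings[a] * t
            sse[a] += ((y[te] - yhat) ** 2).sum()
        for a in range(model.n_components, A_max):  # truncated rank: carry forward
            sse[a] += ((y[te] - yhat) ** 2).sum()
    rmse = np.sqrt(sse / n)
    chosen = int(np.argmin(rmse)) + 1
    return ComponentSelection(candidates=list(range(1, A_max + 1)), cv_rmse=rmse, chosen=chosen)


# ----------------------------------------------------------------- BPNN

@dataclass
class BPNNModel:
    """Single-hidden-layer ReLU network for spectra -> LAI regression."""

    hidden_size: int
    w1: np.ndarray  # (bands, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    epochs_run: int = 0
    seed: int = 0
    repeat_index: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.x_mean) / self.x_std
        H = np.maximum(Z @ self.w1 + self.b1, 0.0)
        return (H @ self.w2 + self.b2) * self.y_std + self.y_mean


@dataclass
class BPNNSelectionReport:
    hidden_grid: list[int]
    cv_rmse_by_hidden: dict[int, float]
    chosen_hidden: int
    repeat_cv_rmse: list[float]
    chosen_repeat: int
    notes: str = (
        "epochs/learning-rate/stopping are engineering defaults: "
        "full-batch Adam, lr 1e-2, plateau early stop"
    )


def _train_once(
    X: np.ndarray,
    y: np.ndarray,
    hidden: int,
    epochs: int,
    lr: float,
    seed: int,
    patience: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int]:
    """Full-batch Adam on standardized data; returns raw weights (z-space).

    A 15% held-out monitor split (seeded) drives early stopping: the best
    snapshot by monitor loss is returned once the monitor loss has not
    improved for ``patience`` epochs.  This guards the interpolating
    network against overfitting its calibration fold.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    n_mon = int(round(0.15 * n)) if n >= 10 else 0
    perm = rng.permutation(n)
    mon, tr = perm[:n_mon], perm[n_mon:]
    Xtr, ytr = X[tr], y[tr]
    Xmon, ymon = X[mon], y[mon]
    n_tr = len(tr)

    w1 = rng.normal(0.0, np.sqrt(2.0 / p), size=(p, hidden))
    b1 = np.zeros(hidden)
    w2 = rng.normal(0.0, np.sqrt(1.0 / hidden), size=hidden)
    b2 = 0.0
    params = [w1, b1, w2, np.array(b2)]
    m = [np.zeros_like(a) for a in params]
    v = [np.zeros_like(a) for a in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    best_loss, best_snapshot, since_best = np.inf, None, 0
    t = 0
    for epoch in range(epochs):
        H_pre = Xtr @ w1 + b1
        H = np.maximum(H_pre, 0.0)
        yhat = H @ w2 + b2
        err = yhat - ytr
        loss = float((err ** 2).mean())
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        if n_mon:
            pm = np.maximum(Xmon @ w1 + b1, 0.0) @ w2 + b2
            monitor = float(((pm - ymon) ** 2).mean())
        else:
            monitor = loss
        if monitor < best_loss - 1e-7:
            best_loss, since_best = monitor, 0
            best_snapshot = (w1.copy(), b1.copy(), w2.copy(), b2, epoch + 1)
        else:
            since_best += 1
            if since_best >= patience:
                break
        g_yhat = 2.0 * err / n_tr
        g_w2 = H.T @ g_yhat
        g_b2 = g_yhat.sum()
        g_H = np.outer(g_yhat, w2)
        g_H[H_pre <= 0] = 0.0
        g_w1 = Xtr.T @ g_H
        g_b1 = g_H.sum(axis=0)
        grads = [g_w1, g_b1, g_w2, np.array(g_b2)]
        t += 1
        for i, (par, g) in enumerate(zip(params, grads)):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mh = m[i] / (1 - beta1 ** t)
            vh = v[i] / (1 - beta2 ** t)
            par -= lr * mh / (np.sqrt(vh) + eps)
        w1, b1, w2 = params[0], params[1], params[2]
        b2 = float(params[3])
    if best_snapshot is None:
        best_snapshot = (w1, b1, w2, b2, epochs)
    return best_snapshot


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _cv_rmse_bpnn(X, y, hidden, folds, epochs, lr, seed) -> float:
    sse = 0.0
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        Ztr, mu, sd = _standardize(X[tr])
        ym, ys = y[tr].mean(), y[tr].std()
        ys = ys if ys > 0 else 1.0
        ztr_y = (y[tr] - ym) / ys
        for attempt in range(3):  # restart on numerical blow-up
            try:
                w1, b1, w2, b2, _ = _train_once(
                    Ztr, ztr_y, hidden, epochs, lr, seed + 1000 * int(f) + attempt
                )
                break
            except FloatingPointError:
                warnings.warn("non-finite BPNN loss; restarting with next seed")
        else:
            raise FloatingPointError("BPNN training diverged in 3 restarts")
        Zte = (X[te] - mu) / sd
        pred = (np.maximum(Zte @ w1 + b1, 0) @ w2 + b2) * ys + ym
        sse += ((pred - y[te]) ** 2).sum()
    return float(np.sqrt(sse / len(y)))


def train_bpnn(
    X: np.ndarray,
    y: np.ndarray,
    hidden_grid: tuple[int, ...] = (5, 10, 20, 50, 100, 200),
    repeats: int = 20,
    epochs: int = 500,
    lr: float = 1e-2,
    seed: int = 0,
    folds: np.ndarray | None = None,
    k: int = 5,
) -> tuple[BPNNModel, BPNNSelectionReport]:
    """Grid-search the hidden size by k-fold CV RMSE, then keep the best of
    ``repeats`` random initializations (again by CV RMSE); the returned
    model is retrained on all samples with the winning seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if any(h < 5 or h > 200 for h in hidden_grid):
        raise ValueError("hidden sizes must lie within [5, 200]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if folds is None:
        folds = kfold_indices(len(y), k, seed)

    cv_by_hidden = {
        h: _cv_rmse_bpnn(X, y, h, folds, epochs, lr, seed + 17 * h) for h in hidden_grid
    }
    chosen_hidden = min(cv_by_hidden, key=lambda h: (cv_by_hidden[h], h))

    repeat_scores = [
        cv_by_hidden[chosen_hidden] if r == 0 else _cv_rmse_bpnn(
            X, y, chosen_hidden, folds, epochs, lr, seed + 17 * chosen_hidden + 7919 * r
        )
        for r in range(repeats)
    ]
    chosen_repeat = int(np.argmin(repeat_scores))
    final_seed = seed + 17 * chosen_hidden + 7919 * chosen_repeat

    Z, mu, sd = _standardize(X)
    ym, ys = y.mean(), y.std()
    ys = ys if ys > 0 else 1.0
    w1, b1, w2, b2, epochs_run = _train_once(
        Z, (y - ym) / ys, chosen_hidden, epochs, lr, final_seed + 1000
    )
    model = BPNNModel(
        hidden_size=chosen_hidden, w1=w1, b1=b1, w2=w2, b2=b2,
        x_mean=mu, x_std=sd, y_mean=float(ym), y_std=float(ys),
        epochs_run=epochs_run, seed=final_seed, repeat_index=chosen_repeat,
    )
    report = BPNNSelectionReport(
        hidden_grid=list(hidden_grid),
        cv_rmse_by_hidden={h: float(r) for h, r in cv_by_hidden.items()},
        chosen_hidden=chosen_hidden,
        repeat_cv_rmse=[float(r) for r in repeat_scores],
        chosen_repeat=chosen_repeat,
    )
    return model, report
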