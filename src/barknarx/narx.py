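"""NARX recurrent network for double bark thickness.

The model is a nonlinear autoregressive network with exogenous inputs: the
double bark thickness at series position ``k`` is predicted from the delayed
exogenous pair ``u(k-1..k-M) = [avg_d, DTT]`` and the delayed target
``y(k-1..k-N)`` (``N = M = delay`` here), through one hidden layer of
sigmoidal units and a linear output.  With ``delay = d`` the hidden layer
therefore sees ``3 d`` Min-Max-scaled regressors and the architecture is the
``2(d)-h-1`` family.

Training is performed in open-loop (series-parallel) form — the delayed
targets are the measured values — with one of three optimizers:

``LM``
    Levenberg–Marquardt: damped Gauss–Newton on the full residual Jacobian,
    damping multiplied/divided by 10 on rejected/accepted steps, validation
    early stopping.
``BR``
    Bayesian regularization: LM steps on ``beta*E_D + alpha*E_W`` with the
    hyperparameters re-estimated from the effective number of parameters
    after every accepted step.  BR uses no validation stop and trains on the
    pooled train+validation samples; its validation cells are reported as 0
    by convention.
``SCG``
    Møller's scaled conjugate gradient (no line search), validation early
    stopping.

Everything is deterministic given the seeds: same (seed, data, config) gives
a bit-identical model and report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .series import ScalerParams, SeriesSample, SplitIndices, fit_series_scalers, series_to_frame

__all__ = [
    "NarxConfig",
    "NarxModel",
    "TrainReport",
    "NarxTrainingError",
    "init_nguyen_widrow",
    "perturb_model",
    "build_regressors",
    "narx_predict",
    "train_narx",
    "compute_fit_metrics",
    "save_model",
    "load_model",
]

TRAINERS = ("BR", "LM", "SCG")


class NarxTrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class NarxConfig:
    """Architecture and optimizer settings for a ``2(delay)-n_hidden-1`` net."""

    n_hidden: int = 10
    delay: int = 1
    trainer: str = "BR"
    max_epochs: int = 1000
    patience: int = 6
    seed: int = 0
    activation: str = "logistic"
    lm_mu0: float = 1e-3
    grad_tol: float = 1e-10
    boundary_reset: bool = False

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.delay < 1 or self.max_epochs < 1:
            raise ValueError("n_hidden, delay and max_epochs must all be >= 1")
        if self.trainer.upper() not in TRAINERS:
            raise ValueError(f"trainer must be one of {TRAINERS}, got {self.trainer!r}")
        if self.activation not in ("logistic", "tanh"):
            raise ValueError(f"activation must be 'logistic' or 'tanh'")

    @property
    def n_inputs(self) -> int:
        """Regressors seen by the hidden layer: 2 exogenous + 1 target per delay step."""
        return 3 * self.delay

    @property
    def label(self) -> str:
        return f"2({self.delay})-{self.n_hidden}-1 {self.trainer.upper()}"


@dataclass
class NarxModel:
    """Weights and scaling of one trained (or initialized) network."""

    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    delay: int
    activation: str = "logistic"
    scalers: dict[str, ScalerParams] | None = None
    seed: int | None = None

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.W1.size + self.b1.size + self.w2.size + 1

    def copy(self) -> "NarxModel":
        return NarxModel(
            W1=self.W1.copy(),
            b1=self.b1.copy(),
            w2=self.w2.copy(),
            b2=float(self.b2),
            delay=self.delay,
            activation=self.activation,
            scalers=dict(self.scalers) if self.scalers else None,
            seed=self.seed,
        )


@dataclass
class TrainReport:
    """Optimization trace and per-split goodness of fit (original units, cm)."""

    trainer: str
    objective_history: list[float] = field(default_factory=list)
    mse: dict[str, float] = field(default_factory=dict)
    r: dict[str, float] = field(default_factory=dict)
    stop_reason: str = "max_epochs"
    epochs: int = 0
    n_parameters: int = 0
    effective_parameters: float | None = None  # BR's gamma at the last step
    br_validation_convention: bool = False


# ---------------------------------------------------------------------------
# initialization


def init_nguyen_widrow(
    config: NarxConfig, scalers: dict[str, ScalerParams] | None = None
) -> NarxModel:
    """Nguyen–Widrow starting weights.

    Each hidden unit's input-weight row is a random direction scaled to the
    magic norm ``0.7 * h**(1/n)`` (h hidden units, n inputs), and the hidden
    biases are spread evenly over ``[-beta, beta]`` so the units' active
    regions tile the (scaled, [0,1]) input range.  The output layer starts
    small-uniform.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    h, n = config.n_hidden, config.n_inputs
    beta = 0.7 * h ** (1.0 / n)
    W1 = rng.uniform(-1.0, 1.0, size=(h, n))
    norms = np.linalg.norm(W1, axis=1)
    norms[norms == 0] = 1.0
    W1 *= (beta / norms)[:, None]
    b1 = beta * np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    w2 = rng.uniform(-0.5, 0.5, size=h) / np.sqrt(h)
    return NarxModel(
        W1=W1,
        b1=b1,
        w2=w2,
        b2=0.0,
        delay=config.delay,
        activation=config.activation,
        scalers=scalers,
        seed=config.seed,
    )


def perturb_model(model: NarxModel, scale: float, seed: int = 0) -> NarxModel:
    """Additive Gaussian perturbation of all weights (for recovery studies)."""
    rng = np.random.default_rng(seed)
    out = model.copy()
    out.W1 = out.W1 + scale * rng.standard_normal(out.W1.shape)
    out.b1 = out.b1 + scale * rng.standard_normal(out.b1.shape)
    out.w2 = out.w2 + scale * rng.standard_normal(out.w2.shape)
    out.b2 = float(out.b2 + scale * rng.standard_normal())
    return out


# ---------------------------------------------------------------------------
# parameter vector packing


def pack_params(m: NarxModel) -> np.ndarray:
    return np.concatenate([m.W1.ravel(), m.b1, m.w2, [m.b2]])


def unpack_params(w: np.ndarray, template: NarxModel) -> NarxModel:
    h, n = template.W1.shape
    out = template.copy()
    out.W1 = w[: h * n].reshape(h, n).copy()
    out.b1 = w[h * n : h * n + h].copy()
    out.w2 = w[h * n + h : h * n + 2 * h].copy()
    out.b2 = float(w[-1])
    return out


def _activation(z: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (a, da/dz)."""
    if kind == "logistic":
        from scipy.special import expit

        a = expit(z)
        return a, a * (1.0 - a)
    a = np.tanh(z)
    return a, 1.0 - a * a


def _forward_vec(w: np.ndarray, X: np.ndarray, shape: tuple[int, int], kind: str):
    h, n = shape
    W1 = w[: h * n].reshape(h, n)
    b1 = w[h * n : h * n + h]
    w2 = w[h * n + h : h * n + 2 * h]
    b2 = w[-1]
    A, dA = _activation(X @ W1.T + b1, kind)
    return A @ w2 + b2, A, dA, w2


def _jacobian(w: np.ndarray, X: np.ndarray, shape: tuple[int, int], kind: str):
    """Prediction values and d(prediction)/d(params), shape (n_samples, P)."""
    yhat, A, dA, w2 = _forward_vec(w, X, shape, kind)
    G = dA * w2[None, :]  # (n, h): dyhat/db1_j
    J_W1 = (G[:, :, None] * X[:, None, :]).reshape(X.shape[0], -1)
    J = np.concatenate([J_W1, G, A, np.ones((X.shape[0], 1))], axis=1)
    return yhat, J


def _sse_and_grad(w, X, t, shape, kind):
    yhat, A, dA, w2 = _forward_vec(w, X, shape, kind)
    r = yhat - t
    sse = float(r @ r)
    G = dA * w2[None, :] * r[:, None]  # (n, h)
    g_W1 = 2.0 * (G.T @ X).ravel()
    g_b1 = 2.0 * G.sum(axis=0)
    g_w2 = 2.0 * (A.T @ r)
    g_b2 = 2.0 * r.sum()
    return sse, np.concatenate([g_W1, g_b1, g_w2, [g_b2]])


# ---------------------------------------------------------------------------
# regressor construction and prediction


def _as_frame(series) -> pd.DataFrame:
    if isinstance(series, pd.DataFrame):
        return series
    return series_to_frame(list(series))


def _scaled_columns(frame: pd.DataFrame, scalers: dict[str, ScalerParams]):
    a = scalers["avg_d"].forward(frame["avg_d"].to_numpy())
    dtt = scalers["DTT"].forward(frame["DTT"].to_numpy())
    y = scalers["DBT"].forward(frame["DBT"].to_numpy())
    return a, dtt, y


def build_regressors(
    series,
    delay: int,
    scalers: dict[str, ScalerParams],
    boundary_reset: bool = False,
):
    """Open-loop design matrix for the flattened series.

    Returns ``(X, t, pos)``: per target position ``k`` (1-based, ``k > delay``)
    a scaled regressor row ``[u1(k-1..k-d), u2(k-1..k-d), y(k-1..k-d)]``, the
    scaled target ``y(k)``, and the positions themselves.  By default the
    delay window runs straight across tree boundaries (the series is treated
    as one continuous record); with ``boundary_reset`` rows whose window
    spans two trees are dropped.
    """
    frame = _as_frame(series)
    K = len(frame)
    if K <= delay:
        raise ValueError(f"series of length {K} is too short for delay {delay}")
    a, dtt, y = _scaled_columns(frame, scalers)
    idx = np.arange(delay, K)  # 0-based target positions
    lags = np.arange(1, delay + 1)
    cols_a = a[idx[:, None] - lags[None, :]]
    cols_d = dtt[idx[:, None] - lags[None, :]]
    cols_y = y[idx[:, None] - lags[None, :]]
    X = np.concatenate([cols_a, cols_d, cols_y], axis=1)
    t = y[idx]
    pos = idx + 1  # 1-based k
    if boundary_reset:
        tree = frame["tree_id"].to_numpy()
        same = np.all(tree[idx[:, None] - lags[None, :]] == tree[idx][:, None], axis=1)
        X, t, pos = X[same], t[same], pos[same]
    return X, t, pos


def narx_predict(model: NarxModel, series, mode: str = "open_loop") -> np.ndarray:
    """Predict the double bark thickness series, in cm.

    ``open_loop`` (series-parallel) feeds the measured past targets into the
    delay taps; ``closed_loop`` feeds the model's own past predictions after
    priming the first ``delay`` positions with measured values.  The returned
    array has the series length, with NaN at the first ``delay`` priming
    positions (excluded from any metric).
    """
    if model.scalers is None:
        raise ValueError("model has no fitted scalers attached")
    frame = _as_frame(series)
    K = len(frame)
    d = model.delay
    if K <= d:
        raise ValueError(f"series of length {K} is too short for delay {d}")
    a, dtt, y = _scaled_columns(frame, model.scalers)
    w = pack_params(model)
    shape = (model.n_hidden, model.n_inputs)

    out_scaled = np.full(K, np.nan)
    if mode == "open_loop":
        X, _, pos = build_regressors(frame, d, model.scalers)
        yhat, *_ = _forward_vec(w, X, shape, model.activation)
        out_scaled[pos - 1] = yhat
    elif mode == "closed_loop":
        ybuf = y.copy()  # positions < d keep measured (priming) values
        lags = np.arange(1, d + 1)
        for i in range(d, K):
            x = np.concatenate([a[i - lags], dtt[i - lags], ybuf[i - lags]])
            pred, *_ = _forward_vec(w, x[None, :], shape, model.activation)
            out_scaled[i] = pred[0]
            ybuf[i] = pred[0]
    else:
        raise ValueError(f"mode must be 'open_loop' or 'closed_loop', got {mode!r}")

    out = model.scalers["DBT"].inverse(out_scaled)
    out[np.isnan(out_scaled)] = np.nan
    return out


def compute_fit_metrics(observed, predicted) -> tuple[float, float]:
    """(MSE, Pearson R) over the finite pairs, in the series' units.

    R is NaN when either side has zero variance (the correlation is
    undefined for a constant series).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = np.isfinite(obs) & np.isfinite(pred)
    obs, pred = obs[ok], pred[ok]
    if obs.size < 2:
        raise ValueError("need at least 2 finite pairs")
    mse = float(np.mean((obs - pred) ** 2))
    if np.std(obs) == 0.0 or np.std(pred) == 0.0:
        return mse, float("nan")
    return mse, float(np.corrcoef(obs, pred)[0, 1])


# ---------------------------------------------------------------------------
# trainers


def _check_finite(value: float, epoch: int, trainer: str) -> None:
    if not np.isfinite(value):
        raise NarxTrainingError(
            f"{trainer}: objective became non-finite at epoch {epoch}"
        )


def _solve_damped(H: np.ndarray, g: np.ndarray, damping: float) -> np.ndarray:
    A = H + damping * np.eye(H.shape[0])
    try:
        from scipy.linalg import cho_factor, cho_solve

        return cho_solve(cho_factor(A), -g)
    except Exception:
        return np.linalg.lstsq(A, -g, rcond=None)[0]


def _val_mse(w, Xv, tv, shape, kind) -> float:
    yhat, *_ = _forward_vec(w, Xv, shape, kind)
    return float(np.mean((yhat - tv) ** 2))


def _train_lm(w, X, t, Xv, tv, shape, kind, cfg: NarxConfig, report: TrainReport):
    n = len(t)
    mu, mu_max = cfg.lm_mu0, 1e10
    yhat, *_ = _forward_vec(w, X, shape, kind)
    r = yhat - t
    sse = float(r @ r)
    report.objective_history.append(sse / n)
    has_val = Xv is not None and len(tv) > 0
    best_val = _val_mse(w, Xv, tv, shape, kind) if has_val else np.inf
    best_w, fails = w.copy(), 0
    for epoch in range(cfg.max_epochs):
        yhat, J = _jacobian(w, X, shape, kind)
        r = yhat - t
        g = J.T @ r
        if np.max(np.abs(g)) < cfg.grad_tol:
            report.stop_reason = "converged"
            break
        JTJ = J.T @ J
        accepted = False
        while mu <= mu_max:
            delta = _solve_damped(JTJ, g, mu)
            w_try = w + delta
            yhat_try, *_ = _forward_vec(w_try, X, shape, kind)
            sse_try = float((yhat_try - t) @ (yhat_try - t))
            if np.isfinite(sse_try) and sse_try < sse:
                w, sse = w_try, sse_try
                mu = max(mu * 0.1, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            report.stop_reason = "converged"
            break
        _check_finite(sse, epoch, "LM")
        report.objective_history.append(sse / n)
        report.epochs = epoch + 1
        if has_val:
            vm = _val_mse(w, Xv, tv, shape, kind)
            if vm < best_val:
                best_val, best_w, fails = vm, w.copy(), 0
            else:
                fails += 1
                if fails >= cfg.patience:
                    report.stop_reason = "early_stop"
                    break
    else:
        report.stop_reason = "max_epochs"
    return best_w if has_val else w


def _train_br(w, X, t, shape, kind, cfg: NarxConfig, report: TrainReport):
    """Bayesian regularization: LM steps on F = beta*E_D + alpha*E_W.

    gamma = P - alpha*tr(H^-1) with H = beta*J'J + alpha*I is the effective
    number of parameters; alpha = gamma/(2 E_W) and beta = (n-gamma)/(2 E_D)
    are re-estimated after every accepted step (MacKay's evidence updates
    under the Gauss-Newton Hessian approximation).
    """
    n, P = len(t), len(w)
    alpha, beta = 0.0, 1.0
    mu, mu_max = 5e-3, 1e10
    yhat, *_ = _forward_vec(w, X, shape, kind)
    r = yhat - t
    ed, ew = 0.5 * float(r @ r), 0.5 * float(w @ w)
    report.objective_history.append(2.0 * ed / n)
    gamma = float(P)
    for epoch in range(cfg.max_epochs):
        yhat, J = _jacobian(w, X, shape, kind)
        r = yhat - t
        g = beta * (J.T @ r) + alpha * w
        if np.max(np.abs(g)) < cfg.grad_tol:
            report.stop_reason = "converged"
            break
        JTJ = J.T @ J
        f_cur = beta * ed + alpha * ew
        accepted = False
        while mu <= mu_max:
            delta = _solve_damped(beta * JTJ, g, alpha + mu)
            w_try = w + delta
            yhat_try, *_ = _forward_vec(w_try, X, shape, kind)
            r_try = yhat_try - t
            ed_try = 0.5 * float(r_try @ r_try)
            ew_try = 0.5 * float(w_try @ w_try)
            f_try = beta * ed_try + alpha * ew_try
            if np.isfinite(f_try) and f_try < f_cur:
                w, ed, ew = w_try, ed_try, ew_try
                mu = max(mu * 0.1, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            report.stop_reason = "converged"
            break
        _check_finite(ed, epoch, "BR")
        report.objective_history.append(2.0 * ed / n)
        report.epochs = epoch + 1
        # hyperparameter re-estimation on the accepted step
        _, J = _jacobian(w, X, shape, kind)
        eig = np.linalg.eigvalsh(beta * (J.T @ J))
        gamma = float(P - np.sum(alpha / (eig + alpha))) if alpha > 0 else float(P)
        if ew > 1e-30:
            alpha = gamma / (2.0 * ew)
        if ed > 1e-30:
            beta = max((n - gamma), 1e-3) / (2.0 * ed)
        else:
            report.stop_reason = "converged"
            break
    else:
        report.stop_reason = "max_epochs"
    report.effective_parameters = gamma
    return w


def _train_scg(w, X, t, Xv, tv, shape, kind, cfg: NarxConfig, report: TrainReport):
    """Møller's scaled conjugate gradient on the training MSE (no line search)."""
    n = len(t)

    def f_and_g(wv):
        sse, g = _sse_and_grad(wv, X, t, shape, kind)
        return sse / n, g / n

    P = len(w)
    sigma0, lam, lam_bar = 5e-5, 5e-7, 0.0
    f, g = f_and_g(w)
    report.objective_history.append(f)
    r_dir = -g
    p = r_dir.copy()
    success = True
    has_val = Xv is not None and len(tv) > 0
    best_val = _val_mse(w, Xv, tv, shape, kind) if has_val else np.inf
    best_w, fails = w.copy(), 0
    delta = 1.0
    for epoch in range(cfg.max_epochs):
        p_norm2 = float(p @ p)
        if p_norm2 < 1e-30 or np.linalg.norm(g) < cfg.grad_tol:
            report.stop_reason = "converged"
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_sig = f_and_g(w + sigma * p)
            delta = float(p @ (g_sig - g)) / sigma
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0:  # make the Hessian surrogate positive definite
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu_ = float(p @ r_dir)
        alpha_step = mu_ / delta
        f_try, g_try = f_and_g(w + alpha_step * p)
        comparison = 2.0 * delta * (f - f_try) / (mu_ * mu_)
        if comparison >= 0 and np.isfinite(f_try):
            w = w + alpha_step * p
            f_old, f, g_new = f, f_try, g_try
            _check_finite(f, epoch, "SCG")
            report.objective_history.append(f)
            report.epochs = epoch + 1
            lam_bar = 0.0
            success = True
            r_new = -g_new
            if (epoch + 1) % P == 0:  # periodic restart of conjugacy
                p = r_new.copy()
            else:
                beta_cg = (float(r_new @ r_new) - float(r_new @ r_dir)) / mu_
                p = r_new + beta_cg * p
            r_dir, g = r_new, g_new
            if comparison >= 0.75:
                lam = max(0.25 * lam, 1e-20)
            if has_val:
                vm = _val_mse(w, Xv, tv, shape, kind)
                if vm < best_val:
                    best_val, best_w, fails = vm, w.copy(), 0
                else:
                    fails += 1
                    if fails >= cfg.patience:
                        report.stop_reason = "early_stop"
                        break
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2
        if lam > 1e15:
            report.stop_reason = "converged"
            break
    else:
        report.stop_reason = "max_epochs"
    return best_w if has_val else w


def train_narx(
    model: NarxModel,
    series,
    split: SplitIndices,
    config: NarxConfig,
) -> tuple[NarxModel, TrainReport]:
    """Fit the network in open-loop form on the training samples.

    The split's index sets refer to 1-based series positions ``k``; positions
    ``k <= delay`` have no full delay window and are excluded.  Scalers are
    taken from the model or, when absent, fitted on the pooled
    train+validation samples.  Reported per-split MSE and Pearson R are in
    original units (cm) from open-loop prediction over the whole series.
    """
    frame = _as_frame(series)
    K = len(frame)
    for part in (split.train, split.validation, split.test):
        if len(part) and (part.min() < 1 or part.max() > K):
            raise ValueError("split indices outside the series range")
    trainer = config.trainer.upper()

    work = model.copy()
    if work.scalers is None:
        work.scalers = fit_series_scalers(frame, rows=split.learning)

    X, t, pos = build_regressors(
        frame, config.delay, work.scalers, boundary_reset=config.boundary_reset
    )
    in_train = np.isin(pos, split.train)
    in_val = np.isin(pos, split.validation)
    if trainer == "BR":
        in_train = in_train | in_val
        in_val = np.zeros_like(in_val)
    if not in_train.any():
        raise NarxTrainingError("degenerate split: no training samples past the delay window")

    shape = (work.n_hidden, work.n_inputs)
    report = TrainReport(trainer=trainer, n_parameters=work.n_parameters)
    w0 = pack_params(work)
    Xtr, ttr = X[in_train], t[in_train]
    Xv, tv = X[in_val], t[in_val]
    if trainer == "LM":
        w_final = _train_lm(w0, Xtr, ttr, Xv, tv, shape, work.activation, config, report)
    elif trainer == "BR":
        w_final = _train_br(w0, Xtr, ttr, shape, work.activation, config, report)
        report.br_validation_convention = True
    else:
        w_final = _train_scg(w0, Xtr, ttr, Xv, tv, shape, work.activation, config, report)

    fitted = unpack_params(w_final, work)
    fitted.seed = config.seed

    preds = narx_predict(fitted, frame, mode="open_loop")
    obs = frame["DBT"].to_numpy()
    for name, idx in (
        ("training", split.train),
        ("validation", split.validation),
        ("testing", split.test),
    ):
        if name == "validation" and trainer == "BR":
            report.mse[name], report.r[name] = 0.0, 0.0  # reported-as-zero convention
            continue
        sel = idx[idx > config.delay] - 1
        if len(sel) >= 2:
            report.mse[name], report.r[name] = compute_fit_metrics(obs[sel], preds[sel])
        else:
            report.mse[name], report.r[name] = float("nan"), float("nan")
    return fitted, report


# ---------------------------------------------------------------------------
# serialization


def model_to_dict(model: NarxModel) -> dict:
    return {
        "architecture": f"2({model.delay})-{model.n_hidden}-1",
        "delay": model.delay,
        "activation": model.activation,
        "seed": model.seed,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "scalers": {
            name: {"minimum": s.minimum, "maximum": s.maximum}
            for name, s in (model.scalers or {}).items()
        },
    }


def model_from_dict(doc: dict) -> NarxModel:
    scalers = {
        name: ScalerParams(name=name, minimum=s["minimum"], maximum=s["maximum"])
        for name, s in doc.get("scalers", {}).items()
    }
    return NarxModel(
        W1=np.asarray(doc["W1"], dtype=float),
        b1=np.asarray(doc["b1"], dtype=float),
        w2=np.asarray(doc["w2"], dtype=float),
        b2=float(doc["b2"]),
        delay=int(doc["delay"]),
        activation=doc.get("activation", "logistic"),
        scalers=scalers or None,
        seed=doc.get("seed"),
    )


def save_model(model: NarxModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path: str | Path) -> NarxModel:
    return model_from_dict(json.loads(Path(path).read_text()))
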