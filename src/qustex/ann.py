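"""Shallow feedforward network trained with Levenberg-Marquardt.

Architecture: one hidden layer (sigmoid, 20 units by default) and a
softmax output layer over two classes, trained full-batch on the mean
squared error against one-hot targets. The Jacobian of the residuals with
respect to the weights is computed by backpropagation; the damping factor
``mu`` starts at 1e-3, shrinks x0.1 on an accepted step, grows x10 on a
rejected one, and training aborts when it exceeds 1000. Optional
validation data stops training after 6 consecutive epochs without
improvement, restoring the best weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LMTrainConfig:
    hidden_units: int = 20
    max_epochs: int = 1000
    goal: float = 0.0
    min_gradient: float = 1e-7
    max_validation_failures: int = 6
    mu0: float = 1e-3
    mu_decrease: float = 0.1
    mu_increase: float = 10.0
    mu_max: float = 1e3


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _softmax(u: np.ndarray) -> np.ndarray:
    u = u - u.max(axis=1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=1, keepdims=True)


class LMNetwork:
    """Two-layer pattern-recognition network with LM training."""

    def __init__(self, n_inputs: int, config: LMTrainConfig | None = None,
                 seed: int | np.random.Generator = 0):
        self.config = config or LMTrainConfig()
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        h = self.config.hidden_units
        # uniform(-0.5, 0.5) scaled by fan-in
        self.w1 = rng.uniform(-0.5, 0.5, size=(h, n_inputs)) / np.sqrt(n_inputs)
        self.b1 = rng.uniform(-0.5, 0.5, size=h) / np.sqrt(n_inputs)
        self.w2 = rng.uniform(-0.5, 0.5, size=(2, h)) / np.sqrt(h)
        self.b2 = rng.uniform(-0.5, 0.5, size=2) / np.sqrt(h)
        self.n_inputs = n_inputs
        self.epochs_run = 0
        self.stop_reason = "not trained"

    # -- parameter vector helpers -------------------------------------------------
    def _get_params(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1, self.w2.ravel(), self.b2])

    def _set_params(self, p: np.ndarray) -> None:
        h, d = self.w1.shape
        k = 0
        self.w1 = p[k:k + h * d].reshape(h, d); k += h * d
        self.b1 = p[k:k + h]; k += h
        self.w2 = p[k:k + 2 * h].reshape(2, h); k += 2 * h
        self.b2 = p[k:k + 2]

    # -- forward / jacobian -------------------------------------------------------
    def _forward(self, x: np.ndarray):
        a = _sigmoid(x @ self.w1.T + self.b1)  # (n, h)
        y = _softmax(a @ self.w2.T + self.b2)  # (n, 2)
        return a, y

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, dtype=float))[1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    def _residuals_jacobian(self, x: np.ndarray, t: np.ndarray):
        """Residuals r = y - t (flattened) and their Jacobian wrt parameters."""
        n, d = x.shape
        h = self.w1.shape[0]
        a, y = self._forward(x)
        r = (y - t).ravel()
        # dy[k]/du[m] for softmax: y_k (delta_km - y_m) -> (n, 2, 2)
        dy_du = y[:, :, None] * (np.eye(2)[None, :, :] - y[:, None, :])
        # output layer params: u_m = w2[m] . a + b2[m]
        j_w2 = np.einsum("nkm,nh->nkmh", dy_du, a).reshape(n, 2, 2 * h)
        j_b2 = dy_du  # (n, 2, 2)
        # hidden layer: du_m/da_q = w2[m, q]; da_q/dv_q = a(1-a)
        dadv = a * (1.0 - a)  # (n, h)
        dy_dv = np.einsum("nkm,mq,nq->nkq", dy_du, self.w2, dadv)  # (n, 2, h)
        j_w1 = np.einsum("nkq,nd->nkqd", dy_dv, x).reshape(n, 2, h * d)
        j_b1 = dy_dv
        jac = np.concatenate([j_w1, j_b1, j_w2, j_b2], axis=2).reshape(n * 2, -1)
        return r, jac

    @staticmethod
    def _mse(y: np.ndarray, t: np.ndarray) -> float:
        return float(np.mean((y - t) ** 2))

    # -- training -----------------------------------------------------------------
    def fit(self, x: np.ndarray, y01: np.ndarray,
            x_val: np.ndarray | None = None, y_val01: np.ndarray | None = None) -> "LMNetwork":
        """Full-batch LM training against one-hot targets (labels in {0, 1})."""
        cfg = self.config
        x = np.asarray(x, dtype=float)
        t = np.eye(2)[np.asarray(y01, dtype=int)]
        has_val = x_val is not None and len(x_val) > 0
        if has_val:
            x_val = np.asarray(x_val, dtype=float)
            t_val = np.eye(2)[np.asarray(y_val01, dtype=int)]
        mu = cfg.mu0
        loss = self._mse(self._forward(x)[1], t)
        best_val = np.inf
        best_params = self._get_params()
        val_failures = 0
        self.stop_reason = "max_epochs"
        for epoch in range(cfg.max_epochs):
            self.epochs_run = epoch + 1
            r, jac = self._residuals_jacobian(x, t)
            if not np.all(np.isfinite(r)):
                raise FloatingPointError("non-finite training loss in LM training")
            grad = jac.T @ r
            if np.max(np.abs(grad)) < cfg.min_gradient:
                self.stop_reason = "min_gradient"
                break
            jtj = jac.T @ jac
            params = self._get_params()
            accepted = False
            while mu <= cfg.mu_max:
                try:
                    step = np.linalg.solve(jtj + mu * np.eye(jtj.shape[0]), -grad)
                except np.linalg.LinAlgError:
                    mu *= cfg.mu_increase
                    continue
                self._set_params(params + step)
                new_loss = self._mse(self._forward(x)[1], t)
                if np.isfinite(new_loss) and new_loss < loss:
                    loss = new_loss
                    mu = max(mu * cfg.mu_decrease, 1e-20)
                    accepted = True
                    break
                self._set_params(params)
                mu *= cfg.mu_increase
            if not accepted:
                self.stop_reason = "mu_max"
                break
            if loss <= cfg.goal:
                self.stop_reason = "goal"
                break
            if has_val:
                val_loss = self._mse(self._forward(x_val)[1], t_val)
                if val_loss < best_val:
                    best_val = val_loss
                    best_params = self._get_params()
                    val_failures = 0
                else:
                    val_failures += 1
                    if val_failures >= cfg.max_validation_failures:
                        self.stop_reason = "validation"
                        break
        if has_val and np.isfinite(best_val):
            self._set_params(best_params)
        return self
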