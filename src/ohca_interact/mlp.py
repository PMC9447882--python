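"""A small feed-forward binary classifier with explicit backpropagation.

Three hidden blocks, each affine -> batch normalization -> sigmoid ->
(inverted) dropout, followed by a final affine and a sigmoid output unit,
trained with mini-batch Adam on a class-weighted binary cross-entropy.  All
forward and backward passes are written out in numpy so that the gradients
are checkable against central finite differences, batch-norm layers
included.

With 145 inputs and the default hidden widths (180, 80, 40) a single-sample
forward pass costs ~44k multiply-accumulates.

Training mode uses batch statistics for normalization and keeps exponential
running statistics; inference mode uses the running statistics and disables
dropout, so prediction is deterministic and invariant to batch partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NetConfig", "ClassWeights", "MLP", "weighted_bce", "weighted_bce_grad"]

_EPS_P = 1e-7   # probability clip for the loss
_EPS_BN = 1e-5  # batch-norm variance epsilon


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class NetConfig:
    """Architecture and optimizer settings of the prognostic network."""

    input_width: int
    hidden_widths: tuple[int, int, int] = (180, 80, 40)
    dropout_rate: float = 0.2
    batch_norm: bool = True
    activation: str = "sigmoid"  # or "relu"
    batch_size: int = 100
    epochs: int = 50
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_width <= 0 or any(w <= 0 for w in self.hidden_widths):
            raise ContractError("layer widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ContractError("dropout_rate must lie in [0, 1)")
        if self.activation not in ("sigmoid", "relu"):
            raise ContractError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights: w_pos multiplies the minority (CPC 1/2) terms."""

    w_pos: float = 1.0
    w_neg: float = 1.0

    def __post_init__(self) -> None:
        if self.w_pos <= 0 or self.w_neg < 0:
            raise ContractError("w_pos must be > 0 and w_neg >= 0")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce(p: np.ndarray, y: np.ndarray, weights: ClassWeights) -> float:
    """Mean of -[w_pos * y * log p + w_neg * (1-y) * log(1-p)]."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ContractError(f"shape mismatch: p {p.shape} vs y {y.shape}")
    p = np.clip(p, _EPS_P, 1.0 - _EPS_P)
    terms = weights.w_pos * y * np.log(p) + weights.w_neg * (1.0 - y) * np.log(1.0 - p)
    return float(-np.mean(terms))


def weighted_bce_grad(p: np.ndarray, y: np.ndarray, weights: ClassWeights) -> np.ndarray:
    """d loss / d p (matching the clipped loss: zero gradient where clipped)."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = (p > _EPS_P) & (p < 1.0 - _EPS_P)
    pc = np.clip(p, _EPS_P, 1.0 - _EPS_P)
    g = -(weights.w_pos * y / pc - weights.w_neg * (1.0 - y) / (1.0 - pc)) / p.size
    return np.where(inside, g, 0.0)


class MLP:
    """Three-hidden-block network with manual forward/backward passes.

    Parameters live in ``self.params`` as a flat dict (W0, b0, gamma0,
    beta0, ..., W3, b3); running batch-norm statistics in ``self.running``.
    """

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(config.seed)))
        widths = [config.input_width, *config.hidden_widths, 1]
        self.n_hidden = len(config.hidden_widths)
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        for i in range(len(widths) - 1):
            fan_in = widths[i]
            self.params[f"W{i}"] = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (widths[i], widths[i + 1]))
            self.params[f"b{i}"] = np.zeros(widths[i + 1])
            if config.batch_norm and i < self.n_hidden:
                self.params[f"gamma{i}"] = np.ones(widths[i + 1])
                self.params[f"beta{i}"] = np.zeros(widths[i + 1])
                self.running[f"mean{i}"] = np.zeros(widths[i + 1])
                self.running[f"var{i}"] = np.ones(widths[i + 1])
        self._bn_momentum = 0.9

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, *, train: bool = False,
                dropout_rng: np.random.Generator | None = None,
                cache: dict | None = None) -> np.ndarray:
        """Predicted probabilities for a batch; fills ``cache`` for backward."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.config.input_width:
            raise ContractError(
                f"input width {X.shape[1] if X.ndim == 2 else X.shape} does not "
                f"match the model's input width {self.config.input_width}"
            )
        cfg = self.config
        h = X
        if cache is not None:
            cache["inputs"] = []
        for i in range(self.n_hidden):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            layer_cache: dict = {"h_in": h, "z": z}
            if cfg.batch_norm:
                if train:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    m = self._bn_momentum
                    self.running[f"mean{i}"] = m * self.running[f"mean{i}"] + (1 - m) * mu
                    self.running[f"var{i}"] = m * self.running[f"var{i}"] + (1 - m) * var
                else:
                    mu = self.running[f"mean{i}"]
                    var = self.running[f"var{i}"]
                inv_sd = 1.0 / np.sqrt(var + _EPS_BN)
                zhat = (z - mu) * inv_sd
                a_in = self.params[f"gamma{i}"] * zhat + self.params[f"beta{i}"]
                layer_cache.update(zhat=zhat, inv_sd=inv_sd, batch_stats=train)
            else:
                a_in = z
            if cfg.activation == "sigmoid":
                a = _sigmoid(a_in)
            else:
                a = np.maximum(a_in, 0.0)
            layer_cache["a_in"] = a_in
            layer_cache["a"] = a
            if train and cfg.dropout_rate > 0.0:
                if dropout_rng is None:
                    raise ContractError("training forward pass needs a dropout rng")
                keep = 1.0 - cfg.dropout_rate
                mask = (dropout_rng.random(a.shape) < keep) / keep
                a = a * mask
                layer_cache["dropout_mask"] = mask
            if cache is not None:
                cache["inputs"].append(layer_cache)
            h = a
        z_out = h @ self.params[f"W{self.n_hidden}"] + self.params[f"b{self.n_hidden}"]
        p = _sigmoid(z_out[:, 0])
        if cache is not None:
            cache["h_last"] = h
            cache["p"] = p
        return p

    def predict(self, X: np.ndarray, batch_size: int | None = None) -> np.ndarray:
        """Inference-mode probabilities (deterministic, batch-invariant)."""
        X = np.asarray(X, dtype=float)
        if batch_size is None:
            return self.forward(X, train=False)
        return np.concatenate(
            [self.forward(X[i:i + batch_size], train=False)
             for i in range(0, len(X), batch_size)]
        ) if len(X) else np.empty(0)

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray, weights: ClassWeights,
                       *, train: bool = True,
                       dropout_rng: np.random.Generator | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Weighted-BCE loss and analytic gradients for every parameter."""
        cache: dict = {}
        p = self.forward(X, train=train, dropout_rng=dropout_rng, cache=cache)
        y = np.asarray(y, dtype=float)
        loss = weighted_bce(p, y, weights)

        grads: dict[str, np.ndarray] = {}
        dp = weighted_bce_grad(p, y, weights)
        dz_out = (dp * p * (1.0 - p))[:, None]  # sigmoid output unit
        h_last = cache["h_last"]
        i = self.n_hidden
        grads[f"W{i}"] = h_last.T @ dz_out
        grads[f"b{i}"] = dz_out.sum(axis=0)
        dh = dz_out @ self.params[f"W{i}"].T

        for i in range(self.n_hidden - 1, -1, -1):
            lc = cache["inputs"][i]
            da = dh
            if "dropout_mask" in lc:
                da = da * lc["dropout_mask"]
            if self.config.activation == "sigmoid":
                a = lc["a"]
                da_in = da * a * (1.0 - a)
            else:
                da_in = da * (lc["a_in"] > 0)
            if self.config.batch_norm:
                zhat, inv_sd = lc["zhat"], lc["inv_sd"]
                gamma = self.params[f"gamma{i}"]
                grads[f"gamma{i}"] = (da_in * zhat).sum(axis=0)
                grads[f"beta{i}"] = da_in.sum(axis=0)
                dzhat = da_in * gamma
                if lc["batch_stats"]:
                    m = zhat.shape[0]
                    dz = (inv_sd / m) * (
                        m * dzhat - dzhat.sum(axis=0) - zhat * (dzhat * zhat).sum(axis=0)
                    )
                else:
                    dz = dzhat * inv_sd
            else:
                dz = da_in
            h_in = lc["h_in"]
            grads[f"W{i}"] = h_in.T @ dz
            grads[f"b{i}"] = dz.sum(axis=0)
            dh = dz @ self.params[f"W{i}"].T
        return loss, grads

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, weights: ClassWeights | None = None
            ) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean training loss."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if not np.isfinite(X).all():
            raise ContractError("training matrix contains undefined values")
        if len(X) != len(y):
            raise ContractError("X and y length mismatch")
        weights = weights or ClassWeights()
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 1])))
        dropout_rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([cfg.seed, 2])))

        m_t = {k: np.zeros_like(v) for k, v in self.params.items()}
        v_t = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        batch = min(cfg.batch_size, len(X))
        history: list[float] = []
        for _ in range(cfg.epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(X), batch):
                idx = order[start:start + batch]
                if len(idx) < 2 and cfg.batch_norm:
                    continue  # batch statistics undefined on a single sample
                loss, grads = self.loss_and_grads(
                    X[idx], y[idx], weights, train=True, dropout_rng=dropout_rng
                )
                losses.append(loss)
                step += 1
                for k, g in grads.items():
                    m_t[k] = beta1 * m_t[k] + (1 - beta1) * g
                    v_t[k] = beta2 * v_t[k] + (1 - beta2) * g * g
                    mhat = m_t[k] / (1 - beta1 ** step)
                    vhat = v_t[k] / (1 - beta2 ** step)
                    self.params[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            history.append(float(np.mean(losses)) if losses else float("nan"))
        return history

    # -- (de)serialization --------------------------------------------------

    def state_dict(self) -> dict:
        return {
            "config": self.config.__dict__ | {"hidden_widths": list(self.config.hidden_widths)},
            "params": {k: v.tolist() for k, v in self.params.items()},
            "running": {k: v.tolist() for k, v in self.running.items()},
        }

    @staticmethod
    def from_state_dict(state: dict) -> "MLP":
        cfg_d = dict(state["config"])
        cfg_d["hidden_widths"] = tuple(cfg_d["hidden_widths"])
        net = MLP(NetConfig(**cfg_d))
        net.params = {k: np.asarray(v, dtype=float) for k, v in state["params"].items()}
        net.running = {k: np.asarray(v, dtype=float) for k, v in state["running"].items()}
        return net
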