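"""Central finite-difference gradient checking for the network."""

import copy

import numpy as np

from ohca_interact.mlp import MLP, ClassWeights


def max_relative_gradient_error(net: MLP, X, y, weights: ClassWeights,
                                n_per_param: int = 5, eps: float = 1e-6) -> float:
    """Compare analytic gradients with central differences.

    Batch-norm running statistics are restored between evaluations so each
    loss evaluation sees the identical training-mode forward pass.
    """
    run0 = copy.deepcopy(net.running)
    _, grads = net.loss_and_grads(X, y, weights, train=True)
    net.running = copy.deepcopy(run0)

    def loss_at():
        val, _ = net.loss_and_grads(X, y, weights, train=True)
        net.running = copy.deepcopy(run0)
        return val

    rng = np.random.default_rng(0)
    worst = 0.0
    for name, P in net.params.items():
        flat = P.reshape(-1)
        g = grads[name].reshape(-1)
        picks = rng.choice(flat.size, size=min(n_per_param, flat.size), replace=False)
        for j in picks:
            orig = flat[j]
            flat[j] = orig + eps
            lp = loss_at()
            flat[j] = orig - eps
            lm = loss_at()
            flat[j] = orig
            fd = (lp - lm) / (2 * eps)
            denom = max(1e-8, abs(fd) + abs(g[j]))
            worst = max(worst, abs(fd - g[j]) / denom)
    return worst
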