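"""Optimisers.  Only AdamW (decoupled weight decay) is provided: the
training recipe uses one parameter group per network module, each with its
own learning rate."""

from __future__ import annotations

import numpy as np

from ._tensor import Parameter

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay (Loshchilov & Hutter).

    Parameters are passed as groups: ``[{"params": [...], "lr": 4e-4}, ...]``.
    ``weight_decay`` may be overridden per group.
    """

    def __init__(self, param_groups: list[dict], betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.groups = []
        for group in param_groups:
            params = list(group["params"])
            self.groups.append({
                "params": params,
                "lr": float(group["lr"]),
                "weight_decay": float(group.get("weight_decay", weight_decay)),
                "m": [np.zeros_like(p.data) for p in params],
                "v": [np.zeros_like(p.data) for p in params],
            })
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for group in self.groups:
            lr = group["lr"]
            wd = group["weight_decay"]
            for p, m, v in zip(group["params"], group["m"], group["v"]):
                if p.grad is None:
                    continue
                g = p.grad
                m *= b1
                m += (1.0 - b1) * g
                v *= b2
                v += (1.0 - b2) * g * g
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.data -= lr * (update + wd * p.data)

    @staticmethod
    def params(parameters: list[Parameter], lr: float) -> dict:
        return {"params": parameters, "lr": lr}
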