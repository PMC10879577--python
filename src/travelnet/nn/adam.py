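"""Adam optimizer with bias correction, operating on named parameter dicts.

The optimizer state (first/second moments and the step counter) is part of
the traveling model's luggage: it is serialised into checkpoints and carried
from center to center unless explicitly reset.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    def __init__(
        self,
        param_names: list[str],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.param_names = list(param_names)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float) -> None:
        """One update: p <- p - lr * m_hat / (sqrt(v_hat) + eps), in place."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for name in self.param_names:
            g = grads[name].astype(np.float32)
            if name not in self.m:
                self.m[name] = np.zeros_like(params[name])
                self.v[name] = np.zeros_like(params[name])
            self.m[name] = b1 * self.m[name] + (1.0 - b1) * g
            self.v[name] = b2 * self.v[name] + (1.0 - b2) * g * g
            m_hat = self.m[name] / bc1
            v_hat = self.v[name] / bc2
            params[name] -= (lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(np.float32)

    def reset(self) -> None:
        """Drop all moments and the step counter (fresh-optimizer mode)."""
        self.t = 0
        self.m.clear()
        self.v.clear()

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": {k: v.copy() for k, v in self.m.items()},
            "v": {k: v.copy() for k, v in self.v.items()},
            "beta1": self.beta1,
            "beta2": self.beta2,
            "eps": self.eps,
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = {k: np.asarray(v, dtype=np.float32).copy() for k, v in state["m"].items()}
        self.v = {k: np.asarray(v, dtype=np.float32).copy() for k, v in state["v"].items()}
        self.beta1 = float(state["beta1"])
        self.beta2 = float(state["beta2"])
        self.eps = float(state["eps"])
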