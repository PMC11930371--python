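"""Adam optimizer with decoupled-from-nothing classic L2 weight decay.

Weight decay is added to the gradient before the moment updates (the
behaviour of the classic Adam + L2 formulation), matching how segmentation
recipes that quote "Adam with weight decay 1e-6" are normally run.
"""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def state_dict(self) -> dict:
        state = {"t": np.asarray(self.t), "lr": np.asarray(self.lr)}
        for i, (m, v) in enumerate(zip(self._m, self._v)):
            state[f"m.{i}"] = m
            state[f"v.{i}"] = v
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        for i in range(len(self.params)):
            self._m[i] = state[f"m.{i}"].copy()
            self._v[i] = state[f"v.{i}"].copy()
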