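"""Geometry-independent partial charges by constrained charge equilibration.

Each atom gets a predicted electronegativity e_i (kcal/mol/e) and hardness
s_i (kcal/mol/e^2, strictly positive). Charges minimize the quadratic

    sum_i  e_i q_i + s_i q_i^2      subject to   sum_i q_i = Q,

whose closed-form solution via the Lagrange multiplier

    lam = (Q + sum_i e_i/(2 s_i)) / sum_i 1/(2 s_i),
    q_i = (lam - e_i) / (2 s_i)

satisfies the total-charge constraint exactly. The hardness convention
(s q^2 vs s q^2 / 2) only rescales the learned s and is observationally
equivalent after training; the convention above is fixed here.
"""

from __future__ import annotations

import numpy as np

from . import nnet
from .model import E_SCALE, S_FLOOR, S_SCALE, ModelWeights

__all__ = ["predict_e_s", "equilibrate", "equilibrate_backward",
           "charge_loss", "charge_head_maps", "charge_head_map_backward"]


def charge_head_maps(charge_raw: np.ndarray):
    """Map the raw 2-channel charge head output to (e, s); s > S_FLOOR."""
    e = E_SCALE * charge_raw[:, 0]
    s = S_SCALE * nnet.softplus(charge_raw[:, 1]) + S_FLOOR
    return e, s


def charge_head_map_backward(charge_raw: np.ndarray, de: np.ndarray,
                             ds: np.ndarray) -> np.ndarray:
    """dL/d(raw head output) from dL/de and dL/ds."""
    draw = np.zeros_like(charge_raw)
    draw[:, 0] = E_SCALE * de
    draw[:, 1] = S_SCALE * nnet.sigmoid(charge_raw[:, 1]) * ds
    return draw


def predict_e_s(emb: np.ndarray, w: ModelWeights):
    """Per-atom electronegativity and hardness from atom embeddings."""
    p = {k.split("/", 1)[1]: v for k, v in w.params.items()
         if k.startswith("charge/")}
    raw, _ = nnet.mlp2_forward(p, emb)
    raw = raw + emb @ p["Wskip"]
    return charge_head_maps(raw)


def equilibrate(e: np.ndarray, s: np.ndarray, Q: float) -> np.ndarray:
    """Closed-form constrained charge equilibration (see module docstring)."""
    e = np.asarray(e, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if np.any(s <= 0):
        raise ValueError("hardness must be strictly positive")
    a = 1.0 / (2.0 * s)
    lam = (Q + np.sum(a * e)) / np.sum(a)
    return a * (lam - e)


def equilibrate_backward(e: np.ndarray, s: np.ndarray, Q: float,
                         dq: np.ndarray):
    """Gradients of L wrt (e, s) given dL/dq, for the closed form above."""
    a = 1.0 / (2.0 * s)
    A = np.sum(a)
    lam = (Q + np.sum(a * e)) / A
    S = np.sum(dq * a)
    de = a * (S / A - dq)
    da = (lam - e) * (dq - S / A)
    ds = -2.0 * a * a * da
    return de, ds


def charge_loss(q_pred: np.ndarray, q_target: np.ndarray) -> float:
    """Mean squared per-atom deviation from target charges."""
    q_pred = np.asarray(q_pred, dtype=np.float64)
    q_target = np.asarray(q_target, dtype=np.float64)
    if q_pred.shape != q_target.shape:
        raise ValueError(f"charge arrays differ in shape: "
                         f"{q_pred.shape} vs {q_target.shape}")
    return float(np.mean((q_pred - q_target) ** 2))
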