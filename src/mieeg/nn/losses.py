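"""Loss functions returning (scalar loss, gradient w.r.t. the first input)."""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of softmax(logits) against integer labels (0-based)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


def bce_with_logits(scores: np.ndarray, target: float):
    """Mean binary cross-entropy of sigmoid(scores) against a constant target
    (0.0 for fake, 1.0 for real), numerically stable in the logit domain."""
    s = scores.reshape(-1)
    # log(1+exp(-|s|)) formulation
    loss = np.maximum(s, 0) - s * target + np.log1p(np.exp(-np.abs(s)))
    sig = np.empty_like(s)
    pos = s >= 0
    sig[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    sig[~pos] = es / (1.0 + es)
    grad = (sig - target) / s.size
    return float(loss.mean()), grad.reshape(scores.shape)
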