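"""Pair fusion, MLP interaction head and the dual training objective.

A drug-protein pair (i, j) is represented by the concatenation of the
residual-fused modality embeddings, Z = [(p_i + delta*x_i) || (d_j +
gamma*y_j)], where x_i, y_j are the initial encodings mapped to the shared
hidden width by learned linear projections.  Z feeds both the sigmoid MLP
head (binary cross-entropy) and a supervised contrastive term in the
NT-Xent family: pairs sharing an interaction label are pulled together
against all other pairs in the batch.  The total objective is
L_BCE + lambda * L_contrastive.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np

from .autodiff import Tensor, concat, constant

__all__ = [
    "fuse_pairs",
    "fuse_pair",
    "head_forward",
    "predict",
    "contrastive_loss",
    "bce_loss",
    "total_loss",
]

BCE_EPS = 1e-12


def fuse_pairs(
    p_rows: Tensor,
    x_rows: Tensor,
    d_rows: Tensor,
    y_rows: Tensor,
    delta: float,
    gamma: float,
) -> Tensor:
    """Residual fusion for a batch: Z = [(p + delta*x) || (d + gamma*y)].

    `x_rows` / `y_rows` are the initial encodings already mapped to the
    model width (or raw, when widths agree).
    """
    if p_rows.shape != x_rows.shape or d_rows.shape != y_rows.shape:
        raise ValueError(
            f"residual shapes mismatch: {p_rows.shape} vs {x_rows.shape}, "
            f"{d_rows.shape} vs {y_rows.shape}"
        )
    return concat([p_rows + delta * x_rows, d_rows + gamma * y_rows], axis=-1)


def fuse_pair(p_i, x_i, d_j, y_j, delta: float, gamma: float) -> np.ndarray:
    """Single-pair convenience wrapper returning a numpy vector."""
    z = fuse_pairs(
        constant(np.atleast_2d(p_i)),
        constant(np.atleast_2d(x_i)),
        constant(np.atleast_2d(d_j)),
        constant(np.atleast_2d(y_j)),
        delta,
        gamma,
    )
    return z.data[0]


def head_forward(
    z: Tensor, params: Dict[str, Tensor], dropout: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Tensor:
    """MLP head ending in a sigmoid; returns scores strictly in (0, 1)."""
    if not np.isfinite(z.data).all():
        raise FloatingPointError("non-finite fused embeddings passed to the head")
    h = z
    i = 0
    while f"head_W{i}" in params:
        h = h @ params[f"head_W{i}"] + params[f"head_b{i}"]
        if f"head_W{i + 1}" in params:          # hidden layer
            h = h.relu()
            if dropout > 0 and rng is not None:
                keep = (rng.uniform(size=h.shape) >= dropout) / (1.0 - dropout)
                h = h * constant(keep)
        i += 1
    return h.sigmoid().reshape(-1)


def predict(z: np.ndarray, params: Dict[str, Tensor]) -> np.ndarray:
    """Score fused pair embeddings with the trained head (deterministic)."""
    return head_forward(constant(np.atleast_2d(z)), params).data


def contrastive_loss(
    z: Tensor,
    labels: np.ndarray,
    tau_c: float,
    similarity: str = "cosine",
) -> Tensor:
    """Supervised contrastive loss over a batch of fused pair embeddings.

    For each anchor k, the positives P(k) are the other batch members with
    the same interaction label and the denominator runs over all other
    members A(k).  Anchors with no same-label partner are skipped.  The
    default similarity is cosine (temperature-scaled), with ``"dot"``
    available for the raw inner product.
    """
    if tau_c <= 0:
        raise ValueError(f"contrastive temperature must be positive, got {tau_c}")
    nb = z.shape[0]
    if nb < 2:
        raise ValueError("contrastive loss needs a batch of at least 2 pairs")
    labels = np.asarray(labels)
    if similarity == "cosine":
        norms = ((z * z).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        zn = z / norms
    elif similarity == "dot":
        zn = z
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    sims = (zn @ zn.T) * (1.0 / tau_c)                      # (nb, nb)
    off_diag = ~np.eye(nb, dtype=bool)
    same = (labels[:, None] == labels[None, :]) & off_diag
    n_pos = same.sum(axis=1)
    anchors = n_pos > 0
    if not anchors.any():
        warnings.warn("every anchor lacks a same-label partner; contrastive loss = 0")
        return constant(0.0)
    # log softmax over A(k) (all off-diagonal entries), restricted to P(k)
    rowmax = constant(sims.data.max(axis=1, keepdims=True))
    e = (sims - rowmax).exp() * constant(off_diag.astype(float))
    log_denom = e.sum(axis=1, keepdims=True).log() + rowmax
    log_prob = sims - log_denom                             # (nb, nb)
    pos_mask = constant(same.astype(float))
    inv_npos = np.zeros(nb)
    inv_npos[anchors] = 1.0 / n_pos[anchors]
    per_anchor = (log_prob * pos_mask).sum(axis=1) * constant(inv_npos)
    return -(per_anchor.sum() * (1.0 / anchors.sum()))


def bce_loss(scores, labels) -> Tensor:
    """Mean binary cross-entropy with log clamping."""
    if not isinstance(scores, Tensor):
        scores = constant(np.asarray(scores, dtype=float))
    labels = np.asarray(labels, dtype=float)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError(
            f"{scores.shape[0]} scores but {labels.shape[0]} labels"
        )
    s = scores.clip(BCE_EPS, 1.0 - BCE_EPS)
    y = constant(labels)
    ll = y * s.log() + (1.0 - y) * (1.0 - s).log()
    return -ll.mean()


def total_loss(bce: Tensor, contrastive: Tensor, lam: float) -> Tensor:
    """Weighted combination L_BCE + lambda * L_contrastive."""
    if lam < 0:
        raise ValueError(f"contrastive weight must be nonnegative, got {lam}")
    return bce + lam * contrastive
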