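"""Dynamic cross-graph attention stack.

At every layer each protein node's policy network scores every drug node as
"select / not select" (and vice versa), conditioning on the current layer
embeddings and on the structure of the other modality's similarity graph
through a two-layer graph convolution.  Selections are sampled with the
straight-through Gumbel-softmax estimator, so the forward pass uses hard
binary neighbor sets while gradients follow the temperature-controlled soft
relaxation.  Node embeddings are then updated by multi-head attention over
(i) intra-graph neighbors in the node's own similarity graph and (ii) the
dynamically selected cross-graph neighbors, and the head outputs are
averaged.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .autodiff import Tensor, constant
from .graphs import SimilarityGraph

__all__ = [
    "init_params",
    "parameters",
    "gcn_norm_adjacency",
    "cns_policy",
    "cns_forward",
    "gumbel_softmax_st",
    "intra_attention_coeffs",
    "cross_attention_coeffs",
    "layer_update",
    "dcgat_forward",
]

GS_EPS = 1e-10            # probability floor before log
LEAKY_SLOPE = 0.2         # attention-score LeakyReLU slope (GAT convention)


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng, *shape):
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    return Tensor(rng.standard_normal(shape) / np.sqrt(fan_in), requires_grad=True)


def init_params(
    p_dim: int,
    q_dim: int,
    hidden_dim: int,
    n_layers: int,
    n_heads: int,
    cns_hidden: int = 16,
    head_hidden=(64, 32),
    share_cns: bool = False,
    seed: int = 0,
) -> Dict[str, Tensor]:
    """Initialize all learnable tensors for the full model.

    Includes the input projections (protein p_dim -> d, drug q_dim -> d),
    the residual projections used in pair fusion, per-layer CNS policy
    networks and per-layer per-head attention weights, and the MLP head.
    """
    rng = np.random.default_rng(seed)
    d, h = hidden_dim, cns_hidden
    params: Dict[str, Tensor] = {
        "proj_p": _glorot(rng, p_dim, d),
        "proj_d": _glorot(rng, q_dim, d),
        "res_p": _glorot(rng, p_dim, d),
        "res_d": _glorot(rng, q_dim, d),
    }

    def cns_block(prefix):
        params[f"{prefix}_g1"] = _glorot(rng, d, h)
        params[f"{prefix}_g2"] = _glorot(rng, h, h)
        params[f"{prefix}_U"] = _glorot(rng, d, h)
        params[f"{prefix}_V"] = _glorot(rng, h, h)
        params[f"{prefix}_b"] = Tensor(np.zeros(h), requires_grad=True)
        params[f"{prefix}_out"] = _glorot(rng, h, 2)

    n_cns = 1 if share_cns else n_layers
    for layer in range(n_cns):
        cns_block(f"l{layer}_cns_p")
        cns_block(f"l{layer}_cns_d")

    for layer in range(n_layers):
        for head in range(n_heads):
            pre = f"l{layer}_h{head}"
            for side in ("p", "d"):
                params[f"{pre}_W{side}"] = _glorot(rng, d, d)
                params[f"{pre}_phi{side}"] = _glorot(rng, 2 * d)
                params[f"{pre}_Wcr{side}"] = _glorot(rng, d, d)
                params[f"{pre}_phicr{side}"] = _glorot(rng, 2 * d)
                params[f"{pre}_W1{side}"] = _glorot(rng, d, d)
                params[f"{pre}_W2{side}"] = _glorot(rng, d, d)

    widths = [2 * d] + list(head_hidden) + [1]
    for i, (a, b) in enumerate(zip(widths[:-1], widths[1:])):
        params[f"head_W{i}"] = _glorot(rng, a, b)
        params[f"head_b{i}"] = Tensor(np.zeros(b), requires_grad=True)
    return params


def parameters(params: Dict[str, Tensor]) -> List[Tensor]:
    return list(params.values())


# ---------------------------------------------------------------------------
# CNS policy networks


def gcn_norm_adjacency(g: SimilarityGraph) -> np.ndarray:
    """Symmetrically normalized adjacency with self-loops, D^-1/2 (A+I) D^-1/2."""
    a = g.adjacency(include_self=True).astype(np.float64)
    deg = a.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _softmax_last(t: Tensor) -> Tensor:
    shift = t - constant(t.data.max(axis=-1, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=-1, keepdims=True)


def cns_policy(
    query: Tensor,
    cross: Tensor,
    cross_adj_norm: np.ndarray,
    params: Dict[str, Tensor],
    prefix: str,
) -> Tensor:
    """Select/not-select distributions for every (query node, cross node) pair.

    The cross modality is first contextualized by a 2-layer GCN over its own
    similarity graph; a pairwise scorer then emits two logits per candidate,
    normalized to a strictly positive 2-way distribution.

    Returns a Tensor of shape (n_query, n_cross, 2); channel 0 is "select".
    """
    if cross.shape[0] == 0:
        raise ValueError("cross modality is empty; cannot form a selection policy")
    a_hat = constant(cross_adj_norm)
    h1 = (a_hat @ (cross @ params[f"{prefix}_g1"])).relu()
    context = a_hat @ (h1 @ params[f"{prefix}_g2"])          # (n_cross, h)
    qu = query @ params[f"{prefix}_U"]                        # (n_query, h)
    cv = context @ params[f"{prefix}_V"]                      # (n_cross, h)
    nq, nc = qu.shape[0], cv.shape[0]
    hidden = (
        qu.reshape(nq, 1, -1) + cv.reshape(1, nc, -1) + params[f"{prefix}_b"]
    ).tanh()                                                  # (nq, nc, h)
    logits = hidden @ params[f"{prefix}_out"]                 # (nq, nc, 2)
    return _softmax_last(logits)


def cns_forward(
    state_query: np.ndarray,
    state_cross: np.ndarray,
    cross_graph: SimilarityGraph,
    params: Dict[str, Tensor],
    own_node: int,
    side: str = "p",
    layer: int = 0,
) -> np.ndarray:
    """Policy distribution for one node; convenience wrapper over cns_policy."""
    prefix = f"l{layer}_cns_{side}"
    rho = cns_policy(
        constant(state_query[[own_node]]),
        constant(state_cross),
        gcn_norm_adjacency(cross_graph),
        params,
        prefix,
    )
    return rho.data[0]


# ---------------------------------------------------------------------------
# straight-through Gumbel-softmax


def gumbel_softmax_st(
    rho: Tensor,
    temperature: float,
    rng: Optional[np.random.Generator] = None,
    hard: bool = True,
    noise: bool = True,
) -> Tensor:
    """Sample binary select bits from 2-way policy rows.

    `rho` has shape (..., 2) with strictly positive rows summing to 1
    (entries below GS_EPS are floored).  Returns a Tensor of shape (...)
    whose forward value is the hard select bit in {0, 1} and whose backward
    pass follows the soft Gumbel-softmax relaxation at the given
    temperature (straight-through estimator).  With ``noise=False`` and
    T=1 the soft scores reproduce the input distribution exactly.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    floored = rho.clip(GS_EPS, 1.0)
    logits = floored.log()
    if noise:
        if rng is None:
            raise ValueError("sampling with noise requires a seeded generator")
        u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=rho.shape)
        g = constant(-np.log(-np.log(u)))
        scores = (logits + g) * (1.0 / temperature)
    else:
        scores = logits * (1.0 / temperature)
    y = _softmax_last(scores)                         # soft relaxation
    soft_select = (y * constant(np.array([1.0, 0.0]))).sum(axis=-1)
    if not hard:
        return soft_select
    hard_select = (
        y.data[..., 0] >= y.data[..., 1]
    ).astype(np.float64)
    # forward: hard bits; backward: gradient of the soft relaxation
    return soft_select + constant(hard_select - soft_select.data)


# ---------------------------------------------------------------------------
# attention


def _masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row softmax restricted to a fixed boolean mask; empty rows -> zeros."""
    neg = np.where(mask, 0.0, -1e30)
    shifted = scores + constant(neg)
    rowmax = constant(shifted.data.max(axis=-1, keepdims=True))
    e = (shifted - rowmax).exp() * constant(mask.astype(np.float64))
    denom = e.sum(axis=-1, keepdims=True)
    safe = denom + constant((denom.data <= 0).astype(np.float64))
    return e / safe


def _selection_softmax(scores: Tensor, actions: Tensor) -> Tensor:
    """Row softmax over the dynamically selected set.

    `actions` carries hard binary forward values with straight-through
    gradients, so the policy receives gradient through both the numerator
    and the normalization.  Rows with no selected entry return zeros.
    """
    rowmax = constant(scores.data.max(axis=-1, keepdims=True))
    e = (scores - rowmax).exp() * actions
    denom = e.sum(axis=-1, keepdims=True)
    safe = denom + constant((denom.data <= 0).astype(np.float64))
    return e / safe


def _attention_scores(
    query: Tensor, keys: Tensor, w: Tensor, phi: Tensor
) -> Tensor:
    """LeakyReLU(phi^T [W q_i || W k_j]) for all (i, j), via the split of phi."""
    d = w.shape[1]
    qw = query @ w                                    # (a, d)
    kw = keys @ w                                     # (b, d)
    phi2d = phi.reshape(2, d)
    phi1 = phi2d.take([0], axis=0).reshape(d, 1)
    phi2 = phi2d.take([1], axis=0).reshape(d, 1)
    s1 = qw @ phi1                                    # (a, 1)
    s2 = kw @ phi2                                    # (b, 1)
    return (s1 + s2.T).leaky_relu(LEAKY_SLOPE)


def intra_attention_coeffs(
    node_emb: np.ndarray,
    neighbor_embs: np.ndarray,
    w: np.ndarray,
    phi: np.ndarray,
) -> np.ndarray:
    """Attention over a node's intra-graph neighbors (single head).

    alpha_r = softmax_r( LeakyReLU( phi^T [W x_i || W x_r] ) ) over the
    neighbor list; positive, sums to 1.
    """
    scores = _attention_scores(
        constant(node_emb[None, :]), constant(neighbor_embs), constant(w), constant(phi)
    )
    mask = np.ones((1, neighbor_embs.shape[0]), dtype=bool)
    return _masked_softmax(scores, mask).data[0]


def cross_attention_coeffs(
    query_emb: np.ndarray,
    selected_cross_embs: np.ndarray,
    w_cr: np.ndarray,
    phi_cr: np.ndarray,
) -> np.ndarray:
    """Attention over a node's selected cross-graph neighbors (single head)."""
    scores = _attention_scores(
        constant(query_emb[None, :]),
        constant(selected_cross_embs),
        constant(w_cr),
        constant(phi_cr),
    )
    mask = np.ones((1, selected_cross_embs.shape[0]), dtype=bool)
    return _masked_softmax(scores, mask).data[0]


def _head_update(
    own: Tensor,
    cross: Tensor,
    intra_mask: np.ndarray,
    actions: Optional[Tensor],
    params: Dict[str, Tensor],
    pre: str,
    side: str,
    own_keys: Optional[Tensor] = None,
    cross_keys: Optional[Tensor] = None,
) -> Tensor:
    """One attention head's pre-mean update for one modality.

    `own_keys` / `cross_keys` default to the clean embeddings; the noise
    probe passes perturbed copies so that only the neighbor (key/value)
    path is affected while the query path stays clean.
    """
    if own_keys is None:
        own_keys = own
    if cross_keys is None:
        cross_keys = cross
    e_intra = _attention_scores(
        own, own_keys, params[f"{pre}_W{side}"], params[f"{pre}_phi{side}"]
    )
    alpha = _masked_softmax(e_intra, intra_mask)
    intra_term = alpha @ (own_keys @ params[f"{pre}_W1{side}"])
    if actions is not None:
        e_cross = _attention_scores(
            own, cross_keys, params[f"{pre}_Wcr{side}"], params[f"{pre}_phicr{side}"]
        )
        beta = _selection_softmax(e_cross, actions)
        cross_term = beta @ (cross_keys @ params[f"{pre}_W2{side}"])
        pre_act = intra_term + cross_term
    else:
        pre_act = intra_term
    return pre_act.elu()


def layer_update(
    p_state: Tensor,
    d_state: Tensor,
    g_p: SimilarityGraph,
    g_d: SimilarityGraph,
    actions_p: Optional[Tensor],
    actions_d: Optional[Tensor],
    params: Dict[str, Tensor],
    layer: int,
    n_heads: int,
    include_self: bool = True,
    noise_p: Optional[np.ndarray] = None,
    noise_d: Optional[np.ndarray] = None,
) -> tuple:
    """One full layer: multi-head intra+cross attention update of both sides.

    `actions_p` is the (m, n) protein-side selection matrix (drug neighbors
    per protein), `actions_d` the (n, m) drug-side one.  Passing None for an
    action matrix drops the cross term entirely (zero vector), which is the
    empty-selection limit.
    """
    mask_p = g_p.adjacency(include_self=include_self)
    mask_d = g_d.adjacency(include_self=include_self)
    p_keys = p_state + constant(noise_p) if noise_p is not None else None
    d_keys = d_state + constant(noise_d) if noise_d is not None else None
    p_heads, d_heads = [], []
    for head in range(n_heads):
        pre = f"l{layer}_h{head}"
        p_heads.append(
            _head_update(
                p_state, d_state, mask_p, actions_p, params, pre, "p",
                own_keys=p_keys, cross_keys=d_keys,
            )
        )
        d_heads.append(
            _head_update(
                d_state, p_state, mask_d, actions_d, params, pre, "d",
                own_keys=d_keys, cross_keys=p_keys,
            )
        )
    inv_h = 1.0 / n_heads
    p_new = p_heads[0] * inv_h
    d_new = d_heads[0] * inv_h
    for t in p_heads[1:]:
        p_new = p_new + t * inv_h
    for t in d_heads[1:]:
        d_new = d_new + t * inv_h
    for name, t in (("protein", p_new), ("drug", d_new)):
        if not np.isfinite(t.data).all():
            raise FloatingPointError(
                f"non-finite {name} embeddings at layer {layer}"
            )
    return p_new, d_new


def dcgat_forward(
    x: np.ndarray,
    y: np.ndarray,
    g_p: SimilarityGraph,
    g_d: SimilarityGraph,
    params: Dict[str, Tensor],
    n_layers: int,
    n_heads: int,
    temperature: float,
    rng: Optional[np.random.Generator] = None,
    train_mode: bool = True,
    include_self: bool = True,
    share_cns: bool = False,
    select_all: bool = False,
    noise_sd: float = 0.0,
    noise_rng: Optional[np.random.Generator] = None,
):
    """Run the full stack: input projection then n_layers of select+attend.

    In train mode selections are Gumbel-softmax samples (fresh draw per node
    per layer); in eval mode they are the deterministic argmax of the policy.
    ``select_all=True`` short-circuits the policy and selects every
    cross-modal candidate (the "without dynamic neighborhood" ablation).
    ``noise_sd`` adds seeded Gaussian noise to neighbor embeddings prior to
    aggregation (robustness probe); the query path stays clean.

    Returns (P, D, selection_log) where P, D are Tensors and selection_log
    is a list of dicts with per-layer per-side selected fractions.
    """
    p_state = constant(x) @ params["proj_p"]
    d_state = constant(y) @ params["proj_d"]
    a_hat_p = gcn_norm_adjacency(g_p)
    a_hat_d = gcn_norm_adjacency(g_d)
    m, n = x.shape[0], y.shape[0]
    selection_log = []
    for layer in range(n_layers):
        cns_layer = 0 if share_cns else layer
        if select_all:
            actions_p = constant(np.ones((m, n)))
            actions_d = constant(np.ones((n, m)))
        else:
            rho_p = cns_policy(p_state, d_state, a_hat_d, params, f"l{cns_layer}_cns_p")
            rho_d = cns_policy(d_state, p_state, a_hat_p, params, f"l{cns_layer}_cns_d")
            if train_mode:
                actions_p = gumbel_softmax_st(rho_p, temperature, rng)
                actions_d = gumbel_softmax_st(rho_d, temperature, rng)
            else:
                actions_p = constant(
                    (rho_p.data[..., 0] >= rho_p.data[..., 1]).astype(np.float64)
                )
                actions_d = constant(
                    (rho_d.data[..., 0] >= rho_d.data[..., 1]).astype(np.float64)
                )
        noise_p = noise_d = None
        if noise_sd > 0:
            gen = noise_rng if noise_rng is not None else rng
            noise_p = noise_sd * gen.standard_normal(p_state.shape)
            noise_d = noise_sd * gen.standard_normal(d_state.shape)
        selection_log.append(
            {
                "layer": layer,
                "protein_selected_fraction": actions_p.data.mean(axis=1),
                "drug_selected_fraction": actions_d.data.mean(axis=1),
            }
        )
        p_state, d_state = layer_update(
            p_state, d_state, g_p, g_d, actions_p, actions_d, params,
            layer, n_heads, include_self=include_self,
            noise_p=noise_p, noise_d=noise_d,
        )
    return p_state, d_state, selection_log
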