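"""Scikit-learn style estimator wrapping the cross-graph attention model.

`DCGATClassifier` is a binary classifier over (drug_id, protein_id) pairs.
The entity embedding matrices are constructor parameters (like a
precomputed vocabulary); ``X`` in `fit`/`predict` is an (n_pairs, 2) array
of ``[drug_id, protein_id]`` strings.  Similarity graphs are built over the
full embedding universe (whole-split scope); probes may rescore pairs
inside restricted entity contexts.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import core, objectives
from .autodiff import Adam, Tensor, constant
from .graphs import SimilarityGraph, build_graph
from .io import EmbeddingMatrix

__all__ = ["DCGATClassifier", "VARIANTS"]

VARIANTS = ("full", "no_dcgat", "no_contrastive", "no_dynamic_neighborhood")


def _as_pairs(X) -> np.ndarray:
    arr = np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"X must be (n_pairs, 2) of [drug_id, protein_id], got {arr.shape}")
    return arr.astype(str)


class DCGATClassifier(BaseEstimator, ClassifierMixin):
    """Drug-target interaction classifier with dynamic cross-graph attention.

    Parameters
    ----------
    protein_embeddings, drug_embeddings : EmbeddingMatrix
        Initial encodings for every entity that can appear in a pair.
    hidden_dim : int
        Shared width d of the projected node embeddings.
    n_layers, n_heads : int
        Depth of the attention stack and heads per layer.
    temperature : float
        Gumbel-softmax temperature T controlling selection sharpness.
    threshold_percentile / threshold_absolute : float
        Similarity-graph threshold, as a percentile of off-diagonal
        distances (default) or an absolute Euclidean distance.
    delta, gamma : float
        Residual-connection scales for the initial encodings in pair fusion.
    lam, tau_c : float
        Contrastive loss weight and temperature.
    variant : str
        "full", "no_dcgat" (skip the attention stack), "no_contrastive"
        (lam treated as 0) or "no_dynamic_neighborhood" (select every
        cross-modal candidate).

    Attributes
    ----------
    params_ : dict of named parameter tensors after fitting.
    protein_graph_, drug_graph_ : the similarity graphs used in training.
    history_ : per-epoch training losses (and validation AUROC if given).
    """

    def __init__(
        self,
        protein_embeddings: Optional[EmbeddingMatrix] = None,
        drug_embeddings: Optional[EmbeddingMatrix] = None,
        hidden_dim: int = 32,
        n_layers: int = 2,
        n_heads: int = 2,
        cns_hidden: int = 16,
        temperature: float = 1.0,
        threshold_percentile: float = 10.0,
        threshold_absolute: Optional[float] = None,
        normalize_embeddings: bool = False,
        include_self: bool = True,
        share_cns: bool = False,
        delta: float = 1.0,
        gamma: float = 1.0,
        lam: float = 0.1,
        tau_c: float = 0.5,
        contrastive_similarity: str = "cosine",
        head_hidden=(64, 32),
        dropout: float = 0.0,
        learning_rate: float = 1e-3,
        batch_size: int = 128,
        max_epochs: int = 200,
        patience: int = 20,
        variant: str = "full",
        random_state: int = 0,
    ):
        self.protein_embeddings = protein_embeddings
        self.drug_embeddings = drug_embeddings
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.cns_hidden = cns_hidden
        self.temperature = temperature
        self.threshold_percentile = threshold_percentile
        self.threshold_absolute = threshold_absolute
        self.normalize_embeddings = normalize_embeddings
        self.include_self = include_self
        self.share_cns = share_cns
        self.delta = delta
        self.gamma = gamma
        self.lam = lam
        self.tau_c = tau_c
        self.contrastive_similarity = contrastive_similarity
        self.head_hidden = head_hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.variant = variant
        self.random_state = random_state

    # ------------------------------------------------------------------ setup
    def _threshold_spec(self) -> dict:
        if self.threshold_absolute is not None:
            return {"absolute": self.threshold_absolute}
        return {"percentile": self.threshold_percentile}

    def _check_setup(self):
        if self.protein_embeddings is None or self.drug_embeddings is None:
            raise ValueError("protein_embeddings and drug_embeddings are required")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")

    def _pair_indices(self, pairs: np.ndarray, pidx: dict, didx: dict):
        missing = []
        for d, p in pairs:
            if d not in didx:
                missing.append(d)
            if p not in pidx:
                missing.append(p)
        if missing:
            raise KeyError(f"IDs missing from embeddings: {sorted(set(missing))[:10]}")
        di = np.array([didx[d] for d, _ in pairs], dtype=int)
        pi = np.array([pidx[p] for _, p in pairs], dtype=int)
        return di, pi

    def _forward(
        self,
        x: np.ndarray,
        y: np.ndarray,
        g_p: SimilarityGraph,
        g_d: SimilarityGraph,
        train_mode: bool,
        rng: Optional[np.random.Generator],
        noise_sd: float = 0.0,
        noise_rng: Optional[np.random.Generator] = None,
    ):
        if self.variant == "no_dcgat":
            p_state = constant(x) @ self.params_["proj_p"]
            d_state = constant(y) @ self.params_["proj_d"]
            return p_state, d_state, []
        return core.dcgat_forward(
            x, y, g_p, g_d, self.params_,
            n_layers=self.n_layers, n_heads=self.n_heads,
            temperature=self.temperature, rng=rng, train_mode=train_mode,
            include_self=self.include_self, share_cns=self.share_cns,
            select_all=(self.variant == "no_dynamic_neighborhood"),
            noise_sd=noise_sd, noise_rng=noise_rng,
        )

    def _fuse_scores(self, p_state, d_state, x, y, pi, di, rng=None, train=False):
        p_rows = p_state.take(pi, axis=0)
        d_rows = d_state.take(di, axis=0)
        x_res = (constant(x) @ self.params_["res_p"]).take(pi, axis=0)
        y_res = (constant(y) @ self.params_["res_d"]).take(di, axis=0)
        z = objectives.fuse_pairs(p_rows, x_res, d_rows, y_res, self.delta, self.gamma)
        scores = objectives.head_forward(
            z, self.params_, dropout=self.dropout if train else 0.0, rng=rng
        )
        return z, scores

    # -------------------------------------------------------------------- fit
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (drug_id, protein_id) pairs with binary labels.

        If a validation set is given, training early-stops on validation
        AUROC with the configured patience and the best parameters are
        restored.
        """
        self._check_setup()
        pairs = _as_pairs(X)
        labels = np.asarray(y, dtype=int)
        if set(np.unique(labels)) - {0, 1}:
            raise ValueError("labels must be binary")
        self.classes_ = np.array([0, 1])

        pe, de = self.protein_embeddings, self.drug_embeddings
        spec = self._threshold_spec()
        self.protein_graph_ = build_graph(pe, spec, normalize=self.normalize_embeddings)
        self.drug_graph_ = build_graph(de, spec, normalize=self.normalize_embeddings)
        self._pidx = pe.index_of()
        self._didx = de.index_of()
        di, pi = self._pair_indices(pairs, self._pidx, self._didx)

        self.params_ = core.init_params(
            pe.dim, de.dim, self.hidden_dim, self.n_layers, self.n_heads,
            cns_hidden=self.cns_hidden, head_hidden=self.head_hidden,
            share_cns=self.share_cns, seed=self.random_state,
        )
        plist = core.parameters(self.params_)
        opt = Adam(plist, lr=self.learning_rate)
        rng = np.random.default_rng(self.random_state)
        eff_lam = 0.0 if self.variant == "no_contrastive" else self.lam

        n = len(pairs)
        history = {"epoch": [], "loss": [], "bce": [], "contrastive": [], "val_auroc": []}
        # early stopping on val AUROC; ties (e.g. a saturated small validation
        # set) broken by validation BCE so training can keep improving
        best_auroc, best_vloss, best_snapshot, since_best = -np.inf, np.inf, None, 0
        last_finite = [p.data.copy() for p in plist]
        diverged = False

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            batches = [
                order[s : s + self.batch_size] for s in range(0, n, self.batch_size)
            ]
            if len(batches) > 1 and len(batches[-1]) < 2:
                batches[-2] = np.concatenate([batches[-2], batches[-1]])
                batches.pop()
            ep_loss, ep_bce, ep_con = [], [], []
            for batch in batches:
                opt.zero_grad()
                p_state, d_state, _ = self._forward(
                    pe.values, de.values, self.protein_graph_, self.drug_graph_,
                    train_mode=True, rng=rng,
                )
                z, scores = self._fuse_scores(
                    p_state, d_state, pe.values, de.values,
                    pi[batch], di[batch], rng=rng, train=True,
                )
                bce = objectives.bce_loss(scores, labels[batch])
                if eff_lam > 0 and len(batch) >= 2:
                    con = objectives.contrastive_loss(
                        z, labels[batch], self.tau_c, self.contrastive_similarity
                    )
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        con = constant(
                            objectives.contrastive_loss(
                                z.detach(), labels[batch], self.tau_c,
                                self.contrastive_similarity,
                            ).item()
                            if len(batch) >= 2 else 0.0
                        )
                loss = objectives.total_loss(bce, con, eff_lam)
                if not np.isfinite(loss.item()):
                    diverged = True
                    break
                loss.backward()
                opt.step()
                ep_loss.append(loss.item())
                ep_bce.append(bce.item())
                ep_con.append(con.item())
            if diverged:
                warnings.warn(
                    f"non-finite loss at epoch {epoch}; restoring last finite parameters"
                )
                for p, snap in zip(plist, last_finite):
                    p.data = snap
                break
            last_finite = [p.data.copy() for p in plist]
            history["epoch"].append(epoch)
            history["loss"].append(float(np.mean(ep_loss)))
            history["bce"].append(float(np.mean(ep_bce)))
            history["contrastive"].append(float(np.mean(ep_con)))

            if X_val is not None and len(np.unique(y_val)) == 2:
                val_scores = self.predict_proba(X_val)[:, 1]
                val_auroc = roc_auc_score(y_val, val_scores)
                val_loss = objectives.bce_loss(val_scores, np.asarray(y_val)).item()
                history["val_auroc"].append(float(val_auroc))
                improved = val_auroc > best_auroc + 1e-12 or (
                    val_auroc >= best_auroc - 1e-12 and val_loss < best_vloss - 1e-12
                )
                if improved:
                    best_auroc = max(best_auroc, val_auroc)
                    best_vloss = min(best_vloss, val_loss)
                    best_snapshot = [p.data.copy() for p in plist]
                    since_best = 0
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
            else:
                history["val_auroc"].append(np.nan)

        if best_snapshot is not None:
            for p, snap in zip(plist, best_snapshot):
                p.data = snap
        self.history_ = history
        self.n_features_in_ = 2
        return self

    # ---------------------------------------------------------------- predict
    def _context_graphs(self, context_drugs, context_proteins):
        pe, de = self.protein_embeddings, self.drug_embeddings
        if context_proteins is None and context_drugs is None:
            return pe, de, self.protein_graph_, self.drug_graph_
        pe_sub = pe.subset(context_proteins) if context_proteins is not None else pe
        de_sub = de.subset(context_drugs) if context_drugs is not None else de
        spec = self._threshold_spec()
        g_p = build_graph(pe_sub, spec, normalize=self.normalize_embeddings)
        g_d = build_graph(de_sub, spec, normalize=self.normalize_embeddings)
        return pe_sub, de_sub, g_p, g_d

    def predict_proba(
        self,
        X,
        context_drugs: Optional[Sequence[str]] = None,
        context_proteins: Optional[Sequence[str]] = None,
        noise_sd: float = 0.0,
        noise_seed: int = 0,
    ) -> np.ndarray:
        """Deterministic scores; selections are the policy argmax (no noise).

        `context_drugs` / `context_proteins` restrict the entity universe
        over which the similarity graphs are rebuilt (batch-context
        scoring); `noise_sd` perturbs neighbor embeddings before
        aggregation (robustness probe).
        """
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        pairs = _as_pairs(X)
        pe, de, g_p, g_d = self._context_graphs(context_drugs, context_proteins)
        di, pi = self._pair_indices(pairs, pe.index_of(), de.index_of())
        noise_rng = np.random.default_rng(noise_seed) if noise_sd > 0 else None
        p_state, d_state, self.selection_log_ = self._forward(
            pe.values, de.values, g_p, g_d, train_mode=False, rng=None,
            noise_sd=noise_sd, noise_rng=noise_rng,
        )
        _, scores = self._fuse_scores(p_state, d_state, pe.values, de.values, pi, di)
        s = scores.data
        return np.column_stack([1.0 - s, s])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    # ------------------------------------------------------------- checkpoint
    def save(self, path) -> None:
        """Write parameters and architecture config to a single .npz archive."""
        import json

        cfg = {k: v for k, v in self.get_params().items()
               if k not in ("protein_embeddings", "drug_embeddings")}
        cfg["head_hidden"] = list(cfg["head_hidden"])
        arrays = {f"param:{k}": t.data for k, t in self.params_.items()}
        np.savez(path, __config__=np.array(json.dumps(cfg)), **arrays)

    @classmethod
    def load(cls, path, protein_embeddings, drug_embeddings) -> "DCGATClassifier":
        import json

        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            cfg["head_hidden"] = tuple(cfg["head_hidden"])
            est = cls(
                protein_embeddings=protein_embeddings,
                drug_embeddings=drug_embeddings,
                **cfg,
            )
            est.params_ = {
                k[len("param:"):]: Tensor(z[k], requires_grad=True)
                for k in z.files if k.startswith("param:")
            }
        est.classes_ = np.array([0, 1])
        spec = est._threshold_spec()
        est.protein_graph_ = build_graph(
            protein_embeddings, spec, normalize=est.normalize_embeddings
        )
        est.drug_graph_ = build_graph(
            drug_embeddings, spec, normalize=est.normalize_embeddings
        )
        est.history_ = {}
        return est
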