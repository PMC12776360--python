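"""Splits, negative sampling, metrics and the robustness diagnostics.

Split strategies follow the standard DTI evaluation protocol: *warm*
partitions interaction pairs, while *cold_drug* / *cold_protein* partition
the entities themselves so that test-set drugs (or proteins) are never seen
in training.  Negatives are sampled uniformly from unobserved pairs at a
configurable ratio per positive (1 for the balanced setting, 10 for the
unbalanced one), restricted to each partition's allowed entities.

Metrics: AUROC/AUPRC (scikit-learn), plus the virtual-screening metrics —
enrichment factor at percentage cutoffs and the Truchon-Bayly BEDROC score
(default alpha = 80.5), which discounts actives retrieved late in the
ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

from .estimator import DCGATClassifier, VARIANTS
from .io import EmbeddingMatrix, InteractionTable

__all__ = [
    "SplitSpec",
    "EvalReport",
    "make_split",
    "train_model",
    "evaluate_model",
    "auroc_auprc",
    "enrichment_factor",
    "bedroc",
    "temperature_sweep",
    "noise_robustness_probe",
    "batch_stability_probe",
    "ablation_suite",
]

STRATEGIES = ("warm", "cold_drug", "cold_protein")


@dataclass
class SplitSpec:
    strategy: str = "warm"
    ratios: Tuple[float, float, float] = (0.79, 0.01, 0.20)
    seed: int = 0
    negative_ratio: int = 1

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if abs(sum(self.ratios) - 1.0) > 1e-9 or any(r < 0 for r in self.ratios):
            raise ValueError(f"ratios must be nonnegative and sum to 1, got {self.ratios}")
        if self.negative_ratio < 1:
            raise ValueError("negative_ratio must be a positive integer")


@dataclass
class EvalReport:
    auroc: float
    auprc: float
    ef: Dict[float, float]
    bedroc: float
    n_repeats: int = 1
    per_repeat: pd.DataFrame = field(default_factory=pd.DataFrame)


def _partition_counts(n: int, ratios) -> Tuple[int, int, int]:
    # floor for val and test; remainder to train
    n_val = math.floor(ratios[1] * n)
    n_test = math.floor(ratios[2] * n)
    return n - n_val - n_test, n_val, n_test


def _sample_negatives(
    rng, drugs, proteins, pos_set, count
) -> List[Tuple[str, str, int]]:
    candidates = [
        (d, p) for d in drugs for p in proteins if (d, p) not in pos_set
    ]
    if count > len(candidates):
        count = len(candidates)  # maximum achievable ratio
    chosen = rng.choice(len(candidates), size=count, replace=False)
    return [(candidates[i][0], candidates[i][1], 0) for i in sorted(chosen)]


def make_split(
    interactions: InteractionTable,
    all_drugs: Sequence[str],
    all_proteins: Sequence[str],
    spec: SplitSpec,
) -> Tuple[InteractionTable, InteractionTable, InteractionTable]:
    """Partition positives per strategy and attach sampled negatives.

    Cold strategies partition the cold-side entities at the given ratios
    (by entity count); each positive pair inherits the partition of its
    cold-side entity.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    positives = interactions.positives()
    pos_set = set(positives)
    parts: List[List[Tuple[str, str]]] = [[], [], []]

    if spec.strategy == "warm":
        order = rng.permutation(len(positives))
        n_train, n_val, n_test = _partition_counts(len(positives), spec.ratios)
        for rank, idx in enumerate(order):
            part = 0 if rank < n_train else (1 if rank < n_train + n_val else 2)
            parts[part].append(positives[idx])
        entity_parts = None
    else:
        side = 0 if spec.strategy == "cold_drug" else 1
        entities = sorted({pair[side] for pair in positives})
        if len(entities) < 3:
            raise ValueError(
                f"{spec.strategy} split infeasible with {len(entities)} distinct entities"
            )
        order = rng.permutation(len(entities))
        n_train, n_val, n_test = _partition_counts(len(entities), spec.ratios)
        entity_parts = {}
        for rank, idx in enumerate(order):
            part = 0 if rank < n_train else (1 if rank < n_train + n_val else 2)
            entity_parts[entities[idx]] = part
        for pair in positives:
            parts[entity_parts[pair[side]]].append(pair)

    tables = []
    names = ("train", "val", "test")
    for part_idx, part_pos in enumerate(parts):
        if spec.strategy == "warm":
            neg_drugs, neg_proteins = list(all_drugs), list(all_proteins)
        elif spec.strategy == "cold_drug":
            neg_drugs = [d for d in all_drugs if entity_parts.get(d, 0) == part_idx]
            neg_proteins = list(all_proteins)
        else:
            neg_drugs = list(all_drugs)
            neg_proteins = [p for p in all_proteins if entity_parts.get(p, 0) == part_idx]
        records = [(d, p, 1) for d, p in part_pos]
        if part_pos and neg_drugs and neg_proteins:
            records += _sample_negatives(
                rng, neg_drugs, neg_proteins, pos_set,
                spec.negative_ratio * len(part_pos),
            )
        tables.append(
            InteractionTable(records, provenance=f"{interactions.provenance}:{names[part_idx]}")
        )
    return tuple(tables)


def _xy(table: InteractionTable):
    x = np.array([[d, p] for d, p, _ in table.records])
    return x, table.labels


def train_model(
    proteins: EmbeddingMatrix,
    drugs: EmbeddingMatrix,
    train_table: InteractionTable,
    val_table: Optional[InteractionTable] = None,
    **params,
) -> DCGATClassifier:
    """Fit a classifier on a training table (thin wrapper over the estimator)."""
    est = DCGATClassifier(
        protein_embeddings=proteins, drug_embeddings=drugs, **params
    )
    x_tr, y_tr = _xy(train_table)
    if val_table is not None and len(val_table) and len(set(val_table.labels)) == 2:
        x_va, y_va = _xy(val_table)
        est.fit(x_tr, y_tr, X_val=x_va, y_val=y_va)
    else:
        est.fit(x_tr, y_tr)
    return est


def evaluate_model(
    est: DCGATClassifier,
    test_table: InteractionTable,
    ef_cutoffs=(0.5, 1.0, 2.0),
    bedroc_alpha: float = 80.5,
) -> EvalReport:
    x_te, y_te = _xy(test_table)
    scores = est.predict_proba(x_te)[:, 1]
    auroc, auprc = auroc_auprc(scores, y_te)
    ef = {}
    for c in ef_cutoffs:
        k = math.ceil(c / 100.0 * len(y_te))
        ef[c] = enrichment_factor(scores, y_te, c) if k >= 1 else float("nan")
    return EvalReport(auroc=auroc, auprc=auprc, ef=ef, bedroc=bedroc(scores, y_te, bedroc_alpha))


# ---------------------------------------------------------------------------
# metrics


def auroc_auprc(scores, labels) -> Tuple[float, float]:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC/AUPRC need both classes present")
    return (
        float(roc_auc_score(labels, scores)),
        float(average_precision_score(labels, scores)),
    )


def _ranking(scores, labels):
    """Stable descending-score order; ties broken by original index."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.lexsort((np.arange(len(scores)), -scores))
    return labels[order]


def enrichment_factor(scores, labels, cutoff_pct: float) -> float:
    """Fold enrichment of actives in the top cutoff_pct% of the ranking."""
    ranked = _ranking(scores, labels)
    n = len(ranked)
    n_act = int(ranked.sum())
    if n_act == 0:
        raise ValueError("enrichment factor undefined with no actives")
    k = math.ceil(cutoff_pct / 100.0 * n)
    if k < 1:
        raise ValueError(f"cutoff {cutoff_pct}% yields an empty top list for N={n}")
    return float((ranked[:k].sum() / k) / (n_act / n))


def bedroc(scores, labels, alpha: float = 80.5) -> float:
    """Truchon-Bayly BEDROC: RIE normalized to [0, 1] at the given alpha."""
    ranked = _ranking(scores, labels)
    n = len(ranked)
    n_act = int(ranked.sum())
    if n_act == 0 or n_act == n:
        raise ValueError("BEDROC needs at least one active and one inactive")
    ra = n_act / n
    ranks = np.flatnonzero(ranked) + 1                     # 1-based active ranks
    s = np.exp(-alpha * ranks / n).sum()
    rie_denom = ra * (1 - np.exp(-alpha)) / (np.exp(alpha / n) - 1)
    rie = s / rie_denom
    factor = ra * np.sinh(alpha / 2) / (np.cosh(alpha / 2) - np.cosh(alpha / 2 - alpha * ra))
    const = 1.0 / (1 - np.exp(alpha * (1 - ra)))
    return float(rie * factor + const)


# ---------------------------------------------------------------------------
# diagnostics


def temperature_sweep(
    est: DCGATClassifier,
    temperatures: Sequence[float],
    n_samples: int = 200,
    seed: int = 0,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Selection strength per Gumbel-softmax temperature on the fitted policies.

    Two measures are reported per temperature.  ``selected_fraction_hard``
    is the frequency of the hard select bit: for a 2-way policy the argmax
    of the perturbed logits equals ``rho_select`` at every temperature, so
    this column is temperature-invariant by construction.  The quantity
    that temperature actually controls is ``selected_fraction_soft`` — the
    mean of the soft relaxation's select coordinate — which flattens toward
    0.5 as T grows and sharpens toward the hard frequency as T shrinks:
    with a policy favoring "not select", higher temperature means more
    selection mass.
    """
    from . import core
    from .autodiff import constant

    pe, de = est.protein_embeddings, est.drug_embeddings
    a_hat_d = core.gcn_norm_adjacency(est.drug_graph_)
    p_state = constant(pe.values) @ est.params_["proj_p"]
    d_state = constant(de.values) @ est.params_["proj_d"]
    rho_p = core.cns_policy(p_state, d_state, a_hat_d, est.params_, "l0_cns_p")
    rows = []
    for t in temperatures:
        rng = np.random.default_rng(seed)
        for rep in range(n_samples):
            hard = core.gumbel_softmax_st(rho_p.detach(), t, rng)
            rng_soft = np.random.default_rng(seed + rep)
            soft = core.gumbel_softmax_st(rho_p.detach(), t, rng_soft, hard=False)
            rows.append({
                "temperature": t, "repeat": rep,
                "selected_fraction_hard": float(hard.data.mean()),
                "selected_fraction_soft": float(soft.data.mean()),
            })
    df = pd.DataFrame(rows)
    if per_sample:
        return df
    return (
        df.groupby("temperature", as_index=False)
        [["selected_fraction_hard", "selected_fraction_soft"]].mean()
        .assign(n_samples=n_samples)
    )


def noise_robustness_probe(
    est: DCGATClassifier,
    test_table: InteractionTable,
    sigmas: Sequence[float],
    seed: int = 0,
) -> pd.DataFrame:
    """Test AUROC with Gaussian noise on neighbor embeddings pre-aggregation."""
    x_te, y_te = _xy(test_table)
    rows = []
    for sd in sorted(sigmas):
        scores = est.predict_proba(x_te, noise_sd=sd, noise_seed=seed)[:, 1]
        auroc, _ = auroc_auprc(scores, y_te)
        rows.append({"sigma": sd, "auroc": auroc})
    return pd.DataFrame(rows)


def batch_stability_probe(
    est: DCGATClassifier,
    anchors: Sequence[Tuple[str, str]],
    n_contexts: int = 30,
    context_size: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Score anchors inside randomly re-sampled batch similarity contexts.

    Each context co-samples `context_size` drugs and proteins (always
    including the anchor's own entities), rebuilds the similarity graphs on
    that subset, and rescores every anchor in deterministic-inference mode.
    """
    rng = np.random.default_rng(seed)
    pe, de = est.protein_embeddings, est.drug_embeddings
    for d, p in anchors:
        if d not in de.index_of() or p not in pe.index_of():
            raise KeyError(f"anchor ({d}, {p}) missing from embeddings")
    anchor_drugs = [d for d, _ in anchors]
    anchor_prots = [p for _, p in anchors]
    scores = np.zeros((len(anchors), n_contexts))
    for c in range(n_contexts):
        extra_d = rng.choice(
            [i for i in de.ids if i not in anchor_drugs],
            size=min(context_size, de.n_entities - len(set(anchor_drugs))),
            replace=False,
        )
        extra_p = rng.choice(
            [i for i in pe.ids if i not in anchor_prots],
            size=min(context_size, pe.n_entities - len(set(anchor_prots))),
            replace=False,
        )
        ctx_d = sorted(set(anchor_drugs)) + list(extra_d)
        ctx_p = sorted(set(anchor_prots)) + list(extra_p)
        s = est.predict_proba(
            np.array(anchors), context_drugs=ctx_d, context_proteins=ctx_p
        )[:, 1]
        scores[:, c] = s
    rows = []
    for i, (d, p) in enumerate(anchors):
        q = np.percentile(scores[i], [25, 50, 75])
        rows.append({
            "drug_id": d, "protein_id": p,
            "mean": scores[i].mean(), "sd": scores[i].std(),
            "q25": q[0], "median": q[1], "q75": q[2],
        })
    return pd.DataFrame(rows)


def ablation_suite(
    proteins: EmbeddingMatrix,
    drugs: EmbeddingMatrix,
    interactions: InteractionTable,
    split_spec: SplitSpec,
    n_repeats: int = 10,
    variants: Sequence[str] = VARIANTS,
    alpha: float = 0.05,
    **model_params,
) -> Dict:
    """Train and evaluate each model variant under one repeated-seed protocol.

    Every variant sees the same sequence of splits (seeds seed+0..n-1); the
    full model is compared with each reduced variant by a one-sided
    rank-sum test on per-repeat AUROC.
    """
    records = []
    for variant in variants:
        for rep in range(n_repeats):
            spec = SplitSpec(
                strategy=split_spec.strategy, ratios=split_spec.ratios,
                seed=split_spec.seed + rep, negative_ratio=split_spec.negative_ratio,
            )
            train_t, val_t, test_t = make_split(
                interactions, drugs.ids, proteins.ids, spec
            )
            est = train_model(
                proteins, drugs, train_t, val_t,
                variant=variant, random_state=split_spec.seed + rep,
                **model_params,
            )
            rep_report = evaluate_model(est, test_t)
            records.append({
                "variant": variant, "repeat": rep,
                "auroc": rep_report.auroc, "auprc": rep_report.auprc,
                "lam_effective": 0.0 if variant == "no_contrastive"
                else est.get_params()["lam"],
            })
    df = pd.DataFrame(records)
    summary = df.groupby("variant")[["auroc", "auprc"]].agg(["mean", "std"])
    tests = {}
    full = df[df.variant == "full"]["auroc"].values
    for variant in variants:
        if variant == "full":
            continue
        other = df[df.variant == variant]["auroc"].values
        stat = mannwhitneyu(full, other, alternative="greater")
        tests[variant] = {
            "pvalue": float(stat.pvalue),
            "significant": bool(stat.pvalue < alpha),
        }
    return {"per_repeat": df, "summary": summary, "rank_sum_vs_full": tests}
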