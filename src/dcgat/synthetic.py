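"""Synthetic drug-protein interaction data with planted cross-modal structure.

The generator emulates the statistical premise the similarity graphs
exploit: entities in each modality fall into latent clusters ("similar
drugs bind similar proteins"), and interaction propensity is bilinear in
the latent factors.  Protein latents u_i and drug latents v_j are drawn
around K shared cluster centers; observed embeddings are fixed random
linear images of the latents plus Gaussian observation noise; a pair
interacts with probability sigmoid(scale * <u_i, v_j> + b), with the bias b
solved so the expected prevalence matches the requested positive rate.
Only the sampled positive pairs are emitted as the interaction table,
mirroring real DTI datasets where non-interactions are unobserved.

Regimes
-------
separable
    Defaults; clear cluster structure in both modalities, strong signal.
noisy_cross_modality
    Drug-side observation noise inflated 20x, largely swamping the raw drug
    encodings (and the drug similarity graph built from them) while the
    latent interaction signal is unchanged.  Paired with scarce supervision
    this is the regime where selective cross-modal aggregation matters:
    attending indiscriminately to the corrupted modality injects noise.
null
    Positive pairs reassigned uniformly at random (same count), severing
    the embedding-label association.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np

from .io import EmbeddingMatrix, InteractionTable

__all__ = ["SynthConfig", "generate", "fixture_small", "bayes_scores"]

REGIMES = ("separable", "noisy_cross_modality", "null")

# within-cluster latent spread, as a fraction of the unit center scale
_CLUSTER_SPREAD = 0.25
_NOISY_FACTOR = 20.0


@dataclass
class SynthConfig:
    m: int = 100                  # proteins
    n: int = 100                  # drugs
    p: int = 32                   # protein embedding width
    q: int = 32                   # drug embedding width
    K: int = 5                    # latent clusters
    latent_dim: int = 8
    noise_sd: float = 0.1
    interaction_scale: float = 3.0
    positive_rate: float = 0.15
    seed: int = 0
    regime: str = "separable"

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if not 0 < self.positive_rate < 1:
            raise ValueError(f"positive_rate must be in (0,1), got {self.positive_rate}")
        if self.K > min(self.m, self.n):
            raise ValueError("K must not exceed min(m, n)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.positive_rate * self.m * self.n < 1:
            raise ValueError("positive_rate unreachable: expected <1 positive pair")


def _solve_bias(logits_nobias: np.ndarray, target: float) -> float:
    """Bisection for b with mean(sigmoid(logits + b)) = target."""
    lo, hi = -60.0, 60.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        prev = 1.0 / (1.0 + np.exp(-(logits_nobias + mid)))
        if prev.mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(
    config: SynthConfig,
) -> Tuple[EmbeddingMatrix, EmbeddingMatrix, InteractionTable, Dict]:
    """Draw one dataset; returns (proteins, drugs, interactions, truth).

    `truth` records the latent factors, cluster assignments, bias and the
    full probability matrix for diagnostics (e.g. the Bayes-optimal
    ranking, which upper-bounds any model's achievable AUROC).
    """
    rng = np.random.default_rng(config.seed)
    K, L = config.K, config.latent_dim
    centers = rng.standard_normal((K, L))
    prot_cluster = rng.integers(0, K, size=config.m)
    drug_cluster = rng.integers(0, K, size=config.n)
    u = centers[prot_cluster] + _CLUSTER_SPREAD * rng.standard_normal((config.m, L))
    v = centers[drug_cluster] + _CLUSTER_SPREAD * rng.standard_normal((config.n, L))

    map_p = rng.standard_normal((L, config.p)) / np.sqrt(L)
    map_d = rng.standard_normal((L, config.q)) / np.sqrt(L)
    sd_p = config.noise_sd
    sd_d = config.noise_sd
    if config.regime == "noisy_cross_modality":
        sd_d = config.noise_sd * _NOISY_FACTOR
    x = u @ map_p + sd_p * rng.standard_normal((config.m, config.p))
    y = v @ map_d + sd_d * rng.standard_normal((config.n, config.q))

    logits = config.interaction_scale * (u @ v.T).T        # (n, m): drug-major
    bias = _solve_bias(logits, config.positive_rate)
    probs = 1.0 / (1.0 + np.exp(-(logits + bias)))
    labels = rng.uniform(size=probs.shape) < probs
    if config.regime == "null":
        flat = labels.ravel()
        labels = rng.permutation(flat).reshape(labels.shape)

    protein_ids = [f"P{i + 1}" for i in range(config.m)]
    drug_ids = [f"D{j + 1}" for j in range(config.n)]
    records = [
        (drug_ids[j], protein_ids[i], 1)
        for j in range(config.n)
        for i in range(config.m)
        if labels[j, i]
    ]
    table = InteractionTable(records, provenance=f"synthetic:{config.regime}")
    truth = {
        "config": config,
        "centers": centers,
        "protein_cluster": prot_cluster,
        "drug_cluster": drug_cluster,
        "u": u,
        "v": v,
        "bias": bias,
        "probs": probs,              # (n, m), drug-major
        "protein_ids": protein_ids,
        "drug_ids": drug_ids,
    }
    proteins = EmbeddingMatrix(protein_ids, x, "protein")
    drugs = EmbeddingMatrix(drug_ids, y, "drug")
    return proteins, drugs, table, truth


FIXTURE_CONFIG = SynthConfig(
    m=40, n=60, p=16, q=16, K=4, latent_dim=8,
    noise_sd=0.1, interaction_scale=3.0, positive_rate=0.15,
    seed=1234, regime="separable",
)


def fixture_small():
    """The frozen tiny instance used across the test suite (PCG64 RNG)."""
    return generate(FIXTURE_CONFIG)


def bayes_scores(truth: Dict, pairs) -> np.ndarray:
    """True interaction probabilities for (drug_id, protein_id) pairs."""
    didx = {d: j for j, d in enumerate(truth["drug_ids"])}
    pidx = {p: i for i, p in enumerate(truth["protein_ids"])}
    return np.array([truth["probs"][didx[d], pidx[p]] for d, p in pairs])
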