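"""Embedding matrices, interaction tables and sequence-encoder adapters.

Canonical on-disk formats are transparent tab-delimited text:

* embedding TSV — ``id<TAB>v1<TAB>...<TAB>vd`` with a header row;
* interaction TSV — ``drug_id<TAB>protein_id<TAB>label`` with a header row.

A binary ``.npz`` option exists for speed.  Pretrained sequence encoders
(ESM-2 for proteins, ChemBERTa for SMILES) are reached only through the
adapter registry; the built-in ``hash`` backend (seeded random projection of
k-mer counts) lets the whole pipeline run with no model download.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "EmbeddingMatrix",
    "InteractionTable",
    "read_embeddings",
    "write_embeddings",
    "read_interactions",
    "write_interactions",
    "encoder_adapter",
    "register_encoder",
    "read_fasta",
    "read_smiles",
]

MODALITIES = ("protein", "drug")


@dataclass
class EmbeddingMatrix:
    """ID-indexed real matrix of entity encodings (one row per entity)."""

    ids: List[str]
    values: np.ndarray
    modality: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.values.shape[0]} embedding rows"
            )
        seen = set()
        for i in self.ids:
            if i in seen:
                raise ValueError(f"duplicate entity ID {i!r}")
            seen.add(i)
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite entries")

    @property
    def n_entities(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def index_of(self) -> Dict[str, int]:
        return {e: i for i, e in enumerate(self.ids)}

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        idx = self.index_of()
        missing = [i for i in ids if i not in idx]
        if missing:
            raise KeyError(f"unknown {self.modality} IDs: {missing[:10]}")
        rows = [idx[i] for i in ids]
        return EmbeddingMatrix(list(ids), self.values[rows], self.modality)


@dataclass
class InteractionTable:
    """(drug_id, protein_id, label) triples with binary labels."""

    records: List[Tuple[str, str, int]]
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for d, p, y in self.records:
            if y not in (0, 1):
                raise ValueError(f"label for pair ({d!r}, {p!r}) is {y!r}, not in {{0,1}}")
            if (d, p) in seen:
                raise ValueError(f"duplicate interaction pair ({d!r}, {p!r})")
            seen.add((d, p))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def drug_ids(self) -> List[str]:
        return [d for d, _, _ in self.records]

    @property
    def protein_ids(self) -> List[str]:
        return [p for _, p, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, _, y in self.records], dtype=int)

    def positives(self) -> List[Tuple[str, str]]:
        return [(d, p) for d, p, y in self.records if y == 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["drug_id", "protein_id", "label"])


# ---------------------------------------------------------------------------
# readers / writers


def read_embeddings(path, modality: str) -> EmbeddingMatrix:
    """Read an embedding matrix from TSV (or ``.npz`` with an ``ids`` array)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            ids = [str(i) for i in z["ids"]]
            values = np.asarray(z["values"], dtype=np.float64)
        return EmbeddingMatrix(ids, values, modality)

    ids: List[str] = []
    rows: List[List[float]] = []
    width = None
    with open(path) as fh:
        header = fh.readline()
        if header == "":
            raise ValueError(f"{path}: empty embedding file")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})"
                )
            ids.append(parts[0])
            row = []
            for col, cell in enumerate(parts[1:], start=2):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                    ) from None
            rows.append(row)
    return EmbeddingMatrix(ids, np.array(rows, dtype=np.float64), modality)


def write_embeddings(emb: EmbeddingMatrix, path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, ids=np.array(emb.ids), values=emb.values)
        return
    with open(path, "w") as fh:
        header = ["id"] + [f"v{i + 1}" for i in range(emb.dim)]
        fh.write("\t".join(header) + "\n")
        for eid, row in zip(emb.ids, emb.values):
            fh.write(eid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_interactions(path) -> InteractionTable:
    """Read an interaction table; labels must be literal 0 or 1."""
    path = Path(path)
    records: List[Tuple[str, str, int]] = []
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            d, p, lab = parts
            if lab not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label {lab!r} not in {{0,1}}")
            records.append((d, p, int(lab)))
    return InteractionTable(records, provenance=str(path))


def write_interactions(table: InteractionTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("drug_id\tprotein_id\tlabel\n")
        for d, p, y in table.records:
            fh.write(f"{d}\t{p}\t{y}\n")


def read_fasta(path) -> Tuple[List[str], List[str]]:
    """Read protein sequences from FASTA; returns (ids, sequences)."""
    from Bio import SeqIO

    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    return ids, seqs


def read_smiles(path) -> List[str]:
    """One SMILES string per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# encoder adapters

_ENCODERS: Dict[str, Callable] = {}


def register_encoder(name: str):
    """Register a sequence-encoder backend under `name`.

    A backend is ``fn(sequences, modality, dim, seed) -> ndarray (n, dim)``.
    External language-model adapters (ESM-2, ChemBERTa) register here in
    user code; the core never imports them.
    """

    def deco(fn):
        _ENCODERS[name] = fn
        return fn

    return deco


def _kmer_counts(seq: str, k: int, n_buckets: int) -> np.ndarray:
    counts = np.zeros(n_buckets)
    for i in range(max(len(seq) - k + 1, 1)):
        kmer = seq[i : i + k]
        h = int.from_bytes(hashlib.blake2b(kmer.encode(), digest_size=8).digest(), "big")
        counts[h % n_buckets] += 1.0
    return counts


@register_encoder("hash")
def _hash_encoder(sequences, modality, dim=64, seed=0, k=3, n_buckets=512):
    # deterministic pseudo-random projection of hashed k-mer counts
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((n_buckets, dim)) / np.sqrt(n_buckets)
    counts = np.stack([_kmer_counts(s, k, n_buckets) for s in sequences])
    norms = np.linalg.norm(counts, axis=1, keepdims=True)
    counts = counts / np.maximum(norms, 1e-12)
    return counts @ proj


def encoder_adapter(
    sequences: Sequence[str],
    modality: str,
    backend: str = "hash",
    ids: Sequence[str] | None = None,
    **kwargs,
) -> EmbeddingMatrix:
    """Encode sequences (amino-acid strings or SMILES) into an EmbeddingMatrix."""
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    if backend not in _ENCODERS:
        raise ValueError(
            f"unknown encoder backend {backend!r}; registered: {sorted(_ENCODERS)}"
        )
    if len(sequences) == 0:
        raise ValueError("no sequences to encode")
    for s in sequences:
        if not s:
            raise ValueError("empty sequence in input")
    values = _ENCODERS[backend](list(sequences), modality, **kwargs)
    if ids is None:
        prefix = "P" if modality == "protein" else "D"
        ids = [f"{prefix}{i + 1}" for i in range(len(sequences))]
    return EmbeddingMatrix(list(ids), values, modality)
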