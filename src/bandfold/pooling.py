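"""Structure-aware attention pooling over spectral bands.

A fixed set of s super-nodes per scale aggregates residue features by
scaled dot-product cross-attention.  The queries are data-specific: they
are linear encodings of the protein's own low-order Laplacian
eigenvectors (zero-padded to a fixed length so one weight matrix serves
proteins of any size).  Keys come from the band-decomposed signal of the
matching scale, values from the full signal F.  Because low-band keys are
nearly parallel across residues, global attention spreads its weight
almost uniformly; high-band keys vary sharply, so local attention is
peaky — the mechanism that lets one model summarize structure at three
scales at once.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import glorot
from .spectral import BandDecomposition, SpectralBasis

SCALES = ("global", "domain", "local")


@dataclass
class PoolingWeights:
    """Nine independent linear maps: per scale, a query, key and value encoder."""

    Wq: dict[str, np.ndarray]  # (max_len, c)
    bq: dict[str, np.ndarray]  # (c,)
    Wk: dict[str, np.ndarray]  # (d, c)
    bk: dict[str, np.ndarray]
    Wv: dict[str, np.ndarray]  # (d, c)
    bv: dict[str, np.ndarray]

    @classmethod
    def init(
        cls, d: int, c: int, max_len: int, rng: np.random.Generator
    ) -> "PoolingWeights":
        return cls(
            Wq={x: glorot(rng, max_len, c) for x in SCALES},
            bq={x: np.zeros(c) for x in SCALES},
            Wk={x: glorot(rng, d, c) for x in SCALES},
            bk={x: np.zeros(c) for x in SCALES},
            Wv={x: glorot(rng, d, c) for x in SCALES},
            bv={x: np.zeros(c) for x in SCALES},
        )

    @property
    def c(self) -> int:
        return self.Wq["global"].shape[1]


@dataclass
class PooledRepresentation:
    """Per-scale super-node aggregations with their attention weights."""

    aggregates: dict[str, np.ndarray]  # scale -> (s, c)
    weights: dict[str, np.ndarray]  # scale -> (s, n), rows sum to 1

    def summary(self) -> np.ndarray:
        """Protein-level vector: mean over super-nodes per scale, concatenated (3c)."""
        return np.concatenate([self.aggregates[x].mean(axis=0) for x in SCALES])


def select_spectral_descriptor(
    basis: SpectralBasis,
    s: int = 8,
    max_len: int = 1024,
    which: str = "smallest",
) -> np.ndarray:
    """Stack s Laplacian eigenvectors as rows, zero-padded to ``max_len``.

    ``which="smallest"`` takes the low-frequency end of the spectrum (the
    global-structure descriptor, the default); ``"largest"`` the other end.
    Padding makes the descriptor shape independent of protein length so a
    single query encoder serves every protein.
    """
    n = basis.n
    if s > n:
        raise ValueError(f"s={s} super-nodes but the graph has only {n} vertices")
    if n > max_len:
        raise ValueError(
            f"protein length {n} exceeds max_len={max_len}; raise max_len"
        )
    if which == "smallest":
        cols = np.arange(s)
    elif which == "largest":
        cols = np.arange(n - s, n)
    else:
        raise ValueError("which must be 'smallest' or 'largest'")
    descriptor = np.zeros((s, max_len))
    descriptor[:, :n] = basis.eigenvectors[:, cols].T
    return descriptor


def encode_queries(
    descriptor: np.ndarray,
    task_embedding: np.ndarray,
    weights: PoolingWeights,
) -> dict[str, np.ndarray]:
    """Q_X = FC_X(S) + task embedding (broadcast to every super-node row)."""
    return {
        x: descriptor @ weights.Wq[x] + weights.bq[x] + task_embedding
        for x in SCALES
    }


def encode_keys(
    bands: BandDecomposition, weights: PoolingWeights
) -> dict[str, np.ndarray]:
    """K_X = FC_X^K(F_X): each scale's keys come from its own band."""
    per_scale = dict(zip(SCALES, bands.bands))
    return {x: per_scale[x] @ weights.Wk[x] + weights.bk[x] for x in SCALES}


def encode_values(
    features: np.ndarray, weights: PoolingWeights
) -> dict[str, np.ndarray]:
    """V_X = FC_X^V(F): values carry the full (undecomposed) signal."""
    return {x: features @ weights.Wv[x] + weights.bv[x] for x in SCALES}


def softmax_rows(scores: np.ndarray) -> np.ndarray:
    shifted = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def attend(
    query: np.ndarray, key: np.ndarray, value: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention: W = softmax(QK⊤/√c), Aggr = WV.

    Returns the (s, c) aggregation and the (s, n) weight matrix; every
    weight row is a probability distribution over residues.
    """
    c = query.shape[1]
    if key.shape[1] != c or value.shape[1] != c:
        raise ValueError("query/key/value widths must match")
    w = softmax_rows(query @ key.T / np.sqrt(c))
    return w @ value, w


def pool(
    descriptor: np.ndarray,
    bands: BandDecomposition,
    features: np.ndarray,
    task_embedding: np.ndarray,
    weights: PoolingWeights,
) -> PooledRepresentation:
    """Run the full three-scale attention pooling for one protein."""
    queries = encode_queries(descriptor, task_embedding, weights)
    keys = encode_keys(bands, weights)
    values = encode_values(features, weights)
    aggregates: dict[str, np.ndarray] = {}
    attn: dict[str, np.ndarray] = {}
    for x in SCALES:
        aggregates[x], attn[x] = attend(queries[x], keys[x], values[x])
    return PooledRepresentation(aggregates, attn)


def attention_entropy(weight_rows: np.ndarray) -> float:
    """Mean Shannon entropy (nats) of attention rows; uniform rows maximize it."""
    p = np.clip(weight_rows, 1e-300, None)
    return float(-(p * np.log(p)).sum(axis=1).mean())


def dump_attention(
    pooled: PooledRepresentation, protein_id: str, path: str | Path
) -> None:
    """Write attention weights as TSV (protein, scale, super_node, residue, weight)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tscale\tsuper_node\tresidue\tweight\n")
        for x in SCALES:
            w = pooled.weights[x]
            for si in range(w.shape[0]):
                for ri in range(w.shape[1]):
                    fh.write(f"{protein_id}\t{x}\t{si + 1}\t{ri + 1}\t{w[si, ri]:.6g}\n")
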