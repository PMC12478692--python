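"""Node features: one-hot residue identity fused with contextual embeddings.

Each residue is mapped to a d-dimensional vector by projecting its one-hot
identity (20 standard amino acids) and a per-residue contextual embedding
to the same width and summing.  The contextual embedding comes from a
pluggable provider: a real protein language model in production, or the
deterministic window-hash mock used throughout the test harness (so no
model download is ever needed).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

#: canonical column order for one-hot encoding
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class NodeFeatures:
    """The graph signal F (n×d) with provenance of how it was built."""

    F: np.ndarray
    one_hot_used: bool = True
    embedder_name: str = ""

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=np.float64)
        if not np.all(np.isfinite(self.F)):
            raise ValueError("node features must be finite")

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def d(self) -> int:
        return self.F.shape[1]


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract for contextual per-residue embedders.

    Must be deterministic (same sequence -> same matrix) and return
    exactly one row per residue.
    """

    name: str
    width: int

    def embed(self, sequence: str) -> np.ndarray: ...


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a residue sequence as an n×20 one-hot matrix.

    Unknown or nonstandard residues ('X', lowercase, etc.) give an
    all-zero row rather than a 21st class; the contextual embedding still
    supplies a signal for such positions.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    out = np.zeros((len(sequence), 20), dtype=np.float64)
    for i, aa in enumerate(sequence):
        j = AA_INDEX.get(aa)
        if j is not None:
            out[i, j] = 1.0
    return out


@dataclass
class FusionWeights:
    """Projection parameters taking one-hot and contextual rows to width d."""

    W_onehot: np.ndarray  # (20, d)
    W_context: np.ndarray  # (e, d)
    bias: np.ndarray  # (d,)

    @classmethod
    def init(cls, context_width: int, d: int, rng: np.random.Generator) -> "FusionWeights":
        return cls(
            W_onehot=glorot(rng, 20, d),
            W_context=glorot(rng, context_width, d),
            bias=np.zeros(d),
        )


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def fuse_features(
    onehot: np.ndarray,
    contextual: np.ndarray,
    weights: FusionWeights,
    use_onehot: bool = True,
    embedder_name: str = "",
) -> NodeFeatures:
    """F = proj(one-hot) + proj(contextual), a strictly per-residue map.

    ``use_onehot=False`` drops the identity channel (the ablation axis),
    leaving the projected contextual embedding alone.
    """
    onehot = np.asarray(onehot, dtype=np.float64)
    contextual = np.asarray(contextual, dtype=np.float64)
    if onehot.shape[0] != contextual.shape[0]:
        raise ValueError(
            f"row count mismatch: one-hot has {onehot.shape[0]} rows, "
            f"contextual has {contextual.shape[0]}"
        )
    f = contextual @ weights.W_context + weights.bias
    if use_onehot:
        f = f + onehot @ weights.W_onehot
    return NodeFeatures(f, one_hot_used=use_onehot, embedder_name=embedder_name)


class MockEmbedder:
    """Deterministic stand-in for a protein language model.

    Each residue's embedding is the sum of per-offset lookup tables over a
    ±2 sequence window, so a single substitution perturbs only the five
    rows whose window covers it.  Entirely seed-determined: same
    (sequence, width, seed) -> bit-identical output.
    """

    WINDOW = 2

    def __init__(self, width: int = 32, seed: int = 0):
        if width <= 0:
            raise ValueError("width must be positive")
        self.width = width
        self.seed = seed
        self.name = f"mock-w{width}-s{seed}"
        rng = np.random.default_rng(seed)
        # tables[offset][residue class] -> embedding contribution
        # residue classes: 20 standard + 1 unknown
        self._tables = rng.normal(
            0.0, 1.0 / np.sqrt(2 * self.WINDOW + 1), size=(2 * self.WINDOW + 1, 21, width)
        )

    def embed(self, sequence: str) -> np.ndarray:
        n = len(sequence)
        idx = np.array([AA_INDEX.get(aa, 20) for aa in sequence])
        out = np.zeros((n, self.width))
        for k, off in enumerate(range(-self.WINDOW, self.WINDOW + 1)):
            lo, hi = max(0, -off), min(n, n - off)
            out[lo:hi] += self._tables[k][idx[lo + off:hi + off]]
        return out


def mock_embedder(sequence: str, width: int = 32, seed: int = 0) -> np.ndarray:
    """Functional form of :class:`MockEmbedder` for one-off calls."""
    return MockEmbedder(width=width, seed=seed).embed(sequence)


@dataclass
class EmbeddingCache:
    """File-based cache of per-protein embedding matrices with a manifest TSV.

    Heavy providers (real language models) run once; every later pipeline
    stage reads the cached matrices.  Matrices are stored as plain-text
    ``.tsv`` files, one per protein id.
    """

    directory: Path
    provider: EmbeddingProvider
    _manifest: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.directory = Path(self.directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _path(self, protein_id: str) -> Path:
        return self.directory / f"{protein_id}.tsv"

    def get(self, protein_id: str, sequence: str) -> np.ndarray:
        path = self._path(protein_id)
        if path.exists():
            mat = np.loadtxt(path, ndmin=2)
        else:
            mat = self.provider.embed(sequence)
            np.savetxt(path, mat, fmt="%.10g", delimiter="\t")
            self._manifest[protein_id] = len(sequence)
            self._write_manifest()
        if mat.shape[0] != len(sequence):
            raise ValueError(
                f"cached embedding for {protein_id} has {mat.shape[0]} rows "
                f"but the sequence has {len(sequence)} residues"
            )
        return mat

    def _write_manifest(self) -> None:
        with open(self.directory / "manifest.tsv", "w") as fh:
            fh.write("id\tlength\twidth\tprovider\n")
            for pid, length in sorted(self._manifest.items()):
                fh.write(f"{pid}\t{length}\t{self.provider.width}\t{self.provider.name}\n")
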