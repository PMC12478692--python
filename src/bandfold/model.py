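"""End-to-end multitask classifier over pooled multiscale representations.

Architecture (all widths configurable):

    one-hot + contextual embedding --fusion--> F (n×d)
    F --spectral band split--> (F_G, F_D, F_L)
    eigenvector descriptor S + task embedding --> per-scale queries
    three-scale attention pooling --> 3c summary vector
    shared ReLU trunk (3c -> 2c) --> per-task sigmoid head

Tasks share the fusion, pooling and trunk parameters; only the task
embedding (which conditions the queries) and the classification head are
per-task.  Training minimizes the summed binary cross-entropy per
protein, drawing tasks round-robin, with Adam.

The network is small enough that forward and backward passes are written
directly in NumPy; the analytic gradients are verified against finite
differences in the test suite.
"""
from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .features import (
    MockEmbedder,
    NodeFeatures,
    glorot,
    one_hot_encode,
)
from .pooling import SCALES, PoolingWeights, softmax_rows
from .spectral import band_boundaries, build_laplacian, eigendecompose
from .structure_io import ProteinStructure, build_contact_graph

logger = logging.getLogger("bandfold")

LOSS_EPS = 1e-7


@dataclass
class TaskSpec:
    """A prediction task: an ordered label vocabulary, optionally DAG-backed."""

    task_id: str
    labels: list[str]
    dag_ref: object | None = None

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("a task needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_labels(self) -> int:
        return len(self.labels)


@dataclass
class ProteinInputs:
    """Per-protein tensors precomputed once before training.

    Everything here is constant with respect to the model parameters:
    the eigenvector basis U with band cut points, the padded descriptor
    S, and the raw one-hot / contextual matrices that enter the fusion.
    """

    id: str
    onehot: np.ndarray  # (n, 20)
    context: np.ndarray  # (n, e)
    U: np.ndarray  # (n, n) eigenvectors, ascending eigenvalue order
    k_G: int
    k_D: int
    descriptor: np.ndarray  # (s, max_len)

    @property
    def n(self) -> int:
        return self.onehot.shape[0]


def multilabel_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Multi-label cross-entropy: −Σ_i [y_i log ŷ_i + (1−y_i) log(1−ŷ_i)].

    Probabilities are clamped to [ε, 1−ε] with ε = 1e−7 before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"label/score length mismatch: {y.shape} vs {y_hat.shape}")
    p = np.clip(y_hat, LOSS_EPS, 1.0 - LOSS_EPS)
    return float(-(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum())


class MultitaskModel:
    """The shared-trunk multitask network with per-task heads.

    Parameters live in a flat ``{name: array}`` dict so the optimizer and
    checkpointing are generic over the architecture.
    """

    def __init__(
        self,
        tasks: list[TaskSpec],
        d: int = 128,
        c: int = 32,
        s: int = 8,
        max_len: int = 1024,
        context_width: int = 32,
        use_onehot: bool = True,
        seed: int = 0,
    ):
        if not tasks:
            raise ValueError("at least one task is required")
        self.tasks = {t.task_id: t for t in tasks}
        self.d, self.c, self.s = d, c, s
        self.max_len = max_len
        self.context_width = context_width
        self.use_onehot = use_onehot
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        p["fusion/W_onehot"] = glorot(rng, 20, d)
        p["fusion/W_context"] = glorot(rng, context_width, d)
        p["fusion/bias"] = np.zeros(d)
        for x in SCALES:
            p[f"pool/Wq/{x}"] = glorot(rng, max_len, c)
            p[f"pool/bq/{x}"] = np.zeros(c)
            p[f"pool/Wk/{x}"] = glorot(rng, d, c)
            p[f"pool/bk/{x}"] = np.zeros(c)
            p[f"pool/Wv/{x}"] = glorot(rng, d, c)
            p[f"pool/bv/{x}"] = np.zeros(c)
        p["trunk/W"] = glorot(rng, 3 * c, 2 * c)
        p["trunk/b"] = np.zeros(2 * c)
        for t in tasks:
            p[f"task_emb/{t.task_id}"] = rng.normal(0.0, 0.1, size=c)
            p[f"head/{t.task_id}/W"] = glorot(rng, 2 * c, t.n_labels)
            p[f"head/{t.task_id}/b"] = np.zeros(t.n_labels)
        self.params = p

    # ------------------------------------------------------------------ utils

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())

    def pooling_weights(self) -> PoolingWeights:
        """Zero-copy view of the pooling parameters for the pooling module."""
        p = self.params
        return PoolingWeights(
            Wq={x: p[f"pool/Wq/{x}"] for x in SCALES},
            bq={x: p[f"pool/bq/{x}"] for x in SCALES},
            Wk={x: p[f"pool/Wk/{x}"] for x in SCALES},
            bk={x: p[f"pool/bk/{x}"] for x in SCALES},
            Wv={x: p[f"pool/Wv/{x}"] for x in SCALES},
            bv={x: p[f"pool/bv/{x}"] for x in SCALES},
        )

    def save(self, path: str | Path) -> None:
        meta = dict(
            d=self.d, c=self.c, s=self.s, max_len=self.max_len,
            context_width=self.context_width, use_onehot=int(self.use_onehot),
        )
        np.savez(path, __meta__=np.array(list(meta.items()), dtype=object),
                 **{k.replace("/", "|"): v for k, v in self.params.items()})

    def load_params(self, path: str | Path) -> None:
        data = np.load(path, allow_pickle=True)
        for key in data.files:
            if key == "__meta__":
                continue
            self.params[key.replace("|", "/")] = data[key]

    # ---------------------------------------------------------------- forward

    def forward(
        self, inputs: ProteinInputs, task_id: str, return_cache: bool = False
    ):
        """Per-task label probabilities for one protein.

        With ``return_cache=True`` also returns the intermediates needed
        by :meth:`backward`.
        """
        if task_id not in self.tasks:
            raise KeyError(f"unknown task {task_id!r}")
        p = self.params
        F = inputs.context @ p["fusion/W_context"] + p["fusion/bias"]
        if self.use_onehot:
            F = F + inputs.onehot @ p["fusion/W_onehot"]
        u = inputs.U
        f_hat = u.T @ F
        slices = {
            "global": slice(0, inputs.k_G),
            "domain": slice(inputs.k_G, inputs.k_D),
            "local": slice(inputs.k_D, inputs.n),
        }
        bands = {x: u[:, sl] @ f_hat[sl] for x, sl in slices.items()}
        task_emb = p[f"task_emb/{task_id}"]
        s_desc = inputs.descriptor
        cache: dict = {"F": F, "bands": bands, "slices": slices}
        sqrt_c = np.sqrt(self.c)
        summary_parts = []
        for x in SCALES:
            q = s_desc @ p[f"pool/Wq/{x}"] + p[f"pool/bq/{x}"] + task_emb
            k = bands[x] @ p[f"pool/Wk/{x}"] + p[f"pool/bk/{x}"]
            v = F @ p[f"pool/Wv/{x}"] + p[f"pool/bv/{x}"]
            attn = softmax_rows(q @ k.T / sqrt_c)
            aggr = attn @ v
            summary_parts.append(aggr.mean(axis=0))
            cache[f"q/{x}"], cache[f"k/{x}"], cache[f"v/{x}"] = q, k, v
            cache[f"attn/{x}"], cache[f"aggr/{x}"] = attn, aggr
        z = np.concatenate(summary_parts)
        a = z @ p["trunk/W"] + p["trunk/b"]
        h = np.maximum(a, 0.0)
        logits = h @ p[f"head/{task_id}/W"] + p[f"head/{task_id}/b"]
        probs = expit(logits)
        if not return_cache:
            return probs
        cache.update({"z": z, "a": a, "h": h, "probs": probs, "task_id": task_id,
                      "inputs": inputs})
        return probs, cache

    # --------------------------------------------------------------- backward

    def backward(
        self, cache: dict, y: np.ndarray, grads: dict[str, np.ndarray], scale: float = 1.0
    ) -> None:
        """Accumulate analytic gradients of the summed BCE into ``grads``.

        ``scale`` multiplies the contribution (1/batch for mean reduction).
        """
        p = self.params
        task_id = cache["task_id"]
        inputs: ProteinInputs = cache["inputs"]
        sqrt_c = np.sqrt(self.c)
        d_logits = scale * (cache["probs"] - y)
        grads[f"head/{task_id}/W"] += np.outer(cache["h"], d_logits)
        grads[f"head/{task_id}/b"] += d_logits
        d_h = p[f"head/{task_id}/W"] @ d_logits
        d_a = d_h * (cache["a"] > 0)
        grads["trunk/W"] += np.outer(cache["z"], d_a)
        grads["trunk/b"] += d_a
        d_z = p["trunk/W"] @ d_a
        u = inputs.U
        d_F = np.zeros_like(cache["F"])
        for xi, x in enumerate(SCALES):
            d_r = d_z[xi * self.c:(xi + 1) * self.c]
            attn, v, q, k = (cache[f"attn/{x}"], cache[f"v/{x}"],
                             cache[f"q/{x}"], cache[f"k/{x}"])
            d_aggr = np.tile(d_r / self.s, (self.s, 1))
            d_attn = d_aggr @ v.T
            d_v = attn.T @ d_aggr
            d_scores = attn * (d_attn - (d_attn * attn).sum(axis=1, keepdims=True))
            d_q = d_scores @ k / sqrt_c
            d_k = d_scores.T @ q / sqrt_c
            grads[f"pool/Wq/{x}"] += inputs.descriptor.T @ d_q
            grads[f"pool/bq/{x}"] += d_q.sum(axis=0)
            grads[f"task_emb/{task_id}"] += d_q.sum(axis=0)
            grads[f"pool/Wk/{x}"] += cache["bands"][x].T @ d_k
            grads[f"pool/bk/{x}"] += d_k.sum(axis=0)
            d_band = d_k @ p[f"pool/Wk/{x}"].T
            sl = cache["slices"][x]
            d_F += u[:, sl] @ (u[:, sl].T @ d_band)  # band projector is symmetric
            grads[f"pool/Wv/{x}"] += cache["F"].T @ d_v
            grads[f"pool/bv/{x}"] += d_v.sum(axis=0)
            d_F += d_v @ p[f"pool/Wv/{x}"].T
        grads["fusion/W_context"] += inputs.context.T @ d_F
        grads["fusion/bias"] += d_F.sum(axis=0)
        if self.use_onehot:
            grads["fusion/W_onehot"] += inputs.onehot.T @ d_F

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.params.items()}


# -------------------------------------------------------------- preprocessing


def prepare_protein(
    structure: ProteinStructure,
    context: np.ndarray | NodeFeatures | None = None,
    embedder: MockEmbedder | None = None,
    contact_threshold: float = 10.0,
    laplacian_kind: str = "normalized",
    p: float = 0.01,
    q: float = 0.03,
    s: int = 8,
    max_len: int = 1024,
    descriptor_which: str = "smallest",
) -> ProteinInputs:
    """Run the fixed (parameter-free) pipeline stages for one protein.

    Builds the contact graph, Laplacian eigenbasis, band cut points and
    padded descriptor, plus the raw one-hot and contextual matrices.
    The eigendecomposition cap propagates: proteins longer than the dense
    solver allows raise here, before any training starts.
    """
    from .pooling import select_spectral_descriptor

    graph = build_contact_graph(structure, threshold=contact_threshold)
    basis = eigendecompose(build_laplacian(graph, kind=laplacian_kind))
    k_g, k_d = band_boundaries(structure.n, p, q)
    descriptor = select_spectral_descriptor(basis, s=s, max_len=max_len,
                                            which=descriptor_which)
    if context is None:
        if embedder is None:
            embedder = MockEmbedder()
        context = embedder.embed(structure.sequence)
    return ProteinInputs(
        id=structure.id,
        onehot=one_hot_encode(structure.sequence),
        context=np.asarray(context, dtype=np.float64),
        U=basis.eigenvectors,
        k_G=k_g,
        k_D=k_d,
        descriptor=descriptor,
    )


# ------------------------------------------------------------------- training


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0


@dataclass
class TrainExample:
    inputs: ProteinInputs
    labels: dict[str, np.ndarray]  # task_id -> binary vector


@dataclass
class TrainResult:
    model: "MultitaskModel"
    loss_log: list[tuple[int, str, float]] = field(default_factory=list)

    @property
    def initial_loss(self) -> float:
        return self.loss_log[0][2]

    @property
    def final_loss(self) -> float:
        return self.loss_log[-1][2]

    def write_log(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\ttask\tloss\n")
            for epoch, task, loss in self.loss_log:
                fh.write(f"{epoch}\t{task}\t{loss:.8f}\n")


class Adam:
    """Plain Adam over a flat parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            params[k] -= c.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + c.adam_eps)


def train(
    model: MultitaskModel,
    dataset: list[TrainExample],
    config: TrainConfig | None = None,
) -> TrainResult:
    """Multitask training: tasks are drawn round-robin, one minibatch per draw.

    Per epoch, each task's protein list is reshuffled (seeded) and split
    into minibatches; steps alternate between tasks until every task's
    batches for the epoch are consumed.  The logged loss is the mean
    per-protein summed BCE of each minibatch.  Fully deterministic given
    (config.seed, model init seed).
    """
    if not dataset:
        raise ValueError("dataset is empty")
    config = config or TrainConfig()
    task_ids = sorted(model.tasks)
    per_task = {
        t: [ex for ex in dataset if t in ex.labels] for t in task_ids
    }
    for t, exs in per_task.items():
        if not exs:
            raise ValueError(f"no training example carries labels for task {t!r}")
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, config)
    result = TrainResult(model=model)
    for epoch in range(config.epochs):
        batches: dict[str, list[list[TrainExample]]] = {}
        for t in task_ids:
            order = rng.permutation(len(per_task[t]))
            exs = [per_task[t][i] for i in order]
            batches[t] = [
                exs[i:i + config.batch_size]
                for i in range(0, len(exs), config.batch_size)
            ]
        step_idx = {t: 0 for t in task_ids}
        remaining = True
        while remaining:
            remaining = False
            for t in task_ids:  # round-robin
                if step_idx[t] >= len(batches[t]):
                    continue
                batch = batches[t][step_idx[t]]
                step_idx[t] += 1
                remaining = True
                grads = model.zero_grads()
                batch_loss = 0.0
                for ex in batch:
                    probs, cache = model.forward(ex.inputs, t, return_cache=True)
                    batch_loss += multilabel_loss(ex.labels[t], probs)
                    model.backward(cache, ex.labels[t], grads, scale=1.0 / len(batch))
                optimizer.step(model.params, grads)
                result.loss_log.append((epoch, t, batch_loss / len(batch)))
        if epoch == 0 or (epoch + 1) % 10 == 0:
            recent = [l for _, _, l in result.loss_log[-len(task_ids):]]
            logger.info("epoch %d mean loss %.4f", epoch, float(np.mean(recent)))
    return result


def predict(
    model: MultitaskModel, examples: list[ProteinInputs], task_id: str
) -> dict[str, np.ndarray]:
    """Per-protein probability vectors for one task: {protein_id: scores}."""
    return {ex.id: model.forward(ex, task_id) for ex in examples}


def clone_single_task(model: MultitaskModel, task_id: str) -> MultitaskModel:
    """A single-task model of identical architecture (for parameter accounting)."""
    clone = MultitaskModel(
        tasks=[model.tasks[task_id]],
        d=model.d, c=model.c, s=model.s, max_len=model.max_len,
        context_width=model.context_width, use_onehot=model.use_onehot,
    )
    return clone


def copy_params(model: MultitaskModel) -> dict[str, np.ndarray]:
    return copy.deepcopy(model.params)
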