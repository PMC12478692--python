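"""CAFA-style evaluation: DAG propagation, Fmax, Smin and micro-AUPR.

Annotations over an ontology obey the true-path rule: a protein
annotated with a term is implicitly annotated with all its ancestors, so
truth and predictions are closed under the ancestor relation before any
metric is computed.

Fmax is protein-centric: at each score threshold τ on a 0.01-step grid,
precision is averaged over proteins with at least one prediction ≥ τ and
recall over all proteins with at least one true term; Fmax is the best
harmonic mean over the grid.  Smin weighs false negatives (remaining
uncertainty, ru) and false positives (misinformation, mi) by per-term
information content and minimizes √(ru²+mi²) over the same grid.  AUPR
is micro-averaged over all (protein, term) pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

DEFAULT_GRID = np.round(np.arange(0.01, 1.001, 0.01), 2)

Annotations = dict[str, set[str]]
Scores = dict[str, dict[str, float]]


@dataclass
class OntologyDAG:
    """A DAG of terms with is_a (child → parent) edges."""

    parents: dict[str, set[str]]  # term -> direct parents

    def __post_init__(self) -> None:
        # every parent must itself be a term
        for term, ps in list(self.parents.items()):
            for parent in ps:
                self.parents.setdefault(parent, set())
        self._check_acyclic()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, ps in self.parents.items():
            g.add_edges_from((child, parent) for parent in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    @property
    def roots(self) -> set[str]:
        return {t for t, ps in self.parents.items() if not ps}

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term``, excluding the term itself."""
        if term not in self.parents:
            raise KeyError(f"unknown term {term!r}")
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out: set[str] = set()
        stack = list(self.parents[term])
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents[t])
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result

    @classmethod
    def from_edges(cls, edges: list[tuple[str, str]]) -> "OntologyDAG":
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        return cls(parents)

    @classmethod
    def from_obo(cls, path: str | Path) -> "OntologyDAG":
        """Load an OBO file, keeping only is_a relationships."""
        import obonet

        graph = obonet.read_obo(str(path))
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        dag = cls.from_edges(edges)
        for term in graph.nodes:
            dag.parents.setdefault(term, set())
        return dag

    @classmethod
    def from_edge_tsv(cls, path: str | Path) -> "OntologyDAG":
        """Two-column TSV: child <tab> parent, optional header."""
        edges = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                child, parent = line.split("\t")[:2]
                if child == "child" and parent == "parent":
                    continue
                edges.append((child, parent))
        return cls.from_edges(edges)


def propagate(annotations: Annotations, dag: OntologyDAG) -> Annotations:
    """Close each protein's term set under the ancestor relation (true-path rule)."""
    out: Annotations = {}
    for protein, terms in annotations.items():
        closed: set[str] = set()
        for term in terms:
            if term not in dag.parents:
                raise KeyError(f"annotation term {term!r} not in the ontology")
            closed.add(term)
            closed |= dag.ancestors(term)
        out[protein] = closed
    return out


def propagate_scores(scores: Scores, dag: OntologyDAG) -> Scores:
    """Propagate prediction scores: each term gets the max over its descendants'
    scores (so predicted sets stay ancestor-closed at every threshold)."""
    out: Scores = {}
    for protein, term_scores in scores.items():
        prop: dict[str, float] = {}
        for term, score in term_scores.items():
            if term not in dag.parents:
                raise KeyError(f"predicted term {term!r} not in the ontology")
            for t in {term} | set(dag.ancestors(term)):
                prop[t] = max(prop.get(t, 0.0), float(score))
        out[protein] = prop
    return out


@dataclass
class ICTable:
    """Per-term information content: IC(t) = −log2 p(t) in a reference set.

    Terms annotated in every reference protein (e.g., roots after
    propagation) get IC 0; terms absent from the reference set are capped
    at −log2(1/(N+1)), finite and monotone in the reference size N.
    """

    ic: dict[str, float]
    ceiling: float

    @classmethod
    def from_annotations(
        cls, reference: Annotations, dag: OntologyDAG
    ) -> "ICTable":
        propagated = propagate(reference, dag)
        n_ref = len(propagated)
        if n_ref == 0:
            raise ValueError("reference annotation set is empty")
        counts: dict[str, int] = {}
        for terms in propagated.values():
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
        ceiling = -np.log2(1.0 / (n_ref + 1))
        ic = {t: float(-np.log2(counts[t] / n_ref)) for t in counts}
        for t in dag.terms:
            ic.setdefault(t, float(ceiling))
        return cls(ic=ic, ceiling=float(ceiling))

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(f"no information content for term {term!r}") from None


@dataclass
class EvalResult:
    fmax: float
    fmax_threshold: float
    smin: float
    aupr: float
    pr_curve: pd.DataFrame | None = field(default=None, repr=False)

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"fmax": self.fmax, "fmax_threshold": self.fmax_threshold,
              "smin": self.smin, "aupr": self.aupr}]
        ).to_csv(path, sep="\t", index=False)


def _predicted_at(term_scores: dict[str, float], tau: float) -> set[str]:
    return {t for t, sc in term_scores.items() if sc >= tau}


def fmax(
    scores: Scores,
    truth: Annotations,
    thresholds: np.ndarray | None = None,
) -> tuple[float, float]:
    """Protein-centric maximum F-score over a threshold grid.

    Returns ``(fmax, best_threshold)``.  Proteins without any true term
    are ignored; proteins with no prediction ≥ τ are excluded from the
    precision average at that τ (CAFA convention).
    """
    grid = DEFAULT_GRID if thresholds is None else np.asarray(thresholds)
    proteins = [p for p, terms in truth.items() if terms]
    if not proteins:
        raise ValueError("no protein has any true term")
    best_f, best_tau = 0.0, float(grid[0])
    for tau in grid:
        precisions, recalls = [], []
        for protein in proteins:
            true_terms = truth[protein]
            pred = _predicted_at(scores.get(protein, {}), tau)
            tp = len(pred & true_terms)
            if pred:
                precisions.append(tp / len(pred))
            recalls.append(tp / len(true_terms))
        if not precisions:
            continue
        pr = float(np.mean(precisions))
        rc = float(np.mean(recalls))
        if pr + rc > 0:
            f = 2 * pr * rc / (pr + rc)
            if f > best_f:
                best_f, best_tau = f, float(tau)
    return best_f, best_tau


def smin(
    scores: Scores,
    truth: Annotations,
    ic: ICTable,
    thresholds: np.ndarray | None = None,
) -> float:
    """Minimum semantic distance √(ru² + mi²) over the threshold grid.

    ru(τ): mean over proteins of the summed IC of true-but-unpredicted
    terms; mi(τ): mean summed IC of predicted-but-untrue terms.
    """
    grid = DEFAULT_GRID if thresholds is None else np.asarray(thresholds)
    proteins = [p for p, terms in truth.items() if terms]
    if not proteins:
        raise ValueError("no protein has any true term")
    best = np.inf
    for tau in grid:
        ru_total, mi_total = 0.0, 0.0
        for protein in proteins:
            true_terms = truth[protein]
            pred = _predicted_at(scores.get(protein, {}), tau)
            ru_total += sum(ic[t] for t in true_terms - pred)
            mi_total += sum(ic[t] for t in pred - true_terms)
        ru = ru_total / len(proteins)
        mi = mi_total / len(proteins)
        best = min(best, float(np.hypot(ru, mi)))
    return best


def _pair_arrays(scores: Scores, truth: Annotations) -> tuple[np.ndarray, np.ndarray]:
    """Flatten to aligned (label, score) arrays over all (protein, term) pairs.

    The pair universe is every (protein, term) with either a prediction
    score or a true annotation; missing scores count as 0.
    """
    y, s = [], []
    proteins = sorted(set(truth) | set(scores))
    for protein in proteins:
        true_terms = truth.get(protein, set())
        term_scores = scores.get(protein, {})
        for term in sorted(set(term_scores) | true_terms):
            y.append(1 if term in true_terms else 0)
            s.append(float(term_scores.get(term, 0.0)))
    return np.asarray(y), np.asarray(s)


def aupr(scores: Scores, truth: Annotations) -> float:
    """Micro-averaged area under the precision-recall curve.

    Step-wise interpolation: AUPR = Σ_k (R_k − R_{k−1}) · P_k over the
    distinct score thresholds in descending order.
    """
    y, s = _pair_arrays(scores, truth)
    if y.sum() == 0:
        raise ValueError("no positive (protein, term) pair")
    return float(average_precision_score(y, s))


def pr_curve(scores: Scores, truth: Annotations) -> pd.DataFrame:
    """Micro PR curve points over distinct thresholds, for TSV export."""
    from sklearn.metrics import precision_recall_curve

    y, s = _pair_arrays(scores, truth)
    precision, recall, thresh = precision_recall_curve(y, s)
    return pd.DataFrame({
        "threshold": np.concatenate([thresh, [np.inf]]),
        "precision": precision,
        "recall": recall,
    })


def evaluate(
    scores: Scores,
    truth: Annotations,
    dag: OntologyDAG,
    ic: ICTable | None = None,
    reference: Annotations | None = None,
) -> EvalResult:
    """Full evaluation: propagate truth and scores, then Fmax, Smin, AUPR.

    ``ic`` may be given directly; otherwise it is estimated from
    ``reference`` (falling back to the truth set itself).
    """
    truth_prop = propagate(truth, dag)
    scores_prop = propagate_scores(scores, dag)
    if ic is None:
        ic = ICTable.from_annotations(reference or truth, dag)
    f, tau = fmax(scores_prop, truth_prop)
    s = smin(scores_prop, truth_prop, ic)
    a = aupr(scores_prop, truth_prop)
    return EvalResult(fmax=f, fmax_threshold=tau, smin=s, aupr=a,
                      pr_curve=pr_curve(scores_prop, truth_prop))


# ---------------------------------------------------------------------- I/O


def read_annotations_tsv(path: str | Path) -> Annotations:
    """TSV with columns protein_id, term (optional task column is ignored)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    pid_col = "protein_id" if "protein_id" in cols else cols[0]
    term_col = "term" if "term" in cols else cols[-1]
    out: Annotations = {}
    for pid, term in zip(df[pid_col], df[term_col]):
        out.setdefault(pid, set()).add(term)
    return out


def read_annotations_tsv_by_task(path: str | Path) -> dict[str, Annotations]:
    """TSV with columns protein_id, task, term -> {task: {protein: terms}}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, Annotations] = {}
    for pid, task, term in zip(df["protein_id"], df["task"], df["term"]):
        out.setdefault(task, {}).setdefault(pid, set()).add(term)
    return out


def read_scores_tsv(path: str | Path) -> Scores:
    """TSV with columns protein_id, term, score."""
    df = pd.read_csv(path, sep="\t", dtype={"score": float})
    out: Scores = {}
    for pid, term, score in zip(df["protein_id"], df["term"], df["score"]):
        out.setdefault(str(pid), {})[str(term)] = float(score)
    return out


def write_scores_tsv(scores: Scores, path: str | Path, task: str = "") -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\ttask\tterm\tscore\n")
        for pid in sorted(scores):
            for term in sorted(scores[pid]):
                fh.write(f"{pid}\t{task}\t{term}\t{scores[pid][term]:.6f}\n")
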