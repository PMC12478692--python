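"""Shared fixtures: hand-built PDB texts and a small synthetic dataset."""
from __future__ import annotations

import numpy as np
import pytest

from bandfold import model as mdl
from bandfold import synthetic as syn
from bandfold.features import MockEmbedder
from bandfold.metrics import propagate


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz: tuple[float, float, float],
    element: str = "C",
) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  {name:<3s} {resname:3s} {chain:1s}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pdb(path, lines: list[str]) -> str:
    text = "\n".join(lines + ["END"]) + "\n"
    path.write_text(text)
    return str(path)


@pytest.fixture
def three_residue_pdb(tmp_path):
    """Three alanines with Cα at (0,0,0), (3.8,0,0), (7.6,0,0) on chain A."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        pdb_atom_line(2, "CA", "CYS", "A", 2, (3.8, 0.0, 0.0)),
        pdb_atom_line(3, "CA", "ASP", "A", 3, (7.6, 0.0, 0.0)),
    ]
    return write_pdb(tmp_path / "tiny.pdb", lines)


@pytest.fixture
def missing_ca_pdb(tmp_path):
    """Residue 2 has only a backbone N, no Cα."""
    lines = [
        pdb_atom_line(1, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0)),
        pdb_atom_line(2, "N", "CYS", "A", 2, (3.8, 0.0, 0.0), element="N"),
        pdb_atom_line(3, "CA", "ASP", "A", 3, (7.6, 0.0, 0.0)),
    ]
    return write_pdb(tmp_path / "gap.pdb", lines)


@pytest.fixture(scope="session")
def small_spec() -> syn.SyntheticSpec:
    return syn.SyntheticSpec(n_proteins=20, length_range=(30, 60), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return syn.generate_proteins(small_spec)


@pytest.fixture(scope="session")
def toy_tasks():
    dag = syn.toy_ontology()
    return [
        mdl.TaskSpec(t, syn.TASK_TERMS[t], dag_ref=dag)
        for t in sorted(syn.TASK_TERMS)
    ], dag


def make_examples(dataset, tasks, dag, ids=None, s=4, max_len=128, context_width=16):
    """Turn synthetic proteins into precomputed training examples."""
    embedder = MockEmbedder(width=context_width, seed=0)
    examples = []
    wanted = set(ids) if ids is not None else None
    for protein in dataset.proteins:
        pid = protein.structure.id
        if wanted is not None and pid not in wanted:
            continue
        inputs = mdl.prepare_protein(
            protein.structure, embedder=embedder, s=s, max_len=max_len
        )
        labels = {}
        for task in tasks:
            terms = propagate({pid: dataset.annotations[pid][task.task_id]}, dag)[pid]
            labels[task.task_id] = np.array(
                [1.0 if t in terms else 0.0 for t in task.labels]
            )
        examples.append(mdl.TrainExample(inputs=inputs, labels=labels))
    return examples


@pytest.fixture(scope="session")
def small_examples(small_dataset, toy_tasks):
    tasks, dag = toy_tasks
    return make_examples(small_dataset, tasks, dag)
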