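"""Synthetic proteins with planted multiscale labels.

Backbones are 3D self-avoiding random walks with a fixed 3.8 Å
consecutive-Cα spacing.  Two fold classes differ only in the turning-angle
distribution of the walk: "compact" chains turn sharply and pack densely
(high contact-graph degree), "extended" chains persist in direction and
stay sparse.  Two labels are planted at different structural scales:

* **global-fold** — the fold class, a whole-graph property readable from
  the contact-graph spectrum;
* **local-motif** — whether a three-residue sequence motif occurs with
  all three Cα atoms mutually within a spatial radius, a residue-level
  property.  Motif-positive proteins get the triplet inserted with a
  forced sharp turn at its center so the spatial condition holds in both
  fold classes; motif-negative proteins carry no occurrence of the
  triplet, keeping the motif label independent of the fold label.

A 6-term toy ontology (two roots, four leaves) wraps the labels so the
full annotation-propagation / Fmax machinery is exercised end to end.
Everything is a pure function of the spec's seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .metrics import OntologyDAG
from .structure_io import ProteinStructure

FOLD_CLASSES = ("compact", "extended")

#: toy ontology: child -> parent is_a edges
TOY_ONTOLOGY_EDGES = [
    ("fold:compact", "fold:root"),
    ("fold:extended", "fold:root"),
    ("motif:present", "motif:root"),
    ("motif:absent", "motif:root"),
]

TASK_FOLD = "global-fold"
TASK_MOTIF = "local-motif"

TASK_TERMS = {
    TASK_FOLD: ["fold:root", "fold:compact", "fold:extended"],
    TASK_MOTIF: ["motif:root", "motif:present", "motif:absent"],
}

#: walk turning-angle distributions (degrees): mean, sd
TURN_ANGLES = {"compact": (75.0, 15.0), "extended": (20.0, 10.0)}
CLASH_DISTANCE = 2.0  # Å, self-avoidance limit
SHARP_TURN = (90.0, 8.0)  # forced turn at a planted motif center


def toy_ontology() -> OntologyDAG:
    return OntologyDAG.from_edges(TOY_ONTOLOGY_EDGES)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset (seed fixes everything)."""

    n_proteins: int = 300
    length_range: tuple[int, int] = (40, 120)
    bond_length: float = 3.8
    contact_threshold: float = 10.0
    motif: str = "CHW"
    motif_radius: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 5:
            raise ValueError("minimum protein length is 5")
        if self.bond_length <= 0:
            raise ValueError("bond length must be positive")
        if len(self.motif) != 3:
            raise ValueError("the motif is a residue triplet")


@dataclass
class SyntheticProtein:
    structure: ProteinStructure
    fold_class: str
    motif_planted: bool


# ------------------------------------------------------------------ backbone


def _random_perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        perp = r - np.dot(r, v) * v
        norm = np.linalg.norm(perp)
        if norm > 1e-8:
            return perp / norm


def _rotate(v: np.ndarray, axis: np.ndarray, theta: float) -> np.ndarray:
    # Rodrigues rotation of v around unit axis
    return (v * np.cos(theta)
            + np.cross(axis, v) * np.sin(theta)
            + axis * np.dot(axis, v) * (1.0 - np.cos(theta)))


def generate_structure(
    length: int,
    fold_class: str,
    seed: int,
    bond_length: float = 3.8,
    sharp_turn_at: int | None = None,
    max_restarts: int = 50,
) -> ProteinStructure:
    """Self-avoiding random-walk backbone with class-specific turning angles.

    ``sharp_turn_at`` forces a ~90° turn at the given residue index
    (0-based), used to plant spatially compact motifs in extended chains.
    Deterministic: the same (length, fold_class, seed) always produces
    identical coordinates.  Raises if self-avoidance cannot be satisfied
    within the restart budget.
    """
    if length < 5:
        raise ValueError("length must be at least 5")
    if fold_class not in TURN_ANGLES:
        raise ValueError(f"fold_class must be one of {FOLD_CLASSES}")
    rng = np.random.default_rng(seed)
    mean_deg, sd_deg = TURN_ANGLES[fold_class]
    for _ in range(max_restarts):
        coords = np.zeros((length, 3))
        direction = np.array([1.0, 0.0, 0.0])
        coords[1] = coords[0] + bond_length * direction
        failed = False
        for i in range(2, length):
            placed = False
            for _attempt in range(30):
                if sharp_turn_at is not None and i - 1 == sharp_turn_at:
                    theta = np.deg2rad(rng.normal(*SHARP_TURN))
                else:
                    theta = np.deg2rad(rng.normal(mean_deg, sd_deg))
                theta = float(np.clip(theta, 0.0, np.pi))
                axis = _random_perpendicular(direction, rng)
                cand_dir = _rotate(direction, axis, theta)
                cand_dir /= np.linalg.norm(cand_dir)
                cand = coords[i - 1] + bond_length * cand_dir
                dists = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if np.all(dists > CLASH_DISTANCE):
                    coords[i] = cand
                    direction = cand_dir
                    placed = True
                    break
            if not placed:
                failed = True
                break
        if not failed:
            sequence = "".join(
                rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length)
            )
            return ProteinStructure(
                id=f"syn{seed:06d}", chain="A", sequence=sequence, coords=coords
            )
    raise RuntimeError(
        f"self-avoiding walk failed after {max_restarts} restarts "
        f"(length={length}, class={fold_class}, seed={seed})"
    )


# -------------------------------------------------------------------- motifs


def find_motif(
    structure: ProteinStructure, motif: str, radius: float
) -> bool:
    """True iff the triplet occurs contiguously in sequence with all three
    residues mutually within ``radius`` Å."""
    seq = structure.sequence
    for i in range(len(seq) - len(motif) + 1):
        if seq[i:i + len(motif)] != motif:
            continue
        pts = structure.coords[i:i + len(motif)]
        pairs = itertools.combinations(range(len(motif)), 2)
        if all(np.linalg.norm(pts[a] - pts[b]) < radius for a, b in pairs):
            return True
    return False


def _strip_motif(sequence: str, motif: str, rng: np.random.Generator) -> str:
    """Resample residues until the motif triplet does not occur."""
    seq = list(sequence)
    alphabet = [aa for aa in "ACDEFGHIKLMNPQRSTVWY" if aa != motif[0]]
    while True:
        joined = "".join(seq)
        pos = joined.find(motif)
        if pos < 0:
            return joined
        seq[pos] = str(rng.choice(alphabet))


def _generate_protein(
    length: int,
    fold_class: str,
    motif_planted: bool,
    spec: SyntheticSpec,
    seed: int,
    max_tries: int = 40,
) -> SyntheticProtein:
    """One protein with its motif label guaranteed by construction."""
    for attempt in range(max_tries):
        sub_seed = seed + 1_000_003 * attempt
        rng = np.random.default_rng(sub_seed)
        if motif_planted:
            pos = int(rng.integers(2, length - 4))
            structure = generate_structure(
                length, fold_class, seed=sub_seed,
                bond_length=spec.bond_length, sharp_turn_at=pos + 1,
            )
            seq = _strip_motif(structure.sequence, spec.motif, rng)
            seq = seq[:pos] + spec.motif + seq[pos + 3:]
            structure = ProteinStructure(
                structure.id, structure.chain, seq, structure.coords
            )
            if find_motif(structure, spec.motif, spec.motif_radius):
                return SyntheticProtein(structure, fold_class, True)
        else:
            structure = generate_structure(
                length, fold_class, seed=sub_seed, bond_length=spec.bond_length
            )
            seq = _strip_motif(structure.sequence, spec.motif, rng)
            structure = ProteinStructure(
                structure.id, structure.chain, seq, structure.coords
            )
            if not find_motif(structure, spec.motif, spec.motif_radius):
                return SyntheticProtein(structure, fold_class, False)
    raise RuntimeError("could not realize the requested motif label")


def plant_labels(
    protein: SyntheticProtein, spec: SyntheticSpec
) -> dict[str, set[str]]:
    """Per-task leaf annotations for one synthetic protein.

    The fold label is the generating class; the motif label is *detected*
    from sequence + geometry, so it holds by measurement, not metadata.
    """
    has_motif = find_motif(protein.structure, spec.motif, spec.motif_radius)
    return {
        TASK_FOLD: {f"fold:{protein.fold_class}"},
        TASK_MOTIF: {"motif:present" if has_motif else "motif:absent"},
    }


# ------------------------------------------------------------------- dataset


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    proteins: list[SyntheticProtein]
    annotations: dict[str, dict[str, set[str]]]  # protein_id -> task -> terms
    splits: dict[str, list[str]] = field(default_factory=dict)  # split -> ids

    @property
    def by_id(self) -> dict[str, SyntheticProtein]:
        return {p.structure.id: p for p in self.proteins}


def generate_proteins(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full stratified dataset in memory.

    Proteins are distributed as evenly as possible over the four
    (fold class × motif label) cells; lengths are drawn uniformly from
    the spec's range; splits are 60/20/20 stratified per cell.
    """
    rng = np.random.default_rng(spec.seed)
    cells = list(itertools.product(FOLD_CLASSES, (True, False)))
    base, extra = divmod(spec.n_proteins, len(cells))
    counts = [base + (1 if i < extra else 0) for i in range(len(cells))]
    proteins: list[SyntheticProtein] = []
    annotations: dict[str, dict[str, set[str]]] = {}
    cell_ids: dict[tuple[str, bool], list[str]] = {cell: [] for cell in cells}
    idx = 0
    for cell, count in zip(cells, counts):
        fold_class, motif_planted = cell
        for _ in range(count):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            protein_seed = int(rng.integers(0, 2**31 - 1))
            protein = _generate_protein(
                length, fold_class, motif_planted, spec, protein_seed
            )
            pid = f"syn{idx:04d}"
            protein.structure.id = pid
            proteins.append(protein)
            annotations[pid] = plant_labels(protein, spec)
            cell_ids[cell].append(pid)
            idx += 1
    splits: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for cell in cells:
        ids = cell_ids[cell]
        order = rng.permutation(len(ids))
        shuffled = [ids[i] for i in order]
        n = len(shuffled)
        n_train = int(round(n * 0.6))
        n_val = int(round(n * 0.2))
        # every split gets at least one protein per cell (when n >= 3)
        if n >= 3:
            n_val = max(n_val, 1)
            while n - n_train - n_val < 1:
                n_train -= 1
            n_train = max(n_train, 1)
        splits["train"] += shuffled[:n_train]
        splits["val"] += shuffled[n_train:n_train + n_val]
        splits["test"] += shuffled[n_train + n_val:]
    for key in splits:
        splits[key] = sorted(splits[key])
    return SyntheticDataset(spec, proteins, annotations, splits)


def _write_pdb(structure: ProteinStructure, path: Path) -> None:
    from biotite.sequence import ProteinSequence
    from biotite.structure import AtomArray
    from biotite.structure.io.pdb import PDBFile

    n = structure.n
    atoms = AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.chain_id = np.full(n, structure.chain)
    atoms.res_id = np.arange(1, n + 1)
    atoms.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(aa) for aa in structure.sequence]
    )
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def generate_dataset(spec: SyntheticSpec, outdir: str | Path) -> SyntheticDataset:
    """Generate and write the dataset in the formats the pipeline consumes.

    Produces per-protein PDB files, a FASTA of all sequences, per-split
    annotation TSVs, the toy-ontology edge TSV and a manifest TSV.
    Regenerating with the same spec is byte-identical.
    """
    outdir = Path(outdir)
    (outdir / "structures").mkdir(parents=True, exist_ok=True)
    dataset = generate_proteins(spec)
    by_id = dataset.by_id
    with open(outdir / "sequences.fasta", "w") as fasta:
        for protein in dataset.proteins:
            s = protein.structure
            _write_pdb(s, outdir / "structures" / f"{s.id}.pdb")
            fasta.write(f">{s.id}\n{s.sequence}\n")
    with open(outdir / "ontology_edges.tsv", "w") as fh:
        fh.write("child\tparent\n")
        for child, parent in TOY_ONTOLOGY_EDGES:
            fh.write(f"{child}\t{parent}\n")
    for split, ids in dataset.splits.items():
        with open(outdir / f"annotations_{split}.tsv", "w") as fh:
            fh.write("protein_id\ttask\tterm\n")
            for pid in ids:
                for task in sorted(dataset.annotations[pid]):
                    for term in sorted(dataset.annotations[pid][task]):
                        fh.write(f"{pid}\t{task}\t{term}\n")
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("protein_id\tlength\tfold_class\tmotif\tsplit\n")
        split_of = {pid: s for s, ids in dataset.splits.items() for pid in ids}
        for protein in dataset.proteins:
            s = protein.structure
            fh.write(
                f"{s.id}\t{s.n}\t{protein.fold_class}\t"
                f"{int(protein.motif_planted)}\t{split_of[s.id]}\n"
            )
    return dataset
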