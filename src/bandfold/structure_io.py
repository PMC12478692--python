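"""Protein coordinate parsing and residue contact-graph construction.

A protein is reduced to one representative atom per residue (Cα by
default).  Residues closer than a distance threshold in 3D become the
edges of an undirected *contact graph* — the graph whose Laplacian
spectrum drives everything downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from biotite.sequence import ProteinSequence
from biotite.structure import filter_amino_acids
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import squareform, pdist

logger = logging.getLogger("bandfold")

#: common nonstandard residues mapped onto their standard parent
NONSTANDARD_MAP = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "PYL": "LYS",
    "HYP": "PRO",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
}

UNKNOWN_RESIDUE = "X"


def three_to_one(res_name: str) -> str:
    """Map a 3-letter residue code to 1-letter; unknown residues give 'X'."""
    res_name = NONSTANDARD_MAP.get(res_name, res_name)
    try:
        code = ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return UNKNOWN_RESIDUE
    return code if code in ProteinSequence.alphabet else UNKNOWN_RESIDUE


@dataclass
class ProteinStructure:
    """A residue sequence with one 3D coordinate per residue (Å).

    Residues are indexed 1..n in file order in all user-facing output;
    internal arrays are 0-based.
    """

    id: str
    chain: str
    sequence: str
    coords: np.ndarray  # (n, 3) float64

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.sequence) != self.coords.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != "
                f"coordinate rows {self.coords.shape[0]}"
            )
        if self.n < 1:
            raise ValueError("a protein must contain at least one residue")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass
class ContactGraph:
    """Undirected simple graph on residues: edge (i,j) iff dist < threshold."""

    n: int
    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.shape != (self.n, self.n):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        self.adjacency = a.astype(np.float64)

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def edges(self) -> set[tuple[int, int]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return {(int(i), int(j)) for i, j in zip(ii, jj)}

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)


def parse_structure(
    path: str | Path,
    chain: str | None = None,
    atom: str = "CA",
    model: int = 1,
) -> ProteinStructure:
    """Read a PDB file and extract one representative atom per residue.

    Parameters
    ----------
    path
        PDB-format coordinate file.
    chain
        Chain identifier.  May be omitted only for single-chain files.
    atom
        Representative atom name, typically ``"CA"`` or ``"CB"``.
        Residues lacking it are dropped (with a warning) and the sequence
        shortened consistently.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model, altloc="first")
    atoms = atoms[filter_amino_acids(atoms)]
    chains = sorted(set(atoms.chain_id))
    if not chains:
        raise ValueError(f"{path.name}: no amino-acid residues found")
    if chain is None:
        if len(chains) > 1:
            raise ValueError(
                f"{path.name} has multiple chains {chains}; pass chain= explicitly"
            )
        chain = chains[0]
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not present in {path.name}; available chains: {chains}"
        )
    atoms = atoms[atoms.chain_id == chain]

    n_residues_total = len(
        {(int(r), str(i)) for r, i in zip(atoms.res_id, atoms.ins_code)}
    )
    rep = atoms[atoms.atom_name == atom]
    if rep.array_length() == 0:
        raise ValueError(f"no residues with a {atom} atom in chain {chain}")
    if rep.array_length() < n_residues_total:
        logger.warning(
            "%s chain %s: dropped %d residue(s) lacking a %s atom",
            path.name, chain, n_residues_total - rep.array_length(), atom,
        )
    # one atom per residue: keep the first occurrence in file order
    seen: set[tuple[int, str]] = set()
    keep = []
    for k in range(rep.array_length()):
        key = (int(rep.res_id[k]), str(rep.ins_code[k]))
        if key not in seen:
            seen.add(key)
            keep.append(k)
    rep = rep[keep]
    sequence = "".join(three_to_one(str(r)) for r in rep.res_name)
    return ProteinStructure(
        id=path.stem, chain=chain, sequence=sequence, coords=rep.coord
    )


def build_contact_graph(
    structure: ProteinStructure, threshold: float = 10.0
) -> ContactGraph:
    """Edges between residues whose pairwise distance is strictly < ``threshold`` Å."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    n = structure.n
    if n == 1:
        return ContactGraph(1, np.zeros((1, 1)), np.zeros((1, 1)))
    dist = squareform(pdist(structure.coords))
    adjacency = (dist < threshold).astype(np.float64)
    np.fill_diagonal(adjacency, 0.0)
    return ContactGraph(n, adjacency, dist)


def write_edge_list(graph: ContactGraph, path: str | Path) -> None:
    """Dump the contact graph as a TSV of (i, j, distance), 1-based indices."""
    with open(path, "w") as fh:
        fh.write("i\tj\tdistance\n")
        for i, j in sorted(graph.edges):
            d = graph.distances[i, j] if graph.distances is not None else float("nan")
            fh.write(f"{i + 1}\t{j + 1}\t{d:.4f}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    from biotite.sequence.io.fasta import FastaFile

    fasta = FastaFile.read(str(path))
    return {header.split()[0]: str(seq) for header, seq in fasta.items()}
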