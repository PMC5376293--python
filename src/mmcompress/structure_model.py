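"""In-memory model of macromolecular structures for coordinate compression.

A :class:`Molecule` is the unit of compression: either an entire model of a
multi-model structure (NMR ensembles), or a single polymer chain / subunit.
A :class:`StructureSet` groups the molecules of one structure.

Coordinates are kept in axis-major layout (all x, then all y, then all z)
because the downstream difference encoders operate on one long array per
molecule; the seam between axes is just another difference.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Residue names treated as amino acids for the reduced representation.
AMINO_ACID_RESIDUES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
        # common modified residues that still carry a CA
        "MSE", "SEC", "PYL",
    }
)

#: Residue names treated as nucleotides for the reduced representation.
NUCLEOTIDE_RESIDUES = frozenset(
    {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU", "DI", "I"}
)


class Representation(enum.Enum):
    """Level of detail kept for compression.

    ``FULL`` keeps every polymer atom.  ``REDUCED`` keeps only the alpha
    carbon of each amino-acid residue and the phosphate phosphorus of each
    nucleotide residue -- the backbone trace that suffices for ribbon
    rendering and coarse structural comparison.
    """

    FULL = "full"
    REDUCED = "reduced"


class EmptySelectionError(ValueError):
    """Raised when a representation filter removes every atom."""


@dataclass(frozen=True)
class Atom:
    """A single atom record (coordinates live in :class:`CoordinateArrays`)."""

    name: str
    element: str = ""
    residue_index: int = 0
    residue_name: str = ""
    chain_id: str = "A"
    is_polymer: bool = True

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")


@dataclass
class CoordinateArrays:
    """Per-molecule coordinates in Angstrom, one array per axis."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        n = len(self.x)
        if n < 1:
            raise ValueError("coordinate arrays must hold at least one atom")
        if len(self.y) != n or len(self.z) != n:
            raise ValueError("x, y, z must have equal length")
        if not (
            np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
            and np.all(np.isfinite(self.z))
        ):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)

    def as_matrix(self) -> np.ndarray:
        """Return an (N, 3) matrix view of the coordinates."""
        return np.column_stack([self.x, self.y, self.z])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "CoordinateArrays":
        m = np.asarray(m, dtype=np.float64)
        return cls(m[:, 0].copy(), m[:, 1].copy(), m[:, 2].copy())


@dataclass
class Molecule:
    """An ordered list of atoms with their coordinates."""

    atoms: list[Atom]
    coords: CoordinateArrays

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.coords):
            raise ValueError(
                f"atom count ({len(self.atoms)}) does not match coordinate "
                f"count ({len(self.coords)})"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


class Grouping(enum.Enum):
    """How the molecules of a set map back onto a structure file."""

    MODELS = "models"
    CHAINS = "chains"


@dataclass
class StructureSet:
    """The molecules of one structure, in file order."""

    molecules: list[Molecule]
    label: str = ""
    grouping: Grouping = Grouping.MODELS

    def __post_init__(self) -> None:
        if not self.molecules:
            raise ValueError("a structure set must contain at least one molecule")

    def __len__(self) -> int:
        return len(self.molecules)


def _keep_reduced(atom: Atom) -> bool:
    if atom.name == "CA" and atom.residue_name in AMINO_ACID_RESIDUES:
        return True
    if atom.name == "P" and atom.residue_name in NUCLEOTIDE_RESIDUES:
        return True
    return False


def extract_representation(mol: Molecule, rep: Representation) -> Molecule:
    """Filter a molecule down to the requested representation.

    ``FULL`` is the identity on polymer atoms.  ``REDUCED`` keeps exactly the
    CA atoms of amino-acid residues and the P atoms of nucleotide residues,
    preserving the original atom order.  Residues that are neither (unknown
    polymer chemistry) contribute no atoms in reduced mode; a warning is
    logged once per molecule.

    Raises
    ------
    EmptySelectionError
        If the reduced selection is empty.
    """
    if rep is Representation.FULL:
        return mol
    mask = [_keep_reduced(a) for a in mol.atoms]
    unknown = {
        a.residue_name
        for a in mol.atoms
        if a.residue_name not in AMINO_ACID_RESIDUES
        and a.residue_name not in NUCLEOTIDE_RESIDUES
    }
    if unknown:
        logger.warning(
            "reduced representation skips %d unknown polymer residue name(s): %s",
            len(unknown),
            ", ".join(sorted(unknown)[:5]),
        )
    if not any(mask):
        raise EmptySelectionError(
            "reduced representation selected no atoms (no CA/P backbone atoms found)"
        )
    idx = np.flatnonzero(mask)
    atoms = [mol.atoms[i] for i in idx]
    coords = CoordinateArrays(
        mol.coords.x[idx].copy(), mol.coords.y[idx].copy(), mol.coords.z[idx].copy()
    )
    return Molecule(atoms, coords)


def extract_representation_set(s: StructureSet, rep: Representation) -> StructureSet:
    """Apply :func:`extract_representation` to every molecule of a set."""
    return StructureSet(
        [extract_representation(m, rep) for m in s.molecules],
        label=s.label,
        grouping=s.grouping,
    )


def flatten_axis_major(coords: CoordinateArrays) -> np.ndarray:
    """Lay coordinates out as one array ``{x0..xn, y0..yn, z0..zn}``."""
    return np.concatenate([coords.x, coords.y, coords.z])


def unflatten_axis_major(flat: Sequence[float]) -> CoordinateArrays:
    """Inverse of :func:`flatten_axis_major`."""
    flat = np.asarray(flat)
    if len(flat) % 3 != 0:
        raise ValueError("flattened coordinate array length must be divisible by 3")
    n = len(flat) // 3
    return CoordinateArrays(flat[:n].copy(), flat[n : 2 * n].copy(), flat[2 * n :].copy())


def check_homogeneous(s: StructureSet) -> bool:
    """True iff all molecules pair atom-for-atom.

    Homogeneity means the same atom count and identical per-position atom
    names across every molecule -- the precondition for the intermolecular
    encoders, which subtract corresponding atoms across molecules.  Matching
    names (not just counts) guarantees the pairing is chemically meaningful.
    """
    first = s.molecules[0]
    ref_names = [a.name for a in first.atoms]
    for mol in s.molecules[1:]:
        if mol.n_atoms != first.n_atoms:
            return False
        if [a.name for a in mol.atoms] != ref_names:
            return False
    return True
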