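"""Seeded generators for synthetic polymer structures.

The codecs exploit two statistical properties of real macromolecules:
consecutive bonded atoms sit ~1.5 A apart (so coordinate differences are
small), and ensembles / repeated subunits are near-duplicates of one
molecule.  The generators below reproduce exactly those properties --
random-walk polymers with Gaussian bond lengths, noisy multi-model
ensembles (optionally given random rigid motions, emulating undeposited
alignment), and repeated-subunit complexes related by rigid transforms.

All outputs are deterministic functions of the spec's seed, and coordinates
are rounded to 3 decimals at generation time because archival coordinate
records carry exactly three decimals; the lossless contract is defined on
that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_model import (
    Atom,
    CoordinateArrays,
    Grouping,
    Molecule,
    StructureSet,
)

_AA_CYCLE = ("ALA", "GLY", "SER", "VAL", "LEU", "THR")


@dataclass
class FixtureSpec:
    """Parameters of the synthetic generators.

    Defaults emulate a protein backbone trace: bond steps of
    Normal(1.5, 0.05) A, ensembles of 10 models with 0.1 A per-atom noise,
    complexes of 4 subunits.
    """

    seed: int = 0
    n_atoms: int = 100
    bond_length_mean: float = 1.5
    bond_length_sd: float = 0.05
    n_models: int = 10
    noise_sd: float = 0.1
    apply_random_rigid: bool = False
    n_subunits: int = 4

    def __post_init__(self) -> None:
        if self.n_atoms < 1 or self.n_models < 1 or self.n_subunits < 1:
            raise ValueError("counts must be positive")
        if self.bond_length_mean <= 0 or self.bond_length_sd < 0 or self.noise_sd < 0:
            raise ValueError("length and noise parameters must be non-negative")


def _backbone_atoms(n: int, chain_id: str = "A") -> list[Atom]:
    return [
        Atom(
            name="CA",
            element="C",
            residue_index=i + 1,
            residue_name=_AA_CYCLE[i % len(_AA_CYCLE)],
            chain_id=chain_id,
        )
        for i in range(n)
    ]


def _random_walk(rng: np.random.Generator, spec: FixtureSpec) -> np.ndarray:
    steps = rng.normal(spec.bond_length_mean, spec.bond_length_sd, spec.n_atoms - 1)
    steps = np.clip(steps, 1e-3, None)
    dirs = rng.normal(size=(max(spec.n_atoms - 1, 1), 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    pts = np.zeros((spec.n_atoms, 3))
    if spec.n_atoms > 1:
        pts[1:] = np.cumsum(dirs[: spec.n_atoms - 1] * steps[:, None], axis=0)
    return pts


def make_polymer(spec: FixtureSpec) -> Molecule:
    """A random-walk CA trace with bond-scale steps, 3-decimal coordinates."""
    rng = np.random.default_rng(spec.seed)
    pts = np.round(_random_walk(rng, spec), 3)
    return Molecule(
        _backbone_atoms(spec.n_atoms),
        CoordinateArrays.from_matrix(pts),
    )


def _random_rigid(rng: np.random.Generator, scale: float = 20.0):
    rot = Rotation.from_quat(_random_quat(rng))
    t = rng.uniform(-scale, scale, 3)
    return rot, t


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def make_ensemble(spec: FixtureSpec) -> StructureSet:
    """A multi-model ensemble: one base polymer plus per-model Gaussian
    per-atom noise; optional random rigid motion per model (unaligned
    deposition).  Homogeneous by construction."""
    rng = np.random.default_rng(spec.seed)
    base = np.round(_random_walk(rng, spec), 3)
    atoms = _backbone_atoms(spec.n_atoms)
    molecules = []
    for _ in range(spec.n_models):
        pts = base + rng.normal(0.0, spec.noise_sd, base.shape)
        if spec.apply_random_rigid:
            rot, t = _random_rigid(rng)
            pts = rot.apply(pts) + t
        molecules.append(
            Molecule(atoms, CoordinateArrays.from_matrix(np.round(pts, 3)))
        )
    return StructureSet(molecules, label=f"ensemble-seed{spec.seed}", grouping=Grouping.MODELS)


def make_complex(spec: FixtureSpec) -> StructureSet:
    """A repeated-subunit complex: one subunit replicated with NCS-like rigid
    transforms plus small conformational noise, one chain per copy."""
    rng = np.random.default_rng(spec.seed)
    base = np.round(_random_walk(rng, spec), 3)
    molecules = []
    for k in range(spec.n_subunits):
        chain = chr(ord("A") + k % 26)
        pts = base + rng.normal(0.0, spec.noise_sd, base.shape)
        rot, t = _random_rigid(rng, scale=30.0)
        pts = rot.apply(pts) + t
        molecules.append(
            Molecule(
                _backbone_atoms(spec.n_atoms, chain_id=chain),
                CoordinateArrays.from_matrix(np.round(pts, 3)),
            )
        )
    return StructureSet(molecules, label=f"complex-seed{spec.seed}", grouping=Grouping.CHAINS)
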