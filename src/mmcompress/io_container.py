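"""Structure file I/O (PDB / PDBx-mmCIF via gemmi) and the compressed
binary container.

Container layout (all multi-byte integers little-endian)::

    magic "MCMP" | version u16 | header_len u32 | gzip(JSON header)
    | transforms_len u32 | transform blobs (56 bytes each)
    | n_blocks u32 | { block_len u32 | block bytes } * n_blocks
    | crc32 u32 over the concatenated block bytes

The JSON header is self-describing: strategy, mode, quantization factor,
representation, packer and entropy ids, per-molecule atom tables, the
traversal plan for intermolecular strategies, and a descriptor for every
payload block.  Decompression needs nothing outside the file.
"""

from __future__ import annotations

import enum
import gzip
import json
import logging
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import gemmi

from .structure_model import (
    AMINO_ACID_RESIDUES,
    NUCLEOTIDE_RESIDUES,
    Atom,
    CoordinateArrays,
    EmptySelectionError,
    Grouping,
    Molecule,
    StructureSet,
)

logger = logging.getLogger(__name__)

MAGIC = b"MCMP"
CONTAINER_VERSION = 1


class StructureFormat(str, enum.Enum):
    PDB = "pdb"
    MMCIF = "mmcif"


class ContainerFormatError(ValueError):
    pass


class ChecksumError(ContainerFormatError):
    pass


@dataclass
class CompressedContainer:
    """Header + transform blobs + entropy-compressed payload blocks."""

    header: dict
    transforms: bytes = b""
    blocks: list[bytes] = field(default_factory=list)

    @property
    def payload_bytes(self) -> int:
        """Compressed coordinate size: payload blocks only.  Transform blobs
        and the header are bookkeeping and excluded, so sizes compare
        encoders rather than container overhead."""
        return sum(len(b) for b in self.blocks)


# ---------------------------------------------------------------------------
# structure reading / writing


def _detect_format(path: Path, fmt: StructureFormat | None) -> StructureFormat:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return StructureFormat.MMCIF
    return StructureFormat.PDB


def _is_polymer_residue(name: str) -> bool:
    return name in AMINO_ACID_RESIDUES or name in NUCLEOTIDE_RESIDUES


def read_structure(path: str | Path, fmt: StructureFormat | None = None) -> StructureSet:
    """Read polymer atoms from a PDB or mmCIF file.

    Multi-model files yield one molecule per model; single-model files yield
    one molecule per polymer chain.  Non-polymer atoms (waters, ligands) are
    dropped with a logged count; for atoms with alternate locations only the
    first altloc is kept.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    try:
        if fmt is StructureFormat.MMCIF:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as e:
        raise ContainerFormatError(f"cannot parse {path.name}: {e}") from e
    st.setup_entities()

    n_dropped = 0
    multi_model = len(st) > 1

    def chain_atoms(chain: "gemmi.Chain") -> tuple[list[Atom], list[list[float]]]:
        nonlocal n_dropped
        atoms: list[Atom] = []
        xyz: list[list[float]] = []
        for residue in chain:
            if not _is_polymer_residue(residue.name):
                n_dropped += len(residue)
                continue
            seen: set[str] = set()
            for a in residue:
                if a.name in seen:  # later altloc of an already-kept atom
                    n_dropped += 1
                    continue
                seen.add(a.name)
                atoms.append(
                    Atom(
                        name=a.name,
                        element=a.element.name,
                        residue_index=residue.seqid.num,
                        residue_name=residue.name,
                        chain_id=chain.name,
                    )
                )
                xyz.append([a.pos.x, a.pos.y, a.pos.z])
        return atoms, xyz

    molecules: list[Molecule] = []
    if multi_model:
        for model in st:
            atoms: list[Atom] = []
            xyz: list[list[float]] = []
            for chain in model:
                a, c = chain_atoms(chain)
                atoms.extend(a)
                xyz.extend(c)
            if atoms:
                molecules.append(
                    Molecule(atoms, CoordinateArrays.from_matrix(np.array(xyz)))
                )
        grouping = Grouping.MODELS
    else:
        for chain in st[0]:
            a, c = chain_atoms(chain)
            if a:
                molecules.append(Molecule(a, CoordinateArrays.from_matrix(np.array(c))))
        grouping = Grouping.CHAINS
    if n_dropped:
        logger.info("dropped %d non-polymer/altloc atoms from %s", n_dropped, path.name)
    if not molecules:
        raise EmptySelectionError(f"no polymer atoms found in {path.name}")
    return StructureSet(molecules, label=st.name or path.stem, grouping=grouping)


def _to_gemmi(s: StructureSet) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.label or "model"

    def fill_model(model: gemmi.Model, mol: Molecule) -> None:
        by_chain: dict[str, gemmi.Chain] = {}
        for atom, x, y, z in zip(mol.atoms, mol.coords.x, mol.coords.y, mol.coords.z):
            chain = by_chain.get(atom.chain_id)
            if chain is None:
                chain = gemmi.Chain(atom.chain_id)
                by_chain[atom.chain_id] = chain
            if (
                len(chain) == 0
                or chain[-1].seqid.num != atom.residue_index
                or chain[-1].name != atom.residue_name
            ):
                res = gemmi.Residue()
                res.name = atom.residue_name or "UNK"
                res.seqid = gemmi.SeqId(atom.residue_index, " ")
                chain.add_residue(res)
            ga = gemmi.Atom()
            ga.name = atom.name
            ga.element = gemmi.Element(atom.element or atom.name[:1])
            ga.pos = gemmi.Position(float(x), float(y), float(z))
            ga.occ = 1.0
            chain[-1].add_atom(ga)
        for chain in by_chain.values():
            model.add_chain(chain)

    if s.grouping is Grouping.MODELS:
        for i, mol in enumerate(s.molecules, start=1):
            model = gemmi.Model(i)
            fill_model(model, mol)
            st.add_model(model)
    else:
        model = gemmi.Model(1)
        for mol in s.molecules:
            fill_model(model, mol)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    s: StructureSet, path: str | Path, fmt: StructureFormat | None = None
) -> None:
    """Write a structure set as PDB or mmCIF (format inferred from the
    extension unless given)."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    st = _to_gemmi(s)
    if fmt is StructureFormat.PDB:
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# atom tables in the header


def atoms_to_table(atoms: list[Atom]) -> dict:
    return {
        "name": [a.name for a in atoms],
        "element": [a.element for a in atoms],
        "residue_index": [a.residue_index for a in atoms],
        "residue_name": [a.residue_name for a in atoms],
        "chain_id": [a.chain_id for a in atoms],
    }


def atoms_from_table(t: dict) -> list[Atom]:
    return [
        Atom(name=n, element=e, residue_index=ri, residue_name=rn, chain_id=ci)
        for n, e, ri, rn, ci in zip(
            t["name"], t["element"], t["residue_index"], t["residue_name"], t["chain_id"]
        )
    ]


# ---------------------------------------------------------------------------
# container serialization


def write_container(container: CompressedContainer, path: str | Path) -> int:
    """Serialize a container; returns the number of bytes written."""
    if not container.blocks:
        raise ContainerFormatError("container must hold at least one payload block")
    header_bytes = gzip.compress(
        json.dumps(container.header, separators=(",", ":")).encode(), mtime=0
    )
    out = bytearray()
    out += MAGIC
    out += struct.pack("<H", CONTAINER_VERSION)
    out += struct.pack("<I", len(header_bytes))
    out += header_bytes
    out += struct.pack("<I", len(container.transforms))
    out += container.transforms
    out += struct.pack("<I", len(container.blocks))
    payload = bytearray()
    for block in container.blocks:
        out += struct.pack("<I", len(block))
        out += block
        payload += block
    out += struct.pack("<I", zlib.crc32(bytes(payload)) & 0xFFFFFFFF)
    Path(path).write_bytes(bytes(out))
    return len(out)


def read_container(path: str | Path) -> CompressedContainer:
    data = Path(path).read_bytes()
    view = memoryview(data)
    if len(data) < 14 or bytes(view[:4]) != MAGIC:
        raise ContainerFormatError("not a compressed-coordinate container (bad magic)")
    (version,) = struct.unpack_from("<H", view, 4)
    if version != CONTAINER_VERSION:
        raise ContainerFormatError(f"unsupported container version {version}")
    off = 6
    (header_len,) = struct.unpack_from("<I", view, off)
    off += 4
    try:
        header = json.loads(gzip.decompress(bytes(view[off : off + header_len])))
    except (OSError, json.JSONDecodeError) as e:
        raise ContainerFormatError(f"corrupt container header: {e}") from e
    off += header_len
    (tr_len,) = struct.unpack_from("<I", view, off)
    off += 4
    transforms = bytes(view[off : off + tr_len])
    off += tr_len
    (n_blocks,) = struct.unpack_from("<I", view, off)
    off += 4
    blocks: list[bytes] = []
    payload = bytearray()
    for _ in range(n_blocks):
        if off + 4 > len(data):
            raise ContainerFormatError("truncated container (block table)")
        (blen,) = struct.unpack_from("<I", view, off)
        off += 4
        if off + blen > len(data):
            raise ContainerFormatError("truncated container (payload)")
        block = bytes(view[off : off + blen])
        off += blen
        blocks.append(block)
        payload += block
    if off + 4 > len(data):
        raise ContainerFormatError("truncated container (missing checksum)")
    (crc,) = struct.unpack_from("<I", view, off)
    if crc != (zlib.crc32(bytes(payload)) & 0xFFFFFFFF):
        raise ChecksumError("payload checksum mismatch: container is corrupted")
    return CompressedContainer(header=header, transforms=transforms, blocks=blocks)
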