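"""Named compression strategies: encoding -> packing -> entropy compression.

Each strategy is a fixed composition of the stage algorithms:

================  ==========================================================
Delta             integer encoding, delta, recursive indexing, gzip
Predictive        integer encoding, predictive, recursive indexing, gzip
Wavelet           integer encoding, delta, CDF 5/3 wavelet, recursive
                  indexing, gzip
UV16              unit-vector compression to 16-bit codes, recursive
                  indexing, gzip
UV32              unit-vector compression to 32-bit codes, gzip (recursive
                  indexing omitted: the codes span the full 32-bit range)
InterDelta        integer encoding, intermolecular delta along a traversal
                  plan, recursive indexing, gzip
InterPredictive   as InterDelta with second-order prediction along the chain
IntegerBaseline   integer encoding, recursive indexing, gzip
FloatBaseline     raw IEEE-754 doubles, gzip (the uncompressed-memory
                  baseline for ratio comparisons)
================  ==========================================================

Lossless mode quantizes at factor 1000 (exact for 3-decimal coordinates);
lossy mode at factor 10 (0.1 A grid).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .entropy import EntropyBackend, entropy_compress, entropy_decompress, shannon_entropy
from .inter_codecs import (
    EdgeMetric,
    InterBase,
    InterPayload,
    SuperpositionTransform,
    TraversalPlan,
    TraversalStrategy,
    inter_decode,
    inter_encode,
    make_plan,
)
from .intra_codecs import (
    LOSSLESS_FACTOR,
    LOSSY_FACTOR,
    CodecId,
    EncodedPayload,
    QuantizedCoords,
    UV_LAYOUT_VERSION,
    delta_decode,
    delta_encode,
    dequantize,
    predictive_decode,
    predictive_encode,
    quantize,
    uv_decode,
    uv_encode,
    wavelet_forward,
    wavelet_inverse,
)
from .io_container import CompressedContainer, ContainerFormatError, atoms_from_table, atoms_to_table
from .packing import PackerId, pack_to_bytes, unpack_from_bytes
from .structure_model import (
    CoordinateArrays,
    Grouping,
    Molecule,
    Representation,
    StructureSet,
    check_homogeneous,
    extract_representation_set,
)


class Mode(str, enum.Enum):
    LOSSLESS = "lossless"
    LOSSY = "lossy"

    @property
    def factor(self) -> int:
        return LOSSLESS_FACTOR if self is Mode.LOSSLESS else LOSSY_FACTOR


class Strategy(str, enum.Enum):
    FLOAT_BASELINE = "float"
    INTEGER_BASELINE = "integer"
    DELTA = "delta"
    PREDICTIVE = "predictive"
    WAVELET = "wavelet"
    UV16 = "uv16"
    UV32 = "uv32"
    INTER_DELTA = "inter-delta"
    INTER_PREDICTIVE = "inter-predictive"


#: Stage composition per strategy (documentation + table-driven tests).
STRATEGY_STAGES: dict[Strategy, tuple[str, ...]] = {
    Strategy.FLOAT_BASELINE: ("float64", "gzip"),
    Strategy.INTEGER_BASELINE: ("integer", "recursive_index", "gzip"),
    Strategy.DELTA: ("integer", "delta", "recursive_index", "gzip"),
    Strategy.PREDICTIVE: ("integer", "predictive", "recursive_index", "gzip"),
    Strategy.WAVELET: ("integer", "delta", "wavelet", "recursive_index", "gzip"),
    Strategy.UV16: ("uv16", "recursive_index", "gzip"),
    Strategy.UV32: ("uv32", "gzip"),
    Strategy.INTER_DELTA: ("integer", "inter_delta", "recursive_index", "gzip"),
    Strategy.INTER_PREDICTIVE: ("integer", "inter_predictive", "recursive_index", "gzip"),
}

INTER_STRATEGIES = (Strategy.INTER_DELTA, Strategy.INTER_PREDICTIVE)


@dataclass
class CompressionOptions:
    """Knobs beyond the strategy itself (defaults follow the recommended
    configuration: lossless delta, full representation, waterfall traversal,
    RMSD metric, superposition on)."""

    traversal: TraversalStrategy = TraversalStrategy.WATERFALL
    metric: EdgeMetric = EdgeMetric.RMSD
    do_superpose: bool = True
    entropy_backend: EntropyBackend = EntropyBackend.GZIP


def _mol_packer(strategy: Strategy, mode: Mode) -> PackerId:
    if strategy is Strategy.UV32:
        return PackerId.RAW_INT32
    if strategy is Strategy.FLOAT_BASELINE:
        raise ValueError("float baseline has no integer packer")
    return PackerId.RECURSIVE_INDEX_16


def _encode_molecule(
    mol: Molecule, strategy: Strategy, factor: int
) -> tuple[list[tuple[str, np.ndarray]], dict]:
    """Encode one molecule into named int32 streams + scalar metadata."""
    if strategy is Strategy.INTEGER_BASELINE:
        return [("main", quantize(mol.coords, factor).values)], {}
    if strategy is Strategy.DELTA:
        return [("main", delta_encode(quantize(mol.coords, factor).values))], {}
    if strategy is Strategy.PREDICTIVE:
        return [("main", predictive_encode(quantize(mol.coords, factor).values))], {}
    if strategy is Strategy.WAVELET:
        return [
            ("main", wavelet_forward(delta_encode(quantize(mol.coords, factor).values)))
        ], {}
    if strategy in (Strategy.UV16, Strategy.UV32):
        bits = 16 if strategy is Strategy.UV16 else 32
        p = uv_encode(mol.coords, bits, factor)
        streams = [
            ("main", p.main),
            ("len_resid", p.aux["len_resid"]),
            ("corrections", p.aux["corrections"]),
        ]
        meta = {
            "first": [int(v) for v in p.aux["first"]],
            "mean_len": int(p.aux["mean_len"][0]),
        }
        return streams, meta
    raise ValueError(f"not an intramolecular strategy: {strategy}")


def _decode_molecule(
    streams: dict[str, np.ndarray], meta: dict, strategy: Strategy, factor: int, n_atoms: int
) -> QuantizedCoords:
    main = streams["main"]
    if strategy is Strategy.INTEGER_BASELINE:
        return QuantizedCoords(main, factor)
    if strategy is Strategy.DELTA:
        return QuantizedCoords(delta_decode(main), factor)
    if strategy is Strategy.PREDICTIVE:
        return QuantizedCoords(predictive_decode(main), factor)
    if strategy is Strategy.WAVELET:
        return QuantizedCoords(delta_decode(wavelet_inverse(main)), factor)
    if strategy in (Strategy.UV16, Strategy.UV32):
        codec = CodecId.UV16 if strategy is Strategy.UV16 else CodecId.UV32
        payload = EncodedPayload(
            codec_id=codec,
            main=main,
            n_atoms=n_atoms,
            factor=factor,
            aux={
                "first": np.array(meta["first"], dtype=np.int32),
                "mean_len": np.array([meta["mean_len"]], dtype=np.int32),
                "len_resid": streams["len_resid"],
                "corrections": streams["corrections"],
            },
        )
        return uv_decode(payload)
    raise ValueError(f"not an intramolecular strategy: {strategy}")


def _build_header(
    s: StructureSet, strategy: Strategy, mode: Mode, rep: Representation
) -> dict:
    header: dict = {
        "strategy": strategy.value,
        "mode": mode.value,
        "factor": mode.factor,
        "representation": rep.value,
        "grouping": s.grouping.value,
        "label": s.label,
        "uv_layout_version": UV_LAYOUT_VERSION,
        "n_atoms": [m.n_atoms for m in s.molecules],
    }
    if check_homogeneous(s) and len(s) > 1:
        header["atoms_shared"] = atoms_to_table(s.molecules[0].atoms)
        # chain ids may still differ between subunit copies
        header["chain_ids"] = [[a.chain_id for a in m.atoms] for m in s.molecules]
    else:
        header["atoms"] = [atoms_to_table(m.atoms) for m in s.molecules]
    return header


def compress(
    s: StructureSet,
    strategy: Strategy = Strategy.DELTA,
    mode: Mode = Mode.LOSSLESS,
    representation: Representation = Representation.FULL,
    options: CompressionOptions | None = None,
) -> CompressedContainer:
    """Compress a structure set with one of the named strategies."""
    container, _ = compress_with_stats(s, strategy, mode, representation, options)
    return container


def compress_with_stats(
    s: StructureSet,
    strategy: Strategy = Strategy.DELTA,
    mode: Mode = Mode.LOSSLESS,
    representation: Representation = Representation.FULL,
    options: CompressionOptions | None = None,
) -> tuple[CompressedContainer, dict]:
    """As :func:`compress`, also returning pre-entropy stream statistics
    (packed byte count and Shannon entropy of the packed stream)."""
    options = options or CompressionOptions()
    s = extract_representation_set(s, representation)
    factor = mode.factor
    header = _build_header(s, strategy, mode, representation)
    header["entropy"] = options.entropy_backend.value
    packed_streams: list[bytes] = []
    descriptors: list[dict] = []
    transforms_blob = b""

    if strategy is Strategy.FLOAT_BASELINE:
        header["packer"] = "float64"
        for i, mol in enumerate(s.molecules):
            raw = np.concatenate(
                [mol.coords.x, mol.coords.y, mol.coords.z]
            ).astype("<f8").tobytes()
            packed_streams.append(raw)
            descriptors.append({"role": "main", "mol": i, "packer": "float64"})
    elif strategy in INTER_STRATEGIES:
        if not check_homogeneous(s):
            raise ValueError(
                "intermolecular strategies need a homogeneous molecule set; "
                "use an intramolecular strategy (e.g. delta) instead"
            )
        packer = PackerId.RECURSIVE_INDEX_16
        header["packer"] = packer.value
        plan = make_plan(s, options.traversal, options.metric, factor)
        base = InterBase.DELTA if strategy is Strategy.INTER_DELTA else InterBase.PREDICTIVE
        payload = inter_encode(s, plan, base=base, do_superpose=options.do_superpose, factor=factor)
        header["plan"] = {
            "strategy": plan.strategy_id.value,
            "root": plan.root_index,
            "pairs": [[t, r] for t, r in plan.pairs],
        }
        header["base"] = base.value
        header["metric"] = options.metric.value
        header["superpose"] = options.do_superpose
        packed_streams.append(pack_to_bytes(payload.root_payload.main, packer))
        descriptors.append({"role": "root", "mol": plan.root_index, "packer": packer.value})
        has_transform = []
        for k, (resid, tr) in enumerate(zip(payload.residuals, payload.transforms)):
            packed_streams.append(pack_to_bytes(resid, packer))
            descriptors.append({"role": "residual", "pair": k, "packer": packer.value})
            has_transform.append(tr is not None)
            if tr is not None:
                transforms_blob += tr.serialize()
        header["has_transform"] = has_transform
    else:
        packer = _mol_packer(strategy, mode)
        header["packer"] = packer.value
        uv_meta = []
        for i, mol in enumerate(s.molecules):
            streams, meta = _encode_molecule(mol, strategy, factor)
            uv_meta.append(meta)
            for role, arr in streams:
                packed_streams.append(pack_to_bytes(arr, packer))
                descriptors.append({"role": role, "mol": i, "packer": packer.value})
        if any(uv_meta):
            header["uv_meta"] = uv_meta

    header["blocks"] = descriptors
    blocks = [entropy_compress(pb, options.entropy_backend) for pb in packed_streams]
    container = CompressedContainer(header=header, transforms=transforms_blob, blocks=blocks)
    packed_all = b"".join(packed_streams)
    stats = {
        "packed_bytes": len(packed_all),
        "shannon_entropy": shannon_entropy(packed_all) if packed_all else 0.0,
    }
    return container, stats


def _atoms_for(header: dict, i: int) -> list:
    if "atoms_shared" in header:
        atoms = atoms_from_table(header["atoms_shared"])
        chains = header.get("chain_ids")
        if chains is not None:
            atoms = [
                type(a)(
                    name=a.name,
                    element=a.element,
                    residue_index=a.residue_index,
                    residue_name=a.residue_name,
                    chain_id=c,
                )
                for a, c in zip(atoms, chains[i])
            ]
        return atoms
    return atoms_from_table(header["atoms"][i])


def decompress(container: CompressedContainer) -> StructureSet:
    """Invert :func:`compress`: exact on the quantized grid (bitwise for
    3-decimal input in lossless mode)."""
    header = container.header
    strategy = Strategy(header["strategy"])
    factor = int(header["factor"])
    backend = EntropyBackend(header.get("entropy", "gzip"))
    n_atoms = [int(n) for n in header["n_atoms"]]
    n_mol = len(n_atoms)
    descriptors = header["blocks"]
    if len(descriptors) != len(container.blocks):
        raise ContainerFormatError("block descriptor count does not match payload")
    raw_blocks = [entropy_decompress(b, backend) for b in container.blocks]

    molecules: list[Molecule] = []
    if strategy is Strategy.FLOAT_BASELINE:
        for i in range(n_mol):
            flat = np.frombuffer(raw_blocks[i], dtype="<f8")
            n = n_atoms[i]
            coords = CoordinateArrays(flat[:n].copy(), flat[n : 2 * n].copy(), flat[2 * n :].copy())
            molecules.append(Molecule(_atoms_for(header, i), coords))
    elif strategy in INTER_STRATEGIES:
        packer = PackerId(header["packer"])
        plan_h = header["plan"]
        plan = TraversalPlan(
            TraversalStrategy(plan_h["strategy"]),
            [(int(t), int(r)) for t, r in plan_h["pairs"]],
            int(plan_h["root"]),
        )
        root_main = unpack_from_bytes(raw_blocks[0], packer)
        residuals = [unpack_from_bytes(b, packer) for b in raw_blocks[1:]]
        transforms: list[SuperpositionTransform | None] = []
        off = 0
        for flag in header["has_transform"]:
            if flag:
                transforms.append(
                    SuperpositionTransform.deserialize(
                        container.transforms[off : off + SuperpositionTransform.SERIALIZED_SIZE]
                    )
                )
                off += SuperpositionTransform.SERIALIZED_SIZE
            else:
                transforms.append(None)
        payload = InterPayload(
            root_payload=EncodedPayload(
                codec_id=CodecId.DELTA, main=root_main, n_atoms=n_atoms[0], factor=factor
            ),
            residuals=residuals,
            transforms=transforms,
            plan=plan,
            factor=factor,
            n_atoms=n_atoms[0],
            base=InterBase(header["base"]),
        )
        for i, q in enumerate(inter_decode(payload)):
            molecules.append(Molecule(_atoms_for(header, i), dequantize(q)))
    else:
        packer = PackerId(header["packer"])
        uv_meta = header.get("uv_meta")
        by_mol: dict[int, dict[str, np.ndarray]] = {i: {} for i in range(n_mol)}
        for desc, raw in zip(descriptors, raw_blocks):
            by_mol[int(desc["mol"])][desc["role"]] = unpack_from_bytes(raw, packer)
        for i in range(n_mol):
            meta = uv_meta[i] if uv_meta else {}
            q = _decode_molecule(by_mol[i], meta, strategy, factor, n_atoms[i])
            molecules.append(Molecule(_atoms_for(header, i), dequantize(q)))
    return StructureSet(
        molecules,
        label=header.get("label", ""),
        grouping=Grouping(header.get("grouping", "models")),
    )


# ---------------------------------------------------------------------------
# benchmark harness


def benchmark(
    corpus: list[StructureSet],
    strategies: list[Strategy],
    modes: list[Mode] | None = None,
    representations: list[Representation] | None = None,
    options: CompressionOptions | None = None,
) -> list[dict]:
    """Compress every corpus entry under every configuration and tabulate
    raw size, compressed size, ratio and pre-entropy Shannon entropy.

    Raw size is the in-memory double-precision footprint (3 x N x 8 bytes),
    the floating-point baseline the ratios are measured against.  Results
    are deterministic for a fixed corpus.
    """
    if not corpus:
        raise ValueError("benchmark needs a non-empty corpus")
    modes = modes or [Mode.LOSSLESS]
    representations = representations or [Representation.FULL]
    rows: list[dict] = []
    for s in corpus:
        for rep in representations:
            for mode in modes:
                for strategy in strategies:
                    if strategy in INTER_STRATEGIES and not check_homogeneous(s):
                        continue
                    container, stats = compress_with_stats(s, strategy, mode, rep, options)
                    n_total = sum(int(n) for n in container.header["n_atoms"])
                    raw = 3 * n_total * 8
                    comp = container.payload_bytes
                    rows.append(
                        {
                            "label": s.label,
                            "strategy": strategy.value,
                            "mode": mode.value,
                            "rep": rep.value,
                            "n_atoms": n_total,
                            "bytes_raw": raw,
                            "bytes_compressed": comp,
                            "ratio": raw / comp,
                            "entropy": stats["shannon_entropy"],
                        }
                    )
    return rows


def benchmark_tsv(rows: list[dict]) -> str:
    cols = [
        "label", "strategy", "mode", "rep", "n_atoms",
        "bytes_raw", "bytes_compressed", "ratio", "entropy",
    ]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append(
            "\t".join(
                f"{r[c]:.4f}" if isinstance(r[c], float) else str(r[c]) for c in cols
            )
        )
    return "\n".join(lines) + "\n"
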