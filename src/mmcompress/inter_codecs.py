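"""Intermolecular referencing for sets of identical molecules.

Multi-model ensembles and repeated identical subunits contain near-duplicate
coordinate sets.  Instead of encoding each molecule independently, one root
molecule is encoded intramolecularly and every other molecule is stored as
per-atom integer residuals against an (optionally superposed) reference
molecule.  The order of referencing is a :class:`TraversalPlan` produced by
one of three strategies:

* ``reference`` -- every molecule referenced to the first;
* ``waterfall`` -- each molecule referenced to its predecessor;
* ``mst`` -- molecules form a complete weighted graph (RMSD or gzipped-
  difference weights); a minimum spanning tree is built with Prim's
  algorithm, its diameter path (found by double BFS) is encoded first as a
  chain, and branches hang off their attachment nodes.

Rigid-body superposition (least-squares fit) before differencing removes
global motion; each transform costs 24 bytes (translation) + 32 bytes
(quaternion) and is stored next to the residuals.
"""

from __future__ import annotations

import enum
import logging
import struct
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .entropy import EntropyBackend, entropy_compress
from .intra_codecs import (
    CodecId,
    EncodedPayload,
    QuantizedCoords,
    delta_decode,
    delta_encode,
    quantize,
    round_half_away,
    _check_int32,
)
from .packing import PackerId, pack_to_bytes
from .structure_model import CoordinateArrays, Molecule, StructureSet, check_homogeneous

logger = logging.getLogger(__name__)


class TraversalStrategy(str, enum.Enum):
    REFERENCE = "reference"
    WATERFALL = "waterfall"
    MST = "mst"


class EdgeMetric(str, enum.Enum):
    RMSD = "rmsd"
    GZIP = "gzip"


class InterBase(str, enum.Enum):
    DELTA = "delta"
    PREDICTIVE = "predictive"


@dataclass
class WeightedMoleculeGraph:
    """Complete undirected graph over molecules with pairwise edge weights."""

    n: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (self.n, self.n):
            raise ValueError("weight matrix shape must be (n, n)")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        self.weights = w


@dataclass
class TraversalPlan:
    """Ordered (target, reference) pairs; the reference of every pair is the
    root or an earlier target."""

    strategy_id: TraversalStrategy
    pairs: list[tuple[int, int]]
    root_index: int = 0

    def validate(self, n: int) -> None:
        seen = {self.root_index}
        targets = [t for t, _ in self.pairs]
        if sorted(targets + [self.root_index]) != list(range(n)):
            raise ValueError("plan must cover every molecule exactly once")
        for t, r in self.pairs:
            if r not in seen:
                raise ValueError(f"pair ({t}, {r}) references a later molecule")
            seen.add(t)


@dataclass
class SuperpositionTransform:
    """Rigid motion mapping a reference molecule onto a target.

    Serialized as 3 + 4 IEEE-754 little-endian doubles: 24 bytes for the
    translation, 32 for the rotation quaternion (scalar-last, w >= 0).
    """

    translation: np.ndarray  # (3,)
    rotation: np.ndarray  # quaternion (x, y, z, w), |q| = 1, w >= 0

    SERIALIZED_SIZE = 56
    TRANSLATION_BYTES = 24
    QUATERNION_BYTES = 32

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        q = np.asarray(self.rotation, dtype=np.float64).reshape(4)
        norm = np.linalg.norm(q)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {norm} is not 1")
        if q[3] < 0:
            q = -q
        self.rotation = q

    def serialize(self) -> bytes:
        return struct.pack("<3d", *self.translation) + struct.pack("<4d", *self.rotation)

    @classmethod
    def deserialize(cls, b: bytes) -> "SuperpositionTransform":
        if len(b) != cls.SERIALIZED_SIZE:
            raise ValueError(f"transform blob must be {cls.SERIALIZED_SIZE} bytes")
        t = np.array(struct.unpack("<3d", b[:24]))
        q = np.array(struct.unpack("<4d", b[24:]))
        return cls(t, q)

    def apply(self, coords: CoordinateArrays) -> CoordinateArrays:
        rot = Rotation.from_quat(self.rotation)
        m = rot.apply(coords.as_matrix()) + self.translation
        return CoordinateArrays.from_matrix(m)

    @classmethod
    def identity(cls) -> "SuperpositionTransform":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]))


def rmsd(a: Molecule, b: Molecule) -> float:
    """Root-mean-square deviation over index-paired atoms, no superposition:
    ``sqrt(sum_i (dx_i^2 + dy_i^2 + dz_i^2) / N)``."""
    if a.n_atoms != b.n_atoms:
        raise ValueError(
            f"RMSD needs equal atom counts, got {a.n_atoms} and {b.n_atoms}"
        )
    d = a.coords.as_matrix() - b.coords.as_matrix()
    return float(np.sqrt(np.sum(d * d) / a.n_atoms))


def gzip_weight(a: Molecule, b: Molecule, factor: int = 1000) -> float:
    """Compressed size of the quantized coordinate differences of a pair.

    The differences are sign-canonicalized (first nonzero difference made
    positive) so the weight is exactly symmetric in its arguments.
    """
    if a.n_atoms != b.n_atoms:
        raise ValueError("gzip weight needs equal atom counts")
    qa = quantize(a.coords, factor).values.astype(np.int64)
    qb = quantize(b.coords, factor).values.astype(np.int64)
    d = qa - qb
    nz = np.flatnonzero(d)
    if len(nz) and d[nz[0]] < 0:
        d = -d
    packed = pack_to_bytes(_check_int32(d, "coordinate difference"), PackerId.RECURSIVE_INDEX_16)
    return float(len(entropy_compress(packed, EntropyBackend.GZIP)))


def build_weight_graph(
    s: StructureSet, metric: EdgeMetric = EdgeMetric.RMSD, factor: int = 1000
) -> WeightedMoleculeGraph:
    n = len(s)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric is EdgeMetric.RMSD:
                w[i, j] = rmsd(s.molecules[i], s.molecules[j])
            else:
                w[i, j] = gzip_weight(s.molecules[i], s.molecules[j], factor)
            w[j, i] = w[i, j]
    return WeightedMoleculeGraph(n, w)


def build_mst(g: WeightedMoleculeGraph) -> np.ndarray:
    """Prim's algorithm over the complete graph; returns a parent array with
    -1 at the root (vertex 0).  Ties break toward the lowest vertex index,
    so the tree is deterministic."""
    n = g.n
    parent = np.full(n, -1, dtype=np.int64)
    if n == 1:
        return parent
    in_tree = np.zeros(n, dtype=bool)
    best_w = np.full(n, np.inf)
    best_p = np.full(n, -1, dtype=np.int64)
    in_tree[0] = True
    best_w[1:] = g.weights[0, 1:]
    best_p[1:] = 0
    for _ in range(n - 1):
        candidates = np.flatnonzero(~in_tree)
        v = candidates[np.argmin(best_w[candidates])]  # argmin takes first = lowest index
        in_tree[v] = True
        parent[v] = best_p[v]
        improved = (~in_tree) & (g.weights[v] < best_w)
        best_w[improved] = g.weights[v][improved]
        best_p[improved] = v
    return parent


def _adjacency(parent: np.ndarray) -> list[list[int]]:
    n = len(parent)
    adj: list[list[int]] = [[] for _ in range(n)]
    for v, p in enumerate(parent):
        if p >= 0:
            adj[v].append(int(p))
            adj[p].append(v)
    for lst in adj:
        lst.sort()
    return adj


def _bfs_farthest(adj: list[list[int]], start: int) -> tuple[int, dict[int, int]]:
    """Farthest vertex from ``start`` by hop count (lowest index on ties),
    plus the BFS predecessor map."""
    prev = {start: -1}
    frontier = [start]
    dist = {start: 0}
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    far = max(dist, key=lambda v: (dist[v], -v))
    return far, prev


def mst_traversal_order(parent: np.ndarray) -> TraversalPlan:
    """Turn an MST into an encoding order: the tree's diameter path first
    (found by running BFS twice), then branches outward from the path.

    The first diameter endpoint becomes the root molecule; branch vertices
    are emitted in BFS order from the path, children visited lowest index
    first.
    """
    n = len(parent)
    if n == 1:
        return TraversalPlan(TraversalStrategy.MST, [], 0)
    adj = _adjacency(parent)
    u, _ = _bfs_farthest(adj, 0)
    v, prev = _bfs_farthest(adj, u)
    path = []
    cur = v
    while cur != -1:
        path.append(cur)
        cur = prev[cur]
    path.reverse()  # runs from u to v
    pairs = [(path[i], path[i - 1]) for i in range(1, len(path))]
    on_path = set(path)
    visited = set(path)
    frontier = list(path)
    while frontier:
        nxt = []
        for p in frontier:
            for c in adj[p]:
                if c not in visited:
                    visited.add(c)
                    pairs.append((c, p))
                    nxt.append(c)
        frontier = nxt
    plan = TraversalPlan(TraversalStrategy.MST, pairs, root_index=path[0])
    plan.validate(n)
    return plan


def reference_plan(n: int) -> TraversalPlan:
    """First molecule is the reference for every other molecule."""
    if n < 1:
        raise ValueError("need at least one molecule")
    return TraversalPlan(TraversalStrategy.REFERENCE, [(i, 0) for i in range(1, n)], 0)


def waterfall_plan(n: int) -> TraversalPlan:
    """Each molecule referenced to the one before it."""
    if n < 1:
        raise ValueError("need at least one molecule")
    return TraversalPlan(TraversalStrategy.WATERFALL, [(i, i - 1) for i in range(1, n)], 0)


def make_plan(
    s: StructureSet,
    strategy: TraversalStrategy,
    metric: EdgeMetric = EdgeMetric.RMSD,
    factor: int = 1000,
) -> TraversalPlan:
    n = len(s)
    if strategy is TraversalStrategy.REFERENCE:
        return reference_plan(n)
    if strategy is TraversalStrategy.WATERFALL:
        return waterfall_plan(n)
    return mst_traversal_order(build_mst(build_weight_graph(s, metric, factor)))


def superpose(
    mobile: Molecule, target: Molecule
) -> tuple[SuperpositionTransform, Molecule]:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``.

    Returns the transform (always a proper rotation, det +1) and the
    transformed copy of ``mobile``.  Degenerate geometry -- fewer than three
    atoms or a collinear point set, where the rotation is not unique --
    falls back to a pure translation of centroids with a logged warning.
    """
    if mobile.n_atoms != target.n_atoms:
        raise ValueError("superposition needs equal atom counts")
    m = mobile.coords.as_matrix()
    t = target.coords.as_matrix()
    cm = m.mean(axis=0)
    ct = t.mean(axis=0)
    mc = m - cm
    degenerate = mobile.n_atoms < 3
    if not degenerate:
        sv = np.linalg.svd(mc, compute_uv=False)
        degenerate = sv[1] <= 1e-9 * max(sv[0], 1.0)
    if degenerate:
        logger.warning(
            "degenerate geometry (collinear or < 3 atoms): translation-only superposition"
        )
        transform = SuperpositionTransform(ct - cm, np.array([0.0, 0.0, 0.0, 1.0]))
    else:
        rot, _ = Rotation.align_vectors(t - ct, mc)
        q = rot.as_quat()
        transform = SuperpositionTransform(ct - rot.apply(cm), q / np.linalg.norm(q))
    moved = transform.apply(mobile.coords)
    return transform, Molecule(mobile.atoms, moved)


@dataclass
class InterPayload:
    """Everything needed to reconstruct a homogeneous set bitwise."""

    root_payload: EncodedPayload
    residuals: list[np.ndarray]  # int32 per plan pair
    transforms: list[SuperpositionTransform | None]
    plan: TraversalPlan
    factor: int
    n_atoms: int
    base: InterBase = InterBase.DELTA


def _predicted_quantized(
    q_ref: QuantizedCoords, transform: SuperpositionTransform | None, factor: int
) -> np.ndarray:
    """Reference coordinates as the decoder will see them: dequantized, moved
    by the stored transform, re-quantized.  Encoder and decoder share this
    path so residuals cancel bitwise."""
    if transform is None:
        return q_ref.values.astype(np.int64)
    from .intra_codecs import dequantize  # local import to avoid cycle noise

    moved = transform.apply(dequantize(q_ref))
    return round_half_away(
        np.concatenate([moved.x, moved.y, moved.z]) * factor
    ).astype(np.int64)


def inter_encode(
    s: StructureSet,
    plan: TraversalPlan,
    base: InterBase = InterBase.DELTA,
    do_superpose: bool = True,
    factor: int = 1000,
) -> InterPayload:
    """Encode a homogeneous set as a root molecule plus per-pair residuals.

    With the ``delta`` base the residual for pair (t, r) is
    ``q(t) - q(moved r)``.  The ``predictive`` base stores the change of that
    residual along the traversal chain (second-order prediction across
    molecules: ``e = c_k - (2 c_{k-1} - c_{k-2})`` in transformed frames),
    falling back to delta where the reference is the chain start.
    """
    if not check_homogeneous(s):
        raise ValueError("intermolecular encoding requires a homogeneous molecule set")
    plan.validate(len(s))
    qs = [quantize(m.coords, factor) for m in s.molecules]
    n_atoms = s.molecules[0].n_atoms
    root = plan.root_index
    root_payload = EncodedPayload(
        codec_id=CodecId.DELTA,
        main=delta_encode(qs[root].values),
        n_atoms=n_atoms,
        factor=factor,
    )
    residuals: list[np.ndarray] = []
    transforms: list[SuperpositionTransform | None] = []
    chain_residual: dict[int, np.ndarray] = {}  # target -> its delta residual
    from .intra_codecs import dequantize

    grid_mols = {
        i: Molecule(s.molecules[i].atoms, dequantize(qs[i])) for i in range(len(s))
    }
    for t, r in plan.pairs:
        if do_superpose:
            transform, _ = superpose(grid_mols[r], grid_mols[t])
        else:
            transform = None
        pred = _predicted_quantized(qs[r], transform, factor)
        d = qs[t].values.astype(np.int64) - pred
        if base is InterBase.PREDICTIVE and r in chain_residual:
            stored = d - chain_residual[r]
        else:
            stored = d
        chain_residual[t] = d
        residuals.append(_check_int32(stored, "intermolecular residual"))
        transforms.append(transform)
    return InterPayload(root_payload, residuals, transforms, plan, factor, n_atoms, base)


def inter_decode(p: InterPayload) -> list[QuantizedCoords]:
    """Reconstruct every molecule's quantized coordinates bitwise; output is
    indexed by molecule position (root included)."""
    n = len(p.residuals) + 1
    p.plan.validate(n)
    values: dict[int, np.ndarray] = {
        p.plan.root_index: delta_decode(p.root_payload.main).astype(np.int64)
    }
    chain_residual: dict[int, np.ndarray] = {}
    for (t, r), stored, transform in zip(p.plan.pairs, p.residuals, p.transforms):
        if r not in values:
            raise ValueError(f"plan order violation: reference {r} not yet decoded")
        q_ref = QuantizedCoords(_check_int32(values[r], "reference"), p.factor)
        pred = _predicted_quantized(q_ref, transform, p.factor)
        stored = stored.astype(np.int64)
        if p.base is InterBase.PREDICTIVE and r in chain_residual:
            d = stored + chain_residual[r]
        else:
            d = stored
        chain_residual[t] = d
        values[t] = pred + d
    return [
        QuantizedCoords(_check_int32(values[i], "molecule"), p.factor) for i in range(n)
    ]
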