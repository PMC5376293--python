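import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mmcompress.inter_codecs import (
    EdgeMetric,
    InterBase,
    SuperpositionTransform,
    TraversalStrategy,
    WeightedMoleculeGraph,
    build_mst,
    build_weight_graph,
    gzip_weight,
    inter_decode,
    inter_encode,
    make_plan,
    mst_traversal_order,
    reference_plan,
    rmsd,
    superpose,
    waterfall_plan,
)
from mmcompress.intra_codecs import quantize
from mmcompress.structure_model import (
    CoordinateArrays,
    Grouping,
    Molecule,
    StructureSet,
)
from mmcompress.synthetic_fixtures import FixtureSpec, make_ensemble, make_polymer


def _bare_molecule(coords):
    from mmcompress.structure_model import Atom
    return Molecule([Atom("CA") for _ in range(len(coords))], coords)


def _shift(mol, dx=0.0, dy=0.0, dz=0.0):
    return Molecule(
        mol.atoms,
        CoordinateArrays(mol.coords.x + dx, mol.coords.y + dy, mol.coords.z + dz),
    )


class TestRmsd:
    def test_identical_molecules(self, polymer):
        assert rmsd(polymer, polymer) == 0.0

    def test_translation_3_4_0_gives_5(self, polymer):
        assert rmsd(polymer, _shift(polymer, 3.0, 4.0)) == pytest.approx(5.0, abs=1e-12)

    def test_two_atom_closed_form(self):
        a = _bare_molecule(CoordinateArrays([0.0, 1.0], [0.0, 0.0], [0.0, 0.0]))
        b = _bare_molecule(CoordinateArrays([0.0, 0.0], [0.0, 0.0], [0.0, 0.0]))
        assert rmsd(a, b) == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_count_mismatch_raises(self, polymer):
        other = make_polymer(FixtureSpec(seed=1, n_atoms=10))
        with pytest.raises(ValueError):
            rmsd(polymer, other)


class TestGzipWeight:
    def test_identical_molecules_near_minimal(self, polymer):
        w_same = gzip_weight(polymer, polymer)
        noisy = _shift(polymer, 0.5)
        rng = np.random.default_rng(0)
        jitter = Molecule(
            polymer.atoms,
            CoordinateArrays.from_matrix(
                (polymer.coords.as_matrix() + rng.normal(0, 0.5, (polymer.n_atoms, 3))).round(3)
            ),
        )
        assert w_same < gzip_weight(polymer, jitter)
        assert w_same < 60  # an all-zero difference stream gzips to a stub

    def test_symmetric(self, ensemble):
        a, b = ensemble.molecules[0], ensemble.molecules[3]
        assert gzip_weight(a, b) == gzip_weight(b, a)

    def test_monotone_in_noise_level(self, polymer):
        rng = np.random.default_rng(42)
        weights = []
        for sigma in (0.01, 0.1, 1.0):
            noisy = Molecule(
                polymer.atoms,
                CoordinateArrays.from_matrix(
                    (polymer.coords.as_matrix()
                     + rng.normal(0, sigma, (polymer.n_atoms, 3))).round(3)
                ),
            )
            weights.append(gzip_weight(polymer, noisy))
        assert weights[0] < weights[1] < weights[2]


def _brute_force_mst_weight(w: np.ndarray) -> float:
    """Minimum spanning-tree weight by exhaustive enumeration of all edge
    subsets of size n-1 that span the graph."""
    n = len(w)
    if n == 1:
        return 0.0
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for i, j in subset:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if ok:
            best = min(best, sum(w[i, j] for i, j in subset))
    return best


class TestMst:
    def test_single_vertex(self):
        g = WeightedMoleculeGraph(1, np.zeros((1, 1)))
        assert list(build_mst(g)) == [-1]

    def test_three_vertex_unique_minimum(self):
        w = np.array([[0, 1, 9], [1, 0, 2], [9, 2, 0]], dtype=float)
        parent = build_mst(WeightedMoleculeGraph(3, w))
        edges = sorted(
            (min(v, int(p)), max(v, int(p))) for v, p in enumerate(parent) if p >= 0
        )
        assert edges == [(0, 1), (1, 2)]

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_total_weight_matches_brute_force(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            w = rng.uniform(0.1, 10.0, (n, n))
            w = (w + w.T) / 2
            np.fill_diagonal(w, 0.0)
            parent = build_mst(WeightedMoleculeGraph(n, w))
            total = sum(w[v, p] for v, p in enumerate(parent) if p >= 0)
            assert total == pytest.approx(_brute_force_mst_weight(w), rel=1e-12)


class TestTraversalPlans:
    def test_path_graph_is_one_chain(self):
        parent = np.array([-1, 0, 1])
        plan = mst_traversal_order(parent)
        chain = {plan.root_index} | {t for t, _ in plan.pairs}
        assert chain == {0, 1, 2}
        for t, r in plan.pairs:
            assert abs(t - r) == 1  # consecutive along the path

    def test_star_graph_third_leaf_references_center(self):
        # center 0, leaves 1..3: the diameter runs leaf-center-leaf and the
        # remaining leaf must reference the center
        parent = np.array([-1, 0, 0, 0])
        plan = mst_traversal_order(parent)
        refs = dict((t, r) for t, r in plan.pairs)
        leaves_on_path = {plan.root_index} | {
            t for t, r in plan.pairs if r != 0 or t == 0
        }
        off_path = [t for t, r in plan.pairs if r == 0]
        assert len(off_path) >= 1
        assert all(refs[t] == 0 for t in off_path)

    def test_branch_off_diameter_references_attachment_node(self):
        # chain 0-1-2 with branch 3 attached to 1: 3 must reference 1
        parent = np.array([-1, 0, 1, 1])
        plan = mst_traversal_order(parent)
        assert (3, 1) in plan.pairs

    def test_reference_and_waterfall_shapes(self):
        assert reference_plan(3).pairs == [(1, 0), (2, 0)]
        assert waterfall_plan(3).pairs == [(1, 0), (2, 1)]
        assert waterfall_plan(1).pairs == []

    def test_plan_invariants(self, ensemble):
        for strategy in TraversalStrategy:
            plan = make_plan(ensemble, strategy)
            plan.validate(len(ensemble))


class TestSuperpose:
    def test_identity_on_equal_molecules(self, polymer):
        tr, moved = superpose(polymer, polymer)
        assert np.allclose(tr.translation, 0.0, atol=1e-9)
        assert np.allclose(tr.rotation, [0, 0, 0, 1], atol=1e-9)
        assert rmsd(moved, polymer) < 1e-9

    def test_recovers_known_rigid_motion(self, polymer):
        rot = Rotation.from_euler("zyx", [12.0, -33.0, 71.0], degrees=True)
        t = np.array([4.0, -7.5, 2.25])
        target = Molecule(
            polymer.atoms,
            CoordinateArrays.from_matrix(rot.apply(polymer.coords.as_matrix()) + t),
        )
        tr, moved = superpose(polymer, target)
        q_true = rot.as_quat()
        if q_true[3] < 0:
            q_true = -q_true
        assert np.allclose(tr.rotation, q_true, atol=1e-6)
        assert np.allclose(tr.translation, t, atol=1e-6)
        assert rmsd(moved, target) < 1e-6

    def test_proper_rotation_for_near_planar_molecule(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 5, (40, 3))
        pts[:, 2] *= 1e-4  # nearly planar: reflections become tempting optima
        mobile = _bare_molecule(CoordinateArrays.from_matrix(pts))
        target = _bare_molecule(CoordinateArrays.from_matrix(-pts))
        tr, _ = superpose(mobile, target)
        det = np.linalg.det(Rotation.from_quat(tr.rotation).as_matrix())
        assert det == pytest.approx(1.0, abs=1e-9)

    def test_collinear_falls_back_to_translation(self):
        x = np.arange(5, dtype=float)
        a = _bare_molecule(CoordinateArrays(x, np.zeros(5), np.zeros(5)))
        b = _bare_molecule(CoordinateArrays(x + 2.0, np.zeros(5) + 1.0, np.zeros(5)))
        tr, moved = superpose(a, b)
        assert np.allclose(tr.rotation, [0, 0, 0, 1])
        assert rmsd(moved, b) < 1e-12

    def test_never_increases_rmsd(self, unaligned_ensemble):
        mols = unaligned_ensemble.molecules
        for a, b in zip(mols, mols[1:]):
            _, moved = superpose(a, b)
            assert rmsd(moved, b) <= rmsd(a, b) + 1e-9


class TestTransformSerialization:
    def test_fixed_24_plus_32_bytes(self):
        tr = SuperpositionTransform.identity()
        blob = tr.serialize()
        assert len(blob) == 56
        assert SuperpositionTransform.TRANSLATION_BYTES == 24
        assert SuperpositionTransform.QUATERNION_BYTES == 32

    def test_serialization_round_trip(self):
        q = np.array([0.1, -0.2, 0.3, 0.9])
        q /= np.linalg.norm(q)
        tr = SuperpositionTransform(np.array([1.5, -2.5, 3.5]), q)
        back = SuperpositionTransform.deserialize(tr.serialize())
        np.testing.assert_array_equal(back.translation, tr.translation)
        np.testing.assert_array_equal(back.rotation, tr.rotation)

    def test_unit_quaternion_enforced(self):
        with pytest.raises(ValueError):
            SuperpositionTransform(np.zeros(3), np.array([1.0, 1.0, 0.0, 0.0]))


class TestInterCoding:
    def test_identical_copies_have_zero_residuals(self, polymer):
        s = StructureSet([polymer] * 3, grouping=Grouping.MODELS)
        p = inter_encode(s, waterfall_plan(3), do_superpose=False)
        assert all(np.all(r == 0) for r in p.residuals)

    def test_translated_copies_zero_residuals_after_superposition(self, polymer):
        # grid-aligned translations are recovered exactly by the fit
        mols = [polymer, _shift(polymer, 5.0, -3.0, 8.0), _shift(polymer, -10.0, 0.5, 2.0)]
        s = StructureSet(mols, grouping=Grouping.MODELS)
        p = inter_encode(s, waterfall_plan(3), do_superpose=True)
        assert all(np.all(r == 0) for r in p.residuals)

    @pytest.mark.parametrize("strategy", list(TraversalStrategy))
    @pytest.mark.parametrize("base", list(InterBase))
    @pytest.mark.parametrize("do_superpose", [True, False])
    def test_round_trip_bitwise(self, unaligned_ensemble, strategy, base, do_superpose):
        s = unaligned_ensemble
        plan = make_plan(s, strategy)
        payload = inter_encode(s, plan, base=base, do_superpose=do_superpose)
        decoded = inter_decode(payload)
        for mol, q in zip(s.molecules, decoded):
            np.testing.assert_array_equal(q.values, quantize(mol.coords, 1000).values)

    def test_lossy_round_trip_bitwise_on_coarse_grid(self, ensemble):
        payload = inter_encode(ensemble, waterfall_plan(len(ensemble)), factor=10)
        decoded = inter_decode(payload)
        for mol, q in zip(ensemble.molecules, decoded):
            np.testing.assert_array_equal(q.values, quantize(mol.coords, 10).values)

    def test_non_homogeneous_rejected(self, polymer):
        other = make_polymer(FixtureSpec(seed=5, n_atoms=polymer.n_atoms - 1))
        s = StructureSet([polymer, other])
        with pytest.raises(ValueError):
            inter_encode(s, waterfall_plan(2))

    def test_decode_rejects_out_of_order_plan(self, ensemble):
        payload = inter_encode(ensemble, waterfall_plan(len(ensemble)))
        payload.plan.pairs[0] = (1, 5)  # reference 5 is decoded after 1
        with pytest.raises(ValueError):
            inter_decode(payload)

    def test_gzip_metric_plan_round_trips(self, ensemble):
        plan = make_plan(ensemble, TraversalStrategy.MST, EdgeMetric.GZIP)
        payload = inter_encode(ensemble, plan)
        decoded = inter_decode(payload)
        for mol, q in zip(ensemble.molecules, decoded):
            np.testing.assert_array_equal(q.values, quantize(mol.coords, 1000).values)
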