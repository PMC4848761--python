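import numpy as np
import pytest

from erprofiler.structure_features import (
    Atom,
    AtomPairSpec,
    Chain,
    LigandComponent,
    Residue,
    StructureError,
    StructureModel,
    atom_pair_distance,
    distance_activity_regression,
    ensemble_distance_stats,
    kabsch_superpose,
    ligand_dimension,
    read_structure,
    superpose_ensemble,
    write_structure_pdb,
)
from erprofiler.synthetic_data import StructureSimParams, simulate_structure_ensemble

MINIMAL_PDB = """\
ATOM      1  CA  ALA A 310       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A 311       3.000   4.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A 312       0.000   0.000   5.000  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A 310       1.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A 310       9.000   0.000   0.000  0.40  0.00           C
ATOM      3  CA  ALA A 311       0.000   2.000   0.000  1.00  0.00           C
ATOM      4  CA  ALA A 312       0.000   0.000   3.000  1.00  0.00           C
HETATM    5  O1  LIG A 901       0.000   0.000   0.000  1.00  0.00           O
HETATM    6  O2  LIG A 901      12.000   0.000   0.000  1.00  0.00           O
HETATM    7  O   HOH A 902       5.000   5.000   5.000  1.00  0.00           O
END
"""


def toy_model(coords_by_residue, sid="TOY", chain_id="A"):
    chain = Chain(chain_id=chain_id)
    for num, pos in coords_by_residue.items():
        chain.residues[num] = Residue(num, "ALA", {"CA": Atom("CA", "C", np.asarray(pos, float))})
    return StructureModel(structure_id=sid, chains={chain_id: chain})


def quaternion_rmsd(P, Q):
    """Independent quaternion-method superposition RMSD (Kearsley/Horn)."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (P0 * P0).sum() + (Q0 * Q0).sum()
    return np.sqrt(max(0.0, e0 - 2.0 * lam) / P.shape[0])


def random_rotation(rng):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


class TestReadStructure:
    def test_minimal_pdb_exact_coordinates(self, tmp_path):
        p = tmp_path / "m.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        chain = model.chains["A"]
        assert len(chain.residues) == 3
        np.testing.assert_allclose(chain.residues[311].atoms["CA"].pos, [3.0, 4.0, 0.0])

    def test_altloc_highest_occupancy_and_water_dropped(self, tmp_path):
        p = tmp_path / "a.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_structure(p)
        chain = model.chains["A"]
        # conformer A (occ 0.60) retained
        assert chain.residues[310].atoms["CA"].pos[0] == pytest.approx(1.0)
        codes = [l.component_code for l in chain.ligands]
        assert codes == ["LIG"]  # water excluded, ligand separated from protein

    def test_unparseable_file_errors(self, tmp_path):
        p = tmp_path / "bad.cif"
        p.write_text("data_x\nloop_ nonsense\n")
        with pytest.raises(StructureError):
            read_structure(p)


class TestKabschSuperpose:
    def test_identity(self, rng):
        P = rng.normal(size=(10, 3))
        res = kabsch_superpose(P, P)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-12)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_rigid_motion(self, rng):
        P = rng.normal(size=(12, 3))
        theta = np.pi / 2
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        t = np.array([5.0, -3.0, 11.0])
        res = kabsch_superpose(P, P @ R.T + t)
        np.testing.assert_allclose(res.rotation, R, atol=1e-8)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(100):
            P = rng.normal(scale=5.0, size=(20, 3))
            Q = P @ random_rotation(rng).T + rng.normal(scale=2.0, size=3) + rng.normal(
                scale=0.5, size=(20, 3)
            )
            res = kabsch_superpose(P, Q)
            assert res.rmsd == pytest.approx(quaternion_rmsd(P, Q), abs=1e-8)

    def test_rotations_proper_orthogonal(self, rng):
        for _ in range(25):
            P = rng.normal(size=(8, 3))
            Q = rng.normal(size=(8, 3))
            R = kabsch_superpose(P, Q).rotation
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_improper_reflection_rejected(self, rng):
        # mirrored cloud: best proper rotation still has det +1
        P = rng.normal(size=(10, 3))
        Q = P.copy()
        Q[:, 0] = -Q[:, 0]
        R = kabsch_superpose(P, Q).rotation
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_rmsd_not_above_untransformed(self, rng):
        P, Q = rng.normal(size=(15, 3)), rng.normal(size=(15, 3))
        raw = np.sqrt(((P - Q) ** 2).sum() / 15)
        assert kabsch_superpose(P, Q).rmsd <= raw + 1e-12

    def test_degenerate_inputs(self):
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(StructureError, match="collinear"):
            kabsch_superpose(line, line)


class TestSuperposeEnsemble:
    def test_identical_copies_rmsd_zero(self, rng):
        coords = {i: rng.normal(size=3) * 10 for i in range(310, 330)}
        models = [toy_model(coords, sid=f"M{k}") for k in range(3)]
        rmsds = superpose_ensemble(models, "M0", core=range(310, 330))
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in rmsds.values())

    def test_rigidity_preserves_intra_structure_distances(self, rng):
        coords = {i: rng.normal(size=3) * 10 for i in range(310, 340)}
        ref = toy_model(coords, sid="REF")
        mob = toy_model(coords, sid="MOB")
        R, t = random_rotation(rng), rng.normal(size=3) * 20
        mob.transform(R, t)
        pairs = [(AtomPairSpec(a, b)) for a, b in [(310, 339), (315, 325), (311, 334)]]
        before = [atom_pair_distance(mob, p, "named_chain", "A") for p in pairs]
        superpose_ensemble([ref, mob], "REF", core=range(310, 340))
        after = [atom_pair_distance(mob, p, "named_chain", "A") for p in pairs]
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_synthetic_rmsd_within_jitter_bound(self):
        params = StructureSimParams(seed=3)
        models, truth = simulate_structure_ensemble(params)
        all_models = models + [truth.reference_model]
        lo, hi = params.core_residues
        rmsds = superpose_ensemble(all_models, "REF", core=range(lo, hi + 1))
        mean_rmsd = np.mean([v for k, v in rmsds.items() if k != "REF"])
        bound = params.jitter_sd * np.sqrt(3)
        assert 0.8 * bound <= mean_rmsd <= 1.2 * bound

    def test_chain_matching_failure_names_structure(self, rng):
        ref = toy_model({i: rng.normal(size=3) for i in range(310, 320)}, sid="REF")
        bad = toy_model({i: rng.normal(size=3) for i in range(400, 410)}, sid="BAD")
        with pytest.raises(StructureError, match="BAD"):
            superpose_ensemble([ref, bad], "REF", core=range(310, 320))


class TestAtomPairDistance:
    def test_pythagorean(self):
        m = toy_model({347: [0.0, 0.0, 0.0], 525: [3.0, 4.0, 0.0]})
        assert atom_pair_distance(m, AtomPairSpec(347, 525), "named_chain", "A") == pytest.approx(5.0)

    def test_same_atom_zero(self):
        m = toy_model({347: [1.0, 2.0, 3.0]})
        assert atom_pair_distance(m, AtomPairSpec(347, 347), "named_chain", "A") == 0.0

    def test_brute_force_norms(self, rng):
        coords = {i: rng.normal(size=3) * 8 for i in range(310, 320)}
        m = toy_model(coords)
        for a in range(310, 315):
            for b in range(315, 320):
                d = atom_pair_distance(m, AtomPairSpec(a, b), "named_chain", "A")
                assert d == pytest.approx(np.linalg.norm(np.subtract(coords[a], coords[b])), abs=1e-12)

    def test_mean_over_chains(self, rng):
        m = toy_model({347: [0.0, 0.0, 0.0], 525: [3.0, 4.0, 0.0]})
        chain_b = Chain(chain_id="B")
        chain_b.residues[347] = Residue(347, "ALA", {"CA": Atom("CA", "C", np.zeros(3))})
        chain_b.residues[525] = Residue(525, "ALA", {"CA": Atom("CA", "C", np.array([0.0, 0.0, 7.0]))})
        m.chains["B"] = chain_b
        assert atom_pair_distance(m, AtomPairSpec(347, 525), "mean_over_chains") == pytest.approx(6.0)
        per = atom_pair_distance(m, AtomPairSpec(347, 525), "each_chain")
        assert per == {"A": pytest.approx(5.0), "B": pytest.approx(7.0)}

    def test_missing_residue_listed(self):
        m = toy_model({347: [0.0, 0.0, 0.0]})
        with pytest.raises(StructureError, match="residue 525"):
            atom_pair_distance(m, AtomPairSpec(347, 525), "named_chain", "A")

    def test_invariant_under_rigid_motion(self, rng):
        coords = {i: rng.normal(size=3) * 5 for i in (347, 525)}
        m = toy_model(coords)
        d0 = atom_pair_distance(m, AtomPairSpec(347, 525), "named_chain", "A")
        m.transform(random_rotation(rng), rng.normal(size=3) * 30)
        d1 = atom_pair_distance(m, AtomPairSpec(347, 525), "named_chain", "A")
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestEnsembleDistanceStats:
    def build(self, dists_a, dists_b):
        models = []
        ids_a, ids_b = [], []
        for k, d in enumerate(dists_a):
            m = toy_model({347: [0.0, 0.0, 0.0], 525: [d, 0.0, 0.0]}, sid=f"A{k}")
            models.append(m)
            ids_a.append(m.structure_id)
        for k, d in enumerate(dists_b):
            m = toy_model({347: [0.0, 0.0, 0.0], 525: [d, 0.0, 0.0]}, sid=f"B{k}")
            models.append(m)
            ids_b.append(m.structure_id)
        return models, ids_a, ids_b

    def test_identical_classes(self):
        models, a, b = self.build([10.0, 10.0, 10.0], [10.0, 10.0])
        res = ensemble_distance_stats(models, AtomPairSpec(347, 525), a, b)
        assert res.mean_difference == 0.0 and res.p_value == 1.0

    def test_exact_separation_flagged(self):
        models, a, b = self.build([10.0, 10.0, 10.0], [11.0] * 5)
        res = ensemble_distance_stats(models, AtomPairSpec(347, 525), a, b)
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.exact_separation and res.p_value == 0.0

    def test_matches_two_sample_t(self, rng):
        da = rng.normal(11.0, 0.3, 5)
        db = rng.normal(11.4, 0.3, 3)
        models, a, b = self.build(da.tolist(), db.tolist())
        res = ensemble_distance_stats(models, AtomPairSpec(347, 525), a, b)
        from scipy import stats

        t_ref, p_ref = stats.ttest_ind(da, db, equal_var=True)
        assert res.t_stat == pytest.approx(t_ref, abs=1e-10)
        assert res.p_value == pytest.approx(p_ref, abs=1e-10)
        assert res.sem_a == pytest.approx(da.std(ddof=1) / np.sqrt(5), abs=1e-12)

    def test_class_too_small(self):
        models, a, b = self.build([10.0], [11.0, 11.5])
        with pytest.raises(StructureError):
            ensemble_distance_stats(models, AtomPairSpec(347, 525), a, b)


class TestDistanceActivityRegression:
    def test_recovers_generator_slope_sign(self):
        params = StructureSimParams(seed=5)
        models, truth = simulate_structure_ensemble(params)
        rng = np.random.default_rng(5)
        # re-derive the activities from stored truth: delta = delta0 + beta*a + noise
        acts = {
            lid: (truth.displacement[sid] - params.delta0) / params.beta
            for sid, lid in truth.structure_ligand.items()
        }
        dists = {m.structure_id: atom_pair_distance(m, AtomPairSpec(354, 525)) for m in models}
        fit, skipped = distance_activity_regression(dists, acts, truth.structure_ligand)
        assert skipped == 0
        assert np.sign(fit.slope) == np.sign(params.beta)
        assert fit.r2 >= 0.8

    def test_constant_distances_explain_nothing(self):
        dists = {f"S{k}": 10.0 for k in range(5)}
        acts = {f"L{k}": float(k) for k in range(5)}
        mapping = {f"S{k}": f"L{k}" for k in range(5)}
        fit, _ = distance_activity_regression(dists, acts, mapping)
        assert (fit.slope, fit.r2, fit.p_value) == (0.0, 0.0, 1.0)

    def test_unmapped_structures_counted(self, rng):
        dists = {f"S{k}": 10.0 + k for k in range(6)}
        acts = {f"L{k}": float(k) * 2 for k in range(4)}
        mapping = {f"S{k}": f"L{k}" for k in range(6)}  # L4, L5 have no activity
        fit, skipped = distance_activity_regression(dists, acts, mapping)
        assert skipped == 2 and fit.n == 4


class TestLigandDimension:
    def test_from_pdb(self, tmp_path):
        p = tmp_path / "l.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_structure(p)
        assert ligand_dimension(model, "LIG", "O1", "O2") == pytest.approx(12.0)
        assert ligand_dimension(model, "LIG", "O1", "O1") == 0.0

    def test_absent_component(self, tmp_path):
        p = tmp_path / "l.pdb"
        p.write_text(ALTLOC_PDB)
        model = read_structure(p)
        with pytest.raises(StructureError, match="EST"):
            ligand_dimension(model, "EST", "O1", "O2")


class TestPdbRoundTrip:
    def test_synthetic_ensemble_round_trips(self, tmp_path):
        models, _ = simulate_structure_ensemble(StructureSimParams(n_structures=2, seed=9))
        for m in models:
            path = write_structure_pdb(m, tmp_path / f"{m.structure_id}.pdb")
            back = read_structure(path)
            orig = np.array([a.pos for a in m.iter_atoms()])
            rt = np.array([a.pos for a in back.iter_atoms()])
            assert orig.shape == rt.shape
            # PDB stores 3 decimals
            np.testing.assert_allclose(np.sort(rt, axis=0), np.sort(orig, axis=0), atol=1e-3)
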