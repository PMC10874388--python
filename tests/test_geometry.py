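"""Interface-geometry operations against brute-force and closed-form oracles."""

import math

import numpy as np
import biotite.structure as struc
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pepgroove import geometry, synth
from pepgroove.errors import (
    InvalidPairingError,
    UnderdeterminedError,
    UnknownElementError,
)
from pepgroove.structio import AtomSet, Structure, select


def point_structure(coords, elements=None, chains=None, resnums=None, names=None):
    """Minimal structure from bare coordinates, one atom per residue by default."""
    coords = np.asarray(coords, float)
    n = len(coords)
    arr = struc.AtomArray(n)
    arr.coord = coords
    arr.chain_id = np.array(chains if chains is not None else ["A"] * n)
    arr.res_id = np.array(resnums if resnums is not None else np.arange(1, n + 1))
    arr.ins_code = np.array([""] * n)
    arr.res_name = np.array(["UNK"] * n)
    arr.atom_name = np.array(names if names is not None else ["C"] * n)
    arr.element = np.array(elements if elements is not None else ["C"] * n)
    arr.hetero = np.array([False] * n)
    return Structure(arr, "points")


class TestContacts:
    def test_planted_contacts_recovered_exactly(self, toy_complex, toy_ligand):
        structure, manifest = toy_complex
        report = geometry.contact_residues(structure, toy_ligand, cutoff=5.0)
        found = sorted(r.resnum for r in report.residues)
        assert found == manifest["contact_residues"]

    def test_matches_brute_force_distance_scan(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        report = geometry.contact_residues(structure, toy_ligand, cutoff=5.0)
        lig_idx = set(toy_ligand.indices.tolist())
        lig_xyz = toy_ligand.coords
        expected = {}
        for key, resname, idx in structure.residues():
            if set(idx.tolist()) & lig_idx:
                continue
            d = min(
                float(np.linalg.norm(structure.coords[i] - q))
                for i in idx
                for q in lig_xyz
            )
            if d <= 5.0:
                expected[key] = d
        assert {r.key: pytest.approx(r.min_distance) for r in report.residues} == {
            k: pytest.approx(v) for k, v in expected.items()
        }

    def test_far_atoms_give_empty_report(self):
        s = point_structure([[0, 0, 0], [6, 0, 0]], chains=["A", "B"])
        lig = select(s, "chain B")
        report = geometry.contact_residues(s, lig, cutoff=5.0)
        assert report.residues == []

    def test_cutoff_monotonicity(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        small = geometry.contact_residues(structure, toy_ligand, cutoff=3.5)
        large = geometry.contact_residues(structure, toy_ligand, cutoff=6.0)
        assert set(small.keys()) <= set(large.keys())


class TestConservation:
    def test_identity_pairing_identical_structures(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        report = geometry.contact_residues(structure, toy_ligand, cutoff=5.0)
        pairing = {k: k for k in report.keys()}
        comp = geometry.compare_conservation(report, report, pairing)
        assert comp.n_non_conserved == 0
        assert len(comp.conserved) == len(report.residues)

    def test_planted_substitutions_counted(self):
        # Homolog pair: same geometry, k=2 contact residues renamed.
        base = synth.ToyComplexSpec(
            n_receptor=12, n_ligand=5, contacts=(2, 5, 8), seed=1
        )
        mutant = synth.ToyComplexSpec(
            n_receptor=12, n_ligand=5, contacts=(2, 5, 8),
            substitutions={2: "MET", 8: "LEU"}, seed=1,
        )
        sa, _ = synth.make_toy_complex(base)
        sb, _ = synth.make_toy_complex(mutant)
        ra = geometry.contact_residues(sa, select(sa, "chain B"), 5.0)
        rb = geometry.contact_residues(sb, select(sb, "chain B"), 5.0)
        comp = geometry.compare_conservation(ra, rb, {k: k for k in ra.keys()})
        assert comp.n_non_conserved == 2
        assert sorted(p[0].resnum for p in comp.non_conserved) == [2, 8]

    def test_duplicate_target_rejected(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        report = geometry.contact_residues(structure, toy_ligand, cutoff=5.0)
        keys = report.keys()
        bad = [(keys[0], keys[0]), (keys[1], keys[0])]
        with pytest.raises(InvalidPairingError):
            geometry.compare_conservation(report, report, bad)

    def test_unmapped_residues_flagged_not_errored(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        report = geometry.contact_residues(structure, toy_ligand, cutoff=5.0)
        comp = geometry.compare_conservation(report, report, {})
        assert len(comp.unpaired_a) == len(report.residues)
        assert comp.n_non_conserved == 0


class TestMinDistance:
    def test_three_four_five(self):
        s = point_structure([[0, 0, 0], [3, 4, 0]])
        a = AtomSet(s, [0])
        b = AtomSet(s, [1])
        assert geometry.min_distance(a, b) == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(size=(100, 3)) * 10
        s = point_structure(coords)
        a = AtomSet(s, np.arange(50))
        b = AtomSet(s, np.arange(50, 100))
        oracle = min(
            float(np.linalg.norm(coords[i] - coords[j]))
            for i in range(50)
            for j in range(50, 100)
        )
        assert geometry.min_distance(a, b) == pytest.approx(oracle)
        assert geometry.min_distance(b, a) == pytest.approx(oracle)  # symmetry

    def test_overlap_rejected(self):
        s = point_structure([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            geometry.min_distance(AtomSet(s, [0, 1]), AtomSet(s, [1]))


class TestHBonds:
    def test_planted_ideal_hbond_detected(self, toy_complex, toy_ligand):
        structure, manifest = toy_complex
        receptor = toy_ligand.complement()
        bonds = geometry.detect_hbonds(structure, toy_ligand, receptor)
        planted = manifest["hbonds"][0]
        hits = [
            h
            for h in bonds
            if h.donor.chain == planted["donor"]["chain"]
            and h.donor.resnum == planted["donor"]["resnum"]
            and h.donor.name == planted["donor"]["atom"]
            and h.acceptor.resnum == planted["acceptor"]["resnum"]
            and h.acceptor.chain == planted["acceptor"]["chain"]
        ]
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(planted["distance"], abs=0.01)
        assert hits[0].angle == pytest.approx(planted["angle"], abs=1.0)

    def test_sorted_by_distance(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        bonds = geometry.detect_hbonds(structure, toy_ligand, toy_ligand.complement())
        dists = [h.distance for h in bonds]
        assert dists == sorted(dists)

    def test_pair_beyond_dmax_not_reported(self):
        # donor N with antecedent C; acceptor O at 5.0 A
        s = point_structure(
            [[0, 0, 0], [-1.4, 0, 0], [5.0, 0, 0]],
            elements=["N", "C", "O"],
            chains=["A", "A", "B"],
            resnums=[1, 1, 2],
            names=["N", "C", "O"],
        )
        bonds = geometry.detect_hbonds(
            s, AtomSet(s, [0, 1]), AtomSet(s, [2]), dmax=3.5
        )
        assert bonds == []


class TestSaltBridges:
    def test_planted_bridge_detected(self, toy_complex, toy_ligand):
        structure, manifest = toy_complex
        bridges = geometry.detect_salt_bridges(
            structure, toy_ligand, toy_ligand.complement()
        )
        planted = manifest["salt_bridges"][0]
        hits = [
            b
            for b in bridges
            if b.cation[0][1] == planted["cation"]["resnum"]
            and b.anion[0][1] == planted["anion"]["resnum"]
        ]
        assert len(hits) == 1
        assert hits[0].distance == pytest.approx(planted["distance"], abs=0.01)

    def test_distant_pair_not_reported(self):
        s = point_structure(
            [[0, 0, 0], [8.0, 0, 0]],
            elements=["N", "O"],
            chains=["A", "B"],
            names=["NH1", "OD1"],
        )
        s.array.res_name = np.array(["ARG", "ASP"])
        bridges = geometry.detect_salt_bridges(
            s, AtomSet(s, [0]), AtomSet(s, [1]), dmax=4.0
        )
        assert bridges == []


def mc_sasa_oracle(coords, radii, probe, n_samples, seed):
    """Monte-Carlo surface-point SASA, independent of the golden-spiral path."""
    rng = np.random.default_rng(seed)
    areas = np.empty(len(coords))
    ext = radii + probe
    for i, (c, r) in enumerate(zip(coords, ext)):
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = c + r * pts
        exposed = np.ones(n_samples, dtype=bool)
        for j, (cj, rj) in enumerate(zip(coords, ext)):
            if j != i:
                exposed &= ((pts - cj) ** 2).sum(axis=1) >= rj * rj
        areas[i] = 4 * np.pi * r * r * exposed.mean()
    return areas


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = point_structure([[0, 0, 0]])
        res = geometry.shrake_rupley_sasa(s, probe=1.4, radii={"C": 1.6})
        assert res.total == pytest.approx(4 * np.pi * 3.0**2, rel=1e-12)

    def test_two_far_atoms_each_isolated(self):
        s = point_structure([[0, 0, 0], [100, 0, 0]])
        res = geometry.shrake_rupley_sasa(s, probe=1.4)
        iso = 4 * np.pi * (1.70 + 1.4) ** 2
        np.testing.assert_allclose(res.per_atom.to_numpy(), [iso, iso], rtol=1e-12)

    def test_cluster_matches_mc_oracle(self, rng):
        coords = np.array(
            [[0, 0, 0], [2.2, 0.5, 0], [1.0, 2.0, 0.3], [-1.5, 1.2, -0.8], [0.5, -1.8, 1.1]]
        )
        elements = ["C", "N", "O", "S", "C"]
        s = point_structure(coords, elements=elements)
        res = geometry.shrake_rupley_sasa(s, probe=1.4, n_points=960)
        radii = np.array([geometry.VDW_RADII[e] for e in elements])
        oracle = mc_sasa_oracle(coords, radii, 1.4, n_samples=1_000_000, seed=7)
        np.testing.assert_allclose(res.per_atom.to_numpy(), oracle, rtol=0.02)

    def test_per_residue_sums_match_per_atom(self, toy_complex):
        structure, _ = toy_complex
        res = geometry.shrake_rupley_sasa(structure, n_points=240)
        assert res.per_residue.sum() == pytest.approx(res.total)
        assert (res.per_atom >= 0).all()

    def test_occlusion_monotonicity(self):
        base = [[0, 0, 0], [2.5, 0, 0]]
        s2 = point_structure(base)
        s3 = point_structure(base + [[1.2, 2.0, 0]])
        sub2 = geometry.shrake_rupley_sasa(s2, subset=AtomSet(s2, [0, 1]))
        sub3 = geometry.shrake_rupley_sasa(s3, subset=AtomSet(s3, [0, 1]))
        assert sub3.per_atom.to_numpy().sum() <= sub2.per_atom.to_numpy().sum() + 1e-9

    def test_unknown_element_raises(self):
        s = point_structure([[0, 0, 0]], elements=["XX"])
        with pytest.raises(UnknownElementError, match="XX"):
            geometry.shrake_rupley_sasa(s)


class TestBuriedInterface:
    def test_equals_three_call_definition(self, toy_complex, toy_ligand):
        structure, _ = toy_complex
        res = geometry.buried_interface(structure, toy_ligand, n_points=240)
        rec = structure.subset(toy_ligand.complement().indices)
        lig = structure.subset(toy_ligand.indices)
        s_r = geometry.shrake_rupley_sasa(rec, n_points=240).total
        s_l = geometry.shrake_rupley_sasa(lig, n_points=240).total
        s_c = geometry.shrake_rupley_sasa(structure, n_points=240).total
        assert res.buried == pytest.approx(0.5 * (s_r + s_l - s_c), abs=1e-9)
        assert res.buried >= 0

    def test_separated_chains_bury_nothing(self):
        spec = synth.ToyComplexSpec(n_receptor=6, n_ligand=4, ligand_offset=50.0, seed=2)
        s, _ = synth.make_toy_complex(spec)
        res = geometry.buried_interface(s, select(s, "chain B"), n_points=240)
        assert res.buried == pytest.approx(0.0, abs=1e-9)


def brute_force_rmsd(p, q, seed=0):
    """Best-rotation RMSD by random scan + simplex refinement over rotation
    vectors -- an optimisation route independent of the Kabsch/SVD solution."""
    p = p - p.mean(axis=0)
    q = q - q.mean(axis=0)

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt(((p @ r.T - q) ** 2).sum() / len(p))

    best_rv, best = None, np.inf
    for rot in Rotation.random(2000, random_state=seed):
        c = cost(rot.as_rotvec())
        if c < best:
            best, best_rv = c, rot.as_rotvec()
    res = minimize(cost, best_rv, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


class TestSuperposition:
    def test_rigid_copy_has_zero_rmsd(self, toy_complex, rng):
        structure, _ = toy_complex
        rot = Rotation.random(random_state=3).as_matrix()
        moved = structure.subset(np.arange(len(structure)))
        moved.array.coord = structure.coords @ rot.T + np.array([5.0, -3.0, 12.0])
        res = geometry.superpose_calpha(structure, moved)
        assert res.rmsd <= 1e-6
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_rotation_scan(self, rng):
        p = rng.normal(size=(10, 3)) * 5
        q = rng.normal(size=(10, 3)) * 5
        chains = ["A"] * 10
        names = ["CA"] * 10
        sp = point_structure(p, chains=chains, names=names)
        sq = point_structure(q, chains=chains, names=names)
        res = geometry.superpose_calpha(sp, sq)
        assert res.rmsd == pytest.approx(brute_force_rmsd(p, q), abs=1e-3)

    def test_matches_scipy_align_vectors(self, rng):
        p = rng.normal(size=(20, 3))
        q = rng.normal(size=(20, 3))
        sp = point_structure(p, names=["CA"] * 20)
        sq = point_structure(q, names=["CA"] * 20)
        res = geometry.superpose_calpha(sp, sq)
        rot, rssd = Rotation.align_vectors(
            q - q.mean(axis=0), p - p.mean(axis=0)
        )
        assert res.rmsd == pytest.approx(rssd / np.sqrt(len(p)), abs=1e-8)

    def test_rigid_invariance(self, toy_complex, rng):
        a, _ = toy_complex
        b = a.subset(np.arange(len(a)))
        b.array.coord = a.coords + rng.normal(size=a.coords.shape) * 0.3
        base = geometry.superpose_calpha(a, b).rmsd
        rot = Rotation.random(random_state=8).as_matrix()
        a2 = a.subset(np.arange(len(a)))
        a2.array.coord = a.coords @ rot.T + 7.0
        assert geometry.superpose_calpha(a2, b).rmsd == pytest.approx(base, abs=1e-6)

    def test_too_few_pairs(self):
        s = point_structure([[0, 0, 0], [1, 0, 0]], names=["CA", "CA"])
        with pytest.raises(UnderdeterminedError):
            geometry.superpose_calpha(s, s, pairing=[(("A", 1), ("A", 1))])
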