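import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cryofit.core import Atom, AtomicModel, ResidueTrack
from cryofit.ensemble import (
    AccuracyScores,
    PredictionSet,
    align_ensemble,
    gate_decision,
    gate_group,
    ips,
    kabsch_superpose,
    lddt,
    pearson,
    residue_correspondence,
    rmsf,
    tm_score,
)
from cryofit.synth import FlexProfile, make_ensemble, make_polymer

from conftest import make_toy_model


class TestKabsch:
    def test_identity_for_equal_point_sets(self):
        P = np.random.default_rng(0).normal(size=(8, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)
        assert rmsd < 1e-12

    def test_known_rigid_transform_recovered_exactly(self):
        rng = np.random.default_rng(1)
        for i in range(20):
            P = rng.normal(size=(6, 3))
            R0 = Rotation.random(random_state=i).as_matrix()
            t0 = rng.normal(size=3) * 20
            Q = P @ R0.T + t0
            R, t, rmsd = kabsch_superpose(P, Q)
            assert rmsd < 1e-9
            assert np.allclose(R, R0, atol=1e-9)

    def test_mirrored_points_still_yield_proper_rotation(self):
        # independent oracle: scipy's align_vectors also restricts to det=+1
        rng = np.random.default_rng(2)
        P = rng.normal(size=(4, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # reflection: cannot be matched by a rotation
        R, t, rmsd = kabsch_superpose(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        rot, _ = Rotation.align_vectors(Qc, Pc)
        oracle = np.sqrt(np.mean(np.sum((Pc @ rot.as_matrix().T - Qc) ** 2, axis=1)))
        assert rmsd == pytest.approx(oracle, abs=1e-9)

    def test_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(P, P + [1.0, 2.0, 3.0])

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.ones((2, 3)))


class TestAlignEnsemble:
    def test_identical_models_unchanged(self, helix20):
        pset = PredictionSet("g", [helix20.copy() for _ in range(5)])
        aligned = align_ensemble(pset)
        for m in aligned.models:
            assert np.allclose(m.coordinates(), helix20.coordinates(), atol=1e-9)

    def test_shifted_model_snaps_back_onto_reference(self, helix20):
        shifted = helix20.copy()
        shifted.transform(np.eye(3), np.array([5.0, 0.0, 0.0]))
        pset = PredictionSet("g", [helix20.copy(), shifted]
                             )
        aligned = align_ensemble(pset)
        assert np.allclose(
            aligned.models[1].coordinates(), helix20.coordinates(), atol=1e-9
        )

    def test_extra_residues_ride_along_with_the_shared_frame(self, helix20):
        longer = make_polymer(25, "helix", seed=1)
        shifted = longer.copy()
        shifted.transform(np.eye(3), np.array([0.0, 7.0, 0.0]))
        pset = PredictionSet("g", [helix20.copy(), shifted])
        aligned = align_ensemble(pset)
        m2 = aligned.models[1]
        assert m2.n_residues == 25
        shared = [r.key for r in helix20.residues()]
        m2_map = m2.residue_map()
        ref_map = helix20.residue_map()
        for k in shared:
            assert np.allclose(
                m2_map[k].representative_atom.position,
                ref_map[k].representative_atom.position,
                atol=1e-9,
            )


class TestRMSF:
    def test_identical_models_have_zero_rmsf(self, helix20):
        pset = PredictionSet("g", [helix20.copy() for _ in range(5)])
        assert np.allclose(rmsf(pset).values(), 0.0)

    def test_symmetric_displacement_matches_hand_formula(self, helix20):
        # residue 10 moved +d in one model and -d in another: RMSF = d sqrt(2/5)
        d = 1.7
        models = [helix20.copy() for _ in range(5)]
        key = ("A", 10, "")
        for m, sign in zip(models[1:3], (+1, -1)):
            res = m.residue_map()[key]
            for a in res.atoms:
                a.position = a.position + np.array([sign * d, 0.0, 0.0])
        track = rmsf(PredictionSet("g", models))
        assert track[key] == pytest.approx(d * np.sqrt(2 / 5), abs=1e-12)
        other = [v for k, v in track.items() if k != key]
        assert np.allclose(other, 0.0)

    def test_gaussian_displacement_matches_closed_form(self, helix30):
        # E[RMSF^2] = 3 sigma^2 (m-1)/m for residue-rigid displacement
        sigma, m = 1.0, 5
        vals = [
            np.mean(rmsf(make_ensemble(helix30, FlexProfile.constant(30, sigma), m, seed=s)).values() ** 2)
            for s in range(150)
        ]
        assert np.mean(vals) == pytest.approx(3 * sigma**2 * (m - 1) / m, rel=0.10)

    def test_rigid_transform_of_whole_set_changes_nothing_after_alignment(self, helix20):
        pset = make_ensemble(helix20, FlexProfile.constant(20, 0.4), 5, seed=3)
        base = rmsf(align_ensemble(pset)).values()
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = [m.copy() for m in pset.models]
        for m in moved:
            m.transform(R, np.array([4.0, 5.0, 6.0]))
        again = rmsf(align_ensemble(PredictionSet("g", moved))).values()
        assert np.allclose(base, again, atol=1e-9)


def brute_force_lddt(model, reference, radius=15.0, thresholds=(0.5, 1.0, 2.0, 4.0)):
    """Naive per-pair enumeration, independent of the library implementation."""
    mod_atoms = {}
    for res in model.residues():
        for a in res.atoms:
            if not a.is_hydrogen:
                mod_atoms[(res.key, a.name)] = a.position
    ref_atoms = []
    for res in reference.residues():
        for a in res.atoms:
            if not a.is_hydrogen and (res.key, a.name) in mod_atoms:
                ref_atoms.append((res.key, a.name, a.position))
    per_res_hits, per_res_tot, g_hit, g_tot = {}, {}, 0, 0
    for i in range(len(ref_atoms)):
        for j in range(i + 1, len(ref_atoms)):
            ki, ni, pi = ref_atoms[i]
            kj, nj, pj = ref_atoms[j]
            if ki == kj:
                continue
            d_ref = np.linalg.norm(pi - pj)
            if d_ref > radius:
                continue
            d_mod = np.linalg.norm(mod_atoms[(ki, ni)] - mod_atoms[(kj, nj)])
            frac = sum(abs(d_mod - d_ref) < t for t in thresholds) / len(thresholds)
            g_hit += frac
            g_tot += 1
            for k in (ki, kj):
                per_res_hits[k] = per_res_hits.get(k, 0.0) + frac
                per_res_tot[k] = per_res_tot.get(k, 0) + 1
    per_res = {k: per_res_hits[k] / per_res_tot[k] for k in per_res_tot}
    return g_hit / g_tot, per_res


class TestLDDT:
    def test_self_and_rigid_transform_score_one(self, helix20):
        assert lddt(helix20, helix20).lddt_global == pytest.approx(1.0)
        moved = helix20.copy()
        moved.transform(Rotation.random(random_state=0).as_matrix(), np.array([9.0, 1.0, -2.0]))
        sc = lddt(moved, helix20)
        assert sc.lddt_global == pytest.approx(1.0)
        assert np.allclose(sc.lddt_per_residue.values(), 1.0)

    def test_matches_brute_force_oracle_on_perturbed_toys(self):
        rng = np.random.default_rng(7)
        for case in range(10):
            ref = make_polymer(5, "helix", seed=case)
            mod = ref.copy()
            for a in mod.atoms():
                a.position = a.position + rng.normal(0, 0.8, 3)
            sc = lddt(mod, ref)
            g_oracle, per_oracle = brute_force_lddt(mod, ref)
            assert sc.lddt_global == pytest.approx(g_oracle, abs=1e-12)
            for key, val in per_oracle.items():
                assert sc.lddt_per_residue[key] == pytest.approx(val, abs=1e-12)

    def test_degrades_with_perturbation_amplitude(self, helix20):
        rng = np.random.default_rng(0)
        scores = []
        for amp in (0.2, 1.0, 3.0):
            mod = helix20.copy()
            for a in mod.atoms():
                a.position = a.position + rng.normal(0, amp, 3)
            scores.append(lddt(mod, helix20).lddt_global)
        assert scores[0] > scores[1] > scores[2]


class TestTMScore:
    def test_identity_and_rigid_are_one(self, helix30):
        assert tm_score(helix30, helix30) == pytest.approx(1.0)
        moved = helix30.copy()
        moved.transform(Rotation.random(random_state=5).as_matrix(), np.array([3.0, 3.0, 3.0]))
        assert tm_score(moved, helix30) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_residues_rejected(self):
        small = make_polymer(10, "helix", seed=0)
        with pytest.raises(ValueError, match="15"):
            tm_score(small, small)

    def test_decreases_with_noise(self, helix30):
        rng = np.random.default_rng(1)
        prev = 1.0
        for amp in (0.5, 2.0):
            mod = helix30.copy()
            for a in mod.atoms():
                a.position = a.position + rng.normal(0, amp, 3)
            val = tm_score(mod, helix30)
            assert 0.0 < val < prev
            prev = val


class TestIPS:
    @staticmethod
    def dimer(b_offset):
        a_res = [[0.0, 0.0, 0.0], [0.0, 0.0, 4.0]]
        b_res = [[4.0, 0.0, 0.0], [4.0, 0.0, 4.0 + b_offset]]
        chains = {}
        ma = make_toy_model(a_res, chain_id="A")
        mb = make_toy_model(b_res, chain_id="B")
        chains["A"] = ma.chains["A"]
        chains["B"] = mb.chains["B"]
        return AtomicModel("dimer", chains)

    def test_identical_dimer_scores_one(self):
        d = self.dimer(0.0)
        assert ips(d, d) == pytest.approx(1.0)

    def test_hand_computed_jaccard(self):
        # reference contacts: {A1-B1, A2-B2}; model keeps only A1-B1 -> 1/2
        ref = self.dimer(0.0)
        mod = self.dimer(5.0)  # A2-B2 distance 6.4 A: contact broken
        assert ips(mod, ref) == pytest.approx(0.5)

    def test_model_with_no_contacts_scores_zero(self):
        ref = self.dimer(0.0)
        far = self.dimer(0.0)
        for r in far.chains["B"]:
            for a in r.atoms:
                a.position = a.position + np.array([50.0, 0.0, 0.0])
        assert ips(far, ref) == pytest.approx(0.0)

    def test_monomer_rejected(self, helix20):
        with pytest.raises(ValueError):
            ips(helix20, helix20)


def _scores(lddt_val, tm_val, ips_val=None):
    return AccuracyScores(lddt_val, ResidueTrack(), tm_val, ips_val)


class TestGate:
    def test_boundary_is_strict(self):
        assert not gate_decision([_scores(0.7, 0.9)])
        assert gate_decision([_scores(0.700001, 0.9)])
        assert not gate_decision([_scores(0.9, 0.8)])
        assert gate_decision([_scores(0.9, 0.800001)])

    def test_ips_ignored_for_monomers_enforced_for_multimers(self):
        sc = [_scores(0.9, 0.9, 0.5)]
        assert gate_decision(sc, is_multimer=False)
        assert not gate_decision(sc, is_multimer=True)
        assert gate_decision([_scores(0.9, 0.9, 0.800001)], is_multimer=True)

    def test_one_bad_model_fails_the_whole_group(self):
        sc = [_scores(0.95, 0.95)] * 4 + [_scores(0.6, 0.95)]
        assert not gate_decision(sc)

    def test_end_to_end_identical_models_pass(self, helix30):
        pset = PredictionSet("g", [helix30.copy() for _ in range(5)])
        passed, scores = gate_group(pset, helix30)
        assert passed
        assert all(s.lddt_global == pytest.approx(1.0) for s in scores)

    def test_end_to_end_scrambled_models_fail(self, helix30):
        rng = np.random.default_rng(3)
        bad = helix30.copy()
        for a in bad.atoms():
            a.position = a.position + rng.normal(0, 5.0, 3)
        pset = PredictionSet("g", [helix30.copy() for _ in range(4)] + [bad])
        passed, _ = gate_group(pset, helix30)
        assert not passed


class TestPearson:
    @staticmethod
    def track(values, start=1):
        return ResidueTrack({("A", start + i, ""): float(v) for i, v in enumerate(values)})

    def test_perfect_correlation(self):
        a = self.track([1, 2, 3, 4])
        r, n = pearson(a, a)
        assert r == pytest.approx(1.0) and n == 4

    def test_affine_anticorrelation_and_absolute_flag(self):
        a = self.track([1, 2, 3, 4])
        b = self.track([-2 * v + 5 for v in [1, 2, 3, 4]])
        r, _ = pearson(a, b)
        assert r == pytest.approx(-1.0)
        r_abs, _ = pearson(a, b, absolute=True)
        assert r_abs == pytest.approx(1.0)

    def test_matches_textbook_formula(self):
        a_vals, b_vals = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0]
        r, _ = pearson(self.track(a_vals), self.track(b_vals))
        am, bm = np.mean(a_vals), np.mean(b_vals)
        num = sum((x - am) * (y - bm) for x, y in zip(a_vals, b_vals))
        den = np.sqrt(
            sum((x - am) ** 2 for x in a_vals) * sum((y - bm) ** 2 for y in b_vals)
        )
        assert r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_is_missing(self):
        r, n = pearson(self.track([1, 1, 1]), self.track([1, 2, 3]))
        assert r is None and n == 3

    def test_too_few_shared_keys_is_missing(self):
        r, n = pearson(self.track([1, 2]), self.track([3, 4], start=10))
        assert r is None and n == 0


class TestCorrespondence:
    def test_matching_numbering_maps_identically(self, helix20):
        corr = residue_correspondence(helix20, helix20)
        assert all(k == v for k, v in corr.items())

    def test_offset_numbering_recovered_by_sequence_alignment(self, helix20):
        shifted = helix20.copy()
        for res in shifted.residues():
            res.seq_id += 100
        corr = residue_correspondence(shifted, helix20)
        assert len(corr) == 20
        assert all(mk[1] == tk[1] + 100 for mk, tk in corr.items())
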