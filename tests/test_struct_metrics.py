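"""Kabsch RMSD, RMSF, reaction-field energies, H-bond and contact counts."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ticycle.minipdb import StructureFrame
from ticycle.struct_metrics import (
    DonorAcceptorTable,
    RfParams,
    count_charge_contacts,
    count_hbonds,
    kabsch_superpose,
    residue_interaction_energy,
    rf_coulomb,
    rmsf,
    summarize_residues,
)
from ticycle.synthetic_data import (
    PlantedRecipe,
    gen_fluctuating_trajectory,
    gen_planted_structure,
)

# frozen hand evaluation (sympy): f*(1/0.5 + k_rf*0.25 - c_rf), rc=1.4, eps=65
RF_HALF_NM = 136.33194486631206
K_RF = 0.17804286381946454
C_RF = 1.0632497273718648


def simple_frame(coords, charges=None, names=None, resids=None, resnames=None):
    n = len(coords)
    return StructureFrame(
        names=np.array(names if names is not None else [f"C{i}" for i in range(n)]),
        residue_ids=np.array(resids if resids is not None else np.ones(n, dtype=int)),
        residue_names=np.array(resnames if resnames is not None else ["GLY"] * n),
        charges=np.array(charges if charges is not None else np.zeros(n), dtype=float),
        coords=np.asarray(coords, dtype=float),
    )


class TestKabsch:
    def test_self_superposition_is_zero(self, planted, rng):
        rmsd, _ = kabsch_superpose(planted.frame, planted.frame)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_superposes_exactly(self, planted, rng):
        rot = Rotation.random(rng=rng).as_matrix()
        moved = planted.frame.coords @ rot.T + np.array([1.0, -2.0, 0.5])
        rmsd, _ = kabsch_superpose(planted.frame.coords, moved)
        assert rmsd <= 1e-10

    def test_rigid_invariance_property(self, planted, rng):
        jitter = planted.frame.coords + 0.05 * rng.standard_normal(
            planted.frame.coords.shape
        )
        base, _ = kabsch_superpose(planted.frame.coords, jitter)
        for _ in range(10):
            rot = Rotation.random(rng=rng).as_matrix()
            moved = jitter @ rot.T + rng.uniform(-3, 3, 3)
            rmsd, _ = kabsch_superpose(planted.frame.coords, moved)
            assert rmsd == pytest.approx(base, rel=1e-9)

    def test_unfit_rmsd_is_root_mean_square_offset(self, rng):
        ref = rng.uniform(0, 1, size=(8, 3))
        offsets = rng.normal(0, 0.1, size=(8, 3))
        rmsd, _ = kabsch_superpose(ref, ref + offsets, fit=False)
        assert rmsd == pytest.approx(np.sqrt(np.mean(np.sum(offsets**2, 1))), rel=1e-12)

    def test_mismatched_selections_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            kabsch_superpose(rng.uniform(size=(5, 3)), rng.uniform(size=(4, 3)))


class TestRmsf:
    def test_static_trajectory_has_zero_rmsf(self, planted):
        frames = [planted.frame] * 10
        assert rmsf(frames, 1) == pytest.approx(0.0, abs=1e-12)

    def test_two_atom_residue_averages_per_atom_rmsf(self, rng):
        # atom 0 jitters with sigma 0.02, atom 1 with sigma 0.04
        base = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        frames = []
        for _ in range(4000):
            xyz = base + np.array([[0.02], [0.04]]) * rng.standard_normal((2, 3))
            frames.append(simple_frame(xyz))
        a, b = 0.02 * np.sqrt(3), 0.04 * np.sqrt(3)
        assert rmsf(frames, 1) == pytest.approx((a + b) / 2, rel=0.05)

    def test_unknown_residue_rejected(self, planted):
        with pytest.raises(KeyError):
            rmsf([planted.frame] * 2, 999)


class TestReactionField:
    def test_pair_term_vanishes_exactly_at_cutoff(self):
        rf = RfParams()
        assert float(rf_coulomb(1.4, 1.0, -1.0, rf)) == 0.0

    def test_derived_constants_match_hand_values(self):
        rf = RfParams(cutoff=1.4, eps_rf=65.0)
        assert rf.k_rf == pytest.approx(K_RF, rel=1e-12)
        assert rf.c_rf == pytest.approx(C_RF, rel=1e-12)

    def test_pair_energy_matches_hand_evaluation(self):
        rf = RfParams()
        frame = simple_frame([[0, 0, 0], [0.5, 0, 0]], charges=[1.0, 1.0],
                             resids=[1, 2])
        e = residue_interaction_energy(frame, 1, rf)
        assert e == pytest.approx(RF_HALF_NM, rel=1e-12)

    def test_energy_is_symmetric_between_residue_and_rest(self, planted):
        rf = RfParams()
        e1 = residue_interaction_energy(planted.frame, 1, rf)
        rest = [
            residue_interaction_energy(planted.frame, int(r), rf)
            for r in np.unique(planted.frame.residue_ids)
        ]
        assert np.isfinite(e1) and all(np.isfinite(e) for e in rest)
        f2 = simple_frame([[0, 0, 0], [0.5, 0, 0]], charges=[1.0, -0.5], resids=[1, 2])
        assert residue_interaction_energy(f2, 1, rf) == pytest.approx(
            residue_interaction_energy(f2, 2, rf), rel=1e-14
        )

    def test_uncharged_residue_has_zero_energy(self):
        frame = simple_frame([[0, 0, 0], [0.4, 0, 0]], charges=[0.0, 1.0],
                             resids=[1, 2])
        assert residue_interaction_energy(frame, 1, RfParams()) == 0.0

    def test_missing_charges_rejected(self):
        frame = simple_frame([[0, 0, 0], [0.4, 0, 0]], charges=[np.nan, 1.0],
                             resids=[1, 2])
        with pytest.raises(ValueError, match="charge"):
            residue_interaction_energy(frame, 1, RfParams())


class TestHbonds:
    def test_ideal_linear_bond_counts_once(self):
        ps = gen_planted_structure(PlantedRecipe(hbond_nm=(0.28,)))
        assert count_hbonds(ps.frame, 1) == 1

    def test_bent_geometry_fails_angle_cutoff(self):
        ps = gen_planted_structure(PlantedRecipe(bent_hbond=((0.28, 60.0),)))
        assert count_hbonds(ps.frame, 1) == 0

    def test_count_equals_planted_manifest(self, planted):
        assert count_hbonds(planted.frame, 1) == planted.hbond_count

    def test_long_bond_fails_distance_cutoff(self):
        ps = gen_planted_structure(PlantedRecipe(hbond_nm=(0.45,)))
        assert count_hbonds(ps.frame, 1) == 0

    def test_explicit_donor_without_hydrogen_is_an_error(self):
        frame = simple_frame([[0, 0, 0], [0.3, 0, 0]], names=["ND1", "OG"],
                             resids=[1, 2])
        table = DonorAcceptorTable(donors=frozenset({"ND1"}))
        with pytest.raises(ValueError, match="hydrogen"):
            count_hbonds(frame, 1, table)


class TestChargeContacts:
    def test_counts_are_cumulative_per_cutoff(self, planted):
        c = count_charge_contacts(planted.frame, 1)
        assert c[0.3] == 1 and c[0.6] == 2 and c.annulus == 1

    def test_like_charged_neighbor_not_counted(self):
        ps = gen_planted_structure(PlantedRecipe(like_charge_nm=(0.25,)))
        c = count_charge_contacts(ps.frame, 1)
        assert c[0.3] == 0 and c[0.6] == 0

    def test_counts_invariant_to_atom_order(self, planted, rng):
        fr = planted.frame
        perm = rng.permutation(fr.n_atoms)
        shuffled = StructureFrame(
            names=fr.names[perm], residue_ids=fr.residue_ids[perm],
            residue_names=fr.residue_names[perm], charges=fr.charges[perm],
            coords=fr.coords[perm],
        )
        c = count_charge_contacts(shuffled, 1)
        assert c[0.3] == 1 and c[0.6] == 2

    def test_bruteforce_distance_oracle_on_random_fixture(self, rng):
        dists = np.round(rng.uniform(0.2, 0.9, size=4), 3)
        ps = gen_planted_structure(PlantedRecipe(opposite_charge_nm=tuple(dists)))
        c = count_charge_contacts(ps.frame, 1)
        assert c[0.3] == int(np.sum(dists <= 0.3))
        assert c[0.6] == int(np.sum(dists <= 0.6))

    def test_uncharged_residue_warns_and_counts_zero(self, planted):
        # residue 2 is a GLU partner; a SER acceptor residue has no charged group
        fr = planted.frame
        ser_id = int(fr.residue_ids[fr.residue_names == "SER"][0])
        with pytest.warns(UserWarning, match="no charged group"):
            c = count_charge_contacts(fr, ser_id)
        assert all(v == 0 for v in c.counts.values())

    def test_small_cutoff_never_exceeds_large(self, rng):
        for _ in range(10):
            dists = tuple(np.round(rng.uniform(0.2, 1.0, size=3), 3))
            ps = gen_planted_structure(PlantedRecipe(opposite_charge_nm=dists))
            c = count_charge_contacts(ps.frame, 1)
            assert c[0.3] <= c[0.6]


class TestSummary:
    def test_summary_table_matches_manifest(self, planted):
        frames = gen_fluctuating_trajectory(planted, 0.0, 3, seed=0)
        table = summarize_residues(planted.frame, frames, [1])
        row = table.loc[1]
        assert row["hbond_count"] == planted.hbond_count
        assert row["contacts_within_0.3_nm"] == 1.0
        assert row["contacts_within_0.6_nm"] == 2.0
        assert row["rmsf_nm"] == pytest.approx(0.0, abs=1e-12)
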