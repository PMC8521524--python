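"""Salt-bridge mode classification, ensemble scanning, conditional distances."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from absb.exceptions import InvalidParameterError
from absb.saltbridge import (
    ConformerEnsemble,
    classify_mode,
    conditional_ca_distance,
    extract_groups,
    mode_from_contacts,
    scan_ensemble,
    simultaneous_bridging,
)
from absb.synthetic import AB40_SEQUENCE, EnsembleConfig, gen_ensemble

from conftest import make_carboxylate, make_guanidinium


def brute_force_mode(contacts: np.ndarray) -> str:
    """Independent oracle: enumerate injective nitrogen->oxygen assignments.

    A bidentate mode holds when some injective map from its nitrogen pair to
    the two oxygens is fully in contact; backside when the contact-bearing
    nitrogens number exactly one.
    """
    c = np.asarray(contacts, dtype=bool)
    NE, NH1, NH2 = 0, 1, 2

    def bidentate(n_a, n_b):
        return any(
            c[n_a, o_a] and c[n_b, o_b]
            for o_a, o_b in itertools.permutations([0, 1], 2)
        )

    if bidentate(NH1, NH2):
        return "side_on"
    if bidentate(NE, NH1) or bidentate(NE, NH2):
        return "end_on"
    touched = sum(1 for n in (NE, NH1, NH2) if c[n].any())
    return "backside" if touched == 1 else "none"


class TestModeFromContacts:
    def test_exhaustive_patterns_match_brute_force(self):
        for bits in itertools.product([False, True], repeat=6):
            c = np.asarray(bits).reshape(3, 2)
            assert mode_from_contacts(c) == brute_force_mode(c), c

    def test_no_contacts_is_none(self):
        assert mode_from_contacts(np.zeros((3, 2), dtype=bool)) == "none"

    def test_two_nitrogens_one_oxygen_is_not_bidentate(self):
        # NE and NH1 both touch O1 only: two touched nitrogens, no distinct
        # oxygens -> neither bidentate nor backside
        c = np.array([[True, False], [True, False], [False, False]])
        assert mode_from_contacts(c) == "none"


class TestClassifyMode:
    def test_side_on_geometry(self, guanidinium):
        g = guanidinium
        u = (0.5 * (g.nh1 + g.nh2) - g.cz)
        u /= np.linalg.norm(u)
        carb = make_carboxylate(g.nh1 + 2.8 * u, g.nh2 + 2.8 * u)
        a = classify_mode(g, carb)
        assert a.mode == "side_on"
        assert len(a.contacts) >= 2

    def test_single_nitrogen_contact_is_backside(self, guanidinium):
        g = guanidinium
        u = (g.nh1 - g.cz) / np.linalg.norm(g.nh1 - g.cz)
        o1 = g.nh1 + 3.0 * u
        carb = make_carboxylate(o1, o1 + 2.2 * u)
        a = classify_mode(g, carb)
        assert a.mode == "backside"

    def test_all_far_is_none(self, guanidinium):
        g = guanidinium
        carb = make_carboxylate([10.0, 0, 0], [12.2, 0, 0])
        a = classify_mode(g, carb)
        assert a.mode == "none"
        assert a.contacts == []

    def test_cutoff_must_be_positive(self, guanidinium):
        carb = make_carboxylate([3.0, 0, 0], [3.0, 2.2, 0])
        with pytest.raises(InvalidParameterError):
            classify_mode(guanidinium, carb, cutoff=0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        g = make_guanidinium()
        o1 = rng.uniform(-5, 5, 3)
        o2 = o1 + 2.2 * _unit(rng)
        carb = make_carboxylate(o1, o2)
        before = classify_mode(g, carb).mode
        # random rotation (QR orthogonalisation) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.uniform(-20, 20, 3)
        move = lambda x: q @ x + t
        from absb.saltbridge import CarboxylateGroup, GuanidiniumGroup

        g2 = GuanidiniumGroup(g.residue_index, move(g.cz), move(g.ne), move(g.nh1), move(g.nh2))
        c2 = CarboxylateGroup(carb.residue_index, carb.residue_name,
                              move(carb.carbon), move(carb.o1), move(carb.o2))
        assert classify_mode(g2, c2).mode == before

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_oxygen_label_swap(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = make_guanidinium()
        o1 = rng.uniform(-4, 4, 3)
        o2 = o1 + 2.2 * _unit(rng)
        from absb.saltbridge import CarboxylateGroup

        c12 = make_carboxylate(o1, o2)
        c21 = CarboxylateGroup(c12.residue_index, c12.residue_name, c12.carbon, o2, o1)
        assert classify_mode(g, c12).mode == classify_mode(g, c21).mode

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        ox=st.floats(-5, 5), oy=st.floats(-5, 5), oz=st.floats(-5, 5),
        theta=st.floats(0, 2 * np.pi), phi=st.floats(0, np.pi),
    )
    def test_oxygen_swap_property(self, ox, oy, oz, theta, phi):
        from absb.saltbridge import CarboxylateGroup

        g = make_guanidinium()
        o1 = np.array([ox, oy, oz])
        o2 = o1 + 2.2 * np.array(
            [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
        )
        c12 = make_carboxylate(o1, o2)
        c21 = CarboxylateGroup(c12.residue_index, c12.residue_name, c12.carbon, o2, o1)
        assert classify_mode(g, c12).mode == classify_mode(g, c21).mode

    @pytest.mark.parametrize("seed", range(8))
    def test_enlarging_cutoff_never_loses_a_bridge(self, seed):
        rng = np.random.default_rng(200 + seed)
        g = make_guanidinium()
        o1 = rng.uniform(-4, 4, 3)
        carb = make_carboxylate(o1, o1 + 2.2 * _unit(rng))
        small = classify_mode(g, carb, cutoff=3.0).mode
        large = classify_mode(g, carb, cutoff=4.5).mode
        if small != "none":
            assert large != "none"


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


class TestExtractGroups:
    def test_ab40_sequence_groups(self):
        ens, _ = gen_ensemble(EnsembleConfig(n_conformers=1), seed=0)
        assert ens.sequence == AB40_SEQUENCE
        gdms, carbs = extract_groups(ens, 0)
        assert [g.residue_index for g in gdms] == [5]
        assert sorted(c.residue_index for c in carbs) == [1, 3, 7, 11, 22, 23]

    def test_no_arginine_gives_empty_guanidinium_list(self):
        ens = ConformerEnsemble(
            residue_index=[1, 2], residue_name=["ALA", "GLY"],
            atom_name=["CA", "CA"], coords=np.zeros((1, 2, 3)),
        )
        gdms, carbs = extract_groups(ens, 0)
        assert gdms == [] and carbs == []

    def test_incomplete_guanidinium_skipped_with_warning(self):
        ens, _ = gen_ensemble(EnsembleConfig(n_conformers=1), seed=0)
        keep = ~((ens.residue_index == 5) & (ens.atom_name == "NH2"))
        trimmed = ConformerEnsemble(
            residue_index=ens.residue_index[keep],
            residue_name=ens.residue_name[keep],
            atom_name=ens.atom_name[keep],
            coords=ens.coords[:, keep, :],
        )
        with pytest.warns(UserWarning, match="NH2"):
            gdms, _ = extract_groups(trimmed, 0)
        assert gdms == []


class TestScanEnsemble:
    def test_no_contacts_gives_zero_occupancy(self):
        cfg = EnsembleConfig(n_conformers=20, pair_occupancy={}, double_fraction=0.0)
        ens, _ = gen_ensemble(cfg, seed=1)
        stats = scan_ensemble(ens)
        assert all(v == 0.0 for v in stats.pair_occupancy.values())

    def test_counting_oracle_exact_fraction(self):
        # force exactly 3 of 10 conformers to carry the bridge by rebuilding
        # a 10-conformer ensemble from planted/unplanted pools
        planted_ens, _ = gen_ensemble(
            EnsembleConfig(n_conformers=3, pair_occupancy={7: 1.0}, double_fraction=0.0),
            seed=2,
        )
        free_ens, _ = gen_ensemble(
            EnsembleConfig(n_conformers=7, pair_occupancy={}, double_fraction=0.0),
            seed=3,
        )
        ens = ConformerEnsemble(
            residue_index=planted_ens.residue_index,
            residue_name=planted_ens.residue_name,
            atom_name=planted_ens.atom_name,
            coords=np.concatenate([planted_ens.coords, free_ens.coords]),
        )
        stats = scan_ensemble(ens, donor_filter=[5], acceptor_filter=[7])
        assert stats.occupancy(5, 7) == pytest.approx(0.3)
        assert stats.pair_modes[(5, 7)]["side_on"] == pytest.approx(0.3)
        assert stats.pair_modes[(5, 7)]["end_on"] == 0.0

    def test_empty_ensemble_rejected(self):
        ens = ConformerEnsemble(
            residue_index=[1], residue_name=["ALA"], atom_name=["CA"],
            coords=np.zeros((0, 1, 3)),
        )
        with pytest.raises(InvalidParameterError, match="empty"):
            scan_ensemble(ens)

    @pytest.mark.parametrize("n", [500, 5000])
    def test_occupancy_converges_to_planted_rate(self, n):
        rate = 0.14
        cfg = EnsembleConfig(n_conformers=n, pair_occupancy={7: rate}, double_fraction=0.0)
        ens, _ = gen_ensemble(cfg, seed=17)
        occ = scan_ensemble(ens, donor_filter=[5], acceptor_filter=[7]).occupancy(5, 7)
        bound = 2 * np.sqrt(rate * (1 - rate) / n)
        assert abs(occ - rate) <= bound

    def test_mode_fractions_sum_to_occupancy(self):
        cfg = EnsembleConfig(
            n_conformers=400,
            pair_occupancy={7: 0.2, 3: 0.15},
            pair_mode={7: "end_on", 3: "backside"},
            double_fraction=0.0,
        )
        ens, _ = gen_ensemble(cfg, seed=5)
        stats = scan_ensemble(ens, donor_filter=[5])
        for pair, occ in stats.pair_occupancy.items():
            assert sum(stats.pair_modes[pair].values()) == pytest.approx(occ)
        # bidentate vs monodentate split
        assert stats.pair_modes[(5, 7)]["end_on"] == pytest.approx(stats.occupancy(5, 7))
        assert stats.pair_modes[(5, 3)]["backside"] == pytest.approx(stats.occupancy(5, 3))


class TestSimultaneousBridging:
    def test_never_exceeds_pair_occupancies(self):
        cfg = EnsembleConfig(n_conformers=300, double_fraction=0.05)
        ens, _ = gen_ensemble(cfg, seed=6)
        frac = simultaneous_bridging(ens, 5, [3, 7])
        stats = scan_ensemble(ens, donor_filter=[5], acceptor_filter=[3, 7])
        assert frac <= min(stats.occupancy(5, 3), stats.occupancy(5, 7)) + 1e-12

    def test_counting_oracle_one_in_two_hundred(self):
        double_ens, _ = gen_ensemble(
            EnsembleConfig(n_conformers=1, pair_occupancy={}, double_fraction=1.0),
            seed=7,
        )
        free_ens, _ = gen_ensemble(
            EnsembleConfig(n_conformers=199, pair_occupancy={}, double_fraction=0.0),
            seed=8,
        )
        ens = ConformerEnsemble(
            residue_index=double_ens.residue_index,
            residue_name=double_ens.residue_name,
            atom_name=double_ens.atom_name,
            coords=np.concatenate([double_ens.coords, free_ens.coords]),
        )
        assert simultaneous_bridging(ens, 5, [3, 7]) == pytest.approx(0.005)

    def test_requires_two_acceptors(self):
        ens, _ = gen_ensemble(EnsembleConfig(n_conformers=2), seed=9)
        with pytest.raises(InvalidParameterError):
            simultaneous_bridging(ens, 5, [7])

    def test_non_carboxylate_acceptor_rejected(self):
        ens, _ = gen_ensemble(EnsembleConfig(n_conformers=2), seed=9)
        with pytest.raises(InvalidParameterError, match="not ASP/GLU"):
            simultaneous_bridging(ens, 5, [7, 8])


class TestConditionalCaDistance:
    def test_identical_conformers_have_zero_sd(self):
        one, _ = gen_ensemble(EnsembleConfig(n_conformers=1, pair_occupancy={7: 1.0},
                                             double_fraction=0.0), seed=10)
        ens = ConformerEnsemble(
            residue_index=one.residue_index, residue_name=one.residue_name,
            atom_name=one.atom_name, coords=np.repeat(one.coords, 5, axis=0),
        )
        cd = conditional_ca_distance(ens, [(5, 7)], (3, 8))
        assert cd.n_with == 5 and cd.n_without == 0
        assert cd.sd_with == 0.0
        assert np.isnan(cd.mean_without)

    def test_partition_matches_per_conformer_classification(self):
        ens, _ = gen_ensemble(EnsembleConfig(n_conformers=120), seed=11)
        cd = conditional_ca_distance(ens, [(5, 3), (5, 7)], (3, 8))
        n_bridged = 0
        for ci in range(ens.n_conformers):
            gdms, carbs = extract_groups(ens, ci)
            by_res = {c.residue_index: c for c in carbs}
            bridged = any(
                classify_mode(gdms[0], by_res[a], conformer_id=ci).mode != "none"
                for a in (3, 7)
            )
            n_bridged += bridged
        assert cd.n_with == n_bridged
        assert cd.n_with + cd.n_without == ens.n_conformers

    def test_recovers_planted_conditional_means(self):
        cfg = EnsembleConfig(n_conformers=2000, pair_occupancy={7: 0.25},
                             double_fraction=0.0,
                             compaction={(3, 8): (1.25, 1.39, 0.05)})
        ens, _ = gen_ensemble(cfg, seed=20)
        cd = conditional_ca_distance(ens, [(5, 3), (5, 7)], (3, 8))
        for mean, target, n in ((cd.mean_with, 1.25, cd.n_with),
                                (cd.mean_without, 1.39, cd.n_without)):
            sem = 0.05 / np.sqrt(n)
            assert abs(mean - target) <= 3 * sem
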