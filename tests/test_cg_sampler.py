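import numpy as np
import pytest
from scipy.integrate import quad

from defold import cg_sampler as cg
from defold import restraints as R
from defold.dca import ContactSet
from defold.ensemble import kabsch_rmsd
from defold.geometry import circular_difference


def torsion_only_bundle(n, half_width=20.0, k=0.05, centers=None):
    phi = centers[0] if centers is not None else np.full(n, 180.0)
    psi = centers[1] if centers is not None else np.full(n, 180.0)
    tors = [R.TorsionRestraint(float(p), float(s), half_width=half_width,
                               k_tor=k) for p, s in zip(phi, psi)]
    return R.RestraintBundle(torsions=tors, contacts=[])


RESTRAINTS_ONLY = cg.ForceFieldOptions(enable_pair=False, enable_env=False)


class TestBackboneConstruction:
    def test_extended_chain_atom_count(self):
        conf = cg.build_extended("ACDEF")
        coords = conf.coords
        assert sum(coords[a].shape[0] for a in ("N", "CA", "C")) == 15

    def test_consecutive_ca_distance_trans(self):
        conf = cg.build_extended("ACDEFGHIKL")
        ca = conf.ca_coords()
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.80) < 0.05)

    def test_extended_torsions_round_trip(self):
        conf = cg.build_extended("ACDEF")
        phi, psi = conf.measured_torsions()
        assert np.allclose(phi[1:], 180.0, atol=1e-6)
        assert np.allclose(psi[:-1], 180.0, atol=1e-6)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError):
            cg.build_extended("ACB-")

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            cg.build_extended("A")

    def test_cb_at_ideal_distance(self):
        conf = cg.build_extended("ACDEF")
        d = np.linalg.norm(conf.coords["CB"] - conf.coords["CA"], axis=1)
        assert np.all(np.abs(d - 1.53) < 0.02)


class TestSetTorsions:
    def test_identity_set_preserves_coordinates(self):
        conf = cg.build_extended("ACDEFGH")
        same = cg.set_torsions(conf, conf.phi, conf.psi)
        assert np.allclose(same.ca_coords(), conf.ca_coords())

    def test_round_trip_to_requested_angles(self):
        conf = cg.build_extended("ACDEFGH")
        rng = np.random.default_rng(4)
        phi = rng.uniform(-179, 180, 7)
        psi = rng.uniform(-179, 180, 7)
        new = cg.set_torsions(conf, phi, psi)
        mphi, mpsi = new.measured_torsions()
        assert np.allclose(mphi[1:], phi[1:], atol=1e-6)
        assert np.allclose(mpsi[:-1], psi[:-1], atol=1e-6)

    def test_helix_is_more_compact_than_extended(self):
        ext = cg.build_extended("ACDEFGHIKL")
        helix = cg.set_torsions(ext, np.full(10, -57.0), np.full(10, -47.0))
        d_h = np.linalg.norm(helix.ca_coords()[3] - helix.ca_coords()[0])
        d_e = np.linalg.norm(ext.ca_coords()[3] - ext.ca_coords()[0])
        assert d_h < d_e

    def test_single_torsion_change_only_moves_downstream_atoms(self):
        conf = cg.build_extended("ACDEFGH")
        phi = conf.phi.copy()
        phi[4] = -60.0
        moved = cg.set_torsions(conf, phi, conf.psi)
        # N and CA of residue 4 and everything upstream stay fixed
        assert np.allclose(moved.coords["N"][:5], conf.coords["N"][:5])
        assert np.allclose(moved.coords["CA"][:5], conf.coords["CA"][:5])
        assert not np.allclose(moved.coords["C"][4:], conf.coords["C"][4:])


class TestEnvironmentCount:
    def test_no_partners_within_exclusion(self):
        conf = cg.build_extended("ACD")
        counts = cg.environment_count(conf)
        assert np.all(np.abs(counts) < 1e-3)

    def test_distance_switch_is_half_at_8A(self):
        from defold.cg_sampler import _env_counts

        # residue 0 with its CA->CB axis along +z and one partner placed
        # on-axis: the angular factor cancels in the 8A / near-contact ratio
        CA = np.array([[0.0, 0.0, -1.0], [50, 50, 50], [60, 60, 60],
                       [0.0, 0.0, 0.0]])
        CB = np.array([[0.0, 0.0, 0.0], [50, 50, 51], [60, 60, 61],
                       [0.0, 0.0, 8.0]])
        n_at_8 = _env_counts(CA, CB)[0]
        CB2 = CB.copy()
        CB2[3, 2] = 0.5  # same direction, well inside the switch
        n_close = _env_counts(CA, CB2)[0]
        assert n_at_8 / n_close == pytest.approx(0.5, abs=0.01)

    def test_compact_state_buries_more_than_extended(self, bundle20):
        compact = bundle20.conformation
        extended = cg.build_extended(compact.sequence)
        nc = cg.environment_count(compact)
        ne = cg.environment_count(extended)
        interior = slice(5, 15)
        assert nc[interior].sum() > ne[interior].sum()


class TestTotalEnergy:
    def test_all_restraints_satisfied_gives_zero_restraint_terms(self):
        conf = cg.build_extended("AC")
        bundle = torsion_only_bundle(2)
        eb = cg.total_energy(conf, bundle, RESTRAINTS_ONLY)
        assert eb.torsion == 0.0
        assert eb.contact == 0.0
        assert eb.environment == 0.0
        assert eb.total == 0.0

    def test_contact_term_is_half_depth_at_its_cutoff(self):
        conf = cg.build_extended("ACDEFGHI")
        CB = conf.coords["CB"]
        d = float(np.linalg.norm(CB[0] - CB[7]))
        bundle = torsion_only_bundle(8)
        bundle.contacts.append((0, 7, d, 2.0, 0.5))  # r_c set at the pair's distance
        eb = cg.total_energy(conf, bundle, RESTRAINTS_ONLY)
        assert eb.contact == pytest.approx(-1.0, abs=1e-9)

    def test_term_switches_zero_exactly_their_component(self, hairpin16):
        conf = hairpin16.conformation
        bundle = torsion_only_bundle(16)
        full = cg.total_energy(conf, bundle, cg.ForceFieldOptions())
        no_pair = cg.total_energy(
            conf, bundle, cg.ForceFieldOptions(enable_pair=False))
        assert no_pair.pairwise == 0.0
        assert no_pair.environment == full.environment
        no_env = cg.total_energy(
            conf, bundle, cg.ForceFieldOptions(enable_env=False))
        assert no_env.environment == 0.0
        assert no_env.pairwise == full.pairwise

    def test_breakdown_sums_to_total(self, hairpin16):
        eb = cg.total_energy(hairpin16.conformation, torsion_only_bundle(16))
        assert eb.total == pytest.approx(
            eb.torsion + eb.pairwise + eb.environment + eb.contact)

    def test_mismatched_bundle_rejected(self):
        with pytest.raises(ValueError):
            cg.total_energy(cg.build_extended("ACDE"), torsion_only_bundle(7))


class TestSampler:
    def test_same_seed_is_bit_identical(self):
        conf = cg.build_extended("ACDEFGHI")
        bundle = torsion_only_bundle(8)
        t1 = cg.run_simulation(conf, bundle, 2000, capture_every=100, seed=5,
                               options=RESTRAINTS_ONLY)
        t2 = cg.run_simulation(conf, bundle, 2000, capture_every=100, seed=5,
                               options=RESTRAINTS_ONLY)
        assert np.array_equal(t1.energies, t2.energies)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.phi, f2.phi)
            assert np.array_equal(f1.psi, f2.psi)

    def test_frame_energies_match_recomputation(self):
        conf = cg.build_extended("ACDEFGHI")
        bundle = torsion_only_bundle(8)
        traj = cg.run_simulation(conf, bundle, 1000, capture_every=200, seed=1,
                                 options=RESTRAINTS_ONLY)
        for frame, e in zip(traj.frames, traj.energies):
            assert cg.total_energy(frame, bundle,
                                   RESTRAINTS_ONLY).total == pytest.approx(
                e, abs=1e-6)

    def test_zero_temperature_only_accepts_downhill(self):
        conf = cg.build_extended("ACDEFGHI")
        centers = (np.full(8, -60.0), np.full(8, -40.0))
        bundle = torsion_only_bundle(8, centers=centers)
        traj = cg.run_simulation(conf, bundle, 3000, capture_every=50,
                                 temperature=1e-12, seed=2,
                                 options=RESTRAINTS_ONLY)
        assert np.all(np.diff(traj.energies) <= 1e-9)

    def test_harmonic_well_variance_short_run(self):
        # quick statistical check; the long high-precision version runs in
        # the acceptance suite
        k, T = 0.05, 1.0
        conf = cg.build_extended("AAA")
        bundle = torsion_only_bundle(3, half_width=0.0, k=k)
        movable = np.zeros(6, dtype=bool)
        movable[1] = True
        traj = cg.run_simulation(conf, bundle, 100_000, capture_every=100_000,
                                 temperature=T, seed=7,
                                 options=RESTRAINTS_ONLY, movable=movable,
                                 record_torsions=True)
        d = circular_difference(traj.torsion_log[20_000:, 1], 180.0)
        assert d.var() == pytest.approx(T / k, rel=0.10)

    def test_stationary_distribution_matches_boltzmann(self):
        # flat-bottom well: occupancy of the zero-energy window against the
        # closed-form Boltzmann weight of window vs harmonic tails
        k, T, hw = 0.05, 1.0, 20.0
        conf = cg.build_extended("AAA")
        bundle = torsion_only_bundle(3, half_width=hw, k=k)
        movable = np.zeros(6, dtype=bool)
        movable[1] = True
        traj = cg.run_simulation(conf, bundle, 100_000, capture_every=100_000,
                                 temperature=T, seed=11,
                                 options=RESTRAINTS_ONLY, movable=movable,
                                 record_torsions=True)
        d = np.abs(circular_difference(traj.torsion_log[10_000:, 1], 180.0))
        p_emp = (d <= hw).mean()
        z_in = 2 * hw
        z_out = 2 * quad(lambda x: np.exp(-0.5 * k * x * x / T), 0, 160)[0]
        assert p_emp == pytest.approx(z_in / (z_in + z_out), abs=0.02)

    def test_nonfinite_start_rejected(self):
        conf = cg.build_extended("ACDE")
        conf.phi[1] = np.nan
        with pytest.raises(cg.SimulationError):
            cg.run_simulation(conf, torsion_only_bundle(4), 10,
                              capture_every=1, options=RESTRAINTS_ONLY)

    def test_step_capture_contract(self):
        conf = cg.build_extended("ACDE")
        with pytest.raises(ValueError):
            cg.run_simulation(conf, torsion_only_bundle(4), 10,
                              capture_every=20)


class TestEnsembleRuns:
    def test_trajectory_count_and_seed_permutation(self):
        conf = cg.build_extended("ACDEFG")
        bundle = torsion_only_bundle(6)
        seeds = [3, 1, 2]
        trajs = cg.run_ensemble(conf, bundle, seeds, 500, capture_every=100,
                                options=RESTRAINTS_ONLY)
        assert len(trajs) == 3
        perm = cg.run_ensemble(conf, bundle, [1, 2, 3], 500, capture_every=100,
                               options=RESTRAINTS_ONLY)
        by_seed = {t.seed: t for t in perm}
        for t in trajs:
            assert np.array_equal(t.energies, by_seed[t.seed].energies)

    def test_duplicate_seeds_warn(self):
        conf = cg.build_extended("ACDE")
        with pytest.warns(UserWarning):
            cg.run_ensemble(conf, torsion_only_bundle(4), [1, 1], 100,
                            capture_every=100, options=RESTRAINTS_ONLY)

    def test_contact_restraints_collapse_the_chain(self, hairpin16):
        tf = hairpin16
        contacts = ContactSet(pairs=[(i, j, 1.0) for i, j in tf.native_contacts],
                              min_separation=3)
        from defold.restraints import bundle as make_bundle
        b = make_bundle(tf.native_phi, tf.native_psi, contacts)
        conf0 = cg.build_extended(tf.conformation.sequence)
        rg0 = cg.radius_of_gyration(conf0)
        trajs = cg.run_ensemble(conf0, b, [0, 1, 2], 2000, capture_every=500,
                                options=RESTRAINTS_ONLY)
        final_rg = np.mean([cg.radius_of_gyration(t.frames[-1])
                            for t in trajs])
        assert final_rg < rg0

    def test_restraint_guided_refolding_reaches_native(self, hairpin16):
        # positive-control miniature: full control (20 seeds, 50k steps)
        # runs in the acceptance suite
        tf = hairpin16
        contacts = ContactSet(pairs=[(i, j, 1.0) for i, j in tf.native_contacts],
                              min_separation=3)
        from defold.restraints import bundle as make_bundle
        b = make_bundle(tf.native_phi, tf.native_psi, contacts)
        conf0 = cg.build_extended(tf.conformation.sequence)
        native_ca = tf.conformation.ca_coords()
        traj = cg.run_simulation(conf0, b, 50_000, capture_every=500, seed=1,
                                 options=RESTRAINTS_ONLY)
        best = min(kabsch_rmsd(f.ca_coords(), native_ca) for f in traj.frames)
        assert best < 2.0
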