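"""Gō-model DMD engine and the d_rms deformation statistic."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from filadyn.godynamics import (
    DMDError,
    DrmsSummary,
    GoParams,
    Trajectory,
    build_go_model,
    compute_drms,
    drms_profile,
    run_dmd,
)
from filadyn.selection import ContactList, native_contacts
from filadyn.structio import ca_array, extract_ca
from filadyn.synthetic import _rotation


def chain_model(structure, params=GoParams()):
    trace = extract_ca(structure)
    ca = ca_array(trace)
    contacts = native_contacts(ca)
    return build_go_model(ca, contacts, params=params)


@pytest.fixture(scope="module")
def folded_model(compact_chain):
    return chain_model(compact_chain)


class TestBuildGoModel:
    def test_two_bead_bonded_dimer(self):
        coords = np.array([[0.0, 0, 0], [3.8, 0, 0]])
        contacts = ContactList(np.empty((0, 2)), np.empty(0), 7.5, 2)
        model = build_go_model(coords, contacts)
        assert len(model.bonds) == 1 and len(model.contacts) == 0
        ptype, _rin2, _rout2 = model.pair_tables()
        assert ptype[0, 1] == 1  # bond

    def test_pair_partition_exhaustive(self, folded_model):
        """bond ∪ contact ∪ repulsive covers every pair exactly once."""
        n = folded_model.n_beads
        ptype, rin2, rout2 = folded_model.pair_tables()
        bonds = {tuple(sorted(p)) for p in map(tuple, folded_model.bonds)}
        contacts = folded_model.contacts.as_set()
        assert bonds.isdisjoint(contacts)
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in bonds:
                    assert ptype[i, j] == 1
                elif (i, j) in contacts:
                    assert ptype[i, j] == 2
                else:
                    assert ptype[i, j] == 0
                assert rin2[i, j] > 0

    def test_interchain_pairs_never_bonds(self, octamer_pair):
        structure, _ = octamer_pair
        trace = extract_ca(structure)
        ca = ca_array(trace)
        cids = [r[0] for r, _ in trace]
        order = sorted(set(cids))
        cidx = np.array([order.index(c) for c in cids])
        model = build_go_model(ca, native_contacts(ca, chain_index=cidx), cidx)
        for i, j in model.bonds:
            assert cidx[i] == cidx[j]

    def test_contact_below_hardcore_rejected(self):
        coords = np.array([[0.0, 0, 0], [50.0, 0, 0], [53.0, 0, 0]])
        bad = ContactList(np.array([[0, 1]]), np.array([3.0]), 7.5, 2)
        with pytest.raises(DMDError):
            build_go_model(coords, bad)


class TestDrms:
    def test_native_frame_zero(self, folded_model):
        assert compute_drms(folded_model.native, folded_model.native,
                            range(10)) == 0.0

    def test_two_residue_closed_form(self):
        native = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        frame = np.array([[0.0, 0, 0], [7.0, 0, 0]])
        assert compute_drms(frame, native, [0, 1]) == pytest.approx(2.0)

    def test_three_residue_closed_form(self):
        # equilateral: all native 5 Å, all current 6 Å -> sqrt(3*1/3) = 1
        def triangle(side):
            return side * np.array([[0.0, 0, 0], [1.0, 0, 0],
                                    [0.5, np.sqrt(3) / 2, 0]])
        assert compute_drms(triangle(6.0), triangle(5.0),
                            [0, 1, 2]) == pytest.approx(1.0)

    def test_matches_brute_force(self, folded_model):
        rng = np.random.default_rng(0)
        frame = folded_model.native + rng.normal(scale=0.7,
                                                 size=folded_model.native.shape)
        idx = list(range(0, 30, 2))
        got = compute_drms(frame, folded_model.native, idx)
        acc = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                d = np.linalg.norm(frame[idx[a]] - frame[idx[b]])
                d0 = np.linalg.norm(folded_model.native[idx[a]]
                                    - folded_model.native[idx[b]])
                acc.append((d - d0) ** 2)
        assert got == pytest.approx(np.sqrt(np.mean(acc)), abs=1e-12)

    def test_rigid_motion_invariance(self, folded_model):
        rng = np.random.default_rng(1)
        frame = folded_model.native + rng.normal(scale=0.5,
                                                 size=folded_model.native.shape)
        rot = _rotation([3, 1, 2], 61.0)
        moved = frame @ rot.T + np.array([9.0, -2.0, 4.0])
        idx = list(range(12))
        assert compute_drms(moved, folded_model.native, idx) == pytest.approx(
            compute_drms(frame, folded_model.native, idx), abs=1e-10)

    def test_single_residue_rejected(self, folded_model):
        with pytest.raises(ValueError):
            compute_drms(folded_model.native, folded_model.native, [0])


class TestEventDynamics:
    def test_head_on_collision_exchanges_velocities(self):
        """Two isolated equal-mass hard beads: 1D elastic velocity exchange."""
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        contacts = ContactList(np.empty((0, 2)), np.empty(0), 7.5, 2)
        model = build_go_model(coords, contacts,
                               chain_index=np.array([0, 1]))
        v0 = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        traj = run_dmd(model, 1, temperature=0.5, seed=0, snapshot_every=1,
                       thermostat_rate=0.0, record_energy=True,
                       start_velocities=v0)
        # after the single collision event the beads separate at hardcore
        d = np.linalg.norm(traj.frames[0][0] - traj.frames[0][1])
        assert d == pytest.approx(model.params.hardcore, abs=1e-9)
        ke = traj.energies[0, 0]
        assert ke == pytest.approx(1.0)  # 0.5*(1+1), conserved through impact

    def test_energy_conservation_microcanonical(self, folded_model):
        traj = run_dmd(folded_model, 100_000, temperature=0.5, seed=2,
                       snapshot_every=100_000, thermostat_rate=0.0,
                       record_energy=True)
        total = traj.energies[:, :2].sum(axis=1)
        drift = np.abs(total - total[0]).max()
        assert drift < 1e-9 * len(total)

    def test_momentum_conserved_without_thermostat(self, folded_model):
        rng = np.random.default_rng(3)
        v0 = rng.normal(scale=0.7, size=folded_model.native.shape)
        v0 -= v0.mean(axis=0)
        # snapshots do not store velocities; check via centre-of-mass motion
        traj = run_dmd(folded_model, 20_000, temperature=0.5, seed=3,
                       snapshot_every=1000, thermostat_rate=0.0,
                       start_velocities=v0)
        com = traj.frames.mean(axis=1)
        # zero net momentum -> centre of mass stays put through all events
        np.testing.assert_allclose(com - com[0], 0.0, atol=1e-8)

    def test_thermostat_maintains_temperature(self, folded_model):
        # strong coupling for tight statistics; the time-weighted mean
        # removes the event-clustering bias of a per-event average
        traj = run_dmd(folded_model, 150_000, temperature=0.5, seed=4,
                       snapshot_every=150_000, thermostat_rate=1.0,
                       record_energy=True)
        assert traj.mean_kinetic_temperature() == pytest.approx(0.5, rel=0.05)

    def test_bit_identical_for_fixed_seed(self, folded_model):
        a = run_dmd(folded_model, 30_000, seed=9, snapshot_every=1000)
        b = run_dmd(folded_model, 30_000, seed=9, snapshot_every=1000)
        assert np.array_equal(a.frames, b.frames)
        c = run_dmd(folded_model, 30_000, seed=10, snapshot_every=1000)
        assert not np.array_equal(a.frames, c.frames)

    def test_fold_retains_native_contacts_at_low_temperature(self, folded_model):
        traj = run_dmd(folded_model, 100_000, temperature=0.5, seed=5,
                       snapshot_every=10_000)
        cl = folded_model.contacts
        final = traj.frames[-1]
        d = np.linalg.norm(final[cl.pairs[:, 0]] - final[cl.pairs[:, 1]], axis=1)
        q = np.mean(d <= folded_model.params.well_hi * cl.distances)
        assert q > 0.9

    def test_overlapping_start_rejected(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        contacts = ContactList(np.empty((0, 2)), np.empty(0), 7.5, 2)
        model = build_go_model(coords, contacts, chain_index=np.array([0, 1]))
        with pytest.raises(DMDError, match="overlap"):
            run_dmd(model, 100, seed=0)

    def test_bad_parameters(self, folded_model):
        with pytest.raises(ValueError):
            run_dmd(folded_model, 0, seed=0)
        with pytest.raises(ValueError):
            run_dmd(folded_model, 10, temperature=-1.0, seed=0)


class TestDrmsProfile:
    def test_frozen_trajectory_all_zero(self, folded_model):
        frames = np.repeat(folded_model.native[None], 6, axis=0)
        traj = Trajectory(np.arange(1, 7) * 1000, frames, 0, 0.5, 6000, 1000)
        summary = drms_profile([traj], folded_model, range(8),
                               burn_in_fraction=1.0 / 3.0)
        assert summary.mean == 0.0 and summary.sd == 0.0

    def test_identical_seeds_pool_identically(self, folded_model):
        t1 = run_dmd(folded_model, 30_000, seed=6, snapshot_every=1000)
        t2 = run_dmd(folded_model, 30_000, seed=6, snapshot_every=1000)
        s1 = drms_profile([t1], folded_model, range(10))
        s12 = drms_profile([t1, t2], folded_model, range(10))
        np.testing.assert_allclose(np.concatenate([s1.values, s1.values]),
                                   s12.values)

    def test_burn_in_too_long_rejected(self, folded_model):
        traj = run_dmd(folded_model, 10_000, seed=7, snapshot_every=1000)
        with pytest.raises(ValueError):
            drms_profile([traj], folded_model, range(5), burn_in_fraction=1.0)

    def test_summary_statistics(self):
        vals = np.array([0.0, 1.0, 2.0, 3.0])
        s = DrmsSummary.from_values(vals, bins=4)
        assert s.mean == pytest.approx(1.5)
        assert s.hist_counts.sum() == 4
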