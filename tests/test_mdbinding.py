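"""MD binding classification, release detection, Coulomb decomposition."""

import io
import math

import numpy as np
import pytest

from motorlab import (
    AtomRecord,
    ChargeSet,
    COULOMB_CONSTANT,
    TrajectoryFrame,
    TrajectorySpec,
    binding_distances,
    classify_frame,
    classify_trajectory,
    compare_contributions,
    coulomb_decomposition,
    gen_trajectory,
)
from motorlab.mdbinding import (
    BindingDistances,
    BOUND_WINDOW,
    UNBOUND_MIN,
    main_chain_dipole_group,
    read_multimodel_pdb,
)
from motorlab.synthetic import write_trajectory_pdb


def truth_table_label(r1, r2, r3):
    """Oracle: restated window logic, independent of the implementation."""
    bound = (4 < r1 < 10) and (2 < r2 < 6) and (2 < r3 < 6)
    unbound = (r1 > 15) and (r2 > 10) and (r3 > 10)
    if bound:
        return "bound"
    if unbound:
        return "unbound"
    return "intermediate"


PROBES = (
    AtomRecord("A", 399, "ARG", "CZ", (0.0, 0.0, 0.0)),
    AtomRecord("A", 396, "SER", "OG", (8.0, 0.0, 0.0)),
    AtomRecord("A", 398, "SER", "OG", (0.0, 8.0, 0.0)),
)


class TestDistances:
    def test_ion_at_probe_gives_zero(self):
        frame = TrajectoryFrame(atoms=list(PROBES), ions=[(0.0, 0.0, 0.0)])
        d = binding_distances(frame)
        assert d.r1 == 0.0
        assert d.r2 == pytest.approx(8.0)

    def test_nearest_of_two_ions(self):
        frame = TrajectoryFrame(
            atoms=list(PROBES), ions=[(5.0, 0.0, 0.0), (20.0, 0.0, 0.0)]
        )
        d = binding_distances(frame)
        assert d.r1 == pytest.approx(5.0)
        assert d.ion_index["r1"] == 0
        # r2 probe at (8,0,0): ion 0 is 3 A away -> also nearest for r2
        assert d.r2 == pytest.approx(3.0)

    def test_brute_force_nearest_oracle(self, rng):
        ions = [tuple(p) for p in rng.normal(0, 15, size=(50, 3))]
        frame = TrajectoryFrame(atoms=list(PROBES), ions=ions)
        d = binding_distances(frame)
        for name, probe in zip(("r1", "r2", "r3"), PROBES):
            expected = min(
                math.dist(probe.xyz, ion) for ion in ions
            )
            assert getattr(d, name) == pytest.approx(expected)

    def test_missing_probe_rejected_by_name(self):
        frame = TrajectoryFrame(atoms=[PROBES[0], PROBES[1]], ions=[(0, 0, 0)])
        with pytest.raises(KeyError, match="398"):
            binding_distances(frame)

    def test_no_ions_rejected(self):
        frame = TrajectoryFrame(atoms=list(PROBES), ions=[])
        with pytest.raises(ValueError):
            binding_distances(frame)


class TestClassifier:
    @pytest.mark.parametrize(
        "r, expected",
        [
            ((5, 3, 3), "bound"),
            ((20, 12, 12), "unbound"),
            ((12, 8, 8), "intermediate"),
            ((4, 3, 3), "intermediate"),   # boundary: strict inequality
            ((15, 11, 11), "intermediate"),
            ((5, 3, 7), "intermediate"),   # one distance out of window
        ],
    )
    def test_quoted_examples_and_boundaries(self, r, expected):
        assert classify_frame(BindingDistances(*r)) == expected

    def test_truth_table_grid_equivalence(self):
        grid = np.linspace(0.5, 20.0, 20)
        for r1 in grid:
            for r2 in grid:
                for r3 in grid:
                    d = BindingDistances(r1, r2, r3)
                    assert classify_frame(d) == truth_table_label(r1, r2, r3)

    def test_rigid_motion_invariance(self, rng):
        # classification depends only on distances, so any rotation +
        # translation of all coordinates leaves the labels unchanged
        frames, labels = gen_trajectory(
            TrajectorySpec(segments=(("bound", 5), ("intermediate", 5), ("unbound", 5)), seed=4)
        )
        theta = 0.7
        R = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1.0]]
        )
        t = np.array([3.0, -7.0, 11.0])
        for frame, lab in zip(frames, labels):
            atoms = [
                AtomRecord(a.chain, a.residue_number, a.residue_name, a.atom_name,
                           tuple(R @ np.asarray(a.xyz) + t))
                for a in frame.atoms
            ]
            ions = [tuple(R @ np.asarray(p) + t) for p in frame.ions]
            moved = TrajectoryFrame(atoms=atoms, ions=ions, time=frame.time)
            assert classify_frame(binding_distances(moved)) == lab


class TestTrajectory:
    def test_planted_labels_recovered_exactly(self):
        segs = (("bound", 40), ("intermediate", 25), ("unbound", 35))
        frames, labels = gen_trajectory(TrajectorySpec(segments=segs, seed=6))
        res = classify_trajectory(frames)
        assert res.labels == labels
        assert res.counts == {"bound": 40, "unbound": 35, "intermediate": 25}
        assert sum(res.counts.values()) == 100

    def test_all_bound_has_no_release(self):
        frames, _ = gen_trajectory(TrajectorySpec(segments=(("bound", 100),), seed=7))
        res = classify_trajectory(frames)
        assert res.release_time is None
        assert res.rebinding_events == []

    def test_planted_release_at_153_ns(self):
        frames, _ = gen_trajectory(
            TrajectorySpec(segments=(("bound", 153), ("unbound", 847)), frame_interval=1.0, seed=8)
        )
        res = classify_trajectory(frames)
        assert res.release_time == pytest.approx(153.0)

    def test_rebinding_after_release(self):
        frames, _ = gen_trajectory(
            TrajectorySpec(
                segments=(("bound", 10), ("unbound", 5), ("bound", 10)), seed=9
            )
        )
        res = classify_trajectory(frames)
        assert res.release_time == pytest.approx(10.0)
        assert res.rebinding_events == [pytest.approx(15.0)]

    def test_counts_additive_over_concatenation(self):
        f1, _ = gen_trajectory(TrajectorySpec(segments=(("bound", 20), ("unbound", 10)), seed=10))
        f2, _ = gen_trajectory(TrajectorySpec(segments=(("intermediate", 15),), seed=11))
        for f in f2:
            f.time += 30.0
        both = classify_trajectory(f1 + f2)
        c1, c2 = classify_trajectory(f1).counts, classify_trajectory(f2).counts
        assert both.counts == {k: c1[k] + c2[k] for k in c1}

    def test_unordered_times_rejected(self):
        frames, _ = gen_trajectory(TrajectorySpec(segments=(("bound", 5),), seed=12))
        frames[2].time = 100.0
        with pytest.raises(ValueError):
            classify_trajectory(frames)

    def test_empty_segments_rejected(self):
        with pytest.raises(ValueError):
            TrajectorySpec(segments=())

    def test_pdb_round_trip_preserves_labels(self, tmp_path):
        frames, labels = gen_trajectory(
            TrajectorySpec(segments=(("bound", 3), ("unbound", 3)), seed=13)
        )
        buf = io.StringIO()
        write_trajectory_pdb(frames, buf)
        p = tmp_path / "traj.pdb"
        p.write_text(buf.getvalue())
        back = read_multimodel_pdb(p)
        assert len(back) == 6
        res = classify_trajectory(back)
        assert res.labels == labels


def two_atom_frame(atoms_xyz_q, ion=(0.0, 0.0, 0.0)):
    atoms = []
    charges = {}
    for i, (xyz, q) in enumerate(atoms_xyz_q):
        rec = AtomRecord("A", i + 1, "UNK", f"X{i}", tuple(xyz))
        atoms.append(rec)
        charges[rec.key] = q
    frame = TrajectoryFrame(atoms=atoms, ions=[tuple(ion)])
    return frame, charges


class TestCoulomb:
    def test_unit_charges_at_one_angstrom(self):
        frame, charges = two_atom_frame([((1.0, 0.0, 0.0), 1.0)])
        cs = ChargeSet(charges=charges, groups={"g": list(charges)})
        dec = coulomb_decomposition(frame, cs)
        assert dec["g"]["energy"] == pytest.approx(-332.0636)
        assert dec["g"]["clashes"] == []

    def test_group_partition_additivity(self, rng):
        pts = rng.normal(0, 10, size=(30, 3))
        qs = rng.uniform(-1, 1, size=30)
        frame, charges = two_atom_frame(list(zip(map(tuple, pts), qs)), ion=(25.0, 0, 0))
        keys = list(charges)
        total = coulomb_decomposition(frame, ChargeSet(charges, {"all": keys}))["all"]["energy"]
        split = coulomb_decomposition(
            frame, ChargeSet(charges, {"a": keys[:11], "b": keys[11:23], "c": keys[23:]})
        )
        assert sum(rec["energy"] for rec in split.values()) == pytest.approx(total, rel=1e-12)

    def test_linearity_in_charges(self, rng):
        pts = rng.normal(0, 8, size=(10, 3))
        qs = rng.uniform(-0.5, 0.5, size=10)
        frame, charges = two_atom_frame(list(zip(map(tuple, pts), qs)), ion=(20.0, 0, 0))
        cs1 = ChargeSet(charges, {"g": list(charges)})
        cs2 = ChargeSet({k: 2 * v for k, v in charges.items()}, {"g": list(charges)})
        e1 = coulomb_decomposition(frame, cs1)["g"]["energy"]
        e2 = coulomb_decomposition(frame, cs2)["g"]["energy"]
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_dipole_far_field_limit(self):
        # +-0.5 e separated by 1 A along x, probed at 20 A on the dipole axis:
        # E ~ -k q_ion * p / r^2 with p = 0.5 e*A
        frame, charges = two_atom_frame(
            [((0.5, 0.0, 0.0), 0.5), ((-0.5, 0.0, 0.0), -0.5)], ion=(20.0, 0.0, 0.0)
        )
        cs = ChargeSet(charges, {"dip": list(charges)})
        e = coulomb_decomposition(frame, cs)["dip"]["energy"]
        point_dipole = -COULOMB_CONSTANT * (-1.0) * (-0.5) / 20.0**2
        assert e == pytest.approx(point_dipole, rel=0.01)

    def test_clash_flagged_but_summed(self):
        frame, charges = two_atom_frame([((0.05, 0.0, 0.0), 1.0)])
        cs = ChargeSet(charges, {"g": list(charges)})
        dec = coulomb_decomposition(frame, cs)
        assert dec["g"]["clashes"] == [("A", 1, "X0")]
        assert np.isfinite(dec["g"]["energy"])

    def test_uncharged_group_atom_rejected(self):
        frame, charges = two_atom_frame([((1.0, 0.0, 0.0), 1.0)])
        cs = ChargeSet(charges={}, groups={"g": list(charges)})
        with pytest.raises(KeyError):
            coulomb_decomposition(frame, cs)


class TestContributions:
    def _bound_frame(self, y=3.0):
        frames, _ = gen_trajectory(TrajectorySpec(segments=(("bound", 1),), seed=20))
        return frames[0]

    def test_closer_dipole_group_ranks_first(self):
        # charge group far from the ion, dipole-like group adjacent: the
        # nearer group must dominate the ranking (more negative mean)
        frame = self._bound_frame()
        ion = np.asarray(frame.ions[0])
        near = AtomRecord("B", 1, "DIP", "D1", tuple(ion + [0.0, 2.0, 0.0]))
        far = AtomRecord("B", 2, "CHG", "Q1", tuple(ion + [0.0, 15.0, 0.0]))
        frame.atoms.extend([near, far])
        charges = {near.key: 0.5, far.key: 1.0}
        cs = ChargeSet(charges, {"dipole": [near.key], "charge": [far.key]})
        table = compare_contributions([frame], cs)
        assert table[0]["group"] == "dipole"
        assert table[0]["mean"] < table[1]["mean"]

    def test_single_frame_sd_zero(self):
        frame = self._bound_frame()
        extra = AtomRecord("B", 1, "CHG", "Q1", (0.0, 20.0, 0.0))
        frame.atoms.append(extra)
        cs = ChargeSet({extra.key: 1.0}, {"g": [extra.key]})
        table = compare_contributions([frame], cs)
        assert table[0]["sd"] == 0.0
        assert table[0]["n"] == 1

    def test_no_bound_frames_gives_empty_table(self):
        frames, _ = gen_trajectory(TrajectorySpec(segments=(("unbound", 5),), seed=21))
        extra_key = None
        for f in frames:
            extra = AtomRecord("B", 1, "CHG", "Q1", (0.0, 30.0, 0.0))
            f.atoms.append(extra)
            extra_key = extra.key
        cs = ChargeSet({extra_key: 1.0}, {"g": [extra_key]})
        assert compare_contributions(frames, cs) == []


def test_main_chain_dipole_group_selects_backbone_only():
    atoms = [
        AtomRecord("A", 10, "ALA", name, (float(i), 0.0, 0.0))
        for i, name in enumerate(["N", "H", "CA", "C", "O", "CB"])
    ]
    frame = TrajectoryFrame(atoms=atoms, ions=[(0, 0, 50.0)])
    keys = main_chain_dipole_group(frame, [10])
    names = {k[2] for k in keys}
    assert names == {"N", "H", "C", "O"}
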