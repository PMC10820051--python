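"""Rigid superposition, fluctuation profiles and the two-pass alignment."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cypwater.core import AtomRecord, Snapshot
from cypwater.rmsf import (
    SuperpositionError,
    aggregate_profiles,
    apply_transform,
    rmsf,
    sidechain_aggregate,
    superpose,
    two_pass_rmsf,
)

from .oracles import quaternion_superpose_rmsd


def random_rigid(rng):
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestSuperpose:
    def test_identity(self):
        points = np.random.default_rng(0).uniform(0, 10, (8, 3))
        R, t, rmsd = superpose(points, points)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 10, (10, 3))
        R0, t0 = random_rigid(rng)
        mobile = ref @ R0.T + t0
        R, t, rmsd = superpose(mobile, ref)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(apply_transform(mobile, R, t), ref, atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_matches_quaternion_method(self):
        """Kabsch RMSD equals the Horn quaternion-method RMSD to 1e-8."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            mobile = rng.uniform(-5, 5, (10, 3))
            ref = rng.uniform(-5, 5, (10, 3))
            _, _, rmsd = superpose(mobile, ref)
            assert abs(rmsd - quaternion_superpose_rmsd(mobile, ref)) < 1e-8

    def test_optimality_against_random_transforms(self):
        rng = np.random.default_rng(3)
        mobile = rng.uniform(-5, 5, (12, 3))
        ref = rng.uniform(-5, 5, (12, 3))
        _, _, best = superpose(mobile, ref)
        for _ in range(100):
            R, t = random_rigid(rng)
            trial = np.sqrt(np.mean(np.sum((mobile @ R.T + t - ref) ** 2, axis=1)))
            assert best <= trial + 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(SuperpositionError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(SuperpositionError, match="collinear"):
            superpose(line, line)


class TestRMSF:
    def test_static_ensemble_zero(self):
        frame = np.random.default_rng(0).uniform(0, 5, (6, 3))
        np.testing.assert_allclose(rmsf(np.stack([frame] * 10)), 0.0, atol=1e-12)

    def test_alternating_displacement(self):
        """An atom hopping ±d about its mean has RMSF exactly d."""
        d = 0.7
        base = np.zeros((1, 3))
        frames = [base + [s * d, 0, 0] for s in (+1, -1) * 25]
        assert rmsf(np.stack(frames))[0] == pytest.approx(d)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        sigma = 0.5
        rng = np.random.default_rng(12)
        base = rng.uniform(0, 20, (30, 3))
        frames = base + rng.normal(0, sigma, size=(1000, 30, 3))
        values = rmsf(frames)
        assert np.mean(values) == pytest.approx(sigma * np.sqrt(3), rel=0.05)


class TestSidechainAggregate:
    @pytest.mark.parametrize(
        "values,expected",
        [([3.0, 4.0], np.sqrt(12.5)), ([2.2], 2.2), ([0.0, 0.0, 0.0], 0.0)],
    )
    def test_root_mean_square(self, values, expected):
        assert sidechain_aggregate(values) == pytest.approx(expected)

    def test_empty_is_absent_not_zero(self):
        assert sidechain_aggregate([]) is None


def build_frames(coords_per_frame, names, resnums, elements=None):
    """Snapshots from (frames, atoms, 3) coordinates and per-atom metadata."""
    elements = elements or ["C"] * len(names)
    frames = []
    for f, coords in enumerate(coords_per_frame):
        atoms = [
            AtomRecord(i + 1, names[i], elements[i], resnums[i], "ALA", "A", coords[i])
            for i in range(len(names))
        ]
        frames.append(Snapshot(frame_index=f, time_ps=250.0 * f, atoms=atoms))
    return frames


def cross_geometry(n_res):
    """Non-collinear Cα scaffold plus one CB per residue."""
    rng = np.random.default_rng(7)
    ca = rng.uniform(0, 15, (n_res, 3))
    cb = ca + rng.normal(0, 1.0, (n_res, 3))
    coords = np.empty((2 * n_res, 3))
    coords[0::2] = ca
    coords[1::2] = cb
    names = ["CA", "CB"] * n_res
    names = [n for pair in zip(["CA"] * n_res, ["CB"] * n_res) for n in pair]
    resnums = [r for r in range(1, n_res + 1) for _ in range(2)]
    return coords, names, resnums


class TestTwoPassRMSF:
    def test_rigid_ensemble_all_in_mask(self):
        coords, names, resnums = cross_geometry(6)
        frames = build_frames([coords.copy() for _ in range(5)], names, resnums)
        profile = two_pass_rmsf(frames, frames[0])
        assert profile.alignment_mask == frozenset(range(1, 7))
        np.testing.assert_allclose(profile.ca_rmsf, 0.0, atol=1e-10)
        np.testing.assert_allclose(profile.sidechain_rmsf, 0.0, atol=1e-10)

    def test_mobile_terminus_excluded_and_core_improved(self):
        """A wildly mobile terminus is dropped from the alignment mask, and
        masking it gives a lower core RMSF than an unmasked alignment."""
        rng = np.random.default_rng(21)
        coords, names, resnums = cross_geometry(12)
        n_res = 12
        mobile_res = {11, 12}
        frames_coords = []
        for f in range(60):
            c = coords.copy()
            for r in mobile_res:  # terminus jumps by several Å each frame
                idx = [i for i, rn in enumerate(resnums) if rn == r]
                c[idx] += rng.uniform(-6, 6, 3)
            frames_coords.append(c)
        frames = build_frames(frames_coords, names, resnums)
        reference = build_frames([coords], names, resnums)[0]
        masked = two_pass_rmsf(frames, reference, mask_threshold=2.0)
        control = two_pass_rmsf(frames, reference, mask_threshold=1e9)  # pass-1-only behaviour
        assert mobile_res.isdisjoint(masked.alignment_mask)
        core = [i for i, r in enumerate(range(1, n_res + 1)) if r not in mobile_res]
        assert masked.ca_rmsf[core].mean() < control.ca_rmsf[core].mean()
        np.testing.assert_allclose(masked.ca_rmsf[core], 0.0, atol=1e-9)

    def test_small_jitter_passes_agree(self):
        """With uniform 0.1 Å jitter the two passes give the same profile."""
        rng = np.random.default_rng(5)
        coords, names, resnums = cross_geometry(10)
        frames_coords = [coords + rng.normal(0, 0.1, coords.shape) for _ in range(200)]
        frames = build_frames(frames_coords, names, resnums)
        reference = build_frames([coords], names, resnums)[0]
        profile = two_pass_rmsf(frames, reference)
        control = two_pass_rmsf(frames, reference, mask_threshold=1e9)
        np.testing.assert_allclose(profile.ca_rmsf, control.ca_rmsf, rtol=0.10)

    def test_global_rigid_transform_invariance(self):
        rng = np.random.default_rng(9)
        coords, names, resnums = cross_geometry(8)
        frames_coords = [coords + rng.normal(0, 0.2, coords.shape) for _ in range(30)]
        frames = build_frames(frames_coords, names, resnums)
        reference = build_frames([coords], names, resnums)[0]
        R0, t0 = random_rigid(rng)
        moved = build_frames([c @ R0.T + t0 for c in frames_coords], names, resnums)
        p1 = two_pass_rmsf(frames, reference)
        p2 = two_pass_rmsf(moved, reference)
        np.testing.assert_allclose(p1.ca_rmsf, p2.ca_rmsf, atol=1e-9)

    def test_degenerate_mask_rejected(self):
        rng = np.random.default_rng(2)
        coords, names, resnums = cross_geometry(4)
        frames_coords = [coords + rng.uniform(-8, 8, coords.shape) for _ in range(10)]
        frames = build_frames(frames_coords, names, resnums)
        with pytest.raises(ValueError, match="degenerate"):
            two_pass_rmsf(frames, frames[0], mask_threshold=0.01)


class TestAggregateProfiles:
    def _profile(self, ca, sc):
        from cypwater.rmsf import RMSFProfile

        n = len(ca)
        return RMSFProfile(
            residue_numbers=np.arange(1, n + 1),
            ca_rmsf=np.asarray(ca, float),
            sidechain_rmsf=np.asarray(sc, float),
            alignment_mask=frozenset(range(1, n + 1)),
        )

    def test_identical_profiles_zero_sd(self):
        profiles = [self._profile([1.0, 2.0], [0.5, 0.7])] * 12
        agg = aggregate_profiles(profiles)
        assert agg.dataset_count == 12
        np.testing.assert_allclose(agg.ca_sd, 0.0)
        np.testing.assert_allclose(agg.ca_mean, [1.0, 2.0])

    def test_two_profile_closed_form(self):
        agg = aggregate_profiles([self._profile([1.0], [1.0]), self._profile([3.0], [3.0])])
        assert agg.ca_mean[0] == pytest.approx(2.0)
        assert agg.ca_sd[0] == pytest.approx(np.sqrt(2.0))

    def test_known_spread_recovered(self):
        rng = np.random.default_rng(31)
        true_mean, true_sd = 1.5, 0.3
        profiles = [
            self._profile(rng.normal(true_mean, true_sd, 40), np.zeros(40)) for _ in range(12)
        ]
        agg = aggregate_profiles(profiles)
        assert np.mean(agg.ca_mean) == pytest.approx(true_mean, abs=0.1)
        assert np.mean(agg.ca_sd) == pytest.approx(true_sd, rel=0.35)

    def test_numbering_mismatch_rejected(self):
        a = self._profile([1.0, 2.0], [0.0, 0.0])
        b = self._profile([1.0, 2.0], [0.0, 0.0])
        b.residue_numbers = np.array([5, 6])
        with pytest.raises(ValueError, match="numbering"):
            aggregate_profiles([a, b])
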