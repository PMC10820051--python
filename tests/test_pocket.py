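"""Pocket selection, water assignment, volume estimation, reference table."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cypwater.core import AtomRecord, Snapshot, percent_increase
from cypwater.pocket import (
    AlphaSphere,
    Pocket,
    load_binding_site_definitions,
    load_crystal_volumes,
    modal_volume,
    pocket_contact_residues,
    pocket_volume,
    select_binding_pocket,
    waters_in_pocket,
)

from .oracles import brute_force_pocket_membership, sphere_volume, two_sphere_union_volume


def make_snapshot(waters: dict[int, tuple], atoms=()) -> Snapshot:
    return Snapshot(
        frame_index=0,
        time_ps=0.0,
        atoms=list(atoms),
        water_oxygens={k: np.array(v, float) for k, v in waters.items()},
    )


class TestReferenceTable:
    def test_residue_counts_per_isoform(self):
        """The packaged binding-site definitions: 20/34/46 amino acids + 1 heme."""
        defs = load_binding_site_definitions()
        assert set(defs) == {"1A2", "2D6", "3A4"}
        expected = {"1A2": 20, "2D6": 34, "3A4": 46}
        for label, n_aa in expected.items():
            assert len(defs[label].amino_acid_residues) == n_aa
            assert len(defs[label].residue_numbers) == n_aa + 1

    def test_heme_is_last_entry(self):
        defs = load_binding_site_definitions()
        assert defs["1A2"].heme_residue == 900
        assert defs["2D6"].heme_residue == 600
        assert defs["3A4"].heme_residue == 508

    def test_crystal_volumes(self):
        volumes = load_crystal_volumes()
        assert volumes == {"1A2": 512.0, "2D6": 1019.0, "3A4": 2206.0}


class TestSelectBindingPocket:
    def test_single_pocket_returned(self):
        pocket = Pocket(1, [AlphaSphere(np.zeros(3), 3.0)])
        assert select_binding_pocket([pocket], np.array([50.0, 0, 0])) is pocket

    def test_nearest_pocket_wins(self):
        near = Pocket(1, [AlphaSphere(np.array([4.0, 0, 0]), 3.0)])
        far = Pocket(2, [AlphaSphere(np.array([40.0, 0, 0]), 3.0)])
        assert select_binding_pocket([far, near], np.zeros(3)) is near

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_binding_pocket([], np.zeros(3))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            pockets = [
                Pocket(i, [AlphaSphere(c, 2.0) for c in rng.uniform(-30, 30, size=(rng.integers(1, 6), 3))])
                for i in range(5)
            ]
            fe = rng.uniform(-30, 30, size=3)
            best = min(
                pockets,
                key=lambda p: (min(float(np.linalg.norm(s.center - fe)) for s in p.spheres), -p.n_spheres),
            )
            assert select_binding_pocket(pockets, fe) is best


class TestWatersInPocket:
    def test_boundary_behaviour(self):
        pocket = Pocket(1, [AlphaSphere(np.zeros(3), 2.0)])
        inside = make_snapshot({7: (0, 0, 1.9)})
        outside = make_snapshot({7: (0, 0, 2.1)})
        on_surface = make_snapshot({7: (0, 0, 2.0)})
        assert waters_in_pocket(inside, pocket) == {7}
        assert waters_in_pocket(outside, pocket) == set()
        assert waters_in_pocket(on_surface, pocket) == {7}  # boundary inclusive

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        spheres = [AlphaSphere(rng.uniform(0, 20, 3), rng.uniform(1.5, 4.0)) for _ in range(6)]
        pocket = Pocket(1, spheres)
        waters = {i: tuple(rng.uniform(0, 20, 3)) for i in range(50)}
        snap = make_snapshot(waters)
        ids, pos = snap.water_arrays()
        expected = brute_force_pocket_membership(ids, pos, pocket.centers(), pocket.radii())
        assert waters_in_pocket(snap, pocket) == expected

    @given(st.integers(0, 2**31 - 1))
    def test_monotone_under_pocket_growth(self, seed):
        """Adding an alpha sphere never removes pocket members."""
        rng = np.random.default_rng(seed)
        snap = make_snapshot({i: tuple(rng.uniform(0, 10, 3)) for i in range(20)})
        spheres = [AlphaSphere(rng.uniform(0, 10, 3), rng.uniform(1, 3)) for _ in range(3)]
        small = waters_in_pocket(snap, Pocket(1, spheres[:2]))
        grown = waters_in_pocket(snap, Pocket(1, spheres))
        assert small <= grown


class TestPocketVolume:
    def test_single_sphere_closed_form(self):
        est = pocket_volume(Pocket(1, [AlphaSphere(np.zeros(3), 3.0)]), n_samples=100_000, seed=0)
        assert abs(est.volume - sphere_volume(3.0)) <= 3 * est.standard_error

    def test_disjoint_spheres_additive(self):
        pocket = Pocket(
            1,
            [AlphaSphere(np.zeros(3), 2.0), AlphaSphere(np.array([20.0, 0, 0]), 2.0)],
        )
        est = pocket_volume(pocket, n_samples=100_000, seed=1)
        assert abs(est.volume - 2 * sphere_volume(2.0)) <= 3 * est.standard_error

    def test_overlapping_spheres_lens_formula(self):
        pocket = Pocket(
            1,
            [AlphaSphere(np.zeros(3), 2.0), AlphaSphere(np.array([2.0, 0, 0]), 2.0)],
        )
        est = pocket_volume(pocket, n_samples=100_000, seed=2)
        assert abs(est.volume - two_sphere_union_volume(2.0, 2.0, 2.0)) <= 3 * est.standard_error

    def test_error_shrinks_with_samples(self):
        """Mean absolute error decreases ~1/√n across three sample sizes."""
        pocket = Pocket(1, [AlphaSphere(np.zeros(3), 3.0)])
        truth = sphere_volume(3.0)
        errors = []
        for n in (1_000, 10_000, 100_000):
            errs = [abs(pocket_volume(pocket, n, seed).volume - truth) for seed in range(8)]
            errors.append(np.mean(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_translation_invariance(self):
        spheres = [AlphaSphere(np.zeros(3), 2.0), AlphaSphere(np.array([1.5, 1.0, 0.0]), 2.5)]
        shift = np.array([100.0, -50.0, 7.0])
        moved = [AlphaSphere(s.center + shift, s.radius) for s in spheres]
        v1 = pocket_volume(Pocket(1, spheres), 50_000, seed=3).volume
        v2 = pocket_volume(Pocket(1, moved), 50_000, seed=3).volume
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            pocket_volume(Pocket(1, [AlphaSphere(np.zeros(3), 1.0)]), n_samples=0)


class TestModalVolume:
    def test_degenerate_distribution(self):
        assert modal_volume([500.0] * 10, bin_width=100) == 500.0
        assert modal_volume([500.0] * 10, bin_width=37.0) == pytest.approx(14 * 37.0)

    def test_counting(self):
        assert modal_volume([400, 500, 500, 600], bin_width=100) == 500.0

    def test_tie_breaks_low(self):
        assert modal_volume([400, 400, 600, 600], bin_width=100) == 400.0

    def test_normal_sample_peak(self):
        rng = np.random.default_rng(9)
        sample = rng.normal(1400.0, 150.0, size=1000)
        assert abs(modal_volume(sample, bin_width=100) - 1400.0) <= 100.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modal_volume([])


class TestModalVolumeIncreases:
    @pytest.mark.parametrize(
        "before,after,expected_pct",
        [(500.0, 1400.0, 180), (1200.0, 1800.0, 50), (2600.0, 3000.0, 15)],
    )
    def test_restrained_to_free_increase(self, before, after, expected_pct):
        """Modal-volume growth between the restrained and free stages, per isoform."""
        assert round(percent_increase(before, after)) == expected_pct


class TestContactResidues:
    def _atom(self, serial, resnum, pos):
        return AtomRecord(serial, "CA", "C", resnum, "ALA", "A", np.array(pos, float))

    def test_surface_distance_rule(self):
        pocket = Pocket(1, [AlphaSphere(np.zeros(3), 3.0)])
        close = make_snapshot({}, atoms=[self._atom(1, 10, (4.0, 0, 0))])  # surface + 1 Å
        far = make_snapshot({}, atoms=[self._atom(1, 11, (8.0, 0, 0))])  # surface + 5 Å
        assert pocket_contact_residues(close, pocket, cutoff=3.0) == [10]
        assert pocket_contact_residues(far, pocket, cutoff=3.0) == []

    def test_matches_all_pairs_scan(self):
        rng = np.random.default_rng(5)
        atoms = [self._atom(i, i // 3, rng.uniform(-10, 10, 3)) for i in range(60)]
        snap = make_snapshot({}, atoms=atoms)
        spheres = [AlphaSphere(rng.uniform(-10, 10, 3), rng.uniform(1, 3)) for _ in range(4)]
        pocket = Pocket(1, spheres)
        cutoff = 2.5
        expected = sorted(
            {
                a.residue_number
                for a in atoms
                if any(
                    np.linalg.norm(a.position - s.center) <= s.radius + cutoff for s in spheres
                )
            }
        )
        assert pocket_contact_residues(snap, pocket, cutoff=cutoff) == expected
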