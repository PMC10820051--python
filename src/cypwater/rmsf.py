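"""Two-pass superposition-based RMSF profiles.

The fluctuation analysis follows the standard protocol for flexible
proteins: every frame is first rigid-body superposed onto a reference
conformation using all Cα atoms (Kabsch least-squares fit), per-Cα RMSF is
computed about the ensemble-mean position, and the alignment is then
repeated using only Cα atoms whose first-pass RMSF is below a threshold
(default 2 Å) so highly mobile loops and termini do not skew the fit.
Cα and sidechain RMSF are reported from the second alignment.

Sidechain atoms are all non-backbone heavy atoms (N, Cα, C, O, OXT and
hydrogens excluded; hydrogen inclusion is configurable).  A residue's
sidechain RMSF is the root-mean-square of its per-atom RMSF values;
residues without sidechain atoms (glycine) yield an absent value rather
than zero.

RMSF is measured about the ensemble-mean position, not the reference: the
reference conformation only anchors the alignment.  This is the standard
convention; measuring about the reference instead is available via
``rmsf(..., reference=...)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import BACKBONE_ATOM_NAMES, Snapshot

__all__ = [
    "RMSFProfile",
    "AggregateProfile",
    "SuperpositionError",
    "superpose",
    "apply_transform",
    "rmsf",
    "two_pass_rmsf",
    "sidechain_aggregate",
    "aggregate_profiles",
]

DEFAULT_MASK_THRESHOLD = 2.0  # Å, strict upper bound for second-pass alignment atoms


class SuperpositionError(ValueError):
    """Raised when a rigid superposition is underdetermined."""


@dataclass
class RMSFProfile:
    """Per-residue Cα and sidechain fluctuation magnitudes for one ensemble."""

    residue_numbers: np.ndarray
    ca_rmsf: np.ndarray  # Å
    sidechain_rmsf: np.ndarray  # Å, NaN where the residue has no sidechain atoms
    alignment_mask: frozenset[int]  # residues used in the second-pass alignment
    label: str = ""


@dataclass
class AggregateProfile:
    """Residue-wise mean ± sd of RMSF across several ensembles."""

    residue_numbers: np.ndarray
    ca_mean: np.ndarray
    ca_sd: np.ndarray
    sidechain_mean: np.ndarray
    sidechain_sd: np.ndarray
    dataset_count: int


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch) of matched point sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det +1).  Requires at least three non-collinear
    pairs, otherwise the rotation is underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise SuperpositionError("mobile and reference must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise SuperpositionError("need at least three matched atom pairs")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise SuperpositionError("points are collinear; rotation underdetermined")
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ R.T
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ rotation.T + translation


def rmsf(ensemble: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Per-atom RMSF of an aligned ensemble.

    ``ensemble`` has shape (frames, atoms, 3).  Displacements are measured
    from the ensemble-mean position of each atom, or from ``reference``
    positions when given.
    """
    ensemble = np.asarray(ensemble, dtype=float)
    if ensemble.ndim != 3 or ensemble.shape[0] < 2:
        raise ValueError("ensemble must be (frames ≥ 2, atoms, 3)")
    center = ensemble.mean(axis=0) if reference is None else np.asarray(reference, float)
    if center.shape != ensemble.shape[1:]:
        raise ValueError("reference shape does not match the ensemble atoms")
    sq = np.sum((ensemble - center) ** 2, axis=2)
    return np.sqrt(sq.mean(axis=0))


def sidechain_aggregate(per_atom_rmsf: Sequence[float]) -> float | None:
    """Single sidechain RMSF: root-mean-square of the atoms' RMSF values.

    Returns None for an empty selection (glycine) — absent, not zero.
    """
    values = np.asarray(list(per_atom_rmsf), dtype=float)
    if values.size == 0:
        return None
    return float(np.sqrt(np.mean(values**2)))


def _frame_coordinates(
    frames: Sequence[Snapshot],
) -> tuple[np.ndarray, list]:
    """Stack per-frame atom coordinates, checking a consistent atom roster."""
    roster = [(a.atom_id, a.name, a.residue_number) for a in frames[0].atoms]
    coords = np.empty((len(frames), len(roster), 3), dtype=float)
    for f, snap in enumerate(frames):
        if [(a.atom_id, a.name, a.residue_number) for a in snap.atoms] != roster:
            raise ValueError(f"frame {snap.frame_index}: atom roster differs from first frame")
        coords[f] = snap.atom_positions()
    return coords, list(frames[0].atoms)


def two_pass_rmsf(
    frames: Sequence[Snapshot],
    reference: Snapshot,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    include_hydrogens: bool = False,
    label: str = "",
) -> RMSFProfile:
    """Cα + sidechain RMSF with mobile atoms excluded from the final alignment.

    Pass 1 superposes every frame onto ``reference`` using all Cα atoms and
    computes per-Cα RMSF; pass 2 repeats the superposition using only Cα
    atoms with pass-1 RMSF strictly below ``mask_threshold`` and recomputes
    Cα and sidechain RMSF from that alignment.
    """
    if mask_threshold <= 0:
        raise ValueError("mask threshold must be positive")
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    coords, atoms = _frame_coordinates(frames)
    ref_roster = {(a.atom_id, a.name, a.residue_number): a.position for a in reference.atoms}
    try:
        ref_coords = np.array(
            [ref_roster[(a.atom_id, a.name, a.residue_number)] for a in atoms], dtype=float
        )
    except KeyError as exc:
        raise ValueError(f"reference is missing ensemble atom {exc}") from exc

    names = np.array([a.name for a in atoms])
    elements = np.array([a.element.upper() for a in atoms])
    residues = np.array([a.residue_number for a in atoms], dtype=np.int64)
    ca_idx = np.flatnonzero(names == "CA")
    if len(ca_idx) < 3:
        raise ValueError("ensemble has fewer than three Cα atoms")

    def align(selection: np.ndarray) -> np.ndarray:
        aligned = np.empty_like(coords)
        for f in range(len(coords)):
            R, t, _ = superpose(coords[f, selection], ref_coords[selection])
            aligned[f] = apply_transform(coords[f], R, t)
        return aligned

    # pass 1: all Cα
    aligned1 = align(ca_idx)
    ca_rmsf1 = rmsf(aligned1[:, ca_idx])
    keep = ca_rmsf1 < mask_threshold
    mask_idx = ca_idx[keep]
    if len(mask_idx) < 3:
        raise ValueError(
            f"alignment mask degenerate: only {len(mask_idx)} Cα atoms below {mask_threshold} Å"
        )
    mask_residues = frozenset(residues[mask_idx].tolist())

    # pass 2: sub-threshold Cα only
    aligned2 = align(mask_idx)
    ca_rmsf2 = rmsf(aligned2[:, ca_idx])
    per_atom = rmsf(aligned2)

    is_hydrogen = (elements == "H") | np.char.startswith(names, "H")
    is_sidechain = ~np.isin(names, list(BACKBONE_ATOM_NAMES))
    if not include_hydrogens:
        is_sidechain &= ~is_hydrogen

    residue_numbers = residues[ca_idx]
    sc_rmsf = np.full(len(residue_numbers), np.nan)
    for i, resnum in enumerate(residue_numbers):
        sel = np.flatnonzero((residues == resnum) & is_sidechain)
        value = sidechain_aggregate(per_atom[sel])
        if value is not None:
            sc_rmsf[i] = value
    return RMSFProfile(
        residue_numbers=residue_numbers,
        ca_rmsf=ca_rmsf2,
        sidechain_rmsf=sc_rmsf,
        alignment_mask=mask_residues,
        label=label,
    )


def aggregate_profiles(profiles: Sequence[RMSFProfile]) -> AggregateProfile:
    """Residue-wise mean and sample standard deviation across RMSF profiles."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    base = profiles[0].residue_numbers
    for p in profiles[1:]:
        if not np.array_equal(p.residue_numbers, base):
            raise ValueError("profiles have mismatched residue numbering")
    ca = np.stack([p.ca_rmsf for p in profiles])
    sc = np.stack([p.sidechain_rmsf for p in profiles])
    ddof = 1 if len(profiles) > 1 else 0
    with np.errstate(invalid="ignore"):
        agg = AggregateProfile(
            residue_numbers=base.copy(),
            ca_mean=ca.mean(axis=0),
            ca_sd=ca.std(axis=0, ddof=ddof),
            sidechain_mean=sc.mean(axis=0),
            sidechain_sd=sc.std(axis=0, ddof=ddof),
            dataset_count=len(profiles),
        )
    return agg
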