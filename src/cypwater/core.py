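"""Core domain containers and geometry helpers.

Coordinates are in Ångström throughout; internal times in picoseconds
(reported in nanoseconds where the residence-correlation axes call for it).
Only orthorhombic periodic boxes are supported: the simulated systems are
cubes, and triclinic cells would complicate minimum-image distances for no
gain here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Snapshot",
    "Trajectory",
    "UnsupportedFeatureError",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_positions",
    "frames_in_interval",
    "integration_steps",
    "percent_increase",
]

#: Residue names recognised as water by default (common conventions across
#: force fields and crystallographic files).
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "TIP3", "WAT", "SPC"})

#: Backbone heavy-atom names excluded from sidechain selections.
BACKBONE_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class UnsupportedFeatureError(NotImplementedError):
    """Raised for inputs the package deliberately does not handle (e.g. triclinic boxes)."""


@dataclass(frozen=True)
class AtomRecord:
    """One non-water atom of a snapshot (protein, heme, ions)."""

    atom_id: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain: str
    position: np.ndarray  # shape (3,), Å

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.atom_id}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Snapshot:
    """A single frame: protein/heme atoms plus water oxygens with persistent ids.

    ``water_oxygens`` maps the persistent integer identity of each water
    molecule to its oxygen position.  Identities come from the input file or
    generator and are never renumbered, so set operations on them across
    frames are meaningful.
    """

    frame_index: int
    time_ps: float
    atoms: Sequence[AtomRecord] = field(default_factory=list)
    water_oxygens: Mapping[int, np.ndarray] = field(default_factory=dict)
    box: np.ndarray | None = None  # orthorhombic edge lengths (3,), Å
    fe_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.time_ps < 0:
            raise ValueError("snapshot time must be non-negative")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape != (3,) or np.any(box <= 0):
                raise ValueError("box must be three positive edge lengths")
            self.box = box
        if self.fe_position is not None:
            self.fe_position = np.asarray(self.fe_position, dtype=float)

    @property
    def n_waters(self) -> int:
        return len(self.water_oxygens)

    def water_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Water ids (sorted) and their oxygen positions as an (n, 3) array."""
        ids = np.fromiter(self.water_oxygens.keys(), dtype=np.int64, count=len(self.water_oxygens))
        order = np.argsort(ids)
        ids = ids[order]
        pos = np.empty((len(ids), 3), dtype=float)
        values = list(self.water_oxygens.values())
        for row, j in enumerate(order):
            pos[row] = values[j]
        return ids, pos

    def atom_positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)


@dataclass
class Trajectory:
    """Time-ordered snapshots sharing one persistent water-id universe."""

    snapshots: Sequence[Snapshot]
    stage_label: str = ""
    replicate_label: str = ""
    protocol_label: str = ""

    def __post_init__(self) -> None:
        times = [s.time_ps for s in self.snapshots]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("snapshot times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self) -> Iterator[Snapshot]:
        return iter(self.snapshots)

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([s.time_ps for s in self.snapshots], dtype=float)


def minimum_image_displacement(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    ``delta`` may be a single 3-vector or an (n, 3) array.  With ``box`` None
    the displacement is returned unchanged (non-periodic geometry).
    """
    delta = np.asarray(delta, dtype=float)
    if box is None:
        return delta
    box = np.asarray(box, dtype=float)
    return delta - box * np.round(delta / box)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Euclidean distance(s) between points under the minimum-image convention."""
    delta = minimum_image_displacement(np.asarray(a, float) - np.asarray(b, float), box)
    return np.linalg.norm(delta, axis=-1)


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap positions into the primary cell [0, box) along each axis."""
    positions = np.asarray(positions, dtype=float)
    box = np.asarray(box, dtype=float)
    return np.mod(positions, box)


def frames_in_interval(span_ps: float, frame_interval_ps: float) -> int:
    """Number of snapshots a sampling interval yields over a span.

    A 250 ns stage sampled every 250 ps gives 1000 snapshots.
    """
    if frame_interval_ps <= 0:
        raise ValueError("frame interval must be positive")
    n = span_ps / frame_interval_ps
    if abs(n - round(n)) > 1e-9:
        raise ValueError("span is not an integer number of frame intervals")
    return int(round(n))


def integration_steps(span_ps: float, timestep_fs: float) -> int:
    """Number of integrator steps covering a span (250 ns at 2 fs → 125e6)."""
    if timestep_fs <= 0:
        raise ValueError("timestep must be positive")
    n = span_ps * 1000.0 / timestep_fs
    if abs(n - round(n)) > 1e-6:
        raise ValueError("span is not an integer number of timesteps")
    return int(round(n))


def percent_increase(before: float, after: float) -> float:
    """Relative increase in percent, e.g. 500 → 1400 ų is 180%."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return 100.0 * (after - before) / before
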