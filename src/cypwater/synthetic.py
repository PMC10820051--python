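"""Synthetic gated-cavity trajectories with known ground truth.

The generator builds a geometric "toy enzyme": a rigid spherical shell of
pseudo-atoms (the protein wall) with an iron marker at its center, an
interior cavity packed with waters on a close lattice (hydrogen-bond
connected by construction), bulk waters on a box-commensurate lattice
outside the shell, and a single-file channel corridor of waters through a
gap in the shell that is present only when the gate is open.  Water
molecules carry persistent integer identities; when the gate is open each
cavity water is exchanged for a fresh identity with a fixed per-frame
probability, and all coordinates receive isotropic Gaussian jitter about
their base positions to emulate the flexibility stages of a restrained →
free simulation protocol.

The model is geometric and stochastic, not physical — no forces or
energies.  It exists so that every analysis (cluster connectivity, pocket
occupancy, residence correlation, RMSF) can be checked against planted
ground truth:

* gate closed → the iron-seeded cluster is exactly the cavity waters
  (isolated); gate open → the corridor joins it to the bulk (bulk-scale);
* identity exchange at known rate → closed-form residence correlation;
* iid jitter of scale σ → RMSF of σ√3 per atom.

Exchanged-in waters take over the lattice site of the water they replace,
so the geometry (and with it iron ligation and cluster connectivity) is
exactly invariant under exchange; only identities change.  This is the
right simplification for identity-based statistics and keeps the planted
connectivity class exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import AtomRecord, Snapshot, Trajectory
from .kinetics import OccupancySeries
from .pocket import AlphaSphere, Pocket

__all__ = [
    "CavityWorldConfig",
    "GroundTruth",
    "CavityWorld",
    "build_cavity_world",
    "simulate_frames",
    "staged_protocol",
    "synthetic_pocket",
    "simulate_swap_occupancy",
    "PRESETS",
]

CAVITY_LATTICE_SPACING = 2.8  # Å; below the 3.5 Å H-bond cutoff with margin
CORRIDOR_SPACING = 3.0  # Å
BULK_TARGET_SPACING = 3.0  # Å; actual spacing is box-commensurate
CHANNEL_CAP_HALF_ANGLE = math.radians(25.0)  # shell opening around +z
FE_OFFSET = 2.1  # Å between the iron and the nearest cavity-water site


@dataclass(frozen=True)
class CavityWorldConfig:
    """Geometry, kinetics and bookkeeping knobs of the synthetic world.

    Defaults mirror the bookkeeping of the emulated study design: 250 ps
    between frames and 1000 frames per stage.  ``channel_open`` is either a
    flag (gate fixed) or a per-frame open probability.
    ``solvation_deletion_radius`` emulates the initial-solvation protocols:
    waters whose oxygen starts within that distance of any shell atom are
    deleted at build time (2 or 3 Å in the emulated protocols).
    ``n_bulk_waters`` is a validation floor: bulk waters fill the lattice
    outside the shell, and construction fails if fewer than this remain.
    """

    shell_radius: float = 14.0
    shell_atom_count: int = 150
    cavity_radius: float = 6.0
    channel_open: bool | float = False
    n_cavity_waters: int = 20
    n_bulk_waters: int | None = None
    box_edge: float = 40.0
    swap_probability_per_frame: float = 0.05
    jitter_sigma: float = 0.1
    frame_interval_ps: float = 250.0
    n_frames: int = 1000
    seed: int = 0
    solvation_deletion_radius: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.cavity_radius < self.shell_radius < self.box_edge / 2):
            raise ValueError("need 0 < cavity_radius < shell_radius < box_edge/2")
        p_open = self.channel_open if isinstance(self.channel_open, float) else float(bool(self.channel_open))
        if not 0.0 <= p_open <= 1.0:
            raise ValueError("channel open probability must be in [0, 1]")
        if not 0.0 <= self.swap_probability_per_frame <= 1.0:
            raise ValueError("swap probability must be in [0, 1]")
        if self.n_cavity_waters < 1 or self.shell_atom_count < 4 or self.n_frames < 1:
            raise ValueError("counts must be positive")
        if self.jitter_sigma < 0 or self.solvation_deletion_radius < 0:
            raise ValueError("jitter and deletion radius must be non-negative")


@dataclass
class GroundTruth:
    """Planted truths recorded alongside a synthetic trajectory."""

    true_swap_probability: float
    gate_states: list[bool] = field(default_factory=list)
    cavity_occupancy: list[frozenset[int]] = field(default_factory=list)
    connectivity_class: list[str] = field(default_factory=list)  # "bulk" | "isolated"
    n_bulk_waters: int = 0
    n_corridor_waters: int = 0
    n_deleted_waters: int = 0


@dataclass
class CavityWorld:
    """Static geometry of the toy system, before per-frame stochastics."""

    atoms: list[AtomRecord]  # shell + heme iron, base positions
    fe_position: np.ndarray
    cavity_center: np.ndarray
    cavity_sites: np.ndarray  # (n_cavity, 3) base positions
    corridor_positions: np.ndarray  # (n_corridor, 3)
    bulk_positions: np.ndarray  # (n_bulk, 3)
    box: np.ndarray
    cavity_ids: list[int]  # initial occupant id per cavity site
    corridor_ids: list[int]
    bulk_ids: list[int]
    next_water_id: int
    n_deleted: int


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _cubic_lattice(spacing: float, half_extent: float) -> np.ndarray:
    m = int(math.floor(half_extent / spacing))
    axis = np.arange(-m, m + 1, dtype=float) * spacing
    grid = np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T
    return grid


def build_cavity_world(config: CavityWorldConfig) -> tuple[CavityWorld, Snapshot]:
    """Construct the static world geometry and its first (unjittered) frame.

    All positions are generated around the box center.  The shell is a
    sphere of pseudo-residues (one CA and one CB atom each) with a polar cap
    left open as the channel mouth; the iron sits at the shell center with
    the nearest cavity-water site 2.1 Å away, so that water ligates the iron
    by construction.
    """
    rng = np.random.default_rng(config.seed)
    center = np.full(3, config.box_edge / 2.0)
    box = np.full(3, config.box_edge)

    # shell pseudo-protein with a channel mouth at +z
    directions = _fibonacci_sphere(config.shell_atom_count)
    keep = directions[:, 2] < math.cos(CHANNEL_CAP_HALF_ANGLE)
    directions = directions[keep]
    atoms: list[AtomRecord] = []
    atom_id = 1
    for resnum, d in enumerate(directions, start=1):
        for name, radius in (("CA", config.shell_radius), ("CB", config.shell_radius + 1.8)):
            atoms.append(
                AtomRecord(
                    atom_id=atom_id,
                    name=name,
                    element="C",
                    residue_number=resnum,
                    residue_name="SHL",
                    chain="A",
                    position=center + d * radius,
                )
            )
            atom_id += 1
    fe_position = center.copy()
    heme_resnum = len(directions) + 1
    atoms.append(
        AtomRecord(
            atom_id=atom_id,
            name="FE",
            element="FE",
            residue_number=heme_resnum,
            residue_name="HEM",
            chain="A",
            position=fe_position,
        )
    )

    # cavity waters: lattice ball around the cavity center, nearest sites first.
    # The site one lattice step up the channel axis is always included so the
    # corridor can dock onto the cluster regardless of the occupant count.
    cavity_center = center + np.array([0.0, 0.0, FE_OFFSET])
    sites = cavity_center + _cubic_lattice(CAVITY_LATTICE_SPACING, config.cavity_radius)
    dist = np.linalg.norm(sites - cavity_center, axis=1)
    sites = sites[dist <= config.cavity_radius]
    order = np.argsort(np.linalg.norm(sites - cavity_center, axis=1), kind="stable")
    sites = sites[order]
    if len(sites) < config.n_cavity_waters:
        raise ValueError(
            f"infeasible packing: cavity of radius {config.cavity_radius} Å holds at most "
            f"{len(sites)} waters, {config.n_cavity_waters} requested"
        )
    axis_site = np.argmin(
        np.linalg.norm(sites - (cavity_center + [0.0, 0.0, CAVITY_LATTICE_SPACING]), axis=1)
    )
    if axis_site >= config.n_cavity_waters and config.n_cavity_waters >= 2:
        sites[[1, axis_site]] = sites[[axis_site, 1]]
    cavity_sites = sites[: config.n_cavity_waters]

    # channel corridor along +z: docks onto the axis cavity site and runs out
    # past the shell into the bulk lattice
    z_targets = np.arange(
        FE_OFFSET + CAVITY_LATTICE_SPACING + CORRIDOR_SPACING,
        config.shell_radius + BULK_TARGET_SPACING + CORRIDOR_SPACING,
        CORRIDOR_SPACING,
    )
    corridor_positions = center + np.column_stack(
        [np.zeros_like(z_targets), np.zeros_like(z_targets), z_targets]
    )

    # bulk waters: box-commensurate lattice outside the shell
    m = max(1, round(config.box_edge / BULK_TARGET_SPACING))
    spacing = config.box_edge / m
    axis = (np.arange(m) + 0.5) * spacing
    grid = np.array(np.meshgrid(axis, axis, axis, indexing="ij")).reshape(3, -1).T
    outside = np.linalg.norm(grid - center, axis=1) > config.shell_radius + 1.0
    bulk_positions = grid[outside]
    bulk_positions = bulk_positions + rng.normal(0.0, 0.15, size=bulk_positions.shape)

    # solvation-protocol emulation: delete waters too close to the protein wall
    shell_positions = np.array([a.position for a in atoms if a.residue_name == "SHL"])
    n_before = len(bulk_positions) + len(corridor_positions) + len(cavity_sites)

    def survives(points: np.ndarray) -> np.ndarray:
        if config.solvation_deletion_radius == 0 or len(points) == 0:
            return np.ones(len(points), dtype=bool)
        from scipy.spatial import cKDTree

        tree = cKDTree(shell_positions)
        d, _ = tree.query(points, k=1)
        return d > config.solvation_deletion_radius

    bulk_positions = bulk_positions[survives(bulk_positions)]
    corridor_positions = corridor_positions[survives(corridor_positions)]
    cavity_keep = survives(cavity_sites)
    if not cavity_keep[0]:
        raise ValueError("infeasible geometry: the iron-ligated water site was deleted")
    cavity_sites = cavity_sites[cavity_keep]
    n_deleted = n_before - (len(bulk_positions) + len(corridor_positions) + len(cavity_sites))

    if config.n_bulk_waters is not None and len(bulk_positions) < config.n_bulk_waters:
        raise ValueError(
            f"infeasible packing: only {len(bulk_positions)} bulk lattice sites available, "
            f"{config.n_bulk_waters} required"
        )

    next_id = 1
    cavity_ids = list(range(next_id, next_id + len(cavity_sites)))
    next_id += len(cavity_sites)
    corridor_ids = list(range(next_id, next_id + len(corridor_positions)))
    next_id += len(corridor_positions)
    bulk_ids = list(range(next_id, next_id + len(bulk_positions)))
    next_id += len(bulk_positions)

    world = CavityWorld(
        atoms=atoms,
        fe_position=fe_position,
        cavity_center=cavity_center,
        cavity_sites=cavity_sites,
        corridor_positions=corridor_positions,
        bulk_positions=bulk_positions,
        box=box,
        cavity_ids=cavity_ids,
        corridor_ids=corridor_ids,
        bulk_ids=bulk_ids,
        next_water_id=next_id,
        n_deleted=n_deleted,
    )
    first = _make_snapshot(world, config, frame_index=0, time_ps=0.0, gate_open=_gate(config, rng), rng=None)
    return world, first


def _gate(config: CavityWorldConfig, rng: np.random.Generator) -> bool:
    if isinstance(config.channel_open, bool):
        return config.channel_open
    return bool(rng.random() < config.channel_open)


def _make_snapshot(
    world: CavityWorld,
    config: CavityWorldConfig,
    frame_index: int,
    time_ps: float,
    gate_open: bool,
    rng: np.random.Generator | None,
) -> Snapshot:
    """Assemble one frame from base geometry plus optional Gaussian jitter."""

    def jitter(points: np.ndarray) -> np.ndarray:
        if rng is None or config.jitter_sigma == 0:
            return np.array(points, dtype=float, copy=True)
        return points + rng.normal(0.0, config.jitter_sigma, size=points.shape)

    atom_base = np.array([a.position for a in world.atoms])
    atom_pos = jitter(atom_base)
    atoms = [replace(a, position=atom_pos[i]) for i, a in enumerate(world.atoms)]
    fe_position = atom_pos[-1]  # heme iron is the last atom

    waters: dict[int, np.ndarray] = {}
    cav = jitter(world.cavity_sites)
    for wid, p in zip(world.cavity_ids, cav):
        waters[wid] = p
    if gate_open and len(world.corridor_positions):
        cor = jitter(world.corridor_positions)
        for wid, p in zip(world.corridor_ids, cor):
            waters[wid] = p
    blk = jitter(world.bulk_positions)
    for wid, p in zip(world.bulk_ids, blk):
        waters[wid] = p

    return Snapshot(
        frame_index=frame_index,
        time_ps=time_ps,
        atoms=atoms,
        water_oxygens=waters,
        box=world.box.copy(),
        fe_position=fe_position,
    )


def simulate_frames(
    config: CavityWorldConfig,
    world: CavityWorld | None = None,
    start_frame: int = 0,
    start_time_ps: float = 0.0,
    stage_label: str = "",
    replicate_label: str = "",
    protocol_label: str = "",
) -> tuple[Trajectory, GroundTruth]:
    """Run the stochastic frame process over the static world.

    Per frame: the gate state is drawn (or fixed), each cavity occupant is
    exchanged for a fresh identity with the swap probability *only while the
    gate is open*, and every coordinate is jittered independently about its
    base position.  Passing ``world`` continues an existing id universe
    (used by :func:`staged_protocol` for successive stages).
    """
    rng = np.random.default_rng(config.seed)
    if world is None:
        world, _ = build_cavity_world(config)

    truth = GroundTruth(
        true_swap_probability=config.swap_probability_per_frame,
        n_bulk_waters=len(world.bulk_ids),
        n_corridor_waters=len(world.corridor_ids),
        n_deleted_waters=world.n_deleted,
    )
    snapshots: list[Snapshot] = []
    for f in range(config.n_frames):
        gate_open = _gate(config, rng)
        if gate_open and config.swap_probability_per_frame > 0:
            swap = rng.random(len(world.cavity_ids)) < config.swap_probability_per_frame
            for i in np.flatnonzero(swap):
                world.cavity_ids[i] = world.next_water_id
                world.next_water_id += 1
        snap = _make_snapshot(
            world,
            config,
            frame_index=start_frame + f,
            time_ps=start_time_ps + f * config.frame_interval_ps,
            gate_open=gate_open,
            rng=rng,
        )
        snapshots.append(snap)
        truth.gate_states.append(gate_open)
        truth.cavity_occupancy.append(frozenset(world.cavity_ids))
        truth.connectivity_class.append("bulk" if gate_open else "isolated")
    trajectory = Trajectory(
        snapshots=snapshots,
        stage_label=stage_label,
        replicate_label=replicate_label,
        protocol_label=protocol_label,
    )
    return trajectory, truth


@dataclass(frozen=True)
class StageSpec:
    """One stage of a staged-flexibility protocol."""

    label: str
    channel_open: bool | float
    swap_probability: float
    jitter_sigma: float


#: Preset staged protocols emulating the qualitative phenomenology of the
#: three isoforms: "1A2-like" has a sealed binding site until sidechain
#: flexibility opens a channel; "2D6-like"/"3A4-like" are open throughout
#: with occasional closures once fully flexible.
PRESETS: dict[str, tuple[StageSpec, ...]] = {
    "1A2-like": (
        StageSpec("Stage 1", False, 0.08, 0.03),
        StageSpec("Stage 2", False, 0.08, 0.05),
        StageSpec("Stage 3", 0.3, 0.08, 0.08),
        StageSpec("Stage 4.1", True, 0.12, 0.1),
        StageSpec("Stage 4.2", True, 0.12, 0.1),
    ),
    "2D6-like": (
        StageSpec("Stage 1", True, 0.02, 0.03),
        StageSpec("Stage 2", True, 0.03, 0.05),
        StageSpec("Stage 3", True, 0.05, 0.08),
        StageSpec("Stage 4.1", 0.85, 0.10, 0.1),
        StageSpec("Stage 4.2", 0.85, 0.12, 0.1),
    ),
    "3A4-like": (
        StageSpec("Stage 1", True, 0.03, 0.03),
        StageSpec("Stage 2", True, 0.04, 0.05),
        StageSpec("Stage 3", True, 0.06, 0.08),
        StageSpec("Stage 4.1", 0.9, 0.12, 0.1),
        StageSpec("Stage 4.2", 0.9, 0.14, 0.1),
    ),
}


def staged_protocol(
    config: CavityWorldConfig,
    stages: Sequence[StageSpec] | str = "1A2-like",
    replicate_label: str = "run1",
    protocol_label: str = "2A",
) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Generate the five successive stages of a staged-flexibility protocol.

    Stages share one world (continuous time, one water-id universe carried
    across stage boundaries); per-stage gate behaviour, exchange rate and
    jitter come from the stage specs or a named preset.
    """
    if isinstance(stages, str):
        stages = PRESETS[stages]
    world, _ = build_cavity_world(config)
    trajectories: list[Trajectory] = []
    truths: list[GroundTruth] = []
    frame0 = 0
    for s, spec in enumerate(stages):
        stage_config = replace(
            config,
            channel_open=spec.channel_open,
            swap_probability_per_frame=spec.swap_probability,
            jitter_sigma=spec.jitter_sigma,
            seed=(config.seed * 1000003 + s * 7919) % (2**31),
        )
        traj, truth = simulate_frames(
            stage_config,
            world=world,
            start_frame=frame0,
            start_time_ps=frame0 * config.frame_interval_ps,
            stage_label=spec.label,
            replicate_label=replicate_label,
            protocol_label=protocol_label,
        )
        trajectories.append(traj)
        truths.append(truth)
        frame0 += stage_config.n_frames
    return trajectories, truths


def synthetic_pocket(world: CavityWorld, n_spheres: int = 4) -> Pocket:
    """Alpha-sphere pocket covering the cavity, for occupancy analyses.

    A central sphere covers all cavity lattice sites (with a 0.5 Å jitter
    margin that still leaves the first corridor water outside); the remaining
    spheres tile the interior at half radius, mimicking the multi-sphere
    pockets real detectors emit.  Pocket occupancy therefore equals cavity
    occupancy at small jitter.
    """
    spheres = [AlphaSphere(center=world.cavity_center, radius=float(np.max(
        np.linalg.norm(world.cavity_sites - world.cavity_center, axis=1)) + 0.5))]
    offsets = _fibonacci_sphere(max(0, n_spheres - 1)) * (spheres[0].radius / 2.0)
    for off in offsets:
        spheres.append(AlphaSphere(center=world.cavity_center + off, radius=spheres[0].radius / 2.0))
    return Pocket(pocket_id=1, spheres=spheres)


def simulate_swap_occupancy(
    n_waters: int,
    swap_probability: float,
    n_frames: int,
    frame_interval_ps: float = 250.0,
    seed: int = 0,
    stage_label: str = "",
    replicate_label: str = "",
) -> OccupancySeries:
    """Pure identity-exchange occupancy series (no geometry).

    A pocket of constant size ``n_waters`` whose occupants are each replaced
    by a fresh identity with probability ``swap_probability`` per frame.
    Under this model the expected residence correlation at lag k frames is
    q/(2−q) with q = (1−p)^k, and the exchange rate is −ln(1−p) per frame —
    the closed forms used for parameter-recovery checks.
    """
    if n_waters < 1 or n_frames < 1:
        raise ValueError("counts must be positive")
    if not 0.0 <= swap_probability <= 1.0:
        raise ValueError("swap probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    occupants = list(range(1, n_waters + 1))
    next_id = n_waters + 1
    sets = [frozenset(occupants)]
    for _ in range(n_frames - 1):
        swap = rng.random(n_waters) < swap_probability
        for i in np.flatnonzero(swap):
            occupants[i] = next_id
            next_id += 1
        sets.append(frozenset(occupants))
    times = np.arange(n_frames, dtype=float) * frame_interval_ps
    return OccupancySeries(
        times_ps=times, occupants=sets, stage_label=stage_label, replicate_label=replicate_label
    )
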