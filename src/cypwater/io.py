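"""Readers and writers for on-disk formats.

Three input formats are handled:

* **PDB** single frames (wwPDB v3.3 ATOM/HETATM columns), read through
  Bio.PDB.  Waters are recognised by residue name and carried as persistent
  ids keyed by their residue sequence number; the heme iron is located by
  element.
* **Fixture trajectories** — a small line-oriented plain-text format for
  multi-frame protein+water coordinate sets with persistent water ids.  It
  exists so synthetic trajectories and hand-built test cases can be stored
  and round-tripped exactly::

      cypwater-trajectory 1
      box 44.0 44.0 44.0        # or: box none
      stage Stage 1
      replicate run1
      protocol 2A
      frame 0 0.000000          # frame index, time in ps
      fe 22.000000 22.000000 24.100000
      atom 1 CA C 1 SHL A 10.000000 0.000000 0.000000
      water 101 1.000000 2.000000 3.000000
      endframe

  Blank lines and ``#`` comments are ignored.  Floats are written with six
  decimals, so write → read → write is byte-identical.
* **fpocket pocket files** in the ``*_pockets.pqr`` dialect: one ATOM/HETATM
  line per alpha sphere with the sphere center in the coordinate fields, the
  pocket index in the residue-number field, and the sphere radius as the
  final numeric field.

Results are written as CSV (pandas) and JSON.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException, PDBConstructionWarning

from .core import (
    DEFAULT_WATER_RESNAMES,
    AtomRecord,
    Snapshot,
    Trajectory,
    UnsupportedFeatureError,
)
from .pocket import AlphaSphere, Pocket

logger = logging.getLogger(__name__)

__all__ = [
    "PDBReadError",
    "FixtureFormatError",
    "FpocketFormatError",
    "read_pdb",
    "read_fixture_trajectory",
    "write_fixture_trajectory",
    "read_fpocket_pockets",
    "write_json",
]

HEME_RESNAMES = frozenset({"HEM", "HEC", "HEA", "HEB", "HEME"})


class PDBReadError(ValueError):
    """Raised when a PDB file cannot be read into a snapshot."""


class FixtureFormatError(ValueError):
    """Raised on malformed fixture-trajectory files."""


class FpocketFormatError(ValueError):
    """Raised on malformed fpocket pocket-PQR files."""


def read_pdb(
    path: str | Path,
    water_resnames: Iterable[str] = DEFAULT_WATER_RESNAMES,
    frame_index: int = 0,
    time_ps: float = 0.0,
) -> Snapshot:
    """Read one PDB file into a :class:`Snapshot`.

    Water molecules are identified by residue name (default set covers
    HOH/TIP3/WAT/SPC); their persistent id is the residue sequence number.
    The heme iron is the first atom with element FE, preferring atoms inside
    heme residues.  Non-coordinate records are ignored; discarded water
    hydrogens are tallied in the log so atom counts can be audited.
    """
    path = Path(path)
    water_resnames = {r.upper() for r in water_resnames}
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except PDBConstructionException as exc:  # message names the offending line
        raise PDBReadError(f"{path}: {exc}") from exc

    atoms: list[AtomRecord] = []
    water_oxygens: dict[int, np.ndarray] = {}
    fe_position: np.ndarray | None = None
    fe_in_heme = False
    n_water_non_oxygen = 0

    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip().upper()
                resseq = residue.get_id()[1]
                is_water = resname in water_resnames
                for atom in residue:
                    element = (atom.element or "").strip().upper()
                    if is_water:
                        if element == "O" or atom.get_name().startswith("O"):
                            if resseq in water_oxygens:
                                raise PDBReadError(
                                    f"{path}: duplicate water residue number {resseq}; "
                                    "persistent water ids must be unique"
                                )
                            water_oxygens[resseq] = np.array(atom.coord, dtype=float)
                        else:
                            n_water_non_oxygen += 1
                        continue
                    atoms.append(
                        AtomRecord(
                            atom_id=atom.serial_number,
                            name=atom.get_name(),
                            element=element,
                            residue_number=resseq,
                            residue_name=resname,
                            chain=chain.id,
                            position=np.array(atom.coord, dtype=float),
                        )
                    )
                    if element == "FE" and (fe_position is None or not fe_in_heme):
                        fe_position = np.array(atom.coord, dtype=float)
                        fe_in_heme = resname in HEME_RESNAMES
        break  # first model only

    if not atoms and not water_oxygens:
        raise PDBReadError(f"{path}: no ATOM/HETATM records found")
    if n_water_non_oxygen:
        logger.info(
            "%s: discarded %d non-oxygen water atoms (water identity is carried by the oxygen)",
            path,
            n_water_non_oxygen,
        )
    return Snapshot(
        frame_index=frame_index,
        time_ps=time_ps,
        atoms=atoms,
        water_oxygens=water_oxygens,
        box=None,
        fe_position=fe_position,
    )


# ---------------------------------------------------------------------------
# fixture trajectory format
# ---------------------------------------------------------------------------

_MAGIC = "cypwater-trajectory 1"


def _fmt(x: float) -> str:
    return f"{float(x):.6f}"


def write_fixture_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the fixture format (see module docstring)."""
    path = Path(path)
    lines: list[str] = [_MAGIC]
    box = trajectory.snapshots[0].box if trajectory.snapshots else None
    if box is None:
        lines.append("box none")
    else:
        lines.append("box " + " ".join(_fmt(e) for e in box))
    lines.append(f"stage {trajectory.stage_label}")
    lines.append(f"replicate {trajectory.replicate_label}")
    lines.append(f"protocol {trajectory.protocol_label}")
    for snap in trajectory.snapshots:
        lines.append(f"frame {snap.frame_index} {_fmt(snap.time_ps)}")
        if snap.fe_position is not None:
            lines.append("fe " + " ".join(_fmt(c) for c in snap.fe_position))
        for atom in snap.atoms:
            lines.append(
                f"atom {atom.atom_id} {atom.name} {atom.element} "
                f"{atom.residue_number} {atom.residue_name} {atom.chain} "
                + " ".join(_fmt(c) for c in atom.position)
            )
        for wid in sorted(snap.water_oxygens):
            lines.append(f"water {wid} " + " ".join(_fmt(c) for c in snap.water_oxygens[wid]))
        lines.append("endframe")
    path.write_text("\n".join(lines) + "\n")


def read_fixture_trajectory(path: str | Path) -> Trajectory:
    """Read a fixture-format trajectory; exact inverse of the writer."""
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    lines: list[tuple[int, str]] = [
        (i + 1, ln.strip()) for i, ln in enumerate(raw_lines) if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines or lines[0][1] != _MAGIC:
        raise FixtureFormatError(f"{path}: missing '{_MAGIC}' header")

    box: np.ndarray | None = None
    stage = replicate = protocol = ""
    snapshots: list[Snapshot] = []
    frame: dict | None = None
    last_time = -np.inf

    def finish_frame() -> None:
        nonlocal frame
        if frame is None:
            return
        snapshots.append(
            Snapshot(
                frame_index=frame["index"],
                time_ps=frame["time"],
                atoms=frame["atoms"],
                water_oxygens=frame["waters"],
                box=box,
                fe_position=frame["fe"],
            )
        )
        frame = None

    for lineno, line in lines[1:]:
        fields = line.split()
        tag = fields[0]
        try:
            if tag == "box":
                box = None if fields[1] == "none" else np.array([float(f) for f in fields[1:4]])
                if box is not None and len(fields) > 4:
                    raise UnsupportedFeatureError("triclinic boxes are not supported")
            elif tag == "stage":
                stage = line[len("stage ") :] if len(fields) > 1 else ""
            elif tag == "replicate":
                replicate = line[len("replicate ") :] if len(fields) > 1 else ""
            elif tag == "protocol":
                protocol = line[len("protocol ") :] if len(fields) > 1 else ""
            elif tag == "frame":
                if frame is not None:
                    raise FixtureFormatError(f"{path}:{lineno}: 'frame' before previous 'endframe'")
                t = float(fields[2])
                if t <= last_time:
                    raise FixtureFormatError(f"{path}:{lineno}: non-monotone frame time {t}")
                last_time = t
                frame = {"index": int(fields[1]), "time": t, "atoms": [], "waters": {}, "fe": None}
            elif tag == "fe":
                frame["fe"] = np.array([float(f) for f in fields[1:4]])
            elif tag == "atom":
                frame["atoms"].append(
                    AtomRecord(
                        atom_id=int(fields[1]),
                        name=fields[2],
                        element=fields[3],
                        residue_number=int(fields[4]),
                        residue_name=fields[5],
                        chain=fields[6],
                        position=np.array([float(f) for f in fields[7:10]]),
                    )
                )
            elif tag == "water":
                wid = int(fields[1])
                if wid in frame["waters"]:
                    raise FixtureFormatError(f"{path}:{lineno}: duplicate water id {wid} in frame")
                frame["waters"][wid] = np.array([float(f) for f in fields[2:5]])
            elif tag == "endframe":
                finish_frame()
            else:
                raise FixtureFormatError(f"{path}:{lineno}: unknown record '{tag}'")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, (FixtureFormatError, UnsupportedFeatureError)):
                raise
            raise FixtureFormatError(f"{path}:{lineno}: malformed '{tag}' record: {line!r}") from exc
        except TypeError as exc:  # record outside a frame block
            raise FixtureFormatError(f"{path}:{lineno}: '{tag}' record outside a frame block") from exc

    if frame is not None:
        raise FixtureFormatError(f"{path}: trailing frame without 'endframe'")
    return Trajectory(
        snapshots=snapshots, stage_label=stage, replicate_label=replicate, protocol_label=protocol
    )


# ---------------------------------------------------------------------------
# fpocket pocket PQR dialect
# ---------------------------------------------------------------------------


def read_fpocket_pockets(path: str | Path) -> list[Pocket]:
    """Parse alpha spheres from an fpocket ``*_pockets.pqr`` file (or a
    directory containing exactly one).

    Each ATOM/HETATM line carries one alpha sphere: center in the coordinate
    fields, pocket index in the residue-number field, radius as the final
    numeric field.  Pockets announced (via HEADER lines or residue numbers)
    but containing no spheres are skipped with a warning.
    """
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.glob("*_pockets.pqr")) or sorted(path.glob("*.pqr"))
        if len(candidates) != 1:
            raise FpocketFormatError(
                f"{path}: expected exactly one pocket PQR file, found {len(candidates)}"
            )
        path = candidates[0]

    spheres_by_pocket: dict[int, list[AlphaSphere]] = {}
    announced: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("HEADER") and "Pocket" in line:
            for tok in line.split():
                if tok.isdigit():
                    announced.append(int(tok))
                    break
            continue
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        fields = line.split()
        if len(fields) < 10:
            raise FpocketFormatError(
                f"{path}:{lineno}: too few fields (radius missing?): {line!r}"
            )
        try:
            # record serial name resname [chain] resseq x y z charge radius
            radius = float(fields[-1])
            x, y, z = (float(f) for f in fields[-5:-2])
            # locate the residue number: last integer field before coordinates
            int_fields = [f for f in fields[3:-5] if f.lstrip("-").isdigit()]
            pocket_id = int(int_fields[-1]) if int_fields else 1
        except (ValueError, IndexError) as exc:
            raise FpocketFormatError(f"{path}:{lineno}: malformed alpha-sphere line: {line!r}") from exc
        if radius <= 0:
            raise FpocketFormatError(f"{path}:{lineno}: non-positive alpha-sphere radius {radius}")
        spheres_by_pocket.setdefault(pocket_id, []).append(
            AlphaSphere(center=np.array([x, y, z]), radius=radius)
        )

    for pid in announced:
        if pid not in spheres_by_pocket:
            logger.warning("%s: pocket %d announced but contains no alpha spheres; skipped", path, pid)
    if not spheres_by_pocket:
        raise FpocketFormatError(f"{path}: no alpha-sphere records found")
    return [
        Pocket(pocket_id=pid, spheres=spheres)
        for pid, spheres in sorted(spheres_by_pocket.items())
    ]


def write_json(obj: object, path: str | Path) -> None:
    """Write a JSON document, converting numpy scalars/arrays transparently."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_csv(frame: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
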