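"""Shared fixtures: tiny PDB/PQR text builders and small synthetic worlds."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from cypwater.synthetic import CavityWorldConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    element: str,
    record: str = "ATOM",
) -> str:
    """One correctly column-aligned PDB ATOM/HETATM line."""
    name_field = f" {name:<3}" if len(name) < 4 else f"{name:<4}"
    return (
        f"{record:<6}{serial:>5} {name_field} {resname:>3} {chain}{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2}"
    )


@pytest.fixture
def write_pdb(tmp_path):
    def _write(lines: list[str], name: str = "test.pdb"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


@pytest.fixture
def small_world_config():
    """A reduced gated-cavity world: quick to simulate, still percolating.

    The bulk region holds a few hundred waters, so bulk classification in
    tests built on this fixture uses a threshold of 100 — far inside the
    gap between the isolated-cavity scale (~10) and the bulk scale (~500).
    """
    return CavityWorldConfig(
        shell_radius=9.0,
        shell_atom_count=80,
        cavity_radius=4.5,
        n_cavity_waters=8,
        box_edge=26.0,
        jitter_sigma=0.05,
        frame_interval_ps=250.0,
        n_frames=20,
        seed=11,
    )


SMALL_BULK_THRESHOLD = 100


@pytest.fixture
def fpocket_pqr_text():
    """Hand-written pocket file in the fpocket *_pockets.pqr dialect.

    Synthetic stand-in for real fpocket output (the tool is not run here);
    radii lie inside fpocket's default alpha-sphere bounds of 3.0-6.0 Å.
    """
    return "\n".join(
        [
            "HEADER 0 - Pocket 1 :",
            "ATOM      1  APOL STP     1      10.000  10.000  10.000  0.00  3.20",
            "ATOM      2  APOL STP     1      12.500  10.000  10.000  0.00  4.10",
            "ATOM      3   POL STP     1      11.000  12.000  10.000  0.00  3.60",
            "HEADER 5 - Pocket 2 :",
            "ATOM      4  APOL STP     2      40.000  40.000  40.000  0.00  5.50",
            "ATOM      5  APOL STP     2      43.000  40.000  40.000  0.00  3.00",
            "ATOM      6   POL STP     2      40.000  43.000  40.000  0.00  4.80",
            "ATOM      7  APOL STP     2      41.500  41.500  42.000  0.00  3.40",
            "TER",
            "END",
        ]
    )
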