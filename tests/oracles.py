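"""Independent reference implementations used only to check the package.

These deliberately use different algorithms and libraries from the
implementation under test: all-pairs distance matrices + networkx for
connected components, per-sphere python loops for pocket membership, and
the Horn quaternion method for rigid superposition.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def brute_force_cluster(
    ids: np.ndarray,
    positions: np.ndarray,
    seeds: set[int],
    cutoff: float,
    box: np.ndarray | None = None,
) -> set[int]:
    """Union of connected components containing seeds, via an all-pairs graph."""
    n = len(ids)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        delta = positions - positions[i]
        if box is not None:
            delta = delta - box * np.round(delta / box)
        dist = np.linalg.norm(delta, axis=1)
        for j in range(i + 1, n):
            if dist[j] <= cutoff:
                graph.add_edge(i, j)
    index_of = {int(w): k for k, w in enumerate(ids)}
    members: set[int] = set()
    for comp in nx.connected_components(graph):
        if any(index_of[s] in comp for s in seeds):
            members |= {int(ids[k]) for k in comp}
    return members


def brute_force_pocket_membership(
    ids: np.ndarray,
    positions: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
) -> set[int]:
    """Per-water, per-sphere containment check (no vectorisation tricks)."""
    members = set()
    for wid, pos in zip(ids, positions):
        for center, radius in zip(centers, radii):
            if np.sqrt(np.sum((pos - center) ** 2)) <= radius:
                members.add(int(wid))
                break
    return members


def quaternion_superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal-superposition RMSD via Horn's quaternion eigenvalue method."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)
    M = mob.T @ ref
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam_max = np.linalg.eigvalsh(K)[-1]
    n = len(mob)
    sq = (np.sum(mob**2) + np.sum(ref**2) - 2.0 * lam_max) / n
    return float(np.sqrt(max(sq, 0.0)))


def sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * np.pi * r**3


def two_sphere_union_volume(r1: float, r2: float, d: float) -> float:
    """Closed-form union volume of two spheres (lens-overlap formula)."""
    if d >= r1 + r2:
        return sphere_volume(r1) + sphere_volume(r2)
    if d <= abs(r1 - r2):
        return sphere_volume(max(r1, r2))
    lens = (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )
    return sphere_volume(r1) + sphere_volume(r2) - lens
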