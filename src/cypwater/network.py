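"""Iron-seeded hydrogen-bond water clusters and bulk-connectivity classification.

For each frame, waters form a graph whose edges are oxygen–oxygen contacts
within a distance cutoff (default 3.5 Å) — a purely geometric hydrogen-bond
criterion with no angle term.  The binding-site water cluster is the union of
connected components containing any water ligated to the heme iron (oxygen
within 3.5 Å of Fe).  A frame whose seed cluster is large enough to merge
with the bulk solvent is classified bulk-connected; observed cluster-size
distributions are strongly bimodal (isolated clusters of at most a few tens
of waters versus bulk components of many thousands), so any threshold inside
the gap gives the same classification.  The default threshold is 1000.

When a periodic box is present, adjacency uses minimum-image distances:
bulk water spans the periodic cell, and without imaging the bulk component
would be artificially fragmented at the box faces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import Snapshot, Trajectory, minimum_image_distance, wrap_positions

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterResult",
    "BulkRatioSummary",
    "find_iron_ligated_waters",
    "water_cluster",
    "classify_bulk",
    "bulk_connected_ratio",
]

DEFAULT_LIGATION_CUTOFF = 3.5  # Å, oxygen–iron
DEFAULT_HBOND_CUTOFF = 3.5  # Å, oxygen–oxygen
DEFAULT_BULK_THRESHOLD = 1000  # waters


@dataclass
class ClusterResult:
    """The iron-seeded water cluster of one frame."""

    frame_index: int
    seed_water_ids: frozenset[int]
    member_ids: frozenset[int]
    bulk_connected: bool = False

    def __post_init__(self) -> None:
        if self.seed_water_ids and not self.seed_water_ids <= self.member_ids:
            raise ValueError("seed waters must be members of their own cluster")

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class BulkRatioSummary:
    """Per-stage fraction of bulk-connected frames, summarised across replicates."""

    stage_label: str
    per_replicate_ratios: tuple[float, ...]
    mean: float
    sd: float


def find_iron_ligated_waters(
    snapshot: Snapshot, cutoff: float = DEFAULT_LIGATION_CUTOFF
) -> set[int]:
    """Waters whose oxygen is within ``cutoff`` of the heme iron.

    Uses minimum-image distances when the snapshot has a box.  May be empty:
    rarely a frame lacks a ligated water (the restrained early frames of some
    trajectories), and callers treat that as an empty, non-bulk cluster.
    """
    if snapshot.fe_position is None:
        raise ValueError("snapshot has no iron position")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ids, pos = snapshot.water_arrays()
    if len(ids) == 0:
        return set()
    dist = minimum_image_distance(pos, snapshot.fe_position, snapshot.box)
    return set(ids[dist <= cutoff].tolist())


def water_cluster(
    snapshot: Snapshot,
    seeds: set[int],
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
) -> ClusterResult:
    """Union of hydrogen-bond connected components containing any seed water.

    Adjacency is O–O distance ≤ ``hbond_cutoff`` over *all* waters in the
    system, periodic when the snapshot has a box.  Pair search uses a k-d
    tree (near-linear at liquid density); the result equals brute-force
    transitive closure.  Empty seed set → empty cluster.
    """
    if hbond_cutoff <= 0:
        raise ValueError("hbond cutoff must be positive")
    ids, pos = snapshot.water_arrays()
    id_set = set(ids.tolist())
    unknown = set(seeds) - id_set
    if unknown:
        raise KeyError(f"seed ids not present in frame: {sorted(unknown)}")
    if not seeds:
        return ClusterResult(
            frame_index=snapshot.frame_index,
            seed_water_ids=frozenset(),
            member_ids=frozenset(),
        )

    if snapshot.box is not None:
        tree = cKDTree(wrap_positions(pos, snapshot.box), boxsize=snapshot.box)
    else:
        tree = cKDTree(pos)
    pairs = tree.query_pairs(hbond_cutoff, output_type="ndarray")
    n = len(ids)
    if len(pairs):
        data = np.ones(len(pairs), dtype=np.int8)
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    index_of = {int(w): i for i, w in enumerate(ids)}
    seed_labels = {labels[index_of[s]] for s in seeds}
    members = frozenset(ids[np.isin(labels, list(seed_labels))].tolist())
    return ClusterResult(
        frame_index=snapshot.frame_index,
        seed_water_ids=frozenset(seeds),
        member_ids=members,
    )


def classify_bulk(cluster: ClusterResult, threshold: int = DEFAULT_BULK_THRESHOLD) -> bool:
    """Bulk-connected iff the seed cluster reaches ``threshold`` waters."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    cluster.bulk_connected = cluster.size >= threshold
    return cluster.bulk_connected


def frame_cluster(
    snapshot: Snapshot,
    ligation_cutoff: float = DEFAULT_LIGATION_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
    bulk_threshold: int = DEFAULT_BULK_THRESHOLD,
) -> ClusterResult:
    """Full per-frame pipeline: find seeds, grow the cluster, classify bulk."""
    seeds = find_iron_ligated_waters(snapshot, cutoff=ligation_cutoff)
    if not seeds:
        logger.warning(
            "frame %d: no iron-ligated water within %.2f Å; cluster size 0",
            snapshot.frame_index,
            ligation_cutoff,
        )
    result = water_cluster(snapshot, seeds, hbond_cutoff=hbond_cutoff)
    classify_bulk(result, threshold=bulk_threshold)
    return result


def bulk_connected_ratio(
    trajectories: Sequence[Trajectory],
    ligation_cutoff: float = DEFAULT_LIGATION_CUTOFF,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
    bulk_threshold: int = DEFAULT_BULK_THRESHOLD,
) -> BulkRatioSummary:
    """Fraction of bulk-connected frames per replicate, averaged across replicates.

    All trajectories must belong to the same stage; the ratio is computed per
    replicate, then the mean and sample standard deviation are taken across
    replicates (sd is 0 for a single replicate).
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    ratios: list[float] = []
    for traj in trajectories:
        if len(traj) == 0:
            raise ValueError(f"empty trajectory ({traj.replicate_label!r})")
        n_bulk = sum(
            frame_cluster(
                snap,
                ligation_cutoff=ligation_cutoff,
                hbond_cutoff=hbond_cutoff,
                bulk_threshold=bulk_threshold,
            ).bulk_connected
            for snap in traj
        )
        ratios.append(n_bulk / len(traj))
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return BulkRatioSummary(
        stage_label=trajectories[0].stage_label,
        per_replicate_ratios=tuple(ratios),
        mean=float(arr.mean()),
        sd=sd,
    )
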