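"""Nucleosome population statistics.

Duplicate removal, per-tomogram nearest-neighbour search, pooled
distance/angle summaries, subpopulation selection by neighbour distance or
angle, and detection of compact stacking motifs (face-to-face type I,
lateral type II, and merged tetra-/poly-nucleosome chains).

All pair statistics are computed within a tomogram; cross-tomogram pairs
are never formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from nucleofiber.geometry import axis_angles
from nucleofiber.particle_io import ParticleSet

logger = logging.getLogger(__name__)

#: Centre-to-centre distance below which a pair is considered duplicate
#: picks of the same nucleosome (strict inequality: exactly at the
#: threshold both survive).
DEFAULT_DEDUP_THRESHOLD_A = 60.0

#: Neighbour-distance subpopulation presets, Å, half-open [lo, hi).
DISTANCE_BIN_PRESETS = ((60.0, 80.0), (80.0, 100.0), (100.0, 120.0))
#: Neighbour-angle subpopulation presets, degrees, half-open [lo, hi).
ANGLE_BIN_PRESETS = ((0.0, 20.0), (20.0, 40.0), (40.0, 60.0))


@dataclass(frozen=True)
class NeighborPair:
    """A particle and its nearest non-duplicate neighbour (directed)."""

    source_id: int
    neighbor_id: int
    distance: float
    angle: float
    tomo_id: str = "tomo_0"


@dataclass
class PopulationSummary:
    """Pooled summary of a nearest-neighbour census."""

    n_input: int
    n_removed_duplicates: int
    n_retained: int
    n_pairs: int
    median_distance: float
    median_angle: float
    distance_histogram: tuple[np.ndarray, np.ndarray]  # (bin_edges, counts)
    angle_histogram: tuple[np.ndarray, np.ndarray]
    per_tomogram_median: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d_edges, d_counts = self.distance_histogram
        a_edges, a_counts = self.angle_histogram
        return {
            "n_input": self.n_input,
            "n_removed_duplicates": self.n_removed_duplicates,
            "n_retained": self.n_retained,
            "n_pairs": self.n_pairs,
            "median_distance_A": self.median_distance,
            "median_angle_deg": self.median_angle,
            "distance_histogram": {"edges_A": list(map(float, d_edges)),
                                   "counts": list(map(int, d_counts))},
            "angle_histogram": {"edges_deg": list(map(float, a_edges)),
                                "counts": list(map(int, a_counts))},
            "per_tomogram_median_A": {k: float(v) for k, v in self.per_tomogram_median.items()},
        }


@dataclass(frozen=True)
class MotifCall:
    """A compact-stacking motif: ordered member ids and a class label."""

    member_ids: tuple[int, ...]
    motif_class: str  # stacked_type_I | stacked_type_II | tetra | poly


@dataclass
class AnalysisResult:
    """Everything the standard pipeline produces for one particle set."""

    retained: ParticleSet
    removed_ids: list[int]
    pairs: list[NeighborPair]
    summary: PopulationSummary


# ---------------------------------------------------------------------------

def deduplicate(
    pset: ParticleSet, threshold: float = DEFAULT_DEDUP_THRESHOLD_A
) -> tuple[ParticleSet, list[int]]:
    """Remove duplicate picks closer than ``threshold`` Å within a tomogram.

    Removal is greedy in ascending particle_id: ids are visited in order and
    a particle is dropped iff it lies strictly closer than the threshold to
    an already-retained particle of the same tomogram.  For any conflicting
    pair the higher id is therefore the one removed.  Idempotent.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    n = len(pset)
    if n == 0:
        return pset.subset(np.zeros(0, dtype=np.int64)), []

    keep = np.ones(n, dtype=bool)
    for _, idx in pset.by_tomogram().items():
        if len(idx) < 2:
            continue
        tree = cKDTree(pset.centers[idx])
        conflicts = tree.query_pairs(threshold, output_type="ndarray")
        if len(conflicts) == 0:
            continue
        # strict inequality: drop pairs at exactly the threshold
        d = np.linalg.norm(
            pset.centers[idx[conflicts[:, 0]]] - pset.centers[idx[conflicts[:, 1]]], axis=1
        )
        conflicts = conflicts[d < threshold]
        adjacency: dict[int, list[int]] = {}
        for a, b in conflicts:
            adjacency.setdefault(int(a), []).append(int(b))
            adjacency.setdefault(int(b), []).append(int(a))
        order = np.argsort(pset.particle_ids[idx], kind="stable")
        kept_local: set[int] = set()
        for local in order:
            local = int(local)
            if any(nb in kept_local for nb in adjacency.get(local, ())):
                keep[idx[local]] = False
            else:
                kept_local.add(local)
    removed = [int(i) for i in pset.particle_ids[~keep]]
    if removed:
        logger.info("deduplicate: removed %d of %d particles (< %.1f Å)", len(removed), n, threshold)
    return pset.subset(keep), removed


def nearest_neighbors(pset: ParticleSet, mutual: bool = False, fold_angle: bool = True) -> list[NeighborPair]:
    """Directed nearest-neighbour pairs within each tomogram.

    One pair per particle (its single nearest other particle in the same
    tomogram), found with a k-d tree; tomograms with fewer than two
    particles contribute nothing.  ``mutual=True`` keeps only pairs where
    each member is the other's nearest neighbour.
    """
    pairs: list[NeighborPair] = []
    for tomo, idx in pset.by_tomogram().items():
        if len(idx) < 2:
            logger.info("tomogram %s has %d particle(s); no neighbour pairs", tomo, len(idx))
            continue
        centers = pset.centers[idx]
        tree = cKDTree(centers)
        dists, nn = tree.query(centers, k=2)
        nn_local = nn[:, 1]
        nn_dist = dists[:, 1]
        angles = axis_angles(pset.rotations[idx], pset.rotations[idx[nn_local]], fold=fold_angle)
        for i in range(len(idx)):
            j = int(nn_local[i])
            if mutual and int(nn_local[j]) != i:
                continue
            pairs.append(
                NeighborPair(
                    source_id=int(pset.particle_ids[idx[i]]),
                    neighbor_id=int(pset.particle_ids[idx[j]]),
                    distance=float(nn_dist[i]),
                    angle=float(angles[i]),
                    tomo_id=tomo,
                )
            )
    return pairs


def summarize(
    pairs: list[NeighborPair],
    distance_bin_A: float = 10.0,
    angle_bin_deg: float = 5.0,
    n_input: int | None = None,
    n_removed_duplicates: int = 0,
) -> PopulationSummary:
    """Pooled median and fixed-width histograms of a neighbour census."""
    if not pairs:
        raise ValueError("cannot summarize an empty neighbour list")
    distances = np.array([p.distance for p in pairs])
    angles = np.array([p.angle for p in pairs])
    d_edges = np.arange(0.0, (np.floor(distances.max() / distance_bin_A) + 1) * distance_bin_A + distance_bin_A / 2, distance_bin_A)
    a_edges = np.arange(0.0, (np.floor(angles.max() / angle_bin_deg) + 1) * angle_bin_deg + angle_bin_deg / 2, angle_bin_deg)
    d_counts, d_edges = np.histogram(distances, bins=d_edges)
    a_counts, a_edges = np.histogram(angles, bins=a_edges)
    per_tomo: dict[str, float] = {}
    for p in pairs:
        per_tomo.setdefault(p.tomo_id, 0.0)
    for tomo in per_tomo:
        per_tomo[tomo] = float(np.median([p.distance for p in pairs if p.tomo_id == tomo]))
    if n_input is not None:
        n_retained = n_input - n_removed_duplicates
    else:
        n_retained = len({p.source_id for p in pairs})
    return PopulationSummary(
        n_input=n_input if n_input is not None else n_retained + n_removed_duplicates,
        n_removed_duplicates=n_removed_duplicates,
        n_retained=n_retained,
        n_pairs=len(pairs),
        median_distance=float(np.median(distances)),
        median_angle=float(np.median(angles)),
        distance_histogram=(d_edges, d_counts),
        angle_histogram=(a_edges, a_counts),
        per_tomogram_median=per_tomo,
    )


def select_subpopulation(
    pairs: list[NeighborPair], by: str = "distance", lo: float = 60.0, hi: float = 80.0
) -> set[int]:
    """Source ids whose nearest-neighbour value falls in the half-open [lo, hi)."""
    if lo >= hi:
        raise ValueError(f"lo must be < hi, got [{lo}, {hi})")
    if by not in ("distance", "angle"):
        raise ValueError(f"by must be 'distance' or 'angle', got {by!r}")
    key = (lambda p: p.distance) if by == "distance" else (lambda p: p.angle)
    return {p.source_id for p in pairs if lo <= key(p) < hi}


def flag_edge_particles(
    pset: ParticleSet,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    radius: float = 200.0,
) -> np.ndarray:
    """Boolean mask of particles within one search radius of the declared
    tomogram bounds.

    Near the field edge a particle's true nearest neighbour may lie outside
    the reconstructed volume, truncating the distance census upward.  The
    default pipeline includes edge particles; callers wanting a conservative
    census can drop the flagged rows with :meth:`ParticleSet.subset`.
    """
    lo = np.asarray(bounds_lo, dtype=float)
    hi = np.asarray(bounds_hi, dtype=float)
    near_lo = (pset.centers - lo) < radius
    near_hi = (hi - pset.centers) < radius
    return (near_lo | near_hi).any(axis=1)


# ---------------------------------------------------------------------------
# Stacking motifs

@dataclass(frozen=True)
class StackGate:
    """Distance/angle gate for a face-to-face or lateral nucleosome pair.

    Defaults were calibrated on constructed ideal stacks: a stacked pair
    sits at roughly one disc height (55-100 Å) with near-parallel axes;
    type I has its centre offset mostly along the shared axis, type II
    mostly in-plane.
    """

    distance_lo_A: float = 55.0
    distance_hi_A: float = 100.0
    angle_max_deg: float = 25.0


def detect_motifs(
    pset: ParticleSet, stack_gate: StackGate | None = None, extend: bool = True
) -> list[MotifCall]:
    """Detect compact di-/tetra-/poly-nucleosome stacking motifs.

    Pairs passing the gate are classified type I (axial offset dominates)
    or type II (in-plane offset dominates).  With ``extend=True``, connected
    chains of gated links with >= 3 members are merged into a single call:
    ``tetra`` for exactly four members, ``poly`` otherwise.
    """
    gate = stack_gate or StackGate()
    links: list[tuple[int, int, str]] = []  # local indices + pair class
    for _, idx in pset.by_tomogram().items():
        if len(idx) < 2:
            continue
        tree = cKDTree(pset.centers[idx])
        cand = tree.query_pairs(gate.distance_hi_A, output_type="ndarray")
        if len(cand) == 0:
            continue
        delta = pset.centers[idx[cand[:, 1]]] - pset.centers[idx[cand[:, 0]]]
        dist = np.linalg.norm(delta, axis=1)
        ok = (dist >= gate.distance_lo_A) & (dist < gate.distance_hi_A)
        ang = axis_angles(pset.rotations[idx[cand[:, 0]]], pset.rotations[idx[cand[:, 1]]])
        ok &= ang < gate.angle_max_deg
        for (a, b), dv in zip(cand[ok], delta[ok]):
            ax_a = pset.rotations[idx[a]][:, 2]
            ax_b = pset.rotations[idx[b]][:, 2]
            if ax_a @ ax_b < 0:
                ax_b = -ax_b
            mean_axis = ax_a + ax_b
            mean_axis = mean_axis / np.linalg.norm(mean_axis)
            axial = abs(float(dv @ mean_axis))
            lateral = float(np.linalg.norm(dv - (dv @ mean_axis) * mean_axis))
            cls = "stacked_type_I" if axial >= lateral else "stacked_type_II"
            links.append((int(idx[a]), int(idx[b]), cls))

    if not links:
        return []

    # connected components over gated links
    parent = {i: i for l in links for i in l[:2]}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if extend:
        for a, b, _ in links:
            parent[find(a)] = find(b)

    components: dict[int, set[int]] = {}
    edge_class: dict[tuple[int, int], str] = {}
    for a, b, cls in links:
        components.setdefault(find(a), set()).update((a, b))
        edge_class[(a, b)] = cls

    calls: list[MotifCall] = []
    for members in components.values():
        ordered = _chain_order(members, links)
        ids = tuple(int(pset.particle_ids[i]) for i in ordered)
        if len(members) == 2:
            a, b = ordered
            cls = edge_class.get((a, b)) or edge_class.get((b, a), "stacked_type_I")
            calls.append(MotifCall(member_ids=ids, motif_class=cls))
        elif len(members) == 4:
            calls.append(MotifCall(member_ids=ids, motif_class="tetra"))
        else:
            calls.append(MotifCall(member_ids=ids, motif_class="poly"))
    calls.sort(key=lambda c: c.member_ids)
    return calls


def _chain_order(members: set[int], links: list[tuple[int, int, str]]) -> list[int]:
    """Order component members along the link graph (BFS from an endpoint)."""
    adj: dict[int, list[int]] = {m: [] for m in members}
    for a, b, _ in links:
        if a in members and b in members:
            adj[a].append(b)
            adj[b].append(a)
    start = min((m for m in members if len(adj[m]) == 1), default=min(members))
    order, seen, queue = [], set(), [start]
    while queue:
        node = queue.pop(0)
        if node in seen:
            continue
        seen.add(node)
        order.append(node)
        queue.extend(sorted(n for n in adj[node] if n not in seen))
    return order


# ---------------------------------------------------------------------------

def run_pipeline(
    pset: ParticleSet,
    threshold: float = DEFAULT_DEDUP_THRESHOLD_A,
    distance_bin_A: float = 10.0,
    angle_bin_deg: float = 5.0,
    mutual: bool = False,
    fold_angle: bool = True,
) -> AnalysisResult:
    """Standard census: deduplicate -> nearest neighbours -> summary."""
    retained, removed = deduplicate(pset, threshold)
    pairs = nearest_neighbors(retained, mutual=mutual, fold_angle=fold_angle)
    summary = summarize(
        pairs,
        distance_bin_A=distance_bin_A,
        angle_bin_deg=angle_bin_deg,
        n_input=len(pset),
        n_removed_duplicates=len(removed),
    )
    return AnalysisResult(retained=retained, removed_ids=removed, pairs=pairs, summary=summary)
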