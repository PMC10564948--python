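"""Map-back, linker-DNA path prediction and DNA concentration.

Mapping back places the averaged nucleosome at every refined pose (a rigid
transform per particle).  Because linker histone H1 marks the side where
linker DNA enters and exits the disc, each pose defines two anchor points
on its H1 side; chaining anchors of nearby particles with short, gently
bent gap segments predicts the linker-DNA path as a polyline.  Counting
nucleosomes in a known tomogram volume gives a DNA concentration estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from nucleofiber.geometry import H1_REFERENCE_DIRECTION
from nucleofiber.particle_io import ParticlePose, ParticleSet, TomoMeta

#: Radius from disc centre to the DNA gyre at the entry/exit site, Å.
DEFAULT_ANCHOR_OFFSET_A = 55.0
#: Half-angle splitting entry from exit about the H1 direction, degrees.
DEFAULT_SPLIT_DEG = 25.0


@dataclass(frozen=True)
class DnaPath:
    """An ordered chain of particles with linker anchor points.

    ``anchors`` holds, per link, the exit point of one nucleosome followed
    by the entry point of the next; ``total_length_A`` is the summed length
    of those gap segments (the predicted straight linkers).
    """

    member_ids: tuple[int, ...]
    anchors: tuple[np.ndarray, ...]
    total_length_A: float


@dataclass(frozen=True)
class ConcentrationEstimate:
    """DNA concentration from a nucleosome count and a tomogram volume.

    concentration [mg/ml] = n * bp * mass_per_bp [g/mol] / N_A / volume,
    with the volume converted from Å^3 (1 Å^3 = 1e-24 ml).  All inputs are
    retained for auditability; the result depends directly on the assumed
    nucleosome repeat length and per-base-pair mass.
    """

    n_nucleosomes: int
    bp_per_nucleosome: int
    mass_per_bp: float
    volume_A3: float
    concentration_mg_per_ml: float

    def to_dict(self) -> dict:
        return {
            "n_nucleosomes": self.n_nucleosomes,
            "bp_per_nucleosome": self.bp_per_nucleosome,
            "mass_per_bp_g_per_mol": self.mass_per_bp,
            "volume_A3": self.volume_A3,
            "concentration_mg_per_ml": self.concentration_mg_per_ml,
        }


def place_models(pset: ParticleSet, reference: str = "nucleosome") -> pd.DataFrame:
    """One rigid transform (rotation + translation, Å) per particle.

    The transform maps reference-frame coordinates into the tomogram frame:
    x_tomo = R @ x_ref + t with t the particle centre.  Class labels are
    carried through for class-wise map-back.
    """
    rows = []
    for i in range(len(pset)):
        R = pset.rotations[i]
        t = pset.centers[i]
        row = {
            "particle_id": int(pset.particle_ids[i]),
            "tomo_id": str(pset.tomo_ids[i]),
            "reference": reference,
        }
        for r in range(3):
            for c in range(3):
                row[f"r{r+1}{c+1}"] = R[r, c]
        row["tx"], row["ty"], row["tz"] = t
        if pset.class_labels is not None:
            row["class"] = int(pset.class_labels[i])
        rows.append(row)
    return pd.DataFrame(rows)


def entry_exit_points(
    pose: ParticlePose,
    offset_A: float = DEFAULT_ANCHOR_OFFSET_A,
    split_deg: float = DEFAULT_SPLIT_DEG,
    h1_direction: np.ndarray = H1_REFERENCE_DIRECTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Linker entry and exit anchor points of one pose.

    Both anchors lie in the disc plane at ``offset_A`` from the centre, on
    the H1 side, split symmetrically by ``±split_deg`` about the H1
    direction (rotation about the disc axis).  Which of the two is called
    entry versus exit is a labelling convention; path prediction treats
    them interchangeably.
    """
    d = np.asarray(h1_direction, dtype=float)
    d = d / np.linalg.norm(d)
    plus = Rotation.from_euler("z", split_deg, degrees=True).apply(d)
    minus = Rotation.from_euler("z", -split_deg, degrees=True).apply(d)
    R, c = pose.rotation, pose.center
    return c + R @ (plus * offset_A), c + R @ (minus * offset_A)


def _all_anchors(pset: ParticleSet, offset_A: float, split_deg: float,
                 h1_direction: np.ndarray) -> np.ndarray:
    """(n, 2, 3) array of both anchors for every particle, vectorised."""
    d = np.asarray(h1_direction, dtype=float)
    d = d / np.linalg.norm(d)
    plus = Rotation.from_euler("z", split_deg, degrees=True).apply(d) * offset_A
    minus = Rotation.from_euler("z", -split_deg, degrees=True).apply(d) * offset_A
    a0 = pset.centers + np.einsum("nij,j->ni", pset.rotations, plus)
    a1 = pset.centers + np.einsum("nij,j->ni", pset.rotations, minus)
    return np.stack([a0, a1], axis=1)


def predict_paths(
    pset: ParticleSet,
    max_linker_A: float = 250.0,
    max_turn_deg: float = 90.0,
    offset_A: float = DEFAULT_ANCHOR_OFFSET_A,
    split_deg: float = DEFAULT_SPLIT_DEG,
    h1_direction: np.ndarray = H1_REFERENCE_DIRECTION,
) -> tuple[list[DnaPath], list[int]]:
    """Greedy linker-DNA chaining from the H1 side.

    Candidate links between particles of the same tomogram are scored by
    the gap between one particle's anchor and the other's (the shortest of
    the four anchor pairings); a link is admissible if the gap is below
    ``max_linker_A`` and the bend at each junction — the angle between the
    gap segment and that nucleosome's disc plane, i.e. how steeply the
    linker would have to pitch out of the plane the DNA gyre wraps in —
    is below ``max_turn_deg``.  Links are accepted
    in ascending gap order; each particle's two anchors can each serve one
    link, giving in-degree <= 1 and out-degree <= 1, and union-find rejects
    cycles.  Returns the chains as polyline paths, plus the unlinked
    singleton particle ids.
    """
    anchors = _all_anchors(pset, offset_A, split_deg, h1_direction)
    disc_axes = pset.rotations[:, :, 2]
    candidates: list[tuple[float, int, int, int, int]] = []  # gap, i, j, ai, aj
    for _, idx in pset.by_tomogram().items():
        if len(idx) < 2:
            continue
        tree = cKDTree(pset.centers[idx])
        for a, b in tree.query_pairs(max_linker_A + 2 * offset_A):
            i, j = int(idx[a]), int(idx[b])
            best = None
            for ai in range(2):
                for aj in range(2):
                    seg = anchors[j, aj] - anchors[i, ai]
                    gap = float(np.linalg.norm(seg))
                    if gap >= max_linker_A:
                        continue
                    if gap > 1e-9:
                        u = seg / gap
                        bend_i = np.degrees(np.arcsin(min(abs(float(u @ disc_axes[i])), 1.0)))
                        bend_j = np.degrees(np.arcsin(min(abs(float(u @ disc_axes[j])), 1.0)))
                        if bend_i > max_turn_deg or bend_j > max_turn_deg:
                            continue
                    if best is None or gap < best[0]:
                        best = (gap, i, j, ai, aj)
            if best is not None:
                candidates.append(best)

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    n = len(pset)
    anchor_used = np.zeros((n, 2), dtype=bool)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    accepted: dict[int, list[tuple[int, int, int]]] = {i: [] for i in range(n)}
    links: list[tuple[int, int, int, int, float]] = []
    for gap, i, j, ai, aj in candidates:
        if anchor_used[i, ai] or anchor_used[j, aj]:
            continue
        ri, rj = find(i), find(j)
        if ri == rj:
            continue
        parent[ri] = rj
        anchor_used[i, ai] = anchor_used[j, aj] = True
        accepted[i].append((j, ai, aj))
        accepted[j].append((i, aj, ai))
        links.append((i, j, ai, aj, gap))

    # walk out each chain from an endpoint
    link_lookup: dict[tuple[int, int], tuple[int, int, float]] = {}
    for i, j, ai, aj, gap in links:
        link_lookup[(i, j)] = (ai, aj, gap)
        link_lookup[(j, i)] = (aj, ai, gap)

    degree = {i: len(accepted[i]) for i in range(n)}
    singletons = [int(pset.particle_ids[i]) for i in range(n) if degree[i] == 0]
    paths: list[DnaPath] = []
    visited: set[int] = set()
    endpoints = sorted(
        (i for i in range(n) if degree[i] == 1), key=lambda i: int(pset.particle_ids[i])
    )
    for start in endpoints:
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = [j for j, _, _ in accepted[cur] if j not in visited]
            if not nxt:
                break
            cur = nxt[0]
            visited.add(cur)
            chain.append(cur)
        anchor_pts: list[np.ndarray] = []
        total = 0.0
        for a, b in zip(chain[:-1], chain[1:]):
            ai, aj, gap = link_lookup[(a, b)]
            anchor_pts.append(anchors[a, ai])
            anchor_pts.append(anchors[b, aj])
            total += gap
        paths.append(
            DnaPath(
                member_ids=tuple(int(pset.particle_ids[i]) for i in chain),
                anchors=tuple(anchor_pts),
                total_length_A=total,
            )
        )
    paths.sort(key=lambda p: p.member_ids)
    return paths, singletons


def paths_to_bild(paths: list[DnaPath], radius: float = 5.0) -> str:
    """Render predicted linker paths as ChimeraX BILD cylinders."""
    lines = [".color 1 0 1"]
    for path in paths:
        for k in range(0, len(path.anchors), 2):
            a, b = path.anchors[k], path.anchors[k + 1]
            lines.append(
                ".cylinder "
                + " ".join(f"{v:.2f}" for v in a)
                + " "
                + " ".join(f"{v:.2f}" for v in b)
                + f" {radius:.2f}"
            )
    return "\n".join(lines) + "\n"


def estimate_concentration(
    pset: ParticleSet,
    meta: TomoMeta,
    bp_per_nucleosome: int = 200,
    mass_per_bp: float = 650.0,
) -> ConcentrationEstimate:
    """DNA concentration in the tomogram volume, mg/ml.

    ``bp_per_nucleosome`` is the nucleosome repeat length (147 bp core plus
    a nominal linker); ``mass_per_bp`` the average double-stranded DNA mass
    in g/mol per base pair.
    """
    n = len(pset)
    if n < 1:
        raise ValueError("need at least one nucleosome")
    volume = meta.volume_A3
    if volume <= 0:
        raise ValueError("tomogram volume must be positive")
    mass_mg = n * bp_per_nucleosome * mass_per_bp / Avogadro * 1e3  # g -> mg
    volume_ml = volume * 1e-24  # 1 Å^3 = 1e-24 cm^3
    return ConcentrationEstimate(
        n_nucleosomes=n,
        bp_per_nucleosome=bp_per_nucleosome,
        mass_per_bp=mass_per_bp,
        volume_A3=volume,
        concentration_mg_per_ml=mass_mg / volume_ml,
    )
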