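"""Synthetic relaxed-zigzag chromatin scenes with ground truth.

Generates lamella-like fields of nucleosome chains: each fibre is a 3D
zigzag walk whose step lengths follow a log-normal (or gamma) law
parameterised by its median, whose step directions alternate about a
slowly meandering fibre axis, confined to a thin slab by reflection.
Disc axes are set perpendicular to the local linker direction (plus
isotropic orientation noise) and the H1 side faces the linker entry/exit
bisector, so linker-DNA path prediction has a well-defined noise-free
limit.  Near-duplicate picks and isolated decoys emulate template-matching
artefacts.

Spacing variance is split between a per-fibre component (nucleosome repeat
length varies from fibre to fibre) and a small per-step component
(``fiber_level_fraction`` of the log-variance lives at the fibre level).
This keeps the population-wide spacing distribution broad while keeping
the nearest-neighbour census — which takes, per particle, the shorter of
its two flanking steps — an essentially unbiased estimate of the spacing
median.

Nucleosome discs cannot interpenetrate, so chains respect an excluded
volume: any two particles that are not chain-adjacent must be at least
``exclusion_A`` apart (default one disc diameter).  Steps that would
violate it are redrawn; without this constraint fibres pass freely
through one another and spurious sub-spacing neighbour pairs appear that
no real specimen could contain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.transform import Rotation

from nucleofiber.particle_io import ParticlePose, ParticleSet

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class SceneSpec:
    """Generator parameters for one synthetic tomogram-like scene.

    Defaults emulate the thin-lamella conditions the analysis is meant
    for: ~1400 nucleosomes in a 1.2 µm × 1.2 µm field (a K3-detector
    tomogram field of view at ~2.2 Å/px), slab 850 Å (~85 nm) thick,
    in-fibre spacing median 120 Å.  ``spacing_sd_A`` is the in-fibre
    step-length spread; the much broader spread of the observed
    neighbour-distance census arises from zigzag geometry, cross-fibre
    encounters and decoys, not from contour-length noise.  To grow a
    scene, scale ``field_xy_A`` with sqrt(n) so the particle density —
    a physical property of the specimen — stays fixed.
    """

    n_fibers: int = 28
    nucleosomes_per_fiber: int = 50
    spacing_median_A: float = 120.0
    spacing_sd_A: float = 10.0
    fiber_level_fraction: float = 0.95
    zigzag_angle_deg: float = 90.0
    angle_jitter_deg: float = 15.0
    orientation_noise_deg: float = 15.0
    meander_deg: float = 5.0
    slab_thickness_A: float = 850.0
    field_xy_A: float = 12000.0
    exclusion_A: float = 110.0
    duplicate_rate: float = 0.05
    duplicate_offset_A: float = 30.0
    decoy_rate: float = 0.02
    distribution: str = "lognormal"  # or "gamma"
    tomo_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplicate_rate", "decoy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fiber_level_fraction <= 1.0:
            raise ValueError("fiber_level_fraction must be in [0, 1]")
        if self.spacing_median_A <= self.duplicate_offset_A:
            raise ValueError("spacing_median_A must exceed duplicate_offset_A")
        if self.slab_thickness_A <= 0 or self.field_xy_A <= 0:
            raise ValueError("slab_thickness_A and field_xy_A must be > 0")
        if self.spacing_median_A > self.slab_thickness_A and self.spacing_median_A > self.field_xy_A:
            raise ValueError("infeasible confinement: spacing exceeds slab and field")
        if self.distribution not in ("lognormal", "gamma"):
            raise ValueError(f"distribution must be 'lognormal' or 'gamma', got {self.distribution!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class GroundTruth:
    """Per-particle provenance of a generated scene.

    ``true_step_A[i]`` is the step length from particle ``i`` to its
    successor in the chain (NaN for chain ends, duplicates and decoys);
    ``duplicate_of[i]`` is the id a duplicate copies (-1 otherwise).
    """

    particle_ids: np.ndarray
    fiber_ids: np.ndarray       # -1 for decoys
    chain_indices: np.ndarray   # -1 for duplicates/decoys
    is_duplicate: np.ndarray
    is_decoy: np.ndarray
    true_step_A: np.ndarray
    duplicate_of: np.ndarray

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "particle_id": self.particle_ids,
                "fiber_id": self.fiber_ids,
                "chain_index": self.chain_indices,
                "is_duplicate": self.is_duplicate.astype(int),
                "is_decoy": self.is_decoy.astype(int),
                "true_step_A": self.true_step_A,
                "duplicate_of": self.duplicate_of,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "GroundTruth":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(
            particle_ids=df["particle_id"].to_numpy(),
            fiber_ids=df["fiber_id"].to_numpy(),
            chain_indices=df["chain_index"].to_numpy(),
            is_duplicate=df["is_duplicate"].to_numpy().astype(bool),
            is_decoy=df["is_decoy"].to_numpy().astype(bool),
            true_step_A=df["true_step_A"].to_numpy(),
            duplicate_of=df["duplicate_of"].to_numpy(),
        )


def _step_lengths(rng: np.random.Generator, n: int, median: float, sigma_log: float,
                  distribution: str) -> np.ndarray:
    if sigma_log == 0.0 or n == 0:
        return np.full(n, median)
    if distribution == "lognormal":
        return median * np.exp(sigma_log * rng.standard_normal(n))
    # gamma with matching log-scale spread, rescaled to the requested median
    cv = np.sqrt(np.exp(sigma_log**2) - 1.0)
    shape = 1.0 / cv**2
    draws = rng.gamma(shape, 1.0, n)
    med = shape * (1.0 - 1.0 / (9.0 * shape)) ** 3  # Wilson-Hilferty median approx
    return median * draws / med


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(3)
    w -= (w @ v) * v
    n = np.linalg.norm(w)
    while n < 1e-9:
        w = rng.standard_normal(3)
        w -= (w @ v) * v
        n = np.linalg.norm(w)
    return w / n


def _frame_from(axis: np.ndarray, h1_toward: np.ndarray) -> np.ndarray:
    """Rotation whose disc axis (3rd column) is ``axis`` and whose H1 side
    (-x after rotation) points along ``h1_toward`` projected in-plane."""
    z = axis / np.linalg.norm(axis)
    b = h1_toward - (h1_toward @ z) * z
    n = np.linalg.norm(b)
    if n < 1e-9:
        b = np.array([1.0, 0.0, 0.0]) - z[0] * z
        n = np.linalg.norm(b)
    b = b / n
    x = -b  # H1 reference direction is -x in the reference frame
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def generate_scene(spec: SceneSpec) -> tuple[ParticleSet, GroundTruth]:
    """Generate one scene; deterministic for a fixed spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    sigma_tot = np.sqrt(np.log1p((spec.spacing_sd_A / spec.spacing_median_A) ** 2))
    sigma_fiber = np.sqrt(spec.fiber_level_fraction) * sigma_tot
    sigma_step = np.sqrt(1.0 - spec.fiber_level_fraction) * sigma_tot

    lo = np.zeros(3)
    hi = np.array([spec.field_xy_A, spec.field_xy_A, spec.slab_thickness_A])

    centers: list[np.ndarray] = []
    rotations: list[np.ndarray] = []
    fiber_ids: list[int] = []
    chain_indices: list[int] = []
    steps: list[float] = []

    from scipy.spatial import cKDTree

    placed: list[np.ndarray] = []  # particles of finished fibres
    prev_tree: cKDTree | None = None
    max_tries = 10

    for f in range(spec.n_fibers):
        m = spec.nucleosomes_per_fiber
        fiber_median = spec.spacing_median_A * float(np.exp(sigma_fiber * rng.standard_normal()))
        lengths = _step_lengths(rng, m - 1, fiber_median, sigma_step, spec.distribution)

        def clearance(point: np.ndarray, own: list[np.ndarray], skip_last: int) -> float:
            """Distance to the nearest non-chain-adjacent placed particle."""
            best = np.inf
            if prev_tree is not None:
                best = float(prev_tree.query(point)[0])
            own_check = own[: len(own) - skip_last]
            if own_check:
                best = min(best, float(np.min(np.linalg.norm(np.array(own_check) - point, axis=1))))
            return best

        # fibre frame: axis u and zigzag normal n, meandering slowly
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        nvec = _perpendicular(u, rng)
        pos = lo + rng.random(3) * (hi - lo)
        for _ in range(max_tries):
            if clearance(pos, [], 0) >= spec.exclusion_A:
                break
            pos = lo + rng.random(3) * (hi - lo)
        pts = [pos]
        dirs: list[np.ndarray] = []
        for i in range(m - 1):
            best_candidate = None  # (clearance, d, nxt, u, nvec)
            for attempt in range(2 * max_tries):
                n_try = nvec
                if 0 < attempt < max_tries:
                    # the zigzag plane twists about the fibre axis to dodge an
                    # obstacle; gives the redraw freedom even with zero jitter
                    phi = rng.uniform(0.0, 2.0 * np.pi)
                    n_try = np.cos(phi) * nvec + np.sin(phi) * np.cross(u, nvec)
                    n_try /= np.linalg.norm(n_try)
                if attempt < max_tries:
                    alpha = (-1.0) ** i * (
                        spec.zigzag_angle_deg / 2.0 + spec.angle_jitter_deg * rng.standard_normal()
                    ) * _DEG
                    d = np.cos(alpha) * u + np.sin(alpha) * n_try
                else:
                    # last resort at walls/corners: a chain defect — the step
                    # leaves the zigzag cone entirely, keeping its length
                    d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                # reflect at slab/field boundaries before stepping, so the step
                # length (and hence the spacing statistics) is preserved exactly
                u_t, n_t = u.copy(), n_try.copy()
                nxt = pts[-1] + lengths[i] * d
                for k in range(3):
                    if nxt[k] < lo[k] or nxt[k] > hi[k]:
                        d[k] = -d[k]
                        u_t[k] = -u_t[k]
                        n_t[k] = -n_t[k]
                nxt = pts[-1] + lengths[i] * d
                nxt = np.clip(nxt, lo, hi)  # guards steps longer than the box
                # excluded volume: redraw steps that put the new nucleosome
                # closer than a disc diameter to any non-adjacent particle
                c = clearance(nxt, pts, skip_last=1)
                if best_candidate is None or c > best_candidate[0]:
                    best_candidate = (c, d, nxt, u_t, n_t)
                if c >= spec.exclusion_A:
                    break
            _, d, nxt, u, nvec = best_candidate
            dirs.append(d)
            pts.append(nxt)
            if spec.meander_deg > 0:
                wobble = Rotation.from_rotvec(
                    spec.meander_deg * _DEG * rng.standard_normal(3)
                ).as_matrix()
                u = wobble @ u
                nvec = wobble @ nvec
                nvec -= (nvec @ u) * u
                nvec /= np.linalg.norm(nvec)

        for i in range(m):
            d_prev = dirs[i - 1] if i > 0 else dirs[0]
            d_next = dirs[i] if i < m - 1 else dirs[-1]
            axis = np.cross(d_prev, d_next)
            if np.linalg.norm(axis) < 1e-9:  # chain end: any axis normal to the linker
                axis = _perpendicular(d_next, rng)
            axis /= np.linalg.norm(axis)
            if i == 0:
                h1_toward = d_next
            elif i == m - 1:
                h1_toward = -d_prev
            else:
                h1_toward = d_next - d_prev
            R = _frame_from(axis, h1_toward)
            if spec.orientation_noise_deg > 0:
                noise = Rotation.from_rotvec(
                    spec.orientation_noise_deg * _DEG * rng.standard_normal(3)
                ).as_matrix()
                R = noise @ R
            centers.append(pts[i])
            rotations.append(R)
            fiber_ids.append(f)
            chain_indices.append(i)
            steps.append(float(lengths[i]) if i < m - 1 else np.nan)

        placed.extend(pts)
        prev_tree = cKDTree(np.array(placed))

    n_real = len(centers)
    duplicate_of = [-1] * n_real
    is_dup = [False] * n_real
    is_decoy = [False] * n_real

    # near-duplicate picks of existing particles
    n_dup = int(round(spec.duplicate_rate * n_real))
    dup_sources = rng.choice(n_real, size=n_dup, replace=False) if n_dup else np.array([], int)
    for src in dup_sources:
        # redraw the displacement direction until the copy stays inside the
        # box, so its distance from the source is exactly duplicate_offset_A
        for _ in range(100):
            offset = rng.standard_normal(3)
            offset = offset / np.linalg.norm(offset) * spec.duplicate_offset_A
            candidate = centers[src] + offset
            if np.all(candidate >= lo) and np.all(candidate <= hi):
                break
        wobble = Rotation.from_rotvec(5.0 * _DEG * rng.standard_normal(3)).as_matrix()
        centers.append(candidate)
        rotations.append(wobble @ rotations[src])
        fiber_ids.append(fiber_ids[src])
        chain_indices.append(-1)
        steps.append(np.nan)
        duplicate_of.append(int(src))
        is_dup.append(True)
        is_decoy.append(False)

    # isolated decoys (false positives of template matching)
    n_decoy = int(round(spec.decoy_rate * n_real))
    for _ in range(n_decoy):
        centers.append(lo + rng.random(3) * (hi - lo))
        rotations.append(Rotation.random(rng=rng).as_matrix())
        fiber_ids.append(-1)
        chain_indices.append(-1)
        steps.append(np.nan)
        duplicate_of.append(-1)
        is_dup.append(False)
        is_decoy.append(True)

    n_total = len(centers)
    poses = [
        ParticlePose(
            particle_id=i, tomo_id=spec.tomo_id, center=centers[i], rotation=rotations[i]
        )
        for i in range(n_total)
    ]
    pset = ParticleSet(poses, pixel_size_A=1.0, source=f"synthetic:seed={spec.seed}")
    truth = GroundTruth(
        particle_ids=np.arange(n_total),
        fiber_ids=np.array(fiber_ids),
        chain_indices=np.array(chain_indices),
        is_duplicate=np.array(is_dup),
        is_decoy=np.array(is_decoy),
        true_step_A=np.array(steps),
        duplicate_of=np.array(duplicate_of),
    )
    return pset, truth


def ground_truth_eval(result, truth: GroundTruth) -> dict:
    """Score a pipeline result against the generating ground truth.

    Reports duplicate-removal sensitivity/specificity, spacing-recovery
    bias (recovered median minus true step median), and the fraction of
    directed nearest-neighbour pairs that join chain-adjacent particles of
    the same fibre.
    """
    known = set(int(i) for i in truth.particle_ids)
    seen = set(int(i) for i in result.retained.particle_ids) | set(result.removed_ids)
    if not seen <= known:
        raise ValueError("pipeline result contains particle ids absent from ground truth")

    removed = set(result.removed_ids)
    dup_ids = set(int(i) for i in truth.particle_ids[truth.is_duplicate])
    n_dup = len(dup_ids)
    n_nondup = len(known) - n_dup
    sensitivity = len(removed & dup_ids) / n_dup if n_dup else float("nan")
    specificity = (n_nondup - len(removed - dup_ids)) / n_nondup if n_nondup else float("nan")

    true_median = float(np.nanmedian(truth.true_step_A))
    bias = result.summary.median_distance - true_median

    row_of = {int(p): k for k, p in enumerate(truth.particle_ids)}
    n_chain = 0
    for pair in result.pairs:
        a, b = row_of[pair.source_id], row_of[pair.neighbor_id]
        same_fiber = truth.fiber_ids[a] == truth.fiber_ids[b] and truth.fiber_ids[a] >= 0
        adjacent = abs(truth.chain_indices[a] - truth.chain_indices[b]) == 1
        if same_fiber and adjacent:
            n_chain += 1
    chain_fraction = n_chain / len(result.pairs) if result.pairs else float("nan")

    return {
        "dedup_sensitivity": sensitivity,
        "dedup_specificity": specificity,
        "spacing_bias_A": bias,
        "true_step_median_A": true_median,
        "recovered_median_A": result.summary.median_distance,
        "chain_neighbor_fraction": chain_fraction,
    }
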