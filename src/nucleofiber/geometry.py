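"""Nucleosome local frame and distance/angle primitives.

Reference frame convention: the reference nucleosome disc lies in the x-y
plane with its superhelical (disc-normal) axis along z and the dyad
direction along +x.  Linker histone H1 sits at the dyad on the linker
entry/exit side, so the default H1 reference direction is -x; it is
configurable because it is defined only pictorially by map-back figures.
A pose's rotation carries these reference vectors into the tomogram frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nucleofiber.particle_io import ParticlePose

#: Reference disc-normal (superhelical) axis.
REFERENCE_AXIS = np.array([0.0, 0.0, 1.0])
#: Reference dyad direction.
REFERENCE_DYAD = np.array([1.0, 0.0, 0.0])
#: Default H1 / linker entry-exit direction (at the dyad, opposite side).
H1_REFERENCE_DIRECTION = np.array([-1.0, 0.0, 0.0])


@dataclass(frozen=True)
class NucleosomeFrame:
    """Local orthonormal frame of one nucleosome in tomogram coordinates."""

    axis: np.ndarray
    dyad: np.ndarray
    h1_side: np.ndarray

    def __post_init__(self) -> None:
        for name in ("axis", "dyad", "h1_side"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be unit length")
            object.__setattr__(self, name, v)
        if abs(float(self.axis @ self.dyad)) > 1e-6:
            raise ValueError("axis and dyad must be orthogonal")


def frame_of(
    pose: ParticlePose, h1_direction: np.ndarray = H1_REFERENCE_DIRECTION
) -> NucleosomeFrame:
    """Rotate the reference frame into the tomogram frame of ``pose``."""
    R = pose.rotation
    d = np.asarray(h1_direction, dtype=float)
    d = d / np.linalg.norm(d)
    return NucleosomeFrame(axis=R @ REFERENCE_AXIS, dyad=R @ REFERENCE_DYAD, h1_side=R @ d)


def pair_distance(a: ParticlePose, b: ParticlePose) -> float:
    """Euclidean centre-to-centre distance in Å."""
    return float(np.linalg.norm(a.center - b.center))


def pair_angle(a: ParticlePose, b: ParticlePose, fold: bool = True) -> float:
    """Angle in degrees between the disc (superhelical) axes of two poses.

    With ``fold=True`` (default) the angle is sign-folded to [0, 90]:
    antiparallel axes count as parallel, reflecting the near-two-fold
    ambiguity of a nucleosome disc at intermediate resolution.  With
    ``fold=False`` the full [0, 180] angle is returned.
    """
    return float(axis_angles(a.rotation[None], b.rotation[None], fold=fold)[0])


def axis_angles(rot_a: np.ndarray, rot_b: np.ndarray, fold: bool = True) -> np.ndarray:
    """Vectorised ``pair_angle`` over stacks of rotation matrices."""
    # disc axis = third column of the rotation matrix (R @ z-hat)
    ax_a = np.asarray(rot_a)[..., :, 2]
    ax_b = np.asarray(rot_b)[..., :, 2]
    dots = np.einsum("...i,...i->...", ax_a, ax_b)
    if fold:
        dots = np.abs(dots)
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
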