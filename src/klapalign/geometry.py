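"""Rigid-body geometry: rotations, transforms, centroids, and RMSD.

Angles are radians everywhere inside the library; the command line accepts
degrees and converts. The rotation convention is extrinsic X-then-Y-then-Z,
``R = R_z(theta_z) @ R_y(theta_y) @ R_x(theta_x)``. Any fixed Euler
convention parameterizes all of SO(3), so the search over transforms is not
restricted by this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "rotation_matrix",
    "apply_transform",
    "centroid",
    "rmsd_of_assignment",
]


def _wrap_angles(theta: np.ndarray) -> np.ndarray:
    """Map angles into [-pi, pi)."""
    return (theta + np.pi) % (2.0 * np.pi) - np.pi


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R(theta) @ x + t``.

    Parameters
    ----------
    t : ndarray, shape (3,)
        Translation in Angstrom.
    theta : ndarray, shape (3,)
        Rotation angles in radians about the lab X, Y and Z axes
        (extrinsic, applied in that order). Normalized to [-pi, pi).
    """

    t: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        t = np.array(self.t, dtype=float).reshape(3)
        theta = np.array(self.theta, dtype=float).reshape(3)
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(theta))):
            raise ValueError("rigid transform components must be finite")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "theta", _wrap_angles(theta))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.zeros(3), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 rotation matrix of this transform."""
        return rotation_matrix(self.theta)

    def inverse(self) -> "RigidTransform":
        """The transform undoing this one: ``x -> R^T (x - t)``."""
        R = self.matrix
        theta_inv = Rotation.from_matrix(R.T).as_euler("xyz")
        return RigidTransform(-R.T @ self.t, theta_inv)

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        return apply_transform(self, coords)


def rotation_matrix(theta) -> np.ndarray:
    """Rotation matrix ``R_z @ R_y @ R_x`` for extrinsic X,Y,Z angles (rad)."""
    theta = np.asarray(theta, dtype=float).reshape(3)
    if not np.all(np.isfinite(theta)):
        raise ValueError("rotation angles must be finite")
    return Rotation.from_euler("xyz", theta).as_matrix()


def apply_transform(transform: RigidTransform, coords) -> np.ndarray:
    """Apply ``R x + t`` to each row of ``coords``; the input is untouched."""
    coords = np.asarray(coords, dtype=float)
    return coords @ transform.matrix.T + transform.t


def centroid(coords) -> np.ndarray:
    """Arithmetic mean of a nonempty set of 3D points."""
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("centroid of an empty point set is undefined")
    return coords.reshape(-1, 3).mean(axis=0)


def rmsd_of_assignment(coords_a, coords_b, pairs) -> float:
    """RMSD over a fixed one-to-one pairing.

    ``pairs`` is a sequence of 1-based ``(i, j)`` index pairs into
    ``coords_a`` and ``coords_b``. Returns
    ``sqrt(mean ||a_i - b_j||^2)`` in the units of the coordinates.

    Raises if the pairing is empty, out of range, or repeats an index on
    either side (each residue may be matched at most once).
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("pairing must be nonempty")
    rows = np.array([p[0] for p in pairs], dtype=int)
    cols = np.array([p[1] for p in pairs], dtype=int)
    if len(set(rows.tolist())) != len(rows) or len(set(cols.tolist())) != len(cols):
        raise ValueError("pairing must be one-to-one: duplicate residue index")
    if rows.min() < 1 or cols.min() < 1 or rows.max() > len(coords_a) or cols.max() > len(coords_b):
        raise IndexError("pair index out of range")
    diff = coords_a[rows - 1] - coords_b[cols - 1]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
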