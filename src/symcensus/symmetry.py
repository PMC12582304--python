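"""ZYZ Euler-angle algebra and cyclic (Cn) symmetry expansion.

Conventions
-----------
Orientations are ZYZ Euler triples (rot, tilt, psi) in degrees, the
parameterization used in single-particle metadata.  The rotation matrix of a
triple is

    R(rot, tilt, psi) = Rz(psi) @ Ry(tilt) @ Rz(rot)

so the Cn operator k (rotation by k*360/n degrees about the symmetry z-axis)
acts on the reference-frame side, i.e. by right multiplication with
Rz(k*360/n) — equivalently by adding k*360/n to rot and touching nothing
else.  Subunit copy index k therefore increases with +360/n increments of
rot; copy 0 is identified with the first (reference) subunit slot.

After normalization rot and psi lie in (-180, 180] and tilt in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .star import ParticleTable, require_columns

__all__ = [
    "EulerTriple",
    "CyclicGroup",
    "SUBUNIT_INDEX_TAG",
    "ANGLE_TAGS",
    "normalize_angle",
    "euler_to_matrix",
    "matrix_to_euler",
    "compose_with_operator",
    "symmetry_expand",
]

#: Column tags of the ZYZ Euler angles in particle metadata.
ANGLE_TAGS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")

#: Tag of the subunit-copy-index column added by :func:`symmetry_expand`.
#: Deliberately outside the _rln namespace so downstream tools ignore it.
SUBUNIT_INDEX_TAG = "_symcensusSubunitIndex"


def normalize_angle(deg):
    """Map angles in degrees to the interval (-180, 180]."""
    a = np.mod(np.asarray(deg, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    return float(a) if np.isscalar(deg) or np.ndim(deg) == 0 else a


@dataclass(frozen=True)
class EulerTriple:
    """A ZYZ orientation in degrees."""

    rot: float
    tilt: float
    psi: float

    def normalized(self) -> "EulerTriple":
        return EulerTriple(
            normalize_angle(self.rot), float(self.tilt), normalize_angle(self.psi)
        )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rot, self.tilt, self.psi)


@dataclass(frozen=True)
class CyclicGroup:
    """The cyclic point group Cn about the reference z-axis."""

    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"group order must be >= 1, got {self.n}")

    @property
    def step(self) -> float:
        """Angular increment of one operator, in degrees."""
        return 360.0 / self.n

    def operator_angle(self, k: int) -> float:
        if not 0 <= k < self.n:
            raise ValueError(f"operator index {k} outside [0, {self.n})")
        return k * self.step


def _rz(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(e: EulerTriple) -> np.ndarray:
    """Rotation matrix Rz(psi) @ Ry(tilt) @ Rz(rot) of a ZYZ triple."""
    return _rz(e.psi) @ _ry(e.tilt) @ _rz(e.rot)


def matrix_to_euler(m: np.ndarray) -> EulerTriple:
    """Decompose a rotation matrix into a normalized ZYZ triple.

    Inverse of :func:`euler_to_matrix` up to the gimbal degeneracy at
    tilt = 0 or 180 (where only psi+rot resp. psi-rot is determined; rot is
    set to 0 there).
    """
    m = np.asarray(m, dtype=float)
    tilt = np.rad2deg(np.arccos(np.clip(m[2, 2], -1.0, 1.0)))
    if np.sin(np.deg2rad(tilt)) > 1e-9:
        psi = np.rad2deg(np.arctan2(m[1, 2], m[0, 2]))
        rot = np.rad2deg(np.arctan2(m[2, 1], -m[2, 0]))
    else:
        # degenerate: m is (close to) a rotation about z (tilt=0) or about an
        # in-plane axis (tilt=180); fold everything into psi
        rot = 0.0
        if m[2, 2] > 0:
            psi = np.rad2deg(np.arctan2(m[1, 0], m[0, 0]))
        else:
            psi = np.rad2deg(np.arctan2(m[1, 0], -m[0, 0]))
    return EulerTriple(normalize_angle(rot), tilt, normalize_angle(psi))


def compose_with_operator(e: EulerTriple, k: int, n: int) -> EulerTriple:
    """Compose an orientation with cyclic operator k of Cn.

    Returns (normalize(rot + k*360/n), tilt, psi); by the stated convention
    this equals the triple of euler_to_matrix(e) @ Rz(k*360/n).
    """
    delta = CyclicGroup(n).operator_angle(k)
    return EulerTriple(normalize_angle(e.rot + delta), e.tilt, e.psi)


def symmetry_expand(table: ParticleTable, n: int) -> ParticleTable:
    """Replicate every record by all n operators of Cn.

    The output holds n consecutive copies of each input record; copy k has
    rot composed with operator k and the copy index stored in the
    :data:`SUBUNIT_INDEX_TAG` column.  Copy k=0 is identical to its parent in
    all original columns.
    """
    group = CyclicGroup(n)
    require_columns(table, ANGLE_TAGS)
    df = table.df
    m = len(df)

    expanded = df.loc[df.index.repeat(n)].reset_index(drop=True)
    k = np.tile(np.arange(n, dtype=np.int64), m)
    rot = expanded["_rlnAngleRot"].to_numpy(dtype=float)
    new_rot = np.where(k == 0, rot, normalize_angle(rot + k * group.step))
    expanded["_rlnAngleRot"] = new_rot
    expanded[SUBUNIT_INDEX_TAG] = k

    out = table.copy()
    out.df = expanded
    return out
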