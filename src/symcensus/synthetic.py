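"""Ground-truthed synthetic inputs for the census/reorientation pipeline.

The generator emulates the statistical structure of a focused-classification
experiment on a cyclic pseudo-symmetric oligomer:

* each particle carries a hidden cyclic configuration drawn from stated
  frequencies (the canonical necklace string, e.g. ``iiiio``);
* consensus refinement under Cn locks onto an arbitrary symmetry copy, so
  the stored orientation is the true one composed with a uniformly random
  operator (the *anchor*), and the subunit labels are observed cyclically
  shifted by that same anchor;
* focused classification mislabels each subunit independently with
  probability epsilon (symmetric flip within the alphabet).

The emitted table is a valid symmetry-expanded focused-classification table
(n records per parent with class numbers encoding the corrupted,
anchor-shifted labels), which exercises backtracking, census and
reorientation end to end.

The toy scene builds pseudo-Cn 3D volumes in which each subunit is an
isotropic Gaussian blob at a fixed azimuth; blobs of ``o``-state subunits
sit at a larger radius, mimicking an outward-displaced structural feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .configuration import CLASS_TAG, PARENT_KEY_TAGS, rotate_string
from .star import ParticleTable
from .symmetry import (
    EulerTriple,
    compose_with_operator,
    euler_to_matrix,
    symmetry_expand,
)

__all__ = [
    "DEFAULT_FREQUENCIES",
    "DEFAULT_CLASS_MAP",
    "GeneratorConfig",
    "GroundTruth",
    "SceneParams",
    "sample_dataset",
    "build_state_volume",
    "render_particles",
    "rotate_volume",
]

#: Default configuration frequencies for a pentamer with two subunit states.
#: All eight cyclic configurations are populated, with per-configuration
#: frequencies spanning roughly 5-24% — the regime reported for pseudo-C5
#: channel particles under subactivating conditions.
DEFAULT_FREQUENCIES: dict[str, float] = {
    "iiiii": 0.236,
    "iiiio": 0.200,
    "iiioo": 0.150,
    "iiooo": 0.100,
    "ioooo": 0.080,
    "ooooo": 0.130,
    "iioio": 0.052,
    "ioioo": 0.052,
}

#: Default focused-classification class numbering.
DEFAULT_CLASS_MAP: dict[int, str] = {1: "i", 2: "o"}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_particles: int = 1000
    frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FREQUENCIES)
    )
    label_error_rate: float = 0.0
    seed: int = 0
    n: int = 5
    class_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"configuration frequencies sum to {total}, not 1")
        if not 0.0 <= self.label_error_rate <= 1.0:
            raise ValueError("label_error_rate must lie in [0, 1]")
        for s in self.frequencies:
            if len(s) != self.n:
                raise ValueError(
                    f"configuration {s!r} has length {len(s)}, expected {self.n}"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Hidden state of one synthetic particle."""

    index: int
    configuration: str  # canonical necklace string (particle's intrinsic frame)
    anchor: int  # symmetry copy the simulated consensus refinement locked onto
    orientation: EulerTriple  # true orientation (before anchor composition)

    def observed_labels(self) -> str:
        """Labels in subunit-index order as seen after anchored refinement
        (before any classification error)."""
        return rotate_string(self.configuration, self.anchor)


def _random_euler(rng: np.random.Generator) -> EulerTriple:
    """Uniform random orientation via uniform quaternions, as a ZYZ triple."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    psi, tilt, rot = Rotation.from_quat(q).as_euler("ZYZ", degrees=True)
    return EulerTriple(rot=rot, tilt=tilt, psi=psi)


def sample_dataset(gc: GeneratorConfig) -> tuple[list[GroundTruth], ParticleTable]:
    """Draw a dataset and emit its symmetry-expanded classification table.

    Deterministic given ``gc.seed``.  The table has gc.n records per parent;
    record j of a parent carries the class number of the label observed in
    subunit slot j — the true configuration rotated by the particle's anchor,
    then flipped per subunit with probability ``label_error_rate``.
    """
    rng = np.random.default_rng(gc.seed)
    n, m = gc.n, gc.n_particles
    names = list(gc.frequencies)
    probs = np.array([gc.frequencies[c] for c in names])
    probs = probs / probs.sum()

    config_idx = rng.choice(len(names), size=m, p=probs)
    anchors = rng.integers(0, n, size=m)

    truths = []
    rows = []
    per_mic = 50  # particles per synthetic micrograph
    for i in range(m):
        e_true = _random_euler(rng)
        gt = GroundTruth(
            index=i,
            configuration=names[config_idx[i]],
            anchor=int(anchors[i]),
            orientation=e_true,
        )
        truths.append(gt)
        e_obs = compose_with_operator(e_true, gt.anchor, n)
        rows.append(
            {
                "_rlnMicrographName": f"mic_{i // per_mic:05d}.mrc",
                "_rlnImageName": f"{i % per_mic + 1:06d}@stack_{i // per_mic:05d}.mrcs",
                "_rlnCoordinateX": float(rng.integers(0, 4096)),
                "_rlnCoordinateY": float(rng.integers(0, 4096)),
                "_rlnAngleRot": e_obs.rot,
                "_rlnAngleTilt": e_obs.tilt,
                "_rlnAnglePsi": e_obs.psi,
            }
        )
    parent = ParticleTable(df=pd.DataFrame(rows, columns=list(PARENT_KEY_TAGS) + [
        "_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi"]))

    expanded = symmetry_expand(parent, n)

    alphabet = sorted({ch for c in names for ch in c})
    label_to_class = {v: k for k, v in gc.class_map.items()}
    observed = np.empty(m * n, dtype="<U1")
    for i, gt in enumerate(truths):
        obs = gt.observed_labels()
        observed[i * n : (i + 1) * n] = list(obs)
    if gc.label_error_rate > 0:
        flip = rng.random(m * n) < gc.label_error_rate
        if len(alphabet) == 2:
            other = {alphabet[0]: alphabet[1], alphabet[1]: alphabet[0]}
            observed[flip] = [other[ch] for ch in observed[flip]]
        else:
            for j in np.nonzero(flip)[0]:
                choices = [a for a in alphabet if a != observed[j]]
                observed[j] = choices[rng.integers(0, len(choices))]
    expanded.df[CLASS_TAG] = np.array(
        [label_to_class[ch] for ch in observed], dtype=np.int64
    )
    return truths, expanded


# ---------------------------------------------------------------------------
# toy volumes


@dataclass
class SceneParams:
    """Geometry of the pseudo-Cn toy volume.

    All lengths in angstroms.  Subunit blob k sits at azimuth k*360/n about
    z in the xy-plane, at radius ``r0`` for an ``i`` subunit and ``r0 +
    delta`` for an ``o`` subunit.
    """

    grid_size: int = 64  # voxels per edge
    voxel_size: float = 2.0  # angstrom
    r0: float = 34.0  # blob ring radius
    delta: float = 10.0  # outward displacement of o-state blobs
    sigma_b: float = 6.0  # blob width (Gaussian sigma)
    noise_sigma: float = 1.0  # additive Gaussian noise per voxel (blob peak = 1)
    n: int = 5

    def __post_init__(self):
        half_edge = self.grid_size * self.voxel_size / 2.0
        if self.r0 + self.delta + 3 * self.sigma_b > half_edge:
            raise ValueError(
                "scene does not fit: r0 + delta + 3*sigma_b = "
                f"{self.r0 + self.delta + 3 * self.sigma_b} A exceeds the "
                f"half-edge {half_edge} A"
            )
        if self.delta < 0:
            raise ValueError("delta must be >= 0")

    @property
    def center(self) -> float:
        """Grid center in voxel coordinates."""
        return (self.grid_size - 1) / 2.0

    def blob_centers(self, config: str) -> np.ndarray:
        """Blob centers in angstroms relative to the grid center, one per slot."""
        out = np.zeros((len(config), 3))
        for k, lab in enumerate(config):
            radius = self.r0 + (self.delta if lab == "o" else 0.0)
            az = np.deg2rad(k * 360.0 / len(config))
            out[k] = (radius * np.cos(az), radius * np.sin(az), 0.0)
        return out


def _grid_coords(scene: SceneParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Physical (x, y, z) coordinates in angstrom, centered, indexed [ix,iy,iz]."""
    ax = (np.arange(scene.grid_size) - scene.center) * scene.voxel_size
    return np.meshgrid(ax, ax, ax, indexing="ij")


def build_state_volume(config, scene: SceneParams) -> np.ndarray:
    """Noise-free reference volume of one configuration: a sum of n unit-peak
    isotropic Gaussian blobs with o-state blobs displaced outward.

    ``config`` may be a canonical string or a :class:`Configuration`.
    Axis convention: array index [ix, iy, iz] is physical (x, y, z), so a
    positive rotation about z carries slot 0 (azimuth 0, +x) toward slot 1.
    """
    s = config if isinstance(config, str) else config.canonical
    if len(s) != scene.n:
        raise ValueError(f"configuration {s!r} does not match scene n={scene.n}")
    x, y, z = _grid_coords(scene)
    vol = np.zeros_like(x)
    for cx, cy, cz in scene.blob_centers(s):
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        vol += np.exp(-d2 / (2.0 * scene.sigma_b**2))
    return vol


def rotate_volume(vol: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Rotate a volume about its center: output(x) = vol(R^-1 (x - c) + c).

    Trilinear interpolation; rotations compose so that rotating by R1 then
    R2 equals rotating once by R2 @ R1.
    """
    R = np.asarray(matrix, dtype=float)
    c = (np.array(vol.shape) - 1) / 2.0
    inv = R.T  # orthonormal
    offset = c - inv @ c
    return ndimage.affine_transform(vol, inv, offset=offset, order=1, mode="constant")


def render_particles(
    truths: list[GroundTruth], scene: SceneParams, seed: int = 0
) -> list[np.ndarray]:
    """Render each particle: its state volume rotated by the *true*
    orientation, plus i.i.d. Gaussian voxel noise.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    cache: dict[str, np.ndarray] = {}
    out = []
    for gt in truths:
        if gt.configuration not in cache:
            cache[gt.configuration] = build_state_volume(gt.configuration, scene)
        vol = rotate_volume(cache[gt.configuration], euler_to_matrix(gt.orientation))
        if scene.noise_sigma > 0:
            vol = vol + rng.normal(0.0, scene.noise_sigma, size=vol.shape)
        out.append(vol)
    return out
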