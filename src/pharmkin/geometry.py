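"""Rigid-body alignment and volume-overlap primitives.

Least-squares superposition (Kabsch, proper rotations only) underlies the
site score of the survival function and the fitness score of database
matching.  Volume overlap between two aligned site sets is approximated by
voxelising 1.7-angstrom spheres on a 0.25-angstrom grid and taking the
Jaccard index of the occupied-voxel sets; the abstract site representation
has no atoms, so feature-centred spheres stand in for the heavy-atom van der
Waals model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

#: sphere radius (angstrom) used for abstract-site volume overlap
SITE_RADIUS = 1.7
#: voxel edge (angstrom) of the overlap grid
VOXEL = 0.25


@dataclass
class Alignment:
    """Result of a least-squares rigid superposition ``ref ~ R @ mov + t``."""

    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # 3-vector
    rmsd: float
    pairing: tuple[int, ...] = field(default_factory=tuple)  # ref site i -> mov site pairing[i]
    degenerate: bool = False  # collinear/degenerate point set flag

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        return vectors @ self.rotation.T


def align_to_reference(ref_points: np.ndarray, mov_points: np.ndarray,
                       pairing: tuple[int, ...] | None = None) -> Alignment:
    """Superpose ``mov_points`` onto ``ref_points`` (paired order given).

    Minimises the RMSD over proper rotations and translations.  Requires at
    least 3 points; collinear sets are flagged ``degenerate`` but an optimal
    alignment is still returned.
    """
    ref = np.asarray(ref_points, dtype=float)
    mov = np.asarray(mov_points, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("point sets must be matching k x 3 arrays")
    k = ref.shape[0]
    if k < 3:
        raise ValueError("alignment requires at least 3 paired points")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    # rank < 2 after centering means all points on a line
    degenerate = np.linalg.matrix_rank(ref_c, tol=1e-8) < 2 or np.linalg.matrix_rank(mov_c, tol=1e-8) < 2
    with warnings.catch_warnings():
        if degenerate:  # the degeneracy is reported via the flag instead
            warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(ref_c, mov_c)
    rotation = rot.as_matrix()
    # evaluate the residual directly: the rssd reported by align_vectors is
    # computed by cancellation of large sums and loses ~sqrt(eps) accuracy
    # near zero
    rmsd = float(np.sqrt(np.mean(np.sum((ref_c - mov_c @ rotation.T) ** 2, axis=1))))
    translation = ref.mean(axis=0) - rotation @ mov.mean(axis=0)
    if pairing is None:
        pairing = tuple(range(k))
    return Alignment(rotation=rotation, translation=translation, rmsd=rmsd,
                     pairing=tuple(pairing), degenerate=degenerate)


def pairwise_rmsd(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Minimal RMSD between two paired point sets (symmetric)."""
    return align_to_reference(points_a, points_b).rmsd


def voxelize_spheres(points: np.ndarray, radius: float = SITE_RADIUS,
                     voxel: float = VOXEL) -> frozenset:
    """Occupied-voxel set of a union of spheres on a global grid.

    Voxels are indexed by ``floor(x / voxel)``; a voxel is occupied when its
    centre lies inside any sphere.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return frozenset()
    occupied: set[tuple[int, int, int]] = set()
    r_vox = int(np.ceil(radius / voxel)) + 1
    offs = np.arange(-r_vox, r_vox + 1)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    for p in pts:
        base = np.floor(p / voxel).astype(int)
        cand = base + offsets
        centers = (cand + 0.5) * voxel
        inside = np.sum((centers - p) ** 2, axis=1) <= radius * radius
        occupied.update(map(tuple, cand[inside]))
    return frozenset(occupied)


def volume_jaccard(points_a: np.ndarray, points_b: np.ndarray,
                   radius: float = SITE_RADIUS, voxel: float = VOXEL) -> float:
    """Jaccard overlap of the sphere-union volumes of two point sets."""
    va = voxelize_spheres(points_a, radius, voxel)
    vb = voxelize_spheres(points_b, radius, voxel)
    if not va and not vb:
        return 1.0
    union = len(va | vb)
    return len(va & vb) / union if union else 1.0


def mean_vector_cosine(ref_vectors: np.ndarray, mov_vectors_rotated: np.ndarray,
                       absolute_ring: np.ndarray | None = None) -> float:
    """Mean cosine between corresponding direction vectors.

    ``absolute_ring`` flags positions where the feature direction is an axis
    (ring normals): for those the absolute cosine is used, since a ring plane
    is invariant under normal flip.  Returns 1.0 when there are no vectors.
    """
    ref = np.asarray(ref_vectors, dtype=float)
    mov = np.asarray(mov_vectors_rotated, dtype=float)
    if ref.size == 0:
        return 1.0
    cos = np.sum(ref * mov, axis=1)
    if absolute_ring is not None:
        cos = np.where(np.asarray(absolute_ring, dtype=bool), np.abs(cos), cos)
    return float(np.mean(cos))
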