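"""Fully automatic 3D proptosis measurement on segmented CT labelmaps.

The measurement mirrors CT exophthalmometry against the interzygomatic
line, but picks every landmark in 3D rather than on a single slice (the
zygomatic base points and the corneal apex generally do not share an axial
slice):

1. the *base point* on each side is the most concave point on the
   upper-outer zygomatic bone surface;
2. the *apex slice* is the axial slice where the globe's cross-sectional
   area is largest;
3. the *corneal apex* is the anterior-most globe surface point on that
   slice;
4. the proptosis distance is the perpendicular distance from the apex to
   the interzygomatic line (the line joining the two base points).  The
   default ``in_plane`` convention projects apex and line into the apex's
   axial plane (Hertel-style anteroposterior protrusion); ``full_3d``
   uses the unprojected 3D point-to-line distance.

Concavity is quantified as hull depth: among bone-surface voxels in the
search region (exterior surface only, so hollow bone does not contribute
its inner table), the depth of a point is its distance to the convex hull
of the regional surface patch; the base point is the deepest point, ties
broken by most superior then most lateral.  A surface whose maximal depth
falls below a configurable floor (default 0.5 mm) is rejected as having no
concavity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from . import schema as sc
from .labelmap import LabelMap, Mask

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class ProptometryError(ValueError):
    pass


class DegenerateSurfaceError(ProptometryError):
    """No concavity of sufficient depth exists in the search region."""


@dataclass(frozen=True)
class SearchRegion:
    """Half-space constraints selecting the upper-outer bone surface patch.

    A surface voxel (world point p) is admitted iff ``p_z > z_above`` and
    ``outward * (p_x - x_beyond) > 0``.  ``outward`` is +1 when lateral
    (away from the midline) means +x for the targeted side.
    """

    z_above: float
    x_beyond: float
    outward: int

    @classmethod
    def upper_outer(cls, center, side: str, midline_x: float) -> "SearchRegion":
        """Octant lateral and superior to *center* for the given side.

        *center* is typically the orbital centroid; *midline_x* decides
        which direction is lateral for each side.
        """
        c = np.asarray(center, dtype=float)
        outward = -1 if c[0] < midline_x else 1
        if (side == "left") != (outward == -1):
            # contralateral request: mirror the centroid across the midline
            c = c.copy()
            c[0] = 2 * midline_x - c[0]
            outward = -outward
        return cls(z_above=float(c[2]), x_beyond=float(c[0]), outward=outward)

    def admits(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return (p[:, 2] > self.z_above) & (self.outward * (p[:, 0] - self.x_beyond) > 0)


@dataclass(frozen=True)
class BasePoint:
    point: np.ndarray  # world mm
    depth: float  # concavity depth, mm
    voxel: tuple[int, int, int]


@dataclass(frozen=True)
class ProptosisResult:
    orbit_id: str
    timepoint: str
    left_base: tuple[float, float, float]
    right_base: tuple[float, float, float]
    corneal_apex: tuple[float, float, float]
    apex_slice: int
    distance: float
    convention: str  # "in_plane" | "full_3d"
    posterior_to_line: bool = False

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ProptometryError("distance must be non-negative")


@dataclass(frozen=True)
class ProptosisReduction:
    orbit_id: str
    pre_distance: float
    post_distance: float
    reduction: float


# ---------------------------------------------------------------------------
# base point
# ---------------------------------------------------------------------------


def exterior_surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean array of mask voxels adjacent to exterior (outside-reachable) air.

    Flood-fills the background from the grid boundary, so cavities fully
    enclosed by the mask (e.g., the hollow of a bone shell) are not counted
    as surface.
    """
    background = ~mask
    comp, _ = ndimage.label(background, _STRUCT6)
    border_labels = np.unique(np.concatenate([
        comp[0, :, :].ravel(), comp[-1, :, :].ravel(),
        comp[:, 0, :].ravel(), comp[:, -1, :].ravel(),
        comp[:, :, 0].ravel(), comp[:, :, -1].ravel(),
    ]))
    border_labels = border_labels[border_labels != 0]
    exterior = np.isin(comp, border_labels)
    return mask & ndimage.binary_dilation(exterior, _STRUCT6)


def hull_depths(points: np.ndarray) -> np.ndarray:
    """Depth of each point below the convex hull of the point set (mm).

    Depth is the smallest outward-normal distance to a hull facet plane;
    points on the hull have depth ~0.
    """
    if len(points) < 4:
        raise DegenerateSurfaceError("fewer than 4 surface points in region")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateSurfaceError(f"degenerate surface patch: {exc}") from exc
    eq = hull.equations  # rows (n, d): n.x + d <= 0 inside
    depths = -(points @ eq[:, :3].T + eq[:, 3])
    return np.maximum(depths.min(axis=1), 0.0)


def detect_base_point(bone: Mask, side: str, region: SearchRegion, *,
                      depth_floor: float = 0.5) -> BasePoint:
    """Deepest concavity on the upper-outer bone surface for one side.

    The reported landmark is localized sub-voxel-robustly: voxel-center
    rasterization perturbs individual surface depths by up to half a voxel
    diagonal, so the returned point is the surface voxel closest to the
    depth-weighted centroid of the near-maximal depth plateau (all voxels
    within half a voxel diagonal of the maximum).  Its reported depth is
    the exact plateau maximum.  Ties among equally close voxels go to the
    most superior, then the most lateral.

    Raises :class:`DegenerateSurfaceError` if the region holds no surface
    or its maximal hull depth is below ``depth_floor`` (mm).
    """
    if side not in ("left", "right"):
        raise ProptometryError("side must be 'left' or 'right'")
    surf = exterior_surface_voxels(bone.data)
    idx = np.argwhere(surf)
    if idx.size == 0:
        raise DegenerateSurfaceError("bone mask has no exterior surface")
    pts = bone.world_points(idx)
    keep = region.admits(pts)
    idx, pts = idx[keep], pts[keep]
    if len(idx) == 0:
        raise DegenerateSurfaceError("search region contains no bone surface")

    depths = hull_depths(pts)
    dmax = float(depths.max())
    if dmax < depth_floor:
        raise DegenerateSurfaceError(
            f"maximal concavity depth {dmax:.3f} mm below floor {depth_floor} mm"
        )
    plateau_tol = 0.5 * float(np.linalg.norm(bone.spacing))
    plateau = np.flatnonzero(depths >= dmax - plateau_tol)
    w = depths[plateau]
    target = (pts[plateau] * w[:, None]).sum(axis=0) / w.sum()
    dist = np.linalg.norm(pts[plateau] - target, axis=1)
    # nearest to the plateau centroid; ties most superior, then most lateral
    tied = plateau[np.isclose(dist, dist.min(), rtol=0, atol=1e-9)]
    cand = pts[tied]
    order = np.lexsort((region.outward * cand[:, 0], cand[:, 2]))
    best = tied[order[-1]]
    return BasePoint(point=pts[best], depth=dmax, voxel=tuple(int(i) for i in idx[best]))


# ---------------------------------------------------------------------------
# corneal apex
# ---------------------------------------------------------------------------


def find_apex_slice(globe: Mask) -> int:
    """Axial slice index (axis 2) with the largest globe cross-section.

    Ties are resolved to the median index of the longest maximal run.
    """
    counts = np.count_nonzero(globe.data, axis=(0, 1))
    if counts.max() == 0:
        raise ProptometryError("globe mask is empty")
    tied = np.flatnonzero(counts == counts.max())
    # split tied indices into consecutive runs, keep the longest
    runs = np.split(tied, np.flatnonzero(np.diff(tied) > 1) + 1)
    run = max(runs, key=len)
    return int(run[(len(run) - 1) // 2])


def corneal_apex(globe: Mask, slice_index: int) -> np.ndarray:
    """Anterior-most globe surface point (world mm) on one axial slice.

    Ties along the anterior axis go to the voxel laterally closest to the
    globe centroid (then to the lower x index, for determinism).
    """
    plane = globe.data[:, :, slice_index]
    if not plane.any():
        raise ProptometryError(f"globe absent on slice {slice_index}")
    ii, jj = np.nonzero(plane)
    j_max = jj.max()
    tied_i = np.sort(ii[jj == j_max])
    centroid_i = np.argwhere(globe.data)[:, 0].mean()
    best_i = tied_i[np.argmin(np.abs(tied_i - centroid_i), )]
    idx = np.array([best_i, j_max, slice_index])
    return globe.world_points(idx)


# ---------------------------------------------------------------------------
# distance
# ---------------------------------------------------------------------------


def proptosis_distance(apex, left_base, right_base, convention: str = "in_plane",
                       *, signed: bool = False) -> float:
    """Perpendicular distance (mm) from the corneal apex to the
    interzygomatic line.

    ``in_plane`` drops the superior coordinate (projection into the apex's
    axial plane) before taking the 2D point-to-line distance; ``full_3d``
    is the perpendicular distance to the 3D line.  With ``signed=True`` the
    in-plane distance is positive anterior to the line and negative
    posterior (enophthalmos).
    """
    a = np.asarray(apex, dtype=float)
    b1 = np.asarray(left_base, dtype=float)
    b2 = np.asarray(right_base, dtype=float)
    if np.allclose(b1, b2):
        raise ProptometryError("base points coincide")
    if convention == "in_plane":
        d = (b2 - b1)[:2]
        n = np.array([-d[1], d[0]])  # in-plane normal
        if n[1] < 0 or (n[1] == 0 and n[0] < 0):
            n = -n  # orient the normal anterior
        val = float(n @ (a[:2] - b1[:2]) / np.linalg.norm(n))
        return val if signed else abs(val)
    if convention == "full_3d":
        d = b2 - b1
        val = float(np.linalg.norm(np.cross(a - b1, d)) / np.linalg.norm(d))
        if signed:
            # sign by the anterior component of the perpendicular foot offset
            t = (a - b1) @ d / (d @ d)
            perp = a - (b1 + t * d)
            return val if perp[1] >= 0 else -val
        return val
    raise ProptometryError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------


def _smooth_globe(mask: Mask) -> Mask:
    """1-voxel morphological opening+closing to suppress boundary speckle."""
    data = ndimage.binary_opening(mask.data, _STRUCT6)
    data = ndimage.binary_closing(data, _STRUCT6)
    if not data.any():  # degenerate tiny globe: keep the raw mask
        return mask
    return Mask(data, mask.spacing, mask.origin)


def measure_proptosis(labelmap: LabelMap, *, orbit_id: str = "orbit",
                      timepoint: str = "pre", convention: str = "in_plane",
                      depth_floor: float = 0.5,
                      search_regions: Optional[dict[str, SearchRegion]] = None,
                      ) -> ProptosisResult:
    """Run the full automatic proptosis measurement on one labelmap.

    The labelmap must contain bilateral bone and the measured globe.
    Search regions for the base points default to the upper-outer octants
    relative to the orbital centroid (mirrored across the bone midline for
    the contralateral side); pass ``search_regions`` to override.
    """
    bone = labelmap.organ_mask(sc.BONE)
    globe = labelmap.organ_mask(sc.GLOBE)
    if not bone.data.any():
        raise ProptometryError("bone mask is empty")
    if not globe.data.any():
        raise ProptometryError("globe mask is empty")

    if search_regions is None:
        orbit_roles = [sc.ORBITAL_CAVITY] + [r for r in sc.SOFT_TISSUE_ROLES
                                             if r in labelmap.schema.roles]
        orbit_idx = np.argwhere(labelmap.union_mask(orbit_roles).data)
        center = Mask(bone.data, bone.spacing, bone.origin).world_points(
            orbit_idx).mean(axis=0) if len(orbit_idx) else np.asarray(labelmap.origin)
        bone_idx = np.argwhere(bone.data)
        midline_x = float(bone.world_points(bone_idx)[:, 0].mean())
        search_regions = {
            s: SearchRegion.upper_outer(center, s, midline_x)
            for s in ("left", "right")
        }

    bases = {s: detect_base_point(bone, s, search_regions[s], depth_floor=depth_floor)
             for s in ("left", "right")}

    globe_s = _smooth_globe(globe)
    apex_slice = find_apex_slice(globe_s)
    apex = corneal_apex(globe_s, apex_slice)

    signed = proptosis_distance(apex, bases["left"].point, bases["right"].point,
                                convention, signed=True)
    return ProptosisResult(
        orbit_id=orbit_id,
        timepoint=timepoint,
        left_base=tuple(map(float, bases["left"].point)),
        right_base=tuple(map(float, bases["right"].point)),
        corneal_apex=tuple(map(float, apex)),
        apex_slice=apex_slice,
        distance=abs(signed),
        convention=convention,
        posterior_to_line=signed < 0,
    )


def proptosis_reduction(pre: ProptosisResult, post: ProptosisResult) -> ProptosisReduction:
    """Pre-minus-post proptosis distance; positive means globe retraction."""
    if pre.orbit_id != post.orbit_id:
        raise ProptometryError("orbit identifiers differ")
    if pre.convention != post.convention:
        raise ProptometryError("conventions differ between timepoints")
    return ProptosisReduction(
        orbit_id=pre.orbit_id,
        pre_distance=pre.distance,
        post_distance=post.distance,
        reduction=pre.distance - post.distance,
    )
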