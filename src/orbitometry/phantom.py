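"""Synthetic orbital phantoms with closed-form ground truth.

The phantom emulates the labelmaps an orbital segmentation pipeline would
produce for one orbit before and after bony wall decompression, on a
bilateral bone scene:

* the orbital cavity is a truncated cone (apex posterior, base anterior),
* the globe is a sphere protruding anterior to the interzygomatic line,
* the four rectus muscles are axis-parallel cylinders near the orbital apex,
  with independent pre/post radii to model post-decompression expansion,
* the optic nerve (optional) is a thin cylinder on the orbital axis,
* bone comprises two zygomatic spherical shells — one per side, each with a
  hemispherically machined notch on its upper-outer surface (the base-point
  target) — plus, preoperatively, a medial wall slab,
* decompression is modelled by deleting the wall slab and annexing its box
  to the cavity (the herniation space), so the removed volume is an exact
  box volume.

Every measured quantity (volumes, IREOV, base points, corneal apex,
proptosis distance and reduction) has a closed-form value recorded in
:class:`PhantomTruth` before rasterization.  Rasterization uses the
voxel-center rule (a voxel belongs to a solid iff its center lies inside),
with priority bone > globe > muscles > optic nerve > cavity.  Boundary
noise, modelling segmentation jitter, flips voxels on soft-tissue surface
shells only, driven by a seeded generator, so a fixed spec + seed is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import schema as sc
from .labelmap import LabelMap, Mask


class PhantomSpecError(ValueError):
    """Phantom geometry is inconsistent or does not fit the grid."""


def _default_pre_radii() -> dict[str, float]:
    return {r: 2.5 for r in sc.RECTUS_ROLES}


def _default_post_radii() -> dict[str, float]:
    # medial rectus expands the most, mirroring the dominant post-surgical
    # change after medial wall decompression
    d = {r: 2.6 for r in sc.RECTUS_ROLES}
    d[sc.MEDIAL_RECTUS] = 3.0
    return d


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric geometry of a pre/post orbital phantom pair (world mm).

    Defaults describe an adult-scale left orbit on a 140 x 75 x 60 mm grid
    at 0.5 mm isotropic spacing: a ~22 cm^3 bony cavity, an 11 mm-radius
    globe ~18.5 mm anterior to the interzygomatic line, ~0.12 cm^3 recti,
    a 3.1 cm^3 medial wall removal (truth IREOV 0.14 with the default
    muscle expansion) and a 3 mm programmed globe retraction.
    """

    shape: tuple[int, int, int] = (280, 150, 120)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    side: str = "left"

    # orbital cavity: truncated cone along +y (anterior)
    orbit_axis_x: float = 52.0
    orbit_axis_z: float = 28.0
    cone_apex_y: float = 8.0
    cone_depth: float = 45.0
    cone_apex_radius: float = 6.0
    cone_base_radius: float = 18.0

    # globe
    globe_center_y: float = 41.0
    globe_radius: float = 11.0
    #: pre -> post globe shift along the anterior axis; negative = retraction
    globe_displacement: float = -3.0

    # rectus muscles: axis-parallel cylinders at a radial offset from the
    # orbital axis (medial/lateral/inferior/superior directions)
    muscle_span: tuple[float, float] = (18.0, 24.0)
    muscle_offset: float = 5.5
    muscle_radii_pre: dict[str, float] = field(default_factory=_default_pre_radii)
    muscle_radii_post: dict[str, float] = field(default_factory=_default_post_radii)

    include_optic_nerve: bool = True
    nerve_radius: float = 1.5
    nerve_span: tuple[float, float] = (12.0, 18.0)

    # bilateral zygomatic shells; given for the left side, mirrored for the
    # right about the grid's midsagittal plane
    zygoma_center: tuple[float, float, float] = (24.0, 32.0, 30.0)
    zygoma_radius: float = 9.0
    zygoma_thickness: float = 5.0
    notch_direction: tuple[float, float, float] = (-0.6, 0.3, 0.75)
    notch_radius: float = 4.0

    #: medial wall slab removed by decompression: ((x0,x1),(y0,y1),(z0,z1));
    #: None models a surgery with no bony wall removal
    wall_box: tuple[tuple[float, float], ...] | None = (
        (69.5, 75.5), (24.0, 50.0), (18.0, 38.0),
    )

    #: probability of flipping a soft-tissue surface-shell voxel
    boundary_noise: float = 0.05

    # ------------------------------------------------------------------

    @property
    def midline_x(self) -> float:
        return self.origin[0] + (self.shape[0] - 1) * self.spacing[0] / 2.0

    def _mirror(self, x: float) -> float:
        return 2.0 * self.midline_x - x

    @property
    def axis_x(self) -> float:
        """Orbital axis x in world mm, honouring the side."""
        return self.orbit_axis_x if self.side == "left" else self._mirror(self.orbit_axis_x)

    @property
    def medial_sign(self) -> float:
        """+1 if medial (toward midline) is +x for this orbit."""
        return 1.0 if self.side == "left" else -1.0

    def cone_radius(self, y) -> np.ndarray:
        """Cavity cross-sectional radius at anterior coordinate *y* (mm)."""
        t = (np.asarray(y, dtype=float) - self.cone_apex_y) / self.cone_depth
        return self.cone_apex_radius + (self.cone_base_radius - self.cone_apex_radius) * t

    def globe_center(self, timepoint: str) -> np.ndarray:
        y = self.globe_center_y + (self.globe_displacement if timepoint == "post" else 0.0)
        return np.array([self.axis_x, y, self.orbit_axis_z])

    def muscle_direction(self, role: str) -> np.ndarray:
        """Unit xz-plane direction from the orbital axis to a muscle."""
        s = self.medial_sign
        return {
            sc.MEDIAL_RECTUS: np.array([s, 0.0, 0.0]),
            sc.LATERAL_RECTUS: np.array([-s, 0.0, 0.0]),
            sc.INFERIOR_RECTUS: np.array([0.0, 0.0, -1.0]),
            sc.SUPERIOR_RECTUS_LEVATOR: np.array([0.0, 0.0, 1.0]),
        }[role]

    def muscle_center_xz(self, role: str) -> tuple[float, float]:
        d = self.muscle_direction(role)
        return (self.axis_x + self.muscle_offset * d[0],
                self.orbit_axis_z + self.muscle_offset * d[2])

    def zygoma_centers(self) -> dict[str, np.ndarray]:
        # the zygoma pair is symmetric about the midsagittal plane
        c = np.asarray(self.zygoma_center, dtype=float)
        x_other = self._mirror(c[0])
        lx, rx = min(c[0], x_other), max(c[0], x_other)
        return {
            "left": np.array([lx, c[1], c[2]]),
            "right": np.array([rx, c[1], c[2]]),
        }

    def notch_units(self) -> dict[str, np.ndarray]:
        u = np.asarray(self.notch_direction, dtype=float)
        u = u / np.linalg.norm(u)
        ul = u.copy()
        ul[0] = -abs(u[0])  # left outer = -x
        ur = u.copy()
        ur[0] = abs(u[0])
        return {"left": ul, "right": ur}

    def wall_box_bounds(self) -> tuple[tuple[float, float], ...] | None:
        if self.wall_box is None:
            return None
        (x0, x1), yb, zb = self.wall_box
        if self.side == "right":
            x0, x1 = sorted((self._mirror(x0), self._mirror(x1)))
        return ((x0, x1), yb, zb)

    # -- analytic volumes ---------------------------------------------

    def cavity_volume(self) -> float:
        r, R, h = self.cone_apex_radius, self.cone_base_radius, self.cone_depth
        return math.pi * h / 3.0 * (R * R + R * r + r * r)

    def wall_removed_volume(self) -> float:
        if self.wall_box is None:
            return 0.0
        return float(np.prod([hi - lo for lo, hi in self.wall_box]))

    def muscle_volume(self, role: str, timepoint: str) -> float:
        radii = self.muscle_radii_post if timepoint == "post" else self.muscle_radii_pre
        length = self.muscle_span[1] - self.muscle_span[0]
        return math.pi * radii[role] ** 2 * length

    def globe_volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.globe_radius ** 3

    def nerve_volume(self) -> float:
        if not self.include_optic_nerve:
            return 0.0
        return math.pi * self.nerve_radius ** 2 * (self.nerve_span[1] - self.nerve_span[0])

    def base_points(self) -> dict[str, np.ndarray]:
        """Deepest machined-notch points (the analytic base points)."""
        centers = self.zygoma_centers()
        units = self.notch_units()
        d = self.zygoma_radius - self.notch_radius
        return {s: centers[s] + d * units[s] for s in ("left", "right")}

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        sp = np.asarray(self.spacing)
        if np.any(sp <= 0):
            raise PhantomSpecError("spacing must be positive")
        if self.side not in ("left", "right"):
            raise PhantomSpecError("side must be 'left' or 'right'")
        for name, v in [
            ("cone_apex_radius", self.cone_apex_radius),
            ("cone_base_radius", self.cone_base_radius),
            ("cone_depth", self.cone_depth),
            ("globe_radius", self.globe_radius),
            ("zygoma_radius", self.zygoma_radius),
            ("zygoma_thickness", self.zygoma_thickness),
            ("notch_radius", self.notch_radius),
            ("nerve_radius", self.nerve_radius),
        ]:
            if v <= 0:
                raise PhantomSpecError(f"{name} must be > 0")
        if not 0.0 <= self.boundary_noise < 1.0:
            raise PhantomSpecError("boundary_noise must be in [0, 1)")
        if self.notch_radius >= self.zygoma_thickness:
            raise PhantomSpecError(
                "notch would pierce the zygomatic shell "
                "(notch_radius must be < zygoma_thickness)"
            )

        extent = np.asarray(self.origin) + (np.asarray(self.shape) - 1) * sp
        lo = np.asarray(self.origin)

        def inside(pt, margin=1.0):
            p = np.asarray(pt)
            return np.all(p >= lo + margin) and np.all(p <= extent - margin)

        # cone within grid
        base_y = self.cone_apex_y + self.cone_depth
        R = self.cone_base_radius
        ax, az = self.axis_x, self.orbit_axis_z
        for pt in [(ax - R, base_y, az), (ax + R, base_y, az),
                   (ax, base_y, az - R), (ax, base_y, az + R),
                   (ax, self.cone_apex_y, az)]:
            if not inside(pt):
                raise PhantomSpecError("orbital cavity does not fit inside the grid")

        # globe inside cone at both timepoints (slice-wise containment)
        for tp in ("pre", "post"):
            c = self.globe_center(tp)
            ys = np.linspace(c[1] - self.globe_radius, c[1] + self.globe_radius, 101)
            cross = np.sqrt(np.maximum(self.globe_radius ** 2 - (ys - c[1]) ** 2, 0.0))
            if ys[0] < self.cone_apex_y or ys[-1] > base_y:
                raise PhantomSpecError(f"globe ({tp}) extends beyond the cavity cone")
            if np.any(cross > self.cone_radius(ys) + 1e-9):
                raise PhantomSpecError(f"globe ({tp}) pierces the cavity wall")

        # muscles inside cone, posterior to both globe positions, disjoint
        y0, y1 = self.muscle_span
        if not self.cone_apex_y <= y0 < y1 <= base_y:
            raise PhantomSpecError("muscle_span outside the cavity cone")
        globe_min_y = min(self.globe_center(tp)[1] for tp in ("pre", "post")) - self.globe_radius
        if y1 > globe_min_y + 1e-9:
            raise PhantomSpecError("muscles overlap the globe (shorten muscle_span)")
        for role in sc.RECTUS_ROLES:
            rmax = max(self.muscle_radii_pre[role], self.muscle_radii_post[role])
            if rmax <= 0:
                raise PhantomSpecError(f"muscle radius for {role} must be > 0")
            if self.muscle_offset + rmax > min(self.cone_radius(y0), self.cone_radius(y1)) + 1e-9:
                raise PhantomSpecError(f"muscle {role} pierces the cavity wall")
            if self.include_optic_nerve and self.muscle_offset - rmax < self.nerve_radius - 1e-9:
                raise PhantomSpecError(f"muscle {role} overlaps the optic nerve")
        pairs = [(a, b) for i, a in enumerate(sc.RECTUS_ROLES)
                 for b in sc.RECTUS_ROLES[i + 1:]]
        for a, b in pairs:
            pa, pb = self.muscle_center_xz(a), self.muscle_center_xz(b)
            gap = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
            ra = max(self.muscle_radii_pre[a], self.muscle_radii_post[a])
            rb = max(self.muscle_radii_pre[b], self.muscle_radii_post[b])
            if gap < ra + rb - 1e-9:
                raise PhantomSpecError(f"muscles {a} and {b} overlap")

        if self.include_optic_nerve:
            n0, n1 = self.nerve_span
            if not self.cone_apex_y <= n0 < n1 <= base_y:
                raise PhantomSpecError("nerve_span outside the cavity cone")
            if self.nerve_radius > min(self.cone_radius(n0), self.cone_radius(n1)):
                raise PhantomSpecError("optic nerve pierces the cavity wall")

        # wall slab: disjoint from the cone, inside the grid
        bounds = self.wall_box_bounds()
        if bounds is not None:
            (x0, x1), (wy0, wy1), (z0, z1) = bounds
            if not (x0 < x1 and wy0 < wy1 and z0 < z1):
                raise PhantomSpecError("wall_box bounds must be ordered")
            if not (inside((x0, wy0, z0), 0.0) and inside((x1, wy1, z1), 0.0)):
                raise PhantomSpecError("wall_box does not fit inside the grid")
            oy0, oy1 = max(wy0, self.cone_apex_y), min(wy1, base_y)
            if oy0 < oy1:  # y-overlap with the cone: need xz clearance
                dx = max(x0 - ax, ax - x1, 0.0)
                dz = max(z0 - az, az - z1, 0.0)
                if math.hypot(dx, dz) < float(self.cone_radius(oy1)) - 1e-9:
                    raise PhantomSpecError("wall_box overlaps the cavity cone")

        # zygomas: clear of cone, wall box and grid edge
        for s, c in self.zygoma_centers().items():
            if not inside(c - self.zygoma_radius) or not inside(c + self.zygoma_radius):
                raise PhantomSpecError(f"{s} zygoma does not fit inside the grid")
            radial = math.hypot(c[0] - ax, c[2] - az)
            if radial < self.cone_base_radius + self.zygoma_radius - 1e-9:
                raise PhantomSpecError(f"{s} zygoma overlaps the cavity cone")
            if bounds is not None:
                dx = max(x0 - c[0], c[0] - x1, 0.0)
                dy = max(wy0 - c[1], c[1] - wy1, 0.0)
                dz = max(z0 - c[2], c[2] - z1, 0.0)
                if math.sqrt(dx * dx + dy * dy + dz * dz) < self.zygoma_radius - 1e-9:
                    raise PhantomSpecError(f"{s} zygoma overlaps the wall slab")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        kw = dict(d)
        for key in ("shape", "spacing", "origin", "muscle_span", "nerve_span",
                    "zygoma_center", "notch_direction"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if kw.get("wall_box") is not None:
            kw["wall_box"] = tuple(tuple(b) for b in kw["wall_box"])
        return cls(**kw)


@dataclass(frozen=True)
class PhantomTruth:
    """Closed-form ground truth for every quantity the package measures."""

    orbital_volume_pre: float
    orbital_volume_post: float
    wall_removed_volume: float
    organ_volumes_pre: dict[str, float]
    organ_volumes_post: dict[str, float]
    globe_volume: float
    nerve_volume: float
    ireov: float
    muscle_delta: dict[str, float]
    base_points: dict[str, tuple[float, float, float]]
    corneal_apex_pre: tuple[float, float, float]
    corneal_apex_post: tuple[float, float, float]
    proptosis_distance_pre: float
    proptosis_distance_post: float
    proptosis_reduction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# rasterization primitives (voxel-center rule)
# ---------------------------------------------------------------------------


def _grid_coords(shape, spacing, origin):
    xs = origin[0] + np.arange(shape[0]) * spacing[0]
    ys = origin[1] + np.arange(shape[1]) * spacing[1]
    zs = origin[2] + np.arange(shape[2]) * spacing[2]
    return xs, ys, zs


def _bbox_slices(shape, spacing, origin, lo, hi, pad=1):
    """Grid slices covering world box [lo, hi] with *pad* extra voxels."""
    sl = []
    for ax in range(3):
        i0 = int(np.floor((lo[ax] - origin[ax]) / spacing[ax])) - pad
        i1 = int(np.ceil((hi[ax] - origin[ax]) / spacing[ax])) + pad + 1
        sl.append(slice(max(i0, 0), min(i1, shape[ax])))
    return tuple(sl)


def ball_mask(shape, spacing, center, radius, origin=(0.0, 0.0, 0.0)) -> Mask:
    """Rasterize a solid sphere by the voxel-center rule."""
    xs, ys, zs = _grid_coords(shape, spacing, origin)
    m = ((xs[:, None, None] - center[0]) ** 2
         + (ys[None, :, None] - center[1]) ** 2
         + (zs[None, None, :] - center[2]) ** 2) <= radius ** 2
    return Mask(m, tuple(spacing), tuple(origin))


def cylinder_y_mask(shape, spacing, center_xz, radius, y_span,
                    origin=(0.0, 0.0, 0.0)) -> Mask:
    """Rasterize a y-axis-aligned cylinder; the y interval is half-open."""
    xs, ys, zs = _grid_coords(shape, spacing, origin)
    radial = ((xs[:, None, None] - center_xz[0]) ** 2
              + (zs[None, None, :] - center_xz[1]) ** 2) <= radius ** 2
    inside_y = (ys[None, :, None] >= y_span[0]) & (ys[None, :, None] < y_span[1])
    return Mask(radial & inside_y, tuple(spacing), tuple(origin))


class _Raster:
    """Label canvas with bbox-restricted solid painting."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.labels = np.zeros(spec.shape, dtype=np.int16)
        self.xs, self.ys, self.zs = _grid_coords(spec.shape, spec.spacing, spec.origin)

    def _paint(self, sl, mask, label):
        region = self.labels[sl]
        region[mask] = label
        self.labels[sl] = region

    def _local(self, sl):
        return (self.xs[sl[0]][:, None, None],
                self.ys[sl[1]][None, :, None],
                self.zs[sl[2]][None, None, :])

    def _slices(self, lo, hi):
        s = self.spec
        return _bbox_slices(s.shape, s.spacing, s.origin, lo, hi)

    def frustum(self, label):
        s = self.spec
        R = s.cone_base_radius
        lo = (s.axis_x - R, s.cone_apex_y, s.orbit_axis_z - R)
        hi = (s.axis_x + R, s.cone_apex_y + s.cone_depth, s.orbit_axis_z + R)
        sl = self._slices(lo, hi)
        X, Y, Z = self._local(sl)
        ok_y = (Y >= s.cone_apex_y) & (Y < s.cone_apex_y + s.cone_depth)
        r = s.cone_radius(Y)
        mask = ok_y & (((X - s.axis_x) ** 2 + (Z - s.orbit_axis_z) ** 2) <= r * r)
        self._paint(sl, mask, label)

    def box(self, bounds, label):
        (x0, x1), (y0, y1), (z0, z1) = bounds
        sl = self._slices((x0, y0, z0), (x1, y1, z1))
        X, Y, Z = self._local(sl)
        mask = ((X >= x0) & (X < x1) & (Y >= y0) & (Y < y1) & (Z >= z0) & (Z < z1))
        self._paint(sl, mask, label)

    def ball(self, center, radius, label):
        c = np.asarray(center, dtype=float)
        sl = self._slices(c - radius, c + radius)
        X, Y, Z = self._local(sl)
        mask = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2) <= radius ** 2
        self._paint(sl, mask, label)

    def cylinder_y(self, center_xz, radius, y_span, label):
        lo = (center_xz[0] - radius, y_span[0], center_xz[1] - radius)
        hi = (center_xz[0] + radius, y_span[1], center_xz[1] + radius)
        sl = self._slices(lo, hi)
        X, Y, Z = self._local(sl)
        mask = (((X - center_xz[0]) ** 2 + (Z - center_xz[1]) ** 2) <= radius ** 2) \
            & (Y >= y_span[0]) & (Y < y_span[1])
        self._paint(sl, mask, label)

    def notched_shell(self, center, radius, thickness, notch_center, notch_radius, label):
        c = np.asarray(center, dtype=float)
        sl = self._slices(c - radius, c + radius)
        X, Y, Z = self._local(sl)
        d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
        shell = (d2 <= radius ** 2) & (d2 > (radius - thickness) ** 2)
        n = np.asarray(notch_center, dtype=float)
        notch = ((X - n[0]) ** 2 + (Y - n[1]) ** 2 + (Z - n[2]) ** 2) <= notch_radius ** 2
        self._paint(sl, shell & ~notch, label)


# ---------------------------------------------------------------------------
# boundary noise
# ---------------------------------------------------------------------------

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _mask_bbox(mask, shape, pad=2):
    idx = np.argwhere(mask)
    if idx.size == 0:
        return None
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, shape)
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def _flip_boundary(labels, label_a, label_b, p, rng):
    """Flip voxels on the a/b interface shell with probability *p* each.

    Voxels of *label_a* adjacent to *label_b* may become *label_b* and vice
    versa; other labels are never touched.  Models segmentation jitter.
    """
    if p <= 0:
        return
    bbox = _mask_bbox(labels == label_a, labels.shape)
    if bbox is None:
        return
    region = labels[bbox]
    a = region == label_a
    b = region == label_b
    shell_a = a & ndimage.binary_dilation(b, _STRUCT6)
    shell_b = b & ndimage.binary_dilation(a, _STRUCT6)
    ia = np.argwhere(shell_a)
    ib = np.argwhere(shell_b)
    fa = rng.random(len(ia)) < p
    fb = rng.random(len(ib)) < p
    for (i, j, k) in ia[fa]:
        region[i, j, k] = label_b
    for (i, j, k) in ib[fb]:
        region[i, j, k] = label_a
    labels[bbox] = region


def _apply_noise(labels, spec: PhantomSpec, schema: sc.LabelSchema, rng):
    """Seeded surface jitter on soft-tissue boundaries (bone untouched)."""
    p = spec.boundary_noise
    cav = schema.label(sc.ORBITAL_CAVITY)
    order = [sc.GLOBE, *sc.RECTUS_ROLES]
    if spec.include_optic_nerve:
        order.append(sc.OPTIC_NERVE)
    for role in order:
        _flip_boundary(labels, schema.label(role), cav, p, rng)
    _flip_boundary(labels, cav, 0, p, rng)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _point_line_distance_2d(p, a, b) -> float:
    p, a, b = (np.asarray(v, dtype=float)[:2] for v in (p, a, b))
    d = b - a
    return float(abs(d[0] * (p[1] - a[1]) - d[1] * (p[0] - a[0])) / np.linalg.norm(d))


def _build_truth(spec: PhantomSpec) -> PhantomTruth:
    v_orb_pre = spec.cavity_volume()
    dv = spec.wall_removed_volume()
    v_orb_post = v_orb_pre + dv
    org_pre = {r: spec.muscle_volume(r, "pre") for r in sc.RECTUS_ROLES}
    org_post = {r: spec.muscle_volume(r, "post") for r in sc.RECTUS_ROLES}
    eff_pre = v_orb_pre - sum(org_pre.values())
    eff_post = v_orb_post - sum(org_post.values())
    ireov = (eff_post - eff_pre) / v_orb_pre

    bps = spec.base_points()
    apex_pre = spec.globe_center("pre") + np.array([0.0, spec.globe_radius, 0.0])
    apex_post = spec.globe_center("post") + np.array([0.0, spec.globe_radius, 0.0])
    d_pre = _point_line_distance_2d(apex_pre, bps["left"], bps["right"])
    d_post = _point_line_distance_2d(apex_post, bps["left"], bps["right"])

    return PhantomTruth(
        orbital_volume_pre=v_orb_pre,
        orbital_volume_post=v_orb_post,
        wall_removed_volume=dv,
        organ_volumes_pre=org_pre,
        organ_volumes_post=org_post,
        globe_volume=spec.globe_volume(),
        nerve_volume=spec.nerve_volume(),
        ireov=ireov,
        muscle_delta={r: org_post[r] - org_pre[r] for r in sc.RECTUS_ROLES},
        base_points={s: tuple(map(float, p)) for s, p in bps.items()},
        corneal_apex_pre=tuple(map(float, apex_pre)),
        corneal_apex_post=tuple(map(float, apex_post)),
        proptosis_distance_pre=d_pre,
        proptosis_distance_post=d_post,
        proptosis_reduction=d_pre - d_post,
    )


def _rasterize(spec: PhantomSpec, timepoint: str, schema: sc.LabelSchema) -> np.ndarray:
    canvas = _Raster(spec)
    lab = schema.label

    # lowest priority first; later structures overwrite
    canvas.frustum(lab(sc.ORBITAL_CAVITY))
    bounds = spec.wall_box_bounds()
    if timepoint == "post" and bounds is not None:
        canvas.box(bounds, lab(sc.ORBITAL_CAVITY))
    if spec.include_optic_nerve:
        canvas.cylinder_y((spec.axis_x, spec.orbit_axis_z), spec.nerve_radius,
                          spec.nerve_span, lab(sc.OPTIC_NERVE))
    radii = spec.muscle_radii_post if timepoint == "post" else spec.muscle_radii_pre
    for role in sc.RECTUS_ROLES:
        canvas.cylinder_y(spec.muscle_center_xz(role), radii[role],
                          spec.muscle_span, lab(role))
    canvas.ball(spec.globe_center(timepoint), spec.globe_radius, lab(sc.GLOBE))

    centers = spec.zygoma_centers()
    units = spec.notch_units()
    for s in ("left", "right"):
        notch_center = centers[s] + spec.zygoma_radius * units[s]
        canvas.notched_shell(centers[s], spec.zygoma_radius, spec.zygoma_thickness,
                             notch_center, spec.notch_radius, lab(sc.BONE))
    if timepoint == "pre" and bounds is not None:
        canvas.box(bounds, lab(sc.BONE))
    return canvas.labels


def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[LabelMap, LabelMap, PhantomTruth]:
    """Generate a (pre, post) labelmap pair and its analytic ground truth.

    A fixed ``spec`` and ``seed`` reproduce the voxel arrays bit-exactly.
    """
    spec.validate()
    schema = sc.default_schema(side=spec.side)
    truth = _build_truth(spec)
    rng = np.random.default_rng(seed)

    maps = []
    for tp in ("pre", "post"):
        labels = _rasterize(spec, tp, schema)
        _apply_noise(labels, spec, schema, rng)
        maps.append(LabelMap(labels, spec.spacing, spec.origin, schema))
    return maps[0], maps[1], truth


def rasterization_error_report(spec: PhantomSpec, pre: LabelMap, post: LabelMap) -> pd.DataFrame:
    """Per-structure relative volume error of the rasterized phantom.

    Rows give ``|voxel volume - analytic volume| / analytic volume`` per
    structure and timepoint; structures with zero analytic volume report NaN.
    """
    rows = []
    for tp, lm in (("pre", pre), ("post", post)):
        vv = lm.voxel_volume
        soft = [sc.ORBITAL_CAVITY, sc.GLOBE, *sc.RECTUS_ROLES]
        if spec.include_optic_nerve:
            soft.append(sc.OPTIC_NERVE)
        orb_measured = float(np.count_nonzero(
            np.isin(lm.data, [lm.schema.label(r) for r in soft]))) * vv
        orb_true = spec.cavity_volume() + (spec.wall_removed_volume() if tp == "post" else 0.0)
        entries = [("orbital_volume", orb_true, orb_measured),
                   (sc.GLOBE, spec.globe_volume(),
                    float(np.count_nonzero(lm.data == lm.schema.label(sc.GLOBE))) * vv)]
        for role in sc.RECTUS_ROLES:
            entries.append((role, spec.muscle_volume(role, tp),
                            float(np.count_nonzero(lm.data == lm.schema.label(role))) * vv))
        if spec.include_optic_nerve:
            entries.append((sc.OPTIC_NERVE, spec.nerve_volume(),
                            float(np.count_nonzero(lm.data == lm.schema.label(sc.OPTIC_NERVE))) * vv))
        for name, true, measured in entries:
            rel = abs(measured - true) / true if true > 0 else float("nan")
            rows.append({"structure": name, "timepoint": tp,
                         "analytic_mm3": true, "measured_mm3": measured,
                         "relative_error": rel})
    return pd.DataFrame(rows)


def random_spec(rng: np.random.Generator, *, muscles_changed: bool = True,
                **overrides) -> PhantomSpec:
    """Draw a valid randomized spec around the default geometry.

    Randomizes the removed-wall slab (snapped to the voxel lattice so its
    analytic volume is attained exactly), the programmed globe retraction
    and, unless ``muscles_changed`` is false, the post-operative muscle
    radii.
    """
    h = 0.5

    def snap(v):
        return round(v / h) * h

    x0 = snap(rng.uniform(69.5, 70.5))
    x1 = x0 + snap(rng.uniform(4.0, 7.0))
    y0 = snap(rng.uniform(24.0, 30.0))
    y1 = snap(rng.uniform(44.0, 50.0))
    z0 = snap(rng.uniform(18.0, 22.0))
    z1 = snap(rng.uniform(34.0, 38.0))
    disp = -float(rng.integers(2, 13)) * h  # 1.0 .. 6.0 mm retraction

    if muscles_changed:
        post = {r: float(rng.uniform(2.5, 3.0)) for r in sc.RECTUS_ROLES}
    else:
        post = dict(_default_pre_radii())

    kw = dict(
        wall_box=((x0, x1), (y0, y1), (z0, z1)),
        globe_displacement=disp,
        muscle_radii_post=post,
    )
    kw.update(overrides)
    spec = PhantomSpec(**kw)
    spec.validate()
    return spec
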