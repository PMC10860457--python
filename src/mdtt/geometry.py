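"""Dual-orthogonal kV imaging geometry for an O-ring gantry linac.

The machine carries two kV x-ray tubes mounted at +/-45 degrees from the MV
beam axis inside the O-ring. Each tube, together with its flat-panel
detector, forms a stereoscopic pair: a structure detected on both 2D images
can be localized in 3D by back-projecting each 2D position toward its source
and intersecting the two rays at the isocenter region.

Conventions fixed project-wide
------------------------------
* Room frame: right-handed, origin at machine isocenter,
  ``x`` = medial-lateral (ML), ``y`` = superior-inferior (SI),
  ``z`` = anterior-posterior (AP).  All positions in mm.
* The ring rotates the gantry about the room vertical (AP, ``z``) axis; the
  gantry then rotates about the (ring-rotated) longitudinal (SI) axis.
* Detectors are modelled at the isocenter-plane-equivalent scale: the stated
  field of view (216 mm x 162 mm) maps onto the full 1024 x 768 matrix at
  the plane through the isocenter perpendicular to each imager's central
  axis.  Pixel pitch at that plane is 216/1024 = 162/768 = 0.2109375 mm.
* Pixel coordinates are 0-based and address pixel centers; the principal
  point (where the central axis hits the detector plane) is the matrix
  center (511.5, 383.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoomPoint",
    "PixelCoord",
    "ImagingGeometry",
    "Ray",
    "Intersection3D",
    "gantry_ring_rotation",
    "project_point",
    "backproject_ray",
    "intersect_rays",
]

#: Tolerance on the cross-product norm below which two rays are treated as
#: parallel (degenerate for triangulation).
PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class RoomPoint:
    """A 3D position in the room frame (mm), origin at isocenter.

    Axis order is fixed as (ML, SI, AP) everywhere in this package.
    """

    x_ml: float
    y_si: float
    z_ap: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("RoomPoint components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x_ml, self.y_si, self.z_ap], dtype=float)

    @staticmethod
    def from_array(a) -> "RoomPoint":
        a = np.asarray(a, dtype=float)
        return RoomPoint(float(a[0]), float(a[1]), float(a[2]))


@dataclass(frozen=True)
class PixelCoord:
    """Sub-pixel detector coordinate (0-based, pixel-center convention)."""

    u: float
    v: float
    imager_id: str = "A"


@dataclass(frozen=True)
class ImagingGeometry:
    """Source/detector poses of both kV imagers at given gantry/ring angles.

    Parameters
    ----------
    sad
        Source-axis distance in mm (source to isocenter).
    imager_offsets_deg
        Azimuths of the two kV central axes measured from the MV beam axis,
        about the machine longitudinal axis. Defaults to (+45, -45): the two
        imagers are then mutually orthogonal.
    field_at_iso
        Detector field of view (width, height) in mm at the isocenter plane.
    matrix_px
        Image matrix (columns, rows).
    gantry_deg, ring_deg
        Machine rotation angles in degrees.
    """

    sad: float = 1000.0
    imager_offsets_deg: tuple = (45.0, -45.0)
    field_at_iso: tuple = (216.0, 162.0)
    matrix_px: tuple = (1024, 768)
    gantry_deg: float = 0.0
    ring_deg: float = 0.0
    imager_ids: tuple = field(default=("A", "B"), repr=False)

    def __post_init__(self) -> None:
        pu = self.field_at_iso[0] / self.matrix_px[0]
        pv = self.field_at_iso[1] / self.matrix_px[1]
        if abs(pu - pv) > 1e-9:
            raise ValueError(
                f"anisotropic pixel pitch at isocenter plane: {pu} vs {pv} mm/px"
            )

    @property
    def pixel_pitch(self) -> float:
        """Pixel pitch (mm/px) at the isocenter plane."""
        return self.field_at_iso[0] / self.matrix_px[0]

    @property
    def principal_point(self) -> tuple:
        """Detector coordinate of the central axis (matrix center)."""
        return ((self.matrix_px[0] - 1) / 2.0, (self.matrix_px[1] - 1) / 2.0)

    def _offset_deg(self, imager_id: str) -> float:
        try:
            return self.imager_offsets_deg[self.imager_ids.index(imager_id)]
        except ValueError:
            raise KeyError(f"unknown imager_id {imager_id!r}") from None

    def imager_axes(self, imager_id: str):
        """Room-frame unit vectors (n, eu, ev) of one imager.

        ``n`` points from the source toward the isocenter (central axis),
        ``eu`` spans detector columns, ``ev`` spans detector rows. Rows
        advance in the machine inferior direction (radiograph orientation:
        superior structures sit at low row indices), so SI motion maps to
        image rows at zero gantry/ring.
        """
        R = gantry_ring_rotation(self.gantry_deg, self.ring_deg).T  # machine->room
        phi = np.deg2rad(self._offset_deg(imager_id))
        # Machine frame at zero angles: MV beam axis along -z (anterior source
        # looking down), kV axes rotated by phi about the longitudinal y axis.
        n_m = np.array([np.sin(phi), 0.0, -np.cos(phi)])
        ev_m = np.array([0.0, -1.0, 0.0])
        eu_m = np.cross(ev_m, n_m)  # right-handed (eu, ev, n)
        return R @ n_m, R @ eu_m, R @ ev_m

    def source_position(self, imager_id: str) -> np.ndarray:
        """Room-frame position (mm) of an imager's x-ray source."""
        n, _, _ = self.imager_axes(imager_id)
        return -self.sad * n


@dataclass(frozen=True)
class Ray:
    """A back-projection ray: origin at the source, unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("ray direction must be a finite non-zero vector")
        object.__setattr__(self, "direction", d / nrm)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction

    def distance_to(self, p) -> float:
        """Perpendicular distance from a point to the ray's line."""
        w = np.asarray(p, dtype=float) - self.origin
        return float(np.linalg.norm(w - (w @ self.direction) * self.direction))


@dataclass(frozen=True)
class Intersection3D:
    """Closest-approach 'intersection' of two skew rays."""

    point: RoomPoint
    residual: float  # mm, length of the common perpendicular segment


def gantry_ring_rotation(gantry_deg: float, ring_deg: float) -> np.ndarray:
    """Rotation matrix mapping room-frame vectors into the machine frame.

    The ring rotation (about the room vertical/AP axis) is applied first,
    then the gantry rotation about the ring-rotated longitudinal (SI) axis.
    The returned matrix is proper (determinant +1); its transpose maps
    machine-frame vectors back to the room frame.
    """
    g = np.deg2rad(gantry_deg)
    r = np.deg2rad(ring_deg)
    if not (np.isfinite(g) and np.isfinite(r)):
        raise ValueError("angles must be finite")
    cr, sr = np.cos(r), np.sin(r)
    cg, sg = np.cos(g), np.sin(g)
    Rz = np.array([[cr, -sr, 0.0], [sr, cr, 0.0], [0.0, 0.0, 1.0]])
    Ry = np.array([[cg, 0.0, sg], [0.0, 1.0, 0.0], [-sg, 0.0, cg]])
    # Intrinsic composition: machine->room is Rz @ Ry; room->machine is its
    # transpose.
    return (Rz @ Ry).T


def project_point(geom: ImagingGeometry, p: RoomPoint, imager_id: str) -> PixelCoord:
    """Perspective-project a room point onto one imager's detector.

    The detector is modelled at the isocenter-plane-equivalent scale: the
    image of the isocenter is the principal point, and a point displaced
    laterally at isocenter depth moves by (displacement / pixel pitch)
    pixels.

    Raises
    ------
    ValueError
        If the point is at, or behind, the source (no valid projection).
    """
    n, eu, ev = geom.imager_axes(imager_id)
    s = geom.source_position(imager_id)
    w = p.as_array() - s
    depth = w @ n  # distance from source along the central axis
    if depth <= 1e-9:
        raise ValueError("point at or behind the kV source: projection undefined")
    # Intersect the ray source->p with the plane through isocenter normal to n.
    t = geom.sad / depth
    q = s + t * w  # in-plane 3D position
    u0, v0 = geom.principal_point
    pitch = geom.pixel_pitch
    return PixelCoord(
        u=u0 + float(q @ eu) / pitch,
        v=v0 + float(q @ ev) / pitch,
        imager_id=imager_id,
    )


def backproject_ray(geom: ImagingGeometry, pc: PixelCoord) -> Ray:
    """Back-project a detector coordinate toward the kV source.

    Sub-pixel and slightly out-of-matrix coordinates are accepted
    (interpolated detections may fall between pixels or just outside the
    matrix edge).
    """
    n, eu, ev = geom.imager_axes(pc.imager_id)
    s = geom.source_position(pc.imager_id)
    u0, v0 = geom.principal_point
    pitch = geom.pixel_pitch
    q = (pc.u - u0) * pitch * eu + (pc.v - v0) * pitch * ev  # on isocenter plane
    return Ray(origin=s, direction=q - s)


def intersect_rays(a: Ray, b: Ray) -> Intersection3D:
    """Locate the 3D point nearest to two back-projected rays.

    With noisy detections the two rays are skew; the returned point is the
    midpoint of their common perpendicular segment and ``residual`` is the
    segment length (closest-approach distance, mm). Symmetric in its
    arguments.

    Raises
    ------
    ValueError
        If the rays are (near-)parallel and no unique closest point exists.
    """
    da, db = a.direction, b.direction
    cross = np.cross(da, db)
    denom = cross @ cross
    if denom < PARALLEL_TOL:
        raise ValueError("rays are parallel or nearly parallel: no unique intersection")
    w0 = b.origin - a.origin
    # Solve for parameters of the closest points on each line.
    ta = (np.cross(w0, db) @ cross) / denom
    tb = (np.cross(w0, da) @ cross) / denom
    pa = a.point_at(ta)
    pb = b.point_at(tb)
    mid = 0.5 * (pa + pb)
    return Intersection3D(
        point=RoomPoint.from_array(mid),
        residual=float(np.linalg.norm(pa - pb)),
    )
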