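"""Fan-beam (flat-detector) sinogram simulation and view subsampling.

Geometry defaults follow the scanner protocol this package emulates:
source-to-detector 988.00 mm, source-to-isocenter 560.00 mm, flat detector
313.89 mm wide, full 360 deg rotation with 720 views; sparse protocols keep
every 6th view (120 views, 3 deg increment) or every 12th (60 views, 6 deg
increment).

Source angle 0 places the X-ray source on the +y axis; angles increase
counter-clockwise.  At angle beta the source sits at
``(-R sin(beta), R cos(beta))`` with R the source-to-isocenter distance, and
the detector axis points along ``(cos(beta), sin(beta))``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .phantoms import EllipsePhantom, Image2D, chord_lengths, pixel_coords

__all__ = [
    "FanBeamGeometry",
    "Sinogram",
    "make_view_angles",
    "forward_project_analytic",
    "forward_project_image",
    "subsample_views",
]


@dataclass(frozen=True)
class FanBeamGeometry:
    """Flat, equispaced fan-beam acquisition geometry (all distances in mm)."""

    source_to_detector: float = 988.00
    source_to_isocenter: float = 560.00
    detector_width: float = 313.89
    n_detector_bins: int = 729
    n_views: int = 720
    angular_range: float = 360.0
    detector_layout: str = "flat-equispaced"

    def __post_init__(self) -> None:
        if not (self.source_to_detector > self.source_to_isocenter > 0):
            raise ValueError("need source_to_detector > source_to_isocenter > 0")
        if self.n_detector_bins < 8:
            raise ValueError("n_detector_bins must be >= 8")
        if self.n_views < 1:
            raise ValueError("n_views must be >= 1")
        if self.detector_layout != "flat-equispaced":
            raise ValueError("only the flat-equispaced detector layout is supported")
        if self.fan_fov_diameter <= 0:
            raise ValueError("fan does not cover a positive field of view")

    @property
    def fan_half_angle(self) -> float:
        """Half fan angle in radians."""
        return float(np.arctan2(self.detector_width / 2.0, self.source_to_detector))

    @property
    def fan_fov_diameter(self) -> float:
        """Diameter (mm) of the isocentric circle covered by every view's fan."""
        return 2.0 * self.source_to_isocenter * float(np.sin(self.fan_half_angle))

    @property
    def magnification(self) -> float:
        return self.source_to_detector / self.source_to_isocenter

    def detector_s(self) -> np.ndarray:
        """Physical detector bin-center offsets (mm) along the detector axis."""
        n = self.n_detector_bins
        pitch = self.detector_width / n
        return (np.arange(n) - (n - 1) / 2.0) * pitch

    def detector_u(self) -> np.ndarray:
        """Bin centers rescaled onto the virtual detector through the isocenter."""
        return self.detector_s() / self.magnification

    def source_position(self, angles_deg: np.ndarray) -> np.ndarray:
        """Source (x, y) in mm for each angle; shape (n, 2)."""
        b = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))
        R = self.source_to_isocenter
        return np.stack([-R * np.sin(b), R * np.cos(b)], axis=-1)

    def assert_covers(self, fov_diameter: float) -> None:
        if fov_diameter > self.fan_fov_diameter * (1 + 1e-9):
            raise ValueError(
                f"object FOV {fov_diameter:.2f} mm exceeds the fan coverage "
                f"{self.fan_fov_diameter:.2f} mm"
            )


@dataclass
class Sinogram:
    """View-by-detector array of line integrals (mm x attenuation)."""

    values: np.ndarray
    angles: np.ndarray
    geometry: FanBeamGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2D (views x bins)")
        if len(self.angles) != self.values.shape[0]:
            raise ValueError("len(angles) must equal the number of views")
        if self.values.shape[1] != self.geometry.n_detector_bins:
            raise ValueError("bin count mismatch with geometry")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    def save(self, path) -> None:
        g = self.geometry
        np.savez(
            path,
            values=self.values,
            angles=self.angles,
            source_to_detector=g.source_to_detector,
            source_to_isocenter=g.source_to_isocenter,
            detector_width=g.detector_width,
            n_detector_bins=g.n_detector_bins,
            n_views=g.n_views,
            angular_range=g.angular_range,
        )

    @classmethod
    def load(cls, path) -> "Sinogram":
        with np.load(path) as z:
            geom = FanBeamGeometry(
                source_to_detector=float(z["source_to_detector"]),
                source_to_isocenter=float(z["source_to_isocenter"]),
                detector_width=float(z["detector_width"]),
                n_detector_bins=int(z["n_detector_bins"]),
                n_views=int(z["n_views"]),
                angular_range=float(z["angular_range"]),
            )
            return cls(z["values"], z["angles"], geom)


def make_view_angles(n_views: int, angular_range: float = 360.0) -> np.ndarray:
    """Equispaced source angles in degrees starting at 0 (step = range / n)."""
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    return np.arange(n_views, dtype=np.float64) * (angular_range / n_views)


def _ray_grid(geometry: FanBeamGeometry, angles: np.ndarray):
    """All (origin, direction) ray pairs; shapes (n_views, n_bins, 2)."""
    src = geometry.source_position(angles)  # (V, 2)
    b = np.deg2rad(angles)
    central = np.stack([np.sin(b), -np.cos(b)], axis=-1)  # toward isocenter
    e_u = np.stack([np.cos(b), np.sin(b)], axis=-1)  # detector axis
    s = geometry.detector_s()  # (B,)
    det = (
        src[:, None, :]
        + geometry.source_to_detector * central[:, None, :]
        + s[None, :, None] * e_u[:, None, :]
    )
    origins = np.broadcast_to(src[:, None, :], det.shape)
    return origins, det - origins


def forward_project_analytic(
    phantom: EllipsePhantom,
    geometry: FanBeamGeometry,
    angles: np.ndarray | None = None,
) -> Sinogram:
    """Exact fan-beam sinogram of an ellipse phantom via closed-form chords."""
    geometry.assert_covers(phantom.fov_diameter)
    if angles is None:
        angles = make_view_angles(geometry.n_views, geometry.angular_range)
    angles = np.asarray(angles, dtype=np.float64)
    origins, dirs = _ray_grid(geometry, angles)
    vals = np.zeros(origins.shape[:2], dtype=np.float64)
    for e in phantom.ellipses:
        vals += e.attenuation_delta * chord_lengths(e, origins, dirs)
    return Sinogram(vals, angles, replace(geometry, n_views=len(angles)))


def forward_project_image(
    image: Image2D,
    geometry: FanBeamGeometry,
    angles: np.ndarray | None = None,
    step_fraction: float = 0.25,
) -> Sinogram:
    """Ray-driven numerical projector: fixed sampling step (default 1/4 pixel)
    with bilinear interpolation.  Linear in the image; converges to the
    analytic projector as the step shrinks."""
    if angles is None:
        angles = make_view_angles(geometry.n_views, geometry.angular_range)
    angles = np.asarray(angles, dtype=np.float64)
    size = image.size
    px = image.pixel_size
    half_extent = size * px / 2.0
    origins, dirs = _ray_grid(geometry, angles)
    dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)

    # sample along each ray only where it can cross the image square
    R = geometry.source_to_isocenter
    reach = np.sqrt(2.0) * half_extent
    step = step_fraction * px
    t = np.arange(R - reach, R + reach + step, step)

    pix = np.zeros_like(image.pixels, dtype=np.float64)
    pix[:] = image.pixels
    out = np.empty(origins.shape[:2], dtype=np.float64)
    for v in range(len(angles)):
        pts = origins[v, :, None, :] + t[None, :, None] * dirs[v, :, None, :]
        # object (x, y) mm -> array (row, col) indices
        col = pts[..., 0] / px + (size - 1) / 2.0
        row = (size - 1) / 2.0 - pts[..., 1] / px
        samp = ndimage.map_coordinates(
            pix, [row.ravel(), col.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(row.shape)
        out[v] = samp.sum(axis=1) * step
    return Sinogram(out, angles, replace(geometry, n_views=len(angles)))


def subsample_views(sino: Sinogram, target_views: int) -> Sinogram:
    """Keep every (n/target)-th view starting at view 0 (e.g. 720 -> 120 -> 60).

    The retained rows are exact copies; the standard protocols 720 -> 120
    (3 deg step) and 720 -> 60 (6 deg step) are exact divisors.
    """
    n = sino.n_views
    if target_views < 1 or n % target_views != 0:
        raise ValueError(
            f"target_views must divide the current view count ({n}); got {target_views}"
        )
    stride = n // target_views
    return Sinogram(
        sino.values[::stride].copy(),
        sino.angles[::stride].copy(),
        replace(sino.geometry, n_views=target_views),
    )
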