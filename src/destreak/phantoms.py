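"""Analytic ellipse phantoms: ground-truth attenuation objects with exact line integrals.

A phantom is an ordered list of ellipses whose attenuation values add where
they overlap.  That additivity makes both rendering (an indicator sum over
pixel centers) and the ray transform (a sum of chord lengths, each from the
closed-form line/ellipse quadratic) exact up to floating point, so phantoms
double as analytic oracles for the numerical projector and for FBP.

Coordinate convention, used everywhere in this package: object coordinates
are in mm with the origin at the image center, x to the right, y up.  Image
row 0 is the *top* row, so row index increases as y decreases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "EllipseSpec",
    "EllipsePhantom",
    "Image2D",
    "render_phantom",
    "make_shepp_logan",
    "sample_random_phantom",
    "line_integral",
    "pixel_coords",
]

#: Nominal peak intensity for 12-bit storage/export.
INTENSITY_SCALE_12BIT = 4095.0


@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse: center (mm), semi-axes (mm), rotation (deg CCW), additive attenuation."""

    center_x: float
    center_y: float
    semi_axis_a: float
    semi_axis_b: float
    rotation: float = 0.0
    attenuation_delta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.semi_axis_a > 0 and self.semi_axis_b > 0):
            raise ValueError("semi-axes must be strictly positive")

    @property
    def outer_radius(self) -> float:
        """Radius of the smallest origin-centered circle guaranteed to contain the ellipse."""
        return float(np.hypot(self.center_x, self.center_y)
                     + max(self.semi_axis_a, self.semi_axis_b))


@dataclass(frozen=True)
class EllipsePhantom:
    """An ordered set of additive ellipses inside a circular field of view."""

    ellipses: tuple[EllipseSpec, ...]
    fov_diameter: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "ellipses", tuple(self.ellipses))
        if len(self.ellipses) == 0:
            raise ValueError("phantom needs at least one ellipse")
        if self.fov_diameter <= 0:
            raise ValueError("fov_diameter must be positive")
        r = self.fov_diameter / 2.0
        for e in self.ellipses:
            if e.outer_radius > r * (1 + 1e-9):
                raise ValueError(
                    f"ellipse {e} is not fully inside the FOV circle (radius {r} mm)"
                )

    def scaled(self, k: float) -> "EllipsePhantom":
        """Phantom with every attenuation value multiplied by ``k``."""
        return EllipsePhantom(
            tuple(
                EllipseSpec(e.center_x, e.center_y, e.semi_axis_a, e.semi_axis_b,
                            e.rotation, e.attenuation_delta * k)
                for e in self.ellipses
            ),
            self.fov_diameter,
        )

    def rotated(self, angle_deg: float) -> "EllipsePhantom":
        """Phantom rotated CCW about the origin by ``angle_deg``."""
        th = np.deg2rad(angle_deg)
        c, s = np.cos(th), np.sin(th)
        return EllipsePhantom(
            tuple(
                EllipseSpec(
                    c * e.center_x - s * e.center_y,
                    s * e.center_x + c * e.center_y,
                    e.semi_axis_a, e.semi_axis_b,
                    e.rotation + angle_deg, e.attenuation_delta,
                )
                for e in self.ellipses
            ),
            self.fov_diameter,
        )

    # -- serialization (structured text) ------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"fov_diameter": self.fov_diameter,
             "ellipses": [asdict(e) for e in self.ellipses]},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EllipsePhantom":
        d = json.loads(text)
        return cls(tuple(EllipseSpec(**e) for e in d["ellipses"]), d["fov_diameter"])


@dataclass
class Image2D:
    """A square 2D image: ground-truth render, reconstruction, or artifact image.

    ``pixels`` is an H x W float array (H == W).  Ground-truth renders are
    non-negative; FBP reconstructions may dip slightly negative and are kept
    that way so residuals stay unbiased.  ``intensity_scale`` is the nominal
    peak used for 12-bit export and for metric reporting.
    """

    pixels: np.ndarray
    pixel_size: float = 0.61
    intensity_scale: float = INTENSITY_SCALE_12BIT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("Image2D must be square (H == W)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def pixel_coords(size: int, pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) object coordinates (mm) of every pixel center of a ``size``^2 image.

    Returns two ``size x size`` arrays.  Row 0 is the top of the image
    (largest y), matching the package-wide convention.
    """
    idx = np.arange(size, dtype=float)
    x = (idx - (size - 1) / 2.0) * pixel_size
    y = ((size - 1) / 2.0 - idx) * pixel_size
    return np.broadcast_to(x[None, :], (size, size)), np.broadcast_to(y[:, None], (size, size))


def render_phantom(phantom: EllipsePhantom, size: int, pixel_size: float) -> Image2D:
    """Render by pixel-center sampling: each pixel is the sum of the attenuation
    values of the ellipses strictly containing its center.  No anti-aliasing,
    so the result is an exact indicator sum and bit-for-bit reproducible."""
    if size < 16:
        raise ValueError("size must be >= 16")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    x, y = pixel_coords(size, pixel_size)
    out = np.zeros((size, size), dtype=np.float64)
    for e in phantom.ellipses:
        th = np.deg2rad(e.rotation)
        c, s = np.cos(th), np.sin(th)
        dx = x - e.center_x
        dy = y - e.center_y
        u = dx * c + dy * s
        v = -dx * s + dy * c
        inside = (u / e.semi_axis_a) ** 2 + (v / e.semi_axis_b) ** 2 < 1.0
        out[inside] += e.attenuation_delta
    return Image2D(out, pixel_size=pixel_size)


# Canonical head phantom ellipse table (center_x, center_y, a, b, rotation, delta)
# in a unit field of view (radius 1); attenuation chosen so the render is
# non-negative everywhere (max value 2.0 in the outer shell).
_SHEPP_LOGAN_TABLE = (
    (0.0, 0.0, 0.69, 0.92, 0.0, 2.0),
    (0.0, -0.0184, 0.6624, 0.874, 0.0, -0.98),
    (0.22, 0.0, 0.11, 0.31, -18.0, -0.02),
    (-0.22, 0.0, 0.16, 0.41, 18.0, -0.02),
    (0.0, 0.35, 0.21, 0.25, 0.0, 0.01),
    (0.0, 0.1, 0.046, 0.046, 0.0, 0.01),
    (0.0, -0.1, 0.046, 0.046, 0.0, 0.01),
    (-0.08, -0.605, 0.046, 0.023, 0.0, 0.01),
    (0.0, -0.605, 0.023, 0.023, 0.0, 0.01),
    (0.06, -0.605, 0.023, 0.046, 0.0, 0.01),
)

#: Maximum attainable render value of the head phantom (outer shell region).
SHEPP_LOGAN_MAX = 2.0


def make_shepp_logan(fov_diameter: float) -> EllipsePhantom:
    """The classic 10-ellipse head phantom, scaled to fill ``fov_diameter`` (mm)."""
    if fov_diameter <= 0:
        raise ValueError("fov_diameter must be positive")
    r = fov_diameter / 2.0
    ells = tuple(
        EllipseSpec(cx * r, cy * r, a * r, b * r, rot, delta)
        for cx, cy, a, b, rot, delta in _SHEPP_LOGAN_TABLE
    )
    return EllipsePhantom(ells, fov_diameter)


def sample_random_phantom(
    seed: int,
    n_ellipses_range: tuple[int, int] = (4, 12),
    fov_diameter: float = 170.0,
) -> EllipsePhantom:
    """Seeded random phantom: a background disk of attenuation 1.0 plus 4-12
    smaller ellipses with positive attenuation in [0.05, 0.5].

    Centers are uniform within 0.8 x FOV; semi-axes are capped so every
    ellipse stays strictly inside the FOV circle.  All attenuation values are
    positive, so the render is non-negative by construction.  The sharp
    ellipse edges are what generate streaks under sparse-view FBP.
    """
    lo, hi = n_ellipses_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid n_ellipses_range")
    rng = np.random.default_rng(seed)
    r_fov = fov_diameter / 2.0
    bg_radius = 0.95 * r_fov
    ells = [EllipseSpec(0.0, 0.0, bg_radius, bg_radius, 0.0, 1.0)]
    n = int(rng.integers(lo, hi + 1))
    for _ in range(n):
        # uniform over the disk of radius 0.8 * r_fov
        rc = 0.8 * r_fov * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        cx, cy = rc * np.cos(phi), rc * np.sin(phi)
        ax_cap = min(0.35 * r_fov, 0.95 * r_fov - rc)
        a = rng.uniform(0.05 * r_fov, ax_cap)
        b = rng.uniform(0.05 * r_fov, ax_cap)
        rot = rng.uniform(0.0, 180.0)
        delta = rng.uniform(0.05, 0.5)
        ells.append(EllipseSpec(cx, cy, a, b, rot, delta))
    return EllipsePhantom(tuple(ells), fov_diameter)


def chord_lengths(
    ellipse: EllipseSpec, points: np.ndarray, directions: np.ndarray
) -> np.ndarray:
    """Chord length of each ray through one ellipse (vectorized).

    ``points``: (..., 2) ray origins in mm; ``directions``: (..., 2), need not
    be unit length (they are normalized here).  Solves the line/ellipse
    quadratic in the ellipse's own frame; rays that miss return 0.
    """
    points = np.asarray(points, dtype=np.float64)
    d = np.asarray(directions, dtype=np.float64)
    norm = np.sqrt(d[..., 0] ** 2 + d[..., 1] ** 2)
    if np.any(norm == 0):
        raise ValueError("ray direction must be non-zero")
    dx, dy = d[..., 0] / norm, d[..., 1] / norm
    th = np.deg2rad(ellipse.rotation)
    c, s = np.cos(th), np.sin(th)
    px = points[..., 0] - ellipse.center_x
    py = points[..., 1] - ellipse.center_y
    # rotate into the ellipse frame
    u0 = px * c + py * s
    v0 = -px * s + py * c
    du = dx * c + dy * s
    dv = -dx * s + dy * c
    a2 = ellipse.semi_axis_a ** 2
    b2 = ellipse.semi_axis_b ** 2
    A = du ** 2 / a2 + dv ** 2 / b2
    B = 2.0 * (u0 * du / a2 + v0 * dv / b2)
    C = u0 ** 2 / a2 + v0 ** 2 / b2 - 1.0
    disc = B ** 2 - 4.0 * A * C
    return np.where(disc > 0.0, np.sqrt(np.maximum(disc, 0.0)) / A, 0.0)


def line_integral(
    phantom: EllipsePhantom,
    point: tuple[float, float],
    direction: tuple[float, float],
) -> float:
    """Exact ray transform: sum over ellipses of attenuation x chord length
    (mm x attenuation).  This is the analytic oracle for the projector."""
    p = np.asarray(point, dtype=np.float64)
    d = np.asarray(direction, dtype=np.float64)
    total = 0.0
    for e in phantom.ellipses:
        total += e.attenuation_delta * float(chord_lengths(e, p, d))
    return total
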