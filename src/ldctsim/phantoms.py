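"""Digital phantoms: a water calibration cylinder and a contrast-tube head phantom.

Phantoms are piecewise-constant 2-D Hounsfield maps sampled at pixel centers,
so the HU histogram of a generated map contains exactly the material values
of its spec (air, water/tissue, bone, tube contrast).  An optional
supersampling flag trades that exactness for anti-aliased edges.

The head phantom emulates a skull slice with four contrast-filled tubes
attached laterally, two per dilution; the tube HU defaults (290 / 370) are
chosen so the pooled tube mean is 330 HU, a typical contrast-enhanced
vessel attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np

from .config import DEFAULT_FOV_MM, DEFAULT_GRID

__all__ = [
    "GeometryError",
    "AttenuationMap",
    "PhantomSpec",
    "make_water_phantom",
    "make_head_phantom",
    "pixel_centers",
]

HU_AIR = -1000.0
HU_WATER = 0.0


class GeometryError(ValueError):
    """Raised when a requested geometry is degenerate or does not fit."""


def pixel_centers(n: int, pixel_size: float) -> np.ndarray:
    """Pixel-center coordinates (mm) for an ``n``-pixel axis, origin at grid center."""
    return (np.arange(n) - (n - 1) / 2.0) * pixel_size


@dataclass
class AttenuationMap:
    """A square 2-D grid of Hounsfield values describing one phantom slice.

    Attributes
    ----------
    grid : ndarray, shape (n, n)
        HU values; air is -1000, water 0.
    pixel_size : float
        Edge length of one pixel in mm.
    """

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2 or self.grid.shape[0] != self.grid.shape[1]:
            raise GeometryError(f"attenuation map must be square, got {self.grid.shape}")
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if np.min(self.grid) < HU_AIR - 1e-9:
            raise ValueError("HU values below -1000 (air) are not physical")

    @property
    def n(self) -> int:
        return self.grid.shape[0]

    @property
    def fov(self) -> float:
        """Field of view in mm (grid side times pixel size)."""
        return self.n * self.pixel_size

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of pixel-center (x, y) coordinates in mm."""
        c = pixel_centers(self.n, self.pixel_size)
        return np.meshgrid(c, c)


@dataclass
class PhantomSpec:
    """Geometry and material values for the generated phantoms.

    ``kind`` selects between the uniform water cylinder used for noise
    calibration and the head phantom with contrast-filled tubes.  Tube HU
    values correspond to contrast-agent dilutions: the defaults place the
    lower dilution at 290 HU and the higher at 370 HU so that the mean over
    all tube pixels is 330 HU.
    """

    kind: str = "head"
    diameter: float = 200.0          # water cylinder diameter, mm
    tube_hu_low: float = 290.0       # lower-dilution contrast tubes
    tube_hu_high: float = 370.0      # higher-dilution contrast tubes
    tube_diameter: float = 20.0      # mm (syringe-sized contrast tubes)
    skull_hu: float = 1200.0
    tissue_hu: float = 40.0
    # head geometry (mm); outer skull ellipse semi-axes and ring thickness
    head_semi_x: float = 65.0
    head_semi_y: float = 80.0
    skull_thickness: float = 6.0
    tube_gap: float = 3.0            # clearance between skull and tube edge
    tube_offset: float = 11.5        # vertical offset of each tube center

    def __post_init__(self) -> None:
        if self.kind not in ("water", "head"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if not self.tube_hu_low < self.tube_hu_high:
            raise ValueError("tube_hu_low must be below tube_hu_high")
        if self.diameter <= 0:
            raise GeometryError("diameter must be positive")

    def tube_centers(self) -> list[tuple[float, float, float]]:
        """Tube centers as (x, y, hu).

        Two tubes per side; the two dilutions are arranged diagonally so the
        low-dilution pixel set is the mirror image of the high-dilution set,
        which makes the two pixel counts exactly equal on a centered grid.
        """
        x0 = self.head_semi_x + self.tube_gap + self.tube_diameter / 2.0
        dy = self.tube_offset
        return [
            (-x0, +dy, self.tube_hu_low),
            (+x0, -dy, self.tube_hu_low),
            (-x0, -dy, self.tube_hu_high),
            (+x0, +dy, self.tube_hu_high),
        ]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        return cls(**json.loads(text))


def _render(shapes, grid_size: int, fov: float, supersample: int) -> AttenuationMap:
    """Paint ``shapes`` (callables mask(X, Y) -> bool array, hu) over air."""
    k = max(1, int(supersample))
    n = grid_size * k
    px = fov / n
    c = pixel_centers(n, px)
    X, Y = np.meshgrid(c, c)
    hu = np.full((n, n), HU_AIR)
    for mask_fn, value in shapes:
        hu[mask_fn(X, Y)] = value
    if k > 1:
        hu = hu.reshape(grid_size, k, grid_size, k).mean(axis=(1, 3))
    return AttenuationMap(hu, fov / grid_size)


def make_water_phantom(
    diameter: float = 200.0,
    grid_size: int = DEFAULT_GRID,
    fov: float = DEFAULT_FOV_MM,
    supersample: int = 1,
) -> AttenuationMap:
    """Centered water cylinder (0 HU) on an air background (-1000 HU).

    The 20-cm default matches the standard noise-calibration phantom.
    """
    if diameter <= 0:
        raise GeometryError("diameter must be positive")
    if diameter > fov:
        raise GeometryError(f"diameter {diameter} mm exceeds fov {fov} mm")
    r = diameter / 2.0
    return _render(
        [(lambda X, Y: X**2 + Y**2 <= r**2, HU_WATER)], grid_size, fov, supersample
    )


def make_head_phantom(
    spec: PhantomSpec | None = None,
    grid_size: int = DEFAULT_GRID,
    fov: float = DEFAULT_FOV_MM,
    supersample: int = 1,
) -> AttenuationMap:
    """Head slice: soft-tissue ellipse, skull ring, four lateral contrast tubes.

    Raises
    ------
    GeometryError
        If the tubes are degenerate, overlap each other, intersect the
        skull, or extend beyond the field of view.
    """
    spec = spec if spec is not None else PhantomSpec(kind="head")
    if spec.tube_diameter <= 0:
        raise GeometryError("tube_diameter must be positive")
    a, b = spec.head_semi_x, spec.head_semi_y
    t = spec.skull_thickness
    if min(a, b) <= t:
        raise GeometryError("skull thickness exceeds head semi-axis")
    r_tube = spec.tube_diameter / 2.0
    centers = spec.tube_centers()
    # pairwise tube overlap
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dx = centers[i][0] - centers[j][0]
            dy = centers[i][1] - centers[j][1]
            if dx * dx + dy * dy < (2 * r_tube) ** 2:
                raise GeometryError("contrast tubes overlap")
    for x0, y0, _ in centers:
        if abs(x0) + r_tube > fov / 2 or abs(y0) + r_tube > fov / 2:
            raise GeometryError("tube extends beyond the field of view")
        # conservative skull clearance: tube circle vs bounding ellipse
        if (x0 / (a + r_tube)) ** 2 + (y0 / (b + r_tube)) ** 2 < 1.0:
            raise GeometryError("tube overlaps the skull")
    if a > fov / 2 or b > fov / 2:
        raise GeometryError("head ellipse exceeds the field of view")

    def ellipse(sx: float, sy: float):
        return lambda X, Y: (X / sx) ** 2 + (Y / sy) ** 2 <= 1.0

    shapes = [
        (ellipse(a, b), spec.skull_hu),
        (ellipse(a - t, b - t), spec.tissue_hu),
    ]
    for x0, y0, hu in centers:
        shapes.append(
            (
                lambda X, Y, x0=x0, y0=y0: (X - x0) ** 2 + (Y - y0) ** 2 <= r_tube**2,
                hu,
            )
        )
    return _render(shapes, grid_size, fov, supersample)
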