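"""Objective image analysis: circular-ROI statistics and dose-series tables.

An ROI is a disk in image millimeter coordinates (origin at image center);
its pixel set is the pixels whose centers fall inside the disk, making the
statistics deterministic for a given image raster.  The ROI standard
deviation is the operational noise measure, and SNR = mean / SD.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import math

import numpy as np
import pandas as pd

from .phantoms import GeometryError, PhantomSpec
from .recon import ReconImage

__all__ = ["RoiSpec", "RoiStats", "roi_stats", "replicate_rois", "tube_rois"]


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest: center (x, y) and diameter in mm."""

    center: tuple[float, float]
    diameter: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise GeometryError("ROI diameter must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class RoiStats:
    """Mean attenuation (HU), noise SD (HU), SNR and pixel count of one ROI.

    ``snr`` is NaN when the SD is zero (flat region; the ratio is undefined).
    """

    mean: float
    sd: float
    snr: float
    n_pixels: int

    @property
    def snr_defined(self) -> bool:
        return math.isfinite(self.snr)


def _roi_mask(image: ReconImage, roi: RoiSpec) -> np.ndarray:
    x0, y0 = roi.center
    r = roi.diameter / 2.0
    half = image.fov / 2.0
    if abs(x0) + r > half or abs(y0) + r > half:
        raise GeometryError(
            f"ROI {roi.label or roi.center} (r={r} mm) extends outside the "
            f"{image.fov:.0f} mm image"
        )
    X, Y = image.coords()
    return (X - x0) ** 2 + (Y - y0) ** 2 <= r**2


def roi_stats(image: ReconImage, roi: RoiSpec) -> RoiStats:
    """Mean/SD/SNR over the pixels whose centers fall inside the ROI disk.

    SD uses the n-1 denominator.  Raises :class:`GeometryError` if the disk
    is not fully inside the image.
    """
    mask = _roi_mask(image, roi)
    vals = image.grid[mask]
    if vals.size == 0:
        raise GeometryError("ROI covers no pixel centers at this resolution")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    snr = mean / sd if sd > 0 else float("nan")
    return RoiStats(mean=mean, sd=sd, snr=snr, n_pixels=int(vals.size))


def replicate_rois(rois: list[RoiSpec], series: list[ReconImage]) -> pd.DataFrame:
    """Apply the identical ROI set to every image of a matched dose series.

    All images must share grid size and field of view (the ROI geometry is
    copied unchanged, emulating copy-and-paste ROI replication across dose
    levels).  Returns one row per (ROI x image) with columns
    ``roi_label, alpha, eff_mas, mean_hu, sd_hu, snr, n_pixels``.
    """
    if not series:
        raise ValueError("empty image series")
    ref = series[0]
    for img in series[1:]:
        if img.n != ref.n or not math.isclose(img.pixel_size, ref.pixel_size):
            raise ValueError("images in a series must share grid and fov")
    rows = []
    for img in series:
        alpha = img.provenance.get("alpha", 1.0)
        eff_mas = img.provenance.get("eff_mas", float("nan"))
        for k, roi in enumerate(rois):
            st = roi_stats(img, roi)
            rows.append(
                {
                    "roi_label": roi.label or f"roi{k}",
                    "alpha": alpha,
                    "eff_mas": eff_mas,
                    "mean_hu": st.mean,
                    "sd_hu": st.sd,
                    "snr": st.snr,
                    "n_pixels": st.n_pixels,
                }
            )
    return pd.DataFrame(rows)


def tube_rois(spec: PhantomSpec, n_rois: int = 10, roi_diameter: float = 6.0) -> list[RoiSpec]:
    """Standard measurement ROIs inside the head phantom's contrast tubes.

    Ten ROIs (five per dilution) distributed over the four tubes, each a
    disk small enough to sit strictly inside the tube lumen with a margin
    against edge blur, mimicking lumen ROIs placed at several levels.
    """
    if n_rois != 10:
        raise ValueError("the standard tube ROI set has 10 ROIs")
    r_tube = spec.tube_diameter / 2.0
    if roi_diameter / 2.0 >= r_tube:
        raise GeometryError("ROI diameter must be smaller than the tube diameter")
    # per-tube ROI center offsets in units of the tube radius (3+2+3+2);
    # essentially disjoint disks, all with a clear margin to the blurred
    # lumen edge so each ROI samples nearly independent noise
    u = 0.42
    offsets = [
        ((0.0, -u), (0.0, u), (u, 0.0)),
        ((0.0, -u), (0.0, u)),
        ((0.0, -u), (0.0, u), (-u, 0.0)),
        ((0.0, -u), (0.0, u)),
    ]
    rois = []
    for (x0, y0, hu), offs in zip(spec.tube_centers(), offsets):
        dil = "low" if hu == spec.tube_hu_low else "high"
        for j, (fx, fy) in enumerate(offs):
            rois.append(
                RoiSpec(
                    center=(x0 + fx * r_tube, y0 + fy * r_tube),
                    diameter=roi_diameter,
                    label=f"{dil}_x{x0:+.0f}_{j}",
                )
            )
    return rois
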