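"""Parallel-beam forward projection and the photon-counting measurement model.

A scan has two stages:

1. ``forward_project`` computes noiseless line integrals of the linear
   attenuation coefficient, ``p = integral mu dl`` (dimensionless), on a
   parallel-beam geometry with views spread uniformly over 180 degrees.

2. ``measure`` pushes those line integrals through the detector model.  Per
   ray the expected detected count is ``lambda = N0 * exp(-p)`` with
   ``N0 = eff_mas * photons_per_mas`` incident photons; the recorded count is
   Poisson(lambda) plus zero-mean Gaussian electronic noise of SD ``sigma_e``
   (in count units, added before the log), and the recorded line integral is
   ``p_hat = -log(max(N, floor) / N0)``.

To first order (delta method) the per-ray variance of ``p_hat`` is
``1/lambda + sigma_e**2 / lambda**2``: quantum noise dominating at clinical
dose, electronic noise taking over once counts drop to the readout-noise
scale.  Radiation dose is proportional to eff_mas, so halving the tube
current doubles the ray variance and raises image noise by sqrt(2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.ndimage as ndi

from .config import (
    COUNT_FLOOR,
    DEFAULT_N_VIEWS,
    DEFAULT_PHOTONS_PER_MAS,
    DEFAULT_SIGMA_E,
    MU_WATER_MM,
    STARVATION_FRACTION,
)
from .phantoms import AttenuationMap, pixel_centers

__all__ = [
    "ScanProtocol",
    "Sinogram",
    "PhotonStarvationWarning",
    "PhotonStarvationError",
    "forward_project",
    "measure",
    "acquire",
    "hu_to_mu",
]


class PhotonStarvationWarning(UserWarning):
    """More than the allowed fraction of rays hit the count floor."""


class PhotonStarvationError(RuntimeError):
    """Photon starvation encountered while acquiring in strict mode."""


def hu_to_mu(hu: np.ndarray, mu_water: float = MU_WATER_MM) -> np.ndarray:
    """Convert Hounsfield units to linear attenuation (mm^-1)."""
    return mu_water * (1.0 + np.asarray(hu) / 1000.0)


@dataclass(frozen=True)
class ScanProtocol:
    """Tube and detector settings that fix the photon budget of a scan.

    ``kv_label`` is metadata only (the measurement model is energy-agnostic);
    ``eff_mas`` times ``photons_per_mas`` gives the incident photons per ray.
    """

    eff_mas: float
    kv_label: str = "100 kV"
    photons_per_mas: float = DEFAULT_PHOTONS_PER_MAS
    sigma_e: float = DEFAULT_SIGMA_E

    def __post_init__(self) -> None:
        if self.eff_mas <= 0:
            raise ValueError("eff_mas must be positive")
        if self.photons_per_mas <= 0:
            raise ValueError("photons_per_mas must be positive")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be non-negative")

    @property
    def n0(self) -> float:
        """Incident photons per ray."""
        return self.eff_mas * self.photons_per_mas

    def at_dose_fraction(self, alpha: float) -> "ScanProtocol":
        """Protocol with the tube current scaled by ``alpha``."""
        return replace(self, eff_mas=self.eff_mas * alpha)


@dataclass
class Sinogram:
    """Line-integral data on a parallel-beam geometry.

    ``values`` has shape (n_views, n_bins); view ``i`` is at angle
    ``i * 180 / n_views`` degrees, and detector bins are centered on the
    rotation axis with spacing ``bin_spacing`` mm.
    """

    values: np.ndarray
    bin_spacing: float
    protocol: ScanProtocol | None = None
    mu_water: float = MU_WATER_MM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (views x bins)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram contains non-finite values")
        if self.bin_spacing <= 0:
            raise ValueError("bin_spacing must be positive")

    @property
    def n_views(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_views) * 180.0 / self.n_views

    @property
    def bin_centers(self) -> np.ndarray:
        """Detector-bin center coordinates in mm."""
        return pixel_centers(self.n_bins, self.bin_spacing)

    @property
    def support(self) -> float:
        """Lateral extent covered by the detector, mm."""
        return self.n_bins * self.bin_spacing


def forward_project(
    amap: AttenuationMap,
    n_views: int = DEFAULT_N_VIEWS,
    n_bins: int | None = None,
    mu_water: float = MU_WATER_MM,
) -> Sinogram:
    """Noiseless line integrals of the attenuation map.

    Rotate-and-sum Radon transform: for each view the attenuation image is
    resampled (linear interpolation) onto a frame rotated by the view angle
    about the grid center, columns are summed, and the profile is scaled by
    the pixel size to turn pixel sums into mm line integrals.  The rotation
    center and the detector origin both sit at the symmetric pixel-center
    origin used throughout the package, so projection and backprojection
    share one geometry.  Values outside the grid count as air (mu = 0).
    Detector bins span the map's field of view (``n_bins`` defaults to the
    grid size).
    """
    if n_views < 1 or (n_bins is not None and n_bins < 1):
        raise ValueError("n_views and n_bins must be >= 1")
    n = amap.n
    n_bins = n if n_bins is None else n_bins
    mu = hu_to_mu(amap.grid, mu_water)
    center = (n - 1) / 2.0
    s_native = pixel_centers(n, amap.pixel_size)
    spacing = amap.fov / n_bins
    s_bins = pixel_centers(n_bins, spacing)
    out = np.empty((n_views, n_bins))
    for i, th in enumerate(np.arange(n_views) * np.pi / n_views):
        ct, st = np.cos(th), np.sin(th)
        # output frame: row index = distance along the ray, col index = t
        mat = np.array([[ct, st], [-st, ct]])
        offset = np.array([center, center]) - mat @ np.array([center, center])
        rotated = ndi.affine_transform(
            mu, mat, offset=offset, order=1, mode="constant", cval=0.0
        )
        profile = rotated.sum(axis=0) * amap.pixel_size
        out[i] = profile if n_bins == n else np.interp(s_bins, s_native, profile)
    return Sinogram(out, spacing, mu_water=mu_water)


def measure(
    sino: Sinogram,
    protocol: ScanProtocol,
    seed: int | np.random.SeedSequence,
    noiseless: bool = False,
    strict: bool = False,
    count_floor: float = COUNT_FLOOR,
) -> Sinogram:
    """Simulate the detector measurement of noiseless line integrals.

    Quantum and electronic noise are drawn from disjoint substreams of
    ``seed``, so the same seed reproduces the acquisition bit for bit.  With
    ``noiseless=True`` the input values pass through unchanged and only the
    protocol is attached (the infinite-photon limit).
    """
    if noiseless:
        return Sinogram(
            sino.values.copy(),
            sino.bin_spacing,
            protocol=protocol,
            mu_water=sino.mu_water,
            meta={**sino.meta, "noiseless": True},
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    q_seed, e_seed = ss.spawn(2)
    rng_q = np.random.default_rng(q_seed)
    rng_e = np.random.default_rng(e_seed)

    n0 = protocol.n0
    lam = n0 * np.exp(-sino.values)
    counts = rng_q.poisson(lam).astype(np.float64)
    if protocol.sigma_e > 0:
        counts += rng_e.normal(0.0, protocol.sigma_e, size=counts.shape)
    starved = float(np.mean(counts < count_floor))
    if starved > STARVATION_FRACTION:
        msg = f"photon starvation: {starved:.1%} of rays at the count floor"
        if strict:
            raise PhotonStarvationError(msg)
        warnings.warn(msg, PhotonStarvationWarning, stacklevel=2)
    p_hat = -np.log(np.maximum(counts, count_floor) / n0)
    return Sinogram(
        p_hat,
        sino.bin_spacing,
        protocol=protocol,
        mu_water=sino.mu_water,
        meta={**sino.meta, "starved_fraction": starved},
    )


def acquire(
    amap: AttenuationMap,
    protocol: ScanProtocol,
    seed: int | np.random.SeedSequence,
    n_views: int = DEFAULT_N_VIEWS,
    n_bins: int | None = None,
    noiseless: bool = False,
    strict: bool = False,
    mu_water: float = MU_WATER_MM,
) -> Sinogram:
    """Full "true scan": forward projection followed by noisy measurement."""
    clean = forward_project(amap, n_views=n_views, n_bins=n_bins, mu_water=mu_water)
    return measure(clean, protocol, seed, noiseless=noiseless, strict=strict)
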