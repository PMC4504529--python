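"""Package-wide physical constants and default simulation settings.

Every value here is a plain module-level constant so that a study script can
override it explicitly at call sites; nothing reads environment variables.
"""

#: Linear attenuation coefficient of water, mm^-1, at an effective CT energy
#: of roughly 60-70 keV (100-120 kV tube voltage with typical filtration).
#: Used for the HU <-> mu conversion  mu = MU_WATER_MM * (1 + HU/1000).
MU_WATER_MM: float = 0.0192

#: Incident photons per detector ray per effective mAs.  This is a free
#: parameter of the simulated scanner; the default is anchored so that a
#: 20-cm water phantom scanned at 200 eff. mAs and reconstructed with the
#: default Hann kernel (180 mm FOV) shows a central 5-cm ROI noise of
#: about 10 HU, a realistic soft-tissue head-protocol noise level.
DEFAULT_PHOTONS_PER_MAS: float = 1000.0

#: Electronic (readout) noise standard deviation in detected-count units.
#: Negligible against quantum noise at full dose, but a substantial
#: contribution once the dose fraction drops to a few percent.
DEFAULT_SIGMA_E: float = 10.0

#: Detected counts are floored at this value before the log transform
#: (photon-starvation guard; log(0) is undefined).
COUNT_FLOOR: float = 1.0

#: Fraction of rays allowed to hit the count floor before an acquisition is
#: flagged as photon-starved.
STARVATION_FRACTION: float = 0.01

#: Default acquisition geometry: parallel-beam views over 180 degrees.
DEFAULT_N_VIEWS: int = 360

#: Default phantom raster and scan field of view (mm).
DEFAULT_GRID: int = 512
DEFAULT_FOV_MM: float = 250.0

#: Default reconstruction field of view (mm) and grid, emulating a
#: head-CTA soft-tissue reconstruction.
DEFAULT_RECON_FOV_MM: float = 180.0
DEFAULT_RECON_GRID: int = 256

#: Default reconstruction kernel (Hann-apodized ramp; a smooth soft-tissue
#: kernel stand-in).
DEFAULT_KERNEL: str = "hann"

#: Default display window for PNG previews: (width, center) in HU.
DISPLAY_WINDOW: tuple[float, float] = (700.0, 100.0)
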