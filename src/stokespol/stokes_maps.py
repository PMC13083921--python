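"""Per-pixel maps derived from a Stokes image.

Definitions, all evaluated pixel-wise with ``Ip = sqrt(Q^2 + U^2 + V^2)``:

* normalised components   i = I/Ip, q = Q/Ip, u = U/Ip, v = V/Ip
* ellipticity angle       epsilon = 1/2 arcsin(V / Ip)
* azimuthal angle         theta   = 1/2 atan2(U, Q)
* degree of polarisation  P  = Ip / I
* depolarisation          Dp = sqrt(1 - P^2)

Pixels whose polarised intensity Ip falls below a relative threshold are
masked (numpy masked arrays), never silently NaN-propagated: masking keeps
downstream ROI statistics well-defined.  Noise can push P marginally above
one; such pixels are clamped to P = 1 before Dp and counted in the map
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.ma as ma

__all__ = [
    "StokesImage",
    "NormalisedStokes",
    "PolarisationMaps",
    "normalise_stokes",
    "ellipticity_map",
    "azimuth_map",
    "dop_map",
    "depolarisation_map",
    "compute_maps",
]

#: relative threshold (times max |I|) below which Ip is treated as zero
EPS_IP_REL = 1e-12


@dataclass
class StokesImage:
    """Four co-registered Stokes planes with spatial metadata.

    ``pixel_size_um`` is sample-plane micrometres per pixel (0.1621 at the
    40x objective, 1.621 at 4x for a 6.5 um camera pitch).
    """

    I: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    V: np.ndarray
    pixel_size_um: float = 1.0 / 6.17
    magnification: str = "40x"

    def __post_init__(self) -> None:
        self.I, self.Q, self.U, self.V = (np.asarray(p, dtype=float)
                                          for p in (self.I, self.Q, self.U, self.V))
        shapes = {p.shape for p in (self.I, self.Q, self.U, self.V)}
        if len(shapes) != 1:
            raise ValueError(f"Stokes planes must share one shape, got {shapes}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.I.shape

    def as_array(self) -> np.ndarray:
        return np.stack([self.I, self.Q, self.U, self.V])

    @classmethod
    def from_array(cls, arr: np.ndarray, **meta) -> "StokesImage":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != 4:
            raise ValueError("expected leading axis of length 4 (I, Q, U, V)")
        return cls(arr[0], arr[1], arr[2], arr[3], **meta)


@dataclass
class NormalisedStokes:
    """Ip-normalised components; masked where Ip is numerically zero."""

    i: ma.MaskedArray
    q: ma.MaskedArray
    u: ma.MaskedArray
    v: ma.MaskedArray
    ip: np.ndarray
    n_masked: int


@dataclass
class PolarisationMaps:
    """The full derived-map set for one Stokes image."""

    normalised: NormalisedStokes
    epsilon: ma.MaskedArray
    theta: ma.MaskedArray
    P: ma.MaskedArray
    Dp: ma.MaskedArray
    n_clamped: int
    pixel_size_um: float


def _polarised_intensity(img: StokesImage) -> tuple[np.ndarray, np.ndarray]:
    ip = np.sqrt(img.Q ** 2 + img.U ** 2 + img.V ** 2)
    eps = EPS_IP_REL * max(float(np.max(np.abs(img.I))), 1e-300)
    return ip, ip <= eps


def normalise_stokes(img: StokesImage) -> NormalisedStokes:
    """Divide each plane by the polarised intensity Ip, masking Ip ~ 0 pixels."""
    ip, mask = _polarised_intensity(img)
    safe = np.where(mask, 1.0, ip)
    comp = [ma.MaskedArray(p / safe, mask=mask) for p in (img.I, img.Q, img.U, img.V)]
    return NormalisedStokes(*comp, ip=ip, n_masked=int(mask.sum()))


def ellipticity_map(img: StokesImage) -> ma.MaskedArray:
    """Ellipticity angle per pixel, in [-pi/4, pi/4]; masked where Ip ~ 0."""
    ip, mask = _polarised_intensity(img)
    safe = np.where(mask, 1.0, ip)
    return ma.MaskedArray(0.5 * np.arcsin(np.clip(img.V / safe, -1.0, 1.0)), mask=mask)


def azimuth_map(img: StokesImage) -> ma.MaskedArray:
    """Polarisation azimuth per pixel in (-pi/2, pi/2].

    Computed as ``theta = 1/2 atan2(U, Q)`` — the two-argument arctangent
    resolves the quadrant that the plain U/Q ratio loses and handles Q = 0.
    Masked where Q and U both vanish (azimuth undefined).
    """
    scale = max(float(np.max(np.hypot(img.Q, img.U))), 1e-300)
    mask = np.hypot(img.Q, img.U) <= EPS_IP_REL * scale
    theta = 0.5 * np.arctan2(img.U, img.Q)
    # map the -pi/2 branch point onto +pi/2 so the range is half-open
    theta = np.where(theta <= -np.pi / 2 + 1e-15, theta + np.pi, theta)
    return ma.MaskedArray(theta, mask=mask)


def dop_map(img: StokesImage, return_diagnostics: bool = False):
    """Degree of polarisation P = Ip / I, clamped to [0, 1].

    Pixels with I <= 0 are masked; noise-driven P > 1 values are clamped and
    (optionally) counted.
    """
    ip, _ = _polarised_intensity(img)
    mask = img.I <= 0
    safe_i = np.where(mask, 1.0, img.I)
    p_raw = ip / safe_i
    n_clamped = int(np.sum(~mask & (p_raw > 1.0)))
    p = ma.MaskedArray(np.clip(p_raw, 0.0, 1.0), mask=mask)
    if return_diagnostics:
        return p, n_clamped
    return p


def depolarisation_map(img: StokesImage, return_diagnostics: bool = False):
    """Depolarisation Dp = sqrt(1 - P^2), in [0, 1]."""
    out = dop_map(img, return_diagnostics=True)
    p, n_clamped = out
    dp = ma.sqrt(1.0 - p ** 2)
    if return_diagnostics:
        return dp, n_clamped
    return dp


def compute_maps(img: StokesImage) -> PolarisationMaps:
    """All derived maps plus masking/clamping diagnostics in one pass."""
    norm = normalise_stokes(img)
    p, n_clamped = dop_map(img, return_diagnostics=True)
    return PolarisationMaps(
        normalised=norm,
        epsilon=ellipticity_map(img),
        theta=azimuth_map(img),
        P=p,
        Dp=ma.sqrt(1.0 - p ** 2),
        n_clamped=n_clamped,
        pixel_size_um=img.pixel_size_um,
    )
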