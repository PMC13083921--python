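"""Synthetic tissue phantoms and full acquisition rendering.

Every downstream stage of the pipeline is testable without real data: a
phantom carries a known per-pixel (delta_s, gamma, sigma) field, and
:func:`render_acquisition` pushes a chosen illumination state through the
sample model and the dual-PEM instrument model to produce the per-pixel
harmonic-signal planes a real acquisition would yield — together with the
matching no-sample reference acquisition ("with and without the sample").

Phantom kinds emulate the collagen architectures the instrument was built
to contrast, with magnitudes anchored to the tissue values the technique
reports so simulated experiments read against familiar numbers:

* ``placenta_villi`` — concentric perivascular rings, optic axis tangential,
  peak retardation 0.04 rad above baseline;
* ``dermis``        — oriented fibre bands with modest orientation
  dispersion, peak 1.00 rad;
* ``keloid``        — a dense lesion patch with chaotic axis orientation,
  peak 1.40 rad and depolarisation rising to 0.96;
* ``flat``          — constant fields, for calibration and noise studies.

Tissue kinds sit on a substrate whose retardation baseline defaults to
0.11 rad and whose depolarisation is ~0.44 (mid-range of the 0.40-0.48
substrate band); tissue outside lesions depolarises at ~0.37.  Peaks are
normalised so the maximum above baseline equals the anchor exactly.  All
randomness is driven by the spec seed: identical seeds give bit-identical
phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import numpy.ma as ma
from scipy import ndimage

from .birefringence import (SampleMap, axis_from_linear, propagate,
                            retardation_from_circular)
from .calibration import KMatrix, stokes_from_signals
from .instrument import (HarmonicSignalSet, PolarimeterConfig,
                         PolarisationState, signal_matrix)
from .stokes_maps import StokesImage, compute_maps, normalise_stokes

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "Acquisition",
    "RecoveredSample",
    "generate_phantom",
    "render_acquisition",
    "recover_sample",
    "tune_read_noise",
    "dp_to_sigma",
]

PHANTOM_KINDS = ("placenta_villi", "dermis", "keloid", "flat")

#: retardation anchors (rad, above baseline) per phantom kind
DEFAULT_DELTA_PEAK = {"placenta_villi": 0.04, "dermis": 1.00, "keloid": 1.40, "flat": 0.0}


def dp_to_sigma(dp: float | np.ndarray) -> float | np.ndarray:
    """Depolarisation factor sigma = P^-1 = (1 - Dp^2)^(-1/2)."""
    dp = np.asarray(dp, dtype=float)
    if np.any((dp < 0) | (dp >= 1)):
        raise ValueError("Dp must lie in [0, 1)")
    out = 1.0 / np.sqrt(1.0 - dp ** 2)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic tissue phantom (all lengths in pixels)."""

    kind: str = "flat"
    shape: tuple = (128, 128)
    seed: int = 0
    delta_peak: float | None = None      # rad above baseline; kind default if None
    background_delta: float | None = None  # rad; 0.11 for tissue kinds, 0 for flat
    background_dp: float = 0.44
    tissue_dp: float = 0.37
    lesion_dp_max: float = 0.96          # keloid only
    n_villi: int = 5                     # placenta ring count
    n_bands: int = 4                     # dermis band count
    band_dispersion: float = 0.25        # rad, spread of band orientations
    lesion_fraction: float = 0.25        # keloid area fraction
    flat_gamma: float = 0.0
    flat_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        peak = self.resolved_delta_peak
        bg = self.resolved_background_delta
        if not 0 <= bg + peak <= np.pi:
            raise ValueError("baseline + peak retardation must lie in [0, pi]")

    @property
    def resolved_delta_peak(self) -> float:
        return DEFAULT_DELTA_PEAK[self.kind] if self.delta_peak is None else self.delta_peak

    @property
    def resolved_background_delta(self) -> float:
        if self.background_delta is not None:
            return self.background_delta
        return 0.0 if self.kind == "flat" else 0.11


@dataclass(frozen=True)
class NoiseSpec:
    """Additive camera noise applied to the demodulated signal planes.

    ``read_noise_sd`` is Gaussian read noise in signal units.  When
    ``photon_scale`` (counts per unit intensity) is set, the DC plane is
    Poisson-resampled and the harmonic planes receive the matching
    shot-noise floor ``sqrt(S_DC / photon_scale)`` — an idealised transfer
    of photon statistics through the lock-in.
    """

    read_noise_sd: float = 0.0
    photon_scale: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")
        if self.photon_scale is not None and self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive (or None to disable)")


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

def _grid(shape: tuple) -> tuple[np.ndarray, np.ndarray]:
    return np.meshgrid(np.arange(shape[0], dtype=float),
                       np.arange(shape[1], dtype=float), indexing="ij")


def _placenta(spec: PhantomSpec, rng: np.random.Generator):
    yy, xx = _grid(spec.shape)
    profile = np.zeros(spec.shape)
    gamma = np.zeros(spec.shape)
    h, w = spec.shape
    for _ in range(spec.n_villi):
        cy, cx = rng.uniform(0.15 * h, 0.85 * h), rng.uniform(0.15 * w, 0.85 * w)
        r0 = rng.uniform(0.06, 0.14) * min(h, w)
        width = rng.uniform(0.25, 0.45) * r0
        r = np.hypot(yy - cy, xx - cx)
        ring = np.exp(-0.5 * ((r - r0) / width) ** 2)
        update = ring > profile
        # optic axis tangential to the ring
        gamma = np.where(update, np.mod(np.arctan2(yy - cy, xx - cx) + np.pi / 2, np.pi), gamma)
        profile = np.maximum(profile, ring)
    return profile, gamma, profile > 0.2


def _dermis(spec: PhantomSpec, rng: np.random.Generator):
    yy, xx = _grid(spec.shape)
    h, w = spec.shape
    profile = np.zeros(spec.shape)
    gamma = np.zeros(spec.shape)
    mean_orientation = rng.uniform(0, np.pi)
    for _ in range(spec.n_bands):
        theta = mean_orientation + rng.normal(0.0, spec.band_dispersion)
        # signed distance from a band centreline perpendicular to theta
        d = (yy - rng.uniform(0, h)) * np.cos(theta) - (xx - rng.uniform(0, w)) * np.sin(theta)
        band = np.exp(-0.5 * (d / (rng.uniform(0.04, 0.09) * min(h, w))) ** 2)
        update = band > profile
        gamma = np.where(update, np.mod(theta, np.pi), gamma)
        profile = np.maximum(profile, band)
    return profile, gamma, profile > 0.2


def _keloid(spec: PhantomSpec, rng: np.random.Generator):
    h, w = spec.shape
    noise = rng.standard_normal(spec.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=0.08 * min(h, w), mode="wrap")
    thresh = np.quantile(smooth, 1.0 - spec.lesion_fraction)
    lesion = smooth > thresh
    # soft-edged retardation profile peaking inside the lesion
    profile = ndimage.gaussian_filter(lesion.astype(float), sigma=0.02 * min(h, w))
    if profile.max() > 0:
        profile /= profile.max()
    # chaotic but spatially correlated axis field
    gfield = ndimage.gaussian_filter(rng.standard_normal(spec.shape),
                                     sigma=0.03 * min(h, w), mode="wrap")
    rge = np.ptp(gfield) or 1.0
    gamma = np.mod((gfield - gfield.min()) / rge * np.pi, np.pi)
    return profile, gamma, lesion


def generate_phantom(spec: PhantomSpec) -> tuple[SampleMap, dict]:
    """Build a SampleMap with ground truth for the requested phantom kind.

    Returns ``(sample_map, truth)`` where ``truth`` records the exact fields
    and the construction parameters.  The structure profile is normalised so
    that max(delta) - baseline equals the kind's peak anchor exactly.
    """
    rng = np.random.default_rng(spec.seed)
    bg_delta = spec.resolved_background_delta
    peak = spec.resolved_delta_peak

    if spec.kind == "flat":
        delta = np.full(spec.shape, bg_delta + peak)
        gamma = np.full(spec.shape, np.mod(spec.flat_gamma, np.pi))
        sigma = np.full(spec.shape, spec.flat_sigma)
        tissue = np.zeros(spec.shape, dtype=bool)
    else:
        builder = {"placenta_villi": _placenta, "dermis": _dermis, "keloid": _keloid}[spec.kind]
        profile, gamma, tissue = builder(spec, rng)
        if profile.max() > 0:
            profile = profile / profile.max()
        delta = bg_delta + peak * profile
        sigma = np.where(tissue, dp_to_sigma(spec.tissue_dp), dp_to_sigma(spec.background_dp))
        if spec.kind == "keloid":
            # depolarisation climbs with collagen density, reaching the lesion maximum
            dp_map = np.where(tissue,
                              spec.tissue_dp + (spec.lesion_dp_max - spec.tissue_dp) * profile,
                              spec.background_dp)
            if tissue.any():  # pin the maximum exactly
                dp_map[np.unravel_index(np.argmax(profile), profile.shape)] = spec.lesion_dp_max
            sigma = dp_to_sigma(dp_map)

    smap = SampleMap(delta=delta, gamma=gamma, sigma=sigma)
    smap.validate()
    truth = {"delta": delta.copy(), "gamma": np.asarray(gamma).copy(),
             "sigma": np.asarray(sigma).copy(), "tissue_mask": tissue,
             "spec": spec}
    return smap, truth


# --------------------------------------------------------------------------
# acquisition rendering and recovery
# --------------------------------------------------------------------------

@dataclass
class Acquisition:
    """Rendered per-pixel signals plus the no-sample reference acquisition."""

    signals: HarmonicSignalSet          # with sample, per pixel
    reference: HarmonicSignalSet        # without sample (input state), per pixel
    input_state: PolarisationState
    cfg: PolarimeterConfig
    stokes_true: StokesImage            # noiseless transmitted Stokes planes
    pixel_size_um: float = 1.0 / 6.17


def _apply_noise(arr: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    out = arr.copy()
    if noise.photon_scale is not None:
        dc = np.clip(out[0], 0.0, None)
        out[0] = rng.poisson(dc * noise.photon_scale) / noise.photon_scale
        shot = np.sqrt(dc / noise.photon_scale)
        for k in (1, 2, 3):
            out[k] = out[k] + rng.normal(0.0, 1.0, dc.shape) * shot
    if noise.read_noise_sd > 0:
        out = out + rng.normal(0.0, noise.read_noise_sd, out.shape)
    return out


def render_acquisition(smap: SampleMap, input_state: PolarisationState,
                       cfg: PolarimeterConfig | None = None,
                       noise: NoiseSpec | None = None,
                       pixel_size_um: float = 1.0 / 6.17) -> Acquisition:
    """Render a complete acquisition through sample and instrument models.

    Per pixel: sample Mueller -> transmitted Stokes -> analytic harmonic
    signals -> optional noise.  The no-sample reference (the illumination
    state seen by the bare instrument) is rendered alongside with
    independent noise.  Noiseless output reconstructs the ground-truth maps
    to solver tolerance.
    """
    if cfg is None:
        cfg = PolarimeterConfig()
    s_in = input_state.as_array().astype(float)
    ip_in = float(np.linalg.norm(s_in[1:]))
    if ip_in <= 0:
        raise ValueError("input state must carry a non-zero polarised component")
    norm_in = s_in / ip_in
    out_norm = propagate(norm_in, smap)              # (4, H, W)
    stokes_out = out_norm * ip_in                    # un-normalise
    m = signal_matrix(cfg)
    sig = np.einsum("ij,j...->i...", m, stokes_out)
    ref = np.einsum("ij,j->i", m, s_in)
    ref = np.broadcast_to(ref[:, None, None], sig.shape).copy()
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        sig = _apply_noise(sig, noise, rng)
        ref = _apply_noise(ref, noise, rng)
    return Acquisition(
        signals=HarmonicSignalSet.from_array(sig),
        reference=HarmonicSignalSet.from_array(ref),
        input_state=input_state, cfg=cfg,
        stokes_true=StokesImage.from_array(stokes_out, pixel_size_um=pixel_size_um),
        pixel_size_um=pixel_size_um)


@dataclass
class RecoveredSample:
    """Pipeline output: estimated sample parameters plus diagnostics."""

    smap: SampleMap
    stokes: StokesImage
    dp: ma.MaskedArray
    n_clamped: int
    n_fallback: int = 0
    mode: str = "circular"


def recover_sample(acq: Acquisition, K: KMatrix, mode: str = "circular") -> RecoveredSample:
    """Reconstruct (delta_s, gamma, sigma) maps from an acquisition.

    Applies K to the signal planes, normalises against the polarised
    intensity, and inverts the sample model.  ``mode='circular'`` uses the
    direct arccos(v') estimator (exact for circular illumination);
    ``mode='full'`` solves the three propagation equations per pixel using
    the measured no-sample reference state, which is slower but unbiased for
    elliptical illumination.
    """
    from .birefringence import retardation_full_inversion  # local: avoids cycle at import

    stokes_out = stokes_from_signals(acq.signals, K)
    stokes_ref = stokes_from_signals(acq.reference, K)
    img = StokesImage(stokes_out.I, stokes_out.Q, stokes_out.U, stokes_out.V,
                      pixel_size_um=acq.pixel_size_um)
    norm = normalise_stokes(img)
    qp = np.asarray(ma.filled(norm.q, 0.0))
    up = np.asarray(ma.filled(norm.u, 0.0))
    vp = np.asarray(ma.filled(norm.v, 0.0))

    ref_arr = stokes_ref.as_array().reshape(4, -1).mean(axis=1)
    ip_ref = float(np.linalg.norm(ref_arr[1:]))
    ref_norm = ref_arr / ip_ref

    if mode == "circular":
        delta, n_clamped = retardation_from_circular(vp, return_diagnostics=True)
        gamma = axis_from_linear(qp, up)
        n_fallback = 0
    elif mode == "full":
        delta, gamma, n_fallback = retardation_full_inversion(qp, up, vp, ref_norm[1:])
        n_clamped = 0
    else:
        raise ValueError("mode must be 'circular' or 'full'")

    # sigma from the intensity excess over the polarised part: i' / i_in
    i_in = ref_arr[0] / ip_ref
    sigma = np.clip(np.asarray(ma.filled(norm.i, np.nan)) / i_in, 1.0, None)
    smap = SampleMap(delta=delta, gamma=gamma, sigma=sigma)
    dp = ma.sqrt(np.clip(1.0 - 1.0 / ma.masked_invalid(sigma) ** 2, 0.0, None))
    return RecoveredSample(smap=smap, stokes=img, dp=dp, n_clamped=n_clamped,
                           n_fallback=n_fallback, mode=mode)


def tune_read_noise(target_sd: float = 0.005,
                    cfg: PolarimeterConfig | None = None,
                    input_state: PolarisationState | None = None,
                    K: KMatrix | None = None,
                    baseline_delta: float = 0.11,
                    shape: tuple = (64, 64),
                    seed: int = 0,
                    pilot_sd: float = 1e-3,
                    n_iter: int = 2) -> float:
    """Read-noise level that produces a chosen retardation noise floor.

    Runs pilot acquisitions of a flat phantom at the substrate baseline,
    measures the standard deviation of the reconstructed retardation map and
    scales the read noise towards ``target_sd`` (the mapping is linear for
    small noise away from delta = 0; one refinement pass corrects residual
    curvature).
    """
    from .calibration import instrument_k

    if cfg is None:
        cfg = PolarimeterConfig()
    if input_state is None:
        input_state = PolarisationState.circular()
    if K is None:
        K = instrument_k(cfg)
    spec = PhantomSpec(kind="flat", shape=shape, seed=seed, delta_peak=0.0,
                       background_delta=baseline_delta)
    smap, _ = generate_phantom(spec)
    sd = pilot_sd
    for k in range(n_iter):
        acq = render_acquisition(smap, input_state, cfg,
                                 noise=NoiseSpec(read_noise_sd=sd, seed=seed + 1 + k))
        rec = recover_sample(acq, K, mode="circular")
        measured = float(np.std(rec.smap.delta))
        if measured == 0:
            raise RuntimeError("pilot acquisition produced a noiseless retardation map")
        sd = sd * target_sd / measured
    return sd
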