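"""Forward model of a dual photoelastic-modulator (PEM) Stokes polarimeter.

The polarimeter places two PEMs and a linear analyser in the imaging path.
Each PEM imposes a sinusoidally oscillating retardance ``delta_k(t) =
A_k sin(2*pi*f_k*t)``, shifting polarisation information to harmonics of the
resonant frequencies ``f_1``, ``f_2``.  The detector sees the first Stokes
component of

    M_pol(beta) . M_ret(delta_2(t), 0) . M_ret(delta_1(t), alpha) . S_in

where, by construction, the optic axis of PEM2 defines the x-axis, PEM1 sits
at angle ``alpha`` (~45 deg) and the analyser transmission axis at ``beta``
(~23 deg).

Four demodulated quantities carry the polarisation state: the DC level
``S_DC``, the second-harmonic amplitudes at ``2 f_1`` and ``2 f_2``
(``S_QU1``, ``S_QU2``) and the first-harmonic amplitude at ``f_1`` (``S_v``).
Two independent routes compute them:

* :func:`lockin_demodulate` — numerical lock-in on a sampled intensity
  series over an integer number of common periods;
* :func:`analytic_harmonics` — a Bessel-series (Jacobi–Anger) expansion of
  the modulated Mueller chain, truncated at a configurable order.

Both are linear in the input Stokes vector; :func:`signal_matrix` returns
the induced 4x4 map (signals <- Stokes), whose inverse is the calibration
matrix K estimated in :mod:`stokespol.calibration`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import gcd

import numpy as np
from scipy.special import jv

__all__ = [
    "PolarimeterConfig",
    "PolarisationState",
    "HarmonicSignalSet",
    "mueller_rotator",
    "mueller_retarder",
    "mueller_polariser",
    "detector_intensity",
    "simulate_time_series",
    "lockin_demodulate",
    "analytic_harmonics",
    "signal_matrix",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarimeterConfig:
    """Geometry and modulation parameters of the dual-PEM polarimeter.

    Angles are radians; frequencies are in arbitrary reciprocal time units
    (only their ratio matters to the demodulation math); PEM amplitudes are
    peak retardations in radians.  Defaults follow standard dual-PEM
    practice: ``A = 2.405`` rad (the first zero of J0) suppresses the
    retardance contribution to the DC level, and the 50/42 frequency pair
    mirrors the 50 kHz / 42 kHz optical heads of the physical instrument.
    """

    alpha: float = np.pi / 4
    beta: float = np.deg2rad(23.0)
    f1: float = 50.0
    f2: float = 42.0
    A1: float = 2.405
    A2: float = 2.405
    wavelength_nm: float = 530.0  # metadata only

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("PEM frequencies must be positive")
        if self.f1 == self.f2:
            raise ValueError("PEM frequencies must be distinct")
        if self.A1 <= 0 or self.A2 <= 0:
            raise ValueError("PEM amplitudes must be positive")

    @property
    def common_period(self) -> float:
        """Shortest interval containing a whole number of both PEM cycles.

        Requires ``f1/f2`` to be a small-denominator rational (p/q with
        q <= 1000, to 1e-9 relative); otherwise no usable common period
        exists and a ``ValueError`` is raised.
        """
        ratio = Fraction(self.f1 / self.f2).limit_denominator(1000)
        if abs(float(ratio) - self.f1 / self.f2) > 1e-9 * (self.f1 / self.f2):
            raise ValueError("f1/f2 must be commensurate for periodic simulation")
        # f1 T = p, f2 T = q whole cycles
        return ratio.numerator / self.f1


@dataclass
class PolarisationState:
    """A Stokes vector (I, Q, U, V) in arbitrary intensity units.

    Fields may be scalars or equally-shaped arrays (per-pixel states).
    """

    I: float | np.ndarray
    Q: float | np.ndarray
    U: float | np.ndarray
    V: float | np.ndarray

    def as_array(self) -> np.ndarray:
        """Stack into an array with the Stokes index first (shape ``(4, ...)``)."""
        return np.stack(np.broadcast_arrays(
            np.asarray(self.I, dtype=float), np.asarray(self.Q, dtype=float),
            np.asarray(self.U, dtype=float), np.asarray(self.V, dtype=float)))

    def validate(self, rtol: float = 1e-9) -> None:
        """Check physicality: ``I >= 0`` and ``Q^2+U^2+V^2 <= I^2`` (within rtol)."""
        arr = self.as_array()
        if np.any(arr[0] < 0):
            raise ValueError("Stokes I must be non-negative")
        pol2 = arr[1] ** 2 + arr[2] ** 2 + arr[3] ** 2
        if np.any(pol2 > arr[0] ** 2 * (1.0 + rtol) + rtol):
            raise ValueError("polarised intensity exceeds total intensity")

    # -- constructors for common states ------------------------------------
    @classmethod
    def unpolarised(cls, intensity: float = 1.0) -> "PolarisationState":
        return cls(intensity, 0.0, 0.0, 0.0)

    @classmethod
    def linear(cls, angle: float, intensity: float = 1.0) -> "PolarisationState":
        return cls(intensity, intensity * np.cos(2 * angle), intensity * np.sin(2 * angle), 0.0)

    @classmethod
    def circular(cls, handedness: int = 1, intensity: float = 1.0) -> "PolarisationState":
        return cls(intensity, 0.0, 0.0, float(np.sign(handedness)) * intensity)

    @classmethod
    def elliptical(cls, ellipticity: float, azimuth: float = 0.0,
                   intensity: float = 1.0, dop: float = 1.0) -> "PolarisationState":
        """Fully (or partially) polarised state from ellipse parameters.

        ``ellipticity`` is the ellipticity angle epsilon (0 linear, pi/4
        circular); ``azimuth`` the major-axis angle; ``dop`` the degree of
        polarisation.
        """
        p = intensity * dop
        return cls(intensity,
                   p * np.cos(2 * ellipticity) * np.cos(2 * azimuth),
                   p * np.cos(2 * ellipticity) * np.sin(2 * azimuth),
                   p * np.sin(2 * ellipticity))


@dataclass
class HarmonicSignalSet:
    """Demodulated polarimeter signals; scalar or per-pixel arrays."""

    s_dc: float | np.ndarray
    s_qu1: float | np.ndarray
    s_qu2: float | np.ndarray
    s_v: float | np.ndarray

    def as_array(self) -> np.ndarray:
        return np.stack(np.broadcast_arrays(
            np.asarray(self.s_dc, dtype=float), np.asarray(self.s_qu1, dtype=float),
            np.asarray(self.s_qu2, dtype=float), np.asarray(self.s_v, dtype=float)))

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "HarmonicSignalSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[0] != 4:
            raise ValueError("expected leading axis of length 4 (S_DC, S_QU1, S_QU2, S_v)")
        return cls(arr[0], arr[1], arr[2], arr[3])


# --------------------------------------------------------------------------
# elementary Mueller matrices
# --------------------------------------------------------------------------

def mueller_rotator(angle: float) -> np.ndarray:
    """Stokes-frame rotation by ``angle``; ``rotator(a) @ rotator(b) == rotator(a+b)``."""
    c, s = np.cos(2 * angle), np.sin(2 * angle)
    return np.array([[1, 0, 0, 0],
                     [0, c, -s, 0],
                     [0, s, c, 0],
                     [0, 0, 0, 1.0]])


def mueller_retarder(delta: float, angle: float = 0.0) -> np.ndarray:
    """Linear retarder: retardance ``delta``, fast axis at ``angle``.

    The sign convention is fixed so that, at ``angle = 0``, right-circular
    light acquires ``U' = sin(delta)``; with a unit depolarisation factor the
    uniaxial sample model in :mod:`stokespol.birefringence` coincides with
    this matrix entry-by-entry.
    """
    cd, sd = np.cos(delta), np.sin(delta)
    m0 = np.array([[1, 0, 0, 0],
                   [0, 1, 0, 0],
                   [0, 0, cd, sd],
                   [0, 0, -sd, cd]])
    if angle == 0.0:
        return m0
    return mueller_rotator(angle) @ m0 @ mueller_rotator(-angle)


def mueller_polariser(angle: float) -> np.ndarray:
    """Ideal linear polariser with transmission axis at ``angle`` (idempotent)."""
    c, s = np.cos(2 * angle), np.sin(2 * angle)
    return 0.5 * np.array([[1, c, s, 0],
                           [c, c * c, c * s, 0],
                           [s, c * s, s * s, 0],
                           [0, 0, 0, 0.0]])


def _retarder_stack(deltas: np.ndarray, angle: float) -> np.ndarray:
    """Retarder matrices for an array of retardances, all at one axis angle."""
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.shape
    cd, sd = np.cos(deltas), np.sin(deltas)
    m = np.zeros(n + (4, 4))
    m[..., 0, 0] = 1.0
    m[..., 1, 1] = 1.0
    m[..., 2, 2] = cd
    m[..., 2, 3] = sd
    m[..., 3, 2] = -sd
    m[..., 3, 3] = cd
    if angle != 0.0:
        r, rinv = mueller_rotator(angle), mueller_rotator(-angle)
        m = np.einsum("ij,...jk,kl->...il", r, m, rinv)
    return m


# --------------------------------------------------------------------------
# time-domain forward model and numerical lock-in
# --------------------------------------------------------------------------

def detector_intensity(state: PolarisationState, cfg: PolarimeterConfig,
                       t: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous detector intensity for input ``state`` at time(s) ``t``."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    d1 = cfg.A1 * np.sin(2 * np.pi * cfg.f1 * t)
    d2 = cfg.A2 * np.sin(2 * np.pi * cfg.f2 * t)
    m1 = _retarder_stack(d1, cfg.alpha)
    m2 = _retarder_stack(d2, 0.0)
    row = mueller_polariser(cfg.beta)[0]
    s = state.as_array()
    out = np.einsum("i,...ij,...jk,k->...", row, m2, m1, s)
    return float(out) if out.ndim == 0 else out


def simulate_time_series(state: PolarisationState, cfg: PolarimeterConfig,
                         n_samples: int = 16384, n_periods: int = 1
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Sample the detector signal uniformly over ``n_periods`` common periods.

    The endpoint is excluded so the samples tile the period exactly, which
    makes the discrete lock-in sums exact Fourier projections.
    """
    T = cfg.common_period * n_periods
    t = np.arange(n_samples) * (T / n_samples)
    return t, detector_intensity(state, cfg, t)


def lockin_demodulate(series: np.ndarray, cfg: PolarimeterConfig,
                      n_periods: int = 1) -> HarmonicSignalSet:
    """Phase-sensitive recovery of DC and harmonic amplitudes.

    ``series`` must be sampled uniformly over exactly ``n_periods`` common
    periods of the two PEMs (endpoint excluded).  References: ``cos(2 w1 t)``
    for S_QU1, ``cos(2 w2 t)`` for S_QU2 and ``sin(w1 t)`` for S_v; in-phase
    amplitudes are twice the mean of the product.

    Raises ``ValueError`` for non-commensurate frequencies or a series too
    short to resolve the fastest relevant harmonic (>= 20 samples per cycle
    of ``2 max(f1, f2)``).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    T = cfg.common_period * n_periods  # raises if f1/f2 non-commensurate
    n = series.size
    fastest = 2.0 * max(cfg.f1, cfg.f2)
    if n < 20 * fastest * T:
        raise ValueError(
            f"series of {n} samples under-samples the {fastest} harmonic over period {T}")
    t = np.arange(n) * (T / n)
    s_dc = series.mean()
    s_qu1 = 2.0 * np.mean(series * np.cos(2 * np.pi * 2 * cfg.f1 * t))
    s_qu2 = 2.0 * np.mean(series * np.cos(2 * np.pi * 2 * cfg.f2 * t))
    s_v = 2.0 * np.mean(series * np.sin(2 * np.pi * cfg.f1 * t))
    return HarmonicSignalSet(s_dc, s_qu1, s_qu2, s_v)


# --------------------------------------------------------------------------
# Bessel-series (Jacobi-Anger) analytic harmonics
# --------------------------------------------------------------------------
#
# The detector intensity is a polynomial of degree <= 1 in each of
# cos(delta_1), sin(delta_1), cos(delta_2), sin(delta_2), so it decomposes
# over the 3x3 tensor basis {1, cos, sin} x {1, cos, sin}.  The coefficients
# are recovered exactly by evaluating the Mueller chain on a 3x3 grid of
# static retardances; the Jacobi-Anger expansion then turns each basis
# function into a line spectrum whose products are collected trigonometric-
# identity by identity.

_BASIS_POINTS = (0.3, 1.3, 2.6)


def _basis_coefficients(state: PolarisationState, cfg: PolarimeterConfig) -> np.ndarray:
    """Coefficients c[i, j] of the intensity over {1, cos d1, sin d1} x {1, cos d2, sin d2}."""
    row = mueller_polariser(cfg.beta)[0]
    s = state.as_array()
    design, rhs = [], []
    for d1 in _BASIS_POINTS:
        m1 = mueller_retarder(d1, cfg.alpha)
        for d2 in _BASIS_POINTS:
            m2 = mueller_retarder(d2, 0.0)
            design.append([b1 * b2
                           for b1 in (1.0, np.cos(d1), np.sin(d1))
                           for b2 in (1.0, np.cos(d2), np.sin(d2))])
            rhs.append(row @ m2 @ m1 @ s)
    coef = np.linalg.solve(np.asarray(design), np.asarray(rhs))
    return coef.reshape(3, 3)


def _bessel_lines(kind: int, amplitude: float, freq: float, order: int) -> dict:
    """Line spectrum {frequency: [cos_amp, sin_amp]} of a basis function.

    kind 0: constant 1; kind 1: cos(A sin wt); kind 2: sin(A sin wt).
    """
    if kind == 0:
        return {0.0: [1.0, 0.0]}
    lines: dict = {}
    if kind == 1:
        lines[0.0] = [float(jv(0, amplitude)), 0.0]
        for k in range(1, order + 1):
            lines[2 * k * freq] = [2.0 * float(jv(2 * k, amplitude)), 0.0]
    else:
        for k in range(order + 1):
            lines[(2 * k + 1) * freq] = [0.0, 2.0 * float(jv(2 * k + 1, amplitude))]
    return lines


def _multiply_lines(la: dict, lb: dict) -> dict:
    """Product of two line spectra via the trigonometric product identities."""
    out: dict = {}

    def _add(f: float, c: float, s: float) -> None:
        if f < 0:  # fold negative frequencies: cos is even, sin is odd
            f, s = -f, -s
        entry = out.setdefault(round(f, 9), [0.0, 0.0])
        entry[0] += c
        entry[1] += s

    for fa, (ca, sa) in la.items():
        for fb, (cb, sb) in lb.items():
            _add(fa - fb, 0.5 * ca * cb, 0.0)
            _add(fa + fb, 0.5 * ca * cb, 0.0)
            _add(fa - fb, 0.5 * sa * sb, 0.0)
            _add(fa + fb, -0.5 * sa * sb, 0.0)
            _add(fa - fb, 0.0, 0.5 * sa * cb)
            _add(fa + fb, 0.0, 0.5 * sa * cb)
            _add(fb - fa, 0.0, 0.5 * ca * sb)
            _add(fa + fb, 0.0, 0.5 * ca * sb)
    return out


def analytic_harmonics(state: PolarisationState, cfg: PolarimeterConfig,
                       order: int = 8) -> HarmonicSignalSet:
    """Demodulated signals from the truncated Bessel-series expansion.

    Independent of the time-domain route: no sampling is involved, only the
    Jacobi-Anger line spectra of the two modulated retardances, truncated at
    Bessel ``order`` (default 8; amplitudes beyond order ~6 are negligible at
    A ~ 2.4 rad).  Each returned signal is a linear functional of
    (I, Q, U, V).
    """
    coef = _basis_coefficients(state, cfg)
    total: dict = {}
    for i in range(3):
        li = _bessel_lines(i, cfg.A1, cfg.f1, order)
        for j in range(3):
            if coef[i, j] == 0.0:
                continue
            lj = _bessel_lines(j, cfg.A2, cfg.f2, order)
            for f, (c, s) in _multiply_lines(li, lj).items():
                entry = total.setdefault(f, [0.0, 0.0])
                entry[0] += coef[i, j] * c
                entry[1] += coef[i, j] * s

    def _at(f: float) -> list:
        return total.get(round(float(f), 9), [0.0, 0.0])

    return HarmonicSignalSet(_at(0.0)[0], _at(2 * cfg.f1)[0],
                             _at(2 * cfg.f2)[0], _at(cfg.f1)[1])


@lru_cache(maxsize=32)
def signal_matrix(cfg: PolarimeterConfig, order: int = 8) -> np.ndarray:
    """The 4x4 linear map M with (S_DC, S_QU1, S_QU2, S_v) = M (I, Q, U, V).

    Built column-by-column from :func:`analytic_harmonics` on the Stokes unit
    vectors; its inverse is the ground-truth calibration matrix K of the
    simulated instrument.
    """
    cols = []
    for e in np.eye(4):
        h = analytic_harmonics(PolarisationState(*e), cfg, order=order)
        cols.append(h.as_array())
    m = np.column_stack(cols)
    m.setflags(write=False)
    return m
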