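"""Uniaxial birefringent-sample model: forward propagation and inversion.

A thin section with in-plane optic axis at angle ``gamma``, phase
retardation ``delta_s`` (radians) and depolarisation factor
``sigma = P^-1 >= 1`` acts on a normalised Stokes vector via

    M_s = [ sigma  0                          0                          0            ]
          [ 0      cos(4g) s^2 + c^2          sin(4g) s^2               -sin(2g) sin d ]
          [ 0      sin(4g) s^2               -cos(4g) s^2 + c^2          cos(2g) sin d ]
          [ 0      sin(2g) sin d             -cos(2g) sin d              cos d         ]

with ``s = sin(d/2)``, ``c = cos(d/2)``, ``d = delta_s``, ``g = gamma``.
With ``sigma = 1`` the lower-right block is a proper rotation and the matrix
equals the ideal linear retarder of :func:`stokespol.instrument.mueller_retarder`.

For perfectly circular input (q, u, v) = (0, 0, 1) the output reduces to

    q' = -sin(2 gamma) sin(delta_s)
    u' =  cos(2 gamma) sin(delta_s)
    v' =  cos(delta_s)

so retardation is read directly from ``v'`` (:func:`retardation_from_circular`)
and the optic axis from ``q'/u' = -tan(2 gamma)`` (:func:`axis_from_linear`).
Near-circular illumination biases the direct estimator; the three-equation
least-squares inversion (:func:`retardation_full_inversion`) removes that
bias given the measured input state.

``sigma`` scales the intensity row exactly as the model prints it, so the
normalised outputs (q', u', v') keep unit norm and sigma manifests only in
the degree of polarisation: P' = 1/sigma for fully polarised circular input,
hence Dp = sqrt(1 - sigma^-2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numpy.ma as ma
from scipy.optimize import least_squares

__all__ = [
    "SampleMap",
    "sample_mueller",
    "propagate",
    "retardation_from_circular",
    "axis_from_linear",
    "retardation_full_inversion",
    "circular_input_error_profile",
    "background_correct",
    "ErrorProfile",
]

#: relative threshold on |(q', u')| below which gamma is masked
TOL_AXIS_REL = 1e-6


@dataclass
class SampleMap:
    """Per-pixel ground-truth or estimated birefringence parameters.

    ``delta`` is the phase retardation in its principal value [0, pi]
    (an arccos-based inversion cannot distinguish d from 2 pi - d; thin
    histology sections sit well below pi).  ``gamma`` is the optic-axis
    angle modulo pi, masked where delta = 0 leaves it undefined.  ``sigma``
    is the depolarisation factor, sigma = P^-1 >= 1.
    """

    delta: np.ndarray
    gamma: np.ndarray | ma.MaskedArray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if not isinstance(self.gamma, ma.MaskedArray):
            self.gamma = np.asarray(self.gamma, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)

    def validate(self) -> None:
        if np.any(self.delta < 0) or np.any(self.delta > np.pi):
            raise ValueError("delta must lie in the principal range [0, pi]")
        if np.any(self.sigma < 1):
            raise ValueError("sigma must be >= 1")

    @property
    def depolarisation(self) -> np.ndarray:
        """Dp implied by the sigma field: sqrt(1 - sigma^-2)."""
        return np.sqrt(1.0 - 1.0 / np.asarray(self.sigma) ** 2)

    @property
    def shape(self) -> tuple:
        return np.broadcast_shapes(np.shape(self.delta), np.shape(self.gamma),
                                   np.shape(self.sigma))


def sample_mueller(delta: float | np.ndarray, gamma: float | np.ndarray,
                   sigma: float | np.ndarray = 1.0) -> np.ndarray:
    """Sample Mueller matrix, vectorised to shape ``(..., 4, 4)``."""
    delta, gamma, sigma = np.broadcast_arrays(
        np.asarray(delta, dtype=float), np.asarray(gamma, dtype=float),
        np.asarray(sigma, dtype=float))
    if np.any(sigma < 1):
        raise ValueError("sigma must be >= 1")
    s2 = np.sin(delta / 2) ** 2
    c2 = np.cos(delta / 2) ** 2
    sd = np.sin(delta)
    m = np.zeros(delta.shape + (4, 4))
    m[..., 0, 0] = sigma
    m[..., 1, 1] = np.cos(4 * gamma) * s2 + c2
    m[..., 1, 2] = np.sin(4 * gamma) * s2
    m[..., 1, 3] = -np.sin(2 * gamma) * sd
    m[..., 2, 1] = np.sin(4 * gamma) * s2
    m[..., 2, 2] = -np.cos(4 * gamma) * s2 + c2
    m[..., 2, 3] = np.cos(2 * gamma) * sd
    m[..., 3, 1] = np.sin(2 * gamma) * sd
    m[..., 3, 2] = -np.cos(2 * gamma) * sd
    m[..., 3, 3] = np.cos(delta)
    return m


def propagate(state: np.ndarray, smap: SampleMap) -> np.ndarray:
    """Apply the sample model per pixel: ``out = M_s(delta, gamma, sigma) @ state``.

    ``state`` is a normalised Stokes 4-vector ``(i, q, u, v)`` shared by all
    pixels, or a ``(4, ...)`` array matching the map shape.  Returns a
    ``(4, ...)`` array ``(i', q', u', v')``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape[0] != 4:
        raise ValueError("state must have leading Stokes axis of length 4")
    gamma = ma.filled(smap.gamma, 0.0) if isinstance(smap.gamma, ma.MaskedArray) else smap.gamma
    m = sample_mueller(smap.delta, gamma, smap.sigma)
    if state.ndim == 1:
        out = np.einsum("...ij,j->...i", m, state)
    else:
        if state.shape[1:] != m.shape[:-2]:
            raise ValueError(f"state shape {state.shape[1:]} does not match map {m.shape[:-2]}")
        out = np.einsum("...ij,j...->...i", m, state)
    return np.moveaxis(out, -1, 0)


def retardation_from_circular(v_prime: np.ndarray,
                              return_diagnostics: bool = False):
    """Direct retardation estimate under circular illumination: d = arccos(v').

    Values outside [-1, 1] (noise) are clamped before the arccos and counted
    when diagnostics are requested.  Output lies in the principal range
    [0, pi].
    """
    v_prime = np.asarray(v_prime, dtype=float)
    n_clamped = int(np.sum(np.abs(v_prime) > 1.0))
    delta = np.arccos(np.clip(v_prime, -1.0, 1.0))
    if return_diagnostics:
        return delta, n_clamped
    return delta


def axis_from_linear(q_prime: np.ndarray, u_prime: np.ndarray,
                     tol_axis: float | None = None) -> ma.MaskedArray:
    """Optic-axis angle from the transmitted linear components, in [0, pi).

    ``gamma = 1/2 atan2(-q', u')`` — consistent with the circular-input
    forward equations, so forward-then-invert recovers gamma modulo pi.
    Masked where ``|(q', u')|`` is below ``tol_axis`` (sin(delta) ~ 0 leaves
    the axis undefined).
    """
    q_prime = np.asarray(q_prime, dtype=float)
    u_prime = np.asarray(u_prime, dtype=float)
    mag = np.hypot(q_prime, u_prime)
    if tol_axis is None:
        tol_axis = TOL_AXIS_REL * max(float(np.max(mag, initial=0.0)), 1e-300)
    mask = mag < tol_axis
    gamma = 0.5 * np.arctan2(-q_prime, u_prime)
    gamma = np.mod(gamma, np.pi)
    return ma.MaskedArray(gamma, mask=mask)


def _inversion_residual(params: np.ndarray, inp: np.ndarray, out: np.ndarray) -> np.ndarray:
    # sample_mueller is smooth in (d, g) and M(-d, g) == M(d, g + pi/2), so the
    # solver may roam freely; the sign/branch is folded back afterwards.
    d, g = params
    pred = sample_mueller(d, g, 1.0)[1:, 1:] @ inp
    return pred - out


def retardation_full_inversion(q_prime: np.ndarray, u_prime: np.ndarray,
                               v_prime: np.ndarray, input_state: np.ndarray,
                               tol_axis: float | None = None,
                               xtol: float = 1e-14):
    """Joint least-squares inversion of the three propagation equations.

    Solves, per pixel, for (delta_s, gamma) given the known normalised input
    ``(q, u, v)`` (measured without the sample) and the transmitted
    ``(q', u', v')``.  Two unknowns against three equations; seeded by the
    circular-approximation estimates, refined by ``scipy.optimize``.  For
    perfectly circular input it coincides with :func:`retardation_from_circular`;
    for elliptical input it removes the orientation-dependent bias the direct
    estimator incurs.

    Returns ``(delta, gamma_masked, n_fallback)`` where ``n_fallback`` counts
    pixels that failed to converge and retained their circular-approximation
    seed.
    """
    q_prime, u_prime, v_prime = np.broadcast_arrays(
        np.asarray(q_prime, float), np.asarray(u_prime, float), np.asarray(v_prime, float))
    inp = np.asarray(input_state, dtype=float)
    if inp.shape != (3,):
        raise ValueError("input_state must be the normalised (q, u, v) triple")

    shape = q_prime.shape
    qp, up, vp = q_prime.ravel(), u_prime.ravel(), v_prime.ravel()
    d0 = retardation_from_circular(vp)
    g0 = np.asarray(ma.filled(axis_from_linear(qp, up, tol_axis=tol_axis), 0.0))

    delta = np.empty_like(d0)
    gamma = np.empty_like(g0)
    n_fallback = 0
    for idx in range(qp.size):
        out = np.array([qp[idx], up[idx], vp[idx]])
        sol = least_squares(_inversion_residual, np.array([d0[idx], g0[idx]]),
                            args=(inp, out), xtol=xtol, ftol=xtol, gtol=xtol,
                            method="lm")
        if sol.success:
            d, g = sol.x
        else:  # pragma: no cover - LM rarely fails on this smooth 2-parameter problem
            d, g = d0[idx], g0[idx]
            n_fallback += 1
        if d < 0:  # fold the sign ambiguity: (-d, g) == (d, g + pi/2)
            d, g = -d, g + np.pi / 2
        d = np.mod(d, 2 * np.pi)
        if d > np.pi:
            d, g = 2 * np.pi - d, g + np.pi / 2
        delta[idx] = d
        gamma[idx] = np.mod(g, np.pi)

    delta = delta.reshape(shape)
    gamma = gamma.reshape(shape)
    sin_scale = np.abs(np.sin(delta))
    mask = sin_scale < TOL_AXIS_REL * max(float(np.max(sin_scale, initial=0.0)), 1e-300)
    return delta, ma.MaskedArray(gamma, mask=mask), n_fallback


@dataclass
class ErrorProfile:
    """Signed error of the circular-approximation estimator over orientation."""

    gamma: np.ndarray
    error: np.ndarray
    max_abs: float
    mean_abs: float


def circular_input_error_profile(delta_s: float, ellipticity: float,
                                 gamma_grid: np.ndarray | None = None,
                                 input_azimuth: float = 0.0) -> ErrorProfile:
    """Bias of the arccos(v') estimator under elliptical illumination.

    For each optic-axis angle in ``gamma_grid``, light of the given
    ellipticity angle (pi/4 = perfectly circular) and azimuth is propagated
    through a sigma = 1 sample of retardation ``delta_s``; the signed error
    of the direct estimator against truth is recorded.
    """
    if not 0 < ellipticity <= np.pi / 4:
        raise ValueError("ellipticity must lie in (0, pi/4]")
    if gamma_grid is None:
        gamma_grid = np.linspace(0.0, np.pi, 181, endpoint=False)
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    state = np.array([1.0,
                      np.cos(2 * ellipticity) * np.cos(2 * input_azimuth),
                      np.cos(2 * ellipticity) * np.sin(2 * input_azimuth),
                      np.sin(2 * ellipticity)])
    smap = SampleMap(np.full_like(gamma_grid, delta_s), gamma_grid,
                     np.ones_like(gamma_grid))
    out = propagate(state, smap)
    est = retardation_from_circular(out[3])
    err = est - delta_s
    return ErrorProfile(gamma=gamma_grid, error=err,
                        max_abs=float(np.max(np.abs(err))),
                        mean_abs=float(np.mean(np.abs(err))))


def background_correct(retardation: np.ndarray | ma.MaskedArray,
                       background_region: tuple | None = None,
                       method: str = "region",
                       bins: int = 256):
    """Subtract the no-tissue baseline from a retardation map.

    ``method='region'`` estimates the baseline as the mean over a
    user-supplied no-tissue region ``(row, col, height, width)``;
    ``method='mode'`` uses the modal value (median of the fullest histogram
    bin), for maps whose background dominates.  Negative corrected values
    are retained: they indicate an optic axis rotated by 90 degrees relative
    to the baseline regions.

    Returns ``(corrected_map, baseline)``.
    """
    data = ma.asarray(retardation, dtype=float)
    if method == "region":
        if background_region is None:
            raise ValueError("method='region' requires background_region=(row, col, h, w)")
        r, c, h, w = background_region
        sub = data[r:r + h, c:c + w]
        if sub.count() == 0:
            raise ValueError("background region is empty or fully masked")
        baseline = float(sub.mean())
    elif method == "mode":
        values = data.compressed() if isinstance(data, ma.MaskedArray) else np.ravel(data)
        if values.size == 0:
            raise ValueError("map has no unmasked pixels")
        if np.ptp(values) == 0:
            baseline = float(values[0])
        else:
            counts, edges = np.histogram(values, bins=bins)
            b = int(np.argmax(counts))
            in_bin = values[(values >= edges[b]) & (values <= edges[b + 1])]
            baseline = float(np.median(in_bin))
    else:
        raise ValueError(f"unknown background method {method!r}")
    return data - baseline, baseline
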