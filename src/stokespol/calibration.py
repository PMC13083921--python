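"""Estimation and application of the signal-to-Stokes transformation K.

The instrument maps a Stokes vector linearly onto the four demodulated
signals; calibration inverts that map.  K is constrained to the sparsity
pattern

    [ k1 k2 k3 0  ]
    [ 0  k4 k5 0  ]        (I Q U V)^T = K (S_DC S_QU1 S_QU2 S_v)^T
    [ 0  k6 k7 0  ]
    [ 0  0  0  k8 ]

which is a necessary condition for the map to exist for this polarimeter
geometry: the DC level mixes only into I, the two second harmonics carry the
linear components, and the first harmonic of PEM1 alone carries V.

Given known generator states and their measured signals the problem is
linear in k1..k8 and solved row-by-row in closed form; an optional nonlinear
mode additionally refines the generator-state ellipse parameters, absorbing
imperfections of the polarisation state generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .instrument import (HarmonicSignalSet, PolarimeterConfig,
                         PolarisationState, analytic_harmonics, signal_matrix)

__all__ = [
    "KMatrix",
    "CalibrationSet",
    "CalibrationResult",
    "SparsityReport",
    "CalibrationError",
    "stokes_from_signals",
    "signals_from_stokes",
    "calibrate",
    "validate_k_sparsity",
    "canonical_states",
    "simulate_calibration_set",
    "instrument_k",
]

#: (row, col) positions that are structurally zero in K.
K_ZERO_POSITIONS: tuple = ((0, 3), (1, 0), (1, 3), (2, 0), (2, 3),
                           (3, 0), (3, 1), (3, 2))

#: (row, col) position of each named element k1..k8.
K_ELEMENT_POSITIONS: tuple = ((0, 0), (0, 1), (0, 2), (1, 1),
                              (1, 2), (2, 1), (2, 2), (3, 3))

_ELEMENT_NAMES = tuple(f"k{i}" for i in range(1, 9))


class CalibrationError(RuntimeError):
    """Raised when the calibration problem is unsolvable or unidentifiable."""


@dataclass
class KMatrix:
    """The eight non-zero elements of the transformation matrix K."""

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    @property
    def matrix(self) -> np.ndarray:
        m = np.zeros((4, 4))
        for name, (r, c) in zip(_ELEMENT_NAMES, K_ELEMENT_POSITIONS):
            m[r, c] = getattr(self, name)
        return m

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _ELEMENT_NAMES])

    @classmethod
    def from_matrix(cls, m: np.ndarray, atol: float = 0.0) -> "KMatrix":
        """Extract k1..k8, rejecting matrices that violate the zero pattern."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("K must be 4x4")
        scale = np.max(np.abs(m))
        for r, c in K_ZERO_POSITIONS:
            if abs(m[r, c]) > max(atol, 0.0) * scale:
                raise ValueError(f"element ({r},{c}) must be zero in K (got {m[r, c]:g})")
        return cls(*[m[r, c] for r, c in K_ELEMENT_POSITIONS])

    def validate(self) -> None:
        if self.k1 == 0:
            raise ValueError("k1 must be non-zero")
        if self.k8 == 0:
            raise ValueError("k8 must be non-zero")
        block = np.array([[self.k4, self.k5], [self.k6, self.k7]])
        if abs(np.linalg.det(block)) < 1e-300:
            raise ValueError("the (k4 k5; k6 k7) block must be invertible")

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in _ELEMENT_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "KMatrix":
        return cls(**{n: float(d[n]) for n in _ELEMENT_NAMES})


@dataclass
class CalibrationSet:
    """Pairs of known generator states and measured harmonic signals.

    ``states`` and ``signals`` are (N, 4) arrays in (I, Q, U, V) and
    (S_DC, S_QU1, S_QU2, S_v) order respectively.
    """

    states: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.states.shape != self.signals.shape or self.states.shape[1] != 4:
            raise ValueError("states and signals must both be (N, 4)")

    def __len__(self) -> int:
        return self.states.shape[0]

    def validate(self) -> None:
        if len(self) < 4:
            raise CalibrationError("calibration needs at least 4 states")
        if np.linalg.matrix_rank(self.states) < 4:
            # name the elements the missing dimension(s) leave unconstrained
            scale = np.max(np.abs(self.states)) or 1.0
            dim_elements = {0: ("k1",), 1: ("k4", "k6"), 2: ("k5", "k7"), 3: ("k8",)}
            dim_names = ("I", "Q", "U", "V")
            dead = [d for d in range(4)
                    if np.linalg.norm(self.states[:, d]) < 1e-12 * scale * len(self)]
            if dead:
                culprits = [e for d in dead for e in dim_elements[d]]
                raise CalibrationError(
                    f"calibration states never excite {[dim_names[d] for d in dead]}: "
                    f"element(s) {culprits} unidentifiable")
            raise CalibrationError("calibration states do not span all four Stokes dimensions")

    # -- tabular text round-trip -------------------------------------------
    _COLUMNS = ("state_I", "state_Q", "state_U", "state_V",
                "S_DC", "S_QU1", "S_QU2", "S_v")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(np.hstack([self.states, self.signals]), columns=self._COLUMNS)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationSet":
        df = pd.read_csv(path)
        missing = [c for c in cls._COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"calibration CSV missing columns: {missing}")
        arr = df[list(cls._COLUMNS)].to_numpy(dtype=float)
        return cls(arr[:, :4], arr[:, 4:])


@dataclass
class CalibrationResult:
    """Fitted K with least-squares diagnostics."""

    K: KMatrix
    residual_norm: float
    condition_numbers: dict
    n_states: int
    method: str
    refined_states: np.ndarray | None = None

    def summary(self) -> str:
        lines = [f"K calibration ({self.method}, {self.n_states} states)",
                 f"  residual norm: {self.residual_norm:.3e}"]
        for n in _ELEMENT_NAMES:
            lines.append(f"  {n} = {getattr(self.K, n):+.6g}")
        for row, c in self.condition_numbers.items():
            lines.append(f"  cond[{row}] = {c:.3g}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# application of K
# --------------------------------------------------------------------------

def stokes_from_signals(signals: HarmonicSignalSet, K: KMatrix) -> PolarisationState:
    """Recover Stokes components from demodulated signals (vectorised)."""
    K.validate()
    arr = signals.as_array()
    stokes = np.einsum("ij,j...->i...", K.matrix, arr)
    return PolarisationState(stokes[0], stokes[1], stokes[2], stokes[3])


def signals_from_stokes(state: PolarisationState, K: KMatrix) -> HarmonicSignalSet:
    """Forward-simulate signals from a state given K (uses K^-1)."""
    K.validate()
    inv = np.linalg.inv(K.matrix)
    arr = state.as_array()
    return HarmonicSignalSet.from_array(np.einsum("ij,j...->i...", inv, arr))


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

# Each Stokes row of K depends on its own subset of signal columns.
_ROW_STRUCTURE = {
    "I": ((0, 1, 2), ("k1", "k2", "k3")),
    "Q": ((1, 2), ("k4", "k5")),
    "U": ((1, 2), ("k6", "k7")),
    "V": ((3,), ("k8",)),
}


def _fit_linear(cal: CalibrationSet) -> tuple[dict, float, dict]:
    """Row-wise linear least squares for k1..k8.

    Returns (elements, residual_norm, condition_numbers); raises
    CalibrationError naming unidentifiable elements when a design matrix is
    rank-deficient (e.g. k8 when no state excites V).
    """
    elements: dict = {}
    cond: dict = {}
    ss_res = 0.0
    scale = np.max(np.abs(cal.signals)) or 1.0
    for row_idx, (row_name, (cols, names)) in enumerate(_ROW_STRUCTURE.items()):
        X = cal.signals[:, list(cols)]
        y = cal.states[:, row_idx]
        sv = np.linalg.svd(X, compute_uv=False)
        tol = max(X.shape) * np.finfo(float).eps * scale
        if sv.size == 0 or sv[-1] <= tol:
            # find which columns are (numerically) dead to name the elements
            dead = [names[j] for j in range(X.shape[1])
                    if np.linalg.norm(X[:, j]) <= tol * max(1, len(cal))]
            culprit = dead or list(names)
            raise CalibrationError(
                f"unidentifiable element(s) {culprit}: calibration states do not "
                f"excite the signals required for the {row_name} row")
        coef, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
        for n, v in zip(names, coef):
            elements[n] = float(v)
        r = y - X @ coef
        ss_res += float(r @ r)
        cond[row_name] = float(sv[0] / sv[-1])
    return elements, float(np.sqrt(ss_res)), cond


def _ellipse_params(states: np.ndarray) -> np.ndarray:
    """(intensity, ellipticity, azimuth) for fully polarised states."""
    out = np.zeros((states.shape[0], 3))
    out[:, 0] = states[:, 0]
    ip = np.linalg.norm(states[:, 1:], axis=1)
    with np.errstate(invalid="ignore"):
        out[:, 1] = 0.5 * np.arcsin(np.clip(states[:, 3] / np.where(ip > 0, ip, 1), -1, 1))
    out[:, 2] = 0.5 * np.arctan2(states[:, 2], states[:, 1])
    return out


def calibrate(cal: CalibrationSet, refine_states: bool = False,
              xtol: float = 1e-12) -> CalibrationResult:
    """Estimate K from a calibration set.

    With ``refine_states=False`` (default) the problem is solved row-by-row
    by linear least squares — exact for known generator states.  With
    ``refine_states=True`` the generator ellipse parameters (ellipticity,
    azimuth of each fully polarised state) are refined jointly with k1..k8
    by nonlinear least squares, absorbing generator imperfections; the
    linear solution seeds the iteration.
    """
    cal.validate()
    elements, res_norm, cond = _fit_linear(cal)
    refined = None
    method = "linear"
    if refine_states:
        method = "nonlinear"
        pol2 = np.sum(cal.states[:, 1:] ** 2, axis=1)
        if np.any(pol2 < 0.99 * cal.states[:, 0] ** 2):
            raise CalibrationError("state refinement requires fully polarised generator states")
        n = len(cal)
        ep0 = _ellipse_params(cal.states)
        x0 = np.concatenate([[elements[n_] for n_ in _ELEMENT_NAMES],
                             ep0[:, 1], ep0[:, 2]])
        intens = ep0[:, 0]

        def _model_states(x):
            eps, azi = x[8:8 + n], x[8 + n:]
            return np.column_stack([
                intens,
                intens * np.cos(2 * eps) * np.cos(2 * azi),
                intens * np.cos(2 * eps) * np.sin(2 * azi),
                intens * np.sin(2 * eps)])

        def _resid(x):
            km = KMatrix(*x[:8]).matrix
            pred = cal.signals @ km.T
            return (pred - _model_states(x)).ravel()

        sol = least_squares(_resid, x0, xtol=xtol, ftol=xtol, gtol=xtol)
        elements = dict(zip(_ELEMENT_NAMES, sol.x[:8]))
        refined = _model_states(sol.x)
        res_norm = float(np.linalg.norm(sol.fun))
    K = KMatrix(**{n_: float(elements[n_]) for n_ in _ELEMENT_NAMES})
    K.validate()
    return CalibrationResult(K=K, residual_norm=res_norm, condition_numbers=cond,
                             n_states=len(cal), method=method, refined_states=refined)


# --------------------------------------------------------------------------
# sparsity validation
# --------------------------------------------------------------------------

@dataclass
class SparsityReport:
    """Unconstrained 4x4 fit checked against the structural zero pattern."""

    K_full: np.ndarray
    max_zero_magnitude: float
    max_element: float
    tol: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "EXCEEDS TOLERANCE"
        return (f"K sparsity check: max |zero-position| = {self.max_zero_magnitude:.3e}, "
                f"max |k_i| = {self.max_element:.3e}, tol = {self.tol:g} -> {status}")


def validate_k_sparsity(cal: CalibrationSet, tol: float = 1e-6) -> SparsityReport:
    """Fit an unconstrained 4x4 K and report leakage into the zero positions.

    Requires at least 16 states so the 16 free elements are fully determined.
    The report is informative: a deliberately mis-built instrument may
    legitimately exceed the tolerance.
    """
    if len(cal) < 16:
        raise CalibrationError("sparsity validation needs at least 16 states")
    # rows of K solve  signals^T k_row = state_component
    k_full, _, _, _ = np.linalg.lstsq(cal.signals, cal.states, rcond=None)
    k_full = k_full.T
    max_zero = max(abs(k_full[r, c]) for r, c in K_ZERO_POSITIONS)
    max_el = max(abs(k_full[r, c]) for r, c in K_ELEMENT_POSITIONS)
    return SparsityReport(K_full=k_full, max_zero_magnitude=float(max_zero),
                          max_element=float(max_el), tol=tol,
                          passed=bool(max_zero < tol * max_el))


# --------------------------------------------------------------------------
# simulated calibration data
# --------------------------------------------------------------------------

def canonical_states(intensity: float = 1.0) -> list:
    """The six Poincaré-axis generator states: H, V, +45, -45, RCP, LCP."""
    return [
        PolarisationState.linear(0.0, intensity),
        PolarisationState.linear(np.pi / 2, intensity),
        PolarisationState.linear(np.pi / 4, intensity),
        PolarisationState.linear(-np.pi / 4, intensity),
        PolarisationState.circular(+1, intensity),
        PolarisationState.circular(-1, intensity),
    ]


def simulate_calibration_set(states: list, cfg: PolarimeterConfig | None = None,
                             K_true: KMatrix | None = None,
                             noise_sd: float = 0.0,
                             rng: np.random.Generator | None = None) -> CalibrationSet:
    """Generate signals for known states, from the instrument model or a given K.

    Exactly one of ``cfg`` (full dual-PEM forward model) or ``K_true``
    (signals = K^-1 state) must be supplied.  Gaussian noise of standard
    deviation ``noise_sd`` is added to every signal when requested.
    """
    if (cfg is None) == (K_true is None):
        raise ValueError("supply exactly one of cfg or K_true")
    rows_s, rows_g = [], []
    for st in states:
        rows_s.append(st.as_array())
        if cfg is not None:
            rows_g.append(analytic_harmonics(st, cfg).as_array())
        else:
            rows_g.append(signals_from_stokes(st, K_true).as_array())
    states_arr = np.array(rows_s)
    signals_arr = np.array(rows_g)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        signals_arr = signals_arr + rng.normal(0.0, noise_sd, signals_arr.shape)
    return CalibrationSet(states_arr, signals_arr)


def instrument_k(cfg: PolarimeterConfig) -> KMatrix:
    """Ground-truth K of the simulated instrument (inverse of the signal map)."""
    m = signal_matrix(cfg)
    k = np.linalg.inv(m)
    # zero out numerically-negligible leakage before pattern extraction
    scale = np.max(np.abs(k))
    k = np.where(np.abs(k) < 1e-12 * scale, 0.0, k)
    return KMatrix.from_matrix(k, atol=1e-10)
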