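"""File formats, acquisition metadata and sampling arithmetic.

Interchange format is multi-page 32-bit float TIFF: page order I, Q, U, V
for Stokes images; (delta_s, gamma, sigma) for phantom-truth sidecars;
(S_DC, S_QU1, S_QU2, S_v) sample planes followed by the same four reference
planes for rendered acquisitions.  Map metadata (units, pixel size) rides in
the TIFF description tag as JSON.  Masked pixels are stored as NaN and
re-masked on read.

All writes are atomic (temporary file in the destination directory, then
rename), so an interrupted run never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass

import numpy as np
import numpy.ma as ma
import tifffile
import yaml

from .instrument import PolarimeterConfig, PolarisationState
from .stokes_maps import StokesImage

__all__ = [
    "AcquisitionMeta",
    "fov_from_sampling",
    "atomic_write_bytes",
    "write_stokes_tiff",
    "read_stokes_tiff",
    "write_map_tiff",
    "read_map_tiff",
    "write_truth_tiff",
    "read_truth_tiff",
    "write_acquisition_tiff",
    "read_acquisition_tiff",
    "save_kmatrix",
    "load_kmatrix",
    "load_polarimeter_config",
    "save_polarimeter_config",
    "load_input_state",
]


@dataclass
class AcquisitionMeta:
    """Camera/objective metadata tied to an acquisition.

    Defaults are the 40x configuration: 6.5 um camera pitch, 6.17 px/um in
    the sample plane, 530 nm illumination.
    """

    camera_pitch_um: float = 6.5
    magnification: float = 40.0
    sampling_px_per_um: float = 6.17
    wavelength_nm: float = 530.0

    def __post_init__(self) -> None:
        if self.camera_pitch_um <= 0 or self.sampling_px_per_um <= 0:
            raise ValueError("camera pitch and sampling density must be positive")

    @property
    def pixel_size_um(self) -> float:
        """Sample-plane micrometres per pixel."""
        return 1.0 / self.sampling_px_per_um


def fov_from_sampling(n_pixels: float, sampling_px_per_um: float) -> float:
    """Physical extent (um) of ``n_pixels`` at the given sampling density.

    E.g. 2561 px at 6.17 px/um -> 415.1 um; the same pixel count at a
    10x lower density covers a 10x larger field.
    """
    if n_pixels <= 0 or sampling_px_per_um <= 0:
        raise ValueError("pixel count and sampling density must be positive")
    return n_pixels / sampling_px_per_um


# --------------------------------------------------------------------------
# atomic file writes
# --------------------------------------------------------------------------

def atomic_write_bytes(path: str | os.PathLike, data: bytes) -> None:
    """Write bytes via a temp file + rename in the destination directory."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", suffix=os.path.basename(path))
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_tiff(path, pages: np.ndarray, description: dict) -> None:
    import io as _io
    buf = _io.BytesIO()
    tifffile.imwrite(buf, pages.astype(np.float32),
                     description=json.dumps(description), photometric="minisblack")
    atomic_write_bytes(path, buf.getvalue())


def _read_pages(path, expected_pages: int, what: str) -> tuple[np.ndarray, dict]:
    with tifffile.TiffFile(os.fspath(path)) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != expected_pages:
        raise ValueError(f"{what} file must have {expected_pages} pages "
                         f"(got {arr.shape[0]}): expected order is documented "
                         f"in stokespol.io")
    if not np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{what} file must contain float data, got {arr.dtype}")
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    return arr.astype(float), meta


# --------------------------------------------------------------------------
# TIFF containers
# --------------------------------------------------------------------------

def write_stokes_tiff(path, img: StokesImage) -> None:
    _atomic_tiff(path, img.as_array(),
                 {"pages": "I,Q,U,V", "pixel_size_um": img.pixel_size_um,
                  "magnification": img.magnification})


def read_stokes_tiff(path) -> StokesImage:
    arr, meta = _read_pages(path, 4, "Stokes")
    return StokesImage.from_array(arr,
                                  pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
                                  magnification=str(meta.get("magnification", "")))


def write_map_tiff(path, map_2d, units: str = "rad", **extra_meta) -> None:
    """One-page float map; masked pixels become NaN."""
    data = ma.filled(ma.asarray(map_2d, dtype=float), np.nan)
    _atomic_tiff(path, data[None], {"pages": "map", "units": units, **extra_meta})


def read_map_tiff(path) -> tuple[ma.MaskedArray, dict]:
    arr, meta = _read_pages(path, 1, "map")
    return ma.masked_invalid(arr[0]), meta


def write_truth_tiff(path, smap) -> None:
    pages = np.stack([np.asarray(smap.delta, dtype=float),
                      ma.filled(ma.asarray(smap.gamma, dtype=float), np.nan),
                      np.asarray(smap.sigma, dtype=float)])
    _atomic_tiff(path, pages, {"pages": "delta_s,gamma,sigma", "units": "rad,rad,1"})


def read_truth_tiff(path):
    from .birefringence import SampleMap
    arr, _ = _read_pages(path, 3, "truth")
    return SampleMap(delta=arr[0], gamma=ma.masked_invalid(arr[1]), sigma=arr[2])


def write_acquisition_tiff(path, acq) -> None:
    """Eight pages: sample signals then no-sample reference signals."""
    pages = np.concatenate([acq.signals.as_array(), acq.reference.as_array()])
    _atomic_tiff(path, pages, {
        "pages": "S_DC,S_QU1,S_QU2,S_v,ref_S_DC,ref_S_QU1,ref_S_QU2,ref_S_v",
        "pixel_size_um": acq.pixel_size_um,
        "input_state": list(map(float, np.atleast_1d(acq.input_state.as_array()).reshape(4))),
        "config": _config_dict(acq.cfg),
    })


def read_acquisition_tiff(path):
    from .instrument import HarmonicSignalSet
    from .phantom import Acquisition
    arr, meta = _read_pages(path, 8, "acquisition")
    cfg = _config_from_dict(meta.get("config", {}))
    state = PolarisationState(*meta.get("input_state", (1.0, 0.0, 0.0, 1.0)))
    stokes_placeholder = StokesImage.from_array(np.zeros((4,) + arr.shape[1:]),
                                                pixel_size_um=float(meta.get("pixel_size_um", 1.0)))
    return Acquisition(signals=HarmonicSignalSet.from_array(arr[:4]),
                       reference=HarmonicSignalSet.from_array(arr[4:]),
                       input_state=state, cfg=cfg, stokes_true=stokes_placeholder,
                       pixel_size_um=float(meta.get("pixel_size_um", 1.0)))


# --------------------------------------------------------------------------
# YAML configuration (human-facing angles in degrees, radians internally)
# --------------------------------------------------------------------------

def _config_dict(cfg: PolarimeterConfig) -> dict:
    return {"alpha_deg": float(np.rad2deg(cfg.alpha)),
            "beta_deg": float(np.rad2deg(cfg.beta)),
            "pem1": {"freq": cfg.f1, "amplitude_rad": cfg.A1},
            "pem2": {"freq": cfg.f2, "amplitude_rad": cfg.A2},
            "wavelength_nm": cfg.wavelength_nm}


def _config_from_dict(d: dict) -> PolarimeterConfig:
    defaults = PolarimeterConfig()
    pem1 = d.get("pem1", {})
    pem2 = d.get("pem2", {})
    return PolarimeterConfig(
        alpha=np.deg2rad(float(d.get("alpha_deg", np.rad2deg(defaults.alpha)))),
        beta=np.deg2rad(float(d.get("beta_deg", np.rad2deg(defaults.beta)))),
        f1=float(pem1.get("freq", defaults.f1)),
        f2=float(pem2.get("freq", defaults.f2)),
        A1=float(pem1.get("amplitude_rad", defaults.A1)),
        A2=float(pem2.get("amplitude_rad", defaults.A2)),
        wavelength_nm=float(d.get("wavelength_nm", defaults.wavelength_nm)))


def save_polarimeter_config(path, cfg: PolarimeterConfig) -> None:
    atomic_write_bytes(path, yaml.safe_dump({"polarimeter": _config_dict(cfg)}).encode())


def load_polarimeter_config(path) -> PolarimeterConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return _config_from_dict(d.get("polarimeter", d))


def save_kmatrix(path, K) -> None:
    atomic_write_bytes(path, yaml.safe_dump({"K": K.to_dict()}).encode())


def load_kmatrix(path):
    from .calibration import KMatrix
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return KMatrix.from_dict(d["K"] if "K" in d else d)


def load_input_state(path) -> PolarisationState:
    """Illumination state from YAML: either Stokes I,Q,U,V or ellipse parameters.

    Ellipse form: ``ellipticity_deg`` (45 = circular), optional
    ``azimuth_deg``, ``intensity``, ``dop``.
    """
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if {"I", "Q", "U", "V"} <= set(d):
        return PolarisationState(float(d["I"]), float(d["Q"]), float(d["U"]), float(d["V"]))
    if "ellipticity_deg" in d:
        return PolarisationState.elliptical(
            np.deg2rad(float(d["ellipticity_deg"])),
            np.deg2rad(float(d.get("azimuth_deg", 0.0))),
            float(d.get("intensity", 1.0)), float(d.get("dop", 1.0)))
    raise ValueError("input-state YAML needs either I,Q,U,V or ellipticity_deg")
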