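"""Core data types and volume/image I/O.

Coordinate convention (used by every module in the package):

* depth index 0 is the shallowest pixel (vitreous side) and increases
  toward the choroid;
* BM-form volumes are indexed ``[location][repeat][depth][ascan]``,
  averaged volumes ``[location][depth][ascan]``;
* raw fringe volumes are indexed ``[location][repeat][ascan][k]``;
* all indices are 0-based.

Volumes are stored on disk as a flat little-endian C-order binary array
(``.oct.raw``) next to a YAML sidecar (``.oct.yaml``) holding the dtype
tag, array kind/shape and the full acquisition metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml


class VolumeFormatError(ValueError):
    """Raised when an on-disk volume and its sidecar disagree, or the
    sidecar is malformed."""


#: dtype tags accepted in sidecars (always little-endian on disk)
_DTYPE_TAGS = {
    "float32": "<f4",
    "float64": "<f8",
    "int16": "<i2",
    "uint16": "<u2",
    "int32": "<i4",
}
_TAG_FOR_KIND = {np.dtype(v): k for k, v in _DTYPE_TAGS.items()}

ILM_NFL = "ILM_NFL"
RPE_BRM = "RPE_BrM"
GENERIC_TOP = "generic_top"


@dataclass
class AcquisitionMeta:
    """Acquisition geometry and scales of an SS-OCT raster scan.

    Defaults mirror a 1060 nm, 100 kHz swept-source retinal scanner
    raster: 360 B-scan locations x 3 repeats (BM-scans) x 360 A-scans,
    2048 spectral samples reconstructed to 1024 depth pixels over an
    approximately 50 x 50 degree field.
    """

    n_locations: int = 360
    n_repeats: int = 3
    n_ascans: int = 360
    n_k: int = 2048
    n_depth: int = 1024
    axial_um_per_px: float = 2.0
    sweep_rate_hz: float = 100e3
    center_wavelength_nm: float = 1060.0
    tuning_range_nm: float = 100.0
    scan_angle_deg: float = 50.0

    def __post_init__(self) -> None:
        for name in ("n_locations", "n_repeats", "n_ascans", "n_depth"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_k < 0:
            raise ValueError("n_k must be >= 0 (0 = pre-reconstructed)")
        if self.n_k > 0 and self.n_depth != self.n_k // 2:
            raise ValueError(
                f"n_depth ({self.n_depth}) must equal n_k/2 ({self.n_k // 2}) "
                "when spectral samples are present"
            )
        if self.axial_um_per_px <= 0:
            raise ValueError("axial_um_per_px must be > 0")

    @property
    def n_bscan_frames(self) -> int:
        """Total number of acquired B-scan frames (locations x repeats)."""
        return self.n_locations * self.n_repeats

    @property
    def acquisition_time_s(self) -> float:
        """Theoretical raster acquisition time at the configured A-scan rate."""
        return self.n_bscan_frames * self.n_ascans / self.sweep_rate_hz

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMeta":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise VolumeFormatError(f"unknown metadata keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FringeVolume:
    """Raw spectral interferograms, shape (location, repeat, ascan, k).

    Fringes are assumed uniformly sampled in wavenumber (k-linear), as
    produced by a hardware k-clock.
    """

    data: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        m = self.meta
        expected = (m.n_locations, m.n_repeats, m.n_ascans, m.n_k)
        if self.data.ndim != 4 or self.data.shape != expected:
            raise ValueError(
                f"fringe data shape {self.data.shape} != metadata shape {expected}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fringe data contains non-finite values")


@dataclass
class OCTVolume:
    """Reconstructed intensity volume.

    BM form is 4-D (location, repeat, depth, ascan); after repeat
    averaging the volume is 3-D (location, depth, ascan).  The intensity
    domain is either ``linear`` (backscattered power, arbitrary units)
    or ``log_grayscale`` (dB-compressed and affinely mapped to [0, 1]).
    """

    data: np.ndarray
    meta: AcquisitionMeta
    is_averaged: bool = False
    intensity_domain: str = "log_grayscale"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        m = self.meta
        if self.intensity_domain not in ("linear", "log_grayscale"):
            raise ValueError(f"bad intensity_domain {self.intensity_domain!r}")
        if self.is_averaged:
            expected = (m.n_locations, m.n_depth, m.n_ascans)
        else:
            expected = (m.n_locations, m.n_repeats, m.n_depth, m.n_ascans)
        if self.data.shape != expected:
            raise ValueError(
                f"OCT data shape {self.data.shape} != metadata shape {expected} "
                f"(is_averaged={self.is_averaged})"
            )
        if self.intensity_domain == "log_grayscale":
            lo = float(self.data.min()) if self.data.size else 0.0
            hi = float(self.data.max()) if self.data.size else 0.0
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ValueError(
                    f"log_grayscale volume outside [0, 1]: [{lo}, {hi}]"
                )


@dataclass
class SurfaceMap:
    """Per-(location, ascan) depth index of a detected boundary.

    ``z`` may be fractional (subpixel refinement); it is always finite
    and within [0, n_depth) after post-processing.
    """

    z: np.ndarray
    label: str = GENERIC_TOP

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("surface map must be 2-D (location, ascan)")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("surface map contains non-finite values")
        if self.z.min() < 0:
            raise ValueError("surface depth indices must be >= 0")


@dataclass
class EnFaceImage:
    """Frontal (fundus-view) 2-D image, shape (location, ascan)."""

    data: np.ndarray
    kind: str = "fundus_sum"
    slab: Optional[object] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("en face image must be 2-D")


# ---------------------------------------------------------------------------
# I/O


def _sidecar_for(vol) -> dict:
    if isinstance(vol, FringeVolume):
        kind = "fringe"
        extra = {}
    elif isinstance(vol, OCTVolume):
        kind = "oct"
        extra = {
            "is_averaged": bool(vol.is_averaged),
            "intensity_domain": vol.intensity_domain,
        }
    else:
        raise TypeError(f"unsupported volume type {type(vol).__name__}")
    dt = np.dtype(vol.data.dtype).newbyteorder("<")
    if dt not in _TAG_FOR_KIND:
        raise VolumeFormatError(f"unsupported dtype {vol.data.dtype}")
    return {
        "format": "octapipe-raw-v1",
        "kind": kind,
        "dtype": _TAG_FOR_KIND[dt],
        "shape": [int(s) for s in vol.data.shape],
        "meta": vol.meta.to_dict(),
        **extra,
    }


def write_volume(vol, path, meta_path=None) -> None:
    """Write a volume as flat little-endian binary plus YAML sidecar.

    The round trip through :func:`read_volume` is bit-exact on the data
    (dtype preserved) and field-for-field on the metadata.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".yaml")
    if vol.data.size == 0:
        raise ValueError("refusing to write a volume with an empty dimension")
    sidecar = _sidecar_for(vol)
    arr = np.ascontiguousarray(vol.data, dtype=_DTYPE_TAGS[sidecar["dtype"]])
    arr.tofile(path)
    with open(meta_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_volume(path, meta_path=None):
    """Read a volume written by :func:`write_volume`.

    Raises :class:`VolumeFormatError` if the sidecar is malformed, the
    dtype tag is unknown, or declared shape x element size does not
    equal the file size.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".yaml")
    with open(meta_path) as fh:
        sidecar = yaml.safe_load(fh)
    if not isinstance(sidecar, dict) or "dtype" not in sidecar:
        raise VolumeFormatError(f"malformed sidecar {meta_path}")
    tag = sidecar["dtype"]
    if tag not in _DTYPE_TAGS:
        raise VolumeFormatError(f"unknown dtype tag {tag!r}")
    dt = np.dtype(_DTYPE_TAGS[tag])
    shape = tuple(int(s) for s in sidecar["shape"])
    expected_bytes = int(np.prod(shape)) * dt.itemsize
    actual_bytes = Path(path).stat().st_size
    if actual_bytes != expected_bytes:
        raise VolumeFormatError(
            f"{path}: file is {actual_bytes} bytes, sidecar declares "
            f"{expected_bytes} ({shape} x {dt.itemsize})"
        )
    data = np.fromfile(path, dtype=dt).reshape(shape)
    meta = AcquisitionMeta.from_dict(sidecar["meta"])
    kind = sidecar.get("kind", "oct")
    if kind == "fringe":
        return FringeVolume(data=data, meta=meta)
    if kind == "oct":
        return OCTVolume(
            data=data,
            meta=meta,
            is_averaged=bool(sidecar.get("is_averaged", False)),
            intensity_domain=sidecar.get("intensity_domain", "log_grayscale"),
        )
    raise VolumeFormatError(f"unknown volume kind {kind!r}")


def export_volume_tiff(vol, path) -> None:
    """Export a volume as a 16-bit grayscale TIFF stack (one page per
    B-scan; BM-form volumes are flattened to location-major frames).
    Values are clipped to [0, 1] and scaled to [0, 65535]."""
    import tifffile

    data = np.asarray(vol.data, dtype=float)
    if data.ndim == 4:  # (location, repeat, depth, ascan) -> frames
        data = data.reshape(-1, *data.shape[2:])
    out = np.floor(np.clip(data, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
    tifffile.imwrite(Path(path), out)


def export_image(img, path, format: str = "png8") -> None:
    """Export a 2-D image (:class:`EnFaceImage` or raw array).

    ``tiff16`` maps [0, 1] linearly to [0, 65535], ``png8`` to
    [0, 255] (round-half-up, clipped); ``csv`` writes the raw floats.
    """
    data = img.data if isinstance(img, EnFaceImage) else np.asarray(img, dtype=float)
    if data.ndim != 2:
        raise ValueError("export_image expects a 2-D image")
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite values; mask before export")
    path = Path(path)
    if format == "csv":
        np.savetxt(path, data, delimiter=",")
        return
    clipped = np.clip(data, 0.0, 1.0)
    if format == "tiff16":
        import tifffile

        out = np.floor(clipped * 65535.0 + 0.5).astype(np.uint16)
        tifffile.imwrite(path, out)
    elif format == "png8":
        import imageio.v3 as iio

        out = np.floor(clipped * 255.0 + 0.5).astype(np.uint8)
        iio.imwrite(path, out, extension=".png")
    else:
        raise ValueError(f"unknown export format {format!r}")
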