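"""Radiometric thermal image I/O.

A radiometric image is a 2-D matrix of calibrated temperatures in degrees
Celsius, not a brightness picture.  Vendor radiometric containers are
proprietary, so two open dialects are supported:

* ``csv``    — comma-separated rows of decimal Celsius values, no header;
  human-readable and lossless.
* ``png16`` / ``tiff16`` — single-channel 16-bit images of digital numbers
  (DN) with a JSON sidecar ``<path>.json`` holding the linear calibration
  ``temperature = scale * DN + offset``.

The default calibration (scale 0.01 C/DN, offset 0) spans 0-655 C with
0.01 C quantisation, ample for skin-temperature work where the quantity of
interest is a gradient of a few degrees.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import CalibrationMissing, EncodingError, FormatError, RangeError

#: Plausibility bounds in Celsius: admit cold outdoor backgrounds and fevers,
#: reject raw digital numbers accidentally read as temperatures.
TEMP_MIN = -40.0
TEMP_MAX = 60.0

#: Smallest image that can hold a face template.
MIN_SIDE = 16


@dataclass(frozen=True)
class Calibration:
    """Linear DN-to-Celsius mapping used by the 16-bit dialects."""

    scale: float = 0.01  # Celsius per digital number
    offset: float = 0.0  # Celsius at DN 0

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise RangeError(f"calibration scale must be positive, got {self.scale}")


@dataclass
class RadiometricImage:
    """A validated temperature matrix plus its encoding calibration.

    Parameters
    ----------
    temperatures
        2-D array of finite Celsius values, shape ``(height, width)``.
    calibration
        Scale/offset used when the image is written in a 16-bit dialect.
    source_id
        Free-text provenance tag carried through detection results.
    """

    temperatures: np.ndarray
    calibration: Calibration = field(default_factory=Calibration)
    source_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=np.float64)
        if t.ndim != 2:
            raise FormatError(f"temperature matrix must be 2-D, got ndim={t.ndim}")
        if t.shape[0] < MIN_SIDE or t.shape[1] < MIN_SIDE:
            raise FormatError(
                f"image {t.shape} too small; need at least {MIN_SIDE}x{MIN_SIDE} "
                "to hold a face template"
            )
        if not np.all(np.isfinite(t)):
            raise RangeError("temperature matrix contains non-finite values")
        if t.min() < TEMP_MIN or t.max() > TEMP_MAX:
            bad = t.min() if t.min() < TEMP_MIN else t.max()
            raise RangeError(
                f"temperature {bad:.2f} C outside plausible range "
                f"[{TEMP_MIN}, {TEMP_MAX}] C"
            )
        self.temperatures = t

    @property
    def height(self) -> int:
        return self.temperatures.shape[0]

    @property
    def width(self) -> int:
        return self.temperatures.shape[1]


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".png":
        return "png16"
    if suffix in (".tif", ".tiff"):
        return "tiff16"
    raise FormatError(f"cannot infer radiometric format from suffix {suffix!r}")


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def read_radiometric(path: str | os.PathLike, format: str = "auto") -> RadiometricImage:
    """Read a radiometric image in either dialect.

    ``format='auto'`` infers the dialect from the file suffix.  16-bit
    formats require the ``<path>.json`` sidecar with keys ``scale`` and
    ``offset``; temperatures are reconstructed as ``scale * DN + offset``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path) if format == "auto" else format

    if fmt == "csv":
        try:
            t = np.loadtxt(path, delimiter=",", ndmin=2, dtype=np.float64)
        except ValueError as exc:
            raise FormatError(f"{path}: not a rectangular numeric CSV ({exc})") from exc
        return RadiometricImage(t, source_id=str(path))

    if fmt in ("png16", "tiff16"):
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise CalibrationMissing(
                f"{path}: 16-bit radiometric images need a sidecar {sidecar.name} "
                'with {"scale": ..., "offset": ...}'
            )
        meta = json.loads(sidecar.read_text())
        try:
            cal = Calibration(scale=float(meta["scale"]), offset=float(meta["offset"]))
        except KeyError as exc:
            raise CalibrationMissing(f"{sidecar}: missing key {exc}") from exc
        dn = iio.imread(path)
        if dn.ndim != 2:
            raise FormatError(f"{path}: expected single-channel image, got shape {dn.shape}")
        t = cal.scale * dn.astype(np.float64) + cal.offset
        return RadiometricImage(t, calibration=cal, source_id=str(path))

    raise FormatError(f"unknown radiometric format {fmt!r}")


def write_radiometric(
    image: RadiometricImage, path: str | os.PathLike, format: str = "auto"
) -> Path:
    """Write ``image`` to ``path`` in the requested dialect.

    CSV is written in full precision and round-trips exactly; the 16-bit
    dialects quantise to the calibration scale (half a scale step of error
    per pixel at most) and also write the JSON sidecar.
    """
    path = Path(path)
    fmt = _infer_format(path) if format == "auto" else format

    if fmt == "csv":
        np.savetxt(path, image.temperatures, delimiter=",", fmt="%.17g")
        return path

    if fmt in ("png16", "tiff16"):
        cal = image.calibration
        dn = np.round((image.temperatures - cal.offset) / cal.scale)
        if dn.min() < 0 or dn.max() > 65535:
            raise EncodingError(
                f"temperatures do not fit 16 bits at scale {cal.scale} C/DN, "
                f"offset {cal.offset} C (DN range {dn.min():.0f}..{dn.max():.0f}); "
                "widen the scale or shift the offset"
            )
        iio.imwrite(path, dn.astype(np.uint16))
        _sidecar_path(path).write_text(
            json.dumps({"scale": cal.scale, "offset": cal.offset, "units": "C"})
        )
        return path

    raise FormatError(f"unknown radiometric format {fmt!r}")
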