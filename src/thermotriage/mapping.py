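"""RGB-to-thermal landmark transfer.

A visual camera and a thermal camera mounted about a centimetre apart see
the same face at a small, nearly constant parallax offset.  Facial
landmarks are easy to find on the visual frame (any visible-spectrum
detector will do); this module transfers those landmarks onto the thermal
frame.

The visual-to-thermal coordinate transform is fitted by least squares from
point correspondences, as either

* ``translation`` — a pure pixel shift, matching the fixed lens geometry at
  a roughly fixed capture distance (the default), or
* ``similarity``  — scale + rotation + translation, for rigs where the
  parallax scales with distance or the sensors differ in resolution.

The similarity fit uses the complex-number formulation: writing each point
as z = x + iy, the model w = a z + b (a = s e^{i theta}) is linear in
(a, b) and solved by the 2x2 normal equations.

After transfer, each landmark may optionally be snapped to the thermal
extremum (hot for canthi, cold for the nose tip) within a small disc — the
mapped point marks the neighbourhood; the thermal extremum inside it is the
physically right sampling spot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .detect import (
    CANTHUS,
    NOSE_TIP,
    DEFAULT_CONFIG,
    DetectionResult,
    DetectorConfig,
    Landmark,
    locate_cold_spot,
    locate_hot_spot,
)
from .errors import DegenerateGeometry, InsufficientData
from .io import RadiometricImage
from .triage import compute_gradient, rate_health, sample_temperature

VISUAL_POINT_NAMES = ("left_inner_canthus", "right_inner_canthus", "nose_tip")


@dataclass(frozen=True)
class VisualLandmarks:
    """Facial landmarks found on the visual frame, in (row, col) pixels."""

    points: Mapping[str, tuple[float, float]]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if "nose_tip" not in self.points:
            raise ValueError("visual landmarks must include the nose_tip")
        if not ("left_inner_canthus" in self.points or "right_inner_canthus" in self.points):
            raise ValueError("visual landmarks must include at least one inner canthus")
        h, w = self.image_shape
        for name, (r, c) in self.points.items():
            if not (np.isfinite(r) and np.isfinite(c)):
                raise ValueError(f"{name}: non-finite coordinates")
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"{name} at ({r}, {c}) outside {h}x{w} visual frame")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        data = {name: [float(r), float(c)] for name, (r, c) in self.points.items()}
        data["image_shape"] = list(self.image_shape)
        path.write_text(json.dumps(data, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "VisualLandmarks":
        data = json.loads(Path(path).read_text())
        shape = tuple(int(v) for v in data.pop("image_shape"))
        points = {name: (float(rc[0]), float(rc[1])) for name, rc in data.items()}
        return cls(points=points, image_shape=shape)


@dataclass(frozen=True)
class OffsetCalibration:
    """Fitted visual-to-thermal coordinate transform.

    ``translation``: (row', col') = (row + dr, col + dc).
    ``similarity``:  rotation by ``theta`` (radians, about the origin, in
    (col, row) axes) and scaling by ``s``, then translation.
    ``residual_rmse`` is the root mean squared Euclidean residual of the
    fit, in thermal pixels.
    """

    model: str
    dr: float
    dc: float
    s: float = 1.0
    theta: float = 0.0
    residual_rmse: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in ("translation", "similarity"):
            raise ValueError(f"unknown calibration model {self.model!r}")
        if not self.s > 0:
            raise ValueError(f"similarity scale must be positive, got {self.s}")
        if self.residual_rmse < 0:
            raise ValueError("residual RMSE cannot be negative")

    def apply(self, row: float, col: float) -> tuple[float, float]:
        """Transform one visual point to (unrounded) thermal coordinates."""
        z = complex(col, row)
        a = self.s * np.exp(1j * self.theta)
        w = a * z + complex(self.dc, self.dr)
        return (w.imag, w.real)

    def invert(self) -> "OffsetCalibration":
        """Thermal-to-visual transform (exact inverse of the fitted model)."""
        a = self.s * np.exp(1j * self.theta)
        b = complex(self.dc, self.dr)
        inv_a = 1.0 / a
        inv_b = -b / a
        return OffsetCalibration(
            model=self.model,
            dr=inv_b.imag,
            dc=inv_b.real,
            s=abs(inv_a),
            theta=float(np.angle(inv_a)),
            residual_rmse=self.residual_rmse,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        data = {"model": self.model, "dr": self.dr, "dc": self.dc,
                "residual_rmse": self.residual_rmse}
        if self.model == "similarity":
            data["s"] = self.s
            data["theta"] = self.theta
        path.write_text(json.dumps(data, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "OffsetCalibration":
        data = json.loads(Path(path).read_text())
        return cls(
            model=data["model"],
            dr=float(data["dr"]),
            dc=float(data["dc"]),
            s=float(data.get("s", 1.0)),
            theta=float(data.get("theta", 0.0)),
            residual_rmse=float(data.get("residual_rmse", 0.0)),
        )


PointPair = tuple[tuple[float, float], tuple[float, float]]


def calibrate_offset(
    pairs: Sequence[PointPair], model: str = "translation"
) -> OffsetCalibration:
    """Least-squares fit of the visual-to-thermal transform from point pairs.

    Each pair is ``((visual_row, visual_col), (thermal_row, thermal_col))``.
    Translation needs one pair; similarity needs two non-coincident visual
    points.
    """
    if model not in ("translation", "similarity"):
        raise ValueError(f"unknown calibration model {model!r}")
    needed = 1 if model == "translation" else 2
    if len(pairs) < needed:
        raise InsufficientData(
            f"{model} calibration needs at least {needed} point pair(s), got {len(pairs)}"
        )
    visual = np.array([p[0] for p in pairs], dtype=np.float64)
    thermal = np.array([p[1] for p in pairs], dtype=np.float64)
    if not (np.all(np.isfinite(visual)) and np.all(np.isfinite(thermal))):
        raise ValueError("calibration points must be finite")

    if model == "translation":
        dr, dc = (thermal - visual).mean(axis=0)
        cal = OffsetCalibration(model="translation", dr=float(dr), dc=float(dc))
    else:
        z = visual[:, 1] + 1j * visual[:, 0]
        w = thermal[:, 1] + 1j * thermal[:, 0]
        n = len(z)
        # normal equations for w = a z + b, linear least squares over C
        szz = np.vdot(z, z).real
        sz = z.sum()
        det = szz * n - abs(sz) ** 2
        if det < 1e-12 * max(szz * n, 1.0):
            raise DegenerateGeometry(
                "visual calibration points are coincident; similarity is unidentifiable"
            )
        szw = np.vdot(z, w)  # sum conj(z) w
        sw = w.sum()
        a = (n * szw - np.conj(sz) * sw) / det
        b = (sw - a * sz) / n
        if abs(a) <= 0:
            raise DegenerateGeometry("fitted similarity collapses to a point")
        cal = OffsetCalibration(
            model="similarity",
            dr=float(b.imag),
            dc=float(b.real),
            s=float(abs(a)),
            theta=float(np.angle(a)),
        )

    predicted = np.array([cal.apply(r, c) for r, c in visual])
    rmse = float(np.sqrt(np.mean(np.sum((predicted - thermal) ** 2, axis=1))))
    return OffsetCalibration(**{**cal.__dict__, "residual_rmse": rmse})


@dataclass(frozen=True)
class MappedPoint:
    row: int
    col: int
    clamped: bool


def map_landmarks(
    landmarks: VisualLandmarks,
    calibration: OffsetCalibration,
    thermal_shape: tuple[int, int],
) -> dict[str, MappedPoint]:
    """Transfer visual landmarks onto the thermal frame.

    Each point is transformed, rounded to the nearest pixel and clamped
    into the thermal bounds; ``clamped`` flags points that fell outside.
    """
    h, w = thermal_shape
    mapped: dict[str, MappedPoint] = {}
    for name, (r, c) in landmarks.points.items():
        tr, tc = calibration.apply(r, c)
        ri, ci = int(round(tr)), int(round(tc))
        clamped = not (0 <= ri < h and 0 <= ci < w)
        mapped[name] = MappedPoint(
            row=int(np.clip(ri, 0, h - 1)),
            col=int(np.clip(ci, 0, w - 1)),
            clamped=clamped,
        )
    return mapped


def _disc_mask(shape: tuple[int, int], row: int, col: int, radius: float) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return (rows - row) ** 2 + (cols - col) ** 2 <= radius**2


def detect_rgbmap(
    thermal: RadiometricImage,
    landmarks: VisualLandmarks,
    calibration: OffsetCalibration,
    refine_radius: float = 3.0,
    config: DetectorConfig = DEFAULT_CONFIG,
) -> DetectionResult:
    """Detection by visual-landmark transfer with optional thermal refinement.

    Maps both canthi (when present) and the nose tip onto the thermal
    image, optionally snaps each to the local thermal extremum within
    ``refine_radius`` pixels, then keeps the hotter canthus and fills in
    the gradient and severity rating.
    """
    if refine_radius < 0:
        raise ValueError("refine_radius must be >= 0")
    shape = (thermal.height, thermal.width)
    mapped = map_landmarks(landmarks, calibration, shape)

    def finalize(name: str, point: MappedPoint, hot: bool, out_name: str) -> Landmark:
        if refine_radius > 0:
            mask = _disc_mask(shape, point.row, point.col, refine_radius)
            locate = locate_hot_spot if hot else locate_cold_spot
            return locate(thermal, mask, config.method, config.q, config.window, name=out_name)
        temp = sample_temperature(thermal, point.row, point.col, config.window)
        return Landmark(out_name, point.row, point.col, temp)

    canthi = [
        finalize(name, mapped[name], hot=True, out_name=CANTHUS)
        for name in ("left_inner_canthus", "right_inner_canthus")
        if name in mapped
    ]
    canthus = max(canthi, key=lambda lm: (lm.temperature, -lm.row, -lm.col))
    nose = finalize("nose_tip", mapped["nose_tip"], hot=False, out_name=NOSE_TIP)
    gradient = compute_gradient(canthus.temperature, nose.temperature)
    return DetectionResult(
        canthus=canthus,
        nose=nose,
        gradient=gradient,
        rating=rate_health(gradient, config.thresholds),
        algorithm="rgb-thermal",
        warning=gradient < 0,
        source_id=thermal.source_id,
    )
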