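"""Face-guide templates and their rasterisation.

Two overlays guide image capture and landmark search:

* ``distance_oval`` — a single face-sized oval; the subject fills it at the
  intended capture distance (too far and the canthus region blurs into its
  surroundings).
* ``eye_nose_circles`` — two eye circles and one nose circle; the inner
  canthus is sought as the hottest spot inside the eye circles and the nose
  tip as the coldest spot inside the nose circle *below* the eye line.

Regions live in normalised coordinates: x rightward in [0, 1] (divided by
width), y downward in [0, 1] (divided by height).  A pixel belongs to a
region iff its centre falls inside the shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import DegenerateROI

EYE_NOSE = "eye_nose_circles"
DISTANCE_OVAL = "distance_oval"


@dataclass(frozen=True)
class EllipseRegion:
    """An axis-aligned ellipse in normalised coordinates (circle if rx == ry)."""

    cx: float
    cy: float
    rx: float
    ry: float

    def contains(self, x: float, y: float) -> bool:
        if self.rx <= 0 or self.ry <= 0:
            return False
        return ((x - self.cx) / self.rx) ** 2 + ((y - self.cy) / self.ry) ** 2 <= 1.0

    def within_unit_square(self) -> bool:
        return (
            self.cx - self.rx >= 0
            and self.cx + self.rx <= 1
            and self.cy - self.ry >= 0
            and self.cy + self.ry <= 1
        )


@dataclass(frozen=True)
class ROITemplate:
    kind: str
    regions: Mapping[str, EllipseRegion]

    def __post_init__(self) -> None:
        for name, region in self.regions.items():
            if not region.within_unit_square():
                raise ValueError(f"region {name!r} extends outside the unit square")
        if self.kind == EYE_NOSE:
            left, right = self.regions["left_eye"], self.regions["right_eye"]
            nose = self.regions["nose"]
            if abs(left.cy - right.cy) > 1e-9:
                raise ValueError("eye centres must share the same height")
            if not nose.cy > left.cy:
                raise ValueError("nose centre must lie below the eye line")
            # centre distance vs radius sum, per axis-aligned circle overlap
            for eye_name in ("left_eye", "right_eye"):
                eye = self.regions[eye_name]
                d = np.hypot(eye.cx - nose.cx, eye.cy - nose.cy)
                if d <= max(eye.rx, eye.ry) + max(nose.rx, nose.ry):
                    raise ValueError(f"{eye_name} overlaps the nose region")


# Default geometry: anthropometrically plausible stand-ins, overridable via
# config.  The nose circle sits clearly below the eye line; eye circles are
# symmetric about the vertical midline.
_DEFAULTS = {
    EYE_NOSE: {
        "left_eye": EllipseRegion(0.38, 0.42, 0.09, 0.09),
        "right_eye": EllipseRegion(0.62, 0.42, 0.09, 0.09),
        "nose": EllipseRegion(0.50, 0.62, 0.08, 0.08),
    },
    DISTANCE_OVAL: {
        "face": EllipseRegion(0.50, 0.50, 0.28, 0.38),
    },
}


def default_template(kind: str = EYE_NOSE) -> ROITemplate:
    """Return the built-in overlay geometry for ``kind``; deterministic."""
    if kind not in _DEFAULTS:
        raise ValueError(f"unknown template kind {kind!r}; expected one of {sorted(_DEFAULTS)}")
    return ROITemplate(kind=kind, regions=dict(_DEFAULTS[kind]))


def template_from_config(path: str | Path) -> ROITemplate:
    """Load a template from a YAML/JSON mapping region -> {cx, cy, rx, ry}.

    The file may carry a top-level ``kind``; otherwise the kind is inferred
    from the region names present.
    """
    data = yaml.safe_load(Path(path).read_text())
    kind = data.pop("kind", None)
    regions = {
        name: EllipseRegion(float(s["cx"]), float(s["cy"]), float(s["rx"]), float(s["ry"]))
        for name, s in data.items()
    }
    if kind is None:
        kind = EYE_NOSE if "nose" in regions else DISTANCE_OVAL
    return ROITemplate(kind=kind, regions=regions)


def resolve_template(name_or_path: str) -> ROITemplate:
    """Accept a built-in template name or a config file path."""
    if name_or_path in (EYE_NOSE, DISTANCE_OVAL, "eye_nose", "oval"):
        kind = EYE_NOSE if name_or_path.startswith("eye") else DISTANCE_OVAL
        return default_template(kind)
    return template_from_config(name_or_path)


def rasterize(template: ROITemplate, region: str, height: int, width: int) -> np.ndarray:
    """Binary mask of ``region`` on a ``height`` x ``width`` grid.

    Pixel (i, j) is inside iff its centre ((j + 0.5)/width, (i + 0.5)/height)
    lies inside the normalised shape.  Raises :class:`DegenerateROI` when no
    pixel centre falls inside (region too small for the resolution).
    """
    if region not in template.regions:
        raise KeyError(f"template has no region {region!r}")
    if height < 16 or width < 16:
        raise ValueError("grid must be at least 16x16")
    shape = template.regions[region]
    ys = (np.arange(height)[:, None] + 0.5) / height
    xs = (np.arange(width)[None, :] + 0.5) / width
    if shape.rx <= 0 or shape.ry <= 0:
        raise DegenerateROI(f"region {region!r} has zero extent")
    mask = ((xs - shape.cx) / shape.rx) ** 2 + ((ys - shape.cy) / shape.ry) ** 2 <= 1.0
    if not mask.any():
        raise DegenerateROI(f"region {region!r} contains no pixel at {height}x{width}")
    return mask


def eye_center_row(template: ROITemplate, height: int) -> int:
    """Pixel row whose centre is nearest the eye-circle centre line."""
    cy = template.regions["left_eye"].cy
    return int(np.clip(round(cy * height - 0.5), 0, height - 1))


def region_mask_below_eyes(template: ROITemplate, height: int, width: int) -> np.ndarray:
    """Nose-circle mask restricted to rows strictly below the eye-centre row.

    This encodes the search region for the nose tip: the coldest spot below
    the eyes.
    """
    if template.kind != EYE_NOSE:
        raise ValueError("below-eyes mask requires an eye_nose_circles template")
    mask = rasterize(template, "nose", height, width)
    row = eye_center_row(template, height)
    mask = mask.copy()
    mask[: row + 1, :] = False
    if not mask.any():
        raise DegenerateROI("nose region lies entirely above the eye line")
    return mask
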