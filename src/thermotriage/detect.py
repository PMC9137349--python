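"""The Max-Min Template detector.

Locates the inner canthus as the hottest spot inside the eye circles and
the nose tip as the coldest spot inside the nose circle below the eye line.
No machine learning: the physiology does the work — the canthus is reliably
the warmest facial region and a cold nose tip marks peripheral shutdown.

Two extremum locators are provided:

* ``single_pixel`` — the raw argmax/argmin inside the mask.  Simple, and
  the oracle used in tests, but a single hot pixel can be sensor noise
  rather than anatomy.
* ``percentile_centroid`` (default, q = 99) — the centroid of the masked
  pixels at or beyond the q-th percentile of masked temperatures, weighted
  by their temperature excess beyond that threshold, rounded to the
  nearest pixel and clamped back into the mask.  This is the minimal
  robust fix for single-pixel noise: a symmetric thermal peak keeps its
  exact centre, and a unique extremum is returned even when temperature
  ties make the percentile threshold non-selective.

Ties in temperature break deterministically to the smallest row, then the
smallest column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateROI, ShapeError
from .io import RadiometricImage
from .templates import ROITemplate, rasterize, region_mask_below_eyes
from .triage import (
    DEFAULT_THRESHOLDS,
    TriageThresholds,
    compute_gradient,
    rate_health,
    sample_temperature,
)

CANTHUS = "inner_canthus"
NOSE_TIP = "nose_tip"


@dataclass(frozen=True)
class Landmark:
    """A detected marker: integer pixel position and its sampled temperature."""

    name: str
    row: int
    col: int
    temperature: float


@dataclass
class DetectionResult:
    """One detection: the red (canthus) and blue (nose-tip) markers.

    ``gradient`` is always ``canthus.temperature - nose.temperature``;
    ``warning`` flags the physiologically unexpected case of a nose warmer
    than the canthus.  ``adjusted`` records whether the markers were moved
    manually after detection (always False at detection time).
    """

    canthus: Landmark
    nose: Landmark
    gradient: float
    rating: str
    algorithm: str
    adjusted: bool = False
    warning: bool = False
    source_id: str = ""

    def __post_init__(self) -> None:
        expected = compute_gradient(self.canthus.temperature, self.nose.temperature)
        if abs(self.gradient - expected) > 1e-9:
            raise ValueError(
                f"stored gradient {self.gradient} inconsistent with landmark "
                f"temperatures (expected {expected})"
            )

    def to_dict(self) -> dict:
        return {
            "source_id": self.source_id,
            "algorithm": self.algorithm,
            "canthus": {
                "row": self.canthus.row,
                "col": self.canthus.col,
                "temperature_C": self.canthus.temperature,
            },
            "nose": {
                "row": self.nose.row,
                "col": self.nose.col,
                "temperature_C": self.nose.temperature,
            },
            "gradient_C": self.gradient,
            "rating": self.rating,
            "adjusted": self.adjusted,
            "warning": self.warning,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DetectionResult":
        return cls(
            canthus=Landmark(
                CANTHUS,
                int(data["canthus"]["row"]),
                int(data["canthus"]["col"]),
                float(data["canthus"]["temperature_C"]),
            ),
            nose=Landmark(
                NOSE_TIP,
                int(data["nose"]["row"]),
                int(data["nose"]["col"]),
                float(data["nose"]["temperature_C"]),
            ),
            gradient=float(data["gradient_C"]),
            rating=data["rating"],
            algorithm=data["algorithm"],
            adjusted=bool(data.get("adjusted", False)),
            warning=bool(data.get("warning", False)),
            source_id=data.get("source_id", ""),
        )


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables shared by the detectors.

    ``window`` is the odd side length of the patch averaged when sampling a
    marker's temperature.  The default of 1 reads the marker pixel itself:
    the percentile-centroid locator already suppresses single-pixel noise,
    and averaging a wider patch over a compact thermal spot systematically
    underestimates the peak and therefore the gradient.
    """

    method: str = "percentile_centroid"
    q: float = 99.0
    window: int = 1
    thresholds: TriageThresholds = field(default_factory=TriageThresholds)


DEFAULT_CONFIG = DetectorConfig()


def _check_mask(image: RadiometricImage, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.temperatures.shape:
        raise ShapeError(f"mask shape {mask.shape} != image shape {image.temperatures.shape}")
    if not mask.any():
        raise DegenerateROI("search mask contains no pixels")
    return mask


def _first_true(mask: np.ndarray) -> tuple[int, int]:
    flat = int(np.argmax(mask))
    return flat // mask.shape[1], flat % mask.shape[1]


def _argext(image: RadiometricImage, mask: np.ndarray, hot: bool) -> tuple[int, int]:
    # row-major argmax gives the smallest (row, col) among exact ties
    fill = -np.inf if hot else np.inf
    values = np.where(mask, image.temperatures, fill)
    flat = int(np.argmax(values) if hot else np.argmin(values))
    return flat // mask.shape[1], flat % mask.shape[1]


def _percentile_centroid(
    image: RadiometricImage, mask: np.ndarray, q: float, hot: bool
) -> tuple[int, int]:
    vals = image.temperatures[mask]
    if hot:
        thr = np.percentile(vals, q)
        sel = mask & (image.temperatures >= thr)
    else:
        thr = np.percentile(vals, 100.0 - q)
        sel = mask & (image.temperatures <= thr)
    rows, cols = np.nonzero(sel)
    # centroid weighted by the temperature excess beyond the threshold: a
    # lone extreme pixel dominates mass ties at the percentile, while a
    # symmetric peak keeps its exact centre; uniform selections fall back
    # to the plain centroid
    excess = image.temperatures[sel] - thr if hot else thr - image.temperatures[sel]
    total = excess.sum()
    if total > 0:
        r = int(np.round(float(np.dot(excess, rows)) / total))
        c = int(np.round(float(np.dot(excess, cols)) / total))
    else:
        r = int(np.round(rows.mean()))
        c = int(np.round(cols.mean()))
    r = int(np.clip(r, 0, mask.shape[0] - 1))
    c = int(np.clip(c, 0, mask.shape[1] - 1))
    if not mask[r, c]:
        mrows, mcols = np.nonzero(mask)
        d2 = (mrows - r) ** 2 + (mcols - c) ** 2
        i = int(np.argmin(d2))  # nonzero is row-major, so ties pick smallest (row, col)
        r, c = int(mrows[i]), int(mcols[i])
    return r, c


def _locate(
    image: RadiometricImage,
    mask: np.ndarray,
    method: str,
    q: float,
    hot: bool,
    name: str,
    window: int,
) -> Landmark:
    mask = _check_mask(image, mask)
    if not (0 < q <= 100):
        raise ValueError(f"percentile q must be in (0, 100], got {q}")
    if method == "single_pixel":
        r, c = _argext(image, mask, hot)
    elif method == "percentile_centroid":
        r, c = _percentile_centroid(image, mask, q, hot)
    else:
        raise ValueError(f"unknown method {method!r}")
    return Landmark(name, r, c, sample_temperature(image, r, c, window))


def locate_hot_spot(
    image: RadiometricImage,
    mask: np.ndarray,
    method: str = "percentile_centroid",
    q: float = 99.0,
    window: int = 1,
    name: str = CANTHUS,
) -> Landmark:
    """Robust hottest spot inside ``mask``; see module docstring for methods."""
    return _locate(image, mask, method, q, hot=True, name=name, window=window)


def locate_cold_spot(
    image: RadiometricImage,
    mask: np.ndarray,
    method: str = "percentile_centroid",
    q: float = 99.0,
    window: int = 1,
    name: str = NOSE_TIP,
) -> Landmark:
    """Mirror of :func:`locate_hot_spot` for the coldest spot."""
    return _locate(image, mask, method, q, hot=False, name=name, window=window)


def detect_maxmin(
    image: RadiometricImage,
    template: ROITemplate,
    config: DetectorConfig = DEFAULT_CONFIG,
) -> DetectionResult:
    """Run the Max-Min Template detection on a radiometric image.

    The canthus marker is the hotter of the per-eye hot spots (both canthi
    are core proxies; the paper-described procedure does not fix an eye);
    the nose marker is the cold spot in the nose circle below the eye line.
    """
    if template.kind != "eye_nose_circles":
        raise ValueError("max-min detection requires an eye_nose_circles template")
    h, w = image.height, image.width
    candidates = [
        locate_hot_spot(
            image,
            rasterize(template, eye, h, w),
            config.method,
            config.q,
            config.window,
        )
        for eye in ("left_eye", "right_eye")
    ]
    canthus = max(candidates, key=lambda lm: (lm.temperature, -lm.row, -lm.col))
    nose = locate_cold_spot(
        image,
        region_mask_below_eyes(template, h, w),
        config.method,
        config.q,
        config.window,
    )
    gradient = compute_gradient(canthus.temperature, nose.temperature)
    return DetectionResult(
        canthus=canthus,
        nose=nose,
        gradient=gradient,
        rating=rate_health(gradient, config.thresholds),
        algorithm="max-min",
        warning=gradient < 0,
        source_id=image.source_id,
    )
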