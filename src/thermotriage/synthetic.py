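"""Synthetic radiometric face generator with full ground truth.

Real triage thermograms of patients are confidential, so detectors are
exercised on synthetic faces that reproduce the statistical structure the
algorithms rely on: a face at skin temperature against a cooler
background, two compact hot spots at the inner canthi (the facial maxima),
a variably cold (or, in a well-perfused patient, warm) spot at the nose
tip, optical blur, and independent per-pixel sensor noise.  The generator
also emits the matching visual-frame landmark coordinates displaced by a
fixed lens parallax, so the RGB-to-thermal transfer path can be tested
end to end.

Construction order for each face:

1. background plane;
2. face oval at skin temperature (distance-oval template geometry);
3. Gaussian bumps whose peak values equal the specified canthus and
   nose-tip temperatures, centred at the template ROI centres displaced by
   an integer jitter;
4. Gaussian optical blur;
5. i.i.d. Gaussian pixel noise.

Ground truth records the pre-blur peak pixels (blur attenuates a symmetric
peak but does not move it) and the true gradient computed from the
specified temperatures, i.e. the value an ideal radiometer would report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import SpecError
from .io import Calibration, RadiometricImage
from .mapping import VisualLandmarks
from .templates import DISTANCE_OVAL, EYE_NOSE, ROITemplate, default_template


@dataclass(frozen=True)
class FaceSpec:
    """Parameters of one synthetic face.

    Temperatures are Celsius; lengths are pixels.  ``spot_sigma`` is the
    Gaussian footprint of the canthus/nose-tip spots, ``blur_sigma`` the
    optical blur, ``noise_sigma`` the per-pixel sensor noise,
    ``landmark_jitter`` the maximum integer displacement of each true
    landmark from its template ROI centre, and ``parallax`` the (dr, dc)
    offset subtracted from thermal coordinates to obtain visual-frame
    coordinates.
    """

    image_shape: tuple[int, int] = (120, 160)  # (height, width), landscape sensor
    background_temp: float = 20.0
    skin_temp: float = 33.5
    canthus_temp_left: float = 36.2
    canthus_temp_right: float = 36.0
    nose_tip_temp: float = 30.5
    spot_sigma: float = 2.5
    blur_sigma: float = 1.0
    noise_sigma: float = 0.1
    landmark_jitter: int = 2
    parallax: tuple[int, int] = (6, 0)

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h < 32 or w < 32:
            raise SpecError(f"image shape {self.image_shape} too small for a face")
        c_max = max(self.canthus_temp_left, self.canthus_temp_right)
        c_min = min(self.canthus_temp_left, self.canthus_temp_right)
        if not (c_min > self.skin_temp > self.background_temp):
            raise SpecError(
                "need canthus temps > skin temp > background temp, got "
                f"{(self.canthus_temp_left, self.canthus_temp_right)}, "
                f"{self.skin_temp}, {self.background_temp}"
            )
        if self.nose_tip_temp > c_max:
            raise SpecError(
                f"nose tip temp {self.nose_tip_temp} above the warmer canthus {c_max}"
            )
        for name in ("spot_sigma", "blur_sigma", "noise_sigma"):
            if getattr(self, name) < 0:
                raise SpecError(f"{name} must be >= 0")
        if self.landmark_jitter < 0:
            raise SpecError("landmark_jitter must be >= 0")
        if self.spot_sigma == 0:
            raise SpecError("spot_sigma must be positive")

    @property
    def true_gradient(self) -> float:
        return max(self.canthus_temp_left, self.canthus_temp_right) - self.nose_tip_temp


@dataclass(frozen=True)
class GroundTruth:
    """Planted landmark pixels and the true gradient for one synthetic face."""

    canthus_left: tuple[int, int]
    canthus_right: tuple[int, int]
    nose_tip: tuple[int, int]
    true_gradient: float
    visual_points: dict[str, tuple[int, int]]
    visual_shape: tuple[int, int]

    def visual_landmarks(self) -> VisualLandmarks:
        """The generator's stand-in for an external visual-frame detector."""
        return VisualLandmarks(
            points={k: (float(r), float(c)) for k, (r, c) in self.visual_points.items()},
            image_shape=self.visual_shape,
        )


def _roi_center_px(cx: float, cy: float, height: int, width: int) -> tuple[int, int]:
    return (int(round(cy * height - 0.5)), int(round(cx * width - 0.5)))


def _jittered_center(
    region, height: int, width: int, jitter: int, rng: np.random.Generator
) -> tuple[int, int]:
    """ROI centre displaced by integer jitter, regenerated while outside the ROI."""
    r0, c0 = _roi_center_px(region.cx, region.cy, height, width)
    if jitter == 0:
        return (r0, c0)
    for _ in range(10):
        dr, dc = rng.integers(-jitter, jitter + 1, size=2)
        r, c = r0 + int(dr), c0 + int(dc)
        if region.contains((c + 0.5) / width, (r + 0.5) / height):
            return (r, c)
    raise SpecError(
        f"landmark jitter {jitter} px repeatedly leaves the ROI "
        f"(radius {region.rx} normalised); reduce the jitter"
    )


def _add_bump(
    field_: np.ndarray, row: int, col: int, peak_delta: float, sigma: float
) -> None:
    # additive Gaussian bump whose value at (row, col) is exactly peak_delta
    h, w = field_.shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    d2 = (rows - row) ** 2 + (cols - col) ** 2
    field_ += peak_delta * np.exp(-d2 / (2.0 * sigma**2))


def generate_face(
    spec: FaceSpec = FaceSpec(),
    seed: int = 0,
    template: ROITemplate | None = None,
) -> tuple[RadiometricImage, GroundTruth]:
    """Generate one synthetic face; deterministic given ``(spec, seed)``."""
    if template is None:
        template = default_template(EYE_NOSE)
    h, w = spec.image_shape
    rng = np.random.default_rng(seed)

    left = _jittered_center(template.regions["left_eye"], h, w, spec.landmark_jitter, rng)
    right = _jittered_center(template.regions["right_eye"], h, w, spec.landmark_jitter, rng)
    nose = _jittered_center(template.regions["nose"], h, w, spec.landmark_jitter, rng)

    temps = np.full((h, w), spec.background_temp, dtype=np.float64)
    oval = default_template(DISTANCE_OVAL).regions["face"]
    ys = (np.arange(h)[:, None] + 0.5) / h
    xs = (np.arange(w)[None, :] + 0.5) / w
    face_mask = ((xs - oval.cx) / oval.rx) ** 2 + ((ys - oval.cy) / oval.ry) ** 2 <= 1.0
    temps[face_mask] = spec.skin_temp

    _add_bump(temps, *left, spec.canthus_temp_left - spec.skin_temp, spec.spot_sigma)
    _add_bump(temps, *right, spec.canthus_temp_right - spec.skin_temp, spec.spot_sigma)
    _add_bump(temps, *nose, spec.nose_tip_temp - spec.skin_temp, spec.spot_sigma)

    if spec.blur_sigma > 0:
        temps = gaussian_filter(temps, spec.blur_sigma, mode="nearest")
    if spec.noise_sigma > 0:
        temps = temps + rng.normal(0.0, spec.noise_sigma, size=(h, w))

    image = RadiometricImage(
        temps, calibration=Calibration(), source_id=f"synthetic-seed{seed}"
    )
    dr, dc = spec.parallax
    visual_points = {
        "left_inner_canthus": (left[0] - dr, left[1] - dc),
        "right_inner_canthus": (right[0] - dr, right[1] - dc),
        "nose_tip": (nose[0] - dr, nose[1] - dc),
    }
    truth = GroundTruth(
        canthus_left=left,
        canthus_right=right,
        nose_tip=nose,
        true_gradient=spec.true_gradient,
        visual_points=visual_points,
        visual_shape=(h, w),
    )
    return image, truth


def cohort_seeds(master_seed: int, n: int) -> list[int]:
    """Reproducible per-face seeds derived from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_cohort(
    n: int,
    gradient_range: tuple[float, float],
    base_spec: FaceSpec = FaceSpec(),
    seed: int = 0,
    template: ROITemplate | None = None,
) -> Iterator[tuple[FaceSpec, RadiometricImage, GroundTruth]]:
    """Yield ``n`` faces whose true gradients are equally spaced over a range.

    The nose-tip temperature is varied against the fixed warmer-canthus
    temperature; all other parameters come from ``base_spec``.  Per-face
    seeds are derived reproducibly from the master ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = gradient_range
    if not lo <= hi:
        raise ValueError(f"gradient range must be ordered, got {gradient_range}")
    gradients = np.linspace(lo, hi, n) if n > 1 else np.array([(lo + hi) / 2.0])
    c_max = max(base_spec.canthus_temp_left, base_spec.canthus_temp_right)
    for face_seed, g in zip(cohort_seeds(seed, n), gradients):
        spec = replace(base_spec, nose_tip_temp=float(c_max - g))
        image, truth = generate_face(spec, face_seed, template)
        yield spec, image, truth
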