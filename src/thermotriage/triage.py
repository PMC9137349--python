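"""Temperature sampling, the core-peripheral gradient, and severity rating.

The gradient is the inner-canthus temperature (core proxy) minus the
nose-tip temperature (peripheral proxy), in Celsius.  A large positive
gradient suggests circulation is centralising around the vital organs — the
early-deterioration signal this tool screens for.

The five-colour severity scale (blue < green < yellow < orange < red) maps
the gradient through four ordered cut-points.  No clinically validated
cut-points are published; the defaults here are explicit placeholders and
must be configured before any clinical interpretation.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .io import RadiometricImage

#: Severity order, least to most severe.
SEVERITY_ORDER = ("blue", "green", "yellow", "orange", "red")


@dataclass(frozen=True)
class TriageThresholds:
    """Ordered gradient cut-points (Celsius) for the five-colour rating.

    Intervals are closed on the left: a gradient exactly at a cut-point
    takes the more severe colour.
    """

    g1: float = 2.0
    g2: float = 4.0
    g3: float = 6.0
    g4: float = 8.0

    def __post_init__(self) -> None:
        cuts = (self.g1, self.g2, self.g3, self.g4)
        if not all(np.isfinite(cuts)):
            raise ValueError("triage cut-points must be finite")
        if not (self.g1 < self.g2 < self.g3 < self.g4):
            raise ValueError(f"triage cut-points must be strictly increasing, got {cuts}")

    @property
    def cuts(self) -> tuple[float, float, float, float]:
        return (self.g1, self.g2, self.g3, self.g4)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TriageThresholds":
        data = yaml.safe_load(Path(path).read_text())
        return cls(float(data["g1"]), float(data["g2"]), float(data["g3"]), float(data["g4"]))


DEFAULT_THRESHOLDS = TriageThresholds()


def sample_temperature(
    image: RadiometricImage, row: int, col: int, window: int = 1
) -> float:
    """Mean temperature of the ``window`` x ``window`` patch centred at (row, col).

    The patch is truncated at image borders (a corner pixel with window 3
    averages the four existing pixels).  ``window`` must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    h, w = image.height, image.width
    if not (0 <= row < h and 0 <= col < w):
        raise IndexError(f"pixel ({row}, {col}) outside {h}x{w} image")
    half = window // 2
    patch = image.temperatures[
        max(0, row - half) : min(h, row + half + 1),
        max(0, col - half) : min(w, col + half + 1),
    ]
    return float(patch.mean())


def compute_gradient(t_canthus: float, t_nose: float) -> float:
    """Core-peripheral gradient: canthus minus nose-tip temperature, Celsius.

    Positive when the nose is colder than the canthus (the concerning
    direction); the sign is preserved when the nose is warmer.
    """
    if not (np.isfinite(t_canthus) and np.isfinite(t_nose)):
        raise ValueError("temperatures must be finite")
    return float(t_canthus) - float(t_nose)


def rate_health(gradient: float, thresholds: TriageThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map a gradient to its severity colour via the configured cut-points."""
    return SEVERITY_ORDER[bisect_right(thresholds.cuts, gradient)]
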