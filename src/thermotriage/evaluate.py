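"""Manual-adjustment evaluation and CSV export.

In the clinical trial of the app, a detector "performed well" when the
nurse did not have to move the red (canthus) and blue (nose-tip) markers
to the correct anatomical spots.  Against synthetic ground truth this
judgement becomes a pixel criterion: a detection needs adjustment when
either marker lies farther than a tolerance from its true landmark, the
canthus being compared against the nearer of the two true canthi (either
eye is anatomically correct).

Per-algorithm results are summarised as an adjustment percentage (rounded
half away from zero), its complement the precision percentage, and a rank
(1 = fewest adjustments by percentage; ties broken by more tests).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detect import DetectionResult
from .errors import InsufficientData
from .synthetic import GroundTruth


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def landmark_errors(detected: DetectionResult, truth: GroundTruth) -> tuple[float, float]:
    """Euclidean pixel distances (canthus, nose) of a detection from truth.

    The canthus error is taken against the nearer true canthus.
    """
    canthus = np.array([detected.canthus.row, detected.canthus.col], dtype=float)
    nose = np.array([detected.nose.row, detected.nose.col], dtype=float)
    d_canthus = min(
        float(np.hypot(*(canthus - np.array(truth.canthus_left, dtype=float)))),
        float(np.hypot(*(canthus - np.array(truth.canthus_right, dtype=float)))),
    )
    d_nose = float(np.hypot(*(nose - np.array(truth.nose_tip, dtype=float))))
    return d_canthus, d_nose


def needs_adjustment(
    detected: DetectionResult, truth: GroundTruth, tolerance: float = 3.0
) -> bool:
    """Whether a nurse would have to move at least one marker.

    True iff the larger of the canthus and nose-tip localisation errors
    exceeds ``tolerance`` pixels.
    """
    if not tolerance > 0:
        raise ValueError("tolerance must be positive")
    return max(landmark_errors(detected, truth)) > tolerance


@dataclass(frozen=True)
class EvaluationRecord:
    face_id: str
    algorithm: str
    detected: DetectionResult
    truth: GroundTruth
    tolerance: float
    needs_adjustment: bool

    @classmethod
    def from_detection(
        cls,
        face_id: str,
        detected: DetectionResult,
        truth: GroundTruth,
        tolerance: float = 3.0,
    ) -> "EvaluationRecord":
        return cls(
            face_id=face_id,
            algorithm=detected.algorithm,
            detected=detected,
            truth=truth,
            tolerance=tolerance,
            needs_adjustment=needs_adjustment(detected, truth, tolerance),
        )


@dataclass(frozen=True)
class AlgorithmStats:
    """One row of the per-algorithm performance table."""

    algorithm: str
    n_tests: int
    n_adjusted: int
    adjustment_pct: int
    precision_pct: int
    rank: int


def summarize_counts(counts: dict[str, tuple[int, int]]) -> list[AlgorithmStats]:
    """Build the performance table from per-algorithm (n_tests, n_adjusted).

    Percentages are rounded half away from zero; rank 1 is the lowest
    adjustment percentage, ties going to the algorithm with more tests.
    Returned sorted by rank.
    """
    if not counts:
        raise InsufficientData("no evaluation records to summarise")
    rows = []
    for algorithm, (n_tests, n_adjusted) in counts.items():
        if not 0 <= n_adjusted <= n_tests or n_tests == 0:
            raise ValueError(f"{algorithm}: invalid counts ({n_tests}, {n_adjusted})")
        pct = _round_half_away(100.0 * n_adjusted / n_tests)
        rows.append((algorithm, n_tests, n_adjusted, pct))
    order = sorted(rows, key=lambda r: (r[3], -r[1], r[0]))
    rank = {row[0]: i + 1 for i, row in enumerate(order)}
    return [
        AlgorithmStats(
            algorithm=a,
            n_tests=n,
            n_adjusted=k,
            adjustment_pct=pct,
            precision_pct=100 - pct,
            rank=rank[a],
        )
        for a, n, k, pct in order
    ]


def summarize(records: Sequence[EvaluationRecord]) -> list[AlgorithmStats]:
    """Group evaluation records by algorithm and compute the performance table."""
    if not records:
        raise InsufficientData("no evaluation records to summarise")
    counts: dict[str, tuple[int, int]] = {}
    for rec in records:
        n, k = counts.get(rec.algorithm, (0, 0))
        counts[rec.algorithm] = (n + 1, k + int(rec.needs_adjustment))
    return summarize_counts(counts)


def stats_to_frame(stats: Sequence[AlgorithmStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "algorithm": s.algorithm,
                "n_tests": s.n_tests,
                "n_adjusted": s.n_adjusted,
                "adjustment_pct": s.adjustment_pct,
                "precision_pct": s.precision_pct,
                "rank": s.rank,
            }
            for s in stats
        ]
    )


EXPORT_COLUMNS = [
    "face_id",
    "timestamp",
    "algorithm",
    "canthus_row",
    "canthus_col",
    "nose_row",
    "nose_col",
    "t_canthus_C",
    "t_nose_C",
    "gradient_C",
    "rating",
    "adjusted",
]


def export_csv(
    results: Iterable[tuple[str, DetectionResult]],
    path: str | Path,
    timestamp: str | None = None,
) -> Path:
    """Write detections as the app's export CSV, one row per detection.

    ``results`` yields (face_id, detection) pairs; ``timestamp`` defaults
    to the current UTC time in ISO format and applies to all rows.
    """
    if timestamp is None:
        timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    rows = [
        {
            "face_id": face_id,
            "timestamp": timestamp,
            "algorithm": det.algorithm,
            "canthus_row": det.canthus.row,
            "canthus_col": det.canthus.col,
            "nose_row": det.nose.row,
            "nose_col": det.nose.col,
            "t_canthus_C": det.canthus.temperature,
            "t_nose_C": det.nose.temperature,
            "gradient_C": det.gradient,
            "rating": det.rating,
            "adjusted": det.adjusted,
        }
        for face_id, det in results
    ]
    frame = pd.DataFrame(rows, columns=EXPORT_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path
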