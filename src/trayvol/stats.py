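"""Robustness statistics over repeated volume estimates.

A "rotation block" is the set of frame-level volume estimates from one pass
of the same plate under the camera at one food orientation.  Stability of
the pipeline is summarized per block (mean, SD, CV = SD/mean) and globally
(CV over all frames pooled, not over block means).  SD uses the sample
(n - 1) denominator, appropriate for the small per-pass frame counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RotationBlock",
    "SequenceReport",
    "block_stats",
    "pooled_cv",
    "proportionality_check",
]


def block_stats(volumes: list[float] | np.ndarray) -> tuple[float, float, float]:
    """Mean, sample SD (n-1) and CV percent of one block of volumes.

    Raises if fewer than 2 values (SD undefined) or the mean is not positive
    (CV undefined).
    """
    v = np.asarray(volumes, dtype=np.float64)
    if v.size < 2:
        raise ValueError("sd undefined: need at least 2 values")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean <= 0:
        raise ValueError("cv undefined: mean must be positive")
    return mean, sd, 100.0 * sd / mean


@dataclass(frozen=True)
class RotationBlock:
    """Frame-level volumes from one rotation/pass, with summary statistics."""

    block_id: str
    volumes: tuple[float, ...]
    mean: float = field(init=False)
    sd: float = field(init=False)
    cv_percent: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "volumes", tuple(float(v) for v in self.volumes))
        mean, sd, cv = block_stats(self.volumes)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "cv_percent", cv)


def pooled_cv(blocks: list[RotationBlock]) -> float:
    """CV percent over the concatenation of all blocks' frame volumes.

    This is the frame-wise variability metric: it pools individual frames,
    never block means, so within-pass fluctuation is not averaged away.
    """
    pooled: list[float] = [v for b in blocks for v in b.volumes]
    _, _, cv = block_stats(pooled)
    return cv


@dataclass(frozen=True)
class SequenceReport:
    """Per-block and pooled statistics for one processed sequence."""

    blocks: tuple[RotationBlock, ...]
    global_cv_percent: float
    n_frames: int
    n_failed: int = 0
    failures: tuple[str, ...] = ()

    @classmethod
    def from_blocks(
        cls, blocks: list[RotationBlock], n_failed: int = 0, failures: tuple[str, ...] = ()
    ) -> "SequenceReport":
        return cls(
            blocks=tuple(blocks),
            global_cv_percent=pooled_cv(blocks),
            n_frames=sum(len(b.volumes) for b in blocks),
            n_failed=n_failed,
            failures=tuple(failures),
        )


def proportionality_check(
    series_a: list[float] | np.ndarray, series_b: list[float] | np.ndarray
) -> tuple[np.ndarray, float]:
    """Elementwise ratio b/a and the sign-consistency of b - a.

    Used to check that two repeated-measure series (e.g. the same food at two
    portion sizes tracked across rotations) move in parallel: ratios near a
    constant and one series staying on one side of the other.  The
    sign-consistency is the largest fraction of indices on which ``b - a``
    keeps a single sign, with exact ties (zero difference) counting toward
    either side; identical series therefore score 1.0.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    if np.any(a == 0):
        raise ValueError("zero denominator in ratio series")
    ratios = b / a
    diff = b - a
    n = diff.size
    n_pos = int(np.sum(diff > 0))
    n_neg = int(np.sum(diff < 0))
    n_zero = n - n_pos - n_neg
    consistency = max(n_pos + n_zero, n_neg + n_zero) / n
    return ratios, consistency
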