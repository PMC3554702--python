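"""Competitive normalization across the K gnostic sets of one channel.

At each location or time step the sets' pooled activities compete: activities
below the population mean are suppressed (half-wave rectification after mean
subtraction) and the survivors are divisively normalized by the population's
contraharmonic mean — the arithmetic mean plus the Fano factor — so a noisy,
high-variability population inhibits itself more than a clean one.  The hard
mode is the grandmother-cell ablation: the single most active set keeps a
response of 1 and every other set is silenced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SOFT = "soft"
HARD = "hard"


@dataclass
class CompetitionConfig:
    mode: str = SOFT
    floor: float = 1e-9  # division-safety constant added to the denominator

    def __post_init__(self) -> None:
        if self.mode not in (SOFT, HARD):
            raise ValueError(f"mode must be 'soft' or 'hard', got {self.mode!r}")
        if self.floor <= 0:
            raise ValueError(f"floor must be positive, got {self.floor}")


def contraharmonic_mean(values: np.ndarray) -> float:
    """(sum v^2) / (sum v) for nonnegative values, not all zero.

    Identically equal to mean(v) + popvar(v)/mean(v), i.e. the arithmetic
    mean plus the Fano factor.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("contraharmonic mean requires nonnegative values")
    s = v.sum()
    if s <= 0:
        raise ValueError("contraharmonic mean is undefined for an all-zero vector")
    return float((v * v).sum() / s)


def competitive_normalize(
    activities: np.ndarray,
    config: CompetitionConfig | None = None,
) -> np.ndarray:
    """Normalize the K per-set activities at one location.

    Soft mode: r = halfwave(a - mean(a)); output r / (contraharmonic(r) + floor),
    or all zeros when nothing exceeds the population mean (a complete tie
    carries no evidence).  Mean-thresholding silences at least the weakest
    set, so at most K-1 entries survive.  Output is invariant to adding a
    constant to all activities and to positively rescaling the rectified
    pattern.

    Hard mode: one-hot at the most active set (ties to the lowest index).
    """
    config = config or CompetitionConfig()
    a = np.asarray(activities, dtype=float)
    if a.ndim != 1 or a.shape[0] < 2:
        raise ValueError(f"need a 1-D vector of K >= 2 activities, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite activities")

    if config.mode == HARD:
        out = np.zeros_like(a)
        out[int(np.argmax(a))] = 1.0
        return out

    r = a - a.mean()
    np.clip(r, 0.0, None, out=r)
    if not np.any(r > 0):
        return np.zeros_like(a)
    return r / (contraharmonic_mean(r) + config.floor)
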