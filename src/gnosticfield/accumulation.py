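"""Evidence accumulation across locations/time and decoder-input assembly.

Per channel, the competitively normalized K-vectors from every location are
summed and normalized — by default by the most active category, so the
winning category's evidence is exactly 1 — and the per-channel vectors are
concatenated channel-major into the length-K*U input of the linear decoder.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

MAX = "max"
CENTER_L2 = "center_l2"


def accumulate_evidence(
    normalized_responses: Sequence[np.ndarray] | np.ndarray,
    mode: str = MAX,
) -> np.ndarray:
    """Sum per-location K-vectors and normalize.

    ``max`` mode divides by the largest category sum (an all-zero total stays
    all-zero), so entries lie in [0, 1] with the maximum exactly 1 whenever
    any evidence arrived.  ``center_l2`` subtracts the mean and divides by the
    Euclidean norm — a variant better suited to margin-based decoders.
    Location order cannot matter: the operation is a sum.
    """
    R = np.atleast_2d(np.asarray(normalized_responses, dtype=float))
    if R.shape[0] < 1 or R.size == 0:
        raise ValueError("need responses from at least one location")
    s = R.sum(axis=0)
    if mode == MAX:
        m = s.max()
        return s / m if m > 0 else s
    if mode == CENTER_L2:
        c = s - s.mean()
        nrm = np.linalg.norm(c)
        return c / nrm if nrm > 0 else c
    raise ValueError(f"unknown accumulation mode {mode!r}")


def assemble_feature(
    per_channel_evidence: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    channel_order: Sequence[str] | None = None,
) -> np.ndarray:
    """Concatenate U per-channel K-vectors into f, channel-major.

    With a mapping input, ``channel_order`` fixes the layout and every listed
    channel must be present.  Layout: f = (ch0_cat0..ch0_catK-1, ch1_cat0, ...).
    """
    if isinstance(per_channel_evidence, Mapping):
        if channel_order is None:
            channel_order = list(per_channel_evidence.keys())
        missing = [c for c in channel_order if c not in per_channel_evidence]
        if missing:
            raise ValueError(f"missing channels in evidence: {missing}")
        parts = [np.asarray(per_channel_evidence[c], dtype=float) for c in channel_order]
    else:
        parts = [np.asarray(v, dtype=float) for v in per_channel_evidence]
        if len(parts) == 0:
            raise ValueError("no channels to assemble")
    return np.concatenate(parts)


def split_feature(f: np.ndarray, n_channels: int, n_categories: int) -> list[np.ndarray]:
    """Inverse of :func:`assemble_feature` for equal-K channels."""
    f = np.asarray(f, dtype=float)
    if f.shape != (n_channels * n_categories,):
        raise ValueError(
            f"expected length {n_channels * n_categories}, got shape {f.shape}"
        )
    return [f[u * n_categories : (u + 1) * n_categories].copy() for u in range(n_channels)]
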