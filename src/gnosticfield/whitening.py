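"""Per-channel PCA whitening followed by spherical (unit-length) normalization.

Whitening decorrelates the channel's features and equalizes their variances so
that dot products between whitened, unit-normalized vectors measure cosine
similarity on an equal footing across feature dimensions.  The transform is

    W = E (Lambda + eps I)^(-1/2) E^T

with E, Lambda the eigendecomposition of the centered training covariance; all
principal components are retained.  A small regularizer eps keeps near-null
directions from blowing up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


class DegenerateVectorWarning(UserWarning):
    """A vector mapped exactly to the training mean; its whitened form is zero."""


@dataclass
class WhiteningModel:
    channel_id: str
    mean: np.ndarray      # (d,) training mean
    matrix: np.ndarray    # (d, d) whitening transform
    epsilon: float        # effective (absolute) regularizer used
    identity_flag: bool = False  # ablation: no whitening, no mean subtraction


def fit_whitener(
    features: np.ndarray,
    epsilon: float = 1e-4,
    *,
    relative: bool = True,
    channel_id: str = "",
) -> WhiteningModel:
    """Fit a whitening transform on features pooled over all categories.

    Parameters
    ----------
    features
        (n, d) array, n >= 2 with at least two distinct rows.
    epsilon
        Regularizer added to every eigenvalue before the inverse square root.
        With ``relative=True`` (default) it is scaled by the mean eigenvalue
        (trace/d) so the same setting works across channels whose features
        live on different scales; the effective absolute value is stored on
        the returned model.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D feature array, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in whitening training data")
    n, d = X.shape
    if n < 2 or len(np.unique(X, axis=0)) < 2:
        raise ValueError("whitening needs at least 2 distinct feature vectors")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")

    mu = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    lam, E = np.linalg.eigh(cov)
    lam = np.clip(lam, 0.0, None)

    eps_abs = epsilon * float(lam.mean()) if relative else float(epsilon)
    denom = lam + eps_abs
    # eps=0 with singular covariance: null directions are projected out
    inv_sqrt = np.where(denom > 0, 1.0 / np.sqrt(np.where(denom > 0, denom, 1.0)), 0.0)
    W = (E * inv_sqrt) @ E.T
    return WhiteningModel(channel_id=channel_id, mean=mu, matrix=W, epsilon=eps_abs)


def identity_whitener(dim: int, channel_id: str = "") -> WhiteningModel:
    """No-whitening ablation: identity transform, no mean subtraction.

    Spherical normalization still applies downstream.
    """
    return WhiteningModel(
        channel_id=channel_id,
        mean=np.zeros(dim),
        matrix=np.eye(dim),
        epsilon=0.0,
        identity_flag=True,
    )


def apply_whitener(model: WhiteningModel, vector: np.ndarray) -> np.ndarray:
    """Whiten one vector and scale it to unit Euclidean length.

    A vector equal to the training mean whitens to the zero vector; it is
    returned as zeros and flagged with :class:`DegenerateVectorWarning`.
    """
    x = np.asarray(vector, dtype=float)
    d = model.matrix.shape[0]
    if x.shape != (d,):
        raise ValueError(f"expected a vector of length {d}, got shape {x.shape}")
    y = x if model.identity_flag else model.matrix @ (x - model.mean)
    nrm = float(np.linalg.norm(y))
    if nrm == 0.0:
        warnings.warn(
            "vector whitened to zero (equal to the training mean); returning zeros",
            DegenerateVectorWarning,
            stacklevel=2,
        )
        return np.zeros(d)
    return y / nrm


def whiten(model: WhiteningModel, X: np.ndarray) -> np.ndarray:
    """Whiten the rows of (n, d) ``X``; each row comes back unit length.

    Degenerate rows (those that whiten to zero) stay zero without warning —
    downstream stages read them as "no evidence here".
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.matrix.shape[0]:
        raise ValueError(
            f"expected (n, {model.matrix.shape[0]}) array, got shape {X.shape}"
        )
    Y = X if model.identity_flag else (X - model.mean) @ model.matrix.T
    nrm = np.linalg.norm(Y, axis=1, keepdims=True)
    return np.divide(Y, nrm, out=np.zeros_like(Y), where=nrm > 0)
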