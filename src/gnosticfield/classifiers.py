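"""Decoders for accumulated evidence vectors.

The primary decoder is multi-category Balanced Winnow.  Winnow maintains
excitatory and inhibitory weight populations updated multiplicatively; both
can be folded into a single weight vector through the hyperbolic sine, under
which the learning rule becomes additive.  We store weights in that
re-expressed (additive) space: the response of category k to evidence f is
sinh(beta_k) . f, and a mistake on an instance of category c strengthens
beta_c by +eta*f while the most active incorrect category is weakened by
-eta*f.  Training is mistake-driven in epochs over the data (batch use).

A winner-take-all rule over a single channel's evidence and a pluggable
external linear-classifier adapter (e.g. a multi-category linear SVM) round
out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np


@dataclass
class WinnowModel:
    categories: list[str]
    beta: np.ndarray  # (K, D) weights in the sinh-reexpressed additive space
    eta: float = 0.8
    epochs_run: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.ndim != 2 or self.beta.shape[0] != len(self.categories):
            raise ValueError(
                f"beta must be (K, D) with K={len(self.categories)}, got {self.beta.shape}"
            )
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("non-finite Winnow weights")

    @property
    def n_features(self) -> int:
        return int(self.beta.shape[1])


def _check_f(model: WinnowModel, f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.shape != (model.n_features,):
        raise ValueError(f"expected evidence of length {model.n_features}, got {f.shape}")
    return f


def winnow_response(model: WinnowModel, f: np.ndarray, k: int) -> float:
    """Response of the unit for category index ``k``: sinh(beta_k) . f."""
    f = _check_f(model, f)
    return float(np.sinh(model.beta[k]) @ f)


def winnow_scores(model: WinnowModel, f: np.ndarray) -> np.ndarray:
    """All K category responses at once."""
    f = _check_f(model, f)
    return np.sinh(model.beta) @ f


def winnow_update(model: WinnowModel, f: np.ndarray, correct: int, incorrect: int) -> None:
    """One mistake-driven update in the additive space, in place.

    Strengthens the correct category's weights by +eta*f and weakens the most
    active incorrect category's by -eta*f; every other category is untouched.
    """
    f = _check_f(model, f)
    model.beta[correct] += model.eta * f
    model.beta[incorrect] -= model.eta * f


def winnow_predict(model: WinnowModel, f: np.ndarray) -> str:
    """Category with the largest response; ties go to the lowest index."""
    return model.categories[int(np.argmax(winnow_scores(model, f)))]


def winnow_train(
    features: np.ndarray,
    labels: Sequence[str],
    categories: Sequence[str] | None = None,
    eta: float = 0.8,
    max_epochs: int = 500,
    shuffle_seed: int | None = None,
) -> WinnowModel:
    """Train multi-category Balanced Winnow on evidence vectors.

    Instances are visited in dataset order (or a seeded per-epoch shuffle);
    each misclassified instance triggers one :func:`winnow_update` against the
    most active incorrect category.  Training stops after an epoch with zero
    updates, or at ``max_epochs`` with a warning.  Deterministic given the
    instance order.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    labels = list(labels)
    if F.shape[0] != len(labels):
        raise ValueError(f"{F.shape[0]} feature rows but {len(labels)} labels")
    if not np.all(np.isfinite(F)):
        raise ValueError("non-finite evidence features")
    if categories is None:
        categories = sorted(set(labels))
    categories = list(categories)
    if len(categories) < 2:
        raise ValueError("Winnow needs at least 2 categories")
    cat_index = {c: i for i, c in enumerate(categories)}
    y = np.array([cat_index[l] for l in labels])

    model = WinnowModel(
        categories=categories,
        beta=np.zeros((len(categories), F.shape[1])),
        eta=eta,
    )
    rng = np.random.default_rng(shuffle_seed) if shuffle_seed is not None else None

    converged = False
    epoch = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(y)) if rng is not None else np.arange(len(y))
        updates = 0
        for i in order:
            pred = int(np.argmax(np.sinh(model.beta) @ F[i]))
            if pred != y[i]:
                winnow_update(model, F[i], correct=int(y[i]), incorrect=pred)
                updates += 1
        if updates == 0:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Winnow did not converge within {max_epochs} epochs", stacklevel=2
        )
    model.epochs_run = epoch
    model.converged = converged
    return model


def wta_predict(single_channel_evidence: np.ndarray) -> int:
    """Winner-take-all over one channel's accumulated K-vector of evidence.

    Returns the index of the most active category (ties to the lowest index).
    This rule is defined for a single channel only; a 2-D (multi-channel)
    input is rejected.
    """
    e = np.asarray(single_channel_evidence, dtype=float)
    if e.ndim != 1:
        raise ValueError(
            "winner-take-all is defined for a single channel's K-vector; "
            f"got a {e.ndim}-D array"
        )
    if e.shape[0] < 1:
        raise ValueError("empty evidence vector")
    return int(np.argmax(e))


class LinearDecoderAdapter(Protocol):
    """Pluggable slot for an external multi-category linear classifier.

    ``fit`` consumes (features, labels) and returns per-category weight rows
    W of shape (K, D); prediction is argmax_k W[k] . f.
    """

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> np.ndarray: ...


@dataclass
class SklearnSVMAdapter:
    """Crammer–Singer multi-category linear SVM adapter (requires scikit-learn).

    The cost parameter defaults low (1e-4): after competitive normalization
    and max accumulation the evidence vectors are already highly separable,
    so little slack penalty is needed.
    """

    C: float = 1e-4
    categories: list[str] = field(default_factory=list)

    def fit(self, features: np.ndarray, labels: Sequence[str]) -> np.ndarray:
        from sklearn.svm import LinearSVC

        self.categories = sorted(set(labels))
        svc = LinearSVC(C=self.C, multi_class="crammer_singer")
        svc.fit(np.asarray(features, dtype=float), list(labels))
        order = np.argsort(svc.classes_)
        # align weight rows with sorted category order
        self.categories = [str(c) for c in np.asarray(svc.classes_)[order]]
        return svc.coef_[order]
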