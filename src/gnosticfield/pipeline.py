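"""End-to-end gnostic-field model: training, prediction, metrics, serialization.

Training composes the stages in order: fit one whitener per channel on the
pooled training features, learn one gnostic set per (category, channel) from
that category's whitened features, compute every training stimulus's
accumulated evidence vector, and fit the decoder (Balanced Winnow by default;
winner-take-all and an external linear adapter are the alternatives).  Every
random choice derives from one seed, so retraining reproduces the model
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .accumulation import MAX, accumulate_evidence, assemble_feature
from .classifiers import (
    LinearDecoderAdapter,
    WinnowModel,
    winnow_scores,
    winnow_train,
    wta_predict,
)
from .competition import CompetitionConfig, competitive_normalize
from .data_model import SPATIAL, ChannelSpec, Dataset, Stimulus, augment_locations
from .gnostic_sets import AllocationPolicy, GnosticSet, fit_gnostic_set
from .whitening import WhiteningModel, fit_whitener, identity_whitener, whiten

logger = logging.getLogger("gnosticfield")

MODEL_VERSION = "1"


@dataclass
class FieldConfig:
    """Architecture and training settings for one gnostic field."""

    whiten: bool = True
    whiten_eps: float = 1e-4        # relative to the mean covariance eigenvalue
    competition: str = "soft"       # soft | hard
    floor: float = 1e-9
    decoder: str = "winnow"         # winnow | wta | external
    alpha: float = 10.0             # unit-allocation scale
    eta: float = 0.8                # Winnow learning rate
    max_epochs: int = 500
    accumulation: str = MAX         # max | center_l2
    location_augment: bool = True   # append (x, y, 1)/|..| to spatial features
    wta_channel: str | None = None  # WTA scores this channel (default: first)
    shuffle_seed: int | None = None  # per-epoch Winnow order; None = dataset order
    seed: int = 0

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class GnosticFieldModel:
    channels: list[ChannelSpec]
    categories: list[str]
    whiteners: dict[str, WhiteningModel]
    sets: dict[tuple[str, str], GnosticSet]
    competition: CompetitionConfig
    decoder: WinnowModel | None
    external_weights: np.ndarray | None
    config: FieldConfig
    version: str = MODEL_VERSION
    _stacks: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def validate(self) -> None:
        for cat in self.categories:
            for spec in self.channels:
                if (cat, spec.channel_id) not in self.sets:
                    raise ValueError(
                        f"missing gnostic set for ({cat!r}, {spec.channel_id!r}); "
                        "one set per category and channel is required"
                    )

    def unit_stack(self, channel_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Stacked unit matrix and per-category row offsets for one channel."""
        if channel_id not in self._stacks:
            mats = [self.sets[(cat, channel_id)].units for cat in self.categories]
            offsets = np.cumsum([0] + [m.shape[0] for m in mats])[:-1]
            self._stacks[channel_id] = (np.vstack(mats), offsets)
        return self._stacks[channel_id]


def _set_seed(base_seed: int, cat_idx: int, ch_idx: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cat_idx, ch_idx))
    return int(ss.generate_state(1)[0] % (2**31))


def _stimulus_matrix(spec: ChannelSpec, stimulus: Stimulus, config: FieldConfig) -> np.ndarray:
    cd = stimulus.channels[spec.channel_id]
    X = cd.vectors
    if spec.locality == SPATIAL and config.location_augment and len(cd) > 0:
        X = augment_locations(X, cd.locations)
    return np.asarray(X, dtype=float)


def compute_evidence(model: GnosticFieldModel, stimulus: Stimulus) -> dict[str, np.ndarray]:
    """Per-channel accumulated K-vector of evidence for one stimulus."""
    K = len(model.categories)
    evidence: dict[str, np.ndarray] = {}
    for spec in model.channels:
        X = _stimulus_matrix(spec, stimulus, model.config)
        if X.shape[0] == 0:
            evidence[spec.channel_id] = np.zeros(K)
            continue
        Xw = whiten(model.whiteners[spec.channel_id], X)
        stack, offsets = model.unit_stack(spec.channel_id)
        S = Xw @ stack.T                              # (T, total units)
        A = np.maximum.reduceat(S, offsets, axis=1)   # (T, K) max-pooled per set
        R = np.stack([competitive_normalize(row, model.competition) for row in A])
        evidence[spec.channel_id] = accumulate_evidence(R, model.config.accumulation)
    return evidence


def _evidence_matrix(model: GnosticFieldModel, stimuli: Sequence[Stimulus]) -> np.ndarray:
    order = [c.channel_id for c in model.channels]
    return np.array(
        [assemble_feature(compute_evidence(model, s), order) for s in stimuli]
    )


def train_model(
    dataset: Dataset,
    config: FieldConfig | None = None,
    adapter: LinearDecoderAdapter | None = None,
) -> GnosticFieldModel:
    """Train a gnostic field on a fully labeled dataset."""
    config = config or FieldConfig()
    dataset.validate()
    if dataset.n_categories < 2:
        raise ValueError("training needs at least 2 categories")
    unlabeled = [s.stimulus_id for s in dataset.stimuli if s.label is None]
    if unlabeled:
        raise ValueError(f"unlabeled training stimuli: {unlabeled[:5]}")

    logger.info("training: seed=%d config=%s", config.seed, config.digest())
    categories = list(dataset.categories)
    policy = AllocationPolicy(alpha=config.alpha)
    competition = CompetitionConfig(mode=config.competition, floor=config.floor)

    # --- stage 1: whiteners, one per channel, on the pooled training features
    t0 = time.perf_counter()
    whiteners: dict[str, WhiteningModel] = {}
    per_stim: dict[str, list[np.ndarray]] = {}
    try:
        for spec in dataset.channels:
            mats = [_stimulus_matrix(spec, s, config) for s in dataset.stimuli]
            per_stim[spec.channel_id] = mats
            pool = np.vstack([m for m in mats if m.shape[0] > 0])
            if config.whiten:
                whiteners[spec.channel_id] = fit_whitener(
                    pool, config.whiten_eps, relative=True, channel_id=spec.channel_id
                )
            else:
                whiteners[spec.channel_id] = identity_whitener(
                    pool.shape[1], channel_id=spec.channel_id
                )
    except Exception as e:
        raise RuntimeError(f"whitening stage failed: {e}") from e
    logger.info("whitening fitted in %.2fs", time.perf_counter() - t0)

    # --- stage 2: one gnostic set per (category, channel)
    t0 = time.perf_counter()
    sets: dict[tuple[str, str], GnosticSet] = {}
    try:
        for ui, spec in enumerate(dataset.channels):
            wmodel = whiteners[spec.channel_id]
            for ci, cat in enumerate(categories):
                rows = [
                    per_stim[spec.channel_id][i]
                    for i, s in enumerate(dataset.stimuli)
                    if s.label == cat and per_stim[spec.channel_id][i].shape[0] > 0
                ]
                if not rows:
                    raise ValueError(
                        f"category {cat!r} has no features in channel {spec.channel_id!r}"
                    )
                P = whiten(wmodel, np.vstack(rows))
                P = P[np.linalg.norm(P, axis=1) > 0]  # drop degenerate rows
                sets[(cat, spec.channel_id)] = fit_gnostic_set(
                    P, cat, spec.channel_id, policy=policy,
                    seed=_set_seed(config.seed, ci, ui),
                )
    except Exception as e:
        raise RuntimeError(f"gnostic-set stage failed: {e}") from e
    logger.info("gnostic sets fitted in %.2fs", time.perf_counter() - t0)

    model = GnosticFieldModel(
        channels=list(dataset.channels),
        categories=categories,
        whiteners=whiteners,
        sets=sets,
        competition=competition,
        decoder=None,
        external_weights=None,
        config=config,
    )
    model.validate()

    # --- stage 3: decoder on the training evidence vectors
    t0 = time.perf_counter()
    try:
        if config.decoder == "winnow":
            F = _evidence_matrix(model, dataset.stimuli)
            labels = [s.label for s in dataset.stimuli]
            model.decoder = winnow_train(
                F, labels, categories=categories, eta=config.eta,
                max_epochs=config.max_epochs, shuffle_seed=config.shuffle_seed,
            )
        elif config.decoder == "wta":
            pass  # no learned weights
        elif config.decoder == "external":
            if adapter is None:
                raise ValueError("decoder='external' requires an adapter")
            F = _evidence_matrix(model, dataset.stimuli)
            labels = [s.label for s in dataset.stimuli]
            model.external_weights = np.asarray(adapter.fit(F, labels), dtype=float)
        else:
            raise ValueError(f"unknown decoder {config.decoder!r}")
    except Exception as e:
        raise RuntimeError(f"decoder stage failed: {e}") from e
    logger.info("decoder fitted in %.2fs", time.perf_counter() - t0)
    return model


def predict(
    model: GnosticFieldModel, dataset: Dataset
) -> tuple[list[str], np.ndarray]:
    """Predicted category per stimulus plus the (N, K*U) evidence matrix."""
    for spec in dataset.channels:
        if spec not in model.channels:
            raise ValueError(f"channel {spec.channel_id!r} does not match the model")
    K = len(model.categories)
    F = _evidence_matrix(model, dataset.stimuli)
    preds: list[str] = []
    if model.config.decoder == "winnow":
        if model.decoder is None:
            raise ValueError("model has no trained Winnow decoder")
        for f in F:
            preds.append(model.categories[int(np.argmax(winnow_scores(model.decoder, f)))])
    elif model.config.decoder == "wta":
        order = [c.channel_id for c in model.channels]
        ch = model.config.wta_channel or order[0]
        u = order.index(ch)
        for f in F:
            preds.append(model.categories[wta_predict(f[u * K : (u + 1) * K])])
    elif model.config.decoder == "external":
        if model.external_weights is None:
            raise ValueError("model has no external decoder weights")
        for f in F:
            preds.append(model.categories[int(np.argmax(model.external_weights @ f))])
    else:
        raise ValueError(f"unknown decoder {model.config.decoder!r}")
    return preds, F


# ---------------------------------------------------------------------------
# Metrics


def mean_per_class_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    """Mean over classes of (correct in class / total in class), in percent.

    Weighs every class equally regardless of its size — the standard metric
    for imbalanced many-category benchmarks.
    """
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("need equally sized, nonempty prediction and label lists")
    classes = sorted(set(y_true))
    accs = []
    for c in classes:
        idx = [i for i, t in enumerate(y_true) if t == c]
        accs.append(sum(y_pred[i] == c for i in idx) / len(idx))
    return 100.0 * float(np.mean(accs))


def overall_accuracy(y_true: Sequence[str], y_pred: Sequence[str]) -> float:
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("need equally sized, nonempty prediction and label lists")
    return 100.0 * float(np.mean([t == p for t, p in zip(y_true, y_pred)]))


# ---------------------------------------------------------------------------
# Serialization: one NPZ archive with arrays plus a JSON metadata string


def save_model(model: GnosticFieldModel, path: str | Path) -> None:
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for ch, w in model.whiteners.items():
        arrays[f"wh_mean__{ch}"] = w.mean
        arrays[f"wh_mat__{ch}"] = w.matrix
    for ci, cat in enumerate(model.categories):
        for ui, spec in enumerate(model.channels):
            arrays[f"units__{ci}__{ui}"] = model.sets[(cat, spec.channel_id)].units
    meta: dict[str, object] = {
        "version": model.version,
        "categories": model.categories,
        "channels": [
            {"channel_id": c.channel_id, "dim": c.dim, "locality": c.locality}
            for c in model.channels
        ],
        "whiteners": {
            ch: {"epsilon": w.epsilon, "identity_flag": w.identity_flag}
            for ch, w in model.whiteners.items()
        },
        "competition": {"mode": model.competition.mode, "floor": model.competition.floor},
        "config": asdict(model.config),
    }
    if model.decoder is not None:
        arrays["beta"] = model.decoder.beta
        meta["winnow"] = {
            "eta": model.decoder.eta,
            "epochs_run": model.decoder.epochs_run,
            "converged": model.decoder.converged,
        }
    if model.external_weights is not None:
        arrays["external_weights"] = model.external_weights
    np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> GnosticFieldModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        config = FieldConfig(**meta["config"])
        channels = [ChannelSpec(**c) for c in meta["channels"]]
        categories = list(meta["categories"])
        whiteners = {
            ch: WhiteningModel(
                channel_id=ch,
                mean=z[f"wh_mean__{ch}"],
                matrix=z[f"wh_mat__{ch}"],
                epsilon=info["epsilon"],
                identity_flag=info["identity_flag"],
            )
            for ch, info in meta["whiteners"].items()
        }
        sets = {}
        for ci, cat in enumerate(categories):
            for ui, spec in enumerate(channels):
                sets[(cat, spec.channel_id)] = GnosticSet(
                    category_id=cat,
                    channel_id=spec.channel_id,
                    units=z[f"units__{ci}__{ui}"],
                )
        decoder = None
        if "beta" in z:
            w = meta["winnow"]
            decoder = WinnowModel(
                categories=categories, beta=z["beta"], eta=w["eta"],
                epochs_run=w["epochs_run"], converged=w["converged"],
            )
        external = z["external_weights"] if "external_weights" in z else None
    model = GnosticFieldModel(
        channels=channels,
        categories=categories,
        whiteners=whiteners,
        sets=sets,
        competition=CompetitionConfig(**meta["competition"]),
        decoder=decoder,
        external_weights=external,
        config=config,
        version=meta["version"],
    )
    model.validate()
    return model
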