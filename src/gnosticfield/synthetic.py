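"""Synthetic datasets with the statistical structure the architecture assumes.

Each category, in each channel, owns a few cluster directions on the unit
sphere; a stimulus is a bag of noisy draws around its category's clusters
(normalized Gaussian perturbation of scale 1/sqrt(kappa), a von Mises-Fisher
stand-in) mixed with category-neutral background draws, tagged with grid
coordinates (spatial channels) or consecutive frame indices (temporal ones).

Two knobs make the architecture's components earn their keep: a fixed
per-channel anisotropic scaling of the raw axes (so whitening has real
decorrelation work to do) and a per-channel multiplier on kappa (so channels
differ in discriminativeness and the decoder must weight them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    SPATIAL,
    TEMPORAL,
    ChannelData,
    ChannelSpec,
    Dataset,
    Stimulus,
)


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the standard benchmark conditions.

    kappa is the concentration of the within-cluster directional spread
    (larger = tighter clusters; ``inf`` = noiseless; <= 0 degenerates to
    uniform directions, i.e. no category signal).  ``channel_snr`` multiplies
    kappa per channel; later channels default to 0.3 so they are noisier and
    less discriminative than the first.  ``distortion_condition`` is the
    condition number of a fixed random axis scaling applied per channel
    before re-normalization, emulating raw features whose variances differ
    wildly across dimensions.
    """

    K: int = 10
    U: int = 2
    d: int = 16
    clusters_per_category: int = 3
    kappa: float = 40.0
    locations_per_stimulus: int = 36
    background_fraction: float = 0.25
    n_train: int = 30
    n_test: int = 15
    channel_snr: tuple[float, ...] | None = None
    localities: tuple[str, ...] | None = None  # default: first spatial, rest temporal
    distortion_condition: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError(f"K must be >= 2, got {self.K}")
        for name in ("U", "d", "clusters_per_category", "locations_per_stimulus", "n_train"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_test < 0:
            raise ValueError(f"n_test must be >= 0, got {self.n_test}")
        if not (0.0 <= self.background_fraction < 1.0):
            raise ValueError(
                f"background_fraction must be in [0, 1), got {self.background_fraction}"
            )
        if self.channel_snr is None:
            self.channel_snr = (1.0,) + (0.3,) * (self.U - 1)
        self.channel_snr = tuple(float(s) for s in self.channel_snr)
        if len(self.channel_snr) != self.U:
            raise ValueError("channel_snr must have one entry per channel")
        if self.localities is None:
            self.localities = (SPATIAL,) + (TEMPORAL,) * (self.U - 1)
        self.localities = tuple(self.localities)
        if len(self.localities) != self.U:
            raise ValueError("localities must have one entry per channel")
        if self.distortion_condition < 1:
            raise ValueError("distortion_condition must be >= 1")


def _unit_rows(X: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(X, axis=-1, keepdims=True)
    return np.divide(X, nrm, out=np.zeros_like(X), where=nrm > 0)


def _grid_locations(n: int) -> np.ndarray:
    g = int(np.ceil(np.sqrt(n)))
    axis = np.linspace(-0.9, 0.9, g) if g > 1 else np.zeros(1)
    xx, yy = np.meshgrid(axis, axis)
    return np.column_stack([xx.ravel(), yy.ravel()])[:n]


def generate_dataset(config: SynthConfig) -> Dataset:
    """Draw a fully labeled train+test dataset, reproducible from the seed.

    Stimulus ids encode the split (``train``/``test``); downstream code
    partitions on that prefix.
    """
    rng = np.random.default_rng(config.seed)
    K, U, d, C = config.K, config.U, config.d, config.clusters_per_category
    T = config.locations_per_stimulus
    categories = [f"cat{k:02d}" for k in range(K)]
    specs = [ChannelSpec(f"ch{u}", d, config.localities[u]) for u in range(U)]

    # per-channel cluster directions and fixed anisotropic axis scaling
    means = _unit_rows(rng.standard_normal((U, K, C, d)))
    scales = np.empty((U, d))
    for u in range(U):
        s = np.geomspace(1.0, config.distortion_condition, d)
        scales[u] = rng.permutation(s)

    spatial_locs = _grid_locations(T)

    def draw_vectors(u: int, cat: int) -> np.ndarray:
        snr_kappa = config.kappa * config.channel_snr[u]
        bg = rng.random(T) < config.background_fraction
        cluster = rng.integers(C, size=T)
        X = means[u, cat, cluster]
        if np.isinf(snr_kappa):
            X = X.copy()
        elif snr_kappa > 0:
            X = X + rng.standard_normal((T, d)) / np.sqrt(snr_kappa)
        else:  # no concentration: uniform directions, no category signal
            X = rng.standard_normal((T, d))
        n_bg = int(bg.sum())
        if n_bg:
            X[bg] = rng.standard_normal((n_bg, d))
        X = _unit_rows(X * scales[u])
        return X

    stimuli: list[Stimulus] = []
    for split, count in (("train", config.n_train), ("test", config.n_test)):
        for cat in range(K):
            for i in range(count):
                chans: dict[str, ChannelData] = {}
                for u, spec in enumerate(specs):
                    X = draw_vectors(u, cat)
                    if spec.locality == SPATIAL:
                        locs: np.ndarray = spatial_locs.copy()
                    else:
                        locs = np.arange(T)
                    chans[spec.channel_id] = ChannelData(locations=locs, vectors=X)
                stimuli.append(
                    Stimulus(
                        stimulus_id=f"{split}_{categories[cat]}_{i:03d}",
                        label=categories[cat],
                        channels=chans,
                    )
                )

    ds = Dataset(channels=specs, categories=categories, stimuli=stimuli)
    ds.validate()
    return ds


def split_dataset(dataset: Dataset) -> tuple[Dataset, Dataset]:
    """Split a generated dataset into its train and test halves by id prefix."""
    train = [s for s in dataset.stimuli if s.stimulus_id.startswith("train_")]
    test = [s for s in dataset.stimuli if s.stimulus_id.startswith("test_")]
    mk = lambda stims: Dataset(
        channels=dataset.channels, categories=dataset.categories, stimuli=stims
    )
    return mk(train), mk(test)


def shuffle_labels(dataset: Dataset, seed: int) -> Dataset:
    """Permute the labels of the labeled stimuli; the label multiset is kept."""
    rng = np.random.default_rng(seed)
    labeled = [i for i, s in enumerate(dataset.stimuli) if s.label is not None]
    perm = rng.permutation(len(labeled))
    new_labels = [dataset.stimuli[labeled[j]].label for j in perm]
    stimuli = list(dataset.stimuli)
    for idx, lab in zip(labeled, new_labels):
        s = stimuli[idx]
        stimuli[idx] = Stimulus(stimulus_id=s.stimulus_id, label=lab, channels=s.channels)
    return Dataset(channels=dataset.channels, categories=dataset.categories, stimuli=stimuli)
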