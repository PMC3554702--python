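"""Domain types and dataset I/O.

A stimulus is a labeled bag of located feature vectors organized by channel.
For spatial channels (images) a location is a 2-D coordinate in [-1, 1]^2 with
the image center at (0, 0); for temporal channels (sounds, odor traces) it is a
nonnegative frame index.  Datasets live on disk as a JSON config naming the
channels plus one delimited text table per channel with columns

    stimulus_id, label, loc1, loc2, f1..fd    (spatial)
    stimulus_id, label, frame, f1..fd         (temporal)

Rows belonging to one stimulus keep their file order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

SPATIAL = "spatial"
TEMPORAL = "temporal"

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly through text


class DatasetError(ValueError):
    """Raised for malformed dataset files or inconsistent stimuli."""


@dataclass(frozen=True)
class ChannelSpec:
    """One feature modality/stream: raw dimensionality and locality kind."""

    channel_id: str
    dim: int
    locality: str

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise DatasetError(f"channel {self.channel_id!r}: dim must be >= 1, got {self.dim}")
        if self.locality not in (SPATIAL, TEMPORAL):
            raise DatasetError(
                f"channel {self.channel_id!r}: locality must be 'spatial' or 'temporal', "
                f"got {self.locality!r}"
            )


@dataclass
class ChannelData:
    """The located feature vectors of one stimulus in one channel.

    ``locations`` is (T, 2) float for spatial channels or (T,) int frame
    indices for temporal ones; ``vectors`` is (T, d).
    """

    locations: np.ndarray
    vectors: np.ndarray

    def __len__(self) -> int:
        return int(self.vectors.shape[0])


@dataclass
class LocatedFeature:
    """A single feature vector together with where (or when) it was observed."""

    location: tuple[float, float] | int
    vector: np.ndarray


@dataclass
class Stimulus:
    stimulus_id: str
    label: str | None
    channels: dict[str, ChannelData]

    def located_features(self, channel_id: str) -> Iterator[LocatedFeature]:
        cd = self.channels[channel_id]
        for loc, vec in zip(cd.locations, cd.vectors):
            if np.ndim(loc) == 0:
                yield LocatedFeature(int(loc), vec)
            else:
                yield LocatedFeature((float(loc[0]), float(loc[1])), vec)


@dataclass
class Dataset:
    channels: list[ChannelSpec]
    categories: list[str]
    stimuli: list[Stimulus]

    def validate(self) -> None:
        ids = [c.channel_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise DatasetError(f"duplicate channel ids: {ids}")
        cats = set(self.categories)
        for s in self.stimuli:
            missing = [cid for cid in ids if cid not in s.channels]
            if missing:
                raise DatasetError(f"stimulus {s.stimulus_id!r}: missing channels {missing}")
            if s.label is not None and s.label not in cats:
                raise DatasetError(
                    f"stimulus {s.stimulus_id!r}: unknown label {s.label!r}"
                )
            if all(len(s.channels[cid]) == 0 for cid in ids):
                raise DatasetError(f"stimulus {s.stimulus_id!r}: no features in any channel")
            for spec in self.channels:
                cd = s.channels[spec.channel_id]
                if cd.vectors.ndim != 2 or cd.vectors.shape[1] != spec.dim:
                    raise DatasetError(
                        f"stimulus {s.stimulus_id!r}, channel {spec.channel_id!r}: "
                        f"expected vectors of dim {spec.dim}, got shape {cd.vectors.shape}"
                    )
                if not np.all(np.isfinite(cd.vectors)):
                    raise DatasetError(
                        f"stimulus {s.stimulus_id!r}, channel {spec.channel_id!r}: "
                        "non-finite feature values"
                    )
                if spec.locality == SPATIAL and len(cd) > 0:
                    if cd.locations.shape != (len(cd), 2):
                        raise DatasetError(
                            f"stimulus {s.stimulus_id!r}, channel {spec.channel_id!r}: "
                            f"spatial locations must be (T, 2), got {cd.locations.shape}"
                        )
                    if np.any(np.abs(cd.locations) > 1.0):
                        raise DatasetError(
                            f"stimulus {s.stimulus_id!r}, channel {spec.channel_id!r}: "
                            "spatial coordinates outside [-1, 1]"
                        )

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def labels(self) -> list[str | None]:
        return [s.label for s in self.stimuli]


def frames_per_second(frame_interval_ms: float) -> float:
    """Number of feature frames per second of signal for a temporal front end.

    A 10 ms interval between successive frames yields 100 frames per second.
    """
    if frame_interval_ms <= 0:
        raise ValueError(f"frame interval must be positive, got {frame_interval_ms}")
    return 1000.0 / frame_interval_ms


def append_location_info(
    vector: np.ndarray,
    location: Sequence[float],
    include_constant: bool = True,
) -> np.ndarray:
    """Append a unit-length location block to a raw spatial feature vector.

    The block is (x, y, 1) normalized to Euclidean length 1; the constant
    component keeps the image center distinguishable from the zero vector.
    Coordinates must already be normalized by the image size to [-1, 1].
    """
    vector = np.asarray(vector, dtype=float)
    x, y = float(location[0]), float(location[1])
    if abs(x) > 1.0 or abs(y) > 1.0:
        raise ValueError(f"location ({x}, {y}) outside [-1, 1]^2")
    block = np.array([x, y, 1.0]) if include_constant else np.array([x, y])
    nrm = float(np.linalg.norm(block))
    if nrm == 0.0:
        raise ValueError("location block has zero norm; cannot normalize")
    return np.concatenate([vector, block / nrm])


def augment_locations(
    vectors: np.ndarray,
    locations: np.ndarray,
    include_constant: bool = True,
) -> np.ndarray:
    """Vectorized :func:`append_location_info` over the rows of a stimulus."""
    vectors = np.asarray(vectors, dtype=float)
    locations = np.asarray(locations, dtype=float)
    if vectors.shape[0] == 0:
        extra = 3 if include_constant else 2
        return np.empty((0, vectors.shape[1] + extra))
    if np.any(np.abs(locations) > 1.0):
        raise ValueError("spatial coordinates outside [-1, 1]")
    if include_constant:
        block = np.column_stack([locations, np.ones(len(locations))])
    else:
        block = locations.copy()
    nrm = np.linalg.norm(block, axis=1, keepdims=True)
    if np.any(nrm == 0):
        raise ValueError("location block has zero norm; cannot normalize")
    return np.hstack([vectors, block / nrm])


# ---------------------------------------------------------------------------
# Disk format


def _channel_columns(spec: ChannelSpec) -> list[str]:
    loc_cols = ["loc1", "loc2"] if spec.locality == SPATIAL else ["frame"]
    return ["stimulus_id", "label"] + loc_cols + [f"f{i + 1}" for i in range(spec.dim)]


def load_dataset(config_path: str | Path) -> Dataset:
    """Load a dataset from its JSON config and per-channel CSV tables.

    The config names each channel's id, dim, locality, and table file
    (relative paths resolve against the config's directory); an optional
    ``categories`` array fixes the category list, otherwise it is the sorted
    set of labels found in the tables.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise DatasetError(f"dataset config not found: {config_path}")
    with open(config_path) as fh:
        cfg = json.load(fh)

    specs = [
        ChannelSpec(c["channel_id"], int(c["dim"]), c["locality"]) for c in cfg["channels"]
    ]
    files = {c["channel_id"]: c["file"] for c in cfg["channels"]}

    # stimulus_id -> (label, {channel_id: ChannelData}); insertion order kept
    stim_labels: dict[str, str | None] = {}
    stim_channels: dict[str, dict[str, ChannelData]] = {}

    for spec in specs:
        fpath = config_path.parent / files[spec.channel_id]
        if not fpath.exists():
            raise DatasetError(f"feature table not found: {fpath}")
        df = pd.read_csv(
            fpath, dtype={"stimulus_id": str, "label": str},
            float_precision="round_trip",
        )
        if len(df) == 0:
            raise DatasetError(f"feature table {fpath} contains no stimuli")
        expected = _channel_columns(spec)
        if list(df.columns) != expected:
            raise DatasetError(
                f"{fpath}: expected columns {expected}, got {list(df.columns)}"
            )
        fcols = [f"f{i + 1}" for i in range(spec.dim)]
        for sid, grp in df.groupby("stimulus_id", sort=False):
            labels = grp["label"].where(grp["label"].notna(), None).unique()
            if len(labels) != 1:
                row = int(grp.index[0]) + 2  # header line + 1-based
                raise DatasetError(
                    f"{fpath} row {row}: stimulus {sid!r} has conflicting labels {list(labels)}"
                )
            label = labels[0]
            if sid in stim_labels and stim_labels[sid] != label:
                raise DatasetError(
                    f"{fpath}: stimulus {sid!r} label {label!r} conflicts with "
                    f"{stim_labels[sid]!r} from another channel"
                )
            stim_labels.setdefault(sid, label)
            vectors = grp[fcols].to_numpy(dtype=float)
            if spec.locality == SPATIAL:
                locations = grp[["loc1", "loc2"]].to_numpy(dtype=float)
            else:
                locations = grp["frame"].to_numpy(dtype=int)
            stim_channels.setdefault(sid, {})[spec.channel_id] = ChannelData(
                locations=locations, vectors=vectors
            )

    for sid, chans in stim_channels.items():
        for spec in specs:  # channels with no rows for a stimulus become empty
            if spec.channel_id not in chans:
                loc_shape = (0, 2) if spec.locality == SPATIAL else (0,)
                chans[spec.channel_id] = ChannelData(
                    locations=np.empty(loc_shape), vectors=np.empty((0, spec.dim))
                )

    if "categories" in cfg and cfg["categories"] is not None:
        categories = list(cfg["categories"])
    else:
        categories = sorted({l for l in stim_labels.values() if l is not None})

    stimuli = [
        Stimulus(stimulus_id=sid, label=stim_labels[sid], channels=stim_channels[sid])
        for sid in stim_labels
    ]
    ds = Dataset(channels=specs, categories=categories, stimuli=stimuli)
    ds.validate()
    return ds


def write_dataset(dataset: Dataset, out_dir: str | Path, name: str = "dataset") -> Path:
    """Write a dataset as ``<name>.json`` plus one CSV per channel.

    Returns the config path.  ``load_dataset(write_dataset(ds, d))`` is the
    identity on every field (float cells are printed with full precision).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = {
        "channels": [
            {
                "channel_id": c.channel_id,
                "dim": c.dim,
                "locality": c.locality,
                "file": f"{name}_{c.channel_id}.csv",
            }
            for c in dataset.channels
        ],
        "categories": dataset.categories,
    }
    for spec in dataset.channels:
        rows = []
        for s in dataset.stimuli:
            cd = s.channels[spec.channel_id]
            for t in range(len(cd)):
                row: dict[str, object] = {"stimulus_id": s.stimulus_id, "label": s.label}
                if spec.locality == SPATIAL:
                    row["loc1"] = cd.locations[t, 0]
                    row["loc2"] = cd.locations[t, 1]
                else:
                    row["frame"] = int(cd.locations[t])
                for i in range(spec.dim):
                    row[f"f{i + 1}"] = cd.vectors[t, i]
                rows.append(row)
        df = pd.DataFrame(rows, columns=_channel_columns(spec))
        df.to_csv(out_dir / f"{name}_{spec.channel_id}.csv", index=False,
                  float_format=_FLOAT_FMT)
    config_path = out_dir / f"{name}.json"
    with open(config_path, "w") as fh:
        json.dump(cfg, fh, indent=2)
    return config_path
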