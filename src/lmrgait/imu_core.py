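"""Domain types and file I/O for IMU gait trials, feature tables and models.

The package works with sagittal-plane signals from four inertial sensors
(two thigh-mounted accelerometer/gyroscope units, two foot pitch-angle
channels) sampled at 100 Hz.  Angles are expressed in degrees throughout,
accelerations in m/s² and angular rates in deg/s; time is 0-based seconds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Terrain",
    "ImuTrial",
    "AngleSet",
    "FeatureVector",
    "ConfusionMatrix",
    "LmrError",
    "SchemaError",
    "DataError",
    "LabelError",
    "ModelFormatError",
    "read_trial",
    "write_trial",
    "read_features",
    "write_features",
    "serialize_model",
    "deserialize_model",
]

MODEL_FORMAT_VERSION = "lmrgait-model-1"

TRIAL_COLUMNS = (
    "t",
    "gx_L",
    "gy_L",
    "omega_L",
    "gx_R",
    "gy_R",
    "omega_R",
    "foot_L",
    "foot_R",
)


class LmrError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LmrError):
    """A file or record does not conform to the expected schema."""


class DataError(LmrError):
    """Numeric content violates an invariant (e.g. non-monotone time)."""


class LabelError(LmrError):
    """A terrain/class label lies outside the defined label set."""


class ModelFormatError(LmrError):
    """A serialized model file is corrupt or has an unknown version."""


class Terrain(IntEnum):
    """The five terrain classes, numbered 1-5.

    LW = level walking, SA/SD = stair ascent/descent,
    RA/RD = ramp ascent/descent.
    """

    LW = 1
    SA = 2
    SD = 3
    RA = 4
    RD = 5


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise SchemaError(f"channel {name!r} must be 1-D, got shape {arr.shape}")
    return arr


@dataclass
class ImuTrial:
    """One walking trial: raw multichannel IMU time series plus metadata.

    Channels per side (L/R): ``gx``/``gy`` thigh accelerometer components
    in m/s² (sagittal axes, gravity along +x when the thigh is vertical),
    ``omega`` thigh angular rate in deg/s, ``foot`` foot pitch angle in
    degrees (toe-up positive).
    """

    trial_id: str
    terrain: Terrain
    bpm: int
    fs: float
    t: np.ndarray
    gx_L: np.ndarray
    gy_L: np.ndarray
    omega_L: np.ndarray
    gx_R: np.ndarray
    gy_R: np.ndarray
    omega_R: np.ndarray
    foot_L: np.ndarray
    foot_R: np.ndarray

    def __post_init__(self) -> None:
        try:
            self.terrain = Terrain(int(self.terrain))
        except ValueError as exc:
            raise LabelError(f"unknown terrain code {self.terrain!r}") from exc
        if not (isinstance(self.bpm, (int, np.integer)) and self.bpm > 0):
            raise DataError(f"bpm must be a positive integer, got {self.bpm!r}")
        self.bpm = int(self.bpm)
        self.fs = float(self.fs)
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        for name in ("t",) + tuple(c for c in TRIAL_COLUMNS if c != "t"):
            setattr(self, name, _as_1d_float(getattr(self, name), name))
        n = len(self.t)
        if n < 2:
            raise DataError("trial channels must have length >= 2")
        for name in TRIAL_COLUMNS:
            if len(getattr(self, name)) != n:
                raise DataError(
                    f"channel {name!r} has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise DataError("time vector must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.fs)) > 1e-9:
            raise DataError(
                f"time vector spacing deviates from 1/fs = {1.0 / self.fs}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in TRIAL_COLUMNS}


@dataclass
class AngleSet:
    """Estimated hip angles and conditioned foot pitch angles on one clock.

    Hip flexion is positive; foot pitch is toe-up positive. All series are
    the same length and contain only finite values.
    """

    t: np.ndarray
    theta_hip_L: np.ndarray
    theta_hip_R: np.ndarray
    theta_foot_L: np.ndarray
    theta_foot_R: np.ndarray

    def __post_init__(self) -> None:
        names = ("t", "theta_hip_L", "theta_hip_R", "theta_foot_L", "theta_foot_R")
        for name in names:
            setattr(self, name, _as_1d_float(getattr(self, name), name))
        n = len(self.t)
        for name in names:
            arr = getattr(self, name)
            if len(arr) != n:
                raise DataError(f"series {name!r} length mismatch")
            if not np.all(np.isfinite(arr)):
                raise DataError(f"series {name!r} contains non-finite values")


@dataclass
class FeatureVector:
    """One stride's terrain-discriminative features.

    pc1: hip amplitude (max flexion minus the opposite hip at that instant),
    degrees.  pc2: rectified foot-pitch integral over the stride segment,
    degree-seconds.  pc3: common foot pitch at the parallel-feet instant,
    degrees; NaN when the feet never come within tolerance of parallel.
    """

    pc1: float
    pc2: float
    pc3: float
    label: Terrain
    stride_index: int = 0
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.pc1 = float(self.pc1)
        self.pc2 = float(self.pc2)
        self.pc3 = float(self.pc3)
        if not (np.isfinite(self.pc1) and np.isfinite(self.pc2)):
            raise DataError("pc1 and pc2 must be finite")
        try:
            self.label = Terrain(int(self.label))
        except ValueError as exc:
            raise LabelError(f"unknown terrain label {self.label!r}") from exc

    @property
    def has_pc3(self) -> bool:
        return bool(np.isfinite(self.pc3))


@dataclass
class ConfusionMatrix:
    """K x K count grid indexed (actual, predicted)."""

    counts: np.ndarray
    class_labels: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_labels = list(self.class_labels)
        k = len(self.class_labels)
        if self.counts.shape != (k, k):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{k} class labels"
            )
        if np.any(self.counts < 0):
            raise DataError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dict(self) -> dict:
        return {
            "class_labels": [int(c) for c in self.class_labels],
            "counts": self.counts.tolist(),
        }


# ---------------------------------------------------------------------------
# Trial CSV I/O
#
# Format: four comment header lines (# trial_id=, # terrain=, # bpm=,
# # fs=), then a CSV with the columns in TRIAL_COLUMNS, floats written in
# round-trip precision so read(write(x)) == x bit-for-bit.
# ---------------------------------------------------------------------------


def write_trial(trial: ImuTrial, path: str | Path) -> None:
    """Write a trial to a self-describing CSV file (see module docs)."""
    path = Path(path)
    lines = [
        f"# trial_id={trial.trial_id}",
        f"# terrain={int(trial.terrain)}",
        f"# bpm={trial.bpm}",
        f"# fs={trial.fs!r}",
        ",".join(TRIAL_COLUMNS),
    ]
    cols = [getattr(trial, name) for name in TRIAL_COLUMNS]
    for row in zip(*cols):
        lines.append(",".join(repr(float(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_trial(path: str | Path) -> ImuTrial:
    """Read a trial CSV written by :func:`write_trial` and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    for key in ("trial_id", "terrain", "bpm", "fs"):
        if key not in meta:
            raise SchemaError(f"trial file {path} lacks header field {key!r}")
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"trial file {path} lacks column {col!r}")
    terrain_code = int(meta["terrain"])
    if terrain_code not in set(int(v) for v in Terrain):
        raise LabelError(f"unknown terrain code {terrain_code} in {path}")
    return ImuTrial(
        trial_id=meta["trial_id"],
        terrain=Terrain(terrain_code),
        bpm=int(meta["bpm"]),
        fs=float(meta["fs"]),
        **{name: df[name].to_numpy(dtype=float) for name in TRIAL_COLUMNS},
    )


# ---------------------------------------------------------------------------
# Feature table CSV I/O
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ("trial_id", "stride_index", "pc1", "pc2", "pc3", "label")


def write_features(features: Sequence[FeatureVector], path: str | Path) -> None:
    """Write feature vectors to CSV (missing pc3 becomes an empty field)."""
    rows = []
    for fv in features:
        rows.append(
            {
                "trial_id": fv.trial_id,
                "stride_index": fv.stride_index,
                "pc1": repr(fv.pc1),
                "pc2": repr(fv.pc2),
                "pc3": repr(fv.pc3) if fv.has_pc3 else "",
                "label": int(fv.label),
            }
        )
    pd.DataFrame(rows, columns=list(FEATURE_COLUMNS)).to_csv(path, index=False)


def read_features(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"feature table {path} lacks column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            FeatureVector(
                pc1=float(row["pc1"]),
                pc2=float(row["pc2"]),
                pc3=float(row["pc3"]) if np.isfinite(row["pc3"]) else np.nan,
                label=Terrain(int(row["label"])),
                stride_index=int(row["stride_index"]),
                trial_id=str(row["trial_id"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Model JSON serialization
# ---------------------------------------------------------------------------


def _check_spd(cov: np.ndarray, where: str) -> None:
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise DataError(f"covariance in {where} is not symmetric")
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DataError(
            f"covariance in {where} is not positive definite"
        ) from exc


def serialize_model(model, path: str | Path) -> None:
    """Write a fitted two-layer recognizer to JSON.

    Refuses to serialize a model whose covariances are not symmetric
    positive definite; such a model could not have come from a valid fit.
    """
    payload = {"format_version": MODEL_FORMAT_VERSION}
    for layer_name, gmm, comp_map, scaler in (
        ("layer1", model.layer1, model.map1, model.scaler1),
        ("layer2", model.layer2, model.map2, model.scaler2),
    ):
        for i, comp in enumerate(gmm.components):
            _check_spd(np.asarray(comp.cov), f"{layer_name} component {i}")
        payload[layer_name] = {
            "weights": [float(c.weight) for c in gmm.components],
            "means": [np.asarray(c.mean, dtype=float).tolist() for c in gmm.components],
            "covariances": [
                np.asarray(c.cov, dtype=float).ravel().tolist()
                for c in gmm.components
            ],
            "d": int(gmm.d),
            "component_to_class": {str(k): int(v) for k, v in comp_map.items()},
            "scaler": {
                "means": np.asarray(scaler.means, dtype=float).tolist(),
                "sds": np.asarray(scaler.sds, dtype=float).tolist(),
            },
        }
    Path(path).write_text(json.dumps(payload, indent=1))


def deserialize_model(path: str | Path):
    """Read a model written by :func:`serialize_model`."""
    from .features import FeatureScaler
    from .gmm_em import GaussianComponent, GmmModel
    from .lmr_pipeline import LmrModel

    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"model file {path} has version {version!r}, "
            f"expected {MODEL_FORMAT_VERSION!r}"
        )
    layers = {}
    for layer_name in ("layer1", "layer2"):
        if layer_name not in payload:
            raise ModelFormatError(f"model file {path} lacks {layer_name}")
        spec = payload[layer_name]
        d = int(spec["d"])
        comps = [
            GaussianComponent(
                weight=w,
                mean=np.asarray(m, dtype=float),
                cov=np.asarray(c, dtype=float).reshape(d, d),
            )
            for w, m, c in zip(spec["weights"], spec["means"], spec["covariances"])
        ]
        layers[layer_name] = (
            GmmModel(components=comps),
            {int(k): int(v) for k, v in spec["component_to_class"].items()},
            FeatureScaler(
                means=np.asarray(spec["scaler"]["means"], dtype=float),
                sds=np.asarray(spec["scaler"]["sds"], dtype=float),
            ),
        )
    gmm1, map1, scaler1 = layers["layer1"]
    gmm2, map2, scaler2 = layers["layer2"]
    return LmrModel(
        layer1=gmm1, map1=map1, scaler1=scaler1,
        layer2=gmm2, map2=map2, scaler2=scaler2,
    )
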