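"""Stride segmentation at hip cross-points and the three gait features.

Strides are delimited by hip cross-points (HCPs): the instants where the
left and right hip-angle trajectories cross.  Per HCP-to-HCP segment three
scalar features are computed:

* ``pc1`` (degrees): peak hip flexion minus the opposite hip's angle at
  that same instant — the inter-hip amplitude, largest on stair ascent.
* ``pc2`` (degree-seconds): the rectified (positive-part) foot pitch
  integral of both feet over the segment.
* ``pc3`` (degrees): the common foot pitch where the two foot-pitch
  curves are closest to parallel within the single-support portion of the
  segment; on ramps this sits near the ground slope, on level ground near
  zero.  Missing (NaN) when the feet never come within tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .imu_core import AngleSet, DataError, FeatureVector, Terrain
from .preprocess import MAD_SCALE

__all__ = [
    "StrideSegment",
    "FeatureScaler",
    "detect_hcp",
    "segment_strides",
    "compute_pc1",
    "compute_pc2",
    "compute_pc3",
    "filter_feature_outliers",
    "fit_scaler",
    "apply_scaler",
    "extract_features",
]

#: fraction of the nominal step period below which two HCPs are merged
HCP_DEBOUNCE_FRACTION = 0.3

#: strides shorter than this many samples are rejected as spurious
MIN_STRIDE_SAMPLES = 2

#: central portion of a segment searched for the parallel-feet instant
PC3_CENTRAL_WINDOW = (0.2, 0.8)

#: feet further apart than this (degrees) never count as parallel
PC3_TOLERANCE_DEG = 10.0


@dataclass
class StrideSegment:
    """Half-open sample range [hcp1_index, hcp2_index) of one stride."""

    hcp1_index: int
    hcp2_index: int
    leading_side: str | None = None

    def __post_init__(self) -> None:
        if self.hcp2_index <= self.hcp1_index + MIN_STRIDE_SAMPLES:
            raise DataError(
                f"segment [{self.hcp1_index}, {self.hcp2_index}) is too short"
            )
        if self.leading_side not in (None, "L", "R"):
            raise DataError(f"leading_side must be L/R, got {self.leading_side!r}")

    def __len__(self) -> int:
        return self.hcp2_index - self.hcp1_index


@dataclass
class FeatureScaler:
    """Per-dimension z-score statistics fit on training data only."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if np.any(self.sds <= 0):
            raise DataError("scaler SDs must be strictly positive")


def detect_hcp(
    theta_hip_L: np.ndarray,
    theta_hip_R: np.ndarray,
    fs: float,
    bpm: int,
) -> list[int]:
    """Sample indices where the hip-angle difference changes sign.

    Each crossing is linearly interpolated between the bracketing samples
    and snapped to the nearest sample index.  Crossings closer than
    ``HCP_DEBOUNCE_FRACTION`` of the nominal step period (60/bpm seconds)
    to the previously accepted one are discarded, which suppresses
    noise-induced double crossings.  Returns a sorted (possibly empty)
    list.
    """
    theta_hip_L = np.asarray(theta_hip_L, dtype=float)
    theta_hip_R = np.asarray(theta_hip_R, dtype=float)
    if theta_hip_L.shape != theta_hip_R.shape:
        raise DataError("hip series must have equal length")
    d = theta_hip_L - theta_hip_R
    nz = np.flatnonzero(d != 0.0)
    if len(nz) < 2:
        return []
    signs = np.sign(d[nz])
    flips = np.flatnonzero(signs[:-1] != signs[1:])
    crossings = []
    for j in flips:
        i0, i1 = nz[j], nz[j + 1]
        frac = d[i0] / (d[i0] - d[i1])
        crossings.append(int(round(i0 + frac * (i1 - i0))))
    min_gap = HCP_DEBOUNCE_FRACTION * (60.0 / bpm) * fs
    kept: list[int] = []
    for c in sorted(crossings):
        if not kept or c - kept[-1] >= min_gap:
            kept.append(c)
    return kept


def segment_strides(hcp_indices: Sequence[int]) -> list[StrideSegment]:
    """Consecutive HCP pairs become stride segments.

    Partial cycles before the first HCP and after the last are discarded;
    fewer than two HCPs yield no segments.
    """
    hcps = sorted(int(i) for i in hcp_indices)
    segments = []
    for a, b in zip(hcps[:-1], hcps[1:]):
        if b > a + MIN_STRIDE_SAMPLES:
            segments.append(StrideSegment(a, b))
    return segments


def compute_pc1(
    theta_hip_L: np.ndarray, theta_hip_R: np.ndarray, seg: StrideSegment
) -> float:
    """Peak hip flexion minus the opposite hip's angle at the same instant."""
    sl = slice(seg.hcp1_index, seg.hcp2_index)
    hl = np.asarray(theta_hip_L, dtype=float)[sl]
    hr = np.asarray(theta_hip_R, dtype=float)[sl]
    stacked = np.stack([hl, hr])
    side, idx = np.unravel_index(np.argmax(stacked), stacked.shape)
    opposite = stacked[1 - side, idx]
    return float(stacked[side, idx] - opposite)


def compute_pc2(
    theta_foot_L: np.ndarray,
    theta_foot_R: np.ndarray,
    seg: StrideSegment,
    fs: float,
) -> float:
    """Rectified foot-pitch integral of both feet over the segment (deg·s)."""
    lo, hi = seg.hcp1_index, min(seg.hcp2_index, len(theta_foot_L) - 1)
    dx = 1.0 / fs
    total = 0.0
    for foot in (theta_foot_L, theta_foot_R):
        y = np.clip(np.asarray(foot, dtype=float)[lo : hi + 1], 0.0, None)
        total += float(np.trapezoid(y, dx=dx))
    return total


def compute_pc3(
    theta_foot_L: np.ndarray,
    theta_foot_R: np.ndarray,
    seg: StrideSegment,
    tolerance: float = PC3_TOLERANCE_DEG,
) -> float:
    """Common foot pitch at the parallel-feet instant, or NaN if none.

    The search is restricted to the central 20-80 % of the segment as a
    single-support proxy; the instant minimizing the inter-foot difference
    is taken, and the mean of the two foot angles there is returned.  If
    even the closest approach exceeds ``tolerance`` degrees the feature is
    reported missing (NaN).
    """
    n = len(seg)
    lo = seg.hcp1_index + int(np.ceil(PC3_CENTRAL_WINDOW[0] * n))
    hi = seg.hcp1_index + int(np.floor(PC3_CENTRAL_WINDOW[1] * n))
    hi = max(hi, lo + 1)
    fl = np.asarray(theta_foot_L, dtype=float)[lo:hi]
    fr = np.asarray(theta_foot_R, dtype=float)[lo:hi]
    diff = np.abs(fl - fr)
    j = int(np.argmin(diff))
    if diff[j] > tolerance:
        return float("nan")
    return float(0.5 * (fl[j] + fr[j]))


def _feature_matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    return np.array([[f.pc1, f.pc2, f.pc3] for f in features], dtype=float)


def filter_feature_outliers(
    features: Sequence[FeatureVector], factor: float = 2.0
) -> list[FeatureVector]:
    """Drop feature vectors far from their terrain-class median.

    Within each terrain class and each feature dimension, a vector is an
    outlier iff ``|x - median| > factor * 1.4826 * MAD`` (strict, so an
    all-identical class keeps everything); a vector is dropped when any
    finite dimension violates.  Missing pc3 values neither violate nor
    contribute to the statistics.  If filtering would leave a class with
    fewer than two vectors the class is kept unfiltered with a warning.
    """
    by_class: dict[Terrain, list[int]] = {}
    for i, fv in enumerate(features):
        by_class.setdefault(fv.label, []).append(i)
    keep = np.ones(len(features), dtype=bool)
    for label, idx in by_class.items():
        X = _feature_matrix([features[i] for i in idx])
        bad = np.zeros(len(idx), dtype=bool)
        for dim in range(X.shape[1]):
            col = X[:, dim]
            finite = np.isfinite(col)
            if finite.sum() < 3:
                continue
            med = np.median(col[finite])
            mad = np.median(np.abs(col[finite] - med))
            viol = np.abs(col - med) > factor * MAD_SCALE * mad
            bad |= viol & finite
        if len(idx) - int(bad.sum()) < 2:
            warnings.warn(
                f"outlier filter would leave class {label.name} with fewer "
                "than 2 vectors; class kept unfiltered",
                stacklevel=2,
            )
            continue
        for j, i in enumerate(idx):
            if bad[j]:
                keep[i] = False
    return [fv for i, fv in enumerate(features) if keep[i]]


def fit_scaler(X: np.ndarray) -> FeatureScaler:
    """Fit per-dimension z-score statistics (population SD) on training data."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DataError("scaler requires at least 2 training vectors")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        dim = int(np.argmax(sds == 0))
        raise DataError(f"feature dimension {dim} has zero variance")
    return FeatureScaler(means=X.mean(axis=0), sds=sds)


def apply_scaler(scaler: FeatureScaler, X: np.ndarray) -> np.ndarray:
    """Z-score using the scaler's stored training statistics only."""
    X = np.asarray(X, dtype=float)
    return (X - scaler.means) / scaler.sds


def extract_features(
    angles: AngleSet,
    terrain: Terrain,
    fs: float,
    bpm: int,
    trial_id: str = "",
    pc3_tolerance: float = PC3_TOLERANCE_DEG,
) -> list[FeatureVector]:
    """Segment a trial's angle set into strides and compute all features.

    Strides with missing pc3 are retained (the first classifier layer does
    not need pc3); downstream consumers exclude them where pc3 is required.
    """
    hcps = detect_hcp(angles.theta_hip_L, angles.theta_hip_R, fs, bpm)
    segments = segment_strides(hcps)
    if not segments:
        warnings.warn(f"no strides found in trial {trial_id!r}", stacklevel=2)
        return []
    out = []
    for k, seg in enumerate(segments):
        sl = slice(seg.hcp1_index, seg.hcp2_index)
        seg.leading_side = (
            "L"
            if np.max(angles.theta_hip_L[sl]) >= np.max(angles.theta_hip_R[sl])
            else "R"
        )
        out.append(
            FeatureVector(
                pc1=compute_pc1(angles.theta_hip_L, angles.theta_hip_R, seg),
                pc2=compute_pc2(angles.theta_foot_L, angles.theta_foot_R, seg, fs),
                pc3=compute_pc3(
                    angles.theta_foot_L, angles.theta_foot_R, seg,
                    tolerance=pc3_tolerance,
                ),
                label=terrain,
                stride_index=k,
                trial_id=trial_id,
            )
        )
    return out
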