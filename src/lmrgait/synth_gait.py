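"""Seeded parametric gait simulator with ground truth.

The simulator emits per-trial IMU channels that are mutually consistent
with a known hip/foot angle trajectory, so every downstream stage can be
checked against truth:

* Hip angles are antiphase raised-cosine waves: left hip
  ``offset + A cos(2 pi t / T)``, right hip the mirror image, with stride
  period ``T = 120 / bpm`` seconds (one stride = two metronome beats).
  Hip cross-points therefore fall at T/4 + k T/2 exactly.
* Foot pitch is a ground-slope baseline plus a raised-cosine swing
  excursion occupying 40 % of the stride, legs half a stride apart; in
  the double-support windows both feet dwell at the slope, which is what
  the parallel-feet feature (pc3) reads out.
* Channels are rendered by inverting the estimation model: accelerometer
  ``g_x = 9.81 cos(theta)``, ``g_y = 9.81 sin(theta)`` (so the tilt angle
  reconstructs theta exactly at zero noise), gyroscope = the analytic
  d(theta)/dt plus a slowly growing bias, feet = the waveform itself.
  Gaussian noise and gyro bias drift are added per the noise spec.

Terrain profiles: stair ascent demands markedly more hip flexion, stair
descent much less hip motion with a toe-down swing; ramps shift the foot
baseline by the ground slope (+/- 5.9 degrees, a standard wheelchair-ramp
grade).  The stair excursion scale is derived from a 0.3 m deep x 0.18 m
high step (incline atan(0.18/0.3) ~ 31 degrees).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .imu_core import AngleSet, DataError, ImuTrial, Terrain

__all__ = [
    "TerrainProfile",
    "NoiseSpec",
    "GroundTruth",
    "DEFAULT_PROFILES",
    "STAIR_DEPTH_M",
    "STAIR_RISE_M",
    "RAMP_SLOPE_DEG",
    "generate_trial",
    "generate_dataset",
    "expected_features",
]

GRAVITY = 9.81  # m/s^2
DEFAULT_FS = 100.0  # Hz

RAMP_SLOPE_DEG = 5.9
STAIR_DEPTH_M = 0.3
STAIR_RISE_M = 0.18
#: effective incline of the stair nosing line, degrees
STAIR_INCLINE_DEG = math.degrees(math.atan2(STAIR_RISE_M, STAIR_DEPTH_M))

#: fraction of the stride each foot spends in swing
SWING_FRACTION = 0.4
#: stride phase at which the left foot's swing begins (right is +0.5)
SWING_ONSET = 0.55


@dataclass(frozen=True)
class TerrainProfile:
    """Waveform parameters of one terrain's gait pattern."""

    hip_amplitude: float  # degrees, half peak-to-peak hip excursion
    hip_offset: float  # degrees, mean hip flexion
    foot_baseline_amplitude: float  # degrees, swing excursion (sign = toe dir)
    ground_slope: float  # degrees, stance dwell level
    stance_toe_down_bias: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if self.hip_amplitude <= 0:
            raise DataError("hip_amplitude must be positive")
        if self.foot_baseline_amplitude == 0:
            raise DataError("foot_baseline_amplitude must be nonzero")


DEFAULT_PROFILES: dict[Terrain, TerrainProfile] = {
    Terrain.LW: TerrainProfile(
        hip_amplitude=20.0, hip_offset=5.0,
        foot_baseline_amplitude=15.0, ground_slope=0.0,
    ),
    Terrain.SA: TerrainProfile(
        hip_amplitude=20.0 + STAIR_INCLINE_DEG / 2.0, hip_offset=10.0,
        foot_baseline_amplitude=20.0, ground_slope=0.0,
    ),
    Terrain.SD: TerrainProfile(
        hip_amplitude=12.0, hip_offset=0.0,
        foot_baseline_amplitude=-0.8 * STAIR_INCLINE_DEG, ground_slope=0.0,
    ),
    Terrain.RA: TerrainProfile(
        hip_amplitude=20.0, hip_offset=7.0,
        foot_baseline_amplitude=15.0, ground_slope=+RAMP_SLOPE_DEG,
    ),
    Terrain.RD: TerrainProfile(
        hip_amplitude=20.0, hip_offset=3.0,
        foot_baseline_amplitude=15.0, ground_slope=-RAMP_SLOPE_DEG,
    ),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise model; all SDs may be zero for noise-free rendering."""

    accel_sd: float = 0.3  # m/s^2
    gyro_sd: float = 1.0  # deg/s
    gyro_bias_drift: float = 0.5  # deg/s accrued per minute
    foot_angle_sd: float = 0.5  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accel_sd", "gyro_sd", "gyro_bias_drift", "foot_angle_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be nonnegative")


ZERO_NOISE = NoiseSpec(accel_sd=0.0, gyro_sd=0.0, gyro_bias_drift=0.0,
                       foot_angle_sd=0.0)


@dataclass
class GroundTruth:
    """What the simulator actually generated, for oracle-style checks."""

    angles: AngleSet
    hcp_indices: list[int]
    expected_pc: tuple[float, float, float]
    profile: TerrainProfile = field(default=None)  # type: ignore[assignment]


def _swing_bump(u: np.ndarray) -> np.ndarray:
    """Raised-cosine swing excursion as a function of stride phase u in [0,1)."""
    v = (u - SWING_ONSET) % 1.0
    inside = v < SWING_FRACTION
    out = np.zeros_like(u)
    out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * v[inside] / SWING_FRACTION))
    return out


def _foot_waveform(u: np.ndarray, profile: TerrainProfile) -> np.ndarray:
    return (
        profile.ground_slope
        + profile.stance_toe_down_bias
        + profile.foot_baseline_amplitude * _swing_bump(u)
    )


def generate_trial(
    terrain: Terrain | int,
    bpm: int,
    n_strides: int,
    profile: TerrainProfile | None = None,
    noise: NoiseSpec | None = None,
    fs: float = DEFAULT_FS,
    trial_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ImuTrial, GroundTruth]:
    """Render one walking trial and return it with its ground truth.

    The trial spans exactly ``n_strides`` stride periods of T = 120/bpm
    seconds.  Randomness comes from ``rng`` if given, else from
    ``noise.seed``.
    """
    terrain = Terrain(int(terrain))
    if n_strides < 1:
        raise DataError("n_strides must be >= 1")
    profile = profile or DEFAULT_PROFILES[terrain]
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng(noise.seed)

    T = 120.0 / bpm
    n = int(round(n_strides * T * fs))
    t = np.arange(n) / fs
    w = 2.0 * np.pi / T

    hip_L = profile.hip_offset + profile.hip_amplitude * np.cos(w * t)
    hip_R = profile.hip_offset - profile.hip_amplitude * np.cos(w * t)
    omega_L_true = -profile.hip_amplitude * w * np.sin(w * t)
    omega_R_true = +profile.hip_amplitude * w * np.sin(w * t)

    u = (t / T) % 1.0
    foot_L_true = _foot_waveform(u, profile)
    foot_R_true = _foot_waveform((u + 0.5) % 1.0, profile)

    bias = noise.gyro_bias_drift * (t / 60.0)

    def accel(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rad = np.radians(theta)
        gx = GRAVITY * np.cos(rad) + rng.normal(0.0, noise.accel_sd, n)
        gy = GRAVITY * np.sin(rad) + rng.normal(0.0, noise.accel_sd, n)
        return gx, gy

    gx_L, gy_L = accel(hip_L)
    gx_R, gy_R = accel(hip_R)
    omega_L = omega_L_true + bias + rng.normal(0.0, noise.gyro_sd, n)
    omega_R = omega_R_true + bias + rng.normal(0.0, noise.gyro_sd, n)
    foot_L = foot_L_true + rng.normal(0.0, noise.foot_angle_sd, n)
    foot_R = foot_R_true + rng.normal(0.0, noise.foot_angle_sd, n)

    if trial_id is None:
        trial_id = f"{terrain.name}_bpm{bpm}_s{n_strides}"
    trial = ImuTrial(
        trial_id=trial_id, terrain=terrain, bpm=int(bpm), fs=fs, t=t,
        gx_L=gx_L, gy_L=gy_L, omega_L=omega_L,
        gx_R=gx_R, gy_R=gy_R, omega_R=omega_R,
        foot_L=foot_L, foot_R=foot_R,
    )

    # Hip trajectories cross where cos(w t) = 0: t = (0.25 + 0.5 k) T.
    hcps = []
    k = 0
    while True:
        idx = int(round((0.25 + 0.5 * k) * T * fs))
        if idx >= n:
            break
        hcps.append(idx)
        k += 1

    truth = GroundTruth(
        angles=AngleSet(
            t=t, theta_hip_L=hip_L, theta_hip_R=hip_R,
            theta_foot_L=foot_L_true, theta_foot_R=foot_R_true,
        ),
        hcp_indices=hcps,
        expected_pc=expected_features(profile, bpm),
        profile=profile,
    )
    return trial, truth


def expected_features(
    profile: TerrainProfile, bpm: int
) -> tuple[float, float, float]:
    """Noise-free feature expectations of one stride under a profile.

    pc1 = 2 * hip_amplitude (the antiphase hips meet peak-against-trough);
    pc2 = positive-part integral of one foot's waveform over a full stride
    (equals the both-feet half-stride segment integral by symmetry),
    evaluated by adaptive quadrature of the continuous waveform;
    pc3 = the stance dwell level (slope + bias).
    """
    T = 120.0 / bpm
    pc1 = 2.0 * profile.hip_amplitude

    def integrand(u: float) -> float:
        val = _foot_waveform(np.array([u]), profile)[0]
        return max(val, 0.0)

    # Integrate in phase; split at the swing window edges where the
    # waveform has kinks so quadrature converges cleanly.
    edges = sorted({0.0, SWING_ONSET, (SWING_ONSET + SWING_FRACTION) % 1.0, 1.0})
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        total += quad(integrand, a, b, limit=200)[0]
    pc2 = T * total

    pc3 = profile.ground_slope + profile.stance_toe_down_bias
    return float(pc1), float(pc2), float(pc3)


def generate_dataset(
    bpm: int = 110,
    strides_per_terrain: int = 40,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    profiles: dict[Terrain, TerrainProfile] | None = None,
    fs: float = DEFAULT_FS,
) -> tuple[list[ImuTrial], pd.DataFrame]:
    """One trial per terrain, deterministic under ``seed``.

    Returns the five trials and a truth table of per-terrain expected
    feature values.  Per-trial random substreams are spawned from the
    single seed, so the dataset is bit-reproducible.
    """
    noise = noise or NoiseSpec()
    profiles = profiles or DEFAULT_PROFILES
    streams = np.random.SeedSequence(seed).spawn(len(profiles))
    trials = []
    rows = []
    for (terrain, profile), stream in zip(sorted(profiles.items()), streams):
        trial, truth = generate_trial(
            terrain, bpm, strides_per_terrain,
            profile=profile, noise=noise, fs=fs,
            rng=np.random.default_rng(stream),
        )
        trials.append(trial)
        pc1, pc2, pc3 = truth.expected_pc
        rows.append(
            {"terrain": int(terrain), "terrain_name": terrain.name,
             "expected_pc1": pc1, "expected_pc2": pc2, "expected_pc3": pc3,
             "n_strides": strides_per_terrain, "bpm": bpm}
        )
    return trials, pd.DataFrame(rows)
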