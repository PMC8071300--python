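"""Signal conditioning: thigh IMU channels to estimated hip angles.

The hip angle is not measured directly.  It is estimated by fusing two
noisy views of thigh orientation: the tilt angle implied by the gravity
vector in the accelerometer (reliable at low frequency, noisy during
swing) and the integral of the gyroscope rate (smooth, but drifts).  A
complementary filter blends them with weight ``alpha`` on the gyro path;
the residual drift is removed as a linear trend, and local quadratic
(loess) smoothing suppresses what noise leaks through the accelerometer
path.  Foot pitch channels come from orientation-filtered sensors and only
need robust outlier rejection (scaled-MAD median rule) plus a short moving
average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .imu_core import AngleSet, DataError, ImuTrial, LmrError

__all__ = [
    "PreprocessConfig",
    "DegenerateGravityError",
    "AllOutliersError",
    "accel_angle",
    "gyro_angle",
    "complementary_blend",
    "complementary_recursive",
    "detrend_linear",
    "smooth_loess",
    "smooth_movmean",
    "remove_signal_outliers",
    "estimate_hip_angles",
]

MAD_SCALE = 1.4826  # scaled MAD ≈ SD for Gaussian data (MATLAB "median" rule)


class DegenerateGravityError(LmrError):
    """Both accelerometer components are zero at some sample."""


class AllOutliersError(LmrError):
    """Every sample of a series was flagged as an outlier."""


@dataclass
class PreprocessConfig:
    """Tunable parameters of the signal-conditioning stage.

    alpha: complementary-filter weight on the gyro path, in [0, 1].
    outlier_threshold: scaled-MAD multiple for the median outlier rule
        (1.0 for a pooled multi-subject model, 2.0 for per-subject models).
    loess_span: fraction of the series length used as the local quadratic
        smoothing window for hip angles.
    movmean_window: centered moving-average window (odd samples) for the
        foot pitch channels.
    recursive_filter: use the per-sample recursive complementary filter
        instead of the whole-trial blend-then-detrend form.
    outlier_on_hip: also apply the median outlier rule to hip estimates.
    """

    alpha: float = 0.99
    outlier_threshold: float = 1.0
    loess_span: float = 0.02
    movmean_window: int = 11
    recursive_filter: bool = False
    outlier_on_hip: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise DataError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.outlier_threshold <= 0:
            raise DataError("outlier_threshold must be positive")
        if not 0.0 < self.loess_span <= 1.0:
            raise DataError("loess_span must be in (0, 1]")
        w = self.movmean_window
        if not (isinstance(w, (int, np.integer)) and w > 0 and w % 2 == 1):
            raise DataError("movmean_window must be an odd positive integer")


def accel_angle(g_x: np.ndarray, g_y: np.ndarray) -> np.ndarray:
    """Thigh tilt angle from the accelerometer, degrees in (-180, 180].

    Four-quadrant arctangent of g_y against g_x; with the convention that
    gravity lies along +x for a vertical thigh, this is the sagittal thigh
    angle.
    """
    g_x = np.asarray(g_x, dtype=float)
    g_y = np.asarray(g_y, dtype=float)
    if g_x.shape != g_y.shape:
        raise DataError("accelerometer components must have equal length")
    zero = (g_x == 0.0) & (g_y == 0.0)
    if np.any(zero):
        raise DegenerateGravityError(
            f"zero gravity vector at sample {int(np.argmax(zero))}"
        )
    theta = np.degrees(np.arctan2(g_y, g_x))
    theta[theta <= -180.0] += 360.0
    return theta


def gyro_angle(omega: np.ndarray, fs: float, theta0: float = 0.0) -> np.ndarray:
    """Integrated gyroscope angle: cumulative trapezoid of the rate.

    First element equals ``theta0`` exactly.
    """
    omega = np.asarray(omega, dtype=float)
    if fs <= 0:
        raise DataError("fs must be positive")
    return theta0 + cumulative_trapezoid(omega, dx=1.0 / fs, initial=0.0)


def complementary_blend(
    theta_gyro: np.ndarray, theta_acc: np.ndarray, alpha: float
) -> np.ndarray:
    """alpha * theta_gyro + (1 - alpha) * theta_acc, element-wise."""
    if not 0.0 <= alpha <= 1.0:
        raise DataError(f"alpha must be in [0, 1], got {alpha}")
    theta_gyro = np.asarray(theta_gyro, dtype=float)
    theta_acc = np.asarray(theta_acc, dtype=float)
    if theta_gyro.shape != theta_acc.shape:
        raise DataError("angle series must have equal length")
    return alpha * theta_gyro + (1.0 - alpha) * theta_acc


def complementary_recursive(
    omega: np.ndarray, theta_acc: np.ndarray, alpha: float, fs: float
) -> np.ndarray:
    """Per-sample recursive complementary filter (comparison variant).

    theta[i] = alpha * (theta[i-1] + omega[i] * dt) + (1 - alpha) * theta_acc[i],
    initialized at theta_acc[0].
    """
    if not 0.0 <= alpha <= 1.0:
        raise DataError(f"alpha must be in [0, 1], got {alpha}")
    omega = np.asarray(omega, dtype=float)
    theta_acc = np.asarray(theta_acc, dtype=float)
    dt = 1.0 / fs
    out = np.empty_like(theta_acc)
    out[0] = theta_acc[0]
    for i in range(1, len(out)):
        out[i] = alpha * (out[i - 1] + omega[i] * dt) + (1 - alpha) * theta_acc[i]
    return out


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (drift) from a series."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise DataError("detrend requires a 1-D series of length >= 2")
    x = np.arange(len(series), dtype=float)
    coef = np.polynomial.polynomial.polyfit(x, series, 1)
    return series - np.polynomial.polynomial.polyval(x, coef)


def _tricube(d: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(d) ** 3, 0.0, None) ** 3
    return w


def smooth_loess(series: np.ndarray, span: float) -> np.ndarray:
    """Local quadratic (loess) smoothing with tricube weights.

    The window is ``round(span * n)`` nearest samples (forced odd, >= 5);
    edge windows are asymmetric but keep the same size, as in the classic
    nearest-neighbour loess.  A weighted quadratic is fit in each window
    and evaluated at the window's query point, so exact quadratics pass
    through unchanged.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    if not 0.0 < span <= 1.0:
        raise DataError("span must be in (0, 1]")
    if n < 5:
        return y.copy()
    k = int(round(span * n))
    k = max(k, 5)
    if k % 2 == 0:
        k += 1
    k = min(k, n if n % 2 == 1 else n - 1)
    half = k // 2

    # Interior points share one symmetric window geometry, so the loess
    # estimate there is a fixed linear filter: precompute its kernel.
    x = np.arange(-half, half + 1, dtype=float)
    w = _tricube(x / half)
    X = np.vander(x, 3, increasing=True)  # [1, x, x^2]
    XtW = X.T * w
    beta_op = np.linalg.solve(XtW @ X, XtW)  # (3, k)
    kernel = beta_op[0]  # row evaluating the fit at x = 0
    out = np.empty_like(y)
    out[half : n - half] = np.convolve(y, kernel[::-1], mode="valid")

    # Edge points: same window size, asymmetric placement.
    for i in list(range(half)) + list(range(n - half, n)):
        lo = 0 if i < half else n - k
        xs = np.arange(lo, lo + k, dtype=float) - i
        ws = _tricube(xs / np.max(np.abs(xs)))
        Xe = np.vander(xs, 3, increasing=True)
        XtWe = Xe.T * ws
        beta = np.linalg.solve(XtWe @ Xe, XtWe @ y[lo : lo + k])
        out[i] = beta[0]
    return out


def smooth_movmean(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edge windows shrink to the available samples."""
    y = np.asarray(series, dtype=float)
    if window > len(y):
        raise DataError(
            f"movmean window {window} exceeds series length {len(y)}"
        )
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def remove_signal_outliers(
    series: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Flag and repair samples far from the median (scaled-MAD rule).

    A sample is an outlier iff
    ``|x - median(x)| > threshold * 1.4826 * median(|x - median(x)|)``
    (strict inequality, so a constant series has no outliers).  Flagged
    samples are replaced by linear interpolation between their nearest
    unflagged neighbours; flagged samples at the edges take the nearest
    unflagged value.  Returns ``(repaired, mask)``.
    """
    y = np.asarray(series, dtype=float)
    if len(y) < 3:
        raise DataError("outlier removal requires length >= 3")
    med = np.median(y)
    mad = np.median(np.abs(y - med))
    mask = np.abs(y - med) > threshold * MAD_SCALE * mad
    if mask.all():
        raise AllOutliersError("every sample was flagged as an outlier")
    repaired = y.copy()
    if mask.any():
        idx = np.arange(len(y))
        repaired[mask] = np.interp(idx[mask], idx[~mask], y[~mask])
    return repaired, mask


def estimate_hip_angles(trial: ImuTrial, cfg: PreprocessConfig | None = None) -> AngleSet:
    """Run the full conditioning chain on one trial.

    Hip, per side: accelerometer tilt -> gyro integral (seeded at the
    initial tilt) -> complementary blend -> linear detrend -> loess smooth.
    Foot, per side: scaled-MAD outlier repair -> centered moving average.
    """
    cfg = cfg or PreprocessConfig()
    hips = {}
    for side in ("L", "R"):
        theta_acc = accel_angle(
            getattr(trial, f"gx_{side}"), getattr(trial, f"gy_{side}")
        )
        if cfg.recursive_filter:
            blended = complementary_recursive(
                getattr(trial, f"omega_{side}"), theta_acc, cfg.alpha, trial.fs
            )
        else:
            theta_gyro = gyro_angle(
                getattr(trial, f"omega_{side}"), trial.fs, theta0=theta_acc[0]
            )
            blended = complementary_blend(theta_gyro, theta_acc, cfg.alpha)
        hip = detrend_linear(blended)
        if cfg.outlier_on_hip:
            hip, _ = remove_signal_outliers(hip, cfg.outlier_threshold)
        hips[side] = smooth_loess(hip, cfg.loess_span)
    feet = {}
    for side in ("L", "R"):
        repaired, _ = remove_signal_outliers(
            getattr(trial, f"foot_{side}"), cfg.outlier_threshold
        )
        feet[side] = smooth_movmean(repaired, cfg.movmean_window)
    return AngleSet(
        t=trial.t.copy(),
        theta_hip_L=hips["L"],
        theta_hip_R=hips["R"],
        theta_foot_L=feet["L"],
        theta_foot_R=feet["R"],
    )
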