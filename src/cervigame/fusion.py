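"""IMU sensor fusion and neutral-pose calibration.

A head-worn inertial unit streams triaxial gyroscope (deg/s),
accelerometer (g) and magnetometer (normalised field) samples.  Fusion
integrates the gyroscope and continuously corrects the resulting
orientation toward the accelerometer-derived gravity direction (tilt)
and the magnetometer-derived heading (yaw) — an explicit complementary
filter with a single blend gain, adequate for the slow angular rates of
cervical exercise.

Calibration averages the fused orientation over a short window in which
the subject holds a neutral upright posture, yielding the reference
orientation ``R_cal`` that anchors the absolute head-to-cursor mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from .rotation import RotationState, angular_distance_deg, nearest_rotation

__all__ = [
    "ImuSample",
    "ImuStream",
    "FusionParams",
    "CalibrationError",
    "fuse_imu",
    "calibrate",
    "chordal_mean",
]

#: world-frame gravity direction sensed by a static accelerometer (reaction, +Z up)
GRAVITY_WORLD = np.array([0.0, 0.0, 1.0])
#: world-frame magnetic reference (horizontal, pointing north / anterior)
MAG_WORLD = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class ImuSample:
    """One timestamped inertial sample.

    t in seconds; gyro in deg/s (head frame); accel in units of g;
    mag as a normalised field vector.
    """

    t: float
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        for name in ("gyro", "accel", "mag"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            object.__setattr__(self, name, v)


class ImuStream:
    """An immutable sequence of :class:`ImuSample` with strictly increasing time."""

    def __init__(self, samples: Iterable[ImuSample]):
        samples = list(samples)
        if not samples:
            raise ValueError("IMU stream is empty")
        t = np.array([s.t for s in samples])
        if np.any(np.diff(t) <= 0):
            raise ValueError("IMU timestamps must be strictly increasing")
        self._samples = samples
        self.t = t

    def __len__(self) -> int:
        return len(self._samples)

    def __iter__(self):
        return iter(self._samples)

    def __getitem__(self, i):
        return self._samples[i]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @classmethod
    def from_arrays(cls, t, gyro, accel, mag) -> "ImuStream":
        t = np.asarray(t, float)
        gyro, accel, mag = (np.asarray(a, float) for a in (gyro, accel, mag))
        return cls(
            ImuSample(float(t[i]), gyro[i], accel[i], mag[i]) for i in range(len(t))
        )


@dataclass(frozen=True)
class FusionParams:
    """Complementary-filter settings.

    gain:
        Fraction of the measured tilt/heading error corrected per
        sample, in [0, 1].  0 is pure gyro integration, 1 snaps to the
        accel/mag attitude each sample.  The default 0.02 at 50 Hz gives
        a correction time constant of about one second.
    sample_rate:
        Nominal rate in Hz; used only as a fallback when a stream has a
        single sample (timestamps otherwise drive integration).
    mag_enabled:
        Apply the magnetometer heading correction.  Without it yaw is
        held by the gyroscope alone.
    """

    gain: float = 0.02
    sample_rate: float = 50.0
    mag_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gain <= 1.0:
            raise ValueError("gain must lie in [0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


class CalibrationError(RuntimeError):
    """Neutral-pose calibration could not be established."""


def _error_rotvec(measured: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Body-frame correction rotvec (rad) for one vector observation.

    Post-multiplying the attitude by this rotation moves the predicted
    body-frame direction onto the measured one (Mahony convention,
    axis = measured × predicted with the sign absorbed by the update
    ``R ← R·exp(e)`` acting on predictions as ``exp(−e)``).
    """
    nm, npred = np.linalg.norm(measured), np.linalg.norm(predicted)
    if nm < 1e-12 or npred < 1e-12:
        return np.zeros(3)
    m, p = measured / nm, predicted / npred
    axis = np.cross(m, p)
    s = np.linalg.norm(axis)
    c = float(np.dot(p, m))
    if s < 1e-12:
        return np.zeros(3)
    return axis / s * np.arctan2(s, c)


def fuse_imu(
    stream: ImuStream, params: FusionParams | None = None
) -> list[tuple[float, RotationState]]:
    """Estimate orientation over an IMU stream.

    Returns one ``(t, RotationState)`` per input sample; the state at
    sample *k* incorporates the gyro increment from *k−1* to *k* and the
    accel/mag correction at *k*.  The initial attitude is taken from the
    first accelerometer/magnetometer reading so a world-aligned static
    stream starts (and stays) at identity.
    """
    if params is None:
        params = FusionParams()
    first = stream[0]
    R = _init_attitude(first, params)
    out: list[tuple[float, RotationState]] = []
    prev_t = first.t
    prev_gyro = first.gyro
    for k, s in enumerate(stream):
        if k > 0:
            dt = s.t - prev_t
            # trapezoidal gyro increment in the head frame
            omega = np.radians(0.5 * (prev_gyro + s.gyro)) * dt
            R = R @ _Rotation.from_rotvec(omega).as_matrix()
        R = _correct(R, s, params)
        if k % 256 == 255:
            R = nearest_rotation(R)
        out.append((s.t, RotationState(nearest_rotation(R))))
        prev_t, prev_gyro = s.t, s.gyro
    return out


def _init_attitude(s: ImuSample, params: FusionParams) -> np.ndarray:
    """Closed-form TRIAD attitude from the first accel/mag reading.

    Body up = normalised accel; body north = horizontal component of the
    magnetic field.  Falls back to a tilt-only attitude (zero yaw) when
    the field is degenerate or the magnetometer is disabled.
    """
    a = s.accel
    if np.linalg.norm(a) < 1e-9:
        return np.eye(3)
    b3 = a / np.linalg.norm(a)
    m_h = s.mag - np.dot(s.mag, b3) * b3
    if params.mag_enabled and np.linalg.norm(m_h) > 1e-9:
        b1 = m_h / np.linalg.norm(m_h)
    else:
        # tilt-only: project body X into the horizontal plane
        x_h = np.array([1.0, 0.0, 0.0]) - b3[0] * b3
        if np.linalg.norm(x_h) < 1e-9:  # looking straight up/down
            x_h = np.array([0.0, 1.0, 0.0]) - b3[1] * b3
        b1 = x_h / np.linalg.norm(x_h)
    b2 = np.cross(b3, b1)
    B = np.column_stack([b1, b2, b3])
    W = np.column_stack([MAG_WORLD, np.cross(GRAVITY_WORLD, MAG_WORLD), GRAVITY_WORLD])
    return nearest_rotation(W @ B.T)


def _correct(R: np.ndarray, s: ImuSample, params: FusionParams) -> np.ndarray:
    if params.gain == 0.0:
        return R
    # tilt: compare measured gravity with the prediction R' g_world
    g_pred = R.T @ GRAVITY_WORLD
    err = _error_rotvec(s.accel, g_pred)
    if params.mag_enabled:
        # heading: compare the horizontal component of the field only, so
        # the magnetometer never disturbs tilt
        m_pred = R.T @ MAG_WORLD
        m_meas = s.mag - np.dot(s.mag, g_pred) * g_pred
        m_pred = m_pred - np.dot(m_pred, g_pred) * g_pred
        err = err + _error_rotvec(m_meas, m_pred)
    if np.any(err):
        R = R @ _Rotation.from_rotvec(params.gain * err).as_matrix()
    return R


def chordal_mean(rotations: Sequence[RotationState]) -> RotationState:
    """Chordal (Frobenius) mean of rotations.

    The element-wise mean matrix projected to the nearest proper
    rotation; deterministic and invariant to input order.
    """
    if not rotations:
        raise ValueError("cannot average an empty set of rotations")
    M = np.mean([r.dcm for r in rotations], axis=0)
    return RotationState(nearest_rotation(M))


def calibrate(
    stream: ImuStream,
    window_s: float = 2.0,
    params: FusionParams | None = None,
    max_deviation_deg: float = 5.0,
) -> RotationState:
    """Estimate the neutral-posture reference orientation ``R_cal``.

    The subject holds the head upright while the device records; the
    trailing ``window_s`` seconds of the fused stream (the posture at
    the moment the operator confirms) are averaged with the chordal
    mean.

    Raises
    ------
    CalibrationError
        If the stream is shorter than ``window_s``, or any orientation
        in the window deviates from the mean by more than
        ``max_deviation_deg`` (the head moved during calibration).
    """
    if stream.duration < window_s:
        raise CalibrationError(
            f"calibration needs {window_s:.2f} s of data, stream spans "
            f"{stream.duration:.2f} s"
        )
    fused = fuse_imu(stream, params)
    t_end = fused[-1][0]
    window = [r for (t, r) in fused if t >= t_end - window_s]
    mean = chordal_mean(window)
    worst = max(mean.angle_to(r) for r in window)
    if worst > max_deviation_deg:
        raise CalibrationError(
            f"head moved during calibration: max deviation {worst:.2f}° "
            f"exceeds {max_deviation_deg:.2f}°"
        )
    return mean
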