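"""Impact-pulse biofidelity rating and drop/compression kinematics.

A simulated head-impact response is judged against an experimental
reference by a correlation score (CS) on the two time histories, decomposed
into three sub-scores, each on a 0–100 scale:

* **N-phase** — timing agreement.  The lag ``delta`` that maximizes the
  cross-correlation of the two signals is found on the common uniform grid;
  the score is ``100 * max(0, 1 - |delta| / D)`` with ``D`` the reference
  pulse duration, so a copy shifted by a quarter of the pulse width scores
  75 and larger shifts score lower.
* **N-amp** — magnitude agreement of the lag-aligned curves, via their RMS
  amplitudes ``A = sqrt(integral v^2 dt)``:
  ``100 * max(0, 1 - |A_test - A_ref| / A_ref)``.
* **N-shape** — waveform agreement once timing and magnitude are factored
  out: the aligned test curve is scaled to the reference RMS amplitude and
  the score is ``100 * max(0, 1 - ||test - ref|| / ||ref||)`` in the L2
  norm.

The three sub-scores are combined by their arithmetic mean, and the mean is
mapped to a biofidelity label; a mean of 86 or more rates *excellent*.

Both curves are resampled to a common uniform grid (default step 0.2 ms)
over the union of their time windows, with zero padding outside each
curve's own support, before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, UndefinedScoreError

__all__ = [
    "SignalCurve",
    "CorrelationScore",
    "DropConfig",
    "RATING_BANDS",
    "DEFAULT_DT",
    "resample_uniform",
    "correlation_score",
    "average_score",
    "classify_rating",
    "impact_velocity",
    "acceleration_from_force",
    "peak_and_duration",
    "characteristic_length",
    "scale_factor",
    "compression_plate_velocity",
]

#: Default resampling interval for scoring [s] (0.2 ms).
DEFAULT_DT = 2.0e-4

#: Biofidelity bands on the mean correlation score.  The top band is
#: closed at 100: perfect agreement cannot rate below excellent.
RATING_BANDS: tuple[tuple[float, str], ...] = (
    (86.0, "excellent"),
    (65.0, "good"),
    (44.0, "fair"),
    (26.0, "marginal"),
    (0.0, "unacceptable"),
)


@dataclass(frozen=True)
class SignalCurve:
    """A sampled time history (acceleration in g, or force in N).

    ``time`` [s] must be strictly increasing with at least two samples;
    values must be finite.  ``kind`` is a free tag ("acceleration_g",
    "force_N", ...).
    """

    time: np.ndarray
    value: np.ndarray
    kind: str = "acceleration_g"

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise DomainError("time and value must be 1-D arrays of equal length")
        if t.size < 2:
            raise DomainError("a signal needs at least two samples")
        if np.any(np.diff(t) <= 0):
            raise DomainError("time must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise DomainError("signal samples must be finite")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class CorrelationScore:
    """Phase/amplitude/shape sub-scores (each 0–100), their mean, and a label."""

    n_phase: float
    n_amp: float
    n_shape: float

    def __post_init__(self):
        for name in ("n_phase", "n_amp", "n_shape"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise DomainError(f"{name} must lie in [0, 100], got {v}")

    @property
    def average(self) -> float:
        return (self.n_phase + self.n_amp + self.n_shape) / 3.0

    @property
    def rating(self) -> str:
        return classify_rating(self.average)


@dataclass(frozen=True)
class DropConfig:
    """Free-fall drop configuration: height [m], head mass [kg], gravity."""

    height: float
    head_mass: float
    gravity: float = 9.81

    def __post_init__(self):
        if self.height < 0:
            raise DomainError("drop height must be nonnegative")
        if not self.head_mass > 0:
            raise DomainError("head mass must be positive")


def resample_uniform(curve: SignalCurve, dt: float = DEFAULT_DT) -> SignalCurve:
    """Linearly interpolate a signal onto a uniform grid.

    The grid starts at the first sample time and steps by ``dt``; the last
    sample time is appended if it does not land on the grid, so both
    endpoints are always preserved.
    """
    if not dt > 0:
        raise DomainError("resampling interval dt must be positive")
    t0, t1 = float(curve.time[0]), float(curve.time[-1])
    span = t1 - t0
    if span < 2 * dt:
        raise DomainError("curve must span at least two resampling intervals")
    n = int(np.floor(span / dt + 1e-9))
    grid = t0 + dt * np.arange(n + 1)
    if grid[-1] < t1 - 1e-12 * max(1.0, abs(t1)):
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    return SignalCurve(time=grid, value=np.interp(grid, curve.time, curve.value),
                       kind=curve.kind)


def _common_grid(test: SignalCurve, reference: SignalCurve, dt: float):
    """Union-window uniform grid with zero padding outside each support."""
    t0 = min(test.time[0], reference.time[0])
    t1 = max(test.time[-1], reference.time[-1])
    n = int(np.ceil((t1 - t0) / dt - 1e-9))
    grid = t0 + dt * np.arange(n + 1)
    x = np.interp(grid, test.time, test.value, left=0.0, right=0.0)
    y = np.interp(grid, reference.time, reference.value, left=0.0, right=0.0)
    # outside a curve's own window the signal is taken as zero
    x[(grid < test.time[0]) | (grid > test.time[-1])] = 0.0
    y[(grid < reference.time[0]) | (grid > reference.time[-1])] = 0.0
    return grid, x, y


def _reference_duration(grid: np.ndarray, y: np.ndarray, threshold_fraction: float = 0.05) -> float:
    """Duration of the reference pulse: time between the first and last
    crossings of ``threshold_fraction`` times the absolute peak."""
    mag = np.abs(y)
    thr = threshold_fraction * float(np.max(mag))
    idx = np.nonzero(mag >= thr)[0]
    return float(grid[idx[-1]] - grid[idx[0]])


def correlation_score(test: SignalCurve, reference: SignalCurve,
                      dt: float = DEFAULT_DT) -> CorrelationScore:
    """Score the agreement of a test curve against a reference curve.

    Both curves are placed on a common uniform grid (union window, zero
    padded) before the phase, amplitude and shape sub-scores are computed;
    see the module docstring for the formulas.  Identical curves score
    (100, 100, 100).

    Raises
    ------
    UndefinedScoreError
        If the reference is identically zero.
    """
    grid, x, y = _common_grid(test, reference, dt)
    a_ref = float(np.sqrt(np.trapezoid(y ** 2, grid)))
    if a_ref == 0.0:
        raise UndefinedScoreError("reference signal is identically zero")
    a_test = float(np.sqrt(np.trapezoid(x ** 2, grid)))
    if a_test == 0.0:
        return CorrelationScore(n_phase=0.0, n_amp=0.0, n_shape=0.0)

    # phase: lag of the cross-correlation peak, normalized by pulse duration
    xc = np.correlate(x, y, mode="full")
    lag = (int(np.argmax(xc)) - (len(y) - 1)) * dt
    duration = _reference_duration(grid, y)
    n_phase = 100.0 * max(0.0, 1.0 - abs(lag) / duration)

    # align the test curve by the detected lag before amplitude/shape
    shift = int(round(lag / dt))
    x_al = np.zeros_like(x)
    if shift == 0:
        x_al[:] = x
    elif shift > 0:
        x_al[:-shift] = x[shift:]
    else:
        x_al[-shift:] = x[:shift]

    a_al = float(np.sqrt(np.trapezoid(x_al ** 2, grid)))
    if a_al == 0.0:  # alignment pushed the whole pulse out of the window
        return CorrelationScore(n_phase=n_phase, n_amp=0.0, n_shape=0.0)
    n_amp = 100.0 * max(0.0, 1.0 - abs(a_al - a_ref) / a_ref)

    x_hat = x_al * (a_ref / a_al)
    mis = float(np.sqrt(np.trapezoid((x_hat - y) ** 2, grid)))
    n_shape = 100.0 * max(0.0, 1.0 - mis / a_ref)

    return CorrelationScore(n_phase=n_phase, n_amp=n_amp, n_shape=n_shape)


def average_score(n_phase: float, n_amp: float, n_shape: float) -> float:
    """Arithmetic mean of the three sub-scores."""
    for v in (n_phase, n_amp, n_shape):
        if not 0.0 <= v <= 100.0:
            raise DomainError("sub-scores must lie in [0, 100]")
    return (n_phase + n_amp + n_shape) / 3.0


def classify_rating(cs: float) -> str:
    """Map a mean correlation score to its biofidelity label."""
    if not 0.0 <= cs <= 100.0:
        raise DomainError("correlation score must lie in [0, 100]")
    for lo, label in RATING_BANDS:
        if cs >= lo:
            return label
    return RATING_BANDS[-1][1]


def impact_velocity(config: DropConfig) -> float:
    """Ideal free-fall impact velocity sqrt(2 g h) [m/s]."""
    return float(np.sqrt(2.0 * config.gravity * config.height))


def acceleration_from_force(force_curve: SignalCurve, config: DropConfig) -> SignalCurve:
    """Convert an impact-force history [N] to head acceleration in g.

    ``a_i = F_i / (m * 9.81)`` — the measured contact force divided by head
    mass, expressed in multiples of standard gravity.
    """
    return SignalCurve(
        time=force_curve.time,
        value=force_curve.value / (config.head_mass * 9.81),
        kind="acceleration_g",
    )


def peak_and_duration(curve: SignalCurve, threshold_fraction: float = 0.05) -> tuple[float, float]:
    """Peak value and impact duration of a pulse.

    The duration is the time between the first and last crossings of
    ``threshold_fraction * peak``, with crossing times refined by linear
    interpolation between samples.
    """
    if not 0.0 <= threshold_fraction < 1.0:
        raise DomainError("threshold fraction must lie in [0, 1)")
    v = curve.value
    peak = float(np.max(v))
    if peak <= 0.0:
        raise DomainError("pulse must have a positive maximum")
    thr = threshold_fraction * peak
    above = v >= thr if thr > 0 else v > 0
    idx = np.nonzero(above)[0]
    t = curve.time
    t_first = float(t[idx[0]])
    if idx[0] > 0 and v[idx[0]] > thr:
        i = idx[0]
        t_first = float(t[i - 1] + (thr - v[i - 1]) / (v[i] - v[i - 1]) * (t[i] - t[i - 1]))
    t_last = float(t[idx[-1]])
    if idx[-1] < len(v) - 1 and v[idx[-1]] > thr:
        i = idx[-1]
        t_last = float(t[i] + (v[i] - thr) / (v[i] - v[i + 1]) * (t[i + 1] - t[i]))
    return peak, t_last - t_first


def characteristic_length(length: float, width: float, circumference: float) -> float:
    """Characteristic head length: head length + width + circumference [m]."""
    for v in (length, width, circumference):
        if not v > 0:
            raise DomainError("head dimensions must be positive")
    return length + width + circumference


def scale_factor(cl_target: float, cl_model: float) -> float:
    """Geometric scaling factor from a model head to a target head."""
    if not (cl_target > 0 and cl_model > 0):
        raise DomainError("characteristic lengths must be positive")
    return cl_target / cl_model


def compression_plate_velocity(dimension: float, rate: float = 0.3) -> float:
    """Plate velocity [m/s] for a head-compression test at a given strain
    rate [1/s] applied over the head dimension along the compression axis."""
    if not dimension > 0:
        raise DomainError("head dimension must be positive")
    if rate < 0:
        raise DomainError("compression rate must be nonnegative")
    return rate * dimension
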