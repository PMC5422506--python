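"""Deterministic synthetic-data generators.

No tabulated experimental records exist for the tissue tests and drop
experiments this toolkit calibrates against, so every input class the
library consumes can be emulated here: uniaxial soft-tissue stress–stretch
curves with a toe and a linear region, scattered age–stiffness data with a
monotone concave trend, and single- or double-peak head-impact acceleration
pulses.  Every generator is a pure function of its arguments — the same
seed gives bit-identical arrays.
"""

from __future__ import annotations

import numpy as np

from .biofidelity import SignalCurve
from .exceptions import DomainError
from .hyperelastic import (
    MooneyRivlinMaterial,
    OgdenMaterial,
    UniaxialCurve,
    mooney_rivlin_nominal_stress,
    ogden_nominal_stress,
)
from .skull_aging import AgeModulusSample, BoneRegion

__all__ = [
    "gen_uniaxial_curve",
    "gen_age_stiffness_samples",
    "gen_acceleration_pulse",
    "saturating_growth",
]


def gen_uniaxial_curve(
    material: OgdenMaterial | MooneyRivlinMaterial,
    stretch_range: tuple[float, float] = (1.0, 3.0),
    n: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> UniaxialCurve:
    """Sample a uniaxial stress–stretch curve from an exact material law.

    Stresses are the exact nominal stresses multiplied by ``(1 + eps)``
    with ``eps ~ N(0, noise_sd)`` (multiplicative noise keeps the zero at
    lambda = 1 exact).  ``noise_sd = 0`` reproduces the law exactly.
    """
    lo, hi = float(stretch_range[0]), float(stretch_range[1])
    if not (0 < lo < hi):
        raise DomainError("stretch range must satisfy 0 < lo < hi")
    if n < 5:
        raise DomainError("need at least 5 samples")
    lam = np.linspace(lo, hi, n)
    if isinstance(material, OgdenMaterial):
        stress = ogden_nominal_stress(material, lam)
    elif isinstance(material, MooneyRivlinMaterial):
        stress = mooney_rivlin_nominal_stress(material, lam)
    else:
        raise DomainError(f"unsupported material type: {type(material).__name__}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + noise_sd * rng.standard_normal(n))
    return UniaxialCurve(stretch=lam, stress=stress)


def saturating_growth(age, e_gain: float = 600.0, tau: float = 12.0,
                      e_birth: float = 150.0):
    """Monotone concave stiffness-growth ground truth [MPa]:
    ``E(age) = e_gain * (1 - exp(-age / tau)) + e_birth``.

    Defaults emulate infant cranial bone: ~150 MPa around term birth rising
    by several hundred MPa over the first years (time constant 12 months).
    """
    return e_gain * (1.0 - np.exp(-np.asarray(age, dtype=float) / tau)) + e_birth


def gen_age_stiffness_samples(
    ages,
    truth=None,
    noise_sd: float = 0.2,
    seed: int = 0,
    region: BoneRegion | str = BoneRegion.PARIETAL,
) -> list[AgeModulusSample]:
    """Scattered (age, E2) samples around a monotone concave ground truth.

    Scatter is multiplicative lognormal — ``E = truth(age) * exp(sigma Z)``
    with ``sigma = noise_sd`` — which keeps every sampled modulus positive,
    matching the large specimen-to-specimen variability of infant skull
    tests.  ``truth`` defaults to :func:`saturating_growth`.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise DomainError("ages must be non-empty")
    truth_fn = saturating_growth if truth is None else truth
    e = np.asarray(truth_fn(ages), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        e = e * np.exp(noise_sd * rng.standard_normal(ages.size))
    region = BoneRegion.coerce(region)
    return [AgeModulusSample(age=float(a), e2=float(v), region=region)
            for a, v in zip(ages, e)]


def gen_acceleration_pulse(
    kind: str = "single",
    peak_g: float = 100.0,
    duration_s: float = 0.010,
    separation_s: float | None = None,
    second_peak_fraction: float = 0.6,
    dt: float = 2.0e-4,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SignalCurve:
    """Synthetic head-impact acceleration pulse.

    ``kind="single"`` is a haversine ``A sin^2(pi t / T)`` on [0, T] —
    the canonical shape of forehead/occiput/vertex impact pulses.  The
    sampling step is shrunk (never grown) so the pulse midpoint lies on the
    grid and the sampled maximum equals ``peak_g`` exactly.

    ``kind="double"`` superposes a second haversine of the same width,
    delayed by ``separation_s`` and scaled by ``second_peak_fraction`` —
    emulating the two-peak morphology of parietal impacts where the bone
    plates move relative to the sutures.
    """
    if not duration_s > 0:
        raise DomainError("pulse duration must be positive")
    if not dt > 0:
        raise DomainError("dt must be positive")
    if not peak_g > 0:
        raise DomainError("peak must be positive")

    t_half = duration_s / 2.0
    m = max(1, int(np.ceil(t_half / dt)))
    step = t_half / m  # step <= dt, midpoint exactly on the grid

    def haversine(t):
        out = np.sin(np.pi * t / duration_s) ** 2
        out[(t < 0) | (t > duration_s)] = 0.0
        return peak_g * out

    if kind == "single":
        t = step * np.arange(2 * m + 1)
        v = haversine(t)
    elif kind == "double":
        if separation_s is None or not 0 < separation_s < duration_s:
            raise DomainError("double pulse needs 0 < separation < duration")
        if not 0 < second_peak_fraction <= 1:
            raise DomainError("second peak fraction must lie in (0, 1]")
        n = int(np.ceil((duration_s + separation_s) / step))
        t = step * np.arange(n + 1)
        v = haversine(t) + second_peak_fraction * haversine(t - separation_s)
    else:
        raise DomainError(f"unknown pulse kind: {kind!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + noise_sd * peak_g * rng.standard_normal(t.size)
    return SignalCurve(time=t, value=v, kind="acceleration_g")
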