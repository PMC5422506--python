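"""Uniaxial hyperelastic constitutive laws and their calibration.

This module implements the incompressible Ogden and Mooney–Rivlin material
laws in their uniaxial nominal-stress form, the tangent (Young's) modulus of
the Ogden law, Levenberg–Marquardt parameter fitting against measured
stress–stretch curves, and modulus-targeted rescaling.

The Ogden nominal stress used throughout is

    sigma(lambda) = sum_i  mu_i * (lambda**(alpha_i - 1) - lambda**(-1 - alpha_i/2))

with stretch ratio ``lambda > 0``; every term vanishes at ``lambda = 1`` so
the unloaded state is stress free.  Cranial suture and scalp are single-term
materials; brain tissue uses a two-term set with one negative (mu, alpha)
pair.  The incompressible Mooney–Rivlin uniaxial nominal stress is

    sigma(lambda) = 2 * (C1 + C2 / lambda) * (lambda - lambda**-2)

Units: stresses and moduli are stored in Pa; stretch is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import DegenerateFitError, DomainError

__all__ = [
    "OgdenMaterial",
    "MooneyRivlinMaterial",
    "UniaxialCurve",
    "FitResult",
    "ogden_nominal_stress",
    "tangent_modulus",
    "mooney_rivlin_nominal_stress",
    "fit_ogden",
    "r_squared",
    "rescale_to_target_modulus",
]


@dataclass(frozen=True)
class OgdenMaterial:
    """Ogden hyperelastic material: ordered (mu_i [Pa], alpha_i [-]) pairs."""

    terms: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self):
        terms = tuple((float(m), float(a)) for m, a in self.terms)
        if len(terms) == 0:
            raise DomainError("OgdenMaterial needs at least one (mu, alpha) term")
        for mu, alpha in terms:
            if alpha == 0.0:
                raise DomainError("Ogden exponent alpha_i must be nonzero")
            if not (np.isfinite(mu) and np.isfinite(alpha)):
                raise DomainError("Ogden constants must be finite")
        object.__setattr__(self, "terms", terms)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def scaled(self, factor: float, label: str | None = None) -> "OgdenMaterial":
        """Return a copy with every mu_i multiplied by ``factor``."""
        return OgdenMaterial(
            terms=tuple((mu * factor, alpha) for mu, alpha in self.terms),
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class MooneyRivlinMaterial:
    """Incompressible Mooney–Rivlin material with constants C1, C2 in Pa."""

    c1: float
    c2: float
    label: str = ""

    def __post_init__(self):
        if not self.c1 > 0:
            raise DomainError("Mooney-Rivlin C1 must be positive")


@dataclass(frozen=True)
class UniaxialCurve:
    """Sampled uniaxial stress–stretch record.

    ``stretch`` must be strictly increasing and positive; ``stress`` holds
    the matching nominal stresses in Pa.
    """

    stretch: np.ndarray
    stress: np.ndarray

    def __post_init__(self):
        stretch = np.asarray(self.stretch, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        if stretch.ndim != 1 or stretch.shape != stress.shape:
            raise DomainError("stretch and stress must be 1-D arrays of equal length")
        if stretch.size < 2:
            raise DomainError("a curve needs at least two samples")
        if np.any(stretch <= 0):
            raise DomainError("stretch ratios must be positive")
        if np.any(np.diff(stretch) <= 0):
            raise DomainError("stretch must be strictly increasing")
        object.__setattr__(self, "stretch", stretch)
        object.__setattr__(self, "stress", stress)

    def __len__(self) -> int:
        return self.stretch.size


@dataclass(frozen=True)
class FitResult:
    """Outcome of a hyperelastic calibration."""

    material: OgdenMaterial
    r_squared: float
    residual_norm: float
    n_iterations: int
    converged: bool
    message: str = field(default="", compare=False)


def _check_stretch(stretch) -> np.ndarray:
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise DomainError("stretch ratio must be positive")
    return lam


def ogden_nominal_stress(material: OgdenMaterial, stretch) -> np.ndarray | float:
    """Nominal (engineering) stress of an Ogden material at the given stretch.

    Accepts a scalar or array stretch; returns Pa on the same shape.
    Exactly zero at ``stretch == 1`` for any parameter set.
    """
    lam = _check_stretch(stretch)
    out = np.zeros_like(lam, dtype=float)
    for mu, alpha in material.terms:
        out += mu * (lam ** (alpha - 1.0) - lam ** (-1.0 - alpha / 2.0))
    return out if out.ndim else float(out)


def tangent_modulus(material: OgdenMaterial, stretch) -> np.ndarray | float:
    """Analytic slope d(sigma)/d(lambda) of the Ogden nominal stress.

    Because nominal stress is plotted against stretch (equivalently
    engineering strain), this slope is the tangent Young's modulus at the
    given stretch.  At ``lambda = 1`` it reduces to ``sum_i 1.5 mu_i alpha_i``.
    """
    lam = _check_stretch(stretch)
    out = np.zeros_like(lam, dtype=float)
    for mu, alpha in material.terms:
        out += mu * (
            (alpha - 1.0) * lam ** (alpha - 2.0)
            + (1.0 + alpha / 2.0) * lam ** (-2.0 - alpha / 2.0)
        )
    return out if out.ndim else float(out)


def mooney_rivlin_nominal_stress(material: MooneyRivlinMaterial, stretch) -> np.ndarray | float:
    """Uniaxial nominal stress of an incompressible Mooney–Rivlin material."""
    lam = _check_stretch(stretch)
    out = 2.0 * (material.c1 + material.c2 / lam) * (lam - lam ** -2.0)
    return out if out.ndim else float(out)


def r_squared(curve: UniaxialCurve, material: OgdenMaterial) -> float:
    """Coefficient of determination of an Ogden material against a curve.

    ``R^2 = 1 - SS_res / SS_tot``; equals 1 only for a perfect match and is
    undefined when the measured stresses have zero variance.
    """
    y = curve.stress
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateFitError("R^2 undefined: stress variance is zero")
    pred = ogden_nominal_stress(material, curve.stretch)
    ss_res = float(np.sum((y - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# Bounds for the fitted exponents.  Positive-exponent terms dominate tension
# curves of collagenous tissue; 50 comfortably covers reported scalp values.
_ALPHA_LO, _ALPHA_HI = 1e-6, 50.0


def _ogden_residuals(params: np.ndarray, lam: np.ndarray, y: np.ndarray,
                     w: np.ndarray) -> np.ndarray:
    n = params.size // 2
    mat = OgdenMaterial(terms=tuple((params[2 * i], params[2 * i + 1]) for i in range(n)))
    return (ogden_nominal_stress(mat, lam) - y) / w


def fit_ogden(
    curve: UniaxialCurve,
    n_terms: int = 1,
    init: OgdenMaterial | None = None,
    seed: int = 0,
    n_starts: int = 3,
    max_nfev: int = 2000,
    weighting: str = "absolute",
) -> FitResult:
    """Calibrate an n-term Ogden material to a stress–stretch curve.

    Uses trust-region Levenberg–Marquardt least squares on the nominal-stress
    residuals.  When ``init`` is omitted, a default start of
    ``mu_1 = max|stress| / 2, alpha_1 = 5`` is used together with
    ``n_starts - 1`` additional randomized starts (seeded) to avoid local
    minima; the best residual wins.  Exponents are bounded to (0, 50].

    ``weighting="absolute"`` (default) minimizes plain stress residuals;
    ``weighting="relative"`` divides each residual by the local stress
    magnitude, which is the matched estimator when the measurement error is
    multiplicative (a stress curve spanning several decades would otherwise
    be fitted by its top few points only).

    Raises
    ------
    DegenerateFitError
        If the curve carries no stress signal (all zeros).
    DomainError
        If the curve has fewer than ``2 n_terms + 1`` points.
    """
    if n_terms < 1:
        raise DomainError("n_terms must be >= 1")
    if len(curve) < 2 * n_terms + 1:
        raise DomainError(f"need at least {2 * n_terms + 1} samples to fit {n_terms} term(s)")
    y = curve.stress
    scale = float(np.max(np.abs(y)))
    if scale == 0.0:
        raise DegenerateFitError("cannot fit an all-zero stress curve")
    if weighting == "absolute":
        w = np.ones_like(y)
    elif weighting == "relative":
        # floor the weight so the zero-stress toe does not blow up
        w = np.maximum(np.abs(y), 1e-3 * scale)
    else:
        raise DomainError(f"unknown weighting: {weighting!r}")

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    if init is not None:
        if init.n_terms != n_terms:
            raise DomainError("init material must have n_terms terms")
        starts.append(np.array([v for t in init.terms for v in t], dtype=float))
    else:
        starts.append(np.array([scale / 2.0, 5.0] * n_terms, dtype=float))
    while len(starts) < n_starts:
        start = np.empty(2 * n_terms)
        start[0::2] = scale * rng.uniform(0.05, 2.0, size=n_terms)
        start[1::2] = rng.uniform(2.0, 20.0, size=n_terms)
        starts.append(start)

    lo = np.array([-np.inf, _ALPHA_LO] * n_terms)
    hi = np.array([np.inf, _ALPHA_HI] * n_terms)

    best = None
    for start in starts:
        start = np.clip(start, lo + 1e-12, hi - 1e-12)
        sol = least_squares(
            _ogden_residuals,
            start,
            args=(curve.stretch, y, w),
            method="trf",        # trust-region LM variant supporting bounds
            bounds=(lo, hi),
            x_scale="jac",
            max_nfev=max_nfev,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    material = OgdenMaterial(
        terms=tuple((best.x[2 * i], best.x[2 * i + 1]) for i in range(n_terms)),
        label="fitted",
    )
    return FitResult(
        material=material,
        r_squared=r_squared(curve, material),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_iterations=int(best.nfev),
        converged=bool(best.success),
        message=str(best.message),
    )


def rescale_to_target_modulus(
    material: OgdenMaterial, ref_stretch: float, target_modulus: float
) -> OgdenMaterial:
    """Scale every mu_i so the tangent modulus at ``ref_stretch`` equals
    ``target_modulus``; exponents are unchanged.

    This is the operation used to lift a single-specimen suture fit to the
    population-average stiffness: the tangent modulus is linear in the mu_i,
    so a single multiplicative factor hits the target exactly.
    """
    if not target_modulus > 0:
        raise DomainError("target modulus must be positive")
    current = tangent_modulus(material, ref_stretch)
    if not current > 0:
        raise DomainError("tangent modulus at the reference stretch must be positive")
    return material.scaled(target_modulus / current)
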