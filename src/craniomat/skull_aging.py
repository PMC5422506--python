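"""Age-dependent orthotropic skull-bone property generation.

Infant cranial bone is a fibrous composite: mineralized trabeculae radiate
from the ossification centre of each plate, making the bone much stiffer
along the fibres (E1) than across them (E2).  Two growth processes act in
opposite directions with age: the fibre anisotropy decays (the bone becomes
isotropic by adulthood) while the overall stiffness grows by an order of
magnitude.  This module models both:

1. an anisotropy ratio ``f(age) = E1/E2`` as a two-term exponential in age
   (months since 40-week gestation; negative ages are preterm),
2. the parallel-fibre modulus ``E1 = E2 * f(age)`` derived from measured
   perpendicular moduli,
3. shape-constrained (monotone nondecreasing, concave) spline fits of
   modulus-vs-age scatter,
4. assembly of the full nine-constant orthotropic elastic set with a
   positive-definiteness (stability) check.

Directions: 1 = parallel-to-fibre, 2 = perpendicular-to-fibre,
3 = through-thickness; E3 is taken equal to E2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline
from scipy.optimize import least_squares, nnls

from .exceptions import (
    AgeRangeError,
    DomainError,
    InsufficientDataError,
    StabilityError,
)

__all__ = [
    "AnisotropyModel",
    "AgeModulusSample",
    "StiffnessGrowthCurve",
    "BoneRegion",
    "OrthotropicConstants",
    "DEFAULT_ANISOTROPY",
    "DEFAULT_POISSON",
    "DEFAULT_DENSITY_TABLE",
    "anisotropy_ratio",
    "fit_anisotropy_model",
    "derive_parallel_modulus",
    "fit_growth_curve",
    "assemble_orthotropic",
    "material_card",
]

#: Default Poisson ratios for cranial bone (adult values, assumed
#: age-invariant): nu12 = nu13 = 0.22, nu23 = 0.19.
DEFAULT_POISSON: dict[str, float] = {"nu12": 0.22, "nu13": 0.22, "nu23": 0.19}

#: Skull-bone density [kg/m^3] at the bundled reference ages [months].
#: Values between tabulated ages are linearly interpolated; outside the
#: table the nearest entry is used.
DEFAULT_DENSITY_TABLE: dict[float, float] = {-1.35: 2150.0, 5.0: 2080.0, 9.0: 2075.3}


class BoneRegion(enum.Enum):
    """Cranial vault region; frontal bone resolves to parietal properties."""

    PARIETAL = "parietal"
    OCCIPITAL = "occipital"
    FRONTAL = "frontal"

    @classmethod
    def coerce(cls, value: "BoneRegion | str") -> "BoneRegion":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise DomainError(f"unknown bone region: {value!r}") from None

    def resolve(self) -> "BoneRegion":
        """Region whose material data applies (frontal -> parietal)."""
        return BoneRegion.PARIETAL if self is BoneRegion.FRONTAL else self


@dataclass(frozen=True)
class AnisotropyModel:
    """Two-term exponential anisotropy-ratio decay f(age) = a1*e^(b1*age) + a2*e^(b2*age).

    Ages are in months (40-week gestation = 0).  The default coefficients
    drop from f(0) ~ 2.31 in a term newborn to ~1.25 at six years and ~1.0
    (isotropy) at 18 years.
    """

    a1: float = 0.9071
    b1: float = -0.3017
    a2: float = 1.398
    b2: float = -0.00155
    valid_age_range: tuple[float, float] = (-5.0, 216.0)

    def __call__(self, age) -> np.ndarray | float:
        return anisotropy_ratio(self, age)


#: The bundled anisotropy decay model (fitted to foetal/child/adult ratios).
DEFAULT_ANISOTROPY = AnisotropyModel()


@dataclass(frozen=True)
class AgeModulusSample:
    """A single (age, perpendicular modulus E2) measurement for one region."""

    age: float          # months; negative = preterm
    e2: float           # MPa
    region: BoneRegion = BoneRegion.PARIETAL

    def __post_init__(self):
        if not self.e2 > 0:
            raise DomainError("modulus sample must be positive")
        if not -5.0 <= self.age <= 216.0:
            raise AgeRangeError(f"sample age {self.age} outside [-5, 216] months")
        object.__setattr__(self, "region", BoneRegion.coerce(self.region))


def anisotropy_ratio(model: AnisotropyModel, age) -> np.ndarray | float:
    """Evaluate the anisotropy ratio E1/E2 at an age in months."""
    age_arr = np.asarray(age, dtype=float)
    lo, hi = model.valid_age_range
    if np.any(age_arr < lo) or np.any(age_arr > hi):
        raise AgeRangeError(f"age outside model validity range [{lo}, {hi}] months")
    out = model.a1 * np.exp(model.b1 * age_arr) + model.a2 * np.exp(model.b2 * age_arr)
    return out if out.ndim else float(out)


def fit_anisotropy_model(samples) -> AnisotropyModel:
    """Least-squares fit of the two-term exponential to (age, ratio) samples.

    Parameters
    ----------
    samples : sequence of (age_months, ratio) pairs

    Raises
    ------
    InsufficientDataError
        Fewer than 5 samples, or all samples at a single age.
    """
    arr = np.asarray(list(samples), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 5:
        raise InsufficientDataError("need at least 5 (age, ratio) samples")
    ages, ratios = arr[:, 0], arr[:, 1]
    if np.unique(ages).size < 2:
        raise InsufficientDataError("samples must span at least two distinct ages")

    order = np.argsort(ages)
    a_lo, a_hi = ratios[order[0]], ratios[order[-1]]
    # Slow term carries the late-age plateau, fast term the early drop.
    x0 = np.array([max(a_lo - a_hi, 0.1), -0.3, max(a_hi, 0.1), -0.001])

    def resid(p):
        return p[0] * np.exp(p[1] * ages) + p[2] * np.exp(p[3] * ages) - ratios

    sol = least_squares(
        resid,
        x0,
        bounds=([0.0, -10.0, 0.0, -10.0], [np.inf, 0.0, np.inf, 0.0]),
        x_scale=[1.0, 0.1, 1.0, 0.01],
        max_nfev=5000,
    )
    a1, b1, a2, b2 = sol.x
    # canonical order: fastest-decaying term first
    if b1 > b2:
        a1, b1, a2, b2 = a2, b2, a1, b1
    lo, hi = float(np.min(ages)), float(np.max(ages))
    return AnisotropyModel(a1=a1, b1=b1, a2=a2, b2=b2,
                           valid_age_range=(min(lo, -5.0), max(hi, 216.0)))


def derive_parallel_modulus(age: float, e2: float, model: AnisotropyModel = DEFAULT_ANISOTROPY) -> float:
    """Parallel-to-fibre modulus E1 = E2 * f(age) from a measured E2 [MPa]."""
    if not e2 > 0:
        raise DomainError("E2 must be positive")
    return float(e2 * anisotropy_ratio(model, age))


@dataclass(frozen=True)
class StiffnessGrowthCurve:
    """Monotone-nondecreasing, concave spline of modulus [MPa] vs age [months].

    Wraps a scipy B-spline; evaluation outside the fitted age span is
    clamped to the span edges (the curve's own monotonicity makes the edge
    values the safest extrapolation for a saturating growth process).
    """

    spline: BSpline
    region: BoneRegion = BoneRegion.PARIETAL
    quantity: str = field(default="E2", compare=False)

    @property
    def knots(self) -> np.ndarray:
        return np.asarray(self.spline.t)

    @property
    def coefficients(self) -> np.ndarray:
        return np.asarray(self.spline.c)

    @property
    def age_span(self) -> tuple[float, float]:
        k = self.spline.k
        return float(self.spline.t[k]), float(self.spline.t[-k - 1])

    def __call__(self, age) -> np.ndarray | float:
        lo, hi = self.age_span
        age_arr = np.clip(np.asarray(age, dtype=float), lo, hi)
        out = self.spline(age_arr)
        return out if out.ndim else float(out)

    def check_shape(self, step: float = 0.5, tol: float = 1e-9) -> bool:
        """Verify monotonicity and concavity on a dense age grid."""
        lo, hi = self.age_span
        grid = np.arange(lo, hi + step / 2, step)
        vals = self.spline(grid)
        d1 = np.diff(vals)
        d2 = np.diff(d1)
        return bool(np.all(d1 >= -tol) and np.all(d2 <= tol))

    @classmethod
    def from_points(cls, ages, moduli, region=BoneRegion.PARIETAL, quantity="E2"):
        """Piecewise-linear interpolant through reference (age, modulus) points.

        The points must already be monotone nondecreasing with nonincreasing
        secant slopes, so the interpolant satisfies the shape constraints.
        """
        ages = np.asarray(ages, dtype=float)
        moduli = np.asarray(moduli, dtype=float)
        if np.any(np.diff(moduli) < 0):
            raise DomainError("reference moduli must be nondecreasing in age")
        slopes = np.diff(moduli) / np.diff(ages)
        if np.any(np.diff(slopes) > 1e-9 * max(1.0, float(np.max(np.abs(slopes))))):
            raise DomainError("reference points must be concave in age")
        return cls(spline=make_interp_spline(ages, moduli, k=1),
                   region=BoneRegion.coerce(region), quantity=quantity)


def _shape_constrained_spline(x: np.ndarray, y: np.ndarray, k: int, t: np.ndarray) -> BSpline:
    """Least-squares B-spline fit with nondecreasing-concave shape constraints.

    The constraints are imposed through a cone reparametrization that an
    exact non-negative least-squares solve (Lawson–Hanson) handles without
    tolerance slack: with derivative-spline coefficients
    ``d_i = k (c_{i+1} - c_i) / (t_{i+k+1} - t_{i+1})``, monotonicity and
    concavity hold iff ``d_0 >= d_1 >= ... >= 0``.  Writing
    ``d_i = sum_{j>=i} u_j`` with ``u_j >= 0`` and splitting the free
    intercept into a positive pair turns the problem into plain NNLS.
    """
    n_coef = len(t) - k - 1
    design = BSpline.design_matrix(x, t, k).toarray()

    # spans h_i = (t_{i+k+1} - t_{i+1}) / k linking c-differences to d
    h = (t[1 + k : n_coef + k] - t[1 : n_coef]) / k
    m = n_coef - 1  # number of d coefficients
    # c_j = c_0 + sum_{i<j} h_i d_i ;  d_i = sum_{l>=i} u_l
    # => c = c0 * 1 + (Hcum @ U) u  with U upper-triangular of ones
    lower = np.tril(np.ones((n_coef, m)), k=-1) * h[np.newaxis, :]  # (j, i): h_i if i < j
    upper = np.triu(np.ones((m, m)))
    cone = lower @ upper                      # maps u -> c - c0
    ones = np.ones((n_coef, 1))

    a_mat = np.hstack([design @ ones, -(design @ ones), design @ cone])
    coef, _ = nnls(a_mat, y, maxiter=10 * a_mat.shape[1] * 50)
    c0 = coef[0] - coef[1]
    u = coef[2:]
    c = c0 + cone @ u
    return BSpline(t, c, k)


def fit_growth_curve(samples, region: BoneRegion | str | None = None,
                     quantity: str = "E2", max_interior_knots: int = 6) -> StiffnessGrowthCurve:
    """Fit a monotone-concave stiffness growth curve to age–modulus scatter.

    Parameters
    ----------
    samples : sequence of AgeModulusSample or (age, modulus) pairs
    region : restrict the fit to one region's samples (required when the
        samples mix regions); frontal resolves to parietal
    max_interior_knots : interior knots are placed at age quantiles, at most
        this many (fewer for small samples)

    Raises
    ------
    InsufficientDataError
        Fewer than 4 usable samples or fewer than 3 distinct ages.
    """
    pairs = []
    for s in samples:
        if isinstance(s, AgeModulusSample):
            if region is not None and s.region.resolve() is not BoneRegion.coerce(region).resolve():
                continue
            pairs.append((s.age, s.e2))
        else:
            pairs.append((float(s[0]), float(s[1])))
    if len(pairs) < 4:
        raise InsufficientDataError("need at least 4 age-modulus samples")
    arr = np.asarray(pairs, dtype=float)
    order = np.argsort(arr[:, 0])
    x, y = arr[order, 0], arr[order, 1]
    distinct = np.unique(x)
    if distinct.size < 3:
        raise InsufficientDataError("need samples at >= 3 distinct ages")

    k = 3
    n_interior = int(np.clip(distinct.size - (k + 1), 0, max_interior_knots))
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(distinct, qs)
    else:
        interior = np.array([])
    t = np.concatenate([[x[0]] * (k + 1), interior, [x[-1]] * (k + 1)])

    spline = _shape_constrained_spline(x, y, k, t)
    out_region = BoneRegion.coerce(region) if region is not None else BoneRegion.PARIETAL
    return StiffnessGrowthCurve(spline=spline, region=out_region, quantity=quantity)


@dataclass(frozen=True)
class OrthotropicConstants:
    """Nine orthotropic elastic constants plus density for skull bone.

    Invariants enforced at construction: E3 = E2, G31 = G12, the compliance
    symmetry nu21 = nu12 * E2 / E1, and positive definiteness of the 6x6
    compliance matrix (material stability).
    """

    rho: float                     # kg/m^3
    e1: float                      # MPa, parallel to fibre
    e2: float                      # MPa, perpendicular
    e3: float                      # MPa, through-thickness (= e2)
    nu12: float
    nu13: float
    nu23: float
    nu21: float
    g12: float                     # MPa
    g23: float                     # MPa
    g31: float                     # MPa (= g12)

    def __post_init__(self):
        for name in ("rho", "e1", "e2", "e3", "g12", "g23", "g31"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if not np.isclose(self.e3, self.e2, rtol=1e-9):
            raise DomainError("through-thickness modulus E3 must equal E2")
        if not np.isclose(self.g31, self.g12, rtol=1e-9):
            raise DomainError("shear modulus G31 must equal G12")
        if not np.isclose(self.nu21, self.nu12 * self.e2 / self.e1, rtol=1e-6):
            raise DomainError("nu21 must equal nu12 * E2 / E1 (compliance symmetry)")
        if not self.is_stable():
            raise StabilityError("compliance matrix is not positive definite")

    def compliance_matrix(self) -> np.ndarray:
        """6x6 orthotropic compliance in Voigt order (11, 22, 33, 23, 31, 12)."""
        e1, e2, e3 = self.e1, self.e2, self.e3
        s = np.zeros((6, 6))
        s[0, 0], s[1, 1], s[2, 2] = 1 / e1, 1 / e2, 1 / e3
        s[0, 1] = s[1, 0] = -self.nu12 / e1
        s[0, 2] = s[2, 0] = -self.nu13 / e1
        s[1, 2] = s[2, 1] = -self.nu23 / e2
        s[3, 3], s[4, 4], s[5, 5] = 1 / self.g23, 1 / self.g31, 1 / self.g12
        return s

    def is_stable(self) -> bool:
        """True if the compliance matrix is symmetric positive definite."""
        s = self.compliance_matrix()
        return bool(np.all(np.linalg.eigvalsh(s) > 0))

    def as_dict(self) -> dict[str, float]:
        return {
            "rho_kg_m3": self.rho,
            "E1_MPa": self.e1, "E2_MPa": self.e2, "E3_MPa": self.e3,
            "nu12": self.nu12, "nu13": self.nu13, "nu23": self.nu23, "nu21": self.nu21,
            "G12_MPa": self.g12, "G23_MPa": self.g23, "G31_MPa": self.g31,
        }


def assemble_orthotropic(e1: float, e2: float, nu12: float, nu13: float,
                         nu23: float, rho: float) -> OrthotropicConstants:
    """Assemble the nine orthotropic constants from (E1, E2) and Poisson ratios.

    Closures for the unmeasured constants:

    * ``E3 = E2`` (through-thickness equals perpendicular),
    * ``nu21 = nu12 * E2 / E1`` (compliance symmetry),
    * ``G23 = E2 / (2 (1 + nu23))`` — isotropic relation in the transverse
      plane,
    * ``G12 = G31 = sqrt(E1 E2) / (2 (1 + sqrt(nu12 nu21)))`` — Huber's
      geometric-mean estimate for the in-plane shear modulus of an
      orthotropic lamina.

    Raises a stability error if the resulting compliance matrix is not
    positive definite, and an anisotropy-order error if E2 > E1.
    """
    if not (e2 > 0 and e1 >= e2):
        raise DomainError("need E1 >= E2 > 0 (fibre direction is the stiffer one)")
    for nu in (nu12, nu13, nu23):
        if not 0 < nu < 0.5:
            raise DomainError("Poisson ratios must lie in (0, 0.5)")
    nu21 = nu12 * e2 / e1
    g23 = e2 / (2.0 * (1.0 + nu23))
    g12 = np.sqrt(e1 * e2) / (2.0 * (1.0 + np.sqrt(nu12 * nu21)))
    return OrthotropicConstants(
        rho=rho, e1=e1, e2=e2, e3=e2,
        nu12=nu12, nu13=nu13, nu23=nu23, nu21=nu21,
        g12=float(g12), g23=float(g23), g31=float(g12),
    )


def lookup_density(age: float, table: dict[float, float] | None = None) -> float:
    """Skull density [kg/m^3] at an age, linearly interpolated in the table
    and clamped to the nearest tabulated age outside it."""
    table = DEFAULT_DENSITY_TABLE if table is None else table
    ages = np.array(sorted(table))
    vals = np.array([table[a] for a in ages])
    return float(np.interp(age, ages, vals))


def material_card(
    age: float,
    region: BoneRegion | str,
    growth_curves: dict,
    model: AnisotropyModel = DEFAULT_ANISOTROPY,
    density_table: dict[float, float] | None = None,
    poisson: dict[str, float] | None = None,
) -> OrthotropicConstants:
    """Full orthotropic material card for a bone region at a given age.

    ``growth_curves`` maps each region to a pair of independently fitted
    growth curves ``{"E1": curve, "E2": curve}``; E1 and E2 are read off
    their own curves at the requested age (the anisotropy model enters only
    when the E1 curve is built, not at evaluation time).  Density comes from
    linear interpolation of the density table.
    """
    reg = BoneRegion.coerce(region).resolve()
    if reg not in growth_curves:
        raise DomainError(f"no growth curves provided for region {reg.value!r}")
    curves = growth_curves[reg]
    e1 = float(curves["E1"](age))
    e2 = float(curves["E2"](age))
    nu = DEFAULT_POISSON if poisson is None else poisson
    rho = lookup_density(age, density_table)
    return assemble_orthotropic(e1=e1, e2=e2, nu12=nu["nu12"], nu13=nu["nu13"],
                                nu23=nu["nu23"], rho=rho)
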