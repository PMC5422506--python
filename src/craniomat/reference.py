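"""Bundled reference material constants and score tables.

These are the published constitutive constants for the infant head-model
tissues (soft tissues and the age-group skull rows) and the published
correlation-score table for the validation drop tests.  They serve three
purposes: ready-to-use material definitions, fixtures for round-trip I/O
tests, and the ground truth for :func:`verify_reference_tables`, which
recomputes every derivable entry with the library's own closures and
reports agreement at printed precision.

Ages are in months since 40-week gestation; the "newborn" skull row
corresponds to a 34-week-gestation specimen, i.e. age -1.35 months.
"""

from __future__ import annotations

from .biofidelity import average_score
from .hyperelastic import MooneyRivlinMaterial, OgdenMaterial
from .skull_aging import (
    DEFAULT_POISSON,
    BoneRegion,
    StiffnessGrowthCurve,
    assemble_orthotropic,
)

__all__ = [
    "SUTURE",
    "SCALP_OUTER",
    "SCALP_INNER",
    "BRAIN",
    "DURA",
    "SOFT_TISSUE_DENSITIES",
    "SKULL_TABLE",
    "SKULL_REFERENCE_AGES",
    "CS_TABLE",
    "reference_growth_curves",
    "verify_reference_tables",
]

# ---------------------------------------------------------------------------
# Soft tissues (constants in Pa)

SUTURE = OgdenMaterial(terms=((1.48e4, 6.9),), label="suture")
SCALP_OUTER = OgdenMaterial(terms=((1.30e4, 24.2),), label="scalp outer")
SCALP_INNER = OgdenMaterial(terms=((3.99e3, 8.8),), label="scalp inner")
BRAIN = OgdenMaterial(terms=((53.8, 10.1), (-120.4, -12.9)), label="brain")
DURA = MooneyRivlinMaterial(c1=1.18e6, c2=0.295e6, label="dura mater")

#: Densities [kg/m^3] and Poisson ratios for the soft tissues.
SOFT_TISSUE_DENSITIES: dict[str, dict] = {
    "brain": {"rho": 1040.0, "nu": 0.5},
    "csf": {"rho": 1000.0, "nu": 0.5},
    "suture": {"rho": 1133.0, "nu": 0.499},
    "scalp outer": {"rho": 1133.0, "nu": 0.5},
    "scalp inner": {"rho": 1133.0, "nu": 0.5},
    "dura mater": {"rho": 1133.0, "nu": 0.49},
}

#: Reference stretch and target for the suture stiffness rescaling: the
#: single-specimen fit gives a tangent modulus of ~3.8 MPa at lambda = 2.5
#: and is scaled to the 8.1 MPa population average at the same stretch.
SUTURE_REF_STRETCH = 2.5
SUTURE_TARGET_MODULUS = 8.1e6  # Pa
SUTURE_SPECIMEN_MODULUS = 3.8e6  # Pa

# ---------------------------------------------------------------------------
# Skull bone rows per age group [months] and region (moduli in MPa)

SKULL_REFERENCE_AGES: dict[str, float] = {"newborn": -1.35, "5M": 5.0, "9M": 9.0}

#: Published per-age, per-region skull constants: density, the two
#: measured/derived Young's moduli, and the shear moduli they imply.
SKULL_TABLE: dict[tuple[str, str], dict[str, float]] = {
    ("newborn", "parietal"):  {"rho": 2150.0, "E1": 731.7, "E2": 266.2, "G23": 111.8, "G12": 194.8},
    ("newborn", "occipital"): {"rho": 2150.0, "E1": 555.5, "E2": 211.2, "G23": 88.7,  "G12": 150.8},
    ("5M", "parietal"):       {"rho": 2080.0, "E1": 849.3, "E2": 528.6, "G23": 222.1, "G12": 285.5},
    ("5M", "occipital"):      {"rho": 2080.0, "E1": 650.9, "E2": 392.9, "G23": 165.1, "G12": 215.9},
    ("9M", "parietal"):       {"rho": 2075.3, "E1": 878.7, "E2": 615.9, "G23": 258.7, "G12": 310.6},
    ("9M", "occipital"):      {"rho": 2075.3, "E1": 686.8, "E2": 474.6, "G23": 199.4, "G12": 241.3},
}

# ---------------------------------------------------------------------------
# Published correlation-score rows for the 30-cm drop validation tests

#: (age group, impact location) -> (N-phase, N-amp, N-shape, average)
CS_TABLE: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("newborn", "forehead"):       (98.98, 99.19, 99.44, 99.20),
    ("newborn", "occiput"):        (99.42, 97.32, 91.17, 95.97),
    ("newborn", "vertex"):         (98.89, 97.95, 91.25, 96.03),
    ("newborn", "right parietal"): (99.40, 90.14, 96.71, 95.41),
    ("newborn", "left parietal"):  (99.73, 88.65, 96.50, 94.96),
    ("5M", "right parietal"):      (97.54, 97.93, 94.33, 96.60),
    ("9M", "forehead"):            (93.08, 96.75, 93.95, 94.60),
    ("9M", "occiput"):             (99.37, 98.55, 98.40, 98.77),
    ("9M", "vertex"):              (99.09, 96.43, 99.77, 98.43),
    ("9M", "right parietal"):      (99.52, 92.87, 96.74, 96.38),
    ("9M", "left parietal"):       (87.79, 95.32, 91.91, 91.67),
}


def reference_growth_curves() -> dict[BoneRegion, dict[str, StiffnessGrowthCurve]]:
    """Piecewise-linear E1/E2 growth curves through the bundled skull rows.

    The three tabulated ages per region happen to be monotone with
    decreasing secant slopes, so the linear interpolant satisfies the
    monotone-concave shape constraints and reproduces each tabulated row
    exactly at its own age.
    """
    curves: dict[BoneRegion, dict[str, StiffnessGrowthCurve]] = {}
    for region in (BoneRegion.PARIETAL, BoneRegion.OCCIPITAL):
        ages = []
        e1s, e2s = [], []
        for group, age in sorted(SKULL_REFERENCE_AGES.items(), key=lambda kv: kv[1]):
            row = SKULL_TABLE[(group, region.value)]
            ages.append(age)
            e1s.append(row["E1"])
            e2s.append(row["E2"])
        curves[region] = {
            "E1": StiffnessGrowthCurve.from_points(ages, e1s, region=region, quantity="E1"),
            "E2": StiffnessGrowthCurve.from_points(ages, e2s, region=region, quantity="E2"),
        }
    return curves


def verify_reference_tables(shear_tol: float = 0.1, avg_tol: float = 0.01) -> dict:
    """Recompute every derivable bundled-table entry and report agreement.

    For each skull row, the shear moduli are re-derived from (E1, E2) and
    the default Poisson ratios through the library's orthotropic closure
    and compared with the stored values to within ``shear_tol`` MPa (one
    unit in the printed decimal); the compliance matrix is checked for
    positive definiteness.  For each score row the stored average is
    recomputed from its sub-scores.  Returns a machine-readable report.
    """
    report: dict = {"skull": {}, "scores": {}, "all_passed": True}
    for (group, region), row in SKULL_TABLE.items():
        card = assemble_orthotropic(
            e1=row["E1"], e2=row["E2"],
            nu12=DEFAULT_POISSON["nu12"], nu13=DEFAULT_POISSON["nu13"],
            nu23=DEFAULT_POISSON["nu23"], rho=row["rho"],
        )
        entry = {
            "G23_computed": round(card.g23, 4),
            "G23_stored": row["G23"],
            "G12_computed": round(card.g12, 4),
            "G12_stored": row["G12"],
            "stable": card.is_stable(),
        }
        entry["passed"] = bool(
            abs(card.g23 - row["G23"]) <= shear_tol
            and abs(card.g12 - row["G12"]) <= shear_tol
            and entry["stable"]
        )
        report["skull"][f"{group}/{region}"] = entry
        report["all_passed"] &= entry["passed"]
    for (group, location), (np_, na, ns, avg) in CS_TABLE.items():
        computed = average_score(np_, na, ns)
        entry = {
            "average_computed": round(computed, 2),
            "average_stored": avg,
            "passed": bool(abs(computed - avg) <= avg_tol + 1e-12),
        }
        report["scores"][f"{group}/{location}"] = entry
        report["all_passed"] &= entry["passed"]
    report["all_passed"] = bool(report["all_passed"])
    return report
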