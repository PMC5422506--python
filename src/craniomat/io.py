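"""File formats: curve CSV, material JSON, and material-card export.

One CSV dialect is used throughout — comma separated, dot decimal, header
required — with the unit embedded in the header so Pa/MPa mix-ups fail
loudly:

* uniaxial curves:  ``stretch,stress_Pa``
* time signals:     ``time_s,value``
* age–modulus data: ``age_months,E2_MPa,region``

Material JSON carries an explicit ``model`` and ``units`` field.  Material
cards can be exported as JSON or as a solver-style keyword text block.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .biofidelity import SignalCurve
from .exceptions import ParseError
from .hyperelastic import MooneyRivlinMaterial, OgdenMaterial, UniaxialCurve
from .skull_aging import AgeModulusSample, OrthotropicConstants

__all__ = [
    "read_uniaxial_csv",
    "write_uniaxial_csv",
    "read_signal_csv",
    "write_signal_csv",
    "read_age_modulus_csv",
    "write_age_modulus_csv",
    "material_to_dict",
    "material_from_dict",
    "read_material_json",
    "write_material_json",
    "export_material_card",
]

_FLOAT_FMT = "{:.17g}"


def _read_two_column(path, col_a: str, col_b: str) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    a_vals, b_vals = [], []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        header = [h.strip() for h in header]
        if header[:2] != [col_a, col_b]:
            raise ParseError(f"expected header '{col_a},{col_b}', got {','.join(header)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 2:
                raise ParseError("expected two columns", line=lineno)
            try:
                a_vals.append(float(row[0]))
                b_vals.append(float(row[1]))
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
    if len(a_vals) < 2:
        raise ParseError("need at least two data rows")
    return np.array(a_vals), np.array(b_vals)


def _write_rows(path, header: list[str], columns) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for row in zip(*columns):
            writer.writerow([_FLOAT_FMT.format(v) if isinstance(v, float) else v for v in row])


def read_uniaxial_csv(path) -> UniaxialCurve:
    stretch, stress = _read_two_column(path, "stretch", "stress_Pa")
    return UniaxialCurve(stretch=stretch, stress=stress)


def write_uniaxial_csv(curve: UniaxialCurve, path) -> None:
    _write_rows(path, ["stretch", "stress_Pa"],
                (curve.stretch.tolist(), curve.stress.tolist()))


def read_signal_csv(path, kind: str = "acceleration_g") -> SignalCurve:
    time, value = _read_two_column(path, "time_s", "value")
    return SignalCurve(time=time, value=value, kind=kind)


def write_signal_csv(curve: SignalCurve, path) -> None:
    _write_rows(path, ["time_s", "value"],
                (curve.time.tolist(), curve.value.tolist()))


def read_age_modulus_csv(path) -> list[AgeModulusSample]:
    path = Path(path)
    samples = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip() for h in next(reader)]
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        if header[:3] != ["age_months", "E2_MPa", "region"]:
            raise ParseError("expected header 'age_months,E2_MPa,region'", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ParseError("expected three columns", line=lineno)
            try:
                samples.append(AgeModulusSample(age=float(row[0]), e2=float(row[1]),
                                                region=row[2].strip()))
            except ValueError as exc:
                raise ParseError(str(exc), line=lineno) from None
    if not samples:
        raise ParseError("no data rows")
    return samples


def write_age_modulus_csv(samples, path) -> None:
    _write_rows(
        path,
        ["age_months", "E2_MPa", "region"],
        ([s.age for s in samples], [s.e2 for s in samples],
         [s.region.value for s in samples]),
    )


def material_to_dict(material: OgdenMaterial | MooneyRivlinMaterial) -> dict:
    """Serialize a hyperelastic material (constants kept in Pa)."""
    if isinstance(material, OgdenMaterial):
        return {
            "model": "ogden",
            "units": "Pa",
            "label": material.label,
            "terms": [{"mu": mu, "alpha": alpha} for mu, alpha in material.terms],
        }
    if isinstance(material, MooneyRivlinMaterial):
        return {"model": "mooney_rivlin", "units": "Pa", "label": material.label,
                "c1": material.c1, "c2": material.c2}
    raise ParseError(f"unsupported material type: {type(material).__name__}")


def material_from_dict(data: dict) -> OgdenMaterial | MooneyRivlinMaterial:
    """Deserialize a material; 'MPa' units are converted to Pa on load."""
    try:
        model = data["model"]
        scale = {"Pa": 1.0, "MPa": 1.0e6}[data.get("units", "Pa")]
        label = data.get("label", "")
        if model == "ogden":
            terms = tuple((t["mu"] * scale, t["alpha"]) for t in data["terms"])
            return OgdenMaterial(terms=terms, label=label)
        if model == "mooney_rivlin":
            return MooneyRivlinMaterial(c1=data["c1"] * scale, c2=data["c2"] * scale,
                                        label=label)
    except KeyError as exc:
        raise ParseError(f"missing material field {exc}") from None
    raise ParseError(f"unknown material model: {model!r}")


def read_material_json(path) -> OgdenMaterial | MooneyRivlinMaterial:
    with Path(path).open() as fh:
        return material_from_dict(json.load(fh))


def write_material_json(material, path) -> None:
    with Path(path).open("w") as fh:
        json.dump(material_to_dict(material), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _card_dict(constants) -> dict:
    if isinstance(constants, OrthotropicConstants):
        return {"model": "orthotropic_elastic", **constants.as_dict()}
    return material_to_dict(constants)


def export_material_card(constants, path, format: str = "json") -> None:
    """Write a material card as JSON or a solver-style keyword text block.

    Output is deterministic: the same input always produces identical
    bytes (sorted keys, fixed float formatting).
    """
    path = Path(path)
    card = _card_dict(constants)
    if format == "json":
        with path.open("w") as fh:
            json.dump(card, fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "keyword":
        lines = ["*MATERIAL_CARD"]
        for key in sorted(card):
            value = card[key]
            if isinstance(value, float):
                value = _FLOAT_FMT.format(value)
            elif isinstance(value, list):
                value = "; ".join(
                    ",".join(f"{k}={_FLOAT_FMT.format(v)}" for k, v in sorted(item.items()))
                    for item in value
                )
            lines.append(f"$ {key} = {value}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ParseError(f"unknown export format: {format!r}")
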