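"""Molecular-formula annotation and ink-signature marker detection.

Observed diagnostic ions are annotated by computing the theoretical m/z of
a candidate formula's adduct ion ([M+H]+ or [M+K]+, singly charged) from
pinned monoisotopic atomic masses and matching within a ppm tolerance.
Separately, empirical marker ions characteristic of historical ink types
(iron gall, ivory black) are looked up directly in a sample's peak list;
both markers firing at once is the signature of a mixed ink.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .spectra_io import SamplePeakList

# Monoisotopic atomic masses (Da), pinned for bit-stable results.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "K": 38.9637069,
}
ELECTRON_MASS = 0.00054858

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

DEFAULT_PPM_TOL = 5.0


@dataclass(frozen=True)
class Adduct:
    """A singly-charged positive adduct: m/z = (M + mass_delta) / charge."""

    name: str
    mass_delta: float
    charge: int = 1


ADDUCTS: dict[str, Adduct] = {
    "M+H": Adduct("M+H", MONOISOTOPIC_MASS["H"] - ELECTRON_MASS),
    "M+K": Adduct("M+K", MONOISOTOPIC_MASS["K"] - ELECTRON_MASS),
}


@dataclass(frozen=True)
class FormulaAnnotation:
    """A formula assigned to an observed peak via one adduct."""

    observed_mz: float
    formula: str
    adduct: Adduct
    theoretical_mz: float
    ppm_error: float


@dataclass(frozen=True)
class DiagnosticEntry:
    """One row of the shipped diagnostic-ion table."""

    author: str
    observed_mz: float
    annotation: str
    formula: str
    adduct: str
    source: str


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse a Hill-notation formula string (e.g. ``"C11H10O4"``).

    No isotopes, charges or parentheses; elements must be in the embedded
    mass table.  Mappings pass through (validated).
    """
    if isinstance(formula, Mapping):
        counts = {el: int(n) for el, n in formula.items() if n}
    else:
        if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
            raise ValidationError(f"cannot parse formula {formula!r}")
        counts = {}
        for el, num in _FORMULA_TOKEN.findall(formula):
            if not el:
                continue
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    for el, n in counts.items():
        if el not in MONOISOTOPIC_MASS:
            raise ValidationError(f"unknown element {el!r} in formula")
        if n < 0:
            raise ValidationError("element counts must be non-negative")
    if not counts or all(n == 0 for n in counts.values()):
        raise ValidationError("formula must contain at least one atom")
    return counts


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Monoisotopic (exact) neutral mass of a formula, in Da."""
    counts = parse_formula(formula)
    return float(sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items()))


def adduct_mz(neutral_mass: float, adduct: Adduct | str) -> float:
    """Theoretical m/z of an adduct ion of a neutral of the given mass."""
    if isinstance(adduct, str):
        adduct = ADDUCTS[adduct]
    return (neutral_mass + adduct.mass_delta) / adduct.charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in ppm."""
    return (observed - theoretical) / theoretical * 1e6


def match_formula(
    peaks: Sequence[float],
    formula: str | Mapping[str, int],
    adducts: Iterable[Adduct | str] = ("M+H",),
    ppm_tol: float = DEFAULT_PPM_TOL,
) -> FormulaAnnotation | None:
    """Assign a formula to the best-matching observed peak, if any.

    Over all (peak, adduct) pairs within ``ppm_tol`` of the theoretical
    adduct m/z, the pair with the smallest absolute ppm error wins; the
    result is independent of the order of ``peaks``.  Returns ``None``
    when nothing qualifies.
    """
    if ppm_tol <= 0:
        raise ValidationError("ppm_tol must be > 0")
    mass = monoisotopic_mass(formula)
    name = formula if isinstance(formula, str) else "".join(
        f"{el}{n}" for el, n in sorted(formula.items())
    )
    best: FormulaAnnotation | None = None
    for adduct in adducts:
        ad = ADDUCTS[adduct] if isinstance(adduct, str) else adduct
        theo = adduct_mz(mass, ad)
        for mz in peaks:
            err = ppm_error(float(mz), theo)
            if abs(err) <= ppm_tol and (best is None or abs(err) < abs(best.ppm_error)):
                best = FormulaAnnotation(
                    observed_mz=float(mz),
                    formula=name,
                    adduct=ad,
                    theoretical_mz=theo,
                    ppm_error=err,
                )
    return best


# ---------------------------------------------------------------------------
# Shipped diagnostic and ink-marker tables


def _data_path(name: str) -> Path:
    return Path(str(resources.files("inkms").joinpath("data", name)))


def load_diagnostic_table(path: str | Path | None = None) -> list[DiagnosticEntry]:
    """Load the shipped (or a user-supplied) diagnostic-ion table."""
    path = _data_path("diagnostic_peaks.csv") if path is None else Path(path)
    entries = []
    with open(path, encoding="utf-8") as fh:
        rows = [r for r in fh if not r.startswith("#")]
    for rec in csv.DictReader(rows):
        entries.append(
            DiagnosticEntry(
                author=rec["author"],
                observed_mz=float(rec["observed_mz"]),
                annotation=rec["annotation"],
                formula=rec["formula"],
                adduct=rec["adduct"],
                source=rec["source"],
            )
        )
    return entries


def diagnostic_peaks(author: str | None = None) -> list[float]:
    """The curated diagnostic m/z list (16 ions; optionally one author)."""
    return [
        e.observed_mz
        for e in load_diagnostic_table()
        if e.source == "table" and (author is None or e.author == author)
    ]


@dataclass(frozen=True)
class InkMarkerTable:
    """Empirical single-ion markers for ink types."""

    markers: tuple[tuple[str, float], ...]

    @classmethod
    def default(cls, path: str | Path | None = None) -> "InkMarkerTable":
        path = _data_path("ink_markers.csv") if path is None else Path(path)
        with open(path, encoding="utf-8") as fh:
            rows = [r for r in fh if not r.startswith("#")]
        markers = tuple(
            (rec["ink_name"], float(rec["marker_mz"])) for rec in csv.DictReader(rows)
        )
        return cls(markers=markers)


def detect_ink_signature(
    sample: SamplePeakList,
    markers: InkMarkerTable | None = None,
    ppm_tol: float = DEFAULT_PPM_TOL,
) -> list[tuple[str, bool, float | None]]:
    """Check a normalized sample for each ink marker ion.

    Returns, per marker, ``(ink_name, detected, matched_mz)`` where
    ``matched_mz`` is the closest peak within ``ppm_tol`` (else ``None``).
    Several markers detecting at once indicates a mixed ink.
    """
    if not sample.normalized:
        raise ValidationError("detect_ink_signature expects a normalized sample")
    if markers is None:
        markers = InkMarkerTable.default()
    out = []
    for ink_name, marker_mz in markers.markers:
        hit = None
        best_err = None
        for mz in sample.mz:
            err = abs(ppm_error(float(mz), marker_mz))
            if err <= ppm_tol and (best_err is None or err < best_err):
                hit, best_err = float(mz), err
        out.append((ink_name, hit is not None, hit))
    return out


def annotate_features(
    feature_mz: Sequence[float], ppm_tol: float = DEFAULT_PPM_TOL
) -> list[dict]:
    """Annotate a feature m/z list against the shipped diagnostic table.

    For each table entry carrying a predicted formula, the feature list is
    searched with :func:`match_formula`; entries without a formula are
    matched directly by ppm distance to the printed m/z.  Returns report
    rows (dicts) suitable for CSV export.
    """
    rows = []
    for entry in load_diagnostic_table():
        if entry.formula:
            ann = match_formula(
                feature_mz, entry.formula, adducts=(entry.adduct or "M+H",),
                ppm_tol=ppm_tol,
            )
            if ann is not None:
                rows.append(
                    {
                        "observed_mz": ann.observed_mz,
                        "formula": entry.formula,
                        "adduct": ann.adduct.name,
                        "theoretical_mz": ann.theoretical_mz,
                        "ppm_error": ann.ppm_error,
                        "annotation_name": entry.annotation,
                        "author": entry.author,
                    }
                )
        else:
            close = [
                float(mz)
                for mz in feature_mz
                if abs(ppm_error(float(mz), entry.observed_mz)) <= ppm_tol
            ]
            if close:
                obs = min(close, key=lambda mz: abs(ppm_error(mz, entry.observed_mz)))
                rows.append(
                    {
                        "observed_mz": obs,
                        "formula": "",
                        "adduct": "",
                        "theoretical_mz": entry.observed_mz,
                        "ppm_error": ppm_error(obs, entry.observed_mz),
                        "annotation_name": entry.annotation,
                        "author": entry.author,
                    }
                )
    return rows
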