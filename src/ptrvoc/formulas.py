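"""Elemental formula assignment for protonated PTR-TOF-MS ions.

PTR ionization transfers a proton from H3O+ to any analyte whose proton
affinity exceeds that of water, so a compound of neutral monoisotopic mass M
is detected at m/z = M + m(H+).  Candidate formulas for a measured m/z are
found by exhaustive enumeration over CHNOS element-count bounds, constrained
by the nitrogen-free valence bound H <= 2C + 2 + N and a non-negative
rings-plus-double-bond equivalent (RDBE).  A candidate can additionally be
checked against the observed 13C isotopologue: the M+1 channel sits
1.003355 Th above the monoisotopic ion with an expected intensity ratio of
n_C * a / (1 - a), where a = 0.0107 is the natural 13C abundance.  Minor
isotopes of other elements (2H, 17O, 33S) contribute well under 1% of M+1
for small volatiles and are deliberately ignored.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "C13_MINUS_C12",
    "C13_ABUNDANCE",
    "DEFAULT_BOUNDS",
    "FormulaCandidate",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "rdbe",
    "expected_m1_ratio",
    "enumerate_formulas",
    "check_isotope_support",
]

#: IUPAC monoisotopic masses (Da) of the elements considered, with the
#: maximum count used by the default enumeration bounds.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

PROTON_MASS = 1.007276  # Da; a proton, not a hydrogen atom
C13_MINUS_C12 = 1.003355  # Da
C13_ABUNDANCE = 0.0107

DEFAULT_BOUNDS: Mapping[str, int] = {"C": 20, "H": 40, "N": 3, "O": 6, "S": 2}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str | Mapping[str, int]) -> dict[str, int]:
    """Parse ``"C8H8O2"`` into element counts. Mappings pass through."""
    if isinstance(formula, Mapping):
        counts = {el: int(n) for el, n in formula.items() if n}
    else:
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            el, num = match.groups()
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r}")
    for el in counts:
        if el not in MONOISOTOPIC_MASS:
            raise KeyError(f"unknown element {el!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Canonical CHNOS-order string; empty formula renders as ''."""
    order = ["C", "H", "N", "O", "S"]
    parts = []
    for el in order:
        n = counts.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Sum of element counts times monoisotopic masses, in Da."""
    counts = parse_formula(formula)
    return sum(n * MONOISOTOPIC_MASS[el] for el, n in counts.items())


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero, the convention used for reported m/z."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def protonated_mz(formula: str | Mapping[str, int], decimals: int = 3) -> float:
    """m/z of the (M)H+ ion, rounded to ``decimals`` (half away from zero)."""
    return round_half_away(monoisotopic_mass(formula) + PROTON_MASS, decimals)


def rdbe(counts: Mapping[str, int]) -> float:
    """Rings-plus-double-bond equivalents: C - H/2 + N/2 + 1."""
    return counts.get("C", 0) - counts.get("H", 0) / 2 + counts.get("N", 0) / 2 + 1


def expected_m1_ratio(n_carbons: int) -> float:
    """Expected (M+1)/M intensity ratio from natural 13C abundance."""
    if n_carbons < 0:
        raise ValueError("carbon count must be non-negative")
    return n_carbons * C13_ABUNDANCE / (1.0 - C13_ABUNDANCE)


@dataclass(frozen=True)
class FormulaCandidate:
    """One candidate assignment for a measured protonated m/z."""

    counts: Mapping[str, int]
    formula: str
    theoretical_mz: float
    error_mda: float  # measured - theoretical, in milli-Th, signed
    rdbe: float
    expected_m1_ratio: float

    def n_heteroatoms(self) -> int:
        return sum(self.counts.get(el, 0) for el in ("N", "O", "S"))


def _valid(counts: Mapping[str, int]) -> bool:
    c = counts.get("C", 0)
    h = counts.get("H", 0)
    n = counts.get("N", 0)
    if h > 2 * c + 2 + n:
        return False
    return rdbe(counts) >= 0


def enumerate_formulas(
    mz: float,
    tolerance_mda: float = 5.0,
    bounds: Mapping[str, int] | None = None,
) -> list[FormulaCandidate]:
    """Exhaustively enumerate CHNOS formulas whose protonated mass matches ``mz``.

    Candidates satisfy the valence bound and RDBE >= 0 and have
    ``|protonated mass - mz| <= tolerance_mda`` (in milli-Th, on the exact,
    unrounded theoretical mass).  Sorted by absolute mass error, ties broken
    by fewer heteroatoms and then ascending carbon count.  The empty formula
    (bare H3O+-transferred proton) is a legal candidate.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    if tolerance_mda <= 0:
        raise ValueError("tolerance must be positive")
    b = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    if not b or any(v < 0 for v in b.values()):
        raise ValueError("element bounds must be non-negative and non-empty")
    tol_da = tolerance_mda / 1000.0
    target = mz - PROTON_MASS  # neutral monoisotopic mass window
    m = MONOISOTOPIC_MASS

    out: list[FormulaCandidate] = []
    for c in range(b.get("C", 0) + 1):
        mass_c = c * m["C"]
        if mass_c > target + tol_da:
            break
        for s in range(b.get("S", 0) + 1):
            mass_cs = mass_c + s * m["S"]
            if mass_cs > target + tol_da:
                break
            for o in range(b.get("O", 0) + 1):
                mass_cso = mass_cs + o * m["O"]
                if mass_cso > target + tol_da:
                    break
                for n in range(b.get("N", 0) + 1):
                    mass_cson = mass_cso + n * m["N"]
                    if mass_cson > target + tol_da:
                        break
                    # remaining mass must be filled by hydrogens
                    h_float = (target - mass_cson) / m["H"]
                    h_slack = tol_da / m["H"]
                    h_lo = max(0, math.floor(h_float - h_slack))
                    h_hi = min(b.get("H", 0), math.ceil(h_float + h_slack))
                    for h in range(h_lo, h_hi + 1):
                        counts = {
                            el: v
                            for el, v in (("C", c), ("H", h), ("N", n), ("O", o), ("S", s))
                            if v
                        }
                        mass = mass_cson + h * m["H"]
                        err_da = mz - (mass + PROTON_MASS)
                        if abs(err_da) > tol_da:
                            continue
                        if not _valid(counts):
                            continue
                        out.append(
                            FormulaCandidate(
                                counts=counts,
                                formula=format_formula(counts),
                                theoretical_mz=round_half_away(mass + PROTON_MASS, 3),
                                error_mda=err_da * 1000.0,
                                rdbe=rdbe(counts),
                                expected_m1_ratio=expected_m1_ratio(counts.get("C", 0)),
                            )
                        )
    out.sort(key=lambda f: (abs(f.error_mda), f.n_heteroatoms(), f.counts.get("C", 0)))
    return out


def check_isotope_support(
    main_conc: float,
    plus1_conc: float,
    candidate: FormulaCandidate,
    rel_tolerance: float = 0.10,
) -> tuple[bool, float]:
    """Check the observed (M+1)/M ratio against a candidate's 13C expectation.

    Returns ``(supported, observed_ratio)``; supported iff the observed ratio
    lies within ``rel_tolerance`` (relative) of the candidate's expectation.
    Carbon-free candidates are never isotope-supported (expected ratio 0).
    """
    if main_conc <= 0:
        raise ValueError("main-channel concentration must be positive")
    observed = plus1_conc / main_conc
    expected = candidate.expected_m1_ratio
    if expected <= 0:
        return False, observed
    return abs(observed / expected - 1.0) <= rel_tolerance, observed
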