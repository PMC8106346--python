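"""Monoisotopic mass arithmetic, adduct m/z, mass errors, formula search.

Masses use the most abundant isotope of each element; adducts assume singly
charged ions and use the proton mass (not the hydrogen-atom mass), so the
electron is accounted for — standard practice in high-resolution MS. Mass
errors are always reported in both millidaltons (absolute) and ppm
(relative) with explicit labels, because a bare number with a wrong unit
label is a classic source of mis-identification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# Monoisotopic atomic masses (Da), CODATA/AME-derived values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "P": 30.97376200,
    "S": 31.97207117,
}

PROTON_MASS = 1.00727646

ADDUCT_SHIFT = {"[M+H]+": PROTON_MASS, "[M-H]-": -PROTON_MASS}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """A molecular formula as an element -> count map."""

    counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if not any(n > 0 for _, n in self.counts):
            raise ValueError("formula must contain at least one atom")
        if any(n < 0 for _, n in self.counts):
            raise ValueError("negative element count")

    @classmethod
    def from_dict(cls, counts: dict[str, int]) -> "Formula":
        return cls(tuple(sorted((e, n) for e, n in counts.items() if n > 0)))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        d = self.as_dict()
        parts = []
        for e in ["C", "H"] + sorted(set(d) - {"C", "H"}):
            if d.get(e, 0) > 0:
                parts.append(e if d[e] == 1 else f"{e}{d[e]}")
        return "".join(parts)


@dataclass(frozen=True)
class MassError:
    observed_mz: float
    theoretical_mz: float

    @property
    def delta_mda(self) -> float:
        """Absolute error in millidaltons: (observed - theoretical) x 1000."""
        return (self.observed_mz - self.theoretical_mz) * 1000.0

    @property
    def delta_ppm(self) -> float:
        """Relative error in parts per million."""
        return (self.observed_mz - self.theoretical_mz) / self.theoretical_mz * 1e6

    def report(self) -> str:
        return (
            f"observed {self.observed_mz:.5f}, theoretical {self.theoretical_mz:.5f}: "
            f"error {self.delta_mda:+.3f} mDa ({self.delta_ppm:+.3f} ppm)"
        )


def parse_formula(text: str, elements: dict[str, float] | None = None) -> Formula:
    """Parse a Hill-style formula string such as ``C27H22O11``."""
    masses = elements or MONOISOTOPIC_MASS
    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = match.end()
        element, digits = match.groups()
        if element not in masses:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return Formula.from_dict(counts)


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic mass in Da: sum of counts times monoisotopic atomic masses."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts)


def adduct_mz(M: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion of neutral mass ``M``."""
    if M <= 0:
        raise ValueError("neutral mass must be > 0")
    if adduct not in ADDUCT_SHIFT:
        raise ValueError(f"unsupported adduct {adduct!r}; use one of {sorted(ADDUCT_SHIFT)}")
    return M + ADDUCT_SHIFT[adduct]


def mass_error(observed_mz: float, f: Formula, adduct: str = "[M+H]+") -> MassError:
    """Mass error of an observed m/z against a formula's adduct ion."""
    if observed_mz <= 0:
        raise ValueError("observed m/z must be > 0")
    return MassError(observed_mz, adduct_mz(monoisotopic_mass(f), adduct))


def rdbe(f: Formula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + (N+P)/2 + 1."""
    d = f.as_dict()
    return d.get("C", 0) - d.get("H", 0) / 2 + (d.get("N", 0) + d.get("P", 0)) / 2 + 1


def find_formulas(
    observed_mz: float,
    adduct: str,
    tol_mda: float,
    element_bounds: dict[str, int],
    rdbe_filter: bool = False,
) -> list[tuple[Formula, float]]:
    """Enumerate candidate formulas within ``tol_mda`` of an observed adduct m/z.

    Exhaustive depth-first enumeration over the finite per-element bounds,
    pruned by remaining achievable mass. Returns (formula, delta_mda) pairs
    sorted by |delta_mda| (ties by formula string). ``rdbe_filter`` drops
    chemically implausible candidates with RDBE < 0 (off by default).
    """
    for e in element_bounds:
        if e not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {e!r} in bounds")
    target = observed_mz - ADDUCT_SHIFT[adduct]
    tol_da = tol_mda / 1000.0
    elements = sorted(element_bounds, key=lambda e: -MONOISOTOPIC_MASS[e])
    results: list[tuple[Formula, float]] = []

    def recurse(idx: int, counts: dict[str, int], mass: float) -> None:
        if mass > target + tol_da:
            return
        if idx == len(elements):
            if abs(mass - target) <= tol_da and any(counts.values()):
                f = Formula.from_dict(counts)
                if rdbe_filter and rdbe(f) < 0:
                    return
                results.append((f, (target - mass) * 1000.0))
            return
        e = elements[idx]
        em = MONOISOTOPIC_MASS[e]
        # remaining elements can only add mass, so prune on the lower bound
        for n in range(element_bounds[e] + 1):
            new_mass = mass + n * em
            if new_mass > target + tol_da:
                break
            counts[e] = n
            recurse(idx + 1, counts, new_mass)
        counts.pop(e, None)

    recurse(0, {}, 0.0)
    results.sort(key=lambda t: (abs(t[1]), str(t[0])))
    return results
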