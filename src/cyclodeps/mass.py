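"""Elemental formulas and exact monoisotopic mass arithmetic.

All ion m/z, ppm-deviation, and ring-double-bond-equivalent (RDBE)
calculations in the package go through this module.  Atomic masses are
read from a plain-text constants table shipped with the package
(``data/elements.tsv``, IUPAC monoisotopic values quoted to >= 7
decimals).
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "Formula",
    "FormulaError",
    "IonSpecies",
    "MassValue",
    "delta_ppm",
    "ion_mz",
    "monoisotopic_mass",
    "parse_formula",
    "ppm_error",
    "rdbe",
]

#: Electron rest mass in Da (CODATA).  Subtracted once per positive charge
#: and added once per negative charge when converting neutral mass to m/z.
ELECTRON_MASS = 0.000548579909


def _load_element_table() -> dict[str, float]:
    table: dict[str, float] = {}
    text = resources.files("cyclodeps.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, mass = line.split("\t")
        table[symbol] = float(mass)
    return table


#: Monoisotopic atomic mass of the most abundant isotope, by element symbol.
MONOISOTOPIC_MASS: dict[str, float] = _load_element_table()


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid formula arithmetic."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """Immutable element -> count map with element-wise arithmetic.

    Counts are non-negative integers; zero-count entries are dropped, so
    two formulas are equal iff they have identical non-zero counts.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, /, **kw: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kw:
            for element, n in source.items():
                merged[element] = merged.get(element, 0) + int(n)
        for element, n in merged.items():
            if n < 0:
                raise FormulaError(f"negative count for element {element!r}: {n}")
        self._counts = {e: n for e, n in sorted(merged.items()) if n > 0}
        self._hash = hash(tuple(self._counts.items()))

    @classmethod
    def parse(cls, text: str) -> "Formula":
        return parse_formula(text)

    # -- Mapping protocol --------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts.get(element, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, element: object) -> bool:
        return element in self._counts

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) + n
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        if not isinstance(other, Formula):
            return NotImplemented
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) - n
            if counts[e] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {e!r} "
                    f"({self.hill()} - {other.hill()})"
                )
        return Formula(counts)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int):
            return NotImplemented
        if k < 0:
            raise FormulaError("formula multiplier must be non-negative")
        return Formula({e: n * k for e, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return self._hash

    def hill(self) -> str:
        """Canonical Hill-order string (C, H, then alphabetical)."""
        parts: list[str] = []
        order: list[str]
        if "C" in self._counts:
            order = ["C"] + (["H"] if "H" in self._counts else [])
            order += sorted(e for e in self._counts if e not in ("C", "H"))
        else:
            order = sorted(self._counts)
        for e in order:
            n = self._counts[e]
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string such as ``"C44H64N4O8"``.

    Implicit counts are 1.  A trailing charge sign (``+``/``-``, ASCII or
    Unicode minus) is ignored; charge state is the business of
    :class:`IonSpecies`, not of the formula grammar.
    """
    if not isinstance(text, str):
        raise FormulaError(f"expected a formula string, got {type(text).__name__}")
    stripped = text.strip().rstrip("+-−^")
    if not stripped:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if m is None or m.end() == pos:
            raise FormulaError(
                f"cannot parse formula {text!r} at position {pos} ({stripped[pos:]!r})"
            )
        symbol, digits = m.groups()
        if symbol not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula(counts)


def monoisotopic_mass(f: Formula | Mapping[str, int]) -> float:
    """Neutral monoisotopic mass in Da (sum of tabulated atomic masses)."""
    total = 0.0
    for element, n in f.items():
        try:
            total += MONOISOTOPIC_MASS[element] * n
        except KeyError:
            raise FormulaError(f"no tabulated monoisotopic mass for {element!r}") from None
    return total


@dataclass(frozen=True)
class MassValue:
    """A tagged mass: either a neutral monoisotopic mass (Da) or an m/z (Th)."""

    value: float
    kind: str  # "neutral_mass" | "mz"

    def __post_init__(self) -> None:
        if self.kind not in ("neutral_mass", "mz"):
            raise ValueError(f"unknown mass kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError(f"mass value must be positive, got {self.value}")


# Adduct name -> (element deltas applied to the neutral formula, charge).
_ADDUCTS: dict[str, tuple[dict[str, int], int]] = {
    "M+H": ({"H": +1}, +1),
    "M+Na": ({"Na": +1}, +1),
    "M+NH4": ({"N": +1, "H": +4}, +1),
    "M+K": ({"K": +1}, +1),
    "M-H": ({"H": -1}, -1),
}


@dataclass(frozen=True)
class IonSpecies:
    """An adduct/charge pair such as [M+H]+, [M+Na]+ or [M-H]-.

    The adduct delta and the charge sign must be mutually consistent:
    ``M-H`` is the only negative species admitted here.
    """

    adduct: str
    charge: int = field(default=0)

    def __post_init__(self) -> None:
        name = self.adduct.replace("−", "-").replace(" ", "")
        if name.startswith("[") and name.endswith("]"):
            name = name[1:-1]
        object.__setattr__(self, "adduct", name)
        if name not in _ADDUCTS:
            raise ValueError(
                f"unknown adduct {self.adduct!r}; known: {sorted(_ADDUCTS)}"
            )
        _, default_charge = _ADDUCTS[name]
        charge = self.charge if self.charge != 0 else default_charge
        object.__setattr__(self, "charge", charge)
        if charge == 0:
            raise ValueError("ion charge must be non-zero")
        if (charge > 0) != (default_charge > 0):
            raise ValueError(
                f"adduct {name!r} is only consistent with "
                f"{'positive' if default_charge > 0 else 'negative'} charge"
            )

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"

    @property
    def delta(self) -> dict[str, int]:
        """Signed element deltas the adduct applies to the neutral formula."""
        return dict(_ADDUCTS[self.adduct][0])

    @property
    def delta_mass(self) -> float:
        return sum(MONOISOTOPIC_MASS[e] * n for e, n in self.delta.items())

    def apply(self, neutral: Formula) -> Formula:
        """Elemental composition of the charged species (e.g. C...Na+)."""
        counts = dict(neutral)
        for e, n in self.delta.items():
            counts[e] = counts.get(e, 0) + n
            if counts[e] < 0:
                raise FormulaError(
                    f"adduct {self.adduct} cannot be formed from {neutral.hill()}"
                )
        return Formula(counts)

    def __str__(self) -> str:
        sign = "+" if self.charge > 0 else "-"
        mag = abs(self.charge)
        return f"[{self.adduct}]{mag if mag > 1 else ''}{sign}"


def ion_mz(f: Formula, species: IonSpecies) -> float:
    """m/z of the given neutral formula under the given ion species.

    m/z = (M + adduct_delta - z * m_e) / |z|, with the electron-mass
    correction applied per charge.
    """
    if species.charge == 0:
        raise ValueError("ion charge must be non-zero")
    m = monoisotopic_mass(f) + species.delta_mass - species.charge * ELECTRON_MASS
    return m / abs(species.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass deviation in parts per million."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    if observed <= 0:
        raise ValueError(f"observed m/z must be positive, got {observed}")
    return 1e6 * (observed - theoretical) / theoretical


def delta_ppm(observed: float, theoretical: float, decimals: int = 1) -> float:
    """Unsigned ppm deviation, rounded half-up to ``decimals`` places.

    This matches the unsigned one-decimal convention used in analytical
    reporting tables.
    """
    value = abs(ppm_error(observed, theoretical))
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def rdbe(f: Formula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1.

    Defined for neutral CHNOS(+Na) formulas; O, S and Na do not enter the
    count (the standard CHN rule).
    """
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1
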