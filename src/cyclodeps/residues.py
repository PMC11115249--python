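"""Residue alphabet and the directed cyclic depsipeptide sequence type.

Residue formulas are stored DEHYDRATED (free acid minus H2O), so the
neutral formula of a macrocycle is the plain element-wise sum of its
residues: cyclization consumes exactly the waters the dehydrated
convention already removed.  A linear peptide would add back one H2O;
linear chains are not modelled here.

Sequence direction convention: in a residue list ``[r0, r1, ..., rn-1]``
the linkage at index ``i`` joins ``r[i]`` (acceptor, bonding through its
alpha-amino or alpha-hydroxy group) to ``r[(i+1) % n]`` (acyl donor).
The linkage is an ester iff the acceptor is a hydroxy-acid residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .mass import Formula, monoisotopic_mass, parse_formula

__all__ = [
    "LXX_ALIASES",
    "CyclicDepsipeptide",
    "Residue",
    "cyclic_equivalent",
    "default_alphabet",
    "load_alphabet",
    "peptide_formula",
]

#: Residue names that are mass-indistinguishable from the ambiguity code
#: Lxx (all C6H11NO as dehydrated residues).  MeVal is deliberately
#: aliased to the same mass; MS2 cannot separate these.
LXX_ALIASES = frozenset({"Leu", "Ile", "MeVal"})


class AlphabetError(ValueError):
    """Raised for malformed or inconsistent residue alphabet definitions."""


@dataclass(frozen=True)
class Residue:
    """A dehydrated amino- or alpha-hydroxy-acid residue."""

    name: str
    formula: Formula
    linkage_class: str  # "amino" | "hydroxy"

    def __post_init__(self) -> None:
        if self.linkage_class not in ("amino", "hydroxy"):
            raise AlphabetError(
                f"residue {self.name!r}: linkage_class must be 'amino' or "
                f"'hydroxy', got {self.linkage_class!r}"
            )
        if monoisotopic_mass(self.formula) <= 0:
            raise AlphabetError(f"residue {self.name!r} has non-positive mass")
        if self.linkage_class == "amino" and self.formula["N"] < 1:
            raise AlphabetError(
                f"amino residue {self.name!r} must contain at least one N"
            )
        if self.linkage_class == "hydroxy" and self.formula["N"] != 0:
            raise AlphabetError(
                f"hydroxy residue {self.name!r} must be nitrogen-free here"
            )

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


def _parse_alphabet_lines(lines: Iterable[str], source: str) -> dict[str, Residue]:
    out: dict[str, Residue] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = [f.strip() for f in line.split(",")]
        if len(fields) != 3:
            raise AlphabetError(
                f"{source}:{lineno}: expected 'name, formula, linkage_class', "
                f"got {raw.rstrip()!r}"
            )
        name, formula_text, linkage = fields
        if name in out:
            raise AlphabetError(f"{source}:{lineno}: duplicate residue name {name!r}")
        out[name] = Residue(name, parse_formula(formula_text), linkage)
    return out


def default_alphabet() -> dict[str, Residue]:
    """The alphabet shipped with the package (Phe, Leu/Ile/MeVal/Lxx, Hba,
    Lac, Hda, Hdda)."""
    text = resources.files("cyclodeps.data").joinpath("residues.csv").read_text()
    return _parse_alphabet_lines(text.splitlines(), "residues.csv")


def load_alphabet(
    source: str | Path | Iterable[str] | None = None,
    *,
    extend_default: bool = True,
) -> dict[str, Residue]:
    """Load a residue alphabet from a comma-separated resource.

    Format: three columns ``name, Hill formula, linkage_class`` with ``#``
    comments.  With ``extend_default`` (the default) user entries extend or
    override the shipped alphabet; duplicate names *within* one file are an
    error.
    """
    base = default_alphabet() if extend_default else {}
    if source is None:
        return base
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
        label = str(source)
    else:
        lines = list(source)
        label = "<lines>"
    base.update(_parse_alphabet_lines(lines, label))
    return base


@dataclass(frozen=True)
class CyclicDepsipeptide:
    """A directed macrocycle of residues (length >= 2)."""

    residues: tuple[Residue, ...]

    def __init__(self, residues: Sequence[Residue]):
        object.__setattr__(self, "residues", tuple(residues))
        if len(self.residues) < 2:
            raise ValueError("a cyclic depsipeptide needs at least 2 residues")

    @classmethod
    def from_names(
        cls, names: Sequence[str], alphabet: dict[str, Residue] | None = None
    ) -> "CyclicDepsipeptide":
        alphabet = alphabet if alphabet is not None else default_alphabet()
        residues = []
        for name in names:
            if name not in alphabet:
                raise KeyError(f"unknown residue code {name!r}")
            residues.append(alphabet[name])
        return cls(residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.residues)

    def formula(self) -> Formula:
        return peptide_formula(self)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula())

    def rotate(self, k: int) -> "CyclicDepsipeptide":
        n = len(self.residues)
        k %= n
        return CyclicDepsipeptide(self.residues[k:] + self.residues[:k])

    def linkage_types(self) -> tuple[str, ...]:
        """Linkage i joins residue i (acceptor) to residue i+1 (donor);
        ester iff the acceptor is a hydroxy residue."""
        return tuple(
            "ester" if r.linkage_class == "hydroxy" else "amide"
            for r in self.residues
        )

    def ester_linkages(self) -> tuple[int, ...]:
        return tuple(
            i for i, t in enumerate(self.linkage_types()) if t == "ester"
        )

    def __str__(self) -> str:
        return "cyclo(" + "-".join(self.names) + ")"


def peptide_formula(p: CyclicDepsipeptide) -> Formula:
    """Neutral molecular formula: element-wise sum of dehydrated residues."""
    total = Formula()
    for r in p.residues:
        total = total + r.formula
    return total


def _names_match(a: str, b: str, wildcard: bool) -> bool:
    if a == b:
        return True
    if not wildcard:
        return False
    return (a == "Lxx" and b in LXX_ALIASES) or (b == "Lxx" and a in LXX_ALIASES)


def cyclic_equivalent(
    a: Sequence[str] | CyclicDepsipeptide,
    b: Sequence[str] | CyclicDepsipeptide,
    wildcard: bool = False,
) -> bool:
    """True iff some rotation of ``a`` matches ``b`` residue-by-residue.

    With ``wildcard`` the code Lxx matches Leu, Ile and MeVal.  No
    reflection: peptide sequences are directional.
    """
    names_a = a.names if isinstance(a, CyclicDepsipeptide) else tuple(a)
    names_b = b.names if isinstance(b, CyclicDepsipeptide) else tuple(b)
    if len(names_a) != len(names_b):
        return False
    n = len(names_a)
    for shift in range(n):
        if all(
            _names_match(names_a[(shift + i) % n], names_b[i], wildcard)
            for i in range(n)
        ):
            return True
    return False


def canonical_rotation(names: Sequence[str], collapse_lxx: bool = True) -> tuple[str, ...]:
    """Deterministic canonical form of a cyclic sequence: optionally map the
    Lxx aliases onto Lxx, then pick the lexicographically smallest rotation."""
    mapped = tuple(
        "Lxx" if (collapse_lxx and n in LXX_ALIASES) else n for n in names
    )
    n = len(mapped)
    return min(tuple(mapped[i:] + mapped[:i]) for i in range(n))
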