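"""Theoretical MS2 fragment ladders for cyclic depsipeptides.

Two ring-opening pathways are modelled:

* P1 ("lactone b"): the ring opens at an ester linkage and the charged
  species then sheds residues one at a time, giving a b-type prefix
  ladder (b_k = sum of the first k residues of the opened chain, plus the
  cationizing adduct).
* P2 ("alpha a"): the ring opens at the alpha-C/C=O bond of one residue;
  the opened ion is isobaric with the precursor (label a0), the first
  neutral loss is that residue minus CO, and subsequent b-type losses run
  down to a terminal x_1 ion that retains the carbonyl on the adjacent
  residue (e.g. Lxx + CO + Na).

Only singly charged, single-cation fragments are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .mass import Formula, IonSpecies, ion_mz, monoisotopic_mass
from .residues import CyclicDepsipeptide, Residue

__all__ = [
    "CO",
    "FragmentIon",
    "LinearForm",
    "all_fragments",
    "fragment_ladder",
    "open_ring",
]

#: Carbonyl unit transferred in P2 ring opening.
CO = Formula(C=1, O=1)

PATHWAY_P1 = "P1_lactone_b"
PATHWAY_P2 = "P2_alpha_a"


class RingOpeningError(ValueError):
    """Raised for chemically inadmissible ring openings."""


@dataclass(frozen=True)
class LinearForm:
    """A ring-opened chain whose ladder ions are prefix sums of residues.

    ``residues`` are ordered so that the k-th ladder ion is the sum of the
    first k residues (plus ``extra`` and the cationizing adduct).  For P1
    the chain runs backwards from the opened ester's acceptor residue; for
    P2 it runs backwards from the residue adjacent to the cleaved
    alpha-C/C=O bond and every ion additionally carries one CO.
    """

    residues: tuple[Residue, ...]
    pathway: str
    opening_site: int
    extra: Formula = field(default_factory=Formula)


def open_ring(p: CyclicDepsipeptide, pathway: str, site: int) -> LinearForm:
    """Open the macrocycle at ``site`` under the given pathway.

    P1 sites are ester linkage indices (linkage i joins residue i, the
    acceptor, to residue i+1); requesting an amide linkage is an error.
    P2 sites are residue indices (any residue's alpha-C/C=O bond).
    Ring opening itself changes no mass.
    """
    n = len(p)
    if not 0 <= site < n:
        raise RingOpeningError(f"site {site} out of range for a {n}-residue cycle")
    if pathway in (PATHWAY_P1, "P1"):
        if p.linkage_types()[site] != "ester":
            raise RingOpeningError(
                f"P1 ring opening requires an ester linkage; linkage {site} "
                f"({p.residues[site].name}<-{p.residues[(site + 1) % n].name}) is an amide"
            )
        chain = tuple(p.residues[(site - i) % n] for i in range(n))
        return LinearForm(chain, PATHWAY_P1, site)
    if pathway in (PATHWAY_P2, "P2"):
        chain = tuple(p.residues[(site - 1 - i) % n] for i in range(n))
        return LinearForm(chain, PATHWAY_P2, site, extra=CO)
    raise RingOpeningError(f"unknown pathway {pathway!r}")


def first_neutral_loss(p: CyclicDepsipeptide, site: int) -> Formula:
    """The first P2 neutral loss: residue(site) minus CO."""
    return p.residues[site].formula - CO


@dataclass(frozen=True)
class FragmentIon:
    """A predicted ladder ion.

    ``formula`` is the charged-species composition including the
    cationizing atom; ``neutral_loss`` is the complement so that
    fragment + neutral loss reconstitute the precursor ion species.
    """

    label: str  # e.g. "b3", "x1", "a0"
    pathway: str
    opening_site: int
    formula: Formula
    mz: float
    neutral_loss: Formula
    provenance: tuple[tuple[str, int, str], ...] = ()

    @property
    def label_class(self) -> str:
        return self.label.rstrip("0123456789")


def fragment_ladder(lf: LinearForm, species: IonSpecies) -> list[FragmentIon]:
    """Ladder ions of one ring-opened chain under a singly charged species.

    P1 yields b_k for k = n-1 .. 2; P2 yields the precursor-isobaric
    opened ion a0 plus x_k for k = n-1 .. 1.  Consecutive ladder ions
    differ by exactly one residue formula.
    """
    if abs(species.charge) != 1:
        raise ValueError(
            f"only singly charged fragment ladders are supported, got z={species.charge}"
        )
    n = len(lf.residues)
    total = Formula()
    for r in lf.residues:
        total = total + r.formula
    precursor_ion = species.apply(total)

    def make(label: str, neutral: Formula) -> FragmentIon:
        charged = species.apply(neutral)
        return FragmentIon(
            label=label,
            pathway=lf.pathway,
            opening_site=lf.opening_site,
            formula=charged,
            mz=ion_mz(neutral, species),
            neutral_loss=precursor_ion - charged,
            provenance=((lf.pathway, lf.opening_site, label),),
        )

    ions: list[FragmentIon] = []
    if lf.pathway == PATHWAY_P1:
        if n == 1:
            # degenerate single-residue chain: one ion, residue + cation
            return [make("b1", lf.residues[0].formula)]
        prefix = Formula()
        prefixes = []
        for r in lf.residues:
            prefix = prefix + r.formula
            prefixes.append(prefix)
        k_min = min(2, n - 1)  # a 2-residue toy ring still yields its b1
        for k in range(n - 1, k_min - 1, -1):
            ions.append(make(f"b{k}", prefixes[k - 1]))
    else:
        ions.append(make("a0", total))
        prefix = Formula(lf.extra)
        prefixes = []
        for r in lf.residues:
            prefix = prefix + r.formula
            prefixes.append(prefix)
        for k in range(n - 1, 0, -1):
            ions.append(make(f"x{k}", prefixes[k - 1]))
    return ions


def all_fragments(p: CyclicDepsipeptide, species: IonSpecies) -> list[FragmentIon]:
    """Union of ladder ions over every admissible opening of both pathways.

    Duplicates (same charged formula and label class) are merged with
    provenance retained; output sorted by m/z descending.
    """
    merged: dict[tuple[Formula, str], FragmentIon] = {}
    ladders = [
        fragment_ladder(open_ring(p, PATHWAY_P1, i), species)
        for i in p.ester_linkages()
    ] + [
        fragment_ladder(open_ring(p, PATHWAY_P2, i), species)
        for i in range(len(p))
    ]
    for ladder in ladders:
        for ion in ladder:
            key = (ion.formula, ion.label_class)
            if key in merged:
                kept = merged[key]
                merged[key] = FragmentIon(
                    label=kept.label,
                    pathway=kept.pathway,
                    opening_site=kept.opening_site,
                    formula=kept.formula,
                    mz=kept.mz,
                    neutral_loss=kept.neutral_loss,
                    provenance=kept.provenance + ion.provenance,
                )
            else:
                merged[key] = ion
    return sorted(
        merged.values(), key=lambda f: (-f.mz, f.label_class, f.opening_site)
    )


def fragment_table(fragments: list[FragmentIon]) -> "list[dict]":
    """Rows for tabular export (label, pathway, site, formula, m/z, loss)."""
    return [
        {
            "label": f.label,
            "pathway": f.pathway,
            "opening_site": f.opening_site,
            "formula": f.formula.hill(),
            "mz": f.mz,
            "neutral_loss": f.neutral_loss.hill(),
            "n_provenance": len(f.provenance),
        }
        for f in fragments
    ]
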