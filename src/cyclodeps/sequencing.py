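"""Fragment matching and de novo residue-sequence inference from MS2 spectra.

The inference builds a spectrum graph: nodes are peaks plus a virtual
precursor node, and a directed edge u -> v exists when the m/z difference
matches a residue mass (or residue - CO for the first alpha-cleavage
step) within tolerance.  Precursor-rooted paths give ordered neutral-loss
sequences; cyclic candidates are completed against the precursor's
neutral composition, de-duplicated up to rotation and Lxx wildcard, and
ranked by how many predicted ladder ions they explain.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fragments import CO, FragmentIon, PATHWAY_P1, all_fragments
from .mass import ELECTRON_MASS, Formula, IonSpecies, ion_mz, monoisotopic_mass
from .residues import (
    CyclicDepsipeptide,
    Residue,
    canonical_rotation,
    default_alphabet,
)
from .spectra import Spectrum

__all__ = [
    "CandidateSequence",
    "MatchReport",
    "annotate_congeners",
    "infer_residues",
    "match_fragments",
    "neutral_mass_of",
]

_CO_MASS = monoisotopic_mass(CO)


def neutral_mass_of(spectrum: Spectrum) -> float:
    """Neutral monoisotopic mass implied by precursor m/z and ion species."""
    if spectrum.species is None:
        raise ValueError("precursor ion species is unknown")
    s = spectrum.species
    return (
        spectrum.precursor_mz * abs(s.charge) - s.delta_mass + s.charge * ELECTRON_MASS
    )


@dataclass
class MatchReport:
    """Greedy one-to-one assignment of predicted ions to observed peaks."""

    matches: list[tuple[FragmentIon, int, float]]  # (ion, peak index, ppm error)
    n_predicted: int
    matched_intensity: float

    @property
    def n_matched(self) -> int:
        return len(self.matches)

    @property
    def coverage(self) -> float:
        if self.n_predicted == 0:
            return 0.0
        return self.n_matched / self.n_predicted

    @property
    def mean_abs_ppm(self) -> float:
        if not self.matches:
            return float("inf")
        return float(np.mean([abs(p) for _, _, p in self.matches]))

    @property
    def score(self) -> float:
        """Sum of log10(1 + intensity) over matched peaks."""
        return self.matched_intensity


def match_fragments(
    predictions: list[FragmentIon], spectrum: Spectrum, tol_ppm: float = 10.0
) -> MatchReport:
    """Match predicted ions against a peak list, each peak used at most once.

    Greedy nearest-m/z assignment processed in descending prediction m/z;
    ties on |ppm| go to the higher-intensity peak.  An empty spectrum
    yields a zero-coverage report, not an error.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    used: set[int] = set()
    matches: list[tuple[FragmentIon, int, float]] = []
    score = 0.0
    mz = spectrum.mz
    for ion in sorted(predictions, key=lambda f: (-f.mz, f.label, f.opening_site)):
        if mz.size == 0:
            break
        tol_da = tol_ppm * 1e-6 * ion.mz
        lo = int(np.searchsorted(mz, ion.mz - tol_da, side="left"))
        hi = int(np.searchsorted(mz, ion.mz + tol_da, side="right"))
        best: int | None = None
        for j in range(lo, hi):
            if j in used:
                continue
            if best is None:
                best = j
                continue
            dj = abs(mz[j] - ion.mz)
            db = abs(mz[best] - ion.mz)
            if dj < db or (dj == db and spectrum.intensity[j] > spectrum.intensity[best]):
                best = j
        if best is not None:
            used.add(best)
            ppm = 1e6 * (mz[best] - ion.mz) / ion.mz
            matches.append((ion, best, ppm))
            score += float(np.log10(1.0 + spectrum.intensity[best]))
    return MatchReport(matches=matches, n_predicted=len(predictions), matched_intensity=score)


@dataclass(frozen=True)
class CandidateSequence:
    """A ranked cyclic-sequence hypothesis."""

    residues: tuple[str, ...]
    total_formula: Formula
    score: float
    n_matched: int
    mean_abs_ppm: float
    coverage: float
    two_pathway_support: bool

    def peptide(self, alphabet: dict[str, Residue] | None = None) -> CyclicDepsipeptide:
        return CyclicDepsipeptide.from_names(self.residues, alphabet)


def _canonical_residues(alphabet: dict[str, Residue]) -> list[Residue]:
    """One representative residue per distinct (formula, linkage) class,
    preferring the ambiguity code Lxx for its mass class."""
    groups: dict[tuple[Formula, str], list[Residue]] = {}
    for r in alphabet.values():
        groups.setdefault((r.formula, r.linkage_class), []).append(r)
    out = []
    for members in groups.values():
        names = sorted(m.name for m in members)
        pick = "Lxx" if "Lxx" in names else names[0]
        out.append(next(m for m in members if m.name == pick))
    out.sort(key=lambda r: (r.mass, r.name))
    return out


def _decompose_formula(
    remaining: Formula, residues: list[Residue], max_count: int
) -> list[tuple[Residue, ...]]:
    """All multisets of residues summing exactly to ``remaining``."""
    results: list[tuple[Residue, ...]] = []

    def rec(rem: Formula, start: int, acc: list[Residue]) -> None:
        if len(rem) == 0:
            results.append(tuple(acc))
            return
        if len(acc) >= max_count:
            return
        for i in range(start, len(residues)):
            r = residues[i]
            try:
                nxt = rem - r.formula
            except Exception:
                continue
            acc.append(r)
            rec(nxt, i, acc)
            acc.pop()

    rec(remaining, 0, [])
    return results


def _decompose_mass(
    remaining: float, residues: list[Residue], max_count: int, tol_da: float
) -> list[tuple[Residue, ...]]:
    """All multisets of residues whose masses sum to ``remaining`` +- tol."""
    results: list[tuple[Residue, ...]] = []
    min_mass = min(r.mass for r in residues)

    def rec(rem: float, start: int, acc: list[Residue]) -> None:
        if abs(rem) <= tol_da:
            if acc:
                results.append(tuple(acc))
            return
        if rem < min_mass - tol_da or len(acc) >= max_count:
            return
        for i in range(start, len(residues)):
            r = residues[i]
            if r.mass > rem + tol_da:
                break
            acc.append(r)
            rec(rem - r.mass, i, acc)
            acc.pop()

    rec(remaining, 0, [])
    return results


def infer_residues(
    spectrum: Spectrum,
    neutral_formula: Formula | None,
    alphabet: dict[str, Residue] | None = None,
    tol_ppm: float = 10.0,
    max_results: int = 10,
    min_relative_intensity: float = 0.0,
    max_paths: int = 50_000,
    max_residues: int = 12,
) -> list[CandidateSequence]:
    """De novo cyclic-sequence inference from neutral-loss ladders.

    ``neutral_formula``, when given, constrains every returned candidate's
    composition exactly; otherwise the neutral mass implied by the
    precursor is used within tolerance.  Returns at most ``max_results``
    equivalence classes under rotation with the Lxx wildcard, ranked by
    (ladder ions matched, matched intensity, mean |ppm|, residue names).
    A spectrum in which no ladder is found yields an empty list.
    """
    if spectrum.species is None:
        raise ValueError("precursor ion species must be known for inference")
    alphabet = alphabet if alphabet is not None else default_alphabet()
    residues = _canonical_residues(alphabet)
    spectrum = spectrum.filter_relative_intensity(min_relative_intensity)
    species = spectrum.species

    if neutral_formula is not None:
        neutral_mass = monoisotopic_mass(neutral_formula)
        precursor_mz = ion_mz(neutral_formula, species)
    else:
        neutral_mass = neutral_mass_of(spectrum)
        precursor_mz = spectrum.precursor_mz

    # Spectrum-graph nodes: peaks below the precursor, plus the precursor
    # itself as a virtual root (index -1).
    keep = spectrum.mz <= precursor_mz * (1 + tol_ppm * 1e-6)
    mz = spectrum.mz[keep]

    def residue_edges(diff: float, upper_mz: float, allow_minus_co: bool):
        tol_da = tol_ppm * 1e-6 * upper_mz
        for r in residues:
            if abs(diff - r.mass) <= tol_da:
                yield r, False
            if allow_minus_co and abs(diff - (r.mass - _CO_MASS)) <= tol_da:
                yield r, True

    # Adjacency: from the root and from each peak to all lower peaks.
    order = np.argsort(-mz, kind="stable")
    nodes = mz[order]
    n_nodes = nodes.size

    paths: list[tuple[tuple[Residue, ...], bool]] = []
    budget = [max_paths]

    def dfs(node_mz: float, node_idx: int, acc: list[Residue], first_minus_co: bool) -> None:
        if budget[0] <= 0 or len(acc) >= max_residues:
            return
        start = 0 if node_idx < 0 else node_idx + 1
        for j in range(start, n_nodes):
            diff = node_mz - nodes[j]
            if diff <= 0:
                continue
            allow_co = node_idx < 0 and not acc
            for r, via_co in residue_edges(diff, node_mz, allow_co):
                budget[0] -= 1
                acc.append(r)
                paths.append((tuple(acc), first_minus_co or via_co))
                dfs(nodes[j], j, acc, first_minus_co or via_co)
                acc.pop()
                if budget[0] <= 0:
                    return

    dfs(precursor_mz, -1, [], False)

    # Assemble cyclic candidates: path losses are consecutive residues in
    # ring order; the remainder is filled by composition.
    tol_da = tol_ppm * 1e-6 * precursor_mz
    seen: set[tuple[str, ...]] = set()
    candidates: list[tuple[tuple[str, ...], Formula]] = []
    for losses, _ in paths:
        loss_formula = Formula()
        for r in losses:
            loss_formula = loss_formula + r.formula
        if neutral_formula is not None:
            try:
                remaining = neutral_formula - loss_formula
            except Exception:
                continue
            room = max_residues - len(losses)
            completions = _decompose_formula(remaining, residues, room)
            if len(remaining) == 0:
                completions = [()]
        else:
            rem_mass = neutral_mass - monoisotopic_mass(loss_formula)
            room = max_residues - len(losses)
            if abs(rem_mass) <= tol_da:
                completions = [()]
            else:
                completions = _decompose_mass(rem_mass, residues, room, tol_da)
        for completion in completions:
            if len(losses) + len(completion) < 2:
                continue
            if len(completion) > 7:  # factorial guard on permutations
                continue
            for perm in set(itertools.permutations(completion)):
                names = tuple(r.name for r in losses) + tuple(r.name for r in perm)
                key = canonical_rotation(names)
                if key in seen:
                    continue
                seen.add(key)
                total = loss_formula
                for r in perm:
                    total = total + r.formula
                candidates.append((key, total))

    # Score every candidate by how well its predicted ladders explain the
    # observed peaks.
    scored: list[CandidateSequence] = []
    for names, total in candidates:
        peptide = CyclicDepsipeptide.from_names(names, alphabet)
        preds = all_fragments(peptide, species)
        report = match_fragments(preds, spectrum, tol_ppm)
        if report.n_matched == 0:
            continue
        matched_pathways = {ion.pathway for ion, _, _ in report.matches}
        scored.append(
            CandidateSequence(
                residues=names,
                total_formula=total,
                score=report.score,
                n_matched=report.n_matched,
                mean_abs_ppm=report.mean_abs_ppm,
                coverage=report.coverage,
                two_pathway_support=len(matched_pathways) >= 2,
            )
        )
    scored.sort(
        key=lambda c: (
            -c.n_matched, -c.coverage, -c.score, c.mean_abs_ppm, c.residues
        )
    )
    return scored[:max_results]


@dataclass(frozen=True)
class CongenerAssignment:
    """Best substitution variant of a reference cycle for one spectrum."""

    feature_id: str | None
    assigned: bool
    residues: tuple[str, ...] | None
    substitutions: tuple[tuple[int, str, str], ...]
    score: float
    n_matched: int


def annotate_congeners(
    reference: CandidateSequence | CyclicDepsipeptide,
    spectra: list[Spectrum],
    substitution_pairs: list[tuple[str, str]],
    alphabet: dict[str, Residue] | None = None,
    tol_ppm: float = 10.0,
) -> list[CongenerAssignment]:
    """Assign congener spectra by residue substitutions of a reference.

    For each spectrum, all substitution combinations of the reference
    cycle consistent with the precursor mass are evaluated and the best
    scoring variant reported; spectra with no mass-consistent variant are
    returned unassigned.
    """
    alphabet = alphabet if alphabet is not None else default_alphabet()
    ref_names = (
        reference.residues
        if isinstance(reference, CandidateSequence)
        else reference.names
    )
    swap: dict[str, set[str]] = {}
    for a, b in substitution_pairs:
        swap.setdefault(a, set()).add(b)
        swap.setdefault(b, set()).add(a)
    options = [
        sorted({name} | swap.get(name, set())) for name in ref_names
    ]

    out: list[CongenerAssignment] = []
    for spectrum in spectra:
        if spectrum.species is None:
            out.append(
                CongenerAssignment(spectrum.feature_id, False, None, (), 0.0, 0)
            )
            continue
        target_mass = neutral_mass_of(spectrum)
        tol_da = tol_ppm * 1e-6 * spectrum.precursor_mz
        best: CongenerAssignment | None = None
        for combo in itertools.product(*options):
            peptide = CyclicDepsipeptide.from_names(combo, alphabet)
            if abs(peptide.mass - target_mass) > tol_da:
                continue
            subs = tuple(
                (i, ref_names[i], combo[i])
                for i in range(len(combo))
                if combo[i] != ref_names[i]
            )
            report = match_fragments(
                all_fragments(peptide, spectrum.species), spectrum, tol_ppm
            )
            cand = CongenerAssignment(
                feature_id=spectrum.feature_id,
                assigned=True,
                residues=tuple(combo),
                substitutions=subs,
                score=report.score,
                n_matched=report.n_matched,
            )
            if (
                best is None
                or (cand.n_matched, cand.score, -len(subs)) >
                (best.n_matched, best.score, -len(best.substitutions))
            ):
                best = cand
        out.append(
            best
            if best is not None
            else CongenerAssignment(spectrum.feature_id, False, None, (), 0.0, 0)
        )
    return out
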