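"""Molecular networking (modified cosine) and ion-identity adduct grouping.

Edges between MS2 spectra use the modified cosine score: peak pairs may
match either directly or after shifting one spectrum by the precursor
mass difference; a one-to-one pairing is chosen greedily by descending
intensity product.  Ion-identity edges group co-eluting MS1 features
whose chromatographic peak shapes correlate and whose m/z difference
matches a known adduct delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mass import ELECTRON_MASS, MONOISOTOPIC_MASS
from .spectra import Spectrum

__all__ = [
    "EicTrace",
    "IonIdentityParams",
    "NetworkEdge",
    "NetworkParams",
    "build_network",
    "default_adduct_deltas",
    "ion_identity_groups",
    "modified_cosine",
    "molecular_families",
]


@dataclass(frozen=True)
class NetworkParams:
    min_cosine: float = 0.7
    frag_tol_da: float = 0.01
    precursor_tol_da: float = 0.01
    min_matched_peaks: int = 6
    sqrt_transform: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_cosine <= 1:
            raise ValueError("min_cosine must be in (0, 1]")
        if self.frag_tol_da <= 0 or self.precursor_tol_da <= 0:
            raise ValueError("mass tolerances must be positive")


def default_adduct_deltas() -> dict[str, float]:
    """Named m/z deltas between singly charged adduct pairs (H/Na/NH4/K)."""
    h = MONOISOTOPIC_MASS["H"]
    na = MONOISOTOPIC_MASS["Na"]
    nh4 = MONOISOTOPIC_MASS["N"] + 4 * h
    k = MONOISOTOPIC_MASS["K"]
    singles = {"H": h, "NH4": nh4, "Na": na, "K": k}
    deltas: dict[str, float] = {}
    names = list(singles)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lo, hi = (a, b) if singles[a] < singles[b] else (b, a)
            deltas[f"{hi}-{lo}"] = singles[hi] - singles[lo]
    return deltas


@dataclass(frozen=True)
class IonIdentityParams:
    rt_tol_min: float = 0.05
    min_shape_corr: float = 0.85
    mz_tol_da: float = 0.01
    adduct_deltas: tuple[tuple[str, float], ...] = field(
        default_factory=lambda: tuple(sorted(default_adduct_deltas().items()))
    )

    def __post_init__(self) -> None:
        if not 0 <= self.min_shape_corr <= 1:
            raise ValueError("min_shape_corr must be in [0, 1]")


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    kind: str  # "cosine" | "ion_identity"
    score: float
    n_matched: int
    annotation: str = ""


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol_da: float = 0.01,
    sqrt_transform: bool = True,
) -> tuple[float, int]:
    """Modified cosine similarity and the number of matched peak pairs.

    Peak pairs are admissible when |mz_a - mz_b| <= tol or
    |mz_a - (mz_b + dP)| <= tol with dP the precursor m/z difference.
    Pairing is one-to-one, chosen greedily by descending intensity
    product.  Intensities are square-root transformed by default.
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa = np.sqrt(a.intensity) if sqrt_transform else a.intensity.astype(float)
    wb = np.sqrt(b.intensity) if sqrt_transform else b.intensity.astype(float)
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    if norm == 0:
        return 0.0, 0
    shift = a.precursor_mz - b.precursor_mz
    pairs: list[tuple[float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for delta in (0.0, shift):
        for i, ma in enumerate(a.mz):
            target = ma - delta
            lo = int(np.searchsorted(b.mz, target - frag_tol_da, side="left"))
            hi = int(np.searchsorted(b.mz, target + frag_tol_da, side="right"))
            for j in range(lo, hi):
                if (i, j) not in seen:
                    seen.add((i, j))
                    pairs.append((float(wa[i] * wb[j]), i, j))
        if shift == 0.0:
            break
    # Greedy one-to-one assignment, deterministic tie-breaking.
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    n_matched = 0
    for w, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += w
        n_matched += 1
    return min(total / norm, 1.0), n_matched


def build_network(
    spectra: list[Spectrum], params: NetworkParams | None = None
) -> list[NetworkEdge]:
    """All-vs-all modified-cosine edges passing the score and matched-peak
    gates.  No top-K neighbor pruning is applied."""
    params = params or NetworkParams()
    indexed = sorted(
        enumerate(spectra), key=lambda t: (str(t[1].feature_id), t[0])
    )
    edges: list[NetworkEdge] = []
    for x in range(len(indexed)):
        _, sa = indexed[x]
        for y in range(x + 1, len(indexed)):
            _, sb = indexed[y]
            score, n = modified_cosine(
                sa, sb, params.frag_tol_da, params.sqrt_transform
            )
            if score >= params.min_cosine and n >= params.min_matched_peaks:
                ida, idb = str(sa.feature_id), str(sb.feature_id)
                if idb < ida:
                    ida, idb = idb, ida
                edges.append(NetworkEdge(ida, idb, "cosine", score, n))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def molecular_families(
    edges: list[NetworkEdge], node_ids: list[str]
) -> dict[str, int]:
    """Connected-component label per node (singletons included)."""
    parent = {n: n for n in node_ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        for n in (e.node_a, e.node_b):
            parent.setdefault(n, n)
        ra, rb = find(e.node_a), find(e.node_b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(n) for n in parent})
    root_label = {r: i for i, r in enumerate(roots)}
    return {n: root_label[find(n)] for n in sorted(parent)}


@dataclass(frozen=True)
class EicTrace:
    """An extracted-ion chromatogram on a shared time grid."""

    feature_id: str
    mz: float
    rt: float  # apex retention time, minutes
    trace: tuple[float, ...]


@dataclass(frozen=True)
class IonIdentityGroup:
    feature_ids: tuple[str, ...]
    neutral_mass: float | None
    edges: tuple[NetworkEdge, ...]


def _shape_correlation(a: EicTrace, b: EicTrace) -> float:
    """Pearson r of two traces on the union support with zero-fill."""
    x = np.asarray(a.trace, dtype=float)
    y = np.asarray(b.trace, dtype=float)
    m = max(x.size, y.size)
    x = np.pad(x, (0, m - x.size))
    y = np.pad(y, (0, m - y.size))
    support = (x > 0) | (y > 0)
    x, y = x[support], y[support]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def ion_identity_groups(
    features: list[EicTrace], params: IonIdentityParams | None = None
) -> list[IonIdentityGroup]:
    """Partition features into adduct groups of the same neutral molecule.

    Two features pair when |dRT| <= rt_tol, shape Pearson r > the gate,
    and their m/z difference matches an adduct delta within tolerance;
    groups are the transitive closure of pairs.  The inferred neutral
    mass assumes the lowest-m/z member is the protonated species.
    """
    params = params or IonIdentityParams()
    feats = sorted(features, key=lambda f: f.feature_id)
    parent = {f.feature_id: f.feature_id for f in feats}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[NetworkEdge] = []
    deltas = dict(params.adduct_deltas)
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            fa, fb = feats[i], feats[j]
            if abs(fa.rt - fb.rt) > params.rt_tol_min:
                continue
            dmz = abs(fa.mz - fb.mz)
            name = next(
                (
                    nm
                    for nm, d in deltas.items()
                    if abs(dmz - d) <= params.mz_tol_da
                ),
                None,
            )
            if name is None:
                continue
            r = _shape_correlation(fa, fb)
            if r <= params.min_shape_corr:
                continue
            edges.append(
                NetworkEdge(fa.feature_id, fb.feature_id, "ion_identity", r, 0, name)
            )
            ra, rb = find(fa.feature_id), find(fb.feature_id)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    by_root: dict[str, list[EicTrace]] = {}
    for f in feats:
        by_root.setdefault(find(f.feature_id), []).append(f)
    groups: list[IonIdentityGroup] = []
    proton = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS
    for root in sorted(by_root):
        members = sorted(by_root[root], key=lambda f: f.mz)
        ids = tuple(f.feature_id for f in members)
        neutral = members[0].mz - proton if len(members) > 1 else None
        group_edges = tuple(
            e for e in edges if e.node_a in ids and e.node_b in ids
        )
        groups.append(IonIdentityGroup(ids, neutral, group_edges))
    return groups
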