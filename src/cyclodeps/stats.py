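"""Integration statistics implemented from definitions.

Bray-Curtis dissimilarity, principal coordinate analysis (Gower double
centering), distance-based PERMANOVA, and all-pairs Spearman rank
correlation with Benjamini-Hochberg step-up FDR control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationRecord",
    "OrdinationResult",
    "bray_curtis",
    "benjamini_hochberg",
    "pcoa",
    "permanova",
    "spearman_bh",
    "top_k_select",
]


def bray_curtis(m: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i).  A pair of all-zero
    samples gets distance 0 with a warning.
    """
    is_frame = isinstance(m, pd.DataFrame)
    x = m.to_numpy(dtype=float) if is_frame else np.asarray(m, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x[:, i:i + 1] - x[:, i + 1:]).sum(axis=0)
        tot = (x[:, i:i + 1] + x[:, i + 1:]).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.where(tot > 0, diff / np.where(tot > 0, tot, 1.0), 0.0)
        if np.any(tot == 0):
            warnings.warn(
                "all-zero sample pair(s): Bray-Curtis distance defined as 0",
                stacklevel=2,
            )
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    if is_frame:
        return pd.DataFrame(d, index=m.columns, columns=m.columns)
    return d


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray
    permanova: dict | None = None


def pcoa(
    d: np.ndarray | pd.DataFrame, n_axes: int | None = None
) -> OrdinationResult:
    """Principal coordinate analysis via Gower double centering of -d^2/2.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues; negative eigenvalues are reported but excluded from the
    coordinates (no correction applied).
    """
    is_frame = isinstance(d, pd.DataFrame)
    labels = list(d.index) if is_frame else list(range(np.asarray(d).shape[0]))
    dm = d.to_numpy(dtype=float) if is_frame else np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = dm.shape[0]
    a = -0.5 * dm**2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12 * abs(eigval).max(initial=1.0), 0.0)
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    # Deterministic sign: largest-magnitude loading positive per axis.
    for j in range(k):
        col = coords[:, j]
        pivot = int(np.argmax(np.abs(col)))
        if col[pivot] < 0:
            coords[:, j] = -col
    total = eigval[eigval > 0].sum()
    proportion = np.where(eigval > 0, eigval / total if total > 0 else 0.0, 0.0)
    frame = pd.DataFrame(
        coords, index=labels, columns=[f"PC{j + 1}" for j in range(k)]
    )
    return OrdinationResult(frame, eigval, proportion)


def _permanova_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's distance-based pseudo-F from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    ss_between = ss_total - ss_within
    g = groups.size
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    d: np.ndarray | pd.DataFrame,
    grouping,
    n_perm: int = 999,
    seed: int | None = 0,
) -> tuple[float, float]:
    """Distance-based PERMANOVA pseudo-F and permutation p-value.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so 1/(1 + n_perm) is the
    attainable floor.  Permutations shuffle group labels with the stated
    seed.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    labels = np.asarray(list(grouping))
    if labels.size != dm.shape[0]:
        raise ValueError("grouping length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if (counts < 2).any():
        small = groups[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    d2 = dm**2
    f_obs = _permanova_f(d2, labels, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        permuted = rng.permutation(labels)
        if _permanova_f(d2, permuted, groups) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(f_obs), float(p)


@dataclass(frozen=True)
class CorrelationRecord:
    otu: str
    feature: str
    rho: float
    p: float
    q: float
    significant: bool
    forced: bool = False


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted q-values (monotone, q >= p elementwise)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _spearman_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho between every row of x and every row of y
    (average-rank ties)."""
    rx = np.apply_along_axis(sps.rankdata, 1, x)
    ry = np.apply_along_axis(sps.rankdata, 1, y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    nx = np.sqrt((rx**2).sum(axis=1))
    ny = np.sqrt((ry**2).sum(axis=1))
    nx[nx == 0] = np.nan
    ny[ny == 0] = np.nan
    rho = (rx @ ry.T) / np.outer(nx, ny)
    return np.clip(rho, -1.0, 1.0)


def spearman_bh(
    features: pd.DataFrame,
    otus: pd.DataFrame,
    alpha: float = 0.05,
    proportion_transform: bool = True,
) -> list[CorrelationRecord]:
    """All-pairs OTU x feature Spearman correlation with joint BH FDR.

    OTU counts are first converted to per-sample proportions.  P-values
    use the t-distribution approximation with average-rank ties; BH is
    applied jointly over all pairs.  Records are sorted by (q, -|rho|,
    otu, feature) for a deterministic total ranking.
    """
    shared = [s for s in features.columns if s in set(otus.columns)]
    n = len(shared)
    if n < 4:
        raise ValueError(f"need >= 4 shared samples, got {n}")
    f = features[shared].to_numpy(dtype=float)
    o = otus[shared].to_numpy(dtype=float)
    if proportion_transform:
        depth = o.sum(axis=0)
        depth[depth == 0] = np.nan
        o = o / depth
    rho = _spearman_matrix(o, f)  # otus x features
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p = np.where(np.isnan(rho), 1.0, p)
    rho_flat = rho.ravel()
    p_flat = p.ravel()
    q_flat = benjamini_hochberg(p_flat)
    otu_ids = [str(i) for i in otus.index]
    feat_ids = [str(i) for i in features.index]
    records = []
    idx = 0
    for oi in otu_ids:
        for fi in feat_ids:
            r = rho_flat[idx]
            records.append(
                CorrelationRecord(
                    otu=oi,
                    feature=fi,
                    rho=float(r) if np.isfinite(r) else float("nan"),
                    p=float(p_flat[idx]),
                    q=float(q_flat[idx]),
                    significant=bool(q_flat[idx] < alpha),
                )
            )
            idx += 1
    records.sort(key=lambda rec: (rec.q, -abs(rec.rho), rec.otu, rec.feature))
    return records


def top_k_select(
    records: list[CorrelationRecord],
    k: int = 20,
    forced_ids: tuple[str, ...] = (),
) -> list[CorrelationRecord]:
    """Heatmap selection: top-k positive and top-k negative significant
    correlations, plus the best record for every forced id (flagged
    ``forced`` even when not significant)."""
    ranked = sorted(records, key=lambda r: (r.q, -abs(r.rho), r.otu, r.feature))
    positive = [r for r in ranked if r.significant and r.rho > 0][:k]
    negative = [r for r in ranked if r.significant and r.rho < 0][:k]
    selected = {(r.otu, r.feature): r for r in positive + negative}
    for fid in forced_ids:
        hits = [r for r in ranked if fid in (r.otu, r.feature)]
        if not hits:
            continue
        best = hits[0]
        key = (best.otu, best.feature)
        selected[key] = CorrelationRecord(
            best.otu, best.feature, best.rho, best.p, best.q,
            best.significant, forced=True,
        )
    return sorted(
        selected.values(), key=lambda r: (r.q, -abs(r.rho), r.otu, r.feature)
    )
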