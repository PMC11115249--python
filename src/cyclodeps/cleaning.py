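"""MS feature-table preprocessing: washout removal, blank subtraction,
TIC normalization, prevalence filtering, centering/scaling.

Fixed pipeline order: washout -> blank -> TIC -> (for correlation only)
prevalence -> center/scale.  Every operation returns a new table and logs
how many features it removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "blank_subtract",
    "center_scale",
    "prevalence_filter",
    "remove_washout",
    "tic_normalize",
]


@dataclass
class FeatureTable:
    """MS features (rows) x samples (columns) with per-feature m/z and RT.

    ``meta`` maps every sample column to station / exposure / blank-flag
    metadata (index = sample name).
    """

    areas: pd.DataFrame  # features x samples, non-negative peak areas
    mz: pd.Series
    rt: pd.Series  # minutes
    meta: pd.DataFrame  # index: sample; columns: station, exposure, is_blank
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.areas.index.duplicated().any():
            dupes = self.areas.index[self.areas.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        if (self.areas.to_numpy() < 0).any():
            raise ValueError("peak areas must be non-negative")
        missing = [c for c in self.areas.columns if c not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    @property
    def feature_ids(self) -> list:
        return self.areas.index.tolist()

    @property
    def samples(self) -> list:
        return self.areas.columns.tolist()

    @property
    def blank_samples(self) -> list:
        flagged = self.meta.index[self.meta["is_blank"].astype(bool)]
        return [s for s in self.areas.columns if s in set(flagged)]

    @property
    def biological_samples(self) -> list:
        blanks = set(self.blank_samples)
        return [s for s in self.areas.columns if s not in blanks]

    def with_areas(self, areas: pd.DataFrame, note: str) -> "FeatureTable":
        return replace(
            self,
            areas=areas,
            mz=self.mz.loc[areas.index],
            rt=self.rt.loc[areas.index],
            log=self.log + [note],
        )


def remove_washout(t: FeatureTable, rt_cut_min: float = 10.0) -> FeatureTable:
    """Drop features eluting in the washout segment (RT >= cut, minutes)."""
    if t.rt.isna().any():
        bad = t.rt.index[t.rt.isna()].tolist()
        raise ValueError(f"features without retention time: {bad}")
    keep = t.rt < rt_cut_min
    removed = int((~keep).sum())
    note = f"remove_washout(rt_cut_min={rt_cut_min}): removed {removed} features"
    logger.info(note)
    return t.with_areas(t.areas.loc[keep], note)


def blank_subtract(t: FeatureTable, cutoff: float = 0.3) -> FeatureTable:
    """Remove features whose mean blank area is >= cutoff of the mean
    biological area, then drop the blank columns.

    Boundary conventions: ratio exactly at the cutoff removes; a feature
    seen only in blanks (x/0, x>0) removes; seen nowhere (0/0) removes.
    """
    blanks = t.blank_samples
    if not blanks:
        raise ValueError("blank_subtract requires at least one blank column")
    bio = t.biological_samples
    blank_mean = t.areas[blanks].mean(axis=1)
    bio_mean = t.areas[bio].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = blank_mean / bio_mean
    # 0/0 -> NaN and x/0 -> inf both count as background.
    remove = ratio.isna() | (ratio >= cutoff)
    keep = ~remove
    note = (
        f"blank_subtract(cutoff={cutoff}): removed {int(remove.sum())} features, "
        f"dropped {len(blanks)} blank columns"
    )
    logger.info(note)
    out = t.with_areas(t.areas.loc[keep, bio], note)
    out.meta = t.meta.loc[[s for s in t.meta.index if s not in set(blanks)]]
    return out


def tic_normalize(t: FeatureTable) -> FeatureTable:
    """Divide each cell by its sample's total ion count (column sum)."""
    sums = t.areas.sum(axis=0)
    zero = sums.index[sums <= 0].tolist()
    if zero:
        raise ValueError(f"all-zero sample columns cannot be TIC-normalized: {zero}")
    note = "tic_normalize: column sums scaled to 1"
    logger.info(note)
    return t.with_areas(t.areas / sums, note)


def prevalence_filter(t: FeatureTable, min_frac: float = 0.10) -> FeatureTable:
    """Keep features observed (area > 0) in at least ceil(min_frac * n)
    samples; min_frac = 0 is the identity."""
    n = len(t.samples)
    threshold = math.ceil(min_frac * n)
    observed = (t.areas > 0).sum(axis=1)
    keep = observed >= threshold
    note = (
        f"prevalence_filter(min_frac={min_frac}): threshold {threshold}/{n} "
        f"samples, removed {int((~keep).sum())} features"
    )
    logger.info(note)
    return t.with_areas(t.areas.loc[keep], note)


def center_scale(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each feature row to mean 0, sd 1 (ddof=1).

    Zero-variance rows are dropped (logged), never divided by zero.
    """
    sd = m.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        logger.info("center_scale: dropped %d constant rows", len(constant))
    kept = m.drop(index=constant)
    sd = sd.drop(index=constant)
    return kept.sub(kept.mean(axis=1), axis=0).div(sd, axis=0)
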