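"""The MS2 spectrum container shared by the sequencer, networking and IO."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mass import IonSpecies

__all__ = ["Spectrum"]


@dataclass
class Spectrum:
    """A centroided MS2 peak list with precursor metadata.

    Peaks are kept sorted by m/z; intensities must be non-negative.
    ``species`` is None when the precursor ion species is unknown.
    """

    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    species: IonSpecies | None = None
    feature_id: str | None = None
    rt: float | None = None  # minutes
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.intensity < 0):
            raise ValueError("peak intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    def filter_relative_intensity(self, min_relative: float) -> "Spectrum":
        """Drop peaks below ``min_relative`` of the base peak (0 keeps all)."""
        if min_relative <= 0 or len(self) == 0:
            return self
        keep = self.intensity >= min_relative * self.intensity.max()
        return Spectrum(
            precursor_mz=self.precursor_mz,
            mz=self.mz[keep],
            intensity=self.intensity[keep],
            species=self.species,
            feature_id=self.feature_id,
            rt=self.rt,
            metadata=dict(self.metadata),
        )
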