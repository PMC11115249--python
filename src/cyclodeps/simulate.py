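"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: MS2 spectra of
planted cyclic depsipeptides (ppm-scale mass jitter plus noise peaks),
MS feature tables with blank channels, washout-region features and a
planted submerged-vs-exposed group effect, and OTU count tables with
planted monotone microbe-metabolite associations.  A manifest plus seed
fully determines every output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

from .cleaning import FeatureTable
from .fragments import all_fragments
from .io import OtuTable
from .mass import IonSpecies, ion_mz
from .residues import CyclicDepsipeptide, Residue, default_alphabet
from .spectra import Spectrum

__all__ = [
    "SimulationManifest",
    "load_manifest",
    "random_peptide",
    "simulate_feature_table",
    "simulate_otu_table",
    "simulate_spectrum",
]


@dataclass(frozen=True)
class SimulationManifest:
    """Fully determines simulated outputs: same seed, same bytes."""

    seed: int = 0
    peptides: tuple[tuple[str, ...], ...] = (
        ("Phe", "Lxx", "Hba", "Phe", "Lxx", "Hda"),
    )
    adducts: tuple[str, ...] = ("M+Na",)
    ppm_sd: float = 5.0
    n_noise: int = 20
    n_stations: int = 9
    station_exposures: tuple[str, ...] = (
        "exposed", "submerged", "exposed", "submerged", "submerged",
        "submerged", "submerged", "exposed", "exposed",
    )
    n_samples_per_station: int = 12
    n_blanks: int = 3
    n_features: int = 500
    n_washout: int = 30
    n_blank_contaminated: int = 20
    n_enriched: int = 30
    effect_size: float = 4.0
    dropout: float = 0.05
    n_otus: int = 300
    depth: int = 50_000
    n_planted_pairs: int = 10
    coupling_noise: float = 0.1

    def __post_init__(self) -> None:
        if len(self.station_exposures) != self.n_stations:
            raise ValueError("one exposure label per station required")
        reserved = (
            self.n_washout + self.n_blank_contaminated + self.n_enriched
            + self.n_planted_pairs
        )
        if reserved > self.n_features:
            raise ValueError("planted feature blocks exceed n_features")


def load_manifest(name_or_path: str | Path) -> SimulationManifest:
    """Load a preset by name ("demo", "null", "strong-signal") or a YAML file."""
    text = resources.files("cyclodeps.data").joinpath("presets.yaml").read_text()
    presets = yaml.safe_load(text)
    if str(name_or_path) in presets:
        raw = presets[str(name_or_path)]
    else:
        raw = yaml.safe_load(Path(name_or_path).read_text())
    raw = dict(raw)
    raw["peptides"] = tuple(tuple(p) for p in raw["peptides"])
    raw["adducts"] = tuple(raw["adducts"])
    raw["station_exposures"] = tuple(raw["station_exposures"])
    return SimulationManifest(**raw)


def random_peptide(
    rng: np.random.Generator,
    alphabet: dict[str, Residue] | None = None,
    length: int = 6,
    min_amino: int = 2,
    min_hydroxy: int = 1,
) -> CyclicDepsipeptide:
    """A random cyclic depsipeptide drawn uniformly from the alphabet's
    distinct-mass residues.

    By default at least two amino and one hydroxy residue are required,
    i.e. the ring carries both amide and ester linkages (the definition
    of a depsipeptide).  Rings made almost entirely of hydroxy acids are
    excluded: with every linkage an ester, distinct arrangements predict
    identical fragment sets and no sequencer can order them.
    """
    alphabet = alphabet if alphabet is not None else default_alphabet()
    names = sorted(
        n for n in alphabet
        if n not in ("Leu", "Ile", "MeVal")  # keep the Lxx representative only
    )
    hydroxy = {n for n in names if alphabet[n].linkage_class == "hydroxy"}
    while True:
        picked = [names[i] for i in rng.integers(0, len(names), size=length)]
        n_hydroxy = sum(p in hydroxy for p in picked)
        if n_hydroxy >= min_hydroxy and length - n_hydroxy >= min_amino:
            return CyclicDepsipeptide.from_names(picked, alphabet)


def simulate_spectrum(
    p: CyclicDepsipeptide,
    species: IonSpecies,
    ppm_sd: float = 0.0,
    n_noise: int = 0,
    seed: int | np.random.Generator = 0,
    feature_id: str | None = None,
    rt: float | None = None,
    shared_intensity: bool = False,
) -> Spectrum:
    """MS2 spectrum of a planted peptide: every predicted ladder ion with
    Normal(0, ppm_sd) m/z jitter and log-uniform [1e3, 1e6] intensities,
    plus uniform-m/z noise peaks below the precursor.

    With ``shared_intensity`` each ladder ion's intensity is a log-uniform
    draw keyed to its label, identical across spectra; congener spectra
    then share intensity patterns the way co-fragmenting analogues do.
    """
    if ppm_sd < 0:
        raise ValueError("ppm_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    precursor = ion_mz(p.formula(), species)
    ions = all_fragments(p, species)
    mz = np.array([f.mz for f in ions])
    mz = mz * (1.0 + rng.normal(0.0, ppm_sd, size=mz.size) * 1e-6)
    if shared_intensity:
        intensity = np.array(
            [
                10.0
                ** np.random.default_rng(
                    zlib.crc32(f"{f.label}:{f.opening_site}".encode())
                ).uniform(3, 6)
                for f in ions
            ]
        )
    else:
        intensity = 10.0 ** rng.uniform(3, 6, size=mz.size)
    if n_noise > 0:
        noise_mz = rng.uniform(100.0, precursor, size=n_noise)
        # noise sits below the ladder's intensity law
        noise_intensity = 10.0 ** rng.uniform(3, 4.5, size=n_noise)
        mz = np.concatenate([mz, noise_mz])
        intensity = np.concatenate([intensity, noise_intensity])
    return Spectrum(
        precursor_mz=precursor,
        mz=mz,
        intensity=intensity,
        species=species,
        feature_id=feature_id,
        rt=rt,
    )


def simulate_spectra(manifest: SimulationManifest) -> tuple[list[Spectrum], dict]:
    """One spectrum per planted peptide x adduct, with truth."""
    rng = np.random.default_rng(manifest.seed)
    alphabet = default_alphabet()
    spectra: list[Spectrum] = []
    truth = {"spectra": []}
    for names in manifest.peptides:
        peptide = CyclicDepsipeptide.from_names(names, alphabet)
        for adduct in manifest.adducts:
            species = IonSpecies(adduct)
            fid = f"pep{len(spectra) + 1}"
            spectra.append(
                simulate_spectrum(
                    peptide, species, manifest.ppm_sd, manifest.n_noise,
                    seed=rng, feature_id=fid, rt=7.8, shared_intensity=True,
                )
            )
            truth["spectra"].append(
                {
                    "feature_id": fid,
                    "residues": list(names),
                    "adduct": adduct,
                    "neutral_formula": peptide.formula().hill(),
                }
            )
    return spectra, truth


def simulate_feature_table(
    manifest: SimulationManifest,
) -> tuple[FeatureTable, dict]:
    """Feature table with planted washout, blank-contaminated and
    submerged-enriched features; truth lists which features each cleaning
    rule should remove."""
    rng = np.random.default_rng(manifest.seed + 1)
    samples, stations, exposures = [], [], []
    station_labels = [str(i) for i in range(1, manifest.n_stations + 1)]
    for st, exp in zip(station_labels, manifest.station_exposures):
        for rep in range(1, manifest.n_samples_per_station + 1):
            samples.append(f"st{st}_r{rep}")
            stations.append(st)
            exposures.append(exp)
    blanks = [f"blank{i + 1}" for i in range(manifest.n_blanks)]

    n = manifest.n_features
    ids = [str(i + 1) for i in range(n)]
    # Partition: washout | contaminated | enriched | clean (disjoint so
    # each cleaning rule fires on exactly its planted set).
    idx = np.arange(n)
    washout = idx[: manifest.n_washout]
    contaminated = idx[manifest.n_washout: manifest.n_washout + manifest.n_blank_contaminated]
    enriched = idx[
        manifest.n_washout + manifest.n_blank_contaminated:
        manifest.n_washout + manifest.n_blank_contaminated + manifest.n_enriched
    ]

    rt = rng.uniform(0.5, 9.5, size=n)
    rt[washout] = rng.uniform(10.0, 13.0, size=washout.size)
    mz = rng.uniform(150.0, 1500.0, size=n)

    log_mean = rng.normal(10.0, 1.0, size=n)
    areas = np.exp(log_mean[:, None] + rng.normal(0.0, 0.5, size=(n, len(samples))))
    # Reserve the tail block of clean features for microbe-metabolite
    # coupling: exempt from dropout so ranks are tie-free.
    coupling = idx[n - manifest.n_planted_pairs:] if manifest.n_planted_pairs else idx[:0]
    if manifest.dropout > 0:
        drop = rng.random(size=areas.shape) < manifest.dropout
        # never zero out a whole feature row
        drop[:, 0] = False
        drop[coupling, :] = False
        areas[drop] = 0.0
    submerged_cols = np.array([e == "submerged" for e in exposures])
    areas[np.ix_(enriched, submerged_cols)] *= manifest.effect_size

    bio_mean = areas.mean(axis=1)
    blank_areas = np.zeros((n, len(blanks)))
    clean_ratio = rng.uniform(0.0, 0.15, size=n) * (rng.random(n) < 0.5)
    contaminated_ratio = rng.uniform(0.35, 0.8, size=n)
    ratio = clean_ratio.copy()
    ratio[contaminated] = contaminated_ratio[contaminated]
    for j in range(len(blanks)):
        blank_areas[:, j] = bio_mean * ratio * rng.uniform(0.9, 1.1, size=n)

    frame = pd.DataFrame(
        np.hstack([areas, blank_areas]), index=ids, columns=samples + blanks
    )
    meta = pd.DataFrame(
        {
            "station": stations + [""] * len(blanks),
            "exposure": exposures + [""] * len(blanks),
            "is_blank": [False] * len(samples) + [True] * len(blanks),
        },
        index=samples + blanks,
    )
    table = FeatureTable(
        areas=frame,
        mz=pd.Series(mz, index=ids),
        rt=pd.Series(rt, index=ids),
        meta=meta,
    )
    truth = {
        "washout_features": [ids[i] for i in washout],
        "blank_features": [ids[i] for i in contaminated],
        "enriched_features": [ids[i] for i in enriched],
        "coupling_candidates": [ids[i] for i in coupling],
        "exposure": dict(zip(samples, exposures)),
        "effect_size": manifest.effect_size,
    }
    return table, truth


def simulate_otu_table(
    manifest: SimulationManifest,
    feature_table: FeatureTable,
    feature_truth: dict,
) -> tuple[OtuTable, dict]:
    """Dirichlet-multinomial OTU counts with planted monotone couplings.

    Planted pairs tie an OTU's within-sample proportion to a feature's
    abundance rank (sign alternates); with coupling_noise = 0 the planted
    OTU proportion is a strictly monotone function of the feature value.
    """
    rng = np.random.default_rng(manifest.seed + 2)
    samples = feature_table.biological_samples
    n_samples = len(samples)
    n_otus = manifest.n_otus
    otu_ids = [f"OTU{i + 1}" for i in range(n_otus)]

    counts = np.zeros((n_otus, n_samples), dtype=int)
    for j in range(n_samples):
        p = rng.dirichlet(np.full(n_otus, 0.8))
        counts[:, j] = rng.multinomial(manifest.depth, p)

    # Plant couplings on clean, always-observed features.
    reserved = set(feature_truth["washout_features"]) | set(
        feature_truth["blank_features"]
    )
    candidates = [
        fid
        for fid in feature_truth.get("coupling_candidates", feature_table.feature_ids)
        if fid not in reserved
        and (feature_table.areas.loc[fid, samples] > 0).all()
    ]
    n_pairs = min(manifest.n_planted_pairs, len(candidates), n_otus)
    pairs = []
    if n_pairs:
        # Target proportions q[k, s]: strictly monotone in the coupled
        # feature's abundance rank.  Solving jointly against the fixed
        # non-planted base B keeps c[k]/total = q exact up to rounding,
        # so coupling_noise = 0 yields Spearman rho of exactly +-1.
        q = np.zeros((n_pairs, n_samples))
        for k in range(n_pairs):
            fid = candidates[k]
            sign = 1 if k % 2 == 0 else -1
            v = feature_table.areas.loc[fid, samples].to_numpy(dtype=float)
            ranks = rankdata(sign * v)
            frac = 0.005 + 0.02 * ranks / n_samples
            if manifest.coupling_noise > 0:
                frac = frac * np.exp(
                    rng.normal(0.0, manifest.coupling_noise, size=n_samples)
                )
            q[k] = frac
            pairs.append({"otu": otu_ids[k], "feature": fid, "sign": sign})
        counts[:n_pairs, :] = 0
        base = counts.sum(axis=0).astype(float)
        q_total = np.minimum(q.sum(axis=0), 0.9)
        counts[:n_pairs, :] = np.maximum(
            1, np.round(base * q / (1.0 - q_total))
        ).astype(int)

    frame = pd.DataFrame(counts, index=otu_ids, columns=samples)
    taxonomy = pd.Series(
        [f"Bacteria;simulated;clade{i % 7 + 1}" for i in range(n_otus)],
        index=otu_ids,
    )
    truth = {"planted_pairs": pairs}
    return OtuTable(counts=frame, taxonomy=taxonomy), truth
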