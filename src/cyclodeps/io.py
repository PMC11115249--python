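"""Readers and writers for the plain-text formats the pipeline consumes.

MGF peak lists, MZmine-style quantification tables with sample metadata,
OTU count tables, EIC traces, network edges (edge list + GraphML), and
JSON run manifests.  Readers reject malformed input rather than silently
coercing it; every writer produces files its own reader accepts.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cleaning import FeatureTable
from .mass import IonSpecies
from .network import EicTrace, NetworkEdge
from .spectra import Spectrum

__all__ = [
    "MgfError",
    "OtuTable",
    "RunManifest",
    "read_eic_traces",
    "read_mgf",
    "read_otu_table",
    "read_quant_table",
    "write_edges",
    "write_eic_traces",
    "write_graphml",
    "write_mgf",
    "write_otu_table",
    "write_quant_table",
]


class MgfError(ValueError):
    """Malformed MGF input, reported with the offending line number."""


_ADDUCT_RE = re.compile(r"\[?(M[+-−][A-Za-z0-9]+)\]?\s*[0-9]*\s*([+-])?")


def _parse_species(text: str, charge: int | None) -> IonSpecies | None:
    m = _ADDUCT_RE.search(text)
    if not m:
        return None
    adduct = m.group(1).replace("−", "-")
    try:
        return IonSpecies(adduct, charge if charge else 0)
    except ValueError:
        return None


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into spectra.

    PEPMASS is required per block; CHARGE, RTINSECONDS, FEATURE_ID, SCANS,
    ION and TITLE are honored when present.  Feature id falls back from
    FEATURE_ID to SCANS to a sequential counter.  Errors carry the line
    number; an empty file yields an empty list.
    """
    spectra: list[Spectrum] = []
    in_block = False
    params: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    block_start = 0
    counter = 0

    def finish(lineno: int) -> None:
        nonlocal counter
        counter += 1
        if "PEPMASS" not in params:
            raise MgfError(f"line {block_start}: block without PEPMASS")
        try:
            pepmass = float(params["PEPMASS"].split()[0])
        except ValueError:
            raise MgfError(
                f"line {block_start}: bad PEPMASS {params['PEPMASS']!r}"
            ) from None
        charge = None
        if "CHARGE" in params:
            raw = params["CHARGE"].strip()
            m = re.fullmatch(r"(\d+)([+-])?", raw)
            if not m:
                raise MgfError(f"line {block_start}: bad CHARGE {raw!r}")
            charge = int(m.group(1)) * (-1 if m.group(2) == "-" else 1)
        species = None
        for key in ("ION", "TITLE"):
            if key in params:
                species = _parse_species(params[key], charge)
                if species is not None:
                    break
        feature_id = params.get("FEATURE_ID") or params.get("SCANS") or str(counter)
        rt = None
        if "RTINSECONDS" in params:
            rt = float(params["RTINSECONDS"]) / 60.0
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        spectra.append(
            Spectrum(
                precursor_mz=pepmass,
                mz=mz,
                intensity=inten,
                species=species,
                feature_id=str(feature_id),
                rt=rt,
                metadata={k: v for k, v in params.items()},
            )
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MgfError(f"line {lineno}: nested BEGIN IONS")
                in_block = True
                params, peaks, block_start = {}, [], lineno
            elif line == "END IONS":
                if not in_block:
                    raise MgfError(f"line {lineno}: END IONS without BEGIN IONS")
                finish(lineno)
                in_block = False
            elif in_block:
                if "=" in line and not line[0].isdigit():
                    key, value = line.split("=", 1)
                    params[key.strip().upper()] = value.strip()
                else:
                    fields = line.split()
                    if len(fields) < 2:
                        raise MgfError(f"line {lineno}: bad peak line {line!r}")
                    try:
                        peaks.append((float(fields[0]), float(fields[1])))
                    except ValueError:
                        raise MgfError(
                            f"line {lineno}: bad peak line {line!r}"
                        ) from None
            else:
                raise MgfError(f"line {lineno}: content outside BEGIN/END IONS")
    if in_block:
        raise MgfError(f"line {block_start}: BEGIN IONS without END IONS")
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.feature_id is not None:
                fh.write(f"FEATURE_ID={s.feature_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            if s.species is not None:
                sign = "+" if s.species.charge > 0 else "-"
                fh.write(f"CHARGE={abs(s.species.charge)}{sign}\n")
                fh.write(f"ION={s.species}\n")
            if s.rt is not None:
                fh.write(f"RTINSECONDS={s.rt * 60.0:.3f}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{mz:.6f} {inten:.6g}\n")
            fh.write("END IONS\n")


def _norm_header(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip()).lower()


def read_quant_table(path: str | Path, metadata_path: str | Path) -> FeatureTable:
    """Read an MZmine-style quant CSV plus a sample metadata table.

    Expected headers (case-insensitive, whitespace-tolerant): "row ID",
    "row m/z", "row retention time", and one "<sample> Peak area" column
    per sample.  Metadata columns: sample, station, exposure, is_blank.
    Every sample column must have a metadata row.
    """
    df = pd.read_csv(path)
    norm = {_norm_header(c): c for c in df.columns}
    try:
        id_col = norm["row id"]
        mz_col = norm["row m/z"]
        rt_col = norm["row retention time"]
    except KeyError as exc:
        raise ValueError(f"quant table missing required column: {exc}") from None
    if df[id_col].duplicated().any():
        dupes = df[id_col][df[id_col].duplicated()].tolist()
        raise ValueError(f"duplicate feature ids: {dupes}")
    sample_cols = {}
    for raw in df.columns:
        n = _norm_header(raw)
        if n.endswith(" peak area"):
            sample_cols[raw[: raw.lower().rfind(" peak area")].strip()] = raw

    meta = pd.read_csv(metadata_path)
    meta.columns = [_norm_header(c) for c in meta.columns]
    required = {"sample", "is_blank"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    meta["sample"] = meta["sample"].astype(str).str.strip()
    meta = meta.set_index("sample")
    meta["is_blank"] = meta["is_blank"].astype(bool)
    for optional in ("station", "exposure"):
        if optional not in meta.columns:
            meta[optional] = ""

    unmatched = [s for s in sample_cols if s not in meta.index]
    if unmatched:
        raise ValueError(f"samples without metadata: {sorted(unmatched)}")

    ids = df[id_col].astype(str)
    areas = df[[sample_cols[s] for s in sample_cols]].astype(float)
    areas.columns = list(sample_cols)
    areas.index = ids
    return FeatureTable(
        areas=areas,
        mz=pd.Series(df[mz_col].to_numpy(dtype=float), index=ids),
        rt=pd.Series(df[rt_col].to_numpy(dtype=float), index=ids),
        meta=meta,
    )


def write_quant_table(
    t: FeatureTable, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    head = pd.DataFrame(
        {
            "row ID": t.areas.index,
            "row m/z": t.mz.to_numpy(),
            "row retention time": t.rt.to_numpy(),
        },
        index=t.areas.index,
    )
    areas = t.areas.rename(columns={s: f"{s} Peak area" for s in t.areas.columns})
    pd.concat([head, areas], axis=1).to_csv(path, index=False)
    if metadata_path is not None:
        meta = t.meta.reset_index()
        meta = meta.rename(columns={meta.columns[0]: "sample"})
        meta.to_csv(metadata_path, index=False)


@dataclass
class OtuTable:
    """OTU counts (rows) x samples (columns) with a taxonomy string per OTU."""

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts.to_numpy()
        if (counts < 0).any():
            raise ValueError("OTU counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValueError("OTU counts must be integers")


def read_otu_table(path: str | Path) -> OtuTable:
    df = pd.read_csv(path)
    norm = {_norm_header(c): c for c in df.columns}
    if "otu" not in norm:
        raise ValueError("OTU table needs an 'otu' column")
    ids = df[norm["otu"]].astype(str)
    taxonomy = (
        df[norm["taxonomy"]].astype(str)
        if "taxonomy" in norm
        else pd.Series([""] * len(df))
    )
    sample_cols = [
        c for c in df.columns if c not in (norm["otu"], norm.get("taxonomy"))
    ]
    counts = df[sample_cols].astype(int)
    counts.index = ids
    taxonomy.index = ids
    return OtuTable(counts=counts, taxonomy=taxonomy)


def write_otu_table(t: OtuTable, path: str | Path) -> None:
    head = pd.DataFrame(
        {"otu": t.counts.index, "taxonomy": t.taxonomy.to_numpy()},
        index=t.counts.index,
    )
    pd.concat([head, t.counts], axis=1).to_csv(path, index=False)


def write_eic_traces(traces: list[EicTrace], path: str | Path) -> None:
    rows = []
    for tr in traces:
        for i, v in enumerate(tr.trace):
            rows.append(
                {"feature": tr.feature_id, "mz": tr.mz, "rt": tr.rt,
                 "index": i, "intensity": v}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_eic_traces(path: str | Path) -> list[EicTrace]:
    df = pd.read_csv(path)
    traces = []
    for fid, grp in df.groupby("feature", sort=True):
        grp = grp.sort_values("index")
        traces.append(
            EicTrace(
                feature_id=str(fid),
                mz=float(grp["mz"].iloc[0]),
                rt=float(grp["rt"].iloc[0]),
                trace=tuple(grp["intensity"].astype(float)),
            )
        )
    return traces


def write_edges(edges: list[NetworkEdge], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "node_a": e.node_a,
                "node_b": e.node_b,
                "kind": e.kind,
                "score": e.score,
                "n_matched": e.n_matched,
                "annotation": e.annotation,
            }
            for e in edges
        ],
        columns=["node_a", "node_b", "kind", "score", "n_matched", "annotation"],
    ).to_csv(path, sep="\t", index=False)


def write_graphml(
    edges: list[NetworkEdge], node_ids: list[str], path: str | Path
) -> None:
    g = nx.Graph()
    g.add_nodes_from(sorted(node_ids))
    for e in edges:
        g.add_edge(
            e.node_a, e.node_b, kind=e.kind, score=float(e.score),
            n_matched=int(e.n_matched),
        )
    nx.write_graphml(g, path)


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record emitted by every CLI run."""

    tool_version: str
    command: str
    seeds: dict = field(default_factory=dict)
    config_hash: str | None = None
    inputs: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    timestamp: str | None = None

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")
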