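"""Readers and writers for the pipeline's on-disk formats.

Canonical tabular dialect is TSV (UTF-8, "." decimal).  The probe
signal table has one row per probe: annotation columns
(probe_id, gene_family, subcategory, category, lineage, is_positive)
followed by a ``<sample>.signal`` / ``<sample>.snr`` column pair per
sample; undetected cells are empty.  Networks are written as GraphML
(typed node/edge attributes) or SIF for Cytoscape.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import (
    ANNOTATION_COLUMNS,
    PipelineError,
    RawProbeTable,
    StudyDesign,
    validate_annotation,
)
from .rmt import GeneNetwork

SIGNAL_SUFFIX = ".signal"
SNR_SUFFIX = ".snr"
META_COLUMNS = ["probe_id", *ANNOTATION_COLUMNS, "is_positive"]


class FormatError(PipelineError):
    """Malformed input file."""


def write_signal_table(path, raw: RawProbeTable, annotation: pd.DataFrame) -> None:
    """Write probe signals, SNRs and annotations to one TSV."""
    path = Path(path)
    out = annotation.loc[raw.probes, ANNOTATION_COLUMNS].copy()
    out.insert(len(out.columns), "is_positive", raw.is_positive.astype(int))
    for sample in raw.samples:
        out[f"{sample}{SIGNAL_SUFFIX}"] = raw.signal[sample]
        out[f"{sample}{SNR_SUFFIX}"] = raw.snr[sample]
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_signal_table(path) -> tuple[RawProbeTable, pd.DataFrame]:
    """Parse a probe signal TSV into a raw table and annotation table."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise FormatError(f"{path.name}: missing columns {missing_meta}")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].tolist()
        raise FormatError(f"{path.name}: duplicate probe ids {dup[:5]}")
    df = df.set_index("probe_id")

    signal_cols = [c for c in df.columns if c.endswith(SIGNAL_SUFFIX)]
    samples = [c[: -len(SIGNAL_SUFFIX)] for c in signal_cols]
    if not samples:
        raise FormatError(f"{path.name}: no '<sample>{SIGNAL_SUFFIX}' columns found")
    missing_snr = [s for s in samples if f"{s}{SNR_SUFFIX}" not in df.columns]
    if missing_snr:
        raise FormatError(
            f"{path.name}: missing SNR columns {[s + SNR_SUFFIX for s in missing_snr]}"
        )

    def numeric(col: str) -> pd.Series:
        raw_col = df[col]
        parsed = pd.to_numeric(raw_col, errors="coerce")
        bad = parsed.isna() & raw_col.notna() & (raw_col.str.strip() != "")
        if bad.any():
            pos = int(bad.to_numpy().argmax())
            raise FormatError(
                f"{path.name}: non-numeric value {raw_col.iloc[pos]!r} in column "
                f"{col!r}, line {pos + 2}"
            )
        return parsed

    signal = pd.DataFrame({s: numeric(f"{s}{SIGNAL_SUFFIX}") for s in samples})
    snr = pd.DataFrame({s: numeric(f"{s}{SNR_SUFFIX}") for s in samples})
    annotation = validate_annotation(df[ANNOTATION_COLUMNS].copy())
    is_positive = df["is_positive"].astype(int).astype(bool)
    return RawProbeTable(signal, snr, is_positive), annotation


def write_design(path, design: StudyDesign) -> None:
    rows = [
        {
            "sample_id": s,
            "lake_id": lake,
            "elevation_group": design.lake_to_group[lake],
            "elevation_m": design.lake_to_elevation.get(lake, ""),
        }
        for s, lake in design.sample_to_lake.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_design(path) -> StudyDesign:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "lake_id": str})
    required = {"sample_id", "lake_id", "elevation_group"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns {sorted(missing)}")
    sample_to_lake = dict(zip(df["sample_id"], df["lake_id"]))
    lake_to_group = dict(zip(df["lake_id"], df["elevation_group"]))
    lake_to_elev = {}
    if "elevation_m" in df.columns:
        lake_to_elev = {
            l: float(e)
            for l, e in zip(df["lake_id"], pd.to_numeric(df["elevation_m"], errors="coerce"))
            if pd.notna(e)
        }
    return StudyDesign(sample_to_lake, lake_to_group, lake_to_elev)


def write_env(path, env: pd.DataFrame) -> None:
    env.to_csv(path, sep="\t", index_label="sample_id")


def read_env(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_truth(path, truth) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))


NETWORK_FORMATS = ("graphml", "sif")


def write_network(network: GeneNetwork, path, format: str = "graphml") -> None:
    """Export a network as GraphML (typed attributes) or Cytoscape SIF.

    SIF lines use interaction labels ``pp+`` / ``pp-`` carrying the edge
    sign; one line per edge, isolated nodes (none exist by construction)
    would be single-column lines.
    """
    path = Path(path)
    if format == "graphml":
        g = network.graph.copy()
        for n in g.nodes:
            g.nodes[n]["degree"] = g.degree(n)
        g.graph["st"] = network.st
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, d in network.graph.edges(data=True):
                label = "pp+" if d.get("sign", 1) > 0 else "pp-"
                fh.write(f"{u}\t{label}\t{v}\n")
    else:
        raise ValueError(f"format must be one of {NETWORK_FORMATS}, got {format!r}")


def read_network_graphml(path) -> GeneNetwork:
    g = nx.read_graphml(path)
    st = float(g.graph.get("st", 0.0))
    return GeneNetwork(g, st)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _json_default(o):
    try:
        import numpy as np

        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except Exception:
        pass
    raise TypeError(f"not JSON serializable: {type(o)}")
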