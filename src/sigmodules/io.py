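"""Readers and writers for the pipeline's plain-text formats.

Every stage reads and writes TSV/JSON/GMT so stages can be mixed with
externally produced data.  Gene and sample identifiers are opaque strings;
no symbol-alias resolution is attempted.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .contexts import validate_catalog
from .signatures import MUTATION_COLUMNS


def read_mutations(path) -> pd.DataFrame:
    """MAF-like mutation TSV: sample, chrom, pos, ref, alt, variant_type,
    consequence, gene, and optional channel / assigned_signature /
    context_group columns.  1-based coordinates."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "gene": str},
                     keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mutation columns {missing}")
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValueError(f"{path}: positions must be 1-based (>= 1)")
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Expression TSV, genes x samples, first column = gene id."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_edge_list(path) -> pd.DataFrame:
    """Scored edge list TSV: gene1, gene2, score."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: edge list needs columns gene1, gene2, score")
    return df


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [(u, v, d.get("score", 1000.0)) for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["gene1", "gene2", "score"]).to_csv(
        path, sep="\t", index=False)


def read_signature_catalog(path) -> pd.DataFrame:
    """96-channel signature catalog TSV (channels x signatures, v2 order)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return validate_catalog(df)


def write_signature_catalog(cat: pd.DataFrame, path) -> None:
    validate_catalog(cat).to_csv(path, sep="\t")


def read_exposures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_biallelic(path) -> pd.DataFrame:
    """Biallelic-inactivation TSV: sample, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "gene"} <= set(df.columns):
        raise ValueError(f"{path}: biallelic table needs sample and gene columns")
    return df.drop_duplicates()


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    lines = [
        "\t".join([name, name] + sorted(genes)) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce))


def _coerce(o):
    import numpy as np
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
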