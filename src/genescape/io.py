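"""Readers and writers for the plain-text formats used across the pipeline.

Per-study gene lists, evidence flags, interaction edges and score tables
travel as TSV; gene sets as GMT; run configuration as YAML.  Everything is
round-trippable: ``read_x(write_x(obj)) == obj`` for all formats here.
"""
from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_study_lists",
    "write_study_lists",
    "read_gmt",
    "write_gmt",
    "read_edges",
    "write_edges",
    "read_yaml",
    "write_yaml",
]


def read_study_lists(path: str | Path) -> list[tuple[str, str, list[str]]]:
    """Read per-study gene lists from a three-column TSV.

    Expected header: ``study_id  data_type  gene`` (one gene per row).
    Returns a list of ``(study_id, data_type, genes)`` tuples in first-seen
    study order, which is the shape :func:`genescape.funnel.compile_input_genes`
    consumes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"study_id", "data_type", "gene"}
    if not required.issubset(df.columns):
        raise ValueError(f"study-list TSV must have columns {sorted(required)}")
    out: list[tuple[str, str, list[str]]] = []
    for (study_id, data_type), grp in df.groupby(["study_id", "data_type"], sort=False):
        out.append((str(study_id), str(data_type), [str(g) for g in grp["gene"]]))
    return out


def write_study_lists(study_lists: Iterable[tuple[str, str, Iterable[str]]], path: str | Path) -> None:
    rows = [
        {"study_id": sid, "data_type": dtype, "gene": g}
        for sid, dtype, genes in study_lists
        for g in genes
    ]
    pd.DataFrame(rows, columns=["study_id", "data_type", "gene"]).to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: ``name <TAB> description <TAB> gene ...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(
    sets: Mapping[str, Iterable[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *sorted(set(genes))]) + "\n")


def read_edges(path: str | Path) -> pd.DataFrame:
    """Read a typed edge list; requires at least ``source`` and ``target``."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    if not {"source", "target"}.issubset(df.columns):
        raise ValueError("edge TSV must have 'source' and 'target' columns")
    return df


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_yaml(obj: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=False)
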