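"""Readers and writers for the package's interchange formats.

Tables are TSV, calorimetry curves CSV, trees Newick, networks GraphML.
Writers emit numbers at 10 significant digits; every writer's output
round-trips through its paired reader.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

from halosoil.calorimetry import PowerTimeCurve
from halosoil.community import OtuTable
from halosoil.exceptions import InputError
from halosoil.network import EcoNetwork

_FLOAT_FMT = "%.10g"

# canonical metadata column spellings, keyed by lowercase
_CANONICAL_COLS = {
    "plot_id": "plot_id", "sample_id": "sample_id", "ec_us_cm": "ec_uS_cm",
    "salinity_g_kg": "salinity_g_kg", "sal_class": "sal_class",
    "ph": "pH", "soc": "SOC", "na": "Na", "an": "AN", "ap": "AP", "k": "K",
    "dehydrogenase": "dehydrogenase",
}


def read_otu_table(path, orientation: str = "auto") -> OtuTable:
    """Read an OTU count table from TSV.

    Default layout: first column ``otu_id``, one column per sample, an
    optional trailing ``taxonomy`` column. ``orientation="samples"`` treats
    rows as samples instead; ``"auto"`` decides from the first header name.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns.empty:
        raise InputError(f"{path}: empty table")
    first = df.columns[0].strip().lower()
    if orientation == "auto":
        orientation = "samples" if first == "sample_id" else "otus"
    if orientation not in ("otus", "samples"):
        raise InputError(f"unknown orientation {orientation!r}")

    df = df.set_index(df.columns[0])
    taxonomy = None
    tax_col = next((c for c in df.columns if c.strip().lower() == "taxonomy"), None)
    if tax_col is not None:
        taxonomy = df[tax_col].to_dict()
        df = df.drop(columns=[tax_col])

    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (row_id, val) in enumerate(df[col].items()):
            try:
                f = float(val)
            except (TypeError, ValueError):
                raise InputError(
                    f"{path}: non-numeric count at row {row_id!r}, column {col!r}: {val!r}"
                ) from None
            if f != int(f):
                raise InputError(
                    f"{path}: non-integer count at row {row_id!r}, column {col!r}: {val!r}"
                )
            if f < 0:
                raise InputError(
                    f"{path}: negative count at row {row_id!r}, column {col!r}: {val!r}"
                )
            counts[i, j] = int(f)

    if orientation == "otus":
        otu_ids = [str(i) for i in df.index]
        sample_ids = [str(c) for c in df.columns]
        counts = counts.T
    else:
        sample_ids = [str(i) for i in df.index]
        otu_ids = [str(c) for c in df.columns]
        if taxonomy is not None:
            raise InputError("taxonomy column requires OTU-per-row orientation")
    return OtuTable(counts, sample_ids, otu_ids, taxonomy)


def write_otu_table(table: OtuTable, path) -> None:
    """Write an OTU table as TSV, OTUs per row, taxonomy last if present."""
    df = pd.DataFrame(table.counts.T, index=pd.Index(table.otu_ids, name="otu_id"),
                      columns=table.sample_ids)
    if table.taxonomy is not None:
        df["taxonomy"] = [table.taxonomy.get(o, "") for o in table.otu_ids]
    df.to_csv(path, sep="\t")


def read_newick(path) -> TreeNode:
    """Parse a rooted Newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as e:
        raise InputError(f"{path}: malformed Newick: {e}") from e
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
    if n_missing:
        warnings.warn(
            f"{path}: {n_missing} branch(es) had no length; defaulted to 0",
            stacklevel=2,
        )
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_curve_csv(path, sample_id: str | None = None,
                   mode: str = "substrate_induced") -> PowerTimeCurve:
    """Read one ampoule's curve from CSV with columns time_h, power_uW_per_g."""
    df = pd.read_csv(path)
    for col in ("time_h", "power_uW_per_g"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    t = df["time_h"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        line = int(bad[0]) + 3  # 1-based, after header and the first point
        raise InputError(f"{path}: time not strictly increasing at line {line}")
    return PowerTimeCurve(
        t=t, p=df["power_uW_per_g"].to_numpy(dtype=float),
        sample_id=sample_id or Path(str(path)).stem, mode=mode,
    )


def write_curve_csv(curve: PowerTimeCurve, path) -> None:
    pd.DataFrame({"time_h": curve.t, "power_uW_per_g": curve.p}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_metadata(path) -> pd.DataFrame:
    """Read a sample/plot metadata TSV with case-normalized column names."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [
        _CANONICAL_COLS.get(str(c).strip().lower(), str(c).strip())
        for c in df.columns
    ]
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_network(net: EcoNetwork, out_dir, prefix: str = "network") -> dict[str, Path]:
    """Write edge list, node table and GraphML for one network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edges = pd.DataFrame(
        [(u, v, d["r"], d["sign"]) for u, v, d in net.graph.edges(data=True)],
        columns=["otu_a", "otu_b", "r", "sign"],
    )
    nodes = pd.DataFrame(
        {"otu_id": list(net.graph.nodes()),
         "degree": [net.graph.degree(n) for n in net.graph.nodes()]}
    )
    paths = {
        "edges": out_dir / f"{prefix}_edges.tsv",
        "nodes": out_dir / f"{prefix}_nodes.tsv",
        "graphml": out_dir / f"{prefix}.graphml",
    }
    edges.to_csv(paths["edges"], sep="\t", index=False, float_format=_FLOAT_FMT)
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    nx.write_graphml(net.graph, paths["graphml"])
    return paths


def write_manifest(out_dir, manifest: dict) -> Path:
    """Write the machine-readable run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
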