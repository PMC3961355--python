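"""Readers and writers for expression tables, GEO series matrices and network outputs.

Expression tables are plain TSV/CSV files whose first column holds probe
IDs and whose remaining column names encode condition, timepoint and
replicate (default layout ``<condition>_<timepoint>_<replicate>``, e.g.
``LD_4_2`` = condition LD, hour 4, replicate 2).  GEO series-matrix files
carry no machine-readable condition/timepoint/replicate assignment, so a
sample-mapping table must be supplied alongside them.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from wcna.dataset import ExpressionDataset

log = logging.getLogger(__name__)

#: Default column layout: ``<condition>_<timepoint>_<replicate>``.
DEFAULT_LAYOUT = r"^(?P<condition>.+)_(?P<timepoint>\d+(?:\.\d+)?)_(?P<replicate>\d+)$"


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if "\t" in head else ","


# ---------------------------------------------------------------------------
# expression tables


def read_expression_table(path: str | Path, layout: str = DEFAULT_LAYOUT) -> ExpressionDataset:
    """Read a delimited probes × samples expression matrix.

    Parameters
    ----------
    path
        Tab- or comma-delimited file; delimiter is sniffed from the header.
    layout
        Regex with named groups ``condition``, ``timepoint`` and
        ``replicate`` applied to every non-ID column name.

    Raises
    ------
    ValueError
        On duplicate probe IDs, column names not matching the layout,
        ragged rows, or an incomplete condition × timepoint × replicate
        grid — the message names the offending row or column.
    """
    path = Path(path)
    pattern = re.compile(layout)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe ID: {dup!r}")
    if df.isna().any().any():
        row = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing value in row {row!r} (ragged or empty cell)")

    parsed: dict[str, tuple[str, float, int]] = {}
    for col in df.columns:
        m = pattern.match(str(col))
        if m is None:
            raise ValueError(f"column {col!r} does not match layout {layout!r}")
        parsed[col] = (m["condition"], float(m["timepoint"]), int(m["replicate"]))

    conditions = list(dict.fromkeys(c for c, _, _ in parsed.values()))
    timepoints = sorted({t for _, t, _ in parsed.values()})
    replicates = sorted({r for _, _, r in parsed.values()})

    values: dict[str, np.ndarray] = {}
    for cond in conditions:
        arr = np.empty((len(df), len(timepoints), len(replicates)))
        arr.fill(np.nan)
        for col, (c, t, r) in parsed.items():
            if c == cond:
                arr[:, timepoints.index(t), replicates.index(r)] = df[col].to_numpy(float)
        if np.isnan(arr).any():
            raise ValueError(
                f"condition {cond!r}: incomplete timepoint × replicate grid"
            )
        values[cond] = arr
    return ExpressionDataset(
        probe_ids=[str(p) for p in df.index],
        timepoints=np.asarray(timepoints),
        values=values,
    )


def write_expression_table(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write *dataset* as a TSV readable by :func:`read_expression_table`."""
    cols: dict[str, np.ndarray] = {}
    for cond in dataset.condition_labels:
        arr = dataset.values[cond]
        for ti, t in enumerate(dataset.timepoints):
            for ri in range(arr.shape[2]):
                cols[f"{cond}_{t:g}_{ri + 1}"] = arr[:, ti, ri]
    pd.DataFrame(cols, index=pd.Index(dataset.probe_ids, name="probe_id")).to_csv(
        path, sep="\t", float_format="%.10g"
    )


# ---------------------------------------------------------------------------
# GEO series matrix


def read_sample_mapping(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns sample_id, condition, timepoint, replicate."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    missing = {"sample_id", "condition", "timepoint", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"sample mapping missing columns: {sorted(missing)}")
    return df


def read_series_matrix(
    path: str | Path, mapping: pd.DataFrame | str | Path
) -> ExpressionDataset:
    """Read a GEO series-matrix text file.

    GEO metadata describes each sample in free text, so the
    sample→(condition, timepoint, replicate) assignment must be supplied
    as a mapping table (see :func:`read_sample_mapping`).  Samples present
    in the file but absent from the mapping are dropped with a warning; a
    mapped sample absent from the file is an error.
    """
    if not isinstance(mapping, pd.DataFrame):
        mapping = read_sample_mapping(mapping)
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        begin = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines) if l.startswith("!series_matrix_table_end"))
    except StopIteration:
        raise ValueError(f"{path}: missing !series_matrix_table_begin/end delimiters")
    table = [next(csv.reader([l], delimiter="\t")) for l in lines[begin + 1 : end] if l]
    header = [h.strip('"') for h in table[0]]
    df = pd.DataFrame(table[1:], columns=header)
    df.index = df[header[0]].str.strip('"')
    df = df.drop(columns=header[0]).astype(float)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe ID: {dup!r}")

    absent = set(mapping["sample_id"]) - set(df.columns)
    if absent:
        raise ValueError(f"mapped samples absent from series matrix: {sorted(absent)}")
    unmapped = [c for c in df.columns if c not in set(mapping["sample_id"])]
    if unmapped:
        log.warning("dropping %d unmapped samples: %s", len(unmapped), unmapped)
        df = df.drop(columns=unmapped)

    conditions = list(dict.fromkeys(mapping["condition"]))
    timepoints = sorted(mapping["timepoint"].astype(float).unique())
    replicates = sorted(mapping["replicate"].astype(int).unique())
    values: dict[str, np.ndarray] = {}
    for cond in conditions:
        arr = np.empty((len(df), len(timepoints), len(replicates)))
        arr.fill(np.nan)
        sub = mapping[mapping["condition"] == cond]
        for _, row in sub.iterrows():
            ti = timepoints.index(float(row["timepoint"]))
            ri = replicates.index(int(row["replicate"]))
            arr[:, ti, ri] = df[row["sample_id"]].to_numpy()
        if np.isnan(arr).any():
            raise ValueError(f"condition {cond!r}: incomplete timepoint × replicate grid")
        values[cond] = arr
    return ExpressionDataset(
        probe_ids=[str(p) for p in df.index],
        timepoints=np.asarray(timepoints),
        values=values,
    )


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a probe→gene TSV (columns probe_id, gene_id; blank = unmapped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"probe_id", "gene_id"} <= set(df.columns):
        raise ValueError("gene map needs columns probe_id, gene_id")
    return {p: g for p, g in zip(df["probe_id"], df["gene_id"]) if g}


# ---------------------------------------------------------------------------
# network outputs

NODE_COLUMNS = ["probe_id", "gene_id", "degree_a", "degree_b", "difference", "selected"]


def write_node_table(table, path: str | Path) -> None:
    """Write a :class:`~wcna.network.ConnectivityDiffTable` as TSV.

    Columns: probe_id, gene_id, per-condition degrees (named after the
    conditions), difference m, and a selection flag
    (``negative``/``positive``/empty).
    """
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_node_table(path: str | Path) -> pd.DataFrame:
    """Read back a node table written by :func:`write_node_table`."""
    return pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str, "selected": str},
                       keep_default_na=False)


def write_edge_list(network, path: str | Path) -> None:
    """Write the thresholded edges of one condition's network as TSV.

    One row per unordered probe pair with an edge (``i < j`` in probe
    order, so (i, j) and (j, i) never both appear), with the correlation
    coefficient and the condition label.
    """
    if network.L is None:
        raise ValueError("network has no adjacency; call threshold_adjacency first")
    ids = network.probe_ids
    rows = [
        (ids[i], ids[j], network.R[i, j], network.condition)
        for i, j in zip(*np.triu_indices(len(ids), k=1))
        if network.L[i, j]
    ]
    pd.DataFrame(rows, columns=["probe_i", "probe_j", "r", "condition"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def write_graphml(network, path: str | Path) -> None:
    """Export one condition's thresholded network as GraphML."""
    if network.L is None:
        raise ValueError("network has no adjacency; call threshold_adjacency first")
    g = nx.Graph(condition=network.condition, tau=float(network.tau))
    g.add_nodes_from(network.probe_ids)
    ids = network.probe_ids
    for i, j in zip(*np.triu_indices(len(ids), k=1)):
        if network.L[i, j]:
            g.add_edge(ids[i], ids[j], r=float(network.R[i, j]))
    nx.write_graphml(g, path)
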