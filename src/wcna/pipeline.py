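"""End-to-end orchestration of the differential-connectivity pipeline.

The chain is: replicate averaging → (optional) gene collapsing → min–max
normalization → distance screening → wavelet frequency vectors → per-
condition correlation networks → hard-threshold adjacency → connectivity
differences → square ratio → key-probe selection.  Every stage's record
counts are logged and collected in a run report, and each stage's output
is persisted as TSV so a run can be audited or resumed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from wcna import io as wio
from wcna import preprocess, screening, wavelet
from wcna import network as net
from wcna.dataset import ExpressionDataset
from wcna.network import ConnectivityDiffTable, CorrelationNetwork
from wcna.screening import DistanceRanking, InflectionConfig
from wcna.wavelet import WaveletSpec

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run (YAML-serializable)."""

    expression: str | None = None
    format: str = "table"  # "table" | "series-matrix"
    layout: str = wio.DEFAULT_LAYOUT
    sample_mapping: str | None = None
    gene_map: str | None = None  # None -> skip gene collapsing
    conditions: list[str] | None = None  # [a, b]; default: dataset order
    screening_threshold: float | None = None  # manual distance cut; None -> auto knee
    screening_window: int | None = None
    screening_skip: bool = False  # keep every record (no distance cut)
    wavelet_basis: str = "haar"
    tau: float = 0.7
    negative_threshold: float | None = None
    positive_threshold: float | None = None
    knee_window: int | None = None
    out_dir: str = "wcna_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def screening_config(self) -> InflectionConfig:
        if self.screening_threshold is not None:
            return InflectionConfig(method="manual", manual_threshold=self.screening_threshold,
                                    smoothing_window=self.screening_window)
        return InflectionConfig(smoothing_window=self.screening_window)

    def branch_config(self, threshold: float | None) -> InflectionConfig:
        if threshold is not None:
            return InflectionConfig(method="manual", manual_threshold=threshold,
                                    smoothing_window=self.knee_window)
        return InflectionConfig(smoothing_window=self.knee_window)


@dataclass
class PipelineResult:
    """All intermediates of one run plus the count report."""

    normalized: ExpressionDataset
    ranking: DistanceRanking
    networks: dict[str, CorrelationNetwork]
    table: ConnectivityDiffTable
    report: dict = field(default_factory=dict)


def run_chain(
    dataset: ExpressionDataset,
    config: PipelineConfig | None = None,
    gene_map: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory dataset.

    ``gene_map`` (probe → gene) enables the collapsing stage; when absent
    the pipeline runs at probe level, as when no platform annotation is
    available.
    """
    config = config or PipelineConfig()
    report: dict = {"config": config.to_dict(), "n_probes_input": dataset.n_probes}

    ds = preprocess.average_replicates(dataset)
    if gene_map:
        ds, stats = preprocess.collapse_to_genes(ds, gene_map)
        report["n_unmapped_removed"] = stats.removed_unmapped
        report["n_probes_merged"] = stats.merged_probes
    report["n_records"] = ds.n_probes
    ds = preprocess.normalize_dataset(ds)

    conds = config.conditions or ds.condition_labels
    if len(conds) != 2:
        raise ValueError(f"need exactly 2 conditions to contrast, got {conds}")
    cond_a, cond_b = conds

    if config.screening_skip:
        ids, dists = screening.rank_distances(ds, cond_a, cond_b)
        ranking = screening.DistanceRanking(ids, dists, (0, float(dists[0])), list(ids))
    else:
        ranking = screening.select_important(ds, config.screening_config(), cond_a, cond_b)
        report["screening_inflection"] = [ranking.inflection[0], float(ranking.inflection[1])]
    report["n_selected"] = len(ranking.selected_ids)
    if not ranking.selected_ids:
        raise RuntimeError("screening selected no records; lower the threshold")

    sel = set(ranking.selected_ids)
    keep = [i for i, p in enumerate(ds.probe_ids) if p in sel]
    sub = ExpressionDataset(
        probe_ids=[ds.probe_ids[i] for i in keep],
        timepoints=ds.timepoints,
        values={c: ds.values[c][keep] for c in ds.condition_labels},
        gene_ids=ds.gene_ids,
    )

    spec = WaveletSpec(basis=config.wavelet_basis)
    freq = wavelet.build_frequency_vectors(sub, spec)

    networks = {}
    for cond in (cond_a, cond_b):
        cn = net.correlation_matrix(freq[cond], sub.probe_ids, cond)
        networks[cond] = net.threshold_adjacency(cn, config.tau)
        report[f"n_edges_{cond}"] = int(networks[cond].L.sum() // 2)

    table = net.connectivity_difference(networks[cond_a], networks[cond_b])
    table.gene_ids = {p: g for p, g in ds.gene_ids.items() if p in set(sub.probe_ids)}
    report["n_negative"] = table.n_negative
    report["n_positive"] = table.n_positive
    report["n_zero"] = table.n_zero
    if table.n_negative or table.n_positive:
        s_neg, s_pos = net.square_ratio(table)
        report["square_ratio_negative"] = round(s_neg, 6)
        report["square_ratio_positive"] = round(s_pos, 6)

    table = net.select_key_probes(
        table,
        config.branch_config(config.negative_threshold),
        config.branch_config(config.positive_threshold),
    )
    report["negative_threshold"] = table.negative_threshold
    report["positive_threshold"] = table.positive_threshold
    report["n_key_negative"] = len(table.selected_negative or [])
    report["n_key_positive"] = len(table.selected_positive or [])
    report["n_key_total"] = report["n_key_negative"] + report["n_key_positive"]
    report["key_negative"] = sorted(table.selected_negative or [])
    report["key_positive"] = sorted(table.selected_positive or [])
    return PipelineResult(normalized=ds, ranking=ranking, networks=networks,
                         table=table, report=report)


def run_pipeline(config: PipelineConfig) -> dict:
    """Load inputs, run the chain, persist every stage under ``out_dir``.

    Returns the run report (also written as ``report.json``).  Identical
    inputs and config produce byte-identical outputs.
    """
    if config.expression is None:
        raise ValueError("config.expression (input path) is required")
    try:
        if config.format == "series-matrix":
            if config.sample_mapping is None:
                raise ValueError("series-matrix input requires sample_mapping")
            dataset = wio.read_series_matrix(config.expression, config.sample_mapping)
        elif config.format == "table":
            dataset = wio.read_expression_table(config.expression, config.layout)
        else:
            raise ValueError(f"unknown input format {config.format!r}")
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed on {config.expression}: {exc}") from exc
    gene_map = wio.read_gene_map(config.gene_map) if config.gene_map else None

    result = run_chain(dataset, config, gene_map)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wio.write_expression_table(result.normalized, out / "working_database.tsv")
    with open(out / "distances.tsv", "w") as fh:
        fh.write("probe_id\tdistance\tselected\n")
        sel = set(result.ranking.selected_ids)
        for pid, d in zip(result.ranking.probe_ids, result.ranking.distances):
            fh.write(f"{pid}\t{d:.10g}\t{int(pid in sel)}\n")
    with open(out / "frequency_vectors.tsv", "w") as fh:
        n_half = result.normalized.n_timepoints // 2
        heads = [f"c{k + 1}" for k in range(n_half)] + [f"d{k + 1}" for k in range(n_half)]
        fh.write("probe_id\tcondition\t" + "\t".join(heads) + "\n")
        for cond, netw in result.networks.items():
            freq = wavelet.build_frequency_vectors(
                _subset(result.normalized, netw.probe_ids), WaveletSpec(config.wavelet_basis)
            )[cond]
            for pid, row in zip(netw.probe_ids, freq):
                fh.write(pid + "\t" + cond + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    for cond, netw in result.networks.items():
        wio.write_edge_list(netw, out / f"edges_{cond}.tsv")
        wio.write_graphml(netw, out / f"network_{cond}.graphml")
    wio.write_node_table(result.table, out / "node_table.tsv")
    (out / "report.json").write_text(json.dumps(result.report, indent=2, sort_keys=True) + "\n")
    return result.report


def _subset(dataset: ExpressionDataset, probe_ids: list[str]) -> ExpressionDataset:
    pos = {p: i for i, p in enumerate(dataset.probe_ids)}
    idx = [pos[p] for p in probe_ids]
    return ExpressionDataset(
        probe_ids=list(probe_ids),
        timepoints=dataset.timepoints,
        values={c: dataset.values[c][idx] for c in dataset.condition_labels},
        gene_ids=dataset.gene_ids,
    )
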