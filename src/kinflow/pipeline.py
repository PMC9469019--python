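"""End-to-end per-time-slice analysis and report bundle.

For each sampling-time slice: diversity table -> rarefaction (per-time
groups) -> Nei distance + PCoA -> isolation-by-distance Mantel test ->
LOD-threshold calibration -> parentage assignment (full error-rate grid;
the primary rate feeds downstream) -> migration counts and rates ->
directed network -> edge betweenness -> greedy modularity clustering ->
source/sink labels and key nodes -> migration-distance summary.  Slices are
analyzed in isolation; only the final cross-slice summaries (label
persistence, cluster counts) combine them.

All randomness fans out from one master seed through a stable per-stage
scheme, so reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import data as dio
from . import distance as dst
from . import diversity as dv
from . import kinship as kin
from . import network as net

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    return (master_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    genotypes_path: Optional[str] = None
    sites_path: Optional[str] = None
    output_dir: str = "kinflow_out"
    min_population_size: int = 10
    error_rate_grid: tuple[float, ...] = kin.DEFAULT_ERROR_GRID
    primary_error_rate: float = 0.0001
    lod_quantile: float = 0.999
    n_threshold_sim: int = 1000
    min_shared_loci: int = kin.DEFAULT_MIN_SHARED_LOCI
    n_perm: int = 999
    rarefaction_g: Optional[tuple[int, ...]] = None
    robustness_bar: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primary_error_rate not in self.error_rate_grid:
            raise ValueError("primary_error_rate must be one of error_rate_grid")

    def config_hash(self) -> str:
        # output_dir is excluded: where a run writes must not change its identity
        blob = json.dumps(
            {k: v for k, v in self.__dict__.items() if k != "output_dir"},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SliceResult:
    time_code: int
    diversity: pd.DataFrame
    nei: dst.DistanceMatrix
    geo: dst.DistanceMatrix
    pcoa: Optional[dst.PcoaResult]
    ibd: dst.IbdResult
    pairs: list[kin.ParentagePair]
    robustness: kin.RobustnessReport
    counts: net.MigrationCountMatrix
    rates: net.MigrationRateMatrix
    network: net.MigrationNetwork
    betweenness: Optional[dict]
    clustering: net.ClusteringResult
    key_nodes: Optional[net.KeyNodeReport]
    source_sink: dict[str, str]
    distance_summary: Optional[net.DistanceSummary]


@dataclass
class ReportBundle:
    config: PipelineConfig
    slices: dict[int, SliceResult]
    rarefaction: pd.DataFrame
    persistence: pd.DataFrame
    cluster_counts: pd.DataFrame
    pooled_distance: Optional[net.DistanceSummary]
    output_dir: Path = field(default_factory=lambda: Path("."))


def load_dataset(config: PipelineConfig) -> dio.TemporalDataset:
    sites = dio.read_sites(config.sites_path) if config.sites_path else None
    return dio.read_genalex(config.genotypes_path, sites=sites)


def run_pipeline(
    config: PipelineConfig, dataset: Optional[dio.TemporalDataset] = None
) -> ReportBundle:
    """Run every stage on every time slice and write the report bundle."""
    if dataset is None:
        dataset = load_dataset(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    slices: dict[int, SliceResult] = {}
    labels_by_slice: dict[int, dict[str, str]] = {}
    networks = []
    for t in dataset.time_codes:
        sl = dataset.time_slice(t)
        logger.info("slice %d: %d populations, %d individuals",
                    t, len(sl.populations), sl.n_individuals)

        div_rows = dv.diversity_table(sl)
        div = dv.diversity_frame(div_rows + [dv.group_means(div_rows)])

        nei = dst.nei_distance_matrix(sl)
        geo = dst.geographic_distance_matrix(sl)
        pco = dst.pcoa(nei) if not nei.has_infinite else None
        ibd = dst.ibd_test(nei, geo, n_perm=config.n_perm,
                           seed=stage_seed(config.seed, f"ibd{t}"))

        kin_sl = dio.filter_min_size(sl, config.min_population_size)
        rob = kin.error_rate_robustness(
            kin_sl, rates=config.error_rate_grid, quantile=config.lod_quantile,
            n_sim=config.n_threshold_sim, seed=stage_seed(config.seed, f"thr{t}"),
            min_shared_loci=config.min_shared_loci, bar=config.robustness_bar)
        pairs = rob.assignments[config.primary_error_rate]

        counts = net.migration_counts(pairs, kin_sl.populations, time_code=t)
        rates = net.migration_rates(counts)
        coords = {p.code: (p.latitude, p.longitude) for p in kin_sl.populations}
        network = net.build_network(counts, coords)
        has_edges = network.graph.number_of_edges() > 0
        eb = net.edge_betweenness(network) if has_edges else None
        clustering = net.fast_greedy_modularity(network, weights=eb)
        keys = net.key_nodes(network, clustering) if has_edges else None
        labels = net.classify_source_sink(network)
        dsum = net.migration_distance_summary(network) if has_edges else None

        labels_by_slice[t] = labels
        if has_edges:
            networks.append(network)
        slices[t] = SliceResult(t, div, nei, geo, pco, ibd, pairs, rob, counts,
                                rates, network, eb, clustering, keys, labels, dsum)

    curves = dv.rarefaction_curves(dataset, config.rarefaction_g)
    raref = dv.curves_frame(curves)
    persistence = net.label_persistence(labels_by_slice)
    pooled = net.migration_distance_summary(networks) if networks else None

    cluster_counts = pd.DataFrame([
        {"time_code": t, "n_clusters": r.clustering.n_clusters,
         "q": r.clustering.q,
         "n_isolated": sum(1 for n_ in r.network.nodes if r.network.degree(n_) == 0)}
        for t, r in sorted(slices.items())])

    bundle = ReportBundle(config, slices, raref, persistence, cluster_counts,
                          pooled, outdir)
    _write_bundle(bundle, chash)
    return bundle


def cluster_count_table(bundle: ReportBundle) -> pd.DataFrame:
    """Per-slice cluster count, modularity, and isolated-node count."""
    return bundle.cluster_counts.copy()


def _write_bundle(bundle: ReportBundle, chash: str) -> None:
    out = bundle.output_dir
    cfg = bundle.config

    def _save(df: pd.DataFrame, name: str, index: bool = False) -> None:
        df.to_csv(out / name, index=index, float_format="%.10g")

    meta = {"config_hash": chash, "seed": cfg.seed,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in cfg.__dict__.items() if k != "output_dir"}}
    (out / "run_config.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    ibd_rows, dist_rows = [], []
    for t, r in sorted(bundle.slices.items()):
        _save(r.diversity, f"diversity_time{t}.csv")
        _save(r.nei.to_frame(), f"nei_time{t}.csv", index=True)
        _save(r.geo.to_frame(), f"geographic_time{t}.csv", index=True)
        if r.pcoa is not None:
            _save(r.pcoa.coords_frame(), f"pcoa_time{t}_coords.csv", index=True)
            _save(pd.DataFrame({"eigenvalue": r.pcoa.eigenvalues}),
                  f"pcoa_time{t}_eigenvalues.csv")
        ibd_rows.append({"time_code": t, "r": r.ibd.r, "p": r.ibd.p,
                         "n_pairs": r.ibd.n_pairs, "n_perm": r.ibd.n_perm,
                         "seed": r.ibd.seed})
        _save(kin.pairs_frame(r.pairs), f"parentage_time{t}.csv")
        _save(r.robustness.jaccard, f"robustness_jaccard_time{t}.csv", index=True)
        _save(r.counts.to_frame(), f"migration_counts_time{t}.csv", index=True)
        _save(r.rates.to_frame(), f"migration_rates_time{t}.csv")
        _save(r.network.edges_frame(), f"network_edges_time{t}.csv")
        _save(r.clustering.to_frame(), f"clusters_time{t}.csv")
        if r.key_nodes is not None:
            _save(r.key_nodes.to_frame(), f"key_nodes_time{t}.csv")
        if r.distance_summary is not None:
            row = r.distance_summary.to_frame()
            row.insert(0, "time_code", t)
            dist_rows.append(row)
    _save(pd.DataFrame(ibd_rows), "ibd.csv")
    _save(bundle.rarefaction, "rarefaction_curves.csv")
    _save(bundle.persistence, "source_sink_persistence.csv")
    _save(bundle.cluster_counts, "cluster_count_table.csv")
    if bundle.pooled_distance is not None:
        pooled = bundle.pooled_distance.to_frame()
        pooled.insert(0, "time_code", "all")
        dist_rows.append(pooled)
    if dist_rows:
        _save(pd.concat(dist_rows, ignore_index=True), "migration_distance_summary.csv")
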