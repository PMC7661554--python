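"""End-to-end orchestration: io -> homology -> census/abundance ->
pathway scoring -> taxonomy, from a single run configuration.

Every threshold lives in :class:`RunConfig` with the printed defaults of
the underlying method (homology identity/coverage 50/50, bin QC 80/5, 16S
rank thresholds 86.5/94.5, AAI family cutoff 60, expression threshold 0);
there are no hidden constants. The result bundle records every threshold
actually used, and identical config plus inputs yield byte-identical
output tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance, census, homology, io_tables, pathway_scoring, taxonomy
from .io_tables import ValidationError

log = logging.getLogger(__name__)

ALL_STAGES = ("abundance", "census", "pathways", "novelty")


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run.

    Optional inputs (``None``) silently disable the stages that need them;
    explicitly requested stages missing an input raise a validation error
    naming the stage.
    """

    qc_table: str
    contig_table: str
    gene_table: str
    hits_table: str
    reference_map: str
    signal_table: str | None = None
    query_lengths: str | None = None
    depth_table: str | None = None
    count_table: str | None = None
    substrate_map: str | None = None
    catalog: str | None = None
    ssu_identity: str | None = None
    aai_identity: str | None = None
    susc_identity: str | None = None
    susc_labels: str | None = None
    out_dir: str | None = None

    min_identity: float = 50.0
    min_coverage: float = 50.0
    min_completeness: float = 80.0
    max_contamination: float = 5.0
    tau: float = 0.0
    family_t: float = 86.5
    genus_t: float = 94.5
    aai_family_cutoff: float = 60.0
    rbh_min_identity: float = 30.0
    rbh_min_coverage: float = 70.0
    strict: bool = True
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for name in ("min_identity", "min_coverage", "min_completeness",
                     "max_contamination", "family_t", "genus_t",
                     "aai_family_cutoff", "rbh_min_identity",
                     "rbh_min_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"threshold {name}={v} outside [0, 100]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        path_fields = {
            "qc_table", "contig_table", "gene_table", "hits_table",
            "reference_map", "signal_table", "query_lengths", "depth_table",
            "count_table", "substrate_map", "catalog", "ssu_identity",
            "aai_identity", "susc_identity", "susc_labels", "out_dir",
        }
        kwargs = {}
        for key, value in raw.items():
            if key in path_fields and value is not None:
                value = str((base / value))
            if key == "stages":
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def for_community_dir(cls, data_dir: str | Path,
                          **overrides) -> "RunConfig":
        """Config over the standard file layout the synthetic generator
        writes (also a convenient convention for real table exports)."""
        d = Path(data_dir)

        def opt(name: str) -> str | None:
            p = d / f"{name}.tsv"
            return str(p) if p.exists() else None

        kwargs = dict(
            qc_table=str(d / "qc.tsv"),
            contig_table=str(d / "contigs.tsv"),
            gene_table=str(d / "genes.tsv"),
            hits_table=str(d / "hits.tsv"),
            reference_map=str(d / "reference_map.tsv"),
            signal_table=opt("signal"),
            query_lengths=opt("query_lengths"),
            depth_table=opt("depth"),
            count_table=opt("counts"),
            substrate_map=opt("substrate_map"),
            ssu_identity=opt("ssu_identity"),
            aai_identity=opt("aai_identity"),
            susc_identity=opt("susc_identity"),
            susc_labels=opt("susc_labels"),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    PATH_FIELDS = ("qc_table", "contig_table", "gene_table", "hits_table",
                   "reference_map", "signal_table", "query_lengths",
                   "depth_table", "count_table", "substrate_map", "catalog",
                   "ssu_identity", "aai_identity", "susc_identity",
                   "susc_labels")

    def validate_paths(self) -> None:
        for name in self.PATH_FIELDS:
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ValidationError(f"{name}: no such file {value}")


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the configured stages; returns the result bundle.

    Bundle keys (stage-dependent): qc_retained, assignments, abundance,
    rpkm, census, highly_expressed, pathway_matrix, pathway_summary,
    novelty_16s, novelty_aai, susc_clusters, manifest/run_config.
    """
    config.validate_paths()

    # --- io stage (always)
    qc = io_tables.read_qc_table(config.qc_table)
    contigs = io_tables.read_contig_table(config.contig_table)
    genes = io_tables.read_gene_table(config.gene_table)
    bins = io_tables.bins_from_tables(qc, contigs, genes)
    retained = io_tables.qc_filter_bins(bins, config.min_completeness,
                                        config.max_contamination)
    retained_ids = {b.bin_id for b in retained}
    log.info("QC filter: retained %d of %d bins", len(retained), len(bins))

    gene_bins = {g.gene_id: g.bin_id for g in genes
                 if g.bin_id in retained_ids}
    gene_lengths = {g.gene_id: g.length for g in genes
                    if g.bin_id in retained_ids}

    # --- homology stage (always)
    qlens = None
    if config.query_lengths:
        qdf = io_tables._read_tsv(config.query_lengths,
                                  ("gene_id", "length"), {"length": int})
        qlens = dict(zip(qdf.gene_id, qdf.length))
    hits = io_tables.parse_hits_table(config.hits_table, qlens,
                                      strict=config.strict)
    filtered = homology.filter_hits(hits, config.min_identity,
                                    config.min_coverage)
    refmap = io_tables.read_reference_map(config.reference_map)
    assignments = homology.assign_categories(filtered, refmap)

    bundle: dict[str, pd.DataFrame] = {
        "qc_retained": pd.DataFrame(
            [{"bin_id": b.bin_id, "completeness": b.completeness,
              "contamination": b.contamination} for b in retained]
        ),
        "assignments": pd.DataFrame(
            [dataclasses.asdict(a) for a in assignments],
            columns=["gene_id", "category_kind", "category_label",
                     "source_subject"],
        ),
    }

    rpkm_df = None
    if config.count_table and (
            "pathways" in config.stages or "census" in config.stages):
        counts = io_tables.read_count_table(config.count_table)
        rpkm_df = abundance.rpkm_table(counts, gene_lengths)
        bundle["rpkm"] = rpkm_df

    if "abundance" in config.stages:
        if not config.depth_table:
            raise ValidationError("abundance stage requires depth_table")
        depth = io_tables.read_depth_table(config.depth_table)
        bundle["abundance"] = abundance.abundance_table(retained, depth)

    if "census" in config.stages:
        signal = (io_tables.read_signal_table(config.signal_table)
                  if config.signal_table else {})
        bundle["census"] = census.census_table(
            assignments, signal, gene_bins, sorted(retained_ids))
        if rpkm_df is not None:
            bundle["highly_expressed"] = census.highly_expressed_table(
                rpkm_df, assignments, signal, gene_bins)

    if "pathways" in config.stages:
        if rpkm_df is None or not config.substrate_map:
            raise ValidationError(
                "pathways stage requires count_table and substrate_map")
        catalog = pathway_scoring.load_catalog(config.catalog)
        substrate = io_tables.read_substrate_map(config.substrate_map)
        symbols_by_bin: dict[str, set[str]] = {b: set() for b in retained_ids}
        symbol_gene: dict[str, dict[str, str]] = {b: {} for b in retained_ids}
        for a in assignments:
            if a.category_kind != "pathway_gene":
                continue
            bin_id = gene_bins.get(a.gene_id)
            if bin_id is None:
                continue
            symbols_by_bin[bin_id].add(a.category_label)
            prev = symbol_gene[bin_id].get(a.category_label)
            if prev is None or a.gene_id < prev:
                symbol_gene[bin_id][a.category_label] = a.gene_id
        matrix = pathway_scoring.expression_matrix(
            symbols_by_bin, catalog, rpkm_df, symbol_gene, substrate,
            tau=config.tau)
        bundle["pathway_matrix"] = matrix
        summary_rows = []
        for bin_id in sorted(retained_ids):
            n_enc, _ = pathway_scoring.encoded_aa_count(
                symbols_by_bin[bin_id], catalog)
            sub = matrix[matrix.bin_id == bin_id]
            n_expr = sub.groupby("aa").expressed.any().sum()
            summary_rows.append({"bin_id": bin_id, "encoded_aa": n_enc,
                                 "expressed_aa": int(n_expr),
                                 "tau": config.tau})
        bundle["pathway_summary"] = pd.DataFrame(summary_rows)

    if "novelty" in config.stages:
        if config.ssu_identity:
            ssu = io_tables.read_identity_table(config.ssu_identity)
            bundle["novelty_16s"] = taxonomy.novelty_table(
                ssu, "16S", family_t=config.family_t, genus_t=config.genus_t)
        if config.aai_identity:
            aai = io_tables.read_identity_table(config.aai_identity,
                                                value_col="aai")
            bundle["novelty_aai"] = taxonomy.novelty_table(
                aai, "AAI", value_col="aai",
                aai_family_cutoff=config.aai_family_cutoff)
        if config.susc_identity and config.susc_labels:
            susc = io_tables.read_identity_table(config.susc_identity)
            labels = io_tables.read_label_table(config.susc_labels)
            bundle["susc_clusters"] = taxonomy.susc_cluster_table(susc, labels)

    if config.out_dir:
        manifest = io_tables.write_report(bundle, config.out_dir)
        bundle["manifest"] = manifest
        used = {f.name: getattr(config, f.name)
                for f in dataclasses.fields(config)}
        used["stages"] = list(config.stages)
        with open(Path(config.out_dir) / "config_used.yaml", "w") as fh:
            yaml.safe_dump(used, fh, sort_keys=True)
    return bundle
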