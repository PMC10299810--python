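"""End-to-end core-genome pipeline: configuration, orchestration, report bundle.

Chains the stages of the family-defining analysis — hit-table ingest,
E-value filtering, per-genome presence resolution, presence/absence matrix,
core/accessory/intermediate classification with out-group-based unique-core
flags, gap-tolerant block finding, conservation profile — and writes a
reproducible report bundle.  Every emitted file carries a header with the
tool version, a hash of the exact configuration used and the seed, because
the choice of thresholds (notably the core threshold) must be auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .blocks import BlockResult, export_genome_map, find_blocks
from .homology import (
    AccessionMap,
    GenomePanel,
    HitDialect,
    parse_hit_table,
    filter_hits,
    resolve_presence,
)
from .pangenome import (
    CLASS_CORE,
    CoreClassification,
    ConservationProfile,
    PresenceAbsenceMatrix,
    build_matrix,
    build_profile,
    classify_genes,
    outgroup_detections,
    summarize,
)

logger = logging.getLogger("phagecore")

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "load_annotations"]


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Threshold defaults follow the family analysis: inclusive E-value cutoff
    0.05; core iff conservation frequency strictly above ``theta_core``
    (0.90), accessory iff at most ``theta_acc`` (0.10); unique-core iff at
    most ``k_outgroup`` (0) out-group detections; blocks of at least
    ``b_min`` (3) core genes tolerating at most ``g_max`` (3) non-core genes
    between.
    """

    hits: str = ""
    accession_map: str = ""
    genomes: str = ""
    gene_order: str = ""
    annotations: str | None = None
    out_dir: str = "phagecore_out"
    e_cutoff: float = 0.05
    round_policy: str = "last"
    theta_core: float = 0.90
    theta_acc: float = 0.10
    k_outgroup: int = 0
    b_min: int = 3
    g_max: int = 3
    circular: bool = False
    bin_width: float = 0.05
    seed: int = 0
    dialect: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.theta_acc < self.theta_core <= 1):
            raise ValueError("need 0 <= theta_acc < theta_core <= 1")
        if not self.e_cutoff > 0:
            raise ValueError("e_cutoff must be > 0")
        if self.b_min < 1 or self.g_max < 0 or self.k_outgroup < 0:
            raise ValueError("b_min >= 1, g_max >= 0, k_outgroup >= 0 required")
        if self.round_policy not in ("last", "union"):
            raise ValueError("round_policy must be 'last' or 'union'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load from a YAML mapping; keyword overrides (CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (not file locations)."""
        params = {k: v for k, v in self.to_dict().items()
                  if k not in ("hits", "accession_map", "genomes", "gene_order",
                               "annotations", "out_dir")}
        blob = json.dumps(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"phagecore v{__version__}",
            f"config_hash={self.config_hash()} seed={self.seed}",
            f"e_cutoff={self.e_cutoff} round_policy={self.round_policy} "
            f"theta_core={self.theta_core} theta_acc={self.theta_acc} "
            f"k_outgroup={self.k_outgroup} b_min={self.b_min} g_max={self.g_max} "
            f"circular={self.circular}",
        ]

    def hit_dialect(self) -> HitDialect:
        return HitDialect(**self.dialect) if self.dialect else HitDialect()


def load_annotations(path: str | Path) -> pd.Series:
    """Load a per-gene function table: gene_id <TAB> hypothetical|annotated."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene_id", "flag"], dtype=str)
    return df.set_index("gene_id")["flag"]


@dataclass
class PipelineReport:
    """Everything a run produced, in memory plus on disk."""

    config: RunConfig
    matrix: PresenceAbsenceMatrix
    classification: CoreClassification
    blocks: BlockResult
    profile: ConservationProfile
    summary: dict
    files: dict[str, Path]

    def summary_text(self) -> str:
        s = self.summary
        lines = [
            f"phagecore v{__version__} core-genome report "
            f"(config {self.config.config_hash()}, seed {self.config.seed})",
            f"in-group genomes : {len(self.matrix.data.columns)}",
            f"reference genes  : {s['n_genes']}",
            f"core genes       : {s['n_core']} ({s['core_percent']}% of genome; "
            f"frequency > {s['theta_core']:.2f})",
            f"accessory genes  : {s['n_accessory']} ({s['accessory_percent']}% of genome; "
            f"frequency <= {s['theta_acc']:.2f})",
            f"intermediate     : {s['n_intermediate']}",
            f"unique-core genes: {s['n_unique_core']} "
            f"(<= {s['k_outgroup']} out-group detections); "
            f"{s['n_outgroup_shared_core']} core genes shared with out-group",
            f"hypothetical core: {s['n_hypothetical_core']} "
            f"({s['hypothetical_core_percent']}% of core genes)",
            f"conserved blocks : {s['n_blocks']} "
            f"(>= {self.config.b_min} core genes, gaps <= {self.config.g_max}); "
            f"{s['n_unblocked_core']} core genes outside blocks",
        ]
        if self.matrix.no_self_hit:
            lines.append(f"note: {len(self.matrix.no_self_hit)} reference genes had no "
                         "self-hit row and were forced present in the reference genome")
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run ingest → filter → presence → classify → blocks → profile → export.

    Deterministic given inputs and configuration.  Stage failures propagate
    as exceptions naming the stage; the CLI maps them to nonzero exit.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()

    logger.info("ingest: parsing %s", config.hits)
    panel = GenomePanel.from_tsv(config.genomes, config.gene_order)
    accmap = AccessionMap.from_tsv(config.accession_map)
    parsed = parse_hit_table(config.hits, config.hit_dialect())
    if parsed.skipped:
        logger.warning("ingest: skipped %d unparseable rows", len(parsed.skipped))
    logger.info("filter: E-value <= %g, round_policy=%s", config.e_cutoff, config.round_policy)
    kept = filter_hits(parsed.records, config.e_cutoff, config.round_policy)
    logger.info("filter: %d of %d hits retained", len(kept), len(parsed.records))
    presence = resolve_presence(kept, accmap, panel)
    if presence.unmapped:
        logger.warning("presence: %d hits to %d unmapped accessions (see unmapped report)",
                       sum(presence.unmapped.values()), len(presence.unmapped))

    matrix = build_matrix(presence, panel)
    if matrix.no_self_hit:
        logger.warning("matrix: %d reference genes lacked a self-hit row; forced present "
                       "in the reference genome", len(matrix.no_self_hit))
    out_counts = outgroup_detections(presence, panel)
    classification = classify_genes(
        matrix, out_counts,
        theta_core=config.theta_core, theta_acc=config.theta_acc,
        k_outgroup=config.k_outgroup,
    )
    core_flags = (classification.table["gene_class"] == CLASS_CORE).tolist()
    blocks = find_blocks(core_flags, b_min=config.b_min, g_max=config.g_max,
                         circular=config.circular,
                         gene_ids=list(panel.reference_gene_order))
    profile = build_profile(matrix, classification, blocks.blocks, bin_width=config.bin_width)
    # attach block ids to the classification table for the exported TSV
    classification.table["block_id"] = profile.per_gene["block_id"]

    annotations = load_annotations(config.annotations) if config.annotations else None
    summary = summarize(classification, annotations)
    summary["n_blocks"] = len(blocks)
    summary["n_unblocked_core"] = len(blocks.unblocked)

    files = {
        "matrix": out_dir / "presence_absence_matrix.tsv",
        "classification": out_dir / "classification.tsv",
        "blocks": out_dir / "blocks.tsv",
        "genome_map": out_dir / "genome_map.bed",
        "profile": out_dir / "conservation_profile.tsv",
        "histogram": out_dir / "conservation_histogram.tsv",
        "unmapped": out_dir / "unmapped_accessions.tsv",
        "summary_txt": out_dir / "summary.txt",
        "summary_tsv": out_dir / "summary.tsv",
    }
    matrix.to_tsv(files["matrix"], header)
    classification.to_tsv(files["classification"], header)
    blocks.summary_tsv(files["blocks"], header)
    export_genome_map(profile, files["genome_map"], header_lines=header)
    profile.to_tsv(files["profile"], files["histogram"], header)
    presence.write_unmapped_report(files["unmapped"])

    report = PipelineReport(config=config, matrix=matrix, classification=classification,
                            blocks=blocks, profile=profile, summary=summary, files=files)
    files["summary_txt"].write_text(report.summary_text() + "\n")
    with open(files["summary_tsv"], "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("key\tvalue\n")
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
    logger.info("report bundle written to %s", out_dir)
    return report
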