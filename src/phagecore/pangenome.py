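"""Presence/absence matrix, conservation frequencies and core/accessory classification.

The family-defining analysis: a reference gene is *core* if detected in more
than ``theta_core`` (default 90%) of the chimallin-encoding (in-group)
genomes, *accessory* if detected in at most ``theta_acc`` (default 10%), and
*intermediate* otherwise.  A core gene is *unique-core* when it has at most
``k_outgroup`` (default 0) detections among out-group genomes — the genes
that plausibly define nucleus-based replication rather than phage biology at
large.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .homology import IN_GROUP, OUT_GROUP, GenomePanel, PresenceResult

__all__ = [
    "CLASS_CORE",
    "CLASS_ACCESSORY",
    "CLASS_INTERMEDIATE",
    "PresenceAbsenceMatrix",
    "CoreClassification",
    "ConservationProfile",
    "build_matrix",
    "outgroup_detections",
    "classify_genes",
    "summarize",
    "build_profile",
]

CLASS_CORE = "core"
CLASS_ACCESSORY = "accessory"
CLASS_INTERMEDIATE = "intermediate"


@dataclass
class PresenceAbsenceMatrix:
    """Boolean genes × in-group genomes detection matrix.

    ``data`` is a pandas DataFrame indexed by reference gene id (in genome
    order) with one boolean column per in-group genome.  ``frequency`` is the
    per-gene fraction of in-group genomes with a detection (row mean).
    ``no_self_hit`` lists reference genes that had no hit row to the
    reference genome itself; they are forced present there (a genome trivially
    contains its own genes) and flagged for the report.
    """

    data: pd.DataFrame
    panel: GenomePanel
    no_self_hit: tuple[str, ...] = ()

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def frequency(self) -> pd.Series:
        return self.data.mean(axis=1)

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("# presence/absence matrix: rows = reference genes (genome order), "
                     "columns = in-group genomes, cells = 0/1 detection\n")
            self.data.astype(int).to_csv(fh, sep="\t", index_label="gene_id")


def build_matrix(presence: PresenceResult, panel: GenomePanel) -> PresenceAbsenceMatrix:
    """Materialize the in-group presence/absence matrix from detection counts.

    Dimensions are |reference genes| × |in-group genomes|.  Reference genes
    with no self-hit row are set present in the reference genome and flagged.
    """
    if panel.n_ingroup < 1:
        raise ValueError("panel must contain at least one in-group genome")
    if not panel.reference_gene_order:
        raise ValueError("reference gene order is empty")
    genes = list(panel.reference_gene_order)
    genomes = list(panel.in_group_genomes)
    arr = np.zeros((len(genes), len(genomes)), dtype=bool)
    gidx = {g: i for i, g in enumerate(genes)}
    midx = {m: j for j, m in enumerate(genomes)}
    for (gene, genome), count in presence.counts.items():
        if count >= 1 and gene in gidx and genome in midx:
            arr[gidx[gene], midx[genome]] = True
    ref_col = midx[panel.reference_genome_id]
    no_self = tuple(g for g in genes if not arr[gidx[g], ref_col])
    arr[:, ref_col] = True
    data = pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=genomes)
    return PresenceAbsenceMatrix(data=data, panel=panel, no_self_hit=no_self)


def outgroup_detections(presence: PresenceResult, panel: GenomePanel) -> pd.Series:
    """Per-gene count of out-group genomes with at least one detection."""
    return pd.Series(
        {g: len(presence.genomes_with(g, OUT_GROUP)) for g in panel.reference_gene_order},
        name="outgroup_detections",
    ).reindex(list(panel.reference_gene_order))


@dataclass
class CoreClassification:
    """Per-gene class labels, out-group detections and unique-core flags.

    ``table`` columns: gene_id (index), index (position in genome order),
    frequency, gene_class, outgroup_detections, unique_core.  The class
    partition is exhaustive and exclusive; ``unique_core`` implies
    ``gene_class == core`` and ``outgroup_detections <= k_outgroup``.
    """

    table: pd.DataFrame
    theta_core: float
    theta_acc: float
    k_outgroup: int

    @property
    def core_genes(self) -> list[str]:
        return list(self.table.index[self.table["gene_class"] == CLASS_CORE])

    @property
    def unique_core_genes(self) -> list[str]:
        return list(self.table.index[self.table["unique_core"]])

    def counts(self) -> dict[str, int]:
        vc = self.table["gene_class"].value_counts()
        return {
            CLASS_CORE: int(vc.get(CLASS_CORE, 0)),
            CLASS_ACCESSORY: int(vc.get(CLASS_ACCESSORY, 0)),
            CLASS_INTERMEDIATE: int(vc.get(CLASS_INTERMEDIATE, 0)),
        }

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# thresholds: theta_core={self.theta_core} (core iff frequency > theta_core), "
                     f"theta_acc={self.theta_acc} (accessory iff frequency <= theta_acc), "
                     f"k_outgroup={self.k_outgroup} (unique-core iff core and "
                     f"outgroup_detections <= k_outgroup)\n")
            fh.write("# columns: gene_id, index (position in reference gene order), "
                     "frequency (fraction of in-group genomes with a detection), gene_class, "
                     "outgroup_detections (out-group genomes with >=1 hit), unique_core, "
                     "block_id (conserved block membership or '.')\n")
            self.table.to_csv(fh, sep="\t", index_label="gene_id")


def classify_genes(
    matrix: PresenceAbsenceMatrix,
    outgroup: Mapping[str, int] | pd.Series | None = None,
    theta_core: float = 0.90,
    theta_acc: float = 0.10,
    k_outgroup: int = 0,
) -> CoreClassification:
    """Classify each reference gene as core / accessory / intermediate.

    Core requires frequency **strictly greater** than ``theta_core`` ("more
    than 90%"); accessory requires frequency ≤ ``theta_acc`` ("10% or
    fewer"); everything else is intermediate.  Classification into
    core/accessory depends only on in-group frequencies; the out-group
    counts only decide the unique-core flag.

    Parameters
    ----------
    outgroup : mapping gene_id -> detection count, optional
        Number of out-group genomes with ≥1 retained hit per gene.  Missing
        genes count as 0 detections.
    """
    if not (0 <= theta_acc < theta_core <= 1):
        raise ValueError(
            f"thresholds must satisfy 0 <= theta_acc < theta_core <= 1, "
            f"got theta_acc={theta_acc}, theta_core={theta_core}"
        )
    if k_outgroup < 0:
        raise ValueError("k_outgroup must be >= 0")
    freq = matrix.frequency
    gene_class = pd.Series(CLASS_INTERMEDIATE, index=freq.index, name="gene_class")
    gene_class[freq > theta_core] = CLASS_CORE
    gene_class[freq <= theta_acc] = CLASS_ACCESSORY
    if outgroup is None:
        out = pd.Series(0, index=freq.index)
    else:
        out = pd.Series(outgroup).reindex(freq.index).fillna(0).astype(int)
    unique = (gene_class == CLASS_CORE) & (out <= k_outgroup)
    table = pd.DataFrame(
        {
            "index": np.arange(len(freq)),
            "frequency": freq,
            "gene_class": gene_class,
            "outgroup_detections": out,
            "unique_core": unique,
        }
    )
    return CoreClassification(table=table, theta_core=theta_core,
                              theta_acc=theta_acc, k_outgroup=k_outgroup)


def summarize(
    classification: CoreClassification,
    annotations: Mapping[str, str] | pd.Series | None = None,
) -> dict:
    """Headline summary statistics of a classification.

    Genome-fraction percentages (core, accessory) are rounded to the nearest
    integer; the hypothetical share of the core genome to one decimal.  Genes
    absent from the annotation table default to ``hypothetical`` and are
    counted in ``n_unannotated_defaulted``.

    Returns a plain dict with counts, percentages and the thresholds used.
    """
    table = classification.table
    n_genes = len(table)
    counts = classification.counts()
    n_core = counts[CLASS_CORE]
    n_acc = counts[CLASS_ACCESSORY]
    core_ids = classification.core_genes

    n_defaulted = 0
    if annotations is None:
        ann = pd.Series("hypothetical", index=table.index)
        n_defaulted = n_genes
    else:
        ann = pd.Series(annotations).reindex(table.index)
        n_defaulted = int(ann.isna().sum())
        ann = ann.fillna("hypothetical")
    bad = set(ann.unique()) - {"hypothetical", "annotated"}
    if bad:
        raise ValueError(f"annotation flags must be hypothetical/annotated, got {sorted(bad)}")
    n_hypo_core = int((ann.loc[core_ids] == "hypothetical").sum()) if core_ids else 0

    summary = {
        "n_genes": n_genes,
        "n_core": n_core,
        "core_percent": round(100 * n_core / n_genes) if n_genes else 0,
        "n_accessory": n_acc,
        "accessory_percent": round(100 * n_acc / n_genes) if n_genes else 0,
        "n_intermediate": counts[CLASS_INTERMEDIATE],
        "n_unique_core": len(classification.unique_core_genes),
        "n_outgroup_shared_core": n_core - len(classification.unique_core_genes),
        "n_hypothetical_core": n_hypo_core,
        "hypothetical_core_percent": round(100 * n_hypo_core / n_core, 1) if n_core else 0.0,
        "n_unannotated_defaulted": n_defaulted,
        "theta_core": classification.theta_core,
        "theta_acc": classification.theta_acc,
        "k_outgroup": classification.k_outgroup,
    }
    return summary


@dataclass
class ConservationProfile:
    """Per-gene conservation along the genome plus the frequency histogram.

    ``per_gene`` has one row per reference gene in genome order (gene_id
    index; columns index, frequency, gene_class, block_id) — sufficient to
    redraw a circular conservation bar plot of the genome.  ``histogram``
    bins the per-gene frequencies over [0, 1]; a conserved panel shows the
    characteristic bimodal shape (accessory peak near 0, core peak near 1).
    """

    per_gene: pd.DataFrame
    histogram: pd.DataFrame
    bin_width: float

    def to_tsv(self, per_gene_path: str | Path, histogram_path: str | Path,
               header_lines: Sequence[str] = ()) -> None:
        with open(per_gene_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("# columns: gene_id, index (genome order), frequency, gene_class, "
                     "block_id ('.' = not in a conserved block)\n")
            self.per_gene.to_csv(fh, sep="\t", index_label="gene_id")
        with open(histogram_path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# conservation-frequency histogram, bin width {self.bin_width}; "
                     "columns: bin_left, bin_right, count\n")
            self.histogram.to_csv(fh, sep="\t", index=False)


def build_profile(
    matrix: PresenceAbsenceMatrix,
    classification: CoreClassification,
    blocks: Sequence = (),
    bin_width: float = 0.05,
) -> ConservationProfile:
    """Assemble the per-gene conservation profile and frequency histogram.

    *blocks* are :class:`~phagecore.blocks.GeneBlock` objects; their member
    indices must be valid positions in the reference gene order.  Histogram
    bin edges cover [0, 1]; the top bin is closed so frequency 1.0 is counted.
    """
    if not (0 < bin_width <= 1):
        raise ValueError("bin_width must be in (0, 1]")
    table = classification.table
    block_id = pd.Series(".", index=table.index, dtype=object)
    genes = list(table.index)
    for blk in blocks:
        for idx in blk.member_indices:
            if not 0 <= idx < len(genes):
                raise ValueError(f"block {blk.block_id} references invalid gene index {idx}")
            block_id.iloc[idx] = str(blk.block_id)
    per_gene = pd.DataFrame(
        {
            "index": table["index"],
            "frequency": table["frequency"],
            "gene_class": table["gene_class"],
            "block_id": block_id,
        }
    )
    n_bins = int(np.ceil(round(1.0 / bin_width, 9)))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    counts, _ = np.histogram(table["frequency"].to_numpy(), bins=edges)
    histogram = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    assert int(histogram["count"].sum()) == len(table)
    return ConservationProfile(per_gene=per_gene, histogram=histogram, bin_width=bin_width)
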