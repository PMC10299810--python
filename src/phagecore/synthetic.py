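"""Synthetic inputs with known ground truth for the whole pipeline.

Generates homology-panel inputs (hit tables, accession maps, panel
definitions) with planted per-gene-family conservation frequencies, planted
conserved blocks along a reference gene order and planted family-unique
genes, plus quantification inputs (circular rotation tracks with
localization noise, cell geometries with nucleoid layouts, binomially
sampled Hill dose-response counts).  Every generator is fully determined by
(parameters, seed); defaults mirror the study conditions of the family
analysis (66 in-group genomes, 317 reference genes, 72 core of which 21
unique, 7 blocks) and of the microscopy quantification (2-minute time lapses
at 4-second intervals).

Presence/absence is the unit of truth; no sequence-level evolution is
simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .homology import (
    IN_GROUP,
    OUT_GROUP,
    AccessionMap,
    GenomePanel,
    HitDialect,
)
from .imaging import CellGeometry, DoseResponseData, RotationTrack
from .pangenome import CLASS_ACCESSORY, CLASS_CORE, CLASS_INTERMEDIATE

__all__ = [
    "PanelTruth",
    "generate_panel",
    "generate_tracks",
    "generate_geometries",
    "generate_dose_response",
    "generate_rotating_cohort",
]


@dataclass
class PanelTruth:
    """Ground truth of a generated genome panel.

    ``genes`` columns (gene_id index): index, planted_frequency,
    planted_class, planted_unique, planted_block_id ('.' if none).
    ``presence`` is the realized genes × in-group-genomes boolean matrix
    (the reference genome column is all True); ``outgroup_presence`` the
    genes × out-group matrix.  ``files`` maps logical names to written paths
    when an output directory was given.
    """

    panel: GenomePanel
    genes: pd.DataFrame
    presence: pd.DataFrame
    outgroup_presence: pd.DataFrame
    seed: int
    n_blocks: int
    files: dict[str, Path] = field(default_factory=dict)

    @property
    def planted_classes(self) -> pd.Series:
        return self.genes["planted_class"]

    @property
    def n_unique(self) -> int:
        return int(self.genes["planted_unique"].sum())


def _block_layout(rng, n_genes, n_core, n_blocks, b_min, g_max):
    """Place n_core core genes into n_blocks gap-tolerant runs along n_genes positions.

    Returns (core_positions ordered by block then position, block_id per core
    position).  Blocks are separated by more than g_max non-core genes so the
    planted count is exactly what the block finder recovers.
    """
    if n_blocks < 1 or n_core < n_blocks * b_min:
        raise ValueError(f"cannot split {n_core} core genes into {n_blocks} blocks of >= {b_min}")
    # member counts: near-even split, every block >= b_min
    sizes = np.full(n_blocks, n_core // n_blocks, dtype=int)
    sizes[: n_core % n_blocks] += 1
    # occasional internal gaps of 1 gene (<= g_max) for realism
    internal = []
    for m in sizes:
        gaps = (rng.random(m - 1) < 0.2).astype(int) if (m > 1 and g_max >= 1) else np.zeros(max(m - 1, 0), int)
        internal.append(gaps)
    spans = [m + int(g.sum()) for m, g in zip(sizes, internal)]
    sep_min = g_max + 1
    n_fill = n_genes - sum(spans) - (n_blocks - 1) * sep_min
    if n_fill < 0:
        # retry without internal gaps before declaring the layout infeasible
        internal = [np.zeros(max(m - 1, 0), int) for m in sizes]
        spans = list(sizes)
        n_fill = n_genes - sum(spans) - (n_blocks - 1) * sep_min
        if n_fill < 0:
            raise ValueError(
                f"infeasible layout: {n_blocks} blocks of {n_core} core genes need more than "
                f"{n_genes} gene positions with separation > {g_max}"
            )
    # distribute the remaining non-core genes over the k+1 outer/between slots
    extra = rng.multinomial(n_fill, np.full(n_blocks + 1, 1.0 / (n_blocks + 1)))
    positions, block_ids = [], []
    cursor = int(extra[0])
    for bi in range(n_blocks):
        pos = cursor
        for j in range(sizes[bi]):
            positions.append(pos)
            block_ids.append(bi + 1)
            if j < sizes[bi] - 1:
                pos += 1 + int(internal[bi][j])
        cursor = pos + 1 + (sep_min + int(extra[bi + 1]) if bi < n_blocks - 1 else 0)
    return positions, block_ids


def generate_panel(
    n_ingroup: int = 66,
    n_outgroup: int = 6,
    n_genes: int = 317,
    n_core: int = 72,
    n_unique: int = 21,
    n_blocks: int = 7,
    n_intermediate: int = 0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    sampling: str = "exact",
    core_freq_range: tuple[float, float] = (0.93, 1.0),
    accessory_freq_range: tuple[float, float] = (0.0, 0.08),
    intermediate_freq_range: tuple[float, float] = (0.20, 0.80),
    theta_core: float = 0.90,
    theta_acc: float = 0.10,
    e_cutoff: float = 0.05,
    decoy_rate: float = 0.02,
    write_fasta: bool = False,
) -> PanelTruth:
    """Generate a genome panel with planted conservation structure.

    Core-family frequencies are drawn from ``core_freq_range`` and accessory
    from ``accessory_freq_range`` (the default bands exclude the window
    between the accessory and core thresholds so planted classes are
    recoverable); ``n_intermediate`` families (default 0) are planted inside
    the window for threshold stress tests.

    ``sampling="exact"`` realizes each family in ``round(p * n_ingroup)``
    genomes (chosen at random, always including the reference), nudged if
    needed so the realized frequency stays on the planted side of the
    thresholds — class recovery is then exact by construction.
    ``sampling="binomial"`` draws presence i.i.d. Bernoulli(p) per genome;
    realized frequencies then fluctuate around the planted ones and may
    cross a threshold for families planted near it.

    Out-group genomes contain homologs of every non-unique core family (at
    least one detection each) and none of the planted-unique families.  The
    emitted hit table is 12-column BLAST ``outfmt 6``; each present
    (gene, genome) pair gets one hit with E-value ≤ ``e_cutoff``, and decoy
    rows (E-value above the cutoff, or subjects absent from the accession
    map) are added at ``decoy_rate`` to exercise the filtering and
    unmapped-report paths.  Files round-trip through the homology ingest to
    reproduce the planted presence exactly.
    """
    if not (n_core + n_intermediate <= n_genes):
        raise ValueError("n_core + n_intermediate must not exceed n_genes")
    if n_unique > n_core:
        raise ValueError("n_unique must not exceed n_core")
    if sampling not in ("exact", "binomial"):
        raise ValueError("sampling must be 'exact' or 'binomial'")
    rng = np.random.default_rng(seed)

    genomes_in = [f"IG{i + 1:03d}" for i in range(n_ingroup)]
    genomes_out = [f"OG{i + 1:03d}" for i in range(n_outgroup)]
    reference = genomes_in[0]
    gene_ids = [f"gp{i + 1:03d}" for i in range(n_genes)]

    core_pos, core_block = _block_layout(rng, n_genes, n_core, n_blocks, b_min=3, g_max=3)
    is_core = np.zeros(n_genes, dtype=bool)
    is_core[core_pos] = True
    block_of = {p: b for p, b in zip(core_pos, core_block)}
    # unique-core families drawn uniformly among core positions
    unique_pos = set(rng.choice(core_pos, size=n_unique, replace=False).tolist())
    # intermediate families among the remaining positions
    non_core_pos = np.flatnonzero(~is_core)
    inter_pos = set(rng.choice(non_core_pos, size=n_intermediate, replace=False).tolist()) \
        if n_intermediate else set()

    freq = np.empty(n_genes)
    classes = np.empty(n_genes, dtype=object)
    for i in range(n_genes):
        if is_core[i]:
            freq[i] = rng.uniform(*core_freq_range)
            classes[i] = CLASS_CORE
        elif i in inter_pos:
            freq[i] = rng.uniform(*intermediate_freq_range)
            classes[i] = CLASS_INTERMEDIATE
        else:
            freq[i] = rng.uniform(*accessory_freq_range)
            classes[i] = CLASS_ACCESSORY

    # realize in-group presence; reference genome always carries all its genes
    presence = np.zeros((n_genes, n_ingroup), dtype=bool)
    presence[:, 0] = True
    lo_acc = math.floor(theta_acc * n_ingroup)          # max count still accessory
    lo_core = math.floor(theta_core * n_ingroup) + 1    # min count strictly core
    for i in range(n_genes):
        if sampling == "binomial":
            presence[i, 1:] = rng.random(n_ingroup - 1) < freq[i]
            continue
        count = int(round(freq[i] * n_ingroup))
        if classes[i] == CLASS_CORE:
            count = max(count, lo_core)
        elif classes[i] == CLASS_ACCESSORY:
            count = min(max(count, 1), lo_acc)
        else:
            count = min(max(count, lo_acc + 1), lo_core - 1)
        count = min(max(count, 1), n_ingroup)
        others = rng.choice(np.arange(1, n_ingroup), size=count - 1, replace=False)
        presence[i, others] = True

    # out-group: every non-unique core family detectable, unique families absent
    out_presence = np.zeros((n_genes, n_outgroup), dtype=bool)
    for i in range(n_genes):
        if i in unique_pos:
            continue
        if classes[i] == CLASS_CORE:
            row = rng.random(n_outgroup) < 0.6
            if not row.any():
                row[rng.integers(n_outgroup)] = True
            out_presence[i] = row
        else:
            out_presence[i] = rng.random(n_outgroup) < 0.10

    genes = pd.DataFrame(
        {
            "index": np.arange(n_genes),
            "planted_frequency": freq,
            "planted_class": classes,
            "planted_unique": [i in unique_pos for i in range(n_genes)],
            "planted_block_id": [str(block_of[i]) if i in block_of else "." for i in range(n_genes)],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    presence_df = pd.DataFrame(presence, index=genes.index, columns=genomes_in)
    out_df = pd.DataFrame(out_presence, index=genes.index, columns=genomes_out)
    panel = GenomePanel(
        in_group_genomes=tuple(genomes_in),
        out_group_genomes=tuple(genomes_out),
        reference_genome_id=reference,
        reference_gene_order=tuple(gene_ids),
    )
    truth = PanelTruth(
        panel=panel, genes=genes, presence=presence_df, outgroup_presence=out_df,
        seed=seed, n_blocks=n_blocks,
    )
    if out_dir is not None:
        _write_panel_files(truth, Path(out_dir), rng, e_cutoff, decoy_rate, write_fasta)
    return truth


def _hit_row(rng, gene_id: str, accession: str, evalue: float) -> str:
    """One 12-column outfmt-6 row with plausible alignment statistics."""
    pident = round(float(rng.uniform(35, 100)), 1)
    length = int(rng.integers(80, 600))
    mismatch = int(rng.integers(0, max(2, int(length * (1 - pident / 100)) + 1)))
    gapopen = int(rng.integers(0, 5))
    qstart = int(rng.integers(1, 50))
    bits = round(float(rng.uniform(50, 900)), 1)
    return (f"{gene_id}\t{accession}\t{pident}\t{length}\t{mismatch}\t{gapopen}\t"
            f"{qstart}\t{qstart + length - 1}\t1\t{length}\t{evalue:.3g}\t{bits}")


def _write_panel_files(truth: PanelTruth, out_dir: Path, rng, e_cutoff: float,
                       decoy_rate: float, write_fasta: bool) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    panel = truth.panel
    gene_ids = list(panel.reference_gene_order)
    map_rows: list[tuple[str, str, str]] = []
    hit_lines = ["# synthetic homology hit table (outfmt 6: qseqid sseqid pident length "
                 "mismatch gapopen qstart qend sstart send evalue bitscore)"]

    def emit(gene_idx: int, genome: str, panel_label: str) -> None:
        gene = gene_ids[gene_idx]
        acc = f"{genome}_g{gene_idx + 1:03d}"
        map_rows.append((acc, genome, panel_label))
        evalue = 10.0 ** rng.uniform(-30.0, math.log10(e_cutoff))
        hit_lines.append(_hit_row(rng, gene, acc, evalue))
        if rng.random() < decoy_rate:  # filtered decoy: above the E-value cutoff
            hit_lines.append(_hit_row(rng, gene, acc, float(rng.uniform(e_cutoff * 1.5, 10.0))))
        if rng.random() < decoy_rate:  # unmapped decoy: subject absent from the map
            hit_lines.append(_hit_row(
                rng, gene, f"UNK_{rng.integers(0, 10**6):06d}",
                10.0 ** rng.uniform(-10.0, math.log10(e_cutoff)),
            ))

    pres = truth.presence.to_numpy()
    outp = truth.outgroup_presence.to_numpy()
    for i in range(len(gene_ids)):
        for j, genome in enumerate(panel.in_group_genomes):
            if pres[i, j]:
                emit(i, genome, IN_GROUP)
        for j, genome in enumerate(panel.out_group_genomes):
            if outp[i, j]:
                emit(i, genome, OUT_GROUP)

    files = {
        "hits": out_dir / "hits.tsv",
        "accession_map": out_dir / "accession_map.tsv",
        "genomes": out_dir / "genomes.tsv",
        "gene_order": out_dir / "gene_order.tsv",
        "truth_genes": out_dir / "truth_genes.tsv",
    }
    files["hits"].write_text("\n".join(hit_lines) + "\n")
    AccessionMap({acc: (g, p) for acc, g, p in map_rows}).to_tsv(files["accession_map"])
    panel.to_tsv(files["genomes"], files["gene_order"])
    with open(files["truth_genes"], "w") as fh:
        fh.write(f"# planted truth, seed={truth.seed}\n")
        truth.genes.to_csv(fh, sep="\t", index_label="gene_id")
    if write_fasta:
        files["proteome"] = out_dir / "reference_proteome.faa"
        _write_random_proteome(files["proteome"], gene_ids, rng)
    truth.files = files


def _write_random_proteome(path: Path, gene_ids: Sequence[str], rng) -> None:
    """Random-sequence reference proteome (interface completeness only)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for gid in gene_ids:
        n = int(rng.integers(80, 800))
        seq = "".join(rng.choice(alphabet, size=n))
        records.append(SeqRecord(Seq(seq), id=gid, description="synthetic protein"))
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# quantification generators


def generate_tracks(
    n_tracks: int = 25,
    radius_nm: float = 300.0,
    omega_deg_s: float = 10.1,
    duration_s: float = 120.0,
    frame_interval_s: float = 4.0,
    noise_sd_nm: float = 20.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[RotationTrack], pd.DataFrame]:
    """Circular-motion tracks with Gaussian localization noise.

    Each track follows a circle of ``radius_nm`` at constant planted angular
    speed (random initial phase and handedness), sampled every
    ``frame_interval_s`` for ``duration_s``, with i.i.d. N(0, noise_sd²)
    added per coordinate — emulating a surface landmark tracked frame by
    frame on a 2-minute, 4-second-interval time lapse.

    Returns the tracks and a truth table (track_id, radius_nm,
    omega_deg_s, direction); writes tracks.csv / tracks_meta.csv /
    tracks_truth.tsv when *out_dir* is given.
    """
    for name, v in [("n_tracks", n_tracks), ("radius_nm", radius_nm),
                    ("duration_s", duration_s), ("frame_interval_s", frame_interval_s)]:
        if not v > 0:
            raise ValueError(f"{name} must be positive")
    if noise_sd_nm < 0 or omega_deg_s < 0:
        raise ValueError("noise_sd_nm and omega_deg_s must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s + frame_interval_s / 2, frame_interval_s)
    tracks, truth_rows, point_rows = [], [], []
    for k in range(n_tracks):
        tid = f"track{k + 1:03d}"
        phase = rng.uniform(0, 2 * np.pi)
        direction = int(rng.choice([-1, 1]))
        cx, cy = rng.uniform(0, 5000, size=2)
        theta = phase + direction * np.deg2rad(omega_deg_s) * t
        x = cx + radius_nm * np.cos(theta) + rng.normal(0, noise_sd_nm, len(t))
        y = cy + radius_nm * np.sin(theta) + rng.normal(0, noise_sd_nm, len(t))
        tracks.append(RotationTrack(t=t, x=x, y=y, nucleus_radius=radius_nm, track_id=tid))
        truth_rows.append({"track_id": tid, "radius_nm": radius_nm,
                           "omega_deg_s": omega_deg_s, "direction": direction})
        for ti, xi, yi in zip(t, x, y):
            point_rows.append({"track_id": tid, "t_s": ti, "x_nm": xi, "y_nm": yi})
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(point_rows).to_csv(out_dir / "tracks.csv", index=False)
        truth[["track_id", "radius_nm"]].rename(
            columns={"radius_nm": "nucleus_radius_nm"}
        ).to_csv(out_dir / "tracks_meta.csv", index=False)
        truth.to_csv(out_dir / "tracks_truth.tsv", sep="\t", index=False)
    return tracks, truth


def generate_geometries(
    n_cells: int = 103,
    nucleoid_mode: str = "two",
    positioning_bias: str = "midcell",
    between_fraction: float = 0.97,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[CellGeometry], pd.DataFrame]:
    """Cell geometries with one or two nucleoid intervals and a positioned nucleus.

    With ``nucleoid_mode="two"`` the nucleoids occupy (0.05 L, 0.35 L) and
    (0.65 L, 0.95 L); under ``positioning_bias="midcell"`` the nucleus center
    is N(L/2, σ) with σ set so the planted probability of landing strictly
    inside the inter-nucleoid gap equals ``between_fraction``.  Other biases:
    ``"random"`` (uniform along the cell) and ``"polar"`` (N(0.12 L, 0.05 L)).
    Cell lengths are N(4.0, 0.4) µm truncated to ≥ 2.5 µm.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if nucleoid_mode not in ("one", "two"):
        raise ValueError("nucleoid_mode must be 'one' or 'two'")
    if positioning_bias not in ("midcell", "random", "polar"):
        raise ValueError("positioning_bias must be midcell/random/polar")
    if not (0 < between_fraction < 1):
        raise ValueError("between_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    z = norm.ppf((1 + between_fraction) / 2)
    cells, rows = [], []
    for k in range(n_cells):
        L = float(max(2.5, rng.normal(4.0, 0.4)))
        if nucleoid_mode == "two":
            ivs = ((0.05 * L, 0.35 * L), (0.65 * L, 0.95 * L))
            gap_half = 0.15 * L
        else:
            ivs = ((0.30 * L, 0.70 * L),)
            gap_half = None
        if positioning_bias == "midcell":
            sd = (gap_half / z) if gap_half is not None else 0.08 * L
            center = rng.normal(0.5 * L, sd)
        elif positioning_bias == "random":
            center = rng.uniform(0, L)
        else:
            center = rng.normal(0.12 * L, 0.05 * L)
        center = float(min(max(center, 0.0), L))
        cid = f"cell{k + 1:04d}"
        cells.append(CellGeometry(cell_length=L, nucleus_center=center,
                                  nucleoid_intervals=ivs, cell_id=cid))
        rows.append({
            "cell_id": cid, "length_um": L, "nucleus_center_um": center,
            "nucleoids": ";".join(f"{a:.4f}:{b:.4f}" for a, b in ivs),
        })
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "geometries.csv", index=False)
        with open(out_dir / "geometries_truth.tsv", "w") as fh:
            fh.write(f"# nucleoid_mode={nucleoid_mode}\tpositioning_bias={positioning_bias}\t"
                     f"planted_between_fraction={between_fraction}\tseed={seed}\n")
            df.to_csv(fh, sep="\t", index=False)
    return cells, df


def generate_dose_response(
    bottom: float = 0.0,
    top: float = 100.0,
    ec50: float = 0.03,
    hill: float = 2.0,
    concentrations: Sequence[float] = (0.0, 0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0),
    n_per_conc: int = 50,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[DoseResponseData, dict]:
    """Binomial filamentation counts around a planted Hill curve.

    At each arabinose concentration, ``n_per_conc`` cells are scored and the
    filamented count drawn Binomial(n, p(c)/100) from the planted
    four-parameter curve.  The default concentration ladder spans 0–1%
    arabinose around an EC50 of 0.03%, matching the induction range used for
    spindle filamentation.
    """
    if n_per_conc < 1:
        raise ValueError("n_per_conc must be >= 1 (empty dataset)")
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise ValueError("at least one concentration is required")
    if not ec50 > 0:
        raise ValueError("ec50 must be > 0")
    rng = np.random.default_rng(seed)
    floor = conc[conc > 0].min() / 10.0 if (conc > 0).any() else 1e-6
    logc = np.log10(np.where(conc <= 0, floor, conc))
    p = np.clip((bottom + (top - bottom) / (1 + 10.0 ** ((math.log10(ec50) - logc) * hill))) / 100,
                0.0, 1.0)
    k = rng.binomial(n_per_conc, p)
    data = DoseResponseData(
        concentrations=conc,
        n_cells=np.full(conc.shape, n_per_conc, dtype=int),
        n_with_filaments=k,
    )
    truth = {"bottom": bottom, "top": top, "ec50": ec50, "log_ec50": math.log10(ec50),
             "hill": hill, "seed": seed}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"concentration": conc, "n_cells": data.n_cells,
                      "n_filamented": data.n_with_filaments}).to_csv(
            out_dir / "dose_response.csv", index=False)
        with open(out_dir / "dose_response_truth.tsv", "w") as fh:
            fh.write("\t".join(truth) + "\n")
            fh.write("\t".join(str(v) for v in truth.values()) + "\n")
    return data, truth


def generate_rotating_cohort(
    n_cells: int = 858,
    p_rotating: float = 0.037,
    seed: int = 0,
) -> list[bool]:
    """Bernoulli rotating/non-rotating flags for a cohort of infected cells."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0 <= p_rotating <= 1):
        raise ValueError("p_rotating must be in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random(n_cells) < p_rotating).tolist()
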