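"""Gap-tolerant conserved-block detection along the reference gene order.

A block is a run of at least ``b_min`` (default 3) core genes in which no two
consecutive core genes are separated by more than ``g_max`` (default 3)
non-core genes.  Gaps are counted in genes, not base pairs, and blocks begin
and end on core genes.  Core genes that fall in no block are reported as
unblocked (drawn black on the genome map).  Greedy left-to-right maximal
merging is deterministic; no tie-breaking arises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .pangenome import ConservationProfile

__all__ = ["GeneBlock", "BlockResult", "find_blocks", "export_genome_map"]


@dataclass(frozen=True)
class GeneBlock:
    """A maximal gap-tolerant run of core genes.

    ``member_indices`` are positions in the reference gene order, listed
    along the run (a run wrapping the circular origin continues past the last
    index back to the start and is reported once).  ``gap_profile[i]`` is the
    number of intervening non-core genes between members ``i`` and ``i+1``.
    """

    block_id: int
    member_indices: tuple[int, ...]
    start_index: int
    end_index: int
    gap_profile: tuple[int, ...]
    member_genes: tuple[str, ...] = ()
    wraps: bool = False

    @property
    def n_members(self) -> int:
        return len(self.member_indices)


@dataclass
class BlockResult:
    """Blocks in genome order plus the core genes left unblocked."""

    blocks: list[GeneBlock]
    unblocked: tuple[int, ...]
    b_min: int
    g_max: int
    circular: bool

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self) -> int:
        return len(self.blocks)

    def summary_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(f"# conserved blocks: >= {self.b_min} core genes, gaps <= {self.g_max} "
                     f"non-core genes; circular={self.circular}\n")
            fh.write("# columns: block_id, start_index, end_index, n_members, wraps_origin, "
                     "member_genes (comma-joined; indices if gene ids unknown)\n")
            fh.write("block_id\tstart_index\tend_index\tn_members\twraps_origin\tmember_genes\n")
            for blk in self.blocks:
                members = (",".join(blk.member_genes) if blk.member_genes
                           else ",".join(str(i) for i in blk.member_indices))
                fh.write(f"{blk.block_id}\t{blk.start_index}\t{blk.end_index}\t"
                         f"{blk.n_members}\t{int(blk.wraps)}\t{members}\n")


def _split_runs(positions: list[int], g_max: int) -> list[list[int]]:
    runs: list[list[int]] = []
    for p in positions:
        if runs and p - runs[-1][-1] - 1 <= g_max:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def find_blocks(
    core_flags: Sequence[bool],
    b_min: int = 3,
    g_max: int = 3,
    circular: bool = False,
    gene_ids: Sequence[str] | None = None,
) -> BlockResult:
    """Find all maximal gap-tolerant core-gene runs of size ≥ ``b_min``.

    Consecutive core genes are merged while at most ``g_max`` non-core genes
    lie between them; merging is maximal, so no emitted block can absorb an
    adjacent core gene without violating ``g_max``.  With ``circular=True``
    the merge may wrap the origin (the gap between the last and first core
    gene, going through the origin, is also considered); a wrapping run is
    reported once.

    Parameters
    ----------
    core_flags : sequence of bool
        Core/non-core flag per gene along the reference gene order.
    gene_ids : sequence of str, optional
        Gene identifiers parallel to *core_flags*, attached to the blocks.

    Returns
    -------
    BlockResult
        Disjoint blocks sorted in genome order, with 1-based ordinal ids,
        plus the indices of core genes not belonging to any block.
    """
    if b_min < 1:
        raise ValueError("b_min must be >= 1")
    if g_max < 0:
        raise ValueError("g_max must be >= 0")
    if gene_ids is not None and len(gene_ids) != len(core_flags):
        raise ValueError("gene_ids length must match core_flags length")
    n = len(core_flags)
    positions = [i for i, f in enumerate(core_flags) if f]
    if not positions:
        return BlockResult([], (), b_min, g_max, circular)

    runs = _split_runs(positions, g_max)
    wrapped = [False] * len(runs)
    if circular and len(runs) > 1:
        # only the origin-spanning gap can join runs: all interior gaps > g_max
        wrap_gap = (n - positions[-1] - 1) + positions[0]
        if wrap_gap <= g_max:
            runs[0] = runs.pop() + runs[0]
            wrapped[0] = True
            wrapped.pop()

    blocks: list[GeneBlock] = []
    unblocked: list[int] = []
    order = sorted(range(len(runs)), key=lambda i: runs[i][0])
    next_id = 1
    for i in order:
        run = runs[i]
        if len(run) < b_min:
            unblocked.extend(run)
            continue
        gaps = []
        for a, b in zip(run, run[1:]):
            gaps.append((b - a - 1) if b > a else (n - a - 1) + b)
        blocks.append(
            GeneBlock(
                block_id=next_id,
                member_indices=tuple(run),
                start_index=run[0],
                end_index=run[-1],
                gap_profile=tuple(gaps),
                member_genes=tuple(gene_ids[j] for j in run) if gene_ids is not None else (),
                wraps=wrapped[i],
            )
        )
        next_id += 1
    unblocked.sort()
    return BlockResult(blocks, tuple(unblocked), b_min, g_max, circular)


def export_genome_map(
    profile: ConservationProfile,
    bed_path: str | Path,
    gene_coordinates: Mapping[str, tuple[int, int, str]] | None = None,
    chrom: str = "reference",
    header_lines: Sequence[str] = (),
) -> None:
    """Write a BED genome map of gene classes and block membership.

    One BED record per gene (0-based half-open), ``name`` field
    ``gene_id|gene_class|block_id`` with ``block_id`` '.' for unblocked
    genes, ``score`` the conservation frequency scaled to 0–1000.  Without
    per-gene coordinates the gene index stands in for position (gene *i*
    spans ``[i, i+1)``).

    Raises
    ------
    ValueError
        On overlapping or malformed coordinates, naming the offending gene.
    """
    per_gene = profile.per_gene
    records = []
    for gene_id, row in per_gene.iterrows():
        if gene_coordinates is not None:
            if gene_id not in gene_coordinates:
                raise ValueError(f"no coordinates for gene {gene_id!r}")
            start, end, strand = gene_coordinates[gene_id]
            if not (0 <= start < end):
                raise ValueError(f"malformed interval for gene {gene_id!r}: [{start}, {end})")
        else:
            start, end, strand = int(row["index"]), int(row["index"]) + 1, "+"
        records.append((start, end, gene_id, row["gene_class"], row["block_id"],
                        int(round(1000 * float(row["frequency"]))), strand))
    records.sort(key=lambda r: (r[0], r[1]))
    for (s1, e1, g1, *_), (s2, _, g2, *_) in zip(records, records[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping gene coordinates: {g1!r} and {g2!r}")
    with open(bed_path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# BED6: chrom, start, end, name=gene_id|gene_class|block_id, "
                 "score=1000*conservation_frequency, strand\n")
        for start, end, gene_id, cls, blk, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene_id}|{cls}|{blk}\t{score}\t{strand}\n")
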