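"""Homology hit-table ingestion: parsing, E-value filtering and per-genome presence.

Presence/absence of a reference gene in a panel genome is defined purely by
mapped homology-search hits (PSI-BLAST style tabular output): a gene is
*present* in a genome if at least one retained hit from that gene maps, via an
explicit protein-accession → genome map, to that genome.  No orthology
clustering or alignment is performed.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "HitDialect",
    "ParseResult",
    "AccessionMap",
    "GenomePanel",
    "PresenceResult",
    "parse_hit_table",
    "write_hit_table",
    "filter_hits",
    "resolve_presence",
    "DEFAULT_E_CUTOFF",
]

#: Inclusive E-value cutoff applied to homology hits.  The bulk homology
#: search behind the family definition used 0.05; "cutoff of 0.05" is read as
#: inclusive (≤), matching BLAST convention.
DEFAULT_E_CUTOFF = 0.05

IN_GROUP = "in_group"
OUT_GROUP = "out_group"


@dataclass(frozen=True)
class HitRecord:
    """One homology hit: a reference (query) gene matching a subject protein.

    Parameters
    ----------
    query_gene_id : str
        Identifier of the reference-genome protein used as query.
    subject_accession : str
        Protein accession of the matched subject.
    evalue : float
        Expectation value of the hit; must be ≥ 0.
    bitscore : float, optional
        Bit score, if the table carries one.
    iteration : int, optional
        PSI-BLAST round that produced the hit (1-based), if recorded.
    """

    query_gene_id: str
    subject_accession: str
    evalue: float
    bitscore: float | None = None
    iteration: int | None = None

    def __post_init__(self) -> None:
        if not self.query_gene_id:
            raise ValueError("query_gene_id must be non-empty")
        if not self.subject_accession:
            raise ValueError("subject_accession must be non-empty")
        if not self.evalue >= 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue!r}")
        if self.iteration is not None and self.iteration < 1:
            raise ValueError("iteration must be a positive integer")


@dataclass(frozen=True)
class HitDialect:
    """Column layout of a tab-separated hit table (0-based indices).

    The default is the standard 12-column BLAST ``outfmt 6`` order
    (qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore).  Deposited tables with other layouts
    are absorbed by overriding the indices; ``iteration`` is ``None`` for
    tables without a PSI-BLAST round column.
    """

    query: int = 0
    subject: int = 1
    evalue: int = 10
    bitscore: int | None = 11
    iteration: int | None = None

    def required_width(self) -> int:
        cols = [self.query, self.subject, self.evalue]
        if self.bitscore is not None:
            cols.append(self.bitscore)
        if self.iteration is not None:
            cols.append(self.iteration)
        return max(cols) + 1


#: Three-column layout (qseqid, sseqid, evalue) used by the synthetic panels'
#: compact hit tables.
MINIMAL_DIALECT = HitDialect(query=0, subject=1, evalue=2, bitscore=None)


@dataclass
class ParseResult:
    """Outcome of parsing a hit table: records plus a skip report.

    ``len(records) + len(skipped)`` equals the number of data rows in the
    file (comment and blank lines excluded).
    """

    records: list[HitRecord]
    skipped: list[tuple[int, str, str]] = field(default_factory=list)
    """(1-based line number, raw line, reason) for each unparseable row."""

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def parse_hit_table(path: str | Path, dialect: HitDialect = HitDialect()) -> ParseResult:
    """Parse a tab-separated homology hit table into :class:`HitRecord` s.

    Lines beginning with ``#`` (BLAST outfmt-7 comments) and blank lines are
    ignored.  Rows whose numeric fields fail to parse, or that are narrower
    than the dialect requires, are reported in ``ParseResult.skipped`` and
    never abort the run.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"hit table not found: {path}")
    width = dialect.required_width()
    records: list[HitRecord] = []
    skipped: list[tuple[int, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < width:
                skipped.append((lineno, line, f"expected >= {width} columns, got {len(fields)}"))
                continue
            try:
                evalue = float(fields[dialect.evalue])
                bitscore = (
                    float(fields[dialect.bitscore]) if dialect.bitscore is not None else None
                )
                iteration = (
                    int(fields[dialect.iteration]) if dialect.iteration is not None else None
                )
                rec = HitRecord(
                    query_gene_id=fields[dialect.query].strip(),
                    subject_accession=fields[dialect.subject].strip(),
                    evalue=evalue,
                    bitscore=bitscore,
                    iteration=iteration,
                )
            except (ValueError, IndexError) as exc:
                skipped.append((lineno, line, str(exc)))
                continue
            records.append(rec)
    return ParseResult(records=records, skipped=skipped)


def write_hit_table(records: Iterable[HitRecord], path: str | Path,
                    dialect: HitDialect = MINIMAL_DIALECT) -> None:
    """Serialize records as a tab-separated table readable by :func:`parse_hit_table`.

    Only the columns the dialect names are written; unnamed positions are
    padded with ``.`` so the layout round-trips.
    """
    width = dialect.required_width()
    with open(path, "w") as fh:
        for rec in records:
            row = ["."] * width
            row[dialect.query] = rec.query_gene_id
            row[dialect.subject] = rec.subject_accession
            row[dialect.evalue] = format(rec.evalue, "g")
            if dialect.bitscore is not None:
                row[dialect.bitscore] = "." if rec.bitscore is None else format(rec.bitscore, "g")
            if dialect.iteration is not None and rec.iteration is not None:
                row[dialect.iteration] = str(rec.iteration)
            fh.write("\t".join(row) + "\n")


def filter_hits(
    hits: Iterable[HitRecord],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    round_policy: str = "last",
) -> list[HitRecord]:
    """Apply the E-value cutoff and the PSI-BLAST round policy.

    A hit is retained iff ``evalue <= e_cutoff`` (inclusive) and, under
    ``round_policy="last"``, it comes from the final recorded iteration for
    its query gene (hits without an iteration are kept regardless).
    ``round_policy="union"`` keeps hits from every round.  The output is a
    subset of the input and the operation is idempotent.
    """
    if not e_cutoff > 0:
        raise ValueError("e_cutoff must be > 0")
    if round_policy not in ("last", "union"):
        raise ValueError(f"round_policy must be 'last' or 'union', got {round_policy!r}")
    hits = list(hits)
    kept = [h for h in hits if h.evalue <= e_cutoff]
    if round_policy == "union":
        return kept
    last_round: dict[str, int] = {}
    for h in kept:
        if h.iteration is not None:
            prev = last_round.get(h.query_gene_id, 0)
            if h.iteration > prev:
                last_round[h.query_gene_id] = h.iteration
    return [
        h for h in kept
        if h.iteration is None or h.iteration == last_round[h.query_gene_id]
    ]


class AccessionMap:
    """Explicit subject-accession → (genome, panel) mapping.

    Genome identity is taken from this user-supplied map, never parsed out of
    accession strings or organism names.  Each accession maps to exactly one
    genome and each genome belongs to exactly one panel (in-group genomes
    encode the nuclear shell protein chimallin; out-group genomes do not).
    """

    def __init__(self, entries: Mapping[str, tuple[str, str]]):
        genome_panel: dict[str, str] = {}
        for acc, (genome, panel) in entries.items():
            if panel not in (IN_GROUP, OUT_GROUP):
                raise ValueError(f"panel for {acc!r} must be in_group/out_group, got {panel!r}")
            if genome_panel.setdefault(genome, panel) != panel:
                raise ValueError(f"genome {genome!r} assigned to both panels")
        self._entries = dict(entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def lookup(self, accession: str) -> tuple[str, str] | None:
        return self._entries.get(accession)

    def genomes(self, panel: str | None = None) -> set[str]:
        return {g for g, p in self._entries.values() if panel is None or p == panel}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AccessionMap":
        """Load a 3-column TSV: accession, genome_id, panel (``#`` comments allowed)."""
        entries: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                acc, genome, panel = parts[0].strip(), parts[1].strip(), parts[2].strip()
                if acc in entries and entries[acc] != (genome, panel):
                    raise ValueError(f"{path}:{lineno}: accession {acc!r} maps to two genomes")
                entries[acc] = (genome, panel)
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# accession\tgenome_id\tpanel\n")
            for acc, (genome, panel) in sorted(self._entries.items()):
                fh.write(f"{acc}\t{genome}\t{panel}\n")


@dataclass(frozen=True)
class GenomePanel:
    """The study design: in-group vs out-group genomes and the reference gene order.

    The reference genome (phage RAY in the original study) supplies the
    ordered list of query genes along which conservation and synteny blocks
    are laid out.
    """

    in_group_genomes: tuple[str, ...]
    out_group_genomes: tuple[str, ...]
    reference_genome_id: str
    reference_gene_order: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "in_group_genomes", tuple(self.in_group_genomes))
        object.__setattr__(self, "out_group_genomes", tuple(self.out_group_genomes))
        object.__setattr__(self, "reference_gene_order", tuple(self.reference_gene_order))
        if self.reference_genome_id not in self.in_group_genomes:
            raise ValueError("reference genome must be in the in-group")
        overlap = set(self.in_group_genomes) & set(self.out_group_genomes)
        if overlap:
            raise ValueError(f"genomes in both panels: {sorted(overlap)}")
        if len(set(self.reference_gene_order)) != len(self.reference_gene_order):
            raise ValueError("reference gene order contains duplicates")
        if len(set(self.in_group_genomes)) != len(self.in_group_genomes):
            raise ValueError("duplicate in-group genome ids")
        if len(set(self.out_group_genomes)) != len(self.out_group_genomes):
            raise ValueError("duplicate out-group genome ids")

    @property
    def n_ingroup(self) -> int:
        return len(self.in_group_genomes)

    @classmethod
    def from_tsv(cls, genomes_path: str | Path, gene_order_path: str | Path) -> "GenomePanel":
        """Load from two TSVs.

        *genomes_path*: columns genome_id, panel (``in_group``/``out_group``),
        with the reference genome flagged by a third column ``reference``.
        *gene_order_path*: one gene id per line in reference order (or
        index<TAB>gene_id rows; the first column is ignored if two are given).
        """
        in_group, out_group = [], []
        reference = None
        with open(genomes_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                genome, panel = parts[0].strip(), parts[1].strip()
                (in_group if panel == IN_GROUP else out_group).append(genome)
                if len(parts) > 2 and parts[2].strip() == "reference":
                    reference = genome
        if reference is None:
            raise ValueError(f"{genomes_path}: no genome flagged as reference")
        order = []
        with open(gene_order_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                order.append(parts[-1].strip())
        return cls(tuple(in_group), tuple(out_group), reference, tuple(order))

    def to_tsv(self, genomes_path: str | Path, gene_order_path: str | Path) -> None:
        with open(genomes_path, "w") as fh:
            fh.write("# genome_id\tpanel\trole\n")
            for g in self.in_group_genomes:
                role = "reference" if g == self.reference_genome_id else "."
                fh.write(f"{g}\t{IN_GROUP}\t{role}\n")
            for g in self.out_group_genomes:
                fh.write(f"{g}\t{OUT_GROUP}\t.\n")
        with open(gene_order_path, "w") as fh:
            fh.write("# index\tgene_id\n")
            for i, gene in enumerate(self.reference_gene_order):
                fh.write(f"{i}\t{gene}\n")


@dataclass
class PresenceResult:
    """Per (gene, genome) detection counts plus the unmapped-accession tally.

    ``counts[(gene, genome)]`` is the number of retained hits from *gene*
    mapping to *genome*; presence is ``count >= 1`` (multiple protein hits in
    one genome count once for conservation frequency).  Subject accessions
    absent from the map are tallied in ``unmapped`` — a warning channel,
    never a silent drop.
    """

    counts: dict[tuple[str, str], int]
    unmapped: Counter
    panel: GenomePanel

    def presence(self, gene: str, genome: str) -> bool:
        return self.counts.get((gene, genome), 0) >= 1

    def genomes_with(self, gene: str, group: str = IN_GROUP) -> set[str]:
        pool = (self.panel.in_group_genomes if group == IN_GROUP
                else self.panel.out_group_genomes)
        return {g for g in pool if self.presence(gene, g)}

    def unmapped_report(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.unmapped.items()), columns=["subject_accession", "n_hits"]
        )
        return df

    def write_unmapped_report(self, path: str | Path) -> None:
        self.unmapped_report().to_csv(path, sep="\t", index=False)


def resolve_presence(
    hits: Iterable[HitRecord],
    accession_map: AccessionMap,
    panel: GenomePanel,
) -> PresenceResult:
    """Collapse filtered hits to per-(gene, genome) detection counts.

    Every genome referenced by the map must belong to the panel; hits to
    accessions outside the map are counted in the unmapped tally.  The result
    is invariant to hit-row order.
    """
    known = set(panel.in_group_genomes) | set(panel.out_group_genomes)
    unknown = accession_map.genomes() - known
    if unknown:
        raise ValueError(f"accession map references genomes outside the panel: {sorted(unknown)}")
    counts: dict[tuple[str, str], int] = defaultdict(int)
    unmapped: Counter = Counter()
    for hit in hits:
        entry = accession_map.lookup(hit.subject_accession)
        if entry is None:
            unmapped[hit.subject_accession] += 1
            continue
        genome, _ = entry
        counts[(hit.query_gene_id, genome)] += 1
    return PresenceResult(counts=dict(counts), unmapped=unmapped, panel=panel)
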