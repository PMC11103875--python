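"""Reference genome model: replicons, gene annotations, and mariner TA-site index.

The mariner transposon inserts exclusively at TA dinucleotides, so the set of
possible insertion sites is exactly the set of TA occurrences in the genome.
All coordinates are 1-based inclusive (GFF3 convention); a TA site is keyed by
the position of its T on the plus strand, regardless of transposon orientation.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

__all__ = [
    "Replicon",
    "Gene",
    "GenomeModel",
    "TASiteIndex",
    "load_genome",
    "build_ta_index",
    "central_gene_assignment",
    "INSIDE_CENTRAL",
    "INSIDE_PERIPHERAL",
    "OUTSIDE",
]

INSIDE_CENTRAL = "inside_central"
INSIDE_PERIPHERAL = "inside_peripheral"
OUTSIDE = "outside"

#: Central coding-region bounds: insertions between 10% and 90% of the CDS
#: (inclusive) are counted as disrupting the gene.
CENTRAL_LO = 0.1
CENTRAL_HI = 0.9


class GenomeError(ValueError):
    """Raised for inconsistent or malformed genome inputs."""


@dataclass(frozen=True)
class Replicon:
    """A chromosome or plasmid (one FASTA record)."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive coordinates."""

    id: str
    replicon: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeError(f"gene {self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise GenomeError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeModel:
    """Replicons plus gene annotations, with a per-replicon gene interval tree."""

    replicons: dict[str, Replicon]
    genes: dict[str, Gene]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for gene in self.genes.values():
            rep = self.replicons.get(gene.replicon)
            if rep is None:
                raise GenomeError(f"gene {gene.id} references unknown replicon {gene.replicon!r}")
            if gene.end > rep.length or gene.start < 1:
                raise GenomeError(
                    f"gene {gene.id}: [{gene.start},{gene.end}] outside replicon "
                    f"{rep.name} (length {rep.length})"
                )
        self._trees = {name: IntervalTree() for name in self.replicons}
        for gene in self.genes.values():
            # interval end is exclusive
            self._trees[gene.replicon].addi(gene.start, gene.end + 1, gene.id)

    def genes_at(self, replicon: str, position: int) -> list[Gene]:
        """All genes whose [start, end] span contains ``position``."""
        tree = self._trees.get(replicon)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree[position]]

    def central_genes_at(self, replicon: str, position: int) -> list[Gene]:
        """Genes for which ``position`` lies in the central 10–90% of the CDS."""
        return [
            g
            for g in self.genes_at(replicon, position)
            if central_gene_assignment(position, g) == INSIDE_CENTRAL
        ]


@dataclass
class TASiteIndex:
    """Sorted 1-based positions of every TA dinucleotide, per replicon.

    Positions refer to the T on the plus strand; overlapping occurrences
    (e.g. TATA) are all indexed.  N bases never form TA sites.
    """

    positions: dict[str, np.ndarray]
    _sets: dict[str, frozenset] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._sets = {rep: frozenset(pos.tolist()) for rep, pos in self.positions.items()}

    def contains(self, replicon: str, position: int) -> bool:
        return position in self._sets.get(replicon, frozenset())

    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def to_bed(self, path: str | Path) -> None:
        """Export as BED (0-based half-open) intervals covering each TA."""
        with open(path, "w") as fh:
            for rep in sorted(self.positions):
                for p in self.positions[rep]:
                    fh.write(f"{rep}\t{p - 1}\t{p + 1}\tTA\n")


def build_ta_index(genome: GenomeModel) -> TASiteIndex:
    """Index every TA dinucleotide occurrence (position of the T, 1-based)."""
    positions: dict[str, np.ndarray] = {}
    for name, rep in genome.replicons.items():
        seq = np.frombuffer(rep.sequence.encode("ascii"), dtype=np.uint8)
        is_t = seq[:-1] == ord("T")
        is_a = seq[1:] == ord("A")
        positions[name] = np.flatnonzero(is_t & is_a).astype(np.int64) + 1
    return TASiteIndex(positions)


def central_gene_assignment(position: int, gene: Gene) -> str:
    """Classify a position relative to a gene's central 10–90% coding region.

    The fractional position along the reading direction is
    ``(position - start) / (end - start)`` on the plus strand and
    ``(end - position) / (end - start)`` on the minus strand; the central
    region is fraction in [0.1, 0.9] inclusive.
    """
    if gene.end == gene.start:
        raise GenomeError(f"gene {gene.id}: zero-length span, central fraction undefined")
    if position < gene.start or position > gene.end:
        return OUTSIDE
    span = gene.end - gene.start
    if gene.strand == "+":
        fraction = (position - gene.start) / span
    else:
        fraction = (gene.end - position) / span
    if CENTRAL_LO <= fraction <= CENTRAL_HI:
        return INSIDE_CENTRAL
    return INSIDE_PERIPHERAL


def _validate_gff_lines(gff_path: str | Path) -> None:
    """Structural pre-check so malformed lines fail with their line number."""
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeError(
                    f"{gff_path}: malformed GFF3 line {lineno}: expected 9 "
                    f"tab-separated fields, found {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GenomeError(
                    f"{gff_path}: malformed GFF3 line {lineno}: non-integer coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            if start < 1 or start > end:
                raise GenomeError(
                    f"{gff_path}: malformed GFF3 line {lineno}: invalid span {start}..{end}"
                )


def load_genome(fasta_path: str | Path, gff_path: str | Path) -> GenomeModel:
    """Load replicon sequences (FASTA) and gene annotations (GFF3).

    Features of type ``gene`` or ``CDS`` are used; the gene id comes from the
    ``ID`` or ``locus_tag`` attribute.  When both a gene and its CDS share an
    id, the ``gene`` feature wins.  Genes referencing unknown replicons, or
    with coordinates outside their replicon, are rejected.
    """
    fasta_path, gff_path = Path(fasta_path), Path(gff_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    if not gff_path.exists():
        raise FileNotFoundError(gff_path)

    replicons: dict[str, Replicon] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in replicons:
            raise GenomeError(f"duplicate replicon name {record.id!r} in {fasta_path}")
        replicons[record.id] = Replicon(record.id, str(record.seq).upper())
    if not replicons:
        raise GenomeError(f"no FASTA records found in {fasta_path}")

    _validate_gff_lines(gff_path)
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes: dict[str, Gene] = {}
        from_gene_feature: set[str] = set()
        for feature in db.all_features():
            if feature.featuretype not in ("gene", "CDS"):
                continue
            attrs = feature.attributes
            gene_id = (attrs.get("locus_tag") or attrs.get("ID") or [feature.id])[0]
            gene = Gene(
                id=gene_id,
                replicon=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=feature.strand if feature.strand in ("+", "-") else "+",
                product=(attrs.get("product") or [""])[0],
            )
            if gene_id in genes:
                if feature.featuretype == "CDS" and gene_id in from_gene_feature:
                    continue  # CDS refines nothing; gene feature already seen
                prev = genes[gene_id]
                if (prev.replicon, prev.start, prev.end) != (gene.replicon, gene.start, gene.end):
                    raise GenomeError(
                        f"{gff_path}: gene id {gene_id!r} appears twice with conflicting coordinates"
                    )
            genes[gene_id] = gene
            if feature.featuretype == "gene":
                from_gene_feature.add(gene_id)

    return GenomeModel(replicons=replicons, genes=genes)
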