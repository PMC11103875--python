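"""Barcode-to-insertion-site mapping from TnSeq junction reads.

Each read carries a 20-nt random barcode between fixed flanking sequences,
followed by the transposon–genome junction.  The genomic segment is located by
exact match of a fixed-length seed against both strands of the reference; the
reported insertion position is always the plus-strand coordinate of the T of
the disrupted TA, so one site has one key regardless of insertion orientation.

Candidates not at an indexed TA site are removed outright (mariner chemistry),
and a barcode enters the pool only if it maps *reliably*: at least
``min_reads`` junction reads, at least ``min_fraction`` of which agree on a
single (replicon, position, strand).  This rejects chimeric barcodes whose
reads split across two loci.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .genome import GenomeModel, TASiteIndex
from .io import open_maybe_gzip, parse_fastq, reverse_complement

__all__ = [
    "MappingFlankModel",
    "Candidate",
    "ParseStats",
    "GenomeSeedIndex",
    "parse_mapping_reads",
    "filter_ta_sites",
    "call_reliable_mutants",
    "BarcodeMap",
    "write_pool_tsv",
    "read_pool_tsv",
]

BARCODE_LEN = 20

POOL_COLUMNS = [
    "barcode",
    "rcbarcode",
    "replicon",
    "strand",
    "pos",
    "nTot",
    "n",
    "fraction",
    "gene_id",
    "central",
]


@dataclass(frozen=True)
class MappingFlankModel:
    """Fixed sequences bracketing the barcode in a TnSeq junction read."""

    pre: str = "GATGTCCACGAGGTCTCT"
    post: str = "CGTACGCTGCAGGTCGAC"
    seed_len: int = 30
    scan_window: int = 60  # how far into the read the pre-flank may start


@dataclass(frozen=True)
class Candidate:
    barcode: str
    replicon: str
    position: int  # 1-based T of the TA on the plus strand
    strand: str


@dataclass
class ParseStats:
    total_reads: int = 0
    no_flank: int = 0
    bad_barcode: int = 0
    short_junction: int = 0
    no_genome_match: int = 0
    candidates: int = 0


class GenomeSeedIndex:
    """Exact-match lookup of fixed-length seeds against both genome strands."""

    def __init__(self, genome: GenomeModel, seed_len: int):
        self.seed_len = seed_len
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, rep in genome.replicons.items():
            seq = rep.sequence
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" not in kmer:
                    self._index[kmer].append((name, i + 1))
        self._index = dict(self._index)

    def lookup(self, segment: str) -> list[tuple[str, int, str]]:
        """Return (replicon, junction position, strand) for every exact hit.

        A forward hit starting at p puts the junction TA at p; a reverse-strand
        hit (segment == revcomp of genome[q .. q+L-1]) puts it at q + L - 2.
        """
        hits: list[tuple[str, int, str]] = []
        for rep, p in self._index.get(segment, ()):
            hits.append((rep, p, "+"))
        for rep, q in self._index.get(reverse_complement(segment), ()):
            hits.append((rep, q + self.seed_len - 2, "-"))
        return hits


def parse_mapping_reads(
    fastq_path: str | Path,
    genome: GenomeModel,
    flank_model: MappingFlankModel | None = None,
    seed_index: GenomeSeedIndex | None = None,
) -> tuple[list[Candidate], ParseStats]:
    """Extract (barcode, candidate insertion location) pairs from junction reads.

    Reads without recognizable flanks, with a malformed barcode (length != 20
    or containing N), or whose genomic segment has no exact match are tallied
    and skipped, never fatal.  A segment matching multiple loci emits one
    candidate per locus; the reliability filter resolves the ambiguity later.
    """
    fm = flank_model or MappingFlankModel()
    idx = seed_index or GenomeSeedIndex(genome, fm.seed_len)
    if idx.seed_len != fm.seed_len:
        raise ValueError("seed index built with a different seed length")
    stats = ParseStats()
    candidates: list[Candidate] = []
    with open_maybe_gzip(fastq_path) as fh:
        for _title, seq, _qual in parse_fastq(fh):
            stats.total_reads += 1
            i = seq.find(fm.pre, 0, fm.scan_window + len(fm.pre))
            if i < 0:
                stats.no_flank += 1
                continue
            bstart = i + len(fm.pre)
            barcode = seq[bstart : bstart + BARCODE_LEN]
            post_at = bstart + BARCODE_LEN
            if seq[post_at : post_at + len(fm.post)] != fm.post:
                # either the barcode is not exactly 20 nt or the read is junk
                stats.bad_barcode += 1
                continue
            if len(barcode) != BARCODE_LEN or "N" in barcode:
                stats.bad_barcode += 1
                continue
            segment = seq[post_at + len(fm.post) : post_at + len(fm.post) + fm.seed_len]
            if len(segment) < fm.seed_len:
                stats.short_junction += 1
                continue
            hits = idx.lookup(segment)
            if not hits:
                stats.no_genome_match += 1
                continue
            for rep, pos, strand in hits:
                candidates.append(Candidate(barcode, rep, pos, strand))
                stats.candidates += 1
    return candidates, stats


def filter_ta_sites(
    candidates: Iterable[Candidate], ta_index: TASiteIndex
) -> tuple[list[Candidate], int]:
    """Keep only candidates whose position is an indexed TA; report removals."""
    kept: list[Candidate] = []
    removed = 0
    for cand in candidates:
        if ta_index.contains(cand.replicon, cand.position):
            kept.append(cand)
        else:
            removed += 1
    return kept, removed


@dataclass
class BarcodeMap:
    """The pool: one row per reliably mapped barcode.

    ``gene_ids`` holds every gene for which the insertion lies in the central
    10–90% coding region (overlapping genes each get the strain).
    """

    table: pd.DataFrame  # POOL_COLUMNS
    gene_ids: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["barcode"].duplicated().any():
            raise ValueError("BarcodeMap must have exactly one row per barcode")
        if not self.gene_ids:
            self.gene_ids = {
                row.barcode: tuple(g for g in str(row.gene_id).split(",") if g)
                for row in self.table.itertuples()
            }

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.table["barcode"])

    def __len__(self) -> int:
        return len(self.table)


def call_reliable_mutants(
    candidates: Iterable[Candidate],
    genome: GenomeModel,
    min_reads: int = 5,
    min_fraction: float = 0.75,
) -> BarcodeMap:
    """Aggregate TA-filtered candidates per barcode and apply the reliability rule.

    A barcode is retained iff it has >= ``min_reads`` candidates and the modal
    (replicon, position, strand) accounts for >= ``min_fraction`` of them.
    Retained barcodes are annotated with every gene whose central region
    contains the insertion.
    """
    per_barcode: dict[str, Counter] = defaultdict(Counter)
    for cand in candidates:
        per_barcode[cand.barcode][(cand.replicon, cand.position, cand.strand)] += 1

    rows = []
    gene_ids: dict[str, tuple[str, ...]] = {}
    for barcode in sorted(per_barcode):
        tally = per_barcode[barcode]
        n_total = sum(tally.values())
        if n_total < min_reads:
            continue
        (rep, pos, strand), n_primary = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        fraction = n_primary / n_total
        if fraction < min_fraction:
            continue
        central = genome.central_genes_at(rep, pos)
        ids = tuple(sorted(g.id for g in central))
        gene_ids[barcode] = ids
        rows.append(
            {
                "barcode": barcode,
                "rcbarcode": reverse_complement(barcode),
                "replicon": rep,
                "strand": strand,
                "pos": pos,
                "nTot": n_total,
                "n": n_primary,
                "fraction": fraction,
                "gene_id": ",".join(ids),
                "central": int(bool(ids)),
            }
        )
    table = pd.DataFrame(rows, columns=POOL_COLUMNS)
    return BarcodeMap(table=table, gene_ids=gene_ids)


def write_pool_tsv(pool: BarcodeMap, path: str | Path) -> None:
    out = pool.table.copy()
    out["fraction"] = out["fraction"].map(lambda x: f"{x:.4f}")
    out.to_csv(path, sep="\t", index=False)


def read_pool_tsv(path: str | Path) -> BarcodeMap:
    table = pd.read_csv(
        path, sep="\t", dtype={"barcode": str, "gene_id": str}, keep_default_na=False
    )
    table["fraction"] = table["fraction"].astype(float)
    return BarcodeMap(table=table)
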