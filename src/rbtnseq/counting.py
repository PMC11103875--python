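"""BarSeq barcode counting: per-sample barcode extraction and the count table.

BarSeq quantifies strain abundance by amplicon-sequencing only the 20-nt
barcodes.  Amplicons are primed with one of 16 staggered forward primers, so
the barcode's offset varies read to read; extraction scans for the exact
pre-flank within the first ``scan_window`` bases.  Counting is restricted to
barcodes present in the pool; anything else is tallied as unmapped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .conditions import TIME0, is_valid_condition
from .io import open_maybe_gzip, parse_fastq
from .pool import BARCODE_LEN, BarcodeMap

__all__ = [
    "BarSeqFlankModel",
    "SampleSheet",
    "CountTable",
    "extract_barcode",
    "count_barcodes",
    "read_sample_sheet",
]

SUMMARY_COLUMNS = ["sample_id", "total_reads", "valid_barcode_reads", "pool_hits", "unmapped"]


@dataclass(frozen=True)
class BarSeqFlankModel:
    """Fixed sequences bracketing the barcode in a BarSeq amplicon read."""

    pre: str = "GTCGACCTGCAGCGTACG"
    post: str = "AGAGACCTCGTGGACATC"
    scan_window: int = 60


@dataclass
class SampleSheet:
    """Sample metadata: sample_id, condition, and FASTQ path(s).

    Multiple FASTQ files per sample (``;``-separated in the TSV) are summed.
    Requires at least one Time0 sample and conditions from the closed
    vocabulary.
    """

    table: pd.DataFrame  # columns: sample_id, condition, fastq_path

    def __post_init__(self) -> None:
        required = {"sample_id", "condition"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table["sample_id"][self.table["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
        bad = [c for c in self.table["condition"] if not is_valid_condition(c)]
        if bad:
            raise ValueError(f"sample sheet has conditions outside the vocabulary: {bad}")
        if TIME0 not in set(self.table["condition"]):
            raise ValueError("sample sheet must contain at least one Time0 sample")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def condition_of(self, sample_id: str) -> str:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["condition"].iloc[0]

    def fastqs_of(self, sample_id: str) -> list[Path]:
        row = self.table[self.table["sample_id"] == sample_id]
        if row.empty or "fastq_path" not in self.table.columns:
            return []
        raw = str(row["fastq_path"].iloc[0])
        return [Path(p) for p in raw.split(";") if p and p != "nan"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


def extract_barcode(read_seq: str, flank_model: BarSeqFlankModel | None = None) -> str | None:
    """Return the 20-mer between exact flank matches, or None.

    None when the pre-flank is absent from the scan window, the post-flank
    does not follow exactly 20 nt later, or the barcode contains N.
    """
    fm = flank_model or BarSeqFlankModel()
    i = read_seq.find(fm.pre, 0, fm.scan_window + len(fm.pre))
    if i < 0:
        return None
    bstart = i + len(fm.pre)
    barcode = read_seq[bstart : bstart + BARCODE_LEN]
    if len(barcode) != BARCODE_LEN or "N" in barcode:
        return None
    if read_seq[bstart + BARCODE_LEN : bstart + BARCODE_LEN + len(fm.post)] != fm.post:
        return None
    return barcode


@dataclass
class CountTable:
    """Barcode x sample read counts restricted to pool barcodes.

    ``counts`` is indexed by barcode with one integer column per sample;
    ``summary`` holds per-sample read accounting (total, valid-barcode, pool
    hits, unmapped); ``sample_sheet`` carries the condition metadata.
    """

    counts: pd.DataFrame
    summary: pd.DataFrame
    sample_sheet: SampleSheet

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def condition_columns(self, condition: str) -> list[str]:
        return [
            s
            for s in self.counts.columns
            if self.sample_sheet.condition_of(s) == condition
        ]

    def to_tsv(self, counts_path: str | Path, summary_path: str | Path | None = None) -> None:
        self.counts.rename_axis("barcode").to_csv(counts_path, sep="\t")
        if summary_path is not None:
            self.summary.to_csv(summary_path, sep="\t", index=False)


def count_barcodes(
    sample_sheet: SampleSheet,
    pool: BarcodeMap,
    flank_model: BarSeqFlankModel | None = None,
    fastq_by_sample: dict[str, list[str | Path]] | None = None,
) -> CountTable:
    """Count pool barcodes per sample from BarSeq FASTQs.

    FASTQ paths come from the sample sheet unless ``fastq_by_sample``
    overrides them.  Off-pool barcodes increment the unmapped tally only.
    A sample with no FASTQ is an error naming the sample.
    """
    fm = flank_model or BarSeqFlankModel()
    pool_barcodes = set(pool.table["barcode"])
    columns: dict[str, pd.Series] = {}
    summary_rows = []
    for sample_id in sample_sheet.sample_ids:
        if fastq_by_sample is not None and sample_id in fastq_by_sample:
            paths = [Path(p) for p in fastq_by_sample[sample_id]]
        else:
            paths = sample_sheet.fastqs_of(sample_id)
        if not paths:
            raise FileNotFoundError(f"no FASTQ file given for sample {sample_id!r}")
        tally: Counter = Counter()
        total_reads = 0
        valid = 0
        for path in paths:
            with open_maybe_gzip(path) as fh:
                for _title, seq, _qual in parse_fastq(fh):
                    total_reads += 1
                    barcode = extract_barcode(seq, fm)
                    if barcode is None:
                        continue
                    valid += 1
                    tally[barcode] += 1
        pool_hits = sum(n for b, n in tally.items() if b in pool_barcodes)
        columns[sample_id] = pd.Series(
            {b: tally.get(b, 0) for b in pool.table["barcode"]}, dtype="int64"
        )
        summary_rows.append(
            {
                "sample_id": sample_id,
                "total_reads": total_reads,
                "valid_barcode_reads": valid,
                "pool_hits": pool_hits,
                "unmapped": valid - pool_hits,
            }
        )
    counts = pd.DataFrame(columns)
    counts.index.name = "barcode"
    summary = pd.DataFrame(summary_rows, columns=SUMMARY_COLUMNS)
    return CountTable(counts=counts, summary=summary, sample_sheet=sample_sheet)
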