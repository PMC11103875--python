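"""Synthetic RB-TnSeq experiments with known ground truth.

Generates, at desk scale, the objects the real pipeline consumes: a random
multi-replicon genome with non-overlapping genes, a barcoded mariner pool
whose insertions sit on genuine TA sites (mostly within central coding
regions, several strains per gene), TnSeq junction reads with configurable
location-error and chimera rates, and post-growth BarSeq samples whose
barcode abundances shift by known per-gene fitness effects across five plant
species and two compartments.

Selection acts once per experiment: a strain's expected post-growth relative
abundance is its Time0 abundance multiplied by 2**f of its gene (intergenic
strains are neutral), renormalized, with read counts drawn multinomially at
the configured depth.  This is the exact generative inverse of the log2-ratio
fitness estimator, so estimates can be compared against truth directly.

Everything is deterministic under a fixed seed, at both fidelity levels
("counts" emits count tables directly; "reads" wraps them in FASTQ).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import COMPARTMENTS, CONDITIONS, SPECIES, TIME0, condition_label
from .counting import BarSeqFlankModel, CountTable, SampleSheet
from .genome import Gene, GenomeModel, Replicon, TASiteIndex, build_ta_index
from .io import FastqWriter, reverse_complement, write_fasta, write_gff3
from .pool import BARCODE_LEN, BarcodeMap, MappingFlankModel, POOL_COLUMNS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_pool",
    "simulate_growth",
    "simulate_mapping_reads",
    "write_barseq_reads",
    "run_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# sub-stream ids so each stage draws from an independent generator
_STAGE_GENOME, _STAGE_FITNESS, _STAGE_POOL, _STAGE_MAPREADS, _STAGE_GROWTH, _STAGE_BARSEQ = range(6)

#: margin (bp) kept free at replicon edges so junction reads never run off
EDGE_MARGIN = 60

CONDITION_LABELS = tuple(c for c in CONDITIONS if c != TIME0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults are the desk-scale standard: a 500 kb chromosome plus a 100 kb
    plasmid, 200 genes, 2000 barcoded strains (~8 per gene in central coding
    regions, the rest intergenic), sequencing depth 5e5 reads per sample, one
    Time0 and five plant species x two compartments, moderate library skew
    (Dirichlet concentration 50), 5% junction-read location errors and 2%
    chimeric barcodes.
    """

    seed: int = 0
    replicon_names: tuple[str, ...] = ("chromosome", "plasmid_pA")
    replicon_lengths: tuple[int, ...] = (500_000, 100_000)
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (600, 1500)
    n_barcodes: int = 2000
    barcodes_per_site_max: int = 3
    genic_fraction: float = 0.8
    fitness_mixture: tuple[tuple[float, float], ...] = (
        (0.0, 0.70),
        (-0.7, 0.10),
        (-1.5, 0.10),
        (-2.5, 0.10),
    )
    n_plant_specific: int = 10
    plant_specific_fitness: float = -2.0
    depth_time0: int = 500_000
    depth_condition: int = 500_000
    mapping_reads_per_barcode: int = 10
    location_error_rate: float = 0.05
    chimera_rate: float = 0.02
    dirichlet_concentration: float = 50.0
    stagger_max: int = 15
    fidelity: str = "counts"

    def __post_init__(self) -> None:
        if len(self.replicon_names) != len(self.replicon_lengths):
            raise ValueError("replicon_names and replicon_lengths must align")
        if abs(sum(p for _f, p in self.fitness_mixture) - 1.0) > 1e-9:
            raise ValueError("fitness_mixture proportions must sum to 1")
        if self.depth_time0 <= 0 or self.depth_condition <= 0:
            raise ValueError("sequencing depths must be positive")
        if not 0 <= self.genic_fraction <= 1:
            raise ValueError("genic_fraction must be in [0, 1]")
        if self.fidelity not in ("counts", "reads"):
            raise ValueError("fidelity must be 'counts' or 'reads'")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])


@dataclass
class GroundTruth:
    """Everything the simulation knows that the pipeline must rediscover."""

    gene_fitness: pd.DataFrame  # index gene_id, one column per non-Time0 condition
    pool: pd.DataFrame  # barcode, replicon, pos, strand, gene_id, chimera, replicon2, pos2
    time0_abundance: pd.Series | None = None  # per non-chimeric barcode

    @property
    def real_barcodes(self) -> pd.DataFrame:
        return self.pool[self.pool["chimera"] == 0]

    def barcode_fitness(self, condition: str) -> pd.Series:
        """True fitness of each non-chimeric barcode in a condition."""
        fit = self.gene_fitness[condition]

        def one(gene_field: str) -> float:
            genes = [g for g in str(gene_field).split(",") if g]
            if not genes:
                return 0.0  # intergenic strains are neutral
            return float(np.mean([fit.get(g, 0.0) for g in genes]))

        sub = self.real_barcodes
        return pd.Series(
            [one(g) for g in sub["gene_id"]], index=pd.Index(sub["barcode"]), dtype=float
        )

    def expected_abundance(self, condition: str) -> pd.Series:
        """Expected relative abundance per barcode in a sample (sums to 1)."""
        if self.time0_abundance is None:
            raise ValueError("growth has not been simulated yet")
        if condition == TIME0:
            return self.time0_abundance
        w = self.time0_abundance * 2.0 ** self.barcode_fitness(condition).to_numpy()
        return w / w.sum()

    def to_barcode_map(self, n_reads: int = 10) -> BarcodeMap:
        """Idealized pool table (non-chimeric barcodes at their true sites)."""
        sub = self.real_barcodes
        table = pd.DataFrame(
            {
                "barcode": sub["barcode"].to_numpy(),
                "rcbarcode": [reverse_complement(b) for b in sub["barcode"]],
                "replicon": sub["replicon"].to_numpy(),
                "strand": sub["strand"].to_numpy(),
                "pos": sub["pos"].to_numpy(),
                "nTot": n_reads,
                "n": n_reads,
                "fraction": 1.0,
                "gene_id": sub["gene_id"].to_numpy(),
                "central": [int(bool(g)) for g in sub["gene_id"]],
            },
            columns=POOL_COLUMNS,
        ).reset_index(drop=True)
        return BarcodeMap(table=table)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_genome(config: SimulationConfig) -> tuple[GenomeModel, GroundTruth]:
    """Random genome with non-overlapping genes and per-gene true fitness.

    Genes are spread over the replicons proportionally to length, placed
    uniformly at random without overlap, on both strands.  Each gene draws a
    base fitness from the configured mixture (shared by all ten plant
    conditions); a random sample of base-neutral genes is then planted as
    plant-specific (strong defect in both compartments of one species, neutral
    elsewhere).
    """
    rng = config.rng(_STAGE_GENOME)
    replicons: dict[str, Replicon] = {}
    for name, length in zip(config.replicon_names, config.replicon_lengths):
        replicons[name] = Replicon(name, _random_dna(rng, length))

    total_len = sum(config.replicon_lengths)
    genes: dict[str, Gene] = {}
    gene_no = 0
    for name, length in zip(config.replicon_names, config.replicon_lengths):
        n_here = round(config.n_genes * length / total_len)
        if name == config.replicon_names[-1]:
            n_here = config.n_genes - gene_no
        occupied: list[tuple[int, int]] = []
        for _ in range(n_here):
            glen = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            placed = False
            for _attempt in range(200):
                start = int(rng.integers(EDGE_MARGIN + 1, length - glen - EDGE_MARGIN))
                end = start + glen - 1
                if all(end < s or start > e for s, e in occupied):
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    f"cannot place {n_here} non-overlapping genes on replicon {name!r}"
                )
            occupied.append((start, end))
            gene_no += 1
            gid = f"SYN{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes[gid] = Gene(gid, name, start, end, strand, "hypothetical protein")

    genome = GenomeModel(replicons=replicons, genes=genes)
    truth = GroundTruth(
        gene_fitness=_assign_true_fitness(genome, config), pool=pd.DataFrame()
    )
    return genome, truth


def _assign_true_fitness(genome: GenomeModel, config: SimulationConfig) -> pd.DataFrame:
    rng = config.rng(_STAGE_FITNESS)
    gene_ids = sorted(genome.genes)
    values = np.array([f for f, _p in config.fitness_mixture])
    probs = np.array([p for _f, p in config.fitness_mixture])
    base = values[rng.choice(len(values), size=len(gene_ids), p=probs)]
    fit = pd.DataFrame(
        {cond: base.copy() for cond in CONDITION_LABELS}, index=pd.Index(gene_ids, name="gene_id")
    )
    neutral_ids = [g for g, b in zip(gene_ids, base) if b == 0.0]
    n_plant = min(config.n_plant_specific, len(neutral_ids))
    planted = rng.choice(len(neutral_ids), size=n_plant, replace=False)
    for i in planted:
        gid = neutral_ids[i]
        species = SPECIES[int(rng.integers(0, len(SPECIES)))]
        for comp in COMPARTMENTS:
            fit.loc[gid, condition_label(species, comp)] = config.plant_specific_fitness
    return fit


def _sample_unique_barcodes(rng: np.random.Generator, n: int) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(out), BARCODE_LEN))]
        for row in block:
            bc = row.tobytes().decode("ascii")
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
    return out


def simulate_pool(
    genome: GenomeModel, truth: GroundTruth, config: SimulationConfig
) -> tuple[GroundTruth, TASiteIndex]:
    """Assign barcodes to TA sites and add chimeric artifact barcodes.

    ``genic_fraction`` of barcodes land on TA sites within central 10–90%
    gene regions (spread as evenly as possible over genes; several barcodes
    may share a site up to ``barcodes_per_site_max``); the rest land on
    intergenic/peripheral TA sites.  Chimeric barcodes — library artifacts
    whose junction reads split 50/50 between two loci — are appended on top,
    each flagged with a second location.
    """
    rng = config.rng(_STAGE_POOL)
    ta = build_ta_index(genome)
    if config.n_barcodes > ta.n_sites() * config.barcodes_per_site_max:
        raise ValueError("more barcodes requested than TA sites x barcodes_per_site_max")

    def usable(rep: str, pos: int) -> bool:
        return EDGE_MARGIN < pos < genome.replicons[rep].length - EDGE_MARGIN

    central_sites: dict[str, list[tuple[str, int]]] = {}
    for gid, gene in genome.genes.items():
        sites = [
            (gene.replicon, int(p))
            for p in ta.positions[gene.replicon]
            if gene.start <= p <= gene.end
            and usable(gene.replicon, int(p))
            and genome.central_genes_at(gene.replicon, int(p))
        ]
        central_sites[gid] = sites

    all_sites = [
        (rep, int(p))
        for rep in sorted(ta.positions)
        for p in ta.positions[rep]
        if usable(rep, int(p))
    ]
    noncentral_sites = [
        (rep, p) for rep, p in all_sites if not genome.central_genes_at(rep, p)
    ]

    site_load: dict[tuple[str, int], int] = {}

    def pick(sites: list[tuple[str, int]]) -> tuple[str, int]:
        for _ in range(50):
            rep, pos = sites[int(rng.integers(0, len(sites)))]
            if site_load.get((rep, pos), 0) < config.barcodes_per_site_max:
                site_load[(rep, pos)] = site_load.get((rep, pos), 0) + 1
                return rep, pos
        raise ValueError("could not find a free TA site (increase barcodes_per_site_max)")

    n_genic = round(config.n_barcodes * config.genic_fraction)
    gene_order = sorted(g for g in genome.genes if central_sites[g])
    placements: list[tuple[str, int]] = []
    for i in range(n_genic):
        gid = gene_order[i % len(gene_order)]
        placements.append(pick(central_sites[gid]))
    for _ in range(config.n_barcodes - n_genic):
        placements.append(pick(noncentral_sites))

    n_chimera = int(rng.binomial(config.n_barcodes, config.chimera_rate))
    barcodes = _sample_unique_barcodes(rng, config.n_barcodes + n_chimera)

    rows = []
    for i, (rep, pos) in enumerate(placements):
        strand = "+" if rng.random() < 0.5 else "-"
        gene_ids = ",".join(sorted(g.id for g in genome.central_genes_at(rep, pos)))
        rows.append(
            {
                "barcode": barcodes[i],
                "replicon": rep,
                "pos": pos,
                "strand": strand,
                "gene_id": gene_ids,
                "chimera": 0,
                "replicon2": "",
                "pos2": 0,
            }
        )
    for j in range(n_chimera):
        (rep_a, pos_a) = all_sites[int(rng.integers(0, len(all_sites)))]
        (rep_b, pos_b) = all_sites[int(rng.integers(0, len(all_sites)))]
        while (rep_b, pos_b) == (rep_a, pos_a):
            (rep_b, pos_b) = all_sites[int(rng.integers(0, len(all_sites)))]
        rows.append(
            {
                "barcode": barcodes[config.n_barcodes + j],
                "replicon": rep_a,
                "pos": pos_a,
                "strand": "+",
                "gene_id": "",
                "chimera": 1,
                "replicon2": rep_b,
                "pos2": pos_b,
            }
        )
    truth.pool = pd.DataFrame(
        rows,
        columns=["barcode", "replicon", "pos", "strand", "gene_id", "chimera", "replicon2", "pos2"],
    )
    return truth, ta


def _junction_segment(genome: GenomeModel, rep: str, pos: int, strand: str, length: int) -> str:
    """Genomic segment of a junction read for an insertion at TA position
    ``pos`` (plus-strand T coordinate), read outward on ``strand``."""
    seq = genome.replicons[rep].sequence
    if strand == "+":
        return seq[pos - 1 : pos - 1 + length]
    return reverse_complement(seq[pos + 1 - length : pos + 1])


def simulate_mapping_reads(
    genome: GenomeModel,
    truth: GroundTruth,
    config: SimulationConfig,
    fastq_path: str | Path,
    flank_model: MappingFlankModel | None = None,
    segment_len: int = 40,
) -> None:
    """Write TnSeq junction reads for every barcode in the truth pool.

    Normal barcodes get ``mapping_reads_per_barcode`` reads at their true
    site, each independently relocated to a uniform random genomic position
    (usually not a TA) with probability ``location_error_rate``.  Chimeric
    barcodes split their reads exactly 50/50 between their two sites.
    """
    fm = flank_model or MappingFlankModel()
    rng = config.rng(_STAGE_MAPREADS)
    reps = sorted(genome.replicons)
    lengths = np.array([genome.replicons[r].length for r in reps], dtype=float)
    rep_probs = lengths / lengths.sum()

    def random_location() -> tuple[str, int, str]:
        rep = reps[int(rng.choice(len(reps), p=rep_probs))]
        pos = int(rng.integers(EDGE_MARGIN + 1, genome.replicons[rep].length - EDGE_MARGIN))
        strand = "+" if rng.random() < 0.5 else "-"
        return rep, pos, strand

    n_reads = config.mapping_reads_per_barcode
    with FastqWriter(fastq_path) as out:
        for row in truth.pool.itertuples():
            if row.chimera:
                half = n_reads // 2
                locs = [(row.replicon, row.pos, "+")] * half + [
                    (row.replicon2, row.pos2, "+")
                ] * (n_reads - half)
            else:
                locs = []
                for _ in range(n_reads):
                    if rng.random() < config.location_error_rate:
                        locs.append(random_location())
                    else:
                        locs.append((row.replicon, row.pos, row.strand))
            for i, (rep, pos, strand) in enumerate(locs):
                seg = _junction_segment(genome, rep, pos, strand, segment_len)
                out.write(f"{row.barcode}_{i}", fm.pre + row.barcode + fm.post + seg)


def simulate_growth(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[CountTable, GroundTruth]:
    """Draw per-sample barcode counts from the generative fitness model.

    Time0 relative abundances are Dirichlet-distributed around uniform
    (concentration per strain = ``dirichlet_concentration``); each condition
    reweights them by 2**f(gene) and renormalizes; read counts are multinomial
    at the configured depths.  Chimeric barcodes are mapping artifacts only
    and carry no abundance.
    """
    rng = config.rng(_STAGE_GROWTH)
    barcodes = truth.real_barcodes["barcode"].to_numpy()
    n = len(barcodes)
    p0 = rng.dirichlet(np.full(n, config.dirichlet_concentration))
    truth.time0_abundance = pd.Series(p0, index=pd.Index(barcodes, name="barcode"))

    sample_ids = [TIME0] + [c.replace(":", "_") for c in CONDITION_LABELS]
    cond_of = {TIME0: TIME0}
    cond_of.update({c.replace(":", "_"): c for c in CONDITION_LABELS})

    data: dict[str, np.ndarray] = {}
    data[TIME0] = rng.multinomial(config.depth_time0, p0)
    for cond in CONDITION_LABELS:
        p = truth.expected_abundance(cond).to_numpy()
        data[cond.replace(":", "_")] = rng.multinomial(config.depth_condition, p)

    counts = pd.DataFrame(data, index=pd.Index(barcodes, name="barcode"), dtype="int64")
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "condition": [cond_of[s] for s in sample_ids],
                "fastq_path": ["" for _ in sample_ids],
            }
        )
    )
    summary = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "total_reads": [int(counts[s].sum()) for s in sample_ids],
            "valid_barcode_reads": [int(counts[s].sum()) for s in sample_ids],
            "pool_hits": [int(counts[s].sum()) for s in sample_ids],
            "unmapped": [0 for _ in sample_ids],
        }
    )
    return CountTable(counts=counts, summary=summary, sample_sheet=sheet), truth


def write_barseq_reads(
    count_table: CountTable,
    config: SimulationConfig,
    outdir: str | Path,
    flank_model: BarSeqFlankModel | None = None,
    read_len: int = 100,
) -> SampleSheet:
    """Wrap a count table into per-sample BarSeq FASTQs.

    Each read is a random stagger prefix (0..``stagger_max`` nt, emulating the
    staggered forward primers), the flanked barcode, and random filler to
    ``read_len``.  Returns a sample sheet pointing at the written files.
    """
    fm = flank_model or BarSeqFlankModel()
    rng = config.rng(_STAGE_BARSEQ)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample_id in count_table.counts.columns:
        path = outdir / f"{sample_id}.fastq"
        with FastqWriter(path) as out:
            col = count_table.counts[sample_id]
            read_no = 0
            for barcode, n in col.items():
                core = fm.pre + barcode + fm.post
                for _ in range(int(n)):
                    stagger = _random_dna(rng, int(rng.integers(0, config.stagger_max + 1)))
                    filler = _random_dna(rng, max(0, read_len - len(stagger) - len(core)))
                    out.write(f"{sample_id}_{read_no}", stagger + core + filler)
                    read_no += 1
        rows.append(
            {
                "sample_id": sample_id,
                "condition": count_table.sample_sheet.condition_of(sample_id),
                "fastq_path": str(path),
            }
        )
    return SampleSheet(pd.DataFrame(rows))


def run_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a complete synthetic experiment on disk.

    Always writes genome.fasta, genes.gff3, gene_truth.tsv, barcode_truth.tsv,
    mapping_reads.fastq, counts.tsv and samples.tsv; with ``fidelity='reads'``
    additionally writes per-sample BarSeq FASTQs under ``barseq/`` and points
    the sample sheet at them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    truth, _ta = simulate_pool(genome, truth, config)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff": outdir / "genes.gff3",
        "gene_truth": outdir / "gene_truth.tsv",
        "barcode_truth": outdir / "barcode_truth.tsv",
        "mapping_fastq": outdir / "mapping_reads.fastq",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
    }
    write_fasta(
        [(name, genome.replicons[name].sequence) for name in config.replicon_names],
        paths["fasta"],
    )
    write_gff3(
        sorted(genome.genes.values(), key=lambda g: (g.replicon, g.start)), paths["gff"]
    )
    truth.gene_fitness.round(4).to_csv(paths["gene_truth"], sep="\t")
    truth.pool.to_csv(paths["barcode_truth"], sep="\t", index=False)
    simulate_mapping_reads(genome, truth, config, paths["mapping_fastq"])
    count_table, truth = simulate_growth(truth, config)
    count_table.to_tsv(paths["counts"])
    if config.fidelity == "reads":
        sheet = write_barseq_reads(count_table, config, outdir / "barseq")
        sheet.to_tsv(paths["samples"])
    else:
        count_table.sample_sheet.to_tsv(paths["samples"])
    return paths
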