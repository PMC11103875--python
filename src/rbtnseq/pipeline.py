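"""End-to-end driver: simulate -> map pool -> count -> fitness -> compare.

Mirrors how the analysis runs on real data, but wired to the synthetic
generator so the whole chain can be exercised (and checked for byte-level
determinism) from a single seed.
"""

from __future__ import annotations

from pathlib import Path

from .compare import compare_compartments
from .counting import count_barcodes, read_sample_sheet
from .fitness import (
    FitnessParams,
    compute_gene_fitness,
    write_gene_fitness_tsv,
    write_strain_fitness_tsv,
)
from .genome import build_ta_index, load_genome
from .pool import (
    call_reliable_mutants,
    filter_ta_sites,
    parse_mapping_reads,
    write_pool_tsv,
)
from .simulate import SimulationConfig, run_simulation

__all__ = ["run_pipeline"]

OUTPUT_FILES = [
    "pool.tsv",
    "strain_fitness.tsv",
    "gene_fitness.tsv",
    "compare/phenotype_calls.tsv",
    "compare/common_rhizosphere.tsv",
    "compare/common_root.tsv",
    "compare/plant_specific_rhizosphere.tsv",
    "compare/plant_specific_root.tsv",
    "compare/progressive_labels.tsv",
    "compare/summary.txt",
]


def run_pipeline(
    config: SimulationConfig,
    outdir: str | Path,
    params: FitnessParams | None = None,
) -> dict[str, Path]:
    """Simulate an experiment and analyse it from the raw reads up.

    Requires ``config.fidelity == 'reads'`` so that pool mapping and barcode
    counting run on actual FASTQ input.  Returns paths of all written outputs.
    """
    if config.fidelity != "reads":
        raise ValueError("run_pipeline requires fidelity='reads'")
    outdir = Path(outdir)
    sim_paths = run_simulation(config, outdir / "sim")

    genome = load_genome(sim_paths["fasta"], sim_paths["gff"])
    ta_index = build_ta_index(genome)
    candidates, _stats = parse_mapping_reads(sim_paths["mapping_fastq"], genome)
    candidates, _removed = filter_ta_sites(candidates, ta_index)
    pool = call_reliable_mutants(candidates, genome)
    write_pool_tsv(pool, outdir / "pool.tsv")

    sheet = read_sample_sheet(sim_paths["samples"])
    count_table = count_barcodes(sheet, pool)

    gene_replicons = {g.id: g.replicon for g in genome.genes.values()}
    gft = compute_gene_fitness(count_table, pool, gene_replicons, params)
    write_strain_fitness_tsv(gft.strains, outdir / "strain_fitness.tsv")
    write_gene_fitness_tsv(gft, outdir / "gene_fitness.tsv")

    result = compare_compartments(gft)
    result.write(outdir / "compare")

    out = {name: outdir / name for name in OUTPUT_FILES}
    out.update(sim_paths)
    return out
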