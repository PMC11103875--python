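"""Shared fixtures: tiny hand-built genomes and a default synthetic run."""

from __future__ import annotations

import pandas as pd
import pytest

from rbtnseq.fitness import compute_gene_fitness
from rbtnseq.genome import Gene, GenomeModel, Replicon
from rbtnseq.simulate import (
    SimulationConfig,
    simulate_genome,
    simulate_growth,
    simulate_pool,
)


@pytest.fixture
def tiny_genome() -> GenomeModel:
    """A 60 bp replicon with two genes and hand-placed TA sites."""
    #          1         2         3         4         5         6
    # 123456789012345678901234567890123456789012345678901234567890
    seq = "GGTACCGGGGTAGGGGGGGGTAGGGGGGGGTAGGGGGGGGTAGGGGGGGGTAGGGGGGG"
    genes = {
        "geneA": Gene("geneA", "chr", 5, 34, "+", "demo A"),
        "geneB": Gene("geneB", "chr", 38, 57, "-", "demo B"),
    }
    return GenomeModel(replicons={"chr": Replicon("chr", seq)}, genes=genes)


@pytest.fixture(scope="session")
def default_sim():
    """Default-scale synthetic experiment (counts fidelity, seed 1) with its
    estimated gene-fitness table; shared because it is the package's standard
    study condition."""
    config = SimulationConfig(seed=1)
    genome, truth = simulate_genome(config)
    truth, ta_index = simulate_pool(genome, truth, config)
    count_table, truth = simulate_growth(truth, config)
    pool = truth.to_barcode_map()
    gene_replicons = {g.id: g.replicon for g in genome.genes.values()}
    gft = compute_gene_fitness(count_table, pool, gene_replicons)
    return {
        "config": config,
        "genome": genome,
        "truth": truth,
        "ta_index": ta_index,
        "count_table": count_table,
        "pool": pool,
        "gft": gft,
    }


def truth_long(truth) -> pd.DataFrame:
    """Ground-truth gene fitness in long (gene_id, condition, f_true) form."""
    long = truth.gene_fitness.stack().rename("f_true").reset_index()
    long.columns = ["gene_id", "condition", "f_true"]
    return long
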