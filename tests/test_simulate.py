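"""Synthetic-data generator: determinism, TA density, generative model."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from rbtnseq.conditions import TIME0, condition_label
from rbtnseq.counting import count_barcodes
from rbtnseq.genome import build_ta_index
from rbtnseq.simulate import (
    SimulationConfig,
    run_simulation,
    simulate_genome,
    simulate_growth,
    simulate_pool,
    write_barseq_reads,
)

SMALL = SimulationConfig(
    seed=11,
    replicon_lengths=(60_000, 20_000),
    n_genes=40,
    n_barcodes=300,
    depth_time0=30_000,
    depth_condition=30_000,
    n_plant_specific=4,
)


@pytest.fixture(scope="module")
def small_sim():
    genome, truth = simulate_genome(SMALL)
    truth, ta = simulate_pool(genome, truth, SMALL)
    count_table, truth = simulate_growth(truth, SMALL)
    return genome, truth, ta, count_table


class TestSimulateGenome:
    def test_gene_count_and_no_overlap(self, small_sim):
        genome, *_ = small_sim
        assert len(genome.genes) == SMALL.n_genes
        by_rep: dict[str, list] = {}
        for g in genome.genes.values():
            by_rep.setdefault(g.replicon, []).append((g.start, g.end))
        for spans in by_rep.values():
            spans.sort()
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                assert e1 < s2
        assert {g.strand for g in genome.genes.values()} == {"+", "-"}

    def test_same_seed_identical_outputs(self, tmp_path):
        cfg = dataclasses.replace(SMALL, depth_time0=2000, depth_condition=2000)
        p1 = run_simulation(cfg, tmp_path / "a")
        p2 = run_simulation(cfg, tmp_path / "b")
        for key in ("fasta", "gff", "gene_truth", "barcode_truth", "mapping_fastq", "counts"):
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_different_seed_differs(self, tmp_path):
        a = simulate_genome(SMALL)[0].replicons["chromosome"].sequence
        b = simulate_genome(dataclasses.replace(SMALL, seed=12))[0].replicons[
            "chromosome"
        ].sequence
        assert a != b

    def test_ta_density_matches_binomial(self, small_sim):
        """Uniform random DNA has TA at each of L-1 windows with p=1/16."""
        genome, _, ta, _ = small_sim
        for name, rep in genome.replicons.items():
            n_windows = rep.length - 1
            expected = n_windows / 16
            sd = math.sqrt(n_windows * (1 / 16) * (15 / 16))
            observed = len(ta.positions[name])
            assert abs(observed - expected) < 3 * sd

    def test_too_many_genes_error(self):
        cfg = SimulationConfig(
            seed=0, replicon_lengths=(4_000,), replicon_names=("chr",), n_genes=10
        )
        with pytest.raises(ValueError, match="non-overlapping"):
            simulate_genome(cfg)


class TestSimulatePool:
    def test_every_barcode_on_genuine_ta(self, small_sim):
        genome, truth, ta, _ = small_sim
        for row in truth.pool.itertuples():
            assert ta.contains(row.replicon, row.pos)
            if row.chimera:
                assert ta.contains(row.replicon2, row.pos2)

    def test_barcodes_unique(self, small_sim):
        _, truth, *_ = small_sim
        assert truth.pool["barcode"].is_unique

    def test_chimera_fraction_near_rate(self):
        cfg = dataclasses.replace(SMALL, n_barcodes=2000, chimera_rate=0.02)
        genome, truth = simulate_genome(cfg)
        truth, _ = simulate_pool(genome, truth, cfg)
        n_chim = int(truth.pool["chimera"].sum())
        # binomial(2000, 0.02): mean 40, sd ~6.3
        assert abs(n_chim - 40) < 4 * 6.3

    def test_too_many_barcodes_error(self, small_sim):
        genome, truth, *_ = small_sim
        cfg = dataclasses.replace(SMALL, n_barcodes=10**9)
        with pytest.raises(ValueError, match="TA sites"):
            simulate_pool(genome, truth, cfg)

    def test_gene_assignment_is_central(self, small_sim):
        genome, truth, *_ = small_sim
        genic = truth.pool[(truth.pool["gene_id"] != "") & (truth.pool["chimera"] == 0)]
        assert len(genic) >= 0.7 * SMALL.n_barcodes
        for row in genic.head(50).itertuples():
            central = {g.id for g in genome.central_genes_at(row.replicon, row.pos)}
            assert set(row.gene_id.split(",")) == central


class TestSimulateGrowth:
    def test_expected_abundances_sum_to_one(self, small_sim):
        _, truth, _, _ = small_sim
        for cond in (TIME0, condition_label("pea", "rhizosphere")):
            assert truth.expected_abundance(cond).sum() == pytest.approx(1.0)

    def test_multinomial_totals_equal_depth(self, small_sim):
        *_, count_table = small_sim
        sums = count_table.counts.sum()
        assert sums[TIME0] == SMALL.depth_time0
        assert (sums.drop(TIME0) == SMALL.depth_condition).all()

    def test_all_neutral_means_no_shift(self):
        cfg = dataclasses.replace(
            SMALL, fitness_mixture=((0.0, 1.0),), n_plant_specific=0
        )
        genome, truth = simulate_genome(cfg)
        truth, _ = simulate_pool(genome, truth, cfg)
        _, truth = simulate_growth(truth, cfg)
        t0 = truth.expected_abundance(TIME0)
        cond = truth.expected_abundance(condition_label("barley", "root"))
        assert np.allclose(t0.to_numpy(), cond.to_numpy())

    def test_fitness_acts_as_abundance_multiplier(self, small_sim):
        """Strains of a gene with true f sink by 2**f relative to neutral."""
        _, truth, _, _ = small_sim
        cond = condition_label("pea", "rhizosphere")
        fit = truth.barcode_fitness(cond)
        t0 = truth.expected_abundance(TIME0)
        pc = truth.expected_abundance(cond)
        ratio = (pc / t0).to_numpy()
        # all strains shift by 2**f divided by one common normalizer
        norm = ratio / 2.0 ** fit.to_numpy()
        assert np.allclose(norm, norm[0])
        hit = fit[fit < -1].index
        neutral = fit[fit == 0].index
        if len(hit):
            observed = (pc[hit] / t0[hit]).iloc[0] / (pc[neutral] / t0[neutral]).iloc[0]
            assert observed == pytest.approx(2.0 ** fit[hit].iloc[0])


class TestBarSeqReads:
    def test_counts_round_trip_through_reads(self, tmp_path):
        """Counting the generated FASTQs recovers the count table exactly."""
        cfg = dataclasses.replace(SMALL, depth_time0=3000, depth_condition=3000)
        genome, truth = simulate_genome(cfg)
        truth, _ = simulate_pool(genome, truth, cfg)
        count_table, truth = simulate_growth(truth, cfg)
        sheet = write_barseq_reads(count_table, cfg, tmp_path)
        recounted = count_barcodes(sheet, truth.to_barcode_map())
        pd.testing.assert_frame_equal(
            recounted.counts.sort_index(), count_table.counts.sort_index()
        )
        assert (recounted.summary["unmapped"] == 0).all()
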