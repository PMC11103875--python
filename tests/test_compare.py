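"""Phenotype bins and gene-set logic across species and compartments."""

from __future__ import annotations

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbtnseq.compare import (
    ADVANTAGEOUS,
    COLONIZATION_SPECIFIC,
    MILD,
    MISSING,
    MODERATE,
    NEUTRAL,
    PROGRESSIVE,
    RHIZOSPHERE_SPECIFIC,
    SEVERE,
    classify,
    common_determinants,
    plant_specific,
    progressive_labels,
)
from rbtnseq.conditions import SPECIES, condition_label
from rbtnseq.fitness import GeneFitnessTable


def make_gft(f_by_gene: dict[str, list[float | None]], compartment="rhizosphere", t_by_gene=None):
    """Build a GeneFitnessTable for one compartment from per-species values."""
    rows = []
    for gene, fs in f_by_gene.items():
        ts = (t_by_gene or {}).get(gene, [None] * len(SPECIES))
        for sp, f, t in zip(SPECIES, fs, ts):
            if t is None and f is not None:
                t = -10.0 if f < 0 else 10.0  # confidently scored by default
            rows.append(
                {
                    "gene_id": gene,
                    "replicon": "chr",
                    "condition": condition_label(sp, compartment),
                    "f": np.nan if f is None else f,
                    "t": np.nan if f is None else t,
                    "n_strains": 0 if f is None else 5,
                    "reads0": 0 if f is None else 100,
                }
            )
    return GeneFitnessTable(table=pd.DataFrame(rows))


class TestClassify:
    @pytest.mark.parametrize(
        "f,category",
        [
            (-2.5, SEVERE),
            (-2.0, MODERATE),  # severe is strictly below -2
            (-1.5, MODERATE),
            (-1.0, MILD),
            (-0.42, MILD),
            (0.0, NEUTRAL),
            (0.41, NEUTRAL),
            (0.42, ADVANTAGEOUS),
            (0.5, ADVANTAGEOUS),
            (None, MISSING),
            (float("nan"), MISSING),
        ],
    )
    def test_bins(self, f, category):
        assert classify(f) == category

    @settings(max_examples=300, deadline=None)
    @given(st.floats(-20, 20, allow_nan=False))
    def test_partitions_real_line(self, f):
        """Every finite fitness maps to exactly one non-missing category."""
        cats = [
            f < -2,
            -2 <= f < -1,
            -1 <= f <= -0.42,
            -0.42 < f < 0.42,
            f >= 0.42,
        ]
        assert sum(cats) == 1
        expected = [SEVERE, MODERATE, MILD, NEUTRAL, ADVANTAGEOUS][cats.index(True)]
        assert classify(f) == expected


class TestCommonDeterminants:
    def test_all_species_disadvantaged_included(self):
        gft = make_gft({"g1": [-0.5, -1.2, -2.1, -0.43, -3.0]})
        assert common_determinants(gft, "rhizosphere") == {"g1"}

    def test_one_neutral_species_excluded(self):
        gft = make_gft({"g1": [-0.5, -1.2, -2.1, -0.3, -3.0]})
        assert common_determinants(gft, "rhizosphere") == set()

    def test_missing_species_excluded(self):
        gft = make_gft({"g1": [-0.5, -1.2, -2.1, None, -3.0]})
        assert common_determinants(gft, "rhizosphere") == set()

    def test_absent_condition_errors(self):
        gft = make_gft({"g1": [-0.5, -1.2, -2.1, -0.5, -3.0]}, compartment="rhizosphere")
        with pytest.raises(ValueError, match="no fitness data"):
            common_determinants(gft, "root")

    def test_agrees_with_classification_route(self):
        """Cross-check: membership equals 'severe/moderate/mild in every
        species' computed through classify()."""
        rng = np.random.default_rng(42)
        genes = {
            f"g{i}": list(rng.uniform(-3, 1, size=len(SPECIES))) for i in range(300)
        }
        gft = make_gft(genes)
        via_threshold = common_determinants(gft, "rhizosphere")
        via_classify = {
            g
            for g, fs in genes.items()
            if all(classify(f) in (SEVERE, MODERATE, MILD) for f in fs)
        }
        assert via_threshold == via_classify


class TestPlantSpecific:
    def test_single_species(self):
        gft = make_gft({"g1": [-1.5, -0.2, 0.0, -0.1, 0.3]})
        out = plant_specific(gft, "rhizosphere")
        assert out["gene_id"].tolist() == ["g1"]
        assert out["species"].iloc[0] == "pea"

    def test_gray_zone_species_blocks(self):
        gft = make_gft({"g1": [-1.5, -0.5, 0.0, -0.1, 0.3]})
        assert plant_specific(gft, "rhizosphere").empty

    def test_two_species_subset(self):
        gft = make_gft({"g1": [-1.5, -1.8, 0.0, -0.1, 0.3]})
        out = plant_specific(gft, "rhizosphere")
        assert out["species"].iloc[0] == "pea,lentil"

    def test_low_t_filtered(self):
        gft = make_gft(
            {"g1": [-1.5, -0.2, 0.0, -0.1, 0.3]},
            t_by_gene={"g1": [-2.0, 1.0, 0.5, 0.5, 0.5]},
        )
        assert plant_specific(gft, "rhizosphere").empty

    def test_all_species_strong_not_specific(self):
        gft = make_gft({"g1": [-1.5, -1.5, -1.5, -1.5, -1.5]})
        assert plant_specific(gft, "rhizosphere").empty

    def test_missing_species_excluded(self):
        gft = make_gft({"g1": [-1.5, None, 0.0, -0.1, 0.3]})
        assert plant_specific(gft, "rhizosphere").empty


class TestProgressiveLabels:
    def test_abstract_arithmetic(self):
        """189 rhizosphere / 230 root with 111 shared leaves 119 colonization-only."""
        rhi = {f"g{i}" for i in range(189)}
        root = {f"g{i}" for i in range(78, 308)}  # overlap 111, total 230
        labels = progressive_labels(rhi, root)
        counts = pd.Series(labels).value_counts()
        assert counts[PROGRESSIVE] == 111
        assert counts[COLONIZATION_SPECIFIC] == 119
        assert counts[RHIZOSPHERE_SPECIFIC] == 78

    def test_disjoint_sets(self):
        labels = progressive_labels({"a"}, {"b"})
        assert labels == {"a": RHIZOSPHERE_SPECIFIC, "b": COLONIZATION_SPECIFIC}

    def test_identical_sets_all_progressive(self):
        labels = progressive_labels({"a", "b"}, {"a", "b"})
        assert set(labels.values()) == {PROGRESSIVE}

    def test_cardinality_identities_random_pairs(self):
        """|rhi-only| + |both| == |rhi| and |col-only| + |both| == |root|."""
        rng = random.Random(7)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(1000):
            rhi = set(rng.sample(universe, rng.randint(0, 60)))
            root = set(rng.sample(universe, rng.randint(0, 60)))
            labels = progressive_labels(rhi, root)
            n_prog = sum(1 for v in labels.values() if v == PROGRESSIVE)
            n_rhi = sum(1 for v in labels.values() if v == RHIZOSPHERE_SPECIFIC)
            n_col = sum(1 for v in labels.values() if v == COLONIZATION_SPECIFIC)
            assert n_rhi + n_prog == len(rhi)
            assert n_col + n_prog == len(root)
            assert len(labels) == len(rhi | root)
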