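"""Phenotype classification and cross-condition gene-set comparison.

Fitness bins (log2 units): severe < -2 (>= 75% growth reduction), moderate
[-2, -1) (50–75%), mild [-1, -0.42] (25–50%), neutral (-0.42, 0.42),
advantageous >= 0.42.  "Disadvantaged" therefore means f <= -0.42.

From the per-species fitness matrices of a compartment we derive:

* common determinants — genes at least mildly disadvantaged in *every* species;
* plant-specific genes — strongly required (f < -1, reliable t) in a proper
  subset of species while neutral (f > -0.42) in all the others;
* cross-compartment labels — rhizosphere-progressive genes are common to both
  the rhizosphere and root compartments; the remainders are rhizosphere- or
  colonization-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import COMPARTMENTS, SPECIES, condition_label
from .fitness import GeneFitnessTable

__all__ = [
    "SEVERE",
    "MODERATE",
    "MILD",
    "NEUTRAL",
    "ADVANTAGEOUS",
    "MISSING",
    "classify",
    "classify_table",
    "common_determinants",
    "plant_specific",
    "progressive_labels",
    "ComparisonResult",
    "compare_compartments",
]

SEVERE = "severe"
MODERATE = "moderate"
MILD = "mild"
NEUTRAL = "neutral"
ADVANTAGEOUS = "advantageous"
MISSING = "missing"

#: f <= DISADVANTAGE_CUTOFF counts as at least a mild disadvantage.
DISADVANTAGE_CUTOFF = -0.42

PROGRESSIVE = "progressive"
RHIZOSPHERE_SPECIFIC = "rhizosphere_specific"
COLONIZATION_SPECIFIC = "colonization_specific"
NONE_LABEL = "none"


def classify(f: float | None) -> str:
    """Bin a gene fitness value into its phenotype category.

    The bins partition the real line: severe f < -2; moderate -2 <= f < -1;
    mild -1 <= f <= -0.42; neutral -0.42 < f < 0.42; advantageous f >= 0.42.
    NaN/None means the gene was not scored.
    """
    if f is None or (isinstance(f, float) and np.isnan(f)):
        return MISSING
    if f < -2:
        return SEVERE
    if f < -1:
        return MODERATE
    if f <= DISADVANTAGE_CUTOFF:
        return MILD
    if f < 0.42:
        return NEUTRAL
    return ADVANTAGEOUS


def classify_table(gft: GeneFitnessTable) -> pd.DataFrame:
    """Gene x condition matrix of phenotype categories."""
    mat = gft.table.pivot(index="gene_id", columns="condition", values="f")
    return mat.apply(lambda col: col.map(classify))


def _species_matrix(
    gft: GeneFitnessTable, compartment: str, species_list: tuple[str, ...], value: str
) -> pd.DataFrame:
    conds = [condition_label(sp, compartment) for sp in species_list]
    present = set(gft.table["condition"])
    absent = [c for c in conds if c not in present]
    if absent:
        raise ValueError(f"no fitness data for condition(s) {absent}")
    mat = gft.matrix(conds, value=value)
    mat.columns = list(species_list)
    return mat


def common_determinants(
    gft: GeneFitnessTable,
    compartment: str,
    species_list: tuple[str, ...] = SPECIES,
    cutoff: float = DISADVANTAGE_CUTOFF,
) -> set[str]:
    """Genes at least mildly disadvantaged (f <= cutoff) in every species.

    Genes missing a fitness value in any species are excluded, not imputed.
    A species with no data at all for the compartment is an error.
    """
    mat = _species_matrix(gft, compartment, species_list, "f")
    if mat.isna().all(axis=None):
        raise ValueError(f"no scored genes for compartment {compartment!r}")
    ok = mat.notna().all(axis=1) & (mat <= cutoff).all(axis=1)
    return set(mat.index[ok])


def plant_specific(
    gft: GeneFitnessTable,
    compartment: str,
    species_list: tuple[str, ...] = SPECIES,
    strong: float = -1.0,
    neutral_floor: float = DISADVANTAGE_CUTOFF,
    t_min: float = 3.0,
) -> pd.DataFrame:
    """Genes strongly required in a proper subset of species, neutral elsewhere.

    A gene is flagged for subset S (non-empty, proper) iff f < ``strong`` for
    every species in S, f > ``neutral_floor`` for every species outside S, and
    |t| >= ``t_min`` for every species in S.  S is the maximal qualifying
    subset {species : f < strong}.  Genes missing in any species are excluded.

    Returns a table: gene_id, species (comma-joined subset), min_f, min_abs_t.
    """
    fmat = _species_matrix(gft, compartment, species_list, "f")
    tmat = _species_matrix(gft, compartment, species_list, "t")
    rows = []
    scored = fmat.notna().all(axis=1)
    strong_mask = fmat < strong
    for gene in fmat.index[scored]:
        in_subset = strong_mask.loc[gene]
        subset = [sp for sp in species_list if in_subset[sp]]
        if not subset or len(subset) == len(species_list):
            continue
        others = [sp for sp in species_list if sp not in subset]
        if not (fmat.loc[gene, others] > neutral_floor).all():
            continue
        if not (tmat.loc[gene, subset].abs() >= t_min).all():
            continue
        rows.append(
            {
                "gene_id": gene,
                "species": ",".join(subset),
                "min_f": float(fmat.loc[gene, subset].min()),
                "min_abs_t": float(tmat.loc[gene, subset].abs().min()),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "species", "min_f", "min_abs_t"])


def progressive_labels(
    common_rhizosphere: set[str], common_root: set[str]
) -> dict[str, str]:
    """Label each gene in either common set by its cross-compartment pattern.

    Progressive genes are required in the rhizosphere *and* for subsequent
    root colonization (the intersection); the set differences are rhizosphere-
    or colonization-specific.  Labels are mutually exclusive.
    """
    labels: dict[str, str] = {}
    for g in common_rhizosphere | common_root:
        in_rhi = g in common_rhizosphere
        in_root = g in common_root
        if in_rhi and in_root:
            labels[g] = PROGRESSIVE
        elif in_rhi:
            labels[g] = RHIZOSPHERE_SPECIFIC
        else:
            labels[g] = COLONIZATION_SPECIFIC
    return labels


@dataclass
class ComparisonResult:
    """Gene sets and labels derived from the two compartments."""

    common: dict[str, set[str]]  # compartment -> common-determinant gene ids
    plant_specific: dict[str, pd.DataFrame]  # compartment -> specificity table
    labels: dict[str, str]  # gene -> progressive/rhizosphere/colonization label
    phenotypes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        rhi, root = self.common["rhizosphere"], self.common["root"]
        n_prog = sum(1 for v in self.labels.values() if v == PROGRESSIVE)
        n_rhi_only = sum(1 for v in self.labels.values() if v == RHIZOSPHERE_SPECIFIC)
        n_col_only = sum(1 for v in self.labels.values() if v == COLONIZATION_SPECIFIC)
        lines = [
            "Gene-set comparison summary",
            "===========================",
            f"Common rhizosphere determinants : {len(rhi)}",
            f"Common root-colonization genes  : {len(root)}",
            f"Rhizosphere-progressive (both)  : {n_prog}",
            f"Rhizosphere-specific only       : {n_rhi_only}",
            f"Colonization-specific only      : {n_col_only}",
            f"Plant-specific (rhizosphere)    : {len(self.plant_specific['rhizosphere'])}",
            f"Plant-specific (root)           : {len(self.plant_specific['root'])}",
        ]
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.phenotypes.to_csv(outdir / "phenotype_calls.tsv", sep="\t")
        for comp in COMPARTMENTS:
            pd.Series(sorted(self.common[comp]), name="gene_id").to_csv(
                outdir / f"common_{comp}.tsv", sep="\t", index=False
            )
            ps = self.plant_specific[comp].copy()
            for c in ("min_f", "min_abs_t"):
                ps[c] = ps[c].map(lambda x: f"{x:.4f}")
            ps.to_csv(outdir / f"plant_specific_{comp}.tsv", sep="\t", index=False)
        labels_df = pd.DataFrame(
            sorted(self.labels.items()), columns=["gene_id", "label"]
        )
        labels_df.to_csv(outdir / "progressive_labels.tsv", sep="\t", index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")


def compare_compartments(
    gft: GeneFitnessTable,
    species_list: tuple[str, ...] = SPECIES,
    t_min: float = 3.0,
) -> ComparisonResult:
    """Run the full comparison: common sets, plant-specific tables, labels."""
    common = {
        comp: common_determinants(gft, comp, species_list) for comp in COMPARTMENTS
    }
    specific = {
        comp: plant_specific(gft, comp, species_list, t_min=t_min)
        for comp in COMPARTMENTS
    }
    labels = progressive_labels(common["rhizosphere"], common["root"])
    return ComparisonResult(
        common=common,
        plant_specific=specific,
        labels=labels,
        phenotypes=classify_table(gft),
    )
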