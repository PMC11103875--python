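"""Gene fitness estimation from barcode counts.

For each insertion mutant (barcode), fitness is the log2 ratio of its relative
abundance after growth in a condition to its relative abundance in the Time0
inoculum.  Gene fitness is the inverse-variance-weighted average of the strain
fitness values of mutants inserted in the central 10–90% of that gene's coding
region, normalized per replicon so the typical (median) gene is at zero, and
accompanied by a t-like reliability score.

A pseudocount keeps zero counts finite, a Time0 read floor drops strains that
were too rare in the inoculum to quantify, and the per-strain weight is capped
so deeply sequenced strains cannot dominate a gene's average.

Formulas (``n`` = strain count, ``N`` = sample total over pool barcodes):

    f_strain = log2((nc + 0.5) / Nc) - log2((n0 + 0.5) / N0)
    var proxy v = (1/(1 + n0) + 1/(1 + nc)) / (ln 2)^2
    weight   = min(1/v, 1/v(20, 20))
    f_gene   = sum(w * f) / sum(w)   over contributing strains
    t        = f_gene_normalized / sqrt(1/sum(w) + tau^2),  tau = 0.1
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import TIME0
from .counting import CountTable
from .pool import BarcodeMap

__all__ = [
    "strain_fitness",
    "strain_weight",
    "gene_fitness",
    "normalize_fitness",
    "t_score",
    "fitness_to_growth_reduction",
    "FitnessParams",
    "GeneFitnessTable",
    "compute_strain_fitness",
    "compute_gene_fitness",
    "write_gene_fitness_tsv",
    "read_gene_fitness_tsv",
    "write_strain_fitness_tsv",
]

LN2_SQ = math.log(2) ** 2

GENE_COLUMNS = ["gene_id", "replicon", "condition", "f", "t", "n_strains", "reads0"]
STRAIN_COLUMNS = ["barcode", "condition", "n0", "nc", "f", "w"]


@dataclass(frozen=True)
class FitnessParams:
    """Tunables of the fitness estimator (defaults are the package standard)."""

    pseudocount: float = 0.5
    min_reads0: int = 3  # Time0 floor: strains rarer than this are unquantifiable
    min_strains: int = 1
    weight_cap_counts: int = 20
    tau: float = 0.1  # variance floor of the reliability score


def strain_fitness(n0, N0, nc, Nc, pseudocount: float = 0.5):
    """log2 relative-abundance ratio of a strain vs the Time0 inoculum.

    Accepts scalars or numpy arrays for the per-strain counts.
    """
    if N0 <= 0 or Nc <= 0:
        raise ValueError("sample totals N0 and Nc must be positive")
    n0 = np.asarray(n0, dtype=float)
    nc = np.asarray(nc, dtype=float)
    f = np.log2((nc + pseudocount) / Nc) - np.log2((n0 + pseudocount) / N0)
    return f.item() if f.ndim == 0 else f


def strain_weight(n0, nc, cap_counts: int = 20):
    """Inverse-variance weight for a strain, capped at the weight of a strain
    with ``cap_counts`` reads in both samples."""
    n0 = np.asarray(n0, dtype=float)
    nc = np.asarray(nc, dtype=float)
    v = (1.0 / (1.0 + n0) + 1.0 / (1.0 + nc)) / LN2_SQ
    v_cap = (2.0 / (1.0 + cap_counts)) / LN2_SQ
    w = np.minimum(1.0 / v, 1.0 / v_cap)
    return w.item() if w.ndim == 0 else w


def gene_fitness(fs, ws) -> float:
    """Weighted average of strain fitness values; NaN when no strains."""
    fs = np.asarray(fs, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if fs.size == 0:
        return float("nan")
    if np.any(ws <= 0):
        raise ValueError("strain weights must be positive")
    return float(np.sum(ws * fs) / np.sum(ws))


def normalize_fitness(table: pd.DataFrame, value_col: str = "f") -> pd.DataFrame:
    """Center gene fitness per (replicon, condition) at the median.

    The median operationalizes "the typical neutral gene"; replicons with no
    scored genes are skipped with a warning.  Idempotent.
    """
    out = table.copy()
    for (rep, cond), idx in out.groupby(["replicon", "condition"], sort=False).groups.items():
        vals = out.loc[idx, value_col]
        finite = vals.dropna()
        med = float(finite.median()) if len(finite) else float("nan")
        if np.isnan(med):
            warnings.warn(f"replicon {rep!r} has no scored genes in {cond!r}; not normalized")
            continue
        out.loc[idx, value_col] = vals - med
    return out


def t_score(f, sum_w, tau: float = 0.1):
    """Reliability score: fitness over its estimated standard error, floored."""
    f = np.asarray(f, dtype=float)
    sum_w = np.asarray(sum_w, dtype=float)
    t = f / np.sqrt(1.0 / sum_w + tau**2)
    return t.item() if t.ndim == 0 else t


def fitness_to_growth_reduction(f: float) -> int:
    """Percent growth reduction vs the average mutant, nearest integer.

    f = -2 -> 75%, f = -1 -> 50%, f = -0.42 -> 25%; negative percentages mean
    a growth advantage.
    """
    if not math.isfinite(f):
        raise ValueError("fitness must be finite")
    return round((1.0 - 2.0**f) * 100.0)


@dataclass
class GeneFitnessTable:
    """Per gene x condition fitness estimates.

    ``table`` columns: gene_id, replicon, condition, f, t, n_strains, reads0.
    Unscored gene/condition pairs are present with NaN fitness (never 0.0).
    ``strains`` is the per-barcode x condition table behind the estimates.
    """

    table: pd.DataFrame
    strains: pd.DataFrame | None = None

    def matrix(self, conditions: list[str], value: str = "f") -> pd.DataFrame:
        """Pivot to a gene x condition matrix for the given conditions."""
        sub = self.table[self.table["condition"].isin(conditions)]
        return sub.pivot(index="gene_id", columns="condition", values=value)[conditions]


def compute_strain_fitness(
    count_table: CountTable,
    pool: BarcodeMap,
    params: FitnessParams | None = None,
) -> pd.DataFrame:
    """Per-barcode fitness and weight for every non-Time0 condition.

    All Time0 samples are summed into one reference column; samples sharing a
    condition are likewise summed (count-level pooling).
    """
    params = params or FitnessParams()
    counts = count_table.counts
    time0_cols = count_table.condition_columns(TIME0)
    if not time0_cols:
        raise ValueError("count table has no Time0 samples")
    n0 = counts[time0_cols].sum(axis=1).to_numpy(dtype=float)
    N0 = float(n0.sum())

    conditions = []
    for sample_id in counts.columns:
        cond = count_table.sample_sheet.condition_of(sample_id)
        if cond != TIME0 and cond not in conditions:
            conditions.append(cond)

    frames = []
    barcodes = counts.index.to_numpy()
    for cond in conditions:
        cols = count_table.condition_columns(cond)
        nc = counts[cols].sum(axis=1).to_numpy(dtype=float)
        Nc = float(nc.sum())
        f = strain_fitness(n0, N0, nc, Nc, params.pseudocount)
        w = strain_weight(n0, nc, params.weight_cap_counts)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "condition": cond,
                    "n0": n0.astype(int),
                    "nc": nc.astype(int),
                    "f": f,
                    "w": w,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def compute_gene_fitness(
    count_table: CountTable,
    pool: BarcodeMap,
    gene_replicons: dict[str, str],
    params: FitnessParams | None = None,
) -> GeneFitnessTable:
    """Full estimator: strain fitness -> weighted gene averages -> per-replicon
    normalization -> t-scores.

    ``gene_replicons`` maps every gene id to its replicon (genes without any
    contributing strain still get NaN rows).  Only strains whose insertion is
    centrally located in the gene and whose Time0 count meets the floor
    contribute.
    """
    params = params or FitnessParams()
    strains = compute_strain_fitness(count_table, pool, params)

    # explode barcode -> gene assignments (overlapping genes each count)
    assign = [
        (b, g) for b, genes in pool.gene_ids.items() for g in genes
    ]
    assign_df = pd.DataFrame(assign, columns=["barcode", "gene_id"])
    merged = strains.merge(assign_df, on="barcode", how="inner")
    merged = merged[merged["n0"] >= params.min_reads0]

    grouped = merged.groupby(["gene_id", "condition"], sort=True)
    agg = grouped.apply(
        lambda g: pd.Series(
            {
                "f": gene_fitness(g["f"].to_numpy(), g["w"].to_numpy()),
                "sum_w": g["w"].sum(),
                "n_strains": len(g),
                "reads0": g["n0"].sum(),
            }
        ),
        include_groups=False,
    ).reset_index()
    agg = agg[agg["n_strains"] >= params.min_strains]

    conditions = sorted(strains["condition"].unique())
    full_index = pd.MultiIndex.from_product(
        [sorted(gene_replicons), conditions], names=["gene_id", "condition"]
    )
    agg = (
        agg.set_index(["gene_id", "condition"])
        .reindex(full_index)
        .reset_index()
    )
    agg["replicon"] = agg["gene_id"].map(gene_replicons)
    agg["n_strains"] = agg["n_strains"].fillna(0).astype(int)
    agg["reads0"] = agg["reads0"].fillna(0).astype(int)

    agg = normalize_fitness(agg, value_col="f")
    agg["t"] = np.where(
        agg["n_strains"] > 0, t_score(agg["f"], agg["sum_w"], params.tau), np.nan
    )
    table = agg[GENE_COLUMNS].copy()
    return GeneFitnessTable(table=table, strains=strains)


def _format_floats(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        out[c] = out[c].map(lambda x: "NA" if pd.isna(x) else f"{x:.4f}")
    return out


def write_gene_fitness_tsv(gft: GeneFitnessTable, path: str | Path) -> None:
    _format_floats(gft.table, ["f", "t"]).to_csv(path, sep="\t", index=False)


def read_gene_fitness_tsv(path: str | Path) -> GeneFitnessTable:
    table = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene_id": str})
    return GeneFitnessTable(table=table)


def write_strain_fitness_tsv(strains: pd.DataFrame, path: str | Path) -> None:
    _format_floats(strains[STRAIN_COLUMNS], ["f", "w"]).to_csv(path, sep="\t", index=False)
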