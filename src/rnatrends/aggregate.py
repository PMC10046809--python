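"""Expression-matrix ingestion, CV filtering and per-age aggregation.

The dataset is a genes x samples matrix of normalized expression
("RNA production") joined to per-sample metadata (tissue, age in months,
sex). Analysis pools all tissues: for each age, a gene's production is its
mean over every valid (tissue, animal) sample of that age, and a gene
group's production is the mean of its genes' values, with a 95% CI from the
between-gene standard error. Cells (gene, tissue, age) whose replicate
animals disagree too much — coefficient of variation sd/mean >= 1 by
default — are masked out of the time-point analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneBlock, GeneCatalog

META_COLUMNS = ("sample", "tissue", "age_months", "sex")

__all__ = [
    "ExpressionDataset",
    "AgeSeries",
    "FilterReport",
    "CoverageRecord",
    "load_dataset",
    "write_dataset",
    "cv_filter",
    "group_age_series",
    "production_coverage",
    "counts_per_million",
]


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, **kw)


@dataclass
class ExpressionDataset:
    """Genes x samples matrix with sample metadata and a validity mask.

    ``matrix``: float DataFrame, gene symbols as index, sample ids as
    columns; missing values are NaN, never 0. ``samples``: indexed by sample
    id with columns tissue, age_months, sex. ``mask``: boolean DataFrame,
    genes x (tissue, age) MultiIndex columns; True = the cell's replicates
    are usable. Starts all-valid; :func:`cv_filter` rewrites it.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples.index.has_duplicates:
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise ValueError(f"duplicated sample id: {dup!r}")
        missing = [c for c in self.matrix.columns if c not in self.samples.index]
        if missing:
            raise ValueError(f"metadata missing matrix column(s): {missing[:5]}")
        extra = [s for s in self.samples.index if s not in self.matrix.columns]
        if extra:
            raise ValueError(f"metadata sample(s) absent from matrix: {extra[:5]}")
        ages = pd.to_numeric(self.samples["age_months"], errors="coerce")
        bad = self.samples.index[~(ages > 0)]
        if len(bad):
            raise ValueError(
                f"age_months not a positive number for sample {bad[0]!r}"
            )
        self.samples = self.samples.assign(age_months=ages.astype(float))
        if (self.matrix.to_numpy() < 0).any():
            raise ValueError("expression matrix contains negative values")
        if self.mask is None:
            self.mask = pd.DataFrame(
                True, index=self.matrix.index, columns=self._cell_index()
            )

    def _cell_index(self) -> pd.MultiIndex:
        cells = (
            self.samples[["tissue", "age_months"]]
            .drop_duplicates()
            .sort_values(["tissue", "age_months"])
        )
        return pd.MultiIndex.from_frame(cells)

    @property
    def ages(self) -> np.ndarray:
        """Sorted distinct ages (months) present in the metadata."""
        return np.sort(self.samples["age_months"].unique())

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    def samples_at(self, age: float, tissues: Sequence[str] | None = None) -> pd.DataFrame:
        sel = self.samples["age_months"] == age
        if tissues is not None:
            sel &= self.samples["tissue"].isin(tissues)
        return self.samples[sel]


@dataclass(frozen=True)
class AgeSeries:
    """Per-age aggregated mean production of a gene set (one table row per age)."""

    ages: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_genes: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ages", "mean", "ci_low", "ci_high", "n_genes"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        k = len(self.ages)
        if any(len(getattr(self, n)) != k for n in ("mean", "ci_low", "ci_high", "n_genes")):
            raise ValueError("AgeSeries fields must have equal length")
        if not np.all(np.diff(self.ages) > 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.ci_low > self.mean + 1e-9) or np.any(self.ci_high < self.mean - 1e-9):
            raise ValueError("CI bounds must bracket the mean")

    @classmethod
    def from_means(
        cls,
        ages: Sequence[float],
        means: Sequence[float],
        ci: Sequence[tuple[float, float]] | None = None,
        n_genes: Sequence[int] | None = None,
    ) -> "AgeSeries":
        """Build a series from published per-age means (CIs optional)."""
        means = np.asarray(means, float)
        if ci is None:
            lo = hi = means
        else:
            lo = np.array([c[0] for c in ci], float)
            hi = np.array([c[1] for c in ci], float)
        n = np.zeros(len(means), int) if n_genes is None else np.asarray(n_genes)
        return cls(np.asarray(ages, float), means, lo, hi, n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_genes": self.n_genes,
            }
        )

    def export(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FilterReport:
    """Outcome of CV filtering: per-age counts of invalidated cells."""

    threshold: float
    n_cells: int
    n_invalidated: int
    invalidated_per_age: dict[float, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "threshold": self.threshold,
                    "n_cells": self.n_cells,
                    "n_invalidated": self.n_invalidated,
                    "invalidated_per_age": {
                        str(a): int(c) for a, c in self.invalidated_per_age.items()
                    },
                },
                indent=2,
            )
        )


@dataclass(frozen=True)
class CoverageRecord:
    """Smallest top-expressed gene prefix reaching a cumulative production share."""

    fraction: float
    n_genes_covering: int
    share_of_genome: float
    n_hg_among_them: int


def load_dataset(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionDataset:
    """Read matrix + metadata files into an :class:`ExpressionDataset`.

    Matrix: TSV/CSV, first column gene symbols, remaining columns samples.
    Metadata: TSV/CSV with columns sample, tissue, age_months, sex.
    """
    matrix = _read_table(matrix_path, index_col=0)
    matrix = matrix.astype(float)
    meta = _read_table(metadata_path)
    missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks column(s): {missing_cols}")
    if meta["sample"].duplicated().any():
        dup = meta.loc[meta["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicated sample id: {dup!r}")
    meta = meta.set_index("sample")
    return ExpressionDataset(matrix=matrix, samples=meta)


def write_dataset(
    dataset: ExpressionDataset, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the dataset in the formats :func:`load_dataset` reads."""
    sep_m = "," if str(matrix_path).endswith(".csv") else "\t"
    dataset.matrix.to_csv(matrix_path, sep=sep_m, index_label="gene")
    sep_s = "," if str(metadata_path).endswith(".csv") else "\t"
    dataset.samples.reset_index(names="sample").to_csv(
        metadata_path, sep=sep_s, index=False
    )


def cv_filter(
    dataset: ExpressionDataset,
    threshold: float = 1.0,
    *,
    scope: str = "cell",
) -> tuple[ExpressionDataset, FilterReport]:
    """Mask out cells whose replicate animals vary too much.

    For each (gene, tissue, age) cell, CV = sample sd / mean over the
    replicate animals (n-1 denominator); the cell is invalid iff
    CV >= ``threshold`` or its mean is 0 (or all replicates missing).
    ``scope="global"`` instead computes one CV per gene over all samples and
    masks whole genes. Returns a new dataset plus a report.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    mask = pd.DataFrame(True, index=dataset.matrix.index, columns=dataset.mask.columns)
    M = dataset.matrix
    if scope == "global":
        mean = M.mean(axis=1)
        cv = M.std(axis=1, ddof=1) / mean
        bad_genes = (cv >= threshold) | (mean == 0) | mean.isna()
        mask.loc[bad_genes.to_numpy(), :] = False
    elif scope == "cell":
        for (tissue, age), cols in _cells(dataset).items():
            if len(cols) < 2:
                raise ValueError(
                    f"cell ({tissue}, {age}) has {len(cols)} replicate(s); need >= 2"
                )
            sub = M[cols]
            mean = sub.mean(axis=1)
            sd = sub.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                cv = sd / mean
            bad = (cv >= threshold) | (mean == 0) | mean.isna()
            mask.loc[bad.to_numpy(), (tissue, age)] = False
    else:
        raise ValueError(f"unknown scope: {scope!r}")

    inv = ~mask
    per_age: dict[float, int] = {}
    for (tissue, age) in mask.columns:
        per_age[age] = per_age.get(age, 0) + int(inv[(tissue, age)].sum())
    report = FilterReport(
        threshold=float(threshold),
        n_cells=int(mask.size),
        n_invalidated=int(inv.to_numpy().sum()),
        invalidated_per_age=per_age,
    )
    return replace(dataset, mask=mask), report


def _cells(dataset: ExpressionDataset) -> dict[tuple[str, float], list[str]]:
    cells: dict[tuple[str, float], list[str]] = {}
    for sample, row in dataset.samples.iterrows():
        cells.setdefault((row["tissue"], row["age_months"]), []).append(sample)
    return cells


def _resolve_genes(
    group, catalog: GeneCatalog | None, universe: pd.Index
) -> tuple[str, list[str]]:
    if isinstance(group, GeneBlock):
        return group.name, [g for g in group.genes if g in universe]
    if isinstance(group, str):
        if catalog is None:
            raise ValueError("a catalog is required to resolve a group label")
        return group, [g for g in catalog.group(group) if g in universe]
    genes = list(group)
    return "custom", [g for g in genes if g in universe]


def group_age_series(
    dataset: ExpressionDataset,
    group,
    *,
    catalog: GeneCatalog | None = None,
    tissues: Sequence[str] | None = None,
    gene_first: bool = True,
    z: float = 1.959963984540054,
) -> AgeSeries:
    """Aggregate a gene group into its per-age mean production series.

    ``group`` is a group label (``"HG"``/``"IntG"``, with ``catalog``), a
    :class:`~rnatrends.catalog.GeneBlock`, or an iterable of gene names.

    Default aggregation is gene-first: per age, each gene is averaged over
    all its valid (tissue, animal) samples, then the group mean and the 95%
    CI (mean ± z * sd / sqrt(n_genes), sd across the per-gene means, n-1
    denominator) are taken across genes. ``gene_first=False`` pools all
    valid gene x sample values directly instead.
    """
    name, genes = _resolve_genes(group, catalog, dataset.matrix.index)
    if not genes:
        raise ValueError("empty gene group after resolution/filtering")
    cells = _cells(dataset)
    sub = dataset.matrix.loc[genes]
    gmask = dataset.mask.loc[genes]

    ages = dataset.ages
    means, lo, hi, ngenes = [], [], [], []
    for age in ages:
        blocks, valids = [], []
        for (tissue, cell_age), cols in cells.items():
            if cell_age != age:
                continue
            if tissues is not None and tissue not in tissues:
                continue
            vals = sub[cols].to_numpy()
            valid = np.broadcast_to(
                gmask[(tissue, cell_age)].to_numpy()[:, None], vals.shape
            )
            blocks.append(vals)
            valids.append(valid & ~np.isnan(vals))
        if not blocks:
            raise ValueError(f"no samples at age {age}")
        V = np.hstack(blocks)
        ok = np.hstack(valids)
        counts = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            gene_means = np.where(
                counts > 0, np.where(ok, V, 0.0).sum(axis=1) / np.maximum(counts, 1), np.nan
            )
        if gene_first:
            vals = gene_means[~np.isnan(gene_means)]
        else:
            vals = V[ok]
        n = vals.size
        if n == 0:
            raise ValueError(f"no valid values for group {name!r} at age {age}")
        m = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        means.append(m)
        lo.append(m - z * se)
        hi.append(m + z * se)
        ngenes.append(int(np.sum(counts > 0)))
    return AgeSeries(
        ages=np.asarray(ages, float),
        mean=np.array(means),
        ci_low=np.array(lo),
        ci_high=np.array(hi),
        n_genes=np.array(ngenes),
    )


def production_coverage(
    dataset: ExpressionDataset,
    catalog: GeneCatalog,
    fraction: float = 0.8,
) -> CoverageRecord:
    """Size of the smallest top-producer prefix covering ``fraction`` of all
    RNA production, its share of the gene count, and its HG membership.

    Genes are ranked by total production over all samples, ties broken by
    descending production then lexicographic name.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    totals = dataset.matrix.sum(axis=1, skipna=True)
    grand = float(totals.sum())
    if grand <= 0:
        raise ValueError("all-zero expression matrix")
    order = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    cum = 0.0
    hg = set(catalog.hg_genes)
    n_hg = 0
    for i, (gene, tot) in enumerate(order, start=1):
        cum += tot
        if gene in hg:
            n_hg += 1
        if cum >= fraction * grand - 1e-12:
            return CoverageRecord(
                fraction=fraction,
                n_genes_covering=i,
                share_of_genome=i / len(order),
                n_hg_among_them=n_hg,
            )
    raise AssertionError("unreachable: cumulative share never reached fraction")


def counts_per_million(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional CPM transform for raw-count inputs (per-sample scaling to 1e6)."""
    return matrix.div(matrix.sum(axis=0), axis=1) * 1e6
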