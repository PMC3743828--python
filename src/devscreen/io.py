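"""Count-panel containers, TSV input/output, RPKM normalization, and strain profiles.

The pipeline starts from a raw count matrix (genes x samples) with sample
metadata, and a gene catalog carrying the uniquely mappable exon length used
for RPKM plus the annotation flags used downstream (developmental /
non-developmental labels, cross-species conservation of expression, and
cell-type enrichment labels).

All on-disk formats are plain TSV: tab-separated, '.' decimal, one header
row, ``gene_id`` as the first column of gene-indexed tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountPanel",
    "GeneCatalog",
    "ExpressionMatrix",
    "StrainProfileSet",
    "read_count_panel",
    "read_catalog",
    "write_count_panel",
    "compute_rpkm",
    "mean_profiles",
]

CELLTYPE_LABELS = ("prespore", "prestalk", "none")
SAMPLE_COLUMNS = ("strain", "category", "time_h", "replicate")


class PanelValidationError(ValueError):
    """Raised when an on-disk or in-memory panel violates its schema."""


@dataclass
class GeneCatalog:
    """Per-gene annotation: mappable exon length and label flags.

    ``table`` is indexed by gene_id with columns
    ``mappable_exon_length_nt`` (positive int), boolean ``dev_flag``,
    ``nondev_flag``, ``conserved_flag``, and ``celltype_label`` in
    {'prespore', 'prestalk', 'none'}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {
            "mappable_exon_length_nt",
            "dev_flag",
            "nondev_flag",
            "conserved_flag",
            "celltype_label",
        }
        missing = required - set(t.columns)
        if missing:
            raise PanelValidationError(f"catalog missing columns: {sorted(missing)}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][:5].tolist()
            raise PanelValidationError(f"duplicate gene ids in catalog: {dup}")
        lengths = t["mappable_exon_length_nt"]
        if (lengths <= 0).any():
            bad = t.index[lengths <= 0][:5].tolist()
            raise PanelValidationError(
                f"non-positive mappable exon length for genes: {bad}"
            )
        for col in ("dev_flag", "nondev_flag", "conserved_flag"):
            self.table[col] = t[col].astype(bool)
        both = t["dev_flag"] & t["nondev_flag"]
        if both.any():
            bad = t.index[both][:5].tolist()
            raise PanelValidationError(
                f"genes flagged both developmental and non-developmental: {bad}"
            )
        bad_label = ~t["celltype_label"].isin(CELLTYPE_LABELS)
        if bad_label.any():
            raise PanelValidationError(
                f"unknown celltype labels: {sorted(t.loc[bad_label, 'celltype_label'].unique())}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def n_genes(self) -> int:
        return len(self.table)

    @property
    def lengths_nt(self) -> pd.Series:
        return self.table["mappable_exon_length_nt"]

    def genes_with_flag(self, flag: str) -> frozenset:
        """Gene ids where boolean column ``flag`` is set."""
        return frozenset(self.table.index[self.table[flag]])

    @property
    def celltype_panel(self) -> frozenset:
        """Genes carrying a prespore or prestalk enrichment label."""
        return frozenset(
            self.table.index[self.table["celltype_label"] != "none"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class CountPanel:
    """Raw read counts per gene per sample, with sample metadata.

    ``counts``: genes x samples DataFrame of non-negative integers.
    ``samples``: DataFrame indexed by sample_id with columns strain,
    category, time_h, replicate; row order matches count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SAMPLE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise PanelValidationError(f"sample metadata missing columns: {sorted(missing)}")
        if self.counts.index.has_duplicates:
            raise PanelValidationError("duplicate gene ids in count matrix")
        if self.samples.index.has_duplicates:
            raise PanelValidationError("duplicate sample ids in metadata")
        if list(self.counts.columns) != list(self.samples.index):
            raise PanelValidationError(
                "count columns and sample metadata rows do not match"
            )
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise PanelValidationError("negative values in count matrix")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise PanelValidationError("count matrix contains non-integer values")
            self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_for(
        self,
        strain: str | None = None,
        category: str | None = None,
        time_h: float | None = None,
    ) -> list[str]:
        """Sample ids matching all the given metadata filters."""
        mask = pd.Series(True, index=self.samples.index)
        if strain is not None:
            mask &= self.samples["strain"] == strain
        if category is not None:
            mask &= self.samples["category"] == category
        if time_h is not None:
            mask &= self.samples["time_h"] == time_h
        return list(self.samples.index[mask])

    @property
    def wildtype_strain(self) -> str:
        wt = self.samples.loc[self.samples["category"] == "wildtype", "strain"].unique()
        if len(wt) != 1:
            raise PanelValidationError(
                f"expected exactly one wildtype strain, found {list(wt)}"
            )
        return str(wt[0])


@dataclass
class ExpressionMatrix:
    """RPKM-normalized abundance with the same shape as its source panel."""

    rpkm: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.rpkm.columns) != list(self.samples.index):
            raise PanelValidationError("rpkm columns and sample metadata do not match")
        if (self.rpkm.to_numpy() < 0).any():
            raise PanelValidationError("negative RPKM values")


@dataclass
class StrainProfileSet:
    """Mean expression per gene for every (strain, time point) cell.

    ``profiles`` is genes x (strain, time_h) with a two-level column
    MultiIndex; all vectors share the gene order of the source matrix.
    ``n_replicates`` records how many replicates each mean averaged.
    """

    profiles: pd.DataFrame
    n_replicates: pd.Series

    @property
    def strain_ids(self) -> list[str]:
        return list(dict.fromkeys(self.profiles.columns.get_level_values(0)))

    @property
    def time_points_h(self) -> list[float]:
        times = sorted(set(self.profiles.columns.get_level_values(1)))
        return [float(t) for t in times]

    @property
    def gene_ids(self) -> pd.Index:
        return self.profiles.index

    def vector(self, strain: str, time_h: float) -> np.ndarray:
        """Mean expression vector of one strain at one time point."""
        return self.profiles[(strain, time_h)].to_numpy(dtype=float)

    def concatenated(self, strain: str) -> np.ndarray:
        """Gene vectors of one strain concatenated over all time points."""
        return np.concatenate(
            [self.vector(strain, t) for t in self.time_points_h]
        )

    def gene_profile(self, gene_id: str, strain: str) -> pd.Series:
        """One gene's mean abundance across time for one strain."""
        vals = {t: self.profiles.at[gene_id, (strain, t)] for t in self.time_points_h}
        return pd.Series(vals, name=gene_id)


# ---------------------------------------------------------------------------
# readers / writers


def read_catalog(path: str | Path) -> GeneCatalog:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return GeneCatalog(table)


def read_count_panel(
    counts_path: str | Path,
    meta_path: str | Path,
    catalog_path: str | Path,
) -> tuple[CountPanel, GeneCatalog]:
    """Load and cross-validate a count matrix, sample metadata, and catalog.

    Every gene in the count matrix must be present in the catalog;
    a missing gene is an error that names the gene.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    catalog = read_catalog(catalog_path)
    panel = CountPanel(counts=counts, samples=meta)
    absent = panel.gene_ids.difference(catalog.gene_ids)
    if len(absent):
        raise PanelValidationError(
            f"genes missing from catalog: {list(absent[:10])}"
            + ("..." if len(absent) > 10 else "")
        )
    return panel, catalog


def write_count_panel(
    panel: CountPanel, counts_path: str | Path, meta_path: str | Path
) -> None:
    panel.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    panel.samples.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# normalization


def compute_rpkm(panel: CountPanel, catalog: GeneCatalog) -> ExpressionMatrix:
    """Reads per kilobase of mappable exon per million uniquely mapped reads.

    For gene g in sample s::

        rpkm[g, s] = counts[g, s] / (length_kb(g) * total(s) / 1e6)

    where ``total(s)`` is the column sum of raw counts for sample s (the
    number of uniquely mapped reads represented in the matrix) and
    ``length_kb`` the uniquely mappable exon length in kilobases.
    """
    missing = panel.gene_ids.difference(catalog.gene_ids)
    if len(missing):
        raise PanelValidationError(f"genes missing from catalog: {list(missing[:10])}")
    totals = panel.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise PanelValidationError(f"samples with zero total reads: {list(zero)}")
    length_kb = catalog.lengths_nt.reindex(panel.gene_ids).to_numpy(dtype=float) / 1e3
    per_million = totals.to_numpy(dtype=float) / 1e6
    rpkm = panel.counts.to_numpy(dtype=float) / (
        length_kb[:, None] * per_million[None, :]
    )
    return ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm, index=panel.gene_ids, columns=panel.counts.columns),
        samples=panel.samples.copy(),
    )


def mean_profiles(expr: ExpressionMatrix) -> StrainProfileSet:
    """Average RPKM over replicates for each (strain, time point) cell.

    Means are unweighted arithmetic means. Every strain must be measured
    at every time point present in the metadata; a missing cell is an
    error listing the (strain, time) pairs.
    """
    meta = expr.samples
    strains = list(dict.fromkeys(meta["strain"]))
    times = sorted(meta["time_h"].unique())
    missing = [
        (s, t)
        for s, t in itertools.product(strains, times)
        if not ((meta["strain"] == s) & (meta["time_h"] == t)).any()
    ]
    if missing:
        raise PanelValidationError(f"missing (strain, time) cells: {missing}")

    cols: dict[tuple[str, float], np.ndarray] = {}
    n_reps: dict[tuple[str, float], int] = {}
    for s in strains:
        for t in times:
            ids = meta.index[(meta["strain"] == s) & (meta["time_h"] == t)]
            cols[(s, float(t))] = expr.rpkm[ids].mean(axis=1).to_numpy()
            n_reps[(s, float(t))] = len(ids)
    profiles = pd.DataFrame(cols, index=expr.rpkm.index)
    profiles.columns = pd.MultiIndex.from_tuples(
        profiles.columns, names=["strain", "time_h"]
    )
    return StrainProfileSet(
        profiles=profiles,
        n_replicates=pd.Series(n_reps, name="n_replicates"),
    )
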