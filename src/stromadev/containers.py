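"""Shared in-memory containers for the stromal-cell multi-omics pipeline.

Conventions used throughout the package:

* count matrices are features x cells (or features x samples), dense
  ``numpy`` integer arrays — problem sizes here (thousands of cells, a few
  thousand features) make dense storage the simplest correct choice;
* genomic coordinates are 0-based, half-open ``[start, end)``;
* metadata tables are :class:`pandas.DataFrame` objects keyed 1:1 to the
  matrix axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "MethylomeTable", "IntervalSet"]


@dataclass
class CountMatrix:
    """Integer feature x cell (or feature x sample) count container.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_features, n_cells)``.
    feature_meta
        One row per feature; the index holds feature names. Optional columns
        used downstream: ``chrom``, ``tss``, ``strand``, ``biotype``,
        ``length``.
    cell_meta
        One row per cell/sample; the index holds cell identifiers. Optional
        columns: ``library``, ``timepoint``, ``condition``.
    """

    counts: np.ndarray
    feature_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if len(self.feature_meta) != self.counts.shape[0]:
            raise ValueError("feature_meta must have one row per feature")
        if len(self.cell_meta) != self.counts.shape[1]:
            raise ValueError("cell_meta must have one row per cell")

    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def feature_names(self) -> pd.Index:
        return self.feature_meta.index

    @property
    def cell_names(self) -> pd.Index:
        return self.cell_meta.index

    # ------------------------------------------------------------------
    def n_genes_detected(self) -> np.ndarray:
        """Number of features with raw count > 0, per cell."""
        return np.count_nonzero(self.counts, axis=0)

    def n_umi(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def pct_of_prefix(self, prefix: str) -> np.ndarray:
        """Percent of each cell's raw counts on features whose name starts
        with ``prefix`` (e.g. ``"mt-"`` for mitochondrial genes)."""
        mask = self.feature_names.str.startswith(prefix)
        total = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts[mask.values if hasattr(mask, "values") else mask].sum(axis=0) / total
        return np.where(total > 0, pct, 0.0)

    def pct_of_regex(self, pattern: str) -> np.ndarray:
        """Percent of raw counts on features matching ``pattern`` (used for
        ribosomal-protein genes, default pattern ``"^Rp[sl]"``)."""
        mask = self.feature_names.str.match(pattern).values
        total = self.counts.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts[mask].sum(axis=0) / total
        return np.where(total > 0, pct, 0.0)

    # ------------------------------------------------------------------
    def subset_cells(self, mask_or_names) -> "CountMatrix":
        idx = self._axis_indexer(mask_or_names, self.cell_names)
        return CountMatrix(self.counts[:, idx], self.feature_meta.copy(), self.cell_meta.iloc[idx].copy())

    def subset_features(self, mask_or_names) -> "CountMatrix":
        idx = self._axis_indexer(mask_or_names, self.feature_names)
        return CountMatrix(self.counts[idx], self.feature_meta.iloc[idx].copy(), self.cell_meta.copy())

    @staticmethod
    def _axis_indexer(sel, names: pd.Index) -> np.ndarray:
        sel = np.asarray(sel)
        if sel.dtype == bool:
            return np.flatnonzero(sel)
        if np.issubdtype(sel.dtype, np.integer):
            return sel
        return names.get_indexer(sel)

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells x genes)."""
        import anndata as ad

        return ad.AnnData(
            X=self.counts.T.astype(np.float32),
            obs=self.cell_meta.copy(),
            var=self.feature_meta.copy(),
        )


@dataclass
class MethylomeTable:
    """Per-CpG methylated/coverage read counts for a set of samples.

    ``df`` holds columns ``chrom``, ``pos`` plus, per sample ``s``,
    ``M_<s>`` (methylated reads) and ``C_<s>`` (coverage). ``groups`` maps
    sample name -> condition label.
    """

    df: pd.DataFrame
    samples: list[str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.samples:
            m, c = self.df[f"M_{s}"].to_numpy(), self.df[f"C_{s}"].to_numpy()
            if np.any(m < 0) or np.any(m > c):
                raise ValueError(f"sample {s}: need 0 <= M <= C")
        for chrom, sub in self.df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: CpG positions must be strictly increasing")

    @property
    def n_cpg(self) -> int:
        return len(self.df)

    def coverage(self) -> np.ndarray:
        """Coverage matrix, CpGs x samples."""
        return self.df[[f"C_{s}" for s in self.samples]].to_numpy()

    def methylated(self) -> np.ndarray:
        return self.df[[f"M_{s}" for s in self.samples]].to_numpy()

    def levels(self) -> np.ndarray:
        """Raw methylation fractions M/C (NaN where coverage is zero)."""
        c = self.coverage().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(c > 0, self.methylated() / c, np.nan)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == condition]


@dataclass
class IntervalSet:
    """Sorted set of genomic intervals (0-based, half-open)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"]))

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("name", "score", "strand"):
            if col not in df.columns:
                df[col] = {"name": ".", "score": 0.0, "strand": "."}[col]
        if len(df):
            if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
                raise ValueError("intervals require start < end")
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
            df = df.drop_duplicates(subset=["chrom", "start", "end", "name", "strand"]).reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: shares >= 1 bp with any interval in
        ``other``."""
        out = np.zeros(len(self.df), dtype=bool)
        if not len(other):
            return out
        by_chrom = {c: sub for c, sub in other.df.groupby("chrom")}
        for i, row in enumerate(self.df.itertuples(index=False)):
            sub = by_chrom.get(row.chrom)
            if sub is None:
                continue
            out[i] = bool(np.any((sub["start"].to_numpy() < row.end) & (sub["end"].to_numpy() > row.start)))
        return out
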