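"""Core data containers: genotype matrices, labelled distance matrices, rasters.

Genotypes are biallelic SNP dosages coded 0/1/2 with ``-1`` for missing.
Distance matrices are labelled, symmetric, zero-diagonal. Rasters are plain
row-major grids with an affine cell geometry and a nodata mask (ESRI ASCII
grid semantics: the origin is the lower-left corner, row 0 is the top row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

REQUIRED_META = ("site_id", "ecotope", "year", "x", "y")

ECOTOPES = ("domestic", "wild")


class LandgenError(Exception):
    """Base error for this package."""


class ConfigurationError(LandgenError):
    pass


class AnalysisError(LandgenError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x loci biallelic genotype matrix with per-sample metadata.

    Parameters
    ----------
    genotypes
        int array, shape (n_samples, n_loci), values in {0, 1, 2, -1}.
    sample_ids, locus_ids
        Unique string labels for rows and columns.
    meta
        DataFrame indexed by sample_id with columns
        site_id, ecotope ("domestic"/"wild"), year, x, y (projected metres).
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(m) for m in self.locus_ids]
        n, p = self.genotypes.shape
        if n != len(self.sample_ids) or p != len(self.locus_ids):
            raise ConfigurationError("genotype matrix shape does not match labels")
        if len(set(self.sample_ids)) != n or len(set(self.locus_ids)) != p:
            raise ConfigurationError("sample/locus identifiers must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ConfigurationError("genotype codes must be 0/1/2 or -1 (missing)")
        missing_meta = [c for c in REQUIRED_META if c not in self.meta.columns]
        if missing_meta:
            raise ConfigurationError(f"metadata lacks columns: {missing_meta}")
        self.meta = self.meta.loc[self.sample_ids]
        if not np.isfinite(self.meta[["x", "y"]].to_numpy(dtype=float)).all():
            raise ConfigurationError("sample coordinates must be finite")

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.genotypes != MISSING

    def groups(self, by: str = "site_id") -> dict[str, np.ndarray]:
        """Row indices per group label.

        `by` is a metadata column, or "site_ecotope" for (site, ecotope)
        composite groups labelled "SITE:ecotope".
        """
        if by == "site_ecotope":
            labels = (
                self.meta["site_id"].astype(str) + ":" + self.meta["ecotope"].astype(str)
            ).to_numpy()
        else:
            labels = self.meta[by].astype(str).to_numpy()
        out: dict[str, np.ndarray] = {}
        for lab in pd.unique(labels):
            out[lab] = np.flatnonzero(labels == lab)
        return out

    def subset(
        self,
        samples: Sequence[int] | None = None,
        loci: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        rows = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        cols = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        return GenotypeMatrix(
            self.genotypes[np.ix_(rows, cols)],
            [self.sample_ids[i] for i in rows],
            [self.locus_ids[j] for j in cols],
            self.meta.iloc[rows],
        )

    def allele_stats(self, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (n_called_individuals, alt_allele_count) for given rows."""
        g = self.genotypes[rows]
        called = g != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        return n_called, alt


def group_allele_freqs(
    gm: GenotypeMatrix, grouping: str = "site_id"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(freq, n_called) DataFrames, groups x loci; NaN where a group has no calls."""
    groups = gm.groups(grouping)
    freqs = {}
    ns = {}
    for lab, rows in groups.items():
        n_called, alt = gm.allele_stats(rows)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[lab] = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        ns[lab] = n_called
    freq = pd.DataFrame(freqs, index=gm.locus_ids).T
    n = pd.DataFrame(ns, index=gm.locus_ids).T
    return freq, n


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ConfigurationError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ConfigurationError("distance matrix must be symmetric")
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Lower-triangle values in (row-major) pair order."""
        iu = np.tril_indices(self.n, k=-1)
        return self.values[iu]

    def pairs(self) -> list[tuple[str, str]]:
        return [
            (self.labels[i], self.labels[j])
            for i in range(1, self.n)
            for j in range(i)
        ]

    def submatrix(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = [str(x) for x in labels]
        idx = [self.labels.index(x) for x in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)], self.kind)

    def align(self, other: "DistanceMatrix") -> "DistanceMatrix":
        """Return `other` reordered to this matrix's labels."""
        return other.submatrix(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class RasterSurface:
    """Georeferenced grid. `origin` is the (x, y) of the lower-left corner."""

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    kind: str = "continuous"
    classes: list[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ConfigurationError("raster must be a 2-D grid")
        if self.cell_size <= 0:
            raise ConfigurationError("cell size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ConfigurationError("nodata mask shape mismatch")
        if not np.isfinite(self.values[~self.nodata_mask]).all():
            raise ConfigurationError("raster has non-finite values outside nodata")
        if self.kind == "categorical":
            vals = np.unique(self.values[~self.nodata_mask])
            if self.classes is None:
                self.classes = [int(v) for v in vals]
            elif not set(vals.astype(int)) <= set(self.classes):
                raise ConfigurationError("categorical raster has undeclared classes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrows = self.values.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrows - row - 0.5) * self.cell_size
        return x, y

    def nearest_cell(self, x: float, y: float) -> tuple[int, int]:
        nrows, ncols = self.values.shape
        col = int(np.clip((x - self.origin[0]) / self.cell_size, 0, ncols - 1))
        row = int(np.clip(nrows - (y - self.origin[1]) / self.cell_size, 0, nrows - 1))
        return row, col

    def copy_with(self, values: np.ndarray, kind: str | None = None) -> "RasterSurface":
        return RasterSurface(
            values,
            self.cell_size,
            self.origin,
            self.nodata_mask.copy(),
            kind or self.kind,
        )
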