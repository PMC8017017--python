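"""Matrix-shaped cohort container: sites × samples count matrices plus the sheet.

Per-sample tables are long and ragged (each species covers only the sites its
genome retains); downstream statistics want aligned arrays. ``CohortDataset``
outer-joins samples onto the union of sites; absent or unsequenced sites carry
zero coverage and are excluded from any per-site fit by their zero weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MethylationTable, validate_sample_sheet

SITE_KEY = ["chrom", "pos", "strand", "context"]


@dataclass
class CohortDataset:
    """Aligned per-site counts across a cohort.

    sites    : DataFrame [chrom, pos, strand, context], sorted by position
    coverage : int array (n_sites, n_samples)
    meth     : int array (n_sites, n_samples)
    sheet    : sample sheet, rows aligned with the matrix columns
    """

    sites: pd.DataFrame
    coverage: np.ndarray = field(repr=False)
    meth: np.ndarray = field(repr=False)
    sheet: pd.DataFrame

    def __post_init__(self) -> None:
        assert self.coverage.shape == self.meth.shape
        assert self.coverage.shape == (len(self.sites), len(self.sheet))

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def sample_ids(self) -> pd.Series:
        return self.sheet["sample_id"]

    def subset_sites(self, mask) -> "CohortDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CohortDataset(self.sites.iloc[idx].reset_index(drop=True),
                             self.coverage[idx], self.meth[idx],
                             self.sheet)

    def subset_samples(self, sample_ids) -> "CohortDataset":
        order = {s: i for i, s in enumerate(self.sheet["sample_id"])}
        idx = np.array([order[s] for s in sample_ids], dtype=int)
        return CohortDataset(self.sites, self.coverage[:, idx],
                             self.meth[:, idx],
                             self.sheet.iloc[idx].reset_index(drop=True))

    def group_labels(self, by=("species", "cell_type")) -> pd.Series:
        return self.sheet[list(by)].agg("_".join, axis=1)

    def group_means(self, by=("species", "cell_type")) -> pd.DataFrame:
        """Coverage-weighted fractional methylation per site per group."""
        labels = self.group_labels(by)
        out = {}
        for g in labels.unique():
            cols = np.flatnonzero((labels == g).to_numpy())
            tot = self.coverage[:, cols].sum(axis=1).astype(float)
            met = self.meth[:, cols].sum(axis=1).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[g] = np.where(tot > 0, met / np.maximum(tot, 1), np.nan)
        return pd.DataFrame(out, index=self.sites.index)


def build_cohort(tables: list[MethylationTable], sheet: pd.DataFrame,
                 context: str | None = None) -> CohortDataset:
    """Align per-sample tables into one sites × samples dataset."""
    sheet = validate_sample_sheet(sheet)
    by_id = {t.sample_id: t for t in tables}
    missing = [s for s in sheet["sample_id"] if s not in by_id]
    if missing:
        raise ValueError(f"sheet samples without tables: {missing}")

    frames = []
    for sid in sheet["sample_id"]:
        df = by_id[sid].data
        if context is not None:
            df = df[df["context"] == context]
        frames.append(df.set_index(SITE_KEY)[["total_reads", "meth_reads"]])
    union = frames[0].index
    for f in frames[1:]:
        union = union.union(f.index)
    sites = union.to_frame(index=False).sort_values(["chrom", "pos", "strand"])
    sites = sites.reset_index(drop=True)
    key = pd.MultiIndex.from_frame(sites[SITE_KEY])

    n_sites, n_samples = len(sites), len(sheet)
    coverage = np.zeros((n_sites, n_samples), dtype=np.int64)
    meth = np.zeros((n_sites, n_samples), dtype=np.int64)
    for j, f in enumerate(frames):
        aligned = f.reindex(key, fill_value=0)
        coverage[:, j] = aligned["total_reads"].to_numpy()
        meth[:, j] = aligned["meth_reads"].to_numpy()
    return CohortDataset(sites, coverage, meth, sheet)
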