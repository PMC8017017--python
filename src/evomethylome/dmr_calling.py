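"""Merge significant sites into differentially methylated regions (DMRs).

A DMR is a maximal run of same-sign significant sites (q below threshold)
with inter-site gaps no larger than ``max_gap``, spanning at least 50 bp and
containing at least four significant positions. areaStat is the sum of the
Wald statistics over *all* tested member sites in the span; regions whose
mean statistic |areaStat| / n_sites falls below t* — the smallest |Wald|
among sites passing the FDR threshold in the same family — are excluded as
weak. CG species/cell-type DMRs additionally face methylation-difference
cutoffs (>10 / >15 percentage points); CH DMRs must cover more than ten
cytosines and show >10 points of regional difference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import CohortDataset

DMR_COLUMNS = ["chrom", "start", "end", "name", "context", "term",
               "n_sites", "n_significant", "areaStat", "direction",
               "group_means"]


def _empty() -> pd.DataFrame:
    return pd.DataFrame(columns=DMR_COLUMNS)


def _runs(positions: np.ndarray, signs: np.ndarray, max_gap: int):
    """Maximal runs of consecutive sites with gap <= max_gap and equal sign."""
    if len(positions) == 0:
        return
    start = 0
    for i in range(1, len(positions) + 1):
        if (i == len(positions)
                or positions[i] - positions[i - 1] > max_gap
                or signs[i] != signs[i - 1]):
            yield start, i
            start = i


def _regional_group_means(dataset: CohortDataset | None, chrom: str,
                          start: int, end: int, context: str) -> dict:
    if dataset is None:
        return {}
    s = dataset.sites
    inside = ((s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] < end)
              & (s["context"] == context)).to_numpy()
    if not inside.any():
        return {}
    sub = dataset.subset_sites(inside)
    labels = sub.group_labels()
    out = {}
    for g in labels.unique():
        cols = np.flatnonzero((labels == g).to_numpy())
        tot = sub.coverage[:, cols].sum()
        out[g] = float(sub.meth[:, cols].sum() / tot) if tot > 0 else np.nan
    return out


def area_stat_threshold(site_results: pd.DataFrame,
                        q_threshold: float = 0.05) -> float:
    """t*: the smallest |Wald| among sites significant at the FDR threshold."""
    sig = site_results[(site_results["tested"])
                       & (site_results["q"] < q_threshold)]
    if len(sig) == 0:
        return np.inf
    return float(np.abs(sig["stat"]).min())


def call_dmrs_cg(site_results: pd.DataFrame, *, q_threshold: float = 0.05,
                 min_len: int = 50, min_sig: int = 4, max_gap: int = 100,
                 dataset: CohortDataset | None = None,
                 apply_area_filter: bool = True,
                 name_prefix: str = "dmr") -> pd.DataFrame:
    """Call CG DMRs from the per-site results of one term.

    ``site_results`` must hold a single term (chrom, pos, stat, q, tested).
    ``dataset`` (the cohort the tests came from) supplies coverage-weighted
    per-group regional means; without it the means column is empty and the
    difference cutoffs cannot be applied downstream.
    """
    res = site_results[site_results["tested"]].copy()
    if res.empty:
        return _empty()
    terms = res["term"].unique()
    if len(terms) != 1:
        raise ValueError(f"expected one term, got {list(terms)}")
    term = terms[0]
    contexts = res["context"].unique()
    context = contexts[0] if len(contexts) == 1 else "CG"
    res = res.sort_values(["chrom", "pos"]).reset_index(drop=True)
    t_star = (area_stat_threshold(site_results, q_threshold)
              if apply_area_filter else 0.0)

    rows = []
    k = 0
    for chrom, grp in res.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        stat = grp["stat"].to_numpy()
        q = grp["q"].to_numpy()
        sig_mask = q < q_threshold
        sig_pos = pos[sig_mask]
        sig_sign = np.sign(stat[sig_mask])
        for a, b in _runs(sig_pos, sig_sign, max_gap):
            n_sig = b - a
            start, last = int(sig_pos[a]), int(sig_pos[b - 1])
            end = last + 1
            if n_sig < min_sig or end - start < min_len:
                continue
            member = (pos >= start) & (pos < end)
            n_sites = int(member.sum())
            area = float(stat[member].sum())
            if apply_area_filter and abs(area) / n_sites < t_star:
                continue
            k += 1
            rows.append({
                "chrom": chrom, "start": start, "end": end,
                "name": f"{name_prefix}_{term}_{k:04d}",
                "context": context, "term": term,
                "n_sites": n_sites, "n_significant": n_sig,
                "areaStat": area,
                "direction": "+" if sig_sign[a] > 0 else "-",
                "group_means": _regional_group_means(dataset, chrom, start,
                                                     end, context),
            })
    if not rows:
        return _empty()
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


def _mean_diff(means: dict, keys_a, keys_b) -> float:
    a = [means[k] for k in keys_a if k in means and np.isfinite(means[k])]
    b = [means[k] for k in keys_b if k in means and np.isfinite(means[k])]
    if not a or not b:
        return np.nan
    return float(np.mean(a) - np.mean(b))


def species_mean_diff(means: dict, a: str = "human",
                      b: str = "chimpanzee") -> float:
    return _mean_diff(means, [f"{a}_NeuN", f"{a}_OLIG2"],
                      [f"{b}_NeuN", f"{b}_OLIG2"])


def celltype_mean_diff(means: dict) -> float:
    keys = list(means)
    neun = [k for k in keys if k.endswith("_NeuN")]
    olig = [k for k in keys if k.endswith("_OLIG2")]
    return _mean_diff(means, neun, olig)


def apply_difference_cutoffs(dmrs: pd.DataFrame, species_min: float = 0.10,
                             celltype_min: float = 0.15) -> pd.DataFrame:
    """Keep species DMRs with >10-point human−chimp difference and cell-type
    DMRs with >15-point NeuN−OLIG2 difference (strict inequalities);
    interaction DMRs face the species cutoff within their stronger cell type.
    """
    if dmrs.empty:
        return dmrs.copy()
    keep = np.ones(len(dmrs), dtype=bool)
    for i, row in enumerate(dmrs.itertuples()):
        means = row.group_means
        if row.term == "species":
            keep[i] = abs(species_mean_diff(means)) > species_min
        elif row.term == "cell_type":
            keep[i] = abs(celltype_mean_diff(means)) > celltype_min
        elif row.term == "interaction":
            diffs = [abs(_mean_diff(means, [f"human_{ct}"],
                                    [f"chimpanzee_{ct}"]))
                     for ct in ("NeuN", "OLIG2")]
            diffs = [d for d in diffs if np.isfinite(d)]
            keep[i] = bool(diffs) and max(diffs) > species_min
    return dmrs[keep].reset_index(drop=True)


def _overlaps_any(dmrs: pd.DataFrame, others: pd.DataFrame) -> np.ndarray:
    """Boolean: which rows of ``dmrs`` overlap >= 1 bp of any row of ``others``."""
    hit = np.zeros(len(dmrs), dtype=bool)
    if dmrs.empty or others.empty:
        return hit
    for chrom, grp in others.groupby("chrom"):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        m = (dmrs["chrom"] == chrom).to_numpy()
        for i in np.flatnonzero(m):
            s, e = dmrs["start"].iat[i], dmrs["end"].iat[i]
            if ((starts < e) & (ends > s)).any():
                hit[i] = True
    return hit


def remove_redundant(celltype_dmrs: pd.DataFrame, species_dmrs: pd.DataFrame,
                     interaction_dmrs: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cell-type and species DMRs that overlap an interaction DMR.

    Cell-type-specific species changes subsume the simpler calls; the
    interaction set itself is returned unchanged by the caller.
    """
    ct = celltype_dmrs[~_overlaps_any(celltype_dmrs, interaction_dmrs)]
    sp = species_dmrs[~_overlaps_any(species_dmrs, interaction_dmrs)]
    return ct.reset_index(drop=True), sp.reset_index(drop=True)


def call_dmrs_ch(site_results: pd.DataFrame, *, q_threshold: float = 0.05,
                 min_len: int = 50, min_sig: int = 4, max_gap: int = 100,
                 min_cytosines: int = 11, min_diff: float = 0.10,
                 dataset: CohortDataset | None = None,
                 pair: tuple[str, str] = ("human", "chimpanzee"),
                 apply_area_filter: bool = True,
                 name_prefix: str = "chdmr") -> pd.DataFrame:
    """CH DMRs from pairwise per-site results: the CG rules plus a strict
    >10-cytosine floor and a >10-point regional mean difference."""
    dmrs = call_dmrs_cg(site_results, q_threshold=q_threshold,
                        min_len=min_len, min_sig=min_sig, max_gap=max_gap,
                        dataset=dataset, apply_area_filter=apply_area_filter,
                        name_prefix=name_prefix)
    if dmrs.empty:
        return dmrs
    keep = dmrs["n_sites"] >= min_cytosines
    if dataset is not None:
        a, b = pair
        diffs = np.array([
            abs(_mean_diff(m, [k for k in m if k.startswith(a + "_")],
                           [k for k in m if k.startswith(b + "_")]))
            for m in dmrs["group_means"]])
        keep &= diffs > min_diff
    return dmrs[keep].reset_index(drop=True)
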