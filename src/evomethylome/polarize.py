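"""Outgroup polarization: which lineage did a methylation change arise on?

A human–chimpanzee DMR says two lineages differ but not which one moved.
Adding the macaque outgroup orients the change: if human differs from both
chimpanzee and macaque while chimpanzee matches macaque, the change is
human-derived (and vice versa). Region-level significance comes from a beta
regression (logit mean link) of per-individual regional mean methylation on
species plus the usual covariates, with Wald contrasts for the three species
pairs and BH correction across DMRs.

Classification vocabulary (``EvoClass``): conserved_celltype,
human_specific_hypo/hyper, chimp_specific_hypo/hyper,
celltype_restricted_species_change (with lineage/cell-type tags), and
unclassified. Every DMR receives exactly one label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.othermod.betareg import BetaModel

from .dataset import CohortDataset
from .diffmeth import AGE_LEVELS, adjust_fdr

EVO_CLASSES = (
    "conserved_celltype",
    "human_specific_hypo", "human_specific_hyper",
    "chimp_specific_hypo", "chimp_specific_hyper",
    "celltype_restricted_species_change",
    "unclassified",
)


# ---------------------------------------------------------------------------
# outgroup mapping
# ---------------------------------------------------------------------------

@dataclass
class OutgroupMapping:
    ok: bool
    alignment_coverage: float
    n_outgroup_cg: int
    reason: str = ""


def map_to_outgroup(dmr, orthology_map, outgroup_cg_positions: pd.DataFrame,
                    min_coverage: float = 0.5, min_cg: int = 4,
                    outgroup: str = "macaque") -> OutgroupMapping:
    """Locate a DMR in the outgroup; verdict 'unclassified' when the region
    aligns poorly (< min_coverage) or retains fewer than ``min_cg`` CGs.

    ``outgroup_cg_positions``: frame [chrom, pos] of CG sites present in the
    outgroup genome (e.g. sites with outgroup read data).
    """
    chrom, start, end = dmr["chrom"], int(dmr["start"]), int(dmr["end"])
    if chrom not in set(orthology_map.blocks["chrom"]):
        return OutgroupMapping(False, 0.0, 0, "chrom_absent")
    cov = orthology_map.alignment_coverage(outgroup, chrom, start, end)
    ocg = outgroup_cg_positions
    n_cg = int(((ocg["chrom"] == chrom) & (ocg["pos"] >= start)
                & (ocg["pos"] < end)).sum())
    if cov < min_coverage:
        return OutgroupMapping(False, cov, n_cg, "low_alignment")
    if n_cg < min_cg:
        return OutgroupMapping(False, cov, n_cg, "few_outgroup_cg")
    return OutgroupMapping(True, cov, n_cg)


# ---------------------------------------------------------------------------
# region-level beta regression
# ---------------------------------------------------------------------------

def squeeze_unit(y: np.ndarray, n: int | None = None) -> np.ndarray:
    """Pull exact 0/1 proportions into the open interval: (y(n−1)+0.5)/n."""
    y = np.asarray(y, dtype=float)
    if n is None:
        n = len(y)
    return (y * (n - 1) + 0.5) / n


def _beta_design(sheet: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """Intercept + species dummies + sex/age/conversion covariates."""
    n = len(sheet)
    cols = [np.ones(n)]
    names = ["intercept"]
    species_cols = {}
    levels = sorted(sheet["species"].unique())
    for lv in levels[1:]:
        species_cols[lv] = len(names)
        cols.append((sheet["species"] == lv).to_numpy(float))
        names.append(f"species[{lv}]")
    if sheet["sex"].nunique() > 1:
        cols.append((sheet["sex"] == "M").to_numpy(float))
        names.append("sex[M]")
    present = [a for a in AGE_LEVELS if a in set(sheet["age_class"])]
    for lv in present[1:]:
        cols.append((sheet["age_class"] == lv).to_numpy(float))
        names.append(f"age[{lv}]")
    cr = sheet["conversion_rate"].to_numpy(float)
    if np.ptp(cr) > 0:
        cols.append(cr - cr.mean())
        names.append("conversion_rate")
    return np.column_stack(cols), names, species_cols


CONTRASTS = (("human", "chimpanzee"), ("human", "macaque"),
             ("chimpanzee", "macaque"))


def fit_region_beta(regional_means: np.ndarray, sheet: pd.DataFrame) -> dict:
    """Beta regression of per-individual regional means on species + covariates.

    Returns Wald p-values and logit-scale estimates for the three species
    contrasts, keyed ``p_human_vs_chimpanzee`` etc., plus ``converged``.
    Species with no finite observations make the affected contrasts NaN.
    """
    y = np.asarray(regional_means, dtype=float)
    keep = np.isfinite(y)
    y, sub = y[keep], sheet[keep].reset_index(drop=True)
    out = {f"p_{a}_vs_{b}": np.nan for a, b in CONTRASTS}
    out.update({f"est_{a}_vs_{b}": np.nan for a, b in CONTRASTS})
    out["converged"] = False
    if len(y) < 6 or sub["species"].nunique() < 2:
        return out
    X, names, species_cols = _beta_design(sub)
    yy = np.clip(squeeze_unit(y, len(y)), 1e-6, 1 - 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = BetaModel(yy, X).fit(disp=False, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        return out
    k = res.params.shape[0]  # mean params + precision
    levels = sorted(sub["species"].unique())
    ref = levels[0]

    def coef_vec(sp):  # logit-mean effect of sp relative to ref
        v = np.zeros(k)
        if sp != ref:
            v[species_cols[sp]] = 1.0
        return v

    for a, b in CONTRASTS:
        if a not in levels or b not in levels:
            continue
        c = coef_vec(a) - coef_vec(b)
        if not c.any():
            continue
        tt = res.t_test(c)
        out[f"p_{a}_vs_{b}"] = float(np.squeeze(tt.pvalue))
        out[f"est_{a}_vs_{b}"] = float(np.squeeze(tt.effect))
    out["converged"] = converged
    return out


def regional_individual_means(dataset: CohortDataset, chrom, start, end,
                              context: str) -> np.ndarray:
    """Coverage-weighted regional mean per individual; NaN when uncovered."""
    s = dataset.sites
    inside = ((s["chrom"] == chrom) & (s["pos"] >= start) & (s["pos"] < end)
              & (s["context"] == context)).to_numpy()
    if not inside.any():
        return np.full(len(dataset.sheet), np.nan)
    tot = dataset.coverage[inside].sum(axis=0).astype(float)
    met = dataset.meth[inside].sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, met / np.maximum(tot, 1), np.nan)


# ---------------------------------------------------------------------------
# classification rules
# ---------------------------------------------------------------------------

def classify_celltype_conservation(focal_direction: float,
                                   outgroup_neun_mean: float,
                                   outgroup_olig2_mean: float,
                                   min_diff: float = 0.15) -> str:
    """Conserved cell-type DMR iff the outgroup shows a same-direction
    NeuN−OLIG2 difference larger than ``min_diff`` (strict)."""
    if not (np.isfinite(outgroup_neun_mean) and np.isfinite(outgroup_olig2_mean)):
        return "unclassified"
    diff = outgroup_neun_mean - outgroup_olig2_mean
    if abs(diff) > min_diff and np.sign(diff) == np.sign(focal_direction) != 0:
        return "conserved_celltype"
    return "unclassified"


def _one_celltype_species_call(stats: dict, q_threshold: float,
                               min_diff: float,
                               criterion3_as_ratio: bool) -> str | None:
    """Species-specificity verdict from one cell type's region statistics.

    ``stats``: q_hc, q_hm, q_cm (BH-adjusted contrast p-values) and
    mean_human, mean_chimp, mean_macaque (pooled regional fractions).
    Returns e.g. "human_specific_hypo" or None.
    """
    h, c, m = stats["mean_human"], stats["mean_chimp"], stats["mean_macaque"]
    if not all(np.isfinite(v) for v in (h, c, m)):
        return None
    hm, cm = abs(h - m), abs(c - m)

    def crit3(d_focal, d_other):
        if criterion3_as_ratio:
            tot = d_focal + d_other
            return tot > 0 and d_focal / tot > 0.05
        return d_focal > min_diff

    # human-derived: human differs from both, change larger on human branch
    if (stats["q_hc"] < q_threshold and stats["q_hm"] < q_threshold
            and hm > cm and crit3(hm, cm)):
        if h < c and h < m:
            return "human_specific_hypo"
        if h > c and h > m:
            return "human_specific_hyper"
    # chimp-derived, mirrored
    if (stats["q_hc"] < q_threshold and stats["q_cm"] < q_threshold
            and cm > hm and crit3(cm, hm)):
        if c < h and c < m:
            return "chimp_specific_hypo"
        if c > h and c > m:
            return "chimp_specific_hyper"
    return None


def classify_species_dmr(per_celltype_stats: dict, q_threshold: float = 0.05,
                         min_diff: float = 0.05,
                         criterion3_as_ratio: bool = False) -> str:
    """Species-DMR classification; both cell types must agree (criterion 4).

    ``per_celltype_stats``: {"NeuN": stats, "OLIG2": stats} as accepted by
    :func:`_one_celltype_species_call`. A DMR is human- (or chimpanzee-)
    specific hypo/hyper only when every cell type yields that same verdict;
    anything else is unclassified.
    """
    calls = [_one_celltype_species_call(s, q_threshold, min_diff,
                                        criterion3_as_ratio)
             for s in per_celltype_stats.values()]
    if calls and all(c is not None and c == calls[0] for c in calls):
        return calls[0]
    return "unclassified"


def classify_interaction_dmr(stats: dict, cell_type: str,
                             q_threshold: float = 0.05,
                             min_diff: float = 0.05,
                             criterion3_as_ratio: bool = False) -> dict:
    """Cell-type-restricted species change: the species criteria applied
    within the single affected cell type."""
    call = _one_celltype_species_call(stats, q_threshold, min_diff,
                                      criterion3_as_ratio)
    if call is None:
        return {"evo_class": "unclassified", "lineage": None,
                "direction": None, "cell_type": cell_type}
    lineage = "human" if call.startswith("human") else "chimpanzee"
    return {"evo_class": "celltype_restricted_species_change",
            "lineage": lineage,
            "direction": "hyper" if call.endswith("hyper") else "hypo",
            "cell_type": cell_type}


def classify_ch_site(q_hc: float, q_hm: float, q_cm: float,
                     mean_h: float, mean_c: float, mean_m: float,
                     q_threshold: float = 0.05,
                     min_diff: float = 0.10) -> tuple[str, str] | None:
    """Parsimonious per-site CH call.

    A site is specific to one species iff the two comparisons involving it
    are significant, the third is not, and its fractional methylation differs
    from *both* other species by more than ``min_diff`` in the same
    direction. Returns (species, "hyper"|"hypo") or None.
    """
    rules = (
        ("human", q_hc < q_threshold and q_hm < q_threshold
         and q_cm >= q_threshold, mean_h, (mean_c, mean_m)),
        ("chimpanzee", q_hc < q_threshold and q_cm < q_threshold
         and q_hm >= q_threshold, mean_c, (mean_h, mean_m)),
        ("macaque", q_hm < q_threshold and q_cm < q_threshold
         and q_hc >= q_threshold, mean_m, (mean_h, mean_c)),
    )
    for sp, sig, own, others in rules:
        if not sig:
            continue
        d = [own - o for o in others]
        if all(v > min_diff for v in d):
            return sp, "hyper"
        if all(v < -min_diff for v in d):
            return sp, "hypo"
    return None


def classify_ch_dmr(mean_h: float, mean_c: float, mean_m: float,
                    min_diff: float = 0.05) -> str:
    """CH DMR polarization from regional means against the outgroup:
    human-specific iff |H−M| > min_diff (strict) and |H−M| > |C−M|;
    chimpanzee mirrored; otherwise unclassified."""
    if not all(np.isfinite(v) for v in (mean_h, mean_c, mean_m)):
        return "unclassified"
    hm, cm = abs(mean_h - mean_m), abs(mean_c - mean_m)
    if hm > min_diff and hm > cm:
        return ("human_specific_hyper" if mean_h > mean_m
                else "human_specific_hypo")
    if cm > min_diff and cm > hm:
        return ("chimp_specific_hyper" if mean_c > mean_m
                else "chimp_specific_hypo")
    return "unclassified"


def shared_ch_dmrs(human_macaque_dmrs: pd.DataFrame,
                   chimp_macaque_dmrs: pd.DataFrame) -> pd.DataFrame:
    """Regions derived on both ape lineages: overlap of the human–macaque and
    chimpanzee–macaque CH DMR sets (>= 1 bp)."""
    rows = []
    for chrom, grp in human_macaque_dmrs.groupby("chrom"):
        other = chimp_macaque_dmrs[chimp_macaque_dmrs["chrom"] == chrom]
        if other.empty:
            continue
        os_, oe = other["start"].to_numpy(), other["end"].to_numpy()
        for r in grp.itertuples():
            if ((os_ < r.end) & (oe > r.start)).any():
                rows.append({"chrom": chrom, "start": r.start, "end": r.end})
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# DMR-set polarization driver
# ---------------------------------------------------------------------------

def polarize_cg_dmrs(dmrs: pd.DataFrame, dataset: CohortDataset,
                     orthology_map, *, q_threshold: float = 0.05,
                     min_coverage: float = 0.5, min_cg: int = 4,
                     conserved_min_diff: float = 0.15,
                     species_min_diff: float = 0.05,
                     criterion3_as_ratio: bool = False) -> pd.DataFrame:
    """Classify a mixed CG DMR set (cell_type/species/interaction terms).

    ``dataset`` must contain all three species. Beta-regression contrast
    p-values are BH-corrected per (contrast, cell type) family across the
    species/interaction DMRs. Adds columns: evo_class, lineage, direction
    (hyper/hypo, derived lineage vs outgroup), alignment_coverage,
    n_outgroup_cg, reason.
    """
    if dmrs.empty:
        out = dmrs.copy()
        for c in ("evo_class", "lineage", "alignment_coverage",
                  "n_outgroup_cg", "reason"):
            out[c] = pd.Series(dtype=object)
        return out

    sheet = dataset.sheet
    mac_sites = dataset.sites[
        (dataset.sites["context"] == "CG")
        & (dataset.coverage[:, (sheet["species"] == "macaque").to_numpy()]
           .sum(axis=1) > 0)][["chrom", "pos"]]

    mappings = [map_to_outgroup(row, orthology_map, mac_sites,
                                min_coverage, min_cg)
                for _, row in dmrs.iterrows()]

    # region stats per DMR per cell type (only where needed)
    ct_subsets = {ct: dataset.subset_samples(
        sheet.loc[sheet["cell_type"] == ct, "sample_id"])
        for ct in ("NeuN", "OLIG2")}
    needs_beta = [i for i, (m, t) in enumerate(zip(mappings, dmrs["term"]))
                  if m.ok and t in ("species", "interaction")]
    raw: dict[tuple[int, str], dict] = {}
    for i in needs_beta:
        row = dmrs.iloc[i]
        for ct, sub in ct_subsets.items():
            y = regional_individual_means(sub, row["chrom"], row["start"],
                                          row["end"], "CG")
            st = fit_region_beta(y, sub.sheet)
            labels = sub.sheet["species"].to_numpy()
            for sp, key in (("human", "mean_human"),
                            ("chimpanzee", "mean_chimp"),
                            ("macaque", "mean_macaque")):
                vals = y[(labels == sp) & np.isfinite(y)]
                st[key] = float(vals.mean()) if len(vals) else np.nan
            raw[(i, ct)] = st

    # BH per contrast per cell type across DMRs
    for ct in ("NeuN", "OLIG2"):
        keys = [k for k in raw if k[1] == ct]
        for a, b in CONTRASTS:
            ps = np.array([raw[k][f"p_{a}_vs_{b}"] for k in keys], dtype=float)
            qs = adjust_fdr(np.clip(ps, 0, 1)) if len(ps) else ps
            for k, q in zip(keys, qs):
                raw[k][f"q_{a}_vs_{b}"] = q

    def _stats(i, ct):
        st = raw[(i, ct)]
        return {"q_hc": st.get("q_human_vs_chimpanzee", np.nan),
                "q_hm": st.get("q_human_vs_macaque", np.nan),
                "q_cm": st.get("q_chimpanzee_vs_macaque", np.nan),
                "mean_human": st["mean_human"],
                "mean_chimp": st["mean_chimp"],
                "mean_macaque": st["mean_macaque"],
                "converged": st["converged"]}

    out_rows = []
    for i, (row, mapping) in enumerate(zip(dmrs.itertuples(), mappings)):
        rec = {"evo_class": "unclassified", "lineage": None,
               "direction_class": None,
               "alignment_coverage": mapping.alignment_coverage,
               "n_outgroup_cg": mapping.n_outgroup_cg,
               "reason": mapping.reason}
        if mapping.ok:
            if row.term == "cell_type":
                means = row.group_means or {}
                foc = np.nanmean([means.get("human_NeuN", np.nan),
                                  means.get("chimpanzee_NeuN", np.nan)]) - \
                    np.nanmean([means.get("human_OLIG2", np.nan),
                                means.get("chimpanzee_OLIG2", np.nan)])
                mac = {ct: regional_individual_means(
                    ct_subsets[ct].subset_samples(
                        ct_subsets[ct].sheet.loc[
                            ct_subsets[ct].sheet["species"] == "macaque",
                            "sample_id"]),
                    row.chrom, row.start, row.end, "CG")
                    for ct in ("NeuN", "OLIG2")}
                mac_means = {ct: (float(np.nanmean(v)) if np.isfinite(v).any()
                                  else np.nan) for ct, v in mac.items()}
                rec["evo_class"] = classify_celltype_conservation(
                    foc, mac_means["NeuN"], mac_means["OLIG2"],
                    conserved_min_diff)
            elif row.term == "species":
                st = {ct: _stats(i, ct) for ct in ("NeuN", "OLIG2")}
                if all(s["converged"] for s in st.values()):
                    rec["evo_class"] = classify_species_dmr(
                        st, q_threshold, species_min_diff, criterion3_as_ratio)
                if rec["evo_class"] != "unclassified":
                    rec["lineage"] = ("human" if "human" in rec["evo_class"]
                                      else "chimpanzee")
                    rec["direction_class"] = ("hyper" if
                                              rec["evo_class"].endswith("hyper")
                                              else "hypo")
            elif row.term == "interaction":
                means = row.group_means or {}
                diffs = {ct: abs(means.get(f"human_{ct}", np.nan)
                                 - means.get(f"chimpanzee_{ct}", np.nan))
                         for ct in ("NeuN", "OLIG2")}
                ct = max(diffs, key=lambda c: (diffs[c]
                                               if np.isfinite(diffs[c])
                                               else -1))
                st = _stats(i, ct)
                if st["converged"]:
                    call = classify_interaction_dmr(
                        st, ct, q_threshold, species_min_diff,
                        criterion3_as_ratio)
                    rec["evo_class"] = call["evo_class"]
                    rec["lineage"] = call["lineage"]
                    rec["direction_class"] = call["direction"]
                    rec["restricted_cell_type"] = call["cell_type"]
        out_rows.append(rec)

    out = dmrs.reset_index(drop=True).copy()
    extra = pd.DataFrame(out_rows)
    for c in extra.columns:
        out[c] = extra[c]
    return out
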