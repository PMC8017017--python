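"""DMR → gene assignment, gene-body methylation, and CH DMR-gene categories.

A DMR supports a gene when it overlaps the gene body extended by 3 kb on
each side (strand-agnostic). Gene-body methylation is the coverage-weighted
fraction Σ meth / Σ total over the gene's cytosines of the requested
context. A gene becomes e.g. a human-hyper CH DMR gene only when it carries
at least one human-specific hyper CH DMR, its human gene-body methylation
exceeds both chimpanzee's and macaque's, and the human–macaque difference
dominates the chimpanzee–macaque difference; the gene-body criteria also
arbitrate genes that would otherwise fall into several categories.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import CohortDataset

# Neuron-subtype marker symbols orthologous across the three species
# (excitatory vs inhibitory cortical neuron markers).
EXCITATORY_MARKERS = (
    "SATB2", "TYRO3", "ARPP21", "SLC17A7", "TBR1", "CAMK2A", "ITPKA",
    "ABI2", "RASAL1", "FOXP1", "SLC8A2", "SV2B", "PTPRD", "LTK",
    "LINGO1", "NRGN", "NPAS4", "KCNH3", "BAIAP2", "ARPP19",
)
INHIBITORY_MARKERS = (
    "ERBB4", "GAD1", "SLC6A1", "CCNE1", "EPHB6", "KCNAB3", "LPP",
    "TBC1D9", "DUSP10", "KCNMB2", "UBASH3B", "MAF", "ANK1",
)


def marker_gene_sets() -> dict[str, tuple[str, ...]]:
    return {"excitatory": EXCITATORY_MARKERS, "inhibitory": INHIBITORY_MARKERS}


def assign_dmr_genes(dmrs: pd.DataFrame, genes: pd.DataFrame,
                     flank: int = 3000) -> pd.DataFrame:
    """Assign each DMR to every gene whose flank-extended body it overlaps.

    Returns long-form rows (gene_id, dmr name, interval columns); a DMR near
    two genes yields two rows. Strand is ignored — the window extends both
    sides of every gene.
    """
    rows = []
    for chrom, grp in genes.groupby("chrom"):
        d = dmrs[dmrs["chrom"] == chrom]
        if d.empty:
            continue
        ds, de = d["start"].to_numpy(), d["end"].to_numpy()
        names = (d["name"] if "name" in d.columns
                 else pd.Series([f"dmr_{i}" for i in d.index], index=d.index))
        for g in grp.itertuples():
            lo, hi = g.start - flank, g.end + flank
            hit = (ds < hi) & (de > lo)
            for j in np.flatnonzero(hit):
                rows.append({"gene_id": g.gene_id, "dmr": names.iloc[j],
                             "chrom": chrom,
                             "dmr_start": int(ds[j]), "dmr_end": int(de[j]),
                             "gene_start": g.start, "gene_end": g.end})
    return pd.DataFrame(rows, columns=["gene_id", "dmr", "chrom",
                                       "dmr_start", "dmr_end",
                                       "gene_start", "gene_end"])


def gene_body_methylation(dataset: CohortDataset, gene,
                          context: str = "CH",
                          by: str = "group") -> dict:
    """Coverage-weighted gene-body methylation.

    ``by='group'`` pools samples per (species, cell_type); ``by='sample'``
    returns one value per sample. Genes without a covered cytosine return an
    empty dict (excluded upstream).
    """
    s = dataset.sites
    inside = ((s["chrom"] == gene["chrom"]) & (s["pos"] >= gene["start"])
              & (s["pos"] < gene["end"]) & (s["context"] == context)).to_numpy()
    if not inside.any():
        return {}
    cov = dataset.coverage[inside]
    met = dataset.meth[inside]
    out = {}
    if by == "sample":
        tot = cov.sum(axis=0)
        for j, sid in enumerate(dataset.sheet["sample_id"]):
            if tot[j] > 0:
                out[sid] = float(met[:, j].sum() / tot[j])
        return out
    labels = dataset.group_labels()
    for g in labels.unique():
        colsel = np.flatnonzero((labels == g).to_numpy())
        tot = cov[:, colsel].sum()
        if tot > 0:
            out[g] = float(met[:, colsel].sum() / tot)
    return out


def _dominance(h: float, c: float, m: float, lineage: str,
               direction: str) -> tuple[bool, float]:
    """Check the gene-body ordering + difference-dominance clause; returns
    (passes, focal-vs-outgroup absolute difference) for tie-breaking."""
    if not all(np.isfinite(v) for v in (h, c, m)):
        return False, 0.0
    own, other = (h, c) if lineage == "human" else (c, h)
    hm = abs(own - m)
    dom = hm > abs(other - m)
    if direction == "hyper":
        ordered = own > other and own > m
    else:
        ordered = own < other and own < m
    return ordered and dom, hm


def classify_ch_dmr_gene(gene_body_means: dict,
                         member_dmr_classes: list[str]) -> str | None:
    """Resolve one gene's CH DMR-gene category.

    ``gene_body_means``: per-species neuronal gene-body CH methylation, keys
    human/chimpanzee/macaque. ``member_dmr_classes``: EvoClass labels of the
    gene's assigned CH DMRs (e.g. "human_specific_hyper"). A category needs
    a member DMR of that class *and* the gene-body ordering/dominance
    clauses; when several categories qualify, the larger focal-vs-outgroup
    gene-body difference wins (redundancy removal).
    """
    h = gene_body_means.get("human", np.nan)
    c = gene_body_means.get("chimpanzee", np.nan)
    m = gene_body_means.get("macaque", np.nan)
    candidates = []
    for cls in set(member_dmr_classes):
        if cls not in ("human_specific_hyper", "human_specific_hypo",
                       "chimp_specific_hyper", "chimp_specific_hypo"):
            continue
        lineage = "human" if cls.startswith("human") else "chimpanzee"
        direction = "hyper" if cls.endswith("hyper") else "hypo"
        ok, margin = _dominance(h, c, m, lineage, direction)
        if ok:
            short = "human" if lineage == "human" else "chimp"
            candidates.append((margin, f"{short}_{direction}_ch_dmr_gene"))
    if not candidates:
        return None
    candidates.sort(reverse=True)
    return candidates[0][1]


def ch_dmr_gene_table(dmrs: pd.DataFrame, genes: pd.DataFrame,
                      neuron_dataset: CohortDataset,
                      flank: int = 3000) -> pd.DataFrame:
    """Gene-level table: assignment, per-species neuronal gene-body CH
    methylation, and the resolved category (one per gene, or none)."""
    assign = assign_dmr_genes(dmrs, genes, flank)
    if assign.empty:
        return pd.DataFrame(columns=["gene_id", "category", "n_dmrs",
                                     "mean_human", "mean_chimp", "mean_macaque"])
    cls_by_dmr = dict(zip(dmrs["name"], dmrs["evo_class"])) \
        if "evo_class" in dmrs.columns else {}
    rows = []
    for gene_id, grp in assign.groupby("gene_id"):
        g = genes[genes["gene_id"] == gene_id].iloc[0]
        body = gene_body_methylation(neuron_dataset, g, context="CH")
        by_species = {}
        for sp in ("human", "chimpanzee", "macaque"):
            vals = [v for k, v in body.items() if k.startswith(sp + "_")]
            by_species[sp] = float(np.mean(vals)) if vals else np.nan
        classes = [cls_by_dmr.get(d, "unclassified") for d in grp["dmr"]]
        cat = classify_ch_dmr_gene(by_species, classes)
        rows.append({"gene_id": gene_id, "category": cat,
                     "n_dmrs": len(grp),
                     "mean_human": by_species["human"],
                     "mean_chimp": by_species["chimpanzee"],
                     "mean_macaque": by_species["macaque"]})
    return pd.DataFrame(rows)
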