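"""Readers/writers for the on-disk formats, variant masking and CG strand collapsing.

All coordinates are 0-based half-open, both on disk and in memory (BED
convention). A CG dinucleotide is reported once, on the + strand, at the
position of the + strand cytosine; CH cytosines stay strand-specific.

Formats
-------
methylation table : TSV  chrom  pos  strand  context  total_reads  meth_reads
sample sheet      : TSV  sample_id  species  cell_type  sex  age_class  conversion_rate
orthology map     : TSV  species  chrom  start  end      (alignable blocks, focal coords)
variant mask      : TSV  chrom  pos  ref  alt  strand
gene annotation   : TSV/BED  chrom  start  end  gene_id  score  strand
DMR output        : BED6+ with extra columns (see :func:`write_dmr_bed`)
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_CONTEXTS = ("CG", "CH")
VALID_STRANDS = ("+", "-")
SPECIES = ("human", "chimpanzee", "macaque")
CELL_TYPES = ("NeuN", "OLIG2")

METH_COLUMNS = ["chrom", "pos", "strand", "context", "total_reads", "meth_reads"]


class FormatError(ValueError):
    """Malformed on-disk input (carries the offending line where known)."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

@dataclass
class MethylationTable:
    """Per-cytosine counts for one sample.

    ``data`` has columns chrom, pos, strand, context, total_reads, meth_reads,
    one row per cytosine site; 0 <= meth_reads <= total_reads everywhere and
    no duplicated (chrom, pos, strand) keys.
    """

    sample_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = validate_methylation_frame(self.data)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fractional_methylation(self) -> pd.Series:
        return self.data["meth_reads"] / self.data["total_reads"].replace(0, np.nan)


def validate_methylation_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns: {missing}")
    df = df[METH_COLUMNS].copy()
    if (df["pos"] < 0).any():
        raise ValidationError("negative position")
    bad = ~df["strand"].isin(VALID_STRANDS)
    if bad.any():
        raise ValidationError(f"invalid strand at row {int(np.flatnonzero(bad)[0])}")
    # CHG/CHH dialects are pooled into CH (H = A, C, T)
    df["context"] = df["context"].replace({"CHG": "CH", "CHH": "CH"})
    bad = ~df["context"].isin(VALID_CONTEXTS)
    if bad.any():
        raise ValidationError(f"invalid context at row {int(np.flatnonzero(bad)[0])}")
    if (df["meth_reads"] > df["total_reads"]).any():
        i = int(np.flatnonzero(df["meth_reads"] > df["total_reads"])[0])
        raise ValidationError(f"meth_reads > total_reads at row {i}")
    if (df["meth_reads"] < 0).any() or (df["total_reads"] < 0).any():
        raise ValidationError("negative read counts")
    if df.duplicated(["chrom", "pos", "strand"]).any():
        raise ValidationError("duplicate (chrom, pos, strand) records")
    return df.reset_index(drop=True)


def read_methylation_table(path, sample_id: str | None = None,
                           context_filter: str | None = None,
                           header: bool = True) -> MethylationTable:
    """Read one per-sample TSV of cytosine counts.

    ``context_filter`` restricts to "CG" or "CH"; ``header=False`` reads a
    headerless dialect with the canonical column order.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(str(path)))[0]
    try:
        df = pd.read_csv(path, sep="\t", header=0 if header else None,
                         names=None if header else METH_COLUMNS,
                         dtype={"chrom": str},
                         comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for col in ("pos", "total_reads", "meth_reads"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        except (ValueError, KeyError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric value in column {col!r}") from exc
    if context_filter is not None:
        if context_filter not in VALID_CONTEXTS:
            raise ValueError(f"context_filter must be one of {VALID_CONTEXTS}")
        df["context"] = df["context"].replace({"CHG": "CH", "CHH": "CH"})
        df = df[df["context"] == context_filter]
    return MethylationTable(sample_id=sample_id, data=df)


def write_methylation_table(table: MethylationTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SHEET_COLUMNS = ["sample_id", "species", "cell_type", "sex", "age_class",
                 "conversion_rate"]


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SHEET_COLUMNS].copy()
    if sheet["sample_id"].duplicated().any():
        raise ValidationError("duplicated sample_id in sheet")
    if not sheet["species"].isin(SPECIES).all():
        raise ValidationError(f"species must be one of {SPECIES}")
    if not sheet["cell_type"].isin(CELL_TYPES).all():
        raise ValidationError(f"cell_type must be one of {CELL_TYPES}")
    cr = sheet["conversion_rate"].astype(float)
    if ((cr < 0) | (cr > 1)).any():
        raise ValidationError("conversion_rate outside [0, 1]")
    sheet["conversion_rate"] = cr
    return sheet.reset_index(drop=True)


def read_sample_sheet(path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t", comment="#"))


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orthology map
# ---------------------------------------------------------------------------

class OrthologyMap:
    """One-to-one alignable blocks of each non-focal genome, in focal coordinates.

    Synthetic and real maps are both reduced to, per species, a set of disjoint
    half-open intervals within which sites are orthologous. Alignment coverage
    of a query interval is the alignable fraction of its bases.
    """

    def __init__(self, blocks: pd.DataFrame):
        missing = [c for c in ("species", "chrom", "start", "end")
                   if c not in blocks.columns]
        if missing:
            raise FormatError(f"orthology map missing columns: {missing}")
        blocks = blocks[["species", "chrom", "start", "end"]].copy()
        if (blocks["start"] >= blocks["end"]).any():
            raise ValidationError("orthology block with start >= end")
        blocks = blocks.sort_values(["species", "chrom", "start"]).reset_index(drop=True)
        # one-to-one only: overlapping blocks within a species would be
        # one-to-many mappings
        for (_, _), grp in blocks.groupby(["species", "chrom"]):
            if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
                raise ValidationError("overlapping orthology blocks (non 1:1 mapping)")
        self.blocks = blocks

    def species_blocks(self, species: str, chrom: str) -> np.ndarray:
        g = self.blocks[(self.blocks["species"] == species)
                        & (self.blocks["chrom"] == chrom)]
        return g[["start", "end"]].to_numpy(dtype=np.int64)

    def alignment_coverage(self, species: str, chrom: str, start: int, end: int) -> float:
        """Alignable fraction of [start, end) for ``species``."""
        if end <= start:
            raise ValueError("empty interval")
        blocks = self.species_blocks(species, chrom)
        if len(blocks) == 0:
            return 0.0
        lo = np.maximum(blocks[:, 0], start)
        hi = np.minimum(blocks[:, 1], end)
        return float(np.maximum(hi - lo, 0).sum()) / (end - start)

    def sites_present(self, species: str, chrom, pos) -> np.ndarray:
        """Boolean mask: which (chrom, pos) sites fall in an alignable block."""
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(chrom):
            blocks = self.species_blocks(species, str(c))
            m = chrom == c
            if len(blocks) == 0:
                continue
            idx = np.searchsorted(blocks[:, 0], pos[m], side="right") - 1
            ok = idx >= 0
            ok[ok] = pos[m][ok] < blocks[idx[ok], 1]
            out[m] = ok
        return out


def read_orthology_map(path) -> OrthologyMap:
    return OrthologyMap(pd.read_csv(path, sep="\t", comment="#",
                                    dtype={"chrom": str}))


def write_orthology_map(omap: OrthologyMap, path) -> None:
    omap.blocks.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation / variant mask
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]


def read_gene_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if "gene_id" not in df.columns:  # headerless BED6
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=GENE_COLUMNS, dtype={0: str})
    if (df["start"] >= df["end"]).any():
        raise ValidationError("gene with start >= end")
    return df[GENE_COLUMNS].reset_index(drop=True)


def write_gene_annotation(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


MASK_COLUMNS = ["chrom", "pos", "ref", "alt", "strand"]


def read_variant_mask(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in MASK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant mask missing columns: {missing}")
    df = df[MASK_COLUMNS].copy()
    if not (df["ref"].str.len().eq(1).all() and df["alt"].str.len().eq(1).all()):
        raise ValidationError("variant mask alleles must be single nucleotides")
    return df.reset_index(drop=True)


def write_variant_mask(mask: pd.DataFrame, path) -> None:
    mask[MASK_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variant masking
# ---------------------------------------------------------------------------

def mask_polymorphic_sites(table: MethylationTable, mask: pd.DataFrame) -> MethylationTable:
    """Remove cytosines whose methylation call a C>T / G>A polymorphism would fake.

    Bisulfite sequencing cannot distinguish an unmethylated (converted)
    cytosine from a genomic thymine, so a C>T variant on the + strand, or its
    G>A complement on the − strand, is removed. For collapsed CG records (one
    + strand record per dinucleotide at the C position) a hit on either
    strand's cytosine — C>T at ``pos`` or G>A at ``pos + 1`` — removes the
    whole unit.
    """
    df = table.data
    if len(mask) == 0 or len(df) == 0:
        return MethylationTable(table.sample_id, df.copy())
    fwd = mask[(mask["strand"] == "+") & (mask["ref"] == "C") & (mask["alt"] == "T")]
    rev = mask[(mask["strand"] == "-") & (mask["ref"] == "G") & (mask["alt"] == "A")]
    fwd_keys = set(zip(fwd["chrom"], fwd["pos"]))
    rev_keys = set(zip(rev["chrom"], rev["pos"]))

    chrom = df["chrom"].to_numpy()
    pos = df["pos"].to_numpy()
    strand = df["strand"].to_numpy()
    is_cg = (df["context"] == "CG").to_numpy()

    drop = np.zeros(len(df), dtype=bool)
    for i in range(len(df)):
        key = (chrom[i], pos[i])
        if is_cg[i] and strand[i] == "+":
            # collapsed CG unit: + strand C at pos, − strand C (G on +) at pos+1
            drop[i] = key in fwd_keys or (chrom[i], pos[i] + 1) in rev_keys
        elif strand[i] == "+":
            drop[i] = key in fwd_keys
        else:
            drop[i] = key in rev_keys
    return MethylationTable(table.sample_id, df[~drop].copy())


def collapse_cg_strands(table: MethylationTable) -> MethylationTable:
    """Pool the two cytosines of each symmetric CG dinucleotide onto the + strand.

    A − strand CG cytosine at position p belongs to the dinucleotide whose +
    strand cytosine sits at p − 1. Read counts are summed; CH records pass
    through untouched. Total and methylated read sums are conserved.
    """
    df = table.data
    cg = df[df["context"] == "CG"].copy()
    ch = df[df["context"] != "CG"]
    if len(cg) == 0:
        return MethylationTable(table.sample_id, df.copy())
    unit_pos = cg["pos"].where(cg["strand"] == "+", cg["pos"] - 1)
    cg["pos"] = unit_pos
    pooled = (cg.groupby(["chrom", "pos"], as_index=False)[["total_reads", "meth_reads"]]
              .sum())
    pooled["strand"] = "+"
    pooled["context"] = "CG"
    out = pd.concat([pooled[METH_COLUMNS], ch[METH_COLUMNS]], ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)
    return MethylationTable(table.sample_id, out)


# ---------------------------------------------------------------------------
# DMR BED6+ output
# ---------------------------------------------------------------------------

DMR_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                   "context", "term", "n_sites", "areaStat", "group_means"]


def _pack_means(means: dict) -> str:
    return ";".join(f"{k}={v:.6g}" for k, v in sorted(means.items()))


def _unpack_means(s: str) -> dict:
    if not isinstance(s, str) or s in ("", "."):
        return {}
    return {k: float(v) for k, v in (kv.split("=") for kv in s.split(";"))}


def write_dmr_bed(dmrs: pd.DataFrame, path, natural_sort: bool = False) -> None:
    """Write DMRs as BED6+ (11 columns).

    Columns 1–6 are standard BED (name = DMR id, score = n_significant,
    strand = effect direction); columns 7–11 are context, tested term, member
    site count, areaStat, and packed per-group mean methylation
    (``group=value;...``). A ``#`` header comment documents the layout.
    """
    cols = ["chrom", "start", "end"]
    for c in cols:
        if len(dmrs) and c not in dmrs.columns:
            raise FormatError(f"DMR frame missing column {c!r}")
    out = pd.DataFrame()
    if len(dmrs):
        chroms = dmrs["chrom"].astype(str)
        if not natural_sort:
            try:
                sorted(chroms.unique())
            except TypeError as exc:  # pragma: no cover - str always sortable
                raise FormatError("unsortable chrom names") from exc
        out["chrom"] = chroms
        out["start"] = dmrs["start"].astype(int)
        out["end"] = dmrs["end"].astype(int)
        out["name"] = dmrs.get("name", pd.Series(
            [f"dmr_{i}" for i in range(len(dmrs))], index=dmrs.index))
        out["score"] = dmrs.get("n_significant", 0)
        out["strand"] = dmrs.get("direction", ".")
        out["context"] = dmrs.get("context", ".")
        out["term"] = dmrs.get("term", ".")
        out["n_sites"] = dmrs.get("n_sites", 0)
        out["areaStat"] = dmrs.get("areaStat", 0.0)
        means = dmrs.get("group_means")
        out["group_means"] = ([_pack_means(m) for m in means]
                              if means is not None else ".")
    buf = io.StringIO()
    buf.write("# BED6+: " + "\t".join(DMR_BED_COLUMNS) + "\n")
    out.to_csv(buf, sep="\t", index=False, header=False,
               float_format="%.10g", columns=DMR_BED_COLUMNS if len(out) else None)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_dmr_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=DMR_BED_COLUMNS, dtype={"chrom": str})
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "name",
                                     "n_significant", "direction", "context",
                                     "term", "n_sites", "areaStat", "group_means"])
    df["group_means"] = df["group_means"].map(_unpack_means)
    df = df.rename(columns={"score": "n_significant", "strand": "direction"})
    return df
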