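"""Synthetic multi-species, multi-cell-type bisulfite cohort with planted DMRs.

Emulates the study design the pipeline targets: three primate species
(human, chimpanzee, macaque = outgroup) × two sorted nuclei populations
(NeuN+ neurons, OLIG2+ oligodendrocytes), ~11–25 individuals per group,
negative-binomial read coverage around 20×, beta-distributed
between-individual variation in fractional methylation, imperfect bisulfite
conversion, and lineage-specific orthology loss that is much faster for CG
than for CH sites. Differentially methylated regions of every evolutionary
class are planted at configured effect sizes and reported as ground truth.

Noise model, per individual i and site s:

    coverage_is ~ NegBin(mean = f_i * mean_coverage, dispersion)
    p_is        ~ Beta(mu_s(group) * kappa, (1 - mu_s(group)) * kappa)
    meth_is     ~ Binomial(coverage_is, 1 - c_i * (1 - p_is))

where f_i is a per-individual depth factor, kappa the between-individual
concentration, and c_i the bisulfite conversion rate — a failed conversion
reads an unmethylated cytosine as methylated, which is exactly what the
lambda-phage spike-in conversion estimate measures.

CG records are emitted already strand-collapsed (one + strand record per CG
dinucleotide); CH cytosines are strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (CELL_TYPES, MethylationTable, OrthologyMap,
                         validate_sample_sheet)

EVO_CLASSES = (
    "conserved_celltype",
    "human_specific_hypo",
    "human_specific_hyper",
    "chimp_specific_hypo",
    "chimp_specific_hyper",
    "celltype_restricted_species_change",
)

GROUPS = [(sp, ct) for sp in ("human", "chimpanzee", "macaque")
          for ct in CELL_TYPES]


@dataclass(frozen=True)
class PlantedDmr:
    """One requested DMR: class, context, span and effect in fraction units."""

    evo_class: str
    context: str = "CG"
    length: int = 400
    effect: float = 0.28
    direction: int = 1          # +1 = derived state is hypermethylated
    cell_type: str | None = None  # tag for cell-type-restricted / CH classes

    def __post_init__(self):
        if self.evo_class not in EVO_CLASSES:
            raise ValueError(f"unknown evo class {self.evo_class!r}")
        if not 0 < self.effect < 1:
            raise ValueError("effect must be in (0, 1)")


def default_roster() -> list[PlantedDmr]:
    """Every evolutionary class, CG and CH, at 25–30-point effects."""
    roster: list[PlantedDmr] = []
    for d in (1, -1):
        for _ in range(4):
            roster.append(PlantedDmr("conserved_celltype", "CG", 400, 0.30, d))
    for cls, d in (("human_specific_hypo", -1), ("human_specific_hyper", 1),
                   ("chimp_specific_hypo", -1), ("chimp_specific_hyper", 1)):
        for _ in range(6):
            roster.append(PlantedDmr(cls, "CG", 400, 0.28, d))
    for d in (1, -1):
        for _ in range(3):
            roster.append(PlantedDmr("celltype_restricted_species_change",
                                     "CG", 400, 0.30, d, cell_type="NeuN"))
    # CH gains are neuronal; plant them in NeuN+ only
    for cls, d in (("human_specific_hyper", 1), ("chimp_specific_hyper", 1)):
        for _ in range(4):
            roster.append(PlantedDmr(cls, "CH", 300, 0.25, d,
                                     cell_type="NeuN"))
    return roster


def _default_n_individuals() -> dict:
    # the cohort sizes of the emulated study design
    return {("human", "NeuN"): 25, ("human", "OLIG2"): 20,
            ("chimpanzee", "NeuN"): 11, ("chimpanzee", "OLIG2"): 11,
            ("macaque", "NeuN"): 15, ("macaque", "OLIG2"): 13}


@dataclass
class SimulationConfig:
    """Desk-scale twin of the study conditions. All rates are fractions.

    Defaults: 2 × 50 kb chromosomes carrying ~5,000 CG and ~15,000 CH sites,
    cohort sizes as in the emulated design, 20.6× mean coverage, equal CG
    baselines across cell types (so a roster-free run is an exact null for
    the cell-type term) and strongly neuron-biased CH baselines, conversion
    rates uniform in (0.9955, 0.9995), and orthology retention tuned so the
    realized 3-way-conserved fraction of CG sites (~0.35) sits far below that
    of CH sites (~0.7).
    """

    chrom_sizes: dict = field(default_factory=lambda: {"chr1": 50_000,
                                                       "chr2": 50_000})
    n_cg_sites: int = 5_000
    n_ch_sites: int = 15_000
    n_individuals: dict = field(default_factory=_default_n_individuals)
    mean_coverage: float = 20.6
    coverage_dispersion: float = 10.0   # NB size; var = mu + mu^2/size
    coverage_sample_sd: float = 0.15    # lognormal sd of per-individual factor
    baseline_cg: dict = field(default_factory=lambda: {"NeuN": 0.77,
                                                       "OLIG2": 0.77})
    baseline_ch: dict = field(default_factory=lambda: {"NeuN": 0.06,
                                                       "OLIG2": 0.01})
    site_sd: float = 0.04               # shared site-to-site baseline jitter
    kappa: float = 120.0                # between-individual beta concentration
    conversion_range: tuple = (0.9955, 0.9995)
    alignment_retention: dict = field(default_factory=lambda: {
        "chimpanzee": 0.98, "macaque": 0.95})
    block_mean_len: int = 2_000
    cg_site_loss: dict = field(default_factory=lambda: {
        "chimpanzee": 0.15, "macaque": 0.50})
    ch_site_loss: dict = field(default_factory=lambda: {
        "chimpanzee": 0.05, "macaque": 0.10})
    sex_effect: float = 0.0
    age_effects: tuple = (0.0, 0.0)     # middle, old vs young
    gc_window: int = 200
    roster: list = field(default_factory=default_roster)
    seed: int = 0

    def __post_init__(self):
        for d in (self.baseline_cg, self.baseline_ch):
            for v in d.values():
                if not 0 < v < 1:
                    raise ValueError("baselines must be in (0, 1)")
        lo, hi = self.conversion_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("conversion_range must lie in [0, 1]")

    def with_roster(self, roster) -> "SimulationConfig":
        return replace(self, roster=list(roster))


def null_config(seed: int = 0, **kw) -> SimulationConfig:
    """Default scenario with nothing planted (exact null for every term)."""
    return SimulationConfig(roster=[], seed=seed, **kw)


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    """Site coordinates, per-lineage presence masks and a composition track."""

    sites: pd.DataFrame                    # chrom pos strand context
    presence: dict = field(repr=False)     # species -> bool array over sites
    gc_track: pd.DataFrame = field(repr=False)  # chrom start end gc_frac cg_count


def _sub_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31),
                                                         stream]))


def _draw_blocks(rng, size: int, retention: float, mean_len: int) -> np.ndarray:
    """Alternating alignable/lost segments with the target alignable fraction."""
    if retention >= 1.0:
        return np.array([[0, size]], dtype=np.int64)
    edges = [0]
    while edges[-1] < size:
        edges.append(edges[-1] + max(50, int(rng.exponential(mean_len))))
    edges[-1] = size
    keep = rng.random(len(edges) - 1) < retention
    blocks = [[edges[i], edges[i + 1]] for i in range(len(edges) - 1) if keep[i]]
    if not blocks:  # degenerate tiny chromosome: keep one block
        blocks = [[0, min(size, mean_len)]]
    # merge adjacent kept segments
    merged = [blocks[0]]
    for s, e in blocks[1:]:
        if s == merged[-1][1]:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def simulate_scaffold(config: SimulationConfig
                      ) -> tuple[Scaffold, OrthologyMap, pd.DataFrame]:
    """Site placement, orthology structure, gene tiling and GC track.

    CG and CH cytosines are scattered uniformly over the chromosomes; each
    non-focal lineage loses (a) whole alignment blocks and (b) individual
    sites on top, with per-context site-loss rates (CG ≫ CH). Genes tile the
    scaffold with intergenic gaps. Raises if the planted roster cannot fit.
    """
    rng = _sub_rng(config.seed, 1)
    total_len = sum(config.chrom_sizes.values())
    need = sum(p.length for p in config.roster) + 600 * max(len(config.roster), 1)
    if need > total_len:
        raise ValueError(f"planted roster needs ~{need} bp, scaffold has "
                         f"{total_len} bp")

    frames = []
    for chrom, size in config.chrom_sizes.items():
        frac = size / total_len
        n_cg = int(round(config.n_cg_sites * frac))
        n_ch = int(round(config.n_ch_sites * frac))
        cg_pos = np.sort(rng.choice(size - 1, size=n_cg, replace=False))
        ch_pos = np.sort(rng.choice(size, size=n_ch, replace=False))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": cg_pos, "strand": "+", "context": "CG"}))
        frames.append(pd.DataFrame({
            "chrom": chrom, "pos": ch_pos,
            "strand": rng.choice(["+", "-"], size=n_ch), "context": "CH"}))
    sites = (pd.concat(frames, ignore_index=True)
             .drop_duplicates(["chrom", "pos", "strand"])
             .sort_values(["chrom", "pos", "strand"]).reset_index(drop=True))
    is_cg = (sites["context"] == "CG").to_numpy()

    block_rows = []
    presence = {"human": np.ones(len(sites), dtype=bool)}
    for sp in ("chimpanzee", "macaque"):
        mask = np.zeros(len(sites), dtype=bool)
        for chrom, size in config.chrom_sizes.items():
            blocks = _draw_blocks(rng, size,
                                  config.alignment_retention.get(sp, 1.0),
                                  config.block_mean_len)
            for s, e in blocks:
                block_rows.append((sp, chrom, int(s), int(e)))
            in_chrom = (sites["chrom"] == chrom).to_numpy()
            pos = sites["pos"].to_numpy()[in_chrom]
            idx = np.searchsorted(blocks[:, 0], pos, side="right") - 1
            ok = idx >= 0
            ok[ok] = pos[ok] < blocks[idx[ok], 1]
            mask[in_chrom] = ok
        lost_cg = rng.random(len(sites)) < config.cg_site_loss.get(sp, 0.0)
        lost_ch = rng.random(len(sites)) < config.ch_site_loss.get(sp, 0.0)
        mask &= ~np.where(is_cg, lost_cg, lost_ch)
        presence[sp] = mask
    omap = OrthologyMap(pd.DataFrame(block_rows,
                                     columns=["species", "chrom", "start", "end"]))

    gene_rows, gid = [], 0
    for chrom, size in config.chrom_sizes.items():
        pos = 500
        while pos + 1500 < size:
            gid += 1
            gene_rows.append((chrom, pos, pos + 1500, f"gene_{gid:04d}", 0,
                              "+" if gid % 2 else "-"))
            pos += 3000
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end",
                                             "gene_id", "score", "strand"])

    gc_rows = []
    for chrom, size in config.chrom_sizes.items():
        starts = np.arange(0, size, config.gc_window)
        base = 0.42 + 0.08 * np.sin(starts / 4000.0)
        gc = np.clip(base + rng.normal(0, 0.02, len(starts)), 0.2, 0.8)
        in_chrom = sites[(sites["chrom"] == chrom)
                         & (sites["context"] == "CG")]["pos"].to_numpy()
        cg_count = np.histogram(in_chrom,
                                bins=np.append(starts, size))[0]
        gc_rows.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": np.minimum(starts + config.gc_window, size),
            "gc_frac": gc, "cg_count": cg_count}))
    gc_track = pd.concat(gc_rows, ignore_index=True)

    return Scaffold(sites, presence, gc_track), omap, genes


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def emit_truth(config: SimulationConfig) -> pd.DataFrame:
    """Place the roster on the scaffold as mutually disjoint intervals.

    Deterministic under the config seed; intervals are separated by at least
    600 bp so that independently planted regions can never merge during DMR
    calling. Columns: chrom, start, end, context, evo_class, effect,
    direction, cell_type.
    """
    rng = _sub_rng(config.seed, 2)
    roster = list(config.roster)
    if not roster:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "evo_class", "effect", "direction",
                                     "cell_type"])
    order = rng.permutation(len(roster))
    chroms = list(config.chrom_sizes.items())
    margin = 600
    rows = []
    ci, cursor = 0, margin
    for k in order:
        p = roster[k]
        while ci < len(chroms) and cursor + p.length + margin > chroms[ci][1]:
            ci += 1
            cursor = margin
        if ci >= len(chroms):
            raise ValueError("planted roster exceeds scaffold capacity")
        start = cursor + int(rng.integers(0, 200))
        rows.append((chroms[ci][0], start, start + p.length, p.context,
                     p.evo_class, p.effect, p.direction, p.cell_type))
        cursor = start + p.length + margin
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "context",
                                        "evo_class", "effect", "direction",
                                        "cell_type"])
    truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    ends = truth.groupby("chrom")["end"].shift()
    if ((truth["start"] < ends).fillna(False)).any():
        raise ValueError("planted intervals overlap")
    return truth


def _class_delta(row, species: str, cell_type: str) -> float:
    """Planted mean shift for one truth row in one (species, cell_type) group."""
    e = row.effect * row.direction
    cls = row.evo_class
    if cls == "conserved_celltype":
        return e if cell_type == "NeuN" else 0.0
    if cls.startswith("human_specific"):
        if species != "human":
            return 0.0
        return e if row.cell_type in (None, cell_type) else 0.0
    if cls.startswith("chimp_specific"):
        if species != "chimpanzee":
            return 0.0
        return e if row.cell_type in (None, cell_type) else 0.0
    if cls == "celltype_restricted_species_change":
        return e if (species == "human" and cell_type == row.cell_type) else 0.0
    return 0.0


def true_group_means(config: SimulationConfig, scaffold: Scaffold,
                     truth: pd.DataFrame) -> dict:
    """Per-group true mean methylation per site: baseline + jitter + effects."""
    rng = _sub_rng(config.seed, 3)
    sites = scaffold.sites
    is_cg = (sites["context"] == "CG").to_numpy()
    jitter = rng.normal(0.0, config.site_sd, len(sites))
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()

    mu = {}
    for sp, ct in GROUPS:
        base = np.where(is_cg, config.baseline_cg[ct], config.baseline_ch[ct])
        m = base + jitter
        for row in truth.itertuples():
            d = _class_delta(row, sp, ct)
            if d:
                inside = (chrom == row.chrom) & (pos >= row.start) & (pos < row.end)
                inside &= is_cg if row.context == "CG" else ~is_cg
                m = np.where(inside, m + d, m)
        mu[(sp, ct)] = np.clip(m, 0.002, 0.998)
    return mu


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _make_sheet(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    lo, hi = config.conversion_range
    for sp, ct in GROUPS:
        n = config.n_individuals.get((sp, ct), 0)
        for i in range(n):
            rows.append({
                "sample_id": f"{sp}_{ct}_{i + 1:02d}",
                "species": sp, "cell_type": ct,
                "sex": "F" if i % 2 == 0 else "M",
                "age_class": ("young", "middle", "old")[i % 3],
                "conversion_rate": float(rng.uniform(lo, hi)),
            })
    return validate_sample_sheet(pd.DataFrame(rows))


def simulate_counts(config: SimulationConfig, scaffold: Scaffold,
                    truth: pd.DataFrame
                    ) -> tuple[list[MethylationTable], pd.DataFrame]:
    """Draw the per-sample count tables under the documented noise model."""
    rng = _sub_rng(config.seed, 4)
    sheet = _make_sheet(config, rng)
    mu = true_group_means(config, scaffold, truth)
    sites = scaffold.sites
    covariate_shift = {"M": config.sex_effect,
                       "middle": config.age_effects[0],
                       "old": config.age_effects[1]}

    tables = []
    for row in sheet.itertuples():
        present = scaffold.presence[row.species]
        n = int(present.sum())
        factor = float(np.exp(rng.normal(-config.coverage_sample_sd**2 / 2,
                                         config.coverage_sample_sd)))
        # NB(mean = factor * mean_coverage, size = dispersion)
        size = config.coverage_dispersion
        p_nb = size / (size + factor * config.mean_coverage)
        cov = rng.negative_binomial(size, p_nb, n)
        m = mu[(row.species, row.cell_type)][present].copy()
        m = m + covariate_shift.get(row.sex, 0.0) + covariate_shift.get(
            row.age_class, 0.0)
        m = np.clip(m, 0.002, 0.998)
        p_i = rng.beta(m * config.kappa, (1.0 - m) * config.kappa)
        apparent = 1.0 - row.conversion_rate * (1.0 - p_i)
        meth = rng.binomial(cov, apparent)
        df = sites[present].reset_index(drop=True).copy()
        df["total_reads"] = cov
        df["meth_reads"] = meth
        df = df[df["total_reads"] > 0].reset_index(drop=True)
        tables.append(MethylationTable(row.sample_id, df))
    return tables, sheet


@dataclass
class SimBundle:
    """Everything one simulated study emits."""

    config: SimulationConfig
    scaffold: Scaffold
    orthology: OrthologyMap
    genes: pd.DataFrame
    truth: pd.DataFrame
    tables: list = field(repr=False)
    sheet: pd.DataFrame = None


def simulate_dataset(config: SimulationConfig) -> SimBundle:
    """One call for the whole input bundle; deterministic under config.seed."""
    scaffold, omap, genes = simulate_scaffold(config)
    truth = emit_truth(config)
    tables, sheet = simulate_counts(config, scaffold, truth)
    return SimBundle(config, scaffold, omap, genes, truth, tables, sheet)
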